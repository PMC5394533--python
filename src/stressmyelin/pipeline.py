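"""Pipeline driver tying the analysis stages together.

Each stage reads its declared inputs, runs the corresponding library
functions, and writes TSV/JSON outputs stamped with the configuration hash
and seed. ``run_pipeline`` pre-flights all requested stages before any
computation and writes a run log with per-stage record counts.
"""

from __future__ import annotations

import datetime
from pathlib import Path

import numpy as np
import pandas as pd

from . import array_de, fish, qpcr, stereology, synthetic
from . import io as smio
from .io import RunConfig

STAGES = ("de", "qpcr", "fish", "stereology", "report")


class PreflightError(FileNotFoundError):
    pass


def _meta(config: RunConfig) -> dict:
    return {"config_hash": config.config_hash(), "seed": config.seed, "config": config.to_dict()}


def stage_simulate(config: RunConfig) -> dict:
    """Write a complete synthetic fixture set plus its truth tables."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    matrix, expr_truth = synthetic.gen_expression(seed=seed)
    smio.write_expression_tsv(matrix, out / "expression.tsv")
    smio.write_group_map(matrix.groups, out / "groups.csv")
    annotation = pd.Series(
        {g: v["category"] for g, v in expr_truth["genes"].items()}, name="category"
    )
    smio.write_annotation(annotation, out / "annotation.csv")

    ct, ct_truth = synthetic.gen_ct_table(seed=seed)
    ct.to_csv(out / "ct.csv", index=False)

    fields, fish_truth = synthetic.gen_fish_field(seed=seed)
    nuc_rows, spot_rows = [], []
    for i, f in enumerate(fields):
        nuc = f.nuclei.copy()
        nuc.insert(0, "field_id", i)
        nuc.insert(1, "animal_id", f.animal_id)
        nuc.insert(2, "group", f.group)
        nuc.insert(3, "image_index", f.image_index)
        nuc_rows.append(nuc)
        sp = f.spots.copy()
        sp.insert(0, "field_id", i)
        spot_rows.append(sp)
    pd.concat(nuc_rows).to_csv(out / "nuclei.csv", index=False)
    pd.concat(spot_rows).to_csv(out / "spots.csv", index=False)
    smio.write_roi_json(fields[0].roi, out / "roi.json")

    phantom, ph_truth = synthetic.gen_fiber_phantom(seed=seed)
    smio.write_phantom_csv(phantom, out / "phantom.csv")
    import shapely

    smio.write_roi_json(
        fish.Roi(name="phantom_roi", polygon=shapely.box(0.0, 0.0, 2000.0, 2000.0)),
        out / "phantom_roi.json",
    )

    truth = {"expression": expr_truth, "qpcr": ct_truth, "fish": fish_truth, "phantom": ph_truth}
    smio.write_json({**_meta(config), "truth": truth}, out / "truth.json")
    return {"n_fragments": len(matrix.fragment_ids), "n_fields": len(fields),
            "n_ct_rows": len(ct), "n_fiber_segments": len(phantom.segments)}


def stage_de(config: RunConfig) -> dict:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix = smio.read_expression_tsv(config.expression, config.groups)
    annotation = smio.read_annotation(config.annotation) if config.annotation else None
    profile = array_de.cv_mean_profile(matrix)
    floor_res = array_de.detect_noise_floor(
        profile,
        span=config.lowess_span,
        linearity_r2=config.linearity_r2,
        window=config.window,
        grid_size=config.grid_size,
    )
    filtered = array_de.filter_and_floor(matrix, floor_res.floor)
    table = array_de.differential_expression(
        filtered,
        fdr_alpha=config.fdr_alpha,
        fc_threshold=config.fc_threshold,
        annotation=annotation,
    )
    summary = array_de.summarize_categories(table)
    sig = table.index[table["direction"] != "ns"]
    cluster = None
    if len(sig) >= 2:
        cluster = array_de.cluster_samples(filtered, genes=sig)
    table.to_csv(out / "de_table.tsv", sep="\t", index_label="id")
    smio.write_json(
        {
            **_meta(config),
            "noise_floor": floor_res.floor,
            "n_discarded": len(matrix.fragment_ids) - len(filtered.fragment_ids),
            "n_tested": len(filtered.fragment_ids),
            "n_up": summary.n_up,
            "n_down": summary.n_down,
            "n_down_myelin": summary.n_down_in_category,
            "pct_down_myelin": summary.pct_down_in_category,
            "sample_order": list(cluster.order) if cluster else None,
        },
        out / "de_summary.json",
    )
    return {"n_tested": len(filtered.fragment_ids), "n_up": summary.n_up, "n_down": summary.n_down}


def stage_qpcr(config: RunConfig) -> dict:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ct = smio.read_ct_csv(config.ct)
    deltas = qpcr.delta_ct(ct, reference_gene=config.reference_gene)
    rel = qpcr.ddct_fold(deltas, control_group=config.control_group)
    rel.summary.to_csv(out / "qpcr_folds.tsv", sep="\t", index=False)
    smio.write_json(
        {
            **_meta(config),
            "n_genes": int(rel.summary["gene"].nunique()),
            "folds": {
                f"{r.gene}:{r.group}": {"fold": float(r.fold), "sem": float(r.sem), "n": int(r.n)}
                for r in rel.summary.itertuples()
            },
        },
        out / "qpcr_summary.json",
    )
    return {"n_genes": int(rel.summary["gene"].nunique())}


def _fields_from_tables(nuclei: pd.DataFrame, spots: pd.DataFrame, roi) -> list:
    fields = []
    for fid, nuc in nuclei.groupby("field_id", sort=True):
        sp = spots[spots["field_id"] == fid] if "field_id" in spots.columns else spots
        fields.append(
            fish.FishField(
                nuclei=nuc[["x", "y", "eq_diameter"]].reset_index(drop=True),
                spots=sp[["x", "y", "channel"]].reset_index(drop=True),
                roi=roi,
                animal_id=str(nuc["animal_id"].iloc[0]) if "animal_id" in nuc.columns else f"a{fid}",
                group=str(nuc["group"].iloc[0]) if "group" in nuc.columns else "HC",
                image_index=int(nuc["image_index"].iloc[0]) if "image_index" in nuc.columns else 1,
            )
        )
    return fields


def stage_fish(config: RunConfig) -> dict:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    nuclei = smio.read_points_csv(config.nuclei)
    spots = smio.read_points_csv(config.spots)
    roi = smio.read_roi_json(config.roi)
    if "field_id" not in nuclei.columns:
        nuclei = nuclei.assign(field_id=0)
    fields = _fields_from_tables(nuclei, spots, roi)
    summary = fish.summarize_counts(fields, disc_factor=config.disc_factor)
    summary.to_csv(out / "fish_counts.tsv", sep="\t", index=False)
    result = {**_meta(config), "n_fields": len(fields), "group_means": {}}
    for g, sub in summary.groupby("group"):
        result["group_means"][g] = {
            "mean": float(sub["mean_count"].mean()),
            "sem": float(sub["mean_count"].sem()) if len(sub) > 1 else 0.0,
            "n_animals": int(len(sub)),
        }
    if summary["group"].nunique() == 2:
        test = fish.compare_groups(summary)
        result["t"] = test.t
        result["p"] = test.p
    smio.write_json(result, out / "fish_summary.json")
    return {"n_fields": len(fields), "n_animals": int(summary["animal_id"].nunique())}


def stage_stereology(config: RunConfig) -> dict:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    phantom = smio.read_phantom_csv(config.phantom)
    roi = smio.read_roi_json(config.phantom_roi or config.roi)
    grid = stereology.ProbeGrid(
        dx=config.dx, dy=config.dy, radius=config.radius, guard=config.guard
    )
    rng = np.random.default_rng(config.seed)
    probes = stereology.place_probes(roi.polygon, grid, config.thickness, rng=rng)
    counts = stereology.count_intersections(phantom, probes, grid, config.thickness)
    est = stereology.estimate_mfld(counts, grid, [roi.polygon.area], [config.thickness])
    pd.DataFrame({"x": probes[:, 0], "y": probes[:, 1], "q": counts}).to_csv(
        out / "stereology_counts.tsv", sep="\t", index=False
    )
    smio.write_json(
        {
            **_meta(config),
            "sum_q": est.sum_q,
            "n_probes": est.n_probes,
            "mfld": est.mfld,
            "ref_volume": est.ref_volume,
            "total_length": est.total_length,
        },
        out / "stereology_estimate.json",
    )
    return {"n_probes": est.n_probes, "sum_q": est.sum_q}


def stage_report(config: RunConfig) -> dict:
    """Cross-check stage outputs: config hashes must match; planted truths
    (if a truth.json is present) are compared with recovered values."""
    out = Path(config.out_dir)
    summaries = {}
    for name in ("de_summary", "qpcr_summary", "fish_summary", "stereology_estimate"):
        path = out / f"{name}.json"
        if path.exists():
            summaries[name] = smio.read_json(path)
    if not summaries:
        raise PreflightError(f"no stage outputs found in {out}")
    hashes = {name: s.get("config_hash") for name, s in summaries.items()}
    if len(set(hashes.values())) > 1:
        raise RuntimeError(f"mixed config hashes across outputs: {hashes}")
    report = {**_meta(config), "stages_present": sorted(summaries), "checks": {}}
    # planted truths are an input, not a stage output: no hash constraint
    truth_path = out / "truth.json"
    truth = smio.read_json(truth_path).get("truth", {}) if truth_path.exists() else {}
    if "de_summary" in summaries and "expression" in truth:
        det = summaries["de_summary"]
        report["checks"]["noise_floor"] = {
            "true": truth["expression"]["noise_floor"],
            "recovered": det["noise_floor"],
        }
    if "stereology_estimate" in summaries and "phantom" in truth:
        est = summaries["stereology_estimate"]
        true_lv = truth["phantom"]["target_lv"]
        report["checks"]["mfld"] = {
            "true_lv": true_lv,
            "recovered": est["mfld"],
            "relative_error": (est["mfld"] - true_lv) / true_lv,
        }
    if "qpcr_summary" in summaries and "qpcr" in truth:
        folds = summaries["qpcr_summary"]["folds"]
        report["checks"]["qpcr_folds"] = {
            g: {"true": tf, "recovered": folds.get(f"{g}:CSD", {}).get("fold")}
            for g, tf in truth["qpcr"]["true_folds"].items()
        }
    smio.write_json(report, out / "report.json")
    return {"stages": sorted(summaries)}


_REQUIRED_INPUTS = {
    "de": ("expression", "groups"),
    "qpcr": ("ct",),
    "fish": ("nuclei", "spots", "roi"),
    "stereology": ("phantom", "roi"),
    "report": (),
}

_STAGE_FUNCS = {
    "de": stage_de,
    "qpcr": stage_qpcr,
    "fish": stage_fish,
    "stereology": stage_stereology,
    "report": stage_report,
}


def run_pipeline(config: RunConfig, stages=("de", "qpcr", "fish", "stereology", "report")) -> dict:
    """Execute the requested stages after a pre-flight input check.

    Raises PreflightError before any computation when an input for a
    requested stage is missing. Writes ``run_log.txt`` with the seed,
    parameters, and per-stage record counts.
    """
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    missing = []
    for stage in stages:
        for attr in _REQUIRED_INPUTS[stage]:
            path = getattr(config, attr)
            if path is None or not Path(path).exists():
                missing.append(f"{stage}: {attr}={path}")
    if missing:
        raise PreflightError("missing inputs — " + "; ".join(missing))
    results = {}
    for stage in [s for s in STAGES if s in stages]:
        results[stage] = _STAGE_FUNCS[stage](config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "run_log.txt", "w") as fh:
        fh.write(f"run at {datetime.datetime.now().isoformat(timespec='seconds')}\n")
        fh.write(f"seed: {config.seed}\nconfig_hash: {config.config_hash()}\n")
        for key, val in sorted(config.to_dict().items()):
            fh.write(f"  {key}: {val}\n")
        for stage, rec in results.items():
            fh.write(f"stage {stage}: {rec}\n")
    return results
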