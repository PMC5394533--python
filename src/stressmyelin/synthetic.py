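"""Seeded generators emulating the statistical structure of each data stage.

Every generator is a pure function of its parameters and a seed, and
returns its dataset together with a TruthTable (a plain dict of the planted
ground truth) so that each analysis stage can be tested as a parameter-
recovery problem. A single global seed fans out to independent named
substreams, so adding a generator never perturbs existing fixtures.

Defaults encode the study conditions the pipeline targets: 6 animals per
group on the array, myelin genes planted with signed fold changes in the
−1.8…−1.2 range against a null background, CV inflation below a linear-
intensity noise floor, FISH positive-cell fractions producing homecage
motor-cortex counts near 45 and defeated counts near 39 per 700 μm box,
and isotropic fiber fields of exactly known total length.
"""

from __future__ import annotations

import zlib

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon

from .array_de import ExpressionMatrix
from .fish import FishField, Roi, square_roi
from .stereology import FiberPhantom

__all__ = [
    "substream",
    "gen_expression",
    "gen_fish_field",
    "gen_fiber_phantom",
    "gen_ct_table",
]


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent, named random stream derived from one global seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) % 2**31, zlib.crc32(name.encode())])
    )


# ---------------------------------------------------------------- expression


def _signed_to_log2(signed_fc: np.ndarray) -> np.ndarray:
    s = np.asarray(signed_fc, dtype=float)
    if (np.abs(s) < 1).any():
        raise ValueError("signed fold changes must have magnitude >= 1")
    out = np.empty_like(s)
    pos = s >= 1
    out[pos] = np.log2(s[pos])
    out[~pos] = -np.log2(-s[~pos])
    return out


def gen_expression(
    n_fragments: int = 2000,
    n_myelin: int = 100,
    n_per_group: int = 6,
    effect_range: tuple = (-1.8, -1.2),
    noise_floor_level: float = 32.0,
    cv_base: float = 0.12,
    cv_exponent: float = 1.0,
    signal_range: tuple = (8.0, 16384.0),
    myelin_signal_range: tuple = (128.0, 8192.0),
    seed: int = 0,
) -> tuple[ExpressionMatrix, dict]:
    """Log2 expression matrix with planted myelin down-regulation and a
    CV–mean noise floor.

    Linear intensities are lognormal around a fragment-specific expected
    level. The coefficient of variation is cv_base above the noise floor
    m0 = ``noise_floor_level`` and inflates as (m0/level)**cv_exponent
    below it, producing the rising low-intensity CV arm whose changepoint
    the noise-floor detector must recover. Myelin fragments carry a signed
    fold change drawn uniformly from ``effect_range`` (applied to the CSD
    group); all other fragments are null.
    """
    if not 0 <= n_myelin < n_fragments:
        raise ValueError("need 0 <= n_myelin < n_fragments")
    lo, hi = effect_range
    if abs(lo) < 1 or abs(hi) < 1:
        raise ValueError("effect_range is on the signed fold-change scale (|fc| >= 1)")
    rng = substream(seed, "expression")
    ids = [f"frag_{i:05d}" for i in range(n_fragments)]
    myelin_idx = np.sort(rng.choice(n_fragments, size=n_myelin, replace=False))
    is_myelin = np.zeros(n_fragments, dtype=bool)
    is_myelin[myelin_idx] = True

    signal = np.exp(rng.uniform(np.log(signal_range[0]), np.log(signal_range[1]), n_fragments))
    signal[is_myelin] = np.exp(
        rng.uniform(np.log(myelin_signal_range[0]), np.log(myelin_signal_range[1]), n_myelin)
    )
    signed_fc = np.ones(n_fragments)
    signed_fc[is_myelin] = rng.uniform(min(lo, hi), max(lo, hi), n_myelin)
    log2fc = _signed_to_log2(signed_fc)

    samples = [f"HC_{i + 1}" for i in range(n_per_group)] + [
        f"CSD_{i + 1}" for i in range(n_per_group)
    ]
    group_effect = np.array([0.0] * n_per_group + [1.0] * n_per_group)
    # expected linear level per fragment × sample
    level = signal[:, None] * 2.0 ** (log2fc[:, None] * group_effect[None, :])
    cv = cv_base * np.maximum(1.0, noise_floor_level / level) ** cv_exponent
    sigma = np.sqrt(np.log1p(cv**2))
    noise = rng.standard_normal(level.shape)
    values = level * np.exp(sigma * noise - sigma**2 / 2.0)

    matrix = ExpressionMatrix(
        values=pd.DataFrame(np.log2(values), index=ids, columns=samples),
        groups=pd.Series(["HC"] * n_per_group + ["CSD"] * n_per_group, index=samples),
    )
    truth = {
        "kind": "expression",
        "seed": int(seed),
        "noise_floor": float(noise_floor_level),
        "params": {
            "n_fragments": n_fragments,
            "n_myelin": n_myelin,
            "n_per_group": n_per_group,
            "effect_range": list(effect_range),
            "cv_base": cv_base,
            "cv_exponent": cv_exponent,
        },
        "genes": {
            ids[i]: {
                "signed_fc": float(signed_fc[i]),
                "category": "myelin" if is_myelin[i] else "other",
            }
            for i in range(n_fragments)
        },
    }
    return matrix, truth


# ---------------------------------------------------------------- FISH fields


def _uniform_in_polygon(rng: np.random.Generator, poly: Polygon, n: int) -> np.ndarray:
    minx, miny, maxx, maxy = poly.bounds
    pts = np.empty((0, 2))
    while len(pts) < n:
        cand = rng.uniform([minx, miny], [maxx, maxy], size=(max(32, 2 * (n - len(pts))), 2))
        keep = shapely.intersects_xy(poly, cand[:, 0], cand[:, 1])
        pts = np.vstack([pts, cand[keep]])
    return pts[:n]


def _positive_spot_count(rng: np.random.Generator, lam: float) -> int:
    k = 0
    while k == 0:  # zero-truncated Poisson
        k = int(rng.poisson(lam))
    return k


def gen_fish_field(
    positive_frac: dict | None = None,
    nuclei_density: float = 6.0e-4,
    spots_lambda: float = 3.0,
    roi: Roi | None = None,
    n_images: int = 4,
    n_animals: int = 5,
    diam_mean: float = 8.0,
    diam_sd: float = 1.0,
    animal_frac_sd: float = 0.03,
    seed: int = 0,
) -> tuple[list[FishField], dict]:
    """FISH fields with group-dependent positive-cell fractions.

    Nuclei fall uniformly in the ROI at ``nuclei_density`` cells/μm² with
    truncated-normal equivalent diameters (default 8 ± 1 μm). Planted-
    positive cells receive a zero-truncated Poisson(``spots_lambda``)
    number of target-channel spots uniform inside their own calling disc;
    planted-negative cells receive none (a neighbour's spot may still fall
    inside their disc — the measured fraction therefore slightly exceeds
    the planted one, as in crowded tissue). Every cell receives control-
    channel spots. Defaults are calibrated so that measured counts in the
    default 700 μm motor-cortex box average ≈45 (HC) and ≈39 (CSD).

    ``positive_frac`` defaults to {"HC": 0.128, "CSD": 0.110} (planted,
    pre-crowding fractions, calibrated by regressing measured counts on
    planted fractions across seeds).
    """
    if positive_frac is None:
        positive_frac = {"HC": 0.128, "CSD": 0.110}
    for g, f in positive_frac.items():
        if not 0 <= f <= 1:
            raise ValueError(f"positive fraction for {g} must be in [0, 1]")
    if spots_lambda <= 0:
        raise ValueError("spots_lambda must be > 0")
    roi = roi if roi is not None else square_roi("M1", center=(350.0, 350.0))
    rng = substream(seed, "fish")
    n_expected = nuclei_density * roi.polygon.area
    fields: list[FishField] = []
    truth_animals: dict = {}
    for group, frac in positive_frac.items():
        for ai in range(n_animals):
            animal = f"{group}_{ai + 1}"
            afrac = float(np.clip(rng.normal(frac, animal_frac_sd), 0.0, 1.0))
            truth_animals[animal] = {"group": group, "positive_frac": afrac}
            for img in range(1, n_images + 1):
                n_nuc = rng.poisson(n_expected)
                centers = _uniform_in_polygon(rng, roi.polygon, n_nuc)
                diam = np.abs(rng.normal(diam_mean, diam_sd, n_nuc))
                diam[diam <= 0.1] = 0.1
                positive = rng.random(n_nuc) < afrac
                sx, sy, chan = [], [], []
                for j in range(n_nuc):
                    n_target = _positive_spot_count(rng, spots_lambda) if positive[j] else 0
                    n_control = 1 + int(rng.poisson(1.0))
                    for n_sp, ch in ((n_target, "target"), (n_control, "control")):
                        if n_sp == 0:
                            continue
                        rr = diam[j] * np.sqrt(rng.random(n_sp))
                        th = rng.uniform(0, 2 * np.pi, n_sp)
                        sx.extend(centers[j, 0] + rr * np.cos(th))
                        sy.extend(centers[j, 1] + rr * np.sin(th))
                        chan.extend([ch] * n_sp)
                fields.append(
                    FishField(
                        nuclei=pd.DataFrame(
                            {"x": centers[:, 0], "y": centers[:, 1], "eq_diameter": diam}
                        ),
                        spots=pd.DataFrame({"x": sx, "y": sy, "channel": chan}),
                        roi=roi,
                        animal_id=animal,
                        group=group,
                        image_index=img,
                    )
                )
    truth = {
        "kind": "fish",
        "seed": int(seed),
        "positive_frac": {g: float(f) for g, f in positive_frac.items()},
        "animals": truth_animals,
        "params": {
            "nuclei_density": nuclei_density,
            "spots_lambda": spots_lambda,
            "n_images": n_images,
            "n_animals": n_animals,
        },
    }
    return fields, truth


# ------------------------------------------------------------ fiber phantoms


def _isotropic_directions(rng: np.random.Generator, n: int) -> np.ndarray:
    z = rng.uniform(-1.0, 1.0, n)
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    s = np.sqrt(1.0 - z**2)
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), z])


def _clip_segments_to_box(p0, p1, lo, hi):
    """Liang–Barsky clip of segments to an axis-aligned box; returns clipped
    endpoint arrays (segments reduced to empty are dropped)."""
    d = p1 - p0
    t0 = np.zeros(len(p0))
    t1 = np.ones(len(p0))
    for axis in range(3):
        da = d[:, axis]
        pa = p0[:, axis]
        with np.errstate(divide="ignore", invalid="ignore"):
            tl = (lo[axis] - pa) / da
            th = (hi[axis] - pa) / da
        tmin = np.where(da >= 0, tl, th)
        tmax = np.where(da >= 0, th, tl)
        par = da == 0
        inside = (pa >= lo[axis]) & (pa <= hi[axis])
        tmin = np.where(par, np.where(inside, 0.0, 1.0), tmin)
        tmax = np.where(par, np.where(inside, 1.0, 0.0), tmax)
        t0 = np.maximum(t0, tmin)
        t1 = np.minimum(t1, tmax)
    keep = t1 > t0
    q0 = p0[keep] + t0[keep, None] * d[keep]
    q1 = p0[keep] + t1[keep, None] * d[keep]
    return q0, q1


def gen_fiber_phantom(
    target_lv: float = 0.05,
    roi: Polygon | None = None,
    thickness: float = 16.0,
    mean_segment_len: float = 150.0,
    orientation: str = "isotropic",
    seed: int = 0,
    max_chords: int = 10_000_000,
) -> tuple[FiberPhantom, dict]:
    """Isotropic fiber field of exactly known length density.

    Chord centers are sampled uniformly in the slab dilated by half a chord
    length (so length density is stationary inside the slab), directions
    uniformly on the sphere ("vertical" forces all fibers along z for bias
    studies), and each chord is clipped to the slab. Chords accumulate until
    the total clipped length reaches target_lv × slab volume; the final
    chord is trimmed so the recorded true_total_length is exact.
    """
    if target_lv <= 0:
        raise ValueError("target_lv must be > 0")
    roi = roi if roi is not None else shapely.box(0.0, 0.0, 2000.0, 2000.0)
    minx, miny, maxx, maxy = roi.bounds
    rect = abs(roi.area - (maxx - minx) * (maxy - miny)) < 1e-9 * max(roi.area, 1.0)
    volume = roi.area * thickness
    target_length = target_lv * volume
    rng = substream(seed, "phantom")
    half = mean_segment_len / 2.0
    lo = np.array([minx, miny, 0.0])
    hi = np.array([maxx, maxy, thickness])
    total = 0.0
    pieces: list[np.ndarray] = []
    n_drawn = 0
    batch = max(256, int(target_length / mean_segment_len / 4) + 1)
    while total < target_length:
        n_drawn += batch
        if n_drawn > max_chords:
            raise RuntimeError("target length density unreachable within max_chords")
        centers = rng.uniform(lo - half, hi + half, size=(batch, 3))
        if orientation == "isotropic":
            dirs = _isotropic_directions(rng, batch)
        elif orientation == "vertical":
            dirs = np.tile([0.0, 0.0, 1.0], (batch, 1))
        else:
            raise ValueError(f"unknown orientation {orientation!r}")
        p0 = centers - half * dirs
        p1 = centers + half * dirs
        if rect:
            q0, q1 = _clip_segments_to_box(p0, p1, lo, hi)
            clipped = list(np.stack([q0, q1], axis=1))
        else:
            clipped = []
            for s0, s1 in zip(p0, p1):
                clipped.extend(_clip_to_prism(s0, s1, roi, thickness))
        for seg in clipped:
            length = float(np.linalg.norm(seg[1] - seg[0]))
            if length <= 0:
                continue
            if total + length > target_length:
                frac = (target_length - total) / length
                seg = np.stack([seg[0], seg[0] + frac * (seg[1] - seg[0])])
                length = target_length - total
            pieces.append(seg)
            total += length
            if total >= target_length:
                break
    phantom = FiberPhantom(
        segments=np.array(pieces),
        true_total_length=target_length,
        orientation_model=orientation,
    )
    truth = {
        "kind": "phantom",
        "seed": int(seed),
        "target_lv": float(target_lv),
        "true_total_length": float(target_length),
        "volume": float(volume),
        "thickness": float(thickness),
        "orientation": orientation,
        "n_segments": len(pieces),
    }
    return phantom, truth


def _clip_to_prism(s0: np.ndarray, s1: np.ndarray, roi: Polygon, thickness: float):
    """Clip one 3-D segment to the polygon × [0, thickness] prism."""
    # z-clip first (interval arithmetic), then xy-clip against the polygon
    d = s1 - s0
    t0, t1 = 0.0, 1.0
    if d[2] != 0:
        ta, tb = sorted([(0.0 - s0[2]) / d[2], (thickness - s0[2]) / d[2]])
        t0, t1 = max(t0, ta), min(t1, tb)
    elif not 0.0 <= s0[2] <= thickness:
        return []
    if t1 <= t0:
        return []
    a = s0 + t0 * d
    b = s0 + t1 * d
    from shapely.geometry import LineString, Point

    if abs(b[0] - a[0]) < 1e-12 and abs(b[1] - a[1]) < 1e-12:
        return [np.stack([a, b])] if roi.intersects(Point(a[0], a[1])) else []
    inter = roi.intersection(LineString([(a[0], a[1]), (b[0], b[1])]))
    if inter.is_empty:
        return []
    parts = getattr(inter, "geoms", [inter])
    out = []
    dxy = np.array([b[0] - a[0], b[1] - a[1]])
    denom = float(dxy @ dxy)
    for part in parts:
        if part.geom_type != "LineString":
            continue
        coords = np.asarray(part.coords)
        u0 = float((coords[0] - a[:2]) @ dxy) / denom
        u1 = float((coords[-1] - a[:2]) @ dxy) / denom
        q0 = a + u0 * (b - a)
        q1 = a + u1 * (b - a)
        out.append(np.stack([q0, q1]))
    return out


# ------------------------------------------------------------------ Ct tables

DEFAULT_TRUE_FOLDS = {
    # down-regulated myelin genes at the fold magnitudes the array stage
    # plants, plus one strongly induced inflammation gene
    "Mog": 1 / 1.75,
    "Ermn": 1 / 1.71,
    "Trf": 1 / 1.63,
    "Mobp": 1 / 1.55,
    "Lcn2": 2.43,
}


def gen_ct_table(
    true_folds: dict | None = None,
    n_per_group: dict | None = None,
    replicate_sd: float = 0.2,
    n_replicates: int = 3,
    reference_gene: str = "Gapdh",
    sample_shift_sd: float = 0.3,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Ct table with planted per-gene fold changes (CSD relative to HC).

    A CSD fold f shifts the target ΔCt by −log2(f); per-sample global
    shifts (loading/efficiency, sd ``sample_shift_sd`` cycles) affect all
    genes of a sample equally and cancel under reference normalization;
    replicate noise has sd ``replicate_sd`` cycles.
    """
    true_folds = dict(DEFAULT_TRUE_FOLDS) if true_folds is None else dict(true_folds)
    if any(f <= 0 for f in true_folds.values()):
        raise ValueError("true folds must be > 0")
    n_per_group = {"HC": 6, "CSD": 5} if n_per_group is None else dict(n_per_group)
    rng = substream(seed, "qpcr")
    gene_base = {g: float(rng.uniform(22.0, 28.0)) for g in true_folds}
    gene_base[reference_gene] = 18.0
    rows = []
    for group, n in n_per_group.items():
        for si in range(n):
            sample = f"{group}_{si + 1}"
            shift = rng.normal(0.0, sample_shift_sd)
            for gene, base in gene_base.items():
                effect = 0.0
                if gene != reference_gene and group == "CSD":
                    effect = -np.log2(true_folds[gene])
                for rep in range(1, n_replicates + 1):
                    rows.append(
                        {
                            "sample": sample,
                            "group": group,
                            "gene": gene,
                            "replicate": rep,
                            "ct": base + shift + effect + rng.normal(0.0, replicate_sd),
                        }
                    )
    table = pd.DataFrame(rows)
    truth = {
        "kind": "qpcr",
        "seed": int(seed),
        "true_folds": {g: float(f) for g, f in true_folds.items()},
        "reference_gene": reference_gene,
        "params": {
            "n_per_group": n_per_group,
            "replicate_sd": replicate_sd,
            "n_replicates": n_replicates,
        },
    }
    return table, truth
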