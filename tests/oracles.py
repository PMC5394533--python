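"""Independent brute-force oracles used only by the test suite."""

from __future__ import annotations

import math

import numpy as np


def brute_force_calls(nuclei, spots, channel: str = "target", disc_factor: float = 2.0):
    """All-pairs positive-cell calling with plain Python loops."""
    out = []
    spot_list = [
        (float(s.x), float(s.y)) for s in spots.itertuples() if s.channel == channel
    ]
    for n in nuclei.itertuples():
        radius = disc_factor / 2.0 * float(n.eq_diameter)
        positive = any(
            math.dist((float(n.x), float(n.y)), s) <= radius for s in spot_list
        )
        out.append(positive)
    return np.array(out, dtype=bool)


def crossing_number_contains(vertices, x: float, y: float, eps: float = 1e-12) -> bool:
    """Point-in-polygon via the crossing-number (even–odd) rule; points within
    eps of an edge count as inside (boundary inclusive)."""
    verts = [(float(a), float(b)) for a, b in vertices]
    n = len(verts)
    # boundary check: distance to each edge segment
    for i in range(n):
        (x1, y1), (x2, y2) = verts[i], verts[(i + 1) % n]
        dx, dy = x2 - x1, y2 - y1
        L2 = dx * dx + dy * dy
        t = 0.0 if L2 == 0 else max(0.0, min(1.0, ((x - x1) * dx + (y - y1) * dy) / L2))
        if math.dist((x, y), (x1 + t * dx, y1 + t * dy)) <= eps:
            return True
    crossings = 0
    for i in range(n):
        (x1, y1), (x2, y2) = verts[i], verts[(i + 1) % n]
        if (y1 > y) != (y2 > y):
            x_at = x1 + (y - y1) / (y2 - y1) * (x2 - x1)
            if x_at > x:
                crossings += 1
    return crossings % 2 == 1


def dense_sampling_counts(phantom, probes, grid, thickness: float, step: float = 0.1):
    """Hemisphere-boundary crossings by marching along each segment at
    ``step`` μm and counting inside/outside transitions of the solid probe."""
    zc = grid.guard if grid.z_placement is None else grid.z_placement
    r = grid.radius
    out = []
    for cx, cy in np.asarray(probes, dtype=float).reshape(-1, 2):
        c = np.array([cx, cy, zc])
        q = 0
        for seg in phantom.segments:
            length = np.linalg.norm(seg[1] - seg[0])
            n = max(2, int(np.ceil(length / step)) + 1)
            t = np.linspace(0.0, 1.0, n)
            pts = seg[0] + t[:, None] * (seg[1] - seg[0])
            inside = (np.linalg.norm(pts - c, axis=1) <= r) & (pts[:, 2] >= zc)
            q += int(np.abs(np.diff(inside.astype(int))).sum())
        out.append(q)
    return np.array(out, dtype=int)


def bh_step_up(pvals):
    """Literal step-up definition of the Benjamini–Hochberg adjustment."""
    p = list(map(float, pvals))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adjusted = [None] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adjusted[i] = running
    return adjusted
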