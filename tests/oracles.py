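"""Independent brute-force oracles used by the test suite.

Everything here recomputes quantities the package measures, through a
deliberately different code path: an explicit cell-by-cell boundary walk
for contours and contact, triple loops for plane scans, an if/else chain
for the staging rules, and definitional sums of squares for ANOVA.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import ndimage

# ---------------------------------------------------------------------------
# marching-squares boundary walk (doubled integer coordinates, no floats)


def _cell_segments(tl, tr, bl, br, r, c):
    """Segments of one 2x2 cell in doubled coordinates.

    Returns a list of (endpoint_a, endpoint_b, probe_inside_candidate_a,
    probe_candidate_b) where probes follow the half-up rounding convention
    of the implementation: vertical straight segments probe the two bottom
    corners, horizontal straight segments the two right corners, diagonal
    segments the cut corner and its diagonal opposite.
    """
    T = (2 * r, 2 * c + 1)
    B = (2 * r + 2, 2 * c + 1)
    L = (2 * r + 1, 2 * c)
    R = (2 * r + 1, 2 * c + 2)
    p_tl, p_tr, p_bl, p_br = (r, c), (r, c + 1), (r + 1, c), (r + 1, c + 1)
    inside = (tl, tr, bl, br)
    n_in = sum(inside)
    if n_in == 0 or n_in == 4:
        return []
    if n_in == 2 and tl == br and tr == bl:
        raise ValueError("saddle cell")  # callers filter these masks out
    if n_in in (1, 3):
        # find the odd corner (inside if n_in==1, outside if n_in==3)
        odd_val = n_in == 1
        if tl == odd_val:
            return [(T, L, p_tl, p_br)]
        if tr == odd_val:
            return [(T, R, p_tr, p_bl)]
        if bl == odd_val:
            return [(B, L, p_bl, p_tr)]
        return [(B, R, p_br, p_tl)]
    # two adjacent corners inside: horizontal segments probe the two right
    # corners, vertical segments the two bottom corners (half-up rounding)
    if (tl and tr) or (bl and br):
        return [(L, R, p_tr, p_br)]
    return [(T, B, p_bl, p_br)]


def has_saddle(mask: np.ndarray) -> bool:
    m = np.pad(mask.astype(bool), 1)
    tl = m[:-1, :-1]
    tr = m[:-1, 1:]
    bl = m[1:, :-1]
    br = m[1:, 1:]
    return bool(((tl == br) & (tr == bl) & (tl != tr)).any())


def walk_contour(mask: np.ndarray) -> list[tuple[int, int]]:
    """Ordered closed boundary walk of a hole-filled mask, doubled coords.

    Returns the longest closed loop of marching-squares segments.
    """
    m = np.pad(ndimage.binary_fill_holes(mask), 1)
    segments = []
    for r in range(m.shape[0] - 1):
        for c in range(m.shape[1] - 1):
            segments.extend(
                (a, b)
                for a, b, _, _ in _cell_segments(
                    m[r, c], m[r, c + 1], m[r + 1, c], m[r + 1, c + 1], r, c
                )
            )
    adj: dict[tuple[int, int], list[tuple[int, int]]] = {}
    for a, b in segments:
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)
    unused = {frozenset(s) for s in segments}
    loops = []
    while unused:
        a, b = tuple(next(iter(unused)))
        loop = [a, b]
        unused.discard(frozenset((a, b)))
        while loop[-1] != loop[0]:
            cur = loop[-1]
            nxt = [p for p in adj[cur] if frozenset((cur, p)) in unused]
            if not nxt:
                break
            loop.append(nxt[0])
            unused.discard(frozenset((cur, nxt[0])))
        loops.append(loop)
    return max(loops, key=len)


def smooth_loop(points: list[tuple[float, float]], window: int) -> list[tuple[float, float]]:
    """Circular moving average of a closed loop (first == last point)."""
    pts = points[:-1]
    n = len(pts)
    half = window // 2
    out = []
    for i in range(n):
        rs = sum(pts[(i + k) % n][0] for k in range(-half, half + 1)) / window
        cs = sum(pts[(i + k) % n][1] for k in range(-half, half + 1)) / window
        out.append((rs, cs))
    out.append(out[0])
    return out


def oracle_perimeter(mask: np.ndarray, spacing=(1.0, 1.0), window: int = 5) -> float:
    """Smoothed boundary-walk perimeter in mm."""
    loop = [(p[0] / 2.0, p[1] / 2.0) for p in walk_contour(mask)]
    loop = smooth_loop(loop, window)
    total = 0.0
    for (r0, c0), (r1, c1) in zip(loop[:-1], loop[1:]):
        total += math.hypot((r1 - r0) * spacing[0], (c1 - c0) * spacing[1])
    return total


def oracle_contact(
    mask: np.ndarray, tumor: np.ndarray, spacing=(1.0, 1.0), window: int = 5
) -> float:
    """Smoothed boundary-walk contact length (across-pixel rule) in mm."""
    filled = np.pad(ndimage.binary_fill_holes(mask), 1)
    tpad = np.pad(tumor.astype(bool), 1)
    # rebuild per-cell probe info keyed by unordered segment endpoints
    probes: dict[frozenset, tuple] = {}
    for r in range(filled.shape[0] - 1):
        for c in range(filled.shape[1] - 1):
            for a, b, pa, pb in _cell_segments(
                filled[r, c], filled[r, c + 1], filled[r + 1, c], filled[r + 1, c + 1], r, c
            ):
                probes[frozenset((a, b))] = (pa, pb)
    loop = walk_contour(mask)
    sm = smooth_loop([(p[0] / 2.0, p[1] / 2.0) for p in loop], window)
    total = 0.0
    for i, (a, b) in enumerate(zip(loop[:-1], loop[1:])):
        pa, pb = probes[frozenset((a, b))]
        in_a, in_b = filled[pa], filled[pb]
        if in_a == in_b:
            continue
        across = pb if in_a else pa
        if tpad[across]:
            (r0, c0), (r1, c1) = sm[i], sm[i + 1]
            total += math.hypot((r1 - r0) * spacing[0], (c1 - c0) * spacing[1])
    return total


# ---------------------------------------------------------------------------
# other oracles


def brute_force_planes_containing(voxels: np.ndarray, a: int, b: int):
    """Triple loop over all slices of all axes."""
    out = []
    for axis in range(3):
        for idx in range(voxels.shape[axis]):
            sl = np.take(voxels, idx, axis=axis)
            if (sl == a).any() and (sl == b).any():
                out.append((axis, idx))
    return out


def brute_force_stage(degrees: dict[str, float]) -> str:
    """If/else re-statement of the default DPCG-style rule table."""

    def arterial(d):
        if d == 0:
            return "resectable"
        if d <= 90:
            return "borderline_resectable"
        return "locally_advanced"

    def venous(d):
        if d <= 90:
            return "resectable"
        if d <= 270:
            return "borderline_resectable"
        return "locally_advanced"

    order = ["resectable", "borderline_resectable", "locally_advanced"]
    stages = [
        arterial(degrees["CeTr"]),
        arterial(degrees["HA"]),
        arterial(degrees["SMA"]),
        venous(degrees["SMV"]),
        venous(degrees["PV"]),
    ]
    return max(stages, key=order.index)


def definitional_anova(groups) -> tuple[float, float]:
    """F and p from the definitional between/within sums of squares."""
    from scipy import stats

    all_vals = [x for g in groups for x in g]
    grand = sum(all_vals) / len(all_vals)
    ss_between = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups)
    ss_within = sum(sum((x - sum(g) / len(g)) ** 2 for x in g) for g in groups)
    df_between = len(groups) - 1
    df_within = len(all_vals) - len(groups)
    F = (ss_between / df_between) / (ss_within / df_within)
    p = float(stats.f.sf(F, df_between, df_within))
    return F, p
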