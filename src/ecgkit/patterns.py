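"""Stage 4: the PVC occurrence-pattern grammar.

Per-beat 0/1 PVC labels of a segment are reduced to one of seven episode
codes:

====  =============
code  episode
====  =============
1     NSR
2     couplet
3     triplet
4     VT
5     bigeminy
6     trigeminy
7     quadrigeminy
====  =============

The longest run of consecutive PVCs (NCPVC) decides couplet / triplet / VT;
isolated PVCs (NCPVC = 1) are classified by the spacing of their positions:
a modal position difference of 2, 3 or 4 beats means bigeminy, trigeminy or
quadrigeminy.  A single isolated PVC, or isolated PVCs with any other
spacing, fall back to NSR.  Mapping each 8 s segment of a recording gives
the vector of episode type (VET).
"""

from __future__ import annotations

import numpy as np

from .errors import EcgKitError

__all__ = [
    "EPISODE_NAMES",
    "max_consecutive_pvc",
    "classify_episode",
    "build_vet",
    "episode_name",
]

EPISODE_NAMES = {
    1: "NSR",
    2: "couplet",
    3: "triplet",
    4: "VT",
    5: "bigeminy",
    6: "trigeminy",
    7: "quadrigeminy",
}


def _as_labels(lv) -> np.ndarray:
    arr = np.asarray(lv, dtype=int)
    if arr.ndim != 1 or arr.size == 0:
        raise EcgKitError("label vector must be non-empty and 1-D")
    if not np.isin(arr, (0, 1)).all():
        raise EcgKitError("label vector entries must be 0 or 1")
    return arr


def max_consecutive_pvc(lv) -> int:
    """Length of the longest run of 1s (NCPVC)."""
    arr = _as_labels(lv)
    best = run = 0
    for v in arr:
        run = run + 1 if v else 0
        best = max(best, run)
    return best


def classify_episode(lv) -> int:
    """Map one segment's per-beat PVC labels to an episode code (1-7)."""
    arr = _as_labels(lv)
    nc = max_consecutive_pvc(arr)
    if nc == 0:
        return 1
    if nc >= 4:
        return 4
    if nc == 3:
        return 3
    if nc == 2:
        return 2
    # isolated PVCs: classify by modal spacing of their positions
    pos = np.flatnonzero(arr)
    if pos.size < 2:
        return 1
    diffs = np.diff(pos)
    vals, counts = np.unique(diffs, return_counts=True)
    modal = int(vals[np.argmax(counts)])  # ties break toward the smaller spacing
    return {2: 5, 3: 6, 4: 7}.get(modal, 1)


def build_vet(per_segment_labels) -> np.ndarray:
    """Vector of episode type: one code per segment label vector."""
    if len(per_segment_labels) == 0:
        raise EcgKitError("need at least one segment label vector")
    return np.array([classify_episode(lv) for lv in per_segment_labels], dtype=int)


def episode_name(code: int) -> str:
    return EPISODE_NAMES[int(code)]
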