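"""Kennard-Stone calibration/validation partitioning.

The Kennard-Stone algorithm picks a representative calibration subset by
max-min Euclidean distance: start from the two most distant samples, then
repeatedly add the sample whose distance to its nearest already-selected
neighbour is largest. The procedure is fully deterministic; distance ties
are broken toward the lowest sample index so that splits are reproducible
across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .errors import ConfigError


@dataclass
class SplitResult:
    """Calibration indices in selection order plus the remaining indices."""

    cal_indices: list[int]
    val_indices: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        overlap = set(self.cal_indices) & set(self.val_indices)
        if overlap:
            raise ConfigError(f"calibration and validation overlap: {sorted(overlap)}")


def kennard_stone(X: np.ndarray, n_select: int) -> SplitResult:
    """Greedy max-min Euclidean selection of ``n_select`` calibration rows.

    Returns the selected indices in the order chosen (the first two are
    the maximally distant pair, lower index first) and the validation
    indices in original order.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ConfigError("X must be a 2-D matrix")
    n = X.shape[0]
    if n_select < 2:
        raise ConfigError(f"n_select must be >= 2 (got {n_select})")
    if n_select > n:
        raise ConfigError(f"n_select {n_select} exceeds n {n}")

    D = cdist(X, X, metric="euclidean")
    # seed pair: maximal distance; ties -> lexicographically smallest (i, j)
    flat = np.argmax(D)  # argmax scans row-major, so ties already favour low i then low j
    i, j = divmod(int(flat), n)
    selected = [min(i, j), max(i, j)]
    in_cal = np.zeros(n, dtype=bool)
    in_cal[selected] = True

    # min distance from each candidate to the selected set, updated per pick
    mindist = np.minimum(D[selected[0]], D[selected[1]])
    mindist[in_cal] = -np.inf
    while len(selected) < n_select:
        nxt = int(np.argmax(mindist))  # argmax ties -> lowest index
        selected.append(nxt)
        in_cal[nxt] = True
        mindist = np.minimum(mindist, D[nxt])
        mindist[nxt] = -np.inf

    val = [k for k in range(n) if not in_cal[k]]
    return SplitResult(cal_indices=selected, val_indices=val)
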