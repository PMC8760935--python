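"""Permutation contrast tests on window statistic tables.

Compares the mean of a per-window statistic between a labelled window set
and the background by permuting the labels, as used for the Dxy and fd
contrasts between a hybrid lineage's recent-source-ancestry windows and
the rest of the genome.  Labels are permuted uniformly at random
preserving group sizes; the one-sided P-value uses the add-one
correction, so P >= 1/(n_perm + 1) always.

The test statistic is the difference of group means of per-window values
(the contrast of window distributions); a site-weighted variant is
available via ``weight_column``.  Simple label permutation ignores the
spatial autocorrelation of adjacent windows — a documented limitation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["PermutationResult", "permutation_contrast"]


@dataclass
class PermutationResult:
    """One-sided permutation test outcome.

    P = (1 + exceedances) / (n_perm + 1); ``degenerate`` flags an all-equal
    statistic column (P forced to 1).
    """

    statistic: str
    observed_in_set: float
    observed_background: float
    observed_diff: float
    n_perm: int
    p_value: float
    direction: str
    seed: int
    n_in_set: int
    n_background: int
    n_excluded: int
    degenerate: bool = False

    def __str__(self) -> str:
        return (
            f"{self.statistic}: in-set mean {self.observed_in_set:.6g} "
            f"vs background {self.observed_background:.6g} "
            f"(diff {self.observed_diff:+.6g}), one-sided P={self.p_value:.4g} "
            f"[{self.direction}, {self.n_perm} permutations]"
        )


def permutation_contrast(
    table: pd.DataFrame,
    label_column: str,
    statistic_column: str,
    direction: str = "less",
    n_perm: int = 1000,
    seed: int = 0,
    in_set_label: str = "in_set",
    background_label: str = "background",
    weight_column: str | None = None,
) -> PermutationResult:
    """Permutation test for a difference in mean window statistic.

    ``direction='less'`` tests whether the in-set mean is lower than the
    background mean (e.g. Dxy of introgressed windows); ``'greater'``
    tests the opposite tail (e.g. fd).  Windows with a missing statistic
    or a label other than the two groups are excluded first.

    With ``weight_column`` set (e.g. per-window site counts), group means
    are weighted, approximating site-pooled statistics.
    """
    if direction not in ("less", "greater"):
        raise ValueError("direction must be 'less' or 'greater'")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")

    labels = table[label_column].astype(str).to_numpy()
    values = pd.to_numeric(table[statistic_column], errors="coerce").to_numpy(dtype=float)
    weights = (
        pd.to_numeric(table[weight_column], errors="coerce").to_numpy(dtype=float)
        if weight_column
        else np.ones_like(values)
    )
    usable = (
        np.isfinite(values)
        & np.isfinite(weights)
        & ((labels == in_set_label) | (labels == background_label))
    )
    n_excluded = int((~usable).sum())
    if n_excluded:
        logger.info("permutation_contrast: excluded %d windows (missing value or label)", n_excluded)
    values, weights, labels = values[usable], weights[usable], labels[usable]
    is_in = labels == in_set_label
    n_in, n_bg = int(is_in.sum()), int((~is_in).sum())
    if n_in == 0 or n_bg == 0:
        raise ValueError(f"both groups must be non-empty (in_set={n_in}, background={n_bg})")

    def group_diff(mask: np.ndarray) -> float:
        w_in, w_bg = weights[mask], weights[~mask]
        return float(
            np.average(values[mask], weights=w_in) - np.average(values[~mask], weights=w_bg)
        )

    obs_in = float(np.average(values[is_in], weights=weights[is_in]))
    obs_bg = float(np.average(values[~is_in], weights=weights[~is_in]))
    observed = obs_in - obs_bg

    if np.all(values == values[0]):
        logger.warning("permutation_contrast: all statistic values identical; degenerate P=1")
        return PermutationResult(
            statistic_column, obs_in, obs_bg, observed, n_perm, 1.0, direction, seed,
            n_in, n_bg, n_excluded, degenerate=True,
        )

    rng = np.random.default_rng(seed)
    exceed = 0
    idx = np.arange(len(values))
    for _ in range(n_perm):
        perm = rng.permutation(idx)
        mask = np.zeros(len(values), dtype=bool)
        mask[perm[:n_in]] = True
        diff = group_diff(mask)
        if direction == "less":
            exceed += diff <= observed
        else:
            exceed += diff >= observed
    p = (1 + exceed) / (n_perm + 1)
    return PermutationResult(
        statistic_column, obs_in, obs_bg, observed, n_perm, float(p), direction, seed,
        n_in, n_bg, n_excluded,
    )
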