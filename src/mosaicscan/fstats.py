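"""Site-pattern and divergence statistics.

Patterson's D (ABBA-BABA) with block-jackknife Z-scores, the f2/f3/f4
family and the f4-ratio admixture proportion, windowed Dxy and the fd
introgression-fraction statistic, and a genome scan combining them.

All statistics work from per-site derived-allele frequencies
(:class:`~mosaicscan.popio.AlleleFrequencyTable`) with per-site
complete-case handling: a site is used only when every required
population has a called frequency.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from mosaicscan.popio import AlleleFrequencyTable, GenomicWindow, WindowAlignment, windows_of_table

logger = logging.getLogger(__name__)

DEFAULT_Z_THRESHOLD = 3.3
DEFAULT_N_BLOCKS = 50

__all__ = [
    "FStatResult",
    "UndefinedStatisticError",
    "patterson_d",
    "block_jackknife",
    "f2",
    "f3",
    "f4",
    "f4_ratio",
    "dxy",
    "dxy_alignment",
    "fd_statistic",
    "scan_windows",
]


class UndefinedStatisticError(ValueError):
    """A statistic's denominator vanished on the supplied data."""


@dataclass
class FStatResult:
    """Point estimate with optional block-jackknife uncertainty."""

    name: str
    populations: tuple[str, ...]
    estimate: float
    se: float | None = None
    z: float | None = None
    n_blocks: int | None = None
    n_sites: int = 0
    num_sum: float | None = None
    den_sum: float | None = None

    def significant(self, z_threshold: float = DEFAULT_Z_THRESHOLD) -> bool | None:
        """True when |Z| exceeds the threshold; None when Z is undefined."""
        if self.z is None or not math.isfinite(self.z):
            return None
        return abs(self.z) > z_threshold

    def __str__(self) -> str:
        z = "NA" if self.z is None or not math.isfinite(self.z) else f"{self.z:.3f}"
        se = "NA" if self.se is None else f"{self.se:.6g}"
        return (
            f"{self.name}({','.join(self.populations)}) = {self.estimate:.6g}"
            f" SE={se} Z={z} sites={self.n_sites}"
        )


# ---------------------------------------------------------------------------
# per-site term builders
#
# Every statistic is a ratio of per-site sums Σnum / Σden; the block
# jackknife below is generic over (num, den) term arrays.


def _cols(freqs: AlleleFrequencyTable, pops: Sequence[str]) -> list[np.ndarray]:
    for p in pops:
        if p not in freqs.populations:
            raise KeyError(f"population {p!r} not in frequency table")
    return [freqs.column(p) for p in pops]


def _abba_baba(freqs: AlleleFrequencyTable, p1: str, p2: str, p3: str, o: str):
    f1, f2_, f3_, fo = _cols(freqs, (p1, p2, p3, o))
    used = ~(np.isnan(f1) | np.isnan(f2_) | np.isnan(f3_) | np.isnan(fo))
    abba = (1 - f1) * f2_ * f3_ * (1 - fo)
    baba = f1 * (1 - f2_) * f3_ * (1 - fo)
    return np.where(used, abba, 0.0), np.where(used, baba, 0.0), used


def _d_terms(freqs: AlleleFrequencyTable, pops: Sequence[str]):
    abba, baba, used = _abba_baba(freqs, *pops)
    return abba - baba, abba + baba, used


def _d_terms_general(freqs: AlleleFrequencyTable, pops: Sequence[str]):
    """Allele-coding-invariant D terms for unpolarized frequency tables:
    num = (p2-p1)(p3-pO), den = (p1+p2-2 p1 p2)(p3+pO-2 p3 pO); reduces to
    ABBA-BABA when the outgroup's derived frequency is 0."""
    f1, f2_, f3_, fo = _cols(freqs, pops)
    used = ~(np.isnan(f1) | np.isnan(f2_) | np.isnan(f3_) | np.isnan(fo))
    num = (f2_ - f1) * (f3_ - fo)
    den = (f1 + f2_ - 2 * f1 * f2_) * (f3_ + fo - 2 * f3_ * fo)
    return np.where(used, num, 0.0), np.where(used, den, 0.0), used


def _hetero_correction(freqs: AlleleFrequencyTable, pop: str) -> np.ndarray:
    """Finite-sample correction term p(1-p)/(n-1) for one population."""
    p = freqs.column(pop)
    n = freqs.counts_column(pop)
    if n is None:
        raise ValueError("unbiased estimators require allele counts (n_chrom) in the table")
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n > 1, p * (1 - p) / (n - 1), np.nan)


def _f2_terms(freqs: AlleleFrequencyTable, pops: Sequence[str], unbiased: bool = False):
    a, b = _cols(freqs, pops)
    term = (a - b) ** 2
    if unbiased:
        term = term - _hetero_correction(freqs, pops[0]) - _hetero_correction(freqs, pops[1])
    used = ~np.isnan(term)
    return np.where(used, term, 0.0), used.astype(float), used


def _f3_terms(freqs: AlleleFrequencyTable, pops: Sequence[str], unbiased: bool = False):
    x, a, b = _cols(freqs, pops)
    term = (x - a) * (x - b)
    if unbiased:
        term = term - _hetero_correction(freqs, pops[0])
    used = ~np.isnan(term)
    return np.where(used, term, 0.0), used.astype(float), used


def _f4_terms(freqs: AlleleFrequencyTable, pops: Sequence[str]):
    a, b, c, d = _cols(freqs, pops)
    term = (a - b) * (c - d)
    used = ~np.isnan(term)
    return np.where(used, term, 0.0), used.astype(float), used


_TERM_BUILDERS: dict[str, Callable] = {
    "D": _d_terms,
    "D_general": _d_terms_general,
    "f2": _f2_terms,
    "f3": _f3_terms,
    "f4": _f4_terms,
}


def _ratio(num: np.ndarray, den: np.ndarray, name: str) -> float:
    den_sum = float(den.sum())
    if den_sum == 0:
        raise UndefinedStatisticError(f"{name}: denominator sum is zero (no informative sites)")
    return float(num.sum()) / den_sum


# ---------------------------------------------------------------------------
# public statistics


def patterson_d(
    freqs: AlleleFrequencyTable, p1: str, p2: str, p3: str, outgroup: str,
    general: bool = False,
) -> FStatResult:
    """Patterson's D for the four-population test (P1, P2; P3, Outgroup).

    With per-site derived frequencies ``p1..pO``::

        ABBA = (1-p1) p2 p3 (1-pO),   BABA = p1 (1-p2) p3 (1-pO)
        D = Sum(ABBA-BABA) / Sum(ABBA+BABA)

    D > 0 indicates excess allele sharing between P2 and P3.  With
    ``general=True`` the allele-coding-invariant form
    ``(p2-p1)(p3-pO) / (p1+p2-2p1p2)(p3+pO-2p3pO)`` is used instead —
    required when the table is not polarized by an outgroup (both forms
    coincide when the outgroup's derived frequency is 0).  Use
    :func:`block_jackknife` for a standard error and Z-score.
    """
    pops = (p1, p2, p3, outgroup)
    num, den, used = (_d_terms_general if general else _d_terms)(freqs, pops)
    return FStatResult(
        "D", pops, _ratio(num, den, "D"), n_sites=int(used.sum()),
        num_sum=float(num.sum()), den_sum=float(den.sum()),
    )


def f2(freqs: AlleleFrequencyTable, a: str, b: str, unbiased: bool = False) -> FStatResult:
    """f2(A,B) = mean (pA - pB)^2; ``unbiased=True`` subtracts the
    within-population sampling terms p(1-p)/(n-1)."""
    num, den, used = _f2_terms(freqs, (a, b), unbiased)
    return FStatResult("f2", (a, b), _ratio(num, den, "f2"), n_sites=int(used.sum()))


def f3(freqs: AlleleFrequencyTable, x: str, a: str, b: str, unbiased: bool = False) -> FStatResult:
    """f3(X; A, B) = mean (pX - pA)(pX - pB)."""
    num, den, used = _f3_terms(freqs, (x, a, b), unbiased)
    return FStatResult("f3", (x, a, b), _ratio(num, den, "f3"), n_sites=int(used.sum()))


def f4(freqs: AlleleFrequencyTable, a: str, b: str, c: str, d: str) -> FStatResult:
    """f4(A,B; C,D) = mean (pA - pB)(pC - pD)."""
    num, den, used = _f4_terms(freqs, (a, b, c, d))
    return FStatResult("f4", (a, b, c, d), _ratio(num, den, "f4"), n_sites=int(used.sum()))


# ---------------------------------------------------------------------------
# block jackknife


def assign_blocks(
    freqs: AlleleFrequencyTable,
    n_blocks: int = DEFAULT_N_BLOCKS,
    span: int | None = None,
) -> np.ndarray:
    """Block index per site.

    Default: contiguous blocks of (near-)equal site count.  With ``span``
    set, blocks are coordinate windows of that many bases per chromosome
    (genomic-span blocking, e.g. 5 Mb), renumbered to drop empty blocks.
    """
    m = freqs.n_sites
    if span is not None:
        keys = [f"{c}:{p // span}" for c, p in zip(freqs.chrom, freqs.pos)]
        _, idx = np.unique(keys, return_inverse=True)
        return idx
    n_blocks = min(n_blocks, m)
    return np.minimum((np.arange(m) * n_blocks) // m, n_blocks - 1)


def block_jackknife(
    freqs: AlleleFrequencyTable,
    statistic: str,
    populations: Sequence[str],
    n_blocks: int = DEFAULT_N_BLOCKS,
    span: int | None = None,
    z_threshold: float = DEFAULT_Z_THRESHOLD,
    unbiased: bool = False,
) -> FStatResult:
    """Delete-one-block jackknife SE and Z for one of D, f2, f3, f4.

    Over m blocks with leave-one-out estimates ``t_(-j)``::

        SE^2 = (m-1)/m * Sum_j (t_(-j) - mean)^2,    Z = t_full / SE

    Blocks are contiguous runs of sites (LD-robust).  A block whose removal
    empties the denominator is merged with its neighbour (logged).
    """
    builder = _TERM_BUILDERS[statistic]
    if statistic in ("f2", "f3"):
        num, den, used = builder(freqs, populations, unbiased)
    else:
        num, den, used = builder(freqs, populations)
    block_idx = assign_blocks(freqs, n_blocks=n_blocks, span=span)
    return _jackknife_from_terms(statistic, tuple(populations), num, den, used, block_idx, z_threshold)


def _jackknife_from_terms(
    name: str,
    populations: tuple[str, ...],
    num: np.ndarray,
    den: np.ndarray,
    used: np.ndarray,
    block_idx: np.ndarray,
    z_threshold: float = DEFAULT_Z_THRESHOLD,
) -> FStatResult:
    m_all = int(block_idx.max()) + 1 if len(block_idx) else 0
    num_b = np.bincount(block_idx, weights=num, minlength=m_all)
    den_b = np.bincount(block_idx, weights=den, minlength=m_all)
    sites_b = np.bincount(block_idx, weights=used.astype(float), minlength=m_all)

    # drop blocks with no used sites, then merge any block whose removal
    # would empty the denominator into its left neighbour
    keep = sites_b > 0
    num_b, den_b = num_b[keep], den_b[keep]
    total_num, total_den = num_b.sum(), den_b.sum()
    if total_den == 0:
        raise UndefinedStatisticError(f"{name}: denominator sum is zero")
    bad = np.nonzero(total_den - den_b == 0)[0]
    if len(bad):
        logger.info("block_jackknife: merging %d block(s) that empty the denominator", len(bad))
        for j in sorted(bad, reverse=True):
            tgt = j - 1 if j > 0 else j + 1
            if 0 <= tgt < len(num_b):
                num_b[tgt] += num_b[j]
                den_b[tgt] += den_b[j]
        mask = np.ones(len(num_b), dtype=bool)
        mask[bad] = False
        num_b, den_b = num_b[mask], den_b[mask]
    m = len(num_b)
    estimate = total_num / total_den
    if m < 2:
        return FStatResult(name, populations, float(estimate), None, None, m, int(used.sum()),
                           float(total_num), float(total_den))

    loo = (total_num - num_b) / (total_den - den_b)
    se = math.sqrt((m - 1) / m * np.sum((loo - loo.mean()) ** 2))
    z = estimate / se if se > 0 else math.inf * np.sign(estimate) if estimate != 0 else math.nan
    if se == 0:
        logger.info("block_jackknife: zero jackknife variance; Z undefined")
        z = math.nan
    return FStatResult(
        name, populations, float(estimate), float(se), float(z), m, int(used.sum()),
        float(total_num), float(total_den),
    )


def f4_ratio(
    freqs: AlleleFrequencyTable,
    a: str,
    outgroup: str,
    x: str,
    b: str,
    c: str,
    n_blocks: int = DEFAULT_N_BLOCKS,
    tol: float = 1e-12,
) -> FStatResult:
    """Admixture proportion alpha = f4(A,O;X,C) / f4(A,O;B,C).

    Canonical layout: X is admixed between a source related to B (proportion
    alpha) and a source related to C; A attaches to the B-side lineage above
    the admixture; O is the outgroup.  The SE is a delete-one-block jackknife
    of the ratio itself.
    """
    num_t, _, used_n = _f4_terms(freqs, (a, outgroup, x, c))
    den_t, _, used_d = _f4_terms(freqs, (a, outgroup, b, c))
    used = used_n & used_d
    num_t = np.where(used, num_t, 0.0)
    den_t = np.where(used, den_t, 0.0)
    if abs(den_t.sum()) < tol:
        raise UndefinedStatisticError("f4_ratio: |f4(A,O;B,C)| below tolerance")
    block_idx = assign_blocks(freqs, n_blocks=n_blocks)
    result = _jackknife_from_terms("f4_ratio", (a, outgroup, x, b, c), num_t, den_t, used, block_idx)
    return result


# ---------------------------------------------------------------------------
# Dxy


def dxy(
    freqs: AlleleFrequencyTable,
    pop_x: str,
    pop_y: str,
    accessible_length: int | None = None,
) -> float:
    """Absolute divergence from allele frequencies.

    Dxy = sum_i [ pX(1-pY) + pY(1-pX) ] / L, with L the accessible length
    (monomorphic sites count as zero difference).  When ``accessible_length``
    is None, L is the number of sites with both frequencies called —
    appropriate only for alignments reduced to variable sites.
    Returns NaN when L = 0.
    """
    px, py = _cols(freqs, (pop_x, pop_y))
    used = ~(np.isnan(px) | np.isnan(py))
    L = accessible_length if accessible_length is not None else int(used.sum())
    if L == 0:
        return math.nan
    per_site = px[used] * (1 - py[used]) + py[used] * (1 - px[used])
    val = float(per_site.sum()) / L
    return min(val, 1.0)


def dxy_alignment(alignment: WindowAlignment, pop_x: str, pop_y: str) -> float:
    """Alignment-mode Dxy: mean over all inter-population sequence pairs of
    per-site differences / compared (non-N) length.  NaN if no comparable
    pair or no comparable site."""
    mat = alignment.matrix()
    ix = [i for i, (_, p, _) in enumerate(alignment.records) if p == pop_x]
    iy = [i for i, (_, p, _) in enumerate(alignment.records) if p == pop_y]
    if not ix or not iy:
        raise KeyError(f"populations {pop_x!r}/{pop_y!r} not both present in alignment")
    n_code = ord("N")
    vals = []
    for i in ix:
        a = mat[i]
        for j in iy:
            b = mat[j]
            ok = (a != n_code) & (b != n_code)
            L = int(ok.sum())
            if L:
                vals.append(float(((a != b) & ok).sum()) / L)
    return float(np.mean(vals)) if vals else math.nan


# ---------------------------------------------------------------------------
# fd


def fd_statistic(
    freqs: AlleleFrequencyTable, p1: str, p2: str, p3: str, outgroup: str
) -> tuple[float, float, float]:
    """Window-scale introgression fraction fd for (P1, P2; P3, O).

    The numerator S is the D numerator; the denominator substitutes the
    donor frequency pD = max(p2, p3) into both the P2 and P3 slots, i.e. the
    value S would take under complete sharing between P2 and P3.  fd is
    reported missing (NaN) when S <= 0 — the statistic is defined only for
    windows with positive D — or when the denominator vanishes.

    Returns ``(fd, S, S_D)``.
    """
    f1, f2_, f3_, fo = _cols(freqs, (p1, p2, p3, outgroup))
    used = ~(np.isnan(f1) | np.isnan(f2_) | np.isnan(f3_) | np.isnan(fo))
    f1, f2_, f3_, fo = f1[used], f2_[used], f3_[used], fo[used]
    s = float(((1 - f1) * f2_ * f3_ * (1 - fo) - f1 * (1 - f2_) * f3_ * (1 - fo)).sum())
    fdn = np.maximum(f2_, f3_)
    s_d = float(((1 - f1) * fdn * fdn * (1 - fo) - f1 * (1 - fdn) * fdn * (1 - fo)).sum())
    if s <= 0 or s_d == 0:
        return math.nan, s, s_d
    return s / s_d, s, s_d


# ---------------------------------------------------------------------------
# genome scan


def scan_windows(
    freqs: AlleleFrequencyTable,
    window_length: int = 200_000,
    step: int | None = None,
    dxy_pairs: Sequence[tuple[str, str]] = (),
    fd_pops: tuple[str, str, str, str] | None = None,
    dxy_accessible: str = "sites",
) -> pd.DataFrame:
    """Per-window statistic table (one row per tiling window).

    ``dxy_accessible``: 'sites' divides by called variable sites in the
    window; 'span' divides by the window length (treats unseen positions as
    monomorphic).  Columns ``topology_class``, ``mean_support`` and
    ``ancestry`` are initialised empty for the treescan stage to fill.
    """
    if not dxy_pairs and fd_pops is None:
        raise ValueError("request at least one statistic")
    rows = []
    for win, mask in windows_of_table(freqs, window_length, step):
        sub = freqs.site_mask(mask)
        row: dict = {
            "chrom": win.chrom,
            "start": win.start,
            "end": win.end,
            "partial": win.partial,
            "n_sites": sub.n_sites,
        }
        for x, y in dxy_pairs:
            L = win.length if dxy_accessible == "span" else None
            row[f"dxy_{x}_{y}"] = dxy(sub, x, y, accessible_length=L) if sub.n_sites else math.nan
        if fd_pops is not None:
            if sub.n_sites:
                fd_val, s, s_d = fd_statistic(sub, *fd_pops)
            else:
                fd_val, s, s_d = math.nan, math.nan, math.nan
            row["fd"] = fd_val
            row["fd_num"] = s
            row["fd_den"] = s_d
        row["topology_class"] = pd.NA
        row["mean_support"] = math.nan
        row["ancestry"] = pd.NA
        rows.append(row)
    table = pd.DataFrame(rows)
    logger.info("scan_windows: %d windows, %d empty", len(table), int((table["n_sites"] == 0).sum()))
    return table


def scan_alignments(
    alignments: Sequence[WindowAlignment],
    dxy_pairs: Sequence[tuple[str, str]] = (),
    fd_pops: tuple[str, str, str, str] | None = None,
    polarize_by: str | None = None,
) -> pd.DataFrame:
    """Window statistic table from per-window alignments.

    Dxy is computed in alignment mode (mean pairwise differences over
    compared length).  fd requires ``polarize_by`` (usually the outgroup
    population) to extract derived-allele frequencies from each alignment;
    windows with no polarizable site get missing fd.
    """
    from mosaicscan.popio import EmptyDataError, alignment_frequencies

    if not dxy_pairs and fd_pops is None:
        raise ValueError("request at least one statistic")
    if fd_pops is not None and polarize_by is None:
        raise ValueError("fd from alignments requires polarize_by")
    rows = []
    for aln in alignments:
        w = aln.window
        row: dict = {
            "chrom": w.chrom,
            "start": w.start,
            "end": w.end,
            "partial": w.partial,
            "n_sites": aln.length,
        }
        for x, y in dxy_pairs:
            row[f"dxy_{x}_{y}"] = dxy_alignment(aln, x, y)
        if fd_pops is not None:
            try:
                freqs = alignment_frequencies(aln, polarize_by)
                fd_val, s, s_d = fd_statistic(freqs, *fd_pops)
            except EmptyDataError:
                fd_val, s, s_d = math.nan, math.nan, math.nan
            row["fd"] = fd_val
            row["fd_num"] = s
            row["fd_den"] = s_d
        row["topology_class"] = pd.NA
        row["mean_support"] = math.nan
        row["ancestry"] = pd.NA
        rows.append(row)
    return pd.DataFrame(rows)
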