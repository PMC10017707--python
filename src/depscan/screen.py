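"""Phenotype-anchored screen over master peaks.

Per-sample peak calls for one antibody are union-merged into *master loci*.
Each locus carries a per-sample presence flag (does the locus overlap that
sample's own peaks?) and a per-sample normalized tag count.  For the screen,
H3K27ac and BRD4 master tables are filtered (detected in >= 3 samples,
maximal normalized count >= 10, cross-mark overlap), paired across marks by
maximal overlap, and each paired locus is correlated against the per-line
dependency scores with Kendall's tau-b.  Loci where both marks clear the
|tau| > cutoff bar with the same sign are labeled dependency-high (YapD_H,
positive taus) or dependency-low (YapD_L, negative taus).

Also here: rank-rank hypergeometric overlap (RRHO) between the two marks'
per-locus statistics, and the ward-linkage row-scaled clustering used for
heatmap ordering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .intervals import (
    GenomicInterval,
    merge_intervals,
    overlaps_any,
    pair_by_max_overlap,
)
from .io import parse_locus_id

__all__ = [
    "MasterPeakTable",
    "ScreenPairs",
    "build_master_table",
    "filter_for_screen",
    "kendall_tau",
    "kendall_tau_matrix",
    "concordance_label",
    "dependency_screen",
    "rrho_map",
    "ClusterResult",
    "cluster_heatmap_order",
    "cut_clusters",
]


@dataclass
class MasterPeakTable:
    """Merged loci x samples matrix of counts plus per-sample presence."""

    antibody: str
    loci: list[GenomicInterval]
    presence: pd.DataFrame  # loci x samples, bool
    counts: pd.DataFrame  # loci x samples, float

    def __post_init__(self) -> None:
        ids = [l.locus_id for l in self.loci]
        if list(self.presence.index) != ids or list(self.counts.index) != ids:
            raise ValueError("presence/counts index must match loci order")
        if list(self.presence.columns) != list(self.counts.columns):
            raise ValueError("presence/counts sample sets differ")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)


def build_master_table(
    peaks_by_sample: Mapping[str, Sequence[GenomicInterval]],
    antibody: str = "",
    counts: pd.DataFrame | None = None,
) -> MasterPeakTable:
    """Union-merge per-sample peaks into master loci and populate the table.

    Master loci are the merge (book-ended included) of all per-sample peaks,
    so by construction every locus overlaps at least one sample peak.
    Presence is per-sample peak overlap.  Counts come either from ``counts``
    (a locus-indexed matrix whose row intervals are mapped onto master loci
    by overlap, summing rows when several merge into one locus) or, if
    omitted, from the per-sample peak score (tag density) summed over peaks
    overlapping the locus.
    """
    samples = list(peaks_by_sample)
    all_peaks = [p for s in samples for p in peaks_by_sample[s]]
    loci = merge_intervals(all_peaks, book_ended=True)
    ids = [l.locus_id for l in loci]

    presence = pd.DataFrame(
        {s: overlaps_any(loci, peaks_by_sample[s]) for s in samples}, index=ids
    )

    if counts is not None:
        src = [parse_locus_id(i) for i in counts.index]
        owner = pair_by_max_overlap(src, loci)
        mat = np.zeros((len(loci), len(counts.columns)))
        vals = counts.to_numpy(dtype=float)
        for row, j in enumerate(owner):
            if j >= 0:
                mat[j] += vals[row]
        cdf = pd.DataFrame(mat, index=ids, columns=list(counts.columns))
        cdf = cdf[samples] if set(samples) <= set(cdf.columns) else cdf
    else:
        mat = np.zeros((len(loci), len(samples)))
        for si, s in enumerate(samples):
            pk = list(peaks_by_sample[s])
            owner = pair_by_max_overlap(pk, loci)
            for p, j in zip(pk, owner):
                if j >= 0:
                    mat[j, si] += p.score
        cdf = pd.DataFrame(mat, index=ids, columns=samples)

    return MasterPeakTable(antibody, loci, presence, cdf)


@dataclass
class ScreenPairs:
    """Cross-mark paired loci surviving the screen filters."""

    loci_k27ac: list[GenomicInterval]
    loci_brd4: list[GenomicInterval]
    counts_k27ac: pd.DataFrame
    counts_brd4: pd.DataFrame


def filter_for_screen(
    k27ac: MasterPeakTable,
    brd4: MasterPeakTable,
    min_samples: int = 3,
    min_max_count: float = 10.0,
) -> ScreenPairs:
    """Apply the screen filters and pair loci across the two marks.

    A locus is retained iff it is detected (presence flag) in at least
    ``min_samples`` samples, its maximal normalized count across samples is
    >= ``min_max_count`` (the removal rule strikes counts < 10), and it
    overlaps at least one retained locus of the other antibody.  Each
    retained H3K27ac locus is paired with its maximal-overlap BRD4 partner
    (ties -> leftmost).
    """
    if set(k27ac.samples) != set(brd4.samples):
        raise ValueError("the two tables must share a sample set")

    def survivors(t: MasterPeakTable) -> list[int]:
        det = t.presence.sum(axis=1).to_numpy() >= min_samples
        mx = t.counts.max(axis=1).to_numpy() >= min_max_count
        return [i for i in range(len(t.loci)) if det[i] and mx[i]]

    ka = survivors(k27ac)
    kb = survivors(brd4)
    loci_a = [k27ac.loci[i] for i in ka]
    loci_b = [brd4.loci[i] for i in kb]
    partner = pair_by_max_overlap(loci_a, loci_b)

    keep_a, keep_b = [], []
    for ia, jb in zip(ka, partner):
        if jb >= 0:
            keep_a.append(ia)
            keep_b.append(kb[jb])
    return ScreenPairs(
        loci_k27ac=[k27ac.loci[i] for i in keep_a],
        loci_brd4=[brd4.loci[i] for i in keep_b],
        counts_k27ac=k27ac.counts.iloc[keep_a],
        counts_brd4=brd4.counts.iloc[keep_b],
    )


def kendall_tau_matrix(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise Kendall tau-b of a loci x samples matrix against ``y``.

    Vectorized over all n(n-1)/2 sample pairs; rows with all-tied values
    yield NaN (tau undefined).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if X.ndim != 2 or X.shape[1] != n:
        raise ValueError("X must be loci x len(y)")
    if n < 3:
        raise ValueError("need at least 3 samples")
    iu, ju = np.triu_indices(n, k=1)
    sy = np.sign(y[ju] - y[iu])
    sx = np.sign(X[:, ju] - X[:, iu])
    num = (sx * sy).sum(axis=1)
    n0 = n * (n - 1) / 2.0
    ties_x = (sx == 0).sum(axis=1)
    ties_y = float((sy == 0).sum())
    denom = np.sqrt((n0 - ties_x) * (n0 - ties_y))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, num / denom, np.nan)


def kendall_tau(x: Sequence[float], y: Sequence[float]) -> float:
    """Kendall tau-b between two vectors (tie-corrected).

    Raises on all-tied input, where the coefficient is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    tau = kendall_tau_matrix(x[None, :], y)[0]
    if np.isnan(tau):
        raise ValueError("tau undefined: a vector is constant (all ties)")
    return float(tau)


def concordance_label(tau1: float, tau2: float, cutoff: float = 0.3) -> str:
    """Concordance call for one locus from its two per-mark taus.

    ``YapD_H`` when both taus exceed +cutoff, ``YapD_L`` when both are below
    -cutoff, otherwise ``none`` (one mark under the bar, or discordant
    signs).  Strictly greater/less than the cutoff.
    """
    if tau1 > cutoff and tau2 > cutoff:
        return "YapD_H"
    if tau1 < -cutoff and tau2 < -cutoff:
        return "YapD_L"
    return "none"


def dependency_screen(
    pairs: ScreenPairs,
    scores: pd.Series,
    cutoff: float = 0.3,
) -> pd.DataFrame:
    """Kendall screen of paired loci against dependency scores.

    Returns one row per pair with tau_k27ac, tau_brd4 and a label:
    ``YapD_H`` when both taus > cutoff (signal tracks dependency),
    ``YapD_L`` when both < -cutoff, else ``none``.  Strict inequality at
    the cutoff.
    """
    samples = list(pairs.counts_k27ac.columns)
    missing = [s for s in samples if s not in scores.index]
    if missing:
        raise ValueError(f"missing dependency score for sample(s): {missing}")
    y = scores.reindex(samples).to_numpy(dtype=float)
    tau_a = kendall_tau_matrix(pairs.counts_k27ac.to_numpy(), y)
    tau_b = kendall_tau_matrix(pairs.counts_brd4[samples].to_numpy(), y)
    label = np.array(
        [concordance_label(a, b, cutoff) for a, b in zip(tau_a, tau_b)],
        dtype=object,
    )
    return pd.DataFrame(
        {
            "locus_k27ac": [l.locus_id for l in pairs.loci_k27ac],
            "locus_brd4": [l.locus_id for l in pairs.loci_brd4],
            "tau_k27ac": tau_a,
            "tau_brd4": tau_b,
            "label": label,
        }
    )


def rrho_map(
    stat1: pd.Series, stat2: pd.Series, step: int | None = None
) -> pd.DataFrame:
    """Rank-rank hypergeometric overlap grid.

    Both series are ranked descending (ties broken by index order for
    determinism).  For every threshold pair (i, j) on a ``step`` grid the
    overlap k of the top-i set of list 1 with the top-j set of list 2 is
    scored by the upper-tail hypergeometric p-value P(X >= k | N, i, j);
    the grid of -log10 p is returned.  Because thresholds sweep the entire
    lists, the four concordance quadrants (both-up, both-down, opposite)
    appear as the grid's corners.
    """
    if not stat1.index.equals(stat2.index):
        stat2 = stat2.reindex(stat1.index)
        if stat2.isna().any():
            raise ValueError("the two statistics must share a locus universe")
    n = len(stat1)
    if step is None:
        step = max(1, n // 50)
    if step >= n:
        raise ValueError("step must be smaller than the list length")
    # rank positions, 0 = top of the descending list
    r1 = np.empty(n, dtype=int)
    r1[np.argsort(-stat1.to_numpy(), kind="stable")] = np.arange(n)
    r2 = np.empty(n, dtype=int)
    r2[np.argsort(-stat2.to_numpy(), kind="stable")] = np.arange(n)

    levels = np.arange(step, n + 1, step)
    # cumulative 2D count: k(i, j) = #{loci with r1 < i and r2 < j}
    hist, _, _ = np.histogram2d(
        r1, r2, bins=[np.r_[0, levels], np.r_[0, levels]]
    )
    k = hist.cumsum(axis=0).cumsum(axis=1)
    ii = levels[:, None].astype(float)
    jj = levels[None, :].astype(float)
    pv = stats.hypergeom.sf(k - 1, n, ii, jj)
    with np.errstate(divide="ignore"):
        grid = -np.log10(np.clip(pv, 1e-320, None))
    return pd.DataFrame(grid, index=levels, columns=levels)


@dataclass
class ClusterResult:
    row_order: list[int]
    col_order: list[int]
    row_linkage: np.ndarray
    col_linkage: np.ndarray
    scaled: pd.DataFrame = field(repr=False, default=None)


def cluster_heatmap_order(
    matrix: pd.DataFrame, scale: str = "row"
) -> ClusterResult:
    """Heatmap ordering: row z-scoring + Ward linkage on Euclidean distance.

    Ward linkage on raw Euclidean distances reproduces R's ``ward.D2``.
    Constant rows cannot be z-scored and are signaled.  Leaf order is
    deterministic: SciPy's agglomeration visits candidate merges in input
    order, so equal-height ties resolve toward the lower original index.
    """
    x = matrix.to_numpy(dtype=float)
    if scale == "row":
        sd = x.std(axis=1, ddof=0)
        if np.any(sd == 0):
            bad = list(matrix.index[sd == 0])
            raise ValueError(f"constant row(s) under row scaling: {bad[:5]}")
        x = (x - x.mean(axis=1, keepdims=True)) / sd[:, None]
    elif scale != "none":
        raise ValueError("scale must be 'row' or 'none'")
    row_link = hierarchy.linkage(pdist(x, metric="euclidean"), method="ward")
    col_link = hierarchy.linkage(pdist(x.T, metric="euclidean"), method="ward")
    scaled = pd.DataFrame(x, index=matrix.index, columns=matrix.columns)
    return ClusterResult(
        row_order=list(hierarchy.leaves_list(row_link)),
        col_order=list(hierarchy.leaves_list(col_link)),
        row_linkage=row_link,
        col_linkage=col_link,
        scaled=scaled,
    )


def cut_clusters(linkage: np.ndarray, k: int) -> np.ndarray:
    """Flat cluster labels from a linkage at ``k`` clusters."""
    return hierarchy.fcluster(linkage, t=k, criterion="maxclust")
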