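"""Chromatin-state classification, TF co-binding categories, super-enhancers.

Master loci (the union-merge of all antibody peak sets in one cell line)
are split into promoter-proximal TSS sites (H3K4me3+) and cis-regulatory
elements (CRE, H3K4me3-).  *Active* means double-positive for H3K27ac and
BRD4; anything not double-positive is inactive.  A seven-way partition used
for heatmap panels subdivides TSS sites into p1-p3 and CREs into e1-e4
according to H3K27ac/BRD4/Jun/Sox2 status.  Co-binding by the four factors
Jun, Sox2, Sox5 and Twist2 is summarized in combinatorial categories, and
super-enhancers are called ROSE-style: stitch CREs within a 12.5 kb gap,
rank stitched regions by total signal, and place the cutoff where the
scaled rank-signal curve first climbs steeper than 45 degrees.

Overlap semantics here are strict (>= 1 bp); book-ended peaks do not set a
flag.  That differs deliberately from master-peak merging, where book-ended
intervals join.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, overlaps_any

__all__ = [
    "STATE_ANTIBODIES",
    "TF_FACTORS",
    "SuperEnhancerCall",
    "seven_cluster_label",
    "combination_category",
    "classify_states",
    "combination_counts",
    "yap_cobinding_summary",
    "stitch_superenhancers",
    "se_overlap_summary",
    "percent",
]

STATE_ANTIBODIES = (
    "H3K4me3",
    "H3K27ac",
    "Brd4",
    "Jun",
    "Sox2",
    "Sox5",
    "Twist2",
    "Yap",
)
TF_FACTORS = ("Jun", "Sox2", "Sox5", "Twist2")

CATEGORIES = (
    "all_four",
    "jun_sox2_sox5|twist2",
    "three_other",
    "two",
    "single",
    "none",
)


def percent(numerator: float, denominator: float) -> int:
    """Integer percent, rounded half-up (the convention of printed summaries)."""
    if denominator == 0:
        raise ZeroDivisionError("percentage of an empty class")
    from decimal import Decimal, ROUND_HALF_UP

    return int(
        Decimal(100 * numerator / denominator).quantize(0, rounding=ROUND_HALF_UP)
    )


def seven_cluster_label(k4: bool, k27: bool, brd4: bool, jun: bool, sox2: bool) -> str:
    """The seven-way heatmap partition.

    TSS side: p1 = H3K4me3+H3K27ac+BRD4+Jun+Sox2+, p2 = same but Jun-,
    p3 = remaining H3K4me3+.  CRE side: e2 = H3K4me3-H3K27ac-BRD4-Jun+Sox2+,
    e3 = ...Jun+Sox2-, e4 = ...Jun-Sox2+, e1 = remaining H3K4me3-.
    """
    if k4:
        if k27 and brd4 and sox2:
            return "p1" if jun else "p2"
        return "p3"
    if not k27 and not brd4:
        if jun and sox2:
            return "e2"
        if jun:
            return "e3"
        if sox2:
            return "e4"
    return "e1"


def combination_category(jun: bool, sox2: bool, sox5: bool, twist2: bool) -> str:
    """Deterministic partition of the 16 co-binding masks.

    The ``jun_sox2_sox5|twist2`` category holds sites bound by Jun and Sox2
    plus *exactly one* of Sox5/Twist2 (a site bound by both Sox5 and Twist2
    falls in ``all_four`` or ``three_other`` instead).
    """
    nb = sum((jun, sox2, sox5, twist2))
    if nb == 4:
        return "all_four"
    if jun and sox2 and (sox5 != twist2):
        return "jun_sox2_sox5|twist2"
    if nb == 3:
        return "three_other"
    if nb == 2:
        return "two"
    if nb == 1:
        return "single"
    return "none"


def classify_states(
    master_loci: Sequence[GenomicInterval],
    peaks_by_antibody: Mapping[str, Sequence[GenomicInterval]],
) -> pd.DataFrame:
    """Flag every master locus by antibody overlap and derive state labels.

    Returns a DataFrame indexed by locus id with one boolean column per
    antibody, plus ``is_tss``, ``is_active``, ``seven_cluster`` and
    ``category``.  A locus overlapping no antibody at all violates the
    master-merge construction and is an error.
    """
    ids = [l.locus_id for l in master_loci]
    flags = pd.DataFrame(index=ids)
    for ab in STATE_ANTIBODIES:
        peaks = peaks_by_antibody.get(ab, [])
        flags[ab.lower()] = overlaps_any(master_loci, peaks, book_ended=False)

    orphan = ~flags.any(axis=1)
    if orphan.any():
        raise ValueError(
            f"locus overlapping no antibody peak: {list(flags.index[orphan])[:5]}"
        )

    flags["is_tss"] = flags["h3k4me3"]
    flags["is_active"] = flags["h3k27ac"] & flags["brd4"]
    flags["seven_cluster"] = [
        seven_cluster_label(r.h3k4me3, r.h3k27ac, r.brd4, r.jun, r.sox2)
        for r in flags.itertuples()
    ]
    flags["category"] = [
        combination_category(r.jun, r.sox2, r.sox5, r.twist2)
        for r in flags.itertuples()
    ]
    return flags


def combination_counts(annotations: pd.DataFrame) -> pd.DataFrame:
    """Category counts within each of the four state classes.

    Rows are co-binding categories; columns are (TSS/CRE) x (active/
    inactive) counts.  Counts in each column partition that class.
    """
    out = {}
    for cls, mask in (
        ("active_TSS", annotations.is_tss & annotations.is_active),
        ("inactive_TSS", annotations.is_tss & ~annotations.is_active),
        ("active_CRE", ~annotations.is_tss & annotations.is_active),
        ("inactive_CRE", ~annotations.is_tss & ~annotations.is_active),
    ):
        sub = annotations.loc[mask, "category"]
        out[cls] = sub.value_counts().reindex(CATEGORIES, fill_value=0)
    return pd.DataFrame(out)


def yap_cobinding_summary(annotations: pd.DataFrame) -> dict:
    """Of the Yap-bound loci, how many are co-bound by >=1 and by all four TFs.

    Percentages are rounded half-up to integers, the convention used when
    such fractions are printed.
    """
    yap = annotations[annotations["yap"]]
    n = len(yap)
    if n == 0:
        raise ValueError("no Yap-bound loci")
    tf = yap[[f.lower() for f in TF_FACTORS]]
    n_any = int((tf.sum(axis=1) >= 1).sum())
    n_all4 = int((tf.sum(axis=1) == 4).sum())
    return {
        "n_yap": n,
        "n_cobound_any": n_any,
        "n_cobound_all4": n_all4,
        "pct_cobound_any": percent(n_any, n),
        "pct_cobound_all4": percent(n_all4, n),
    }


@dataclass
class SuperEnhancerCall:
    region: GenomicInterval
    constituents: list[GenomicInterval]
    total_signal: float
    rank: int = -1  # ascending by total signal
    is_se: bool = False


def stitch_superenhancers(
    loci: Sequence[GenomicInterval],
    signals: Sequence[float],
    stitch_gap: int = 12500,
) -> list[SuperEnhancerCall]:
    """ROSE-style super-enhancer calling.

    Loci whose gaps are <= ``stitch_gap`` are stitched into regions; regions
    are ranked ascending by total signal; both axes are scaled to the unit
    square and the cutoff is the signal of the first region where the
    discrete slope of the rank-signal curve exceeds 1.  Regions with signal
    >= cutoff are super-enhancers (SE), the rest regular enhancers (RE).
    Fewer than 3 regions, or an all-equal signal curve, yields no SE.
    """
    if len(loci) != len(signals):
        raise ValueError("loci/signals length mismatch")
    if any(s < 0 for s in signals):
        raise ValueError("signals must be nonnegative")
    order = sorted(
        range(len(loci)), key=lambda i: (loci[i].chrom, loci[i].start, loci[i].end)
    )
    calls: list[SuperEnhancerCall] = []
    cur: list[int] = []
    for i in order:
        if cur:
            prev = loci[cur[-1]]
            gap = loci[i].start - prev.end
            if loci[i].chrom == prev.chrom and gap <= stitch_gap:
                cur.append(i)
                continue
            calls.append(_make_region(loci, signals, cur))
            cur = []
        cur.append(i)
    if cur:
        calls.append(_make_region(loci, signals, cur))

    n = len(calls)
    by_sig = sorted(range(n), key=lambda i: (calls[i].total_signal, i))
    for r, i in enumerate(by_sig):
        calls[i].rank = r
    if n < 3:
        warnings.warn("fewer than 3 stitched regions; tangent undefined, all RE")
        return calls
    sig = np.array([calls[i].total_signal for i in by_sig])
    if sig.max() == sig.min():
        return calls  # linear curve: no point exceeds the tangent
    y = (sig - sig.min()) / (sig.max() - sig.min())
    slope = np.diff(y) * (n - 1)  # d(y_scaled)/d(x_scaled), x step = 1/(n-1)
    above = np.nonzero(slope > 1.0)[0]
    if len(above) == 0:
        return calls
    cutoff = float(sig[above[0] + 1])
    for c in calls:
        c.is_se = c.total_signal >= cutoff
    return calls


def _make_region(loci, signals, idxs) -> SuperEnhancerCall:
    members = [loci[i] for i in idxs]
    start = min(m.start for m in members)
    end = max(m.end for m in members)
    total = float(sum(signals[i] for i in idxs))
    region = GenomicInterval(members[0].chrom, start, end, score=total)
    return SuperEnhancerCall(region=region, constituents=members, total_signal=total)


def se_overlap_summary(
    annotations: pd.DataFrame, se_calls: Sequence[SuperEnhancerCall]
) -> pd.DataFrame:
    """Per co-binding category: constituent loci inside SE vs RE regions.

    Loci of ``annotations`` not constituent to any stitched region count as
    RE.  Fractions are per column (share of the category among SE and RE
    loci respectively).
    """
    in_se: set[str] = set()
    for call in se_calls:
        if call.is_se:
            in_se.update(m.locus_id for m in call.constituents)
    cat = annotations["category"]
    se_counts = cat[cat.index.isin(in_se)].value_counts()
    re_counts = cat[~cat.index.isin(in_se)].value_counts()
    df = pd.DataFrame(
        {
            "SE": se_counts.reindex(CATEGORIES, fill_value=0),
            "RE": re_counts.reindex(CATEGORIES, fill_value=0),
        }
    )
    for col in ("SE", "RE"):
        tot = df[col].sum()
        df[f"frac_{col}"] = df[col] / tot if tot > 0 else 0.0
    return df
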