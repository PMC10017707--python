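"""TF footprint quantification from per-base insertion signal.

Antibody-tethered Tn5 tagments accessible chromatin around a bound factor,
but the motif base pairs under the factor are protected, leaving a local
dip (footprint) in the insertion profile.  Around each motif occurrence we
summarize a strand-oriented window as:

* ``flank_height`` — mean insertion signal in the two windows immediately
  flanking the motif core, as a fold over the local background (the
  outermost stretch of the window).  Dimensionless, so comparable across
  antibodies with different depths.
* ``footprint_depth`` — flank height minus the same fold-over-background
  quantity for the core.
* ``relative_depth`` — footprint depth / flank height; 0 for no
  protection, 1 for a fully protected core.

Per-site depths are split into bound/unbound by a two-component Gaussian
mixture; sites assigned to the higher-mean component are "bound".  A
simplified k-mer expectation track is provided for sequence-bias
flattening of profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.mixture import GaussianMixture

from .intervals import GenomicInterval

__all__ = [
    "InsertionProfile",
    "FootprintMetrics",
    "aggregate_profile",
    "footprint_metrics",
    "per_site_depths",
    "classify_bound",
    "kmer_bias_expectation",
    "bias_correct",
]


@dataclass
class InsertionProfile:
    """Per-base insertion counts around one motif occurrence.

    The counts vector spans ``half_width`` bases, the motif core
    (``motif_width`` bases), then ``half_width`` bases, in genomic order;
    minus-strand sites are reversed before aggregation so that all
    profiles read 5'->3' relative to the motif.
    """

    site: GenomicInterval
    half_width: int
    motif_width: int
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        expected = 2 * self.half_width + self.motif_width
        if len(self.counts) != expected:
            raise ValueError(
                f"profile length {len(self.counts)} != 2*{self.half_width}"
                f"+{self.motif_width}"
            )
        if np.any(self.counts < 0):
            raise ValueError("insertion counts must be nonnegative")

    def oriented_counts(self) -> np.ndarray:
        return self.counts[::-1] if self.site.strand == "-" else self.counts


@dataclass
class FootprintMetrics:
    flank_height: float
    footprint_depth: float
    relative_depth: float
    bound: bool | None = None


def aggregate_profile(profiles: Sequence[InsertionProfile]) -> np.ndarray:
    """Positionwise mean of strand-oriented profiles (identical geometry)."""
    if not profiles:
        raise ValueError("no profiles")
    geom = (profiles[0].half_width, profiles[0].motif_width)
    for p in profiles:
        if (p.half_width, p.motif_width) != geom:
            raise ValueError("window geometry mismatch among profiles")
    return np.mean([p.oriented_counts() for p in profiles], axis=0)


def footprint_metrics(
    profile: InsertionProfile | np.ndarray,
    motif_width: int | None = None,
    flank_width: int = 20,
    background_width: int = 50,
) -> FootprintMetrics:
    """Flank height, footprint depth and relative depth of one profile.

    ``flank_width`` bases on each side of the core are the flanks; the
    outermost ``background_width`` bases on each side are the local
    background.  Requires half_width >= flank_width + background_width and
    a nonzero background mean.
    """
    if isinstance(profile, InsertionProfile):
        counts = profile.oriented_counts()
        motif_width = profile.motif_width
        half = profile.half_width
    else:
        counts = np.asarray(profile, dtype=float)
        if motif_width is None:
            raise ValueError("motif_width required for a bare array")
        half = (len(counts) - motif_width) // 2
        if 2 * half + motif_width != len(counts):
            raise ValueError("array length minus motif width must be even")
    if half < flank_width + background_width:
        raise ValueError(
            "window too small: half-width must cover flank + background"
        )
    core = counts[half : half + motif_width]
    flanks = np.r_[counts[half - flank_width : half],
                   counts[half + motif_width : half + motif_width + flank_width]]
    background = np.r_[counts[:background_width], counts[-background_width:]]
    bg = float(background.mean())
    if bg <= 0:
        raise ValueError("zero background signal")
    flank_height = float(flanks.mean()) / bg
    core_height = float(core.mean()) / bg
    depth = flank_height - core_height
    rel = depth / flank_height if flank_height > 0 else 0.0
    return FootprintMetrics(flank_height, depth, rel)


def per_site_depths(
    profiles: Sequence[InsertionProfile],
    flank_width: int = 20,
    background_width: int = 50,
) -> np.ndarray:
    """Footprint depth of every site (the score used for bound/unbound)."""
    return np.array(
        [
            footprint_metrics(
                p, flank_width=flank_width, background_width=background_width
            ).footprint_depth
            for p in profiles
        ]
    )


def classify_bound(
    scores: Sequence[float], random_state: int = 0
) -> tuple[np.ndarray, float]:
    """Bound/unbound split of per-site footprint-depth scores.

    Fits a two-component Gaussian mixture; sites with posterior > 0.5 for
    the higher-mean component are bound.  The reported threshold is the
    smallest score called bound (+inf when nothing is).  Degenerate fits —
    all-identical scores, or components whose means are inseparable
    relative to the pooled spread — call everything unbound, with a
    warning.
    """
    scores = np.asarray(scores, dtype=float)
    if len(scores) < 10:
        raise ValueError("need at least 10 sites")
    sd = scores.std()
    if sd < 1e-12:
        warnings.warn("degenerate (constant) scores: all sites called unbound")
        return np.zeros(len(scores), dtype=bool), float("inf")
    gm = GaussianMixture(
        n_components=2, n_init=5, random_state=random_state
    ).fit(scores[:, None])
    means = gm.means_.ravel()
    if abs(means[1] - means[0]) < 0.05 * sd:
        warnings.warn("unimodal fit: all sites called unbound")
        return np.zeros(len(scores), dtype=bool), float("inf")
    hi = int(np.argmax(means))
    post = gm.predict_proba(scores[:, None])[:, hi]
    bound = post > 0.5
    threshold = float(scores[bound].min()) if bound.any() else float("inf")
    return bound, threshold


def kmer_bias_expectation(
    sequence: str, counts: Sequence[float], k: int = 6
) -> np.ndarray:
    """Expected insertions per position from global k-mer preference.

    Each position is attributed the k-mer centered on it; the expected
    signal at a position is proportional to the mean observed insertion
    count over all positions sharing that k-mer, rescaled so the expected
    track totals the observed one (signal-preserving).  Edge positions
    without a full centered k-mer get the global mean.
    """
    counts = np.asarray(counts, dtype=float)
    L = len(sequence)
    if k > L:
        raise ValueError("k exceeds sequence length")
    if len(counts) != L:
        raise ValueError("counts must cover the sequence")
    off = k // 2
    totals: dict[str, float] = {}
    nums: dict[str, int] = {}
    for i in range(L - k + 1):
        pos = i + off
        kmer = sequence[i : i + k]
        totals[kmer] = totals.get(kmer, 0.0) + counts[pos]
        nums[kmer] = nums.get(kmer, 0) + 1
    weights = {m: totals[m] / nums[m] for m in totals}
    global_mean = float(counts.mean())
    expected = np.full(L, global_mean)
    for i in range(L - k + 1):
        pos = i + off
        expected[pos] = weights[sequence[i : i + k]]
    if expected.sum() > 0:
        expected *= counts.sum() / expected.sum()
    return expected


def bias_correct(counts: Sequence[float], expected: Sequence[float]) -> np.ndarray:
    """Observed / expected, rescaled to preserve the total signal."""
    counts = np.asarray(counts, dtype=float)
    expected = np.asarray(expected, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(expected > 0, counts / expected, 0.0)
    if ratio.sum() > 0:
        ratio *= counts.sum() / ratio.sum()
    return ratio
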