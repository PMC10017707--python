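"""Synthetic panel generator with recorded ground truth.

Emulates the experimental design the analysis chain targets: a 19-line tumor-cell
panel with heterogeneous oncogene-dependency scores, H3K27ac/BRD4 signal
matrices over loci some of which rank-correlate with dependency at a
planted effect size, a reference cell line's peak sets for eight antibodies
with planted co-binding and chromatin-state structure (including spatially
clustered high-signal enhancers that stitch into super-enhancers),
exponential-growth competition assays observed with multinomial FACS
sampling, and Tn5 insertion profiles with planted motif protection.

Everything lives on one synthetic contig ``chrS``; all draws come from a
single seeded generator, so a fixed seed reproduces every file bit for bit.

Count model: negative binomial with variance mu*(1 + dispersion*mu)
(Poisson at dispersion 0).  The planted effect is a per-line mean curve
``base_mean * 2**(+/- A*(u - 1/2))`` where ``u`` is the dependency rank
scaled to [0, 1]; the amplitude ``A`` is calibrated numerically so that
the *expected sample Kendall tau-b* between noisy counts and dependency
equals ``effect_tau``.  At ``effect_tau = 1`` with dispersion 0 the
planted counts are emitted noiselessly (the perfectly rank-ordered limit).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .chromatin import combination_category, seven_cluster_label
from .dependency import PTF_FACTORS, CompetitionTimeSeries, ptf_score
from .footprint import InsertionProfile
from .intervals import GenomicInterval
from .io import write_bed, write_count_matrix

__all__ = [
    "PanelConfig",
    "SimTruth",
    "SCREEN_ANTIBODIES",
    "calibrate_effect_amplitude",
    "simulate_screen_counts",
    "simulate_state_truth",
    "simulate_competition",
    "simulate_insertion_profiles",
    "generate_panel",
]

SCREEN_ANTIBODIES = ("H3K27ac", "Brd4")


@dataclass
class PanelConfig:
    """Conditions of the synthetic panel.

    Defaults mirror the emulated study: 19 lines, Kendall cutoff-scale
    effects, overdispersed tag counts.
    """

    n_lines: int = 19
    n_loci: int = 2000
    frac_tss: float = 0.3
    n_pos_planted: int = 100
    n_neg_planted: int = 100
    effect_tau: float = 0.6
    dispersion: float = 0.2
    seed: int = 0

    # genome model
    contig: str = "chrS"
    locus_width: tuple[int, int] = (400, 1200)
    inter_gap: tuple[int, int] = (13000, 30000)

    # count model
    base_mean: float = 50.0
    null_mean_log_mu: float = float(np.log(30.0))
    null_mean_log_sd: float = 1.0
    detection_threshold: float | None = None  # default: median null mean

    # dependency scores (log2 units/day; higher = more dependent)
    dep_low: float = -0.2
    dep_high: float = 1.5

    # chromatin-state structure
    frac_active: float = 0.4
    n_se_clusters: int = 5
    se_cluster_size: int = 5
    se_intra_gap: int = 2000

    # competition assay
    rate_ref: float = 1.0
    facs_days: tuple[float, ...] = (0.0, 3.0, 7.0, 10.0, 14.0)
    facs_cells: int = 10000

    # footprint fixtures
    fp_sites_per_motif: int = 300
    fp_protection: float = 0.75
    fp_flank_fold: float = 4.0
    fp_background: float = 1.0
    fp_motif_width: int = 12
    fp_half_width: int = 100

    def __post_init__(self) -> None:
        if self.n_lines < 3 or self.n_loci <= 0:
            raise ValueError("need n_lines >= 3 and n_loci > 0")
        if not 0 <= self.frac_tss <= 1:
            raise ValueError("frac_tss must be in [0, 1]")
        if self.n_pos_planted + self.n_neg_planted > self.n_loci:
            raise ValueError("planted loci exceed n_loci")
        if not 0 < self.effect_tau <= 1:
            raise ValueError("effect_tau must be in (0, 1]")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.n_se_clusters * self.se_cluster_size > self.n_loci:
            raise ValueError("SE clusters exceed n_loci")


@dataclass
class SimTruth:
    """Ground truth serialized alongside every fixture."""

    lines: pd.DataFrame  # index line_id: dependency, rate_test, ptf levels+score
    loci: pd.DataFrame  # index locus_id: coordinates, labels, flags
    footprint_sites: pd.DataFrame  # index site_id: motif, bound, protection
    config: PanelConfig


# ---------------------------------------------------------------------------
# effect-size calibration


def _count_dists(mu: np.ndarray, dispersion: float, kmax: int):
    """pmf matrix (n x kmax+1) and P(X > k) matrix for NB/Poisson counts."""
    k = np.arange(kmax + 1)
    if dispersion == 0:
        pmf = stats.poisson.pmf(k[None, :], mu[:, None])
    else:
        r = 1.0 / dispersion
        p = r / (r + mu)
        pmf = stats.nbinom.pmf(k[None, :], r, p[:, None])
    cdf = np.cumsum(pmf, axis=1)
    sf = 1.0 - cdf
    return pmf, sf


def _expected_tau(amp: float, u: np.ndarray, base_mean: float, dispersion: float) -> float:
    """Expected sample Kendall tau-b between planted counts and dependency."""
    u = np.sort(u)
    mu = base_mean * 2.0 ** (amp * (u - 0.5))
    var = mu * (1.0 + dispersion * mu)
    kmax = int(mu.max() + 12 * np.sqrt(var.max()) + 20)
    pmf, sf = _count_dists(mu, dispersion, kmax)
    gt = pmf @ sf.T  # gt[s, t] = P(X_t > X_s)
    tie = pmf @ pmf.T
    n = len(u)
    iu, ju = np.triu_indices(n, k=1)
    num = float(np.sum(gt[iu, ju] - gt[ju, iu]))  # u ascending: u_j > u_i
    n0 = n * (n - 1) / 2.0
    exp_ties = float(np.sum(tie[iu, ju]))
    return num / np.sqrt((n0 - exp_ties) * n0)


def calibrate_effect_amplitude(
    effect_tau: float,
    u: np.ndarray,
    base_mean: float,
    dispersion: float,
    max_amp: float = 6.0,
) -> float:
    """Log2 amplitude A with expected sample tau-b ~= effect_tau.

    Bisection on the (monotone) map A -> expected tau.  Targets above the
    amplitude ceiling saturate at ``max_amp``; ``effect_tau = 1`` is the
    noiseless limit and returns the ceiling directly.
    """
    if effect_tau >= 1.0:
        return max_amp
    if _expected_tau(max_amp, u, base_mean, dispersion) <= effect_tau:
        return max_amp
    lo, hi = 0.0, max_amp
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if _expected_tau(mid, u, base_mean, dispersion) < effect_tau:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-4:
            break
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# screen counts


def _sample_counts(rng: np.random.Generator, mu: np.ndarray, dispersion: float):
    if dispersion == 0:
        return rng.poisson(mu).astype(float)
    r = 1.0 / dispersion
    p = r / (r + mu)
    return rng.negative_binomial(r, p).astype(float)


def simulate_screen_counts(
    cfg: PanelConfig,
    rng: np.random.Generator,
    dependency: np.ndarray,
    locus_ids: list[str] | None = None,
    line_ids: list[str] | None = None,
):
    """Per-antibody count matrices with planted rank-correlated loci.

    Returns ``(counts, labels)`` where ``counts`` maps each screen antibody
    to a loci x lines DataFrame and ``labels`` is the per-locus truth
    ('pos'/'neg'/'null').  Both marks share the planted mean curve
    (concordant) with independent noise.
    """
    n, m = cfg.n_loci, cfg.n_lines
    if len(dependency) != m:
        raise ValueError("dependency length != n_lines")
    u = (stats.rankdata(dependency) - 1) / (m - 1)

    labels = np.array(["null"] * n, dtype=object)
    planted = rng.choice(n, size=cfg.n_pos_planted + cfg.n_neg_planted, replace=False)
    pos_idx = planted[: cfg.n_pos_planted]
    neg_idx = planted[cfg.n_pos_planted :]
    labels[pos_idx] = "pos"
    labels[neg_idx] = "neg"

    if len(planted):
        amp = calibrate_effect_amplitude(
            cfg.effect_tau, u, cfg.base_mean, cfg.dispersion
        )
    else:
        amp = 0.0

    mu = np.empty((n, m))
    null_mu = rng.lognormal(cfg.null_mean_log_mu, cfg.null_mean_log_sd, size=n)
    mu[:] = null_mu[:, None]
    mu[pos_idx] = cfg.base_mean * 2.0 ** (amp * (u[None, :] - 0.5))
    mu[neg_idx] = cfg.base_mean * 2.0 ** (-amp * (u[None, :] - 0.5))

    noiseless_planted = cfg.effect_tau >= 1.0 and cfg.dispersion == 0
    if locus_ids is None:
        locus_ids = [f"locus{i:05d}" for i in range(n)]
    if line_ids is None:
        line_ids = [f"line{j + 1:02d}" for j in range(m)]
    counts = {}
    for ab in SCREEN_ANTIBODIES:
        x = _sample_counts(rng, mu, cfg.dispersion)
        if noiseless_planted:
            x[planted] = mu[planted]
        counts[ab] = pd.DataFrame(x, index=locus_ids, columns=line_ids)
    return counts, labels


# ---------------------------------------------------------------------------
# chromatin-state truth

_ACTIVE_CAT_P = {"all4": 0.35, "three": 0.25, "two": 0.15, "one": 0.10, "none": 0.15}
_INACTIVE_CAT_P = {"all4": 0.02, "three": 0.03, "two": 0.10, "one": 0.25, "none": 0.60}
_YAP_P_BY_COUNT = (0.05, 0.2, 0.3, 0.5, 0.8)

_MASKS_BY_COUNT = {
    4: [(1, 1, 1, 1)],
    3: [(0, 1, 1, 1), (1, 0, 1, 1), (1, 1, 0, 1), (1, 1, 1, 0)],
    2: [(1, 1, 0, 0), (1, 0, 1, 0), (1, 0, 0, 1), (0, 1, 1, 0), (0, 1, 0, 1), (0, 0, 1, 1)],
    1: [(1, 0, 0, 0), (0, 1, 0, 0), (0, 0, 1, 0), (0, 0, 0, 1)],
    0: [(0, 0, 0, 0)],
}
_NB_BY_NAME = {"all4": 4, "three": 3, "two": 2, "one": 1, "none": 0}


def _draw_mask(rng: np.random.Generator, active: bool):
    probs = _ACTIVE_CAT_P if active else _INACTIVE_CAT_P
    names = list(probs)
    name = names[rng.choice(len(names), p=np.array([probs[x] for x in names]))]
    masks = _MASKS_BY_COUNT[_NB_BY_NAME[name]]
    return masks[rng.integers(len(masks))]


def simulate_state_truth(cfg: PanelConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Place loci on chrS and plant state labels, TF masks and SE clusters.

    SE-cluster loci are consecutive runs with small (< stitch gap) spacing,
    forced to active CRE, and given ~100x enhancer signal; all other
    inter-locus gaps exceed the default 12.5 kb stitch gap, so planted SE
    membership is exactly the set of cluster loci.
    """
    n = cfg.n_loci
    cluster_of = np.full(n, -1)
    block = max(1, n // max(1, cfg.n_se_clusters))
    for c in range(cfg.n_se_clusters):
        start = c * block
        cluster_of[start : start + cfg.se_cluster_size] = c

    rows = []
    cursor = 10_000
    for i in range(n):
        w = int(rng.integers(cfg.locus_width[0], cfg.locus_width[1] + 1))
        start, end = cursor, cursor + w
        in_cluster = cluster_of[i] >= 0
        same_cluster_next = (
            i + 1 < n and in_cluster and cluster_of[i + 1] == cluster_of[i]
        )
        gap = (
            cfg.se_intra_gap
            if same_cluster_next
            else int(rng.integers(cfg.inter_gap[0], cfg.inter_gap[1] + 1))
        )
        cursor = end + gap

        if in_cluster:
            is_tss, k27, brd4 = False, True, True
            se_signal = float(rng.lognormal(np.log(100.0), 0.1))
        else:
            is_tss = bool(rng.random() < cfg.frac_tss)
            active = bool(rng.random() < cfg.frac_active)
            if active:
                k27 = brd4 = True
            else:
                roll = rng.random()
                k27 = roll < 0.2
                brd4 = 0.2 <= roll < 0.4
            se_signal = float(rng.lognormal(0.0, 0.25))
        jun, sox2, sox5, twist2 = _draw_mask(rng, k27 and brd4)
        nb = jun + sox2 + sox5 + twist2
        yap = bool(rng.random() < _YAP_P_BY_COUNT[nb])
        if not any((is_tss, k27, brd4, jun, sox2, sox5, twist2, yap)):
            # master loci are recognized by at least one antibody by
            # construction; give the residue a lone BRD4 call
            brd4 = True
        rows.append(
            dict(
                chrom=cfg.contig,
                start=start,
                end=end,
                is_tss=is_tss,
                h3k4me3=is_tss,
                h3k27ac=bool(k27),
                brd4=bool(brd4),
                jun=bool(jun),
                sox2=bool(sox2),
                sox5=bool(sox5),
                twist2=bool(twist2),
                yap=yap,
                is_active=bool(k27 and brd4),
                se_member=bool(in_cluster),
                se_signal=se_signal,
            )
        )
    df = pd.DataFrame(rows)
    df.index = [f"{cfg.contig}:{r.start}-{r.end}" for r in df.itertuples()]
    df.index.name = "locus"
    df["seven_cluster"] = [
        seven_cluster_label(r.h3k4me3, r.h3k27ac, r.brd4, r.jun, r.sox2)
        for r in df.itertuples()
    ]
    df["category"] = [
        combination_category(r.jun, r.sox2, r.sox5, r.twist2) for r in df.itertuples()
    ]
    return df


# ---------------------------------------------------------------------------
# competition assay


def simulate_competition(
    rate_ref: float,
    rate_test: float,
    days,
    n_cells: int,
    rng: np.random.Generator | int,
    line_id: str = "sim",
) -> CompetitionTimeSeries:
    """Exponential growth from a 50/50 mix, observed by multinomial FACS.

    Rates are log2 fold-changes per day.  At each day the expected test
    fraction is ``2**(rate_test*t) / (2**(rate_test*t) + 2**(rate_ref*t))``
    and the observed (test, ref) counts are multinomial with ``n_cells``
    analyzed cells.
    """
    if len(days) == 0:
        raise ValueError("days must be non-empty")
    days = np.asarray(days, dtype=float)
    if np.any(np.diff(days) <= 0):
        raise ValueError("days must be strictly increasing")
    if n_cells <= 0:
        raise ValueError("n_cells must be positive")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    # work with the rate difference to keep the odds exact at large t
    log2_odds = (rate_test - rate_ref) * days
    frac_test = 1.0 / (1.0 + 2.0 ** (-log2_odds))
    draws = np.array([rng.multinomial(n_cells, [f, 1 - f]) for f in frac_test])
    return CompetitionTimeSeries(
        line_id=line_id,
        days=days,
        count_test=draws[:, 0],
        count_ref=draws[:, 1],
    )


# ---------------------------------------------------------------------------
# insertion profiles


def simulate_insertion_profiles(
    background_rate: float,
    flank_fold: float,
    protection: float,
    motif_width: int,
    window: int,
    n_sites: int,
    rng: np.random.Generator | int,
    flank_width: int = 20,
    chrom: str = "chrS",
    start0: int = 100_000,
    spacing: int = 5_000,
) -> list[InsertionProfile]:
    """Poisson insertion profiles with planted motif protection.

    Per-base rates: ``background_rate`` in the outer window,
    ``background_rate * flank_fold`` in the flanks, and
    ``background_rate * flank_fold * (1 - protection)`` in the motif core.
    ``window`` is the half-width on each side of the core.  Strands
    alternate so aggregation exercises orientation handling.
    """
    if background_rate <= 0 or flank_fold <= 0:
        raise ValueError("rates must be positive")
    if not 0 <= protection <= 1:
        raise ValueError("protection must be in [0, 1]")
    if window <= motif_width:
        raise ValueError("window must exceed motif width")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    L = 2 * window + motif_width
    rate = np.full(L, background_rate)
    rate[window - flank_width : window] = background_rate * flank_fold
    rate[window + motif_width : window + motif_width + flank_width] = (
        background_rate * flank_fold
    )
    rate[window : window + motif_width] = (
        background_rate * flank_fold * (1.0 - protection)
    )
    out = []
    for i in range(n_sites):
        counts = rng.poisson(rate)
        strand = "+" if i % 2 == 0 else "-"
        s = start0 + i * spacing
        site = GenomicInterval(
            chrom, s, s + motif_width, name=f"site{i:05d}", strand=strand
        )
        # stored 5'->3' of the site; genomic order for minus strand is reversed
        stored = counts if strand == "+" else counts[::-1]
        out.append(
            InsertionProfile(
                site=site, half_width=window, motif_width=motif_width, counts=stored
            )
        )
    return out


# ---------------------------------------------------------------------------
# full panel


def generate_panel(cfg: PanelConfig, outdir: str | Path) -> SimTruth:
    """Write the full synthetic panel to ``outdir`` and return its truth.

    Layout::

        peaks/screen/<antibody>/<line>.bed   per-line peak calls (score = count)
        peaks/state/<antibody>.bed           reference-line peak sets
        counts/<antibody>.tsv                loci x lines count matrices
        facs.tsv                             competition counts, long format
        ptf_expression.tsv                   lines x 5 PTF expression levels
        footprint/sites_<motif>.bed          motif occurrences (stranded)
        footprint/profiles_<motif>.tsv       per-site insertion profiles
        truth/lines.tsv, truth/loci.tsv, truth/footprint_sites.tsv
        truth/config.json
    """
    cfg = cfg if isinstance(cfg, PanelConfig) else PanelConfig(**cfg)
    rng = np.random.default_rng(cfg.seed)
    outdir = Path(outdir)
    for sub in ("peaks/screen", "peaks/state", "counts", "footprint", "truth"):
        (outdir / sub).mkdir(parents=True, exist_ok=True)

    line_ids = [f"line{j + 1:02d}" for j in range(cfg.n_lines)]
    dependency = rng.uniform(cfg.dep_low, cfg.dep_high, size=cfg.n_lines)

    # chromatin-state truth fixes the locus coordinates
    loci_df = simulate_state_truth(cfg, rng)
    locus_ids = list(loci_df.index)
    loci = [
        GenomicInterval(cfg.contig, int(r.start), int(r.end))
        for r in loci_df.itertuples()
    ]

    counts, labels = simulate_screen_counts(
        cfg, rng, dependency, locus_ids=locus_ids, line_ids=line_ids
    )
    loci_df["label"] = labels

    thr = (
        cfg.detection_threshold
        if cfg.detection_threshold is not None
        else float(np.exp(cfg.null_mean_log_mu))
    )
    for ab in SCREEN_ANTIBODIES:
        write_count_matrix(counts[ab], outdir / "counts" / f"{ab}.tsv")
        abdir = outdir / "peaks" / "screen" / ab
        abdir.mkdir(exist_ok=True)
        for line in line_ids:
            col = counts[ab][line]
            present = col.to_numpy() > thr
            recs = [
                GenomicInterval(
                    l.chrom, l.start, l.end, l.locus_id, float(col.iloc[i]), ".", line
                )
                for i, l in enumerate(loci)
                if present[i]
            ]
            write_bed(recs, abdir / f"{line}.bed")

    # reference-line peak sets from the state truth
    flag_cols = {
        "H3K4me3": "h3k4me3",
        "H3K27ac": "h3k27ac",
        "Brd4": "brd4",
        "Jun": "jun",
        "Sox2": "sox2",
        "Sox5": "sox5",
        "Twist2": "twist2",
        "Yap": "yap",
    }
    for ab, col in flag_cols.items():
        score = loci_df["se_signal"] if ab == "H3K27ac" else pd.Series(1.0, index=loci_df.index)
        recs = [
            GenomicInterval(l.chrom, l.start, l.end, l.locus_id, float(score.iloc[i]))
            for i, l in enumerate(loci)
            if bool(loci_df[col].iloc[i])
        ]
        write_bed(recs, outdir / "peaks" / "state" / f"{ab}.bed")

    # PTF expression: resistant (low-dependency) lines express more PTFs
    span = cfg.dep_high - cfg.dep_low
    resistance = (cfg.dep_high - dependency) / span if span > 0 else np.zeros_like(dependency)
    expr = {}
    for f in PTF_FACTORS:
        scale = float(rng.uniform(1.0, 10.0))
        expr[f] = np.maximum(0.0, resistance + rng.normal(0.0, 0.15, cfg.n_lines)) * scale
    expr_df = pd.DataFrame(expr, index=line_ids)
    expr_df.index.name = "line_id"
    expr_df.to_csv(outdir / "ptf_expression.tsv", sep="\t", float_format="%.6g")
    ptf = ptf_score(expr_df)

    # competition assays: rate_test - rate_ref = -dependency
    facs_rows = []
    for j, line in enumerate(line_ids):
        ts = simulate_competition(
            cfg.rate_ref,
            cfg.rate_ref - dependency[j],
            cfg.facs_days,
            cfg.facs_cells,
            rng,
            line_id=line,
        )
        for d, ct, cr in zip(ts.days, ts.count_test, ts.count_ref):
            facs_rows.append((line, d, int(ct), int(cr)))
    facs = pd.DataFrame(facs_rows, columns=["line_id", "day", "count_test", "count_ref"])
    facs.to_csv(outdir / "facs.tsv", sep="\t", index=False, float_format="%.6g")

    # footprint fixtures: per motif, a mix of protected and unprotected sites
    fp_rows = []
    for mi, motif in enumerate(("JunAP1", "Sox2HMG")):
        profiles = []
        bound_truth = []
        for i in range(cfg.fp_sites_per_motif):
            is_bound = i < cfg.fp_sites_per_motif // 2
            prot = cfg.fp_protection if is_bound else 0.0
            p = simulate_insertion_profiles(
                cfg.fp_background,
                cfg.fp_flank_fold,
                prot,
                cfg.fp_motif_width,
                cfg.fp_half_width,
                1,
                rng,
                start0=2_000_000 + mi * 10_000_000 + i * 5_000,
            )[0]
            if i % 2 == 1:  # alternate strands; the rate model is symmetric
                p = InsertionProfile(
                    site=GenomicInterval(
                        p.site.chrom, p.site.start, p.site.end, p.site.name, 0.0, "-"
                    ),
                    half_width=p.half_width,
                    motif_width=p.motif_width,
                    counts=p.counts[::-1],
                )
            profiles.append(p)
            bound_truth.append(is_bound)
            fp_rows.append(
                dict(
                    site_id=f"{motif}_{i:05d}",
                    motif=motif,
                    chrom=p.site.chrom,
                    start=p.site.start,
                    end=p.site.end,
                    strand=p.site.strand,
                    bound=is_bound,
                    protection=prot,
                )
            )
        write_bed(
            [
                GenomicInterval(
                    p.site.chrom,
                    p.site.start,
                    p.site.end,
                    f"{motif}_{i:05d}",
                    0.0,
                    p.site.strand,
                )
                for i, p in enumerate(profiles)
            ],
            outdir / "footprint" / f"sites_{motif}.bed",
        )
        mat = pd.DataFrame(
            [p.counts for p in profiles],
            index=[f"{motif}_{i:05d}" for i in range(len(profiles))],
        )
        mat.index.name = "site_id"
        mat.columns = [f"pos{c}" for c in mat.columns]
        mat.to_csv(outdir / "footprint" / f"profiles_{motif}.tsv", sep="\t")
    fp_truth = pd.DataFrame(fp_rows).set_index("site_id")

    lines_df = pd.DataFrame(
        {
            "dependency": dependency,
            "rate_test": cfg.rate_ref - dependency,
            "rate_ref": cfg.rate_ref,
            "ptf_score": [s.score for s in ptf],
        },
        index=line_ids,
    )
    lines_df.index.name = "line_id"

    lines_df.to_csv(outdir / "truth" / "lines.tsv", sep="\t", float_format="%.6g")
    loci_df.to_csv(outdir / "truth" / "loci.tsv", sep="\t", float_format="%.6g")
    fp_truth.to_csv(outdir / "truth" / "footprint_sites.tsv", sep="\t", float_format="%.6g")
    with open(outdir / "truth" / "config.json", "w") as fh:
        json.dump(asdict(cfg), fh, indent=1, default=float)

    return SimTruth(lines=lines_df, loci=loci_df, footprint_sites=fp_truth, config=cfg)
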