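"""End-to-end orchestration over a panel directory.

Stages run in order — score-dependency, normalize, screen, classify,
footprint — each logging its parameters and record counts and writing its
outputs before the next starts, so a failing stage preserves everything
upstream.  A machine-readable ``summary.json`` collects the headline counts
(filter survivors, YapD_H/YapD_L sizes, state-class totals, SE count,
bound/unbound totals).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import chromatin, dependency, footprint, normalization, screen
from .intervals import GenomicInterval, merge_intervals, pair_by_max_overlap
from .io import read_bed, read_count_matrix, write_bed, write_count_matrix
from .synthetic import SCREEN_ANTIBODIES

logger = logging.getLogger("depscan")

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Paths and parameters of a full run.

    Parameter defaults are the pipeline's standard settings: tau cutoff
    0.3, detection in >= 3 samples, maximal normalized count >= 10, bin
    widths 1250 (TFs) / 10800 (histones, BRD4), 12.5 kb stitch gap.
    """

    input_dir: str
    output_dir: str
    cutoff: float = 0.3
    min_samples: int = 3
    min_max_count: float = 10.0
    bin_width_tf: int = 1250
    bin_width_histone: int = 10800
    stitch_gap: int = 12500
    flank_width: int = 20
    background_width: int = 50
    ptf_frac: float = 0.25
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def _stage(name):
    def deco(fn):
        def wrapper(cfg, state):
            logger.info("stage %s: start (params: %s)", name, asdict(cfg))
            try:
                return fn(cfg, state)
            except Exception as exc:  # noqa: BLE001 — rewrap with stage name
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        wrapper.stage_name = name
        return wrapper

    return deco


@_stage("score-dependency")
def _score_dependency(cfg: RunConfig, state: dict) -> None:
    ind, outd = Path(cfg.input_dir), Path(cfg.output_dir)
    facs = pd.read_csv(ind / "facs.tsv", sep="\t")
    rows = []
    for line_id, grp in facs.groupby("line_id", sort=True):
        ts = dependency.CompetitionTimeSeries(
            line_id=str(line_id),
            days=grp["day"].to_numpy(),
            count_test=grp["count_test"].to_numpy(),
            count_ref=grp["count_ref"].to_numpy(),
        )
        d = dependency.relative_growth_rate(ts)
        rows.append(
            dict(
                line_id=d.line_id,
                log2_rel_growth=d.log2_rel_growth,
                se=d.standard_error,
                yap_dependency=d.yap_dependency,
            )
        )
    dep = pd.DataFrame(rows).set_index("line_id")

    expr_path = ind / "ptf_expression.tsv"
    if expr_path.exists():
        expr = pd.read_csv(expr_path, sep="\t", index_col=0)
        scores = dependency.ptf_score(expr, frac=cfg.ptf_frac)
        dep["ptf_score"] = pd.Series(
            {s.line_id: s.score for s in scores}
        ).reindex(dep.index)
    dep.to_csv(outd / "dependency.tsv", sep="\t", float_format="%.6g")
    state["dependency"] = dep
    state["summary"]["n_lines"] = len(dep)
    logger.info("stage score-dependency: %d lines scored", len(dep))


@_stage("normalize")
def _normalize(cfg: RunConfig, state: dict) -> None:
    ind, outd = Path(cfg.input_dir), Path(cfg.output_dir)
    norm = {}
    fac_rows = []
    for ab in SCREEN_ANTIBODIES:
        raw = read_count_matrix(ind / "counts" / f"{ab}.tsv")
        factors = normalization.tmm_factors(raw)
        norm[ab] = normalization.normalize_counts(raw, factors)
        write_count_matrix(norm[ab], outd / f"normalized_{ab}.tsv")
        for s in factors.factors.index:
            fac_rows.append(
                dict(
                    antibody=ab,
                    sample=s,
                    library_size=int(factors.library_sizes[s]),
                    factor=float(factors.factors[s]),
                )
            )
    pd.DataFrame(fac_rows).to_csv(
        outd / "norm_factors.tsv", sep="\t", index=False, float_format="%.6g"
    )
    state["normalized"] = norm
    logger.info("stage normalize: factors for %d samples x %d antibodies",
                len(fac_rows) // len(SCREEN_ANTIBODIES), len(SCREEN_ANTIBODIES))


@_stage("screen")
def _screen(cfg: RunConfig, state: dict) -> None:
    ind, outd = Path(cfg.input_dir), Path(cfg.output_dir)
    if "dependency" not in state:
        raise FileNotFoundError("dependency scores missing (run score-dependency)")
    tables = {}
    for ab in SCREEN_ANTIBODIES:
        abdir = ind / "peaks" / "screen" / ab
        peaks_by_sample = {
            p.stem: read_bed(p) for p in sorted(abdir.glob("*.bed"))
        }
        if not peaks_by_sample:
            raise FileNotFoundError(f"no peak files under {abdir}")
        tables[ab] = screen.build_master_table(
            peaks_by_sample, antibody=ab, counts=state["normalized"][ab]
        )
    pairs = screen.filter_for_screen(
        tables["H3K27ac"],
        tables["Brd4"],
        min_samples=cfg.min_samples,
        min_max_count=cfg.min_max_count,
    )
    scores = state["dependency"]["yap_dependency"]
    result = screen.dependency_screen(pairs, scores, cutoff=cfg.cutoff)
    result.to_csv(outd / "screen.tsv", sep="\t", index=False, float_format="%.6g")

    for lab, fname in (("YapD_H", "yapd_high.bed"), ("YapD_L", "yapd_low.bed")):
        sub = result[result.label == lab]
        recs = []
        for r in sub.itertuples():
            iv = pairs.loci_k27ac[r.Index]
            recs.append(
                GenomicInterval(
                    iv.chrom,
                    iv.start,
                    iv.end,
                    f"tau_k27ac={r.tau_k27ac:.3f};tau_brd4={r.tau_brd4:.3f}",
                )
            )
        write_bed(recs, outd / fname)

    grid = screen.rrho_map(
        pd.Series(result.tau_k27ac.to_numpy(), index=result.locus_k27ac),
        pd.Series(result.tau_brd4.to_numpy(), index=result.locus_k27ac),
    )
    grid.to_csv(outd / "rrho_grid.tsv", sep="\t", float_format="%.6g")

    hits = result[result.label != "none"]
    if len(hits) >= 3:
        mat = np.log2(pairs.counts_k27ac.iloc[hits.index.to_numpy()] + 1.0)
        keep = mat.std(axis=1) > 0
        dropped = int((~keep).sum())
        if dropped:
            logger.info("screen clustering: dropped %d constant rows", dropped)
        if keep.sum() >= 3:
            order = screen.cluster_heatmap_order(mat[keep])
            pd.Series(
                [mat[keep].columns[i] for i in order.col_order], name="sample"
            ).to_csv(outd / "cluster_column_order.tsv", sep="\t", index=False)

    s = state["summary"]
    s["n_master_k27ac"] = len(tables["H3K27ac"].loci)
    s["n_master_brd4"] = len(tables["Brd4"].loci)
    s["n_screened_pairs"] = len(result)
    s["n_yapd_high"] = int((result.label == "YapD_H").sum())
    s["n_yapd_low"] = int((result.label == "YapD_L").sum())
    state["screen"] = result
    logger.info(
        "stage screen: %d pairs, %d YapD_H, %d YapD_L",
        len(result), s["n_yapd_high"], s["n_yapd_low"],
    )


@_stage("classify")
def _classify(cfg: RunConfig, state: dict) -> None:
    ind, outd = Path(cfg.input_dir), Path(cfg.output_dir)
    sdir = ind / "peaks" / "state"
    peaks = {p.stem: read_bed(p) for p in sorted(sdir.glob("*.bed"))}
    if not peaks:
        raise FileNotFoundError(f"no state peak files under {sdir}")
    master = merge_intervals([iv for pk in peaks.values() for iv in pk])
    ann = chromatin.classify_states(master, peaks)
    ann.to_csv(outd / "state_annotations.tsv", sep="\t")
    combos = chromatin.combination_counts(ann)
    combos.to_csv(outd / "combination_counts.tsv", sep="\t")
    yap_summary = chromatin.yap_cobinding_summary(ann)

    # super-enhancers: stitch H3K27ac+ CREs, signal = overlapping peak score
    k27 = peaks.get("H3K27ac", [])
    cre_mask = ann["h3k27ac"] & ~ann["is_tss"]
    cre_loci = [m for m, keep in zip(master, cre_mask) if keep]
    owner = pair_by_max_overlap(k27, cre_loci)
    signal = np.zeros(len(cre_loci))
    for p, j in zip(k27, owner):
        if j >= 0:
            signal[j] += p.score
    calls = chromatin.stitch_superenhancers(cre_loci, signal, stitch_gap=cfg.stitch_gap)
    write_bed(
        [c.region for c in calls if c.is_se], outd / "superenhancers.bed"
    )
    se_table = chromatin.se_overlap_summary(ann.loc[cre_mask], calls)
    se_table.to_csv(outd / "se_overlap_summary.tsv", sep="\t", float_format="%.6g")

    s = state["summary"]
    s["n_master_state"] = len(master)
    s["n_tss"] = int(ann.is_tss.sum())
    s["n_cre"] = int((~ann.is_tss).sum())
    s["n_active_tss"] = int((ann.is_tss & ann.is_active).sum())
    s["n_active_cre"] = int((~ann.is_tss & ann.is_active).sum())
    s["seven_cluster_totals"] = ann.seven_cluster.value_counts().to_dict()
    s["n_stitched_regions"] = len(calls)
    s["n_superenhancers"] = int(sum(c.is_se for c in calls))
    s["yap_cobinding"] = yap_summary
    logger.info(
        "stage classify: %d loci (%d TSS / %d CRE), %d SE of %d regions",
        len(master), s["n_tss"], s["n_cre"], s["n_superenhancers"],
        s["n_stitched_regions"],
    )


@_stage("footprint")
def _footprint(cfg: RunConfig, state: dict) -> None:
    ind, outd = Path(cfg.input_dir), Path(cfg.output_dir)
    fdir = ind / "footprint"
    site_files = sorted(fdir.glob("sites_*.bed"))
    if not site_files:
        raise FileNotFoundError(f"no motif site files under {fdir}")
    totals = {"bound": 0, "unbound": 0, "all": 0}
    for sf in site_files:
        motif = sf.stem.removeprefix("sites_")
        sites = read_bed(sf)
        mat = pd.read_csv(fdir / f"profiles_{motif}.tsv", sep="\t", index_col=0)
        width = mat.shape[1]
        motif_width = len(sites[0])
        half = (width - motif_width) // 2
        profiles = [
            footprint.InsertionProfile(
                site=s,
                half_width=half,
                motif_width=motif_width,
                counts=mat.loc[s.name].to_numpy(),
            )
            for s in sites
        ]
        depths = footprint.per_site_depths(
            profiles, flank_width=cfg.flank_width, background_width=cfg.background_width
        )
        bound, threshold = footprint.classify_bound(depths, random_state=cfg.seed)
        agg = footprint.aggregate_profile(profiles)
        m = footprint.footprint_metrics(
            agg,
            motif_width=motif_width,
            flank_width=cfg.flank_width,
            background_width=cfg.background_width,
        )
        out = pd.DataFrame(
            {
                "site_id": [s.name for s in sites],
                "footprint_depth": depths,
                "bound": bound,
            }
        )
        out.to_csv(outd / f"footprint_{motif}.tsv", sep="\t", index=False,
                   float_format="%.6g")
        np.savetxt(outd / f"aggregate_{motif}.tsv", agg, fmt="%.6g")
        totals["bound"] += int(bound.sum())
        totals["unbound"] += int((~bound).sum())
        totals["all"] += len(bound)
        logger.info(
            "stage footprint: motif %s — %d/%d bound, threshold %.3g, "
            "aggregate flank height %.3g rel depth %.3g",
            motif, int(bound.sum()), len(bound), threshold,
            m.flank_height, m.relative_depth,
        )
    state["summary"]["footprint_totals"] = totals


_STAGES = (_score_dependency, _normalize, _screen, _classify, _footprint)


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage and write ``summary.json``; returns the summary."""
    outd = Path(cfg.output_dir)
    outd.mkdir(parents=True, exist_ok=True)
    state: dict = {"summary": {"seed": cfg.seed}}
    logger.info("pipeline start: seed=%d input=%s", cfg.seed, cfg.input_dir)
    for stage in _STAGES:
        stage(cfg, state)
    with open(outd / "summary.json", "w") as fh:
        json.dump(state["summary"], fh, indent=1, sort_keys=True)
    return state["summary"]
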