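"""End-to-end pipeline: read → assign → score → tally → test → report.

The across-boundary tally is tested against an equal-thirds multinomial
(break / uncertain / homogeneity) and the within-centre tally against
equal halves (break / homogeneity), each with a Monte-Carlo simulated
p-value.  All randomness flows from the single configured seed; a run is
byte-identical for a given config and seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import List, Optional, Sequence

import pandas as pd

from .assignment import Assignment, Status, assign_all, assignments_frame
from .coe_map import CoEMap, coe_adjacency, load_coe_map
from .gof_test import GofResult, mc_pvalue
from .pair_scoring import (
    Category,
    PairScore,
    ScoreTally,
    pair_scores_frame,
    score_all,
    study_summary,
    tally,
    tally_frames,
)
from .study_io import StudySet, read_populations

logger = logging.getLogger("coebreaks")

__all__ = ["PipelineConfig", "PipelineResult", "PipelineError", "run_analysis", "run_pipeline", "render_report"]

ACROSS_CATEGORIES = (Category.BREAK, Category.UNCERTAIN, Category.HOMOGENEITY)
WITHIN_CATEGORIES = (Category.BREAK, Category.HOMOGENEITY)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of one pipeline run (echoed into every output)."""

    populations: Optional[str] = None
    coe_map: Optional[str] = None
    out_dir: Optional[str] = None
    adjacency_mode: str = "rook"
    buffer_cells: int = 1
    buffer_km: float = 0.0
    include_uncertain_within: bool = False
    replicates: int = 10_000
    seed: int = 0


@dataclass
class PipelineResult:
    """In-memory outputs of one analysis run."""

    config: PipelineConfig
    assignments: List[Assignment]
    pairs: List[PairScore]
    tally: ScoreTally
    summary: pd.DataFrame
    gof_across: Optional[GofResult]
    gof_within: Optional[GofResult]
    warnings: List[str] = field(default_factory=list)

    @property
    def across_break_pct(self) -> Optional[float]:
        n = self.tally.across_total
        return 100.0 * self.tally.across[Category.BREAK] / n if n else None

    @property
    def within_break_pct(self) -> Optional[float]:
        n = self.tally.within_total
        return 100.0 * self.tally.within[Category.BREAK] / n if n else None


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc

        return wrapper

    return deco


def run_analysis(s: StudySet, m: CoEMap, cfg: PipelineConfig) -> PipelineResult:
    """Run the full concordance analysis in memory."""
    warnings: List[str] = []
    if not s.populations:
        raise PipelineError("stage 'read' failed: empty population table")

    assignments = _stage("assign")(assign_all)(
        s, m, cfg.buffer_cells, cfg.buffer_km, cfg.adjacency_mode
    )
    outside = [a for a in assignments if a.status is Status.OUTSIDE]
    if outside:
        keys = [f"{a.population.study_id}/{a.population.population_id}" for a in outside]
        msg = f"{len(outside)} population(s) outside every CoE, excluded: {keys[:10]}"
        warnings.append(msg)
        logger.warning(msg)

    adjacency = _stage("adjacency")(coe_adjacency)(m, cfg.adjacency_mode)
    pairs = _stage("score")(score_all)(
        assignments, adjacency, cfg.include_uncertain_within
    )
    t = _stage("tally")(tally)(pairs)
    summary = _stage("summarize")(study_summary)(pairs, s)

    gof_across = gof_within = None
    across = t.across
    if t.across_total > 0:
        obs = [across[c] for c in ACROSS_CATEGORIES]
        k = len(obs)
        gof_across = _stage("test")(mc_pvalue)(
            obs, [1.0 / k] * k, cfg.replicates, cfg.seed
        )
    within = t.within
    if t.within_total > 0:
        obs = [within[c] for c in WITHIN_CATEGORIES]
        k = len(obs)
        gof_within = _stage("test")(mc_pvalue)(
            obs, [1.0 / k] * k, cfg.replicates, cfg.seed + 1
        )

    return PipelineResult(cfg, assignments, pairs, t, summary, gof_across, gof_within, warnings)


def _fmt_pct(x: Optional[float]) -> str:
    return "NA" if x is None else f"{x:.1f}"


def render_report(result: PipelineResult) -> str:
    """Plain-text/Markdown report: tallies, percentages and test results."""
    t = result.tally
    lines = ["# Phylogeographic breaks vs. Centre-of-Endemism boundaries", ""]
    lines.append("## Across-boundary comparisons")
    if t.across_total:
        a = t.across
        lines += [
            f"- population pairs compared across {len(t.per_boundary)} "
            f"adjacent-CoE boundaries: {t.across_total}",
            f"- phylogeographic breaks: {a[Category.BREAK]} "
            f"({_fmt_pct(result.across_break_pct)}%)",
            f"- uncertain CoE membership: {a[Category.UNCERTAIN]}",
            f"- inter-CoE homogeneity: {a[Category.HOMOGENEITY]}",
            f"- combined non-break pairs (uncertain + homogeneous): "
            f"{t.across_nonbreak_combined}",
        ]
        g = result.gof_across
        lines.append(
            f"- equal-probability test: chi2 = {g.statistic:.1f}, df = {g.df}, "
            f"MC p = {g.p_mc:.3g} ({g.replicates} replicates, seed {g.seed})"
        )
        lines += ["", "| boundary | break | uncertain | homogeneity |", "|---|---|---|---|"]
        for b, c in sorted(t.per_boundary.items()):
            lines.append(
                f"| {b[0]}–{b[1]} | {c[Category.BREAK]} | "
                f"{c[Category.UNCERTAIN]} | {c[Category.HOMOGENEITY]} |"
            )
    else:
        lines.append("- no across-boundary pairs: not applicable")
    lines += ["", "## Within-centre comparisons"]
    if t.within_total:
        w = t.within
        lines += [
            f"- population pairs compared within {len(t.per_coe)} CoEs: {t.within_total}",
            f"- intra-CoE divergence (breaks): {w[Category.BREAK]} "
            f"({_fmt_pct(result.within_break_pct)}%)",
            f"- intra-CoE homogeneity: {w[Category.HOMOGENEITY]}",
        ]
        g = result.gof_within
        lines.append(
            f"- equal-probability test: chi2 = {g.statistic:.1f}, df = {g.df}, "
            f"MC p = {g.p_mc:.3g} ({g.replicates} replicates, seed {g.seed})"
        )
    else:
        lines.append("- no within-centre pairs: not applicable")
    if result.warnings:
        lines += ["", "## Warnings"] + [f"- {w}" for w in result.warnings]
    return "\n".join(lines) + "\n"


def gof_frame(result: PipelineResult) -> pd.DataFrame:
    rows = []
    for name, cats, g in (
        ("across", ACROSS_CATEGORIES, result.gof_across),
        ("within", WITHIN_CATEGORIES, result.gof_within),
    ):
        if g is None:
            continue
        rows.append(
            {
                "analysis": name,
                "categories": "|".join(c.value for c in cats),
                "observed": "|".join(str(x) for x in g.observed),
                "statistic": g.statistic,
                "df": g.df,
                "p_mc": g.p_mc,
                "replicates": g.replicates,
                "seed": g.seed,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["analysis", "categories", "observed", "statistic", "df", "p_mc", "replicates", "seed"],
    )


def write_outputs(result: PipelineResult, out_dir) -> Path:
    """Write every export table, the report and a config echo to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: List[Path] = []
    try:
        def w(name: str, writer):
            p = out / name
            writer(p)
            written.append(p)

        w("assignments.csv", lambda p: assignments_frame(result.assignments).to_csv(p, index=False))
        w("pair_scores.csv", lambda p: pair_scores_frame(result.pairs).to_csv(p, index=False))
        tb, tc = tally_frames(result.tally)
        w("tally_boundaries.csv", lambda p: tb.to_csv(p, index=False))
        w("tally_coes.csv", lambda p: tc.to_csv(p, index=False))
        w("study_summary.csv", lambda p: result.summary.to_csv(p, index=False))
        w("gof_results.csv", lambda p: gof_frame(result).to_csv(p, index=False))
        w("report.md", lambda p: p.write_text(render_report(result), encoding="utf-8"))
        log = {"config": asdict(result.config), "warnings": result.warnings}
        w("run_log.json", lambda p: p.write_text(json.dumps(log, indent=2), encoding="utf-8"))
    except Exception as exc:
        for p in written:  # keep the directory free of partial outputs
            p.unlink(missing_ok=True)
        raise PipelineError(f"stage 'write' failed: {exc}") from exc
    return out


def run_pipeline(cfg: PipelineConfig) -> Path:
    """File-to-file pipeline: read inputs, analyse, write all outputs."""
    if not cfg.populations or not cfg.coe_map or not cfg.out_dir:
        raise PipelineError("stage 'config' failed: populations, coe_map and out_dir are required")
    try:
        s = read_populations(cfg.populations)
    except Exception as exc:
        raise PipelineError(f"stage 'read' failed: {exc}") from exc
    try:
        m = load_coe_map(cfg.coe_map)
    except Exception as exc:
        raise PipelineError(f"stage 'load-map' failed: {exc}") from exc
    result = run_analysis(s, m, cfg)
    return write_outputs(result, cfg.out_dir)
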