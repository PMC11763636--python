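"""End-to-end orchestration: expression grading → gene layer → plant ranking.

One :class:`PipelineConfig` drives the whole flow: read the four inputs,
grade miRNAs by div, apply the experiment-count filter, classify net
direction, aggregate onto target genes (quadrants, distance ranking,
concordance test), score every plant miRNA against the down- and
up-regulated human sets, and report the headline numbers (down/up ratio,
concordance r and p, margin-exceedance fraction).

Outputs are plain TSVs plus a flat key=value run report; with the same
config and seed the run is byte-reproducible.  Any stage failure aborts the
run with the stage name and removes partial outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from . import complementarity as comp
from . import expression_stats as es
from . import gene_integration as gi
from . import io_formats as io

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and original cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline aborted in stage '{stage}': {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class PipelineConfig:
    """Paths and parameters for one full run.  ``seed`` is mandatory."""

    expression_path: str
    links_path: str
    gene_expression_path: str
    human_fasta: str
    plant_fasta: str
    out_dir: str
    seed: int
    min_experiments: int = es.DEFAULT_MIN_EXPERIMENTS
    div_cut: float = es.DEFAULT_DIV_CUT
    experiment_type: str | None = None
    top_k: int = gi.DEFAULT_TOP_K
    n_permutations: int = gi.DEFAULT_PERMUTATIONS
    positive_div_only: bool = False
    mode: comp.Mode = "global"
    match: float = 1.0
    mismatch: float = 0.0
    gap: float = -1.0
    allow_wobble: bool = False
    delta_threshold: float = comp.DEFAULT_DELTA_THRESHOLD
    dialects: Mapping[str, Mapping[str, str]] = field(default_factory=dict)


def _fmt(value) -> str:
    if isinstance(value, float):
        return format(value, ".10g")
    return str(value)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the report as an ordered dict.

    Writes ``mirna_summary.tsv``, ``gene_summary.tsv``, ``plant_ranking.tsv``
    and ``report.txt`` under ``config.out_dir``.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    report: dict[str, object] = {}
    for key in (
        "seed", "min_experiments", "div_cut", "experiment_type", "top_k",
        "n_permutations", "positive_div_only", "mode", "match", "mismatch",
        "gap", "allow_wobble", "delta_threshold",
    ):
        report[f"param.{key}"] = getattr(config, key)

    def _write(name: str, rows) -> None:
        path = out_dir / name
        io.write_tsv(rows, path)
        written.append(path)

    stage = "read_inputs"
    try:
        expr_records, expr_counts = io.read_expression_table(
            config.expression_path, config.dialects.get("expression")
        )
        links, link_counts = io.read_target_links(
            config.links_path, config.dialects.get("links")
        )
        gene_records, gene_counts = io.read_gene_expression_table(
            config.gene_expression_path, config.dialects.get("gene_expression")
        )
        human_seqs, human_counts = io.read_fasta_sequences(
            config.human_fasta, io.Kingdom.HUMAN
        )
        plant_seqs, plant_counts = io.read_fasta_sequences(
            config.plant_fasta, io.Kingdom.PLANT
        )
        report["count.expression_records"] = expr_counts.n_kept
        report["count.expression_skipped"] = expr_counts.n_skipped
        report["count.sign_disagreements"] = expr_counts.n_sign_disagreements
        report["count.target_links"] = link_counts.n_kept
        report["count.gene_records"] = gene_counts.n_kept
        report["count.human_sequences"] = human_counts.n_kept
        report["count.plant_sequences"] = plant_counts.n_kept

        stage = "summarize_mirnas"
        predicate = None
        if config.experiment_type:
            wanted = config.experiment_type.lower()
            predicate = lambda rec: rec.experiment_type.lower() == wanted
        summaries = es.summarize_mirnas(expr_records, predicate)
        report["count.mirnas_total"] = len(summaries)

        stage = "filter_by_min_experiments"
        kept = es.filter_by_min_experiments(summaries, config.min_experiments)
        report["count.mirnas_after_filter"] = len(kept)
        _write("mirna_summary.tsv", kept)

        stage = "down_up_ratio"
        ratio = es.down_up_ratio(kept, config.div_cut)
        report["headline.down_up_ratio"] = ratio

        stage = "gene_integration"
        gene_summaries, n_gene_omitted = gi.build_gene_summaries(
            links, kept, gene_records, positive_div_only=config.positive_div_only
        )
        if not gene_summaries:
            raise ValueError("no gene has both a surviving miRNA and expression data")
        report["count.genes_summarized"] = len(gene_summaries)
        report["count.genes_omitted_all_mirnas_filtered"] = n_gene_omitted
        ranked = gi.rank_genes_by_distance(gene_summaries, config.top_k)
        _write("gene_summary.tsv", ranked)

        stage = "concordance"
        r_obs, p_value = gi.mirna_gene_concordance(
            gene_summaries, config.n_permutations, config.seed
        )
        report["headline.concordance_r"] = r_obs
        report["headline.concordance_p"] = p_value

        stage = "plant_ranking"
        seq_by_id = {s.seq_id: s for s in human_seqs}
        down_set = [
            seq_by_id[s.mirna_id]
            for s in kept
            if es.classify_direction(s, config.div_cut) == "down"
            and s.mirna_id in seq_by_id
        ]
        up_set = [
            seq_by_id[s.mirna_id]
            for s in kept
            if es.classify_direction(s, config.div_cut) == "up"
            and s.mirna_id in seq_by_id
        ]
        report["count.down_set"] = len(down_set)
        report["count.up_set"] = len(up_set)
        params = comp.AlignmentParams(
            match=config.match,
            mismatch=config.mismatch,
            gap=config.gap,
            mode=config.mode,
            allow_wobble=config.allow_wobble,
        )
        rankings = comp.rank_plant_mirnas(plant_seqs, down_set, up_set, params)
        _write("plant_ranking.tsv", rankings)
        report["headline.delta_exceed_fraction"] = comp.delta_exceed_fraction(
            rankings, config.delta_threshold
        )
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        raise PipelineError(stage, exc) from exc

    report_path = out_dir / "report.txt"
    with open(report_path, "w", encoding="utf-8") as handle:
        for key, value in report.items():
            handle.write(f"{key}={_fmt(value)}\n")
    return report
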