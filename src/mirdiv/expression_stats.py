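"""Per-miRNA directional-expression grading.

Across a corpus of differential-expression experiments, each miRNA is graded
by the *div* statistic

    div = (num_down - num_up) / (num_down + num_up)

where ``num_down`` and ``num_up`` count the experiments in which the miRNA was
reported down- and up-regulated.  div is a bounded membership ratio in
[-1, 1]: +1 means the miRNA is down-regulated in every experiment, -1 up in
every experiment, 0 a perfect split.  For a miRNA whose per-experiment
probability of being reported down is p, div is a consistent estimator of
2p - 1.

miRNAs measured in too few experiments carry unreliable div values; the
standard filter keeps miRNAs with at least ``min_n`` experiments (default 6,
i.e. miRNAs seen in five or fewer experiments are dropped).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Callable, Iterable, Literal, Sequence

from .io_formats import ExpressionRecord, Status

__all__ = [
    "DivError",
    "MirnaDivSummary",
    "compute_div",
    "summarize_mirnas",
    "filter_by_min_experiments",
    "classify_direction",
    "down_up_ratio",
    "cancer_vs_normal_only",
]

Direction = Literal["down", "up", "ambiguous"]

#: Default minimum experiment count for a miRNA's div to be trusted.
DEFAULT_MIN_EXPERIMENTS = 6
#: Default |div| cut for calling a miRNA's net direction.
DEFAULT_DIV_CUT = 0.2


class DivError(ValueError):
    """Raised for undefined statistics (no experiments, no up-classified set)."""


@dataclass(frozen=True)
class MirnaDivSummary:
    """Per-miRNA experiment counts and the div membership ratio."""

    mirna_id: str
    num_down: int
    num_up: int
    n_experiments: int
    div: float

    @classmethod
    def from_counts(cls, mirna_id: str, num_down: int, num_up: int) -> "MirnaDivSummary":
        return cls(
            mirna_id=mirna_id,
            num_down=num_down,
            num_up=num_up,
            n_experiments=num_down + num_up,
            div=compute_div(num_down, num_up),
        )


def read_summary_tsv(path) -> list[MirnaDivSummary]:
    """Read back a miRNA summary table written by :func:`mirdiv.io_formats.write_tsv`."""
    import pandas as pd

    frame = pd.read_csv(path, sep="\t")
    return [
        MirnaDivSummary(
            mirna_id=str(row.mirna_id),
            num_down=int(row.num_down),
            num_up=int(row.num_up),
            n_experiments=int(row.n_experiments),
            div=float(row.div),
        )
        for row in frame.itertuples(index=False)
    ]


def compute_div(num_down: int, num_up: int) -> float:
    """Exact value of (num_down - num_up) / (num_down + num_up).

    Computed through an exact rational so e.g. (3, 1) gives exactly 0.5.
    Both counts zero is an error, never silently 0.
    """
    if num_down < 0 or num_up < 0:
        raise DivError(f"negative experiment counts ({num_down}, {num_up})")
    total = num_down + num_up
    if total == 0:
        raise DivError("undefined div: zero experiments")
    return float(Fraction(num_down - num_up, total))


def cancer_vs_normal_only(record: ExpressionRecord) -> bool:
    """Predicate restricting the corpus to cancer-vs-normal comparisons."""
    return record.experiment_type.lower() == "cancer vs normal"


def summarize_mirnas(
    records: Iterable[ExpressionRecord],
    experiment_filter: Callable[[ExpressionRecord], bool] | None = None,
) -> list[MirnaDivSummary]:
    """Count up/down experiments per miRNA and grade each by div.

    An optional predicate (e.g. :func:`cancer_vs_normal_only`) restricts which
    experiments are counted; by default all experiment types contribute.
    Output is sorted by (n_experiments desc, div desc, mirna_id asc) so the
    best-measured, most consistently down-regulated miRNAs come first.
    """
    counts: dict[str, list[int]] = {}
    for rec in records:
        if experiment_filter is not None and not experiment_filter(rec):
            continue
        down_up = counts.setdefault(rec.mirna_id, [0, 0])
        if rec.status is Status.DOWN:
            down_up[0] += 1
        else:
            down_up[1] += 1
    summaries = [
        MirnaDivSummary.from_counts(mirna_id, down, up)
        for mirna_id, (down, up) in counts.items()
    ]
    summaries.sort(key=lambda s: (-s.n_experiments, -s.div, s.mirna_id))
    return summaries


def filter_by_min_experiments(
    summaries: Iterable[MirnaDivSummary], min_n: int = DEFAULT_MIN_EXPERIMENTS
) -> list[MirnaDivSummary]:
    """Keep miRNAs measured in at least ``min_n`` experiments.

    The default of 6 drops every miRNA seen in five or fewer experiments.
    """
    if min_n < 1:
        raise ValueError(f"min_n must be >= 1, got {min_n}")
    return [s for s in summaries if s.n_experiments >= min_n]


def classify_direction(
    summary: MirnaDivSummary | float, div_cut: float = DEFAULT_DIV_CUT
) -> Direction:
    """Call a miRNA's net direction from its div value.

    ``down`` iff div >= div_cut, ``up`` iff div <= -div_cut, else
    ``ambiguous``; the boundary is inclusive so ties are classified
    deterministically.  ``div_cut=0`` selects the bare sign rule (strict
    inequalities, div == 0 stays ambiguous).
    """
    if div_cut < 0 or div_cut > 1:
        raise ValueError(f"div_cut must be in [0, 1], got {div_cut}")
    div = summary.div if isinstance(summary, MirnaDivSummary) else float(summary)
    if div_cut == 0:
        if div > 0:
            return "down"
        if div < 0:
            return "up"
        return "ambiguous"
    if div >= div_cut:
        return "down"
    if div <= -div_cut:
        return "up"
    return "ambiguous"


def down_up_ratio(
    summaries: Sequence[MirnaDivSummary], div_cut: float = DEFAULT_DIV_CUT
) -> float:
    """Ratio of down-classified to up-classified miRNAs at the given cut."""
    n_down = sum(1 for s in summaries if classify_direction(s, div_cut) == "down")
    n_up = sum(1 for s in summaries if classify_direction(s, div_cut) == "up")
    if n_up == 0:
        raise DivError("ratio undefined: no miRNA classified up at this cut")
    return n_down / n_up
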