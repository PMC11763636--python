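"""Seeded generators for all four pipeline inputs, with known ground truth.

No public accession ships with this package, so every stage is exercised on
synthetic data that emulates the real databases' shapes:

* expression records (dbDEMC-style): each miRNA i gets a true per-experiment
  down-probability p_i drawn from a three-component Beta mixture
  (down-biased / up-biased / neutral) and n_i ~ 1 + Poisson(mean - 1)
  experiments, each independently "down" with probability p_i.  The default
  mixture weights (0.60, 0.24, 0.16) encode the roughly 2.5:1 preponderance
  of down-regulated miRNAs seen in large cancer compendia.
* target links + gene logFC tables (miRTarBase / OncoDB-style): each gene is
  linked to a handful of miRNAs; its true signal s_g is the mean of the
  linked miRNAs' (2 p_i - 1), and its per-cancer logFC mixes that signal
  with Gaussian noise at a tunable coupling rho (rho=0: independent layers;
  rho=1, noise->0: logFC rank-identical to s_g).
* sequence libraries (miRBase / PMRD-style): uniform random A/C/G/U mature
  sequences, plus a *planted* benchmark in which a few plant sequences are
  high-identity mutants of down-set human miRNAs hidden among random decoys.

Every generator is a pure function of (config, seed): rerunning with the
same seed reproduces the records byte-for-byte, and the returned ground
truth attributes every record to the parameters that produced it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .io_formats import (
    ExpressionRecord,
    GeneExpressionRecord,
    Kingdom,
    SequenceRecord,
    Status,
    TargetLink,
)

__all__ = [
    "SimulationConfig",
    "MirnaGroundTruth",
    "GeneGroundTruth",
    "PlantedPlant",
    "PlantGroundTruth",
    "CANCER_TYPES",
    "simulate_expression_records",
    "simulate_gene_layer",
    "simulate_sequences",
    "simulate_plant_library",
]

#: Fixed cancer-type vocabulary for synthetic records.
CANCER_TYPES = (
    "bladder", "breast", "colorectal", "gastric", "glioma",
    "hepatocellular", "lung", "melanoma", "ovarian", "prostate",
)

_BASES = np.array(list("ACGU"))


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic universe.  ``seed`` is mandatory.

    The defaults are the package's reference study conditions: 500 miRNAs
    measured in ~100 experiments each, a 300-gene layer with ~5 links per
    gene, 20-24 nt sequences, and a plant library of 195 decoys plus 5
    planted 95%-identity mutants.
    """

    seed: int
    n_mirnas: int = 500
    experiments_mean: float = 100.0
    mixture_weights: tuple[float, float, float] = (0.60, 0.24, 0.16)
    beta_down: tuple[float, float] = (8.0, 2.0)
    beta_up: tuple[float, float] = (2.0, 8.0)
    beta_neutral: tuple[float, float] = (60.0, 60.0)
    n_genes: int = 300
    links_per_gene: int = 5
    coupling_rho: float = 0.0
    noise_sd: float = 0.5
    seq_length_range: tuple[int, int] = (20, 24)
    n_plant_decoys: int = 195
    n_planted: int = 5
    planted_identity: float = 0.95

    def __post_init__(self) -> None:
        if not math.isclose(sum(self.mixture_weights), 1.0, abs_tol=1e-9):
            raise ValueError(f"mixture weights must sum to 1, got {self.mixture_weights}")
        if any(w < 0 for w in self.mixture_weights):
            raise ValueError("mixture weights must be non-negative")
        if self.experiments_mean < 1:
            raise ValueError("experiments_mean must be >= 1")
        lo, hi = self.seq_length_range
        if not (15 <= lo <= hi <= 30):
            raise ValueError("seq_length_range must lie within [15, 30]")
        if not (0 < self.planted_identity <= 1):
            raise ValueError("planted_identity must be in (0, 1]")
        if not (-1 <= self.coupling_rho <= 1):
            raise ValueError("coupling_rho must be in [-1, 1]")


@dataclass(frozen=True)
class MirnaGroundTruth:
    """True down-probability and experiment count per simulated miRNA."""

    p_down: dict[str, float]
    n_experiments: dict[str, int]
    component: dict[str, str]  # "down" / "up" / "neutral"


@dataclass(frozen=True)
class GeneGroundTruth:
    """True coupled signal s_g = mean of (2 p_down - 1) over linked miRNAs."""

    signal: dict[str, float]
    linked_mirnas: dict[str, tuple[str, ...]]
    coupling_rho: float


@dataclass(frozen=True)
class PlantedPlant:
    plant_id: str
    source_id: str
    realized_identity: float
    n_mutations: int


@dataclass(frozen=True)
class PlantGroundTruth:
    planted: tuple[PlantedPlant, ...]

    @property
    def planted_ids(self) -> frozenset[str]:
        return frozenset(p.plant_id for p in self.planted)


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    # Independent, call-order-free streams per generator.
    return np.random.default_rng([config.seed, stream])


def simulate_expression_records(
    config: SimulationConfig,
) -> tuple[list[ExpressionRecord], MirnaGroundTruth]:
    """Draw the dbDEMC-style experiment corpus.

    For each miRNA: p_down from the Beta mixture, n ~ 1 + Poisson(mean-1)
    experiments, per-experiment status ~ Bernoulli(p_down), logFC magnitude
    |Normal(1, 0.5)| signed to agree with status, cancer type uniform over a
    fixed 10-name vocabulary.
    """
    rng = _rng(config, 1)
    names = ("down", "up", "neutral")
    shapes = (config.beta_down, config.beta_up, config.beta_neutral)
    components = rng.choice(3, size=config.n_mirnas, p=list(config.mixture_weights))
    records: list[ExpressionRecord] = []
    p_down: dict[str, float] = {}
    n_exp: dict[str, int] = {}
    comp_of: dict[str, str] = {}
    width = len(str(max(config.n_mirnas, 1)))
    for i in range(config.n_mirnas):
        mirna_id = f"hsa-sim-{i:0{width}d}"
        a, b = shapes[components[i]]
        p = float(rng.beta(a, b))
        n = 1 + int(rng.poisson(config.experiments_mean - 1))
        statuses = rng.random(n) < p
        magnitudes = np.abs(rng.normal(1.0, 0.5, size=n))
        cancers = rng.integers(0, len(CANCER_TYPES), size=n)
        p_down[mirna_id] = p
        n_exp[mirna_id] = n
        comp_of[mirna_id] = names[components[i]]
        for is_down, mag, c in zip(statuses, magnitudes, cancers):
            status = Status.DOWN if is_down else Status.UP
            records.append(
                ExpressionRecord(
                    mirna_id=mirna_id,
                    cancer_type=CANCER_TYPES[c],
                    subtype="",
                    cell_type="",
                    experiment_type="cancer vs normal",
                    log_fc=round(float(-mag if is_down else mag), 6),
                    status=status,
                )
            )
    truth = MirnaGroundTruth(p_down=p_down, n_experiments=n_exp, component=comp_of)
    return records, truth


def simulate_gene_layer(
    config: SimulationConfig, mirna_truth: MirnaGroundTruth
) -> tuple[list[TargetLink], list[GeneExpressionRecord], GeneGroundTruth]:
    """Draw miRNA→gene links and the per-gene per-cancer logFC table.

    Each gene links to 1 + Poisson(links_per_gene - 1) distinct miRNAs; its
    logFC in every cancer is rho * s_g + sqrt(1 - rho^2) * Normal(0,
    noise_sd), so rho is the true miRNA-gene coupling on the signal scale.
    """
    rng = _rng(config, 2)
    mirna_ids = sorted(mirna_truth.p_down)
    rho = config.coupling_rho
    links: list[TargetLink] = []
    gene_records: list[GeneExpressionRecord] = []
    signal: dict[str, float] = {}
    linked: dict[str, tuple[str, ...]] = {}
    width = len(str(max(config.n_genes, 1)))
    for g in range(config.n_genes):
        gene_id = f"GENE{g:0{width}d}"
        k = 1 + int(rng.poisson(max(config.links_per_gene - 1, 0)))
        k = min(k, len(mirna_ids))
        chosen = sorted(rng.choice(len(mirna_ids), size=k, replace=False))
        mirnas = tuple(mirna_ids[c] for c in chosen)
        s_g = float(np.mean([2 * mirna_truth.p_down[m] - 1 for m in mirnas]))
        signal[gene_id] = s_g
        linked[gene_id] = mirnas
        links.extend(TargetLink(mirna_id=m, gene_id=gene_id) for m in mirnas)
        noise = rng.normal(0.0, config.noise_sd, size=len(CANCER_TYPES))
        for cancer, eps in zip(CANCER_TYPES, noise):
            log_fc = rho * s_g + math.sqrt(1 - rho**2) * eps
            gene_records.append(
                GeneExpressionRecord(
                    gene_id=gene_id, cancer_type=cancer, log_fc=round(float(log_fc), 6)
                )
            )
    truth = GeneGroundTruth(signal=signal, linked_mirnas=linked, coupling_rho=rho)
    return links, gene_records, truth


def simulate_sequences(
    config: SimulationConfig,
    n: int,
    kingdom: Kingdom | str = Kingdom.HUMAN,
    stream: int = 3,
) -> list[SequenceRecord]:
    """Uniform random mature-miRNA sequences, lengths uniform in the range."""
    rng = _rng(config, stream)
    kingdom = Kingdom(kingdom)
    prefix = "hsa-rna" if kingdom is Kingdom.HUMAN else "pla-rna"
    lo, hi = config.seq_length_range
    records = []
    width = len(str(max(n, 1)))
    for i in range(n):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(_BASES[rng.integers(0, 4, size=length)])
        records.append(
            SequenceRecord(
                seq_id=f"{prefix}-{i:0{width}d}", sequence=seq, kingdom=kingdom
            )
        )
    return records


def sequences_for_mirnas(
    config: SimulationConfig, mirna_ids: Sequence[str], stream: int = 6
) -> list[SequenceRecord]:
    """Random human sequences whose ids are the given miRNA ids.

    Ties the expression corpus to a FASTA so the end-to-end pipeline can map
    classified miRNAs to sequences.
    """
    seqs = simulate_sequences(config, len(mirna_ids), Kingdom.HUMAN, stream=stream)
    return [replace(s, seq_id=mid) for s, mid in zip(seqs, mirna_ids)]


def simulate_plant_library(
    config: SimulationConfig, down_set: Sequence[SequenceRecord]
) -> tuple[list[SequenceRecord], PlantGroundTruth]:
    """Plant library with planted near-copies of down-set human miRNAs.

    ``n_planted`` sequences are copies of randomly chosen down-set members
    with round((1 - planted_identity) * L) positions mutated to a different
    base; ``n_plant_decoys`` are uniform random sequences.  The ground truth
    records each planted id, its human source and the realized identity.
    """
    if not down_set:
        raise ValueError("down_set must be non-empty")
    rng = _rng(config, 4)
    planted: list[PlantedPlant] = []
    records: list[SequenceRecord] = []
    width = len(str(max(config.n_planted, 1)))
    for i in range(config.n_planted):
        source = down_set[int(rng.integers(0, len(down_set)))]
        seq = list(source.sequence)
        n_mut = round((1 - config.planted_identity) * len(seq))
        positions = rng.choice(len(seq), size=n_mut, replace=False)
        for pos in positions:
            alternatives = [b for b in "ACGU" if b != seq[pos]]
            seq[pos] = alternatives[int(rng.integers(0, 3))]
        plant_id = f"pla-planted-{i:0{width}d}"
        records.append(
            SequenceRecord(seq_id=plant_id, sequence="".join(seq), kingdom=Kingdom.PLANT)
        )
        planted.append(
            PlantedPlant(
                plant_id=plant_id,
                source_id=source.seq_id,
                realized_identity=(len(seq) - n_mut) / len(seq),
                n_mutations=int(n_mut),
            )
        )
    decoys = simulate_sequences(config, config.n_plant_decoys, Kingdom.PLANT, stream=5)
    records.extend(
        replace(d, seq_id=d.seq_id.replace("pla-rna", "pla-decoy")) for d in decoys
    )
    return records, PlantGroundTruth(planted=tuple(planted))
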