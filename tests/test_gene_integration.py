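"""Gene-layer aggregation, quadrants, distance ranking, concordance test."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from mirdiv import gene_integration as gi
from mirdiv.expression_stats import MirnaDivSummary, summarize_mirnas
from mirdiv.io_formats import GeneExpressionRecord, TargetLink
from mirdiv.synthetic_data import (
    SimulationConfig,
    simulate_expression_records,
    simulate_gene_layer,
)


def _summary(mirna_id: str, div: float, n: int = 10) -> MirnaDivSummary:
    num_down = round(n * (1 + div) / 2)
    return MirnaDivSummary(mirna_id, num_down, n - num_down, n, div)


def _gene(gene_id, mean_div, mean_log_fc, distance=0.0):
    return gi.GeneSummary(
        gene_id=gene_id,
        mean_log_fc=mean_log_fc,
        mean_div=mean_div,
        n_targeting_mirnas=1,
        n_cancers=1,
        quadrant=gi.classify_quadrant(mean_div, mean_log_fc),
        distance=distance,
    )


class TestMeanLogFC:
    def test_two_cancers_average_to_zero(self):
        records = [GeneExpressionRecord("G1", "lung", 1.0), GeneExpressionRecord("G1", "breast", -1.0)]
        assert gi.compute_gene_mean_logfc(records) == {"G1": (0.0, 2)}

    def test_single_cancer_passthrough(self):
        records = [GeneExpressionRecord("G1", "lung", 2.5)]
        assert gi.compute_gene_mean_logfc(records)["G1"] == (2.5, 1)

    def test_matches_bruteforce_on_synthetic(self):
        config = SimulationConfig(seed=3, n_mirnas=50, experiments_mean=10, n_genes=100)
        _, truth = simulate_expression_records(config)
        _, gene_records, _ = simulate_gene_layer(config, truth)
        result = gi.compute_gene_mean_logfc(gene_records)
        for gene_id, (mean, n) in result.items():
            values = [r.log_fc for r in gene_records if r.gene_id == gene_id]
            assert n == len(values)
            assert mean == pytest.approx(np.mean(values), abs=1e-12)


class TestMeanDiv:
    def test_mean_over_linked_mirnas(self):
        links = [TargetLink("m1", "G1"), TargetLink("m2", "G1")]
        summaries = [_summary("m1", 1.0), _summary("m2", 0.0)]
        result, n_omitted = gi.compute_gene_mean_div(links, summaries)
        assert result == {"G1": (0.5, 2)} and n_omitted == 0

    def test_gene_with_only_filtered_mirnas_is_omitted_and_counted(self):
        links = [TargetLink("gone", "G1"), TargetLink("m1", "G2")]
        summaries = [_summary("m1", 0.4)]
        result, n_omitted = gi.compute_gene_mean_div(links, summaries)
        assert "G1" not in result and n_omitted == 1

    def test_duplicate_links_do_not_double_count(self):
        links = [TargetLink("m1", "G1"), TargetLink("m1", "G1"), TargetLink("m2", "G1")]
        summaries = [_summary("m1", 1.0), _summary("m2", 0.0)]
        result, _ = gi.compute_gene_mean_div(links, summaries)
        assert result["G1"] == (0.5, 2)

    def test_matches_bruteforce_on_synthetic_network(self):
        config = SimulationConfig(seed=4, n_mirnas=80, experiments_mean=15, n_genes=60)
        records, truth = simulate_expression_records(config)
        links, _, _ = simulate_gene_layer(config, truth)
        summaries = summarize_mirnas(records)
        result, _ = gi.compute_gene_mean_div(links, summaries)
        div_of = {s.mirna_id: s.div for s in summaries}
        for gene_id, (mean_div, n) in result.items():
            mirnas = {l.mirna_id for l in links if l.gene_id == gene_id}
            assert n == len(mirnas)
            assert mean_div == pytest.approx(np.mean([div_of[m] for m in mirnas]), abs=1e-12)


class TestQuadrants:
    @pytest.mark.parametrize(
        "mean_div,mean_log_fc,expected",
        [
            (0.5, 1.2, "I"),
            (-0.2, 0.7, "II"),
            (-0.3, -0.3, "III"),
            (0.8, -2.0, "IV"),
            (0.0, 3.0, "axis"),
            (0.4, 0.0, "axis"),
        ],
    )
    def test_sign_mapping(self, mean_div, mean_log_fc, expected):
        assert gi.classify_quadrant(mean_div, mean_log_fc) == expected

    @given(
        st.floats(-1, 1, allow_nan=False),
        st.floats(-10, 10, allow_nan=False),
    )
    def test_partition_is_total_and_unique(self, mean_div, mean_log_fc):
        quadrant = gi.classify_quadrant(mean_div, mean_log_fc)
        if mean_div == 0 or mean_log_fc == 0:
            assert quadrant == "axis"
        else:
            assert quadrant in ("I", "II", "III", "IV")


class TestDistanceRanking:
    def test_single_gene_zero_variance_axes(self):
        (top,) = gi.rank_genes_by_distance([_gene("G1", 0.3, 2.0)], k=5)
        assert top.distance == 0.0

    def test_symmetric_genes_tie_broken_by_id(self):
        genes = [_gene("B", 0.5, 1.0), _gene("A", -0.5, -1.0)]
        ranked = gi.rank_genes_by_distance(genes, k=2)
        assert [g.gene_id for g in ranked] == ["A", "B"]
        assert ranked[0].distance == pytest.approx(ranked[1].distance)

    def test_top_k_matches_bruteforce_sort(self):
        rng = np.random.default_rng(11)
        genes = [
            _gene(f"G{i:03d}", float(rng.uniform(-1, 1)), float(rng.normal(0, 2)))
            for i in range(200)
        ]
        ranked = gi.rank_genes_by_distance(genes, k=50)
        div = np.array([g.mean_div for g in genes])
        fc = np.array([g.mean_log_fc for g in genes])
        dz = (div - div.mean()) / div.std()
        fz = (fc - fc.mean()) / fc.std()
        dist = {g.gene_id: float(np.hypot(a, b)) for g, a, b in zip(genes, dz, fz)}
        expected = sorted(dist, key=lambda g: (-dist[g], g))[:50]
        assert [g.gene_id for g in ranked] == expected

    def test_axis_swap_invariance(self):
        rng = np.random.default_rng(12)
        genes = [
            _gene(f"G{i}", float(rng.uniform(-1, 1)), float(rng.normal(0, 3)))
            for i in range(40)
        ]
        swapped = [
            dataclasses.replace(g, mean_div=g.mean_log_fc, mean_log_fc=g.mean_div)
            for g in genes
        ]
        order = [g.gene_id for g in gi.rank_genes_by_distance(genes, 40)]
        order_swapped = [g.gene_id for g in gi.rank_genes_by_distance(swapped, 40)]
        assert order == order_swapped

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            gi.rank_genes_by_distance([_gene("G1", 0.1, 0.1)], k=0)


class TestConcordance:
    def test_identical_vectors_give_r_one(self):
        genes = [_gene(f"G{i}", 0.1 * i - 0.4, 0.1 * i - 0.4) for i in range(10)]
        r, p = gi.mirna_gene_concordance(genes, n_permutations=199, seed=1)
        assert r == pytest.approx(1.0)
        assert p <= 0.05

    def test_constant_axis_is_an_error(self):
        genes = [_gene(f"G{i}", 0.5, float(i)) for i in range(5)]
        with pytest.raises(ValueError, match="constant"):
            gi.mirna_gene_concordance(genes, n_permutations=199, seed=1)

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(7)
        genes = [
            _gene(f"G{i}", float(rng.uniform(-1, 1)), float(rng.normal())) for i in range(30)
        ]
        first = gi.mirna_gene_concordance(genes, n_permutations=499, seed=3)
        second = gi.mirna_gene_concordance(genes, n_permutations=499, seed=3)
        assert first == second

    def test_observed_r_is_spearman(self):
        rng = np.random.default_rng(8)
        genes = [
            _gene(f"G{i}", float(rng.uniform(-1, 1)), float(rng.normal())) for i in range(25)
        ]
        r, _ = gi.mirna_gene_concordance(genes, n_permutations=99, seed=0)
        x = [g.mean_div for g in genes]
        y = [g.mean_log_fc for g in genes]
        assert r == pytest.approx(stats.spearmanr(x, y).statistic)

    def test_pvalues_uniform_under_null(self):
        """With decoupled layers the permutation p-value is uniform (KS check)."""
        pvals = []
        for rep in range(120):
            config = SimulationConfig(
                seed=1000 + rep, n_mirnas=60, experiments_mean=15,
                n_genes=100, coupling_rho=0.0,
            )
            records, truth = simulate_expression_records(config)
            links, gene_records, _ = simulate_gene_layer(config, truth)
            summaries = summarize_mirnas(records)
            genes, _ = gi.build_gene_summaries(links, summaries, gene_records)
            _, p = gi.mirna_gene_concordance(genes, n_permutations=199, seed=rep)
            pvals.append(p)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01
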