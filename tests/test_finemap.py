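"""Region partitioning, Bayes factors, posteriors, and credible sets."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from twaskit.exceptions import ValidationError
from twaskit.finemap import (
    bayes_factor,
    credible_set,
    empirical_prior_scale,
    flag_novel_regions,
    gene_posteriors,
    partition_regions,
    region_credible_set,
    summarize_credible_sets,
)
from twaskit.sumstats import SumStats
from twaskit.twas import p_to_z


def _genes(tss_list, chrom="1"):
    return pd.DataFrame(
        {
            "gene": [f"g{i}" for i in range(len(tss_list))],
            "chrom": chrom,
            "tss": tss_list,
        }
    )


def _ss(pos_p):
    """SumStats with SNPs at given (pos, p-value) pairs on chromosome 1."""
    return SumStats(
        pd.DataFrame(
            {
                "snp": [f"rs{i}" for i in range(len(pos_p))],
                "chrom": "1",
                "pos": [p for p, _ in pos_p],
                "a1": "A",
                "a2": "G",
                "z": [p_to_z(pv) for _, pv in pos_p],
                "maf": 0.2,
                "n": 1000.0,
            }
        )
    )


class TestPartition:
    def test_nearby_tss_merge_into_one_region(self):
        regions = partition_regions(_genes([1_000_000, 1_400_000]))
        assert len(regions) == 1
        assert len(regions[0].members) == 2

    def test_distant_tss_split(self):
        regions = partition_regions(_genes([1_000_000, 3_000_000]))
        assert len(regions) == 2

    def test_single_gene_single_region(self):
        regions = partition_regions(_genes([5_000_000]))
        assert len(regions) == 1
        assert list(regions[0].members["gene"]) == ["g0"]

    def test_different_chromosomes_never_merge(self):
        genes = pd.DataFrame(
            {"gene": ["a", "b"], "chrom": ["1", "2"], "tss": [1_000_000, 1_000_000]}
        )
        assert len(partition_regions(genes)) == 2


class TestNovelFlags:
    def test_nearby_genomewide_hit_blocks_novelty(self):
        regions = partition_regions(_genes([2_000_000]))
        ss = _ss([(1_500_000, 1e-9)])  # 0.5 Mb from the TSS
        flag_novel_regions(regions, ss)
        assert regions[0].is_novel is False

    def test_subthreshold_best_snp_keeps_novelty(self):
        # best flanking SNP at P = 1.49e-5, far above genome-wide significance
        regions = partition_regions(_genes([2_000_000]))
        ss = _ss([(1_800_000, 1.49e-5), (2_100_000, 2e-3)])
        flag_novel_regions(regions, ss)
        assert regions[0].is_novel is True
        assert regions[0].no_snps_in_flank is False

    def test_empty_flank_is_novel_with_warning(self):
        regions = partition_regions(_genes([50_000_000]))
        ss = _ss([(1_000_000, 0.5)])
        flag_novel_regions(regions, ss)
        assert regions[0].is_novel is True
        assert regions[0].no_snps_in_flank is True


class TestBayesFactor:
    def test_formula_at_z_zero(self):
        for s in (0.5, 30.0, 100.0):
            assert bayes_factor(0.0, n=1000, sigma_a2=s / 1000) == pytest.approx(
                -0.5 * np.log1p(s)
            )

    def test_null_prior_gives_unit_bf(self):
        assert bayes_factor(7.0, n=1000, sigma_a2=0.0) == 0.0

    def test_hand_evaluated_closed_form(self):
        # z = 5, n*sigma_a2 = 100: -log(101)/2 + 12.5 * 100/101
        expected = -0.5 * np.log(101.0) + 12.5 * (100.0 / 101.0)
        assert bayes_factor(5.0, n=100, sigma_a2=1.0) == pytest.approx(expected)
        assert expected == pytest.approx(10.0687, abs=1e-4)

    def test_no_overflow_at_extreme_z(self):
        lbf = bayes_factor(40.0, n=142392, sigma_a2=30.0 / 142392)
        assert np.isfinite(lbf)
        assert lbf > 700  # would overflow exp()

    def test_empirical_prior_scale(self):
        z = np.array([6.0, -7.0, 5.0])
        assert empirical_prior_scale(z) == pytest.approx(np.mean(z**2) - 1.0)
        assert empirical_prior_scale(np.array([0.1])) == 0.0


class TestPosteriors:
    def test_symmetry(self):
        np.testing.assert_allclose(gene_posteriors(np.zeros(4)), 0.25)

    def test_domination(self):
        post = gene_posteriors(np.array([20.0, 0.0, 0.0]))
        assert post[0] > 0.999

    def test_softmax_arithmetic(self):
        post = gene_posteriors(np.array([2.0, 1.0, 0.0]))
        e = np.exp([2.0, 1.0, 0.0])
        np.testing.assert_allclose(post, e / e.sum())
        np.testing.assert_allclose(post, [0.665, 0.245, 0.090], atol=5e-4)

    @given(st.floats(-100, 100))
    @settings(deadline=None, max_examples=30)
    def test_invariant_to_constant_shift(self, c):
        lbf = np.array([3.0, -1.0, 0.5])
        np.testing.assert_allclose(
            gene_posteriors(lbf), gene_posteriors(lbf + c), atol=1e-9
        )


class TestCredibleSet:
    def test_dominant_gene_defines_singleton_set(self):
        cs = credible_set(np.array([0.94, 0.03, 0.02, 0.01]), rho=0.9)
        assert cs.members == [0]
        assert cs.achieved_density == pytest.approx(0.94)

    def test_cumulative_sum_by_hand(self):
        cs = credible_set(np.array([0.5, 0.3, 0.15, 0.05]), rho=0.9)
        assert cs.members == [0, 1, 2]
        assert cs.achieved_density == pytest.approx(0.95)

    def test_rho_one_keeps_all_positive(self):
        cs = credible_set(np.array([0.6, 0.4, 0.0]), rho=1.0)
        assert cs.members == [0, 1]

    def test_tie_break_on_gene_id(self):
        cs = credible_set(
            np.array([0.5, 0.5]), rho=0.4, gene_ids=["zzz", "aaa"]
        )
        assert cs.member_genes == ["aaa"]

    def test_set_shrinks_as_dominant_posterior_grows(self):
        sizes = []
        for top in (0.5, 0.7, 0.95):
            rest = (1 - top) / 3
            cs = credible_set(np.array([top, rest, rest, rest]), rho=0.9)
            sizes.append(len(cs.members))
        assert sizes == sorted(sizes, reverse=True)

    def test_region_credible_set_end_to_end(self):
        cs = region_credible_set(
            np.array([7.0, 1.0, 0.5]), n=142392, rho=0.9, gene_ids=list("abc")
        )
        assert cs.member_genes == ["a"]
        assert cs.posteriors[0] > 0.99


class TestSummaries:
    def _set(self, genes, posts=None):
        posts = posts or [1.0 / len(genes)] * len(genes)
        return credible_set(
            np.array(posts), rho=0.999999, gene_ids=genes
        )

    def test_counts_and_sizes(self):
        s1 = self._set(["A"], [1.0])
        s2 = self._set(["A", "B"], [0.6, 0.4])
        out = summarize_credible_sets([s1, s2])
        assert out["n_unique_genes"] == 2
        assert out["set_sizes"] == [1, 2]
        assert out["mean_size"] == pytest.approx(1.5)

    def test_same_gene_across_panels_collapses(self):
        s = self._set(["A", "A"], [0.6, 0.4])  # same gene via two panels
        out = summarize_credible_sets([s])
        assert out["n_unique_genes"] == 1
        assert out["set_sizes"] == [1]

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            summarize_credible_sets([])
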