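import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from gwaspost import meta
from gwaspost import simulate as sim
from gwaspost.meta import (
    AlignmentError,
    Locus,
    VariantAssociation,
    align_alleles,
    annotate_novelty,
    clump_loci,
    cross_ancestry_compare,
    filter_variants,
    ivw_meta,
    qvalue_fdr,
    sex_heterogeneity,
    two_sided_p,
)
from gwaspost.simulate import InputError


def va(beta=0.05, se=0.01, ea="A", nea="G", eaf=0.3, pos=100, p=0.5,
       rsid="rs1", n_cases=1000):
    return VariantAssociation(
        chrom="1", pos=pos, rsid=rsid, effect_allele=ea, non_effect_allele=nea,
        eaf=eaf, beta=beta, se=se, p=p, n_cases=n_cases, n_controls=3000,
    )


class TestVariantAssociation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"se": 0.0},
            {"se": -1.0},
            {"eaf": 0.0},
            {"eaf": 1.0},
            {"p": 0.0},
            {"ea": "A", "nea": "A"},
        ],
    )
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(InputError):
            va(**kwargs)


class TestAlignAlleles:
    def test_identical_alleles_unchanged(self):
        a, b = va(), va(beta=0.02)
        _, b2 = align_alleles(a, b)
        assert b2.beta == 0.02 and b2.eaf == b.eaf

    def test_swapped_alleles_flip(self):
        a = va()
        b = va(ea="G", nea="A", beta=0.05, eaf=0.3)
        _, b2 = align_alleles(a, b)
        assert b2.beta == pytest.approx(-0.05)
        assert b2.eaf == pytest.approx(0.7)
        assert b2.effect_allele == "A"

    def test_strand_complement_resolved(self):
        a = va(ea="A", nea="G")
        b = va(ea="T", nea="C", beta=0.04)  # complement strand, same direction
        _, b2 = align_alleles(a, b)
        assert b2.beta == pytest.approx(0.04)

    def test_palindromic_high_maf_dropped(self):
        a = va(ea="A", nea="T", eaf=0.49)
        b = va(ea="A", nea="T", eaf=0.49)
        with pytest.raises(AlignmentError):
            align_alleles(a, b)

    def test_palindromic_low_maf_aligned_by_frequency(self):
        a = va(ea="A", nea="T", eaf=0.1)
        b = va(ea="T", nea="A", eaf=0.9, beta=0.05)
        _, b2 = align_alleles(a, b)
        assert b2.beta == pytest.approx(-0.05)
        assert b2.eaf == pytest.approx(0.1)

    def test_incompatible_alleles_error(self):
        with pytest.raises(AlignmentError):
            align_alleles(va(ea="A", nea="G"), va(ea="A", nea="C"))

    def test_different_site_error(self):
        with pytest.raises(AlignmentError):
            align_alleles(va(pos=100), va(pos=200))


class TestIVW:
    def test_equal_weights(self):
        res = ivw_meta([va(beta=0.1, se=0.1), va(beta=0.1, se=0.1)])
        assert res.beta == pytest.approx(0.1)
        assert res.se == pytest.approx(0.1 / np.sqrt(2))

    def test_hand_closed_form(self):
        # w = (100, 25): beta = (100*0.2)/125 = 0.16, se = 125^-0.5
        res = ivw_meta([va(beta=0.2, se=0.1), va(beta=0.0, se=0.2)])
        assert res.beta == pytest.approx(0.16)
        assert res.se == pytest.approx(0.0894427, rel=1e-5)

    def test_single_study_identity(self):
        v = va(beta=0.07, se=0.02)
        res = ivw_meta([v])
        assert res.beta == pytest.approx(v.beta)
        assert res.se == pytest.approx(v.se)
        assert res.n_studies == 1

    def test_duplicated_study_halves_variance(self):
        v = va(beta=0.05, se=0.02)
        res = ivw_meta([v, v])
        assert res.se == pytest.approx(v.se / np.sqrt(2))
        assert res.beta == pytest.approx(v.beta)

    def test_zero_se_rejected(self):
        v = va()
        v.se = 0.0  # bypass constructor validation
        with pytest.raises(InputError):
            ivw_meta([v])

    def test_empty_rejected(self):
        with pytest.raises(InputError):
            ivw_meta([])

    @given(
        betas=st.lists(st.floats(-1, 1), min_size=1, max_size=8),
        raw_ses=st.lists(st.floats(0.01, 2.0), min_size=8, max_size=8),
    )
    def test_matches_wls_oracle(self, betas, raw_ses):
        ses = raw_ses[: len(betas)]
        studies = [va(beta=b, se=s) for b, s in zip(betas, ses)]
        res = ivw_meta(studies)
        # weighted-least-squares closed form for an intercept-only model
        w = 1.0 / np.array(ses) ** 2
        expected = np.sum(w * np.array(betas)) / np.sum(w)
        assert res.beta == pytest.approx(expected, abs=1e-12)
        assert res.z == pytest.approx(res.beta / res.se)

    def test_extreme_z_p_not_zero(self):
        res = ivw_meta([va(beta=0.4, se=0.01)])  # z = 40
        assert res.p > 0.0
        assert np.isfinite(res.log10_p)
        assert res.log10_p < -300


class TestTwoSidedP:
    def test_z40_positive(self):
        p, log10p = two_sided_p(40.0)
        assert p > 0
        # exact log-space value: log10(2) + logsf(40)/ln(10)
        expected = (stats.norm.logsf(40.0) + np.log(2)) / np.log(10)
        assert log10p == pytest.approx(expected, rel=1e-12)
        assert log10p < -300

    def test_matches_scipy_moderate(self):
        p, _ = two_sided_p(2.0)
        assert p == pytest.approx(2 * stats.norm.sf(2.0), rel=1e-12)


class TestFilterVariants:
    def _table(self):
        return pd.DataFrame(
            {
                "RSID": [f"rs{i}" for i in range(6)],
                "N_STUDIES": [1, 2, 2, 3, 1, 5],
                "N_CASES": [50000, 29999, 30000, 100000, 10000, 31000],
            }
        )

    def test_single_study_removed(self):
        out = filter_variants(self._table())
        assert "rs0" not in out["RSID"].tolist()

    def test_case_boundary(self):
        out = filter_variants(self._table())
        assert "rs1" not in out["RSID"].tolist()  # 29,999 cases
        assert "rs2" in out["RSID"].tolist()      # exactly 30,000

    def test_hand_trace(self):
        out = filter_variants(self._table())
        assert out["RSID"].tolist() == ["rs2", "rs3", "rs5"]


class TestClumpLoci:
    def _df(self, positions, pvals=None, chrom="1"):
        n = len(positions)
        return pd.DataFrame(
            {
                "CHR": chrom,
                "POS": positions,
                "RSID": [f"rs{i}" for i in range(n)],
                "P": pvals if pvals is not None else [1e-9] * n,
            }
        )

    def test_two_loci(self):
        loci = clump_loci(self._df([1_000_000, 1_300_000, 2_500_000]))
        assert len(loci) == 2
        assert loci[0].members == ["rs0", "rs1"]
        assert loci[1].members == ["rs2"]

    def test_transitive_chain_single_locus(self):
        loci = clump_loci(self._df([1_000_000, 1_400_000, 1_800_000]))
        assert len(loci) == 1
        assert loci[0].members == ["rs0", "rs1", "rs2"]

    def test_singleton(self):
        loci = clump_loci(self._df([5_000_000]))
        assert len(loci) == 1
        assert loci[0].sentinel == "rs0"

    def test_sentinel_min_p_tie_lowest_position(self):
        loci = clump_loci(
            self._df([1_000_000, 1_100_000], pvals=[1e-9, 1e-9])
        )
        assert loci[0].sentinel == "rs0"

    def test_partition_property(self):
        rng = np.random.default_rng(0)
        pos = np.sort(rng.integers(1, 50_000_000, size=200))
        df = self._df(pos.tolist())
        loci = clump_loci(df)
        all_members = [m for l in loci for m in l.members]
        assert sorted(all_members) == sorted(df["RSID"])
        assert len(all_members) == len(set(all_members))

    def test_chromosomes_separate(self):
        df = pd.concat(
            [self._df([1_000_000]), self._df([1_000_100], chrom="2")]
        )
        assert len(clump_loci(df)) == 2


class TestNovelty:
    def _locus(self, sentinel="rs1", start=90_000, end=120_000):
        return Locus(
            chrom="1", start=start, end=end, sentinel=sentinel,
            sentinel_pos=100_000, sentinel_p=1e-10, members=[sentinel],
        )

    def test_high_r2_known(self, panel_factory):
        panel = panel_factory([0.3, 0.3], [[1, 0.975], [0.975, 1]])
        known = pd.DataFrame({"RSID": ["rs2"], "CHR": ["1"], "POS": [200_000]})
        locus = annotate_novelty(self._locus(), known, panel)
        assert locus.novelty == "known"  # r^2 = 0.95

    def test_low_r2_new(self, panel_factory):
        panel = panel_factory([0.3, 0.3], [[1, 0.2236], [0.2236, 1]])
        known = pd.DataFrame({"RSID": ["rs2"], "CHR": ["1"], "POS": [200_000]})
        locus = annotate_novelty(self._locus(), known, panel)
        assert locus.novelty == "new"  # r^2 = 0.05

    def test_boundary_r2_exactly_02_is_known(self, panel_factory):
        r = np.sqrt(0.2)
        panel = panel_factory([0.3, 0.3], [[1, r], [r, 1]])
        known = pd.DataFrame({"RSID": ["rs2"], "CHR": ["1"], "POS": [200_000]})
        locus = annotate_novelty(self._locus(), known, panel)
        assert locus.novelty == "known"

    def test_known_variant_inside_region(self, panel_factory):
        panel = panel_factory([0.3], [[1.0]])
        known = pd.DataFrame({"RSID": ["rsX"], "CHR": ["1"], "POS": [100_000]})
        locus = annotate_novelty(self._locus(), known, panel)
        assert locus.novelty == "known"

    def test_sentinel_absent_unassessed(self, panel_factory):
        panel = panel_factory([0.3], [[1.0]])  # holds rs1 only
        known = pd.DataFrame({"RSID": ["rs1"], "CHR": ["1"], "POS": [300_000]})
        locus = annotate_novelty(
            self._locus(sentinel="rs_absent"), known, panel
        )
        assert locus.novelty == "unassessed"

    def test_no_known_nearby_new(self, panel_factory):
        panel = panel_factory([0.3], [[1.0]])
        known = pd.DataFrame({"RSID": ["rsY"], "CHR": ["2"], "POS": [100_000]})
        locus = annotate_novelty(self._locus(), known, panel)
        assert locus.novelty == "new"


class TestQValues:
    def test_all_ones(self):
        res = qvalue_fdr([1.0, 1.0, 1.0])
        np.testing.assert_allclose(res.qvalues, 1.0)

    def test_bh_hand_example(self):
        # pi0 = 1: q = min over j>=i of m p_(j)/j = 0.04 for all four
        res = qvalue_fdr([0.01, 0.02, 0.03, 0.04], pi0=1.0)
        np.testing.assert_allclose(res.qvalues, 0.04)

    def test_uniform_pi0_near_one(self):
        rng = np.random.default_rng(1)
        res = qvalue_fdr(rng.uniform(size=10000))
        assert 0.9 <= res.pi0 <= 1.1

    def test_order_invariance(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(size=500)
        perm = rng.permutation(500)
        res1 = qvalue_fdr(p)
        res2 = qvalue_fdr(p[perm])
        np.testing.assert_allclose(res1.qvalues[perm], res2.qvalues)

    def test_q_bounded_and_monotone(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=300) ** 2
        res = qvalue_fdr(p)
        assert (res.qvalues <= 1.0).all()
        order = np.argsort(p)
        assert (np.diff(res.qvalues[order]) >= -1e-12).all()

    def test_pi0_one_equals_bh(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(size=200)
        res = qvalue_fdr(p, pi0=1.0)
        bh = stats.false_discovery_control(p, method="bh")
        np.testing.assert_allclose(res.qvalues, bh, atol=1e-12)

    def test_threshold_reported(self):
        p = [1e-6, 1e-5, 0.5, 0.8]
        res = qvalue_fdr(p, target=0.01, pi0=1.0)
        assert res.threshold == pytest.approx(1e-5)

    def test_empty_rejected(self):
        with pytest.raises(InputError):
            qvalue_fdr([])


class TestSexHeterogeneity:
    def test_equal_betas_p_one(self):
        z, p = sex_heterogeneity(0.05, 0.01, 0.05, 0.02)
        assert z == 0.0
        assert p == pytest.approx(1.0)

    def test_hand_example(self):
        z, p = sex_heterogeneity(0.05, 0.01, 0.02, 0.01)
        assert z == pytest.approx(2.1213, abs=1e-4)
        assert p == pytest.approx(0.0339, abs=1e-3)

    def test_bad_se(self):
        with pytest.raises(InputError):
            sex_heterogeneity(0.05, 0.0, 0.02, 0.01)

    def test_null_calibration_uniform(self):
        rng = np.random.default_rng(5)
        n = 1000
        beta = rng.normal(0.05, 0.01, size=n)
        bm = beta + rng.normal(0, 0.01, size=n)
        bf = beta + rng.normal(0, 0.015, size=n)
        pvals = [
            sex_heterogeneity(m, 0.01, f, 0.015)[1] for m, f in zip(bm, bf)
        ]
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_flag_requires_both_conditions(self):
        out = meta.flag_sex_heterogeneity(
            beta_m=[0.1, 0.1], se_m=[0.01, 0.01], p_m=[1e-10, 1e-3],
            beta_f=[0.02, 0.02], se_f=[0.01, 0.01], p_f=[0.5, 0.5],
        )
        assert out["FLAG"].tolist() == [True, False]


class TestCrossAncestry:
    def _tables(self, betas_a, betas_b):
        n = len(betas_a)
        base = {
            "CHR": ["1"] * n,
            "POS": 1000 * (1 + np.arange(n)),
            "RSID": [f"rs{i}" for i in range(n)],
            "EA": ["A"] * n,
            "NEA": ["G"] * n,
            "EAF": np.linspace(0.1, 0.4, n),
        }
        a = pd.DataFrame({**base, "BETA": betas_a})
        b = pd.DataFrame({**base, "BETA": betas_b})
        return a, b

    def test_identical_r_one(self):
        a, b = self._tables([0.1, 0.2, 0.3, 0.15], [0.1, 0.2, 0.3, 0.15])
        res = cross_ancestry_compare(a, b, a["RSID"].tolist())
        assert res.r_beta == pytest.approx(1.0)
        assert res.r_eaf == pytest.approx(1.0)

    def test_anticorrelated(self):
        a, b = self._tables([1.0, 2.0, 3.0], [3.0, 2.0, 1.0])
        res = cross_ancestry_compare(a, b, a["RSID"].tolist())
        assert res.r_beta == pytest.approx(-1.0)

    def test_insufficient_overlap(self):
        a, b = self._tables([0.1, 0.2], [0.1, 0.2])
        with pytest.raises(InputError):
            cross_ancestry_compare(a, b, a["RSID"].tolist())

    def test_allele_flip_handled(self):
        a, b = self._tables([0.1, 0.2, 0.3, 0.4], [0.1, 0.2, 0.3, 0.4])
        b.loc[0, ["EA", "NEA"]] = ["G", "A"]
        b.loc[0, "BETA"] = -0.1
        b.loc[0, "EAF"] = 1 - b.loc[0, "EAF"]
        res = cross_ancestry_compare(a, b, a["RSID"].tolist())
        assert res.r_beta == pytest.approx(1.0)

    def test_outlier_exclusion(self):
        a, b = self._tables([0.1, 0.2, 0.3, 0.4, 0.5], [0.1, 0.2, 0.3, 0.4, -2.0])
        res = cross_ancestry_compare(
            a, b, a["RSID"].tolist(), exclude=["rs4"]
        )
        assert res.n_excluded == 1
        assert res.r_beta_no_outliers == pytest.approx(1.0)
        assert res.r_beta < 0.5


class TestIVWTables:
    def test_meta_of_simulated_studies_gains_precision(self, small_stats):
        pooled = meta.ivw_meta_tables(small_stats)
        single = small_stats[0]
        merged = pooled.merge(single, on="RSID", suffixes=("_meta", ""))
        assert (merged["SE_meta"] < merged["SE"] + 1e-12).all()
        assert (pooled["N_STUDIES"] == len(small_stats)).all()
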