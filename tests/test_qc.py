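"""Genotype QC: counts, exact HWE test, outlier filters, relatedness, cascade."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import hwe_enumeration_pvalue
from conftest import make_matrix
from gbrecall import (
    CohortSpec,
    MarkerSpec,
    QcThresholds,
    ancestry_components,
    apply_qc_cascade,
    compute_genotype_counts,
    genotype_count_table,
    heterozygosity_outliers,
    hwe_exact_pvalue,
    relatedness_matrix,
    relatedness_prune,
    simulate_genotypes,
)
from gbrecall.containers import MISSING


class TestGenotypeCounts:
    def test_hand_enumerated_counts_and_maf(self):
        m = make_matrix(np.array([[0], [0], [1], [1], [2]]))
        c = compute_genotype_counts(m, "rs0")
        assert (c.n_minor_hom, c.n_het, c.n_major_hom, c.n_missing) == (1, 2, 2, 0)
        assert c.maf == pytest.approx(0.4)

    def test_all_missing_marker_flagged(self):
        m = make_matrix(np.full((4, 1), MISSING))
        c = compute_genotype_counts(m, "rs0")
        assert (c.n_minor_hom, c.n_het, c.n_major_hom, c.n_missing) == (0, 0, 0, 4)
        assert c.call_rate == 0.0
        assert not c.maf_defined and np.isnan(c.maf)

    def test_orientation_flips_when_stored_minor_is_actually_major(self):
        # stored dosage counts an allele at frequency 0.9 -> flipped
        m = make_matrix(np.array([[2], [2], [2], [2], [1]]))
        c = compute_genotype_counts(m, "rs0")
        assert c.maf == pytest.approx(0.1)
        assert c.n_minor_hom == 0 and c.n_major_hom == 4

    def test_cohort_fixture_reproduces_published_maf(self):
        # 31 aa / 561 aA / 1786 AA in 2378 unrelated samples -> MAF 623/4756
        calls = np.concatenate([np.full(31, 2), np.full(561, 1), np.full(1786, 0)])
        m = make_matrix(calls[:, None])
        c = compute_genotype_counts(m, "rs0")
        assert c.maf == pytest.approx(623 / 4756)
        assert c.maf == pytest.approx(0.131, abs=5e-4)

    def test_unknown_marker_raises(self):
        m = make_matrix(np.zeros((3, 1)))
        with pytest.raises(KeyError, match="nope"):
            compute_genotype_counts(m, "nope")

    def test_vectorized_table_matches_scalar_path(self):
        rng = np.random.default_rng(0)
        calls = rng.integers(-1, 3, size=(50, 8))
        m = make_matrix(calls)
        tab = genotype_count_table(m)
        for rsid in m.marker_ids:
            c = compute_genotype_counts(m, rsid)
            row = tab.loc[rsid]
            assert (row["n_minor_hom"], row["n_het"], row["n_major_hom"]) == (
                c.n_minor_hom, c.n_het, c.n_major_hom)


class TestHweExact:
    def test_monomorphic_marker_has_p_one(self):
        assert hwe_exact_pvalue((0, 0, 57)) == 1.0

    def test_small_fixture_matches_full_enumeration(self):
        # (1, 0, 49): only het counts 0 and 2 are feasible; direct enumeration
        # gives P(h=0) = 50/4950, and the observed config is the least probable.
        assert hwe_exact_pvalue((1, 0, 49)) == pytest.approx(50 / 4950, rel=1e-12)
        assert hwe_exact_pvalue((1, 0, 49)) == pytest.approx(
            hwe_enumeration_pvalue(1, 0, 49), rel=1e-12)

    def test_focal_cohort_counts_survive_array_filter(self):
        p = hwe_exact_pvalue((31, 561, 1786))
        assert p == pytest.approx(hwe_enumeration_pvalue(31, 561, 1786), abs=1e-12)
        assert p > 1e-4

    def test_label_swap_invariance(self):
        assert hwe_exact_pvalue((7, 21, 80)) == pytest.approx(
            hwe_exact_pvalue((80, 21, 7)), rel=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact_pvalue((-1, 2, 3))
        with pytest.raises(ValueError):
            hwe_exact_pvalue((0, 0, 0))

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(
        aa=st.integers(0, 160), ab=st.integers(0, 160), bb=st.integers(0, 180)
    )
    def test_matches_enumeration_oracle_everywhere(self, aa, ab, bb):
        if aa + ab + bb == 0:
            return
        assert hwe_exact_pvalue((aa, ab, bb)) == pytest.approx(
            hwe_enumeration_pvalue(aa, ab, bb), abs=1e-12)

    def test_null_calibration_under_simulated_hwe(self):
        """Fraction of HWE-simulated markers rejected at 0.05 is ~5%."""
        n_markers = 2000
        spec = CohortSpec(
            n_samples=500,
            markers=tuple(MarkerSpec(maf=m) for m in
                          np.linspace(0.1, 0.5, n_markers)),
            seed=42,
        )
        tab = genotype_count_table(simulate_genotypes(spec))
        ps = np.array([
            hwe_exact_pvalue((r.n_minor_hom, r.n_het, r.n_major_hom))
            for r in tab.itertuples()
        ])
        frac = (ps < 0.05).mean()
        se = np.sqrt(0.05 * 0.95 / n_markers)
        # exact test is conservative; allow the band below nominal
        assert frac <= 0.05 + 3 * se


class TestHeterozygosityOutliers:
    def test_constructed_all_het_sample_is_flagged(self):
        rng = np.random.default_rng(3)
        calls = rng.binomial(2, 0.3, size=(99, 400))
        calls = np.vstack([calls, np.ones((1, 400), dtype=int)])
        m = make_matrix(calls)
        flagged = heterozygosity_outliers(m)
        assert flagged == [m.sample_ids[-1]]

    def test_zero_variance_stratum_yields_no_flags(self):
        m = make_matrix(np.tile([0, 1, 2], (6, 4)).reshape(6, 12)[:, :3])
        assert heterozygosity_outliers(m) == []

    def test_flags_invariant_to_marker_order(self):
        rng = np.random.default_rng(4)
        calls = rng.binomial(2, 0.25, size=(60, 200))
        calls[0] = 1  # extreme heterozygosity
        m = make_matrix(calls)
        perm = rng.permutation(200)
        m_perm = make_matrix(calls[:, perm], rsids=[f"rs{j}" for j in perm])
        assert heterozygosity_outliers(m) == heterozygosity_outliers(m_perm)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            heterozygosity_outliers(make_matrix(np.zeros((1, 5))))


class TestAncestry:
    def test_identical_samples_have_zero_distance(self):
        calls = np.tile(np.array([0, 1, 2, 1, 0]), (2, 1))
        coords, _ = ancestry_components(make_matrix(calls), k=1)
        assert np.allclose(coords.to_numpy(), 0.0, atol=1e-9)

    def test_component_one_separates_simulated_subpopulations(self):
        spec = CohortSpec(
            n_samples=200,
            markers=tuple(MarkerSpec(maf=0.3) for _ in range(400)),
            n_subpops=2, fst_like_divergence=0.1, seed=7,
        )
        gm = simulate_genotypes(spec)
        coords, _ = ancestry_components(gm, k=2)
        labels = gm.subpop_labels.to_numpy()
        r = np.corrcoef(coords["mds1"], labels)[0, 1]
        assert abs(r) > 0.8

    def test_outlier_flags_invariant_to_component_sign(self, clean_cohort):
        coords, flags = ancestry_components(clean_cohort, k=2)
        # flipping the sign of a component cannot change |x - mean| / sd
        flipped = -coords["mds1"]
        sd = flipped.std(ddof=0)
        reflag = set(flipped.index[(flipped - flipped.mean()).abs() > 3 * sd])
        orig = coords["mds1"]
        assert reflag == set(orig.index[(orig - orig.mean()).abs() > 3 * orig.std(ddof=0)])
        assert set(flags) >= reflag - set()  # comp-1 flags are a subset of all flags

    def test_k_out_of_range(self, clean_cohort):
        with pytest.raises(ValueError):
            ancestry_components(clean_cohort, k=0)
        with pytest.raises(ValueError):
            ancestry_components(clean_cohort, k=clean_cohort.n_samples)


class TestRelatedness:
    def test_duplicate_sample_near_maximal_and_pruned(self):
        rng = np.random.default_rng(8)
        calls = rng.binomial(2, rng.uniform(0.1, 0.5, size=2000), size=(100, 2000))
        calls[1] = calls[0]
        m = make_matrix(calls)
        rel = relatedness_matrix(m)
        assert rel.iloc[0, 1] > 0.85
        retained, pairs = relatedness_prune(m, 0.1875)
        assert len(retained) == 99
        assert ("P000" in retained) ^ ("P001" in retained)
        assert any({a, b} == {"P000", "P001"} for a, b, _ in pairs)

    def test_simulated_full_sib_pair_estimated_and_pruned(self):
        spec = CohortSpec(
            n_samples=200,
            markers=tuple(MarkerSpec(maf=m) for m in
                          np.linspace(0.1, 0.5, 3000)),
            related_pairs=1, related_kinship="full_sib", seed=21,
        )
        m = simulate_genotypes(spec)
        rel = relatedness_matrix(m)
        sib = rel.iloc[-2, -1]
        assert sib == pytest.approx(0.5, abs=0.1)
        retained, _ = relatedness_prune(m, 0.1875)
        assert len(retained) == 199

    def test_threshold_one_removes_nothing(self, clean_cohort):
        retained, _ = relatedness_prune(clean_cohort, 1.0)
        assert len(retained) == clean_cohort.n_samples


class TestCascade:
    def test_clean_matrix_essentially_untouched(self, clean_cohort):
        """No defect reasons fire on a clean cohort.

        SD-based outlier rules flag ~0.3% of samples per component even on
        perfectly homogeneous data, so sample removals are allowed up to
        that false-positive allowance; every other filter must be silent.
        """
        out, report = apply_qc_cascade(clean_cohort)
        assert out.n_markers == clean_cohort.n_markers
        reasons = {r.reason for r in report.removals}
        assert reasons <= {"ancestry_outlier", "heterozygosity_outlier"}
        assert len(report.removals) <= 0.01 * clean_cohort.n_samples
        assert any("sex-discordance" in n for n in report.notices)

    def test_injected_defects_removed_with_reasons(self, clean_cohort):
        calls = clean_cohort.calls.copy()
        # marker 0 forced far out of HWE: all heterozygous
        calls[:, 0] = 1
        # sample 0 at 90% call rate
        n_miss = int(0.1 * clean_cohort.n_markers) + 1
        calls[0, 1:1 + n_miss] = MISSING
        m = make_matrix(calls, rsids=list(clean_cohort.marker_ids),
                        sample_ids=list(clean_cohort.sample_ids))
        out, report = apply_qc_cascade(m)
        assert clean_cohort.marker_ids[0] in report.removed_ids("hwe")
        assert clean_cohort.sample_ids[0] in report.removed_ids("sample_call_rate")

    def test_optional_score_filters_apply_when_columns_present(self, clean_cohort):
        scores = pd.DataFrame(
            {"cluster_sep": 1.0, "gentrain": 1.0},
            index=clean_cohort.marker_ids,
        )
        bad = clean_cohort.marker_ids[3]
        scores.loc[bad, "cluster_sep"] = 0.2
        out, report = apply_qc_cascade(clean_cohort, marker_scores=scores)
        assert bad in report.removed_ids("cluster_separation")
        assert bad not in out.marker_ids

    def test_tightening_thresholds_never_retains_more(self, clean_cohort):
        base_out, _ = apply_qc_cascade(clean_cohort)
        for thr in (
            QcThresholds(sample_call_rate_min=0.995),
            QcThresholds(hwe_p_min=0.05),
            QcThresholds(marker_call_rate_min_postcall=0.999),
            QcThresholds(ancestry_sd_max=2.0),
            QcThresholds(het_sd_max=2.0),
        ):
            out, _ = apply_qc_cascade(clean_cohort, thresholds=thr)
            assert out.n_samples <= base_out.n_samples
            assert out.n_markers <= base_out.n_markers

    def test_cascade_rerun_stable_except_relative_outlier_rules(self, clean_cohort):
        """A second cascade pass changes nothing except, possibly, SD-rule flags.

        Absolute-threshold filters (call rates, HWE, relatedness) are
        idempotent by construction. The SD-based outlier filters are
        relative — means and SDs shift once the tail is removed — so a
        rerun may chip at most a false-positive allowance off the tail.
        """
        once, _ = apply_qc_cascade(clean_cohort)
        twice, report = apply_qc_cascade(once)
        assert list(twice.marker_ids) == list(once.marker_ids)
        reasons = {r.reason for r in report.removals}
        assert reasons <= {"ancestry_outlier", "heterozygosity_outlier"}
        assert len(report.removals) <= 0.01 * once.n_samples
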