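"""Recall design: exclusions, matched invitations, batches, tallies, concordance."""

import numpy as np
import pandas as pd
import pytest

from gbrecall import (
    MatchRule,
    apply_exclusions,
    assign_batches,
    build_matched_invitations,
    clinic_export,
    genotype_concordance,
    tally_participation,
)
from gbrecall.containers import RecallPlan


def small_pool(rows):
    """rows: (sample_id, age, sex, dosage)"""
    df = pd.DataFrame(rows, columns=["sample_id", "age", "sex", "dosage"]).set_index("sample_id")
    return df[["age", "sex"]], df["dosage"]


class TestExclusions:
    def test_all_clear_pool_unchanged(self, recall_pool):
        pool, log = apply_exclusions(recall_pool)
        assert len(pool) == len(recall_pool)
        assert log.empty

    def test_flagged_samples_listed_with_reasons(self):
        df = pd.DataFrame({
            "anticoagulant_flag": [True] + [False] * 9,
            "lipid_lowering_flag": [False, True] + [False] * 8,
            "diabetes_flag": [False, False, True] + [False] * 7,
        }, index=[f"P{i}" for i in range(10)])
        pool, log = apply_exclusions(df)
        assert len(pool) == 7
        assert set(log["sample_id"]) == {"P0", "P1", "P2"}
        assert set(log["reason"]) == {"anticoagulant", "lipid_lowering", "diabetes"}

    def test_all_flagged_warns_and_empties(self, caplog):
        df = pd.DataFrame({c: [True, True] for c in
                           ("anticoagulant_flag", "lipid_lowering_flag", "diabetes_flag")},
                          index=["A", "B"])
        with caplog.at_level("WARNING"):
            pool, _ = apply_exclusions(df)
        assert pool.empty
        assert any("empty" in r.message for r in caplog.records)

    def test_missing_flag_column_errors(self):
        with pytest.raises(ValueError, match="diabetes_flag"):
            apply_exclusions(pd.DataFrame({"anticoagulant_flag": [False],
                                           "lipid_lowering_flag": [False]}))


class TestMatchedInvitations:
    def test_minimal_triad_all_invited(self):
        pool, dosage = small_pool([("A", 60, 1, 2), ("B", 60, 1, 1), ("C", 60, 1, 0)])
        plan = build_matched_invitations(pool, dosage, "rsX", seed=0)
        df = plan.invitees
        assert len(df) == 3
        assert set(df["group"]) == {"hom_minor", "het", "hom_major"}
        assert (df.loc[df["group"] != "hom_minor", "anchor_id"] == "A").all()

    def test_candidate_just_outside_window_unmatched(self):
        # window 2.0 years total => +/- 1.0; candidate at +1.01 excluded
        pool, dosage = small_pool([("A", 60.0, 1, 2), ("B", 61.01, 1, 1), ("C", 60.5, 1, 0)])
        plan = build_matched_invitations(pool, dosage, "rsX",
                                         MatchRule(age_window_years=2.0), seed=0)
        assert ("A", "het") in {(r.anchor_id, r.group) for r in plan.unmatched.itertuples()}
        assert "B" not in set(plan.invitees["sample_id"])
        assert "C" in set(plan.invitees["sample_id"])

    def test_match_contract_on_simulated_pool(self, recall_pool):
        rng = np.random.default_rng(17)
        dosage = pd.Series(rng.binomial(2, 0.131, len(recall_pool)),
                           index=recall_pool.index)
        for seed in range(5):
            plan = build_matched_invitations(recall_pool, dosage, "rsX", seed=seed)
            df = plan.invitees
            assert not df["sample_id"].duplicated().any()
            anchors = df[df["group"] == "hom_minor"].set_index("sample_id")
            matched = df[df["anchor_id"].notna()]
            for r in matched.itertuples():
                assert recall_pool.at[r.sample_id, "sex"] == recall_pool.at[r.anchor_id, "sex"]
                assert abs(recall_pool.at[r.sample_id, "age"]
                           - recall_pool.at[r.anchor_id, "age"]) <= 1.0
            # every pool hom-minor is an anchor
            assert set(anchors.index) == set(dosage.index[dosage == 2])

    def test_pool_row_order_irrelevant(self, recall_pool):
        rng = np.random.default_rng(23)
        dosage = pd.Series(rng.binomial(2, 0.131, len(recall_pool)),
                           index=recall_pool.index)
        a = build_matched_invitations(recall_pool, dosage, "rsX", seed=3)
        shuffled = recall_pool.sample(frac=1.0, random_state=1)
        b = build_matched_invitations(shuffled, dosage, "rsX", seed=3)
        key = lambda p: sorted(map(tuple, p.invitees[["sample_id", "group", "anchor_id"]]
                                   .fillna("").to_numpy()))
        assert key(a) == key(b)

    def test_over_invitation_knob_adds_unanchored_carriers(self, recall_pool):
        rng = np.random.default_rng(29)
        dosage = pd.Series(rng.binomial(2, 0.131, len(recall_pool)),
                           index=recall_pool.index)
        rule = MatchRule(extra_invites=(("hom_major", 5), ("het", 2)))
        base = build_matched_invitations(recall_pool, dosage, "rsX", seed=0)
        plan = build_matched_invitations(recall_pool, dosage, "rsX", rule, seed=0)
        t0, t1 = tally_participation(base), tally_participation(plan)
        assert t1.at["hom_major", "invited"] == t0.at["hom_major", "invited"] + 5
        assert t1.at["het", "invited"] == t0.at["het", "invited"] + 2
        assert not plan.invitees["sample_id"].duplicated().any()

    def test_variant_absent_from_pool(self, recall_pool):
        empty = pd.Series(np.nan, index=recall_pool.index)
        with pytest.raises(ValueError, match="rsX"):
            build_matched_invitations(recall_pool, empty, "rsX")


class TestBatches:
    def _plan(self, n_triads=30):
        rows = []
        for t in range(n_triads):
            rows.append((f"anchor{t}", "hom_minor", None))
            rows.append((f"het{t}", "het", f"anchor{t}"))
            rows.append((f"maj{t}", "hom_major", f"anchor{t}"))
        df = pd.DataFrame(rows, columns=["sample_id", "group", "anchor_id"])
        df["batch"] = 1
        df["invited"] = True
        df["responded"] = False
        df["included"] = False
        return RecallPlan("rsX", df)

    def test_single_batch_fraction_one(self):
        plan = assign_batches(self._plan(), (1.0, 0.0), seed=0)
        assert (plan.invitees["batch"] == 1).all()

    def test_even_split_of_triads(self):
        plan = assign_batches(self._plan(30), (0.5, 0.5), seed=1)
        per_batch = plan.invitees.groupby("batch")["sample_id"].count()
        assert per_batch.tolist() == [45, 45]

    def test_partners_share_anchor_batch(self):
        plan = assign_batches(self._plan(11), (0.4, 0.6), seed=2)
        df = plan.invitees.set_index("sample_id")
        for r in df[df["anchor_id"].notna()].itertuples():
            assert r.batch == df.at[r.anchor_id, "batch"]

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError):
            assign_batches(self._plan(), (0.7, 0.7))
        with pytest.raises(ValueError):
            assign_batches(self._plan(), (-0.1, 1.1))


class TestTally:
    def test_study_arithmetic(self):
        """Invited (39, 34, 30), included (12, 15, 13): rates 31/44/43, n=40."""
        rows = []
        for group, inv, inc in zip(("hom_major", "het", "hom_minor"),
                                   (39, 34, 30), (12, 15, 13)):
            for i in range(inv):
                rows.append((f"{group}{i}", group, True, i < inc, i < inc))
        df = pd.DataFrame(rows, columns=["sample_id", "group", "invited",
                                         "responded", "included"])
        t = tally_participation(df)
        assert t["invited"].tolist() == [39, 34, 30]
        assert t["included"].tolist() == [12, 15, 13]
        assert t.at["hom_major", "rate_percent"] == 31
        assert t.at["het", "rate_percent"] == 44
        assert t.at["hom_minor", "rate_percent"] == 43  # 13/30, not the rounded-down 40
        assert t["included"].sum() == 40

    def test_zero_invited_group_undefined_rate(self):
        df = pd.DataFrame({"sample_id": ["a"], "group": ["het"], "invited": [True],
                           "responded": [False], "included": [False]})
        t = tally_participation(df)
        assert np.isnan(t.at["hom_minor", "rate_percent"])
        assert t.at["het", "rate_percent"] == 0

    def test_included_exceeding_invited_is_inconsistent(self):
        df = pd.DataFrame({"sample_id": ["a"], "group": ["het"], "invited": [False],
                           "responded": [False], "included": [True]})
        with pytest.raises(ValueError):
            tally_participation(df)


class TestConcordance:
    def test_identical_calls_fully_concordant(self):
        calls = pd.Series([0, 1, 2, 1], index=list("abcd"))
        frac, disc = genotype_concordance(calls, calls.copy())
        assert frac == 1.0 and disc == []

    def test_one_discordant_of_forty(self):
        idx = [f"s{i}" for i in range(40)]
        a = pd.Series(1, index=idx)
        b = a.copy()
        b.iloc[0] = 2
        frac, disc = genotype_concordance(a, b)
        assert frac == pytest.approx(0.975)
        assert disc == ["s0"]

    def test_id_mismatch_errors(self):
        a = pd.Series([1], index=["x"])
        b = pd.Series([1], index=["y"])
        with pytest.raises(ValueError):
            genotype_concordance(a, b)


class TestClinicExport:
    def test_export_is_blinded(self, recall_pool):
        rng = np.random.default_rng(31)
        dosage = pd.Series(rng.binomial(2, 0.131, len(recall_pool)),
                           index=recall_pool.index)
        plan = build_matched_invitations(recall_pool, dosage, "rsX", seed=0)
        export = clinic_export(plan, recall_pool)
        assert "group" not in export.columns
        assert "anchor_id" not in export.columns
        assert "dosage" not in export.columns
        assert set(export["sample_id"]) == set(plan.invitees["sample_id"])
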