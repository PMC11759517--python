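"""Precursor validation, peptide ratios, protein roll-up and imputation."""

import numpy as np
import pandas as pd
import pytest

from prmflux import quantify as q
from prmflux.quantify import ProteinQuantMatrix

from conftest import transition_frame


class TestValidatePrecursor:
    def test_two_matched_fragments_invalid(self):
        df = transition_frame({"y3": 10, "y4": 20}, {"y3": 5, "y4": 10})
        meas = q.validate_precursor(df)
        assert not meas.valid and meas.reason == "lt3_transitions"
        assert meas.n_transitions == 2

    def test_three_matched_fragments_valid(self):
        df = transition_frame({"y3": 10, "y4": 20, "y5": 5}, {"y3": 5, "y4": 10, "y5": 5})
        meas = q.validate_precursor(df)
        assert meas.valid and meas.n_transitions == 3

    def test_flags_reduce_retained_below_three(self):
        frags_l = {f"y{i}": 10 for i in range(3, 8)}
        frags_h = {f"y{i}": 10 for i in range(3, 8)}
        df = transition_frame(frags_l, frags_h, flags={"y3", "y4", "y5"})
        meas = q.validate_precursor(df)
        assert not meas.valid and meas.reason == "lt3_transitions"

    def test_zero_heavy_sum_reported(self):
        df = transition_frame({"y3": 10, "y4": 20, "y5": 5}, {"y3": 0, "y4": 0, "y5": 0})
        meas = q.validate_precursor(df)
        assert not meas.valid and meas.reason == "no_heavy"
        with pytest.raises(ValueError):
            q.peptide_ratio(meas)

    def test_unmatched_fragments_not_counted(self):
        df = transition_frame({"y3": 10, "y4": 20, "y5": 5, "y9": 99},
                              {"y3": 5, "y4": 10, "y5": 5})
        meas = q.validate_precursor(df)
        assert meas.n_transitions == 3
        assert meas.light_sum == 35  # y9 has no heavy counterpart


class TestPeptideRatio:
    def test_identity(self):
        df = transition_frame({"y3": 10, "y4": 20, "y5": 5}, {"y3": 10, "y4": 20, "y5": 5})
        assert q.peptide_ratio(q.validate_precursor(df)) == 1.0

    def test_sum_over_fragments(self):
        df = transition_frame({"y3": 100, "y4": 200, "y5": 300},
                              {"y3": 50, "y4": 100, "y5": 150})
        assert q.peptide_ratio(q.validate_precursor(df)) == 2.0

    def test_ratio_invariant_to_run_level_scaling(self):
        df = transition_frame({"y3": 100, "y4": 200, "y5": 300},
                              {"y3": 50, "y4": 100, "y5": 150})
        scaled = df.assign(area=df["area"] * 37.5)
        r1 = q.peptide_ratio(q.validate_precursor(df))
        r2 = q.peptide_ratio(q.validate_precursor(scaled))
        assert r1 == pytest.approx(r2)


class TestFlagInterference:
    def test_proportional_patterns_unflagged(self):
        df = transition_frame({"y3": 20, "y4": 40, "y5": 60}, {"y3": 10, "y4": 20, "y5": 30})
        out = q.flag_interference(df)
        assert not out["interference_flag"].any()

    def test_spiked_fragment_flagged(self):
        # y3 at 10x its reference share
        df = transition_frame({"y3": 1000, "y4": 20, "y5": 30}, {"y3": 10, "y4": 20, "y5": 30})
        out = q.flag_interference(df)
        flagged = out[(out["label"] == "light") & out["interference_flag"]]
        assert set(flagged["fragment"]) == {"y3"}

    def test_all_zero_light_unflagged(self):
        df = transition_frame({"y3": 0, "y4": 0}, {"y3": 10, "y4": 20})
        out = q.flag_interference(df)
        assert not out["interference_flag"].any()

    def test_missing_heavy_warns(self):
        df = transition_frame({"y3": 10, "y4": 20}, {})
        with pytest.warns(UserWarning, match="heavy"):
            out = q.flag_interference(df)
        assert not out["interference_flag"].any()


def peptide_frame(rows):
    """rows: (sample, protein, peptide, valid, ratio)"""
    return pd.DataFrame(
        rows, columns=["sample", "protein", "peptide", "valid", "ratio"]
    ).assign(charge=2, n_transitions=4, reason=None)


def two_sample_design():
    return pd.DataFrame(
        {"condition": ["DMEM", "DMEM"], "bafa1": [False, False],
         "bio_rep": [1, 2], "tech_rep": [1, 1]},
        index=["s1", "s2"],
    )


class TestProteinRollup:
    def test_single_peptide_passes_through(self):
        peps = peptide_frame([("s1", "P1", "AK", True, 1.5), ("s2", "P1", "AK", True, 2.5)])
        m = q.protein_rollup(peps, two_sample_design(), None)
        assert m.values.loc["P1", "s1"] == 1.5
        assert m.values.loc["P1", "s2"] == 2.5
        assert (m.status.loc["P1"] == "measured").all()

    def test_protein_value_is_mean_of_peptides(self):
        peps = peptide_frame([
            ("s1", "P1", "AK", True, 1.0), ("s1", "P1", "BK", True, 3.0),
            ("s2", "P1", "AK", True, 1.0), ("s2", "P1", "BK", True, 3.0),
        ])
        m = q.protein_rollup(peps, two_sample_design(), None)
        assert m.values.loc["P1", "s1"] == 2.0

    def test_all_peptides_below_loq_gives_missing_protein(self):
        peps = peptide_frame([("s1", "P1", "AK", True, 1.0), ("s2", "P1", "AK", True, 1.0)])
        lodq = pd.DataFrame({"peptide": ["AK"], "loq": [1e9], "quantifiable": [True]})
        m = q.protein_rollup(peps, two_sample_design(), lodq, heavy_spike=120.0)
        assert (m.status.loc["P1"] == "missing").all()
        assert m.rollup_log["P1"]["mode"] == "none"

    def test_loq_gating_uses_back_computed_amount(self):
        # ratio 1.0 * 120 fmol spike = 120 fmol > loq 100 -> above
        peps = peptide_frame([("s1", "P1", "AK", True, 1.0), ("s2", "P1", "AK", True, 1.0)])
        lodq = pd.DataFrame({"peptide": ["AK"], "loq": [100.0], "quantifiable": [True]})
        m = q.protein_rollup(peps, two_sample_design(), lodq, heavy_spike=120.0)
        assert (m.status.loc["P1"] == "measured").all()
        m2 = q.protein_rollup(peps, two_sample_design(), lodq, heavy_spike=12.0)
        assert (m2.status.loc["P1"] == "missing").all()  # 12 fmol < loq

    def test_all_sample_peptide_set_preferred(self):
        # AK valid everywhere; BK valid only in s1 -> roll-up uses AK alone
        peps = peptide_frame([
            ("s1", "P1", "AK", True, 1.0), ("s2", "P1", "AK", True, 1.0),
            ("s1", "P1", "BK", True, 9.0), ("s2", "P1", "BK", False, np.nan),
        ])
        m = q.protein_rollup(peps, two_sample_design(), None)
        assert m.rollup_log["P1"]["mode"] == "all_samples"
        assert m.rollup_log["P1"]["used"] == ["AK"]
        assert m.values.loc["P1", "s1"] == 1.0

    def test_fallback_to_candidates_with_per_sample_missingness(self):
        peps = peptide_frame([
            ("s1", "P1", "AK", True, 2.0), ("s2", "P1", "AK", False, np.nan),
        ])
        m = q.protein_rollup(peps, two_sample_design(), None)
        assert m.rollup_log["P1"]["mode"] == "any_replicate"
        assert m.status.loc["P1", "s1"] == "measured"
        assert m.status.loc["P1", "s2"] == "missing"

    def test_shared_peptide_is_configuration_error(self):
        peps = peptide_frame([
            ("s1", "P1", "AK", True, 1.0), ("s1", "P2", "AK", True, 1.0),
            ("s2", "P1", "AK", True, 1.0), ("s2", "P2", "AK", True, 1.0),
        ])
        with pytest.raises(ValueError, match="multiple proteins"):
            q.protein_rollup(peps, two_sample_design(), None)

    def test_permutation_invariance(self):
        rows = [
            ("s1", "P1", "AK", True, 1.0), ("s1", "P1", "BK", True, 3.0),
            ("s2", "P1", "AK", True, 2.0), ("s2", "P1", "BK", True, 4.0),
            ("s1", "P2", "CK", True, 5.0), ("s2", "P2", "CK", True, 6.0),
        ]
        m1 = q.protein_rollup(peptide_frame(rows), two_sample_design(), None)
        shuffled = peptide_frame(rows[::-1])
        design_flipped = two_sample_design().iloc[::-1]
        m2 = q.protein_rollup(shuffled, design_flipped, None)
        pd.testing.assert_frame_equal(
            m1.values.sort_index()[["s1", "s2"]],
            m2.values.sort_index()[["s1", "s2"]],
        )


def matrix_with_missing(measured, n_missing, protein="P1"):
    cols = [f"m{i}" for i in range(len(measured))] + [f"x{i}" for i in range(n_missing)]
    values = pd.DataFrame([list(measured) + [np.nan] * n_missing],
                          index=[protein], columns=cols)
    status = pd.DataFrame([["measured"] * len(measured) + ["missing"] * n_missing],
                          index=[protein], columns=cols)
    design = pd.DataFrame(
        {"condition": "DMEM", "bafa1": False, "bio_rep": range(1, len(cols) + 1)},
        index=cols,
    )
    return ProteinQuantMatrix(values, status, design)


class TestImputeMissing:
    def test_zero_sd_imputes_exactly_downshifted_mean(self):
        m = q.impute_missing(matrix_with_missing([1.0, 1.0, 1.0], 2), seed=0)
        imputed = m.values.loc["P1", ["x0", "x1"]]
        assert (imputed == 0.8).all()
        assert (m.status.loc["P1", ["x0", "x1"]] == "imputed").all()

    def test_monte_carlo_moments_match_downshifted_normal(self):
        # measured mean 1.0, sd 0.1; 10^4 imputed cells
        m = q.impute_missing(matrix_with_missing([0.9, 1.0, 1.1], 10_000), seed=42)
        imputed = m.values.loc["P1"].iloc[3:]
        assert imputed.mean() == pytest.approx(0.8, rel=0.01)
        assert imputed.std(ddof=1) == pytest.approx(0.1, rel=0.05)

    def test_insufficient_support_left_missing(self):
        m = q.impute_missing(matrix_with_missing([1.0], 2), seed=0)
        assert (m.status.loc["P1", ["x0", "x1"]] == "missing").all()
        reasons = {e["reason"] for e in m.imputation_log if not e.get("imputed", True)}
        assert reasons == {"insufficient_support"}

    def test_measured_cells_untouched_and_seed_recorded(self):
        base = matrix_with_missing([0.9, 1.0, 1.1], 3)
        m = q.impute_missing(base, seed=7)
        pd.testing.assert_series_equal(
            m.values.loc["P1", ["m0", "m1", "m2"]],
            base.values.loc["P1", ["m0", "m1", "m2"]],
        )
        assert all(e["seed"] == 7 for e in m.imputation_log)
        m2 = q.impute_missing(base, seed=7)
        pd.testing.assert_frame_equal(m.values, m2.values)


class TestAverageTechnical:
    def test_tech_reps_average_into_biological_samples(self):
        from prmflux import synth

        design = synth.make_design(["DMEM"], bafa1=(False,), n_bio=2, n_tech=2)
        values = pd.DataFrame(
            [[1.0, 3.0, 10.0, np.nan]], index=["P1"], columns=design.index
        )
        status = pd.DataFrame(
            [["measured", "measured", "measured", "missing"]],
            index=["P1"], columns=design.index,
        )
        m = ProteinQuantMatrix(values, status, design)
        bio = q.average_technical(m)
        assert bio.values.loc["P1", "DMEM_b1"] == 2.0
        assert bio.values.loc["P1", "DMEM_b2"] == 10.0  # mean of measured only
        assert "tech_rep" not in bio.design.columns


class TestParameterRecovery:
    def test_rollup_recovers_log2_fold_changes_with_small_bias(self):
        from prmflux import synth

        rng = np.random.default_rng(77)
        n = 100
        proteins = [f"PROT{i + 1:03d}" for i in range(n)]
        true_fc = {p: {"HBSS": float(rng.uniform(-1, 1))} for p in proteins}
        truth = synth.make_truth(
            n, 2, 4, seed=78, cv_technical=5.0, cv_biological=5.0,
            condition_log2fc=true_fc,
        )
        design = synth.make_design(["DMEM", "HBSS"], bafa1=(False,), n_bio=3, n_tech=3)
        records, design = synth.generate_experiment(truth, design, seed=79)
        bio = q.average_technical(
            q.protein_rollup(q.peptide_table(records), design, None)
        )
        d = bio.design
        dmem = bio.values[[c for c in bio.values.columns if d.loc[c, "condition"] == "DMEM"]]
        hbss = bio.values[[c for c in bio.values.columns if d.loc[c, "condition"] == "HBSS"]]
        est = np.log2(hbss.mean(axis=1) / dmem.mean(axis=1))
        bias = np.mean([est[p] - true_fc[p]["HBSS"] for p in proteins])
        assert abs(bias) < 0.05
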