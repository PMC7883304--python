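"""Unit tests for mixed-model inference, per-trial tests and Holm correction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from disgaze import inference
from disgaze.inference import (
    ModelSpec,
    dwell_to_long,
    fit_mixed_model,
    fit_with_null,
    holm_bonferroni,
    per_trial_tests,
    posthoc_drug_difference,
    null_evidence_table,
)
from disgaze.synthetic_data import (
    GazeSimConfig,
    RLSimConfig,
    make_design,
    simulate_study,
)


@pytest.fixture(scope="module")
def study25():
    design = make_design(25, seed=1)
    return simulate_study(design, GazeSimConfig(seed=1, drug_phase_interaction=0.7),
                          RLSimConfig(seed=1), emit_fixations=False)


@pytest.fixture(scope="module")
def incentive_long(study25):
    dw = study25.dwell_truth
    return dwell_to_long(dw[dw.phase.isin(["pre_incentive", "post_incentive"])])


class TestModelSpec:
    def test_rejects_trial_factor_for_self_report(self):
        with pytest.raises(ValueError, match="trial"):
            ModelSpec(outcome="self_report", fixed=("stimulus", "trial"))

    def test_rejects_unknown_factor_and_outcome(self):
        with pytest.raises(ValueError, match="unknown factors"):
            ModelSpec(outcome="dwell_proportion", fixed=("weather",))
        with pytest.raises(ValueError, match="unknown outcome"):
            ModelSpec(outcome="saccades")


class TestFitMixedModel:
    def test_recovers_injected_stimulus_effect(self, incentive_long):
        spec = ModelSpec(outcome="dwell_proportion",
                         fixed=("stimulus", "drug", "phase", "trial"))
        fit = fit_mixed_model(incentive_long, spec)
        stim = fit.effect("stimulus")
        assert stim.beta < 0 and stim.p < 0.05
        assert stim.ci_low <= stim.beta <= stim.ci_high

    def test_n_obs_bookkeeping(self, incentive_long):
        spec = ModelSpec(outcome="dwell_proportion", fixed=("stimulus",))
        fit = fit_mixed_model(incentive_long, spec)
        assert fit.n_obs == len(incentive_long)

    def test_information_criteria_consistent_with_loglik(self, incentive_long):
        spec = ModelSpec(outcome="dwell_proportion", fixed=("stimulus",))
        fit = fit_mixed_model(incentive_long, spec)
        assert fit.aic == pytest.approx(2 * fit.k - 2 * fit.llf)
        assert fit.bic == pytest.approx(fit.k * np.log(fit.n_obs) - 2 * fit.llf)

    def test_sign_flips_with_factor_recoding(self, incentive_long):
        spec = ModelSpec(outcome="dwell_proportion", fixed=("stimulus",))
        fit = fit_mixed_model(incentive_long, spec)
        relabeled = incentive_long.copy()
        relabeled["stimulus"] = relabeled["stimulus"].map(
            {"disgust": "neutral", "neutral": "disgust"})
        flipped = fit_mixed_model(relabeled, spec)
        assert flipped.effect("stimulus").beta == pytest.approx(
            -fit.effect("stimulus").beta, abs=1e-6)

    def test_alternative_beats_null_when_effect_present(self, incentive_long):
        spec = ModelSpec(outcome="dwell_proportion", fixed=("stimulus",))
        _full, _null, comp = fit_with_null(incentive_long, spec)
        assert comp.log_er_0 < 0 and comp.log_bf_01 < 0

    def test_requires_two_participants(self, incentive_long):
        solo = incentive_long[incentive_long.participant == 0]
        spec = ModelSpec(outcome="dwell_proportion", fixed=("stimulus",))
        with pytest.raises(ValueError, match="participants"):
            fit_mixed_model(solo, spec)


class TestPosthoc:
    def test_exchangeable_relabeling_gives_zero_effect(self):
        # same per-participant values under both drug labels -> exact zero
        base = pd.DataFrame({
            "participant": np.repeat(np.arange(10), 2),
            "phase": ["pre_admin", "post_admin"] * 10,
            "value": np.tile([0.4, 0.6], 10) + np.repeat(
                np.linspace(-0.1, 0.1, 10), 2),
        })
        both = pd.concat([base.assign(visit="placebo"),
                          base.assign(visit="domperidone")])
        res = posthoc_drug_difference(both, "value", ("pre_admin", "post_admin"))
        assert res.estimate.beta == pytest.approx(0.0, abs=1e-8)
        assert res.comparison.er_0 > 1.0

    def test_recovers_injected_interaction_sign(self, study25):
        dw = study25.dwell_truth
        inc = dw[dw.phase.isin(["pre_incentive", "post_incentive"])].copy()
        inc["avoid"] = inc.p_neutral - inc.p_disgust
        res = posthoc_drug_difference(inc, "avoid",
                                      ("pre_incentive", "post_incentive"))
        # positive injected interaction reduces avoidance under domperidone
        assert res.estimate.beta < 0 and res.estimate.p < 0.05

    def test_requires_both_drug_conditions(self, study25):
        dw = study25.dwell_truth
        inc = dw[(dw.phase.isin(["pre_incentive", "post_incentive"]))
                 & (dw.visit == "placebo")].copy()
        inc["avoid"] = inc.p_neutral - inc.p_disgust
        with pytest.raises(ValueError, match="drug conditions"):
            posthoc_drug_difference(inc, "avoid",
                                    ("pre_incentive", "post_incentive"))


class TestPerTrialTests:
    def test_strong_avoidance_is_detected_on_most_trials(self, study25):
        out = per_trial_tests(study25.dwell_truth)
        testable = out[~out.untestable]
        assert (testable.p < 0.05).mean() > 0.8
        assert out.significant_holm.sum() <= out.significant_uncorrected.sum()

    def test_identical_dwell_yields_p_one(self):
        dw = pd.DataFrame({
            "participant": list(range(6)), "visit": "placebo",
            "phase": "baseline", "trial": 0,
            "p_disgust": 0.4, "p_neutral": 0.4, "p_nonstim": 0.2,
        })
        out = per_trial_tests(dw)
        assert out.p.iloc[0] == 1.0 and not out.untestable.iloc[0]

    def test_constant_nonzero_difference_is_untestable(self):
        dw = pd.DataFrame({
            "participant": list(range(6)), "visit": "placebo",
            "phase": "baseline", "trial": 0,
            "p_disgust": 0.2, "p_neutral": 0.6, "p_nonstim": 0.2,
        })
        out = per_trial_tests(dw)
        assert out.untestable.iloc[0] and np.isnan(out.p.iloc[0])

    def test_too_few_participants_flagged(self):
        dw = pd.DataFrame({
            "participant": [0, 1], "visit": "placebo", "phase": "baseline",
            "trial": 0, "p_disgust": [0.2, 0.3], "p_neutral": [0.6, 0.5],
            "p_nonstim": [0.2, 0.2],
        })
        assert per_trial_tests(dw).untestable.iloc[0]

    def test_invariant_to_participant_ordering(self, study25, rng):
        dw = study25.dwell_truth.query("phase == 'incentive'")
        shuffled = dw.sample(frac=1.0, random_state=7)
        a = per_trial_tests(dw).sort_values(["visit", "phase", "trial"])
        b = per_trial_tests(shuffled).sort_values(["visit", "phase", "trial"])
        assert np.allclose(a.p.to_numpy(), b.p.to_numpy(), equal_nan=True)


class TestHolm:
    def test_worked_examples(self):
        assert holm_bonferroni([0.04]).tolist() == [True]
        assert holm_bonferroni([0.01, 0.04]).tolist() == [True, True]
        assert holm_bonferroni([0.03, 0.04]).tolist() == [False, False]
        assert holm_bonferroni([0.02, 0.2]).tolist() == [True, False]
        assert holm_bonferroni([1.0, 1.0, 1.0]).tolist() == [False] * 3

    def test_rejects_invalid_pvalues(self):
        with pytest.raises(ValueError):
            holm_bonferroni([0.0, 0.5])
        with pytest.raises(ValueError):
            holm_bonferroni([0.5, float("nan")])

    @given(p=st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=30),
           alpha=st.sampled_from([0.01, 0.05, 0.1]))
    @settings(deadline=None, max_examples=60)
    def test_between_bonferroni_and_uncorrected(self, p, alpha):
        p = np.asarray(p)
        holm = holm_bonferroni(p, alpha)
        bonf = p <= alpha / p.size
        raw = p <= alpha
        assert (holm | raw).tolist() == raw.tolist()     # subset of uncorrected
        assert (holm & bonf).tolist() == bonf.tolist()   # superset of Bonferroni

    @given(p=st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=30))
    @settings(deadline=None, max_examples=60)
    def test_agrees_with_statsmodels(self, p):
        ours = holm_bonferroni(p, 0.05)
        theirs = multipletests(p, alpha=0.05, method="holm")[0]
        assert ours.tolist() == theirs.tolist()


def test_self_report_model_without_trial_factor(study25):
    """Ratings use the same LMM machinery with stimulus category but no
    trial factor; the disgust-vs-neutral separation must come out positive."""
    sr = study25.self_report.rename(columns={"category": "stimulus"})
    sr = sr[sr.phase.isin(["baseline", "post_admin"])]
    spec = ModelSpec(outcome="self_report", fixed=("stimulus", "drug", "phase"))
    fit = fit_mixed_model(sr, spec)
    stim = fit.effect("stimulus")
    assert stim.beta > 0 and stim.p < 0.001
    # no injected drug x phase x stimulus effect on ratings
    assert fit.effect("stimulus:drug:phase").p > 0.05


def test_null_evidence_table_structure(study25):
    summ = (study25.choices.groupby(["participant", "visit", "rl_phase"])
            .reward.mean().rename("p_win").reset_index())
    tab = null_evidence_table(summ, measures=("p_win",))
    row = tab.iloc[0]
    assert row.measure == "p_win"
    assert np.isfinite(row.er0_null) and np.isfinite(row.bf01_null)
    assert 0 < row.p_drug <= 1 and 0 < row.p_interaction <= 1
    assert np.exp(row.log_er0_null) == pytest.approx(row.er0_null, rel=1e-9)
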