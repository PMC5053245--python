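import warnings

import numpy as np
import pytest
from scipy import stats

from paqc.paqc_score import ITEM_NAMES, score_cohort
from paqc.synthetic import (
    SimulationConfig,
    adherence_recovery_report,
    generate_cohort,
    resolved_item_probs,
)


def quiet_generate(cfg, cb):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_cohort(cfg, cb)


def quiet_scores(records, cb):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return score_cohort(records, cb)


def flat_config(p: float, **kw):
    defaults = dict(seed=99, n_hospitals=2, n_per_hospital_per_survey=60,
                    hospital_sd=0.0, arm_effect=0.0, survey_effect=0.0,
                    interaction=0.0, item_probs={k: p for k in ITEM_NAMES})
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestConfigValidation:
    def test_disease_mix_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SimulationConfig(seed=1, disease_mix={"malaria": 0.5})

    def test_hierarchy_ordering_enforced(self):
        probs = {k: 0.5 for k in ITEM_NAMES}
        probs["complete_assessment"] = 0.9
        with pytest.raises(ValueError, match="complete_assessment"):
            SimulationConfig(seed=1, item_probs=probs)
        probs = {k: 0.5 for k in ITEM_NAMES}
        probs["correct_use"] = 0.8
        with pytest.raises(ValueError, match="correct_use"):
            SimulationConfig(seed=1, item_probs=probs)

    def test_seed_is_mandatory(self):
        with pytest.raises(ValueError):
            SimulationConfig()


class TestForcedExtremes:
    def test_all_adherent_gives_q6(self, codebook):
        records = quiet_generate(flat_config(1.0), codebook)
        scores, not_scoreable = quiet_scores(records, codebook)
        assert not_scoreable == []
        assert {s.q for s in scores} == {6}

    def test_all_nonadherent_gives_q0(self, codebook):
        records = quiet_generate(flat_config(0.0), codebook)
        scores, _ = quiet_scores(records, codebook)
        assert {s.q for s in scores} == {0}


class TestReproducibility:
    def test_same_seed_identical_cohort(self, codebook):
        cfg = flat_config(0.6)
        a = quiet_generate(cfg, codebook)
        b = quiet_generate(cfg, codebook)
        assert a == b

    def test_different_seed_differs(self, codebook):
        a = quiet_generate(flat_config(0.6, seed=1), codebook)
        b = quiet_generate(flat_config(0.6, seed=2), codebook)
        assert a != b


class TestAdherenceRecovery:
    def test_marginals_recovered_at_n10000(self, codebook):
        """Observed patient-level item proportions match the configured
        targets within +-0.02 on a 10 000-record single-disease cohort."""
        cfg = SimulationConfig(
            seed=77, n_hospitals=4, n_per_hospital_per_survey=1250,
            hospital_sd=0.0, arm_effect=0.0, survey_effect=0.0, interaction=0.0,
            disease_mix={"malaria": 0.4, "pneumonia": 0.3, "diarrhoea_dehydration": 0.3},
            item_probs={"primary_signs": 0.7, "secondary_signs": 0.55,
                        "complete_assessment": 0.3, "classification": 0.6,
                        "drug_choice": 0.45, "correct_use": 0.35},
        )
        records = quiet_generate(cfg, codebook)
        assert len(records) == 10_000
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report = adherence_recovery_report(records, cfg, codebook)
        for item in ITEM_NAMES:
            row = report.loc[item]
            assert abs(row["observed"] - row["target"]) < 0.02, item

    def test_degenerate_target_exact(self, codebook):
        records = quiet_generate(flat_config(1.0), codebook)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report = adherence_recovery_report(records, flat_config(1.0), codebook)
        assert (report["observed"] == 1.0).all()
        assert (report["target"] == 1.0).all()

    def test_multimorbidity_product_law(self, codebook):
        """With independent per-disease items at p each, the combined item
        proportion is close to p^k for k diagnosed diseases."""
        p = 0.7
        cfg = flat_config(
            p, seed=31, n_hospitals=2, n_per_hospital_per_survey=2500,
            disease_mix={"malaria+pneumonia": 1.0},
            severity_probs={
                "malaria": {"severe": 0.0, "non_severe": 1.0},
                "pneumonia": {"very_severe": 0.0, "severe": 0.0, "non_severe": 1.0},
                "diarrhoea_dehydration": {"shock": 0.25, "severe": 0.25,
                                          "some": 0.25, "none": 0.25},
            },
        )
        records = quiet_generate(cfg, codebook)
        scores, _ = quiet_scores(records, codebook)
        observed = np.mean([s.combined.primary_signs for s in scores])
        assert observed == pytest.approx(p ** 2, abs=0.03)
        # chained treatment items follow the same product law
        observed_cls = np.mean([s.combined.classification for s in scores])
        assert observed_cls == pytest.approx(p ** 2, abs=0.03)


class TestStructuralPatterns:
    def test_raising_one_item_does_not_lower_median_q(self, codebook):
        base_probs = {"primary_signs": 0.8, "secondary_signs": 0.4,
                      "complete_assessment": 0.2, "classification": 0.5,
                      "drug_choice": 0.3, "correct_use": 0.2}
        cfg_lo = SimulationConfig(seed=55, n_hospitals=2, n_per_hospital_per_survey=500,
                                  hospital_sd=0.0, item_probs=base_probs)
        raised = dict(base_probs, classification=0.9)
        cfg_hi = cfg_lo.model_copy(update={"item_probs": raised})
        q_lo = np.median([s.q for s in quiet_scores(quiet_generate(cfg_lo, codebook), codebook)[0]])
        q_hi = np.median([s.q for s in quiet_scores(quiet_generate(cfg_hi, codebook), codebook)[0]])
        assert q_hi >= q_lo

    def test_multimorbidity_scores_lower_than_single_disease(self, codebook):
        cfg = SimulationConfig(seed=13, n_hospitals=2, n_per_hospital_per_survey=1500,
                               hospital_sd=0.0)
        scores, _ = quiet_scores(quiet_generate(cfg, codebook), codebook)
        single = [s.q for s in scores if len(s.diseases) == 1]
        multi = [s.q for s in scores if len(s.diseases) > 1]
        assert np.mean(multi) < np.mean(single)

    def test_positive_interaction_shifts_intervention_endline(self, codebook):
        """A positive arm-by-survey adherence interaction produces a
        rightward endline score shift in the intervention arm
        (rank-sum p < 0.01 at 2000 records per cell)."""
        cfg = SimulationConfig(seed=2024, n_hospitals=2, n_per_hospital_per_survey=2000,
                               hospital_sd=0.0, arm_effect=0.0,
                               survey_effect=0.0, interaction=0.9)
        records = quiet_generate(cfg, codebook)
        scores, _ = quiet_scores(records, codebook)
        by_id = {r.record_id: r for r in records}
        cells = {}
        for s in scores:
            rec = by_id[s.record_id]
            cells.setdefault((rec.arm.value, rec.survey), []).append(s.q)
        res = stats.mannwhitneyu(cells[("intervention", "endline")],
                                 cells[("intervention", "baseline")],
                                 alternative="greater")
        assert res.pvalue < 0.01
        # control arm saw no shift in this design
        ctl = stats.mannwhitneyu(cells[("control", "endline")],
                                 cells[("control", "baseline")],
                                 alternative="two-sided")
        assert ctl.pvalue > 0.01


class TestResolvedProbs:
    def test_logit_shifts_apply_only_where_configured(self):
        cfg = SimulationConfig(seed=1, arm_effect=0.5, survey_effect=0.3, interaction=0.2)
        base = resolved_item_probs(cfg, "control", 0, 0.0)
        assert base == pytest.approx(cfg.item_probs)
        shifted = resolved_item_probs(cfg, "intervention", 1, 0.0)
        for item in ITEM_NAMES:
            assert shifted[item] > base[item]

    def test_degenerate_probabilities_stay_degenerate(self):
        probs = {k: 1.0 for k in ITEM_NAMES}
        probs["correct_use"] = 0.0
        cfg = SimulationConfig(seed=1, item_probs=probs, arm_effect=5.0)
        out = resolved_item_probs(cfg, "intervention", 1, 2.0)
        assert out["primary_signs"] == 1.0
        assert out["correct_use"] == 0.0
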