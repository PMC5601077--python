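"""Trial orchestration on the fast surrogate population."""

import math

import numpy as np
import pytest

import aptrial as ap
from aptrial.cell_engine import IonicScaling
from aptrial.drug import ChannelBlock, CompoundRecord, ConcentrationSpec
from aptrial.population import PopulationTable
from aptrial.trial import (
    TrialResult, merge_worst_case, model_results_frame, run_control,
    run_drug_trial, trial_summary_frame,
)


@pytest.fixture(scope="module")
def null_compound():
    return CompoundRecord("nothing", "I", (), eftpc_max_um=1.0,
                          tdp_category="0")


@pytest.fixture(scope="module")
def strong_ikr_blocker():
    # multiples {1,10,30,100} x EFTPC -> remaining I_Kr {0.33,0.05,0.02,0.005}
    return CompoundRecord("herg-strong", "I",
                          (ChannelBlock("I_Kr", ic50_um=0.5),),
                          eftpc_max_um=1.0, tdp_category="1")


@pytest.fixture(scope="module")
def moderate_ikr_blocker():
    # remaining I_Kr {0.95,0.67,0.4,0.17}: prolongs without abolishing the AP
    return CompoundRecord("herg-moderate", "I",
                          (ChannelBlock("I_Kr", ic50_um=20.0),),
                          eftpc_max_um=1.0, tdp_category="1")


@pytest.fixture(scope="module")
def null_trial(toy_population, toy_model, toy_control, null_compound):
    return run_drug_trial(toy_population, null_compound,
                          model=toy_model, control=toy_control)


@pytest.fixture(scope="module")
def strong_trial(toy_population, toy_model, toy_control, strong_ikr_blocker):
    return run_drug_trial(toy_population, strong_ikr_blocker,
                          model=toy_model, control=toy_control)


class TestRunControl:
    def test_population_of_one_baseline_cell(self, toy_model):
        population = PopulationTable([("only", IonicScaling.baseline())])
        control = run_control(population, toy_model)
        values = control.results[0].biomarkers
        assert control.summary.median["apd90"] == values.apd90
        assert control.summary.delta_apd90 == 0.0

    def test_calibrated_population_has_no_abnormal_flags(self, toy_control):
        assert all(not r.flags.abnormal for r in toy_control.results)

    def test_abnormal_drug_free_cell_is_configuration_error(self, toy_model):
        population = PopulationTable([("bad", IonicScaling(g_Kr=0.01))])
        with pytest.raises(RuntimeError, match="inconsistent"):
            run_control(population, toy_model)


class TestRunDrugTrial:
    def test_null_compound_reproduces_control(self, null_trial):
        trial = null_trial
        assert all(n == 0 for n in trial.nRA.values())
        assert all(n == 0 for n in trial.nDA.values())
        for multiple in trial.multiples:
            summary = trial.summaries[multiple]
            for name, pct in summary.pct_change.items():
                assert pct == pytest.approx(0.0, abs=1e-9), name

    def test_moderate_ikr_block_prolongs_apd(self, toy_population, toy_model,
                                             toy_control, moderate_ikr_blocker):
        trial = run_drug_trial(toy_population, moderate_ikr_blocker,
                               model=toy_model, control=toy_control)
        assert trial.apd90_pct_change[100.0] > 0.0
        assert trial.apd90_pct_change[100.0] > trial.apd90_pct_change[1.0]

    def test_strong_ikr_block_ra_monotone_in_dose(self, strong_trial):
        trial = strong_trial
        counts = [trial.nRA[m] for m in trial.multiples]
        assert counts == sorted(counts)
        assert counts[-1] > 0

    def test_conservation_per_concentration(self, strong_trial):
        trial = strong_trial
        for multiple in trial.multiples:
            records = trial.records[multiple]
            n_normal = sum(1 for r in records
                           if not r.failed and not r.flags.abnormal)
            n_abnormal = sum(1 for r in records
                             if not r.failed and r.flags.abnormal)
            n_failed = sum(1 for r in records if r.failed)
            assert n_normal + n_abnormal + n_failed == trial.n_mod
            assert len({r.model_id for r in records}) == trial.n_mod

    def test_result_independent_of_population_order(self, toy_population,
                                                    toy_model, toy_control,
                                                    strong_ikr_blocker,
                                                    strong_trial):
        reversed_pop = PopulationTable(list(toy_population)[::-1])
        forward = strong_trial
        backward = run_drug_trial(reversed_pop, strong_ikr_blocker,
                                  model=toy_model, control=toy_control)
        assert forward.nRA == backward.nRA
        for m in forward.multiples:
            ids_f = [r.model_id for r in forward.records[m]]
            ids_b = [r.model_id for r in backward.records[m]]
            assert ids_f == ids_b  # aggregation sorts by model id


def _fake_trial(name, source, nra, apd, n_mod=10,
                multiples=(1.0, 10.0, 30.0, 100.0)):
    compound = CompoundRecord(name, source, (), 1.0, "1")
    return TrialResult(
        compound=compound, multiples=multiples,
        doses_um={m: m for m in multiples}, n_mod=n_mod,
        nRA=dict(zip(multiples, nra)), nDA={m: 0 for m in multiples},
        n_failed={m: 0 for m in multiples},
        apd90_pct_change=dict(zip(multiples, apd)),
    )


class TestMergeWorstCase:
    def test_single_variant_unchanged(self):
        only = _fake_trial("X", "I", (0, 0, 1, 3), (1, 2, 3, 4))
        assert merge_worst_case([only]) is only

    def test_max_rules(self):
        a = _fake_trial("X", "I", (0, 0, 1, 3), (1.0, 10.0, 12.0, 20.0))
        b = _fake_trial("X", "II", (0, 1, 0, 7), (2.0, 25.0, 11.0, 15.0))
        merged = merge_worst_case([a, b])
        assert merged.nRA[100.0] == 7
        assert merged.apd90_pct_change[10.0] == 25.0
        assert merged.apd90_pct_change[30.0] == 12.0
        assert merged.provenance["contributions"][100.0]["nRA"] == "II"
        assert merged.provenance["contributions"][10.0]["apd90"] == "II"

    def test_mismatched_grids_rejected(self):
        a = _fake_trial("X", "I", (0, 0), (1.0, 2.0), multiples=(1.0, 10.0))
        b = _fake_trial("X", "II", (0, 0, 0, 0), (1.0, 2.0, 3.0, 4.0))
        with pytest.raises(ValueError, match="grid"):
            merge_worst_case([a, b])

    def test_different_compounds_rejected(self):
        a = _fake_trial("X", "I", (0, 0, 0, 0), (0, 0, 0, 0))
        b = _fake_trial("Y", "I", (0, 0, 0, 0), (0, 0, 0, 0))
        with pytest.raises(ValueError, match="different compounds"):
            merge_worst_case([a, b])


class TestExportFrames:
    def test_summary_frame_shape(self, null_trial):
        frame = trial_summary_frame(null_trial)
        assert list(frame["multiple"]) == [1.0, 10.0, 30.0, 100.0]
        assert (frame["nRA"] == 0).all()
        assert (frame["pct_change_apd90"].abs() < 1e-9).all()

    def test_model_frame_covers_population(self, null_trial):
        trial = null_trial
        frame = model_results_frame(trial)
        assert len(frame) == trial.n_mod * len(trial.multiples)
        assert not frame["ra"].any() and not frame["failed"].any()
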