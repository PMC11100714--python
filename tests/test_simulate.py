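import numpy as np
import pandas as pd
import pytest

from adaptscan.simcortex.behavior import CHANCE_LEVELS, simulate_behavior
from adaptscan.simcortex.cohort import (
    CS_TARGETS,
    DEFAULT_ACCURACY,
    DEFAULT_TRIALS,
    GROUPS,
    RESPONSIVITY_TARGETS,
    RS_TARGET,
    CohortSpec,
    participant_records,
    rsa_target_covariance,
    simulate_activation_patterns,
    simulate_measures,
    solve_adaptation_tuning,
)
from adaptscan.simcortex.signal import (
    VoxelTuningParams,
    event_fatigue_exponents,
    expected_condition_attenuation,
    simulate_timeseries,
)
from adaptscan._seeds import derive_rng, derive_seed


class TestSeeds:
    def test_streams_independent_and_reproducible(self):
        a = derive_rng(1, "x").standard_normal(5)
        b = derive_rng(1, "x").standard_normal(5)
        c = derive_rng(1, "y").standard_normal(5)
        assert np.allclose(a, b)
        assert not np.allclose(a, c)

    def test_derive_seed_31_bit(self):
        for s in range(10):
            v = derive_seed(s, "lbl")
            assert 0 <= v < 2**31


class TestFatigueModel:
    def test_exponents_orderings(self, adaptation_design):
        exps = event_fatigue_exponents(adaptation_design)
        # same blocks count 0..11, different all 0, alternating 0,0,1,1,...
        for cat in ("faces", "objects", "words"):
            same = exps[f"{cat}_same"]
            assert same[:12] == list(range(12))
            assert all(k == 0 for k in exps[f"{cat}_different"])
            assert exps[f"{cat}_alternating"][:12] == [i // 2 for i in range(12)]

    def test_immediate_mode_alternating_unattenuated(self, adaptation_design):
        exps = event_fatigue_exponents(adaptation_design, mode="immediate")
        assert all(k == 0 for k in exps["faces_alternating"])
        assert exps["faces_same"][:12] == list(range(12))

    def test_expected_attenuation_closed_forms(self):
        f = 0.8
        n = 12
        assert expected_condition_attenuation("different", n, f) == 1.0
        assert expected_condition_attenuation("same", n, f) == pytest.approx(
            sum(f**k for k in range(n)) / n
        )
        assert expected_condition_attenuation("alternating", n, f) == pytest.approx(
            sum(f ** (i // 2) for i in range(n)) / n
        )

    def test_attenuation_ordering(self):
        for f in (0.5, 0.8, 0.95):
            d = expected_condition_attenuation("different", 12, f)
            a = expected_condition_attenuation("alternating", 12, f)
            s = expected_condition_attenuation("same", 12, f)
            assert d > a > s


class TestSimulateTimeseries:
    def test_shapes_and_determinism(self, adaptation_design):
        tun = [VoxelTuningParams(selectivity={"faces": 5.0}, noise_sd=2.0, ar1=0.3)] * 3
        a = simulate_timeseries(adaptation_design, tun, seed=9)
        b = simulate_timeseries(adaptation_design, tun, seed=9)
        assert a.signal.shape == (3, adaptation_design.n_volumes)
        assert np.allclose(a.signal, b.signal)
        assert a.motion.shape == (adaptation_design.n_volumes, 6)

    def test_noise_ar1_autocorrelation(self, adaptation_design):
        tun = [VoxelTuningParams(noise_sd=3.0, ar1=0.6)] * 400
        ds = simulate_timeseries(adaptation_design, tun, seed=5)
        x = ds.signal - 1000.0
        num = (x[:, 1:] * x[:, :-1]).sum()
        den = (x**2).sum()
        assert num / den == pytest.approx(0.6, abs=0.05)

    def test_validation(self):
        with pytest.raises(ValueError):
            VoxelTuningParams(fatigue=0.0)
        with pytest.raises(ValueError):
            VoxelTuningParams(ar1=1.0)
        with pytest.raises(ValueError):
            VoxelTuningParams(selectivity={"faces": -1.0})


class TestSolveAdaptationTuning:
    def test_round_trip(self):
        f, sel = solve_adaptation_tuning(0.74, 0.27)
        gs = expected_condition_attenuation("same", 12, f)
        ga = expected_condition_attenuation("alternating", 12, f)
        mean_resp = 0.1 * sel * (1 + ga + gs) / 3.0
        rs = 0.1 * sel * (1 - gs)
        assert mean_resp == pytest.approx(0.74, rel=1e-9)
        assert rs == pytest.approx(0.27, rel=1e-9)
        assert 0 < f < 1

    def test_rejects_impossible_targets(self):
        with pytest.raises(ValueError):
            solve_adaptation_tuning(0.1, 0.35)


class TestParticipantRecords:
    def test_group_sizes_default(self):
        rec = participant_records(CohortSpec(seed=0))
        counts = rec.group.value_counts()
        assert counts["TD"] == 21
        assert counts["control_patient"] == 12
        assert counts["OTC_patient"] == 9

    def test_td_both_hemispheres_patients_one(self):
        rec = participant_records(CohortSpec(seed=1))
        assert (rec.loc[rec.group == "TD", "preserved_hemisphere"] == "both").all()
        pats = rec[rec.group != "TD"]
        assert set(pats.preserved_hemisphere) == {"LH", "RH"}

    def test_ages_within_range(self):
        spec = CohortSpec(seed=2)
        rec = participant_records(spec)
        assert rec.age.between(*spec.age_range).all()


class TestSimulateMeasures:
    def test_calibration_to_targets(self):
        # average over several cohorts approaches the anchored targets
        vals = {"cs_amplitude": [], "rs_magnitude": []}
        resp = []
        for s in range(12):
            m = simulate_measures(CohortSpec(seed=100 + s))
            td = m[m.group == "TD"]
            vals["cs_amplitude"].append(
                td[td.measure == "cs_amplitude"].value.mean()
            )
            vals["rs_magnitude"].append(td[td.measure == "rs_magnitude"].value.mean())
            resp.append(td[td.measure == "responsivity"].value.mean())
        assert np.mean(vals["cs_amplitude"]) == pytest.approx(
            np.mean(list(CS_TARGETS.values())), abs=0.08
        )
        assert np.mean(vals["rs_magnitude"]) == pytest.approx(RS_TARGET, abs=0.04)
        assert np.mean(resp) == pytest.approx(
            np.mean(list(RESPONSIVITY_TARGETS.values())), abs=0.05
        )

    def test_effect_delta_shifts_group_mean(self):
        deltas = {"OTC_patient": {"rs_magnitude": -0.1}}
        diffs = []
        for s in range(10):
            m = simulate_measures(CohortSpec(effect_deltas=deltas, seed=300 + s))
            rs = m[m.measure == "rs_magnitude"]
            diffs.append(
                rs[rs.group == "OTC_patient"].value.mean()
                - rs[rs.group == "TD"].value.mean()
            )
        assert np.mean(diffs) == pytest.approx(-0.1, abs=0.05)

    def test_accuracy_rows_binomial_consistency(self):
        m = simulate_measures(CohortSpec(seed=4))
        acc = m[m.measure == "accuracy"]
        prod = (acc.value.astype(float) * acc.n_trials.astype(float)).round()
        assert prod.astype(int).equals(acc.n_correct.astype(int))
        for task, n in DEFAULT_TRIALS.items():
            assert (acc.loc[acc.category == task, "n_trials"] == n).all()

    def test_exchangeable_under_null(self):
        # with zero deltas the group means coincide in expectation
        means = {g: [] for g in GROUPS}
        for s in range(12):
            m = simulate_measures(CohortSpec(seed=700 + s))
            rs = m[m.measure == "rs_magnitude"]
            for g in GROUPS:
                means[g].append(rs[rs.group == g].value.mean())
        grand = [np.mean(means[g]) for g in GROUPS]
        assert max(grand) - min(grand) < 0.05


class TestBehavior:
    def test_accuracy_near_reported_table(self):
        ks = {(g, t): [] for g in GROUPS for t in DEFAULT_TRIALS}
        for s in range(8):
            b = simulate_behavior(CohortSpec(seed=50 + s), seed=50 + s)
            for (g, t), grp in b.groupby(["group", "task"]):
                ks[(g, t)].append(grp.accuracy.mean())
        for (g, t), v in ks.items():
            assert np.mean(v) == pytest.approx(DEFAULT_ACCURACY[g][t], abs=0.05)

    def test_chance_levels(self):
        assert CHANCE_LEVELS == {"faces": 1 / 3, "objects": 1 / 3, "words": 0.5}

    def test_invalid_probability_raises(self):
        spec = CohortSpec(effect_deltas={"TD": {"accuracy": 0.5}}, seed=0)
        with pytest.raises(ValueError, match="outside"):
            simulate_behavior(spec)


class TestRSAGenerator:
    def test_covariance_psd_and_structure(self):
        cov = rsa_target_covariance()
        assert np.all(np.linalg.eigvalsh(cov) > 0)
        assert np.allclose(np.diag(cov), 1.0)
        # one-step within-category pairs carry the shared signal
        from adaptscan.simcortex.designs import ADAPTATION_BLOCK_TYPES

        i = ADAPTATION_BLOCK_TYPES.index("faces_same")
        j = ADAPTATION_BLOCK_TYPES.index("faces_alternating")
        k = ADAPTATION_BLOCK_TYPES.index("faces_different")
        m = ADAPTATION_BLOCK_TYPES.index("words_same")
        assert cov[i, j] == pytest.approx(0.5)
        assert cov[i, k] == pytest.approx(0.0)
        assert cov[i, m] == pytest.approx(0.0)

    def test_patterns_shape_and_mean(self):
        rng = np.random.default_rng(0)
        pats = np.mean(
            [simulate_activation_patterns(200, rng) for _ in range(20)], axis=(0, 1)
        )
        from adaptscan.simcortex.designs import ADAPTATION_BLOCK_TYPES

        i_same = ADAPTATION_BLOCK_TYPES.index("faces_same")
        i_diff = ADAPTATION_BLOCK_TYPES.index("faces_different")
        assert pats[i_diff] - pats[i_same] == pytest.approx(RS_TARGET, abs=0.05)
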