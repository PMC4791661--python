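"""Flat-bottom restraint energies, two-layer averaging and Q factors."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from oligorient.errors import ConfigError, DataError
from oligorient.observables import ComputedObservable, backcalc_table
from oligorient.restraints import (FORCE_CONSTANT_TABLE, ObservableTable,
                                   RestraintConfig, average_observables,
                                   ensemble_restraint_energy,
                                   flat_bottom_energy, q_factor,
                                   ramp_schedule, restraint_energy,
                                   restraint_gradient)
from oligorient.structures import (ReplicaEnsemble, oligomer_coords,
                                   oligomer_with_coords)


class TestObservableTable:
    def test_default_errors_filled(self):
        t = ObservableTable.from_records([(2, "CSA", 100.0), (2, "DC", 3.0)])
        lut = t.lookup()
        assert lut[(2, "CSA")][1] == 5.0
        assert lut[(2, "DC")][1] == 0.5

    def test_duplicate_records_rejected(self):
        with pytest.raises(DataError):
            ObservableTable.from_records([(2, "CSA", 1.0), (2, "CSA", 2.0)])

    def test_unknown_kind_rejected(self):
        with pytest.raises(DataError):
            ObservableTable.from_records([(2, "NOE", 1.0)])

    def test_tsv_round_trip(self, tmp_path):
        t = ObservableTable.from_records([(2, "CSA", 100.0, 3.0),
                                          (3, "DC", 4.5)])
        path = tmp_path / "obs.tsv"
        t.write_tsv(path)
        back = ObservableTable.read_tsv(path)
        pd.testing.assert_frame_equal(t.frame, back.frame)


class TestConfig:
    def test_table_defaults_by_setup(self):
        cfg = RestraintConfig.from_table(16, "replica_internal")
        assert (cfg.alpha_csa, cfg.alpha_dc) == (25.0, 1000.0)
        cfg = RestraintConfig.from_table(1, "replica")
        assert (cfg.alpha_csa, cfg.alpha_dc) == (4.5, 150.0)
        cfg = RestraintConfig.from_table(1, "replica_internal")
        assert (cfg.alpha_csa, cfg.alpha_dc) == (12.5, 250.0)

    def test_table_covers_published_rows(self):
        assert set(FORCE_CONSTANT_TABLE) == {1, 2, 3, 4, 8, 16}

    def test_invalid_scheme_rejected(self):
        with pytest.raises(ConfigError):
            RestraintConfig(averaging="protomer")


class TestRamp:
    def test_endpoints_and_midpoint(self):
        cfg = RestraintConfig(ramp_steps=100)
        assert ramp_schedule(0, cfg) == 0.0
        assert ramp_schedule(50, cfg) == 0.5
        assert ramp_schedule(100, cfg) == 1.0
        assert ramp_schedule(500, cfg) == 1.0

    def test_negative_step_rejected(self):
        with pytest.raises(ConfigError):
            ramp_schedule(-1, RestraintConfig())


class TestAveraging:
    def test_identity_for_single_copy(self):
        recs = [ComputedObservable(2, "A", "CSA", 5.0, 0)]
        assert average_observables(recs)[(2, "CSA")] == 5.0

    def test_replica_mean(self):
        recs = [ComputedObservable(2, "A", "CSA", v, m)
                for m, v in enumerate((1.0, 2.0, 6.0))]
        avg = average_observables(recs, "replica")
        assert avg[(2, "CSA", "A")] == pytest.approx(3.0)

    def test_combined_equals_flat_mean_and_nested_mean(self, rng):
        """Combined replica+internal averaging is the flat mean over all
        M*P copies, and equals replica-averaging the per-replica internal
        means (algebraic identity)."""
        M, P = 4, 5
        recs, values = [], {}
        for resid in (2, 3, 4):
            for kind in ("CSA", "DC"):
                vals = rng.normal(100.0, 10.0, size=(M, P))
                values[(resid, kind)] = vals
                for m in range(M):
                    for p in range(P):
                        recs.append(ComputedObservable(
                            resid, "ABCDE"[p], kind, vals[m, p], m))
        avg = average_observables(recs, "replica_internal")
        for key, vals in values.items():
            flat = vals.mean()
            nested = vals.mean(axis=1).mean()
            assert abs(avg[key] - flat) < 1e-12 * abs(flat)
            assert abs(avg[key] - nested) < 1e-12 * abs(flat)

    def test_missing_keys_raise(self):
        recs = [ComputedObservable(2, "A", "CSA", 1.0, 0),
                ComputedObservable(3, "A", "CSA", 1.0, 1)]
        with pytest.raises(DataError):
            average_observables(recs)


class TestFlatBottomEnergy:
    def test_published_example_one_ppm_past_boundary(self):
        """CSA deviation 6 ppm with error 5 ppm at the 16-replica constant
        gives (6-5)^2 * 25.0 = 25.0 J/mol."""
        obs = ObservableTable.from_records([(5, "CSA", 100.0)])
        cfg = RestraintConfig.from_table(16)
        rep = restraint_energy({(5, "CSA"): 106.0}, obs, cfg, 1.0)
        assert rep.total_energy == pytest.approx(25.0, abs=1e-12)

    @pytest.mark.parametrize("avg,expected", [
        ({(5, "CSA"): 104.9}, 0.0),             # inside the CSA flat bottom
        ({(5, "DC"): 3.4}, 0.0),                # inside the DC flat bottom
        ({(5, "DC"): 3.6}, 10.0),               # (0.6-0.5)^2 * 1000
    ])
    def test_flat_bottom_cases(self, avg, expected):
        obs = ObservableTable.from_records([(5, "CSA", 100.0), (5, "DC", 3.0)])
        cfg = RestraintConfig.from_table(16)
        rep = restraint_energy(avg, obs, cfg, 1.0)
        assert rep.total_energy == pytest.approx(expected, abs=1e-9)

    def test_zero_ramp_kills_energy(self):
        obs = ObservableTable.from_records([(5, "CSA", 100.0)])
        rep = restraint_energy({(5, "CSA"): 150.0}, obs,
                               RestraintConfig.from_table(16), 0.0)
        assert rep.total_energy == 0.0

    @given(st.floats(-30.0, 30.0))
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_continuity_and_monotonicity(self, dev):
        """E is 0 inside the bottom, continuous at the boundary and
        non-decreasing in |deviation|."""
        e = flat_bottom_energy(dev, 5.0, 25.0, 1.0)
        assert e >= 0.0
        if abs(dev) <= 5.0:
            assert e == 0.0
        else:
            assert e == pytest.approx(25.0 * (abs(dev) - 5.0) ** 2)
            bigger = flat_bottom_energy(dev * 1.1, 5.0, 25.0, 1.0)
            assert bigger >= e

    def test_permutation_invariance(self, perturbed_ensemble):
        """Replica and protomer order do not affect the averaged energy."""
        obs_src = backcalc_table(perturbed_ensemble)
        avg = average_observables(obs_src)
        obs = ObservableTable.from_records(
            [(k[0], k[1], v + (7.0 if k[1] == "CSA" else 0.9))
             for k, v in avg.items()])
        cfg = RestraintConfig.from_table(2)
        e1 = ensemble_restraint_energy(perturbed_ensemble, obs, cfg).total_energy
        swapped = ReplicaEnsemble(replicas=perturbed_ensemble.replicas[::-1])
        e2 = ensemble_restraint_energy(swapped, obs, cfg).total_energy
        reordered = ReplicaEnsemble(replicas=[
            type(r)(protomers=r.protomers[::-1])
            for r in perturbed_ensemble.replicas])
        e3 = ensemble_restraint_energy(reordered, obs, cfg).total_energy
        assert e1 == pytest.approx(e2, rel=1e-12)
        assert e1 == pytest.approx(e3, rel=1e-12)


class TestQFactor:
    def test_perfect_agreement(self):
        obs = ObservableTable.from_records([(2, "CSA", 10.0), (3, "CSA", 20.0)])
        out = q_factor({(2, "CSA"): 10.0, (3, "CSA"): 20.0}, obs)
        assert out["CSA"]["q"] == 0.0

    def test_double_everything(self):
        obs = ObservableTable.from_records([(2, "DC", 4.0), (3, "DC", 4.0)])
        out = q_factor({(2, "DC"): 8.0, (3, "DC"): 8.0}, obs)
        assert out["DC"]["q"] == pytest.approx(1.0)

    def test_hand_computed_example(self):
        obs = ObservableTable.from_records([(2, "CSA", 10.0), (3, "CSA", 20.0)])
        out = q_factor({(2, "CSA"): 11.0, (3, "CSA"): 19.0}, obs)
        assert out["CSA"]["q"] == pytest.approx(math.sqrt(2) / math.sqrt(500))

    def test_all_zero_observed_rejected(self):
        obs = ObservableTable.from_records([(2, "CSA", 0.0)])
        with pytest.raises(DataError):
            q_factor({(2, "CSA"): 1.0}, obs)


class TestGradient:
    @staticmethod
    def _offset_obs(ens, csa_off=8.0, dc_off=1.2):
        avg = average_observables(backcalc_table(ens))
        return ObservableTable.from_records(
            [(k[0], k[1], v + (csa_off if k[1] == "CSA" else dc_off))
             for k, v in avg.items()])

    def test_zero_inside_flat_bottom(self, perturbed_ensemble):
        """No force while every deviation is within experimental error."""
        obs = self._offset_obs(perturbed_ensemble, 0.0, 0.0)
        grads = restraint_gradient(perturbed_ensemble, obs,
                                   RestraintConfig.from_table(2))
        assert all(np.all(g == 0.0) for g in grads)

    def test_matches_central_differences(self, perturbed_ensemble, rng):
        obs = self._offset_obs(perturbed_ensemble)
        cfg = RestraintConfig.from_table(2)
        grads = restraint_gradient(perturbed_ensemble, obs, cfg)
        coords = [oligomer_coords(r) for r in perturbed_ensemble.replicas]
        h = 1e-5
        checked = 0
        while checked < 20:
            m = int(rng.integers(2))
            p = int(rng.integers(5))
            i = int(rng.integers(coords[0].shape[1]))
            a = int(rng.integers(5))
            x = int(rng.integers(3))
            if np.any(np.isnan(coords[m][p, i, a])):
                continue

            def energy(delta):
                cc = [c.copy() for c in coords]
                cc[m][p, i, a, x] += delta
                reps = [oligomer_with_coords(perturbed_ensemble.replicas[k],
                                             cc[k]) for k in range(2)]
                return ensemble_restraint_energy(
                    ReplicaEnsemble(replicas=reps), obs, cfg).total_energy

            num = (energy(h) - energy(-h)) / (2 * h)
            ana = grads[m][p, i, a, x]
            if abs(num) > 1e-6:
                assert abs(ana - num) / abs(num) <= 1e-4
            else:
                assert abs(ana) < 1e-6
            checked += 1

    def test_doubling_replicas_halves_per_replica_gradient(self,
                                                           perturbed_ensemble):
        """With identical replicas the chain-rule averaging factor 1/M makes
        each replica's gradient half as large at M=2 as at M=1."""
        rep = perturbed_ensemble.replicas[0]
        obs = self._offset_obs(ReplicaEnsemble(replicas=[rep]))
        g1 = restraint_gradient(ReplicaEnsemble(replicas=[rep]), obs,
                                RestraintConfig(M=1))
        g2 = restraint_gradient(ReplicaEnsemble(replicas=[rep, rep]), obs,
                                RestraintConfig(M=2))
        assert np.allclose(g2[0], 0.5 * g1[0], atol=1e-12)
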