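"""GA fitting tests: L1 objective semantics, determinism, elitism
monotonicity, synthetic-observation design and trajectory recovery."""

import numpy as np
import pytest

from crpcsim.fitting import (
    GAConfig,
    Observation,
    ObservationSet,
    PROTEINS,
    SKP2_TIMES,
    fit_ga,
    generate_synthetic_observations,
    objective,
)
from crpcsim.signaling import LigandInput, ODEParams, integrate


@pytest.fixture(scope="module")
def true_params():
    return ODEParams()


@pytest.fixture(scope="module")
def clean_obs(true_params):
    return generate_synthetic_observations(true_params, noise_sd=0.0)


class TestObjective:
    def test_zero_on_self_generated_data(self, true_params, clean_obs):
        assert objective(true_params, clean_obs) == pytest.approx(0.0, abs=1e-5)

    def test_single_offset_observation(self, true_params):
        base = generate_synthetic_observations(true_params, noise_sd=0.0)
        o = base.entries[1]
        shifted = ObservationSet(
            [Observation(o.protein, o.t_min, o.condition, o.dose, o.value + 0.2)]
        )
        assert objective(true_params, shifted) == pytest.approx(0.2, abs=1e-5)

    def test_matches_independent_residual_sum(self, true_params):
        """Three-observation toy set: objective equals a per-point residual
        sum computed directly from independent integrations."""
        entries = [
            Observation("erk", 30.0, "wnt5a", 1.0, 0.8),
            Observation("akt", 60.0, "egf", 1.0, 0.1),
            Observation("ar", 420.0, "wnt5a", 1.0, 0.55),
        ]
        obs = ObservationSet(entries)
        total = 0.0
        cols = {"erk": 0, "akt": 2, "ar": 3}
        for o in entries:
            lig = LigandInput(wnt5a=o.dose) if o.condition == "wnt5a" \
                else LigandInput(egf=o.dose)
            traj = integrate(true_params, lig, t_grid=np.array([0.0, o.t_min]))
            total += abs(o.value - traj[-1, cols[o.protein]])
        assert objective(true_params, obs) == pytest.approx(total, rel=1e-4)

    def test_permutation_invariance(self, true_params, clean_obs):
        rev = ObservationSet(list(reversed(clean_obs.entries)))
        assert objective(true_params, rev) == pytest.approx(
            objective(true_params, clean_obs)
        )

    def test_empty_set_rejected(self, true_params):
        with pytest.raises(ValueError):
            objective(true_params, ObservationSet([]))


class TestSyntheticObservations:
    def test_skp2_restricted_to_30_and_60_minutes(self, clean_obs):
        skp2_times = {o.t_min for o in clean_obs if o.protein == "skp2"}
        assert skp2_times == set(SKP2_TIMES)
        with pytest.raises(ValueError):
            Observation("skp2", 420.0, "wnt5a", 1.0, 0.5)

    def test_design_covers_proteins_and_conditions(self, clean_obs):
        assert {o.protein for o in clean_obs} == set(PROTEINS)
        assert {o.condition for o in clean_obs} == {"wnt5a", "egf"}

    def test_noise_scale_recovered(self, true_params):
        """Empirical residual SD over many seeds matches the requested
        noise level to within three standard errors."""
        sd = 0.05
        resid = []
        clean = {
            (o.protein, o.t_min, o.condition): o.value
            for o in generate_synthetic_observations(true_params, noise_sd=0.0)
        }
        for seed in range(40):
            noisy = generate_synthetic_observations(
                true_params, noise_sd=sd, seed=seed
            )
            for o in noisy:
                key = (o.protein, o.t_min, o.condition)
                if clean[key] > 3 * sd:  # away from the zero-clipping boundary
                    resid.append(o.value - clean[key])
        resid = np.asarray(resid)
        se = sd / np.sqrt(2 * len(resid))
        assert abs(resid.std() - sd) < 3 * se

    def test_values_non_negative_and_seeded(self, true_params):
        a = generate_synthetic_observations(true_params, noise_sd=0.3, seed=5)
        b = generate_synthetic_observations(true_params, noise_sd=0.3, seed=5)
        assert all(o.value >= 0 for o in a)
        assert [o.value for o in a] == [o.value for o in b]

    def test_csv_round_trip(self, clean_obs, tmp_path):
        path = tmp_path / "obs.csv"
        clean_obs.to_csv(path)
        back = ObservationSet.from_csv(path)
        a, b = back.to_frame(), clean_obs.to_frame()
        assert (a[["protein", "condition"]] == b[["protein", "condition"]]).all().all()
        assert np.allclose(a[["t_min", "dose", "value"]],
                           b[["t_min", "dose", "value"]], atol=1e-12)


class TestGA:
    def test_same_seed_identical_result(self, clean_obs):
        cfg = GAConfig(population=10, generations=3, seed=11)
        p1, t1 = fit_ga(clean_obs, cfg)
        p2, t2 = fit_ga(clean_obs, GAConfig(population=10, generations=3, seed=11))
        assert p1.as_dict() == p2.as_dict()
        assert np.array_equal(t1, t2)

    def test_best_fitness_non_increasing(self, clean_obs):
        _, trace = fit_ga(clean_obs, GAConfig(population=14, generations=8, seed=3))
        assert np.all(np.diff(trace) <= 0.0)

    def test_degenerate_ga_returns_better_candidate(self, clean_obs):
        cfg = GAConfig(population=2, generations=1, seed=2)
        params, trace = fit_ga(clean_obs, cfg)
        assert objective(params, clean_obs) <= trace[0] + 1e-12

    def test_empty_observations_rejected(self):
        with pytest.raises(ValueError):
            fit_ga(ObservationSet([]), GAConfig(population=4, generations=1))

    def test_trajectory_recovery_on_clean_data(self, true_params, clean_obs):
        """Parameter estimation on noise-free synthetic observations
        recovers the observed trajectories to within 5% RMS (the
        parameters themselves need not be identifiable)."""
        cfg = GAConfig(population=60, generations=35, seed=17)
        fitted, trace = fit_ga(clean_obs, cfg)
        grid = np.array([0.0, 30.0, 60.0, 420.0])
        err2, ref2 = 0.0, 0.0
        for lig in (LigandInput(wnt5a=1.0), LigandInput(egf=1.0)):
            truth = integrate(true_params, lig, t_grid=grid)[:, :4]
            est = integrate(fitted, lig, t_grid=grid)[:, :4]
            err2 += np.sum((truth - est) ** 2)
            ref2 += np.sum(truth**2)
        assert np.sqrt(err2 / ref2) < 0.05
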