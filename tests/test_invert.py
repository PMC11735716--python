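"""Maximum-entropy and Gaussian-model inversion of order parameters."""

import numpy as np
import pytest

import fisskit as fk
from fisskit.errors import NoCompatibleOrientationError
from fisskit.frames import ProbeGeometry
from fisskit.invert import (
    MaximumEntropyModel,
    angular_distance,
    find_peaks,
    gaussian_density,
)
from fisskit.omap import OrientationMap
from fisskit.synthfix import make_probe_dataset

from conftest import probe_data


def xz_probes():
    """Probes whose dipoles all lie in the molecular xz plane.

    cos(theta) is then even in gamma, so any data set generated from
    (beta0, gamma0) is exactly degenerate with (beta0, -gamma0): the
    constructed two-minima situation.
    """
    dirs = [
        [0.0, 0.0, 1.0],
        [0.766, 0.0, 0.643],
        [0.985, 0.0, -0.174],
    ]
    return [ProbeGeometry(f"xz{i}", (("A", i), ("A", i + 7)), d)
            for i, d in enumerate(dirs)]


class TestMaximumEntropy:
    def test_zero_probes_gives_uniform(self):
        res = fk.me_invert([])
        assert res.converged
        assert res.map.density.std() < 1e-12
        # unconstrained entropy maximum on the sphere-of-orientations
        # (midpoint quadrature of the log term limits the agreement)
        assert res.entropy == pytest.approx(np.log(4 * np.pi), abs=1e-4)

    def test_order_params_of_isotropy_return_uniform(self, domain5):
        _, _, probes = domain5
        uniform = OrientationMap.regular(2.0)
        ops = fk.forward_order_params(uniform, probes[0])
        res = fk.me_invert([(probes[0], ops)])
        assert res.converged and res.mode == "exact"
        # flat to well below 1e-6 (the absolute level carries the grid's
        # own quadrature normalisation, not exactly 1/4pi)
        flat = res.map.density
        assert np.max(np.abs(flat - flat.mean())) < 1e-9

    def test_five_probe_delta_recovery_within_5_deg(self, domain5):
        _, _, probes = domain5
        truth = (100.0, -30.0)
        df, _ = make_probe_dataset(probes, truth, noise_sd=0.0)
        res = fk.me_invert(probe_data(probes, df))
        assert res.converged
        peaks = res.peaks().peaks
        assert peaks, "no peak found"
        err = angular_distance((peaks[0].beta, peaks[0].gamma), truth)
        assert err < 5.0

    def test_incompatible_folds_raise_no_solution(self, domain5):
        """Mixing order parameters from two different orientations of the
        same fold produces constraints no single distribution satisfies."""
        _, _, probes = domain5
        df_a, _ = make_probe_dataset(probes, (100.0, -30.0))
        df_b, _ = make_probe_dataset(probes, (30.0, 90.0))
        mixed = probe_data(probes, df_a)[:3] + probe_data(probes, df_b)[3:]
        with pytest.raises(NoCompatibleOrientationError) as exc:
            fk.me_invert(mixed)
        assert exc.value.residual > 0

    def test_me_map_is_inversion_fixed_point(self, domain5):
        """Order parameters computed FROM an ME map reproduce that map."""
        _, _, probes = domain5
        dist = gaussian_density(70.0, 30.0, 25.0, OrientationMap.regular(2.0))
        data1 = [(p, fk.forward_order_params(dist, p)) for p in probes[:3]]
        res1 = fk.me_invert(data1)
        data2 = [(p, fk.forward_order_params(res1.map, p)) for p in probes[:3]]
        res2 = fk.me_invert(data2)
        scale = res1.map.density.max()
        assert np.max(np.abs(res1.map.density - res2.map.density)) < 1e-3 * scale

    def test_entropy_maximal_among_feasible_perturbations(self, domain5):
        """No feasible perturbation of the ME solution has higher entropy."""
        _, _, probes = domain5
        dist = gaussian_density(80.0, 0.0, 30.0, OrientationMap.regular(6.0))
        data = [(p, fk.forward_order_params(dist, p)) for p in probes[:2]]
        model = MaximumEntropyModel(data, spacing=6.0)
        res = model.fit()
        assert res.converged and res.mode == "exact"
        w = res.map.weights().ravel()
        f = res.map.density.ravel()
        # constraint matrix incl. normalisation, acting on density values
        A = np.vstack([w, model._G * w])
        null = np.linalg.svd(A)[2][A.shape[0]:]  # basis of the null space
        rng = np.random.default_rng(12)
        base_entropy = res.map.entropy()
        for _ in range(50):
            coef = rng.normal(size=null.shape[0])
            d = coef @ null
            # scale so the density stays strictly positive
            step = 0.25 * f.min() / (np.abs(d).max() + 1e-300)
            pert = OrientationMap(
                res.map.beta_deg, res.map.gamma_deg,
                (f + step * d).reshape(res.map.density.shape),
            )
            assert abs(pert.integral() - 1.0) < 1e-9
            assert pert.entropy() <= base_entropy + 1e-10

    def test_all_outputs_dipole_symmetric(self, domain5):
        _, _, probes = domain5
        df, _ = make_probe_dataset(probes, (100.0, -30.0))
        res = fk.me_invert(probe_data(probes, df))
        assert res.map.dipole_asymmetry() < 1e-8

    def test_measurement_sigmas_relax_constraints(self, domain5):
        _, _, probes = domain5
        df, _ = make_probe_dataset(probes, (100.0, -30.0), noise_sd=0.01, seed=5)
        res = fk.me_invert(probe_data(probes, df, sigma=0.01))
        assert res.mode == "relaxed"
        assert res.converged
        assert np.all(np.abs(res.residuals) <= 3 * res.sigma_eff + 1e-9)

    def test_wobble_divided_out(self, domain5):
        """Fast-wobble-scaled data with the matching WobbleModel recovers
        the same orientation as rigid data."""
        _, _, probes = domain5
        wob = fk.WobbleModel(p2_fast=0.85)
        df, _ = make_probe_dataset(probes, (100.0, -30.0), wobble=wob)
        res = fk.me_invert(probe_data(probes, df), wobble=wob)
        peaks = res.peaks().peaks
        assert angular_distance((peaks[0].beta, peaks[0].gamma), (100.0, -30.0)) < 5.0


class TestFindPeaks:
    def test_uniform_map_has_no_peaks(self):
        assert find_peaks(OrientationMap.regular(4.0)).peaks == []

    def test_single_bump_found_at_centre(self):
        dist = gaussian_density(60.0, 40.0, 15.0, OrientationMap.regular(2.0))
        peaks = find_peaks(dist).peaks
        assert len(peaks) == 1
        assert angular_distance((peaks[0].beta, peaks[0].gamma), (60.0, 40.0)) < 2.0

    def test_dipole_mate_bumps_fold_to_one_peak(self):
        grid = OrientationMap.regular(2.0)
        a = gaussian_density(60.0, 40.0, 12.0, grid)
        b = gaussian_density(120.0, -140.0, 12.0, grid)  # the dipole mate
        both = OrientationMap(
            grid.beta_deg, grid.gamma_deg, a.density + b.density
        ).normalized()
        peaks = find_peaks(both).peaks
        assert len(peaks) == 1
        assert peaks[0].beta <= 90.0

    def test_two_distinct_peaks_kept(self):
        grid = OrientationMap.regular(2.0)
        a = gaussian_density(40.0, -60.0, 10.0, grid)
        b = gaussian_density(75.0, 80.0, 10.0, grid)
        both = OrientationMap(
            grid.beta_deg, grid.gamma_deg, a.density + 0.9 * b.density
        ).normalized()
        peaks = find_peaks(both).peaks
        assert len(peaks) == 2
        assert peaks[0].density >= peaks[1].density


class TestGaussianFit:
    def test_parameter_recovery(self, domain5):
        _, _, probes = domain5
        dist = gaussian_density(57.0, 46.0, 20.0, OrientationMap.regular(1.0))
        data = [(p, fk.forward_order_params(dist, p)) for p in probes]
        sols = fk.gaussian_fit(data, seed=1)
        best = sols[0]
        assert angular_distance((best.beta0, best.gamma0), (57.0, 46.0)) < 3.0
        assert best.dispersion == pytest.approx(20.0, abs=3.0)

    def test_sharp_distribution_recovers_small_sigma(self, domain5):
        _, _, probes = domain5
        dist = gaussian_density(70.0, -20.0, 1.0, OrientationMap.regular(0.5))
        data = [(p, fk.forward_order_params(dist, p)) for p in probes]
        sols = fk.gaussian_fit(data, seed=2)
        assert sols[0].dispersion <= 5.0

    def test_constructed_degeneracy_returns_two_solutions(self):
        probes = xz_probes()
        dist = gaussian_density(70.0, 40.0, 15.0, OrientationMap.regular(1.0))
        data = [(p, fk.forward_order_params(dist, p)) for p in probes]
        sols = fk.gaussian_fit(data, n_starts=12, seed=3)
        assert len(sols) >= 2
        gammas = sorted(round(s.gamma0) for s in sols[:2])
        assert gammas[0] == pytest.approx(-40, abs=3)
        assert gammas[1] == pytest.approx(40, abs=3)

    def test_recovery_bias_under_noise(self, domain5):
        """Bias < 2 degrees at noise sd 0.005 over 50 seeds."""
        _, _, probes = domain5
        truth = (57.0, 46.0)
        dist = gaussian_density(*truth, 20.0, OrientationMap.regular(1.0))
        clean = [fk.forward_order_params(dist, p) for p in probes]
        db, dg = [], []
        for seed in range(50):
            rng = np.random.default_rng(1000 + seed)
            data = []
            for p, ops in zip(probes, clean):
                data.append(
                    (
                        p,
                        fk.OrderParameters(
                            float(np.clip(ops.p2 + rng.normal(0, 0.005), -0.5, 1)),
                            float(np.clip(ops.p4 + rng.normal(0, 0.005), -3 / 7, 1)),
                        ),
                    )
                )
            best = fk.gaussian_fit(data, n_starts=4, seed=seed)[0]
            # solutions may come back on the dipole-mate branch; fold first
            c = fk.DomainOrientation(best.beta0, best.gamma0).canonical()
            db.append(c.beta - truth[0])
            dg.append(c.gamma - truth[1])
        assert abs(np.mean(db)) < 2.0
        assert abs(np.mean(dg)) < 2.0


class TestResolution:
    def test_single_probe_resolution_is_tens_of_degrees(self):
        r1 = fk.resolution_probe(1, noise_sd=0.01, n_reps=3, seed=4)
        assert r1["mean_fwhm_deg"] >= 15.0

    def test_resolution_improves_with_probe_count(self):
        r1 = fk.resolution_probe(1, noise_sd=0.01, n_reps=3, seed=4)
        r5 = fk.resolution_probe(5, noise_sd=0.01, n_reps=3, seed=4)
        assert r5["mean_fwhm_deg"] < r1["mean_fwhm_deg"]

    def test_noiseless_five_probe_peak_error_small(self):
        r = fk.resolution_probe(5, noise_sd=0.0, n_reps=1, seed=5)
        assert r["mean_peak_error_deg"] < 2.0
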