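import itertools

import numpy as np
import pytest

from pdbsi.core_io import ConfigurationError, DataError, GradientScheme, make_scheme
from pdbsi.model import (
    DBSISpectrum,
    DiffusionDictionary,
    build_dictionary,
    cellularity,
    dti_fit,
    estimate_noise_sigma,
    fit_volume,
    fit_voxel,
    predict_signal,
    rician_floor_correct,
)
from pdbsi.simulate import add_noise
from pdbsi.synthetic import synthetic_dmri_volume


def uniform_spectrum(dictionary, iso_weights):
    return DBSISpectrum(
        iso_fractions=np.asarray(iso_weights, dtype=float),
        aniso_fractions=np.zeros(dictionary.n_aniso),
    )


def point_spectrum(dictionary, adc, weight=1.0):
    f = np.zeros(dictionary.n_iso)
    f[np.argmin(np.abs(dictionary.iso_adcs - adc))] = weight
    return uniform_spectrum(dictionary, f)


class TestBuildDictionary:
    def test_window_edges_and_bounds_on_grid(self, dictionary):
        for v in (0.01, 0.6, 3.0):
            assert v in dictionary.iso_adcs

    def test_restricted_indices_contiguous(self, dictionary):
        idx = np.nonzero(dictionary.restricted_index)[0]
        assert np.array_equal(idx, np.arange(idx[0], idx[-1] + 1))
        # zero atom excluded, 0.6 included
        assert dictionary.iso_adcs[idx[0]] == pytest.approx(0.01)
        assert dictionary.iso_adcs[idx[-1]] == pytest.approx(0.6)

    def test_pure_isotropic_dictionary_valid(self):
        d = build_dictionary(aniso_spec=None)
        assert d.n_aniso == 0
        assert d.n_atoms == d.n_iso

    def test_window_outside_grid_rejected(self):
        with pytest.raises(ConfigurationError):
            build_dictionary(grid_max=0.5)

    def test_grid_size_contract(self):
        with pytest.raises(ConfigurationError):
            build_dictionary(grid_size=10)

    def test_without_zero_atom(self):
        d = build_dictionary(include_zero=False)
        assert d.iso_adcs[0] == pytest.approx(0.01)

    def test_aniso_ordering_enforced(self):
        with pytest.raises(ConfigurationError):
            DiffusionDictionary(
                iso_adcs=[0.01, 1.0, 3.0],
                aniso_atoms=[[0.5, 2.0, 1, 0, 0]],
            )


class TestPredictSignal:
    def test_single_isotropic_atom_closed_form(self, dictionary):
        scheme = GradientScheme([1000.0], [[1.0, 0, 0]])
        spec = point_spectrum(dictionary, 1.0)
        s = predict_signal(spec, dictionary, scheme)
        assert s[0] == pytest.approx(np.exp(-1.0), abs=1e-12)

    def test_b0_equals_fraction_sum(self, dictionary, rng):
        scheme = GradientScheme([0.0], [[0, 0, 0]])
        f = rng.uniform(0, 1, dictionary.n_iso)
        s = predict_signal(uniform_spectrum(dictionary, f), dictionary, scheme)
        assert s[0] == pytest.approx(f.sum(), rel=1e-12)

    def test_isotropic_aniso_atom_equivalence(self, exvivo_scheme):
        d_iso = build_dictionary()
        d_aniso = build_dictionary(aniso_spec=[[1.0, 1.0, 0.3, 0.5, 0.9]])
        s_iso = predict_signal(point_spectrum(d_iso, 1.0), d_iso, exvivo_scheme)
        spec = DBSISpectrum(
            iso_fractions=np.zeros(d_aniso.n_iso), aniso_fractions=np.array([1.0])
        )
        s_aniso = predict_signal(spec, d_aniso, exvivo_scheme)
        assert np.allclose(s_iso, s_aniso, atol=1e-12)

    def test_negative_fractions_rejected(self, dictionary, exvivo_scheme):
        spec = uniform_spectrum(dictionary, -np.ones(dictionary.n_iso))
        with pytest.raises(DataError):
            predict_signal(spec, dictionary, exvivo_scheme)


def brute_force_two_atom(signal, scheme, dictionary, n_frac=201):
    """Oracle: exhaustive two-atom search minimizing the LS residual."""
    A = dictionary.design_matrix(scheme)
    best = (np.inf, None, None, None)
    fracs = np.linspace(0, 1, n_frac)
    for i, j in itertools.combinations(range(A.shape[1]), 2):
        # closed-form LS for weight on a segment, then clamp to [0,1]
        d = A[:, i] - A[:, j]
        t = float(d @ (signal - A[:, j])) / float(d @ d)
        for tt in (np.clip(t, 0, 1), *fracs[:: n_frac // 20]):
            resid = np.linalg.norm(tt * A[:, i] + (1 - tt) * A[:, j] - signal)
            if resid < best[0]:
                best = (resid, i, j, tt)
    return best


class TestFitVoxel:
    def test_single_atom_self_consistency(self, exvivo_scheme, dictionary):
        b = exvivo_scheme.bvals * 1e-3
        y = np.exp(-b * 0.3)
        spec = fit_voxel(y, exvivo_scheme, dictionary)
        adcs = dictionary.iso_adcs
        k = int(np.argmin(np.abs(adcs - 0.3)))
        lo = adcs[max(k - 1, 0)] - 1e-12
        hi = adcs[min(k + 1, adcs.size - 1)] + 1e-12
        near = (adcs >= lo) & (adcs <= hi)
        assert spec.iso_fractions[near].sum() >= 0.99

    def test_two_atom_mixture_vs_oracle(self, exvivo_scheme, dictionary, two_pool_signal):
        """Frozen oracle: exhaustive two-atom search on the same dictionary."""
        y = two_pool_signal(exvivo_scheme, 0.3)
        resid_bf, i, j, t = brute_force_two_atom(y, exvivo_scheme, dictionary)
        # oracle must identify the planted atoms (0.3 and 2.0 are on-grid)
        planted = sorted(
            [np.argmin(np.abs(dictionary.iso_adcs - 0.3)),
             np.argmin(np.abs(dictionary.iso_adcs - 2.0))]
        )
        assert sorted([i, j]) == planted
        spec = fit_voxel(y, exvivo_scheme, dictionary)
        adcs = dictionary.iso_adcs
        near_03 = np.abs(np.log(np.maximum(adcs, 1e-9) / 0.3)) < 0.35
        near_20 = np.abs(np.log(np.maximum(adcs, 1e-9) / 2.0)) < 0.35
        assert abs(spec.iso_fractions[near_03].sum() - 0.3) < 0.05
        assert abs(spec.iso_fractions[near_20].sum() - 0.7) < 0.05

    def test_nnls_beats_exhaustive_two_atom(self, exvivo_scheme, two_pool_signal):
        """On ≤12-atom dictionaries the NNLS residual is ≤ the oracle's."""
        small = DiffusionDictionary(
            iso_adcs=np.geomspace(0.01, 3.0, 12), aniso_atoms=np.zeros((0, 5))
        )
        rng = np.random.default_rng(4)
        A = small.design_matrix(exvivo_scheme)
        for _ in range(10):
            i, j = rng.choice(12, 2, replace=False)
            w = rng.uniform(0.1, 0.9)
            y = w * A[:, i] + (1 - w) * A[:, j]
            spec = fit_voxel(y, exvivo_scheme, small, reg_lambda=0.0)
            resid_nnls = np.linalg.norm(A @ (spec.iso_fractions * spec.s0) - y)
            resid_bf, *_ = brute_force_two_atom(y, exvivo_scheme, small)
            assert resid_nnls <= resid_bf + 1e-8

    def test_b0_only_scheme_rejected(self, dictionary):
        scheme = GradientScheme(np.zeros(4), np.zeros((4, 3)))
        with pytest.raises(ConfigurationError):
            fit_voxel(np.ones(4), scheme, dictionary)

    def test_all_zero_signal_is_background(self, exvivo_scheme, dictionary):
        spec = fit_voxel(np.zeros(len(exvivo_scheme)), exvivo_scheme, dictionary)
        assert spec.background
        assert spec.total == 0.0
        assert cellularity(spec, dictionary) == 0.0

    def test_nonfinite_signal_rejected(self, exvivo_scheme, dictionary):
        y = np.ones(len(exvivo_scheme))
        y[3] = np.inf
        with pytest.raises(DataError):
            fit_voxel(y, exvivo_scheme, dictionary)

    def test_fractions_nonnegative_normalized(self, exvivo_scheme, dictionary, rng):
        for _ in range(5):
            y = np.abs(rng.uniform(0.1, 1.0)) * np.exp(
                -exvivo_scheme.bvals * 1e-3 * rng.uniform(0.1, 2.5)
            )
            spec = fit_voxel(y, exvivo_scheme, dictionary)
            assert np.all(spec.iso_fractions >= 0)
            assert spec.total == pytest.approx(1.0, abs=1e-9)


class TestForwardInverseConsistency:
    @pytest.mark.parametrize("seed", range(5))
    def test_on_grid_spectrum_roundtrip(self, exvivo_scheme, dictionary, seed):
        """Restricted fraction survives predict → fit within 0.02."""
        rng = np.random.default_rng(seed)
        f = np.zeros(dictionary.n_iso)
        support = rng.choice(np.arange(1, dictionary.n_iso), 3, replace=False)
        f[support] = rng.dirichlet(np.ones(3))
        spec = DBSISpectrum(iso_fractions=f, aniso_fractions=np.zeros(0))
        y = predict_signal(spec, dictionary, exvivo_scheme)
        refit = fit_voxel(y, exvivo_scheme, dictionary)
        truth = cellularity(spec, dictionary)
        assert abs(cellularity(refit, dictionary) - truth) < 0.02

    def test_monotone_in_planted_fraction(self, exvivo_scheme, dictionary, two_pool_signal):
        estimates = [
            cellularity(
                fit_voxel(two_pool_signal(exvivo_scheme, f), exvivo_scheme, dictionary),
                dictionary,
            )
            for f in np.arange(0.0, 0.51, 0.1)
        ]
        assert np.all(np.diff(estimates) > 0)


class TestCellularity:
    def test_all_restricted(self, dictionary, exvivo_scheme):
        spec = fit_voxel(
            np.exp(-exvivo_scheme.bvals * 1e-3 * 0.3), exvivo_scheme, dictionary
        )
        assert cellularity(spec, dictionary) == pytest.approx(1.0, abs=1e-6)

    def test_all_free(self, dictionary, exvivo_scheme):
        spec = fit_voxel(
            np.exp(-exvivo_scheme.bvals * 1e-3 * 2.0), exvivo_scheme, dictionary
        )
        assert cellularity(spec, dictionary) == pytest.approx(0.0, abs=1e-6)

    def test_mass_at_window_edge_counted(self, dictionary):
        spec = point_spectrum(dictionary, 0.6)
        assert dictionary.iso_adcs[np.argmax(spec.iso_fractions)] == 0.6
        assert cellularity(spec, dictionary) == pytest.approx(1.0)

    def test_bounded(self, dictionary, rng):
        for _ in range(20):
            f = rng.uniform(0, 1, dictionary.n_iso)
            c = cellularity(uniform_spectrum(dictionary, f), dictionary)
            assert 0.0 <= c <= 1.0


class TestDTI:
    def test_isotropic_closed_form(self, exvivo_scheme):
        y = np.exp(-exvivo_scheme.bvals * 1e-3 * 1.0)
        _, adc = dti_fit(y, exvivo_scheme)
        assert adc == pytest.approx(1.0, abs=1e-6)

    def test_prolate_tensor_adc(self, exvivo_scheme):
        lpar, lperp = 2.0, 0.5
        b = exvivo_scheme.bvals * 1e-3
        cos2 = (exvivo_scheme.bvecs @ np.array([0, 0, 1.0])) ** 2
        y = np.exp(-b * (lperp + (lpar - lperp) * cos2))
        _, adc = dti_fit(y, exvivo_scheme)
        assert adc == pytest.approx((lpar + 2 * lperp) / 3.0, abs=1e-9)

    def test_b0_only_rejected(self):
        scheme = GradientScheme(np.zeros(8), np.zeros((8, 3)))
        with pytest.raises(ConfigurationError):
            dti_fit(np.ones(8), scheme)

    def test_nonpositive_clamped_with_warning(self, exvivo_scheme):
        y = np.exp(-exvivo_scheme.bvals * 1e-3)
        y[-1] = -0.01
        with pytest.warns(UserWarning):
            dti_fit(y, exvivo_scheme)


class TestNoiseSigma:
    def test_estimate_matches_planted(self, exvivo_scheme, rng):
        y = np.exp(-exvivo_scheme.bvals * 1e-3 * 1.5)
        noisy = np.vstack(
            [add_noise(y, 25.0, seed=i) for i in range(300)]
        )
        sigma = estimate_noise_sigma(noisy, exvivo_scheme)
        assert sigma == pytest.approx(0.04, rel=0.1)

    def test_floor_correct_identity_at_zero_sigma(self, rng):
        y = rng.uniform(0.1, 1.0, 30)
        assert np.allclose(rician_floor_correct(y, 0.0), y)


class TestFitVolume:
    def test_constant_two_pool_volume(self, exvivo_scheme, dictionary, two_pool_signal):
        vol = synthetic_dmri_volume(0.3, exvivo_scheme, shape=(4, 4, 1))
        maps = fit_volume(vol, dictionary)
        assert maps["cellularity"].values.shape == (4, 4, 1)
        assert np.allclose(maps["cellularity"].values, 0.3, atol=0.02)

    def test_background_voxels_zero(self, exvivo_scheme, dictionary):
        vol = synthetic_dmri_volume(0.3, exvivo_scheme, shape=(3, 3, 1))
        vol.mask[0, 0, 0] = False
        maps = fit_volume(vol, dictionary)
        assert maps["cellularity"].values[0, 0, 0] == 0.0

    def test_empty_mask_rejected(self, exvivo_scheme, dictionary):
        vol = synthetic_dmri_volume(0.3, exvivo_scheme, shape=(2, 2, 1))
        vol.mask[:] = False
        with pytest.raises(DataError):
            fit_volume(vol, dictionary)

    def test_noisy_volume_mae(self, exvivo_scheme):
        """Rician noise at b0 SNR 37 on 200 voxels: MAE < 0.05.

        Pilot-calibrated configuration: floor correction + no constant atom
        + reg 3e-3 (raw magnitudes with the 0 atom give MAE ≈ 0.064).
        """
        vol = synthetic_dmri_volume(0.3, exvivo_scheme, shape=(20, 10, 1), snr=37.0, seed=5)
        d = build_dictionary(include_zero=False)
        maps = fit_volume(vol, d, reg_lambda=3e-3, floor_correction=True)
        mae = np.abs(maps["cellularity"].values - 0.3).mean()
        assert mae < 0.05
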