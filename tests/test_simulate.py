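import numpy as np
import pytest

from pdbsi.core_io import ConfigurationError, GradientScheme, make_scheme
from pdbsi.geometry import (
    LABEL_EXTRACELLULAR,
    LABEL_PRISM,
    LABEL_SPHERE,
    LABEL_TUBE,
    Geometry,
    GeometryParams,
    build_geometry,
)
from pdbsi.simulate import (
    WalkerEnsemble,
    add_noise,
    gpd_sphere_adc,
    simulate_walkers,
    sphere_adc,
    suggest_dt,
    synthesize_signal,
)


def single_sphere_geometry(radius=8.0, box=20.0):
    return Geometry(
        field_size=(box, box, box),
        sphere_centers=np.array([[box / 2, box / 2, box / 2]]),
        sphere_radii=np.array([radius]),
        prism_centers=np.zeros((0, 2)),
        prism_circumradii=np.zeros(0),
        tube_centers=np.zeros((0, 2)),
        tube_inner_radii=np.zeros(0),
        tube_outer_radii=np.zeros(0),
    )


@pytest.fixture(scope="module")
def region_ensemble():
    geom = build_geometry(
        np.full((50, 50), 0.03), (0, 0, 250.0, 250.0), GeometryParams(), seed=5
    )
    ens = simulate_walkers(geom, 600, 23.0, 0.025, 2.0, seed=6)
    return geom, ens


class TestWalk:
    def test_free_diffusion_step_variance(self):
        """Single walker, 1e6 steps: per-axis increment variance / (2 dt) = D0."""
        ens = simulate_walkers(None, 1, 1e6 * 0.005, 0.005, d0=2.0, seed=0)
        steps = np.diff(ens.positions[0].astype(np.float64), axis=0)
        d_hat = steps.var(axis=0) / (2 * 0.005)
        assert np.allclose(d_hat, 2.0, atol=0.05)

    def test_sphere_confinement_every_step(self):
        geom = single_sphere_geometry(8.0)
        ens = simulate_walkers(
            geom, 50, 23.0, 0.005, 2.0, seed=1, compartment=LABEL_SPHERE
        )
        center = geom.sphere_centers[0]
        dist = np.linalg.norm(
            ens.positions.astype(np.float64) - center, axis=-1
        )
        assert dist.max() <= 8.0 + 1e-5

    def test_compartment_confinement_region(self, region_ensemble):
        """No walker ever violates its compartment (checked every step)."""
        geom, ens = region_ensemble
        pos = ens.positions.astype(np.float64)
        # sphere walkers: confined to the sphere that contains them at t=0
        for w in np.nonzero(ens.labels == LABEL_SPHERE)[0]:
            d0 = np.linalg.norm(geom.sphere_centers - pos[w, 0], axis=1)
            k = int(np.argmin(d0))
            d = np.linalg.norm(pos[w] - geom.sphere_centers[k], axis=1)
            assert d.max() <= geom.sphere_radii[k] + 1e-4
        # tube-wall walkers: inside their annulus at every step
        for w in np.nonzero(ens.labels == LABEL_TUBE)[0]:
            d0 = np.hypot(*(pos[w, 0, :2] - geom.tube_centers).T)
            (inside,) = np.nonzero(
                (d0 >= geom.tube_inner_radii - 1e-6)
                & (d0 <= geom.tube_outer_radii + 1e-6)
            )
            assert inside.size == 1
            k = int(inside[0])
            d = np.hypot(
                pos[w, :, 0] - geom.tube_centers[k, 0],
                pos[w, :, 1] - geom.tube_centers[k, 1],
            )
            assert d.min() >= geom.tube_inner_radii[k] - 1e-4
            assert d.max() <= geom.tube_outer_radii[k] + 1e-4
        # extracellular walkers: never inside any sphere (chunked cdist)
        from scipy.spatial import cKDTree

        tree = cKDTree(geom.sphere_centers)
        ec = pos[ens.labels == LABEL_EXTRACELLULAR][:, ::7].reshape(-1, 3)
        dist, idx = tree.query(ec, k=3)
        assert np.all(dist >= geom.sphere_radii[idx] - 1e-4)

    def test_labels_never_change_by_construction(self, region_ensemble):
        _, ens = region_ensemble
        assert ens.labels.shape == (ens.n_walkers,)

    def test_seeding_proportional_to_volume(self):
        geom = build_geometry(
            np.full((50, 50), 0.05), (0, 0, 250.0, 250.0), GeometryParams(), seed=2
        )
        ens = simulate_walkers(geom, 4000, 1.0, 0.025, 2.0, seed=3)
        vols = geom.compartment_volumes()
        counts = np.bincount(ens.labels, minlength=4)
        assert np.allclose(counts / 4000, vols / vols.sum(), atol=0.001)

    def test_same_seed_identical(self):
        geom = single_sphere_geometry(6.0)
        a = simulate_walkers(geom, 20, 5.0, 0.005, 2.0, seed=11)
        b = simulate_walkers(geom, 20, 5.0, 0.005, 2.0, seed=11)
        assert np.array_equal(a.positions, b.positions)

    def test_dt_too_coarse_rejected(self):
        geom = single_sphere_geometry(4.0)
        with pytest.raises(ConfigurationError, match="dt"):
            simulate_walkers(geom, 10, 5.0, 0.2, 2.0, seed=0)
        assert suggest_dt(4.0, 2.0) == pytest.approx(1.0 / 12.0)

    def test_msd_helper_shape(self):
        ens = simulate_walkers(None, 7, 1.0, 0.01, 2.0, seed=4)
        assert ens.msd().shape == (101, 3)


class TestSynthesizeSignal:
    def test_free_diffusion_matches_closed_form(self, exvivo_scheme):
        ens = simulate_walkers(None, 20000, 23.0, 0.025, 2.0, seed=8)
        sig = synthesize_signal(ens, exvivo_scheme)
        expected = np.exp(-exvivo_scheme.bvals * 1e-3 * 2.0)
        # 3 standard errors of the phase-ensemble mean
        se = np.sqrt((1 - expected**2) / (2 * ens.n_walkers)) + 1e-4
        assert np.all(np.abs(sig - expected) < 3 * se + 0.006)

    def test_b0_exactly_one(self, exvivo_scheme):
        ens = simulate_walkers(None, 100, 23.0, 0.025, 2.0, seed=9)
        sig = synthesize_signal(ens, exvivo_scheme)
        assert np.all(sig[exvivo_scheme.bvals == 0] == 1.0)

    def test_signal_bounded_and_decreasing_for_sphere(self, exvivo_scheme):
        geom = single_sphere_geometry(8.0)
        ens = simulate_walkers(
            geom, 4000, 23.0, 0.005, 2.0, seed=10, compartment=LABEL_SPHERE
        )
        sig = synthesize_signal(ens, exvivo_scheme)
        assert np.all((sig >= 0) & (sig <= 1))
        order = np.argsort(exvivo_scheme.bvals)
        s = sig[order]
        # non-increasing in b within 3 MC standard errors
        se = np.sqrt((1 - s**2) / (2 * ens.n_walkers))
        tol = 3 * np.hypot(se[1:], se[:-1]) + 1e-9
        assert np.all(np.diff(s) < tol)

    def test_restriction_lowers_adc(self, exvivo_scheme):
        adc = sphere_adc(8.0, 2.0, exvivo_scheme, n_walkers=3000, dt=0.01, seed=12)
        assert adc < 2.0

    def test_duration_too_short_rejected(self, exvivo_scheme):
        ens = simulate_walkers(None, 10, 5.0, 0.025, 2.0, seed=0)
        with pytest.raises(ConfigurationError):
            synthesize_signal(ens, exvivo_scheme)

    def test_missing_timing_rejected(self):
        ens = simulate_walkers(None, 10, 25.0, 0.025, 2.0, seed=0)
        scheme = GradientScheme([0.0, 1000.0], [[0, 0, 0], [1, 0, 0]])
        with pytest.raises(ConfigurationError):
            synthesize_signal(ens, scheme)

    def test_identical_seeds_identical_signals(self, exvivo_scheme):
        geom = single_sphere_geometry(6.0)
        sig = [
            synthesize_signal(
                simulate_walkers(geom, 500, 23.0, 0.01, 2.0, seed=13), exvivo_scheme
            )
            for _ in range(2)
        ]
        assert np.array_equal(sig[0], sig[1])


class TestAddNoise:
    def test_infinite_snr_identity(self, rng):
        y = rng.uniform(0, 1, 50)
        assert np.array_equal(add_noise(y, np.inf, seed=0), y)

    def test_rician_floor_expectation(self):
        """Zero signal, σ=1: E|n1+i n2| = √(π/2)."""
        out = add_noise(np.zeros(10**6), 1.0, seed=1, s0=1.0)
        expected = np.sqrt(np.pi / 2)
        se = np.sqrt((2 - np.pi / 2) / 10**6)
        assert abs(out.mean() - expected) < 3 * se

    def test_b0_snr_definition(self):
        out = add_noise(np.ones(10**5), 25.0, seed=2)
        assert out.std() == pytest.approx(0.04, rel=0.02)

    def test_deterministic(self):
        y = np.linspace(0, 1, 20)
        assert np.array_equal(add_noise(y, 25, seed=3), add_noise(y, 25, seed=3))

    def test_invalid_snr(self):
        with pytest.raises(ConfigurationError):
            add_noise(np.ones(3), 0.0)


class TestSphereADCOracle:
    def test_gpd_short_time_limit(self):
        assert gpd_sphere_adc(200.0, 2.0, 16.0, 7.0, n_roots=400) == pytest.approx(
            2.0, rel=0.05
        )

    def test_gpd_small_radius_limit(self):
        assert gpd_sphere_adc(0.3, 2.0, 16.0, 7.0) < 1e-4

    def test_gpd_monotone_in_radius(self):
        vals = [gpd_sphere_adc(r, 2.0, 16.0, 7.0) for r in (3, 4, 5, 6, 7, 8)]
        assert np.all(np.diff(vals) > 0)

    def test_gpd_invalid_inputs(self):
        with pytest.raises(ConfigurationError):
            gpd_sphere_adc(-1.0, 2.0, 16.0, 7.0)

    @pytest.mark.parametrize("radius,dt", [(4.0, 0.004), (6.0, 0.005), (8.0, 0.008)])
    def test_mc_matches_gpd_within_10pct(self, exvivo_scheme, radius, dt):
        mc = sphere_adc(radius, 2.0, exvivo_scheme, n_walkers=4000, dt=dt, seed=21)
        gpd = gpd_sphere_adc(radius, 2.0, 16.0, 7.0)
        assert mc == pytest.approx(gpd, rel=0.10)


class TestPerCompartmentD0:
    def test_step_variance_follows_label_override(self):
        """Inside the overridden compartment, steps have variance 2·D0'·dt."""
        geom = single_sphere_geometry(8.0)
        dt = 0.002
        ens = simulate_walkers(
            geom,
            400,
            0.2,
            dt,
            2.0,
            seed=14,
            compartment=LABEL_SPHERE,
            d0_by_label={LABEL_SPHERE: 1.0},
        )
        steps = np.diff(ens.positions.astype(np.float64), axis=1)
        # early steps, walkers seeded well inside: reflections negligible
        var = steps.var()
        assert var == pytest.approx(2 * 1.0 * dt, rel=0.05)

    def test_big_sphere_adc_tracks_intracellular_d0(self, exvivo_scheme):
        """At r=8 µm (weak-restriction side) the GPD oracle predicts a lower
        ADC for lower intracellular D0; the MC signal must agree."""
        assert gpd_sphere_adc(8.0, 1.0, 16.0, 7.0) < gpd_sphere_adc(8.0, 2.0, 16.0, 7.0)
        geom = single_sphere_geometry(8.0)
        sigs = {}
        for d0i in (2.0, 1.0):
            ens = simulate_walkers(
                geom,
                4000,
                23.0,
                0.008,
                2.0,
                seed=14,
                compartment=LABEL_SPHERE,
                d0_by_label={LABEL_SPHERE: d0i},
            )
            sigs[d0i] = synthesize_signal(ens, exvivo_scheme)
        dw = exvivo_scheme.bvals > 2000
        assert sigs[1.0][dw].mean() > sigs[2.0][dw].mean()
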