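"""Synthetic inputs: stain-density maps, simulated validation sets, planted
diffusion volumes, and longitudinal two-group cohorts."""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import scipy.ndimage
import scipy.stats

from .core_io import ConfigurationError, DiffusionVolume, GradientScheme, ScalarMap
from .geometry import GeometryParams, build_geometry, tile_regions
from .model import B_SCALE
from .simulate import add_noise, simulate_walkers, synthesize_signal

__all__ = [
    "DensityMap",
    "CohortSpec",
    "ValidationSet",
    "generate_density_map",
    "generate_validation_set",
    "generate_cohort",
    "synthetic_dmri_volume",
    "DEFAULT_REGION_MM",
]

DEFAULT_REGION_MM = 0.25


@dataclasses.dataclass
class DensityMap:
    """2D positive-stain area ratio map; pixels in µm, field in mm."""

    values: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ConfigurationError("density map must be 2D")
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise ConfigurationError("density values must lie in [0, 1]")
        nx, ny = self.region_grid_shape(DEFAULT_REGION_MM)
        del nx, ny  # raises if the field does not tile

    @property
    def field_size_mm(self) -> tuple[float, float]:
        ny, nx = self.values.shape
        return (nx * self.pixel_size / 1000.0, ny * self.pixel_size / 1000.0)

    def region_grid_shape(self, region_mm: float = DEFAULT_REGION_MM):
        px_per_region = region_mm * 1000.0 / self.pixel_size
        if abs(px_per_region - round(px_per_region)) > 1e-9:
            raise ConfigurationError(
                "region size is not an integer number of pixels"
            )
        ny, nx = self.values.shape
        p = int(round(px_per_region))
        if ny % p or nx % p:
            raise ConfigurationError(
                f"{self.field_size_mm} mm field does not tile into "
                f"{region_mm} mm regions"
            )
        return nx // p, ny // p

    def region_patch(self, box_um, region_mm: float = DEFAULT_REGION_MM):
        x0, y0, x1, y1 = box_um
        ps = self.pixel_size
        return self.values[
            int(round(y0 / ps)) : int(round(y1 / ps)),
            int(round(x0 / ps)) : int(round(x1 / ps)),
        ]

    def to_csv(self, path) -> None:
        np.savetxt(path, self.values, delimiter=",", fmt="%.6g")


def generate_density_map(
    field_size_mm: tuple[float, float] = (5.0, 5.0),
    mean_density: float = 0.05,
    clump_scale: float = 150.0,
    seed: int = 0,
    pixel_size: float = 5.0,
    lognormal_sigma: float = 0.7,
    clip_max: float = 1.0,
) -> DensityMap:
    """Spatially correlated lognormal random density field.

    A Gaussian random field smoothed to correlation length ``clump_scale``
    (µm) is exponentiated with a -σ²/2 offset so the expected value equals
    ``mean_density``; values are clipped to [0, clip_max] (a cap below 1
    keeps sphere packing feasible downstream).  Deterministic per seed.
    """
    if not (0 < mean_density <= 0.3):
        raise ConfigurationError("mean_density must lie in (0, 0.3]")
    rng = np.random.default_rng(seed)
    shape = (
        int(round(field_size_mm[1] * 1000.0 / pixel_size)),
        int(round(field_size_mm[0] * 1000.0 / pixel_size)),
    )
    g = rng.standard_normal(shape)
    if clump_scale > 0:
        g = scipy.ndimage.gaussian_filter(g, sigma=clump_scale / pixel_size)
        sd = g.std()
        if sd > 0:
            g /= sd
    values = mean_density * np.exp(
        lognormal_sigma * g - lognormal_sigma**2 / 2.0
    )
    return DensityMap(
        values=np.clip(values, 0.0, clip_max), pixel_size=pixel_size
    )


@dataclasses.dataclass
class ValidationSet:
    """Ground truth and signals for the simulation validation workflow."""

    truth: pd.DataFrame  # columns: region_id, true_density
    noiseless: np.ndarray  # (n_regions, n_measurements)
    noisy: dict[float, np.ndarray]
    scheme: GradientScheme


def generate_validation_set(
    density_map: DensityMap,
    scheme: GradientScheme,
    snr_list=(25.0, 50.0, 75.0),
    seed: int = 0,
    params: GeometryParams | None = None,
    n_walkers: int = 2500,
    dt: float = 0.025,
    d0: float = 2.0,
    region_mm: float = DEFAULT_REGION_MM,
    max_regions: int | None = None,
    d0_by_label: dict[int, float] | None = None,
    progress=None,
) -> ValidationSet:
    """Per region: substrate, random walk, PGSE synthesis, Rician noise.

    One noiseless signal per region; each SNR gets its own noise seeds.
    Ground truth per region is the exact placed immune volume fraction.
    ``max_regions`` truncates the tiling for smoke runs.
    """
    if any(s <= 0 for s in snr_list):
        raise ConfigurationError("snr values must be positive")
    params = params or GeometryParams()
    boxes = tile_regions(density_map.field_size_mm, region_mm)
    if max_regions is not None:
        boxes = boxes[:max_regions]
    duration = scheme.big_delta + scheme.small_delta
    seeds = np.random.SeedSequence(seed).spawn(len(boxes))
    rows = []
    signals = []
    for i, box in enumerate(boxes):
        child = seeds[i].generate_state(2)
        patch = density_map.region_patch(box, region_mm)
        geom = build_geometry(patch, box, params, seed=int(child[0]))
        ens = simulate_walkers(
            geom,
            n_walkers,
            duration,
            dt,
            d0,
            seed=int(child[1]),
            d0_by_label=d0_by_label,
        )
        signals.append(synthesize_signal(ens, scheme))
        rows.append(
            {"region_id": i, "true_density": geom.immune_volume_fraction}
        )
        if progress is not None:
            progress(i, len(boxes))
    noiseless = np.vstack(signals)
    noisy = {}
    for j, snr in enumerate(snr_list):
        noise_seed = np.random.SeedSequence([seed, 7_000_003 + j])
        child_states = noise_seed.generate_state(len(boxes))
        noisy[float(snr)] = np.vstack(
            [
                add_noise(noiseless[i], snr, seed=int(child_states[i]))
                for i in range(len(boxes))
            ]
        )
    return ValidationSet(
        truth=pd.DataFrame(rows), noiseless=noiseless, noisy=noisy, scheme=scheme
    )


# ---------------------------------------------------------------------------
# planted diffusion volumes


def synthetic_dmri_volume(
    cellularity: np.ndarray | float,
    scheme: GradientScheme,
    shape: tuple[int, int, int] | None = None,
    restricted_adc: float = 0.3,
    free_adc: float = 2.0,
    snr: float = np.inf,
    s0: float = 1000.0,
    seed: int = 0,
    voxel_size=(3.0, 3.0, 3.0),
) -> DiffusionVolume:
    """4D volume whose voxels mix a restricted and a free isotropic pool.

    Each voxel's signal is ``s0 · (c·e^{-b·D_r} + (1-c)·e^{-b·D_f})`` with
    c the planted cellularity, plus optional Rician noise at the given b0
    SNR.  Useful as a fit target with known ground truth.
    """
    if np.isscalar(cellularity):
        if shape is None:
            shape = (4, 4, 1)
        cell = np.full(shape, float(cellularity))
    else:
        cell = np.asarray(cellularity, dtype=float)
    if np.any(cell < 0) or np.any(cell > 1):
        raise ConfigurationError("cellularity must lie in [0, 1]")
    b = scheme.bvals * B_SCALE
    decay_r = np.exp(-b * restricted_adc)
    decay_f = np.exp(-b * free_adc)
    signal = s0 * (
        cell[..., None] * decay_r + (1.0 - cell[..., None]) * decay_f
    )
    if np.isfinite(snr):
        rng_states = np.random.SeedSequence(seed).generate_state(cell.size)
        flat = signal.reshape(-1, len(scheme))
        for i in range(flat.shape[0]):
            flat[i] = add_noise(flat[i], snr, seed=int(rng_states[i]), s0=s0)
        signal = flat.reshape(signal.shape)
    return DiffusionVolume(
        signal=signal,
        scheme=scheme,
        mask=np.ones(cell.shape, dtype=bool),
        voxel_size=voxel_size,
    )


# ---------------------------------------------------------------------------
# longitudinal cohort

GESTATION_VISITS = (12.0, 20.0, 32.0, 36.0)


def _interp_profile(visits, early: float, late: float) -> tuple[float, ...]:
    v = np.asarray(visits, dtype=float)
    return tuple(np.interp(v, [v[0], v[-1]], [early, late]))


@dataclasses.dataclass(frozen=True)
class CohortSpec:
    """Per-group, per-visit truncated-normal cellularity parameters.

    Defaults follow the reported group summaries: non-inflammation
    2.8% ± 0.7% early rising to 4.75% ± 0.9% late; inflammation
    4.8% ± 0.65% early rising to 7.25% ± 2.13% late, with visits at about
    12, 20, 32, and 36 weeks' gestation, n = 70 vs 12.
    """

    visits: tuple[float, ...] = GESTATION_VISITS
    group_sizes: tuple[int, int] = (70, 12)
    group_names: tuple[str, str] = ("noninflammation", "inflammation")
    means_a: tuple[float, ...] = _interp_profile(GESTATION_VISITS, 0.028, 0.0475)
    sds_a: tuple[float, ...] = _interp_profile(GESTATION_VISITS, 0.007, 0.009)
    means_b: tuple[float, ...] = _interp_profile(GESTATION_VISITS, 0.048, 0.0725)
    sds_b: tuple[float, ...] = _interp_profile(GESTATION_VISITS, 0.0065, 0.0213)
    seed: int = 0

    def __post_init__(self) -> None:
        if np.any(np.diff(self.visits) <= 0):
            raise ConfigurationError("visits must be increasing")
        for means, sds in ((self.means_a, self.sds_a), (self.means_b, self.sds_b)):
            if len(means) != len(self.visits) or len(sds) != len(self.visits):
                raise ConfigurationError("per-visit parameter length mismatch")
            if not all(0 < m < 1 for m in means):
                raise ConfigurationError("means must lie in (0, 1)")
            if not all(s >= 0 for s in sds):
                raise ConfigurationError("s.d. must be non-negative")
        if min(self.group_sizes) < 1:
            raise ConfigurationError("group sizes must be ≥ 1")

    def group_params(self, name: str):
        if name == self.group_names[0]:
            return self.means_a, self.sds_a
        if name == self.group_names[1]:
            return self.means_b, self.sds_b
        raise ConfigurationError(f"unknown group {name!r}")


def _truncnorm_draw(mean, sd, size, rng):
    if sd == 0:
        return np.full(size, mean)
    a, b = (0.0 - mean) / sd, (1.0 - mean) / sd
    return scipy.stats.truncnorm.rvs(
        a, b, loc=mean, scale=sd, size=size, random_state=rng
    )


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Longitudinal table (patient_id, group, visit_week, mean_cellularity).

    Patient visit values are independent truncated-normal draws from the
    group/visit parameters (truncation to (0, 1) keeps means unbiased near
    zero).  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    pid = 0
    for name, size in zip(spec.group_names, spec.group_sizes):
        means, sds = spec.group_params(name)
        for _ in range(size):
            pid += 1
            for week, mean, sd in zip(spec.visits, means, sds):
                rows.append(
                    {
                        "patient_id": f"pt{pid:03d}",
                        "group": name,
                        "visit_week": week,
                        "mean_cellularity": float(
                            _truncnorm_draw(mean, sd, 1, rng)[0]
                        ),
                    }
                )
    return pd.DataFrame(rows)


def cellularity_volume(
    patient_mean: float,
    shape: tuple[int, int, int] = (12, 12, 4),
    spatial_sd: float = 0.01,
    seed: int = 0,
    voxel_size=(3.0, 3.0, 3.0),
) -> ScalarMap:
    """Voxelized cellularity map with truncated spatial noise about a mean.

    The within-placenta covariance is an invention of this generator (no
    reference structure exists); it is plain i.i.d. voxel noise.
    """
    rng = np.random.default_rng(seed)
    values = _truncnorm_draw(patient_mean, spatial_sd, int(np.prod(shape)), rng)
    return ScalarMap(
        values=values.reshape(shape),
        metric_name="cellularity",
        voxel_size=voxel_size,
    )
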