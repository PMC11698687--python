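"""Imaging volumes, gradient tables, and the acquisition-scheme data model.

Diffusivity convention: all diffusivities are in µm²/ms (= 1e-3 mm²/s);
b-values are in s/mm², so the exponent of a monoexponential decay is
``b * D * 1e-3``.  Gradient tables are FSL-style ``bval``/``bvec`` text
files (one row of b-values; three rows of direction components).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "B0_THRESHOLD",
    "GradientScheme",
    "DiffusionVolume",
    "ScalarMap",
    "load_dmri",
    "save_map",
    "make_scheme",
    "FormatError",
    "DataError",
    "ConfigurationError",
]

#: measurements with b below this (s/mm²) count as b0 for normalization
B0_THRESHOLD = 50.0


class FormatError(ValueError):
    """Input file layout inconsistent (e.g. frame count vs gradient table)."""


class DataError(ValueError):
    """Input values unusable (non-finite signal, empty mask, ...)."""


class ConfigurationError(ValueError):
    """Parameters outside the supported envelope."""


@dataclasses.dataclass(frozen=True)
class GradientScheme:
    """Per-measurement b-value, unit direction, and PGSE timing.

    Parameters
    ----------
    bvals : (N,) array
        Diffusion weightings in s/mm².
    bvecs : (N, 3) array
        Gradient directions; unit norm wherever ``bvals > 0``.
    big_delta, small_delta : float or None
        Gradient lobe separation Δ and duration δ in ms.  ``None`` when the
        timing is unknown (timing is only needed by the simulator).
    """

    bvals: np.ndarray
    bvecs: np.ndarray
    big_delta: float | None = None
    small_delta: float | None = None

    def __post_init__(self) -> None:
        bvals = np.asarray(self.bvals, dtype=float).ravel()
        bvecs = np.asarray(self.bvecs, dtype=float)
        if bvecs.ndim != 2 or bvecs.shape[1] != 3:
            raise FormatError(f"bvecs must be (N, 3), got {bvecs.shape}")
        if bvals.shape[0] != bvecs.shape[0]:
            raise FormatError(
                f"{bvals.shape[0]} b-values vs {bvecs.shape[0]} directions"
            )
        if not np.all(np.isfinite(bvals)) or not np.all(np.isfinite(bvecs)):
            raise DataError("non-finite entries in gradient table")
        if np.any(bvals < 0):
            raise DataError("negative b-values")
        bvecs = bvecs.copy()
        dw = bvals > 0
        norms = np.linalg.norm(bvecs[dw], axis=1)
        if np.any(norms <= 0):
            raise DataError("zero-norm direction with b > 0")
        bvecs[dw] /= norms[:, None]
        if self.big_delta is not None or self.small_delta is not None:
            if self.big_delta is None or self.small_delta is None:
                raise ConfigurationError("set both big_delta and small_delta")
            if not (self.small_delta > 0 and self.big_delta > self.small_delta / 3.0):
                raise ConfigurationError(
                    "need big_delta > small_delta/3 > 0 for a positive "
                    "effective diffusion time"
                )
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)
        self.bvals.setflags(write=False)
        self.bvecs.setflags(write=False)

    def __len__(self) -> int:
        return self.bvals.shape[0]

    @property
    def n_b0(self) -> int:
        return int(np.sum(self.bvals == 0))

    @property
    def b0_mask(self) -> np.ndarray:
        """Measurements treated as b0 for normalization (b < 50 s/mm²)."""
        return self.bvals < B0_THRESHOLD

    @property
    def effective_diffusion_time(self) -> float:
        """Δ − δ/3 in ms."""
        if self.big_delta is None:
            raise ConfigurationError("scheme has no PGSE timing")
        return self.big_delta - self.small_delta / 3.0

    def save(self, bval_path, bvec_path) -> None:
        np.savetxt(bval_path, self.bvals[None, :], fmt="%.6g")
        np.savetxt(bvec_path, self.bvecs.T, fmt="%.8f")

    @classmethod
    def from_files(
        cls,
        bval_path,
        bvec_path,
        big_delta: float | None = None,
        small_delta: float | None = None,
    ) -> "GradientScheme":
        bvals = np.loadtxt(bval_path).ravel()
        bvecs = np.loadtxt(bvec_path)
        if bvecs.ndim != 2:
            raise FormatError(f"bvec file {bvec_path} is not a 2D table")
        if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
            bvecs = bvecs.T
        elif bvecs.shape[1] != 3:
            raise FormatError(f"bvec table shape {bvecs.shape} has no 3-axis")
        return cls(bvals, bvecs, big_delta=big_delta, small_delta=small_delta)


@dataclasses.dataclass
class DiffusionVolume:
    """A 4D diffusion-weighted volume with its scheme and mask."""

    signal: np.ndarray
    scheme: GradientScheme
    mask: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 4:
            raise FormatError(f"signal must be 4D, got {self.signal.ndim}D")
        if self.signal.shape[3] != len(self.scheme):
            raise FormatError(
                f"{self.signal.shape[3]} frames vs "
                f"{len(self.scheme)} scheme entries"
            )
        if not np.all(np.isfinite(self.signal)):
            raise DataError("non-finite signal values")
        if self.mask is None:
            self.mask = np.ones(self.signal.shape[:3], dtype=bool)
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.shape != self.signal.shape[:3]:
            raise FormatError(
                f"mask shape {self.mask.shape} vs image {self.signal.shape[:3]}"
            )
        b0 = self.signal[..., self.scheme.b0_mask].mean(axis=-1)
        if self.mask.any() and not np.all(b0[self.mask] > 0):
            raise DataError("masked voxels with non-positive mean b0 signal")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.signal.shape[:3]


@dataclasses.dataclass
class ScalarMap:
    """A 3D scalar metric map (cellularity, ADC, ...)."""

    values: np.ndarray
    metric_name: str
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise FormatError("scalar map must be 3D")


def _affine_from_voxel_size(voxel_size) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size
    return aff


def load_dmri(
    image_path,
    bval_path,
    bvec_path,
    mask_path=None,
    big_delta: float | None = None,
    small_delta: float | None = None,
) -> DiffusionVolume:
    """Load a 4D NIfTI with its FSL gradient table into a validated volume."""
    img = nib.load(str(image_path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise FormatError(f"{image_path}: expected 4D image, got {data.ndim}D")
    scheme = GradientScheme.from_files(
        bval_path, bvec_path, big_delta=big_delta, small_delta=small_delta
    )
    if data.shape[3] != len(scheme):
        raise FormatError(
            f"{image_path}: {data.shape[3]} frames but gradient table has "
            f"{len(scheme)} entries"
        )
    mask = None
    if mask_path is not None:
        mimg = nib.load(str(mask_path))
        mask = np.asarray(mimg.dataobj) > 0
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    return DiffusionVolume(
        signal=data,
        scheme=scheme,
        mask=mask,
        voxel_size=voxel_size,
        affine=img.affine,
    )


def save_map(scalar_map: ScalarMap, path) -> Path:
    """Write a ScalarMap as NIfTI; NaNs are stored as 0 (background)."""
    values = np.nan_to_num(scalar_map.values, nan=0.0)
    affine = scalar_map.affine
    if affine is None:
        affine = _affine_from_voxel_size(scalar_map.voxel_size)
    img = nib.Nifti1Image(values.astype(np.float64), affine)
    img.header.set_zooms(scalar_map.voxel_size)
    nib.save(img, str(path))
    return Path(path)


def load_map(path, metric_name: str = "unknown") -> ScalarMap:
    img = nib.load(str(path))
    return ScalarMap(
        values=np.asarray(img.dataobj, dtype=np.float64),
        metric_name=metric_name,
        voxel_size=tuple(float(z) for z in img.header.get_zooms()[:3]),
        affine=img.affine,
    )


def _repulsion_directions(n: int, seed: int, n_iter: int = 300) -> np.ndarray:
    """Approximately uniform directions by electrostatic repulsion.

    Antipodally symmetric energy (directions and their negatives repel), as
    appropriate for diffusion encoding where +u and -u are equivalent.
    """
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n, 3))
    x /= np.linalg.norm(x, axis=1, keepdims=True)
    step = 0.1
    for _ in range(n_iter):
        # force from both the point and its antipode
        diff = x[:, None, :] - x[None, :, :]
        dsum = x[:, None, :] + x[None, :, :]
        d1 = np.linalg.norm(diff, axis=-1)
        d2 = np.linalg.norm(dsum, axis=-1)
        np.fill_diagonal(d1, np.inf)
        np.fill_diagonal(d2, np.inf)
        f = (diff / d1[..., None] ** 3).sum(axis=1) + (
            dsum / d2[..., None] ** 3
        ).sum(axis=1)
        x = x + step * f / n
        x /= np.linalg.norm(x, axis=1, keepdims=True)
    return x


def min_pairwise_angle(directions: np.ndarray) -> float:
    """Smallest pairwise angular separation (degrees, antipodally symmetric)."""
    d = np.asarray(directions, dtype=float)
    cos = np.abs(d @ d.T)
    np.fill_diagonal(cos, 0.0)
    return float(np.degrees(np.arccos(np.clip(cos.max(), -1, 1))))


def make_scheme(
    n_directions: int,
    b_max: float,
    n_b0: int,
    big_delta: float,
    small_delta: float,
    seed: int,
    n_shells: int | None = None,
) -> GradientScheme:
    """Build a scheme with repulsion-optimized directions.

    ``n_b0`` zero-weighted measurements are prepended.  By default every
    diffusion direction carries its own b-value, spread uniformly over
    (0, b_max] — distinct weightings are what give the isotropic-spectrum
    fit its resolution in ADC.  Pass ``n_shells`` for a conventional
    multi-shell layout instead (b-values b_max·s/n_shells, round-robin).
    """
    if n_directions < 6:
        raise ConfigurationError(
            "need at least 6 diffusion directions for a tensor fit"
        )
    if b_max <= 0:
        raise ConfigurationError("b_max must be positive")
    dirs = _repulsion_directions(n_directions, seed)
    if n_shells is None:
        # seeded shuffle so neighbouring directions get unrelated b-values
        perm = np.random.default_rng(seed).permutation(n_directions)
        bvals_dw = b_max * (perm + 1.0) / n_directions
    else:
        shells = b_max * np.arange(1, n_shells + 1) / n_shells
        bvals_dw = shells[np.arange(n_directions) % n_shells]
    bvals = np.concatenate([np.zeros(n_b0), bvals_dw])
    bvecs = np.vstack([np.zeros((n_b0, 3)), dirs])
    return GradientScheme(
        bvals, bvecs, big_delta=big_delta, small_delta=small_delta
    )
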