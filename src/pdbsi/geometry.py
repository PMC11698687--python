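"""Histology-style 3D substrates for the random-walk simulator.

A region is a box (µm units, origin at 0) populated with three kinds of
impermeable primitives:

* vertical *tubes* (annular walls) standing in for the syncytiotrophoblast
  layer wrapping each villus,
* hexagonal *prisms* inside the tubes standing in for large resident cells,
* *spheres* of radius 4–8 µm standing in for immune cells, placed with
  local density proportional to a stain-density map.

Tubes and prisms are extruded through the full slab height; spheres are
fully 3D.  Everything else is extracellular space (intervillous space plus
villous stroma).  Compartment labels: 0 extracellular, 1 sphere, 2 prism,
3 tube wall.
"""

from __future__ import annotations

import dataclasses
import json
import math

import numpy as np
from numba import njit

from .core_io import ConfigurationError

__all__ = [
    "LABEL_EXTRACELLULAR",
    "LABEL_SPHERE",
    "LABEL_PRISM",
    "LABEL_TUBE",
    "GeometryParams",
    "Geometry",
    "build_geometry",
    "tile_regions",
]

LABEL_EXTRACELLULAR = 0
LABEL_SPHERE = 1
LABEL_PRISM = 2
LABEL_TUBE = 3

SQRT3_2 = math.sqrt(3.0) / 2.0
#: inward normals of the three slab pairs whose intersection is the hexagon
HEX_NORMALS = np.array(
    [[1.0, 0.0], [0.5, SQRT3_2], [-0.5, SQRT3_2]]
)


@dataclasses.dataclass(frozen=True)
class GeometryParams:
    """Substrate construction parameters (all lengths in µm)."""

    slab_height: float = 1000.0
    tube_outer_radius: float = 55.0
    tube_wall_thickness: float = 6.0
    tube_jitter: float = 5.0
    prism_circumradius: float = 18.0
    prisms_per_tube: int = 2
    prism_orbit_radius: float = 21.0
    # upper radius kept below 8 µm so the immune pool's apparent ADC stays
    # strictly inside the restricted window (an 8 µm sphere sits exactly at
    # the 0.6 µm²/ms edge and splits across it on a discrete grid)
    sphere_radius_range: tuple[float, float] = (4.0, 6.5)
    grid_cell: float = 18.0
    candidate_factor: float = 40.0
    max_batches: int = 40

    def __post_init__(self) -> None:
        r_lo, r_hi = self.sphere_radius_range
        if not (4.0 <= r_lo <= r_hi <= 8.0):
            raise ConfigurationError("immune sphere radii must lie in [4, 8] µm")
        if self.grid_cell < 2 * r_hi:
            raise ConfigurationError("grid_cell must exceed the sphere diameter")


@dataclasses.dataclass
class Geometry:
    """A labelled substrate over ``field_size`` (µm, origin at 0)."""

    field_size: tuple[float, float, float]
    sphere_centers: np.ndarray  # (n, 3)
    sphere_radii: np.ndarray  # (n,)
    prism_centers: np.ndarray  # (m, 2) xy; prisms span the full slab
    prism_circumradii: np.ndarray  # (m,)
    tube_centers: np.ndarray  # (t, 2) xy
    tube_inner_radii: np.ndarray  # (t,)
    tube_outer_radii: np.ndarray  # (t,)

    def __post_init__(self) -> None:
        self.sphere_centers = np.atleast_2d(
            np.asarray(self.sphere_centers, dtype=float)
        ).reshape(-1, 3)
        self.sphere_radii = np.asarray(self.sphere_radii, dtype=float).ravel()
        self.prism_centers = np.asarray(
            self.prism_centers, dtype=float
        ).reshape(-1, 2)
        self.prism_circumradii = np.asarray(
            self.prism_circumradii, dtype=float
        ).ravel()
        self.tube_centers = np.asarray(self.tube_centers, dtype=float).reshape(
            -1, 2
        )
        self.tube_inner_radii = np.asarray(
            self.tube_inner_radii, dtype=float
        ).ravel()
        self.tube_outer_radii = np.asarray(
            self.tube_outer_radii, dtype=float
        ).ravel()
        if self.sphere_radii.size and (
            self.sphere_radii.min() < 4.0 - 1e-9
            or self.sphere_radii.max() > 8.0 + 1e-9
        ):
            raise ConfigurationError("immune sphere radii must lie in [4, 8] µm")

    # -- volumes -----------------------------------------------------------
    @property
    def field_volume(self) -> float:
        return float(np.prod(self.field_size))

    @property
    def sphere_volumes(self) -> np.ndarray:
        return 4.0 / 3.0 * np.pi * self.sphere_radii**3

    @property
    def prism_volumes(self) -> np.ndarray:
        # regular hexagon area = (3√3/2) R², extruded over the slab
        return 1.5 * math.sqrt(3.0) * self.prism_circumradii**2 * self.field_size[2]

    @property
    def tube_wall_volumes(self) -> np.ndarray:
        return (
            np.pi
            * (self.tube_outer_radii**2 - self.tube_inner_radii**2)
            * self.field_size[2]
        )

    def compartment_volumes(self) -> np.ndarray:
        """Volumes of (extracellular, spheres, prisms, tube walls)."""
        vs = float(self.sphere_volumes.sum())
        vp = float(self.prism_volumes.sum())
        vt = float(self.tube_wall_volumes.sum())
        return np.array([self.field_volume - vs - vp - vt, vs, vp, vt])

    @property
    def immune_volume_fraction(self) -> float:
        """Exact bookkeeping identity: Σ sphere volume / field volume."""
        return float(self.sphere_volumes.sum() / self.field_volume)

    @property
    def tube_centerlines(self) -> list[np.ndarray]:
        """Tube centerlines as 2-point vertical polylines (µm)."""
        h = self.field_size[2]
        return [
            np.array([[cx, cy, 0.0], [cx, cy, h]])
            for cx, cy in self.tube_centers
        ]

    def min_primitive_radius(self) -> float:
        candidates = [np.inf]
        if self.sphere_radii.size:
            candidates.append(self.sphere_radii.min())
        if self.prism_circumradii.size:
            candidates.append(self.prism_circumradii.min() * SQRT3_2)
        if self.tube_outer_radii.size:
            candidates.append(
                float((self.tube_outer_radii - self.tube_inner_radii).min())
            )
        return float(min(candidates))

    # -- serialization -----------------------------------------------------
    def to_json(self, path=None) -> str:
        payload = {
            "units": "um",
            "field_size": list(self.field_size),
            "spheres": [
                {"center": c.tolist(), "radius": float(r), "label": "immune"}
                for c, r in zip(self.sphere_centers, self.sphere_radii)
            ],
            "prisms": [
                {
                    "center": c.tolist(),
                    "circumradius": float(r),
                    "height": self.field_size[2],
                    "label": "resident",
                }
                for c, r in zip(self.prism_centers, self.prism_circumradii)
            ],
            "tubes": [
                {
                    "centerline": line.tolist(),
                    "outer_radius": float(ro),
                    "wall_thickness": float(ro - ri),
                    "label": "syncytiotrophoblast",
                }
                for line, ri, ro in zip(
                    self.tube_centerlines,
                    self.tube_inner_radii,
                    self.tube_outer_radii,
                )
            ],
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "Geometry":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        spheres = payload.get("spheres", [])
        prisms = payload.get("prisms", [])
        tubes = payload.get("tubes", [])
        return cls(
            field_size=tuple(payload["field_size"]),
            sphere_centers=np.array([s["center"] for s in spheres]).reshape(-1, 3),
            sphere_radii=np.array([s["radius"] for s in spheres]),
            prism_centers=np.array(
                [p["center"] for p in prisms]
            ).reshape(-1, 2),
            prism_circumradii=np.array([p["circumradius"] for p in prisms]),
            tube_centers=np.array(
                [t["centerline"][0][:2] for t in tubes]
            ).reshape(-1, 2),
            tube_inner_radii=np.array(
                [t["outer_radius"] - t["wall_thickness"] for t in tubes]
            ),
            tube_outer_radii=np.array([t["outer_radius"] for t in tubes]),
        )


def tile_regions(
    field_size_mm: tuple[float, float], region_size_mm: float = 0.25
) -> list[tuple[float, float, float, float]]:
    """Tile a field into square regions; boxes are (x0, y0, x1, y1) in µm.

    Raises if the field does not split into an integer number of regions.
    """
    fx, fy = field_size_mm
    nx = fx / region_size_mm
    ny = fy / region_size_mm
    if abs(nx - round(nx)) > 1e-9 or abs(ny - round(ny)) > 1e-9:
        raise ConfigurationError(
            f"field {field_size_mm} mm does not tile into "
            f"{region_size_mm} mm regions"
        )
    nx, ny = int(round(nx)), int(round(ny))
    s = region_size_mm * 1000.0
    return [
        (i * s, j * s, (i + 1) * s, (j + 1) * s)
        for j in range(ny)
        for i in range(nx)
    ]


@njit(cache=True)
def _place_spheres(
    cand_xyz,
    cand_r,
    n_init,
    init_vol,
    target_vol,
    tube_c,
    tube_rin,
    tube_rout,
    prism_c,
    prism_rr,
    lx,
    ly,
    lz,
    cs,
):  # pragma: no cover - exercised via build_geometry
    n = cand_xyz.shape[0]
    nx = max(1, int(np.ceil(lx / cs)))
    ny = max(1, int(np.ceil(ly / cs)))
    nz = max(1, int(np.ceil(lz / cs)))
    head = -np.ones(nx * ny * nz, dtype=np.int64)
    nxt = -np.ones(n, dtype=np.int64)
    accepted = np.zeros(n, dtype=np.bool_)
    vol = init_vol
    # first n_init entries are already-placed spheres: register them only
    for i in range(n_init):
        accepted[i] = True
        ix = min(int(cand_xyz[i, 0] / cs), nx - 1)
        iy = min(int(cand_xyz[i, 1] / cs), ny - 1)
        iz = min(int(cand_xyz[i, 2] / cs), nz - 1)
        cell = (ix * ny + iy) * nz + iz
        nxt[i] = head[cell]
        head[cell] = i
    for i in range(n_init, n):
        if vol >= target_vol:
            break
        x = cand_xyz[i, 0]
        y = cand_xyz[i, 1]
        z = cand_xyz[i, 2]
        r = cand_r[i]
        if x - r < 0 or x + r > lx or y - r < 0 or y + r > ly:
            continue
        if z - r < 0 or z + r > lz:
            continue
        ok = True
        for t in range(tube_c.shape[0]):
            d = math.hypot(x - tube_c[t, 0], y - tube_c[t, 1])
            if tube_rin[t] - r < d < tube_rout[t] + r:
                ok = False
                break
        if not ok:
            continue
        for p in range(prism_c.shape[0]):
            d = math.hypot(x - prism_c[p, 0], y - prism_c[p, 1])
            if d < prism_rr[p] + r:
                ok = False
                break
        if not ok:
            continue
        ix = min(int(x / cs), nx - 1)
        iy = min(int(y / cs), ny - 1)
        iz = min(int(z / cs), nz - 1)
        for dx in range(-1, 2):
            jx = ix + dx
            if jx < 0 or jx >= nx:
                continue
            for dy in range(-1, 2):
                jy = iy + dy
                if jy < 0 or jy >= ny:
                    continue
                for dz in range(-1, 2):
                    jz = iz + dz
                    if jz < 0 or jz >= nz:
                        continue
                    k = head[(jx * ny + jy) * nz + jz]
                    while k >= 0:
                        ddx = x - cand_xyz[k, 0]
                        ddy = y - cand_xyz[k, 1]
                        ddz = z - cand_xyz[k, 2]
                        rr = r + cand_r[k]
                        if ddx * ddx + ddy * ddy + ddz * ddz < rr * rr:
                            ok = False
                            break
                        k = nxt[k]
                    if not ok:
                        break
                if not ok:
                    break
            if not ok:
                break
        if not ok:
            continue
        accepted[i] = True
        cell = (ix * ny + iy) * nz + iz
        nxt[i] = head[cell]
        head[cell] = i
        vol += 4.0 / 3.0 * np.pi * r**3
    return accepted, vol


def _layout_tubes(
    lx: float, ly: float, params: GeometryParams, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    ro = params.tube_outer_radius
    spacing = 2 * ro + 2 * params.tube_jitter
    nx = max(0, int(lx // spacing))
    ny = max(0, int(ly // spacing))
    centers = []
    for i in range(nx):
        for j in range(ny):
            cx = (i + 0.5) * lx / max(nx, 1)
            cy = (j + 0.5) * ly / max(ny, 1)
            jx, jy = rng.uniform(-params.tube_jitter, params.tube_jitter, 2)
            centers.append((cx + jx, cy + jy))
    centers = np.array(centers, dtype=float).reshape(-1, 2)
    rin = np.full(centers.shape[0], ro - params.tube_wall_thickness)
    rout = np.full(centers.shape[0], ro)
    return centers, rin, rout


def _layout_prisms(
    tube_centers: np.ndarray,
    tube_rin: np.ndarray,
    params: GeometryParams,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Ring of prisms inside each tube; deterministic count, seeded rotation."""
    k = params.prisms_per_tube
    orbit = params.prism_orbit_radius
    rr = params.prism_circumradius
    if k and tube_centers.shape[0]:
        if orbit + rr >= tube_rin.min():
            raise ConfigurationError(
                "prism_orbit_radius + prism_circumradius exceeds tube inner "
                "radius"
            )
        if k > 1 and 2 * orbit * math.sin(math.pi / k) < 2 * rr:
            raise ConfigurationError(
                "prisms_per_tube too large for the prism orbit"
            )
    centers = []
    for cx, cy in tube_centers:
        theta0 = rng.uniform(0, 2 * math.pi)
        for m in range(k):
            th = theta0 + 2 * math.pi * m / max(k, 1)
            centers.append((cx + orbit * math.cos(th), cy + orbit * math.sin(th)))
    centers = np.array(centers, dtype=float).reshape(-1, 2)
    return centers, np.full(centers.shape[0], rr)


def build_geometry(
    density_map: np.ndarray,
    region_box: tuple[float, float, float, float],
    params: GeometryParams | None = None,
    seed: int = 0,
) -> Geometry:
    """Build one region's substrate from a stain-density patch.

    ``density_map`` is a 2D array of positive-stain area ratios covering the
    region; the target immune sphere volume fraction equals its mean, and
    sphere xy positions are drawn with per-pixel probability proportional to
    the local density.  Deterministic given ``seed``.
    """
    params = params or GeometryParams()
    density = np.asarray(density_map, dtype=float)
    if density.ndim != 2 or np.any(density < 0) or np.any(density > 1):
        raise ConfigurationError("density map must be 2D with values in [0, 1]")
    x0, y0, x1, y1 = region_box
    lx, ly = x1 - x0, y1 - y0
    lz = params.slab_height
    if lx <= 0 or ly <= 0:
        raise ConfigurationError("empty region box")
    rng = np.random.default_rng(seed)

    tube_c, tube_rin, tube_rout = _layout_tubes(lx, ly, params, rng)
    prism_c, prism_rr = _layout_prisms(tube_c, tube_rin, params, rng)

    mean_density = float(density.mean())
    target_vol = mean_density * lx * ly * lz
    r_lo, r_hi = params.sphere_radius_range
    sphere_centers = np.zeros((0, 3))
    sphere_radii = np.zeros(0)
    placed_vol = 0.0
    if target_vol > 0:
        mean_sphere_vol = (
            4.0 / 3.0 * np.pi * (r_hi**4 - r_lo**4) / (4 * (r_hi - r_lo))
            if r_hi > r_lo
            else 4.0 / 3.0 * np.pi * r_lo**3
        )
        weights = density.ravel() + 1e-300
        weights = weights / weights.sum()
        psx, psy = lx / density.shape[1], ly / density.shape[0]
        for _ in range(params.max_batches):
            # size each batch by the volume still missing; later batches see
            # lower acceptance (rejection-sampling crowding) but need fewer
            batch = (
                int(
                    params.candidate_factor
                    * (target_vol - placed_vol)
                    / mean_sphere_vol
                )
                + 64
            )
            px = rng.choice(density.size, size=batch, p=weights)
            rows, cols = np.unravel_index(px, density.shape)
            # rows index y, cols index x; jitter uniformly inside the pixel
            new_xyz = np.column_stack(
                [
                    (cols + rng.uniform(0, 1, batch)) * psx,
                    (rows + rng.uniform(0, 1, batch)) * psy,
                    rng.uniform(0, lz, batch),
                ]
            )
            new_r = rng.uniform(r_lo, r_hi, batch)
            cand_xyz = np.vstack([sphere_centers, new_xyz])
            cand_r = np.concatenate([sphere_radii, new_r])
            accepted, placed_vol = _place_spheres(
                cand_xyz,
                cand_r,
                sphere_centers.shape[0],
                placed_vol,
                target_vol,
                tube_c,
                tube_rin,
                tube_rout,
                prism_c,
                prism_rr,
                lx,
                ly,
                lz,
                params.grid_cell,
            )
            sphere_centers = np.ascontiguousarray(cand_xyz[accepted])
            sphere_radii = np.ascontiguousarray(cand_r[accepted])
            if placed_vol >= target_vol:
                break
        if placed_vol < 0.8 * target_vol:
            raise ConfigurationError(
                f"could not reach immune density {mean_density:.3g} without "
                "overlap; lower mean density or sphere_radius_range"
            )

    return Geometry(
        field_size=(lx, ly, lz),
        sphere_centers=sphere_centers,
        sphere_radii=sphere_radii,
        prism_centers=prism_c,
        prism_circumradii=prism_rr,
        tube_centers=tube_c,
        tube_inner_radii=tube_rin,
        tube_outer_radii=tube_rout,
    )
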