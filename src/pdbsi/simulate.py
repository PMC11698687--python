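"""Monte Carlo random-walk diffusion, PGSE signal synthesis, and noise.

Walkers take Gaussian steps (per-axis variance 2·D0·dt) and reflect
specularly off impermeable compartment boundaries; a step whose reflection
cannot be resolved (e.g. at a corner) is rejected, so a walker can never
leave its compartment.  Signals come from the standard two-lobe PGSE phase
integral with rectangular gradients: b = (γ g δ)² (Δ − δ/3).

Units: µm, ms, µm²/ms; b-values in s/mm² (× 1e-3 → ms/µm²).
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import scipy.optimize
from numba import njit

from .core_io import ConfigurationError, DataError, GradientScheme
from .geometry import (
    HEX_NORMALS,
    LABEL_EXTRACELLULAR,
    LABEL_PRISM,
    LABEL_SPHERE,
    LABEL_TUBE,
    SQRT3_2,
    Geometry,
)

__all__ = [
    "WalkerEnsemble",
    "simulate_walkers",
    "synthesize_signal",
    "add_noise",
    "sphere_adc",
    "gpd_sphere_adc",
    "suggest_dt",
]

B_SCALE = 1.0e-3


@dataclasses.dataclass
class WalkerEnsemble:
    """Trajectories of an impermeable-compartment random walk.

    ``positions`` is (n_walkers, n_steps + 1, 3) in µm (float32);
    ``labels`` holds the fixed compartment label of each walker.
    """

    positions: np.ndarray
    labels: np.ndarray
    dt: float
    d0: float
    seed: int

    @property
    def n_walkers(self) -> int:
        return self.positions.shape[0]

    @property
    def duration(self) -> float:
        return (self.positions.shape[1] - 1) * self.dt

    def msd(self) -> np.ndarray:
        """Per-axis mean squared displacement from t=0, shape (n_steps+1, 3)."""
        disp = self.positions - self.positions[:, :1, :]
        return np.mean(disp.astype(np.float64) ** 2, axis=0)


def suggest_dt(min_radius: float, d0: float) -> float:
    """Largest dt satisfying sqrt(6 D0 dt) < min_radius / 4."""
    return (min_radius / 4.0) ** 2 / (6.0 * d0)


@njit(cache=True)
def _walk_kernel(
    pos0,
    labels,
    prim,
    steps,
    traj,
    sph_c,
    sph_r,
    sph_head,
    sph_next,
    cs,
    ngx,
    ngy,
    ngz,
    prism_c,
    prism_a,
    tube_c,
    tube_rin,
    tube_rout,
    lx,
    ly,
    lz,
):  # pragma: no cover - exercised via simulate_walkers
    n_walkers = steps.shape[0]
    n_steps = steps.shape[1]
    n0x, n0y = 1.0, 0.0
    n1x, n1y = 0.5, SQRT3_2
    n2x, n2y = -0.5, SQRT3_2
    for w in range(n_walkers):
        x = pos0[w, 0]
        y = pos0[w, 1]
        z = pos0[w, 2]
        traj[w, 0, 0] = x
        traj[w, 0, 1] = y
        traj[w, 0, 2] = z
        lab = labels[w]
        pi = prim[w]
        for t in range(n_steps):
            px = x + steps[w, t, 0]
            py = y + steps[w, t, 1]
            pz = z + steps[w, t, 2]
            ok = True
            if lab == 1:  # confined to one sphere
                cx = sph_c[pi, 0]
                cy = sph_c[pi, 1]
                cz = sph_c[pi, 2]
                r = sph_r[pi]
                dx = px - cx
                dy = py - cy
                dz = pz - cz
                d = math.sqrt(dx * dx + dy * dy + dz * dz)
                if d > r:
                    dn = 2.0 * r - d
                    if dn <= 0.0 or d == 0.0:
                        ok = False
                    else:
                        f = dn / d
                        px = cx + dx * f
                        py = cy + dy * f
                        pz = cz + dz * f
            elif lab == 2:  # confined to one hexagonal prism (xy) + slab (z)
                if pz < 0.0:
                    pz = -pz
                elif pz > lz:
                    pz = 2.0 * lz - pz
                cx = prism_c[pi, 0]
                cy = prism_c[pi, 1]
                a = prism_a[pi]
                dx = px - cx
                dy = py - cy
                s0 = dx * n0x + dy * n0y
                if abs(s0) > a:
                    corr = 2.0 * (abs(s0) - a) * (1.0 if s0 > 0 else -1.0)
                    dx -= corr * n0x
                    dy -= corr * n0y
                s1 = dx * n1x + dy * n1y
                if abs(s1) > a:
                    corr = 2.0 * (abs(s1) - a) * (1.0 if s1 > 0 else -1.0)
                    dx -= corr * n1x
                    dy -= corr * n1y
                s2 = dx * n2x + dy * n2y
                if abs(s2) > a:
                    corr = 2.0 * (abs(s2) - a) * (1.0 if s2 > 0 else -1.0)
                    dx -= corr * n2x
                    dy -= corr * n2y
                if (
                    abs(dx * n0x + dy * n0y) > a
                    or abs(dx * n1x + dy * n1y) > a
                    or abs(dx * n2x + dy * n2y) > a
                    or pz < 0.0
                    or pz > lz
                ):
                    ok = False
                else:
                    px = cx + dx
                    py = cy + dy
            elif lab == 3:  # confined to one tube wall annulus + slab
                if pz < 0.0:
                    pz = -pz
                elif pz > lz:
                    pz = 2.0 * lz - pz
                cx = tube_c[pi, 0]
                cy = tube_c[pi, 1]
                rin = tube_rin[pi]
                rout = tube_rout[pi]
                dx = px - cx
                dy = py - cy
                d = math.sqrt(dx * dx + dy * dy)
                dn = d
                if d > rout:
                    dn = 2.0 * rout - d
                elif d < rin:
                    dn = 2.0 * rin - d
                if dn < rin or dn > rout or d == 0.0 or pz < 0.0 or pz > lz:
                    ok = False
                elif dn != d:
                    f = dn / d
                    px = cx + dx * f
                    py = cy + dy * f
            else:  # extracellular: reflecting field box + all obstacles
                collided = False
                if px < 0.0:
                    px = -px
                    collided = True
                elif px > lx:
                    px = 2.0 * lx - px
                    collided = True
                if py < 0.0:
                    py = -py
                    collided = True
                elif py > ly:
                    py = 2.0 * ly - py
                    collided = True
                if pz < 0.0:
                    pz = -pz
                    collided = True
                elif pz > lz:
                    pz = 2.0 * lz - pz
                    collided = True
                for j in range(tube_c.shape[0]):
                    dx = px - tube_c[j, 0]
                    dy = py - tube_c[j, 1]
                    d = math.sqrt(dx * dx + dy * dy)
                    if tube_rin[j] < d < tube_rout[j]:
                        mid = 0.5 * (tube_rin[j] + tube_rout[j])
                        dn = (
                            2.0 * tube_rout[j] - d
                            if d >= mid
                            else 2.0 * tube_rin[j] - d
                        )
                        f = dn / d
                        px = tube_c[j, 0] + dx * f
                        py = tube_c[j, 1] + dy * f
                        collided = True
                for j in range(prism_c.shape[0]):
                    dx = px - prism_c[j, 0]
                    dy = py - prism_c[j, 1]
                    a = prism_a[j]
                    s0 = dx * n0x + dy * n0y
                    s1 = dx * n1x + dy * n1y
                    s2 = dx * n2x + dy * n2y
                    if abs(s0) < a and abs(s1) < a and abs(s2) < a:
                        # exit through the face with least penetration
                        p0 = a - abs(s0)
                        p1 = a - abs(s1)
                        p2 = a - abs(s2)
                        if p0 <= p1 and p0 <= p2:
                            corr = 2.0 * p0 * (1.0 if s0 > 0 else -1.0)
                            dx += corr * n0x
                            dy += corr * n0y
                        elif p1 <= p2:
                            corr = 2.0 * p1 * (1.0 if s1 > 0 else -1.0)
                            dx += corr * n1x
                            dy += corr * n1y
                        else:
                            corr = 2.0 * p2 * (1.0 if s2 > 0 else -1.0)
                            dx += corr * n2x
                            dy += corr * n2y
                        px = prism_c[j, 0] + dx
                        py = prism_c[j, 1] + dy
                        collided = True
                if sph_c.shape[0] > 0:
                    ix = int(px / cs)
                    iy = int(py / cs)
                    iz = int(pz / cs)
                    if ix >= ngx:
                        ix = ngx - 1
                    if iy >= ngy:
                        iy = ngy - 1
                    if iz >= ngz:
                        iz = ngz - 1
                    if ix < 0:
                        ix = 0
                    if iy < 0:
                        iy = 0
                    if iz < 0:
                        iz = 0
                    for ddx in range(-1, 2):
                        jx = ix + ddx
                        if jx < 0 or jx >= ngx:
                            continue
                        for ddy in range(-1, 2):
                            jy = iy + ddy
                            if jy < 0 or jy >= ngy:
                                continue
                            for ddz in range(-1, 2):
                                jz = iz + ddz
                                if jz < 0 or jz >= ngz:
                                    continue
                                k = sph_head[(jx * ngy + jy) * ngz + jz]
                                while k >= 0:
                                    dx = px - sph_c[k, 0]
                                    dy = py - sph_c[k, 1]
                                    dz = pz - sph_c[k, 2]
                                    d = math.sqrt(
                                        dx * dx + dy * dy + dz * dz
                                    )
                                    r = sph_r[k]
                                    if d < r:
                                        if d == 0.0:
                                            ok = False
                                        else:
                                            f = (2.0 * r - d) / d
                                            px = sph_c[k, 0] + dx * f
                                            py = sph_c[k, 1] + dy * f
                                            pz = sph_c[k, 2] + dz * f
                                        collided = True
                                    k = sph_next[k]
                if collided and ok:
                    # validate the resolved position; reject on any residual
                    # violation (multi-surface corner cases)
                    if (
                        px < 0.0
                        or px > lx
                        or py < 0.0
                        or py > ly
                        or pz < 0.0
                        or pz > lz
                    ):
                        ok = False
                    if ok:
                        for j in range(tube_c.shape[0]):
                            dx = px - tube_c[j, 0]
                            dy = py - tube_c[j, 1]
                            d = math.sqrt(dx * dx + dy * dy)
                            if tube_rin[j] < d < tube_rout[j]:
                                ok = False
                                break
                    if ok:
                        for j in range(prism_c.shape[0]):
                            dx = px - prism_c[j, 0]
                            dy = py - prism_c[j, 1]
                            a = prism_a[j]
                            if (
                                abs(dx * n0x + dy * n0y) < a
                                and abs(dx * n1x + dy * n1y) < a
                                and abs(dx * n2x + dy * n2y) < a
                            ):
                                ok = False
                                break
                    if ok and sph_c.shape[0] > 0:
                        ix = min(max(int(px / cs), 0), ngx - 1)
                        iy = min(max(int(py / cs), 0), ngy - 1)
                        iz = min(max(int(pz / cs), 0), ngz - 1)
                        for ddx in range(-1, 2):
                            jx = ix + ddx
                            if jx < 0 or jx >= ngx:
                                continue
                            for ddy in range(-1, 2):
                                jy = iy + ddy
                                if jy < 0 or jy >= ngy:
                                    continue
                                for ddz in range(-1, 2):
                                    jz = iz + ddz
                                    if jz < 0 or jz >= ngz:
                                        continue
                                    k = sph_head[(jx * ngy + jy) * ngz + jz]
                                    while k >= 0:
                                        dx = px - sph_c[k, 0]
                                        dy = py - sph_c[k, 1]
                                        dz = pz - sph_c[k, 2]
                                        if (
                                            dx * dx + dy * dy + dz * dz
                                            < sph_r[k] * sph_r[k]
                                        ):
                                            ok = False
                                            break
                                        k = sph_next[k]
                                    if not ok:
                                        break
                                if not ok:
                                    break
                            if not ok:
                                break
            if ok:
                x, y, z = px, py, pz
            traj[w, t + 1, 0] = x
            traj[w, t + 1, 1] = y
            traj[w, t + 1, 2] = z


def _sphere_grid(geometry: Geometry, cs: float):
    lx, ly, lz = geometry.field_size
    ngx = max(1, int(np.ceil(lx / cs)))
    ngy = max(1, int(np.ceil(ly / cs)))
    ngz = max(1, int(np.ceil(lz / cs)))
    head = -np.ones(ngx * ngy * ngz, dtype=np.int64)
    nxt = -np.ones(max(geometry.sphere_radii.size, 1), dtype=np.int64)
    for i, c in enumerate(geometry.sphere_centers):
        ix = min(int(c[0] / cs), ngx - 1)
        iy = min(int(c[1] / cs), ngy - 1)
        iz = min(int(c[2] / cs), ngz - 1)
        cell = (ix * ngy + iy) * ngz + iz
        nxt[i] = head[cell]
        head[cell] = i
    return head, nxt, ngx, ngy, ngz


def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation proportional to weights, summing exactly to total."""
    w = np.asarray(weights, dtype=float)
    if w.sum() <= 0:
        out = np.zeros(w.size, dtype=int)
        if w.size:
            out[0] = total
        return out
    quota = w / w.sum() * total
    base = np.floor(quota).astype(int)
    rem = total - base.sum()
    order = np.argsort(-(quota - base))
    base[order[:rem]] += 1
    return base


def _point_in_hexagon(dx: np.ndarray, dy: np.ndarray, a: float) -> np.ndarray:
    s = np.abs(np.outer(dx, HEX_NORMALS[:, 0]) + np.outer(dy, HEX_NORMALS[:, 1]))
    return np.all(s < a, axis=1)


def _seed_positions(
    geometry: Geometry, n_walkers: int, rng: np.random.Generator, compartment
):
    vols = geometry.compartment_volumes()
    if compartment is None:
        counts = _largest_remainder(vols, n_walkers)
    else:
        counts = np.zeros(4, dtype=int)
        counts[compartment] = n_walkers
    lx, ly, lz = geometry.field_size
    positions, labels, prim = [], [], []

    # spheres (vectorized over the whole population)
    if counts[LABEL_SPHERE]:
        if geometry.sphere_radii.size == 0:
            raise ConfigurationError("no spheres to seed walkers in")
        per = _largest_remainder(geometry.sphere_volumes, counts[LABEL_SPHERE])
        idx = np.repeat(np.arange(per.size), per)
        u = rng.standard_normal((idx.size, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        rad = geometry.sphere_radii[idx] * rng.uniform(0, 1, idx.size) ** (1 / 3)
        positions.append(geometry.sphere_centers[idx] + u * rad[:, None])
        labels.append(np.full(idx.size, LABEL_SPHERE))
        prim.append(idx)

    # prisms
    if counts[LABEL_PRISM]:
        if geometry.prism_circumradii.size == 0:
            raise ConfigurationError("no prisms to seed walkers in")
        per = _largest_remainder(geometry.prism_volumes, counts[LABEL_PRISM])
        for i, n in enumerate(per):
            if n == 0:
                continue
            a = geometry.prism_circumradii[i] * SQRT3_2
            got = []
            while sum(len(g) for g in got) < n:
                cand = rng.uniform(
                    -geometry.prism_circumradii[i],
                    geometry.prism_circumradii[i],
                    (2 * n + 8, 2),
                )
                keep = cand[_point_in_hexagon(cand[:, 0], cand[:, 1], a)]
                got.append(keep)
            xy = np.vstack(got)[:n] + geometry.prism_centers[i]
            zs = rng.uniform(0, lz, n)
            positions.append(np.column_stack([xy, zs]))
            labels.append(np.full(n, LABEL_PRISM))
            prim.append(np.full(n, i))

    # tube walls
    if counts[LABEL_TUBE]:
        if geometry.tube_outer_radii.size == 0:
            raise ConfigurationError("no tubes to seed walkers in")
        per = _largest_remainder(geometry.tube_wall_volumes, counts[LABEL_TUBE])
        for i, n in enumerate(per):
            if n == 0:
                continue
            ri, ro = geometry.tube_inner_radii[i], geometry.tube_outer_radii[i]
            rad = np.sqrt(rng.uniform(ri**2, ro**2, n))
            th = rng.uniform(0, 2 * np.pi, n)
            positions.append(
                np.column_stack(
                    [
                        geometry.tube_centers[i, 0] + rad * np.cos(th),
                        geometry.tube_centers[i, 1] + rad * np.sin(th),
                        rng.uniform(0, lz, n),
                    ]
                )
            )
            labels.append(np.full(n, LABEL_TUBE))
            prim.append(np.full(n, i))

    # extracellular: rejection sampling against every primitive
    if counts[LABEL_EXTRACELLULAR]:
        from scipy.spatial import cKDTree

        n = counts[LABEL_EXTRACELLULAR]
        tree = (
            cKDTree(geometry.sphere_centers)
            if geometry.sphere_radii.size
            else None
        )
        r_max = geometry.sphere_radii.max() if tree is not None else 0.0
        got = []
        n_got = 0
        while n_got < n:
            cand = rng.uniform(0, 1, (2 * n + 16, 3)) * np.array([lx, ly, lz])
            keep = np.ones(cand.shape[0], dtype=bool)
            for c, ri, ro in zip(
                geometry.tube_centers,
                geometry.tube_inner_radii,
                geometry.tube_outer_radii,
            ):
                d = np.hypot(cand[:, 0] - c[0], cand[:, 1] - c[1])
                keep &= (d <= ri) | (d >= ro)
            for c, rr in zip(
                geometry.prism_centers, geometry.prism_circumradii
            ):
                keep &= ~_point_in_hexagon(
                    cand[:, 0] - c[0], cand[:, 1] - c[1], rr * SQRT3_2
                )
            if tree is not None:
                # non-overlapping spheres of radius ≥ 4 µm: at most a
                # handful of centers lie within r_max of any point
                dist, idx = tree.query(
                    cand, k=min(8, geometry.sphere_radii.size),
                    distance_upper_bound=r_max,
                )
                dist = np.atleast_2d(dist.T).T
                idx = np.atleast_2d(idx.T).T
                hit = np.isfinite(dist) & (
                    dist < geometry.sphere_radii[np.minimum(
                        idx, geometry.sphere_radii.size - 1
                    )]
                )
                keep &= ~hit.any(axis=1)
            got.append(cand[keep])
            n_got += int(keep.sum())
        positions.append(np.vstack(got)[:n])
        labels.append(np.full(n, LABEL_EXTRACELLULAR))
        prim.append(np.full(n, -1))

    return (
        np.vstack(positions),
        np.concatenate(labels).astype(np.int64),
        np.concatenate(prim).astype(np.int64),
    )


def simulate_walkers(
    geometry: Geometry | None,
    n_walkers: int,
    duration: float,
    dt: float,
    d0: float = 2.0,
    seed: int = 0,
    compartment: int | None = None,
    d0_by_label: dict[int, float] | None = None,
) -> WalkerEnsemble:
    """Run the random walk and return full trajectories.

    ``geometry=None`` simulates unbounded free diffusion.  ``compartment``
    restricts seeding to one label; otherwise walkers are allocated to
    compartments proportional to volume.  ``d0_by_label`` overrides the
    intrinsic diffusivity per compartment label (impermeable membranes make
    per-compartment diffusivities well defined).  Deterministic per seed.
    """
    if n_walkers < 1 or duration <= 0 or dt <= 0 or d0 <= 0:
        raise ConfigurationError("n_walkers, duration, dt, d0 must be positive")
    n_steps = int(round(duration / dt))
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(2.0 * d0 * dt)
    if geometry is None:
        steps = rng.standard_normal((n_walkers, n_steps, 3)) * sigma
        traj = np.zeros((n_walkers, n_steps + 1, 3), dtype=np.float32)
        np.cumsum(steps, axis=1, out=steps)
        traj[:, 1:, :] = steps
        return WalkerEnsemble(
            positions=traj,
            labels=np.full(n_walkers, LABEL_EXTRACELLULAR, dtype=np.int64),
            dt=dt,
            d0=d0,
            seed=seed,
        )
    r_min = geometry.min_primitive_radius()
    d0_max = max([d0, *(d0_by_label or {}).values()])
    if np.isfinite(r_min) and math.sqrt(6.0 * d0_max * dt) >= r_min / 4.0:
        raise ConfigurationError(
            f"dt={dt} too coarse for the smallest primitive "
            f"(radius {r_min:.3g} µm); use dt ≤ {suggest_dt(r_min, d0_max):.4g} ms"
        )
    pos0, labels, prim = _seed_positions(geometry, n_walkers, rng, compartment)
    steps = rng.standard_normal((n_walkers, n_steps, 3)) * sigma
    if d0_by_label:
        scale = np.ones(n_walkers)
        for lab, dd in d0_by_label.items():
            if dd <= 0:
                raise ConfigurationError("per-compartment d0 must be positive")
            scale[labels == lab] = math.sqrt(dd / d0)
        steps *= scale[:, None, None]
    traj = np.empty((n_walkers, n_steps + 1, 3), dtype=np.float32)
    cs = 18.0
    head, nxt, ngx, ngy, ngz = _sphere_grid(geometry, cs)
    lx, ly, lz = geometry.field_size
    _walk_kernel(
        pos0,
        labels,
        prim,
        steps,
        traj,
        geometry.sphere_centers,
        geometry.sphere_radii,
        head,
        nxt,
        cs,
        ngx,
        ngy,
        ngz,
        geometry.prism_centers,
        geometry.prism_circumradii * SQRT3_2,
        geometry.tube_centers,
        geometry.tube_inner_radii,
        geometry.tube_outer_radii,
        lx,
        ly,
        lz,
    )
    return WalkerEnsemble(
        positions=traj, labels=labels, dt=dt, d0=d0, seed=seed
    )


def synthesize_signal(
    ensemble: WalkerEnsemble,
    scheme: GradientScheme,
    label_filter: int | None = None,
) -> np.ndarray:
    """PGSE signal magnitude per scheme measurement (normalized, noiseless).

    Phase per walker: φ_k = γg_k · u_k · (∫lobe1 x dt − ∫lobe2 x dt) with
    γg_k = sqrt(b_k / (Δ − δ/3)) / δ; S_k = |⟨e^{iφ}⟩|.  b=0 gives exactly 1.
    """
    if scheme.big_delta is None or scheme.small_delta is None:
        raise ConfigurationError("scheme has no PGSE timing")
    delta = scheme.small_delta
    bdelta = scheme.big_delta
    dt = ensemble.dt
    if ensemble.duration < bdelta + delta - 1e-9:
        raise ConfigurationError(
            f"ensemble duration {ensemble.duration:.3g} ms shorter than "
            f"Δ+δ = {bdelta + delta:.3g} ms"
        )
    n1 = int(round(delta / dt))
    i2 = int(round(bdelta / dt))
    if n1 < 2:
        raise ConfigurationError("dt too coarse to resolve the gradient lobe")
    pos = ensemble.positions
    if label_filter is not None:
        pos = pos[ensemble.labels == label_filter]
        if pos.shape[0] == 0:
            raise DataError("no walkers with the requested label")
    f_net = (
        pos[:, 0:n1, :].sum(axis=1, dtype=np.float64)
        - pos[:, i2 : i2 + n1, :].sum(axis=1, dtype=np.float64)
    ) * dt
    t_eff = bdelta - delta / 3.0
    gamma_g = np.sqrt(scheme.bvals * B_SCALE / t_eff) / delta
    phases = (f_net @ scheme.bvecs.T) * gamma_g[None, :]
    signal = np.abs(np.exp(1j * phases).mean(axis=0))
    signal[scheme.bvals == 0] = 1.0
    return signal


def add_noise(
    signal: np.ndarray, snr: float, seed: int = 0, s0: float | None = None
) -> np.ndarray:
    """Rician magnitude noise: |s + n1 + i·n2| with n ~ Normal(0, s0/snr).

    ``s0`` defaults to the maximum of the signal (the b0 level for a
    normalized decay curve).
    """
    if not snr > 0:
        raise ConfigurationError("snr must be positive")
    s = np.asarray(signal, dtype=float)
    if np.isinf(snr):
        return s.copy()
    sigma = (s.max() if s0 is None else s0) / snr
    rng = np.random.default_rng(seed)
    n1 = rng.normal(0.0, sigma, s.shape)
    n2 = rng.normal(0.0, sigma, s.shape)
    return np.hypot(s + n1, n2)


def sphere_adc(
    radius: float,
    d0: float,
    scheme: GradientScheme,
    n_walkers: int = 20000,
    dt: float = 0.005,
    seed: int = 0,
    b: float = 1000.0,
) -> float:
    """Monte Carlo ADC (µm²/ms) inside one impermeable sphere.

    Uses the scheme's PGSE timing; the attenuation at ``b`` (averaged over
    x/y/z gradients) is converted by a log-linear fit over b ∈ {0, b}.
    """
    if radius <= 0:
        raise ConfigurationError("radius must be positive")
    if scheme.big_delta is None:
        raise ConfigurationError("scheme has no PGSE timing")
    box = 2 * radius + 2.0
    geom = Geometry(
        field_size=(box, box, box),
        sphere_centers=np.array([[box / 2, box / 2, box / 2]]),
        sphere_radii=np.array([radius]),
        prism_centers=np.zeros((0, 2)),
        prism_circumradii=np.zeros(0),
        tube_centers=np.zeros((0, 2)),
        tube_inner_radii=np.zeros(0),
        tube_outer_radii=np.zeros(0),
    )
    duration = scheme.big_delta + scheme.small_delta
    ens = simulate_walkers(
        geom, n_walkers, duration, dt, d0, seed, compartment=LABEL_SPHERE
    )
    probe = GradientScheme(
        bvals=[0.0, b, b, b],
        bvecs=[[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]],
        big_delta=scheme.big_delta,
        small_delta=scheme.small_delta,
    )
    sig = synthesize_signal(ens, probe)
    return float(-math.log(sig[1:].mean()) / (b * B_SCALE))


# ---------------------------------------------------------------------------
# analytic oracle: Gaussian phase distribution for a sphere


def _sphere_bessel_roots(n_roots: int) -> np.ndarray:
    """Roots x_m of x·j1'(x) = 0, i.e. 2x cos x + (x² − 2) sin x = 0."""

    def f(x: float) -> float:
        return 2 * x * math.cos(x) + (x * x - 2.0) * math.sin(x)

    roots = []
    m = 1
    while len(roots) < n_roots:
        # f(x) ~ x³/3 near 0 underflows; keep the lower bracket away from 0
        lo = max((m - 1) * math.pi, 0.5)
        hi = m * math.pi - 1e-9
        if f(lo) * f(hi) < 0:
            roots.append(scipy.optimize.brentq(f, lo, hi, xtol=1e-12))
        m += 1
        if m > 10 * n_roots + 10:
            raise ArithmeticError("sphere Bessel root search did not converge")
    return np.array(roots)


def gpd_sphere_attenuation(
    radius: float,
    d0: float,
    big_delta: float,
    small_delta: float,
    b: float,
    n_roots: int = 30,
) -> float:
    """ln-attenuation (≤ 0) for restricted diffusion in a sphere.

    Murday–Cotts series under the Gaussian phase distribution approximation
    for a rectangular-lobe PGSE with separation Δ and duration δ.
    """
    if min(radius, d0, big_delta, small_delta) <= 0:
        raise ConfigurationError("radius, d0, timings must be positive")
    x = _sphere_bessel_roots(n_roots)
    alpha2 = (x / radius) ** 2
    lam = d0 * alpha2
    psi = 2 * small_delta - (
        2.0
        + np.exp(-lam * (big_delta - small_delta))
        - 2 * np.exp(-lam * small_delta)
        - 2 * np.exp(-lam * big_delta)
        + np.exp(-lam * (big_delta + small_delta))
    ) / lam
    terms = psi / (alpha2**2 * (x**2 - 2.0))
    if not np.all(np.isfinite(terms)):
        raise ArithmeticError("GPD series produced non-finite terms")
    t_eff = big_delta - small_delta / 3.0
    gamma_g2 = b * B_SCALE / t_eff / small_delta**2
    return float(-2.0 * gamma_g2 / d0 * terms.sum())


def gpd_sphere_adc(
    radius: float,
    d0: float,
    big_delta: float,
    small_delta: float,
    b: float = 1000.0,
    n_roots: int = 30,
) -> float:
    """Analytic (GPD) sphere ADC in µm²/ms at weighting ``b`` (s/mm²)."""
    ln_e = gpd_sphere_attenuation(radius, d0, big_delta, small_delta, b, n_roots)
    return -ln_e / (b * B_SCALE)
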