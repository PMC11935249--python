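"""Simplified stochastic proton transport engine.

Each history samples an individual range from the straggling distribution
and an initial lateral position, then steps through the density grid
depositing energy bookkept exactly from the Bragg-Kleeman range-energy
relation, with Highland angular diffusion applied per step.  A small,
configurable fraction of histories is rerouted to a wide-Gaussian lateral
halo (a crude surrogate for nuclear out-scatter) so that narrow fields
develop the low-dose envelope that the analytical engine lacks, while
broad-field doses agree between engines by construction.

Per step the engine scores dose-to-water and dose x LET, where LET is the
transported proton's own residual-range LET (track-local, unrestricted
stopping power in water); voxelwise dose-averaged LET is then the ratio
of the weighted accumulations (``combine_letd``).  Batch bookkeeping
yields a statistical-uncertainty estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy import sparse

from . import physics
from .pencilbeam import (DOSE_UNIT_SCALE, DoseColumn, PBParams, Spot,
                         check_scenario)
from .phantom import BeamConfig, DensityMap, VoxelGrid


@dataclass(frozen=True)
class MCParams:
    """Monte Carlo engine parameters (shared geometry fields mirror PBParams)."""

    sigma_initial_mm: float = 4.0
    cutoff_rel: float = 1e-4
    energy_limits_mev: tuple[float, float] = (70.0, 230.0)
    step_mm: float | None = None
    rbe_constant: float = 1.1
    halo_fraction: float = 0.005
    halo_sigma_scale: float = 5.0
    n_batches: int = 2
    min_scatter_energy_mev: float = 3.0


@dataclass
class ScoredColumn:
    """Per-spot MC scores: dose, dose x LET, batches, history count."""

    indices: np.ndarray
    values: np.ndarray            # dose, Gy(RBE) per weight unit
    dose_let: np.ndarray          # Gy(RBE) * keV/um per weight unit
    batch_values: np.ndarray      # (n_batches, nnz) per-batch dose estimates
    n_histories: int
    engine: str = "mc"
    scenario: str = "nominal"
    spot_id: int = -1

    def __post_init__(self):
        if np.any(self.values < 0) or np.any(self.dose_let < 0):
            raise ValueError("scored columns must be nonnegative")

    def to_dose_column(self) -> DoseColumn:
        return DoseColumn(self.indices, self.values, self.engine, self.scenario,
                          self.spot_id)

    def to_dense(self, n_voxels: int) -> np.ndarray:
        out = np.zeros(n_voxels)
        out[self.indices] = self.values
        return out


# ---------------------------------------------------------------------------
# lookup tables (uniform residual-range grid) and the transport kernel


def _residual_tables(energy_mev: float, tables: physics.PhysicsTables,
                     min_scatter_energy: float):
    """Uniform-grid lookups vs residual range.

    Returns (dr, E(r), S(r), LET(r), T(r)): energy, stopping power, LET
    and Highland scattering power on a uniform residual-range grid.
    """
    r_max = float(physics.range_from_energy(energy_mev, tables)) * 1.1 + 1.0
    dr = 0.005  # cm
    r = np.arange(0.0, r_max + dr, dr)
    e = physics.energy_from_range(np.maximum(r, 1e-12), tables)
    s = physics.stopping_power(np.maximum(e, 1e-3), tables)
    let = physics.let_vs_residual_range(r, tables)
    t_pow = physics.scattering_power(np.maximum(e, min_scatter_energy), 1.0)
    return dr, e, s, let, t_pow


_TABLE_CACHE: dict = {}


def _cached_residual_tables(energy_mev, tables, min_scatter_energy):
    key = (round(float(energy_mev), 6), id(tables), min_scatter_energy)
    if key not in _TABLE_CACHE:
        if len(_TABLE_CACHE) > 512:
            _TABLE_CACHE.clear()
        _TABLE_CACHE[key] = _residual_tables(energy_mev, tables, min_scatter_energy)
    return _TABLE_CACHE[key]


@njit(cache=True, inline="always")
def _lut(tab, dr, r):
    x = r / dr
    i = int(x)
    if i >= tab.shape[0] - 1:
        return tab[-1]
    f = x - i
    return tab[i] * (1.0 - f) + tab[i + 1] * f


@njit(cache=True, fastmath=True)
def _transport_kernel(density, origin, spacing, dims, lo, hi,
                      ray_origin, ray_dir, u_ax, v_ax,
                      r0_cm, sig_r_cm, sigma_i_mm, halo_frac, halo_scale,
                      range_scale, n_hist, seed, step_mm,
                      dr, e_tab, s_tab, let_tab, t_tab,
                      weight_scale, out_dose, out_dlet, out_batch):
    np.random.seed(seed)
    nb = out_batch.shape[0]
    nx, ny, nz = dims[0], dims[1], dims[2]
    inv_sx = 1.0 / spacing[0]
    inv_sy = 1.0 / spacing[1]
    inv_sz = 1.0 / spacing[2]
    # voxel index = int(pos - lower_corner) * inv_spacing, via +2/-2 so that
    # plain int() truncation acts as floor for slightly negative values
    cx = origin[0] - 0.5 * spacing[0]
    cy = origin[1] - 0.5 * spacing[1]
    cz = origin[2] - 0.5 * spacing[2]
    inv_dr = 1.0 / dr
    n_tab = e_tab.shape[0]
    escaped_mev = 0.0
    for h in range(n_hist):
        s_lat = sigma_i_mm
        if np.random.random() < halo_frac:
            s_lat = sigma_i_mm * halo_scale
        du = s_lat * np.random.normal()
        dv = s_lat * np.random.normal()
        x = ray_origin[0] + du * u_ax[0] + dv * v_ax[0]
        y = ray_origin[1] + du * u_ax[1] + dv * v_ax[1]
        z = ray_origin[2] + du * u_ax[2] + dv * v_ax[2]
        ddx, ddy, ddz = ray_dir[0], ray_dir[1], ray_dir[2]
        r = r0_cm + sig_r_cm * np.random.normal()
        if r <= 0.0:
            continue
        # advance to the grid box along the initial direction
        t_in = -1.0e30
        t_out = 1.0e30
        ok = True
        for a in range(3):
            if a == 0:
                da, pa = ddx, x
            elif a == 1:
                da, pa = ddy, y
            else:
                da, pa = ddz, z
            if abs(da) < 1e-12:
                if pa < lo[a] or pa > hi[a]:
                    ok = False
                    break
            else:
                t1 = (lo[a] - pa) / da
                t2 = (hi[a] - pa) / da
                if t1 > t2:
                    t1, t2 = t2, t1
                if t1 > t_in:
                    t_in = t1
                if t2 < t_out:
                    t_out = t2
        if not ok or t_in >= t_out:
            escaped_mev += _lut(e_tab, dr, r)
            continue
        if t_in > 0.0:
            x += ddx * t_in
            y += ddy * t_in
            z += ddz * t_in
        b = h % nb
        th2_acc = 0.0
        kick_count = 0
        while r > 0.0:
            # score each step segment at its midpoint so deposits never sit
            # on a voxel boundary (steps are exactly half a voxel)
            mx = x + 0.5 * step_mm * ddx
            my = y + 0.5 * step_mm * ddy
            mz = z + 0.5 * step_mm * ddz
            ix = int((mx - cx) * inv_sx + 2.0) - 2
            iy = int((my - cy) * inv_sy + 2.0) - 2
            iz = int((mz - cz) * inv_sz + 2.0) - 2
            inside = (0 <= ix < nx) and (0 <= iy < ny) and (0 <= iz < nz)
            if not inside:
                # left the box: the remaining energy escapes
                if (mx < lo[0] - spacing[0] or mx > hi[0] + spacing[0]
                        or my < lo[1] - spacing[1] or my > hi[1] + spacing[1]
                        or mz < lo[2] - spacing[2] or mz > hi[2] + spacing[2]):
                    escaped_mev += _lut(e_tab, dr, r)
                    break
                rho = 1e-3 * range_scale
            else:
                rho = density[ix, iy, iz] * range_scale
            wstep = rho * step_mm * 0.1
            if wstep >= r:
                de = _lut(e_tab, dr, r)
                r_mid = 0.5 * r
                r_new = 0.0
                if inside and de > 0.0:
                    dep = de / rho * weight_scale
                    fi = (ix * ny + iy) * nz + iz
                    out_dose[fi] += dep
                    out_dlet[fi] += dep * _lut(let_tab, dr, r_mid)
                    out_batch[b, fi] += dep
                break
            # midpoint-rule energy loss: one shared table index for S, LET
            # and the scattering power
            r_mid = r - 0.5 * wstep
            xi = r_mid * inv_dr
            i0 = int(xi)
            if i0 >= n_tab - 1:
                i0 = n_tab - 2
            f = xi - i0
            s_val = s_tab[i0] * (1.0 - f) + s_tab[i0 + 1] * f
            de = s_val * wstep
            r_new = r - wstep
            if inside:
                dep = de / rho * weight_scale
                fi = (ix * ny + iy) * nz + iz
                out_dose[fi] += dep
                out_dlet[fi] += dep * (let_tab[i0] * (1.0 - f) + let_tab[i0 + 1] * f)
                out_batch[b, fi] += dep
            r = r_new
            # Highland angular diffusion: variance accumulated over a few
            # substeps per applied kick (diffusion-equivalent, cheaper RNG)
            th2_acc += (t_tab[i0] * (1.0 - f) + t_tab[i0 + 1] * f) * rho * step_mm * 0.1
            kick_count += 1
            if kick_count >= 4 and th2_acc > 0.0:
                th = np.sqrt(th2_acc)
                th2_acc = 0.0
                kick_count = 0
                # perpendicular frame (ddz never ~1 for coplanar beams, but
                # guard anyway)
                if abs(ddz) < 0.9:
                    p1x, p1y, p1z = -ddy, ddx, 0.0
                else:
                    p1x, p1y, p1z = 0.0, -ddz, ddy
                n1 = np.sqrt(p1x * p1x + p1y * p1y + p1z * p1z)
                p1x /= n1
                p1y /= n1
                p1z /= n1
                p2x = ddy * p1z - ddz * p1y
                p2y = ddz * p1x - ddx * p1z
                p2z = ddx * p1y - ddy * p1x
                g1 = th * np.random.normal()
                g2 = th * np.random.normal()
                ddx += g1 * p1x + g2 * p2x
                ddy += g1 * p1y + g2 * p2y
                ddz += g1 * p1z + g2 * p2z
                nrm = np.sqrt(ddx * ddx + ddy * ddy + ddz * ddz)
                ddx /= nrm
                ddy /= nrm
                ddz /= nrm
            x += ddx * step_mm
            y += ddy * step_mm
            z += ddz * step_mm
    return escaped_mev


def spot_seed(master_seed: int, spot_id: int) -> int:
    """Counter-style per-spot stream key: independent and order-free."""
    return int((int(master_seed) * 1000003 + 7919 * int(spot_id) + 1) % (2**31 - 1))


def _run_spot(spot: Spot, beam: BeamConfig, grid: VoxelGrid, density: DensityMap,
              scenario, tables: physics.PhysicsTables, n_histories: int, seed: int,
              params: MCParams, weight: float,
              out_dose, out_dlet, out_batch) -> float:
    lo_e, hi_e = params.energy_limits_mev
    if not lo_e <= spot.energy_mev <= hi_e:
        raise ValueError("spot energy outside machine limits")
    step = params.step_mm or min(grid.spacing) / 2.0
    u_ax, v_ax = beam.bev_axes
    d = beam.direction
    iso = np.asarray(beam.isocenter_mm, float) + np.asarray(scenario.setup_shift_mm, float)
    ray_origin = iso + spot.u_mm * u_ax + spot.v_mm * v_ax - 300.0 * d
    r0 = float(physics.range_from_energy(spot.energy_mev, tables))
    sig_r = float(physics.sigma_range(spot.energy_mev, tables))
    dr, e_tab, s_tab, let_tab, t_tab = _cached_residual_tables(
        spot.energy_mev, tables, params.min_scatter_energy_mev
    )
    lo, hi = grid.world_bounds()
    # deposit -> dose-to-water: de / (rho * V_mm3 * 1e-3 g/mm3) MeV/g
    vox_mm3 = float(np.prod(grid.spacing))
    weight_scale = (weight * DOSE_UNIT_SCALE * params.rbe_constant * 1e3
                    / (n_histories * vox_mm3))
    return _transport_kernel(
        density.values, np.asarray(grid.origin, float), np.asarray(grid.spacing, float),
        np.asarray(grid.dims, np.int64), lo, hi,
        ray_origin, d, u_ax, v_ax,
        r0, sig_r, params.sigma_initial_mm, params.halo_fraction,
        params.halo_sigma_scale, scenario.range_scale,
        n_histories, seed, step,
        dr, e_tab, s_tab, let_tab, t_tab,
        weight_scale, out_dose, out_dlet, out_batch,
    )


def mc_beamlet_transport(spot: Spot, beam: BeamConfig, grid: VoxelGrid,
                         density: DensityMap, scenario, tables: physics.PhysicsTables,
                         n_histories: int, seed: int,
                         params: MCParams = MCParams()) -> ScoredColumn:
    """Transport one spot's histories; return its sparse scored column.

    Reproducible: the same (seed, n_histories) give bitwise-identical
    columns.  Estimates are unbiased in the history count; the sparsity
    cutoff (relative to the column max) matches the analytical engine's.
    """
    if n_histories < 100:
        raise ValueError("need at least 100 histories per spot")
    check_scenario(scenario)
    n_vox = grid.n_voxels
    out_dose = np.zeros(n_vox)
    out_dlet = np.zeros(n_vox)
    out_batch = np.zeros((params.n_batches, n_vox))
    _run_spot(spot, beam, grid, density, scenario, tables, n_histories, seed,
              params, 1.0, out_dose, out_dlet, out_batch)
    if out_dose.max() > 0:
        keep = np.flatnonzero(out_dose >= params.cutoff_rel * out_dose.max())
    else:
        keep = np.empty(0, np.int64)
    return ScoredColumn(
        indices=keep.astype(np.int64),
        values=out_dose[keep],
        dose_let=out_dlet[keep],
        batch_values=out_batch[:, keep].copy(),
        n_histories=int(n_histories),
        scenario=scenario.label,
        spot_id=spot.id,
    )


def mc_plan_dose(spots, weights, beams, grid: VoxelGrid, density: DensityMap,
                 scenario, tables: physics.PhysicsTables,
                 n_histories_per_spot: int, seed: int,
                 params: MCParams = MCParams(), n_batches: int = 5,
                 weight_skip_rel: float = 1e-6):
    """Recalculate a whole plan: weighted accumulation over all spots.

    Returns dense (dose, dose_let, batch) arrays in Gy(RBE) (and
    Gy(RBE).keV/um); spots whose weight is below ``weight_skip_rel`` times
    the largest weight contribute nothing and are skipped.
    """
    if n_histories_per_spot < 100:
        raise ValueError("need at least 100 histories per spot")
    check_scenario(scenario)
    weights = np.asarray(weights, float)
    if weights.shape != (len(spots),):
        raise ValueError("one weight per spot required")
    if np.any(weights < 0):
        raise ValueError("weights must be nonnegative")
    n_vox = grid.n_voxels
    out_dose = np.zeros(n_vox)
    out_dlet = np.zeros(n_vox)
    out_batch = np.zeros((n_batches, n_vox))
    w_floor = weight_skip_rel * (weights.max() if weights.size else 0.0)
    for spot, w in zip(spots, weights):
        if w <= w_floor:
            continue
        _run_spot(spot, beams[spot.beam_index], grid, density, scenario, tables,
                  n_histories_per_spot, spot_seed(seed, spot.id), params, float(w),
                  out_dose, out_dlet, out_batch)
    return out_dose, out_dlet, out_batch


def mc_uncertainty(column_or_batches, dose=None) -> float:
    """Batch-based mean relative standard error in high-dose voxels.

    Accepts a :class:`ScoredColumn` (its stored batches) or a raw
    (n_batches, n) batch array together with the total dose.  Per-batch
    estimates are n_batches * batch sums; the SE of their mean is averaged
    over voxels above 50% of the maximum dose.  Scales as 1/sqrt(N).
    """
    if isinstance(column_or_batches, ScoredColumn):
        batches = column_or_batches.batch_values
        dose = column_or_batches.values
    else:
        batches = np.asarray(column_or_batches)
        if dose is None:
            raise ValueError("dose array required with raw batches")
    nb = batches.shape[0]
    if nb < 2:
        raise ValueError("uncertainty needs at least two independent batches")
    dose = np.asarray(dose, float)
    hot = dose > 0.5 * dose.max()
    if not np.any(hot):
        raise ValueError("no voxels above half the maximum dose")
    est = nb * batches[:, hot]
    se = est.std(axis=0, ddof=1) / np.sqrt(nb)
    return float(np.mean(se / dose[hot]))


def combine_letd(dose_columns, dose_let_columns, weights,
                 dose_floor: float = 1e-12):
    """Dose-averaged LET map from influence columns and spot weights.

    LET_d(i) = sum_j w_j c_ij / sum_j w_j d_ij with c = dose x LET and
    d = dose; voxels whose total dose is below ``dose_floor`` (relative to
    the map maximum) get LET_d = 0 and are flagged.

    Accepts scipy sparse matrices (n_voxels x n_spots) or equal-length
    lists of ScoredColumns' dense vectors.  Returns (letd, zero_flag).
    """
    w = np.asarray(weights, float)
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    if sparse.issparse(dose_columns):
        if dose_columns.shape != dose_let_columns.shape:
            raise ValueError("dose and dose x LET matrices must share a shape")
        d = np.asarray(dose_columns @ w).ravel()
        c = np.asarray(dose_let_columns @ w).ravel()
    else:
        d_mat = np.asarray(dose_columns, float)
        c_mat = np.asarray(dose_let_columns, float)
        if d_mat.shape != c_mat.shape:
            raise ValueError("mismatched column shapes")
        d = d_mat @ w
        c = c_mat @ w
    zero = d <= dose_floor * max(d.max(), 1e-300)
    letd = np.zeros_like(d)
    np.divide(c, d, out=letd, where=~zero)
    return letd, zero
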