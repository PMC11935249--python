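"""Analytical pencil-beam dose engine.

Each spot's dose column is the product of an integrated depth-dose (IDD)
looked up at the water-equivalent depth along the spot's *central ray
only*, and a single-Gaussian lateral kernel whose width combines the
initial spot size with Fermi-Eyges accumulated multiple-scattering.  The
engine deliberately carries the classic limitations of its algorithm
family: heterogeneity is handled through the central-axis radiological
depth alone, the lateral model has no nuclear low-dose halo, and range
straggling is a fixed water-computed width.  These limitations are the
mechanism by which this engine disagrees with the stochastic engine for
narrow or distally patched fields while agreeing for broad flat fields.

Dose is reported as dose-to-water times the constant RBE, per unit spot
weight (one weight unit = 1e9 protons).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from . import physics
from .phantom import BeamConfig, DensityMap, VoxelGrid

#: Gy per MeV/g
GY_PER_MEV_PER_G = 1.602176634e-10
#: protons delivered by one spot-weight unit
PROTONS_PER_WEIGHT = 1.0e9
#: Gy(RBE) per (MeV/g per proton) at RBE 1.1 and one weight unit
DOSE_UNIT_SCALE = GY_PER_MEV_PER_G * PROTONS_PER_WEIGHT


@dataclass(frozen=True)
class Spot:
    """One scanned beamlet: beam index, energy, lateral offsets in BEV, id."""

    beam_index: int
    energy_mev: float
    u_mm: float
    v_mm: float
    id: int


@dataclass
class DoseColumn:
    """Sparse per-voxel dose at unit spot weight, Gy(RBE)."""

    indices: np.ndarray  # flat voxel indices (C order over grid dims)
    values: np.ndarray
    engine: str
    scenario: str
    spot_id: int

    def __post_init__(self):
        if np.any(~np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("dose column must be finite and nonnegative")

    def to_dense(self, n_voxels: int) -> np.ndarray:
        out = np.zeros(n_voxels)
        out[self.indices] = self.values
        return out


@dataclass(frozen=True)
class PBParams:
    """Pencil-beam engine parameters."""

    sigma_initial_mm: float = 4.0
    cutoff_rel: float = 1e-4
    energy_limits_mev: tuple[float, float] = (70.0, 230.0)
    step_mm: float | None = None  # default: half the smallest voxel dimension
    lateral_cut_sigmas: float = 4.5
    rbe_constant: float = 1.1


def check_scenario(scenario) -> None:
    """Validate the shared scenario contract used by both engines."""
    shift = np.asarray(scenario.setup_shift_mm, float)
    if shift.shape != (3,) or np.any(np.abs(shift) > 10.0):
        raise ValueError("setup shift must be a triple within +/-10 mm per axis")
    if not 0.9 <= scenario.range_scale <= 1.1:
        raise ValueError("range scale must lie in [0.9, 1.1]")


# ---------------------------------------------------------------------------
# integrated depth dose


@dataclass
class DepthDoseCurve:
    """Pristine-peak IDD: energy deposited per unit water-equivalent depth.

    Units MeV/cm per proton; the area under the curve equals the initial
    kinetic energy (the lateral-integrated dose at any depth is the IDD
    value, which at shallow depth equals the plateau stopping power).
    """

    energy_mev: float
    z_cm: np.ndarray
    idd_mev_cm: np.ndarray
    _cum: np.ndarray | None = None

    def __call__(self, z_cm):
        return np.interp(z_cm, self.z_cm, self.idd_mev_cm, left=0.0, right=0.0)

    def averaged(self, w_lo_cm, w_hi_cm):
        """Mean IDD over a WEPL interval (voxel depth averaging).

        Uses the cumulative deposited energy so that a voxel straddling
        the peak scores its true mean, matching what a stochastic engine
        scores by binning deposits into voxels.
        """
        if self._cum is None:
            self._cum = np.concatenate([[0.0], np.cumsum(
                0.5 * (self.idd_mev_cm[1:] + self.idd_mev_cm[:-1])
                * np.diff(self.z_cm))])
        cum = self._cum
        g_hi = np.interp(w_hi_cm, self.z_cm, cum, left=0.0, right=cum[-1])
        g_lo = np.interp(w_lo_cm, self.z_cm, cum, left=0.0, right=cum[-1])
        width = np.maximum(w_hi_cm - w_lo_cm, 1e-9)
        return (g_hi - g_lo) / width

    @property
    def peak_z_cm(self) -> float:
        return float(self.z_cm[np.argmax(self.idd_mev_cm)])

    def distal_width_at(self, frac: float = 0.8) -> float:
        """Full width (cm) of the region where IDD >= frac * max."""
        above = self.idd_mev_cm >= frac * self.idd_mev_cm.max()
        zs = self.z_cm[above]
        return float(zs[-1] - zs[0])


def pb_depth_dose(energy_mev: float, tables: physics.PhysicsTables,
                  energy_limits_mev: tuple[float, float] = (70.0, 230.0),
                  dz_cm: float = 0.02) -> DepthDoseCurve:
    """Integrated depth-dose of a pristine Bragg peak in water.

    The Bragg-Kleeman stopping profile s(r) = E'(r) (with its integrable
    singularity at the end of range) is averaged over a Gaussian range
    distribution N(R(E), sigma_R):

        IDD(z) = E[ s(R' - z) ; R' > z ],   R' ~ N(R, sigma_R).

    Evaluated by quadrature after substituting r = t^2, which removes the
    end-of-range singularity.  The integral of IDD over depth equals the
    initial energy (convolution conserves the deposited energy).
    """
    lo, hi = energy_limits_mev
    if not lo <= energy_mev <= hi:
        raise ValueError(f"energy {energy_mev} MeV outside machine limits {energy_limits_mev}")
    r0 = float(physics.range_from_energy(energy_mev, tables))
    sig = float(physics.sigma_range(energy_mev, tables))
    z = np.arange(0.0, r0 + 6.0 * sig, dz_cm)
    # s(r) = r^(1/p - 1) / (alpha^(1/p) p); with r = t^2, 2 t s(t^2) is smooth
    t = np.linspace(1e-6, np.sqrt(r0 + 8.0 * sig), 600)
    p, a = tables.p, tables.alpha
    smooth = 2.0 * t ** (2.0 / p - 1.0) / (a ** (1.0 / p) * p)
    gauss = np.exp(-((z[:, None] + t[None, :] ** 2 - r0) ** 2) / (2.0 * sig**2)) / (
        np.sqrt(2.0 * np.pi) * sig
    )
    idd = np.trapezoid(smooth[None, :] * gauss, t, axis=1)
    return DepthDoseCurve(energy_mev, z, idd)


@lru_cache(maxsize=256)
def _cached_idd(energy_mev: float, alpha: float, p: float, frac: float,
                lo: float, hi: float) -> DepthDoseCurve:
    tables = physics.PhysicsTables(alpha=alpha, p=p, straggling_fraction=frac)
    return pb_depth_dose(energy_mev, tables, (lo, hi))


def get_idd(energy_mev: float, tables: physics.PhysicsTables,
            params: PBParams) -> DepthDoseCurve:
    lo, hi = params.energy_limits_mev
    return _cached_idd(float(energy_mev), tables.alpha, tables.p,
                       tables.straggling_fraction, float(lo), float(hi))


# ---------------------------------------------------------------------------
# ray marching and Fermi-Eyges lateral width


def ray_entry_exit(grid: VoxelGrid, origin_mm: np.ndarray, direction: np.ndarray):
    """Parameter interval [t_in, t_out] (mm) of a ray inside the grid box."""
    lo, hi = grid.world_bounds()
    t_in, t_out = -np.inf, np.inf
    for a in range(3):
        d = direction[a]
        if abs(d) < 1e-12:
            if not lo[a] <= origin_mm[a] <= hi[a]:
                return None
            continue
        t1 = (lo[a] - origin_mm[a]) / d
        t2 = (hi[a] - origin_mm[a]) / d
        t_in = max(t_in, min(t1, t2))
        t_out = min(t_out, max(t1, t2))
    if t_in >= t_out:
        return None
    return float(t_in), float(t_out)


def march_central_ray(grid: VoxelGrid, density: DensityMap, origin_mm: np.ndarray,
                      direction: np.ndarray, step_mm: float, range_scale: float = 1.0):
    """Sample density along a ray (nearest voxel) and accumulate WEPL.

    Returns (t_mm, wepl_cm, rho) at sample midpoints; t is measured from
    ``origin_mm`` along ``direction``; densities include the range-scale
    multiplier.
    """
    span = ray_entry_exit(grid, origin_mm, direction)
    if span is None:
        return None
    t_in, t_out = span
    n = max(int(np.ceil((t_out - t_in) / step_mm)), 1)
    t = t_in + (np.arange(n) + 0.5) * step_mm
    pts = origin_mm[None, :] + t[:, None] * direction[None, :]
    idx = np.round((pts - np.asarray(grid.origin)) / np.asarray(grid.spacing)).astype(int)
    inside = np.all((idx >= 0) & (idx < np.asarray(grid.dims)), axis=1)
    rho = np.full(n, 1e-3)
    ii = idx[inside]
    rho[inside] = density.values[ii[:, 0], ii[:, 1], ii[:, 2]]
    rho = rho * range_scale
    # WEPL evaluated at sample midpoints (half-step trapezoid)
    wepl = (np.cumsum(rho) - 0.5 * rho) * (step_mm / 10.0)  # cm of water
    return t, wepl, rho


def fermi_eyges_sigma(t_mm: np.ndarray, rho: np.ndarray, wepl_cm: np.ndarray,
                      energy_mev: float, tables: physics.PhysicsTables,
                      step_mm: float) -> np.ndarray:
    """Accumulated multiple-scattering lateral sigma (mm) at each sample.

    sigma^2(t) = integral_0^t T(E(t'), rho(t')) (t - t')^2 dt' evaluated
    with cumulative sums; T is the Highland scattering power and E(t') the
    residual-range energy along the central axis (clamped at 3 MeV).
    """
    r0 = float(physics.range_from_energy(energy_mev, tables))
    residual = np.maximum(r0 - wepl_cm, 0.0)
    e_local = physics.energy_from_range(np.maximum(residual, 1e-9), tables)
    e_local = np.maximum(e_local, 3.0)
    t_power = physics.scattering_power(e_local, rho)  # rad^2/cm
    t_power = np.where(residual > 0, t_power, 0.0)
    dt_cm = step_mm / 10.0
    # sigma^2(t_j) = sum_k T_k dt (t_j - t_k)^2, expanded into cumsums (mm^2)
    tk = t_mm
    c0 = np.cumsum(t_power * dt_cm)
    c1 = np.cumsum(t_power * dt_cm * tk)
    c2 = np.cumsum(t_power * dt_cm * tk**2)
    sig2 = tk**2 * c0 - 2.0 * tk * c1 + c2
    return np.sqrt(np.maximum(sig2, 0.0))


@lru_cache(maxsize=8)
def _grid_points(grid: VoxelGrid) -> np.ndarray:
    xs, ys, zs = np.meshgrid(*(grid.axis_centers(a) for a in range(3)), indexing="ij")
    return np.column_stack([xs.ravel(), ys.ravel(), zs.ravel()])


# ---------------------------------------------------------------------------
# beamlet dose


def pb_beamlet_dose(spot: Spot, beam: BeamConfig, grid: VoxelGrid,
                    density: DensityMap, scenario, tables: physics.PhysicsTables,
                    params: PBParams = PBParams(),
                    voxel_subset: np.ndarray | None = None) -> DoseColumn:
    """Dose column of one spot at unit weight under one scenario.

    The scenario shifts the beam isocenter rigidly (setup error) and
    scales the density (range error).  ``voxel_subset`` optionally
    restricts scoring to a flat-index subset of voxels (used to keep
    perturbed-scenario influence small); the sparsity cutoff is relative
    to the full column maximum either way.
    """
    check_scenario(scenario)
    lo, hi = params.energy_limits_mev
    if not lo <= spot.energy_mev <= hi:
        raise ValueError("spot energy outside machine limits")
    step = params.step_mm or min(grid.spacing) / 2.0
    u_ax, v_ax = beam.bev_axes
    d = beam.direction
    iso = np.asarray(beam.isocenter_mm, float) + np.asarray(scenario.setup_shift_mm, float)
    origin = iso + spot.u_mm * u_ax + spot.v_mm * v_ax

    marched = march_central_ray(grid, density, origin, d, step, scenario.range_scale)
    if marched is None:
        return DoseColumn(np.empty(0, np.int64), np.empty(0), "pb", scenario.label, spot.id)
    t_s, wepl_s, rho_s = marched
    idd = get_idd(spot.energy_mev, tables, params)
    sig_mcs = fermi_eyges_sigma(t_s, rho_s, wepl_s, spot.energy_mev, tables, step)
    sig_s = np.sqrt(params.sigma_initial_mm**2 + sig_mcs**2)

    pts = _grid_points(grid)
    if voxel_subset is not None:
        flat = np.asarray(voxel_subset, np.int64)
        pts = pts[flat]
    else:
        flat = None

    rel = pts - origin
    t = rel @ d
    lat2 = np.einsum("ij,ij->i", rel, rel) - t**2
    sig_max = float(sig_s.max())
    r_end = float(physics.range_from_energy(spot.energy_mev, tables))
    sig_r = float(physics.sigma_range(spot.energy_mev, tables))
    # depth beyond which the IDD is numerically zero
    wepl_max = r_end + 6.0 * sig_r
    cand = (t >= t_s[0] - step) & (lat2 <= (params.lateral_cut_sigmas * sig_max) ** 2)
    if not np.any(cand):
        return DoseColumn(np.empty(0, np.int64), np.empty(0), "pb", scenario.label, spot.id)

    spacing = np.asarray(grid.spacing)
    # voxel half-extent projected on the beam axis and the two BEV axes
    half_t = 0.5 * float(np.abs(d) @ spacing)
    half_u = max(0.5 * float(np.abs(u_ax) @ spacing), 1e-6)
    half_v = max(0.5 * float(np.abs(v_ax) @ spacing), 1e-6)

    tc = t[cand]
    wepl_c = np.interp(tc, t_s, wepl_s, left=0.0)
    ok = wepl_c <= wepl_max
    tc = tc[ok]
    relc = rel[cand][ok]
    sig_c = np.interp(tc, t_s, sig_s)
    w_lo = np.interp(tc - half_t, t_s, wepl_s, left=0.0)
    w_hi = np.interp(tc + half_t, t_s, wepl_s, left=0.0)
    idd_c = idd.averaged(w_lo, w_hi)  # MeV/cm water-equivalent, voxel-mean

    # voxel-averaged lateral Gaussian via erf integrals in the BEV frame
    from scipy.special import erf

    uc = relc @ u_ax
    vc = relc @ v_ax
    s2 = sig_c * np.sqrt(2.0)
    lat_u = 0.5 * (erf((uc + half_u) / s2) - erf((uc - half_u) / s2)) / (2.0 * half_u)
    lat_v = 0.5 * (erf((vc + half_v) / s2) - erf((vc - half_v) / s2)) / (2.0 * half_v)
    # dose-to-water per proton: (IDD/10 MeV per mm WEPL) * lateral density
    # (1/mm^2) / (1e-3 g/mm^3); the medium density cancels in dose-to-water
    dose = idd_c / 10.0 * lat_u * lat_v / 1e-3  # MeV/g per proton
    dose *= DOSE_UNIT_SCALE * params.rbe_constant  # Gy(RBE) per weight unit

    keep = dose >= params.cutoff_rel * dose.max() if dose.size else np.zeros(0, bool)
    idx_local = np.flatnonzero(cand)
    idx_local = idx_local[ok][keep]
    values = dose[keep]
    indices = idx_local if flat is None else flat[idx_local]
    return DoseColumn(indices.astype(np.int64), values, "pb", scenario.label, spot.id)
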