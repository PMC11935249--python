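"""Spot placement, uncertainty scenarios, and influence assembly.

Spots are placed per beam over the scanning target volume (STV): energy
layers span the water-equivalent depth interval of the STV along the beam
with a spacing tied to the pristine peak's width at 80% of its maximum,
and each layer carries a square lateral grid of spots at 1.5 x the initial
spot sigma, restricted to lateral positions that actually see STV voxels
near that layer's depth.  The robust-scenario set is the standard nominal
+ eight composition: +/- setup shifts along each axis and +/- range scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, sparse
from scipy.spatial import cKDTree

from . import physics
from .montecarlo import MCParams, mc_beamlet_transport, spot_seed
from .pencilbeam import (PBParams, Spot, check_scenario, march_central_ray,
                         get_idd, pb_beamlet_dose)
from .phantom import BeamConfig, DensityMap, StructureSet, VoxelGrid


@dataclass(frozen=True)
class Scenario:
    """One uncertainty scenario: rigid setup shift and range scaling."""

    setup_shift_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    range_scale: float = 1.0
    label: str = "nominal"

    def validate(self) -> None:
        check_scenario(self)

    @property
    def is_nominal(self) -> bool:
        return all(s == 0 for s in self.setup_shift_mm) and self.range_scale == 1.0


def make_scenarios(setup_mm: float, range_pct: float) -> list[Scenario]:
    """Nominal + eight perturbed scenarios (setup +/- each axis, range +/-)."""
    if setup_mm < 0 or range_pct < 0:
        raise ValueError("scenario magnitudes must be nonnegative")
    out = [Scenario()]
    axes = ("x", "y", "z")
    for a in range(3):
        for sign, tag in ((1.0, "+"), (-1.0, "-")):
            shift = [0.0, 0.0, 0.0]
            shift[a] = sign * setup_mm
            out.append(Scenario(tuple(shift), 1.0, f"setup{axes[a]}{tag}{setup_mm:g}mm"))
    for sign, tag in ((1.0, "+"), (-1.0, "-")):
        out.append(Scenario((0.0, 0.0, 0.0), 1.0 + sign * range_pct / 100.0,
                            f"range{tag}{range_pct:g}pct"))
    return out


@dataclass(frozen=True)
class SpotSpacing:
    """Spot-placement parameters.

    Lateral spacing is ``lateral_factor`` times the initial spot sigma;
    energy-layer spacing is the width of the deepest pristine peak above
    80% of its maximum (floored at ``min_layer_spacing_mm``).
    """

    sigma_initial_mm: float = 4.0
    lateral_factor: float = 1.5
    min_layer_spacing_mm: float = 2.0

    @property
    def lateral_spacing_mm(self) -> float:
        return self.lateral_factor * self.sigma_initial_mm


def stv_wepl_and_lateral(stv_mask: np.ndarray, beam: BeamConfig, grid: VoxelGrid,
                         density: DensityMap, step_mm: float = 1.0):
    """Per-STV-voxel water-equivalent depth and BEV lateral coordinates.

    WEPL is accumulated by sampling the density (trilinear) backwards from
    each voxel center to the grid boundary along the beam axis.
    """
    idx = np.argwhere(stv_mask)
    if idx.size == 0:
        raise ValueError("empty STV mask")
    pts = np.asarray(grid.origin) + idx * np.asarray(grid.spacing)
    d = beam.direction
    u_ax, v_ax = beam.bev_axes
    iso = np.asarray(beam.isocenter_mm, float)
    rel = pts - iso
    t = rel @ d
    u = rel @ u_ax
    v = rel @ v_ax
    # march from the most upstream extent of the grid to each voxel
    lo, hi = grid.world_bounds()
    corners_t = np.array([
        (np.array([cx, cy, cz]) - iso) @ d
        for cx in (lo[0], hi[0]) for cy in (lo[1], hi[1]) for cz in (lo[2], hi[2])
    ])
    t_start = corners_t.min()
    n_steps = int(np.ceil((t.max() - t_start) / step_mm)) + 1
    ks = t_start + (np.arange(n_steps) + 0.5) * step_mm
    # sample positions: voxel lateral position, depth k along d
    samp = (iso[None, None, :] + u[:, None, None] * u_ax[None, None, :]
            + v[:, None, None] * v_ax[None, None, :]
            + ks[None, :, None] * d[None, None, :])
    coords = (samp - np.asarray(grid.origin)) / np.asarray(grid.spacing)
    rho = ndimage.map_coordinates(
        density.values, coords.reshape(-1, 3).T, order=1, mode="constant", cval=1e-3
    ).reshape(len(idx), n_steps)
    active = ks[None, :] < t[:, None]
    wepl = (rho * active).sum(axis=1) * step_mm / 10.0  # cm
    return idx, wepl, u, v


def place_spots(stv_mask: np.ndarray, beams: list[BeamConfig], grid: VoxelGrid,
                density: DensityMap, tables: physics.PhysicsTables,
                spacing: SpotSpacing = SpotSpacing(),
                energy_limits_mev: tuple[float, float] = (70.0, 230.0)) -> list[Spot]:
    """Place scanned spots covering the STV for every beam.

    Coverage contract: every STV voxel has a spot whose lateral position
    is within one lateral spacing and whose nominal peak depth is within
    one layer spacing of the voxel's WEPL.  Raises if any required energy
    exceeds the machine limits.
    """
    if not np.any(stv_mask):
        raise ValueError("empty STV mask")
    spots: list[Spot] = []
    sid = 0
    pb_params = PBParams(sigma_initial_mm=spacing.sigma_initial_mm,
                         energy_limits_mev=energy_limits_mev)
    for bi, beam in enumerate(beams):
        _, wepl, u, v = stv_wepl_and_lateral(stv_mask, beam, grid, density)
        w_min, w_max = float(wepl.min()), float(wepl.max())
        e_max_needed = float(physics.energy_from_range(w_max, tables))
        if e_max_needed > energy_limits_mev[1]:
            n_bad = int((physics.energy_from_range(wepl, tables) > energy_limits_mev[1]).sum())
            raise ValueError(
                f"beam {bi}: {n_bad} STV voxels beyond machine energy reach "
                f"(need {e_max_needed:.1f} MeV)")
        e_deep = max(e_max_needed, energy_limits_mev[0])
        layer_dw = max(
            10.0 * get_idd(e_deep, tables, pb_params).distal_width_at(0.8),
            spacing.min_layer_spacing_mm,
        )  # mm WEPL
        n_layers = max(int(np.ceil((w_max - w_min) * 10.0 / layer_dw)) + 1, 1)
        layers_w = w_min * 10.0 + np.arange(n_layers) * layer_dw  # mm WEPL

        duv = spacing.lateral_spacing_mm
        u_grid = np.arange(np.floor(u.min() / duv) - 1, np.ceil(u.max() / duv) + 2) * duv
        v_grid = np.arange(np.floor(v.min() / duv) - 1, np.ceil(v.max() / duv) + 2) * duv
        # voxel cloud in scaled (u, v, wepl) space; spots keep only lattice
        # nodes with an STV voxel within one spacing box
        cloud = np.column_stack([u / duv, v / duv, wepl * 10.0 / layer_dw])
        tree = cKDTree(cloud)
        uu, vv, ww = np.meshgrid(u_grid, v_grid, layers_w, indexing="ij")
        nodes = np.column_stack([uu.ravel() / duv, vv.ravel() / duv,
                                 ww.ravel() / layer_dw])
        hit = tree.query_ball_point(nodes, r=1.0, p=np.inf, return_length=True) > 0
        for (su, sv, sw), keep in zip(
            np.column_stack([uu.ravel(), vv.ravel(), ww.ravel()]), hit
        ):
            if not keep:
                continue
            energy = float(physics.energy_from_range(sw / 10.0, tables))
            energy = max(energy, energy_limits_mev[0])
            spots.append(Spot(bi, energy, float(su), float(sv), sid))
            sid += 1
    if not spots:
        raise ValueError("no spots placed")
    return spots


@dataclass
class InfluenceSet:
    """Per-engine beamlet influence: dose (and dose x LET) columns.

    ``matrices[label]`` is an (n_rows x n_spots) CSC matrix of dose per
    unit spot weight under that scenario.  Non-nominal scenarios may be
    restricted to a voxel subset (``row_subsets[label]`` holds the flat
    voxel indices of the rows; None means the full grid).  MC sets carry
    a dose x LET matrix for the nominal scenario.
    """

    engine: str
    spots: list[Spot]
    beams: list[BeamConfig]
    grid: VoxelGrid
    scenarios: list[Scenario]
    matrices: dict[str, sparse.csc_matrix]
    row_subsets: dict[str, np.ndarray | None]
    dose_let: sparse.csc_matrix | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def n_spots(self) -> int:
        return len(self.spots)

    def nominal(self) -> sparse.csc_matrix:
        return self.matrices["nominal"]

    def validate(self) -> None:
        for label, mat in self.matrices.items():
            if mat.shape[1] != self.n_spots:
                raise ValueError(f"scenario {label!r}: column count != spot count")
            if mat.nnz and mat.data.min() < 0:
                raise ValueError(f"scenario {label!r}: negative influence")

    def rows_for(self, label: str, flat_indices: np.ndarray) -> np.ndarray:
        """Map full-grid flat voxel indices to row numbers of a scenario."""
        subset = self.row_subsets.get(label)
        if subset is None:
            return np.asarray(flat_indices, np.int64)
        lookup = {int(f): i for i, f in enumerate(subset)}
        try:
            return np.array([lookup[int(f)] for f in flat_indices], np.int64)
        except KeyError as exc:
            raise KeyError(
                f"voxel {exc} not in the stored subset for scenario {label!r}"
            ) from exc


def _columns_to_csc(cols, n_rows, subset_lookup=None):
    data, rows, cptr = [], [], [0]
    for idx, vals in cols:
        if subset_lookup is not None:
            rows.append(subset_lookup[idx])
        else:
            rows.append(idx)
        data.append(vals)
        cptr.append(cptr[-1] + len(idx))
    data = np.concatenate(data) if data else np.empty(0)
    rows = np.concatenate(rows) if rows else np.empty(0, np.int64)
    return sparse.csc_matrix(
        (data.astype(np.float64), rows, np.asarray(cptr)), shape=(n_rows, len(cols))
    )


def assemble_influence(engine: str, spots: list[Spot], beams: list[BeamConfig],
                       grid: VoxelGrid, density: DensityMap,
                       scenarios: list[Scenario], tables: physics.PhysicsTables,
                       pb_params: PBParams = PBParams(),
                       mc_params: MCParams = MCParams(),
                       n_histories: int = 2000, seed: int = 0,
                       scenario_subset: np.ndarray | None = None) -> InfluenceSet:
    """Compute every (spot x scenario) dose column with one engine.

    ``scenario_subset`` (flat voxel indices) restricts *non-nominal*
    scenario columns to the voxels that robust objectives actually read;
    the nominal scenario is always stored on the full grid.  MC columns
    are reproducible given (seed, spot id) and include dose x LET for the
    nominal scenario.
    """
    if engine not in ("pb", "mc"):
        raise ValueError("engine must be 'pb' or 'mc'")
    n_vox = grid.n_voxels
    if scenario_subset is not None:
        scenario_subset = np.asarray(np.sort(scenario_subset), np.int64)
        sub_lookup = np.full(n_vox, -1, np.int64)
        sub_lookup[scenario_subset] = np.arange(scenario_subset.size)
    matrices: dict[str, sparse.csc_matrix] = {}
    row_subsets: dict[str, np.ndarray | None] = {}
    dose_let = None
    for scenario in scenarios:
        scenario.validate()
        restrict = scenario_subset if not scenario.is_nominal else None
        cols, let_cols = [], []
        for spot in spots:
            beam = beams[spot.beam_index]
            if engine == "pb":
                col = pb_beamlet_dose(spot, beam, grid, density, scenario, tables,
                                      pb_params, voxel_subset=restrict)
                idx, vals = col.indices, col.values
                if restrict is not None:
                    idx = sub_lookup[idx]
                cols.append((idx, vals))
            else:
                sc = mc_beamlet_transport(spot, beam, grid, density, scenario,
                                          tables, n_histories,
                                          spot_seed(seed, spot.id), mc_params)
                idx, vals, lvals = sc.indices, sc.values, sc.dose_let
                if restrict is not None:
                    keep = sub_lookup[idx] >= 0
                    idx, vals, lvals = sub_lookup[idx[keep]], vals[keep], lvals[keep]
                cols.append((idx, vals))
                if scenario.is_nominal:
                    let_cols.append((idx, lvals))
        n_rows = n_vox if restrict is None else scenario_subset.size
        matrices[scenario.label] = _columns_to_csc(cols, n_rows)
        row_subsets[scenario.label] = None if restrict is None else scenario_subset
        if engine == "mc" and scenario.is_nominal:
            dose_let = _columns_to_csc(let_cols, n_rows)
    out = InfluenceSet(
        engine=engine, spots=list(spots), beams=list(beams), grid=grid,
        scenarios=list(scenarios), matrices=matrices, row_subsets=row_subsets,
        dose_let=dose_let,
        metadata={
            "engine": engine, "seed": seed, "n_histories": n_histories,
            "n_spots": len(spots),
            "halo_fraction": mc_params.halo_fraction if engine == "mc" else None,
        },
    )
    out.validate()
    return out


def spot_table(spots: list[Spot]):
    """Spot list as a DataFrame (beam, energy, u, v, id) for CSV export."""
    import pandas as pd

    return pd.DataFrame(
        {
            "beam": [s.beam_index for s in spots],
            "energy_mev": [s.energy_mev for s in spots],
            "u_mm": [s.u_mm for s in spots],
            "v_mm": [s.v_mm for s in spots],
            "id": [s.id for s in spots],
        }
    )
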