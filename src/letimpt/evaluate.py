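"""Plan evaluation: dose rendering, DVH indices, gEUD, LET indices,
cross-engine delta reports, and the exact Wilcoxon signed-rank test.

Dose-volume indices are computed from exact sorted voxel doses (no
binning): Dv is the largest dose such that at least a fraction v of the
structure receives it; D1cc interpolates the sorted cumulative absolute
volume.  The signed-rank test enumerates all 2^n sign assignments
(mid-ranks for ties, two-sided p as the doubled smaller tail, capped
at 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.stats import rankdata

from .phantom import StructureSet, VoxelGrid
from .planning import InfluenceSet


@dataclass
class DoseMap:
    """Per-voxel dose, Gy(RBE), with provenance."""

    grid: VoxelGrid
    values: np.ndarray
    engine: str = ""
    plan: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, float).reshape(self.grid.dims)
        if np.any(self.values < 0) or np.any(~np.isfinite(self.values)):
            raise ValueError("dose map must be finite and nonnegative")


@dataclass
class LETdMap:
    """Per-voxel dose-averaged LET, keV/um; zero-dose voxels flagged."""

    grid: VoxelGrid
    values: np.ndarray
    zero_dose: np.ndarray
    engine: str = ""
    plan: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, float).reshape(self.grid.dims)
        self.zero_dose = np.asarray(self.zero_dose, bool).reshape(self.grid.dims)
        if np.any(self.values < 0) or np.any(~np.isfinite(self.values)):
            raise ValueError("LET_d map must be finite and nonnegative")


def render_dose(weights: np.ndarray, influence: InfluenceSet,
                scenario_label: str = "nominal") -> DoseMap:
    """Voxelwise dose d = sum_j w_j column_j (linear in the weights)."""
    w = np.asarray(weights, float)
    if w.shape != (influence.n_spots,):
        raise ValueError("weight vector length must equal the spot count")
    mat = influence.matrices[scenario_label]
    if influence.row_subsets.get(scenario_label) is not None:
        raise ValueError("cannot render a full map from subset-restricted influence")
    vals = np.asarray(mat @ w).ravel()
    return DoseMap(influence.grid, vals, engine=influence.engine)


# ---------------------------------------------------------------------------
# DVH and indices


@dataclass
class DVH:
    """Exact (unbinned) cumulative DVH of one structure."""

    structure: str
    sorted_doses: np.ndarray      # descending
    voxel_volume_cc: float

    @classmethod
    def from_doses(cls, structure: str, doses, voxel_volume_cc: float) -> "DVH":
        d = np.sort(np.asarray(doses, float))[::-1]
        if d.size == 0:
            raise ValueError("empty structure")
        return cls(structure, d, float(voxel_volume_cc))

    def volume_fraction_at(self, dose: float) -> float:
        """Fraction of the structure receiving at least ``dose``."""
        return float(np.count_nonzero(self.sorted_doses >= dose)) / self.sorted_doses.size

    def curve(self, bin_gy: float = 0.1) -> pd.DataFrame:
        """Binned export for plotting only (0.1 Gy default bins)."""
        top = float(self.sorted_doses[0]) + bin_gy
        edges = np.arange(0.0, top + bin_gy, bin_gy)
        frac = [(self.sorted_doses >= e).mean() for e in edges]
        return pd.DataFrame({"dose_gy": edges, "volume_fraction": frac})


def dose_index(doses, voxel_volume_cc: float, index: str) -> float:
    """Exact DVH index from per-voxel doses of one structure.

    ``Dv`` (D98, D2, ...): the largest dose d such that the fraction of
    the structure receiving >= d is at least v; with equal-volume voxels
    sorted descending this is the ceil(v*n)-th value.  ``D1cc``: the dose
    exceeded by exactly 1 cc, interpolated between adjacent sorted voxels.
    ``Dmean``: arithmetic mean.
    """
    d = np.sort(np.asarray(doses, float))[::-1]
    if d.size == 0:
        raise ValueError("empty structure")
    if index == "Dmean":
        return float(d.mean())
    if index == "D1cc":
        vol = d.size * voxel_volume_cc
        if vol < 1.0:
            raise ValueError(f"structure volume {vol:.3f} cc is below 1 cc")
        # cumulative volume after k voxels is k * vv; find k* with k* vv = 1
        k = 1.0 / voxel_volume_cc
        k0 = int(np.floor(k))
        if k0 >= d.size:
            return float(d[-1])
        if k0 < 1:
            return float(d[0])
        frac = k - k0
        return float(d[k0 - 1] * (1.0 - frac) + d[k0] * frac)
    if index.startswith("D"):
        v = float(index[1:]) / 100.0
        if not 0.0 < v <= 1.0:
            raise ValueError(f"bad volume fraction in index {index!r}")
        k = int(np.ceil(v * d.size))
        return float(d[max(k, 1) - 1])
    raise ValueError(f"unknown index {index!r}")


def geud(doses, a: float, floor_gy: float = 0.01) -> float:
    """Generalized equivalent uniform dose (mean d^a)^(1/a).

    Zero or near-zero doses are floored at ``floor_gy`` when a < 0 so the
    cold-spot emphasis stays finite (documented convention).
    """
    if a == 0:
        raise ValueError("gEUD exponent must be nonzero")
    d = np.asarray(doses, float)
    if d.size == 0:
        raise ValueError("empty structure")
    if a < 0:
        d = np.maximum(d, floor_gy)
    # normalize by the dominating extremum so large |a| cannot overflow
    m = float(d.max() if a > 0 else d.min())
    if m == 0.0:
        return 0.0
    return float(m * np.mean((d / m) ** a) ** (1.0 / a))


def let_indices(letd_map: LETdMap, ctv_mask: np.ndarray,
                max_zero_fraction: float = 0.05) -> tuple[float, float]:
    """(mean LET_d, LET_d covering 98%) over the CTV.

    Zero-dose-flagged voxels are excluded; if they exceed
    ``max_zero_fraction`` of the CTV the plan is invalid and an error is
    raised.
    """
    ctv_mask = np.asarray(ctv_mask, bool)
    if not ctv_mask.any():
        raise ValueError("empty CTV mask")
    flagged = letd_map.zero_dose[ctv_mask]
    zero_frac = float(flagged.mean())
    if zero_frac > max_zero_fraction:
        raise ValueError(
            f"{zero_frac:.1%} of CTV voxels have zero dose (plan invalid)")
    vals = letd_map.values[ctv_mask][~flagged]
    mean_let = float(vals.mean())
    let98 = dose_index(vals, 1.0, "D98")
    return mean_let, let98


# ---------------------------------------------------------------------------
# index tables and delta reports

#: (structure, index) rows mirroring the published comparison layout
DEFAULT_INDEX_LAYOUT = (
    ("ctv", "D98"), ("ctv", "D2"),
    ("rectum", "D1cc"), ("rectum", "Dmean"),
    ("bladder", "D1cc"), ("bladder", "Dmean"),
)


@dataclass
class IndexTable:
    """Dosimetric (and CTV LET) indices of one rendered plan."""

    label: str
    indices: dict          # (structure, index) -> Gy(RBE)
    let: dict = field(default_factory=dict)  # 'mean_letd'/'letd98' -> keV/um

    def to_frame(self) -> pd.DataFrame:
        rows = [{"structure": s, "index": i, "value": v}
                for (s, i), v in self.indices.items()]
        rows += [{"structure": "ctv", "index": k, "value": v}
                 for k, v in self.let.items()]
        return pd.DataFrame(rows)


def index_table(label: str, dose: DoseMap, structures: StructureSet,
                letd: LETdMap | None = None,
                layout=DEFAULT_INDEX_LAYOUT) -> IndexTable:
    vv = structures.grid.voxel_volume_cc
    out = {}
    for struct, idx in layout:
        out[(struct, idx)] = dose_index(dose.values[structures[struct]], vv, idx)
    table = IndexTable(label, out)
    if letd is not None:
        mean_let, let98 = let_indices(letd, structures["ctv"])
        table.let = {"mean_letd": mean_let, "letd98": let98}
    return table


@dataclass
class DeltaReport:
    """Cross-engine percentage and absolute index differences.

    ``doseopt`` convention: delta = (MC - PB)/PB x 100 (recalculation of
    the dose-optimized plan); ``letopt``: delta = (PB - MC)/MC x 100.
    """

    convention: str
    table_a: IndexTable    # reference engine (denominator)
    table_b: IndexTable
    percent: dict = field(default_factory=dict)
    absolute: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for key in self.percent:
            rows.append({
                "structure": key[0], "index": key[1],
                "ref": self.table_a.indices[key], "other": self.table_b.indices[key],
                "delta_pct": self.percent[key], "delta_gy": self.absolute[key],
            })
        return pd.DataFrame(rows)


def delta_report(indices_pb: IndexTable, indices_mc: IndexTable,
                 convention: str) -> DeltaReport:
    """Signed percentage differences between engine-paired index tables."""
    if convention not in ("doseopt", "letopt"):
        raise ValueError("convention must be 'doseopt' or 'letopt'")
    if set(indices_pb.indices) != set(indices_mc.indices):
        raise ValueError("index tables cover different structures")
    ref, other = ((indices_pb, indices_mc) if convention == "doseopt"
                  else (indices_mc, indices_pb))
    pct, ab = {}, {}
    for key, ref_val in ref.indices.items():
        if ref_val == 0:
            raise ZeroDivisionError(f"zero reference index for {key}")
        diff = other.indices[key] - ref_val
        pct[key] = 100.0 * diff / ref_val
        ab[key] = diff
    return DeltaReport(convention, ref, other, pct, ab)


# ---------------------------------------------------------------------------
# exact Wilcoxon signed-rank test


def wilcoxon_signed_rank_exact(differences, max_n: int = 20):
    """Exact two-sided Wilcoxon signed-rank test for small samples.

    Zero differences are dropped; tied magnitudes get mid-ranks; W is the
    sum of ranks of the positive differences.  The two-sided p doubles the
    smaller of P(W <= w) and P(W >= w) over all 2^n equiprobable sign
    assignments, capped at 1.
    """
    d = np.asarray(differences, float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("signed-rank test undefined: all differences are zero")
    if n > max_n:
        raise ValueError(f"exact enumeration limited to n <= {max_n}")
    ranks = rankdata(np.abs(d))
    w_obs = float(ranks[d > 0].sum())
    # distribution of W: subset sums of the ranks (vector doubling)
    sums = np.zeros(1)
    for r in ranks:
        sums = np.concatenate([sums, sums + r])
    total = sums.size
    eps = 1e-9
    p_low = np.count_nonzero(sums <= w_obs + eps) / total
    p_high = np.count_nonzero(sums >= w_obs - eps) / total
    p = min(1.0, 2.0 * min(p_low, p_high))
    return w_obs, p
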