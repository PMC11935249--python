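"""Seeded cohort of phantom variants and cohort-level statistics.

The cohort stands in for a set of patients: each case jitters the CTV
semi-axes (+/-10%), the OAR abutment gaps (+/-3 mm) and the bone density
(+/-0.1 g/cc) around the default phantom.  It makes no claim of matching
any real population's variability; it exists so that means +/- SD and the
paired exact signed-rank test over cases are exercisable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .evaluate import IndexTable, wilcoxon_signed_rank_exact
from .phantom import PhantomConfig, build_phantom


@dataclass(frozen=True)
class CohortSpec:
    n_cases: int = 10
    ctv_jitter_frac: float = 0.10
    oar_shift_mm: float = 3.0
    bone_density_jitter: float = 0.10
    master_seed: int = 0
    max_retries: int = 20

    def __post_init__(self):
        if self.n_cases < 2:
            raise ValueError("a cohort needs at least 2 cases")


def generate_cohort(spec: CohortSpec,
                    base: PhantomConfig | None = None) -> list[PhantomConfig]:
    """n_cases phantom configs, each validated by construction.

    Deterministic given the master seed; geometries that fail validation
    (e.g. an OAR pushed into the CTV) are resampled up to the retry cap.
    """
    base = base or PhantomConfig()
    rng = np.random.default_rng(spec.master_seed)
    configs = []
    for _ in range(spec.n_cases):
        for attempt in range(spec.max_retries + 1):
            f = spec.ctv_jitter_frac
            semis = tuple(s * (1.0 + rng.uniform(-f, f)) for s in base.ctv_semiaxes_mm)
            cfg = replace(
                base,
                ctv_semiaxes_mm=semis,
                bladder_gap_mm=max(base.bladder_gap_mm + rng.uniform(
                    -spec.oar_shift_mm, spec.oar_shift_mm), 0.5),
                rectum_gap_mm=max(base.rectum_gap_mm + rng.uniform(
                    -spec.oar_shift_mm, spec.oar_shift_mm), 0.5),
                bone_density=max(base.bone_density + rng.uniform(
                    -spec.bone_density_jitter, spec.bone_density_jitter), 1.1),
            )
            try:
                build_phantom(cfg)
                configs.append(cfg)
                break
            except ValueError:
                if attempt == spec.max_retries:
                    raise
    return configs


def format_mean_sd(values, decimals: int = 1) -> str:
    """Cohort cell formatting, e.g. '2.6 ± 0.1'."""
    v = np.asarray(values, float)
    return f"{v.mean():.{decimals}f} ± {v.std(ddof=1):.{decimals}f}"


def cohort_statistics(case_tables: list[dict], pairs=(("pb_doseopt", "mc_doseopt"),
                                                      ("mc_letopt", "pb_letopt"))):
    """Means +/- SD per index and paired exact signed-rank tests.

    ``case_tables`` holds one dict per case mapping plan/engine labels to
    :class:`IndexTable`; every requested pair is compared index by index
    across cases.  All-zero paired differences propagate as p = NaN with
    note 'undefined'.
    """
    if len(case_tables) < 2:
        raise ValueError("need at least 2 cases")
    labels = set(case_tables[0])
    for ct in case_tables:
        if set(ct) != labels or any(not isinstance(t, IndexTable) for t in ct.values()):
            raise ValueError("case tables have mismatching schemas")
    rows = []
    for label_a, label_b in pairs:
        keys = case_tables[0][label_a].indices.keys()
        for key in keys:
            a = np.array([ct[label_a].indices[key] for ct in case_tables])
            b = np.array([ct[label_b].indices[key] for ct in case_tables])
            diffs = b - a
            if np.all(diffs == 0):
                p, note = np.nan, "undefined"
            else:
                _, p = wilcoxon_signed_rank_exact(diffs)
                note = ""
            rows.append({
                "comparison": f"{label_a} vs {label_b}",
                "structure": key[0], "index": key[1],
                "a_mean_sd": format_mean_sd(a), "b_mean_sd": format_mean_sd(b),
                "delta_mean_sd": format_mean_sd(diffs),
                "p_exact": p, "note": note,
            })
    return pd.DataFrame(rows)
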