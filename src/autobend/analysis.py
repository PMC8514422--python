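"""Aggregation, constraint tallies, factorial sensitivity, and stiffness.

Left and right measures of lateroflexion and axial rotation are averaged to
absorb asymmetry and doubled (equivalently, summed); dorsiflexion and
ventroflexion are summed into total sagittal mobility.  The sensitivity
design re-runs the bending experiment over a full factorial of joint
spacing, intersection threshold, and strain levels, and effect sizes are
reported as sequential sums of squares.  The stiffness proxy is
(force proxy x moment arm) / oROM with force approximated by centrum
cross-sectional area (height x width) to the power 3/2.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .bending_engine import BendingConfig, BendingResult, run_all_directions
from .segment_model import MotionSegment, adjust_spacing

__all__ = [
    "AggregatedROM", "SensitivityDesign", "StiffnessInputs",
    "StiffnessResult", "aggregate_directions", "tally_constraints",
    "run_sensitivity", "variance_decomposition", "estimate_stiffness",
    "normalize_stiffness", "DIRECTION_GROUPS",
]

# direction label -> tally group (dorsi/ventroflexion analyzed separately)
DIRECTION_GROUPS = {
    "left-lateral": "lateroflexion", "right-lateral": "lateroflexion",
    "left-axial": "axial", "right-axial": "axial",
    "dorsiflexion": "dorsiflexion", "ventroflexion": "ventroflexion",
}


@dataclass(frozen=True)
class AggregatedROM:
    """Per-joint mobility by plane: lateral/axial = left + right (the mean of
    the two sides doubled), sagittal = dorsiflexion + ventroflexion."""
    lateral: float
    sagittal: float
    axial: float


def aggregate_directions(result) -> AggregatedROM:
    """Aggregate six directional stop angles into three planes of motion."""
    if isinstance(result, BendingResult):
        angles = result.stop_angles()
    else:
        angles = dict(result)
    required = set(DIRECTION_GROUPS)
    missing = required - set(angles)
    if missing:
        raise ValueError(f"missing direction(s): {sorted(missing)}")
    return AggregatedROM(
        lateral=angles["left-lateral"] + angles["right-lateral"],
        sagittal=angles["dorsiflexion"] + angles["ventroflexion"],
        axial=angles["left-axial"] + angles["right-axial"])


def tally_constraints(results: pd.DataFrame) -> pd.DataFrame:
    """Proportion of runs stopped by each constraint, per direction group.

    Rows with several simultaneous labels were already resolved to a single
    ``constraint_label`` by the fixed priority (intersection > zygapophyseal
    > centrum), so each run is counted once and the fractions within a
    direction group sum to 1.
    """
    if len(results) == 0:
        raise ValueError("empty result table")
    df = results.copy()
    df["group"] = df["direction"].map(DIRECTION_GROUPS)
    if df["group"].isna().any():
        bad = sorted(df.loc[df["group"].isna(), "direction"].unique())
        raise ValueError(f"unknown direction(s): {bad}")
    counts = (df.groupby(["group", "constraint_label"]).size()
              .unstack(fill_value=0))
    props = counts.div(counts.sum(axis=1), axis=0)
    return props


@dataclass(frozen=True)
class SensitivityDesign:
    """Full-factorial (low, high) levels; None leaves a parameter fixed.

    ``strain_levels`` apply symmetrically to both the zygapophyseal and the
    centrum strain bounds (e.g. 0.45 -> bounds (-0.45, +0.45)).
    """
    spacing_levels: Optional[tuple] = (-0.10, +0.10)
    intersection_levels: Optional[tuple] = (0.0025, 0.005)
    strain_levels: Optional[tuple] = (0.45, 0.55)

    def factors(self):
        out = []
        for name, levels in (("spacing", self.spacing_levels),
                             ("intersection", self.intersection_levels),
                             ("strain", self.strain_levels)):
            if levels is not None:
                if len(levels) != 2:
                    raise ValueError(f"{name}_levels must be (low, high)")
                out.append((name, tuple(levels)))
        return out

    def variants(self):
        """Yield (variant_label, {factor: (level_name, value)}) over the
        2^k factorial (a single base variant when nothing is varied)."""
        factors = self.factors()
        if not factors:
            yield "base", {}
            return
        for combo in itertools.product(("low", "high"), repeat=len(factors)):
            assignment = {name: (lev, levels[0] if lev == "low" else levels[1])
                          for (name, levels), lev in zip(factors, combo)}
            label = ",".join(f"{k}={v[0]}" for k, v in assignment.items())
            yield label, assignment


def _variant_config(base: BendingConfig, assignment: dict) -> BendingConfig:
    cfg = base
    if "intersection" in assignment:
        cfg = replace(cfg, intersection_threshold=assignment["intersection"][1])
    if "strain" in assignment:
        s = assignment["strain"][1]
        cfg = replace(cfg, zyg_bounds=(-s, s), centrum_bounds=(-s, s))
    return cfg


def run_sensitivity(segment: MotionSegment,
                    design: SensitivityDesign = SensitivityDesign(),
                    base_config: BendingConfig = BendingConfig()
                    ) -> pd.DataFrame:
    """One full bending run (six directions) per factorial variant.

    Joint spacing is applied by re-spacing the segment before bending (the
    shifted pose becomes that variant's neutral).  Variants whose neutral
    pose is invalid are flagged in the ``flagged`` column and the run
    continues.
    """
    rows = []
    for label, assignment in design.variants():
        seg = segment
        flagged = False
        if "spacing" in assignment:
            seg = adjust_spacing(segment, assignment["spacing"][1])
            flagged = seg.neutral_overlap_warning
        cfg = _variant_config(base_config, assignment)
        result = run_all_directions(seg, cfg)
        for row in result.to_rows(segment_id=segment.segment_id,
                                  run_variant=label):
            for name, (lev, _val) in assignment.items():
                row[name] = lev
            row["flagged"] = flagged or result[row["direction"]].flagged
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Variance decomposition (sequential sums of squares on balanced designs)
# ---------------------------------------------------------------------------

def variance_decomposition(table: pd.DataFrame, response: str = "stop_angle",
                           factors: Sequence[str] = ("joint", "direction"),
                           params: Sequence[str] = ("spacing", "intersection",
                                                    "strain"),
                           interaction: bool = True) -> pd.DataFrame:
    """Sequential (type-I) sums of squares for the bending response.

    Effects entered in order: main factors, their pairwise interaction
    (joint x direction), then each sensitivity parameter.  Requires a
    balanced table (equal replication of every full factor-level cross),
    where all classical ANOVA types coincide; unbalanced input is rejected
    with the offending cells named.
    """
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    all_factors = [f for f in list(factors) + list(params)
                   if f in table.columns]
    missing = [f for f in list(factors) if f not in table.columns]
    if missing:
        raise ValueError(f"missing factor column(s): {missing}")
    counts = table.groupby(all_factors, observed=True).size()
    if counts.nunique() != 1 or len(counts) != int(np.prod(
            [table[f].nunique() for f in all_factors])):
        lo = counts.index[counts.argmin()]
        raise ValueError(f"unbalanced design: cell {lo!r} has "
                         f"{counts.min()} rows vs max {counts.max()}")

    terms = [f"C({f})" for f in factors]
    if interaction and len(factors) >= 2:
        terms.append(f"C({factors[0]}):C({factors[1]})")
    terms += [f"C({p})" for p in params if p in table.columns]
    formula = f"{response} ~ " + " + ".join(terms)
    fit = smf.ols(formula, data=table).fit()
    aov = anova_lm(fit, typ=1)
    out = aov[["df", "sum_sq"]].copy()
    out.index = [i.replace("C(", "").replace(")", "") for i in out.index]
    total = float((table[response] - table[response].mean()).pow(2).sum())
    explained = float(out["sum_sq"].sum())
    if total > 0 and abs(explained - total) > 1e-6 * total:
        raise AssertionError("sums of squares do not add up to the total")
    return out


# ---------------------------------------------------------------------------
# Stiffness proxy
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StiffnessInputs:
    """Morphometrics (mm) and mobility (degrees) for one joint.

    Centrum height/width are the anterior/posterior averages; the sagittal
    moment arm is half the centrum height plus the vertebral arch height
    (the lever of the arch ligaments), the lateral arm half the centrum
    width (the lever of the annular ligaments).
    """
    centrum_height: float
    centrum_width: float
    arch_height: float
    orom_sagittal: float
    orom_lateral: float

    def __post_init__(self):
        for name in ("centrum_height", "centrum_width", "arch_height",
                     "orom_sagittal", "orom_lateral"):
            v = getattr(self, name)
            if name == "arch_height":
                if v < 0:
                    raise ValueError("arch_height must be >= 0")
            elif v <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class StiffnessResult:
    sagittal: float
    lateral: float
    force: float
    mode: str  # "full-precision" | "printed-arithmetic"


def estimate_stiffness(inputs: StiffnessInputs,
                       printed_arithmetic: bool = False) -> StiffnessResult:
    """Stiffness proxy (mm^4 per degree): force x moment arm / oROM.

    Force is the centrum cross-sectional area (height x width, the rectangle
    proxy) to the power 3/2.  Printed-arithmetic mode rounds the force and
    the final quotients to the nearest integer, reproducing the displayed
    calculation chain; full precision is the default for analysis.
    """
    h, w = inputs.centrum_height, inputs.centrum_width
    force = (h * w) ** 1.5
    if printed_arithmetic:
        force = round(force)
    sag = force * (h / 2 + inputs.arch_height) / inputs.orom_sagittal
    lat = force * (w / 2) / inputs.orom_lateral
    if printed_arithmetic:
        sag, lat = round(sag), round(lat)
    return StiffnessResult(sagittal=float(sag), lateral=float(lat),
                           force=float(force),
                           mode=("printed-arithmetic" if printed_arithmetic
                                 else "full-precision"))


def normalize_stiffness(values, mean_centrum_length: float,
                        mode: str = "log-then-divide") -> np.ndarray:
    """Size-normalize stiffness values by a species-level centrum length.

    ``log-then-divide`` (default): log10(value) / length;
    ``divide-then-log``: log10(value / length).  Both preserve the
    within-species rank order of values.
    """
    v = np.asarray(values, dtype=float)
    if np.any(v <= 0):
        raise ValueError("stiffness values must be positive")
    if mean_centrum_length <= 0:
        raise ValueError("mean_centrum_length must be positive")
    if mode == "log-then-divide":
        return np.log10(v) / mean_centrum_length
    if mode == "divide-then-log":
        return np.log10(v / mean_centrum_length)
    raise ValueError(f"unknown normalization mode {mode!r}")
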