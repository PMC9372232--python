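"""Genetic-risk-adjusted cumulative incidence curves.

A population age-specific cumulative incidence table (ages 40-70) is split
into clinically significant and non-significant components by an
age-specific fraction schedule, then adjusted for the top 20% / top 5%
genetic-risk bands by multiplying by the band's mean hazard ratio versus
the middle 40% (HR_80/50, HR_95/50). The direct product is a rare-disease
approximation and is what is emitted as the primary curve; an exact
hazard-scaled alternative, 1 - (1 - F)^HR, is emitted alongside for
comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "load_incidence",
    "split_by_significance",
    "risk_adjust",
    "IncidenceCurveSet",
    "build_curve_set",
    "ClippingWarning",
]

AGE_GRID = np.arange(40, 71)  # years, inclusive


class ClippingWarning(UserWarning):
    """An adjusted incidence curve exceeded 1 and was clipped."""


def load_incidence(path_or_frame) -> pd.Series:
    """Validated baseline cumulative incidence on the integer age grid 40-70.

    Accepts a CSV path or DataFrame with columns (age, cumulative_incidence);
    the input must be non-decreasing in age and cover the grid; values are
    linearly interpolated onto integer ages.
    """
    if isinstance(path_or_frame, pd.DataFrame):
        df = path_or_frame
    else:
        df = pd.read_csv(path_or_frame)
    for c in ("age", "cumulative_incidence"):
        if c not in df.columns:
            raise ValueError(f"incidence table missing column {c!r}")
    df = df.sort_values("age")
    ages = df["age"].to_numpy(dtype=float)
    ci = df["cumulative_incidence"].to_numpy(dtype=float)
    if np.any((ci < 0) | (ci > 1)):
        raise ValueError("cumulative incidence must lie in [0,1]")
    drops = np.flatnonzero(np.diff(ci) < 0)
    if drops.size:
        raise ValueError(
            f"cumulative incidence decreases after age {ages[drops[0]]:g}"
        )
    if ages.min() > AGE_GRID[0] or ages.max() < AGE_GRID[-1]:
        raise ValueError(
            f"incidence table must cover ages {AGE_GRID[0]}-{AGE_GRID[-1]}"
        )
    vals = np.interp(AGE_GRID, ages, ci)
    return pd.Series(vals, index=AGE_GRID, name="cumulative_incidence")


def split_by_significance(baseline_any: pd.Series, significant_fraction):
    """Split the baseline curve into significant / non-significant parts.

    ``significant_fraction`` is a scalar in [0,1] or a per-age schedule
    (Series on the age grid, or DataFrame with columns age and
    significant_fraction). Both resulting curves must remain non-decreasing.
    """
    base = np.asarray(baseline_any, dtype=float)
    if np.isscalar(significant_fraction):
        frac = np.full(base.shape, float(significant_fraction))
    elif isinstance(significant_fraction, pd.DataFrame):
        df = significant_fraction.sort_values("age")
        frac = np.interp(
            AGE_GRID,
            df["age"].to_numpy(dtype=float),
            df["significant_fraction"].to_numpy(dtype=float),
        )
    else:
        frac = np.asarray(significant_fraction, dtype=float)
        if frac.shape != base.shape:
            raise ValueError("fraction schedule does not match the age grid")
    if np.any((frac < 0) | (frac > 1)):
        raise ValueError("significant fractions must lie in [0,1]")
    sig = frac * base
    nonsig = (1.0 - frac) * base
    for name, curve in (("significant", sig), ("non-significant", nonsig)):
        bad = np.flatnonzero(np.diff(curve) < -1e-12)
        if bad.size:
            raise ValueError(
                f"{name} curve decreases after age {AGE_GRID[bad[0]]}: "
                "fraction schedule incompatible with the baseline"
            )
    idx = baseline_any.index if isinstance(baseline_any, pd.Series) else AGE_GRID
    return (
        pd.Series(sig, index=idx, name="significant"),
        pd.Series(nonsig, index=idx, name="nonsignificant"),
    )


def risk_adjust(curve, hr: float):
    """Pointwise product ``curve * hr``, clipped at 1 with a warning."""
    if not hr > 0:
        raise ValueError("hazard ratio must be positive")
    vals = np.asarray(curve, dtype=float) * hr
    if np.any(vals > 1.0):
        warnings.warn(
            "adjusted cumulative incidence exceeds 1; clipping",
            ClippingWarning,
            stacklevel=2,
        )
        vals = np.minimum(vals, 1.0)
    if isinstance(curve, pd.Series):
        return pd.Series(vals, index=curve.index, name=curve.name)
    return vals


def hazard_scale(curve, hr: float):
    """Exact proportional-hazards transform 1 - (1 - F)^hr of a cumulative
    incidence curve (stays in [0,1] without clipping)."""
    if not hr > 0:
        raise ValueError("hazard ratio must be positive")
    vals = 1.0 - (1.0 - np.asarray(curve, dtype=float)) ** hr
    if isinstance(curve, pd.Series):
        return pd.Series(vals, index=curve.index, name=curve.name)
    return vals


@dataclass
class IncidenceCurveSet:
    """Baseline and genetic-risk-adjusted cumulative incidence curves."""

    age_grid: np.ndarray
    baseline_any: pd.Series
    baseline_significant: pd.Series
    baseline_nonsignificant: pd.Series
    adjusted: dict               # (band, component) -> Series (direct product)
    adjusted_exact: dict         # same keys, hazard-scaled variant
    hr_used: dict                # band -> HR applied

    def validate(self):
        curves = [
            self.baseline_any,
            self.baseline_significant,
            self.baseline_nonsignificant,
            *self.adjusted.values(),
            *self.adjusted_exact.values(),
        ]
        for c in curves:
            v = np.asarray(c, dtype=float)
            if np.any((v < 0) | (v > 1)):
                raise ValueError("incidence values outside [0,1]")
            if np.any(np.diff(v) < -1e-12):
                raise ValueError("non-monotone incidence curve")
        tot = (
            np.asarray(self.baseline_significant)
            + np.asarray(self.baseline_nonsignificant)
        )
        if np.any(tot - np.asarray(self.baseline_any) > 1e-9):
            raise ValueError("significant + nonsignificant exceeds baseline")
        return self

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"age": self.age_grid})
        out["baseline_any"] = np.asarray(self.baseline_any)
        out["baseline_significant"] = np.asarray(self.baseline_significant)
        out["baseline_nonsignificant"] = np.asarray(self.baseline_nonsignificant)
        for (band, comp), series in sorted(self.adjusted.items()):
            out[f"{band}_{comp}"] = np.asarray(series)
        for (band, comp), series in sorted(self.adjusted_exact.items()):
            out[f"{band}_{comp}_exact"] = np.asarray(series)
        return out

    def write_csv(self, path):
        self.validate()
        self.to_frame().to_csv(path, index=False, lineterminator="\n")


def build_curve_set(
    baseline: pd.Series,
    significant_fraction,
    hr_80_50: float,
    hr_95_50: float,
) -> IncidenceCurveSet:
    """Assemble the full curve set from a baseline, a significance split and
    the two top-band hazard ratios."""
    sig, nonsig = split_by_significance(baseline, significant_fraction)
    hr_used = {"top20": float(hr_80_50), "top5": float(hr_95_50)}
    adjusted = {}
    adjusted_exact = {}
    for band, hr in hr_used.items():
        for comp, comp_curve in (("significant", sig), ("nonsignificant", nonsig)):
            adjusted[(band, comp)] = risk_adjust(comp_curve, hr)
            adjusted_exact[(band, comp)] = hazard_scale(comp_curve, hr)
    return IncidenceCurveSet(
        age_grid=AGE_GRID.copy(),
        baseline_any=pd.Series(np.asarray(baseline), index=AGE_GRID),
        baseline_significant=sig,
        baseline_nonsignificant=nonsig,
        adjusted=adjusted,
        adjusted_exact=adjusted_exact,
        hr_used=hr_used,
    ).validate()
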