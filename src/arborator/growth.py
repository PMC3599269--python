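"""Growth-curve fitness extraction and trait-profile comparison.

Fitness components follow the standard micro-cultivation conventions: the
maximum specific growth rate from the log-linear part of the curve (doubling
time = ln2 / mu_max), the lag as the time where the tangent through the
log-linear fit meets the pre-growth baseline, and the efficiency as the
total density change.  Profiles are log2 ratios against a same-plate
reference strain; group differences use Bonferroni-corrected t-tests.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class GrowthCurve:
    strain_id: str
    condition_id: str
    replicate: int
    times: np.ndarray
    ods: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.ods = np.asarray(self.ods, dtype=float)
        if len(self.times) != len(self.ods):
            raise ValueError("times/ods length mismatch")
        if (np.diff(self.times) <= 0).any():
            raise ValueError("times must be strictly increasing")


@dataclass
class GrowthParams:
    lag_min: float
    doubling_min: float
    efficiency_od: float
    mu_max: float = np.nan
    is_grower: bool = True


@dataclass
class TraitProfile:
    strain_id: str
    values: dict[tuple[str, str], float] = field(default_factory=dict)

    COMPONENTS = ("lag", "rate", "efficiency")


# ---------------------------------------------------------------- extraction

def _smooth(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x
    kernel = np.ones(window) / window
    pad = window // 2
    padded = np.concatenate([np.full(pad, x[0]), x, np.full(pad, x[-1])])
    return np.convolve(padded, kernel, mode="valid")[: len(x)]


def extract_growth(curve: GrowthCurve, smoothing_window: int = 3,
                   min_efficiency: float = 0.05, floor: float | None = None,
                   band: tuple[float, float] = (0.05, 0.8)) -> GrowthParams:
    """Extract lag, doubling time and efficiency from one curve.

    The baseline is the median of the first 3 ODs; efficiency is the density
    gain of the smoothed curve; mu_max is the OLS slope of
    ln(od − baseline + floor) over the log-linear band (points whose density
    gain lies between ``band`` fractions of the total gain); the lag is where
    that fitted line crosses the baseline level.  ``floor`` defaults to the
    baseline itself, so the log argument is simply the OD.  Curves with
    efficiency below ``min_efficiency`` or non-positive slope are flagged
    non-growers.
    """
    if len(curve.times) < 10:
        raise ValueError("need at least 10 samples")
    t, od = curve.times, curve.ods
    baseline = float(np.median(od[:3]))
    smooth = _smooth(od, smoothing_window)
    gain = smooth - baseline
    efficiency = float(gain.max())
    if floor is None:
        floor = max(baseline, 1e-6)
    if efficiency < min_efficiency:
        return GrowthParams(np.nan, np.nan, efficiency, np.nan, is_grower=False)

    lo, hi = band[0] * efficiency, band[1] * efficiency
    mask = (gain >= lo) & (gain <= hi)
    # restrict to the contiguous rise up to the first maximum
    peak = int(np.argmax(gain))
    mask[peak + 1:] = False
    if mask.sum() < 3:
        mask = (gain > 0) & (np.arange(len(gain)) <= peak)
        if mask.sum() < 3:
            return GrowthParams(np.nan, np.nan, efficiency, np.nan, is_grower=False)
    y = np.log(np.clip(gain + floor, floor * 1e-3, None))
    slope, intercept = np.polyfit(t[mask], y[mask], 1)
    if slope <= 0:
        return GrowthParams(np.nan, np.nan, efficiency, float(slope), is_grower=False)
    doubling = float(np.log(2) / slope)
    lag = float((np.log(floor) - intercept) / slope)
    return GrowthParams(max(lag, 0.0), doubling, efficiency, float(slope))


def curves_from_frame(df: pd.DataFrame) -> list[GrowthCurve]:
    """Split a long-format table (strain, condition, replicate, time_min, od)
    into GrowthCurve objects."""
    out = []
    for (s, c, r), grp in df.groupby(["strain", "condition", "replicate"]):
        grp = grp.sort_values("time_min")
        out.append(GrowthCurve(str(s), str(c), int(r),
                               grp["time_min"].to_numpy(), grp["od"].to_numpy()))
    return out


# ---------------------------------------------------------------- profiles

def normalize_profiles(isolate: dict[str, GrowthParams],
                       reference: dict[str, list[GrowthParams]],
                       strain_id: str = "") -> TraitProfile:
    """log2 trait ratios against the plate reference.

    Lag and doubling: log2(reference/isolate); efficiency:
    log2(isolate/reference) — larger is always better than the reference.
    The reference value per condition is the mean over its replicates.
    """
    prof = TraitProfile(strain_id)
    for cond, p in isolate.items():
        refs = [r for r in reference.get(cond, []) if r.is_grower]
        if not refs or not p.is_grower:
            continue
        ref_lag = float(np.mean([r.lag_min for r in refs]))
        ref_dbl = float(np.mean([r.doubling_min for r in refs]))
        ref_eff = float(np.mean([r.efficiency_od for r in refs]))
        prof.values[(cond, "lag")] = float(np.log2(ref_lag / p.lag_min))
        prof.values[(cond, "rate")] = float(np.log2(ref_dbl / p.doubling_min))
        prof.values[(cond, "efficiency")] = float(np.log2(p.efficiency_od / ref_eff))
    return prof


def profile_correlation(profiles: list[TraitProfile], min_shared: int = 10
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlation over shared (condition, component)
    values; returns (correlation matrix, shared-count matrix).  Pairs with
    fewer than ``min_shared`` shared values get NaN."""
    names = [p.strain_id for p in profiles]
    corr = pd.DataFrame(np.eye(len(profiles)), index=names, columns=names)
    nsh = pd.DataFrame(0, index=names, columns=names, dtype=int)
    for i, a in enumerate(profiles):
        nsh.iloc[i, i] = len(a.values)
        for j in range(i + 1, len(profiles)):
            b = profiles[j]
            shared = sorted(set(a.values) & set(b.values))
            nsh.iloc[i, j] = nsh.iloc[j, i] = len(shared)
            if len(shared) < min_shared:
                corr.iloc[i, j] = corr.iloc[j, i] = np.nan
                continue
            x = np.array([a.values[k] for k in shared])
            y = np.array([b.values[k] for k in shared])
            r = float(stats.pearsonr(x, y).statistic)
            corr.iloc[i, j] = corr.iloc[j, i] = r
    return corr, nsh


def differential_traits(group_a: list[TraitProfile], group_b: list[TraitProfile],
                        alpha: float = 0.2, equal_var: bool = True
                        ) -> list[tuple[tuple[str, str], float, float, float]]:
    """Bonferroni-corrected two-sample t-tests per (condition, component).

    Returns [(key, t, p_raw, p_adjusted)] for keys significant at the
    corrected level; Student's (equal-variance) t by default, Welch behind
    the flag.
    """
    keys = sorted(set.intersection(
        *(set(p.values) for p in group_a + group_b))) if group_a and group_b else []
    tested = []
    for key in keys:
        xa = [p.values[key] for p in group_a]
        xb = [p.values[key] for p in group_b]
        if len(xa) < 2 or len(xb) < 2:
            continue
        if np.ptp(xa) == 0 and np.ptp(xb) == 0 and xa[0] == xb[0]:
            continue  # identical constant groups: no evidence of difference
        t, p = stats.ttest_ind(xa, xb, equal_var=equal_var)
        tested.append((key, float(t), float(p)))
    m = len(tested)
    out = []
    for key, t, p in tested:
        p_adj = min(p * m, 1.0)
        if p_adj < alpha:
            out.append((key, t, p, p_adj))
    return out
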