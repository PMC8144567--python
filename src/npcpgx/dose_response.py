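"""Viability normalization, four-parameter log-logistic fitting, and IC50
extraction with range-censoring proxies.

The potency readout of an organoid drug screen is the IC50 of a 4PL (Hill)
curve fitted to % viability over a 6-point dilution series.  Because the
tested range is 0.08–20 µM, IC50s falling outside it are not extrapolated but
replaced by the nearest tested dose ("proxy" censoring), and curves that fail
to converge or are flat are reported as maximally resistant (20 µM).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

DOSE_RANGE_UM = (0.08, 20.0)

#: a fitted span of less than this many percentage points is "flat"
FLAT_SPAN_PCT = 5.0


def normalize_viability(raw_signal, control_wells) -> np.ndarray:
    """Express raw well luminescence as % viability of the control mean.

    Negative raw readings are clipped to 0 before division.  Raises if the
    control mean is not positive (a dead control plate carries no scale).
    """
    raw = np.asarray(raw_signal, dtype=float)
    controls = np.asarray(control_wells, dtype=float)
    if controls.size < 1:
        raise ValueError("at least one control well required")
    ctrl_mean = controls.mean()
    if ctrl_mean <= 0:
        raise ValueError("control mean must be > 0 (dead control plate)")
    return 100.0 * np.maximum(raw, 0.0) / ctrl_mean


def _4pl(log_dose, top, bottom, log_ic50, hill):
    return bottom + (top - bottom) / (1.0 + np.exp(hill * (log_dose - log_ic50)))


@dataclass(frozen=True)
class FourPLFit:
    """Least-squares four-parameter log-logistic fit on log-dose."""

    top: float
    bottom: float
    ic50_raw: float
    hill: float
    converged: bool
    residual_sse: float


@dataclass(frozen=True)
class IC50Estimate:
    """IC50 censored to the tested dose range.

    censoring: 'none' (in range), 'clipped_high' (raw > max dose),
    'clipped_low' (raw < min dose), or 'nonconverged' (flat/failed fit,
    reported at the resistant end of the range).
    """

    value: float
    censoring: str


def average_replicates(plate: pd.DataFrame) -> pd.DataFrame:
    """Mean % viability per dose from a tidy plate table."""
    out = (
        plate.groupby("dose_uM", as_index=False)["viability_pct"]
        .mean()
        .sort_values("dose_uM")
        .reset_index(drop=True)
    )
    return out


def fit_4pl(doses, viability, max_top: float = 120.0, n_starts: int = 3) -> FourPLFit:
    """Fit ``v(d) = bottom + (top-bottom)/(1 + (d/ic50)^hill)`` by least squares.

    Requires >= 4 distinct positive doses.  The fit is parameterized on
    log-dose with bounds bottom >= 0 and top <= ``max_top``; initialization
    takes top/bottom from the data extremes, IC50 from the geometric mean of
    the doses and hill = 1, with up to ``n_starts`` jittered restarts when the
    optimizer fails.  A fitted span of < 5 percentage points (no dose effect)
    is flagged ``converged=False``.
    """
    doses = np.asarray(doses, dtype=float)
    viability = np.asarray(viability, dtype=float)
    if np.unique(doses).size < 4:
        raise ValueError("at least 4 distinct doses required for 4PL fitting")
    if doses.shape != viability.shape or not np.all(np.isfinite(viability)):
        raise ValueError("viability must be finite and match doses")
    log_d = np.log(doses)

    def resid(theta):
        return _4pl(log_d, *theta) - viability

    lo = np.array([0.0, 0.0, log_d.min() - np.log(1e4), 0.05])
    hi = np.array([max_top, max_top, log_d.max() + np.log(1e4), 20.0])
    x0 = np.array(
        [
            min(float(viability.max()), max_top),
            max(float(viability.min()), 0.0),
            float(log_d.mean()),
            1.0,
        ]
    )
    best = None
    rng = np.random.default_rng(0)
    for start in range(n_starts):
        guess = x0 if start == 0 else np.clip(
            x0 + rng.normal(0.0, [5.0, 5.0, 1.0, 0.5]), lo, hi
        )
        try:
            sol = least_squares(resid, guess, bounds=(lo, hi))
        except Exception:  # optimizer blow-up counts as a failed start
            continue
        if best is None or sol.cost < best.cost:
            best = sol
        if sol.success and start == 0:
            break
    if best is None:
        return FourPLFit(np.nan, np.nan, np.nan, np.nan, False, np.inf)
    top, bottom, log_ic50, hill = best.x
    inverted = bottom > top  # rising dose-response: no meaningful IC50
    if inverted:
        top, bottom = bottom, top
    sse = float(2 * best.cost)
    flat = (top - bottom) < FLAT_SPAN_PCT
    return FourPLFit(
        top=float(top),
        bottom=float(bottom),
        ic50_raw=float(np.exp(log_ic50)),
        hill=float(hill),
        converged=bool(best.success and not flat and not inverted),
        residual_sse=sse,
    )


def fit_plate(plate: pd.DataFrame, **kwargs) -> FourPLFit:
    """Average replicates per dose, then fit the 4PL curve."""
    avg = average_replicates(plate)
    return fit_4pl(avg["dose_uM"].values, avg["viability_pct"].values, **kwargs)


def predict_viability(fit: FourPLFit, doses) -> np.ndarray:
    """Fitted % viability at the given doses."""
    doses = np.asarray(doses, dtype=float)
    return fit.bottom + (fit.top - fit.bottom) / (
        1.0 + (doses / fit.ic50_raw) ** fit.hill
    )


def ic50_with_proxy(fit: FourPLFit, dose_range=DOSE_RANGE_UM) -> IC50Estimate:
    """Censor a fitted IC50 to the tested dose range.

    Raw IC50 above the maximum tested dose is replaced by that dose
    (clipped_high); below the minimum, by the minimum (clipped_low);
    non-converged fits get the resistant proxy (maximum dose).
    """
    lo, hi = dose_range
    if not fit.converged or not np.isfinite(fit.ic50_raw):
        return IC50Estimate(value=hi, censoring="nonconverged")
    if fit.ic50_raw > hi:
        return IC50Estimate(value=hi, censoring="clipped_high")
    if fit.ic50_raw < lo:
        return IC50Estimate(value=lo, censoring="clipped_low")
    return IC50Estimate(value=float(fit.ic50_raw), censoring="none")


DEFAULT_IR_DOSES_GY = (0.0, 2.0, 4.0, 6.0, 8.0, 10.0)


def ir_survival(plate: pd.DataFrame, allowed_doses=DEFAULT_IR_DOSES_GY) -> pd.DataFrame:
    """Per-dose mean viability +/- SD for an ionizing-radiation series (Gy).

    Doses outside ``allowed_doses`` are rejected so a typo'd grid cannot
    silently feed the additive model.
    """
    doses = set(np.unique(plate["dose_gy"] if "dose_gy" in plate else plate["dose_uM"]))
    extra = doses - set(allowed_doses)
    if extra:
        raise ValueError(f"unexpected IR doses: {sorted(extra)}")
    col = "dose_gy" if "dose_gy" in plate else "dose_uM"
    prof = (
        plate.groupby(col)["viability_pct"]
        .agg(mean_viability_pct="mean", sd_viability_pct="std")
        .reset_index()
        .rename(columns={col: "dose_gy"})
        .sort_values("dose_gy")
        .reset_index(drop=True)
    )
    prof["inhibition"] = np.clip(1.0 - prof["mean_viability_pct"] / 100.0, 0.0, 1.0)
    return prof


def ir_inhibition_at(profile: pd.DataFrame, dose_gy: float = 4.0) -> float:
    """Inhibition fraction E1 at the chosen IR dose (default 4 Gy)."""
    row = profile[profile["dose_gy"] == dose_gy]
    if row.empty:
        raise ValueError(f"IR dose {dose_gy} Gy not present in profile")
    return float(row["inhibition"].iloc[0])


def fit_screen(plates: pd.DataFrame) -> pd.DataFrame:
    """Fit every (sample, drug, ir_gy) arm in a tidy multi-plate table.

    Returns one row per arm with the raw fit, the proxy-censored IC50 and
    censoring status — the table feeding synergy fold-change calls.
    """
    rows = []
    for (sample, drug, ir), grp in plates.groupby(["sample", "drug", "ir_gy"]):
        fit = fit_plate(grp)
        est = ic50_with_proxy(fit)
        rows.append(
            {
                "sample": sample,
                "drug": drug,
                "ir_gy": ir,
                "top": fit.top,
                "bottom": fit.bottom,
                "ic50_raw": fit.ic50_raw,
                "hill": fit.hill,
                "converged": fit.converged,
                "ic50_proxy": est.value,
                "censoring": est.censoring,
            }
        )
    return pd.DataFrame(rows)
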