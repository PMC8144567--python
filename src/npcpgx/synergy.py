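"""Bliss-independence chemoradiotherapy (CRT) synergy calling.

Two independently acting inhibitors with inhibition fractions E1 (ionizing
radiation at a fixed dose, 4 Gy in the emulated screen) and E2 (drug at dose
d) are expected, under Bliss independence, to combine to
``E_total = E1 + E2 - E1*E2``.  A combination is called synergistic when the
observed combination curve sits below the additive viability curve, and a
combination is a "good" radiosensitizer candidate when the mono/combo IC50
fold change exceeds 3 (both IC50s already censored to the tested range, so
the ratio is always defined).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dose_response import IC50Estimate

FOLD_CHANGE_CUT = 3.0
DEFAULT_TOL = 0.02  # 2 percentage points on the viability scale
DEFAULT_MIN_POINTS = 3


def _as_fraction(x, name):
    x = np.asarray(x, dtype=float)
    if np.any(x < 0) or np.any(x > 1):
        raise ValueError(f"{name} must be within [0, 1]")
    return x


def bliss_additive(e1, e2):
    """Bliss additive inhibition ``e1 + e2 - e1*e2`` (fractions in [0, 1])."""
    e1 = _as_fraction(e1, "e1")
    e2 = _as_fraction(e2, "e2")
    return e1 + e2 - e1 * e2


def inhibition_from_viability(viability_pct):
    """Inhibition fraction 1 - v/100, clipped to [0, 1]."""
    v = np.asarray(viability_pct, dtype=float)
    return np.clip(1.0 - v / 100.0, 0.0, 1.0)


def additive_curve(drug_inhibition, ir_inhibition):
    """Predicted combo inhibition per dose, plus the matching viability curve.

    Returns ``(inhibition, viability_pct)``: the elementwise Bliss prediction
    and ``100*(1 - E_total)`` for plotting against observed curves.
    """
    e_total = bliss_additive(float(ir_inhibition), drug_inhibition)
    return e_total, 100.0 * (1.0 - e_total)


@dataclass(frozen=True)
class SynergyCall:
    verdict: str  # synergistic | additive | antagonistic-or-none
    n_doses_below_additive: int
    tol: float
    min_points: int
    fold_change: float | None = None
    good_combination: bool | None = None


def classify_synergy(
    combo_inhibition,
    additive_inhibition,
    tol: float = DEFAULT_TOL,
    min_points: int = DEFAULT_MIN_POINTS,
) -> SynergyCall:
    """Call synergy from observed-vs-additive inhibition on a shared grid.

    Synergistic iff combo viability is below additive viability by more than
    ``tol`` (default 2 pp, i.e. combo inhibition exceeds additive by > tol)
    at >= ``min_points`` doses; additive iff within +/- tol everywhere;
    otherwise antagonistic-or-none.
    """
    combo = np.asarray(combo_inhibition, dtype=float)
    add = np.asarray(additive_inhibition, dtype=float)
    if combo.shape != add.shape:
        raise ValueError("combo and additive curves must share the dose grid")
    diff = combo - add
    n_below = int(np.sum(diff > tol))
    if n_below >= min_points:
        verdict = "synergistic"
    elif np.all(np.abs(diff) <= tol):
        verdict = "additive"
    else:
        verdict = "antagonistic-or-none"
    return SynergyCall(
        verdict=verdict, n_doses_below_additive=n_below, tol=tol,
        min_points=min_points,
    )


def crt_fold_change(ic50_mono: IC50Estimate, ic50_combo: IC50Estimate):
    """Mono/combo IC50 ratio and the good-combination flag (strictly > 3).

    Both estimates must already be proxy-censored to the tested range, which
    guarantees positive values; the boundary ratio 3.0 is not flagged.
    """
    fold = ic50_mono.value / ic50_combo.value
    return fold, bool(fold > FOLD_CHANGE_CUT)


def call_pair(
    mono_plate,
    combo_plate,
    ir_inhibition: float,
    ic50_mono: IC50Estimate,
    ic50_combo: IC50Estimate,
    tol: float = DEFAULT_TOL,
    min_points: int = DEFAULT_MIN_POINTS,
    smooth: bool = True,
) -> SynergyCall:
    """Full synergy call for one drug-IR pair from tidy plate tables.

    With ``smooth=True`` (default) the observed and additive curves are the
    fitted 4PL responses evaluated on the dose grid, mirroring how screen
    response curves are compared; ``smooth=False`` compares raw
    replicate-mean viabilities, which at realistic assay noise is dominated
    by well-to-well scatter.
    """
    from .dose_response import average_replicates, fit_plate, predict_viability

    mono = average_replicates(mono_plate)
    combo = average_replicates(combo_plate)
    if not np.allclose(mono["dose_uM"].values, combo["dose_uM"].values):
        raise ValueError("mono and combo arms must share the dose grid")
    doses = mono["dose_uM"].values
    if smooth:
        fm, fc = fit_plate(mono_plate), fit_plate(combo_plate)
        mono_v = predict_viability(fm, doses) if fm.converged else mono[
            "viability_pct"].values
        combo_v = predict_viability(fc, doses) if fc.converged else combo[
            "viability_pct"].values
    else:
        mono_v = mono["viability_pct"].values
        combo_v = combo["viability_pct"].values
    e2 = inhibition_from_viability(mono_v)
    add, _ = additive_curve(e2, ir_inhibition)
    obs = inhibition_from_viability(combo_v)
    call = classify_synergy(obs, add, tol=tol, min_points=min_points)
    fold, good = crt_fold_change(ic50_mono, ic50_combo)
    return SynergyCall(
        verdict=call.verdict,
        n_doses_below_additive=call.n_doses_below_additive,
        tol=tol,
        min_points=min_points,
        fold_change=fold,
        good_combination=good,
    )
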