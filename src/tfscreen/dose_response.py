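"""Logistic dose-response modelling and TF classification.

For each TF, the per-cell overall transcriptomic change is modelled as a
four-parameter logistic function of dose d (ln-UMI units):

    change(d) = a + K / (1 + exp(-s (d - d50)))

K (the plateau) is the TF's *reprogramming capacity*; d50 (the midpoint) its
*dose sensitivity*.  TFs are classified high-capacity when the fitted
asymptote a + K exceeds the functional-change threshold (0.23) *and* the
plateau is supported by the data (d50 below the observed max dose);
high-capacity TFs split into high/low sensitivity by d50.  A truncation
power analysis quantifies how a limited max dose can masquerade a
high-capacity TF as low-capacity, yielding a per-TF probability of a false
low-capacity call given its observed max dose.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import least_squares

from .embed_change import DEFAULT_CHANGE_THRESHOLD

logger = logging.getLogger(__name__)

CAPACITY_HIGH = "high"
CAPACITY_LOW = "low"
SENSITIVITY_HIGH = "high"
SENSITIVITY_LOW = "low"
SENSITIVITY_NA = "NA"

BOUNDS_LO = np.array([-0.2, 0.0, 0.0, 0.1])   # a, K, d50, s
BOUNDS_HI_BASE = np.array([0.2, 3.0, np.inf, 20.0])


@dataclass
class DoseResponseFit:
    tf: str
    baseline: float
    plateau: float
    midpoint: float
    slope: float
    rmse: float
    n_cells: int
    max_dose: float
    converged: bool
    capacity_class: str = ""
    sensitivity_class: str = ""
    p_false_low: float = float("nan")

    @property
    def asymptote(self) -> float:
        return self.baseline + self.plateau


def _model(params, d):
    a, K, d50, s = params
    return a + K / (1.0 + np.exp(-s * (d - d50)))


def _jacobian(params, d):
    a, K, d50, s = params
    L = 1.0 / (1.0 + np.exp(-s * (d - d50)))
    dL = L * (1.0 - L)
    return np.column_stack([
        np.ones_like(d),        # d/da
        L,                      # d/dK
        -K * s * dL,            # d/dd50
        K * (d - d50) * dL,     # d/ds
    ])


def fit_logistic(doses, changes, tf: str = "", min_cells: int = 20,
                 min_span: float = 2.0, n_starts: str = "full") -> DoseResponseFit:
    """Bounded least-squares logistic fit with a multi-start grid.

    Bounds: a in [-0.2, 0.2], K in [0, 3], s in [0.1, 20],
    d50 in [0, max_dose + 1].  Initial values run over a grid of d50
    (dose quantiles) and s; the best-RMSE solution is kept.  Fits from
    fewer than ``min_cells`` cells or a dose span below ``min_span``
    ln-UMI units are rejected (non-converged).
    """
    doses = np.asarray(doses, float)
    changes = np.asarray(changes, float)
    ok = np.isfinite(doses) & np.isfinite(changes)
    doses, changes = doses[ok], changes[ok]
    n = len(doses)
    max_dose = float(doses.max()) if n else float("nan")
    if n < min_cells or (n and (doses.max() - doses.min()) < min_span):
        return DoseResponseFit(tf, np.nan, np.nan, np.nan, np.nan, np.nan,
                               n, max_dose, converged=False)

    lo = BOUNDS_LO.copy()
    hi = BOUNDS_HI_BASE.copy()
    hi[2] = max_dose + 1.0

    if n_starts == "fast":
        d50_grid = np.quantile(doses, [0.3, 0.7])
        s_grid = [1.0, 6.0]
    else:
        d50_grid = np.quantile(doses, [0.2, 0.4, 0.6, 0.8])
        s_grid = [0.5, 2.0, 8.0]
    a0 = float(np.clip(np.median(changes[doses <= np.quantile(doses, 0.1)])
                       if (doses <= np.quantile(doses, 0.1)).sum() >= 3 else 0.0,
                       lo[0], hi[0]))
    K0 = float(np.clip(np.quantile(changes, 0.95) - a0, 1e-3, hi[1]))

    best, best_cost = None, np.inf
    for d50_0 in d50_grid:
        for s0 in s_grid:
            x0 = np.clip([a0, K0, d50_0, s0], lo, hi)
            try:
                res = least_squares(
                    lambda p: _model(p, doses) - changes, x0,
                    jac=lambda p: _jacobian(p, doses),
                    bounds=(lo, hi), method="trf", max_nfev=500)
            except Exception:   # pragma: no cover - defensive
                continue
            if res.cost < best_cost:
                best, best_cost = res, res.cost
    if best is None:
        return DoseResponseFit(tf, np.nan, np.nan, np.nan, np.nan, np.nan,
                               n, max_dose, converged=False)
    a, K, d50, s = best.x
    rmse = float(np.sqrt(2 * best.cost / n))
    return DoseResponseFit(tf, float(a), float(K), float(d50), float(s),
                           rmse, n, max_dose, converged=True)


def classify_tf(fit: DoseResponseFit,
                capacity_threshold: float = DEFAULT_CHANGE_THRESHOLD,
                sensitivity_threshold_d50: float = 2.75) -> DoseResponseFit:
    """Assign capacity and sensitivity classes to a converged fit.

    Capacity is high iff the fitted asymptote a + K exceeds
    ``capacity_threshold`` *and* the plateau is supported (d50 < max dose);
    an extrapolated plateau beyond the observed dose range is not evidence
    of capacity.  Sensitivity (high iff d50 <= ``sensitivity_threshold_d50``)
    is defined only for high-capacity TFs.
    """
    if not fit.converged:
        fit.capacity_class = ""
        fit.sensitivity_class = ""
        return fit
    supported = fit.midpoint < fit.max_dose
    if fit.asymptote > capacity_threshold and supported:
        fit.capacity_class = CAPACITY_HIGH
        fit.sensitivity_class = (
            SENSITIVITY_HIGH if fit.midpoint <= sensitivity_threshold_d50
            else SENSITIVITY_LOW)
    else:
        fit.capacity_class = CAPACITY_LOW
        fit.sensitivity_class = SENSITIVITY_NA
    return fit


def cohort_sensitivity_threshold(fits) -> float:
    """Median d50 of high-capacity fits (data-driven sensitivity split)."""
    d50s = [f.midpoint for f in fits
            if f.converged and f.capacity_class == CAPACITY_HIGH]
    if not d50s:
        raise ValueError("no high-capacity fits to derive a threshold from")
    return float(np.median(d50s))


def classify_cohort(fits, capacity_threshold: float = DEFAULT_CHANGE_THRESHOLD,
                    sensitivity_threshold_d50=None):
    """Classify a cohort; ``sensitivity_threshold_d50=None`` uses the cohort
    median d50 of high-capacity TFs (two-pass)."""
    for f in fits:
        classify_tf(f, capacity_threshold, sensitivity_threshold_d50
                    if sensitivity_threshold_d50 is not None else np.inf)
    if sensitivity_threshold_d50 is None:
        thr = cohort_sensitivity_threshold(fits)
        for f in fits:
            classify_tf(f, capacity_threshold, thr)
    return fits


# ---------------------------------------------------------------------------
# Truncation power analysis
# ---------------------------------------------------------------------------

@dataclass
class PowerAnalysisResult:
    records: pd.DataFrame          # per (tf, threshold): max_dose, correct
    coef: tuple                    # logit intercept, slope on max dose
    p_false_low: dict              # low-capacity tf -> probability
    curve: pd.DataFrame            # dose grid -> predicted correctness


def power_analysis(data: dict, fits, capacity_threshold: float = DEFAULT_CHANGE_THRESHOLD,
                   sensitivity_threshold_d50: float = 2.75,
                   step: float = 0.25, min_threshold: float = 2.0,
                   min_cells: int = 20) -> PowerAnalysisResult:
    """Dose-truncation power analysis.

    For each high-capacity TF, cells above a descending grid of dose
    thresholds (step 0.25 ln-UMI units, from the TF's max dose down to 2)
    are removed, the logistic model is refit and the TF reclassified; refit
    failures count as misclassification.  A binomial-logit regression of
    correct classification on the truncated max dose then yields, for each
    low-capacity TF, the probability that it was falsely called low capacity
    given its observed max dose (1 - predicted correctness).
    """
    fits_by_tf = {f.tf: f for f in fits}
    high = [f for f in fits if f.capacity_class == CAPACITY_HIGH]
    if len(high) < 5:
        raise ValueError(f"need >= 5 high-capacity TFs, got {len(high)}")

    rows = []
    for f in high:
        doses, changes = data[f.tf]
        doses = np.asarray(doses, float)
        changes = np.asarray(changes, float)
        thresholds = np.arange(f.max_dose, min_threshold - 1e-9, -step)
        for t in thresholds:
            keep = doses <= t
            sub_d, sub_c = doses[keep], changes[keep]
            if keep.sum() < min_cells:
                correct = False
                obs_max = float(sub_d.max()) if keep.any() else float(t)
            else:
                refit = fit_logistic(sub_d, sub_c, tf=f.tf, min_cells=min_cells,
                                     min_span=0.0, n_starts="fast")
                refit = classify_tf(refit, capacity_threshold,
                                    sensitivity_threshold_d50)
                correct = refit.converged and refit.capacity_class == CAPACITY_HIGH
                obs_max = float(sub_d.max())
            rows.append({"tf": f.tf, "threshold": float(t),
                         "max_dose": obs_max, "correct": bool(correct)})
    records = pd.DataFrame(rows)

    X = sm.add_constant(records["max_dose"].values)
    y = records["correct"].astype(float).values
    model = sm.GLM(y, X, family=sm.families.Binomial())
    try:
        res = model.fit(maxiter=200)
        coef = tuple(res.params)
    except Exception:
        logger.warning("logit fit failed; falling back to empirical rates")
        res, coef = None, (np.nan, np.nan)

    def predict(md):
        if res is None:
            return float(y.mean())
        return float(res.predict(np.array([[1.0, md]]))[0])

    grid = np.linspace(min_threshold, records["max_dose"].max(), 50)
    if res is not None:
        pred = res.predict(sm.add_constant(grid))
    else:
        pred = np.full_like(grid, y.mean())
    curve = pd.DataFrame({"max_dose": grid, "p_correct_high": pred})

    p_false_low = {}
    for f in fits:
        if f.capacity_class == CAPACITY_LOW and f.converged:
            p_false_low[f.tf] = 1.0 - predict(f.max_dose)
            fits_by_tf[f.tf].p_false_low = p_false_low[f.tf]
    return PowerAnalysisResult(records=records, coef=coef,
                               p_false_low=p_false_low, curve=curve)


def fits_to_frame(fits) -> pd.DataFrame:
    return pd.DataFrame([{
        "tf": f.tf, "baseline": f.baseline, "plateau": f.plateau,
        "midpoint": f.midpoint, "slope": f.slope, "rmse": f.rmse,
        "n_cells": f.n_cells, "max_dose": f.max_dose,
        "converged": f.converged, "capacity_class": f.capacity_class,
        "sensitivity_class": f.sensitivity_class,
        "p_false_low": f.p_false_low,
    } for f in fits])
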