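"""Piecewise-linear mixed models for glucose-clamp timecourses.

Plasma glucose (or insulin) during a clamp rises from baseline toward the
target and then settles, so the population curve is modelled as a hinge
regression with a fixed breakpoint (55 min after clamp start): per
condition, an intercept, a pre-breakpoint slope, and a slope change that
switches on after the breakpoint.  The mean curve is continuous at the
breakpoint by construction.  Repeated samples share a random intercept
for study visit nested within subject; estimation is REML via statsmodels
MixedLM, with asymptotic-normal 95% CIs and uncorrected Wald p-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "DESIGN_COLUMNS",
    "PiecewiseFit",
    "build_piecewise_design",
    "fit_clamp_model",
    "predict_mean_curve",
]

#: Fixed-effect columns of the hinge design, in order.
DESIGN_COLUMNS = ("intercept", "cond_hyper", "time", "time_x_hyper",
                  "hinge_eu", "hinge_hyper")

_REQUIRED = ("subject", "visit", "condition", "time", "value")


def build_piecewise_design(series: pd.DataFrame, breakpoint: float = 55.0
                           ) -> tuple[pd.DataFrame, np.ndarray]:
    """Build the hinge design matrix and response for a clamp series.

    ``series`` is tidy with columns ``subject, visit, condition, time,
    value`` and conditions ``eu``/``hyper``.  Columns of the returned
    design: intercept, hyper indicator, time, time x hyper, and one hinge
    term ``max(0, t - breakpoint)`` per condition (zero for ``t <=
    breakpoint`` exactly).
    """
    missing = [c for c in _REQUIRED if c not in series.columns]
    if missing:
        raise ValueError(f"series is missing columns {missing}")
    conds = set(series["condition"])
    for cond in ("eu", "hyper"):
        if cond not in conds:
            raise ValueError(f"condition {cond!r} absent from the series")
    unknown = conds - {"eu", "hyper"}
    if unknown:
        raise ValueError(f"unknown conditions {sorted(unknown)}")
    t = series["time"].to_numpy(float)
    if np.any(t < 0):
        raise ValueError("times must be >= 0 (minutes from clamp start)")
    hyper = (series["condition"] == "hyper").to_numpy(float)
    hinge = np.maximum(0.0, t - breakpoint)
    design = pd.DataFrame({
        "intercept": np.ones_like(t),
        "cond_hyper": hyper,
        "time": t,
        "time_x_hyper": t * hyper,
        "hinge_eu": hinge * (1.0 - hyper),
        "hinge_hyper": hinge * hyper,
    }, index=series.index)
    return design, series["value"].to_numpy(float)


@dataclass(frozen=True)
class PiecewiseFit:
    """Fixed effects, CIs and variance components of one clamp fit."""

    breakpoint: float
    estimates: pd.DataFrame  # index: DESIGN_COLUMNS; columns: estimate, ci_low, ci_high, p
    variance_components: Mapping[str, float]
    n_obs: int
    converged: bool
    engine: str  # "mixedlm" or "ols" (degenerate zero-variance fallback)

    def coef(self, name: str) -> float:
        return float(self.estimates.loc[name, "estimate"])

    @property
    def slopes(self) -> dict[str, float]:
        """Per-condition slopes before and after the breakpoint."""
        b = self.coef
        return {
            "eu_pre": b("time"),
            "eu_post": b("time") + b("hinge_eu"),
            "hyper_pre": b("time") + b("time_x_hyper"),
            "hyper_post": b("time") + b("time_x_hyper") + b("hinge_hyper"),
        }


def fit_clamp_model(series: pd.DataFrame, breakpoint: float = 55.0,
                    alpha: float = 0.05) -> PiecewiseFit:
    """Fit the piecewise linear mixed model to one analyte's series.

    Random intercepts for subject and for visit nested within subject;
    REML estimation.  If the residual variance is numerically zero (e.g.
    noiseless synthetic data) the mixed model is degenerate and the same
    design is solved by ordinary least squares instead, reported with
    ``engine="ols"``.
    """
    import statsmodels.api as sm
    from scipy import stats as sps

    if series["subject"].nunique() < 2:
        raise ValueError("need at least two subjects")
    design, y = build_piecewise_design(series, breakpoint)
    X = design.to_numpy(float)

    # zero-residual degenerate case: exact interpolation, OLS fallback
    beta_ols, res_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta_ols
    scale = max(float(np.std(y)), 1.0)
    if float(np.max(np.abs(resid))) < 1e-8 * scale:
        est = pd.DataFrame({"estimate": beta_ols,
                            "ci_low": beta_ols, "ci_high": beta_ols,
                            "p": np.zeros_like(beta_ols)},
                           index=list(DESIGN_COLUMNS))
        return PiecewiseFit(breakpoint, est,
                            {"subject": 0.0, "visit": 0.0, "residual": 0.0},
                            n_obs=len(y), converged=True, engine="ols")

    frame = design.copy()
    frame["value"] = y
    frame["subject"] = series["subject"].to_numpy()
    frame["visit"] = series["visit"].astype(str).to_numpy()
    fixed = " + ".join(c for c in DESIGN_COLUMNS if c != "intercept")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM.from_formula(
            f"value ~ {fixed}", data=frame, groups="subject",
            re_formula="1", vc_formula={"visit": "0 + C(visit)"})
        result = model.fit(reml=True)
    beta = np.asarray(result.fe_params, float)
    se = np.asarray(result.bse_fe, float)
    z = sps.norm.ppf(1.0 - alpha / 2.0)
    pvals = 2.0 * sps.norm.sf(np.abs(beta / np.where(se > 0, se, np.inf)))
    est = pd.DataFrame({"estimate": beta, "ci_low": beta - z * se,
                        "ci_high": beta + z * se, "p": pvals},
                       index=list(DESIGN_COLUMNS))
    vcomp = {
        "subject": float(result.cov_re.iloc[0, 0]),
        "visit": float(result.vcomp[0]),
        "residual": float(result.scale),
    }
    return PiecewiseFit(breakpoint, est, vcomp, n_obs=len(y),
                        converged=bool(result.converged), engine="mixedlm")


def predict_mean_curve(fit: PiecewiseFit, times: np.ndarray,
                       condition: str) -> np.ndarray:
    """Population mean curve of one condition at the given times."""
    if condition not in ("eu", "hyper"):
        raise ValueError("condition must be 'eu' or 'hyper'")
    t = np.asarray(times, float)
    hyper = 1.0 if condition == "hyper" else 0.0
    hinge = np.maximum(0.0, t - fit.breakpoint)
    b = fit.coef
    return (b("intercept") + b("cond_hyper") * hyper
            + (b("time") + b("time_x_hyper") * hyper) * t
            + (b("hinge_hyper") if hyper else b("hinge_eu")) * hinge)
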