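"""Hypothesis tests for fixed effects and variance components.

Three routes are provided, matching standard practice for this model class:

* Wald z-tests for single fixed-effect terms (the group x time interaction is
  the default effect of interest);
* likelihood-ratio tests (LRTs) between structurally nested models refit by
  ML, with a chi-square reference — anti-conservative for variance
  components because the null value 0 lies on the parameter-space boundary;
* parametric bootstrap tests that simulate from the fitted null model and
  refit both models per replicate, giving a reference distribution that
  respects the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import LongitudinalDataset
from .model import (LMMResults, ModelSpec, SpecError, TrajectoryLMM,
                    embed_theta)

__all__ = [
    "TestResult",
    "wald_test",
    "lrt",
    "parametric_bootstrap_test",
    "fixed_effect_ci",
    "is_nested",
]


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    df: int | None = None
    n_boot: int | None = None
    n_boot_failed: int | None = None
    note: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value outside [0, 1]")

    def to_dict(self) -> dict:
        out = {"statistic": self.statistic, "p_value": self.p_value,
               "method": self.method}
        for k in ("df", "n_boot", "n_boot_failed"):
            v = getattr(self, k)
            if v is not None:
                out[k] = v
        if self.note:
            out["note"] = self.note
        return out


def wald_test(fit: LMMResults, term: str = "group:time") -> TestResult:
    """Wald z-test of a fixed-effect term against zero.

    Uses the standard-normal reference z = beta_hat / se(beta_hat); at small
    numbers of independent subjects this approximation is what drives the
    conservatism seen in the calibration study.
    """
    if not fit.converged:
        raise RuntimeError(
            "refusing Wald test on a non-converged fit; inspect the "
            "stability report or refit with another optimizer")
    if term not in fit.params.index:
        raise KeyError(f"term {term!r} not among fitted fixed effects")
    z = float(fit.params[term] / fit.bse[term])
    p = 2.0 * float(stats.norm.sf(abs(z)))
    return TestResult(statistic=z, p_value=min(p, 1.0), method="wald")


def is_nested(spec_null: ModelSpec, spec_alt: ModelSpec) -> bool:
    """Structural nesting: every null term is present in the alternative."""
    if spec_null.fixed_terms != spec_alt.fixed_terms:
        return False
    for lv in spec_null.levels:
        lv_alt = spec_alt.level(lv.level)
        if lv_alt is None or not set(lv.terms) <= set(lv_alt.terms):
            return False
    if spec_null.has_ar1 and not spec_alt.has_ar1:
        return False
    return True


def _boundary_note(spec_null: ModelSpec, spec_alt: ModelSpec) -> str:
    if spec_null.n_theta < spec_alt.n_theta and (
            len(spec_alt.levels) > len(spec_null.levels)
            or any(spec_alt.level(lv.level).dim > lv.dim
                   for lv in spec_null.levels)):
        return ("tested parameters include variances whose null value lies "
                "on the boundary of the parameter space; the chi-square "
                "reference is approximate — consider the parametric bootstrap")
    return ""


def lrt(fit_null: LMMResults, fit_alt: LMMResults) -> TestResult:
    """Likelihood-ratio test of nested ML fits, chi-square reference."""
    if fit_null.method != "ml" or fit_alt.method != "ml":
        raise ValueError("LRT requires both fits by maximum likelihood (ML)")
    if not is_nested(fit_null.spec, fit_alt.spec):
        raise SpecError("null model is not nested in the alternative")
    stat = 2.0 * (fit_alt.llf - fit_null.llf)
    if stat < -1e-6:
        raise ValueError(
            f"alternative log-likelihood below null by {-stat / 2:.3g}; "
            "refit (e.g. warm-started) before testing")
    stat = max(stat, 0.0)
    df = fit_alt.spec.n_theta - fit_null.spec.n_theta
    if df == 0:
        return TestResult(statistic=stat, p_value=1.0, method="lrt", df=0)
    p = float(stats.chi2.sf(stat, df))
    return TestResult(statistic=stat, p_value=p, method="lrt", df=df,
                      note=_boundary_note(fit_null.spec, fit_alt.spec))


def parametric_bootstrap_test(
    spec_null: ModelSpec,
    spec_alt: ModelSpec,
    ds: LongitudinalDataset,
    B: int = 1000,
    seed: int | None = None,
    optimizer: str = "lbfgsb",
) -> TestResult:
    """Parametric bootstrap LRT for (boundary) variance-component tests.

    Simulates ``B`` datasets from the ML fit of the null model, refits both
    models on each, and reports p = (1 + #{LRT* >= LRT_obs}) / (B_ok + 1)
    where B_ok excludes replicates whose refits failed. More than 20%
    failures flags the result as unreliable.
    """
    if not is_nested(spec_null, spec_alt):
        raise SpecError("null model is not nested in the alternative")
    model_null = TrajectoryLMM(ds, spec_null)
    model_alt = TrajectoryLMM(ds, spec_alt)
    fit_null = model_null.fit(method="ml", optimizer=optimizer)
    warm = embed_theta(spec_null, fit_null.theta, spec_alt)
    fit_alt = model_alt.fit(method="ml", optimizer=optimizer, start=warm)
    if fit_null.singular:
        import warnings
        warnings.warn("null fit is singular (variance at boundary); "
                      "bootstrap proceeds from the boundary value")
    stat_obs = max(2.0 * (fit_alt.llf - fit_null.llf), 0.0)

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(B)
    n_ge = 0
    n_failed = 0
    for child in children:
        rng = np.random.default_rng(child)
        y_star = fit_null.simulate(rng)
        try:
            model_null.problem.set_response(y_star)
            model_alt.problem.set_response(y_star)
            f0 = model_null.fit(method="ml", optimizer=optimizer)
            f1 = model_alt.fit(method="ml", optimizer=optimizer,
                               start=embed_theta(spec_null, f0.theta, spec_alt))
            if not (f0.converged and f1.converged):
                n_failed += 1
                continue
            stat_b = max(2.0 * (f1.llf - f0.llf), 0.0)
        except Exception:  # noqa: BLE001 - count refit failures
            n_failed += 1
            continue
        if stat_b >= stat_obs:
            n_ge += 1
    # restore original responses
    y0 = ds.df["response"].to_numpy(dtype=float)
    model_null.problem.set_response(y0)
    model_alt.problem.set_response(y0)
    b_ok = B - n_failed
    p = (1.0 + n_ge) / (b_ok + 1.0)
    note = ""
    if n_failed > 0.2 * B:
        note = "unreliable: more than 20% of bootstrap refits failed"
    return TestResult(statistic=stat_obs, p_value=p,
                      method="parametric_bootstrap", n_boot=b_ok,
                      n_boot_failed=n_failed, note=note)


def fixed_effect_ci(fit: LMMResults, level: float = 0.95) -> pd.DataFrame:
    """Normal-theory confidence intervals beta_hat +/- z * se per term."""
    if not fit.converged:
        raise RuntimeError("cannot form intervals from a non-converged fit")
    if not 0.0 <= level < 1.0:
        raise ValueError("level must be in [0, 1)")
    z = stats.norm.ppf(0.5 + level / 2.0)
    lo = fit.params - z * fit.bse
    hi = fit.params + z * fit.bse
    return pd.DataFrame({"estimate": fit.params, "lower": lo, "upper": hi,
                         "level": level})
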