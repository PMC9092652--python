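"""The eight named model structures and the nested-comparison ladder.

Roman-numeral ids follow the re-analysis convention for two-group nested
growth designs (donor = cluster, mouse = subject):

    I     donor intercept+slope, mouse intercept+slope, independent errors
    II    donor intercept,       mouse intercept+slope
    III                          mouse intercept+slope
    IV                           mouse intercept
    V     no random effects (ordinary two-factor ANOVA with interaction)
    VI                           mouse slope,           AR(1) errors
    VII                          mouse intercept,       AR(1) errors
    VIII  no random effects,                            AR(1) errors

Coefficients are reported from REML fits; likelihood-ratio tests along the
nesting edges use ML refits, warm-started up the ladder so the likelihood is
monotone under nesting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import LongitudinalDataset
from .model import (LMMResults, ModelSpec, RandomEffectsLevel,
                    ResidualStructure, SpecError, TrajectoryLMM, embed_theta)
from .inference import is_nested, lrt, fixed_effect_ci

__all__ = [
    "MODEL_IDS",
    "NESTED_ONLY_IDS",
    "LADDER_EDGES",
    "NamedModel",
    "make_model_spec",
    "fit_ladder",
    "comparison_table",
    "ComparisonTable",
    "residual_profiles",
    "coefficient_ci_table",
]

MODEL_IDS = ("I", "II", "III", "IV", "V", "VI", "VII", "VIII")
#: models available when the data are not nested (no donor level)
NESTED_ONLY_IDS = ("III", "IV", "V")

_LABELS = {
    "I": "Donor intercept and slope + mouse intercept and slope",
    "II": "Donor intercept + mouse intercept and slope",
    "III": "Mouse intercept and slope",
    "IV": "Mouse intercept",
    "V": "No random effects",
    "VI": "Mouse slope + AR(1) errors",
    "VII": "Mouse intercept + AR(1) errors",
    "VIII": "AR(1) errors only",
}

#: nesting edges (child ⊂ parent) fixed a priori along the comparison ladder
LADDER_EDGES = (
    ("II", "I"), ("III", "II"), ("IV", "III"), ("V", "IV"),
    ("VIII", "VI"), ("VIII", "VII"), ("V", "VIII"),
)


@dataclass(frozen=True)
class NamedModel:
    id: str
    spec: ModelSpec
    label: str


def make_model_spec(model_id: str, nested: bool = True) -> NamedModel:
    """Build one of the eight named specifications.

    ``nested=False`` restricts to the mouse-level ladder (III-V), for designs
    with one mouse per donor; donor-level models then raise a spec error.
    """
    mid = str(model_id).upper()
    if mid not in MODEL_IDS:
        raise SpecError(f"unknown model id {model_id!r}; expected I-VIII")
    if not nested and mid not in NESTED_ONLY_IDS:
        raise SpecError(
            f"model {mid} needs a nested (donor-level) design; "
            f"non-nested data support models {NESTED_ONLY_IDS}")
    donor_is = RandomEffectsLevel("cluster", intercept=True, slope=True)
    donor_i = RandomEffectsLevel("cluster", intercept=True, slope=False)
    mouse_is = RandomEffectsLevel("subject", intercept=True, slope=True)
    mouse_i = RandomEffectsLevel("subject", intercept=True, slope=False)
    mouse_s = RandomEffectsLevel("subject", intercept=False, slope=True)
    indep = ResidualStructure("independent")
    ar1 = ResidualStructure("ar1")
    levels_resid = {
        "I": ((donor_is, mouse_is), indep),
        "II": ((donor_i, mouse_is), indep),
        "III": ((mouse_is,), indep),
        "IV": ((mouse_i,), indep),
        "V": ((), indep),
        "VI": ((mouse_s,), ar1),
        "VII": ((mouse_i,), ar1),
        "VIII": ((), ar1),
    }[mid]
    spec = ModelSpec(levels=levels_resid[0], residual=levels_resid[1])
    return NamedModel(id=mid, spec=spec, label=_LABELS[mid])


def _ladder_order(ids) -> list:
    """Order ids smallest to largest so warm starts flow up the ladder."""
    rank = {"V": 0, "IV": 1, "III": 2, "II": 3, "I": 4,
            "VIII": 1, "VII": 2, "VI": 2}
    return sorted(ids, key=lambda i: (rank[str(i).upper()], str(i)))


def fit_ladder(ds: LongitudinalDataset, ids, method: str = "reml",
               nested: bool | None = None, optimizer: str = "lbfgsb") -> dict:
    """Fit several named models, warm-starting larger models from nested fits.

    Returns {id: LMMResults}. A cold fit is kept unless a warm start from a
    nested, already-fitted model improves the likelihood, which enforces
    the loglik ordering I >= II >= III >= IV >= V at convergence.
    """
    if nested is None:
        nested = ds.has_cluster
    models = {str(i).upper(): make_model_spec(i, nested=nested) for i in ids}
    fits: dict = {}
    for mid in _ladder_order(models):
        nm = models[mid]
        model = TrajectoryLMM(ds, nm.spec)
        try:
            res = model.fit(method=method, optimizer=optimizer)
        except Exception:  # noqa: BLE001 - flagged row, ladder continues
            fits[mid] = None
            continue
        for omid, ofit in fits.items():
            if ofit is None or ofit.method != method:
                continue
            if is_nested(ofit.spec, nm.spec) and ofit.llf > res.llf + 1e-9:
                warm = model.fit(method=method, optimizer=optimizer,
                                 start=embed_theta(ofit.spec, ofit.theta,
                                                   nm.spec))
                if warm.llf > res.llf:
                    res = warm
        fits[mid] = res
    return fits


@dataclass
class ComparisonTable:
    """Per-model coefficient/loglik table plus the LRT edge table."""

    models: pd.DataFrame   # one row per model id
    lrt_edges: pd.DataFrame  # one row per tested nested pair

    def to_text(self) -> str:
        with pd.option_context("display.width", 120):
            return ("Model comparison (coefficients from REML, LRTs from ML)\n"
                    + self.models.to_string() + "\n\nNested-pair LRTs\n"
                    + (self.lrt_edges.to_string()
                       if len(self.lrt_edges) else "  (none)"))


def comparison_table(ds: LongitudinalDataset, ids=None,
                     nested: bool | None = None,
                     optimizer: str = "lbfgsb") -> ComparisonTable:
    """REML coefficient table with ML likelihood-ratio tests along the ladder.

    Non-nested pairs are never compared; a non-converged model keeps its row
    (flagged) and the ladder continues.
    """
    if nested is None:
        nested = ds.has_cluster
    if ids is None:
        ids = ("I", "II", "III", "IV", "V") if nested else NESTED_ONLY_IDS
    ids = [str(i).upper() for i in ids]
    reml_fits = fit_ladder(ds, ids, method="reml", nested=nested,
                           optimizer=optimizer)
    ml_fits = fit_ladder(ds, ids, method="ml", nested=nested,
                         optimizer=optimizer)
    rows = []
    for mid in ids:
        nm = make_model_spec(mid, nested=nested)
        f = reml_fits.get(mid)
        row: dict = {"model": mid, "label": nm.label}
        if f is None:
            row["converged"] = False
            rows.append(row)
            continue
        for term in f.params.index:
            row[term] = f"{f.params[term]:.4f} ({f.bse[term]:.4f})"
        fml = ml_fits.get(mid)
        row["loglik_reml"] = f.llf
        row["loglik_ml"] = fml.llf if fml is not None else np.nan
        row["converged"] = f.converged and (fml is None or fml.converged)
        row["singular"] = f.singular
        rows.append(row)
    edges = []
    for child, parent in LADDER_EDGES:
        if child in ids and parent in ids:
            f0, f1 = ml_fits.get(child), ml_fits.get(parent)
            if f0 is None or f1 is None:
                continue
            res = lrt(f0, f1)
            edges.append({"null": child, "alternative": parent,
                          "statistic": res.statistic, "df": res.df,
                          "p_value": res.p_value})
    return ComparisonTable(models=pd.DataFrame(rows),
                           lrt_edges=pd.DataFrame(edges))


def residual_profiles(fit: LMMResults) -> tuple:
    """Per-subject conditional residual time series and per-time spread.

    Returns ``(profiles, spread)``: tidy (subject, time, resid) rows ordered
    by time within subject, and the residual SD at each time point.
    """
    if not fit.converged:
        raise RuntimeError("residual profiles need a converged fit")
    df = fit.model.dataset.df
    profiles = pd.DataFrame({
        "subject": df["subject"], "time": df["time"], "resid": fit.resid,
    }).sort_values(["subject", "time"], kind="mergesort").reset_index(drop=True)
    spread = (profiles.groupby("time")["resid"].std(ddof=1)
              .rename("resid_sd").reset_index())
    return profiles, spread


def coefficient_ci_table(fits: dict, level: float = 0.95) -> pd.DataFrame:
    """Fixed-effect confidence intervals keyed by (model id, term)."""
    rows = []
    for mid, f in fits.items():
        if f is None:
            continue
        ci = fixed_effect_ci(f, level)
        for term in ci.index:
            rows.append({"model": mid, "term": term,
                         "estimate": ci.loc[term, "estimate"],
                         "lower": ci.loc[term, "lower"],
                         "upper": ci.loc[term, "upper"],
                         "level": level})
    return pd.DataFrame(rows)
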