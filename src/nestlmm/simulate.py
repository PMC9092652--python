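"""Synthetic longitudinal data: simulation scenarios and a demo dataset.

The simulation scenarios draw each subject's response vector from a
multivariate normal with mean ``X beta`` (the interaction coefficient scaled
by an effect fraction) and covariance ``Z g Z' + sigma^2 I`` over that
subject's timepoints; subjects are independent and share one covariance
matrix. Three covariance scenarios are supported:

* ``intercept_slope`` — random intercept and slope per mouse,
* ``intercept_only`` — random intercept per mouse,
* ``none``           — no random effects.

The default parameter set ``blanton-like-v1`` emulates a two-group
percent-weight-change experiment over 32 days with clearly separated group
trajectories and moderate variance components; see ``docs/methods.md`` for
the rationale behind each value.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .data import DesignGrid, LongitudinalDataset, apply_missingness, build_design

__all__ = [
    "BLANTON_DAYS",
    "DEFAULT_FIXED_EFFECTS",
    "DEFAULT_PARAMS_VERSION",
    "SimulationScenario",
    "simulate_dataset",
    "theoretical_covariance",
    "make_demo_dataset",
    "make_independent_design",
    "default_nested_grid",
    "blanton_design_grid",
]

#: the 12 measurement days of the original growth experiment
BLANTON_DAYS = (0.0, 1.0, 3.0, 4.0, 7.0, 11.0, 14.0, 18.0, 21.0, 25.0, 28.0, 32.0)

DEFAULT_PARAMS_VERSION = "blanton-like-v1"
#: (b0, b1, b2, b3): intercept, group offset, slope %/day, interaction %/day
DEFAULT_FIXED_EFFECTS = (0.0, -1.0, 0.75, -0.5)
_DEFAULT_SIGMA2 = 4.0
_DEFAULT_G_INTERCEPT = 4.0
_DEFAULT_G_SLOPE = 0.01

_SCENARIOS = ("intercept_slope", "intercept_only", "none")


@dataclass(frozen=True)
class SimulationScenario:
    """Generating model for one simulation condition.

    ``effect_fraction`` scales the interaction coefficient b3 only, tracing
    the power curve from the null (0) to the full observed effect (1).
    """

    name: str
    fixed_effects: tuple = DEFAULT_FIXED_EFFECTS
    g: tuple | None = None          # subject-level covariance (d x d) or None
    sigma2: float = _DEFAULT_SIGMA2
    effect_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.name not in _SCENARIOS:
            raise ValueError(f"unknown scenario {self.name!r}; "
                             f"expected one of {_SCENARIOS}")
        if not 0.0 <= self.effect_fraction <= 1.0:
            raise ValueError("effect_fraction must be in [0, 1]")
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")
        g = self.g
        if self.name == "none":
            if g is not None:
                raise ValueError("scenario 'none' takes no g matrix")
        else:
            dim = 2 if self.name == "intercept_slope" else 1
            if g is None:
                g = (np.diag([_DEFAULT_G_INTERCEPT, _DEFAULT_G_SLOPE])
                     if dim == 2 else np.array([[_DEFAULT_G_INTERCEPT]]))
            g = np.atleast_2d(np.asarray(g, dtype=float))
            if g.shape != (dim, dim):
                raise ValueError(f"g must be {dim}x{dim} for {self.name}")
            if np.linalg.eigvalsh(g).min() < -1e-10:
                raise ValueError("g must be positive semi-definite")
            object.__setattr__(self, "g", tuple(map(tuple, g)))

    @property
    def g_matrix(self) -> np.ndarray | None:
        return None if self.g is None else np.asarray(self.g, dtype=float)

    def beta(self) -> np.ndarray:
        b = np.asarray(self.fixed_effects, dtype=float).copy()
        b[3] = b[3] * self.effect_fraction
        return b

    def z_columns(self, times: np.ndarray) -> np.ndarray | None:
        if self.name == "none":
            return None
        if self.name == "intercept_only":
            return np.ones((len(times), 1))
        return np.column_stack([np.ones(len(times)), times])

    def with_fraction(self, effect_fraction: float) -> "SimulationScenario":
        return replace(self, effect_fraction=effect_fraction)


def theoretical_covariance(scenario: SimulationScenario,
                           timepoints) -> np.ndarray:
    """Per-subject covariance Z g Z' + sigma^2 I implied by the scenario."""
    t = np.asarray(timepoints, dtype=float)
    if t.size == 0:
        raise ValueError("timepoints must be nonempty")
    V = scenario.sigma2 * np.eye(len(t))
    z = scenario.z_columns(t)
    if z is not None:
        V += z @ scenario.g_matrix @ z.T
    return V


def _mean_response(scenario: SimulationScenario, group_ind: np.ndarray,
                   times: np.ndarray) -> np.ndarray:
    b = scenario.beta()
    return b[0] + b[1] * group_ind + b[2] * times + b[3] * group_ind * times


def simulate_dataset(scenario: SimulationScenario, grid: DesignGrid,
                     seed: int | None = None,
                     rng: np.random.Generator | None = None) -> LongitudinalDataset:
    """Draw one dataset: independent MVN response vectors per subject.

    Subjects are visited in the deterministic design order, each consuming
    ``len(timepoints)`` standard normals, so a fixed seed gives a
    byte-identical dataset.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    skeleton = build_design(grid)
    df = skeleton.df
    ref = skeleton.group_levels[0]
    y = np.empty(len(df))
    for subj, sub in df.groupby("subject", sort=False, observed=True):
        t = sub["time"].to_numpy(dtype=float)
        gind = float(sub["group"].iloc[0] != ref)
        L = np.linalg.cholesky(theoretical_covariance(scenario, t))
        y[sub.index] = (_mean_response(scenario, gind, t)
                        + L @ rng.standard_normal(len(t)))
    return skeleton.with_response(y)


def default_nested_grid(donors_per_group: int = 4, mice_per_donor: int = 5,
                        timepoints=BLANTON_DAYS) -> DesignGrid:
    """The simulation design: 4+4 donors x 5 mice x the 12 days (480 cells)."""
    return DesignGrid(groups=("healthy", "undernourished"),
                      donors_per_group=donors_per_group,
                      mice_per_donor=mice_per_donor,
                      timepoints=tuple(timepoints))


def blanton_design_grid() -> DesignGrid:
    """The re-analysed design: 3 healthy + 5 undernourished donors x 5 mice."""
    return DesignGrid(groups=("healthy", "undernourished"),
                      donors_per_group={"healthy": 3, "undernourished": 5},
                      mice_per_donor=5, timepoints=BLANTON_DAYS)


def make_independent_design(n_subjects: int,
                            timepoints=BLANTON_DAYS) -> DesignGrid:
    """One mouse per donor, groups balanced: n independent subjects."""
    if n_subjects % 2 != 0:
        raise ValueError("n_subjects must be even (equal groups)")
    if n_subjects < 2:
        raise ValueError("need at least one subject per group")
    return DesignGrid(groups=("healthy", "undernourished"),
                      donors_per_group=n_subjects // 2,
                      mice_per_donor=1, timepoints=tuple(timepoints))


def make_demo_dataset(seed: int = 20220506,
                      donor_slope_sd: float = 0.15,
                      mouse_slope_sd: float = 0.10,
                      resid_sd: float = 1.5,
                      n_missing: int = 43) -> LongitudinalDataset:
    """Blanton-like demo data: 3+5 donors x 5 mice x 12 days, 437 records.

    Growth is change from baseline, so every trajectory is anchored at 0 on
    day 0 and the random effects are slopes (donor- and mouse-level); 43
    records are then removed completely at random, leaving 437.
    """
    grid = blanton_design_grid()
    skeleton = build_design(grid)
    df = skeleton.df
    ref = skeleton.group_levels[0]
    b = np.asarray(DEFAULT_FIXED_EFFECTS, dtype=float)
    rng = np.random.default_rng(seed)
    donor_slopes = {d: rng.normal(0.0, donor_slope_sd)
                    for d in df["cluster"].unique()}
    y = np.empty(len(df))
    for subj, sub in df.groupby("subject", sort=False, observed=True):
        t = sub["time"].to_numpy(dtype=float)
        gind = float(sub["group"].iloc[0] != ref)
        slope = (b[2] + b[3] * gind
                 + donor_slopes[sub["cluster"].iloc[0]]
                 + rng.normal(0.0, mouse_slope_sd))
        eps = rng.normal(0.0, resid_sd, size=len(t))
        eps[t == 0] = 0.0  # baseline anchoring: day-0 response is exactly 0
        y[sub.index] = slope * t + eps
    ds = skeleton.with_response(y)
    if n_missing:
        ds = apply_missingness(ds, n_missing, seed=seed + 1)
    return ds
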