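"""Monte-Carlo type I error and power for the group x time Wald test.

Each cell of a rejection-rate table is defined by (scenario, fitted model,
design, effect fraction): replicate datasets are simulated from the scenario,
the model is fitted by REML, the Wald z-test of the interaction is performed
at the chosen alpha, and the rejection proportion over converged replicates
is reported with an exact (Clopper-Pearson) binomial interval.

Within a table row the fitted models share replicate datasets (common random
numbers), so model contrasts are paired. Replicate seeds are pre-split from
the root seed, making every cell reproducible and order-independent.

The hot path re-uses one pre-processed design per cell and only swaps the
simulated response vector between replicates.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import DesignGrid, build_design
from .model import TrajectoryLMM
from .simulate import SimulationScenario, theoretical_covariance
from .suite import make_model_spec

__all__ = [
    "RejectionRateTable",
    "rejection_rate",
    "type1_table",
    "power_curve",
    "mc_ci",
]

_EFFECT_TERM = "group:time"


def mc_ci(p_hat: float, n_reps: int, level: float = 0.95) -> tuple:
    """Exact (Clopper-Pearson) binomial interval for a Monte-Carlo proportion."""
    if not 0.0 <= p_hat <= 1.0:
        raise ValueError("p_hat must be in [0, 1]")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    k = int(round(p_hat * n_reps))
    ci = stats.binomtest(k, n_reps).proportion_ci(confidence_level=level,
                                                 method="exact")
    return float(ci.low), float(ci.high)


@dataclass
class RejectionRateTable:
    """Tidy table of Monte-Carlo rejection rates, one row per cell."""

    table: pd.DataFrame

    def cell(self, **key) -> pd.Series:
        mask = np.ones(len(self.table), dtype=bool)
        for k, v in key.items():
            mask &= self.table[k] == v
        sub = self.table[mask]
        if len(sub) != 1:
            raise KeyError(f"{key} matches {len(sub)} rows")
        return sub.iloc[0]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


class _CellEngine:
    """Reusable simulate-and-fit machinery for one (scenario, design) pair."""

    def __init__(self, scenario: SimulationScenario, grid: DesignGrid):
        self.scenario = scenario
        self.grid = grid
        self.skeleton = build_design(grid)
        df = self.skeleton.df
        ref = self.skeleton.group_levels[0]
        self.N = len(df)
        # per-subject simulation structure, in dataset (design) order
        self.subjects = []
        b = scenario.beta()
        mean = np.empty(self.N)
        for subj, sub in df.groupby("subject", sort=False, observed=True):
            t = sub["time"].to_numpy(dtype=float)
            gind = float(sub["group"].iloc[0] != ref)
            L = np.linalg.cholesky(theoretical_covariance(scenario, t))
            idx = sub.index.to_numpy()
            mean[idx] = (b[0] + b[1] * gind + b[2] * t + b[3] * gind * t)
            self.subjects.append((idx, L))
        self.mean = mean
        self._problems: dict = {}

    def simulate_y(self, rng: np.random.Generator) -> np.ndarray:
        """Identical draw to simulate_dataset on the same grid and rng state."""
        y = np.empty(self.N)
        for idx, L in self.subjects:
            y[idx] = L @ rng.standard_normal(len(idx))
        return self.mean + y

    def model_for(self, model_id: str) -> TrajectoryLMM:
        if model_id not in self._problems:
            spec = make_model_spec(model_id, nested=True).spec
            self._problems[model_id] = TrajectoryLMM(self.skeleton, spec)
        return self._problems[model_id]

    def wald_p(self, model_id: str, y: np.ndarray, method: str = "reml"):
        """Fit and return (p_value, converged, singular)."""
        model = self.model_for(model_id)
        model.problem.set_response(y)
        res = model.fit(method=method)
        term = list(res.params.index).index(_EFFECT_TERM)
        z = res.params.iloc[term] / res.bse.iloc[term]
        return 2.0 * float(stats.norm.sf(abs(z))), res.converged, res.singular


def _rep_seeds(seed: int | None, n_reps: int):
    return np.random.SeedSequence(seed).spawn(n_reps)


def _stable_key(*parts) -> int:
    """Process-independent 31-bit key for seed-stream splitting."""
    digest = hashlib.sha256(repr(parts).encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2 ** 31)


def _row_seeds(root: np.random.SeedSequence, key_parts, n_reps: int):
    entropy = root.entropy if root.entropy is not None else 0
    row_ss = np.random.SeedSequence(entropy=entropy,
                                    spawn_key=(_stable_key(*key_parts),))
    return row_ss.spawn(n_reps)


def _run_cell(engine: _CellEngine, model_id: str, rep_seeds, alpha: float,
              method: str = "reml", collect_hash: bool = False) -> dict:
    n_reject = 0
    n_converged = 0
    n_failed = 0
    hasher = hashlib.sha256() if collect_hash else None
    for child in rep_seeds:
        rng = np.random.default_rng(child)
        y = engine.simulate_y(rng)
        if hasher is not None:
            hasher.update(np.ascontiguousarray(y).tobytes())
        try:
            p, converged, _ = engine.wald_p(model_id, y, method)
        except Exception:  # noqa: BLE001 - count and exclude
            n_failed += 1
            continue
        if not converged:
            n_failed += 1
            continue
        n_converged += 1
        if p < alpha:
            n_reject += 1
    n_reps = len(rep_seeds)
    rate = n_reject / n_converged if n_converged else np.nan
    lo, hi = (mc_ci(rate, n_converged) if n_converged else (np.nan, np.nan))
    return {
        "scenario": engine.scenario.name,
        "model": model_id,
        "effect_fraction": engine.scenario.effect_fraction,
        "n_reps": n_reps,
        "n_converged": n_converged,
        "n_failed": n_failed,
        "n_reject": n_reject,
        "rate": rate,
        "ci_low": lo,
        "ci_high": hi,
        "alpha": alpha,
        "flagged": n_failed > 0.1 * n_reps,
        "data_hash": hasher.hexdigest() if hasher is not None else None,
    }


def _design_label(grid: DesignGrid) -> str:
    if grid.mice_per_donor == 1:
        n = sum(grid.donors_for(g) for g in grid.groups)
        return f"independent:{n}"
    donors = "+".join(str(grid.donors_for(g)) for g in grid.groups)
    return f"nested:{donors}x{grid.mice_per_donor}"


def rejection_rate(scenario: SimulationScenario, model_id: str,
                   grid: DesignGrid, n_reps: int, alpha: float = 0.05,
                   seed: int | None = None, effect_fraction: float | None = None,
                   method: str = "reml") -> dict:
    """One Monte-Carlo cell: simulate, fit, Wald-test, count rejections.

    Non-converged replicates are excluded from the denominator and counted;
    a cell with more than 10% failures is flagged.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must be in (0, 1]")
    if effect_fraction is not None:
        scenario = scenario.with_fraction(effect_fraction)
    engine = _CellEngine(scenario, grid)
    cell = _run_cell(engine, str(model_id).upper(), _rep_seeds(seed, n_reps),
                     alpha, method)
    cell["design"] = _design_label(grid)
    return cell


def type1_table(scenarios, model_ids, designs, n_reps: int,
                alpha: float = 0.05, seed: int | None = None,
                method: str = "reml",
                collect_hash: bool = False) -> RejectionRateTable:
    """Type I error grid: effect fraction forced to 0 in every scenario.

    ``designs`` maps labels to :class:`DesignGrid` objects. Within each
    (scenario, design) row the fitted models see identical simulated
    datasets (common random numbers).
    """
    root = np.random.SeedSequence(seed)
    rows = []
    for scenario in scenarios:
        scenario = scenario.with_fraction(0.0)
        for label, grid in dict(designs).items():
            rep_seeds = _row_seeds(root, (scenario.name, label), n_reps)
            engine = _CellEngine(scenario, grid)
            for mid in model_ids:
                cell = _run_cell(engine, str(mid).upper(), rep_seeds, alpha,
                                 method, collect_hash=collect_hash)
                cell["design"] = label
                rows.append(cell)
    return RejectionRateTable(pd.DataFrame(rows))


def power_curve(scenario: SimulationScenario, model_ids, grid: DesignGrid,
                effect_fractions, n_reps: int, alpha: float = 0.05,
                seed: int | None = None,
                method: str = "reml") -> RejectionRateTable:
    """Rejection rate across effect fractions, paired across fitted models.

    The fraction-0 column is the type I error cell for the same seed and
    design; common random numbers make the curve monotone up to pairing
    noise for a matched model.
    """
    fractions = [float(f) for f in effect_fractions]
    if sorted(fractions) != fractions:
        raise ValueError("effect_fractions must be sorted ascending")
    root = np.random.SeedSequence(seed)
    rows = []
    for frac in fractions:
        sc = scenario.with_fraction(frac)
        rep_seeds = _row_seeds(root, (sc.name, _design_label(grid)), n_reps)
        engine = _CellEngine(sc, grid)
        for mid in model_ids:
            cell = _run_cell(engine, str(mid).upper(), rep_seeds, alpha, method)
            cell["design"] = _design_label(grid)
            rows.append(cell)
    return RejectionRateTable(pd.DataFrame(rows))
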