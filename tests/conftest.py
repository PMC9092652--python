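"""Shared fixtures and the dense brute-force likelihood oracle.

The oracle assembles the full N x N marginal covariance entry by entry from
record metadata (subject/cluster identity, time products, AR lag) and
evaluates the Gaussian (restricted) density directly; it shares no code with
the engine's block-pattern path.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import nestlmm as nl
from nestlmm.model import unpack_theta


def dense_negloglik(ds, spec, theta, reml: bool) -> float:
    """Brute-force profiled negative (restricted) log-likelihood."""
    df = ds.df
    gs, sigma2, phi = unpack_theta(spec, theta)
    N = len(df)
    ref = sorted(df["group"].unique())[0]
    g = (df["group"] != ref).astype(float).to_numpy()
    t = df["time"].to_numpy(float)
    X = np.column_stack([np.ones(N), g, t, g * t])
    y = df["response"].to_numpy(float)
    subj = df["subject"].to_numpy()
    clus = df["cluster"].to_numpy() if "cluster" in df.columns else np.array([None] * N)
    order = np.zeros(N, int)
    for s in np.unique(subj):
        idx = np.where(subj == s)[0]
        idx = idx[np.argsort(t[idx])]
        order[idx] = np.arange(len(idx))
    gmap = {lv.level: (lv, G) for lv, G in zip(spec.levels, gs)}
    V = np.zeros((N, N))
    for i in range(N):
        for j in range(N):
            v = 0.0
            if "cluster" in gmap and clus[i] == clus[j]:
                lv, G = gmap["cluster"]
                zi = ([1.0] if lv.intercept else []) + ([t[i]] if lv.slope else [])
                zj = ([1.0] if lv.intercept else []) + ([t[j]] if lv.slope else [])
                v += float(np.array(zi) @ np.atleast_2d(G) @ np.array(zj))
            if subj[i] == subj[j]:
                if "subject" in gmap:
                    lv, G = gmap["subject"]
                    zi = ([1.0] if lv.intercept else []) + ([t[i]] if lv.slope else [])
                    zj = ([1.0] if lv.intercept else []) + ([t[j]] if lv.slope else [])
                    v += float(np.array(zi) @ np.atleast_2d(G) @ np.array(zj))
                if spec.has_ar1:
                    v += sigma2 * phi ** abs(int(order[i]) - int(order[j]))
                elif i == j:
                    v += sigma2
            V[i, j] = v
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
    r = y - X @ beta
    qf = float(r @ Vi @ r)
    sld = np.linalg.slogdet(V)[1]
    p = X.shape[1]
    if reml:
        return 0.5 * ((N - p) * np.log(2 * np.pi) + sld
                      + np.linalg.slogdet(XtViX)[1] + qf)
    return 0.5 * (N * np.log(2 * np.pi) + sld + qf)


@pytest.fixture(scope="session")
def demo_dataset():
    return nl.make_demo_dataset(seed=20220506)


@pytest.fixture(scope="session")
def small_nested_dataset():
    """2 groups x 2 donors x 2 mice x 4 uneven times, random response."""
    rng = np.random.default_rng(7)
    grid = nl.DesignGrid(groups=("a", "b"), donors_per_group=2,
                         mice_per_donor=2, timepoints=(0.0, 1.0, 2.5, 4.0))
    sk = nl.build_design(grid)
    return sk.with_response(rng.normal(size=sk.n_records))


@pytest.fixture(scope="session")
def intercept_only_dataset():
    """Matched-model benchmark data: 20 independent mice, full effect."""
    sc = nl.SimulationScenario("intercept_only", effect_fraction=1.0)
    return nl.simulate_dataset(sc, nl.make_independent_design(20), seed=42)


def random_small_instance(rng):
    """Random tiny design (<=3 clusters, <=3 subjects, <=4 times) + data."""
    n_donors = int(rng.integers(1, 3))
    n_mice = int(rng.integers(1, 3))
    n_times = int(rng.integers(2, 5))
    times = np.sort(rng.uniform(0, 5, size=n_times))
    times[0] = 0.0
    grid = nl.DesignGrid(groups=("a", "b"), donors_per_group=n_donors,
                         mice_per_donor=n_mice, timepoints=times)
    sk = nl.build_design(grid)
    return sk.with_response(rng.normal(size=sk.n_records))
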