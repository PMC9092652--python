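"""(RE)ML estimation for two-level nested linear mixed models.

The model for subject *i* (optionally nested in cluster *c*) is

    y_it = b0 + b1*group + b2*time + b3*group*time
           + [cluster intercept/slope] + [subject intercept/slope] + e_it

with Gaussian random effects, covariance ``G`` per level, and residuals that
are either independent or follow a first-order autoregression over successive
observations within a subject (corr(e_j, e_k) = phi**|j-k| in observation
order).  Estimation maximises the exact marginal (restricted) likelihood

    -2 l_ML   = N log 2pi + log|V| + (y - X bhat)' V^-1 (y - X bhat)
    -2 l_REML = -2 l_ML(with N-p) + log|X' V^-1 X|

with ``V = sum_levels Z G Z' + R`` evaluated cluster block by cluster block,
``bhat`` the GLS estimate profiled out.  Variance parameters are optimised on
an unconstrained scale (log-Cholesky factors for each G, log sigma^2, atanh
phi), which keeps every iterate valid.

Blocks that share an identical covariance pattern (same time grid and
subject partition) are factorised once per likelihood evaluation and their
quadratic forms accumulated with stacked linear algebra; balanced designs
therefore cost one small Cholesky per evaluation regardless of the number of
subjects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .data import LongitudinalDataset

__all__ = [
    "RandomEffectsLevel",
    "ResidualStructure",
    "ModelSpec",
    "TrajectoryLMM",
    "LMMResults",
    "StabilityReport",
    "design_matrices",
    "marginal_covariance",
    "neg_log_likelihood",
    "fit",
    "refit_all_optimizers",
    "predict_blup",
    "theta_names",
    "pack_theta",
    "unpack_theta",
    "embed_theta",
]

FIXED_TERMS = ("Intercept", "group", "time", "group:time")
_PENALTY = 1e10
_SING_VAR_FRAC = 1e-8  # variance below this fraction of sigma2 -> singular
_SING_CORR = 1.0 - 1e-6


class SpecError(ValueError):
    """Model specification inconsistent with the data or itself."""


# ---------------------------------------------------------------------------
# specification types


@dataclass(frozen=True)
class RandomEffectsLevel:
    """Random-effect terms at one grouping level.

    ``level`` is ``"cluster"`` (e.g. donor) or ``"subject"`` (e.g. mouse);
    the included terms are a random intercept and/or a random slope on time.
    Within a level the included terms are correlated (their joint covariance
    ``G`` is a free PSD matrix); levels are mutually independent.
    """

    level: str
    intercept: bool = True
    slope: bool = False

    def __post_init__(self) -> None:
        if self.level not in ("cluster", "subject"):
            raise SpecError(f"unknown level {self.level!r}")
        if not (self.intercept or self.slope):
            raise SpecError("a random-effects level needs intercept and/or slope")

    @property
    def dim(self) -> int:
        return int(self.intercept) + int(self.slope)

    @property
    def terms(self) -> tuple:
        out = []
        if self.intercept:
            out.append("intercept")
        if self.slope:
            out.append("slope")
        return tuple(out)

    def z_columns(self, t: np.ndarray) -> np.ndarray:
        cols = []
        if self.intercept:
            cols.append(np.ones_like(t))
        if self.slope:
            cols.append(t)
        return np.column_stack(cols)


@dataclass(frozen=True)
class ResidualStructure:
    """Within-subject residual family: independent or AR(1) in observation order."""

    family: str = "independent"

    def __post_init__(self) -> None:
        if self.family not in ("independent", "ar1"):
            raise SpecError(f"unknown residual family {self.family!r}")


@dataclass(frozen=True)
class ModelSpec:
    """Fixed-effect terms + random-effect levels + residual family.

    ``levels`` are ordered outer to inner (cluster before subject).
    """

    levels: tuple = ()
    residual: ResidualStructure = ResidualStructure()
    fixed_terms: tuple = FIXED_TERMS

    def __post_init__(self) -> None:
        object.__setattr__(self, "levels", tuple(self.levels))
        object.__setattr__(self, "fixed_terms", tuple(self.fixed_terms))
        names = [lv.level for lv in self.levels]
        if len(set(names)) != len(names):
            raise SpecError("duplicate random-effects level")
        if names not in ([], ["cluster"], ["subject"], ["cluster", "subject"]):
            raise SpecError("levels must be ordered outer (cluster) to inner (subject)")
        unknown = set(self.fixed_terms) - set(FIXED_TERMS)
        if unknown:
            raise SpecError(f"unknown fixed terms {sorted(unknown)}")

    @property
    def has_ar1(self) -> bool:
        return self.residual.family == "ar1"

    def level(self, name: str) -> RandomEffectsLevel | None:
        for lv in self.levels:
            if lv.level == name:
                return lv
        return None

    @property
    def n_theta(self) -> int:
        n = sum(lv.dim * (lv.dim + 1) // 2 for lv in self.levels)
        return n + 1 + (1 if self.has_ar1 else 0)

    def describe(self) -> str:
        parts = []
        for lv in self.levels:
            parts.append(f"{lv.level}({'+'.join(lv.terms)})")
        parts.append(self.residual.family)
        return " + ".join(parts)


# ---------------------------------------------------------------------------
# parameter transforms (log-Cholesky / log / atanh)


def theta_names(spec: ModelSpec) -> list:
    names = []
    for lv in spec.levels:
        terms = lv.terms
        for j in range(lv.dim):
            for k in range(j + 1):
                if j == k:
                    names.append(f"{lv.level}:log_chol[{terms[j]}]")
                else:
                    names.append(f"{lv.level}:chol[{terms[j]},{terms[k]}]")
    names.append("log_sigma2")
    if spec.has_ar1:
        names.append("atanh_phi")
    return names


def unpack_theta(spec: ModelSpec, theta: np.ndarray):
    """Map the unconstrained vector to (list of G, sigma2, phi)."""
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (spec.n_theta,):
        raise ValueError(f"theta must have length {spec.n_theta}")
    pos = 0
    gs = []
    for lv in spec.levels:
        d = lv.dim
        L = np.zeros((d, d))
        for j in range(d):
            for k in range(j + 1):
                v = theta[pos]
                pos += 1
                L[j, k] = np.exp(v) if j == k else v
        gs.append(L @ L.T)
    sigma2 = float(np.exp(theta[pos]))
    pos += 1
    phi = float(np.tanh(theta[pos])) if spec.has_ar1 else None
    return gs, sigma2, phi


def pack_theta(spec: ModelSpec, gs, sigma2: float, phi: float | None = None,
               floor: float = 1e-12) -> np.ndarray:
    """Inverse of :func:`unpack_theta`; PSD matrices get a tiny jitter."""
    out = []
    gs = list(gs)
    if len(gs) != len(spec.levels):
        raise ValueError("one G per level required")
    for lv, g in zip(spec.levels, gs):
        g = np.atleast_2d(np.asarray(g, dtype=float))
        if g.shape != (lv.dim, lv.dim):
            raise ValueError(f"G for level {lv.level} must be {lv.dim}x{lv.dim}")
        L = linalg.cholesky(g + floor * np.eye(lv.dim), lower=True)
        for j in range(lv.dim):
            for k in range(j + 1):
                out.append(np.log(max(L[j, j], floor)) if j == k else L[j, k])
    out.append(np.log(max(sigma2, floor)))
    if spec.has_ar1:
        phi = 0.0 if phi is None else float(np.clip(phi, -0.999999, 0.999999))
        out.append(np.arctanh(phi))
    return np.array(out)


def embed_theta(spec_from: ModelSpec, theta_from: np.ndarray,
                spec_to: ModelSpec) -> np.ndarray:
    """Embed a nested model's solution into a larger model's parameter space.

    New variance terms start at a negligible floor so the starting likelihood
    essentially equals the nested optimum; used for warm starts along the
    model ladder.
    """
    gs_from, sigma2, phi = unpack_theta(spec_from, theta_from)
    from_by_name = {lv.level: (lv, g) for lv, g in zip(spec_from.levels, gs_from)}
    gs_to = []
    for lv in spec_to.levels:
        g = np.zeros((lv.dim, lv.dim))
        # tiny floor, scaled down for slopes (time can be O(30) days)
        for j, term in enumerate(lv.terms):
            g[j, j] = 1e-10 if term == "intercept" else 1e-12
        if lv.level in from_by_name:
            lv_f, g_f = from_by_name[lv.level]
            for j, tj in enumerate(lv.terms):
                for k, tk in enumerate(lv.terms):
                    if tj in lv_f.terms and tk in lv_f.terms:
                        jf = lv_f.terms.index(tj)
                        kf = lv_f.terms.index(tk)
                        g[j, k] = g_f[jf, kf]
            for j in range(lv.dim):
                g[j, j] = max(g[j, j], 1e-12)
        gs_to.append(g)
    if spec_to.has_ar1:
        phi = phi if (spec_from.has_ar1 and phi is not None) else 0.0
    return pack_theta(spec_to, gs_to, sigma2, phi)


# ---------------------------------------------------------------------------
# design construction


@dataclass
class _Pattern:
    """Blocks sharing one covariance pattern, stacked for vectorised GLS."""

    times: np.ndarray                # concatenated within-block times, length n
    subj_slices: list                # per-subject slices into the block
    z_cluster: np.ndarray | None     # n x d_c or None
    z_subject: list | None           # per-subject (slice, ns x d_s) or None
    lag: list                        # per-subject integer lag matrices
    X: np.ndarray = None             # m x n x p
    X2d: np.ndarray = None           # (m*n) x p view of X
    y: np.ndarray = None             # m x n
    rows: np.ndarray = None          # m x n row indices into problem order
    block_ids: list = field(default_factory=list)
    subj_labels: list = field(default_factory=list)  # per-subject labels, per block


def _fixed_design(df: pd.DataFrame, group_ind: np.ndarray,
                  fixed_terms) -> np.ndarray:
    t = df["time"].to_numpy(dtype=float)
    cols = {
        "Intercept": np.ones_like(t),
        "group": group_ind,
        "time": t,
        "group:time": group_ind * t,
    }
    return np.column_stack([cols[name] for name in fixed_terms])


class LMMProblem:
    """Pre-processed design: sorted rows, blocks, stacked patterns.

    Rows are sorted by (cluster, subject, time); ``row_order`` maps problem
    rows back to the dataset's row positions.
    """

    def __init__(self, ds: LongitudinalDataset, spec: ModelSpec):
        self.spec = spec
        df = ds.df
        if spec.level("cluster") is not None and not ds.has_cluster:
            raise SpecError("spec has cluster-level random effects but the "
                            "dataset has no cluster column")
        sort_cols = (["cluster", "subject", "time"]
                     if ds.has_cluster else ["subject", "time"])
        order = df.sort_values(sort_cols, kind="mergesort").index.to_numpy()
        self.row_order = order
        sdf = df.loc[order].reset_index(drop=True)
        self.df = sdf
        self.group_levels = ds.group_levels
        if "group" in spec.fixed_terms and len(self.group_levels) < 2:
            raise SpecError("fixed-effect design is rank deficient: "
                            "a single group level cannot identify the group terms")
        ref = self.group_levels[0]
        gind = (sdf["group"].to_numpy() != ref).astype(float)
        self.X_all = _fixed_design(sdf, gind, spec.fixed_terms)
        self.y_all = sdf["response"].to_numpy(dtype=float)
        self.N, self.p = self.X_all.shape
        if np.linalg.matrix_rank(self.X_all) < self.p:
            raise SpecError("fixed-effect design matrix is rank deficient")

        # blocks: by cluster when cluster-level effects exist, else by subject
        block_col = "cluster" if spec.level("cluster") is not None else "subject"
        self.block_col = block_col
        codes, _ = pd.factorize(sdf[block_col])
        self.patterns: dict = {}
        t_all = sdf["time"].to_numpy(dtype=float)
        subj_codes, _ = pd.factorize(sdf["subject"])
        start = 0
        buckets: dict = {}
        for b in range(codes.max() + 1):
            idx = np.flatnonzero(codes == b)
            times = t_all[idx]
            subjects = subj_codes[idx]
            # subject partition within the block (contiguous by sort)
            bounds = [0] + list(np.flatnonzero(np.diff(subjects)) + 1) + [len(idx)]
            sizes = tuple(bounds[i + 1] - bounds[i] for i in range(len(bounds) - 1))
            key = (tuple(np.round(times, 12)), sizes)
            buckets.setdefault(key, []).append((idx, bounds))
        for key, blocks in buckets.items():
            idx0, bounds0 = blocks[0]
            times = t_all[idx0]
            n = len(idx0)
            subj_slices = [slice(bounds0[i], bounds0[i + 1])
                           for i in range(len(bounds0) - 1)]
            lv_c = spec.level("cluster")
            z_cluster = lv_c.z_columns(times) if lv_c is not None else None
            lv_s = spec.level("subject")
            z_subject = None
            if lv_s is not None:
                z_subject = [(s, lv_s.z_columns(times[s])) for s in subj_slices]
            lag = [np.abs(np.subtract.outer(np.arange(s.stop - s.start),
                                            np.arange(s.stop - s.start)))
                   for s in subj_slices]
            pat = _Pattern(times=times, subj_slices=subj_slices,
                           z_cluster=z_cluster, z_subject=z_subject, lag=lag)
            m = len(blocks)
            pat.X = np.empty((m, n, self.p))
            pat.y = np.empty((m, n))
            pat.rows = np.empty((m, n), dtype=int)
            for i, (idx, _) in enumerate(blocks):
                pat.X[i] = self.X_all[idx]
                pat.y[i] = self.y_all[idx]
                pat.rows[i] = idx
                pat.block_ids.append(sdf[block_col].iloc[idx[0]])
                pat.subj_labels.append(
                    [sdf["subject"].iloc[idx[s.start]] for s in subj_slices])
            pat.X2d = pat.X.reshape(m * n, self.p)
            self.patterns[key] = pat

    # -- response swapping (Monte-Carlo fast path) -----------------------
    def set_response(self, y_dataset_order: np.ndarray) -> None:
        """Replace the response; ``y`` is in the original dataset row order."""
        y = np.asarray(y_dataset_order, dtype=float)[self.row_order]
        self.y_all = y
        for pat in self.patterns.values():
            pat.y = y[pat.rows]

    # -- covariance assembly --------------------------------------------
    def build_v(self, pat: _Pattern, gs, sigma2: float, phi) -> np.ndarray:
        n = len(pat.times)
        V = np.zeros((n, n))
        spec = self.spec
        gc = gsub = None
        for lv, g in zip(spec.levels, gs):
            if lv.level == "cluster":
                gc = g
            else:
                gsub = g
        if spec.has_ar1:
            for s, lag in zip(pat.subj_slices, pat.lag):
                V[s, s] = sigma2 * phi ** lag
        else:
            V[np.diag_indices(n)] += sigma2
        if gsub is not None:
            for s, z in pat.z_subject:
                V[s, s] += z @ gsub @ z.T
        if gc is not None:
            V += pat.z_cluster @ gc @ pat.z_cluster.T
        return V

    # -- likelihood ------------------------------------------------------
    def _accumulate(self, theta: np.ndarray):
        """GLS sufficient statistics (XtViX, XtViy, yViy, logdetV) or None."""
        gs, sigma2, phi = unpack_theta(self.spec, theta)
        XtViX = np.zeros((self.p, self.p))
        XtViy = np.zeros(self.p)
        yViy = 0.0
        logdetV = 0.0
        for pat in self.patterns.values():
            V = self.build_v(pat, gs, sigma2, phi)
            try:
                cho = linalg.cho_factor(V, lower=True, check_finite=False)
            except linalg.LinAlgError:
                return None
            m, n, _ = pat.X.shape
            logdetV += 2.0 * m * np.log(np.diag(cho[0])).sum()
            # V is small (one block): invert once, then batched GEMMs
            W = linalg.cho_solve(cho, np.eye(n), check_finite=False)
            WX = np.matmul(W, pat.X)            # m x n x p, batched
            Wy = pat.y @ W                      # m x n (W symmetric)
            XtViX += pat.X2d.T @ WX.reshape(m * n, self.p)
            XtViy += pat.X2d.T @ Wy.reshape(m * n)
            yViy += float((pat.y * Wy).sum())
        return XtViX, XtViy, yViy, logdetV

    def gls(self, theta: np.ndarray):
        """Profiled GLS at theta.

        Returns (beta_hat, cov_beta=(X'V^-1X)^-1, logdetV, logdetXtViX, qf)
        or None if V is not positive definite.
        """
        acc = self._accumulate(theta)
        if acc is None:
            return None
        XtViX, XtViy, yViy, logdetV = acc
        try:
            cf = linalg.cho_factor(XtViX, lower=True, check_finite=False)
        except linalg.LinAlgError:
            return None
        beta = linalg.cho_solve(cf, XtViy, check_finite=False)
        logdetXtViX = 2.0 * np.log(np.diag(cf[0])).sum()
        qf = yViy - float(beta @ XtViy)
        cov_beta = linalg.cho_solve(cf, np.eye(self.p), check_finite=False)
        return beta, cov_beta, logdetV, logdetXtViX, qf

    def nll(self, theta: np.ndarray, reml: bool) -> float:
        with np.errstate(over="ignore", invalid="ignore"):
            acc = self._accumulate(theta)
            if acc is None:
                return _PENALTY * (1.0 + float(np.sum(np.square(theta))))
            XtViX, XtViy, yViy, logdetV = acc
            try:
                cf = linalg.cho_factor(XtViX, lower=True, check_finite=False)
            except linalg.LinAlgError:
                return _PENALTY * (1.0 + float(np.sum(np.square(theta))))
            beta = linalg.cho_solve(cf, XtViy, check_finite=False)
            logdetXtViX = 2.0 * np.log(np.diag(cf[0])).sum()
            qf = yViy - float(beta @ XtViy)
        if not np.isfinite(qf):
            return _PENALTY * (1.0 + float(np.sum(np.square(theta))))
        N, p = self.N, self.p
        log2pi = np.log(2.0 * np.pi)
        if reml:
            val = 0.5 * ((N - p) * log2pi + logdetV + logdetXtViX + qf)
        else:
            val = 0.5 * (N * log2pi + logdetV + qf)
        if not np.isfinite(val):
            return _PENALTY * (1.0 + float(np.sum(np.square(theta))))
        return float(val)


# ---------------------------------------------------------------------------
# public functional surface


def design_matrices(ds: LongitudinalDataset, spec: ModelSpec) -> dict:
    """Per-block design matrices {block_id: {X, y, Z_cluster, Z_subject, times}}."""
    prob = LMMProblem(ds, spec)
    out = {}
    for pat in prob.patterns.values():
        for i, bid in enumerate(pat.block_ids):
            entry = {
                "X": pat.X[i],
                "y": pat.y[i],
                "times": pat.times,
                "Z_cluster": pat.z_cluster,
                "Z_subject": ([z for _, z in pat.z_subject]
                              if pat.z_subject is not None else None),
                "subjects": pat.subj_labels[i],
            }
            out[bid] = entry
    return out


def marginal_covariance(spec: ModelSpec, params: dict,
                        times: np.ndarray,
                        subject_sizes=None) -> np.ndarray:
    """Marginal covariance V = sum Z G Z' + R for one block.

    ``params`` carries ``g_cluster``/``g_subject`` (matching the spec's
    levels), ``sigma2`` and, for AR(1), ``phi``. ``times`` concatenates the
    within-subject time vectors; ``subject_sizes`` partitions them (default:
    a single subject).
    """
    times = np.asarray(times, dtype=float)
    n = len(times)
    if subject_sizes is None:
        subject_sizes = [n]
    if sum(subject_sizes) != n:
        raise ValueError("subject_sizes must partition times")
    for key in ("g_cluster", "g_subject"):
        g = params.get(key)
        if g is not None:
            g = np.atleast_2d(np.asarray(g, dtype=float))
            ev = np.linalg.eigvalsh(g)
            if ev.min() < -1e-10:
                raise ValueError(f"{key} must be positive semi-definite")
    V = np.zeros((n, n))
    sigma2 = float(params["sigma2"])
    bounds = np.concatenate([[0], np.cumsum(subject_sizes)])
    slices = [slice(bounds[i], bounds[i + 1]) for i in range(len(subject_sizes))]
    if spec.has_ar1:
        phi = float(params["phi"])
        for s in slices:
            k = s.stop - s.start
            lag = np.abs(np.subtract.outer(np.arange(k), np.arange(k)))
            V[s, s] = sigma2 * phi ** lag
    else:
        V[np.diag_indices(n)] += sigma2
    lv_s = spec.level("subject")
    if lv_s is not None:
        g = np.atleast_2d(np.asarray(params["g_subject"], dtype=float))
        for s in slices:
            z = lv_s.z_columns(times[s])
            V[s, s] += z @ g @ z.T
    lv_c = spec.level("cluster")
    if lv_c is not None:
        g = np.atleast_2d(np.asarray(params["g_cluster"], dtype=float))
        z = lv_c.z_columns(times)
        V += z @ g @ z.T
    return V


def neg_log_likelihood(spec: ModelSpec, theta: np.ndarray,
                       ds: LongitudinalDataset, reml: bool = True) -> float:
    """Profiled negative (restricted) log-likelihood at unconstrained theta."""
    return LMMProblem(ds, spec).nll(np.asarray(theta, dtype=float), reml)


# ---------------------------------------------------------------------------
# results


@dataclass
class VarianceComponents:
    g: dict            # level name -> G matrix (DataFrame)
    sigma2: float
    phi: float | None = None

    def to_dict(self) -> dict:
        out = {lvl: g.values.tolist() for lvl, g in self.g.items()}
        out["sigma2"] = self.sigma2
        if self.phi is not None:
            out["phi"] = self.phi
        return out


class LMMResults:
    """Fitted mixed-model results: estimates, uncertainties, diagnostics."""

    def __init__(self, model: "TrajectoryLMM", theta, beta, cov_beta,
                 llf, method, converged, optimizer, n_iter, message=""):
        self.model = model
        self.spec = model.spec
        self.theta = np.asarray(theta, dtype=float)
        self.params = pd.Series(beta, index=list(model.spec.fixed_terms))
        self.cov_params = pd.DataFrame(cov_beta,
                                       index=self.params.index,
                                       columns=self.params.index)
        self.bse = pd.Series(np.sqrt(np.diag(cov_beta)), index=self.params.index)
        self.llf = float(llf)
        self.method = method
        self.converged = bool(converged)
        self.optimizer = optimizer
        self.n_iter = n_iter
        self.message = message
        self.n_obs = model.problem.N
        self.n_params = model.problem.p + model.spec.n_theta
        gs, sigma2, phi = unpack_theta(model.spec, self.theta)
        gd = {}
        for lv, g in zip(model.spec.levels, gs):
            gd[lv.level] = pd.DataFrame(g, index=lv.terms, columns=lv.terms)
        self.vc = VarianceComponents(g=gd, sigma2=sigma2, phi=phi)
        self.singular = self._check_singular()
        self._ranef = None
        self._fitted = None

    # -- diagnostics -----------------------------------------------------
    def _check_singular(self) -> bool:
        s2 = self.vc.sigma2
        for g in self.vc.g.values():
            v = np.diag(g.values)
            if (v < _SING_VAR_FRAC * s2).any():
                return True
            if g.shape[0] == 2 and v.min() > 0:
                corr = g.values[0, 1] / np.sqrt(v[0] * v[1])
                if abs(corr) > _SING_CORR:
                    return True
        if self.vc.phi is not None and abs(self.vc.phi) > _SING_CORR:
            return True
        return False

    @property
    def df_resid(self) -> int:
        return self.n_obs - self.model.problem.p

    # -- inference helpers (thin wrappers over nestlmm.inference) --------
    def wald_test(self, term: str = "group:time"):
        from .inference import wald_test
        return wald_test(self, term)

    def conf_int(self, level: float = 0.95) -> pd.DataFrame:
        from .inference import fixed_effect_ci
        return fixed_effect_ci(self, level)

    # -- random effects / fitted values ----------------------------------
    def _compute_ranef(self):
        prob = self.model.problem
        gs, sigma2, phi = unpack_theta(self.spec, self.theta)
        gc = gsub = None
        for lv, g in zip(self.spec.levels, gs):
            if lv.level == "cluster":
                gc = g
            else:
                gsub = g
        beta = self.params.to_numpy()
        ranef = {"cluster": {}, "subject": {}}
        fitted = np.empty(prob.N)
        for pat in prob.patterns.values():
            V = prob.build_v(pat, gs, sigma2, phi)
            cho = linalg.cho_factor(V, lower=True, check_finite=False)
            for i in range(pat.X.shape[0]):
                r = pat.y[i] - pat.X[i] @ beta
                Vir = linalg.cho_solve(cho, r, check_finite=False)
                contrib = pat.X[i] @ beta
                if gc is not None:
                    gamma_c = gc @ pat.z_cluster.T @ Vir
                    ranef["cluster"][pat.block_ids[i]] = gamma_c
                    contrib = contrib + pat.z_cluster @ gamma_c
                if gsub is not None:
                    for (s, z), label in zip(pat.z_subject, pat.subj_labels[i]):
                        gamma_s = gsub @ z.T @ Vir[s]
                        ranef["subject"][label] = gamma_s
                        contrib[s] = contrib[s] + z @ gamma_s
                fitted[pat.rows[i]] = contrib
        self._ranef = ranef
        # problem row i corresponds to dataset row row_order[i]
        out = np.empty(prob.N)
        out[prob.row_order] = fitted
        self._fitted = out

    @property
    def random_effects(self) -> dict:
        """Empirical BLUPs gamma_hat = G Z' V^-1 (y - X beta_hat) per unit."""
        if self._ranef is None:
            self._compute_ranef()
        return self._ranef

    @property
    def fittedvalues(self) -> np.ndarray:
        """Conditional fitted trajectories X beta + Z gamma, dataset row order."""
        if self._fitted is None:
            self._compute_ranef()
        return self._fitted

    @property
    def resid(self) -> np.ndarray:
        """Conditional residuals y - fitted, dataset row order."""
        y = self.model.dataset.df["response"].to_numpy(dtype=float)
        return y - self.fittedvalues

    def simulate(self, rng: np.random.Generator) -> np.ndarray:
        """Draw a response vector from the fitted model (dataset row order)."""
        prob = self.model.problem
        gs, sigma2, phi = unpack_theta(self.spec, self.theta)
        beta = self.params.to_numpy()
        y_prob = np.empty(prob.N)
        for pat in prob.patterns.values():
            V = prob.build_v(pat, gs, sigma2, phi)
            L = linalg.cholesky(V, lower=True, check_finite=False)
            m, n, _ = pat.X.shape
            z = rng.standard_normal((m, n))
            y_prob[pat.rows.ravel()] = (pat.X @ beta + z @ L.T).ravel()
        # pat.rows index problem order; map problem order -> dataset order
        y = np.empty(prob.N)
        y[prob.row_order] = y_prob
        return y

    def summary(self) -> str:
        spec = self.spec
        lines = []
        lines.append("Nested longitudinal linear mixed model")
        lines.append("=" * 54)
        lines.append(f"Structure:    {spec.describe()}")
        lines.append(f"Method:       {self.method.upper()}   "
                     f"log-likelihood: {self.llf:.4f}")
        lines.append(f"Observations: {self.n_obs}   parameters: {self.n_params}")
        flags = []
        if not self.converged:
            flags.append("NOT CONVERGED")
        if self.singular:
            flags.append("singular fit (variance component near boundary)")
        if flags:
            lines.append("Flags:        " + "; ".join(flags))
        lines.append("-" * 54)
        lines.append(f"{'term':<14}{'estimate':>12}{'std err':>12}{'z':>9}")
        from scipy.stats import norm
        for term in self.params.index:
            b = self.params[term]
            se = self.bse[term]
            lines.append(f"{term:<14}{b:>12.4f}{se:>12.4f}{b / se:>9.2f}")
        lines.append("-" * 54)
        lines.append("Variance components")
        for lvl, g in self.vc.g.items():
            for j, tj in enumerate(g.index):
                lines.append(f"  {lvl} {tj:<10} var = {g.values[j, j]:.5g}")
            if g.shape[0] == 2:
                lines.append(f"  {lvl} cov(int,slope) = {g.values[0, 1]:.5g}")
        lines.append(f"  residual sigma^2  = {self.vc.sigma2:.5g}")
        if self.vc.phi is not None:
            lines.append(f"  AR(1) phi         = {self.vc.phi:.5g}")
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"<LMMResults {self.spec.describe()} {self.method} "
                f"llf={self.llf:.3f} converged={self.converged}>")


# ---------------------------------------------------------------------------
# the model class


_OPTIMIZERS = {
    "lbfgsb": "L-BFGS-B",
    "nelder-mead": "Nelder-Mead",
    "powell": "Powell",
    "tnc": "TNC",
}


class TrajectoryLMM:
    """Two-group growth-trajectory mixed model for a longitudinal dataset.

    Parameters
    ----------
    dataset : LongitudinalDataset or pandas.DataFrame
        Long-format data with canonical columns.
    spec : ModelSpec
        Random-effects levels and residual family. Fixed effects are the
        intercept, group, time and group x time terms.
    """

    def __init__(self, dataset, spec: ModelSpec):
        if isinstance(dataset, pd.DataFrame):
            dataset = LongitudinalDataset(dataset)
        self.dataset = dataset
        self.spec = spec
        self.problem = LMMProblem(dataset, spec)
        if self.problem.N < self.problem.p + spec.n_theta:
            raise SpecError("fewer observations than parameters")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, spec: ModelSpec,
                       column_map=None) -> "TrajectoryLMM":
        if column_map:
            df = df.rename(columns={v: k for k, v in column_map.items()})
        return cls(LongitudinalDataset(df), spec)

    @classmethod
    def from_model_id(cls, dataset, model_id: str) -> "TrajectoryLMM":
        from .suite import make_model_spec
        return cls(dataset, make_model_spec(model_id).spec)

    # -- starting values --------------------------------------------------
    def _default_start(self) -> np.ndarray:
        prob = self.problem
        beta_ols, _, _, _ = np.linalg.lstsq(prob.X_all, prob.y_all, rcond=None)
        resid = prob.y_all - prob.X_all @ beta_ols
        s2 = float(resid @ resid) / max(prob.N - prob.p, 1)
        s2 = max(s2, 1e-8)
        t = self.dataset.df["time"].to_numpy(dtype=float)
        t2 = max(float(np.mean(t * t)), 1e-8)
        n_re = sum(lv.dim for lv in self.spec.levels)
        share = 0.5 / max(n_re, 1)
        gs = []
        for lv in self.spec.levels:
            g = np.zeros((lv.dim, lv.dim))
            for j, term in enumerate(lv.terms):
                g[j, j] = share * s2 if term == "intercept" else share * s2 / t2
            gs.append(g)
        sigma2_0 = s2 * (0.5 if n_re else 1.0)
        return pack_theta(self.spec, gs, sigma2_0,
                          0.0 if self.spec.has_ar1 else None)

    def _bounds(self):
        bounds = []
        for name in theta_names(self.spec):
            if name.startswith("log") or ":log_chol" in name:
                # variance range [exp(-30), exp(30)]; the floor is far below
                # the singular-fit threshold, so boundary walks stop early
                bounds.append((-15.0, 15.0))
            elif name == "atanh_phi":
                bounds.append((-8.0, 8.0))
            else:  # off-diagonal Cholesky entry
                bounds.append((-1e4, 1e4))
        return bounds

    # -- fitting -----------------------------------------------------------
    def fit(self, method: str = "reml", optimizer: str = "lbfgsb",
            start=None, max_iter: int = 500, tol: float = 1e-10) -> LMMResults:
        """Maximise the (restricted) likelihood and return results.

        ``method`` is ``"reml"`` (default; matches how the coefficients are
        reported) or ``"ml"`` (required for likelihood-ratio tests).
        """
        method = method.lower()
        if method not in ("reml", "ml"):
            raise ValueError("method must be 'reml' or 'ml'")
        reml = method == "reml"
        prob = self.problem

        # ordinary linear model: closed form
        if not self.spec.levels and not self.spec.has_ar1:
            return self._fit_ols(reml)

        theta0 = np.asarray(start, dtype=float) if start is not None \
            else self._default_start()
        fun = lambda th: prob.nll(th, reml)
        opt_name = _OPTIMIZERS.get(optimizer.lower().replace("_", "-"))
        if opt_name is None:
            raise ValueError(f"unknown optimizer {optimizer!r}; "
                             f"choose from {sorted(_OPTIMIZERS)}")
        if opt_name in ("L-BFGS-B", "TNC"):
            res = optimize.minimize(
                fun, theta0, method=opt_name, bounds=self._bounds(),
                options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-7}
                if opt_name == "L-BFGS-B" else {"maxiter": max_iter},
            )
        elif opt_name == "Powell":
            res = optimize.minimize(
                fun, theta0, method="Powell", bounds=self._bounds(),
                options={"maxiter": max_iter, "xtol": 1e-8, "ftol": tol})
        else:
            res = optimize.minimize(
                fun, theta0, method="Nelder-Mead",
                options={"maxiter": max_iter * max(len(theta0), 1),
                         "xatol": 1e-8, "fatol": tol})
        converged = bool(res.success)
        if not converged and opt_name == "L-BFGS-B":
            # derivative-free fallback from the best point found
            res2 = optimize.minimize(
                fun, res.x, method="Nelder-Mead",
                options={"maxiter": 400 * len(theta0),
                         "xatol": 1e-8, "fatol": tol})
            if res2.fun <= res.fun:
                res = res2
                converged = bool(res2.success)
        theta, best = self._polish_boundary(np.asarray(res.x, dtype=float),
                                            float(res.fun), fun)
        out = prob.gls(theta)
        if out is None:
            raise RuntimeError("optimizer returned an invalid parameter point")
        beta, cov_unscaled, *_ = out
        return LMMResults(self, theta, beta, cov_unscaled, -best, method,
                          converged, optimizer, getattr(res, "nit", None),
                          message=str(getattr(res, "message", "")))

    def _polish_boundary(self, theta: np.ndarray, f0: float, fun):
        """Snap near-zero variance components onto the boundary.

        The log-scale parameterization approaches zero variances only
        asymptotically, so the optimizer plateaus at small positive values.
        For each variance below 1e-3 * sigma2 the corresponding G row/column
        is floored and the trial kept when the objective does not worsen;
        this makes boundary (singular) solutions detectable.
        """
        for _ in range(3):
            gs, sigma2, phi = unpack_theta(self.spec, theta)
            accepted = False
            for li, lv in enumerate(self.spec.levels):
                for j in range(lv.dim):
                    var = gs[li][j, j]
                    if not 1e-11 < var < 1e-3 * sigma2:
                        continue
                    gs_trial = [g.copy() for g in gs]
                    gs_trial[li][j, :] = 0.0
                    gs_trial[li][:, j] = 0.0
                    trial = pack_theta(self.spec, gs_trial, sigma2, phi)
                    f1 = fun(trial)
                    if f1 <= f0 + 1e-8:
                        theta, f0 = trial, min(f0, f1)
                        accepted = True
            if not accepted:
                break
        return theta, f0

    def _fit_ols(self, reml: bool) -> LMMResults:
        prob = self.problem
        X, y, N, p = prob.X_all, prob.y_all, prob.N, prob.p
        XtX = X.T @ X
        cf = linalg.cho_factor(XtX, lower=True)
        beta = linalg.cho_solve(cf, X.T @ y)
        r = y - X @ beta
        rss = float(r @ r)
        dof = N - p if reml else N
        sigma2 = rss / dof
        theta = np.array([np.log(max(sigma2, 1e-300))])
        llf = -prob.nll(theta, reml)
        cov = sigma2 * linalg.cho_solve(cf, np.eye(p))
        method = "reml" if reml else "ml"
        return LMMResults(self, theta, beta, cov, llf, method,
                          True, "closed-form", 0)


# module-level convenience mirroring the functional surface ------------------


def fit(spec: ModelSpec, ds: LongitudinalDataset, optimizer: str = "lbfgsb",
        method: str = "reml", max_iter: int = 500, tol: float = 1e-10,
        start=None) -> LMMResults:
    """Fit ``spec`` to ``ds``; see :meth:`TrajectoryLMM.fit`."""
    return TrajectoryLMM(ds, spec).fit(method=method, optimizer=optimizer,
                                       start=start, max_iter=max_iter, tol=tol)


@dataclass
class StabilityReport:
    fits: dict              # optimizer name -> LMMResults
    max_rel_discrepancy: float | None
    stable: bool | None
    n_converged: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, f in self.fits.items():
            row = {"optimizer": name, "converged": f.converged,
                   "singular": f.singular, "llf": f.llf}
            for term in f.params.index:
                row[term] = f.params[term]
            rows.append(row)
        return pd.DataFrame(rows)


def refit_all_optimizers(spec: ModelSpec, ds: LongitudinalDataset,
                         optimizers=("lbfgsb", "powell", "nelder-mead"),
                         method: str = "reml") -> StabilityReport:
    """Refit with several optimizers and compare the fixed-effect estimates.

    The fit is called stable when the maximum relative discrepancy among the
    converged optimizers' fixed effects is below 1e-4.
    """
    if len(optimizers) < 2:
        raise ValueError("need at least two optimizers")
    model = TrajectoryLMM(ds, spec)
    fits = {}
    for name in optimizers:
        if name in fits:
            continue
        try:
            fits[name] = model.fit(method=method, optimizer=name)
        except Exception as exc:  # noqa: BLE001 - record failure, keep going
            warnings.warn(f"optimizer {name} failed: {exc}")
    conv = [f for f in fits.values() if f.converged]
    if not conv:
        return StabilityReport(fits, None, None, 0)
    betas = np.array([f.params.to_numpy() for f in conv])
    scale = np.maximum(np.abs(betas).max(axis=0), 1e-8)
    disc = float(((betas.max(axis=0) - betas.min(axis=0)) / scale).max())
    return StabilityReport(fits, disc, disc < 1e-4, len(conv))


def predict_blup(fit_result: LMMResults, ds: LongitudinalDataset | None = None):
    """Per-unit random-effect predictions and fitted trajectories.

    Returns (random_effects dict, tidy DataFrame with fitted values and
    conditional residuals in dataset row order).
    """
    if not fit_result.converged:
        raise RuntimeError("cannot predict from a non-converged fit")
    df = fit_result.model.dataset.df.copy()
    df["fitted"] = fit_result.fittedvalues
    df["resid"] = fit_result.resid
    beta = fit_result.params.to_numpy()
    X_dataset_order = np.empty_like(fit_result.model.problem.X_all)
    X_dataset_order[fit_result.model.problem.row_order] = \
        fit_result.model.problem.X_all
    df["population"] = X_dataset_order @ beta
    return fit_result.random_effects, df
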