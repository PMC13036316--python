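"""Joint species co-occurrence model: Gaussian phylogenetic/spatial mixed model.

All species x unit presences enter one Gaussian (linear-probability)
likelihood with fixed effects

    intercept + trait + 3 environment covariates + 3 trait x environment
    interactions  (the null model drops the trait and interactions)

and four random effects: species i.i.d. (sigma_a2 I), species phylogenetic
(sigma_b2 Sigma_spp), unit i.i.d. (sigma_c2 I), and unit spatial
(sigma_d2 Sigma_m, exponential kernel on centroid distances), plus residual
sigma_e2.  The marginal covariance over the n = S*M observations is

    V = sigma_a2 (I_S (x) J_M) + sigma_b2 (Sigma_spp (x) J_M)
      + sigma_c2 (J_S (x) I_M) + sigma_d2 (J_S (x) Sigma_m) + sigma_e2 I,

which is a low-rank (S + M) update of a diagonal, so likelihood, GLS fixed
effects, BLUPs, leave-one-out CPO and held-out predictions are all computed
through the Woodbury identity at O(n (S+M) + (S+M)^3) cost per evaluation.
Variance components are estimated by maximum likelihood (the Bayesian
posterior mean of the original formulation is essentially the ML point for
a Gaussian model with vague priors); fixed effects are profiled by GLS.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve
from scipy.spatial.distance import pdist, squareform
from scipy.stats import norm

from .occurrences import PlanningGrid
from .traits import TraitTable

_LOG2PI = np.log(2 * np.pi)


def spatial_covariance(grid_or_centroids) -> np.ndarray:
    """Spatial covariance Sigma_m[i,j] = exp(-d_ij / d_max), unit diagonal."""
    if isinstance(grid_or_centroids, PlanningGrid):
        cents = grid_or_centroids.centroids
    else:
        cents = np.asarray(grid_or_centroids, float)
    M = cents.shape[0]
    if M == 1:
        return np.ones((1, 1))
    D = squareform(pdist(cents))
    dmax = D.max()
    return np.exp(-D / (dmax if dmax > 0 else 1.0))


@dataclass
class ModelSpec:
    """Which trait (if any) parameterizes the model.

    ``trait=None`` is the null model: intercept + the three environment
    covariates, no interactions.
    """

    trait: str | None = None
    include_interactions: bool = True
    variant: str = "points"

    def __post_init__(self):
        if self.trait is None:
            self.include_interactions = False

    @property
    def is_null(self) -> bool:
        return self.trait is None


@dataclass
class Design:
    """Fixed-effect design over the S*M observations (species-major rows)."""

    X: np.ndarray
    columns: list[str]
    sp_idx: np.ndarray
    un_idx: np.ndarray
    S: int
    M: int

    @property
    def n(self) -> int:
        return self.X.shape[0]

    def subset(self, rows: np.ndarray) -> "Design":
        return Design(
            self.X[rows], self.columns, self.sp_idx[rows], self.un_idx[rows],
            self.S, self.M,
        )


def build_design(spec: ModelSpec, traits_table, env: pd.DataFrame) -> Design:
    """Design matrix with row order species-major (row = s * M + m).

    Columns: intercept, trait, env1..env3, then trait x env interactions
    (trait models), or intercept + env (null).
    """
    env_arr = env.to_numpy(float)
    M = env_arr.shape[0]
    if isinstance(traits_table, TraitTable):
        trait_df = traits_table.data
    else:
        trait_df = traits_table
    S = trait_df.shape[0]
    if not np.isfinite(env_arr).all():
        raise ValueError("environment covariates contain non-finite values")
    sp_idx = np.repeat(np.arange(S), M)
    un_idx = np.tile(np.arange(M), S)
    env_rows = env_arr[un_idx]
    cols = [np.ones(S * M)]
    names = ["intercept"]
    if spec.trait is not None:
        x = trait_df[spec.trait].to_numpy(float)
        if not np.isfinite(x).all():
            raise ValueError(f"trait {spec.trait!r} contains non-finite values")
        cols.append(x[sp_idx])
        names.append(spec.trait)
    for j, name in enumerate(env.columns):
        cols.append(env_rows[:, j])
        names.append(str(name))
    if spec.trait is not None and spec.include_interactions:
        x = trait_df[spec.trait].to_numpy(float)[sp_idx]
        for j, name in enumerate(env.columns):
            cols.append(x * env_rows[:, j])
            names.append(f"{spec.trait}:{name}")
    X = np.column_stack(cols)
    return Design(X=X, columns=names, sp_idx=sp_idx, un_idx=un_idx, S=S, M=M)


# ---------------------------------------------------------------------------
# Woodbury machinery
# ---------------------------------------------------------------------------


class _CovStructure:
    """Precomputed pieces shared by all variance-component evaluations."""

    def __init__(self, Sigma_spp, Sigma_m, sp_idx, un_idx):
        self.S = Sigma_spp.shape[0]
        self.M = Sigma_m.shape[0]
        self.sp_idx = np.asarray(sp_idx)
        self.un_idx = np.asarray(un_idx)
        self.n = len(self.sp_idx)
        ws, Us = np.linalg.eigh(np.asarray(Sigma_spp, float))
        self.ws, self.Us = np.clip(ws, 0.0, None), Us
        wm, Um = np.linalg.eigh(np.asarray(Sigma_m, float))
        self.wm, self.Um = np.clip(wm, 0.0, None), Um
        self.cs = np.bincount(self.sp_idx, minlength=self.S).astype(float)
        self.cm = np.bincount(self.un_idx, minlength=self.M).astype(float)
        Nsm = np.zeros((self.S, self.M))
        np.add.at(Nsm, (self.sp_idx, self.un_idx), 1.0)
        self.Nsm = Nsm

    def V(self, variances) -> "_WoodburyV":
        return _WoodburyV(self, *variances)


class _WoodburyV:
    """V = se2 I + W_s A W_s' + W_m B W_m' with A = sa2 I + sb2 Sigma_spp,
    B = sc2 I + sd2 Sigma_m; all solves via the capacitance matrix."""

    def __init__(self, cs: _CovStructure, sa2, sb2, sc2, sd2, se2):
        self.cs = cs
        self.se2 = max(float(se2), 1e-10)
        da = np.sqrt(np.clip(sa2 + sb2 * cs.ws, 0.0, None))
        db = np.sqrt(np.clip(sc2 + sd2 * cs.wm, 0.0, None))
        self.Ah = (cs.Us * da) @ cs.Us.T  # A^(1/2), symmetric
        self.Bh = (cs.Um * db) @ cs.Um.T
        S, M = cs.S, cs.M
        UtU = np.empty((S + M, S + M))
        UtU[:S, :S] = (self.Ah * cs.cs) @ self.Ah
        UtU[S:, S:] = (self.Bh * cs.cm) @ self.Bh
        cross = self.Ah @ cs.Nsm @ self.Bh
        UtU[:S, S:] = cross
        UtU[S:, :S] = cross.T
        Bcap = np.eye(S + M) + UtU / self.se2
        self.chol = cho_factor(Bcap, lower=True)
        self._logdet_cap = 2.0 * np.sum(np.log(np.diag(self.chol[0])))

    # -- primitives ---------------------------------------------------------
    def _Wt(self, R: np.ndarray) -> np.ndarray:
        """U' R for R (n, p): group sums then half-covariance multiply."""
        R2 = R if R.ndim == 2 else R[:, None]
        p = R2.shape[1]
        Ssum = np.zeros((self.cs.S, p))
        np.add.at(Ssum, self.cs.sp_idx, R2)
        Msum = np.zeros((self.cs.M, p))
        np.add.at(Msum, self.cs.un_idx, R2)
        out = np.vstack([self.Ah @ Ssum, self.Bh @ Msum])
        return out if R.ndim == 2 else out[:, 0]

    def _expand(self, Z: np.ndarray) -> np.ndarray:
        """U Z for Z (S+M, p)."""
        Z2 = Z if Z.ndim == 2 else Z[:, None]
        S = self.cs.S
        top = self.Ah @ Z2[:S]
        bot = self.Bh @ Z2[S:]
        out = top[self.cs.sp_idx] + bot[self.cs.un_idx]
        return out if Z.ndim == 2 else out[:, 0]

    def solve(self, R: np.ndarray) -> np.ndarray:
        """V^{-1} R."""
        UtR = self._Wt(R)
        inner = cho_solve(self.chol, UtR)
        return (R - self._expand(inner) / self.se2) / self.se2

    @property
    def logdet(self) -> float:
        return self.cs.n * np.log(self.se2) + self._logdet_cap

    def diag_inverse(self) -> np.ndarray:
        """diag(V^{-1}) for the CPO identities."""
        Urows = np.hstack(
            [self.Ah[self.cs.sp_idx], self.Bh[self.cs.un_idx]]
        )  # (n, S+M)
        T = cho_solve(self.chol, Urows.T).T
        quad = np.einsum("ij,ij->i", Urows, T)
        return (1.0 - quad / self.se2) / self.se2

    def latent_cov_mult(self, v: np.ndarray) -> np.ndarray:
        """(V - se2 I) v = W G W' v: covariance between latent surface and data."""
        Ssum = np.zeros(self.cs.S)
        np.add.at(Ssum, self.cs.sp_idx, v)
        Msum = np.zeros(self.cs.M)
        np.add.at(Msum, self.cs.un_idx, v)
        A_s = self.Ah @ (self.Ah @ Ssum)
        B_m = self.Bh @ (self.Bh @ Msum)
        return A_s[self.cs.sp_idx] + B_m[self.cs.un_idx]

    def cross_cov_mult(self, v_on_train, train_struct: "_WoodburyV") -> np.ndarray:
        """W_test G W_train' v for prediction of held-out observations.

        ``self`` carries the test-row index structure, ``train_struct`` the
        (identical-parameter) covariance on the training rows.
        """
        Ssum = np.zeros(train_struct.cs.S)
        np.add.at(Ssum, train_struct.cs.sp_idx, v_on_train)
        Msum = np.zeros(train_struct.cs.M)
        np.add.at(Msum, train_struct.cs.un_idx, v_on_train)
        A_s = self.Ah @ (self.Ah @ Ssum)
        B_m = self.Bh @ (self.Bh @ Msum)
        return A_s[self.cs.sp_idx] + B_m[self.cs.un_idx]


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


@dataclass
class FitOptions:
    max_iter: int = 200
    rel_tol: float = 1e-6
    #: maximum objective evaluations for the simplex search
    max_fev: int = 1200


@dataclass
class FitResult:
    beta: np.ndarray
    beta_se: np.ndarray
    columns: list[str]
    variances: dict
    loglik: float
    converged: bool
    n_eval: int
    latent: np.ndarray  # conditional mean of the latent surface, (S, M) or (n,)
    spec: ModelSpec | None = None
    _internals: dict = field(default_factory=dict, repr=False)

    def wald_intervals(self, level: float = 0.95) -> pd.DataFrame:
        z = norm.ppf(0.5 + level / 2)
        return pd.DataFrame(
            {
                "estimate": self.beta,
                "se": self.beta_se,
                "lower": self.beta - z * self.beta_se,
                "upper": self.beta + z * self.beta_se,
            },
            index=self.columns,
        )

    def report(self) -> dict:
        return {
            "fixed_effects": dict(zip(self.columns, map(float, self.beta))),
            "standard_errors": dict(zip(self.columns, map(float, self.beta_se))),
            "variances": {k: float(v) for k, v in self.variances.items()},
            "loglik": float(self.loglik),
            "converged": bool(self.converged),
            "n_eval": int(self.n_eval),
        }


_VAR_NAMES = ("sigma_a2", "sigma_b2", "sigma_c2", "sigma_d2", "sigma_e2")


def _profile_nll(theta, struct, X, y):
    """Negative profile log-likelihood over log-variances theta."""
    variances = np.exp(np.clip(theta, -30.0, 10.0))
    V = struct.V(variances)
    VX = V.solve(X)
    Vy = V.solve(y)
    XtVX = X.T @ VX
    XtVy = X.T @ Vy
    try:
        beta = np.linalg.solve(XtVX, XtVy)
    except np.linalg.LinAlgError:
        beta = np.linalg.lstsq(XtVX, XtVy, rcond=None)[0]
    r = y - X @ beta
    quad = float(r @ (Vy - VX @ beta))
    nll = 0.5 * (struct.n * _LOG2PI + V.logdet + quad)
    return nll, beta, V, VX, XtVX


def fit(
    Y,
    design: Design,
    Sigma_spp: np.ndarray,
    Sigma_m: np.ndarray,
    opts: FitOptions | None = None,
    spec: ModelSpec | None = None,
    init_variances: dict | None = None,
) -> FitResult:
    """Maximum-likelihood fit of the Gaussian mixed co-occurrence model.

    ``Y`` is the (S, M) 0/1 presence matrix (or an already-flattened
    species-major vector).  Variance components are optimized on the log
    scale by Nelder-Mead from the initialization var(Y)/5 for every
    component; fixed effects are profiled by GLS inside the objective.
    Non-convergence is flagged on the result, not raised.
    """
    opts = opts or FitOptions()
    y = np.asarray(Y, float)
    reshape = y.ndim == 2
    if reshape:
        y = y.reshape(-1)
    if y.shape[0] != design.n:
        raise ValueError("response and design sizes differ")
    X = design.X
    struct = _CovStructure(Sigma_spp, Sigma_m, design.sp_idx, design.un_idx)

    if init_variances is not None:
        theta0 = np.log(
            np.clip([init_variances[k] for k in _VAR_NAMES], 1e-12, None)
        )
    else:
        v0 = max(float(np.var(y)), 1e-6) / 5.0
        theta0 = np.log(np.full(5, v0))
    best = {"nll": np.inf, "theta": theta0}

    def objective(theta):
        nll = _profile_nll(theta, struct, X, y)[0]
        if nll < best["nll"]:
            best["nll"], best["theta"] = nll, theta.copy()
        return nll

    res = optimize.minimize(
        objective,
        theta0,
        method="Nelder-Mead",
        options={
            "maxiter": opts.max_iter * 5,
            "maxfev": opts.max_fev,
            "fatol": opts.rel_tol * max(1.0, abs(float(objective(theta0)))),
            "xatol": 1e-4,
        },
    )
    theta = best["theta"]
    nll, beta, V, VX, XtVX = _profile_nll(theta, struct, X, y)
    cov_beta = np.linalg.inv(XtVX)
    se = np.sqrt(np.clip(np.diag(cov_beta), 0.0, None))
    r = y - X @ beta
    Vr = V.solve(r)
    latent = X @ beta + V.latent_cov_mult(Vr)
    variances = dict(zip(_VAR_NAMES, np.exp(np.clip(theta, -30.0, 10.0))))
    out_latent = latent.reshape(design.S, design.M) if reshape else latent
    return FitResult(
        beta=beta,
        beta_se=se,
        columns=design.columns,
        variances=variances,
        loglik=-nll,
        converged=bool(res.success),
        n_eval=int(res.nfev),
        latent=out_latent,
        spec=spec,
        _internals={
            "V": V, "resid": r, "y": y, "design": design, "struct": struct,
            "Vr": Vr,
        },
    )


def predict(fit_result: FitResult) -> np.ndarray:
    """Relative occurrence probability: latent surface min-max rescaled to [0,1].

    A constant surface maps to 0.5 everywhere.
    """
    eta = np.asarray(fit_result.latent, float)
    lo, hi = eta.min(), eta.max()
    if hi - lo <= 1e-12:
        return np.full_like(eta, 0.5)
    return (eta - lo) / (hi - lo)


def average_runs(surfaces) -> np.ndarray:
    """Arithmetic mean of aligned S x M probability surfaces."""
    arrs = [np.asarray(a, float) for a in surfaces]
    shape = arrs[0].shape
    for a in arrs[1:]:
        if a.shape != shape:
            raise ValueError("surface shapes differ")
    return np.mean(arrs, axis=0)


def _species_stratified_folds(design: Design, k: int, seed: int) -> np.ndarray:
    """Fold labels such that every species appears in every training set."""
    rng = np.random.default_rng(seed)
    labels = np.empty(design.n, dtype=int)
    for s in range(design.S):
        rows = np.flatnonzero(design.sp_idx == s)
        rng.shuffle(rows)
        labels[rows] = (np.arange(len(rows)) + rng.integers(k)) % k
    return labels


def cross_validate(
    Y,
    design: Design,
    Sigma_spp: np.ndarray,
    Sigma_m: np.ndarray,
    k: int = 10,
    seed: int = 0,
    opts: FitOptions | None = None,
    init_variances: dict | None = None,
) -> np.ndarray:
    """k-fold cross-validated RMSE with folds stratified by species.

    Held-out observations are predicted by their conditional expectation
    given the training observations under the fitted covariance.  Passing
    the variance components of a full-data fit as ``init_variances`` warm
    starts the per-fold optimizations.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    y = np.asarray(Y, float).reshape(-1)
    labels = _species_stratified_folds(design, k, seed)
    rmses = np.empty(k)
    for fold in range(k):
        test = labels == fold
        train = ~test
        d_tr = design.subset(train)
        fit_tr = fit(y[train], d_tr, Sigma_spp, Sigma_m, opts=opts,
                     init_variances=init_variances)
        V_tr = fit_tr._internals["V"]
        r_tr = fit_tr._internals["resid"]
        t = V_tr.solve(r_tr)
        d_te = design.subset(test)
        V_te = _CovStructure(Sigma_spp, Sigma_m, d_te.sp_idx, d_te.un_idx).V(
            [fit_tr.variances[v] for v in _VAR_NAMES]
        )
        mu = d_te.X @ fit_tr.beta + V_te.cross_cov_mult(t, V_tr)
        rmses[fold] = float(np.sqrt(np.mean((y[test] - mu) ** 2)))
    return rmses


def cpo(fit_result: FitResult, Y=None) -> np.ndarray:
    """Per-observation conditional predictive ordinate.

    The leave-one-out predictive density of each observation under the
    fitted Gaussian model, from the precision-matrix identities:
    conditional variance 1/Q_ii and conditional mean y_i - (Q r)_i / Q_ii
    with Q = V^{-1} and r the GLS residual vector.
    """
    V = fit_result._internals["V"]
    r = fit_result._internals["resid"]
    y = fit_result._internals["y"] if Y is None else np.asarray(Y, float).reshape(-1)
    Qr = fit_result._internals["Vr"]
    Qd = V.diag_inverse()
    Qd = np.clip(Qd, 1e-300, None)
    cond_var = 1.0 / Qd
    cond_mean = y - Qr / Qd
    return norm.pdf(y, loc=cond_mean, scale=np.sqrt(cond_var))


# ---------------------------------------------------------------------------
# model comparison metrics
# ---------------------------------------------------------------------------


@dataclass
class EvalResult:
    """Scaled RMSE deltas and CPO deltas between trait and null models."""

    rmse_table: pd.DataFrame  # variant, model, rmse, rmse_scaled, delta_rmse
    delta_cpo_species: pd.DataFrame  # species, trait, delta_cpo, quartile
    quartile_summary: pd.DataFrame  # quartile x trait (+ overall) medians

    @property
    def delta_rmse_by_trait(self) -> pd.Series:
        t = self.rmse_table[self.rmse_table.model != "null"]
        return t.groupby("model")["delta_rmse"].mean()


def delta_metrics(
    rmse_trait: dict,
    rmse_null: dict,
    cpo_trait: dict,
    cpo_null: dict,
    quartiles: pd.Series,
    species: list[str],
) -> EvalResult:
    """Model-improvement metrics.

    ``rmse_trait`` maps (trait, variant) -> per-fold RMSE array;
    ``rmse_null`` maps variant -> per-fold RMSE array.  RMSEs are min-max
    scaled within each dataset variant across all models (traits + null);
    delta RMSE = scaled trait - scaled null, so negative means the trait
    improved the model.  ``cpo_trait``/(``cpo_null``) map the same keys to
    per-observation CPO arrays of shape (S, M); the per-species delta CPO is
    the median over that species' observations of CPO_trait - CPO_null,
    pooled across variants, and summaries are medians per rarity quartile.
    """
    variants = sorted({v for (_, v) in rmse_trait} | set(rmse_null))
    rows = []
    for variant in variants:
        models = {"null": float(np.mean(rmse_null[variant]))}
        for (trait, var), arr in rmse_trait.items():
            if var == variant:
                models[trait] = float(np.mean(arr))
        vals = np.array(list(models.values()))
        lo, hi = vals.min(), vals.max()
        span = hi - lo if hi > lo else 1.0
        scaled = {m: (v - lo) / span for m, v in models.items()}
        for m, v in models.items():
            rows.append(
                {
                    "variant": variant,
                    "model": m,
                    "rmse": v,
                    "rmse_scaled": scaled[m],
                    "delta_rmse": scaled[m] - scaled["null"],
                }
            )
    rmse_table = pd.DataFrame(rows)

    cpo_rows = []
    traits = sorted({t for (t, _) in cpo_trait})
    for trait in traits:
        diffs = []
        for (t, variant), arr in cpo_trait.items():
            if t != trait or variant not in cpo_null:
                continue
            diffs.append(np.asarray(arr, float) - np.asarray(cpo_null[variant], float))
        if not diffs:
            continue
        stacked = np.concatenate([d.reshape(len(species), -1) for d in diffs], axis=1)
        med = np.median(stacked, axis=1)
        for sp, v in zip(species, med):
            cpo_rows.append({"species": sp, "trait": trait, "delta_cpo": float(v)})
    delta_cpo = pd.DataFrame(cpo_rows)
    if len(delta_cpo):
        delta_cpo["quartile"] = delta_cpo["species"].map(quartiles)
        per_trait = (
            delta_cpo.groupby(["quartile", "trait"])["delta_cpo"].median().unstack()
        )
        per_trait["overall"] = delta_cpo.groupby("quartile")["delta_cpo"].median()
        quartile_summary = per_trait
    else:
        quartile_summary = pd.DataFrame()
    return EvalResult(
        rmse_table=rmse_table,
        delta_cpo_species=delta_cpo,
        quartile_summary=quartile_summary,
    )
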