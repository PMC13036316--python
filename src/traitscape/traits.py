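"""Trait tables: transforms, Gower distances, and phylogenetically informed imputation.

The trait set mirrors what taxonomic descriptions typically yield for a
tropical flora: five continuous size traits (plant size, leaf length, leaf
width, flower size, fruit size; largest recorded measurements, log- then
z-scored), five growth-habit binaries (tree, shrub, climbing, herb,
epiphyte) and seven flower-color binaries (red, yellow, white, purple,
pink, orange, brown).  Missing entries are NaN.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

CONTINUOUS_TRAITS = ("plant_size", "leaf_length", "leaf_width", "flower_size", "fruit_size")
HABIT_TRAITS = ("tree", "shrub", "climbing", "herb", "epiphyte")
COLOR_TRAITS = ("red", "yellow", "white", "purple", "pink", "orange", "brown")


@dataclass
class TraitTable:
    """Species x trait table with a missingness mask (NaN = missing)."""

    data: pd.DataFrame
    continuous: tuple = CONTINUOUS_TRAITS
    habit: tuple = HABIT_TRAITS
    color: tuple = COLOR_TRAITS
    #: per-column (mean, sd) of the log values, stored when transforming
    transform_params: dict = field(default_factory=dict)

    def __post_init__(self):
        self.continuous = tuple(c for c in self.continuous if c in self.data.columns)
        self.habit = tuple(c for c in self.habit if c in self.data.columns)
        self.color = tuple(c for c in self.color if c in self.data.columns)
        for col in self.binary:
            vals = self.data[col].dropna().unique()
            if not np.isin(vals, [0, 1]).all():
                raise ValueError(f"binary trait {col!r} has values outside {{0,1}}")
        frac = self.data.isna().mean()
        bad = frac[frac >= 0.7]
        if len(bad):
            raise ValueError(
                f"columns with >= 70% missing data: {list(bad.index)}"
            )

    @property
    def binary(self) -> tuple:
        return self.habit + self.color

    @property
    def species(self) -> list[str]:
        return list(self.data.index)

    @property
    def mask(self) -> pd.DataFrame:
        """True where a value is missing."""
        return self.data.isna()

    @property
    def complete(self) -> bool:
        return not self.data.isna().any().any()

    def copy(self) -> "TraitTable":
        return TraitTable(
            self.data.copy(), self.continuous, self.habit, self.color,
            dict(self.transform_params),
        )


def transform_continuous(raw: TraitTable) -> TraitTable:
    """Natural log then per-column z-score of the continuous traits.

    Means/sds are computed over non-missing entries and stored in
    ``transform_params`` so the transform can be inverted.  A column with
    zero spread gets sd := 1 (values map to zero).
    """
    out = raw.copy()
    for col in raw.continuous:
        vals = out.data[col]
        obs = vals.dropna()
        if (obs <= 0).any():
            offender = obs[obs <= 0].index[0]
            raise ValueError(
                f"non-positive value for trait {col!r}, species {offender!r}"
            )
        logged = np.log(vals.astype(float))
        mu = float(np.nanmean(logged))
        sd = float(np.nanstd(logged, ddof=1)) if obs.size > 1 else 0.0
        if not np.isfinite(sd) or sd == 0.0:
            sd = 1.0
        out.data[col] = (logged - mu) / sd
        out.transform_params[col] = (mu, sd)
    return out


def invert_continuous(table: TraitTable) -> TraitTable:
    """Undo :func:`transform_continuous` using the stored parameters."""
    out = table.copy()
    for col, (mu, sd) in table.transform_params.items():
        out.data[col] = np.exp(table.data[col] * sd + mu)
    out.transform_params = {}
    return out


@dataclass
class GowerWeights:
    """Per-column weights for the Gower distance.

    Default semantics: each continuous trait has weight 1, while the habit
    and flower-color blocks are downweighted so each whole block carries the
    weight of a single continuous trait (1/5 per habit column, 1/7 per color
    column).
    """

    weights: dict

    @classmethod
    def paper_default(cls, table: TraitTable) -> "GowerWeights":
        w = {c: 1.0 for c in table.continuous}
        w.update({c: 1.0 / max(len(table.habit), 1) for c in table.habit})
        w.update({c: 1.0 / max(len(table.color), 1) for c in table.color})
        return cls(w)


def gower_matrix(table: TraitTable, weights: GowerWeights | None = None) -> np.ndarray:
    """Weighted Gower distance matrix over species.

    Continuous columns contribute ``|x_i - x_j| / range``; binaries
    contribute the simple mismatch.  Distances are the weighted mean of
    per-column contributions: symmetric, zero diagonal, entries in [0, 1].
    Requires a complete (imputed) table.
    """
    if not table.complete:
        raise ValueError("trait table has missing values; impute before Gower")
    if weights is None:
        weights = GowerWeights.paper_default(table)
    S = len(table.species)
    num = np.zeros((S, S))
    wtot = 0.0
    for col in table.continuous:
        x = table.data[col].to_numpy(float)
        rng = x.max() - x.min()
        contrib = np.abs(x[:, None] - x[None, :]) / (rng if rng > 0 else 1.0)
        w = weights.weights.get(col, 1.0)
        num += w * contrib
        wtot += w
    for col in table.binary:
        x = table.data[col].to_numpy(float)
        contrib = (x[:, None] != x[None, :]).astype(float)
        w = weights.weights.get(col, 1.0)
        num += w * contrib
        wtot += w
    D = num / wtot
    np.fill_diagonal(D, 0.0)
    return np.clip((D + D.T) / 2, 0.0, 1.0)


# ---------------------------------------------------------------------------
# imputation
# ---------------------------------------------------------------------------


def impute_phylo_ml(
    table: TraitTable, cov: np.ndarray, species: list[str] | None = None,
    nugget: float = 1e-6,
) -> TraitTable:
    """Phylogenetic maximum-likelihood imputation of the continuous traits.

    Each continuous column is modeled as a Brownian-motion draw: values
    jointly multivariate normal with mean ``mu`` and covariance
    ``sigma2 * (C + nugget * I)``, where ``C`` is the (standardized)
    phylogenetic covariance.  ``mu`` and ``sigma2`` are estimated by maximum
    likelihood on the observed tips (GLS mean, profiled variance); missing
    entries are replaced by their conditional expectation given the observed
    tips.  Columns with fewer than 3 observed values fall back to the column
    mean with a warning.  Binary traits are left untouched.
    """
    out = table.copy()
    if species is None:
        species = table.species
    order = [species.index(s) for s in table.species]
    C = np.asarray(cov)[np.ix_(order, order)] + nugget * np.eye(len(order))
    for col in table.continuous:
        y = out.data[col].to_numpy(float)
        miss = np.isnan(y)
        if not miss.any():
            continue
        obs = ~miss
        if obs.sum() < 3:
            warnings.warn(
                f"trait {col!r}: fewer than 3 observed values; using column mean"
            )
            y[miss] = np.nanmean(y) if obs.any() else 0.0
            out.data[col] = y
            continue
        Coo = C[np.ix_(obs, obs)]
        Cmo = C[np.ix_(miss, obs)]
        Loo = np.linalg.cholesky(Coo)
        ones = np.ones(obs.sum())
        yi = y[obs]
        a = np.linalg.solve(Loo, ones)
        b = np.linalg.solve(Loo, yi)
        mu = float(a @ b / (a @ a))
        resid = b - mu * a  # whitened residuals
        # sigma2 ML = resid' Coo^-1 resid / n; cancels in the conditional mean
        w = np.linalg.solve(Loo.T, resid)
        y[miss] = mu + Cmo @ w
        out.data[col] = y
    return out


def impute_rf(
    table: TraitTable,
    eigenvectors: np.ndarray,
    seed: int = 0,
    max_sweeps: int = 10,
    tol: float = 1e-3,
    n_estimators: int = 100,
) -> TraitTable:
    """Iterative random-forest imputation with phylogenetic eigenvectors.

    missForest-style: initialize missing entries with the column mean (mode
    for binaries), then refit a random forest per column -- regression for
    continuous, classification for binary -- on all other trait columns plus
    the phylogenetic eigenvectors, re-imputing until the normalized change
    between sweeps drops below ``tol`` or ``max_sweeps`` is reached.
    Deterministic for a given seed.
    """
    out = table.copy()
    cols = list(table.continuous) + list(table.binary)
    mask = {c: out.data[c].isna().to_numpy() for c in cols}
    if not any(m.any() for m in mask.values()):
        return out
    E = np.asarray(eigenvectors, float)
    # initialize
    for c in table.continuous:
        m = mask[c]
        if m.any():
            fill = np.nanmean(out.data[c].to_numpy(float)) if (~m).any() else 0.0
            out.data.loc[m, c] = fill
    for c in table.binary:
        m = mask[c]
        if m.any():
            obs = out.data[c].dropna()
            fill = float(obs.mode().iloc[0]) if len(obs) else 0.0
            out.data.loc[m, c] = fill
    rng = np.random.default_rng(seed)
    prev = out.data[cols].to_numpy(float).copy()
    for _ in range(max_sweeps):
        for c in cols:
            m = mask[c]
            if not m.any() or (~m).sum() < 2:
                continue
            others = [o for o in cols if o != c]
            X = np.column_stack([out.data[others].to_numpy(float), E])
            y = out.data[c].to_numpy(float)
            rf_seed = int(rng.integers(0, 2**31 - 1))
            if c in table.continuous:
                rf = RandomForestRegressor(
                    n_estimators=n_estimators, random_state=rf_seed, n_jobs=1
                )
                rf.fit(X[~m], y[~m])
                out.data.loc[m, c] = rf.predict(X[m])
            else:
                yo = y[~m].astype(int)
                if len(np.unique(yo)) < 2:
                    out.data.loc[m, c] = float(yo[0]) if len(yo) else 0.0
                    continue
                rf = RandomForestClassifier(
                    n_estimators=n_estimators, random_state=rf_seed, n_jobs=1
                )
                rf.fit(X[~m], yo)
                out.data.loc[m, c] = rf.predict(X[m]).astype(float)
        cur = out.data[cols].to_numpy(float)
        denom = np.sum(cur**2)
        change = np.sum((cur - prev) ** 2) / denom if denom > 0 else 0.0
        prev = cur.copy()
        if change < tol:
            break
    return out


def ensemble_impute(
    table: TraitTable,
    cov: np.ndarray,
    eigenvectors: np.ndarray,
    iterations: int = 15,
    seed: int = 0,
    rf_kwargs: dict | None = None,
) -> TraitTable:
    """Ensemble of the two imputers, repeated ``iterations`` times.

    Continuous traits: the mean across all repetitions of both imputers
    (random forest and phylogenetic ML).  Binary traits: the modal value
    across the random-forest repetitions (the phylogenetic-ML imputer only
    handles continuous columns).  The returned table has no missing values.
    """
    rf_kwargs = rf_kwargs or {}
    if table.complete:
        return table.copy()
    seeds = np.random.SeedSequence(seed).generate_state(iterations)
    cont_stack: list[np.ndarray] = []
    bin_stack: list[np.ndarray] = []
    cont = list(table.continuous)
    bins = list(table.binary)
    ml = impute_phylo_ml(table, cov)  # deterministic; same in every repetition
    for s in seeds:
        rf = impute_rf(table, eigenvectors, seed=int(s % (2**31 - 1)), **rf_kwargs)
        if cont:
            cont_stack.append(rf.data[cont].to_numpy(float))
            cont_stack.append(ml.data[cont].to_numpy(float))
        if bins:
            bin_stack.append(rf.data[bins].to_numpy(float))
    out = table.copy()
    if cont:
        mean_cont = np.mean(cont_stack, axis=0)
        vals = out.data[cont].to_numpy(float)
        miss = np.isnan(vals)
        vals[miss] = mean_cont[miss]
        out.data[cont] = vals
    if bins:
        stack = np.stack(bin_stack)  # (iters, S, B)
        modal = (stack.mean(axis=0) > 0.5).astype(float)
        # exact ties (possible with even iteration counts) resolve to 1
        modal[np.isclose(stack.mean(axis=0), 0.5)] = 1.0
        vals = out.data[bins].to_numpy(float)
        miss = np.isnan(vals)
        vals[miss] = modal[miss]
        out.data[bins] = vals
    return out
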