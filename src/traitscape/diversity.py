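"""Hill-number diversity layers: coverage-extrapolated alpha and Jaccard-type beta.

Per-unit "abundances" are the summed presences over K (default 20)
independent Bernoulli draws from the modeled relative occurrence
probabilities.  From these the four prioritization features are computed:

* species alpha: q = 0 richness interpolated/extrapolated to a target
  sample coverage (default 98.5%),
* trait alpha: the same estimator applied to functional entities --
  species merged by single-linkage clustering of Gower trait distances at
  the cut height tau, the abundance-weighted mean pairwise trait distance
  of the pooled assemblage,
* species beta: one minus the mean pairwise Jaccard-type similarity
  (q = 0, lambda = 1) between the focal unit and every other unit,
* trait beta: as above with abundance weighting (q = 2) and the quadratic
  attribute-diversity framework (lambda = 2) under distances truncated
  at tau.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform


def draw_abundance(probs: np.ndarray, K: int = 20, seed: int = 0) -> np.ndarray:
    """Summed presence over K independent Bernoulli draws per cell."""
    p = np.asarray(probs, float)
    if p.min() < 0 or p.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    return rng.binomial(K, p).astype(int)


def sample_coverage(abund) -> float:
    """Estimated sample coverage of an abundance vector.

    C-hat = 1 - (f1/n) * [(n-1) f1 / ((n-1) f1 + 2 f2)] with n the total
    count, f1 the number of singletons and f2 the number of doubletons.
    """
    x = np.asarray(abund, int)
    x = x[x > 0]
    n = int(x.sum())
    if n < 1:
        raise ValueError("abundance vector must have a positive total count")
    f1 = int((x == 1).sum())
    f2 = int((x == 2).sum())
    if f1 == 0:
        return 1.0
    if n == 1:
        return 0.0
    denom = (n - 1) * f1 + 2 * f2
    bracket = (n - 1) * f1 / denom if denom > 0 else 0.0
    return 1.0 - (f1 / n) * bracket


def _chao1_f0(n: int, f1: int, f2: int) -> float:
    """Chao1 estimate of the number of unseen species."""
    if f1 == 0:
        return 0.0
    if f2 > 0:
        return f1 * f1 / (2.0 * f2)
    return f1 * (f1 - 1) / 2.0


def alpha_coverage(abund, target: float = 0.985) -> float:
    """q = 0 richness at a target sample coverage.

    If the observed coverage already meets the target the observed richness
    is returned (diversity is never rarefied below what was seen -- a
    deliberate convention for sparse assemblages where every detected
    species counts).  Otherwise richness is extrapolated:

        S(n + m*) = S_obs + f0 * [1 - (1 - f1 / (n f0 + f1))**m*]

    with f0 the Chao1 unseen-species estimate and m* solving the
    extrapolated-coverage equation
    C(n + m) = 1 - (f1/n) * A**(m+1), A = (n-1) f1 / ((n-1) f1 + 2 f2),
    for the target.  When the coverage curve cannot reach the target
    (f2 = 0 makes A = 1) the asymptotic estimate S_obs + f0 is returned.
    """
    if not 0 < target <= 1:
        raise ValueError("target coverage must lie in (0, 1]")
    x = np.asarray(abund, int)
    x = x[x > 0]
    n = int(x.sum())
    if n < 1:
        raise ValueError("abundance vector must have a positive total count")
    S_obs = int(len(x))
    f1 = int((x == 1).sum())
    f2 = int((x == 2).sum())
    if f1 == 0:
        return float(S_obs)
    if sample_coverage(x) >= target:
        return float(S_obs)
    f0 = _chao1_f0(n, f1, f2)
    if f0 <= 0:
        return float(S_obs)
    denom = (n - 1) * f1 + 2 * f2
    A = (n - 1) * f1 / denom if denom > 0 else 1.0
    if A >= 1.0:
        return float(S_obs + f0)
    ratio = (1.0 - target) * n / f1
    if ratio <= 0:
        return float(S_obs + f0)
    m_star = np.log(ratio) / np.log(A) - 1.0
    m_star = max(m_star, 0.0)
    extra = f0 * (1.0 - (1.0 - f1 / (n * f0 + f1)) ** m_star)
    return float(S_obs + extra)


def functional_threshold(pooled_abund, gower: np.ndarray) -> float:
    """Mean Gower distance between two individuals drawn from the pooled pool.

    tau = sum_ij p_i p_j d_ij with p the pooled relative abundances
    (self-pairs contribute zero distance).
    """
    x = np.asarray(pooled_abund, float)
    if (x > 0).sum() < 2:
        raise ValueError("pooled assemblage must contain at least 2 species")
    p = x / x.sum()
    return float(p @ np.asarray(gower, float) @ p)


def functional_entities(gower: np.ndarray, tau: float) -> np.ndarray:
    """Entity membership: complete-linkage clusters cut at height tau.

    Complete linkage keeps every within-entity pairwise distance below the
    cut, so an entity is a set of species that are all mutually closer than
    tau, and distinct entities are separated by at least one pair exceeding
    it.  (Single linkage would chain a species-rich pool into one entity
    whenever nearest-neighbour distances fall below tau, collapsing the
    trait-alpha layer to 1.)
    """
    D = np.asarray(gower, float)
    if D.shape[0] == 1:
        return np.zeros(1, dtype=int)
    Z = linkage(squareform(D, checks=False), method="complete")
    return fcluster(Z, t=tau, criterion="distance") - 1


def trait_alpha(
    abund, gower: np.ndarray, tau: float, target: float = 0.985
) -> float:
    """Coverage-extrapolated richness of functional entities.

    Species are merged into entities wherever their complete-linkage Gower
    distance falls below tau; the entity abundance vector (sums of member
    abundances) is then passed through :func:`alpha_coverage`.  Always
    <= the species alpha of the same vector, since merging reduces richness
    and pools counts.
    """
    x = np.asarray(abund, int)
    ent = functional_entities(gower, tau)
    n_ent = ent.max() + 1
    pooled = np.zeros(n_ent, dtype=int)
    np.add.at(pooled, ent, x)
    return alpha_coverage(pooled, target=target)


# ---------------------------------------------------------------------------
# Jaccard-type beta dissimilarity
# ---------------------------------------------------------------------------


def _jaccard_similarity(d_beta: float, q: float, lam: int, N: int = 2) -> float:
    """U_qN transformation of a beta ratio D_beta in [1, N**lam]."""
    top = float(N**lam)
    d_beta = min(max(d_beta, 1.0), top)
    if abs(q - 1.0) < 1e-12:
        # continuity limit: U = 1 - log(D_beta)/ (lam log N)
        return 1.0 - np.log(d_beta) / (lam * np.log(N))
    e = 1.0 - q
    u = ((1.0 / d_beta) ** e - (1.0 / top) ** e) / (1.0 - (1.0 / top) ** e)
    return float(min(max(u, 0.0), 1.0))


def _species_beta_pair(xu: np.ndarray, xw: np.ndarray) -> float:
    """q=0, lambda=1 Jaccard-type similarity between two abundance vectors.

    D_gamma is the pooled richness; D_alpha is the richness of the joint
    species x assemblage item set divided by N = 2.
    """
    pu, pw = xu > 0, xw > 0
    d_gamma = float((pu | pw).sum())
    d_alpha = (pu.sum() + pw.sum()) / 2.0
    if d_alpha == 0:
        return 1.0
    return _jaccard_similarity(d_gamma / d_alpha, q=0.0, lam=1)


def _trait_beta_pair(
    xu: np.ndarray, xw: np.ndarray, d_tau: np.ndarray
) -> float:
    """q=2, lambda=2 functional Jaccard-type similarity under tau-truncated
    distances, via the quadratic attribute-diversity decomposition.

    Gamma uses the pooled relative abundances; alpha treats the 2S
    species-assemblage items (abundances halved); both share the pooled
    Rao Q so the ratio lies in [1, 4].
    """
    su, sw = xu.sum(), xw.sum()
    if su == 0 or sw == 0:
        return 1.0
    pu = xu / su
    pw = xw / sw
    pp = (pu + pw) / 2.0
    Q = float(pp @ d_tau @ pp)
    if Q <= 0:
        # no functional distinctness in the pooled pair: identical in trait space
        return 1.0
    pp2 = pp * pp
    g_sum = float(pp2 @ d_tau @ pp2) / Q**2
    fd_gamma = 1.0 / g_sum
    qu = (pu / 2.0) ** 2
    qw = (pw / 2.0) ** 2
    a_sum = (
        float(qu @ d_tau @ qu)
        + 2.0 * float(qu @ d_tau @ qw)
        + float(qw @ d_tau @ qw)
    ) / Q**2
    fd_alpha = 0.25 / a_sum
    return _jaccard_similarity(fd_gamma / fd_alpha, q=2.0, lam=2)


def beta_dissimilarity(
    abund: np.ndarray,
    kind: str = "species",
    gower: np.ndarray | None = None,
    tau: float | None = None,
) -> np.ndarray:
    """Per-unit beta dissimilarity: 1 - mean pairwise Jaccard-type similarity.

    ``kind='species'`` uses q = 0, lambda = 1 taxonomic Hill numbers;
    ``kind='trait'`` uses q = 2, lambda = 2 attribute diversity with Gower
    distances truncated at tau.  Units with zero total abundance are
    excluded as partners and get NaN as focal units.
    """
    X = np.asarray(abund, float)
    S, M = X.shape
    if M < 2:
        raise ValueError("need at least 2 units")
    if kind == "trait":
        if gower is None or tau is None:
            raise ValueError("trait beta requires gower and tau")
        d_tau = np.minimum(np.asarray(gower, float), tau)
    elif kind != "species":
        raise ValueError(f"unknown kind {kind!r}")
    nonempty = np.flatnonzero(X.sum(axis=0) > 0)
    out = np.full(M, np.nan)
    for u in nonempty:
        sims = []
        for w in nonempty:
            if w == u:
                continue
            if kind == "species":
                sims.append(_species_beta_pair(X[:, u], X[:, w]))
            else:
                sims.append(_trait_beta_pair(X[:, u], X[:, w], d_tau))
        if sims:
            out[u] = 1.0 - float(np.mean(sims))
    ok = ~np.isnan(out)
    out[ok] = np.clip(out[ok], 0.0, 1.0)
    return out


@dataclass
class DiversityLayers:
    """The four per-unit prioritization features plus provenance."""

    species_alpha: np.ndarray
    trait_alpha: np.ndarray
    species_beta: np.ndarray
    trait_beta: np.ndarray
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "species_alpha": self.species_alpha,
            "trait_alpha": self.trait_alpha,
            "species_beta": self.species_beta,
            "trait_beta": self.trait_beta,
        }


def build_layers(
    probs: np.ndarray,
    gower: np.ndarray,
    K: int = 20,
    target: float = 0.985,
    seed: int = 0,
) -> DiversityLayers:
    """Draw abundances once (seeded) and compute the four diversity layers.

    tau is the abundance-weighted mean pairwise Gower distance of the
    landscape-pooled assemblage.  Empty units get alpha 0 and beta NaN
    replaced by 0 so the layers can be used directly as feature amounts.
    """
    abund = draw_abundance(probs, K=K, seed=seed)
    S, M = abund.shape
    pooled = abund.sum(axis=1)
    tau = functional_threshold(pooled, gower)
    sp_alpha = np.zeros(M)
    tr_alpha = np.zeros(M)
    for m in range(M):
        if abund[:, m].sum() > 0:
            sp_alpha[m] = alpha_coverage(abund[:, m], target=target)
            tr_alpha[m] = trait_alpha(abund[:, m], gower, tau, target=target)
    sp_beta = np.nan_to_num(beta_dissimilarity(abund, "species"), nan=0.0)
    tr_beta = np.nan_to_num(
        beta_dissimilarity(abund, "trait", gower=gower, tau=tau), nan=0.0
    )
    return DiversityLayers(
        species_alpha=sp_alpha,
        trait_alpha=tr_alpha,
        species_beta=sp_beta,
        trait_beta=tr_beta,
        provenance={
            "tau": float(tau),
            "coverage_target": target,
            "draws": K,
            "seed": seed,
            "alpha_q": 0,
            "beta_species_q": 0,
            "beta_trait_q": 2,
        },
    )
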