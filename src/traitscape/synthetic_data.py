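"""Synthetic landscape, phylogeny, trait, and occurrence generator.

Everything downstream (imputation, joint occurrence models, diversity
layers, prioritization) is exercised on data produced here.  The generator
emulates the data structure of a sparse tropical-flora inventory: a dated
ultrametric phylogeny, traits with Brownian-motion signal and missing
entries, spatially autocorrelated environment/cost/carbon/deforestation
layers on a planar grid of 11 x 11-km planning units, and presences from a
linear-probability model with trait x environment interactions plus
species-level (i.i.d. + phylogenetic) and unit-level (i.i.d. + spatial)
random effects.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field, asdict

import dendropy
import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist

from .occurrences import PlanningGrid
from .phylogeny import phylo_covariance, read_newick_string, tip_labels
from .traits import (
    COLOR_TRAITS,
    CONTINUOUS_TRAITS,
    HABIT_TRAITS,
    TraitTable,
)

ENV_NAMES = ("annual_mean_temp", "temp_seasonality", "soil_organic_carbon")

#: the 13 candidate environmental variables emulated for the PCA selection step
ENV_CANDIDATE_NAMES = (
    "elevation",
    "annual_mean_temp",
    "mean_diurnal_range",
    "isothermality",
    "temp_seasonality",
    "temp_annual_range",
    "annual_precip",
    "precip_seasonality",
    "bulk_density",
    "coarse_fragments",
    "ph",
    "sand",
    "soil_organic_carbon",
)


@dataclass
class TraitEffect:
    """True fixed-effect sizes for one trait: main effect and the three
    trait x environment interaction coefficients."""

    main: float = 0.0
    interactions: tuple[float, float, float] = (0.0, 0.0, 0.0)


def default_trait_effects() -> dict:
    # two traits carry signal by default: one continuous, one color binary
    return {
        "leaf_length": TraitEffect(0.04, (0.10, 0.04, 0.0)),
        "red": TraitEffect(0.02, (0.08, 0.0, 0.04)),
    }


@dataclass
class SimConfig:
    """Study conditions for the synthetic landscape.

    Defaults are desk-scale stand-ins for the real study system (hundreds of
    species over ~1000 planning units): sparse presences, Brownian trait
    signal, trait x environment effects on occurrence, and spatially
    autocorrelated layers.  The intercept of 0.12 puts the species mean
    number of presences across the five dataset variants near the sparse
    occupancy regime of a poorly collected flora (~0.17 of units).
    """

    n_species: int = 40
    n_x: int = 8
    n_y: int = 8
    intercept: float = 0.15
    env_effects: tuple[float, float, float] = (-0.22, -0.08, 0.10)
    trait_effect_sizes: dict = field(default_factory=default_trait_effects)
    #: (sigma_a2, sigma_b2, sigma_c2, sigma_d2, sigma_e2)
    variance_components: tuple = (0.004, 0.008, 0.004, 0.010, 0.015)
    missing_rate: float = 0.30
    seed: int = 0
    side_km: float = 11.0

    def __post_init__(self):
        if self.n_x * self.n_y < 4:
            raise ValueError("grid must have at least 4 planning units")
        if any(v < 0 for v in self.variance_components):
            raise ValueError("variance components must be non-negative")
        if not (0 <= self.missing_rate < 0.7):
            raise ValueError("missing_rate must lie in [0, 0.7)")
        self.trait_effect_sizes = {
            k: (v if isinstance(v, TraitEffect) else TraitEffect(*v))
            for k, v in self.trait_effect_sizes.items()
        }

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=2, default=list)


def gen_phylogeny(n_species: int, seed: int = 0) -> dendropy.Tree:
    """Random rooted ultrametric pure-birth tree with labelled tips.

    Tips are relabelled ``Sp0001 .. SpNNNN`` in leaf-iteration order so the
    output is deterministic for a given seed.
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    if n_species == 1:
        tree = read_newick_string("(Sp0001:1.0);")
        return tree
    from dendropy.simulate import treesim

    rng = random.Random(seed)
    tree = treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_species,
        rng=rng,
    )
    tree.is_rooted = True
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"Sp{i + 1:04d}"
    return tree


def _bm_cholesky(tree: dendropy.Tree) -> tuple[np.ndarray, list[str]]:
    C, labels = phylo_covariance(tree, standardize=True)
    L = np.linalg.cholesky(C + 1e-9 * np.eye(len(labels)))
    return L, labels


def gen_traits(tree: dendropy.Tree, config: SimConfig) -> TraitTable:
    """Traits with Brownian-motion phylogenetic signal.

    Continuous traits are Brownian draws on the log scale, z-scored per
    column.  Binary traits (habits + flower colors) are Brownian draws
    thresholded at the empirical median, so they also carry signal.
    Missingness is applied completely at random at ``config.missing_rate``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    L, labels = _bm_cholesky(tree)
    S = len(labels)
    cols = {}
    for name in CONTINUOUS_TRAITS:
        x = L @ rng.standard_normal(S)
        sd = x.std(ddof=1) if S > 1 else 1.0
        cols[name] = (x - x.mean()) / (sd if sd > 0 else 1.0)
    for name in HABIT_TRAITS + COLOR_TRAITS:
        x = L @ rng.standard_normal(S)
        cols[name] = (x > np.median(x)).astype(float)
    df = pd.DataFrame(cols, index=pd.Index(labels, name="species"))
    if config.missing_rate > 0:
        mask = rng.random(df.shape) < config.missing_rate
        # keep at least 3 observed values per column so every imputer has data
        for j in range(df.shape[1]):
            obs = np.flatnonzero(~mask[:, j])
            if obs.size < 3:
                mask[: min(3, S), j] = False
        df = df.mask(mask)
    return TraitTable(df)


def _gp_field(rng, dists: np.ndarray, length_scale: float) -> np.ndarray:
    K = np.exp(-dists / length_scale) + 1e-8 * np.eye(dists.shape[0])
    return np.linalg.cholesky(K) @ rng.standard_normal(dists.shape[0])


def _minmax(x: np.ndarray) -> np.ndarray:
    rng = x.max() - x.min()
    if rng <= 0:
        return np.zeros_like(x)
    return (x - x.min()) / rng


@dataclass
class Landscape:
    """Per-unit layers on a planar planning grid."""

    grid: PlanningGrid
    env: pd.DataFrame  # 3 z-scored model covariates
    env_candidates: pd.DataFrame  # 13 candidate variables (z-scored)
    elevation_range: np.ndarray  # (M, 2) min/max metres, min <= max
    cost_components: pd.DataFrame  # 3 columns in [0, 1]
    carbon: np.ndarray  # non-negative
    deforestation_prob: np.ndarray  # in [0, 1]

    def __post_init__(self):
        M = self.grid.n_units
        for name, layer in [
            ("env", self.env),
            ("env_candidates", self.env_candidates),
            ("cost_components", self.cost_components),
        ]:
            if len(layer) != M:
                raise ValueError(f"layer {name} has wrong length")
        if self.elevation_range.shape != (M, 2):
            raise ValueError("elevation_range must be (M, 2)")
        if (self.elevation_range[:, 0] > self.elevation_range[:, 1]).any():
            raise ValueError("elevation min > max")
        cc = self.cost_components.to_numpy()
        if cc.min() < 0 or cc.max() > 1:
            raise ValueError("cost components must lie in [0, 1]")


def gen_landscape(config: SimConfig) -> Landscape:
    """Spatially autocorrelated environmental, cost, carbon and deforestation
    layers (exponential kernel on unit-centroid distances).

    Elevation is the master gradient, as on a tropical mountain landscape:
    temperature falls with elevation, the three cost components (inverse
    accessibility, human footprint, population density) concentrate in the
    accessible lowlands, and deforestation risk follows the cost gradient,
    while carbon and the remaining environmental variables mix elevation
    with two further latent fields.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    grid = PlanningGrid(config.n_x, config.n_y, side=config.side_km)
    M = grid.n_units
    cents = grid.centroids
    if M > 1:
        dists = squareform(pdist(cents))
    else:
        dists = np.zeros((1, 1))
    extent = max(config.n_x, config.n_y) * config.side_km
    ls = max(0.3 * extent, config.side_km)

    # elevation master field plus two independent latents
    elev_field = _gp_field(rng, dists, ls)
    z_elev = (elev_field - elev_field.mean()) / max(elev_field.std(), 1e-12)
    latents = [-z_elev, _gp_field(rng, dists, ls), _gp_field(rng, dists, ls)]

    # 13 candidate env variables built from the latent fields plus local
    # noise, in blocks so the PCA selection step has structure to find
    blocks = [0, 0, 1, 1, 1, 1, 2, 2, 0, 2, 1, 0, 2]  # latent index per variable
    cand = {}
    for name, b in zip(ENV_CANDIDATE_NAMES, blocks):
        x = latents[b] + 0.4 * _gp_field(rng, dists, ls / 2) + 0.2 * rng.standard_normal(M)
        if name == "elevation":
            x = z_elev.copy()
        sd = x.std(ddof=0)
        cand[name] = (x - x.mean()) / (sd if sd > 0 else 1.0)
    env_candidates = pd.DataFrame(cand)
    env = env_candidates[list(ENV_NAMES)].copy()

    base_elev = 1500.0 * _minmax(elev_field)
    half_width = 100.0 + 200.0 * rng.random(M)
    elev_range = np.column_stack(
        [np.clip(base_elev - half_width, 0.0, None), base_elev + half_width]
    )

    # land is costly near accessible lowland population hubs; accessibility,
    # footprint and population density are strongly right-skewed once scaled
    # to 0-1 (a few peri-urban cells dominate), hence the exponential link
    cost = pd.DataFrame(
        {
            name: _minmax(
                np.exp(1.2 * (-0.85 * z_elev + 0.25 * _gp_field(rng, dists, ls)))
            )
            for name in ("accessibility_inverse", "footprint", "population_density")
        }
    )
    carbon = 100.0 * np.exp(0.5 * _gp_field(rng, dists, ls))
    defor = 1.0 / (1.0 + np.exp(-(0.8 * -z_elev + 0.6 * _gp_field(rng, dists, ls))))
    return Landscape(
        grid=grid,
        env=env,
        env_candidates=env_candidates,
        elevation_range=elev_range,
        cost_components=cost,
        carbon=carbon,
        deforestation_prob=defor,
    )


@dataclass
class SimulatedOccurrences:
    """True presences, point records and the generating parameters."""

    presence: np.ndarray  # (S, M) 0/1
    records: pd.DataFrame  # species, x_km, y_km, elevation_m
    species: list[str]
    truth: dict
    eta: np.ndarray  # latent linear predictor, (S, M)


def spatial_covariance_matrix(grid: PlanningGrid) -> np.ndarray:
    """exp(-d / d_max) between unit centroids (unit diagonal)."""
    from .jsdm import spatial_covariance

    return spatial_covariance(grid)


def gen_occurrences(
    tree: dendropy.Tree,
    traits_table: TraitTable,
    landscape: Landscape,
    config: SimConfig,
) -> SimulatedOccurrences:
    """Presences from the generative linear-probability co-occurrence model.

    The linear predictor per species s and unit m is::

        eta = intercept + env @ env_effects
              + sum_t [beta_t x_ts + sum_e theta_te x_ts env_me]
              + a_s + b_s + c_m + d_m + eps

    with a ~ N(0, sa2 I), b ~ N(0, sb2 Sigma_spp), c ~ N(0, sc2 I),
    d ~ N(0, sd2 Sigma_m), eps ~ N(0, se2).  Presence is Bernoulli of eta
    clipped to [0, 1], so a Gaussian linear-probability fit is correctly
    specified up to clipping.  One point record is placed uniformly inside
    each presence unit, with elevation uniform within the unit's range.
    """
    if not traits_table.complete:
        raise ValueError("traits must be complete (imputed) before simulation")
    sa2, sb2, sc2, sd2, se2 = config.variance_components
    if min(config.variance_components) < 0:
        raise ValueError("variance components must be non-negative")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    L, labels = _bm_cholesky(tree)
    if list(traits_table.species) != labels:
        # align trait rows to tree tip order
        traits_table = TraitTable(
            traits_table.data.loc[labels],
            traits_table.continuous, traits_table.habit, traits_table.color,
        )
    S = len(labels)
    grid = landscape.grid
    M = grid.n_units
    env = landscape.env.to_numpy(float)  # (M, 3)

    eta = np.full((S, M), config.intercept, dtype=float)
    eta += (env @ np.asarray(config.env_effects))[None, :]
    for trait, eff in config.trait_effect_sizes.items():
        x = traits_table.data[trait].to_numpy(float)
        eta += eff.main * x[:, None]
        theta = np.asarray(eff.interactions)
        eta += x[:, None] * (env @ theta)[None, :]

    a = np.sqrt(sa2) * rng.standard_normal(S)
    b = np.sqrt(sb2) * (L @ rng.standard_normal(S))
    Sm = spatial_covariance_matrix(grid)
    Lm = np.linalg.cholesky(Sm + 1e-9 * np.eye(M))
    c = np.sqrt(sc2) * rng.standard_normal(M)
    d = np.sqrt(sd2) * (Lm @ rng.standard_normal(M))
    eps = np.sqrt(se2) * rng.standard_normal((S, M))
    eta += a[:, None] + b[:, None] + c[None, :] + d[None, :] + eps

    p = np.clip(eta, 0.0, 1.0)
    Y = (rng.random((S, M)) < p).astype(np.int8)

    recs = []
    cents = grid.centroids
    half = grid.side / 2.0
    for s in range(S):
        for m in np.flatnonzero(Y[s]):
            x = cents[m, 0] + (rng.random() - 0.5) * 2 * half
            y = cents[m, 1] + (rng.random() - 0.5) * 2 * half
            lo, hi = landscape.elevation_range[m]
            recs.append(
                {
                    "species": labels[s],
                    "x_km": x,
                    "y_km": y,
                    "elevation_m": lo + rng.random() * (hi - lo),
                }
            )
    records = pd.DataFrame(recs, columns=["species", "x_km", "y_km", "elevation_m"])
    truth = {
        "intercept": config.intercept,
        "env_effects": list(config.env_effects),
        "trait_effects": {
            k: {"main": v.main, "interactions": list(v.interactions)}
            for k, v in config.trait_effect_sizes.items()
        },
        "variance_components": list(config.variance_components),
        "random_effects": {
            "a": a.tolist(), "b": b.tolist(), "c": c.tolist(), "d": d.tolist(),
        },
        "seed": config.seed,
    }
    return SimulatedOccurrences(
        presence=Y, records=records, species=labels, truth=truth, eta=eta
    )


def write_truth(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)


def read_truth(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


# ---------------------------------------------------------------------------
# fixture backbone for the grafting rules
# ---------------------------------------------------------------------------

_BACKBONE_NEWICK = (
    "(((Delta_a:3,Delta_b:3):3,Epsilon_a:6):4,"
    "(((Alpha_a:2,Alpha_b:2,Alpha_c:2):3,Beta_a:5):3,"
    "(Gamma_a:1,Gamma_b:1):7):2);"
)


def fixture_backbone(seed: int = 0) -> tuple[dendropy.Tree, pd.DataFrame]:
    """Hand-built genus/family-labelled backbone plus a species manifest.

    The manifest covers every grafting rule: a species of an existing
    multi-tip genus (polytomy at the genus crown), a species of a
    single-tip genus, species of genera absent from two families where the
    midpoint rule applies, a species of a genus absent from a family whose
    long stem triggers the two-thirds rule, and a species whose genus and
    family are both unknown (unresolved).  The tree is ultrametric with
    total depth 10; family F3 has root (stem) age 10 and basal (crown)
    age 6, so the midpoint attachment age is 8.  Deterministic for every
    seed (the seed is recorded in the manifest only).
    """
    tree = read_newick_string(_BACKBONE_NEWICK)
    rows = [
        # backbone taxonomy (genus -> family map)
        ("Alpha_a", "Alpha", "F1", "backbone"),
        ("Alpha_b", "Alpha", "F1", "backbone"),
        ("Alpha_c", "Alpha", "F1", "backbone"),
        ("Beta_a", "Beta", "F1", "backbone"),
        ("Gamma_a", "Gamma", "F2", "backbone"),
        ("Gamma_b", "Gamma", "F2", "backbone"),
        ("Delta_a", "Delta", "F3", "backbone"),
        ("Delta_b", "Delta", "F3", "backbone"),
        ("Epsilon_a", "Epsilon", "F3", "backbone"),
        # species to graft
        ("Alpha_nova", "Alpha", "F1", "genus_polytomy"),
        ("Beta_nova", "Beta", "F1", "single_tip_genus"),
        ("Theta_nova", "Theta", "F1", "family_midpoint"),
        ("Zeta_nova", "Zeta", "F3", "family_midpoint"),
        ("Eta_nova", "Eta", "F2", "family_two_thirds"),
        ("Mystery_sp", "Mystery", "FX", "unresolved"),
    ]
    manifest = pd.DataFrame(rows, columns=["species", "genus", "family", "case"])
    manifest["seed"] = seed
    return tree, manifest
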