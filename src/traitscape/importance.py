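"""Irreplaceability-style importance values and trait-impact classification.

Importance of a planning unit for one conservation feature is computed over
an ensemble of near-optimal selection scenarios (randomized greedy with
seeded cost jitter):

    importance = (included - removed) / (included + excluded)

where *included* counts target-achieving scenarios containing the unit,
*removed* counts those that would no longer achieve the target if the
unit's feature amount were subtracted, and *excluded* counts achieving
scenarios without the unit.  The score lies in [0, 1]; raw counts are kept
so the degenerate case (a unit essential to every achieving scenario scores
0 by the formula) can be audited.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .prioritization import Problem, solve_greedy


@dataclass
class ScenarioEnsemble:
    feature: str
    target: float
    selections: np.ndarray  # (K, M) bool
    attainment: np.ndarray  # (K,)
    achieved: np.ndarray  # (K,) bool
    seeds: list[int] = field(default_factory=list)

    @property
    def K(self) -> int:
        return self.selections.shape[0]


def scenario_ensemble(
    problem: Problem,
    feature: str,
    K: int = 100,
    seed: int = 0,
    cost_jitter_sd: float = 0.3,
) -> ScenarioEnsemble:
    """K randomized-greedy scenarios targeting a single feature."""
    single = problem.with_features([feature])
    target = single.targets[feature]
    sub_seeds = [int(s % (2**31 - 1)) for s in np.random.SeedSequence(seed).generate_state(K)]
    sels, att = [], []
    for s in sub_seeds:
        sol = solve_greedy(single, seed=s, cost_jitter_sd=cost_jitter_sd)
        sels.append(sol.selected)
        att.append(sol.attainment[feature])
    sels = np.asarray(sels, bool)
    att = np.asarray(att, float)
    return ScenarioEnsemble(
        feature=feature,
        target=target,
        selections=sels,
        attainment=att,
        achieved=att >= target - 1e-9,
        seeds=sub_seeds,
    )


@dataclass
class ImportanceScores:
    feature: str
    scores: np.ndarray
    included: np.ndarray
    removed: np.ndarray
    excluded: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "importance": self.scores,
                "included": self.included,
                "removed": self.removed,
                "excluded": self.excluded,
            }
        ).rename_axis("unit_id")


def importance_scores(
    ensemble: ScenarioEnsemble, feature_amounts: np.ndarray
) -> ImportanceScores:
    """Per-unit importance from an ensemble of achieving scenarios.

    ``removed`` is evaluated by subtracting the unit's feature amount from
    the scenario's attainment, without re-solving.
    """
    a = np.asarray(feature_amounts, float)
    M = ensemble.selections.shape[1]
    ach = ensemble.achieved
    sel_ach = ensemble.selections[ach]  # (Ka, M)
    att_ach = ensemble.attainment[ach]
    included = sel_ach.sum(axis=0).astype(int)
    fails = (att_ach[:, None] - a[None, :] < ensemble.target - 1e-9) & sel_ach
    removed = fails.sum(axis=0).astype(int)
    excluded = (int(ach.sum()) - included).astype(int)
    denom = included + excluded
    with np.errstate(invalid="ignore", divide="ignore"):
        scores = np.where(denom > 0, (included - removed) / np.maximum(denom, 1), 0.0)
    scores = np.clip(scores, 0.0, 1.0)
    return ImportanceScores(
        feature=ensemble.feature,
        scores=scores,
        included=included,
        removed=removed,
        excluded=excluded,
    )


@dataclass
class TraitImpact:
    delta_alpha: np.ndarray
    delta_beta: np.ndarray
    classes: np.ndarray  # 'trait_priority' | 'species_priority' | 'neutral'

    def counts(self) -> dict:
        vals, cnt = np.unique(self.classes, return_counts=True)
        out = {"trait_priority": 0, "species_priority": 0, "neutral": 0}
        out.update(dict(zip(vals.tolist(), cnt.tolist())))
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "delta_alpha": self.delta_alpha,
                "delta_beta": self.delta_beta,
                "class": self.classes,
            }
        ).rename_axis("unit_id")


def trait_impact(
    imp_trait_alpha: np.ndarray,
    imp_species_alpha: np.ndarray,
    imp_trait_beta: np.ndarray,
    imp_species_beta: np.ndarray,
) -> TraitImpact:
    """Trait-impact scores and the priority classification.

    delta_alpha/delta_beta are trait-minus-species importance differences.
    A unit is *trait priority* when either delta is > 0, *species priority*
    when both are < 0, and *neutral* otherwise (both zero, or one zero and
    the other negative).
    """
    da = np.asarray(imp_trait_alpha, float) - np.asarray(imp_species_alpha, float)
    db = np.asarray(imp_trait_beta, float) - np.asarray(imp_species_beta, float)
    classes = np.full(da.shape, "neutral", dtype=object)
    classes[(da > 0) | (db > 0)] = "trait_priority"
    classes[(da < 0) & (db < 0)] = "species_priority"
    return TraitImpact(delta_alpha=da, delta_beta=db, classes=classes)


def compare_feature_importance(
    impact: TraitImpact,
    imp_carbon: np.ndarray,
    imp_deforestation: np.ndarray,
    n_boot: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean/SD of carbon and deforestation importance per priority class.

    The trait-minus-species difference of class means gets a seeded
    bootstrap percentile interval (``n_boot`` resamples).  Empty classes
    yield NA rows.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for name, vec in [("carbon", imp_carbon), ("deforestation", imp_deforestation)]:
        vec = np.asarray(vec, float)
        stats = {}
        for cls in ("trait_priority", "species_priority"):
            sel = vec[impact.classes == cls]
            stats[cls] = sel
            rows.append(
                {
                    "feature": name,
                    "class": cls,
                    "n": len(sel),
                    "mean": float(sel.mean()) if len(sel) else np.nan,
                    "sd": float(sel.std(ddof=1)) if len(sel) > 1 else np.nan,
                }
            )
        tp, sp = stats["trait_priority"], stats["species_priority"]
        if len(tp) and len(sp):
            diff = tp.mean() - sp.mean()
            boots = np.empty(n_boot)
            for b in range(n_boot):
                boots[b] = (
                    tp[rng.integers(len(tp), size=len(tp))].mean()
                    - sp[rng.integers(len(sp), size=len(sp))].mean()
                )
            lo, hi = np.percentile(boots, [2.5, 97.5])
        else:
            diff, lo, hi = np.nan, np.nan, np.nan
        rows.append(
            {
                "feature": name,
                "class": "difference (trait - species)",
                "n": int(len(tp) + len(sp)),
                "mean": float(diff),
                "sd": np.nan,
                "ci_lower": float(lo),
                "ci_upper": float(hi),
            }
        )
    return pd.DataFrame(rows)
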