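"""Balanced fold construction and the six training/test scenario designs.

Scenarios (numbering follows the gene-bank genomic-prediction workflow this
package implements):

1. k-fold cross-validation *within* each subpopulation.
2. Pooled k-fold cross-validation over all subpopulations, with the
   subpopulation either ignored, entered as a fixed covariate, or replaced
   by externally estimated ancestry coefficients as fixed covariates.
3. Prediction *across* subpopulations: each group trains a model that is
   evaluated on every other group (diagonal filled from scenario 1).
4. Training on a predefined core collection, testing on the remainder.
5. Training on all phenotyped accessions to predict the unphenotyped ones,
   reported through BLUP reliabilities rather than a hold-out correlation.
6. Cross-growth-habit prediction (e.g. spring -> winter and vice versa),
   with within-group cross-validation abilities as the reference point.

Prediction ability is the Pearson correlation of predicted and observed
values in the test set.  Reported dispersions are sample standard
deviations across folds (scenarios 1-2) or across repeated random
subsamplings of the training group (scenario 3).  A leakage guard asserts
that no accession ever sits in both the training and the test side of the
same evaluation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import Kinship
from .gblup import (
    GBLUPFit,
    ModelSpec,
    VarianceComponents,
    estimate_variance_components,
    fit_gblup,
    predict_ability,
)

__all__ = [
    "FoldPlan",
    "ScenarioResult",
    "balanced_kfold",
    "run_scenario_within",
    "run_scenario_pooled",
    "run_scenario_across",
    "run_scenario_core",
    "run_scenario_predict_all",
    "run_scenario_cross_habit",
]

logger = logging.getLogger(__name__)

DEFAULT_MIN_SUBPOP = 10


@dataclass
class FoldPlan:
    """Disjoint folds covering the population, stratified and seeded."""

    folds: list[list[str]]
    strata: pd.Series | None
    seed: int

    @property
    def k(self) -> int:
        return len(self.folds)


@dataclass
class ScenarioResult:
    """Per-scenario evaluation summary."""

    scenario: int
    trait: str
    description: str
    table: pd.DataFrame
    overall: tuple[float, float] | None = None  # (mean ability, sd)
    per_subpop: dict = field(default_factory=dict)  # name -> (mean, sd)
    extras: dict = field(default_factory=dict)


def balanced_kfold(ids, strata, k: int, seed: int) -> FoldPlan:
    """Random balanced k-fold partition.

    Within every stratum the members are spread over the folds so that each
    fold's count differs from the others by at most one; fold totals are
    balanced by rotating the starting fold between strata.  Reproducible
    under the seed.
    """
    ids = [str(i) for i in ids]
    if k < 2:
        raise ValueError("k must be at least 2")
    if strata is None:
        strata = pd.Series("all", index=ids)
    else:
        strata = pd.Series(strata)
        strata.index = strata.index.astype(str)
        strata = strata.loc[ids]
    rng = np.random.default_rng(seed)
    folds: list[list[str]] = [[] for _ in range(k)]
    offset = 0
    for stratum in sorted(strata.unique().astype(str)):
        members = [i for i in ids if str(strata.loc[i]) == stratum]
        if len(members) < k:
            warnings.warn(
                f"stratum {stratum!r} has fewer members ({len(members)}) than folds ({k})",
                RuntimeWarning,
            )
        members = list(rng.permutation(members))
        for j, acc in enumerate(members):
            folds[(j + offset) % k].append(acc)
        offset = (offset + len(members)) % k
    return FoldPlan(folds=folds, strata=strata, seed=seed)


def _check_no_leakage(train_ids, test_ids):
    train, test = set(train_ids), set(test_ids)
    if not train or not test:
        raise ValueError("training and test sets must both be non-empty")
    if train & test:
        raise ValueError(
            f"accessions appear in both training and test: {sorted(train & test)[:5]}"
        )


def _subset_covariates(covariates, ids):
    if covariates is None:
        return None
    cov = covariates.copy()
    cov.index = cov.index.astype(str)
    return cov.loc[[str(i) for i in ids]]


def _predicted_for(fit: GBLUPFit, ids, covariates) -> pd.Series:
    pred = fit.g_hat.loc[ids].astype(float).copy()
    for name, b in fit.beta_hat.items():
        if name == "intercept":
            pred += b
        else:
            pred += b * covariates.loc[ids, name].to_numpy(dtype=float)
    return pred


def _evaluate_split(
    response: pd.Series,
    kinship: Kinship,
    train_ids,
    test_ids,
    covariates=None,
    vc: VarianceComponents | None = None,
    allow_undefined_ability: bool = False,
) -> tuple[float, pd.Series]:
    """Fit on the training accessions, return (ability, predictions) on test."""
    _check_no_leakage(train_ids, test_ids)
    sub_ids = list(train_ids) + list(test_ids)
    spec = ModelSpec(
        response=response.loc[list(train_ids)],
        kinship=kinship.submatrix(sub_ids),
        covariates=_subset_covariates(covariates, sub_ids),
    )
    fit = fit_gblup(spec, vc=vc, compute_reliability=False)
    cov = _subset_covariates(covariates, test_ids)
    pred = _predicted_for(fit, list(test_ids), cov)
    obs = response.loc[list(test_ids)]
    try:
        ability = predict_ability(pred.to_numpy(), obs.to_numpy())
    except ValueError:
        if not allow_undefined_ability:
            raise
        warnings.warn(
            "prediction ability undefined (constant or too-short vector); "
            "reporting NaN",
            RuntimeWarning,
        )
        ability = float("nan")
    return ability, pred


def _mean_sd(values) -> tuple[float, float]:
    arr = np.asarray([v for v in values if np.isfinite(v)], dtype=float)
    if arr.size == 0:
        return float("nan"), float("nan")
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return float(arr.mean()), sd


def _phenotyped(blues: pd.Series, kinship: Kinship) -> list[str]:
    obs = set(pd.Series(blues).dropna().index.astype(str))
    return [a for a in kinship.accession_ids if a in obs]


def _as_series(blues) -> pd.Series:
    if isinstance(blues, pd.DataFrame):
        blues = blues["blue"]
    s = pd.Series(blues, dtype=float)
    s.index = s.index.astype(str)
    return s


def run_scenario_within(
    blues,
    kinship: Kinship,
    subpop_labels: pd.Series,
    trait: str,
    k: int = 5,
    reps: int = 1,
    seed: int = 0,
    min_subpop: int = DEFAULT_MIN_SUBPOP,
) -> ScenarioResult:
    """Scenario 1: independent k-fold cross-validation inside each
    subpopulation; mean (SD) ability per subpopulation across folds."""
    y = _as_series(blues)
    labels = pd.Series(subpop_labels)
    labels.index = labels.index.astype(str)
    rows = []
    per_subpop = {}
    for subpop in sorted(labels.dropna().unique().astype(str)):
        members = [a for a in _phenotyped(y, kinship) if labels.get(a) == subpop]
        if len(members) < max(min_subpop, k):
            logger.info("excluding subpopulation %s (n=%d below threshold)", subpop, len(members))
            continue
        abilities = []
        for rep in range(reps):
            plan = balanced_kfold(members, None, k, seed + 1000 * rep)
            for fold in plan.folds:
                train = [a for a in members if a not in set(fold)]
                ability, _ = _evaluate_split(y, kinship, train, fold)
                abilities.append(ability)
                rows.append((subpop, subpop, ability, len(train), len(fold)))
        per_subpop[subpop] = _mean_sd(abilities)
    if not per_subpop:
        raise ValueError("no subpopulation meets the minimum-size threshold")
    table = pd.DataFrame(rows, columns=["train", "test", "ability", "n_train", "n_test"])
    return ScenarioResult(
        scenario=1,
        trait=trait,
        description=f"{k}-fold CV within each subpopulation",
        table=table,
        overall=_mean_sd(table["ability"]),
        per_subpop=per_subpop,
    )


def _pooled_covariates(covariate_mode, subpop_labels, ancestry, ids):
    if covariate_mode == "ignored":
        return None
    if covariate_mode == "covariate":
        labels = pd.Series(subpop_labels)
        labels.index = labels.index.astype(str)
        dummies = pd.get_dummies(labels.loc[ids], drop_first=True, dtype=float)
        return dummies
    if covariate_mode == "ancestry":
        if ancestry is None:
            raise ValueError("covariate_mode='ancestry' requires an ancestry matrix")
        anc = ancestry.copy()
        anc.index = anc.index.astype(str)
        missing = set(ids) - set(anc.index)
        if missing:
            raise ValueError(f"ancestry matrix missing accessions: {sorted(missing)[:5]}")
        return anc.loc[ids]
    raise ValueError(f"unknown covariate_mode {covariate_mode!r}")


def run_scenario_pooled(
    blues,
    kinship: Kinship,
    subpop_labels: pd.Series,
    trait: str,
    covariate_mode: str = "ignored",
    ancestry: pd.DataFrame | None = None,
    k: int = 5,
    seed: int = 0,
    min_subpop: int = DEFAULT_MIN_SUBPOP,
) -> ScenarioResult:
    """Scenario 2: pooled k-fold CV over all subpopulations.

    Besides the overall ability, the ability within each subpopulation's
    test members is reported per fold, so structure-driven inflation of the
    pooled correlation is visible.
    """
    y = _as_series(blues)
    labels = pd.Series(subpop_labels)
    labels.index = labels.index.astype(str)
    members = [a for a in _phenotyped(y, kinship) if pd.notna(labels.get(a))]
    counts = labels.loc[members].value_counts()
    keep_pops = sorted(counts[counts >= min_subpop].index.astype(str))
    members = [a for a in members if str(labels.loc[a]) in keep_pops]
    covariates = _pooled_covariates(covariate_mode, subpop_labels, ancestry, members)
    plan = balanced_kfold(members, labels.loc[members], k, seed)
    rows = []
    overall = []
    per_pop_abilities: dict[str, list[float]] = {p: [] for p in keep_pops}
    for fold in plan.folds:
        train = [a for a in members if a not in set(fold)]
        ability, pred = _evaluate_split(y, kinship, train, fold, covariates=covariates)
        overall.append(ability)
        rows.append(("pooled", "pooled", ability, len(train), len(fold)))
        for pop in keep_pops:
            sub = [a for a in fold if str(labels.loc[a]) == pop]
            if len(sub) >= 3 and y.loc[sub].std() > 0 and pred.loc[sub].std() > 0:
                a_pop = predict_ability(pred.loc[sub].to_numpy(), y.loc[sub].to_numpy())
                per_pop_abilities[pop].append(a_pop)
                rows.append(("pooled", pop, a_pop, len(train), len(sub)))
    table = pd.DataFrame(rows, columns=["train", "test", "ability", "n_train", "n_test"])
    return ScenarioResult(
        scenario=2,
        trait=trait,
        description=f"pooled {k}-fold CV, subpopulation {covariate_mode}",
        table=table,
        overall=_mean_sd(overall),
        per_subpop={p: _mean_sd(v) for p, v in per_pop_abilities.items() if v},
        extras={"covariate_mode": covariate_mode},
    )


def run_scenario_across(
    blues,
    kinship: Kinship,
    subpop_labels: pd.Series,
    trait: str,
    reps: int = 10,
    subsample: float = 0.8,
    seed: int = 0,
    min_subpop: int = DEFAULT_MIN_SUBPOP,
) -> ScenarioResult:
    """Scenario 3: every subpopulation trains a model evaluated on each of
    the other subpopulations.

    The across-group evaluation itself is deterministic; dispersion comes
    from `reps` repeated random ``subsample`` fractions of the training
    group.  The diagonal (within-group) entries are filled from scenario 1.
    """
    y = _as_series(blues)
    labels = pd.Series(subpop_labels)
    labels.index = labels.index.astype(str)
    phen = _phenotyped(y, kinship)
    groups = {}
    for pop in sorted(labels.dropna().unique().astype(str)):
        ids = [a for a in phen if str(labels.get(a)) == pop]
        if len(ids) >= min_subpop:
            groups[pop] = ids
    if len(groups) < 2:
        raise ValueError("need at least 2 subpopulations above the size threshold")
    rng = np.random.default_rng(seed)
    rows = []
    matrix = {}
    for train_pop, train_all in groups.items():
        for test_pop, test_ids in groups.items():
            if train_pop == test_pop:
                continue
            abilities = []
            for _ in range(reps):
                n_sub = max(2, int(round(subsample * len(train_all))))
                train = list(rng.choice(train_all, size=n_sub, replace=False))
                ability, _ = _evaluate_split(y, kinship, train, test_ids)
                abilities.append(ability)
            m, s = _mean_sd(abilities)
            matrix[(train_pop, test_pop)] = (m, s)
            rows.append((train_pop, test_pop, m, s, len(train_all), len(test_ids)))
    within = run_scenario_within(
        blues, kinship, subpop_labels, trait, seed=seed, min_subpop=min_subpop
    )
    for pop, (m, s) in within.per_subpop.items():
        matrix[(pop, pop)] = (m, s)
        rows.append((pop, pop, m, s, len(groups[pop]), len(groups[pop])))
    table = pd.DataFrame(
        rows, columns=["train", "test", "ability", "sd", "n_train", "n_test"]
    )
    off_diag = [m for (a, b), (m, _) in matrix.items() if a != b]
    return ScenarioResult(
        scenario=3,
        trait=trait,
        description="across-subpopulation prediction (diagonal from scenario 1)",
        table=table,
        overall=_mean_sd(off_diag),
        per_subpop={p: matrix[(p, p)] for p in groups if (p, p) in matrix},
        extras={"matrix": matrix},
    )


def run_scenario_core(
    blues,
    kinship: Kinship,
    core_ids,
    trait: str,
    subpop_labels: pd.Series | None = None,
    vc: VarianceComponents | None = None,
) -> ScenarioResult:
    """Scenario 4: train on the phenotyped members of a predefined core
    collection, test on all remaining phenotyped accessions."""
    y = _as_series(blues)
    phen = _phenotyped(y, kinship)
    core = {str(c) for c in core_ids}
    unknown = core - set(kinship.accession_ids)
    if unknown:
        raise ValueError(f"core ids absent from kinship: {sorted(unknown)[:5]}")
    train = [a for a in phen if a in core]
    test = [a for a in phen if a not in core]
    if not train:
        raise ValueError("no phenotyped core member to train on")
    if not test:
        raise ValueError("core covers every phenotyped accession; no test set remains")
    low_confidence = len(train) < 10
    if vc is None and low_confidence:
        warnings.warn(
            "fewer than 10 phenotyped core members; variance components "
            "estimated from all phenotyped accessions",
            RuntimeWarning,
        )
        vc = estimate_variance_components(
            ModelSpec(response=y.loc[phen], kinship=kinship.submatrix(phen))
        )
    ability, pred = _evaluate_split(
        y, kinship, train, test, vc=vc, allow_undefined_ability=low_confidence
    )
    rows = [("core", "rest", ability, len(train), len(test))]
    per_subpop = {}
    if subpop_labels is not None:
        labels = pd.Series(subpop_labels)
        labels.index = labels.index.astype(str)
        for pop in sorted(labels.dropna().unique().astype(str)):
            sub = [a for a in test if str(labels.get(a)) == pop]
            if len(sub) >= 3 and y.loc[sub].std() > 0 and pred.loc[sub].std() > 0:
                a_pop = predict_ability(pred.loc[sub].to_numpy(), y.loc[sub].to_numpy())
                per_subpop[pop] = (a_pop, 0.0)
                rows.append(("core", pop, a_pop, len(train), len(sub)))
    table = pd.DataFrame(rows, columns=["train", "test", "ability", "n_train", "n_test"])
    return ScenarioResult(
        scenario=4,
        trait=trait,
        description="core-collection training, remainder testing",
        table=table,
        overall=(ability, 0.0),
        per_subpop=per_subpop,
        extras={"low_confidence": low_confidence},
    )


def run_scenario_predict_all(
    blues,
    kinship: Kinship,
    trait: str,
    covariates: pd.DataFrame | None = None,
    reliability_threshold: float = 0.6,
) -> ScenarioResult:
    """Scenario 5: fit on all phenotyped accessions, emit genetic-value
    predictions and reliabilities for everyone.

    Reports reliability distribution summaries separately for phenotyped and
    unphenotyped accessions, and the fraction of unphenotyped accessions
    whose reliability exceeds the threshold (0.6 by default)."""
    y = _as_series(blues)
    phen = _phenotyped(y, kinship)
    unphen = [a for a in kinship.accession_ids if a not in set(phen)]
    if not unphen:
        raise ValueError("no unphenotyped accession to predict")
    spec = ModelSpec(
        response=y.loc[phen], kinship=kinship, covariates=covariates
    )
    fit = fit_gblup(spec, compute_reliability=True)
    rel = fit.reliability
    summarize = lambda ids: {
        "n": len(ids),
        "mean": float(rel.loc[ids].mean()),
        "median": float(rel.loc[ids].median()),
        "q25": float(rel.loc[ids].quantile(0.25)),
        "q75": float(rel.loc[ids].quantile(0.75)),
    }
    frac_high = float((rel.loc[unphen] > reliability_threshold).mean())
    table = pd.DataFrame(
        {
            "g_hat": fit.g_hat,
            "reliability": rel,
            "phenotyped": [a in set(phen) for a in kinship.accession_ids],
        }
    )
    return ScenarioResult(
        scenario=5,
        trait=trait,
        description="all phenotyped accessions predict the remainder",
        table=table.reset_index(names="accession"),
        overall=None,
        extras={
            "fit": fit,
            "reliability_phenotyped": summarize(phen),
            "reliability_unphenotyped": summarize(unphen),
            "fraction_unphenotyped_above_threshold": frac_high,
            "reliability_threshold": reliability_threshold,
        },
    )


def run_scenario_cross_habit(
    blues_spring,
    blues_winter,
    kinship: Kinship,
    habit_labels: pd.Series,
    trait: str,
    comparable: bool = True,
    k: int = 5,
    seed: int = 0,
) -> ScenarioResult:
    """Scenario 6: spring accessions predict winter ones and vice versa.

    Refuses traits flagged incomparable across the two growth habits (the
    flowering-time case, where the reference date differs between spring and
    winter material).  Within-group k-fold CV abilities are included for
    reference."""
    if not comparable:
        raise ValueError(
            f"trait {trait!r} is flagged incomparable between growth habits "
            "(e.g. different reference dates); cross-habit prediction refused"
        )
    labels = pd.Series(habit_labels)
    labels.index = labels.index.astype(str)
    ys = _as_series(blues_spring)
    yw = _as_series(blues_winter)
    spring = [a for a in _phenotyped(ys, kinship) if labels.get(a) == "spring"]
    winter = [a for a in _phenotyped(yw, kinship) if labels.get(a) == "winter"]
    if not spring or not winter:
        raise ValueError("both growth-habit groups must have phenotyped members")
    combined = pd.concat([ys.loc[spring], yw.loc[winter]])
    rows = []
    per = {}
    for train, test, tr_name, te_name in (
        (spring, winter, "spring", "winter"),
        (winter, spring, "winter", "spring"),
    ):
        ability, _ = _evaluate_split(combined, kinship, train, test)
        rows.append((tr_name, te_name, ability, len(train), len(test)))
        per[f"{tr_name}->{te_name}"] = (ability, 0.0)
    for name, group, y in (("spring", spring, ys), ("winter", winter, yw)):
        if len(group) >= max(DEFAULT_MIN_SUBPOP, k):
            plan = balanced_kfold(group, None, k, seed)
            abilities = []
            for fold in plan.folds:
                train = [a for a in group if a not in set(fold)]
                ability, _ = _evaluate_split(y, kinship, train, fold)
                abilities.append(ability)
            m, s = _mean_sd(abilities)
            per[f"{name}->{name}"] = (m, s)
            rows.append((name, name, m, len(group), len(group)))
    table = pd.DataFrame(rows, columns=["train", "test", "ability", "n_train", "n_test"])
    return ScenarioResult(
        scenario=6,
        trait=trait,
        description="cross-growth-habit prediction with within-group CV reference",
        table=table,
        overall=_mean_sd(
            [per["spring->winter"][0], per["winter->spring"][0]]
        ),
        per_subpop=per,
    )
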