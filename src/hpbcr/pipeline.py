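"""End-to-end orchestration of the hybrid recurrence predictor.

The full pipeline, on the training split only: univariate statistical
feature selection -> cut-point discretization of the selected interval
features with clinical thresholds (age 40, nodal ratio 0.25, tumor size
2/5 cm) -> PSO over the categorical inclusion mask and interval weights
-> final bagged decision tree under the best transform -> evaluation on
the held-out split (and optionally stratified k-fold cross-validation,
re-running the whole pipeline inside each fold).

Also here: ablation scenarios (dropping PSO; swapping the bagged tree
for an RBF-SVM or a 10-unit sigmoid MLP inside the PSO loop), plain
comparator classifiers on the filter-selected features, the Nottingham
Prognostic Index baseline, and pairwise McNemar comparisons.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import (GridSearchCV, StratifiedKFold,
                                     train_test_split)
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from . import diagnostics
from .cohort import CohortTable, discretize
from .diagnostics import MetricReport, confusion, mcnemar, metrics
from .ensemble_tree import (FeatureTransform, bagged_fit, bagged_predict,
                            encode_cohort, grow_tree, prune_tree, tree_predict)
from .pso import SwarmConfig, decode_particle, optimize, pso_maximize
from .stat_select import SelectionResult, select_features

__all__ = [
    "SplitPlan",
    "NPIInput",
    "RunReport",
    "split",
    "stratified_folds",
    "run_hpbcr",
    "run_scenario",
    "run_comparators",
    "npi_score",
    "compare_all",
    "SCENARIOS",
]

#: interval features replaced by their clinical discretization before PSO
_DISCRETIZED = {"age": "age_cat", "nr": "nr_cat", "ts": "ts_cat"}

SCENARIOS = ("baseline", "no_pso", "svm_pso", "mlp_pso")

#: NPI risk-group boundary; scores at or above are high risk.
NPI_CUT = 3.4


@dataclass
class SplitPlan:
    """Holdout and cross-validation layout."""

    holdout_fraction: float = 0.70   #: training share
    k_folds: int = 4
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.holdout_fraction < 1.0):
            raise ValueError("holdout_fraction must lie in (0, 1)")
        if self.k_folds < 2:
            raise ValueError("need k_folds >= 2")


@dataclass(frozen=True)
class NPIInput:
    tumor_size_cm: float
    histological_grade: int
    positive_nodes: int

    def __post_init__(self) -> None:
        if self.tumor_size_cm <= 0:
            raise ValueError("tumor size must be positive")
        if not (1 <= self.histological_grade <= 4):
            raise ValueError("histological grade must be 1-4")
        if self.positive_nodes < 0:
            raise ValueError("positive node count must be non-negative")


@dataclass
class RunReport:
    """Everything one pipeline run produced, JSON-serializable."""

    scenario: str
    n_train: int
    n_test: int
    selection: SelectionResult | None
    categorical_candidates: list
    interval_candidates: list
    transform: FeatureTransform | None
    holdout: MetricReport
    predictions: list
    y_test: list
    cv_reports: list = field(default_factory=list)
    cv_summary: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=dict)
    config_echo: dict = field(default_factory=dict)
    fitness_history: list = field(default_factory=list)

    def to_json(self, **kwargs) -> str:
        doc = {
            "scenario": self.scenario,
            "n_train": self.n_train,
            "n_test": self.n_test,
            "selected_features": (self.selection.selected_names
                                  if self.selection else None),
            "categorical_candidates": self.categorical_candidates,
            "interval_candidates": self.interval_candidates,
            "transform": self.transform.to_dict() if self.transform else None,
            "holdout": self.holdout.to_dict(),
            "predictions": [int(p) for p in self.predictions],
            "y_test": [int(v) for v in self.y_test],
            "cv_reports": self.cv_reports,
            "cv_summary": self.cv_summary,
            "seeds": self.seeds,
            "config_echo": self.config_echo,
            "fitness_history": [float(v) for v in self.fitness_history],
        }
        return json.dumps(doc, sort_keys=True, default=_json_default, **kwargs)


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, float) and math.isnan(o):
        return None
    raise TypeError(type(o))


def split(cohort: CohortTable, plan: SplitPlan) -> tuple:
    """Seeded (stratified) holdout split into train/test cohorts."""
    idx = np.arange(cohort.n)
    strat = cohort.outcome if plan.stratified else None
    tr, te = train_test_split(idx, train_size=plan.holdout_fraction,
                              random_state=plan.seed, stratify=strat)
    return cohort.subset(np.sort(tr)), cohort.subset(np.sort(te))


def stratified_folds(cohort: CohortTable, plan: SplitPlan) -> list:
    """k disjoint (train_idx, test_idx) pairs partitioning the cohort."""
    if plan.stratified:
        kf = StratifiedKFold(n_splits=plan.k_folds, shuffle=True,
                             random_state=plan.seed)
        return list(kf.split(np.zeros(cohort.n), cohort.outcome))
    from sklearn.model_selection import KFold
    kf = KFold(n_splits=plan.k_folds, shuffle=True, random_state=plan.seed)
    return list(kf.split(np.zeros(cohort.n)))


def pso_candidates(selection: SelectionResult, cohort: CohortTable) -> tuple:
    """Split filter-selected features into PSO candidate lists.

    Selected interval features with a clinical cut point enter as their
    discretized categorical version; other selected interval features
    keep real-valued weights; nominal/ordinal features are mask bits.
    """
    cats, ints = [], []
    for name in selection.selected_names:
        spec = cohort.spec(name)
        if name in _DISCRETIZED:
            cats.append(_DISCRETIZED[name])
        elif spec.is_interval:
            ints.append(name)
        else:
            cats.append(name)
    return cats, ints


def _evaluate(y_true, y_pred) -> MetricReport:
    return metrics(confusion(y_true, y_pred))


def _cv_summary(cv_reports: list) -> dict:
    """Mean/SD/min/max per metric over exactly the k folds.

    A fold that calls no positives has undefined precision; it enters
    the summary as 0 (the zero-division convention) so the spread stays
    computable over all k folds.
    """
    out = {}
    for key in ("se", "sp", "acc", "pr"):
        vals = np.array([r[key] for r in cv_reports], dtype=float)
        vals = np.nan_to_num(vals, nan=0.0)
        out[key] = {"mean": float(vals.mean()), "sd": float(vals.std(ddof=1)),
                    "min": float(vals.min()), "max": float(vals.max())}
    return out


def run_hpbcr(cohort: CohortTable, plan: SplitPlan | None = None,
              swarm_config: SwarmConfig | None = None, alpha: float = 0.05,
              cv: bool = False, cv_reuse_transform: bool = False,
              n_trees: int = 10, fitness_mode: str = "resubstitution") -> RunReport:
    """Full hybrid pipeline with holdout (and optional k-fold) evaluation."""
    plan = plan or SplitPlan()
    swarm_config = swarm_config or SwarmConfig()
    cohort = discretize(cohort)
    train, test = split(cohort, plan)

    base_features = [s.name for s in cohort.schema
                     if s.name not in _DISCRETIZED.values()]
    selection = select_features(train, alpha, features=base_features)
    cats, ints = pso_candidates(selection, cohort)
    if not cats and not ints:
        raise ValueError(
            "statistical filter selected no feature; diagnostic report:\n"
            + selection.to_json(indent=2))

    transform, state = optimize(train, cats, ints, swarm_config,
                                n_trees=n_trees, fitness_mode=fitness_mode)
    enc_train = encode_cohort(train, cats, ints)
    enc_test = encode_cohort(test, cats, ints)
    model = bagged_fit(enc_train, transform, n_trees=n_trees,
                       seed=swarm_config.seed)
    pred = bagged_predict(model, enc_test)
    report = RunReport(
        scenario="baseline", n_train=train.n, n_test=test.n,
        selection=selection, categorical_candidates=cats,
        interval_candidates=ints, transform=transform,
        holdout=_evaluate(test.outcome, pred),
        predictions=pred.tolist(), y_test=test.outcome.tolist(),
        seeds={"split": plan.seed, "swarm": swarm_config.seed},
        fitness_history=list(state.fitness_history),
    )
    report.config_echo = {"n_trees": n_trees, "alpha": alpha,
                          "fitness_mode": fitness_mode}

    if cv:
        for fold_i, (tr_idx, te_idx) in enumerate(stratified_folds(cohort, plan)):
            ftrain, ftest = cohort.subset(tr_idx), cohort.subset(te_idx)
            if cv_reuse_transform:
                fcats, fints, ftransform = cats, ints, transform
            else:
                fsel = select_features(ftrain, alpha, features=base_features)
                fcats, fints = pso_candidates(fsel, cohort)
                fold_cfg = SwarmConfig(**{**swarm_config.__dict__,
                                          "seed": swarm_config.seed + 1 + fold_i})
                ftransform, _ = optimize(ftrain, fcats, fints, fold_cfg,
                                         n_trees=n_trees,
                                         fitness_mode=fitness_mode)
            fenc_tr = encode_cohort(ftrain, fcats, fints)
            fenc_te = encode_cohort(ftest, fcats, fints)
            fmodel = bagged_fit(fenc_tr, ftransform, n_trees=n_trees,
                                seed=swarm_config.seed + 1 + fold_i)
            fpred = bagged_predict(fmodel, fenc_te)
            rep = _evaluate(ftest.outcome, fpred)
            report.cv_reports.append({"fold": fold_i, "se": rep.se, "sp": rep.sp,
                                      "acc": rep.acc, "pr": rep.pr})
        report.cv_summary = _cv_summary(report.cv_reports)
    return report, model


# ---------------------------------------------------------------------------
# Design matrix for margin/gradient comparators
# ---------------------------------------------------------------------------

class _DesignMatrix:
    """One-hot categoricals + z-scored intervals for SVM/MLP.

    Unlike trees these learners are scale sensitive, so here the PSO
    interval weights multiply the standardized feature values, and a
    mask bit zeroes a categorical feature's whole indicator block.
    """

    def __init__(self, train: CohortTable, categorical_names, interval_names):
        self.cat_names = list(categorical_names)
        self.int_names = list(interval_names)
        self.cat_categories = [list(train.spec(n).categories) for n in self.cat_names]
        xi = np.column_stack([train.df[n].to_numpy(dtype=float)
                              for n in self.int_names]) if self.int_names else np.zeros((train.n, 0))
        self.mu = xi.mean(axis=0) if xi.size else np.zeros(0)
        self.sigma = np.where(xi.std(axis=0) > 0, xi.std(axis=0), 1.0) if xi.size else np.zeros(0)

    def encode(self, cohort: CohortTable, transform: FeatureTransform | None = None):
        blocks = []
        for j, name in enumerate(self.cat_names):
            cats = self.cat_categories[j]
            col = cohort.df[name].astype(str)
            onehot = np.column_stack([(col == c).to_numpy(dtype=float) for c in cats])
            if transform is not None and not transform.categorical_mask[j]:
                onehot = onehot * 0.0
            blocks.append(onehot)
        if self.int_names:
            xi = np.column_stack([cohort.df[n].to_numpy(dtype=float)
                                  for n in self.int_names])
            z = (xi - self.mu) / self.sigma
            if transform is not None:
                z = z * transform.interval_weights
            blocks.append(z)
        return np.hstack(blocks) if blocks else np.zeros((cohort.n, 0))


def _svm_grid_search(x, y, seed: int) -> dict:
    """5-fold CV grid for the RBF soft margin, base-2 grid in steps of 2."""
    grid = {"C": [2.0 ** e for e in range(-5, 16, 2)],
            "gamma": [2.0 ** e for e in range(-15, 4, 2)]}
    cv = StratifiedKFold(5, shuffle=True, random_state=seed)
    gs = GridSearchCV(SVC(kernel="rbf"), grid, scoring="f1", cv=cv, n_jobs=1)
    gs.fit(x, y)
    return {"C": float(gs.best_params_["C"]),
            "gamma": float(gs.best_params_["gamma"])}


def _make_svm(params: dict):
    return SVC(kernel="rbf", C=params["C"], gamma=params["gamma"])


def _make_mlp(seed: int):
    return MLPClassifier(hidden_layer_sizes=(10,), activation="logistic",
                         solver="adam", early_stopping=True,
                         validation_fraction=0.1, max_iter=500,
                         random_state=seed)


def run_scenario(cohort: CohortTable, plan: SplitPlan | None = None,
                 scenario: str = "baseline",
                 swarm_config: SwarmConfig | None = None, alpha: float = 0.05,
                 n_trees: int = 10) -> RunReport:
    """Ablation scenarios sharing the baseline's split seed.

    ``no_pso``: filter-selected features straight into the bagged tree.
    ``svm_pso`` / ``mlp_pso``: the PSO loop wraps the alternative
    classifier; interval weights multiply standardized values there.
    """
    if scenario == "baseline":
        report, _ = run_hpbcr(cohort, plan, swarm_config, alpha, n_trees=n_trees)
        return report
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}")
    plan = plan or SplitPlan()
    swarm_config = swarm_config or SwarmConfig()
    cohort = discretize(cohort)
    train, test = split(cohort, plan)
    base_features = [s.name for s in cohort.schema
                     if s.name not in _DISCRETIZED.values()]
    selection = select_features(train, alpha, features=base_features)
    cats, ints = pso_candidates(selection, cohort)
    if not cats and not ints:
        raise ValueError("statistical filter selected no feature")

    if scenario == "no_pso":
        transform = FeatureTransform.full(cats, ints)
        enc_train = encode_cohort(train, cats, ints)
        enc_test = encode_cohort(test, cats, ints)
        model = bagged_fit(enc_train, transform, n_trees=n_trees,
                           seed=swarm_config.seed)
        pred = bagged_predict(model, enc_test)
        report = RunReport(
            scenario=scenario, n_train=train.n, n_test=test.n,
            selection=selection, categorical_candidates=cats,
            interval_candidates=ints, transform=transform,
            holdout=_evaluate(test.outcome, pred),
            predictions=pred.tolist(), y_test=test.outcome.tolist(),
            seeds={"split": plan.seed, "swarm": swarm_config.seed})
        report.config_echo = {"n_trees": n_trees}
        return report

    dm = _DesignMatrix(train, cats, ints)
    x_all = dm.encode(train)
    y_tr = train.outcome
    if scenario == "svm_pso":
        params = _svm_grid_search(x_all, y_tr, swarm_config.seed)
        make = lambda: _make_svm(params)
        echo = {"classifier": "svm", "kernel": "rbf",
                "hyperparameter_search": "5-fold CV grid, C 2^-5..2^15, gamma 2^-15..2^3",
                **params}
    else:
        make = lambda: _make_mlp(swarm_config.seed)
        echo = {"classifier": "mlp", "hidden_layers": 1, "hidden_neurons": 10,
                "activation": "sigmoid", "early_stopping": "10% validation split"}

    def fitness(position):
        transform = decode_particle(position, cats, ints)
        if transform.is_degenerate:
            return 0.0
        x = dm.encode(train, transform)
        clf = make()
        clf.fit(x, y_tr)
        pred = clf.predict(x)
        cm = confusion(y_tr, pred)
        pr = cm.tp / (cm.tp + cm.fp) if (cm.tp + cm.fp) else 0.0
        se = cm.tp / (cm.tp + cm.fn) if (cm.tp + cm.fn) else 0.0
        return diagnostics.f_score(pr, se)

    best_x, state = pso_maximize(fitness, len(cats) + len(ints), swarm_config)
    transform = decode_particle(best_x, cats, ints)
    clf = make()
    clf.fit(dm.encode(train, transform), y_tr)
    pred = clf.predict(dm.encode(test, transform))
    report = RunReport(
        scenario=scenario, n_train=train.n, n_test=test.n,
        selection=selection, categorical_candidates=cats,
        interval_candidates=ints, transform=transform,
        holdout=_evaluate(test.outcome, pred),
        predictions=pred.tolist(), y_test=test.outcome.tolist(),
        seeds={"split": plan.seed, "swarm": swarm_config.seed},
        fitness_history=list(state.fitness_history))
    report.config_echo = echo
    return report


def run_comparators(cohort: CohortTable, plan: SplitPlan | None = None,
                    alpha: float = 0.05, seed: int = 0) -> dict:
    """Single pruned tree, RBF-SVM and MLP on the filter-selected features.

    Returns ``{name: (MetricReport, predictions)}`` on the shared test
    split, for pairwise McNemar comparison against the hybrid.
    """
    plan = plan or SplitPlan()
    cohort = discretize(cohort)
    train, test = split(cohort, plan)
    base_features = [s.name for s in cohort.schema
                     if s.name not in _DISCRETIZED.values()]
    selection = select_features(train, alpha, features=base_features)
    cats, ints = pso_candidates(selection, cohort)
    out = {}

    enc_train = encode_cohort(train, cats, ints)
    enc_test = encode_cohort(test, cats, ints)
    tree = prune_tree(grow_tree(enc_train, FeatureTransform.full(cats, ints)))
    pred = tree_predict(tree, enc_test)
    out["decision_tree"] = (_evaluate(test.outcome, pred), pred)

    dm = _DesignMatrix(train, cats, ints)
    x_tr, x_te = dm.encode(train), dm.encode(test)
    svm = _make_svm(_svm_grid_search(x_tr, train.outcome, seed))
    svm.fit(x_tr, train.outcome)
    pred = svm.predict(x_te)
    out["svm"] = (_evaluate(test.outcome, pred), pred)

    mlp = _make_mlp(seed)
    mlp.fit(x_tr, train.outcome)
    pred = mlp.predict(x_te)
    out["mlp"] = (_evaluate(test.outcome, pred), pred)
    return out


def npi_score(inp: NPIInput) -> tuple:
    """Nottingham Prognostic Index and its risk group.

    score = 0.2 x tumor size (cm) + histological grade + node point,
    where the node point is 1 for no positive nodes, 2 for 1-3 and 3
    for >= 4; scores >= 3.4 are high risk.
    """
    nodes = inp.positive_nodes
    node_point = 1 if nodes == 0 else (2 if nodes <= 3 else 3)
    score = 0.2 * inp.tumor_size_cm + inp.histological_grade + node_point
    risk = "high" if score >= NPI_CUT else "low"
    return score, risk


def compare_all(predictions: dict, y_true, dp: dict | None = None) -> list:
    """All pairwise McNemar tests; winner by discriminant power.

    ``predictions`` maps classifier name -> 0/1 vector on the same test
    rows; ``dp`` maps name -> discriminant power (used only to call the
    winner when a difference is significant). Pairs with no discordant
    misclassifications are reported as such rather than tested.
    """
    dp = dp or {}
    names = list(predictions)
    out = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            try:
                res = mcnemar(predictions[a], predictions[b], y_true,
                              label_a=a, label_b=b,
                              dp_a=dp.get(a, math.nan), dp_b=dp.get(b, math.nan))
                out.append({"pair": [a, b], **res.to_dict()})
            except ValueError:
                out.append({"pair": [a, b], "note": "no discordant pairs"})
    return out
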