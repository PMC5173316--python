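"""Filter (statistical) feature selection on mixed measurement scales.

Each candidate feature is tested univariately against the binary
recurrence outcome with a test keyed to its scale:

* interval — Lilliefors-corrected Kolmogorov–Smirnov normality check in
  each outcome class; when both classes look normal an equal-variance
  two-sample t-test is used, otherwise the Wilcoxon–Mann–Whitney test;
* ordinal — always Mann–Whitney on the rank codes;
* nominal/binary — Pearson chi-square on the k x 2 contingency table,
  with a seeded Monte-Carlo p-value when any expected cell is < 5.

Selection keeps features with p < alpha (default 0.05, two-sided, no
multiplicity correction — the filter is deliberately liberal, the
downstream embedded selection refines it).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors

from .cohort import CohortTable

__all__ = [
    "FeatureTestResult",
    "SelectionResult",
    "ks_normality",
    "compare_interval",
    "chi_square_nominal",
    "select_features",
]

#: per-class normality level used to route interval features to the t-test
NORMALITY_ALPHA = 0.05

#: Monte-Carlo replicates for small-expected-cell chi-square p-values
_MC_REPLICATES = 10_000
_MC_SEED = 0


@dataclass
class FeatureTestResult:
    feature: str
    test: str  # t_test | mann_whitney | chi_square
    statistic: float
    p_value: float
    selected: bool
    normality_by_class: tuple | None = None  # interval features only
    note: str = ""

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SelectionResult:
    results: list
    alpha: float
    selected_names: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.selected_names:
            self.selected_names = [r.feature for r in self.results if r.selected]

    def to_json(self, **kwargs) -> str:
        doc = {"alpha": self.alpha,
               "selected": self.selected_names,
               "results": [r.to_dict() for r in self.results]}
        return json.dumps(doc, sort_keys=True, **kwargs)


def ks_normality(values) -> float:
    """Lilliefors-corrected one-sample KS p-value against normality.

    The classic KS test is anti-conservative when mean and sd are
    estimated from the sample; the Lilliefors correction restores the
    nominal level. A constant vector is degenerate and returns p = 0.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 5:
        raise ValueError("need at least 5 values")
    if np.ptp(x) == 0:
        return 0.0
    _, p = lilliefors(x, dist="norm", pvalmethod="table")
    return float(p)


def compare_interval(values, classes, alpha: float = 0.05,
                     scale: str = "interval", name: str = "") -> FeatureTestResult:
    """Two-group comparison of an interval or ordinal feature.

    Routing: both class-conditional distributions must pass the
    Lilliefors check at 0.05 for the (equal-variance) t-test; otherwise,
    and always for ordinal features, the two-sided Mann–Whitney test
    with midrank tie correction is used.
    """
    x = np.asarray(values, dtype=float)
    y = np.asarray(classes, dtype=int)
    g0, g1 = x[y == 0], x[y == 1]
    if g0.size < 5 or g1.size < 5:
        raise ValueError("both outcome classes need at least 5 members")

    normality = None
    if scale == "interval":
        normality = (ks_normality(g0) > NORMALITY_ALPHA,
                     ks_normality(g1) > NORMALITY_ALPHA)
        use_t = all(normality)
    else:
        use_t = False

    if use_t:
        stat, p = stats.ttest_ind(g0, g1, equal_var=True)
        test = "t_test"
    else:
        stat, p = stats.mannwhitneyu(g0, g1, alternative="two-sided",
                                     method="asymptotic")
        test = "mann_whitney"
    return FeatureTestResult(feature=name, test=test, statistic=float(stat),
                             p_value=float(p), selected=bool(p < alpha),
                             normality_by_class=normality)


def _chi_square_stat(table: np.ndarray) -> float:
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = (table - expected) ** 2 / expected
    return float(np.nansum(terms))


def chi_square_nominal(values, classes, alpha: float = 0.05,
                       name: str = "") -> FeatureTestResult:
    """Pearson chi-square (no continuity correction) on the k x 2 table.

    When any expected count is below 5 the asymptotic reference is
    unreliable; a seeded Monte-Carlo permutation p-value (multivariate
    hypergeometric draws under fixed margins) is used instead.
    """
    vals = np.asarray(values, dtype=object)
    y = np.asarray(classes, dtype=int)
    cats, codes = np.unique(vals.astype(str), return_inverse=True)
    if len(cats) < 2:
        raise ValueError("all observations fall in a single category")
    k = len(cats)
    table = np.zeros((k, 2), dtype=float)
    np.add.at(table, (codes, y), 1.0)

    statistic = _chi_square_stat(table)
    df = k - 1
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    note = ""
    if (expected < 5).any():
        # permutation null with fixed margins: draw the class-1 column
        rng = np.random.default_rng(_MC_SEED)
        n1 = int(table[:, 1].sum())
        colors = table.sum(axis=1).astype(int)
        draws = rng.multivariate_hypergeometric(colors, n1, size=_MC_REPLICATES)
        tables = np.stack([colors[None, :] - draws, draws], axis=2).astype(float)
        exp = expected[None, :, :]
        with np.errstate(invalid="ignore", divide="ignore"):
            perm_stats = np.nansum((tables - exp) ** 2 / exp, axis=(1, 2))
        p = float((1 + np.sum(perm_stats >= statistic - 1e-12)) / (1 + _MC_REPLICATES))
        note = "monte_carlo (expected count < 5)"
    else:
        p = float(stats.chi2.sf(statistic, df)) if statistic > 0 else 1.0
    return FeatureTestResult(feature=name, test="chi_square",
                             statistic=statistic, p_value=p,
                             selected=bool(p < alpha), note=note)


def select_features(cohort: CohortTable, alpha: float = 0.05,
                    features: list | None = None) -> SelectionResult:
    """Run the scale-appropriate test for every candidate feature."""
    y = cohort.outcome
    if len(np.unique(y)) < 2:
        raise ValueError("cohort must contain both outcome classes")
    names = features or cohort.feature_names()
    results = []
    for name in names:
        spec = cohort.spec(name)
        col = cohort.df[name]
        if spec.scale in ("interval", "ordinal"):
            if spec.is_interval:
                x = col.to_numpy(dtype=float)
            else:
                x = np.array([spec.categories.index(str(v)) for v in col],
                             dtype=float)
            if np.ptp(x) == 0:
                res = _constant_result(name, "mann_whitney")
            else:
                res = compare_interval(x, y, alpha, scale=spec.scale, name=name)
        else:
            vals = col.to_numpy(dtype=object)
            if len(set(map(str, vals))) < 2:
                res = _constant_result(name, "chi_square")
            else:
                res = chi_square_nominal(vals, y, alpha, name=name)
        results.append(res)
    return SelectionResult(results=results, alpha=alpha)


def _constant_result(name: str, test: str) -> FeatureTestResult:
    """A constant column carries no class information by construction."""
    return FeatureTestResult(feature=name, test=test, statistic=0.0,
                             p_value=1.0, selected=False,
                             note="constant feature")
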