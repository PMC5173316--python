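"""Cohort data model, clinical transforms, and the synthetic-cohort generator.

The unit of analysis is a patient with 21 clinicopathologic features on
mixed measurement scales (interval, ordinal, nominal/binary) and a binary
outcome: recurrence within 5 years of diagnosis. This module provides

* a typed feature schema (:class:`FeatureSpec`) and validated container
  (:class:`CohortTable`) with CSV I/O,
* clinical derivations: the nodal ratio, literature cut-point
  discretization of age/nodal-ratio/tumor-size, and the molecular
  subtype from ER/PR/HER2/Ki67,
* a seeded synthetic-cohort generator calibrated to per-class marginal
  summaries (truncated-normal interval features, categorical frequency
  tables) with a Gaussian copula tying the involved and dissected
  lymph-node counts to a target Pearson correlation.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, special, stats

__all__ = [
    "FeatureSpec",
    "CohortTable",
    "SyntheticSpec",
    "IntervalParams",
    "DiscretizationRule",
    "DISCRETIZATION_RULES",
    "KI67_HIGH_CUTOFF",
    "OUTCOME_COLUMN",
    "METASTASIS_COLUMN",
    "SUBTYPES",
    "default_schema",
    "load_cohort",
    "compute_nr",
    "discretize",
    "derive_subtype",
    "default_spec",
    "generate_synthetic_cohort",
]

OUTCOME_COLUMN = "recurrence_5y"
METASTASIS_COLUMN = "primary_metastasis"

#: Ki67 percentage at and above which proliferation counts as "high".
KI67_HIGH_CUTOFF = 14.0

SUBTYPES = ["LA", "LB", "HLB", "NLH", "3N"]

_CLASSES = ("recurrent", "nonrecurrent")


@dataclass(frozen=True)
class FeatureSpec:
    """Name, measurement scale and (for categorical scales) category labels."""

    name: str
    scale: str  # interval | ordinal | nominal | binary
    categories: tuple = ()
    units: str = ""

    def __post_init__(self) -> None:
        if self.scale not in {"interval", "ordinal", "nominal", "binary"}:
            raise ValueError(f"unknown scale {self.scale!r} for {self.name}")
        if self.scale == "interval" and self.categories:
            raise ValueError(f"interval feature {self.name} must not list categories")
        if self.scale in {"nominal", "ordinal", "binary"} and not self.categories:
            raise ValueError(f"{self.scale} feature {self.name} needs categories")
        if self.scale == "binary" and len(self.categories) != 2:
            raise ValueError(f"binary feature {self.name} needs exactly 2 categories")

    @property
    def is_interval(self) -> bool:
        return self.scale == "interval"


def default_schema() -> list[FeatureSpec]:
    """The 21-feature clinicopathologic schema of the study cohort."""
    binary = ("neg", "pos")
    return [
        FeatureSpec("age", "interval", units="years"),
        FeatureSpec("nr", "interval", units="ratio"),
        FeatureSpec("menarche", "interval", units="years"),
        FeatureSpec("n_preg", "interval", units="count"),
        FeatureSpec("ts", "interval", units="cm"),
        FeatureSpec("ki67", "interval", units="percent"),
        FeatureSpec("i_node", "interval", units="count"),
        FeatureSpec("t_node", "interval", units="count"),
        FeatureSpec("n_chemo", "interval", units="count"),
        FeatureSpec("fh", "binary", binary),
        FeatureSpec("multifocal", "binary", binary),
        FeatureSpec("er", "binary", binary),
        FeatureSpec("pr", "binary", binary),
        FeatureSpec("p53", "binary", binary),
        FeatureSpec("surgery", "nominal", ("MRM", "BCS", "Mast")),
        FeatureSpec("her2", "binary", binary),
        FeatureSpec("cathepsin", "binary", binary),
        FeatureSpec("hrt", "binary", binary),
        FeatureSpec("xrt", "binary", binary),
        FeatureSpec("subtype", "nominal", tuple(SUBTYPES)),
        FeatureSpec("grade", "ordinal", ("1", "2", "3", "4")),
    ]


@dataclass
class CohortTable:
    """Validated patient table: features ``df`` + binary ``outcome``."""

    schema: list[FeatureSpec]
    df: pd.DataFrame
    outcome: np.ndarray
    dropped_count: int = 0
    excluded_metastasis: int = 0

    @property
    def n(self) -> int:
        return len(self.df)

    def spec(self, name: str) -> FeatureSpec:
        for s in self.schema:
            if s.name == name:
                return s
        raise KeyError(name)

    def feature_names(self) -> list[str]:
        return [s.name for s in self.schema]

    def validate(self) -> None:
        if len(self.outcome) != self.n:
            raise ValueError("outcome length does not match row count")
        if not np.isin(self.outcome, [0, 1]).all():
            raise ValueError("outcome must be binary 0/1")
        for s in self.schema:
            if s.name not in self.df.columns:
                raise ValueError(f"missing column {s.name}")
            col = self.df[s.name]
            if col.isna().any():
                raise ValueError(f"missing values in column {s.name}")
            if s.is_interval:
                if not np.issubdtype(col.dtype, np.number):
                    raise ValueError(f"non-numeric values in interval column {s.name}")
            else:
                bad = ~col.astype(str).isin(s.categories)
                if bad.any():
                    raise ValueError(
                        f"unknown category {col[bad].iloc[0]!r} in column {s.name}")
        cols = set(self.df.columns)
        if {"i_node", "t_node", "nr"} <= cols:
            expect = self.df["i_node"].to_numpy(float) / self.df["t_node"].to_numpy(float)
            if not np.allclose(self.df["nr"].to_numpy(float), expect, atol=1e-9):
                raise ValueError("nr column inconsistent with i_node/t_node")

    def to_frame(self) -> pd.DataFrame:
        out = self.df.copy()
        out[OUTCOME_COLUMN] = self.outcome
        return out

    def to_csv(self, path=None):
        """Serialize features + outcome as comma-separated UTF-8 text."""
        return self.to_frame().to_csv(path, index=False)

    def subset(self, index: Iterable[int]) -> "CohortTable":
        idx = np.asarray(list(index), dtype=int)
        return CohortTable(
            schema=list(self.schema),
            df=self.df.iloc[idx].reset_index(drop=True),
            outcome=self.outcome[idx].copy(),
        )


def load_cohort(path, schema: list[FeatureSpec] | None = None) -> CohortTable:
    """Read a cohort CSV, excluding primary-metastasis and incomplete rows.

    The CSV must carry a header with every schema feature plus the
    ``recurrence_5y`` outcome column; an optional ``primary_metastasis``
    0/1 column marks patients excluded a priori (stage IV at registry).
    Incomplete rows are dropped and counted in ``dropped_count``.
    """
    schema = schema or default_schema()
    raw = pd.read_csv(path, dtype=str, skipinitialspace=True)
    needed = [s.name for s in schema] + [OUTCOME_COLUMN]
    missing = [c for c in needed if c not in raw.columns]
    if missing:
        raise ValueError(f"schema error: missing column(s) {missing}")

    excluded = 0
    if METASTASIS_COLUMN in raw.columns:
        flag = raw[METASTASIS_COLUMN].fillna("0").astype(str).str.lower()
        is_meta = flag.isin({"1", "true", "yes"})
        excluded = int(is_meta.sum())
        raw = raw.loc[~is_meta]

    df = pd.DataFrame(index=raw.index)
    for s in schema:
        col = raw[s.name].replace("", np.nan)
        if s.is_interval:
            parsed = pd.to_numeric(col, errors="coerce")
            bad = parsed.isna() & col.notna()
            if bad.any():
                i = int(np.flatnonzero(bad.to_numpy())[0])
                raise ValueError(
                    f"parse error: non-numeric value {col[bad].iloc[0]!r} "
                    f"in interval column {s.name} (row {i})")
            df[s.name] = parsed
        else:
            df[s.name] = col
    outcome = pd.to_numeric(raw[OUTCOME_COLUMN].replace("", np.nan), errors="coerce")

    complete = df.notna().all(axis=1) & outcome.notna()
    dropped = int((~complete).sum())
    df = df.loc[complete].reset_index(drop=True)
    outcome = outcome.loc[complete].to_numpy(dtype=int)

    table = CohortTable(schema=list(schema), df=df, outcome=outcome,
                        dropped_count=dropped, excluded_metastasis=excluded)
    table.validate()
    return table


def compute_nr(i_node: float, t_node: float) -> float:
    """Nodal ratio: involved / dissected axillary lymph nodes."""
    if t_node < 1:
        raise ValueError("at least one dissected node is required")
    if i_node < 0 or i_node > t_node:
        raise ValueError("involved nodes must lie in [0, dissected nodes]")
    return i_node / t_node


@dataclass(frozen=True)
class DiscretizationRule:
    """Cut-point discretization of one interval feature.

    ``right_closed`` puts a value equal to a cut into the lower bin
    (x <= cut), otherwise into the upper bin (x < cut goes lower).
    """

    source: str
    name: str
    cuts: tuple
    labels: tuple
    right_closed: bool = True

    def __post_init__(self) -> None:
        if list(self.cuts) != sorted(set(self.cuts)):
            raise ValueError("cut points must be strictly increasing")
        if len(self.labels) != len(self.cuts) + 1:
            raise ValueError("need exactly one more label than cuts")

    def apply(self, values: np.ndarray) -> np.ndarray:
        idx = np.digitize(values, self.cuts, right=self.right_closed)
        return np.asarray(self.labels, dtype=object)[idx]

    def spec(self) -> FeatureSpec:
        scale = "binary" if len(self.labels) == 2 else "nominal"
        return FeatureSpec(self.name, scale, tuple(self.labels))


#: Literature cut points: age dichotomized at 40 years (boundary assigned to
#: the older, lower-risk group), nodal ratio at 0.25, tumor size at the
#: 2 cm / 5 cm T-stage boundaries.
DISCRETIZATION_RULES = [
    DiscretizationRule("age", "age_cat", (40.0,), ("<40", ">=40"), right_closed=False),
    DiscretizationRule("nr", "nr_cat", (0.25,), ("<=0.25", ">0.25")),
    DiscretizationRule("ts", "ts_cat", (2.0, 5.0), ("T1", "T2", "T3")),
]


def discretize(cohort: CohortTable) -> CohortTable:
    """Append age_cat / nr_cat / ts_cat columns; idempotent."""
    df = cohort.df.copy()
    schema = list(cohort.schema)
    have = {s.name for s in schema}
    for rule in DISCRETIZATION_RULES:
        if rule.name in have:
            continue
        if rule.source not in df.columns:
            raise ValueError(f"missing source column {rule.source}")
        df[rule.name] = rule.apply(df[rule.source].to_numpy(dtype=float))
        schema.append(rule.spec())
    out = CohortTable(schema=schema, df=df, outcome=cohort.outcome.copy(),
                      dropped_count=cohort.dropped_count,
                      excluded_metastasis=cohort.excluded_metastasis)
    return out


def _is_pos(v) -> bool:
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    return str(v).lower() in {"pos", "positive", "+", "1", "true"}


def derive_subtype(er, pr, her2, ki67: float) -> str:
    """Molecular subtype from hormone receptors, HER2 and Ki67.

    Luminal (ER and/or PR positive): HER2+ -> HER2-positive luminal B
    (HLB, any Ki67); HER2- with low Ki67 (<14%) -> luminal A (LA), with
    high Ki67 -> luminal B (LB). Non-luminal (ER and PR negative):
    HER2+ -> NLH, HER2- -> triple negative (3N).
    """
    luminal = _is_pos(er) or _is_pos(pr)
    if luminal:
        if _is_pos(her2):
            return "HLB"
        return "LB" if ki67 >= KI67_HIGH_CUTOFF else "LA"
    return "NLH" if _is_pos(her2) else "3N"


# ---------------------------------------------------------------------------
# Synthetic cohort generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IntervalParams:
    """Target mean/sd and hard bounds of one truncated-normal marginal."""

    mean: float
    sd: float
    min: float
    max: float
    integer: bool = False

    def __post_init__(self) -> None:
        if not (self.min <= self.mean <= self.max):
            raise ValueError("require min <= mean <= max")
        if self.sd <= 0:
            raise ValueError("sd must be positive")


@dataclass
class SyntheticSpec:
    """Per-class calibration of the synthetic cohort.

    ``interval`` maps feature name -> class -> :class:`IntervalParams`;
    ``categorical`` maps feature name -> class -> {label: probability}.
    The nodal ratio and the molecular subtype are always derived, so the
    only sampled features are the eight primary interval features and
    the non-derived categorical ones.
    """

    interval: dict
    categorical: dict
    prevalence: float
    node_correlation: float
    seed: int = 0
    flags: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0.0 < self.prevalence < 1.0):
            raise ValueError("prevalence must lie strictly in (0, 1)")
        for feat, per_class in self.categorical.items():
            for cls in _CLASSES:
                probs = per_class[cls]
                total = float(sum(probs.values()))
                if abs(total - 1.0) > 0.1:
                    raise ValueError(
                        f"category probabilities for {feat}/{cls} sum to {total}")
                if abs(total - 1.0) > 1e-9:
                    self.flags.append(
                        f"{feat}/{cls}: probabilities sum to {total:g}, normalized")
                    per_class[cls] = {k: v / total for k, v in probs.items()}

    @classmethod
    def from_dict(cls, doc: dict) -> "SyntheticSpec":
        interval = {
            name: {c: IntervalParams(
                mean=float(p[c]["mean"]), sd=float(p[c]["sd"]),
                min=float(p[c]["min"]), max=float(p[c]["max"]),
                integer=bool(p.get("integer", False)))
                for c in _CLASSES}
            for name, p in doc.get("interval", {}).items()
        }
        categorical = {}
        for block in ("nominal", "ordinal"):
            for name, p in doc.get(block, {}).items():
                categorical[name] = {c: {str(k): float(v) for k, v in p[c].items()}
                                     for c in _CLASSES}
        return cls(interval=interval, categorical=categorical,
                   prevalence=float(doc["prevalence"]),
                   node_correlation=float(doc["node_correlation"]),
                   seed=int(doc.get("seed", 0)))

    @classmethod
    def from_yaml(cls, path) -> "SyntheticSpec":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def null(self) -> "SyntheticSpec":
        """Spec with identical class marginals (non-recurrent for both):
        the outcome carries no information about any feature."""
        interval = {f: {c: p["nonrecurrent"] for c in _CLASSES}
                    for f, p in self.interval.items()}
        categorical = {f: {c: dict(p["nonrecurrent"]) for c in _CLASSES}
                       for f, p in self.categorical.items()}
        return SyntheticSpec(interval=interval, categorical=categorical,
                             prevalence=self.prevalence,
                             node_correlation=self.node_correlation,
                             seed=self.seed)


def default_spec() -> SyntheticSpec:
    """The packaged calibration emulating the study cohort."""
    ref = resources.files("hpbcr").joinpath("data/default_cohort.yaml")
    return SyntheticSpec.from_dict(yaml.safe_load(ref.read_text(encoding="utf-8")))


@functools.lru_cache(maxsize=64)
def _truncnorm_loc_scale(mean: float, sd: float, lo: float, hi: float):
    """loc/scale of a truncated normal whose *truncated* moments match.

    The calibration tables report the sample mean/sd of bounded
    quantities, so using them directly as loc/scale would bias heavily
    truncated features (e.g. node counts with sd ~ mean). Solve the
    two-moment inverse problem instead. The mean is matched exactly; the
    sd as closely as the family allows (an overdispersed count such as
    sd > mean on a lower-bounded support has no truncated-normal match,
    in which case the nearest feasible, exponential-like member is used).
    """
    def residual(q):
        loc, log_scale = q
        scale = math.exp(log_scale)
        a, b = (lo - loc) / scale, (hi - loc) / scale
        m, v = stats.truncnorm.stats(a, b, loc=loc, scale=scale, moments="mv")
        return [10.0 * (float(m) - mean) / sd,
                (math.sqrt(max(float(v), 1e-300)) - sd) / sd]

    sol = optimize.least_squares(
        residual, x0=[mean, math.log(sd)],
        bounds=([lo - 60.0 * sd, math.log(sd) - 6.0],
                [hi + 60.0 * sd, math.log(sd) + 6.0]),
        xtol=1e-13, ftol=1e-13, gtol=1e-13)
    loc, log_scale = sol.x
    scale = math.exp(log_scale)

    # exact-mean refinement: at fixed scale the truncated mean is strictly
    # increasing in loc, spanning (lo, hi), so a root always exists
    def mean_err(l):
        a, b = (lo - l) / scale, (hi - l) / scale
        return float(stats.truncnorm.mean(a, b, loc=l, scale=scale)) - mean

    lo_b, hi_b = lo - 80.0 * scale, hi + 80.0 * scale
    if mean_err(lo_b) > 0 or mean_err(hi_b) < 0:
        raise ValueError(
            f"infeasible truncation bounds: no truncated normal on [{lo}, {hi}] "
            f"has mean {mean} (sd target {sd})")
    loc = optimize.brentq(mean_err, lo_b, hi_b, xtol=1e-10)
    return float(loc), float(scale)


def _truncnorm_ab(loc, scale, p: IntervalParams):
    return (p.min - loc) / scale, (p.max - loc) / scale


def _sample_interval(p: IntervalParams, size: int, rng: np.random.Generator,
                     loc_scale=None) -> np.ndarray:
    loc, scale = loc_scale or _truncnorm_loc_scale(p.mean, p.sd, p.min, p.max)
    a, b = _truncnorm_ab(loc, scale, p)
    x = stats.truncnorm.rvs(a, b, loc=loc, scale=scale, size=size, random_state=rng)
    if p.integer:
        x = np.rint(x)
    return x


def _node_pair(pi: IntervalParams, pt: IntervalParams, rho: float,
               i_eff, t_eff, size: int, rng: np.random.Generator):
    """Joint involved/dissected node counts via a Gaussian copula."""
    cov = np.array([[1.0, rho], [rho, 1.0]])
    z = rng.multivariate_normal([0.0, 0.0], cov, size=size, method="cholesky")
    u = special.ndtr(z)
    loc_i, sc_i = _truncnorm_loc_scale(*i_eff)
    loc_t, sc_t = _truncnorm_loc_scale(*t_eff)
    ai, bi = (pi.min - loc_i) / sc_i, (pi.max - loc_i) / sc_i
    at, bt = (pt.min - loc_t) / sc_t, (pt.max - loc_t) / sc_t
    i_node = stats.truncnorm.ppf(u[:, 0], ai, bi, loc=loc_i, scale=sc_i)
    t_node = stats.truncnorm.ppf(u[:, 1], at, bt, loc=loc_t, scale=sc_t)
    i_node = np.rint(i_node)
    t_node = np.maximum(np.rint(t_node), 1.0)
    i_node = np.clip(i_node, 0.0, t_node)
    return i_node, t_node


def _node_cal_key(spec: SyntheticSpec):
    parts = [spec.prevalence, spec.node_correlation]
    for f in ("i_node", "t_node"):
        for c in _CLASSES:
            p = spec.interval[f][c]
            parts += [p.mean, p.sd, p.min, p.max]
    return tuple(parts)


@functools.lru_cache(maxsize=16)
def _calibrate_nodes_cached(key):
    """Solve for per-class effective truncation moments and the latent
    copula correlation so that, after rounding and enforcing
    involved <= dissected, the node counts hit their target per-class
    mean/sd and the pooled Pearson correlation target.

    Fixed-point iteration against an internal deterministic simulation.
    """
    (prev, target_r,
     im_r, is_r, ilo_r, ihi_r, im_n, is_n, ilo_n, ihi_n,
     tm_r, ts_r, tlo_r, thi_r, tm_n, ts_n, tlo_n, thi_n) = key
    targets = {
        "recurrent": {"i": (im_r, is_r, ilo_r, ihi_r), "t": (tm_r, ts_r, tlo_r, thi_r)},
        "nonrecurrent": {"i": (im_n, is_n, ilo_n, ihi_n), "t": (tm_n, ts_n, tlo_n, thi_n)},
    }
    pi = {c: IntervalParams(*targets[c]["i"], integer=True) for c in _CLASSES}
    pt = {c: IntervalParams(*targets[c]["t"], integer=True) for c in _CLASSES}
    eff = {c: {k: list(targets[c][k]) for k in ("i", "t")} for c in _CLASSES}
    rho = target_r
    m = 20000
    n_rec = int(round(prev * m))
    for it in range(10):
        rng = np.random.default_rng(987654321 + it)
        pooled_i, pooled_t = [], []
        for c in _CLASSES:
            i_node, t_node = _node_pair(
                pi[c], pt[c], rho, tuple(eff[c]["i"]), tuple(eff[c]["t"]), m, rng)
            for name, x in (("i", i_node), ("t", t_node)):
                tgt = targets[c][name]
                e = eff[c][name]
                e[0] += 0.9 * (tgt[0] - float(np.mean(x)))
                e[1] *= float(np.clip(tgt[1] / max(np.std(x), 1e-9), 0.5, 2.0)) ** 0.9
                e[0] = float(np.clip(e[0], tgt[2] - 5 * tgt[1], tgt[3]))
                e[1] = float(np.clip(e[1], 1e-3, 5 * tgt[1]))
            take = n_rec if c == "recurrent" else m - n_rec
            pooled_i.append(i_node[:take])
            pooled_t.append(t_node[:take])
        r_obs = float(np.corrcoef(np.concatenate(pooled_i), np.concatenate(pooled_t))[0, 1])
        rho = float(np.clip(rho + 0.9 * (target_r - r_obs), -0.99, 0.99))
    return {c: {k: tuple(eff[c][k]) for k in ("i", "t")} for c in _CLASSES}, rho


def generate_synthetic_cohort(spec: SyntheticSpec, n: int,
                              seed: int | None = None) -> CohortTable:
    """Draw a synthetic cohort of ``n`` patients under ``spec``.

    Outcome ~ Bernoulli(prevalence); interval features per-class
    truncated normal; node counts jointly via the calibrated copula with
    involved <= dissected; the nodal ratio and molecular subtype are
    recomputed from their parents, never sampled. Deterministic under a
    fixed seed.
    """
    if n < 20:
        raise ValueError("need n >= 20")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    outcome = (rng.random(n) < spec.prevalence).astype(int)
    idx = {"recurrent": np.flatnonzero(outcome == 1),
           "nonrecurrent": np.flatnonzero(outcome == 0)}

    node_eff, rho = _calibrate_nodes_cached(_node_cal_key(spec))
    cols: dict[str, np.ndarray] = {}
    for name, per_class in spec.interval.items():
        if name in ("i_node", "t_node"):
            continue
        out = np.empty(n, dtype=float)
        for c in _CLASSES:
            out[idx[c]] = _sample_interval(per_class[c], len(idx[c]), rng)
        cols[name] = out

    i_all = np.empty(n, dtype=float)
    t_all = np.empty(n, dtype=float)
    for c in _CLASSES:
        i_node, t_node = _node_pair(
            spec.interval["i_node"][c], spec.interval["t_node"][c], rho,
            node_eff[c]["i"], node_eff[c]["t"], len(idx[c]), rng)
        i_all[idx[c]] = i_node
        t_all[idx[c]] = t_node
    cols["i_node"] = i_all
    cols["t_node"] = t_all
    cols["nr"] = i_all / t_all

    cat_cols: dict[str, np.ndarray] = {}
    for name, per_class in spec.categorical.items():
        out = np.empty(n, dtype=object)
        for c in _CLASSES:
            labels = list(per_class[c].keys())
            probs = np.array([per_class[c][k] for k in labels], dtype=float)
            out[idx[c]] = rng.choice(labels, size=len(idx[c]), p=probs)
        cat_cols[name] = out

    subtype = np.array([
        derive_subtype(cat_cols["er"][i], cat_cols["pr"][i],
                       cat_cols["her2"][i], cols["ki67"][i])
        for i in range(n)], dtype=object)

    schema = default_schema()
    df = pd.DataFrame(index=range(n))
    for s in schema:
        if s.name == "subtype":
            df[s.name] = subtype
        elif s.is_interval:
            df[s.name] = cols[s.name]
        else:
            df[s.name] = cat_cols[s.name]
    table = CohortTable(schema=schema, df=df, outcome=outcome)
    table.validate()
    return table
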