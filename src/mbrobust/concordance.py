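"""Feature-concordance statistics for pairs of ML models, with meta-analysis.

Two classifiers trained on variants of the same data (e.g. raw versus
batch-corrected counts) each emit a nonnegative importance score per feature
over a shared feature universe.  A feature is *used* iff its score is
strictly positive.  Concordance is assessed two ways:

* binary overlap — a 2x2 contingency table of used/unused status, tested
  with Fisher's exact test (one-sided ``greater`` by default, i.e. testing
  enrichment of joint usage);
* rank agreement — Kendall's tau-b on rank vectors where used features are
  ranked 1..k by descending importance (midranks for score ties) and every
  unused feature is assigned the fixed rank k+1, k being that model's count
  of used features.  The k+1 rule creates large tie blocks, hence the
  tie-corrected tau-b variant and a tie-adjusted normal p-value.

Per-class p-values from independent batches are combined with Fisher's
method (-2*sum(ln p) against chi-square with 2m df, computed in log space); a
class observed in a single batch passes its raw p-value through.  Combined
p-values are Benjamini-Hochberg adjusted across classes.  Underflowing
p-values are clamped at the smallest normalized double (~2.2e-308), with the
exact log10 value retained for plotting.

Classifier performance series (per-fold or per-batch AUROC/AUPR) are
summarized with normal-approximation confidence intervals; two classifiers
are called equivalent when their intervals overlap.
"""

from __future__ import annotations

import math
import sys
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import (
    average_precision_score,
    precision_recall_curve,
    roc_auc_score,
)
from statsmodels.stats.multitest import multipletests

from .errors import ContractError

__all__ = [
    "P_CLAMP",
    "ImportanceVector",
    "ContingencyTable2x2",
    "ConcordanceResult",
    "BatchRun",
    "build_contingency",
    "fisher_exact",
    "rank_concordance",
    "combine_fisher",
    "combine_fisher_log10",
    "bh_adjust",
    "auroc",
    "aupr",
    "aggregate_ci",
    "equivalent",
    "per_batch_compare",
]

# Smallest positive normalized double; p-values below this are clamped.
P_CLAMP = sys.float_info.min

_Z = {0.99: 2.576, 0.95: 1.960}


@dataclass(frozen=True)
class ImportanceVector:
    """feature -> nonnegative importance over a shared universe.

    Features in the universe missing from *scores* are treated as zero
    (unused).  ``used`` is the set of features with strictly positive score.
    """

    scores: Mapping[str, float]
    universe: frozenset[str]

    def __post_init__(self):
        object.__setattr__(self, "scores", dict(self.scores))
        object.__setattr__(self, "universe", frozenset(self.universe))
        stray = set(self.scores) - self.universe
        if stray:
            raise ContractError(f"scored features outside universe: {sorted(stray)[:5]}")
        negative = [f for f, s in self.scores.items() if s < 0]
        if negative:
            raise ContractError(f"negative importance scores: {sorted(negative)[:5]}")

    @property
    def used(self) -> frozenset[str]:
        return frozenset(f for f, s in self.scores.items() if s > 0)

    def score(self, feature: str) -> float:
        return float(self.scores.get(feature, 0.0))

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, universe: Iterable[str] | None = None
    ) -> "ImportanceVector":
        scores = dict(zip(frame["feature"].astype(str), frame["score"].astype(float)))
        return cls(scores, frozenset(universe) if universe is not None else frozenset(scores))


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts of features used by both models (a), A only (b), B only (c),
    neither (d)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ContractError("negative contingency cell")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


def build_contingency(
    va: ImportanceVector, vb: ImportanceVector
) -> ContingencyTable2x2:
    """Cross-tabulate used/unused status of two models on a shared universe."""
    if va.universe != vb.universe:
        diff = sorted(va.universe ^ vb.universe)
        raise ContractError(
            f"feature universes differ; symmetric difference ({len(diff)}): {diff[:10]}"
        )
    ua, ub = va.used, vb.used
    a = len(ua & ub)
    b = len(ua - ub)
    c = len(ub - ua)
    d = len(va.universe) - a - b - c
    return ContingencyTable2x2(a, b, c, d)


def fisher_exact(
    table: ContingencyTable2x2, sided: str = "greater"
) -> tuple[float, float]:
    """Fisher's exact test on a 2x2 table; returns (p, odds ratio).

    ``greater`` tests enrichment of joint usage; ``two-sided`` sums the
    probabilities of all tables no more probable than the observed one.
    Degenerate margins (an all-zero row or column) give p = 1 with a warning.
    """
    alternative = {"greater": "greater", "two-sided": "two-sided"}.get(sided)
    if alternative is None:
        raise ContractError(f"sided must be 'greater' or 'two-sided', got {sided!r}")
    arr = table.as_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        warnings.warn("degenerate 2x2 margins; p = 1", stacklevel=2)
    odds, p = stats.fisher_exact(arr, alternative=alternative)
    return float(p), float(odds)


def _importance_ranks(v: ImportanceVector, order: Sequence[str]) -> np.ndarray:
    """Ranks per the k+1 rule: used features get midranks 1..k by descending
    score; every unused feature gets the fixed rank k+1."""
    scores = np.array([v.score(f) for f in order])
    used = scores > 0
    k = int(used.sum())
    ranks = np.full(len(order), float(k + 1))
    if k:
        ranks[used] = stats.rankdata(-scores[used], method="average")
    return ranks


def rank_concordance(
    va: ImportanceVector, vb: ImportanceVector
) -> tuple[float, float]:
    """Kendall tau-b between two importance rankings (k+1 rule for zeros).

    Requires at least two used features per vector; the p-value uses the
    tie-adjusted normal approximation.
    """
    if va.universe != vb.universe:
        raise ContractError("feature universes differ")
    if len(va.used) < 2 or len(vb.used) < 2:
        raise ContractError(
            "rank concordance needs >= 2 features with nonzero importance per model"
        )
    order = sorted(va.universe)
    ra = _importance_ranks(va, order)
    rb = _importance_ranks(vb, order)
    res = stats.kendalltau(ra, rb, variant="b", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def combine_fisher(pvalues: Sequence[float]) -> float:
    """Fisher's method: chi-square survival of -2*sum(ln p) at 2m df.

    Computed in log space and clamped at the smallest normalized double.  A
    single p-value is returned unchanged (the single-batch pass-through
    rule); p = 0 inputs are treated as the clamp value with a warning.
    """
    ps = list(pvalues)
    if not ps:
        raise ContractError("no p-values to combine")
    clean = []
    for p in ps:
        if not (0 <= p <= 1):
            raise ContractError(f"p-value out of range: {p}")
        if p == 0:
            warnings.warn("p = 0 input clamped to smallest normalized double", stacklevel=2)
            p = P_CLAMP
        clean.append(p)
    if len(clean) == 1:
        return clean[0]
    stat = -2.0 * sum(math.log(p) for p in clean)
    logp = stats.chi2.logsf(stat, 2 * len(clean))
    return max(float(np.exp(logp)), P_CLAMP)


def combine_fisher_log10(pvalues: Sequence[float]) -> float:
    """Exact log10 of the combined p-value (not clamped), for plotting."""
    ps = [P_CLAMP if p == 0 else p for p in pvalues]
    if len(ps) == 1:
        return math.log10(ps[0])
    stat = -2.0 * sum(math.log(p) for p in ps)
    return float(stats.chi2.logsf(stat, 2 * len(ps)) / math.log(10))


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order."""
    ps = np.asarray(pvalues, dtype=float)
    if ps.size == 0:
        return ps
    if ((ps < 0) | (ps > 1)).any():
        raise ContractError("p-values must lie in [0, 1]")
    return multipletests(ps, method="fdr_bh")[1]


@dataclass(frozen=True)
class ConcordanceResult:
    """Joint binary-overlap and rank-agreement result for one model pair."""

    table: ContingencyTable2x2
    fisher_p: float
    odds_ratio: float
    tau: float
    tau_p: float


def compare_importances(
    va: ImportanceVector, vb: ImportanceVector, sided: str = "greater"
) -> ConcordanceResult:
    table = build_contingency(va, vb)
    p, odds = fisher_exact(table, sided)
    tau, tau_p = rank_concordance(va, vb)
    return ConcordanceResult(table, p, odds, tau, tau_p)


# -- classifier metrics ----------------------------------------------------

def _check_binary(labels: np.ndarray) -> None:
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ContractError("both classes must be present")


def auroc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve (rank statistic, half credit for ties)."""
    labels = np.asarray(labels)
    _check_binary(labels)
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def aupr(
    scores: Sequence[float], labels: Sequence[int], method: str = "step"
) -> float:
    """Area under the precision-recall curve.

    ``step`` (default) is the non-interpolated stepwise summation
    sum((R_i - R_{i-1}) * P_i); ``trapezoid`` integrates the PR curve with
    the trapezoidal rule.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    _check_binary(labels)
    if method == "step":
        return float(average_precision_score(labels, scores))
    if method == "trapezoid":
        precision, recall, _ = precision_recall_curve(labels, scores)
        order = np.argsort(recall)
        return float(np.trapezoid(precision[order], recall[order]))
    raise ContractError(f"unknown AUPR method {method!r}")


def aggregate_ci(
    values: Sequence[float], level: float = 0.99
) -> tuple[float, float, float]:
    """Normal-approximation CI (mean, low, high) for a metric series in [0,1].

    mean +/- z * sd / sqrt(n) with z = 2.576 at 99% and 1.960 at 95%,
    truncated to [0, 1].  Fewer than two values collapse to a point CI.
    """
    if level not in _Z:
        raise ContractError(f"CI level must be one of {sorted(_Z)}, got {level}")
    vals = np.asarray(values, dtype=float)
    if vals.size == 0:
        raise ContractError("empty metric series")
    mean = float(vals.mean())
    if vals.size < 2:
        warnings.warn("single-value series; CI collapses to the point", stacklevel=2)
        return mean, mean, mean
    half = _Z[level] * float(vals.std(ddof=1)) / math.sqrt(vals.size)
    return mean, max(0.0, mean - half), min(1.0, mean + half)


def equivalent(
    series_a: Sequence[float], series_b: Sequence[float], level: float = 0.99
) -> bool:
    """Two metric series are equivalent when their CIs overlap."""
    _, lo_a, hi_a = aggregate_ci(series_a, level)
    _, lo_b, hi_b = aggregate_ci(series_b, level)
    return lo_a <= hi_b and lo_b <= hi_a


# -- per-batch meta-analysis ----------------------------------------------

@dataclass(frozen=True)
class BatchRun:
    """One per-batch, per-class model pair (with optional class size)."""

    batch: str
    cls: str
    va: ImportanceVector
    vb: ImportanceVector
    n_samples: int | None = None


def per_batch_compare(
    runs: Sequence[BatchRun],
    min_per_class: int = 20,
    sided: str = "greater",
) -> pd.DataFrame:
    """Concordance per batch and class, combined across batches per class.

    Per run: contingency + Fisher exact + rank concordance.  Per class:
    Fisher's method across batches (single-batch classes pass the raw p
    through), then BH adjustment across classes.  Runs with fewer than
    *min_per_class* samples are excluded; a class left with zero batches is
    omitted with a note (stderr warning).  Returns one row per class with
    combined p-values, q-values and plotting-ready -log10 q.
    """
    per_class: dict[str, list[tuple[str, float, float]]] = {}
    for run in runs:
        if run.n_samples is not None and run.n_samples < min_per_class:
            continue
        result = compare_importances(run.va, run.vb, sided)
        per_class.setdefault(run.cls, []).append((run.batch, result.fisher_p, result.tau_p))
    dropped = {r.cls for r in runs} - set(per_class)
    for cls in sorted(dropped):
        warnings.warn(
            f"class {cls!r} has no batch with >= {min_per_class} samples; omitted",
            stacklevel=2,
        )
    classes = sorted(per_class)
    rows = []
    for cls in classes:
        entries = per_class[cls]
        fisher_ps = [p for _, p, _ in entries]
        tau_ps = [p for _, _, p in entries]
        rows.append(
            {
                "class": cls,
                "n_batches": len(entries),
                "fisher_combined_p": combine_fisher(fisher_ps),
                "tau_combined_p": combine_fisher(tau_ps),
            }
        )
    frame = pd.DataFrame(rows)
    if len(frame):
        frame["fisher_q"] = bh_adjust(frame["fisher_combined_p"])
        frame["tau_q"] = bh_adjust(frame["tau_combined_p"])
        frame["neg_log10_fisher_q"] = -np.log10(frame["fisher_q"].clip(lower=P_CLAMP))
        frame["neg_log10_tau_q"] = -np.log10(frame["tau_q"].clip(lower=P_CLAMP))
    return frame
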