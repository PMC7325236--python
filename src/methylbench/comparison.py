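"""Statistical comparison of imputation performances.

The benchmark's verdicts come from paired Wilcoxon signed-rank tests on
per-repetition average scores (MAE or RMSE), with Benjamini-Hochberg
adjustment across the comparison family of one table stratum
(mechanism x cohort status x metric):

* intra-method: for each method, is one representation (beta or M)
  significantly better?  The winner is the scale with the smaller mean
  score when the adjusted two-sided p-value falls below alpha.
* inter-method: the relaxed "best performance" set — every
  (method, scale) cell that is never statistically significantly worse
  than any other cell in the table.  Because Wilcoxon verdicts are
  rank-based they can disagree with the means; reports print both.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .evaluation import ScoreRecord

__all__ = [
    "PerformanceVector",
    "ComparisonReport",
    "paired_wilcoxon",
    "bh_adjust",
    "intra_method_winner",
    "best_method_set",
    "summarize_table",
    "render_report",
]

EXACT_LIMIT = 25  # nonzero pairs up to which the exact null is used


@dataclass(frozen=True)
class PerformanceVector:
    """Per-repetition average scores for one (method, scale, metric) cell."""

    method: str
    scale: str
    metric: str
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 2:
            raise ValueError("performance vectors need at least 2 repetitions")
        if not np.all(np.isfinite(v)):
            raise ValueError("performance values must be finite")
        object.__setattr__(self, "values", v)

    @property
    def cell(self) -> tuple[str, str]:
        return (self.method, self.scale)

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def sd(self) -> float:
        return float(self.values.std(ddof=1))


def paired_wilcoxon(a, b) -> tuple[float, bool]:
    """Two-sided paired Wilcoxon signed-rank p-value.

    Zero differences are dropped (classical Wilcoxon); the exact null
    distribution is used for up to 25 nonzero pairs, the normal
    approximation with continuity correction beyond.  Returns
    (p-value, degenerate flag); all-zero differences give p = 1 with the
    degenerate flag set.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be 1-D vectors of equal length")
    if a.size < 5:
        raise ValueError("need at least 5 pairs")
    d = a - b
    nonzero = int(np.count_nonzero(d))
    if nonzero == 0:
        return 1.0, True
    method = "exact" if nonzero <= EXACT_LIMIT else "approx"
    res = stats.wilcoxon(
        a, b, zero_method="wilcox", correction=(method == "approx"), method=method
    )
    return float(res.pvalue), False


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def intra_method_winner(
    beta_scores: PerformanceVector,
    m_scores: PerformanceVector,
    alpha: float = 0.05,
    adjusted_p: float | None = None,
) -> str:
    """Which representation wins for one method: 'beta', 'M' or 'none'.

    The test p-value may be replaced by a family-adjusted one
    (``adjusted_p``); the winner is the scale with the smaller mean when
    the (adjusted) p-value is below alpha.
    """
    if beta_scores.method != m_scores.method or beta_scores.metric != m_scores.metric:
        raise ValueError("intra-method comparison requires the same method and metric")
    if beta_scores.values.size != m_scores.values.size:
        raise ValueError("repetition pairing mismatch")
    p = adjusted_p
    if p is None:
        p, _ = paired_wilcoxon(beta_scores.values, m_scores.values)
    if p >= alpha:
        return "none"
    return "beta" if beta_scores.mean < m_scores.mean else "M"


def best_method_set(
    vectors: list[PerformanceVector],
    alpha: float = 0.05,
    return_pmatrix: bool = False,
):
    """The relaxed best-performance set of (method, scale) cells.

    All pairwise BH-adjusted Wilcoxon tests are computed within the
    family; a cell belongs to the set iff no other cell is both
    significantly different (adjusted p < alpha) and better on the mean.
    """
    if len(vectors) < 2:
        raise ValueError("need at least two cells to compare")
    metrics = {v.metric for v in vectors}
    if len(metrics) != 1:
        raise ValueError("all vectors must share one metric")
    pairs = list(itertools.combinations(range(len(vectors)), 2))
    raw = np.array([paired_wilcoxon(vectors[i].values, vectors[j].values)[0] for i, j in pairs])
    adj = bh_adjust(raw)
    n = len(vectors)
    padj = np.ones((n, n))
    for (i, j), p in zip(pairs, adj):
        padj[i, j] = padj[j, i] = p
    means = np.array([v.mean for v in vectors])
    best = {
        vectors[i].cell
        for i in range(n)
        if not any(padj[i, j] < alpha and means[j] < means[i] for j in range(n) if j != i)
    }
    if return_pmatrix:
        return best, padj
    return best


@dataclass
class ComparisonReport:
    """Per-stratum summary: means +- sd, scale winners, best cells, p-matrix."""

    stratum: tuple
    metric: str
    summary: dict[tuple[str, str], tuple[float, float]]
    intra_winners: dict[str, str]
    best_set: set[tuple[str, str]]
    alpha: float
    adjusted_p: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "stratum": list(self.stratum),
                "metric": self.metric,
                "alpha": self.alpha,
                "summary": {f"{m}|{s}": [mu, sd] for (m, s), (mu, sd) in self.summary.items()},
                "intra_winners": self.intra_winners,
                "best_set": sorted(f"{m}|{s}" for m, s in self.best_set),
                "adjusted_p": {f"{a}|{b}": p for (a, b), p in self.adjusted_p.items()},
            },
            indent=2,
        )


def _vectors_from_records(
    records: list[ScoreRecord], metric: str
) -> dict[tuple[str, str], PerformanceVector]:
    """Per-repetition averages (over datasets) for each (method, scale)."""
    cells: dict[tuple[str, str], dict[int, list[float]]] = {}
    for r in records:
        cells.setdefault((r.method, r.scale), {}).setdefault(r.repetition, []).append(
            getattr(r, metric)
        )
    out = {}
    for cell, reps in cells.items():
        values = [float(np.mean(v)) for _, v in sorted(reps.items())]
        out[cell] = PerformanceVector(cell[0], cell[1], metric, np.array(values))
    return out


def summarize_table(
    records: list[ScoreRecord],
    group: tuple[str, ...] = ("mechanism", "status"),
    alpha: float = 0.05,
) -> list[ComparisonReport]:
    """Build one ComparisonReport per stratum and metric.

    Records are stratified by ``group`` (the table-per-mechanism layout:
    mechanism x cohort status); within each stratum, per-repetition
    scores are averaged over datasets, and the Wilcoxon/BH machinery is
    applied per metric.
    """
    strata: dict[tuple, list[ScoreRecord]] = {}
    for r in records:
        key = tuple(getattr(r, g) for g in group)
        strata.setdefault(key, []).append(r)

    reports = []
    for key in sorted(strata):
        recs = strata[key]
        for metric in ("mae", "rmse"):
            vectors = _vectors_from_records(recs, metric)
            summary = {c: (v.mean, v.sd) for c, v in vectors.items()}
            n_reps = min(v.values.size for v in vectors.values())
            # intra-method winners: BH family = the per-method scale tests
            methods = sorted({m for m, _ in vectors})
            intra: dict[str, str] = {}
            testable = [
                m
                for m in methods
                if (m, "beta") in vectors and (m, "M") in vectors and n_reps >= 5
            ]
            if testable:
                raw = np.array(
                    [
                        paired_wilcoxon(vectors[(m, "beta")].values, vectors[(m, "M")].values)[0]
                        for m in testable
                    ]
                )
                adj = bh_adjust(raw)
                for m, p in zip(testable, adj):
                    intra[m] = intra_method_winner(
                        vectors[(m, "beta")], vectors[(m, "M")], alpha, adjusted_p=float(p)
                    )
            vec_list = list(vectors.values())
            if len(vec_list) >= 2 and n_reps >= 5:
                best, padj = best_method_set(vec_list, alpha, return_pmatrix=True)
                adjusted = {
                    (f"{vec_list[i].method}|{vec_list[i].scale}", f"{vec_list[j].method}|{vec_list[j].scale}"): float(padj[i, j])
                    for i in range(len(vec_list))
                    for j in range(i + 1, len(vec_list))
                }
            else:
                # a single cell, or too few repetitions to test: no cell can
                # be significantly worse, so all cells qualify
                best = {v.cell for v in vec_list}
                adjusted = {}
            reports.append(
                ComparisonReport(
                    stratum=key,
                    metric=metric,
                    summary=summary,
                    intra_winners=intra,
                    best_set=best,
                    alpha=alpha,
                    adjusted_p=adjusted,
                )
            )
    return reports


def render_report(report: ComparisonReport) -> str:
    """Plain-text table: mean +- sd per cell, '*' marks the winning scale
    within a method, '[best]' marks cells in the relaxed best set."""
    lines = [
        f"stratum={'/'.join(map(str, report.stratum))}  metric={report.metric.upper()}  alpha={report.alpha}",
        f"{'method':<14}{'scale':<7}{'mean±sd':<20}flags",
    ]
    for (method, scale), (mu, sd) in sorted(report.summary.items()):
        flags = []
        winner = report.intra_winners.get(method)
        if winner == scale:
            flags.append("*")
        if (method, scale) in report.best_set:
            flags.append("[best]")
        lines.append(f"{method:<14}{scale:<7}{mu:.4f} ±{sd:.4f}     {' '.join(flags)}")
    return "\n".join(lines)
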