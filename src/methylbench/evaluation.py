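"""Score imputations against held-out truth, always on the beta scale.

Both MAE and RMSE are computed over the masked positions that the
method actually imputed; positions a method could not impute are
ignored and counted.  Imputations run on the M scale are converted back
to beta-values before scoring, so the two representations share one
evaluation surface.  Per-bin profiles use ten equal-width bins on the
TRUE beta value ([0, 0.1), ..., [0.9, 1.0], last bin right-closed),
exposing the value-dependent difficulty of imputation (mid-range
beta-values carry more variance and are harder to impute).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .imputation import ImputationOutcome
from .matrix import Scale
from .missingness import MaskedDataset
from .representation import m_to_beta

__all__ = ["mae", "rmse", "BinScore", "ScoreRecord", "score_imputation", "profile_by_range"]


class UndefinedScoreError(ValueError):
    """No positions could be scored (empty vectors or all unimputable)."""


def _check(pred, truth):
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape:
        raise ValueError("prediction and truth vectors must have equal length")
    if pred.size == 0:
        raise UndefinedScoreError("cannot score an empty vector")
    return pred, truth


def mae(pred, truth) -> float:
    """Mean absolute error, sum |P_i - T_i| / n."""
    pred, truth = _check(pred, truth)
    return float(np.mean(np.abs(pred - truth)))


def rmse(pred, truth) -> float:
    """Root mean square error, sqrt(sum (P_i - T_i)^2 / n); >= MAE by Jensen."""
    pred, truth = _check(pred, truth)
    return float(np.sqrt(np.mean((pred - truth) ** 2)))


@dataclass(frozen=True)
class BinScore:
    lo: float
    hi: float
    n: int
    mae: float
    rmse: float


@dataclass
class ScoreRecord:
    """One (dataset, method, scale, mechanism, repetition) evaluation."""

    dataset: str
    method: str
    scale: str
    mechanism: str
    repetition: int
    n_scored: int
    n_ignored: int
    mae: float
    rmse: float
    per_bin: list[BinScore] = field(default_factory=list)
    status: str = "healthy"


def score_imputation(
    masked: MaskedDataset,
    outcome: ImputationOutcome,
    bins: int = 10,
    dataset: str = "",
    method: str = "",
    repetition: int = 0,
    status: str = "healthy",
) -> ScoreRecord:
    """Gather predictions at the masked positions and score them.

    Predictions from an M-scale imputation are converted to beta-values
    first.  Unimputable positions are excluded from scoring and counted
    in ``n_ignored``.
    """
    imputed = outcome.imputed
    if imputed.values.shape != masked.matrix.values.shape:
        raise ValueError("imputation outcome does not match the masked dataset")
    pos = masked.positions
    keep = np.array(
        [(int(i), int(j)) not in outcome.unimputable for i, j in pos], dtype=bool
    )
    pred = imputed.values[pos[keep, 0], pos[keep, 1]]
    truth = masked.truth[keep]
    # a position can also be unimputable without being listed (defensive)
    ok = ~np.isnan(pred)
    pred, truth = pred[ok], truth[ok]
    n_ignored = int(len(pos) - len(pred))
    if len(pred) == 0:
        raise UndefinedScoreError(
            "every masked position was unimputable; no score can be computed"
        )
    if imputed.scale is Scale.M:
        pred = np.asarray(m_to_beta(pred))

    edges = np.linspace(0.0, 1.0, bins + 1)
    idx = np.clip(np.digitize(truth, edges[1:-1]), 0, bins - 1)
    per_bin = []
    for b in range(bins):
        sel = idx == b
        if sel.any():
            per_bin.append(
                BinScore(edges[b], edges[b + 1], int(sel.sum()), mae(pred[sel], truth[sel]), rmse(pred[sel], truth[sel]))
            )
    return ScoreRecord(
        dataset=dataset,
        method=method,
        scale=imputed.scale.value,
        mechanism=masked.mechanism.kind.value,
        repetition=repetition,
        n_scored=int(len(pred)),
        n_ignored=n_ignored,
        mae=mae(pred, truth),
        rmse=rmse(pred, truth),
        per_bin=per_bin,
        status=status,
    )


def profile_by_range(records: list[ScoreRecord]) -> pd.DataFrame:
    """Aggregate per-bin errors over records.

    Returns one row per (method, scale, mechanism, bin) with count-weighted
    mean MAE/RMSE (RMSE pooled as sqrt of the count-weighted mean square).
    """
    if not records:
        raise ValueError("no records to aggregate")
    all_edges = {(b.lo, b.hi) for r in records for b in r.per_bin}
    rows = []
    for r in records:
        for b in r.per_bin:
            rows.append(
                dict(
                    method=r.method,
                    scale=r.scale,
                    mechanism=r.mechanism,
                    lo=b.lo,
                    hi=b.hi,
                    n=b.n,
                    mae=b.mae,
                    msq=b.rmse**2,
                )
            )
    df = pd.DataFrame(rows)
    grouped = df.groupby(["method", "scale", "mechanism", "lo", "hi"], sort=True)
    out = grouped.apply(
        lambda g: pd.Series(
            {
                "n": g["n"].sum(),
                "mae": np.average(g["mae"], weights=g["n"]),
                "rmse": float(np.sqrt(np.average(g["msq"], weights=g["n"]))),
            }
        ),
        include_groups=False,
    ).reset_index()
    # consistency check: all records share the same bin grid where populated
    widths = {round(hi - lo, 12) for lo, hi in all_edges}
    if len(widths) > 1:
        raise ValueError("records use inconsistent bin edges")
    return out
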