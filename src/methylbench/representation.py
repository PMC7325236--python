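"""Conversions between probe intensities, beta-values and M-values.

The Illumina Infinium assay measures a methylated and an unmethylated
fluorescence intensity per CpG.  The beta-value is the regularized
fraction

    beta = max(meth, 0) / (max(meth, 0) + max(unmeth, 0) + alpha),   alpha = 100

and the M-value the regularized log-ratio

    M = log2((max(meth, 0) + alpha) / (max(unmeth, 0) + alpha)),     alpha = 1.

Ignoring the alpha offsets the two are related by a base-2 logit:
M = log2(beta / (1 - beta)) and beta = 2^M / (2^M + 1).  Boundary
beta-values (0 and 1) map to infinite M, so logit conversion clips beta
into [eps, 1 - eps] first; eps is configurable and defaults to 1e-6.

All functions accept scalars or numpy arrays and propagate NaN, which is
how missing entries are represented throughout the package.
"""

from __future__ import annotations

import numpy as np

from .matrix import MethylMatrix, Scale

__all__ = [
    "beta_from_intensities",
    "m_from_intensities",
    "beta_to_m",
    "m_to_beta",
    "convert_matrix",
    "DEFAULT_EPS",
]

DEFAULT_EPS = 1e-6


class UndefinedRatioError(ZeroDivisionError):
    """Both intensities clamp to zero and alpha is zero: beta is undefined."""


def beta_from_intensities(meth, unmeth, alpha: float = 100.0):
    """Beta-value from a (methylated, unmethylated) intensity pair.

    Negative intensities are legal inputs and are clamped to zero.  The
    nonnegative offset ``alpha`` regularizes the ratio when both
    intensities are low; with alpha > 0 the result lies in [0, 1).
    """
    if alpha < 0:
        raise ValueError("alpha must be nonnegative")
    meth = np.clip(np.asarray(meth, dtype=float), 0.0, None)
    unmeth = np.clip(np.asarray(unmeth, dtype=float), 0.0, None)
    denom = meth + unmeth + alpha
    if np.any(denom == 0.0):
        raise UndefinedRatioError(
            "both intensities clamp to 0 and alpha=0: beta-value undefined"
        )
    out = meth / denom
    return float(out) if out.ndim == 0 else out


def m_from_intensities(meth, unmeth, alpha: float = 1.0):
    """M-value (log2 intensity ratio) from an intensity pair; alpha > 0."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    meth = np.clip(np.asarray(meth, dtype=float), 0.0, None)
    unmeth = np.clip(np.asarray(unmeth, dtype=float), 0.0, None)
    out = np.log2((meth + alpha) / (unmeth + alpha))
    return float(out) if out.ndim == 0 else out


def beta_to_m(b, eps: float = DEFAULT_EPS):
    """Base-2 logit: M = log2(b / (1 - b)) after clipping b into [eps, 1-eps].

    NaN entries (missing values) pass through unchanged; any finite value
    outside [0, 1] raises a domain error.
    """
    b = np.asarray(b, dtype=float)
    finite = ~np.isnan(b)
    if np.any((b[finite] < 0.0) | (b[finite] > 1.0)):
        raise ValueError("beta-values must lie in [0, 1]")
    clipped = np.clip(b, eps, 1.0 - eps)
    out = np.log2(clipped / (1.0 - clipped))
    return float(out) if out.ndim == 0 else out


def m_to_beta(m):
    """Inverse base-2 logit: beta = 2^M / (2^M + 1), overflow-safe.

    Computed as a logistic in a branch-free form so that large |M| never
    overflows; the result is always in the open interval (0, 1).  NaN
    passes through.
    """
    m = np.asarray(m, dtype=float)
    # logistic(x) with x = m * ln 2, evaluated stably on both tails
    x = m * np.log(2.0)
    out = np.empty_like(x)
    pos = x >= 0
    with np.errstate(over="ignore"):
        out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
        ex = np.exp(x[~pos])
        out[~pos] = ex / (1.0 + ex)
    # keep strictly inside (0,1) even at extreme M
    tiny = np.finfo(float).tiny
    out = np.where(np.isnan(m), np.nan, np.clip(out, tiny, 1.0 - np.finfo(float).epsneg))
    return float(out) if out.ndim == 0 else out


def convert_matrix(
    x: MethylMatrix, target: Scale | str, eps: float = DEFAULT_EPS
) -> MethylMatrix:
    """Convert a whole matrix between the beta and M scales.

    Conversion applies elementwise to observed entries only; missing
    entries (NaN) stay missing, so missingness is representation
    invariant.  Converting to the current scale returns an identical
    copy.
    """
    target = Scale(target)
    if x.scale is target:
        return x.copy()
    if x.scale is Scale.BETA and target is Scale.M:
        vals = beta_to_m(x.values, eps=eps)
    elif x.scale is Scale.M and target is Scale.BETA:
        vals = m_to_beta(x.values)
    else:  # pragma: no cover - enum exhausts the cases
        raise ValueError(f"unknown scale conversion {x.scale} -> {target}")
    return MethylMatrix(vals, list(x.sample_ids), list(x.cpg_ids), target)
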