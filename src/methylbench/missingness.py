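"""Simulate MCAR, MAR and MNAR missing values on a methylation matrix.

All simulators mask exactly round(fraction * n_samples * n_cpgs)
positions — 3% of the dataset size by default — drawn without
replacement from the currently observed entries, and record the held-out
ground truth on the beta scale so that the same masked positions can be
imputed under either representation.

Mechanisms
----------
MCAR   positions drawn uniformly at random.
MAR    position probability proportional to a per-CpG propensity weight
       (uniform across samples within a CpG); weights can be estimated
       from observed missingness frequencies.
MNAR   each draw falls, with probability ``in_range_prob`` (default
       0.70), uniformly inside a chosen beta-value range — [0, 0.2]
       (low), [0.4, 0.6] (mid) or [0.8, 1] (high) — and otherwise
       uniformly outside it; if one pool empties the remaining draws
       come from the other pool and a warning counter is incremented.
"""

from __future__ import annotations

import csv
import enum
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .matrix import MethylMatrix, Scale
from .synthetic import PropensityProfile

__all__ = [
    "Mechanism",
    "MechanismSpec",
    "MaskedDataset",
    "target_count",
    "simulate_mcar",
    "simulate_mar",
    "simulate_mnar",
    "estimate_mar_weights",
    "simulate",
    "MNAR_RANGES",
    "InfeasibleMaskError",
]

MNAR_RANGES: dict[str, tuple[float, float]] = {
    "MNAR_LOW": (0.0, 0.2),
    "MNAR_MID": (0.4, 0.6),
    "MNAR_HIGH": (0.8, 1.0),
}

DEFAULT_FRACTION = 0.03
DEFAULT_IN_RANGE_PROB = 0.70


class Mechanism(str, enum.Enum):
    MCAR = "MCAR"
    MAR = "MAR"
    MNAR_LOW = "MNAR_LOW"
    MNAR_MID = "MNAR_MID"
    MNAR_HIGH = "MNAR_HIGH"

    @property
    def beta_range(self) -> tuple[float, float] | None:
        return MNAR_RANGES.get(self.value)


class InfeasibleMaskError(ValueError):
    """The requested number of masked positions cannot be drawn."""


@dataclass(frozen=True)
class MechanismSpec:
    """Full description of one masking draw."""

    kind: Mechanism
    fraction: float = DEFAULT_FRACTION
    in_range_prob: float = DEFAULT_IN_RANGE_PROB
    beta_range: tuple[float, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", Mechanism(self.kind))
        if not 0.0 < self.fraction < 1.0:
            raise ValueError("fraction must lie in (0, 1)")
        if not 0.0 <= self.in_range_prob <= 1.0:
            raise ValueError("in_range_prob must lie in [0, 1]")
        if self.beta_range is None and self.kind.beta_range is not None:
            object.__setattr__(self, "beta_range", self.kind.beta_range)


@dataclass
class MaskedDataset:
    """A matrix with simulated missing entries plus the held-out truth.

    ``positions`` is an (k, 2) integer array of (sample, CpG) indices;
    ``truth`` holds the pre-masking beta values at those positions.
    """

    matrix: MethylMatrix
    positions: np.ndarray
    truth: np.ndarray
    mechanism: MechanismSpec
    warnings: int = 0

    def restore(self) -> MethylMatrix:
        """Put the truth back — reproduces the original matrix bit-exactly."""
        out = self.matrix.copy()
        out.values[self.positions[:, 0], self.positions[:, 1]] = self.truth
        return out

    def write_positions_csv(self, path: str | Path, repetition: int = 0) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["sample_id", "cpg_id", "truth_beta", "mechanism", "repetition", "seed"])
            for (i, j), t in zip(self.positions, self.truth):
                w.writerow(
                    [
                        self.matrix.sample_ids[i],
                        self.matrix.cpg_ids[j],
                        repr(float(t)),
                        self.mechanism.kind.value,
                        repetition,
                        self.mechanism.seed,
                    ]
                )


def target_count(x: MethylMatrix, fraction: float) -> int:
    """Number of positions to mask: round-half-up of fraction * all entries.

    All entries (observed or not) count toward the dataset "size";
    masking itself only ever draws from currently observed entries.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    count = math.floor(fraction * x.n_samples * x.n_cpgs + 0.5)
    n_observed = x.values.size - x.n_missing
    if count < 1:
        raise InfeasibleMaskError("requested fraction masks no entries")
    if count > n_observed:
        raise InfeasibleMaskError(
            f"cannot mask {count} positions: only {n_observed} observed entries"
        )
    return count


def _finish(
    x: MethylMatrix, flat: np.ndarray, spec: MechanismSpec, warnings: int = 0
) -> MaskedDataset:
    positions = np.column_stack(np.unravel_index(flat, x.values.shape))
    truth = x.values[positions[:, 0], positions[:, 1]].copy()
    masked = x.copy()
    masked.values[positions[:, 0], positions[:, 1]] = np.nan
    return MaskedDataset(masked, positions, truth, spec, warnings=warnings)


def simulate_mcar(x: MethylMatrix, fraction: float = DEFAULT_FRACTION, seed: int = 0) -> MaskedDataset:
    """Mask positions drawn uniformly without replacement from observed entries."""
    count = target_count(x, fraction)
    rng = np.random.default_rng(seed)
    observed = np.flatnonzero(~x.mask.ravel())
    flat = rng.choice(observed, size=count, replace=False)
    return _finish(x, flat, MechanismSpec(Mechanism.MCAR, fraction, seed=seed))


def estimate_mar_weights(mask: np.ndarray, pseudocount: float = 0.5) -> PropensityProfile:
    """Per-CpG propensity weights from observed missingness frequencies.

    weight_j is proportional to (missing count in CpG j + pseudocount);
    the pseudocount keeps never-missing CpGs maskable and makes a fully
    observed matrix yield a uniform profile.
    """
    mask = np.asarray(mask, dtype=bool)
    counts = mask.sum(axis=0).astype(float)
    return PropensityProfile(counts + pseudocount)


def simulate_mar(
    x: MethylMatrix,
    fraction: float = DEFAULT_FRACTION,
    weights: PropensityProfile | np.ndarray | None = None,
    seed: int = 0,
) -> MaskedDataset:
    """Mask positions with probability proportional to their CpG's weight.

    Sampling is without replacement (Efraimidis–Spirakis exponential
    keys), uniform across samples within a CpG.
    """
    count = target_count(x, fraction)
    if weights is None:
        weights = estimate_mar_weights(x.mask)
    w = weights.weights if isinstance(weights, PropensityProfile) else np.asarray(weights, float)
    if len(w) != x.n_cpgs:
        raise ValueError("weights length must equal number of CpGs")
    if np.all(w <= 0):
        raise ValueError("MAR weights are all zero")
    rng = np.random.default_rng(seed)
    observed = np.flatnonzero(~x.mask.ravel())
    w_cell = w[observed % x.n_cpgs]
    eligible = observed[w_cell > 0]
    w_cell = w_cell[w_cell > 0]
    if count > eligible.size:
        raise InfeasibleMaskError("not enough positively weighted observed entries")
    # weighted sampling without replacement: smallest Exp(1)/w keys win
    keys = rng.exponential(size=eligible.size) / w_cell
    flat = eligible[np.argpartition(keys, count - 1)[:count]]
    return _finish(x, flat, MechanismSpec(Mechanism.MAR, fraction, seed=seed))


def simulate_mnar(
    x: MethylMatrix,
    fraction: float = DEFAULT_FRACTION,
    beta_range: tuple[float, float] = MNAR_RANGES["MNAR_LOW"],
    in_range_prob: float = DEFAULT_IN_RANGE_PROB,
    seed: int = 0,
    kind: Mechanism | None = None,
) -> MaskedDataset:
    """Mask positions, each with probability ``in_range_prob`` of lying
    inside ``beta_range`` (draws without replacement from the in-range /
    out-of-range pools; an exhausted pool redirects the remaining draws
    to the other pool and counts a warning).
    """
    if x.scale is not Scale.BETA:
        raise ValueError("MNAR masking requires a beta-scale matrix")
    count = target_count(x, fraction)
    lo, hi = beta_range
    rng = np.random.default_rng(seed)
    vals = x.values.ravel()
    obs = ~np.isnan(vals)
    in_pool = np.flatnonzero(obs & (vals >= lo) & (vals <= hi))
    out_pool = np.flatnonzero(obs & ~((vals >= lo) & (vals <= hi)))

    # sequential semantics: per-draw coin picks the pool; once a pool has
    # emptied, every remaining draw is forced from the other pool and
    # increments the warning counter
    coins = rng.random(count) < in_range_prob
    wanted_in = int(coins.sum())
    n_in, n_out, warnings = wanted_in, count - wanted_in, 0
    if wanted_in > in_pool.size:
        hits = np.flatnonzero(coins)
        t = 0 if in_pool.size == 0 else int(hits[in_pool.size - 1]) + 1
        warnings = count - t
        n_in = in_pool.size
        n_out = count - n_in
    elif count - wanted_in > out_pool.size:
        misses = np.flatnonzero(~coins)
        s = 0 if out_pool.size == 0 else int(misses[out_pool.size - 1]) + 1
        warnings = count - s
        n_out = out_pool.size
        n_in = count - n_out
    if n_in > in_pool.size or n_out > out_pool.size:
        raise InfeasibleMaskError("both value pools exhausted before target count")
    parts = []
    if n_in:
        parts.append(rng.choice(in_pool, size=n_in, replace=False))
    if n_out:
        parts.append(rng.choice(out_pool, size=n_out, replace=False))
    flat = np.concatenate(parts) if parts else np.empty(0, dtype=int)
    mech = kind if kind is not None else Mechanism.MNAR_LOW
    spec = MechanismSpec(mech, fraction, in_range_prob, beta_range, seed)
    return _finish(x, flat, spec, warnings=warnings)


def simulate(
    x: MethylMatrix,
    mechanism: Mechanism | str,
    fraction: float = DEFAULT_FRACTION,
    weights: PropensityProfile | None = None,
    in_range_prob: float = DEFAULT_IN_RANGE_PROB,
    seed: int = 0,
) -> MaskedDataset:
    """Dispatch on the mechanism name."""
    mech = Mechanism(mechanism)
    if mech is Mechanism.MCAR:
        return simulate_mcar(x, fraction, seed)
    if mech is Mechanism.MAR:
        return simulate_mar(x, fraction, weights, seed)
    return simulate_mnar(
        x, fraction, mech.beta_range, in_range_prob, seed, kind=mech
    )
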