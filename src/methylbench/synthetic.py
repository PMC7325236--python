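"""Synthetic methylation cohorts with array-like statistical structure.

The generator reproduces the features of 450k-array beta-value matrices
that the downstream benchmark depends on:

* a bimodal marginal beta distribution with most mass near 0 and 1
  (unmethylated / methylated CpG classes, plus a smaller mid-range
  class);
* heteroscedastic per-CpG noise — Beta-distributed observations with a
  common concentration kappa have variance mu (1 - mu) / (kappa + 1),
  maximal mid-range and compressed at the extremes;
* strong inter-sample correlation, induced by a low-rank factor model
  acting on the logit of the per-CpG baseline (this is the signal that
  regression-based imputation exploits);
* a subpopulation of "high-missingness" CpGs whose beta distribution is
  shifted into the mid-range and which carry most of the baseline
  missingness propensity (the empirical picture behind missing-at-random
  simulation: ~11% of CpGs account for the frequently-missing columns);
* a disease mode with lower concentration (higher dispersion), mirroring
  the methylation heterogeneity of disease tissue.

Dispersion knobs: kappa defaults to 60 for healthy cohorts and 15 for
disease cohorts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .matrix import MethylMatrix, Scale

__all__ = [
    "CohortConfig",
    "PropensityProfile",
    "generate_cohort",
    "apply_baseline_missingness",
    "DISEASE_KAPPA",
]

logger = logging.getLogger(__name__)

DISEASE_KAPPA = 15.0

# clip bounds keeping Beta parameters and logits well behaved
_MU_LO, _MU_HI = 1e-3, 1.0 - 1e-3
_BETA_LO, _BETA_HI = 1e-6, 1.0 - 1e-6


def _logit(p):
    return np.log(p / (1.0 - p))


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of one synthetic cohort.

    ``class_props`` are the proportions of the unmethylated / mid-range /
    methylated CpG classes with baseline means ``class_means``;
    high-propensity CpGs (fraction ``high_missing_frac``) draw their
    class from ``high_class_props`` instead, which shifts their beta
    distribution into the mid-range.  ``kappa`` is the Beta
    concentration (dispersion knob); ``latent_rank`` factors on the
    logit scale induce inter-sample correlation.  ``propensity_ratio``
    is the relative baseline-missingness weight of high- vs
    normal-propensity CpGs.
    """

    n_samples: int = 50
    n_cpgs: int = 1000
    class_props: tuple[float, float, float] = (0.38, 0.14, 0.48)
    class_means: tuple[float, float, float] = (0.08, 0.50, 0.92)
    kappa: float = 60.0
    latent_rank: int = 3
    latent_scale: float = 0.35
    baseline_jitter: float = 0.6
    high_missing_frac: float = 0.11
    high_class_props: tuple[float, float, float] = (0.15, 0.60, 0.25)
    propensity_ratio: float = 150.0
    status: str = "healthy"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.n_cpgs < 1:
            raise ConfigError("n_samples and n_cpgs must be positive")
        for props in (self.class_props, self.high_class_props):
            if len(props) != 3 or abs(sum(props) - 1.0) > 1e-9 or min(props) < 0:
                raise ConfigError("class proportions must be a probability triple")
        if not all(0.0 < m < 1.0 for m in self.class_means):
            raise ConfigError("class means must lie strictly inside (0, 1)")
        if self.kappa <= 0:
            raise ConfigError("kappa must be positive")
        if self.latent_rank < 0:
            raise ConfigError("latent_rank must be nonnegative")
        if not 0.0 <= self.high_missing_frac < 1.0:
            raise ConfigError("high_missing_frac must be in [0, 1)")
        if self.propensity_ratio <= 0:
            raise ConfigError("propensity_ratio must be positive")

    @classmethod
    def disease(cls, **kwargs) -> "CohortConfig":
        """Disease-mode defaults: same structure, higher dispersion."""
        kwargs.setdefault("kappa", DISEASE_KAPPA)
        kwargs.setdefault("status", "disease")
        return cls(**kwargs)

    def with_(self, **kwargs) -> "CohortConfig":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class PropensityProfile:
    """Per-CpG baseline missingness weights, normalized to sum to one."""

    weights: np.ndarray
    high_cpgs: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < 0):
            raise ConfigError("propensity weights must be nonnegative")
        total = w.sum()
        if total <= 0:
            raise ConfigError("propensity weights must have positive sum")
        object.__setattr__(self, "weights", w / total)
        object.__setattr__(self, "high_cpgs", np.asarray(self.high_cpgs, dtype=int))

    @classmethod
    def uniform(cls, n_cpgs: int) -> "PropensityProfile":
        return cls(np.full(n_cpgs, 1.0 / n_cpgs))

    def __len__(self) -> int:
        return len(self.weights)


def generate_cohort(cfg: CohortConfig) -> tuple[MethylMatrix, PropensityProfile]:
    """Draw one fully observed beta-scale cohort and its propensity profile.

    Per CpG j: a class c_j (high-propensity CpGs use the mid-shifted
    class proportions), a baseline mean mu_j from a logit-normal jitter
    around the class mean, and per-sample means mu_ij obtained by adding
    a rank-``latent_rank`` sample-factor perturbation on the logit
    scale.  Observations are Beta(mu_ij * kappa, (1 - mu_ij) * kappa).
    Deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    n, p = cfg.n_samples, cfg.n_cpgs

    n_high = int(round(cfg.high_missing_frac * p))
    high = rng.choice(p, size=n_high, replace=False)
    is_high = np.zeros(p, dtype=bool)
    is_high[high] = True

    classes = np.empty(p, dtype=int)
    classes[~is_high] = rng.choice(3, size=p - n_high, p=cfg.class_props)
    classes[is_high] = rng.choice(3, size=n_high, p=cfg.high_class_props)

    mu_base = _expit(
        _logit(np.asarray(cfg.class_means)[classes])
        + cfg.baseline_jitter * rng.standard_normal(p)
    )

    eta = np.tile(_logit(np.clip(mu_base, _MU_LO, _MU_HI)), (n, 1))
    if cfg.latent_rank > 0:
        factors = rng.standard_normal((n, cfg.latent_rank))
        loadings = rng.standard_normal((cfg.latent_rank, p)) * (
            cfg.latent_scale / np.sqrt(cfg.latent_rank)
        )
        eta = eta + factors @ loadings
    mu = np.clip(_expit(eta), _MU_LO, _MU_HI)

    beta = rng.beta(mu * cfg.kappa, (1.0 - mu) * cfg.kappa)
    beta = np.clip(beta, _BETA_LO, _BETA_HI)

    weights = np.where(is_high, cfg.propensity_ratio, 1.0)
    profile = PropensityProfile(weights, high_cpgs=np.sort(high))

    matrix = MethylMatrix(
        beta,
        sample_ids=[f"S{i:04d}" for i in range(n)],
        cpg_ids=[f"cg{j:07d}" for j in range(p)],
        scale=Scale.BETA,
    )
    return matrix, profile


def apply_baseline_missingness(
    x: MethylMatrix,
    profile: PropensityProfile,
    overall_rate: float,
    rng_seed: int,
) -> MethylMatrix:
    """Mark entries missing with per-CpG probability proportional to the
    propensity weights, scaled so the expected overall missing fraction
    equals ``overall_rate``.

    This emulates the real-data missingness from which missing-at-random
    weights can then be re-estimated.  Per-CpG probabilities exceeding 1
    after scaling are capped with a logged warning.
    """
    if not 0.0 <= overall_rate < 1.0:
        raise ConfigError("overall_rate must be in [0, 1)")
    if len(profile) != x.n_cpgs:
        raise ConfigError("propensity profile length must equal n_cpgs")
    rng = np.random.default_rng(rng_seed)
    p_col = overall_rate * x.n_cpgs * profile.weights
    if np.any(p_col > 1.0):
        logger.warning(
            "capping %d per-CpG missing probabilities at 1 (requested rate %.3f)",
            int((p_col > 1.0).sum()),
            overall_rate,
        )
        p_col = np.minimum(p_col, 1.0)
    miss = rng.random(x.values.shape) < p_col[None, :]
    out = x.copy()
    out.values[miss] = np.nan
    return out
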