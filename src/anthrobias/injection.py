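"""Error-injection experiment: add non-directional noise and track threshold crossings.

Non-directional measurement error is modelled as an independent, zero-mean
normal perturbation added to each z-score.  It leaves the distribution mean
untouched but inflates its standard deviation from ``sd`` to
``sqrt(sd^2 + error_sd^2)``, moving individual observations across the
indicator threshold in both directions.

Following the mechanism study's terminology, an observation that noise moves
from at-or-above the threshold to below it is a *false positive* (spuriously
counted toward prevalence), and one moved from below to at-or-above is a
*false negative*.  Note this is relative to the noise-free sample, not to a
clinical gold standard.  The net prevalence bias is exactly
``(false_positive - false_negative) / n``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import (
    DEFAULT_THRESHOLD,
    NormalParams,
    PrevalenceEstimate,
    prevalence_empirical,
    simulate_normal,
)
from .exceptions import InvalidInputError, InvalidParameterError


@dataclass(frozen=True)
class NoiseSpec:
    """Additive normal measurement-error model.

    ``error_mean`` defaults to 0 (non-directional error); nonzero values let
    users explore directional error as well, though the bias map assumes the
    non-directional case.
    """

    error_sd: float
    error_mean: float = 0.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.error_sd) and math.isfinite(self.error_mean)):
            raise InvalidParameterError("noise parameters must be finite")
        if self.error_sd < 0:
            raise InvalidParameterError(f"error_sd must be >= 0, got {self.error_sd}")


@dataclass(frozen=True)
class ClassificationCounts:
    """Per-observation tallies of threshold-crossing categories."""

    true_positive: int
    false_positive: int
    true_negative: int
    false_negative: int

    def __post_init__(self) -> None:
        for name in ("true_positive", "false_positive", "true_negative", "false_negative"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")

    @property
    def total(self) -> int:
        return (
            self.true_positive
            + self.false_positive
            + self.true_negative
            + self.false_negative
        )


@dataclass(frozen=True)
class InjectionResult:
    """Before/after summary of one error-injection run."""

    before: PrevalenceEstimate
    after: PrevalenceEstimate
    counts: ClassificationCounts
    sd_before: float
    sd_after: float
    net_bias: float  # (FP - FN) / n, identically after.value - before.value

    def to_dict(self) -> dict:
        return {
            "prevalence_before": self.before.value,
            "prevalence_after": self.after.value,
            "sd_before": self.sd_before,
            "sd_after": self.sd_after,
            "net_bias": self.net_bias,
            "true_positive": self.counts.true_positive,
            "false_positive": self.counts.false_positive,
            "true_negative": self.counts.true_negative,
            "false_negative": self.counts.false_negative,
            "n": self.counts.total,
            "threshold": self.before.threshold,
        }


def inject_noise(samples: np.ndarray, noise: NoiseSpec, seed) -> np.ndarray:
    """Element-wise sum of ``samples`` and independent noise draws.

    Order is preserved so each observation pairs with its perturbed value.
    A zero-SD, zero-mean noise spec returns the input unchanged.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise InvalidInputError("cannot inject noise into an empty sample")
    if noise.error_sd == 0.0 and noise.error_mean == 0.0:
        return samples.copy()
    rng = np.random.Generator(np.random.PCG64(seed))
    return samples + rng.normal(noise.error_mean, noise.error_sd, size=samples.size)


def classify_crossings(
    before: np.ndarray, after: np.ndarray, threshold: float = DEFAULT_THRESHOLD
) -> ClassificationCounts:
    """Assign each (before, after) pair to one of the four crossing categories.

    Uses the strict-below convention: "positive" means strictly below the
    threshold.
    """
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape:
        raise InvalidInputError(
            f"before/after length mismatch: {before.shape} vs {after.shape}"
        )
    if before.size == 0:
        raise InvalidInputError("cannot classify empty collections")
    below_before = before < threshold
    below_after = after < threshold
    return ClassificationCounts(
        true_positive=int(np.count_nonzero(below_before & below_after)),
        false_positive=int(np.count_nonzero(~below_before & below_after)),
        true_negative=int(np.count_nonzero(~below_before & ~below_after)),
        false_negative=int(np.count_nonzero(below_before & ~below_after)),
    )


def run_injection_experiment(
    params: NormalParams,
    noise: NoiseSpec,
    n: int,
    seed,
    threshold: float = DEFAULT_THRESHOLD,
) -> InjectionResult:
    """Simulate, perturb, classify, and summarise one experiment.

    The base sample and the noise draws use independent child streams spawned
    from ``seed``, so the same base sample can be re-perturbed reproducibly.
    """
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    base_seed, noise_seed = ss.spawn(2)
    samples = simulate_normal(params, n, base_seed)
    perturbed = inject_noise(samples, noise, noise_seed)
    counts = classify_crossings(samples, perturbed, threshold)
    before = prevalence_empirical(samples, threshold)
    after = prevalence_empirical(perturbed, threshold)
    net_bias = (counts.false_positive - counts.false_negative) / counts.total
    return InjectionResult(
        before=before,
        after=after,
        counts=counts,
        sd_before=float(np.std(samples, ddof=1)),
        sd_after=float(np.std(perturbed, ddof=1)),
        net_bias=net_bias,
    )
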