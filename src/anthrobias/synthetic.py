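"""Synthetic survey generator.

Emulates the statistical structure the assessment layer assumes: a latent,
genuinely-normal z-score distribution per indicator; additive zero-mean
(non-directional) measurement error; reported ages that heap on the 24-, 36-
and 48-month clusters; log-normal survey weights; and per-indicator
missingness.  Output tables carry the exact ``age,haz,whz,waz,wt`` column
schema the reader expects, so every assessment operation is testable with no
external data.

Heaping is modelled as snap-to-nearest of the target months for a random
subset of children.  The link between heaping and z-score noise in
``generate_survey_collection`` — surveys with more heaping get more noise —
is a construction used to exercise the cross-survey correlation machinery,
not a mechanistic claim about how caregiver age estimation perturbs
height-for-age in real data.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .exceptions import InvalidParameterError
from .survey import INDICATORS, SurveyTable

DEFAULT_HEAP_TARGETS = (24.0, 36.0, 48.0)

#: LMIC-plausible defaults: stunting-range HAZ mean, mild WHZ/WAZ deficits
DEFAULT_TRUE_MEANS = {"haz": -1.5, "whz": -0.4, "waz": -1.0}


def _per_indicator(value, name: str) -> Dict[str, float]:
    """Broadcast a scalar to all indicators, or validate a mapping's keys."""
    if isinstance(value, dict):
        unknown = set(value) - set(INDICATORS)
        if unknown:
            raise InvalidParameterError(f"{name}: unknown indicator(s) {sorted(unknown)}")
        missing = set(INDICATORS) - set(value)
        if missing:
            raise InvalidParameterError(f"{name}: missing indicator(s) {sorted(missing)}")
        return {k: float(v) for k, v in value.items()}
    return {k: float(value) for k in INDICATORS}


@dataclass(frozen=True)
class SyntheticSurveySpec:
    """All knobs of one synthetic survey.

    ``true_mean``, ``true_sd``, ``noise_sd`` and ``missing_rate`` accept
    either a scalar (applied to haz, whz and waz alike) or a per-indicator
    mapping.  ``noise_sd`` is the total non-directional error SD from all
    sources combined, so the recorded SD is sqrt(true_sd^2 + noise_sd^2) in
    expectation.  ``weight_dispersion`` is the coefficient of variation of
    the log-normal survey weights (normalised to mean 1 per survey).
    """

    n_children: int = 1000
    true_mean: object = field(default_factory=lambda: dict(DEFAULT_TRUE_MEANS))
    true_sd: object = 1.0
    noise_sd: object = 0.0
    heaping_fraction: float = 0.0
    age_range: Tuple[float, float] = (0.0, 59.0)
    heap_targets: Tuple[float, ...] = DEFAULT_HEAP_TARGETS
    weight_dispersion: float = 0.3
    missing_rate: object = 0.0
    seed: int = 0
    survey_id: str = "synthetic"

    def __post_init__(self) -> None:
        if self.n_children < 1:
            raise InvalidParameterError(f"n_children must be >= 1, got {self.n_children}")
        means = _per_indicator(self.true_mean, "true_mean")
        sds = _per_indicator(self.true_sd, "true_sd")
        noise = _per_indicator(self.noise_sd, "noise_sd")
        miss = _per_indicator(self.missing_rate, "missing_rate")
        if any(not math.isfinite(v) for v in means.values()):
            raise InvalidParameterError("true_mean values must be finite")
        if any(v <= 0 for v in sds.values()):
            raise InvalidParameterError("true_sd values must be > 0")
        if any(v < 0 for v in noise.values()):
            raise InvalidParameterError("noise_sd values must be >= 0")
        if any(not 0 <= v < 1 for v in miss.values()):
            raise InvalidParameterError("missing_rate values must lie in [0, 1)")
        if not 0 <= self.heaping_fraction <= 1:
            raise InvalidParameterError(
                f"heaping_fraction must lie in [0, 1], got {self.heaping_fraction}"
            )
        if self.weight_dispersion < 0:
            raise InvalidParameterError("weight_dispersion must be >= 0")
        lo, hi = self.age_range
        if not lo < hi:
            raise InvalidParameterError(f"age_range must satisfy min < max, got {self.age_range}")

    def true_params(self) -> dict:
        """Ground-truth parameters, e.g. for a JSON sidecar in recovery tests."""
        return {
            "n_children": self.n_children,
            "true_mean": _per_indicator(self.true_mean, "true_mean"),
            "true_sd": _per_indicator(self.true_sd, "true_sd"),
            "noise_sd": _per_indicator(self.noise_sd, "noise_sd"),
            "expected_recorded_sd": {
                k: math.sqrt(
                    _per_indicator(self.true_sd, "true_sd")[k] ** 2
                    + _per_indicator(self.noise_sd, "noise_sd")[k] ** 2
                )
                for k in INDICATORS
            },
            "heaping_fraction": self.heaping_fraction,
            "age_range": list(self.age_range),
            "weight_dispersion": self.weight_dispersion,
            "missing_rate": _per_indicator(self.missing_rate, "missing_rate"),
            "seed": self.seed,
            "survey_id": self.survey_id,
        }


def generate_survey(spec: SyntheticSurveySpec, csv_path=None, sidecar_path=None) -> SurveyTable:
    """Draw one synthetic survey; optionally write the CSV and a truth sidecar.

    Per child: true age uniform on ``age_range``; recorded age snapped to
    the nearest heap target with probability ``heaping_fraction``; latent
    z ~ Normal(true_mean, true_sd^2) per indicator; recorded
    z = latent + Normal(0, noise_sd^2); weights log-normal with CV
    ``weight_dispersion`` normalised to mean 1; missingness independent per
    indicator.  Deterministic under ``seed``.
    """
    rng = np.random.Generator(np.random.PCG64(spec.seed))
    n = spec.n_children
    means = _per_indicator(spec.true_mean, "true_mean")
    sds = _per_indicator(spec.true_sd, "true_sd")
    noise = _per_indicator(spec.noise_sd, "noise_sd")
    miss = _per_indicator(spec.missing_rate, "missing_rate")

    lo, hi = spec.age_range
    age = rng.uniform(lo, hi + 1.0, size=n)  # continuous months over [lo, hi+1)
    heaped = rng.random(n) < spec.heaping_fraction
    if heaped.any():
        targets = np.asarray(spec.heap_targets, dtype=float)
        nearest = targets[np.argmin(np.abs(age[:, None] - targets[None, :]), axis=1)]
        age = np.where(heaped, nearest, age)

    cols = {"age": age}
    for ind in INDICATORS:
        z = rng.normal(means[ind], sds[ind], size=n)
        if noise[ind] > 0:
            z = z + rng.normal(0.0, noise[ind], size=n)
        if miss[ind] > 0:
            z = np.where(rng.random(n) < miss[ind], np.nan, z)
        cols[ind] = z

    if spec.weight_dispersion > 0:
        sigma2 = math.log(1.0 + spec.weight_dispersion**2)
        wt = rng.lognormal(-sigma2 / 2.0, math.sqrt(sigma2), size=n)
        wt = wt / wt.mean()  # normalise to mean 1 per survey
    else:
        wt = np.ones(n)
    cols["wt"] = wt

    df = pd.DataFrame(cols, columns=["age", "haz", "whz", "waz", "wt"])
    table = SurveyTable(data=df, survey_id=spec.survey_id)
    if csv_path is not None:
        df.to_csv(csv_path, index=False)
    if sidecar_path is not None:
        with open(sidecar_path, "w") as fh:
            json.dump(spec.true_params(), fh, indent=2)
    return table


def default_noise_link(heaping_fraction: float) -> float:
    """Monotone heaping -> noise link: noise_sd = 2 * heaping_fraction."""
    return 2.0 * heaping_fraction


def generate_survey_collection(
    base_spec: SyntheticSurveySpec,
    k: int = 21,
    heaping_range: Tuple[float, float] = (0.05, 0.5),
    noise_link: Optional[Callable[[float], float]] = None,
    seed: Optional[int] = None,
) -> List[SurveyTable]:
    """Generate ``k`` surveys whose noise rises monotonically with heaping.

    Heaping fractions are evenly spaced over ``heaping_range`` and each
    survey's HAZ noise SD is ``noise_link(heaping_fraction)``, so the
    collection has a positive heaping-vs-SD association by construction —
    mirroring the empirical pattern seen when age estimation drives
    height-for-age error.  Each survey gets an independent child seed.
    """
    if k < 3:
        raise InvalidParameterError(f"need k >= 3 surveys, got {k}")
    if noise_link is None:
        noise_link = default_noise_link
    root = np.random.SeedSequence(base_spec.seed if seed is None else seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(k)]
    heaps = np.linspace(heaping_range[0], heaping_range[1], k)
    tables = []
    for i in range(k):
        h = float(heaps[i])
        noise = _per_indicator(base_spec.noise_sd, "noise_sd")
        noise["haz"] = float(noise_link(h))
        spec_i = replace(
            base_spec,
            heaping_fraction=h,
            noise_sd=noise,
            seed=child_seeds[i],
            survey_id=f"{base_spec.survey_id}-{i + 1:02d}",
        )
        tables.append(generate_survey(spec_i))
    return tables
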