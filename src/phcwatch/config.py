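"""Configuration objects and named data-quality profiles.

The simulator emulates a municipality-level primary-health-care (PHC)
encounter registry with SISAB-like upload behaviour: weekly encounter
counts per municipality, per-record registration delays, optional monthly
batch uploads, and occasional municipality-weeks whose registrations are
postponed past the real-time horizon and only amended later (registries
allow a four-month amendment window after each monthly submission).
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field, replace

__all__ = [
    "AMENDMENT_WINDOW_WEEKS",
    "ConfigError",
    "InputError",
    "SimulationConfig",
    "PROFILES",
    "quality_profile",
    "make_config",
]

#: Length of the late-amendment window in whole weeks (four months).
AMENDMENT_WINDOW_WEEKS = 16


class ConfigError(ValueError):
    """A configuration field is outside its allowed domain."""


class InputError(ValueError):
    """Inputs passed to an operation are inconsistent or unknown."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic registry generator.

    Weekly true incidence per municipality is an overdispersed
    (negative-binomial) count with mean ``baseline_rate`` modulated by a
    multiplicative seasonal cycle and, during outbreak weeks, by
    ``outbreak_fold``.  Registration behaviour is controlled by
    ``delay_pmf`` (distribution of registration delay in whole weeks),
    ``monthly_uploader_fraction`` (municipalities that batch uploads to
    every fourth week) and ``dropout_prob`` (municipality-weeks whose
    registrations slip past the study horizon and arrive only as late
    amendments).
    """

    n_municipalities: int
    n_weeks: int = 23
    baseline_rate: float = 50.0
    dispersion: float = 5.0
    seasonal_amplitude: float = 0.2
    outbreak_prob_per_week: float = 0.02
    outbreak_fold: float = 5.0
    outbreak_duration_weeks: int = 3
    delay_pmf: tuple[float, ...] = (0.6, 0.25, 0.1, 0.05)
    monthly_uploader_fraction: float = 0.0
    dropout_prob: float = 0.0
    forced_outbreak_week: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "delay_pmf", tuple(float(p) for p in self.delay_pmf))
        self._check()

    def _check(self) -> None:
        def bad(name: str, why: str) -> ConfigError:
            return ConfigError(f"{name}: {why} (got {getattr(self, name)!r})")

        if not isinstance(self.n_municipalities, int) or self.n_municipalities < 1:
            raise bad("n_municipalities", "must be a positive integer")
        if not isinstance(self.n_weeks, int) or self.n_weeks < 1:
            raise bad("n_weeks", "must be a positive integer")
        if not self.baseline_rate >= 0:
            raise bad("baseline_rate", "must be nonnegative")
        if not self.dispersion > 0:
            raise bad("dispersion", "must be positive (math.inf gives Poisson counts)")
        if not 0 <= self.seasonal_amplitude < 1:
            raise bad("seasonal_amplitude", "must lie in [0, 1)")
        if not 0 <= self.outbreak_prob_per_week <= 1:
            raise bad("outbreak_prob_per_week", "must be a probability")
        if not self.outbreak_fold > 1:
            raise bad("outbreak_fold", "must exceed 1")
        if not isinstance(self.outbreak_duration_weeks, int) or self.outbreak_duration_weeks < 1:
            raise bad("outbreak_duration_weeks", "must be a positive integer")
        pmf = self.delay_pmf
        if len(pmf) == 0 or any(p < 0 for p in pmf):
            raise bad("delay_pmf", "entries must be nonnegative")
        if abs(sum(pmf) - 1.0) > 1e-9:
            raise bad("delay_pmf", "entries must sum to 1 within 1e-9")
        if not 0 <= self.monthly_uploader_fraction <= 1:
            raise bad("monthly_uploader_fraction", "must be a fraction in [0, 1]")
        if not 0 <= self.dropout_prob <= 1:
            raise bad("dropout_prob", "must be a probability")
        if self.forced_outbreak_week is not None and not (
            0 <= self.forced_outbreak_week < self.n_weeks
        ):
            raise bad("forced_outbreak_week", "must be a week index within the study span")
        if not isinstance(self.seed, int):
            raise bad("seed", "must be an integer")

    def replace(self, **changes) -> "SimulationConfig":
        return replace(self, **changes)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["delay_pmf"] = list(self.delay_pmf)
        if math.isinf(self.dispersion):
            d["dispersion"] = "inf"
        return d


#: Named registration-quality presets spanning the quality spectrum seen
#: across municipalities: prompt same-week uploads, monthly batch uploads,
#: and poor reporters with heavy delays and frequent missed weeks.
PROFILES: dict[str, dict] = {
    "prompt": dict(
        delay_pmf=(1.0,),
        monthly_uploader_fraction=0.0,
        dropout_prob=0.0,
    ),
    "monthly": dict(
        delay_pmf=(0.7, 0.2, 0.1),
        monthly_uploader_fraction=1.0,
        dropout_prob=0.0,
    ),
    "poor": dict(
        delay_pmf=(0.10, 0.10, 0.10, 0.20, 0.20, 0.15, 0.10, 0.05),
        monthly_uploader_fraction=0.5,
        dropout_prob=0.25,
    ),
}


def quality_profile(name: str) -> dict:
    """Return the partial configuration for a named quality profile.

    Raises :class:`InputError` listing the valid profile names when the
    name is unknown.
    """
    try:
        return dict(PROFILES[name])
    except KeyError:
        valid = ", ".join(sorted(PROFILES))
        raise InputError(f"unknown quality profile {name!r}; valid profiles: {valid}") from None


def make_config(n_municipalities: int, *, profile: str | None = None, **overrides) -> SimulationConfig:
    """Build a :class:`SimulationConfig`, optionally starting from a profile.

    Explicit keyword overrides take precedence over profile fields.
    """
    fields: dict = {}
    if profile is not None:
        fields.update(quality_profile(profile))
    fields.update(overrides)
    return SimulationConfig(n_municipalities=n_municipalities, **fields)
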