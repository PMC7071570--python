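"""Core domain types shared by every pipeline stage.

The package operates on tabular EMR extracts (one CSV per table) and a
single run configuration.  Records are represented as plain dataclasses
where per-record logic matters (the classifier) and as pandas DataFrames
everywhere throughput matters.
"""
from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from enum import Enum


class SmokingStatus(str, Enum):
    """Five-level calculated smoking status.

    ``not_current`` means the record implies the patient does not smoke
    now without distinguishing a former smoker from a never smoker
    (e.g. "non-smoker").  It is a legitimate classifier *output* but is
    never a valid *imputed* value.  ``unknown`` is the only level that
    is recoded to missing before imputation.
    """

    CURRENT = "current"
    PAST = "past"
    NEVER = "never"
    NOT_CURRENT = "not_current"
    UNKNOWN = "unknown"


#: categories a classifier may assign from text (everything but unknown)
ASSIGNABLE_CATEGORIES = ("current", "past", "never", "not_current")
#: categories a missing smoking cell may be imputed to
IMPUTABLE_CATEGORIES = ("current", "past", "never")
#: all five status levels
STATUS_LEVELS = ("current", "past", "never", "not_current", "unknown")


class ConfigError(ValueError):
    """Raised when a run configuration violates an invariant."""


class ImputationError(RuntimeError):
    """Raised when an imputation precondition fails (e.g. a degenerate
    category under the MNAR restriction)."""


@dataclass(frozen=True)
class RiskFactorRecord:
    """One raw EMR smoking entry: three free-text fields plus a date.

    ``entry_date`` may be ``None`` (undated record, kept but flagged);
    text fields are canonical strings, never ``None``.
    """

    patient_id: str
    entry_date: dt.date | None
    name_text: str = ""
    value_text: str = ""
    status_text: str = ""

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise ValueError("patient_id must be non-empty")


@dataclass
class RunConfig:
    """Run parameters.

    Defaults are the study conditions: a two-year activity window
    (2016-07-01 to 2018-06-30), at least one encounter in the window
    (three for the sensitivity analysis), BMI plausibility limits of
    12-70 kg/m^2 with a 10 kg/m^2 maximum jump between retained
    measurements, 40 imputed datasets with 5 chained-equation
    iterations, and a 40.8% missingness-injection fraction for the
    error simulation.
    """

    window_start: dt.date = dt.date(2016, 7, 1)
    window_end: dt.date = dt.date(2018, 6, 30)
    min_encounters: int = 1
    bmi_min: float = 12.0
    bmi_max: float = 70.0
    bmi_max_jump: float = 10.0
    mi_m: int = 40
    mi_iterations: int = 5
    mi_strategy: str = "mar_all"  # or "mnar_no_current"
    mi_param_draw: str = "bootstrap"  # or "posterior"
    missing_injection_fraction: float = 0.408
    seed: int = 0

    _STRATEGIES = ("mar_all", "mnar_no_current")
    _PARAM_DRAWS = ("bootstrap", "posterior")

    def validate(self) -> "RunConfig":
        if not isinstance(self.window_start, dt.date) or not isinstance(
            self.window_end, dt.date
        ):
            raise ConfigError("window_start/window_end must be dates")
        if not self.window_start < self.window_end:
            raise ConfigError("window_start must precede window_end")
        if self.min_encounters < 0:
            raise ConfigError("min_encounters must be >= 0")
        if not 0 < self.bmi_min < self.bmi_max:
            raise ConfigError("bmi_min must satisfy 0 < bmi_min < bmi_max")
        if self.bmi_max_jump <= 0:
            raise ConfigError("bmi_max_jump must be positive")
        if self.mi_m < 2:
            raise ConfigError("mi_m must be >= 2")
        if self.mi_iterations < 1:
            raise ConfigError("mi_iterations must be >= 1")
        if self.mi_strategy not in self._STRATEGIES:
            raise ConfigError(f"mi_strategy must be one of {self._STRATEGIES}")
        if self.mi_param_draw not in self._PARAM_DRAWS:
            raise ConfigError(f"mi_param_draw must be one of {self._PARAM_DRAWS}")
        if not 0 < self.missing_injection_fraction < 1:
            raise ConfigError("missing_injection_fraction must be in (0, 1)")
        if not isinstance(self.seed, int):
            raise ConfigError("seed must be an integer")
        return self
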