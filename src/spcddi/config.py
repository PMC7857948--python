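"""Analysis configuration.

All tunable constants of the alert-filtering analysis live in
:class:`AnalysisConfig`: the INR excursion thresholds that define VKA
potentiation / inhibition, the observation-window lags (onset of action and
residual post-discontinuation action, in whole days), the minimum number of
exposed stays required before odds ratios are estimated, the type-I error
level, and the ATC prefix that identifies vitamin K antagonists.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass(frozen=True)
class AnalysisConfig:
    """Constants of the DDI-rule analysis.

    Attributes
    ----------
    inr_high_threshold : float
        INR at or above this value counts as VKA potentiation (default 5.0).
    inr_low_threshold : float
        INR at or below this value counts as VKA inhibition (default 1.5).
    onset_lag_days : int
        Days between the triggering drug event and the start of the
        observation window (drug onset of action; default 1).
    offset_lag_days : int
        Days of residual drug action appended after discontinuation
        (default 4).
    min_exposed_stays : int
        Minimum number of exposed stays for a rule to be estimated
        (default 3; rules below it are flagged ``insufficient_data``).
    alpha : float
        Two-sided type-I error for all confidence limits (default 0.05).
    vka_atc_prefix : str
        ATC prefix identifying vitamin K antagonists (default ``B01AA``).
    delimiter : str
        Field delimiter of the cohort CSV files.
    basis : str
        Which OR tier drives alert decisions: ``unadjusted``, ``adjusted``
        or ``stepwise`` (default).
    deactivate_nonsignificant : bool
        Whether rules with no significant association have their alert
        turned off (default True).
    separation_bound : float
        |log-OR| above which a logistic fit is flagged non-computable.
    """

    inr_high_threshold: float = 5.0
    inr_low_threshold: float = 1.5
    onset_lag_days: int = 1
    offset_lag_days: int = 4
    min_exposed_stays: int = 3
    alpha: float = 0.05
    vka_atc_prefix: str = "B01AA"
    delimiter: str = ","
    basis: str = "stepwise"
    deactivate_nonsignificant: bool = True
    separation_bound: float = 15.0

    def __post_init__(self) -> None:
        if not self.inr_low_threshold < self.inr_high_threshold:
            raise ValueError("inr_low_threshold must be < inr_high_threshold")
        if self.onset_lag_days < 0 or self.offset_lag_days < 0:
            raise ValueError("window lags must be non-negative")
        if self.min_exposed_stays < 1:
            raise ValueError("min_exposed_stays must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.basis not in ("unadjusted", "adjusted", "stepwise"):
            raise ValueError(f"unknown basis {self.basis!r}")

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        """Load a config from a YAML or JSON file (keys as in the dataclass)."""
        path = Path(path)
        with open(path, encoding="utf-8") as fh:
            data = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
        if data is None:
            data = {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


DEFAULT_CONFIG = AnalysisConfig()
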