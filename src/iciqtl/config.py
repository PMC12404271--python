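"""Study-level configuration.

A :class:`StudyConfig` carries every constant the pipeline stages share: the
first dosing day, the tumor-volume detection limit, the 21-day horizon of the
rate-based tumor/control (RTC) statistic, permutation/bootstrap replicate
counts, the significance level, and the weights of the combined response
trait.  Configurations load from YAML or JSON and validate on construction.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import ParameterError, ValidationError

#: Arm labels seen in the wild mapped onto the two canonical arms.  The study
#: vocabulary uses "isotype" for the control antibody and "aPD1" for the
#: PD-1-blocking treatment.
DEFAULT_ARM_ALIASES: dict[str, str] = {
    "control": "control",
    "isotype": "control",
    "treated": "treated",
    "apd1": "treated",
    "apd-1": "treated",
    "anti-pd1": "treated",
}

ARMS = ("control", "treated")


@dataclass
class StudyConfig:
    """Constants shared by all pipeline stages.

    Parameters
    ----------
    start_day
        First day of antibody dosing (days post-engraftment); slope fitting
        and response classification only consider measurements from this day
        on.  Default 7, the MC38 schedule.
    detection_limit
        Minimum measurable tumor volume in mm^3; smaller measurements are
        censored in slope fits.  Volumes recorded as exactly 0 are always
        below the limit.
    rtc_scale_days
        Horizon (days) over which the slope difference is exponentiated in
        the RTC statistic: RTC = 10**((b_i - mu_C) * rtc_scale_days).
    n_perm_herit, n_boot
        Permutation and bootstrap replicate counts for heritability
        inference.
    n_perm_scan
        Permutations for genome-scan significance thresholds.
    alpha
        Genome-wide significance level.
    quantile_for_imputation
        Quantile of arm-wise fitted slopes assigned to tumors that regressed
        to zero after a single detectable measurement.
    w_rtc, w_crstar
        Weights of the RTC and CR*-enrichment Z-scores in the combined
        response trait; must sum to 1.
    """

    start_day: int = 7
    detection_limit: float = 1.0
    rtc_scale_days: int = 21
    n_perm_herit: int = 10000
    n_boot: int = 10000
    n_perm_scan: int = 1000
    alpha: float = 0.05
    seed: int = 0
    quantile_for_imputation: float = 0.10
    w_rtc: float = 0.8
    w_crstar: float = 0.2
    arm_aliases: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_ARM_ALIASES)
    )

    def __post_init__(self) -> None:
        if self.detection_limit <= 0:
            raise ParameterError("detection_limit must be > 0")
        if self.rtc_scale_days <= 0:
            raise ParameterError("rtc_scale_days must be a positive integer")
        for name in ("n_perm_herit", "n_boot", "n_perm_scan"):
            if getattr(self, name) < 1:
                raise ParameterError(f"{name} must be a positive integer")
        for name in ("alpha", "quantile_for_imputation"):
            value = getattr(self, name)
            if not 0.0 < value < 1.0:
                raise ParameterError(f"{name} must lie in (0, 1)")
        if abs(self.w_rtc + self.w_crstar - 1.0) > 1e-12:
            raise ParameterError("w_rtc + w_crstar must equal 1")
        if min(self.w_rtc, self.w_crstar) < 0:
            raise ParameterError("trait weights must be nonnegative")

    # -- construction -----------------------------------------------------

    @classmethod
    def from_file(cls, path: str | Path) -> "StudyConfig":
        """Load a configuration from a YAML or JSON file.

        Unknown keys are rejected so that typos fail loudly.
        """
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if data is None:
            data = {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    # -- helpers ----------------------------------------------------------

    def rng(self, offset: int = 0) -> np.random.Generator:
        """Seeded generator for a stage; `offset` decorrelates stages."""
        return np.random.default_rng(int(self.seed) + int(offset))

    def normalize_arm(self, label: str) -> str:
        """Map an arm label onto {'control', 'treated'} via the alias table."""
        key = str(label).strip().lower()
        try:
            return self.arm_aliases[key]
        except KeyError:
            raise ValidationError(
                f"unknown treatment-arm label {label!r}; extend arm_aliases "
                "to map it onto 'control' or 'treated'"
            ) from None
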