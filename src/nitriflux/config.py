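"""Pipeline configuration and operational classifications.

Holds the handful of thresholds the analysis depends on, with the
conventional defaults: the ¹⁵N/¹⁴N ratio of atmospheric N₂ as the delta
reference, a 0.999 minimum R² for isotope calibrations, the 95% ANI
species boundary, CheckM-style medium/high MAG quality presets, and the
operational dissolved-oxygen bounds separating hypoxic, low-oxygen and
oxygen-saturated seawater.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .exceptions import InputError

log = logging.getLogger("nitriflux")

#: ¹⁵N/¹⁴N isotope ratio of atmospheric N₂ (the AIR delta reference).
R_AIR = 0.0036765

#: Natural-abundance ¹⁵N atom fraction implied by R_AIR.
NATURAL_15N_AF = R_AIR / (1.0 + R_AIR)


@dataclass(frozen=True)
class QualityPreset:
    """MAG quality thresholds: completeness floor and contamination ceiling (%)."""

    min_completeness: float
    max_contamination: float


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable thresholds shared across pipeline stages.

    Parameters
    ----------
    r_reference
        Isotope ratio of the delta reference scale (AIR by default).
    r2_min
        Minimum acceptable R² for the isotope-standard calibration fit.
    ani_threshold
        ANI percent used for genome dereplication and novelty calls.
    quality_presets
        Named MAG quality filters; "medium" is (50, 10), "high" is (90, 5).
    exact_max_n
        Largest combined sample size for which the rank-sum test
        enumerates the exact null distribution.
    low_oxygen_bounds
        Dissolved-oxygen bounds (mg L⁻¹): at or below the first value is
        hypoxic, at or above the second is oxygen-saturated, in between is
        operationally "low-oxygen seawater".
    """

    r_reference: float = R_AIR
    r2_min: float = 0.999
    ani_threshold: float = 95.0
    quality_presets: dict = field(
        default_factory=lambda: {
            "medium": QualityPreset(50.0, 10.0),
            "high": QualityPreset(90.0, 5.0),
        }
    )
    exact_max_n: int = 20
    low_oxygen_bounds: tuple = (2.0, 6.0)

    def __post_init__(self):
        if not (0 < self.r_reference < 1):
            raise InputError("r_reference must be in (0, 1)")
        if not (0 < self.r2_min <= 1):
            raise InputError("r2_min must be in (0, 1]")
        if not (0 < self.ani_threshold <= 100):
            raise InputError("ani_threshold must be in (0, 100]")
        lo, hi = self.low_oxygen_bounds
        if not (0 <= lo < hi):
            raise InputError("low_oxygen_bounds must satisfy 0 <= lo < hi")


DEFAULT_CONFIG = PipelineConfig()


def classify_oxygen(do_mg_per_l: float, config: PipelineConfig = DEFAULT_CONFIG) -> str:
    """Classify a dissolved-oxygen concentration into an oxygen regime.

    Returns ``"hypoxic"`` for DO ≤ lower bound (2 mg L⁻¹ by default),
    ``"oxygenated"`` for DO ≥ upper bound (6 mg L⁻¹), and ``"low_oxygen"``
    for the interval between — the operational definition of low-oxygen
    seawater in stratified coastal systems. Boundaries are inclusive on
    the outer classes.
    """
    do = float(do_mg_per_l)
    if do < 0:
        raise InputError(f"dissolved oxygen must be non-negative, got {do}")
    lo, hi = config.low_oxygen_bounds
    if do <= lo:
        return "hypoxic"
    if do >= hi:
        return "oxygenated"
    return "low_oxygen"
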