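"""Fiber counts to airborne concentration.

The conversion is

    C (f/L) = A * N / (a * n * V)

with A the effective filter area (mm^2, a circular sampling spot), N the
number of fibers counted over the observed fields, a the area of one
microscope field (mm^2), n the number of fields counted, and V the volume
of air sampled (L). Defaults reproduce the instrument: a 15-mm spot, a
0.66 mm x 0.44 mm field, one field, and 20 min of sampling at 10 L/min,
under which one counted fiber corresponds to 3.0 f/L.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from .errors import ParameterError

__all__ = [
    "SamplingConfig",
    "ConcentrationResult",
    "effective_filter_area",
    "fiber_concentration",
    "required_fields_or_volume",
]


def effective_filter_area(diameter_mm: float) -> float:
    """Area (mm^2) of the circular sampling spot: pi * d^2 / 4."""
    if diameter_mm <= 0:
        raise ParameterError("filter diameter must be positive")
    return math.pi * diameter_mm**2 / 4.0


@dataclass
class SamplingConfig:
    """Sampling geometry and air volume behind the concentration formula."""

    filter_diameter_mm: float = 15.0
    field_width_mm: float = 0.66
    field_height_mm: float = 0.44
    flow_rate_lpm: float = 10.0
    duration_min: float = 20.0
    n_fields: int = 1

    def __post_init__(self) -> None:
        for name in (
            "filter_diameter_mm",
            "field_width_mm",
            "field_height_mm",
            "flow_rate_lpm",
            "duration_min",
        ):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if self.n_fields < 1:
            raise ParameterError("n_fields must be >= 1")

    @property
    def filter_area_mm2(self) -> float:
        """A: effective filter area (mm^2)."""
        return effective_filter_area(self.filter_diameter_mm)

    @property
    def field_area_mm2(self) -> float:
        """a: area of one microscope field (mm^2)."""
        return self.field_width_mm * self.field_height_mm

    @property
    def air_volume_l(self) -> float:
        """V: total air volume sampled (L)."""
        return self.flow_rate_lpm * self.duration_min


@dataclass
class ConcentrationResult:
    """One concentration estimate; reported value rounded to one decimal."""

    n_fibers: int
    concentration_raw: float  # f/L, full precision
    concentration: float  # f/L, rounded to one decimal place
    single_fiber_equivalent: float  # f/L for N = 1 (raw)


def fiber_concentration(n_fibers: int, config: SamplingConfig | None = None) -> ConcentrationResult:
    """Convert a fiber count into an airborne concentration (f/L)."""
    config = config or SamplingConfig()
    if n_fibers < 0:
        raise ParameterError("fiber count must be >= 0")
    sfe = config.filter_area_mm2 / (
        config.field_area_mm2 * config.n_fields * config.air_volume_l
    )
    raw = sfe * n_fibers
    return ConcentrationResult(
        n_fibers=int(n_fibers),
        concentration_raw=raw,
        concentration=round(raw, 1),
        single_fiber_equivalent=sfe,
    )


def required_fields_or_volume(
    target_single_fiber_fl: float,
    config: SamplingConfig | None = None,
    vary: str = "n_fields",
    max_n_fields: int | None = None,
):
    """Smallest n_fields (or air volume) whose single-fiber equivalent
    concentration is at or below the target.

    With ``vary='n_fields'`` returns the smallest integer field count; a
    ``max_n_fields`` cap makes the target explicitly unreachable (returns
    None) when even the cap does not suffice. With ``vary='volume'``
    returns the minimal air volume in litres.
    """
    config = config or SamplingConfig()
    if target_single_fiber_fl <= 0:
        raise ParameterError("target must be positive")
    A = config.filter_area_mm2
    a = config.field_area_mm2
    if vary == "n_fields":
        n = max(1, math.ceil(A / (a * config.air_volume_l * target_single_fiber_fl)))
        # Guard against ceil() landing one high/low at representation edges.
        while n > 1 and A / (a * (n - 1) * config.air_volume_l) <= target_single_fiber_fl:
            n -= 1
        if max_n_fields is not None and n > max_n_fields:
            return None
        return n
    if vary == "volume":
        return A / (a * config.n_fields * target_single_fiber_fl)
    raise ParameterError("vary must be 'n_fields' or 'volume'")
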