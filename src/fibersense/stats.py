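"""Agreement analysis and Poisson counting-variability simulation.

Two methods measuring the same airborne fiber concentration disagree even
when both are unbiased, because each counts a small Poisson number of
fibers in its own microscope fields. This module quantifies that
agreement the standard way — Bland–Altman limits of agreement on relative
differences (each pair's difference as a percentage of the pair mean) —
and simulates the counting process to show the funnel: limits of
agreement widen as the expected fiber count per measurement falls.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .conc import SamplingConfig
from .errors import InputError, ParameterError

__all__ = [
    "PairedSeries",
    "AgreementResult",
    "CountSimConfig",
    "FunnelPoint",
    "relative_differences",
    "bland_altman",
    "expected_fibers_per_field",
    "simulate_paired_series",
    "loa_funnel",
]


@dataclass
class PairedSeries:
    """Paired concentration measurements from two methods (f/L)."""

    method_x: np.ndarray
    method_y: np.ndarray
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.method_x = np.asarray(self.method_x, dtype=float)
        self.method_y = np.asarray(self.method_y, dtype=float)
        if self.method_x.shape != self.method_y.shape or self.method_x.ndim != 1:
            raise InputError("method_x and method_y must be equal-length 1-D series")
        if len(self.method_x) < 1:
            raise InputError("paired series must contain at least one pair")
        if np.any(self.method_x < 0) or np.any(self.method_y < 0):
            raise InputError("concentrations must be >= 0")


@dataclass
class AgreementResult:
    """Bland–Altman summary of relative differences (percent)."""

    n_pairs_used: int
    mean_rel_diff: float
    sd_rel_diff: float | None
    loa_low: float | None
    loa_high: float | None
    z_mult: float = 1.96
    n_excluded: int = 0

    @property
    def loa_width(self) -> float | None:
        if self.loa_low is None or self.loa_high is None:
            return None
        return self.loa_high - self.loa_low


def relative_differences(pairs: PairedSeries) -> tuple[np.ndarray, int]:
    """Per-pair relative differences: 100 * (x - y) / ((x + y) / 2).

    Pairs with x = y = 0 have an undefined ratio; they are excluded and
    their count returned separately. The result is bounded in
    (-200 %, +200 %) for positive pairs, reaching the bound only as one
    member goes to zero.
    """
    x, y = pairs.method_x, pairs.method_y
    mean = (x + y) / 2.0
    valid = mean > 0
    d = 100.0 * (x[valid] - y[valid]) / mean[valid]
    return d, int(np.count_nonzero(~valid))


def bland_altman(
    diffs: Sequence[float], z_mult: float = 1.96, n_excluded: int = 0
) -> AgreementResult:
    """Mean, sample SD (n-1) and limits of agreement of difference values.

    Limits of agreement are mean ± z_mult * SD (default 1.96, the 95 %
    limits). A single value has no SD and hence no limits.
    """
    d = np.asarray(diffs, dtype=float)
    if d.size == 0:
        raise InputError("no difference values")
    mean = float(d.mean())
    if d.size == 1:
        return AgreementResult(1, mean, None, None, None, z_mult, n_excluded)
    sd = float(d.std(ddof=1))
    return AgreementResult(
        n_pairs_used=int(d.size),
        mean_rel_diff=mean,
        sd_rel_diff=sd,
        loa_low=mean - z_mult * sd,
        loa_high=mean + z_mult * sd,
        z_mult=z_mult,
        n_excluded=n_excluded,
    )


def expected_fibers_per_field(c_true: float, sampling: SamplingConfig) -> float:
    """Expected fiber count per microscope field at a true concentration.

    Inverts the concentration formula: lambda = C * a * V / A for a single
    field, so converting a count of lambda fibers in one field back to a
    concentration recovers C exactly.
    """
    if c_true < 0:
        raise ParameterError("concentration must be >= 0")
    return (
        c_true
        * sampling.field_area_mm2
        * sampling.air_volume_l
        / sampling.filter_area_mm2
    )


@dataclass
class CountSimConfig:
    """Paired counting simulation: two methods, one true concentration.

    Each method counts fibers on its own disjoint set of fields; fibers
    deposit as a homogeneous Poisson process over the filter (uniform air
    mixing), so each method's total count is Poisson(lambda * n_fields).
    """

    true_concentration: float = 3.0
    sampling_x: SamplingConfig = field(default_factory=SamplingConfig)
    sampling_y: SamplingConfig | None = None
    n_reps: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_concentration < 0:
            raise ParameterError("true_concentration must be >= 0")
        if self.n_reps < 1:
            raise ParameterError("n_reps must be >= 1")
        if self.sampling_y is None:
            self.sampling_y = replace(self.sampling_x)


def simulate_paired_series(config: CountSimConfig) -> PairedSeries:
    """Draw paired concentration estimates from the Poisson counting model.

    For every repetition and method, the total count over the method's
    fields is Poisson(lambda * n_fields) and is converted back to f/L via
    the concentration formula. Deterministic under the seed.
    """
    rng = np.random.default_rng([int(config.seed), 0x57A7])
    out = []
    for sampling in (config.sampling_x, config.sampling_y):
        lam = expected_fibers_per_field(config.true_concentration, sampling)
        counts = rng.poisson(lam * sampling.n_fields, size=config.n_reps)
        sfe = sampling.filter_area_mm2 / (
            sampling.field_area_mm2 * sampling.n_fields * sampling.air_volume_l
        )
        out.append(counts * sfe)
    return PairedSeries(method_x=out[0], method_y=out[1])


@dataclass
class FunnelPoint:
    """Agreement summary at one true concentration on the funnel grid."""

    c_true: float
    lambda_per_method: float
    mean_detected_count: float
    agreement: AgreementResult


def loa_funnel(
    c_grid: Sequence[float], template: CountSimConfig
) -> list[FunnelPoint]:
    """Limits-of-agreement width versus mean fiber count over a C grid.

    Reruns the paired counting simulation at each true concentration in
    ``c_grid`` (seeded per grid point for independence) and summarises the
    relative differences with Bland–Altman limits. As the expected count
    per measurement falls, the limits widen — the low-count funnel.
    """
    if len(c_grid) == 0:
        raise InputError("empty concentration grid")
    points = []
    for k, c in enumerate(c_grid):
        cfg = replace(template, true_concentration=float(c), seed=template.seed + k)
        series = simulate_paired_series(cfg)
        diffs, n_excl = relative_differences(series)
        agreement = bland_altman(diffs, n_excluded=n_excl)
        lam_total = expected_fibers_per_field(c, cfg.sampling_x) * cfg.sampling_x.n_fields
        sfe_x = cfg.sampling_x.filter_area_mm2 / (
            cfg.sampling_x.field_area_mm2
            * cfg.sampling_x.n_fields
            * cfg.sampling_x.air_volume_l
        )
        mean_count = float(np.mean(series.method_x / sfe_x))
        points.append(
            FunnelPoint(
                c_true=float(c),
                lambda_per_method=lam_total,
                mean_detected_count=mean_count,
                agreement=agreement,
            )
        )
    return points
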