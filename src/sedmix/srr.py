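"""Sulfate reduction rates from 35S radiotracer incubations.

A sediment subsample is injected with carrier-free 35S-sulfate and
incubated; the fraction of tracer recovered as total reduced inorganic
sulfur (TRIS) after the incubation, scaled by the ambient sulfate pool
and corrected for the kinetic isotope discrimination against 35S, gives
the sulfate reduction rate:

    SRR = [SO4] * phi * a_TRIS' / (a_TRIS' + a_SO4) * 1.06 / t

where ``a_TRIS' = a_TRIS - blank`` is the killed-control-corrected TRIS
radioactivity, ``[SO4]`` the porewater sulfate concentration, ``phi``
porosity (converting the porewater pool to whole-sediment volume) and
1.06 the isotope fractionation factor.  Results are reported in
nmol SO4 per cm^3 wet sediment per day.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .profiles import DepthProfile

__all__ = ["TracerMeasurement", "SrrConstants", "srr_from_tracer", "srr_profile"]

#: nmol of sulfate per cm^3 porewater and mM: 1 mM = 1 umol/cm^3 = 1000 nmol/cm^3
_NMOL_PER_CM3_PER_MM = 1000.0
_HOURS_PER_DAY = 24.0


@dataclass(frozen=True)
class TracerMeasurement:
    """One 35S incubation: radioactivities, sulfate pool and timing."""

    a_tris: float          # TRIS radioactivity (counts or Bq)
    a_so4: float           # radioactivity remaining as sulfate
    sulfate_conc: float    # porewater sulfate, mM
    incubation_time: float = 5.0   # h
    porosity: float = 0.8
    blank_tris: float = 0.0        # killed-control TRIS radioactivity

    def __post_init__(self) -> None:
        if self.a_tris < 0 or self.a_so4 < 0 or self.blank_tris < 0:
            raise ValueError("radioactivities must be non-negative")
        if not (0.0 < self.porosity < 1.0):
            raise ValueError("porosity must lie in (0, 1)")
        if self.incubation_time <= 0:
            raise ValueError("incubation time must be positive")
        if self.sulfate_conc < 0:
            raise ValueError("sulfate concentration must be non-negative")


@dataclass(frozen=True)
class SrrConstants:
    """Fixed conversion constants; the 1.06 fractionation factor corrects
    for the slower microbial turnover of 35S relative to 32S."""

    fractionation_factor: float = 1.06

    def __post_init__(self) -> None:
        if self.fractionation_factor <= 1.0:
            raise ValueError("fractionation factor must exceed 1")


def srr_from_tracer(m: TracerMeasurement, c: SrrConstants = SrrConstants()) -> float:
    """Sulfate reduction rate in nmol SO4 per cm^3 wet sediment per day.

    Negative blank-corrected TRIS is clipped to zero; a measurement with
    zero total radioactivity after blank correction is rejected.
    """
    tris = max(m.a_tris - m.blank_tris, 0.0)
    total = tris + m.a_so4
    if total <= 0:
        raise ValueError("zero total radioactivity after blank correction")
    fraction = tris / total
    pool_nmol_cm3 = m.sulfate_conc * _NMOL_PER_CM3_PER_MM * m.porosity
    per_hour = pool_nmol_cm3 * fraction * c.fractionation_factor / m.incubation_time
    return per_hour * _HOURS_PER_DAY


def srr_profile(measurements: list[TracerMeasurement], bins: DepthProfile | None = None,
                c: SrrConstants = SrrConstants(),
                bin_top: np.ndarray | None = None,
                bin_bottom: np.ndarray | None = None) -> DepthProfile:
    """Element-wise SRR over a depth series of tracer measurements.

    Binning comes either from a template ``bins`` profile or explicit
    ``bin_top``/``bin_bottom`` arrays (one measurement per bin); a bin
    whose measurement is invalid is reported by index.
    """
    if bins is not None:
        bin_top, bin_bottom = bins.bin_top, bins.bin_bottom
    if bin_top is None or bin_bottom is None:
        raise ValueError("provide bins or bin_top/bin_bottom")
    bin_top = np.asarray(bin_top, dtype=float)
    if len(measurements) != len(bin_top):
        raise ValueError("need exactly one measurement per bin")
    values = np.empty(len(measurements))
    for i, m in enumerate(measurements):
        try:
            values[i] = srr_from_tracer(m, c)
        except ValueError as err:
            raise ValueError(f"bin {i} ([{bin_top[i]}, {np.asarray(bin_bottom)[i]}) cm): {err}") from err
    return DepthProfile(bin_top=bin_top, bin_bottom=np.asarray(bin_bottom, dtype=float),
                        value=values, units="nmol cm-3 d-1")
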