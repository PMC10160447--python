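"""Spectrophotometric pigment quantification and the colorimetric CCI.

Chlorophyll a/b and total carotenoid concentrations (mg/L of a 96%
ethanol extract) follow the standard three-wavelength linear equations
from absorbances at 665, 649 and 470 nm:

    C_a   = 13.96*D665 - 6.88*D649
    C_b   = 24.96*D649 - 7.32*D665
    C_x.c = (1000*D470 - 2.05*C_a - 114.8*C_b) / 245

The citrus colour index summarises CIELAB colorimeter readings as
CCI = 1000*a* / (L* * b*): positive for red/yellow hues, negative for
green ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from statistics import fmean

#: Litres of extract per gram of fresh tissue (1 g soaked in 15 mL).
EXTRACT_L_PER_G = 0.015


@dataclass(frozen=True)
class AbsorbanceTriplet:
    """Absorbances at 470, 649 and 665 nm (1 cm path, ethanol blank)."""

    d470: float
    d649: float
    d665: float

    def __post_init__(self):
        for name in ("d470", "d649", "d665"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite")
            if v < 0:
                raise ValueError(f"{name} must be non-negative (got {v})")


@dataclass(frozen=True)
class PigmentContent:
    """Chlorophyll a, chlorophyll b and carotenoid concentration (mg/L)."""

    chlorophyll_a: float
    chlorophyll_b: float
    carotenoid: float

    def per_gram_fresh_weight(self, litres_per_gram: float = EXTRACT_L_PER_G) -> "PigmentContent":
        """Convert mg/L of extract to mg/g tissue (default 15 mL per 1 g)."""
        return PigmentContent(
            self.chlorophyll_a * litres_per_gram,
            self.chlorophyll_b * litres_per_gram,
            self.carotenoid * litres_per_gram,
        )


def pigment_content(triplet: AbsorbanceTriplet) -> PigmentContent:
    """Apply the three-wavelength equations to one absorbance triplet."""
    c_a = 13.96 * triplet.d665 - 6.88 * triplet.d649
    c_b = 24.96 * triplet.d649 - 7.32 * triplet.d665
    c_xc = (1000 * triplet.d470 - 2.05 * c_a - 114.8 * c_b) / 245
    return PigmentContent(c_a, c_b, c_xc)


def mean_triplet(replicates) -> AbsorbanceTriplet:
    """Average replicate absorbance readings (e.g. three biological reps).

    Because the pigment equations are linear, averaging absorbances first
    equals averaging the computed contents.
    """
    reps = list(replicates)
    if not reps:
        raise ValueError("no replicates given")
    return AbsorbanceTriplet(
        fmean(t.d470 for t in reps), fmean(t.d649 for t in reps), fmean(t.d665 for t in reps)
    )


@dataclass(frozen=True)
class ColorReading:
    """CIELAB colorimeter reading: L* lightness (0-100), a* red-green,
    b* yellow-blue."""

    lightness: float
    a: float
    b: float

    def __post_init__(self):
        if not 0 <= self.lightness <= 100:
            raise ValueError(f"L* must be in [0, 100] (got {self.lightness})")


def cci(reading: ColorReading) -> float:
    """Colour index 1000*a*/(L* x b*); NaN when the denominator is zero."""
    denom = reading.lightness * reading.b
    if denom == 0:
        return math.nan
    return 1000.0 * reading.a / denom
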