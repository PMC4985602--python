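"""Broth-microdilution MIC estimation and fold-resistance.

The MIC is the bacteriocin concentration (sum of both peptides, 1:1)
that inhibits growth by 50% in a two-fold dilution microtiter assay
read spectrophotometrically at 600 nm.  Growth is normalized against a
no-bacteriocin control and a medium blank; the 50% crossing is located
by linear interpolation on log2 concentration, which matches the
two-fold ladder of the assay.  A mutant's resistance is expressed as
the ratio of its MIC to the wild-type MIC, with a replicate half-range
as the spread.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

MONOTONE_TOLERANCE = 0.1  # inhibition may wobble this much before the curve is flagged


@dataclass
class DilutionSeries:
    """One strain x one bacteriocin: descending two-fold concentrations with OD readings."""

    concentrations: np.ndarray  # strictly decreasing by factor 2
    od: np.ndarray  # one OD600 reading per concentration
    blank_od: float  # medium-only well
    control_od: float  # no-bacteriocin growth control

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.concentrations.shape != self.od.shape:
            raise ValueError("concentrations and od must have the same length")
        ratios = self.concentrations[:-1] / self.concentrations[1:]
        if not np.allclose(ratios, 2.0, rtol=1e-6):
            raise ValueError("concentrations must be a strictly decreasing two-fold series")
        if np.any(self.od < 0):
            raise ValueError("growth readings must be non-negative")


@dataclass
class MicResult:
    mic: float | None  # nmol/L; None when censored
    censored: str | None  # None | 'above_top' | 'below_bottom'
    top: float
    bottom: float
    inhibition: np.ndarray  # per-concentration inhibition fraction, clamped to [0, 1]
    non_monotone: bool = False

    @property
    def value_or_bound(self) -> str:
        if self.censored == "above_top":
            return f"> {self.top:g}"
        if self.censored == "below_bottom":
            return f"< {self.bottom:g}"
        return f"{self.mic:g}"


@dataclass
class FoldIncrease:
    ratio: float | None  # mutant MIC / wild-type MIC; None when censored
    spread: float | None  # replicate half-range, one significant figure
    censored: str | None  # None | '>' | '<'
    bound: float | None  # the bound when censored (e.g. top/wildtype MIC)

    @property
    def text(self) -> str:
        if self.censored:
            return f"{self.censored} {self.bound:g}"
        if self.spread:
            return f"{self.ratio:g} ± {self.spread:g}"
        return f"{self.ratio:g}"


def inhibition_fractions(series: DilutionSeries) -> np.ndarray:
    """Per-concentration growth inhibition, control-relative and clamped to [0, 1]."""
    span = series.control_od - series.blank_od
    if span <= 0:
        raise ValueError(
            f"failed assay: growth control OD ({series.control_od}) does not exceed "
            f"blank OD ({series.blank_od})"
        )
    return np.clip(1.0 - (series.od - series.blank_od) / span, 0.0, 1.0)


def mic(series: DilutionSeries) -> MicResult:
    """MIC as the 50%-inhibition crossing of the dilution curve.

    Interpolates linearly in log2(concentration) between the bracketing
    wells.  When the curve never crosses 0.5 the result is censored
    (above the top or below the bottom concentration).  A curve that is
    non-monotone beyond tolerance is flagged and the first downward
    crossing from the high-concentration end is used.
    """
    if len(series.concentrations) < 3:
        raise ValueError("at least 3 concentrations are required")
    inh = inhibition_fractions(series)
    conc = series.concentrations
    top, bottom = float(conc[0]), float(conc[-1])
    non_monotone = bool(np.any(np.diff(inh) > MONOTONE_TOLERANCE))

    if inh[-1] >= 0.5:
        return MicResult(None, "below_bottom", top, bottom, inh, non_monotone)
    crossing = None
    for i in range(len(conc) - 1):
        if inh[i] >= 0.5 > inh[i + 1]:
            crossing = i
            break
    if crossing is None:
        return MicResult(None, "above_top", top, bottom, inh, non_monotone)
    x_hi, x_lo = math.log2(conc[crossing]), math.log2(conc[crossing + 1])
    y_hi, y_lo = float(inh[crossing]), float(inh[crossing + 1])
    x = x_lo + (0.5 - y_lo) * (x_hi - x_lo) / (y_hi - y_lo)
    return MicResult(2.0**x, None, top, bottom, inh, non_monotone)


def _round_one_sig(x: float) -> float:
    if x == 0:
        return 0.0
    exp = math.floor(math.log10(abs(x)))
    return round(x, -exp)


def fold_increase(
    mutant: MicResult,
    wildtype: MicResult,
    replicates: Sequence[tuple[MicResult, MicResult]] = (),
) -> FoldIncrease:
    """Mutant-over-wild-type MIC ratio with a replicate half-range spread.

    Censored inputs yield a censored ratio with its direction (e.g. a
    mutant MIC above the top concentration gives '> top/wildtype').
    """
    if wildtype.censored:
        raise ValueError("wild-type MIC is censored; fold increase undefined")
    if mutant.censored == "above_top":
        return FoldIncrease(None, None, ">", mutant.top / wildtype.mic)
    if mutant.censored == "below_bottom":
        return FoldIncrease(None, None, "<", mutant.bottom / wildtype.mic)
    ratio = mutant.mic / wildtype.mic
    spread = None
    ratios = [
        m.mic / w.mic
        for m, w in replicates
        if not m.censored and not w.censored
    ]
    if len(ratios) >= 2:
        spread = _round_one_sig((max(ratios) - min(ratios)) / 2.0)
    return FoldIncrease(ratio, spread, None, None)
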