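"""Duplex stability, dye signal, and the functional factor F.

Mismatched heteroduplexes melt earlier than perfect duplexes, so at the
elongation temperature they hold less intercalating dye and fluoresce less.
This module maps a mismatch count ``m`` to (a) a melting temperature via a
linear penalty per mismatch, (b) a bound (double-stranded) fraction via a
logistic melting transition, (c) a normalized dye-signal factor, and (d) the
functional factor ``F`` — a 0-to-1 score that is 1.0 for a perfectly
complementary duplex and decreases with mismatching, anchored at the mean
mismatch counts of random pairs from 10- and 20-position fully degenerate
libraries (7.5 -> 0.5, 15 -> 0.1).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.special import expit

__all__ = [
    "ThermalParams",
    "FFunction",
    "DuplexKind",
    "DuplexClass",
    "melting_temperature",
    "bound_fraction",
    "dye_signal_factor",
    "functional_factor",
    "pool_F",
]

# Mean pairwise mismatch counts of 10- and 20-position fully degenerate
# libraries (n * 3/4): the anchor abscissae of the default F function.
_F_ANCHORS_DEFAULT = ((0.0, 1.0), (7.5, 0.5), (15.0, 0.1))


@dataclass(frozen=True)
class ThermalParams:
    """Thermal model of a 60-bp duplex under a dye-based readout.

    ``tm_full`` is the melting temperature of the perfectly matched duplex;
    each mismatch lowers it by ``delta_tm_per_mismatch``; the helix-coil
    transition has logistic width ``transition_width``; ``t_elongation`` is
    the temperature at which fluorescence is read.  All in deg C.  Defaults
    place the steep signal decline between roughly 9 and 14 mismatches and
    make 68 vs 74 deg C elongation discriminate low- vs high-diversity pools.
    """

    tm_full: float = 82.0
    delta_tm_per_mismatch: float = 1.2
    transition_width: float = 2.5
    t_elongation: float = 72.0

    def __post_init__(self) -> None:
        if self.delta_tm_per_mismatch <= 0:
            raise ValueError("delta_tm_per_mismatch must be > 0")
        if self.transition_width <= 0:
            raise ValueError("transition_width must be > 0")


class DuplexKind(str, Enum):
    PRIMER_TEMPLATE_SENSE = "primer_template_sense"
    PRIMER_TEMPLATE_ANTISENSE = "primer_template_antisense"
    MATCHED_FULL = "matched_full"
    MISMATCHED_FULL = "mismatched_full"
    AGGREGATE = "aggregate"


@dataclass(frozen=True)
class DuplexClass:
    """A population of duplexes sharing a kind and a mismatch count.

    ``label`` carries experiment bookkeeping (e.g. which restriction site the
    paired strands share); it does not affect thermodynamics.
    """

    kind: DuplexKind
    m: float
    concentration: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError("concentration must be non-negative")
        if self.kind is DuplexKind.MATCHED_FULL and self.m != 0:
            raise ValueError("a matched duplex has m = 0")


@dataclass(frozen=True)
class FFunction:
    """Monotone interpolation of F through (mismatch count, F) anchors."""

    anchors: tuple[tuple[float, float], ...] = _F_ANCHORS_DEFAULT

    def __post_init__(self) -> None:
        anchors = tuple((float(x), float(y)) for x, y in self.anchors)
        if len(anchors) < 2:
            raise ValueError("need at least two anchors")
        xs = [x for x, _ in anchors]
        ys = [y for _, y in anchors]
        if xs != sorted(xs) or len(set(xs)) != len(xs):
            raise ValueError("anchor mismatch counts must be strictly increasing")
        if xs[0] != 0.0 or ys[0] != 1.0:
            raise ValueError("F must be anchored at F(0) = 1.0")
        if any(b > a for a, b in zip(ys, ys[1:])):
            raise ValueError("anchor F values must be non-increasing")
        if any(not 0.0 <= y <= 1.0 for y in ys):
            raise ValueError("F values must lie in [0, 1]")
        object.__setattr__(self, "anchors", anchors)

    def __call__(self, m) -> np.ndarray | float:
        return functional_factor(m, self)


@lru_cache(maxsize=32)
def _f_interpolator(anchors: tuple[tuple[float, float], ...]) -> PchipInterpolator:
    xs = np.array([x for x, _ in anchors])
    ys = np.array([y for _, y in anchors])
    return PchipInterpolator(xs, ys, extrapolate=False)


def melting_temperature(m: float, params: ThermalParams) -> float:
    """Tm of a duplex with ``m`` mismatches: linear penalty per mismatch."""
    return params.tm_full - params.delta_tm_per_mismatch * m


def bound_fraction(tm, t, params: ThermalParams):
    """Fraction of duplexes double-stranded at temperature ``t``.

    Logistic in ``(tm - t) / transition_width``: exactly 0.5 at ``t = tm``,
    saturating to 1 well below Tm, strictly decreasing in ``t``.
    """
    return expit((np.asarray(tm, dtype=float) - t) / params.transition_width)


def dye_signal_factor(m, params: ThermalParams, t: float | None = None):
    """Per-duplex dye fluorescence relative to a perfect duplex at the default
    elongation temperature.

    Normalized so that ``factor(0)`` at ``params.t_elongation`` equals 1 and
    clamped to [0, 1]; non-increasing in ``m`` for every temperature.
    """
    if t is None:
        t = params.t_elongation
    tm = melting_temperature(np.asarray(m, dtype=float), params)
    reference = bound_fraction(melting_temperature(0.0, params), params.t_elongation, params)
    out = np.minimum(bound_fraction(tm, t, params) / reference, 1.0)
    return float(out) if np.isscalar(m) or np.ndim(m) == 0 else out

def functional_factor(m, f: FFunction | None = None):
    """F value of a duplex with ``m`` mismatches (real-valued ``m`` allowed).

    Monotone shape-preserving (PCHIP) interpolation through the anchors,
    clamped to the last anchor value beyond the anchored range and to [0, 1]
    everywhere.
    """
    if f is None:
        f = FFunction()
    arr = np.asarray(m, dtype=float)
    if np.any(arr < 0):
        raise ValueError("mismatch count must be >= 0")
    xs_max = f.anchors[-1][0]
    tail = f.anchors[-1][1]
    values = _f_interpolator(f.anchors)(np.minimum(arr, xs_max))
    values = np.clip(np.where(arr >= xs_max, tail, values), 0.0, 1.0)
    return float(values) if arr.ndim == 0 else values


def pool_F(classes: Iterable[DuplexClass] | Sequence[DuplexClass], f: FFunction | None = None) -> float:
    """Concentration-weighted mean F over duplex classes."""
    classes = list(classes)
    total = sum(c.concentration for c in classes)
    if not classes or total <= 0:
        raise ValueError("pool_F needs a non-empty pool with positive total concentration")
    weighted = sum(c.concentration * functional_factor(c.m, f) for c in classes)
    return weighted / total
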