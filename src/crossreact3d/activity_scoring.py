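"""Cross-reactivity scoring from per-clone recognition data and
functional-avidity arithmetic from titration curves.

Per-clone recognition is categorised from specific lysis: >60% -> +4,
>40% -> +3, >20% -> +2, >10% -> +1, otherwise -1 (no significant lysis).
A peptide's cross-reactivity score is the sum of the categories over its
clones (17 clones in the reference data set, so the floor is -17); the
alternative clone-count score is the number of recognising clones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats

__all__ = [
    "CloneRecognitionProfile",
    "TitrationCurve",
    "lysis_to_category",
    "cross_reactivity_score",
    "clone_count_score",
    "ec50",
    "relative_avidity_log",
    "mean_over_clones",
    "normalized_competition_lysis",
    "round_half_up",
]

CATEGORIES = (-1, 1, 2, 3, 4)


@dataclass
class CloneRecognitionProfile:
    """Recognition of one peptide by a panel of CTL clones.

    ``entries`` maps clone id to either a lysis percentage (float) or a
    recognition category (one of -1, +1, +2, +3, +4 given as int).
    """

    peptide_id: str
    entries: dict[str, float | int]
    n_clones: int = 17

    def __post_init__(self) -> None:
        if len(self.entries) != self.n_clones:
            raise ValueError(
                f"profile for {self.peptide_id!r} has {len(self.entries)} entries, "
                f"expected {self.n_clones}"
            )

    def categories(self) -> list[int]:
        cats = []
        for clone, value in self.entries.items():
            if isinstance(value, bool):
                raise TypeError(f"clone {clone}: boolean entry not allowed")
            if isinstance(value, (int, np.integer)):
                if value not in CATEGORIES:
                    raise ValueError(f"clone {clone}: invalid category {value}")
                cats.append(int(value))
            else:
                cats.append(lysis_to_category(float(value)))
        return cats


def lysis_to_category(percent: float) -> int:
    """Map a specific-lysis percentage to a recognition category."""
    if not (0.0 <= percent <= 100.0) or not math.isfinite(percent):
        raise ValueError(f"specific lysis must be in [0, 100], got {percent}")
    if percent > 60:
        return 4
    if percent > 40:
        return 3
    if percent > 20:
        return 2
    if percent > 10:
        return 1
    return -1


def cross_reactivity_score(profile: CloneRecognitionProfile) -> int:
    """Sum of per-clone categories (floor -n_clones when nothing is recognised)."""
    return int(sum(profile.categories()))


def clone_count_score(profile: CloneRecognitionProfile) -> int:
    """Number of clones recognising the peptide (category >= +1)."""
    return int(sum(1 for c in profile.categories() if c >= 1))


@dataclass
class TitrationCurve:
    """Specific lysis versus peptide concentration for one clone."""

    clone_id: str
    concentrations: np.ndarray  # Molar, any order; stored descending
    lysis: np.ndarray  # percent

    def __post_init__(self) -> None:
        conc = np.asarray(self.concentrations, dtype=float)
        lys = np.asarray(self.lysis, dtype=float)
        if conc.size != lys.size or conc.size < 2:
            raise ValueError("need >= 2 paired (concentration, lysis) points")
        if np.any(conc <= 0):
            raise ValueError("concentrations must be strictly positive")
        order = np.argsort(-conc)
        self.concentrations = conc[order]
        self.lysis = lys[order]


def _linear_domain(lysis: np.ndarray, max_lysis: float) -> slice:
    """Longest consecutive run of points with lysis in [20%, 80%] of the max."""
    in_band = (lysis >= 0.2 * max_lysis) & (lysis <= 0.8 * max_lysis)
    best = (0, 0)
    start = None
    for i, flag in enumerate(np.append(in_band, False)):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            if i - start > best[1] - best[0]:
                best = (start, i)
            start = None
    return slice(*best)


def ec50(curve: TitrationCurve, max_lysis: float | None = None) -> float:
    """Concentration (Molar) giving half of the maximal lysis.

    A line is fitted to lysis versus log10(concentration) over the linear
    domain of the curve (the longest run of points between 20% and 80% of the
    maximal lysis) and solved for 0.5*max_lysis.  Raises if the curve never
    reaches the half-maximal level.
    """
    if max_lysis is None:
        max_lysis = float(curve.lysis.max())
    half = 0.5 * max_lysis
    if curve.lysis.max() < half:
        raise ValueError("50% of maximal lysis not reached")
    domain = _linear_domain(curve.lysis, max_lysis)
    logc = np.log10(curve.concentrations[domain])
    lys = curve.lysis[domain]
    if lys.size < 2 or np.ptp(logc) == 0:
        raise ValueError("no linear domain to fit (curve too flat or too steep)")
    fit = stats.linregress(logc, lys)
    if fit.slope == 0:
        raise ValueError("flat fit; EC50 undefined")
    return float(10 ** ((half - fit.intercept) / fit.slope))


def relative_avidity_log(ec50_ref: float, ec50_x: float) -> float:
    """log10(EC50_ref / EC50_x); negative when x needs a higher concentration."""
    if ec50_ref <= 0 or ec50_x <= 0:
        raise ValueError("EC50 values must be positive")
    return float(np.log10(ec50_ref / ec50_x))


def mean_over_clones(values: np.ndarray) -> float:
    """Arithmetic mean of per-clone log relative avidities."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("at least one value required")
    return float(v.mean())


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Decimal rounding with ties away from zero (the convention of printed
    tables), immune to binary-float artifacts like -0.965 -> -0.96."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(f"{value:.6f}").quantize(q, rounding=ROUND_HALF_UP))


def normalized_competition_lysis(lysis_with_competitor: float, lysis_reference: float) -> float:
    """100 * lysis(with competitor) / lysis(reference antigen alone); may exceed 100."""
    if lysis_reference <= 0:
        raise ValueError("reference lysis must be positive")
    return 100.0 * lysis_with_competitor / lysis_reference
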