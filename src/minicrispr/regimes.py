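"""Critical coinfection thresholds and regime classification.

Whether a virus maintains a mini-CRISPR array against its rival is
decided by where its coinfection probability sits relative to two
critical thresholds:

* ``P*`` -- the coinfection probability above which targeting pays off
  against a *non-targeting* opponent: P* = c / (1 - w).
* ``P**`` -- the threshold against a *targeting* opponent:
  P** = c / (q - qc + c).

Comparing each strain's coinfection probability with its (P*, P**) pair
partitions parameter space into pure regimes (no targeting,
unidirectional targeting either way, mutual targeting), a cyclic
polymorphism (closed orbits around an interior neutral equilibrium) and
two bistable regions (unidirectional-either-way, and
mutual-or-none).

Classification is computed from the signs of the reduced replicator
coefficients -- sign(a) = sign(p - P*), sign(a + b) = sign(p - P**) --
with the threshold inequalities retained for reporting, so there is a
single provably consistent code path.  An independent corner-stability
oracle evaluated directly from the fitness components is provided for
verification.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import FrozenSet, Optional, Tuple

from .game_core import (
    PairConfig,
    StrainParams,
    fitness_components,
    payoff_matrix,
    reduced_coefficients,
    ReducedCoefficients,
    VARIANTS,
)

__all__ = [
    "Thresholds",
    "RegimeResult",
    "REGIME_LABELS",
    "critical_thresholds",
    "threshold_from_payoff",
    "classify_regime",
    "corner_stability_oracle",
]

#: The four corner states (x_A, x_B) of the unit square.
CORNERS: Tuple[Tuple[int, int], ...] = ((0, 0), (1, 0), (0, 1), (1, 1))

REGIME_LABELS = (
    "no_targeting",
    "A_targets_B",
    "B_targets_A",
    "mutual_targeting",
    "cyclic",
    "bistable_unidirectional",
    "bistable_mutual_or_none",
    "boundary",
)

_CORNER_TO_LABEL = {
    (0, 0): "no_targeting",
    (1, 0): "A_targets_B",
    (0, 1): "B_targets_A",
    (1, 1): "mutual_targeting",
}


@dataclass(frozen=True)
class Thresholds:
    """Critical coinfection probabilities (may be ``math.inf``)."""

    P_star: float
    P_star_star: float


def _linear_root_threshold(c: float, slope: float) -> float:
    """Root of the invasion fitness  -c + slope * p  on p >= 0.

    Every variant's invasion fitness is linear in p with intercept -c,
    so the critical probability is c / slope when the slope is positive
    and +infinity when targeting never becomes beneficial.
    """
    if slope > 0.0:
        return c / slope
    return math.inf


def threshold_from_payoff(strain: StrainParams, variant: str = "standard",
                          against_targeting: bool = False) -> float:
    """Critical coinfection probability derived from the payoff matrix.

    The invasion fitness of the array (f1 - f2 at opponent fraction 0
    for ``P*``, or 1 for ``P**``) is linear in p; its root is found from
    evaluations at p = 0 and p = 1.  This generic route lets the
    modified provirus threshold emerge from the modified payoff rather
    than from a hard-coded formula.
    """
    x = 1.0 if against_targeting else 0.0

    def invasion(p: float) -> float:
        f1, f2 = fitness_components(strain, p, x, variant)
        return f1 - f2

    g0 = invasion(0.0)  # equals -c in every variant
    slope = invasion(1.0) - g0
    return _linear_root_threshold(-g0, slope)


def critical_thresholds(strain: StrainParams,
                        variant: str = "standard") -> Thresholds:
    """Closed-form critical thresholds (P*, P**) for one strain.

    ``standard``: P* = c/(1-w) (infinite when w = 1 and c > 0) and
    P** = c/(q - qc + c) (infinite when the denominator is <= 0).

    ``provirus_pair``: the targeting payoff no longer depends on the
    opponent, which modifies P*; at q = 1/2 it takes the closed form
    2c / (1 + c - 2w) (infinite when the denominator is <= 0).  P** is
    unchanged.

    ``se_blocking``: arrays never pay off; both thresholds are infinite
    for c > 0.
    """
    if variant not in VARIANTS:
        raise ValueError(f"variant={variant!r} not one of {VARIANTS}")
    c, w, q = strain.c, strain.w, strain.q
    if variant == "se_blocking":
        p1 = p2 = math.inf if c > 0 else 0.0
        return Thresholds(P_star=p1, P_star_star=p2)
    if variant == "provirus_pair":
        # slope of the invasion fitness vs a non-targeting opponent
        p_star = _linear_root_threshold(c, (1.0 - c) * q - w + c)
    else:
        p_star = _linear_root_threshold(c, 1.0 - w)
    p_star_star = _linear_root_threshold(c, q - q * c + c)
    return Thresholds(P_star=p_star, P_star_star=p_star_star)


@dataclass(frozen=True)
class RegimeResult:
    """Outcome of the regime classification for one virus pair."""

    label: str
    thresholds_A: Thresholds
    thresholds_B: Thresholds
    stable_corners: FrozenSet[Tuple[int, int]]
    interior_equilibrium: Optional[Tuple[float, float]]
    coefficients: ReducedCoefficients

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "P_star_A": self.thresholds_A.P_star,
            "P_star_star_A": self.thresholds_A.P_star_star,
            "P_star_B": self.thresholds_B.P_star,
            "P_star_star_B": self.thresholds_B.P_star_star,
            "stable_corners": sorted(list(c) for c in self.stable_corners),
            "interior_equilibrium": (
                list(self.interior_equilibrium)
                if self.interior_equilibrium is not None else None),
        }

    def to_json(self) -> str:
        def _enc(o):
            return "Infinity" if o == math.inf else o
        return json.dumps(self.to_dict(), default=_enc)


def _interior_equilibrium(coeffs: ReducedCoefficients
                          ) -> Optional[Tuple[float, float]]:
    """Interior rest point (x_A*, x_B*) = (-a'/b', -a/b), if in (0,1)^2."""
    if coeffs.b == 0.0 or coeffs.b_prime == 0.0:
        return None
    x_b = -coeffs.a / coeffs.b
    x_a = -coeffs.a_prime / coeffs.b_prime
    if 0.0 < x_a < 1.0 and 0.0 < x_b < 1.0:
        return (x_a, x_b)
    return None


def _stable_corners_from_signs(a: float, ab: float, ap: float, abp: float
                               ) -> FrozenSet[Tuple[int, int]]:
    """Corners of [0,1]^2 that resist invasion (strict inequalities)."""
    stable = set()
    if a < 0.0 and ap < 0.0:
        stable.add((0, 0))
    if ab > 0.0 and abp > 0.0:
        stable.add((1, 1))
    if a > 0.0 and abp < 0.0:
        stable.add((1, 0))
    if ab < 0.0 and ap > 0.0:
        stable.add((0, 1))
    return frozenset(stable)


def classify_regime(pair: PairConfig) -> RegimeResult:
    """Classify the evolutionary outcome of a two-virus competition.

    The label is determined by the signs of the invasion-fitness
    coefficients (a, a+b) for strain A and (a', a'+b') for strain B,
    which is equivalent to comparing each strain's coinfection
    probability with its critical thresholds:

    * one stable corner: the corresponding pure regime;
    * two stable corners: a bistable regime (``bistable_unidirectional``
      for {(1,0),(0,1)}, ``bistable_mutual_or_none`` for {(0,0),(1,1)});
    * no stable corner: ``cyclic`` (closed orbits around the interior
      neutral equilibrium);
    * any coefficient exactly zero (the coinfection probability sits
      exactly on a threshold): ``boundary``.

    Loss rates must be zero; the spacer-loss extension is handled in
    :mod:`minicrispr.loss_model`.
    """
    if pair.strain_A.d != 0.0 or pair.strain_B.d != 0.0:
        raise ValueError(
            "classify_regime requires d_A = d_B = 0; use the loss model for "
            "nonzero spacer-loss rates")
    coeffs = reduced_coefficients(pair)
    a, b = coeffs.a, coeffs.b
    ap, bp = coeffs.a_prime, coeffs.b_prime
    signs = (a, a + b, ap, ap + bp)
    thr_A = critical_thresholds(pair.strain_A, pair.effective_variant("A"))
    thr_B = critical_thresholds(pair.strain_B, pair.effective_variant("B"))
    stable = _stable_corners_from_signs(*signs)
    interior = _interior_equilibrium(coeffs)

    if any(s == 0.0 for s in signs):
        label = "boundary"
    elif len(stable) == 1:
        label = _CORNER_TO_LABEL[next(iter(stable))]
    elif len(stable) == 2:
        if stable == frozenset({(1, 0), (0, 1)}):
            label = "bistable_unidirectional"
        elif stable == frozenset({(0, 0), (1, 1)}):
            label = "bistable_mutual_or_none"
        else:  # pragma: no cover - impossible for strict signs
            raise AssertionError(f"unexpected stable-corner pair {stable}")
    else:
        # With strict signs, no stable corner implies the mixed
        # coordination/anti-coordination case with a center inside
        # (0,1)^2: the cyclic polymorphism.
        assert len(stable) == 0 and interior is not None, (stable, interior)
        label = "cyclic"

    return RegimeResult(label=label, thresholds_A=thr_A, thresholds_B=thr_B,
                        stable_corners=stable, interior_equilibrium=interior,
                        coefficients=coeffs)


def corner_stability_oracle(pair: PairConfig) -> FrozenSet[Tuple[int, int]]:
    """Stable corners found by direct invasion analysis.

    Independent of the reduced coefficients: for each corner of
    [0,1]^2, the invasion fitness of each strain's absent strategy is
    evaluated straight from the payoff-mixture fitness components; a
    corner is stable when neither absent strategy can invade (strictly).
    Used to verify :func:`classify_regime`.
    """
    stable = set()
    for corner in CORNERS:
        ok = True
        for strain_name, own, other in (("A", corner[0], corner[1]),
                                        ("B", corner[1], corner[0])):
            params, p = pair.focal(strain_name)
            f1, f2 = fitness_components(
                params, p, float(other), pair.effective_variant(strain_name))
            invasion = (f1 - f2) if own == 0 else (f2 - f1)
            if invasion >= 0.0:
                ok = False
                break
        if ok:
            stable.add(corner)
    return frozenset(stable)
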