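"""Spacer-loss extension of the mini-CRISPR conflict game.

Spacers in mini-arrays are lost at a per-generation rate ``d`` (deletion
bias / recombination between repeats), turning the replicator equations
into a replicator-mutator system.  The closed-form results below are
derived for the neutral-coinfection case w = 1/2; other values of w
route to direct numerical integration of the mutator dynamics
(:func:`minicrispr.dynamics.simulate_replicator`), for which no closed
forms are available.

Key quantities (all at w = 1/2):

* first threshold  P* = 2 (c + d - c d);
* selection coefficient against array loss (opponent not engaged)
  s = (p/2 - c) / (1 - c);
* second threshold for strain A
  P**_A = 2 (c_A + d_A - c_A d_A) /
          (1 + (1 - d_B/s_B)(1 - 2 (1-c_A)(1-q_A)(1-d_A))),
  where (1 - d_B/s_B) is the polymorphic spacer fraction of the
  targeting opponent;
* in targeting populations, loss maintains a polymorphism with carrier
  fraction x = 1 - d/s.

With c = 0 the cost and loss rate are exchangeable: the thresholds
reduce (to first order in d) to P* = 2d and P** = d/(q - qd + d), the
loss-free forms with c replaced by d.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Tuple

from .game_core import PairConfig, StrainParams

__all__ = [
    "LossThresholds",
    "BistableTopology",
    "selection_coefficient",
    "loss_thresholds",
    "polymorphic_fraction",
    "bistable_region_approx",
]

_W_TOL = 1e-12


def _require_half_w(*strains: StrainParams) -> None:
    for s in strains:
        if abs(s.w - 0.5) > _W_TOL:
            raise ValueError(
                f"the spacer-loss closed forms are derived for w = 1/2; "
                f"got w = {s.w}. Use simulate_replicator for other yields.")


def selection_coefficient(p_coinf_other_strain: float, c: float) -> float:
    """Selection coefficient s against losing the mini-array (w = 1/2).

    s = (p/2 - c) / (1 - c): the relative fitness reduction a virus
    suffers on losing its array, given that the opponent does not engage
    in the arms race.  May be <= 0 when the array is not beneficial.
    """
    if c >= 1.0:
        raise ValueError(f"c={c} must be < 1")
    if c < 0.0:
        raise ValueError(f"c={c} must be >= 0")
    p = float(p_coinf_other_strain)
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p_coinf_other_strain={p} outside [0, 1]")
    return (p / 2.0 - c) / (1.0 - c)


@dataclass(frozen=True)
class LossThresholds:
    """Loss-adjusted critical thresholds for one strain.

    ``s_self`` is the strain's own selection coefficient against array
    loss; ``s_other`` the opponent's (which enters this strain's P**
    through the opponent's polymorphic carrier fraction).
    ``array_unsustainable_other`` flags the case where the opponent
    cannot maintain its array at all (s_other <= 0 or d >= s_other with
    d > 0), in which case P** is reported as +infinity.
    """

    P_star: float
    P_star_star: float
    s_self: float
    s_other: float
    array_unsustainable_other: bool = False


def _one_strain_loss_thresholds(own: StrainParams, other: StrainParams,
                                p_own: float, p_other: float
                                ) -> LossThresholds:
    c, d, q = own.c, own.d, own.q
    p_star = 2.0 * (c + d - c * d)
    s_self = selection_coefficient(p_own, c)
    s_other = selection_coefficient(p_other, other.c)

    unsustainable = False
    if other.d > 0.0 and (s_other <= 0.0 or other.d >= s_other):
        unsustainable = True
        p_star_star = math.inf
    else:
        x_other = 1.0 if other.d == 0.0 else 1.0 - other.d / s_other
        denom = 1.0 + x_other * (1.0 - 2.0 * (1.0 - c) * (1.0 - q) * (1.0 - d))
        p_star_star = p_star / denom if denom > 0.0 else math.inf
    return LossThresholds(P_star=p_star, P_star_star=p_star_star,
                          s_self=s_self, s_other=s_other,
                          array_unsustainable_other=unsustainable)


def loss_thresholds(pair: PairConfig) -> Tuple[LossThresholds, LossThresholds]:
    """Loss-adjusted (P*, P**) for both strains of a w = 1/2 pair.

    P* = 2(c + d - cd) per strain.  P** for a strain depends on the
    *opponent's* coinfection probability through the opponent's
    polymorphic carrier fraction 1 - d/s, so in the coinfection plane it
    is a curve rather than a straight line.  With d = 0 both reduce to
    the loss-free forms at w = 1/2.
    """
    _require_half_w(pair.strain_A, pair.strain_B)
    thr_A = _one_strain_loss_thresholds(
        pair.strain_A, pair.strain_B, pair.p_B_given_A, pair.p_A_given_B)
    thr_B = _one_strain_loss_thresholds(
        pair.strain_B, pair.strain_A, pair.p_A_given_B, pair.p_B_given_A)
    return thr_A, thr_B


def polymorphic_fraction(d: float, s: float) -> float:
    """Equilibrium spacer-carrier fraction 1 - d/s under loss-selection
    balance (unidirectional-targeting regime).

    Nonpositive values are reported as 0 (the array cannot be
    maintained), with a warning when selection cannot oppose loss at
    all (s <= 0 with d > 0).
    """
    if d < 0.0:
        raise ValueError(f"d={d} must be >= 0")
    if d == 0.0:
        return 1.0
    if s <= 0.0:
        warnings.warn(
            "selection coefficient s <= 0 with d > 0: the mini-array "
            "cannot persist; returning carrier fraction 0",
            RuntimeWarning, stacklevel=2)
        return 0.0
    return max(0.0, 1.0 - d / s)


@dataclass(frozen=True)
class BistableTopology:
    """Which bistable-region topology governs the phase plane at small loss.

    ``indicator`` per strain is (1-q)(1-c)(1-d); the topology is
    ``unidirectional_bistable`` (P* < P**: the central bistable region
    holds unidirectional targeting either way) when the indicator
    exceeds 1/2 for both strains, and ``mutual_or_none_bistable``
    (P** < P*) when it is below 1/2 for both; ``mixed`` when the strains
    fall on opposite sides, and ``boundary`` when an indicator equals
    1/2 exactly.  The approximation requires d small
    compared to both selection coefficients; ``approximation_valid``
    records whether d <= s/10 holds for both strains.
    """

    topology: str  # unidirectional_bistable | mutual_or_none_bistable | mixed | boundary
    indicator_A: float
    indicator_B: float
    s_A: float
    s_B: float
    approximation_valid: bool


def bistable_region_approx(pair: PairConfig) -> BistableTopology:
    """Small-loss approximation of the bistable-region topology."""
    _require_half_w(pair.strain_A, pair.strain_B)
    A, B = pair.strain_A, pair.strain_B
    ind_A = (1.0 - A.q) * (1.0 - A.c) * (1.0 - A.d)
    ind_B = (1.0 - B.q) * (1.0 - B.c) * (1.0 - B.d)
    s_A = selection_coefficient(pair.p_B_given_A, A.c)
    s_B = selection_coefficient(pair.p_A_given_B, B.c)
    valid = all(s > 0.0 and d <= s / 10.0
                for s, d in ((s_A, A.d), (s_B, B.d)))
    if ind_A == 0.5 or ind_B == 0.5:
        topology = "boundary"
    elif ind_A > 0.5 and ind_B > 0.5:
        topology = "unidirectional_bistable"
    elif ind_A < 0.5 and ind_B < 0.5:
        topology = "mutual_or_none_bistable"
    else:
        topology = "mixed"
    return BistableTopology(topology=topology, indicator_A=ind_A,
                            indicator_B=ind_B, s_A=s_A, s_B=s_B,
                            approximation_valid=valid)
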