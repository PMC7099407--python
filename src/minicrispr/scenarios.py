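"""Lifestyle-specific presets of the mini-CRISPR conflict game.

The general two-virus game specialises according to the competitors'
lifestyles:

* **lytic vs lytic** -- either virus is equally likely to enter first
  (q = 1/2); closely related viruses warrant a shared cost and yield,
  giving thresholds P* = c/(1-w) and P** = 2c/(1+c).
* **lytic vs temperate/chronic** -- coinfection is superinfection of a
  resident temperate virus by an incoming lytic one, so the resident
  always "arrives first": q_T = 1, q_L = 0.  A chronic virus's
  productivity is ruined by lytic superinfection (w_T -> 0), collapsing
  its thresholds to P_T* ~ P_T** = c_T.
* **lytic vs provirus with early-acting superinfection exclusion** --
  arrays help neither side; no targeting evolves (``se_blocking``).
* **lytic vs provirus with late-acting exclusion** -- the lytic virus
  can use its array to destroy proviral genes and escape exclusion;
  without targeting it gets nothing (w_L = 0) while the provirus is
  safe (w_T = 1), giving P_T* = infinity, P_T** = c_T, P_L* = c_L and a
  cyclic arms race whenever both coinfection probabilities exceed the
  costs.
* **temperate vs temperate (active)** -- formally the lytic-lytic game.
* **provirus vs provirus** -- destroying the resident degrades the host
  genome, so a targeting provirus forfeits nothing more when targeted
  back: the ``provirus_pair`` payoff with q = 1/2 and
  P* = 2c/(1+c-2w).

The multi-virus case with linearly scaling array cost decomposes into
independent pairwise games (:func:`pairwise_decompose`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .game_core import PairConfig, StrainParams
from .regimes import RegimeResult, Thresholds, classify_regime

__all__ = [
    "SCENARIO_NAMES",
    "ScenarioPreset",
    "build_scenario",
    "lytic_temperate_thresholds",
    "lytic_temperate_classify",
    "pairwise_decompose",
]


@dataclass(frozen=True)
class ScenarioPreset:
    """A named lifestyle scenario: the constraints it imposes and the
    parameters it leaves free."""

    name: str
    fixed: dict
    free: Tuple[str, ...]
    description: str


SCENARIOS: Dict[str, ScenarioPreset] = {
    "lytic_lytic": ScenarioPreset(
        "lytic_lytic",
        fixed={"q_A": 0.5, "q_B": 0.5, "variant": "standard"},
        free=("c", "w", "p_B_given_A", "p_A_given_B", "d"),
        description="two closely related lytic viruses; shared c and w"),
    "lytic_temperate_chronic": ScenarioPreset(
        "lytic_temperate_chronic",
        fixed={"q_T": 1.0, "q_L": 0.0, "variant": "standard", "w_T": 0.0},
        free=("c_L", "c_T", "w_L", "w_T", "p_L_given_T", "p_T_given_L"),
        description="resident chronic/temperate virus (strain A) vs "
                    "incoming lytic virus (strain B); w_T defaults to 0"),
    "lytic_provirus_early_SE": ScenarioPreset(
        "lytic_provirus_early_SE",
        fixed={"q_T": 1.0, "q_L": 0.0, "variant": "se_blocking"},
        free=("c_L", "c_T", "p_L_given_T", "p_T_given_L"),
        description="early-acting superinfection exclusion: arrays help "
                    "neither virus"),
    "lytic_provirus_late_SE": ScenarioPreset(
        "lytic_provirus_late_SE",
        fixed={"q_T": 1.0, "q_L": 0.0, "w_L": 0.0, "w_T": 1.0,
               "variant": "standard"},
        free=("c_L", "c_T", "p_L_given_T", "p_T_given_L"),
        description="late-acting exclusion that CRISPR targeting can "
                    "overcome: w_L = 0, w_T = 1"),
    "temperate_temperate_active": ScenarioPreset(
        "temperate_temperate_active",
        fixed={"q_A": 0.5, "q_B": 0.5, "variant": "standard"},
        free=("c", "w", "p_B_given_A", "p_A_given_B", "d"),
        description="two actively replicating non-lytic viruses; formally "
                    "the lytic-lytic game"),
    "provirus_provirus": ScenarioPreset(
        "provirus_provirus",
        fixed={"q_A": 0.5, "q_B": 0.5, "variant": "provirus_pair"},
        free=("c", "w", "p_B_given_A", "p_A_given_B", "d"),
        description="two proviruses; destroying the resident degrades the "
                    "host genome (modified payoff)"),
    "provirus_provirus_SE": ScenarioPreset(
        "provirus_provirus_SE",
        fixed={"q_A": 0.5, "q_B": 0.5, "variant": "provirus_pair"},
        free=("c", "w", "p_B_given_A", "p_A_given_B", "se", "d"),
        description="proviruses with unbeatable superinfection exclusion: "
                    "the protected strain(s) gain nothing from arrays"),
}

SCENARIO_NAMES = tuple(SCENARIOS)


def _reject_overrides(name: str, kwargs: dict, allowed: Sequence[str]) -> None:
    bad = sorted(set(kwargs) - set(allowed))
    if bad:
        raise ValueError(
            f"scenario {name!r} fixes or does not accept parameters {bad}; "
            f"free parameters are {sorted(allowed)}")


def _symmetric_scenario(name: str, lifestyle: str, variant: str,
                        kwargs: dict) -> PairConfig:
    allowed = ("c", "w", "p_B_given_A", "p_A_given_B", "d")
    _reject_overrides(name, kwargs, allowed)
    c = kwargs.get("c", 0.1)
    w = kwargs.get("w", 0.5)
    d = kwargs.get("d", 0.0)
    strain = StrainParams(c=c, w=w, q=0.5, d=d, lifestyle=lifestyle)
    return PairConfig(strain_A=strain, strain_B=strain,
                      p_B_given_A=kwargs.get("p_B_given_A", 0.3),
                      p_A_given_B=kwargs.get("p_A_given_B", 0.3),
                      variant=variant)


def build_scenario(name: str, **free_params) -> PairConfig:
    """Build the :class:`PairConfig` of a named lifestyle scenario.

    Only the scenario's free parameters may be supplied; attempts to
    override a constrained parameter (e.g. q in any scenario) raise.
    For the lytic-temperate scenarios strain A is the temperate/provirus
    resident and strain B the lytic invader, so ``p_L_given_T`` maps to
    ``p_B_given_A``.
    """
    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; choose from "
                         f"{SCENARIO_NAMES}")
    kw = dict(free_params)

    if name in ("lytic_lytic", "temperate_temperate_active"):
        lifestyle = "lytic" if name == "lytic_lytic" else "chronic"
        return _symmetric_scenario(name, lifestyle, "standard", kw)

    if name == "provirus_provirus":
        return _symmetric_scenario(name, "provirus", "provirus_pair", kw)

    if name == "provirus_provirus_SE":
        se = kw.pop("se", "both")
        if se not in ("A", "B", "both"):
            raise ValueError(f"se={se!r} must be 'A', 'B' or 'both'")
        pair = _symmetric_scenario(name, "provirus", "provirus_pair", kw)
        return PairConfig(strain_A=pair.strain_A, strain_B=pair.strain_B,
                          p_B_given_A=pair.p_B_given_A,
                          p_A_given_B=pair.p_A_given_B,
                          variant="provirus_pair",
                          se_A=se in ("A", "both"),
                          se_B=se in ("B", "both"))

    # lytic-temperate family: A = temperate/provirus resident (q=1),
    # B = lytic invader (q=0).
    allowed = {"lytic_temperate_chronic":
                   ("c_L", "c_T", "w_L", "w_T", "p_L_given_T", "p_T_given_L"),
               "lytic_provirus_early_SE":
                   ("c_L", "c_T", "p_L_given_T", "p_T_given_L"),
               "lytic_provirus_late_SE":
                   ("c_L", "c_T", "p_L_given_T", "p_T_given_L")}[name]
    _reject_overrides(name, kw, allowed)
    c_T = kw.get("c_T", 0.1)
    c_L = kw.get("c_L", 0.1)
    if name == "lytic_temperate_chronic":
        w_T = kw.get("w_T", 0.0)
        w_L = kw.get("w_L", 0.5)
        lifestyle_T = "chronic"
        variant = "standard"
    elif name == "lytic_provirus_early_SE":
        w_T, w_L = 1.0, 0.0
        lifestyle_T = "provirus"
        variant = "se_blocking"
    else:  # lytic_provirus_late_SE
        w_T, w_L = 1.0, 0.0
        lifestyle_T = "provirus"
        variant = "standard"
    temperate = StrainParams(c=c_T, w=w_T, q=1.0, lifestyle=lifestyle_T)
    lytic = StrainParams(c=c_L, w=w_L, q=0.0, lifestyle="lytic")
    return PairConfig(strain_A=temperate, strain_B=lytic,
                      p_B_given_A=kw.get("p_L_given_T", 0.3),
                      p_A_given_B=kw.get("p_T_given_L", 0.3),
                      variant=variant)


def lytic_temperate_thresholds(c_L: float, c_T: float, w_L: float,
                               w_T: float) -> Tuple[float, float, float, float]:
    """Critical thresholds (P_T*, P_T**, P_L*, P_L**) with q_T=1, q_L=0.

    P_T* = c_T/(1-w_T) (infinite at w_T = 1), P_T** = c_T,
    P_L* = c_L/(1-w_L), and P_L** = 1 always (with q_L = 0 the lytic
    virus never profits from targeting a targeting resident, and
    p <= 1 by definition).
    """
    T = StrainParams(c=c_T, w=w_T, q=1.0, lifestyle="chronic")
    L = StrainParams(c=c_L, w=w_L, q=0.0, lifestyle="lytic")
    from .regimes import critical_thresholds
    thr_T = critical_thresholds(T)
    thr_L = critical_thresholds(L)
    return (thr_T.P_star, thr_T.P_star_star, thr_L.P_star, thr_L.P_star_star)


def lytic_temperate_classify(c_L: float, c_T: float, w_L: float, w_T: float,
                             p_L_given_T: float, p_T_given_L: float
                             ) -> RegimeResult:
    """Classify a lytic-vs-temperate competition.

    Strain A is the temperate resident, strain B the lytic invader.
    With q_L = 0 the corner of mutual targeting is never stable: the
    lytic virus's payoff against a targeting resident is strictly
    dominated by dropping the array, so only no-targeting,
    unidirectional targeting (either way) or cyclic polymorphism can
    result.
    """
    temperate = StrainParams(c=c_T, w=w_T, q=1.0, lifestyle="chronic")
    lytic = StrainParams(c=c_L, w=w_L, q=0.0, lifestyle="lytic")
    pair = PairConfig(strain_A=temperate, strain_B=lytic,
                      p_B_given_A=p_L_given_T, p_A_given_B=p_T_given_L)
    return classify_regime(pair)


def pairwise_decompose(strains: Sequence[StrainParams],
                       p_matrix,
                       cost_scaling: str = "linear"
                       ) -> Dict[Tuple[int, int], RegimeResult]:
    """Decompose an n-virus competition into independent pairwise games.

    When the array cost scales linearly with the number of targeted
    competitors, each pair can be analysed separately with the two-virus
    model.  ``p_matrix[i][j]`` is the probability that an infection by
    virus ``i`` is a coinfection with virus ``j``.  Returns a dict
    mapping each ordered pair (i, j), i != j, to the RegimeResult of the
    game with A = strain i, B = strain j (the (j, i) entry is the
    mirrored game).
    """
    if cost_scaling != "linear":
        raise NotImplementedError(
            f"cost_scaling={cost_scaling!r}: only 'linear' cost scaling "
            "admits a pairwise decomposition")
    strains = list(strains)
    n = len(strains)
    if n < 2:
        raise ValueError("need at least 2 strains")
    p = np.asarray(p_matrix, dtype=float)
    if p.shape != (n, n):
        raise ValueError(f"p_matrix must be {n}x{n}, got {p.shape}")
    if np.any(p < 0.0) or np.any(p > 1.0):
        raise ValueError("p_matrix entries must be probabilities in [0, 1]")
    out: Dict[Tuple[int, int], RegimeResult] = {}
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            pair = PairConfig(strain_A=strains[i], strain_B=strains[j],
                              p_B_given_A=p[i, j], p_A_given_B=p[j, i])
            out[(i, j)] = classify_regime(pair)
    return out
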