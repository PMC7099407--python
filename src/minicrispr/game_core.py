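"""Core machinery of the mini-CRISPR interviral-conflict game.

Some bacterial and archaeal viruses carry mini-CRISPR arrays (one or two
spacers, no *cas* genes) that, combined with the host's Cas machinery,
target a competing virus during coinfection of the same host cell.
Whether carrying such an array pays off is a cost--benefit problem: the
array imposes a productivity cost ``c`` on its carrier, and pays off only
in the fraction ``p`` of infections that are coinfections with the rival.

This module holds the parameter containers, the 2x2 payoff (mean
productivity) matrix of the game and its provirus / superinfection-
exclusion variants, the strategy-class fitness components and mean
fitness, the reduced replicator coefficients (a, b, a', b'), and the
Bayes bookkeeping that relates the two directed coinfection
probabilities.

Conventions
-----------
* Productivity of a single clean infection is normalised to 1.
* ``x_A``/``x_B`` denote the fraction of each strain carrying a spacer
  against the other strain ("targeting" strategy).
* ``p_B_given_A`` is the probability that an infection by virus A is a
  coinfection with virus B (and symmetrically for ``p_A_given_B``).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import yaml

__all__ = [
    "LIFESTYLES",
    "VARIANTS",
    "StrainParams",
    "PairConfig",
    "CoinfectionMarginals",
    "PayoffMatrix",
    "ReducedCoefficients",
    "payoff_matrix",
    "fitness_components",
    "mean_fitness",
    "strain_coefficients",
    "coefficients_from_payoff",
    "reduced_coefficients",
    "bayes_coinfection",
    "split_by_arrival",
    "read_pair_config",
    "write_pair_config",
]

LIFESTYLES = ("lytic", "chronic", "provirus")
VARIANTS = ("standard", "provirus_pair", "se_blocking")


def _check_range(name: str, value: float, lo: float, hi: float,
                 *, hi_open: bool = False) -> float:
    """Validate lo <= value <= hi (or < hi), raising with the field name."""
    try:
        value = float(value)
    except (TypeError, ValueError):
        raise ValueError(f"{name} must be a number, got {value!r}") from None
    if math.isnan(value):
        raise ValueError(f"{name} must not be NaN")
    if value < lo or value > hi or (hi_open and value == hi):
        bound = f"[{lo}, {hi})" if hi_open else f"[{lo}, {hi}]"
        raise ValueError(f"{name}={value} outside the valid range {bound}")
    return value


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StrainParams:
    """Parameters of one virus strain.

    Attributes
    ----------
    c : float
        Fitness cost of carrying the mini-CRISPR array, as a fraction of
        single-infection productivity (0 <= c < 1).
    w : float
        Productivity in a mixed coinfection when neither virus targets
        the other, relative to a pure infection (0 <= w <= 1).  w = 1/2
        means no interference, w < 1/2 interference, w > 1/2
        facilitation.
    q : float
        Probability that this virus is the first to arrive (and hence
        survives) when there is mutual targeting (0 <= q <= 1).
    d : float
        Spacer loss rate per generation (0 <= d < 1); d = 0 recovers the
        loss-free model.
    lifestyle : str
        One of ``lytic``, ``chronic`` (actively replicating non-lytic),
        or ``provirus``.
    """

    c: float
    w: float
    q: float
    d: float = 0.0
    lifestyle: str = "lytic"

    def __post_init__(self) -> None:
        object.__setattr__(self, "c", _check_range("c", self.c, 0.0, 1.0, hi_open=True))
        object.__setattr__(self, "w", _check_range("w", self.w, 0.0, 1.0))
        object.__setattr__(self, "q", _check_range("q", self.q, 0.0, 1.0))
        object.__setattr__(self, "d", _check_range("d", self.d, 0.0, 1.0, hi_open=True))
        if self.lifestyle not in LIFESTYLES:
            raise ValueError(
                f"lifestyle={self.lifestyle!r} not one of {LIFESTYLES}")


@dataclass(frozen=True)
class PairConfig:
    """A two-virus competition: both strains plus directed coinfection
    probabilities and the game variant.

    ``variant`` selects the payoff structure:

    * ``standard`` -- the base game.
    * ``provirus_pair`` -- destroying a resident provirus degrades the
      host genome, so a targeting virus obtains the mutual-targeting
      payoff regardless of the opponent's strategy.
    * ``se_blocking`` -- early-acting superinfection exclusion: arrays
      confer no benefit to either virus (both pay the cost only), which
      forces the no-targeting outcome.

    ``se_A`` / ``se_B`` zero the array benefit for one strain only
    (a provirus protected by exclusion that cannot be overcome); setting
    ``variant='se_blocking'`` is equivalent to setting both flags.
    """

    strain_A: StrainParams
    strain_B: StrainParams
    p_B_given_A: float
    p_A_given_B: float
    variant: str = "standard"
    se_A: bool = False
    se_B: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "p_B_given_A",
            _check_range("p_B_given_A", self.p_B_given_A, 0.0, 1.0))
        object.__setattr__(
            self, "p_A_given_B",
            _check_range("p_A_given_B", self.p_A_given_B, 0.0, 1.0))
        if self.variant not in VARIANTS:
            raise ValueError(f"variant={self.variant!r} not one of {VARIANTS}")
        q_sum = self.strain_A.q + self.strain_B.q
        if q_sum > 1.0 + 1e-12:
            raise ValueError(
                f"q_A + q_B = {q_sum} > 1; at most one virus can win a "
                "mutual-targeting race")

    # -- variant resolution -------------------------------------------------

    def effective_variant(self, strain: str) -> str:
        """Payoff variant that applies to strain ``'A'`` or ``'B'``."""
        if strain not in ("A", "B"):
            raise ValueError(f"strain must be 'A' or 'B', got {strain!r}")
        se = self.se_A if strain == "A" else self.se_B
        if self.variant == "se_blocking" or se:
            return "se_blocking"
        return self.variant

    def focal(self, strain: str) -> tuple[StrainParams, float]:
        """Return (params, coinfection probability) for one strain."""
        if strain == "A":
            return self.strain_A, self.p_B_given_A
        if strain == "B":
            return self.strain_B, self.p_A_given_B
        raise ValueError(f"strain must be 'A' or 'B', got {strain!r}")

    def swapped(self) -> "PairConfig":
        """The same pair with the roles of A and B exchanged."""
        return PairConfig(
            strain_A=self.strain_B, strain_B=self.strain_A,
            p_B_given_A=self.p_A_given_B, p_A_given_B=self.p_B_given_A,
            variant=self.variant, se_A=self.se_B, se_B=self.se_A)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        """Flat key-value form (keys follow the standard symbols)."""
        return {
            "c_A": self.strain_A.c, "c_B": self.strain_B.c,
            "w_A": self.strain_A.w, "w_B": self.strain_B.w,
            "q_A": self.strain_A.q, "q_B": self.strain_B.q,
            "d_A": self.strain_A.d, "d_B": self.strain_B.d,
            "p_B_given_A": self.p_B_given_A,
            "p_A_given_B": self.p_A_given_B,
            "variant": self.variant,
            "lifestyle_A": self.strain_A.lifestyle,
            "lifestyle_B": self.strain_B.lifestyle,
            "se_A": self.se_A, "se_B": self.se_B,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "PairConfig":
        required = ("c_A", "c_B", "w_A", "w_B", "q_A", "q_B",
                    "p_B_given_A", "p_A_given_B")
        missing = [k for k in required if k not in data]
        if missing:
            raise ValueError(f"config is missing required keys: {missing}")
        known = set(required) | {"d_A", "d_B", "variant", "lifestyle_A",
                                 "lifestyle_B", "se_A", "se_B"}
        unknown = sorted(set(data) - known)
        if unknown:
            raise ValueError(f"config has unknown keys: {unknown}")
        strain_A = StrainParams(
            c=data["c_A"], w=data["w_A"], q=data["q_A"],
            d=data.get("d_A", 0.0), lifestyle=data.get("lifestyle_A", "lytic"))
        strain_B = StrainParams(
            c=data["c_B"], w=data["w_B"], q=data["q_B"],
            d=data.get("d_B", 0.0), lifestyle=data.get("lifestyle_B", "lytic"))
        return cls(strain_A=strain_A, strain_B=strain_B,
                   p_B_given_A=data["p_B_given_A"],
                   p_A_given_B=data["p_A_given_B"],
                   variant=data.get("variant", "standard"),
                   se_A=bool(data.get("se_A", False)),
                   se_B=bool(data.get("se_B", False)))


def read_pair_config(path: Union[str, Path]) -> PairConfig:
    """Read a :class:`PairConfig` from a flat JSON or YAML file."""
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise ValueError(f"config file {path} is empty")
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:  # .yaml / .yml; YAML is a JSON superset so this also reads JSON
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} does not contain a mapping")
    return PairConfig.from_dict(data)


def write_pair_config(pair: PairConfig, path: Union[str, Path]) -> None:
    """Write a :class:`PairConfig` to JSON or YAML (by file suffix).

    Floats are written with full (round-trip) precision.
    """
    path = Path(path)
    data = pair.to_dict()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=True))


@dataclass(frozen=True)
class CoinfectionMarginals:
    """Host-centric infection probabilities for the two viruses.

    ``p_A`` (``p_B``) is the probability of finding a host infected by
    virus A (B).  The optional order-split components decompose each
    directed coinfection probability by arrival order, e.g.
    ``p_AB_given_A + p_BA_given_A = p_B_given_A``.
    """

    p_A: float
    p_B: float
    p_AB_given_A: Optional[float] = None
    p_BA_given_A: Optional[float] = None
    p_AB_given_B: Optional[float] = None
    p_BA_given_B: Optional[float] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "p_A", _check_range("p_A", self.p_A, 0.0, 1.0))
        object.__setattr__(self, "p_B", _check_range("p_B", self.p_B, 0.0, 1.0))
        for name in ("p_AB_given_A", "p_BA_given_A",
                     "p_AB_given_B", "p_BA_given_B"):
            v = getattr(self, name)
            if v is not None:
                object.__setattr__(self, name, _check_range(name, v, 0.0, 1.0))
        # Bayes consistency when both directed probabilities are implied.
        pba = self.p_B_given_A
        pab = self.p_A_given_B
        if pba is not None and pab is not None:
            if abs(pba * self.p_A - pab * self.p_B) > 1e-9:
                raise ValueError(
                    "inconsistent marginals: p_B_given_A * p_A != "
                    "p_A_given_B * p_B")

    @property
    def p_B_given_A(self) -> Optional[float]:
        if self.p_AB_given_A is None or self.p_BA_given_A is None:
            return None
        return self.p_AB_given_A + self.p_BA_given_A

    @property
    def p_A_given_B(self) -> Optional[float]:
        if self.p_AB_given_B is None or self.p_BA_given_B is None:
            return None
        return self.p_AB_given_B + self.p_BA_given_B


# ---------------------------------------------------------------------------
# Payoffs and fitness
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PayoffMatrix:
    """Mean productivity of one focal virus conditional on both strategies.

    Rows are the focal strategy (array / no array), columns the
    opponent's.  Entries:

    * ``both_target`` -- focal and opponent both carry cross-targeting
      arrays; the first to arrive wins: (1-c)(1-p+qp).
    * ``self_only`` -- only the focal carries an array: 1-c (the rival is
      destroyed in every coinfection).
    * ``other_only`` -- only the opponent targets: 1-p.
    * ``neither`` -- no arrays; coinfections yield w: 1-(1-w)p.
    """

    both_target: float
    self_only: float
    other_only: float
    neither: float

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.both_target, self.self_only, self.other_only, self.neither)


def payoff_matrix(focal: StrainParams, p_coinf: float,
                  variant: str = "standard") -> PayoffMatrix:
    """Payoff (mean productivity) matrix for one focal strain.

    Parameters
    ----------
    focal : StrainParams
        The focal strain's parameters (its cost c, yield w, arrival
        probability q).
    p_coinf : float
        The focal strain's coinfection probability (probability that one
        of its infections is joined by the rival).
    variant : str
        ``standard``, ``provirus_pair`` (targeting pays the
        mutual-targeting payoff regardless of the opponent's strategy),
        or ``se_blocking`` (arrays confer no benefit; carriers simply
        pay the cost).
    """
    p = _check_range("p_coinf", p_coinf, 0.0, 1.0)
    c, w, q = focal.c, focal.w, focal.q
    if variant not in VARIANTS:
        raise ValueError(f"variant={variant!r} not one of {VARIANTS}")
    if variant == "se_blocking":
        base = 1.0 - (1.0 - w) * p
        return PayoffMatrix(both_target=(1.0 - c) * base,
                            self_only=(1.0 - c) * base,
                            other_only=base, neither=base)
    both = (1.0 - c) * (1.0 - p + q * p)
    self_only = both if variant == "provirus_pair" else 1.0 - c
    return PayoffMatrix(both_target=both, self_only=self_only,
                        other_only=1.0 - p, neither=1.0 - (1.0 - w) * p)


def fitness_components(focal: StrainParams, p_coinf: float, x_other: float,
                       variant: str = "standard") -> tuple[float, float]:
    """Fitness of the targeting (f1) and array-free (f2) classes.

    ``x_other`` is the fraction of the opponent strain that carries a
    cross-targeting spacer; f1 and f2 are the ``x_other``-weighted
    mixtures of the corresponding payoff-matrix rows.
    """
    x = _check_range("x_other", x_other, 0.0, 1.0)
    pm = payoff_matrix(focal, p_coinf, variant)
    f1 = pm.both_target * x + pm.self_only * (1.0 - x)
    f2 = pm.other_only * x + pm.neither * (1.0 - x)
    return f1, f2


def mean_fitness(focal: StrainParams, p_coinf: float, x_self: float,
                 x_other: float, variant: str = "standard") -> float:
    """Mean fitness of the focal strain's mixed population."""
    xs = _check_range("x_self", x_self, 0.0, 1.0)
    f1, f2 = fitness_components(focal, p_coinf, x_other, variant)
    return xs * f1 + (1.0 - xs) * f2


# ---------------------------------------------------------------------------
# Reduced replicator coefficients
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReducedCoefficients:
    """Coefficients of the reduced replicator system.

    The two-strain replicator dynamics reduce to

        dx_A/dt = x_A (1 - x_A) (a + b x_B)
        dx_B/dt = x_B (1 - x_B) (a' + b' x_A)

    so that a (a') is strain A's (B's) invasion fitness against a
    non-targeting opponent and a+b (a'+b') against a fully targeting
    one.
    """

    a: float
    b: float
    a_prime: float
    b_prime: float

    def for_strain(self, strain: str) -> tuple[float, float]:
        if strain == "A":
            return self.a, self.b
        if strain == "B":
            return self.a_prime, self.b_prime
        raise ValueError(f"strain must be 'A' or 'B', got {strain!r}")


def coefficients_from_payoff(pm: PayoffMatrix) -> tuple[float, float]:
    """(a, b) derived from the payoff entries.

    f1(x) - f2(x) is linear in the opponent fraction x, so
    a = f1(0) - f2(0) and b = (f1(1) - f2(1)) - a.  This route is
    variant-agnostic and serves as the generic derivation for the
    modified (provirus / exclusion) payoffs.
    """
    a = pm.self_only - pm.neither
    b = (pm.both_target - pm.other_only) - a
    return a, b


def strain_coefficients(focal: StrainParams, p_coinf: float,
                        variant: str = "standard") -> tuple[float, float]:
    """(a, b) for one strain.

    For the standard game the closed forms are used:
    a = (1-w) p - c and b = p (q - qc + c + w - 1).  For the modified
    variants the coefficients are derived from the payoff matrix.
    """
    if variant == "standard":
        c, w, q = focal.c, focal.w, focal.q
        p = _check_range("p_coinf", p_coinf, 0.0, 1.0)
        a = (1.0 - w) * p - c
        b = p * (q - q * c + c + w - 1.0)
        return a, b
    return coefficients_from_payoff(payoff_matrix(focal, p_coinf, variant))


def reduced_coefficients(pair: PairConfig) -> ReducedCoefficients:
    """Reduced replicator coefficients (a, b, a', b') for a pair."""
    a, b = strain_coefficients(pair.strain_A, pair.p_B_given_A,
                               pair.effective_variant("A"))
    ap, bp = strain_coefficients(pair.strain_B, pair.p_A_given_B,
                                 pair.effective_variant("B"))
    return ReducedCoefficients(a=a, b=b, a_prime=ap, b_prime=bp)


# ---------------------------------------------------------------------------
# Coinfection-probability bookkeeping
# ---------------------------------------------------------------------------

def bayes_coinfection(marginals: CoinfectionMarginals,
                      p_A_given_B: float) -> float:
    """Directed coinfection probability p_B|A from Bayes' theorem.

    p_B|A = (p_B / p_A) * p_A|B.  Raises if p_A = 0 (the conditional is
    undefined) or if the marginals are inconsistent (result > 1).
    """
    pab = _check_range("p_A_given_B", p_A_given_B, 0.0, 1.0)
    if marginals.p_A == 0.0:
        raise ValueError(
            "p_A = 0: the coinfection probability p_B_given_A is undefined")
    result = marginals.p_B / marginals.p_A * pab
    if result > 1.0 + 1e-12:
        raise ValueError(
            f"inconsistent marginals: implied p_B_given_A = {result} > 1")
    return min(result, 1.0)


def split_by_arrival(p_coinf: float, q: float) -> tuple[float, float]:
    """Split a coinfection probability by arrival order.

    Returns (p_first, p_second) = (q p, (1-q) p): the probabilities that
    the focal virus's coinfections have it arriving first or second.
    """
    p = _check_range("p_coinf", p_coinf, 0.0, 1.0)
    qv = _check_range("q", q, 0.0, 1.0)
    return qv * p, (1.0 - qv) * p


def replace_param(pair: PairConfig, name: str, value: float) -> PairConfig:
    """Return a copy of ``pair`` with one flat-key parameter replaced.

    ``name`` uses the config-file keys (``c_A``, ``w_B``,
    ``p_B_given_A``, ...).  Used by parameter sweeps.
    """
    if name in ("p_B_given_A", "p_A_given_B"):
        return dataclasses.replace(pair, **{name: value})
    if len(name) > 2 and name[-2] == "_" and name[-1] in "AB":
        field, strain = name[:-2], name[-1]
        if field in ("c", "w", "q", "d"):
            key = f"strain_{strain}"
            new_strain = dataclasses.replace(getattr(pair, key), **{field: value})
            return dataclasses.replace(pair, **{key: new_strain})
    raise ValueError(f"unknown parameter name {name!r}")
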