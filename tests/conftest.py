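import numpy as np
import pytest

from minicrispr import PairConfig, StrainParams


@pytest.fixture
def cyclic_pair() -> PairConfig:
    """Asymmetric pair in the cyclic-polymorphism regime.

    Coefficients (a, b, a', b') = (-0.06, 0.07, 0.05, -0.066); the
    interior neutral equilibrium sits at (25/33, 6/7).
    """
    return PairConfig(
        strain_A=StrainParams(c=0.1, w=0.8, q=0.5),
        strain_B=StrainParams(c=0.1, w=0.5, q=0.2),
        p_B_given_A=0.2,
        p_A_given_B=0.3,
    )


@pytest.fixture
def bistable_pair() -> PairConfig:
    """Symmetric pair where both no-targeting and mutual targeting are
    stable (P** < p < P* for both strains)."""
    strain = StrainParams(c=0.1, w=0.8, q=0.5)
    return PairConfig(strain_A=strain, strain_B=strain,
                      p_B_given_A=0.3, p_A_given_B=0.3)


def random_pair(rng: np.random.Generator, *, c_max: float = 0.3,
                margin: float = 0.0) -> PairConfig:
    """One random parameter draw, optionally excluding near-boundary sets."""
    from minicrispr import reduced_coefficients

    while True:
        q_A, q_B = rng.uniform(0, 1, size=2)
        if q_A + q_B > 1:
            continue
        pair = PairConfig(
            strain_A=StrainParams(c=rng.uniform(0.0, c_max),
                                  w=rng.uniform(0, 1), q=q_A),
            strain_B=StrainParams(c=rng.uniform(0.0, c_max),
                                  w=rng.uniform(0, 1), q=q_B),
            p_B_given_A=rng.uniform(0, 1),
            p_A_given_B=rng.uniform(0, 1),
        )
        if margin > 0:
            co = reduced_coefficients(pair)
            vals = (co.a, co.a + co.b, co.a_prime, co.a_prime + co.b_prime)
            if not all(abs(v) > margin for v in vals):
                continue
        return pair
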