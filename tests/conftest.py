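import numpy as np
import pytest

from g4phase.core_model import (
    Conditions,
    SPECIES,
    Speciation,
    SystemModel,
    equilibrium_constants,
)


@pytest.fixture
def model() -> SystemModel:
    """The reference 22GT/360A parameter set."""
    return SystemModel.default()


def brute_force_speciation(model: SystemModel, cond: Conditions,
                           rounds: int = 14, n: int = 65) -> Speciation:
    """Independent speciation oracle: iteratively refined dense grid search
    over the free-ligand level, minimising the ligand-conservation residual.

    Never calls the package's root solver; constructs the mass-action species
    weights directly from the step equilibrium constants.
    """
    K_ui, K_iq, K1, K2 = equilibrium_constants(model, cond.T, cond.cK)

    def weights(L):
        return np.array([1.0, K_ui, K_ui * K_iq, K_ui * K_iq * K2 * L,
                         K_ui * K2 * L, K_ui * K1 * L, K_ui * K1 * K2 * L * L])

    stoich = np.array([0, 0, 0, 1, 1, 1, 2], dtype=float)

    def residual(L):
        w = weights(L)
        return abs(L + cond.cDNA * (stoich @ w) / w.sum() - cond.cL)

    lo, hi = 0.0, cond.cL
    best = 0.0
    for _ in range(rounds):
        xs = np.linspace(lo, hi, n)
        vals = [residual(x) for x in xs]
        i = int(np.argmin(vals))
        best = xs[i]
        lo, hi = xs[max(i - 1, 0)], xs[min(i + 1, n - 1)]
    w = weights(best)
    fr = w / w.sum()
    return Speciation(dict(zip(SPECIES, fr)), float(best))


def random_conditions(rng: np.random.Generator, with_ligand: bool = True) -> Conditions:
    T = rng.uniform(278.0, 368.0)
    cK = 10.0 ** rng.uniform(-4.0, -1.0)
    cDNA = 10.0 ** rng.uniform(-6.0, -3.7)
    cL = rng.uniform(0.0, 3.0) * cDNA if with_ligand else 0.0
    return Conditions(T=T, cK=cK, cDNA=cDNA, cL=cL)
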