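"""Seven-species linked-equilibrium model of G-quadruplex folding and ligand binding.

The model describes a G-rich DNA strand that folds through a single
intermediate and binds a small-molecule ligand at two ends::

    U  <->  I  <->  Q              (folding, coupled to K+ uptake)
    I + L <-> LI                   (site 1, "upper" end, intermediate only)
    Q + L <-> QL                   (site 2, "bottom" end)
    I + L <-> IL                   (site 2)
    LI + L <-> LIL                 (site 2)

Species labels: U (unfolded strand, no specifically bound K+), I (two-quartet
antiparallel intermediate, one bound K+), Q (folded hybrid-3 quadruplex, two
bound K+).  The position of the ``L`` index marks the occupied end: in LI the
ligand sits on site 1, in IL/QL on site 2, LIL carries one ligand on each.
Site 2 is assumed thermodynamically equivalent on Q, I and LI, and no LQ
species exists (site 1 opens only after the second K+ leaves).

Step thermodynamics are stored at a reference state (by default 25 °C,
100 mM K+) and propagated with the Gibbs–Helmholtz expression plus an ion
linkage term for the folding steps:

    dG(T)       = dH0 - T*(dH0 - dG0)/T0 + dCp*[(T - T0) - T*ln(T/T0)]
    dG(T, cK)   = dG(T, cref) + n*R*T*ln(cK/cref)      (folding steps only)
    dH(T)       = dH0 + dCp*(T - T0)

All internal units are K, mol/L and kcal/mol; R = 1.9872e-3 kcal/(mol K).
The entropy is never an independent parameter: T0*dS0 = dH0 - dG0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "R_KCAL",
    "ReferenceConditions",
    "TransitionThermo",
    "SiteThermo",
    "SystemModel",
    "Conditions",
    "Speciation",
    "gibbs_energy",
    "enthalpy",
    "equilibrium_constant",
    "equilibrium_constants",
    "species_enthalpies",
    "composite_transition",
    "folding_fractions",
    "solve_speciation",
]

#: gas constant in kcal mol^-1 K^-1
R_KCAL = 1.9872e-3

SPECIES = ("U", "I", "Q", "QL", "IL", "LI", "LIL")

TRANSITION_NAMES = ("U->I", "I->Q")


class DomainError(ValueError):
    """Raised when a physical quantity is outside its admissible domain."""


def _check_positive(name: str, value: float) -> None:
    if not (value > 0.0) or not math.isfinite(value):
        raise DomainError(f"{name} must be positive and finite, got {value!r}")


@dataclass(frozen=True)
class ReferenceConditions:
    """Reference state at which step parameters are defined.

    Defaults correspond to 25 °C and 100 mM K+.
    """

    T0: float = 298.15  # K
    cref: float = 0.1   # mol/L K+

    def __post_init__(self) -> None:
        _check_positive("T0", self.T0)
        _check_positive("cref", self.cref)


@dataclass(frozen=True)
class TransitionThermo:
    """Thermodynamics of one folding step at the reference state.

    Parameters
    ----------
    name : {"U->I", "I->Q"}
    dG0, dH0 : kcal/mol
    dCp : kcal mol^-1 K^-1
    n : signed number of K+ ions exchanged along the step (folding direction).
    """

    name: str
    dG0: float
    dH0: float
    dCp: float
    n: float

    def __post_init__(self) -> None:
        if self.name not in TRANSITION_NAMES:
            raise ValueError(
                f"transition name must be one of {TRANSITION_NAMES}, got {self.name!r}"
            )
        for f in ("dG0", "dH0", "dCp", "n"):
            if not math.isfinite(getattr(self, f)):
                raise ValueError(f"{f} must be finite")

    @property
    def TdS0(self) -> float:
        """T0*dS0, derived from dH0 - dG0 (never stored independently)."""
        return self.dH0 - self.dG0


@dataclass(frozen=True)
class SiteThermo:
    """Per-site ligand binding thermodynamics at the reference state.

    Binding steps carry no ion-linkage term (no K+ is exchanged on binding
    in this model).
    """

    site: int
    dG0: float
    dH0: float
    dCp: float

    def __post_init__(self) -> None:
        if self.site not in (1, 2):
            raise ValueError(f"site must be 1 or 2, got {self.site!r}")
        for f in ("dG0", "dH0", "dCp"):
            if not math.isfinite(getattr(self, f)):
                raise ValueError(f"{f} must be finite")

    @property
    def TdS0(self) -> float:
        return self.dH0 - self.dG0


@dataclass(frozen=True)
class SystemModel:
    """Full parameter set: two folding transitions, two binding sites.

    ``species`` is the fixed ordered label list.  Site 2 thermodynamics is
    shared by Q+L->QL, I+L->IL and LI+L->LIL.
    """

    transitions: tuple[TransitionThermo, TransitionThermo]
    sites: tuple[SiteThermo, SiteThermo]
    ref: ReferenceConditions = field(default_factory=ReferenceConditions)

    species = SPECIES

    def __post_init__(self) -> None:
        if len(self.transitions) != 2:
            raise ValueError("exactly two transitions required")
        names = tuple(t.name for t in self.transitions)
        if names != TRANSITION_NAMES:
            raise ValueError(f"transitions must be ordered {TRANSITION_NAMES}, got {names}")
        if len(self.sites) != 2 or tuple(s.site for s in self.sites) != (1, 2):
            raise ValueError("sites must be (site 1, site 2) in order")

    @property
    def ui(self) -> TransitionThermo:
        return self.transitions[0]

    @property
    def iq(self) -> TransitionThermo:
        return self.transitions[1]

    @property
    def site1(self) -> SiteThermo:
        return self.sites[0]

    @property
    def site2(self) -> SiteThermo:
        return self.sites[1]

    @classmethod
    def default(cls) -> "SystemModel":
        """Reference parameter set for the human telomeric 22GT fragment and
        the bisquinolinium ligand 360A (fitted values at 25 °C, 100 mM K+)."""
        return cls(
            transitions=(
                TransitionThermo("U->I", dG0=-4.7, dH0=-34.0, dCp=-0.22, n=-1.3),
                TransitionThermo("I->Q", dG0=-1.0, dH0=-22.0, dCp=-0.1, n=-0.4),
            ),
            sites=(
                SiteThermo(1, dG0=-9.6, dH0=-18.0, dCp=-0.02),
                SiteThermo(2, dG0=-8.7, dH0=-20.0, dCp=-0.16),
            ),
        )

    def with_updates(self, **flat: float) -> "SystemModel":
        """Return a copy with parameters replaced, keyed as
        ``"UI.dH0"``, ``"IQ.n"``, ``"site1.dG0"``, ``"site2.dCp"`` etc."""
        ui, iq, s1, s2 = self.ui, self.iq, self.site1, self.site2
        groups: dict[str, dict[str, float]] = {"UI": {}, "IQ": {}, "site1": {}, "site2": {}}
        for key, value in flat.items():
            group, _, fieldname = key.partition(".")
            if group not in groups or not fieldname:
                raise KeyError(f"unknown parameter key {key!r}")
            groups[group][fieldname] = float(value)
        if groups["UI"]:
            ui = replace(ui, **groups["UI"])
        if groups["IQ"]:
            iq = replace(iq, **groups["IQ"])
        if groups["site1"]:
            s1 = replace(s1, **groups["site1"])
        if groups["site2"]:
            s2 = replace(s2, **groups["site2"])
        return SystemModel(transitions=(ui, iq), sites=(s1, s2), ref=self.ref)


@dataclass(frozen=True)
class Conditions:
    """One solution condition.

    T in K, concentrations in mol/L.  ``r`` (total ligand / total DNA molar
    ratio) is derived, never stored.
    """

    T: float
    cK: float
    cDNA: float = 0.0
    cL: float = 0.0

    def __post_init__(self) -> None:
        if not (273.0 <= self.T <= 380.0):
            raise DomainError(f"T must lie in [273, 380] K, got {self.T}")
        _check_positive("cK", self.cK)
        if self.cDNA < 0 or self.cL < 0:
            raise DomainError("cDNA and cL must be non-negative")

    @property
    def r(self) -> float:
        return self.cL / self.cDNA if self.cDNA > 0 else math.inf


@dataclass(frozen=True)
class Speciation:
    """Equilibrium molar fractions of total DNA plus the free-ligand level."""

    fractions: dict[str, float]
    free_ligand: float

    def __getitem__(self, species: str) -> float:
        return self.fractions[species]


# ---------------------------------------------------------------------------
# thermodynamic propagation


def gibbs_energy(t, T, cK, ref: ReferenceConditions | None = None):
    """Standard Gibbs energy of a folding or binding step at (T, cK).

    Gibbs–Helmholtz propagation from the reference state; folding steps
    (records carrying ``n``) additionally pick up the K+-linkage term
    ``n*R*T*ln(cK/cref)``.  Accepts array temperatures.
    """
    ref = ref or ReferenceConditions()
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise DomainError("T must be positive")
    if not (cK > 0):
        raise DomainError(f"cK must be positive, got {cK!r}")
    T0 = ref.T0
    dS0 = (t.dH0 - t.dG0) / T0
    dG = t.dH0 - T * dS0 + t.dCp * ((T - T0) - T * np.log(T / T0))
    if hasattr(t, "n"):
        dG = dG + t.n * R_KCAL * T * np.log(cK / ref.cref)
    return dG if dG.ndim else float(dG)


def enthalpy(t, T, ref: ReferenceConditions | None = None):
    """Standard enthalpy of a step at temperature T: dH0 + dCp*(T - T0)."""
    ref = ref or ReferenceConditions()
    T = np.asarray(T, dtype=float)
    dH = t.dH0 + t.dCp * (T - ref.T0)
    return dH if dH.ndim else float(dH)


def equilibrium_constant(dG, T):
    """K = exp(-dG / RT)."""
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise DomainError("T must be positive")
    K = np.exp(-np.asarray(dG, dtype=float) / (R_KCAL * T))
    return K if K.ndim else float(K)


def equilibrium_constants(model: SystemModel, T, cK):
    """(K_UI, K_IQ, K1, K2) at (T, cK); folding constants carry the linkage."""
    K_ui = equilibrium_constant(gibbs_energy(model.ui, T, cK, model.ref), T)
    K_iq = equilibrium_constant(gibbs_energy(model.iq, T, cK, model.ref), T)
    K1 = equilibrium_constant(gibbs_energy(model.site1, T, cK, model.ref), T)
    K2 = equilibrium_constant(gibbs_energy(model.site2, T, cK, model.ref), T)
    return K_ui, K_iq, K1, K2


def species_enthalpies(model: SystemModel, T) -> dict[str, float | np.ndarray]:
    """Enthalpy of every species at T, relative to U (path sums of step dH).

    Path independence holds by construction: LIL via IL or via LI gives the
    same value.
    """
    h_ui = enthalpy(model.ui, T, model.ref)
    h_iq = enthalpy(model.iq, T, model.ref)
    h1 = enthalpy(model.site1, T, model.ref)
    h2 = enthalpy(model.site2, T, model.ref)
    zero = 0.0 * h_ui
    return {
        "U": zero,
        "I": h_ui,
        "Q": h_ui + h_iq,
        "QL": h_ui + h_iq + h2,
        "IL": h_ui + h2,
        "LI": h_ui + h1,
        "LIL": h_ui + h1 + h2,
    }


def composite_transition(model: SystemModel) -> TransitionThermo:
    """The composite U->Q step by Hess additivity over U->I and I->Q."""
    ui, iq = model.ui, model.iq
    # name validation restricted to the two elementary labels; the composite
    # is returned as a plain record with the same propagation behaviour
    object_ = TransitionThermo.__new__(TransitionThermo)
    object.__setattr__(object_, "name", "U->Q")
    object.__setattr__(object_, "dG0", ui.dG0 + iq.dG0)
    object.__setattr__(object_, "dH0", ui.dH0 + iq.dH0)
    object.__setattr__(object_, "dCp", ui.dCp + iq.dCp)
    object.__setattr__(object_, "n", ui.n + iq.n)
    return object_


# ---------------------------------------------------------------------------
# speciation


def folding_fractions(model: SystemModel, T, cK):
    """Ligand-free (three-state) fractions alpha_U, alpha_I, alpha_Q.

    Vectorised over T; Boltzmann weights 1 : K_UI : K_UI*K_IQ.
    """
    g_ui = gibbs_energy(model.ui, T, cK, model.ref)
    g_iq = gibbs_energy(model.iq, T, cK, model.ref)
    T = np.asarray(T, dtype=float)
    # work in log space to avoid overflow of large folding constants
    lw = np.stack(
        [np.zeros_like(T * 1.0), -g_ui / (R_KCAL * T), -(g_ui + g_iq) / (R_KCAL * T)]
    )
    lw -= lw.max(axis=0, keepdims=True)
    w = np.exp(lw)
    w /= w.sum(axis=0, keepdims=True)
    return w[0], w[1], w[2]


def _weights_from_constants(K: tuple, L: float) -> np.ndarray:
    """Relative concentrations of all seven species at free-ligand level L,
    normalised to [U] = 1, given (K_UI, K_IQ, K1, K2)."""
    K_ui, K_iq, K1, K2 = K
    return np.array(
        [
            1.0,
            K_ui,
            K_ui * K_iq,
            K_ui * K_iq * K2 * L,
            K_ui * K2 * L,
            K_ui * K1 * L,
            K_ui * K1 * K2 * L * L,
        ]
    )


def _species_weights(model: SystemModel, T: float, cK: float, L: float):
    return _weights_from_constants(equilibrium_constants(model, T, cK), L)


#: ligand stoichiometry of each species, ordered as SPECIES
_LIGAND_STOICH = np.array([0.0, 0.0, 0.0, 1.0, 1.0, 1.0, 2.0])


class SpeciationError(RuntimeError):
    pass


def solve_speciation(model: SystemModel, cond: Conditions) -> Speciation:
    """Solve the mass-action speciation problem at one condition.

    The free-ligand concentration is the unique root of the ligand
    conservation relation on [0, cL] (the bound-ligand function is monotone
    increasing in the free level), located by bracketed Brent iteration to
    relative tolerance ~1e-12 and polished.  With cL = 0 the ligand complexes
    are exactly zero and the three-state closed form is used.
    """
    T, cK, cDNA, cL = cond.T, cond.cK, cond.cDNA, cond.cL
    K = equilibrium_constants(model, T, cK)

    if cL == 0.0:
        w = _weights_from_constants(K, 0.0)
        fr = w / w.sum()
        return Speciation(dict(zip(SPECIES, fr)), 0.0)

    def bound_ligand(L: float) -> float:
        w = _weights_from_constants(K, L)
        return cDNA * float(_LIGAND_STOICH @ w) / float(w.sum())

    if cDNA == 0.0:
        w = _weights_from_constants(K, cL)
        fr = w / w.sum()
        return Speciation(dict(zip(SPECIES, fr)), cL)

    # scaled residual: x = L / cL in [0, 1]
    def g(x: float) -> float:
        L = x * cL
        return (L + bound_ligand(L) - cL) / cL

    g0, g1 = g(0.0), g(1.0)
    if g0 > 0 or g1 < 0:  # pragma: no cover - conservation guarantees bracket
        raise SpeciationError(
            f"failed to bracket free ligand at T={T}, cK={cK}: g(0)={g0}, g(cL)={g1}"
        )
    try:
        x = brentq(g, 0.0, 1.0, xtol=1e-16, rtol=8.9e-16, maxiter=200)
    except Exception as exc:  # pragma: no cover
        raise SpeciationError(f"free-ligand solve failed at T={T}, cK={cK}: {exc}") from exc
    L = x * cL
    w = _weights_from_constants(K, L)
    fr = w / w.sum()
    resid = abs(L + cDNA * float(_LIGAND_STOICH @ w) / float(w.sum()) - cL)
    if resid > 1e-8 * max(cL, 1e-30):  # pragma: no cover
        raise SpeciationError(
            f"free-ligand solve did not converge at T={T}, cK={cK}: residual {resid:g}"
        )
    return Speciation(dict(zip(SPECIES, fr)), L)
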