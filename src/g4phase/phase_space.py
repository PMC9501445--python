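"""Binding energy decomposition and stability pseudophase diagrams.

The apparent binding free energy of each ligand site is split into a
hydration term (estimated from the binding heat capacity change at 25 °C as
dG_hyd = 80 K * dCp), a specific-interaction term approximated by the
binding enthalpy (dG_int ~ dH), and a remainder dG_other = dG - dG_hyd -
dG_int collecting rotational/translational and conformational entropy costs.
The closure dG = dG_hyd + dG_int + dG_other is exact by construction.

A pseudophase diagram labels each point of a 2-D condition grid (temperature
against log10 K+ concentration, or against the ligand/DNA molar ratio r)
with the most populated species; phase boundaries are equal-population loci
and triple points are three-way ties, refined by bisection from the labelled
grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import root

from .core_model import Conditions, SPECIES, SiteThermo, SystemModel, solve_speciation

__all__ = [
    "HYDRATION_FACTOR_K",
    "EnergyDecomposition",
    "PhaseDiagram",
    "decompose_binding",
    "dominant_species_map",
    "trace_boundaries",
]

logger = logging.getLogger(__name__)

#: temperature factor (K) converting the binding heat capacity change into
#: the hydration free energy at 25 °C; the literature value is 80 (+/- 10) K
HYDRATION_FACTOR_K = 80.0


@dataclass(frozen=True)
class EnergyDecomposition:
    site: int
    Gtotal: float
    Ghyd: float
    Gint: float
    Gother: float


def decompose_binding(site: SiteThermo,
                      hyd_factor: float = HYDRATION_FACTOR_K) -> EnergyDecomposition:
    """Decompose the binding free energy of one site at the 25 °C reference.

    Ghyd = hyd_factor * dCp, Gint = dH0, Gother closes the balance exactly.
    """
    ghyd = hyd_factor * site.dCp
    gint = site.dH0
    gother = site.dG0 - ghyd - gint
    return EnergyDecomposition(site=site.site, Gtotal=site.dG0,
                               Ghyd=ghyd, Gint=gint, Gother=gother)


# ---------------------------------------------------------------------------
# pseudophase diagrams


@dataclass
class PhaseDiagram:
    """Dominant-species labels over a 2-D condition grid.

    ``x_name`` is "log10_cK" (with fixed ``r``) or "r" (with fixed ``cK``);
    the y axis is always temperature in °C.  ``labels`` holds indices into
    ``species`` with shape (n_T, n_x); -1 marks a failed cell.
    """

    x_name: str
    x_grid: np.ndarray
    t_grid_c: np.ndarray
    labels: np.ndarray
    cDNA: float
    fixed: float  # the held-constant variable: r for log10_cK axis, cK for r axis
    species: tuple = SPECIES
    boundaries: dict = field(default_factory=dict)
    triple_points: list = field(default_factory=list)

    def label_names(self) -> np.ndarray:
        out = np.empty(self.labels.shape, dtype=object)
        for idx, s in enumerate(self.species):
            out[self.labels == idx] = s
        out[self.labels < 0] = "?"
        return out


def _conditions(diagram_kind: str, x: float, t_c: float, cDNA: float,
                fixed: float) -> Conditions:
    T = t_c + 273.15
    if diagram_kind == "log10_cK":
        cK = 10.0 ** x
        cL = fixed * cDNA
    else:  # r axis
        cK = fixed
        cL = x * cDNA
    return Conditions(T=T, cK=cK, cDNA=cDNA, cL=cL)


def _fractions_at(model: SystemModel, kind: str, x: float, t_c: float,
                  cDNA: float, fixed: float) -> np.ndarray:
    sp = solve_speciation(model, _conditions(kind, x, t_c, cDNA, fixed))
    return np.array([sp.fractions[s] for s in SPECIES])


def dominant_species_map(model: SystemModel, x_name: str = "log10_cK",
                         x_range: tuple[float, float] = (-4.0, -1.0),
                         t_range_c: tuple[float, float] = (0.0, 95.0),
                         shape: tuple[int, int] = (200, 200),
                         cDNA: float = 1e-5, fixed: float = 0.0) -> PhaseDiagram:
    """Label each cell of a (T, x) grid with the most populated species.

    For ``x_name="log10_cK"`` the ligand/DNA ratio r is held at ``fixed``
    (default 0: the ligand-free folding diagram); for ``x_name="r"`` the K+
    concentration is held at ``fixed`` (mol/L).  Ties within 1e-12 are
    resolved by species-list order and logged.  Cells where the speciation
    solve fails are flagged with label -1, never silently filled.
    """
    if x_name not in ("log10_cK", "r"):
        raise ValueError("x_name must be 'log10_cK' or 'r'")
    if shape[0] < 50 or shape[1] < 50:
        raise ValueError("grid resolution must be at least 50 x 50")
    t_grid = np.linspace(*t_range_c, shape[0])
    x_grid = np.linspace(*x_range, shape[1])
    labels = np.empty((shape[0], shape[1]), dtype=int)
    for i, t_c in enumerate(t_grid):
        for j, x in enumerate(x_grid):
            try:
                fr = _fractions_at(model, x_name, x, t_c, cDNA, fixed)
            except Exception as exc:
                logger.warning("speciation failed at T=%.2f °C, x=%.3g: %s", t_c, x, exc)
                labels[i, j] = -1
                continue
            top = int(np.argmax(fr))
            ties = np.nonzero(fr >= fr[top] - 1e-12)[0]
            if ties.size > 1:
                logger.info("tie at T=%.2f °C, x=%.3g between %s",
                            t_c, x, [SPECIES[k] for k in ties])
                top = int(ties[0])
            labels[i, j] = top
    return PhaseDiagram(x_name=x_name, x_grid=x_grid, t_grid_c=t_grid,
                        labels=labels, cDNA=cDNA, fixed=fixed)


def _bisect_boundary(model, diagram, p0, p1, lab0, lab1, tol=1e-6, maxiter=80):
    """Bisect along the segment p0 -> p1 (x, t_c) for the equal-population
    point of the two labelled species.  Returns the point or None."""
    def gap(p):
        fr = _fractions_at(model, diagram.x_name, p[0], p[1],
                           diagram.cDNA, diagram.fixed)
        return fr[lab0] - fr[lab1]
    a, b = np.asarray(p0, float), np.asarray(p1, float)
    ga, gb = gap(a), gap(b)
    if ga == 0.0:
        return a
    if ga * gb > 0:
        return None
    for _ in range(maxiter):
        mid = 0.5 * (a + b)
        gm = gap(mid)
        if abs(gm) < tol:
            return mid
        if ga * gm <= 0:
            b, gb = mid, gm
        else:
            a, ga = mid, gm
    logger.warning("boundary bisection did not converge between %s and %s", p0, p1)
    return None


def trace_boundaries(diagram: PhaseDiagram, model: SystemModel,
                     tol: float = 1e-6, tie_tol: float = 1e-5,
                     max_points_per_pair: int | None = None) -> PhaseDiagram:
    """Refine phase boundaries and locate triple points on a labelled grid.

    For every adjacent-cell label change, the equal-population point is found
    by bisection along the connecting grid segment to |f1 - f2| < ``tol``.
    Triple points are seeded where three labels meet in a 2x2 cell block and
    refined by a two-dimensional root solve on the pairwise fraction gaps;
    accepted only if the three top fractions tie pairwise within ``tie_tol``.
    Results are stored on the diagram (``boundaries``: dict mapping species
    pairs to point arrays; ``triple_points``: list of dicts) and returned.
    """
    labels, tg, xg = diagram.labels, diagram.t_grid_c, diagram.x_grid
    pairs: dict[tuple[str, str], list] = {}

    def add_point(i0, j0, i1, j1):
        l0, l1 = labels[i0, j0], labels[i1, j1]
        if l0 < 0 or l1 < 0 or l0 == l1:
            return
        key = tuple(sorted((SPECIES[l0], SPECIES[l1])))
        if max_points_per_pair and len(pairs.get(key, [])) >= max_points_per_pair:
            return
        pt = _bisect_boundary(model, diagram, (xg[j0], tg[i0]), (xg[j1], tg[i1]),
                              l0, l1, tol=tol)
        if pt is not None:
            pairs.setdefault(key, []).append(pt)

    for i in range(labels.shape[0]):
        for j in range(labels.shape[1]):
            if i + 1 < labels.shape[0]:
                add_point(i, j, i + 1, j)
            if j + 1 < labels.shape[1]:
                add_point(i, j, i, j + 1)

    diagram.boundaries = {
        k: np.array(sorted(v, key=lambda p: (p[1], p[0]))) for k, v in pairs.items()
    }

    # triple points: 2x2 blocks containing three distinct labels
    triples = []
    seen = []
    for i in range(labels.shape[0] - 1):
        for j in range(labels.shape[1] - 1):
            block = labels[i:i + 2, j:j + 2].ravel()
            uniq = sorted(set(int(b) for b in block if b >= 0))
            if len(uniq) < 3:
                continue
            a, b, c = uniq[:3]
            x0 = np.array([0.5 * (xg[j] + xg[j + 1]), 0.5 * (tg[i] + tg[i + 1])])

            def gaps(p, a=a, b=b, c=c):
                fr = _fractions_at(model, diagram.x_name, p[0], p[1],
                                   diagram.cDNA, diagram.fixed)
                return [fr[a] - fr[b], fr[a] - fr[c]]

            sol = root(gaps, x0, method="hybr", tol=1e-12)
            if not sol.success:
                continue
            fr = _fractions_at(model, diagram.x_name, sol.x[0], sol.x[1],
                               diagram.cDNA, diagram.fixed)
            vals = sorted([fr[a], fr[b], fr[c]], reverse=True)
            if vals[0] - vals[2] > tie_tol:
                continue
            if any(np.hypot(sol.x[0] - p[0], sol.x[1] - p[1]) < 1e-3 for p in seen):
                continue
            seen.append(sol.x)
            triples.append({
                "x": float(sol.x[0]), "t_c": float(sol.x[1]),
                "species": tuple(SPECIES[k] for k in (a, b, c)),
                "fractions": tuple(float(fr[k]) for k in (a, b, c)),
            })
    diagram.triple_points = triples
    return diagram
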