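"""Fixed-pH chemical equilibrium speciation for the Fe(II)-citrate assay.

The iron oxidation assay supplies Fe(II) as ferrous citrate in MES buffer at
pH 6.3.  Citrate is a weak Fe(II) ligand, so an appreciable share of the
iron remains as the free aquo ion Fe2+ — the actual substrate of the
oxidase.  This module solves the mass-action/mass-balance system at fixed
pH (Newton iteration on the log free component concentrations) and reports
the free-Fe2+ fraction.

Conventions: activity coefficients are unity (concentrations as
activities), H+ is fixed by the buffer and does not enter any mass balance,
and every complex is written as a cumulative formation reaction from the
free components plus H+, e.g.

    Fe2+ + Cit3-        = FeCit-   (log K = 4.38)
    Cit3- + H+          = HCit2-   (log K = 6.40)
    Cit3- + 2 H+        = H2Cit-   (log K = 11.16)
    Cit3- + 3 H+        = H3Cit    (log K = 14.29)

The default constants are the NIST SRD 46 critically-selected values at
25 degC and infinite dilution (the same selection MINTEQ-style speciation
programs ship).  Note that the widely quoted Fe(II)-citrate constant of
log K = 3.20 refers to 0.1 M ionic strength; at the I = 0 reference state
the constant is 4.38, and it is the latter that reproduces the assay's
~20% free Fe2+.  The table is configuration, not code, and can be
overridden entirely from JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "Reaction",
    "SpeciationSystem",
    "SpeciationResult",
    "solve_equilibrium",
    "fe2_fraction",
    "default_assay_system",
    "ConvergenceError",
]


class ConvergenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class Reaction:
    """A complex formed from free components (and H+): product of free
    concentrations raised to their stoichiometries, times 10**log_k."""

    name: str
    stoich: Mapping[str, float]  # component -> stoichiometric coefficient
    log_k: float
    h_stoich: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.log_k):
            raise ValueError(f"reaction {self.name}: log K must be finite")


def _default_reactions() -> tuple[Reaction, ...]:
    return (
        Reaction("FeCit-", {"Fe2": 1, "Cit": 1}, 4.38),
        Reaction("HCit2-", {"Cit": 1}, 6.40, h_stoich=1),
        Reaction("H2Cit-", {"Cit": 1}, 11.16, h_stoich=2),
        Reaction("H3Cit", {"Cit": 1}, 14.29, h_stoich=3),
    )


@dataclass(frozen=True)
class SpeciationSystem:
    """Totals, pH and the reaction (stability-constant) table."""

    pH: float = 6.3
    totals: Mapping[str, float] = field(
        default_factory=lambda: {"Fe2": 2e-3, "Cit": 2e-3}
    )
    reactions: tuple[Reaction, ...] = field(default_factory=_default_reactions)

    def __post_init__(self) -> None:
        for comp, tot in self.totals.items():
            if tot <= 0:
                raise ValueError(f"total for {comp} must be positive")
        comps = set(self.totals)
        for rxn in self.reactions:
            unknown = set(rxn.stoich) - comps
            if unknown:
                raise ValueError(f"reaction {rxn.name} uses unknown component(s) {unknown}")

    @classmethod
    def from_json(cls, path: str | Path) -> "SpeciationSystem":
        d = json.loads(Path(path).read_text())
        reactions = tuple(
            Reaction(
                name=r["name"],
                stoich=r["stoich"],
                log_k=r["log_k"],
                h_stoich=r.get("h_stoich", 0.0),
            )
            for r in d["reactions"]
        )
        return cls(pH=d["pH"], totals=d["totals_molar"], reactions=reactions)


@dataclass
class SpeciationResult:
    """Equilibrium concentrations (mol/L) of free components and complexes."""

    species: dict[str, float]
    totals: dict[str, float]
    fraction_free_fe2: float
    iterations: int


def default_assay_system() -> SpeciationSystem:
    """The iron oxidase assay: 2 mM Fe(II), 2 mM citrate, pH 6.3."""
    return SpeciationSystem()


def solve_equilibrium(
    system: SpeciationSystem,
    tol: float = 1e-12,
    max_iter: int = 200,
    fe_component: str = "Fe2",
) -> SpeciationResult:
    """Newton iteration on log free-component concentrations at fixed pH.

    Converges when every component's mass-balance residual is below ``tol``
    relative to its total; starts deterministically from the totals.
    """
    comps = list(system.totals)
    totals = np.array([system.totals[c] for c in comps], dtype=float)
    nu = np.array(
        [[rxn.stoich.get(c, 0.0) for c in comps] for rxn in system.reactions]
    )  # (nreact, ncomp)
    log10_k_eff = np.array(
        [rxn.log_k - rxn.h_stoich * system.pH for rxn in system.reactions]
    )  # H+ activity folded into the constant at fixed pH
    ln_k = log10_k_eff * np.log(10.0)

    x = np.log(totals)  # ln free concentrations
    for it in range(1, max_iter + 1):
        conc = np.exp(ln_k + nu @ x) if len(system.reactions) else np.zeros(0)
        free = np.exp(x)
        residual = free + (nu.T @ conc if conc.size else 0.0) - totals
        if np.all(np.abs(residual) <= tol * totals):
            species = {c: float(f) for c, f in zip(comps, free)}
            for rxn, cc in zip(system.reactions, conc):
                species[rxn.name] = float(cc)
            frac = float(free[comps.index(fe_component)] / totals[comps.index(fe_component)]) if fe_component in comps else float("nan")
            return SpeciationResult(
                species=species,
                totals={c: float(t) for c, t in zip(comps, totals)},
                fraction_free_fe2=frac,
                iterations=it,
            )
        jac = np.diag(free) + (nu.T @ (conc[:, None] * nu) if conc.size else 0.0)
        step = np.linalg.solve(jac, -residual)
        # damp: cap the log-space step to keep Newton in its basin
        step = np.clip(step, -2.0, 2.0)
        x = x + step
    raise ConvergenceError(
        f"no convergence in {max_iter} iterations; residuals {residual.tolist()}"
    )


def fe2_fraction(result: SpeciationResult, fe_component: str = "Fe2") -> float:
    """Free Fe2+ over total Fe(II), in [0, 1]."""
    if fe_component not in result.totals:
        raise ValueError(f"result has no component {fe_component!r}")
    return result.species[fe_component] / result.totals[fe_component]
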