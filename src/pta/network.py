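"""Constraint-based model container and thermodynamic priors.

The network is the usual stoichiometric description of metabolism: a matrix
``S`` (m metabolites x n reactions), flux bounds ``lb``/``ub`` in
mmol/gDW/h, and per-reaction role flags.  On top of it, a subset Gamma of
the internal, mass-balanced reactions carries thermodynamic constraints:
each reaction in Gamma must run with non-zero flux in the direction of
negative Gibbs reaction energy.

Priors describe log metabolite concentrations (natural log of molar
concentrations) and standard Gibbs reaction energies (kJ/mol) as Gaussians;
the covariance of the standard energies may be rank-deficient, as produced
by group-contribution estimators whose errors are shared across reactions.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace

import numpy as np

from ._lp import steady_state_lp

__all__ = [
    "MetabolicNetwork",
    "ThermoPriors",
    "ValidationError",
    "select_thermo_reactions",
    "detect_blocked_reactions",
    "DEFAULT_R_GAS",
    "DEFAULT_TEMPERATURE",
]

logger = logging.getLogger(__name__)

#: Gas constant in kJ/(mol K).
DEFAULT_R_GAS = 8.314e-3
#: Temperature in K.
DEFAULT_TEMPERATURE = 298.15

ROLES = ("internal", "exchange", "biomass", "maintenance")

_BIOMASS_RE = re.compile(r"biomass", re.IGNORECASE)
_MAINTENANCE_RE = re.compile(r"^ATPM|maintenance", re.IGNORECASE)


class ValidationError(ValueError):
    """Raised when a model or prior fails its structural contract."""


@dataclass
class MetabolicNetwork:
    """Stoichiometric model with reaction roles and a thermodynamic subset.

    Parameters
    ----------
    S:
        Stoichiometric matrix, metabolites by reactions.
    lb, ub:
        Flux bounds per reaction (mmol/gDW/h).
    reaction_ids, metabolite_ids:
        Identifiers; order defines the index spaces.
    compartments:
        Compartment label per metabolite (e.g. ``"c"``, ``"p"``, ``"e"``).
    roles:
        One of ``internal | exchange | biomass | maintenance`` per reaction.
    gamma:
        Ordered indices of the thermodynamically constrained reactions.
    """

    S: np.ndarray
    lb: np.ndarray
    ub: np.ndarray
    reaction_ids: list[str]
    metabolite_ids: list[str]
    compartments: list[str] = field(default_factory=list)
    roles: list[str] = field(default_factory=list)
    gamma: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.S = np.atleast_2d(np.asarray(self.S, dtype=float))
        self.lb = np.asarray(self.lb, dtype=float)
        self.ub = np.asarray(self.ub, dtype=float)
        if not self.compartments:
            self.compartments = ["c"] * self.n_metabolites
        if not self.roles:
            self.roles = [self._infer_role(j) for j in range(self.n_reactions)]
        self.validate()

    # -- basic dimensions -------------------------------------------------
    @property
    def n_metabolites(self) -> int:
        return self.S.shape[0]

    @property
    def n_reactions(self) -> int:
        return self.S.shape[1]

    @property
    def n_gamma(self) -> int:
        return len(self.gamma)

    @property
    def S_gamma(self) -> np.ndarray:
        """Columns of S for the thermodynamically constrained reactions."""
        return self.S[:, self.gamma]

    def reaction_index(self, rid: str) -> int:
        return self.reaction_ids.index(rid)

    def internal_reactions(self) -> list[int]:
        return [j for j, r in enumerate(self.roles) if r == "internal"]

    def is_reversible(self, j: int) -> bool:
        return self.lb[j] < 0 < self.ub[j]

    def _infer_role(self, j: int) -> str:
        rid = self.reaction_ids[j]
        if _BIOMASS_RE.search(rid):
            return "biomass"
        if _MAINTENANCE_RE.search(rid):
            return "maintenance"
        # boundary reaction: involves a single metabolite
        if np.count_nonzero(self.S[:, j]) <= 1:
            return "exchange"
        return "internal"

    # -- contracts ---------------------------------------------------------
    def validate(self) -> None:
        m, n = self.S.shape
        if not (len(self.lb) == len(self.ub) == len(self.reaction_ids) == n):
            raise ValidationError("reaction dimensions inconsistent")
        if len(self.metabolite_ids) != m or len(self.compartments) != m:
            raise ValidationError("metabolite dimensions inconsistent")
        if len(self.roles) != n or any(r not in ROLES for r in self.roles):
            raise ValidationError("invalid reaction roles")
        bad = np.where(self.lb > self.ub)[0]
        if bad.size:
            raise ValidationError(
                f"lb > ub for reactions {[self.reaction_ids[j] for j in bad]}"
            )
        internal = set(self.internal_reactions())
        for j in self.gamma:
            if j not in internal:
                raise ValidationError(
                    f"Gamma reaction {self.reaction_ids[j]} is not internal"
                )

    def copy(self) -> "MetabolicNetwork":
        return replace(
            self,
            S=self.S.copy(),
            lb=self.lb.copy(),
            ub=self.ub.copy(),
            reaction_ids=list(self.reaction_ids),
            metabolite_ids=list(self.metabolite_ids),
            compartments=list(self.compartments),
            roles=list(self.roles),
            gamma=list(self.gamma),
        )


@dataclass
class ThermoPriors:
    """Gaussian priors for ln-concentrations and standard reaction energies.

    ``mu_c``/``Sigma_c`` describe ``ln c`` with ``c`` in molar units;
    ``mu_0``/``Sigma_0`` describe the standard transformed Gibbs reaction
    energies of the Gamma reactions in kJ/mol (already corrected for pH,
    ionic strength and transport).  ``Sigma_0`` may be rank-deficient.
    """

    mu_c: np.ndarray
    Sigma_c: np.ndarray
    mu_0: np.ndarray
    Sigma_0: np.ndarray
    T: float = DEFAULT_TEMPERATURE
    R_gas: float = DEFAULT_R_GAS

    def __post_init__(self) -> None:
        self.mu_c = np.asarray(self.mu_c, dtype=float)
        self.mu_0 = np.asarray(self.mu_0, dtype=float)
        self.Sigma_c = np.atleast_2d(np.asarray(self.Sigma_c, dtype=float))
        self.Sigma_0 = np.atleast_2d(np.asarray(self.Sigma_0, dtype=float))
        for name, mu, Sigma in (
            ("concentration", self.mu_c, self.Sigma_c),
            ("standard energy", self.mu_0, self.Sigma_0),
        ):
            k = mu.shape[0]
            if Sigma.shape != (k, k):
                raise ValidationError(f"{name} covariance shape mismatch")
            if not np.allclose(Sigma, Sigma.T, atol=1e-10):
                raise ValidationError(f"{name} covariance not symmetric")
            if k and np.linalg.eigvalsh(Sigma).min() < -1e-8 * max(
                1.0, float(np.abs(Sigma).max())
            ):
                raise ValidationError(f"{name} covariance not PSD")
        if self.T <= 0:
            raise ValidationError("temperature must be positive")

    @property
    def RT(self) -> float:
        """R*T in kJ/mol."""
        return self.R_gas * self.T


def select_thermo_reactions(
    network: MetabolicNetwork,
    exclude_roles: set[str] = frozenset({"exchange", "biomass", "maintenance"}),
    exclude_ids: set[str] = frozenset(),
    drop_blocked: bool = True,
) -> list[int]:
    """Build the thermodynamically constrained set Gamma.

    All internal, mass-balanced reactions are included except explicit
    exclusions (typically water transport and export reactions other than
    CO2, which carry no useful thermodynamic information).  Structurally
    blocked reactions are removed because they cannot satisfy the non-zero
    flux requirement; a warning is logged for each.
    """
    exclude_roles = set(exclude_roles)
    exclude_ids = set(exclude_ids)
    gamma = [
        j
        for j in range(network.n_reactions)
        if network.roles[j] not in exclude_roles
        and network.reaction_ids[j] not in exclude_ids
    ]
    if drop_blocked:
        blocked = detect_blocked_reactions(network)
        for j in sorted(set(gamma) & blocked):
            logger.warning(
                "dropping structurally blocked reaction %s from Gamma",
                network.reaction_ids[j],
            )
        gamma = [j for j in gamma if j not in blocked]
    if not gamma:
        raise ValidationError("thermodynamically constrained set is empty")
    return gamma


def detect_blocked_reactions(
    network: MetabolicNetwork, tol: float = 1e-9
) -> set[int]:
    """Reactions that carry zero flux in every steady-state solution.

    Detected by maximizing and minimizing each flux over the steady-state
    polytope; a reaction is blocked when both optima are below ``tol`` in
    magnitude.
    """
    blocked: set[int] = set()
    n = network.n_reactions
    for j in range(n):
        c = np.zeros(n)
        c[j] = 1.0
        vmax = steady_state_lp(network.S, network.lb, network.ub, c=-c)
        vmin = steady_state_lp(network.S, network.lb, network.ub, c=c)
        if not (vmax.optimal and vmin.optimal):
            raise RuntimeError(
                f"flux variability LP failed for {network.reaction_ids[j]}"
            )
        if abs(vmax.x[j]) < tol and abs(vmin.x[j]) < tol:
            blocked.add(j)
    return blocked
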