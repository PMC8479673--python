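"""Structural thermodynamic assessment.

A model is structurally inconsistent when its irreversibility annotations
force an internal cycle: a loop of reactions that is active, with fixed
directions, in *every* non-zero flux distribution.  Such a cycle would
dissipate no free energy and can never satisfy the second law, whatever
the concentrations — the fix is a curation action (relaxing a wrong
irreversibility, adding a missing exchange), not a numerical one.

Detection proceeds in two stages: enumerate the elementary flux modes
(EFMs) of the internal subnetwork (exchange, biomass and ATP-maintenance
reactions blocked), then test each cycle with linear programs — can the
network carry flux with the cycle switched off, and does any sign flip of
the cycle admit a flux distribution?  A cycle that can neither be switched
off nor rerouted is reported as forced, together with the irreversible
member reactions whose relaxation would clear it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._lp import steady_state_lp
from .network import MetabolicNetwork

__all__ = [
    "InternalEFM",
    "ForcedCycle",
    "enumerate_internal_efms",
    "find_forced_cycles",
    "assess_structure",
]

logger = logging.getLogger(__name__)

#: Flux magnitude treated as "active" when testing forced cycles.
ACTIVITY_TOL = 1e-6
#: Hard cap on intermediate rays during enumeration.
DEFAULT_RAY_CAP = 1_000_000


@dataclass
class InternalEFM:
    """Support-minimal steady-state mode of the internal subnetwork."""

    support: tuple[int, ...]  # network reaction indices
    signs: tuple[int, ...]  # direction per support reaction
    coefficients: np.ndarray  # flux ratios, normalized to max |.| = 1

    def as_flux(self, n_reactions: int) -> np.ndarray:
        v = np.zeros(n_reactions)
        for j, s, c in zip(self.support, self.signs, self.coefficients):
            v[j] = s * c
        return v


@dataclass
class ForcedCycle:
    efm: InternalEFM
    #: sign variants shown infeasible (single flips and full reversal)
    witnesses: list[tuple[int, ...]] = field(default_factory=list)
    #: irreversible member reactions — candidate curation targets
    suggested_relaxations: tuple[int, ...] = ()


class EnumerationOverflow(RuntimeError):
    """Raised when intermediate ray counts exceed the configured cap."""


def _extreme_rays(S: np.ndarray, cap: int) -> np.ndarray:
    """Extreme rays of ``{x >= 0 : S x = 0}`` by the double-description
    tableau: process one equality row at a time, combining positive and
    negative rays and keeping support-minimal candidates."""
    n = S.shape[1]
    rays = np.eye(n)
    for row in S:
        vals = rays @ row
        zero = rays[np.abs(vals) < 1e-10]
        pos = rays[vals >= 1e-10]
        neg = rays[vals <= -1e-10]
        vp = vals[vals >= 1e-10]
        vn = vals[vals <= -1e-10]
        combos = []
        for i in range(len(pos)):
            for j in range(len(neg)):
                r = vp[i] * neg[j] - vn[j] * pos[i]
                r[np.abs(r) < 1e-12] = 0.0
                mx = r.max()
                if mx > 0:
                    combos.append(r / mx)
        cand = list(zero) + combos
        if len(cand) > cap:
            raise EnumerationOverflow(
                f"ray count {len(cand)} exceeds cap {cap}; "
                "reduce the model before enumerating"
            )
        # support-minimality filter
        supports = [frozenset(np.nonzero(r > 1e-10)[0]) for r in cand]
        keep = []
        for i, si in enumerate(supports):
            minimal = True
            for j, sj in enumerate(supports):
                if i != j and sj < si:
                    minimal = False
                    break
                if i > j and sj == si:
                    minimal = False  # duplicate support: keep first
                    break
            if minimal:
                keep.append(i)
        rays = np.array([cand[i] for i in keep]) if keep else np.zeros((0, n))
        if len(rays) == 0:
            break
    return rays


def enumerate_internal_efms(
    network: MetabolicNetwork, cap: int = DEFAULT_RAY_CAP
) -> list[InternalEFM]:
    """All EFMs of the internal subnetwork, respecting irreversibilities.

    Reversible internal reactions are split into forward/backward halves,
    extreme rays of the resulting pointed cone are enumerated exactly, and
    the spurious forward+backward two-cycles are discarded.  Intended for
    reduced or toy models; the ray cap fails loudly on blow-up.
    """
    internal = network.internal_reactions()
    if not internal:
        raise ValueError("internal subnetwork is empty")
    cols = []
    col_rxn: list[tuple[int, int]] = []  # (network reaction, direction)
    for j in internal:
        if network.ub[j] > 0:
            cols.append(network.S[:, j])
            col_rxn.append((j, 1))
        if network.lb[j] < 0:
            cols.append(-network.S[:, j])
            col_rxn.append((j, -1))
    S_split = np.column_stack(cols)
    rays = _extreme_rays(S_split, cap)

    efms: dict[tuple, InternalEFM] = {}
    for r in rays:
        v = np.zeros(network.n_reactions)
        for x, (j, d) in zip(r, col_rxn):
            v[j] += d * x
        nz = np.nonzero(np.abs(v) > 1e-10)[0]
        if len(nz) == 0:
            continue  # forward/backward two-cycle
        coeffs = v[nz] / np.abs(v[nz]).max()
        efm = InternalEFM(
            support=tuple(int(j) for j in nz),
            signs=tuple(int(np.sign(c)) for c in coeffs),
            coefficients=np.abs(coeffs),
        )
        # canonical key up to overall sign (reversible EFMs count once)
        key_fwd = (efm.support, efm.signs)
        key_rev = (efm.support, tuple(-s for s in efm.signs))
        if key_fwd not in efms and key_rev not in efms:
            efms[key_fwd] = efm
    return sorted(efms.values(), key=lambda e: (len(e.support), e.support, e.signs))


def _variant_feasible(
    network: MetabolicNetwork,
    support: tuple[int, ...],
    signs: tuple[int, ...],
    v_min: float,
) -> bool:
    extra_lb, extra_ub = {}, {}
    for j, s in zip(support, signs):
        if s > 0:
            extra_lb[j] = v_min
        else:
            extra_ub[j] = -v_min
    res = steady_state_lp(
        network.S, network.lb, network.ub, extra_lb=extra_lb, extra_ub=extra_ub
    )
    return res.optimal


def _can_switch_off(
    network: MetabolicNetwork, support: tuple[int, ...], activity: float
) -> bool:
    """Does any non-zero flux distribution exist with the support at zero?"""
    lb = network.lb.copy()
    ub = network.ub.copy()
    for j in support:
        lb[j] = ub[j] = 0.0
    for j in range(network.n_reactions):
        if j in support:
            continue
        c = np.zeros(network.n_reactions)
        c[j] = 1.0
        for sense in (-1.0, 1.0):
            res = steady_state_lp(network.S, lb, ub, c=sense * c)
            if res.optimal and abs(res.x[j]) >= activity:
                return True
    return False


def find_forced_cycles(
    network: MetabolicNetwork,
    efms: list[InternalEFM] | None = None,
    v_min: float = ACTIVITY_TOL,
    joint_flips: bool = False,
) -> list[ForcedCycle]:
    """Internal EFMs active, with their signs, in every non-zero solution.

    An EFM is forced when (i) no non-zero flux distribution exists with
    its support switched off and (ii) every sign variant — each single
    flip and the full reversal, or all joint flips with ``joint_flips`` —
    is LP-infeasible.  Every reported cycle therefore certifies a genuine
    thermodynamic inconsistency of the irreversibility annotations.
    """
    if efms is None:
        efms = enumerate_internal_efms(network)
    forced: list[ForcedCycle] = []
    for efm in efms:
        if not _variant_feasible(network, efm.support, efm.signs, v_min):
            continue  # mode cannot run at all; not a directionality conflict
        if _can_switch_off(network, efm.support, ACTIVITY_TOL):
            continue
        k = len(efm.support)
        if joint_flips:
            variants = []
            for bits in range(1, 1 << k):
                variants.append(
                    tuple(
                        -s if (bits >> i) & 1 else s
                        for i, s in enumerate(efm.signs)
                    )
                )
        else:
            variants = [
                tuple(-s if i == f else s for i, s in enumerate(efm.signs))
                for f in range(k)
            ]
            variants.append(tuple(-s for s in efm.signs))
        infeasible = []
        all_blocked = True
        for var in variants:
            if _variant_feasible(network, efm.support, var, v_min):
                all_blocked = False
                break
            infeasible.append(var)
        if all_blocked:
            relax = tuple(
                j for j in efm.support if not network.is_reversible(j)
            )
            forced.append(
                ForcedCycle(
                    efm=efm, witnesses=infeasible, suggested_relaxations=relax
                )
            )
    return forced


def assess_structure(network: MetabolicNetwork) -> dict:
    """Full structural report: EFM count, forced cycles, suggestions."""
    efms = enumerate_internal_efms(network)
    forced = find_forced_cycles(network, efms)
    return {
        "n_internal_efms": len(efms),
        "forced_cycles": [
            {
                "reactions": [network.reaction_ids[j] for j in fc.efm.support],
                "signs": list(fc.efm.signs),
                "suggested_relaxations": [
                    network.reaction_ids[j] for j in fc.suggested_relaxations
                ],
            }
            for fc in forced
        ],
        "consistent": not forced,
    }
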