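"""Model and prior I/O.

Models are exchanged as COBRA-style JSON (canonical) or SBML Level 3 with
the fbc package; both are parsed with COBRApy and converted to the plain
array container used by the analysis code.  Priors travel as two TSV
tables: per-metabolite mean/sd of ln-concentration and a dense covariance
table for the standard reaction energies.
"""

from __future__ import annotations

import pathlib

import numpy as np
import pandas as pd

from .network import (
    DEFAULT_R_GAS,
    DEFAULT_TEMPERATURE,
    MetabolicNetwork,
    ThermoPriors,
    ValidationError,
)

__all__ = [
    "load_network",
    "save_network",
    "network_from_cobra",
    "network_to_cobra",
    "load_priors",
    "save_priors",
]


def network_from_cobra(model) -> MetabolicNetwork:
    """Convert a ``cobra.Model`` into a :class:`MetabolicNetwork`."""
    met_ids = [m.id for m in model.metabolites]
    rxn_ids = [r.id for r in model.reactions]
    met_index = {mid: i for i, mid in enumerate(met_ids)}
    S = np.zeros((len(met_ids), len(rxn_ids)))
    lb = np.zeros(len(rxn_ids))
    ub = np.zeros(len(rxn_ids))
    for j, rxn in enumerate(model.reactions):
        lb[j], ub[j] = rxn.lower_bound, rxn.upper_bound
        for met, coeff in rxn.metabolites.items():
            S[met_index[met.id], j] = coeff
    compartments = [m.compartment or "c" for m in model.metabolites]
    return MetabolicNetwork(
        S=S,
        lb=lb,
        ub=ub,
        reaction_ids=rxn_ids,
        metabolite_ids=met_ids,
        compartments=compartments,
    )


def network_to_cobra(network: MetabolicNetwork):
    """Convert back to a ``cobra.Model`` (for serialization)."""
    import cobra

    model = cobra.Model("pta_model")
    mets = [
        cobra.Metabolite(mid, compartment=comp)
        for mid, comp in zip(network.metabolite_ids, network.compartments)
    ]
    model.add_metabolites(mets)
    rxns = []
    for j, rid in enumerate(network.reaction_ids):
        rxn = cobra.Reaction(rid)
        rxn.lower_bound = float(network.lb[j])
        rxn.upper_bound = float(network.ub[j])
        rxns.append(rxn)
    model.add_reactions(rxns)
    for j, rxn in enumerate(model.reactions):
        col = network.S[:, j]
        rxn.add_metabolites(
            {mets[i]: float(col[i]) for i in np.nonzero(col)[0]}
        )
    return model


def load_network(path: str | pathlib.Path, format: str | None = None) -> MetabolicNetwork:
    """Load a model from COBRA JSON or SBML.

    The format is inferred from the suffix unless given explicitly as
    ``"cobra-json"`` or ``"sbml"``.
    """
    import cobra.io

    path = pathlib.Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "sbml" if path.suffix.lower() in {".xml", ".sbml"} else "cobra-json"
    if format == "cobra-json":
        model = cobra.io.load_json_model(str(path))
    elif format == "sbml":
        model = cobra.io.read_sbml_model(str(path))
    else:
        raise ValueError(f"unknown model format: {format!r}")
    return network_from_cobra(model)


def save_network(network: MetabolicNetwork, path: str | pathlib.Path) -> None:
    """Write a model as COBRA JSON or SBML depending on the suffix."""
    import cobra.io

    path = pathlib.Path(path)
    model = network_to_cobra(network)
    if path.suffix.lower() in {".xml", ".sbml"}:
        cobra.io.write_sbml_model(model, str(path))
    else:
        cobra.io.save_json_model(model, str(path))


def save_priors(
    priors: ThermoPriors,
    network: MetabolicNetwork,
    conc_path: str | pathlib.Path,
    dg0_path: str | pathlib.Path,
) -> None:
    """Write priors as TSV tables.

    The concentration table holds per-metabolite mean and sd of ln c plus
    the dense covariance columns; the energy table holds the mean standard
    energy per Gamma reaction and its dense covariance columns.
    """
    met_ids = network.metabolite_ids
    conc = pd.DataFrame({"metabolite_id": met_ids, "mean_ln_c": priors.mu_c})
    cov_c = pd.DataFrame(priors.Sigma_c, columns=[f"cov_{m}" for m in met_ids])
    pd.concat([conc, cov_c], axis=1).to_csv(conc_path, sep="\t", index=False)

    g_ids = [network.reaction_ids[j] for j in network.gamma]
    dg0 = pd.DataFrame(
        {
            "reaction_id": g_ids,
            "mean_dg0": priors.mu_0,
            "temperature": priors.T,
        }
    )
    cov_0 = pd.DataFrame(priors.Sigma_0, columns=[f"cov_{r}" for r in g_ids])
    pd.concat([dg0, cov_0], axis=1).to_csv(dg0_path, sep="\t", index=False)


def load_priors(
    network: MetabolicNetwork,
    conc_path: str | pathlib.Path,
    dg0_path: str | pathlib.Path,
) -> ThermoPriors:
    """Read priors written by :func:`save_priors`, reordered to the model."""
    conc = pd.read_csv(conc_path, sep="\t").set_index("metabolite_id")
    try:
        conc = conc.loc[network.metabolite_ids]
    except KeyError as exc:
        raise ValidationError(f"priors missing metabolites: {exc}") from exc
    mu_c = conc["mean_ln_c"].to_numpy()
    cov_cols = [f"cov_{m}" for m in network.metabolite_ids]
    if set(cov_cols) <= set(conc.columns):
        Sigma_c = conc[cov_cols].to_numpy()
    elif "sd" in conc.columns:
        Sigma_c = np.diag(conc["sd"].to_numpy() ** 2)
    else:
        raise ValidationError("concentration priors need cov_* or sd columns")

    dg0 = pd.read_csv(dg0_path, sep="\t").set_index("reaction_id")
    g_ids = [network.reaction_ids[j] for j in network.gamma]
    try:
        dg0 = dg0.loc[g_ids]
    except KeyError as exc:
        raise ValidationError(f"priors missing reactions: {exc}") from exc
    mu_0 = dg0["mean_dg0"].to_numpy()
    g_cov_cols = [f"cov_{r}" for r in g_ids]
    if set(g_cov_cols) <= set(dg0.columns):
        Sigma_0 = dg0[g_cov_cols].to_numpy()
    elif "sd" in dg0.columns:
        Sigma_0 = np.diag(dg0["sd"].to_numpy() ** 2)
    else:
        raise ValidationError("energy priors need cov_* or sd columns")
    T = float(dg0["temperature"].iloc[0]) if "temperature" in dg0.columns else DEFAULT_TEMPERATURE
    return ThermoPriors(
        mu_c=mu_c, Sigma_c=Sigma_c, mu_0=mu_0, Sigma_0=Sigma_0, T=T, R_gas=DEFAULT_R_GAS
    )
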