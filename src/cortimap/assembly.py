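"""Assembly of the population-resolved connectome and connectivity measures.

Combines the local (type I) synapse matrices with the cortico-cortical
(type III) synapses into one synapse-count matrix over all populations,
derives the external (type II + IV) indegrees from the per-area synapse
budget set by a constant synapse volume density, and converts between the
connectivity measures: synapse counts, average in/outdegrees and pairwise
connection probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from cortimap.architecture import PopulationGrid
from cortimap.errors import InvalidArgumentError, InvalidStateError

#: Default synapse volume density (synapses / mm^3), the product of the mean
#: measured V1 indegree and the V1 neuron volume density.
RHO_SYN_DEFAULT = 8.3e8


def mean_v1_indegree(values) -> float:
    """Arithmetic mean of measured average indegrees (synapses/neuron)."""
    values = list(values)
    if not values:
        raise InvalidArgumentError("need at least one measured indegree")
    return float(np.mean(values))


def derive_rho_syn(mean_indegree: float, rho_neuron: float) -> float:
    """Synapse volume density from a mean indegree and a neuron density."""
    return float(mean_indegree * rho_neuron)


@dataclass
class Connectome:
    """Population-resolved synaptic connectome.

    ``syn`` (and the per-origin partitions ``syn_I`` / ``syn_III``) are
    dense [target, source] matrices over ``pops.populations``; external
    type II + IV input is carried per population as an indegree.
    """

    pops: PopulationGrid
    syn_I: np.ndarray
    syn_III: np.ndarray
    rho_syn: float
    fln_i: float
    K_ext: pd.Series | None = None
    type_II_totals: pd.Series | None = None

    @property
    def syn(self) -> np.ndarray:
        return self.syn_I + self.syn_III

    @property
    def populations(self) -> list[str]:
        return self.pops.populations

    def area_synapse_matrix(self) -> pd.DataFrame:
        """Total type-III synapses aggregated to area level (target x source)."""
        labels = self.pops.df["area"].to_numpy()
        areas = self.pops.areas
        idx = {a: np.flatnonzero(labels == a) for a in areas}
        out = np.zeros((len(areas), len(areas)))
        for i, a in enumerate(areas):
            for j, b in enumerate(areas):
                out[i, j] = self.syn_III[np.ix_(idx[a], idx[b])].sum()
        return pd.DataFrame(out, index=areas, columns=areas)


def build_connectome(
    pops: PopulationGrid,
    local: dict,
    type3: pd.DataFrame,
    rho_syn: float,
    fln_i: float,
) -> Connectome:
    """Assemble synapse matrices from per-area local circuits and the
    long-format type-III table."""
    names = pops.populations
    pos = {p: k for k, p in enumerate(names)}
    n = len(names)
    syn_I = np.zeros((n, n))
    for area, ls in local.items():
        idx = [pos[f"{area}-{p}"] for p in ls.populations]
        syn_I[np.ix_(idx, idx)] = ls.nsyn_I
    syn_III = np.zeros((n, n))
    if len(type3):
        ti = type3["target_pop"].map(pos).to_numpy()
        si = type3["source_pop"].map(pos).to_numpy()
        np.add.at(syn_III, (ti, si), type3["synapses"].to_numpy(dtype=float))
    type_II = pd.Series(
        {area: ls.nsyn_II_total for area, ls in local.items()}, name="type_II"
    )
    return Connectome(
        pops=pops,
        syn_I=syn_I,
        syn_III=syn_III,
        rho_syn=rho_syn,
        fln_i=fln_i,
        type_II_totals=type_II,
    )


def external_indegrees(connectome: Connectome, arch: pd.DataFrame) -> pd.Series:
    """External (type II + IV) indegree per population.

    For each area the total number of external synapses is the difference
    between the area's synapse budget ``rho_syn * S_patch * D`` and the
    internal (type I + III) synapses, distributed so that every neuron of
    the area has the same external indegree.  A negative residual raises
    an inconsistency error naming the area.
    """
    pops = connectome.pops
    S_patch = np.pi * pops.radius**2
    internal_in = connectome.syn.sum(axis=1)
    k_ext = pd.Series(0.0, index=pops.populations, name="K_ext")
    for area in pops.areas:
        sel = pops.df["area"] == area
        budget = connectome.rho_syn * S_patch * float(arch.at[area, "thickness_total"])
        internal = float(internal_in[sel.to_numpy()].sum())
        residual = budget - internal
        if residual < -1e-6 * budget:
            raise InvalidStateError(
                f"area {area}: internal synapses exceed the synapse budget"
            )
        n_area = pops.area_total(area)
        k_ext[sel.to_numpy()] = max(residual, 0.0) / n_area
    connectome.K_ext = k_ext
    return k_ext


def measures(connectome: Connectome):
    """Indegrees, outdegrees and pairwise connection probabilities.

    ``K = Nsyn / N_target`` per target neuron, ``Kout = Nsyn / N_source``
    per source neuron, and ``C = 1 - (1 - 1/(N_t N_s))**Nsyn`` the
    probability of at least one synapse between a random neuron pair.
    """
    N = connectome.pops.sizes
    if np.any((N <= 0) & (connectome.syn.sum(axis=1) > 0)):
        raise InvalidStateError("zero population size with nonzero synapses")
    syn = connectome.syn
    K = syn / N[:, None]
    Kout = syn / N[None, :]
    inv = 1.0 / (N[:, None] * N[None, :])
    C = -np.expm1(syn * np.log1p(-inv))
    return K, Kout, C
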