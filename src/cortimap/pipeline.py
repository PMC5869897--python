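"""End-to-end derivation pipeline on synthetic inputs.

``run_pipeline`` chains the full derivation: synthetic input generation,
architecture completion, population sizes, local-circuit scaling,
cortico-cortical fitting and disaggregation, connectome assembly, and the
graph analyses.  All tunables live in :class:`PipelineConfig`; everything
is deterministic given the configuration's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any

import numpy as np
import pandas as pd
import yaml

from cortimap import architecture as arch_mod
from cortimap import assembly, cortico_cortical as cc, graph as graph_mod
from cortimap import local_circuit as lc
from cortimap import synthetic
from cortimap.synthetic import GroundTruth


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run.

    Defaults reproduce the study conditions: 32 areas, 11 injected areas
    with repeats in 2, intrinsic labeling fraction 0.79, subcortical
    fraction 0.013, synapse density 8.3e8 / mm^3, SLN thresholds
    0.35 / 0.65, teleportation probability 0.15, 93% excitatory targeting.
    """

    n_areas: int = 32
    seed: int = 0
    n_injections: int = 11
    truth: dict = field(default_factory=dict)
    missing_fraction: float = 0.55
    sln_coverage: float = 1.0 / 3.0
    pattern_coverage: float = 0.4
    gamma: dict | None = None
    rho_syn: float = assembly.RHO_SYN_DEFAULT
    fln_i: float = 0.79
    subcortical: float = 0.013
    sln_link: str = "probit"
    sln_lo: float = cc.SLN_FEEDBACK_MAX
    sln_hi: float = cc.SLN_FEEDFORWARD_MIN
    excitatory_target_fraction: float = 0.93
    redistribute: str = "all"
    p_jump: float = 0.15
    cluster_restarts: int = 100
    n_surrogates: int = 100
    surrogate_restarts: int = 5
    J_E: float = 0.15
    g_ratio: float = 4.0
    run_graph: bool = True
    run_paths: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PipelineResult:
    """All intermediate and final products of one pipeline run."""

    config: PipelineConfig
    truth: GroundTruth
    arch: pd.DataFrame
    distances: pd.DataFrame
    tracing: Any
    thickness_fit: arch_mod.LinearFit
    pops: arch_mod.PopulationGrid
    local: dict
    edr_fit: cc.EDRFit
    fln_complete: pd.DataFrame
    fln_nonmodeled: pd.DataFrame | None
    sln_fit: cc.SLNFit
    sln_complete: pd.DataFrame
    p_cond: pd.DataFrame
    type3: pd.DataFrame
    connectome: assembly.Connectome
    K: np.ndarray
    Kout: np.ndarray
    C: np.ndarray
    K_ext: pd.Series
    origin_shares: dict
    nsyn_area: pd.DataFrame | None = None
    clustering: dict | None = None
    codelength: float | None = None
    Q: float | None = None
    surrogate_Q: np.ndarray | None = None
    gain: graph_mod.GainGraph | None = None
    pathset: graph_mod.PathSet | None = None
    path_stats: graph_mod.PathPatternStats | None = None


def derive_connectome(
    config: PipelineConfig,
    arch_raw: pd.DataFrame,
    distances: pd.DataFrame,
    tracing,
    celltypes: pd.DataFrame,
    truth: GroundTruth,
) -> PipelineResult:
    """Run the derivation stages on explicit inputs."""
    # --- architecture completion and population sizes
    arch = arch_mod.fill_densities_by_type(arch_raw)
    thickness_fit, arch = arch_mod.fit_thickness(arch)
    arch = arch_mod.fit_laminar_fractions(arch)
    pops = arch_mod.population_sizes(arch, lc.R0_MM, config.gamma)

    # --- local circuits (type I and II)
    template = lc.load_local_template()
    local = {}
    for area in arch.index:
        pop_names = tuple(p.split("-")[1] for p in pops.area_populations(area))
        N_area = np.array([pops.df.at[f"{area}-{p}", "N"] for p in pop_names])
        local[area] = lc.local_synapses(
            area,
            arch.loc[area],
            N_area,
            pop_names,
            template,
            config.rho_syn,
            config.fln_i,
        )

    # --- cortico-cortical: map, fit, complete
    fln_mapped = cc.map_fln(tracing.injections, tracing.overlap)
    sln_mapped = cc.map_sln(tracing.injections, tracing.overlap)
    edr_fit = cc.fit_edr(fln_mapped, distances)
    fln_complete, fln_nonmodeled = cc.fill_and_normalize_fln(
        fln_mapped,
        edr_fit,
        tracing.binary,
        config.fln_i,
        config.subcortical,
        distances,
        tracing.nonmodeled_distances,
    )
    log_rho = np.log(arch["rho_total"])
    counts = tracing.sln_counts
    ell_fit = (
        log_rho.loc[counts["target"]].to_numpy()
        - log_rho.loc[counts["source"]].to_numpy()
    )
    sln_fit = cc.fit_sln(
        counts["supra"].to_numpy(),
        counts["n"].to_numpy(),
        ell_fit,
        link=config.sln_link,
    )
    ell_mat = log_rho.to_numpy()[:, None] - log_rho.to_numpy()[None, :]
    sln_pred = cc.predict_sln(sln_fit, ell_mat)
    sln_complete = sln_mapped.copy()
    fill = sln_complete.isna().to_numpy() & (fln_complete.to_numpy() > 0)
    vals = sln_complete.to_numpy()
    vals[fill] = sln_pred[fill]
    sln_complete = pd.DataFrame(
        vals, index=sln_complete.index, columns=sln_complete.columns
    )

    # --- synapse-to-cell-body conditionals anchored to the densest area
    ref_area = arch["rho_total"].idxmax()
    ref_pops = pops.area_populations(ref_area)
    ref_tot = pops.area_total(ref_area)
    occurrence = {
        p.split("-")[1]: pops.df.at[p, "N"] / ref_tot for p in ref_pops
    }
    p_cond = cc.synapse_to_cellbody(celltypes, occurrence)

    # --- type III assembly
    S0 = np.pi * lc.R0_MM**2
    nsyn_tot = config.rho_syn * S0 * arch["thickness_total"]
    nsyn_cc = fln_complete.mul(nsyn_tot, axis=0)
    type3 = cc.assemble_type_iii(
        nsyn_cc,
        sln_complete,
        arch,
        pops,
        p_cond,
        tracing.patterns,
        excitatory_target_fraction=config.excitatory_target_fraction,
        redistribute=config.redistribute,
        sln_lo=config.sln_lo,
        sln_hi=config.sln_hi,
    )

    # --- assemble and measure
    connectome = assembly.build_connectome(
        pops, local, type3, config.rho_syn, config.fln_i
    )
    K, Kout, C = assembly.measures(connectome)
    K_ext = assembly.external_indegrees(connectome, arch)

    # --- per-neuron origin-type shares across the network
    budget = float((config.rho_syn * S0 * arch["thickness_total"]).sum())
    tot_I = float(connectome.syn_I.sum())
    tot_III = float(connectome.syn_III.sum())
    tot_II = float(connectome.type_II_totals.sum())
    origin_shares = {
        "I": tot_I / budget,
        "II": tot_II / budget,
        "III": tot_III / budget,
        "IV": (budget - tot_I - tot_II - tot_III) / budget,
    }

    return PipelineResult(
        config=config,
        truth=truth,
        arch=arch,
        distances=distances,
        tracing=tracing,
        thickness_fit=thickness_fit,
        pops=pops,
        local=local,
        edr_fit=edr_fit,
        fln_complete=fln_complete,
        fln_nonmodeled=fln_nonmodeled,
        sln_fit=sln_fit,
        sln_complete=sln_complete,
        p_cond=p_cond,
        type3=type3,
        connectome=connectome,
        K=K,
        Kout=Kout,
        C=C,
        K_ext=K_ext,
        origin_shares=origin_shares,
    )


def analyze_graph(result: PipelineResult) -> PipelineResult:
    """Community detection and path analysis on a derived connectome."""
    config = result.config
    pops = result.pops
    n_area = pd.Series({a: pops.area_total(a) for a in pops.areas})
    nsyn_area = result.connectome.area_synapse_matrix()
    result.nsyn_area = nsyn_area
    W_out, W_in = graph_mod.relative_degrees(nsyn_area, n_area)
    clustering, codelength = graph_mod.map_equation_cluster(
        W_out, p_jump=config.p_jump, restarts=config.cluster_restarts, seed=config.seed
    )
    result.clustering = clustering
    result.codelength = codelength
    result.Q = graph_mod.modularity(W_out, W_in, clustering)
    if config.n_surrogates > 0:
        result.surrogate_Q = graph_mod.surrogates(
            nsyn_area,
            n_area,
            config.n_surrogates,
            seed=config.seed + 1,
            p_jump=config.p_jump,
            restarts=config.surrogate_restarts,
        )
    if config.run_paths:
        ei = pops.df["ei"].to_numpy()
        gain = graph_mod.build_gain(
            result.K, ei, pops.populations, J_E=config.J_E, g_ratio=config.g_ratio
        )
        result.gain = gain
        node_areas = pops.df["area"].to_numpy()
        result.pathset = graph_mod.shortest_paths(gain, node_areas)
        result.path_stats = graph_mod.categorize_and_summarize(
            result.pathset,
            result.sln_complete,
            result.arch["arch_type"],
            binary=result.tracing.binary,
            sln_lo=config.sln_lo,
            sln_hi=config.sln_hi,
        )
    return result


def run_pipeline(config: PipelineConfig | None = None) -> PipelineResult:
    """Generate synthetic inputs and run the full derivation and analyses."""
    config = config or PipelineConfig()
    truth = GroundTruth(seed=config.seed, **config.truth)
    arch_raw = synthetic.make_architecture(
        config.n_areas, config.seed, missing_fraction=config.missing_fraction
    )
    distances = synthetic.make_distances(config.n_areas, config.seed)
    tracing = synthetic.make_tracing(
        arch_raw,
        distances,
        truth,
        config.n_injections,
        sln_coverage=config.sln_coverage,
        pattern_coverage=config.pattern_coverage,
        fln_row_total=1.0 - config.fln_i - config.subcortical,
    )
    celltypes = synthetic.make_celltypes()
    result = derive_connectome(config, arch_raw, distances, tracing, celltypes, truth)
    if config.run_graph:
        result = analyze_graph(result)
    return result
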