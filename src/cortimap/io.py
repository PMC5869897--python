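"""Plain-text readers and writers for the pipeline's file interfaces.

All inputs and outputs are CSV or JSON: the architecture table, the
distance matrix, long-format FLN/SLN tables, the binary connectivity
matrix, ordinal laminar patterns, the parcellation-overlap matrix, the
cell-type table, the connectome bundle (population sizes, synapse counts,
degrees, probabilities, external input) and the analysis products
(clusters, modularity, paths, path patterns).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from cortimap.synthetic import GroundTruth, TracingData


def write_inputs(outdir, arch, distances, tracing: TracingData, truth: GroundTruth, celltypes):
    """Write the synthetic input dataset as the CSV/JSON file set."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    arch.to_csv(out / "architecture.csv")
    distances.to_csv(out / "distances.csv")
    tracing.injections[["injection", "target", "source", "fln", "nln"]].to_csv(
        out / "fln.csv", index=False
    )
    sln = tracing.injections.dropna(subset=["sln"])
    sln[["injection", "target", "source", "sln", "sln_supra", "sln_n"]].to_csv(
        out / "sln.csv", index=False
    )
    tracing.binary.to_csv(out / "cocomac_binary.csv")
    tracing.patterns.to_csv(out / "laminar_patterns.csv", index=False)
    tracing.overlap.to_csv(out / "overlap.csv")
    tracing.nonmodeled_distances.to_csv(out / "nonmodeled_distances.csv")
    celltypes.to_csv(out / "celltypes.csv", index=False)
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(truth.to_dict(), fh, indent=2)


def read_inputs(indir):
    """Read a dataset written by :func:`write_inputs`.

    Returns ``(arch, distances, tracing, truth, celltypes)``.
    """
    ind = Path(indir)
    arch = pd.read_csv(ind / "architecture.csv", index_col=0)
    distances = pd.read_csv(ind / "distances.csv", index_col=0)
    binary = pd.read_csv(ind / "cocomac_binary.csv", index_col=0)
    fln = pd.read_csv(ind / "fln.csv")
    sln = pd.read_csv(ind / "sln.csv")
    inj = fln.merge(
        sln.rename(columns={"sln_supra": "sln_supra", "sln_n": "sln_n"}),
        on=["injection", "target", "source"],
        how="left",
    )
    patterns = pd.read_csv(ind / "laminar_patterns.csv", dtype={"layer": str})
    overlap = pd.read_csv(ind / "overlap.csv", index_col=0)
    nonmodeled = pd.read_csv(ind / "nonmodeled_distances.csv", index_col=0)
    with open(ind / "ground_truth.json") as fh:
        truth = GroundTruth(**json.load(fh))
    celltypes = pd.read_csv(ind / "celltypes.csv")

    mean_fln = inj.groupby(["target", "source"])["fln"].mean()
    fln_mat = pd.DataFrame(np.nan, index=binary.index, columns=binary.columns)
    for (t, s), v in mean_fln.items():
        fln_mat.loc[t, s] = v
    with_sln = inj.dropna(subset=["sln"])
    sln_mat = pd.DataFrame(np.nan, index=binary.index, columns=binary.columns)
    for (t, s), v in with_sln.groupby(["target", "source"])["sln"].mean().items():
        sln_mat.loc[t, s] = v
    sln_counts = (
        with_sln.groupby(["target", "source"])[["sln_supra", "sln_n"]]
        .sum()
        .reset_index()
        .rename(columns={"sln_supra": "supra", "sln_n": "n"})
    )
    tracing = TracingData(
        injections=inj,
        binary=binary,
        fln=fln_mat,
        sln=sln_mat,
        sln_counts=sln_counts,
        patterns=patterns,
        overlap=overlap,
        distances=distances,
        nonmodeled_distances=nonmodeled,
        fln_row_total=None,
    )
    return arch, distances, tracing, truth, celltypes


def write_connectome(outdir, result):
    """Write the connectome bundle as a CSV file set."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    pops = result.pops
    pops.df.to_csv(out / "N.csv")
    names = pops.populations
    for fname, mat in [
        ("synapses.csv", result.connectome.syn),
        ("indegrees.csv", result.K),
        ("outdegrees.csv", result.Kout),
        ("probabilities.csv", result.C),
    ]:
        pd.DataFrame(mat, index=names, columns=names).to_csv(out / fname)
    result.K_ext.to_csv(out / "external.csv")
    with open(out / "fits.json", "w") as fh:
        json.dump(
            {
                "edr": result.edr_fit.to_dict(),
                "sln": result.sln_fit.to_dict(),
                "thickness": result.thickness_fit.to_dict(),
                "origin_shares": result.origin_shares,
            },
            fh,
            indent=2,
        )


def write_analysis(outdir, result):
    """Write clustering, modularity and path analysis products."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    if result.clustering is not None:
        pd.Series(result.clustering, name="cluster").rename_axis("area").to_csv(
            out / "clusters.csv"
        )
        payload = {"Q": result.Q, "codelength_bits": result.codelength}
        if result.surrogate_Q is not None:
            payload["surrogate_Q_mean"] = float(np.mean(result.surrogate_Q))
            payload["surrogate_Q_sd"] = float(np.std(result.surrogate_Q))
            payload["n_surrogates"] = int(len(result.surrogate_Q))
        with open(out / "modularity.json", "w") as fh:
            json.dump(payload, fh, indent=2)
    if result.pathset is not None:
        paths = result.pathset.paths.copy()
        paths["nodes"] = paths["nodes"].map(lambda seq: "|".join(seq))
        paths["intermediate_areas"] = paths["intermediate_areas"].map(
            lambda seq: "|".join(seq)
        )
        paths.to_csv(out / "paths.csv", index=False)
    if result.path_stats is not None:
        rows = []
        for cat, counter in result.path_stats.start_end_by_sln.items():
            for (sp, ep), cnt in counter.items():
                rows.append(("sln", cat, f"{sp}->{ep}", cnt))
        for cat, counter in result.path_stats.start_end_by_type.items():
            for (sp, ep), cnt in counter.items():
                rows.append(("type", cat, f"{sp}->{ep}", cnt))
        for cat, counter in result.path_stats.relay_by_type.items():
            for pat, cnt in counter.items():
                rows.append(("relay", cat, pat, cnt))
        pd.DataFrame(
            rows, columns=["kind", "category", "pattern", "count"]
        ).to_csv(out / "path_patterns.csv", index=False)
        with open(out / "path_stats.json", "w") as fh:
            json.dump(
                {
                    "frac_indirect": result.path_stats.frac_indirect,
                    "frac_direct_pairs_indirect": result.path_stats.frac_direct_pairs_indirect,
                },
                fh,
                indent=2,
            )
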