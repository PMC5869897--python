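"""Synthetic anatomical datasets with known ground truth.

The raw inputs of the connectome derivation (laminar neuron densities,
thicknesses, retrograde tracing fractions, laminar projection patterns,
cell-type morphology statistics) come from sources that cannot be shipped
with the package.  This module generates replacement datasets that carry
the statistical structure the derivation assumes:

* overall neuron density increases with architectural type, total cortical
  thickness decreases with the logarithm of density, and the relative
  thickness of layer 4 increases with it;
* the fraction of labeled neurons (FLN) of existing connections follows an
  exponential distance rule with multiplicative log10-normal noise;
* supragranular labeled-neuron counts are beta-binomial with a probit-linear
  mean in the log ratio of the two areas' neuron densities.

All generating parameters live in :class:`GroundTruth` so that recovery
tests can compare fitted against generating values.  Every function is
deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr

from cortimap.errors import InvalidArgumentError

#: Layers that contain neurons (layer 1 carries synapses but no somata).
LAYERS = ("23", "4", "5", "6")
#: Layers that carry thickness, including layer 1.
FRAC_LAYERS = ("1", "23", "4", "5", "6")
#: The eight local populations, target-side ordering used throughout.
POPULATIONS = ("23E", "23I", "4E", "4I", "5E", "5I", "6E", "6I")


@dataclass(frozen=True)
class GroundTruth:
    """Generating parameters of the synthetic tracing data.

    Parameters
    ----------
    lambda_decay:
        Decay rate of the exponential distance rule, in 1/mm.
    c_scale:
        Scale of the exponential distance rule (FLN at zero distance).
    a0, a1:
        Probit-scale intercept and slope of the SLN relation
        ``g(SLN) = a0 + a1 * ell`` with ``ell`` the natural-log ratio of
        target over source overall neuron density.
    phi:
        Dispersion of the beta-binomial labeling model, in (0, 1).
    fln_noise_sd:
        Standard deviation of log10-FLN residuals around the distance rule.
    seed:
        Integer seed for the tracing generator.
    """

    lambda_decay: float = 0.11
    c_scale: float = 0.045
    a0: float = -0.152
    a1: float = -1.534
    phi: float = 0.214
    fln_noise_sd: float = 0.4
    seed: int = 0

    def __post_init__(self):
        if not self.lambda_decay > 0:
            raise InvalidArgumentError("lambda_decay must be > 0")
        if not 0 <= self.phi < 1:
            raise InvalidArgumentError("phi must lie in [0, 1)")
        if self.fln_noise_sd < 0:
            raise InvalidArgumentError("fln_noise_sd must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TracingData:
    """Container for (synthetic or mapped) tract-tracing data.

    ``injections`` is a long table with one row per (injection, source)
    pair in the source parcellation scheme ("beta" scheme), columns
    ``injection, target, source, fln, nln, sln_supra, sln_n, sln`` (SLN
    columns NaN where unobserved).  ``binary`` / ``fln`` / ``sln`` are
    square area-level matrices (target rows, source columns).
    """

    injections: pd.DataFrame
    binary: pd.DataFrame
    fln: pd.DataFrame
    sln: pd.DataFrame
    sln_counts: pd.DataFrame  # columns target, source, supra, n
    patterns: pd.DataFrame  # columns target, source, side, layer, ordinal
    overlap: pd.DataFrame  # rows: model scheme areas, cols: beta scheme
    distances: pd.DataFrame
    nonmodeled_distances: pd.DataFrame  # rows: targets, cols: external areas
    fln_row_total: float | None


def _area_names(n: int) -> list[str]:
    return [f"A{i + 1:02d}" for i in range(n)]


def make_architecture(
    n_areas: int,
    seed: int,
    missing_fraction: float = 0.55,
) -> pd.DataFrame:
    """Generate a per-area architecture table.

    The table mirrors the empirical gradients used by the completion stage:
    overall neuron density increases with architectural type, total
    thickness decreases linearly with log10 density, and the relative L4
    thickness increases with log10 density.  Exactly one area is agranular
    (type 2) with zero L4 thickness and density.  A ``missing_fraction`` of
    areas has densities and thicknesses masked (NaN) to emulate incomplete
    coverage; every architectural type keeps at least one measured
    representative so that completion by type averages is possible.

    Returns a DataFrame indexed by area name with columns ``arch_type``,
    ``rho_total``, ``rho_23/4/5/6``, ``thickness_total``,
    ``frac_1/23/4/5/6``, ``surface`` and provenance columns
    ``src_density``, ``src_thickness`` in {"measured", "missing"}.
    """
    if n_areas < 4:
        raise InvalidArgumentError("n_areas must be >= 4")
    if not 0 <= missing_fraction < 1:
        raise InvalidArgumentError("missing_fraction must lie in [0, 1)")
    rng = np.random.default_rng([int(seed), 101])
    areas = _area_names(n_areas)

    types = np.concatenate([[2], rng.integers(3, 9, size=n_areas - 1)])
    rng.shuffle(types)

    log_rho = 4.55 + 0.075 * types + rng.normal(0.0, 0.04, n_areas)
    rho_total = 10.0 ** log_rho
    thickness = 9.4 - 1.56 * log_rho + rng.normal(0.0, 0.08, n_areas)
    thickness = np.clip(thickness, 0.8, None)

    frac4 = np.clip(-0.93 + 0.225 * log_rho + rng.normal(0.0, 0.015, n_areas), 0.0, None)
    frac4[types == 2] = 0.0
    frac_other = np.column_stack(
        [
            rng.normal(0.09, 0.01, n_areas),  # L1
            rng.normal(0.32, 0.03, n_areas),  # L2/3
            rng.normal(0.13, 0.015, n_areas),  # L5
            rng.normal(0.20, 0.02, n_areas),  # L6
        ]
    ).clip(0.02, None)
    fracs = np.column_stack(
        [frac_other[:, 0], frac_other[:, 1], frac4, frac_other[:, 2], frac_other[:, 3]]
    )
    fracs /= fracs.sum(axis=1, keepdims=True)

    # Laminar densities: layer 4 is densest; rescale so the thickness-weighted
    # mean over neuron-bearing layers reproduces the overall density.
    mult = np.column_stack(
        [
            rng.normal(0.75, 0.05, n_areas),  # L2/3
            rng.normal(1.60, 0.10, n_areas),  # L4
            rng.normal(0.85, 0.05, n_areas),  # L5
            rng.normal(1.00, 0.05, n_areas),  # L6
        ]
    ).clip(0.1, None)
    mult[types == 2, 1] = 0.0
    weighted = (mult * fracs[:, 1:]).sum(axis=1)
    rho_lam = mult * (rho_total / weighted)[:, None]

    surface = np.clip(10.0 ** rng.normal(2.3, 0.45, n_areas), 30.0, 3000.0)

    df = pd.DataFrame(
        {
            "arch_type": types,
            "rho_total": rho_total,
            "rho_23": rho_lam[:, 0],
            "rho_4": rho_lam[:, 1],
            "rho_5": rho_lam[:, 2],
            "rho_6": rho_lam[:, 3],
            "thickness_total": thickness,
            "frac_1": fracs[:, 0],
            "frac_23": fracs[:, 1],
            "frac_4": fracs[:, 2],
            "frac_5": fracs[:, 3],
            "frac_6": fracs[:, 4],
            "surface": surface,
        },
        index=pd.Index(areas, name="area"),
    )
    df["src_density"] = "measured"
    df["src_thickness"] = "measured"

    n_missing = int(round(missing_fraction * n_areas))
    if n_missing > 0:
        # keep one measured representative per occurring type
        keep = set()
        for t in np.unique(types):
            keep.add(int(rng.choice(np.flatnonzero(types == t))))
        candidates = [i for i in range(n_areas) if i not in keep]
        rng.shuffle(candidates)
        missing_idx = sorted(candidates[:n_missing])
        density_cols = ["rho_total", "rho_23", "rho_4", "rho_5", "rho_6"]
        thick_cols = ["thickness_total", "frac_1", "frac_23", "frac_4", "frac_5", "frac_6"]
        df.iloc[missing_idx, [df.columns.get_loc(c) for c in density_cols]] = np.nan
        df.iloc[missing_idx, [df.columns.get_loc(c) for c in thick_cols]] = np.nan
        df.iloc[missing_idx, df.columns.get_loc("src_density")] = "missing"
        df.iloc[missing_idx, df.columns.get_loc("src_thickness")] = "missing"
        # an agranular area always keeps its structural zero in L4
        df.loc[df["arch_type"] == 2, ["rho_4", "frac_4"]] = (
            df.loc[df["arch_type"] == 2, ["rho_4", "frac_4"]].fillna(0.0)
        )
    return df


def make_distances(n_areas: int, seed: int, box_mm: float = 34.0, min_sep: float = 4.0) -> pd.DataFrame:
    """Place areas as points in 3-space and return pairwise Euclidean distances.

    Points are uniform in a cube of side ``box_mm`` with a minimum pairwise
    separation, giving inter-area distances in roughly 5-60 mm.  The result
    is symmetric with a zero diagonal and satisfies the triangle inequality
    by construction.
    """
    if n_areas < 2:
        raise InvalidArgumentError("n_areas must be >= 2")
    rng = np.random.default_rng([int(seed), 202])
    pts = np.empty((n_areas, 3))
    n_placed = 0
    attempts = 0
    while n_placed < n_areas:
        cand = rng.uniform(0.0, box_mm, size=3)
        if n_placed == 0 or np.min(
            np.linalg.norm(pts[:n_placed] - cand, axis=1)
        ) >= min_sep:
            pts[n_placed] = cand
            n_placed += 1
        attempts += 1
        if attempts > 100000:
            raise InvalidArgumentError("cannot satisfy min_sep; reduce n_areas or min_sep")
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
    areas = _area_names(n_areas)
    return pd.DataFrame(d, index=pd.Index(areas, name="area"), columns=areas)


def _beta_binomial_counts(rng, mean, phi, n):
    """Counts from a beta-binomial with given mean, dispersion and size."""
    mean = np.clip(mean, 1e-9, 1 - 1e-9)
    if phi <= 0:
        p = mean
    else:
        alpha = mean * (1 - phi) / phi
        beta = (1 - mean) * (1 - phi) / phi
        p = rng.beta(alpha, beta)
    return rng.binomial(n, p)


def make_tracing(
    arch: pd.DataFrame,
    dist: pd.DataFrame,
    truth: GroundTruth,
    n_injections: int,
    injections: Sequence[str] | None = None,
    existence_density: float = 0.62,
    sln_coverage: float = 1.0 / 3.0,
    pattern_coverage: float = 0.4,
    n_labeled: int = 100,
    fln_row_total: float | None = 0.197,
    n_repeat: int = 2,
    n_nonmodeled: int = 10,
) -> TracingData:
    """Generate injection-wise tracing data for a synthetic area set.

    For each injected target area, the FLN of existing connections is
    ``c * exp(-lambda * d)`` times a multiplicative ``10**N(0, sd)`` noise
    term.  If ``fln_row_total`` is given, each injection's FLN values are
    renormalized so that their sum equals it, emulating the normalization
    inherent in measured labeling fractions (which discards the absolute
    scale ``c``); pass ``None`` to keep the raw draws, e.g. for parameter
    recovery studies.  Supragranular counts are beta-binomial with a
    probit-linear mean in the log density ratio.  Ordinal laminar
    source/target patterns (0-3) are produced for a ``pattern_coverage``
    fraction of existing connections, qualitatively consistent with SLN.

    The overlap matrix is the identity (the injected scheme coincides with
    the model scheme); :func:`cortimap.cortico_cortical.map_fln` handles
    nontrivial overlap matrices.
    """
    areas = list(arch.index)
    n_areas = len(areas)
    if injections is None:
        if n_injections > n_areas:
            raise InvalidArgumentError("n_injections must be <= n_areas")
        rng0 = np.random.default_rng([int(truth.seed), 303])
        targets = list(rng0.choice(areas, size=n_injections, replace=False))
        # repeat injections in a few areas, as in real campaigns
        targets += targets[: min(n_repeat, len(targets))]
    else:
        unknown = set(injections) - set(areas)
        if unknown:
            raise InvalidArgumentError(f"unknown injection areas: {sorted(unknown)}")
        targets = list(injections)

    rng = np.random.default_rng([int(truth.seed), 304])
    binary = (rng.random((n_areas, n_areas)) < existence_density).astype(int)
    np.fill_diagonal(binary, 0)
    binary = pd.DataFrame(binary, index=pd.Index(areas, name="area"), columns=areas)

    # densities may be missing in arch; ell falls back to the type gradient
    log_rho = np.log(arch["rho_total"]).copy()
    if log_rho.isna().any():
        fit_rho = np.log(10.0) * (4.55 + 0.075 * arch["arch_type"])
        log_rho = log_rho.fillna(fit_rho)

    rows = []
    for k, tgt in enumerate(targets):
        src_mask = binary.loc[tgt].to_numpy().astype(bool)
        sources = [a for a, m in zip(areas, src_mask) if m]
        if not sources:
            continue
        d = dist.loc[tgt, sources].to_numpy(dtype=float)
        raw = truth.c_scale * np.exp(-truth.lambda_decay * d)
        raw = raw * 10.0 ** rng.normal(0.0, truth.fln_noise_sd, size=len(sources))
        fln = raw * (fln_row_total / raw.sum()) if fln_row_total is not None else raw
        nln = np.maximum(1, np.round(fln * 1e5)).astype(int)
        ell = (log_rho[tgt] - log_rho[sources]).to_numpy(dtype=float)
        mu = ndtr(truth.a0 + truth.a1 * ell)
        supra = _beta_binomial_counts(rng, mu, truth.phi, n_labeled)
        observed = rng.random(len(sources)) < sln_coverage
        for j, src in enumerate(sources):
            rows.append(
                {
                    "injection": k,
                    "target": tgt,
                    "source": src,
                    "fln": fln[j],
                    "nln": nln[j],
                    "sln_supra": int(supra[j]) if observed[j] else np.nan,
                    "sln_n": n_labeled if observed[j] else np.nan,
                    "sln": supra[j] / n_labeled if observed[j] else np.nan,
                }
            )
    inj = pd.DataFrame(rows)

    # area-level matrices: arithmetic mean over repeat injections
    fln_mat = pd.DataFrame(np.nan, index=binary.index, columns=binary.columns)
    sln_mat = pd.DataFrame(np.nan, index=binary.index, columns=binary.columns)
    mean_fln = inj.groupby(["target", "source"])["fln"].mean()
    for (tgt, src), v in mean_fln.items():
        fln_mat.loc[tgt, src] = v
    with_sln = inj.dropna(subset=["sln"])
    mean_sln = with_sln.groupby(["target", "source"])["sln"].mean()
    for (tgt, src), v in mean_sln.items():
        sln_mat.loc[tgt, src] = v
    sln_counts = (
        with_sln.groupby(["target", "source"])[["sln_supra", "sln_n"]]
        .sum()
        .reset_index()
        .rename(columns={"sln_supra": "supra", "sln_n": "n"})
    )

    # ordinal laminar patterns for a fraction of existing connections
    pat_rows = []
    tgt_idx, src_idx = np.nonzero(binary.to_numpy())
    for ti, si in zip(tgt_idx, src_idx):
        if rng.random() >= pattern_coverage:
            continue
        tgt, src = areas[ti], areas[si]
        ell = log_rho[tgt] - log_rho[src]
        mu = ndtr(truth.a0 + truth.a1 * ell)
        # source pattern over {2/3, 5, 6}: stronger supra ordinal for high SLN
        a_supra = 3 if mu > 0.65 else (2 if mu > 0.35 else 1)
        a_infra = 3 if mu < 0.35 else (2 if mu < 0.65 else 1)
        src_pat = {"23": a_supra, "5": a_infra, "6": max(1, a_infra - 1)}
        # target pattern over all layers, category-consistent
        if mu > 0.65:
            tgt_pat = {"1": 0, "23": 0, "4": 3, "5": 0, "6": 0}
        elif mu < 0.35:
            tgt_pat = {"1": 2, "23": 2, "4": 0, "5": 2, "6": 1}
        else:
            tgt_pat = {"1": 1, "23": 2, "4": 2, "5": 2, "6": 1}
        for layer, a in src_pat.items():
            pat_rows.append(
                {"target": tgt, "source": src, "side": "source", "layer": layer, "ordinal": a}
            )
        for layer, a in tgt_pat.items():
            pat_rows.append(
                {"target": tgt, "source": src, "side": "target", "layer": layer, "ordinal": a}
            )
    patterns = pd.DataFrame(
        pat_rows, columns=["target", "source", "side", "layer", "ordinal"]
    )

    overlap = pd.DataFrame(
        np.eye(n_areas), index=pd.Index(areas, name="area"), columns=areas
    )
    ext_names = [f"X{i + 1:02d}" for i in range(n_nonmodeled)]
    nonmodeled = pd.DataFrame(
        rng.uniform(15.0, 60.0, size=(n_areas, n_nonmodeled)),
        index=pd.Index(areas, name="area"),
        columns=ext_names,
    )
    return TracingData(
        injections=inj,
        binary=binary,
        fln=fln_mat,
        sln=sln_mat,
        sln_counts=sln_counts,
        patterns=patterns,
        overlap=overlap,
        distances=dist,
        nonmodeled_distances=nonmodeled,
        fln_row_total=fln_row_total,
    )


def make_planted_blocks(
    n_areas: int = 30,
    n_blocks: int = 6,
    seed: int = 0,
    w_within: tuple = (0.5, 1.0),
    w_between: tuple = (0.0, 0.05),
    density_between: float = 0.3,
    scale: float = 1e6,
):
    """Area-level synapse matrix with a planted block (community) structure.

    Within-block directed weights are strong and dense; between-block
    weights are weak and sparse.  Used to validate community detection:
    the planted labels are returned alongside the matrix and a uniform
    per-area neuron count.

    Returns ``(nsyn, labels, n_area)``.
    """
    if n_areas % n_blocks:
        raise InvalidArgumentError("n_areas must be a multiple of n_blocks")
    rng = np.random.default_rng([int(seed), 404])
    labels = np.repeat(np.arange(n_blocks), n_areas // n_blocks)
    W = rng.uniform(*w_between, size=(n_areas, n_areas))
    W *= rng.random((n_areas, n_areas)) < density_between
    same = labels[:, None] == labels[None, :]
    W[same] = rng.uniform(*w_within, size=(n_areas, n_areas))[same]
    np.fill_diagonal(W, 0.0)
    areas = _area_names(n_areas)
    nsyn = pd.DataFrame(W * scale, index=pd.Index(areas, name="area"), columns=areas)
    return nsyn, pd.Series(labels, index=areas), pd.Series(1e5, index=areas)


def make_celltypes() -> pd.DataFrame:
    """Synthetic cell-type table mapping synapse layers to target somata.

    This is a synthetic stand-in for a morphology-derived table: it lists,
    per reconstructed cell type, the relative occurrence, the number of
    synapses the cell receives in each layer, and the probability that a
    synapse in that layer is of cortico-cortical origin.  Pyramidal cells
    have apical dendrites reaching into the layers above their soma (so
    e.g. L4 and L5 pyramids collect synapses in L2/3 and L1), while
    interneurons are confined to their home layer.  The numbers are
    hand-set to be anatomically plausible, not measured.

    Columns: ``cell_type``, ``population``, ``occurrence``, then per layer
    ``v`` in {1, 23, 4, 5, 6}: ``nsyn_v`` and ``pcc_v``.
    """
    rows = [
        # cell_type, population, occurrence, nsyn per layer (1,23,4,5,6), pcc per layer
        ("p2/3", "23E", 0.26, (1500, 4500, 0, 0, 0), (0.9, 0.4, 0.0, 0.0, 0.0)),
        ("b2/3", "23I", 0.06, (0, 3500, 0, 0, 0), (0.0, 0.35, 0.0, 0.0, 0.0)),
        ("p4", "4E", 0.14, (800, 2600, 3200, 0, 0), (0.9, 0.45, 0.25, 0.0, 0.0)),
        ("ss4", "4E", 0.10, (0, 0, 4000, 0, 0), (0.0, 0.0, 0.25, 0.0, 0.0)),
        ("b4", "4I", 0.06, (0, 0, 3300, 0, 0), (0.0, 0.0, 0.2, 0.0, 0.0)),
        ("p5", "5E", 0.09, (1200, 1800, 900, 3800, 0), (0.9, 0.4, 0.25, 0.2, 0.0)),
        ("b5", "5I", 0.02, (0, 0, 0, 3000, 0), (0.0, 0.0, 0.0, 0.15, 0.0)),
        ("p6", "6E", 0.20, (400, 600, 1500, 1200, 4200), (0.9, 0.35, 0.25, 0.2, 0.15)),
        ("b6", "6I", 0.07, (0, 0, 0, 0, 3200), (0.0, 0.0, 0.0, 0.0, 0.1)),
    ]
    records = []
    for name, pop, occ, nsyn, pcc in rows:
        rec = {"cell_type": name, "population": pop, "occurrence": occ}
        for layer, n, p in zip(FRAC_LAYERS, nsyn, pcc):
            rec[f"nsyn_{layer}"] = float(n)
            rec[f"pcc_{layer}"] = float(p)
        records.append(rec)
    df = pd.DataFrame(records)
    df["occurrence"] /= df["occurrence"].sum()
    return df
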