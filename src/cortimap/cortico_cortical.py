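"""Cortico-cortical (type III) connectivity from tracing data.

The area-level connection strength is carried by the fraction of labeled
neurons (FLN) from retrograde tracing; gaps are filled by an exponential
distance rule (EDR) fitted to the measured FLN, and every target's row is
normalized so that cortical FLN (modeled plus non-modeled areas) sums to
``1 - FLN_i - subcortical``.  The laminar origin of a projection is the
fraction of supragranular labeled neurons (SLN); gaps are filled by a
beta-binomial regression of the labeling counts with a probit-linear mean
in the log ratio of the two areas' overall neuron densities.  Synapses of
each projection are then distributed over source populations (SLN plus
ordinal infragranular weights), target layers (ordinal anterograde
patterns, or SLN-category termination sets weighted by laminar thickness),
and target populations (morphology-based synapse-to-cell-body
conditionals), and finally redistributed so that a fixed fraction of each
projection's synapses lands on excitatory neurons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, logit, ndtr, ndtri

from cortimap.errors import (
    FitFailureError,
    InsufficientDataError,
    InvalidArgumentError,
    InvalidStateError,
)
from cortimap.synthetic import FRAC_LAYERS

#: SLN thresholds separating feedback / lateral / feedforward projections.
SLN_FEEDBACK_MAX = 0.35
SLN_FEEDFORWARD_MIN = 0.65

#: Termination-layer sets per SLN category.
TERMINATION_SETS = {
    "feedforward": ("4",),
    "feedback": ("1", "23", "5", "6"),
    "lateral": ("1", "23", "4", "5", "6"),
}


def sln_category(sln: float, lo: float = SLN_FEEDBACK_MAX, hi: float = SLN_FEEDFORWARD_MIN) -> str:
    """Classify a projection by its SLN value."""
    if sln > hi:
        return "feedforward"
    if sln < lo:
        return "feedback"
    return "lateral"


def ordinal_weight(alpha) -> float:
    """Relative synaptic mass of an ordinal tracing strength 0-3.

    Strengths 1/2/3 are interpreted as orders of magnitude (1:10:100);
    0 means absent.
    """
    alpha = int(alpha)
    if alpha == 0:
        return 0.0
    return 10.0 ** (alpha - 1)


# ---------------------------------------------------------------------------
# scheme mapping


def map_fln(
    raw: pd.DataFrame,
    overlap: pd.DataFrame,
    injection_targets: dict | None = None,
    source_weights: pd.Series | None = None,
) -> pd.DataFrame:
    """Map injection-wise FLN from the injected scheme to the model scheme.

    ``raw`` is long-format with columns ``injection, target, source, fln``
    where ``source`` names areas of the injected ("beta") scheme.  Repeat
    injections into the same model-scheme target are averaged
    arithmetically; the FLN of each beta source is then distributed over
    model-scheme areas proportionally to its overlap with them.

    ``overlap`` is row-stochastic over beta areas for each model area.  The
    distribution weight of beta area ``b`` to model area ``B`` is
    ``overlap[B][b] * w_B / sum_B' overlap[B'][b] * w_B'`` with ``w_B``
    the relative surface of ``B`` (``source_weights``; equal by default).

    Returns a target x source matrix in the model scheme (NaN where no
    injection covered the target).
    """
    if injection_targets is not None:
        unknown = set(raw["target"]) - set(injection_targets)
        if unknown:
            raise InvalidArgumentError(f"unmapped injection targets: {sorted(unknown)}")
        raw = raw.assign(target=raw["target"].map(injection_targets))
    if not np.allclose(overlap.sum(axis=1), 1.0, atol=1e-9):
        raise InvalidArgumentError("overlap matrix must be row-stochastic")
    w = (
        pd.Series(1.0, index=overlap.index)
        if source_weights is None
        else source_weights.reindex(overlap.index)
    )
    dist = overlap.mul(w, axis=0)
    dist = dist.div(dist.sum(axis=0), axis=1).fillna(0.0)  # column-normalized

    mean_fln = raw.groupby(["target", "source"])["fln"].mean().unstack(fill_value=0.0)
    mean_fln = mean_fln.reindex(columns=overlap.columns, fill_value=0.0)
    mapped = mean_fln @ dist.T  # (targets x beta) @ (beta x model)
    out = pd.DataFrame(np.nan, index=overlap.index, columns=overlap.index)
    out.loc[mapped.index, mapped.columns] = mapped.values
    return out


def map_sln(
    raw: pd.DataFrame,
    overlap: pd.DataFrame,
    injection_targets: dict | None = None,
) -> pd.DataFrame:
    """Map injection-wise SLN to the model scheme by FLN-weighted overlap.

    ``raw`` is long-format with columns ``injection, target, source, fln,
    sln`` (beta-scheme sources; rows without SLN are ignored).  The mean
    over repeat injections is taken per (target, beta source) before
    mapping.  The model-scheme value is
    ``SLN_AB = sum_b c[B][b] FLN_Ab SLN_Ab / sum_b c[B][b] FLN_Ab``;
    pairs with zero total weight stay missing.
    """
    if injection_targets is not None:
        raw = raw.assign(target=raw["target"].map(injection_targets))
    raw = raw.dropna(subset=["sln"])
    mean = raw.groupby(["target", "source"])[["fln", "sln"]].mean()
    fln = mean["fln"].unstack().reindex(columns=overlap.columns)
    sln = mean["sln"].unstack().reindex(columns=overlap.columns)
    out = pd.DataFrame(np.nan, index=overlap.index, columns=overlap.index)
    for tgt in fln.index:
        f = fln.loc[tgt].fillna(0.0).to_numpy()
        s = sln.loc[tgt].to_numpy()
        valid = ~np.isnan(s)
        for B in overlap.index:
            c = overlap.loc[B].to_numpy()
            wgt = c * f * valid
            tot = wgt.sum()
            if tot > 0:
                out.loc[tgt, B] = float(np.nansum(wgt * np.where(valid, s, 0.0)) / tot)
    return out


# ---------------------------------------------------------------------------
# exponential distance rule


@dataclass(frozen=True)
class EDRFit:
    """Exponential distance rule ``FLN = c * exp(-lambda * d)``."""

    c_scale: float
    lambda_decay: float
    p_value: float
    n_points: int
    r: float

    def predict(self, d):
        return self.c_scale * np.exp(-self.lambda_decay * np.asarray(d, dtype=float))

    def to_dict(self) -> dict:
        return {
            "c_scale": self.c_scale,
            "lambda_decay": self.lambda_decay,
            "p_value": self.p_value,
            "n_points": self.n_points,
            "r": self.r,
        }


def fit_edr(fln: pd.DataFrame, distances: pd.DataFrame, mask: pd.DataFrame | None = None) -> EDRFit:
    """Fit the exponential distance rule to positive FLN values.

    Ordinary least squares of ``log10(FLN)`` on distance over existing
    connections (positive FLN inside ``mask`` if given);
    ``lambda = -slope * ln(10)`` and ``c = 10**intercept``.
    """
    f = fln.to_numpy(dtype=float)
    d = distances.loc[fln.index, fln.columns].to_numpy(dtype=float)
    ok = np.isfinite(f) & (f > 0)
    if mask is not None:
        ok &= mask.loc[fln.index, fln.columns].to_numpy(dtype=bool)
    if ok.sum() < 3:
        raise InsufficientDataError("need >= 3 positive FLN values")
    x, y = d[ok], np.log10(f[ok])
    if np.allclose(y, y[0]):
        return EDRFit(10.0 ** y[0], 0.0, 1.0, int(ok.sum()), 0.0)
    res = stats.linregress(x, y)
    return EDRFit(
        c_scale=float(10.0**res.intercept),
        lambda_decay=float(-res.slope * np.log(10.0)),
        p_value=float(res.pvalue),
        n_points=int(ok.sum()),
        r=float(res.rvalue),
    )


def fill_and_normalize_fln(
    fln: pd.DataFrame,
    fit: EDRFit,
    binary: pd.DataFrame,
    FLN_i: float,
    subcortical: float,
    distances: pd.DataFrame,
    nonmodeled_distances: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Complete and normalize the FLN matrix.

    Existing connections (union of the binary matrix and positive measured
    FLN) without a measurement get the distance-rule estimate; absent
    connections stay exactly zero.  FLN toward non-modeled cortical source
    areas is estimated from their distances.  Each target row is scaled so
    that modeled plus non-modeled cortical FLN sums to
    ``1 - FLN_i - subcortical``.

    Returns ``(fln_modeled, fln_nonmodeled)``.
    """
    areas = list(fln.index)
    f = fln.to_numpy(dtype=float).copy()
    exists = (binary.loc[areas, areas].to_numpy(dtype=bool)) | (np.nan_to_num(f) > 0)
    np.fill_diagonal(exists, False)
    d = distances.loc[areas, areas].to_numpy(dtype=float)
    est = fit.predict(d)
    missing = exists & ~(np.isfinite(f) & (f > 0))
    f = np.where(missing, est, np.nan_to_num(f))
    f[~exists] = 0.0

    if nonmodeled_distances is not None and nonmodeled_distances.shape[1] > 0:
        ext = fit.predict(nonmodeled_distances.loc[areas].to_numpy(dtype=float))
    else:
        ext = np.zeros((len(areas), 0))
    target_total = 1.0 - FLN_i - subcortical
    row_tot = f.sum(axis=1) + ext.sum(axis=1)
    if np.any(row_tot <= 0):
        bad = [a for a, t in zip(areas, row_tot) if t <= 0]
        raise InvalidStateError(f"zero cortical FLN total for target areas {bad}")
    scale = target_total / row_tot
    f *= scale[:, None]
    ext *= scale[:, None]
    fln_out = pd.DataFrame(f, index=fln.index, columns=fln.columns)
    ext_out = (
        pd.DataFrame(ext, index=fln.index, columns=nonmodeled_distances.columns)
        if nonmodeled_distances is not None
        else None
    )
    return fln_out, ext_out


# ---------------------------------------------------------------------------
# beta-binomial SLN regression


@dataclass(frozen=True)
class SLNFit:
    """Beta-binomial regression of supragranular labeling on log density ratio."""

    a0: float
    a1: float
    phi: float
    link: str
    loglik: float
    se_a0: float
    se_a1: float
    se_phi: float
    n_points: int

    def to_dict(self) -> dict:
        return {
            "a0": self.a0,
            "a1": self.a1,
            "phi": self.phi,
            "link": self.link,
            "loglik": self.loglik,
            "se_a0": self.se_a0,
            "se_a1": self.se_a1,
            "se_phi": self.se_phi,
            "n_points": self.n_points,
        }


def _link_inv(eta, link):
    if link == "probit":
        return ndtr(eta)
    if link == "logit":
        return expit(eta)
    raise InvalidArgumentError(f"unknown link {link!r}")


def _link(p, link):
    if link == "probit":
        return ndtri(p)
    if link == "logit":
        return logit(p)
    raise InvalidArgumentError(f"unknown link {link!r}")


def _betabin_nll(theta, supra, n, ell, link):
    a0, a1, z = theta
    phi = expit(z)
    mu = np.clip(_link_inv(a0 + a1 * ell, link), 1e-10, 1.0 - 1e-10)
    alpha = mu * (1.0 - phi) / phi
    beta = (1.0 - mu) * (1.0 - phi) / phi
    ll = stats.betabinom.logpmf(supra, n, alpha, beta)
    if not np.all(np.isfinite(ll)):
        return 1e12
    return -float(ll.sum())


def _numerical_hessian(f, x, eps=1e-4):
    x = np.asarray(x, dtype=float)
    k = len(x)
    H = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = eps
            ej[j] = eps
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * eps * eps)
    return H


def fit_sln(
    supra: np.ndarray,
    total: np.ndarray,
    ell: np.ndarray,
    link: str = "probit",
) -> SLNFit:
    """Maximum-likelihood beta-binomial regression of labeling counts.

    The supragranular count of each projection is beta-binomial with mean
    ``g^{-1}(a0 + a1 * ell)`` (``g`` probit by default) and dispersion
    ``phi``; the fit maximizes the exact beta-binomial likelihood with
    L-BFGS-B from a fixed grid of starting points (deterministic given the
    data).  Standard errors come from the observed information (numerical
    Hessian at the optimum; delta method for ``phi``).
    """
    supra = np.asarray(supra, dtype=float)
    total = np.asarray(total, dtype=float)
    ell = np.asarray(ell, dtype=float)
    if len(supra) < 3:
        raise InsufficientDataError("need >= 3 pairs with counts")
    args = (supra, total, ell, link)

    starts = [
        (a0, a1, logit(phi))
        for a0 in (-1.0, 0.0, 1.0)
        for a1 in (-2.0, -0.5, 0.5)
        for phi in (0.05, 0.2, 0.5)
    ]
    best = None
    for x0 in starts:
        res = optimize.minimize(
            _betabin_nll, x0, args=args, method="L-BFGS-B",
            bounds=[(-20, 20), (-50, 50), (logit(1e-6), logit(1 - 1e-6))],
        )
        if best is None or (res.success and res.fun < best.fun):
            if res.success or best is None:
                best = res
    if best is None or not np.isfinite(best.fun):
        raise FitFailureError("beta-binomial fit did not converge from any start")

    a0, a1, z = best.x
    phi = float(expit(z))
    H = _numerical_hessian(lambda th: _betabin_nll(th, *args), best.x)
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
        se_phi = se[2] * phi * (1.0 - phi)  # delta method through the logit
    except np.linalg.LinAlgError:
        se = np.array([np.nan, np.nan, np.nan])
        se_phi = np.nan
    return SLNFit(
        a0=float(a0),
        a1=float(a1),
        phi=phi,
        link=link,
        loglik=-float(best.fun),
        se_a0=float(se[0]),
        se_a1=float(se[1]),
        se_phi=float(se_phi),
        n_points=len(supra),
    )


def predict_sln(fit: SLNFit, ell) -> np.ndarray:
    """Predicted SLN ``g^{-1}(a0 + a1 * ell)`` in (0, 1)."""
    return _link_inv(fit.a0 + fit.a1 * np.asarray(ell, dtype=float), fit.link)


# ---------------------------------------------------------------------------
# laminar disaggregation


def source_layer_fractions(
    sln: float,
    n_5e: float,
    n_6e: float,
    source_pattern: dict | None = None,
) -> dict:
    """Fractions X_j of a projection's synapses per source population.

    The supragranular share equals the SLN and is carried by 2/3E; the
    infragranular share ``1 - SLN`` is split between 5E and 6E either by
    ordinal tracing weights (``source_pattern`` maps layer -> 0..3; orders
    of magnitude) or, absent those, in proportion to the excitatory
    population sizes.  Layers excluded by the pattern (ordinal 0) carry
    zero mass; the result sums to one.  Cortico-cortical sources are
    exclusively excitatory.
    """
    w = {"23E": float(sln)}
    if source_pattern is not None and ("5" in source_pattern or "6" in source_pattern):
        w5 = ordinal_weight(source_pattern.get("5", 0))
        w6 = ordinal_weight(source_pattern.get("6", 0))
    else:
        w5, w6 = float(n_5e), float(n_6e)
    tot_infra = w5 + w6
    if tot_infra > 0:
        w["5E"] = (1.0 - sln) * w5 / tot_infra
        w["6E"] = (1.0 - sln) * w6 / tot_infra
    else:
        w["5E"] = w["6E"] = 0.0
    if source_pattern is not None and ordinal_weight(source_pattern.get("23", 1)) == 0:
        w["23E"] = 0.0
    total = sum(w.values())
    if total <= 0:
        raise InvalidStateError("all source layers excluded")
    return {k: v / total for k, v in w.items()}


def target_layer_fractions(
    sln: float,
    fracs: dict,
    target_pattern: dict | None = None,
    lo: float = SLN_FEEDBACK_MAX,
    hi: float = SLN_FEEDFORWARD_MIN,
) -> dict:
    """Fractions Y_v of a projection's synapses per target layer.

    An ordinal anterograde termination pattern, when available, sets the
    weights directly (orders of magnitude).  Otherwise the SLN category
    selects the termination set ({4} feedforward, {1,2/3,5,6} feedback,
    all layers lateral) and the mass is distributed in proportion to the
    layers' relative thickness ``fracs``.  Layers with zero thickness
    (e.g. L4 of agranular areas) are dropped; if the set empties, all
    layers with thickness are used as fallback.
    """
    if target_pattern is not None:
        w = {v: ordinal_weight(target_pattern.get(v, 0)) for v in FRAC_LAYERS}
    else:
        layers = TERMINATION_SETS[sln_category(sln, lo, hi)]
        w = {v: (fracs.get(v, 0.0) if v in layers else 0.0) for v in FRAC_LAYERS}
    # layers absent from the area (zero thickness, e.g. L4 of agranular
    # areas) cannot host synapses regardless of the reported pattern
    w = {v: (x if fracs.get(v, 0.0) > 0 else 0.0) for v, x in w.items()}
    if sum(w.values()) <= 0:
        # pattern has no thickness in this area (e.g. agranular target of a
        # feedforward projection): spread over existing layers
        w = {v: fracs.get(v, 0.0) for v in FRAC_LAYERS}
    total = sum(w.values())
    if total <= 0:
        raise InvalidStateError("empty termination pattern")
    return {v: x / total for v, x in w.items()}


# ---------------------------------------------------------------------------
# synapse -> cell body mapping


def synapse_to_cellbody(
    celltypes: pd.DataFrame, macaque_occurrence: dict | pd.Series
) -> pd.DataFrame:
    """Conditional probabilities P(population | cortico-cortical synapse in v).

    Cell-type occurrences are rescaled so that the types belonging to each
    population jointly occur with that population's share in the reference
    area (``macaque_occurrence``, population -> fraction of neurons).  The
    joint probability of a cortico-cortical synapse in layer ``v`` on cell
    type ``c`` is proportional to ``P(cc | c, v) * Nsyn(v, c) * P(c)``;
    conditioning on the layer and summing the types of each population
    gives the returned populations x layers matrix, each column summing to
    one.  Layers with zero cortico-cortical synapse mass yield NaN columns.
    """
    ct = celltypes.copy()
    occ = pd.Series(macaque_occurrence, dtype=float)
    pop_sum = ct.groupby("population")["occurrence"].transform("sum")
    ct["occurrence"] = ct["occurrence"] / pop_sum * ct["population"].map(occ)
    layers = list(FRAC_LAYERS)
    joint = np.zeros((len(ct), len(layers)))
    for k, v in enumerate(layers):
        joint[:, k] = ct[f"pcc_{v}"] * ct[f"nsyn_{v}"] * ct["occurrence"]
    total = joint.sum()
    if total <= 0:
        raise InvalidStateError("cell-type table carries no cortico-cortical synapses")
    joint /= total
    layer_mass = joint.sum(axis=0)
    pops = sorted(ct["population"].unique())
    out = pd.DataFrame(np.nan, index=pops, columns=layers)
    for k, v in enumerate(layers):
        if layer_mass[k] <= 0:
            continue  # conditional undefined for this layer
        cond = joint[:, k] / layer_mass[k]
        out[v] = pd.Series(cond, index=ct.index).groupby(ct["population"]).sum().reindex(pops)
    return out


def redistribute_ei(mass: pd.Series, excitatory_fraction: float) -> pd.Series:
    """Rescale per-population synapse mass to a fixed excitatory share.

    Population labels end in 'E' or 'I'.  The projection total is
    conserved exactly.  If one of the two pools carries no mass the input
    is returned unchanged (no mass can be created in an empty pool).
    """
    is_e = mass.index.str.endswith("E")
    tot = float(mass.sum())
    e_mass = float(mass[is_e].sum())
    i_mass = tot - e_mass
    if tot <= 0:
        raise InvalidStateError("projection with zero synapse mass")
    if e_mass <= 0:
        raise InvalidStateError("projection with zero excitatory candidates")
    if i_mass <= 0:
        return mass
    out = mass.copy()
    out[is_e] *= excitatory_fraction * tot / e_mass
    out[~is_e] *= (1.0 - excitatory_fraction) * tot / i_mass
    return out


def assemble_type_iii(
    nsyn_cc: pd.DataFrame,
    sln: pd.DataFrame,
    arch: pd.DataFrame,
    pops,
    p_cond: pd.DataFrame,
    patterns: pd.DataFrame | None = None,
    excitatory_target_fraction: float = 0.93,
    redistribute: str = "all",
    sln_lo: float = SLN_FEEDBACK_MAX,
    sln_hi: float = SLN_FEEDFORWARD_MIN,
) -> pd.DataFrame:
    """Population-resolved cortico-cortical synapse counts.

    For every ordered area pair with ``nsyn_cc[A][B] > 0`` (total type-III
    synapses from source area B into target area A), synapses factorize as
    ``N(iA <- jB) = N_cc(A<-B) * X_j * sum_v Y_v * P(i | s_cc in v)``,
    then get redistributed so that ``excitatory_target_fraction`` of the
    projection lands on excitatory populations (``redistribute`` is
    ``"all"`` per projection, or ``"feedback"`` for feedback-category
    projections only).  Layer-4 populations of agranular target areas
    receive zero, their mass reassigned proportionally.

    Returns a long DataFrame with columns ``target_area, target_pop,
    source_area, source_pop, synapses``.
    """
    pat_src: dict = {}
    pat_tgt: dict = {}
    if patterns is not None and len(patterns):
        for (tgt, src, side), grp in patterns.groupby(["target", "source", "side"]):
            d = dict(zip(grp["layer"].astype(str), grp["ordinal"]))
            (pat_src if side == "source" else pat_tgt)[(tgt, src)] = d

    pop_df = pops.df
    records = []
    for A in nsyn_cc.index:
        agranular = arch.at[A, "arch_type"] == 2
        fracs_A = {v: float(arch.at[A, f"frac_{v}"]) for v in FRAC_LAYERS}
        target_pops = pop_df.index[pop_df["area"] == A]
        tp_labels = [p.split("-")[1] for p in target_pops]
        for B in nsyn_cc.columns:
            if A == B:
                continue
            n_cc = nsyn_cc.at[A, B]
            if not np.isfinite(n_cc) or n_cc <= 0:
                continue
            s = sln.at[A, B]
            if not np.isfinite(s):
                raise InvalidStateError(f"missing SLN for projection {A} <- {B}")
            n5e = pop_df["N"].get(f"{B}-5E", 0.0)
            n6e = pop_df["N"].get(f"{B}-6E", 0.0)
            X = source_layer_fractions(s, n5e, n6e, pat_src.get((A, B)))
            Y = target_layer_fractions(
                s, fracs_A, pat_tgt.get((A, B)), lo=sln_lo, hi=sln_hi
            )
            # per-target-population mass from layer routing
            mass = np.zeros(len(tp_labels))
            for v, yv in Y.items():
                if yv <= 0:
                    continue
                col = p_cond[v]
                for k, lab in enumerate(tp_labels):
                    mass[k] += yv * float(col.get(lab, 0.0))
            mass = pd.Series(mass, index=[p.split("-")[1] for p in target_pops])
            if agranular:
                mass[mass.index.str.startswith("4")] = 0.0
            tot = mass.sum()
            if tot <= 0:
                raise InvalidStateError(f"no target populations for {A} <- {B}")
            mass /= tot
            apply_z = redistribute == "all" or (
                redistribute == "feedback"
                and sln_category(s, sln_lo, sln_hi) == "feedback"
            )
            if apply_z:
                mass = redistribute_ei(mass, excitatory_target_fraction)
            for j, xj in X.items():
                if xj <= 0:
                    continue
                src_pop = f"{B}-{j}"
                if src_pop not in pop_df.index:
                    continue  # agranular source areas lack no E source pops here
                for pop_label, m in mass.items():
                    if m <= 0:
                        continue
                    records.append(
                        (A, f"{A}-{pop_label}", B, src_pop, n_cc * xj * m)
                    )
    return pd.DataFrame(
        records,
        columns=["target_area", "target_pop", "source_area", "source_pop", "synapses"],
    )
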