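"""Area-specific scaling of the local microcircuit template.

The within-area connectivity of every area derives from a single 8x8
template of pairwise connection probabilities for a 1 mm^2 patch (the
"canonical microcircuit").  The underlying distance-dependent connection
probability is a Gaussian of width ``sigma``; averaging it over neuron
positions in a disk of radius R links patch size to mean connection
probability.  Adapting the template to an area preserves the relative
indegrees between population pairs and rescales all of them by one
area-specific conversion factor ``c_A`` chosen so that a fixed fraction
(the intrinsic labeling fraction ``FLN_i``) of the area's total synapses,
set by a constant synapse volume density, is intra-areal.

Synapses inside the modeled disk of radius ``R0`` (surface 1 mm^2) are
"type I"; the remaining intra-areal synapses up to the area's full surface
are "type II" and enter the external-input budget.  All synapse counts are
real-valued expectations.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import integrate

from cortimap.errors import InvalidArgumentError, InvalidStateError
from cortimap.synthetic import POPULATIONS

#: Radius (mm) of a disk with 1 mm^2 surface.
R0_MM = float(np.sqrt(1.0 / np.pi))


@dataclass(frozen=True)
class LocalTemplate:
    """Local microcircuit template (probabilities C[target][source])."""

    populations: tuple
    C: np.ndarray
    N_prime: np.ndarray
    sigma: float
    C0: float
    Cbar_center_R0: float

    def __post_init__(self):
        if self.sigma <= 0:
            raise InvalidArgumentError("sigma must be > 0")
        if np.any(self.C < 0) or np.any(self.C > 1):
            raise InvalidArgumentError("template probabilities must lie in [0, 1]")


def load_local_template() -> LocalTemplate:
    """Load the packaged microcircuit template."""
    with resources.files("cortimap.data").joinpath("local_template.json").open() as fh:
        raw = json.load(fh)
    return LocalTemplate(
        populations=tuple(raw["populations"]),
        C=np.asarray(raw["connection_probabilities"], dtype=float),
        N_prime=np.asarray(raw["population_sizes"], dtype=float),
        sigma=float(raw["sigma_mm"]),
        C0=float(raw["C0"]),
        Cbar_center_R0=float(raw["Cbar_center_R0"]),
    )


def _disk_distance_pdf(t: np.ndarray, R: float) -> np.ndarray:
    """Density of the distance between two independent uniform points in a
    disk of radius R (disk line-picking), supported on [0, 2R]."""
    u = np.clip(t / (2.0 * R), 0.0, 1.0)
    return (4.0 * t / (np.pi * R * R)) * (np.arccos(u) - u * np.sqrt(1.0 - u * u))


def disk_average_gaussian(C0: float, sigma: float, R: float, mode: str = "center") -> float:
    """Disk-averaged Gaussian connection probability.

    ``mode="center"`` fixes one neuron at the disk center and averages the
    Gaussian profile ``C0 * exp(-r^2 / 2 sigma^2)`` over the position of
    the other neuron, which has the closed form
    ``C0 * (2 sigma^2 / R^2) * (1 - exp(-R^2 / 2 sigma^2))``.
    ``mode="pairwise"`` averages over independent uniform positions of both
    neurons, evaluated by deterministic quadrature over the disk
    line-picking density (relative tolerance 1e-6).  The pairwise average
    is always below the centered one.
    """
    if R <= 0 or sigma <= 0:
        raise InvalidArgumentError("R and sigma must be > 0")
    if not 0.0 <= C0 <= 1.0:
        raise InvalidArgumentError("C0 must lie in [0, 1]")
    if mode == "center":
        x = R * R / (2.0 * sigma * sigma)
        return C0 * (1.0 - np.exp(-x)) / x
    if mode == "pairwise":
        val, _ = integrate.quad(
            lambda t: _disk_distance_pdf(np.asarray(t), R)
            * np.exp(-t * t / (2.0 * sigma * sigma)),
            0.0,
            2.0 * R,
            epsrel=1e-9,
            epsabs=0.0,
            limit=200,
        )
        return C0 * float(val)
    raise InvalidArgumentError(f"unknown mode {mode!r}")


def rescale_template(template: LocalTemplate, R: float) -> np.ndarray:
    """Template connection probabilities for a disk of radius R.

    Every template probability is multiplied by the ratio of the
    pairwise-mode disk average at R to the template's centered average at
    R0, which converts the template calibration (one neuron fixed at the
    center of the 1 mm^2 disk) to the all-pairs average at the requested
    size.  Values are clipped to [0, 1] with a warning if clipping occurs.
    """
    cbar = disk_average_gaussian(template.C0, template.sigma, R, mode="pairwise")
    ratio = cbar / template.Cbar_center_R0
    if not np.isfinite(ratio):
        raise InvalidStateError("nonfinite rescaling ratio")
    C = template.C * ratio
    if np.any(C > 1.0):
        warnings.warn("rescaled connection probabilities clipped to [0, 1]")
        C = np.clip(C, 0.0, 1.0)
    return C


def probability_to_synapses(C, N_source, N_target):
    """Expected synapse count reproducing connection probability ``C``.

    Inverts the at-least-one-synapse relation
    ``C = 1 - (1 - 1/(N_source N_target))**N_syn`` to
    ``N_syn = log(1 - C) / log(1 - 1/(N_source N_target))``; vectorized.
    """
    C = np.asarray(C, dtype=float)
    Ns = np.asarray(N_source, dtype=float)
    Nt = np.asarray(N_target, dtype=float)
    if np.any(C < 0):
        raise InvalidArgumentError("C must be >= 0")
    if np.any(C >= 1):
        raise InvalidArgumentError("C = 1 requires infinitely many synapses")
    if np.any((Ns * Nt < 2) & (C > 0)):
        raise InvalidArgumentError("need N_source * N_target >= 2")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.log1p(-C) / np.log1p(-1.0 / (Ns * Nt))
    out = np.where(C == 0, 0.0, out)
    return out if out.ndim else float(out)


def template_indegrees(template: LocalTemplate, R: float) -> np.ndarray:
    """Indegrees K'[i][j] of the template scaled to a disk of radius R.

    The template population sizes grow with the disk surface,
    ``N'(R) = N'(R0) * R^2 / R0^2``; probabilities follow
    :func:`rescale_template`; indegrees are synapse counts per target
    neuron.
    """
    C = rescale_template(template, R)
    N = template.N_prime * (R / R0_MM) ** 2
    nsyn = probability_to_synapses(C, N[None, :], N[:, None])
    return nsyn / N[:, None]


def conversion_factor(
    D_total: float,
    K_prime_R: np.ndarray,
    K_prime_Rfull: np.ndarray,
    N: np.ndarray,
    rho_syn: float,
    FLN_i: float,
    R: float,
) -> float:
    """Area-specific indegree conversion factor ``c_A(R)``.

    ``c_A(R) = N_syn_tot(R) / sum_ij N_i(R) K'_ij(R) * FLN_i *
    <K'_ij(R) / K'_ij(R_full)>_ij`` with ``N_syn_tot(R) = rho_syn * pi R^2
    * D_total`` and the unweighted mean taken over population pairs with
    nonzero template indegree.  Scaling all local indegrees by ``c_A``
    makes the intra-areal synapse count equal the intrinsic share
    ``FLN_i`` of the area's total synapses (at full radius).
    """
    K_prime_R = np.asarray(K_prime_R, dtype=float)
    K_prime_Rfull = np.asarray(K_prime_Rfull, dtype=float)
    N = np.asarray(N, dtype=float)
    nz = K_prime_Rfull > 0
    if not nz.any():
        raise InvalidStateError("template has no nonzero indegrees")
    nsyn_tot = rho_syn * np.pi * R * R * D_total
    denom = float(np.sum(N[:, None] * K_prime_R))
    if denom <= 0:
        raise InvalidStateError("zero denominator in conversion factor")
    mean_ratio = float(np.mean(K_prime_R[nz] / K_prime_Rfull[nz]))
    return nsyn_tot / denom * FLN_i * mean_ratio


@dataclass
class LocalSynapses:
    """Type-I synapse counts of one area plus its type-II total."""

    area: str
    populations: tuple
    nsyn_I: np.ndarray  # [target][source]
    nsyn_II_total: float
    c_A: float


def local_synapses(
    area: str,
    arch_row: pd.Series,
    N_area: np.ndarray,
    pop_names: tuple,
    template: LocalTemplate,
    rho_syn: float,
    FLN_i: float,
    R: float = R0_MM,
) -> LocalSynapses:
    """Type-I synapse matrix and type-II total for one area.

    ``N_area`` holds the area's population sizes at radius ``R`` in the
    order of ``pop_names`` (a subset of the template populations; agranular
    areas lack the layer-4 entries).  Type-I counts follow
    ``N^syn,I_ij = c_A(R) K'_ij(R) N_i(R)``.  The type-II total is the
    remaining intrinsic input onto the modeled patch: evaluating the local
    indegrees at the area's full radius (where the template's Gaussian
    tails are fully sampled) and summing over the patch's neurons gives the
    intrinsic budget ``rho_syn * pi R^2 * D * FLN_i``, from which the
    type-I total is subtracted.
    """
    R_full = float(np.sqrt(arch_row["surface"] / np.pi))
    K_R = template_indegrees(template, R)
    K_full = template_indegrees(template, R_full)
    # restrict the template to the populations present in this area
    idx = [template.populations.index(p) for p in pop_names]
    K_R = K_R[np.ix_(idx, idx)]
    K_full = K_full[np.ix_(idx, idx)]
    c_A = conversion_factor(
        float(arch_row["thickness_total"]), K_R, K_full, N_area, rho_syn, FLN_i, R
    )
    nsyn_I = c_A * K_R * N_area[:, None]
    intrinsic_total = rho_syn * np.pi * R * R * arch_row["thickness_total"] * FLN_i
    nsyn_II = intrinsic_total - float(nsyn_I.sum())
    if nsyn_II < 0:
        raise InvalidStateError(f"negative type-II synapse total for area {area}")
    return LocalSynapses(
        area=area,
        populations=tuple(pop_names),
        nsyn_I=nsyn_I,
        nsyn_II_total=nsyn_II,
        c_A=c_A,
    )
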