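"""Completion of per-area architecture and population sizes.

An architecture table holds, per cortical area, the ordinal architectural
type (2-8), overall and laminar neuron volume densities (neurons/mm^3),
total thickness (mm), relative laminar thicknesses and surface area (mm^2).
Measured coverage is incomplete; three completion steps fill the gaps:

1. missing densities are replaced by the mean over measured areas of the
   same architectural type;
2. missing total thicknesses are predicted from an ordinary least-squares
   fit of thickness on log10 overall density;
3. missing relative laminar thicknesses are predicted from a linear fit
   (layer 4, which thickens with density) or the measured mean (other
   layers), and each completed row is renormalized to sum to one.

Population sizes then follow from density x volume, split into excitatory
and inhibitory pools with layer-specific excitatory fractions.  Agranular
(type 2) areas have no layer-4 populations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from cortimap.errors import (
    CompletionError,
    InsufficientDataError,
    InvalidArgumentError,
    InvalidStateError,
)
from cortimap.synthetic import LAYERS, FRAC_LAYERS

#: Default excitatory fractions per layer (2/3, 4, 5, 6).
DEFAULT_GAMMA = {"23": 0.78, "4": 0.80, "5": 0.82, "6": 0.83}

_DENSITY_COLS = ["rho_total", "rho_23", "rho_4", "rho_5", "rho_6"]
_FRAC_COLS = [f"frac_{v}" for v in FRAC_LAYERS]


@dataclass(frozen=True)
class LinearFit:
    """Ordinary least-squares fit of y on x with correlation statistics."""

    slope: float
    intercept: float
    r: float
    p: float
    n: int

    def predict(self, x):
        return self.intercept + self.slope * np.asarray(x, dtype=float)

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r": self.r,
            "p": self.p,
            "n": self.n,
        }


def _ols(x: np.ndarray, y: np.ndarray) -> LinearFit:
    if len(x) < 3:
        raise InsufficientDataError(f"need >= 3 points for a fit, got {len(x)}")
    if np.allclose(y, y[0]):
        # degenerate: constant response; slope 0, correlation undefined -> 0
        return LinearFit(0.0, float(y[0]), 0.0, 1.0, len(x))
    res = stats.linregress(x, y)
    return LinearFit(
        float(res.slope), float(res.intercept), float(res.rvalue), float(res.pvalue), len(x)
    )


def fill_densities_by_type(arch: pd.DataFrame) -> pd.DataFrame:
    """Fill missing overall and laminar densities by architectural-type means.

    Every architectural type occurring among areas with missing densities
    must have at least one measured representative; otherwise a
    :class:`CompletionError` naming the type is raised.  Measured values and
    their provenance flags are left untouched.
    """
    arch = arch.copy()
    measured = arch["src_density"] == "measured"
    missing = arch["rho_total"].isna()
    for t in sorted(arch.loc[missing, "arch_type"].unique()):
        if not (measured & (arch["arch_type"] == t)).any():
            raise CompletionError(f"no measured densities for architectural type {t}")
    type_means = arch.loc[measured].groupby("arch_type")[_DENSITY_COLS].mean()
    for area in arch.index[missing]:
        t = arch.at[area, "arch_type"]
        fill = type_means.loc[t]
        for col in _DENSITY_COLS:
            if pd.isna(arch.at[area, col]):
                arch.at[area, col] = fill[col]
        arch.at[area, "src_density"] = "filled"
        if t == 2:
            arch.at[area, "rho_4"] = 0.0
    return arch


def fit_thickness(arch: pd.DataFrame, log_base: float = 10.0):
    """Fit total thickness against logarithmized overall density; fill gaps.

    Returns ``(fit, completed_table)`` where ``fit`` is the OLS fit of
    ``thickness_total`` on ``log(rho_total)`` over areas with both measured.
    Missing total thicknesses are predicted from the fit.  The logarithm
    base is configurable; base 10 by default (fit quality is
    base-invariant, slope units are not).
    """
    arch = arch.copy()
    measured = (arch["src_thickness"] == "measured") & arch["thickness_total"].notna()
    x = np.log(arch.loc[measured, "rho_total"].to_numpy(dtype=float)) / np.log(log_base)
    y = arch.loc[measured, "thickness_total"].to_numpy(dtype=float)
    fit = _ols(x, y)
    missing = arch["thickness_total"].isna()
    if missing.any():
        if arch.loc[missing, "rho_total"].isna().any():
            raise InvalidStateError("fill densities before predicting thicknesses")
        xm = np.log(arch.loc[missing, "rho_total"].to_numpy(dtype=float)) / np.log(log_base)
        arch.loc[missing, "thickness_total"] = fit.predict(xm)
    return fit, arch


def fit_laminar_fractions(arch: pd.DataFrame, log_base: float = 10.0) -> pd.DataFrame:
    """Complete relative laminar thicknesses.

    The relative L4 thickness of areas with missing laminar data is
    predicted from a linear fit on logarithmized overall density (the one
    laminar fraction with a clear density trend), floored at zero.
    Agranular (type 2) areas are excluded from the fit and keep an exact
    zero.  Other layers are filled with the measured mean.  Every completed
    row is renormalized so its fractions sum to one.
    """
    arch = arch.copy()
    measured = (arch["src_thickness"] == "measured") & arch["frac_23"].notna()
    fit_rows = measured & (arch["arch_type"] != 2)
    if fit_rows.sum() < 3:
        raise InsufficientDataError("need >= 3 measured laminar rows")
    x = np.log(arch.loc[fit_rows, "rho_total"].to_numpy(dtype=float)) / np.log(log_base)
    fit4 = _ols(x, arch.loc[fit_rows, "frac_4"].to_numpy(dtype=float))
    layer_means = arch.loc[measured, _FRAC_COLS].mean()

    missing = arch["frac_23"].isna()
    for area in arch.index[missing]:
        if arch.at[area, "arch_type"] == 2:
            arch.at[area, "frac_4"] = 0.0
        else:
            lx = np.log(arch.at[area, "rho_total"]) / np.log(log_base)
            arch.at[area, "frac_4"] = max(0.0, float(fit4.predict(lx)))
        for col in ["frac_1", "frac_23", "frac_5", "frac_6"]:
            arch.at[area, col] = layer_means[col]
        arch.at[area, "src_thickness"] = "filled"
    # renormalize every row (no-op for rows already summing to 1)
    total = arch[_FRAC_COLS].sum(axis=1)
    arch[_FRAC_COLS] = arch[_FRAC_COLS].div(total, axis=0)
    arch.loc[arch["arch_type"] == 2, "frac_4"] = 0.0
    return arch


class PopulationGrid:
    """Neuron counts for the (area, layer, E/I) populations of a network.

    Populations are ordered by area (table order), then layer (2/3, 4, 5,
    6), then E before I; layer-4 populations of agranular areas are absent.
    ``df`` has columns ``area, layer, ei, N`` and index ``population``
    (e.g. ``"A01-4E"``).
    """

    def __init__(self, df: pd.DataFrame, gamma: dict, radius: float):
        self.df = df
        self.gamma = dict(gamma)
        self.radius = float(radius)

    def __len__(self):
        return len(self.df)

    @property
    def populations(self) -> list[str]:
        return list(self.df.index)

    @property
    def sizes(self) -> np.ndarray:
        return self.df["N"].to_numpy(dtype=float)

    def area_populations(self, area: str) -> list[str]:
        return list(self.df.index[self.df["area"] == area])

    def area_total(self, area: str) -> float:
        return float(self.df.loc[self.df["area"] == area, "N"].sum())

    @property
    def areas(self) -> list[str]:
        return list(dict.fromkeys(self.df["area"]))


def population_sizes(
    arch: pd.DataFrame, R: float, gamma: dict | None = None
) -> PopulationGrid:
    """Compute population sizes ``N = rho_lam * S(R) * D_lam * gamma``.

    ``S(R) = pi R^2`` is the modeled disk surface, ``D_lam`` the laminar
    thickness (total thickness times relative fraction).  The excitatory
    population of a layer receives a fraction ``gamma[layer]`` of the
    layer's neurons, the inhibitory one the rest.  The table must be fully
    completed; agranular areas contribute no layer-4 populations.
    """
    if R <= 0:
        raise InvalidArgumentError("R must be > 0")
    gamma = dict(DEFAULT_GAMMA if gamma is None else gamma)
    needed = _DENSITY_COLS + _FRAC_COLS + ["thickness_total"]
    if arch[needed].isna().any().any():
        raise InvalidStateError("architecture table is not fully completed")
    S = np.pi * R**2
    rows = []
    for area, row in arch.iterrows():
        agranular = row["arch_type"] == 2
        for layer in LAYERS:
            if layer == "4" and agranular:
                continue
            n_layer = row[f"rho_{layer}"] * S * row["thickness_total"] * row[f"frac_{layer}"]
            g = gamma[layer]
            for ei, frac in (("E", g), ("I", 1.0 - g)):
                rows.append(
                    {
                        "population": f"{area}-{layer}{ei}",
                        "area": area,
                        "layer": layer,
                        "ei": ei,
                        "N": n_layer * frac,
                    }
                )
    df = pd.DataFrame(rows).set_index("population")
    return PopulationGrid(df, gamma, R)
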