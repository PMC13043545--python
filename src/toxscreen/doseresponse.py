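"""Four-parameter logistic (4PL) viability fitting and fractional
inhibitory concentrations.

v(c) = bottom + (top - bottom) / (1 + (c / ic50)^hill)

Viabilities are vehicle-normalized (divided by the mean 0-µM response)
before fitting. IC_f uses the relative, asymptote-anchored definition:
the concentration where the response has dropped by a fraction f of the
fitted top-bottom range, which has the closed form
c = ic50 * (f / (1 - f))^(1/hill).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = ["FourPLFit", "four_pl", "fit_4pl", "ic_fraction", "read_viability_table"]


@dataclass
class FourPLFit:
    top: float
    bottom: float
    ic50: float
    hill: float
    rss: float
    converged: bool


def four_pl(c, top: float, bottom: float, ic50: float, hill: float):
    """Evaluate the 4PL curve; c = 0 maps to the zero-dose asymptote."""
    c = np.asarray(c, dtype=float)
    with np.errstate(divide="ignore", over="ignore"):
        t = np.where(c > 0, (np.maximum(c, 1e-300) / ic50) ** hill,
                     0.0 if hill > 0 else np.inf)
    return bottom + (top - bottom) / (1.0 + t)


def read_viability_table(path: str | Path) -> pd.DataFrame:
    """Read a long-format viability TSV (concentration_uM, viability)."""
    df = pd.read_csv(path, sep="\t")
    if not {"concentration_uM", "viability"} <= set(df.columns):
        raise ValueError(f"{path}: needs concentration_uM and viability columns")
    return df


def fit_4pl(table: pd.DataFrame, normalize: bool = True) -> FourPLFit:
    """Nonlinear least-squares 4PL fit of a viability table.

    Initialization: top = mean vehicle viability, bottom = minimum of the
    per-concentration means, ic50 = geometric mean of positive tested
    concentrations, hill = 1. The bottom asymptote is constrained to be
    non-negative (a viability fraction cannot drop below zero), which
    keeps fits identified when the tested range does not reach the lower
    plateau. ``converged`` is false when the optimizer fails or the fitted
    curve is not a decreasing response (hill <= 0 or top <= bottom).
    """
    conc = table["concentration_uM"].to_numpy(dtype=float)
    viab = table["viability"].to_numpy(dtype=float)
    if len(np.unique(conc)) < 4:
        raise ValueError("4PL fit needs at least 4 distinct concentrations")
    if not (conc == 0).any():
        raise ValueError("a vehicle (0 µM) condition is required")
    if normalize:
        vehicle = viab[conc == 0].mean()
        if vehicle <= 0:
            raise ValueError("mean vehicle viability must be positive")
        viab = viab / vehicle

    means = pd.Series(viab).groupby(pd.Series(conc)).mean()
    top0 = float(means.loc[0.0])
    bottom0 = float(means.min())
    pos = np.unique(conc[conc > 0])
    ic0 = float(np.exp(np.log(pos).mean()))
    p0 = [top0, max(bottom0, 1e-6), ic0, 1.0]
    vmax = float(viab.max())
    bounds = (
        [0.0, 0.0, pos.min() / 1e3, -20.0],
        [2 * vmax + 1e-6, 2 * vmax + 1e-6, pos.max() * 1e3, 20.0],
    )
    try:
        popt, _ = curve_fit(
            four_pl, conc, viab, p0=p0, bounds=bounds,
            xtol=1e-8, ftol=1e-8, maxfev=20_000,
        )
        ok = True
    except RuntimeError:
        popt = np.asarray(p0, dtype=float)
        ok = False
    top, bottom, ic50, hill = (float(v) for v in popt)
    rss = float(((four_pl(conc, *popt) - viab) ** 2).sum())
    converged = ok and hill > 0 and top > bottom
    return FourPLFit(top=top, bottom=bottom, ic50=ic50, hill=hill,
                     rss=rss, converged=converged)


def ic_fraction(fit: FourPLFit, fraction: float) -> float:
    """Concentration reducing the response by ``fraction`` of the fitted
    range (relative IC definition); fraction 0.5 returns ic50 exactly."""
    if not fit.converged:
        raise ValueError("cannot compute an IC from a non-converged fit")
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    return float(fit.ic50 * (fraction / (1.0 - fraction)) ** (1.0 / fit.hill))
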