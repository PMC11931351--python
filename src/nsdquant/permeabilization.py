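"""Digitonin-release curve fitting and fractionation design.

Digitonin permeabilizes the cholesterol-rich plasma membrane selectively,
releasing cytoplasmic contents into the supernatant while organelles stay
intact at low doses.  Plotting the normalized supernatant amount against
digitonin concentration gives a sigmoidal release curve,

    y(x) = a + b / (1 + exp((c - x) / d)),

with floor ``a``, span ``b``, midpoint ``c`` (µg/mL at half release) and
steepness ``d``.  Combined with literature estimates of the relative
metabolite content of Golgi and cytoplasm (concentration x volume), the
curve is inverted at the cytoplasmic share to find the digitonin
concentration at which the supernatant captures exactly the cytoplasmic
pool, and the result is rounded *down* onto the available concentration
grid to protect the organelle fraction from cross-contamination.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "SigmoidFit",
    "CompartmentModel",
    "CompartmentShares",
    "DesignPoint",
    "DEFAULT_COMPARTMENT_MODEL",
    "normalize_series",
    "pooled_release_curve",
    "fit_release_sigmoid",
    "eval_sigmoid",
    "invert_sigmoid",
    "compartment_distribution",
    "select_operating_digitonin",
]


@dataclass(frozen=True)
class SigmoidFit:
    """Four-parameter logistic release curve plus goodness of fit."""

    a: float          # floor (normalized fraction)
    b: float          # span
    c: float          # midpoint, µg/mL digitonin
    d: float          # steepness, µg/mL
    r_squared: float
    n_points: int

    def __post_init__(self) -> None:
        if self.b == 0:
            raise ValueError("degenerate fit: zero span")
        if self.d <= 0:
            raise ValueError("steepness must be positive")
        if self.r_squared > 1 + 1e-12:
            raise ValueError("r_squared cannot exceed 1")


def _sigmoid(x, a, b, c, d):
    with np.errstate(over="ignore"):  # exp overflow saturates to the floor
        return a + b / (1.0 + np.exp((c - x) / d))


def eval_sigmoid(fit: SigmoidFit, x):
    """Evaluate the release curve; y(c) = a + b/2 exactly."""
    out = _sigmoid(np.asarray(x, dtype=float), fit.a, fit.b, fit.c, fit.d)
    return float(out) if np.ndim(x) == 0 else out


def invert_sigmoid(fit: SigmoidFit, y: float) -> float:
    """Digitonin concentration at which the curve passes through y.

    Closed form x = c - d * ln(b / (y - a) - 1), defined on the open range
    (a, a + b); outside it the curve never attains y.
    """
    lo, hi = min(fit.a, fit.a + fit.b), max(fit.a, fit.a + fit.b)
    if not lo < y < hi:
        raise ValueError(
            f"y={y:g} outside the attainable open range ({lo:g}, {hi:g})"
        )
    return fit.c - fit.d * math.log(fit.b / (y - fit.a) - 1.0)


def normalize_series(series: pd.DataFrame) -> pd.DataFrame:
    """Normalize a titration so each analyte's maximum total equals 1.

    For every analyte, all amounts are divided by the maximum over the
    digitonin gradient of the replicate-mean total (CP + organelle)
    amount — the 'maximum cellular concentration'.  Idempotent on data
    already normalized this way.
    """
    out = series.copy()
    out["amount_amol_per_cell"] = out["amount_amol_per_cell"].astype(float)
    for analyte, grp in series.groupby("analyte"):
        totals = (
            grp.groupby(["digitonin_ug_per_ml", "replicate"])["amount_amol_per_cell"]
            .sum()
            .groupby("digitonin_ug_per_ml")
            .mean()
        )
        denom = float(totals.max())
        if denom <= 0:
            raise ValueError(f"{analyte}: all-zero titration, cannot normalize")
        mask = out["analyte"] == analyte
        out.loc[mask, "amount_amol_per_cell"] = (
            out.loc[mask, "amount_amol_per_cell"] / denom
        )
    return out


def pooled_release_curve(
    normalized: pd.DataFrame, fraction: str = "CP"
) -> tuple[np.ndarray, np.ndarray]:
    """Average normalized release share across analytes and replicates.

    Mirrors fitting the mean curve of all panel analytes: for each
    digitonin level, the normalized amounts of the requested fraction are
    averaged over analytes and replicates.
    """
    sel = normalized[normalized["fraction"] == fraction]
    if sel.empty:
        raise ValueError(f"no rows for fraction {fraction!r}")
    mean = sel.groupby("digitonin_ug_per_ml")["amount_amol_per_cell"].mean()
    return mean.index.to_numpy(dtype=float), mean.to_numpy(dtype=float)


def fit_release_sigmoid(
    series: pd.DataFrame,
    fraction: str = "CP",
    replicate_level: bool = False,
    max_restarts: int = 5,
    seed: int = 0,
) -> SigmoidFit:
    """Least-squares fit of the release sigmoid to a normalized titration.

    By default the fit is unweighted on replicate means per digitonin
    level; ``replicate_level=True`` fits every replicate point instead.
    Initial values follow the shape of the data (floor = min, span =
    max - min, midpoint = level nearest midrange, steepness = quarter of
    the gradient span), with up to ``max_restarts`` jittered restarts from
    a fixed sub-seed on non-convergence.
    """
    sel = series[series["fraction"] == fraction]
    if sel.empty:
        raise ValueError(f"no rows for fraction {fraction!r}")
    if replicate_level:
        x = sel["digitonin_ug_per_ml"].to_numpy(dtype=float)
        y = sel["amount_amol_per_cell"].to_numpy(dtype=float)
    else:
        mean = sel.groupby("digitonin_ug_per_ml")["amount_amol_per_cell"].mean()
        x = mean.index.to_numpy(dtype=float)
        y = mean.to_numpy(dtype=float)
    levels = np.unique(x)
    if len(levels) < 4:
        raise ValueError(
            f"need >= 4 distinct digitonin levels to fit 4 parameters, "
            f"got {len(levels)}"
        )
    span_y = float(y.max() - y.min())
    if span_y <= 1e-12 * max(abs(float(y.max())), 1.0):
        raise ValueError("constant response: release curve is degenerate (b ~ 0)")
    span_x = float(levels.max() - levels.min())
    mid_y = (y.max() + y.min()) / 2.0
    p0 = np.array(
        [float(y.min()), span_y, float(x[np.argmin(np.abs(y - mid_y))]), span_x / 4.0]
    )
    rng = np.random.default_rng(seed)
    best = None
    best_ssr = math.inf
    last_err: Exception | None = None
    for attempt in range(max_restarts + 1):
        start = p0 if attempt == 0 else p0 * rng.uniform(0.5, 1.5, size=4)
        start[3] = max(start[3], 1e-3)
        try:
            popt, _ = curve_fit(
                _sigmoid,
                x,
                y,
                p0=start,
                bounds=([-np.inf, 1e-12, -np.inf, 1e-9], [np.inf, np.inf, np.inf, np.inf]),
                maxfev=20000,
            )
        except RuntimeError as err:
            last_err = err
            continue
        ssr = float(np.sum((y - _sigmoid(x, *popt)) ** 2))
        if ssr < best_ssr:
            best, best_ssr = popt, ssr
    if best is None:
        raise RuntimeError(
            f"sigmoid fit failed after {max_restarts + 1} attempts: {last_err}"
        )
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - best_ssr / sst if sst > 0 else 1.0
    return SigmoidFit(
        a=float(best[0]),
        b=float(best[1]),
        c=float(best[2]),
        d=float(best[3]),
        r_squared=r2,
        n_points=len(x),
    )


# --------------------------------------------------------------------------
# compartment distribution and design point

@dataclass(frozen=True)
class CompartmentModel:
    """Relative metabolite concentration and volume of GA and CP.

    Literature-informed defaults: Golgi metabolite concentrations ~40x the
    cytoplasmic level in ~2.2 % of the cell volume, against the cytoplasm's
    55 % volume share at unit concentration.
    """

    conc_ga: float = 40.0
    vol_ga: float = 0.022
    conc_cp: float = 1.0
    vol_cp: float = 0.55

    def __post_init__(self) -> None:
        if min(self.conc_ga, self.vol_ga, self.conc_cp, self.vol_cp) <= 0:
            raise ValueError("all compartment model fields must be positive")


DEFAULT_COMPARTMENT_MODEL = CompartmentModel()


@dataclass(frozen=True)
class CompartmentShares:
    n_ga: float
    n_cp: float
    n_total: float
    ga_percent: float
    cp_percent: float


def compartment_distribution(model: CompartmentModel) -> CompartmentShares:
    """Relative amounts n_i = c_i * V_i and percentage shares of GA and CP."""
    n_ga = model.conc_ga * model.vol_ga
    n_cp = model.conc_cp * model.vol_cp
    total = n_ga + n_cp
    if total <= 0:
        raise ValueError("zero total amount in compartment model")
    return CompartmentShares(
        n_ga=n_ga,
        n_cp=n_cp,
        n_total=total,
        ga_percent=100.0 * n_ga / total,
        cp_percent=100.0 * n_cp / total,
    )


@dataclass(frozen=True)
class DesignPoint:
    target_cp_share: float
    exact_solve_ug_per_ml: float
    selected_ug_per_ml: float
    below_grid: bool      # True when even the smallest grid value overshoots


def select_operating_digitonin(
    fit: SigmoidFit,
    target_cp_share: float,
    grid: Sequence[float],
) -> DesignPoint:
    """Pick the working digitonin concentration from an available grid.

    The release curve is inverted at the cytoplasmic share and the largest
    grid concentration not exceeding the exact solution is selected
    (rounding *down* protects the organelle fraction).  An exact solution
    below every grid value returns the smallest grid concentration with
    ``below_grid=True`` as a warning.
    """
    if not grid:
        raise ValueError("empty concentration grid")
    exact = invert_sigmoid(fit, target_cp_share)
    candidates = [g for g in grid if g <= exact]
    if candidates:
        return DesignPoint(
            target_cp_share=target_cp_share,
            exact_solve_ug_per_ml=exact,
            selected_ug_per_ml=max(candidates),
            below_grid=False,
        )
    return DesignPoint(
        target_cp_share=target_cp_share,
        exact_solve_ug_per_ml=exact,
        selected_ug_per_ml=min(grid),
        below_grid=True,
    )
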