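"""Standard-addition calibration and per-cell back-calculation.

LC-MS/MS peak areas of nucleotide sugar donors are calibrated internally by
standard addition: known spike concentrations are added to aliquots of the
sample and the response line ``area = slope * (native + spike)`` is
extrapolated to zero signal, cancelling matrix effects.  The fitted native
vial concentration is then propagated back through the dilution chain
(transfers, reconstitutions) and divided by the number of cells in the
original sample to give an absolute amount in amol/cell.

A method-detection-limit (MDL) check flags results whose vial
concentration sits below, near (within threefold of), or safely above the
detection limit of the LC-MS/MS method.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "DilutionChain",
    "StandardAdditionSet",
    "StandardAdditionFit",
    "QuantResult",
    "DEFAULT_CHAIN",
    "DEFAULT_MDL_NM",
    "fit_standard_addition",
    "back_calculate_per_cell",
    "vial_conc_from_per_cell",
    "apply_mdl",
    "compartment_ratio",
]

#: Median method detection limit of the LC-MS/MS assay, nM.
DEFAULT_MDL_NM = 12.0

Step = tuple[str, float]


@dataclass(frozen=True)
class DilutionChain:
    """Ordered dilution/concentration history of one sample.

    Each step is either ``("transfer", fraction)`` — a fraction in (0, 1]
    of the material carried forward (e.g. taking 650 of 900 µL of the
    aqueous phase) — or ``("reconstitute", volume_ul)`` — redissolving the
    dried residue in a given volume, which changes concentration but not
    the amount of analyte.  ``cells`` is the cell count of the original
    sample the chain started from.
    """

    steps: tuple[Step, ...]
    cells: float

    def __post_init__(self) -> None:
        if self.cells <= 0:
            raise ValueError("cell count must be positive")
        for kind, value in self.steps:
            if kind == "transfer":
                if not (0.0 < value <= 1.0):
                    raise ValueError(
                        f"transfer fraction must be in (0, 1], got {value!r}"
                    )
            elif kind == "reconstitute":
                if value <= 0:
                    raise ValueError(f"reconstitution volume must be positive, got {value!r}")
            else:
                raise ValueError(f"unknown dilution step kind {kind!r}")

    @property
    def transfer_product(self) -> float:
        """Product of all transfer fractions (1.0 for an identity chain)."""
        out = 1.0
        for kind, value in self.steps:
            if kind == "transfer":
                out *= value
        return out

    @property
    def final_volume_ul(self) -> float | None:
        """Volume of the last reconstitution step, if any."""
        for kind, value in reversed(self.steps):
            if kind == "reconstitute":
                return value
        return None


#: Default chain: biphasic extraction in 900 µL, 650 µL aqueous phase
#: carried forward, dried and reconstituted in 100 µL; 8e6 cells/sample.
DEFAULT_CHAIN = DilutionChain(
    steps=(("transfer", 650.0 / 900.0), ("reconstitute", 100.0)),
    cells=8e6,
)


@dataclass(frozen=True)
class StandardAdditionSet:
    """Peak areas versus spiked concentration for one analyte/sample.

    ``points`` are (spike_nM, peak_area) pairs; a zero spike must be
    present and at least two distinct spike levels are required for the
    calibration line to be identifiable.
    """

    analyte: str
    points: tuple[tuple[float, float], ...]
    chain: DilutionChain | None = None

    def __post_init__(self) -> None:
        spikes = [s for s, _ in self.points]
        areas = [a for _, a in self.points]
        if len(set(spikes)) < 2:
            raise ValueError(
                f"{self.analyte}: need >= 2 distinct spike levels, calibration "
                "is unidentifiable"
            )
        if not any(s == 0 for s in spikes):
            raise ValueError(f"{self.analyte}: a zero-spike point is required")
        if any(a < 0 for a in areas):
            raise ValueError(f"{self.analyte}: negative peak area")

    @property
    def spikes(self) -> np.ndarray:
        return np.array([s for s, _ in self.points], dtype=float)

    @property
    def areas(self) -> np.ndarray:
        return np.array([a for _, a in self.points], dtype=float)


@dataclass(frozen=True)
class StandardAdditionFit:
    slope: float                # area per nM
    intercept: float            # area
    native_conc_nm: float       # x-axis extrapolation, intercept/slope
    se_native_nm: float         # first-order error propagation (nan if dof < 1)
    r_squared: float
    n_points: int


def fit_standard_addition(sa: StandardAdditionSet) -> StandardAdditionFit:
    """Ordinary least squares of peak area on spike concentration.

    The native vial concentration is the magnitude of the x-intercept,
    ``intercept / slope``.  Its standard error follows from first-order
    propagation of the OLS parameter covariance.  A non-positive slope
    means the analyte did not respond to the spikes and is an error.
    """
    x, y = sa.spikes, sa.areas
    n = len(x)
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0:  # guarded by the set's validation, kept for safety
        raise ValueError(f"{sa.analyte}: singular design (all spikes equal)")
    slope = float(np.sum((x - x.mean()) * (y - y.mean())) / sxx)
    intercept = float(y.mean() - slope * x.mean())
    if slope <= 0:
        raise ValueError(
            f"{sa.analyte}: non-positive standard-addition slope ({slope:.4g}); "
            "analyte does not respond to added standard"
        )
    resid = y - (intercept + slope * x)
    ssr = float(np.sum(resid**2))
    sst = float(np.sum((y - y.mean()) ** 2))
    r_squared = 1.0 - ssr / sst if sst > 0 else 1.0
    native = intercept / slope
    dof = n - 2
    if dof >= 1:
        s2 = ssr / dof
        var_slope = s2 / sxx
        var_int = s2 * (1.0 / n + x.mean() ** 2 / sxx)
        cov = -s2 * x.mean() / sxx
        # native = intercept/slope; gradient (1/slope, -intercept/slope^2)
        var_native = (
            var_int / slope**2
            + intercept**2 * var_slope / slope**4
            - 2.0 * intercept * cov / slope**3
        )
        se_native = math.sqrt(max(var_native, 0.0))
    else:
        se_native = math.nan
    return StandardAdditionFit(
        slope=slope,
        intercept=intercept,
        native_conc_nm=native,
        se_native_nm=se_native,
        r_squared=r_squared,
        n_points=n,
    )


def back_calculate_per_cell(
    vial_conc_nm: float,
    vial_volume_ul: float,
    chain: DilutionChain,
) -> float:
    """Convert a vial concentration to an amount per original cell.

    amount_in_vial [amol] = conc [nM] * volume [µL] * 1e3 (exact unit
    conversion: 1 nM * 1 µL = 1e-15 mol = 1000 amol).  Dividing by the
    product of transfer fractions undoes every loss of material along the
    chain; reconstitutions carry the full amount and do not enter.  The
    result is amol per cell of the original sample.
    """
    if vial_volume_ul <= 0:
        raise ValueError("vial volume must be positive")
    amol_in_vial = vial_conc_nm * vial_volume_ul * 1e3
    return amol_in_vial / chain.transfer_product / chain.cells


def vial_conc_from_per_cell(
    amount_amol_per_cell: float,
    vial_volume_ul: float,
    chain: DilutionChain,
) -> float:
    """Forward model: expected vial concentration (nM) for a given pool.

    Exact inverse of :func:`back_calculate_per_cell`; used when simulating
    the measurement of a known per-cell amount.
    """
    if vial_volume_ul <= 0:
        raise ValueError("vial volume must be positive")
    amol_in_vial = amount_amol_per_cell * chain.cells * chain.transfer_product
    return amol_in_vial / (vial_volume_ul * 1e3)


MdlFlag = Literal["below", "near", "pass"]


@dataclass(frozen=True)
class QuantResult:
    """One analyte/compartment quantification.

    Negative extrapolated native concentrations can occur under noise; they
    are reported with ``negative_extrapolation=True`` rather than clipped,
    so that averaging over replicates stays unbiased.
    """

    analyte: str
    compartment: str
    vial_conc_nm: float
    amount_amol_per_cell: float
    mdl_flag: MdlFlag | None = None
    negative_extrapolation: bool = False


def apply_mdl(result: QuantResult, mdl_nm: float = DEFAULT_MDL_NM) -> QuantResult:
    """Flag a result against the method detection limit.

    below: vial concentration under the MDL; near: within threefold of it;
    pass: at least three times the MDL (the threefold margin mirrors the
    common requirement that quantified levels clear the MDL comfortably).
    """
    if mdl_nm <= 0:
        raise ValueError("MDL must be positive")
    c = result.vial_conc_nm
    if c < mdl_nm:
        flag: MdlFlag = "below"
    elif c < 3.0 * mdl_nm:
        flag = "near"
    else:
        flag = "pass"
    return replace(result, mdl_flag=flag)


def compartment_ratio(cp: QuantResult, ga: QuantResult) -> float:
    """Golgi-to-cytoplasm amount ratio for one analyte.

    Undefined (NaN, never infinity) when the cytoplasmic amount is not
    positive.
    """
    if cp.amount_amol_per_cell <= 0:
        return math.nan
    return ga.amount_amol_per_cell / cp.amount_amol_per_cell
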