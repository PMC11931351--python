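"""Antibody N-glycan annotation and galactosylation indices.

HILIC retention times of 2-AB-labelled glycans are normalized to glucose
units (GU) against a dextran ladder, assigned to library species by nearest
GU, and summarized as relative abundances.  For IgG-type profiles built on
the core-fucosylated biantennary scaffold (FA2 = no galactose, FA2G1 = one
arm galactosylated, FA2G2 = both arms), the galactosylation index I_G
summarizes terminal galactose occupancy.

Two I_G conventions are offered.  The default normalizes by the number of
available arms, I_G = 100 * (2 FA2G2 + FA2G1) / (2 (FA2 + FA2G1 + FA2G2)),
which is bounded by [0, 100] and equals the per-arm galactosylation
probability in percent.  The literal convention drops the factor 2 in the
denominator and can exceed 100 for strongly galactosylated samples; it is
kept selectable because some reports use it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

__all__ = [
    "GUCalibration",
    "GlycanProfile",
    "AssignmentResult",
    "CORE_SPECIES",
    "DEFAULT_GU_TOLERANCE",
    "gu_calibrate",
    "assign_glycans",
    "relative_abundances",
    "galactosylation_index",
]

CORE_SPECIES = ("FA2", "FA2G1", "FA2G2")
DEFAULT_GU_TOLERANCE = 0.3


@dataclass(frozen=True)
class GUCalibration:
    """Piecewise-linear monotone map from retention time to glucose units.

    Exact at ladder nodes; linear extrapolation beyond the outermost nodes
    (use :meth:`is_extrapolated` to flag peaks outside the ladder range).
    """

    rt: tuple[float, ...]
    gu: tuple[float, ...]

    def __call__(self, rt):
        rt_arr = np.asarray(rt, dtype=float)
        x = np.array(self.rt)
        y = np.array(self.gu)
        out = np.interp(rt_arr, x, y)
        # np.interp clamps outside the range; replace by linear extrapolation
        lo = rt_arr < x[0]
        hi = rt_arr > x[-1]
        if np.any(lo):
            s = (y[1] - y[0]) / (x[1] - x[0])
            out = np.where(lo, y[0] + s * (rt_arr - x[0]), out)
        if np.any(hi):
            s = (y[-1] - y[-2]) / (x[-1] - x[-2])
            out = np.where(hi, y[-1] + s * (rt_arr - x[-1]), out)
        return float(out) if np.isscalar(rt) or np.ndim(rt) == 0 else out

    def is_extrapolated(self, rt) -> bool | np.ndarray:
        rt_arr = np.asarray(rt, dtype=float)
        out = (rt_arr < self.rt[0]) | (rt_arr > self.rt[-1])
        return bool(out) if np.ndim(rt) == 0 else out


def gu_calibrate(ladder: Sequence[tuple[float, float]]) -> GUCalibration:
    """Build a GU calibration from (retention time, glucose units) pairs.

    The ladder must be strictly increasing in both coordinates.
    """
    if len(ladder) < 2:
        raise ValueError("ladder needs at least 2 points")
    rt = [p[0] for p in ladder]
    gu = [p[1] for p in ladder]
    if any(b <= a for a, b in zip(rt, rt[1:])) or any(
        b <= a for a, b in zip(gu, gu[1:])
    ):
        raise ValueError("ladder must be strictly increasing in rt and GU")
    return GUCalibration(rt=tuple(rt), gu=tuple(gu))


@dataclass
class GlycanProfile:
    """Named glycan abundances for one sample.

    The three core species keys are always present (zero if not observed);
    additional species are allowed.  ``units`` distinguishes raw peak areas
    from normalized fractions.
    """

    abundances: dict[str, float] = field(default_factory=dict)
    units: Literal["area", "fraction"] = "area"

    def __post_init__(self) -> None:
        for sp in CORE_SPECIES:
            self.abundances.setdefault(sp, 0.0)
        for sp, v in self.abundances.items():
            if v < 0:
                raise ValueError(f"negative abundance for {sp}")

    @property
    def total(self) -> float:
        return float(sum(self.abundances.values()))

    def __getitem__(self, species: str) -> float:
        return self.abundances[species]


@dataclass
class AssignmentResult:
    profile: GlycanProfile
    unassigned: list[tuple[float, float]]   # (rt, area) with no library match
    ties: list[tuple[float, str]]           # (rt, chosen species) for tie-breaks


def assign_glycans(
    peaks: Iterable[float | tuple[float, float]],
    calib: GUCalibration,
    library: Sequence[tuple[str, float]],
    tolerance: float = DEFAULT_GU_TOLERANCE,
) -> AssignmentResult:
    """Assign chromatographic peaks to library glycans by glucose units.

    ``peaks`` are retention times, optionally with areas (unit area is
    assumed for bare retention times).  Each peak is converted to GU and
    matched to the nearest library entry within ``tolerance`` GU; areas of
    peaks assigned to the same species accumulate.  A peak equidistant
    between two entries is assigned to the lower-GU entry with a warning.
    Peaks farther than the tolerance from every entry are reported as
    unassigned.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    if not library:
        raise ValueError("empty glycan library")
    lib = sorted(library, key=lambda e: e[1])
    abundances: dict[str, float] = {}
    unassigned: list[tuple[float, float]] = []
    ties: list[tuple[float, str]] = []
    for peak in peaks:
        rt, area = peak if isinstance(peak, tuple) else (peak, 1.0)
        gu = calib(rt)
        dists = [abs(gu - lg) for _, lg in lib]
        best = min(dists)
        if best > tolerance:
            unassigned.append((rt, area))
            continue
        # distances equal up to rounding noise count as a tie
        tie_eps = 1e-9 * max(1.0, abs(gu))
        hits = [i for i, d in enumerate(dists) if d <= best + tie_eps]
        idx = hits[0]  # lib sorted by GU: first hit is the lower-GU entry
        name = lib[idx][0]
        if len(hits) > 1:
            ties.append((rt, name))
            warnings.warn(
                f"peak at rt={rt:g} equidistant between library entries; "
                f"assigned to lower-GU species {name}",
                stacklevel=2,
            )
        abundances[name] = abundances.get(name, 0.0) + area
    return AssignmentResult(
        profile=GlycanProfile(abundances=abundances, units="area"),
        unassigned=unassigned,
        ties=ties,
    )


def relative_abundances(profile: GlycanProfile) -> GlycanProfile:
    """Normalize a profile to fractions summing to 1."""
    total = profile.total
    if total <= 0:
        raise ValueError("cannot normalize an all-zero glycan profile")
    return GlycanProfile(
        abundances={sp: v / total for sp, v in profile.abundances.items()},
        units="fraction",
    )


def galactosylation_index(
    profile: GlycanProfile,
    convention: Literal["arm_normalized", "as_printed"] = "arm_normalized",
) -> float:
    """Galactosylation index I_G in percent of the FA2-family species.

    arm_normalized (default):
        I_G = 100 * (2 FA2G2 + FA2G1) / (2 * (FA2 + FA2G1 + FA2G2)),
        the fraction of galactosylated arms; bounded by [0, 100].
    as_printed:
        I_G = 100 * (2 FA2G2 + FA2G1) / (FA2 + FA2G1 + FA2G2), the same
        numerator over the species count; reaches 200 for pure FA2G2.

    Only the three core species enter; other species in the profile are
    ignored.
    """
    f0 = profile.abundances["FA2"]
    f1 = profile.abundances["FA2G1"]
    f2 = profile.abundances["FA2G2"]
    denom = f0 + f1 + f2
    if denom <= 0:
        raise ValueError("FA2 + FA2G1 + FA2G2 must be positive")
    numer = 2.0 * f2 + f1
    if convention == "arm_normalized":
        return 100.0 * numer / (2.0 * denom)
    if convention == "as_printed":
        return 100.0 * numer / denom
    raise ValueError(f"unknown I_G convention {convention!r}")
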