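"""Sample-processing quality control for subcellular metabolomics.

Fast metabolite turnover makes fractionation workflows vulnerable to two
artefacts: enzymatic interconversion of nucleotides during sample handling,
and degradation during concentration of the extracts.  This module provides
the standard diagnostics used to judge both:

* the Atkinson adenylate **energy charge** ``EC = (NTP + 0.5 NDP) / (NTP +
  NDP + NMP)``, applied per nucleobase, which drops as triphosphates are
  dephosphorylated;
* the **triphosphate fraction** of a nucleotide pool, a cruder but
  assumption-free preservation measure;
* a **Q10 time budget** that converts a known warm-temperature processing
  time into the time available when working on ice, using the empirical
  rule that biochemical rates roughly halve per 10 K of cooling.

All functions are pure: they take small value objects and return numbers or
new value objects, so QC verdicts are reproducible from the tables alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "GAS_CONSTANT_J_PER_MOL_K",
    "NucleotidePanel",
    "TimeBudget",
    "Q10Budget",
    "energy_charge",
    "triphosphate_fraction",
    "method_preservation_ratio",
    "q10_time_budget",
    "arrhenius_rate_ratio",
]

GAS_CONSTANT_J_PER_MOL_K = 8.314462618


@dataclass(frozen=True)
class NucleotidePanel:
    """Tri-, di- and monophosphate amounts for one nucleobase.

    Amounts may be in any consistent unit (amol/cell in the pipeline).
    At least one species must be positive: an all-zero panel carries no
    information and is rejected at construction.
    """

    base: str
    ntp: float
    ndp: float
    nmp: float

    def __post_init__(self) -> None:
        for name in ("ntp", "ndp", "nmp"):
            if getattr(self, name) < 0:
                raise ValueError(
                    f"{self.base}: negative {name.upper()} amount "
                    f"({getattr(self, name)!r})"
                )
        if self.total == 0:
            raise ValueError(f"{self.base}: all-zero nucleotide panel")

    @property
    def total(self) -> float:
        return self.ntp + self.ndp + self.nmp


def energy_charge(panel: NucleotidePanel) -> float:
    """Atkinson energy charge of one nucleobase pool, in [0, 1].

    EC = (NTP + 0.5 NDP) / (NTP + NDP + NMP).  1 for a pure triphosphate
    pool, 0 for a pure monophosphate pool.
    """
    return (panel.ntp + 0.5 * panel.ndp) / panel.total


def triphosphate_fraction(panel: NucleotidePanel) -> float:
    """Fraction of the pool still present as the triphosphate species."""
    return panel.ntp / panel.total


def method_preservation_ratio(ec_test: float, ec_reference: float) -> float:
    """Energy charge of a test method relative to a reference, in percent.

    Used to compare concentration methods, e.g. evaporation against the
    milder lyophilization.  100 means the test method preserved the pool
    exactly as well as the reference.
    """
    if ec_reference <= 0:
        raise ValueError("reference energy charge must be positive")
    return 100.0 * ec_test / ec_reference


@dataclass(frozen=True)
class TimeBudget:
    """Inputs for a Q10 cold-processing time budget.

    ``t_warm_min`` is the known duration of the lumped process at the warm
    (growth) temperature; ``n_steps`` splits the budget over sequential
    catalytic steps.  ``q10_factor`` is the rate change per 10 K (default 2,
    the classical halving rule); values other than 2 support sensitivity
    analysis.  Temperatures are in degrees Celsius (only their difference
    enters).
    """

    t_warm_min: float = 22.0
    temp_warm_c: float = 37.0
    temp_cold_c: float = 4.0
    q10_factor: float = 2.0
    n_steps: int = 7

    def __post_init__(self) -> None:
        if self.t_warm_min <= 0:
            raise ValueError("t_warm_min must be positive")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.q10_factor <= 1:
            raise ValueError("q10_factor must exceed 1")


@dataclass(frozen=True)
class Q10Budget:
    """Result of a Q10 budget: rounded headline values plus exact ones."""

    delta_t_k: float
    t_cold_min: float           # rounded to 0.1 min
    t_per_step_min: int         # rounded to nearest minute
    t_cold_min_exact: float
    t_per_step_min_exact: float


def q10_time_budget(budget: TimeBudget) -> Q10Budget:
    """Scale a warm-temperature processing time to cold conditions.

    t_cold = t_warm * q10 ** (dT / 10) with dT = T_warm - T_cold.  A
    negative dT (processing warmer than the reference) is allowed and
    yields a speed-up rather than a budget extension.
    """
    delta_t = budget.temp_warm_c - budget.temp_cold_c
    t_cold = budget.t_warm_min * budget.q10_factor ** (delta_t / 10.0)
    per_step = t_cold / budget.n_steps
    return Q10Budget(
        delta_t_k=delta_t,
        t_cold_min=round(t_cold, 1),
        t_per_step_min=round(per_step),
        t_cold_min_exact=t_cold,
        t_per_step_min_exact=per_step,
    )


def arrhenius_rate_ratio(
    activation_energy_j_per_mol: float,
    temp_warm_k: float,
    temp_cold_k: float,
) -> float:
    """k_cold / k_warm from the Arrhenius law, an alternative to Q10.

    Returns exp(-Ea/R * (1/T_cold - 1/T_warm)); < 1 when cooling.  Offered
    for users who prefer an explicit activation energy over a fixed Q10
    factor.
    """
    if temp_warm_k <= 0 or temp_cold_k <= 0:
        raise ValueError("absolute temperatures must be positive")
    ea = activation_energy_j_per_mol
    return math.exp(-ea / GAS_CONSTANT_J_PER_MOL_K * (1.0 / temp_cold_k - 1.0 / temp_warm_k))
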