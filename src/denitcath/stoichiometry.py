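"""Cathodic electron and nitrogen bookkeeping for a denitrifying biocathode.

A biocathode fed nitrate (or nitrite) removes nitrogen through the stepwise
respiratory chain NO3- -> NO2- -> NO -> N2O -> N2, drawing electrons from the
electrode. Two ledgers describe the process:

* a nitrogen ledger: daily loads of each species entering and leaving the
  cathode compartment, whose closure yields the dinitrogen production that is
  not measured directly;
* an electron ledger: the supply implied by the measured current
  (I * 86400 / F mol e- per day) against the demand implied by the observed
  nitrogen conversions (2 e- per N for NO3- -> NO2-, 2 e- per N from NO2- to
  N2O, and 1 further e- per N reaching N2).

Coulombic efficiency relates the two ledgers; the gas split between N2O and
N2 can alternatively be inferred from the electron balance when only the
total gaseous nitrogen is known.

NO production is treated as negligible throughout: its daily load is pinned
to zero and only the electron cost of passing through NO is kept.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional

__all__ = [
    "FARADAY",
    "SECONDS_PER_DAY",
    "MOLAR_MASS_N",
    "StoichiometryTable",
    "DEFAULT_STOICHIOMETRY",
    "OperatingPeriod",
    "NitrogenBalance",
    "ElectronLedger",
    "GasSplit",
    "PerformanceSummary",
    "current_from_density",
    "electron_supply",
    "nitrogen_removed",
    "estimate_n2_by_closure",
    "close_balance",
    "electron_demand",
    "split_gas_by_electron_balance",
    "coulombic_efficiency",
    "n2o_share",
    "summarize_period",
]

FARADAY = 96485.0  # C per mol electrons
SECONDS_PER_DAY = 86400.0
MOLAR_MASS_N = 14.007  # g per mol N


@dataclass(frozen=True)
class StoichiometryTable:
    """Electrons transferred per N atom at each denitrification step."""

    no3_to_no2: float = 2.0
    no2_to_no: float = 1.0
    no_to_n2o: float = 1.0
    n2o_to_n2: float = 1.0
    molar_mass_n: float = MOLAR_MASS_N

    @property
    def no2_to_n2o(self) -> float:
        """Combined electron cost per N from nitrite to nitrous oxide."""
        return self.no2_to_no + self.no_to_n2o

    @property
    def no3_to_n2(self) -> float:
        return self.no3_to_no2 + self.no2_to_no + self.no_to_n2o + self.n2o_to_n2

    @property
    def no2_to_n2(self) -> float:
        return self.no2_to_no + self.no_to_n2o + self.n2o_to_n2


DEFAULT_STOICHIOMETRY = StoichiometryTable()


@dataclass
class OperatingPeriod:
    """One feeding regime of the cell: flows, chemistry and current density.

    Concentrations are mg N/L (mg COD/L for COD); ``None`` encodes "not
    detected"/absent. ``flow`` is the cathode feed in L/day, assumed equal in
    and out. ``ncc_volume`` is the net cathodic compartment volume in m^3.
    """

    period_id: str
    regime: str = ""
    flow: float = 1.0
    cod_in: Optional[float] = None
    cod_out: Optional[float] = None
    no3_in: Optional[float] = None
    no3_out: Optional[float] = None
    no2_in: Optional[float] = None
    no2_out: Optional[float] = None
    n2o_out: Optional[float] = None
    n2_out: Optional[float] = None
    current_density: Optional[float] = None  # A per m^3 NCC
    ncc_volume: float = 145e-6  # m^3

    def __post_init__(self) -> None:
        if self.flow <= 0:
            raise ValueError(
                f"period {self.period_id!r}: flow must be positive, got {self.flow}"
            )
        if self.ncc_volume <= 0:
            raise ValueError(
                f"period {self.period_id!r}: ncc_volume must be positive, "
                f"got {self.ncc_volume}"
            )
        for name in (
            "cod_in", "cod_out", "no3_in", "no3_out",
            "no2_in", "no2_out", "n2o_out", "n2_out", "current_density",
        ):
            value = getattr(self, name)
            if value is not None and value < 0:
                raise ValueError(
                    f"period {self.period_id!r}: {name} must be >= 0, got {value}"
                )


@dataclass
class NitrogenBalance:
    """Daily nitrogen loads (mg N/day) through the denitrification chain.

    ``delta_no3`` is nitrate consumption, ``delta_no2`` net nitrite
    production (negative when nitrite is consumed), ``delta_no`` is fixed at
    zero, and ``delta_n2o``/``delta_n2`` are gas production rates. The
    closure residual is the removed nitrogen not yet accounted for as gas.
    """

    delta_no3: float
    delta_no2: float
    delta_n2o: float = 0.0
    delta_n2: float = 0.0
    flow: Optional[float] = None  # L/day, kept to convert loads back to mg N/L
    delta_no: float = field(default=0.0, init=False)

    @property
    def removed_n(self) -> float:
        return self.delta_no3 - self.delta_no2

    @property
    def closure_residual(self) -> float:
        return self.removed_n - (self.delta_n2o + self.delta_n2)

    @property
    def removed_concentration(self) -> float:
        if self.flow is None:
            raise ValueError("flow unknown; cannot express removal as mg N/L")
        return self.removed_n / self.flow


@dataclass
class ElectronLedger:
    """Electron supply from current against per-step demand (mol e-/day)."""

    current: float  # A
    demand_by_step: Mapping[str, float]
    faraday: float = FARADAY

    def __post_init__(self) -> None:
        for step, demand in self.demand_by_step.items():
            if demand < 0:
                raise ValueError(f"negative electron demand for step {step!r}")

    @property
    def charge_per_day(self) -> float:
        return self.current * SECONDS_PER_DAY

    @property
    def electron_supply(self) -> float:
        return self.charge_per_day / self.faraday

    @property
    def total_demand(self) -> float:
        return float(sum(self.demand_by_step.values()))


@dataclass(frozen=True)
class GasSplit:
    """N2O/N2 partition of gaseous nitrogen inferred from the electron balance."""

    n2o: float  # mol N/day
    n2: float  # mol N/day
    clamped: bool  # True when supply fell outside the feasible band


@dataclass
class PerformanceSummary:
    period_id: str
    removed_n_concentration: float  # mg N/L
    n2o_concentration: float  # mg N/L
    n2_concentration: float  # mg N/L
    current_density: Optional[float]  # A/m^3 NCC
    coulombic_efficiency: Optional[float]  # %
    n2o_share_of_removed: float  # %
    n2o_share_of_gas: float  # %


def current_from_density(current_density: float, ncc_volume: float) -> float:
    """Invert the reported volumetric current density (A/m^3) to current (A)."""
    if current_density < 0:
        raise ValueError(f"current density must be >= 0, got {current_density}")
    if ncc_volume < 0:
        raise ValueError(f"compartment volume must be >= 0, got {ncc_volume}")
    return current_density * ncc_volume


def electron_supply(current: float) -> float:
    """Daily electron supply (mol e-/day) carried by a steady current (A)."""
    if current < 0:
        raise ValueError(f"current must be >= 0, got {current}")
    return current * SECONDS_PER_DAY / FARADAY


def _require(period: OperatingPeriod, *names: str) -> None:
    missing = [n for n in names if getattr(period, n) is None]
    if missing:
        raise ValueError(
            f"period {period.period_id!r}: missing concentration(s) "
            + ", ".join(missing)
        )


def nitrogen_removed(period: OperatingPeriod) -> NitrogenBalance:
    """Nitrate/nitrite loads and net nitrogen removal for one period.

    Returns a partial balance (gas terms zero) whose ``closure_residual``
    equals the removed nitrogen still to be assigned to N2O and N2.
    """
    _require(period, "no3_in", "no3_out", "no2_in", "no2_out")
    delta_no3 = (period.no3_in - period.no3_out) * period.flow
    delta_no2 = (period.no2_out - period.no2_in) * period.flow
    return NitrogenBalance(delta_no3=delta_no3, delta_no2=delta_no2, flow=period.flow)


def estimate_n2_by_closure(period: OperatingPeriod, n2o_conc: float) -> float:
    """Dinitrogen in the effluent (mg N/L) that closes the nitrogen balance.

    With nitrate consumption, net nitrite production and the nitrous-oxide
    level known, every removed N atom not leaving as N2O must leave as N2.
    """
    if n2o_conc < 0:
        raise ValueError(f"N2O concentration must be >= 0, got {n2o_conc}")
    removed_conc = nitrogen_removed(period).removed_concentration
    if n2o_conc > removed_conc + 1e-12:
        raise ValueError(
            f"period {period.period_id!r}: N2O ({n2o_conc} mg N/L) exceeds removed "
            f"nitrogen ({removed_conc:.4g} mg N/L); balance infeasible"
        )
    return removed_conc - n2o_conc


def close_balance(period: OperatingPeriod, n2o_conc: float) -> NitrogenBalance:
    """Full nitrogen balance with the N2 term chosen so the closure is exact."""
    n2_conc = estimate_n2_by_closure(period, n2o_conc)
    balance = nitrogen_removed(period)
    balance.delta_n2o = n2o_conc * period.flow
    balance.delta_n2 = n2_conc * period.flow
    return balance


def electron_demand(
    balance: NitrogenBalance,
    stoich: StoichiometryTable = DEFAULT_STOICHIOMETRY,
    residual_tol: float = 1e-9,
) -> dict[str, float]:
    """Per-step electron demand (mol e-/day) implied by a closed balance.

    Nitrate-derived N pays 2 e- per N at the first step; all gaseous N pays
    2 e- per N on the nitrite-to-N2O stretch (N fed as nitrite enters here);
    N reaching N2 pays 1 further e-.
    """
    if abs(balance.closure_residual) > residual_tol * max(1.0, abs(balance.removed_n)):
        raise ValueError(
            f"nitrogen balance not closed (residual {balance.closure_residual:.4g} "
            "mg N/day); close it before computing electron demand"
        )
    mg_to_mol = 1.0 / (stoich.molar_mass_n * 1000.0)
    gas_n = balance.delta_n2o + balance.delta_n2
    return {
        "no3_to_no2": stoich.no3_to_no2 * balance.delta_no3 * mg_to_mol,
        "no2_to_n2o": stoich.no2_to_n2o * gas_n * mg_to_mol,
        "n2o_to_n2": stoich.n2o_to_n2 * balance.delta_n2 * mg_to_mol,
    }


def split_gas_by_electron_balance(
    removed_gas_n: float,
    supply: float,
    pre_gas_demand: float,
    stoich: StoichiometryTable = DEFAULT_STOICHIOMETRY,
) -> GasSplit:
    """Partition gaseous N between N2O and N2 from the electron budget.

    All units molar and per day. Every gaseous N costs ``no2_to_n2o``
    electrons to reach N2O; the final reduction to N2 is the marginal
    consumer, so N2 takes whatever electrons remain after the pre-gas demand
    and the obligatory cost of reaching N2O, clamped to the physical range.
    """
    if removed_gas_n < 0:
        raise ValueError("removed gaseous nitrogen must be >= 0")
    if supply < 0:
        raise ValueError("electron supply must be >= 0")
    leftover = (supply - pre_gas_demand - stoich.no2_to_n2o * removed_gas_n)
    n2_unclamped = leftover / stoich.n2o_to_n2
    n2 = min(max(n2_unclamped, 0.0), removed_gas_n)
    clamped = not math.isclose(n2, n2_unclamped, rel_tol=0.0, abs_tol=1e-15)
    return GasSplit(n2o=removed_gas_n - n2, n2=n2, clamped=clamped)


def coulombic_efficiency(supply: float, total_demand: float) -> float:
    """Coulombic efficiency (%) as electron supply over electron demand."""
    if total_demand <= 0:
        raise ValueError("coulombic efficiency undefined for zero electron demand")
    if supply < 0:
        raise ValueError("electron supply must be >= 0")
    return 100.0 * supply / total_demand


def n2o_share(n2o: float, removed_n: float) -> float:
    """Percentage of removed nitrogen leaving as nitrous oxide."""
    if removed_n <= 0:
        raise ValueError("share undefined: removed nitrogen must be positive")
    if not 0 <= n2o <= removed_n + 1e-12:
        raise ValueError(f"N2O load {n2o} outside [0, removed={removed_n}]")
    return 100.0 * n2o / removed_n


def summarize_period(
    period: OperatingPeriod,
    stoich: StoichiometryTable = DEFAULT_STOICHIOMETRY,
) -> PerformanceSummary:
    """Close the nitrogen balance for a period and derive the performance row.

    Requires the period's measured/estimated N2O effluent concentration;
    N2 is recomputed by closure (any provided ``n2_out`` is ignored).
    Coulombic efficiency is supply/demand with demand taken from the
    observed conversions, reported only when a current density is given.
    """
    _require(period, "n2o_out")
    balance = close_balance(period, period.n2o_out)
    n2_conc = balance.delta_n2 / period.flow
    gas = balance.delta_n2o + balance.delta_n2
    ce = None
    if period.current_density is not None:
        current = current_from_density(period.current_density, period.ncc_volume)
        supply = electron_supply(current)
        demand = sum(electron_demand(balance, stoich).values())
        ce = coulombic_efficiency(supply, demand) if demand > 0 else None
    return PerformanceSummary(
        period_id=period.period_id,
        removed_n_concentration=balance.removed_concentration,
        n2o_concentration=period.n2o_out,
        n2_concentration=n2_conc,
        current_density=period.current_density,
        coulombic_efficiency=ce,
        n2o_share_of_removed=n2o_share(balance.delta_n2o, balance.removed_n),
        n2o_share_of_gas=(100.0 * balance.delta_n2o / gas) if gas > 0 else 0.0,
    )
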