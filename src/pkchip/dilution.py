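"""Two-step dilution planning from DMSO stocks to reservoir working solutions.

Step 1 dispenses stock into an array of small intermediate aliquots (200 µL by
default, matching a digital-dispenser workflow); step 2 pipettes from the
intermediate into each flow reservoir of culture medium.  The planner tracks
transfer volumes, residual DMSO fraction, and mass conservation at every
transfer.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from typing import Sequence

from .schedule import ReservoirStep

__all__ = [
    "StockSolution",
    "ReservoirTarget",
    "DilutionPlan",
    "plan_two_step_dilution",
    "reservoir_volume_requirement",
    "plan_to_worklist",
]

DEFAULT_ALIQUOT_UL = 200.0
DEFAULT_DMSO_CAP = 0.001  # 0.1 % v/v, common cell-culture tolerance
MIN_PIPETTE_UL = 0.5


@dataclass(frozen=True)
class StockSolution:
    """A concentrated drug stock (concentration stored in nM)."""

    analyte: str
    concentration_nM: float
    solvent: str = "DMSO"

    def __post_init__(self) -> None:
        if self.concentration_nM <= 0:
            raise ValueError("stock concentration must be > 0")

    @classmethod
    def from_mM(cls, analyte: str, conc_mM: float, solvent: str = "DMSO"):
        return cls(analyte, conc_mM * 1e6, solvent)

    @classmethod
    def from_uM(cls, analyte: str, conc_uM: float, solvent: str = "DMSO"):
        return cls(analyte, conc_uM * 1e3, solvent)


@dataclass
class ReservoirTarget:
    """Planned make-up of one flow reservoir."""

    index: int
    final_conc_nM: float
    volume_mL: float
    transfer_uL: float  # intermediate -> reservoir
    dmso_fraction: float  # v/v in the final reservoir
    needs_extra_serial_step: bool = False


@dataclass
class DilutionPlan:
    """Stock → intermediate → reservoir ledger for one analyte."""

    analyte: str
    stock_conc_nM: float
    intermediate_conc_nM: float
    aliquot_volume_uL: float
    n_aliquots: int
    stock_per_aliquot_uL: float
    reservoirs: list[ReservoirTarget]
    dmso_cap: float = DEFAULT_DMSO_CAP

    @property
    def intermediate_conc_uM(self) -> float:
        return self.intermediate_conc_nM / 1e3

    def verify_conservation(self, rel_tol: float = 1e-9) -> None:
        """Check volume×concentration bookkeeping at both transfer steps."""
        made = self.stock_per_aliquot_uL * self.stock_conc_nM
        want = self.aliquot_volume_uL * self.intermediate_conc_nM
        if not math.isclose(made, want, rel_tol=rel_tol):
            raise AssertionError("step-1 transfer violates mass conservation")
        for r in self.reservoirs:
            moles_in = r.transfer_uL * self.intermediate_conc_nM
            moles_out = r.volume_mL * 1e3 * r.final_conc_nM
            if not math.isclose(moles_in, moles_out, rel_tol=rel_tol):
                raise AssertionError(
                    f"reservoir {r.index}: step-2 transfer violates mass conservation"
                )


def plan_two_step_dilution(
    stock: StockSolution,
    reservoir_concs_nM: Sequence[float],
    reservoir_volumes_mL: Sequence[float],
    second_step_factor: float = 100.0,
    first_step_factor: float | None = None,
    intermediate_conc_nM: float | None = None,
    aliquot_volume_uL: float = DEFAULT_ALIQUOT_UL,
    dmso_cap: float = DEFAULT_DMSO_CAP,
) -> DilutionPlan:
    """Plan the stock → intermediate → reservoir dilution for one analyte.

    The intermediate concentration is, in order of precedence:
    ``intermediate_conc_nM`` (explicit), ``stock / first_step_factor`` (a
    fixed first-step dilution, e.g. 0.1 mM SN38 → 1 µM at factor 100), or
    ``max(reservoir_concs) * second_step_factor`` (a fixed second-step
    dilution for the top reservoir, e.g. 192 nM AZD0156 × 100 → 19.2 µM).

    Transfer volumes at the second step follow C1·V1 = C2·V2 per reservoir.
    A reservoir whose transfer would fall below the 0.5 µL pipettable minimum
    is flagged for an extra serial dilution step.
    """
    concs = [float(c) for c in reservoir_concs_nM]
    vols = [float(v) for v in reservoir_volumes_mL]
    if len(concs) != len(vols):
        raise ValueError("reservoir concentration and volume lists must align")
    if not concs:
        raise ValueError("need at least one reservoir")
    if any(c < 0 for c in concs) or any(v <= 0 for v in vols):
        raise ValueError("concentrations must be >= 0 and volumes > 0")

    if intermediate_conc_nM is not None:
        inter = float(intermediate_conc_nM)
    elif first_step_factor is not None:
        if first_step_factor < 1:
            raise ValueError("first_step_factor must be >= 1")
        inter = stock.concentration_nM / first_step_factor
    else:
        inter = max(concs) * second_step_factor
    if inter > stock.concentration_nM * (1 + 1e-12):
        raise ValueError(
            f"required intermediate {inter:g} nM exceeds stock "
            f"{stock.concentration_nM:g} nM"
        )
    if inter < max(concs):
        raise ValueError("intermediate must be at least the top reservoir concentration")

    stock_per_aliquot = aliquot_volume_uL * inter / stock.concentration_nM
    aliquot_dmso = stock_per_aliquot / aliquot_volume_uL if stock.solvent == "DMSO" else 0.0

    reservoirs = []
    total_needed_uL = 0.0
    for i, (c, v) in enumerate(zip(concs, vols), start=1):
        transfer = v * 1e3 * c / inter
        dmso = transfer * aliquot_dmso / (v * 1e3)
        if dmso > dmso_cap:
            raise ValueError(
                f"reservoir {i}: DMSO fraction {dmso:.3%} exceeds cap {dmso_cap:.3%}"
            )
        reservoirs.append(
            ReservoirTarget(
                index=i,
                final_conc_nM=c,
                volume_mL=v,
                transfer_uL=transfer,
                dmso_fraction=dmso,
                needs_extra_serial_step=0 < transfer < MIN_PIPETTE_UL,
            )
        )
        total_needed_uL += transfer
    n_aliquots = max(1, math.ceil(total_needed_uL / aliquot_volume_uL))
    plan = DilutionPlan(
        analyte=stock.analyte,
        stock_conc_nM=stock.concentration_nM,
        intermediate_conc_nM=inter,
        aliquot_volume_uL=aliquot_volume_uL,
        n_aliquots=n_aliquots,
        stock_per_aliquot_uL=stock_per_aliquot,
        reservoirs=reservoirs,
        dmso_cap=dmso_cap,
    )
    plan.verify_conservation()
    return plan


def reservoir_volume_requirement(
    step: ReservoirStep,
    flow_rate: float = 20.0,
    spare_mL: float = 5.0,
) -> float:
    """Medium volume (mL) one reservoir must hold for its step.

    Perfused volume at ``flow_rate`` µL/min over the step duration, plus a
    spare allowance (default 5 mL) so the line never runs dry.
    """
    if step.duration <= 0:
        raise ValueError("step duration must be > 0")
    if flow_rate <= 0:
        raise ValueError("flow_rate must be > 0")
    return flow_rate * step.duration * 60.0 / 1e3 + spare_mL


def plan_to_worklist(plan: DilutionPlan) -> str:
    """Render a plan as a delimited worklist
    (``analyte,step,source,target,transfer_uL,final_conc_nM``)."""
    buf = io.StringIO()
    buf.write("analyte,step,source,target,transfer_uL,final_conc_nM\n")
    for k in range(1, plan.n_aliquots + 1):
        buf.write(
            f"{plan.analyte},1,stock,aliquot_{k},"
            f"{plan.stock_per_aliquot_uL:g},{plan.intermediate_conc_nM:g}\n"
        )
    for r in plan.reservoirs:
        buf.write(
            f"{plan.analyte},2,intermediate,reservoir_{r.index},"
            f"{r.transfer_uL:g},{r.final_conc_nM:g}\n"
        )
    return buf.getvalue()
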