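"""Recovery index and hepatosomatic index.

The recovery index (RI) quantifies how much of the depleted seminal stock a
group of electroejaculated males has regained after a holding period, on a
percentage scale anchored by two day-0 baseline groups:

    A  = mean VDW(depleted, t1) - mean VDW(depleted, t0)   increment regained
    B  = mean VDW(control, t0)  - mean VDW(depleted, t0)   amount to recover
    RI = A / B * 100

where VDW is the paired vasa deferentia dry weight in mg. The design is
cross-sectional (each group is a different set of sacrificed animals), so RI
is a function of group means, not of per-animal ratios. RI may exceed 100
(overcompensation) or be negative (net loss); neither is clamped. Residual
material left after electroejaculation is not subtracted.

The hepatosomatic index (HSI) is the hepatopancreas dry weight as a
percentage of whole-body dry weight, a standard crustacean body-condition
and energy-reserve indicator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .data_io import Cell
from .errors import DegenerateBaselineError, MissingCellError, SemrecError


@dataclass(frozen=True)
class RecoveryIndexInput:
    """The three VDW samples (mg) feeding one recovery-index estimate."""

    vdw_control_t0: tuple[float, ...]
    vdw_ee_t0: tuple[float, ...]
    vdw_ee_t1: tuple[float, ...]
    cell: Optional[Cell] = None

    @staticmethod
    def from_groups(control_t0, ee_t0, ee_t1, cell=None) -> "RecoveryIndexInput":
        return RecoveryIndexInput(
            tuple(float(v) for v in control_t0),
            tuple(float(v) for v in ee_t0),
            tuple(float(v) for v in ee_t1),
            cell,
        )


@dataclass
class RecoveryIndexResult:
    """Plug-in RI with its components; CI fields filled by the bootstrap."""

    A: float            # mg, mean increment after t1
    B: float            # mg, mean quantity to be recovered
    ri: float           # %, A / B * 100
    cell: Optional[Cell] = None
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    b_replicates: Optional[int] = None
    seed: Optional[int] = None


def ri_from_means(mean_control_t0: float, mean_ee_t0: float, mean_ee_t1: float) -> float:
    """RI as a pure function of the three group means (internal kernel)."""
    B = mean_control_t0 - mean_ee_t0
    if B <= 0:
        raise DegenerateBaselineError(
            f"depleted baseline mean ({mean_ee_t0:g} mg) is not below the control "
            f"mean ({mean_control_t0:g} mg); B = {B:g} <= 0"
        )
    A = mean_ee_t1 - mean_ee_t0
    return A / B * 100.0


def compute_ri(inp: RecoveryIndexInput) -> RecoveryIndexResult:
    """Plug-in recovery index from the three observed groups."""
    for name in ("vdw_control_t0", "vdw_ee_t0", "vdw_ee_t1"):
        vals = getattr(inp, name)
        if len(vals) == 0:
            raise MissingCellError(f"group {name} is empty")
        if any(not (v > 0) for v in vals):
            raise SemrecError(f"group {name} holds non-positive weights")
    m_c = float(np.mean(inp.vdw_control_t0))
    m_e0 = float(np.mean(inp.vdw_ee_t0))
    m_e1 = float(np.mean(inp.vdw_ee_t1))
    ri = ri_from_means(m_c, m_e0, m_e1)
    return RecoveryIndexResult(
        A=m_e1 - m_e0, B=m_c - m_e0, ri=ri, cell=inp.cell
    )


def hepatosomatic_index(hep_dry_weight: float, body_dry_weight: float) -> float:
    """HSI (%) = hepatopancreas / whole-body dry weight * 100, both in g."""
    if not body_dry_weight > 0:
        raise SemrecError(f"body dry weight must be > 0, got {body_dry_weight}")
    if hep_dry_weight < 0:
        raise SemrecError(f"hepatopancreas dry weight must be >= 0, got {hep_dry_weight}")
    if hep_dry_weight > body_dry_weight:
        raise SemrecError(
            f"hepatopancreas ({hep_dry_weight} g) exceeds whole body "
            f"({body_dry_weight} g)"
        )
    return hep_dry_weight / body_dry_weight * 100.0


def ri_input_from_table(table, cell: Cell) -> RecoveryIndexInput:
    """Assemble the three VDW groups for one recovery cell from a table."""
    control = [r.vd_dry_weight for r in table.cell_records(Cell.control_t0())]
    depleted = [r.vd_dry_weight for r in table.cell_records(Cell.depleted_t0())]
    recovered = [r.vd_dry_weight for r in table.cell_records(cell)]
    if not control or not depleted:
        raise MissingCellError("baseline day-0 groups missing from table")
    if not recovered:
        raise MissingCellError(f"no records in recovery cell {cell.label()}")
    return RecoveryIndexInput.from_groups(control, depleted, recovered, cell)
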