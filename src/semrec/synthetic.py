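"""Synthetic study generator.

Emulates the statistical structure of the depletion experiment: two day-0
baseline groups (control n=4, electroejaculated n=4) and a 2x2x2 factorial
of electroejaculated recovery groups (temperature 12/16 degC x food
ad-libitum/deprived x 15/30 d) with n=5 per cell except n=4 in the two
30-day 16 degC cells. Within a cell each variable is drawn independently
from a normal distribution truncated at zero by redraw; the hepatopancreas
weight is additionally redrawn whenever it exceeds the body weight.

The default configuration reproduces the study's reported group statistics:
baseline vasa deferentia dry weights 84 +- 4 and 52 +- 4 mg (mean +- SE,
n = 4, so within-cell SD = 8 mg), carapace length 98.6 mm common to all
cells, and hepatosomatic-index means of 6.0% at day 0 rising to 8.5% (30 d,
16 degC, fed) or falling to 4.1/4.6% (30 d, deprived). Where a group mean is
not printed it is set from the reported recovery trajectory (full recovery by
30 days everywhere, 165% overcompensation at 30 d/16 degC/deprived, near-zero
recovery at 15 d/12 degC/deprived); see docs/methods.md for the full table.

Each cell draws from its own substream of the master seed (split by cell
index), so adding a cell never perturbs another cell's draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .data_io import Cell, CrabRecord, StudyTable
from .errors import ConfigError
from .recovery import ri_from_means

#: Default within-cell SD of VDW (mg): the printed baseline SE 4 at n = 4.
VDW_SD = 8.0
#: Default whole-body dry weight distribution (g).
BODY_MEAN, BODY_SD = 10.0, 0.8
#: Carapace length (mm): one common distribution for all cells (the study
#: found no size differences among groups).
CARAPACE_MEAN, CARAPACE_SD = 98.6, 5.0


def mean_se_to_sd(se: float, n: int) -> float:
    """Within-group SD implied by a reported mean +- SE at sample size n."""
    return se * math.sqrt(n)


def organ_params(
    hsi_mean: float,
    hsi_sd: float,
    body_mean: float = BODY_MEAN,
    body_sd: float = BODY_SD,
) -> tuple[float, float]:
    """Hepatopancreas mean/SD (g) inducing a target HSI mean/SD (%).

    HSI is a ratio of two independent normals, so its coefficient of
    variation decomposes approximately as cv_hsi^2 = cv_hep^2 + cv_body^2.
    The hepatopancreas CV is floored at 0.02 when the body-weight variation
    alone already exceeds the target.
    """
    hep_mean = hsi_mean / 100.0 * body_mean
    cv_hsi = hsi_sd / hsi_mean
    cv_body = body_sd / body_mean
    cv_hep = math.sqrt(max(cv_hsi**2 - cv_body**2, 0.02**2))
    return hep_mean, cv_hep * hep_mean


@dataclass(frozen=True)
class CellSpec:
    """True distribution of one design cell."""

    cell: Cell
    n: int
    vdw_mean: float   # mg
    vdw_sd: float
    hep_mean: float   # g
    hep_sd: float
    body_mean: float  # g
    body_sd: float
    cl_mean: float = CARAPACE_MEAN  # mm
    cl_sd: float = CARAPACE_SD

    def validate(self) -> None:
        if self.n < 2:
            raise ConfigError(f"cell {self.cell.label()}: n must be >= 2, got {self.n}")
        for name in ("vdw_mean", "hep_mean", "body_mean", "cl_mean"):
            if not getattr(self, name) > 0:
                raise ConfigError(
                    f"cell {self.cell.label()}: {name} must be > 0"
                )
        for name in ("vdw_sd", "hep_sd", "body_sd", "cl_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(
                    f"cell {self.cell.label()}: {name} must be >= 0"
                )


@dataclass
class SyntheticConfig:
    """Ground truth of a simulated study: one :class:`CellSpec` per cell."""

    cells: list[CellSpec]
    seed: int = 0

    def validate(self) -> None:
        labels = [spec.cell.label() for spec in self.cells]
        if len(set(labels)) != len(labels):
            raise ConfigError("duplicate design cells in config")
        for spec in self.cells:
            spec.validate()

    def spec_for(self, cell: Cell) -> CellSpec:
        for spec in self.cells:
            if spec.cell == cell:
                return spec
        raise ConfigError(f"cell {cell.label()} not in config")

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "cells": [
                {
                    "temperature": s.cell.temperature,
                    "food": s.cell.food,
                    "period_days": s.cell.period_days,
                    "electroejaculated": s.cell.electroejaculated,
                    "n": s.n,
                    "vdw_mean": s.vdw_mean,
                    "vdw_sd": s.vdw_sd,
                    "hep_mean": s.hep_mean,
                    "hep_sd": s.hep_sd,
                    "body_mean": s.body_mean,
                    "body_sd": s.body_sd,
                    "cl_mean": s.cl_mean,
                    "cl_sd": s.cl_sd,
                }
                for s in self.cells
            ],
        }

    @staticmethod
    def from_dict(d: dict) -> "SyntheticConfig":
        cells = []
        for c in d.get("cells", []):
            cell = Cell(
                c["temperature"] if c["temperature"] is not None else None,
                c["food"],
                int(c["period_days"]),
                bool(c["electroejaculated"]),
            )
            cells.append(
                CellSpec(
                    cell=cell,
                    n=int(c["n"]),
                    vdw_mean=float(c["vdw_mean"]),
                    vdw_sd=float(c["vdw_sd"]),
                    hep_mean=float(c["hep_mean"]),
                    hep_sd=float(c["hep_sd"]),
                    body_mean=float(c["body_mean"]),
                    body_sd=float(c["body_sd"]),
                    cl_mean=float(c.get("cl_mean", CARAPACE_MEAN)),
                    cl_sd=float(c.get("cl_sd", CARAPACE_SD)),
                )
            )
        cfg = SyntheticConfig(cells=cells, seed=int(d.get("seed", 0)))
        cfg.validate()
        return cfg


#: (cell, n, vdw_mean mg, hsi_mean %, hsi_sd %) defining the default study.
#: RI trajectory implied by the VDW means, via baselines 84 / 52 mg:
#: 15 d  — 12C fed 30%, 16C fed 100%, 12C deprived 5%, 16C deprived 55%
#: 30 d  — full recovery (100%) everywhere except 165% at 16C deprived.
_DEFAULT_ROWS = (
    (Cell.control_t0(), 4, 84.0, 6.0, 1.0),
    (Cell.depleted_t0(), 4, 52.0, 6.0, 1.0),
    (Cell.recovery(12, "ad_libitum", 15), 5, 61.6, 4.7, 1.0),
    (Cell.recovery(12, "deprived", 15), 5, 53.6, 7.2, 1.0),
    (Cell.recovery(16, "ad_libitum", 15), 5, 84.0, 5.8, 1.0),
    (Cell.recovery(16, "deprived", 15), 5, 69.6, 4.7, 1.0),
    (Cell.recovery(12, "ad_libitum", 30), 5, 84.0, 6.0, 1.57),
    (Cell.recovery(12, "deprived", 30), 5, 84.0, 4.1, 0.89),
    (Cell.recovery(16, "ad_libitum", 30), 4, 84.0, 8.5, 1.6),
    (Cell.recovery(16, "deprived", 30), 4, 104.8, 4.6, 0.4),
)


def default_config(seed: int = 0) -> SyntheticConfig:
    """The study-design defaults (group sizes, means, spreads) as a config."""
    cells = []
    for cell, n, vdw_mean, hsi_mean, hsi_sd in _DEFAULT_ROWS:
        hep_mean, hep_sd = organ_params(hsi_mean, hsi_sd)
        cells.append(
            CellSpec(
                cell=cell,
                n=n,
                vdw_mean=vdw_mean,
                vdw_sd=VDW_SD,
                hep_mean=hep_mean,
                hep_sd=hep_sd,
                body_mean=BODY_MEAN,
                body_sd=BODY_SD,
            )
        )
    cfg = SyntheticConfig(cells=cells, seed=seed)
    cfg.validate()
    return cfg


def _draw_positive(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    """Normal draws truncated at 0 by redraw (no point mass, no clipping)."""
    out = rng.normal(mean, sd, n)
    bad = out <= 0
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = out <= 0
    return out


def generate_study(config: SyntheticConfig) -> StudyTable:
    """Draw one study table from the configured ground truth.

    Deterministic: identical (config, seed) gives an identical table.
    """
    config.validate()
    children = np.random.SeedSequence(config.seed).spawn(len(config.cells))
    records = []
    for spec, ss in zip(config.cells, children):
        rng = np.random.default_rng(ss)
        vdw = _draw_positive(rng, spec.vdw_mean, spec.vdw_sd, spec.n)
        body = _draw_positive(rng, spec.body_mean, spec.body_sd, spec.n)
        hep = _draw_positive(rng, spec.hep_mean, spec.hep_sd, spec.n)
        bad = hep > body
        while bad.any():
            hep[bad] = rng.normal(spec.hep_mean, spec.hep_sd, int(bad.sum()))
            bad = (hep <= 0) | (hep > body)
        cl = _draw_positive(rng, spec.cl_mean, spec.cl_sd, spec.n)
        for i in range(spec.n):
            records.append(
                CrabRecord(
                    crab_id=f"{spec.cell.label()}_{i + 1:02d}",
                    temperature=spec.cell.temperature,
                    food=spec.cell.food,
                    period_days=spec.cell.period_days,
                    electroejaculated=spec.cell.electroejaculated,
                    carapace_length=float(cl[i]),
                    vd_dry_weight=float(vdw[i]),
                    hep_dry_weight=float(hep[i]),
                    body_dry_weight=float(body[i]),
                )
            )
    return StudyTable(records=records, provenance=f"synthetic:seed={config.seed}")


def true_ri(config: SyntheticConfig, cell: Cell) -> float:
    """Ground-truth RI (%) of a recovery cell from the configured means."""
    if cell.period_days == 0:
        raise ConfigError("true_ri is defined for recovery cells (period > 0)")
    try:
        control = config.spec_for(Cell.control_t0())
        depleted = config.spec_for(Cell.depleted_t0())
    except ConfigError as exc:
        raise ConfigError(f"baseline cells missing from config: {exc}") from exc
    target = config.spec_for(cell)
    return ri_from_means(control.vdw_mean, depleted.vdw_mean, target.vdw_mean)


def true_hsi(config: SyntheticConfig, cell: Cell) -> float:
    """Approximate ground-truth HSI (%) of a cell (ratio of mean weights)."""
    spec = config.spec_for(cell)
    return spec.hep_mean / spec.body_mean * 100.0
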