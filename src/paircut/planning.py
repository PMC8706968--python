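"""Poisson MOI conversions and lentivirus titration planning.

Under the Poisson infection model the fraction of uninfected cells is
P(0) = e^(-MOI), so MOI = -ln(1 - P(+)) where P(+) is the
fluorescence-positive fraction measured by FACS.  Screens transduce at MOI
0.5-0.7, i.e. a 39-50% positive fraction, to keep most infected cells at a
single integration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd


class TitrationPoint(NamedTuple):
    volume_ul: float
    positive_fraction: float


def moi_from_fraction(p1: float) -> float:
    """MOI = -ln(1 - p1) for a positive-cell fraction p1 in [0, 1)."""
    if not 0.0 <= p1 < 1.0:
        raise ValueError(f"positive fraction must be in [0, 1), got {p1}")
    return -math.log1p(-p1)


def fraction_from_moi(moi: float) -> float:
    """p1 = 1 - e^(-MOI); inverse of :func:`moi_from_fraction`."""
    if moi < 0:
        raise ValueError(f"MOI must be >= 0, got {moi}")
    return -math.expm1(-moi)


@dataclass(frozen=True)
class InfectionPlan:
    volume_ul: float
    moi_per_ul: float
    target_moi: float
    cells: float
    table: pd.DataFrame


def plan_infection(points: Sequence[TitrationPoint], target_moi: float,
                   cells: float, titration_cells: float = 2e5) -> InfectionPlan:
    """Recommend the virus volume reaching ``target_moi`` on ``cells`` cells.

    Each titration point is converted to MOI and a standard curve
    MOI = k * volume is fit through the origin by least squares (MOI is
    additive in dose, unlike the saturating positive fraction).  The
    recommendation scales with the cell count relative to the titration's
    plating density, keeping dose per cell conserved.
    """
    pts = [TitrationPoint(float(v), float(f)) for v, f in points]
    if len({p.volume_ul for p in pts}) < 2:
        raise ValueError("need >= 2 titration points with distinct volumes")
    for p in pts:
        if p.volume_ul < 0:
            raise ValueError("volumes must be >= 0")
    mois = np.array([moi_from_fraction(p.positive_fraction) for p in pts])
    vols = np.array([p.volume_ul for p in pts])
    if not np.any(mois > 0):
        raise ValueError("all titration fractions are zero: no signal to fit")
    k = float((vols * mois).sum() / (vols * vols).sum())
    volume = target_moi / k * (cells / titration_cells)
    table = pd.DataFrame({
        "volume_ul": vols, "positive_fraction": [p.positive_fraction for p in pts],
        "moi": mois, "fitted_moi": k * vols})
    return InfectionPlan(volume_ul=float(volume), moi_per_ul=k,
                         target_moi=float(target_moi), cells=float(cells),
                         table=table)
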