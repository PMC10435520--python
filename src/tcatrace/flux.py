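"""Extracellular exchange rates from spent-medium bioanalyser data.

For each metabolite, the net amount exchanged over a 48 h culture is the
spent-medium amount minus the amount in cell-free medium incubated in
parallel (which accounts for spontaneous degradation/evaporation),
normalised to the mean of the day-0 and day-2 live-cell counts:

    rate_48h = (amount_spent − amount_cellfree) / ((cells_d0 + cells_d2)/2)

Positive rates are secretion, negative rates consumption.  Concentrations
are converted to absolute amounts with the culture volume (default 1 mL)
before dividing by cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ExchangeInput", "ExchangeRate", "exchange_rate", "growth_metric",
           "exchange_table"]


@dataclass(frozen=True)
class ExchangeInput:
    """Spent vs cell-free medium concentrations with matched cell counts.

    Concentrations are mmol per unit volume; ``volume`` converts them to
    absolute amounts (mmol) and defaults to 1 mL cultures.
    """

    metabolite: str
    conc_spent: float
    conc_cellfree: float
    cells_d0: float
    cells_d2: float
    volume: float = 1.0

    def __post_init__(self) -> None:
        if self.conc_spent < 0 or self.conc_cellfree < 0:
            raise ValueError(f"{self.metabolite}: negative concentration")
        if self.cells_d0 <= 0 or self.cells_d2 <= 0:
            raise ValueError(f"{self.metabolite}: cell counts must be > 0")
        if self.volume <= 0:
            raise ValueError(f"{self.metabolite}: volume must be > 0")


@dataclass(frozen=True)
class ExchangeRate:
    """Signed exchange rate: + secretion, − consumption."""

    metabolite: str
    rate_per_48h: float  # mmol / cell / 48 h
    rate_per_hour: float  # mmol / cell / h


def exchange_rate(inp: ExchangeInput) -> ExchangeRate:
    """Exchange rate per cell over 48 h (and per hour) for one metabolite."""
    delta_amount = (inp.conc_spent - inp.conc_cellfree) * inp.volume
    mean_cells = (inp.cells_d0 + inp.cells_d2) / 2.0
    if mean_cells <= 0:
        raise ValueError(f"{inp.metabolite}: non-positive mean cell count")
    r48 = delta_amount / mean_cells
    return ExchangeRate(inp.metabolite, r48, r48 / 48.0)


def growth_metric(
    density_48h: float, seeding_density: float = 4e5
) -> dict[str, float]:
    """Culture growth over 48 h, reported two ways.

    ``fold_of_quadruple`` divides four times the seeding density by the
    48 h density (the idiosyncratic convention of the source assay: a
    culture that quadruples scores 1); ``doublings`` is the conventional
    log2(density / seeding).  Both are returned because the former is
    ambiguous on its own.
    """
    if density_48h <= 0 or seeding_density <= 0:
        raise ValueError("densities must be > 0")
    return {
        "fold_of_quadruple": 4.0 * seeding_density / density_48h,
        "doublings": float(np.log2(density_48h / seeding_density)),
    }


def exchange_table(df: pd.DataFrame) -> pd.DataFrame:
    """Apply :func:`exchange_rate` to each row of a delimited input table.

    Required columns: metabolite, conc_spent, conc_cellfree, cells_d0,
    cells_d2; optional volume (default 1).
    """
    required = ["metabolite", "conc_spent", "conc_cellfree", "cells_d0",
                "cells_d2"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"exchange table missing columns {missing}")
    rows = []
    for _, row in df.iterrows():
        inp = ExchangeInput(
            metabolite=str(row["metabolite"]),
            conc_spent=float(row["conc_spent"]),
            conc_cellfree=float(row["conc_cellfree"]),
            cells_d0=float(row["cells_d0"]),
            cells_d2=float(row["cells_d2"]),
            volume=float(row.get("volume", 1.0)) if "volume" in df.columns else 1.0,
        )
        r = exchange_rate(inp)
        rows.append(
            {
                "metabolite": r.metabolite,
                "rate_per_48h": r.rate_per_48h,
                "rate_per_hour": r.rate_per_hour,
                "direction": "secretion" if r.rate_per_48h > 0
                else ("consumption" if r.rate_per_48h < 0 else "none"),
            }
        )
    return pd.DataFrame(rows)
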