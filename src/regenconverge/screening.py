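"""Metabolite proliferation-screen normalization and ranking.

The screen measures phase-object confluence (%) in 96-well plates: per
(metabolite, concentration) condition, nominally 6 treated wells against a
shared set of nominally 6 vehicle wells. Relative proliferation is
mean(treated) / mean(vehicle); metabolites are ranked by their best
relative proliferation across tested concentrations. Ranking only -- the
screen carries no significance test.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PLATE_COLUMNS = ("metabolite", "concentration", "well", "group", "confluence")


def _check_plate(plate: pd.DataFrame) -> None:
    missing = set(PLATE_COLUMNS) - set(plate.columns)
    if missing:
        raise ValueError(f"screen plate missing columns: {sorted(missing)}")
    bad = plate["group"][~plate["group"].isin(["treated", "vehicle"])]
    if len(bad):
        raise ValueError(f"unknown group labels: {sorted(set(bad))}")


def relative_proliferation(
    plate: pd.DataFrame,
    metabolite: str,
    concentration: float | None = None,
    min_wells: int = 3,
) -> float:
    """Mean treated confluence over mean vehicle confluence for one condition.

    Vehicle wells are shared across the plate. ``concentration=None`` pools
    all concentrations of the metabolite. Fewer than ``min_wells`` wells on
    either side triggers a warning; a zero vehicle mean is an error.
    """
    _check_plate(plate)
    treated = plate[(plate["group"] == "treated") & (plate["metabolite"] == metabolite)]
    if concentration is not None:
        treated = treated[treated["concentration"] == concentration]
    vehicle = plate[plate["group"] == "vehicle"]
    if treated.empty or vehicle.empty:
        raise ValueError(
            f"condition ({metabolite!r}, {concentration!r}) needs >=1 treated "
            "and >=1 vehicle well"
        )
    for name, wells in (("treated", treated), ("vehicle", vehicle)):
        if len(wells) < min_wells:
            logger.warning(
                "%s wells for (%s, %s): %d below minimum %d",
                name, metabolite, concentration, len(wells), min_wells,
            )
    vehicle_mean = float(vehicle["confluence"].mean())
    if vehicle_mean == 0:
        raise ValueError("vehicle mean confluence is zero; cannot normalize")
    return float(treated["confluence"].mean()) / vehicle_mean


def rank_screen(plate: pd.DataFrame, summary: str = "max") -> pd.DataFrame:
    """Rank metabolites by relative proliferation.

    Per metabolite, the ``max`` (default) or ``mean`` relative
    proliferation across its tested concentrations; the reported "best
    concentration" under ``mean`` is still the argmax condition. Output is
    sorted by relative proliferation descending; ties break toward the
    lower concentration. Every tested metabolite appears exactly once.
    """
    if summary not in ("max", "mean"):
        raise ValueError("summary must be 'max' or 'mean'")
    _check_plate(plate)
    treated = plate[plate["group"] == "treated"]
    if treated.empty:
        raise ValueError("plate has no treated wells")
    rows = []
    for metabolite, sub in treated.groupby("metabolite", sort=False):
        ratios = {
            conc: relative_proliferation(plate, metabolite, conc)
            for conc in sorted(sub["concentration"].unique())
        }
        best_conc = max(ratios, key=lambda c: (ratios[c], -c))
        value = max(ratios.values()) if summary == "max" else float(np.mean(list(ratios.values())))
        rows.append((metabolite, best_conc, value))
    out = pd.DataFrame(
        rows, columns=["metabolite", "best_concentration", "relative_proliferation"]
    )
    out = out.sort_values(
        ["relative_proliferation", "best_concentration"],
        ascending=[False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    out.index = pd.RangeIndex(1, len(out) + 1, name="rank")
    return out
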