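"""Biolog plate modelling and average well color development (AWCD).

AWCD at a time point is the mean over substrate wells of the blank-corrected
OD590, with negative differences clamped to zero:
AWCD(t) = (1/n) * sum_i max(OD_i(t) - OD_control(t), 0).  The per-category
AWCD averages only that category's wells, so the category values, weighted by
well counts, reproduce the overall AWCD exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

CATEGORIES = (
    "amino acids", "monosaccharides", "carboxylic acids", "esters",
    "fatty acids", "hexonic acid", "hexosephosphate", "other",
)

PLATE_CSV_COLUMNS = ("sample_id", "well_id", "carbon_source", "category",
                     "is_control", "time_h", "od590")


@dataclass
class BiologPlate:
    """One sample's plate: well annotations and an OD590 reading matrix.

    ``wells`` (index well_id): carbon_source, category, is_control.
    ``od`` (index well_id, columns time in hours): OD590 readings on a time
    grid shared by every well.  Exactly one control (water blank) well.
    """

    sample_id: str
    wells: pd.DataFrame
    od: pd.DataFrame

    def __post_init__(self) -> None:
        n_control = int(self.wells["is_control"].sum())
        if n_control != 1:
            raise ValueError(
                f"plate {self.sample_id!r}: expected exactly 1 control well, "
                f"found {n_control}"
            )
        if set(self.wells.index) != set(self.od.index):
            raise ValueError(
                f"plate {self.sample_id!r}: wells and readings disagree "
                "(time grid must be shared across wells)"
            )
        if self.od.isna().any().any():
            raise ValueError(
                f"plate {self.sample_id!r}: missing readings; the time grid "
                "must be shared across wells"
            )
        self.od = self.od.loc[self.wells.index]

    @property
    def times(self) -> np.ndarray:
        return np.asarray(self.od.columns, dtype=float)

    @property
    def control_well(self) -> str:
        return self.wells.index[self.wells["is_control"]][0]

    @property
    def substrate_wells(self) -> pd.Index:
        return self.wells.index[~self.wells["is_control"]]


@dataclass
class AwcdResult:
    """AWCD per time point (overall + per category) and the reference scalar."""

    sample_id: str
    curve: pd.DataFrame  # index time_h; columns "overall" + categories
    reference_time: float

    @property
    def reference_awcd(self) -> float:
        """The single reported AWCD value (at the reference time)."""
        return float(self.curve.loc[self.reference_time, "overall"])


def awcd(plate: BiologPlate, t: float) -> pd.Series:
    """Overall and per-category AWCD at one time point."""
    times = list(plate.od.columns)
    if t not in times:
        raise ValueError(f"time {t} not on the plate's grid {times}")
    control = plate.od.loc[plate.control_well, t]
    if pd.isna(control):
        raise ValueError(f"missing control reading at t={t}")
    diffs = (plate.od.loc[plate.substrate_wells, t] - control).clip(lower=0.0)
    cats = plate.wells.loc[plate.substrate_wells, "category"]
    out = {"overall": float(diffs.mean())}
    for cat in sorted(cats.unique()):
        out[cat] = float(diffs[cats == cat].mean())
    return pd.Series(out, name=t)


def awcd_curve(plate: BiologPlate, reference_time: float | None = None) -> AwcdResult:
    """AWCD trajectory over the plate's time grid.

    ``reference_time`` picks the scalar AWCD that is reported per sample
    (default: the final time point).
    """
    times = list(plate.od.columns)
    if len(times) < 2:
        raise ValueError("awcd_curve needs at least 2 time points")
    curve = pd.DataFrame([awcd(plate, t) for t in times])
    curve.index.name = "time_h"
    if reference_time is None:
        reference_time = times[-1]
    if reference_time not in times:
        raise ValueError(f"reference time {reference_time} not on the grid")
    return AwcdResult(sample_id=plate.sample_id, curve=curve,
                      reference_time=reference_time)


def load_substrate_catalog() -> pd.DataFrame:
    """Default 71-substrate catalog (well_id, carbon_source, category).

    The category assignment ships as an editable CSV; swap in a lab-specific
    mapping by passing your own wells table when building plates.
    """
    path = resources.files("wormnet.data") / "biolog_catalog.csv"
    with resources.as_file(path) as p:
        df = pd.read_csv(p)
    return df.set_index("well_id")


def read_plates_csv(path) -> dict[str, BiologPlate]:
    """Read the long-format plate CSV (one row per sample, well, time point)."""
    df = pd.read_csv(path)
    missing = set(PLATE_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"plate CSV missing columns: {sorted(missing)}")
    plates = {}
    for sid, sub in df.groupby("sample_id", sort=False):
        wells = (sub[["well_id", "carbon_source", "category", "is_control"]]
                 .drop_duplicates().set_index("well_id"))
        wells["is_control"] = wells["is_control"].astype(bool)
        od = sub.pivot_table(index="well_id", columns="time_h", values="od590")
        od = od.reindex(index=wells.index)
        plates[str(sid)] = BiologPlate(sample_id=str(sid), wells=wells, od=od)
    return plates


def write_plates_csv(plates: dict[str, BiologPlate], path) -> None:
    rows = []
    for sid, plate in plates.items():
        for well in plate.wells.index:
            info = plate.wells.loc[well]
            for t in plate.od.columns:
                rows.append(
                    {"sample_id": sid, "well_id": well,
                     "carbon_source": info["carbon_source"],
                     "category": info["category"],
                     "is_control": bool(info["is_control"]),
                     "time_h": float(t), "od590": float(plate.od.loc[well, t])}
                )
    pd.DataFrame(rows, columns=list(PLATE_CSV_COLUMNS)).to_csv(path, index=False)


def awcd_table(plates: dict[str, BiologPlate],
               reference_time: float | None = None) -> pd.DataFrame:
    """Reference-time AWCD (overall + categories) per sample, as one table."""
    rows = {}
    for sid, plate in plates.items():
        res = awcd_curve(plate, reference_time)
        rows[sid] = res.curve.loc[res.reference_time]
    out = pd.DataFrame(rows).T
    out.index.name = "sample_id"
    return out
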