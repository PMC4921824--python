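"""Measurement containers and the CSV interchange format.

The on-disk format mirrors the steady-state oligomer experiments: one
row per replicate measurement with the header exactly

    system,total_conc_nM,oligomer_conc_nM,replicate

``system`` is one of ``self_A`` (Aβ40), ``self_B`` (Aβ42) or ``mixed``
(1:1 Aβ40:Aβ42 with cross-colour labelling).  Concentrations are
nanomolar on disk and molar in memory.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

from .exceptions import DataValidationError
from .observation import CROSS, SELF_MIXED, LabelScheme

__all__ = [
    "MeasurementPoint",
    "MeasurementDataset",
    "read_measurements",
    "write_measurements",
    "CSV_COLUMNS",
    "SYSTEMS",
]

CSV_COLUMNS = ["system", "total_conc_nM", "oligomer_conc_nM", "replicate"]
SYSTEMS = ("self_A", "self_B", "mixed")
NM = 1e-9


def default_scheme(system: str) -> LabelScheme:
    return LabelScheme(mode=CROSS if system == "mixed" else SELF_MIXED)


@dataclass(frozen=True)
class MeasurementPoint:
    total_conc: float  # molar
    observed_oligomer_conc: float  # molar
    replicate: str

    def __post_init__(self) -> None:
        if self.total_conc < 0 or self.observed_oligomer_conc < 0:
            raise DataValidationError("concentrations must be non-negative")


@dataclass
class MeasurementDataset:
    """Replicated (total, observed oligomer) measurements for one system."""

    system: str
    points: list[MeasurementPoint]
    label_scheme: LabelScheme = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.system not in SYSTEMS:
            raise DataValidationError(
                f"system must be one of {SYSTEMS}, got {self.system!r}"
            )
        if self.label_scheme is None:
            self.label_scheme = default_scheme(self.system)
        n_distinct = len({p.total_conc for p in self.points})
        if n_distinct < 3:
            raise DataValidationError(
                f"need >= 3 distinct total concentrations, got {n_distinct}"
            )

    def to_frame(self) -> pd.DataFrame:
        """DataFrame with molar columns total_conc, oligomer_conc, replicate."""
        return pd.DataFrame(
            {
                "total_conc": [p.total_conc for p in self.points],
                "oligomer_conc": [p.observed_oligomer_conc for p in self.points],
                "replicate": [p.replicate for p in self.points],
            }
        )

    @classmethod
    def from_arrays(
        cls,
        system: str,
        total_conc: Iterable[float],
        oligomer_conc: Iterable[float],
        replicate: Iterable,
        label_scheme: LabelScheme | None = None,
    ) -> "MeasurementDataset":
        points = [
            MeasurementPoint(float(t), float(o), str(r))
            for t, o, r in zip(total_conc, oligomer_conc, replicate, strict=True)
        ]
        return cls(system=system, points=points, label_scheme=label_scheme)


def _validate_frame(df: pd.DataFrame, path: str) -> None:
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise DataValidationError(f"{path}: missing columns {missing}")
    for col in ("total_conc_nM", "oligomer_conc_nM"):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[numeric.isna() | (numeric < 0)]
        if len(bad):
            rows = ", ".join(str(i + 2) for i in bad[:5])  # +2: header + 0-base
            raise DataValidationError(
                f"{path}: column {col!r} has missing/negative/non-numeric "
                f"values at file row(s) {rows}"
            )
        df[col] = numeric
    unknown = sorted(set(df["system"]) - set(SYSTEMS))
    if unknown:
        raise DataValidationError(f"{path}: unknown system label(s) {unknown}")


def read_measurements(path: str | Path) -> dict[str, MeasurementDataset]:
    """Read a measurement CSV; returns one dataset per system present."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise DataValidationError(f"{path}: file is empty") from exc
    if df.empty:
        raise DataValidationError(f"{path}: no data rows")
    _validate_frame(df, str(path))
    out: dict[str, MeasurementDataset] = {}
    for system, sub in df.groupby("system", sort=False):
        out[str(system)] = MeasurementDataset.from_arrays(
            system=str(system),
            total_conc=sub["total_conc_nM"].to_numpy() * NM,
            oligomer_conc=sub["oligomer_conc_nM"].to_numpy() * NM,
            replicate=sub["replicate"].to_numpy(),
        )
    return out


def write_measurements(datasets: Iterable[MeasurementDataset], path: str | Path) -> None:
    frames = []
    for ds in datasets:
        df = ds.to_frame()
        frames.append(
            pd.DataFrame(
                {
                    "system": ds.system,
                    "total_conc_nM": df["total_conc"] / NM,
                    "oligomer_conc_nM": df["oligomer_conc"] / NM,
                    "replicate": df["replicate"],
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, columns=CSV_COLUMNS)
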