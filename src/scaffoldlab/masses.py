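"""Mass-balance arithmetic for polymer-coated scaffolds.

Coating efficiency (CE) quantifies the polymer mass fraction taken up by a
batch of β-TCP scaffolds during vacuum impregnation:

    CE% = 100 · (weight_after − weight_before) / weight_after

Water absorption capacity (WAC) quantifies retained open porosity of a
coated scaffold after a brief water rinse:

    WAC% = 100 · (wet_weight − dry_weight) / wet_weight

Both are percentages of the *final* (coated / wet) weight.  Polymer-content
and water-content intermediates are always recomputed from the raw weights,
never read from a pre-tabulated content column.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

from scaffoldlab.summary import GroupSummary, summarize

__all__ = [
    "CoatingRow",
    "CoatingBatch",
    "WacRecord",
    "coating_efficiency",
    "batch_ce_summary",
    "water_absorption_capacity",
    "wac_group_summary",
    "read_coating_csv",
    "read_wac_csv",
]


@dataclass(frozen=True)
class CoatingRow:
    """One syringe-batch row: average scaffold weight before/after coating."""

    series_id: str
    syringe_id: str
    n_pieces: int
    weight_before: float  # g
    weight_after: float  # g

    def __post_init__(self) -> None:
        if self.n_pieces < 1:
            raise ValueError("n_pieces must be >= 1")
        if not 0 <= self.weight_before <= self.weight_after:
            raise ValueError(
                "weights must satisfy 0 <= weight_before <= weight_after, got "
                f"before={self.weight_before}, after={self.weight_after}"
            )


@dataclass(frozen=True)
class CoatingBatch:
    rows: tuple[CoatingRow, ...]
    label: str = ""
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "rows", tuple(self.rows))
        if not self.rows:
            raise ValueError("CoatingBatch must contain at least one row")


@dataclass(frozen=True)
class WacRecord:
    """Dry / wet weight pair for one coated scaffold sample."""

    sample_id: str
    dry_weight: float  # g
    wet_weight: float  # g

    def __post_init__(self) -> None:
        if not 0 <= self.dry_weight <= self.wet_weight:
            raise ValueError(
                "weights must satisfy 0 <= dry_weight <= wet_weight, got "
                f"dry={self.dry_weight}, wet={self.wet_weight}"
            )


def coating_efficiency(row: CoatingRow) -> float:
    """Coating efficiency of one batch row, in percent of the coated weight."""
    if row.weight_after == 0:
        raise ZeroDivisionError("weight_after is zero; CE undefined")
    content = row.weight_after - row.weight_before
    return 100.0 * content / row.weight_after


def batch_ce_summary(batch: CoatingBatch) -> GroupSummary:
    """Mean ± sample SD of per-row coating efficiencies."""
    if len(batch.rows) < 2:
        raise ValueError("batch CE summary needs >= 2 rows (sd undefined)")
    return summarize(coating_efficiency(r) for r in batch.rows)


def water_absorption_capacity(rec: WacRecord) -> float:
    """Water absorption capacity of one sample, in percent of the wet weight."""
    if rec.wet_weight == 0:
        raise ZeroDivisionError("wet_weight is zero; WAC undefined")
    content = rec.wet_weight - rec.dry_weight
    return 100.0 * content / rec.wet_weight


def wac_group_summary(
    records: Union[Sequence[WacRecord], Iterable[float]]
) -> GroupSummary:
    """Mean ± sample SD of WAC percentages.

    Accepts either :class:`WacRecord` objects (WAC recomputed from raw
    weights) or pre-computed WAC percentages.
    """
    records = list(records)
    if records and isinstance(records[0], WacRecord):
        values = [water_absorption_capacity(r) for r in records]
    else:
        values = [float(v) for v in records]
    if len(values) < 2:
        raise ValueError("WAC summary needs >= 2 values (sd undefined)")
    return summarize(values)


# --- CSV I/O -----------------------------------------------------------------

_COATING_HEADER = ["series", "syringe", "n_pieces", "weight_before_g", "weight_after_g"]
_WAC_HEADER = ["sample", "dry_g", "wet_g"]


def read_coating_csv(path: Union[str, Path], label: str = "") -> CoatingBatch:
    """Read a coating table (``series,syringe,n_pieces,weight_before_g,weight_after_g``)."""
    rows = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = set(_COATING_HEADER) - set(reader.fieldnames or [])
        if missing:
            raise ValueError(f"coating CSV missing columns: {sorted(missing)}")
        for rec in reader:
            rows.append(
                CoatingRow(
                    series_id=rec["series"],
                    syringe_id=rec["syringe"],
                    n_pieces=int(rec["n_pieces"]),
                    weight_before=float(rec["weight_before_g"]),
                    weight_after=float(rec["weight_after_g"]),
                )
            )
    return CoatingBatch(rows=tuple(rows), label=label or str(path))


def read_wac_csv(path: Union[str, Path]) -> list[WacRecord]:
    """Read a WAC table (``sample,dry_g,wet_g``)."""
    out = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = set(_WAC_HEADER) - set(reader.fieldnames or [])
        if missing:
            raise ValueError(f"WAC CSV missing columns: {sorted(missing)}")
        for rec in reader:
            out.append(
                WacRecord(
                    sample_id=rec["sample"],
                    dry_weight=float(rec["dry_g"]),
                    wet_weight=float(rec["wet_g"]),
                )
            )
    return out


def write_coating_csv(batch: CoatingBatch, path: Union[str, Path]) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_COATING_HEADER)
        for r in batch.rows:
            writer.writerow(
                [r.series_id, r.syringe_id, r.n_pieces, f"{r.weight_before:.6g}", f"{r.weight_after:.6g}"]
            )


def write_wac_csv(records: Sequence[WacRecord], path: Union[str, Path]) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_WAC_HEADER)
        for r in records:
            writer.writerow([r.sample_id, f"{r.dry_weight:.6g}", f"{r.wet_weight:.6g}"])
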