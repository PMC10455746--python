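"""Published reference mass-balance tables for PDL-coated β-TCP scaffolds.

Two small measurement tables from the scaffold-optimization study this
package supports are bundled verbatim so the mass-balance arithmetic can be
validated and demonstrated without access to the original lab records:

* the PDL-04 coating-efficiency table — 16 syringe batches across three
  experimental series (average scaffold weight before / after coating), with
  the per-batch CE percentages as printed alongside,
* the water-absorption table — dry / wet weights of four PDL-02- and four
  PDL-04-coated samples, with the printed per-sample WAC percentages.

Weights are the raw inputs; CE / WAC columns here are the *printed* values
(one decimal) used only to cross-check recomputation from the weights.
"""

from __future__ import annotations

from scaffoldlab.masses import CoatingBatch, CoatingRow, WacRecord

__all__ = [
    "coating_efficiency_table",
    "water_absorption_records",
    "PRINTED_CE_PERCENT",
    "PRINTED_WAC_PERCENT",
]

# (series, syringe, n_pieces, weight_before_g, weight_after_g)
_COATING_ROWS = [
    ("#1", "1", 50, 3.157, 3.684),
    ("#1", "2", 50, 3.285, 3.716),
    ("#1", "3", 55, 3.605, 4.166),
    ("#1", "4", 54, 3.533, 3.761),
    ("#2", "1", 50, 3.283, 3.894),
    ("#2", "2", 50, 3.269, 3.972),
    ("#2", "3", 55, 3.613, 4.487),
    ("#3", "1", 56, 3.662, 4.236),
    ("#3", "2", 55, 3.592, 4.304),
    ("#3", "3", 56, 3.644, 4.262),
    ("#3", "4", 56, 3.646, 4.434),
    ("#3", "5", 56, 3.657, 4.378),
    ("#3", "6", 55, 3.592, 4.112),
    ("#3", "7", 55, 3.579, 4.271),
    ("#3", "8", 55, 3.587, 4.120),
    ("#3", "9", 53, 3.466, 4.003),
]

#: Per-batch coating efficiencies as printed (one decimal), same row order.
PRINTED_CE_PERCENT = [
    14.3, 11.6, 13.5, 6.1, 15.7, 17.7, 19.5, 13.6,
    16.5, 14.5, 17.8, 16.5, 12.6, 16.2, 12.9, 13.4,
]

# (sample, dry_g, wet_g) per coating group
_WAC_ROWS = {
    "PDL-02": [
        ("PDL-02-1", 0.291, 0.384),
        ("PDL-02-2", 0.283, 0.376),
        ("PDL-02-3", 0.283, 0.414),
        ("PDL-02-4", 0.283, 0.345),
    ],
    "PDL-04": [
        ("PDL-04-1", 0.290, 0.334),
        ("PDL-04-2", 0.285, 0.328),
        ("PDL-04-3", 0.288, 0.343),
        ("PDL-04-4", 0.289, 0.342),
    ],
}

#: Per-sample WAC percentages as printed (one decimal), same order as above.
PRINTED_WAC_PERCENT = {
    "PDL-02": [24.4, 24.8, 31.7, 18.0],
    "PDL-04": [13.1, 13.1, 15.8, 15.5],
}


def coating_efficiency_table() -> CoatingBatch:
    """The 16-row PDL-04 coating batch as a :class:`CoatingBatch`."""
    rows = tuple(
        CoatingRow(series_id=s, syringe_id=y, n_pieces=n, weight_before=wb, weight_after=wa)
        for s, y, n, wb, wa in _COATING_ROWS
    )
    return CoatingBatch(rows=rows, label="PDL-04 coating efficiency")


def water_absorption_records() -> dict[str, list[WacRecord]]:
    """Dry/wet weight records per coating group (PDL-02, PDL-04)."""
    return {
        group: [WacRecord(sample_id=s, dry_weight=d, wet_weight=w) for s, d, w in rows]
        for group, rows in _WAC_ROWS.items()
    }
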