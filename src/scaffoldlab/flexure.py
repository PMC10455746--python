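"""3-point-bending analysis of brittle scaffold bars.

For a rectangular bar of width ``w`` and thickness ``b`` on supports a span
``L`` apart, loaded centrally to a breaking load ``P``:

* flexural strength      σ   = 3·P·L / (2·w·b²)          [MPa, with N and mm]
* elastic modulus        E   = m·L³ / (4·w·b³)            from the fitted
  load–deflection slope m (N/mm); equivalent to the beam-theory deflection
  δ = P·L³ / (48·E·I) with the rectangular second moment I = w·b³/12
* elongation at break    A_g = crosshead deflection at maximum load [mm]

The slope is an ordinary-least-squares fit over the 20–80 % of-peak-load
window, the standard linear region for brittle ceramics.  Working in N and
mm yields stresses and moduli directly in MPa.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import numpy as np

from scaffoldlab.summary import GroupSummary, summarize

__all__ = [
    "FlexureSpecimen",
    "FlexureResult",
    "average_dimensions",
    "flexural_strength",
    "elastic_modulus",
    "elongation_at_break",
    "analyze_specimen",
    "flexure_group_summary",
    "read_curve_csv",
    "write_curve_csv",
]


@dataclass(frozen=True)
class FlexureSpecimen:
    """Geometry plus the recorded load–deflection curve of one test bar.

    Width and thickness are measured with a caliper at three points along
    the bar and averaged.
    """

    specimen_id: str
    span: float  # mm, center-to-center support distance
    width_measurements: tuple[float, float, float]  # mm
    thickness_measurements: tuple[float, float, float]  # mm
    curve: np.ndarray  # (n, 2): deflection mm, load N
    break_load: float  # N
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if not self.span > 0:
            raise ValueError("span must be > 0")
        for name, vals in (
            ("width_measurements", self.width_measurements),
            ("thickness_measurements", self.thickness_measurements),
        ):
            vals = tuple(float(v) for v in vals)
            if len(vals) != 3:
                raise ValueError(f"{name} needs exactly 3 caliper readings, got {len(vals)}")
            if any(v <= 0 for v in vals):
                raise ValueError(f"{name} must all be > 0")
            object.__setattr__(self, name, vals)
        curve = np.asarray(self.curve, dtype=float)
        if curve.ndim != 2 or curve.shape[1] != 2 or curve.shape[0] < 1:
            raise ValueError("curve must be an (n>=1, 2) array of (deflection, load)")
        if curve.shape[0] > 1 and not np.all(np.diff(curve[:, 0]) > 0):
            raise ValueError("curve deflection must be strictly increasing")
        if not self.break_load > 0:
            raise ValueError("break_load must be > 0")
        if not np.isclose(self.break_load, float(np.max(curve[:, 1])), rtol=1e-6, atol=1e-9):
            raise ValueError(
                f"break_load ({self.break_load}) must equal the curve's maximum load "
                f"({float(np.max(curve[:, 1]))})"
            )
        object.__setattr__(self, "curve", curve)


@dataclass(frozen=True)
class FlexureResult:
    specimen_id: str
    sigma: float  # MPa
    modulus: float  # MPa
    elongation_at_break: float  # mm
    slope: float  # N/mm

    def __post_init__(self) -> None:
        for name in ("sigma", "modulus", "elongation_at_break", "slope"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def average_dimensions(specimen: FlexureSpecimen) -> tuple[float, float]:
    """Arithmetic means of the three width and three thickness readings (mm)."""
    w = float(np.mean(specimen.width_measurements))
    b = float(np.mean(specimen.thickness_measurements))
    return w, b


def flexural_strength(P: float, span: float, w: float, b: float) -> float:
    """σ = 3·P·L / (2·w·b²) in MPa (inputs in N and mm)."""
    if P < 0:
        raise ValueError("breaking load must be >= 0")
    if span <= 0 or w <= 0 or b <= 0:
        raise ValueError("span, width and thickness must all be > 0")
    return 3.0 * P * span / (2.0 * w * b * b)


def _linear_window(specimen: FlexureSpecimen, lo_frac: float, hi_frac: float) -> np.ndarray:
    load = specimen.curve[:, 1]
    mask = (load >= lo_frac * specimen.break_load) & (load <= hi_frac * specimen.break_load)
    return specimen.curve[mask]


def elastic_modulus(
    specimen: FlexureSpecimen,
    window: tuple[float, float] = (0.2, 0.8),
    min_points: int = 5,
) -> float:
    """Elastic modulus (MPa) from the load–deflection slope.

    OLS slope m over the ``window`` fraction of peak load, converted with
    E = m·L³ / (4·w·b³).
    """
    pts = _linear_window(specimen, *window)
    if pts.shape[0] < min_points:
        raise ValueError(
            f"only {pts.shape[0]} curve points in the {window[0]:.0%}-{window[1]:.0%} "
            f"load window; need >= {min_points}"
        )
    if np.ptp(pts[:, 0]) <= 0:
        raise ValueError("zero deflection range in the linear window; slope undefined")
    m = float(np.polyfit(pts[:, 0], pts[:, 1], 1)[0])
    if m <= 0:
        raise ValueError(f"non-positive fitted slope ({m:.3g} N/mm)")
    w, b = average_dimensions(specimen)
    return m * specimen.span**3 / (4.0 * w * b**3)


def fitted_slope(
    specimen: FlexureSpecimen, window: tuple[float, float] = (0.2, 0.8), min_points: int = 5
) -> float:
    """OLS load–deflection slope m (N/mm) over the linear window."""
    pts = _linear_window(specimen, *window)
    if pts.shape[0] < min_points:
        raise ValueError(f"insufficient points in linear window: {pts.shape[0]} < {min_points}")
    return float(np.polyfit(pts[:, 0], pts[:, 1], 1)[0])


def elongation_at_break(specimen: FlexureSpecimen) -> float:
    """Crosshead deflection (mm) at the point of maximum load."""
    idx = int(np.argmax(specimen.curve[:, 1]))
    return float(specimen.curve[idx, 0])


def analyze_specimen(
    specimen: FlexureSpecimen, window: tuple[float, float] = (0.2, 0.8)
) -> FlexureResult:
    """σ, E and A_g of one specimen."""
    w, b = average_dimensions(specimen)
    sigma = flexural_strength(specimen.break_load, specimen.span, w, b)
    modulus = elastic_modulus(specimen, window=window)
    slope = fitted_slope(specimen, window=window)
    return FlexureResult(
        specimen_id=specimen.specimen_id,
        sigma=sigma,
        modulus=modulus,
        elongation_at_break=elongation_at_break(specimen),
        slope=slope,
    )


def flexure_group_summary(results: Sequence[FlexureResult]) -> dict[str, GroupSummary]:
    """Mean ± sample SD per metric (sigma, modulus, elongation) over specimens."""
    if len(results) < 2:
        raise ValueError("group summary needs >= 2 specimens")
    return {
        "sigma": summarize(r.sigma for r in results),
        "modulus": summarize(r.modulus for r in results),
        "elongation_at_break": summarize(r.elongation_at_break for r in results),
    }


def read_curve_csv(path: Union[str, Path]) -> np.ndarray:
    """Read a load–deflection curve CSV with header ``deflection_mm,load_N``."""
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if set(reader.fieldnames or []) < {"deflection_mm", "load_N"}:
            raise ValueError("curve CSV must have columns deflection_mm,load_N")
        rows = [(float(r["deflection_mm"]), float(r["load_N"])) for r in reader]
    if not rows:
        raise ValueError(f"{path}: empty curve")
    return np.asarray(rows, dtype=float)


def write_curve_csv(curve: np.ndarray, path: Union[str, Path]) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["deflection_mm", "load_N"])
        for d, p in np.asarray(curve, dtype=float):
            writer.writerow([f"{d:.8g}", f"{p:.8g}"])
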