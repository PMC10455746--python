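"""Seeded generators emulating every instrument in the scaffold workflow.

Each generator is a pure function of its model (including the seed) and the
generated objects carry their ground-truth parameters in ``meta``, so the
analysis modules can be tested for exact recovery without a side channel:

* Raman spectra — sums of Gaussian bands over a polynomial baseline with
  additive Gaussian (shot-like) noise, on a 600–1800 cm⁻¹ grid covering
  every marker band; mapping sets add per-spectrum multiplicative amplitude
  jitter, emulating the spatial heterogeneity of a 90–148-point map;
* flexure records — linear-elastic load–deflection curves (beam-theory
  slope m = 4·E·w·b³/L³) terminating in brittle failure at the break load;
* coating mass tables — rows with multiplicative weighing noise around a
  true coating fraction;
* degradation series — exponential pH decay toward an acidic plateau and a
  saturating conductivity rise.

Invalid model parameters are rejected at construction, never clamped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from scaffoldlab.degradation import DegradationSeries
from scaffoldlab.flexure import FlexureSpecimen
from scaffoldlab.masses import CoatingBatch, CoatingRow
from scaffoldlab.raman import RamanSpectrum, SpectrumSet

__all__ = [
    "BandSpec",
    "SpectrumModel",
    "FlexureModel",
    "DegradationModel",
    "DEFAULT_AXIS",
    "default_bands",
    "gen_spectrum",
    "gen_spectrum_set",
    "gen_flexure_curve",
    "gen_mass_table",
    "gen_degradation_series",
]

#: Default wavenumber grid: 600–1800 cm⁻¹ at 1 cm⁻¹ spacing.
DEFAULT_AXIS = np.arange(600.0, 1801.0, 1.0)


@dataclass(frozen=True)
class BandSpec:
    """One Gaussian band of the simulated spectrum."""

    name: str
    center: float  # cm^-1
    amplitude: float  # counts
    sigma: float  # cm^-1

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError(f"band {self.name!r}: sigma must be > 0")
        if self.amplitude < 0:
            raise ValueError(f"band {self.name!r}: amplitude must be >= 0")

    def scaled(self, factor: float) -> "BandSpec":
        return BandSpec(self.name, self.center, self.amplitude * factor, self.sigma)


def default_bands(
    pla: float = 150.0,
    ha: float = 200.0,
    po: float = 120.0,
    phe: float = 60.0,
    carbonate: float = 50.0,
    nu_po: float = 80.0,
    amide3: float = 45.0,
    p_o: float = 40.0,
    ha_sigma: float = 8.0,
) -> tuple[BandSpec, ...]:
    """The eight marker bands with adjustable amplitudes.

    Amplitude defaults give a coated-scaffold-like spectrum: a strong
    phosphate doublet (960/971), a clear PLA band, and weaker matrix bands.
    """
    return (
        BandSpec("pla_874", 874.0, pla, 7.0),
        BandSpec("ha_960", 960.0, ha, ha_sigma),
        BandSpec("po_971", 971.0, po, 7.0),
        BandSpec("phe_1004", 1004.0, phe, 5.0),
        BandSpec("carbonate_1070", 1070.0, carbonate, 9.0),
        BandSpec("nu_po_1091", 1091.0, nu_po, 8.0),
        BandSpec("amide3_1244", 1244.0, amide3, 12.0),
        BandSpec("p_o_1374", 1374.0, p_o, 10.0),
    )


@dataclass(frozen=True)
class SpectrumModel:
    """Generative model of one Raman spectrum."""

    axis: np.ndarray = field(default_factory=lambda: DEFAULT_AXIS.copy())
    bands: tuple[BandSpec, ...] = ()
    baseline_coeffs: tuple[float, ...] = (0.0,)  # ascending powers of cm^-1
    noise_sd: float = 0.0  # counts
    seed: int = 0

    def __post_init__(self) -> None:
        axis = np.asarray(self.axis, dtype=float)
        if axis.ndim != 1 or axis.size < 2:
            raise ValueError("axis must be a 1-D grid with >= 2 points")
        if not np.all(np.diff(axis) > 0):
            raise ValueError("axis must be strictly increasing")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        bands = tuple(self.bands)
        for bd in bands:
            if not (axis[0] <= bd.center <= axis[-1]):
                raise ValueError(
                    f"band {bd.name!r}: center {bd.center} outside axis "
                    f"[{axis[0]}, {axis[-1]}]"
                )
        object.__setattr__(self, "axis", axis)
        object.__setattr__(self, "bands", bands)
        object.__setattr__(self, "baseline_coeffs", tuple(self.baseline_coeffs))


def _band_profile(axis: np.ndarray, bands: Sequence[BandSpec]) -> np.ndarray:
    y = np.zeros_like(axis)
    for bd in bands:
        y += bd.amplitude * np.exp(-((axis - bd.center) ** 2) / (2.0 * bd.sigma**2))
    return y


def _one_spectrum(
    model: SpectrumModel,
    rng: np.random.Generator,
    jitter: float,
    index: int,
    label: str,
) -> RamanSpectrum:
    if jitter > 0:
        factors = rng.normal(1.0, jitter, size=len(model.bands))
        bands = tuple(bd.scaled(max(f, 0.0)) for bd, f in zip(model.bands, factors))
    else:
        bands = model.bands
    y = _band_profile(model.axis, bands)
    y += np.polynomial.polynomial.polyval(model.axis, model.baseline_coeffs)
    if model.noise_sd > 0:
        y += rng.normal(0.0, model.noise_sd, size=model.axis.size)
    meta = {
        "true_bands": bands,
        "model_bands": model.bands,
        "baseline_coeffs": model.baseline_coeffs,
        "noise_sd": model.noise_sd,
        "seed": model.seed,
        "index": index,
        "label": label,
    }
    return RamanSpectrum(axis=model.axis, intensity=y, meta=meta)


def gen_spectrum(model: SpectrumModel) -> RamanSpectrum:
    """One spectrum: Gaussian bands + polynomial baseline + Gaussian noise."""
    rng = np.random.default_rng(model.seed)
    return _one_spectrum(model, rng, jitter=0.0, index=0, label="synthetic")


def gen_spectrum_set(
    model: SpectrumModel, n_spectra: int, jitter: float = 0.0, label: str = "synthetic"
) -> SpectrumSet:
    """A mapping measurement: ``n_spectra`` spectra on one grid.

    Per-spectrum band amplitudes are multiplied by Normal(1, ``jitter``)
    draws (truncated at zero), emulating point-to-point composition
    variation across the mapped area.
    """
    if n_spectra < 1:
        raise ValueError("n_spectra must be >= 1")
    if jitter < 0:
        raise ValueError("jitter must be >= 0")
    rng = np.random.default_rng(model.seed)
    spectra = tuple(
        _one_spectrum(model, rng, jitter=jitter, index=i, label=label)
        for i in range(n_spectra)
    )
    return SpectrumSet(spectra=spectra, label=label)


@dataclass(frozen=True)
class FlexureModel:
    """Generative model of one 3-point-bending record (linear to failure)."""

    E_true: float = 800.0  # MPa
    span: float = 40.0  # mm
    width: float = 6.0  # mm
    thickness: float = 6.0  # mm
    break_load: float = 30.0  # N
    noise_sd: float = 0.0  # N
    seed: int = 0
    n_points: int = 200

    def __post_init__(self) -> None:
        for name in ("E_true", "span", "width", "thickness"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if not self.break_load > 0:
            raise ValueError("break_load must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_points < 2:
            raise ValueError("n_points must be >= 2")

    @property
    def slope(self) -> float:
        """Beam-theory load–deflection slope m = 4·E·w·b³/L³ (N/mm)."""
        return 4.0 * self.E_true * self.width * self.thickness**3 / self.span**3


def gen_flexure_curve(model: FlexureModel, specimen_id: str = "synthetic") -> FlexureSpecimen:
    """Linear-elastic curve from zero to brittle failure at ``break_load``.

    Load noise is additive Gaussian; the final point is pinned to the break
    load so the specimen invariant (break load = curve maximum) holds.
    """
    m = model.slope
    delta_break = model.break_load / m
    deflection = np.linspace(0.0, delta_break, model.n_points)
    load = m * deflection
    if model.noise_sd > 0:
        rng = np.random.default_rng(model.seed)
        load = load + rng.normal(0.0, model.noise_sd, size=load.size)
        load = np.clip(load, 0.0, model.break_load)
    load[0] = 0.0
    load[-1] = model.break_load
    return FlexureSpecimen(
        specimen_id=specimen_id,
        span=model.span,
        width_measurements=(model.width,) * 3,
        thickness_measurements=(model.thickness,) * 3,
        curve=np.column_stack([deflection, load]),
        break_load=model.break_load,
        meta={"E_true": model.E_true, "slope_true": m, "seed": model.seed},
    )


def gen_mass_table(
    true_ce: float,
    n_rows: int,
    base_weight: float = 3.5,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_pieces: int = 50,
) -> CoatingBatch:
    """Coating-batch rows around a true coating fraction ``true_ce``.

    weight_after = weight_before / (1 − true_ce) · Normal(1, noise_sd), so
    the noiseless per-row CE is exactly 100·true_ce and the mean recovered
    CE converges to it as rows accumulate.  Weighing noise is multiplicative
    on both columns.
    """
    if not 0 <= true_ce < 1:
        raise ValueError("true_ce must lie in [0, 1)")
    if n_rows < 1:
        raise ValueError("n_rows must be >= 1")
    if base_weight <= 0:
        raise ValueError("base_weight must be > 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_rows):
        before = base_weight * (rng.normal(1.0, noise_sd) if noise_sd > 0 else 1.0)
        factor = rng.normal(1.0, noise_sd) if noise_sd > 0 else 1.0
        after = before / (1.0 - true_ce) * factor
        after = max(after, before)  # weighing noise cannot make coating mass negative
        rows.append(
            CoatingRow(
                series_id="synthetic",
                syringe_id=str(i + 1),
                n_pieces=n_pieces,
                weight_before=before,
                weight_after=after,
            )
        )
    return CoatingBatch(
        rows=tuple(rows),
        label="synthetic",
        meta={"true_ce": true_ce, "noise_sd": noise_sd, "seed": seed},
    )


@dataclass(frozen=True)
class DegradationModel:
    """Generative model of a pH / conductivity degradation trajectory.

    pH(t) = ph_inf + (ph0 − ph_inf)·exp(−rate·t); conductivity rises with
    initial slope ``cond_rate`` and saturates on the ``duration`` timescale:
    cond(t) = cond0 + cond_rate·T·(1 − exp(−t/T)), T = duration.
    """

    ph0: float = 7.0
    ph_inf: float = 2.0
    rate: float = 0.05  # per day
    cond0: float = 1.0  # µS/cm
    cond_rate: float = 10.0  # µS/cm per day, initial slope
    duration: float = 180.0  # days
    sampling: float = 5.0  # days
    noise_sd: float = 0.0  # per-channel (pH units / µS/cm)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.ph_inf <= self.ph0 <= 14:
            raise ValueError("require 0 <= ph_inf <= ph0 <= 14")
        if self.rate < 0:
            raise ValueError("rate must be >= 0")
        if not self.duration > 0:
            raise ValueError("duration must be > 0")
        if not 0 < self.sampling <= self.duration:
            raise ValueError("sampling must be in (0, duration]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def gen_degradation_series(model: DegradationModel, label: str = "synthetic") -> DegradationSeries:
    """Sampled degradation trajectory with additive per-channel noise.

    Noisy pH values are clipped into the physical [0, 14] range.
    """
    t = np.arange(0.0, model.duration + model.sampling / 2.0, model.sampling)
    ph = model.ph_inf + (model.ph0 - model.ph_inf) * np.exp(-model.rate * t)
    tau = model.duration
    cond = model.cond0 + model.cond_rate * tau * (1.0 - np.exp(-t / tau))
    if model.noise_sd > 0:
        rng = np.random.default_rng(model.seed)
        ph = ph + rng.normal(0.0, model.noise_sd, size=t.size)
        cond = cond + rng.normal(0.0, model.noise_sd, size=t.size)
    ph = np.clip(ph, 0.0, 14.0)
    return DegradationSeries(
        label=label,
        times=t,
        ph=ph,
        conductivity=cond,
        meta={
            "ph0": model.ph0, "ph_inf": model.ph_inf, "rate": model.rate,
            "cond0": model.cond0, "cond_rate": model.cond_rate, "seed": model.seed,
        },
    )
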