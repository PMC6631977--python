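"""Synthetic two-class NIR transflectance spectra of tissue sections.

The generator emulates the statistical structure the classification pipeline
assumes, so every stage is testable without clinical data:

* a shared 12,000 -> 4,000 cm^-1 grid at 4 cm^-1 spacing (2001 points);
* a smooth low-order polynomial baseline plus Gaussian absorption bands at
  the C-H / O-H overtone and combination positions that distinguish valine
  ((CH3)2CH-) from glutamic acid (-(CH2)2COOH): the mutant class raises the
  CH2- and COOH-associated bands and lowers the CH3-associated ones;
* per-sample biological variability (relative band-amplitude scatter drawn
  once per sample) and per-replicate heterogeneity (the mutation can be
  unevenly distributed over a section, so each of the 3 replicate spectra
  re-jitters band amplitudes);
* a fixed additive interference profile per preparation class (paraffin
  embedding or hematoxylin-eosin staining; HE is the stronger disturber);
* per-replicate multiplicative/additive scatter (a*x + b) and white noise.

Samples alternate mutant / wild type in storage order and split into 40
calibration + 12 validation samples per class (3 spectra each).  Everything
is a deterministic function of the seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ParameterError
from .spectra_io import (
    Label,
    PrepClass,
    SpectraSet,
    SpectrumMeta,
    WavenumberGrid,
)


@dataclass(frozen=True)
class BandSpec:
    """One Gaussian absorption band with a signed class-difference shift."""

    center: float  # cm^-1
    width: float  # Gaussian sigma, cm^-1
    amplitude: float  # absorbance units (wild-type baseline)
    class_delta: float = 0.0  # added to mutant amplitude (x effect_size)

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ParameterError("band width must be positive")


#: Band table: C-H overtone/combination and O-H combination positions, with
#: mutant shifts up on CH2/COOH-associated bands and down on CH3-associated
#: ones (valine -> glutamic-acid side-chain substitution).  Delta magnitudes
#: are calibrated once so the default pipeline sits in its intended
#: performance band, and frozen here.
DEFAULT_BANDS: tuple[BandSpec, ...] = (
    BandSpec(8480.0, 60.0, 0.080, -0.035),  # CH3+CH2 second overtone (CH3-rich)
    BandSpec(8163.0, 40.0, 0.050, +0.014),  # CH second overtone
    BandSpec(7355.0, 40.0, 0.100, -0.042),  # CH3 combination
    BandSpec(7263.0, 40.0, 0.090, -0.035),  # CH3 combination
    BandSpec(7186.0, 40.0, 0.090, +0.042),  # CH2 combination
    BandSpec(7080.0, 40.0, 0.100, +0.042),  # CH2 combination
    BandSpec(6944.0, 40.0, 0.060, +0.014),  # CH combination
    BandSpec(5905.0, 35.0, 0.120, -0.049),  # CH3 first overtone
    BandSpec(5872.0, 35.0, 0.110, -0.042),  # CH3 first overtone
    BandSpec(5680.0, 40.0, 0.120, +0.049),  # CH2 first overtone
    BandSpec(5600.0, 50.0, 0.080, +0.014),  # CH first overtone region
    BandSpec(4520.0, 50.0, 0.100, +0.042),  # O-H (COOH) + CH3 combination
    BandSpec(4395.0, 40.0, 0.090, -0.035),  # CH3 combination
    BandSpec(4250.0, 45.0, 0.120, +0.042),  # CH2 + O-H (COOH) combination
)

_INTERFERENCE_BANDS = {
    # paraffin: long-chain CH2 alkane bands, moderate amplitude
    "paraffin": (0.0, (
        (5680.0, 60.0, 0.060),
        (7186.0, 50.0, 0.030),
        (7080.0, 50.0, 0.030),
        (4250.0, 60.0, 0.050),
        (8480.0, 80.0, 0.020),
    )),
    # hematoxylin-eosin: broad absorbance offset plus dye bands; stronger
    "he_stain": (0.05, (
        (5920.0, 120.0, 0.080),
        (6900.0, 150.0, 0.050),
        (4600.0, 150.0, 0.080),
    )),
}

_PREP_FOR_INTERFERENCE = {
    "none": PrepClass.DEPARAFFINIZED,
    "paraffin": PrepClass.PARAFFIN_EMBEDDED,
    "he_stain": PrepClass.STAINED,
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Frozen study conditions for one synthetic dataset."""

    n_samples_per_class: int = 52  # 40 calibration + 12 validation
    n_calibration_per_class: int = 40
    replicates: int = 3
    grid_high: float = 12_000.0
    grid_low: float = 4_000.0
    grid_step: float = 4.0
    bands: tuple[BandSpec, ...] = DEFAULT_BANDS
    effect_size: float = 1.0
    interference: str = "paraffin"  # none | paraffin | he_stain
    scatter_slope_sd: float = 0.05
    scatter_offset_sd: float = 0.02
    noise_sd: float = 0.01
    replicate_jitter_sd: float = 0.10  # relative band-amplitude sd per replicate
    sample_amp_sd: float = 0.05  # relative band-amplitude sd per sample
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates != 3:
            raise ParameterError("the acquisition protocol is 3 replicates per sample")
        if self.n_calibration_per_class >= self.n_samples_per_class:
            raise ParameterError("need at least one validation sample per class")
        for name in (
            "scatter_slope_sd",
            "scatter_offset_sd",
            "noise_sd",
            "replicate_jitter_sd",
            "sample_amp_sd",
        ):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.interference not in _PREP_FOR_INTERFERENCE:
            raise ParameterError(f"unknown interference kind {self.interference!r}")

    def make_grid(self) -> WavenumberGrid:
        values = np.arange(self.grid_high, self.grid_low - self.grid_step / 2, -self.grid_step)
        return WavenumberGrid(values)


def _gaussian(grid: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((grid - center) / width) ** 2)


def _baseline(grid: np.ndarray) -> np.ndarray:
    # gentle upward slope toward low wavenumber, as in tissue transflectance
    u = (grid - 4000.0) / 8000.0  # 1 at 12000, 0 at 4000 cm^-1
    return 0.45 - 0.10 * u - 0.05 * u**2


def interference_profile(kind: str, grid: WavenumberGrid | None = None) -> np.ndarray:
    """Fixed additive interference spectrum for a preparation class.

    Paraffin contributes moderate CH2-region alkane bands; HE stain a broad
    offset plus dye bands of larger amplitude (HE disturbs more strongly).
    The profile is deterministic — identical across calls.
    """
    if kind not in _INTERFERENCE_BANDS:
        raise ParameterError(f"unknown interference kind {kind!r}")
    grid = grid or SyntheticConfig().make_grid()
    values = grid.values
    offset, bands = _INTERFERENCE_BANDS[kind]
    out = np.full_like(values, offset, dtype=float)
    for center, width, amplitude in bands:
        out += amplitude * _gaussian(values, center, width)
    return out


def difference_signature(config: SyntheticConfig) -> np.ndarray:
    """Noise-free expected mutant-minus-wild mean difference spectrum."""
    values = config.make_grid().values
    out = np.zeros_like(values)
    for band in config.bands:
        out += config.effect_size * band.class_delta * _gaussian(
            values, band.center, band.width
        )
    return out


def _clean_spectrum(
    values: np.ndarray,
    bands: Sequence[BandSpec],
    amplitudes: np.ndarray,
) -> np.ndarray:
    out = _baseline(values).copy()
    for band, amp in zip(bands, amplitudes):
        out += amp * _gaussian(values, band.center, band.width)
    return out


def generate(config: SyntheticConfig) -> tuple[SpectraSet, SpectraSet]:
    """Generate (calibration, validation) spectra sets for one seed.

    Mutant and wild-type samples alternate in storage order (mirroring the
    alternating acquisition protocol that avoids drift bias); the first
    ``n_calibration_per_class`` pairs form the calibration set.
    """
    grid = config.make_grid()
    values = grid.values
    rng = np.random.default_rng(config.seed)
    prep = _PREP_FOR_INTERFERENCE[config.interference]
    interference = (
        interference_profile(config.interference, grid)
        if config.interference != "none"
        else np.zeros_like(values)
    )
    base_amps = np.asarray([b.amplitude for b in config.bands])
    deltas = np.asarray([b.class_delta for b in config.bands]) * config.effect_size

    spectra: list[np.ndarray] = []
    meta: list[SpectrumMeta] = []
    for pair in range(config.n_samples_per_class):
        for label in (Label.MUTANT, Label.WILD_TYPE):
            sample_index = len(meta) // config.replicates + 1
            sid = f"S{sample_index:03d}"
            amps = base_amps + (deltas if label is Label.MUTANT else 0.0)
            # per-sample biological variability, one draw per band
            amps = amps * (1.0 + config.sample_amp_sd * rng.standard_normal(amps.size))
            for rep in range(1, config.replicates + 1):
                rep_amps = amps * (
                    1.0 + config.replicate_jitter_sd * rng.standard_normal(amps.size)
                )
                clean = _clean_spectrum(values, config.bands, rep_amps) + interference
                a = 1.0 + config.scatter_slope_sd * rng.standard_normal()
                b = config.scatter_offset_sd * rng.standard_normal()
                noisy = a * clean + b + config.noise_sd * rng.standard_normal(values.size)
                spectra.append(noisy)
                meta.append(
                    SpectrumMeta(sample_id=sid, replicate=rep, prep_class=prep, label=label)
                )

    matrix = np.asarray(spectra)
    n_cal_spectra = 2 * config.n_calibration_per_class * config.replicates
    cal = SpectraSet(grid, matrix[:n_cal_spectra], meta[:n_cal_spectra])
    val = SpectraSet(grid, matrix[n_cal_spectra:], meta[n_cal_spectra:])
    return cal, val
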