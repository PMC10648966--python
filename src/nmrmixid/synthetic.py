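"""Synthetic plant-flavor ¹H-NMR spectra.

Plant flavors are extracts containing dozens of small metabolites, so their
600 MHz ¹H spectra show many narrow Lorentzian lines spread over roughly
0.5-9.5 ppm, one or more dominant solvent resonances (residual CHD₂OD near
3.31 ppm and water near 4.79 ppm, typically far taller than the analyte
lines), a smooth low-order baseline drift, and additive Gaussian noise.
This module generates spectra with exactly that statistical structure so the
whole identification pipeline can be exercised without any measured data.

A formulated flavor (a mixture of mixtures) is emulated as a weighted
superposition of library spectra, optionally diluted: diluting by a fraction
``d`` scales the flavor signal by ``1 - d`` and adds a fixed diluent pattern
(two large lines near 1.1 and 3.5 ppm, echoing propylene glycol) scaled by
``d``, reproducing the peak-masking effect of heavy dilution.

No spin physics is simulated: there is no J-coupling and no lineshape
distortion; peak positions and amplitudes are draws, not assignments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import Spectrum, SpectralLibrary

__all__ = [
    "PeakSpec",
    "FlavorSpec",
    "SimulationConfig",
    "lorentzian",
    "render_spectrum",
    "make_flavor_specs",
    "make_flavor_library",
    "simulate_formulated",
    "DILUENT_PEAKS",
]


@dataclass(frozen=True)
class PeakSpec:
    """One Lorentzian line: center (ppm), half-width at half-maximum (ppm),
    peak amplitude (arbitrary intensity units)."""

    center: float
    width: float
    amplitude: float

    def __post_init__(self) -> None:
        if not (self.width > 0):
            raise ValueError("peak width must be > 0")
        if not (self.amplitude > 0):
            raise ValueError("peak amplitude must be > 0")


@dataclass
class FlavorSpec:
    """Recipe for one synthetic plant-flavor spectrum."""

    name: str
    peaks: list[PeakSpec]
    solvent_peaks: list[PeakSpec] = field(default_factory=list)
    baseline_coeffs: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if len(self.peaks) < 5:
            raise ValueError("a flavor needs at least 5 analyte peaks")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    ``noise_sigma`` is relative to the maximum clean intensity;
    ``dilution_factor`` is the diluent volume fraction in [0, 1).
    """

    n_flavors: int = 12
    axis_min: float = 0.0
    axis_max: float = 11.0
    n_points: int = 4096
    noise_sigma: float = 0.001
    dilution_factor: float = 0.0
    seed: int = 0

    # peak-statistics knobs; defaults emulate a metabolite-rich extract
    n_peaks_range: tuple[int, int] = (30, 80)
    peak_region: tuple[float, float] = (0.5, 9.5)
    width_range: tuple[float, float] = (0.002, 0.01)
    amplitude_range: tuple[float, float] = (0.05, 1.0)
    solvent_centers: tuple[float, ...] = (3.31, 4.79)
    solvent_amplitude_range: tuple[float, float] = (5.0, 20.0)
    solvent_width_range: tuple[float, float] = (0.01, 0.03)
    baseline_scale: float = 0.1

    def __post_init__(self) -> None:
        if self.n_points < 512:
            raise ValueError("n_points must be >= 512")
        if not (0.0 <= self.dilution_factor < 1.0):
            raise ValueError("dilution_factor must be in [0, 1)")
        if self.axis_max <= self.axis_min:
            raise ValueError("axis_max must exceed axis_min")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    @property
    def axis(self) -> np.ndarray:
        return np.linspace(self.axis_min, self.axis_max, self.n_points)


#: Fixed propylene-glycol-like diluent pattern: CH₃ doublet region near
#: 1.1 ppm and CH/CH₂ multiplet region near 3.5 ppm.  Amplitudes are on the
#: solvent scale so heavy dilution visibly masks flavor peaks.
DILUENT_PEAKS: tuple[PeakSpec, ...] = (
    PeakSpec(center=1.10, width=0.008, amplitude=12.0),
    PeakSpec(center=1.13, width=0.008, amplitude=12.0),
    PeakSpec(center=3.45, width=0.012, amplitude=8.0),
    PeakSpec(center=3.55, width=0.012, amplitude=8.0),
    PeakSpec(center=3.90, width=0.012, amplitude=5.0),
)


def lorentzian(axis: np.ndarray, center: float, width: float, amplitude: float) -> np.ndarray:
    """Lorentzian line with unit-free peak height ``amplitude`` at ``center``
    and half-width at half-maximum ``width``."""
    return amplitude * width**2 / ((axis - center) ** 2 + width**2)


def render_spectrum(
    spec: FlavorSpec | None,
    axis: np.ndarray,
    noise_sigma: float = 0.0,
    rng: np.random.Generator | None = None,
    *,
    peaks: list[PeakSpec] | None = None,
    name: str = "",
) -> Spectrum:
    """Render a flavor recipe on a ppm grid.

    intensity = sum of analyte Lorentzians + solvent Lorentzians
    + polynomial baseline + Gaussian noise (sd = noise_sigma x clean max).

    ``peaks`` allows rendering an ad-hoc peak list without a full recipe
    (used for the diluent pattern).
    """
    axis = np.asarray(axis, dtype=np.float64)
    if axis.ndim != 1 or axis.size < 2 or not np.all(np.diff(axis) > 0):
        raise ValueError("axis must be a strictly ascending 1-D grid")
    y = np.zeros_like(axis)
    if spec is not None:
        peak_list = list(spec.peaks) + list(spec.solvent_peaks)
        coeffs = spec.baseline_coeffs
        name = name or spec.name
    else:
        peak_list = list(peaks or [])
        coeffs = ()
    for p in peak_list:
        y += lorentzian(axis, p.center, p.width, p.amplitude)
    if coeffs:
        # coeffs are ascending powers of (ppm - axis midpoint)
        x = axis - 0.5 * (axis[0] + axis[-1])
        y += np.polynomial.polynomial.polyval(x, np.asarray(coeffs, float))
    if noise_sigma > 0:
        if rng is None:
            raise ValueError("rng required when noise_sigma > 0")
        scale = float(np.max(np.abs(y))) if y.any() else 1.0
        y = y + rng.normal(0.0, noise_sigma * scale, size=axis.size)
    return Spectrum(axis, y, name=name)


def make_flavor_specs(config: SimulationConfig) -> list[FlavorSpec]:
    """Draw ``config.n_flavors`` flavor recipes (deterministic per seed)."""
    if config.n_flavors < 2:
        raise ValueError(
            "n_flavors must be >= 2: augmentation needs distinct flavors for negative pairs"
        )
    rng = np.random.default_rng(config.seed)
    width = len(str(config.n_flavors - 1))
    specs = []
    for i in range(config.n_flavors):
        n_peaks = int(rng.integers(config.n_peaks_range[0], config.n_peaks_range[1] + 1))
        peaks = [
            PeakSpec(
                center=float(rng.uniform(*config.peak_region)),
                width=float(rng.uniform(*config.width_range)),
                amplitude=float(rng.uniform(*config.amplitude_range)),
            )
            for _ in range(n_peaks)
        ]
        solvent = [
            PeakSpec(
                center=c,
                width=float(rng.uniform(*config.solvent_width_range)),
                amplitude=float(rng.uniform(*config.solvent_amplitude_range)),
            )
            for c in config.solvent_centers
        ]
        # gentle quadratic drift, positive over the axis span
        span = 0.5 * (config.axis_max - config.axis_min)
        c1 = rng.uniform(-1, 1) * config.baseline_scale / span
        c2 = rng.uniform(0, 1) * config.baseline_scale / span**2
        c0 = config.baseline_scale * rng.uniform(0.5, 1.5) + abs(c1) * span + c2 * span**2
        specs.append(
            FlavorSpec(
                name=f"flavor_{i:0{width}d}",
                peaks=peaks,
                solvent_peaks=solvent,
                baseline_coeffs=(float(c0), float(c1), float(c2)),
            )
        )
    return specs


def make_flavor_library(config: SimulationConfig) -> SpectralLibrary:
    """Render a raw (unpreprocessed) synthetic flavor library.

    Deterministic for a fixed ``config.seed``; spectra are non-negative
    before noise (Lorentzians are positive and the drawn baselines are
    positive over the axis).
    """
    specs = make_flavor_specs(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    axis = config.axis
    rows = [render_spectrum(s, axis, config.noise_sigma, rng).intensity for s in specs]
    return SpectralLibrary([s.name for s in specs], axis, np.vstack(rows))


def simulate_formulated(
    library: SpectralLibrary,
    component_names: list[str],
    weights: list[float] | np.ndarray,
    dilution_factor: float = 0.0,
    rng: np.random.Generator | None = None,
    noise_sigma: float = 0.0,
    name: str = "",
) -> Spectrum:
    """Blend library flavors into a formulated-flavor spectrum.

    intensity = (1 - d) * sum_i w_i * library[i]  +  d * diluent pattern
    + Gaussian noise, with d = ``dilution_factor``.
    """
    if not (0.0 <= dilution_factor < 1.0):
        raise ValueError("dilution_factor must be in [0, 1)")
    weights = np.asarray(weights, dtype=float)
    if len(component_names) != weights.size:
        raise ValueError("one weight per component required")
    if np.any(weights <= 0):
        raise ValueError("weights must be > 0")
    unknown = [n for n in component_names if n not in library.names]
    if unknown:
        raise KeyError(f"unknown component name(s): {unknown}")
    idx = [library.names.index(n) for n in component_names]
    y = weights @ library.matrix[idx]
    y = (1.0 - dilution_factor) * y
    if dilution_factor > 0:
        diluent = render_spectrum(None, library.grid, peaks=list(DILUENT_PEAKS)).intensity
        y = y + dilution_factor * diluent
    if noise_sigma > 0:
        if rng is None:
            raise ValueError("rng required when noise_sigma > 0")
        y = y + rng.normal(0.0, noise_sigma * float(np.max(np.abs(y))), size=y.size)
    return Spectrum(library.grid, y, name=name or "+".join(component_names))
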