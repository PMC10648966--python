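"""Spectrum preprocessing: baseline correction, solvent zeroing,
normalization, and interval cutting.

The pipeline order is fixed: airPLS baseline correction, then solvent-window
zeroing, then max-normalization, then cutting to the informative interval
(default 0.300-10.700 ppm, closed on both ends).  Normalizing *after* the
solvent windows are zeroed amplifies the analyte peaks relative to the
(much taller) solvent resonances — the reverse order would leave analyte
peaks at a tiny fraction of full scale.

airPLS (adaptive iteratively reweighted penalized least squares) estimates a
baseline z minimizing  sum_i w_i (y_i - z_i)^2 + lambda * sum (Delta^2 z)^2,
re-weighting each pass: points sitting above the current baseline (peaks) get
weight 0, points below it get weights growing exponentially with the size of
the negative residual, so the fit sinks to the peak-free envelope.  Iteration
stops when the L1 norm of the negative residuals falls below ``ratio`` times
the L1 norm of the spectrum, or after ``max_iter`` passes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_banded

from .io import Spectrum, SpectralLibrary

__all__ = [
    "PreprocessConfig",
    "airpls_baseline",
    "correct_baseline",
    "zero_solvent",
    "normalize",
    "cut_interval",
    "preprocess_spectrum",
    "preprocess_library",
]

# slack when deciding whether a grid point lies inside a closed ppm interval;
# well below any realistic grid step, only absorbs float representation error
_PPM_EPS = 1e-9


@dataclass
class PreprocessConfig:
    """Preprocessing parameters.

    ``airpls_lambda`` controls baseline smoothness (larger = stiffer; 1e5 is
    the standard default for NMR-length vectors), ``solvent_regions`` are the
    ppm windows zeroed out (defaults cover residual methanol-d4 at 3.31 ppm
    and water at ~4.8 ppm), and ``interval`` is the retained ppm range.
    """

    airpls_lambda: float = 1e5
    airpls_max_iter: int = 15
    airpls_ratio: float = 1e-3
    solvent_regions: tuple[tuple[float, float], ...] = ((3.28, 3.34), (4.70, 5.00))
    interval: tuple[float, float] = (0.300, 10.700)
    normalization: str = "max"

    def __post_init__(self) -> None:
        if self.airpls_lambda <= 0:
            raise ValueError("airpls_lambda must be > 0")
        if self.airpls_max_iter < 1:
            raise ValueError("airpls_max_iter must be >= 1")
        for lo, hi in self.solvent_regions:
            if lo >= hi:
                raise ValueError(f"solvent region ({lo}, {hi}) must have lo < hi")
        if self.interval[0] >= self.interval[1]:
            raise ValueError("interval must have lo < hi")
        if self.normalization != "max":
            raise ValueError("only max-normalization is supported")


def _whittaker(y: np.ndarray, w: np.ndarray, lam: float) -> np.ndarray:
    """Solve (W + lam * D2'D2) z = W y for the pentadiagonal Whittaker system."""
    n = y.size
    # banded representation (upper 2 .. lower 2) of lam * D2'D2 + diag(w)
    ab = np.zeros((5, n))
    # second-difference penalty stencil [1, -4, 6, -4, 1] with edge corrections
    d0 = np.full(n, 6.0)
    d0[[0, -1]] = 1.0
    d0[[1, -2]] = 5.0
    d1 = np.full(n - 1, -4.0)
    d1[[0, -1]] = -2.0
    d2 = np.full(n - 2, 1.0)
    ab[0, 2:] = lam * d2
    ab[1, 1:] = lam * d1
    ab[2, :] = lam * d0 + w
    ab[3, :-1] = lam * d1
    ab[4, :-2] = lam * d2
    return solve_banded((2, 2), ab, w * y)


def airpls_baseline(
    spectrum: Spectrum | np.ndarray,
    lam: float = 1e5,
    max_iter: int = 15,
    ratio: float = 1e-3,
) -> np.ndarray:
    """Estimate a baseline by adaptive iteratively reweighted penalized
    least squares.

    Returns the baseline vector (same length as the input intensities).
    """
    y = spectrum.intensity if isinstance(spectrum, Spectrum) else np.asarray(spectrum, float)
    if y.size < 3:
        raise ValueError("airPLS needs at least 3 points")
    if not np.all(np.isfinite(y)):
        raise ValueError("airPLS input must be finite")
    n = y.size
    w = np.ones(n)
    y_norm = np.abs(y).sum()
    z = y.copy()
    for it in range(1, max_iter + 1):
        z = _whittaker(y, w, lam)
        d = y - z
        neg = d < 0
        dssn = np.abs(d[neg]).sum()
        if dssn < ratio * y_norm or not neg.any():
            break
        w[~neg] = 0.0
        w[neg] = np.exp(it * np.abs(d[neg]) / dssn)
        # anchor the ends so the exponential reweighting cannot detach them
        w[0] = np.exp(it * np.abs(d[neg]).max() / dssn)
        w[-1] = w[0]
    return z


def correct_baseline(spectrum: Spectrum, config: PreprocessConfig | None = None) -> Spectrum:
    """Subtract the airPLS baseline estimate from a spectrum."""
    config = config or PreprocessConfig()
    baseline = airpls_baseline(
        spectrum, config.airpls_lambda, config.airpls_max_iter, config.airpls_ratio
    )
    return spectrum.copy(intensity=spectrum.intensity - baseline)


def zero_solvent(
    spectrum: Spectrum, regions: tuple[tuple[float, float], ...] | list[tuple[float, float]]
) -> Spectrum:
    """Set intensities inside each (lo, hi) ppm window exactly to zero."""
    y = spectrum.intensity.copy()
    for lo, hi in regions:
        if lo >= hi:
            raise ValueError(f"solvent region ({lo}, {hi}) must have lo < hi")
        if hi < spectrum.ppm[0] or lo > spectrum.ppm[-1]:
            raise ValueError(f"solvent region ({lo}, {hi}) lies outside the axis")
        y[(spectrum.ppm >= lo - _PPM_EPS) & (spectrum.ppm <= hi + _PPM_EPS)] = 0.0
    return spectrum.copy(intensity=y)


def normalize(spectrum: Spectrum) -> Spectrum:
    """Scale so the maximum intensity equals 1 (shape-preserving)."""
    peak = float(spectrum.intensity.max())
    if peak <= 0:
        raise ValueError("cannot normalize a spectrum with no positive intensity")
    return spectrum.copy(intensity=spectrum.intensity / peak)


def cut_interval(spectrum: Spectrum, lo: float = 0.300, hi: float = 10.700) -> Spectrum:
    """Keep exactly the points with lo <= ppm <= hi (closed interval)."""
    if lo >= hi:
        raise ValueError("interval must have lo < hi")
    mask = (spectrum.ppm >= lo - _PPM_EPS) & (spectrum.ppm <= hi + _PPM_EPS)
    if mask.sum() < 2:
        raise ValueError(f"interval ({lo}, {hi}) retains fewer than 2 grid points")
    return Spectrum(spectrum.ppm[mask], spectrum.intensity[mask], spectrum.name)


def preprocess_spectrum(spectrum: Spectrum, config: PreprocessConfig | None = None) -> Spectrum:
    """Full pipeline for one spectrum: baseline -> zero solvent -> normalize -> cut."""
    config = config or PreprocessConfig()
    s = correct_baseline(spectrum, config)
    s = zero_solvent(s, config.solvent_regions)
    s = normalize(s)
    return cut_interval(s, *config.interval)


def preprocess_library(
    library: SpectralLibrary, config: PreprocessConfig | None = None
) -> SpectralLibrary:
    """Apply the preprocessing pipeline identically to every library row."""
    config = config or PreprocessConfig()
    processed = [
        preprocess_spectrum(Spectrum(library.grid, row, name), config)
        for name, row in zip(library.names, library.matrix)
    ]
    grid = processed[0].ppm
    return SpectralLibrary(list(library.names), grid, np.vstack([s.intensity for s in processed]))
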