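"""Data augmentation by spectral superposition.

Labeled training pairs are manufactured from a preprocessed flavor library:
a composite ("formulated") spectrum is the sum of 1-5 library spectra, each
multiplied by a random concentration scale in (0.2, 1.0); the reference
spectrum is one library entry, drawn from the composite's components for a
positive pair (label 1) or from the remaining flavors for a negative pair
(label 0).  Each reference receives its own chemical-shift drift (uniform in
±3e-4 ppm, realized by linear interpolation so sub-grid-step drifts are
meaningful) and Gaussian noise draw; the composite receives one noise draw of
its own so that composites built from identical library rows do not share
identical noise.

Datasets are split 8:1:1 into train/validation/test by a seeded shuffle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import SpectralLibrary, Spectrum

__all__ = [
    "SpectralPair",
    "PairSet",
    "AugmentConfig",
    "shift_spectrum",
    "add_noise",
    "sample_pair",
    "generate_dataset",
    "split_dataset",
]


@dataclass
class SpectralPair:
    """One (reference flavor, composite flavor, label) training unit.

    ``label`` is 1 iff the reference's source flavor is among the composite's
    components.  The sampling metadata (component names, scales, drift) is
    kept so label correctness can be audited by construction.
    """

    reference: np.ndarray
    composite: np.ndarray
    label: int
    ref_name: str = ""
    component_names: tuple[str, ...] = ()
    scales: tuple[float, ...] = ()
    shift_ppm: float = 0.0

    def __post_init__(self) -> None:
        if self.reference.shape != self.composite.shape:
            raise ValueError("reference and composite must have equal length")
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")


@dataclass
class PairSet:
    """A pair collection as dense arrays (references/composites: n x P)."""

    references: np.ndarray
    composites: np.ndarray
    labels: np.ndarray
    ref_names: list[str] = field(default_factory=list)
    component_names: list[tuple[str, ...]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if len(self.references) != len(self.composites) or len(self.references) != len(self.labels):
            raise ValueError("references, composites and labels must align")
        if not self.ref_names:
            self.ref_names = [""] * len(self.labels)
        if not self.component_names:
            self.component_names = [()] * len(self.labels)

    def __len__(self) -> int:
        return int(self.labels.size)

    def subset(self, idx: np.ndarray) -> "PairSet":
        idx = np.asarray(idx)
        return PairSet(
            self.references[idx],
            self.composites[idx],
            self.labels[idx],
            [self.ref_names[i] for i in idx],
            [self.component_names[i] for i in idx],
        )

    @classmethod
    def from_pairs(cls, pairs: list[SpectralPair]) -> "PairSet":
        if not pairs:
            empty = np.zeros((0, 0), dtype=np.float32)
            return cls(empty, empty.copy(), np.zeros(0, dtype=np.int8), [], [])
        return cls(
            np.stack([p.reference for p in pairs]).astype(np.float32),
            np.stack([p.composite for p in pairs]).astype(np.float32),
            np.asarray([p.label for p in pairs], dtype=np.int8),
            [p.ref_name for p in pairs],
            [p.component_names for p in pairs],
        )


@dataclass
class AugmentConfig:
    """Augmentation parameters (defaults follow the study design:
    50,000 balanced pairs, 1-5 components, scales 0.2-1.0, drift
    ±3e-4 ppm, split 8:1:1)."""

    n_pairs: int = 50_000
    pos_fraction: float = 0.5
    n_components: tuple[int, int] = (1, 5)
    scale_range: tuple[float, float] = (0.2, 1.0)
    shift_range_ppm: tuple[float, float] = (-3e-4, 3e-4)
    noise_sigma: float = 0.001
    split_ratios: tuple[float, float, float] = (8, 1, 1)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.pos_fraction < 1.0):
            raise ValueError("pos_fraction must be in (0, 1)")
        if not (0 < self.scale_range[0] <= self.scale_range[1] <= 1.0):
            raise ValueError("scale bounds must lie in (0, 1] and be ordered")
        if self.n_components[0] < 1 or self.n_components[0] > self.n_components[1]:
            raise ValueError("n_components range must be ordered and >= 1")
        if self.shift_range_ppm[0] > self.shift_range_ppm[1]:
            raise ValueError("shift range must be ordered")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if len(self.split_ratios) != 3 or any(r < 0 for r in self.split_ratios):
            raise ValueError("split_ratios must be 3 non-negative numbers")


def shift_spectrum(spectrum: Spectrum | tuple[np.ndarray, np.ndarray], delta_ppm: float) -> np.ndarray:
    """Translate a spectrum by ``delta_ppm`` along the axis.

    The shifted signal is re-sampled on the original grid by linear
    interpolation (a feature at c moves to c + delta); out-of-range ends are
    filled with the edge values.  Returns the intensity vector.
    """
    if not np.isfinite(delta_ppm):
        raise ValueError("delta_ppm must be finite")
    if isinstance(spectrum, Spectrum):
        ppm, y = spectrum.ppm, spectrum.intensity
    else:
        ppm, y = spectrum
    if abs(delta_ppm) >= ppm[-1] - ppm[0]:
        raise ValueError("|delta_ppm| must be smaller than the axis span")
    if delta_ppm == 0.0:
        return np.array(y, copy=True)
    return np.interp(ppm, ppm + delta_ppm, y)


def add_noise(intensity: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Add i.i.d. Gaussian noise with sd = sigma x max intensity."""
    intensity = np.asarray(intensity)
    if sigma == 0:
        return np.array(intensity, copy=True)
    scale = float(np.max(intensity)) if intensity.size else 1.0
    return intensity + rng.normal(0.0, sigma * scale, size=intensity.shape)


def sample_pair(
    library: SpectralLibrary,
    positive: bool,
    config: AugmentConfig,
    rng: np.random.Generator,
) -> SpectralPair:
    """Draw one labeled spectral pair from the library.

    Composite: k ~ U{n_components}, k flavors without replacement, each times
    a scale ~ U(scale_range), summed, plus one noise draw.  Reference: a
    component flavor (positive) or one of the remaining flavors (negative),
    with its own drift and noise draw.
    """
    n = len(library)
    k_lo, k_hi = config.n_components
    k_hi = min(k_hi, n if positive else n - 1)
    if n < 2:
        raise ValueError("library must hold at least 2 flavors")
    if not positive and n <= k_lo:
        raise ValueError("library too small to draw a negative pair")
    k = int(rng.integers(k_lo, k_hi + 1))
    comp_idx = rng.choice(n, size=k, replace=False)
    scales = rng.uniform(*config.scale_range, size=k)
    composite = scales @ library.matrix[comp_idx]
    composite = add_noise(composite, config.noise_sigma, rng)

    if positive:
        ref_idx = int(comp_idx[rng.integers(k)])
    else:
        remaining = np.setdiff1d(np.arange(n), comp_idx)
        ref_idx = int(remaining[rng.integers(remaining.size)])
    delta = float(rng.uniform(*config.shift_range_ppm))
    reference = shift_spectrum((library.grid, library.matrix[ref_idx]), delta)
    reference = add_noise(reference, config.noise_sigma, rng)

    names = tuple(library.names[i] for i in comp_idx)
    return SpectralPair(
        reference=reference.astype(np.float32),
        composite=composite.astype(np.float32),
        label=int(positive),
        ref_name=library.names[ref_idx],
        component_names=names,
        scales=tuple(float(s) for s in scales),
        shift_ppm=delta,
    )


def generate_dataset(library: SpectralLibrary, config: AugmentConfig) -> PairSet:
    """Generate ``config.n_pairs`` pairs with an exact class balance of
    round(pos_fraction * n_pairs) positives.  Deterministic per seed."""
    rng = np.random.default_rng(config.seed)
    n_pos = round(config.pos_fraction * config.n_pairs)
    P = library.n_points
    refs = np.empty((config.n_pairs, P), dtype=np.float32)
    comps = np.empty((config.n_pairs, P), dtype=np.float32)
    labels = np.empty(config.n_pairs, dtype=np.int8)
    ref_names: list[str] = []
    comp_names: list[tuple[str, ...]] = []
    for i in range(config.n_pairs):
        pair = sample_pair(library, i < n_pos, config, rng)
        refs[i] = pair.reference
        comps[i] = pair.composite
        labels[i] = pair.label
        ref_names.append(pair.ref_name)
        comp_names.append(pair.component_names)
    return PairSet(refs, comps, labels, ref_names, comp_names)


def split_dataset(
    pairs: PairSet,
    ratios: tuple[float, float, float] = (8, 1, 1),
    rng: np.random.Generator | int | None = None,
) -> tuple[PairSet, PairSet, PairSet]:
    """Shuffle and partition into train/validation/test.

    Validation and test sizes are floor(n * r / sum(r)); the remainder goes
    to the training set, so 50,000 pairs at 8:1:1 split 40,000/5,000/5,000.
    """
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    n = len(pairs)
    total = float(sum(ratios))
    n_val = int(n * ratios[1] / total)
    n_test = int(n * ratios[2] / total)
    n_train = n - n_val - n_test
    perm = rng.permutation(n)
    return (
        pairs.subset(perm[:n_train]),
        pairs.subset(perm[n_train : n_train + n_val]),
        pairs.subset(perm[n_train + n_val :]),
    )
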