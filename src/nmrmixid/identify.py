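"""Mixture identification: which library flavors are in a composite?

A query (formulated-flavor) spectrum s is paired with every row D_i of the
library matrix D (N x P), giving N spectral pairs (s, D_1) ... (s, D_N); the
trained network scores each pair with a presence probability, and every
flavor whose probability is strictly larger than the threshold is flagged as
a candidate.  The report keeps all N entries, sorted by descending
probability (ties broken by name), so raising the threshold can only shrink
the candidate set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import SpectralLibrary, Spectrum
from .network import TrainedModel, PseudoSiameseNetwork

__all__ = ["ReportEntry", "IdentificationReport", "identify", "batch_identify"]


@dataclass(frozen=True)
class ReportEntry:
    name: str
    probability: float
    candidate: bool


@dataclass
class IdentificationReport:
    """Per-library-entry probabilities for one query, threshold-filtered."""

    query_name: str
    entries: list[ReportEntry]
    threshold: float

    @property
    def candidates(self) -> list[str]:
        """Names of flavors with probability strictly above the threshold."""
        return [e.name for e in self.entries if e.candidate]

    @property
    def probabilities(self) -> dict[str, float]:
        return {e.name: e.probability for e in self.entries}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "flavor": [e.name for e in self.entries],
                "probability": [e.probability for e in self.entries],
                "candidate": [e.candidate for e in self.entries],
            }
        )


def identify(
    model: TrainedModel | PseudoSiameseNetwork,
    query: Spectrum,
    library: SpectralLibrary,
    threshold: float = 0.5,
) -> IdentificationReport:
    """Score one query spectrum against every library entry.

    The query must already be preprocessed onto the library grid (same
    pipeline the model was trained with); a grid mismatch is an error, not a
    silent resample, because the model's input statistics would be wrong.
    """
    if query.ppm.size != library.grid.size or not np.allclose(
        query.ppm, library.grid, rtol=0, atol=1e-9
    ):
        raise ValueError("query grid does not match the library grid; preprocess the query first")
    net = model.network if isinstance(model, TrainedModel) else model
    n = len(library)
    comps = np.broadcast_to(
        query.intensity.astype(np.float32), (n, query.intensity.size)
    )
    probs = net.predict_proba(library.matrix.astype(np.float32), np.ascontiguousarray(comps))
    order = sorted(range(n), key=lambda i: (-probs[i], library.names[i]))
    entries = [
        ReportEntry(library.names[i], float(probs[i]), bool(probs[i] > threshold))
        for i in order
    ]
    return IdentificationReport(query.name or "query", entries, threshold)


def batch_identify(
    model: TrainedModel | PseudoSiameseNetwork,
    queries: list[Spectrum],
    library: SpectralLibrary,
    threshold: float = 0.5,
) -> list[IdentificationReport]:
    """Independent per-query identification (one report per query)."""
    return [identify(model, q, library, threshold) for q in queries]
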