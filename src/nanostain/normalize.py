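"""Population intensity normalization and dark-fraction bookkeeping.

Raw per-molecule intensities are converted to *relative intensities* by
dividing by the population's saturation limit — the distinct upper edge of
the intensity distribution, taken to correspond to full intercalation (one
dye per 4 bp).  Because dye binding is heterogeneous, a sample with low
average dye load contains molecules too dark to detect (the *dark
fraction*), so the detected cohort is biased toward brighter molecules;
helpers here quantify both effects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .profilefit import MoleculeSummary

__all__ = [
    "NormalizationResult",
    "IntensityHistogram",
    "estimate_saturation_intensity",
    "relative_intensity",
    "dark_fraction",
    "intensity_histogram",
]

MIN_MOLECULES_FOR_LIMIT = 20


@dataclass
class NormalizationResult:
    saturation_intensity: float
    method_label: str
    relative_intensities: dict
    n_clipped: int  # molecules with relative intensity > 1 (reported, kept)

    def values(self) -> np.ndarray:
        return np.array(list(self.relative_intensities.values()))


@dataclass
class IntensityHistogram:
    bin_edges: np.ndarray
    counts: np.ndarray
    n_total: int


def estimate_saturation_intensity(
    intensities: Sequence[float],
    percentile: float = 0.975,
) -> float:
    """Estimate the saturation-limit intensity as an upper empirical quantile.

    The limit is identified from the measured population itself (ideally a
    pooled, dye-rich or equilibrated cohort so that near-saturated molecules
    are present).  An empirical quantile (default 97.5th percentile) is
    deterministic and robust to a few outliers above the physical limit.
    """
    intensities = np.asarray(intensities, dtype=float)
    if intensities.size < MIN_MOLECULES_FOR_LIMIT:
        raise ValueError(
            f"need at least {MIN_MOLECULES_FOR_LIMIT} molecules to place the "
            "saturation limit; pool samples from the same condition"
        )
    if np.any(intensities <= 0):
        raise ValueError("all intensities must be positive")
    if not 0.0 < percentile <= 1.0:
        raise ValueError("percentile must lie in (0, 1]")
    return float(np.quantile(intensities, percentile))


def relative_intensity(
    summaries: Sequence[MoleculeSummary] | Mapping[object, float],
    saturation_intensity: float,
    method_label: str = "quantile",
) -> NormalizationResult:
    """Divide each molecule's mean intensity by the saturation limit.

    Values above 1 (molecules brighter than the estimated limit) are kept
    and counted in ``n_clipped`` so estimator bias stays visible in QC.
    """
    if saturation_intensity <= 0:
        raise ValueError("saturation_intensity must be positive")
    if isinstance(summaries, Mapping):
        raw = dict(summaries)
    else:
        raw = {
            (s.molecule_id if s.molecule_id is not None else i): s.mean_intensity
            for i, s in enumerate(summaries)
        }
    rel = {k: v / saturation_intensity for k, v in raw.items()}
    n_clipped = sum(1 for v in rel.values() if v > 1.0)
    return NormalizationResult(
        saturation_intensity=float(saturation_intensity),
        method_label=method_label,
        relative_intensities=rel,
        n_clipped=n_clipped,
    )


def dark_fraction(truth_count: int, detected_count: int) -> float:
    """Fraction of molecules below the detection limit: 1 − detected/total."""
    if truth_count < 0 or detected_count < 0:
        raise ValueError("counts must be non-negative")
    if detected_count > truth_count:
        raise ValueError(
            f"detected ({detected_count}) exceeds simulated ({truth_count}): "
            "bookkeeping error"
        )
    if truth_count == 0:
        raise ValueError("truth_count must be positive")
    return 1.0 - detected_count / truth_count


def intensity_histogram(
    values: Sequence[float],
    bin_width: float,
) -> IntensityHistogram:
    """Histogram on contiguous half-open bins [k·w, (k+1)·w) from zero.

    Counts always sum to the number of input values; an empty input yields
    an empty histogram with ``n_total = 0``.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        return IntensityHistogram(np.array([0.0]), np.array([], dtype=int), 0)
    if np.any(values < 0):
        raise ValueError("intensities must be non-negative")
    idx = np.floor(values / bin_width).astype(int)
    counts = np.bincount(idx)
    edges = np.arange(counts.size + 1) * bin_width
    return IntensityHistogram(edges, counts, int(values.size))
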