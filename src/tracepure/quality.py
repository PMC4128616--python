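"""Phred-scale quality conversions and the trace-feature quality model.

The Phred Quality Value of a basecall with error probability ``Pe`` is
``QV = -10 * log10(Pe)``; QV 20 therefore corresponds to a 1% chance that
the call is wrong.  Real capillary basecallers derive ``Pe`` from measured
chromatogram features — peak spacing regularity, the uncalled/called peak
height ratio, and peak resolution.  :func:`assign_qualities` implements a
deliberately simple monotone model over those same three features: the
error probability is a non-negative weighted sum, clipped to a floor and a
ceiling.  A base whose strongest non-called channel rivals the called
channel (ratio near 1, as at a divergent position in a mixed-template
trace) is driven to the ceiling and lands far below QV 20.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "QualityModelParams",
    "PeakFeatures",
    "pe_to_qv",
    "qv_to_pe",
    "assign_qualities",
]


def pe_to_qv(pe: float) -> float:
    """Convert a basecall error probability to a Phred quality value.

    Returns the exact (unrounded) value ``-10 * log10(pe)``.  Callers that
    store QVs round to the nearest integer.
    """
    pe = np.asarray(pe, dtype=float)
    if np.any(pe <= 0) or np.any(pe > 1):
        raise ValueError("error probability must lie in (0, 1]")
    out = -10.0 * np.log10(pe)
    return float(out) if out.ndim == 0 else out


def qv_to_pe(qv: float) -> float:
    """Convert a Phred quality value back to an error probability."""
    qv = np.asarray(qv, dtype=float)
    if np.any(qv < 0):
        raise ValueError("quality value must be non-negative")
    out = 10.0 ** (-qv / 10.0)
    return float(out) if out.ndim == 0 else out


@dataclass
class QualityModelParams:
    """Weights and clipping bounds of the feature-to-Pe model.

    Defaults give a base with equal called and uncalled peaks (ratio 1) an
    error probability of at least 0.5 — a 50:50 mixed base is uncallable —
    while a clean, well-resolved, evenly spaced base sits at the floor
    (``pe_floor`` = 1e-4, i.e. QV 40).
    """

    w_ratio: float = 0.5    # weight on uncalled/called peak height ratio
    w_res: float = 0.3      # weight on (1 - peak resolution)
    w_space: float = 0.2    # weight on normalised peak-spacing deviation
    pe_floor: float = 1e-4
    pe_ceiling: float = 0.75

    def validate(self) -> None:
        if min(self.w_ratio, self.w_res, self.w_space) < 0:
            raise ValueError("feature weights must be non-negative")
        if self.w_ratio + self.w_res + self.w_space <= 0:
            raise ValueError("at least one feature weight must be positive")
        if not (0 < self.pe_floor < self.pe_ceiling <= 1):
            raise ValueError("require 0 < pe_floor < pe_ceiling <= 1")


@dataclass
class PeakFeatures:
    """Per-base chromatogram features measured at each called peak."""

    primary: np.ndarray       # called-channel peak height
    secondary: np.ndarray     # tallest non-called channel at the same scan
    resolution: np.ndarray    # valley-to-peak separation from neighbours, in [0, 1]
    spacing_dev: np.ndarray   # |observed - mean spacing| / mean spacing, >= 0

    def __post_init__(self) -> None:
        self.primary = np.asarray(self.primary, dtype=float)
        self.secondary = np.asarray(self.secondary, dtype=float)
        self.resolution = np.asarray(self.resolution, dtype=float)
        self.spacing_dev = np.asarray(self.spacing_dev, dtype=float)
        n = {len(self.primary), len(self.secondary),
             len(self.resolution), len(self.spacing_dev)}
        if len(n) != 1:
            raise ValueError("feature arrays must have equal length")

    def __len__(self) -> int:
        return len(self.primary)


def assign_qualities(features: PeakFeatures,
                     params: QualityModelParams | None = None) -> np.ndarray:
    """Map per-base peak features to integer Phred quality values.

    Per base ``i``::

        pe_i = clip(w_ratio * secondary_i / primary_i
                    + w_res * (1 - resolution_i)
                    + w_space * spacing_dev_i,
                    pe_floor, pe_ceiling)
        qv_i = round(-10 * log10(pe_i))

    A base with ``primary_i == 0`` carries no signal and is assigned the
    ceiling error probability.  The mapping is monotone: increasing the
    uncalled/called ratio or decreasing the resolution never raises a QV.
    """
    if params is None:
        params = QualityModelParams()
    params.validate()
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(features.primary > 0,
                         features.secondary / features.primary, np.inf)
    pe = (params.w_ratio * ratio
          + params.w_res * (1.0 - features.resolution)
          + params.w_space * features.spacing_dev)
    pe = np.clip(pe, params.pe_floor, params.pe_ceiling)
    pe = np.where(features.primary > 0, pe, params.pe_ceiling)
    return np.rint(pe_to_qv(pe)).astype(np.int64)
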