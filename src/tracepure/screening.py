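"""Sub-QV20 purity statistic and unialgal classification.

A culture's Sanger read, after quality trimming, is summarised by the
fraction of retained basecalls whose QV falls strictly below 20 (i.e. whose
error probability exceeds 1%).  In a trace amplified from a single template
that fraction is essentially zero; template mixtures produce ambiguous
double peaks at every divergent position, depressing the QV there, so the
fraction grows with both the divergence and the minority proportion.  A
trimmed read is classified *unialgal* when the fraction is strictly smaller
than 1% (default), *mixed* otherwise, and *indeterminate* when trimming
found no usable 5' window.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .trace_io import Read, read_abif, read_fasta_qual, to_read
from .trimming import TrimParams, TrimResult, trim_read

__all__ = [
    "PurityParams",
    "PurityResult",
    "subqv_fraction",
    "classify",
    "screen_batch",
    "REPORT_COLUMNS",
]

UNIALGAL = "unialgal"
MIXED = "mixed"
INDETERMINATE = "indeterminate"

REPORT_COLUMNS = ["id", "status", "start", "end", "retained_length",
                  "n_subthreshold", "percent_subthreshold", "classification",
                  "note"]


@dataclass
class PurityParams:
    """Threshold of the purity rule: strictly fewer than
    ``max_bad_fraction`` of retained calls may fall strictly below
    ``qv_threshold``."""

    qv_threshold: int = 20
    max_bad_fraction: float = 0.01

    def validate(self) -> None:
        if not (0 < self.max_bad_fraction < 1):
            raise ValueError("max_bad_fraction must lie in (0, 1)")
        if self.qv_threshold < 0:
            raise ValueError("qv_threshold must be >= 0")


@dataclass
class PurityResult:
    id: str
    classification: str
    retained_length: int = 0
    n_subthreshold: int = 0
    fraction_subthreshold: float = float("nan")
    note: str = ""

    @property
    def percent_subthreshold(self) -> float:
        """Sub-threshold percentage, rounded to 2 decimals for reporting."""
        if np.isnan(self.fraction_subthreshold):
            return float("nan")
        return round(100.0 * self.fraction_subthreshold, 2)


def subqv_fraction(qualities: np.ndarray, qv_threshold: int = 20) -> tuple[int, float]:
    """Count and fraction of calls strictly below ``qv_threshold``.

    Calls at exactly the threshold are not counted.
    """
    q = np.asarray(qualities)
    if len(q) == 0:
        raise ValueError("cannot compute sub-QV fraction of an empty quality array")
    count = int((q < qv_threshold).sum())
    return count, count / len(q)


def classify(trim: TrimResult, params: PurityParams | None = None) -> PurityResult:
    """Classify one trimmed read as unialgal, mixed or indeterminate.

    The unialgal call requires a successful trim *and* a sub-threshold
    fraction strictly below ``max_bad_fraction`` — a read with exactly 1.0%
    sub-QV20 calls is mixed under the default rule.
    """
    if params is None:
        params = PurityParams()
    params.validate()
    if trim.status != "trimmed":
        return PurityResult(id=trim.id, classification=INDETERMINATE,
                            note="no 5' window passed quality trimming")
    count, fraction = subqv_fraction(trim.read.qualities, params.qv_threshold)
    label = UNIALGAL if fraction < params.max_bad_fraction else MIXED
    return PurityResult(id=trim.id, classification=label,
                        retained_length=trim.retained_length,
                        n_subthreshold=count, fraction_subthreshold=fraction)


def _load_input(item) -> Iterable[Read]:
    """Yield reads from one batch input: an ``.ab1`` path or a
    ``(fasta, qual)`` pair."""
    if isinstance(item, (tuple, list)) and len(item) == 2:
        yield from read_fasta_qual(item[0], item[1])
        return
    path = Path(item)
    record = read_abif(path)
    read = to_read(record)
    if not record.name:
        read.id = path.stem
    yield read


def screen_batch(inputs: Sequence,
                 trim_params: TrimParams | None = None,
                 purity_params: PurityParams | None = None) -> pd.DataFrame:
    """Screen a batch of traces; one report row per read.

    Inputs may mix ``.ab1`` paths and ``(fasta, qual)`` path pairs.  A file
    that cannot be read contributes an indeterminate row carrying the error
    message; it never aborts the rest of the batch.  Trim coordinates in
    the report are 1-based inclusive.
    """
    rows = []
    for item in inputs:
        try:
            reads = list(_load_input(item))
        except (OSError, ValueError) as exc:
            name = Path(item).stem if not isinstance(item, (tuple, list)) \
                else Path(item[0]).stem
            rows.append({"id": name, "status": "error", "start": None,
                         "end": None, "retained_length": 0,
                         "n_subthreshold": None, "percent_subthreshold": None,
                         "classification": INDETERMINATE, "note": str(exc)})
            continue
        for read in reads:
            trim = trim_read(read, trim_params)
            result = classify(trim, purity_params)
            rows.append({
                "id": result.id,
                "status": trim.status,
                # user-facing coordinates are 1-based inclusive
                "start": None if trim.start is None else trim.start + 1,
                "end": trim.end,
                "retained_length": result.retained_length,
                "n_subthreshold": result.n_subthreshold
                if trim.status == "trimmed" else None,
                "percent_subthreshold": result.percent_subthreshold
                if trim.status == "trimmed" else None,
                "classification": result.classification,
                "note": result.note,
            })
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)
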