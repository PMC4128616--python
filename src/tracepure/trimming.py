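"""Two-rule Phred-quality trimming of Sanger reads.

The trimmer applies two sequential window scans to the per-base QV array:

* **5' rule** — skip the first ``head_skip`` bases (capillary reads start
  with an unavoidable low-quality ramp), then keep from the first position
  where a ``window``-long run of consecutive calls is *strictly above* the
  QV threshold.
* **3' rule** — scanning only after ``tail_scan_start`` bases past the 5'
  trim point (so every passing read keeps a floor-length segment long
  enough for a reliable purity assessment), cut immediately before the
  first ``window``-long run that contains *more than* ``max_bad_in_window``
  calls strictly below the threshold.

All comparisons are strict: a call at exactly the threshold QV is neither
good enough for the 5' rule nor bad enough for the 3' rule.  A read with
no qualifying 5' window is reported as ``failed_head`` rather than trimmed
to nothing; downstream classification treats it as indeterminate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .trace_io import Read

__all__ = ["TrimParams", "TrimResult", "find_head_trim", "find_tail_trim", "trim_read"]


@dataclass
class TrimParams:
    """Thresholds of the two-rule trimmer.

    ``head_skip`` defaults to the lower bound of the customary 25-35 base
    ramp allowance; the scan itself then finds the first clean window, so a
    longer ramp only moves the trim point later, never earlier.
    """

    qv_threshold: int = 20
    head_skip: int = 25
    window: int = 20
    tail_scan_start: int = 350
    max_bad_in_window: int = 1

    def validate(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if min(self.head_skip, self.tail_scan_start, self.max_bad_in_window) < 0:
            raise ValueError("head_skip, tail_scan_start and max_bad_in_window must be >= 0")


@dataclass
class TrimResult:
    """Outcome of trimming one read.

    ``status`` is ``"trimmed"`` or ``"failed_head"``.  For a trimmed read,
    ``[start, end)`` is the retained 0-based half-open interval on the
    original read and ``read`` carries the retained bases and QVs.
    """

    status: str
    id: str
    start: Optional[int] = None
    end: Optional[int] = None
    read: Optional[Read] = None

    @property
    def retained_length(self) -> int:
        if self.status != "trimmed":
            return 0
        return self.end - self.start


def find_head_trim(qualities: np.ndarray,
                   params: TrimParams | None = None) -> Optional[int]:
    """Locate the 5' trim point, or ``None`` when no clean window exists.

    Returns the smallest ``s >= head_skip`` such that every call in the
    window ``qualities[s : s + window]`` is strictly above the threshold.
    The window is truncated at the read end (a clean run that ends exactly
    at the read end qualifies), but must contain at least one call.
    """
    if params is None:
        params = TrimParams()
    params.validate()
    q = np.asarray(qualities)
    n = len(q)
    if n <= params.head_skip:
        return None
    good = q > params.qv_threshold
    w = params.window
    # next_bad[s] = first sub-threshold position at or after s (n if none);
    # the window starting at s is clean iff next_bad[s] falls past its end
    bad_idx = np.flatnonzero(~good)
    next_bad = np.full(n, n, dtype=np.int64)
    if len(bad_idx):
        next_bad[bad_idx] = bad_idx
        next_bad = np.minimum.accumulate(next_bad[::-1])[::-1]
    starts = np.arange(params.head_skip, n)
    window_end = np.minimum(starts + w, n)
    ok = next_bad[starts] >= window_end
    hits = np.flatnonzero(ok)
    if len(hits) == 0:
        return None
    return int(starts[hits[0]])


def find_tail_trim(qualities: np.ndarray, start: int,
                   params: TrimParams | None = None) -> int:
    """Locate the 3' cut point for a read whose 5' trim point is ``start``.

    Scanning window offsets ``s >= tail_scan_start`` measured from
    ``start``, returns ``start + s`` for the first full window
    ``qualities[start+s : start+s+window]`` holding strictly more than
    ``max_bad_in_window`` calls strictly below the threshold; returns the
    read length when no such window exists (including reads too short for
    the scan to begin).
    """
    if params is None:
        params = TrimParams()
    params.validate()
    q = np.asarray(qualities)
    n = len(q)
    w = params.window
    first = start + params.tail_scan_start
    if first + w > n:
        return n
    bad = (q < params.qv_threshold).astype(np.int64)
    csum = np.concatenate(([0], np.cumsum(bad)))
    starts = np.arange(first, n - w + 1)
    counts = csum[starts + w] - csum[starts]
    hits = np.flatnonzero(counts > params.max_bad_in_window)
    if len(hits) == 0:
        return n
    return int(starts[hits[0]])


def trim_read(read: Read, params: TrimParams | None = None) -> TrimResult:
    """Apply the 5' then the 3' rule to a read.

    Returns a ``failed_head`` result when no clean 5' window exists;
    otherwise the retained interval ``[start, end)`` applied to both the
    sequence and the quality array.
    """
    if params is None:
        params = TrimParams()
    start = find_head_trim(read.qualities, params)
    if start is None:
        return TrimResult(status="failed_head", id=read.id)
    end = find_tail_trim(read.qualities, start, params)
    trimmed = Read(id=read.id, sequence=read.sequence[start:end],
                   qualities=read.qualities[start:end])
    return TrimResult(status="trimmed", id=read.id, start=start, end=end, read=trimmed)
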