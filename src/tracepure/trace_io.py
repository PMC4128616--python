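"""Read and write Sanger trace files (ABIF ``.ab1``) and FASTA+QUAL pairs.

The ABIF container is a big-endian tagged directory of typed records.  Only
the tags this pipeline needs are handled: processed channel intensities
(``DATA`` 9-12), peak locations (``PLOC``), basecalls (``PBAS``), per-base
quality values (``PCON``) and the channel-to-dye order (``FWO_``), plus two
free-text metadata tags.  The reader prefers tag number 1 and falls back to
tag number 2, which covers the variants common basecallers emit; the writer
emits tag number 1 only.

Coordinates are 0-based half-open throughout; 1-based positions appear only
in user-facing reports produced elsewhere.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TraceRecord",
    "Read",
    "AbifError",
    "read_abif",
    "write_abif",
    "read_fasta_qual",
    "write_fasta_qual",
    "to_read",
]

#: Nucleotide order used for the in-memory channel dictionary.
BASES = "ACGT"

QV_MAX = 93  # printable Phred ceiling; larger values indicate corrupt data
_INTENSITY_MAX = 32767  # ABIF stores processed channels as signed shorts

_MAGIC = b"ABIF"
_HEADER_SIZE = 128
_DIR_FMT = ">4sihhiiii"  # name, number, elem type, elem size, count, size, offset, handle
_DIR_SIZE = struct.calcsize(_DIR_FMT)

# ABIF element type codes used by the writer
_T_BYTE, _T_CHAR, _T_SHORT, _T_PSTRING = 1, 2, 4, 18


class AbifError(ValueError):
    """Raised for files that are not, or are no longer, valid ABIF traces."""


@dataclass
class TraceRecord:
    """A processed Sanger chromatogram.

    Parameters
    ----------
    channels : dict
        Maps each nucleotide in ``ACGT`` to a non-negative intensity array
        indexed by scan number; all four arrays have equal length.
    channel_order : str
        Permutation of ``ACGT`` giving the nucleotide assigned to each of
        the four ``DATA`` slots in the file (the ``FWO_`` tag).
    peak_positions : ndarray
        Per-base scan index of the called peak, strictly increasing.
    basecalls : str
        Called bases (IUPAC), one per peak.
    qualities : ndarray
        Per-base Phred quality values, integers in ``[0, 93]``.
    """

    channels: dict[str, np.ndarray]
    peak_positions: np.ndarray
    basecalls: str
    qualities: np.ndarray
    channel_order: str = "GATC"
    name: str = ""
    instrument: str = ""

    def __post_init__(self) -> None:
        self.channels = {b: np.asarray(v, dtype=np.int64) for b, v in self.channels.items()}
        self.peak_positions = np.asarray(self.peak_positions, dtype=np.int64)
        self.qualities = np.asarray(self.qualities, dtype=np.int64)

    @property
    def n_bases(self) -> int:
        return len(self.basecalls)

    @property
    def n_scans(self) -> int:
        return len(next(iter(self.channels.values()))) if self.channels else 0

    def validate(self) -> None:
        """Raise ``AbifError`` if any structural invariant is violated."""
        if sorted(self.channels) != sorted(BASES):
            raise AbifError("corrupt trace: channels must cover A, C, G and T")
        if sorted(self.channel_order) != sorted(BASES):
            raise AbifError("corrupt trace: channel_order must be a permutation of ACGT")
        lengths = {len(v) for v in self.channels.values()}
        if len(lengths) != 1:
            raise AbifError("corrupt trace: channel arrays differ in length")
        if any((v < 0).any() for v in self.channels.values()):
            raise AbifError("corrupt trace: negative channel intensity")
        if any((v > _INTENSITY_MAX).any() for v in self.channels.values()):
            raise AbifError("corrupt trace: channel intensity exceeds %d" % _INTENSITY_MAX)
        n = self.n_bases
        if not (len(self.qualities) == n == len(self.peak_positions)):
            raise AbifError("corrupt trace: basecall/quality/peak length mismatch")
        if n:
            if self.qualities.min() < 0 or self.qualities.max() > QV_MAX:
                raise AbifError("corrupt trace: quality values outside [0, %d]" % QV_MAX)
            if (np.diff(self.peak_positions) <= 0).any():
                raise AbifError("corrupt trace: peak positions not strictly increasing")
            if self.peak_positions[0] < 0 or self.peak_positions[-1] >= self.n_scans:
                raise AbifError("corrupt trace: peak position outside channel bounds")


@dataclass
class Read:
    """A called sequence with parallel per-base quality values."""

    id: str
    sequence: str
    qualities: np.ndarray = field(default_factory=lambda: np.array([], dtype=np.int64))

    def __post_init__(self) -> None:
        self.qualities = np.asarray(self.qualities, dtype=np.int64)
        if len(self.sequence) != len(self.qualities):
            raise ValueError("sequence and qualities differ in length")
        if len(self.qualities) and (
            self.qualities.min() < 0 or self.qualities.max() > QV_MAX
        ):
            raise ValueError("quality values outside [0, %d]" % QV_MAX)

    def __len__(self) -> int:
        return len(self.sequence)


def to_read(record: TraceRecord) -> Read:
    """Project a :class:`TraceRecord` onto its basecalls and qualities."""
    return Read(id=record.name or "trace", sequence=record.basecalls,
                qualities=record.qualities.copy())


# ---------------------------------------------------------------------------
# ABIF writing

def _pack_entries(tags: list[tuple[bytes, int, int, int, int, bytes]]) -> bytes:
    """Lay out tag payloads after the header and append the directory."""
    blobs = []
    offset = _HEADER_SIZE
    entries = []
    for name, number, etype, esize, count, data in tags:
        size = len(data)
        if size <= 4:
            # small payloads live inline in the offset field, left-justified
            inline = data.ljust(4, b"\x00")
            entries.append(struct.pack(_DIR_FMT, name, number, etype, esize,
                                       count, size, int.from_bytes(inline, "big"), 0))
        else:
            entries.append(struct.pack(_DIR_FMT, name, number, etype, esize,
                                       count, size, offset, 0))
            blobs.append(data)
            offset += size
    dir_offset = offset
    body = b"".join(blobs) + b"".join(entries)
    header = _MAGIC + struct.pack(">h", 101)
    header += struct.pack(_DIR_FMT, b"tdir", 1, 1023, _DIR_SIZE,
                          len(tags), len(tags) * _DIR_SIZE, dir_offset, 0)
    header = header.ljust(_HEADER_SIZE, b"\x00")
    return header + body


def write_abif(record: TraceRecord, path) -> None:
    """Write ``record`` as a minimal valid ABIF file.

    Emits tags ``DATA9-12`` (channels in ``FWO_`` order), ``PLOC1``,
    ``PBAS1``, ``PCON1``, ``FWO_1``, and pascal-string metadata ``SMPL1``
    / ``MCHN1``.  ``read_abif`` recovers the record exactly.
    """
    record.validate()

    def shorts(a: np.ndarray) -> bytes:
        return np.asarray(a, dtype=">i2").tobytes()

    tags: list[tuple[bytes, int, int, int, int, bytes]] = []
    for slot, base in enumerate(record.channel_order):
        data = shorts(record.channels[base])
        tags.append((b"DATA", 9 + slot, _T_SHORT, 2, len(record.channels[base]), data))
    tags.append((b"FWO_", 1, _T_CHAR, 1, 4, record.channel_order.encode("ascii")))
    # real traces carry both the edited (1) and basecaller (2) copies;
    # emitting both keeps third-party viewers and parsers happy
    for number in (1, 2):
        tags.append((b"PLOC", number, _T_SHORT, 2, record.n_bases,
                     shorts(record.peak_positions)))
        tags.append((b"PBAS", number, _T_CHAR, 1, record.n_bases,
                     record.basecalls.encode("ascii")))
        # PCON is conventionally typed as char, one QV byte per base
        tags.append((b"PCON", number, _T_CHAR, 1, record.n_bases,
                     np.asarray(record.qualities, dtype=np.uint8).tobytes()))
    for tag, text in ((b"SMPL", record.name), (b"MCHN", record.instrument)):
        raw = text.encode("utf-8")[:255]
        tags.append((tag, 1, _T_PSTRING, 1, len(raw) + 1, bytes([len(raw)]) + raw))

    with open(path, "wb") as fh:
        fh.write(_pack_entries(tags))


# ---------------------------------------------------------------------------
# ABIF reading

def _read_directory(buf: bytes) -> dict[tuple[bytes, int], tuple[int, int, int, bytes]]:
    if len(buf) < _HEADER_SIZE or buf[:4] != _MAGIC:
        raise AbifError("not an ABIF file")
    (_, _, _, _, count, _, dir_offset, _) = struct.unpack(
        _DIR_FMT, buf[6:6 + _DIR_SIZE])
    entries: dict[tuple[bytes, int], tuple[int, int, int, bytes]] = {}
    for i in range(count):
        raw = buf[dir_offset + i * _DIR_SIZE: dir_offset + (i + 1) * _DIR_SIZE]
        if len(raw) < _DIR_SIZE:
            raise AbifError("corrupt trace: truncated directory")
        name, number, etype, esize, n, size, offset, _ = struct.unpack(_DIR_FMT, raw)
        if size <= 4:
            data = offset.to_bytes(4, "big", signed=True)[:size]
        else:
            data = buf[offset: offset + size]
            if len(data) < size:
                raise AbifError("corrupt trace: truncated tag data")
        entries[(name, number)] = (etype, esize, n, data)
    return entries


def _get_tag(entries, name: bytes, required: bool = True):
    """Fetch a tag, preferring number 1 and falling back to number 2."""
    for number in (1, 2):
        if (name, number) in entries:
            return entries[(name, number)]
    if required:
        raise AbifError("incomplete trace: missing tag %s" % name.decode())
    return None


def read_abif(path) -> TraceRecord:
    """Parse an ABIF trace into a :class:`TraceRecord`.

    Raises
    ------
    AbifError
        ``"not an ABIF file"`` when the magic bytes are absent,
        ``"incomplete trace"`` when a mandatory tag is missing, and
        ``"corrupt trace"`` when tag lengths are mutually inconsistent.
    """
    with open(path, "rb") as fh:
        buf = fh.read()
    entries = _read_directory(buf)

    def shorts(data: bytes) -> np.ndarray:
        return np.frombuffer(data, dtype=">i2").astype(np.int64)

    _, _, _, fwo = _get_tag(entries, b"FWO_")
    channel_order = fwo.decode("ascii")
    if sorted(channel_order) != sorted(BASES):
        raise AbifError("corrupt trace: FWO_ is not a permutation of ACGT")

    channels: dict[str, np.ndarray] = {}
    for slot, base in enumerate(channel_order):
        tag = entries.get((b"DATA", 9 + slot))
        if tag is None:
            raise AbifError("incomplete trace: missing tag DATA%d" % (9 + slot))
        channels[base] = shorts(tag[3])

    _, _, _, pbas = _get_tag(entries, b"PBAS")
    basecalls = pbas.decode("ascii")
    _, _, _, pcon = _get_tag(entries, b"PCON")
    qualities = np.frombuffer(pcon, dtype=np.uint8).astype(np.int64)
    _, _, _, ploc = _get_tag(entries, b"PLOC")
    peak_positions = shorts(ploc)

    if not (len(basecalls) == len(qualities) == len(peak_positions)):
        raise AbifError("corrupt trace: PBAS/PCON/PLOC length mismatch")

    name = instrument = ""
    for attr, tag in (("name", b"SMPL"), ("instrument", b"MCHN")):
        got = _get_tag(entries, tag, required=False)
        if got is not None:
            raw = got[3]
            text = raw[1:1 + raw[0]].decode("utf-8", "replace") if raw else ""
            if attr == "name":
                name = text
            else:
                instrument = text

    record = TraceRecord(channels=channels, channel_order=channel_order,
                         peak_positions=peak_positions, basecalls=basecalls,
                         qualities=qualities, name=name, instrument=instrument)
    record.validate()
    return record


# ---------------------------------------------------------------------------
# FASTA + QUAL

def read_fasta_qual(fasta, qual) -> list[Read]:
    """Read a paired FASTA/QUAL file set into :class:`Read` objects.

    Record ids must match pairwise between the two files; a missing or
    reordered record raises ``ValueError("paired file mismatch: ...")``.
    """
    from Bio import SeqIO

    seqs = list(SeqIO.parse(fasta, "fasta"))
    quals = list(SeqIO.parse(qual, "qual"))
    if len(seqs) != len(quals):
        raise ValueError("paired file mismatch: %d sequences vs %d quality records"
                         % (len(seqs), len(quals)))
    reads = []
    for s, q in zip(seqs, quals):
        if s.id != q.id:
            raise ValueError("paired file mismatch: id %r vs %r" % (s.id, q.id))
        qv = q.letter_annotations["phred_quality"]
        if len(s.seq) != len(qv):
            raise ValueError("paired file mismatch: lengths differ for %r" % s.id)
        reads.append(Read(id=s.id, sequence=str(s.seq), qualities=np.asarray(qv)))
    return reads


def write_fasta_qual(reads: list[Read], fasta, qual) -> None:
    """Write reads as paired FASTA and Phred-scale QUAL files (UTF-8)."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.id, description="")
        rec.letter_annotations["phred_quality"] = [int(q) for q in r.qualities]
        records.append(rec)
    seqio_write(records, fasta, "fasta")
    seqio_write(records, qual, "qual")
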