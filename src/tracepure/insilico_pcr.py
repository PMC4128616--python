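"""Degenerate-primer matching and in-silico amplification.

Predicts the products a primer pair would amplify from a template by exact
(or bounded-mismatch) string matching — no thermodynamics.  Ships the V4
18S rDNA eukaryote primer pair TAReuk454FWD1 / TAReukREV3, whose products
from diatom templates run around 420 bp; predicted amplicons double as
templates for the chromatogram simulator.

Degenerate IUPAC positions (S = G/C, Y = C/T, R = A/G, ...) match any base
in their code set at zero mismatch cost.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import Seq

__all__ = [
    "Primer",
    "Amplicon",
    "BUILTIN_PRIMERS",
    "expand_degenerate",
    "find_primer_sites",
    "amplify",
]

#: IUPAC code -> set of concrete bases it stands for
_CODE_SETS = {code: frozenset(bases) for code, bases in ambiguous_dna_values.items()}


@dataclass(frozen=True)
class Primer:
    """A named oligo in IUPAC notation (degenerate codes allowed)."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if not seq:
            raise ValueError("primer sequence must be non-empty")
        bad = set(seq) - set(_CODE_SETS)
        if bad:
            raise ValueError("invalid IUPAC characters in primer: %s"
                             % "".join(sorted(bad)))
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Amplicon:
    """A predicted PCR product, primer-inclusive, on the template plus strand."""

    template_id: str
    start: int   # 0-based, first base of the forward primer site
    end: int     # 0-based exclusive, past the last base of the reverse site
    sequence: str

    @property
    def length(self) -> int:
        return self.end - self.start


#: The V4 18S rDNA eukaryote primer pair used for culture screening.
BUILTIN_PRIMERS = {
    "TAReuk454FWD1": Primer("TAReuk454FWD1", "CCAGCASCYGCGGTAATTCC"),
    "TAReukREV3": Primer("TAReukREV3", "ACTTTCGTTCTTGATYRA"),
}


def expand_degenerate(sequence: str) -> list[str]:
    """All concrete ACGT expansions of an IUPAC string, lexicographic.

    The count equals the product of per-position degeneracies; e.g. the
    two twofold-degenerate positions of TAReukREV3 yield 4 expansions.
    """
    seq = sequence.upper()
    bad = set(seq) - set(_CODE_SETS)
    if bad:
        raise ValueError("invalid IUPAC characters: %s" % "".join(sorted(bad)))
    choices = [sorted(_CODE_SETS[c]) for c in seq]
    return ["".join(p) for p in itertools.product(*choices)]


def _mismatches(template: str, pos: int, primer_seq: str) -> int:
    """Substitution count of ``primer_seq`` against ``template[pos:]``;
    a template base matches a degenerate primer position when their IUPAC
    code sets intersect."""
    m = 0
    for i, p in enumerate(primer_seq):
        t = template[pos + i]
        if not (_CODE_SETS.get(t, frozenset()) & _CODE_SETS[p]):
            m += 1
    return m


def find_primer_sites(template: str, primer: Primer,
                      max_mismatch: int = 0) -> list[tuple[int, str]]:
    """All annealing sites of a primer on both strands of a template.

    Returns ``(position, strand)`` pairs where ``position`` is the 0-based
    plus-strand start of the matched segment.  A ``'+'`` hit means the
    primer matches the plus strand as written; a ``'-'`` hit means the
    primer anneals to the plus strand's complement, i.e. the reverse
    complement of the primer appears on the plus strand at that position.
    """
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    template = template.upper()
    n, k = len(template), len(primer)
    sites: list[tuple[int, str]] = []
    if k > n:
        return sites
    rc = str(Seq(primer.sequence).reverse_complement())
    for pos in range(n - k + 1):
        if _mismatches(template, pos, primer.sequence) <= max_mismatch:
            sites.append((pos, "+"))
        if _mismatches(template, pos, rc) <= max_mismatch:
            sites.append((pos, "-"))
    return sites


def amplify(template: str, fwd: Primer, rev: Primer,
            max_mismatch: int = 0, template_id: str = "template") -> list[Amplicon]:
    """Predict all primer-inclusive products of a primer pair.

    A product pairs a forward site with a downstream reverse site on the
    opposite strand; both orientations of the template are considered, and
    coordinates are always reported on the plus strand as written.  The
    sequence runs from the first to the last primer-bound base, matching
    what gel electrophoresis sizes.  Products are sorted by start, then
    length.
    """
    template = template.upper()
    fwd_sites = find_primer_sites(template, fwd, max_mismatch)
    rev_sites = find_primer_sites(template, rev, max_mismatch)
    pairs = []
    # canonical orientation: fwd on plus strand, rev annealing downstream
    for f in (p for p, s in fwd_sites if s == "+"):
        for r in (p for p, s in rev_sites if s == "-"):
            pairs.append((f, len(fwd), r, len(rev)))
    # flipped orientation: the product sits on the minus strand
    for r in (p for p, s in rev_sites if s == "+"):
        for f in (p for p, s in fwd_sites if s == "-"):
            pairs.append((r, len(rev), f, len(fwd)))
    products = []
    seen = set()
    for left, left_len, right, right_len in pairs:
        end = right + right_len
        # the product must contain both full primer sites
        if right < left or end < left + left_len:
            continue
        if (left, end) in seen:
            continue
        seen.add((left, end))
        products.append(Amplicon(template_id=template_id, start=left, end=end,
                                 sequence=template[left:end]))
    products.sort(key=lambda a: (a.start, a.length))
    return products
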