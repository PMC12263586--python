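"""Coordinate arithmetic, fragment assembly, motif scanning and in-silico
site-directed mutagenesis for enhancer constructs.

All genomic coordinates at this module's interfaces are 1-based inclusive,
the convention under which the published ZRS fragment coordinates reproduce
their printed lengths (e.g. Chr2:8,553,160-8,554,532 -> 1,373 bp). BED input
(0-based, half-open) is converted on read. Sequences are handled
case-insensitively and emitted uppercase.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from typing import Iterator, Sequence

from Bio.Seq import Seq

__all__ = [
    "GenomicInterval",
    "FragmentSpec",
    "MotifHit",
    "MutationSpec",
    "MutationVerification",
    "interval_length",
    "parse_region",
    "assemble_fragment",
    "audit_fragments",
    "ZRS_FRAGMENTS",
    "ZRS_REGIONS",
    "scan_motif",
    "apply_mutation",
    "verify_mutation",
    "enumerate_kmers",
    "reverse_complement",
    "iupac_to_regex",
]

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]",
    "B": "[CGT]", "D": "[AGT]", "H": "[ACT]", "V": "[ACG]",
    "N": "[ACGTN]",
}


class SequenceError(ValueError):
    """Invalid sequence, motif, interval or mutation specification."""


def reverse_complement(sequence: str) -> str:
    """Reverse complement of a DNA string (IUPAC codes supported)."""
    return str(Seq(sequence.upper()).reverse_complement())


# ---------------------------------------------------------------------------
# Intervals and fragments
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicInterval:
    """A 1-based, inclusive genomic interval.

    ``length`` is ``end - start + 1``; a single base has start == end.
    """

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 1:
            raise SequenceError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise SequenceError(
                f"end ({self.end}) precedes start ({self.start}) on {self.chrom}"
            )
        if self.strand not in {"+", "-"}:
            raise SequenceError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @classmethod
    def from_bed(cls, chrom: str, bed_start: int, bed_end: int,
                 strand: str = "+") -> "GenomicInterval":
        """Convert a BED (0-based half-open) record to 1-based inclusive."""
        return cls(chrom, bed_start + 1, bed_end, strand)


def interval_length(interval: GenomicInterval) -> int:
    """Length in bp of a 1-based inclusive interval (end - start + 1)."""
    return interval.length


_REGION_RE = re.compile(r"^([^:]+):([\d,]+)-([\d,]+)$")


def parse_region(text: str) -> GenomicInterval:
    """Parse 'chrom:start-end' with optional thousands separators.

    >>> parse_region("Chr2:8,553,160-8,554,532").length
    1373
    """
    m = _REGION_RE.match(text.strip())
    if m is None:
        raise SequenceError(f"cannot parse region string {text!r}")
    chrom, start, end = m.group(1), m.group(2), m.group(3)
    return GenomicInterval(chrom, int(start.replace(",", "")),
                           int(end.replace(",", "")))


@dataclass(frozen=True)
class FragmentSpec:
    """An enhancer construct assembled from ordered components.

    Each component is ``(label, length_in_bp)`` or ``(label, GenomicInterval)``
    pointing into the source sequence. ``printed_length`` optionally records a
    published total for auditing against the component sum.
    """

    name: str
    components: tuple = ()
    printed_length: int | None = None

    def component_length(self, component) -> int:
        _, payload = component
        if isinstance(payload, GenomicInterval):
            return payload.length
        if isinstance(payload, int):
            if payload < 0:
                raise SequenceError(f"negative component length in {self.name}")
            return payload
        raise SequenceError(
            f"component payload must be int bp or GenomicInterval, got {payload!r}"
        )

    @property
    def total_length(self) -> int:
        return sum(self.component_length(c) for c in self.components)


def assemble_fragment(spec: FragmentSpec,
                      source: str | None = None) -> tuple[str | None, int]:
    """Assemble a construct from its components.

    With a source sequence, components given as intervals are sliced
    (1-based inclusive) and concatenated in listed order. Without a source
    (lengths-only mode) the returned sequence is None and only the length
    audit is performed.

    Returns ``(sequence_or_None, total_length)``.
    """
    total = spec.total_length
    if source is None:
        return None, total
    source = source.upper()
    parts: list[str] = []
    for label, payload in spec.components:
        if not isinstance(payload, GenomicInterval):
            raise SequenceError(
                f"component {label!r} of {spec.name} has no coordinates; "
                "sequence assembly needs explicit intervals"
            )
        if payload.end > len(source):
            raise SequenceError(
                f"component {label!r} of {spec.name} extends past the source "
                f"({payload.end} > {len(source)})"
            )
        parts.append(source[payload.start - 1: payload.end])
    seq = "".join(parts)
    return seq, total


# Published construct bookkeeping: component lengths and printed totals for the
# chicken ZRS deletion series. Two constructs (F2, F1F2) have printed totals
# that do not equal their printed component sums; the audit reports both
# numbers rather than silently choosing one.
ZRS_FRAGMENTS: dict[str, FragmentSpec] = {
    "F1": FragmentSpec("F1", (("5' subdomain", 168), ("upstream DNA", 581)),
                       printed_length=749),
    "F2": FragmentSpec("F2", (("central subdomain", 236),
                              ("adjacent 5' subdomain", 60),
                              ("adjacent 3' subdomain", 11)),
                       printed_length=309),
    "F3": FragmentSpec("F3", (("3' subdomain", 236), ("adjacent 3' DNA", 66)),
                       printed_length=302),
    "F1F2": FragmentSpec("F1F2", (("F1", 749), ("central subdomain", 236),
                                  ("adjacent 3' subdomain", 11)),
                         printed_length=1065),
    "F2F3": FragmentSpec("F2F3", (("central subdomain", 236),
                                  ("3' subdomain", 253),
                                  ("adjacent 5' subdomain", 60),
                                  ("adjacent 3' DNA", 66)),
                         printed_length=615),
    "F1F3": FragmentSpec("F1F3", (("5' subdomain", 175), ("upstream DNA", 581),
                                  ("F3", 302)),
                         printed_length=1058),
}

# Published enhancer coordinates (1-based inclusive; lengths 1373 and 1198 bp).
ZRS_REGIONS: dict[str, GenomicInterval] = {
    "chicken_ZRS": parse_region("Chr2:8,553,160-8,554,532"),
    "human_ZRS": parse_region("Chr7:156,791,072-156,792,269"),
}


def audit_fragments(specs: dict[str, FragmentSpec] | None = None) -> list[dict]:
    """Length audit of construct specs: component sum vs printed total.

    Returns one record per construct with ``computed_length``,
    ``printed_length`` and ``consistent``. Discrepancies are reported, never
    corrected.
    """
    specs = ZRS_FRAGMENTS if specs is None else specs
    report = []
    for name, spec in specs.items():
        computed = spec.total_length
        record = {
            "name": name,
            "computed_length": computed,
            "printed_length": spec.printed_length,
            "consistent": (spec.printed_length is None
                           or computed == spec.printed_length),
        }
        report.append(record)
    return report


# ---------------------------------------------------------------------------
# Motif scanning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MotifHit:
    """A motif match; position is the 1-based start on the plus strand."""

    position: int
    strand: str
    matched: str
    motif_name: str


def iupac_to_regex(pattern: str) -> str:
    """Translate an IUPAC degenerate DNA pattern to a regular expression."""
    out = []
    for ch in pattern.upper():
        if ch not in IUPAC:
            raise SequenceError(f"invalid IUPAC character {ch!r} in {pattern!r}")
        out.append(IUPAC[ch])
    return "".join(out)


def scan_motif(sequence: str, motif: str, motif_name: str = "",
               both_strands: bool = False) -> list[MotifHit]:
    """Find all (overlapping) matches of an IUPAC motif.

    Minus-strand hits are reported in plus-strand coordinates with the
    minus-strand matched string. Overlapping matches are all reported; Hox
    sites and E-boxes can overlap in enhancer sequence, so no greedy
    consumption. Hits are sorted by position, plus strand first on ties.
    """
    sequence = sequence.upper()
    if not set(sequence) <= set("ACGTN"):
        raise SequenceError("sequence contains non-ACGTN characters")
    regex = re.compile(f"(?=({iupac_to_regex(motif)}))")
    motif_len = len(motif)
    hits = [
        MotifHit(m.start() + 1, "+", m.group(1), motif_name)
        for m in regex.finditer(sequence)
    ]
    if both_strands:
        rc = reverse_complement(sequence)
        n = len(sequence)
        for m in regex.finditer(rc):
            # RC match starting at 0-based p spans plus-strand positions
            # n - p - motif_len + 1 .. n - p (1-based).
            start_plus = n - m.start() - motif_len + 1
            hits.append(MotifHit(start_plus, "-", m.group(1), motif_name))
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits


# ---------------------------------------------------------------------------
# Site-directed mutagenesis (in silico)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MutationSpec:
    """A substitution mutation over a construct interval.

    Mirrors bench practice for binding-site knockouts: 3-4 core bases of the
    site are altered (substitution only, never an indel) and a restriction
    site is introduced for colony screening.
    """

    name: str
    start: int  # 1-based inclusive, within the construct
    end: int
    replacement: str
    restriction_site: str = ""

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise SequenceError(f"invalid interval {self.start}-{self.end}")
        if len(self.replacement) != self.end - self.start + 1:
            raise SequenceError(
                f"replacement length {len(self.replacement)} != interval "
                f"length {self.end - self.start + 1} (substitution only)"
            )
        if not set(self.replacement.upper()) <= set("ACGT"):
            raise SequenceError("replacement must be plain ACGT")


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def apply_mutation(sequence: str, spec: MutationSpec,
                   require_core_bases: bool = True) -> str:
    """Apply a substitution mutation; the result has unchanged length.

    The number of altered bases must be 3-4 when ``require_core_bases`` is
    set (the screening-friendly regime); a replacement identical to the
    original is a no-op error.
    """
    sequence = sequence.upper()
    replacement = spec.replacement.upper()
    if spec.end > len(sequence):
        raise SequenceError(
            f"mutation {spec.name} interval {spec.start}-{spec.end} exceeds "
            f"sequence length {len(sequence)}"
        )
    original = sequence[spec.start - 1: spec.end]
    changed = _hamming(original, replacement)
    if changed == 0:
        raise SequenceError(f"mutation {spec.name} is a no-op (replacement "
                            "identical to original)")
    if require_core_bases and not 3 <= changed <= 4:
        raise SequenceError(
            f"mutation {spec.name} alters {changed} bases; expected 3-4"
        )
    return sequence[: spec.start - 1] + replacement + sequence[spec.end:]


@dataclass
class MutationVerification:
    """Report from verify_mutation; overall pass requires all three checks."""

    destroyed_ok: bool
    restriction_ok: bool
    no_new_sites_ok: bool
    residual_hits: list[MotifHit] = field(default_factory=list)
    new_forbidden_hits: list[MotifHit] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return self.destroyed_ok and self.restriction_ok and self.no_new_sites_ok

    def to_dict(self) -> dict:
        return {
            "passed": self.passed,
            "destroyed_ok": self.destroyed_ok,
            "restriction_ok": self.restriction_ok,
            "no_new_sites_ok": self.no_new_sites_ok,
            "residual_hits": [vars(h) for h in self.residual_hits],
            "new_forbidden_hits": [vars(h) for h in self.new_forbidden_hits],
        }


def verify_mutation(original: str, mutated: str,
                    destroyed_motifs: Sequence[str] = (),
                    forbidden_new_motifs: Sequence[str] = (),
                    restriction_site: str = "") -> MutationVerification:
    """Check a mutagenesis product the way transformants are screened.

    (a) no destroyed-motif match survives overlapping a mutated position;
    (b) the screening restriction site occurs in the mutant but not the
    original; (c) no forbidden motif (e.g. limb-relevant binding sites)
    appears in the mutant at a (position, strand) absent from the original.
    """
    original, mutated = original.upper(), mutated.upper()
    if len(original) != len(mutated):
        raise SequenceError("original and mutated sequences differ in length")

    mutated_pos = {i + 1 for i, (a, b) in enumerate(zip(original, mutated))
                   if a != b}

    residual: list[MotifHit] = []
    for motif in destroyed_motifs:
        for hit in scan_motif(mutated, motif, motif, both_strands=True):
            span = set(range(hit.position, hit.position + len(motif)))
            if span & mutated_pos:
                residual.append(hit)

    if restriction_site:
        site = restriction_site.upper()
        restriction_ok = site in mutated and site not in original
    else:
        restriction_ok = False

    new_hits: list[MotifHit] = []
    for motif in forbidden_new_motifs:
        before = {(h.position, h.strand)
                  for h in scan_motif(original, motif, motif, both_strands=True)}
        for hit in scan_motif(mutated, motif, motif, both_strands=True):
            if (hit.position, hit.strand) not in before:
                new_hits.append(hit)

    return MutationVerification(
        destroyed_ok=not residual,
        restriction_ok=restriction_ok,
        no_new_sites_ok=not new_hits,
        residual_hits=residual,
        new_forbidden_hits=new_hits,
    )


# ---------------------------------------------------------------------------
# K-mer enumeration
# ---------------------------------------------------------------------------

def enumerate_kmers(k: int, materialize: bool = False
                    ) -> tuple[int, Iterator[str] | list[str]]:
    """Count (4^k) and lazily enumerate all DNA k-mers in lexicographic order.

    Materialized enumeration is limited to k <= 12 (16.7M strings).
    """
    if k < 1:
        raise SequenceError(f"k must be >= 1, got {k}")
    count = 4 ** k
    if materialize and k > 12:
        raise SequenceError("materialized enumeration limited to k <= 12")
    it = ("".join(p) for p in itertools.product("ACGT", repeat=k))
    return count, list(it) if materialize else it
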