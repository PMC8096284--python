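"""Structural-variant domain objects and the genotype → copy-number map.

A diploid genotype is the number of haplotypes carrying the alternate
allele: 0/0 (absent), 0/1 (heterozygous), 1/1 (homozygous alternate).
Each SV changes the copy number of specific k-mers: k-mers created by
the event (novel breakpoint junctions, inserted sequence) appear once
per alternate haplotype, while k-mers destroyed by it (deleted sequence,
reference-breakpoint context) disappear from each alternate haplotype.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from .kmers import revcomp


class SVType(str, enum.Enum):
    DEL = "DEL"
    INS = "INS"
    INV = "INV"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class Genotype(enum.IntEnum):
    """Diploid genotype, ordered by alternate-allele dosage.

    The ordering 0/0 < 0/1 < 1/1 is relied on for deterministic
    tie-breaking toward the fewer-alternate-alleles call.
    """

    HOM_REF = 0
    HET = 1
    HOM_ALT = 2

    @property
    def label(self) -> str:
        return ("0/0", "0/1", "1/1")[self]

    @property
    def dosage(self) -> int:
        return int(self)

    @classmethod
    def from_label(cls, label: str) -> "Genotype":
        norm = label.replace("|", "/")
        if norm == "1/0":
            norm = "0/1"
        try:
            return {"0/0": cls.HOM_REF, "0/1": cls.HET, "1/1": cls.HOM_ALT}[norm]
        except KeyError:
            raise ValueError(f"unknown genotype label {label!r}") from None


GENOTYPES = (Genotype.HOM_REF, Genotype.HET, Genotype.HOM_ALT)

# roles a selected k-mer can play for its SV
ROLE_INNER_ALT = "inner_alt"
ROLE_INNER_REF = "inner_ref"
ROLE_JUNCTION_ALT = "junction_alt"
ROLE_JUNCTION_REF = "junction_ref"
ROLE_CONTROL = "control"

ALT_ROLES = frozenset({ROLE_INNER_ALT, ROLE_JUNCTION_ALT})
REF_ROLES = frozenset({ROLE_INNER_REF, ROLE_JUNCTION_REF})
JUNCTION_ROLES = frozenset({ROLE_JUNCTION_ALT, ROLE_JUNCTION_REF})


@dataclass(frozen=True)
class SVRecord:
    """One structural variant in 0-based half-open reference coordinates.

    ``[start, end)`` is the reference footprint; insertions have
    ``start == end`` (the insertion point) and carry the inserted
    sequence when known.
    """

    id: str
    chrom: str
    start: int
    end: int
    svtype: SVType
    inserted_seq: str = ""

    def __post_init__(self) -> None:
        if self.start < 0 or self.start > self.end:
            raise ValueError(f"{self.id}: invalid interval [{self.start}, {self.end})")
        if self.svtype is SVType.INS and self.start != self.end:
            raise ValueError(f"{self.id}: insertions must have start == end")
        if self.svtype is not SVType.INS and self.inserted_seq:
            raise ValueError(f"{self.id}: inserted_seq only valid for insertions")

    @property
    def span(self) -> int:
        """Length of the reference footprint."""
        return self.end - self.start


def alt_haplotype_window(ref_seq: str, sv: SVRecord, flank: int) -> str:
    """Alternate-allele sequence spliced from the reference around an SV.

    ``flank`` reference bases are kept on each side of the event (truncated
    at contig edges).  A deletion removes ``[start, end)``, an insertion
    splices its sequence in at the insertion point, an inversion
    reverse-complements the interval in place.
    """
    if flank < 0:
        raise ValueError("flank must be non-negative")
    left = ref_seq[max(0, sv.start - flank) : sv.start]
    if sv.svtype is SVType.DEL:
        mid = ""
        right = ref_seq[sv.end : sv.end + flank]
    elif sv.svtype is SVType.INS:
        mid = sv.inserted_seq
        right = ref_seq[sv.start : sv.start + flank]
    else:  # INV
        mid = revcomp(ref_seq[sv.start : sv.end])
        right = ref_seq[sv.end : sv.end + flank]
    return left + mid + right


def expected_copy_table(role: str, svtype: SVType) -> dict[Genotype, int]:
    """Expected diploid copy number of a k-mer per genotype.

    Alt-derived k-mers appear once per alternate haplotype; ref-derived
    k-mers (sequence the SV destroys) appear once per reference
    haplotype.  The two tables sum to 2 at every genotype.
    """
    if role == ROLE_INNER_REF and svtype is not SVType.DEL:
        raise ValueError("inner_ref k-mers only exist for deletions")
    if role == ROLE_INNER_ALT and svtype is not SVType.INS:
        raise ValueError("inner_alt k-mers only exist for insertions")
    if role in ALT_ROLES:
        return {Genotype.HOM_REF: 0, Genotype.HET: 1, Genotype.HOM_ALT: 2}
    if role in REF_ROLES:
        return {Genotype.HOM_REF: 2, Genotype.HET: 1, Genotype.HOM_ALT: 0}
    raise ValueError(f"unknown k-mer role {role!r}")
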