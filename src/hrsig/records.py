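"""Somatic mutation records.

A catalog is a list of :class:`MutationRecord` objects, one per somatic SNV or
short indel, each attributed to exactly one sample (clone).  Indels use the
anchored VCF-style representation: the REF field starts at the first affected
reference base minus one anchor base, so a deletion of ``AG`` after position
100 is ``ref="CAG", alt="C", pos=100``.  :func:`normalize` reduces any
anchored pair to its minimal form and infers the mutation kind.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from enum import Enum

_DNA = frozenset("ACGT")


class MutationKind(str, Enum):
    SNV = "SNV"
    INS = "INS"
    DEL = "DEL"


class CatalogParseError(ValueError):
    """Raised when a catalog line cannot be interpreted as a mutation."""


@dataclass(frozen=True)
class MutationRecord:
    """One somatic mutation unique to one sample.

    ``pos`` is 1-based and points at the first reference base of ``ref``.
    For indels the minimal anchored representation is used: ``alt`` is a
    1-base prefix of ``ref`` for deletions (and vice versa for insertions).
    """

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    kind: MutationKind

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise CatalogParseError(f"ref equals alt at {self.chrom}:{self.pos}")
        for allele in (self.ref, self.alt):
            if not allele or not set(allele) <= _DNA:
                raise CatalogParseError(
                    f"non-ACGT allele {allele!r} at {self.chrom}:{self.pos}"
                )
        if self.kind is MutationKind.SNV:
            if len(self.ref) != 1 or len(self.alt) != 1:
                raise CatalogParseError("SNV requires single-base ref and alt")
        elif self.kind is MutationKind.DEL:
            if not (len(self.ref) > len(self.alt) and self.ref.startswith(self.alt)):
                raise CatalogParseError("DEL requires alt to be a prefix of ref")
        elif self.kind is MutationKind.INS:
            if not (len(self.alt) > len(self.ref) and self.alt.startswith(self.ref)):
                raise CatalogParseError("INS requires ref to be a prefix of alt")

    @property
    def indel_seq(self) -> str:
        """Inserted or deleted bases (empty for SNVs)."""
        if self.kind is MutationKind.DEL:
            return self.ref[len(self.alt):]
        if self.kind is MutationKind.INS:
            return self.alt[len(self.ref):]
        return ""


def infer_kind(ref: str, alt: str) -> MutationKind:
    if len(ref) == 1 and len(alt) == 1:
        return MutationKind.SNV
    if len(ref) > len(alt):
        return MutationKind.DEL
    return MutationKind.INS


def normalize(sample_id: str, chrom: str, pos: int, ref: str, alt: str) -> MutationRecord:
    """Build a record in minimal anchored form from any VCF-style allele pair.

    Shared suffixes and all but one shared prefix base are trimmed, adjusting
    ``pos``; a same-length pair longer than 1 bp that does not reduce to a
    single substitution is rejected (complex events are out of scope).
    """
    ref, alt = ref.upper(), alt.upper()
    if not ref or not alt or not set(ref) <= _DNA or not set(alt) <= _DNA:
        raise CatalogParseError(f"non-ACGT allele pair {ref!r}/{alt!r} at {chrom}:{pos}")
    # trim common suffix
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    # trim common prefix, keeping one anchor base for indels
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    if len(ref) == len(alt):
        if len(ref) != 1:
            raise CatalogParseError(
                f"complex substitution {ref}>{alt} at {chrom}:{pos} not supported"
            )
    elif ref[0] != alt[0]:
        raise CatalogParseError(f"unanchored indel {ref}>{alt} at {chrom}:{pos}")
    return MutationRecord(sample_id, chrom, int(pos), ref, alt, infer_kind(ref, alt))


def left_align(record: MutationRecord, genome) -> MutationRecord:
    """Shift an indel to its leftmost equivalent position on the reference.

    ``genome`` is any mapping of chromosome name to an indexable sequence
    (e.g. a :class:`pyfaidx.Fasta`).  SNVs are returned unchanged.  Indels are
    shifted left one base at a time while the base preceding the event equals
    the last base of the inserted/deleted unit, which preserves the resulting
    alternate sequence.
    """
    if record.kind is MutationKind.SNV:
        return record
    chrom = str(genome[record.chrom][:])
    L = len(record.indel_seq)
    if record.kind is MutationKind.DEL:
        # 0-based index of the first deleted base
        i0 = record.pos
        while i0 > 1 and chrom[i0 - 1] == chrom[i0 + L - 1]:
            i0 -= 1
        anchor = chrom[i0 - 1]
        deleted = chrom[i0: i0 + L]
        return replace(record, pos=i0, ref=anchor + deleted, alt=anchor)
    # insertion: inserted seq sits between 0-based indices pos-1 and pos
    seq = record.indel_seq
    j0 = record.pos  # junction index (0-based position the insertion precedes)
    while j0 > 1 and chrom[j0 - 1] == seq[-1]:
        seq = chrom[j0 - 1] + seq[:-1]
        j0 -= 1
    anchor = chrom[j0 - 1]
    return replace(record, pos=j0, ref=anchor, alt=anchor + seq)


def warn_shared_calls(records: list[MutationRecord]) -> int:
    """Warn when the same chrom/pos/alt appears in more than one sample.

    Per-sample uniqueness is an input assumption (the upstream caller emits
    only calls unique to one sample); shared calls usually indicate germline
    contamination or a mis-merged catalog.  Returns the number of shared keys.
    """
    seen: dict[tuple, set] = {}
    for r in records:
        seen.setdefault((r.chrom, r.pos, r.alt), set()).add(r.sample_id)
    shared = sum(1 for samples in seen.values() if len(samples) > 1)
    if shared:
        warnings.warn(
            f"{shared} call(s) shared between samples; catalog may not be "
            "per-sample unique",
            stacklevel=2,
        )
    return shared
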