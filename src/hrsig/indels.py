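"""Sequence-context classification of short insertions and deletions.

Short deletions are classified by the local reference context:

* **repeat** — the deleted sequence is present in at least two tandem
  copies (the deleted copy plus at least one adjacent exact copy);
* **microhomology** — the sequences at the two breakpoints share at least
  1 bp of homology (the deleted sequence's prefix recurs just past the 3'
  breakpoint, or its suffix just before the 5' breakpoint);
* **none** — neither applies.

Repeat takes precedence over microhomology: a full-length breakpoint match
*is* an adjacent tandem copy.  The same contexts drive the 83-channel
insertion/deletion classification (1-bp events by homopolymer length,
longer events by length x repeat-copy number, microhomology deletions by
length x homology length), which summarizes a catalog as an ID-83 spectrum.

Deletion phenotypes separate HR-pathway defects that a substitution
signature cannot: loss of the BRCA2/PALB2 axis yields longer deletions
dominated by microhomology, while other HR mutants keep short
repeat/no-homology deletions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .records import MutationKind, MutationRecord, left_align

#: flank length retained around a deletion, as a multiple of its length
_FLANK_UNITS = 6
_FLANK_PAD = 10


def _id83_labels() -> tuple[str, ...]:
    labels = []
    for base in "CT":
        labels += [f"1:Del:{base}:{n}" for n in (1, 2, 3, 4, 5, "6+")]
    for base in "CT":
        labels += [f"1:Ins:{base}:{n}" for n in (0, 1, 2, 3, 4, "5+")]
    for length in (2, 3, 4, "5+"):
        labels += [f"{length}:Del:R:{n}" for n in (0, 1, 2, 3, 4, "5+")]
    for length in (2, 3, 4, "5+"):
        labels += [f"{length}:Ins:R:{n}" for n in (0, 1, 2, 3, 4, "5+")]
    for length, max_mh in ((2, 1), (3, 2), (4, 3), ("5+", 5)):
        labels += [
            f"{length}:Del:M:{m if m < 5 or length != '5+' else '5+'}"
            for m in range(1, max_mh + 1)
        ]
    return tuple(labels)


#: the 83 indel channel labels, canonical order.
ID83_CHANNELS = _id83_labels()
_ID83_INDEX = {label: i for i, label in enumerate(ID83_CHANNELS)}

#: upper bound (exclusive) on the length of a "short" indel; longer events
#: belong to the structural-variant workflow.
SHORT_INDEL_MAX = 50

_PYR = {"A": "T", "G": "C", "C": "C", "T": "T"}


@dataclass(frozen=True)
class DeletionCall:
    """A short deletion with its sequence-context classification."""

    record: MutationRecord
    deleted_seq: str
    left_flank: str
    right_flank: str
    context_class: str  # "repeat" | "microhomology" | "none"
    mh_length: int
    tandem_copies: int
    id83_channel: int

    @property
    def length(self) -> int:
        return len(self.deleted_seq)


def max_microhomology(deleted_seq: str, left_flank: str, right_flank: str) -> int:
    """Longest breakpoint homology, capped at ``len(deleted_seq) - 1``.

    Compares the deleted sequence's prefix with the start of the 3' flank
    and its suffix with the end of the 5' flank; returns the longer match.
    A full-length match is a tandem copy, handled by the repeat class,
    hence the cap.
    """
    if not deleted_seq:
        raise ValueError("empty deleted sequence")
    cap = len(deleted_seq) - 1
    k1 = 0
    for a, b in zip(deleted_seq, right_flank):
        if a != b:
            break
        k1 += 1
    k2 = 0
    for a, b in zip(reversed(deleted_seq), reversed(left_flank)):
        if a != b:
            break
        k2 += 1
    return min(max(k1, k2), cap)


def tandem_copies(deleted_seq: str, left_flank: str, right_flank: str) -> int:
    """Number of consecutive copies of the deleted unit at the site.

    Counts the deleted copy itself plus adjacent exact copies scanning
    outward left and right.
    """
    if not deleted_seq:
        raise ValueError("empty deleted sequence")
    unit, L = deleted_seq, len(deleted_seq)
    copies = 1
    i = len(left_flank)
    while i >= L and left_flank[i - L: i] == unit:
        copies += 1
        i -= L
    j = 0
    while j + L <= len(right_flank) and right_flank[j: j + L] == unit:
        copies += 1
        j += L
    return copies


def _flanks(genome, chrom: str, start0: int, end0: int, want: int) -> tuple[str, str]:
    """Reference flanks around 0-based [start0, end0); truncated at edges."""
    seq = genome[chrom]
    n = len(seq)
    left = str(seq[max(0, start0 - want): start0]).upper()
    right = str(seq[end0: min(n, end0 + want)]).upper()
    if len(left) < want or len(right) < want:
        warnings.warn(
            f"flank truncated at contig edge near {chrom}:{start0 + 1}",
            stacklevel=3,
        )
    return left, right


def classify_deletion(record: MutationRecord, genome) -> DeletionCall:
    """Classify a short deletion by sequence context.

    The record is left-aligned first, so any equivalent representation of
    the same deletion yields the identical call.  Precedence:
    repeat (>= 2 tandem copies) > microhomology (>= 1 bp) > none.
    """
    if record.kind is not MutationKind.DEL:
        raise ValueError("classify_deletion requires a deletion record")
    record = left_align(record, genome)
    deleted = record.indel_seq
    L = len(deleted)
    start0 = record.pos  # 0-based first deleted base (anchor is pos, 1-based)
    left, right = _flanks(
        genome, record.chrom, start0, start0 + L, _FLANK_UNITS * L + _FLANK_PAD
    )
    copies = tandem_copies(deleted, left, right)
    mh = max_microhomology(deleted, left, right) if L > 1 else 0
    if copies >= 2:
        context = "repeat"
    elif mh >= 1:
        context = "microhomology"
    else:
        context = "none"
        mh = 0
    channel = _deletion_id83(deleted, left, right, copies, mh)
    return DeletionCall(
        record=record,
        deleted_seq=deleted,
        left_flank=left,
        right_flank=right,
        context_class=context,
        mh_length=mh,
        tandem_copies=copies,
        id83_channel=channel,
    )


def _deletion_id83(deleted: str, left: str, right: str, copies: int, mh: int) -> int:
    L = len(deleted)
    if L == 1:
        base = _PYR[deleted]
        run = copies  # homopolymer length including the deleted base
        label = f"1:Del:{base}:{min(run, 6) if run < 6 else '6+'}"
        return _ID83_INDEX[label]
    lbin = L if L < 5 else "5+"
    extra = copies - 1
    if extra >= 1:
        return _ID83_INDEX[f"{lbin}:Del:R:{extra if extra < 5 else '5+'}"]
    if mh >= 1:
        m = min(mh, 5, L - 1)
        return _ID83_INDEX[f"{lbin}:Del:M:{m if (m < 5 or lbin != '5+') else '5+'}"]
    return _ID83_INDEX[f"{lbin}:Del:R:0"]


def classify_indel_id83(record: MutationRecord, genome) -> int:
    """ID-83 channel (0..82) of a short insertion or deletion."""
    if record.kind is MutationKind.SNV:
        raise ValueError("ID-83 classification is defined for indels only")
    if record.kind is MutationKind.DEL:
        return classify_deletion(record, genome).id83_channel
    record = left_align(record, genome)
    inserted = record.indel_seq
    L = len(inserted)
    at0 = record.pos  # insertion precedes this 0-based reference index
    _, right = _flanks(genome, record.chrom, at0, at0, _FLANK_UNITS * L + _FLANK_PAD)
    if L == 1:
        base = _PYR[inserted]
        run = 0
        while run < len(right) and right[run] == inserted:
            run += 1
        return _ID83_INDEX[f"1:Ins:{base}:{run if run < 5 else '5+'}"]
    copies = 0
    j = 0
    while j + L <= len(right) and right[j: j + L] == inserted:
        copies += 1
        j += L
    lbin = L if L < 5 else "5+"
    return _ID83_INDEX[f"{lbin}:Ins:R:{copies if copies < 5 else '5+'}"]


def id83_spectrum(records, genome, label: str = "") -> pd.Series:
    """Tally a catalog's short indels into the 83-channel spectrum.

    Indels of ``SHORT_INDEL_MAX`` (50 bp) or longer are ignored with a
    warning — they belong to the structural-variant workflow.  The returned
    Series sums to the number of classified indels.
    """
    counts = np.zeros(83, dtype=float)
    long_events = 0
    for record in records:
        if record.kind is MutationKind.SNV:
            continue
        if len(record.indel_seq) >= SHORT_INDEL_MAX:
            long_events += 1
            continue
        counts[classify_indel_id83(record, genome)] += 1
    if long_events:
        warnings.warn(
            f"{long_events} indel(s) >= {SHORT_INDEL_MAX} bp ignored", stacklevel=2
        )
    return pd.Series(counts, index=list(ID83_CHANNELS), name=label or None)


def deletion_size_ecdf(lengths) -> tuple[pd.Series, float]:
    """Empirical cumulative distribution and median of deletion lengths.

    Accepts an iterable of lengths or of :class:`DeletionCall`.  The median
    uses the lower-midpoint convention: for an even count the lower of the
    two middle order statistics is reported (deletion lengths are integers
    and so is the median).
    """
    values = sorted(
        c.length if isinstance(c, DeletionCall) else int(c) for c in lengths
    )
    if not values:
        raise ValueError("no deletions to summarize")
    arr = np.asarray(values)
    uniq = np.unique(arr)
    ecdf = pd.Series(
        [np.mean(arr <= u) for u in uniq], index=uniq, name="cumulative_fraction"
    )
    n = len(values)
    median = values[(n - 1) // 2]
    return ecdf, float(median)


def context_class_fractions(calls) -> pd.Series:
    """Fractions of the repeat / microhomology / none classes in a call set."""
    counts = {"repeat": 0, "microhomology": 0, "none": 0}
    total = 0
    for call in calls:
        counts[call.context_class] += 1
        total += 1
    if total == 0:
        raise ValueError("no deletion calls")
    return pd.Series({k: v / total for k, v in counts.items()})
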