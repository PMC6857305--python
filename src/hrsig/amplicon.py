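"""Deletion/insertion spectra at CRISPR/Cas9 cut sites from amplicon reads.

Merged amplicon reads are aligned globally against the theoretical amplicon
sequence (affine gap penalties, free end gaps, so trimmed read ends do not
register as events), gap runs are converted to deletion/insertion events,
and events far from the cut site are discarded as sequencing noise.  A read
with no retained event is wild type.  Substitutions are not counted as
events: a blunt double-strand break repaired without indel formation is
indistinguishable from an unedited molecule at this resolution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align, SeqIO
from Bio.Align import substitution_matrices

from .indels import deletion_size_ecdf


@dataclass(frozen=True)
class AlignmentParams:
    """Needle-style scoring: +5 match, -4 mismatch, gap open 10, extend 0.5
    (penalties positive; a gap of length L costs open + (L-1) * extend).
    N is neutral (scores 0 against everything)."""

    match: float = 5.0
    mismatch: float = -4.0
    gap_open: float = 10.0
    gap_extend: float = 0.5

    def __post_init__(self) -> None:
        if not self.gap_open >= self.gap_extend >= 0:
            raise ValueError("require gap_open >= gap_extend >= 0")


@dataclass(frozen=True)
class IndelEvent:
    kind: str  # "deletion" | "insertion" | "mixed"
    start: int  # 0-based reference amplicon offset
    length: int  # deleted bp (deletion/mixed) or inserted bp (insertion)
    inserted_seq: str = ""


@dataclass(frozen=True)
class AmpliconEvent:
    """Mutation events extracted from one aligned amplicon read."""

    read_id: str
    events: tuple[IndelEvent, ...] = field(default_factory=tuple)

    @property
    def wildtype(self) -> bool:
        return not self.events


@dataclass(frozen=True)
class GlobalAlignment:
    reference: str  # aligned, with '-' for insertions
    query: str  # aligned, with '-' for deletions
    score: float


def _make_aligner(params: AlignmentParams) -> Align.PairwiseAligner:
    alphabet = "ACGTN"
    mat = substitution_matrices.Array(alphabet, dims=2)
    for a in alphabet:
        for b in alphabet:
            if "N" in (a, b):
                mat[a, b] = 0.0
            else:
                mat[a, b] = params.match if a == b else params.mismatch
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = mat
    aligner.open_gap_score = -params.gap_open
    aligner.extend_gap_score = -params.gap_extend
    # free end gaps: length variation at amplicon ends is not an event
    aligner.end_gap_score = 0.0
    return aligner


def global_align(
    query: str, reference: str, params: AlignmentParams | None = None
) -> GlobalAlignment:
    """Optimal global alignment of a read against the reference amplicon.

    Affine gap cost (a length-L gap costs ``gap_open + (L-1)*gap_extend``),
    end gaps free.  Ties are broken deterministically (the aligner's first
    reported optimum).
    """
    params = params or AlignmentParams()
    query = query.upper()
    reference = reference.upper()
    if not query or not reference:
        raise ValueError("empty sequence")
    for seq, name in ((query, "query"), (reference, "reference")):
        if not set(seq) <= set("ACGTN"):
            raise ValueError(f"{name} contains non-ACGTN characters")
    aligner = _make_aligner(params)
    alignment = aligner.align(reference, query)[0]
    return GlobalAlignment(
        reference=str(alignment[0]), query=str(alignment[1]),
        score=float(alignment.score),
    )


def extract_events(
    alignment: GlobalAlignment,
    cut_site: int,
    window: int = 20,
    mixed_gap: int = 3,
) -> AmpliconEvent:
    """Convert an alignment's gap runs into cut-site mutation events.

    Gap runs in the query are deletions, gap runs in the reference are
    insertions; a deletion and an insertion within ``mixed_gap`` bp of each
    other merge into one "mixed" event (length = deleted bp, carrying the
    inserted sequence).  Events lying entirely outside ``cut_site +/-
    window`` on the reference are discarded as noise, as are end gaps
    (trimmed read ends).  Terminal ``read_id`` is filled by the caller via
    :func:`read_events`; here it is empty.
    """
    ref, qry = alignment.reference, alignment.query
    ref_len = len(ref) - ref.count("-")
    if not 0 <= cut_site <= ref_len:
        raise ValueError(f"cut site {cut_site} outside reference (0..{ref_len})")
    raw: list[IndelEvent] = []
    ref_pos = 0  # 0-based reference offset of the current column
    i = 0
    n = len(ref)
    # identify end-gap spans of the query (free ends, not events)
    lead = n - len(qry.lstrip("-"))
    trail = n - len(qry.rstrip("-"))
    while i < n:
        if qry[i] == "-" and ref[i] != "-":
            j = i
            while j < n and qry[j] == "-" and ref[j] != "-":
                j += 1
            if not (i < lead or j > n - trail):
                raw.append(IndelEvent("deletion", ref_pos, j - i))
            ref_pos += j - i
            i = j
        elif ref[i] == "-":
            j = i
            while j < n and ref[j] == "-":
                j += 1
            inserted = qry[i:j].replace("-", "")
            if inserted and not (i == 0 or j == n):
                raw.append(IndelEvent("insertion", ref_pos, len(inserted), inserted))
            i = j
        else:
            ref_pos += 1
            i += 1
    merged = _merge_mixed(raw, mixed_gap)
    lo, hi = cut_site - window, cut_site + window
    kept = tuple(
        e for e in merged
        if e.start <= hi and (e.start + (e.length if e.kind != "insertion" else 0)) >= lo
    )
    return AmpliconEvent(read_id="", events=kept)


def _merge_mixed(events: list[IndelEvent], mixed_gap: int) -> list[IndelEvent]:
    merged: list[IndelEvent] = []
    for event in sorted(events, key=lambda e: e.start):
        if merged:
            prev = merged[-1]
            pair = {prev.kind, event.kind}
            prev_end = prev.start + (prev.length if prev.kind != "insertion" else 0)
            if pair == {"deletion", "insertion"} and event.start - prev_end <= mixed_gap:
                del_len = prev.length if prev.kind == "deletion" else event.length
                ins_seq = prev.inserted_seq or event.inserted_seq
                merged[-1] = IndelEvent("mixed", prev.start, del_len, ins_seq)
                continue
        merged.append(event)
    return merged


def read_events(
    reads_path,
    reference: str,
    cut_site: int,
    window: int = 20,
    params: AlignmentParams | None = None,
    fmt: str | None = None,
) -> list[AmpliconEvent]:
    """Align every merged read in a FASTA/FASTQ file and extract its events."""
    path = str(reads_path)
    if fmt is None:
        fmt = "fastq" if path.endswith(("fastq", "fq")) else "fasta"
    out = []
    for record in SeqIO.parse(path, fmt):
        alignment = global_align(str(record.seq), reference, params)
        event = extract_events(alignment, cut_site, window)
        out.append(AmpliconEvent(read_id=record.id, events=event.events))
    return out


def event_spectrum(events: list[AmpliconEvent]) -> dict:
    """Summarize per-read events as percentages of all sequenced amplicons.

    Returns a dict with:

    * ``percentages`` — DataFrame of (kind, length) percentages over *all*
      reads (wild type included in the denominator);
    * ``wildtype_percent`` — percent of reads with no retained event;
    * ``deletion_ecdf`` / ``deletion_median`` — size distribution of
      deletion events among mutant reads (lower-midpoint median).
    """
    if not events:
        raise ValueError("no reads")
    n_reads = len(events)
    tally: dict[tuple[str, int], int] = {}
    deletion_lengths: list[int] = []
    n_wt = 0
    for read in events:
        if read.wildtype:
            n_wt += 1
        for e in read.events:
            tally[(e.kind, e.length)] = tally.get((e.kind, e.length), 0) + 1
            if e.kind == "deletion":
                deletion_lengths.append(e.length)
    percentages = pd.DataFrame(
        [(kind, length, 100.0 * count / n_reads)
         for (kind, length), count in sorted(tally.items())],
        columns=["kind", "length", "percent_of_reads"],
    )
    result = {
        "percentages": percentages,
        "wildtype_percent": 100.0 * n_wt / n_reads,
        "n_reads": n_reads,
    }
    if deletion_lengths:
        ecdf, median = deletion_size_ecdf(deletion_lengths)
        result["deletion_ecdf"] = ecdf
        result["deletion_median"] = median
    else:
        warnings.warn("no deletion events among reads", stacklevel=2)
        result["deletion_ecdf"] = None
        result["deletion_median"] = float("nan")
    return result
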