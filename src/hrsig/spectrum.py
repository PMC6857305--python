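"""Trinucleotide substitution spectra.

Single-base substitutions are classified into the standard 96 channels:
six pyrimidine-referenced substitution classes (C>A, C>G, C>T, T>A, T>C,
T>G) times the 16 combinations of the 5' and 3' neighboring bases.
Substitutions whose reference base is a purine are reverse-complemented,
together with their context, before classification.  Channel order is fixed:
substitution classes in the order above, within a class the 5' base then the
3' base alphabetically.
"""

from __future__ import annotations

import warnings
from collections.abc import Iterable

import numpy as np
import pandas as pd

from .records import MutationKind, MutationRecord

BASES = "ACGT"
SUB_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: 96 channel labels, e.g. ``A[C>A]A``, in canonical order.
CHANNELS_96 = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUB_CLASSES
    for five in BASES
    for three in BASES
)

#: 32 pyrimidine-centered triplet labels (NCN then NTN, neighbors alphabetical).
TRIPLETS_32 = tuple(
    five + center + three for center in "CT" for five in BASES for three in BASES
)

_CHANNEL_INDEX = {label: i for i, label in enumerate(CHANNELS_96)}
_TRIPLET_INDEX = {t: i for i, t in enumerate(TRIPLETS_32)}

#: pyrimidine-centered reference triplet of each channel, e.g. ``ACA`` for A[C>A]A.
CHANNEL_TRIPLETS = tuple(label[0] + label[2] + label[6] for label in CHANNELS_96)


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


class ContextError(ValueError):
    """Reference context disagrees with the record or is unavailable."""


def triplet_class(genome, record: MutationRecord) -> int:
    """Return the 0..95 channel index of an SNV given its reference context.

    Raises :class:`ContextError` when the reference base at ``record.pos``
    does not equal ``record.ref`` or when a flanking base is N (the caller
    may count and skip such records).
    """
    if record.kind is not MutationKind.SNV:
        raise ValueError("triplet_class is defined for SNVs only")
    chrom = genome[record.chrom]
    i = record.pos - 1  # 0-based
    if i < 1 or i + 1 >= len(chrom):
        raise ContextError(f"{record.chrom}:{record.pos} lacks a flanking base")
    context = str(chrom[i - 1: i + 2]).upper()
    if context[1] != record.ref:
        raise ContextError(
            f"reference mismatch at {record.chrom}:{record.pos}: "
            f"genome has {context[1]}, record says {record.ref}"
        )
    if "N" in context:
        raise ContextError(f"N in context at {record.chrom}:{record.pos}")
    ref, alt = record.ref, record.alt
    if ref in "AG":  # purine reference: flip to the pyrimidine strand
        context = revcomp(context)
        ref = context[1]
        alt = revcomp(alt)
    return _CHANNEL_INDEX[f"{context[0]}[{ref}>{alt}]{context[2]}"]


def build_spectrum(
    records: Iterable[MutationRecord], genome, label: str = ""
) -> pd.Series:
    """Tally SNVs into a 96-channel spectrum.

    Non-SNV records are ignored; SNVs with unusable context (flanking N,
    contig edge) are skipped with a warning.  The returned Series is indexed
    by channel label, named ``label``, and sums to the number of classified
    SNVs.
    """
    counts = np.zeros(96, dtype=float)
    skipped = 0
    for record in records:
        if record.kind is not MutationKind.SNV:
            continue
        try:
            counts[triplet_class(genome, record)] += 1
        except ContextError as exc:
            if "mismatch" in str(exc):
                raise
            skipped += 1
    if skipped:
        warnings.warn(f"{skipped} SNV(s) skipped for unusable context", stacklevel=2)
    return pd.Series(counts, index=list(CHANNELS_96), name=label or None)


def spectra_by_group(
    records: Iterable[MutationRecord],
    genome,
    group_of: dict[str, str] | None = None,
    how: str = "sum",
) -> pd.DataFrame:
    """Per-sample or per-group spectra as a samples x 96 DataFrame.

    ``group_of`` maps sample_id to a group (e.g. genotype); when given,
    per-sample spectra are aggregated per group either by summing counts
    (``how="sum"``, the default, suited to factorization input) or by
    averaging the per-sample spectra (``how="mean"``, suited to display).
    """
    by_sample: dict[str, list[MutationRecord]] = {}
    for record in records:
        by_sample.setdefault(record.sample_id, []).append(record)
    rows = {
        sample: build_spectrum(recs, genome, label=sample)
        for sample, recs in sorted(by_sample.items())
    }
    frame = pd.DataFrame(rows).T
    frame.columns = list(CHANNELS_96)
    if group_of is None:
        return frame
    groups = frame.index.map(lambda s: group_of[s])
    if how == "sum":
        return frame.groupby(groups).sum()
    if how == "mean":
        return frame.groupby(groups).mean()
    raise ValueError("how must be 'sum' or 'mean'")


def count_triplet_frequencies(genome) -> pd.Series:
    """Strand-collapsed pyrimidine-centered triplet frequencies of a genome.

    Every overlapping 3-mer is counted once; purine-centered triplets count
    toward their reverse complement.  Windows containing N are skipped.
    Returns a normalized 32-entry Series (all entries of a real genome > 0).
    """
    counts = np.zeros(32, dtype=float)
    total_len = 0
    for name in genome.keys():
        seq = str(genome[name][:]).upper()
        total_len += len(seq)
        for i in range(len(seq) - 2):
            tri = seq[i: i + 3]
            if "N" in tri:
                continue
            if tri[1] in "AG":
                tri = revcomp(tri)
            counts[_TRIPLET_INDEX[tri]] += 1
    if total_len < 3:
        raise ValueError("genome shorter than 3 bp")
    total = counts.sum()
    if total == 0:
        raise ValueError("no countable triplets (all N?)")
    return pd.Series(counts / total, index=list(TRIPLETS_32))


def adjust_triplet_frequencies(
    signatures: pd.DataFrame, source_freq: pd.Series, target_freq: pd.Series
) -> pd.DataFrame:
    """Re-weight 96-channel signatures from one genome's triplet frequencies
    to another's.

    Each channel is multiplied by ``target_freq / source_freq`` of its
    pyrimidine-centered reference triplet and the columns are renormalized.
    Used to compare signatures derived on one species (or an exome) against
    references defined on another.
    """
    source = source_freq.reindex(list(TRIPLETS_32))
    target = target_freq.reindex(list(TRIPLETS_32))
    if source.isna().any() or (source <= 0).any():
        raise ValueError("source frequencies must be positive for all 32 triplets")
    ratio = (target / source).to_numpy()
    weights = ratio[[_TRIPLET_INDEX[t] for t in CHANNEL_TRIPLETS]]
    sigs = as_signature_frame(signatures)
    adjusted = sigs.mul(weights, axis=0)
    return adjusted / adjusted.sum(axis=0)


def as_signature_frame(signatures) -> pd.DataFrame:
    """Coerce to a channels x k DataFrame indexed by the 96 channel labels."""
    frame = pd.DataFrame(signatures)
    if list(frame.index) != list(CHANNELS_96):
        if frame.shape[0] != 96:
            raise ValueError("expected 96 channel rows")
        frame = frame.set_axis(list(CHANNELS_96), axis=0)
    return frame.astype(float)
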