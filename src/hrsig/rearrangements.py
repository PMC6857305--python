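"""Structural-variant post-filtering, clustering and 32-category classification.

Breakpoint calls from a split-read caller are post-filtered with three
orthogonal criteria (cross-sample breakpoint uniqueness, coverage of both
breakpoints in every sample, minimum soft-clip support), scanned for
clustered rearrangements by piecewise-constant fitting (PCF) of the log10
inter-breakpoint distances, and classified into the 32 categories used to
define rearrangement signatures: {clustered, non-clustered} x ({deletion,
tandem duplication, inversion} x five size bins + translocation).  Signature
contributions are then obtained by nonnegative least squares.
"""

from __future__ import annotations

import math
import warnings
from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fitting import ReferenceSignatureFit

SV_TYPES = ("deletion", "insertion", "tandem-duplication", "inversion", "ITX", "CTX")

_TYPE_ALIASES = {
    "del": "deletion", "deletion": "deletion",
    "ins": "insertion", "insertion": "insertion",
    "dup": "tandem-duplication", "tandem-duplication": "tandem-duplication",
    "td": "tandem-duplication",
    "inv": "inversion", "inversion": "inversion",
    "itx": "ITX", "ctx": "CTX",
}

#: half-open size bins, upper-exclusive: [1,10) kb ... [10 Mb, inf)
SIZE_BINS = (
    ("1-10kb", 1e3, 1e4),
    ("10-100kb", 1e4, 1e5),
    ("100kb-1Mb", 1e5, 1e6),
    ("1-10Mb", 1e6, 1e7),
    (">10Mb", 1e7, math.inf),
)

#: the 32 rearrangement channels, canonical order.
RS_CHANNELS = tuple(
    f"{cluster}:{kind}:{size}"
    for cluster in ("clustered", "non_clustered")
    for kind in ("del", "dup", "inv")
    for size, _, _ in SIZE_BINS
) + ("clustered:trans", "non_clustered:trans")
# reorder so each cluster block is contiguous with its translocation channel
RS_CHANNELS = tuple(
    [c for c in RS_CHANNELS if c.startswith("clustered:") and ":trans" not in c]
    + ["clustered:trans"]
    + [c for c in RS_CHANNELS if c.startswith("non_clustered:") and ":trans" not in c]
    + ["non_clustered:trans"]
)


@dataclass(frozen=True)
class SVRecord:
    """One structural-variant call (CREST-style breakpoint pair)."""

    sample_id: str
    chrom1: str
    pos1: int
    chrom2: str
    pos2: int
    sv_type: str
    softclip_support: int = 0

    def __post_init__(self) -> None:
        if self.sv_type not in SV_TYPES:
            raise ValueError(f"unknown SV type {self.sv_type!r}")
        if self.softclip_support < 0:
            raise ValueError("softclip support must be >= 0")
        if (self.chrom1 != self.chrom2) != (self.sv_type == "CTX"):
            raise ValueError("CTX if and only if breakpoints on different chromosomes")

    @property
    def size(self) -> int | None:
        """Event size in bp (intra-chromosomal only)."""
        if self.chrom1 != self.chrom2:
            return None
        return abs(self.pos2 - self.pos1)

    @property
    def breakpoints(self) -> tuple[tuple[str, int], tuple[str, int]]:
        return (self.chrom1, self.pos1), (self.chrom2, self.pos2)


def load_sv_table(path) -> list[SVRecord]:
    """Read a CREST-like TSV: sample, chrom1, pos1, chrom2, pos2, type, softclips."""
    table = pd.read_csv(path, sep=r"\s+", dtype=str)
    table.columns = [c.lower() for c in table.columns]
    records = []
    for row in table.itertuples(index=False):
        records.append(
            SVRecord(
                sample_id=row.sample,
                chrom1=row.chrom1, pos1=int(row.pos1),
                chrom2=row.chrom2, pos2=int(row.pos2),
                sv_type=_TYPE_ALIASES[row.type.lower()],
                softclip_support=int(row.softclips),
            )
        )
    return records


# ----------------------------------------------------------------------
# post-filtering
# ----------------------------------------------------------------------

def filter_svs(
    candidates: Sequence[SVRecord],
    coverage_lookup,
    samples: Sequence[str] | None = None,
    min_softclip: int = 5,
    uniqueness_tol: int = 10,
) -> list[SVRecord]:
    """Apply the three validity filters to candidate SV calls.

    A call is retained when (i) neither breakpoint occurs (within
    ``uniqueness_tol`` bp) in a *different* sample's call set, (ii) every
    sample has coverage >= 1 at both breakpoints, and (iii) the call is
    supported by at least ``min_softclip`` soft-clipped reads.

    ``coverage_lookup`` maps ``(sample, chrom, pos) -> depth`` (mapping or
    callable); a missing entry raises ``KeyError`` naming sample and
    position.  The retained set is independent of candidate order.
    """
    if samples is None:
        samples = sorted({c.sample_id for c in candidates})
    if isinstance(coverage_lookup, Mapping):
        lookup = coverage_lookup.__getitem__
    else:
        lookup = coverage_lookup

    by_chrom: dict[str, list[tuple[int, str]]] = {}
    for cand in candidates:
        for chrom, pos in cand.breakpoints:
            by_chrom.setdefault(chrom, []).append((pos, cand.sample_id))

    def unique_to_sample(chrom: str, pos: int, sample: str) -> bool:
        for other_pos, other_sample in by_chrom.get(chrom, ()):
            if other_sample != sample and abs(other_pos - pos) <= uniqueness_tol:
                return False
        return True

    def covered_in_all(chrom: str, pos: int) -> bool:
        for sample in samples:
            try:
                depth = lookup((sample, chrom, pos))
            except KeyError:
                raise KeyError(
                    f"coverage missing for sample {sample!r} at {chrom}:{pos}"
                ) from None
            if depth < 1:
                return False
        return True

    retained = []
    for cand in candidates:
        if cand.softclip_support < min_softclip:
            continue
        if not all(unique_to_sample(c, p, cand.sample_id) for c, p in cand.breakpoints):
            continue
        if not all(covered_in_all(c, p) for c, p in cand.breakpoints):
            continue
        retained.append(cand)
    return retained


# ----------------------------------------------------------------------
# clustered-rearrangement detection (piecewise-constant fitting)
# ----------------------------------------------------------------------

def segment_piecewise_constant(
    values: np.ndarray, kmin: int = 10, gamma: float = 25.0
) -> list[tuple[int, int]]:
    """Exact least-squares piecewise-constant segmentation.

    Minimizes sum of squared residuals around per-segment means plus
    ``gamma`` per changepoint, subject to a minimum segment length
    ``kmin``, by O(n^2) dynamic programming.  Returns half-open index
    ranges ``(start, end)`` covering ``values``.
    """
    y = np.asarray(values, dtype=float)
    n = len(y)
    if n == 0:
        return []
    if n < 2 * kmin:
        return [(0, n)]
    s1 = np.concatenate([[0.0], np.cumsum(y)])
    s2 = np.concatenate([[0.0], np.cumsum(y * y)])

    def sse(i: int, j: int) -> float:  # half-open [i, j)
        m = j - i
        seg_sum = s1[j] - s1[i]
        return (s2[j] - s2[i]) - seg_sum * seg_sum / m

    INF = math.inf
    best = np.full(n + 1, INF)
    prev = np.zeros(n + 1, dtype=int)
    best[0] = -gamma  # first segment carries no changepoint penalty
    for j in range(kmin, n + 1):
        for i in range(0, j - kmin + 1):
            if best[i] == INF:
                continue
            c = best[i] + gamma + sse(i, j)
            if c < best[j]:
                best[j], prev[j] = c, i
    bounds = []
    j = n
    while j > 0:
        i = int(prev[j])
        bounds.append((i, j))
        j = i
    return bounds[::-1]


def detect_clusters(
    breakpoints: Mapping[str, Sequence[int]],
    kmin: int = 10,
    gamma: float = 25.0,
    fold: float = 10.0,
) -> dict[str, list[tuple[int, int]]]:
    """Detect clustered-rearrangement regions per chromosome.

    For each chromosome's sorted breakpoint positions, the log10
    inter-breakpoint distances are segmented by exact PCF (``kmin``,
    ``gamma``); a segment whose mean inter-breakpoint distance is more than
    ``fold`` times smaller than the chromosome average marks its
    breakpoints as clustered.  Chromosomes with fewer than ``kmin``
    distances yield no clusters.  Returns position intervals
    ``(first_bp, last_bp)`` of the clustered runs.
    """
    clusters: dict[str, list[tuple[int, int]]] = {}
    for chrom, positions in breakpoints.items():
        pos = np.sort(np.asarray(positions, dtype=float))
        out: list[tuple[int, int]] = []
        if len(pos) >= 2:
            d = np.maximum(np.diff(pos), 1.0)
            if len(d) >= kmin:
                chrom_mean = d.mean()
                for i, j in segment_piecewise_constant(np.log10(d), kmin, gamma):
                    if d[i:j].mean() < chrom_mean / fold:
                        out.append((int(pos[i]), int(pos[j])))
        clusters[chrom] = out
    return clusters


def _in_cluster(clusters: Mapping[str, list[tuple[int, int]]],
                chrom: str, pos: int) -> bool:
    return any(lo <= pos <= hi for lo, hi in clusters.get(chrom, ()))


# ----------------------------------------------------------------------
# 32-category classification and signature fitting
# ----------------------------------------------------------------------

_KIND_OF = {"deletion": "del", "tandem-duplication": "dup",
            "insertion": "dup", "inversion": "inv", "CTX": "trans"}


def size_bin(size: float) -> str:
    """Half-open size bin label; sub-kb events fall into the smallest bin."""
    if size < SIZE_BINS[0][1]:
        warnings.warn(
            f"SV of {size:.0f} bp below the 1 kb bin floor; counted in 1-10kb",
            stacklevel=3,
        )
        return SIZE_BINS[0][0]
    for label, lo, hi in SIZE_BINS:
        if lo <= size < hi:
            return label
    raise AssertionError("unreachable")


def classify_rearrangements(
    svs: Sequence[SVRecord],
    clusters: Mapping[str, list[tuple[int, int]]],
) -> tuple[pd.Series, list[SVRecord]]:
    """Assign filtered SVs to the 32 rearrangement channels.

    An SV is clustered when either breakpoint lies in a clustered region.
    CREST "insertion" calls are counted as tandem duplications (an inserted
    duplicated segment); ITX calls lack the orientation needed to map onto
    the deletion/duplication/inversion scheme and are excluded from the
    32-channel catalog, returned separately.

    Returns the 32-channel count Series (summing to the number of
    classified SVs) and the list of excluded ITX records.
    """
    counts = pd.Series(0.0, index=list(RS_CHANNELS))
    excluded: list[SVRecord] = []
    for sv in svs:
        if sv.sv_type == "ITX":
            excluded.append(sv)
            continue
        clustered = any(_in_cluster(clusters, c, p) for c, p in sv.breakpoints)
        prefix = "clustered" if clustered else "non_clustered"
        kind = _KIND_OF[sv.sv_type]
        if kind == "trans":
            counts[f"{prefix}:trans"] += 1
        else:
            counts[f"{prefix}:{kind}:{size_bin(sv.size)}"] += 1
    if excluded:
        warnings.warn(
            f"{len(excluded)} ITX call(s) excluded from the 32-channel catalog",
            stacklevel=2,
        )
    return counts, excluded


def fit_rearrangement_signatures(
    catalog: pd.Series, rs: pd.DataFrame, min_contribution: float = 0.0
):
    """NNLS contributions of rearrangement signatures to a 32-channel catalog.

    Returns a :class:`~hrsig.fitting.ReferenceSignatureFitResults` whose
    ``contributions`` are the display fractions; no pruning by default.
    """
    catalog = catalog.reindex(list(RS_CHANNELS)).fillna(0.0)
    return ReferenceSignatureFit(catalog, rs).fit(min_contribution=min_contribution)
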