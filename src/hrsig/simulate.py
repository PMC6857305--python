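"""Ground-truthed synthetic data generators.

These generators emulate the study conditions of an isogenic-clone mutation
accumulation experiment: per-clone SNV burdens drawn from genotype-specific
means (wild type ~120 SNVs/genome, HR-deficient lines 7-8x higher, partial
phenotypes in between), spectra drawn multinomially from signature
mixtures, genomes with deletions planted in contexts that force a known
repeat/microhomology/none classification, and structural-variant sets drawn
from rearrangement-category mixtures.  Every generator is seed-deterministic
and emits machine-readable truth alongside the data.

:func:`separability_experiment` is the simulation used to ask whether two
near-degenerate ("featureless") substitution signatures can be separated by
rank-2 NMF at realistic burdens; its defaults are the scale of the cell-line
experiment (33 genomes, ~1,000 mutations each).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fitting import cosine_similarity
from .indels import max_microhomology, tandem_copies
from .nmf import SignatureNMF
from .rearrangements import RS_CHANNELS, SIZE_BINS, SVRecord
from .records import MutationKind, MutationRecord
from .spectrum import CHANNELS_96

# ----------------------------------------------------------------------
# study-condition defaults (per-genome mutation burdens by genotype)
# ----------------------------------------------------------------------

#: mean newly arising SNVs per sequenced genome; wild type ~120, BRCA1/2 and
#: RAD51-paralog/PALB2 knockouts 7-8x, RAD54 3x, ATM 1.5x, RAD52/CHK2 ~1x.
DEFAULT_SNV_BURDEN = {
    "WT": 120, "BRCA1": 900, "BRCA2": 930, "PALB2": 870, "RAD51C": 840,
    "XRCC2": 900, "XRCC3": 870, "RAD54": 360, "RAD52": 120, "ATM": 180,
    "CHK2": 130,
}

#: mean short deletions per genome (BRCA2/PALB2 carry the strongest phenotype).
DEFAULT_DEL_BURDEN = {
    "WT": 4, "BRCA1": 10, "BRCA2": 24, "PALB2": 22, "RAD51C": 10,
    "XRCC2": 11, "XRCC3": 10, "RAD54": 7, "RAD52": 4, "ATM": 4, "CHK2": 4,
}

#: mean short insertions per genome (few arise; mild XRCC2/PALB2 excess).
DEFAULT_INS_BURDEN = {
    "WT": 1, "BRCA1": 1, "BRCA2": 2, "PALB2": 3, "RAD51C": 1,
    "XRCC2": 3, "XRCC3": 1, "RAD54": 1, "RAD52": 1, "ATM": 1, "CHK2": 1,
}

#: deletion length distributions: most genotypes are dominated by 1-bp
#: events (median 1 bp); BRCA2/PALB2 produce longer, microhomology-rich
#: deletions (median ~4 bp), resembling repair products at blunt breaks.
DEL_LENGTH_SHORT = {1: 0.75, 2: 0.10, 3: 0.05, 4: 0.03, 5: 0.02, 6: 0.02,
                    8: 0.01, 10: 0.01, 15: 0.01}
DEL_LENGTH_LONG_MH = {1: 0.20, 2: 0.10, 3: 0.15, 4: 0.15, 5: 0.12, 6: 0.08,
                      8: 0.08, 10: 0.06, 15: 0.04, 20: 0.02}
DEFAULT_DEL_LENGTH_DIST = {
    g: (DEL_LENGTH_LONG_MH if g in ("BRCA2", "PALB2") else DEL_LENGTH_SHORT)
    for g in DEFAULT_SNV_BURDEN
}

#: deletion context-class mixes (repeat, microhomology, none); the
#: BRCA2/PALB2 axis exceeds 50% microhomology.
DEFAULT_CLASS_MIX = {
    g: ((0.20, 0.55, 0.25) if g in ("BRCA2", "PALB2") else (0.40, 0.25, 0.35))
    for g in DEFAULT_SNV_BURDEN
}


def simulate_clone_counts(
    n_clones: int = 3,
    snv_burden: dict | None = None,
    del_burden: dict | None = None,
    ins_burden: dict | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-clone Poisson mutation counts at genotype-specific means.

    Returns one row per clone with columns ``genotype``/``sample``/``snv``/
    ``ins``/``del`` — the input layout of the rate summary.
    """
    snv_burden = snv_burden or DEFAULT_SNV_BURDEN
    del_burden = del_burden or DEFAULT_DEL_BURDEN
    ins_burden = ins_burden or DEFAULT_INS_BURDEN
    rng = np.random.default_rng(seed)
    rows = []
    for genotype, mean_snv in snv_burden.items():
        for clone in range(1, n_clones + 1):
            rows.append({
                "genotype": genotype,
                "sample": f"{genotype}_c{clone}",
                "snv": int(rng.poisson(mean_snv)),
                "ins": int(rng.poisson(ins_burden.get(genotype, 1))),
                "del": int(rng.poisson(del_burden.get(genotype, 2))),
            })
    return pd.DataFrame(rows)


def simulate_deletion_lengths(
    genotype: str, n: int, seed: int | None = None
) -> np.ndarray:
    """Draw deletion lengths from the genotype's default length distribution."""
    dist = DEFAULT_DEL_LENGTH_DIST[genotype]
    rng = np.random.default_rng(seed)
    lengths = np.array(list(dist.keys()))
    probs = np.array(list(dist.values()), dtype=float)
    return rng.choice(lengths, size=n, p=probs / probs.sum())


# ----------------------------------------------------------------------
# signature-mixture SNV catalogs
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class CatalogSimSpec:
    """Specification of a signature-mixture spectrum simulation.

    ``signatures`` is a channels x k column-stochastic DataFrame;
    ``exposures`` a samples x k array of expected mutation counts.
    """

    signatures: pd.DataFrame
    exposures: np.ndarray
    seed: int | None = None

    @property
    def n_samples(self) -> int:
        return np.asarray(self.exposures).shape[0]


def simulate_catalog(spec: CatalogSimSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw per-sample channel counts from exposure-weighted mixtures.

    Each sample's counts are multinomial with total equal to its summed
    exposure and channel probabilities given by the exposure-weighted
    signature mixture.  Returns ``(spectra, truth_exposures)``, both
    samples x (channels | k) DataFrames.
    """
    sigs = spec.signatures.to_numpy(dtype=float)
    exposures = np.atleast_2d(np.asarray(spec.exposures, dtype=float))
    if exposures.shape[1] != sigs.shape[1]:
        raise ValueError("exposure columns must match signature columns")
    if (exposures < 0).any():
        raise ValueError("exposures must be nonnegative")
    totals = exposures.sum(axis=1)
    if (totals == 0).any():
        raise ValueError("each sample needs a positive total exposure")
    rng = np.random.default_rng(spec.seed)
    rows = []
    for i in range(exposures.shape[0]):
        probs = sigs @ (exposures[i] / totals[i])
        probs = probs / probs.sum()
        rows.append(rng.multinomial(int(round(totals[i])), probs))
    samples = [f"sample_{i + 1}" for i in range(len(rows))]
    spectra = pd.DataFrame(rows, index=samples, columns=spec.signatures.index)
    truth = pd.DataFrame(exposures, index=samples, columns=spec.signatures.columns)
    return spectra, truth


@dataclass(frozen=True)
class SeparabilityResult:
    mae_percent: float
    per_replicate: tuple[float, ...]
    mean_cosine: float


def separability_experiment(
    sig_a: pd.Series,
    sig_b: pd.Series,
    mixture_grid: tuple[float, ...] = (0.2, 0.35, 0.5, 0.65, 0.8),
    n_samples: int = 33,
    muts_per_sample: int = 1000,
    replicates: int = 10,
    seed: int | None = None,
    n_restarts: int = 10,
) -> SeparabilityResult:
    """Can rank-2 NMF separate two near-degenerate signatures?

    For each replicate, ``n_samples`` spectra are drawn from mixtures of the
    two signatures (mixture fractions cycling over ``mixture_grid``) at
    ``muts_per_sample`` mutations each; rank-2 NMF is run and the recovered
    signatures are matched to the generators by best cosine assignment.  The
    result is the mean absolute error between recovered and generating
    channel probabilities, in percentage points (channels expressed as
    percentages summing to 100), averaged over replicates.
    """
    a = np.asarray(sig_a, dtype=float).ravel()
    b = np.asarray(sig_b, dtype=float).ravel()
    a, b = a / a.sum(), b / b.sum()
    if cosine_similarity(a, b) >= 1.0 - 1e-12:
        raise ValueError("signatures are identical; mixture is non-identifiable")
    sigs = pd.DataFrame({"A": a, "B": b})
    ss = np.random.SeedSequence(seed)
    rep_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(replicates)]
    maes, cosines = [], []
    for rep_seed in rep_seeds:
        fractions = np.array(
            [mixture_grid[i % len(mixture_grid)] for i in range(n_samples)]
        )
        exposures = muts_per_sample * np.column_stack([fractions, 1 - fractions])
        spectra, _ = simulate_catalog(
            CatalogSimSpec(signatures=sigs, exposures=exposures, seed=rep_seed)
        )
        res = SignatureNMF(spectra).fit(
            rank=2, n_restarts=n_restarts, seed=rep_seed + 1
        )
        recovered = res.signatures.to_numpy()
        truth = np.column_stack([a, b])
        order = _best_cosine_assignment(recovered, truth)
        matched = recovered[:, order]
        maes.append(100.0 * np.mean(np.abs(matched - truth)))
        cosines.append(np.mean(
            [cosine_similarity(matched[:, j], truth[:, j]) for j in range(2)]
        ))
    return SeparabilityResult(
        mae_percent=float(np.mean(maes)),
        per_replicate=tuple(float(m) for m in maes),
        mean_cosine=float(np.mean(cosines)),
    )


def _best_cosine_assignment(recovered: np.ndarray, truth: np.ndarray) -> list[int]:
    """Column order of ``recovered`` best matching ``truth`` (k=2 exact)."""
    k = truth.shape[1]
    if k == 2:
        straight = (cosine_similarity(recovered[:, 0], truth[:, 0])
                    + cosine_similarity(recovered[:, 1], truth[:, 1]))
        crossed = (cosine_similarity(recovered[:, 1], truth[:, 0])
                   + cosine_similarity(recovered[:, 0], truth[:, 1]))
        return [0, 1] if straight >= crossed else [1, 0]
    # greedy for k > 2
    order: list[int] = []
    free = list(range(k))
    for j in range(k):
        best = max(free, key=lambda c: cosine_similarity(recovered[:, c], truth[:, j]))
        order.append(best)
        free.remove(best)
    return order


# ----------------------------------------------------------------------
# genomes with planted, context-classified deletions
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class IndelSimSpec:
    """Specification for planting context-classified deletions in a genome."""

    genome_length: int = 100_000
    class_mix: tuple[float, float, float] = (0.4, 0.25, 0.35)  # repeat, MH, none
    length_dist: dict = field(default_factory=lambda: dict(DEL_LENGTH_SHORT))
    n_events: int = 50
    seed: int | None = None
    gc: float = 0.5
    chrom_name: str = "chrS"

    def __post_init__(self) -> None:
        if abs(sum(self.class_mix) - 1.0) > 1e-9:
            raise ValueError("class mix fractions must sum to 1")
        if any(l < 1 for l in self.length_dist):
            raise ValueError("deletion lengths must be >= 1")


@dataclass(frozen=True)
class PlantedDeletion:
    record: MutationRecord
    truth_class: str
    truth_mh: int
    truth_copies: int


def simulate_genome_with_indels(
    spec: IndelSimSpec,
) -> tuple[dict[str, str], list[PlantedDeletion]]:
    """Generate a random genome with deletions planted in forced contexts.

    * repeat — the deleted unit is embedded in a tandem array of >= 2 copies;
    * microhomology — a k-bp prefix of the deleted sequence is copied just
      past the 3' breakpoint (and nowhere adjacent as a full copy);
    * none — sites with incidental breakpoint homology or tandem copies are
      rejected and re-drawn.

    Events are non-overlapping with generous spacing.  Returns the genome as
    ``{chrom: sequence}`` (usable wherever an indexed FASTA is) and the
    truth list.  Raises if the genome is too short to place all events.
    """
    rng = np.random.default_rng(spec.seed)
    max_len = max(spec.length_dist) if spec.length_dist else 1
    required = max(
        10 * max_len * max(spec.n_events, 1),
        (6 * max_len + 12) * (spec.n_events + 1),
    )
    if spec.genome_length < required:
        raise ValueError(
            "genome too short to place all events; increase genome_length"
        )
    base_probs = np.array(
        [(1 - spec.gc) / 2, spec.gc / 2, spec.gc / 2, (1 - spec.gc) / 2]
    )
    genome = rng.choice(list("ACGT"), size=spec.genome_length, p=base_probs)
    lengths = np.array(list(spec.length_dist.keys()))
    length_p = np.array(list(spec.length_dist.values()), dtype=float)
    length_p /= length_p.sum()

    classes = rng.choice(
        ["repeat", "microhomology", "none"], size=spec.n_events, p=spec.class_mix
    )
    if spec.n_events == 0:
        return {spec.chrom_name: "".join(genome)}, []
    spacing = spec.genome_length // (spec.n_events + 1)
    truths: list[PlantedDeletion] = []
    for e, cls in enumerate(classes):
        L = int(rng.choice(lengths, p=length_p))
        # MH needs length >= 2; 1-bp events with forced homology are repeats
        if cls == "microhomology":
            while L < 2:
                L = int(rng.choice(lengths, p=length_p))
        site = (e + 1) * spacing  # 0-based index of first deleted base
        for _attempt in range(200):
            ok, mh, copies = _plant(genome, site, L, cls, rng)
            if ok:
                break
        else:
            raise RuntimeError(f"could not force class {cls!r} at site {site}")
        chrom = genome  # mutated in place by _plant
        deleted = "".join(chrom[site: site + L])
        anchor = chrom[site - 1]
        record = MutationRecord(
            sample_id="sim", chrom=spec.chrom_name, pos=site,
            ref=anchor + deleted, alt=anchor, kind=MutationKind.DEL,
        )
        truths.append(PlantedDeletion(record, cls, mh, copies))
    return {spec.chrom_name: "".join(genome)}, truths


def _plant(genome: np.ndarray, site: int, L: int, cls: str,
           rng: np.random.Generator) -> tuple[bool, int, int]:
    """Write a context of the requested class at ``site``; returns
    (success, mh_length, tandem_copies) as measured on the written context."""
    flank = 6 * L + 10
    lo, hi = max(1, site - flank), min(len(genome) - 1, site + L + flank)

    def draw(n: int) -> str:
        return "".join(rng.choice(list("ACGT"), size=n))

    # randomize the whole neighborhood, then impose the class structure
    genome[lo:hi] = list(draw(hi - lo))
    if cls == "repeat":
        unit = draw(L)
        copies = int(rng.integers(2, 4))
        array = unit * copies
        genome[site: site + len(array)] = list(array)
        # left neighbor must not extend the array (keeps it left-aligned)
        if genome[site - 1] == unit[-1]:
            genome[site - 1] = _other_base(unit[-1], rng)
        if genome[site + len(array)] == array[0]:
            # avoid a partial extra copy confusing nothing; harmless, keep
            pass
    elif cls == "microhomology":
        seq = draw(L)
        k = int(rng.integers(1, min(L - 1, 5) + 1))
        genome[site: site + L] = list(seq)
        genome[site + L: site + L + k] = list(seq[:k])
        # break any full tandem copy and any left-side effects
        if site + L + k < len(genome) and genome[site + L + k] == seq[k % L]:
            genome[site + L + k] = _other_base(seq[k % L], rng)
        if genome[site - 1] == seq[-1]:
            genome[site - 1] = _other_base(seq[-1], rng)
    left = "".join(genome[lo:site])
    right = "".join(genome[site + L: hi])
    deleted = "".join(genome[site: site + L])
    copies = tandem_copies(deleted, left, right)
    mh = max_microhomology(deleted, left, right) if L > 1 else 0
    measured = "repeat" if copies >= 2 else ("microhomology" if mh >= 1 else "none")
    if measured != cls:
        return False, 0, 1
    return True, mh if measured != "none" else 0, copies


def _other_base(base: str, rng: np.random.Generator) -> str:
    choices = [b for b in "ACGT" if b != base]
    return choices[int(rng.integers(0, 3))]


# ----------------------------------------------------------------------
# structural-variant catalogs
# ----------------------------------------------------------------------

#: synthetic karyotype used for SV placement
_SYNTH_CHROMS = {f"chr{i}": 120_000_000 for i in range(1, 9)}


def simulate_sv_catalog(
    rs: pd.DataFrame,
    contributions,
    n_events: int,
    seed: int | None = None,
    samples: tuple[str, ...] = ("sim",),
) -> tuple[list[SVRecord], pd.Series]:
    """Draw SVs from a rearrangement-signature mixture.

    Channel counts are multinomial under the mixture probability vector;
    within a size bin sizes are log-uniform; positions are uniform on a
    synthetic karyotype, except that clustered-channel events are packed
    into one dense region per chromosome so that clustered geometry is
    physically present.  Returns the records (soft-clip support drawn
    8-30, so they pass the support filter) and the truth channel counts.
    """
    contributions = np.asarray(contributions, dtype=float)
    if (contributions < 0).any() or contributions.sum() == 0:
        raise ValueError("contributions must be nonnegative and not all zero")
    probs = rs.to_numpy() @ (contributions / contributions.sum())
    probs = probs / probs.sum()
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_events, probs)
    truth = pd.Series(counts.astype(float), index=list(rs.index))
    chroms = list(_SYNTH_CHROMS)
    bins = {label: (lo, hi if np.isfinite(hi) else 3e7)
            for label, lo, hi in SIZE_BINS}
    records: list[SVRecord] = []
    cluster_anchor = {c: rng.integers(2e7, 8e7) for c in chroms}
    for channel, count in truth.items():
        for _ in range(int(count)):
            parts = channel.split(":")
            clustered = parts[0] == "clustered"
            kind = parts[1]
            sample = samples[int(rng.integers(0, len(samples)))]
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            if kind == "trans":
                other = chroms[int(rng.integers(0, len(chroms) - 1))]
                if other == chrom:
                    other = chroms[-1]
                p1 = _place(rng, chrom, clustered, cluster_anchor)
                p2 = int(rng.integers(1e6, _SYNTH_CHROMS[other] - 1e6))
                records.append(SVRecord(sample, chrom, p1, other, p2, "CTX",
                                        int(rng.integers(8, 30))))
            else:
                lo, hi = bins[parts[2]]
                size = int(10 ** rng.uniform(np.log10(lo), np.log10(hi)))
                p1 = _place(rng, chrom, clustered, cluster_anchor)
                sv_type = {"del": "deletion", "dup": "tandem-duplication",
                           "inv": "inversion"}[kind]
                records.append(SVRecord(sample, chrom, p1, chrom, p1 + size,
                                        sv_type, int(rng.integers(8, 30))))
    return records, truth


def _place(rng, chrom, clustered, cluster_anchor) -> int:
    if clustered:
        return int(cluster_anchor[chrom] + rng.integers(0, 500_000))
    return int(rng.integers(1e6, _SYNTH_CHROMS[chrom] - 3.1e7))
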