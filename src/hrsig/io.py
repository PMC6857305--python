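"""Catalog and reference-genome I/O.

Catalogs travel either as VCF 4.x (one sample per file, or the sample name
given explicitly) or as a headered tab-separated table with columns
``sample``/``chrom``/``pos``/``ref``/``alt`` — the layout of typical
per-clone mutation tables.  Records come back in file order, normalized to
minimal anchored form.
"""

from __future__ import annotations

import os
from pathlib import Path

import pandas as pd
import pysam
from pyfaidx import Fasta

from .records import CatalogParseError, MutationRecord, normalize

TSV_COLUMNS = ("sample", "chrom", "pos", "ref", "alt")


def open_genome(path: str | os.PathLike) -> Fasta:
    """Open an indexed FASTA (builds the .fai on first use)."""
    return Fasta(str(path), as_raw=False, sequence_always_upper=True)


def load_catalog(
    path: str | os.PathLike,
    format: str | None = None,
    sample_id: str | None = None,
) -> list[MutationRecord]:
    """Read a mutation catalog from VCF or TSV.

    Parameters
    ----------
    path : file path
    format : ``"vcf"`` or ``"tsv"``; inferred from the suffix when omitted.
    sample_id : sample attribution for VCFs without a usable sample column;
        ignored for TSV input, which carries its own ``sample`` column.
    """
    path = Path(path)
    if format is None:
        format = "vcf" if path.suffix.lower() in {".vcf", ".bcf", ".gz"} else "tsv"
    if format == "tsv":
        return _load_tsv(path)
    if format == "vcf":
        return _load_vcf(path, sample_id)
    raise ValueError(f"unknown catalog format {format!r}")


def _load_tsv(path: Path) -> list[MutationRecord]:
    table = pd.read_csv(path, sep=r"\s+", dtype=str)
    table.columns = [c.lower() for c in table.columns]
    missing = [c for c in TSV_COLUMNS if c not in table.columns]
    if missing:
        raise CatalogParseError(f"{path}: missing column(s) {', '.join(missing)}")
    records = []
    for i, row in enumerate(table.itertuples(index=False), start=2):
        try:
            records.append(
                normalize(row.sample, row.chrom, int(row.pos), row.ref, row.alt)
            )
        except (CatalogParseError, ValueError) as exc:
            raise CatalogParseError(f"{path} line {i}: {exc}") from exc
    return records


def _load_vcf(path: Path, sample_id: str | None) -> list[MutationRecord]:
    records = []
    with pysam.VariantFile(str(path)) as vcf:
        header_samples = list(vcf.header.samples)
        if sample_id is None:
            if len(header_samples) == 1:
                sample_id = header_samples[0]
            else:
                raise CatalogParseError(
                    f"{path}: sample_id required for a VCF with "
                    f"{len(header_samples)} sample columns"
                )
        for line_no, variant in enumerate(vcf, start=1):
            for alt in variant.alts or ():
                try:
                    records.append(
                        normalize(sample_id, variant.chrom, variant.pos,
                                  variant.ref, alt)
                    )
                except CatalogParseError as exc:
                    raise CatalogParseError(
                        f"{path} record {line_no}: {exc}"
                    ) from exc
    return records


def write_catalog_tsv(records: list[MutationRecord], path: str | os.PathLike) -> None:
    frame = pd.DataFrame(
        [(r.sample_id, r.chrom, r.pos, r.ref, r.alt, r.kind.value) for r in records],
        columns=["sample", "chrom", "pos", "ref", "alt", "kind"],
    )
    frame.to_csv(path, sep="\t", index=False)
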