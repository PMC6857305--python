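import pathlib
import random

import pytest

from hrsig.spectrum import revcomp


@pytest.fixture
def tiny_genome(tmp_path) -> dict[str, str]:
    """Deterministic 400-bp toy genome as a {chrom: seq} mapping."""
    rng = random.Random(42)
    seq = "".join(rng.choice("ACGT") for _ in range(400))
    return {"chr1": seq, "chr2": revcomp(seq)}


@pytest.fixture
def tiny_fasta(tmp_path, tiny_genome) -> pathlib.Path:
    """The toy genome written as an indexed FASTA."""
    path = tmp_path / "genome.fa"
    with open(path, "w") as fh:
        for name, seq in tiny_genome.items():
            fh.write(f">{name}\n{seq}\n")
    return path
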