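"""Synthetic reference signature sets.

The published reference sets normally used for deconvolution — the COSMIC v2
SNV signatures and the breast-cancer rearrangement signatures — are external
database artifacts that this package does not redistribute.  This module
instead constructs *synthetic stand-ins* with the documented qualitative
shapes, deterministically, so that every fitting and simulation routine can
run self-contained:

* ``synthetic_snv_signatures()`` — 96-channel stand-ins for the signatures
  the HR-phenotyping workflow refers to by number: the clock-like CpG
  deamination signature ("1"), the flat HR-deficiency signature ("3"), the
  flat clock-like signature ("5"), the mismatch-repair-deficiency group
  ("6", "15", "20", "26") and the alkylation/POLE-discussion signature
  ("11").  The "3"/"5" pair is deliberately built flat and highly collinear
  (cosine ≈ 0.9), mirroring the near-degeneracy that makes the real pair
  hard to separate.
* ``synthetic_rearrangement_signatures()`` — 32-category stand-ins RS1–RS6,
  with the deletion-dominated "RS5"-like column that HR-deficient genomes
  load on.

Signatures are probability vectors (columns sum to 1).  All constructions
use a fixed internal seed; they are bit-reproducible and are *not* the
published matrices.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .rearrangements import RS_CHANNELS
from .spectrum import CHANNELS_96, SUB_CLASSES

_SEED = 20190114  # fixed; texture only, not tuned


def _texture(rng: np.random.Generator, concentration: float) -> np.ndarray:
    """Mild multiplicative channel texture (gamma noise around 1)."""
    return rng.gamma(concentration, 1.0 / concentration, size=96)


def synthetic_snv_signatures() -> pd.DataFrame:
    """Synthetic 96-channel stand-ins for the COSMIC v2 signatures used here.

    Returns a 96 x 8 column-stochastic DataFrame with columns
    ``["1", "3", "5", "6", "11", "15", "20", "26"]``.  Shapes are qualitative
    emulations (see module docstring), not the published values.
    """
    rng = np.random.default_rng(_SEED)
    idx = np.arange(96)
    sub = idx // 16  # substitution class of each channel
    five = (idx % 16) // 4
    three = idx % 4
    is_ct = sub == SUB_CLASSES.index("C>T")
    is_tc = sub == SUB_CLASSES.index("T>C")
    three_is_g = three == 2  # alphabetical A,C,G,T

    cols = {}

    # "1": CpG C>T deamination — mass on N[C>T]G, faint flat background.
    w = np.full(96, 0.08)
    w[is_ct & three_is_g] += 12.0
    w[is_ct & ~three_is_g] += 0.6
    cols["1"] = w * _texture(rng, 40)

    # "3": featureless/flat (HR-deficiency-like): near-uniform with texture.
    cols["3"] = np.ones(96) * _texture(rng, 12)

    # "5": flat with a T>C lean, its own texture.
    w = np.ones(96)
    w[is_tc] = 2.0
    cols["5"] = w * _texture(rng, 12)

    # MMR-deficiency group: C>T-heavy variants with context preferences.
    w = np.full(96, 0.15)
    w[is_ct & three_is_g] += 6.0
    w[is_ct & (five == 2)] += 3.0  # G[C>T]N
    cols["6"] = w * _texture(rng, 25)

    w = np.full(96, 0.15)
    w[is_ct & (three == 3)] += 6.0  # N[C>T]T
    w[is_tc & (five == 0)] += 2.0
    cols["15"] = w * _texture(rng, 25)

    w = np.full(96, 0.2)
    w[is_ct & three_is_g] += 4.0
    w[sub == SUB_CLASSES.index("C>A")] += 1.0
    cols["20"] = w * _texture(rng, 25)

    w = np.full(96, 0.2)
    w[is_tc] += 3.0
    w[is_ct & (five == 1)] += 2.0  # C[C>T]N
    cols["26"] = w * _texture(rng, 25)

    # "11": alkylation-like, broad C>T at non-CpG.
    w = np.full(96, 0.1)
    w[is_ct & ~three_is_g] += 8.0
    cols["11"] = w * _texture(rng, 30)

    frame = pd.DataFrame(cols, index=list(CHANNELS_96))
    frame = frame[["1", "3", "5", "6", "11", "15", "20", "26"]]
    return frame / frame.sum(axis=0)


def synthetic_rearrangement_signatures() -> pd.DataFrame:
    """Synthetic 32-category rearrangement signature stand-ins RS1–RS6.

    Column-stochastic 32 x 6 DataFrame.  "RS5" concentrates on non-clustered
    deletions below 100 kb (the pattern HR-deficient genomes reconstruct
    with); the other columns cover large deletions/duplications, small tandem
    duplications, clustered translocations and clustered inversions, so the
    set spans the category space.  Qualitative stand-ins, not the published
    matrices.
    """
    def channel(cluster: str, kind: str, size: str = "") -> int:
        label = f"{cluster}:{kind}" + (f":{size}" if size else "")
        return RS_CHANNELS.index(label)

    weights = np.full((32, 6), 0.02)
    # RS1: non-clustered large deletions and duplications (1-10 Mb, >10 Mb)
    for size, w in (("1-10Mb", 4.0), (">10Mb", 2.0)):
        weights[channel("non_clustered", "del", size), 0] += w
        weights[channel("non_clustered", "dup", size), 0] += w / 2
    # RS2: non-clustered mid-size duplications and inversions
    for size, w in (("100kb-1Mb", 4.0), ("1-10Mb", 2.0)):
        weights[channel("non_clustered", "dup", size), 1] += w
        weights[channel("non_clustered", "inv", size), 1] += 1.5
    # RS3: small tandem duplications (1-10 kb)
    weights[channel("non_clustered", "dup", "1-10kb"), 2] += 8.0
    weights[channel("non_clustered", "dup", "10-100kb"), 2] += 2.0
    # RS4: clustered translocations
    weights[channel("clustered", "trans"), 3] += 8.0
    weights[channel("clustered", "del", "1-10kb"), 3] += 1.0
    # RS5: non-clustered small/mid deletions
    weights[channel("non_clustered", "del", "1-10kb"), 4] += 5.0
    weights[channel("non_clustered", "del", "10-100kb"), 4] += 4.0
    weights[channel("non_clustered", "del", "100kb-1Mb"), 4] += 1.5
    # RS6: clustered inversions and deletions
    for size in ("1-10kb", "10-100kb", "100kb-1Mb"):
        weights[channel("clustered", "inv", size), 5] += 2.5
        weights[channel("clustered", "del", size), 5] += 1.0

    frame = pd.DataFrame(
        weights, index=list(RS_CHANNELS),
        columns=[f"RS{i}" for i in range(1, 7)],
    )
    return frame / frame.sum(axis=0)
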