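"""Control-based post-filtering and per-genotype mutation-rate statistics.

Isogenic clone experiments carry their own false-positive control: the
ancestral clone of each line was sequenced alongside its descendants, and a
mutation called as unique to an *ancestral* clone after the experiment can
only be an artifact.  :func:`tune_control_threshold` turns that into a
quality-score cutoff; :func:`summarize_rates` compares per-genotype burdens
against the wild type with a chi-square test on summed counts.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class ScoredCall:
    """A candidate mutation call with its caller quality score."""

    sample_id: str
    kind: str  # "SNV" or "indel"
    score: float


def tune_control_threshold(
    candidates: list[ScoredCall],
    control_ids: set[str],
    max_snv: int = 5,
    max_indel: int = 1,
) -> tuple[float, float]:
    """Smallest score thresholds keeping every control within its caps.

    A call is retained iff ``score > threshold``; SNVs and indels get
    independent thresholds.  Defaults cap each control (ancestral) sample at
    five SNVs and one indel.  Returns ``inf`` with a warning for a class
    whose caps cannot be met (score ties at the ceiling).
    """
    snv_thr = _tune_one(
        [c for c in candidates if c.kind.upper() == "SNV"], control_ids, max_snv
    )
    indel_thr = _tune_one(
        [c for c in candidates if c.kind.upper() != "SNV"], control_ids, max_indel
    )
    return snv_thr, indel_thr


def _tune_one(calls: list[ScoredCall], control_ids: set[str], cap: int) -> float:
    controls = [c for c in calls if c.sample_id in control_ids]
    if not controls:
        return 0.0
    ceiling = max(c.score for c in calls)
    for threshold in sorted({0.0, *(c.score for c in controls)}):
        kept: dict[str, int] = {}
        for c in controls:
            if c.score > threshold:
                kept[c.sample_id] = kept.get(c.sample_id, 0) + 1
        if all(n <= cap for n in kept.values()):
            if threshold >= ceiling:
                break  # only satisfiable by discarding every call
            return threshold
    warnings.warn(
        "control caps unattainable at any usable threshold (score ties at "
        "the ceiling); returning inf",
        stacklevel=3,
    )
    return math.inf


def summarize_rates(
    counts: pd.DataFrame,
    wt_label: str,
    n_comparisons: int | None = None,
    count_col: str = "snv",
    genotype_col: str = "genotype",
) -> pd.DataFrame:
    """Per-genotype mutation burden summary with chi-square tests vs wild type.

    Parameters
    ----------
    counts : one row per sequenced clone with its genotype and per-class
        mutation counts (columns such as ``snv``/``ins``/``del``).
    wt_label : genotype label of the wild-type group.
    n_comparisons : Bonferroni multiplier; defaults to the number of
        non-wild-type genotypes.
    count_col : which count column the test and fold change are computed on.

    The test is a chi-square on the *summed* counts of the genotype versus
    the wild type, with expectation proportional to the number of clones in
    each group (equal mutational opportunity per clone is assumed: same
    genome, same culture time), no continuity correction, df = 1.  P values
    are Bonferroni-multiplied and capped at 1.
    """
    if genotype_col not in counts.columns:
        raise ValueError(f"missing {genotype_col!r} column")
    groups = counts.groupby(genotype_col)
    if wt_label not in groups.groups:
        raise ValueError(f"wild-type group {wt_label!r} not present")
    genotypes = list(groups.groups)
    if n_comparisons is None:
        n_comparisons = len(genotypes) - 1
    wt = groups.get_group(wt_label)
    wt_mean = wt[count_col].mean()
    wt_sum, wt_n = wt[count_col].sum(), len(wt)
    if wt_mean == 0:
        warnings.warn("wild-type mean count is 0; fold changes undefined", stacklevel=2)

    rows = []
    for genotype in genotypes:
        grp = groups.get_group(genotype)
        values = grp[count_col].to_numpy(dtype=float)
        mean = values.mean()
        sem = values.std(ddof=1) / np.sqrt(len(values)) if len(values) > 1 else 0.0
        fold = mean / wt_mean if wt_mean > 0 else float("nan")
        if genotype == wt_label:
            chi2, p_adj = 0.0, 1.0
        else:
            chi2, p = _chi2_summed(values.sum(), len(values), wt_sum, wt_n)
            p_adj = min(1.0, p * n_comparisons)
        row = {
            "genotype": genotype,
            "n_clones": len(grp),
            f"mean_{count_col}": mean,
            f"sem_{count_col}": sem,
            "fold_vs_wt": fold,
            "chi2": chi2,
            "p_adjusted": p_adj,
        }
        for other in ("snv", "ins", "del"):
            if other != count_col and other in counts.columns:
                row[f"mean_{other}"] = grp[other].mean()
        rows.append(row)
    return pd.DataFrame(rows).set_index("genotype")


def _chi2_summed(sum_a: float, n_a: int, sum_b: float, n_b: int) -> tuple[float, float]:
    """Chi-square on two summed counts, expectation prop. to clone numbers."""
    total = sum_a + sum_b
    if total == 0:
        return 0.0, 1.0
    expected = np.array([n_a, n_b], dtype=float) / (n_a + n_b) * total
    chi2, p = stats.chisquare([sum_a, sum_b], f_exp=expected)
    return float(chi2), float(p)
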