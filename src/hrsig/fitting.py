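"""Reference-signature fitting and signature comparison.

Deconvolution of an observed spectrum against a fixed reference signature
matrix is a nonnegative least squares (NNLS) problem; following common
deconvolution practice, signatures whose fitted contribution falls below a
minimum fraction (default 6%) are zeroed and the remainder refit once, which
suppresses spurious low-weight assignments.

Also provides the similarity measures used to compare de novo signatures
against references (cosine similarity, Spearman rank correlation) and the
confounder rule that flags samples whose spectra are dominated by mismatch
repair deficiency or POLE-type signatures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import nnls


def cosine_similarity(a, b) -> float:
    """Cosine of the angle between two nonzero channel vectors, in [0, 1]
    for nonnegative input; scale-invariant."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("vectors must have the same length")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(a @ b / (na * nb))


def spearman_similarity(a, b) -> float:
    """Spearman rank correlation (Pearson on average ranks), in [-1, 1]."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("vectors must have the same length")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("Spearman correlation undefined for a constant vector")
    ra, rb = stats.rankdata(a), stats.rankdata(b)
    return float(np.corrcoef(ra, rb)[0, 1])


def reconstruction_rmsd(spectrum, reference, exposures) -> float:
    """Root-mean-square deviation between observed and reconstructed channel
    fractions.  ``exposures`` are fractional contributions of the reference
    columns; both spectra are compared as probability vectors."""
    ref = pd.DataFrame(reference).to_numpy(dtype=float)
    obs = np.asarray(spectrum, dtype=float).ravel()
    w = np.asarray(exposures, dtype=float).ravel()
    if ref.shape[0] != obs.size or ref.shape[1] != w.size:
        raise ValueError("dimension mismatch")
    obs_frac = obs / obs.sum() if obs.sum() > 0 else obs
    fit = ref @ w
    fit_frac = fit / fit.sum() if fit.sum() > 0 else fit
    return float(np.sqrt(np.mean((obs_frac - fit_frac) ** 2)))


class ReferenceSignatureFit:
    """Fit fractional signature contributions to one observed spectrum.

    Parameters
    ----------
    spectrum : channel vector of counts or fractions (any scale).
    reference : channels x k column-stochastic signature matrix
        (DataFrame columns name the signatures).

    ``fit()`` returns a :class:`ReferenceSignatureFitResults`.
    """

    def __init__(self, spectrum, reference) -> None:
        self.reference = pd.DataFrame(reference).astype(float)
        if self.reference.size == 0:
            raise ValueError("empty reference signature matrix")
        if (self.reference.sum(axis=0) == 0).any():
            raise ValueError("reference contains an all-zero signature column")
        spectrum = pd.Series(np.asarray(spectrum, dtype=float).ravel())
        if len(spectrum) != len(self.reference):
            raise ValueError("spectrum/reference channel mismatch")
        if (spectrum < 0).any():
            raise ValueError("spectrum must be nonnegative")
        if spectrum.sum() == 0:
            raise ValueError("spectrum is all zero")
        self.total = float(spectrum.sum())
        self.spectrum = (spectrum / self.total).to_numpy()

    def fit(self, min_contribution: float = 0.06) -> "ReferenceSignatureFitResults":
        A = self.reference.to_numpy()
        b = self.spectrum
        w, _ = nnls(A, b)
        if w.sum() > 0 and min_contribution > 0:
            frac = w / w.sum()
            keep = frac >= min_contribution
            if keep.any() and not keep.all():
                w = np.zeros_like(w)
                w[keep], _ = nnls(A[:, keep], b)
        contributions = w / w.sum() if w.sum() > 0 else w
        return ReferenceSignatureFitResults(self, w, contributions)


class ReferenceSignatureFitResults:
    """NNLS deconvolution results.

    Attributes
    ----------
    weights : raw NNLS weights on the fraction scale.
    contributions : weights normalized to fractions of the fitted mass.
    exposures : contributions scaled to mutation counts of the input.
    rmsd : per-channel root-mean-square reconstruction deviation.
    """

    def __init__(self, model: ReferenceSignatureFit, weights, contributions) -> None:
        self.model = model
        names = model.reference.columns
        self.weights = pd.Series(weights, index=names)
        self.contributions = pd.Series(contributions, index=names)
        self.exposures = self.contributions * model.total
        self.fitted = pd.Series(
            model.reference.to_numpy() @ weights, index=model.reference.index
        )
        self.rmsd = reconstruction_rmsd(
            model.spectrum, model.reference, weights
        )

    def kkt_gradient(self) -> pd.Series:
        """Gradient of the squared loss at the solution, A^T (A w - b).

        At an NNLS optimum the gradient is ~0 for active (positive)
        signatures and >= 0 for zeroed ones.
        """
        A = self.model.reference.to_numpy()
        return pd.Series(
            A.T @ (A @ self.weights.to_numpy() - self.model.spectrum),
            index=self.model.reference.columns,
        )

    def summary(self) -> str:
        lines = [
            "Reference signature fit (NNLS)",
            f"  channels: {len(self.model.spectrum)}   signatures: "
            f"{len(self.weights)}   input mutations: {self.model.total:.0f}",
            f"  reconstruction RMSD: {self.rmsd:.5f}",
            "",
            "  contribution  exposure  signature",
        ]
        for name in self.contributions.index:
            c = self.contributions[name]
            if c > 0:
                lines.append(
                    f"  {c:12.3f}  {self.exposures[name]:8.1f}  {name}"
                )
        return "\n".join(lines)


@dataclass(frozen=True)
class ConfounderFlag:
    """Outcome of the dominant-confounder screen for one sample."""

    sample_id: str
    flag: str  # "none", "MMR" or "POLE"
    fraction: float


MMR_SIGNATURES = ("6", "15", "20", "26")
POLE_SIGNATURES = ("11",)


def flag_confounded(
    exposures: pd.Series,
    sample_id: str = "",
    threshold: float = 0.40,
) -> ConfounderFlag:
    """Flag a sample whose SNV load is dominated by confounding processes.

    ``exposures`` are fractional signature contributions indexed by
    signature name.  The sample is flagged MMR when the summed fraction of
    the mismatch-repair signatures (6, 15, 20, 26) exceeds the threshold
    (default 40%), else POLE when signature 11 exceeds it; MMR is evaluated
    first.  Such samples mimic or mask an HR-deficiency spectrum and are
    excluded from deletion-phenotype comparisons.
    """
    frac = exposures.astype(float)
    mmr = float(frac.reindex(MMR_SIGNATURES).fillna(0.0).sum())
    pole = float(frac.reindex(POLE_SIGNATURES).fillna(0.0).sum())
    if mmr > threshold:
        return ConfounderFlag(sample_id, "MMR", mmr)
    if pole > threshold:
        return ConfounderFlag(sample_id, "POLE", pole)
    return ConfounderFlag(sample_id, "none", max(mmr, pole))
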