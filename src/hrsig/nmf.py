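"""De novo mutational-signature extraction by non-negative matrix factorization.

The model follows the standard Brunet-style protocol for mutation spectra:
the samples x channels count matrix X is factorized as X ~ E S^T with
nonnegative exposures E (samples x k) and column-stochastic signatures S
(channels x k), under Frobenius loss with multiplicative updates, random
nonnegative initialization, and a best-of-restarts strategy.  Rank selection
diagnostics (cophenetic correlation of the restart consensus, residual sum
of squares) are provided by :meth:`SignatureNMF.rank_survey`.

Usage::

    model = SignatureNMF(spectra)            # DataFrame, samples x 96
    res = model.fit(rank=2, seed=17)
    res.signatures                           # 96 x 2, columns sum to 1
    res.exposures                            # samples x 2, counts
    print(res.summary())
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.decomposition import NMF as _SkNMF
from sklearn.exceptions import ConvergenceWarning


class SignatureNMF:
    """Nonnegative factorization model for mutation spectra.

    Parameters
    ----------
    spectra : DataFrame or array, samples x channels, nonnegative counts.
        All-zero sample rows are excluded with a warning (they carry no
        spectral information and break multiplicative updates).
    """

    def __init__(self, spectra) -> None:
        frame = pd.DataFrame(spectra).astype(float)
        if (frame.to_numpy() < 0).any():
            raise ValueError("spectra must be nonnegative")
        zero = frame.sum(axis=1) == 0
        if zero.any():
            warnings.warn(
                f"excluding {int(zero.sum())} all-zero sample row(s)", stacklevel=2
            )
            frame = frame.loc[~zero]
        self.spectra = frame
        self.n_samples, self.n_channels = frame.shape

    # ------------------------------------------------------------------
    def fit(
        self,
        rank: int,
        n_restarts: int = 50,
        seed: int | None = None,
        max_iter: int = 5000,
        tol: float = 1e-9,
    ) -> "SignatureNMFResults":
        """Best-of-restarts factorization at a fixed rank.

        Signatures are ordered by total exposure, descending; results are
        deterministic for a fixed ``seed``.
        """
        if not 1 <= rank < min(self.n_samples + 1, self.n_channels):
            raise ValueError(
                f"rank must be in [1, {min(self.n_samples, self.n_channels - 1)}]"
            )
        if rank > self.n_samples:
            raise ValueError("rank exceeds the number of samples")
        X = self.spectra.to_numpy()
        streams = np.random.SeedSequence(seed).spawn(n_restarts)
        best: tuple[float, np.ndarray, np.ndarray] | None = None
        assignments = []
        for stream in streams:
            rs = np.random.RandomState(int(stream.generate_state(1)[0]))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                solver = _SkNMF(
                    n_components=rank, init="random", solver="mu",
                    beta_loss="frobenius", max_iter=max_iter, tol=tol,
                    random_state=rs,
                )
                W = solver.fit_transform(X)
            H = solver.components_
            rss = float(np.sum((X - W @ H) ** 2))
            assignments.append(_dominant_assignment(W, H))
            if best is None or rss < best[0]:
                best = (rss, W, H)
        rss, W, H = best
        signatures, exposures = _normalize_factors(W, H)
        order = np.argsort(-exposures.sum(axis=0), kind="stable")
        signatures, exposures = signatures[:, order], exposures[:, order]
        names = [f"S{i + 1}" for i in range(rank)]
        return SignatureNMFResults(
            model=self,
            signatures=pd.DataFrame(
                signatures, index=self.spectra.columns, columns=names
            ),
            exposures=pd.DataFrame(
                exposures, index=self.spectra.index, columns=names
            ),
            rss=rss,
            rank=rank,
            n_restarts=n_restarts,
            cophenetic=_cophenetic(assignments) if rank > 1 else 1.0,
        )

    # ------------------------------------------------------------------
    def rank_survey(
        self,
        ranks,
        n_restarts: int = 20,
        seed: int | None = None,
        **fit_kwargs,
    ) -> pd.DataFrame:
        """Fit a range of ranks and tabulate rank-selection diagnostics.

        Returns a DataFrame indexed by rank with columns ``rss`` and
        ``cophenetic``; the attribute ``chosen_rank`` on the frame holds the
        rank maximizing the cophenetic correlation (smallest such rank on
        ties) — the standard consensus-stability criterion.
        """
        rows = {}
        for i, rank in enumerate(ranks):
            res = self.fit(
                rank, n_restarts=n_restarts,
                seed=None if seed is None else seed + i, **fit_kwargs,
            )
            rows[rank] = {"rss": res.rss, "cophenetic": res.cophenetic}
        table = pd.DataFrame(rows).T.rename_axis("rank")
        table.attrs["chosen_rank"] = int(table["cophenetic"].idxmax())
        return table


class SignatureNMFResults:
    """Factorization results: signatures, exposures and diagnostics.

    Attributes
    ----------
    signatures : channels x rank DataFrame; columns sum to 1.
    exposures : samples x rank DataFrame of mutation counts per signature.
    rss : residual sum of squares of the best restart.
    cophenetic : consensus-clustering cophenetic correlation over restarts.
    """

    def __init__(self, model, signatures, exposures, rss, rank, n_restarts,
                 cophenetic) -> None:
        self.model = model
        self.signatures = signatures
        self.exposures = exposures
        self.rss = rss
        self.rank = rank
        self.n_restarts = n_restarts
        self.cophenetic = cophenetic

    def reconstruct(self) -> pd.DataFrame:
        """Model reconstruction E S^T, samples x channels."""
        return self.exposures @ self.signatures.T

    def exposure_fractions(self) -> pd.DataFrame:
        """Exposures row-normalized to per-sample fractions."""
        return self.exposures.div(self.exposures.sum(axis=1), axis=0)

    def summary(self) -> str:
        lines = [
            "Signature NMF results",
            f"  samples: {self.model.n_samples}   channels: "
            f"{self.model.n_channels}   rank: {self.rank}",
            f"  restarts: {self.n_restarts}   RSS: {self.rss:.4g}   "
            f"cophenetic: {self.cophenetic:.4f}",
            "",
            "  Total exposure per signature (mutation counts):",
        ]
        totals = self.exposures.sum(axis=0)
        for name, value in totals.items():
            lines.append(f"    {name}: {value:.1f}")
        return "\n".join(lines)

    def plot_signatures(self, ax=None):
        """Bar plot of signature channel probabilities (one panel per column)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(
                self.rank, 1, figsize=(12, 2.2 * self.rank), squeeze=False
            )
            ax = ax[:, 0]
        for axis, name in zip(np.atleast_1d(ax), self.signatures.columns):
            axis.bar(range(len(self.signatures)), self.signatures[name].to_numpy())
            axis.set_ylabel(name)
            axis.set_xticks([])
        return ax


def _normalize_factors(W: np.ndarray, H: np.ndarray):
    """Fold signature scale into exposures; signatures column-stochastic."""
    scale = H.sum(axis=1)  # per-signature channel mass
    scale[scale == 0] = 1.0
    signatures = (H / scale[:, None]).T  # channels x k
    exposures = W * scale[None, :]  # samples x k
    return signatures, exposures


def _dominant_assignment(W: np.ndarray, H: np.ndarray) -> np.ndarray:
    exposures = W * H.sum(axis=1)[None, :]
    return exposures.argmax(axis=1)


def _cophenetic(assignments: list[np.ndarray]) -> float:
    """Cophenetic correlation of the restart consensus matrix.

    Each restart assigns samples to their dominant signature; the consensus
    matrix holds co-assignment frequencies.  Average-linkage clustering of
    1 - consensus gives the cophenetic distances whose correlation with the
    consensus distances measures factorization stability (1 = perfectly
    reproducible clustering).
    """
    n = len(assignments[0])
    if n < 3:
        return 1.0
    consensus = np.zeros((n, n))
    for a in assignments:
        consensus += (a[:, None] == a[None, :]).astype(float)
    consensus /= len(assignments)
    dist = squareform(1.0 - consensus, checks=False)
    if np.allclose(dist.std(), 0.0):
        return 1.0
    link = hierarchy.average(dist)
    coph, _ = hierarchy.cophenet(link, dist)
    return float(coph)
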