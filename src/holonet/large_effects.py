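"""Permutation-based estimation and removal of latent large-effect variables.

A dominant environmental axis (in the motivating salmon data, the
fresh-/salt-water transition) can drive so much covariance that secondary
host-microbiota associations are masked.  The number of latent variables is
estimated by comparing the eigenvalue fractions of the feature-standardized
data against spectra of row-permuted data, and the corresponding leading
principal-component score vectors are regressed out of every feature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import OmicsMatrix

logger = logging.getLogger(__name__)


@dataclass
class LatentEstimate:
    n_sv: int
    spectrum: np.ndarray  # observed eigenvalue fractions, descending
    null_quantiles: np.ndarray  # (1 - alpha) permutation quantile per rank
    B: int
    alpha: float
    seed: int


def _standardized(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1)
    keep = sd > 0
    if not keep.all():
        logger.warning("dropping %d zero-variance feature(s) from latent estimation",
                       int((~keep).sum()))
    return (X[keep] - mu[keep]) / sd[keep][:, None]


def _eigen_fractions(Xs: np.ndarray) -> np.ndarray:
    s = np.linalg.svd(Xs, compute_uv=False)
    ev = s**2
    return ev / ev.sum()


def estimate_num_sv(
    matrix: OmicsMatrix, B: int = 100, alpha: float = 0.05, seed: int = 0
) -> LatentEstimate:
    """Estimate the number of large latent effects by permutation.

    Each of ``B`` permutations shuffles values independently within every
    feature row (destroying cross-feature correlation while preserving
    marginals).  ``n_sv`` counts, from the top, observed eigenvalue fractions
    that exceed the ``1 - alpha`` quantile of their permuted counterparts,
    stopping at the first failure.
    """
    X = matrix.values.to_numpy(dtype=float)
    if X.shape[1] < 5:
        raise ValueError("estimate_num_sv requires at least 5 samples")
    if not np.isfinite(X).all():
        raise ValueError("matrix contains non-finite values")
    if B < 20:
        logger.warning("B = %d permutations is low; the null quantiles will be noisy", B)
    Xs = _standardized(X)
    obs = _eigen_fractions(Xs)
    rng = np.random.default_rng(seed)
    null = np.empty((B, obs.size))
    for b in range(B):
        null[b] = _eigen_fractions(rng.permuted(Xs, axis=1))
    q = np.quantile(null, 1.0 - alpha, axis=0)
    cap = min(Xs.shape[0], Xs.shape[1]) - 1
    n_sv = 0
    for i in range(min(obs.size, cap)):
        if obs[i] > q[i]:
            n_sv += 1
        else:
            break
    return LatentEstimate(n_sv=n_sv, spectrum=obs, null_quantiles=q, B=B, alpha=alpha, seed=seed)


def remove_latent_pcs(matrix: OmicsMatrix, n: int) -> OmicsMatrix:
    """Regress the top-``n`` principal-component score vectors out of every
    feature (intercept included); output is feature-centered residuals with
    stage ``corrected``."""
    X = matrix.values.to_numpy(dtype=float)
    n_feat, n_samp = X.shape
    if n < 0 or n > min(n_feat, n_samp) - 1:
        raise ValueError(f"n must lie in [0, {min(n_feat, n_samp) - 1}]")
    Y = X - X.mean(axis=1, keepdims=True)
    if n == 0:
        out = Y
    else:
        Xs = _standardized(X)
        _, _, Vt = np.linalg.svd(Xs, full_matrices=False)
        scores = Vt[:n].T  # samples x n
        design = np.column_stack([np.ones(n_samp), scores])
        coef, *_ = np.linalg.lstsq(design, Y.T, rcond=None)
        out = (Y.T - design @ coef).T
    return OmicsMatrix(
        pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns),
        kingdom=matrix.kingdom,
        stage="corrected",
    )
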