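"""Expression preprocessing for variance-association testing.

The pipeline mirrors common practice for microarray expression ahead of
variance-QTL scans: log2 transform, removal of latent population
structure via genotype principal components, residualization on known
covariates, removal of residual expression structure via expression
principal components, and empirical quantile normalization to
standard-normal quantiles.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InvalidArgumentError

logger = logging.getLogger(__name__)


def top_pcs(matrix: np.ndarray, k: int) -> np.ndarray:
    """Top-k sample-space principal components (samples x k) of a
    features x samples matrix, via SVD of the column-centered matrix."""
    if k == 0:
        return np.empty((matrix.shape[1], 0))
    centered = matrix - matrix.mean(axis=1, keepdims=True)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    return vt[:k].T


def _residualize(Y: np.ndarray, design: np.ndarray) -> np.ndarray:
    """Per-feature least-squares residuals of Y (features x samples) on a
    samples x p design with intercept; residuals are mean-centered.
    Collinear design columns are dropped with a warning."""
    n = Y.shape[1]
    X = np.column_stack([np.ones(n), design])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # drop collinear columns greedily
        keep = [0]
        for j in range(1, X.shape[1]):
            if np.linalg.matrix_rank(X[:, keep + [j]]) > len(keep):
                keep.append(j)
        logger.warning("rank-deficient design: dropped %d collinear column(s)",
                       X.shape[1] - len(keep))
        X = X[:, keep]
    coef, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
    resid = Y - (X @ coef).T
    return resid - resid.mean(axis=1, keepdims=True)


def preprocess_expression(traits: pd.DataFrame,
                          covariates: pd.DataFrame | None = None,
                          genotypes: pd.DataFrame | None = None,
                          n_genotype_pcs: int = 2,
                          n_expression_pcs: int = 2) -> pd.DataFrame:
    """Full expression preprocessing pipeline.

    Steps, in order: (1) elementwise log2 (requires strictly positive
    values); (2) top ``n_genotype_pcs`` of the genotype matrix
    (variants x samples) by SVD; (3) per-gene residualization on known
    covariates (samples x p, aligned on sample identifiers) plus the
    genotype PCs, mean-centering residuals; (4) top ``n_expression_pcs``
    of the residual matrix, and a second residualization on those.
    """
    Y = traits.to_numpy(dtype=float)
    if np.any(Y <= 0):
        raise InvalidArgumentError(
            "log2 step requires strictly positive trait values")
    Y = np.log2(Y)

    design_parts = []
    if covariates is not None:
        cov = covariates.loc[traits.columns] if set(traits.columns) <= set(
            covariates.index) else covariates
        design_parts.append(np.asarray(cov, dtype=float))
    if genotypes is not None and n_genotype_pcs > 0:
        G = genotypes[traits.columns].to_numpy(dtype=float) \
            if isinstance(genotypes, pd.DataFrame) else np.asarray(genotypes)
        design_parts.append(top_pcs(G, n_genotype_pcs))
    design = (np.column_stack(design_parts) if design_parts
              else np.empty((Y.shape[1], 0)))
    Y = _residualize(Y, design)
    if n_expression_pcs > 0:
        Y = _residualize(Y, top_pcs(Y, n_expression_pcs))
    return pd.DataFrame(Y, index=traits.index, columns=traits.columns)


def quantile_normalize(traits: pd.DataFrame) -> pd.DataFrame:
    """Map each feature row to standard-normal quantiles.

    Values are replaced by Phi^-1((rank - 0.5) / n) with average ranks
    for ties, so every (tie-free) row has the identical sorted value
    multiset and mean 0.  Constant rows map to all zeros with a warning.
    """
    Y = traits.to_numpy(dtype=float)
    out = np.empty_like(Y)
    n = Y.shape[1]
    for i in range(Y.shape[0]):
        row = Y[i]
        if np.isnan(row).any():
            raise InvalidArgumentError(
                f"missing values in feature {traits.index[i]!r}")
        if np.ptp(row) == 0:
            logger.warning("quantile_normalize: constant feature %r mapped to 0",
                           traits.index[i])
            out[i] = 0.0
            continue
        ranks = stats.rankdata(row, method="average")
        out[i] = stats.norm.ppf((ranks - 0.5) / n)
    return pd.DataFrame(out, index=traits.index, columns=traits.columns)
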