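"""Mean-effect-preserving permutations and permutation-based FDR calibration.

The permutation null keeps the fitted mean relationship between trait
and covariate but destroys any variance effect: residuals from the
least-squares fit are permuted and re-added to the fitted values.  Each
emitted permutation is checked by a slope t-test (permuted residuals
regressed on the covariate) and redrawn while the mean effect of the
residuals is statistically distinguishable from zero.

The FDR at score threshold t is estimated as the ratio of permutation
scores above t to real scores above t,

    FDR(t) = #{ s_perm > t } / #{ s_real > t },

with the convention FDR(t) = 0 when there are no discoveries.  For
signed scores (Bayes factors) the comparison uses absolute values;
p-value based methods should be supplied as -log10 p.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .exceptions import InvalidArgumentError

logger = logging.getLogger(__name__)

#: Default MAF bin edges for stratified FDR; bins partition (0, 0.5].
DEFAULT_MAF_BINS = (0.05, 0.1, 0.2, 0.3, 0.5)


@dataclass
class PermutedTrait:
    """A mean-effect-preserving permutation of one trait vector."""

    y_perm: np.ndarray
    fitted: np.ndarray
    slope_p: float
    redraws: int
    accepted: bool  # False when the redraw budget ran out


@dataclass
class FdrCurve:
    thresholds: np.ndarray
    fdr_at: np.ndarray
    n_real: int
    n_perm: int


@dataclass
class CalibratedThreshold:
    level: float
    d_fdr: float
    discoveries: list = field(default_factory=list)

    @property
    def n_discoveries(self) -> int:
        return len(self.discoveries)


def mean_preserving_permutation(
    y, x, rng=None, seed=None, accept_p: float = 0.10, max_redraws: int = 100,
) -> PermutedTrait:
    """Permute residuals of the least-squares fit y ~ 1 + x and re-add the
    fitted values, preserving mean effects while removing variance effects.

    A candidate permutation is accepted when the two-sided slope t-test of
    the permuted residuals on x has p >= ``accept_p``; up to
    ``max_redraws`` candidates are drawn, after which the last one is
    accepted with a warning (``accepted=False``).
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise InvalidArgumentError("y and x must be 1-D vectors of equal length")
    if np.ptp(x) == 0:
        raise InvalidArgumentError("covariate has zero variance")
    if rng is None:
        rng = np.random.default_rng(seed)
    X = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ coef
    resid = y - fitted
    slope_p = 0.0
    for redraw in range(max_redraws):
        perm = rng.permutation(y.size)
        r_perm = resid[perm]
        if np.ptp(r_perm) == 0:
            slope_p = 1.0
            break
        slope_p = float(stats.linregress(x, r_perm).pvalue)
        if slope_p >= accept_p:
            break
    else:
        logger.warning(
            "mean_preserving_permutation: no draw reached slope p >= %.2f "
            "after %d redraws; accepting last", accept_p, max_redraws)
        return PermutedTrait(fitted + r_perm, fitted, slope_p, max_redraws,
                             accepted=False)
    return PermutedTrait(fitted + r_perm, fitted, slope_p, redraw, accepted=True)


def _oriented(scores, absolute):
    s = np.asarray(scores, dtype=float)
    return np.abs(s) if absolute else s


def estimate_fdr(real_scores, perm_scores, threshold: float,
                 absolute: bool = False) -> float:
    """Permutation FDR estimate at one threshold: #{perm > t} / #{real > t}
    (0 when nothing is discovered)."""
    real = _oriented(real_scores, absolute)
    perm = _oriented(perm_scores, absolute)
    if real.size == 0 or perm.size == 0:
        raise InvalidArgumentError("score collections must be non-empty")
    n_real = int(np.sum(real > threshold))
    if n_real == 0:
        return 0.0
    return float(np.sum(perm > threshold)) / n_real


def fdr_curve(real_scores, perm_scores, thresholds=None,
              absolute: bool = False) -> FdrCurve:
    """FDR estimates over a grid of thresholds (default: the observed
    real score values, ascending)."""
    real = _oriented(real_scores, absolute)
    perm = _oriented(perm_scores, absolute)
    if real.size == 0 or perm.size == 0:
        raise InvalidArgumentError("score collections must be non-empty")
    if thresholds is None:
        thresholds = np.unique(real)
    thresholds = np.sort(np.asarray(thresholds, dtype=float))
    # vectorized counts of strictly-greater scores
    n_real = real.size - np.searchsorted(np.sort(real), thresholds, side="right")
    n_perm = perm.size - np.searchsorted(np.sort(perm), thresholds, side="right")
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.where(n_real > 0, n_perm / np.maximum(n_real, 1), 0.0)
    return FdrCurve(thresholds=thresholds, fdr_at=fdr,
                    n_real=real.size, n_perm=perm.size)


def calibrate_threshold(real_scores, perm_scores, level: float,
                        absolute: bool = False, ids=None) -> CalibratedThreshold:
    """Smallest observed-score threshold whose estimated FDR is <= level.

    Discoveries (real scores strictly above the threshold) are listed in
    descending score order; when no threshold attains the level the
    threshold is +inf with zero discoveries.
    """
    if not 0.0 < level < 1.0:
        raise InvalidArgumentError("level must be in (0, 1)")
    real = _oriented(real_scores, absolute)
    perm = _oriented(perm_scores, absolute)
    # candidate thresholds span both score sets so that a cut below the
    # smallest real score (discovering everything) can be selected
    candidates = np.unique(np.concatenate([real, perm]))
    curve = fdr_curve(real_scores, perm_scores, thresholds=candidates,
                      absolute=absolute)
    ok = np.flatnonzero((curve.fdr_at <= level)
                        & (real.size - np.searchsorted(
                            np.sort(real), curve.thresholds, side="right") > 0))
    if ok.size == 0:
        return CalibratedThreshold(level=level, d_fdr=math.inf, discoveries=[])
    d = float(curve.thresholds[ok[0]])
    idx = np.flatnonzero(real > d)
    order = idx[np.argsort(-real[idx])]
    if ids is None:
        discoveries = order.tolist()
    else:
        ids = list(ids)
        discoveries = [ids[i] for i in order]
    return CalibratedThreshold(level=level, d_fdr=d, discoveries=discoveries)


def maf_stratified_fdr(real_scores, perm_scores, mafs, level: float,
                       bins=DEFAULT_MAF_BINS, absolute: bool = False,
                       ids=None, perm_mafs=None) -> dict:
    """Independent FDR calibration within MAF bins.

    ``bins`` are ascending edges; bin b spans [bins[b], bins[b+1]) with
    the last bin closed on the right.  Permutation scores are stratified
    by ``perm_mafs`` (defaults to ``mafs``, the matched-permutation
    design).  Empty bins are skipped with a warning.  Returns a dict
    mapping "[lo,hi)" labels to :class:`CalibratedThreshold`.
    """
    real = np.asarray(real_scores, dtype=float)
    perm = np.asarray(perm_scores, dtype=float)
    mafs = np.asarray(mafs, dtype=float)
    if mafs.shape != real.shape:
        raise InvalidArgumentError("every real score needs a MAF annotation")
    pmafs = mafs if perm_mafs is None else np.asarray(perm_mafs, dtype=float)
    edges = np.asarray(bins, dtype=float)
    out = {}
    for b in range(edges.size - 1):
        lo, hi = edges[b], edges[b + 1]
        last = b == edges.size - 2
        in_bin = (mafs >= lo) & ((mafs <= hi) if last else (mafs < hi))
        in_perm = (pmafs >= lo) & ((pmafs <= hi) if last else (pmafs < hi))
        label = f"[{lo:g},{hi:g}{']' if last else ')'}"
        if not in_bin.any() or not in_perm.any():
            logger.warning("maf_stratified_fdr: empty bin %s skipped", label)
            continue
        bin_ids = None
        if ids is not None:
            ids_arr = np.asarray(list(ids), dtype=object)
            bin_ids = ids_arr[in_bin]
        out[label] = calibrate_threshold(
            real[in_bin], perm[in_perm], level, absolute=absolute, ids=bin_ids)
    return out


def benjamini_hochberg(p_values, level: float) -> np.ndarray:
    """Analytic BH step-up procedure (convenience only; the primary FDR
    path in this package is permutation-based).  Returns a boolean
    rejection mask."""
    from statsmodels.stats.multitest import multipletests

    reject, *_ = multipletests(np.asarray(p_values, dtype=float),
                               alpha=level, method="fdr_bh")
    return reject
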