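"""Precision-recall evaluation of heteroskedasticity tests over
simulation suites.

Each benchmark suite pairs simulated alternatives with matched
mean-effect-preserving permutation nulls; every method scores every
dataset on a common larger-is-more-significant scale (log10 Bayes factor
for BTH, -log10 p otherwise; non-converged fits score 0 so that all
methods see identical label sets).  Precision-recall curves group tied
scores at a single threshold, and the area under the curve is obtained
by trapezoidal integration over recall.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classical import run_test
from .exceptions import InvalidArgumentError
from .simulate import SimulationConfig, generate_benchmark_suite

logger = logging.getLogger(__name__)


@dataclass
class PrCurve:
    """Precision-recall points (ascending recall) with areas."""

    recall: np.ndarray
    precision: np.ndarray
    auc: float
    average_precision: float
    n_pos: int
    n_neg: int


def precision_recall(scores, labels) -> PrCurve:
    """PR curve over descending score thresholds with tied scores grouped.

    The curve starts at (recall 0, precision of the top tie group), so an
    uninformative all-tied scoring with balanced labels integrates to an
    AUC of the positive fraction.  Average precision is the
    recall-increment-weighted mean of precision over tie groups.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise InvalidArgumentError("scores and labels must match in length")
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise InvalidArgumentError(
            "need at least one positive and one negative label")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    l = labels[order]
    # indices where a tie group ends
    ends = np.flatnonzero(np.diff(s) != 0)
    ends = np.append(ends, s.size - 1)
    tp = np.cumsum(l)[ends]
    pred = ends + 1
    recall = tp / n_pos
    precision = tp / pred
    recall = np.concatenate([[0.0], recall])
    precision = np.concatenate([[precision[0]], precision])
    auc = float(np.trapezoid(precision, recall))
    ap = float(np.sum(np.diff(recall) * precision[1:]))
    return PrCurve(recall=recall, precision=precision, auc=auc,
                   average_precision=ap, n_pos=n_pos, n_neg=n_neg)


def score_dataset(method: str, ds, hyper=None) -> tuple[float, bool]:
    """Score one dataset with one method; returns (score, converged)."""
    try:
        res = run_test(method, ds.y, ds.x, hyper=hyper)
    except InvalidArgumentError:
        raise
    return res.score, res.converged


def score_suite(datasets, methods, hyper=None,
                label_mode: str = "real_vs_perm") -> pd.DataFrame:
    """Score every dataset with every method.

    ``label_mode='real_vs_perm'`` labels non-permutation datasets 1 (under
    a null configuration an AUC near the positive fraction then indicates
    a well-calibrated permutation); ``'truth'`` additionally requires a
    nonzero simulated variance effect for label 1.
    """
    rows = []
    for i, ds in enumerate(datasets):
        if label_mode == "truth":
            label = int(not ds.is_permutation_null
                        and ds.truth.log_alpha != 0)
        else:
            label = int(not ds.is_permutation_null)
        for method in methods:
            score, converged = score_dataset(method, ds, hyper=hyper)
            rows.append({
                "dataset_id": ds.dataset_id or f"d{i}",
                "dataset_index": i,
                "method": method,
                "score": score,
                "label": label,
                "converged": converged,
            })
    return pd.DataFrame(rows)


def run_benchmark(configs, methods, reps: int, seed: int,
                  hyper=None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate suites and score them for each configuration.

    Returns ``(summary, scores)``: per-(config, method) AUC / average
    precision / convergence counts, and the per-dataset score table used
    to compute them.  Methods incompatible with a config's covariate kind
    (categorical-only tests on continuous dosages) are skipped with a
    warning.
    """
    if isinstance(configs, SimulationConfig):
        configs = [configs]
    summaries = []
    score_frames = []
    for j, config in enumerate(configs):
        suite = generate_benchmark_suite(config, reps=reps, seed=seed + j)
        usable = []
        for method in methods:
            if (method in ("levene", "brown_forsythe", "bartlett")
                    and config.covariate_kind in ("imputed", "continuous")):
                logger.warning("skipping %s for continuous covariate config",
                               method)
                continue
            usable.append(method)
        scores = score_suite(suite, usable, hyper=hyper)
        scores.insert(0, "config_index", j)
        score_frames.append(scores)
        for method in usable:
            sub = scores[scores.method == method]
            pr = precision_recall(sub.score.to_numpy(), sub.label.to_numpy())
            summaries.append({
                "config_index": j,
                "n": config.n, "maf": config.pi_maf, "beta": config.beta,
                "beta0": config.beta0, "log_alpha": config.log_alpha,
                "family": config.family, "method": method,
                "auc": pr.auc, "average_precision": pr.average_precision,
                "n_converged": int(sub.converged.sum()),
                "n_tests": int(len(sub)),
            })
    return pd.DataFrame(summaries), pd.concat(score_frames, ignore_index=True)


def compare_methods(scores: pd.DataFrame, method_a: str, method_b: str,
                    n_boot: int = 1000, seed: int = 0) -> dict:
    """AUC and average-precision differences (a minus b) with bootstrap
    percentile intervals over datasets."""
    for m in (method_a, method_b):
        if m not in set(scores.method):
            raise InvalidArgumentError(f"method {m!r} not present in scores")
    a = scores[scores.method == method_a].set_index("dataset_index")
    b = scores[scores.method == method_b].set_index("dataset_index")
    idx = a.index.to_numpy()
    labels = a.label.to_numpy()
    sa, sb = a.score.to_numpy(), b.loc[a.index].score.to_numpy()

    def deltas(sel):
        pa = precision_recall(sa[sel], labels[sel])
        pb = precision_recall(sb[sel], labels[sel])
        return pa.auc - pb.auc, pa.average_precision - pb.average_precision

    d_auc, d_ap = deltas(np.arange(idx.size))
    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_boot):
        sel = rng.integers(0, idx.size, idx.size)
        try:
            boots.append(deltas(sel))
        except InvalidArgumentError:  # single-class resample
            continue
    boots = np.asarray(boots) if boots else np.empty((0, 2))
    ci = (np.percentile(boots, [2.5, 97.5], axis=0)
          if len(boots) else np.full((2, 2), np.nan))
    return {
        "auc_diff": float(d_auc),
        "average_precision_diff": float(d_ap),
        "auc_diff_ci": (float(ci[0, 0]), float(ci[1, 0])),
        "average_precision_diff_ci": (float(ci[0, 1]), float(ci[1, 1])),
        "n_boot": int(len(boots)),
    }
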