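"""Bootstrap Spearman correlation of TF activities with metabolite
abundances, ROC-based correlation thresholding and stability scoring.

Each bootstrap sample draws a fixed-size subset of the shared conditions
without replacement (30 of 40 by default), computes Spearman's rho for
every (TF, metabolite) pair over that subset, and the pair's reported
correlation score is the mean over all samples. Known interactions serve
as true positives for a per-sample ROC curve; the correlation threshold
is the median over samples of the smallest per-sample score threshold
whose false positive rate is at or below the target (0.1 by default).
A pair's stability is the proportion of samples in which its correlation
strictly exceeds that threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn import metrics as skmetrics

from .datamodel import KnownInteractionSet, MetaboliteAbundanceMatrix, TFActivityMatrix

__all__ = [
    "spearman",
    "BootstrapResult",
    "bootstrap_correlations",
    "ROCCurve",
    "roc_for_sample",
    "fpr_threshold",
    "median_roc_threshold",
    "StabilityScores",
    "stability_scores",
    "select_stability_threshold",
]


def spearman(x, y) -> float:
    """Spearman's rho: Pearson correlation of average-ranked values.

    Returns NaN when either profile is constant (ranks undefined for
    correlation purposes).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise ValueError("profiles must have length >= 3")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        return float("nan")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def _rank_standardize(block: np.ndarray) -> np.ndarray:
    """Rank rows, then center and scale to unit norm; constant rows -> NaN."""
    ranks = stats.rankdata(block, axis=1).astype(float)
    ranks -= ranks.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(ranks, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = ranks / norms
    out[np.squeeze(norms, axis=1) == 0] = np.nan
    return out


@dataclass
class BootstrapResult:
    """Mean and (optionally) per-sample Spearman correlations per pair."""

    tfs: list[str]
    metabolites: list[str]
    mean_correlation: pd.DataFrame  # TFs x metabolites
    samples: np.ndarray | None  # (n_samples, n_tfs, n_metabolites) float32
    n_samples: int
    subsample_size: int
    seed: int | None

    @property
    def n_pairs(self) -> int:
        return len(self.tfs) * len(self.metabolites)

    def pair_index(self) -> pd.MultiIndex:
        return pd.MultiIndex.from_product(
            [self.tfs, self.metabolites], names=["tf", "metabolite"]
        )

    def mean_flat(self) -> pd.Series:
        return pd.Series(
            self.mean_correlation.to_numpy().ravel(), index=self.pair_index()
        )


def bootstrap_correlations(
    act: TFActivityMatrix,
    met: MetaboliteAbundanceMatrix,
    n_samples: int = 1000,
    subsample_size: int = 30,
    seed: int | None = None,
    keep_samples: bool = True,
) -> BootstrapResult:
    """Bootstrap Spearman correlations over shared conditions.

    Conditions are subsampled without replacement within each sample.
    Pairs with a constant profile in a given subsample contribute NaN for
    that sample and are excluded pairwise from the mean.
    """
    shared = [c for c in act.conditions if c in set(met.conditions)]
    if subsample_size > len(shared):
        raise ValueError(
            f"subsample_size {subsample_size} exceeds {len(shared)} shared conditions"
        )
    A = act.values[shared].to_numpy(dtype=float)
    M = met.values[shared].to_numpy(dtype=float)
    n_tfs, n_mets = A.shape[0], M.shape[0]
    rng = np.random.default_rng(seed)

    samples = (
        np.empty((n_samples, n_tfs, n_mets), dtype=np.float32)
        if keep_samples
        else None
    )
    total = np.zeros((n_tfs, n_mets))
    count = np.zeros((n_tfs, n_mets))
    for s in range(n_samples):
        idx = rng.choice(len(shared), size=subsample_size, replace=False)
        za = _rank_standardize(A[:, idx])
        zm = _rank_standardize(M[:, idx])
        corr = za @ zm.T
        np.clip(corr, -1.0, 1.0, out=corr)
        if samples is not None:
            samples[s] = corr
        ok = np.isfinite(corr)
        total[ok] += corr[ok]
        count[ok] += 1
    with np.errstate(invalid="ignore"):
        mean = np.where(count > 0, total / np.where(count > 0, count, 1), np.nan)
    return BootstrapResult(
        tfs=list(act.values.index),
        metabolites=list(met.values.index),
        mean_correlation=pd.DataFrame(
            mean, index=act.values.index, columns=met.values.index
        ),
        samples=samples,
        n_samples=n_samples,
        subsample_size=subsample_size,
        seed=seed,
    )


@dataclass
class ROCCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def _oriented_scores(
    corr_flat: pd.Series, known: KnownInteractionSet, effect: str
) -> tuple[np.ndarray, np.ndarray]:
    """Scores oriented so larger = more likely interacting, plus labels."""
    positives = known.pairs(effect)
    if not positives:
        raise ValueError(f"no known pairs with effect {effect!r}")
    scores = corr_flat.to_numpy(dtype=float)
    if effect == "inactivating":
        scores = -scores
    labels = np.fromiter(
        (pair in positives for pair in corr_flat.index), dtype=bool, count=len(corr_flat)
    )
    ok = np.isfinite(scores)
    scores, labels = scores[ok], labels[ok]
    if not labels.any():
        raise ValueError(f"no measured known pairs with effect {effect!r}")
    return scores, labels


def roc_for_sample(
    corr_flat: pd.Series, known: KnownInteractionSet, effect: str = "activating"
) -> ROCCurve:
    """ROC curve for one sample's correlations against known interactions.

    Positives are known pairs of the requested effect; every other
    measured pair is a negative. For inactivating interactions the score
    is the negated correlation.
    """
    scores, labels = _oriented_scores(corr_flat, known, effect)
    fpr, tpr, thr = skmetrics.roc_curve(labels, scores)
    auc = skmetrics.roc_auc_score(labels, scores)
    return ROCCurve(fpr=fpr, tpr=tpr, thresholds=thr, auc=float(auc))


def fpr_threshold(
    scores: np.ndarray, labels: np.ndarray, target_fpr: float = 0.1
) -> float:
    """Smallest observed score threshold with FPR <= ``target_fpr``.

    FPR(t) = #(negatives with score > t) / #negatives; candidate
    thresholds are the observed score values.
    """
    neg = np.sort(scores[~labels])
    n = neg.size
    if n == 0:
        return float(np.min(scores))
    uniq = np.unique(scores)
    above = n - np.searchsorted(neg, uniq, side="right")
    valid = above <= target_fpr * n
    return float(uniq[valid][0])


def median_roc_threshold(
    result: BootstrapResult,
    known: KnownInteractionSet,
    effect: str = "activating",
    target_fpr: float = 0.1,
    grid_points: int = 101,
) -> tuple[float, pd.DataFrame]:
    """Median over samples of per-sample FPR-controlled score thresholds.

    Also returns the median ROC curve (median TPR across samples on an
    evenly spaced FPR grid) for reporting. Samples in which no known
    positive has a finite correlation are skipped.
    """
    if result.samples is None:
        raise ValueError("per-sample correlations were not retained")
    positives = known.pairs(effect)
    if not positives:
        raise ValueError(f"no known pairs with effect {effect!r}")
    pair_index = result.pair_index()
    all_labels = np.fromiter(
        (pair in positives for pair in pair_index), dtype=bool, count=len(pair_index)
    )
    sign = -1.0 if effect == "inactivating" else 1.0
    grid = np.linspace(0.0, 1.0, grid_points)
    thresholds, tprs = [], []
    for s in range(result.n_samples):
        scores = sign * result.samples[s].ravel().astype(float)
        ok = np.isfinite(scores)
        scores, labels = scores[ok], all_labels[ok]
        if not labels.any():
            continue
        thresholds.append(fpr_threshold(scores, labels, target_fpr))
        fpr, tpr, _ = skmetrics.roc_curve(labels, scores)
        tprs.append(np.interp(grid, fpr, tpr))
    if not thresholds:
        raise ValueError("no bootstrap sample had usable known positives")
    median_curve = pd.DataFrame(
        {"fpr": grid, "tpr": np.median(np.vstack(tprs), axis=0)}
    )
    # for inactivating interactions the threshold applies to -rho, the same
    # orientation stability_scores uses
    return float(np.median(thresholds)), median_curve


@dataclass
class StabilityScores:
    """Per-pair proportion of samples above the correlation threshold."""

    values: pd.DataFrame  # TFs x metabolites, in [0, 1]
    threshold: float
    effect: str = "activating"

    def flat(self) -> pd.Series:
        return pd.Series(
            self.values.to_numpy().ravel(),
            index=pd.MultiIndex.from_product(
                [self.values.index, self.values.columns], names=["tf", "metabolite"]
            ),
        )


def stability_scores(
    result: BootstrapResult, threshold: float, effect: str = "activating"
) -> StabilityScores:
    """Proportion of samples whose oriented rho strictly exceeds threshold."""
    if result.samples is None:
        raise ValueError("per-sample correlations were not retained")
    oriented = result.samples if effect == "activating" else -result.samples
    above = np.nansum(oriented > threshold, axis=0)
    props = above / result.n_samples
    return StabilityScores(
        values=pd.DataFrame(
            props, index=result.mean_correlation.index,
            columns=result.mean_correlation.columns,
        ),
        threshold=threshold,
        effect=effect,
    )


def select_stability_threshold(
    scores: StabilityScores, known: KnownInteractionSet, effect: str = "activating"
) -> float:
    """Cutoff maximizing the known-interaction fraction among retained pairs.

    Retention at cutoff c keeps pairs with stability >= c (matching the
    cascade's comparison rule); among observed stability values the one
    maximizing known_retained / all_retained wins, ties going to the
    larger cutoff.
    """
    flat = scores.flat()
    positives = known.pairs(effect)
    known_mask = np.fromiter(
        (pair in positives for pair in flat.index), dtype=bool, count=len(flat)
    )
    if not known_mask.any():
        raise ValueError(f"no known pairs with effect {effect!r} have stability scores")
    vals = flat.to_numpy(dtype=float)
    best_cut, best_ratio = None, -1.0
    for cut in np.unique(vals):
        retained = vals >= cut
        n_ret = retained.sum()
        if n_ret == 0:
            continue
        ratio = (retained & known_mask).sum() / n_ret
        if ratio >= best_ratio:
            best_ratio, best_cut = ratio, float(cut)
    return best_cut
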