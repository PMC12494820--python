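"""TF activity inference by signed regulon enrichment with subnetwork
subsampling, plus the knockout benchmark used to validate it.

Activity of a TF in a condition is the coordinated deviation of its
signed target genes in that condition's expression signature. The
enrichment statistic is a rank-based, signed, size-normalized score: the
per-gene signature is z-scored across conditions, genes are converted to
standard-normal quantiles (normal scores) within each condition, and the
TF's score is

    sum_g sign(g) * normal_score(g, c) / sqrt(n_targets)

over its targets with nonzero regulation sign. Because the score uses
only within-condition ranks, it is invariant to strictly monotone
per-condition transforms of the signature, and flipping every regulon
sign negates every activity.

To buffer uneven regulon sizes and network incompleteness, each TF is
scored inside ten subsampled subnetworks of itself plus 40 random other
TFs; within each subnetwork and condition the member scores are
standardized, and the TF's final activity is the median of its
standardized scores across subnetworks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import ExpressionMatrix, RegulatoryNetwork, TFActivityMatrix

__all__ = [
    "build_signature",
    "normal_scores",
    "enrich_regulon",
    "raw_scores",
    "infer_activities",
    "BenchmarkResult",
    "ko_direction_benchmark",
    "dynamic_chi2_threshold",
    "activity_range",
    "ActivityFilter",
]

#: Reference activity-filter cutoffs reported for the original E. coli
#: dataset (basal maximum activity, maximum activity range). Shipped only
#: as documentation defaults; ``dynamic_chi2_threshold`` recomputes them
#: from the data at hand.
REFERENCE_BASAL_MAX_CUTOFF = -0.752
REFERENCE_RANGE_CUTOFF = 0.166

MIN_REGULON_SIZE = 3


def build_signature(expr: ExpressionMatrix) -> pd.DataFrame:
    """Z-score each gene across conditions; constant genes become zero."""
    if len(expr.conditions) < 3:
        raise ValueError("signature needs at least 3 conditions")
    vals = expr.values.to_numpy(dtype=float)
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (vals - mean) / sd
    z[np.squeeze(sd, axis=1) == 0] = 0.0
    return pd.DataFrame(z, index=expr.values.index, columns=expr.values.columns)


def normal_scores(signature: pd.DataFrame) -> pd.DataFrame:
    """Map each condition column to standard-normal quantiles of its ranks.

    Average ranks are used for ties; rank r of n maps to
    ``Phi^-1(r / (n + 1))``.
    """
    n = signature.shape[0]
    ranks = stats.rankdata(signature.to_numpy(dtype=float), axis=0)
    ns = stats.norm.ppf(ranks / (n + 1))
    return pd.DataFrame(ns, index=signature.index, columns=signature.columns)


def enrich_regulon(
    signature: pd.DataFrame, regulon: dict[str, int], condition: str
) -> float:
    """Raw enrichment score of one signed regulon in one condition."""
    ns = normal_scores(signature)
    score = 0.0
    n_used = 0
    for gene, sign in regulon.items():
        if sign == 0 or gene not in ns.index:
            continue
        score += sign * ns.at[gene, condition]
        n_used += 1
    if n_used == 0:
        raise ValueError("regulon has no usable (nonzero-sign) targets")
    return score / np.sqrt(n_used)


def raw_scores(
    expr: ExpressionMatrix,
    net: RegulatoryNetwork,
    min_regulon: int = MIN_REGULON_SIZE,
) -> pd.DataFrame:
    """Vectorized raw enrichment scores for every eligible TF.

    Eligible TFs have at least ``min_regulon`` targets with nonzero sign
    present in the expression matrix; dual (sign-0) edges are excluded.
    """
    ns = normal_scores(build_signature(expr)).to_numpy(dtype=float)
    gene_idx = {g: i for i, g in enumerate(expr.genes)}
    tfs, rows = [], []
    n_genes = len(gene_idx)
    for tf in net.tfs:
        sign_vec = np.zeros(n_genes)
        for gene, sign in net.regulon(tf).items():
            if sign != 0 and gene in gene_idx:
                sign_vec[gene_idx[gene]] = sign
        n_used = int(np.count_nonzero(sign_vec))
        if n_used < min_regulon:
            continue
        tfs.append(tf)
        rows.append(sign_vec @ ns / np.sqrt(n_used))
    if not tfs:
        raise ValueError(
            f"no TF has >= {min_regulon} signed targets in the expression matrix"
        )
    return pd.DataFrame(rows, index=tfs, columns=expr.conditions)


def infer_activities(
    expr: ExpressionMatrix,
    net: RegulatoryNetwork,
    n_subnets: int = 10,
    extra_tfs: int = 40,
    seed: int | None = None,
    min_regulon: int = MIN_REGULON_SIZE,
) -> TFActivityMatrix:
    """Median-of-subnetworks TF activities.

    For each TF, ``n_subnets`` subnetworks are drawn, each holding the TF
    plus ``extra_tfs`` distinct random other TFs (all others if fewer
    exist). Raw scores are standardized across subnetwork members within
    each condition (sample sd), and the TF's activity is the median of
    its standardized scores over subnetworks. Per-subnetwork scores are
    retained for the knockout benchmark.
    """
    raw = raw_scores(expr, net, min_regulon=min_regulon)
    tfs = list(raw.index)
    n_tfs, n_cond = raw.shape
    rng = np.random.default_rng(seed)
    rawv = raw.to_numpy()

    if n_tfs <= 1:
        warnings.warn(
            "only one eligible TF: subnetwork standardization skipped, "
            "raw scores used",
            stacklevel=2,
        )
        sub = np.broadcast_to(rawv[:, None, :], (n_tfs, n_subnets, n_cond)).copy()
        return TFActivityMatrix(values=raw.copy(), subnet_scores=sub).validate()

    k = min(extra_tfs, n_tfs - 1)
    subnet_scores = np.empty((n_tfs, n_subnets, n_cond))
    for i in range(n_tfs):
        others = np.delete(np.arange(n_tfs), i)
        for s in range(n_subnets):
            members = np.concatenate(([i], rng.choice(others, size=k, replace=False)))
            block = rawv[members]
            mu = block.mean(axis=0)
            sd = block.std(axis=0, ddof=1)
            sd[sd == 0] = 1.0
            subnet_scores[i, s] = (block[0] - mu) / sd
    values = pd.DataFrame(np.median(subnet_scores, axis=1), index=tfs, columns=raw.columns)
    return TFActivityMatrix(values=values, subnet_scores=subnet_scores).validate()


@dataclass
class BenchmarkResult:
    """Knockout-benchmark outcome for every (TF, KO condition) pair."""

    records: pd.DataFrame = field(default_factory=pd.DataFrame)
    # columns: tf, ko_condition, control_condition, direction_correct,
    #          accuracy, rank_percentile

    @property
    def n_correct(self) -> int:
        return int(self.records["direction_correct"].sum()) if len(self.records) else 0

    @property
    def n_total(self) -> int:
        return len(self.records)


def ko_direction_benchmark(
    act: TFActivityMatrix, meta: pd.DataFrame
) -> BenchmarkResult:
    """Check that each knocked-out TF's activity drops below its control.

    ``direction_correct`` compares final (median) activities;
    ``accuracy`` is the proportion of subnetwork replicates agreeing with
    the expected direction; ``rank_percentile`` is the rank (ascending,
    1 = lowest) of the KO condition among all conditions for that TF,
    divided by the number of conditions — low is good.
    """
    rows = []
    conds = act.conditions
    cond_idx = {c: i for i, c in enumerate(conds)}
    for cond in meta.index:
        ko = meta.at[cond, "knocked_out_gene"] if "knocked_out_gene" in meta else ""
        ctrl = (
            meta.at[cond, "control_condition_id"]
            if "control_condition_id" in meta
            else ""
        )
        if not (isinstance(ko, str) and ko and ko in act.values.index):
            continue
        if not (isinstance(ctrl, str) and ctrl and ctrl in cond_idx):
            warnings.warn(f"KO condition {cond!r} has no control; skipped", stacklevel=2)
            continue
        tf_row = act.values.loc[ko]
        correct = bool(tf_row[cond] < tf_row[ctrl])
        if act.subnet_scores is not None:
            i = act.values.index.get_loc(ko)
            per_subnet = act.subnet_scores[i, :, cond_idx[cond]] < act.subnet_scores[
                i, :, cond_idx[ctrl]
            ]
            accuracy = float(per_subnet.mean())
        else:
            accuracy = float(correct)
        rank = float(stats.rankdata(tf_row.to_numpy())[cond_idx[cond]])
        rows.append(
            {
                "tf": ko,
                "ko_condition": cond,
                "control_condition": ctrl,
                "direction_correct": correct,
                "accuracy": accuracy,
                "rank_percentile": rank / len(conds),
            }
        )
    return BenchmarkResult(records=pd.DataFrame(rows))


def dynamic_chi2_threshold(
    values: np.ndarray, correct: np.ndarray
) -> float:
    """Cutoff on a per-TF metric that best separates correct assignments.

    Scans every midpoint between consecutive distinct metric values; for
    each candidate cutoff forms the 2x2 table (above/below x
    correct/incorrect) and computes a chi-squared p-value (no continuity
    correction). Returns the cutoff minimizing p among candidates where
    the above-cutoff group has the higher proportion correct, breaking
    ties toward the smaller cutoff (retaining more TFs). Returns ``-inf``
    (no filtering) when no candidate qualifies.
    """
    values = np.asarray(values, dtype=float)
    correct = np.asarray(correct, dtype=bool)
    distinct = np.unique(values)
    if distinct.size < 2:
        warnings.warn("fewer than two distinct metric values; no cutoff", stacklevel=2)
        return -np.inf
    if correct.all() or not correct.any():
        warnings.warn("only one correctness class present; no cutoff", stacklevel=2)
        return -np.inf
    best_p, best_cut = np.inf, -np.inf
    for cut in (distinct[:-1] + distinct[1:]) / 2.0:
        above = values > cut
        table = np.array(
            [
                [np.sum(above & correct), np.sum(above & ~correct)],
                [np.sum(~above & correct), np.sum(~above & ~correct)],
            ]
        )
        if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
            continue
        prop_above = table[0, 0] / table[0].sum()
        prop_below = table[1, 0] / table[1].sum()
        if prop_above <= prop_below:
            continue
        p = stats.chi2_contingency(table, correction=False)[1]
        if p < best_p:
            best_p, best_cut = p, cut
    if not np.isfinite(best_cut):
        warnings.warn("no valid chi-squared cutoff found; not filtering", stacklevel=2)
    return float(best_cut)


@dataclass(frozen=True)
class ActivityFilter:
    """TF-level filter on basal maximum activity and activity range."""

    basal_max_activity_cutoff: float = -np.inf
    activity_range_cutoff: float = -np.inf

    def keep(self, act: TFActivityMatrix) -> list[str]:
        vals = act.values
        basal_max = vals.max(axis=1)
        rng = vals.max(axis=1) - vals.min(axis=1)
        mask = (basal_max >= self.basal_max_activity_cutoff) & (
            rng >= self.activity_range_cutoff
        )
        return list(vals.index[mask])


def activity_range(
    act: TFActivityMatrix, subset: list[str]
) -> pd.DataFrame:
    """Per-TF activity range over all conditions vs a condition subset.

    ``retention`` = range over subset / range over all conditions (1 when
    the full range is 0).
    """
    if not subset:
        raise ValueError("condition subset is empty")
    missing = [c for c in subset if c not in act.values.columns]
    if missing:
        raise ValueError(f"subset conditions absent from matrix: {missing}")
    full = act.values.max(axis=1) - act.values.min(axis=1)
    sub = act.values[subset].max(axis=1) - act.values[subset].min(axis=1)
    retention = np.where(full.to_numpy() == 0, 1.0, sub.to_numpy() / full.to_numpy())
    return pd.DataFrame(
        {"range_full": full, "range_subset": sub, "retention": retention},
        index=act.values.index,
    )
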