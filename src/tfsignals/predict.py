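"""Three-filter cascade producing the candidate TF-metabolite list.

A pair survives when (i) its mean bootstrap correlation strictly exceeds
the ROC-derived correlation threshold, (ii) its stability is at or above
the stability cutoff, and (iii) its metabolic distance is at or below
the distance cutoff (0 by default). TFs without any regulated enzyme
have infinite distance everywhere and therefore drop out of the search
space entirely.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bootstrap import BootstrapResult, StabilityScores
from .datamodel import CandidatePair, ConsistencyError, KnownInteractionSet

__all__ = [
    "FilterConfig",
    "filter_candidates",
    "PredictionSummary",
    "summarize_predictions",
]

#: Stability cutoff reported for the original dataset; shipped as a
#: documented reference value — the pipeline recomputes the cutoff from
#: the data via ``select_stability_threshold``.
REFERENCE_STABILITY_CUTOFF = 0.128


@dataclass(frozen=True)
class FilterConfig:
    """Cutoffs of the candidate cascade."""

    target_fpr: float = 0.1
    stability_cutoff: float = REFERENCE_STABILITY_CUTOFF
    distance_cutoff: float = 0
    effect: str = "activating"

    def validate(self) -> "FilterConfig":
        if not 0 < self.target_fpr < 1:
            raise ValueError("target_fpr must lie in (0, 1)")
        if not 0 <= self.stability_cutoff <= 1:
            raise ValueError("stability_cutoff must lie in [0, 1]")
        if self.distance_cutoff < 0:
            raise ValueError("distance_cutoff must be >= 0")
        if self.effect not in ("activating", "inactivating"):
            raise ValueError(f"unknown effect {self.effect!r}")
        return self


def filter_candidates(
    boot: BootstrapResult,
    stab: StabilityScores,
    distances: pd.DataFrame,
    cfg: FilterConfig,
    known: KnownInteractionSet | None = None,
) -> list[CandidatePair]:
    """Apply the correlation / stability / distance cascade.

    ``distances`` is a DataFrame with columns tf, metabolite, distance,
    position covering the same pair universe as ``boot``. The correlation
    threshold is the one stored on ``stab`` (the ROC-derived value its
    stabilities were counted against).
    """
    cfg.validate()
    mean_flat = boot.mean_flat()
    stab_flat = stab.flat()
    if len(stab_flat) != len(mean_flat):
        raise ConsistencyError("correlation and stability pair universes disagree")
    df = pd.DataFrame({"mean_rho": mean_flat, "stability": stab_flat}).reset_index()
    merged = df.merge(
        distances[["tf", "metabolite", "distance", "position"]],
        on=["tf", "metabolite"],
        how="left",
        indicator=True,
    )
    missing = merged.loc[merged["_merge"] != "both", ["tf", "metabolite"]]
    if len(missing):
        raise ConsistencyError(
            "pair universes disagree; missing distances for "
            f"{list(missing.itertuples(index=False, name=None))[:5]}"
        )
    rho = merged["mean_rho"].to_numpy(dtype=float)
    score = rho if cfg.effect == "activating" else -rho
    dist = merged["distance"].to_numpy(dtype=float)
    keep = (
        np.isfinite(score)
        & (score > stab.threshold)
        & (merged["stability"].to_numpy(dtype=float) >= cfg.stability_cutoff)
        & (dist <= cfg.distance_cutoff)
    )
    known_pairs = known.pairs(cfg.effect) if known is not None else set()
    out = [
        CandidatePair(
            tf=row.tf,
            metabolite=row.metabolite,
            correlation_score=float(row.mean_rho),
            stability=float(row.stability),
            distance=float(row.distance),
            position=str(row.position),
            known=(row.tf, row.metabolite) in known_pairs,
        ).validate()
        for row in merged[keep].itertuples(index=False)
    ]
    out.sort(key=lambda p: (p.tf, -p.correlation_score))
    return out


@dataclass
class PredictionSummary:
    """Per-TF counts, position proportions and known-interaction recovery."""

    per_tf_counts: pd.Series
    position_proportions: pd.Series
    known_recovered_any: int
    known_recovered_top: int
    known_measured: int

    def as_dict(self) -> dict:
        return {
            "n_candidates": int(self.per_tf_counts.sum()),
            "n_tfs_with_candidates": int((self.per_tf_counts > 0).sum()),
            "position_proportions": self.position_proportions.to_dict(),
            "known_recovered_any": self.known_recovered_any,
            "known_recovered_top": self.known_recovered_top,
            "known_measured": self.known_measured,
        }


def summarize_predictions(
    pairs: list[CandidatePair], known: KnownInteractionSet
) -> PredictionSummary:
    """Summary statistics over the final candidate list.

    Known-interaction recovery is reported under both readings: a TF
    counts as recovered when *any* of its candidates matches its known
    signal, and separately when its *top-correlating* candidate does.
    """
    counts = pd.Series(dtype=int)
    if pairs:
        counts = pd.Series([p.tf for p in pairs]).value_counts().sort_index()
    classified = [p for p in pairs if p.position != "unclassified"]
    if classified:
        props = (
            pd.Series([p.position for p in classified])
            .value_counts(normalize=True)
            .reindex(["upstream", "within", "downstream"], fill_value=0.0)
        )
    else:
        props = pd.Series(
            0.0, index=pd.Index(["upstream", "within", "downstream"])
        )

    known_by_tf: dict[str, set[str]] = {}
    for _, row in known.entries.iterrows():
        known_by_tf.setdefault(row["tf"], set()).add(row["metabolite"])

    by_tf: dict[str, list[CandidatePair]] = {}
    for p in pairs:
        by_tf.setdefault(p.tf, []).append(p)
    rec_any = rec_top = 0
    for tf, mets in known_by_tf.items():
        cands = by_tf.get(tf, [])
        if any(c.metabolite in mets for c in cands):
            rec_any += 1
        if cands and max(cands, key=lambda c: c.correlation_score).metabolite in mets:
            rec_top += 1
    return PredictionSummary(
        per_tf_counts=counts,
        position_proportions=props,
        known_recovered_any=rec_any,
        known_recovered_top=rec_top,
        known_measured=len(known_by_tf),
    )
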