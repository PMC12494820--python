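"""Metabolomics preprocessing: replicate merging, TIC normalization,
CV-based quality filtering and exact-mass annotation.

The fixed pipeline order is

    merge_replicates -> tic_normalize -> cv_filter -> annotate_ions

mirroring how flow-injection MS ion tables are turned into a single
abundance value per annotated metabolite and condition: technical
injections are averaged first, each injection column is scaled to unit
total ion count, ions with a coefficient of variation of >= 15% across
biological replicates are discarded, and surviving ions are matched to
reference compounds by [M-H]- exact mass within 0.001 Da. Compounds that
share a monoisotopic mass are indistinguishable by exact mass and
collapse into one matrix row carrying the full annotation set.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datamodel import (
    CompoundReference,
    FormatError,
    IonTable,
    MetaboliteAbundanceMatrix,
    PROTON_MASS,
)

__all__ = [
    "merge_replicates",
    "tic_normalize",
    "cv_filter",
    "annotate_ions",
    "max_fold_change",
    "preprocess",
]


class NormalizationError(ValueError):
    """A measurement column cannot be normalized."""


class AnnotationError(ValueError):
    """Ion annotation cannot proceed."""


def merge_replicates(table: IonTable) -> IonTable:
    """Average technical replicates per ion and biological replicate."""
    df = table.data
    merged = (
        df.groupby(["ion_id", "mz", "condition", "bio_rep"], sort=False, as_index=False)[
            "intensity"
        ]
        .mean()
        .assign(tech_rep=1)
    )
    return IonTable(data=merged[list(IonTable.COLUMNS)])


def tic_normalize(table: IonTable) -> IonTable:
    """Scale every (condition, bio_rep, tech_rep) column to unit total."""
    df = table.data.copy()
    key = ["condition", "bio_rep", "tech_rep"]
    totals = df.groupby(key)["intensity"].transform("sum")
    zero = totals <= 0
    if zero.any():
        col = df.loc[zero, key].iloc[0]
        raise NormalizationError(
            f"all-zero measurement column {tuple(col)} cannot be TIC-normalized"
        )
    df["intensity"] = df["intensity"] / totals
    return IonTable(data=df)


def cv_filter(table: IonTable, max_cv: float = 0.15) -> IonTable:
    """Drop ions whose CV across biological replicates is >= ``max_cv``.

    An ion failing the criterion in any condition is removed entirely:
    the downstream correlation needs complete condition profiles. The
    returned table holds one column per condition with the mean over
    biological replicates.
    """
    df = table.data
    if df.groupby(["ion_id", "condition"])["bio_rep"].nunique().min() < 2:
        raise FormatError("cv_filter requires >= 2 biological replicates")
    stats = df.groupby(["ion_id", "condition"])["intensity"].agg(["mean", "std"])
    mean, sd = stats["mean"], stats["std"]
    # zero mean with nonzero spread is an undefined CV: treat as failing
    cv = np.where(mean > 0, sd / mean.replace(0, np.nan), np.where(sd > 0, np.inf, 0.0))
    failing = stats.index[cv >= max_cv].get_level_values("ion_id").unique()
    keep = ~df["ion_id"].isin(failing)
    collapsed = (
        df[keep]
        .groupby(["ion_id", "mz", "condition"], sort=False, as_index=False)["intensity"]
        .mean()
        .assign(bio_rep=1, tech_rep=1)
    )
    return IonTable(data=collapsed[list(IonTable.COLUMNS)])


def annotate_ions(
    table: IonTable,
    ref: CompoundReference,
    tol: float = 0.001,
    adduct_mass_shift: float = -PROTON_MASS,
) -> MetaboliteAbundanceMatrix:
    """Match ions to compounds by exact mass and build the abundance matrix.

    Expected m/z of a compound is ``monoisotopic_mass + adduct_mass_shift``
    (default [M-H]-). An ion is annotated with every compound within
    ``tol``; isobaric compounds (identical mass after rounding to 6
    decimals) collapse into one row keyed by the sorted annotation set.
    Unmatched ions are dropped; if two ions map to the same annotation
    set, the one with the smallest mass error wins.
    """
    ref.validate()
    df = table.data
    masses = ref.entries["monoisotopic_mass"].to_numpy(dtype=float)
    compounds = ref.entries["compound_id"].to_numpy()
    expected = masses + adduct_mass_shift

    ion_mz = df.groupby("ion_id", sort=False)["mz"].first()
    rows: dict[str, dict] = {}
    for ion, mz in ion_mz.items():
        err = np.abs(expected - mz)
        hit = err <= tol
        if not hit.any():
            continue
        annots = frozenset(compounds[hit])
        label = ";".join(sorted(annots))
        best_err = float(err[hit].min())
        if label in rows and rows[label]["mass_error"] <= best_err:
            continue
        rows[label] = {"ion_id": ion, "mz": float(mz), "mass_error": best_err, "annots": annots}

    if not rows:
        return MetaboliteAbundanceMatrix(
            values=pd.DataFrame(columns=sorted(df["condition"].unique())),
            annotations={},
            provenance=pd.DataFrame(columns=["ion_id", "mz", "mass_error"]),
        )

    wide = (
        df.groupby(["ion_id", "condition"], sort=False)["intensity"]
        .mean()
        .unstack("condition")
        .sort_index(axis=1)
    )
    labels = sorted(rows)
    values = pd.DataFrame(
        [wide.loc[rows[lab]["ion_id"]] for lab in labels], index=labels
    )
    values.index.name = "metabolite"
    provenance = pd.DataFrame(
        [
            {"ion_id": rows[lab]["ion_id"], "mz": rows[lab]["mz"], "mass_error": rows[lab]["mass_error"]}
            for lab in labels
        ],
        index=labels,
    )
    return MetaboliteAbundanceMatrix(
        values=values,
        annotations={lab: rows[lab]["annots"] for lab in labels},
        provenance=provenance,
    ).validate()


def max_fold_change(matrix: MetaboliteAbundanceMatrix) -> pd.Series:
    """Max over conditions / min over conditions, per metabolite row.

    A zero minimum yields an infinite ratio.
    """
    vals = matrix.values.to_numpy(dtype=float)
    hi = vals.max(axis=1)
    lo = vals.min(axis=1)
    with np.errstate(divide="ignore"):
        ratio = np.where(lo > 0, hi / np.where(lo > 0, lo, 1.0), np.inf)
    ratio = np.where((hi == 0) & (lo == 0), 1.0, ratio)
    return pd.Series(ratio, index=matrix.values.index, name="max_fold_change")


def preprocess(
    table: IonTable,
    ref: CompoundReference,
    max_cv: float = 0.15,
    tol: float = 0.001,
) -> MetaboliteAbundanceMatrix:
    """Run the full fixed-order preprocessing pipeline."""
    return annotate_ions(
        cv_filter(tic_normalize(merge_replicates(table)), max_cv=max_cv),
        ref,
        tol=tol,
    )
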