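"""Shared data model for the TF input-signal prediction pipeline.

The pipeline couples four kinds of measurements and prior knowledge:

* a gene expression matrix (genes x conditions) with per-condition
  metadata, including which gene (if any) was knocked out;
* a signed transcriptional regulatory network defining each TF's regulon;
* a genome-scale metabolic model linking genes to reactions;
* a replicated ion-intensity table from untargeted mass spectrometry,
  annotated against a reference list of compound monoisotopic masses;
* a table of already-known TF-metabolite interactions used as positives.

All containers are thin dataclasses around pandas objects with explicit
``validate`` methods; validation errors name the offending record.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ConsistencyError",
    "ExpressionMatrix",
    "RegulatoryNetwork",
    "Reaction",
    "MetabolicModel",
    "IonTable",
    "CompoundReference",
    "KnownInteractionSet",
    "MetaboliteAbundanceMatrix",
    "TFActivityMatrix",
    "CandidatePair",
    "PROTON_MASS",
]

#: Mass of a proton in Da; the [M-H]- adduct expected in negative-mode
#: flow-injection MS subtracts exactly this from the neutral mass.
PROTON_MASS = 1.007276


class FormatError(ValueError):
    """A file or table violates the expected format."""


class ConsistencyError(ValueError):
    """Cross-references between inputs do not line up."""


def _check_unique(values: Iterable, what: str) -> None:
    seen: set = set()
    for v in values:
        if v in seen:
            raise FormatError(f"duplicate {what}: {v!r}")
        seen.add(v)


@dataclass
class ExpressionMatrix:
    """Log-scale expression values, genes as rows, conditions as columns.

    ``condition_meta`` is indexed by condition id and may carry the columns
    ``strain``, ``perturbation``, ``knocked_out_gene`` and
    ``control_condition_id`` (the latter two may be empty/NaN).
    """

    values: pd.DataFrame
    condition_meta: pd.DataFrame

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def conditions(self) -> list[str]:
        return list(self.values.columns)

    def validate(self) -> "ExpressionMatrix":
        _check_unique(self.values.index, "gene id")
        _check_unique(self.values.columns, "condition id")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            bad = self.values.index[
                ~np.isfinite(self.values.to_numpy(dtype=float)).all(axis=1)
            ][0]
            raise FormatError(f"non-finite expression value in gene {bad!r}")
        genes = set(self.values.index)
        conds = set(self.values.columns)
        for cond in self.condition_meta.index:
            if cond not in conds:
                raise ConsistencyError(
                    f"metadata condition {cond!r} absent from expression matrix"
                )
        if "knocked_out_gene" in self.condition_meta:
            for cond, ko in self.condition_meta["knocked_out_gene"].items():
                if isinstance(ko, str) and ko and ko not in genes:
                    raise ConsistencyError(
                        f"knocked-out gene {ko!r} of condition {cond!r} "
                        "absent from expression matrix"
                    )
        if "control_condition_id" in self.condition_meta:
            for cond, ctrl in self.condition_meta["control_condition_id"].items():
                if isinstance(ctrl, str) and ctrl and ctrl not in conds:
                    raise ConsistencyError(
                        f"control condition {ctrl!r} of condition {cond!r} "
                        "absent from expression matrix"
                    )
        return self

    def knockout_pairs(self) -> list[tuple[str, str, str]]:
        """Return (knocked-out gene, KO condition, control condition) triples."""
        out = []
        meta = self.condition_meta
        if "knocked_out_gene" not in meta or "control_condition_id" not in meta:
            return out
        for cond in meta.index:
            ko = meta.at[cond, "knocked_out_gene"]
            ctrl = meta.at[cond, "control_condition_id"]
            if isinstance(ko, str) and ko and isinstance(ctrl, str) and ctrl:
                out.append((ko, cond, ctrl))
        return out


@dataclass
class RegulatoryNetwork:
    """Signed TF -> target edges; sign 0 encodes dual/unknown regulation."""

    edges: pd.DataFrame  # columns: tf, target, sign

    def validate(self) -> "RegulatoryNetwork":
        required = {"tf", "target", "sign"}
        if not required.issubset(self.edges.columns):
            raise FormatError(f"network table needs columns {sorted(required)}")
        dup = self.edges.duplicated(subset=["tf", "target"])
        if dup.any():
            row = self.edges[dup].iloc[0]
            raise FormatError(f"duplicate edge ({row['tf']!r}, {row['target']!r})")
        if not self.edges["sign"].isin([-1, 0, 1]).all():
            bad = self.edges.loc[~self.edges["sign"].isin([-1, 0, 1])].iloc[0]
            raise FormatError(f"invalid sign {bad['sign']!r} on edge {bad['tf']!r}")
        return self

    @property
    def tfs(self) -> list[str]:
        return sorted(self.edges["tf"].unique())

    def regulon(self, tf: str) -> dict[str, int]:
        """Targets of ``tf`` mapped to their regulation sign."""
        sub = self.edges[self.edges["tf"] == tf]
        return dict(zip(sub["target"], sub["sign"].astype(int)))

    def regulon_sizes(self) -> pd.Series:
        return self.edges.groupby("tf").size()


@dataclass(frozen=True)
class Reaction:
    """One metabolic reaction with species ids and flattened gene set."""

    id: str
    substrates: tuple[str, ...]
    products: tuple[str, ...]
    reversible: bool = False
    genes: frozenset[str] = frozenset()

    def participants(self) -> tuple[str, ...]:
        return self.substrates + self.products


@dataclass
class MetabolicModel:
    """Reaction list plus per-species compartment labels."""

    reactions: list[Reaction]
    compartments: dict[str, str] = field(default_factory=dict)

    def validate(self) -> "MetabolicModel":
        _check_unique((r.id for r in self.reactions), "reaction id")
        for r in self.reactions:
            if not r.substrates or not r.products:
                raise ConsistencyError(
                    f"reaction {r.id!r} lacks a substrate or a product"
                )
            for sp in r.participants():
                if sp not in self.compartments:
                    raise ConsistencyError(
                        f"species {sp!r} of reaction {r.id!r} has no compartment"
                    )
        return self

    @property
    def species(self) -> list[str]:
        out: set[str] = set()
        for r in self.reactions:
            out.update(r.participants())
        return sorted(out)


@dataclass
class IonTable:
    """Long-format replicated ion intensities.

    Columns: ``ion_id``, ``mz``, ``condition``, ``bio_rep``, ``tech_rep``,
    ``intensity``.  One measurement column in the wide sense corresponds to
    one (condition, bio_rep, tech_rep) triple.
    """

    data: pd.DataFrame

    COLUMNS = ("ion_id", "mz", "condition", "bio_rep", "tech_rep", "intensity")

    def validate(self) -> "IonTable":
        missing = set(self.COLUMNS) - set(self.data.columns)
        if missing:
            raise FormatError(f"ion table missing columns {sorted(missing)}")
        if (self.data["mz"] <= 0).any():
            bad = self.data.loc[self.data["mz"] <= 0, "ion_id"].iloc[0]
            raise FormatError(f"non-positive m/z for ion {bad!r}")
        if (self.data["intensity"] < 0).any():
            bad = self.data.loc[self.data["intensity"] < 0, "ion_id"].iloc[0]
            raise FormatError(f"negative intensity for ion {bad!r}")
        # replicate completeness: every ion observed in every column
        cols = self.data.groupby(["condition", "bio_rep", "tech_rep"]).ngroups
        per_ion = self.data.groupby("ion_id").size()
        if per_ion.nunique() > 1 or (per_ion != cols).any():
            bad = per_ion.index[per_ion != cols][0]
            raise FormatError(f"ion {bad!r} missing replicate measurements")
        return self

    @property
    def ions(self) -> list:
        return list(self.data["ion_id"].unique())

    def ion_masses(self) -> pd.Series:
        return self.data.groupby("ion_id")["mz"].first()


@dataclass
class CompoundReference:
    """Compound ids with monoisotopic neutral masses (Da)."""

    entries: pd.DataFrame  # columns: compound_id, monoisotopic_mass [, formula]

    def validate(self) -> "CompoundReference":
        if self.entries.empty:
            raise FormatError("empty compound reference")
        _check_unique(self.entries["compound_id"], "compound id")
        if (self.entries["monoisotopic_mass"] <= 0).any():
            bad = self.entries.loc[
                self.entries["monoisotopic_mass"] <= 0, "compound_id"
            ].iloc[0]
            raise FormatError(f"non-positive mass for compound {bad!r}")
        return self


@dataclass
class KnownInteractionSet:
    """Previously reported TF-metabolite interactions with effect direction."""

    entries: pd.DataFrame  # columns: tf, metabolite, effect

    EFFECTS = ("activating", "inactivating")

    def validate(self) -> "KnownInteractionSet":
        dup = self.entries.duplicated(subset=["tf", "metabolite"])
        if dup.any():
            row = self.entries[dup].iloc[0]
            raise FormatError(
                f"duplicate known pair ({row['tf']!r}, {row['metabolite']!r})"
            )
        bad = ~self.entries["effect"].isin(self.EFFECTS)
        if bad.any():
            raise FormatError(
                f"unknown effect label {self.entries.loc[bad, 'effect'].iloc[0]!r}"
            )
        return self

    def pairs(self, effect: str | None = None) -> set[tuple[str, str]]:
        sub = self.entries
        if effect is not None:
            sub = sub[sub["effect"] == effect]
        return set(zip(sub["tf"], sub["metabolite"]))


@dataclass
class MetaboliteAbundanceMatrix:
    """Annotated, normalized metabolite abundances, metabolites x conditions.

    A row may represent several isobaric compounds; ``annotations`` maps the
    row label to the full compound set, and ``provenance`` records the ion
    each row came from.
    """

    values: pd.DataFrame
    annotations: dict[str, frozenset[str]] = field(default_factory=dict)
    provenance: pd.DataFrame | None = None

    @property
    def metabolites(self) -> list[str]:
        return list(self.values.index)

    @property
    def conditions(self) -> list[str]:
        return list(self.values.columns)

    def validate(self) -> "MetaboliteAbundanceMatrix":
        _check_unique(self.values.index, "metabolite row")
        if (self.values.to_numpy(dtype=float) < 0).any():
            raise FormatError("negative abundance value")
        for row in self.values.index:
            if row in self.annotations and not self.annotations[row]:
                raise FormatError(f"row {row!r} has an empty annotation set")
        return self

    def annotation_set(self, row: str) -> frozenset[str]:
        return self.annotations.get(row, frozenset([row]))


@dataclass
class TFActivityMatrix:
    """Inferred TF activities, TFs x conditions.

    ``subnet_scores`` optionally retains the per-subnetwork standardized
    scores (TFs x subnetworks x conditions) that the final median was taken
    over; the knockout benchmark uses them for its accuracy metric.
    """

    values: pd.DataFrame
    subnet_scores: np.ndarray | None = None

    @property
    def tfs(self) -> list[str]:
        return list(self.values.index)

    @property
    def conditions(self) -> list[str]:
        return list(self.values.columns)

    def validate(self) -> "TFActivityMatrix":
        _check_unique(self.values.index, "TF id")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise FormatError("non-finite activity value")
        return self


@dataclass
class CandidatePair:
    """One TF-metabolite interaction hypothesis after the filter cascade."""

    tf: str
    metabolite: str
    correlation_score: float
    stability: float
    distance: float  # nonnegative int or math.inf
    position: str = "unclassified"  # upstream | within | downstream | unclassified
    known: bool = False

    POSITIONS = ("upstream", "within", "downstream", "unclassified")

    def validate(self) -> "CandidatePair":
        if not -1.0 <= self.correlation_score <= 1.0:
            raise FormatError(
                f"correlation {self.correlation_score} outside [-1, 1] "
                f"for pair ({self.tf}, {self.metabolite})"
            )
        if not 0.0 <= self.stability <= 1.0:
            raise FormatError(
                f"stability {self.stability} outside [0, 1] "
                f"for pair ({self.tf}, {self.metabolite})"
            )
        if self.distance < 0:
            raise FormatError(f"negative distance for pair ({self.tf}, {self.metabolite})")
        if self.position not in self.POSITIONS:
            raise FormatError(f"unknown position label {self.position!r}")
        return self
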