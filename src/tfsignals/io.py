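"""Readers and writers for the pipeline's tabular and model formats.

All tables are UTF-8 TSV with a header row; matrices are stored with
conditions as columns. Metabolic models are read from SBML (via cobrapy)
or from a cobrapy-style JSON reaction list with a ``metabolites``
stoichiometry map and a ``gene_reaction_rule`` string. Infinite distances
serialize as the literal ``inf``.
"""

from __future__ import annotations

import json
import math
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import (
    CandidatePair,
    CompoundReference,
    ConsistencyError,
    ExpressionMatrix,
    FormatError,
    IonTable,
    KnownInteractionSet,
    MetabolicModel,
    MetaboliteAbundanceMatrix,
    Reaction,
    RegulatoryNetwork,
    TFActivityMatrix,
)

_EFFECT_TOKENS = {
    "activator": 1,
    "repressor": -1,
    "dual": 0,
    "+": 1,
    "-": -1,
    "−": -1,
    "+-": 0,
    "-+": 0,
}


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def read_expression_matrix(path, meta_path) -> ExpressionMatrix:
    raw = _read_tsv(path)
    gene_col = raw.columns[0]
    values = raw.set_index(gene_col)
    for col in values.columns:
        try:
            values[col] = values[col].astype(float)
        except ValueError as exc:
            bad = values.index[pd.to_numeric(values[col], errors="coerce").isna()][0]
            raise FormatError(
                f"non-numeric expression value at gene {bad!r}, condition {col!r}"
            ) from exc
    meta = _read_tsv(meta_path).set_index("condition")
    return ExpressionMatrix(values=values, condition_meta=meta).validate()


def write_expression_matrix(expr: ExpressionMatrix, path, meta_path) -> None:
    expr.values.to_csv(path, sep="\t", index_label="gene")
    expr.condition_meta.to_csv(meta_path, sep="\t", index_label="condition")


def read_regulatory_network(path) -> RegulatoryNetwork:
    raw = _read_tsv(path)
    if raw.shape[1] < 3:
        raise FormatError("network table needs columns tf, target, effect")
    raw = raw.rename(
        columns=dict(zip(raw.columns[:3], ["tf", "target", "effect"]))
    )
    signs = []
    for tok in raw["effect"]:
        key = str(tok).strip().lower()
        if key in _EFFECT_TOKENS:
            signs.append(_EFFECT_TOKENS[key])
        elif key in {"1", "-1", "0"}:
            signs.append(int(key))
        else:
            raise FormatError(f"unknown effect token {tok!r}")
    edges = pd.DataFrame(
        {"tf": raw["tf"], "target": raw["target"], "sign": signs}
    )
    # conflicting duplicate rows collapse to dual (sign 0)
    def _collapse(group: pd.Series) -> int:
        vals = set(group)
        return vals.pop() if len(vals) == 1 else 0

    edges = (
        edges.groupby(["tf", "target"], sort=False)["sign"]
        .agg(_collapse)
        .reset_index()
    )
    return RegulatoryNetwork(edges=edges).validate()


def write_regulatory_network(net: RegulatoryNetwork, path) -> None:
    token = {1: "activator", -1: "repressor", 0: "dual"}
    out = net.edges.assign(effect=net.edges["sign"].map(token))
    out[["tf", "target", "effect"]].to_csv(path, sep="\t", index=False)


_GENE_SPLIT = re.compile(r"\band\b|\bor\b|[()]", flags=re.IGNORECASE)


def parse_gene_rule(rule: str) -> frozenset[str]:
    """Flatten a boolean gene-association rule to the set of gene ids."""
    if not rule or not rule.strip():
        return frozenset()
    parts = [p.strip() for p in _GENE_SPLIT.split(rule)]
    return frozenset(p for p in parts if p)


def read_metabolic_model(path) -> MetabolicModel:
    path = Path(path)
    if path.suffix.lower() == ".json":
        return _read_model_json(path)
    return _read_model_sbml(path)


def _read_model_json(path: Path) -> MetabolicModel:
    doc = json.loads(Path(path).read_text())
    compartments: dict[str, str] = {}
    for met in doc.get("metabolites", []):
        compartments[met["id"]] = met.get("compartment", "c")
    reactions = []
    for rxn in doc["reactions"]:
        stoich = rxn["metabolites"]
        subs = tuple(sorted(m for m, c in stoich.items() if c < 0))
        prods = tuple(sorted(m for m, c in stoich.items() if c > 0))
        if not subs or not prods:
            raise ConsistencyError(
                f"reaction {rxn['id']!r} lacks a substrate or a product"
            )
        lb = rxn.get("lower_bound", 0.0)
        ub = rxn.get("upper_bound", 1000.0)
        reversible = bool(rxn.get("reversible", lb < 0 < ub))
        genes = parse_gene_rule(rxn.get("gene_reaction_rule", ""))
        for m in stoich:
            compartments.setdefault(m, "c")
        reactions.append(
            Reaction(
                id=rxn["id"],
                substrates=subs,
                products=prods,
                reversible=reversible,
                genes=genes,
            )
        )
    return MetabolicModel(reactions=reactions, compartments=compartments).validate()


def _read_model_sbml(path: Path) -> MetabolicModel:
    from cobra.io import read_sbml_model

    cmodel = read_sbml_model(str(path))
    compartments = {m.id: m.compartment or "c" for m in cmodel.metabolites}
    reactions = []
    for rxn in cmodel.reactions:
        subs = tuple(sorted(m.id for m, c in rxn.metabolites.items() if c < 0))
        prods = tuple(sorted(m.id for m, c in rxn.metabolites.items() if c > 0))
        if not subs or not prods:
            raise ConsistencyError(
                f"reaction {rxn.id!r} lacks a substrate or a product"
            )
        genes = frozenset(g.id for g in rxn.genes)
        reactions.append(
            Reaction(
                id=rxn.id,
                substrates=subs,
                products=prods,
                reversible=rxn.reversibility,
                genes=genes,
            )
        )
    return MetabolicModel(reactions=reactions, compartments=compartments).validate()


def write_metabolic_model_json(model: MetabolicModel, path) -> None:
    mets = [
        {"id": m, "compartment": model.compartments.get(m, "c")}
        for m in model.species
    ]
    rxns = []
    for r in model.reactions:
        stoich: dict[str, float] = {}
        for s in r.substrates:
            stoich[s] = stoich.get(s, 0.0) - 1.0
        for p in r.products:
            stoich[p] = stoich.get(p, 0.0) + 1.0
        rxns.append(
            {
                "id": r.id,
                "metabolites": stoich,
                "gene_reaction_rule": " or ".join(sorted(r.genes)),
                "lower_bound": -1000.0 if r.reversible else 0.0,
                "upper_bound": 1000.0,
                "reversible": r.reversible,
            }
        )
    Path(path).write_text(
        json.dumps({"metabolites": mets, "reactions": rxns}, indent=1, sort_keys=True)
    )


def write_metabolic_model_sbml(model: MetabolicModel, path) -> None:
    import cobra
    from cobra.io import write_sbml_model

    cmodel = cobra.Model("model")
    met_objs = {
        m: cobra.Metabolite(m, compartment=model.compartments.get(m, "c"))
        for m in model.species
    }
    for r in model.reactions:
        rxn = cobra.Reaction(r.id)
        rxn.lower_bound = -1000.0 if r.reversible else 0.0
        rxn.upper_bound = 1000.0
        cmodel.add_reactions([rxn])
        rxn.add_metabolites(
            {
                **{met_objs[s]: -1.0 for s in r.substrates},
                **{met_objs[p]: 1.0 for p in r.products},
            }
        )
        if r.genes:
            rxn.gene_reaction_rule = " or ".join(sorted(r.genes))
    write_sbml_model(cmodel, str(path))


def read_ion_table(path) -> IonTable:
    df = pd.read_csv(path, sep="\t")
    return IonTable(data=df).validate()


def write_ion_table(table: IonTable, path) -> None:
    table.data.to_csv(path, sep="\t", index=False)


def read_compound_reference(path) -> CompoundReference:
    df = pd.read_csv(path, sep="\t")
    return CompoundReference(entries=df).validate()


def write_compound_reference(ref: CompoundReference, path) -> None:
    ref.entries.to_csv(path, sep="\t", index=False)


def read_known_interactions(path) -> KnownInteractionSet:
    df = _read_tsv(path)
    return KnownInteractionSet(entries=df).validate()


def write_known_interactions(known: KnownInteractionSet, path) -> None:
    known.entries.to_csv(path, sep="\t", index=False)


def read_abundance_matrix(path) -> MetaboliteAbundanceMatrix:
    raw = _read_tsv(path)
    values = raw.set_index(raw.columns[0]).astype(float)
    annotations = {row: frozenset(row.split(";")) for row in values.index}
    return MetaboliteAbundanceMatrix(values=values, annotations=annotations).validate()


def write_abundance_matrix(matrix: MetaboliteAbundanceMatrix, path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="metabolite")


def read_activity_matrix(path) -> TFActivityMatrix:
    raw = _read_tsv(path)
    values = raw.set_index(raw.columns[0]).astype(float)
    return TFActivityMatrix(values=values).validate()


def write_activity_matrix(act: TFActivityMatrix, path) -> None:
    act.values.to_csv(path, sep="\t", index_label="tf")


CANDIDATE_COLUMNS = [
    "tf",
    "metabolite",
    "correlation_score",
    "stability",
    "distance",
    "position",
    "known",
]


def write_candidates(pairs: list[CandidatePair], path) -> None:
    """Write candidates sorted by (tf, descending correlation score)."""
    rows = []
    for p in sorted(pairs, key=lambda p: (p.tf, -p.correlation_score)):
        p.validate()
        rows.append(
            {
                "tf": p.tf,
                "metabolite": p.metabolite,
                "correlation_score": repr(float(p.correlation_score)),
                "stability": repr(float(p.stability)),
                "distance": "inf" if math.isinf(p.distance) else str(int(p.distance)),
                "position": p.position,
                "known": str(bool(p.known)),
            }
        )
    pd.DataFrame(rows, columns=CANDIDATE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_candidates(path) -> list[CandidatePair]:
    df = _read_tsv(path)
    pairs = []
    for _, row in df.iterrows():
        pairs.append(
            CandidatePair(
                tf=row["tf"],
                metabolite=row["metabolite"],
                correlation_score=float(row["correlation_score"]),
                stability=float(row["stability"]),
                distance=math.inf if row["distance"] == "inf" else float(int(row["distance"])),
                position=row["position"],
                known=row["known"] == "True",
            ).validate()
        )
    return pairs
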