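"""Synthetic benchmark generator with planted ground truth.

Emulates the five inputs of the pipeline — expression matrix with knockout
conditions, signed regulatory network, metabolomics ion table with a
compound reference, toy metabolic model, and known-interaction table —
from a single seeded configuration, so that every stage (activity
inference, bootstrap correlation, distance filtering, candidate cascade)
can be checked against known truth.

The generative model:

* TF activities are i.i.d. standard normal per (TF, condition). In each
  knockout condition the deleted TF's activity is forced to its row
  minimum minus 2, guaranteeing the expected direction of change at any
  noise scale.
* Target-gene expression is the signed sum of its regulators' activities
  plus Gaussian noise; unregulated genes are pure noise.
* Each planted effector coupling ties one metabolite to one TF through an
  exponential link: abundance = exp(strength * activity + noise) for
  activating couplings (negated activity for inactivating). The link is
  monotone, so Spearman correlation is exactly +/-1 at zero noise;
  uncoupled metabolites are log-normal noise.
* The toy metabolic model realizes, for each planted pair, a small linear
  pathway whose regulated reactions carry a target gene of the planted TF,
  placing the metabolite at a chosen network distance (0, 1 or 2) and —
  for distance 0 — at a chosen position (upstream / within / downstream).
  A hub metabolite participating in 51 reactions and an ATP/ADP cofactor
  pair attached to the pathway reactions exercise the graph filtering.

All randomness flows from one seed through ``numpy.random.SeedSequence``
spawning, so a bundle is reproducible byte-for-byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as tio
from .datamodel import (
    ExpressionMatrix,
    IonTable,
    CompoundReference,
    KnownInteractionSet,
    MetabolicModel,
    MetaboliteAbundanceMatrix,
    Reaction,
    RegulatoryNetwork,
)

__all__ = [
    "GeneratorConfig",
    "PlantedCoupling",
    "SyntheticTruth",
    "SyntheticBundle",
    "generate_truth",
    "generate_expression",
    "generate_metabolome",
    "generate_ion_table",
    "generate_toy_metabolic_model",
    "generate_dataset",
]

#: cycle of planted (distance, position) classes assigned to couplings
_DISTANCE_CYCLE = [
    (0, "upstream"),
    (0, "within"),
    (0, "downstream"),
    (1, "unclassified"),
    (2, "unclassified"),
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition parameters of the synthetic benchmark.

    Defaults mirror a desk-scale version of the study design: 40 matched
    conditions of which 8 are TF knockouts, regulons of at least three
    targets, strong planted activating couplings, and mild measurement
    noise on both omics layers.
    """

    n_tfs: int = 30
    n_genes: int = 300
    n_conditions: int = 40
    n_metabolites: int = 60
    targets_per_tf: int = 8
    noise_sd_expression: float = 0.1
    noise_sd_metabolite: float = 0.1
    n_planted: int = 10
    n_ko_conditions: int = 8
    planted_strength: float = 1.0
    activating_fraction: float = 1.0
    known_fraction: float = 0.5
    replicate_noise_sd: float = 0.02
    n_bio_reps: int = 2
    n_tech_reps: int = 2
    seed: int = 7

    def validate(self) -> "GeneratorConfig":
        counts = {
            "n_tfs": self.n_tfs,
            "n_genes": self.n_genes,
            "n_conditions": self.n_conditions,
            "n_metabolites": self.n_metabolites,
            "targets_per_tf": self.targets_per_tf,
        }
        for name, v in counts.items():
            if v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")
        if self.targets_per_tf < 3:
            raise ValueError("targets_per_tf must be >= 3 (minimum regulon size)")
        if self.n_genes < self.targets_per_tf:
            raise ValueError("n_genes must be >= targets_per_tf")
        if self.noise_sd_expression < 0 or self.noise_sd_metabolite < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if not 0 < self.planted_strength <= 1:
            raise ValueError("planted_strength must lie in (0, 1]")
        if self.n_planted > min(self.n_tfs, self.n_metabolites):
            raise ValueError("n_planted exceeds available TFs or metabolites")
        if self.n_ko_conditions > min(self.n_tfs, self.n_conditions):
            raise ValueError("n_ko_conditions exceeds available TFs or conditions")
        return self

    def rngs(self, n: int) -> list[np.random.Generator]:
        """Spawn ``n`` independent child generators from the single seed."""
        children = np.random.SeedSequence(self.seed).spawn(n)
        return [np.random.default_rng(s) for s in children]


@dataclass(frozen=True)
class PlantedCoupling:
    tf: str
    metabolite: str
    effect: str  # activating | inactivating
    strength: float


@dataclass
class SyntheticTruth:
    """Ground truth the generators share and the tests recover."""

    true_activity: pd.DataFrame  # TFs x conditions
    planted_couplings: list[PlantedCoupling]
    ko_map: dict[str, str]  # condition -> knocked-out TF
    planted_distances: dict[tuple[str, str], tuple[int, str]]
    metabolites: list[str]

    def validate(self) -> "SyntheticTruth":
        tfs = set(self.true_activity.index)
        conds = set(self.true_activity.columns)
        mets = set(self.metabolites)
        for pc in self.planted_couplings:
            if pc.tf not in tfs:
                raise ValueError(f"planted coupling references unknown TF {pc.tf!r}")
            if pc.metabolite not in mets:
                raise ValueError(
                    f"planted coupling references unknown metabolite {pc.metabolite!r}"
                )
            if not 0 < pc.strength <= 1:
                raise ValueError(f"strength {pc.strength} outside (0, 1]")
        for cond in self.ko_map:
            if cond not in conds:
                raise ValueError(f"KO condition {cond!r} unknown")
        return self


def _ids(prefix: str, n: int) -> list[str]:
    width = max(2, len(str(n)))
    return [f"{prefix}{i + 1:0{width}d}" for i in range(n)]


def generate_truth(cfg: GeneratorConfig) -> tuple[SyntheticTruth, RegulatoryNetwork]:
    """Draw true activities, knockout assignments and the regulatory network."""
    cfg.validate()
    rng_act, rng_net, rng_plant, _, _, _ = cfg.rngs(6)

    tfs = _ids("tf", cfg.n_tfs)
    genes = _ids("g", cfg.n_genes)
    conds = _ids("cond", cfg.n_conditions)
    mets = _ids("m", cfg.n_metabolites)

    activity = rng_act.standard_normal((cfg.n_tfs, cfg.n_conditions))
    # knockouts occupy the last conditions; one distinct TF each
    ko_map: dict[str, str] = {}
    for k in range(cfg.n_ko_conditions):
        cond_idx = cfg.n_conditions - cfg.n_ko_conditions + k
        activity[k, cond_idx] = activity[k].min() - 2.0
        ko_map[conds[cond_idx]] = tfs[k]
    true_activity = pd.DataFrame(activity, index=tfs, columns=conds)

    # disjoint regulons whenever the gene pool allows; targets are shared
    # across TFs only when n_tfs * targets_per_tf exceeds n_genes
    disjoint = cfg.n_tfs * cfg.targets_per_tf <= cfg.n_genes
    if disjoint:
        pool = rng_net.permutation(cfg.n_genes)
    rows = []
    for k, tf in enumerate(tfs):
        if disjoint:
            targets = pool[k * cfg.targets_per_tf : (k + 1) * cfg.targets_per_tf]
        else:
            targets = rng_net.choice(
                cfg.n_genes, size=cfg.targets_per_tf, replace=False
            )
        signs = rng_net.choice([-1, 1], size=cfg.targets_per_tf)
        if cfg.targets_per_tf >= 2 and len(set(signs)) == 1:
            signs[0] = -signs[0]  # guarantee at least one of each sign
        for t, s in zip(targets, signs):
            rows.append((tf, genes[t], int(s)))
    net = RegulatoryNetwork(
        edges=pd.DataFrame(rows, columns=["tf", "target", "sign"])
    ).validate()

    planted_tfs = rng_plant.choice(cfg.n_tfs, size=cfg.n_planted, replace=False)
    planted_mets = rng_plant.choice(cfg.n_metabolites, size=cfg.n_planted, replace=False)
    n_activating = int(round(cfg.activating_fraction * cfg.n_planted))
    couplings = []
    planted_distances = {}
    for i, (ti, mi) in enumerate(zip(planted_tfs, planted_mets)):
        effect = "activating" if i < n_activating else "inactivating"
        couplings.append(
            PlantedCoupling(
                tf=tfs[ti],
                metabolite=mets[mi],
                effect=effect,
                strength=cfg.planted_strength,
            )
        )
        planted_distances[(tfs[ti], mets[mi])] = _DISTANCE_CYCLE[
            i % len(_DISTANCE_CYCLE)
        ]

    truth = SyntheticTruth(
        true_activity=true_activity,
        planted_couplings=couplings,
        ko_map=ko_map,
        planted_distances=planted_distances,
        metabolites=mets,
    ).validate()
    return truth, net


def generate_expression(
    truth: SyntheticTruth, net: RegulatoryNetwork, cfg: GeneratorConfig
) -> ExpressionMatrix:
    """Expression = signed sum of regulator activities + Gaussian noise.

    The TF genes themselves are appended as pure-noise rows so that
    knockout metadata can reference a gene present in the matrix (TF
    activity, not TF expression, carries the signal).
    """
    _, _, _, rng, _, _ = cfg.rngs(6)
    genes = _ids("g", cfg.n_genes)
    tfs = list(truth.true_activity.index)
    conds = list(truth.true_activity.columns)

    signal = np.zeros((cfg.n_genes, cfg.n_conditions))
    gene_idx = {g: i for i, g in enumerate(genes)}
    act = truth.true_activity.to_numpy()
    tf_idx = {t: i for i, t in enumerate(tfs)}
    for _, row in net.edges.iterrows():
        if row["sign"] == 0 or row["target"] not in gene_idx:
            continue
        signal[gene_idx[row["target"]]] += row["sign"] * act[tf_idx[row["tf"]]]

    all_genes = genes + tfs
    values = np.vstack([signal, np.zeros((len(tfs), cfg.n_conditions))])
    values = values + rng.normal(
        0.0, cfg.noise_sd_expression, size=values.shape
    ) if cfg.noise_sd_expression > 0 else values

    ctrl = conds[0]
    meta = pd.DataFrame(
        {
            "strain": "synthetic",
            "perturbation": "none",
            "knocked_out_gene": "",
            "control_condition_id": "",
        },
        index=pd.Index(conds, name="condition"),
    )
    for cond, tf in truth.ko_map.items():
        meta.at[cond, "perturbation"] = f"ko:{tf}"
        meta.at[cond, "knocked_out_gene"] = tf
        meta.at[cond, "control_condition_id"] = ctrl

    expr = ExpressionMatrix(
        values=pd.DataFrame(values, index=all_genes, columns=conds),
        condition_meta=meta,
    )
    return expr.validate()


def generate_metabolome(
    truth: SyntheticTruth, cfg: GeneratorConfig
) -> MetaboliteAbundanceMatrix:
    """Positive abundances monotonically coupled to planted effector TFs.

    Noise enters the exponent, keeping abundances strictly positive and
    leaving the zero-noise Spearman correlation exactly +/-1.
    """
    _, _, _, _, rng, _ = cfg.rngs(6)
    conds = list(truth.true_activity.columns)
    coupling = {pc.metabolite: pc for pc in truth.planted_couplings}
    rows = np.empty((cfg.n_metabolites, cfg.n_conditions))
    for i, m in enumerate(truth.metabolites):
        eps = rng.normal(0.0, cfg.noise_sd_metabolite, size=cfg.n_conditions)
        if m in coupling:
            pc = coupling[m]
            base = pc.strength * truth.true_activity.loc[pc.tf].to_numpy()
            if pc.effect == "inactivating":
                base = -base
            rows[i] = np.exp(base + eps)
        else:
            rows[i] = np.exp(rng.standard_normal(cfg.n_conditions) + eps)
    values = pd.DataFrame(rows, index=truth.metabolites, columns=conds)
    return MetaboliteAbundanceMatrix(
        values=values,
        annotations={m: frozenset([m]) for m in truth.metabolites},
    ).validate()


def metabolite_masses(truth: SyntheticTruth) -> pd.Series:
    """Deterministic, well-separated monoisotopic masses (Da) per metabolite."""
    masses = {m: 120.0 + 1.5 * i for i, m in enumerate(truth.metabolites)}
    return pd.Series(masses, name="monoisotopic_mass")


def generate_ion_table(
    abundance: MetaboliteAbundanceMatrix,
    truth: SyntheticTruth,
    cfg: GeneratorConfig,
) -> tuple[IonTable, CompoundReference]:
    """Replicated negative-mode ion table realizing the abundance matrix.

    Each metabolite yields one [M-H]- ion; replicate intensities carry
    mild log-normal technical scatter and each injection column a random
    total-intensity scale factor that TIC normalization must remove.
    """
    _, _, _, _, _, rng = cfg.rngs(6)
    from .datamodel import PROTON_MASS

    masses = metabolite_masses(truth)
    conds = abundance.conditions
    col_scale = {
        (c, b, t): rng.uniform(0.5, 2.0)
        for c in conds
        for b in range(1, cfg.n_bio_reps + 1)
        for t in range(1, cfg.n_tech_reps + 1)
    }
    rows = []
    for m in abundance.metabolites:
        mz = masses[m] - PROTON_MASS
        for c in conds:
            base = abundance.values.at[m, c]
            for b in range(1, cfg.n_bio_reps + 1):
                for t in range(1, cfg.n_tech_reps + 1):
                    noise = math.exp(rng.normal(0.0, cfg.replicate_noise_sd))
                    rows.append(
                        {
                            "ion_id": f"ion_{m}",
                            "mz": mz,
                            "condition": c,
                            "bio_rep": b,
                            "tech_rep": t,
                            "intensity": base * noise * col_scale[(c, b, t)],
                        }
                    )
    table = IonTable(data=pd.DataFrame(rows)).validate()
    ref = CompoundReference(
        entries=pd.DataFrame(
            {
                "compound_id": abundance.metabolites,
                "monoisotopic_mass": [masses[m] for m in abundance.metabolites],
            }
        )
    ).validate()
    return table, ref


def _unshared_target(tf: str, net: RegulatoryNetwork) -> str:
    """A target gene of ``tf``, preferring one no other TF regulates."""
    targets = sorted(net.regulon(tf))
    counts = net.edges.groupby("target").size()
    for g in targets:
        if counts.get(g, 0) == 1:
            return g
    return targets[0]


def generate_toy_metabolic_model(
    truth: SyntheticTruth, net: RegulatoryNetwork, cfg: GeneratorConfig
) -> MetabolicModel:
    """Toy model realizing each planted (distance, position) class.

    Pathway auxiliaries are unique per planted pair so pathways never
    cross-link; ATP/ADP ride along on regulated reactions as cofactors and
    a hub metabolite participates in 51 reactions, so that both must be
    removed by graph filtering before the planted distances hold.
    """
    reactions: list[Reaction] = []
    compartments: dict[str, str] = {"atp_c": "c", "adp_c": "c"}

    def met(name: str) -> str:
        sid = f"{name}_c"
        compartments[sid] = "c"
        return sid

    for i, pc in enumerate(truth.planted_couplings):
        dist, position = truth.planted_distances[(pc.tf, pc.metabolite)]
        m = met(pc.metabolite)
        gene = _unshared_target(pc.tf, net)
        aux = lambda j: met(f"aux{i}x{j}")  # noqa: E731 - tiny local factory
        orf = lambda j: f"orf{i}x{j}"  # noqa: E731
        if dist == 0 and position == "upstream":
            reactions.append(
                Reaction(
                    id=f"R{i}a",
                    substrates=(m, "atp_c"),
                    products=(aux(1), "adp_c"),
                    genes=frozenset({gene}),
                )
            )
        elif dist == 0 and position == "downstream":
            reactions.append(
                Reaction(
                    id=f"R{i}a",
                    substrates=(aux(1), "atp_c"),
                    products=(m, "adp_c"),
                    genes=frozenset({gene}),
                )
            )
        elif dist == 0 and position == "within":
            reactions.append(
                Reaction(
                    id=f"R{i}a",
                    substrates=(aux(1), "atp_c"),
                    products=(m, "adp_c"),
                    genes=frozenset({gene}),
                )
            )
            reactions.append(
                Reaction(
                    id=f"R{i}b",
                    substrates=(m,),
                    products=(aux(2),),
                    genes=frozenset({gene}),
                )
            )
        else:
            # chain of `dist` unregulated reactions before the regulated one
            prev = m
            for j in range(dist):
                nxt = aux(j + 1)
                reactions.append(
                    Reaction(
                        id=f"R{i}u{j}",
                        substrates=(prev,),
                        products=(nxt,),
                        genes=frozenset({orf(j)}),
                    )
                )
                prev = nxt
            reactions.append(
                Reaction(
                    id=f"R{i}a",
                    substrates=(prev, "atp_c"),
                    products=(aux(dist + 1), "adp_c"),
                    genes=frozenset({gene}),
                )
            )

    # hub metabolite in 51 reactions (> the default degree cutoff of 50)
    hub = met("hub")
    for k in range(51):
        reactions.append(
            Reaction(
                id=f"Rhub{k}",
                substrates=(hub,),
                products=(met(f"hubaux{k}"),),
                genes=frozenset({f"orfhub{k}"}),
            )
        )
    # one extracellular species plus its transport, to exercise the
    # intracellular-only filter
    compartments["ext1_e"] = "e"
    reactions.append(
        Reaction(
            id="Rtransport",
            substrates=("ext1_e",),
            products=(met("extprod"),),
            genes=frozenset({"orftrans"}),
        )
    )
    return MetabolicModel(reactions=reactions, compartments=compartments).validate()


@dataclass
class SyntheticBundle:
    """A consistent, fully seeded set of pipeline inputs plus the truth."""

    cfg: GeneratorConfig
    truth: SyntheticTruth
    network: RegulatoryNetwork
    expression: ExpressionMatrix
    metabolome: MetaboliteAbundanceMatrix
    ion_table: IonTable
    compound_reference: CompoundReference
    model: MetabolicModel
    known: KnownInteractionSet

    def planted_pairs(self, effect: str | None = None) -> set[tuple[str, str]]:
        return {
            (pc.tf, pc.metabolite)
            for pc in self.truth.planted_couplings
            if effect is None or pc.effect == effect
        }

    def save(self, outdir) -> dict[str, Path]:
        """Serialize every component as TSV/SBML/JSON under ``outdir``."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "expression": outdir / "expression.tsv",
            "condition_meta": outdir / "condition_meta.tsv",
            "network": outdir / "network.tsv",
            "metabolome": outdir / "metabolome.tsv",
            "ion_table": outdir / "ion_table.tsv",
            "compound_reference": outdir / "compound_reference.tsv",
            "model_json": outdir / "model.json",
            "model_sbml": outdir / "model.xml",
            "known": outdir / "known_interactions.tsv",
            "truth_activity": outdir / "true_activity.tsv",
            "truth_couplings": outdir / "planted_couplings.tsv",
        }
        tio.write_expression_matrix(
            self.expression, paths["expression"], paths["condition_meta"]
        )
        tio.write_regulatory_network(self.network, paths["network"])
        tio.write_abundance_matrix(self.metabolome, paths["metabolome"])
        tio.write_ion_table(self.ion_table, paths["ion_table"])
        tio.write_compound_reference(self.compound_reference, paths["compound_reference"])
        tio.write_metabolic_model_json(self.model, paths["model_json"])
        tio.write_metabolic_model_sbml(self.model, paths["model_sbml"])
        tio.write_known_interactions(self.known, paths["known"])
        self.truth.true_activity.to_csv(paths["truth_activity"], sep="\t", index_label="tf")
        pd.DataFrame(
            [
                {
                    "tf": pc.tf,
                    "metabolite": pc.metabolite,
                    "effect": pc.effect,
                    "strength": pc.strength,
                    "distance": self.truth.planted_distances[(pc.tf, pc.metabolite)][0],
                    "position": self.truth.planted_distances[(pc.tf, pc.metabolite)][1],
                }
                for pc in self.truth.planted_couplings
            ]
        ).to_csv(paths["truth_couplings"], sep="\t", index=False)
        return paths


def generate_dataset(cfg: GeneratorConfig | None = None) -> SyntheticBundle:
    """Generate the full, mutually consistent input bundle.

    The known-interaction table exposes only a ``known_fraction`` of the
    planted couplings; the remainder are the "novel" interactions the
    pipeline is expected to discover.
    """
    cfg = (cfg or GeneratorConfig()).validate()
    truth, net = generate_truth(cfg)
    expr = generate_expression(truth, net, cfg)
    metabolome = generate_metabolome(truth, cfg)
    ions, ref = generate_ion_table(metabolome, truth, cfg)
    model = generate_toy_metabolic_model(truth, net, cfg)

    n_known = int(round(cfg.known_fraction * len(truth.planted_couplings)))
    known_entries = [
        {"tf": pc.tf, "metabolite": pc.metabolite, "effect": pc.effect}
        for pc in truth.planted_couplings[:n_known]
    ]
    known = KnownInteractionSet(
        entries=pd.DataFrame(known_entries, columns=["tf", "metabolite", "effect"])
    ).validate()

    return SyntheticBundle(
        cfg=cfg,
        truth=truth,
        network=net,
        expression=expr,
        metabolome=metabolome,
        ion_table=ions,
        compound_reference=ref,
        model=model,
        known=known,
    )
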