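"""Synthetic interactomes, drug libraries, annotations, and screen outcomes.

Every pipeline stage is testable without external downloads: the generator
emulates the statistical structure the analysis assumes — a heavy-tailed
evidence-scored interactome, drugs whose targets are biased toward
well-connected proteins, phenotype/gene-set annotations enriched around a
planted signal, and screen outcomes driven by a linear effect of planted
genes' network membership plus noise. Planted ground truth makes parameter
recovery and consensus recovery measurable.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .io_formats import (
    DrugTargetMap,
    GeneSetCollection,
    Interactome,
    PhenotypeCatalog,
    ScreenTable,
)
from .pathfx import DrugNetwork, build_drug_network

import pandas as pd

# sub-stream ids so each generator stage has an independent, reproducible rng
_STAGE = {"interactome": 1, "drugs": 2, "annotations": 3, "plant": 4, "screen": 5}


def _rng(seed: int, stage: str, extra: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed % (2**31), _STAGE[stage], extra]))


@dataclass
class SyntheticScenario:
    """Parameters of one synthetic study.

    Defaults describe the scale the pipeline is exercised at: a 500-gene
    preferential-attachment interactome (m=2), Beta(2,2) edge evidence
    rescaled into (0.05, 1], 200 drugs with Poisson(2, min 1) targets drawn
    degree-proportionally, planted effects of magnitude 0.5 and outcome
    noise sd 0.05.
    """

    seed: int = 0
    n_genes: int = 500
    attachment: int = 2  # preferential-attachment edges per new node
    edge_beta_a: float = 2.0
    edge_beta_b: float = 2.0
    score_floor: float = 0.05
    n_drugs: int = 200
    targets_lambda: float = 2.0
    n_phenotypes: int = 20
    genes_per_phenotype: int = 15
    n_terms: int = 30
    genes_per_term: int = 12
    n_planted_favorable: int = 8
    n_planted_unfavorable: int = 8
    planted_target_prevalence: float = 0.3  # P(a drug gains a planted gene as target)
    effect_size: float = 0.5
    noise_sd: float = 0.05
    or_scale: float = 0.1  # log-odds-ratio per unit of linear predictor
    phenotype_enrichment: float = 0.4  # fraction of one phenotype drawn from planted genes
    planted_term_fraction: float = 0.8  # fraction of each planted term drawn from its planted set
    max_depth: int = 1  # network radius; keeps networks sparse at this interactome size
    selection_bound: float = 0.125  # |coefficient| cutoff bracketing the shrunk planted effect
    planted_favorable: tuple[str, ...] | None = None
    planted_unfavorable: tuple[str, ...] | None = None

    def __post_init__(self):
        for name in ("n_genes", "n_drugs", "n_phenotypes", "n_terms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.planted_favorable and self.planted_unfavorable:
            if set(self.planted_favorable) & set(self.planted_unfavorable):
                raise ValueError("planted favorable and unfavorable sets overlap")

    @property
    def n_planted(self) -> int:
        return self.n_planted_favorable + self.n_planted_unfavorable

    def screen_selection_bound(self, kind: str) -> float:
        """|coefficient| bound bracketing the planted effect on a screen's scale.

        Odds-ratio screens report exp(or_scale * eta), so the planted
        per-gene slope on the ratio scale is about or_scale * effect_size;
        the exponential compresses it further under ridge shrinkage, so the
        bound sits at half that nominal slope rather than the quarter used
        on the linear scale.
        """
        if kind == "odds_ratio":
            return self.or_scale * self.effect_size / 2
        return self.selection_bound


@dataclass
class GroundTruth:
    """What was planted, per-screen conventions, and the expected consensus."""

    planted_effects: dict[str, float]  # gene -> beta on the favorable axis
    favorable_sign: dict[str, int]  # screen -> +1 / -1
    expected_favorable: set[str] = field(default_factory=set)
    expected_unfavorable: set[str] = field(default_factory=set)


def _gene_name(i: int, width: int) -> str:
    return f"G{i:0{width}d}"


def _reserved_gene_names(scenario: SyntheticScenario) -> list[str]:
    """Names of the genes reserved for planted effects (the last indices)."""
    width = len(str(scenario.n_genes))
    start = scenario.n_genes - scenario.n_planted
    return [_gene_name(i + 1, width) for i in range(start, scenario.n_genes)]


def generate_interactome(scenario: SyntheticScenario) -> Interactome:
    """Connected, heavy-tailed-degree interactome with Beta-distributed evidence.

    Unless the scenario names planted genes explicitly, the last
    ``n_planted`` gene indices are reserved as planted-effect slots: each is
    attached to the single highest-degree hub of the preferential-attachment
    core by one floor-score edge. The hub sits in nearly every drug network
    anyway, so its membership column is near-constant, and a reserved gene
    enters a network (at radius 1) essentially only when it is itself a
    target — the regime in which a planted effect on its membership is
    identifiable rather than split across correlated neighbor columns.
    """
    if scenario.n_genes < 10:
        raise ValueError("need at least 10 genes")
    explicit = scenario.planted_favorable is not None and scenario.planted_unfavorable is not None
    n_reserved = 0 if explicit else scenario.n_planted
    n_core = scenario.n_genes - n_reserved
    m = scenario.attachment
    if m < 1 or m >= n_core or n_core < 10:
        raise ValueError("attachment parameter cannot build a connected graph")
    rng = _rng(scenario.seed, "interactome")
    ba_seed = int(rng.integers(0, 2**31))
    g0 = nx.barabasi_albert_graph(n_core, m, seed=ba_seed)
    width = len(str(scenario.n_genes))
    mapping = {i: _gene_name(i + 1, width) for i in g0.nodes}
    g = nx.relabel_nodes(g0, mapping)
    floor = scenario.score_floor
    for u, v in sorted(g.edges()):
        x = rng.beta(scenario.edge_beta_a, scenario.edge_beta_b)
        g.edges[u, v]["score"] = floor + (1 - floor) * x
    if n_reserved:
        hub = max(sorted(g.nodes), key=lambda n: g.degree[n])
        for name in _reserved_gene_names(scenario):
            g.add_edge(name, hub, score=floor * 1.001)
    return Interactome(g)


def generate_drug_library(scenario: SyntheticScenario, interactome: Interactome) -> DrugTargetMap:
    """Drugs with >=1 target sampled degree-proportionally; ids DB90001...

    When the scenario carries planted gene sets, each planted gene is
    additionally wired as a target of an independent random fraction of
    drugs (``planted_target_prevalence``). That gives every planted gene's
    network-membership column variance of its own, so the planted effect is
    identifiable instead of being absorbed by correlated hub-neighborhood
    columns.
    """
    rng = _rng(scenario.seed, "drugs")
    nodes = sorted(interactome.nodes)
    degrees = np.array([interactome.graph.degree[n] for n in nodes], dtype=float)
    probs = degrees / degrees.sum()
    planted = list(scenario.planted_favorable or ()) + list(scenario.planted_unfavorable or ())
    entries: dict[str, list[str]] = {}
    vocab: dict[str, str] = {}
    for i in range(scenario.n_drugs):
        drug_id = f"DB{90001 + i:05d}"
        k = max(1, int(rng.poisson(scenario.targets_lambda)))
        k = min(k, len(nodes))
        targets = set(rng.choice(nodes, size=k, replace=False, p=probs))
        for g in planted:
            if rng.random() < scenario.planted_target_prevalence:
                targets.add(g)
        entries[drug_id] = sorted(targets)
        vocab[f"SYNDRUG{i + 1}"] = drug_id
    return DrugTargetMap(entries=entries, vocabulary=vocab)


def build_library_networks(
    scenario: SyntheticScenario, interactome: Interactome, library: DrugTargetMap
) -> list[DrugNetwork]:
    """Predicted network for every drug in the synthetic library."""
    return [
        build_drug_network(interactome, drug_id, targets, max_depth=scenario.max_depth)
        for drug_id, targets in sorted(library.entries.items())
    ]


def plant_genes(
    scenario: SyntheticScenario, interactome: Interactome
) -> SyntheticScenario:
    """Assign the reserved planted-effect genes to favorable/unfavorable sets.

    The reserved genes (see :func:`generate_interactome`) are randomly
    partitioned into the favorable and unfavorable directions. Because each
    reserved gene hangs off the main hub by a single floor-score edge, its
    network-membership column is close to an independent Bernoulli draw once
    :func:`generate_drug_library` wires it as a target of a random drug
    subset — the identifiable regime. Returns a scenario copy with the
    planted sets filled in; explicit planted sets are kept as given.
    """
    if scenario.planted_favorable is not None and scenario.planted_unfavorable is not None:
        return scenario
    reserved = _reserved_gene_names(scenario)
    missing = [g for g in reserved if g not in interactome.nodes]
    if missing:
        raise ValueError(f"reserved planted genes absent from interactome: {missing}")
    rng = _rng(scenario.seed, "plant")
    chosen = [str(g) for g in rng.permutation(reserved)]
    fav = tuple(sorted(chosen[: scenario.n_planted_favorable]))
    unfav = tuple(sorted(chosen[scenario.n_planted_favorable :]))
    return dataclasses.replace(scenario, planted_favorable=fav, planted_unfavorable=unfav)


def weaken_planted_edges(scenario: SyntheticScenario, interactome: Interactome) -> None:
    """Drop evidence on edges incident to planted genes to the score floor.

    Weak incident evidence keeps planted genes out of other drugs' networks
    (path products through them fall below the empirical threshold), so a
    planted gene's membership column reflects its independent target wiring
    rather than its hub neighborhood — the regime where the planted effect
    is recoverable. Mutates the interactome in place.
    """
    planted = set(scenario.planted_favorable or ()) | set(scenario.planted_unfavorable or ())
    g = interactome.graph
    weak = scenario.score_floor * 1.001
    for gene in planted:
        for nb in g.neighbors(gene):
            g.edges[gene, nb]["score"] = weak


def generate_annotations(
    scenario: SyntheticScenario, interactome: Interactome
) -> tuple[PhenotypeCatalog, GeneSetCollection]:
    """Phenotype catalog and gene-set library enriched around the planted genes.

    One phenotype and one GMT term per planted direction concentrate on the
    planted genes (term overlap fraction = ``planted_term_fraction``), so
    enrichment-recovery is measurable; the rest are uniform draws.
    """
    if scenario.planted_favorable is None or scenario.planted_unfavorable is None:
        raise ValueError("planted gene sets must be set (see plant_genes) before annotating")
    rng = _rng(scenario.seed, "annotations")
    genes = sorted(interactome.nodes)
    if scenario.genes_per_phenotype > len(genes) or scenario.genes_per_term > len(genes):
        raise ValueError("requested set sizes exceed the gene pool")
    planted = {
        "favorable": list(scenario.planted_favorable),
        "unfavorable": list(scenario.planted_unfavorable),
    }

    def enriched_set(core: list[str], size: int, core_fraction: float) -> set[str]:
        n_core = min(len(core), max(1, int(round(core_fraction * size))))
        picked = set(rng.choice(sorted(core), size=n_core, replace=False))
        rest = [g for g in genes if g not in picked]
        picked |= set(rng.choice(rest, size=size - len(picked), replace=False))
        return picked

    phenotypes: dict[str, set[str]] = {}
    for direction in ("favorable", "unfavorable"):
        phenotypes[f"planted {direction} phenotype"] = enriched_set(
            planted[direction], scenario.genes_per_phenotype, scenario.phenotype_enrichment
        )
    for i in range(scenario.n_phenotypes - 2):
        phenotypes[f"phenotype {i + 1:02d}"] = set(
            rng.choice(genes, size=scenario.genes_per_phenotype, replace=False)
        )

    terms: dict[str, tuple[str, set[str]]] = {}
    for j, direction in enumerate(("favorable", "unfavorable")):
        terms[f"SYN:{j + 1:04d}"] = (
            f"planted {direction} term",
            enriched_set(planted[direction], scenario.genes_per_term, scenario.planted_term_fraction),
        )
    for i in range(scenario.n_terms - 2):
        terms[f"SYN:{i + 3:04d}"] = (
            f"background term {i + 1}",
            set(rng.choice(genes, size=scenario.genes_per_term, replace=False)),
        )
    return PhenotypeCatalog(entries=phenotypes), GeneSetCollection(terms=terms)


def generate_screen_outcomes(
    scenario: SyntheticScenario,
    networks: list[DrugNetwork],
    screen_kind: str = "continuous",
    screen_name: str = "synthetic",
    favorable_sign: int = 1,
    stage_extra: int = 0,
) -> tuple[ScreenTable, GroundTruth]:
    """Outcomes from a linear effect of planted network membership.

    The linear predictor is eta(d) = sum_g beta_g * 1[g in network(d)] with
    beta_g = favorable_sign * effect_size for planted favorable genes and the
    opposite sign for unfavorable ones. Continuous screens add Normal(0, sd)
    noise; odds-ratio screens report exp(or_scale * (eta + noise)), a
    positive ratio near 1 whose log responds linearly to the planted effect;
    binary screens draw Bernoulli(logistic(eta)).
    """
    if scenario.planted_favorable is None or scenario.planted_unfavorable is None:
        raise ValueError("planted gene sets must be set before generating outcomes")
    if favorable_sign not in (1, -1):
        raise ValueError("favorable_sign must be +1 or -1")
    beta: dict[str, float] = {}
    for g in scenario.planted_favorable:
        beta[g] = favorable_sign * scenario.effect_size
    for g in scenario.planted_unfavorable:
        beta[g] = -favorable_sign * scenario.effect_size
    if not any(g in net.genes for net in networks for g in beta):
        raise ValueError("no planted gene appears in any network: unidentifiable scenario")
    rng = _rng(scenario.seed, "screen", stage_extra)
    ids, values = [], []
    for net in networks:
        eta = sum(b for g, b in beta.items() if g in net.genes)
        if screen_kind == "continuous":
            y = eta + rng.normal(0.0, scenario.noise_sd)
        elif screen_kind == "odds_ratio":
            y = float(np.exp(scenario.or_scale * (eta + rng.normal(0.0, scenario.noise_sd))))
        elif screen_kind == "binary":
            y = float(rng.random() < 1.0 / (1.0 + np.exp(-eta)))
        else:
            raise ValueError(f"unknown screen kind {screen_kind!r}")
        ids.append(net.drug_id)
        values.append(y)
    table = ScreenTable(
        screen_name=screen_name,
        outcome_type="binary" if screen_kind == "binary" else "continuous",
        favorable_sign=favorable_sign,
        outcomes=pd.Series(values, index=pd.Index(ids, name="drug"), name="outcome"),
    )
    truth = GroundTruth(
        planted_effects=beta,
        favorable_sign={screen_name: favorable_sign},
        expected_favorable=set(scenario.planted_favorable),
        expected_unfavorable=set(scenario.planted_unfavorable),
    )
    return table, truth


#: Screen layout of three-screen mode: name -> (kind, favorable_sign).
THREE_SCREENS: dict[str, tuple[str, int]] = {
    "in_silico": ("continuous", -1),
    "zebrafish": ("continuous", 1),
    "clinical": ("odds_ratio", 1),
}


@dataclass
class SyntheticDataset:
    """Everything one scenario generates, ready for the pipeline."""

    scenario: SyntheticScenario  # with planted sets filled in
    interactome: Interactome
    library: DrugTargetMap
    networks: list[DrugNetwork]
    catalog: PhenotypeCatalog
    gene_sets: GeneSetCollection
    screens: dict[str, ScreenTable]
    truth: GroundTruth


def generate_dataset(
    scenario: SyntheticScenario,
    screens: dict[str, tuple[str, int]] | None = None,
) -> SyntheticDataset:
    """Run the full generator: interactome, drugs, networks, annotations, screens.

    ``screens`` maps screen name -> (kind, favorable_sign); default is the
    three-screen layout sharing one planted favorable set with an inverted
    sign convention for the in-silico-like screen.
    """
    if screens is None:
        screens = THREE_SCREENS
    interactome = generate_interactome(scenario)
    scenario = plant_genes(scenario, interactome)
    weaken_planted_edges(scenario, interactome)
    library = generate_drug_library(scenario, interactome)
    networks = build_library_networks(scenario, interactome, library)
    catalog, gene_sets = generate_annotations(scenario, interactome)
    tables: dict[str, ScreenTable] = {}
    signs: dict[str, int] = {}
    for extra, (name, (kind, sign)) in enumerate(sorted(screens.items())):
        table, _ = generate_screen_outcomes(
            scenario, networks, screen_kind=kind, screen_name=name, favorable_sign=sign, stage_extra=extra + 1
        )
        tables[name] = table
        signs[name] = sign
    truth = GroundTruth(
        planted_effects={
            **{g: scenario.effect_size for g in scenario.planted_favorable},
            **{g: -scenario.effect_size for g in scenario.planted_unfavorable},
        },
        favorable_sign=signs,
        expected_favorable=set(scenario.planted_favorable),
        expected_unfavorable=set(scenario.planted_unfavorable),
    )
    return SyntheticDataset(
        scenario=scenario,
        interactome=interactome,
        library=library,
        networks=networks,
        catalog=catalog,
        gene_sets=gene_sets,
        screens=tables,
        truth=truth,
    )
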