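"""Per-drug pathway network prediction and phenotype association.

A drug's network is grown from its protein targets over the evidence-scored
interactome: every gene within ``max_depth`` edges of a target receives a
score equal to the best path-product of edge evidence connecting it to a
target (targets score 1.0). An empirical threshold search then keeps the
edge-score cutoff that maximizes the number of downstream proteins scoring
above the mean score of the candidate neighborhood, which differentiates
target neighborhoods instead of simply growing them. Phenotype association
uses a one-sided Fisher exact test against the interactome universe, a
randomized-network null (random target sets of the same size), and
Benjamini–Hochberg correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import Interactome, PhenotypeCatalog
from .stats import bh_adjust, fisher_enrichment_p

logger = logging.getLogger(__name__)


class DrugNotConnectedError(ValueError):
    """No target of the drug is present in the interactome."""


@dataclass
class NodeScoreMap:
    """Evidence scores for genes reachable from a drug's targets."""

    drug_id: str
    max_depth: int
    scores: dict[str, float]  # gene -> score in (0, 1]; targets exactly 1.0
    provenance: dict[str, str]  # gene -> "target" | "downstream"

    @property
    def targets(self) -> set[str]:
        return {g for g, p in self.provenance.items() if p == "target"}

    @property
    def downstream(self) -> dict[str, float]:
        return {g: s for g, s in self.scores.items() if self.provenance[g] == "downstream"}


@dataclass
class DrugNetwork:
    """Targets plus downstream proteins retained by the threshold search."""

    drug_id: str
    targets: frozenset[str]
    downstream_scores: dict[str, float]  # retained downstream genes only
    threshold: float
    edges: list[tuple[str, str, float]] = field(default_factory=list)

    @property
    def genes(self) -> set[str]:
        return set(self.targets) | set(self.downstream_scores)


def compute_node_scores(
    interactome: Interactome,
    targets: list[str],
    max_depth: int = 2,
    drug_id: str = "",
) -> NodeScoreMap:
    """Score every gene within ``max_depth`` edges of a target.

    score(v) = max over simple paths of length <= max_depth from any target
    to v of the product of edge evidence scores along the path. Targets are
    pinned at 1.0. Targets absent from the interactome are dropped with a
    warning; if none remain a :class:`DrugNotConnectedError` is raised.
    """
    g = interactome.graph
    present = [t.upper() for t in targets if t.upper() in g]
    dropped = set(t.upper() for t in targets) - set(present)
    if dropped:
        logger.warning("drug %s: targets %s absent from interactome", drug_id, sorted(dropped))
    if not present:
        raise DrugNotConnectedError(f"drug {drug_id or '<unnamed>'}: no target in interactome")

    target_set = set(present)
    best: dict[str, float] = {t: 1.0 for t in target_set}

    # bounded DFS over simple paths; max_depth is small (default 2)
    def visit(node: str, product: float, depth: int, on_path: set[str]) -> None:
        if depth == max_depth:
            return
        for nbr in g.neighbors(node):
            if nbr in on_path:
                continue
            p = product * g.edges[node, nbr]["score"]
            if nbr not in target_set and p > best.get(nbr, 0.0):
                best[nbr] = p
            # continue even if not improved: a deeper extension may still win
            on_path.add(nbr)
            visit(nbr, p, depth + 1, on_path)
            on_path.discard(nbr)

    for t in target_set:
        visit(t, 1.0, 0, {t})

    provenance = {gene: ("target" if gene in target_set else "downstream") for gene in best}
    return NodeScoreMap(drug_id=drug_id, max_depth=max_depth, scores=best, provenance=provenance)


def select_threshold(node_scores: NodeScoreMap, interactome: Interactome | None = None) -> tuple[float, DrugNetwork]:
    """Empirical threshold search over candidate edge-score cutoffs.

    Candidates are the unique downstream scores. For each cutoff t the
    candidate network keeps downstream genes scoring >= t; the objective is
    the number of kept downstream genes scoring strictly above the mean
    downstream score of that candidate network. Ties break toward the
    largest cutoff (the sparsest network). With no downstream candidates the
    network is targets-only with threshold 1.0.
    """
    downstream = node_scores.downstream
    targets = frozenset(node_scores.targets)
    if not downstream:
        net = DrugNetwork(node_scores.drug_id, targets, {}, 1.0)
        _induce_edges(net, interactome)
        return 1.0, net

    values = np.array(sorted(downstream.values()))
    candidates = np.unique(values)
    best_theta, best_obj = None, -1
    for theta in candidates:  # ascending; >= keeps later ties at larger theta
        kept = values[values >= theta]
        mu = kept.mean()
        obj = int((kept > mu).sum())
        if obj >= best_obj:  # >= so ties prefer the largest theta
            best_obj, best_theta = obj, float(theta)
    retained = {g: s for g, s in downstream.items() if s >= best_theta}
    net = DrugNetwork(node_scores.drug_id, targets, retained, best_theta)
    _induce_edges(net, interactome)
    return best_theta, net


def _induce_edges(net: DrugNetwork, interactome: Interactome | None) -> None:
    if interactome is None:
        return
    g = interactome.graph
    genes = sorted(net.genes)
    present = [x for x in genes if x in g]
    seen = set()
    for u in present:
        for v in g.neighbors(u):
            if v in net.genes and (v, u) not in seen:
                seen.add((u, v))
                net.edges.append((u, v, g.edges[u, v]["score"]))


def build_drug_network(
    interactome: Interactome,
    drug_id: str,
    targets: list[str],
    max_depth: int = 2,
) -> DrugNetwork:
    """Compose node scoring and threshold selection; deterministic."""
    nsm = compute_node_scores(interactome, targets, max_depth=max_depth, drug_id=drug_id)
    _, network = select_threshold(nsm, interactome)
    return network


def associate_phenotypes(
    network: DrugNetwork,
    catalog: PhenotypeCatalog,
    universe: set[str],
) -> pd.DataFrame:
    """One Fisher enrichment row per phenotype with annotated genes in the universe.

    The universe is the full interactome gene set; the 2x2 table counts
    network membership against phenotype annotation within it.
    """
    net_genes = network.genes & universe
    rows = []
    for phenotype in sorted(catalog.entries):
        annotated = catalog.entries[phenotype] & universe
        if not annotated:
            logger.warning("phenotype %r has no genes in universe; skipped", phenotype)
            continue
        overlap = sorted(net_genes & annotated)
        a = len(overlap)
        b = len(net_genes) - a
        c = len(annotated) - a
        d = len(universe) - a - b - c
        p = fisher_enrichment_p(a, b, c, d)
        rows.append(
            {
                "drug_id": network.drug_id,
                "phenotype": phenotype,
                "overlap": tuple(overlap),
                "a": a,
                "b": b,
                "c": c,
                "d": d,
                "p_value": p,
            }
        )
    return pd.DataFrame(
        rows, columns=["drug_id", "phenotype", "overlap", "a", "b", "c", "d", "p_value"]
    )


class RandomNetworkNull:
    """Null distribution of phenotype p-values from random drug networks.

    Draws target sets of a given size uniformly without replacement from an
    eligible gene pool (target-like genes when a drug-target map is
    available, otherwise all interactome genes), rebuilds the network —
    including the threshold search — and re-runs the phenotype association.
    Medians are cached per target-set size so drugs with equally many
    targets share one null ensemble.
    """

    def __init__(
        self,
        interactome: Interactome,
        catalog: PhenotypeCatalog,
        n_iter: int = 100,
        seed: int = 0,
        target_pool: set[str] | None = None,
        max_depth: int = 2,
    ):
        self.interactome = interactome
        self.catalog = catalog
        self.n_iter = n_iter
        self.seed = seed
        self.max_depth = max_depth
        pool = target_pool if target_pool else interactome.nodes
        self.pool = sorted(pool & interactome.nodes)
        self._universe = interactome.nodes
        self._cache: dict[int, pd.Series] = {}

    def median_p(self, n_targets: int) -> pd.Series:
        """Per-phenotype median null p-value for random networks of this size."""
        if n_targets < 1:
            raise ValueError("n_targets must be >= 1")
        if n_targets > len(self.pool):
            raise ValueError(f"n_targets={n_targets} exceeds pool size {len(self.pool)}")
        if n_targets in self._cache:
            return self._cache[n_targets]
        rng = np.random.default_rng((self.seed + n_targets) % (2**31))
        phenos = sorted(self.catalog.entries)
        pvals = np.ones((self.n_iter, len(phenos)))  # missing rows impute p=1
        idx = {ph: j for j, ph in enumerate(phenos)}
        for i in range(self.n_iter):
            targets = list(rng.choice(self.pool, size=n_targets, replace=False))
            net = build_drug_network(self.interactome, f"NULL{i}", targets, self.max_depth)
            table = associate_phenotypes(net, self.catalog, self._universe)
            for ph, p in zip(table["phenotype"], table["p_value"]):
                pvals[i, idx[ph]] = p
        medians = pd.Series(np.median(pvals, axis=0), index=phenos)
        self._cache[n_targets] = medians
        return medians


def null_filter(
    association_table: pd.DataFrame,
    interactome: Interactome,
    catalog: PhenotypeCatalog,
    n_targets: int,
    n_iter: int = 100,
    seed: int = 0,
    target_pool: set[str] | None = None,
    max_depth: int = 2,
    null_model: RandomNetworkNull | None = None,
) -> pd.DataFrame:
    """Retain associations more significant than the random-network null median.

    An association is kept only if its p-value is strictly smaller than the
    median p-value of the same phenotype across ``n_iter`` random drug
    networks built from target sets of the same size. Phenotypes the null
    never produced count as p = 1.
    """
    if null_model is None:
        null_model = RandomNetworkNull(
            interactome, catalog, n_iter=n_iter, seed=seed, target_pool=target_pool, max_depth=max_depth
        )
    medians = null_model.median_p(n_targets)
    out = association_table.copy()
    out["null_median_p"] = out["phenotype"].map(medians).fillna(1.0)
    out["retained"] = out["p_value"] < out["null_median_p"]
    return out


def bh_filter(association_table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """BH-adjust p-values of null-retained rows and keep those <= alpha."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    out = association_table.copy()
    out["adjusted_p"] = np.nan
    mask = out["retained"].to_numpy(dtype=bool)
    if mask.any():
        out.loc[mask, "adjusted_p"] = bh_adjust(out.loc[mask, "p_value"].to_numpy())
        out["retained"] = mask & (out["adjusted_p"].to_numpy() <= alpha)
    return out


def summarize_predictions(
    tables: dict[str, pd.DataFrame],
    labels: set[str] | frozenset[str] | None = None,
) -> dict:
    """Counts over retained drug–phenotype associations.

    Returns drugs per phenotype, the total number of drug–phenotype pairs,
    and network genes ranked by how many retained (drug, phenotype) overlap
    rows they support.
    """
    pheno_drugs: dict[str, set[str]] = {}
    gene_counts: dict[str, int] = {}
    total_pairs = 0
    for drug_id, table in tables.items():
        if table.empty:
            continue
        kept = table[table["retained"]]
        if labels is not None:
            kept = kept[kept["phenotype"].isin(labels)]
        for _, row in kept.iterrows():
            total_pairs += 1
            pheno_drugs.setdefault(row["phenotype"], set()).add(drug_id)
            for gene in row["overlap"]:
                gene_counts[gene] = gene_counts.get(gene, 0) + 1
    drugs_per_phenotype = pd.Series(
        {ph: len(ds) for ph, ds in pheno_drugs.items()}, dtype=int
    ).sort_index()
    gene_ranking = pd.Series(gene_counts, dtype=int).sort_values(ascending=False)
    unique_drugs = set().union(*pheno_drugs.values()) if pheno_drugs else set()
    return {
        "drugs_per_phenotype": drugs_per_phenotype,
        "total_pairs": total_pairs,
        "n_unique_drugs": len(unique_drugs),
        "gene_ranking": gene_ranking,
    }


def write_network_files(
    network: DrugNetwork,
    association_table: pd.DataFrame | None,
    outdir: str | Path,
) -> tuple[Path, Path]:
    """Write the two tab-delimited files a graph viewer can import.

    ``<drug>_merged_neighborhood__withDrugTargsAndPhens.txt`` holds edge rows
    (gene, gene, score) and, when an association table is given, retained
    phenotype rows (gene, phenotype, adjusted p). ``<drug>_network_nodeType.txt``
    labels each node as drug, target, downstream, or phenotype.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    merged = outdir / f"{network.drug_id}_merged_neighborhood__withDrugTargsAndPhens.txt"
    node_type = outdir / f"{network.drug_id}_network_nodeType.txt"
    with open(merged, "w", encoding="utf-8") as fh:
        fh.write("source\ttarget\tscore_or_p\tedge_type\n")
        for t in sorted(network.targets):
            fh.write(f"{network.drug_id}\t{t}\t1.0\tdrug_target\n")
        for u, v, s in sorted(network.edges):
            fh.write(f"{u}\t{v}\t{s:.6g}\tinteraction\n")
        if association_table is not None:
            kept = association_table[association_table["retained"]]
            for _, row in kept.iterrows():
                p = row.get("adjusted_p", row["p_value"])
                for gene in row["overlap"]:
                    fh.write(f"{gene}\t{row['phenotype']}\t{p:.6g}\tphenotype\n")
    with open(node_type, "w", encoding="utf-8") as fh:
        fh.write("node\ttype\n")
        fh.write(f"{network.drug_id}\tdrug\n")
        for t in sorted(network.targets):
            fh.write(f"{t}\ttarget\n")
        for g in sorted(network.downstream_scores):
            fh.write(f"{g}\tdownstream\n")
        if association_table is not None:
            kept = association_table[association_table["retained"]]
            for ph in sorted(set(kept["phenotype"])):
                fh.write(f"{ph}\tphenotype\n")
    return merged, node_type
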