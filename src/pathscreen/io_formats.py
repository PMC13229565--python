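"""Readers, writers, and normalization for every external table the pipeline touches.

All gene symbols and drug names are uppercased before any comparison.
TSV/CSV files are UTF-8; lines starting with ``#`` are ignored as comments.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

DRUG_ID_RE = re.compile(r"^DB\d{5}$")

#: Disease labels tracked as psychiatric by default.
PSYCHIATRIC_LABELS = frozenset(
    {
        "schizophrenia",
        "paranoid schizophrenia",
        "bipolar disorder",
        "unipolar depression",
        "major depressive disorder",
    }
)


class ValidationError(ValueError):
    """Raised when an input file violates a format contract."""


@dataclass(frozen=True)
class Interactome:
    """Undirected evidence-scored gene graph.

    Edge evidence scores lie in (0, 1] and aggregate published experimental
    support for each protein–protein interaction. Duplicate unordered pairs
    are collapsed to the maximum score; self-loops are rejected.
    """

    graph: nx.Graph

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_score(self, u: str, v: str) -> float:
        return self.graph.edges[u, v]["score"]

    def edges(self) -> Iterable[tuple[str, str, float]]:
        for u, v, d in self.graph.edges(data=True):
            yield u, v, d["score"]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Interactome):
            return NotImplemented
        if self.nodes != other.nodes:
            return False
        mine = {frozenset((u, v)): s for u, v, s in self.edges()}
        theirs = {frozenset((u, v)): s for u, v, s in other.edges()}
        return mine == theirs

    def __hash__(self):  # frozen dataclass requires it; identity is fine
        return id(self)


@dataclass
class DrugTargetMap:
    """Drug id → sorted unique target gene list, plus a name vocabulary."""

    entries: dict[str, list[str]]
    vocabulary: dict[str, str] = field(default_factory=dict)

    def targets(self, drug_id: str) -> list[str]:
        return self.entries[drug_id]

    def target_pool(self) -> set[str]:
        """All genes that are a target of at least one drug."""
        return {g for ts in self.entries.values() for g in ts}

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class PhenotypeCatalog:
    """Phenotype label → annotated gene set."""

    entries: dict[str, set[str]]
    psychiatric_labels: frozenset[str] = PSYCHIATRIC_LABELS

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class GeneSetCollection:
    """GMT-style gene-set library: term_id → (term_name, gene set)."""

    terms: dict[str, tuple[str, set[str]]]

    def genes(self, term_id: str) -> set[str]:
        return self.terms[term_id][1]

    def __len__(self) -> int:
        return len(self.terms)


@dataclass
class ScreenTable:
    """One screen's per-drug outcomes after de-duplication.

    ``favorable_sign`` is the coefficient sign deemed favorable for this
    screen (negative only for the in silico phagocytosis screen).
    """

    screen_name: str
    outcome_type: Literal["binary", "continuous"]
    favorable_sign: int
    outcomes: pd.Series  # index: drug_id, values: outcome

    def __post_init__(self):
        if self.favorable_sign not in (1, -1):
            raise ValidationError("favorable_sign must be +1 or -1")

    @property
    def drug_ids(self) -> list[str]:
        return list(self.outcomes.index)


def _data_lines(path: Path) -> Iterable[tuple[int, str]]:
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            yield i, line


def read_interactome(path: str | Path, header: bool = False) -> Interactome:
    """Read a 3-column TSV (geneA, geneB, score) into an :class:`Interactome`.

    Symbols are uppercased, duplicate pairs collapse to the max score, and a
    self-loop or out-of-range score raises :class:`ValidationError` naming
    the offending line.
    """
    g = nx.Graph()
    for lineno, line in _data_lines(Path(path)):
        if header:
            header = False
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValidationError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
        a, b, raw = parts[0].strip().upper(), parts[1].strip().upper(), parts[2]
        try:
            score = float(raw)
        except ValueError as exc:
            raise ValidationError(f"{path}:{lineno}: non-numeric score {raw!r}") from exc
        if not 0 < score <= 1:
            raise ValidationError(f"{path}:{lineno}: score {score} outside (0, 1]")
        if a == b:
            raise ValidationError(f"{path}:{lineno}: self-loop on {a}")
        if g.has_edge(a, b):
            g.edges[a, b]["score"] = max(g.edges[a, b]["score"], score)
        else:
            g.add_edge(a, b, score=score)
    return Interactome(g)


def write_interactome(interactome: Interactome, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for u, v, s in sorted(interactome.edges()):
            fh.write(f"{u}\t{v}\t{s:.17g}\n")


def read_drug_targets(path: str | Path) -> DrugTargetMap:
    """Read a drug-target TSV (drug_id, drug_name, target gene).

    Rows group to sorted, deduplicated target lists; drugs whose target list
    is empty after filtering are dropped with a warning.
    """
    raw: dict[str, set[str]] = {}
    vocab: dict[str, str] = {}
    for lineno, line in _data_lines(Path(path)):
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValidationError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
        drug_id, name, gene = parts[0].strip(), parts[1].strip().upper(), parts[2].strip().upper()
        if not DRUG_ID_RE.match(drug_id):
            raise ValidationError(f"{path}:{lineno}: malformed drug id {drug_id!r}")
        raw.setdefault(drug_id, set())
        if gene:
            raw[drug_id].add(gene)
        if name:
            if name in vocab and vocab[name] != drug_id:
                raise ValidationError(f"{path}:{lineno}: name {name!r} maps to multiple ids")
            vocab[name] = drug_id
    entries: dict[str, list[str]] = {}
    for drug_id, genes in raw.items():
        if not genes:
            logger.warning("drug %s has no targets after filtering; dropped", drug_id)
            continue
        entries[drug_id] = sorted(genes)
    return DrugTargetMap(entries=entries, vocabulary=vocab)


def write_drug_targets(dtm: DrugTargetMap, path: str | Path) -> None:
    id_to_name = {v: k for k, v in dtm.vocabulary.items()}
    with open(path, "w", encoding="utf-8") as fh:
        for drug_id in sorted(dtm.entries):
            name = id_to_name.get(drug_id, drug_id)
            for gene in dtm.entries[drug_id]:
                fh.write(f"{drug_id}\t{name}\t{gene}\n")


def read_gene_sets(
    path: str | Path, format: Literal["gmt", "tsv"] = "gmt"
) -> GeneSetCollection | PhenotypeCatalog:
    """Read a gene-set library (GMT) or a 2-column phenotype TSV (label, gene)."""
    if format == "gmt":
        terms: dict[str, tuple[str, set[str]]] = {}
        for lineno, line in _data_lines(Path(path)):
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValidationError(f"{path}:{lineno}: GMT line needs term and description")
            term_id, desc = parts[0].strip(), parts[1].strip()
            genes = {p.strip().upper() for p in parts[2:] if p.strip()}
            if term_id in terms:
                raise ValidationError(f"{path}:{lineno}: duplicate term id {term_id!r}")
            if not genes:
                logger.warning("term %s has zero genes; dropped", term_id)
                continue
            terms[term_id] = (desc, genes)
        return GeneSetCollection(terms=terms)
    if format == "tsv":
        entries: dict[str, set[str]] = {}
        for lineno, line in _data_lines(Path(path)):
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValidationError(f"{path}:{lineno}: expected 2 columns")
            label, gene = parts[0].strip(), parts[1].strip().upper()
            entries.setdefault(label, set()).add(gene)
        empty = [k for k, v in entries.items() if not v]
        for k in empty:
            logger.warning("phenotype %s has zero genes; dropped", k)
            del entries[k]
        return PhenotypeCatalog(entries=entries)
    raise ValueError(f"unknown format {format!r}")


def write_gene_sets(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for term_id in sorted(collection.terms):
            desc, genes = collection.terms[term_id]
            fh.write("\t".join([term_id, desc, *sorted(genes)]) + "\n")


def write_phenotypes(catalog: PhenotypeCatalog, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for label in sorted(catalog.entries):
            for gene in sorted(catalog.entries[label]):
                fh.write(f"{label}\t{gene}\n")


def read_screen_table(
    path: str | Path,
    screen_name: str,
    outcome_type: Literal["binary", "continuous"],
    favorable_sign: int,
    duplicate_policy: Literal["max"] = "max",
) -> ScreenTable:
    """Read a per-drug outcome CSV (columns ``drug,outcome``).

    Drugs measured multiple times collapse to one row; under the default
    policy the maximum outcome is retained (the rule used for repeated
    zebrafish phenoscore measurements).
    """
    df = pd.read_csv(path, comment="#", dtype={0: str})
    if df.shape[1] < 2:
        raise ValidationError(f"{path}: expected columns drug,outcome")
    df = df.iloc[:, :2]
    df.columns = ["drug", "outcome"]
    df["drug"] = df["drug"].str.strip().str.upper()
    outcome = pd.to_numeric(df["outcome"], errors="coerce")
    if outcome.isna().any():
        bad = df.loc[outcome.isna(), "outcome"].iloc[0]
        raise ValidationError(f"{path}: non-numeric outcome {bad!r}")
    df["outcome"] = outcome
    if not df["outcome"].map(lambda x: pd.notna(x) and abs(x) != float("inf")).all():
        raise ValidationError(f"{path}: non-finite outcome")
    if outcome_type == "binary" and not df["outcome"].isin([0, 1]).all():
        bad = df.loc[~df["outcome"].isin([0, 1]), "outcome"].iloc[0]
        raise ValidationError(f"{path}: binary outcome {bad} not in {{0, 1}}")
    if duplicate_policy != "max":
        raise ValueError(f"unknown duplicate policy {duplicate_policy!r}")
    collapsed = df.groupby("drug", sort=True)["outcome"].max()
    return ScreenTable(
        screen_name=screen_name,
        outcome_type=outcome_type,
        favorable_sign=favorable_sign,
        outcomes=collapsed,
    )


def write_screen_table(table: ScreenTable, path: str | Path) -> None:
    table.outcomes.rename("outcome").rename_axis("drug").to_csv(path)


def normalize_drug_name(raw_name: str, vocabulary: DrugTargetMap) -> str | None:
    """Map a raw drug name to a drug id by case-insensitive exact match.

    Salt forms and other formulations absent from the vocabulary return
    ``None`` (a value, not an error), matching the policy of skipping
    formulation variants rather than fuzzy-matching them.
    """
    key = raw_name.strip().upper()
    if not key:
        return None
    return vocabulary.vocabulary.get(key)


def match_rate(raw_names: Iterable[str], vocabulary: DrugTargetMap) -> float:
    """Fraction of names in a file that normalize to a drug id."""
    names = list(raw_names)
    if not names:
        return 0.0
    hits = sum(normalize_drug_name(n, vocabulary) is not None for n in names)
    return hits / len(names)
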