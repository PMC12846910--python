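"""Abstract corpora: loading real ones, generating synthetic ones.

The synthetic generator plants a known relation graph into template
abstracts built from unambiguous trigger verbs, so that the gazetteer
tagger plus the deterministic verb-lookup relation backend recover exactly
the planted triples. That makes every downstream stage testable offline,
end to end, against a known ground truth.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

from . import relations as rel
from .graph import ICKG
from .types import (
    AbstractRecord,
    Direction,
    NodeType,
    ParseError,
    RelationTriple,
    ValidationError,
)

_REQUIRED_FIELDS = ("abstract_id", "year", "text")
_CORPUS_COLUMNS = ("abstract_id", "year", "title", "text", "cell_type_tag")


def load_corpus(
    path: str | Path, year_min: int = 2020, year_max: int = 2024
) -> list[AbstractRecord]:
    """Load a TSV (header) or JSON-lines corpus, keeping years in range.

    File order is preserved; records outside [year_min, year_max] are
    dropped. Missing required fields raise a :class:`ParseError` naming the
    line; duplicate abstract ids raise a :class:`ValidationError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    rows: list[tuple[int, dict]] = []
    with open(path, newline="") as fh:
        first = fh.read(1)
        fh.seek(0)
        if path.suffix in {".json", ".jsonl"} or first == "{":
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    rows.append((lineno, json.loads(line)))
                except json.JSONDecodeError as exc:
                    raise ParseError(f"{path}:{lineno}: invalid JSON: {exc}") from None
        else:
            reader = csv.DictReader(fh, delimiter="\t")
            for row in reader:
                rows.append((reader.line_num, {k: v for k, v in row.items() if k}))

    records, seen = [], set()
    for lineno, row in rows:
        for key in _REQUIRED_FIELDS:
            if row.get(key) in (None, ""):
                raise ParseError(f"{path}:{lineno}: missing required field {key!r}")
        try:
            year = int(row["year"])
        except (TypeError, ValueError):
            raise ParseError(
                f"{path}:{lineno}: year {row['year']!r} is not an integer"
            ) from None
        rec = AbstractRecord(
            abstract_id=str(row["abstract_id"]),
            year=year,
            title=str(row.get("title") or ""),
            text=str(row["text"]),
            cell_type_tag=str(row.get("cell_type_tag") or "other"),
        )
        if rec.abstract_id in seen:
            raise ValidationError(
                f"{path}:{lineno}: duplicate abstract_id {rec.abstract_id!r}"
            )
        seen.add(rec.abstract_id)
        if year_min <= rec.year <= year_max:
            records.append(rec)
    return records


def write_corpus(records: Iterable[AbstractRecord], path: str | Path) -> None:
    """Write the canonical TSV corpus dialect."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_CORPUS_COLUMNS)
        for r in records:
            writer.writerow([r.abstract_id, r.year, r.title, r.text, r.cell_type_tag])


@dataclass
class PlantedTruth:
    """Ground truth planted into a synthetic corpus.

    ``support`` maps each planted (source, target, direction) relation to
    the ids of the abstracts written to support it; ``entities`` maps every
    planted entity name to its node type.
    """

    entities: dict[str, NodeType]
    support: dict[tuple[str, str, str], frozenset[str]]

    @property
    def triples(self) -> list[tuple[str, str, str]]:
        """Sorted planted (source, target, direction) relations."""
        return sorted(self.support)

    def gazetteer(self) -> dict[str, NodeType]:
        """Vocabulary for a :class:`~ickg.entities.GazetteerTagger`."""
        return dict(self.entities)

    def expected_edge_weights(self) -> dict[tuple[str, str, str], int]:
        """Distinct-abstract support count per planted relation."""
        return {k: len(v) for k, v in self.support.items()}


_GENE_TEMPLATE = "{src} {verb} {tgt} in {tag} cells."
_PATHWAY_TEMPLATE = "{src} {verb} {tgt} signaling in {tag} cells."
_FILLER = (
    "These findings reveal a regulatory mechanism relevant to cancer immunotherapy."
)
_TAGS = ("T", "B", "NK", "macrophage")


def generate_synthetic_corpus(
    n_genes: int = 20,
    n_pathways: int = 5,
    n_relations: int = 15,
    abstracts_per_relation: int = 2,
    seed: int = 0,
    year_range: tuple[int, int] = (2020, 2024),
) -> tuple[list[AbstractRecord], PlantedTruth]:
    """Emit one abstract per (relation, support) pair with a planted truth.

    Relations run from a gene to a gene or pathway; each supporting abstract
    states the relation once with a sign-unambiguous trigger verb, so the
    number of emitted abstracts is ``n_relations * abstracts_per_relation``.
    The same seed reproduces the corpus byte for byte.
    """
    if min(n_genes, n_pathways, n_relations, abstracts_per_relation) < 1:
        raise ValidationError("all synthetic-corpus counts must be >= 1")
    rng = np.random.default_rng(seed)
    genes = [f"GENE{i}" for i in range(1, n_genes + 1)]
    pathways = [f"PATHWAY{j}" for j in range(1, n_pathways + 1)]
    entities = {g: NodeType.GENE for g in genes}
    entities.update({p: NodeType.PATHWAY for p in pathways})

    possible = [(s, t) for s in genes for t in genes + pathways if s != t]
    if n_relations > len(possible):
        raise ValidationError(
            f"n_relations={n_relations} exceeds the {len(possible)} possible "
            "ordered gene->entity pairs"
        )
    chosen = [possible[i] for i in rng.choice(len(possible), n_relations, replace=False)]

    records: list[AbstractRecord] = []
    support: dict[tuple[str, str, str], set[str]] = {}
    counter = 0
    for src, tgt in chosen:
        direction = Direction.ACTIVATE if rng.random() < 0.5 else Direction.INHIBIT
        verbs = (
            rel.ACTIVATE_VERBS if direction is Direction.ACTIVATE else rel.INHIBIT_VERBS
        )
        key = (src, tgt, direction.value)
        support[key] = set()
        for _ in range(abstracts_per_relation):
            counter += 1
            abstract_id = f"SYN{counter:06d}"
            tag = _TAGS[rng.integers(len(_TAGS))]
            verb = verbs[rng.integers(len(verbs))]
            template = (
                _PATHWAY_TEMPLATE
                if entities[tgt] is NodeType.PATHWAY
                else _GENE_TEMPLATE
            )
            sentence = template.format(src=src, verb=verb, tgt=tgt, tag=tag)
            records.append(
                AbstractRecord(
                    abstract_id=abstract_id,
                    year=int(rng.integers(year_range[0], year_range[1] + 1)),
                    title=f"Regulation of {tgt} by {src}",
                    text=f"{sentence} {_FILLER}",
                    cell_type_tag=tag,
                )
            )
            support[key].add(abstract_id)
    truth = PlantedTruth(
        entities=entities, support={k: frozenset(v) for k, v in support.items()}
    )
    return records, truth


@dataclass
class PlantedReasoningTruth:
    """Structure planted into a reasoning benchmark graph."""

    hub: str
    hub_targets: frozenset[str]
    pathway: str
    pathway_members: frozenset[str]
    background_edges: int = 0


def generate_planted_reasoning_graph(
    seed: int = 0,
    n_genes: int = 50,
    n_pathways: int = 10,
    hub_out_degree: int = 8,
    pathway_members: int = 4,
    n_background_edges: int = 80,
) -> tuple[ICKG, PlantedReasoningTruth]:
    """Random ICKG with a planted hub gene and a planted pathway.

    The hub gene activates ``hub_out_degree`` downstream genes with strong
    support (weights 3-6); ``pathway_members`` genes activate the planted
    pathway (weights 3-5). Background relations among the remaining nodes
    carry weak support (weights 1-2) and never point into the planted
    pathway or out of the hub, so the planted structure is the signal and
    the background is the noise floor.
    """
    if hub_out_degree + pathway_members + 1 > n_genes:
        raise ValidationError("n_genes too small for the requested planted structure")
    rng = np.random.default_rng(seed)
    genes = [f"G{i}" for i in range(1, n_genes + 1)]
    pathways = [f"P{j}" for j in range(1, n_pathways + 1)]
    g = ICKG()
    for name in genes:
        g.add_entity(name, NodeType.GENE)
    for name in pathways:
        g.add_entity(name, NodeType.PATHWAY)

    hub, pathway = genes[0], pathways[0]
    others = genes[1:]
    picked = rng.choice(len(others), hub_out_degree + pathway_members, replace=False)
    targets = [others[i] for i in picked[:hub_out_degree]]
    members = [others[i] for i in picked[hub_out_degree:]]

    counter = 0

    def add(src_name, src_type, tgt_name, tgt_type, direction, weight):
        nonlocal counter
        src, tgt = (src_name, src_type.value), (tgt_name, tgt_type.value)
        if g.has_edge(src, tgt, key=direction):
            return False
        counter += 1
        prov = frozenset(f"SYNREF{counter:05d}.{k}" for k in range(weight))
        g.add_edge(
            src, tgt, key=direction, direction=direction, weight=weight, provenance=prov
        )
        return True

    for t in targets:
        add(hub, NodeType.GENE, t, NodeType.GENE, "activate", int(rng.integers(3, 7)))
    for m in members:
        add(m, NodeType.GENE, pathway, NodeType.PATHWAY, "activate", int(rng.integers(3, 6)))

    n_nodes = genes + pathways
    added = 0
    while added < n_background_edges:
        src = genes[int(rng.integers(1, len(genes)))]  # never the hub
        tgt = n_nodes[int(rng.integers(len(n_nodes)))]
        if tgt in (src, pathway):
            continue
        direction = "activate" if rng.random() < 0.7 else "inhibit"
        tgt_type = NodeType.GENE if tgt in set(genes) else NodeType.PATHWAY
        if add(src, NodeType.GENE, tgt, tgt_type, direction, int(rng.integers(1, 3))):
            added += 1

    truth = PlantedReasoningTruth(
        hub=hub,
        hub_targets=frozenset(targets),
        pathway=pathway,
        pathway_members=frozenset(members),
        background_edges=added,
    )
    return g, truth


def fetch_pubmed(
    query: str, year_min: int, year_max: int, email: str, retmax: int = 1000
) -> list[AbstractRecord]:
    """Fetch abstracts from PubMed E-utilities (network; never used in tests)."""
    from Bio import Entrez, Medline

    Entrez.email = email
    term = f"{query} AND {year_min}:{year_max}[dp]"
    with Entrez.esearch(db="pubmed", term=term, retmax=retmax) as handle:
        ids = Entrez.read(handle)["IdList"]
    records = []
    if not ids:
        return records
    with Entrez.efetch(
        db="pubmed", id=",".join(ids), rettype="medline", retmode="text"
    ) as handle:
        for entry in Medline.parse(handle):
            text = entry.get("AB")
            pmid = entry.get("PMID")
            date = entry.get("DP", "")
            if not text or not pmid:
                continue
            try:
                year = int(date.split()[0])
            except (IndexError, ValueError):
                continue
            records.append(
                AbstractRecord(
                    abstract_id=str(pmid),
                    year=year,
                    title=entry.get("TI", ""),
                    text=text,
                )
            )
    return records
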