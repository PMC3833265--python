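"""Small Molecule Mechanisms Database: build, store and query.

A *record* is a unique (molecule, concentration, cell line, platform)
perturbation experiment.  Building a record runs the full discovery
pipeline on its expression data: rank genes by differential expression,
induce a high-confidence subnetwork on the top genes, attach the molecule's
known targets via shortest reference paths, enumerate chains starting at
the targets and score them — the 100 most active pathways (lowest p) are
stored with their p-values.

A query compares user-discovered active pathways (APs) against stored
database pathways (DPs) with the asymmetric similarity score

    score(AP, DP) = overlap(AP, DP) / (p(AP) + p(DP)),
    overlap(AP, DP) = |AP ∩ DP| / |AP|,

aggregates per record by the best pair, and returns the top records.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

from .chains import ChainQuery
from .network import (
    ExpressionDataset,
    FunctionalNetwork,
    align,
    build_influence_matrix,
    connect_targets,
    de_rank_genes,
    subnetwork_from_top_genes,
)

__all__ = [
    "DatabasePathway",
    "MoleculeRecord",
    "SMMDatabase",
    "QueryHit",
    "RecordSkipped",
    "build_record",
    "overlap",
    "similarity_score",
    "query_db",
    "write_db",
    "read_db",
    "P_FLOOR",
    "SCHEMA_VERSION",
]

logger = logging.getLogger(__name__)

#: floor applied to p-values entering the similarity denominator
P_FLOOR = 1e-16

SCHEMA_VERSION = 1


class RecordSkipped(RuntimeError):
    """A record failed its preconditions and was not built."""


@dataclass(frozen=True)
class DatabasePathway:
    """A stored active pathway: its gene chain and activity p-value."""

    genes: tuple[str, ...]
    p_value: float

    def __post_init__(self) -> None:
        if len(self.genes) < 2:
            raise ValueError("a database pathway needs at least two genes")
        if not 0.0 < self.p_value <= 1.0:
            raise ValueError("p_value must lie in (0, 1]")


@dataclass
class MoleculeRecord:
    """One perturbation record with its stored active pathways."""

    molecule: str
    concentration: str
    cell_line: str
    platform: str
    targets: tuple[str, ...]
    pathways: list[DatabasePathway] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.targets = tuple(self.targets)
        self.pathways = sorted(self.pathways, key=lambda p: (p.p_value, p.genes))
        bad = [p for p in self.pathways if p.genes[0] not in self.targets]
        if bad:
            raise ValueError("every stored pathway must start at a target gene")

    @property
    def record_id(self) -> str:
        return "|".join((self.molecule, str(self.concentration), self.cell_line, self.platform))


@dataclass
class SMMDatabase:
    records: list[MoleculeRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other) -> bool:
        if not isinstance(other, SMMDatabase):
            return NotImplemented
        return [
            (r.molecule, r.concentration, r.cell_line, r.platform, r.targets, r.pathways)
            for r in self.records
        ] == [
            (r.molecule, r.concentration, r.cell_line, r.platform, r.targets, r.pathways)
            for r in other.records
        ]


def build_record(
    meta: dict,
    expr: ExpressionDataset,
    reference: FunctionalNetwork,
    targets,
    top_n: int = 2000,
    min_conf: float = 0.9,
    max_links: int = 6,
    max_pathways: int = 100,
    damping: float = 0.5,
    chain_cap: int = 5_000_000,
) -> MoleculeRecord:
    """Run the discovery pipeline for one record and keep its top pathways.

    ``meta`` needs keys molecule/concentration/cell_line/platform.  Raises
    :class:`RecordSkipped` (with a log entry) when no target survives, the
    filtered network is empty, or no chain can be scored.
    """
    from .activity import score_all

    rec_id = "|".join(
        str(meta.get(k, "?")) for k in ("molecule", "concentration", "cell_line", "platform")
    )
    targets = sorted(set(targets))
    if not targets:
        raise RecordSkipped(f"{rec_id}: no high-confidence targets")
    ranked = de_rank_genes(expr)
    try:
        net = subnetwork_from_top_genes(ranked, reference, top_n=top_n, min_conf=min_conf)
    except ValueError as exc:
        logger.warning("record %s skipped: %s", rec_id, exc)
        raise RecordSkipped(f"{rec_id}: {exc}") from exc
    net = connect_targets(net, reference, targets)
    net, expr_al = align(net, expr)
    start = sorted(set(targets) & set(net.genes))
    if not start:
        logger.warning("record %s skipped: no connected targets", rec_id)
        raise RecordSkipped(f"{rec_id}: no target connected to the network")
    infl = build_influence_matrix(net, damping=damping)
    query = ChainQuery(start, net.genes, max_links=max_links, chain_cap=chain_cap)
    results = score_all(net, expr_al, infl, query)
    if not results:
        logger.warning("record %s skipped: no chains from the targets", rec_id)
        raise RecordSkipped(f"{rec_id}: no chains start at a connected target")
    pathways = [
        DatabasePathway(r.chain.genes, max(r.p, P_FLOOR)) for r in results[:max_pathways]
    ]
    return MoleculeRecord(
        molecule=str(meta["molecule"]),
        concentration=str(meta.get("concentration", "")),
        cell_line=str(meta.get("cell_line", "")),
        platform=str(meta.get("platform", "")),
        targets=tuple(targets),
        pathways=pathways,
    )


def overlap(ap_genes, dp_genes) -> float:
    """|AP ∩ DP| / |AP| — asymmetric, the query pathway in the denominator."""
    ap = set(ap_genes)
    if not ap:
        raise ValueError("active pathway gene set is empty")
    return len(ap & set(dp_genes)) / len(ap)


def similarity_score(ap_genes, p_ap: float, dp_genes, p_dp: float) -> float:
    """overlap(AP, DP) / (p(AP) + p(DP)), p-values floored at P_FLOOR."""
    return overlap(ap_genes, dp_genes) / (max(p_ap, P_FLOOR) + max(p_dp, P_FLOOR))


@dataclass
class QueryHit:
    """A database record matched by a query, with its best-scoring pathway."""

    record: MoleculeRecord
    best_pathway: DatabasePathway
    score: float
    pathway_scores: list[tuple[DatabasePathway, float]] = field(default_factory=list)


def query_db(db: SMMDatabase, active_pathways, top_records: int = 100) -> list[QueryHit]:
    """Match active pathways against every record; return the best records.

    ``active_pathways`` is a sequence of (genes, p_value) pairs (scored
    chains).  Each record scores as the maximum similarity over all
    (AP, DP) pairs; records are sorted by descending score, ties by record
    identity.  An empty database yields an empty result with a warning.
    """
    aps = [(tuple(g), float(p)) for g, p in active_pathways]
    if not aps:
        raise ValueError("at least one active pathway must be selected")
    if not db.records:
        logger.warning("query against an empty database")
        return []
    hits = []
    for rec in db.records:
        per_pathway = []
        for dp in rec.pathways:
            best = max(
                (similarity_score(g, p, dp.genes, dp.p_value) for g, p in aps),
                default=0.0,
            )
            per_pathway.append((dp, best))
        if per_pathway:
            best_dp, best_score = max(per_pathway, key=lambda t: (t[1], t[0].genes))
        else:
            continue
        hits.append(QueryHit(rec, best_dp, best_score, per_pathway))
    hits.sort(key=lambda h: (-h.score, h.record.record_id))
    return hits[:top_records]


# ---------------------------------------------------------------------------
# portable storage: JSON lines with a schema header


def write_db(db: SMMDatabase, path) -> None:
    """Write the database as UTF-8 JSON lines (header line + one record/line)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(json.dumps({"schema_version": SCHEMA_VERSION, "records": len(db)}) + "\n")
        for rec in db.records:
            fh.write(
                json.dumps(
                    {
                        "molecule": rec.molecule,
                        "concentration": rec.concentration,
                        "cell_line": rec.cell_line,
                        "platform": rec.platform,
                        "targets": list(rec.targets),
                        "pathways": [
                            {"genes": list(p.genes), "p_value": p.p_value}
                            for p in rec.pathways
                        ],
                    },
                    sort_keys=True,
                )
                + "\n"
            )


def read_db(path) -> SMMDatabase:
    """Read a JSON-lines database; malformed lines raise with their number."""
    records = []
    with open(path, encoding="utf-8") as fh:
        header_line = fh.readline()
        try:
            header = json.loads(header_line)
        except json.JSONDecodeError as exc:
            raise ValueError(f"line 1: malformed header: {exc}") from exc
        version = header.get("schema_version")
        if version != SCHEMA_VERSION:
            raise ValueError(f"line 1: unsupported schema_version {version!r}")
        for lineno, raw in enumerate(fh, start=2):
            if not raw.strip():
                continue
            try:
                obj = json.loads(raw)
                records.append(
                    MoleculeRecord(
                        molecule=obj["molecule"],
                        concentration=obj["concentration"],
                        cell_line=obj["cell_line"],
                        platform=obj["platform"],
                        targets=tuple(obj["targets"]),
                        pathways=[
                            DatabasePathway(tuple(p["genes"]), float(p["p_value"]))
                            for p in obj["pathways"]
                        ],
                    )
                )
            except (json.JSONDecodeError, KeyError, TypeError, ValueError) as exc:
                raise ValueError(f"line {lineno}: malformed record: {exc}") from exc
    return SMMDatabase(records)
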