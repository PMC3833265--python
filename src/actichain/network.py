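"""Functional networks, expression datasets and the influence matrix.

A *functional network* is a gene/protein interaction graph: nodes are genes
(gene products are conflated with their genes), links are either physical
interactions (undirected) or regulatory relations (optionally directed,
signed as stimulation or inhibition).  By default a network is undirected and
unweighted; direction, sign, weight and a confidence score can be attached
per link.

The *influence matrix* W encodes how the expression of a gene's in-neighbours
contributes to its own expression: incoming raw edge weights are normalised
to sum to a damping factor ``damping`` in (0, 1), signed -1 for inhibition and
+1 otherwise.  Because every row of |W| sums to at most ``damping`` < 1,
I - W is strictly diagonally dominant and invertible, which makes the
latent-variable transform and its generative inverse well defined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Link",
    "FunctionalNetwork",
    "ExpressionDataset",
    "InfluenceMatrix",
    "NetworkParseError",
    "ExpressionParseError",
    "read_network",
    "write_network",
    "read_expression",
    "read_condition_map",
    "align",
    "build_influence_matrix",
    "de_rank_genes",
    "subnetwork_from_top_genes",
    "connect_targets",
]

SIGNS = ("stimulation", "inhibition", "interaction")

#: SIF relation keywords -> (directed, sign)
_SIF_RELATIONS = {
    "pp": (False, "interaction"),
    "interaction": (False, "interaction"),
    "activates": (True, "stimulation"),
    "stimulation": (True, "stimulation"),
    "inhibits": (True, "inhibition"),
    "inhibition": (True, "inhibition"),
}


class NetworkParseError(ValueError):
    """Malformed network file; message carries the offending line number."""


class ExpressionParseError(ValueError):
    """Malformed expression table; message carries the offending row."""


@dataclass(frozen=True)
class Link:
    """A single link between two distinct genes.

    ``sign`` is one of stimulation/inhibition/interaction; inhibition carries
    numeric sign -1, the other two +1.  ``raw_weight`` defaults to 1
    (unweighted network); ``confidence`` is an optional score in [0, 1] as in
    STRING/STITCH exports.
    """

    source: str
    target: str
    directed: bool = False
    sign: str = "interaction"
    raw_weight: float = 1.0
    confidence: float | None = None

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise ValueError(f"self-loop on gene {self.source!r}")
        if self.sign not in SIGNS:
            raise ValueError(f"unknown link sign {self.sign!r}")
        if self.raw_weight < 0:
            raise ValueError("raw_weight must be nonnegative")
        if self.confidence is not None and not 0.0 <= self.confidence <= 1.0:
            raise ValueError("confidence must lie in [0, 1]")

    @property
    def numeric_sign(self) -> int:
        return -1 if self.sign == "inhibition" else 1

    @property
    def key(self) -> tuple:
        """Identity of the gene pair: ordered if directed, unordered if not."""
        if self.directed:
            return (self.source, self.target, True)
        a, b = sorted((self.source, self.target))
        return (a, b, False)

    def traversable_from(self, gene: str) -> bool:
        if self.directed:
            return gene == self.source
        return gene in (self.source, self.target)

    def other(self, gene: str) -> str:
        return self.target if gene == self.source else self.source


class FunctionalNetwork:
    """Gene interaction graph with at most one link per gene pair.

    Duplicate links on the same (ordered for directed, unordered for
    undirected) pair collapse to the entry with maximum confidence.
    """

    def __init__(self, genes=(), links=()):
        self._genes: dict[str, None] = {}
        self._links: dict[tuple, Link] = {}
        self.parse_warnings: list[str] = []
        for g in genes:
            self.add_gene(g)
        for ln in links:
            self.add_link(ln)

    # -- construction -------------------------------------------------------

    def add_gene(self, gene: str) -> None:
        self._genes.setdefault(gene, None)

    def add_link(self, link: Link) -> None:
        self.add_gene(link.source)
        self.add_gene(link.target)
        key = link.key
        old = self._links.get(key)
        if old is not None:
            old_c = -math.inf if old.confidence is None else old.confidence
            new_c = -math.inf if link.confidence is None else link.confidence
            if new_c <= old_c:
                return
        self._links[key] = link

    # -- views --------------------------------------------------------------

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(self._genes)

    @property
    def links(self) -> list[Link]:
        return list(self._links.values())

    @property
    def node_count(self) -> int:
        return len(self._genes)

    def __len__(self) -> int:
        return len(self._genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self._genes

    def __eq__(self, other) -> bool:
        if not isinstance(other, FunctionalNetwork):
            return NotImplemented
        return self._genes.keys() == other._genes.keys() and self._links == other._links

    def out_links(self, gene: str) -> list[Link]:
        """Links traversable starting at ``gene`` (undirected or directed out)."""
        return [ln for ln in self._links.values() if ln.traversable_from(gene)]

    def in_links(self, gene: str) -> list[tuple[str, Link]]:
        """(neighbour, link) pairs whose influence flows into ``gene``."""
        out = []
        for ln in self._links.values():
            if ln.directed:
                if ln.target == gene:
                    out.append((ln.source, ln))
            elif gene in (ln.source, ln.target):
                out.append((ln.other(gene), ln))
        return out

    def adjacency(self) -> dict[str, list[tuple[str, Link]]]:
        """Traversal adjacency: gene -> sorted (next_gene, link) list."""
        adj: dict[str, list[tuple[str, Link]]] = {g: [] for g in self._genes}
        for ln in self._links.values():
            adj[ln.source].append((ln.target, ln))
            if not ln.directed:
                adj[ln.target].append((ln.source, ln))
        for g in adj:
            adj[g].sort(key=lambda pair: pair[0])
        return adj

    def undirected_adjacency(self) -> dict[str, list[str]]:
        """Direction-blind neighbour lists, sorted (for BFS distances)."""
        adj: dict[str, list[str]] = {g: [] for g in self._genes}
        for ln in self._links.values():
            adj[ln.source].append(ln.target)
            adj[ln.target].append(ln.source)
        for g in adj:
            adj[g].sort()
        return adj

    def degree(self, gene: str) -> int:
        return sum(1 for ln in self._links.values() if gene in (ln.source, ln.target))

    def subgraph(self, genes) -> "FunctionalNetwork":
        keep = set(genes)
        sub = FunctionalNetwork(genes=[g for g in self._genes if g in keep])
        for ln in self._links.values():
            if ln.source in keep and ln.target in keep:
                sub.add_link(ln)
        return sub

    def copy(self) -> "FunctionalNetwork":
        return FunctionalNetwork(genes=self._genes, links=self._links.values())

    def find_link(self, a: str, b: str) -> Link | None:
        """Any link joining a and b, regardless of direction."""
        for key in ((a, b, True), (b, a, True), (*sorted((a, b)), False)):
            if key in self._links:
                return self._links[key]
        return None

    def to_networkx(self, directed: bool = False):
        import networkx as nx

        G = nx.DiGraph() if directed else nx.Graph()
        G.add_nodes_from(self._genes)
        for ln in self._links.values():
            if directed:
                G.add_edge(ln.source, ln.target, link=ln)
                if not ln.directed:
                    G.add_edge(ln.target, ln.source, link=ln)
            else:
                G.add_edge(ln.source, ln.target, link=ln)
        return G


# ---------------------------------------------------------------------------
# file I/O


def _parse_bool(tok: str, lineno: int) -> bool:
    t = tok.strip().lower()
    if t in ("true", "1", "yes"):
        return True
    if t in ("false", "0", "no", ""):
        return False
    raise NetworkParseError(f"line {lineno}: cannot parse boolean {tok!r}")


def read_network(path, dialect: str | None = None) -> FunctionalNetwork:
    """Read a network from a SIF or TSV edge-list file.

    SIF rows are ``source relation target`` (whitespace separated); TSV files
    have a header ``source<TAB>target[<TAB>directed<TAB>sign<TAB>weight<TAB>confidence]``.
    Unspecified direction means undirected, unspecified sign means
    interaction, unspecified weight means 1.  Self-loops are dropped with a
    warning recorded in ``parse_warnings``.
    """
    path = str(path)
    if dialect is None:
        dialect = "sif" if path.lower().endswith(".sif") else "tsv"
    if dialect not in ("sif", "tsv"):
        raise ValueError(f"unknown network dialect {dialect!r}")
    net = FunctionalNetwork()
    with open(path, encoding="utf-8") as fh:
        if dialect == "sif":
            _read_sif(fh, net)
        else:
            _read_tsv(fh, net)
    return net


def _read_sif(fh, net: FunctionalNetwork) -> None:
    for lineno, raw in enumerate(fh, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 3:
            raise NetworkParseError(
                f"line {lineno}: expected 'source relation target', got {line!r}"
            )
        src, rel, tgt = parts
        if rel not in _SIF_RELATIONS:
            raise NetworkParseError(f"line {lineno}: unknown relation {rel!r}")
        if src == tgt:
            net.add_gene(src)
            net.parse_warnings.append(f"line {lineno}: self-loop on {src!r} dropped")
            continue
        directed, sign = _SIF_RELATIONS[rel]
        net.add_link(Link(src, tgt, directed=directed, sign=sign))


_TSV_COLUMNS = ("source", "target", "directed", "sign", "weight", "confidence")


def _read_tsv(fh, net: FunctionalNetwork) -> None:
    header = fh.readline().rstrip("\n")
    cols = header.split("\t")
    if cols[:2] != ["source", "target"] or any(c not in _TSV_COLUMNS for c in cols):
        raise NetworkParseError(
            f"line 1: header must start with 'source\\ttarget' using columns {_TSV_COLUMNS}"
        )
    idx = {c: i for i, c in enumerate(cols)}
    for lineno, raw in enumerate(fh, start=2):
        line = raw.rstrip("\n")
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) != len(cols):
            raise NetworkParseError(
                f"line {lineno}: expected {len(cols)} fields, got {len(parts)}"
            )

        def get(col: str, default: str = "") -> str:
            return parts[idx[col]].strip() if col in idx else default

        src, tgt = get("source"), get("target")
        if src and not tgt:
            # isolated-gene row (gene with no links)
            net.add_gene(src)
            continue
        if not src or not tgt:
            raise NetworkParseError(f"line {lineno}: empty gene identifier")
        if src == tgt:
            net.add_gene(src)
            net.parse_warnings.append(f"line {lineno}: self-loop on {src!r} dropped")
            continue
        sign = get("sign") or "interaction"
        if sign not in SIGNS:
            raise NetworkParseError(f"line {lineno}: unknown sign {sign!r}")
        try:
            weight = float(get("weight") or "1")
            conf_tok = get("confidence")
            confidence = float(conf_tok) if conf_tok else None
        except ValueError as exc:
            raise NetworkParseError(f"line {lineno}: {exc}") from None
        net.add_link(
            Link(
                src,
                tgt,
                directed=_parse_bool(get("directed"), lineno),
                sign=sign,
                raw_weight=weight,
                confidence=confidence,
            )
        )


def write_network(net: FunctionalNetwork, path) -> None:
    """Write a network as the TSV dialect (round-trips through read_network).

    Isolated genes are emitted as rows with an empty target field so the
    full gene set survives the round trip.
    """
    linked = {g for ln in net.links for g in (ln.source, ln.target)}
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_TSV_COLUMNS) + "\n")
        for g in net.genes:
            if g not in linked:
                fh.write(f"{g}\t\tfalse\tinteraction\t1\t\n")
        for ln in net.links:
            conf = "" if ln.confidence is None else repr(ln.confidence)
            fh.write(
                f"{ln.source}\t{ln.target}\t{str(ln.directed).lower()}\t{ln.sign}"
                f"\t{ln.raw_weight!r}\t{conf}\n"
            )


# ---------------------------------------------------------------------------
# expression data


@dataclass
class ExpressionDataset:
    """Genes x samples expression values with a two-condition design.

    ``condition`` maps every sample to "A" or "B"; the model requires at
    least two replicates per condition.
    """

    genes: tuple[str, ...]
    samples: tuple[str, ...]
    values: np.ndarray  # shape (len(genes), len(samples))
    condition: dict[str, str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError("values shape does not match genes x samples")
        if np.isnan(self.values).any():
            raise ValueError("expression values contain missing entries")
        missing = [s for s in self.samples if s not in self.condition]
        if missing:
            raise ValueError(f"samples without condition assignment: {missing}")
        bad = sorted({c for c in self.condition.values()} - {"A", "B"})
        if bad:
            raise ValueError(f"conditions must be 'A' or 'B', got {bad}")
        if self.n_A < 2 or self.n_B < 2:
            raise ValueError(
                "at least two replicates per condition are required "
                f"(n_A={self.n_A}, n_B={self.n_B})"
            )

    @property
    def n_A(self) -> int:
        return sum(1 for s in self.samples if self.condition[s] == "A")

    @property
    def n_B(self) -> int:
        return sum(1 for s in self.samples if self.condition[s] == "B")

    def condition_mask(self, label: str) -> np.ndarray:
        return np.array([self.condition[s] == label for s in self.samples])

    def subset_genes(self, genes) -> "ExpressionDataset":
        index = {g: i for i, g in enumerate(self.genes)}
        keep = [g for g in genes if g in index]
        rows = [index[g] for g in keep]
        return ExpressionDataset(
            tuple(keep), self.samples, self.values[rows, :], dict(self.condition)
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.genes), columns=list(self.samples))

    def write_tsv(self, path) -> None:
        df = self.to_frame()
        df.index.name = "gene"
        df.to_csv(path, sep="\t", float_format="%.17g")


def read_condition_map(path) -> dict[str, str]:
    """Read a two-column TSV ``sample<TAB>condition`` (header optional)."""
    out: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ExpressionParseError(
                    f"line {lineno}: expected 'sample<TAB>condition'"
                )
            if lineno == 1 and parts == ["sample", "condition"]:
                continue
            out[parts[0]] = parts[1]
    return out


def read_expression(path, condition_map) -> ExpressionDataset:
    """Read a genes x samples TSV (first column ``gene``) into a dataset.

    ``condition_map`` is a sample -> {A,B} dict or a path to a two-column
    TSV.  Conditions with fewer than two replicates are a hard error.
    """
    if not isinstance(condition_map, dict):
        condition_map = read_condition_map(condition_map)
    try:
        df = pd.read_csv(
            str(path), sep="\t", index_col=0, dtype={0: str},
            float_precision="round_trip",
        )
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ExpressionParseError(f"cannot read expression table: {exc}") from exc
    if df.index.isna().any() or any(str(g).strip() == "" for g in df.index):
        bad = [i for i, g in enumerate(df.index, start=2) if not str(g).strip() or pd.isna(g)]
        raise ExpressionParseError(f"empty gene identifier at row(s) {bad}")

    def _cell(x):
        try:
            return float(x)  # correctly rounded, unlike the fast csv parser
        except (TypeError, ValueError):
            return float("nan")

    num = df.apply(
        lambda col: col if col.dtype.kind in "fiu" else col.map(_cell)
    )
    values = num.to_numpy(dtype=float)
    if np.isnan(values).any():
        rows = sorted({int(i) + 2 for i in np.argwhere(np.isnan(values))[:, 0]})
        raise ExpressionParseError(f"non-numeric or missing cell(s) at row(s) {rows}")
    samples = tuple(str(c) for c in df.columns)
    cond = {s: condition_map[s] for s in samples if s in condition_map}
    missing = [s for s in samples if s not in cond]
    if missing:
        raise ExpressionParseError(f"samples without condition assignment: {missing}")
    return ExpressionDataset(tuple(str(g) for g in df.index), samples, values, cond)


def align(
    network: FunctionalNetwork, expr: ExpressionDataset
) -> tuple[FunctionalNetwork, ExpressionDataset]:
    """Restrict both objects to their common genes, in a shared order.

    The shared order is the expression dataset's gene order filtered to the
    intersection; an empty intersection is a hard error.
    """
    net_genes = set(network.genes)
    common = [g for g in expr.genes if g in net_genes]
    if not common:
        raise ValueError("network and expression data share no genes")
    keep = set(common)
    # rebuild the network over `common` so both gene orders are identical
    sub = FunctionalNetwork(genes=common)
    for ln in network.links:
        if ln.source in keep and ln.target in keep:
            sub.add_link(ln)
    return sub, expr.subset_genes(common)


# ---------------------------------------------------------------------------
# influence matrix


@dataclass
class InfluenceMatrix:
    """Signed, damped, in-degree-normalised influence weights.

    ``matrix[i, j]`` is the influence of gene j on gene i; for every gene the
    absolute incoming weights sum to exactly ``damping`` (or 0 for genes with
    no in-links), so I - matrix is invertible.
    """

    genes: tuple[str, ...]
    matrix: np.ndarray
    damping: float

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.genes)
        if self.matrix.shape != (n, n):
            raise ValueError("influence matrix must be square over the gene set")

    @property
    def n(self) -> int:
        return len(self.genes)

    def weight(self, source: str, target: str) -> float:
        gi = {g: i for i, g in enumerate(self.genes)}
        return float(self.matrix[gi[target], gi[source]])


def build_influence_matrix(
    network: FunctionalNetwork, damping: float = 0.5
) -> InfluenceMatrix:
    """Construct W with incoming weights per gene normalised to ``damping``.

    W[h -> g] = damping * sign(link) * raw_weight / (sum of incoming raw
    weights of g); undirected links contribute in both directions.
    """
    if not 0.0 < damping < 1.0:
        raise ValueError("damping must lie strictly between 0 and 1")
    genes = network.genes
    if not genes:
        raise ValueError("network is empty")
    gi = {g: i for i, g in enumerate(genes)}
    W = np.zeros((len(genes), len(genes)))
    for g in genes:
        incoming = network.in_links(g)
        total = sum(ln.raw_weight for _, ln in incoming)
        if total <= 0:
            continue
        for h, ln in incoming:
            W[gi[g], gi[h]] += damping * ln.numeric_sign * ln.raw_weight / total
    return InfluenceMatrix(genes, W, damping)


# ---------------------------------------------------------------------------
# differential-expression ranking and network assembly filters


def de_rank_genes(expr: ExpressionDataset) -> pd.DataFrame:
    """Rank genes by a two-sample pooled-variance t statistic (B minus A).

    Plain plumbing around the usual pooled t; intended as a stand-in for an
    externally supplied differential-expression ranking.  Genes are sorted by
    |t| descending, ties broken by gene identifier; zero pooled variance
    with a nonzero mean difference yields signed infinity (ranked first),
    with a zero difference t = 0.
    """
    mask_a = expr.condition_mask("A")
    mask_b = expr.condition_mask("B")
    A, B = expr.values[:, mask_a], expr.values[:, mask_b]
    n_a, n_b = A.shape[1], B.shape[1]
    diff = B.mean(axis=1) - A.mean(axis=1)
    ss = ((A - A.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (B - B.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    pooled = ss / (n_a + n_b - 2)
    se = np.sqrt(pooled * (1.0 / n_a + 1.0 / n_b))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, diff / np.where(se > 0, se, 1.0), np.where(diff != 0, np.sign(diff) * np.inf, 0.0))
    df = pd.DataFrame({"gene": list(expr.genes), "t": t})
    df["abs_t"] = df["t"].abs()
    df = df.sort_values(["abs_t", "gene"], ascending=[False, True], kind="mergesort")
    df = df.drop(columns="abs_t").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def subnetwork_from_top_genes(
    ranked: pd.DataFrame,
    reference: FunctionalNetwork,
    top_n: int = 2000,
    min_conf: float = 0.9,
) -> FunctionalNetwork:
    """Induced subgraph on the top-ranked genes, confidence-filtered.

    Keeps only reference links with confidence >= ``min_conf`` among the top
    ``top_n`` genes, then removes every isolated gene.  Mirrors the
    high-confidence network assembly used for database construction
    (top-2000 genes, confidence threshold 0.9).
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    top = list(ranked["gene"].head(top_n))
    induced = reference.subgraph(top)
    net = FunctionalNetwork()
    for ln in induced.links:
        if ln.confidence is not None and ln.confidence >= min_conf:
            net.add_link(ln)
    if not net.links:
        raise ValueError("empty network after filtering")
    return net


def _bfs_distances(adj: dict[str, list[str]], sources) -> dict[str, int]:
    from collections import deque

    dist = {s: 0 for s in sources}
    queue = deque(sources)
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def connect_targets(
    network: FunctionalNetwork,
    reference: FunctionalNetwork,
    targets,
) -> FunctionalNetwork:
    """Attach absent target genes to the network via reference shortest paths.

    For each target not already in the network, the genes and links of one
    unweighted shortest path (in the reference, direction-blind) to the
    nearest network gene are added.  Among equal-length paths the
    lexicographically smallest node sequence is chosen.  Unreachable targets
    are recorded in ``parse_warnings`` and omitted.
    """
    targets = sorted(set(targets))
    absent = [t for t in targets if t not in reference]
    if absent:
        raise ValueError(f"targets not in the reference network: {absent}")
    out = network.copy()
    net_genes = set(network.genes)
    adj = reference.undirected_adjacency()
    dist_to_net = _bfs_distances(adj, sorted(net_genes & set(reference.genes)))
    for t in targets:
        if t in net_genes:
            continue
        if t not in dist_to_net:
            out.parse_warnings.append(f"target {t!r} unconnected to the network")
            continue
        dist_from_t = _bfs_distances(adj, [t])
        d_star = dist_to_net[t]
        # greedy lexicographically-smallest shortest path: always step to the
        # smallest neighbour still on *some* shortest t -> network path
        path = [t]
        cur = t
        while cur not in net_genes:
            nxt = min(
                v
                for v in adj[cur]
                if dist_from_t.get(v) == dist_from_t[cur] + 1
                and dist_to_net.get(v, math.inf) + dist_from_t[v] == d_star
            )
            path.append(nxt)
            cur = nxt
        for a, b in zip(path, path[1:]):
            link = reference.find_link(a, b)
            assert link is not None
            out.add_link(link)
    return out
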