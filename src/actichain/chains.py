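"""Enumeration of linear-chain pathways (simple paths) in a functional network.

A *chain* is an ordered simple path of genes; it is the unit whose activity
is tested.  Enumeration is a deterministic depth-first traversal: start genes
in lexicographic order, neighbours visited in lexicographic order, directed
links traversable only source -> target.  A fully undirected chain and its
reverse describe the same pathway; when both orientations satisfy the query
only the canonical (lexicographically smaller) one is emitted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

from .network import FunctionalNetwork, Link

__all__ = [
    "Chain",
    "ChainQuery",
    "ChainCapExceeded",
    "enumerate_chains",
    "canonicalize",
    "count_chains",
    "chain_to_string",
    "parse_chain_genes",
]

#: glyphs used when rendering a chain as text
_SIGN_GLYPH = {"stimulation": "->", "inhibition": "-|", "interaction": "--"}


class ChainCapExceeded(RuntimeError):
    """Raised when enumeration would exceed the configured chain cap."""


@dataclass(frozen=True)
class Chain:
    """An ordered simple path: k genes joined by k-1 traversable links."""

    genes: tuple[str, ...]
    links: tuple[Link, ...]

    def __post_init__(self) -> None:
        if len(self.genes) < 2 or len(self.links) != len(self.genes) - 1:
            raise ValueError("a chain needs >= 2 genes and one link per step")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("chain repeats a gene")
        for a, b, ln in zip(self.genes, self.genes[1:], self.links):
            ok = (ln.source, ln.target) == (a, b) or (
                not ln.directed and (ln.source, ln.target) == (b, a)
            )
            if not ok:
                raise ValueError(f"link {ln.source}-{ln.target} does not join {a}->{b}")

    @property
    def n_links(self) -> int:
        return len(self.links)

    def all_undirected(self) -> bool:
        return all(not ln.directed for ln in self.links)

    def reversed(self) -> "Chain":
        return Chain(tuple(reversed(self.genes)), tuple(reversed(self.links)))

    def __str__(self) -> str:
        return chain_to_string(self)


def chain_to_string(chain: Chain) -> str:
    """Render e.g. ``A->B-|C`` (stimulation ``->``, inhibition ``-|``,
    interaction ``--``)."""
    parts = [chain.genes[0]]
    for gene, ln in zip(chain.genes[1:], chain.links):
        parts.append(_SIGN_GLYPH[ln.sign])
        parts.append(gene)
    return "".join(parts)


def parse_chain_genes(text: str) -> tuple[str, ...]:
    """Recover the gene list from a rendered chain string."""
    import re

    genes = tuple(g for g in re.split(r"->|-\||--", text.strip()) if g)
    if len(genes) < 2:
        raise ValueError(f"cannot parse chain string {text!r}")
    return genes


@dataclass(frozen=True)
class ChainQuery:
    """Start/end gene sets and size limits for chain enumeration.

    ``max_links`` defaults to 6 (seven genes), the exhaustive-search depth
    used throughout; ``chain_cap`` guards runaway exhaustive runs.
    """

    start_set: frozenset[str]
    end_set: frozenset[str]
    max_links: int = 6
    chain_cap: int = 5_000_000

    def __init__(self, start_set, end_set, max_links: int = 6, chain_cap: int = 5_000_000):
        object.__setattr__(self, "start_set", frozenset(start_set))
        object.__setattr__(self, "end_set", frozenset(end_set))
        object.__setattr__(self, "max_links", int(max_links))
        object.__setattr__(self, "chain_cap", int(chain_cap))
        if not self.start_set or not self.end_set:
            raise ValueError("start and end sets must be nonempty")
        if self.max_links < 1:
            raise ValueError("max_links must be >= 1")

    def validate_against(self, network: FunctionalNetwork) -> None:
        genes = set(network.genes)
        for name, s in (("start", self.start_set), ("end", self.end_set)):
            missing = sorted(s - genes)
            if missing:
                raise ValueError(f"{name} genes not in the network: {missing}")


def canonicalize(chain: Chain) -> Chain:
    """Return the representative orientation of a chain.

    A chain whose links are all undirected is interchangeable with its
    reverse; the lexicographically smaller gene sequence is the canonical
    form.  Chains containing any directed link are returned unchanged.
    """
    if chain.all_undirected():
        rev = tuple(reversed(chain.genes))
        if rev < chain.genes:
            return chain.reversed()
    return chain


def _emit(chain: Chain, query: ChainQuery) -> bool:
    """Emit policy implementing once-per-canonical-form semantics.

    If the reversed orientation also satisfies the query (possible only for
    fully undirected chains), only the canonical orientation is emitted;
    otherwise the chain is emitted as traversed.
    """
    if chain.all_undirected():
        rev = tuple(reversed(chain.genes))
        if rev != chain.genes and rev[0] in query.start_set and rev[-1] in query.end_set:
            return chain.genes < rev
    return True


def _walk(network: FunctionalNetwork, query: ChainQuery) -> Iterator[Chain]:
    adj = network.adjacency()
    genes: list[str] = []
    links: list[Link] = []
    on_path: set[str] = set()

    def dfs() -> Iterator[Chain]:
        cur = genes[-1]
        for nxt, ln in adj[cur]:
            if nxt in on_path:
                continue
            genes.append(nxt)
            links.append(ln)
            on_path.add(nxt)
            if nxt in query.end_set:
                chain = Chain(tuple(genes), tuple(links))
                if _emit(chain, query):
                    yield chain
            if len(links) < query.max_links:
                yield from dfs()
            on_path.discard(nxt)
            genes.pop()
            links.pop()

    for start in sorted(query.start_set):
        if start not in adj:
            continue
        genes[:] = [start]
        links[:] = []
        on_path = {start}
        yield from dfs()


def enumerate_chains(network: FunctionalNetwork, query: ChainQuery) -> Iterator[Chain]:
    """Lazily yield every chain satisfying the query, each exactly once.

    Deterministic order: depth-first from lexicographically sorted start
    genes, neighbours in lexicographic order.  Raises :class:`ChainCapExceeded`
    once more than ``query.chain_cap`` chains have been produced — narrow the
    start/end sets or lower ``max_links`` (exhaustive exploration over all
    genes can take a long time).
    """
    query.validate_against(network)
    produced = 0
    for chain in _walk(network, query):
        produced += 1
        if produced > query.chain_cap:
            raise ChainCapExceeded(
                f"more than {query.chain_cap} chains; narrow the start/end sets "
                "or reduce max_links"
            )
        yield chain


def count_chains(network: FunctionalNetwork, query: ChainQuery) -> int:
    """Number of canonical chains the query would yield (ignores chain_cap)."""
    query.validate_against(network)
    return sum(1 for _ in _walk(network, query))
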