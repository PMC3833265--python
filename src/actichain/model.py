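"""Model/Results interface tying the pipeline together.

:class:`ChainActivityModel` is constructed from a functional network and a
two-condition expression dataset (aligning them and building the influence
matrix up front); :meth:`ChainActivityModel.fit` enumerates and scores chains
and returns a :class:`ChainActivityResults` carrying the ranked tests, the
per-gene effect estimates, and a ``summary()`` table of the most active
pathways.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import activity as _activity
from .chains import ChainQuery, chain_to_string
from .network import (
    ExpressionDataset,
    FunctionalNetwork,
    align,
    build_influence_matrix,
    read_expression,
    read_network,
)

__all__ = ["ChainActivityModel", "ChainActivityResults"]


class ChainActivityModel:
    """Two-condition latent-variable activity model over a gene network.

    Parameters
    ----------
    network : FunctionalNetwork
        Functional network; restricted to genes with expression values.
    expression : ExpressionDataset
        Genes x samples values with an A/B condition map (>= 2 replicates
        per condition).
    damping : float, default 0.5
        Damping factor of the influence matrix; incoming link weights of
        each gene are normalised to sum to this value, keeping I - W
        invertible.
    """

    def __init__(
        self,
        network: FunctionalNetwork,
        expression: ExpressionDataset,
        damping: float = 0.5,
    ):
        self.network, self.expression = align(network, expression)
        self.damping = float(damping)
        self.influence = build_influence_matrix(self.network, damping=self.damping)
        self.gamma = _activity.latent_contributions(self.expression, self.influence)
        self.gene_effects = _activity.estimate_gene_effects(self.gamma, self.expression)

    @classmethod
    def from_files(
        cls,
        network_path,
        expression_path,
        condition_map,
        damping: float = 0.5,
        network_dialect: str | None = None,
    ) -> "ChainActivityModel":
        """Build the model from a network file (SIF/TSV), an expression TSV
        and a condition map (dict or two-column TSV path)."""
        net = read_network(network_path, dialect=network_dialect)
        expr = read_expression(expression_path, condition_map)
        return cls(net, expr, damping=damping)

    def fit(
        self,
        start=None,
        end=None,
        max_links: int = 6,
        chain_cap: int = 5_000_000,
        top_k: int = 10,
        alpha: float = 0.05,
    ) -> "ChainActivityResults":
        """Enumerate and score chains; return ranked results.

        ``start``/``end`` default to all network genes (exhaustive search).
        ``top_k`` only controls how many rows ``summary()`` displays;
        the full ranked table is retained on the results object.
        """
        genes = self.network.genes
        query = ChainQuery(
            start if start is not None else genes,
            end if end is not None else genes,
            max_links=max_links,
            chain_cap=chain_cap,
        )
        results = _activity._score_stream(
            _activity.enumerate_chains(self.network, query), self.gene_effects
        )
        _activity.rank_results(results)
        return ChainActivityResults(self, query, results, top_k=top_k, alpha=alpha)


@dataclass
class ChainActivityResults:
    """Ranked chain activity tests from :meth:`ChainActivityModel.fit`."""

    model: ChainActivityModel
    query: ChainQuery
    results: list
    top_k: int = 10
    alpha: float = 0.05

    @property
    def n_chains(self) -> int:
        return len(self.results)

    def top(self, k: int | None = None) -> list:
        return self.results[: (self.top_k if k is None else k)]

    @property
    def significant(self) -> list:
        """Chains whose BH-adjusted p falls below the reporting threshold."""
        return [r for r in self.results if r.p_adj is not None and r.p_adj < self.alpha]

    def to_frame(self, k: int | None = None) -> pd.DataFrame:
        rows = self.results if k is None else self.results[:k]
        return pd.DataFrame(
            {
                "rank": [r.rank for r in rows],
                "chain": [r.chain_string for r in rows],
                "T": [r.T for r in rows],
                "df": [r.df for r in rows],
                "p": [r.p for r in rows],
                "p_adj": [r.p_adj for r in rows],
            }
        )

    def write_tsv(self, path, k: int | None = None) -> None:
        self.to_frame(k=k).to_csv(path, sep="\t", index=False, float_format="%.6g")

    def summary(self, k: int | None = None) -> str:
        """Plain-text summary of the top-ranked active pathways."""
        k = self.top_k if k is None else k
        n = self.model.expression
        head = [
            "Chain activity model (two-condition latent-variable contrast)",
            f"genes: {len(self.model.network.genes)}   links: {len(self.model.network.links)}"
            f"   samples: {n.n_A}+{n.n_B} (A+B)   damping: {self.model.damping}",
            f"chains scored: {self.n_chains} (max {self.query.max_links} links)"
            f"   significant at BH {self.alpha:g}: {len(self.significant)}",
            "",
        ]
        if not self.results:
            head.append("no chains matched the query")
            return "\n".join(head)
        df = self.to_frame(k=k)
        with pd.option_context("display.max_colwidth", 60, "display.width", 120):
            head.append(df.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
        return "\n".join(head)
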