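"""Chain activity scoring under the two-condition latent-variable model.

The expression level of a gene is modelled as its own latent contribution
plus the damped, signed, normalised influence of its in-neighbours:
``Y = W Y + gamma`` per sample, hence the latent contributions are recovered
exactly by the linear transform ``gamma = (I - W) Y``.  With the latent
contributions assumed independent normal, the two-condition comparison
reduces to independent per-gene pooled-variance contrasts on gamma.

A chain's activity statistic is the sign-propagated sum of its genes'
condition effects divided by the square root of the summed effect variances
— a single linear contrast, so under the null it follows a t-distribution
with ``k * (n_A + n_B - 2)`` pooled degrees of freedom for a chain of k
genes.  Ranking uses two-sided p-values with Benjamini–Hochberg adjustment
across all scored chains.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .chains import Chain, ChainQuery, canonicalize, chain_to_string, enumerate_chains
from .network import ExpressionDataset, FunctionalNetwork, InfluenceMatrix

__all__ = [
    "GeneEffects",
    "ActivityTestResult",
    "latent_contributions",
    "estimate_gene_effects",
    "propagate_signs",
    "score_chain",
    "score_all",
    "adjust_bh",
]

#: smallest p-value reported for degenerate zero-variance chains
MIN_P = float(np.finfo(float).tiny)


def latent_contributions(expr: ExpressionDataset, infl: InfluenceMatrix) -> np.ndarray:
    """Latent self-contributions gamma = (I - W) Y, genes x samples.

    ``expr`` must be aligned to the influence matrix's gene order.  A gene
    with no in-links keeps its expression row unchanged.
    """
    if expr.genes != infl.genes:
        raise ValueError("expression gene order does not match the influence matrix")
    return expr.values - infl.matrix @ expr.values


@dataclass
class GeneEffects:
    """Per-gene two-condition effect estimates on the latent scale.

    For each gene: ``delta`` is the condition-B-minus-A mean difference of
    gamma, ``pooled_var`` the pooled within-condition variance and
    ``var_delta = pooled_var * (1/n_A + 1/n_B)``; each gene carries
    ``n_A + n_B - 2`` degrees of freedom.
    """

    genes: tuple[str, ...]
    delta: np.ndarray
    pooled_var: np.ndarray
    var_delta: np.ndarray
    n_A: int
    n_B: int
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._index = {g: i for i, g in enumerate(self.genes)}

    @property
    def df_per_gene(self) -> int:
        return self.n_A + self.n_B - 2

    def for_genes(self, genes: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
        idx = [self._index[g] for g in genes]
        return self.delta[idx], self.var_delta[idx]


def estimate_gene_effects(
    gamma: np.ndarray, expr: ExpressionDataset
) -> GeneEffects:
    """Pooled two-sample estimates of the condition effect per gene.

    delta_hat = mean_B(gamma) - mean_A(gamma);
    pooled_var = (SS_A + SS_B) / (n_A + n_B - 2);
    var(delta_hat) = pooled_var * (1/n_A + 1/n_B).
    """
    mask_a = expr.condition_mask("A")
    mask_b = expr.condition_mask("B")
    A, B = gamma[:, mask_a], gamma[:, mask_b]
    n_a, n_b = A.shape[1], B.shape[1]
    if n_a < 2 or n_b < 2:
        raise ValueError("at least two replicates per condition are required")
    delta = B.mean(axis=1) - A.mean(axis=1)
    ss = ((A - A.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (B - B.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    pooled = ss / (n_a + n_b - 2)
    var_delta = pooled * (1.0 / n_a + 1.0 / n_b)
    return GeneEffects(expr.genes, delta, pooled, var_delta, n_a, n_b)


def propagate_signs(chain: Chain) -> np.ndarray:
    """Signal-flow signs along a chain: +1 at the first gene, flipped by
    every inhibition link (stimulation and interaction preserve the sign)."""
    signs = np.ones(len(chain.genes), dtype=int)
    for j, ln in enumerate(chain.links):
        signs[j + 1] = signs[j] * ln.numeric_sign
    return signs


@dataclass
class ActivityTestResult:
    """Wald-type test of one chain's two-condition activity."""

    chain: Chain
    T: float
    df: int
    p: float
    p_adj: float | None = None
    rank: int | None = None
    degenerate: bool = False

    @property
    def chain_string(self) -> str:
        return chain_to_string(self.chain)


def score_chain(chain: Chain, effects: GeneEffects) -> ActivityTestResult:
    """Score one chain: T = sum_j s_j delta_j / sqrt(sum_j var_j).

    df = k * (n_A + n_B - 2).  Degenerate chains (all variances zero) get
    p = 1 when the contrast is also zero, otherwise the smallest
    representable p and a ``degenerate`` flag.
    """
    delta, var = effects.for_genes(chain.genes)
    signs = propagate_signs(chain)
    contrast = float(signs @ delta)
    total_var = float(var.sum())
    k = len(chain.genes)
    df = k * effects.df_per_gene
    if total_var <= 0.0:
        if contrast == 0.0:
            return ActivityTestResult(chain, 0.0, df, 1.0)
        T = np.inf if contrast > 0 else -np.inf
        return ActivityTestResult(chain, float(T), df, MIN_P, degenerate=True)
    T = contrast / np.sqrt(total_var)
    p = float(2.0 * stats.t.sf(abs(T), df))
    return ActivityTestResult(chain, float(T), df, min(max(p, MIN_P), 1.0))


def adjust_bh(p: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values.

    p_adj[(i)] = min over j >= i of min(1, m * p[(j)] / j) on the sorted
    scale, mapped back to the input order.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
    out = np.empty(m)
    out[order] = adjusted
    return out


def _score_stream(chains: Iterable[Chain], effects: GeneEffects) -> list[ActivityTestResult]:
    return [score_chain(c, effects) for c in chains]


def score_all(
    network: FunctionalNetwork,
    expr: ExpressionDataset,
    infl: InfluenceMatrix,
    query: ChainQuery,
) -> list[ActivityTestResult]:
    """Enumerate, score, BH-adjust and rank every chain matching the query.

    Returns the full ranked list sorted by ascending p, ties broken by
    descending |T| then by the canonical chain string; ranks are 1-based.
    An empty enumeration returns an empty list.
    """
    gamma = latent_contributions(expr, infl)
    effects = estimate_gene_effects(gamma, expr)
    results = _score_stream(enumerate_chains(network, query), effects)
    return rank_results(results)


def rank_results(results: list[ActivityTestResult]) -> list[ActivityTestResult]:
    """Apply BH adjustment over all results, sort and assign ranks in place."""
    if not results:
        return results
    p_adj = adjust_bh([r.p for r in results])
    for r, a in zip(results, p_adj):
        r.p_adj = float(a)
    results.sort(key=lambda r: (r.p, -abs(r.T), chain_to_string(canonicalize(r.chain))))
    for i, r in enumerate(results, start=1):
        r.rank = i
    return results
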