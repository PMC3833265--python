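"""Generative simulator: random networks with a planted active chain.

Data are drawn from the same latent-variable model the scorer assumes:
latent contributions are independent normals with a per-gene baseline, a
condition-B shift of ``delta`` (sign-propagated along the planted chain) on
the planted genes, and noise scale ``sigma``; expression is then
``Y = (I - W)^{-1} gamma``.  Planting the effect on the latent means rather
than on expression keeps the generative and analysis models identical, so
parameter recovery is a fair test of the scorer.

Defaults define the reference study conditions used throughout the test
suite: a 150-gene Erdős–Rényi network of density 0.03, damping 0.5, three
replicates per condition, unit noise, effect size 2 on a 4-link chain.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np

from .chains import Chain
from .network import (
    ExpressionDataset,
    FunctionalNetwork,
    Link,
    build_influence_matrix,
    write_network,
)

__all__ = ["SimulationConfig", "simulate_network", "simulate_expression", "make_fixture_bundle"]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the generative model (all ranges validated)."""

    n_genes: int = 150
    edge_prob: float = 0.03
    frac_directed: float = 0.0
    frac_inhibition: float = 0.25
    damping: float = 0.5
    n_A: int = 3
    n_B: int = 3
    chain_length: int = 4  # links in the planted chain
    delta: float = 2.0  # condition-B latent shift along the chain
    sigma: float = 1.0  # latent noise scale
    n_targets: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < self.chain_length + 2:
            raise ValueError("n_genes must be at least chain_length + 2")
        if not 0.0 <= self.edge_prob <= 1.0:
            raise ValueError("edge_prob must lie in [0, 1]")
        for name in ("frac_directed", "frac_inhibition"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0.0 < self.damping < 1.0:
            raise ValueError("damping must lie in (0, 1)")
        if self.n_A < 2 or self.n_B < 2:
            raise ValueError("at least two replicates per condition are required")
        if self.chain_length < 1:
            raise ValueError("chain_length must be >= 1")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not 1 <= self.n_targets <= self.n_genes:
            raise ValueError("n_targets must lie in [1, n_genes]")


def _gene_name(i: int, width: int) -> str:
    return f"G{i:0{width}d}"


def simulate_network(
    config: SimulationConfig,
) -> tuple[FunctionalNetwork, tuple[str, ...], Chain]:
    """Erdős–Rényi network with one planted simple chain.

    Returns (network, targets, planted_chain).  The chain's genes are
    distinct; links missing from the random graph are added.  The first
    chain gene is always a designated target; further targets (up to
    ``n_targets``) are drawn uniformly from the remaining genes.  Directed
    links on the planted chain are oriented along it so the chain stays
    traversable.  Fully deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    width = max(3, len(str(config.n_genes - 1)))
    genes = [_gene_name(i, width) for i in range(config.n_genes)]
    net = FunctionalNetwork(genes=genes)

    chain_idx = rng.choice(config.n_genes, size=config.chain_length + 1, replace=False)
    chain_genes = [genes[i] for i in chain_idx]
    chain_pairs = set()
    for a, b in zip(chain_genes, chain_genes[1:]):
        chain_pairs.add(frozenset((a, b)))

    def sample_link(a: str, b: str, along_chain: bool) -> Link:
        directed = bool(rng.random() < config.frac_directed)
        if rng.random() < config.frac_inhibition:
            sign = "inhibition"
        else:
            # regulatory links are stimulations; undirected physical links
            # without regulation semantics stay plain interactions
            sign = "stimulation" if directed else "interaction"
        if directed and not along_chain and rng.random() < 0.5:
            a, b = b, a
        return Link(a, b, directed=directed, sign=sign)

    # random background links (upper-triangular Bernoulli draw)
    n = config.n_genes
    mask = np.triu(rng.random((n, n)) < config.edge_prob, k=1)
    for i, j in np.argwhere(mask):
        a, b = genes[int(i)], genes[int(j)]
        if frozenset((a, b)) in chain_pairs:
            continue
        net.add_link(sample_link(a, b, along_chain=False))

    chain_links = []
    for a, b in zip(chain_genes, chain_genes[1:]):
        ln = sample_link(a, b, along_chain=True)
        net.add_link(ln)
        chain_links.append(ln)
    planted = Chain(tuple(chain_genes), tuple(chain_links))

    targets = [chain_genes[0]]
    others = [g for g in genes if g != chain_genes[0]]
    extra = rng.choice(len(others), size=config.n_targets - 1, replace=False)
    targets.extend(others[int(i)] for i in sorted(extra))
    return net, tuple(targets), planted


def simulate_expression(
    network: FunctionalNetwork,
    chain: Chain | None,
    config: SimulationConfig,
    seed: int | None = None,
    return_gamma: bool = False,
):
    """Draw a two-condition expression dataset from the latent model.

    gamma[g, s] ~ Normal(mu_g + 1[s in B] * Delta_g, sigma^2) with
    Delta_g = s_g * delta on the planted chain (s_g the propagated sign) and
    0 elsewhere; Y = (I - W)^{-1} gamma.  Baselines mu_g ~ Normal(0, 1) are
    fixed per gene.  ``seed`` overrides ``config.seed`` (to redraw
    expression on a fixed network).
    """
    from .activity import propagate_signs

    rng = np.random.default_rng(config.seed if seed is None else seed)
    genes = network.genes
    gi = {g: i for i, g in enumerate(genes)}
    n = len(genes)
    shift = np.zeros(n)
    if chain is not None and config.delta != 0.0:
        signs = propagate_signs(chain)
        for g, s in zip(chain.genes, signs):
            shift[gi[g]] = s * config.delta
    mu = rng.standard_normal(n)
    n_s = config.n_A + config.n_B
    samples = tuple(f"s{i + 1}" for i in range(n_s))
    condition = {s: ("A" if i < config.n_A else "B") for i, s in enumerate(samples)}
    means = mu[:, None] + shift[:, None] * np.array(
        [condition[s] == "B" for s in samples], dtype=float
    )
    gamma = means + config.sigma * rng.standard_normal((n, n_s))
    infl = build_influence_matrix(network, damping=config.damping)
    Y = np.linalg.solve(np.eye(n) - infl.matrix, gamma)
    expr = ExpressionDataset(genes, samples, Y, condition)
    if return_gamma:
        return expr, gamma
    return expr


def make_fixture_bundle(config: SimulationConfig, out_dir) -> dict[str, str]:
    """Write a complete synthetic study to ``out_dir``.

    Files: network.tsv, expression.tsv, conditions.tsv, targets.txt and
    planted_chain.txt (the answer key, genes joined by tabs).  All content
    is deterministic under ``config.seed``; returns the path map.
    """
    os.makedirs(out_dir, exist_ok=True)
    net, targets, planted = simulate_network(config)
    expr = simulate_expression(net, planted, config)
    paths = {
        "network": os.path.join(out_dir, "network.tsv"),
        "expression": os.path.join(out_dir, "expression.tsv"),
        "conditions": os.path.join(out_dir, "conditions.tsv"),
        "targets": os.path.join(out_dir, "targets.txt"),
        "planted_chain": os.path.join(out_dir, "planted_chain.txt"),
    }
    write_network(net, paths["network"])
    expr.write_tsv(paths["expression"])
    with open(paths["conditions"], "w", encoding="utf-8") as fh:
        fh.write("sample\tcondition\n")
        for s in expr.samples:
            fh.write(f"{s}\t{expr.condition[s]}\n")
    with open(paths["targets"], "w", encoding="utf-8") as fh:
        fh.writelines(t + "\n" for t in targets)
    with open(paths["planted_chain"], "w", encoding="utf-8") as fh:
        fh.write("\t".join(planted.genes) + "\n")
    return paths
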