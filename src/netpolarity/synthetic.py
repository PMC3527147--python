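"""Synthetic layered signaling networks with confounded gene attributes.

The generator produces the kind of data the polarity analyses are designed
for: a directed, acyclic, layered network (~1000 genes, ~2400 edges,
spanning pure-upstream through pure-downstream positions) together with
per-gene attributes whose causal structure can be controlled exactly.

The default configuration encodes the mediated-polarity scenario: protein
connectivity rises both with a gene's total degree and with its depth in
the network, log-omega falls with connectivity (and, more weakly, with
expression level and breadth), and depth has *no* direct effect on omega
(``delta_position = 0``).  Under these defaults any upstream/downstream
polarity in omega is entirely a byproduct of the confounders — the
situation the confound-control procedures must be able to recognize.
Synonymous divergence dS is independent of everything; dN is defined as
omega * dS so the ratio identity holds exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .attributes import COMPARTMENTS, assemble_attribute_table
from .network import SignalingNetwork, network_from_edges

__all__ = [
    "SyntheticConfig",
    "SyntheticDataset",
    "generate_network",
    "generate_attributes",
    "generate_dataset",
    "generate_null_dataset",
    "write_dataset",
]


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic generator.

    Effect sizes are standardized: each operates on a z-scored predictor,
    so e.g. ``beta_connectivity = 0.5`` means one standard deviation of
    log-connectivity shifts log-omega by -0.5.

    Attributes
    ----------
    n_genes, n_layers : int
        Network size and number of hierarchy layers.
    edge_density : float
        Expected directed edges per gene.
    p_skip : float
        Probability that an edge skips past the adjacent layer.
    beta_connectivity, beta_level, beta_breadth : float
        Negative standardized effects of log-connectivity, log-expression
        level, and expression breadth on log-omega.
    delta_position : float
        Direct standardized effect of layer depth on log-omega (0 = the
        polarity, if any, is purely mediated).
    gamma_degree : float
        Coupling of log-connectivity to the gene's z-scored total degree.
    kappa_depth : float
        Coupling of log-connectivity to z-scored depth (downstream genes
        encode more highly connected proteins).
    alpha_level, alpha_breadth : float
        Couplings of log-expression level and of breadth (on the logit
        scale) to z-scored depth.
    sigma : float
        Residual standard deviation of log-omega.
    sigma_connectivity, sigma_level : float
        Residual standard deviations of log-connectivity and log-level.
    missing_rates : mapping
        Per-field probability that a gene's value is masked to missing.
    seed : int
        Seed for the generator's random stream.
    """

    n_genes: int = 1000
    n_layers: int = 6
    edge_density: float = 2.4
    p_skip: float = 0.3
    beta_connectivity: float = 0.5
    beta_level: float = 0.15
    beta_breadth: float = 0.2
    delta_position: float = 0.0
    gamma_degree: float = 0.5
    kappa_depth: float = 0.5
    alpha_level: float = 0.3
    alpha_breadth: float = 0.3
    sigma: float = 1.0
    sigma_connectivity: float = 0.6
    sigma_level: float = 1.0
    n_tissues: int = 25
    mu_omega: float = -2.6
    mu_connectivity: float = 2.3
    mu_level: float = 3.9
    mu_dS: float = -0.55
    sigma_dS: float = 0.35
    missing_rates: dict[str, float] = field(default_factory=lambda: {
        "connectivity": 0.09, "expr_level": 0.03, "expr_breadth": 0.03,
    })
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_layers < 2:
            raise ValueError("n_layers must be >= 2")
        if self.edge_density <= 0:
            raise ValueError("edge_density must be positive")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not 0 <= self.p_skip <= 1:
            raise ValueError("p_skip must lie in [0, 1]")


@dataclass
class SyntheticDataset:
    """A generated network, its attribute table, and the generating truth."""

    network: SignalingNetwork
    attributes: pd.DataFrame
    layers: dict[str, int]
    config: SyntheticConfig

    @property
    def truth(self) -> pd.DataFrame:
        t = pd.DataFrame({"layer": pd.Series(self.layers)})
        t.index.name = "gene"
        return t.sort_index()


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x, dtype=float)
    return (x - x.mean()) / sd


def _gene_names(n: int) -> list[str]:
    width = len(str(n - 1))
    return [f"G{i:0{width}d}" for i in range(n)]


def generate_network(
    config: SyntheticConfig, rng: np.random.Generator,
) -> tuple[SignalingNetwork, dict[str, int]]:
    """Draw a layered acyclic network; returns the network and gene layers.

    Genes are assigned uniformly to layers 1..L.  Each edge starts at a
    uniformly chosen gene above the bottom layer and ends in the adjacent
    deeper layer with probability ``1 - p_skip``, otherwise in a uniformly
    chosen deeper layer.  Distinct ordered pairs accumulate until the
    expected density ``edge_density * n_genes`` is reached (or the pair
    space near-saturates, with a warning).  Edges always point to deeper
    layers, so the graph is acyclic and every top-layer gene with an edge is
    pure-upstream, every bottom-layer gene with an edge pure-downstream.
    """
    n, L = config.n_genes, config.n_layers
    names = _gene_names(n)
    layer_arr = rng.integers(1, L + 1, size=n)
    # ensure no layer is empty so the full upstream..downstream span exists
    for lay in range(1, L + 1):
        if not np.any(layer_arr == lay):
            layer_arr[rng.integers(0, n)] = lay

    by_layer = {lay: np.flatnonzero(layer_arr == lay) for lay in range(1, L + 1)}
    sources = np.flatnonzero(layer_arr < L)
    target_edges = int(round(config.edge_density * n))
    edges: set[tuple[int, int]] = set()
    attempts = 0
    max_attempts = 50 * target_edges + 1000
    while len(edges) < target_edges and attempts < max_attempts:
        batch = target_edges - len(edges)
        attempts += batch
        src = rng.choice(sources, size=batch)
        skip = rng.random(batch) < config.p_skip
        for s, sk in zip(src, skip):
            s_lay = layer_arr[s]
            if sk:
                t_lay = int(rng.integers(s_lay + 1, L + 1))
            else:
                t_lay = s_lay + 1
            t = int(rng.choice(by_layer[t_lay]))
            edges.add((int(s), t))
    if len(edges) < target_edges:
        import warnings
        warnings.warn(
            f"requested density unreachable: achieved {len(edges)} of "
            f"{target_edges} edges", stacklevel=2)
    # guarantee at least one pure-upstream and one pure-downstream gene
    if not any(layer_arr[s] == 1 for s, _ in edges) or \
            not any(layer_arr[t] == L for _, t in edges):
        s = int(rng.choice(by_layer[1]))
        t = int(rng.choice(by_layer[L]))
        edges.add((s, t))

    net = network_from_edges(
        [(names[s], names[t], "unspecified") for s, t in sorted(edges)],
        nodes=names)
    layers = {names[i]: int(layer_arr[i]) for i in range(n)}
    return net, layers


def generate_attributes(
    network: SignalingNetwork,
    layers: Mapping[str, int],
    config: SyntheticConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Draw the per-gene attribute table given the network and layers.

    See the module docstring for the causal structure.  Standardizations
    use the realized sample moments, so effect sizes are comparable across
    configurations.
    """
    genes = sorted(network.nodes)
    missing = [g for g in genes if g not in layers]
    if missing:
        raise KeyError(f"layers missing for genes: {missing[:5]}")
    n = len(genes)
    g = network.graph
    depth = np.array([layers[x] for x in genes], dtype=float)
    total_deg = np.array([g.in_degree(x) + g.out_degree(x) for x in genes],
                         dtype=float)
    z_depth = _zscore(depth)
    z_deg = _zscore(total_deg)

    log_conn = (config.mu_connectivity
                + config.gamma_degree * z_deg
                + config.kappa_depth * z_depth
                + rng.normal(0.0, config.sigma_connectivity, n))
    connectivity = np.maximum(np.round(np.exp(log_conn)), 0.0)

    log_level = (config.mu_level
                 + config.alpha_level * z_depth
                 + rng.normal(0.0, config.sigma_level, n))
    expr_level = np.exp(log_level)

    p_expr = 1.0 / (1.0 + np.exp(-(config.alpha_breadth * z_depth)))
    expr_breadth = rng.binomial(config.n_tissues, p_expr).astype(float)

    log_omega = (config.mu_omega
                 - config.beta_connectivity * _zscore(np.log1p(connectivity))
                 - config.beta_level * _zscore(log_level)
                 - config.beta_breadth * _zscore(expr_breadth)
                 + config.delta_position * z_depth
                 + rng.normal(0.0, config.sigma, n))
    omega = np.exp(log_omega)

    dS = np.exp(rng.normal(config.mu_dS, config.sigma_dS, n))
    dN = omega * dS

    enc = np.clip(rng.normal(50.0, 3.0, n), 20.0, 61.0)
    n_paralogs = rng.poisson(5.0, n).astype(float)
    possel_p = rng.uniform(0.0, 1.0, n)

    comp_rates = {"extracellular": 0.10, "membrane": 0.36,
                  "cytoplasm": 0.54, "nucleus": 0.43}
    draws = {c: rng.random(n) < comp_rates[c] for c in COMPARTMENTS}
    compartments = {
        genes[i]: frozenset(c for c in COMPARTMENTS if draws[c][i])
        for i in range(n)
    }

    fields = {
        "omega": omega, "dN": dN, "dS": dS, "expr_level": expr_level,
        "expr_breadth": expr_breadth, "enc": enc,
        "connectivity": connectivity, "n_paralogs": n_paralogs,
        "possel_p": possel_p,
    }
    for name, rate in config.missing_rates.items():
        if name not in fields or rate <= 0:
            continue
        mask = rng.random(n) < rate
        fields[name] = np.where(mask, np.nan, fields[name])

    def m(arr: np.ndarray) -> dict[str, float]:
        return {genes[i]: float(arr[i]) for i in range(n)
                if not np.isnan(arr[i])}

    expression = pd.DataFrame(
        {"expr_level": pd.Series(m(fields["expr_level"])),
         "expr_breadth": pd.Series(m(fields["expr_breadth"]))})
    expression.index.name = "gene"
    return assemble_attribute_table(
        genes,
        omega=m(fields["omega"]), dN=m(fields["dN"]), dS=m(fields["dS"]),
        expression=expression, enc=m(fields["enc"]),
        connectivity=m(fields["connectivity"]),
        n_paralogs=m(fields["n_paralogs"]),
        compartments=compartments, possel_p=m(fields["possel_p"]),
    )


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Generate a full dataset (network + attributes) from a config.

    The dataset is a pure function of the config, including its seed.
    """
    rng = np.random.default_rng(config.seed)
    network, layers = generate_network(config, rng)
    attributes = generate_attributes(network, layers, config, rng)
    return SyntheticDataset(network, attributes, layers, config)


def generate_null_dataset(n_genes: int = 1000, seed: int = 0) -> SyntheticDataset:
    """Dataset with every coupling zero: attributes independent of position.

    Used by the type-I-error suites: any polarity test applied to such data
    should reject at its nominal rate.
    """
    if n_genes < 20:
        raise ValueError("n_genes must be >= 20")
    config = SyntheticConfig(
        n_genes=n_genes,
        beta_connectivity=0.0, beta_level=0.0, beta_breadth=0.0,
        delta_position=0.0, gamma_degree=0.0, kappa_depth=0.0,
        alpha_level=0.0, alpha_breadth=0.0, seed=seed)
    return generate_dataset(config)


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write edge list, attribute table and truth file as TSV."""
    from .attributes import write_attribute_table
    from .network import write_edge_list

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "network": outdir / "network.tsv",
        "attributes": outdir / "attributes.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_edge_list(dataset.network, paths["network"])
    write_attribute_table(dataset.attributes, paths["attributes"])
    truth = dataset.truth
    for key, val in asdict(dataset.config).items():
        if key == "missing_rates":
            continue
        truth[key] = val
    truth.to_csv(paths["truth"], sep="\t")
    return paths
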