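"""Synthetic data with planted, recoverable structure for every stage.

The generators emulate the shape of an ocean survey dataset: a sparse,
heavy-tailed marker-gene count table over ~59 photic-zone samples with a
linear carbon-export-efficiency signal planted in CLR space; a viral
phylogeny containing clades whose members co-occur with a designated host
taxon; and a trait table in which a chosen virus group's network partners
are enriched for one functional trait. Every generator is deterministic
under a fixed seed, and ground truth (true predictors, planted clade roots,
biased trait) is returned as sidecar records, never embedded in the inputs
themselves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import dendropy
import numpy as np
import pandas as pd

from .compositional import (
    AbundanceMatrix,
    clr_transform,
    closure_partition,
    length_normalize,
)
from .errors import DataError, ParameterError

_RESPONSES = ("CEE", "CE150", "NPP", "T100")


@dataclass
class SyntheticScenario:
    """Parameters of one simulated survey.

    ``marker_class_mix`` gives the proportions of PolB/RdRP/Rep markers
    (default mirrors the composition of a filtered marker set dominated by
    NCLDV PolB genes). ``sparsity`` is the per-cell dropout probability.
    Exactly one of ``noise_sd`` (response noise standard deviation) or
    ``target_r2`` (population R2 of the generating linear model; noise
    variance is then derived from the realized planted-signal variance)
    must be set. ``baseline`` shifts the response so the export-efficiency
    ratio stays in a physically plausible positive range.
    """

    n_samples: int = 59
    n_markers: int = 1500
    marker_class_mix: tuple[float, float, float] = (0.86, 0.12, 0.02)
    sparsity: float = 0.6
    n_true_predictors: int = 10
    effect_sizes: tuple[float, ...] | None = None
    noise_sd: float | None = None
    target_r2: float | None = 0.7
    baseline: float = 1.0
    shared_responses: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 3:
            raise ParameterError("n_samples must be at least 3")
        if self.n_markers < 1:
            raise ParameterError("n_markers must be positive")
        mix = np.asarray(self.marker_class_mix, dtype=float)
        if mix.size != 3 or (mix < 0).any() or abs(mix.sum() - 1.0) > 1e-9:
            raise ParameterError(
                "marker_class_mix must be 3 non-negative proportions summing to 1"
            )
        if not 0.0 <= self.sparsity < 1.0:
            raise ParameterError("sparsity must lie in [0, 1)")
        if not 0 <= self.n_true_predictors <= self.n_markers:
            raise ParameterError("n_true_predictors must not exceed n_markers")
        if self.effect_sizes is not None and (
            len(self.effect_sizes) != self.n_true_predictors
        ):
            raise ParameterError(
                "effect_sizes must have one entry per true predictor"
            )
        if (self.noise_sd is None) == (self.target_r2 is None):
            raise ParameterError("set exactly one of noise_sd and target_r2")
        if self.noise_sd is not None and self.noise_sd < 0:
            raise ParameterError("noise_sd must be non-negative")
        if self.target_r2 is not None and not 0.0 < self.target_r2 < 1.0:
            raise ParameterError("target_r2 must lie in (0, 1)")
        for resp in self.shared_responses:
            if resp not in _RESPONSES[1:]:
                raise ParameterError(
                    f"shared_responses entries must be among {_RESPONSES[1:]}"
                )

    @property
    def betas(self) -> np.ndarray:
        """Signed effect sizes; default alternates +1/-1."""
        if self.effect_sizes is not None:
            return np.asarray(self.effect_sizes, dtype=float)
        k = self.n_true_predictors
        return np.where(np.arange(k) % 2 == 0, 1.0, -1.0)


def _rng_for(scenario: SyntheticScenario, stage: int) -> np.random.Generator:
    """Independent substream per stage so stages do not perturb each other."""
    return np.random.default_rng(
        np.random.SeedSequence(scenario.seed).spawn(8)[stage]
    )


def generate_community(scenario: SyntheticScenario) -> AbundanceMatrix:
    """Sparse marker x sample read counts.

    Relative abundances come from a log-normal field (per-marker mean plus
    per-cell variation), thinned by a Bernoulli dropout process with the
    scenario's sparsity; reads are drawn per sample from a Poisson at the
    sample's library size (log-uniform in [5e4, 5e5]). Cells that survived
    dropout are floored at one read, so the realized zero fraction equals
    the dropout rate and a sparsity of 0 yields a dense matrix.
    """
    rng = _rng_for(scenario, 0)
    n, m = scenario.n_markers, scenario.n_samples
    mix = np.asarray(scenario.marker_class_mix, dtype=float)
    n_per_class = np.floor(mix * n).astype(int)
    n_per_class[0] += n - n_per_class.sum()
    classes = np.repeat(["PolB", "RdRP", "Rep"], n_per_class)
    ids = [f"{cls}_{i:06d}" for i, cls in enumerate(classes)]
    lengths = rng.integers(600, 3001, size=n)

    base = rng.normal(0.0, 1.0, size=n)
    log_field = base[:, None] + rng.normal(0.0, 1.0, size=(n, m))
    keep = rng.random((n, m)) >= scenario.sparsity
    # every sequencing library yields at least one read per marker catalog,
    # so each CLR closure group stays non-degenerate in every sample
    for group_mask in (classes == "PolB", np.isin(classes, ["RdRP", "Rep"])):
        idx = np.flatnonzero(group_mask)
        if idx.size == 0:
            continue
        empty = ~keep[idx].any(axis=0)
        keep[idx[0], empty] = True
    rel = np.where(keep, np.exp(log_field), 0.0)
    rel = rel / rel.sum(axis=0, keepdims=True)
    libs = np.exp(rng.uniform(np.log(5e4), np.log(5e5), size=m))
    counts = rng.poisson(rel * libs[None, :])
    counts = np.where(keep & (counts == 0), 1, counts)
    return AbundanceMatrix(
        counts=pd.DataFrame(
            counts,
            index=pd.Index(ids, name="marker_id"),
            columns=[f"S{j:03d}" for j in range(m)],
        ),
        marker_class=pd.Series(classes, index=ids),
        gene_length=pd.Series(lengths, index=ids),
    )


class PlantedResponse(NamedTuple):
    metadata: pd.DataFrame
    truth: pd.DataFrame


def plant_response(
    abundance: AbundanceMatrix, scenario: SyntheticScenario
) -> PlantedResponse:
    """Sample metadata with a linear CLR-space response planted in it.

    CEE_i = baseline + sum_j beta_j clr_ij + eps_i with eps ~ N(0, sd),
    using the same CLR convention as the compositional module (per-library
    closure, half-min pseudocount). True predictors are drawn among markers
    present (>= 2 reads) in at least half the samples, so the planted
    signal is recoverable rather than erased by dropout. CE_surface is set
    to 1 and CE_deep to CEE, so the export-efficiency ratio round-trips
    exactly. Secondary responses (CE150, NPP, T100) are independent noise
    unless listed in ``shared_responses``, in which case they reuse the
    planted predictors with fresh noise.

    Returns the metadata table and a truth sidecar listing the true
    predictors with their coefficients.
    """
    if (
        abundance.counts.shape[0] != scenario.n_markers
        or abundance.counts.shape[1] != scenario.n_samples
    ):
        raise DataError(
            "abundance matrix shape does not match the scenario "
            f"({abundance.counts.shape} vs "
            f"({scenario.n_markers}, {scenario.n_samples}))"
        )
    rng = _rng_for(scenario, 1)
    rel = clr_transform(
        length_normalize(abundance), closure_partition(abundance)
    )
    prevalent = abundance.markers[
        (abundance.counts >= 2).sum(axis=1) >= scenario.n_samples // 2
    ]
    pool = prevalent if len(prevalent) >= scenario.n_true_predictors else (
        abundance.markers
    )
    chosen = pd.Index(
        sorted(rng.choice(pool, size=scenario.n_true_predictors, replace=False))
    )
    betas = scenario.betas
    signal = betas @ rel.values.loc[chosen].to_numpy()

    if scenario.noise_sd is not None:
        noise_sd = scenario.noise_sd
    else:
        var_sig = float(np.var(signal, ddof=1)) if signal.size else 0.0
        noise_sd = np.sqrt(
            var_sig * (1.0 - scenario.target_r2) / scenario.target_r2
        )
    eps = rng.normal(0.0, noise_sd, size=scenario.n_samples)
    cee = scenario.baseline + signal + eps

    meta = pd.DataFrame(index=abundance.samples.rename("sample_id"))
    meta["station"] = [f"ST{j // 2:02d}" for j in range(scenario.n_samples)]
    meta["depth_layer"] = [
        "SRF" if j % 2 == 0 else "DCM" for j in range(scenario.n_samples)
    ]
    meta["CE_surface"] = 1.0
    meta["CE_deep"] = cee
    meta["CEE"] = cee
    for resp in ("CE150", "NPP", "T100"):
        if resp in scenario.shared_responses:
            meta[resp] = (
                scenario.baseline
                + signal
                + rng.normal(0.0, noise_sd, size=scenario.n_samples)
            )
        else:
            meta[resp] = rng.normal(
                scenario.baseline, 1.0, size=scenario.n_samples
            )
    truth = pd.DataFrame(
        {
            "marker_id": chosen,
            "beta": betas,
            "is_true_predictor": True,
        }
    )
    return PlantedResponse(metadata=meta, truth=truth)


def simulate_survey(scenario: SyntheticScenario):
    """Convenience wrapper: community plus planted response."""
    abundance = generate_community(scenario)
    planted = plant_response(abundance, scenario)
    return abundance, planted.metadata, planted.truth


class TreeNetwork(NamedTuple):
    tree: dendropy.Tree
    edges: pd.DataFrame
    taxonomy: pd.DataFrame
    planted_nodes: list


def _join_random_binary(nodes, rng) -> dendropy.Node:
    """Random binary topology by repeated pairwise joins."""
    nodes = list(nodes)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        parent = dendropy.Node()
        parent.add_child(left)
        parent.add_child(right)
        left.edge.length = float(rng.exponential(0.1)) + 0.01
        right.edge.length = float(rng.exponential(0.1)) + 0.01
        nodes.append(parent)
    return nodes[0]


def generate_tree_network(
    n_leaves: int,
    taxa: Sequence[str],
    planted: Sequence[tuple[int, str]] = (),
    background_edge_rate: float = 0.1,
    seed: int = 0,
    n_otus_per_taxon: int = 30,
    planted_edge_prob: float = 0.9,
) -> TreeNetwork:
    """Viral tree plus bipartite virus-eukaryote co-occurrence edges.

    Builds a random binary tree over ``n_leaves`` viral leaves in which each
    ``(clade_size, taxon)`` pair in ``planted`` becomes one monophyletic
    clade whose leaves get an edge to a random OTU of that taxon with
    probability ``planted_edge_prob``; independently, every leaf gets a
    background edge to a random OTU of a random taxon with probability
    ``background_edge_rate``. Internal nodes receive stable preorder labels
    and the planted clade root labels are returned as ground truth.
    """
    if not 0.0 <= background_edge_rate <= 1.0:
        raise ParameterError("background_edge_rate must lie in [0, 1]")
    sizes = [size for size, _ in planted]
    if any(s < 1 for s in sizes):
        raise ParameterError("planted clade sizes must be positive")
    if sum(sizes) > n_leaves:
        raise ParameterError(
            f"planted clades need {sum(sizes)} leaves but only "
            f"{n_leaves} are available"
        )
    for _, taxon in planted:
        if taxon not in taxa:
            raise ParameterError(f"planted taxon {taxon!r} not in taxa list")
    rng = np.random.default_rng(seed)
    tns = dendropy.TaxonNamespace()
    leaf_labels = [f"virus_{i:04d}" for i in range(n_leaves)]
    leaves = []
    for lab in leaf_labels:
        taxon = dendropy.Taxon(label=lab)
        tns.add_taxon(taxon)
        node = dendropy.Node(taxon=taxon)
        leaves.append(node)

    cursor = 0
    units = []
    clade_roots = []
    for size, _taxon in planted:
        sub = _join_random_binary(leaves[cursor : cursor + size], rng)
        units.append(sub)
        clade_roots.append(sub)
        cursor += size
    units.extend(leaves[cursor:])
    root = _join_random_binary(units, rng)
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = True
    counter = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        node.label = f"node{counter:04d}"
        counter += 1
    planted_nodes = [node.label for node in clade_roots if not node.is_leaf()]

    otus = {
        taxon: [f"{taxon}_otu{k:03d}" for k in range(n_otus_per_taxon)]
        for taxon in taxa
    }
    records = []
    cursor = 0
    for size, taxon in planted:
        for lab in leaf_labels[cursor : cursor + size]:
            if rng.random() < planted_edge_prob:
                records.append((lab, otus[taxon][rng.integers(n_otus_per_taxon)]))
        cursor += size
    for lab in leaf_labels:
        if rng.random() < background_edge_rate:
            taxon = taxa[rng.integers(len(taxa))]
            records.append((lab, otus[taxon][rng.integers(n_otus_per_taxon)]))
    edges = pd.DataFrame(records, columns=["virus_id", "eukaryote_otu_id"])
    taxonomy = pd.DataFrame(
        [(otu, taxon) for taxon in taxa for otu in otus[taxon]],
        columns=["eukaryote_otu_id", "taxon"],
    )
    return TreeNetwork(
        tree=tree, edges=edges, taxonomy=taxonomy, planted_nodes=planted_nodes
    )


def generate_trait_table(
    otus: Sequence[str],
    trait_rates: dict[str, float],
    biased_set: Sequence[str] = (),
    bias_factor: float = 1.0,
    biased_trait: str | None = None,
    seed: int = 0,
    na_rate: float = 0.0,
) -> pd.DataFrame:
    """Bernoulli presence/absence trait table with one optionally biased trait.

    OTUs in ``biased_set`` receive probability ``rate * bias_factor`` for
    ``biased_trait``; everyone else (and every other trait) uses the base
    rate. ``na_rate`` converts a random fraction of entries to missing.
    """
    for trait, rate in trait_rates.items():
        if not 0.0 <= rate <= 1.0:
            raise ParameterError(f"rate for {trait!r} must lie in [0, 1]")
    if biased_trait is not None:
        if biased_trait not in trait_rates:
            raise ParameterError(f"biased trait {biased_trait!r} has no rate")
        if not 0.0 <= trait_rates[biased_trait] * bias_factor <= 1.0:
            raise ParameterError("rate * bias_factor must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    otus = list(otus)
    biased = set(biased_set)
    table = pd.DataFrame(index=pd.Index(otus, name="eukaryote_otu_id"))
    for trait, rate in trait_rates.items():
        probs = np.full(len(otus), rate)
        if biased_trait == trait and biased:
            probs[[o in biased for o in otus]] = rate * bias_factor
        vals = (rng.random(len(otus)) < probs).astype(float)
        if na_rate > 0:
            vals[rng.random(len(otus)) < na_rate] = np.nan
        table[trait] = vals
    return table
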