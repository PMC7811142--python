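"""Phylogeny-guided, network-based virus host prediction.

Each viral leaf of a marker-gene phylogeny is annotated with the set of
eukaryotic orders of its co-occurrence-network partners. For every internal
node with enough annotated descendant leaves, and every taxon observed
below it, a one-sided Fisher exact test (hypergeometric upper tail) asks
whether leaves under the node carry that taxon more often than the rest of
the tree; Benjamini-Hochberg correction is applied across the full grid of
executed (node, taxon) tests. Significant nodes that have another
significant node for the same taxon among their ancestors or descendants
are flagged as parent-to-child repeats, so the per-taxon summary can count
independent detections.

Leaves with no annotated partner are excluded from both margins of every
test: they would only inflate the totals identically for all taxa.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, ParameterError, VirofluxError
from .traits import bh_adjust

logger = logging.getLogger(__name__)


class UnrootedTreeError(VirofluxError):
    """Raised when a scan is attempted on an unrooted tree."""


ENRICHMENT_COLUMNS = [
    "node_id", "taxon", "k", "n", "K", "N", "n_leaves_total", "p", "q",
    "significant", "has_parent_child",
]


def leaf_taxon_profile(
    edges: pd.DataFrame, taxonomy: pd.DataFrame
) -> dict[str, frozenset]:
    """Map each virus leaf to the set of partner taxa.

    A leaf carries taxon ``t`` iff it has at least one network edge to an
    OTU annotated ``t``; duplicate edges are merged first (logged), and
    partners without annotation contribute nothing.
    """
    required = {"virus_id", "eukaryote_otu_id"}
    if not required.issubset(edges.columns):
        raise DataError(
            f"edge list must have columns {sorted(required)}"
        )
    dedup = edges.drop_duplicates(subset=["virus_id", "eukaryote_otu_id"])
    if len(dedup) < len(edges):
        logger.info(
            "merged %d duplicate co-occurrence edges", len(edges) - len(dedup)
        )
    annot = taxonomy.set_index("eukaryote_otu_id")["taxon"]
    annot = annot[annot.astype(str).str.len() > 0]
    merged = dedup.join(annot, on="eukaryote_otu_id")
    profiles: dict[str, frozenset] = {}
    for virus, grp in merged.groupby("virus_id"):
        taxa = frozenset(grp["taxon"].dropna())
        profiles[str(virus)] = taxa
    return profiles


def midpoint_root(tree: dendropy.Tree) -> dendropy.Tree:
    """Deterministically midpoint-root a tree in place and relabel nodes."""
    tree.encode_bipartitions()
    tree.reroot_at_midpoint(update_bipartitions=True)
    tree.is_rooted = True
    _ensure_node_labels(tree, force=True)
    return tree


def _ensure_node_labels(tree: dendropy.Tree, force: bool = False) -> None:
    counter = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        if force or not node.label:
            node.label = f"node{counter:04d}"
        counter += 1


def node_enrichment_scan(
    tree: dendropy.Tree,
    profiles: dict[str, frozenset],
    min_leaves: int = 3,
    alpha: float = 0.05,
    direction: str = "greater",
) -> pd.DataFrame:
    """Fisher scan of every (internal node, taxon) pair.

    For each internal node with at least ``min_leaves`` annotated
    descendant leaves and each taxon present in some descendant profile,
    the 2x2 table (under node vs rest) x (carries taxon vs not), restricted
    to annotated leaves, is tested one-sided for enrichment
    (``direction="greater"``, hypergeometric upper tail) or two-sided
    (``direction="two-sided"``). Q-values are Benjamini-Hochberg over all
    executed tests; ``significant`` marks Q <= alpha.

    Returns the full test table (all executed tests), so callers can filter
    to significant rows or inspect the near-misses.
    """
    if not tree.is_rooted:
        raise UnrootedTreeError(
            "tree is unrooted; midpoint-root it first (viroflux.host_prediction"
            ".midpoint_root) or use predict_hosts which does so automatically"
        )
    if direction not in ("greater", "two-sided"):
        raise ParameterError(f"unknown test direction {direction!r}")
    _ensure_node_labels(tree)
    leaf_taxa = {}
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label if leaf.taxon else leaf.label
        taxa = profiles.get(label, frozenset())
        if taxa:
            leaf_taxa[label] = taxa
    if not leaf_taxa:
        logger.warning("no annotated leaves; empty enrichment scan")
        return pd.DataFrame(columns=ENRICHMENT_COLUMNS)
    N = len(leaf_taxa)
    all_taxa = sorted(set().union(*leaf_taxa.values()))
    K = {t: sum(t in s for s in leaf_taxa.values()) for t in all_taxa}

    rows = []
    for node in tree.preorder_internal_node_iter():
        under = [
            (lf.taxon.label if lf.taxon else lf.label)
            for lf in node.leaf_iter()
        ]
        annotated = [l for l in under if l in leaf_taxa]
        n = len(annotated)
        if n < min_leaves:
            continue
        local_taxa = sorted(set().union(*(leaf_taxa[l] for l in annotated)))
        for t in local_taxa:
            k = sum(t in leaf_taxa[l] for l in annotated)
            if direction == "greater":
                p = float(stats.hypergeom.sf(k - 1, N, K[t], n))
            else:
                table = [[k, n - k], [K[t] - k, (N - n) - (K[t] - k)]]
                p = float(stats.fisher_exact(table, alternative="two-sided")[1])
            rows.append(
                {
                    "node_id": node.label, "taxon": t,
                    "k": k, "n": n, "K": K[t], "N": N,
                    "n_leaves_total": len(under), "p": min(p, 1.0),
                }
            )
    result = pd.DataFrame(rows)
    if result.empty:
        return pd.DataFrame(columns=ENRICHMENT_COLUMNS)
    result["q"] = bh_adjust(result["p"].to_numpy())
    result["significant"] = result["q"] <= alpha
    result["has_parent_child"] = False
    return result[ENRICHMENT_COLUMNS]


def rank_enrichments(enrichments: pd.DataFrame) -> pd.DataFrame:
    """Order a scan by evidence, most specific node first on ties.

    An enriched clade and its ancestors share the same contingency table as
    long as the leaves separating them carry no annotation, so p and Q tie
    exactly; ranking then prefers the node with the fewest total leaves —
    the most specific clade compatible with the signal.
    """
    return enrichments.sort_values(
        ["q", "p", "n_leaves_total", "node_id"], kind="mergesort"
    ).reset_index(drop=True)


def flag_parent_child(
    enrichments: pd.DataFrame, tree: dendropy.Tree
) -> pd.DataFrame:
    """Mark significant records repeated along an ancestor-descendant line.

    A significant record is flagged iff another *significant* record for the
    same taxon sits on a node that is an ancestor or a descendant of its
    node. Returns a copy with ``has_parent_child`` filled in.
    """
    out = enrichments.copy()
    if out.empty:
        return out
    nodes = {
        node.label: node
        for node in tree.preorder_internal_node_iter()
    }
    missing = set(out["node_id"]) - set(nodes)
    if missing:
        raise DataError(f"node ids not present in tree: {sorted(missing)[:3]}")
    ancestors: dict[str, set] = {}
    for label, node in nodes.items():
        anc = set()
        cur = node.parent_node
        while cur is not None:
            if cur.label:
                anc.add(cur.label)
            cur = cur.parent_node
        ancestors[label] = anc

    out["has_parent_child"] = False
    sig = out[out["significant"]]
    for taxon, grp in sig.groupby("taxon"):
        labels = list(grp["node_id"])
        flagged = set()
        for i, a in enumerate(labels):
            for b in labels[i + 1 :]:
                if a in ancestors[b] or b in ancestors[a]:
                    flagged.add(a)
                    flagged.add(b)
        mask = (out["taxon"] == taxon) & out["node_id"].isin(flagged)
        out.loc[mask, "has_parent_child"] = True
    return out


@dataclass
class HostPredictionResult:
    """Full scan table plus the per-taxon detection summary."""

    enrichments: pd.DataFrame
    summary: pd.DataFrame
    n_annotated_leaves: int
    rooted_by_midpoint: bool = False

    @property
    def significant(self) -> pd.DataFrame:
        return self.enrichments[self.enrichments["significant"]]


SUMMARY_COLUMNS = ["taxon", "n_nodes", "n_independent", "n_lineages"]


def summarize_by_taxon(
    enrichments: pd.DataFrame, tree: dendropy.Tree | None = None
) -> pd.DataFrame:
    """Per-taxon counts of significant nodes and independent detections.

    ``n_independent`` counts significant nodes without a parent-to-child
    relationship to another significant node for the same taxon — the
    "detected at N nodes (M of them had no parent-to-child relationships)"
    summary shape. A clade detected together with several of its nested
    sub- or super-clades contributes many nodes but zero unflagged ones, so
    ``n_lineages`` additionally counts the connected ancestor-descendant
    components among the significant nodes — the number of distinct clades
    supporting the taxon (requires ``tree``; NaN otherwise).
    """
    sig = enrichments[enrichments["significant"]]
    if sig.empty:
        return pd.DataFrame(columns=SUMMARY_COLUMNS)
    ancestors: dict[str, set] = {}
    if tree is not None:
        nodes = {nd.label: nd for nd in tree.preorder_internal_node_iter()}
        for label, node in nodes.items():
            anc = set()
            cur = node.parent_node
            while cur is not None:
                if cur.label:
                    anc.add(cur.label)
                cur = cur.parent_node
            ancestors[label] = anc
    rows = []
    for taxon, grp in sig.groupby("taxon"):
        labels = list(grp["node_id"])
        if tree is not None:
            parent = {l: l for l in labels}

            def find(x):
                while parent[x] != x:
                    parent[x] = parent[parent[x]]
                    x = parent[x]
                return x

            for i, a in enumerate(labels):
                for b in labels[i + 1 :]:
                    if a in ancestors[b] or b in ancestors[a]:
                        parent[find(a)] = find(b)
            n_lineages = len({find(l) for l in labels})
        else:
            n_lineages = np.nan
        rows.append(
            {
                "taxon": taxon,
                "n_nodes": len(grp),
                "n_independent": int((~grp["has_parent_child"]).sum()),
                "n_lineages": n_lineages,
            }
        )
    return (
        pd.DataFrame(rows)
        .sort_values(["n_nodes", "taxon"], ascending=[False, True])
        .reset_index(drop=True)
    )


def predict_hosts(
    tree: dendropy.Tree,
    edges: pd.DataFrame,
    taxonomy: pd.DataFrame,
    min_leaves: int = 3,
    alpha: float = 0.05,
    direction: str = "greater",
) -> HostPredictionResult:
    """End-to-end host prediction: root, profile, scan, flag, summarize."""
    rooted_by_midpoint = False
    if not tree.is_rooted:
        logger.info("input tree unrooted; applying midpoint rooting")
        midpoint_root(tree)
        rooted_by_midpoint = True
    if edges.empty:
        logger.warning("empty co-occurrence edge list; no host predictions")
        return HostPredictionResult(
            enrichments=pd.DataFrame(columns=ENRICHMENT_COLUMNS),
            summary=pd.DataFrame(columns=SUMMARY_COLUMNS),
            n_annotated_leaves=0,
            rooted_by_midpoint=rooted_by_midpoint,
        )
    profiles = leaf_taxon_profile(edges, taxonomy)
    tree_leaves = {
        (lf.taxon.label if lf.taxon else lf.label)
        for lf in tree.leaf_node_iter()
    }
    missing = set(profiles) - tree_leaves
    if missing:
        logger.warning(
            "%d network viruses absent from the tree (e.g. %s)",
            len(missing), sorted(missing)[0],
        )
    enrich = node_enrichment_scan(
        tree, profiles, min_leaves=min_leaves, alpha=alpha, direction=direction
    )
    enrich = flag_parent_child(enrich, tree)
    n_annot = len(
        [l for l in tree_leaves if profiles.get(l)]
    )
    return HostPredictionResult(
        enrichments=enrich,
        summary=summarize_by_taxon(enrich, tree),
        n_annotated_leaves=n_annot,
        rooted_by_midpoint=rooted_by_midpoint,
    )
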