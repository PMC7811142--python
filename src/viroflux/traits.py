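"""Functional-trait enrichment of co-occurrence network partners.

Compares presence/absence traits (chloroplast, silicification,
calcification) between the eukaryotes connected to one virus group (e.g.
the positively associated key predictors of export efficiency) and those
connected to a contrast group (e.g. the non-important viruses). Each trait
yields one 2x2 contingency table, a two-sided Fisher exact test and a
Benjamini-Hochberg Q across the traits of the contrast. OTUs whose trait
status is unknown are dropped from that trait's table only, which is why
denominators legitimately differ between traits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DataError, ParameterError


def connected_partners(
    edges: pd.DataFrame,
    virus_set,
    mode: str = "any",
    contrast_set=None,
) -> set:
    """Eukaryote OTUs connected to a virus group.

    ``mode="any"`` returns OTUs with at least one edge to the group;
    ``mode="exclusive"`` additionally removes OTUs that also have an edge
    to ``contrast_set``.
    """
    virus_set = set(virus_set)
    sub = edges[edges["virus_id"].isin(virus_set)]
    partners = set(sub["eukaryote_otu_id"])
    if mode == "any":
        return partners
    if mode == "exclusive":
        if contrast_set is None:
            raise ParameterError("exclusive mode requires a contrast set")
        other = set(
            edges[edges["virus_id"].isin(set(contrast_set))]["eukaryote_otu_id"]
        )
        return partners - other
    raise ParameterError(f"unknown partner mode {mode!r}")


def fisher_exact_two_sided(a: int, b: int, c: int, d: int):
    """Two-sided Fisher exact test on the 2x2 table [[a, b], [c, d]].

    Uses the conditional minimum-likelihood rule (the p-value sums the
    probabilities of all tables, with margins fixed, whose point
    probability does not exceed the observed one). Returns
    ``(odds_ratio, p)`` with the sample odds ratio ad/bc.
    """
    cells = np.array([a, b, c, d])
    if (cells < 0).any():
        raise DataError("contingency cells must be non-negative")
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        raise DataError("all margins of the 2x2 table must be positive")
    odds_ratio, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(odds_ratio), float(p)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise DataError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class TraitEnrichmentRow:
    """One trait's 2x2 comparison between two partner sets."""

    contrast: str
    trait: str
    a: int  # group-1 present
    b: int  # group-1 absent
    c: int  # group-2 present
    d: int  # group-2 absent
    odds_ratio: float
    p: float
    q: float
    skipped: bool = False


def _contingency(
    partners_1: set, partners_2: set, trait_values: pd.Series
) -> tuple[int, int, int, int]:
    known = trait_values.dropna()
    g1 = known.loc[known.index.intersection(partners_1)]
    g2 = known.loc[known.index.intersection(partners_2)]
    a = int((g1 == 1).sum())
    b = int((g1 == 0).sum())
    c = int((g2 == 1).sum())
    d = int((g2 == 0).sum())
    return a, b, c, d


def trait_comparison(
    edges: pd.DataFrame,
    vip_sets: dict[str, set],
    traits: pd.DataFrame,
    contrasts=(("positive", "non_vip"),),
    mode: str = "any",
) -> pd.DataFrame:
    """Table of trait enrichments for each requested group contrast.

    ``vip_sets`` maps group names (e.g. ``positive``, ``negative``,
    ``non_vip``) to virus id sets; ``traits`` is an OTU-indexed frame of
    1/0/NaN values. For each contrast, one 2x2 per trait is built from the
    groups' partner sets and tested two-sided; Q-values are BH within the
    contrast (m = number of traits actually tested). Empty partner sets or
    degenerate margins yield a reported row with the test skipped.
    """
    if traits.index.name is None and "eukaryote_otu_id" in traits.columns:
        traits = traits.set_index("eukaryote_otu_id")
    rows: list[TraitEnrichmentRow] = []
    for group_1, group_2 in contrasts:
        for g in (group_1, group_2):
            if g not in vip_sets:
                raise ParameterError(f"unknown virus group {g!r}")
        contrast_name = f"{group_1}_vs_{group_2}"
        p1 = connected_partners(
            edges, vip_sets[group_1], mode=mode, contrast_set=vip_sets[group_2]
        )
        p2 = connected_partners(
            edges, vip_sets[group_2], mode=mode, contrast_set=vip_sets[group_1]
        )
        contrast_rows = []
        for trait in traits.columns:
            a, b, c, d = _contingency(p1, p2, traits[trait])
            try:
                orr, p = fisher_exact_two_sided(a, b, c, d)
                skipped = False
            except DataError:
                orr, p, skipped = np.nan, np.nan, True
            contrast_rows.append(
                TraitEnrichmentRow(
                    contrast=contrast_name, trait=trait,
                    a=a, b=b, c=c, d=d,
                    odds_ratio=orr, p=p, q=np.nan, skipped=skipped,
                )
            )
        tested = [r for r in contrast_rows if not r.skipped]
        if tested:
            qs = bh_adjust([r.p for r in tested])
            for r, q in zip(tested, qs):
                r.q = float(q)
        rows.extend(contrast_rows)
    return pd.DataFrame([vars(r) for r in rows])


def trait_table_from_counts(counts: dict[str, tuple[int, int, int, int]]):
    """Fisher p and BH Q straight from pre-tabulated 2x2 counts.

    ``counts`` maps trait name to (a, b, c, d); useful for re-running a
    published contingency table without the underlying network.
    """
    rows = []
    for trait, (a, b, c, d) in counts.items():
        orr, p = fisher_exact_two_sided(a, b, c, d)
        rows.append({"trait": trait, "a": a, "b": b, "c": c, "d": d,
                     "odds_ratio": orr, "p": p})
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out
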