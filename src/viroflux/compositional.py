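"""Compositional preprocessing of viral marker-gene count tables.

Raw mapped-read counts are not comparable across samples or across genes:
library sizes differ between samples and longer genes recruit more reads.
The pipeline therefore works with *relative abundance*, defined as the
centered log-ratio (CLR) transform of gene-length-normalized read counts.
Because the DNA-virus marker (PolB, metagenome-derived) and the RNA/ssDNA
markers (RdRP and Rep, metatranscriptome-derived) come from different
sequencing libraries, CLR closure is applied separately within the two
catalogs by default; a single-closure mode is available.

The module also computes the carbon export efficiency response
(CEE = CE_deep / CE_surface) and applies the marker filter used upstream of
regression: a marker must occur in at least ``min_samples`` samples and its
CLR profile must have a Spearman correlation with CEE strictly greater than
``rho_threshold`` in absolute value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, ParameterError, UndefinedStatisticError

logger = logging.getLogger(__name__)

MARKER_CLASSES = ("PolB", "RdRP", "Rep")

#: Default CLR closure: PolB genes come from prokaryote-enriched metagenomes,
#: RdRP and Rep genes from eukaryotic metatranscriptomes, so each library
#: type forms its own composition.
DEFAULT_CLOSURE = "by_library"


@dataclass
class AbundanceMatrix:
    """Marker x sample read counts plus per-marker annotation.

    Parameters
    ----------
    counts
        Non-negative integer DataFrame, rows indexed by marker id,
        columns by sample id.
    marker_class
        Series mapping marker id to one of ``PolB``, ``RdRP``, ``Rep``.
    gene_length
        Series mapping marker id to gene length in base pairs (> 0).
    """

    counts: pd.DataFrame
    marker_class: pd.Series
    gene_length: pd.Series
    taxon_annotation: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise DataError("duplicate marker ids in abundance matrix")
        if not self.marker_class.index.equals(self.counts.index):
            self.marker_class = self.marker_class.reindex(self.counts.index)
        if not self.gene_length.index.equals(self.counts.index):
            self.gene_length = self.gene_length.reindex(self.counts.index)
        if self.marker_class.isna().any():
            missing = self.marker_class.index[self.marker_class.isna()][0]
            raise DataError(f"marker {missing!r} has no marker_class")
        bad = ~self.marker_class.isin(MARKER_CLASSES)
        if bad.any():
            raise DataError(
                f"marker {self.marker_class.index[bad][0]!r} has unknown class "
                f"{self.marker_class[bad].iloc[0]!r}"
            )
        if self.gene_length.isna().any():
            missing = self.gene_length.index[self.gene_length.isna()][0]
            raise DataError(f"marker {missing!r} has no gene length")
        if (self.gene_length <= 0).any():
            bad_id = self.gene_length.index[self.gene_length <= 0][0]
            raise DataError(f"marker {bad_id!r} has non-positive gene length")
        if (self.counts.to_numpy() < 0).any():
            raise DataError("negative read counts in abundance matrix")

    @property
    def markers(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    def subset_markers(self, marker_ids: Sequence[str]) -> "AbundanceMatrix":
        ids = pd.Index(marker_ids)
        return AbundanceMatrix(
            counts=self.counts.loc[ids],
            marker_class=self.marker_class.loc[ids],
            gene_length=self.gene_length.loc[ids],
            taxon_annotation=None
            if self.taxon_annotation is None
            else self.taxon_annotation.loc[ids],
        )


@dataclass
class RelativeAbundance:
    """CLR-transformed, gene-length-normalized abundances.

    ``values`` is markers x samples; within each closure group each sample's
    values sum to zero. ``provenance`` records the zero-replacement policy.
    """

    values: pd.DataFrame
    closure_groups: Mapping[str, list] = field(default_factory=dict)
    provenance: str = ""


def compute_cee(ce_surface, ce_deep):
    """Carbon export efficiency: ratio of deep to surface carbon flux.

    Accepts scalars or aligned array-likes. Raises :class:`DataError` when
    any surface flux is non-positive (the ratio is then undefined).
    """
    surface = np.asarray(ce_surface, dtype=float)
    deep = np.asarray(ce_deep, dtype=float)
    if np.any(surface <= 0):
        raise DataError("CE_surface must be strictly positive to form CEE")
    out = deep / surface
    if out.ndim == 0:
        return float(out)
    if isinstance(ce_surface, pd.Series):
        return pd.Series(out, index=ce_surface.index)
    return out


def length_normalize(matrix: AbundanceMatrix) -> pd.DataFrame:
    """Divide each marker's counts by its gene length in kilobases.

    Zeros are preserved; the result has reads-per-kilobase units.
    """
    kb = matrix.gene_length.astype(float) / 1000.0
    return matrix.counts.astype(float).div(kb, axis=0)


def closure_partition(matrix: AbundanceMatrix, mode: str = DEFAULT_CLOSURE) -> dict:
    """Partition markers into CLR closure groups.

    ``by_library`` keeps the metagenome-derived PolB markers separate from
    the metatranscriptome-derived RdRP/Rep markers; ``single`` puts all
    markers in one composition.
    """
    if mode == "single":
        return {"all": list(matrix.markers)}
    if mode == "by_library":
        groups: dict[str, list] = {}
        polb = matrix.markers[matrix.marker_class == "PolB"]
        rna = matrix.markers[matrix.marker_class.isin(["RdRP", "Rep"])]
        if len(polb):
            groups["PolB"] = list(polb)
        if len(rna):
            groups["RdRP+Rep"] = list(rna)
        return groups
    raise ParameterError(f"unknown closure mode {mode!r}")


def clr_transform(
    values: pd.DataFrame,
    closure_groups: Mapping[str, Sequence[str]] | None = None,
    pseudocount_strategy: str | float = "half-min",
) -> RelativeAbundance:
    """Centered log-ratio transform within closure groups.

    For each group and sample, zeros are replaced according to
    ``pseudocount_strategy`` and each value is mapped to its log-ratio
    against the group's per-sample geometric mean, so the transformed
    values in a group sum to zero for every sample.

    Strategies: ``"half-min"`` (default) replaces zeros by half the smallest
    non-zero value in the closure group; a float replaces zeros by that
    fixed value.
    """
    vals = values.astype(float)
    if (vals.to_numpy() < 0).any():
        raise DataError("negative values passed to clr_transform")
    if closure_groups is None:
        closure_groups = {"all": list(vals.index)}
    out = pd.DataFrame(np.nan, index=vals.index, columns=vals.columns)
    for name, members in closure_groups.items():
        block = vals.loc[list(members)].to_numpy(copy=True)
        if block.size == 0:
            continue
        zero_samples = (block <= 0).all(axis=0)
        if zero_samples.any():
            sid = vals.columns[np.flatnonzero(zero_samples)[0]]
            raise DataError(
                f"sample {sid!r} has all-zero values in closure group {name!r}"
            )
        if isinstance(pseudocount_strategy, (int, float)):
            delta = float(pseudocount_strategy)
            if delta <= 0:
                raise ParameterError("fixed pseudocount must be positive")
        elif pseudocount_strategy == "half-min":
            delta = 0.5 * block[block > 0].min()
        else:
            raise ParameterError(
                f"unknown pseudocount strategy {pseudocount_strategy!r}"
            )
        block[block == 0] = delta
        logb = np.log(block)
        out.loc[list(members)] = logb - logb.mean(axis=0, keepdims=True)
    return RelativeAbundance(
        values=out,
        closure_groups={k: list(v) for k, v in closure_groups.items()},
        provenance=f"pseudocount={pseudocount_strategy}",
    )


def spearman(x, y) -> float:
    """Spearman rank correlation (Pearson correlation of mid-ranks)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DataError("spearman requires two equal-length vectors")
    if x.size < 3:
        raise DataError("spearman requires at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError("correlation undefined for constant vector")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def filter_markers(
    matrix: AbundanceMatrix,
    rel: RelativeAbundance,
    cee: pd.Series,
    min_samples: int = 5,
    presence_reads: int = 2,
    rho_threshold: float = 0.2,
) -> pd.DataFrame:
    """Occurrence and correlation filter ahead of regression.

    A marker is kept when it is present (``count >= presence_reads``) in at
    least ``min_samples`` samples and its relative-abundance profile has
    ``|Spearman rho| > rho_threshold`` (strict) with the response.

    Returns a DataFrame indexed by marker id with columns ``n_present``,
    ``rho`` and boolean ``kept``. Markers absent from ``rel`` (e.g. removed
    before CLR) get ``rho = NaN`` and are not kept.
    """
    cee = pd.Series(cee)
    samples = matrix.samples.intersection(cee.index)
    if len(samples) < 3:
        raise DataError("fewer than 3 samples shared between counts and response")
    counts = matrix.counts[samples]
    n_present = (counts >= presence_reads).sum(axis=1)
    occ_ok = n_present >= min_samples
    resp = cee.loc[samples].to_numpy(dtype=float)

    rhos = pd.Series(np.nan, index=matrix.markers)
    for mid in matrix.markers[occ_ok]:
        if mid not in rel.values.index:
            continue
        profile = rel.values.loc[mid, samples].to_numpy(dtype=float)
        if np.isnan(profile).any() or np.ptp(profile) == 0:
            continue
        rhos[mid] = spearman(profile, resp)
    kept = occ_ok & (rhos.abs() > rho_threshold)
    return pd.DataFrame(
        {"n_present": n_present, "rho": rhos, "kept": kept.fillna(False)}
    )


def select_markers(
    matrix: AbundanceMatrix,
    cee: pd.Series,
    min_samples: int = 5,
    presence_reads: int = 2,
    rho_threshold: float = 0.2,
    closure: str = DEFAULT_CLOSURE,
    pseudocount_strategy: str | float = "half-min",
    correlate_on: str = "clr",
) -> tuple[RelativeAbundance, pd.DataFrame]:
    """Staged marker selection: occurrence gate, CLR, correlation gate.

    Samples whose response is missing are dropped first (with a logged
    count). The CLR transform is computed on the markers passing the
    occurrence gate, so the composition used for modelling is closed over
    that set; the Spearman gate is then applied to the CLR profiles
    (``correlate_on="clr"``, default) or the length-normalized counts
    (``correlate_on="normalized"``).

    Returns the relative abundance of the occurrence-passing markers and the
    filter table from :func:`filter_markers`.
    """
    cee = pd.Series(cee).dropna()
    n_dropped = len(matrix.samples) - len(matrix.samples.intersection(cee.index))
    if n_dropped:
        logger.info("dropping %d samples with missing response", n_dropped)
    samples = matrix.samples.intersection(cee.index)
    sub = AbundanceMatrix(
        counts=matrix.counts[samples],
        marker_class=matrix.marker_class,
        gene_length=matrix.gene_length,
    )
    n_present = (sub.counts >= presence_reads).sum(axis=1)
    occ = sub.subset_markers(sub.markers[n_present >= min_samples])
    norm = length_normalize(occ)
    rel = clr_transform(
        norm, closure_partition(occ, closure), pseudocount_strategy
    )
    if correlate_on == "normalized":
        rel_for_corr = RelativeAbundance(values=norm, provenance="normalized")
    elif correlate_on == "clr":
        rel_for_corr = rel
    else:
        raise ParameterError(f"unknown correlate_on mode {correlate_on!r}")
    table = filter_markers(
        sub, rel_for_corr, cee.loc[samples],
        min_samples=min_samples,
        presence_reads=presence_reads,
        rho_threshold=rho_threshold,
    )
    return rel, table
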