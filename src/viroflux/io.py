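"""Readers and writers for the pipeline's tab-separated and newick formats.

All tables are UTF-8, tab-delimited, '.' decimal. Writers prepend comment
lines (``# key=value``) carrying the tool version, seed and configuration
hash so every output is traceable to its run; readers skip ``#`` lines.
"""

from __future__ import annotations

from pathlib import Path

import dendropy
import pandas as pd

from . import __version__
from .compositional import MARKER_CLASSES, AbundanceMatrix
from .errors import DataError

_FLOAT_FMT = "%.10g"

ABUNDANCE_META_COLUMNS = ["marker_id", "marker_class", "gene_length_bp"]
METADATA_COLUMNS = [
    "sample_id", "station", "depth_layer", "CE_surface", "CE_deep",
    "CEE", "CE150", "NPP", "T100",
]


def header_lines(header: dict | None) -> str:
    items = {"tool": f"viroflux {__version__}"}
    items.update(header or {})
    return "".join(f"# {k}={v}\n" for k, v in items.items())


def write_table(df: pd.DataFrame, path, header: dict | None, index: bool) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(header_lines(header))
        df.to_csv(fh, sep="\t", index=index, float_format=_FLOAT_FMT,
                  lineterminator="\n")


def _read_tsv(path, **kwargs) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", comment="#", **kwargs)
    except (pd.errors.ParserError, ValueError) as exc:
        raise DataError(f"{path}: malformed table ({exc})") from exc


def write_abundance(matrix: AbundanceMatrix, path, header: dict | None = None):
    df = pd.DataFrame(
        {
            "marker_id": matrix.markers,
            "marker_class": matrix.marker_class.to_numpy(),
            "gene_length_bp": matrix.gene_length.to_numpy(),
        }
    )
    df = pd.concat([df, matrix.counts.reset_index(drop=True)], axis=1)
    write_table(df, path, header, index=False)


def read_abundance(path) -> AbundanceMatrix:
    df = _read_tsv(path)
    missing = [c for c in ABUNDANCE_META_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing columns {missing}")
    if df["marker_id"].duplicated().any():
        dup = df["marker_id"][df["marker_id"].duplicated()].iloc[0]
        line = int(df.index[df["marker_id"] == dup][1]) + 2
        raise DataError(f"{path}: line {line}: duplicate marker id {dup!r}")
    bad = ~df["marker_class"].isin(MARKER_CLASSES)
    if bad.any():
        line = int(df.index[bad][0]) + 2
        raise DataError(
            f"{path}: line {line}: unknown marker class "
            f"{df['marker_class'][bad].iloc[0]!r}"
        )
    df = df.set_index("marker_id")
    sample_cols = [c for c in df.columns if c not in ABUNDANCE_META_COLUMNS[1:]]
    counts = df[sample_cols]
    if counts.isna().any().any():
        raise DataError(f"{path}: missing count values")
    return AbundanceMatrix(
        counts=counts.astype(int),
        marker_class=df["marker_class"],
        gene_length=df["gene_length_bp"].astype(int),
    )


def write_metadata(meta: pd.DataFrame, path, header: dict | None = None):
    out = meta.reset_index() if meta.index.name == "sample_id" else meta.copy()
    write_table(out, path, header, index=False)


def read_metadata(path) -> pd.DataFrame:
    df = _read_tsv(path)
    if "sample_id" not in df.columns:
        raise DataError(f"{path}: missing sample_id column")
    if df["sample_id"].duplicated().any():
        raise DataError(f"{path}: duplicate sample ids")
    return df.set_index("sample_id")


def write_edges(edges: pd.DataFrame, path, header: dict | None = None):
    write_table(edges, path, header, index=False)


def read_edges(path) -> pd.DataFrame:
    df = _read_tsv(path)
    required = {"virus_id", "eukaryote_otu_id"}
    if not required.issubset(df.columns):
        raise DataError(f"{path}: edge list needs columns {sorted(required)}")
    return df


def write_taxonomy(taxonomy: pd.DataFrame, path, header: dict | None = None):
    write_table(taxonomy, path, header, index=False)


def read_taxonomy(path) -> pd.DataFrame:
    df = _read_tsv(path)
    required = {"eukaryote_otu_id", "taxon"}
    if not required.issubset(df.columns):
        raise DataError(f"{path}: taxonomy needs columns {sorted(required)}")
    return df


def write_traits(traits: pd.DataFrame, path, header: dict | None = None):
    out = traits.reset_index()
    out = out.rename(columns={out.columns[0]: "eukaryote_otu_id"})
    write_table(out.fillna("NA"), path, header, index=False)


def read_traits(path) -> pd.DataFrame:
    df = _read_tsv(path, na_values=["NA"])
    if "eukaryote_otu_id" not in df.columns:
        raise DataError(f"{path}: traits table needs an eukaryote_otu_id column")
    df = df.set_index("eukaryote_otu_id")
    for col in df.columns:
        bad = ~df[col].isin([0, 1]) & df[col].notna()
        if bad.any():
            raise DataError(
                f"{path}: trait {col!r} has values outside 1/0/NA"
            )
    return df


def write_tree(tree: dendropy.Tree, path, header: dict | None = None):
    with open(path, "w", encoding="utf-8") as fh:
        for line in header_lines(header).splitlines():
            fh.write(f"[{line}]\n")  # newick comment syntax
        fh.write(
            tree.as_string(schema="newick", suppress_rooting=False).strip()
            + "\n"
        )


def read_tree(path) -> dendropy.Tree:
    try:
        return dendropy.Tree.get(
            path=str(path), schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises many parse error types
        raise DataError(f"{path}: cannot parse newick tree ({exc})") from exc


def write_truth(truth: pd.DataFrame, path, header: dict | None = None):
    write_table(truth, path, header, index=False)


def read_truth(path) -> pd.DataFrame:
    return _read_tsv(path)
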