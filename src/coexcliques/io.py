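"""Readers and writers for every on-disk artifact of the clique pipeline.

All formats are plain tab-separated text, UTF-8, with ``NA`` written for
missing values.  Gene identifiers are case-sensitive and matched exactly.

Containers
----------
Expression matrices are :class:`pandas.DataFrame` objects (rows = genes,
columns = samples, ``NaN`` = missing).  Differential profiles are
:class:`pandas.Series` (index = genes, values = signed log2 differences).
Annotation tables are DataFrames with columns ``gene``, ``term``,
``category``.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

MISSING_TOKENS = ["", "NA", "nan", "NaN"]

ANNOTATION_CATEGORIES = ("GO", "TF_binding", "TF_activating", "TF_inhibiting")

#: maps the category column of a TF flat table onto canonical category labels
_TF_CATEGORY_ALIASES = {
    "binding": "TF_binding",
    "activating": "TF_activating",
    "activator": "TF_activating",
    "inhibiting": "TF_inhibiting",
    "inhibitor": "TF_inhibiting",
    "TF_binding": "TF_binding",
    "TF_activating": "TF_activating",
    "TF_inhibiting": "TF_inhibiting",
}


def _read_table(path, **kwargs) -> pd.DataFrame:
    """pandas.read_csv with ragged-row errors translated to line numbers."""
    try:
        return pd.read_csv(
            path,
            sep="\t",
            na_values=MISSING_TOKENS,
            keep_default_na=False,
            comment="#",
            **kwargs,
        )
    except pd.errors.ParserError as exc:  # pandas reports the offending line
        raise ValueError(f"malformed table in {path}: {exc}") from exc


def validate_expression_matrix(mat: pd.DataFrame) -> pd.DataFrame:
    """Check the ExpressionMatrix invariants, returning the matrix."""
    if mat.index.size == 0:
        raise ValueError("expression matrix has no genes")
    dup = mat.index[mat.index.duplicated()]
    if len(dup):
        raise ValueError(f"duplicate gene identifier: {dup[0]!r}")
    dup = mat.columns[mat.columns.duplicated()]
    if len(dup):
        raise ValueError(f"duplicate sample identifier: {dup[0]!r}")
    return mat


def read_expression_matrix(path, dialect: str = "tsv") -> pd.DataFrame:
    """Read a genes x samples expression matrix.

    Parameters
    ----------
    path
        File to read.
    dialect
        ``"tsv"`` for a plain matrix (first column = gene id, header row =
        sample ids) or ``"pcl"`` for the SPELL dialect (columns ``ID``,
        ``NAME``, ``GWEIGHT``, then samples; optional ``EWEIGHT`` row).

    Empty cells and the tokens ``NA``/``nan`` become missing values.
    """
    if dialect == "tsv":
        df = _read_table(path, index_col=0)
        df.index = df.index.astype(str)
        df.index.name = None
        mat = df.astype(float)
    elif dialect == "pcl":
        df = _read_table(path, dtype=str)
        cols = list(df.columns)
        if len(cols) < 3 or cols[0] != "ID" or cols[1] != "NAME" or cols[2] != "GWEIGHT":
            raise ValueError(
                f"PCL file {path} must start with columns ID, NAME, GWEIGHT"
            )
        if len(df) and str(df.iloc[0, 0]) == "EWEIGHT":
            df = df.iloc[1:]
        mat = df.set_index("ID").drop(columns=["NAME", "GWEIGHT"]).astype(float)
        mat.index = mat.index.astype(str)
        mat.index.name = None
    else:
        raise ValueError(f"unknown expression dialect: {dialect!r}")
    return validate_expression_matrix(mat)


def write_expression_matrix(path, mat: pd.DataFrame, dialect: str = "tsv") -> None:
    validate_expression_matrix(mat)
    if dialect == "tsv":
        mat.to_csv(path, sep="\t", na_rep="NA", index_label="gene")
    elif dialect == "pcl":
        out = mat.copy()
        out.insert(0, "GWEIGHT", 1)
        out.insert(0, "NAME", out.index)
        out.insert(0, "ID", out.index)
        out.to_csv(path, sep="\t", na_rep="NA", index=False)
    else:
        raise ValueError(f"unknown expression dialect: {dialect!r}")


def read_platform_map(path) -> dict[str, str]:
    """Read a 2-column probe -> gene table (GPL-annotation style).

    Probes with an empty gene field map to ``""`` (treated as unmapped by
    :func:`collapse_probes`).  Duplicate probe ids are an error.
    """
    df = _read_table(path, header=None, names=["probe", "gene"], dtype=str)
    probes = df["probe"].astype(str)
    dup = probes[probes.duplicated()]
    if len(dup):
        raise ValueError(f"duplicate probe id in platform map: {dup.iloc[0]!r}")
    genes = df["gene"].where(df["gene"].notna(), "")
    return dict(zip(probes, genes.astype(str)))


def collapse_probes(mat: pd.DataFrame, pmap: Mapping[str, str]) -> pd.DataFrame:
    """Collapse probe rows to gene rows.

    Probes mapping to the same gene are averaged per sample over the
    non-missing values.  Probes absent from the map (or mapped to an empty
    gene name) keep their probe id — mirroring platforms where control
    probes and a handful of probe sets carry no gene name.
    """
    targets = [pmap.get(p) or p for p in mat.index]
    out = mat.groupby(pd.Index(targets, name=None), sort=False).mean()
    out.index.name = None
    return validate_expression_matrix(out)


def read_annotations(path, category: str | None = None) -> pd.DataFrame:
    """Read a gene-annotation flat table.

    With ``category`` given (one of ``GO``, ``TF_binding``,
    ``TF_activating``, ``TF_inhibiting``) the file is a 2-column table
    ``gene<TAB>term``.  With ``category=None`` the file is a 3-column
    TF flat table ``tf<TAB>target<TAB>category`` whose category column is
    translated to the canonical ``TF_*`` labels.  Duplicate
    (gene, term, category) records are dropped.
    """
    if category is not None:
        if category not in ANNOTATION_CATEGORIES:
            raise ValueError(
                f"unknown annotation category {category!r}; "
                f"expected one of {ANNOTATION_CATEGORIES}"
            )
        df = _read_table(path, header=None, names=["gene", "term"], dtype=str)
        df["category"] = category
    else:
        df = _read_table(
            path, header=None, names=["term", "gene", "category"], dtype=str
        )
        try:
            df["category"] = df["category"].map(lambda c: _TF_CATEGORY_ALIASES[c])
        except KeyError as exc:
            raise ValueError(f"unknown TF category label: {exc.args[0]!r}") from exc
    df = df[["gene", "term", "category"]].drop_duplicates(ignore_index=True)
    return df


def write_annotations(path, annotations: pd.DataFrame) -> None:
    ann = annotations[["gene", "term", "category"]].drop_duplicates()
    ann.to_csv(path, sep="\t", header=False, index=False)


def read_profile(path) -> pd.Series:
    """Read a differential-expression profile (``gene<TAB>difference``)."""
    df = _read_table(path, header=None, names=["gene", "diff"], dtype={0: str})
    genes = df["gene"].astype(str)
    dup = genes[genes.duplicated()]
    if len(dup):
        raise ValueError(f"duplicate gene in profile: {dup.iloc[0]!r}")
    prof = pd.Series(df["diff"].astype(float).values, index=genes.values)
    return prof.dropna()


def write_profile(path, profile: pd.Series) -> None:
    profile.to_csv(path, sep="\t", header=False)


def read_gene_sets(path) -> dict[str, frozenset[str]]:
    """Read named gene sets from a GMT file (set, description, genes...)."""
    sets: dict[str, frozenset[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"GMT line {lineno} has fewer than 3 fields")
            name = fields[0]
            if name in sets:
                raise ValueError(f"duplicate gene-set name: {name!r}")
            sets[name] = frozenset(g for g in fields[2:] if g)
    return sets


def write_gene_sets(path, sets: Mapping[str, frozenset[str]], description: str = "na") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *sorted(genes)]) + "\n")


def write_clique_set(path, cliques) -> None:
    """Write a clique set as a 2-column ``gene<TAB>clique`` table.

    Parameters used for the separation (top-K, protection threshold) are
    kept in ``#`` header comments so the round trip is exact.
    """
    with open(path, "w", encoding="utf-8") as fh:
        if cliques.k is not None:
            fh.write(f"#k={cliques.k}\n")
        if cliques.t is not None:
            fh.write(f"#t={cliques.t}\n")
        for name, genes in cliques.items():
            for g in sorted(genes):
                fh.write(f"{g}\t{name}\n")


def read_clique_set(path):
    """Read a 2-column ``gene<TAB>clique`` table written by :func:`write_clique_set`."""
    from .cliques import CliqueSet

    k = t = None
    members: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line[1:].partition("=")
                if key == "k":
                    k = int(val)
                elif key == "t":
                    t = int(val)
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"clique file line {lineno}: expected 2 fields")
            gene, name = fields
            members.setdefault(name, []).append(gene)
    return CliqueSet({n: frozenset(gs) for n, gs in members.items()}, k=k, t=t)


def color_bin(diff: float) -> int:
    """Map an expression difference to the Cytoscape color bin in -4..+4.

    Bins step at |d| = 0.25, 0.5, 0.75 and 1.0: bin 0 for |d| < 0.25, then
    +-1..+-3 per quarter step, +-4 for |d| >= 1.0.
    """
    if not np.isfinite(diff):
        raise ValueError("color_bin requires a finite difference")
    magnitude = min(int(abs(diff) / 0.25), 4)
    return magnitude if diff >= 0 else -magnitude


def export_cytoscape(profile: pd.Series, cliques, network=None):
    """Build Cytoscape node and edge attribute tables.

    Returns ``(nodes, edges)``: a node table with one row per clique-set
    gene (clique, difference, color bin, blank flag for genes the profile
    did not measure) and an edge table (source, target, strength,
    multiplicity), empty when no network is given.
    """
    rows = []
    for name, genes in cliques.items():
        for g in sorted(genes):
            if g in profile.index:
                d = float(profile[g])
                rows.append((g, name, d, color_bin(d), False))
            else:
                rows.append((g, name, np.nan, 0, True))
    nodes = pd.DataFrame(
        rows, columns=["gene", "clique", "diff", "color_bin", "blank"]
    )
    if network is not None:
        erows = [
            (u, v, data["strength"], data["multiplicity"])
            for u, v, data in network.graph.edges(data=True)
        ]
        erows.sort()
        edges = pd.DataFrame(
            erows, columns=["source", "target", "strength", "multiplicity"]
        )
    else:
        edges = pd.DataFrame(columns=["source", "target", "strength", "multiplicity"])
    return nodes, edges


def write_sif(path, network) -> None:
    """Write the undirected co-expression network in Cytoscape SIF format."""
    with open(path, "w", encoding="utf-8") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in network.graph.edges):
            fh.write(f"{u}\tcoexp\t{v}\n")
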