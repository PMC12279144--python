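"""File formats: data/metadata/constraints tables, edge tables, graph export.

All tables are delimited text (comma for ``.csv``, otherwise tab) with a
header row; the missing-value code is the literal string ``NA``.  Edge
tables use the same column semantics as the published supplementary tables:
``from,to,strength,direction``.  Graphs export to GraphML (via networkx,
with class/strength/direction attributes) or DOT.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .average_network import AverageNetwork
from .genetics import GenotypeMatrix
from .model_core import ConstraintSet, DataMatrix, VariableMeta

NA = "NA"

_CLASS_COLOUR = {  # node colour classes used in the field's figures
    "metabolite": "red",
    "protein": "blue",
    "expression": "purple",
    "clinical": "orange",
    "allele_score": "green",
}


def _sep(path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_metadata(path) -> list[VariableMeta]:
    """Read a variable-metadata table: name, dtype, vclass, levels (';'-joined)."""
    df = pd.read_csv(path, sep=_sep(path), dtype=str, keep_default_na=False)
    out = []
    for row in df.itertuples(index=False):
        levels = tuple(l for l in str(getattr(row, "levels", "")).split(";") if l)
        out.append(VariableMeta(row.name, row.dtype, row.vclass, levels))
    return out


def write_metadata(meta: Sequence[VariableMeta], path) -> None:
    rows = [
        {"name": v.name, "dtype": v.dtype, "vclass": v.vclass, "levels": ";".join(v.levels)}
        for v in meta
    ]
    pd.DataFrame(rows).to_csv(path, sep=_sep(path), index=False)


def read_data(path, metadata_path) -> DataMatrix:
    """Read a sample x variable table; first column is the sample id.

    Variables are aligned to the metadata by name, not position.
    """
    meta = metadata_path if isinstance(metadata_path, list) else read_metadata(metadata_path)
    df = pd.read_csv(
        path, sep=_sep(path), index_col=0, na_values=[NA], keep_default_na=False
    )
    return DataMatrix(df, meta)


def write_data(data: DataMatrix, path) -> None:
    frame = data.frame.copy()
    frame.index.name = frame.index.name or "sample_id"
    frame.to_csv(path, sep=_sep(path), na_rep=NA)


def read_constraints(path) -> ConstraintSet:
    """Read one rule per line: kind plus endpoints.

    Kinds: ``require``/``forbid`` (two endpoints), ``parent_only``/
    ``no_parents`` (one node).
    """
    cs = ConstraintSet()
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p for p in line.replace(",", "\t").split("\t") if p]
            kind = parts[0]
            if kind == "require":
                cs.required_edges.add((parts[1], parts[2]))
            elif kind == "forbid":
                cs.forbidden_edges.add((parts[1], parts[2]))
            elif kind == "parent_only":
                cs.parent_only.add(parts[1])
            elif kind == "no_parents":
                cs.no_parents.add(parts[1])
            else:
                raise ValueError(f"unknown constraint kind {kind!r}")
    return ConstraintSet(cs.required_edges, cs.forbidden_edges, cs.parent_only, cs.no_parents)


def write_constraints(constraints: ConstraintSet, path) -> None:
    with open(path, "w") as fh:
        for p, c in sorted(constraints.required_edges):
            fh.write(f"require\t{p}\t{c}\n")
        for p, c in sorted(constraints.forbidden_edges):
            fh.write(f"forbid\t{p}\t{c}\n")
        for n in sorted(constraints.parent_only):
            fh.write(f"parent_only\t{n}\n")
        for n in sorted(constraints.no_parents):
            fh.write(f"no_parents\t{n}\n")


def write_edge_table(edges, path) -> None:
    """Write ``from,to,strength,direction`` CSV, sorted by (from, to).

    Accepts an :class:`AverageNetwork` (full pair table, oriented a->b as
    stored) or a thresholded edge DataFrame.
    """
    if isinstance(edges, AverageNetwork):
        df = edges.pairs.rename(
            columns={"node_a": "from", "node_b": "to", "direction_a_to_b": "direction"}
        )
    else:
        df = pd.DataFrame(edges)
    cols = ["from", "to", "strength", "direction"]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"edge table lacks columns {missing}")
    df = df[cols].sort_values(["from", "to"], ignore_index=True)
    df.to_csv(path, sep=_sep(path), index=False)


def read_edge_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sep(path))
    required = {"from", "to", "strength", "direction"}
    if not required.issubset(df.columns):
        raise ValueError(f"edge table must have columns {sorted(required)}")
    return df


def genotypes_to_files(genotypes: GenotypeMatrix, dosage_path, map_path) -> None:
    """Write a dosage matrix (samples x SNPs) and a SNP map (id, chrom, pos)."""
    df = pd.DataFrame(
        genotypes.dosages, index=genotypes.sample_ids, columns=genotypes.snp_ids
    )
    df.index.name = "sample_id"
    df.to_csv(dosage_path, sep=_sep(dosage_path), na_rep=NA)
    pd.DataFrame(
        {
            "snp_id": genotypes.snp_ids,
            "chromosome": genotypes.chromosome,
            "position": genotypes.position,
        }
    ).to_csv(map_path, sep=_sep(map_path), index=False)


def genotypes_from_files(dosage_path, map_path) -> GenotypeMatrix:
    df = pd.read_csv(
        dosage_path, sep=_sep(dosage_path), index_col=0, na_values=[NA],
        keep_default_na=False,
    )
    snp_map = pd.read_csv(map_path, sep=_sep(map_path))
    order = [str(s) for s in snp_map["snp_id"]]
    return GenotypeMatrix(
        sample_ids=list(df.index),
        snp_ids=order,
        chromosome=snp_map["chromosome"].to_numpy(),
        position=snp_map["position"].to_numpy(),
        dosages=df[order].to_numpy(dtype=float),
    )


def _as_edge_frame(edges) -> pd.DataFrame:
    if isinstance(edges, pd.DataFrame):
        return edges
    return pd.DataFrame(edges, columns=["from", "to"])


def export_graph(edges, meta: Sequence[VariableMeta], path, format: str = "graphml") -> None:
    """Export an edge list with node class and edge strength attributes.

    Nodes carry ``vclass`` and a conventional class colour; edges carry
    ``strength``/``direction`` when available plus a visual ``weight``
    proportional to strength.
    """
    df = _as_edge_frame(edges)
    vclass = {v.name: v.vclass for v in meta}
    g = nx.DiGraph()
    for v in meta:
        g.add_node(v.name, vclass=v.vclass, colour=_CLASS_COLOUR[v.vclass])
    for _, row in df.iterrows():
        attrs = {}
        if "strength" in df.columns:
            attrs["strength"] = float(row["strength"])
            attrs["weight"] = float(row["strength"])
        if "direction" in df.columns:
            attrs["direction"] = float(row["direction"])
        g.add_edge(row["from"], row["to"], **attrs)
    unknown = [n for n in g.nodes if n not in vclass]
    if unknown:
        raise KeyError(f"edge endpoints without metadata: {unknown}")
    if format == "graphml":
        nx.write_graphml(g, path)
    elif format == "dot":
        _write_dot(g, path)
    else:
        raise ValueError(f"unknown export format {format!r}")


def _write_dot(g: nx.DiGraph, path) -> None:
    lines = ["digraph average_network {"]
    for n, attrs in sorted(g.nodes(data=True)):
        colour = attrs.get("colour", "black")
        lines.append(f'  "{n}" [color="{colour}", vclass="{attrs.get("vclass", "")}"];')
    for a, b, attrs in sorted(g.edges(data=True)):
        label = ""
        if "strength" in attrs:
            label = f' [label="{attrs["strength"]:.2f}", penwidth={1 + 4 * attrs["strength"]:.2f}]'
        lines.append(f'  "{a}" -> "{b}"{label};')
    lines.append("}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_provenance(path, **fields) -> None:
    """Sidecar provenance record (config hash, seeds, package version)."""
    from . import __version__

    record = {"package_version": __version__, **fields}
    Path(path).write_text(json.dumps(record, indent=2, default=str) + "\n")
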