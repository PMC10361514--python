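"""Readers and writers for every on-disk format the pipeline touches.

Conventions
-----------
* Expression matrices: TSV, first column feature ids, header row of sample
  ids; group map as a 2-column TSV ``sample<TAB>group``.
* Annotation: BED6 (0-based half-open, taken verbatim) or GFF3 (1-based
  closed, converted to internal 0-based half-open at the boundary:
  ``start-1, end``). Dialect declared by the file extension.
* Evidence: 4- or 5-column TSV ``mirna, target, target_class, source
  [, score]``.
* Survival: TSV ``sample, time, event``.
* Networks: edge-list TSV, SIF or GraphML — GraphML and the edge list are
  fully round-trip safe (node types included); SIF encodes node types in
  the relation label with the miRNA written first.

Parsers reject malformed input instead of coercing it, and error messages
name the offending line or field.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import pandas as pd

from .containers import (ExpressionMatrix, ValidationError, validate_annotation,
                         validate_survival)

logger = logging.getLogger("cerna_texo")

EVIDENCE_COLUMNS = ("mirna", "target", "target_class", "source")


class FormatError(ValueError):
    """Raised when a file does not conform to its declared format."""


def log_stage(stage: str, **counts) -> None:
    """One structured log line per pipeline stage with record counts."""
    fields = " ".join(f"{key}={value}" for key, value in counts.items())
    logger.info("stage=%s %s", stage, fields)


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def read_group_map(path: str | Path) -> pd.Series:
    """Read a 2-column sample->group TSV (no header)."""
    table = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if table.shape[1] != 2:
        raise FormatError(f"{path}: group map must have exactly 2 columns, found {table.shape[1]}")
    if table[0].duplicated().any():
        dupe = table[0][table[0].duplicated()].iloc[0]
        raise FormatError(f"{path}: duplicate sample id {dupe!r} in group map")
    return pd.Series(table[1].to_numpy(), index=table[0].to_numpy(), name="group")


def read_expression(path: str | Path, rna_class: str,
                    group_map_path: str | Path) -> ExpressionMatrix:
    """Read a features x samples FPKM TSV plus its group map."""
    table = pd.read_csv(path, sep="\t", index_col=0)
    if table.index.duplicated().any():
        dupe = table.index[table.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate feature id {dupe!r}")
    if table.columns.duplicated().any():
        dupe = table.columns[table.columns.duplicated()][0]
        raise FormatError(f"{path}: duplicate sample id {dupe!r}")
    try:
        values = table.astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric expression value ({exc})") from None
    groups = read_group_map(group_map_path)
    try:
        matrix = ExpressionMatrix(values, rna_class, groups)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from None
    log_stage("read_expression", path=str(path), rna_class=rna_class,
              features=matrix.n_features, samples=matrix.n_samples)
    return matrix


def write_expression(matrix: ExpressionMatrix, path: str | Path,
                     group_map_path: str | Path | None = None) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="feature")
    if group_map_path is not None:
        matrix.groups.to_csv(group_map_path, sep="\t", header=False)


# ---------------------------------------------------------------------------
# Annotation (BED6 / GFF3)
# ---------------------------------------------------------------------------

def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read BED6 or GFF3 annotation into the internal 0-based half-open table."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".bed":
        table = _read_bed(path)
    elif suffix in (".gff3", ".gff"):
        table = _read_gff3(path)
    else:
        raise FormatError(f"{path}: unknown annotation extension {suffix!r} (use .bed or .gff3)")
    try:
        table = validate_annotation(table)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from None
    log_stage("read_annotation", path=str(path), features=len(table))
    return table


def _data_lines(path: Path):
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            yield lineno, line


def _read_bed(path: Path) -> pd.DataFrame:
    rows = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 6:
            raise FormatError(f"{path}:{lineno}: BED6 needs 6 fields, found {len(fields)}")
        chrom, start, end, name, _score, strand = fields[:6]
        try:
            start_i, end_i = int(start), int(end)
        except ValueError:
            raise FormatError(f"{path}:{lineno}: non-integer coordinate "
                              f"({start!r}, {end!r})") from None
        rows.append({"feature": name, "chrom": chrom, "start": start_i,
                     "end": end_i, "strand": strand})
    return pd.DataFrame(rows, columns=["feature", "chrom", "start", "end", "strand"])


def _read_gff3(path: Path) -> pd.DataFrame:
    rows = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) != 9:
            raise FormatError(f"{path}:{lineno}: GFF3 needs 9 fields, found {len(fields)}")
        chrom, _source, _ftype, start, end, _score, strand, _phase, attrs = fields
        try:
            start_i, end_i = int(start), int(end)
        except ValueError:
            raise FormatError(f"{path}:{lineno}: non-integer coordinate "
                              f"({start!r}, {end!r})") from None
        feature_id = None
        for item in attrs.split(";"):
            key, _, value = item.strip().partition("=")
            if key == "ID":
                feature_id = value
                break
        if not feature_id:
            raise FormatError(f"{path}:{lineno}: attribute column lacks an ID= tag")
        # GFF3 is 1-based closed; internal representation is 0-based half-open.
        rows.append({"feature": feature_id, "chrom": chrom, "start": start_i - 1,
                     "end": end_i, "strand": strand})
    return pd.DataFrame(rows, columns=["feature", "chrom", "start", "end", "strand"])


def write_annotation(table: pd.DataFrame, path: str | Path,
                     feature_type: str = "gene") -> None:
    """Write the internal annotation table as BED6 or GFF3 (by extension)."""
    path = Path(path)
    table = validate_annotation(table)
    suffix = path.suffix.lower()
    if suffix == ".bed":
        with open(path, "w") as handle:
            for row in table.itertuples(index=False):
                handle.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.feature}\t0\t{row.strand}\n")
    elif suffix in (".gff3", ".gff"):
        with open(path, "w") as handle:
            handle.write("##gff-version 3\n")
            for row in table.itertuples(index=False):
                handle.write(f"{row.chrom}\tcerna_texo\t{feature_type}\t{row.start + 1}\t"
                             f"{row.end}\t.\t{row.strand}\t.\tID={row.feature}\n")
    else:
        raise FormatError(f"{path}: unknown annotation extension {suffix!r}")


# ---------------------------------------------------------------------------
# Interaction evidence
# ---------------------------------------------------------------------------

def read_evidence(path: str | Path) -> pd.DataFrame:
    """Read the candidate miRNA->target evidence TSV."""
    table = pd.read_csv(path, sep="\t", dtype={c: str for c in EVIDENCE_COLUMNS})
    missing = [c for c in EVIDENCE_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"{path}: evidence table missing column(s) {missing}")
    bad = sorted(set(table["target_class"]) - {"mRNA", "lncRNA"})
    if bad:
        raise ValidationError(f"{path}: unknown target_class value(s) {bad}")
    inconsistent = table.groupby("target")["target_class"].nunique()
    inconsistent = inconsistent[inconsistent > 1]
    if len(inconsistent):
        raise ValidationError(
            f"{path}: target(s) with inconsistent target_class: {sorted(inconsistent.index[:5])}")
    log_stage("read_evidence", path=str(path), rows=len(table))
    return table.reset_index(drop=True)


def write_evidence(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Survival
# ---------------------------------------------------------------------------

def read_survival(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    try:
        table = validate_survival(table)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from None
    log_stage("read_survival", path=str(path), samples=len(table))
    return table


def write_survival(table: pd.DataFrame, path: str | Path) -> None:
    validate_survival(table).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Networks
# ---------------------------------------------------------------------------

NETWORK_FORMATS = ("edgelist", "sif", "graphml")


def _graph_of(network) -> nx.Graph:
    return network.graph if hasattr(network, "graph") else network


def write_network(network, path: str | Path, fmt: str = "graphml") -> None:
    """Write a ceRNA network; GraphML and edge-list TSV round-trip exactly."""
    graph = _graph_of(network)
    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(graph, path)
    elif fmt == "edgelist":
        rows = []
        for u, v, data in sorted(graph.edges(data=True)):
            rows.append({"source": u, "target": v, "kind": data.get("kind", ""),
                         "source_type": graph.nodes[u].get("node_type", ""),
                         "target_type": graph.nodes[v].get("node_type", "")})
        pd.DataFrame(rows, columns=["source", "target", "kind", "source_type",
                                    "target_type"]).to_csv(path, sep="\t", index=False)
    elif fmt == "sif":
        with open(path, "w") as handle:
            for u, v, data in sorted(graph.edges(data=True)):
                # write the miRNA endpoint first so node types are recoverable
                if graph.nodes[v].get("node_type") == "miRNA":
                    u, v = v, u
                handle.write(f"{u}\t{data.get('kind', 'interacts')}\t{v}\n")
    else:
        raise FormatError(f"unknown network format {fmt!r} (use one of {NETWORK_FORMATS})")
    log_stage("write_network", path=str(path), fmt=fmt,
              nodes=graph.number_of_nodes(), edges=graph.number_of_edges())


def read_network(path: str | Path, fmt: str = "graphml") -> nx.Graph:
    """Read a network written by :func:`write_network`."""
    path = Path(path)
    if fmt == "graphml":
        return nx.read_graphml(path)
    graph = nx.Graph()
    if fmt == "edgelist":
        table = pd.read_csv(path, sep="\t", dtype=str)
        for row in table.itertuples(index=False):
            graph.add_node(row.source, node_type=row.source_type)
            graph.add_node(row.target, node_type=row.target_type)
            graph.add_edge(row.source, row.target, kind=row.kind)
        return graph
    if fmt == "sif":
        for lineno, line in _data_lines(path):
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: SIF line needs >= 3 fields")
            mirna, kind, partners = fields[0], fields[1], fields[2:]
            partner_type = kind.split("-")[-1] if "-" in kind else ""
            graph.add_node(mirna, node_type="miRNA")
            for partner in partners:
                graph.add_node(partner, node_type=partner_type)
                graph.add_edge(mirna, partner, kind=kind)
        return graph
    raise FormatError(f"unknown network format {fmt!r} (use one of {NETWORK_FORMATS})")
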