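"""Readers and writers for the pipeline's plain-text formats.

Expression matrices travel as TSV with a leading ``probe_id`` column and
one column per sample; sample sheets as three-column TSV (sample_id,
subject_id, condition).  Decimal commas ("5,1") are accepted in numeric
cells, as European spreadsheet exports commonly produce them.  Gene
lists are one symbol per line; ontologies are read either from an
edge-list TSV (term_id, parent_id, name) or from a minimal OBO subset
([Term] stanzas with id:, name: and is_a: lines).
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .simulate import ExpressionDataset, TruthTable

__all__ = [
    "ParseError",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_sample_sheet",
    "read_gene_list",
    "write_gene_list",
    "read_ontology_edges",
    "read_obo",
    "read_annotations",
    "write_dataset",
    "read_de_table",
]


class ParseError(ValueError):
    """Malformed input file; message carries the offending line."""


def _to_float(cell: str, path: Path, line_no: int) -> float:
    txt = str(cell).strip().replace(",", ".")
    try:
        return float(txt)
    except ValueError:
        raise ParseError(
            f"{path}:{line_no}: non-numeric cell {cell!r}"
        ) from None


def read_expression_tsv(path, samples_path=None) -> ExpressionDataset:
    """Read a probe x sample intensity TSV (+ optional sample sheet).

    Errors on ragged rows, duplicate probe ids and non-numeric cells,
    reporting the offending line.  Without a sample sheet, sample ids
    are parsed from headers of the form ``R<subject>_<time>`` where the
    0 h time point is the reference.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise ParseError(f"{path}:1: expected probe_id plus sample columns")
        sample_ids = header[1:]
        probe_ids: list[str] = []
        genes: list[str] = []
        has_gene = header[1].lower() in ("gene", "gene symbol", "gene_symbol")
        if has_gene:
            sample_ids = header[2:]
        rows = []
        seen = set()
        for line_no, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise ParseError(
                    f"{path}:{line_no}: expected {len(header)} columns, "
                    f"got {len(parts)}"
                )
            pid = parts[0].strip()
            if pid in seen:
                raise ParseError(f"{path}:{line_no}: duplicate probe id {pid!r}")
            seen.add(pid)
            probe_ids.append(pid)
            if has_gene:
                genes.append(parts[1].strip())
                cells = parts[2:]
            else:
                genes.append(pid)
                cells = parts[1:]
            rows.append([_to_float(c, path, line_no) for c in cells])
    matrix = pd.DataFrame(
        np.asarray(rows, dtype=float),
        index=pd.Index(probe_ids, name="probe_id"),
        columns=sample_ids,
    )
    if samples_path is not None:
        sheet = read_sample_sheet(samples_path)
    else:
        records = []
        for sid in sample_ids:
            subject, _, time = sid.partition("_")
            cond = "reference" if time.startswith("0") else "treated"
            records.append(
                {"sample_id": sid, "subject_id": subject, "condition": cond}
            )
        sheet = pd.DataFrame(records)
    sheet = sheet.set_index("sample_id").loc[sample_ids].reset_index()
    return ExpressionDataset(
        intensities=matrix,
        sample_sheet=sheet,
        probe_annotation=pd.Series(genes, index=matrix.index, name="gene"),
    )


def write_expression_tsv(dataset: ExpressionDataset, path, gene_column=True) -> None:
    path = Path(path)
    out = dataset.intensities.copy()
    if gene_column:
        out.insert(0, "gene", dataset.probe_annotation.reindex(out.index))
    out.to_csv(path, sep="\t")


def read_sample_sheet(path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "subject_id", "condition"}
    missing = required - set(sheet.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    return sheet[["sample_id", "subject_id", "condition"]]


def read_gene_list(path) -> list[str]:
    """One symbol per line, upper-cased, blanks skipped, order kept."""
    out: list[str] = []
    seen = set()
    for line in Path(path).read_text().splitlines():
        g = line.strip().upper()
        if g and g not in seen:
            seen.add(g)
            out.append(g)
    return out


def write_gene_list(genes, path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))


def read_ontology_edges(path) -> nx.DiGraph:
    """Edge-list TSV: term_id, parent_id, name (parent empty for root)."""
    path = Path(path)
    dag = nx.DiGraph()
    with open(path) as fh:
        header = fh.readline()
        if not header.lower().startswith("term_id"):
            raise ParseError(f"{path}:1: expected header term_id/parent_id/name")
        for line_no, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise ParseError(f"{path}:{line_no}: expected >= 2 columns")
            term, parent = parts[0].strip(), parts[1].strip()
            name = parts[2].strip() if len(parts) > 2 else ""
            dag.add_node(term, name=name)
            if parent:
                dag.add_edge(term, parent)
    return dag


def write_ontology_edges(dag: nx.DiGraph, path) -> None:
    lines = ["term_id\tparent_id\tname\n"]
    for term in sorted(dag.nodes):
        parents = sorted(dag.successors(term))
        name = dag.nodes[term].get("name", "")
        if not parents:
            lines.append(f"{term}\t\t{name}\n")
        for p in parents:
            lines.append(f"{term}\t{p}\t{name}\n")
    Path(path).write_text("".join(lines))


def read_obo(path) -> nx.DiGraph:
    """Read an OBO ontology, keeping only is-a edges (child -> parent)."""
    import obonet

    multigraph = obonet.read_obo(Path(path))
    dag = nx.DiGraph()
    for node, data in multigraph.nodes(data=True):
        dag.add_node(node, name=data.get("name", ""))
    for child, parent, key in multigraph.edges(keys=True):
        if key == "is_a":
            dag.add_edge(child, parent)
    return dag


def read_annotations(path) -> dict[str, set[str]]:
    """Two-column TSV gene<TAB>term_id -> gene -> set of term ids."""
    ann: dict[str, set[str]] = {}
    path = Path(path)
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            if not line.strip() or line.lower().startswith("gene\t"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise ParseError(f"{path}:{line_no}: expected gene<TAB>term_id")
            ann.setdefault(parts[0].strip().upper(), set()).add(parts[1].strip())
    return ann


def write_annotations(annotations: dict[str, set[str]], path) -> None:
    lines = ["gene\tterm_id\n"]
    for gene in sorted(annotations):
        for term in sorted(annotations[gene]):
            lines.append(f"{gene}\t{term}\n")
    Path(path).write_text("".join(lines))


def write_dataset(dataset: ExpressionDataset, truth: TruthTable, out_dir) -> None:
    """Write a simulated dataset: matrix, sample sheet and truth table."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_expression_tsv(dataset, out_dir / "expression.tsv", gene_column=False)
    dataset.sample_sheet.to_csv(out_dir / "samples.tsv", sep="\t", index=False)
    truth.probes.to_csv(out_dir / "truth.tsv", sep="\t", index=False)
    truth.calibration.to_csv(out_dir / "calibration_truth.tsv", sep="\t",
                             index=False)


def read_de_table(path) -> pd.DataFrame:
    """Read a differential-expression table exported to TSV.

    Accepts both this package's column names (gene, logFC, adj_p) and the
    spreadsheet-export dialect ("Gene symbol", "logFC", "adj. P.Val")
    with decimal commas.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    colmap = {}
    for col in df.columns:
        key = col.strip().lower()
        if key in ("gene symbol", "gene_symbol", "gene"):
            colmap[col] = "gene"
        elif key == "logfc":
            colmap[col] = "logFC"
        elif key in ("adj. p.val", "adj.p.val", "adj_p", "adj.p"):
            colmap[col] = "adj_p"
        elif key in ("p.value", "p", "p value"):
            colmap[col] = "p"
    df = df.rename(columns=colmap)
    if "gene" not in df.columns or "logFC" not in df.columns:
        raise ParseError(f"{path}: need gene and logFC columns")
    for col in ("logFC", "adj_p", "p"):
        if col in df.columns:
            df[col] = [
                _to_float(v, path, i + 2) for i, v in enumerate(df[col])
            ]
    df["gene"] = df["gene"].str.strip().str.strip("*").str.upper()
    return df


def write_json_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
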