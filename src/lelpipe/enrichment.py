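"""Over-representation analysis on an ontology DAG.

Terms form a rooted is-a DAG (edges child -> parent).  Gene annotations
obey the true-path rule: a gene annotated to a term is implicitly
annotated to every ancestor, so each term's effective gene set is the
union of direct annotations over the term and all its descendants.

Each term is scored with the one-sided hypergeometric upper tail
P(X >= k) for k list genes among its ``size`` universe genes.  The
conditional variant walks the DAG children-first: when a term has
children already significant at ``alpha_cond``, the genes those children
contributed are removed from the term's gene set before testing, so a
parent is only called enriched for signal its significant children do
not already explain.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd
from scipy.stats import hypergeom

__all__ = [
    "OntologyError",
    "validate_dag",
    "propagate_annotations",
    "hypergeom_test",
    "conditional_enrichment",
]


class OntologyError(ValueError):
    """Structural problem with the term DAG or its annotations."""


def validate_dag(dag: nx.DiGraph) -> str:
    """Check acyclicity and a single root; return the root term id.

    Edges must run child -> parent; the root is the unique term with no
    outgoing edge, and every term must reach it.
    """
    if not nx.is_directed_acyclic_graph(dag):
        raise OntologyError("ontology graph contains a cycle")
    roots = [t for t in dag.nodes if dag.out_degree(t) == 0]
    if len(roots) != 1:
        raise OntologyError(f"expected a single root, found {sorted(roots)}")
    root = roots[0]
    for term in dag.nodes:
        if term != root and not nx.has_path(dag, term, root):
            raise OntologyError(f"term {term} cannot reach the root")
    return root


def propagate_annotations(
    dag: nx.DiGraph, annotations: dict[str, set[str]]
) -> dict[str, set[str]]:
    """True-path closure: term -> genes of the term and all descendants.

    ``annotations`` maps gene -> directly annotated term ids.  Raises
    :class:`OntologyError` listing any annotation to an unknown term.
    """
    validate_dag(dag)
    unknown = sorted(
        {t for terms in annotations.values() for t in terms if t not in dag}
    )
    if unknown:
        raise OntologyError(f"annotations reference unknown terms: {unknown}")
    direct: dict[str, set[str]] = {t: set() for t in dag.nodes}
    for gene, terms in annotations.items():
        for t in terms:
            direct[t].add(gene)
    closed: dict[str, set[str]] = {}
    # children before parents (edges child -> parent => topological order)
    for term in nx.lexicographical_topological_sort(dag):
        genes = set(direct[term])
        for child in dag.predecessors(term):
            genes |= closed[child]
        closed[term] = genes
    return closed


def hypergeom_test(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail inclusive hypergeometric p-value P(X >= k).

    ``k`` list genes hit a term of ``K`` universe genes, with a list of
    ``n`` genes drawn from a universe of ``N``.
    """
    if not (0 <= k <= min(K, n) and 0 <= K <= N and 0 <= n <= N):
        raise ValueError(
            f"inconsistent counts: k={k}, K={K}, n={n}, N={N}"
        )
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def conditional_enrichment(
    dag: nx.DiGraph,
    closed_annotations: dict[str, set[str]],
    gene_list: set[str],
    universe: set[str],
    alpha_cond: float = 0.05,
) -> pd.DataFrame:
    """Term-by-term over-representation, conditional on the DAG.

    Terms are processed children-first (ties broken by term id).  A term
    whose children are already significant (conditional p < alpha_cond)
    is tested on its gene set minus those children's genes, shrinking
    both its ``count`` and its ``size``.  With ``alpha_cond = 0`` no
    child is ever significant and the test is plain hypergeometric.

    Returns a DataFrame sorted by p ascending with columns term, name,
    p, count, size and a ``conditioned`` flag.
    """
    validate_dag(dag)
    gene_list = set(gene_list)
    universe = set(universe)
    if not gene_list <= universe:
        missing = sorted(gene_list - universe)[:5]
        raise ValueError(f"gene list not contained in universe (e.g. {missing})")
    N = len(universe)
    n = len(gene_list)
    pvals: dict[str, float] = {}
    rows = []
    for term in nx.lexicographical_topological_sort(dag):
        term_genes = closed_annotations.get(term, set()) & universe
        removed: set[str] = set()
        for child in dag.predecessors(term):
            if pvals.get(child, 1.0) < alpha_cond:
                removed |= closed_annotations.get(child, set())
        conditioned = bool(removed & term_genes)
        term_genes = term_genes - removed
        size = len(term_genes)
        count = len(term_genes & gene_list)
        p = hypergeom_test(count, size, n, N)
        pvals[term] = p
        rows.append(
            {
                "term": term,
                "name": dag.nodes[term].get("name", ""),
                "p": p,
                "count": count,
                "size": size,
                "conditioned": conditioned,
            }
        )
    out = pd.DataFrame(rows)
    return out.sort_values(["p", "term"], kind="stable").reset_index(drop=True)
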