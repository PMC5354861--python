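"""Resnik-style functional similarity within one ontology namespace.

A gene pair's similarity is the information content (IC) of the most
informative common ancestor (MICA) of their annotated terms.  With
``n_t`` genes annotated (after true-path propagation) to term ``t`` out
of ``N`` genes in total,

    IC(t) = -ln(n_t / N),
    FS(g1, g2) = max{ IC(t) : t ancestor of both genes' terms }.

A term counts as its own ancestor, so FS(g, g) equals the IC of the
gene's rarest term.  Unannotated genes and pairs without a common
ancestor score 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import obonet
import pandas as pd

__all__ = [
    "OntologyDag",
    "AnnotationMap",
    "propagate_annotations",
    "compute_ic",
    "gene_pair_fs_go",
    "read_annotations",
    "GoContext",
]

_RELATIONS = ("is_a", "part_of")


@dataclass(frozen=True)
class OntologyDag:
    """Rooted acyclic ontology with child->parent is_a / part_of edges."""

    terms: frozenset[str]
    edges: frozenset[tuple[str, str, str]]  # (child, parent, relation)
    namespace: str = "synthetic"

    def __post_init__(self) -> None:
        for child, parent, rel in self.edges:
            if rel not in _RELATIONS:
                raise ValueError(f"unsupported relation {rel!r}")
            if child not in self.terms or parent not in self.terms:
                raise ValueError(f"edge {child}->{parent} references unknown term")
        g = nx.DiGraph((c, p) for c, p, _ in self.edges)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("ontology contains a cycle")

    @property
    def parents(self) -> Mapping[str, frozenset[str]]:
        try:
            return self._parents  # type: ignore[attr-defined]
        except AttributeError:
            pass
        out: dict[str, set[str]] = {t: set() for t in self.terms}
        for child, parent, _ in self.edges:
            out[child].add(parent)
        frozen = {t: frozenset(ps) for t, ps in out.items()}
        object.__setattr__(self, "_parents", frozen)
        return frozen

    @property
    def roots(self) -> frozenset[str]:
        return frozenset(t for t, ps in self.parents.items() if not ps)

    def ancestors(self, term: str) -> frozenset[str]:
        """All ancestors of ``term`` including the term itself."""
        try:
            cache = self._anc  # type: ignore[attr-defined]
        except AttributeError:
            cache = {}
            object.__setattr__(self, "_anc", cache)
        got = cache.get(term)
        if got is not None:
            return got
        closure = {term}
        stack = [term]
        parents = self.parents
        while stack:
            for p in parents[stack.pop()]:
                if p not in closure:
                    closure.add(p)
                    stack.append(p)
        result = frozenset(closure)
        cache[term] = result
        return result

    @classmethod
    def from_obo(cls, path: str | Path, namespace: str | None = None) -> "OntologyDag":
        """Load an OBO 1.2 flat file; obsolete terms are dropped and only
        is_a / part_of relationships are kept.  If ``namespace`` is given,
        terms from other namespaces are discarded."""
        graph = obonet.read_obo(path)
        keep = set()
        for term, data in graph.nodes(data=True):
            if namespace is not None and data.get("namespace") != namespace:
                continue
            keep.add(term)
        edges = set()
        for child, parent, rel in graph.edges(keys=True):
            if rel in _RELATIONS and child in keep and parent in keep:
                edges.add((child, parent, rel))
        ns = namespace or "synthetic"
        return cls(frozenset(keep), frozenset(edges), namespace=ns)


@dataclass(frozen=True)
class AnnotationMap:
    """Direct and true-path propagated gene -> term annotations."""

    direct: Mapping[str, frozenset[str]]
    propagated: Mapping[str, frozenset[str]]
    genome_size: int

    def __post_init__(self) -> None:
        if self.genome_size < len(self.propagated):
            raise ValueError(
                "genome_size must be at least the number of annotated genes"
            )


def propagate_annotations(
    dag: OntologyDag,
    direct: Mapping[str, Iterable[str]],
    genome_size: int | None = None,
) -> AnnotationMap:
    """Close each gene's annotation upward through is_a / part_of links.

    ``genome_size`` defaults to the number of annotated genes; pass a
    larger value to use a fixed genome-wide denominator for IC.
    """
    unknown = sorted(
        {t for terms in direct.values() for t in terms} - set(dag.terms)
    )
    if unknown:
        raise ValueError(f"annotations reference unknown terms: {unknown}")
    direct_f = {g: frozenset(ts) for g, ts in direct.items()}
    propagated = {
        g: frozenset().union(*(dag.ancestors(t) for t in ts)) if ts else frozenset()
        for g, ts in direct_f.items()
    }
    n = genome_size if genome_size is not None else len(direct_f)
    return AnnotationMap(direct_f, propagated, genome_size=n)


def compute_ic(dag: OntologyDag, ann: AnnotationMap) -> dict[str, float]:
    """IC(t) = -ln(n_t / N) for every term annotating >= 1 gene."""
    counts: dict[str, int] = {}
    for terms in ann.propagated.values():
        for t in terms:
            counts[t] = counts.get(t, 0) + 1
    N = ann.genome_size
    bad = sorted(t for t, n in counts.items() if n > N)
    if bad:
        raise ValueError(f"terms annotate more genes than genome_size: {bad}")
    return {t: -math.log(n / N) for t, n in counts.items()}


def gene_pair_fs_go(
    g1: str,
    g2: str,
    dag: OntologyDag,
    ann: AnnotationMap,
    ic: Mapping[str, float],
) -> float:
    """IC of the most informative common ancestor; 0 for degenerate input."""
    t1 = ann.propagated.get(g1, frozenset())
    t2 = ann.propagated.get(g2, frozenset())
    common = t1 & t2
    if not common:
        return 0.0
    return max(ic[t] for t in common)


def read_annotations(path: str | Path) -> dict[str, frozenset[str]]:
    """Read gene -> term annotations from GAF 2.x or a two-column TSV.

    GAF files are recognized by their column count (>= 15); only the
    object-id and term columns are used and NOT-qualified rows dropped.
    """
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="!")
    if df.shape[1] >= 15:
        qualifier = df.iloc[:, 3].fillna("")
        keep = ~qualifier.str.contains("NOT", na=False)
        genes, terms = df.loc[keep].iloc[:, 1], df.loc[keep].iloc[:, 4]
    elif df.shape[1] >= 2:
        first = [str(v).strip().lower() for v in df.iloc[0, :2]]
        if first[0] in {"gene", "gene_id", "lncrna_id"} or first[1] in {
            "term", "term_id", "go_id",
        }:
            df = df.iloc[1:]
        genes, terms = df.iloc[:, 0], df.iloc[:, 1]
    else:
        raise ValueError(f"{path}: expected a GAF or two-column TSV")
    out: dict[str, set[str]] = {}
    for g, t in zip(genes, terms):
        out.setdefault(str(g).strip(), set()).add(str(t).strip())
    return {g: frozenset(ts) for g, ts in out.items()}


class GoContext:
    """Functional context backed by one annotated ontology namespace."""

    def __init__(
        self,
        dag: OntologyDag,
        ann: AnnotationMap,
        ic: Mapping[str, float] | None = None,
        name: str | None = None,
    ) -> None:
        self.dag = dag
        self.ann = ann
        self.ic = dict(ic) if ic is not None else compute_ic(dag, ann)
        self.name = name if name is not None else dag.namespace
        self._cache: dict[tuple[str, str], float] = {}

    def covers(self, gene_id: str) -> bool:
        return bool(self.ann.propagated.get(gene_id))

    def gene_fs(self, g1: str, g2: str) -> float:
        key = (g1, g2) if g1 <= g2 else (g2, g1)
        fs = self._cache.get(key)
        if fs is None:
            fs = gene_pair_fs_go(g1, g2, self.dag, self.ann, self.ic)
            self._cache[key] = fs
        return fs
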