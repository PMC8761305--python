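"""Ontology handling: OBO parsing, ancestor propagation, information accretion.

Only ``is_a`` and ``relationship: part_of`` edges are kept — the relations
along which functional annotation propagates in protein-centric evaluation;
regulates-type edges are ignored.  Information accretion, the per-term weight
used by the semantic-distance metric, is the negative base-2 log of a term's
probability conditional on all its parents being annotated, estimated from a
propagated annotation corpus; root terms carry zero accretion.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field
from math import log2
from pathlib import Path

import networkx as nx
import obonet

logger = logging.getLogger(__name__)

_RELATIONS = ("is_a", "part_of")


@dataclass
class OntologyDAG:
    """Directed acyclic term graph (child -> parents over is_a / part_of)."""

    parents: dict[str, frozenset[str]]
    namespaces: dict[str, str]
    roots: frozenset[str]
    obsolete: frozenset[str]
    alt_ids: dict[str, str] = field(default_factory=dict)

    def __contains__(self, term: str) -> bool:
        return term in self.parents or term in self.alt_ids or term in self.obsolete

    def resolve(self, term: str) -> str:
        """Map an alternate id to its primary term id (identity otherwise)."""
        return self.alt_ids.get(term, term)

    def ancestors(self, term: str) -> set[str]:
        """All ancestors of a term (excluding the term itself)."""
        term = self.resolve(term)
        out: set[str] = set()
        stack = list(self.parents.get(term, ()))
        while stack:
            t = stack.pop()
            if t not in out:
                out.add(t)
                stack.extend(self.parents.get(t, ()))
        return out


def parse_obo(path: str | Path) -> OntologyDAG:
    """Parse an OBO 1.2 file into an :class:`OntologyDAG`.

    Keeps ``is_a`` and ``relationship: part_of`` edges; obsolete terms are
    recorded but carry no edges; ``alt_id`` lines map aliases to their primary
    id.  Edges pointing at undefined terms are dropped with a warning; a cycle
    is a fatal error.
    """
    graph = obonet.read_obo(Path(path), ignore_obsolete=False)

    parents: dict[str, frozenset[str]] = {}
    namespaces: dict[str, str] = {}
    obsolete: set[str] = set()
    alt_ids: dict[str, str] = {}

    term_ids = set(graph.nodes)
    for term, data in graph.nodes(data=True):
        namespaces[term] = data.get("namespace", "")
        for alias in data.get("alt_id", []):
            alt_ids[alias] = term
        if data.get("is_obsolete") == "true":
            obsolete.add(term)
            continue
        term_parents: set[str] = set()
        for parent in data.get("is_a", []):
            parent = parent.split("!")[0].strip()
            if parent in term_ids:
                term_parents.add(parent)
            else:
                logger.warning("dropping is_a edge %s -> undefined term %s", term, parent)
        for rel in data.get("relationship", []):
            fields = rel.split()
            if len(fields) >= 2 and fields[0] == "part_of":
                parent = fields[1]
                if parent in term_ids:
                    term_parents.add(parent)
                else:
                    logger.warning("dropping part_of edge %s -> undefined term %s", term, parent)
        parents[term] = frozenset(term_parents)

    dag = nx.DiGraph((child, parent) for child, ps in parents.items() for parent in ps)
    if not nx.is_directed_acyclic_graph(dag):
        raise ValueError(f"ontology {path} contains a cycle among is_a/part_of edges")

    roots = frozenset(t for t, ps in parents.items() if not ps)
    return OntologyDAG(
        parents=parents,
        namespaces=namespaces,
        roots=roots,
        obsolete=frozenset(obsolete),
        alt_ids=alt_ids,
    )


def propagate(terms: Iterable[str], dag: OntologyDAG, exclude_roots: bool = False) -> set[str]:
    """Close a term set under the ancestor relation (idempotent).

    Unknown terms are dropped with a warning; with ``exclude_roots`` the
    namespace roots are removed from the result.
    """
    out: set[str] = set()
    for term in terms:
        term = dag.resolve(term)
        if term not in dag.parents:
            logger.warning("dropping unknown ontology term %s", term)
            continue
        out.add(term)
        out |= dag.ancestors(term)
    if exclude_roots:
        out -= dag.roots
    return out


def propagate_annotations(
    annotations: Mapping[str, set[str]], dag: OntologyDAG, exclude_roots: bool = False
) -> dict[str, set[str]]:
    """Propagate every protein's term set; proteins losing all terms are dropped."""
    out = {}
    for prot, terms in annotations.items():
        prop = propagate(terms, dag, exclude_roots=exclude_roots)
        if prop:
            out[prot] = prop
    return out


@dataclass
class TermIC:
    """Per-term information accretion in bits (non-negative; zero at roots)."""

    ia: dict[str, float]
    pseudo_count: float = 1.0

    def get(self, term: str) -> float:
        return self.ia.get(term, 0.0)


def information_accretion(
    annotations: Mapping[str, set[str]],
    dag: OntologyDAG,
    pseudo_count: float = 1.0,
) -> TermIC:
    """Estimate information accretion from a propagated annotation corpus.

    ``ia(t) = -log2( n(t) / n(parents of t) )`` where ``n(t)`` counts proteins
    annotated with ``t`` and ``n(parents)`` counts proteins annotated with
    *all* parents of ``t``.  Roots get 0.  A term never seen in the corpus
    (``n(t) = 0``) gets ``-log2( pc / (n(parents) + pc) )`` so its weight stays
    finite and configurable via ``pseudo_count``.
    """
    ia: dict[str, float] = {}
    for term, term_parents in dag.parents.items():
        if not term_parents:
            ia[term] = 0.0
            continue
        n_term = sum(1 for terms in annotations.values() if term in terms)
        n_parents = sum(1 for terms in annotations.values() if term_parents <= terms)
        if n_term > 0:
            # a fully propagated corpus guarantees n_parents >= n_term; a corpus
            # stripped of some ancestors (e.g. root-free sets) may not, so clamp
            n_parents = max(n_parents, n_term)
            ia[term] = max(-log2(n_term / n_parents), 0.0)
        else:
            ia[term] = -log2(pseudo_count / (n_parents + pseudo_count))
    return TermIC(ia=ia, pseudo_count=pseudo_count)
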