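"""Tripartite domain-protein-function networks.

Proteins form the middle layer of a three-layer graph: each protein carries a
set of structural-domain annotations (e.g. CATH-Gene3D superfamilies or
FunFams) and a set of functional annotations (GO terms, KEGG or Reactome
pathways).  Domains and functions are never linked directly; every
domain-function association is mediated by the proteins they share.

The network exposes the neighbour sets the association indices operate on:
``Np(D)`` (proteins of a domain), ``Np(F)`` (proteins of a function) and
``n_total`` (the number of protein nodes).
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field
from pathlib import Path

logger = logging.getLogger(__name__)

DOMAIN_LAYER = "domain"
FUNCTION_LAYER = "function"
_LAYERS = (DOMAIN_LAYER, FUNCTION_LAYER)


@dataclass
class AnnotationPairs:
    """Deduplicated (protein, feature[, evidence]) annotation pairs for one layer.

    Parameters
    ----------
    pairs
        Tuples ``(protein_id, feature_id, evidence)``; evidence is ``None``
        when the source file had no third column.
    layer
        ``"domain"`` or ``"function"``.
    source_label
        Free-text tag of the annotation source (e.g. ``"FunFam"``, ``"GOMF"``).
    n_lines_read, n_duplicates
        Parsing diagnostics (lines consumed, duplicate pairs collapsed).
    """

    pairs: list[tuple[str, str, str | None]]
    layer: str
    source_label: str = ""
    n_lines_read: int = 0
    n_duplicates: int = 0

    def __post_init__(self) -> None:
        if self.layer not in _LAYERS:
            raise ValueError(f"layer must be one of {_LAYERS}, got {self.layer!r}")

    @property
    def has_evidence(self) -> bool:
        return any(ev is not None for _, _, ev in self.pairs)

    def proteins(self) -> set[str]:
        return {p for p, _, _ in self.pairs}

    def to_mapping(self) -> dict[str, set[str]]:
        """protein id -> set of feature ids."""
        out: dict[str, set[str]] = {}
        for prot, feat, _ in self.pairs:
            out.setdefault(prot, set()).add(feat)
        return out


def read_pairs_file(path: str | Path, layer: str, source_label: str = "") -> AnnotationPairs:
    """Read a 2-3 column tab-separated annotation file.

    Each non-empty, non-comment (``#``-prefixed) line must hold
    ``protein<TAB>feature`` with an optional third evidence column.
    Duplicate (protein, feature) rows are collapsed, keeping the first
    evidence value seen.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"annotation pair file not found: {path}")

    pairs: list[tuple[str, str, str | None]] = []
    seen: set[tuple[str, str]] = set()
    n_lines = 0
    n_dups = 0
    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) not in (2, 3):
                raise ValueError(
                    f"{path}:{lineno}: expected 2-3 tab-separated columns, got {len(cols)}"
                )
            prot, feat = cols[0].strip(), cols[1].strip()
            if not prot or not feat:
                raise ValueError(f"{path}:{lineno}: empty identifier")
            evidence = cols[2].strip() if len(cols) == 3 else None
            n_lines += 1
            key = (prot, feat)
            if key in seen:
                n_dups += 1
                continue
            seen.add(key)
            pairs.append((prot, feat, evidence))

    if not pairs:
        logger.warning("no annotation pairs read from %s", path)
    logger.info("%s: read %d lines, %d pairs, %d duplicates dropped", path, n_lines, len(pairs), n_dups)
    return AnnotationPairs(pairs, layer, source_label, n_lines_read=n_lines, n_duplicates=n_dups)


def write_pairs_file(pairs: AnnotationPairs, path: str | Path) -> None:
    """Serialize pairs back to the tab-separated dialect ``read_pairs_file`` consumes."""
    with Path(path).open("w", encoding="utf-8") as fh:
        for prot, feat, ev in pairs.pairs:
            if ev is None:
                fh.write(f"{prot}\t{feat}\n")
            else:
                fh.write(f"{prot}\t{feat}\t{ev}\n")


def filter_annotations(
    pairs: AnnotationPairs,
    excluded_evidence: Iterable[str] = (),
    excluded_protein_flags: Iterable[str] = (),
    protein_flags: Mapping[str, set[str]] | None = None,
) -> AnnotationPairs:
    """Apply evidence-code and protein-flag quality filters.

    Annotations whose evidence code is in ``excluded_evidence`` (e.g. ``IEA``,
    "Inferred from Electronic Annotation") are dropped.  Proteins carrying any
    flag in ``excluded_protein_flags`` (e.g. ``fragment``) lose *all* their
    annotations.  With both exclusion sets empty the input is returned
    unchanged (same object contents, new container).
    """
    excluded_evidence = set(excluded_evidence)
    excluded_protein_flags = set(excluded_protein_flags)

    if excluded_evidence and not pairs.has_evidence:
        raise ValueError(
            "evidence-code filter requested but the annotation pairs carry no evidence column"
        )

    flagged: set[str] = set()
    if excluded_protein_flags and protein_flags:
        flagged = {
            prot for prot, flags in protein_flags.items() if flags & excluded_protein_flags
        }

    kept = [
        (prot, feat, ev)
        for prot, feat, ev in pairs.pairs
        if prot not in flagged and (ev is None or ev not in excluded_evidence)
    ]
    n_removed = len(pairs.pairs) - len(kept)
    if n_removed:
        logger.info("filter removed %d/%d annotation pairs", n_removed, len(pairs.pairs))
    return AnnotationPairs(
        kept, pairs.layer, pairs.source_label,
        n_lines_read=pairs.n_lines_read, n_duplicates=pairs.n_duplicates,
    )


@dataclass
class TripartiteNetwork:
    """Domain-protein-function network restricted to dually annotated proteins.

    Invariants: every protein has at least one edge in each layer;
    ``domain_to_proteins`` / ``function_to_proteins`` are exact inverses of
    the forward maps; ``n_total`` is the number of protein nodes.
    """

    protein_to_domains: dict[str, set[str]]
    protein_to_functions: dict[str, set[str]]
    domain_to_proteins: dict[str, set[str]]
    function_to_proteins: dict[str, set[str]]
    n_total: int
    dropped_domain_layer: int = 0
    dropped_function_layer: int = 0
    duplicate_domain_edges: int = 0
    duplicate_function_edges: int = 0

    def neighbor_proteins(self, node_id: str, layer: str) -> set[str]:
        """Return ``Np(node)``: the proteins connected to a domain or function node."""
        if layer == DOMAIN_LAYER:
            index = self.domain_to_proteins
        elif layer == FUNCTION_LAYER:
            index = self.function_to_proteins
        else:
            raise ValueError(f"layer must be one of {_LAYERS}, got {layer!r}")
        try:
            return index[node_id]
        except KeyError:
            raise KeyError(f"node {node_id!r} not found in {layer} layer") from None

    def summary(self) -> dict[str, int]:
        return {
            "proteins": self.n_total,
            "domains": len(self.domain_to_proteins),
            "functions": len(self.function_to_proteins),
            "domain_edges": sum(len(v) for v in self.protein_to_domains.values()),
            "function_edges": sum(len(v) for v in self.protein_to_functions.values()),
            "dropped_domain_layer": self.dropped_domain_layer,
            "dropped_function_layer": self.dropped_function_layer,
        }


def build_network(domain_pairs: AnnotationPairs, function_pairs: AnnotationPairs) -> TripartiteNetwork:
    """Assemble the tripartite network from the two annotation layers.

    Only proteins annotated in *both* layers become network nodes; the equations
    that consume ``n_total`` assume every protein can mediate a domain-function
    co-occurrence.  Counts of proteins dropped from each layer are recorded.
    """
    if not domain_pairs.pairs or not function_pairs.pairs:
        raise ValueError("both annotation layers must be non-empty")

    dom_map_all = domain_pairs.to_mapping()
    fun_map_all = function_pairs.to_mapping()
    shared = dom_map_all.keys() & fun_map_all.keys()
    if not shared:
        raise ValueError("empty network: no protein is annotated in both layers")

    protein_to_domains = {p: set(dom_map_all[p]) for p in shared}
    protein_to_functions = {p: set(fun_map_all[p]) for p in shared}

    domain_to_proteins: dict[str, set[str]] = {}
    for prot, doms in protein_to_domains.items():
        for d in doms:
            domain_to_proteins.setdefault(d, set()).add(prot)
    function_to_proteins: dict[str, set[str]] = {}
    for prot, funs in protein_to_functions.items():
        for f in funs:
            function_to_proteins.setdefault(f, set()).add(prot)

    # duplicate multiplicity (same pair listed twice in the source) is diagnostic only
    net = TripartiteNetwork(
        protein_to_domains=protein_to_domains,
        protein_to_functions=protein_to_functions,
        domain_to_proteins=domain_to_proteins,
        function_to_proteins=function_to_proteins,
        n_total=len(shared),
        dropped_domain_layer=len(dom_map_all) - len(shared),
        dropped_function_layer=len(fun_map_all) - len(shared),
        duplicate_domain_edges=domain_pairs.n_duplicates,
        duplicate_function_edges=function_pairs.n_duplicates,
    )
    logger.info(
        "network built: %d proteins (dropped %d domain-only, %d function-only)",
        net.n_total, net.dropped_domain_layer, net.dropped_function_layer,
    )
    return net


def neighbor_proteins(network: TripartiteNetwork, node_id: str, layer: str) -> set[str]:
    """Functional alias for :meth:`TripartiteNetwork.neighbor_proteins`."""
    return network.neighbor_proteins(node_id, layer)


def write_network(network: TripartiteNetwork, out_dir: str | Path) -> None:
    """Dump the network as two TSV edge lists plus a keyed summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with (out / "protein_domain_edges.tsv").open("w", encoding="utf-8") as fh:
        for prot in sorted(network.protein_to_domains):
            for d in sorted(network.protein_to_domains[prot]):
                fh.write(f"{prot}\t{d}\n")
    with (out / "protein_function_edges.tsv").open("w", encoding="utf-8") as fh:
        for prot in sorted(network.protein_to_functions):
            for f in sorted(network.protein_to_functions[prot]):
                fh.write(f"{prot}\t{f}\n")
    with (out / "network_summary.txt").open("w", encoding="utf-8") as fh:
        for key, value in network.summary().items():
            fh.write(f"{key}\t{value}\n")
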