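"""Synthetic tripartite networks, toy ontologies and benchmark splits.

The generator emulates the structure the prediction method assumes: each
domain is planted with a small set of functions, and a protein's functional
annotation is the union of its domains' planted functions, optionally
corrupted by noise.  Functions therefore co-occur with their domains via
shared proteins, exactly the signal the association indices measure.  A
fraction of proteins can be left without domain annotation (they receive
random functions instead), mimicking real proteins that lack structural-domain
assignments and bound the method's coverage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .network import DOMAIN_LAYER, FUNCTION_LAYER, AnnotationPairs

logger = logging.getLogger(__name__)


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic study condition.

    Defaults describe a clean, well-covered corpus: 500 proteins over 50
    domains and 20 functions, one planted function per domain, 1-3 domains per
    protein, no noise and no domainless proteins.  ``noise_rate`` is the
    probability that a planted (protein, function) edge is replaced by a
    uniformly random function; ``fraction_domainless`` is the probability a
    protein carries no domain annotation.  The same seed reproduces the same
    corpus exactly.
    """

    n_proteins: int = 500
    n_domains: int = 50
    n_functions: int = 20
    planted_map: dict[str, set[str]] | None = None
    functions_per_domain: tuple[int, int] = (1, 1)
    domains_per_protein: tuple[int, int] = (1, 3)
    noise_rate: float = 0.0
    fraction_domainless: float = 0.0
    function_ids: list[str] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_proteins, self.n_domains, self.n_functions) < 1:
            raise ValueError("counts must be >= 1")
        for p in (self.noise_rate, self.fraction_domainless):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.domains_per_protein[0] < 1 or self.domains_per_protein[1] > self.n_domains:
            raise ValueError("domains_per_protein range must fit within [1, n_domains]")
        if self.function_ids is not None and len(self.function_ids) != self.n_functions:
            raise ValueError("function_ids must supply exactly n_functions identifiers")


def _default_function_ids(n: int) -> list[str]:
    return [f"F{i:04d}" for i in range(1, n + 1)]


def generate_network(
    spec: SyntheticSpec,
) -> tuple[AnnotationPairs, AnnotationPairs, dict[str, set[str]]]:
    """Draw one synthetic corpus: domain pairs, function pairs, ground truth.

    Ground truth maps each protein to its pre-noise function set (the union of
    its domains' planted functions, or the random functions assigned to a
    domainless protein).  The function layer holds the post-noise annotation.
    """
    rng = np.random.default_rng(spec.seed)
    proteins = [f"P{i:05d}" for i in range(1, spec.n_proteins + 1)]
    domains = [f"D{i:04d}" for i in range(1, spec.n_domains + 1)]
    functions = list(spec.function_ids) if spec.function_ids else _default_function_ids(spec.n_functions)

    planted = spec.planted_map
    if planted is None:
        lo, hi = spec.functions_per_domain
        planted = {}
        for d in domains:
            k = int(rng.integers(lo, hi + 1))
            chosen = rng.choice(len(functions), size=min(k, len(functions)), replace=False)
            planted[d] = {functions[i] for i in chosen}
    else:
        unknown = {f for fs in planted.values() for f in fs} - set(functions)
        if unknown:
            raise ValueError(f"planted_map references unknown functions: {sorted(unknown)[:5]}")

    domain_pairs: list[tuple[str, str, str | None]] = []
    function_pairs: list[tuple[str, str, str | None]] = []
    ground_truth: dict[str, set[str]] = {}
    lo_d, hi_d = spec.domains_per_protein

    for prot in proteins:
        domainless = rng.random() < spec.fraction_domainless
        n_dom = int(rng.integers(lo_d, hi_d + 1))
        if domainless:
            # annotated in the function layer only: draw functions at random
            idx = rng.choice(len(functions), size=min(n_dom, len(functions)), replace=False)
            truth = {functions[i] for i in idx}
        else:
            idx = rng.choice(len(domains), size=n_dom, replace=False)
            prot_domains = [domains[i] for i in idx]
            for d in sorted(prot_domains):
                domain_pairs.append((prot, d, None))
            truth = set().union(*(planted[d] for d in prot_domains))
        ground_truth[prot] = truth
        for f in sorted(truth):
            if spec.noise_rate > 0 and rng.random() < spec.noise_rate:
                f = functions[int(rng.integers(0, len(functions)))]
            function_pairs.append((prot, f, None))

    # corruption can create duplicate (protein, function) rows; collapse them
    seen: set[tuple[str, str]] = set()
    deduped = []
    for prot, f, ev in function_pairs:
        if (prot, f) not in seen:
            seen.add((prot, f))
            deduped.append((prot, f, ev))

    dom = AnnotationPairs(domain_pairs, DOMAIN_LAYER, source_label="synthetic-domains")
    fun = AnnotationPairs(deduped, FUNCTION_LAYER, source_label="synthetic-functions")
    logger.info(
        "synthetic corpus: %d proteins, %d domain edges, %d function edges",
        spec.n_proteins, len(domain_pairs), len(deduped),
    )
    return dom, fun, ground_truth


def resolve_planted_map(spec: SyntheticSpec) -> dict[str, set[str]]:
    """The planted map actually used for ``spec`` (regenerates the draw if implicit)."""
    if spec.planted_map is not None:
        return spec.planted_map
    rng = np.random.default_rng(spec.seed)
    domains = [f"D{i:04d}" for i in range(1, spec.n_domains + 1)]
    functions = list(spec.function_ids) if spec.function_ids else _default_function_ids(spec.n_functions)
    lo, hi = spec.functions_per_domain
    planted: dict[str, set[str]] = {}
    for d in domains:
        k = int(rng.integers(lo, hi + 1))
        chosen = rng.choice(len(functions), size=min(k, len(functions)), replace=False)
        planted[d] = {functions[i] for i in chosen}
    return planted


def generate_ontology(
    depth: int, branching: int, seed: int = 0, path: str | Path | None = None
) -> str:
    """Serialize a complete rooted tree of the given depth/branching as OBO 1.2.

    Term count is ``sum(branching**level for level in 0..depth)``.  The text is
    returned and optionally written to ``path``.
    """
    if depth < 1 or branching < 1:
        raise ValueError("depth and branching must be >= 1")
    lines = ["format-version: 1.2", "ontology: synthetic", ""]
    counter = 1

    def term_id(i: int) -> str:
        return f"SYN:{i:07d}"

    # breadth-first levels; parent of node i>1 is ((i-2)//branching)+1 in level order
    levels: list[list[int]] = [[counter]]
    ids_parent: dict[int, int] = {}
    for _ in range(depth):
        nxt: list[int] = []
        for parent in levels[-1]:
            for _ in range(branching):
                counter += 1
                nxt.append(counter)
                ids_parent[counter] = parent
        levels.append(nxt)

    for level_idx, level in enumerate(levels):
        for node in level:
            lines.append("[Term]")
            lines.append(f"id: {term_id(node)}")
            lines.append(f"name: synthetic term {node}")
            lines.append("namespace: synthetic_ontology")
            if node in ids_parent:
                lines.append(f"is_a: {term_id(ids_parent[node])} ! synthetic term {ids_parent[node]}")
            lines.append("")

    text = "\n".join(lines)
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text


def ontology_leaf_ids(depth: int, branching: int) -> list[str]:
    """Term ids of the deepest level of :func:`generate_ontology`'s tree."""
    first_leaf = sum(branching**level for level in range(depth)) + 1
    n_leaves = branching**depth
    return [f"SYN:{i:07d}" for i in range(first_leaf, first_leaf + n_leaves)]


def split_benchmark(
    domain_pairs: AnnotationPairs,
    function_pairs: AnnotationPairs,
    holdout_fraction: float,
    seed: int = 0,
) -> tuple[AnnotationPairs, AnnotationPairs, dict[str, set[str]]]:
    """Hold out a random protein subset's function annotations as benchmark truth.

    Withheld proteins keep their domain annotations (the predictor's input)
    but vanish from the training function layer; their function sets become
    the benchmark truth.  Mimics a temporal annotation split: the benchmark
    proteins are those that 'gain' annotation after training.
    """
    if not 0.0 < holdout_fraction < 1.0:
        raise ValueError("holdout_fraction must lie strictly between 0 and 1")
    fun_map = function_pairs.to_mapping()
    candidates = sorted(fun_map)
    n_hold = int(round(holdout_fraction * len(candidates)))
    if n_hold == 0 or n_hold == len(candidates):
        raise ValueError("split would leave an empty training or benchmark set")
    rng = np.random.default_rng(seed)
    held = set(rng.choice(candidates, size=n_hold, replace=False).tolist())

    train_fun = AnnotationPairs(
        [p for p in function_pairs.pairs if p[0] not in held],
        FUNCTION_LAYER,
        function_pairs.source_label,
    )
    truth = {p: set(fun_map[p]) for p in held}
    if not train_fun.pairs:
        raise ValueError("split left an empty training function layer")
    return domain_pairs, train_fun, truth
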