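import math
import random

import pytest

from dompred import AnnotationPairs, build_network
from dompred.network import DOMAIN_LAYER, FUNCTION_LAYER


def make_network(domain_map: dict[str, set[str]], function_map: dict[str, set[str]]):
    """Build a TripartiteNetwork from protein->domains / protein->functions dicts."""
    dom = AnnotationPairs(
        [(p, d, None) for p, ds in domain_map.items() for d in sorted(ds)], DOMAIN_LAYER
    )
    fun = AnnotationPairs(
        [(p, f, None) for p, fs in function_map.items() for f in sorted(fs)], FUNCTION_LAYER
    )
    return build_network(dom, fun)


def random_network(rng: random.Random, max_proteins: int = 20):
    """Small random tripartite network for oracle comparisons."""
    n_prot = rng.randint(2, max_proteins)
    n_dom = rng.randint(1, 6)
    n_fun = rng.randint(1, 6)
    proteins = [f"p{i}" for i in range(n_prot)]
    domain_map = {}
    function_map = {}
    for p in proteins:
        domain_map[p] = {f"d{rng.randrange(n_dom)}" for _ in range(rng.randint(1, 3))}
        function_map[p] = {f"f{rng.randrange(n_fun)}" for _ in range(rng.randint(1, 3))}
    return make_network(domain_map, function_map)


def hypergeom_tail_bruteforce(n_total: int, nd: int, nf: int, inter: int) -> float:
    """Exhaustive upper-tail hypergeometric probability via pmf enumeration."""
    tail = 0.0
    denom = math.comb(n_total, nf)
    for i in range(inter, min(nd, nf) + 1):
        tail += math.comb(nd, i) * math.comb(n_total - nd, nf - i) / denom
    return tail


def fisher_closed_form(p_values) -> float:
    """Even-dof chi-square survival: exp(-x/2) * sum_{i<k} (x/2)^i / i!."""
    x = -2.0 * sum(math.log(p) for p in p_values)
    half = x / 2.0
    return math.exp(-half) * sum(half**i / math.factorial(i) for i in range(len(p_values)))


@pytest.fixture
def tiny_network():
    """3 proteins, 2 domains, 2 functions with a known overlap structure."""
    return make_network(
        {"p1": {"d1"}, "p2": {"d1", "d2"}, "p3": {"d2"}},
        {"p1": {"f1"}, "p2": {"f1", "f2"}, "p3": {"f2"}},
    )


@pytest.fixture
def chain_obo(tmp_path):
    """Minimal 3-term chain ontology: leaf is_a mid is_a root."""
    text = """format-version: 1.2

[Term]
id: T:0000001
name: root
namespace: test

[Term]
id: T:0000002
name: mid
namespace: test
is_a: T:0000001 ! root

[Term]
id: T:0000003
name: leaf
namespace: test
alt_id: T:0000099
is_a: T:0000002 ! mid

[Term]
id: T:0000004
name: gone
namespace: test
is_obsolete: true
"""
    path = tmp_path / "chain.obo"
    path.write_text(text, encoding="utf-8")
    return path
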