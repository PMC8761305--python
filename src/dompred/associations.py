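"""Domain-function association indices over a tripartite network.

For a domain ``D`` and a function ``F`` sharing at least one protein, four
indices quantify how strongly their protein neighbourhoods overlap:

* Jaccard:   ``|Np(D) & Np(F)| / |Np(D) | Np(F)|``
* Simpson:   ``|Np(D) & Np(F)| / min(|Np(D)|, |Np(F)|)``
* PCC (phi): ``(|&|*nT - |Np(D)|*|Np(F)|) / sqrt(|Np(D)|*|Np(F)|*(nT-|Np(D)|)*(nT-|Np(F)|))``
* HyI:       ``-log10`` of the upper-tail hypergeometric probability of
  observing at least the seen overlap when ``|Np(F)|`` proteins are drawn
  without replacement from the ``nT`` network proteins.

Simpson normalises by the smaller neighbourhood, which copes with the large
size imbalance between domain and function protein sets; HyI is an
over-representation test statistic, larger for more surprising overlaps.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

from .network import DOMAIN_LAYER, FUNCTION_LAYER, TripartiteNetwork

logger = logging.getLogger(__name__)

METRICS = ("jaccard", "simpson", "pcc", "hyi")

#: -log10(p) cap applied when the hypergeometric tail underflows to zero.
DEFAULT_HYI_CAP = 300.0

_LN10 = math.log(10.0)


def jaccard_index(np_d: set[str], np_f: set[str]) -> float:
    """Intersection over union of the two protein neighbourhoods."""
    if not np_d or not np_f:
        raise ValueError("protein sets must be non-empty")
    inter = len(np_d & np_f)
    union = len(np_d) + len(np_f) - inter
    return inter / union


def simpson_index(np_d: set[str], np_f: set[str]) -> float:
    """Intersection over the size of the smaller neighbourhood."""
    if not np_d or not np_f:
        raise ValueError("protein sets must be non-empty")
    return len(np_d & np_f) / min(len(np_d), len(np_f))


def pcc_index(np_d: set[str], np_f: set[str], n_total: int) -> float:
    """Phi coefficient of the two membership indicators over ``n_total`` proteins."""
    nd, nf = len(np_d), len(np_f)
    if nd == 0 or nf == 0 or nd >= n_total or nf >= n_total:
        raise ValueError(
            "PCC undefined: neighbourhood sizes must lie strictly between 0 and n_total"
        )
    inter = len(np_d & np_f)
    num = inter * n_total - nd * nf
    den = math.sqrt(nd * nf * (n_total - nd) * (n_total - nf))
    return num / den


def hypergeometric_index(
    np_d: set[str], np_f: set[str], n_total: int, cap: float = DEFAULT_HYI_CAP
) -> float:
    """Upper-tail hypergeometric over-representation score, ``-log10 P(X >= |&|)``.

    Computed in log space (``hypergeom.logsf``) so small tails do not
    underflow; a tail that is numerically zero is capped at ``cap``.
    """
    if not np_d or not np_f:
        raise ValueError("protein sets must be non-empty")
    nd, nf = len(np_d), len(np_f)
    if nd > n_total or nf > n_total:
        raise ValueError("neighbourhood sizes cannot exceed n_total")
    inter = len(np_d & np_f)
    if inter == 0:
        return 0.0  # tail sums to 1
    # X ~ Hypergeom(population n_total, nd marked, nf drawn); P(X >= inter)
    log_tail = stats.hypergeom.logsf(inter - 1, n_total, nd, nf)
    if not np.isfinite(log_tail):
        logger.warning(
            "hypergeometric tail underflow (nT=%d, |D|=%d, |F|=%d, |&|=%d); capped at %g",
            n_total, nd, nf, inter, cap,
        )
        return cap
    hyi = -log_tail / _LN10
    # guard tiny negative rounding at inter == max overlap with tail ~ 1
    return min(max(hyi, 0.0), cap)


_INDEX_FUNCS = {
    "jaccard": lambda d, f, n: jaccard_index(d, f),
    "simpson": lambda d, f, n: simpson_index(d, f),
    "pcc": pcc_index,
    "hyi": hypergeometric_index,
}


@dataclass
class AssociationTable:
    """All (domain, function) association values for one metric on one network.

    ``mean`` and ``std`` (population form) summarise the value distribution;
    they parameterise the z-standardization used when combining values.
    """

    metric: str
    records: dict[tuple[str, str], float]
    mean: float
    std: float

    def __len__(self) -> int:
        return len(self.records)

    def by_domain(self) -> dict[str, dict[str, float]]:
        """domain -> {function: value}."""
        out: dict[str, dict[str, float]] = {}
        for (d, f), v in self.records.items():
            out.setdefault(d, {})[f] = v
        return out


def compute_associations(
    network: TripartiteNetwork, metric: str, hyi_cap: float = DEFAULT_HYI_CAP
) -> AssociationTable:
    """Score every (domain, function) pair that shares at least one protein.

    Zero-overlap pairs are omitted: they carry no co-occurrence signal and
    materialising the full cross-product is quadratic in the layer sizes.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")
    func = _INDEX_FUNCS[metric]
    nT = network.n_total
    records: dict[tuple[str, str], float] = {}
    for d, np_d in network.domain_to_proteins.items():
        overlap: Counter[str] = Counter()
        for prot in np_d:
            overlap.update(network.protein_to_functions[prot])
        for f in overlap:
            np_f = network.function_to_proteins[f]
            if metric == "pcc" and (len(np_d) == nT or len(np_f) == nT):
                # indicator is constant over the network: phi undefined, no signal
                logger.warning("PCC undefined for (%s, %s): a neighbourhood spans all proteins", d, f)
                continue
            if metric == "hyi":
                records[(d, f)] = func(np_d, np_f, nT, hyi_cap)
            else:
                records[(d, f)] = func(np_d, np_f, nT)
    values = np.fromiter(records.values(), dtype=float, count=len(records))
    mean = float(values.mean()) if len(values) else math.nan
    std = float(values.std()) if len(values) else math.nan  # population std
    return AssociationTable(metric=metric, records=records, mean=mean, std=std)


def write_associations(table: AssociationTable, path: str | Path) -> None:
    """Write a 3-column TSV (domain, function, value), sorted for reproducibility."""
    with Path(path).open("w", encoding="utf-8") as fh:
        for (d, f) in sorted(table.records):
            fh.write(f"{d}\t{f}\t{table.records[(d, f)]:.10g}\n")


def read_associations(path: str | Path, metric: str) -> AssociationTable:
    """Read a 3-column TSV back into an :class:`AssociationTable`."""
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")
    records: dict[tuple[str, str], float] = {}
    with Path(path).open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns, got {len(cols)}")
            records[(cols[0], cols[1])] = float(cols[2])
    values = np.fromiter(records.values(), dtype=float, count=len(records))
    mean = float(values.mean()) if len(values) else math.nan
    std = float(values.std()) if len(values) else math.nan
    return AssociationTable(metric=metric, records=records, mean=mean, std=std)
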