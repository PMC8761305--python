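"""Standardization, per-protein score combination and score-range normalization.

A protein with several domains supporting the same function gets one combined
score per function:

* Jaccard / Simpson / PCC values are z-standardized over the whole association
  table, ``z = (a - mean) / std`` (population std), and combined with
  Stouffer's method, ``Z = sum(z_i) / sqrt(k)``.  PCC values are taken in
  absolute value before standardization, since sign only encodes direction of
  co-occurrence.
* HyI values are turned back into upper-tail p-values, ``p = 10**(-HyI)``, and
  combined with Fisher's method: ``X = -2 * sum(ln p_i)`` referred to a
  chi-square distribution with ``2k`` degrees of freedom.

``k`` is the number of domains of the protein contributing a value for the
function being scored.

Submission-style normalization maps combined scores into (0, 1]: Stouffer
scores are re-standardized over the prediction run, clipped to [-2, 2] and
mapped through ``z/4 + 0.5``; Fisher combined p-values are mapped to ``1 - p``.
Scores below 0.001 are discarded as spurious.
"""

from __future__ import annotations

import logging
import math
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .associations import AssociationTable

logger = logging.getLogger(__name__)

COMBINERS = ("stouffer", "fisher")

#: normalized scores below this are removed as spurious predictions
MIN_SCORE = 0.001


@dataclass
class StandardizedTable:
    """Z-standardized association values (one metric, one network)."""

    records: dict[tuple[str, str], float]
    source_metric: str
    abs_transformed: bool
    mean: float
    std: float

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class CombinedScore:
    """Protein-level combined score for one function.

    ``raw`` is the Stouffer Z (method ``"stouffer"``) or the Fisher combined
    p-value (method ``"fisher"``); ``k`` counts the contributing domains.
    """

    protein_id: str
    function_id: str
    contributing_domains: frozenset[str]
    k: int
    raw: float
    method: str

    def __post_init__(self) -> None:
        if self.k != len(self.contributing_domains) or self.k < 1:
            raise ValueError("k must equal the number of contributing domains (>= 1)")


def standardize(table: AssociationTable, take_absolute: bool = False) -> StandardizedTable:
    """Z-standardize an association table: ``z = (v - mean) / std``.

    ``take_absolute`` applies ``abs`` to every value first (intended for PCC
    tables, whose sign carries no strength information); mean and population
    std are recomputed after the transform.
    """
    if not table.records:
        raise ValueError("cannot standardize an empty association table")
    keys = list(table.records)
    values = np.array([table.records[k] for k in keys], dtype=float)
    if take_absolute:
        values = np.abs(values)
    mean = float(values.mean())
    std = float(values.std())
    if std == 0.0:
        raise ValueError("degenerate association distribution: zero standard deviation")
    z = (values - mean) / std
    return StandardizedTable(
        records=dict(zip(keys, z.tolist())),
        source_metric=table.metric,
        abs_transformed=take_absolute,
        mean=mean,
        std=std,
    )


def stouffer_combine(z_values: Sequence[float]) -> float:
    """Stouffer's combined Z: ``sum(z_i) / sqrt(k)``."""
    if len(z_values) == 0:
        raise ValueError("cannot combine an empty sequence of z-scores")
    return float(sum(z_values) / math.sqrt(len(z_values)))


def hyi_to_pvalue(hyi: float) -> float:
    """Invert the hypergeometric index: ``p = 10**(-HyI)``, in (0, 1]."""
    if hyi < 0:
        raise ValueError("hypergeometric index must be non-negative")
    return 10.0 ** (-hyi)


def fisher_combine(p_values: Sequence[float]) -> float:
    """Fisher's combined probability: survival of ``-2*sum(ln p)`` under chi2(2k)."""
    if len(p_values) == 0:
        raise ValueError("cannot combine an empty sequence of p-values")
    arr = np.asarray(p_values, dtype=float)
    if np.any(arr <= 0) or np.any(arr > 1):
        raise ValueError("p-values must lie in (0, 1]")
    x = -2.0 * float(np.log(arr).sum())
    return float(stats.chi2.sf(x, df=2 * len(arr)))


def combine_for_protein(
    protein_id: str,
    per_domain_values: Mapping[str, Iterable[tuple[str, float]]],
    method: str,
) -> list[CombinedScore]:
    """Combine each function's per-domain values into one :class:`CombinedScore`.

    ``per_domain_values`` maps function id -> iterable of (domain id, value),
    where values are z-scores for ``"stouffer"`` and p-values for ``"fisher"``.
    """
    if method not in COMBINERS:
        raise ValueError(f"unknown combination method {method!r}; expected one of {COMBINERS}")
    out: list[CombinedScore] = []
    for function_id, pairs in per_domain_values.items():
        pairs = list(pairs)
        if not pairs:
            raise ValueError(f"function {function_id!r} has no contributing values")
        domains = frozenset(d for d, _ in pairs)
        values = [v for _, v in pairs]
        raw = stouffer_combine(values) if method == "stouffer" else fisher_combine(values)
        out.append(
            CombinedScore(
                protein_id=protein_id,
                function_id=function_id,
                contributing_domains=domains,
                k=len(domains),
                raw=raw,
                method=method,
            )
        )
    return out


def squash_z(z: float) -> float:
    """Map a z-score into [0, 1]: clip to [-2, 2], then ``z/4 + 0.5``."""
    return min(max(z, -2.0), 2.0) / 4.0 + 0.5


def normalize_scores(
    scores: Sequence[CombinedScore],
    method: str,
    min_score: float = MIN_SCORE,
    restandardize: bool = True,
) -> list[tuple[str, str, float]]:
    """Normalize combined scores into (0, 1] and drop those below ``min_score``.

    Stouffer path: raw combined Z values are re-standardized over the whole
    prediction run (population mean/std), clipped to [-2, 2] and mapped through
    ``z/4 + 0.5`` (set ``restandardize=False`` to treat the raw values as
    z-scores directly).  Fisher path: ``1 - p``.  The clip/4 + 0.5 map is
    monotone, so within-run rank order is preserved up to ties at the clip
    boundaries.
    """
    if method not in COMBINERS:
        raise ValueError(f"unknown combination method {method!r}; expected one of {COMBINERS}")
    if any(s.method != method for s in scores):
        raise ValueError("mixed-method combined scores passed to normalize_scores")
    if not scores:
        return []

    if method == "fisher":
        normalized = [1.0 - s.raw for s in scores]
    else:
        raw = np.array([s.raw for s in scores], dtype=float)
        if restandardize:
            std = float(raw.std())
            if std == 0.0:
                logger.warning("all combined scores identical; normalizing to 0.5")
                z = np.zeros_like(raw)
            else:
                z = (raw - raw.mean()) / std
        else:
            z = raw
        normalized = [squash_z(v) for v in z.tolist()]

    return [
        (s.protein_id, s.function_id, n)
        for s, n in zip(scores, normalized)
        if n >= min_score
    ]
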