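"""Protein function prediction from domain-function associations.

Given a query protein, look up its domains, collect every function associated
with at least one of them, combine the per-domain association values into one
score per function (Stouffer on z-scores, or Fisher on HyI-derived p-values)
and normalize the scores into (0, 1].  Proteins without domain annotation, or
whose domains have no recorded associations, are reported as unpredictable
with the reason — they determine the method's coverage.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field
from pathlib import Path

from .associations import AssociationTable
from .combine import (
    MIN_SCORE,
    CombinedScore,
    StandardizedTable,
    combine_for_protein,
    hyi_to_pvalue,
    normalize_scores,
)

logger = logging.getLogger(__name__)

NO_DOMAINS = "no-domains"
NO_ASSOCIATIONS = "no-associations"


@dataclass
class PredictionRecord:
    protein_id: str
    function_id: str
    domains: frozenset[str]
    raw: float
    normalized: float
    method_tag: str


@dataclass
class PredictionSet:
    """Ranked function predictions plus per-protein coverage bookkeeping.

    ``predicted_proteins`` and ``unpredictable_proteins`` partition the query
    set; every record's protein belongs to ``predicted_proteins``.
    """

    records: list[PredictionRecord] = field(default_factory=list)
    predicted_proteins: set[str] = field(default_factory=set)
    unpredictable_proteins: dict[str, str] = field(default_factory=dict)  # protein -> reason

    def by_protein(self) -> dict[str, dict[str, float]]:
        """protein -> {function: normalized score}."""
        out: dict[str, dict[str, float]] = {}
        for r in self.records:
            out.setdefault(r.protein_id, {})[r.function_id] = r.normalized
        return out

    def validate(self) -> None:
        if self.predicted_proteins & self.unpredictable_proteins.keys():
            raise ValueError("predicted and unpredictable protein sets overlap")
        for r in self.records:
            if r.protein_id not in self.predicted_proteins:
                raise ValueError(f"record protein {r.protein_id!r} not in predicted set")


def _association_lookup(
    associations: StandardizedTable | AssociationTable, method: str
) -> dict[str, dict[str, float]]:
    """domain -> {function: value}, converting HyI to p-values for Fisher."""
    if method == "stouffer":
        if not isinstance(associations, StandardizedTable):
            raise TypeError("Stouffer combination requires a z-standardized association table")
        items = associations.records.items()
        return _group(items)
    if method == "fisher":
        if not isinstance(associations, AssociationTable):
            raise TypeError("Fisher combination requires a raw HyI association table")
        if associations.metric != "hyi":
            raise TypeError("Fisher combination operates on hypergeometric-index tables")
        return _group(((k, hyi_to_pvalue(v)) for k, v in associations.records.items()))
    raise ValueError(f"unknown combination method {method!r}")


def _group(items: Iterable[tuple[tuple[str, str], float]]) -> dict[str, dict[str, float]]:
    out: dict[str, dict[str, float]] = {}
    for (d, f), v in items:
        out.setdefault(d, {})[f] = v
    return out


def predict_protein(
    protein_id: str,
    protein_domain_map: Mapping[str, set[str]],
    associations: StandardizedTable | AssociationTable,
    method: str,
    _lookup: Mapping[str, Mapping[str, float]] | None = None,
) -> list[CombinedScore] | str:
    """Score every function supported by at least one of the protein's domains.

    Returns the combined scores, or an unpredictable-reason string
    (``"no-domains"`` / ``"no-associations"``) — absence of predictions is a
    value, not an error.
    """
    lookup = _lookup if _lookup is not None else _association_lookup(associations, method)
    domains = protein_domain_map.get(protein_id)
    if not domains:
        return NO_DOMAINS
    per_function: dict[str, list[tuple[str, float]]] = {}
    for d in domains:
        for f, v in lookup.get(d, {}).items():
            per_function.setdefault(f, []).append((d, v))
    if not per_function:
        return NO_ASSOCIATIONS
    return combine_for_protein(protein_id, per_function, method)


def predict_all(
    proteins: Iterable[str],
    protein_domain_map: Mapping[str, set[str]],
    associations: StandardizedTable | AssociationTable,
    method: str,
    min_score: float = MIN_SCORE,
    restandardize: bool = True,
) -> PredictionSet:
    """Predict functions for a set of query proteins.

    Scores are normalized jointly over the whole run (the Stouffer path
    re-standardizes over all combined scores produced here) and entries below
    ``min_score`` are dropped.  A protein whose every prediction falls below
    the cutoff remains in ``predicted_proteins`` with no records.
    """
    proteins = list(proteins)
    if not proteins:
        raise ValueError("no query proteins given")
    lookup = _association_lookup(associations, method)

    all_scores: list[CombinedScore] = []
    pset = PredictionSet()
    for prot in proteins:
        result = predict_protein(prot, protein_domain_map, associations, method, _lookup=lookup)
        if isinstance(result, str):
            pset.unpredictable_proteins[prot] = result
        else:
            pset.predicted_proteins.add(prot)
            all_scores.extend(result)

    normalized = normalize_scores(all_scores, method, min_score=min_score, restandardize=restandardize)
    norm_map = {(p, f): n for p, f, n in normalized}
    for s in all_scores:
        key = (s.protein_id, s.function_id)
        if key in norm_map:
            pset.records.append(
                PredictionRecord(
                    protein_id=s.protein_id,
                    function_id=s.function_id,
                    domains=s.contributing_domains,
                    raw=s.raw,
                    normalized=norm_map[key],
                    method_tag=method,
                )
            )
    pset.validate()
    logger.info(
        "predicted %d proteins (%d records), %d unpredictable",
        len(pset.predicted_proteins), len(pset.records), len(pset.unpredictable_proteins),
    )
    return pset


def _sorted_records(records: list[PredictionRecord]) -> list[PredictionRecord]:
    # deterministic: protein asc, score desc, function asc
    return sorted(records, key=lambda r: (r.protein_id, -r.normalized, r.function_id))


def write_predictions(pset: PredictionSet, path: str | Path, format: str = "tsv") -> None:
    """Write predictions as a full TSV table or 3-column submission-style rows.

    The submission format (``"cafa"``) rounds scores to 2 decimals and floors
    zero-rounded scores at 0.01 so every emitted score stays in (0, 1].
    """
    path = Path(path)
    records = _sorted_records(pset.records)
    if not records:
        logger.warning("writing empty prediction set to %s", path)
    with path.open("w", encoding="utf-8") as fh:
        if format == "tsv":
            fh.write("protein\tfunction\tdomains\traw\tnormalized\tmethod\n")
            for r in records:
                doms = ",".join(sorted(r.domains))
                fh.write(
                    f"{r.protein_id}\t{r.function_id}\t{doms}\t{r.raw:.10g}\t{r.normalized:.10g}\t{r.method_tag}\n"
                )
        elif format == "cafa":
            for r in records:
                score = max(round(r.normalized, 2), 0.01)
                fh.write(f"{r.protein_id}\t{r.function_id}\t{score:.2f}\n")
        else:
            raise ValueError(f"unknown prediction format {format!r}")


def read_predictions(path: str | Path) -> PredictionSet:
    """Read the full TSV format written by :func:`write_predictions` back."""
    pset = PredictionSet()
    with Path(path).open(encoding="utf-8") as fh:
        header = fh.readline()
        if header and not header.startswith("protein\t"):
            raise ValueError(f"{path}: unrecognized prediction table header")
        for line in fh:
            if not line.strip():
                continue
            prot, func, doms, raw, norm, method = line.rstrip("\n").split("\t")
            pset.records.append(
                PredictionRecord(
                    protein_id=prot,
                    function_id=func,
                    domains=frozenset(doms.split(",")) if doms else frozenset(),
                    raw=float(raw),
                    normalized=float(norm),
                    method_tag=method,
                )
            )
            pset.predicted_proteins.add(prot)
    return pset
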