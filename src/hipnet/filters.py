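"""Interaction-level boolean metadata filtering.

Filters act on the raw confirmed observations, not on genes, so a user can
select interactions from experiments matching specific criteria. Each
metadata field carries at most one filter with an AND, OR or NOT operator
over its selected values; distinct fields always combine conjunctively.

Semantics: OR- and NOT-filters constrain the observation set (an
observation survives if its field value is in / not in the selected
values); a gene is kept if any of its observations survive. An AND-filter
additionally requires, for each selected value, that the gene retains at
least one surviving observation carrying that value — e.g. selecting
{Mice, Human} with AND returns genes identified at least once in mice and
at least once in humans.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .catalog import METADATA_FIELDS, GeneRecord, PPIObservation
from .errors import DuplicateFilterError, InvalidThresholdError


@dataclass(frozen=True)
class FilterSpec:
    """One per-field filter: a set of values and a boolean operator."""

    field: str
    values: frozenset
    operator: str  # AND | OR | NOT

    def __post_init__(self):
        if self.field not in METADATA_FIELDS:
            raise InvalidThresholdError(
                "field", self.field, f"one of {METADATA_FIELDS}"
            )
        if self.operator not in ("AND", "OR", "NOT"):
            raise InvalidThresholdError(
                "operator", self.operator, "AND, OR or NOT"
            )
        if not self.values:
            raise InvalidThresholdError("values", self.values, "non-empty set")
        object.__setattr__(
            self, "values", frozenset(_canon(v) for v in self.values)
        )


def _canon(value: str) -> str:
    return str(value).strip().casefold()


def apply_filters(
    observations: Iterable[PPIObservation],
    filters: Sequence[FilterSpec] = (),
) -> set[str]:
    """Return the human gene symbols passing all filters.

    An empty filter list returns every gene with at least one confirmed
    observation. Value matching is exact after whitespace trim and
    case-fold.
    """
    seen_fields = set()
    for spec in filters:
        if spec.field in seen_fields:
            raise DuplicateFilterError(spec.field)
        seen_fields.add(spec.field)

    obs = [o for o in observations if o.interaction_confirmed]

    constraining = [f for f in filters if f.operator in ("OR", "NOT")]
    and_filters = [f for f in filters if f.operator == "AND"]

    def survives(o: PPIObservation) -> bool:
        for spec in constraining:
            val = _canon(o.metadata(spec.field))
            if spec.operator == "OR" and val not in spec.values:
                return False
            if spec.operator == "NOT" and val in spec.values:
                return False
        return True

    surviving = [o for o in obs if survives(o)]
    genes = {o.gene_symbol_human for o in surviving}

    for spec in and_filters:
        for value in spec.values:
            with_value = {
                o.gene_symbol_human
                for o in surviving
                if _canon(o.metadata(spec.field)) == value
            }
            genes &= with_value
    return genes


def min_study_filter(
    genes: Iterable[str],
    catalog: Mapping[str, GeneRecord],
    k: int,
) -> set[str]:
    """Keep genes reported by at least ``k`` distinct studies globally."""
    if k < 1:
        raise InvalidThresholdError("k", k, ">= 1")
    return {g for g in genes if catalog[g].study_count >= k}


def gene_list_search(
    genes: Iterable[str],
    query_list: Iterable[str],
) -> tuple[set[str], list[str]]:
    """Case-insensitive intersection with a user gene list.

    Returns (matched genes in catalog casing, unmatched query symbols).
    Unknown query symbols are reported, never an error.
    """
    by_fold = {}
    for g in genes:
        by_fold.setdefault(g.casefold(), g)
    matched: set[str] = set()
    unmatched: list[str] = []
    for q in query_list:
        hit = by_fold.get(q.strip().casefold())
        if hit is None:
            unmatched.append(q)
        else:
            matched.add(hit)
    return matched, unmatched
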