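"""Keyword search and performance ranking over the model registry.

Search flattens each entry's metadata into lowercase strings (every
string-valued leaf plus every key name) and matches query values as
case-insensitive substrings. The operator decides how many query values a
model must match: ``AND`` all of them, ``OR`` at least one, ``XOR``
exactly one (the k-ary generalization of two-input XOR). Numeric leaves
are not searched, but their key names are — so a query for ``"fid"``
finds models carrying an FID metric.

Ranking sorts models by a performance indicator addressed by a dotted
path into ``selection.performance`` (e.g. ``"FID"`` or
``"downstream.dice"``). Models lacking the metric are appended after the
ranked ones, flagged, so the full candidate set stays visible.
"""

from __future__ import annotations

import enum
import logging
import warnings
from dataclasses import dataclass, field
from typing import Any, Sequence

from .registry import ModelMetadata, Registry, get_metadata

logger = logging.getLogger(__name__)

#: Metrics for which smaller values indicate better models.
LOWER_IS_BETTER = {"FID", "FIDrr"}


class SearchOperator(enum.Enum):
    AND = "AND"
    OR = "OR"
    XOR = "XOR"

    @classmethod
    def parse(cls, value: "SearchOperator | str") -> "SearchOperator":
        if isinstance(value, SearchOperator):
            return value
        try:
            return cls[str(value).upper()]
        except KeyError:
            raise ValueError(
                f"unknown search operator {value!r}; expected AND, OR, or XOR"
            ) from None


@dataclass
class MatchedEntry:
    """One model's match status for a query."""

    model_id: str
    matched_values: set[str] = field(default_factory=set)
    is_match: bool = False


@dataclass
class MatchCandidates:
    """All models that matched at least one query value, plus the query."""

    candidates: list[MatchedEntry]
    values: list[str]
    operator: SearchOperator


@dataclass
class RankedModel:
    """One row of a ranking: id, metric value (None when absent)."""

    model_id: str
    value: float | None
    has_metric: bool


def flatten_metadata(entry: ModelMetadata) -> list[str]:
    """Depth-first list of searchable strings for one entry.

    Collects every key name and every string leaf, lowercased. Numbers,
    booleans, and nulls are excluded; their key names still appear.
    """
    out: list[str] = []

    def walk(node: Any) -> None:
        if isinstance(node, dict):
            for k, v in node.items():
                out.append(str(k).lower())
                walk(v)
        elif isinstance(node, (list, tuple)):
            for item in node:
                walk(item)
        elif isinstance(node, str):
            out.append(node.lower())

    out.append(entry.model_id.lower())
    walk(entry.to_dict())
    return out


def match_candidates(
    registry: Registry, values: Sequence[str], operator: SearchOperator | str
) -> MatchCandidates:
    """Search every registry entry, returning per-model match detail."""
    op = SearchOperator.parse(operator)
    if not values:
        raise ValueError("search values must be non-empty")
    queries = [str(v).lower() for v in values]
    candidates: list[MatchedEntry] = []
    for entry in registry:
        haystack = flatten_metadata(entry)
        matched = {
            q for q in queries if any(q in s for s in haystack)
        }
        if not matched:
            continue
        k = len(matched)
        if op is SearchOperator.AND:
            is_match = k == len(queries)
        elif op is SearchOperator.OR:
            is_match = k >= 1
        else:  # XOR: exactly one query value matches
            is_match = k == 1
        candidates.append(MatchedEntry(entry.model_id, matched, is_match))
    return MatchCandidates(candidates=candidates, values=list(values), operator=op)


def find_matching_models(
    registry: Registry, values: Sequence[str], operator: SearchOperator | str = SearchOperator.AND
) -> list[MatchedEntry]:
    """Models satisfying the query under the operator, in registry order."""
    return [c for c in match_candidates(registry, values, operator).candidates if c.is_match]


def _lookup_metric(performance: dict[str, Any], dotted: str) -> float | None:
    node: Any = performance
    for part in dotted.split("."):
        if not isinstance(node, dict) or part not in node:
            return None
        node = node[part]
    if isinstance(node, bool) or not isinstance(node, (int, float)):
        return None
    return float(node)


def default_order(metric_key: str) -> str:
    """'asc' for lower-is-better metrics (FID family), 'desc' otherwise."""
    leaf = metric_key.split(".")[-1]
    return "asc" if leaf in LOWER_IS_BETTER or metric_key in LOWER_IS_BETTER else "desc"


def rank_models_by_performance(
    registry: Registry,
    model_ids: Sequence[str] | None = None,
    metric_key: str = "FID",
    order: str | None = None,
) -> list[RankedModel]:
    """Rank models by a metric addressed by a dotted path.

    Ties break by model id, lexicographic ascending. Models without the
    metric are appended last in registry order with ``has_metric=False``.
    When no model carries the metric at all, an empty list is returned
    with a warning.
    """
    if not metric_key:
        raise ValueError("metric_key must be non-empty")
    if order is None:
        order = default_order(metric_key)
    if order not in ("asc", "desc", "ascending", "descending"):
        raise ValueError(f"order must be 'asc' or 'desc', got {order!r}")
    ascending = order.startswith("asc")

    if model_ids is None:
        pool = list(registry)
    else:
        pool = [get_metadata(registry, m) for m in model_ids]

    with_metric: list[RankedModel] = []
    without: list[RankedModel] = []
    for entry in pool:
        value = _lookup_metric(entry.selection.performance, metric_key)
        if value is None:
            without.append(RankedModel(entry.model_id, None, False))
        else:
            with_metric.append(RankedModel(entry.model_id, value, True))

    if not with_metric:
        warnings.warn(
            f"no model carries metric {metric_key!r}; ranking is empty", stacklevel=2
        )
        return []

    sign = 1.0 if ascending else -1.0
    with_metric.sort(key=lambda r: (sign * r.value, r.model_id))
    if without:
        logger.info(
            "%d model(s) lack metric %r and are listed last: %s",
            len(without), metric_key, [r.model_id for r in without],
        )
    return with_metric + without


def find_and_rank(
    registry: Registry,
    values: Sequence[str],
    operator: SearchOperator | str = SearchOperator.AND,
    metric_key: str = "FID",
    order: str | None = None,
) -> list[RankedModel]:
    """Keyword search, then rank the matches by a performance metric."""
    matches = find_matching_models(registry, values, operator)
    if not matches:
        return []
    ranked = rank_models_by_performance(
        registry, [m.model_id for m in matches], metric_key, order
    )
    if not ranked:
        # every match lacked the metric: keep the matches, flagged, so a
        # single keyword hit is still returned
        return [RankedModel(m.model_id, None, False) for m in matches]
    return ranked
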