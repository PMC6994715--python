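"""Mouse-human orthologue selection.

Orthologue inferences are scored by how many of twelve established
inference methods support them. Downstream analysis keeps only
unambiguous one-to-one pairs: at least moderate support (>= 5 methods),
at least one protein-coding partner, and the edge must be the strict
unique best-scoring partner for both its human and its mouse gene.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

__all__ = ["OrthologyEdge", "support_tier", "select_one_to_one", "select_one_to_one_table"]

N_METHODS_MAX = 12
MIN_SUPPORT = 5


@dataclass(frozen=True)
class OrthologyEdge:
    human_id: str
    mouse_id: str
    n_methods: int
    human_coding: bool = True
    mouse_coding: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.n_methods <= N_METHODS_MAX:
            raise ValueError(f"n_methods must be in [0, {N_METHODS_MAX}]")


def support_tier(n_methods: int) -> str:
    """Confidence tier of an orthologue inference.

    9-12 supporting methods -> good, 5-8 -> moderate, 1-4 -> low,
    0 -> none.
    """
    if not 0 <= n_methods <= N_METHODS_MAX:
        raise ValueError(f"n_methods out of range: {n_methods}")
    if n_methods >= 9:
        return "good"
    if n_methods >= MIN_SUPPORT:
        return "moderate"
    if n_methods >= 1:
        return "low"
    return "none"


def select_one_to_one(edges: Sequence[OrthologyEdge]) -> list[OrthologyEdge]:
    """Keep unambiguous one-to-one orthologue pairs.

    An edge survives the support filter when ``n_methods >= 5`` and at
    least one partner is protein coding. A surviving edge is accepted
    iff its score is the strict unique maximum among surviving edges of
    both its human gene and its mouse gene (ties are rejected, matching
    the duplicated-maximum filter).
    """
    seen = set()
    for e in edges:
        key = (e.human_id, e.mouse_id)
        if key in seen:
            raise ValueError(f"duplicate edge {key}")
        seen.add(key)
    surviving = [
        e
        for e in edges
        if e.n_methods >= MIN_SUPPORT and (e.human_coding or e.mouse_coding)
    ]
    by_human: dict[str, list[OrthologyEdge]] = {}
    by_mouse: dict[str, list[OrthologyEdge]] = {}
    for e in surviving:
        by_human.setdefault(e.human_id, []).append(e)
        by_mouse.setdefault(e.mouse_id, []).append(e)

    def strict_unique_max(e: OrthologyEdge, group: list[OrthologyEdge]) -> bool:
        best = max(g.n_methods for g in group)
        return e.n_methods == best and sum(g.n_methods == best for g in group) == 1

    return [
        e
        for e in surviving
        if strict_unique_max(e, by_human[e.human_id])
        and strict_unique_max(e, by_mouse[e.mouse_id])
    ]


def select_one_to_one_table(edges: pd.DataFrame) -> pd.DataFrame:
    """Table wrapper around :func:`select_one_to_one`.

    Expects columns ``human_id, mouse_id, n_methods, human_coding,
    mouse_coding``; returns accepted rows in input order.
    """
    parsed = [
        OrthologyEdge(
            human_id=str(r.human_id),
            mouse_id=str(r.mouse_id),
            n_methods=int(r.n_methods),
            human_coding=bool(r.human_coding),
            mouse_coding=bool(r.mouse_coding),
        )
        for r in edges.itertuples(index=False)
    ]
    accepted = {(e.human_id, e.mouse_id) for e in select_one_to_one(parsed)}
    mask = [
        (str(r.human_id), str(r.mouse_id)) in accepted
        for r in edges.itertuples(index=False)
    ]
    return edges.loc[mask].reset_index(drop=True)
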