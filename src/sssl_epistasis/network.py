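"""Statistical promote/inhibit relationships between QTLs.

Two loci are independent when the effect of one is unchanged by the
genetic background supplied by the other; a significant change in the
focal effect (the delta equals the epistasis between them) marks promotion
or inhibition.  Edges are statistical background-dependence only — no
claim about molecular regulation direction is made.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .decompose import (
    EffectEstimate,
    EffectKind,
    EffectTable,
    state_token,
)
from .design import LocusState, MaterialGenotype

STATES = (LocusState.HET, LocusState.HOM)


@dataclass
class ThresholdPolicy:
    """What counts as a changed effect: significance and a magnitude floor.

    When the table carries p-values the delta must be significant at
    ``alpha`` *and* at least ``min_delta`` days in magnitude; without
    p-values (e.g. a table of printed values) the magnitude rule alone
    applies.
    """

    alpha: float = 0.05
    min_delta: float = 1.0


@dataclass
class BackgroundEffect:
    focal: str  # token such as "Ehd1-1"
    background: str  # material id of the background
    effect_in_background: Optional[float]
    baseline: Optional[float]
    delta: Optional[float]
    p: Optional[float] = None
    available: bool = True

    def active(self, policy: ThresholdPolicy) -> bool:
        if not self.available or self.delta is None:
            return False
        if abs(self.delta) < policy.min_delta:
            return False
        if self.p is not None and self.p > policy.alpha:
            return False
        return True


def _material_effect(table: EffectTable, material_id: str) -> Optional[EffectEstimate]:
    """g (or single effect) of any material, looked up by canonical id."""
    for kind in (
        EffectKind.PYRAMIDING,
        EffectKind.ADDITIVE,
        EffectKind.DOMINANCE,
    ):
        e = table.get(kind, material_id)
        if e is not None:
            return e
    return None


def effect_in_background(
    table: EffectTable,
    focal: Tuple[str, LocusState],
    background: MaterialGenotype,
) -> BackgroundEffect:
    """Effect of a focal (locus, state) conditional on a background material.

    The conditional effect is g(background + focal) - g(background); the
    delta subtracts the focal locus's solo effect.  With a full truth
    model the delta equals the applicable dual (plus triple) epistasis
    terms.  Missing materials yield an explicitly unavailable record.
    """
    locus, state = focal
    token = state_token(locus, state)
    if background.state_of(locus) is not LocusState.ABSENT:
        raise ValueError(f"background already carries {locus}")
    combined = MaterialGenotype.from_mapping(
        {**dict(background.states), locus: state},
        [l for l, _ in table_locus_order(table, background, locus)],
    )
    bg_id = background.material_id
    bg_entry = _material_effect(table, bg_id) if background.order else None
    comb_entry = _material_effect(table, combined.material_id)
    solo = table.single_effect(locus, state)

    record = BackgroundEffect(
        focal=token,
        background=bg_id,
        effect_in_background=None,
        baseline=None,
        delta=None,
        available=False,
    )
    bg_ok = background.order == 0 or (
        bg_entry is not None and bg_entry.available and math.isfinite(bg_entry.value)
    )
    if (
        comb_entry is None
        or not comb_entry.available
        or not math.isfinite(comb_entry.value)
        or solo is None
        or not solo.available
        or not math.isfinite(solo.value)
        or not bg_ok
    ):
        return record
    bg_val = bg_entry.value if background.order else 0.0
    record.available = True
    record.effect_in_background = comb_entry.value - bg_val
    record.baseline = solo.value
    record.delta = record.effect_in_background - solo.value
    # for single-locus backgrounds the delta is the dual epistasis row; reuse
    # its significance when the table carries one
    if background.order == 1:
        dual = table.get(EffectKind.DUAL_EPI, combined.material_id)
        if dual is not None and dual.available:
            record.p = dual.p
    return record


def table_locus_order(
    table: EffectTable, background: MaterialGenotype, focal_locus: str
) -> List[Tuple[str, None]]:
    """Catalog order of loci as implied by the table's single-effect rows."""
    order: List[str] = []
    for e in table.entries:
        for locus, _ in e.loci_states:
            if locus not in order:
                order.append(locus)
    for locus, _ in background.states:
        if locus not in order:
            order.append(locus)
    if focal_locus not in order:
        order.append(focal_locus)
    return [(l, None) for l in order]


class Relation:
    PROMOTES = "promotes"
    INHIBITS = "inhibits"
    INDEPENDENT = "independent"
    AMBIGUOUS = "ambiguous"


@dataclass
class NetworkEdge:
    source: str  # background locus
    target: str  # focal locus
    relation: str
    per_state: Dict[str, str] = field(default_factory=dict)
    evidence: List[BackgroundEffect] = field(default_factory=list)


def _classify(deltas: Sequence[float]) -> str:
    pos = sum(1 for d in deltas if d > 0)
    neg = sum(1 for d in deltas if d < 0)
    if pos > neg:
        return Relation.PROMOTES
    if neg > pos:
        return Relation.INHIBITS
    return Relation.AMBIGUOUS


def build_network(
    table: EffectTable, policy: Optional[ThresholdPolicy] = None
) -> List[NetworkEdge]:
    """Classify every ordered locus pair from single-locus-background evidence.

    For the edge source -> target the evidence set is the four
    (target state, source state) combinations; a piece of evidence is
    *active* when its delta passes the threshold policy.  The pair is
    independent when fewer than half of the evaluable evidence is active
    (or none is evaluable); otherwise the summary relation is the majority
    sign of the active deltas, reported per focal state as well because
    heterozygous and homozygous substitutions can behave oppositely.
    """
    policy = policy or ThresholdPolicy()
    loci: List[str] = []
    for e in table.entries:
        for locus, _ in e.loci_states:
            if locus not in loci:
                loci.append(locus)

    edges = []
    for source in loci:
        for target in loci:
            if source == target:
                continue
            evidence = []
            for t_state in STATES:
                for s_state in STATES:
                    bg = MaterialGenotype(states=((source, s_state),))
                    evidence.append(
                        effect_in_background(table, (target, t_state), bg)
                    )
            available = [ev for ev in evidence if ev.available]
            active = [ev for ev in evidence if ev.active(policy)]
            if not available or len(active) < len(available) / 2.0:
                relation = Relation.INDEPENDENT
            else:
                relation = _classify([ev.delta for ev in active])
            per_state = {}
            for t_state in STATES:
                token = state_token(target, t_state)
                sub = [
                    ev
                    for ev in evidence
                    if ev.focal == token and ev.active(policy)
                ]
                per_state[token] = (
                    _classify([ev.delta for ev in sub])
                    if sub
                    else Relation.INDEPENDENT
                )
            edges.append(
                NetworkEdge(
                    source=source,
                    target=target,
                    relation=relation,
                    per_state=per_state,
                    evidence=evidence,
                )
            )
    return edges


def to_networkx(edges: Sequence[NetworkEdge]):
    """Directed graph of the non-independent relations."""
    import networkx as nx

    g = nx.DiGraph()
    for e in edges:
        g.add_node(e.source)
        g.add_node(e.target)
        if e.relation != Relation.INDEPENDENT:
            g.add_edge(e.source, e.target, relation=e.relation)
    return g


def to_dot(edges: Sequence[NetworkEdge]) -> str:
    """Graphviz DOT rendering; promotion as solid, inhibition as tee arrows."""
    lines = ["digraph qtl_network {"]
    nodes = sorted({e.source for e in edges} | {e.target for e in edges})
    for n in nodes:
        lines.append(f'  "{n}";')
    for e in edges:
        if e.relation == Relation.INDEPENDENT:
            continue
        style = {
            Relation.PROMOTES: "arrowhead=normal",
            Relation.INHIBITS: "arrowhead=tee",
            Relation.AMBIGUOUS: "arrowhead=diamond, style=dashed",
        }[e.relation]
        lines.append(
            f'  "{e.source}" -> "{e.target}" [label="{e.relation}", {style}];'
        )
    lines.append("}")
    return "\n".join(lines) + "\n"
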