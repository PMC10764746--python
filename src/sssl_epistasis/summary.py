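"""Aggregate statements about an effect table.

Counts and sign fractions of significant effects per decomposition level,
per-class means and standard deviations (a-a vs d-d components and so on),
and the genetic-homeostasis pattern: whether the summed epistatic effects
oppose the summed single-QTL effects, partially neutralizing pyramiding.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .decompose import EffectKind, EffectTable, state_token


@dataclass(frozen=True)
class SignSummary:
    level: str
    n_total: int
    n_significant: int
    n_negative_significant: int
    n_positive_significant: int

    @property
    def frac_significant(self) -> float:
        return self.n_significant / self.n_total if self.n_total else float("nan")

    @property
    def frac_negative(self) -> float:
        if not self.n_significant:
            return float("nan")
        return self.n_negative_significant / self.n_significant

    @property
    def frac_positive(self) -> float:
        if not self.n_significant:
            return float("nan")
        return self.n_positive_significant / self.n_significant


def summarize_signs(table: EffectTable, level: EffectKind) -> SignSummary:
    """Count significant entries at a level and partition them by sign.

    All entries at the level count toward ``n_total`` (including ones whose
    value is unavailable); significance means a non-empty star annotation.
    A significant zero would be counted as positive, which cannot occur at
    the reported one-decimal precision.
    """
    entries = table.level(level)
    sig = [e for e in entries if e.significant]
    neg = [e for e in sig if e.value < 0]
    return SignSummary(
        level=level.value,
        n_total=len(entries),
        n_significant=len(sig),
        n_negative_significant=len(neg),
        n_positive_significant=len(sig) - len(neg),
    )


@dataclass(frozen=True)
class ClassStats:
    component_class: str
    mean: float
    sd: Optional[float]
    n: int


def class_stats(
    table: EffectTable, level: EffectKind, significant_only: bool = True
) -> List[ClassStats]:
    """Mean +- SD (n-1 denominator) of effect values per component class.

    By default only significant entries enter, matching how class averages
    of epistatic components are usually quoted; classes with a single entry
    report an undefined SD.
    """
    groups: Dict[str, List[float]] = {}
    for e in table.level(level):
        if not e.available or not np.isfinite(e.value):
            continue
        if significant_only and not e.significant:
            continue
        groups.setdefault(e.component_class, []).append(e.value)
    out = []
    for cls in sorted(groups):
        vals = np.asarray(groups[cls], dtype=float)
        sd = float(vals.std(ddof=1)) if len(vals) > 1 else None
        out.append(ClassStats(cls, float(vals.mean()), sd, len(vals)))
    return out


@dataclass
class HomeostasisReport:
    """Sign pattern of singles vs dual vs triple epistasis, plus per-pyramid
    neutralization fractions |sum of epistases| / |sum of singles|."""

    sum_singles: float
    sum_dual: float
    sum_triple: float
    pattern: str
    per_pyramid: pd.DataFrame = field(repr=False, default=None)

    def frame(self) -> pd.DataFrame:
        return self.per_pyramid


def _sign_word(x: float) -> str:
    if x > 0:
        return "positive"
    if x < 0:
        return "negative"
    return "zero"


def homeostasis_report(table: EffectTable) -> HomeostasisReport:
    """Summarize the buffering relationship between QTL effects and epistasis.

    The headline pattern gives the sign of (i) the summed single-QTL
    effects, (ii) the summed significant dual epistases and (iii) the summed
    significant triple epistases.  Per pyramid, the epistatic residual
    (dual epistasis for order-2, mixed epistasis for order-3) is compared
    with the sum of the constituent single effects; a pyramid is flagged
    when epistasis opposes that sum.
    """
    singles = [
        e
        for kind in (EffectKind.ADDITIVE, EffectKind.DOMINANCE)
        for e in table.level(kind)
        if e.available and np.isfinite(e.value)
    ]
    sum_singles = float(sum(e.value for e in singles))
    sum_dual = float(
        sum(e.value for e in table.level(EffectKind.DUAL_EPI) if e.significant)
    )
    sum_triple = float(
        sum(e.value for e in table.level(EffectKind.TRIPLE_EPI) if e.significant)
    )
    pattern = "/".join(
        _sign_word(x) for x in (sum_singles, sum_dual, sum_triple)
    )

    rows = []
    for kind in (EffectKind.DUAL_EPI, EffectKind.MIXED_EPI):
        for e in table.level(kind):
            if not e.available or not np.isfinite(e.value):
                continue
            parts = [
                table.single_effect(locus, state)
                for locus, state in e.loci_states
            ]
            if any(p is None or not p.available for p in parts):
                continue
            s = sum(p.value for p in parts)
            rows.append(
                {
                    "material": e.material,
                    "level": kind.value,
                    "sum_singles": s,
                    "epistasis": e.value,
                    "neutralization": abs(e.value) / abs(s) if s != 0 else np.inf,
                    "opposes": bool(e.value * s < 0),
                }
            )
    per_pyramid = pd.DataFrame(
        rows,
        columns=[
            "material",
            "level",
            "sum_singles",
            "epistasis",
            "neutralization",
            "opposes",
        ],
    )
    return HomeostasisReport(
        sum_singles=sum_singles,
        sum_dual=sum_dual,
        sum_triple=sum_triple,
        pattern=pattern,
        per_pyramid=per_pyramid,
    )
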