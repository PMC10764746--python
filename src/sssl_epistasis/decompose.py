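"""Hierarchical decomposition of genotypic effects in an SSSL pyramiding design.

Effects follow the substitution-line convention throughout:

* additive ``a``  = homozygous single line minus recipient,
* dominance ``d`` = heterozygous single line minus recipient,
* pyramiding ``g`` = multi-segment material minus recipient,
* dual epistasis ``e`` = ``g`` minus the sum of the constituent single
  effects,
* mixed epistasis (order-3 material) = ``g`` minus the sum of singles —
  i.e. all pairwise plus three-way interaction lumped together,
* triple epistasis = mixed epistasis minus the sum of the three dual
  epistases.

Note that ``a`` and ``d`` here are deviations from the recipient, not the
classical midparent parameterization; ``d/a`` ratios must be read with that
in mind.

Each effect carries per-environment interaction components in deviation
coding (they sum to zero over environments) and, when a plot-level error
variance is supplied, a standard error, a two-sided t-test p-value and the
conventional star annotation (* for p <= 0.05, ** for p <= 0.01).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .design import (
    RECIPIENT_ID,
    LocusState,
    MaterialGenotype,
    component_class,
    state_token,
)

ALPHA_LEVELS = (0.05, 0.01)


class EffectKind(Enum):
    """Decomposition level of an effect estimate."""

    ADDITIVE = "additive"
    DOMINANCE = "dominance"
    PYRAMIDING = "pyramiding"
    DUAL_EPI = "dual_epistasis"
    TRIPLE_EPI = "triple_epistasis"
    MIXED_EPI = "mixed_epistasis"


def stars_for(p: Optional[float], alphas: Tuple[float, float] = ALPHA_LEVELS) -> str:
    if p is None or not math.isfinite(p):
        return ""
    if p <= alphas[1]:
        return "**"
    if p <= alphas[0]:
        return "*"
    return ""


@dataclass
class ErrorContext:
    """Plot-level error variance and layout needed for contrast t-tests.

    ``sigma2`` is the residual (plot) variance, ``df`` its degrees of
    freedom; ``n_env`` and ``n_blocks`` give the replication behind each
    material mean (``n_env * n_blocks`` plots per material).
    """

    sigma2: float
    df: int
    n_env: int
    n_blocks: int


@dataclass
class EnvComponent:
    value: float
    se: Optional[float] = None
    p: Optional[float] = None
    stars: str = ""


@dataclass
class EffectEstimate:
    """One named genetic effect with environment-interaction components."""

    kind: EffectKind
    material: str
    loci_states: Tuple[Tuple[str, LocusState], ...]
    component_class: str
    value: float
    se: Optional[float] = None
    p: Optional[float] = None
    stars: str = ""
    env: Dict[str, EnvComponent] = field(default_factory=dict)
    contrast: Optional[Dict[str, float]] = None
    available: bool = True

    @property
    def significant(self) -> bool:
        return self.available and self.stars != ""


class EffectTable:
    """Ordered collection of effect estimates across all decomposition levels."""

    def __init__(
        self,
        environments: Sequence[str] = (),
        err: Optional[ErrorContext] = None,
        reference: str = RECIPIENT_ID,
    ) -> None:
        self.entries: List[EffectEstimate] = []
        self.environments: List[str] = list(environments)
        self.err = err
        self.reference = reference
        self._index: Dict[Tuple[EffectKind, str], EffectEstimate] = {}

    def add(self, entry: EffectEstimate) -> None:
        key = (entry.kind, entry.material)
        if key in self._index:
            raise ValueError(f"duplicate effect entry {key}")
        self.entries.append(entry)
        self._index[key] = entry

    def get(self, kind: EffectKind, material: str) -> Optional[EffectEstimate]:
        return self._index.get((kind, material))

    def level(self, kind: EffectKind) -> List[EffectEstimate]:
        return [e for e in self.entries if e.kind is kind]

    def extend(self, other: "EffectTable") -> "EffectTable":
        for e in other.entries:
            self.add(e)
        for env in other.environments:
            if env not in self.environments:
                self.environments.append(env)
        if self.err is None:
            self.err = other.err
        return self

    def single_effect(
        self, locus: str, state: LocusState
    ) -> Optional[EffectEstimate]:
        """Look up the single-QTL effect behind one (locus, state) pair."""
        kind = EffectKind.ADDITIVE if state is LocusState.HOM else EffectKind.DOMINANCE
        return self.get(kind, state_token(locus, state))

    def frame(self):
        import pandas as pd

        rows = []
        for e in self.entries:
            row = {
                "level": e.kind.value,
                "material": e.material,
                "class": e.component_class,
                "value": e.value,
                "se": e.se,
                "p": e.p,
                "stars": e.stars,
                "available": e.available,
            }
            for env in self.environments:
                comp = e.env.get(env)
                row[f"{env}_value"] = comp.value if comp else np.nan
                row[f"{env}_se"] = comp.se if comp else np.nan
                row[f"{env}_p"] = comp.p if comp else np.nan
                row[f"{env}_stars"] = comp.stars if comp else ""
            rows.append(row)
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# contrast arithmetic and significance
# ---------------------------------------------------------------------------


def _combine(*terms: Tuple[float, Optional[Dict[str, float]]]) -> Optional[Dict[str, float]]:
    """Signed sum of material contrasts; None if any constituent lacks one."""
    out: Dict[str, float] = {}
    for sign, contrast in terms:
        if contrast is None:
            return None
        for mat, coef in contrast.items():
            out[mat] = out.get(mat, 0.0) + sign * coef
    return {m: c for m, c in out.items() if abs(c) > 1e-12}


def _annotate(entry: EffectEstimate, err: Optional[ErrorContext]) -> None:
    """Attach SE/p/stars to an entry from its contrast and the plot error."""
    if err is None or entry.contrast is None or not entry.available:
        return
    c2 = sum(c * c for c in entry.contrast.values())
    if err.df <= 0 or err.sigma2 < 0:
        return
    se = math.sqrt(c2 * err.sigma2 / (err.n_env * err.n_blocks))
    entry.se = se
    if se > 0:
        t = entry.value / se
        entry.p = float(2.0 * stats.t.sf(abs(t), err.df))
        entry.stars = stars_for(entry.p)
    for comp in entry.env.values():
        se_env = math.sqrt(c2 * err.sigma2 * (1.0 - 1.0 / err.n_env) / err.n_blocks)
        comp.se = se_env
        if se_env > 0:
            t = comp.value / se_env
            comp.p = float(2.0 * stats.t.sf(abs(t), err.df))
            comp.stars = stars_for(comp.p)


def test_significance(table: EffectTable, err: Optional[ErrorContext] = None) -> EffectTable:
    """(Re)compute SE, p-values and stars for every entry that has a contrast.

    Entries without a contrast (e.g. loaded from a report that only printed
    values) are left untouched.  With zero residual degrees of freedom the
    annotations are withheld rather than fabricated.
    """
    err = err or table.err
    for entry in table.entries:
        _annotate(entry, err)
    return table


# ---------------------------------------------------------------------------
# sequential-difference estimators
# ---------------------------------------------------------------------------


def _pred_value(preds, material: str) -> float:
    return float(preds.G[material])


def _pred_env(preds, env: str, material: str) -> float:
    return float(preds.GE.loc[env, material])


def _environments(preds) -> List[str]:
    return [str(e) for e in preds.GE.index]


def estimate_single_effects(
    preds,
    materials: Sequence[MaterialGenotype],
    err: Optional[ErrorContext] = None,
) -> EffectTable:
    """Additive and dominance effects of each locus, with their G×E parts.

    ``a(locus)`` is the difference between the homozygous single-segment
    material and the recipient; ``d(locus)`` the analogous heterozygous
    difference.  The same contrasts applied to the per-environment GE
    predictions give ``ae`` and ``de``.
    """
    envs = _environments(preds)
    table = EffectTable(environments=envs, err=err)
    if RECIPIENT_ID not in preds.G.index:
        raise ValueError("recipient material missing from predictions")
    loci_seen: List[str] = []
    for m in materials:
        if m.order == 1 and m.states[0][0] not in loci_seen:
            loci_seen.append(m.states[0][0])
    present = {m.material_id for m in materials if m.order == 1}
    for locus in loci_seen:
        for state, kind in (
            (LocusState.HOM, EffectKind.ADDITIVE),
            (LocusState.HET, EffectKind.DOMINANCE),
        ):
            mat_id = state_token(locus, state)
            entry = EffectEstimate(
                kind=kind,
                material=mat_id,
                loci_states=((locus, state),),
                component_class="a" if state is LocusState.HOM else "d",
                value=float("nan"),
                available=False,
            )
            if mat_id in present and mat_id in preds.G.index:
                entry.available = True
                entry.value = _pred_value(preds, mat_id) - _pred_value(
                    preds, RECIPIENT_ID
                )
                entry.contrast = {mat_id: 1.0, RECIPIENT_ID: -1.0}
                entry.env = {
                    env: EnvComponent(
                        _pred_env(preds, env, mat_id)
                        - _pred_env(preds, env, RECIPIENT_ID)
                    )
                    for env in envs
                }
            table.add(entry)
    test_significance(table, err)
    return table


def estimate_pyramiding_effects(
    preds,
    materials: Sequence[MaterialGenotype],
    err: Optional[ErrorContext] = None,
) -> EffectTable:
    """Pyramiding effects ``g`` (material minus recipient) for order >= 2."""
    envs = _environments(preds)
    table = EffectTable(environments=envs, err=err)
    if RECIPIENT_ID not in preds.G.index:
        raise ValueError("recipient material missing from predictions")
    for m in materials:
        if m.order < 2:
            continue
        mat_id = m.material_id
        entry = EffectEstimate(
            kind=EffectKind.PYRAMIDING,
            material=mat_id,
            loci_states=m.states,
            component_class=component_class(m),
            value=float("nan"),
            available=False,
        )
        if mat_id in preds.G.index:
            entry.available = True
            entry.value = _pred_value(preds, mat_id) - _pred_value(
                preds, RECIPIENT_ID
            )
            entry.contrast = {mat_id: 1.0, RECIPIENT_ID: -1.0}
            entry.env = {
                env: EnvComponent(
                    _pred_env(preds, env, mat_id)
                    - _pred_env(preds, env, RECIPIENT_ID)
                )
                for env in envs
            }
        table.add(entry)
    test_significance(table, err)
    return table


def _residual_entry(
    kind: EffectKind,
    g_entry: EffectEstimate,
    parts: List[Optional[EffectEstimate]],
    envs: Sequence[str],
) -> EffectEstimate:
    """Residual of a pyramiding effect after subtracting lower-order parts."""
    entry = EffectEstimate(
        kind=kind,
        material=g_entry.material,
        loci_states=g_entry.loci_states,
        component_class=g_entry.component_class,
        value=float("nan"),
        available=False,
    )
    usable = g_entry.available and all(
        p is not None and p.available and math.isfinite(p.value) for p in parts
    )
    if not usable or not math.isfinite(g_entry.value):
        return entry
    entry.available = True
    entry.value = g_entry.value - sum(p.value for p in parts)  # type: ignore[union-attr]
    entry.contrast = _combine(
        (1.0, g_entry.contrast), *[(-1.0, p.contrast) for p in parts]  # type: ignore[union-attr]
    )
    entry.env = {}
    for env in envs:
        g_env = g_entry.env.get(env)
        p_envs = [p.env.get(env) for p in parts]  # type: ignore[union-attr]
        if g_env is None or any(pe is None for pe in p_envs):
            continue
        entry.env[env] = EnvComponent(
            g_env.value - sum(pe.value for pe in p_envs)  # type: ignore[union-attr]
        )
    return entry


def _singles_for(
    table: EffectTable, states: Iterable[Tuple[str, LocusState]]
) -> List[Optional[EffectEstimate]]:
    return [table.single_effect(locus, state) for locus, state in states]


def estimate_dual_epistasis(table: EffectTable) -> EffectTable:
    """Add dual-QTL epistasis: ``e = g - sum(single effects)`` per order-2 pyramid.

    Non-significant constituent singles are carried at their estimated
    values, never zeroed; a combination with an unavailable constituent is
    flagged undefined rather than silently dropped.
    """
    for g_entry in table.level(EffectKind.PYRAMIDING):
        if len(g_entry.loci_states) != 2:
            continue
        parts = _singles_for(table, g_entry.loci_states)
        entry = _residual_entry(
            EffectKind.DUAL_EPI, g_entry, parts, table.environments
        )
        _annotate(entry, table.err)
        table.add(entry)
    return table


def estimate_mixed_epistasis(table: EffectTable) -> EffectTable:
    """Add mixed epistasis for order-3 pyramids: ``e = g - sum(singles)``."""
    for g_entry in table.level(EffectKind.PYRAMIDING):
        if len(g_entry.loci_states) != 3:
            continue
        parts = _singles_for(table, g_entry.loci_states)
        entry = _residual_entry(
            EffectKind.MIXED_EPI, g_entry, parts, table.environments
        )
        _annotate(entry, table.err)
        table.add(entry)
    return table


def estimate_triple_epistasis(table: EffectTable) -> EffectTable:
    """Add pure three-way epistasis: mixed epistasis minus the three duals."""
    import itertools

    for mixed in table.level(EffectKind.MIXED_EPI):
        duals: List[Optional[EffectEstimate]] = []
        for pair in itertools.combinations(mixed.loci_states, 2):
            pair_id = "/".join(state_token(l, s) for l, s in pair)
            duals.append(table.get(EffectKind.DUAL_EPI, pair_id))
        entry = _residual_entry(
            EffectKind.TRIPLE_EPI, mixed, duals, table.environments
        )
        _annotate(entry, table.err)
        table.add(entry)
    return table


def decompose_effects(
    preds,
    materials: Sequence[MaterialGenotype],
    err: Optional[ErrorContext] = None,
) -> EffectTable:
    """Run the full sequential decomposition: singles, g, dual, mixed, triple."""
    table = estimate_single_effects(preds, materials, err)
    table.extend(estimate_pyramiding_effects(preds, materials, err))
    estimate_dual_epistasis(table)
    estimate_mixed_epistasis(table)
    estimate_triple_epistasis(table)
    return table


# ---------------------------------------------------------------------------
# least-squares (design-matrix) estimator
# ---------------------------------------------------------------------------


def _lm_columns(materials: Sequence[MaterialGenotype]):
    """Hierarchical indicator columns: a/d per locus, dual and triple terms."""
    cols: List[Tuple[str, EffectKind, Tuple[Tuple[str, LocusState], ...]]] = []
    seen = set()
    for m in materials:
        for locus, state in m.states:
            kind = (
                EffectKind.ADDITIVE
                if state is LocusState.HOM
                else EffectKind.DOMINANCE
            )
            key = state_token(locus, state)
            if (kind, key) not in seen:
                seen.add((kind, key))
                cols.append((key, kind, ((locus, state),)))
    for m in materials:
        if m.order < 2:
            continue
        for k, kind in ((2, EffectKind.DUAL_EPI), (3, EffectKind.TRIPLE_EPI)):
            for sub in m.subsets(k):
                key = sub.material_id
                if (kind, key) not in seen:
                    seen.add((kind, key))
                    cols.append((key, kind, sub.states))
    # deterministic: singles by catalog appearance, then interactions by order/id
    singles = [c for c in cols if len(c[2]) == 1]
    inter = sorted(
        (c for c in cols if len(c[2]) > 1), key=lambda c: (len(c[2]), c[0])
    )
    return singles + inter


def estimate_effects_lm(
    preds,
    materials: Sequence[MaterialGenotype],
    err: Optional[ErrorContext] = None,
) -> EffectTable:
    """Least-squares fit of G (and each GE column) on the hierarchical design.

    The design has an intercept plus one indicator column per single-locus
    state, per dual (pair, state-pair) and per triple combination present in
    the materials.  On the saturated design this reproduces the
    sequential-difference estimates exactly; pyramiding and mixed-epistasis
    rows are reconstructed from the fitted components so the output table has
    the same shape as :func:`decompose_effects`.
    """
    envs = _environments(preds)
    mats = [m for m in materials if m.material_id in preds.G.index]
    ids = [m.material_id for m in mats]
    cols = _lm_columns(mats)
    X = np.zeros((len(mats), 1 + len(cols)))
    X[:, 0] = 1.0
    for j, (_, _, states) in enumerate(cols, start=1):
        need = set(states)
        for i, m in enumerate(mats):
            if need <= set(m.states):
                X[i, j] = 1.0
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        from scipy.linalg import qr

        _, _, piv = qr(X, pivoting=True)
        aliased = [
            ("intercept" if j == 0 else cols[j - 1][0])
            for j in sorted(piv[rank:])
        ]
        raise ValueError(f"rank-deficient effect design; aliased columns: {aliased}")

    y = preds.G.loc[ids].to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    ge_beta = {}
    for env in envs:
        ge_beta[env], *_ = np.linalg.lstsq(
            X, preds.GE.loc[env, ids].to_numpy(dtype=float), rcond=None
        )
    xtx_inv_diag = np.diag(np.linalg.inv(X.T @ X))

    table = EffectTable(environments=envs, err=err)
    coef = {}
    for j, (key, kind, states) in enumerate(cols, start=1):
        cls = component_class(MaterialGenotype(states=states))
        entry = EffectEstimate(
            kind=kind,
            material=key,
            loci_states=states,
            component_class=cls,
            value=float(beta[j]),
            env={env: EnvComponent(float(ge_beta[env][j])) for env in envs},
        )
        if err is not None and err.df > 0:
            se = math.sqrt(xtx_inv_diag[j] * err.sigma2 / (err.n_env * err.n_blocks))
            entry.se = se
            if se > 0:
                entry.p = float(2.0 * stats.t.sf(abs(entry.value / se), err.df))
                entry.stars = stars_for(entry.p)
            for env, comp in entry.env.items():
                se_env = math.sqrt(
                    xtx_inv_diag[j]
                    * err.sigma2
                    * (1.0 - 1.0 / err.n_env)
                    / err.n_blocks
                )
                comp.se = se_env
                if se_env > 0:
                    comp.p = float(2.0 * stats.t.sf(abs(comp.value / se_env), err.df))
                    comp.stars = stars_for(comp.p)
        coef[(kind, key)] = entry
        table.add(entry)

    # reconstruct g and mixed epistasis from the fitted components
    for m in mats:
        if m.order < 2:
            continue
        terms: List[EffectEstimate] = []
        for locus, state in m.states:
            kind = (
                EffectKind.ADDITIVE
                if state is LocusState.HOM
                else EffectKind.DOMINANCE
            )
            terms.append(coef[(kind, state_token(locus, state))])
        inter_terms: List[EffectEstimate] = []
        for k, kind in ((2, EffectKind.DUAL_EPI), (3, EffectKind.TRIPLE_EPI)):
            for sub in m.subsets(k):
                e = coef.get((kind, sub.material_id))
                if e is not None:
                    inter_terms.append(e)
        g_entry = EffectEstimate(
            kind=EffectKind.PYRAMIDING,
            material=m.material_id,
            loci_states=m.states,
            component_class=component_class(m),
            value=sum(t.value for t in terms + inter_terms),
            env={
                env: EnvComponent(
                    sum(t.env[env].value for t in terms + inter_terms)
                )
                for env in envs
            },
        )
        table.add(g_entry)
        if m.order == 3:
            mixed = EffectEstimate(
                kind=EffectKind.MIXED_EPI,
                material=m.material_id,
                loci_states=m.states,
                component_class=component_class(m),
                value=sum(t.value for t in inter_terms),
                env={
                    env: EnvComponent(sum(t.env[env].value for t in inter_terms))
                    for env in envs
                },
            )
            table.add(mixed)
    return table


# ---------------------------------------------------------------------------
# dominance degree
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DominanceDegree:
    ratio: Optional[float]
    label: str


def dominance_degree(a: float, d: float) -> DominanceDegree:
    """Dominance degree ``d/a`` with the usual verbal classification.

    ``|d/a| > 1`` is super-dominance; with a zero additive effect the ratio
    is undefined and the locus is labelled dominance-only.
    """
    if a == 0:
        return DominanceDegree(None, "dominance only")
    r = d / a
    if abs(r) > 1:
        label = "super-dominant"
    elif r == 0:
        label = "no dominance"
    elif abs(r) == 1:
        label = "complete dominance"
    else:
        label = "partial dominance"
    return DominanceDegree(r, label)
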