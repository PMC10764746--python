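"""Synthetic plot-level data with the exact structure the analysis assumes.

The generator emulates a randomized-block trial of substitution-line
pyramids grown in several environments: each plot value is

    y = mu + E_h + G_j + GE_hj + B_k(h) + eps,

with fixed environment shifts ``E_h``, a genotypic value ``G_j`` built from
configurable additive/dominance/epistatic truth terms, interaction
deviations ``GE_hj`` that sum to zero over environments, Gaussian block
effects nested in environments and Gaussian plot error.  Ground truth is
exported in the same table shape the estimators produce, so
parameter-recovery tests reduce to a table diff.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .decompose import (
    EffectEstimate,
    EffectKind,
    EffectTable,
    EnvComponent,
)
from .design import (
    RECIPIENT_ID,
    LocusState,
    MaterialGenotype,
    component_class,
    state_token,
)

DEFAULT_ENVIRONMENTS = ("e1", "e2", "e3")


@dataclass
class TruthModel:
    """True parameter values behind a simulated trial (all in days).

    Effect keys use canonical material-id tokens: ``"Hd3a-2"`` for the
    additive entry of *Hd3a*, ``"Ehd1-1/Hd3a-2"`` for a dual interaction,
    and so on.  ``ge`` maps an effect key to its per-environment deviations,
    which must sum to zero across environments.
    """

    mu: float = 87.0
    env_effects: Dict[str, float] = field(
        default_factory=lambda: {"e1": -4.0, "e2": 6.0, "e3": -2.0}
    )
    a: Dict[str, float] = field(default_factory=dict)
    d: Dict[str, float] = field(default_factory=dict)
    dual_e: Dict[str, float] = field(default_factory=dict)
    triple_e: Dict[str, float] = field(default_factory=dict)
    ge: Dict[str, Dict[str, float]] = field(default_factory=dict)
    block_sd: float = 0.5
    resid_sd: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.block_sd < 0 or self.resid_sd < 0:
            raise ValueError("standard deviations must be nonnegative")
        envs = set(self.env_effects)
        for key, devs in self.ge.items():
            if set(devs) - envs:
                raise ValueError(f"ge[{key!r}] names unknown environments")
            total = sum(devs.get(e, 0.0) for e in envs)
            if abs(total) > 1e-8:
                raise ValueError(
                    f"ge[{key!r}] must sum to zero over environments, got {total}"
                )

    @property
    def environments(self) -> Tuple[str, ...]:
        return tuple(self.env_effects)


def _term_keys(m: MaterialGenotype):
    """Every truth-term key applicable to a material: singles, pairs, triple."""
    for k in range(1, m.order + 1):
        for sub in m.subsets(k):
            yield k, sub


def genotypic_value(m: MaterialGenotype, t: TruthModel) -> float:
    """True genotypic value G(m): sum of all applicable truth terms.

    Each homozygous locus contributes its additive effect, each heterozygous
    locus its dominance effect, plus every applicable dual and triple
    interaction.  The recipient is the zero point: G(recipient) = 0.
    """
    total = 0.0
    for k, sub in _term_keys(m):
        key = sub.material_id
        if k == 1:
            locus, state = sub.states[0]
            src = t.a if state is LocusState.HOM else t.d
            total += src.get(key, 0.0)
        elif k == 2:
            total += t.dual_e.get(key, 0.0)
        elif k == 3:
            total += t.triple_e.get(key, 0.0)
    return total


def ge_value(m: MaterialGenotype, t: TruthModel, env: str) -> float:
    """True genotype-by-environment deviation GE(m, env)."""
    total = 0.0
    for _, sub in _term_keys(m):
        devs = t.ge.get(sub.material_id)
        if devs:
            total += devs.get(env, 0.0)
    return total


def generate_experiment(
    t: TruthModel,
    materials: Sequence[MaterialGenotype],
    environments: Optional[Sequence[str]] = None,
    blocks_per_env: int = 3,
) -> pd.DataFrame:
    """Simulate plot records (columns env, block, material, hd).

    Block effects are Normal(0, block_sd^2) per (environment, block); plot
    errors Normal(0, resid_sd^2).  The same seed always yields the same
    table, row for row.
    """
    if not materials:
        raise ValueError("materials list is empty")
    if blocks_per_env < 1:
        raise ValueError("blocks_per_env must be >= 1")
    envs = list(environments) if environments is not None else list(t.environments)
    rng = np.random.default_rng(t.seed)
    g = {m.material_id: genotypic_value(m, t) for m in materials}
    ge = {
        (env, m.material_id): ge_value(m, t, env)
        for env in envs
        for m in materials
    }
    rows = []
    for env in envs:
        e_h = t.env_effects.get(env, 0.0)
        for b in range(1, blocks_per_env + 1):
            block_eff = rng.normal(0.0, t.block_sd) if t.block_sd > 0 else 0.0
            for m in materials:
                eps = rng.normal(0.0, t.resid_sd) if t.resid_sd > 0 else 0.0
                rows.append(
                    {
                        "env": env,
                        "block": f"b{b}",
                        "material": m.material_id,
                        "hd": t.mu
                        + e_h
                        + g[m.material_id]
                        + ge[(env, m.material_id)]
                        + block_eff
                        + eps,
                    }
                )
    return pd.DataFrame(rows)


def truth_effect_table(
    t: TruthModel, materials: Sequence[MaterialGenotype]
) -> EffectTable:
    """Export ground truth in the estimator's table shape (for table diffs)."""
    envs = list(t.environments)
    table = EffectTable(environments=envs)
    singles: Dict[str, MaterialGenotype] = {}
    for m in materials:
        if m.order == 1:
            singles[m.material_id] = m

    def env_components(key: str) -> Dict[str, EnvComponent]:
        devs = t.ge.get(key, {})
        return {env: EnvComponent(devs.get(env, 0.0)) for env in envs}

    for mat_id, m in singles.items():
        locus, state = m.states[0]
        kind = (
            EffectKind.ADDITIVE if state is LocusState.HOM else EffectKind.DOMINANCE
        )
        src = t.a if state is LocusState.HOM else t.d
        table.add(
            EffectEstimate(
                kind=kind,
                material=mat_id,
                loci_states=m.states,
                component_class=component_class(m),
                value=src.get(mat_id, 0.0),
                env=env_components(mat_id),
            )
        )
    for m in materials:
        if m.order < 2:
            continue
        mat_id = m.material_id
        g_val = genotypic_value(m, t)
        g_env = {
            env: EnvComponent(ge_value(m, t, env)) for env in envs
        }
        table.add(
            EffectEstimate(
                kind=EffectKind.PYRAMIDING,
                material=mat_id,
                loci_states=m.states,
                component_class=component_class(m),
                value=g_val,
                env=g_env,
            )
        )
        if m.order == 2:
            table.add(
                EffectEstimate(
                    kind=EffectKind.DUAL_EPI,
                    material=mat_id,
                    loci_states=m.states,
                    component_class=component_class(m),
                    value=t.dual_e.get(mat_id, 0.0),
                    env=env_components(mat_id),
                )
            )
        elif m.order == 3:
            mixed = t.triple_e.get(mat_id, 0.0) + sum(
                t.dual_e.get(sub.material_id, 0.0) for sub in m.subsets(2)
            )
            mixed_env = {}
            for env in envs:
                v = t.ge.get(mat_id, {}).get(env, 0.0) + sum(
                    t.ge.get(sub.material_id, {}).get(env, 0.0)
                    for sub in m.subsets(2)
                )
                mixed_env[env] = EnvComponent(v)
            table.add(
                EffectEstimate(
                    kind=EffectKind.MIXED_EPI,
                    material=mat_id,
                    loci_states=m.states,
                    component_class=component_class(m),
                    value=mixed,
                    env=mixed_env,
                )
            )
            table.add(
                EffectEstimate(
                    kind=EffectKind.TRIPLE_EPI,
                    material=mat_id,
                    loci_states=m.states,
                    component_class=component_class(m),
                    value=t.triple_e.get(mat_id, 0.0),
                    env=env_components(mat_id),
                )
            )
    return table


def random_truth(
    materials: Sequence[MaterialGenotype],
    seed: int,
    effect_scale: float = 6.0,
    ge_scale: float = 2.0,
    block_sd: float = 0.0,
    resid_sd: float = 0.0,
    environments: Sequence[str] = DEFAULT_ENVIRONMENTS,
) -> TruthModel:
    """Draw a fully random truth model over the given materials (for tests)."""
    rng = np.random.default_rng(seed)
    envs = list(environments)
    env_effects = rng.normal(0.0, 4.0, size=len(envs))
    env_effects -= env_effects.mean()
    t = TruthModel(
        mu=float(rng.uniform(80, 95)),
        env_effects=dict(zip(envs, map(float, env_effects))),
        block_sd=block_sd,
        resid_sd=resid_sd,
        seed=seed,
    )
    keys: Dict[int, list] = {1: [], 2: [], 3: []}
    for m in materials:
        if m.order == 1:
            keys[1].append(m)
        elif m.order == 2:
            keys[2].append(m)
        elif m.order == 3:
            keys[3].append(m)
    for m in keys[1]:
        locus, state = m.states[0]
        val = float(rng.normal(0.0, effect_scale))
        if state is LocusState.HOM:
            t.a[m.material_id] = val
        else:
            t.d[m.material_id] = val
    for m in keys[2]:
        t.dual_e[m.material_id] = float(rng.normal(0.0, effect_scale))
    for m in keys[3]:
        t.triple_e[m.material_id] = float(rng.normal(0.0, effect_scale))
    if ge_scale > 0:
        all_ids = [m.material_id for order in (1, 2, 3) for m in keys[order]]
        for key in all_ids:
            devs = rng.normal(0.0, ge_scale, size=len(envs))
            devs -= devs.mean()
            t.ge[key] = dict(zip(envs, map(float, devs)))
    return t


def generate_vc_experiment(
    sigma2_G: float,
    sigma2_GE: float,
    sigma2_B: float,
    sigma2_e: float,
    n_materials: int,
    environments: Sequence[str] = DEFAULT_ENVIRONMENTS,
    blocks_per_env: int = 3,
    mu: float = 90.0,
    env_effects: Optional[Mapping[str, float]] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a balanced trial with Gaussian G/GE/B/e at given variances.

    Unlike :func:`generate_experiment` the genotypic values are drawn iid
    Normal rather than built from locus effects; this is the natural input
    for variance-component recovery studies.
    """
    rng = np.random.default_rng(seed)
    envs = list(environments)
    mats = [f"m{i:03d}" for i in range(n_materials)]
    G = rng.normal(0.0, np.sqrt(sigma2_G), size=n_materials)
    GE = rng.normal(0.0, np.sqrt(sigma2_GE), size=(len(envs), n_materials))
    rows = []
    for h, env in enumerate(envs):
        e_h = (env_effects or {}).get(env, 0.0)
        for b in range(1, blocks_per_env + 1):
            block_eff = rng.normal(0.0, np.sqrt(sigma2_B))
            eps = rng.normal(0.0, np.sqrt(sigma2_e), size=n_materials)
            for j, mat in enumerate(mats):
                rows.append(
                    {
                        "env": env,
                        "block": f"b{b}",
                        "material": mat,
                        "hd": mu + e_h + G[j] + GE[h, j] + block_eff + eps[j],
                    }
                )
    return pd.DataFrame(rows)
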