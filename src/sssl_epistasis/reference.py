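"""Packaged reference effect tables for the four heading-date QTLs.

The package ships the published single-QTL, pyramiding and epistasis
effect values for the HJX74 substitution-line system (loci Ehd1, OsMADS50,
Hd3a, Hd1) as plain CSV.  Blank cells are effects that were not reported
(non-significant); they load as unavailable rather than zero.  Interaction
values whose environment assignment is not unambiguous in the source
record occupy the leading environment columns in reported order.

These tables serve two purposes: identity tests of the decomposition
arithmetic, and a "study-like" truth-model preset for the simulator.
"""

from __future__ import annotations

from importlib import resources
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .decompose import EffectKind, EffectTable
from .design import DEFAULT_LOCI, LocusState, enumerate_materials
from .io import read_effect_report
from .truth import TruthModel

LOCUS_NAMES = tuple(l.name for l in DEFAULT_LOCI)
ENVIRONMENTS = ("e1", "e2", "e3")

_FILES = {
    "additive": "reference_additive.csv",
    "dominance": "reference_dominance.csv",
    "pyramiding": "reference_pyramiding.csv",
    "dual_epistasis": "reference_dual_epistasis.csv",
    "triple_epistasis": "reference_triple_epistasis.csv",
    "mixed_epistasis": "reference_mixed_epistasis.csv",
}


def _data_path(name: str):
    return resources.files("sssl_epistasis.data") / _FILES[name]


def load_reference_table(name: str) -> EffectTable:
    """Load one reference table (additive, dominance, pyramiding, ...)."""
    if name not in _FILES:
        raise KeyError(f"unknown reference table {name!r}")
    with resources.as_file(_data_path(name)) as path:
        table = _read_fixture(path)
    return table


def _read_fixture(path) -> EffectTable:
    df = pd.read_csv(path, dtype={"stars": str})
    df = df.rename(
        columns={
            **{f"ee{i}": f"e{i}_value" for i in (1, 2, 3)},
            **{f"ee{i}_stars": f"e{i}_stars" for i in (1, 2, 3)},
        }
    )
    # reuse the report reader by staging the renamed frame
    import io as _io

    buf = _io.StringIO()
    df.to_csv(buf, index=False)
    buf.seek(0)
    table = read_effect_report(buf, LOCUS_NAMES)
    table.environments = list(ENVIRONMENTS)
    return table


def load_reference_effects(names: Optional[Sequence[str]] = None) -> EffectTable:
    """Combine several reference tables into one effect table."""
    names = list(names) if names is not None else list(_FILES)
    combined = EffectTable(environments=list(ENVIRONMENTS))
    for name in names:
        combined.extend(load_reference_table(name))
    return combined


def paper_like_truth(
    seed: int = 0,
    block_sd: float = 0.5,
    resid_sd: float = 1.5,
    include_ge: bool = True,
) -> TruthModel:
    """Truth model whose effects are the packaged reference values.

    Unreported effects enter as zero and every interaction vector is
    balanced to sum to zero over the three environments (the reference
    rows never report all three, so the missing deviations absorb the
    remainder equally).
    """
    singles = load_reference_effects(["additive", "dominance"])
    inter = load_reference_effects(
        ["pyramiding", "dual_epistasis", "triple_epistasis"]
    )
    t = TruthModel(
        mu=87.0,
        env_effects={"e1": -4.0, "e2": 6.0, "e3": -2.0},
        block_sd=block_sd,
        resid_sd=resid_sd,
        seed=seed,
    )

    def ge_of(entry) -> Optional[Dict[str, float]]:
        if not include_ge:
            return None
        vals = {
            env: c.value
            for env, c in entry.env.items()
            if np.isfinite(c.value)
        }
        if not vals:
            return None
        rest = [e for e in ENVIRONMENTS if e not in vals]
        if rest:
            fill = -sum(vals.values()) / len(rest)
            for e in rest:
                vals[e] = fill
        else:  # should not occur; keep the invariant anyway
            total = sum(vals.values()) / len(vals)
            vals = {e: v - total for e, v in vals.items()}
        return vals

    for e in singles.entries:
        if not e.available or not np.isfinite(e.value):
            continue
        if e.kind is EffectKind.ADDITIVE:
            t.a[e.material] = e.value
        else:
            t.d[e.material] = e.value
        g = ge_of(e)
        if g:
            t.ge[e.material] = g
    for e in inter.entries:
        if e.kind is EffectKind.DUAL_EPI and e.available and np.isfinite(e.value):
            t.dual_e[e.material] = e.value
        elif (
            e.kind is EffectKind.TRIPLE_EPI
            and e.available
            and np.isfinite(e.value)
        ):
            t.triple_e[e.material] = e.value
        else:
            continue
        g = ge_of(e)
        if g:
            t.ge[e.material] = g
    return t


def reference_materials():
    """The 65-material design behind the reference tables."""
    return enumerate_materials(list(DEFAULT_LOCI), max_order=3)
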