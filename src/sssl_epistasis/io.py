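"""Delimited-text I/O for plot tables and effect reports.

All tables are comma-separated UTF-8 with "." decimals.  Report files are
written at full precision so a write/read round trip is lossless; the
human-readable rendering rounds to 0.1 day and appends the significance
stars (any en-dash minus signs in externally produced files are normalized
to ASCII on ingest).  Lines starting with ``#`` carry provenance metadata
and are ignored on read.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence

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
    PlotRecord,
    parse_material_id,
)

PLOT_COLUMNS = ("env", "block", "material", "hd")


def _normalize_minus(s: str) -> str:
    return s.replace("−", "-").replace("–", "-").replace(" ", "")


def read_plot_table(path, known_materials: Optional[Iterable[str]] = None) -> List[PlotRecord]:
    """Read plot records, validating structure row by row.

    Raises explicit errors for an empty file, a missing or duplicated
    header, non-numeric heading dates (naming the offending row) and,
    when ``known_materials`` is given, unknown material ids.
    """
    path = Path(path)
    lines = [
        l
        for l in path.read_text(encoding="utf-8").splitlines()
        if l.strip() and not l.startswith("#")
    ]
    if not lines:
        raise ValueError(f"{path}: empty plot table")
    header = [c.strip() for c in lines[0].split(",")]
    if header != list(PLOT_COLUMNS):
        raise ValueError(
            f"{path}: expected header {','.join(PLOT_COLUMNS)!r}, got {lines[0]!r}"
        )
    known = set(known_materials) if known_materials is not None else None
    records = []
    for i, line in enumerate(lines[1:], start=2):
        parts = [c.strip() for c in line.split(",")]
        if parts == header:
            raise ValueError(f"{path}: duplicated header at row {i}")
        if len(parts) != 4:
            raise ValueError(f"{path}: row {i} has {len(parts)} fields, expected 4")
        env, block, material, hd_raw = parts
        try:
            hd = float(_normalize_minus(hd_raw))
        except ValueError:
            raise ValueError(
                f"{path}: row {i}: non-numeric heading date {hd_raw!r}"
            ) from None
        if known is not None and material not in known:
            raise ValueError(f"{path}: row {i}: unknown material {material!r}")
        records.append(PlotRecord(env, block, material, hd))
    if not records:
        raise ValueError(f"{path}: plot table has a header but no rows")
    return records


def write_plot_table(plots, path, meta: Optional[Dict[str, str]] = None) -> None:
    from .mixed_model import as_plot_frame

    df = as_plot_frame(plots)
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, index=False, float_format="%.12g", lineterminator="\n")


# ---------------------------------------------------------------------------
# effect reports
# ---------------------------------------------------------------------------

_BASE_COLS = ["level", "material", "class", "value", "se", "p", "stars", "available"]


def write_effect_report(
    table: EffectTable, path, meta: Optional[Dict[str, str]] = None
) -> None:
    """Full-precision CSV of an effect table (round-trips losslessly)."""
    df = table.frame()
    path = Path(path)
    with Path(path).open("w", encoding="utf-8") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, index=False, float_format="%.12g", lineterminator="\n")


def read_effect_report(path, locus_names: Sequence[str]) -> EffectTable:
    """Rebuild an :class:`EffectTable` from a report written by this module."""
    df = pd.read_csv(path, comment="#", dtype={"stars": str})
    env_names = sorted(
        {
            c[: -len("_value")]
            for c in df.columns
            if c.endswith("_value") and c != "value"
        }
    )
    table = EffectTable(environments=env_names)
    for _, row in df.iterrows():
        m = parse_material_id(str(row["material"]), locus_names)
        env = {}
        for e in env_names:
            v = row.get(f"{e}_value")
            if v is None or (isinstance(v, float) and math.isnan(v)):
                continue
            stars = row.get(f"{e}_stars")
            p = row.get(f"{e}_p")
            se = row.get(f"{e}_se")
            env[e] = EnvComponent(
                value=float(v),
                se=None if pd.isna(se) else float(se),
                p=None if pd.isna(p) else float(p),
                stars="" if pd.isna(stars) else str(stars),
            )
        value = row["value"]
        available = bool(row.get("available", True)) and not pd.isna(value)
        table.add(
            EffectEstimate(
                kind=EffectKind(row["level"]),
                material=str(row["material"]),
                loci_states=m.states,
                component_class=str(row["class"]),
                value=float(value) if not pd.isna(value) else float("nan"),
                se=None if pd.isna(row.get("se")) else float(row["se"]),
                p=None if pd.isna(row.get("p")) else float(row["p"]),
                stars="" if pd.isna(row.get("stars")) else str(row["stars"]),
                env=env,
                available=available,
            )
        )
    return table


def render_report(table: EffectTable) -> str:
    """Human-readable view: values to 0.1 day with star annotations."""

    def fmt(value, stars) -> str:
        if value is None or (isinstance(value, float) and math.isnan(value)):
            return ""
        return f"{value:.1f}{stars}"

    lines = []
    envs = table.environments
    header = ["level", "material", "class", "effect"] + [
        f"{e}" for e in envs
    ]
    lines.append("\t".join(header))
    for e in table.entries:
        row = [
            e.kind.value,
            e.material,
            e.component_class,
            fmt(e.value, e.stars) if e.available else "",
        ]
        for env in envs:
            comp = e.env.get(env)
            row.append(fmt(comp.value, comp.stars) if comp else "")
        lines.append("\t".join(row))
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# material catalogs
# ---------------------------------------------------------------------------


def read_material_catalog(path, locus_names: Sequence[str]) -> List[MaterialGenotype]:
    """Catalog file: columns material_id then one 0/1/2 column per locus."""
    df = pd.read_csv(path, comment="#")
    if "material_id" not in df.columns:
        raise ValueError(f"{path}: missing material_id column")
    missing = [l for l in locus_names if l not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing locus columns {missing}")
    out = []
    for _, row in df.iterrows():
        states = {
            l: LocusState.from_code(row[l])
            for l in locus_names
            if int(row[l]) != 0
        }
        m = MaterialGenotype.from_mapping(states, locus_names)
        if m.material_id != str(row["material_id"]) and str(
            row["material_id"]
        ) not in (RECIPIENT_ID,):
            # names are advisory; the state mapping is authoritative
            pass
        out.append(m)
    return out
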