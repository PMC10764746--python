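"""End-to-end driver: simulate -> fit -> decompose -> summarize -> network.

A :class:`StudyConfig` describes the trial (locus catalog, environments,
blocks, truth model or input plot table, significance levels, seed); the
pipeline executes every stage, writes each intermediate as delimited text
into the output directory and records provenance (config hash, seed) in
every file header plus a ``provenance.json``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import pandas as pd
import yaml

from . import __version__
from .decompose import EffectKind, decompose_effects, estimate_effects_lm
from .design import DEFAULT_LOCI, Locus, enumerate_materials
from .io import write_effect_report, write_plot_table, read_plot_table
from .mixed_model import as_plot_frame, fit_mixed_model
from .network import ThresholdPolicy, build_network, to_dot
from .reference import paper_like_truth
from .summary import class_stats, homeostasis_report, summarize_signs
from .truth import TruthModel, generate_experiment, truth_effect_table


@dataclass
class StudyConfig:
    loci: List[Dict] = field(
        default_factory=lambda: [
            {"name": l.name, "chromosome": l.chromosome, "donor": l.donor}
            for l in DEFAULT_LOCI
        ]
    )
    environments: List[Dict] = field(
        default_factory=lambda: [
            {"name": "e1", "day_length": "NSD"},
            {"name": "e2", "day_length": "NLD"},
            {"name": "e3", "day_length": "NSD"},
        ]
    )
    blocks_per_env: int = 3
    max_order: int = 3
    truth: str = "paper_like"  # "paper_like" | "null" | inline mapping
    plot_table: Optional[str] = None  # analyse an existing table instead
    alpha_levels: List[float] = field(default_factory=lambda: [0.05, 0.01])
    min_delta: float = 1.0
    seed: int = 0
    out_dir: str = "results"

    def locus_objects(self) -> List[Locus]:
        return [
            Locus(
                name=l["name"],
                chromosome=l.get("chromosome"),
                donor=l.get("donor"),
            )
            for l in self.loci
        ]

    def env_names(self) -> List[str]:
        return [e["name"] for e in self.environments]

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path) -> StudyConfig:
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    cfg = StudyConfig(**raw)
    if cfg.plot_table and not Path(cfg.plot_table).exists():
        raise FileNotFoundError(f"plot table {cfg.plot_table!r} does not exist")
    if not cfg.loci:
        raise ValueError("config names no loci")
    return cfg


def _truth_from_config(cfg: StudyConfig) -> TruthModel:
    if cfg.truth == "paper_like":
        t = paper_like_truth(seed=cfg.seed)
    elif cfg.truth == "null":
        t = TruthModel(seed=cfg.seed)
    elif isinstance(cfg.truth, dict):
        t = TruthModel(**cfg.truth)
        t.seed = cfg.seed
    else:
        raise ValueError(f"unknown truth preset {cfg.truth!r}")
    t.seed = cfg.seed
    return t


def run_pipeline(cfg: StudyConfig, out_dir: Optional[str] = None) -> Path:
    """Execute all stages and return the artifact directory."""
    out = Path(out_dir or cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {
        "config_sha256": cfg.config_hash(),
        "seed": str(cfg.seed),
        "version": __version__,
    }
    loci = cfg.locus_objects()
    materials = enumerate_materials(loci, cfg.max_order)
    locus_names = [l.name for l in loci]
    envs = cfg.env_names()

    stage = "simulate"
    try:
        if cfg.plot_table:
            plots = as_plot_frame(
                read_plot_table(
                    cfg.plot_table, known_materials=[m.material_id for m in materials]
                )
            )
        else:
            t = _truth_from_config(cfg)
            plots = generate_experiment(
                t, materials, environments=envs, blocks_per_env=cfg.blocks_per_env
            )
            write_effect_report(
                truth_effect_table(t, materials), out / "truth_effects.csv", meta
            )
        write_plot_table(plots, out / "plots.csv", meta)

        stage = "fit"
        fit = fit_mixed_model(plots)
        with (out / "anova.csv").open("w", encoding="utf-8") as fh:
            for k, v in meta.items():
                fh.write(f"# {k}={v}\n")
            fit.anova.table.to_csv(fh, float_format="%.12g", lineterminator="\n")
        vc_rows = pd.DataFrame(
            {
                "component": ["G", "GE", "B", "e"],
                "sigma2": [
                    fit.vc.sigma2_G,
                    fit.vc.sigma2_GE,
                    fit.vc.sigma2_B,
                    fit.vc.sigma2_e,
                ],
            }
        )
        with (out / "variance_components.csv").open("w", encoding="utf-8") as fh:
            for k, v in meta.items():
                fh.write(f"# {k}={v}\n")
            vc_rows.to_csv(fh, index=False, float_format="%.12g", lineterminator="\n")
        (out / "heritability.json").write_text(
            json.dumps(
                {
                    "general": fit.heritability.general,
                    "peculiar": fit.heritability.peculiar,
                    **meta,
                },
                indent=2,
                sort_keys=True,
            )
            + "\n",
            encoding="utf-8",
        )
        with (out / "blup_G.csv").open("w", encoding="utf-8") as fh:
            for k, v in meta.items():
                fh.write(f"# {k}={v}\n")
            fit.blup.G.rename("G").to_csv(fh, float_format="%.12g", lineterminator="\n")
        with (out / "blup_GE.csv").open("w", encoding="utf-8") as fh:
            for k, v in meta.items():
                fh.write(f"# {k}={v}\n")
            fit.blup.GE.to_csv(fh, float_format="%.12g", lineterminator="\n")

        stage = "decompose"
        table = decompose_effects(fit.ls, materials, err=fit.err)
        for kind, name in (
            (EffectKind.ADDITIVE, "effects_additive"),
            (EffectKind.DOMINANCE, "effects_dominance"),
            (EffectKind.PYRAMIDING, "effects_pyramiding"),
            (EffectKind.DUAL_EPI, "effects_dual_epistasis"),
            (EffectKind.TRIPLE_EPI, "effects_triple_epistasis"),
            (EffectKind.MIXED_EPI, "effects_mixed_epistasis"),
        ):
            sub = table.frame()
            sub = sub[sub["level"] == kind.value]
            with (out / f"{name}.csv").open("w", encoding="utf-8") as fh:
                for k, v in meta.items():
                    fh.write(f"# {k}={v}\n")
                sub.to_csv(fh, index=False, float_format="%.12g", lineterminator="\n")

        stage = "summarize"
        signs = [
            summarize_signs(table, kind)
            for kind in (
                EffectKind.DUAL_EPI,
                EffectKind.TRIPLE_EPI,
                EffectKind.MIXED_EPI,
            )
        ]
        sign_df = pd.DataFrame(
            [
                {
                    "level": s.level,
                    "n_total": s.n_total,
                    "n_significant": s.n_significant,
                    "n_negative_significant": s.n_negative_significant,
                    "n_positive_significant": s.n_positive_significant,
                }
                for s in signs
            ]
        )
        with (out / "sign_summary.csv").open("w", encoding="utf-8") as fh:
            for k, v in meta.items():
                fh.write(f"# {k}={v}\n")
            sign_df.to_csv(fh, index=False, lineterminator="\n")
        cls_rows = []
        for kind in (EffectKind.DUAL_EPI, EffectKind.TRIPLE_EPI, EffectKind.MIXED_EPI):
            for c in class_stats(table, kind):
                cls_rows.append(
                    {
                        "level": kind.value,
                        "class": c.component_class,
                        "mean": c.mean,
                        "sd": c.sd,
                        "n": c.n,
                    }
                )
        with (out / "class_stats.csv").open("w", encoding="utf-8") as fh:
            for k, v in meta.items():
                fh.write(f"# {k}={v}\n")
            pd.DataFrame(cls_rows).to_csv(
                fh, index=False, float_format="%.12g", lineterminator="\n"
            )
        hom = homeostasis_report(table)
        with (out / "homeostasis.csv").open("w", encoding="utf-8") as fh:
            for k, v in meta.items():
                fh.write(f"# {k}={v}\n")
            fh.write(f"# pattern={hom.pattern}\n")
            hom.per_pyramid.to_csv(
                fh, index=False, float_format="%.12g", lineterminator="\n"
            )

        stage = "network"
        edges = build_network(
            table,
            ThresholdPolicy(alpha=cfg.alpha_levels[0], min_delta=cfg.min_delta),
        )
        edge_df = pd.DataFrame(
            [
                {
                    "source": e.source,
                    "target": e.target,
                    "relation": e.relation,
                    **{f"state_{k}": v for k, v in e.per_state.items()},
                }
                for e in edges
            ]
        )
        with (out / "network_edges.csv").open("w", encoding="utf-8") as fh:
            for k, v in meta.items():
                fh.write(f"# {k}={v}\n")
            edge_df.to_csv(fh, index=False, lineterminator="\n")
        (out / "network.dot").write_text(to_dot(edges), encoding="utf-8")

        (out / "provenance.json").write_text(
            json.dumps(
                {
                    "config": asdict(cfg),
                    **meta,
                    "n_materials": len(materials),
                    "n_plots": int(len(plots)),
                },
                indent=2,
                sort_keys=True,
            )
            + "\n",
            encoding="utf-8",
        )
    except Exception as exc:  # annotate with the failing stage
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return out
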