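"""End-to-end orchestration: clean -> targets -> interconnectivity -> null /
z-scores -> topology -> overlaps -> enrichment -> cocktail report.

One YAML config drives a full run.  A single master seed is declared; each
randomised stage derives its own seed from (master seed, stage name), so
adding or removing a stage never perturbs the randomness of the others and
reruns are byte-identical.  Outputs are TSV tables plus a JSON run report
carrying the config echo, per-stage row counts and every provenance note.
"""

from __future__ import annotations

import json
import logging
import zlib
from collections import Counter
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cocktail import (
    aggregate_targets,
    category_coverage,
    cocktail_union,
    compare_to_tf_targets,
    load_catalog,
    load_cocktails,
    sm_frequency,
)
from .interactome import clean_interactome
from .io import read_chem_targets, read_edge_list, read_gmt, read_tf_targets
from .null_model import null_curve, z_for_observed
from .set_statistics import enrich
from .topology import DegreePowerLawModel

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated inputs and tunables for one pipeline run."""

    graph_path: str
    chem_targets_path: str
    out_dir: str
    gmt_path: str | None = None
    tf_table_path: str | None = None
    cocktails_path: str | None = None
    catalog_path: str | None = None
    tf_query: list[str] = field(default_factory=list)
    taxon: int = 9606
    graph_dialect: str = "simple_tsv"
    score_scale: str = "unit"
    score_threshold: float = 0.4
    curve_reps: int = 100
    z_reps: int = 1000
    curve_min: int = 50
    curve_step: int = 50
    curve_max: int | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as handle:
            raw = yaml.safe_load(handle) or {}
        unknown = set(raw) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        for label in ("graph_path", "chem_targets_path", "gmt_path",
                      "tf_table_path", "cocktails_path", "catalog_path"):
            value = getattr(self, label)
            if value is not None and not Path(value).exists():
                raise FileNotFoundError(f"{label}: {value} does not exist")
        if self.curve_reps < 2 or self.z_reps < 2:
            raise ValueError("replicate counts must be >= 2")
        if not 0.0 <= self.score_threshold <= 1.0:
            raise ValueError("score_threshold must be on [0, 1]")


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed keyed on the stage name (< 2**31)."""
    ss = np.random.SeedSequence([master, zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute every configured stage; return (and write) the run report."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {
        "version": __version__,
        "config": asdict(config),
        "stages": {},
    }

    def stage(name: str):
        logger.info("stage %s", name)
        return report["stages"].setdefault(name, {})

    # 1. interactome cleaning
    info = stage("clean_interactome")
    try:
        records = read_edge_list(config.graph_path, dialect=config.graph_dialect)
        g = clean_interactome(records, taxon=config.taxon)
    except Exception as exc:
        raise RuntimeError(f"stage clean_interactome failed on {config.graph_path}") from exc
    info.update(
        input_rows=len(records),
        nodes=g.number_of_nodes(),
        edges=g.number_of_edges(),
        removed=dict(g.provenance),
    )
    g.to_edge_tsv(out / "interactome_clean.tsv")

    # 2. chemical targets
    info = stage("chem_targets")
    table = read_chem_targets(config.chem_targets_path, score_scale=config.score_scale)
    info.update(rows=len(table), chemicals=len({r.chemical_id for r in table}))

    # 3. cocktail combinatorics
    info = stage("cocktails")
    catalog = load_catalog(config.catalog_path)
    cocktails = load_cocktails(config.cocktails_path, catalog)
    union = cocktail_union(cocktails)
    freq = sm_frequency(cocktails)
    info.update(n_cocktails=len(cocktails), union_size=len(union))
    pd.DataFrame(
        {"sm": list(freq), "n_cocktails": list(freq.values())}
    ).to_csv(out / "sm_frequency.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {"cocktail": c.name, "size": len(c.members),
             **{f"n_{cat}": n for cat, n in category_coverage(c, catalog).items()}}
            for c in cocktails
        ]
    ).fillna(0).to_csv(out / "cocktail_coverage.tsv", sep="\t", index=False)

    # 4. per-cocktail targets + interconnectivity z-scores
    info = stage("cocktail_networks")
    rows = []
    for c in cocktails:
        targets = aggregate_targets(c, table, threshold=config.score_threshold)
        row: dict[str, Any] = {"cocktail": c.name, "n_targets": len(targets)}
        mapped = targets & g.nodes
        if len(mapped) >= 2:
            summary = z_for_observed(
                g, targets, reps=config.z_reps,
                seed=stage_seed(config.seed, f"cocktail:{c.name}"),
            )
            row.update(
                n_mapped=summary.sample_size,
                observed_fraction=summary.observed_fraction,
                null_mean=summary.mean_fraction,
                null_sd=summary.sd_fraction,
                z_score=summary.z_score,
            )
        else:
            row.update(n_mapped=len(mapped), observed_fraction=None,
                       null_mean=None, null_sd=None, z_score=None)
        rows.append(row)
    cocktail_df = pd.DataFrame(rows)
    cocktail_df.to_csv(out / "cocktail_interconnectivity.tsv", sep="\t", index=False)
    info.update(rows=len(rows))

    # 5. pooled SM-target network
    info = stage("sm_target_network")
    all_targets = frozenset(
        r.protein for r in table if r.combined_score >= config.score_threshold
    )
    info["n_targets"] = len(all_targets)
    if len(all_targets & g.nodes) >= 2:
        summary = z_for_observed(
            g, all_targets, reps=config.z_reps, seed=stage_seed(config.seed, "sm_targets")
        )
        info.update(
            n_mapped=summary.sample_size,
            observed_fraction=summary.observed_fraction,
            null_mean=summary.mean_fraction,
            null_sd=summary.sd_fraction,
            z_score=summary.z_score,
        )
        # 6. topology of the induced SM-target subgraph
        tinfo = stage("topology")
        sub = g.graph.subgraph(all_targets & g.nodes)
        hist = dict(Counter(d for _, d in sub.degree()))
        try:
            fit = DegreePowerLawModel(hist).fit()
            tinfo.update(
                coefficient=fit.coefficient, exponent=fit.exponent,
                r_squared=fit.r_squared, k_range=list(fit.k_range),
                n_points=fit.n_points,
            )
        except ValueError as exc:
            tinfo["error"] = str(exc)
        pd.DataFrame(
            sorted(hist.items()), columns=["k", "count"]
        ).to_csv(out / "sm_target_degree_histogram.tsv", sep="\t", index=False)

    # 7. null curve on the cleaned interactome
    info = stage("null_curve")
    points = null_curve(
        g, min_size=config.curve_min, step=config.curve_step,
        max_size=config.curve_max, reps=config.curve_reps,
        seed=stage_seed(config.seed, "null_curve"),
    )
    pd.DataFrame(
        [
            {"sample_size": p.sample_size, "reps": p.reps,
             "mean_fraction": p.mean_fraction, "sd_fraction": p.sd_fraction}
            for p in points
        ]
    ).to_csv(out / "null_curve.tsv", sep="\t", index=False)
    info["points"] = len(points)

    # 8. enrichment of pooled SM targets
    if config.gmt_path:
        info = stage("enrichment")
        collection = read_gmt(config.gmt_path)
        rows2 = enrich(all_targets, collection)
        pd.DataFrame([asdict(r) for r in rows2]).to_csv(
            out / "enrichment.tsv", sep="\t", index=False
        )
        info["sets"] = len(rows2)

    # 9. cocktail vs TF-target overlaps
    if config.tf_table_path and config.tf_query:
        info = stage("tf_overlap")
        tf_table = read_tf_targets(config.tf_table_path)
        # genes present in both the chemical-target and TF-target sources
        universe = tf_table.all_targets & {r.protein for r in table}
        rows3 = []
        for c in cocktails:
            targets = aggregate_targets(c, table, threshold=config.score_threshold)
            try:
                res = compare_to_tf_targets(targets, tf_table, config.tf_query, universe)
            except ValueError as exc:
                raise RuntimeError(f"stage tf_overlap failed on cocktail {c.name}") from exc
            rows3.append({"cocktail": c.name, **asdict(res)})
        pd.DataFrame(rows3).to_csv(out / "tf_overlap.tsv", sep="\t", index=False)
        info["rows"] = len(rows3)

    with open(out / "report.json", "w", encoding="utf-8") as handle:
        json.dump(report, handle, indent=2, sort_keys=True)
    return report
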