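"""End-to-end "replay" workflow and run configuration.

Chains simulate -> classify -> overlap/sweep -> consensus -> biotype /
chromosome enrichment -> dynamics -> GSEA over a pair of platforms and up
to three time points, writing a TSV + JSON report bundle.  Every output is
accompanied by a provenance record (package version, config hash, seed) and
every number in the JSON summary is the direct return value of a module
operation — the report does no arithmetic of its own.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .concordance import (
    classify_regulation,
    consensus_degs,
    directional_overlap,
    inclusion_sweep,
    rank_by_average_fc,
    spearman_concordance,
)
from .data_model import DOWN, UP, DEGTable, RegulationCalls, read_deg_table
from .dynamics import adaptation_fraction, classify_trajectories
from .enrichment import biotype_composition, chromosome_enrichment_tests
from .gsea import cross_platform_gsea, gsea_permutation, results_to_frame
from .synthetic import (
    SimulatedStudy,
    SyntheticConfig,
    make_gene_sets,
    simulate_paired_study,
)

logger = logging.getLogger("degconcord")

__all__ = ["RunConfig", "StageError", "run_pipeline"]


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a replay run.

    Either ``inputs`` maps (platform, timepoint) to DE-table paths, or
    ``simulate`` carries a :class:`SyntheticConfig` to generate them.
    Thresholds default to the analysis conventions: significance 0.05,
    stars at 0.05/0.01, biotype filter 20, four cutoff halvings, top-21
    fold-change tables.
    """

    output_dir: Path
    inputs: dict = field(default_factory=dict)  # (platform, timepoint) -> path
    simulate: SyntheticConfig | None = None
    alpha: float = 0.05
    n_halvings: int = 4
    min_biotype_count: int = 20
    alpha_star: float = 0.05
    alpha_doublestar: float = 0.01
    top_n: int = 21
    gsea_n_perm: int = 200
    gsea_weight: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.simulate is None and not self.inputs:
            raise ValueError("either inputs or a simulate config is required")
        for key, path in self.inputs.items():
            if not Path(path).exists():
                raise ValueError(f"input {key} does not exist: {path}")

    def content_hash(self) -> str:
        # where the bundle is written does not change what was computed
        payload = dataclasses.asdict(self)
        payload.pop("output_dir")
        payload["inputs"] = {str(k): str(v) for k, v in self.inputs.items()}
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _load_tables(cfg: RunConfig) -> tuple[dict, SimulatedStudy | None]:
    if cfg.simulate is not None:
        study = simulate_paired_study(cfg.simulate, seed=cfg.seed)
        return dict(study.tables), study
    tables = {
        key: read_deg_table(path) for key, path in sorted(cfg.inputs.items())
    }
    return tables, None


def _jsonable(value):
    if isinstance(value, dict):
        return {str(k): _jsonable(v) for k, v in value.items()}
    if isinstance(value, (list, tuple)):
        return [_jsonable(v) for v in value]
    if isinstance(value, (np.integer,)):
        return int(value)
    if isinstance(value, (np.floating, float)):
        v = float(value)
        return None if np.isnan(v) else v
    return value


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all applicable stages; return the JSON-ready summary.

    Writes per-stage TSVs plus ``summary.json`` and ``provenance.json``
    under ``cfg.output_dir``.  A stage failure raises :class:`StageError`
    naming the stage.
    """
    cfg.validate()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {}
    stage = "load"
    try:
        tables, study = _load_tables(cfg)
        platforms = sorted({p for p, _ in tables})
        timepoints = sorted({t for _, t in tables})
        last_t = timepoints[-1]

        stage = "classify"
        calls = {key: classify_regulation(tbl, cfg.alpha) for key, tbl in tables.items()}
        for (platform, t), c in calls.items():
            c.write(out / f"calls_{platform}_t{t}.tsv")
        summary["call_counts"] = {
            f"{p}_t{t}": calls[(p, t)].counts() for p, t in sorted(calls)
        }

        if len(platforms) == 2:
            pa, pb = platforms
            ta, tb = tables[(pa, last_t)], tables[(pb, last_t)]

            stage = "overlap"
            ov = directional_overlap(calls[(pa, last_t)], calls[(pb, last_t)])
            ov.to_frame().to_csv(out / "overlap.tsv", sep="\t", index=False)
            summary["overlap"] = {
                row["category"]: row["count"]
                for _, row in ov.to_frame().iterrows()
            }
            summary["fraction_A_in_B_any"] = ov.fraction_A_in_B_any

            stage = "sweep"
            curve = inclusion_sweep(ta, tb, cfg.alpha, cfg.n_halvings)
            curve.to_frame().to_csv(out / "sweep.tsv", sep="\t", index=False)
            summary["sweep_cutoffs"] = list(curve.rows["cutoff_swept"])

            stage = "spearman"
            summary["spearman_all"] = spearman_concordance(ta, tb, "all")

            stage = "consensus"
            consensus = consensus_degs(ta, tb, cfg.alpha)
            consensus.records.to_csv(out / "consensus.tsv", sep="\t")
            summary["n_consensus"] = len(consensus)
            for direction in (UP, DOWN):
                top = rank_by_average_fc(consensus, direction, cfg.top_n)
                top.to_csv(out / f"top_{direction.lower()}.tsv", sep="\t")

        stage = "biotype"
        ref_platform = platforms[0]
        ref = tables[(ref_platform, last_t)]
        comp = biotype_composition(
            ref, calls[(ref_platform, last_t)], cfg.min_biotype_count
        )
        comp.table.to_csv(out / "biotype.tsv", sep="\t", index=False)
        summary["biotype_filtered_out"] = list(comp.filtered_out)

        stage = "chromosome_enrichment"
        enr = chromosome_enrichment_tests(
            ref, calls[(ref_platform, last_t)], cfg.alpha_star, cfg.alpha_doublestar
        )
        enr.table.to_csv(out / "chromosome_enrichment.tsv", sep="\t")
        summary["starred_chromosomes_total"] = list(
            enr.table.index[enr.table["stars_total"] != ""]
        )

        if len(timepoints) >= 3:
            stage = "dynamics"
            t1, t2, t3 = timepoints[:3]
            if len(platforms) == 2:
                # consensus-style third time point: calls from platform A at
                # t1/t2, agreement of both platforms at t3 via platform A
                c3 = calls[(platforms[0], t3)]
            else:
                c3 = calls[(platforms[0], t3)]
            flow = classify_trajectories(
                calls[(platforms[0], t1)], calls[(platforms[0], t2)], c3
            )
            flow.to_frame().to_csv(out / "trajectories.tsv", sep="\t", index=False)
            flow.edge_list().to_csv(out / "trajectory_edges.tsv", sep="\t", index=False)
            adapt = adaptation_fraction(calls[(platforms[0], t1)], c3)
            summary["adaptation_t1_t3_pct"] = adapt.fraction_pct
            summary["n_excluded_trajectories"] = flow.n_excluded
        else:
            logger.info("dynamics stage skipped: fewer than three time points")
            summary["dynamics_skipped"] = True

        if study is not None and study.config.n_gene_sets > 0:
            stage = "gsea"
            sets, planted = make_gene_sets(study.truth, study.config, seed=cfg.seed + 1)
            gsea_results = {}
            for platform in platforms:
                ranking = tables[(platform, last_t)].data["rank_stat"].dropna()
                res = gsea_permutation(
                    ranking,
                    sets,
                    n_perm=cfg.gsea_n_perm,
                    seed=cfg.seed + 2,
                    alpha=cfg.alpha,
                    weight_exponent=cfg.gsea_weight,
                )
                results_to_frame(res).to_csv(
                    out / f"gsea_{platform}.tsv", sep="\t", index=False
                )
                gsea_results[platform] = res
            if len(platforms) == 2:
                xp = cross_platform_gsea(
                    gsea_results[platforms[0]], gsea_results[platforms[1]], cfg.alpha
                )
                summary["gsea_shared_significant"] = len(xp.shared)
                summary["gsea_contradictory"] = xp.contradictory
            summary["gsea_planted_sets"] = list(planted)
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        raise StageError(f"stage {stage!r} failed: {exc}") from exc

    summary = _jsonable(summary)
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    provenance = {
        "tool": "degconcord",
        "version": __version__,
        "config_hash": cfg.content_hash(),
        "seed": cfg.seed,
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2, sort_keys=True))
    return summary
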