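"""End-to-end orchestration: ingest -> portrait -> score -> RRHO -> report.

A :class:`RunConfig` names the disease DE tables, the study manifest and
the treatment tables; :func:`run_pipeline` materializes a run directory
with the portrait TSV, the ranked-treatment TSV, reversed-gene lists, RRHO
outputs and a machine-readable manifest.  Reruns with identical inputs
produce byte-identical TSVs.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .errors import PipelineStageError
from .ingest import ColumnSpec, read_de_table, to_signed_scores
from .overlap import (
    DEFAULT_SHARED_GENE_THRESHOLD,
    rank_treatments,
    reversed_genes,
    treatment_table,
)
from .portrait import (
    DEFAULT_PRESENCE_FRACTION,
    StudyManifest,
    WeightScheme,
    build_composite,
    build_portrait,
)
from .rrho import render_rrho, rrho_grid


@dataclass
class RunConfig:
    """Parameters of one end-to-end run (defaults match the reference analysis:
    top 1000 lists, strata to 8000, presence strictly above 2/3)."""

    disease_tables: list[str]
    out_dir: str
    manifest: str | None = None
    treatment_tables: list[str] = field(default_factory=list)
    columns: ColumnSpec = field(default_factory=ColumnSpec)
    n_top: int = 1000
    stratum_bounds: tuple[int, ...] = WeightScheme().stratum_bounds
    stratum_weights: tuple[float, ...] = WeightScheme().stratum_weights
    min_presence_fraction: float = DEFAULT_PRESENCE_FRACTION
    shared_gene_threshold: int = DEFAULT_SHARED_GENE_THRESHOLD
    strict_compatibility: bool = False
    p_floor: float = 1e-320
    rrho_step: int = 100
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "columns" in raw and isinstance(raw["columns"], dict):
            raw["columns"] = ColumnSpec(**raw["columns"])
        for key in ("stratum_bounds", "stratum_weights"):
            if key in raw:
                raw[key] = tuple(raw[key])
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        return cls(**known)

    @property
    def scheme(self) -> WeightScheme:
        return WeightScheme(self.stratum_bounds, self.stratum_weights)


def _stage(stage: str, source: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except PipelineStageError:
        raise
    except Exception as exc:  # noqa: BLE001 - deliberately re-tagged with stage context
        raise PipelineStageError(stage, source, exc) from exc


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full pipeline; returns the run directory.

    Stage errors propagate as :class:`PipelineStageError` carrying the
    stage name and offending input path.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    for path in [*config.disease_tables, *config.treatment_tables] + (
        [config.manifest] if config.manifest else []
    ):
        if not Path(path).exists():
            raise FileNotFoundError(f"input file does not exist: {path}")

    counts: dict[str, int] = {}

    # --- ingest -----------------------------------------------------------
    disease_scores = []
    for path in config.disease_tables:
        table = _stage("ingest", path, read_de_table, path, config.columns)
        counts[f"dropped_rows:{table.study_id}"] = table.n_dropped
        disease_scores.append(to_signed_scores(table))

    # --- portrait ---------------------------------------------------------
    if config.manifest:
        manifest = _stage("portrait", config.manifest, StudyManifest.from_tsv, config.manifest)
        portrait = _stage(
            "portrait", "disease tables", build_portrait,
            disease_scores, manifest, config.scheme, config.min_presence_fraction,
        )
    else:
        portrait = _stage(
            "portrait", "disease tables", build_composite,
            disease_scores, config.scheme, config.min_presence_fraction,
        )
    portrait.to_tsv(out / "portrait.tsv")
    counts["portrait_genes"] = len(portrait)
    counts["portrait_input_genes"] = portrait.n_input_genes
    counts["portrait_filtered_low_presence"] = portrait.n_filtered_low_presence

    # --- treatments -------------------------------------------------------
    top_signature = None
    if config.treatment_tables:
        treatment_scores = []
        for path in config.treatment_tables:
            table = _stage("score", path, read_de_table, path, config.columns)
            counts[f"dropped_rows:{table.study_id}"] = table.n_dropped
            treatment_scores.append(to_signed_scores(table))
        ranked = _stage(
            "score", "treatment tables", rank_treatments,
            portrait, treatment_scores, config.n_top,
            config.shared_gene_threshold, config.p_floor, config.strict_compatibility,
        )
        treatment_table(ranked).to_csv(
            out / "treatments_ranked.tsv", sep="\t", index=False, float_format="%.6g"
        )
        counts["treatments_scored"] = len(ranked)
        if ranked:
            top_id = ranked[0].dataset_id
            top_signature = next(t for t in treatment_scores if t.study_id == top_id)
            rev = _stage(
                "combine", top_id, reversed_genes,
                portrait, top_signature, config.n_top,
                config.shared_gene_threshold, config.p_floor,
            )
            (out / "reversed_up.txt").write_text(
                "\n".join(sorted(rev.up_reversed)) + "\n" if rev.up_reversed else ""
            )
            (out / "reversed_down.txt").write_text(
                "\n".join(sorted(rev.down_reversed)) + "\n" if rev.down_reversed else ""
            )
            counts["top_treatment_reversed"] = rev.n_reversed

            # --- rrho -----------------------------------------------------
            shared = len(portrait.genes & top_signature.genes)
            if shared >= config.rrho_step:
                grid = _stage(
                    "rrho", top_id, rrho_grid,
                    portrait, top_signature, config.rrho_step, config.p_floor,
                )
                grid.to_tsv(out / "rrho_top_treatment.tsv")
                _stage("rrho", top_id, render_rrho, grid, out / "rrho_top_treatment.png")

    # --- manifest ---------------------------------------------------------
    run_manifest = {
        "inputs": {
            "disease_tables": list(config.disease_tables),
            "manifest": config.manifest,
            "treatment_tables": list(config.treatment_tables),
        },
        "parameters": {
            "n_top": config.n_top,
            "stratum_bounds": list(config.stratum_bounds),
            "stratum_weights": list(config.stratum_weights),
            "min_presence_fraction": config.min_presence_fraction,
            "shared_gene_threshold": config.shared_gene_threshold,
            "strict_compatibility": config.strict_compatibility,
            "p_floor": config.p_floor,
            "rrho_step": config.rrho_step,
        },
        "versions": _versions(),
        "counts": counts,
    }
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(run_manifest, fh, indent=1, sort_keys=True)
    return out


def _versions() -> dict[str, str]:
    import numpy
    import pandas
    import scipy

    return {
        "sigportrait": __version__,
        "numpy": numpy.__version__,
        "pandas": pandas.__version__,
        "scipy": scipy.__version__,
    }
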