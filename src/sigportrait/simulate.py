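"""Synthetic multi-study differential-expression collections with known truth.

Generates GEO2R-style per-study tables containing a planted consensus
up/down signal shared across studies (small log-uniform p-values,
consistent signs) on top of uniform-p null genes with random signs, plus
treatment tables that flip a controllable fraction of the planted genes.
All draws are integer-indexed from ``numpy.random.default_rng`` so results
are reproducible across platforms.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError
from .ingest import AliasMap, DEGTable


@dataclass(frozen=True)
class SimulationConfig:
    n_genes: int = 15000
    n_studies: int = 6
    n_planted_up: int = 50
    n_planted_down: int = 50
    planted_rank_ceiling: int = 1000
    planted_p_range: tuple[float, float] = (1e-12, 1e-4)
    missing_fraction: float = 0.0
    reversal_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_studies < 1:
            raise ConfigurationError("n_genes and n_studies must be positive")
        if self.n_planted_up < 0 or self.n_planted_down < 0:
            raise ConfigurationError("planted counts must be nonnegative")
        if self.n_planted_up + self.n_planted_down >= self.n_genes:
            raise ConfigurationError("planted genes must be fewer than n_genes")
        if (self.n_planted_up > self.planted_rank_ceiling
                or self.n_planted_down > self.planted_rank_ceiling):
            raise ConfigurationError(
                "planted count per direction exceeds planted_rank_ceiling capacity"
            )
        lo, hi = self.planted_p_range
        if not (0.0 < lo <= hi < 1.0):
            raise ConfigurationError("planted_p_range must satisfy 0 < lo <= hi < 1")
        for name in ("missing_fraction", "reversal_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        if "planted_p_range" in known:
            known["planted_p_range"] = tuple(known["planted_p_range"])
        return cls(**known)


@dataclass(frozen=True)
class GroundTruth:
    planted_up: frozenset[str]
    planted_down: frozenset[str]
    treatment_reversed: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.planted_up & self.planted_down:
            raise ConfigurationError("planted up/down sets must be disjoint")

    @property
    def planted(self) -> frozenset[str]:
        return self.planted_up | self.planted_down

    def to_json(self, path: str | Path) -> None:
        payload = {
            "planted_up": sorted(self.planted_up),
            "planted_down": sorted(self.planted_down),
            "treatment_reversed": {
                k: sorted(v) for k, v in self.treatment_reversed.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(
            planted_up=frozenset(raw["planted_up"]),
            planted_down=frozenset(raw["planted_down"]),
            treatment_reversed={
                k: frozenset(v) for k, v in raw.get("treatment_reversed", {}).items()
            },
        )


def _gene_names(n: int) -> np.ndarray:
    return np.array([f"G{i:06d}" for i in range(1, n + 1)])


def _planted_indices(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    rng = np.random.default_rng([config.seed, 0])
    total = config.n_planted_up + config.n_planted_down
    idx = rng.choice(config.n_genes, size=total, replace=False)
    return idx[: config.n_planted_up], idx[config.n_planted_up:]


def _planted_p(rng: np.random.Generator, size: int, p_range: tuple[float, float]) -> np.ndarray:
    lo, hi = np.log10(p_range[0]), np.log10(p_range[1])
    return 10.0 ** rng.uniform(lo, hi, size)


def generate_study_collection(
    config: SimulationConfig,
) -> tuple[list[DEGTable], GroundTruth]:
    """Generate ``n_studies`` DE tables sharing one planted directional signal.

    Planted genes get small p-values (log-uniform over
    ``planted_p_range``) and the same sign in every study; null genes get
    uniform p and random signs; per-study missingness is applied
    independently (planted genes included).
    """
    genes = _gene_names(config.n_genes)
    up_idx, down_idx = _planted_indices(config)
    truth = GroundTruth(
        planted_up=frozenset(genes[up_idx]),
        planted_down=frozenset(genes[down_idx]),
    )
    tables: list[DEGTable] = []
    for s in range(config.n_studies):
        rng = np.random.default_rng([config.seed, 1, s])
        p = rng.uniform(0.0, 1.0, config.n_genes)
        magnitude = rng.uniform(0.1, 2.0, config.n_genes)
        signs = rng.choice([-1.0, 1.0], config.n_genes)
        lfc = magnitude * signs
        planted_idx = np.concatenate([up_idx, down_idx])
        p[planted_idx] = _planted_p(rng, len(planted_idx), config.planted_p_range)
        planted_mag = rng.uniform(0.5, 2.0, len(planted_idx))
        lfc[up_idx] = planted_mag[: len(up_idx)]
        lfc[down_idx] = -planted_mag[len(up_idx):]
        keep = np.ones(config.n_genes, dtype=bool)
        if config.missing_fraction > 0:
            keep = rng.uniform(0.0, 1.0, config.n_genes) >= config.missing_fraction
        frame = pd.DataFrame(
            {
                "gene_symbol": genes[keep],
                "p_value": p[keep],
                "direction_value": lfc[keep],
            }
        )
        tables.append(DEGTable(study_id=f"SIM{s:02d}", data=frame))
    return tables, truth


def generate_treatment(
    config: SimulationConfig,
    disease_truth: GroundTruth,
    reversal_fraction: float,
    index: int = 0,
    treatment_id: str | None = None,
) -> tuple[DEGTable, frozenset[str]]:
    """Generate one treatment DE table reversing a fraction of planted genes.

    Exactly ``round(reversal_fraction * n_planted)`` planted genes appear
    with flipped sign and small p; every other gene is null.  ``index``
    decouples the random streams of different treatments under one seed.
    """
    if not (0.0 <= reversal_fraction <= 1.0):
        raise ConfigurationError(
            f"reversal_fraction must be in [0, 1], got {reversal_fraction}"
        )
    genes = _gene_names(config.n_genes)
    rng = np.random.default_rng([config.seed, 2, index])
    p = rng.uniform(0.0, 1.0, config.n_genes)
    magnitude = rng.uniform(0.1, 2.0, config.n_genes)
    lfc = magnitude * rng.choice([-1.0, 1.0], config.n_genes)

    planted = sorted(disease_truth.planted_up) + sorted(disease_truth.planted_down)
    n_rev = round(reversal_fraction * len(planted))
    rev_pick = rng.choice(len(planted), size=n_rev, replace=False) if n_rev else np.array([], dtype=int)
    reversed_set = frozenset(planted[i] for i in rev_pick)

    pos = {g: i for i, g in enumerate(genes)}
    rev_idx = np.array([pos[g] for g in sorted(reversed_set)], dtype=int)
    if len(rev_idx):
        p[rev_idx] = _planted_p(rng, len(rev_idx), config.planted_p_range)
        mag = rng.uniform(0.5, 2.0, len(rev_idx))
        flip = np.array(
            [-1.0 if g in disease_truth.planted_up else 1.0 for g in sorted(reversed_set)]
        )
        lfc[rev_idx] = flip * mag
    keep = np.ones(config.n_genes, dtype=bool)
    if config.missing_fraction > 0:
        keep = rng.uniform(0.0, 1.0, config.n_genes) >= config.missing_fraction
    frame = pd.DataFrame(
        {
            "gene_symbol": genes[keep],
            "p_value": p[keep],
            "direction_value": lfc[keep],
        }
    )
    tid = treatment_id or f"TRT{index:03d}"
    return DEGTable(study_id=tid, data=frame), reversed_set


def inject_aliases(
    tables: list[DEGTable], fraction: float, seed: int = 0
) -> tuple[list[DEGTable], AliasMap]:
    """Rename a fraction of gene symbols to stale aliases across all tables.

    Returns the renamed tables plus the alias map that restores the
    original symbols (for exercising ``apply_symbol_map``).
    """
    if not (0.0 <= fraction <= 1.0):
        raise ConfigurationError(f"fraction must be in [0, 1], got {fraction}")
    all_genes = sorted({g for t in tables for g in t.data["gene_symbol"]})
    rng = np.random.default_rng([seed, 3])
    n_alias = round(fraction * len(all_genes))
    picked = rng.choice(len(all_genes), size=n_alias, replace=False)
    alias_of = {all_genes[i]: f"OLD_{all_genes[i]}" for i in picked}
    out: list[DEGTable] = []
    for t in tables:
        df = t.data.copy()
        df["gene_symbol"] = df["gene_symbol"].map(lambda g: alias_of.get(g, g))
        out.append(DEGTable(study_id=t.study_id, data=df))
    restore = AliasMap({old: new for new, old in alias_of.items()})
    return out, restore


def write_collection(
    tables: list[DEGTable], truth: GroundTruth, out_dir: str | Path
) -> None:
    """Write GEO2R-style TSVs plus a ground-truth JSON into a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for t in tables:
        df = t.data.rename(
            columns={
                "gene_symbol": "Gene.symbol",
                "p_value": "P.Value",
                "direction_value": "logFC",
            }
        )
        df.to_csv(out / f"{t.study_id}.tsv", sep="\t", index=False, float_format="%.6g")
    truth.to_json(out / "truth.json")
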