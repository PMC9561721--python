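"""Consensus portrait construction by directional rank-stratum aggregation.

Each study votes for its top up- and down-regulated genes with a
piecewise-constant decreasing weight over rank strata (default: weight 8
for ranks 1-1000 down to weight 1 for ranks 7001-8000, zero beyond).
Signed weights are summed across studies; genes measured in too few
datasets are removed by a presence filter.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from ._log import log_event
from .errors import ConfigurationError, ManifestError
from .ingest import SignedScoreTable

DEFAULT_STRATUM_BOUNDS: tuple[int, ...] = (1000, 2000, 3000, 4000, 5000, 6000, 7000, 8000)
DEFAULT_STRATUM_WEIGHTS: tuple[float, ...] = (8.0, 7.0, 6.0, 5.0, 4.0, 3.0, 2.0, 1.0)
DEFAULT_PRESENCE_FRACTION = 2.0 / 3.0

PORTRAIT_COLUMNS = ["gene_symbol", "aggregate_score", "n_studies_present", "mean_sign1", "rank"]


@dataclass(frozen=True)
class WeightScheme:
    """Rank strata with decreasing positive weights; zero beyond the last bound."""

    stratum_bounds: tuple[int, ...] = DEFAULT_STRATUM_BOUNDS
    stratum_weights: tuple[float, ...] = DEFAULT_STRATUM_WEIGHTS

    def __post_init__(self) -> None:
        bounds = tuple(int(b) for b in self.stratum_bounds)
        weights = tuple(float(w) for w in self.stratum_weights)
        if len(bounds) != len(weights):
            raise ConfigurationError("stratum_bounds and stratum_weights lengths differ")
        if len(bounds) == 0:
            raise ConfigurationError("weight scheme needs at least one stratum")
        if any(b2 <= b1 for b1, b2 in zip(bounds, bounds[1:])):
            raise ConfigurationError("stratum_bounds must be strictly increasing")
        if any(w <= 0 for w in weights):
            raise ConfigurationError("stratum_weights must be positive")
        if any(w2 >= w1 for w1, w2 in zip(weights, weights[1:])):
            raise ConfigurationError("stratum_weights must be strictly decreasing")
        object.__setattr__(self, "stratum_bounds", bounds)
        object.__setattr__(self, "stratum_weights", weights)

    @property
    def max_weight(self) -> float:
        return self.stratum_weights[0]

    @property
    def max_rank(self) -> int:
        return self.stratum_bounds[-1]


@dataclass(frozen=True)
class StudyManifest:
    """Maps dataset ids to the independent study they belong to.

    At most two datasets per independent study may enter a portrait build
    so that no single study dominates the consensus.
    """

    records: pd.DataFrame  # columns: dataset_id, study_id, sex, region

    def __post_init__(self) -> None:
        df = self.records.copy()
        required = {"dataset_id", "study_id"}
        missing = required - set(df.columns)
        if missing:
            raise ManifestError(f"manifest missing columns: {sorted(missing)}")
        for opt in ("sex", "region"):
            if opt not in df.columns:
                df[opt] = ""
        df = df.astype(str)
        if df["dataset_id"].duplicated().any():
            dupes = df.loc[df["dataset_id"].duplicated(), "dataset_id"].tolist()
            raise ManifestError(f"duplicate dataset ids in manifest: {dupes}")
        object.__setattr__(self, "records", df.reset_index(drop=True))

    def study_of(self, dataset_id: str) -> str:
        row = self.records.loc[self.records["dataset_id"] == dataset_id, "study_id"]
        if row.empty:
            raise ManifestError(f"dataset {dataset_id!r} not in manifest")
        return row.iloc[0]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "StudyManifest":
        return cls(pd.read_csv(path, sep="\t", dtype=str))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyManifest":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(pd.DataFrame(raw))

    @classmethod
    def trivial(cls, dataset_ids: Iterable[str]) -> "StudyManifest":
        """One independent study per dataset (no cap binds)."""
        ids = list(dataset_ids)
        return cls(pd.DataFrame({"dataset_id": ids, "study_id": ids}))


@dataclass
class Portrait:
    """Consensus ranking of genes by aggregate signed stratum-weight score.

    ``data`` columns: gene_symbol, aggregate_score, n_studies_present,
    mean_sign1, rank -- sorted by |aggregate_score| desc, ties by
    |mean_sign1| desc, then alphabetical.  ``n_input_genes`` and
    ``n_filtered_low_presence`` record the presence-filter bookkeeping.
    """

    data: pd.DataFrame
    n_input_genes: int = 0
    n_filtered_low_presence: int = 0

    def __len__(self) -> int:
        return len(self.data)

    @property
    def genes(self) -> set[str]:
        return set(self.data["gene_symbol"])

    def score_of(self, gene: str) -> float:
        row = self.data.loc[self.data["gene_symbol"] == gene, "aggregate_score"]
        if row.empty:
            raise KeyError(gene)
        return float(row.iloc[0])

    def to_tsv(self, path: str | Path) -> None:
        df = self.data.copy()
        df["aggregate_score"] = df["aggregate_score"].map(lambda v: f"{v:.6g}")
        df["mean_sign1"] = df["mean_sign1"].map(lambda v: f"{v:.6g}")
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Portrait":
        df = pd.read_csv(path, sep="\t")
        missing = set(PORTRAIT_COLUMNS) - set(df.columns)
        if missing:
            raise ConfigurationError(f"portrait file missing columns: {sorted(missing)}")
        return cls(data=df[PORTRAIT_COLUMNS].reset_index(drop=True))


def rank_directional(scores: SignedScoreTable) -> tuple[list[str], list[str]]:
    """Split a signed-score table into ordered up/down gene lists.

    Up-list: genes with sign1 > 0, strongest first; down-list: sign1 < 0,
    most negative first.  Ties broken alphabetically; sign1 == 0 genes are
    in neither list.
    """
    s = scores.scores
    df = pd.DataFrame({"gene": s.index, "sign1": s.to_numpy()})
    up = df[df["sign1"] > 0].sort_values(
        ["sign1", "gene"], ascending=[False, True], kind="stable"
    )
    down = df[df["sign1"] < 0].sort_values(
        ["sign1", "gene"], ascending=[True, True], kind="stable"
    )
    return up["gene"].tolist(), down["gene"].tolist()


def stratum_weight(rank: int, scheme: WeightScheme = WeightScheme()) -> float:
    """Weight of a 1-based directional rank under the scheme (0 beyond last bound)."""
    if rank < 1:
        raise ValueError(f"rank must be >= 1, got {rank}")
    idx = int(np.searchsorted(scheme.stratum_bounds, rank, side="left"))
    if idx >= len(scheme.stratum_bounds):
        return 0.0
    return scheme.stratum_weights[idx]


def _signed_weight_series(table: SignedScoreTable, scheme: WeightScheme) -> pd.Series:
    """Per-gene signed stratum weight for one study (0 for unranked genes)."""
    up, down = rank_directional(table)
    weights = pd.Series(0.0, index=table.scores.index)
    bounds = np.asarray(scheme.stratum_bounds)
    wvals = np.asarray(scheme.stratum_weights)
    for genes, sign in ((up, 1.0), (down, -1.0)):
        if not genes:
            continue
        ranks = np.arange(1, len(genes) + 1)
        idx = np.searchsorted(bounds, ranks, side="left")
        inside = idx < len(bounds)
        w = np.where(inside, wvals[np.minimum(idx, len(bounds) - 1)], 0.0)
        weights.loc[genes] = sign * w
    return weights


def _aggregate(
    tables: Sequence[SignedScoreTable],
    scheme: WeightScheme,
    min_presence_fraction: float,
) -> Portrait:
    n_tables = len(tables)
    weight_df = pd.concat(
        [_signed_weight_series(t, scheme) for t in tables], axis=1, join="outer"
    )
    sign1_df = pd.concat([t.scores for t in tables], axis=1, join="outer")
    presence = sign1_df.notna().sum(axis=1)
    score = weight_df.sum(axis=1)  # NaN (absent) treated as 0 contribution
    mean_sign1 = sign1_df.mean(axis=1)

    n_input = len(presence)
    keep = presence > min_presence_fraction * n_tables
    n_filtered = int((~keep).sum())
    df = pd.DataFrame(
        {
            "gene_symbol": presence.index[keep],
            "aggregate_score": score[keep].to_numpy(),
            "n_studies_present": presence[keep].to_numpy(dtype=int),
            "mean_sign1": mean_sign1[keep].to_numpy(),
        }
    )
    df["_abs_score"] = df["aggregate_score"].abs()
    df["_abs_mean"] = df["mean_sign1"].abs()
    df = df.sort_values(
        ["_abs_score", "_abs_mean", "gene_symbol"],
        ascending=[False, False, True],
        kind="stable",
    ).drop(columns=["_abs_score", "_abs_mean"])
    df["rank"] = np.arange(1, len(df) + 1)
    df = df.reset_index(drop=True)
    if len(df) == 0:
        warnings.warn("portrait is empty after presence filtering", stacklevel=3)
    log_event(
        "portrait_built",
        n_tables=n_tables,
        n_input_genes=n_input,
        n_filtered_low_presence=n_filtered,
        n_portrait_genes=len(df),
    )
    return Portrait(data=df, n_input_genes=n_input, n_filtered_low_presence=n_filtered)


def build_portrait(
    tables: Sequence[SignedScoreTable],
    manifest: StudyManifest,
    scheme: WeightScheme = WeightScheme(),
    min_presence_fraction: float = DEFAULT_PRESENCE_FRACTION,
) -> Portrait:
    """Aggregate many studies into a consensus disease portrait.

    Enforces the two-datasets-per-independent-study cap via the manifest;
    genes present in <= ``min_presence_fraction`` of the input datasets
    (strict inequality required to stay) are removed.
    """
    if len(tables) < 2:
        raise ValueError("build_portrait requires at least 2 tables; see build_composite")
    if not (0.0 <= min_presence_fraction < 1.0):
        raise ConfigurationError(
            f"min_presence_fraction must be in [0, 1), got {min_presence_fraction}"
        )
    per_study: dict[str, list[str]] = {}
    for t in tables:
        study = manifest.study_of(t.study_id)
        per_study.setdefault(study, []).append(t.study_id)
    offenders = {s: ds for s, ds in per_study.items() if len(ds) > 2}
    if offenders:
        raise ManifestError(
            f"more than two datasets share an independent study: {offenders}"
        )
    return _aggregate(tables, scheme, min_presence_fraction)


def build_composite(
    tables: Sequence[SignedScoreTable],
    scheme: WeightScheme = WeightScheme(),
    min_presence_fraction: float = DEFAULT_PRESENCE_FRACTION,
) -> Portrait:
    """Portrait-style aggregation for treatment composites (no per-study cap)."""
    if len(tables) < 1:
        raise ValueError("build_composite requires at least 1 table")
    if not (0.0 <= min_presence_fraction < 1.0):
        raise ConfigurationError(
            f"min_presence_fraction must be in [0, 1), got {min_presence_fraction}"
        )
    return _aggregate(tables, scheme, min_presence_fraction)


def reverse_portrait(portrait: Portrait) -> Portrait:
    """Negate every aggregate_score and mean_sign1; ordering unchanged."""
    df = portrait.data.copy()
    df["aggregate_score"] = -df["aggregate_score"] + 0.0
    df["mean_sign1"] = -df["mean_sign1"] + 0.0
    return Portrait(
        data=df,
        n_input_genes=portrait.n_input_genes,
        n_filtered_low_presence=portrait.n_filtered_low_presence,
    )
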