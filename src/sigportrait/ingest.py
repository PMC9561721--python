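"""Ingestion of per-study differential-expression tables.

Reads GEO2R/GREIN-style delimited exports (gene symbol, p-value, signed
fold change), converts them to per-gene signed dysregulation scores
(``sign1 = -log10(p) * sgn(direction)``), applies symbol alias maps, and
round-trips the two-column ``Gene.symbol / sign1`` exchange format.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from ._log import log_event
from .errors import ConfigurationError, EmptyInputError, ParseError

#: Default p-value clamp applied before -log10 so p = 0 stays finite.
DEFAULT_P_FLOOR = 1e-300

#: Header of the two-column exchange format.
EXCHANGE_HEADER = "Gene.symbol\tsign1"


@dataclass(frozen=True)
class ColumnSpec:
    """Column-name mapping for a differential-expression export.

    Defaults match GEO2R's standard output header.
    ``delimiter=None`` means "infer from file extension" (.csv -> comma,
    anything else -> tab).
    """

    gene_col: str = "Gene.symbol"
    pval_col: str = "P.Value"
    lfc_col: str = "logFC"
    delimiter: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ColumnSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        return cls(**known)


@dataclass
class DEGTable:
    """One study's differential-expression result.

    ``data`` holds columns ``gene_symbol`` (non-empty, upper-cased),
    ``p_value`` (in [0, 1]) and ``direction_value`` (signed real whose sign
    gives the direction of change vs control).  Rows violating these
    invariants are dropped at construction and counted in ``n_dropped``.
    """

    study_id: str
    data: pd.DataFrame
    n_dropped: int = 0

    def __post_init__(self) -> None:
        df = self.data
        required = {"gene_symbol", "p_value", "direction_value"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"DEGTable missing columns: {sorted(missing)}")
        before = len(df)
        gene = df["gene_symbol"].astype(str).str.strip().str.upper()
        p = pd.to_numeric(df["p_value"], errors="coerce")
        direction = pd.to_numeric(df["direction_value"], errors="coerce")
        keep = (
            gene.ne("")
            & gene.ne("NAN")
            & p.notna()
            & (p >= 0.0)
            & (p <= 1.0)
            & direction.notna()
        )
        clean = pd.DataFrame(
            {
                "gene_symbol": gene[keep],
                "p_value": p[keep].astype(float),
                "direction_value": direction[keep].astype(float),
            }
        ).reset_index(drop=True)
        dropped_here = before - len(clean)
        self.data = clean
        self.n_dropped = self.n_dropped + dropped_here
        if dropped_here:
            log_event(
                "rows_dropped",
                study_id=self.study_id,
                n_dropped=dropped_here,
                n_kept=len(clean),
            )

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class SignedScoreTable:
    """Per-gene signed dysregulation scores for one study.

    ``scores`` is a float Series indexed by unique upper-case gene symbol;
    positive values mean up vs control.
    """

    study_id: str
    scores: pd.Series

    def __post_init__(self) -> None:
        s = self.scores
        if s.index.has_duplicates:
            raise ValueError("SignedScoreTable requires unique gene symbols")
        if not np.all(np.isfinite(s.to_numpy(dtype=float))):
            raise ValueError("sign1 values must be finite")
        self.scores = s.astype(float)
        self.scores.index = self.scores.index.astype(str)
        self.scores.index.name = "gene_symbol"
        self.scores.name = "sign1"

    def __len__(self) -> int:
        return len(self.scores)

    @property
    def genes(self) -> set[str]:
        return set(self.scores.index)

    def equals(self, other: "SignedScoreTable", rtol: float = 1e-5) -> bool:
        """Equality up to float formatting (~6 significant digits)."""
        a = self.scores.sort_index()
        b = other.scores.sort_index()
        if not a.index.equals(b.index):
            return False
        return bool(np.allclose(a.to_numpy(), b.to_numpy(), rtol=rtol, atol=1e-12))


@dataclass(frozen=True)
class AliasMap:
    """Many-to-one old-symbol -> current-symbol map.

    Chains (A -> B, B -> C) are resolved at construction so the map is
    idempotent on its output symbols.
    """

    mapping: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        raw = {str(k).strip().upper(): str(v).strip().upper() for k, v in self.mapping.items()}
        resolved: dict[str, str] = {}
        for key in raw:
            target = raw[key]
            seen = {key}
            while target in raw and raw[target] != target:
                if target in seen:
                    raise ConfigurationError(f"alias cycle involving {target!r}")
                seen.add(target)
                target = raw[target]
            resolved[key] = target
        object.__setattr__(self, "mapping", resolved)

    def __len__(self) -> int:
        return len(self.mapping)

    def get(self, symbol: str) -> str:
        return self.mapping.get(symbol, symbol)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AliasMap":
        """Read a two-column (old, current) TSV; a header row is optional."""
        pairs: dict[str, str] = {}
        with open(path) as fh:
            for i, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line.strip():
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise ParseError(f"expected 2 tab-separated fields in {path}", line=i)
                old, new = parts
                if i == 1 and old.lower() in {"old_symbol", "old", "alias"}:
                    continue
                pairs[old] = new
        return cls(pairs)


def read_de_table(
    path: str | Path,
    format_spec: ColumnSpec | Mapping[str, str] | None = None,
    study_id: str | None = None,
) -> DEGTable:
    """Parse one differential-expression export into a :class:`DEGTable`.

    Rows with missing/unparseable gene symbol, p-value or direction value
    are dropped and counted (logged via the structured log); they are never
    silently truncated.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    ConfigurationError
        If a configured column is absent (message lists available columns).
    EmptyInputError
        If no row parses.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if format_spec is None:
        spec = ColumnSpec()
    elif isinstance(format_spec, ColumnSpec):
        spec = format_spec
    else:
        spec = ColumnSpec(**{k: v for k, v in format_spec.items()
                             if k in ColumnSpec.__dataclass_fields__})

    delim = spec.delimiter
    if delim is None:
        delim = "," if path.suffix.lower() == ".csv" else "\t"

    raw = pd.read_csv(path, sep=delim, dtype=str, keep_default_na=False)
    for col in (spec.gene_col, spec.pval_col, spec.lfc_col):
        if col not in raw.columns:
            raise ConfigurationError(
                f"column {col!r} not found in {path.name}; "
                f"available columns: {list(raw.columns)}"
            )
    frame = pd.DataFrame(
        {
            "gene_symbol": raw[spec.gene_col],
            "p_value": raw[spec.pval_col],
            "direction_value": raw[spec.lfc_col],
        }
    )
    table = DEGTable(study_id=study_id or path.stem, data=frame)
    if len(table) == 0:
        raise EmptyInputError(f"no parseable rows in {path}")
    return table


def to_signed_scores(table: DEGTable, p_floor: float = DEFAULT_P_FLOOR) -> SignedScoreTable:
    """Convert a DE table to per-gene sign1 scores.

    ``sign1 = -log10(max(p, p_floor)) * sgn(direction_value)``; duplicate
    symbols (multiple probes) keep the row with the smallest p-value, ties
    keep the first occurrence in input order.
    """
    if not (0.0 < p_floor < 1.0):
        raise ConfigurationError(f"p_floor must be in (0, 1), got {p_floor}")
    df = table.data
    # stable sort by p: first occurrence wins ties, smallest p wins otherwise
    dedup = df.sort_values("p_value", kind="stable").drop_duplicates(
        "gene_symbol", keep="first"
    )
    n_dups = len(df) - len(dedup)
    if n_dups:
        log_event("duplicate_symbols_resolved", study_id=table.study_id, n_duplicates=n_dups)
    p = np.maximum(dedup["p_value"].to_numpy(), p_floor)
    sign1 = -np.log10(p) * np.sign(dedup["direction_value"].to_numpy())
    sign1 = sign1 + 0.0  # normalize -0.0 -> 0.0
    scores = pd.Series(sign1, index=dedup["gene_symbol"].to_numpy()).sort_index()
    return SignedScoreTable(study_id=table.study_id, scores=scores)


def apply_symbol_map(scores: SignedScoreTable, aliases: AliasMap) -> SignedScoreTable:
    """Replace symbols per the alias map.

    When two source symbols collapse onto one target, the entry with the
    larger ``|sign1|`` is kept (ties: first in input order); the collision
    count is logged.
    """
    if len(aliases) == 0:
        return SignedScoreTable(scores.study_id, scores.scores.copy())
    s = scores.scores
    mapped = pd.DataFrame(
        {
            "gene_symbol": [aliases.get(g) for g in s.index],
            "sign1": s.to_numpy(),
        }
    )
    mapped["_mag"] = mapped["sign1"].abs()
    picked = (
        mapped.sort_values("_mag", ascending=False, kind="stable")
        .drop_duplicates("gene_symbol", keep="first")
        .drop(columns="_mag")
    )
    n_collisions = len(mapped) - len(picked)
    if n_collisions:
        log_event("symbol_collisions", study_id=scores.study_id, n_collisions=n_collisions)
    out = pd.Series(
        picked["sign1"].to_numpy(), index=picked["gene_symbol"].to_numpy()
    ).sort_index()
    return SignedScoreTable(study_id=scores.study_id, scores=out)


def write_signed_scores(scores: SignedScoreTable, path: str | Path) -> None:
    """Write the two-column exchange format (6 significant digits)."""
    with open(path, "w") as fh:
        fh.write(EXCHANGE_HEADER + "\n")
        for gene, value in scores.scores.items():
            fh.write(f"{gene}\t{value:.6g}\n")


def read_signed_scores(path: str | Path, study_id: str | None = None) -> SignedScoreTable:
    """Read the two-column exchange format written by :func:`write_signed_scores`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    genes: list[str] = []
    values: list[float] = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if i == 1:
                if line != EXCHANGE_HEADER:
                    raise ParseError(
                        f"expected header {EXCHANGE_HEADER!r}, got {line!r}", line=1
                    )
                continue
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError("expected 2 tab-separated fields", line=i)
            gene, raw = parts
            try:
                value = float(raw)
            except ValueError:
                raise ParseError(f"non-numeric sign1 value {raw!r}", line=i) from None
            if not math.isfinite(value):
                raise ParseError(f"non-finite sign1 value {raw!r}", line=i)
            genes.append(gene.strip().upper())
            values.append(value)
    series = pd.Series(values, index=genes, dtype=float).sort_index()
    if series.index.has_duplicates:
        raise ParseError(f"duplicate gene symbols in {path}")
    return SignedScoreTable(study_id=study_id or path.stem, scores=series)
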