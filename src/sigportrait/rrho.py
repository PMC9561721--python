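"""Rank-rank hypergeometric overlap (RRHO) grids and heatmaps.

Both signatures are ordered most-up-regulated first to most-down-regulated
last over their shared genes; for every pair of rank thresholds the overlap
of the two prefixes is scored with a signed -log10 hypergeometric tail:
positive where the overlap exceeds its expectation (upper tail), negative
otherwise (lower tail).
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .ingest import SignedScoreTable
from .overlap import DEFAULT_P_FLOOR, Signature, _restrict, _signature_genes
from .portrait import Portrait


@dataclass(frozen=True)
class RRHOMap:
    """Signed -log10 hypergeometric grid over nested rank thresholds.

    ``values[j, i]`` scores the overlap of the first ``thresholds_x[i]``
    genes of the x-axis signature with the first ``thresholds_y[j]`` genes
    of the y-axis signature.
    """

    step: int
    thresholds_x: tuple[int, ...]
    thresholds_y: tuple[int, ...]
    values: np.ndarray
    x_order: tuple[str, ...]  # x-axis gene ordering, most-up first
    y_order: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.thresholds_y), len(self.thresholds_x)):
            raise ValueError("values shape does not match thresholds")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("RRHO values must be finite")

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            self.values,
            index=pd.Index(self.thresholds_y, name="rank_y"),
            columns=[str(t) for t in self.thresholds_x],
        )
        df.to_csv(path, sep="\t", float_format="%.6g")


def _full_order(sig: Signature) -> list[str]:
    """All shared genes sorted most-up first, most-down last (ties alphabetical)."""
    if isinstance(sig, Portrait):
        df = sig.data
        ordered = df.sort_values(
            ["aggregate_score", "gene_symbol"], ascending=[False, True], kind="stable"
        )
        return ordered["gene_symbol"].tolist()
    s = sig.scores
    df = pd.DataFrame({"gene": s.index, "sign1": s.to_numpy()})
    ordered = df.sort_values(["sign1", "gene"], ascending=[False, True], kind="stable")
    return ordered["gene"].tolist()


def rrho_grid(
    sig1: Signature,
    sig2: Signature,
    step: int = 100,
    p_floor: float = DEFAULT_P_FLOOR,
) -> RRHOMap:
    """Compute the full RRHO grid of two signed signatures.

    ``sig1`` is the x axis, ``sig2`` the y axis.  Thresholds run
    ``step, 2*step, ...`` up to the shared-gene count.  Cell sign is
    positive iff the observed overlap strictly exceeds its hypergeometric
    mean; magnitude is ``-log10`` of the matching tail probability, clamped
    at ``p_floor``.
    """
    if step < 1:
        raise ValueError(f"step must be >= 1, got {step}")
    shared = _signature_genes(sig1) & _signature_genes(sig2)
    N = len(shared)
    if step > N:
        raise ValueError(f"step {step} exceeds shared gene count {N}")
    order1 = _full_order(_restrict(sig1, shared))
    order2 = _full_order(_restrict(sig2, shared))

    n_thresh = N // step
    thresholds = tuple(step * (i + 1) for i in range(n_thresh))

    # 1-based rank of each shared gene in each ordering
    rank2 = {g: r for r, g in enumerate(order2, start=1)}
    r1 = np.arange(1, N + 1, dtype=float)
    r2 = np.array([rank2[g] for g in order1], dtype=float)
    # half-integer edges so a rank exactly at a threshold lands in its prefix
    edges = np.array([0.5] + [t + 0.5 for t in thresholds], dtype=float)
    hist, _, _ = np.histogram2d(r1, r2, bins=[edges, edges])
    k = hist.cumsum(axis=0).cumsum(axis=1)  # k[i, j]: overlap of prefixes

    K = np.asarray(thresholds, dtype=float)[:, None]  # prefix of sig1
    n = np.asarray(thresholds, dtype=float)[None, :]  # prefix of sig2
    mean = K * n / N
    upper = hypergeom.sf(k - 1, N, K, n)
    lower = hypergeom.cdf(k, N, K, n)
    nlp_upper = -np.log10(np.clip(upper, p_floor, 1.0))
    nlp_lower = -np.log10(np.clip(lower, p_floor, 1.0))
    signed = np.where(k > mean, nlp_upper, -nlp_lower)

    # values[j, i] indexes (y threshold j, x threshold i)
    return RRHOMap(
        step=step,
        thresholds_x=thresholds,
        thresholds_y=thresholds,
        values=signed.T,
        x_order=tuple(order1),
        y_order=tuple(order2),
    )


def render_rrho(
    rrho: RRHOMap,
    path: str | Path,
    palette: str = "RdBu_r",
    dpi: int = 150,
    bare: bool = False,
) -> None:
    """Write a deterministic PNG heatmap of the grid.

    Diverging palette centered at 0; ``bare=True`` draws only the colored
    matrix (no axes/colorbar).  Identical maps yield byte-identical files.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    vmax = float(np.max(np.abs(rrho.values)))
    if vmax == 0.0:
        vmax = 1.0
    fig, ax = plt.subplots(figsize=(4.5, 4.0))
    im = ax.imshow(
        rrho.values,
        cmap=palette,
        vmin=-vmax,
        vmax=vmax,
        origin="lower",
        aspect="auto",
        interpolation="nearest",
        extent=(0, rrho.thresholds_x[-1], 0, rrho.thresholds_y[-1]),
    )
    if bare:
        ax.set_axis_off()
        fig.savefig(path, dpi=dpi, bbox_inches="tight", pad_inches=0, metadata={})
    else:
        ax.set_xlabel("rank threshold (x signature, up first)")
        ax.set_ylabel("rank threshold (y signature, up first)")
        fig.colorbar(im, ax=ax, label="signed -log10 p")
        fig.tight_layout()
        fig.savefig(path, dpi=dpi, metadata={})
    plt.close(fig)
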