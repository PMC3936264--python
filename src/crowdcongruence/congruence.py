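"""Rank-correlation congruence indexes, computed from first principles.

Congruence between the crowdsourced hospital ranking and the official
government ranking of a district is measured with Kendall's tau and
Spearman's rho.  Both are implemented directly — tau from explicit
concordant/discordant/tied pair counts, rho as the Pearson correlation of
the (average-tie) rank vectors — rather than delegated, because the pair
bookkeeping is the quantity of interest; library routines serve as
independent oracles in the test suite.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    import pandas as pd
    from .ranking import RankingPair

__all__ = [
    "PairCounts",
    "CongruenceResult",
    "count_pairs",
    "kendall_tau",
    "spearman_rho",
    "congruence_table",
]


@dataclass(frozen=True)
class PairCounts:
    """Classification of all n(n-1)/2 unordered index pairs of two equal
    length vectors: concordant, discordant, tied in x only, tied in y only,
    tied in both."""

    concordant: int
    discordant: int
    tied_x: int
    tied_y: int
    tied_both: int
    n: int

    @property
    def n0(self) -> int:
        return self.n * (self.n - 1) // 2

    @property
    def ties_x_total(self) -> int:
        """Pairs tied in x (whether or not also tied in y)."""
        return self.tied_x + self.tied_both

    @property
    def ties_y_total(self) -> int:
        return self.tied_y + self.tied_both


@dataclass(frozen=True)
class CongruenceResult:
    district_id: str
    kendall_tau: float
    spearman_rho: float
    n: int


def _as_vectors(x: Sequence[float], y: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.ndim != 1 or yv.ndim != 1:
        raise ValueError("rank vectors must be one-dimensional")
    if xv.shape != yv.shape:
        raise ValueError(f"length mismatch: {xv.shape[0]} vs {yv.shape[0]}")
    if xv.shape[0] < 2:
        raise ValueError("need at least two items to compare rankings")
    return xv, yv


def count_pairs(x: Sequence[float], y: Sequence[float]) -> PairCounts:
    """Classify every unordered pair of observations.

    A pair (i, j) is concordant when x and y order it the same way,
    discordant when they order it oppositely, and tied when either
    coordinate is equal.
    """
    xv, yv = _as_vectors(x, y)
    # pairwise sign comparison; n is small (districts have tens of clinics)
    dx = np.sign(xv[:, None] - xv[None, :])
    dy = np.sign(yv[:, None] - yv[None, :])
    iu = np.triu_indices(len(xv), k=1)
    sx, sy = dx[iu], dy[iu]
    concordant = int(np.sum((sx * sy) > 0))
    discordant = int(np.sum((sx * sy) < 0))
    tied_both = int(np.sum((sx == 0) & (sy == 0)))
    tied_x = int(np.sum((sx == 0) & (sy != 0)))
    tied_y = int(np.sum((sx != 0) & (sy == 0)))
    return PairCounts(concordant, discordant, tied_x, tied_y, tied_both, len(xv))


def kendall_tau(
    x: Sequence[float], y: Sequence[float], variant: str = "b"
) -> float:
    """Kendall rank correlation from pair counts.

    ``variant="b"`` (default) corrects the denominator for ties,
    (C - D) / sqrt((n0 - Tx)(n0 - Ty)); ``variant="a"`` uses the plain
    (C - D) / n0.  Both coincide on tie-free vectors.  Returns NaN (with a
    warning) when the tau-b denominator vanishes, i.e. a vector is
    constant.
    """
    if variant not in ("a", "b"):
        raise ValueError(f"variant must be 'a' or 'b', got {variant!r}")
    pc = count_pairs(x, y)
    num = pc.concordant - pc.discordant
    if variant == "a":
        return num / pc.n0
    denom = (pc.n0 - pc.ties_x_total) * (pc.n0 - pc.ties_y_total)
    if denom == 0:
        warnings.warn(
            "kendall tau-b undefined for a constant rank vector; returning NaN",
            stacklevel=2,
        )
        return math.nan
    return num / math.sqrt(denom)


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation: Pearson product-moment correlation of the
    rank vectors (callers supply average ranks for ties).  Returns NaN with
    a warning when either vector has zero variance."""
    xv, yv = _as_vectors(x, y)
    xc = xv - xv.mean()
    yc = yv - yv.mean()
    sx = float(np.sqrt(np.sum(xc**2)))
    sy = float(np.sqrt(np.sum(yc**2)))
    if sx == 0.0 or sy == 0.0:
        warnings.warn(
            "spearman rho undefined for a zero-variance rank vector; returning NaN",
            stacklevel=2,
        )
        return math.nan
    # identical / exactly reversed rankings hit the bounds exactly
    if np.array_equal(xc, yc):
        return 1.0
    if np.array_equal(xc, -yc):
        return -1.0
    return float(np.clip(np.sum(xc * yc) / (sx * sy), -1.0, 1.0))


def congruence_table(
    pairs: Sequence["RankingPair"], tau_variant: str = "b"
) -> "pd.DataFrame":
    """Per-district congruence table: n, tau, rho, and the descending rank
    of each index across districts (competition ranking, so equal values
    share the better rank).  Excluded districts (too few commonly ranked
    clinics) are skipped."""
    import pandas as pd
    from scipy.stats import rankdata

    rows = []
    for p in pairs:
        if p.excluded:
            continue
        tau = kendall_tau(p.crowd_rank, p.gov_rank, variant=tau_variant)
        rho = spearman_rho(p.crowd_rank, p.gov_rank)
        rows.append(
            {
                "district_id": p.district_id,
                "n": p.n,
                "kendall_tau": tau,
                "spearman_rho": rho,
            }
        )
    df = pd.DataFrame(rows, columns=["district_id", "n", "kendall_tau", "spearman_rho"])
    if len(df):
        for col, rank_col in (
            ("kendall_tau", "tau_rank"),
            ("spearman_rho", "rho_rank"),
        ):
            vals = df[col].to_numpy()
            ranks = np.full(len(vals), np.nan)
            ok = ~np.isnan(vals)
            if ok.any():
                ranks[ok] = rankdata(-vals[ok], method="min")
            df[rank_col] = ranks
    else:
        df["tau_rank"] = []
        df["rho_rank"] = []
    return df[
        ["district_id", "n", "kendall_tau", "tau_rank", "spearman_rho", "rho_rank"]
    ]
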