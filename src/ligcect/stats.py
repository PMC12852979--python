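"""Paired comparisons and correlation screening.

Group differences use the exact Wilcoxon signed-rank test (the null
distribution of the positive-rank sum is computed by dynamic programming
over sign assignments, conditional on the observed ranks, which matches
full 2^n enumeration); associations use Spearman's rank correlation with an
exact permutation p-value at small n and the t-approximation otherwise.
Ties receive average (mid) ranks in both tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import ValidationError
from .mechanics import DAMAGE_PARAMETER_NAMES

ALPHA = 0.05
WILCOXON_EXACT_MAX_N = 25
SPEARMAN_EXACT_MAX_N = 8


@dataclass
class PairedComparison:
    parameter: str
    control: np.ndarray
    damaged: np.ndarray
    W: float
    p_value: float
    n: int
    underpowered: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.p_value <= 1.0:
            raise ValidationError("p-value must lie in (0, 1]")


@dataclass
class CorrelationResult:
    x: str
    y: str
    rho: float
    p_value: float
    n: int
    pooling: str = "pooled"
    significant: bool = False

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.rho <= 1.0 + 1e-12:
            raise ValidationError("rho must lie in [-1, 1]")


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank, exact by rank-sum DP
# ---------------------------------------------------------------------------

def _signed_rank_statistic(diffs: np.ndarray) -> tuple[float, np.ndarray]:
    """Positive-rank sum W+ and the mid-ranks of |d| (zeros already dropped)."""
    ranks = sps.rankdata(np.abs(diffs))
    w_plus = float(ranks[diffs > 0].sum())
    return w_plus, ranks


def _wplus_null_distribution(ranks: np.ndarray) -> tuple[np.ndarray, int]:
    """Exact null pmf of 2*W+ over all 2^n sign assignments (DP convolution).

    Mid-ranks are half-integers at worst, so doubling makes them integers;
    returns (counts over 2*W+ = 0..2*sum, n).
    """
    r2 = np.rint(2.0 * ranks).astype(np.int64)
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    for r in r2:
        counts[r:] += counts[: counts.size - r].copy()
    return counts, len(ranks)


def wilcoxon_exact_p(diffs: np.ndarray) -> tuple[float, float]:
    """Two-sided exact p for the signed-rank test: (W+, p).

    p = min(1, 2 * min(P(W+ <= w), P(W+ >= w))) under the sign-flip null,
    conditional on the observed mid-ranks.
    """
    w_plus, ranks = _signed_rank_statistic(diffs)
    counts, _ = _wplus_null_distribution(ranks)
    w2 = int(np.rint(2.0 * w_plus))
    total = counts.sum()
    p_lo = counts[: w2 + 1].sum() / total
    p_hi = counts[w2:].sum() / total
    return w_plus, float(min(1.0, 2.0 * min(p_lo, p_hi)))


def wilcoxon_signed_rank(
    x: Sequence[float],
    y: Sequence[float] | None = None,
    parameter: str = "",
) -> PairedComparison:
    """Exact two-sided Wilcoxon signed-rank test on paired data.

    ``x`` and ``y`` are the paired measurements (or ``x`` the differences if
    ``y`` is omitted).  Zero differences are dropped; ties in |d| get average
    ranks.  Exact enumeration is used up to n = 25 non-zero differences and a
    tie-corrected normal approximation beyond; fewer than 5 non-zero
    differences flags the comparison as underpowered.
    """
    x = np.asarray(x, dtype=float)
    if y is None:
        diffs, ctrl, dmg = x, x, np.zeros_like(x)
    else:
        y = np.asarray(y, dtype=float)
        if x.shape != y.shape:
            raise ValidationError("paired vectors must have equal length")
        diffs, ctrl, dmg = x - y, x, y
    diffs = diffs[diffs != 0]
    n = diffs.size
    if n == 0:
        raise ValidationError("all paired differences are zero")
    if n <= WILCOXON_EXACT_MAX_N:
        w_plus, p = wilcoxon_exact_p(diffs)
    else:
        res = sps.wilcoxon(diffs, correction=True, mode="approx")
        w_plus = float(sps.rankdata(np.abs(diffs))[diffs > 0].sum())
        p = float(res.pvalue)
    return PairedComparison(
        parameter=parameter, control=ctrl, damaged=dmg,
        W=w_plus, p_value=max(p, np.finfo(float).tiny), n=int(n),
        underpowered=n < 5,
    )


# ---------------------------------------------------------------------------
# Spearman rank correlation
# ---------------------------------------------------------------------------

def _rank_corr(rx: np.ndarray, ry: np.ndarray) -> float:
    """Pearson correlation of rank vectors (handles ties via mid-ranks)."""
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx**2).sum() * (ry**2).sum())
    if denom == 0:
        raise ValidationError("constant input vector")
    return float((rx * ry).sum() / denom)


def spearman_correlation(
    x: Sequence[float],
    y: Sequence[float],
    *,
    x_name: str = "x",
    y_name: str = "y",
    pooling: str = "pooled",
    alpha: float = ALPHA,
) -> CorrelationResult:
    """Spearman rho with an exact permutation p for n <= 8.

    The exact two-sided p enumerates all n! permutations of one rank vector
    (conditional on observed ranks, so ties are handled consistently);
    larger samples use the t-approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("vectors must have equal length")
    n = x.size
    if n < 4:
        raise ValidationError(f"need n >= 4, got {n}")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = _rank_corr(rx, ry)
    if n <= SPEARMAN_EXACT_MAX_N:
        perms = np.array(list(permutations(ry)))
        rxc = rx - rx.mean()
        pc = perms - ry.mean()
        denom = np.sqrt((rxc**2).sum() * (pc[0] ** 2).sum())
        rhos = pc @ rxc / denom
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    else:
        if abs(rho) >= 1.0:
            p = np.finfo(float).tiny
        else:
            t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
            p = float(2.0 * sps.t.sf(abs(t), df=n - 2))
    p = max(p, np.finfo(float).tiny)
    return CorrelationResult(
        x=x_name, y=y_name, rho=rho, p_value=p, n=int(n),
        pooling=pooling, significant=p < alpha,
    )


# ---------------------------------------------------------------------------
# correlation screen
# ---------------------------------------------------------------------------

def correlation_screen(
    biomech: pd.DataFrame,
    cect: pd.DataFrame,
    *,
    damage_parameters: Iterable[str] = DAMAGE_PARAMETER_NAMES,
    uptake_parameters: tuple[str, ...] = ("Pmax", "tau_h"),
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Screen every biomechanical parameter against the uptake parameters.

    ``biomech`` is keyed by (ligament_id, group) with one column per
    parameter; ``cect`` is keyed by (ligament_id, group, agent) with Pmax and
    tau_h columns.  Control and damaged rows are pooled except for the
    damage-specific parameters, which exist only for the damaged group and
    are correlated damaged-only.  Returns one row per parameter x uptake
    parameter x agent with rho, p and a significance flag at ``alpha``.
    """
    damage_parameters = set(damage_parameters)
    key = ["ligament_id", "group"]
    for df, name in ((biomech, "biomech"), (cect, "cect")):
        missing = set(key) - set(df.columns)
        if missing:
            raise ValidationError(f"{name} table lacks key column(s) {sorted(missing)}")
    merged = biomech.merge(cect, on=key, how="inner")
    if merged.empty:
        raise ValidationError("no common (ligament_id, group) keys between tables")
    param_cols = [
        c for c in biomech.columns
        if c not in key and pd.api.types.is_numeric_dtype(biomech[c])
    ]
    out = []
    for agent, sub_all in merged.groupby("agent", sort=True):
        for param in param_cols:
            damage_only = param in damage_parameters
            sub = sub_all[sub_all["group"] == "damaged"] if damage_only else sub_all
            for upt in uptake_parameters:
                pair = sub[[param, upt]].dropna()
                if len(pair) < 4:
                    continue
                res = spearman_correlation(
                    pair[param].to_numpy(), pair[upt].to_numpy(),
                    x_name=param, y_name=f"{upt}[{agent}]",
                    pooling="damaged-only" if damage_only else "pooled",
                    alpha=alpha,
                )
                out.append(
                    {
                        "parameter": param, "uptake": upt, "agent": agent,
                        "rho": res.rho, "p_value": res.p_value, "n": res.n,
                        "pooling": res.pooling, "significant": res.significant,
                    }
                )
    return pd.DataFrame(out)


__all__ = [
    "ALPHA",
    "CorrelationResult",
    "PairedComparison",
    "correlation_screen",
    "spearman_correlation",
    "wilcoxon_exact_p",
    "wilcoxon_signed_rank",
]
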