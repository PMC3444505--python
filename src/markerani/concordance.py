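"""Agreement statistics between gene-level and genome-level ANI.

Given matched vectors of genome ANI (x) and gene/concatenate ANI (y) over the
same strain pairs: Pearson and Spearman correlations, linear and quadratic
least-squares fits with overall F tests, the extra sum-of-squares comparison
of the nested fits, and the 2-D region tally of the delimitation scatter.

Correlations and fits are computed from the product-moment, average-rank and
normal-equation formulas directly; only F-distribution tail areas come from
scipy. P-values below 1e-4 are additionally formatted as "<0.0001" to match
the conventional reporting style.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as _sps

from .screen import ThresholdConfig

__all__ = [
    "CorrelationResult",
    "FitResult",
    "ModelComparison",
    "correlations",
    "fit_polynomial",
    "extra_ss_test",
    "region_tally",
    "format_p",
]

P_FLOOR = 1e-4


def format_p(p: float) -> str:
    return "<0.0001" if p < P_FLOOR else f"{p:.4g}"


@dataclass(frozen=True)
class CorrelationResult:
    pearson_r: float
    spearman_rho: float
    n: int


@dataclass(frozen=True)
class FitResult:
    model: str  # linear | quadratic
    coefficients: tuple[float, ...]  # (intercept, b1[, b2])
    r_squared: float
    sse: float
    df_residual: int
    f_overall: float
    p_overall: float

    @property
    def n(self) -> int:
        return self.df_residual + len(self.coefficients)


@dataclass(frozen=True)
class ModelComparison:
    f_extra: float
    df: tuple[int, int]
    p_value: float
    better: str  # linear | quadratic
    infinite_f: bool = False


def _as_vec(v: Sequence[float]) -> np.ndarray:
    arr = np.asarray(v, dtype=float)
    if arr.ndim != 1:
        raise ValueError("expected a 1-D vector")
    return arr


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt((xc * xc).sum())
    sy = np.sqrt((yc * yc).sum())
    if sx == 0.0 or sy == 0.0:
        raise ValueError("zero variance: correlation undefined")
    return float((xc * yc).sum() / (sx * sy))


def _average_ranks(v: np.ndarray) -> np.ndarray:
    """Ranks 1..n with ties sharing their mean rank."""
    order = np.argsort(v, kind="mergesort")
    ranks = np.empty(len(v), dtype=float)
    sv = v[order]
    i = 0
    while i < len(sv):
        j = i
        while j + 1 < len(sv) and sv[j + 1] == sv[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def correlations(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson (product-moment) and Spearman (rank Pearson) correlations."""
    xv, yv = _as_vec(x), _as_vec(y)
    if len(xv) != len(yv):
        raise ValueError("vectors differ in length")
    if len(xv) < 3:
        raise ValueError("need n >= 3")
    return CorrelationResult(
        pearson_r=_pearson(xv, yv),
        spearman_rho=_pearson(_average_ranks(xv), _average_ranks(yv)),
        n=len(xv),
    )


def fit_polynomial(x: Sequence[float], y: Sequence[float], degree: int) -> FitResult:
    """Least-squares polynomial fit (degree 1 or 2) with the overall F test.

    R^2 = 1 - SSE/SST about the mean; F_overall = (SSR/p) / (SSE/(n-p-1))
    with p regression terms, tested against F(p, n-p-1).
    """
    if degree not in (1, 2):
        raise ValueError("degree must be 1 or 2")
    xv, yv = _as_vec(x), _as_vec(y)
    n = len(xv)
    if len(yv) != n:
        raise ValueError("vectors differ in length")
    if n <= degree + 1:
        raise ValueError("need n > degree + 1")
    X = np.vander(xv, degree + 1, increasing=True)
    if np.linalg.matrix_rank(X) < degree + 1:
        raise ValueError("rank-deficient design (degenerate x values)")
    beta, *_ = np.linalg.lstsq(X, yv, rcond=None)
    resid = yv - X @ beta
    sse = float(resid @ resid)
    sst = float(((yv - yv.mean()) ** 2).sum())
    ssr = sst - sse
    p = degree
    df_resid = n - p - 1
    r_squared = 1.0 - sse / sst if sst > 0 else 1.0
    if sse > 0:
        f_overall = (ssr / p) / (sse / df_resid)
        p_overall = float(_sps.f.sf(f_overall, p, df_resid))
    else:
        f_overall, p_overall = float("inf"), 0.0
    return FitResult(
        model="linear" if degree == 1 else "quadratic",
        coefficients=tuple(float(b) for b in beta),
        r_squared=float(np.clip(r_squared, 0.0, 1.0)),
        sse=sse,
        df_residual=df_resid,
        f_overall=float(f_overall),
        p_overall=p_overall,
    )


def extra_ss_test(
    fit_lin: FitResult, fit_quad: FitResult, alpha: float = 0.05
) -> ModelComparison:
    """Extra sum-of-squares F test for quadratic vs linear on the same data.

    F = ((SSE_lin - SSE_quad)/1) / (SSE_quad/(n-3)) with df (1, n-3). A
    perfect quadratic fit (SSE_quad = 0) is reported as infinite F with the
    p = 0 convention flagged.
    """
    if fit_lin.model != "linear" or fit_quad.model != "quadratic":
        raise ValueError("pass (linear fit, quadratic fit)")
    if fit_lin.n != fit_quad.n:
        raise ValueError("fits are not over the same data")
    n = fit_quad.n
    df2 = n - 3
    # SSE from a numerically exact fit comes back as rounding dust, not 0
    tol = 1e-12 * max(fit_lin.sse, 1.0)
    if fit_quad.sse <= tol:
        if fit_lin.sse <= tol:
            return ModelComparison(0.0, (1, df2), 1.0, "linear")
        return ModelComparison(float("inf"), (1, df2), 0.0, "quadratic", infinite_f=True)
    f_extra = max(0.0, (fit_lin.sse - fit_quad.sse) / (fit_quad.sse / df2))
    p = float(_sps.f.sf(f_extra, 1, df2))
    return ModelComparison(
        f_extra=float(f_extra),
        df=(1, df2),
        p_value=p,
        better="quadratic" if p < alpha else "linear",
    )


def region_tally(
    anim: Sequence[float],
    anistt: Sequence[float],
    cfg: ThresholdConfig | None = None,
) -> dict:
    """Count pairs in the strict 2-D inter/intra regions and between them.

    Inter region: ANIm < 93 and ANIstt < 94; intra region: ANIm > 95 and
    ANIstt > 96. Everything else — including pairs sitting exactly on a
    boundary — is "between". The three counts always sum to the total.
    """
    cfg = cfg or ThresholdConfig()
    xv, yv = _as_vec(anim), _as_vec(anistt)
    if len(xv) != len(yv):
        raise ValueError("vectors differ in length")
    inter = int(((xv < cfg.region_genome_low) & (yv < cfg.inter_ceiling)).sum())
    intra = int(((xv > cfg.region_genome_high) & (yv > cfg.intra_floor)).sum())
    total = len(xv)
    return {
        "n_intra_region": intra,
        "n_inter_region": inter,
        "n_between": total - intra - inter,
        "total": total,
    }
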