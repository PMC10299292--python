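"""Linear association of candidate genes with clinical endpoints (MMSE, NFT).

Candidates are ranked by ordinary least squares fit quality, MMSE R^2 first.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from coherence_screen.dataio import DataIOError, ExpressionMatrix, PhenotypeTable

logger = logging.getLogger(__name__)

ENDPOINTS = ("mmse", "nft")


@dataclass(frozen=True)
class LinearFitResult:
    """Simple OLS fit of a clinical score on one gene's expression."""

    gene_id: str
    endpoint: str
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int

    def __post_init__(self) -> None:
        if self.endpoint not in ENDPOINTS:
            raise ValueError(f"unknown endpoint '{self.endpoint}'")
        if not (-1e-12 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError(f"r_squared {self.r_squared} outside [0, 1]")
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"p_value {self.p_value} outside (0, 1]")
        if self.n < 3:
            raise ValueError("fit needs n >= 3")


def linear_fit(
    x: Sequence[float],
    y: Sequence[float],
    gene_id: str = "",
    endpoint: str = "mmse",
) -> LinearFitResult:
    """Closed-form OLS of y on x with slope t-test (n-2 df).

    Pairs with a missing (NaN) score are dropped (logged).  Constant x or
    fewer than 3 complete pairs is an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DataIOError("x and y must be 1-D arrays of equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("linear_fit(%s, %s): dropped %d incomplete pairs",
                    gene_id or "<x>", endpoint, dropped)
        x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise DataIOError(f"need >=3 complete pairs, got {n}")
    if np.ptp(x) == 0:
        raise DataIOError("x is constant; slope undefined")

    xm, ym = x.mean(), y.mean()
    sxx = float(((x - xm) ** 2).sum())
    sxy = float(((x - xm) * (y - ym)).sum())
    slope = sxy / sxx
    intercept = ym - slope * xm
    resid = y - (intercept + slope * x)
    sse = float((resid**2).sum())
    sst = float(((y - ym) ** 2).sum())
    r2 = 1.0 if sst == 0 else max(0.0, 1.0 - sse / sst)

    df = n - 2
    if sse <= 0:
        p = np.finfo(float).tiny
    else:
        se = np.sqrt(sse / df / sxx)
        t = slope / se
        p = float(2.0 * stats.t.sf(abs(t), df))
    return LinearFitResult(
        gene_id=gene_id, endpoint=endpoint, slope=float(slope),
        intercept=float(intercept), r_squared=float(min(r2, 1.0)),
        p_value=float(min(max(p, np.finfo(float).tiny), 1.0)), n=int(n),
    )


def rank_by_fit(
    candidates: Sequence[str],
    expr: ExpressionMatrix,
    phenotype: PhenotypeTable,
    case_only: bool = True,
) -> list[tuple[str, dict[str, LinearFitResult | None]]]:
    """Fit each candidate against MMSE and NFT and rank by fit quality.

    Sort key: MMSE R^2 descending, then NFT R^2 descending, then gene id.
    By default only case samples are used (controls lack meaningful
    pathology scores).  A candidate whose NFT fit is impossible (no scores)
    gets ``None`` for that endpoint and sorts last on the NFT key.
    """
    candidates = list(candidates)
    if not candidates:
        raise DataIOError("no candidate genes to rank")
    sample_ids = phenotype.case_ids if case_only else list(phenotype.sample_ids)
    mmse = phenotype.score_for(sample_ids, "mmse")
    nft = phenotype.score_for(sample_ids, "nft")
    if np.isfinite(mmse).sum() < 3:
        raise DataIOError("need MMSE for >=3 samples to rank candidates")

    results: list[tuple[str, dict[str, LinearFitResult | None]]] = []
    for gene in candidates:
        x = expr.gene_values(gene, sample_ids)
        fits: dict[str, LinearFitResult | None] = {}
        fits["mmse"] = linear_fit(x, mmse, gene_id=gene, endpoint="mmse")
        try:
            fits["nft"] = linear_fit(x, nft, gene_id=gene, endpoint="nft")
        except DataIOError:
            fits["nft"] = None
        results.append((gene, fits))

    def key(item: tuple[str, dict[str, LinearFitResult | None]]):
        gene, fits = item
        m = fits["mmse"].r_squared if fits["mmse"] else -1.0
        f = fits["nft"].r_squared if fits["nft"] else -1.0
        return (-m, -f, gene)

    results.sort(key=key)
    return results
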