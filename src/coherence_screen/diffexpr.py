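"""Dual differential-expression screen.

Two complementary contrasts feed the screen: case vs control over all
samples, and anchor-high vs anchor-low within the case group (split at the
anchor gene's median expression).  Each contrast yields per-gene log2 fold
changes and p-values; genes passing ``|log2FC| > 0.3 and p < 0.05`` in both
contrasts form the anchor-related gene set.

The default test is Welch's t.  A moderated-t mode shrinks per-gene pooled
variances toward their grand mean with a configurable prior df, an
empirical-Bayes approximation for small sample sizes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from coherence_screen.dataio import DataIOError, ExpressionMatrix

EPS_P = np.finfo(float).tiny  # p-value floor for zero-variance exact shifts


@dataclass(frozen=True)
class DEGRecord:
    """Per-gene differential expression result.

    ``log2fc`` is mean(group A) - mean(group B) on the log2 scale;
    ``direction`` is "up"/"down" by its sign ("none" at exactly 0).
    """

    gene_id: str
    log2fc: float
    p_value: float
    direction: str

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"p_value {self.p_value} outside (0, 1]")
        expected = "up" if self.log2fc > 0 else ("down" if self.log2fc < 0 else "none")
        if self.direction != expected:
            raise ValueError(
                f"direction '{self.direction}' inconsistent with log2fc {self.log2fc}"
            )


@dataclass(frozen=True)
class GeneSetPartition:
    """Filtered DEG set, partitioned by direction; preserves input gene order."""

    up: list[str]
    down: list[str]

    @property
    def genes(self) -> list[str]:
        return self.up + self.down

    def __len__(self) -> int:
        return len(self.up) + len(self.down)


def _direction(lfc: float) -> str:
    return "up" if lfc > 0 else ("down" if lfc < 0 else "none")


def two_group_test(
    expr: ExpressionMatrix,
    labels: Sequence[str],
    group_a: str = "case",
    group_b: str = "control",
    method: str = "welch",
    prior_df: float = 4.0,
) -> list[DEGRecord]:
    """Per-gene two-group comparison; log2fc = mean(A) - mean(B).

    Parameters
    ----------
    labels : one label per sample column of ``expr``.
    method : "welch" (default) or "moderated" (EB-shrunk pooled variance).
    prior_df : prior degrees of freedom for the moderated mode.
    """
    labels = np.asarray([str(l) for l in labels])
    if len(labels) != expr.n_samples:
        raise DataIOError(
            f"{len(labels)} labels for {expr.n_samples} samples"
        )
    a_mask = labels == group_a
    b_mask = labels == group_b
    if not (a_mask | b_mask).all():
        extra = sorted(set(labels) - {group_a, group_b})
        raise DataIOError(f"labels contain unknown groups: {extra}")
    na, nb = int(a_mask.sum()), int(b_mask.sum())
    if na < 2 or nb < 2:
        raise DataIOError(
            f"each group needs >=2 samples (got {group_a}={na}, {group_b}={nb})"
        )
    xa = expr.values[:, a_mask]
    xb = expr.values[:, b_mask]
    mean_a = xa.mean(axis=1)
    mean_b = xb.mean(axis=1)
    lfc = mean_a - mean_b
    var_a = xa.var(axis=1, ddof=1)
    var_b = xb.var(axis=1, ddof=1)

    if method == "welch":
        se2 = var_a / na + var_b / nb
        with np.errstate(divide="ignore", invalid="ignore"):
            t = lfc / np.sqrt(se2)
            df = se2**2 / (
                (var_a / na) ** 2 / (na - 1) + (var_b / nb) ** 2 / (nb - 1)
            )
        p = 2.0 * stats.t.sf(np.abs(t), df)
    elif method == "moderated":
        # pooled per-gene variance shrunk toward the grand mean variance
        df_resid = na + nb - 2
        s2 = ((na - 1) * var_a + (nb - 1) * var_b) / df_resid
        positive = s2 > 0
        s2_prior = float(s2[positive].mean()) if positive.any() else 0.0
        s2_post = (prior_df * s2_prior + df_resid * s2) / (prior_df + df_resid)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = lfc / np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
        p = 2.0 * stats.t.sf(np.abs(t), df_resid + prior_df)
    else:
        raise ValueError(f"unknown test method '{method}'")

    # zero within-group variance: exact shift -> floor p; identical constants -> p=1
    degenerate = ~np.isfinite(p)
    p = np.where(degenerate & (lfc != 0), EPS_P, p)
    p = np.where(degenerate & (lfc == 0), 1.0, p)
    p = np.clip(p, EPS_P, 1.0)

    return [
        DEGRecord(g, float(f), float(pv), _direction(float(f)))
        for g, f, pv in zip(expr.gene_ids, lfc, p)
    ]


def adjust_bh(records: Sequence[DEGRecord]) -> list[DEGRecord]:
    """Return records with Benjamini-Hochberg adjusted p-values."""
    p = np.array([r.p_value for r in records])
    adj = stats.false_discovery_control(p, method="bh")
    adj = np.clip(adj, EPS_P, 1.0)
    return [
        DEGRecord(r.gene_id, r.log2fc, float(q), r.direction)
        for r, q in zip(records, adj)
    ]


def filter_degs(
    records: Sequence[DEGRecord],
    lfc_min: float = 0.3,
    p_max: float = 0.05,
) -> GeneSetPartition:
    """Keep genes with ``|log2fc| > lfc_min`` AND ``p < p_max`` (both strict)."""
    if lfc_min <= 0 or p_max <= 0:
        raise ValueError("thresholds must be > 0")
    up = [r.gene_id for r in records if r.log2fc > lfc_min and r.p_value < p_max]
    down = [r.gene_id for r in records if r.log2fc < -lfc_min and r.p_value < p_max]
    return GeneSetPartition(up=up, down=down)


def median_split(
    expr: ExpressionMatrix,
    anchor: str,
    samples: Sequence[str],
) -> dict[str, str]:
    """Split ``samples`` into anchor-high/low at the anchor's median expression.

    Samples strictly above the median go to "high"; samples at or below it go
    to "low" (deterministic tie rule).  Both sides are guaranteed non-empty.
    """
    samples = list(samples)
    if len(samples) < 4:
        raise DataIOError(f"median split needs >=4 samples, got {len(samples)}")
    x = expr.gene_values(anchor, samples)
    if np.ptp(x) == 0:
        raise DataIOError(
            f"anchor '{anchor}' is constant over the given samples; split undefined"
        )
    med = float(np.median(x))
    assignment = {s: ("high" if v > med else "low") for s, v in zip(samples, x)}
    if "high" not in assignment.values() or "low" not in assignment.values():
        # median equal to the max: push strictly-below-median samples to low
        # and the rest to high so both sides are populated
        assignment = {s: ("low" if v < med else "high") for s, v in zip(samples, x)}
    return assignment


def intersect_gene_sets(a: Sequence[str], b: Sequence[str]) -> list[str]:
    """Exact set intersection, ordered as in ``a``."""
    b_set = set(b)
    seen: set[str] = set()
    out = []
    for g in a:
        if g in b_set and g not in seen:
            out.append(g)
            seen.add(g)
    return out
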