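"""Per-sample gene-set variation scores and AR-based patient stratification.

The enrichment score follows the single-sample kernel-CDF / weighted
Kolmogorov-Smirnov construction: for each gene a Gaussian-kernel estimate
of the expression CDF across samples (bandwidth = per-gene SD / 4) yields a
sample-level statistic; genes are ranked by it within each sample and a
weighted random walk over the ranking produces the score as the difference
between the largest positive and largest negative running-sum deviations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSetCollection",
    "ScoreTable",
    "gsva_enrichment",
    "rescale_scores",
    "ar_activity",
    "stratify_ar_gly",
]

AR_LOW_GLY_HIGH = "AR_low_Gly_high"
OTHER = "other"


@dataclass
class GeneSetCollection:
    """Named gene sets with optional per-set descriptions."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if len(set(members)) != len(members):
                raise ValueError(f"gene set {name!r} has duplicate members")

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)


@dataclass
class ScoreTable:
    """Per-sample signature scores.

    ``scores`` is samples x signatures; ``scale`` is one of ``raw``,
    ``percent_0_100`` or ``unit_0_1``.
    """

    scores: pd.DataFrame
    scale: str = "raw"

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.index)

    def __getitem__(self, signature: str) -> pd.Series:
        return self.scores[signature]


def _kernel_cdf_statistic(values: np.ndarray) -> np.ndarray:
    """Gaussian-kernel CDF estimate per gene, bandwidth = sd/4.

    ``values`` is genes x samples; the returned statistic is the mean over
    reference samples k of Phi((x_j - x_k) / h). Affine-invariant per gene
    because h scales with the per-gene SD.
    """
    sd = values.std(axis=1, ddof=1)
    h = sd / 4.0
    out = np.empty_like(values)
    # chunk over genes to bound the (chunk, n, n) broadcast at ~64 MB
    n = values.shape[1]
    chunk = max(1, int(8e6 // (n * n)))
    for start in range(0, values.shape[0], chunk):
        block = values[start : start + chunk]
        hb = h[start : start + chunk, None, None]
        diffs = (block[:, :, None] - block[:, None, :]) / hb
        out[start : start + chunk] = ndtr(diffs).mean(axis=2)
    return out


def gsva_enrichment(
    expr: pd.DataFrame,
    sets: GeneSetCollection,
    weight_exponent: float = 1.0,
) -> ScoreTable:
    """Single-sample enrichment scores for each gene set.

    Parameters
    ----------
    expr
        Genes x samples expression matrix (log scale).
    sets
        Gene sets to score; every set must overlap the matrix in at least
        two genes after dropping zero-variance genes.
    weight_exponent
        Exponent on the symmetric rank statistic in the random walk.

    Returns
    -------
    ScoreTable with raw scores in (-1, 1), samples x signatures.
    """
    if expr.shape[1] < 2:
        raise ValueError("gsva_enrichment requires at least 2 samples")
    variances = expr.var(axis=1, ddof=1)
    keep = variances > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("dropping %d zero-variance genes before enrichment", n_dropped)
    mat = expr.loc[keep]
    gene_index = pd.Index(mat.index)
    p = len(gene_index)

    set_masks: dict[str, np.ndarray] = {}
    for name, members in sets.sets.items():
        if not members:
            raise ValueError(f"gene set {name!r} is empty")
        present = gene_index.isin(members)
        n_match = int(present.sum())
        if n_match < len(members):
            warnings.warn(
                f"gene set {name!r}: {n_match}/{len(members)} genes matched the "
                "expression matrix",
                stacklevel=2,
            )
        if n_match < 1:
            raise ValueError(
                f"gene set {name!r} has no usable genes after zero-variance filtering"
            )
        if n_match < 2:
            warnings.warn(
                f"gene set {name!r} reduces to a single usable gene", stacklevel=2
            )
        if n_match == p:
            raise ValueError(f"gene set {name!r} covers the whole gene universe")
        set_masks[name] = present

    z = _kernel_cdf_statistic(mat.to_numpy(dtype=float))

    # deterministic ordering: decreasing statistic, gene id as tie-break
    gene_rank_key = np.argsort(gene_index.to_numpy())
    scores = np.empty((expr.shape[1], len(set_masks)))
    half_p = p / 2.0
    for j in range(expr.shape[1]):
        order = np.lexsort((gene_rank_key, -z[:, j]))
        ranks = np.empty(p)
        ranks[order] = np.arange(p, 1 - 1, -1)  # top gene gets rank p
        sym = np.abs(ranks - half_p) ** weight_exponent
        sym_ordered = sym[order]
        for si, (name, mask) in enumerate(set_masks.items()):
            in_set = mask[order]
            m = in_set.sum()
            step_up = np.where(in_set, sym_ordered, 0.0)
            denom_up = step_up.sum()
            if denom_up == 0:  # every set gene sits at the median rank
                step_up = in_set.astype(float)
                denom_up = float(m)
            walk = np.where(in_set, step_up / denom_up, -1.0 / (p - m))
            running = np.cumsum(walk)
            max_pos = max(running.max(), 0.0)
            max_neg = min(running.min(), 0.0)
            scores[j, si] = max_pos + max_neg
    return ScoreTable(
        pd.DataFrame(scores, index=expr.columns, columns=list(set_masks)),
        scale="raw",
    )


def rescale_scores(raw: ScoreTable, lo: float = 0.0, hi: float = 100.0) -> ScoreTable:
    """Min-max rescale each signature onto [lo, hi] within the cohort."""
    out = {}
    for sig in raw.scores.columns:
        vals = raw.scores[sig]
        vmin, vmax = vals.min(), vals.max()
        if vmax == vmin:
            raise ValueError(f"signature {sig!r}: constant scores, rescale undefined")
        out[sig] = lo + (vals - vmin) / (vmax - vmin) * (hi - lo)
    return ScoreTable(pd.DataFrame(out, index=raw.scores.index), scale="percent_0_100")


def ar_activity(expr: pd.DataFrame, ar_set: list[str]) -> ScoreTable:
    """AR pathway activity: per-gene z-scores summed, min-max scaled to [0,1]."""
    if expr.shape[1] < 2:
        raise ValueError("ar_activity requires at least 2 samples")
    present = [g for g in ar_set if g in expr.index]
    missing = set(ar_set) - set(present)
    if missing:
        warnings.warn(
            f"AR signature: {len(missing)} genes absent from matrix", stacklevel=2
        )
    sub = expr.loc[present]
    sd = sub.std(axis=1, ddof=0)
    zero_var = sd == 0
    if zero_var.any():
        warnings.warn(
            f"AR signature: dropping {int(zero_var.sum())} zero-variance genes",
            stacklevel=2,
        )
        sub = sub.loc[~zero_var]
        sd = sd[~zero_var]
    if sub.empty:
        raise ValueError("no usable AR signature genes (all missing or zero-variance)")
    zsums = ((sub.sub(sub.mean(axis=1), axis=0)).div(sd, axis=0)).sum(axis=0)
    lo, hi = zsums.min(), zsums.max()
    if hi == lo:
        raise ValueError("AR z-score sums are constant; scaling undefined")
    scaled = (zsums - lo) / (hi - lo)
    return ScoreTable(scaled.to_frame("ar_activity"), scale="unit_0_1")


def stratify_ar_gly(ar: ScoreTable, gly: ScoreTable, gly_signature: str | None = None) -> pd.Series:
    """Label samples AR_low_Gly_high (strictly below median AR and strictly
    above median glycolysis) or other."""
    ar_vals = ar.scores.iloc[:, 0]
    gly_vals = gly.scores[gly_signature] if gly_signature else gly.scores.iloc[:, 0]
    if set(ar_vals.index) != set(gly_vals.index):
        raise ValueError("AR and glycolysis score tables cover different samples")
    gly_vals = gly_vals.reindex(ar_vals.index)
    ar_med = ar_vals.median()
    gly_med = gly_vals.median()
    labels = np.where(
        (ar_vals < ar_med) & (gly_vals > gly_med), AR_LOW_GLY_HIGH, OTHER
    )
    return pd.Series(labels, index=ar_vals.index, name="stratum")
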