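"""Gene filtering ahead of network construction.

Two sequential filters select the network substrate: a detection filter
keeping genes with statistical evidence of expression in at least a given
fraction of strains, and a variance filter keeping the most varying genes.
"Most varying" is the highest sample variance on the normalized scale (the
input is assumed variance-stabilized), not the coefficient of variation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, asdict

from .data import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class FilterReport:
    """Gene counts before/after each filtering stage."""

    n_input: int
    n_detected: int | None = None
    n_selected: int | None = None

    def as_dict(self) -> dict:
        return asdict(self)


def detection_filter(
    expr: ExpressionMatrix, alpha: float = 0.01, min_fraction: float = 0.5
) -> ExpressionMatrix:
    """Keep genes detected (detection p < ``alpha``) in at least
    ``ceil(min_fraction × n_strains)`` strains.

    The strain set and the relative gene order are preserved.  An empty result
    is legal and only logged.
    """
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must lie in (0, 1]")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if expr.detection_p is None:
        raise ValueError("expression matrix carries no detection p-values")
    need = math.ceil(min_fraction * expr.n_strains)
    detected_counts = (expr.detection_p < alpha).sum(axis=1)
    keep = detected_counts >= need
    if not keep.any():
        logger.warning("detection filter removed every gene (alpha=%g)", alpha)
    logger.info("detection filter: %d of %d genes kept", int(keep.sum()), expr.n_genes)
    return expr.subset_genes(expr.values.index[keep])


def variance_filter(expr: ExpressionMatrix, top_k: int = 3600) -> ExpressionMatrix:
    """Keep the ``top_k`` genes with the highest sample variance across
    strains; ties broken by input order (stable sort).

    If ``top_k`` exceeds the gene count all genes are returned with a warning.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    if top_k >= expr.n_genes:
        if top_k > expr.n_genes:
            logger.warning(
                "variance filter asked for %d genes but only %d available",
                top_k, expr.n_genes,
            )
        return expr.subset_genes(expr.values.index)
    variances = expr.values.var(axis=1, ddof=1)
    # stable sort on negated variance keeps input order among ties
    order = (-variances.to_numpy()).argsort(kind="stable")[:top_k]
    keep_idx = sorted(order)  # preserve relative input order of the winners
    logger.info("variance filter: kept top %d of %d genes", top_k, expr.n_genes)
    return expr.subset_genes(expr.values.index[keep_idx])
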