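"""Module–trait association statistics.

Gene significance (GS) for a trait is the absolute Pearson correlation between
a gene's expression profile and the strain-level trait.  Module significance
(MS) is the mean GS over a module's genes; its p-value treats the MS magnitude
as a single correlation observed on n strains (two-sided t test with n − 2
degrees of freedom, the default behaviour of R's ``cor.test``; a Fisher
z-transform variant is available behind a flag).  The module eigengene — the
first principal component of the standardized module expression — offers an
alternative one-number-per-strain module summary.
"""

from __future__ import annotations

import logging
import sys

import numpy as np
import pandas as pd
from scipy import stats

from .data import ExpressionMatrix, TraitTable
from .network import ModuleAssignment

logger = logging.getLogger(__name__)


def average_replicates(replicates: pd.DataFrame) -> TraitTable:
    """Collapse mouse-level trait replicates to per-strain arithmetic means.

    Missing values are averaged over the available replicates; replicate
    counts per strain are logged.
    """
    if "strain" not in replicates.columns:
        raise ValueError("replicate table needs a 'strain' column")
    value_cols = [c for c in replicates.columns if c not in ("strain", "mouse_id")]
    grouped = replicates.groupby("strain", sort=False)
    counts = grouped.size()
    logger.info(
        "averaged replicates for %d strains (replicates per strain: %d–%d)",
        len(counts), int(counts.min()), int(counts.max()),
    )
    means = grouped[value_cols].mean()
    return TraitTable(means)


def _align(x: pd.Series, y: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    common = x.index.intersection(y.index)
    dropped = max(len(x), len(y)) - len(common)
    if dropped:
        logger.info("strain alignment dropped %d non-overlapping strains", dropped)
    if len(common) < 3:
        raise ValueError("need at least 3 common strains")
    return x.loc[common].to_numpy(float), y.loc[common].to_numpy(float)


def gene_significance(expr_row: pd.Series, trait_vector: pd.Series) -> float:
    """GS = |Pearson correlation| between a gene's expression and a trait,
    over the strains the two share.  Constant vectors give GS 0."""
    x, y = _align(expr_row, trait_vector)
    if np.std(x) == 0 or np.std(y) == 0:
        logger.warning("constant vector in gene significance; GS set to 0")
        return 0.0
    return float(abs(np.corrcoef(x, y)[0, 1]))


def gene_significance_table(
    expr: ExpressionMatrix, traits: TraitTable
) -> pd.DataFrame:
    """GS for every gene × trait pair (vectorized over genes)."""
    common = expr.values.columns.intersection(traits.values.index)
    if len(common) < 3:
        raise ValueError("need at least 3 common strains")
    X = expr.values[common].to_numpy(float)
    Xc = X - X.mean(axis=1, keepdims=True)
    xsd = Xc.std(axis=1, ddof=1)
    out = {}
    for trait in traits.trait_names:
        y = traits.values.loc[common, trait].to_numpy(float)
        yc = y - y.mean()
        ysd = yc.std(ddof=1)
        if ysd == 0:
            out[trait] = np.zeros(X.shape[0])
            continue
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (Xc @ yc) / ((len(common) - 1) * xsd * ysd)
        r[xsd == 0] = 0.0
        out[trait] = np.abs(np.clip(r, -1.0, 1.0))
    return pd.DataFrame(out, index=expr.values.index)


def module_significance(gs_values) -> float:
    """MS = arithmetic mean of GS over one module's genes."""
    gs = np.asarray(gs_values, dtype=float)
    if gs.size == 0:
        raise ValueError("module significance of an empty module is undefined")
    return float(gs.mean())


def ms_pvalue(ms_value: float, n_strains: int, method: str = "t") -> float:
    """Two-sided p-value for an MS (or correlation) magnitude on n strains.

    ``method='t'`` uses the correlation t test (``t = r√((n−2)/(1−r²))``
    against t with n − 2 df), matching ``cor.test``'s default; ``method='z'``
    uses the Fisher transform (``z = atanh(r)·√(n−3)`` against the standard
    normal).  An MS of exactly 1 reports the smallest positive float.
    """
    if not 0 <= ms_value <= 1:
        raise ValueError("MS must lie in [0, 1]")
    if n_strains < 4:
        raise ValueError("need at least 4 strains")
    r = float(ms_value)
    if r >= 1.0:
        return sys.float_info.min
    if method == "t":
        t = r * np.sqrt((n_strains - 2) / (1.0 - r * r))
        p = 2.0 * stats.t.sf(t, df=n_strains - 2)
    elif method == "z":
        z = np.arctanh(r) * np.sqrt(n_strains - 3)
        p = 2.0 * stats.norm.sf(z)
    else:
        raise ValueError("method must be 't' or 'z'")
    return float(min(p, 1.0))


def critical_r(n_strains: int, alpha: float = 0.05) -> float:
    """Two-sided critical |r| at level alpha for n strains (t criterion)."""
    t = stats.t.ppf(1.0 - alpha / 2.0, df=n_strains - 2)
    return float(t / np.sqrt(n_strains - 2 + t * t))


def module_trait_table(
    expr: ExpressionMatrix,
    assignment: ModuleAssignment,
    traits: TraitTable,
    method: str = "t",
) -> pd.DataFrame:
    """MS and its p-value for every (module, trait) pair.

    Unassigned genes are excluded from module-level reporting.
    """
    gs = gene_significance_table(expr, traits)
    n = len(expr.values.columns.intersection(traits.values.index))
    rows = []
    for module in assignment.module_names:
        genes = [g for g in assignment.members(module) if g in gs.index]
        if not genes:
            continue
        for trait in gs.columns:
            ms = module_significance(gs.loc[genes, trait])
            rows.append(
                {
                    "module": module, "trait": trait, "n_genes": len(genes),
                    "MS": ms, "p": ms_pvalue(ms, n, method=method), "n_strains": n,
                }
            )
    return pd.DataFrame(rows)


def module_eigengene(expr: ExpressionMatrix, gene_ids) -> tuple[pd.Series, float]:
    """First principal component of a module's standardized expression.

    Returns the per-strain eigengene (unit norm) and the fraction of variance
    it explains.  The sign is oriented so the eigengene correlates positively
    with the per-strain mean of the standardized module expression.
    """
    genes = list(gene_ids)
    if len(genes) < 2:
        raise ValueError("module eigengene needs at least 2 genes")
    X = expr.values.loc[genes].to_numpy(float)  # genes × strains
    sd = X.std(axis=1, ddof=1, keepdims=True)
    if np.all(sd == 0):
        raise ValueError("degenerate module: all genes constant")
    sd[sd == 0] = 1.0
    Z = (X - X.mean(axis=1, keepdims=True)) / sd
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    eig = Vt[0]  # per-strain
    var_explained = float(S[0] ** 2 / np.sum(S**2))
    reference = Z.mean(axis=0)
    if np.dot(eig, reference) < 0:
        eig = -eig
    return (
        pd.Series(eig, index=expr.values.columns, name="eigengene"),
        var_explained,
    )


def trait_trait_correlation(traits: TraitTable, method: str = "t") -> pd.DataFrame:
    """Pairwise trait correlations with two-sided p-values (long form)."""
    if len(traits.strain_ids) < 4:
        raise ValueError("need at least 4 strains")
    names = traits.trait_names
    n = len(traits.strain_ids)
    rows = []
    for i, a in enumerate(names):
        for b in names[i:]:
            r = float(
                np.corrcoef(
                    traits.values[a].to_numpy(float), traits.values[b].to_numpy(float)
                )[0, 1]
            )
            rows.append(
                {
                    "trait_a": a, "trait_b": b, "r": r,
                    "p": ms_pvalue(min(abs(r), 1.0), n, method=method),
                    "n_strains": n,
                }
            )
    return pd.DataFrame(rows)
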