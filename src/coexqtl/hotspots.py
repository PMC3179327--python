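"""Module-QTL (trans-eQTL hotspot) detection.

A module QTL is a marker where significantly more module genes have an eQTL
(single-point LRS above a cutoff, default 13.8 ≙ LOD 3) than expected from
the network-wide rate.  Two significance measures are computed per marker:
an empirical p from permutations that redraw module-sized gene sets from the
network pool, and an upper-tail hypergeometric p comparing the module's
exceedance count with the pool's.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .qtl import LrsMatrix

logger = logging.getLogger(__name__)

DEFAULT_LRS_CUTOFF = 13.8  # LOD 3 under LOD = LRS / 4.6


@dataclass
class HotspotTable:
    """Per-marker module-gene eQTL exceedance counts with p-values."""

    table: pd.DataFrame  # marker-indexed
    module: str
    cutoff: float
    n_perm: int
    pool_size: int
    module_size: int
    seed: int | None

    def metadata(self) -> dict:
        return {
            "module": self.module,
            "cutoff": self.cutoff,
            "n_perm": self.n_perm,
            "pool": "network genes present in the LRS matrix",
            "pool_size": self.pool_size,
            "module_size": self.module_size,
            "seed": self.seed,
        }


def hotspot_counts(
    lrs: LrsMatrix, module_genes, cutoff: float = DEFAULT_LRS_CUTOFF
) -> pd.DataFrame:
    """Per-marker count of module genes with LRS strictly above ``cutoff``
    and the mean LRS over exactly those exceeders (NaN when none)."""
    genes = list(module_genes)
    if not genes:
        raise ValueError("empty module")
    missing = set(genes) - set(lrs.lrs.index)
    if missing:
        raise ValueError(f"module genes absent from LRS matrix: {sorted(missing)[:3]}")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    sub = lrs.lrs.loc[genes].to_numpy(float)
    exceed = np.where(np.isnan(sub), False, sub > cutoff)
    counts = exceed.sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean_lrs = np.where(
            counts > 0,
            np.nansum(np.where(exceed, sub, 0.0), axis=0) / np.maximum(counts, 1),
            np.nan,
        )
    return pd.DataFrame(
        {"count": counts.astype(int), "mean_lrs": mean_lrs},
        index=lrs.lrs.columns.rename("marker"),
    )


def empirical_hotspot_p(
    lrs: LrsMatrix,
    module_size: int,
    marker: str,
    observed_count: int,
    n_perm: int = 10000,
    cutoff: float = DEFAULT_LRS_CUTOFF,
    seed: int | None = None,
    pool=None,
) -> float:
    """Permutation p for one marker's module-gene exceedance count.

    Each permutation samples ``module_size`` genes without replacement from
    the pool (by default every gene with an LRS value in the matrix) and
    counts those with LRS > ``cutoff`` at the marker;
    ``p = (1 + #{perm count ≥ observed}) / (n_perm + 1)``.
    """
    if observed_count > module_size:
        raise ValueError("observed count cannot exceed module size")
    pool_genes = list(pool) if pool is not None else list(lrs.lrs.index)
    if module_size > len(pool_genes):
        raise ValueError("module size exceeds pool size")
    col = lrs.lrs.loc[pool_genes, marker].to_numpy(float)
    exceed = np.where(np.isnan(col), False, col > cutoff).astype(np.int8)
    rng = np.random.default_rng(np.random.SeedSequence(0 if seed is None else seed))
    n_pool = exceed.size
    counts = np.empty(n_perm, dtype=np.int64)
    # sampling without replacement via per-permutation partial shuffles
    for p in range(n_perm):
        take = rng.choice(n_pool, size=module_size, replace=False)
        counts[p] = exceed[take].sum()
    return float((1 + np.sum(counts >= observed_count)) / (n_perm + 1))


def hypergeom_hotspot_p(
    observed_count: int, module_size: int, pool_hits: int, pool_size: int
) -> float:
    """Upper-tail hypergeometric p: P(X ≥ observed) for X ~
    Hypergeometric(pool_size, pool_hits, module_size)."""
    if not (0 <= observed_count <= module_size):
        raise ValueError("observed count outside [0, module size]")
    if observed_count > pool_hits:
        raise ValueError("observed count cannot exceed pool hits")
    if pool_hits > pool_size or module_size > pool_size:
        raise ValueError("module size and pool hits cannot exceed pool size")
    return float(stats.hypergeom.sf(observed_count - 1, pool_size, pool_hits, module_size))


def hotspot_table(
    lrs: LrsMatrix,
    module_genes,
    module: str = "module",
    cutoff: float = DEFAULT_LRS_CUTOFF,
    n_perm: int = 10000,
    seed: int | None = None,
    markers=None,
) -> HotspotTable:
    """Full per-marker hotspot table: counts, mean LRS, empirical and
    hypergeometric p.

    The sampling/reference pool is the network gene set present in the LRS
    matrix; ``pool_hits`` for the hypergeometric test is recomputed from the
    same LRS column at the same cutoff.  One set of permutation gene draws is
    shared across markers (each marker's empirical p is marginally identical
    to a per-marker run, and restricting ``markers`` does not change
    per-marker results since the draws do not depend on the marker set).
    """
    genes = list(module_genes)
    counts = hotspot_counts(lrs, genes, cutoff)
    pool_genes = list(lrs.lrs.index)
    pool_size = len(pool_genes)
    module_size = len(genes)
    marker_list = list(markers) if markers is not None else list(lrs.lrs.columns)

    pool_matrix = lrs.lrs.loc[pool_genes, marker_list].to_numpy(float)
    exceed = np.where(np.isnan(pool_matrix), False, pool_matrix > cutoff).astype(np.int8)
    pool_hits_per_marker = exceed.sum(axis=0)

    rng = np.random.default_rng(np.random.SeedSequence(0 if seed is None else seed))
    ge_counts = np.zeros(len(marker_list), dtype=np.int64)
    observed_vec = counts.loc[marker_list, "count"].to_numpy()
    block = max(1, min(n_perm, 40_000_000 // max(module_size * len(marker_list), 1)))
    done = 0
    while done < n_perm:
        b = min(block, n_perm - done)
        keys = rng.random((b, pool_size))
        take = np.argpartition(keys, module_size - 1, axis=1)[:, :module_size]
        perm_counts = exceed[take].sum(axis=1)  # b × markers
        ge_counts += (perm_counts >= observed_vec[None, :]).sum(axis=0)
        done += b
    emp_p = (1 + ge_counts) / (n_perm + 1)

    rows = []
    for j, marker in enumerate(marker_list):
        observed = int(observed_vec[j])
        pool_hits = int(pool_hits_per_marker[j])
        emp = float(emp_p[j])
        hyp = hypergeom_hotspot_p(min(observed, pool_hits), module_size, pool_hits, pool_size)
        rows.append(
            {
                "marker": marker,
                "chromosome": lrs.markers.loc[marker, "chromosome"],
                "Mb": lrs.markers.loc[marker, "Mb"],
                "count": observed,
                "mean_lrs": counts.loc[marker, "mean_lrs"],
                "pool_hits": pool_hits,
                "empirical_p": emp,
                "hypergeom_p": hyp,
            }
        )
    table = pd.DataFrame(rows).set_index("marker")
    return HotspotTable(table, module, cutoff, n_perm, pool_size, module_size, seed)


def _empirical_p_from_stream(
    col: np.ndarray, module_size: int, observed: int, cutoff: float,
    n_perm: int, rng: np.random.Generator,
) -> float:
    exceed = np.where(np.isnan(col), False, col > cutoff).astype(np.int8)
    n_pool = exceed.size
    # vectorized without-replacement draws: argpartition of uniform keys
    counts = np.empty(n_perm, dtype=np.int64)
    block = max(1, min(n_perm, 2_000_000 // max(n_pool, 1)))
    done = 0
    while done < n_perm:
        b = min(block, n_perm - done)
        keys = rng.random((b, n_pool))
        take = np.argpartition(keys, module_size - 1, axis=1)[:, :module_size]
        counts[done : done + b] = exceed[take].sum(axis=1)
        done += b
    return float((1 + np.sum(counts >= observed)) / (n_perm + 1))


def call_hotspots(hotspots: HotspotTable, alpha: float = 0.05) -> pd.DataFrame:
    """Flag module QTLs: markers with both p-values ≤ alpha, collapsing
    overlapping flagged runs within a chromosome to the marker with the
    maximal count (ties broken by larger mean LRS)."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    t = hotspots.table
    flagged = t[(t["empirical_p"] <= alpha) & (t["hypergeom_p"] <= alpha)]
    if flagged.empty:
        return flagged.copy()
    reps = []
    for _, sub in flagged.groupby("chromosome", sort=False):
        # consecutive flagged markers on a chromosome form one run
        positions = t.index.get_indexer(sub.index)
        order = np.argsort(positions)
        sub = sub.iloc[order]
        positions = positions[order]
        run_start = 0
        for i in range(1, len(sub) + 1):
            if i == len(sub) or positions[i] != positions[i - 1] + 1:
                run = sub.iloc[run_start:i]
                best = run.sort_values(
                    by=["count", "mean_lrs"], ascending=[False, False]
                ).iloc[0]
                reps.append(best)
                run_start = i
    out = pd.DataFrame(reps)
    out.index.name = "marker"
    return out
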