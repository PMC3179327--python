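"""Single-marker expression QTL mapping on a merged RI panel.

Crosses are merged by renaming every D or H allele to N ("BXN" coding), so
BXD-like and BXH-like strains map as one panel.  The per-marker statistic is
the likelihood ratio statistic of two-group marker regression,
``LRS = n · ln(TSS / RSS)``, the normal-likelihood LRS for a model with one
mean per genotype class against a single grand mean; ``LOD = LRS / 4.6``.
Genome-wide significance per transcript comes from permutations of the strain
labels of the expression vector with genotypes held fixed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import ExpressionMatrix, GenotypeTable

logger = logging.getLogger(__name__)

LRS_PER_LOD = 4.6
_RSS_FLOOR = 1e-12  # RSS floored at this fraction of TSS (perfect-fit guard)


class LrsUndefined(ValueError):
    """Marker regression undefined (monomorphic marker or class too small)."""


@dataclass
class LrsMatrix:
    """Gene × marker LRS values plus marker metadata and permutation results."""

    lrs: pd.DataFrame  # genes × markers, NaN where undefined
    markers: pd.DataFrame  # chromosome, cM, Mb per marker
    thresholds: pd.DataFrame | None = None  # per-gene permutation summary
    n_perm: int = 0
    seed: int | None = None

    @property
    def lod(self) -> pd.DataFrame:
        return self.lrs / LRS_PER_LOD

    def max_per_gene(self) -> pd.DataFrame:
        """Per-gene maximum LRS and the marker attaining it."""
        arr = self.lrs.to_numpy(float)
        all_nan = np.all(np.isnan(arr), axis=1)
        safe = np.where(np.isnan(arr), -np.inf, arr)
        idx = safe.argmax(axis=1)
        out = pd.DataFrame(
            {
                "max_lrs": np.where(all_nan, np.nan, safe.max(axis=1)),
                "marker": np.asarray(self.lrs.columns)[idx],
            },
            index=self.lrs.index,
        )
        out.loc[all_nan, "marker"] = None
        return out


def merge_crosses(tables: list[GenotypeTable]) -> GenotypeTable:
    """Merge per-cross genotype tables into one BXN-coded panel.

    Markers are restricted to the intersection across tables (ordered by
    chromosome then cM); D and H calls become N, B stays B, U becomes missing;
    strain columns are concatenated.
    """
    if not tables:
        raise ValueError("need at least one genotype table")
    common = set(tables[0].marker_ids)
    for t in tables[1:]:
        common &= set(t.marker_ids)
    if not common:
        raise ValueError("empty marker intersection across crosses")
    all_strains: list[str] = []
    for t in tables:
        overlap = set(all_strains) & set(t.strain_ids)
        if overlap:
            raise ValueError(f"strain ids not disjoint across crosses: {sorted(overlap)[:3]}")
        all_strains.extend(t.strain_ids)

    ref = tables[0].markers.loc[sorted(common)]
    ref = ref.sort_values(
        by=["chromosome", "cM"],
        key=lambda s: s.map(_chrom_sort_key) if s.name == "chromosome" else s,
    )
    order = list(ref.index)

    recode = {"B": "B", "D": "N", "H": "N", "U": np.nan}
    merged_calls = pd.concat(
        [t.calls.loc[order].apply(lambda col: col.map(recode)) for t in tables], axis=1
    )
    cross_parts = [
        t.cross if t.cross is not None
        else pd.Series("NA", index=pd.Index(t.strain_ids))
        for t in tables
    ]
    cross = pd.concat(cross_parts)
    return GenotypeTable(ref, merged_calls, cross)


def _chrom_sort_key(c: str):
    try:
        return (0, int(c))
    except (TypeError, ValueError):
        return (1, str(c))


def lrs(expr_vector, genotype_calls, min_class: int = 3) -> float:
    """Single-point marker-regression LRS for one gene at one marker.

    With n strains having both data, ``TSS = Σ(y − ȳ)²`` and ``RSS`` the sum
    of squared deviations from the two genotype-class means;
    ``LRS = n · ln(TSS / RSS)``.  RSS is floored at ``1e-12 × TSS`` when a
    class fits perfectly.  Raises :class:`LrsUndefined` when the marker is
    monomorphic among the usable strains or a class has fewer than
    ``min_class`` members.
    """
    y = np.asarray(expr_vector, dtype=float)
    g = _code_calls(genotype_calls)
    ok = ~np.isnan(y) & ~np.isnan(g)
    y, g = y[ok], g[ok]
    classes = np.unique(g)
    if classes.size < 2:
        raise LrsUndefined("monomorphic marker")
    n0 = int((g == classes[0]).sum())
    n1 = int((g == classes[1]).sum())
    if min(n0, n1) < min_class:
        raise LrsUndefined(f"genotype class below minimum size {min_class}")
    n = y.size
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0.0:
        return 0.0
    rss = 0.0
    for c in classes:
        sub = y[g == c]
        rss += float(np.sum((sub - sub.mean()) ** 2))
    rss = max(rss, _RSS_FLOOR * tss)
    return float(n * np.log(tss / rss))


def _code_calls(calls) -> np.ndarray:
    if isinstance(calls, pd.Series):
        calls = calls.to_numpy()
    arr = np.asarray(calls, dtype=object)
    if arr.dtype.kind in "fi":
        return arr.astype(float)
    mapping = {"B": 0.0, "N": 1.0, "D": 1.0, "H": 1.0, "U": np.nan, None: np.nan}
    out = np.empty(arr.shape, dtype=float)
    for i, v in enumerate(arr.ravel()):
        if isinstance(v, float) and np.isnan(v):
            out.ravel()[i] = np.nan
        else:
            out.ravel()[i] = mapping.get(v, np.nan)
    return out


def lod(lrs_value: float) -> float:
    """LOD = LRS / 4.6."""
    if np.any(np.asarray(lrs_value) < 0):
        raise ValueError("LRS must be non-negative")
    return lrs_value / LRS_PER_LOD


@dataclass
class _MarkerDesign:
    """Pre-computed per-marker strain index groups for vectorized scans."""

    marker_id: str
    idx: np.ndarray  # usable strain positions
    mask1: np.ndarray  # within idx: genotype class 1 membership
    usable: bool
    reason: str | None = None


def _marker_designs(
    geno: GenotypeTable, strain_order: list[str], min_class: int = 3
) -> list[_MarkerDesign]:
    coded = geno.coded()[strain_order].to_numpy(float)  # markers × strains
    designs = []
    for mi, marker in enumerate(geno.marker_ids):
        g = coded[mi]
        ok = ~np.isnan(g)
        gv = g[ok]
        classes = np.unique(gv)
        if classes.size < 2:
            designs.append(_MarkerDesign(marker, np.array([]), np.array([]), False,
                                         "monomorphic"))
            continue
        mask1 = gv == classes[1]
        if min(int((~mask1).sum()), int(mask1.sum())) < min_class:
            designs.append(_MarkerDesign(marker, np.array([]), np.array([]), False,
                                         "class below minimum size"))
            continue
        designs.append(_MarkerDesign(marker, np.where(ok)[0], mask1, True))
    skipped = sum(not d.usable for d in designs)
    if skipped:
        logger.info("genome scan skipping %d unusable markers", skipped)
    return designs


def _lrs_block(Y: np.ndarray, design: _MarkerDesign) -> np.ndarray:
    """Vectorized LRS for many expression vectors (rows of Y) at one marker."""
    Yv = Y[:, design.idx]
    n = Yv.shape[1]
    mean_all = Yv.mean(axis=1)
    tss = np.sum((Yv - mean_all[:, None]) ** 2, axis=1)
    y1 = Yv[:, design.mask1]
    y0 = Yv[:, ~design.mask1]
    rss = (
        np.sum((y0 - y0.mean(axis=1)[:, None]) ** 2, axis=1)
        + np.sum((y1 - y1.mean(axis=1)[:, None]) ** 2, axis=1)
    )
    out = np.zeros(Y.shape[0])
    nonzero = tss > 0
    rss_f = np.maximum(rss, _RSS_FLOOR * tss)
    with np.errstate(divide="ignore", invalid="ignore"):
        out[nonzero] = n * np.log(tss[nonzero] / rss_f[nonzero])
    return out


def genome_scan(
    expr: ExpressionMatrix,
    geno: GenotypeTable,
    n_perm: int = 0,
    quantile: float = 0.95,
    seed: int | None = None,
    min_class: int = 3,
) -> LrsMatrix:
    """LRS at every (gene, marker) pair, optionally with per-gene genome-wide
    permutation thresholds.

    Strains are aligned by id intersection between expression and genotypes.
    When ``n_perm > 0``, each gene gets its own pre-split permutation stream
    (so results do not depend on gene order or thread count) and the returned
    ``thresholds`` table carries the empirical ``quantile`` of the permuted
    genome-wide maxima and the permutation p of the observed maximum under
    the plus-one rule.
    """
    strains = [s for s in expr.strain_ids if s in set(geno.strain_ids)]
    if len(strains) < 2 * min_class:
        raise ValueError("too few strains shared between expression and genotypes")
    designs = _marker_designs(geno, strains, min_class=min_class)
    usable = [d for d in designs if d.usable]
    if not usable:
        raise ValueError("no usable marker")
    Y = expr.values[strains].to_numpy(float)
    L = np.full((Y.shape[0], len(designs)), np.nan)
    for mi, d in enumerate(designs):
        if d.usable:
            L[:, mi] = _lrs_block(Y, d)
    lrs_df = pd.DataFrame(L, index=expr.values.index, columns=geno.marker_ids)

    thresholds = None
    if n_perm > 0:
        root = np.random.SeedSequence(0 if seed is None else seed)
        streams = root.spawn(Y.shape[0])
        rows = []
        observed = np.nanmax(np.where(np.isnan(L), -np.inf, L), axis=1)
        for gi, gene in enumerate(expr.values.index):
            rng = np.random.default_rng(streams[gi])
            perm_max = _permuted_maxima(Y[gi], usable, n_perm, rng)
            thr = float(np.quantile(perm_max, quantile))
            p = float((1 + np.sum(perm_max >= observed[gi])) / (n_perm + 1))
            rows.append(
                {
                    "gene_id": gene, "threshold": thr,
                    "max_lrs": float(observed[gi]), "perm_p": p,
                }
            )
        thresholds = pd.DataFrame(rows).set_index("gene_id")
        thresholds["n_perm"] = n_perm
        thresholds["seed"] = 0 if seed is None else seed
    return LrsMatrix(lrs_df, geno.markers.copy(), thresholds, n_perm, seed)


def _permuted_maxima(
    y: np.ndarray, designs: list[_MarkerDesign], n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    P = rng.permuted(np.tile(y, (n_perm, 1)), axis=1)
    maxima = np.full(n_perm, -np.inf)
    for d in designs:
        np.maximum(maxima, _lrs_block(P, d), out=maxima)
    return maxima


def permutation_threshold(
    expr_vector,
    geno: GenotypeTable,
    n_perm: int = 1000,
    quantile: float = 0.95,
    seed: int | None = None,
    min_class: int = 3,
) -> dict:
    """Genome-wide permutation threshold and p for one expression vector.

    Strain labels of the expression vector are shuffled with genotypes held
    fixed; each permutation records the genome-wide maximum LRS.  The
    threshold is the empirical ``quantile`` of those maxima and
    ``p = (1 + #{perm max ≥ observed max}) / (n_perm + 1)``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if isinstance(expr_vector, pd.Series):
        strains = [s for s in expr_vector.index if s in set(geno.strain_ids)]
        y = expr_vector.loc[strains].to_numpy(float)
    else:
        strains = list(geno.strain_ids)
        y = np.asarray(expr_vector, dtype=float)
    designs = [d for d in _marker_designs(geno, strains, min_class) if d.usable]
    if not designs:
        raise ValueError("no usable marker")
    observed = float(np.max(_scan_one(y, designs)))
    rng = np.random.default_rng(np.random.SeedSequence(0 if seed is None else seed))
    perm_max = _permuted_maxima(y, designs, n_perm, rng)
    return {
        "threshold": float(np.quantile(perm_max, quantile)),
        "max_lrs": observed,
        "perm_p": float((1 + np.sum(perm_max >= observed)) / (n_perm + 1)),
        "n_perm": n_perm,
        "seed": 0 if seed is None else seed,
    }


def _scan_one(y: np.ndarray, designs: list[_MarkerDesign]) -> np.ndarray:
    return np.array([_lrs_block(y[None, :], d)[0] for d in designs])
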