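"""Synthetic recombinant-inbred panel generator.

Emulates the study design every downstream stage expects: ~27 fully inbred
strains drawn from two crosses (BXD-like and BXH-like), genotypes forming
homozygous blocks along each chromosome, a modular expression matrix built
from per-module latent strain factors, one module whose factor is shifted by
the genotype at a planted hotspot marker (a trans-eQTL band), and strain-level
bone traits correlated with one module's factor, each trait averaged over
replicate mice per strain.

All randomness flows from a single seed through named substreams (one per
operation), so regenerating genotypes does not perturb expression noise and
stages can be re-simulated independently.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data import ExpressionMatrix, GenotypeTable, TraitTable, TRAIT_NAMES

# substream indices of the single-seed splitter; order is part of the contract
_STREAMS = {"genotypes": 0, "factors": 1, "loadings": 2, "noise": 3,
            "detection": 4, "traits": 5}


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


@dataclass
class SimConfig:
    """Parameters of the synthetic RI panel.

    Defaults mirror the emulated study design: 27 strains from two crosses,
    six planted coexpression modules among 1200 genes, one trans-eQTL hotspot
    driving the first module with a standardized effect of 1.5, traits tied to
    the same module at correlation 0.6, and five replicate mice per strain.
    """

    n_strains: int = 27
    crosses: tuple[tuple[str, int], ...] = (("BXD", 16), ("BXH", 11))
    n_genes: int = 1200
    n_modules: int = 6
    module_sizes: tuple[int, ...] | None = None  # default: 120 genes each
    n_chromosomes: int = 19
    n_markers_per_chr: int = 20
    cm_spacing: float = 3.0
    mb_spacing: float = 6.0
    recomb_fraction: float = 0.15
    hotspot_marker: int | None = None  # default: middle of chromosome 5
    eqtl_effect: float = 1.5
    trait_module: int = 0
    trait_cor: float = 0.6
    trait_cors: tuple[float, float, float, float] | None = None
    replicate_count: int = 5
    # mouse-level trait noise SD; None = calibrate so the strain-level
    # correlation with the factor hits trait_cor regardless of replicate_count
    trait_mouse_noise_sd: float | None = None
    noise_sd: float = 0.3
    background_sd: float = 0.5
    loading_range: tuple[float, float] = (0.6, 0.95)
    detected_fraction: float = 0.9
    seed: int = 0

    def resolved_module_sizes(self) -> tuple[int, ...]:
        if self.module_sizes is not None:
            return tuple(self.module_sizes)
        return (120,) * self.n_modules

    def resolved_hotspot_marker(self) -> int:
        if self.hotspot_marker is not None:
            return self.hotspot_marker
        # middle of chromosome 5 (or of the last chromosome on short maps)
        chrom = min(4, self.n_chromosomes - 1)
        return chrom * self.n_markers_per_chr + self.n_markers_per_chr // 2

    def validate(self) -> None:
        if self.n_strains < 1 or self.n_chromosomes < 1 or self.n_markers_per_chr < 1:
            raise ConfigurationError("strain, chromosome and marker counts must be >= 1")
        if sum(n for _, n in self.crosses) != self.n_strains:
            raise ConfigurationError("cross strain counts must sum to n_strains")
        sizes = self.resolved_module_sizes()
        if len(sizes) != self.n_modules:
            raise ConfigurationError("module_sizes length must equal n_modules")
        if sum(sizes) > self.n_genes:
            raise ConfigurationError("module sizes exceed n_genes")
        if not 0.0 <= self.recomb_fraction <= 1.0:
            raise ConfigurationError("recomb_fraction must lie in [0, 1]")
        if not 0.0 <= self.detected_fraction <= 1.0:
            raise ConfigurationError("detected_fraction must lie in [0, 1]")
        cors = self.trait_cors or (self.trait_cor,) * 4
        if any(abs(c) > 1.0 for c in cors):
            raise ConfigurationError("trait correlations must lie in [-1, 1]")
        if self.replicate_count < 1:
            raise ConfigurationError("replicate_count must be >= 1")
        total_markers = self.n_chromosomes * self.n_markers_per_chr
        if not 0 <= self.resolved_hotspot_marker() < total_markers:
            raise ConfigurationError("hotspot_marker outside the marker map")
        if not 0 <= self.trait_module < self.n_modules:
            raise ConfigurationError("trait_module outside the module range")


@dataclass
class SimTruth:
    """Ground truth of one simulated panel, for parameter-recovery tests."""

    planted_membership: dict[str, int]  # gene id -> module index; -1 background
    hotspot_marker_id: str
    driven_module_id: int
    trait_module_id: int
    module_factors: pd.DataFrame | None = None  # modules × strains latent factors
    realized_trait_cors: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def module_genes(self, module: int) -> list[str]:
        return [g for g, m in self.planted_membership.items() if m == module]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "planted_membership": self.planted_membership,
            "hotspot_marker_id": self.hotspot_marker_id,
            "driven_module_id": self.driven_module_id,
            "trait_module_id": self.trait_module_id,
            "realized_trait_cors": self.realized_trait_cors,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            planted_membership=payload["planted_membership"],
            hotspot_marker_id=payload["hotspot_marker_id"],
            driven_module_id=payload["driven_module_id"],
            trait_module_id=payload["trait_module_id"],
            realized_trait_cors=payload.get("realized_trait_cors", {}),
            seed=payload.get("seed", 0),
        )


def _stream(config: SimConfig, name: str) -> np.random.Generator:
    ss = np.random.SeedSequence(config.seed, spawn_key=(_STREAMS[name],))
    return np.random.default_rng(ss)


def strain_names(config: SimConfig) -> tuple[list[str], pd.Series]:
    names, cross_of = [], {}
    for label, count in config.crosses:
        for i in range(1, count + 1):
            name = f"{label}{i:02d}"
            names.append(name)
            cross_of[name] = label
    return names, pd.Series(cross_of)


def simulate_genotypes(config: SimConfig) -> GenotypeTable:
    """Simulate homozygous RI genotypes as a two-state Markov chain per
    chromosome with switch probability ``recomb_fraction`` per marker interval.

    The non-B allele is written with the cross's own code (D for the BXD-like
    cross, H for the BXH-like cross) so that cross merging downstream has real
    work to do.
    """
    config.validate()
    rng = _stream(config, "genotypes")
    strains, cross = strain_names(config)

    marker_ids, chrom, cm, mb = [], [], [], []
    for c in range(1, config.n_chromosomes + 1):
        for j in range(config.n_markers_per_chr):
            marker_ids.append(f"rs{c:02d}_{j:03d}")
            chrom.append(str(c))
            cm.append(j * config.cm_spacing)
            mb.append(j * config.mb_spacing)
    markers = pd.DataFrame(
        {"chromosome": chrom, "cM": cm, "Mb": mb},
        index=pd.Index(marker_ids, name="marker"),
    )

    n_markers = len(marker_ids)
    calls = np.empty((n_markers, config.n_strains), dtype="<U1")
    for s, strain in enumerate(strains):
        alt = "D" if cross[strain] == "BXD" else "H"
        col = np.empty(n_markers, dtype="<U1")
        pos = 0
        for _ in range(config.n_chromosomes):
            state = rng.random() < 0.5  # True = B
            for j in range(config.n_markers_per_chr):
                if j > 0 and rng.random() < config.recomb_fraction:
                    state = not state
                col[pos + j] = "B" if state else alt
            pos += config.n_markers_per_chr
        calls[:, s] = col

    calls_df = pd.DataFrame(calls, index=markers.index, columns=strains)
    return GenotypeTable(markers, calls_df, cross)


def split_by_cross(geno: GenotypeTable) -> dict[str, GenotypeTable]:
    """Split a combined genotype table into one table per cross label."""
    if geno.cross is None:
        return {"ALL": geno}
    out = {}
    for label in geno.cross.unique():
        strains = [s for s in geno.strain_ids if geno.cross[s] == label]
        out[label] = GenotypeTable(
            geno.markers.copy(), geno.calls[strains].copy(), geno.cross[strains]
        )
    return out


def simulate_expression(
    config: SimConfig, genotypes: GenotypeTable
) -> tuple[ExpressionMatrix, SimTruth]:
    """Simulate modular expression from per-module latent strain factors.

    Module ``m`` has a latent factor :math:`f_m` (standard normal over
    strains); the trait/driven module's factor is shifted by
    ``eqtl_effect × coded hotspot genotype`` (homozygous classes coded ±1,
    the usual additive-effect parametrization, so class means differ by twice
    the effect) before re-standardization, planting a trans-eQTL band at that
    marker.  Gene ``g``
    of module ``m`` is :math:`\\lambda_g f_m + \\varepsilon`,
    ``λ_g ~ U(loading_range)``, ``ε ~ N(0, noise_sd²)``; background genes are
    pure noise with ``background_sd``.  Detection p-values are drawn from a
    two-component mixture: expressed genes get Beta(0.3, 30) (tiny) values,
    a ``1 − detected_fraction`` share of background genes gets Uniform(0, 1).
    Expressed genes therefore show detection p < 0.01 in nearly every strain
    and always clear the default detection filter.
    """
    config.validate()
    strains = genotypes.strain_ids
    if len(strains) != config.n_strains:
        raise ConfigurationError("genotype table strain count differs from config")
    hotspot_idx = config.resolved_hotspot_marker()
    if hotspot_idx >= len(genotypes.marker_ids):
        raise ConfigurationError("hotspot marker absent from genotype table")
    hotspot_id = genotypes.marker_ids[hotspot_idx]

    rng_f = _stream(config, "factors")
    rng_l = _stream(config, "loadings")
    rng_n = _stream(config, "noise")
    rng_d = _stream(config, "detection")

    n_strains = config.n_strains
    sizes = config.resolved_module_sizes()

    factors = rng_f.standard_normal((config.n_modules, n_strains))
    # additive QTL coding: homozygous classes at ±1, so the class means of the
    # latent factor differ by twice the allelic effect (the usual RI-panel
    # parametrization of an additive effect)
    coded = genotypes.coded().loc[hotspot_id].to_numpy()  # 0/1, no missing here
    coded = 2.0 * (np.where(np.isnan(coded), 0.5, coded) - 0.5)
    f = factors[config.trait_module] + config.eqtl_effect * coded
    factors[config.trait_module] = (f - f.mean()) / f.std(ddof=0)
    for m in range(config.n_modules):
        if m != config.trait_module:
            fm = factors[m]
            factors[m] = (fm - fm.mean()) / fm.std(ddof=0)

    gene_ids = [f"g{i:04d}" for i in range(config.n_genes)]
    membership = {g: -1 for g in gene_ids}
    values = np.empty((config.n_genes, n_strains))
    row = 0
    lo, hi = config.loading_range
    for m, size in enumerate(sizes):
        lam = rng_l.uniform(lo, hi, size=size)
        noise = rng_n.standard_normal((size, n_strains)) * config.noise_sd
        values[row : row + size] = lam[:, None] * factors[m][None, :] + noise
        for g in gene_ids[row : row + size]:
            membership[g] = m
        row += size
    n_bg = config.n_genes - row
    if n_bg:
        values[row:] = rng_n.standard_normal((n_bg, n_strains)) * config.background_sd

    # detection p-values: expressed genes detect everywhere; an undetected
    # share of the background does not
    detection = rng_d.beta(0.2, 60.0, size=(config.n_genes, n_strains))
    if n_bg:
        n_undetected = int(round((1.0 - config.detected_fraction) * n_bg))
        if n_undetected:
            undetected_rows = row + rng_d.permutation(n_bg)[:n_undetected]
            detection[undetected_rows] = rng_d.uniform(0, 1, size=(n_undetected, n_strains))

    values_df = pd.DataFrame(values, index=pd.Index(gene_ids, name="gene_id"), columns=strains)
    det_df = pd.DataFrame(detection, index=values_df.index, columns=strains)
    expr = ExpressionMatrix(values_df, det_df)
    truth = SimTruth(
        planted_membership=membership,
        hotspot_marker_id=hotspot_id,
        driven_module_id=config.trait_module,
        trait_module_id=config.trait_module,
        module_factors=pd.DataFrame(factors, columns=strains),
        seed=config.seed,
    )
    return expr, truth


def simulate_replicate_traits(config: SimConfig, truth: SimTruth) -> pd.DataFrame:
    """Simulate mouse-level trait replicates tied to the trait module's factor.

    With target correlation ρ the mouse-level draw is ρ·f + ε with
    ``ε ~ N(0, (1 − ρ²)·R)`` so the strain mean over R replicates has unit
    variance and population correlation ρ with the factor.  The z-scale values
    are mapped to plausible units per trait (mm for geometry, g/cm² for BMD).
    """
    config.validate()
    if truth.module_factors is None:
        raise ConfigurationError("truth carries no module factors")
    cors = config.trait_cors or (config.trait_cor,) * 4
    rng = _stream(config, "traits")
    f = truth.module_factors.iloc[truth.trait_module_id]
    strains = list(truth.module_factors.columns)
    R = config.replicate_count
    # (location, scale) per trait on the measurement scale
    units = {
        "femur_length": (15.5, 0.40),
        "ap_diameter": (1.30, 0.08),
        "ml_diameter": (1.70, 0.10),
        "bmd": (0.0650, 0.0040),
    }
    rows = []
    for strain in strains:
        for rep in range(1, R + 1):
            rec = {"strain": strain, "mouse_id": f"{strain}_m{rep}"}
            for t, (name, rho) in enumerate(zip(TRAIT_NAMES, cors)):
                if config.trait_mouse_noise_sd is not None:
                    resid_sd = config.trait_mouse_noise_sd
                else:
                    resid_sd = float(np.sqrt(max(0.0, 1.0 - rho * rho) * R))
                z = rho * f[strain] + resid_sd * rng.standard_normal()
                loc, scale = units[name]
                rec[name] = loc + scale * z
            rows.append(rec)
    return pd.DataFrame(rows)


def simulate_traits(config: SimConfig, truth: SimTruth) -> TraitTable:
    """Average simulated replicate mice into a strain-level trait table and
    record the realized trait–factor correlations on the ground truth."""
    reps = simulate_replicate_traits(config, truth)
    means = reps.drop(columns="mouse_id").groupby("strain", sort=False).mean()
    f = truth.module_factors.iloc[truth.trait_module_id].loc[means.index]
    for name in TRAIT_NAMES:
        v = means[name].to_numpy()
        if np.std(v) == 0 or np.std(f.to_numpy()) == 0:
            truth.realized_trait_cors[name] = 0.0
        else:
            truth.realized_trait_cors[name] = float(np.corrcoef(v, f.to_numpy())[0, 1])
    return TraitTable(means)


def simulate_panel(
    config: SimConfig,
) -> tuple[GenotypeTable, ExpressionMatrix, TraitTable, SimTruth]:
    """Generate the full synthetic panel in one call."""
    geno = simulate_genotypes(config)
    expr, truth = simulate_expression(config, geno)
    traits = simulate_traits(config, truth)
    return geno, expr, traits, truth
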