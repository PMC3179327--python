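"""Core data containers and file codecs.

The pipeline moves three tabular substrates between stages:

* :class:`ExpressionMatrix` — normalized expression (genes × strains) with
  per-cell detection p-values, the network substrate;
* :class:`GenotypeTable` — recombinant-inbred marker calls with genetic and
  physical positions, the mapping substrate;
* :class:`TraitTable` — strain-level bone traits (replicate means).

All on-disk formats are plain text: tab-separated matrices for expression and
genotypes (the genotype dialect follows GeneNetwork conventions: metadata lines
starting with ``@``, then a header of ``Chr  Locus  cM  Mb`` followed by strain
columns with allele codes B/D/H/U), and CSV for traits.  Lines starting with
``#`` are comments in every dialect.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

VALID_ALLELE_CODES = {"B", "D", "H", "U", "N"}
TRAIT_NAMES = ("femur_length", "ap_diameter", "ml_diameter", "bmd")

MISSING_TOKEN = "."


class ValidationError(ValueError):
    """Raised when an input table violates its structural contract."""


@dataclass
class ExpressionMatrix:
    """Normalized expression values with companion detection p-values.

    Parameters
    ----------
    values
        DataFrame of normalized intensities, genes as rows, strains as
        columns.  Values are assumed log-scale/variance-stabilized upstream.
    detection_p
        Per gene × strain detection p-value in [0, 1]; same shape and labels
        as ``values``.  May be ``None`` when detection filtering is not used.
    """

    values: pd.DataFrame
    detection_p: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValidationError("duplicate gene ids in expression matrix")
        if self.values.columns.duplicated().any():
            raise ValidationError("duplicate strain ids in expression matrix")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValidationError("expression values must be finite")
        if self.detection_p is not None:
            d = self.detection_p
            if list(d.index) != list(self.values.index) or list(d.columns) != list(
                self.values.columns
            ):
                raise ValidationError("detection table labels differ from expression")
            arr = d.to_numpy(dtype=float)
            if arr.size and (np.nanmin(arr) < 0 or np.nanmax(arr) > 1):
                raise ValidationError("detection p-values must lie in [0, 1]")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def strain_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_strains(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        det = self.detection_p.loc[gene_ids] if self.detection_p is not None else None
        return ExpressionMatrix(self.values.loc[gene_ids], det)


@dataclass
class GenotypeTable:
    """RI marker calls per strain with genetic and physical positions.

    ``markers`` is indexed by marker id with columns ``chromosome`` (string),
    ``cM`` and ``Mb`` (float); ``calls`` shares the marker index and holds one
    column per strain with values from ``{B, D, H, U, N}`` or NaN for missing.
    ``cross`` maps each strain to its cross label (e.g. BXD / BXH).
    """

    markers: pd.DataFrame
    calls: pd.DataFrame
    cross: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.markers.index.duplicated().any():
            raise ValidationError("duplicate marker ids")
        if list(self.calls.index) != list(self.markers.index):
            raise ValidationError("calls index must equal marker index")
        if (self.markers[["cM", "Mb"]].to_numpy(dtype=float) < 0).any():
            raise ValidationError("marker positions must be non-negative")
        bad = set(self.calls.stack().dropna().unique()) - VALID_ALLELE_CODES
        if bad:
            raise ValidationError(f"unknown allele codes: {sorted(bad)}")
        for _, sub in self.markers.groupby("chromosome", sort=False):
            if not sub["cM"].is_monotonic_increasing:
                raise ValidationError("cM positions must be monotone within chromosome")

    @property
    def marker_ids(self) -> list[str]:
        return list(self.markers.index)

    @property
    def strain_ids(self) -> list[str]:
        return list(self.calls.columns)

    def coded(self) -> pd.DataFrame:
        """Numeric coding for marker regression: B → 0, D/H/N → 1, U → NaN."""
        mapping = {"B": 0.0, "D": 1.0, "H": 1.0, "N": 1.0, "U": np.nan}
        return self.calls.apply(lambda col: col.map(mapping))


@dataclass
class TraitTable:
    """Strain-level trait means (femur length, AP/ML midshaft diameter, BMD)."""

    values: pd.DataFrame  # strains × traits

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValidationError("duplicate strain ids in trait table")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValidationError("trait values must be finite")

    @property
    def strain_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def trait_names(self) -> list[str]:
        return list(self.values.columns)


# ---------------------------------------------------------------------------
# codecs
# ---------------------------------------------------------------------------

def _strip_header_comments(path: Path) -> tuple[list[str], str]:
    """Split leading @/# metadata lines from the body of a text table."""
    meta: list[str] = []
    body: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith(("#", "@")) and not body:
                meta.append(line.rstrip("\n"))
            elif line.startswith("#"):
                continue
            else:
                body.append(line)
    return meta, "".join(body)


def read_expression(
    values_path: str | Path, detection_path: str | Path | None = None
) -> ExpressionMatrix:
    """Read an expression TSV (gene_id column + strain columns) and optional
    companion detection TSV of identical shape."""
    _, body = _strip_header_comments(Path(values_path))
    values = pd.read_csv(_io.StringIO(body), sep="\t", index_col=0)
    det = None
    if detection_path is not None:
        _, dbody = _strip_header_comments(Path(detection_path))
        det = pd.read_csv(_io.StringIO(dbody), sep="\t", index_col=0)
    return ExpressionMatrix(values, det)


def write_expression(
    expr: ExpressionMatrix,
    values_path: str | Path,
    detection_path: str | Path | None = None,
    header_comment: str | None = None,
) -> None:
    _write_tsv(expr.values, values_path, "gene_id", header_comment)
    if detection_path is not None and expr.detection_p is not None:
        _write_tsv(expr.detection_p, detection_path, "gene_id", header_comment)


def _write_tsv(
    df: pd.DataFrame, path: str | Path, index_label: str, header_comment: str | None
) -> None:
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index_label=index_label, na_rep=MISSING_TOKEN)


def read_genotypes(path: str | Path, strict: bool = False) -> GenotypeTable:
    """Read a GeneNetwork-style genotype TSV.

    Metadata lines ``@key: value`` before the header are honoured; ``@cross``
    assigns a single cross label to every strain in the file.  With
    ``strict=False`` unknown allele codes are coerced to missing (U) and
    counted; with ``strict=True`` they raise :class:`ValidationError`.
    """
    meta_lines, body = _strip_header_comments(Path(path))
    meta = {}
    for line in meta_lines:
        if line.startswith("@") and ":" in line:
            key, _, val = line[1:].partition(":")
            meta[key.strip()] = val.strip()
    df = pd.read_csv(_io.StringIO(body), sep="\t", dtype=str)
    required = ["Chr", "Locus", "cM", "Mb"]
    if list(df.columns[:4]) != required:
        raise ValidationError(
            f"genotype file must start with columns {required}, got {list(df.columns[:4])}"
        )
    markers = pd.DataFrame(
        {
            "chromosome": df["Chr"].astype(str).values,
            "cM": df["cM"].astype(float).values,
            "Mb": df["Mb"].astype(float).values,
        },
        index=pd.Index(df["Locus"].values, name="marker"),
    )
    calls = df.iloc[:, 4:].copy()
    calls.index = markers.index
    bad_cells = []
    for col in calls.columns:
        col_vals = calls[col]
        unknown = ~col_vals.isin(sorted(VALID_ALLELE_CODES)) & col_vals.notna()
        if unknown.any():
            for mk in calls.index[unknown]:
                bad_cells.append((mk, col, col_vals.loc[mk]))
    if bad_cells:
        if strict:
            mk, st, val = bad_cells[0]
            raise ValidationError(
                f"unknown genotype call {val!r} at marker {mk}, strain {st}"
                f" ({len(bad_cells)} bad cells total)"
            )
        for mk, st, _ in bad_cells:
            calls.loc[mk, st] = "U"
    cross = None
    if "cross" in meta:
        cross = pd.Series(meta["cross"], index=calls.columns)
    return GenotypeTable(markers, calls, cross)


def write_genotypes(
    geno: GenotypeTable, path: str | Path, header_comment: str | None = None
) -> None:
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        if geno.cross is not None and geno.cross.nunique() == 1:
            fh.write(f"@cross: {geno.cross.iloc[0]}\n")
        out = pd.DataFrame(
            {
                "Chr": geno.markers["chromosome"].values,
                "Locus": geno.markers.index,
                "cM": geno.markers["cM"].values,
                "Mb": geno.markers["Mb"].values,
            }
        )
        calls = geno.calls.reset_index(drop=True).fillna("U")
        out = pd.concat([out, calls], axis=1)
        out.to_csv(fh, sep="\t", index=False)


def read_traits(path: str | Path) -> TraitTable:
    """Read a strain-level trait CSV (strain column + one column per trait)."""
    _, body = _strip_header_comments(Path(path))
    df = pd.read_csv(_io.StringIO(body), index_col=0)
    return TraitTable(df)


def write_traits(
    traits: TraitTable, path: str | Path, header_comment: str | None = None
) -> None:
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        traits.values.to_csv(fh, index_label="strain", na_rep=MISSING_TOKEN)


def read_replicate_traits(path: str | Path) -> pd.DataFrame:
    """Read a replicate-level trait CSV with columns strain, mouse_id, traits."""
    _, body = _strip_header_comments(Path(path))
    df = pd.read_csv(_io.StringIO(body))
    if "strain" not in df.columns:
        raise ValidationError("replicate trait file needs a 'strain' column")
    return df
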