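"""File formats, run configuration and logging.

All on-disk formats are delimited text (TSV by default) so that inputs and
results stay inspectable at desk scale.  Genotypes are allele dosages
(0/1/2 copies of the B allele of an Illumina A/B-style panel); a reader for
PLINK ``.raw``-style dosage exports is provided as a dialect since that is
the de-facto dosage interchange format.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("fatscan")

MISSING_CODES = {"NA", "-9", ".", "NaN", "nan", ""}

#: fixed-effect covariates measured on every analyzed animal: subcutaneous
#: fat thickness, longissimus muscle area, hot carcass weight, chemically
#: extracted fat.
COVARIATE_COLUMNS = ("fat_thickness", "lma", "hcw", "extracted_fat")


class FormatError(ValueError):
    """Raised when an input file violates its schema."""


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Animals x SNPs dosage matrix (number of B alleles, 0/1/2).

    ``dosages`` is float64 with NaN marking missing calls; use
    :func:`mean_impute` before analysis.
    """

    animal_ids: list[str]
    snp_ids: list[str]
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, m = self.dosages.shape
        if n != len(self.animal_ids) or m != len(self.snp_ids):
            raise FormatError(
                f"dosage matrix {self.dosages.shape} inconsistent with "
                f"{len(self.animal_ids)} animals / {len(self.snp_ids)} SNPs"
            )
        if len(set(self.animal_ids)) != n:
            raise FormatError("duplicate animal ids")
        if len(set(self.snp_ids)) != m:
            raise FormatError("duplicate SNP ids")
        vals = self.dosages[~np.isnan(self.dosages)]
        bad = ~np.isin(vals, (0.0, 1.0, 2.0))
        if bad.any():
            raise FormatError(
                f"{bad.sum()} dosage entries outside {{0,1,2}} "
                f"(first offending value: {vals[bad][0]!r})"
            )

    @property
    def n_animals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def allele_frequencies(self) -> np.ndarray:
        """Observed B-allele frequency per SNP (missing entries ignored)."""
        return np.nanmean(self.dosages, axis=0) / 2.0


def mean_impute(genos: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing dosages by the SNP mean (2p̂), preserving frequency."""
    Z = genos.dosages
    if not np.isnan(Z).any():
        return genos
    Z = Z.copy()
    col_mean = np.nanmean(Z, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)  # all-missing SNP
    idx = np.where(np.isnan(Z))
    Z[idx] = col_mean[idx[1]]
    out = GenotypeMatrix.__new__(GenotypeMatrix)
    out.animal_ids = list(genos.animal_ids)
    out.snp_ids = list(genos.snp_ids)
    out.dosages = Z
    return out


@dataclass
class MarkerMap:
    """Per-SNP chromosome and bp position; unmapped SNPs allowed.

    Backed by a DataFrame with columns ``snp_id``, ``chrom`` (string label or
    NaN) and ``pos_bp`` (float, NaN when unmapped).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"snp_id", "chrom", "pos_bp"}
        if not required.issubset(self.table.columns):
            raise FormatError(f"marker map needs columns {sorted(required)}")
        if self.table["snp_id"].duplicated().any():
            raise FormatError("duplicate SNP ids in marker map")
        pos = self.table["pos_bp"]
        if (pos.dropna() < 0).any():
            raise FormatError("negative bp positions in marker map")

    def aligned_to(self, snp_ids: Sequence[str]) -> "MarkerMap":
        """Reindex to ``snp_ids``; SNPs absent from the map become unmapped."""
        tab = self.table.set_index("snp_id").reindex(snp_ids)
        n_missing = int(tab["chrom"].isna().sum() - self.table["chrom"].isna().sum())
        if n_missing > 0:
            logger.warning(
                "%d genotyped SNPs absent from the map; assigned to the "
                "unmapped window", n_missing,
            )
        return MarkerMap(tab.reset_index())


@dataclass
class TraitTable:
    """Per-animal phenotypes, contemporary group and covariates."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        cols = set(self.table.columns)
        if "animal_id" not in cols:
            raise FormatError("trait table needs an 'animal_id' column")
        if "contemporary_group" not in cols:
            raise FormatError("trait table needs a 'contemporary_group' column")

    @property
    def trait_names(self) -> list[str]:
        reserved = {"animal_id", "contemporary_group", *COVARIATE_COLUMNS}
        return [c for c in self.table.columns if c not in reserved]


@dataclass
class RunConfig:
    """MCMC and analysis settings.

    Defaults mirror the study protocol: mixture probability ``pi`` = 0.999,
    41,040 Gibbs iterations with burn-in and a thinning interval of 40 so
    that exactly 1,000 post-burn-in samples are stored, 1-Mb windows and a
    strict PPI > 0.90 significance rule.  Burn-in is 1,040 iterations: the
    stated 40,000 post-burn-in iterations at thin 40 yield the stated 1,000
    stored samples only if (n_iter - n_burn) is an exact multiple of 40.
    """

    pi: float = 0.999
    n_iter: int = 41_040
    n_burn: int = 1_040
    thin: int = 40
    nu_u: float = 4.0
    nu_e: float = 10.0
    seed: int = 0
    basis: str = "fat_percent"
    window_size_bp: int = 1_000_000
    ppi_threshold: float = 0.90
    n_clusters: int = 6
    n_folds: int = 5
    kmeans_restarts: int = 25
    elicit_pi: float = 0.95
    elicit_n_iter: int = 2_000
    elicit_n_burn: int = 500
    elicit_thin: int = 5

    def __post_init__(self) -> None:
        if not 0.0 <= self.pi <= 1.0:
            raise ValueError("pi must lie in [0, 1]")
        if self.n_burn >= self.n_iter:
            raise ValueError("n_burn must be < n_iter")
        if (self.n_iter - self.n_burn) % self.thin != 0:
            raise ValueError("(n_iter - n_burn) must be divisible by thin")
        if self.basis not in ("beef", "fat_percent"):
            raise ValueError("basis must be 'beef' or 'fat_percent'")

    @property
    def n_stored(self) -> int:
        return (self.n_iter - self.n_burn) // self.thin

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _sniff_sep(path: Path) -> str | None:
    first = path.open().readline()
    if "\t" in first:
        return "\t"
    if "," in first:
        return ","
    return None  # whitespace


def read_genotypes(path: str | Path, dialect: str = "auto") -> GenotypeMatrix:
    """Read a dosage matrix from TSV/CSV or a PLINK ``.raw``-style export.

    Plain format: first column holds animal ids, header row holds SNP ids.
    PLINK ``.raw`` dialect: leading FID/IID/PAT/MAT/SEX/PHENOTYPE columns,
    SNP headers suffixed with the counted allele (``rs123_A``).
    """
    path = Path(path)
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep if sep else r"\s+", dtype=str,
                     engine="c" if sep else "python")
    if dialect == "auto":
        plink_lead = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
        dialect = "raw" if list(df.columns[:6]) == plink_lead else "tsv"
    if dialect == "raw":
        animal_ids = df["IID"].tolist()
        geno = df.iloc[:, 6:]
        snp_ids = [re.sub(r"_[ACGT0-9]+$", "", c) for c in geno.columns]
    else:
        animal_ids = df.iloc[:, 0].tolist()
        geno = df.iloc[:, 1:]
        snp_ids = list(geno.columns)

    arr = geno.to_numpy()
    flat = arr.ravel()
    mask = np.isin(flat, list(MISSING_CODES))
    numeric = np.full(flat.shape, np.nan)
    try:
        numeric[~mask] = flat[~mask].astype(float)
    except ValueError as exc:
        raise FormatError(f"non-numeric dosage in {path.name}: {exc}") from exc
    dosages = numeric.reshape(arr.shape)

    bad = np.argwhere(~np.isnan(dosages) & ~np.isin(dosages, (0.0, 1.0, 2.0)))
    if bad.size:
        i, j = bad[0]
        raise FormatError(
            f"{path.name}: dosage {dosages[i, j]!r} outside {{0,1,2}} at "
            f"animal {animal_ids[i]!r}, SNP {snp_ids[j]!r}"
        )
    return GenotypeMatrix(animal_ids, snp_ids, dosages)


def read_marker_map(path: str | Path) -> MarkerMap:
    path = Path(path)
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep if sep else r"\s+",
                     engine="c" if sep else "python",
                     na_values=sorted(MISSING_CODES), keep_default_na=True)
    ren = {}
    for col in df.columns:
        lc = col.lower()
        if lc in ("snp", "snp_id", "marker", "name"):
            ren[col] = "snp_id"
        elif lc in ("chrom", "chr", "chromosome", "bta"):
            ren[col] = "chrom"
        elif lc in ("pos", "pos_bp", "position", "bp", "position_bp"):
            ren[col] = "pos_bp"
    df = df.rename(columns=ren)
    if not {"snp_id", "chrom", "pos_bp"}.issubset(df.columns):
        raise FormatError(
            f"{path.name}: expected columns snp_id, chrom, pos_bp "
            f"(got {list(df.columns)})"
        )
    # pandas reads integer chromosomes as floats when NaNs are present
    def _norm_chrom(c):
        if pd.isna(c):
            return None
        if isinstance(c, float) and c.is_integer():
            return str(int(c))
        return str(c)

    df["chrom"] = [_norm_chrom(c) for c in df["chrom"]]
    df["pos_bp"] = pd.to_numeric(df["pos_bp"], errors="coerce").astype(float)
    return MarkerMap(df[["snp_id", "chrom", "pos_bp"]])


def read_traits(path: str | Path) -> TraitTable:
    path = Path(path)
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep if sep else r"\s+",
                     engine="c" if sep else "python",
                     na_values=sorted(MISSING_CODES), keep_default_na=True)
    df = df.rename(columns={df.columns[0]: "animal_id"}
                   if df.columns[0].lower() in ("animal", "id", "animal_id")
                   else {})
    if "animal_id" not in df.columns or "contemporary_group" not in df.columns:
        raise FormatError(
            f"{path.name}: trait table must contain 'animal_id' and "
            f"'contemporary_group' columns (got {list(df.columns)})"
        )
    df["animal_id"] = df["animal_id"].astype(str)
    df["contemporary_group"] = df["contemporary_group"].astype(str)
    return TraitTable(df)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path: str | Path,
                float_format: str = "%.10g") -> None:
    """Write a result table as TSV, losslessly round-trippable by read_table."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format=float_format)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_genotypes(genos: GenotypeMatrix, path: str | Path) -> None:
    df = pd.DataFrame(genos.dosages, columns=genos.snp_ids)
    df = df.astype(object).where(~df.isna(), "NA")
    df.insert(0, "animal_id", genos.animal_ids)
    # dosages are small integers; avoid '1.0'
    for c in genos.snp_ids:
        df[c] = [("NA" if v == "NA" else str(int(v))) for v in df[c]]
    df.to_csv(path, sep="\t", index=False)


def write_marker_map(mmap: MarkerMap, path: str | Path) -> None:
    tab = mmap.table.copy()
    tab["chrom"] = [c if c is not None else "NA" for c in tab["chrom"]]
    tab["pos_bp"] = [("NA" if pd.isna(p) else str(int(p))) for p in tab["pos_bp"]]
    tab.to_csv(path, sep="\t", index=False)


def write_traits(traits: TraitTable, path: str | Path) -> None:
    write_table(traits.table, path)


def configure_logging(level: int = logging.INFO) -> None:
    """Attach a plain stderr handler to the package logger (idempotent)."""
    if not logger.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
        logger.addHandler(handler)
    logger.setLevel(level)
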