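"""Readers and writers for the plain-text formats the pipeline touches.

Genotypes arrive either as a PLINK additive ``.raw`` file plus a ``.map``,
or as a plain TSV matrix (sires x SNPs) plus the same ``.map``.  Phenotypes
are a TSV of progeny records.  All results are written as TSV tables with a
JSON manifest so a run can be reconstructed bit-stably.

Missing genotype calls are kept as NaN throughout; nothing here imputes.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: columns a phenotype file must provide
PHENO_COLUMNS = ["animal_id", "sire_id", "cg", "sex", "age", "y"]

#: significant digits used for all floating-point table output
FLOAT_FORMAT = "%.12g"


class FormatError(ValueError):
    """A file does not conform to the expected dialect."""


def _read_map(path: Path) -> pd.DataFrame:
    """Read a PLINK-style map: chromosome, snp_id, [cM,] bp (whitespace)."""
    try:
        raw = pd.read_csv(path, sep=r"\s+", header=None, dtype=str, comment="#")
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"empty map: {path}") from exc
    if raw.empty:
        raise FormatError(f"empty map: {path}")
    if raw.shape[1] == 4:  # chr snp cM bp
        snp_map = pd.DataFrame(
            {"snp_id": raw[1], "chromosome": raw[0], "bp": raw[3]}
        )
    elif raw.shape[1] == 3:  # chr snp bp
        snp_map = pd.DataFrame(
            {"snp_id": raw[1], "chromosome": raw[0], "bp": raw[2]}
        )
    else:
        raise FormatError(f"map must have 3 or 4 columns, got {raw.shape[1]}: {path}")
    try:
        snp_map["chromosome"] = snp_map["chromosome"].astype(int)
        snp_map["bp"] = snp_map["bp"].astype(int)
    except ValueError as exc:
        raise FormatError(f"non-integer chromosome/bp in map {path}: {exc}") from exc
    if snp_map["snp_id"].duplicated().any():
        dup = snp_map.loc[snp_map["snp_id"].duplicated(), "snp_id"].iloc[0]
        raise FormatError(f"duplicate SNP id in map: {dup}")
    return snp_map.reset_index(drop=True)


@dataclass
class GenotypeMatrix:
    """Sires x SNPs additive genotype codes with a physical SNP map.

    ``codes[i, j]`` counts copies of the B allele (0/1/2) for sire *i* at
    SNP *j*; missing calls are ``NaN``.  The map gives 1-based physical
    positions used downstream to define non-overlapping 1-Mb windows.
    """

    sire_ids: list[str]
    snp_map: pd.DataFrame  # columns: snp_id, chromosome, bp
    codes: np.ndarray  # float array, shape (n_sires, n_snps), NaN = missing

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=float)
        if len(self.snp_map) == 0:
            raise FormatError("empty map")
        if self.codes.shape != (len(self.sire_ids), len(self.snp_map)):
            raise FormatError(
                f"codes shape {self.codes.shape} does not match "
                f"{len(self.sire_ids)} sires x {len(self.snp_map)} SNPs"
            )
        valid = np.isnan(self.codes) | np.isin(self.codes, (0.0, 1.0, 2.0))
        if not valid.all():
            bad = self.codes[~valid].flat[0]
            raise FormatError(f"non-{{0,1,2,NA}} genotype code: {bad!r}")
        if self.snp_map["snp_id"].duplicated().any():
            raise FormatError("duplicate SNP id in map")

    @property
    def n_sires(self) -> int:
        return len(self.sire_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_map)

    @property
    def call_rate(self) -> np.ndarray:
        """Per-sire fraction of non-missing calls."""
        return 1.0 - np.isnan(self.codes).mean(axis=1)

    def subset(self, sire_mask=None, snp_mask=None) -> "GenotypeMatrix":
        """Return a copy restricted to the selected sires and/or SNPs."""
        sire_mask = np.ones(self.n_sires, bool) if sire_mask is None else np.asarray(sire_mask)
        snp_mask = np.ones(self.n_snps, bool) if snp_mask is None else np.asarray(snp_mask)
        return GenotypeMatrix(
            sire_ids=[s for s, keep in zip(self.sire_ids, sire_mask) if keep],
            snp_map=self.snp_map.loc[snp_mask].reset_index(drop=True),
            codes=self.codes[np.ix_(sire_mask, snp_mask)],
        )


def read_genotypes(path: str | Path, dialect: str = "tsv", map_path: str | Path | None = None) -> GenotypeMatrix:
    """Read a genotype matrix in one of two dialects.

    Parameters
    ----------
    path
        The matrix file: a PLINK additive ``.raw`` (``dialect="plink_raw"``)
        or a TSV with a ``sire_id`` column followed by one column per SNP
        (``dialect="tsv"``).
    dialect
        ``"plink_raw"`` or ``"tsv"``.
    map_path
        The SNP map.  Defaults to ``path`` with its suffix replaced by
        ``.map``.
    """
    path = Path(path)
    if map_path is None:
        map_path = path.with_suffix(".map")
    snp_map = _read_map(Path(map_path))

    if dialect == "plink_raw":
        df = pd.read_csv(path, sep=r"\s+", dtype=str)
        meta_cols = [c for c in ("FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE") if c in df.columns]
        if "IID" not in df.columns:
            raise FormatError(f"not a PLINK .raw file (no IID column): {path}")
        sire_ids = df["IID"].tolist()
        snp_cols = [c for c in df.columns if c not in meta_cols]
        # .raw headers are '<snp>_<counted allele>'; strip the allele suffix
        snp_ids = [c.rsplit("_", 1)[0] if "_" in c else c for c in snp_cols]
        codes_df = df[snp_cols]
    elif dialect == "tsv":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if "sire_id" not in df.columns:
            raise FormatError(f"TSV genotype matrix needs a 'sire_id' column: {path}")
        sire_ids = df["sire_id"].tolist()
        snp_ids = [c for c in df.columns if c != "sire_id"]
        codes_df = df[snp_ids]
    else:
        raise ValueError(f"unknown genotype dialect: {dialect!r}")

    if list(snp_map["snp_id"]) != list(snp_ids):
        if len(snp_ids) != len(snp_map):
            raise FormatError(
                f"matrix has {len(snp_ids)} SNP columns but map has {len(snp_map)} rows"
            )
        raise FormatError("SNP ids in matrix and map disagree (order must match)")

    codes = codes_df.replace({"NA": np.nan, "": np.nan}).to_numpy(dtype=object)
    try:
        codes = codes.astype(float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"non-numeric genotype code in {path}: {exc}") from exc
    geno = GenotypeMatrix(sire_ids=sire_ids, snp_map=snp_map, codes=codes)
    n_missing = int(np.isnan(geno.codes).sum())
    if n_missing:
        logger.info("read_genotypes: %d missing calls flagged (not imputed)", n_missing)
    return geno


def write_genotypes(geno: GenotypeMatrix, path: str | Path, map_path: str | Path | None = None) -> None:
    """Write a TSV genotype matrix plus a 4-column PLINK-style map."""
    path = Path(path)
    if map_path is None:
        map_path = path.with_suffix(".map")
    codes = geno.codes
    df = pd.DataFrame(codes, columns=geno.snp_map["snp_id"])
    # integer codes where called, NA where missing
    df = df.map(lambda v: "NA" if np.isnan(v) else str(int(v)))
    df.insert(0, "sire_id", geno.sire_ids)
    df.to_csv(path, sep="\t", index=False)
    m = geno.snp_map
    pd.DataFrame(
        {0: m["chromosome"], 1: m["snp_id"], 2: 0, 3: m["bp"]}
    ).to_csv(map_path, sep="\t", index=False, header=False)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Read a progeny phenotype TSV.

    Required columns: ``animal_id, sire_id, cg, sex, age, y``.  Rows with a
    missing trait value are dropped and the drop count is logged.
    """
    df = pd.read_csv(Path(path), sep="\t", dtype={"animal_id": str, "sire_id": str, "cg": str, "sex": str})
    missing_cols = [c for c in PHENO_COLUMNS if c not in df.columns]
    if missing_cols:
        raise FormatError(f"phenotype file missing column(s): {', '.join(missing_cols)}")
    for col in ("age", "y"):
        df[col] = pd.to_numeric(df[col], errors="coerce").astype(float)
    if df["age"].isna().any():
        raise FormatError("non-numeric or missing age in phenotype file")
    n0 = len(df)
    df = df.dropna(subset=["y"]).reset_index(drop=True)
    if len(df) < n0:
        logger.info("read_phenotypes: dropped %d record(s) with missing trait value", n0 - len(df))
    if (df["age"] <= 0).any():
        raise FormatError("age must be positive")
    return df[PHENO_COLUMNS]


def write_phenotypes(pheno: pd.DataFrame, path: str | Path) -> None:
    pheno[PHENO_COLUMNS].to_csv(Path(path), sep="\t", index=False, float_format=FLOAT_FORMAT)


def _config_hash(meta: dict) -> str:
    return hashlib.sha256(json.dumps(meta, sort_keys=True, default=str).encode()).hexdigest()[:16]


def write_results(tables: dict[str, pd.DataFrame], out_dir: str | Path, meta: dict | None = None) -> dict:
    """Write named result tables as TSV plus a JSON manifest.

    The manifest records file names, row counts, the package and library
    versions and a hash of ``meta`` (seeds, configuration) so that outputs
    are traceable.  Returns the manifest dict.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta = dict(meta or {})
    files = {}
    for name, table in tables.items():
        fname = f"{name}.tsv"
        table.to_csv(out_dir / fname, sep="\t", index=False, float_format=FLOAT_FORMAT)
        files[name] = {"file": fname, "n_rows": int(len(table))}
    from sirevar import __version__

    manifest = {
        "files": files,
        "meta": meta,
        "config_hash": _config_hash(meta),
        "versions": {
            "sirevar": __version__,
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
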