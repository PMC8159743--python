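"""File input/output for cross data.

Native dialect: three CSV files (comma-separated, UTF-8, ``.`` decimal,
``NA`` for missing — fixed, not sniffed):

* map:       ``marker,chrom,pos_mb,pos_cm``
* genotypes: rows = individuals, first column ``id``, one column per
  marker with codes ``BB``/``BF``/``FF``/``NA`` (``0/1/2`` and ``A/H/B``
  are accepted on read and normalized)
* phenotypes: ``id,generation,sex,diet,<trait columns...>``

An R/qtl-style "csvs" rotated export is also provided: a genotype file
with rows = markers (columns ``marker,chrom,pos_cm`` then one column per
individual, codes A/H/B) next to the phenotype file.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (CODE_STRINGS, CrossDataError, GENO_CODES, GeneticMap,
                         GenotypeMatrix, MISSING, validate_phenotypes)

__all__ = ["read_map", "read_cross", "write_cross", "export_rqtl_csvs", "read_rqtl_csvs"]

_NA = "NA"

# accepted genotype spellings, normalized to the internal integer code
_CODE_ALIASES = {
    "BB": 0, "BF": 1, "FF": 2,
    "0": 0, "1": 1, "2": 2,
    "A": 0, "H": 1, "B": 2,
}


def read_map(path) -> GeneticMap:
    df = pd.read_csv(path, na_values=[_NA, ""], keep_default_na=False, dtype={"chrom": str})
    return GeneticMap(df)


def _normalize_codes(df: pd.DataFrame, markers: list[str], path) -> np.ndarray:
    codes = np.full((len(df), len(markers)), MISSING, dtype=np.int8)
    for j, m in enumerate(markers):
        col = df[m].astype("string").str.strip()
        known = (col.isna() | (col == _NA)).fillna(False).to_numpy(dtype=bool)
        for alias, code in _CODE_ALIASES.items():
            hit = (col == alias).fillna(False).to_numpy(dtype=bool)
            codes[hit, j] = code
            known |= hit
        if not known.all():
            row = int(np.flatnonzero(~known)[0])
            raise CrossDataError(
                f"{path}: unknown genotype code {col.iloc[row]!r} "
                f"at row {row + 2}, column {m!r}")
    return codes


def read_cross(pheno_path, geno_path, map_path) -> tuple[pd.DataFrame, GenotypeMatrix, GeneticMap]:
    """Read and cross-link the three native CSV files.

    Genotype codes are normalized; ids present in the genotype file but
    not the phenotype file (or vice versa) are tolerated but reported via
    the returned objects' id sets.  Duplicate ids, unknown genotype codes
    and markers absent from the map each raise a distinct diagnostic.
    """
    gmap = read_map(map_path)
    pheno = pd.read_csv(pheno_path, na_values=[_NA, ""], keep_default_na=False)
    for col in ("sex", "diet", "generation"):
        if col in pheno.columns:
            pheno[col] = pheno[col].astype("string")
    trait_cols = [c for c in pheno.columns if c not in ("id", "generation", "sex", "diet")]
    for col in trait_cols:
        pheno[col] = pd.to_numeric(pheno[col])
    validate_phenotypes(pheno)
    geno_df = pd.read_csv(geno_path, na_values=[_NA, ""], keep_default_na=False, dtype=str)
    if "id" not in geno_df.columns:
        raise CrossDataError(f"{geno_path}: genotype file lacks an 'id' column")
    if geno_df["id"].duplicated().any():
        dup = geno_df["id"][geno_df["id"].duplicated()].iloc[0]
        raise CrossDataError(f"{geno_path}: duplicate individual id {dup!r}")
    markers = [c for c in geno_df.columns if c != "id"]
    unknown = [m for m in markers if m not in set(gmap.marker_names)]
    if unknown:
        raise CrossDataError(
            f"{geno_path}: markers absent from map: {unknown[:5]}"
            + ("..." if len(unknown) > 5 else ""))
    # marker order is map order, never file order
    ordered = [m for m in gmap.marker_names if m in set(markers)]
    sub_map = gmap.subset(np.isin(gmap.marker_names, ordered))
    codes = _normalize_codes(geno_df, ordered, geno_path)
    geno = GenotypeMatrix(geno_df["id"].to_numpy(), codes, sub_map)
    return pheno, geno, gmap


def write_cross(prefix, pheno: pd.DataFrame, geno: GenotypeMatrix) -> dict:
    """Write pheno/geno/map CSVs under ``<prefix>_{pheno,geno,map}.csv``."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "pheno": prefix.with_name(prefix.name + "_pheno.csv"),
        "geno": prefix.with_name(prefix.name + "_geno.csv"),
        "map": prefix.with_name(prefix.name + "_map.csv"),
    }
    pheno.to_csv(paths["pheno"], index=False, na_rep=_NA)
    geno.to_frame().to_csv(paths["geno"], index=False, na_rep=_NA)
    geno.gmap.df.to_csv(paths["map"], index=False, na_rep=_NA)
    return paths


_RQTL_CODES = np.array(["A", "H", "B"])


def export_rqtl_csvs(prefix, pheno: pd.DataFrame, geno: GenotypeMatrix) -> dict:
    """R/qtl "csvs"-style rotated export (rows = markers, codes A/H/B)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    calls = np.where(geno.codes >= 0,
                     _RQTL_CODES[np.clip(geno.codes, 0, 2)], _NA).T  # (m, n)
    gdf = pd.concat([
        pd.DataFrame({
            "marker": geno.gmap.marker_names,
            "chrom": geno.gmap.df["chrom"],
            "pos_cm": geno.gmap.df["pos_cm"],
        }),
        pd.DataFrame(calls, columns=list(geno.ids)),
    ], axis=1)
    paths = {
        "geno": prefix.with_name(prefix.name + "_rqtl_geno.csv"),
        "pheno": prefix.with_name(prefix.name + "_rqtl_pheno.csv"),
    }
    gdf.to_csv(paths["geno"], index=False, na_rep=_NA)
    pheno.to_csv(paths["pheno"], index=False, na_rep=_NA)
    return paths


def read_rqtl_csvs(geno_path, pheno_path, mb_per_cm: float = 2.0):
    """Read the rotated dialect back into native objects.

    The dialect stores only cM positions; Mb coordinates are restored with
    a constant expansion factor, matching the synthetic map convention.
    """
    gdf = pd.read_csv(geno_path, na_values=[_NA, ""], keep_default_na=False,
                      dtype={"chrom": str})
    pheno = pd.read_csv(pheno_path, na_values=[_NA, ""], keep_default_na=False)
    for col in ("sex", "diet", "generation"):
        if col in pheno.columns:
            pheno[col] = pheno[col].astype("string")
    map_df = gdf[["marker", "chrom", "pos_cm"]].copy()
    map_df["pos_mb"] = map_df["pos_cm"] * mb_per_cm
    gmap = GeneticMap(map_df[["marker", "chrom", "pos_mb", "pos_cm"]])
    ids = [c for c in gdf.columns if c not in ("marker", "chrom", "pos_cm")]
    rotated = gdf[ids].T  # individuals × markers
    rotated.columns = gdf["marker"]
    codes = np.full(rotated.shape, MISSING, dtype=np.int8)
    arr = rotated.to_numpy(dtype=object)
    for alias, code in (("A", 0), ("H", 1), ("B", 2)):
        codes[arr == alias] = code
    bad = ~np.isin(arr, ["A", "H", "B", _NA]) & ~pd.isna(arr)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise CrossDataError(
            f"{geno_path}: unknown genotype code {arr[i, j]!r} for "
            f"individual {ids[i]!r}, marker {rotated.columns[j]!r}")
    return pheno, GenotypeMatrix(np.array(ids), codes, gmap), gmap
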