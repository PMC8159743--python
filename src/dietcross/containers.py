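"""Core data containers shared by all analysis stages.

An F2 intercross dataset is held in three linked objects:

* :class:`GeneticMap` — ordered markers with chromosome, physical (Mb) and
  genetic (cM) coordinates;
* :class:`GenotypeMatrix` — individuals × markers, three genotype classes
  (``BB``/``BF``/``FF``, i.e. 0/1/2 copies of the FVB allele) plus missing;
* a phenotype table, which is a plain :class:`pandas.DataFrame` with the
  reserved columns ``id``, ``generation``, ``sex``, ``diet`` and one column
  per quantitative trait (see :func:`validate_phenotypes`).

Genotypes are stored internally as ``int8`` codes (-1 = missing, 0 = BB,
1 = BF, 2 = FF) so that genome scans can operate on dense numpy arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: canonical string codes, indexed by the internal integer code
CODE_STRINGS = np.array(["BB", "BF", "FF"])
GENO_CODES = {"BB": 0, "BF": 1, "FF": 2}
MISSING = -1

#: columns every phenotype table carries in addition to trait columns
PHENO_ID_COLS = ["id", "generation", "sex", "diet"]

SEXES = ("F", "M")
DIETS = ("american", "ketogenic")


class CrossDataError(ValueError):
    """Raised when phenotype/genotype/map inputs violate their contracts."""


@dataclass(frozen=True)
class GeneticMap:
    """Ordered marker map.

    ``df`` has columns ``marker``, ``chrom``, ``pos_mb``, ``pos_cm`` and is
    sorted by (chromosome, cM position); marker names are unique.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["marker", "chrom", "pos_mb", "pos_cm"]
        missing = [c for c in required if c not in self.df.columns]
        if missing:
            raise CrossDataError(f"genetic map lacks columns {missing}")
        names = self.df["marker"]
        if names.duplicated().any():
            dup = names[names.duplicated()].iloc[0]
            raise CrossDataError(f"duplicate marker name {dup!r} in map")
        if (self.df["pos_cm"] < 0).any() or (self.df["pos_mb"] < 0).any():
            raise CrossDataError("marker positions must be non-negative")
        for _, grp in self.df.groupby("chrom", sort=False):
            if not grp["pos_cm"].is_monotonic_increasing:
                raise CrossDataError("cM positions must be non-decreasing within chromosome")
        object.__setattr__(self, "df", self.df.reset_index(drop=True))

    @property
    def n_markers(self) -> int:
        return len(self.df)

    @property
    def marker_names(self) -> np.ndarray:
        return self.df["marker"].to_numpy()

    @property
    def chroms(self) -> list:
        """Chromosome labels in map order."""
        return list(dict.fromkeys(self.df["chrom"]))

    def index_of(self, marker: str) -> int:
        idx = np.flatnonzero(self.marker_names == marker)
        if idx.size == 0:
            raise KeyError(f"marker {marker!r} not in map")
        return int(idx[0])

    def subset(self, keep: np.ndarray) -> "GeneticMap":
        """Subset by boolean mask or list of marker names, preserving order."""
        if isinstance(keep, np.ndarray) and keep.dtype == bool:
            return GeneticMap(self.df.loc[keep].reset_index(drop=True))
        keep_set = set(keep)
        mask = self.df["marker"].isin(keep_set).to_numpy()
        return GeneticMap(self.df.loc[mask].reset_index(drop=True))


@dataclass
class GenotypeMatrix:
    """Individuals × markers genotype calls tied to a :class:`GeneticMap`."""

    ids: np.ndarray
    codes: np.ndarray  # (n_individuals, n_markers) int8; -1 missing
    gmap: GeneticMap

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.ndim != 2:
            raise CrossDataError("genotype codes must be 2-D")
        if self.codes.shape != (len(self.ids), self.gmap.n_markers):
            raise CrossDataError(
                f"genotype shape {self.codes.shape} does not match "
                f"{len(self.ids)} individuals × {self.gmap.n_markers} markers"
            )
        if len(set(self.ids)) != len(self.ids):
            raise CrossDataError("duplicate individual ids in genotype matrix")
        bad = ~np.isin(self.codes, [-1, 0, 1, 2])
        if bad.any():
            raise CrossDataError("genotype codes must be in {-1, 0, 1, 2}")

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_markers(self) -> int:
        return self.gmap.n_markers

    def column(self, marker: str) -> np.ndarray:
        """Integer codes for one marker, aligned to ``self.ids``."""
        return self.codes[:, self.gmap.index_of(marker)]

    def subset_markers(self, keep) -> "GenotypeMatrix":
        if isinstance(keep, np.ndarray) and keep.dtype == bool:
            mask = keep
        else:
            mask = np.isin(self.gmap.marker_names, list(keep))
        return GenotypeMatrix(self.ids, self.codes[:, mask], self.gmap.subset(mask))

    def subset_individuals(self, ids) -> "GenotypeMatrix":
        order = {v: i for i, v in enumerate(self.ids)}
        try:
            rows = np.array([order[i] for i in ids])
        except KeyError as exc:
            raise CrossDataError(f"individual {exc.args[0]!r} not genotyped") from None
        return GenotypeMatrix(np.asarray(ids), self.codes[rows], self.gmap)

    def aligned_codes(self, ids) -> np.ndarray:
        """Codes re-ordered to ``ids`` (all of which must be present)."""
        order = {v: i for i, v in enumerate(self.ids)}
        rows = np.array([order[i] for i in ids])
        return self.codes[rows]

    def to_frame(self) -> pd.DataFrame:
        """String-coded frame (first column ``id``; NA for missing)."""
        strings = np.where(self.codes >= 0, CODE_STRINGS[np.clip(self.codes, 0, 2)], "NA")
        out = pd.DataFrame(strings, columns=self.gmap.marker_names)
        out.insert(0, "id", self.ids)
        return out

    @classmethod
    def from_frame(cls, df: pd.DataFrame, gmap: GeneticMap) -> "GenotypeMatrix":
        if "id" not in df.columns:
            raise CrossDataError("genotype table must have an 'id' column")
        markers = [c for c in df.columns if c != "id"]
        extra = [m for m in markers if m not in set(gmap.marker_names)]
        if extra:
            raise CrossDataError(f"genotyped markers absent from map: {extra[:5]}")
        # map order, never file order
        ordered = [m for m in gmap.marker_names if m in set(markers)]
        sub = gmap.subset(np.isin(gmap.marker_names, ordered))
        codes = np.full((len(df), len(ordered)), MISSING, dtype=np.int8)
        for j, m in enumerate(ordered):
            col = df[m].astype("string")
            for s, code in GENO_CODES.items():
                codes[(col == s).fillna(False).to_numpy(dtype=bool), j] = code
            known = (col.isna() | col.isin(list(GENO_CODES) + ["NA"])).fillna(
                False).to_numpy(dtype=bool)
            if not known.all():
                row = int(np.flatnonzero(~known)[0])
                raise CrossDataError(
                    f"unknown genotype code {col.iloc[row]!r} at row {row}, marker {m!r}"
                )
        return cls(df["id"].to_numpy(), codes, sub)


def validate_phenotypes(pheno: pd.DataFrame, traits: list[str] | None = None) -> list[str]:
    """Check a phenotype table and return its trait columns.

    F2 rows must carry non-missing sex and diet; ids must be unique.
    """
    for col in PHENO_ID_COLS:
        if col not in pheno.columns:
            raise CrossDataError(f"phenotype table lacks column {col!r}")
    if pheno["id"].duplicated().any():
        raise CrossDataError("duplicate individual ids in phenotype table")
    f2 = pheno["generation"] == "F2"
    if pheno.loc[f2, ["sex", "diet"]].isna().any().any():
        raise CrossDataError("F2 rows must have non-missing sex and diet")
    found = [c for c in pheno.columns if c not in PHENO_ID_COLS]
    if traits is not None:
        missing = [t for t in traits if t not in found]
        if missing:
            raise CrossDataError(f"traits not in phenotype table: {missing}")
        return traits
    return found
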