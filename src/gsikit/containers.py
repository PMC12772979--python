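"""Core tabular containers shared across the pipeline.

All containers are thin wrappers around long-format pandas DataFrames with a
fixed column vocabulary, so that every stage can round-trip through plain CSV
and user-supplied tables (e.g. ANGSD-derived FST tables) can be dropped in.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

GENOTYPE_COLUMNS = ["indiv", "collection", "repunit", "locus", "allele_1", "allele_2"]
READS_COLUMNS = ["indiv", "locus", "haplotype", "depth"]
LANDSCAPE_COLUMNS = ["locus", "chrom", "pos", "pair_id", "fst"]


def canonical_pair_id(a: str, b: str) -> str:
    """Unordered collection pair encoded as a sorted 'A|B' string."""
    if a == b:
        raise ValueError(f"pair members must differ, got {a!r} twice")
    lo, hi = sorted([str(a), str(b)])
    return f"{lo}|{hi}"


def all_pairs(collections: list[str]) -> list[str]:
    """Canonical ids for every unordered pair of collections.

    For the 11-collection baseline this yields the 55 pairwise comparisons
    over which per-locus FST is computed.
    """
    names = sorted(set(map(str, collections)))
    if len(names) < len(collections):
        raise ValueError("collection names must be unique")
    return [
        canonical_pair_id(names[i], names[j])
        for i in range(len(names))
        for j in range(i + 1, len(names))
    ]


@dataclass
class GenotypeTable:
    """Diploid multi-allelic genotypes in long format.

    ``data`` columns: indiv, collection, repunit, locus, allele_1, allele_2.
    A missing genotype is either an absent (indiv, locus) row or a row whose
    allele columns are NaN; both conventions are accepted on input and
    normalised to absent rows plus the ``loci`` panel for call-rate math.

    ``loci`` (optional) carries per-locus chromosome/position metadata and, when
    present, defines the panel against which call rates are computed.

    ``true_origin`` (optional) maps simulated individuals to their true source
    collection; it is held separately so assignment accuracy can be scored
    without leaking truth into the genotype table itself.
    """

    data: pd.DataFrame
    loci: pd.DataFrame | None = None
    true_origin: pd.Series | None = None

    def __post_init__(self) -> None:
        missing = [c for c in GENOTYPE_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"genotype table missing columns: {missing}")
        self.data = self.data[GENOTYPE_COLUMNS].copy()
        dup = self.data.duplicated(subset=["indiv", "locus"])
        if dup.any():
            bad = self.data.loc[dup, ["indiv", "locus"]].iloc[0]
            raise ValueError(
                f"duplicate (indiv, locus) entry: ({bad['indiv']}, {bad['locus']})"
            )
        if self.loci is not None:
            for c in ("locus", "chrom", "pos"):
                if c not in self.loci.columns:
                    raise ValueError(f"loci metadata missing column {c!r}")
            self.loci = self.loci[["locus", "chrom", "pos"]].reset_index(drop=True)

    # -- panel geometry ---------------------------------------------------

    @property
    def locus_names(self) -> list[str]:
        if self.loci is not None:
            return list(self.loci["locus"])
        return sorted(self.data["locus"].unique())

    @property
    def individuals(self) -> list[str]:
        return list(pd.unique(self.data["indiv"]))

    @property
    def collections(self) -> list[str]:
        return sorted(self.data["collection"].dropna().unique())

    def called(self) -> pd.DataFrame:
        """Rows with a called (non-missing) genotype."""
        ok = self.data["allele_1"].notna() & self.data["allele_2"].notna()
        return self.data[ok]

    def repunit_map(self) -> dict[str, str]:
        sub = self.data[["collection", "repunit"]].dropna().drop_duplicates()
        return dict(zip(sub["collection"], sub["repunit"]))

    # -- I/O ---------------------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, loci: pd.DataFrame | None = None) -> "GenotypeTable":
        df = pd.read_csv(path, dtype={"allele_1": "string", "allele_2": "string"})
        missing = [c for c in GENOTYPE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing columns {missing}")
        df["allele_1"] = df["allele_1"].astype(object).where(df["allele_1"].notna(), np.nan)
        df["allele_2"] = df["allele_2"].astype(object).where(df["allele_2"].notna(), np.nan)
        return cls(df, loci=loci)

    def subset_loci(self, loci: list[str]) -> "GenotypeTable":
        keep = set(loci)
        meta = None
        if self.loci is not None:
            meta = self.loci[self.loci["locus"].isin(keep)].reset_index(drop=True)
        return GenotypeTable(
            self.data[self.data["locus"].isin(keep)].reset_index(drop=True),
            loci=meta,
            true_origin=self.true_origin,
        )


@dataclass
class HaplotypeReadTable:
    """Per-individual, per-locus haplotype read depths (microhaplot style)."""

    data: pd.DataFrame
    collections: pd.DataFrame | None = None  # indiv, collection, repunit
    loci: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        missing = [c for c in READS_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"read table missing columns: {missing}")
        self.data = self.data[READS_COLUMNS].copy()
        if (self.data["depth"] < 0).any():
            raise ValueError("read depths must be non-negative")

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, **kw) -> "HaplotypeReadTable":
        return cls(pd.read_csv(path), **kw)


@dataclass
class FSTLandscape:
    """Per-locus, per-population-pair FST values with genomic coordinates.

    Long format (locus, chrom, pos, pair_id, fst); ``wide()`` pivots to a
    locus x pair matrix. ``chrom_lengths`` maps chromosome -> length in bp and
    is required by windowed panel selection.
    """

    data: pd.DataFrame
    chrom_lengths: dict[str, int] | None = None

    def __post_init__(self) -> None:
        missing = [c for c in LANDSCAPE_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"FST landscape missing columns: {missing}")
        self.data = self.data[LANDSCAPE_COLUMNS].copy()
        if (self.data["fst"] > 1 + 1e-12).any():
            raise ValueError("FST values must be <= 1")

    @property
    def pairs(self) -> list[str]:
        return sorted(self.data["pair_id"].unique())

    def loci_meta(self) -> pd.DataFrame:
        return (
            self.data[["locus", "chrom", "pos"]]
            .drop_duplicates("locus")
            .reset_index(drop=True)
        )

    def wide(self) -> pd.DataFrame:
        """Locus x pair FST matrix (index: locus; columns: pair ids)."""
        return self.data.pivot(index="locus", columns="pair_id", values="fst")

    def max_fst(self) -> pd.DataFrame:
        """Per locus: max FST over pairs and the pair achieving it.

        Ties in the argmax go to the lexicographically first pair id.
        """
        wide = self.wide().sort_index(axis=1)
        vals = wide.to_numpy(dtype=float)
        # NaN-safe argmax; all-NaN loci get score NaN
        best = np.full(vals.shape[0], np.nan)
        best_pair = np.full(vals.shape[0], None, dtype=object)
        ok = ~np.all(np.isnan(vals), axis=1)
        if ok.any():
            idx = np.nanargmax(vals[ok], axis=1)
            best[ok] = vals[ok, idx]
            best_pair[ok] = wide.columns.to_numpy()[idx]
        out = self.loci_meta().set_index("locus")
        out = out.loc[wide.index]
        out["score"] = best
        out["attributed_pair"] = best_pair
        return out.reset_index()

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(
        cls, path: str | Path, chrom_lengths: dict[str, int] | None = None
    ) -> "FSTLandscape":
        return cls(pd.read_csv(path), chrom_lengths=chrom_lengths)


def read_chrom_lengths(path: str | Path) -> dict[str, int]:
    """Read a two-column (chrom, length) TSV into a dict."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"], comment="#")
    return dict(zip(df["chrom"].astype(str), df["length"].astype(int)))
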