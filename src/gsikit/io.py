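"""Readers and writers for genotype tables.

Long-format CSV is the canonical interchange (columns indiv, collection,
repunit, locus, allele_1, allele_2). VCF is supported for genotype ingest and
optional export of simulated tables; multi-allelic records map one-to-one to
microhaplotype loci, with allele sequences as REF/ALT. VCF positions are
1-based on disk and 0-based in the internal loci table.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .containers import GENOTYPE_COLUMNS, GenotypeTable


def read_sample_map(path: str | Path) -> pd.DataFrame:
    """Sidecar CSV mapping sample -> collection (and optionally repunit)."""
    df = pd.read_csv(path)
    if "indiv" not in df.columns or "collection" not in df.columns:
        raise ValueError(f"{path}: sample map needs 'indiv' and 'collection' columns")
    if "repunit" not in df.columns:
        df["repunit"] = df["collection"]
    return df[["indiv", "collection", "repunit"]]


def _validate_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in GENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    bad = df.index[(df["indiv"] == "") | (df["locus"] == "")]
    if len(bad):
        lines = [i + 2 for i in bad[:5]]  # +2: header and 1-based lines
        raise ValueError(f"{path}: malformed rows at lines {lines}")
    for col in ("allele_1", "allele_2"):
        df[col] = df[col].replace({"": np.nan, ".": np.nan, "NA": np.nan})
    return df


def read_genotypes(
    path: str | Path,
    format: str = "csv",
    sample_map: pd.DataFrame | str | Path | None = None,
    loci: pd.DataFrame | None = None,
) -> GenotypeTable:
    """Read a genotype table from long CSV or (multi-allelic) VCF."""
    if isinstance(sample_map, (str, Path)):
        sample_map = read_sample_map(sample_map)
    if format == "csv":
        df = _validate_csv(path)
        if sample_map is not None:
            df = df.drop(columns=["collection", "repunit"]).merge(
                sample_map, on="indiv", how="left"
            )
        return GenotypeTable(df[GENOTYPE_COLUMNS], loci=loci)
    if format != "vcf":
        raise ValueError(f"unknown format {format!r}")
    rows = []
    loci_rows = []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            locus = rec.id or f"{rec.chrom}_{rec.pos}"
            alleles = list(rec.alleles)
            loci_rows.append({"locus": locus, "chrom": rec.chrom, "pos": rec.pos - 1})
            for s in samples:
                gt = rec.samples[s].get("GT", (None, None))
                if gt is None or None in gt:
                    a1 = a2 = np.nan
                else:
                    a1, a2 = alleles[gt[0]], alleles[gt[1]]
                rows.append(
                    {"indiv": s, "collection": "", "repunit": "",
                     "locus": locus, "allele_1": a1, "allele_2": a2}
                )
    df = pd.DataFrame(rows, columns=GENOTYPE_COLUMNS)
    if sample_map is not None:
        df = df.drop(columns=["collection", "repunit"]).merge(
            sample_map, on="indiv", how="left"
        )
    return GenotypeTable(df[GENOTYPE_COLUMNS], loci=pd.DataFrame(loci_rows))


def write_genotypes(table: GenotypeTable, path: str | Path, format: str = "csv") -> None:
    """Write a genotype table as long CSV or multi-allelic VCF."""
    if format == "csv":
        table.to_csv(path)
        return
    if format != "vcf":
        raise ValueError(f"unknown format {format!r}")
    if table.loci is None:
        raise ValueError("VCF export needs loci metadata (chrom, pos)")
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for chrom, grp in table.loci.groupby("chrom"):
        header.contigs.add(str(chrom), length=int(grp["pos"].max()) + 1000)
    indivs = table.individuals
    for s in indivs:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for row in table.loci.sort_values(["chrom", "pos"]).itertuples(index=False):
            sub = table.data[table.data["locus"] == row.locus]
            obs = sorted(
                set(sub["allele_1"].dropna()) | set(sub["allele_2"].dropna())
            )
            if len(obs) == 0:
                continue
            alleles = obs if len(obs) > 1 else obs + ["N"]
            a_idx = {a: i for i, a in enumerate(alleles)}
            rec = out.new_record(
                contig=str(row.chrom), start=int(row.pos),
                alleles=tuple(alleles), id=str(row.locus),
            )
            geno = {
                (i, l): (a1, a2)
                for i, l, a1, a2 in zip(sub["indiv"], sub["locus"],
                                        sub["allele_1"], sub["allele_2"])
            }
            for s in indivs:
                a1, a2 = geno.get((s, row.locus), (np.nan, np.nan))
                if isinstance(a1, float) or isinstance(a2, float):
                    rec.samples[s]["GT"] = (None, None)
                else:
                    rec.samples[s]["GT"] = (a_idx[a1], a_idx[a2])
            out.write(rec)
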