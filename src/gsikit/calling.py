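"""Microhaplotype genotype calling and filtering from haplotype read counts.

Per individual/locus cell: require a minimum total read depth, drop haplotypes
whose depth ratio against the deepest haplotype falls below a floor, and call
the genotype heterozygous for the two deepest surviving haplotypes or
homozygous if one survives. Table-level filters then drop poorly genotyped
individuals, then loci, and finally loci out of Hardy-Weinberg equilibrium in
a majority of reference collections.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GenotypeTable, HaplotypeReadTable
from .popgen import genotype_counts, hwe_test

logger = logging.getLogger(__name__)


@dataclass
class CallConfig:
    min_locus_depth: int = 20           # total reads per individual-locus cell
    min_depth_ratio: float = 0.2        # vs the deepest haplotype in the cell
    min_indiv_callrate: float = 0.75    # strict > threshold
    min_locus_callrate: float = 0.75    # strict >, after individual pass
    hwe_alpha: float = 0.05
    hwe_collection_majority: int | None = None  # default floor(n/2)+1
    hwe_min_n: int = 5                  # collections smaller than this skipped
    hwe_permutations: int = 10_000
    hwe_seed: int = 0

    def __post_init__(self) -> None:
        if self.min_locus_depth < 1:
            raise ValueError("min_locus_depth must be >= 1")
        for r in (self.min_depth_ratio, self.min_indiv_callrate, self.min_locus_callrate):
            if not (0.0 < r <= 1.0):
                raise ValueError("rate/ratio thresholds must lie in (0, 1]")

    def majority(self, n_collections: int) -> int:
        if self.hwe_collection_majority is not None:
            return self.hwe_collection_majority
        return n_collections // 2 + 1


@dataclass
class CalledGenotype:
    indiv: str
    locus: str
    alleles: tuple[str, str] | None   # None = missing
    supporting_depths: dict[str, int] = field(default_factory=dict)
    flag: str | None = None           # e.g. ">2 surviving haplotypes"

    @property
    def missing(self) -> bool:
        return self.alleles is None


def call_genotype(
    cell: dict[str, int], cfg: CallConfig | None = None,
    indiv: str = "", locus: str = "",
) -> CalledGenotype:
    """Call one individual-locus cell from its haplotype->depth map.

    Missing when total depth < ``min_locus_depth``. Haplotypes below
    ``min_depth_ratio`` of the deepest haplotype are dropped; two or more
    survivors call a heterozygote for the two deepest (second-place ties
    broken by lexicographic haplotype id, flagged), one survivor a homozygote.
    The call is invariant to the ordering of the input map.
    """
    cfg = cfg or CallConfig()
    if any(d < 0 for d in cell.values()):
        raise ValueError("negative read depth")
    total = sum(cell.values())
    if total < cfg.min_locus_depth:
        return CalledGenotype(indiv, locus, None)
    max_depth = max(cell.values())
    survivors = {
        h: d for h, d in cell.items() if d / max_depth >= cfg.min_depth_ratio and d > 0
    }
    if not survivors:
        return CalledGenotype(indiv, locus, None)
    # depth desc, then haplotype id asc: deterministic top-two
    ranked = sorted(survivors.items(), key=lambda kv: (-kv[1], kv[0]))
    flag = None
    if len(ranked) == 1:
        h = ranked[0][0]
        return CalledGenotype(indiv, locus, (h, h), {h: ranked[0][1]})
    if len(ranked) > 2:
        flag = "more_than_two_haplotypes"
    if len(ranked) > 2 and ranked[1][1] == ranked[2][1]:
        flag = (flag + ";second_place_tie") if flag else "second_place_tie"
    (h1, d1), (h2, d2) = ranked[0], ranked[1]
    a, b = sorted((h1, h2))
    return CalledGenotype(indiv, locus, (a, b), {h1: d1, h2: d2}, flag=flag)


def call_table(
    reads: HaplotypeReadTable, cfg: CallConfig | None = None
) -> GenotypeTable:
    """Call every (indiv, locus) cell of a read table into a genotype table.

    Collection/repunit labels are joined from ``reads.collections`` when
    present. Missing calls are recorded as rows with NaN alleles so call
    rates can be computed against the full cell set.
    """
    cfg = cfg or CallConfig()
    rows = []
    for (indiv, locus), grp in reads.data.groupby(["indiv", "locus"], sort=True):
        cell = dict(zip(grp["haplotype"], grp["depth"]))
        g = call_genotype(cell, cfg, indiv=indiv, locus=locus)
        rows.append(
            {"indiv": indiv, "locus": locus,
             "allele_1": g.alleles[0] if g.alleles else np.nan,
             "allele_2": g.alleles[1] if g.alleles else np.nan}
        )
    df = pd.DataFrame(rows)
    if reads.collections is not None:
        df = df.merge(reads.collections, on="indiv", how="left")
    else:
        df["collection"] = ""
        df["repunit"] = ""
    return GenotypeTable(df, loci=reads.loci)


@dataclass
class FilterReport:
    dropped_indivs: list[str]
    dropped_loci: list[str]
    indiv_callrate: pd.Series
    locus_callrate: pd.Series


def missingness_filter(
    calls: GenotypeTable, cfg: CallConfig | None = None
) -> tuple[GenotypeTable, FilterReport]:
    """Two-pass missing-data filter: individuals first, then loci.

    Individuals are retained only when called at strictly more than
    ``min_indiv_callrate`` of panel loci; loci are then retained only when
    called in strictly more than ``min_locus_callrate`` of the remaining
    individuals. The operation is idempotent.
    """
    cfg = cfg or CallConfig()
    loci = calls.locus_names
    indivs = calls.individuals
    called = calls.called()
    present = called.assign(ok=1).pivot_table(
        index="indiv", columns="locus", values="ok", aggfunc="first", fill_value=0
    )
    present = present.reindex(index=indivs, columns=loci, fill_value=0)
    indiv_rate = present.sum(axis=1) / len(loci)
    keep_indiv = indiv_rate > cfg.min_indiv_callrate
    kept_indivs = indiv_rate.index[keep_indiv]
    locus_rate = (
        present.loc[kept_indivs].sum(axis=0) / max(len(kept_indivs), 1)
        if len(kept_indivs)
        else pd.Series(0.0, index=loci)
    )
    keep_locus = locus_rate > cfg.min_locus_callrate
    kept_loci = list(locus_rate.index[keep_locus])
    data = calls.data[
        calls.data["indiv"].isin(set(kept_indivs))
        & calls.data["locus"].isin(set(kept_loci))
    ].reset_index(drop=True)
    meta = None
    if calls.loci is not None:
        meta = calls.loci[calls.loci["locus"].isin(set(kept_loci))].reset_index(drop=True)
    report = FilterReport(
        dropped_indivs=sorted(set(indivs) - set(kept_indivs)),
        dropped_loci=sorted(set(loci) - set(kept_loci)),
        indiv_callrate=indiv_rate,
        locus_callrate=locus_rate,
    )
    return GenotypeTable(data, loci=meta, true_origin=calls.true_origin), report


def hwe_locus_filter(
    calls: GenotypeTable, cfg: CallConfig | None = None
) -> tuple[GenotypeTable, pd.DataFrame]:
    """Drop loci out of HWE in at least a majority of reference collections.

    Per locus, collections with HWE p < ``hwe_alpha`` are counted; the locus
    is dropped when the count reaches the majority threshold (default
    floor(n_collections/2) + 1). Collections with fewer than ``hwe_min_n``
    genotyped individuals at the locus are excluded from the count.

    Returns the filtered table and the per-locus HWE summary.
    """
    cfg = cfg or CallConfig()
    collections = calls.collections
    majority = cfg.majority(len(collections))
    rows = []
    drop = []
    for locus, grp in calls.called().groupby("locus"):
        n_sig = 0
        n_tested = 0
        for coll, sub in grp.groupby("collection"):
            if len(sub) < cfg.hwe_min_n:
                logger.debug("HWE: %s in %s skipped (n=%d)", locus, coll, len(sub))
                continue
            p = hwe_test(
                genotype_counts(sub),
                n_permutations=cfg.hwe_permutations,
                seed=cfg.hwe_seed,
            )
            n_tested += 1
            if p < cfg.hwe_alpha:
                n_sig += 1
        dropped = n_sig >= majority
        if dropped:
            drop.append(locus)
        rows.append(
            {"locus": locus, "n_collections_tested": n_tested,
             "n_significant": n_sig, "majority_threshold": majority,
             "dropped": dropped}
        )
    keep = [l for l in calls.locus_names if l not in set(drop)]
    return calls.subset_loci(keep), pd.DataFrame(rows)
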