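"""Population-genetic statistics: allele frequencies, pairwise FST, exact
Hardy-Weinberg tests, and a permutation linkage screen.

FST is the Weir & Cockerham (1984) theta computed from called genotypes; for
multi-allelic loci the per-allele variance components a, b, c are summed over
alleles before the ratio. Negative estimates are retained (not clamped) so
locus ranking is unaffected; clamp only when reporting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .containers import FSTLandscape, GenotypeTable, canonical_pair_id

_LOG2 = np.log(2.0)


# ---------------------------------------------------------------------------
# allele frequencies
# ---------------------------------------------------------------------------

@dataclass
class AlleleFreqTable:
    """Observed allele frequencies per collection x locus.

    ``data`` columns: collection, locus, allele, freq, n (diploid individuals
    genotyped). Collection/locus cells with no genotyped individuals are listed
    in ``missing`` rather than zero-filled.
    """

    data: pd.DataFrame
    missing: pd.DataFrame


def allele_freqs(genotypes: GenotypeTable) -> AlleleFreqTable:
    """Frequencies from observed alleles only; missing cells excluded."""
    called = genotypes.called()
    rows = []
    for (coll, locus), grp in called.groupby(["collection", "locus"]):
        n = len(grp)
        counts = pd.concat([grp["allele_1"], grp["allele_2"]]).value_counts()
        for allele, c in counts.sort_index().items():
            rows.append(
                {"collection": coll, "locus": locus, "allele": allele,
                 "freq": c / (2 * n), "n": n}
            )
    data = pd.DataFrame(rows, columns=["collection", "locus", "allele", "freq", "n"])
    # flag (collection, locus) combinations with zero called genotypes
    colls = genotypes.collections
    loci = genotypes.locus_names
    seen = set(zip(data["collection"], data["locus"]))
    miss = [
        {"collection": c, "locus": l}
        for c in colls for l in loci if (c, l) not in seen
    ]
    return AlleleFreqTable(data, pd.DataFrame(miss, columns=["collection", "locus"]))


# ---------------------------------------------------------------------------
# Weir-Cockerham FST
# ---------------------------------------------------------------------------

def _locus_sample_stats(grp: pd.DataFrame, alleles: list[str]):
    """(n, p, h): sample size, allele freqs, per-allele heterozygote freqs."""
    n = len(grp)
    idx = {a: i for i, a in enumerate(alleles)}
    a1 = grp["allele_1"].map(idx).to_numpy()
    a2 = grp["allele_2"].map(idx).to_numpy()
    counts = np.bincount(a1, minlength=len(alleles)) + np.bincount(a2, minlength=len(alleles))
    p = counts / (2 * n)
    het = a1 != a2
    h = np.zeros(len(alleles))
    if het.any():
        h = (
            np.bincount(a1[het], minlength=len(alleles))
            + np.bincount(a2[het], minlength=len(alleles))
        ) / n
    return n, p, h


def wc_components(n: np.ndarray, p: np.ndarray, h: np.ndarray) -> tuple[float, float, float]:
    """Weir-Cockerham (1984) variance components (a, b, c), summed over
    alleles, from per-population summaries.

    ``n``: (r,) diploid sample sizes; ``p``: (r, A) allele frequencies;
    ``h``: (r, A) frequencies of heterozygotes carrying each allele.
    """
    r = len(n)
    nbar = n.mean()
    nc = (r * nbar - (n**2).sum() / (r * nbar)) / (r - 1)
    pbar = (n[:, None] * p).sum(axis=0) / (r * nbar)
    s2 = (n[:, None] * (p - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
    hbar = (n[:, None] * h).sum(axis=0) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    return float(a.sum()), float(b.sum()), float(c.sum())


def wc_theta(n: np.ndarray, p: np.ndarray, h: np.ndarray) -> float:
    """Single-locus WC84 theta = a / (a + b + c); NaN when the locus is
    monomorphic across the populations (undefined, not 0)."""
    a, b, c = wc_components(n, p, h)
    denom = a + b + c
    if denom == 0.0:
        return float("nan")
    return a / denom


def pairwise_fst(
    genotypes: GenotypeTable,
    pair: tuple[str, str],
    loci: list[str] | None = None,
    return_components: bool = False,
) -> pd.DataFrame:
    """Per-locus WC84 theta for one unordered collection pair.

    Loci monomorphic in both collections, or with < 2 genotyped individuals in
    either collection, return NaN (flagged undefined, not 0). The estimate is
    symmetric in the two collections by construction.
    """
    ca, cb = pair
    pair_id = canonical_pair_id(ca, cb)
    called = genotypes.called()
    sub = called[called["collection"].isin([ca, cb])]
    loci = loci if loci is not None else genotypes.locus_names
    meta = (
        genotypes.loci.set_index("locus")
        if genotypes.loci is not None
        else pd.DataFrame(columns=["chrom", "pos"])
    )
    grouped = {k: g for k, g in sub.groupby(["collection", "locus"])}
    rows = []
    for locus in loci:
        ga = grouped.get((ca, locus))
        gb = grouped.get((cb, locus))
        theta = float("nan")
        comp = (float("nan"),) * 3
        if ga is not None and gb is not None and len(ga) >= 2 and len(gb) >= 2:
            alleles = sorted(
                set(ga["allele_1"]) | set(ga["allele_2"])
                | set(gb["allele_1"]) | set(gb["allele_2"])
            )
            if len(alleles) > 1:
                na, pa, ha = _locus_sample_stats(ga, alleles)
                nb, pb, hb = _locus_sample_stats(gb, alleles)
                comp = wc_components(
                    np.array([na, nb], dtype=float),
                    np.vstack([pa, pb]),
                    np.vstack([ha, hb]),
                )
                denom = sum(comp)
                theta = comp[0] / denom if denom != 0 else float("nan")
        chrom = meta["chrom"].get(locus, None) if len(meta) else None
        pos = meta["pos"].get(locus, np.nan) if len(meta) else np.nan
        row = {"locus": locus, "chrom": chrom, "pos": pos, "pair_id": pair_id, "fst": theta}
        if return_components:
            row.update({"comp_a": comp[0], "comp_b": comp[1], "comp_c": comp[2]})
        rows.append(row)
    cols = ["locus", "chrom", "pos", "pair_id", "fst"]
    if return_components:
        cols += ["comp_a", "comp_b", "comp_c"]
    return pd.DataFrame(rows, columns=cols)


def multilocus_fst(
    genotypes: GenotypeTable, pair: tuple[str, str], loci: list[str] | None = None
) -> float:
    """Multi-locus WC84 theta as a ratio of averages: sum of per-locus a
    components over sum of (a + b + c), the standard genome-wide estimator."""
    df = pairwise_fst(genotypes, pair, loci=loci, return_components=True)
    ok = df["comp_a"].notna()
    denom = (df.loc[ok, ["comp_a", "comp_b", "comp_c"]].to_numpy()).sum()
    if denom == 0:
        return float("nan")
    return float(df.loc[ok, "comp_a"].sum() / denom)


def fst_landscape(genotypes: GenotypeTable, min_n: int = 2) -> FSTLandscape:
    """Per-locus FST for every pair of collections, as an FSTLandscape.

    Written in the same CSV dialect as the synthetic landscapes so tables
    derived from other estimators can be substituted by users.
    """
    colls = genotypes.collections
    frames = []
    for i in range(len(colls)):
        for j in range(i + 1, len(colls)):
            frames.append(pairwise_fst(genotypes, (colls[i], colls[j])))
    data = pd.concat(frames, ignore_index=True)
    lengths = None
    if genotypes.loci is not None:
        lengths = {
            str(c): int(g["pos"].max()) + 1
            for c, g in genotypes.loci.groupby("chrom")
        }
    return FSTLandscape(data.dropna(subset=["fst"]).reset_index(drop=True), chrom_lengths=lengths)


# ---------------------------------------------------------------------------
# Hardy-Weinberg tests
# ---------------------------------------------------------------------------

def genotype_counts(grp: pd.DataFrame) -> dict[tuple[str, str], int]:
    """Tally called genotypes of one collection at one locus into a dict."""
    out: dict[tuple[str, str], int] = {}
    for x, y in zip(grp["allele_1"], grp["allele_2"]):
        key = tuple(sorted((x, y)))
        out[key] = out.get(key, 0) + 1
    return out


def _exact_biallelic_p(n_het_obs: int, n_a: int, n_total: int) -> float:
    """Two-sided exact conditional HWE p for a biallelic locus.

    Enumerates all heterozygote counts consistent with the allele counts and
    sums the probabilities of configurations no more probable than observed.
    """
    n_b = 2 * n_total - n_a
    hs = np.arange(n_a % 2, min(n_a, n_b) + 1, 2)
    log_probs = (
        hs * _LOG2
        - gammaln((n_a - hs) / 2 + 1)
        - gammaln(hs + 1)
        - gammaln((n_b - hs) / 2 + 1)
    )
    log_probs -= log_probs.max()
    probs = np.exp(log_probs)
    probs /= probs.sum()
    p_obs = probs[np.flatnonzero(hs == n_het_obs)[0]]
    return float(min(probs[probs <= p_obs * (1 + 1e-12)].sum(), 1.0))


def _table_log_weight(codes: np.ndarray, n_alleles: int) -> float:
    """log of the conditional table probability, up to constants shared by all
    tables with the same allele counts: h*log2 - sum log(n_ij!)."""
    het = (codes // n_alleles) != (codes % n_alleles)
    counts = np.bincount(codes)
    return float(het.sum() * _LOG2 - gammaln(counts + 1).sum())


def hwe_test(
    counts: dict[tuple[str, str], int],
    n_permutations: int = 10_000,
    seed: int | None = 0,
) -> float:
    """Exact test of Hardy-Weinberg proportions at one locus.

    Biallelic loci use the exact conditional (Levene/Haldane) test by full
    enumeration; multi-allelic loci use a Monte-Carlo exact test that randomly
    re-pairs the observed allele pool (add-one p-value rule). Monomorphic loci
    return p = 1 by convention.
    """
    n_total = sum(counts.values())
    if n_total < 1:
        raise ValueError("need at least one genotyped individual")
    alleles = sorted({a for pair in counts for a in pair})
    if len(alleles) < 2:
        return 1.0
    if len(alleles) == 2:
        # use the rarer allele for the enumeration variable
        ca = sum(
            v * ((k[0] == alleles[0]) + (k[1] == alleles[0]))
            for k, v in counts.items()
        )
        n_a = min(ca, 2 * n_total - ca)
        n_het = sum(v for k, v in counts.items() if k[0] != k[1])
        return _exact_biallelic_p(n_het, n_a, n_total)

    # multi-allelic: Monte-Carlo exact test
    rng = np.random.default_rng(seed)
    idx = {al: i for i, al in enumerate(alleles)}
    A = len(alleles)
    pool = []
    obs_codes = []
    for (x, y), v in counts.items():
        i, j = sorted((idx[x], idx[y]))
        obs_codes.extend([i * A + j] * v)
        pool.extend([i, j] * v)
    obs_w = _table_log_weight(np.asarray(obs_codes), A)
    pool_arr = np.asarray(pool)
    perms = rng.permuted(np.tile(pool_arr, (n_permutations, 1)), axis=1)
    lo = np.minimum(perms[:, 0::2], perms[:, 1::2])
    hi = np.maximum(perms[:, 0::2], perms[:, 1::2])
    codes = np.sort(lo * A + hi, axis=1)
    het = (lo != hi).sum(axis=1)
    # sum log(count!) per row via within-run occurrence indices on sorted codes
    occ = np.ones_like(codes, dtype=float)
    for j in range(1, codes.shape[1]):
        same = codes[:, j] == codes[:, j - 1]
        occ[:, j] = np.where(same, occ[:, j - 1] + 1, 1.0)
    # log(count!) accumulates as sum of log(occurrence index) over the run
    w = het * _LOG2 - np.log(occ).sum(axis=1)
    n_le = int((w <= obs_w + 1e-9).sum())
    return (1 + n_le) / (n_permutations + 1)


def hwe_test_table(
    genotypes: GenotypeTable,
    n_permutations: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """HWE p-value for every (collection, locus) with >= 1 called genotype."""
    rows = []
    for (coll, locus), grp in genotypes.called().groupby(["collection", "locus"]):
        p = hwe_test(genotype_counts(grp), n_permutations=n_permutations, seed=seed)
        rows.append({"collection": coll, "locus": locus, "n": len(grp), "p": p})
    return pd.DataFrame(rows, columns=["collection", "locus", "n", "p"])


# ---------------------------------------------------------------------------
# linkage screen
# ---------------------------------------------------------------------------

def _dosage_matrix(genotypes: GenotypeTable, loci: list[str]) -> pd.DataFrame:
    """Individuals x loci dosage of each locus's overall most frequent allele."""
    called = genotypes.called()
    cols = {}
    for locus in loci:
        grp = called[called["locus"] == locus]
        if grp.empty:
            continue
        counts = pd.concat([grp["allele_1"], grp["allele_2"]]).value_counts()
        # most frequent allele, ties to the lexicographically first name
        top = counts.index[np.lexsort((counts.index, -counts.to_numpy()))[0]]
        dosage = (grp["allele_1"] == top).astype(int) + (grp["allele_2"] == top).astype(int)
        cols[locus] = pd.Series(dosage.to_numpy(), index=grp["indiv"].to_numpy())
    return pd.DataFrame(cols)


def linkage_screen(
    genotypes: GenotypeTable,
    pairs: list[tuple[str, str]] | None = None,
    n_permutations: int = 999,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Composite genotypic-association screen for same-chromosome locus pairs.

    The statistic is the squared Pearson correlation of allele dosages (dosage
    of each locus's most frequent allele); the null is a permutation
    distribution from shuffling one locus's genotypes across individuals
    (add-one p rule). Pairs with a monomorphic member are skipped.
    """
    if pairs is None:
        if genotypes.loci is None:
            raise ValueError("need loci metadata (or explicit pairs) for the screen")
        pairs = []
        for _, grp in genotypes.loci.groupby("chrom"):
            ll = sorted(grp["locus"])
            pairs.extend((ll[i], ll[j]) for i in range(len(ll)) for j in range(i + 1, len(ll)))
    loci_needed = sorted({l for p in pairs for l in p})
    dos = _dosage_matrix(genotypes, loci_needed)
    rng = np.random.default_rng(seed)
    rows = []
    for la, lb in pairs:
        if la not in dos.columns or lb not in dos.columns:
            continue
        sub = dos[[la, lb]].dropna()
        n = len(sub)
        if n < 20:
            continue
        x = sub[la].to_numpy(dtype=float)
        y = sub[lb].to_numpy(dtype=float)
        if x.std() == 0 or y.std() == 0:  # monomorphic member: undefined
            continue
        xc = x - x.mean()
        yc = y - y.mean()
        denom = np.sqrt((xc**2).sum() * (yc**2).sum())
        r2_obs = float((xc @ yc) ** 2 / denom**2)
        perms = rng.permuted(np.tile(yc, (n_permutations, 1)), axis=1)
        r2_perm = (perms @ xc) ** 2 / denom**2
        p = (1 + int((r2_perm >= r2_obs - 1e-12).sum())) / (n_permutations + 1)
        rows.append(
            {"locus_a": la, "locus_b": lb, "n": n, "r2": r2_obs, "p": p,
             "linked": p < alpha}
        )
    return pd.DataFrame(
        rows, columns=["locus_a", "locus_b", "n", "r2", "p", "linked"]
    )
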