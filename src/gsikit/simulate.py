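"""Synthetic baselines, mixtures, read counts and FST landscapes.

Every downstream stage of the pipeline is testable without real data because
this module generates all of its inputs with known ground truth:

* population allele frequencies diverge from an ancestral frequency vector
  under the Balding-Nichols model (Dirichlet with concentration (1-F)/F),
  which gives analytic moments for oracle tests;
* baselines and mixtures are drawn under Hardy-Weinberg within populations;
* haplotype read counts follow a negative-binomial depth model with a
  per-read error rate;
* FST landscapes over many chromosomes are constructible in "saturated" and
  "starved" configurations so windowed panel selection has exact expected
  outputs.

Every stochastic operation takes an explicit integer seed; identical seeds
give bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import FSTLandscape, GenotypeTable, HaplotypeReadTable, all_pairs

_NUCS = "ACGT"


def _kmer_alphabet(k: int) -> list[str]:
    out = [""]
    for _ in range(k):
        out = [s + n for s in out for n in _NUCS]
    return out


@dataclass
class PopulationModel:
    """Ancestral allele frequencies plus per-population divergence.

    ``fst`` may be a scalar (shared by all populations) or one value per
    population; it is the Balding-Nichols divergence parameter in [0, 1).
    """

    n_pops: int
    fst: float | np.ndarray
    loci: pd.DataFrame  # locus, chrom, pos
    ancestral_freqs: dict[str, np.ndarray]
    alleles: dict[str, list[str]]
    pop_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_pops < 1:
            raise ValueError("n_pops must be >= 1")
        fst = np.broadcast_to(np.asarray(self.fst, dtype=float), (self.n_pops,))
        if np.any(fst < 0) or np.any(fst >= 1):
            raise ValueError("fst must lie in [0, 1)")
        self.fst = fst.copy()
        if not self.pop_names:
            self.pop_names = [f"P{i + 1:02d}" for i in range(self.n_pops)]
        for locus, vec in self.ancestral_freqs.items():
            vec = np.asarray(vec, dtype=float)
            if abs(vec.sum() - 1.0) > 1e-9:
                raise ValueError(f"{locus}: ancestral frequencies must sum to 1")
            if len(vec) < 2:
                raise ValueError(f"{locus}: need >= 2 alleles")
            if len(vec) != len(self.alleles[locus]):
                raise ValueError(f"{locus}: allele list / frequency length mismatch")
            self.ancestral_freqs[locus] = vec
        for chrom, grp in self.loci.groupby("chrom"):
            pos = grp["pos"].to_numpy()
            if (pos < 0).any():
                raise ValueError(f"{chrom}: negative positions")
            if len(np.unique(pos)) != len(pos):
                raise ValueError(f"{chrom}: duplicate positions")


@dataclass
class MixtureSpec:
    """Known mixing proportions over reporting units for a simulated mixture."""

    true_proportions: np.ndarray
    n_individuals: int
    seed: int
    units: list[str] | None = None

    def __post_init__(self) -> None:
        p = np.asarray(self.true_proportions, dtype=float)
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("true_proportions must sum to 1")
        if (p < 0).any():
            raise ValueError("true_proportions must be non-negative")
        self.true_proportions = p
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")


@dataclass
class ReadSimSpec:
    """Depth and error model for simulated GT-seq haplotype reads.

    ``depth_dispersion`` is the negative-binomial size parameter k with
    variance m + m^2/k; ``None`` (or inf) selects the Poisson special case.
    """

    mean_depth: float
    depth_dispersion: float | None = 5.0
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be > 0")
        if not (0.0 <= self.error_rate < 0.5):
            raise ValueError("error_rate must be in [0, 0.5)")
        if self.depth_dispersion is not None and self.depth_dispersion <= 0:
            raise ValueError("depth_dispersion must be > 0")


@dataclass
class PopulationFreqs:
    """Realised per-population allele frequencies (output of the BN draw)."""

    pop_names: list[str]
    loci: pd.DataFrame
    alleles: dict[str, list[str]]
    freqs: dict[str, dict[str, np.ndarray]]  # pop -> locus -> vector


def default_population_model(
    n_pops: int,
    n_loci: int,
    fst: float | np.ndarray,
    seed: int,
    n_chroms: int = 23,
    chrom_length: int = 25_000_000,
    max_alleles: int = 8,
) -> PopulationModel:
    """A realistic microhaplotype panel model.

    Loci carry 2..``max_alleles`` alleles (mean ~3.5, matching multi-allelic
    amplicon panels) with geometric-decay ancestral frequencies; allele names
    are distinct 3-mer nucleotide strings so tables export cleanly to VCF.
    """
    rng = np.random.default_rng(seed)
    kmers = np.array(_kmer_alphabet(3))
    chroms = [f"chr{i + 1:02d}" for i in range(n_chroms)]
    rows = []
    anc: dict[str, np.ndarray] = {}
    alleles: dict[str, list[str]] = {}
    used_pos: dict[str, set[int]] = {c: set() for c in chroms}
    for j in range(n_loci):
        chrom = chroms[j % n_chroms]
        while True:
            pos = int(rng.integers(1, chrom_length))
            if pos not in used_pos[chrom]:
                used_pos[chrom].add(pos)
                break
        locus = f"L{j + 1:04d}"
        n_all = int(rng.integers(2, max_alleles + 1))
        names = sorted(rng.choice(kmers, size=n_all, replace=False).tolist())
        # geometric-ish decay with jitter, then normalise
        base = 0.55 ** np.arange(n_all)
        base = base * rng.uniform(0.6, 1.4, size=n_all)
        vec = base / base.sum()
        rows.append({"locus": locus, "chrom": chrom, "pos": pos})
        anc[locus] = vec
        alleles[locus] = names
    return PopulationModel(
        n_pops=n_pops,
        fst=fst,
        loci=pd.DataFrame(rows),
        ancestral_freqs=anc,
        alleles=alleles,
    )


def _dirichlet(rng: np.random.Generator, alpha: np.ndarray) -> np.ndarray:
    """Dirichlet draw that is safe for very small concentrations.

    Plain gamma sampling underflows to exactly 0 for shapes below ~1e-3,
    which would collapse the whole vector; instead draw log-gamma via the
    boost identity  G(a) = G(a+1) * U^(1/a)  and normalise in log space.
    Entries with alpha == 0 stay exactly 0 (ancestrally absent alleles).
    """
    alpha = np.asarray(alpha, dtype=float)
    pos = alpha > 0
    logg = np.full(alpha.shape, -np.inf)
    a = alpha[pos]
    boost = rng.gamma(a + 1.0)
    u = rng.random(a.shape)
    with np.errstate(divide="ignore"):
        logg[pos] = np.log(boost) + np.log(u) / a
    m = logg.max()
    g = np.exp(logg - m)
    return g / g.sum()


def draw_population_freqs(model: PopulationModel, seed: int) -> PopulationFreqs:
    """Balding-Nichols draw of per-population allele frequencies.

    Each population's frequency vector at each locus is Dirichlet-distributed
    with mean equal to the ancestral vector and concentration (1-F)/F. F = 0
    returns the ancestral vector verbatim (infinite-concentration limit).
    """
    rng = np.random.default_rng(seed)
    freqs: dict[str, dict[str, np.ndarray]] = {}
    for i, pop in enumerate(model.pop_names):
        f = float(model.fst[i])
        per_locus: dict[str, np.ndarray] = {}
        for locus, anc in model.ancestral_freqs.items():
            if f == 0.0:
                per_locus[locus] = anc.copy()
                continue
            alpha = anc * (1.0 - f) / f
            per_locus[locus] = _dirichlet(rng, alpha)
        freqs[pop] = per_locus
    return PopulationFreqs(
        pop_names=list(model.pop_names),
        loci=model.loci.copy(),
        alleles={k: list(v) for k, v in model.alleles.items()},
        freqs=freqs,
    )


def _genotype_rows(
    rng: np.random.Generator,
    indivs: list[str],
    collection: str,
    repunit: str,
    pfreqs: PopulationFreqs,
    pop: str,
) -> dict[str, list]:
    n = len(indivs)
    cols: dict[str, list] = {c: [] for c in ("indiv", "collection", "repunit", "locus", "allele_1", "allele_2")}
    for locus in pfreqs.loci["locus"]:
        p = pfreqs.freqs[pop][locus]
        names = pfreqs.alleles[locus]
        draw = rng.choice(len(p), size=(n, 2), p=p)
        cols["indiv"].extend(indivs)
        cols["collection"].extend([collection] * n)
        cols["repunit"].extend([repunit] * n)
        cols["locus"].extend([locus] * n)
        cols["allele_1"].extend([names[a] for a in draw[:, 0]])
        cols["allele_2"].extend([names[a] for a in draw[:, 1]])
    return cols


def simulate_baseline(
    pfreqs: PopulationFreqs,
    n_per_pop: int,
    seed: int,
    repunit_map: dict[str, str] | None = None,
) -> GenotypeTable:
    """Reference individuals of known origin, Hardy-Weinberg within population."""
    if n_per_pop < 1:
        raise ValueError("n_per_pop must be >= 1")
    rng = np.random.default_rng(seed)
    repunit_map = repunit_map or {p: p for p in pfreqs.pop_names}
    frames = []
    for pop in pfreqs.pop_names:
        indivs = [f"{pop}_{i + 1:03d}" for i in range(n_per_pop)]
        frames.append(
            pd.DataFrame(_genotype_rows(rng, indivs, pop, repunit_map[pop], pfreqs, pop))
        )
    return GenotypeTable(pd.concat(frames, ignore_index=True), loci=pfreqs.loci.copy())


def simulate_mixture(
    pfreqs: PopulationFreqs,
    spec: MixtureSpec,
    repunit_map: dict[str, str] | None = None,
) -> GenotypeTable:
    """Unknown-origin individuals with hidden true origins.

    Each individual's reporting unit is drawn from ``spec.true_proportions``;
    its source collection is uniform among the unit's collections, and its
    genotype is drawn from that collection's frequencies. True origins are
    returned in ``GenotypeTable.true_origin``, never in the genotype columns
    (collection/repunit are left blank, as for a real mixture sample).
    """
    rng = np.random.default_rng(spec.seed)
    repunit_map = repunit_map or {p: p for p in pfreqs.pop_names}
    units = spec.units or sorted(set(repunit_map.values()))
    if len(units) != len(spec.true_proportions):
        raise ValueError("true_proportions length must match number of units")
    unit_pops = {u: [p for p in pfreqs.pop_names if repunit_map[p] == u] for u in units}
    for u, pops in unit_pops.items():
        if not pops:
            raise ValueError(f"reporting unit {u!r} has no collections")
    unit_idx = rng.choice(len(units), size=spec.n_individuals, p=spec.true_proportions)
    origins = []
    for k in unit_idx:
        pops = unit_pops[units[k]]
        origins.append(pops[rng.integers(len(pops))])
    indivs = [f"mix_{i + 1:04d}" for i in range(spec.n_individuals)]
    # draw genotypes individual-by-locus, grouped by origin for vectorisation
    frames = []
    origins_arr = np.array(origins)
    for pop in sorted(set(origins)):
        sel = np.flatnonzero(origins_arr == pop)
        sub = [indivs[i] for i in sel]
        frames.append(pd.DataFrame(_genotype_rows(rng, sub, "", "", pfreqs, pop)))
    data = pd.concat(frames, ignore_index=True)
    true_origin = pd.Series(origins, index=indivs, name="true_origin")
    return GenotypeTable(data, loci=pfreqs.loci.copy(), true_origin=true_origin)


def simulate_reads(
    genotypes: GenotypeTable,
    spec: ReadSimSpec,
    locus_alleles: dict[str, list[str]] | None = None,
) -> HaplotypeReadTable:
    """Haplotype read counts for every called genotype cell.

    Total depth per cell is negative-binomial (Poisson when dispersion is
    None); reads split ~50/50 between the two true haplotypes; each read is
    mis-assigned with probability ``error_rate`` to a uniformly-chosen other
    haplotype of the locus. Haplotype counts always sum to the drawn depth.
    """
    rng = np.random.default_rng(spec.seed)
    called = genotypes.called().reset_index(drop=True)
    n = len(called)
    if locus_alleles is None:
        locus_alleles = {
            loc: sorted(
                set(grp["allele_1"].dropna()) | set(grp["allele_2"].dropna())
            )
            for loc, grp in called.groupby("locus")
        }
    if spec.depth_dispersion is None or math.isinf(spec.depth_dispersion):
        depth = rng.poisson(spec.mean_depth, size=n)
    else:
        k = spec.depth_dispersion
        depth = rng.negative_binomial(k, k / (k + spec.mean_depth), size=n)
    a1 = called["allele_1"].to_numpy()
    a2 = called["allele_2"].to_numpy()
    reads1 = rng.binomial(depth, 0.5)
    reads2 = depth - reads1
    err1 = rng.binomial(reads1, spec.error_rate) if spec.error_rate > 0 else np.zeros(n, int)
    err2 = rng.binomial(reads2, spec.error_rate) if spec.error_rate > 0 else np.zeros(n, int)
    loci = called["locus"].to_numpy()
    indiv = called["indiv"].to_numpy()
    out: dict[str, list] = {"indiv": [], "locus": [], "haplotype": [], "depth": []}
    for i in range(n):
        counts: dict[str, int] = {}
        counts[a1[i]] = counts.get(a1[i], 0) + int(reads1[i] - err1[i])
        counts[a2[i]] = counts.get(a2[i], 0) + int(reads2[i] - err2[i])
        for true_hap, n_err in ((a1[i], int(err1[i])), (a2[i], int(err2[i]))):
            if n_err == 0:
                continue
            others = [h for h in locus_alleles[loci[i]] if h != true_hap]
            if not others:
                counts[true_hap] += n_err  # nowhere to divert: reads stay correct
                continue
            alloc = rng.multinomial(n_err, np.full(len(others), 1.0 / len(others)))
            for h, c in zip(others, alloc):
                if c:
                    counts[h] = counts.get(h, 0) + int(c)
        for h, c in counts.items():
            if c > 0:
                out["indiv"].append(indiv[i])
                out["locus"].append(loci[i])
                out["haplotype"].append(h)
                out["depth"].append(c)
    collections = (
        genotypes.data[["indiv", "collection", "repunit"]].drop_duplicates("indiv")
        .reset_index(drop=True)
    )
    return HaplotypeReadTable(
        pd.DataFrame(out), collections=collections, loci=genotypes.loci
    )


@dataclass
class LandscapeConfig:
    """Controls how many loci per window clear the selection FST floor.

    mode:
      * ``saturated`` — every window on every chromosome contains at least
        ``eligible_per_window`` loci whose max pairwise FST exceeds the floor,
        with distinct argmax pairs across the chromosome (so the
        one-pair-per-chromosome rule never starves a window);
      * ``all_below_floor`` — no locus clears the floor anywhere;
      * ``random`` — each locus clears the floor independently with
        probability ``high_prob``.
    """

    mode: str = "saturated"
    windows_per_chrom: int = 6
    eligible_per_window: int = 2
    fst_floor: float = 0.2
    high_fst_range: tuple[float, float] = (0.25, 0.9)
    high_prob: float = 0.1

    def __post_init__(self) -> None:
        if self.mode not in {"saturated", "all_below_floor", "random"}:
            raise ValueError(f"unknown landscape mode {self.mode!r}")


def simulate_fst_landscape(
    n_chroms: int,
    chrom_length: int,
    n_loci_per_chrom: int,
    n_pairs: int,
    config: LandscapeConfig | None = None,
    seed: int = 0,
) -> FSTLandscape:
    """A per-locus FST landscape over many chromosomes and population pairs."""
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    cfg = config or LandscapeConfig()
    rng = np.random.default_rng(seed)

    # enough synthetic collection names to produce n_pairs canonical pairs
    k = 2
    while k * (k - 1) // 2 < n_pairs:
        k += 1
    pairs = all_pairs([f"C{i + 1:02d}" for i in range(k)])[:n_pairs]

    if cfg.mode == "saturated":
        needed = cfg.windows_per_chrom * cfg.eligible_per_window
        if needed > n_pairs:
            raise ValueError(
                f"saturated mode needs >= {needed} pairs for distinct attribution"
            )
        if n_loci_per_chrom < needed:
            raise ValueError(f"saturated mode needs >= {needed} loci per chromosome")

    rows: list[pd.DataFrame] = []
    bg_scale = cfg.fst_floor * 0.95
    for c in range(n_chroms):
        chrom = f"chr{c + 1:02d}"
        nw = cfg.windows_per_chrom
        # stratify positions over windows so saturated windows are non-empty
        quota = np.full(nw, n_loci_per_chrom // nw)
        quota[: n_loci_per_chrom % nw] += 1
        pos_list: list[int] = []
        win_of: list[int] = []
        for w in range(nw):
            lo = int(w * chrom_length / nw)
            hi = int((w + 1) * chrom_length / nw)
            pts = rng.choice(np.arange(lo, hi), size=quota[w], replace=False)
            pos_list.extend(int(p) for p in pts)
            win_of.extend([w] * quota[w])
        order = np.argsort(pos_list)
        pos_arr = np.asarray(pos_list)[order]
        win_arr = np.asarray(win_of)[order]
        loci = [f"{chrom}_L{j + 1:04d}" for j in range(n_loci_per_chrom)]
        fst = rng.beta(0.5, 8.0, size=(n_loci_per_chrom, n_pairs)) * bg_scale
        if cfg.mode == "saturated":
            chosen_pairs = rng.choice(
                n_pairs, size=cfg.windows_per_chrom * cfg.eligible_per_window, replace=False
            )
            pi = 0
            for w in range(cfg.windows_per_chrom):
                in_win = np.flatnonzero(win_arr == w)
                picks = rng.choice(in_win, size=cfg.eligible_per_window, replace=False)
                for j in picks:
                    lo, hi = cfg.high_fst_range
                    fst[j, chosen_pairs[pi]] = rng.uniform(lo, hi)
                    pi += 1
        elif cfg.mode == "random":
            hot = rng.random(n_loci_per_chrom) < cfg.high_prob
            for j in np.flatnonzero(hot):
                lo, hi = cfg.high_fst_range
                fst[j, rng.integers(n_pairs)] = rng.uniform(lo, hi)
        rows.append(
            pd.DataFrame(
                {
                    "locus": np.repeat(loci, n_pairs),
                    "chrom": chrom,
                    "pos": np.repeat(pos_arr, n_pairs),
                    "pair_id": np.tile(pairs, n_loci_per_chrom),
                    "fst": fst.ravel(),
                }
            )
        )
    data = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["locus", "chrom", "pos", "pair_id", "fst"]
    )
    lengths = {f"chr{c + 1:02d}": chrom_length for c in range(n_chroms)}
    return FSTLandscape(data, chrom_lengths=lengths)
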