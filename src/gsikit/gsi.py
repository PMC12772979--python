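"""Bayesian genetic stock identification.

The model is the conditional mixture model of Pella & Masuda: baseline
collections contribute Dirichlet-posterior mean allele frequencies, mixture
individuals carry latent origin collections, and a Gibbs sampler alternates

* z_i ~ Categorical( pi_c * P(genotype_i | collection c) ) and
* pi  ~ Dirichlet( prior + origin counts ).

Genotype probabilities assume Hardy-Weinberg within collections (p^2 / 2pq),
independent loci, and missing loci contribute a factor of 1. Reporting-unit
quantities are sums of member-collection quantities.

Diagnostics: a per-individual z-score standardises the observed genotype
log-likelihood against its analytic mean and variance under draws from the
MAP collection's frequencies, flagging fish from populations absent from the
baseline. Assignment quality is assessed by leave-one-out simulated mixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GenotypeTable

_LOG2 = np.log(2.0)


@dataclass
class McmcConfig:
    n_sweeps: int = 2000
    burn_in: int = 100
    pi_prior: float | str = "1/C"   # Dirichlet parameter per collection
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.burn_in < self.n_sweeps):
            raise ValueError("require 0 <= burn_in < n_sweeps")

    def pi_prior_vec(self, n_collections: int) -> np.ndarray:
        if self.pi_prior == "1/C":
            return np.full(n_collections, 1.0 / n_collections)
        return np.full(n_collections, float(self.pi_prior))


class Baseline:
    """Reference collections with a Dirichlet allele-frequency prior.

    ``allele_prior`` is either the string ``"1/A"`` (pseudo-count 1/A_l per
    allele at a locus with A_l alleles, so one prior observation per locus) or
    a positive float used as a flat per-allele pseudo-count.
    """

    def __init__(self, genotypes: GenotypeTable, allele_prior: float | str = "1/A"):
        called = genotypes.called()
        if called.empty:
            raise ValueError("baseline has no called genotypes")
        if isinstance(allele_prior, (int, float)) and allele_prior <= 0:
            raise ValueError("allele_prior must be positive")
        self.genotypes = genotypes
        self.allele_prior = allele_prior
        self.collections: list[str] = genotypes.collections
        self.repunit_map: dict[str, str] = genotypes.repunit_map()
        missing_units = [c for c in self.collections if c not in self.repunit_map]
        if missing_units:
            raise ValueError(f"collections without reporting unit: {missing_units}")
        self.units: list[str] = sorted(set(self.repunit_map.values()))
        self.loci: list[str] = genotypes.locus_names
        c_idx = {c: i for i, c in enumerate(self.collections)}
        self.alleles: dict[str, list[str]] = {}
        self.counts: dict[str, np.ndarray] = {}
        self.n_called: dict[str, np.ndarray] = {}
        for locus, grp in called.groupby("locus"):
            names = sorted(set(grp["allele_1"]) | set(grp["allele_2"]))
            a_idx = {a: i for i, a in enumerate(names)}
            cnt = np.zeros((len(self.collections), len(names)))
            ncall = np.zeros(len(self.collections))
            ci = grp["collection"].map(c_idx).to_numpy()
            a1 = grp["allele_1"].map(a_idx).to_numpy()
            a2 = grp["allele_2"].map(a_idx).to_numpy()
            np.add.at(cnt, (ci, a1), 1)
            np.add.at(cnt, (ci, a2), 1)
            np.add.at(ncall, ci, 1)
            self.alleles[locus] = names
            self.counts[locus] = cnt
            self.n_called[locus] = ncall

    def unit_of(self, collection: str) -> str:
        return self.repunit_map[collection]


class _FreqModel:
    """Posterior-mean allele frequencies over a (possibly extended) allele
    universe: freq = (count + prior) / (2 n_called + sum priors)."""

    def __init__(self, baseline: Baseline, extra_alleles: dict[str, set] | None = None):
        self.baseline = baseline
        self.alleles: dict[str, list[str]] = {}
        self.a_idx: dict[str, dict[str, int]] = {}
        self.freqs: dict[str, np.ndarray] = {}      # C x A
        self.log_freqs: dict[str, np.ndarray] = {}
        self.counts: dict[str, np.ndarray] = {}
        self.priors: dict[str, np.ndarray] = {}
        C = len(baseline.collections)
        for locus in baseline.loci:
            base = baseline.alleles.get(locus, [])
            extra = sorted((extra_alleles or {}).get(locus, set()) - set(base))
            names = list(base) + extra
            if not names:
                continue
            A = len(names)
            cnt = np.zeros((C, A))
            if locus in baseline.counts:
                cnt[:, : baseline.counts[locus].shape[1]] = baseline.counts[locus]
            if baseline.allele_prior == "1/A":
                prior = np.full(A, 1.0 / A)
            else:
                prior = np.full(A, float(baseline.allele_prior))
            n = baseline.n_called.get(locus, np.zeros(C))
            freq = (cnt + prior) / (2 * n + prior.sum())[:, None]
            self.alleles[locus] = names
            self.a_idx[locus] = {a: i for i, a in enumerate(names)}
            self.freqs[locus] = freq
            self.log_freqs[locus] = np.log(freq)
            self.counts[locus] = cnt
            self.priors[locus] = prior

    def loglik_matrix(self, genotypes: GenotypeTable) -> tuple[np.ndarray, list[str]]:
        """(n_indiv x C) genotype log-likelihood; missing loci contribute 0."""
        indivs = genotypes.individuals
        r_idx = {ind: i for i, ind in enumerate(indivs)}
        C = len(self.baseline.collections)
        M = np.zeros((len(indivs), C))
        for locus, grp in genotypes.called().groupby("locus"):
            if locus not in self.a_idx:
                continue  # locus absent from baseline panel: uninformative
            idx = self.a_idx[locus]
            lf = self.log_freqs[locus]  # C x A
            rows = grp["indiv"].map(r_idx).to_numpy()
            i1 = grp["allele_1"].map(idx).to_numpy()
            i2 = grp["allele_2"].map(idx).to_numpy()
            het = (i1 != i2).astype(float)
            M[rows] += lf[:, i1].T + lf[:, i2].T + _LOG2 * het[:, None]
        return M, indivs

    def loo_freq(self, locus: str, collection_i: int, allele_i: int,
                 own: np.ndarray) -> float:
        """Posterior-mean frequency of one allele with one individual's two
        alleles removed from its collection's counts (``own`` is that
        individual's per-allele contribution at the locus)."""
        cnt = self.counts[locus][collection_i]
        prior = self.priors[locus]
        n = self.baseline.n_called[locus][collection_i] - 1
        denom = 2 * n + prior.sum()
        return (cnt[allele_i] - own[allele_i] + prior[allele_i]) / denom


def baseline_posterior_freqs(baseline: Baseline) -> dict[str, dict[str, dict[str, float]]]:
    """Dirichlet-posterior mean allele frequencies, nested as
    {collection: {locus: {allele: freq}}}."""
    fm = _FreqModel(baseline)
    out: dict[str, dict[str, dict[str, float]]] = {c: {} for c in baseline.collections}
    for locus, names in fm.alleles.items():
        for ci, coll in enumerate(baseline.collections):
            out[coll][locus] = dict(zip(names, fm.freqs[locus][ci]))
    return out


def genotype_log_likelihood(
    genotype: dict[str, tuple[str, str]],
    freqs: dict[str, dict[str, float]],
) -> float:
    """HWE log-likelihood of one individual against one collection's
    frequencies: sum over called loci of log p^2 (hom) or log 2pq (het).
    Loci absent from ``freqs`` are skipped (missing-data convention)."""
    total = 0.0
    for locus, (a, b) in genotype.items():
        if locus not in freqs:
            continue
        f = freqs[locus]
        if a not in f or b not in f:
            raise KeyError(f"allele missing from frequency table at {locus}")
        if a == b:
            total += 2 * np.log(f[a])
        else:
            total += _LOG2 + np.log(f[a]) + np.log(f[b])
    return float(total)


@dataclass
class MixtureResult:
    collections: list[str]
    units: list[str]
    repunit_map: dict[str, str]
    mixing_proportions: pd.Series          # over collections
    unit_mixing_proportions: pd.Series     # over reporting units
    indiv_posteriors: pd.DataFrame         # indiv x collections
    unit_posteriors: pd.DataFrame          # indiv x units
    map_collection: pd.Series
    map_unit: pd.Series
    confidence: pd.Series                  # max unit posterior
    z_score: pd.Series                     # NaN = undefined (flagged)

    def to_frame(self) -> pd.DataFrame:
        """Per-individual assignment table."""
        out = self.unit_posteriors.add_prefix("post_").copy()
        out.insert(0, "map_unit", self.map_unit)
        out.insert(1, "map_collection", self.map_collection)
        out["confidence"] = self.confidence
        out["z_score"] = self.z_score
        return out.reset_index(names="indiv")


def _gibbs(
    M: np.ndarray, pi_prior: np.ndarray, cfg: McmcConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Gibbs sampler on a fixed log-likelihood matrix.

    Returns post-burn-in means of (per-individual origin posterior, pi).
    """
    n, C = M.shape
    expl = np.exp(M - M.max(axis=1, keepdims=True))
    pi = np.full(C, 1.0 / C)
    post = np.zeros((n, C))
    pi_acc = np.zeros(C)
    kept = 0
    for sweep in range(cfg.n_sweeps):
        P = expl * pi
        P /= P.sum(axis=1, keepdims=True)
        u = rng.random(n)
        z = (P.cumsum(axis=1) < u[:, None]).sum(axis=1)
        counts = np.bincount(z, minlength=C)
        pi = rng.dirichlet(pi_prior + counts)
        if sweep >= cfg.burn_in:
            post += P
            pi_acc += pi
            kept += 1
    return post / kept, pi_acc / kept


def infer_mixture(
    baseline: Baseline,
    mixture: GenotypeTable,
    cfg: McmcConfig | None = None,
    compute_z: bool = True,
) -> MixtureResult:
    """Infer mixing proportions and individual origins for a mixture sample.

    Deterministic given ``cfg.seed``. Raises when no locus is shared between
    baseline and mixture, or the mixture is empty.
    """
    cfg = cfg or McmcConfig()
    if not mixture.individuals:
        raise ValueError("mixture contains no individuals")
    mix_called = mixture.called()
    shared = set(mix_called["locus"]) & set(baseline.loci)
    if not shared:
        raise ValueError("no loci shared between baseline and mixture")
    extra = {
        locus: set(grp["allele_1"]) | set(grp["allele_2"])
        for locus, grp in mix_called.groupby("locus")
        if locus in set(baseline.loci)
    }
    fm = _FreqModel(baseline, extra_alleles=extra)
    M, indivs = fm.loglik_matrix(mixture)
    rng = np.random.default_rng(cfg.seed)
    post, pi_mean = _gibbs(M, cfg.pi_prior_vec(len(baseline.collections)), cfg, rng)
    return _package_result(baseline, mixture, fm, M, post, pi_mean, indivs, compute_z)


def _package_result(
    baseline: Baseline,
    mixture: GenotypeTable,
    fm: "_FreqModel",
    M: np.ndarray,
    post: np.ndarray,
    pi_mean: np.ndarray,
    indivs: list[str],
    compute_z: bool,
) -> MixtureResult:
    colls = baseline.collections
    units = baseline.units
    unit_of = np.array([units.index(baseline.repunit_map[c]) for c in colls])
    indiv_post = pd.DataFrame(post, index=indivs, columns=colls)
    unit_post = pd.DataFrame(0.0, index=indivs, columns=units)
    for ci, ui in enumerate(unit_of):
        unit_post.iloc[:, ui] += indiv_post.iloc[:, ci]
    mixing = pd.Series(pi_mean, index=colls, name="pi")
    unit_mixing = mixing.groupby(mixing.index.map(baseline.repunit_map)).sum()
    unit_mixing = unit_mixing.reindex(units)
    map_coll = indiv_post.idxmax(axis=1)
    map_unit = unit_post.idxmax(axis=1)
    confidence = unit_post.max(axis=1)
    if compute_z:
        z = z_scores(baseline, mixture, map_coll, fm=fm)
    else:
        z = pd.Series(np.nan, index=indivs)
    return MixtureResult(
        collections=colls, units=units, repunit_map=dict(baseline.repunit_map),
        mixing_proportions=mixing, unit_mixing_proportions=unit_mixing,
        indiv_posteriors=indiv_post, unit_posteriors=unit_post,
        map_collection=map_coll, map_unit=map_unit,
        confidence=confidence, z_score=z,
    )


def z_scores(
    baseline: Baseline,
    genotypes: GenotypeTable,
    map_collection: pd.Series,
    fm: "_FreqModel | None" = None,
) -> pd.Series:
    """Standardised genotype log-likelihood under the MAP collection.

    z = (logL_obs - mu) / sigma, with mu and sigma^2 summed over the
    individual's called loci from the exact per-locus moments of log P(G)
    under HWE draws from the MAP collection's posterior-mean frequencies.
    Individuals whose informative-locus variance is zero get NaN (flagged).
    """
    if fm is None:
        called = genotypes.called()
        extra = {
            locus: set(grp["allele_1"]) | set(grp["allele_2"])
            for locus, grp in called.groupby("locus")
            if locus in set(baseline.loci)
        }
        fm = _FreqModel(baseline, extra_alleles=extra)
    moments: dict[tuple[int, str], tuple[float, float]] = {}

    def locus_moments(ci: int, locus: str) -> tuple[float, float]:
        key = (ci, locus)
        if key not in moments:
            p = fm.freqs[locus][ci]
            Q = np.outer(p, p)
            V = np.zeros_like(Q)
            off = ~np.eye(len(p), dtype=bool)
            with np.errstate(divide="ignore"):
                np.fill_diagonal(V, 2 * np.log(p))
                V[off] = np.log(2 * Q[off])
            ok = Q > 0
            mu = float((Q[ok] * V[ok]).sum())
            m2 = float((Q[ok] * V[ok] ** 2).sum())
            moments[key] = (mu, m2 - mu**2)
        return moments[key]

    c_idx = {c: i for i, c in enumerate(baseline.collections)}
    out = {}
    called = genotypes.called()
    by_indiv = dict(tuple(called.groupby("indiv")))
    for indiv, map_c in map_collection.items():
        ci = c_idx[map_c]
        grp = by_indiv.get(indiv)
        if grp is None:
            out[indiv] = np.nan
            continue
        logl = 0.0
        mu = 0.0
        var = 0.0
        for locus, a, b in zip(grp["locus"], grp["allele_1"], grp["allele_2"]):
            if locus not in fm.a_idx:
                continue
            idx = fm.a_idx[locus]
            lf = fm.log_freqs[locus][ci]
            ia, ib = idx[a], idx[b]
            logl += lf[ia] + lf[ib] + (_LOG2 if ia != ib else 0.0)
            m, v = locus_moments(ci, locus)
            mu += m
            var += v
        out[indiv] = (logl - mu) / np.sqrt(var) if var > 0 else np.nan
    return pd.Series(out, name="z_score").reindex(map_collection.index)


def confidence_filter(
    result: MixtureResult,
    min_posterior: float = 0.9,
    z_bounds: tuple[float, float] = (-5.0, 5.0),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Retain individuals with confident, in-range assignments.

    Retained iff max reporting-unit posterior > ``min_posterior`` (strict) and
    z strictly inside ``z_bounds``. Individuals with undefined z are excluded
    and reported. Returns (retained, excluded-with-reasons) frames.
    """
    frame = result.to_frame().set_index("indiv")
    lo, hi = z_bounds
    reasons = []
    for indiv, row in frame.iterrows():
        r = []
        if not row["confidence"] > min_posterior:
            r.append("low_confidence")
        z = row["z_score"]
        if np.isnan(z):
            r.append("z_undefined")
        elif not (lo < z < hi):
            r.append("z_out_of_range")
        reasons.append(";".join(r))
    frame = frame.assign(exclusion_reason=reasons)
    keep = frame["exclusion_reason"] == ""
    return (
        frame[keep].drop(columns="exclusion_reason").reset_index(),
        frame[~keep].reset_index(),
    )


@dataclass
class LooResult:
    """Accuracy of simulated-mixture leave-one-out self-assignment."""

    per_unit: pd.DataFrame      # unit, n, accuracy, n_filtered, accuracy_filtered
    overall: float              # unfiltered accuracy
    overall_filtered: float     # among confidence-passing individuals
    n_individuals: int
    n_filtered: int
    meta: dict = field(default_factory=dict)


def _baseline_loglik_loo(
    baseline: Baseline, leave_one_out: bool
) -> tuple[np.ndarray, list[str], np.ndarray, np.ndarray]:
    """Log-likelihood of every baseline individual against every collection,
    with the self-collection entry recomputed leave-one-out when requested.

    Returns (M, individuals, collection index per individual, unit index)."""
    fm = _FreqModel(baseline)
    M, indivs = fm.loglik_matrix(baseline.genotypes)
    info = (
        baseline.genotypes.data[["indiv", "collection"]]
        .drop_duplicates("indiv").set_index("indiv")["collection"]
    )
    c_idx = {c: i for i, c in enumerate(baseline.collections)}
    u_idx = {u: i for i, u in enumerate(baseline.units)}
    coll_of = np.array([c_idx[info[i]] for i in indivs])
    unit_of = np.array([u_idx[baseline.repunit_map[info[i]]] for i in indivs])
    if leave_one_out:
        called = baseline.genotypes.called()
        r_idx = {ind: i for i, ind in enumerate(indivs)}
        for (indiv, locus), grp in called.groupby(["indiv", "locus"]):
            row = r_idx[indiv]
            ci = coll_of[row]
            idx = fm.a_idx[locus]
            a, b = grp["allele_1"].iloc[0], grp["allele_2"].iloc[0]
            ia, ib = idx[a], idx[b]
            own = np.zeros(len(fm.alleles[locus]))
            own[ia] += 1
            own[ib] += 1
            lf = fm.log_freqs[locus][ci]
            old = lf[ia] + lf[ib] + (_LOG2 if ia != ib else 0.0)
            n_left = baseline.n_called[locus][ci] - 1
            if n_left <= 0:
                prior = fm.priors[locus]
                fa = prior[ia] / prior.sum()
                fb = prior[ib] / prior.sum()
            else:
                fa = fm.loo_freq(locus, ci, ia, own)
                fb = fm.loo_freq(locus, ci, ib, own)
            new = np.log(fa) + np.log(fb) + (_LOG2 if ia != ib else 0.0)
            M[row, ci] += new - old
    return M, indivs, coll_of, unit_of


def loo_assess(
    baseline: Baseline,
    n_mixtures: int = 50,
    mixture_size: int = 200,
    proportion_prior: float = 1.5,
    cfg: McmcConfig | None = None,
    seed: int = 0,
    min_posterior: float = 0.9,
    leave_one_out: bool = True,
    proportions: str = "dirichlet",
) -> LooResult:
    """Leave-one-out simulated-mixture assessment of assignment accuracy.

    Repeats ``n_mixtures`` times: draw reporting-unit proportions from a
    symmetric Dirichlet(``proportion_prior``) (or use equal proportions when
    ``proportions='equal'``), resample baseline individuals (with replacement)
    according to those proportions, infer the mixture, and score each
    individual's MAP reporting unit against its true unit. An evaluated
    individual's own alleles are removed from its source collection's
    frequency estimate (leave-one-out), so self-assignment is not
    optimistically biased.

    Accuracy is reported overall and per unit, both unfiltered and among
    individuals whose max unit posterior exceeds ``min_posterior``.
    """
    cfg = cfg or McmcConfig()
    if proportions not in {"dirichlet", "equal"}:
        raise ValueError("proportions must be 'dirichlet' or 'equal'")
    M, indivs, coll_of, unit_of = _baseline_loglik_loo(baseline, leave_one_out)
    all_units = baseline.units
    empty = [u for u in all_units if not (unit_of == all_units.index(u)).any()]
    if empty:
        import logging
        logging.getLogger(__name__).warning(
            "units with no baseline individuals excluded from simulation: %s", empty
        )
    sim_units = [u for u in all_units if u not in set(empty)]
    sim_idx = np.array([all_units.index(u) for u in sim_units])
    U = len(sim_units)
    by_unit = {all_units.index(u): np.flatnonzero(unit_of == all_units.index(u))
               for u in sim_units}
    rng = np.random.default_rng(seed)
    pi_prior = cfg.pi_prior_vec(len(baseline.collections))
    unit_of_coll = np.array(
        [all_units.index(baseline.repunit_map[c]) for c in baseline.collections]
    )
    records = []
    for rep in range(n_mixtures):
        if proportions == "dirichlet":
            p = rng.dirichlet(np.full(U, proportion_prior))
        else:
            p = np.full(U, 1.0 / U)
        true_units = sim_idx[rng.choice(U, size=mixture_size, p=p)]
        rows = np.array([rng.choice(by_unit[u]) for u in true_units])
        sub_cfg = McmcConfig(
            n_sweeps=cfg.n_sweeps, burn_in=cfg.burn_in, pi_prior=cfg.pi_prior,
            seed=int(rng.integers(2**31 - 1)),
        )
        post, _ = _gibbs(
            M[rows], pi_prior, sub_cfg, np.random.default_rng(sub_cfg.seed)
        )
        unit_post = np.zeros((mixture_size, len(all_units)))
        for ci, ui in enumerate(unit_of_coll):
            unit_post[:, ui] += post[:, ci]
        map_u = unit_post.argmax(axis=1)
        conf = unit_post.max(axis=1)
        records.append(
            pd.DataFrame(
                {"rep": rep, "true_unit": true_units, "map_unit": map_u,
                 "confidence": conf, "correct": map_u == true_units}
            )
        )
    allrec = pd.concat(records, ignore_index=True)
    passing = allrec[allrec["confidence"] > min_posterior]
    per_unit = []
    for ui, unit in enumerate(all_units):
        sub = allrec[allrec["true_unit"] == ui]
        subf = passing[passing["true_unit"] == ui]
        per_unit.append(
            {"unit": unit, "n": len(sub),
             "accuracy": sub["correct"].mean() if len(sub) else np.nan,
             "n_filtered": len(subf),
             "accuracy_filtered": subf["correct"].mean() if len(subf) else np.nan}
        )
    return LooResult(
        per_unit=pd.DataFrame(per_unit),
        overall=float(allrec["correct"].mean()),
        overall_filtered=float(passing["correct"].mean()) if len(passing) else np.nan,
        n_individuals=len(allrec),
        n_filtered=len(passing),
        meta={
            "n_mixtures": n_mixtures, "mixture_size": mixture_size,
            "proportion_prior": proportion_prior, "proportions": proportions,
            "leave_one_out": leave_one_out, "min_posterior": min_posterior,
            "n_sweeps": cfg.n_sweeps, "burn_in": cfg.burn_in, "seed": seed,
        },
    )


def mixture_composition_report(
    results_by_site: dict[str, MixtureResult],
    min_individuals: int = 10,
    min_posterior: float = 0.9,
    z_bounds: tuple[float, float] = (-5.0, 5.0),
    on_undersized: str = "error",
) -> pd.DataFrame:
    """Stacked stock-composition table across mixture collection sites.

    Per site: reporting-unit mixing proportions (chain averages), MAP counts
    among retained individuals, and exclusion tallies from the confidence and
    z filters. Sites with fewer than ``min_individuals`` raise an error by
    default (callers should merge nearby sites before inference) or are kept
    with a flag when ``on_undersized='keep'``.
    """
    if on_undersized not in {"error", "keep"}:
        raise ValueError("on_undersized must be 'error' or 'keep'")
    rows = []
    for site, res in results_by_site.items():
        n = len(res.indiv_posteriors)
        if n < min_individuals and on_undersized == "error":
            raise ValueError(
                f"site {site!r} has {n} < {min_individuals} individuals; "
                "merge with a neighbouring site before inference"
            )
        retained, excluded = confidence_filter(res, min_posterior, z_bounds)
        row: dict = {"site": site, "n": n, "n_retained": len(retained),
                     "n_excluded": len(excluded),
                     "undersized": n < min_individuals}
        for unit in res.units:
            row[f"prop_{unit}"] = res.unit_mixing_proportions[unit]
        map_counts = retained["map_unit"].value_counts() if len(retained) else pd.Series(dtype=int)
        for unit in res.units:
            row[f"n_map_{unit}"] = int(map_counts.get(unit, 0))
        rows.append(row)
    return pd.DataFrame(rows)
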