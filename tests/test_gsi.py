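"""Bayesian mixture engine: posterior frequencies, likelihoods, Gibbs
inference, z-score diagnostics, confidence filtering, and LOO assessment."""

import numpy as np
import pandas as pd
import pytest

import gsikit as gk
from gsikit.gsi import (
    Baseline,
    McmcConfig,
    MixtureResult,
    baseline_posterior_freqs,
    confidence_filter,
    genotype_log_likelihood,
    infer_mixture,
    loo_assess,
    mixture_composition_report,
    z_scores,
)
from gsikit.simulate import MixtureSpec

from conftest import biallelic_model


def table(rows) -> gk.GenotypeTable:
    return gk.GenotypeTable(pd.DataFrame(rows))


def geno_rows(coll, unit, genos, locus="L1", prefix=None):
    prefix = prefix or coll
    return [
        {"indiv": f"{prefix}_{i}", "collection": coll, "repunit": unit,
         "locus": locus, "allele_1": a, "allele_2": b}
        for i, (a, b) in enumerate(genos)
    ]


@pytest.fixture(scope="module")
def separable():
    """4 units x 1 collection, 150 multi-allelic loci at FST 0.05, n=50."""
    model = gk.default_population_model(4, 150, 0.05, seed=201)
    pfreqs = gk.draw_population_freqs(model, seed=202)
    gt = gk.simulate_baseline(pfreqs, 50, seed=203)
    return model, pfreqs, Baseline(gt)


class TestBaselinePosterior:
    def test_closed_form_pseudocount(self):
        rows = geno_rows("X", "U", [("A", "A")] * 10)
        rows += geno_rows("Y", "U", [("A", "T")] * 5)
        base = Baseline(table(rows), allele_prior=0.5)
        freqs = baseline_posterior_freqs(base)
        assert freqs["X"]["L1"]["A"] == pytest.approx(20.5 / 21)

    def test_absent_collection_gets_uniform_prior(self):
        rows = geno_rows("X", "U", [("A", "T")] * 5, locus="L1")
        rows += geno_rows("X", "U", [("A", "T")] * 5, locus="L2")
        rows += geno_rows("Y", "U", [("A", "T")] * 5, locus="L1")
        gt = table(rows)
        # Y has no calls at L2
        gt.data.loc[
            (gt.data["collection"] == "Y") & (gt.data["locus"] == "L2"),
            ["allele_1", "allele_2"],
        ] = np.nan
        freqs = baseline_posterior_freqs(Baseline(gt))
        assert freqs["Y"]["L2"]["A"] == pytest.approx(0.5)

    def test_frequencies_sum_to_one(self, separable):
        _, _, base = separable
        freqs = baseline_posterior_freqs(base)
        for coll in base.collections:
            for vec in freqs[coll].values():
                assert sum(vec.values()) == pytest.approx(1.0)


class TestGenotypeLogLikelihood:
    def test_homozygote_value(self):
        ll = genotype_log_likelihood({"L1": ("A", "A")}, {"L1": {"A": 0.5, "T": 0.5}})
        assert ll == pytest.approx(np.log(0.25))

    def test_additivity_over_loci(self):
        freqs = {"L1": {"A": 0.5, "T": 0.5}, "L2": {"A": 0.2, "T": 0.8}}
        l1 = genotype_log_likelihood({"L1": ("A", "A")}, freqs)
        l2 = genotype_log_likelihood({"L2": ("A", "T")}, freqs)
        both = genotype_log_likelihood({"L1": ("A", "A"), "L2": ("A", "T")}, freqs)
        assert both == pytest.approx(l1 + l2)

    def test_matches_product_oracle(self):
        freqs = {"L1": {"A": 0.7, "T": 0.3}, "L2": {"C": 0.1, "G": 0.9}}
        geno = {"L1": ("A", "T"), "L2": ("G", "G")}
        oracle = np.log(2 * 0.7 * 0.3) + np.log(0.9 * 0.9)
        assert genotype_log_likelihood(geno, freqs) == pytest.approx(oracle)

    def test_missing_locus_skipped(self):
        ll = genotype_log_likelihood({"Lx": ("A", "A")}, {"L1": {"A": 1.0}})
        assert ll == 0.0


class TestInferMixture:
    def test_pure_mixture_recovers_unit(self, separable):
        _, pfreqs, base = separable
        mix = gk.simulate_mixture(
            pfreqs, MixtureSpec(np.array([1.0, 0, 0, 0]), 60, seed=204)
        )
        res = infer_mixture(base, mix, McmcConfig(n_sweeps=800, burn_in=100, seed=1))
        assert res.unit_mixing_proportions["P01"] >= 0.95

    def test_identical_collections_split_posterior(self):
        rng = np.random.default_rng(9)
        genos = [tuple(sorted(rng.choice(["A", "T"], 2))) for _ in range(40)]
        rows = geno_rows("X", "U1", genos) + geno_rows("Y", "U2", genos, prefix="Y")
        base = Baseline(table(rows))
        mix_rows = [
            {"indiv": f"m{i}", "collection": "", "repunit": "", "locus": "L1",
             "allele_1": a, "allele_2": b}
            for i, (a, b) in enumerate(genos[:20])
        ]
        res = infer_mixture(base, table(mix_rows),
                            McmcConfig(n_sweeps=2000, burn_in=100, seed=2))
        # byte-identical baselines: every posterior ~0.5/0.5
        assert np.allclose(res.indiv_posteriors["X"], 0.5, atol=0.05)

    def test_parameter_recovery(self, separable):
        _, pfreqs, base = separable
        truth = np.array([0.6, 0.3, 0.1, 0.0])
        mix = gk.simulate_mixture(pfreqs, MixtureSpec(truth, 400, seed=205))
        res = infer_mixture(base, mix, McmcConfig(n_sweeps=2000, burn_in=100, seed=3))
        est = res.unit_mixing_proportions.to_numpy()
        assert np.all(np.abs(est - truth) <= 0.05)

    def test_seed_determinism_bitwise(self, separable):
        _, pfreqs, base = separable
        mix = gk.simulate_mixture(
            pfreqs, MixtureSpec(np.array([0.5, 0.5, 0, 0]), 30, seed=206)
        )
        cfg = McmcConfig(n_sweeps=300, burn_in=50, seed=7)
        a = infer_mixture(base, mix, cfg)
        b = infer_mixture(base, mix, cfg)
        assert np.array_equal(a.mixing_proportions.to_numpy(),
                              b.mixing_proportions.to_numpy())
        assert np.array_equal(a.indiv_posteriors.to_numpy(),
                              b.indiv_posteriors.to_numpy())

    def test_label_permutation_invariance(self, separable):
        _, pfreqs, base = separable
        mix = gk.simulate_mixture(
            pfreqs, MixtureSpec(np.array([0.4, 0.3, 0.2, 0.1]), 120, seed=207)
        )
        res = infer_mixture(base, mix, McmcConfig(n_sweeps=1000, burn_in=100, seed=4))
        # relabel collections (reverse order) and re-infer
        relabel = dict(zip(base.collections, reversed(base.collections)))
        gt2 = base.genotypes.data.copy()
        gt2["collection"] = gt2["collection"].map(relabel)
        gt2["repunit"] = gt2["collection"]
        base2 = Baseline(gk.GenotypeTable(gt2, loci=base.genotypes.loci))
        res2 = infer_mixture(base2, mix, McmcConfig(n_sweeps=1000, burn_in=100, seed=4))
        for c in base.collections:
            assert res.mixing_proportions[c] == pytest.approx(
                res2.mixing_proportions[relabel[c]], abs=0.01
            )

    def test_uninformative_loci_return_prior_mean(self):
        rows = geno_rows("X", "U1", [("A", "A")] * 15)
        rows += geno_rows("Y", "U2", [("A", "A")] * 15, prefix="Y")
        base = Baseline(table(rows))
        mix_rows = [
            {"indiv": f"m{i}", "collection": "", "repunit": "", "locus": "L1",
             "allele_1": "A", "allele_2": "A"}
            for i in range(20)
        ]
        res = infer_mixture(base, table(mix_rows),
                            McmcConfig(n_sweeps=4000, burn_in=500, seed=5),
                            compute_z=False)
        # flat likelihood: posterior over pi equals the Dirichlet prior
        assert res.mixing_proportions["X"] == pytest.approx(0.5, abs=0.05)

    def test_empty_inputs_rejected(self, separable):
        _, pfreqs, base = separable
        empty = gk.GenotypeTable(base.genotypes.data.iloc[:0])
        with pytest.raises(ValueError):
            infer_mixture(base, empty)
        foreign = table(
            [{"indiv": "m0", "collection": "", "repunit": "", "locus": "ZZZ",
              "allele_1": "A", "allele_2": "A"}]
        )
        with pytest.raises(ValueError):
            infer_mixture(base, foreign)


class TestZScores:
    def test_calibration_under_true_collection(self):
        """Individuals drawn from the MAP collection have z ~ N(0, 1).

        The baseline must be large: z is referenced to posterior-mean
        frequencies, so finite-sample estimation error otherwise shifts the
        mean negative by ~ sum of per-locus KL divergences / sigma."""
        model = gk.default_population_model(2, 200, 0.05, seed=301)
        pfreqs = gk.draw_population_freqs(model, seed=302)
        gt = gk.simulate_baseline(pfreqs, 600, seed=303)
        base = Baseline(gt)
        fresh = gk.simulate_mixture(
            pfreqs, MixtureSpec(np.array([1.0, 0.0]), 200, seed=304)
        )
        map_coll = pd.Series("P01", index=fresh.individuals)
        z = z_scores(base, fresh, map_coll)
        assert -0.2 < z.mean() < 0.2
        assert 0.8 < z.std() < 1.2

    def test_foreign_individual_strongly_negative(self):
        # baseline nearly fixed for A at every locus; the outlier is T/T
        # throughout, i.e. from a population absent from the baseline
        rows = []
        for j in range(30):
            rows += geno_rows("X", "U", [("A", "A")] * 20 + [("A", "T")],
                              locus=f"L{j:02d}")
        base = Baseline(table(rows))
        out_rows = [
            {"indiv": "alien", "collection": "", "repunit": "",
             "locus": f"L{j:02d}", "allele_1": "T", "allele_2": "T"}
            for j in range(30)
        ]
        z = z_scores(base, table(out_rows), pd.Series("X", index=["alien"]))
        assert z["alien"] < -5

    def test_monomorphic_only_flagged_undefined(self):
        rows = geno_rows("X", "U", [("A", "A")] * 10)
        base = Baseline(table(rows))
        mrows = [{"indiv": "m0", "collection": "", "repunit": "", "locus": "L1",
                  "allele_1": "A", "allele_2": "A"}]
        z = z_scores(base, table(mrows), pd.Series("X", index=["m0"]))
        assert np.isnan(z["m0"])


class TestConfidenceFilter:
    def _result(self, confidence, z):
        idx = [f"i{k}" for k in range(len(confidence))]
        units = ["U1", "U2"]
        post = pd.DataFrame(
            {"U1": confidence, "U2": [1 - c for c in confidence]}, index=idx
        )
        return MixtureResult(
            collections=["X", "Y"], units=units, repunit_map={"X": "U1", "Y": "U2"},
            mixing_proportions=pd.Series([0.5, 0.5], index=["X", "Y"]),
            unit_mixing_proportions=pd.Series([0.5, 0.5], index=units),
            indiv_posteriors=post.rename(columns={"U1": "X", "U2": "Y"}),
            unit_posteriors=post,
            map_collection=pd.Series("X", index=idx),
            map_unit=post.idxmax(axis=1),
            confidence=post.max(axis=1),
            z_score=pd.Series(z, index=idx),
        )

    def test_boundary_and_z_rules(self):
        res = self._result([0.89, 0.99, 0.99, 0.99], [0.0, -5.2, 0.0, np.nan])
        retained, excluded = confidence_filter(res)
        assert retained["indiv"].tolist() == ["i2"]
        reasons = dict(zip(excluded["indiv"], excluded["exclusion_reason"]))
        assert "low_confidence" in reasons["i0"]
        assert "z_out_of_range" in reasons["i1"]
        assert "z_undefined" in reasons["i3"]

    def test_exactly_ninety_percent_excluded(self):
        res = self._result([0.9], [0.0])
        retained, excluded = confidence_filter(res)
        assert retained.empty and len(excluded) == 1


class TestLooAssess:
    def test_single_unit_trivially_perfect(self):
        rows = geno_rows("X", "U", [("A", "T")] * 25)
        base = Baseline(table(rows))
        res = loo_assess(base, n_mixtures=2, mixture_size=10,
                         cfg=McmcConfig(n_sweeps=200, burn_in=50, seed=0), seed=1)
        assert res.overall == 1.0

    def test_separable_baseline_high_accuracy(self, separable):
        _, _, base = separable
        res = loo_assess(base, n_mixtures=5, mixture_size=80,
                         cfg=McmcConfig(n_sweeps=600, burn_in=100, seed=0), seed=2)
        assert res.overall_filtered >= 0.97

    def test_no_loo_is_optimistic(self):
        """Disabling leave-one-out inflates self-assignment accuracy."""
        model = biallelic_model(2, 30, 0.02, seed=401)  # weakly separated
        pfreqs = gk.draw_population_freqs(model, seed=402)
        gt = gk.simulate_baseline(pfreqs, 25, seed=403)
        base = Baseline(gt)
        kw = dict(n_mixtures=6, mixture_size=50,
                  cfg=McmcConfig(n_sweeps=400, burn_in=100, seed=0), seed=3)
        with_loo = loo_assess(base, leave_one_out=True, **kw)
        without = loo_assess(base, leave_one_out=False, **kw)
        assert without.overall >= with_loo.overall

    def test_equal_proportions_mode(self, separable):
        _, _, base = separable
        res = loo_assess(base, n_mixtures=2, mixture_size=40, proportions="equal",
                         cfg=McmcConfig(n_sweeps=300, burn_in=50, seed=0), seed=4)
        counts = res.per_unit.set_index("unit")["n"]
        assert counts.sum() == 80


class TestCompositionReport:
    def _pure_result(self):
        idx = ["a", "b", "c"] + [f"x{k}" for k in range(7)]
        units = ["U1", "U2"]
        post = pd.DataFrame({"U1": [0.99] * 10, "U2": [0.01] * 10}, index=idx)
        return MixtureResult(
            collections=["X", "Y"], units=units, repunit_map={"X": "U1", "Y": "U2"},
            mixing_proportions=pd.Series([0.97, 0.03], index=["X", "Y"]),
            unit_mixing_proportions=pd.Series([0.97, 0.03], index=units),
            indiv_posteriors=post.rename(columns={"U1": "X", "U2": "Y"}),
            unit_posteriors=post,
            map_collection=pd.Series("X", index=idx),
            map_unit=post.idxmax(axis=1),
            confidence=post.max(axis=1),
            z_score=pd.Series(0.0, index=idx),
        )

    def test_single_unit_site(self):
        rep = mixture_composition_report({"site1": self._pure_result()})
        row = rep.iloc[0]
        assert row["n_map_U1"] == 10 and row["n_map_U2"] == 0
        assert row["prop_U1"] + row["prop_U2"] == pytest.approx(1.0)

    def test_undersized_site_rejected(self):
        res = self._pure_result()
        small = MixtureResult(
            **{**res.__dict__, "indiv_posteriors": res.indiv_posteriors.iloc[:5]}
        )
        with pytest.raises(ValueError):
            mixture_composition_report({"tiny": small})
        rep = mixture_composition_report({"tiny": small}, on_undersized="keep")
        assert rep.iloc[0]["undersized"]
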