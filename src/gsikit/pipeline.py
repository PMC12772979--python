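"""End-to-end pipeline: simulate -> FST -> panel -> calling -> GSI -> movement.

A YAML/dict configuration drives the stages; unknown keys are rejected, every
stochastic stage derives its seed from the global seed, and a JSON manifest
records seeds, parameters, and SHA-256 hashes of every output so identical
configurations produce hash-identical runs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from importlib.metadata import version as _pkg_version
from pathlib import Path

import numpy as np
import yaml

from . import calling, gsi, movement, panel, popgen, simulate

logger = logging.getLogger(__name__)

_ALLOWED = {
    None: {"seed", "out_dir", "log_level", "simulate", "select_panel", "call",
           "gsi", "movement_test"},
    "simulate": {"n_pops", "n_loci", "fst", "n_per_pop", "n_chroms",
                 "chrom_length", "mixture", "reads"},
    "mixture": {"proportions", "n_individuals"},
    "reads": {"mean_depth", "depth_dispersion", "error_rate"},
    "select_panel": {"top_n_per_chrom_pair", "fst_floor", "windows_per_chrom",
                     "loci_per_window", "one_pair_per_chrom"},
    "call": {"min_locus_depth", "min_depth_ratio", "min_indiv_callrate",
             "min_locus_callrate", "hwe_alpha", "hwe_collection_majority",
             "hwe_min_n", "hwe_permutations", "apply_hwe_filter"},
    "gsi": {"n_sweeps", "burn_in", "pi_prior", "min_posterior", "z_bounds",
            "loo"},
    "loo": {"n_mixtures", "mixture_size", "proportion_prior"},
    "movement_test": {"n_replicates", "replicate_mode"},
}


def _check_keys(block: dict, name: str | None) -> None:
    allowed = _ALLOWED[name]
    unknown = set(block) - allowed
    if unknown:
        where = name or "top level"
        raise ValueError(f"unknown config keys in {where}: {sorted(unknown)}")
    for key, val in block.items():
        if key in _ALLOWED and isinstance(val, dict):
            _check_keys(val, key)


@dataclass
class PipelineConfig:
    """Validated pipeline configuration with paper-default stage parameters."""

    seed: int = 1
    out_dir: str = "gsikit_run"
    log_level: str = "INFO"
    simulate: dict = field(default_factory=dict)
    select_panel: dict = field(default_factory=dict)
    call: dict = field(default_factory=dict)
    gsi: dict = field(default_factory=dict)
    movement_test: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        _check_keys(raw, None)
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)


def demo_config(out_dir: str = "gsikit_demo") -> PipelineConfig:
    """A small configuration that exercises every stage in well under a
    minute: 4 populations, 60 microhaplotype loci on 6 chromosomes."""
    return PipelineConfig.from_dict(
        {
            "seed": 1,
            "out_dir": out_dir,
            "simulate": {
                "n_pops": 4, "n_loci": 60, "fst": 0.05, "n_per_pop": 30,
                "n_chroms": 6, "chrom_length": 25_000_000,
                "mixture": {"proportions": [0.7, 0.1, 0.1, 0.1],
                            "n_individuals": 60},
                "reads": {"mean_depth": 80, "depth_dispersion": 5,
                          "error_rate": 0.005},
            },
            "select_panel": {"fst_floor": 0.02},
            "call": {"hwe_permutations": 2000},
            "gsi": {"n_sweeps": 600, "burn_in": 100,
                    "loo": {"n_mixtures": 3, "mixture_size": 40}},
            "movement_test": {"n_replicates": 5000},
        }
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured pipeline and return the manifest dict.

    Stages: simulate baseline/mixture/reads -> per-locus pairwise FST ->
    windowed panel selection -> microhaplotype calling and filtering ->
    mixture inference with LOO assessment -> seasonal movement test. All
    outputs land in ``config.out_dir``; the manifest records seeds and
    SHA-256 hashes of every file.
    """
    logging.basicConfig(level=getattr(logging, config.log_level, logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s) for s in ss.generate_state(8) % (2**31 - 1)]
    manifest: dict = {
        "package": "gsikit", "version": _pkg_version("gsikit"),
        "seed": config.seed, "stage_seeds": seeds, "outputs": {},
        "config": asdict(config),
    }
    sim = config.simulate
    n_pops = sim.get("n_pops", 4)
    model = simulate.default_population_model(
        n_pops=n_pops,
        n_loci=sim.get("n_loci", 60),
        fst=sim.get("fst", 0.05),
        seed=seeds[0],
        n_chroms=sim.get("n_chroms", 6),
        chrom_length=sim.get("chrom_length", 25_000_000),
    )
    pfreqs = simulate.draw_population_freqs(model, seed=seeds[1])
    baseline_gt = simulate.simulate_baseline(
        pfreqs, n_per_pop=sim.get("n_per_pop", 30), seed=seeds[2]
    )
    mix_conf = sim.get("mixture", {})
    props = np.asarray(mix_conf.get("proportions", [0.7, 0.1, 0.1, 0.1]))
    spec = simulate.MixtureSpec(
        true_proportions=props,
        n_individuals=mix_conf.get("n_individuals", 60),
        seed=seeds[3],
    )
    mixture_gt = simulate.simulate_mixture(pfreqs, spec)
    reads_conf = sim.get("reads", {})
    rspec = simulate.ReadSimSpec(
        mean_depth=reads_conf.get("mean_depth", 80),
        depth_dispersion=reads_conf.get("depth_dispersion", 5),
        error_rate=reads_conf.get("error_rate", 0.005),
        seed=seeds[4],
    )
    baseline_reads = simulate.simulate_reads(baseline_gt, rspec, model.alleles)
    rspec_mix = simulate.ReadSimSpec(
        mean_depth=rspec.mean_depth, depth_dispersion=rspec.depth_dispersion,
        error_rate=rspec.error_rate, seed=seeds[5],
    )
    mixture_reads = simulate.simulate_reads(mixture_gt, rspec_mix, model.alleles)
    baseline_gt.to_csv(out / "baseline_true.csv")
    mixture_gt.to_csv(out / "mixture_true.csv")
    baseline_reads.to_csv(out / "baseline_reads.csv")
    mixture_reads.to_csv(out / "mixture_reads.csv")

    # per-locus pairwise FST from the simulated baseline
    landscape = popgen.fst_landscape(baseline_gt)
    landscape.chrom_lengths = {
        c: sim.get("chrom_length", 25_000_000)
        for c in baseline_gt.loci["chrom"].unique()
    }
    landscape.to_csv(out / "fst_landscape.csv")

    sel_cfg = panel.SelectionConfig(**config.select_panel)
    candidates = panel.select_panel(landscape, cfg=sel_cfg)
    candidates.to_csv(out / "panel.csv", index=False)
    panel_loci = list(candidates["locus"])

    call_conf = dict(config.call)
    apply_hwe = call_conf.pop("apply_hwe_filter", True)
    ccfg = calling.CallConfig(**call_conf)
    called_baseline = calling.call_table(baseline_reads, ccfg).subset_loci(panel_loci)
    called_baseline, base_report = calling.missingness_filter(called_baseline, ccfg)
    if apply_hwe:
        called_baseline, hwe_summary = calling.hwe_locus_filter(called_baseline, ccfg)
        hwe_summary.to_csv(out / "hwe_summary.csv", index=False)
    called_mixture = calling.call_table(mixture_reads, ccfg).subset_loci(
        called_baseline.locus_names
    )
    called_mixture, _ = calling.missingness_filter(called_mixture, ccfg)
    called_mixture.true_origin = mixture_gt.true_origin
    called_baseline.to_csv(out / "baseline_called.csv")
    called_mixture.to_csv(out / "mixture_called.csv")

    gsi_conf = config.gsi
    mcfg = gsi.McmcConfig(
        n_sweeps=gsi_conf.get("n_sweeps", 2000),
        burn_in=gsi_conf.get("burn_in", 100),
        pi_prior=gsi_conf.get("pi_prior", "1/C"),
        seed=seeds[6],
    )
    base = gsi.Baseline(called_baseline)
    result = gsi.infer_mixture(base, called_mixture, mcfg)
    result.to_frame().to_csv(out / "assignments.csv", index=False)
    retained, excluded = gsi.confidence_filter(
        result,
        min_posterior=gsi_conf.get("min_posterior", 0.9),
        z_bounds=tuple(gsi_conf.get("z_bounds", (-5, 5))),
    )
    excluded.to_csv(out / "excluded.csv", index=False)
    loo_conf = gsi_conf.get("loo", {})
    loo = gsi.loo_assess(
        base,
        n_mixtures=loo_conf.get("n_mixtures", 3),
        mixture_size=loo_conf.get("mixture_size", 40),
        proportion_prior=loo_conf.get("proportion_prior", 1.5),
        cfg=mcfg,
        seed=seeds[7],
    )
    loo.per_unit.to_csv(out / "loo_accuracy.csv", index=False)

    # seasonal test: summer = the mixture collection, winter = the dominant
    # unit's baseline collection self-labels
    major_unit = base.units[int(np.argmax(props))] if len(props) == len(base.units) else base.units[0]
    winter_counts = (
        int((called_baseline.data.drop_duplicates("indiv")["repunit"] == major_unit).sum()),
        int((called_baseline.data.drop_duplicates("indiv")["repunit"] != major_unit).sum()),
    )
    succ = int((retained["map_unit"] == major_unit).sum())
    fail = int(len(retained) - succ)
    cont = movement.SeasonalContingency(
        site="mixture", winter_counts=winter_counts, summer_counts=(succ, fail),
        n_replicates=config.movement_test.get("n_replicates", 5000),
    )
    test = movement.chisq_test(
        cont,
        seed=seeds[7],
        replicate_mode=config.movement_test.get("replicate_mode", "multinomial"),
    )
    (out / "movement_test.json").write_text(json.dumps(test.to_dict(), indent=2))

    summary = {
        "n_panel_candidates": int(len(candidates)),
        "n_loci_after_filters": len(called_baseline.locus_names),
        "mixing_proportions": {
            u: float(v) for u, v in result.unit_mixing_proportions.items()
        },
        "loo_overall_accuracy": loo.overall,
        "loo_overall_accuracy_filtered": loo.overall_filtered,
        "movement_p": test.p_value,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    for f in sorted(out.iterdir()):
        if f.name != "manifest.json" and f.is_file():
            manifest["outputs"][f.name] = _sha256(f)
    manifest["summary"] = summary
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
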