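import numpy as np
import pandas as pd
import pytest

import gsikit as gk


def biallelic_model(n_pops: int, n_loci: int, fst: float, seed: int,
                    anc: tuple[float, float] = (0.5, 0.5)) -> gk.PopulationModel:
    """A minimal hand-built model: biallelic loci, shared ancestral freqs."""
    loci = pd.DataFrame(
        {"locus": [f"L{j:03d}" for j in range(n_loci)],
         "chrom": "chr01", "pos": np.arange(n_loci) * 1000 + 1}
    )
    return gk.PopulationModel(
        n_pops=n_pops, fst=fst, loci=loci,
        ancestral_freqs={f"L{j:03d}": np.array(anc) for j in range(n_loci)},
        alleles={f"L{j:03d}": ["AAA", "TTT"] for j in range(n_loci)},
    )


@pytest.fixture(scope="session")
def four_pop_baseline() -> tuple[gk.PopulationModel, "gk.simulate.PopulationFreqs", gk.GenotypeTable]:
    """Four well-separated collections, 80 multi-allelic loci, 40 each."""
    model = gk.default_population_model(4, 80, 0.05, seed=101)
    pfreqs = gk.draw_population_freqs(model, seed=102)
    gt = gk.simulate_baseline(pfreqs, 40, seed=103)
    return model, pfreqs, gt


@pytest.fixture(scope="session")
def small_genotypes() -> gk.GenotypeTable:
    """Six individuals, one tri-allelic locus, counts hand-enumerable."""
    rows = []
    genos = [("A", "A"), ("A", "B"), ("B", "B"), ("A", "C"), ("C", "C"), ("B", "C")]
    for i, (a, b) in enumerate(genos):
        rows.append({"indiv": f"i{i}", "collection": "X", "repunit": "X",
                     "locus": "L1", "allele_1": a, "allele_2": b})
    return gk.GenotypeTable(pd.DataFrame(rows))
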