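"""Seasonal stock-movement tests.

Compares a summer mixture collection's stock composition against its winter
baseline region with a 2x2 Pearson chi-square (season x local/non-local
assignment). When any expected cell falls below 5 the p-value is simulated by
Monte-Carlo: replicate tables are drawn multinomially over the four cells
with probabilities given by the margin-derived expected proportions (total
fixed), and p uses the add-one rule (1 + #{X2_rep >= X2_obs}) / (B + 1), so
the smallest attainable p with 5000 replicates is 1/5001 ~ 0.0002.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class SeasonalContingency:
    """Success/failure counts per season for one mixture collection site.

    A success is an individual assigned to the reporting unit local to the
    region it was collected from.
    """

    site: str
    winter_counts: tuple[int, int]   # (successes, failures)
    summer_counts: tuple[int, int]
    n_replicates: int = 5000

    def __post_init__(self) -> None:
        counts = [*self.winter_counts, *self.summer_counts]
        if any(c < 0 for c in counts):
            raise ValueError("counts must be non-negative")
        if sum(counts) == 0:
            raise ValueError("at least one margin must be nonzero")

    def table(self) -> np.ndarray:
        return np.array([self.winter_counts, self.summer_counts], dtype=float)


@dataclass
class TestResult:
    site: str
    statistic: float
    p_value: float
    method: str           # "asymptotic" | "monte_carlo"
    significance: str

    def to_dict(self) -> dict:
        return {
            "site": self.site, "statistic": self.statistic, "p": self.p_value,
            "method": self.method, "significance": self.significance,
        }


def build_contingency(
    assignments: pd.DataFrame,
    site_region_map: dict[str, str],
    winter_counts_by_region: dict[str, tuple[int, int]],
    site: str,
    n_replicates: int = 5000,
) -> SeasonalContingency:
    """Tally a site's confidence-filtered assignments against its winter region.

    ``assignments`` needs columns site, map_unit; the local reporting unit for
    each site comes from ``site_region_map`` and the winter reference counts
    for that region from ``winter_counts_by_region``.
    """
    if site not in site_region_map:
        raise ValueError(f"site {site!r} has no mapped region")
    region = site_region_map[site]
    sub = assignments[assignments["site"] == site]
    if sub.empty:
        raise ValueError(f"no assignments for site {site!r}")
    succ = int((sub["map_unit"] == region).sum())
    fail = int(len(sub) - succ)
    if region not in winter_counts_by_region:
        raise ValueError(f"region {region!r} has no winter reference counts")
    return SeasonalContingency(
        site=site,
        winter_counts=tuple(winter_counts_by_region[region]),
        summer_counts=(succ, fail),
        n_replicates=n_replicates,
    )


def _pearson_x2(obs: np.ndarray) -> tuple[float, np.ndarray]:
    """Pearson X^2 without continuity correction; cells with E=0 contribute 0."""
    total = obs.sum()
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / total
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = (obs - expected) ** 2 / expected
    terms[expected == 0] = 0.0
    return float(terms.sum()), expected


def chisq_test(
    contingency: SeasonalContingency,
    n_replicates: int | None = None,
    seed: int = 0,
    replicate_mode: str = "multinomial",
    method: str = "auto",
) -> TestResult:
    """Pearson chi-square for a seasonal 2x2 table.

    With ``method='auto'``: asymptotic chi2(1) p when all expected cells are
    >= 5, otherwise a Monte-Carlo p with ``n_replicates`` simulated tables;
    'monte_carlo' or 'asymptotic' force the respective path.
    ``replicate_mode`` 'multinomial' draws cells multinomially on the expected
    proportions with the total fixed; 'patefield' conditions on both margins.
    """
    if method not in {"auto", "monte_carlo", "asymptotic"}:
        raise ValueError("method must be 'auto', 'monte_carlo' or 'asymptotic'")
    B = n_replicates if n_replicates is not None else contingency.n_replicates
    obs = contingency.table()
    if obs.sum(axis=1).min() == 0 or obs.sum(axis=0).min() == 0:
        # degenerate: one season or one outcome entirely absent
        return TestResult(contingency.site, 0.0, 1.0, "degenerate", significance_codes(1.0))
    x2, expected = _pearson_x2(obs)
    use_asymptotic = method == "asymptotic" or (
        method == "auto" and (expected >= 5).all()
    )
    if use_asymptotic:
        p = float(stats.chi2.sf(x2, df=1))
        return TestResult(contingency.site, x2, p, "asymptotic", significance_codes(p))
    rng = np.random.default_rng(seed)
    total = int(obs.sum())
    if replicate_mode == "multinomial":
        probs = (expected / total).ravel()
        reps = rng.multinomial(total, probs, size=B).reshape(B, 2, 2).astype(float)
    elif replicate_mode == "patefield":
        row = obs.sum(axis=1).astype(int)
        col = obs.sum(axis=0).astype(int)
        reps = stats.random_table(row, col).rvs(size=B, random_state=rng).astype(float)
        reps = reps.reshape(B, 2, 2)
    else:
        raise ValueError("replicate_mode must be 'multinomial' or 'patefield'")
    tot = reps.sum(axis=(1, 2), keepdims=True)
    exp_rep = (
        reps.sum(axis=2, keepdims=True) * reps.sum(axis=1, keepdims=True) / tot
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = (reps - exp_rep) ** 2 / exp_rep
    terms[~np.isfinite(terms)] = 0.0
    x2_rep = terms.sum(axis=(1, 2))
    p = (1 + int((x2_rep >= x2 - 1e-9).sum())) / (B + 1)
    return TestResult(contingency.site, x2, p, "monte_carlo", significance_codes(p))


def significance_codes(p: float) -> str:
    """NS / * / ** / *** significance banding."""
    if not (0 < p <= 1):
        raise ValueError("p must lie in (0, 1]")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "NS"


def movement_test_report(
    contingencies: list[SeasonalContingency],
    n_replicates: int | None = None,
    seed: int = 0,
    replicate_mode: str = "multinomial",
    method: str = "auto",
) -> pd.DataFrame:
    """Run the seasonal test for every site and tabulate the results."""
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(len(contingencies))
    rows = []
    for cont, s in zip(contingencies, seeds):
        res = chisq_test(cont, n_replicates=n_replicates, seed=int(s % (2**31 - 1)),
                         replicate_mode=replicate_mode, method=method)
        rows.append(res.to_dict())
    return pd.DataFrame(rows)
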