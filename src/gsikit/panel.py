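"""FST-landscape-driven GT-seq panel selection.

Four-step locus downsampling from a per-locus, per-population-pair FST table:

1. keep the top-N loci by FST per chromosome per pairwise comparison;
2. reduce the multiset to unique loci;
3. drop loci whose maximum FST over all pairs is below a floor;
4. split each chromosome into equal physical windows and keep the top-scoring
   loci per window, with at most one locus attributed to any given pairwise
   comparison per chromosome.

With the defaults (10 per chromosome-pair, floor 0.2, 6 windows x 2 loci over
23 chromosomes) a saturated landscape yields 276 candidates; supplemental
loci are then injected to form the final candidate panel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import FSTLandscape

logger = logging.getLogger(__name__)


@dataclass
class SelectionConfig:
    top_n_per_chrom_pair: int = 10
    fst_floor: float = 0.2
    windows_per_chrom: int = 6
    loci_per_window: int = 2
    one_pair_per_chrom: bool = True

    def __post_init__(self) -> None:
        if min(self.top_n_per_chrom_pair, self.windows_per_chrom, self.loci_per_window) < 1:
            raise ValueError("selection counts must be >= 1")
        if not (0.0 <= self.fst_floor <= 1.0):
            raise ValueError("fst_floor must lie in [0, 1]")


def step1_top_per_chrom_pair(
    landscape: FSTLandscape, cfg: SelectionConfig | None = None
) -> pd.DataFrame:
    """Top-N loci by FST for every (chromosome, pair): a locus multiset.

    Ties are broken by lower position then lexicographic locus id. Chromosomes
    with fewer loci contribute all of them. Returns one row per selection
    event (a locus maximal for several pairs appears once per pair).
    """
    cfg = cfg or SelectionConfig()
    if landscape.data.empty:
        raise ValueError("empty FST landscape")
    df = landscape.data
    # sort: fst desc, then pos asc, then locus id asc; stable head-per-group
    orderd = df.sort_values(
        ["fst", "pos", "locus"], ascending=[False, True, True], kind="mergesort"
    )
    top = (
        orderd.groupby(["chrom", "pair_id"], sort=True)
        .head(cfg.top_n_per_chrom_pair)
        .reset_index(drop=True)
    )
    return top[["locus", "chrom", "pos", "pair_id", "fst"]]


def step2_unique(multiset: pd.DataFrame) -> pd.DataFrame:
    """Reduce the per-pair selection multiset to unique loci."""
    return (
        multiset.drop_duplicates("locus")[["locus", "chrom", "pos"]]
        .reset_index(drop=True)
    )


def step3_fst_floor(
    loci: pd.DataFrame, landscape: FSTLandscape, cfg: SelectionConfig | None = None
) -> pd.DataFrame:
    """Drop loci whose maximum FST across all pairs is below the floor.

    The max over comparisons is what counts: a locus at 0.21 in one pair and
    ~0 elsewhere is retained, because low-FST comparisons should not disqualify
    a locus selected by an informative one.
    """
    cfg = cfg or SelectionConfig()
    scores = landscape.max_fst().set_index("locus")
    missing = set(loci["locus"]) - set(scores.index)
    if missing:
        raise ValueError(f"loci absent from landscape: {sorted(missing)[:5]} ...")
    keep = loci["locus"].map(scores["score"]) >= cfg.fst_floor
    return loci[keep.to_numpy()].reset_index(drop=True)


def step4_window_select(
    loci: pd.DataFrame,
    landscape: FSTLandscape,
    chrom_lengths: dict[str, int] | None = None,
    cfg: SelectionConfig | None = None,
) -> pd.DataFrame:
    """Equal-window, pair-constrained greedy pick of the final candidates.

    Each chromosome is split into ``windows_per_chrom`` equal physical
    intervals [i*L/w, (i+1)*L/w), the last closed at L. Candidates are scored
    by their max pairwise FST and attributed to the argmax pair (ties to the
    lexicographically first pair). Within a chromosome, loci are accepted in
    descending score order (ties by position then id), skipping loci whose
    window is full or, when ``one_pair_per_chrom`` is on, whose attributed
    pair was already consumed on that chromosome.

    Returns PanelCandidate rows: locus, chrom, pos, window, score,
    attributed_pair.
    """
    cfg = cfg or SelectionConfig()
    chrom_lengths = chrom_lengths or landscape.chrom_lengths
    if chrom_lengths is None:
        raise ValueError("chromosome lengths required for windowing")
    scores = landscape.max_fst().set_index("locus")
    cand = loci.merge(
        scores[["score", "attributed_pair"]], left_on="locus", right_index=True
    )
    out_rows = []
    for chrom, grp in cand.groupby("chrom"):
        if chrom not in chrom_lengths:
            raise ValueError(f"no length for chromosome {chrom!r}")
        L = chrom_lengths[chrom]
        w = cfg.windows_per_chrom
        win = np.minimum((grp["pos"].to_numpy() / L * w).astype(int), w - 1)
        grp = grp.assign(window=win)
        grp = grp.sort_values(
            ["score", "pos", "locus"], ascending=[False, True, True], kind="mergesort"
        )
        used_pairs: set[str] = set()
        filled = np.zeros(w, dtype=int)
        for row in grp.itertuples(index=False):
            if filled[row.window] >= cfg.loci_per_window:
                continue
            if cfg.one_pair_per_chrom and row.attributed_pair in used_pairs:
                continue
            filled[row.window] += 1
            used_pairs.add(row.attributed_pair)
            out_rows.append(
                {"locus": row.locus, "chrom": chrom, "pos": row.pos,
                 "window": int(row.window), "score": row.score,
                 "attributed_pair": row.attributed_pair}
            )
    out = pd.DataFrame(
        out_rows,
        columns=["locus", "chrom", "pos", "window", "score", "attributed_pair"],
    )
    return out.sort_values(["chrom", "pos"]).reset_index(drop=True)


def select_panel(
    landscape: FSTLandscape,
    chrom_lengths: dict[str, int] | None = None,
    cfg: SelectionConfig | None = None,
) -> pd.DataFrame:
    """Run selection steps 1-4 on a landscape."""
    cfg = cfg or SelectionConfig()
    s1 = step1_top_per_chrom_pair(landscape, cfg)
    s2 = step2_unique(s1)
    s3 = step3_fst_floor(s2, landscape, cfg)
    return step4_window_select(s3, landscape, chrom_lengths, cfg)


def add_supplemental(candidates: pd.DataFrame, extra_loci: pd.DataFrame) -> pd.DataFrame:
    """Inject explicitly chosen loci (e.g. known outlier regions) into a panel.

    Extras already present are skipped with a warning; the result has
    |candidates| + |new extras| rows.
    """
    extra = extra_loci.copy()
    dup = extra["locus"].isin(set(candidates["locus"]))
    for locus in extra.loc[dup, "locus"]:
        logger.warning("supplemental locus %s already in panel; skipped", locus)
    extra = extra[~dup]
    for col in candidates.columns:
        if col not in extra.columns:
            extra[col] = np.nan
    out = pd.concat([candidates, extra[candidates.columns]], ignore_index=True)
    return out


def attrition_report(stage_counts: list[tuple[str, int]]) -> pd.DataFrame:
    """Bookkeeping of panel attrition across design/optimisation stages.

    Counts must be non-increasing. Per stage: absolute loss and percentage
    loss relative both to the stage's entering count and to the initial panel
    size.
    """
    if len(stage_counts) < 1:
        raise ValueError("need at least one stage")
    names = [s for s, _ in stage_counts]
    counts = [int(c) for _, c in stage_counts]
    if any(b > a for a, b in zip(counts, counts[1:])):
        raise ValueError("stage counts must be non-increasing")
    initial = counts[0]
    rows = [{"stage": names[0], "count": counts[0], "loss": 0,
             "pct_of_entering": 0.0, "pct_of_initial": 0.0}]
    for (prev, cur), name in zip(zip(counts, counts[1:]), names[1:]):
        loss = prev - cur
        rows.append(
            {"stage": name, "count": cur, "loss": loss,
             "pct_of_entering": 100.0 * loss / prev if prev else 0.0,
             "pct_of_initial": 100.0 * loss / initial if initial else 0.0}
        )
    return pd.DataFrame(rows)
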