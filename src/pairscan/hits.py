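"""Hit calling: synergistic-lethal, compensatory, buffering and neutral pairs.

A pair is *synergistic* when its gene-level interaction score falls below the
z cut (default -4). Synergy splits into *lethal* (mean combination LFC below
the screen-average LFC — the dotted line of the screen's LFC/z scatter) and
*compensatory non-lethal* (both single knockouts fitness-positive, the double
knockout back near baseline — the ING1;ING2 / BRD2;BRD3 pattern). Scores
above +|z cut| are *buffering*; everything else is *neutral*.

Per-pair significance uses a two-tailed Mann-Whitney test of the pair's
construct LFCs against the two genes' control pairings; pair-level FDR uses a
one-sided (depletion) normal p-value on z_gene with Benjamini-Hochberg.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import UserInputError
from .library import DEFAULT_CONTROL_CATEGORIES, ConstructCatalog

logger = logging.getLogger("pairscan")

LABELS = (
    "synergistic_lethal",
    "synergistic_nonlethal",
    "compensatory_non_lethal",
    "buffering",
    "neutral",
)


@dataclass(frozen=True)
class HitThresholds:
    z_cut: float = -4.0
    #: None -> use the screen-average gene-pair LFC of the same condition
    lethality_cut: float | None = None
    positivity_cut: float = 0.5


def single_ko_lfc(
    gene: str,
    y: pd.Series,
    catalog: ConstructCatalog,
    control_categories: frozenset[str] = DEFAULT_CONTROL_CATEGORIES,
) -> float:
    """Mean LFC of a gene's guides paired with negative controls (both orientations)."""
    tab = single_ko_table(y, catalog, control_categories)
    if gene not in tab.index:
        logger.warning("single_ko_lfc: gene %r has no control pairings", gene)
        return float("nan")
    return float(tab.loc[gene, "single_ko_lfc"])


def single_ko_table(
    y: pd.Series,
    catalog: ConstructCatalog,
    control_categories: frozenset[str] = DEFAULT_CONTROL_CATEGORIES,
) -> pd.DataFrame:
    """Per-gene mean LFC over all gene-control constructs (index: gene)."""
    cats = set(control_categories)
    c = catalog.constructs.merge(
        y.rename("lfc"), left_on="construct_id", right_index=True, how="inner"
    )
    c = c[c["lfc"].notna()]
    sp_side = c[(c["sp_category"] == "targeting") & (c["sa_category"].isin(cats))]
    sa_side = c[(c["sa_category"] == "targeting") & (c["sp_category"].isin(cats))]
    both = pd.concat([
        sp_side[["sp_gene", "lfc"]].rename(columns={"sp_gene": "gene"}),
        sa_side[["sa_gene", "lfc"]].rename(columns={"sa_gene": "gene"}),
    ])
    if both.empty:
        return pd.DataFrame(columns=["single_ko_lfc", "n_constructs"])
    out = both.groupby("gene")["lfc"].agg(single_ko_lfc="mean", n_constructs="size")
    out["n_constructs"] = out["n_constructs"].astype(int)
    return out


def screen_average_lfc(scores: pd.DataFrame) -> float:
    """Mean of gene-pair mean LFCs over gene_gene pairs (same-gene excluded)."""
    distinct = scores[~scores["flags"].str.contains("same_gene", na=False)]
    if distinct.empty:
        raise UserInputError("no gene_gene pairs to average")
    return float(distinct["mean_observed_lfc"].mean())


def classify_pairs(
    scores: pd.DataFrame,
    single_ko: pd.DataFrame,
    thresholds: HitThresholds = HitThresholds(),
    include_same_gene: bool = False,
) -> pd.DataFrame:
    """Label every scored gene pair; deterministic given scores and thresholds.

    Pairs missing a single-KO estimate get synergy status only (compensation
    test skipped, flagged ``no_single_ko``).
    """
    s = scores.copy()
    if not include_same_gene:
        s = s[~s["flags"].str.contains("same_gene", na=False)].copy()
    lethality_cut = (
        thresholds.lethality_cut
        if thresholds.lethality_cut is not None
        else screen_average_lfc(s)
    )
    ko = single_ko["single_ko_lfc"] if "single_ko_lfc" in single_ko else single_ko
    s["single_ko_lfc_I"] = s["gene_I"].map(ko)
    s["single_ko_lfc_J"] = s["gene_J"].map(ko)

    labels = []
    flags = []
    for row in s.itertuples():
        flag = row.flags
        if row.z_gene < thresholds.z_cut:
            if row.mean_observed_lfc < lethality_cut:
                labels.append("synergistic_lethal")
            else:
                singles = (row.single_ko_lfc_I, row.single_ko_lfc_J)
                if any(np.isnan(v) for v in singles):
                    labels.append("synergistic_nonlethal")
                    flag = (flag + ";" if flag else "") + "no_single_ko"
                elif all(v > thresholds.positivity_cut for v in singles):
                    labels.append("compensatory_non_lethal")
                else:
                    labels.append("synergistic_nonlethal")
        elif row.z_gene > abs(thresholds.z_cut):
            labels.append("buffering")
        else:
            labels.append("neutral")
        flags.append(flag)
    s["label"] = labels
    s["flags"] = flags
    s["z_cut"] = thresholds.z_cut
    s["lethality_cut"] = lethality_cut
    s["positivity_cut"] = thresholds.positivity_cut
    return s.reset_index(drop=True)


def compute_fdr(scores: pd.DataFrame) -> pd.DataFrame:
    """One-sided depletion p from z_gene plus Benjamini-Hochberg q per condition."""
    s = scores.copy()
    s["p_value"] = stats.norm.cdf(s["z_gene"])
    if "condition" in s.columns:
        groups = [g.index for _, g in s.groupby("condition")]
    else:
        groups = [s.index]
    # BH is applied over distinct-gene pairs only; same-gene rows keep NaN q
    distinct = ~s["flags"].str.contains("same_gene", na=False)
    q = pd.Series(np.nan, index=s.index)
    for idx in groups:
        p = s.loc[idx, "p_value"]
        ok = p.notna() & distinct.loc[idx]
        if ok.any():
            q.loc[idx[ok]] = multipletests(p[ok], method="fdr_bh")[1]
    s["fdr_q"] = q
    return s


def mann_whitney_pair_test(pair_lfcs, control_lfcs) -> float:
    """Two-tailed Mann-Whitney U p-value: pair constructs vs control pairings.

    Exact when both groups have <= 8 observations and no cross-group ties;
    otherwise the tie-corrected normal approximation (no continuity
    correction, so identical groups give p = 1).
    """
    a = np.asarray(pair_lfcs, dtype=float)
    b = np.asarray(control_lfcs, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise UserInputError("mann_whitney_pair_test: empty group")
    no_ties = len(np.unique(np.concatenate([a, b]))) == len(a) + len(b)
    method = "exact" if (len(a) <= 8 and len(b) <= 8 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=False)
    return float(min(res.pvalue, 1.0))


def pair_lfc_groups(
    gene_i: str,
    gene_j: str,
    y: pd.Series,
    catalog: ConstructCatalog,
    control_categories: frozenset[str] = DEFAULT_CONTROL_CATEGORIES,
) -> tuple[np.ndarray, np.ndarray]:
    """Construct LFCs of a gene pair and of the two genes' control pairings."""
    cats = set(control_categories)
    pair = ";".join(sorted((gene_i, gene_j)))
    c = catalog.constructs.merge(
        y.rename("lfc"), left_on="construct_id", right_index=True, how="inner"
    )
    c = c[c["lfc"].notna()]
    pair_vals = c.loc[c["gene_pair"] == pair, "lfc"].to_numpy()
    is_ctrl_sp = (c["sa_category"].isin(cats) & c["sp_gene"].isin([gene_i, gene_j])
                  & (c["sp_category"] == "targeting"))
    is_ctrl_sa = (c["sp_category"].isin(cats) & c["sa_gene"].isin([gene_i, gene_j])
                  & (c["sa_category"] == "targeting"))
    ctrl_vals = c.loc[is_ctrl_sp | is_ctrl_sa, "lfc"].to_numpy()
    return pair_vals, ctrl_vals


def rank_top_hits(hitcalls: pd.DataFrame, k: int) -> pd.DataFrame:
    """Top-k synergistic-lethal pairs: ascending z_gene, then LFC, then name."""
    if k < 1:
        raise UserInputError(f"k must be >= 1, got {k}")
    hits = hitcalls[hitcalls["label"] == "synergistic_lethal"]
    hits = hits.sort_values(
        ["z_gene", "mean_observed_lfc", "gene_I", "gene_J"],
        ascending=[True, True, True, True],
        kind="mergesort",
    )
    if len(hits) < k:
        logger.info("rank_top_hits: only %d of requested %d hits", len(hits), k)
    return hits.head(k).reset_index(drop=True)
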