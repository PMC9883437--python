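"""Anchor-regression genetic-interaction scoring.

For every guide *i* (the *anchor*), the observed LFCs of its combinations
``y_ij`` are regressed against the partner guides' single-knockout proxies
``x_j`` (*base LFCs*: each guide's mean LFC when paired with opposite-ortholog
negative controls):

    y_hat_ij = m_i * x_j + b_i          (ordinary least squares per anchor)

The regression line is the no-interaction expectation; residuals
``y_ij - y_hat_ij`` are z-scored within each anchor. Gene-pair scores sum the
residual z's over all constructs targeting the pair, once with each gene's
guides as the anchor:

    S_I = sum_ij z_ij / sqrt(n),   S_J likewise,   z_gene = (S_I + S_J) / sqrt(2)

where n is the number of constructs targeting the pair across both Cas9
arrangements. z_gene is symmetric in the gene labels by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateFitError, UserInputError
from .library import DEFAULT_CONTROL_CATEGORIES, ConstructCatalog, CountMatrix, GuideLibrary
from .lfc import LfcTable, average_replicates, compute_lfc, counts_to_log2rpm

logger = logging.getLogger("pairscan")


@dataclass(frozen=True)
class ScoringConfig:
    """Knobs of the interaction-scoring pipeline (defaults are the shipped analysis)."""

    pseudocount: float = 1.0
    control_categories: frozenset[str] = DEFAULT_CONTROL_CATEGORIES
    #: anchors with fewer regression points are dropped, not fit
    min_anchor_partners: int = 10
    #: below this residual sd the anchor's z's are set to 0 and flagged
    sd_tolerance: float = 1e-8
    #: 1 = sample standard deviation (n-1) for the within-anchor z-score
    z_ddof: int = 1
    combine_replicates: bool = True


@dataclass
class BaseLfcTable:
    """Per-guide single-knockout proxy: mean LFC with negative-control partners."""

    base: pd.DataFrame  # index guide_id; columns base_lfc, n_control_partners

    def lookup(self) -> pd.Series:
        return self.base["base_lfc"]


@dataclass
class AnchorFit:
    anchor_guide_id: str
    slope: float
    intercept: float
    n_points: int
    residual_mean: float
    residual_sd: float
    degenerate_sd: bool = False


def compute_base_lfc(
    y: pd.Series,
    catalog: ConstructCatalog,
    library: GuideLibrary,
    control_categories: frozenset[str] = DEFAULT_CONTROL_CATEGORIES,
) -> BaseLfcTable:
    """Mean LFC of each guide over its pairings with opposite-ortholog controls.

    ``y`` is one condition's construct LFC series (index construct_id). Guides
    with no scored control pairing are omitted (logged).
    """
    cats = set(control_categories)
    lib_cats = set(library.guides["category"])
    if not (cats & lib_cats):
        raise UserInputError(
            f"library contains no guides in control categories {sorted(cats)}"
        )
    c = catalog.constructs
    obs = c.merge(y.rename("lfc"), left_on="construct_id", right_index=True, how="inner")
    parts = []
    for anchor_col, partner_cat in (("sp_guide_id", "sa_category"), ("sa_guide_id", "sp_category")):
        sub = obs[obs[partner_cat].isin(cats) & obs["lfc"].notna()]
        if len(sub):
            g = sub.groupby(anchor_col)["lfc"].agg(["mean", "size"])
            parts.append(g)
    if not parts:
        raise UserInputError("no control-paired constructs with observed LFCs")
    base = pd.concat(parts)
    base.columns = ["base_lfc", "n_control_partners"]
    base["n_control_partners"] = base["n_control_partners"].astype(int)
    base.index.name = "guide_id"
    n_all = library.guides["guide_id"].nunique()
    if len(base) < n_all:
        logger.warning("compute_base_lfc: %d guide(s) lack control pairings, omitted",
                       n_all - len(base))
    return BaseLfcTable(base)


def fit_anchor_model(
    anchor_guide_id: str,
    x: np.ndarray,
    y: np.ndarray,
    min_points: int = 10,
    sd_tolerance: float = 1e-8,
) -> tuple[AnchorFit, np.ndarray]:
    """OLS fit of one anchor's combination LFCs against partner base LFCs.

    Returns the fit parameters and the residual vector ``y - (m x + b)``.
    Raises :class:`DegenerateFitError` for a zero-variance regressor or too
    few points.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < max(min_points, 2):
        raise DegenerateFitError(
            f"anchor {anchor_guide_id!r}: {len(x)} partners < min_points {min_points}"
        )
    if np.ptp(x) == 0:
        raise DegenerateFitError(f"anchor {anchor_guide_id!r}: zero-variance regressor")
    res = stats.linregress(x, y)
    residuals = y - (res.slope * x + res.intercept)
    sd = float(np.std(residuals, ddof=1)) if len(residuals) > 1 else 0.0
    fit = AnchorFit(
        anchor_guide_id=anchor_guide_id,
        slope=float(res.slope),
        intercept=float(res.intercept),
        n_points=len(x),
        residual_mean=float(residuals.mean()),
        residual_sd=sd,
        degenerate_sd=sd < sd_tolerance,
    )
    return fit, residuals


def zscore_residuals(
    fit: AnchorFit,
    residuals: np.ndarray,
    sd_tolerance: float = 1e-8,
    ddof: int = 1,
) -> tuple[np.ndarray, bool]:
    """Standardise one anchor's residuals (sample sd by default).

    Returns ``(z, degenerate)``; a near-zero residual sd yields all-zero z's
    with ``degenerate=True`` rather than dividing by ~0.
    """
    r = np.asarray(residuals, dtype=float)
    if len(r) < 2:
        raise DegenerateFitError(
            f"anchor {fit.anchor_guide_id!r}: cannot z-score {len(r)} residual(s)"
        )
    sd = float(np.std(r, ddof=ddof))
    if sd < sd_tolerance:
        return np.zeros_like(r), True
    return (r - r.mean()) / sd, False


def _anchor_long_table(
    y: pd.Series,
    catalog: ConstructCatalog,
    base: BaseLfcTable,
) -> pd.DataFrame:
    """Long table: one row per (anchor guide, targeting partner) observation."""
    c = catalog.constructs
    obs = c.merge(y.rename("y"), left_on="construct_id", right_index=True, how="inner")
    obs = obs[obs["y"].notna()]
    blk = []
    sides = (
        ("sp_guide_id", "sp_gene", "sa_guide_id", "sa_gene", "sa_category"),
        ("sa_guide_id", "sa_gene", "sp_guide_id", "sp_gene", "sp_category"),
    )
    for a_id, a_gene, p_id, p_gene, p_cat in sides:
        sub = obs[obs[p_cat] == "targeting"]
        blk.append(pd.DataFrame({
            "construct_id": sub["construct_id"],
            "anchor_guide_id": sub[a_id],
            "partner_guide_id": sub[p_id],
            "anchor_gene": sub[a_gene],
            "partner_gene": sub[p_gene],
            "gene_pair": sub["gene_pair"],
            "pair_class": sub["pair_class"],
            "y": sub["y"],
        }))
    long = pd.concat(blk, ignore_index=True)
    long["x"] = long["partner_guide_id"].map(base.lookup())
    dropped = long["x"].isna()
    if dropped.any():
        logger.info("scoring: %d observation(s) dropped (partner lacks base LFC)",
                    int(dropped.sum()))
    return long[~dropped].reset_index(drop=True)


def score_anchors(
    y: pd.Series,
    catalog: ConstructCatalog,
    base: BaseLfcTable,
    config: ScoringConfig = ScoringConfig(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fit every anchor, z-score residuals; return (fits table, residual z table).

    Anchors with too few partners or a degenerate regressor are excluded and
    listed in the fits table with ``excluded_reason`` set.
    """
    long = _anchor_long_table(y, catalog, base)
    fits: list[dict] = []
    chunks: list[pd.DataFrame] = []
    for anchor, grp in long.groupby("anchor_guide_id", sort=True):
        try:
            fit, resid = fit_anchor_model(
                anchor, grp["x"].to_numpy(), grp["y"].to_numpy(),
                min_points=config.min_anchor_partners,
                sd_tolerance=config.sd_tolerance,
            )
        except DegenerateFitError as e:
            logger.info("scoring: anchor excluded — %s", e)
            fits.append({"anchor_guide_id": anchor, "n_points": len(grp),
                         "excluded_reason": str(e)})
            continue
        z, degen = zscore_residuals(fit, resid, config.sd_tolerance, config.z_ddof)
        fits.append({
            "anchor_guide_id": anchor, "slope": fit.slope, "intercept": fit.intercept,
            "n_points": fit.n_points, "residual_mean": fit.residual_mean,
            "residual_sd": fit.residual_sd,
            "degenerate_sd": degen, "excluded_reason": "",
        })
        out = grp.copy()
        out["expected"] = fit.slope * out["x"] + fit.intercept
        out["residual"] = resid
        out["z"] = z
        chunks.append(out)
    fits_df = pd.DataFrame(fits)
    z_table = (pd.concat(chunks, ignore_index=True) if chunks
               else long.iloc[0:0].assign(expected=[], residual=[], z=[]))
    return fits_df, z_table


def score_gene_pairs(
    z_table: pd.DataFrame,
    catalog: ConstructCatalog,
    y: pd.Series | None = None,
) -> pd.DataFrame:
    """Aggregate residual z's to gene-pair scores over both anchor orientations.

    ``n_constructs`` counts the distinct constructs contributing z's (both
    Cas9 arrangements). Pairs observed from a single orientation keep that
    orientation's S as z_gene and are flagged ``asymmetric``; same-gene pairs
    are scored for QC but flagged ``same_gene``.
    """
    empty_cols = [
        "gene_I", "gene_J", "gene_pair", "n_constructs",
        "S_I", "S_J", "z_gene", "mean_observed_lfc", "flags",
    ]
    rows = z_table[z_table["gene_pair"] != ""]
    if rows.empty:
        return pd.DataFrame(columns=empty_cols)

    n = rows.groupby("gene_pair")["construct_id"].nunique()
    out = pd.DataFrame(index=n.index)
    out["n_constructs"] = n.astype(int)
    split = out.index.to_series().str.split(";", n=1, expand=True)
    out["gene_I"], out["gene_J"] = split[0], split[1]

    sums = rows.groupby(["gene_pair", "anchor_gene"])["z"].sum().reset_index()
    gi = out["gene_I"].reindex(sums["gene_pair"]).to_numpy()
    gj = out["gene_J"].reindex(sums["gene_pair"]).to_numpy()
    sum_i = sums[sums["anchor_gene"].to_numpy() == gi].set_index("gene_pair")["z"]
    sum_j = sums[(sums["anchor_gene"].to_numpy() == gj) & (gi != gj)].set_index("gene_pair")["z"]
    sqrt_n = np.sqrt(out["n_constructs"].astype(float))
    out["S_I"] = sum_i.reindex(out.index) / sqrt_n
    out["S_J"] = sum_j.reindex(out.index) / sqrt_n

    same = out["gene_I"] == out["gene_J"]
    asym = ~same & (out["S_I"].isna() | out["S_J"].isna())
    out["z_gene"] = (out["S_I"] + out["S_J"]) / np.sqrt(2)
    # same-gene "pairs": both anchor views share the gene; scored for QC only
    s_same = sum_i.reindex(out.index) / np.sqrt(2 * out["n_constructs"].astype(float))
    out.loc[same, "z_gene"] = s_same[same]
    out.loc[same, "S_I"] = s_same[same]
    out.loc[same, "S_J"] = s_same[same]
    out.loc[asym, "z_gene"] = out.loc[asym, ["S_I", "S_J"]].sum(axis=1, skipna=True)
    out["flags"] = ""
    out.loc[same, "flags"] = "same_gene"
    out.loc[asym, "flags"] = "asymmetric"

    if y is not None:
        cat = catalog.constructs
        obs = cat.loc[cat["gene_pair"].isin(out.index), ["gene_pair", "construct_id"]]
        obs = obs.merge(y.rename("y"), left_on="construct_id", right_index=True,
                        how="left")
        out["mean_observed_lfc"] = obs.groupby("gene_pair")["y"].mean()
    else:
        out["mean_observed_lfc"] = (
            rows.drop_duplicates("construct_id").groupby("gene_pair")["y"].mean()
        )
    out = out.rename_axis("gene_pair").reset_index()
    return out[empty_cols]


def score_lfc(
    y: pd.Series,
    catalog: ConstructCatalog,
    library: GuideLibrary,
    config: ScoringConfig = ScoringConfig(),
) -> pd.DataFrame:
    """Score a single condition's construct LFC series to gene-pair scores."""
    base = compute_base_lfc(y, catalog, library, config.control_categories)
    _, z_table = score_anchors(y, catalog, base, config)
    return score_gene_pairs(z_table, catalog, y)


@dataclass
class ScreenScores:
    """Bundle of every scoring stage's output, one entry per condition."""

    lfc: LfcTable
    base: dict[str, BaseLfcTable]
    anchor_fits: dict[str, pd.DataFrame]
    z_tables: dict[str, pd.DataFrame]
    gene_scores: pd.DataFrame  # concatenated, with a `condition` column
    config: ScoringConfig = field(default_factory=ScoringConfig)


def score_screen(
    counts: CountMatrix,
    library: GuideLibrary,
    catalog: ConstructCatalog | None = None,
    config: ScoringConfig = ScoringConfig(),
) -> ScreenScores:
    """End-to-end: counts -> log2 RPM -> LFC -> base LFC -> anchor z -> gene scores."""
    from .library import build_all_by_all_catalog

    if catalog is None:
        catalog = build_all_by_all_catalog(library)
    log2rpm = counts_to_log2rpm(counts, config.pseudocount)
    lfc = compute_lfc(log2rpm, counts.samples, config.pseudocount)
    if config.combine_replicates:
        lfc = average_replicates(lfc)
    base: dict[str, BaseLfcTable] = {}
    fits: dict[str, pd.DataFrame] = {}
    ztabs: dict[str, pd.DataFrame] = {}
    scores = []
    for cond in lfc.values.columns:
        y = lfc.values[cond]
        b = compute_base_lfc(y, catalog, library, config.control_categories)
        f, zt = score_anchors(y, catalog, b, config)
        gs = score_gene_pairs(zt, catalog, y)
        gs.insert(0, "condition", cond)
        base[cond], fits[cond], ztabs[cond] = b, f, zt
        scores.append(gs)
    gene_scores = pd.concat(scores, ignore_index=True) if scores else pd.DataFrame()
    return ScreenScores(lfc=lfc, base=base, anchor_fits=fits, z_tables=ztabs,
                        gene_scores=gene_scores, config=config)
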