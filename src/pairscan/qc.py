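"""Screen quality control: replicate concordance, ortholog agreement, controls.

Well-behaved pooled screens show high Pearson correlation between replicate
LFCs, agreement between the two Cas9 orthologs' single-knockout estimates for
the same genes, and clear dropout of essential-gene controls relative to
non-targeting controls.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import UserInputError
from .library import ConstructCatalog, GuideLibrary
from .lfc import LfcTable
from .scoring import BaseLfcTable

logger = logging.getLogger("pairscan")


@dataclass
class QcReport:
    """JSON-serialisable QC summary of one screen."""

    replicate_correlations: list[dict] = field(default_factory=list)
    ortholog_concordance: dict[str, float | None] = field(default_factory=dict)
    control_summary: dict[str, dict] = field(default_factory=dict)
    excluded_anchors: dict[str, int] = field(default_factory=dict)
    excluded_constructs: dict[str, int] = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "QcReport":
        if hasattr(source, "read"):
            data = json.load(source)
        else:
            try:
                data = json.loads(source)
            except (json.JSONDecodeError, TypeError):
                with open(source) as fh:
                    data = json.load(fh)
        return cls(**data)

    def to_text(self) -> str:
        lines = ["pairscan QC report", "==================", ""]
        for rec in self.replicate_correlations:
            lines.append(
                f"replicate r  {rec['condition']}: rep{rec['replicate_a']} vs "
                f"rep{rec['replicate_b']}  r = {rec['r']:.4f}  (n = {rec['n']})"
            )
        for cond, r in self.ortholog_concordance.items():
            shown = "undefined" if r is None else f"{r:.4f}"
            lines.append(f"ortholog r   {cond}: {shown}")
        for cond, summ in self.control_summary.items():
            lines.append(f"controls     {cond}: " + ", ".join(
                f"{k} = {summ[k]:.3f}" if isinstance(summ[k], float) else f"{k} = {summ[k]}"
                for k in sorted(summ)))
        for cond, n in self.excluded_anchors.items():
            lines.append(f"excluded anchors    {cond}: {n}")
        for cond, n in self.excluded_constructs.items():
            lines.append(f"excluded constructs {cond}: {n}")
        return "\n".join(lines) + "\n"


def replicate_correlation(lfc: LfcTable) -> pd.DataFrame:
    """Pearson r between each pair of replicate LFC columns within a condition."""
    if lfc.replicate_counts:
        raise UserInputError("replicate_correlation needs per-replicate LFCs")
    meta = lfc.samples.set_index("sample_id")
    recs = []
    for cond, grp in meta.groupby("condition", sort=False):
        cols = list(grp.index)
        for a, b in combinations(cols, 2):
            sub = lfc.values[[a, b]].dropna()
            if len(sub) < 3:
                logger.warning("replicate_correlation: <3 shared constructs for %s", cond)
                r = np.nan
            else:
                r = float(stats.pearsonr(sub[a], sub[b]).statistic)
            recs.append({
                "condition": cond,
                "replicate_a": int(meta.loc[a, "replicate"]),
                "replicate_b": int(meta.loc[b, "replicate"]),
                "r": r,
                "n": int(len(sub)),
            })
    return pd.DataFrame(recs)


def ortholog_concordance(base: BaseLfcTable, library: GuideLibrary) -> float | None:
    """Pearson r between per-gene mean base LFCs of SpCas9 vs SaCas9 guides.

    Returns None (flagged) when fewer than 3 genes are covered by both
    orthologs.
    """
    g = library.guides[library.guides["category"] == "targeting"]
    tab = g.merge(base.base, left_on="guide_id", right_index=True, how="inner")
    means = tab.pivot_table(index="target_gene", columns="ortholog",
                            values="base_lfc", aggfunc="mean")
    if not {"SpCas9", "SaCas9"} <= set(means.columns):
        logger.warning("ortholog_concordance: one ortholog has no scored guides")
        return None
    means = means.dropna()
    if len(means) < 3:
        logger.warning("ortholog_concordance: only %d gene(s) shared", len(means))
        return None
    return float(stats.pearsonr(means["SpCas9"], means["SaCas9"]).statistic)


def control_separation(
    guide_lfcs_by_category: dict[str, np.ndarray],
) -> dict[str, float]:
    """Medians per control category plus a MAD-standardised NT-vs-essential gap.

    separation = (median_NT - median_essential) / pooled MAD; larger values
    mean cleaner essential dropout.
    """
    nt = np.asarray(guide_lfcs_by_category.get("non_targeting", []), dtype=float)
    ess = np.asarray(guide_lfcs_by_category.get("essential_control", []), dtype=float)
    if len(nt) == 0 or len(ess) == 0:
        raise UserInputError("control_separation needs both NT and essential values")
    out = {
        f"median_{cat}": float(np.median(np.asarray(v, dtype=float)))
        for cat, v in guide_lfcs_by_category.items()
        if len(v)
    }
    centered = np.concatenate([np.abs(nt - np.median(nt)), np.abs(ess - np.median(ess))])
    mad = float(np.median(centered))
    diff = float(np.median(nt) - np.median(ess))
    if mad == 0:
        sep = 0.0 if diff == 0 else float(np.inf) * np.sign(diff)
    else:
        sep = diff / mad
    out["separation"] = float(sep)
    return out


def guide_base_lfcs_by_category(
    base: BaseLfcTable, library: GuideLibrary
) -> dict[str, np.ndarray]:
    """Base LFC vectors grouped by guide category (input to control_separation)."""
    tab = library.guides.merge(base.base, left_on="guide_id", right_index=True,
                               how="inner")
    return {
        cat: grp["base_lfc"].to_numpy()
        for cat, grp in tab.groupby("category", sort=False)
    }


def qc_report(
    per_replicate_lfc: LfcTable,
    base_by_condition: dict[str, BaseLfcTable],
    library: GuideLibrary,
    catalog: ConstructCatalog,
    anchor_fits: dict[str, pd.DataFrame] | None = None,
) -> QcReport:
    """Assemble the full QC report for a screen."""
    rep = replicate_correlation(per_replicate_lfc)
    report = QcReport(replicate_correlations=rep.to_dict(orient="records"))
    for cond, base in base_by_condition.items():
        report.ortholog_concordance[cond] = ortholog_concordance(base, library)
        groups = guide_base_lfcs_by_category(base, library)
        if "non_targeting" in groups and "essential_control" in groups:
            report.control_summary[cond] = control_separation(groups)
        else:
            report.control_summary[cond] = {
                f"median_{cat}": float(np.median(v)) for cat, v in groups.items()
            }
    if anchor_fits:
        for cond, fits in anchor_fits.items():
            if "excluded_reason" in fits.columns:
                n_exc = int((fits["excluded_reason"] != "").sum())
            else:
                n_exc = 0
            report.excluded_anchors[cond] = n_exc
    n_total = len(catalog)
    n_seen = per_replicate_lfc.values.shape[0]
    report.excluded_constructs["all"] = int(n_total - n_seen)
    return report
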