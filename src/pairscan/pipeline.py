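"""End-to-end orchestration: files in, artifact bundle out.

``run_pipeline`` ties the stages together (counts -> LFC -> interaction
scores -> hit calls -> QC) and writes every stage's table plus a manifest
recording the configuration, input checksums and package version. Outputs are
written to ``<name>.partial`` as each stage completes and renamed on success,
so a failed run leaves its partial artifacts inspectable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError, PairscanError, UserInputError
from .hits import HitThresholds, classify_pairs, compute_fdr, rank_top_hits, single_ko_table
from .lfc import average_replicates, compute_lfc, counts_to_log2rpm
from .library import (
    DEFAULT_CONTROL_CATEGORIES,
    GuideLibrary,
    build_all_by_all_catalog,
    read_counts,
    read_sample_sheet,
)
from .qc import qc_report
from .scoring import ScoringConfig, score_anchors, score_gene_pairs, compute_base_lfc

logger = logging.getLogger("pairscan")


@dataclass(frozen=True)
class RunConfig:
    """Full configuration of one analysis run (rejects unknown keys)."""

    library: str
    counts: str
    sample_sheet: str
    output_dir: str = "pairscan_out"
    pseudocount: float = 1.0
    control_categories: tuple[str, ...] = tuple(sorted(DEFAULT_CONTROL_CATEGORIES))
    min_anchor_partners: int = 10
    z_cut: float = -4.0
    lethality_cut: float | None = None  # None -> screen-average LFC
    positivity_cut: float = 0.5
    fdr_method: str = "normal_one_sided_bh"
    combine_replicates: bool = True
    top_k: int = 5
    verbosity: str = "info"

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        if "control_categories" in data:
            data = {**data, "control_categories": tuple(data["control_categories"])}
        try:
            return cls(**data)
        except TypeError as e:
            raise ConfigError(str(e)) from e

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["control_categories"] = list(d["control_categories"])
        return d

    def scoring(self) -> ScoringConfig:
        return ScoringConfig(
            pseudocount=self.pseudocount,
            control_categories=frozenset(self.control_categories),
            min_anchor_partners=self.min_anchor_partners,
            combine_replicates=self.combine_replicates,
        )

    def thresholds(self) -> HitThresholds:
        return HitThresholds(
            z_cut=self.z_cut,
            lethality_cut=self.lethality_cut,
            positivity_cut=self.positivity_cut,
        )


@dataclass
class Bundle:
    """In-memory results of a pipeline run plus the paths of their artifacts."""

    config: RunConfig
    lfc: pd.DataFrame
    gene_scores: pd.DataFrame
    hit_calls: pd.DataFrame
    qc: "object"
    manifest: dict
    paths: dict[str, str] = field(default_factory=dict)


class PipelineStageError(PairscanError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> Bundle:
    """Execute every stage and write the artifact bundle under output_dir."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    partial: list[tuple[Path, Path]] = []

    def write_tsv(df: pd.DataFrame, name: str, index: bool = False) -> None:
        tmp = out / (name + ".partial")
        df.to_csv(tmp, sep="\t", index=index, float_format="%.6g")
        partial.append((tmp, out / name))

    def write_text(text: str, name: str) -> None:
        tmp = out / (name + ".partial")
        tmp.write_text(text)
        partial.append((tmp, out / name))

    stage = "read_inputs"
    try:
        for p in (config.library, config.counts, config.sample_sheet):
            if not os.path.exists(p):
                raise UserInputError(f"input file not found: {p}")
        library = GuideLibrary.from_tsv(config.library)
        catalog = build_all_by_all_catalog(library)
        sheet = read_sample_sheet(config.sample_sheet)
        counts = read_counts(config.counts, catalog, sheet)

        stage = "lfc"
        log2rpm = counts_to_log2rpm(counts, config.pseudocount)
        lfc_reps = compute_lfc(log2rpm, counts.samples, config.pseudocount)
        lfc = average_replicates(lfc_reps) if config.combine_replicates else lfc_reps
        lfc_out = lfc.values.copy()
        write_tsv(lfc_out.rename_axis("construct_id"), "lfc.tsv", index=True)

        stage = "score"
        scfg = config.scoring()
        base_by_cond, fits_by_cond, scores_parts = {}, {}, []
        singles_parts = []
        for cond in lfc.values.columns:
            y = lfc.values[cond]
            b = compute_base_lfc(y, catalog, library, scfg.control_categories)
            fits, ztab = score_anchors(y, catalog, b, scfg)
            gs = score_gene_pairs(ztab, catalog, y)
            gs.insert(0, "condition", cond)
            base_by_cond[cond], fits_by_cond[cond] = b, fits
            scores_parts.append(gs)
            st = single_ko_table(y, catalog, scfg.control_categories)
            st.insert(0, "condition", cond)
            singles_parts.append(st)
            write_tsv(b.base.reset_index(), f"base_lfc_{cond}.tsv")
        gene_scores = compute_fdr(pd.concat(scores_parts, ignore_index=True))
        singles = pd.concat(singles_parts)
        write_tsv(gene_scores, "gene_scores.tsv")
        write_tsv(singles.rename_axis("gene").reset_index(), "single_ko_lfc.tsv")

        stage = "call"
        calls = []
        for cond, grp in gene_scores.groupby("condition"):
            ko = singles[singles["condition"] == cond]
            calls.append(classify_pairs(grp, ko, config.thresholds()))
        hit_calls = pd.concat(calls, ignore_index=True)
        write_tsv(hit_calls, "hit_calls.tsv")

        stage = "qc"
        report = qc_report(lfc_reps, base_by_cond, library, catalog, fits_by_cond)
        write_text(report.to_json(), "qc_report.json")
        write_text(report.to_text(), "qc_report.txt")

        stage = "manifest"
        manifest = {
            "pairscan_version": __version__,
            "config": config.to_dict(),
            "inputs": {
                "library": _sha256(config.library),
                "counts": _sha256(config.counts),
                "sample_sheet": _sha256(config.sample_sheet),
            },
            "fdr_method": config.fdr_method,
            "summary": {
                "n_guides": int(len(library.guides)),
                "n_constructs_by_class": {
                    k: int(v) for k, v in catalog.class_counts().items()
                },
                "screen_average_lfc": {
                    cond: float(grp["mean_observed_lfc"].mean())
                    for cond, grp in gene_scores[
                        ~gene_scores["flags"].str.contains("same_gene", na=False)
                    ].groupby("condition")
                },
                "hit_counts_by_label": {
                    k: int(v)
                    for k, v in hit_calls["label"].value_counts().items()
                },
            },
        }
        write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n", "manifest.json")

        bundle = Bundle(
            config=config, lfc=lfc_out, gene_scores=gene_scores,
            hit_calls=hit_calls, qc=report, manifest=manifest,
        )
        stage = "report"
        write_text(write_report(bundle), "report.md")
    except Exception as e:  # retain .partial artifacts written so far
        raise PipelineStageError(stage, e) from e

    for tmp, final in partial:
        os.replace(tmp, final)
        bundle.paths[final.name] = str(final)
    return bundle


def write_report(bundle: Bundle) -> str:
    """Human-readable markdown summary of a run (idempotent)."""
    m = bundle.manifest
    lines = [
        "# pairscan run report",
        "",
        f"pairscan version: {m['pairscan_version']}",
        f"guides: {m['summary']['n_guides']}",
        "",
        "## Constructs by pair class",
        "",
    ]
    for k in sorted(m["summary"]["n_constructs_by_class"]):
        lines.append(f"- {k}: {m['summary']['n_constructs_by_class'][k]}")
    lines += ["", "## Screen-average gene-pair LFC", ""]
    for cond in sorted(m["summary"]["screen_average_lfc"]):
        lines.append(f"- {cond}: {m['summary']['screen_average_lfc'][cond]:.4f}")
    lines += ["", "## Hit counts by label", ""]
    counts = bundle.hit_calls["label"].value_counts()
    for label in ("synergistic_lethal", "synergistic_nonlethal",
                  "compensatory_non_lethal", "buffering", "neutral"):
        lines.append(f"- {label}: {int(counts.get(label, 0))}")
    lines += ["", f"## Top {bundle.config.top_k} synergistic-lethal pairs", ""]
    top = rank_top_hits(bundle.hit_calls, bundle.config.top_k)
    if top.empty:
        lines.append("(none)")
    else:
        lines.append("| condition | gene_I | gene_J | z_gene | mean LFC | q |")
        lines.append("|---|---|---|---|---|---|")
        for r in top.itertuples():
            lines.append(
                f"| {r.condition} | {r.gene_I} | {r.gene_J} | {r.z_gene:.3f} "
                f"| {r.mean_observed_lfc:.3f} | {r.fdr_q:.3g} |"
            )
    lines += ["", "## QC", "", "```", bundle.qc.to_text().rstrip(), "```", ""]
    return "\n".join(lines)
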