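"""Dual-ortholog guide libraries, construct catalogs and count matrices.

A pooled dual-knockout screen delivers one *S. pyogenes* and one *S. aureus*
guide per lentiviral construct, so a library of ``n_sp`` SpCas9 guides and
``n_sa`` SaCas9 guides yields an all-by-all catalog of ``n_sp * n_sa``
constructs. Each construct is classified by what its two guides target:

``gene_gene``
    both guides target (distinct) genes — the pairs that get interaction scores;
``same_gene``
    both guides target the same gene (a within-gene double cut);
``gene_control``
    one targeting guide paired with a control — the single-knockout proxy;
``control_control``
    two control guides — the null fitness reference.

All on-disk formats are tab-separated UTF-8 with a header row.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import MalformedLibraryError, ParseError

logger = logging.getLogger("pairscan")

ORTHOLOGS = ("SpCas9", "SaCas9")
CATEGORIES = ("targeting", "non_targeting", "essential_control", "safe_harbor")
PAIR_CLASSES = ("gene_gene", "same_gene", "gene_control", "control_control")

#: categories usable as negative controls for base-LFC estimation. Safe-harbor
#: guides cut the genome (unlike non-targeting) and are excluded by default.
DEFAULT_CONTROL_CATEGORIES = frozenset({"non_targeting"})

LIBRARY_COLUMNS = ["guide_id", "ortholog", "category", "target_gene", "note"]
SAMPLE_COLUMNS = ["sample_id", "condition", "replicate", "timepoint_days", "is_reference"]


@dataclass
class GuideLibrary:
    """A validated table of guides with ortholog, category and target gene.

    ``guides`` has columns guide_id / ortholog / category / target_gene / note;
    target_gene is "" for guides without a gene (non-targeting controls).
    """

    guides: pd.DataFrame

    def __post_init__(self) -> None:
        g = self.guides.copy()
        for col in ("target_gene", "note"):
            if col not in g.columns:
                g[col] = ""
        g = g[LIBRARY_COLUMNS].fillna({"target_gene": "", "note": ""})
        g["target_gene"] = g["target_gene"].astype(str).replace("nan", "")
        g["note"] = g["note"].astype(str).replace("nan", "")

        dup = g["guide_id"][g["guide_id"].duplicated()]
        if len(dup):
            raise MalformedLibraryError(f"duplicate guide_id: {dup.iloc[0]!r}")
        bad_orth = set(g["ortholog"]) - set(ORTHOLOGS)
        if bad_orth:
            raise ParseError(f"unknown ortholog token(s): {sorted(bad_orth)}")
        bad_cat = set(g["category"]) - set(CATEGORIES)
        if bad_cat:
            raise ParseError(f"unknown category token(s): {sorted(bad_cat)}")
        missing_gene = g[(g["category"] == "targeting") & (g["target_gene"] == "")]
        if len(missing_gene):
            raise MalformedLibraryError(
                f"targeting guide without target_gene: {missing_gene['guide_id'].iloc[0]!r}"
            )
        has_gene_nt = g[(g["category"] == "non_targeting") & (g["target_gene"] != "")]
        if len(has_gene_nt):
            raise MalformedLibraryError(
                f"non_targeting guide with a target_gene: {has_gene_nt['guide_id'].iloc[0]!r}"
            )
        for orth in ORTHOLOGS:
            if not (g["ortholog"] == orth).any():
                raise MalformedLibraryError(f"library has no {orth} guides")
        self.guides = g.reset_index(drop=True)

    def subset(self, ortholog: str) -> pd.DataFrame:
        return self.guides[self.guides["ortholog"] == ortholog]

    @property
    def sp(self) -> pd.DataFrame:
        return self.subset("SpCas9")

    @property
    def sa(self) -> pd.DataFrame:
        return self.subset("SaCas9")

    def genes(self) -> list[str]:
        """Distinct target genes of `targeting` guides, in first-seen order."""
        t = self.guides.loc[self.guides["category"] == "targeting", "target_gene"]
        return list(dict.fromkeys(t))

    @classmethod
    def from_tsv(cls, path, dialect: dict[str, str] | None = None) -> "GuideLibrary":
        """Read a guide-library TSV; ``dialect`` maps file column names to ours."""
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        if dialect:
            df = df.rename(columns=dialect)
        required = {"guide_id", "ortholog", "category"}
        missing = required - set(df.columns)
        if missing:
            raise ParseError(f"guide library {path} missing columns: {sorted(missing)}")
        return cls(df)

    def to_tsv(self, path) -> None:
        self.guides.to_csv(path, sep="\t", index=False)


def _pair_class(sp_cat: str, sa_cat: str, sp_gene: str, sa_gene: str) -> str:
    sp_t = sp_cat == "targeting"
    sa_t = sa_cat == "targeting"
    if sp_t and sa_t:
        return "same_gene" if sp_gene == sa_gene else "gene_gene"
    if sp_t or sa_t:
        return "gene_control"
    return "control_control"


@dataclass
class ConstructCatalog:
    """All dual-guide constructs with derived pair classification.

    ``constructs`` columns: construct_id, sp_guide_id, sa_guide_id, sp_gene,
    sa_gene, sp_category, sa_category, pair_class, gene_pair (``"A;B"`` with
    sorted gene symbols for gene_gene/same_gene, "" otherwise).
    """

    constructs: pd.DataFrame

    def __post_init__(self) -> None:
        c = self.constructs
        dup = c.duplicated(subset=["sp_guide_id", "sa_guide_id"])
        if dup.any():
            i = c[dup].iloc[0]
            raise MalformedLibraryError(
                f"duplicate construct ({i['sp_guide_id']!r}, {i['sa_guide_id']!r})"
            )
        self.constructs = c.reset_index(drop=True)

    def class_counts(self) -> pd.Series:
        counts = self.constructs["pair_class"].value_counts()
        return counts.reindex(PAIR_CLASSES, fill_value=0)

    def __len__(self) -> int:
        return len(self.constructs)


def build_all_by_all_catalog(library: GuideLibrary) -> ConstructCatalog:
    """Cross every SpCas9 guide with every SaCas9 guide.

    Output size is exactly ``len(sp) * len(sa)``; construct ids are
    ``"<sp_guide_id>;<sa_guide_id>"``.
    """
    sp = library.sp.reset_index(drop=True)
    sa = library.sa.reset_index(drop=True)
    if sp.empty or sa.empty:
        raise MalformedLibraryError("both orthologs need at least one guide")
    n_sp, n_sa = len(sp), len(sa)
    sp_rep = sp.loc[np.repeat(np.arange(n_sp), n_sa)].reset_index(drop=True)
    sa_til = sa.loc[np.tile(np.arange(n_sa), n_sp)].reset_index(drop=True)
    df = pd.DataFrame(
        {
            "sp_guide_id": sp_rep["guide_id"],
            "sa_guide_id": sa_til["guide_id"],
            "sp_gene": sp_rep["target_gene"],
            "sa_gene": sa_til["target_gene"],
            "sp_category": sp_rep["category"],
            "sa_category": sa_til["category"],
        }
    )
    df["construct_id"] = df["sp_guide_id"] + ";" + df["sa_guide_id"]
    sp_t = (df["sp_category"] == "targeting").to_numpy()
    sa_t = (df["sa_category"] == "targeting").to_numpy()
    same = (df["sp_gene"] == df["sa_gene"]).to_numpy()
    pair_class = np.where(
        sp_t & sa_t,
        np.where(same, "same_gene", "gene_gene"),
        np.where(sp_t | sa_t, "gene_control", "control_control"),
    )
    df["pair_class"] = pair_class
    both = sp_t & sa_t
    first = (df["sp_gene"] <= df["sa_gene"]).to_numpy()
    lo = df["sp_gene"].where(first, df["sa_gene"])
    hi = df["sa_gene"].where(first, df["sp_gene"])
    df["gene_pair"] = np.where(both, lo + ";" + hi, "")
    cols = [
        "construct_id", "sp_guide_id", "sa_guide_id", "sp_gene", "sa_gene",
        "sp_category", "sa_category", "pair_class", "gene_pair",
    ]
    return ConstructCatalog(df[cols])


@dataclass
class CountMatrix:
    """Integer read counts per construct (rows) and sample (columns).

    ``samples`` is the sample sheet (one row per count column); exactly the
    rows with ``is_reference`` true form the pDNA reference pool.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    flagged_missing: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ParseError("negative read count")
        self.counts = self.counts.astype(np.int64)
        sheet_ids = list(self.samples["sample_id"])
        missing = [c for c in self.counts.columns if c not in sheet_ids]
        if missing:
            raise ParseError(f"sample column(s) absent from sample sheet: {missing}")
        self.samples = self.samples.set_index("sample_id", drop=False).loc[
            list(self.counts.columns)
        ].reset_index(drop=True)

    @property
    def reference_ids(self) -> list[str]:
        return list(self.samples.loc[self.samples["is_reference"], "sample_id"])

    def to_tsv(self, counts_path, sheet_path=None) -> None:
        out = self.counts.copy()
        out.insert(0, "construct_id", out.index)
        out.to_csv(counts_path, sep="\t", index=False)
        if sheet_path is not None:
            self.samples.to_csv(sheet_path, sep="\t", index=False)


def read_sample_sheet(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(SAMPLE_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"sample sheet {path} missing columns: {sorted(missing)}")
    df["is_reference"] = df["is_reference"].astype(bool)
    if not df["is_reference"].any():
        raise ParseError(f"sample sheet {path} designates no reference (pDNA) sample")
    return df[SAMPLE_COLUMNS]


def read_counts(path, catalog: ConstructCatalog, sample_sheet) -> CountMatrix:
    """Read a counts TSV keyed by construct_id, restricted to the catalog.

    Rows absent from the catalog are dropped (logged); cataloged constructs
    absent from the file get count 0 and are flagged in ``flagged_missing``.
    """
    samples = sample_sheet if isinstance(sample_sheet, pd.DataFrame) else read_sample_sheet(sample_sheet)
    df = pd.read_csv(path, sep="\t")
    if "construct_id" not in df.columns:
        raise ParseError(f"counts file {path} lacks a construct_id column")
    df = df.set_index("construct_id")
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = df.index[vals.isna().argmax()]
            raise ParseError(f"non-numeric count at row {row!r}, column {col!r}")
        if (vals < 0).any():
            row = df.index[(vals < 0).argmax()]
            raise ParseError(f"negative count at row {row!r}, column {col!r}")
        if (vals != vals.round()).any():
            row = df.index[(vals != vals.round()).argmax()]
            raise ParseError(f"non-integer count at row {row!r}, column {col!r}")
        df[col] = vals.astype(np.int64)

    cat_ids = pd.Index(catalog.constructs["construct_id"])
    extra = df.index.difference(cat_ids)
    if len(extra):
        logger.warning("read_counts: dropped %d row(s) not in catalog (e.g. %r)",
                       len(extra), extra[0])
        df = df.loc[df.index.intersection(cat_ids)]
    missing = cat_ids.difference(df.index)
    if len(missing):
        logger.warning("read_counts: %d cataloged construct(s) missing, filled with 0",
                       len(missing))
    df = df.reindex(cat_ids, fill_value=0)
    df.index.name = "construct_id"
    return CountMatrix(df, samples, flagged_missing=list(missing))
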