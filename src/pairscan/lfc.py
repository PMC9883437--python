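"""Log2 fold changes of construct abundance versus the plasmid (pDNA) pool.

Counts are normalised to reads per million within each sample, a pseudocount
is added before the log2 so zero counts stay finite, and each endpoint sample
is compared to the mean log2-RPM of the reference (pDNA) samples:

    LFC(c, s) = log2(RPM_s(c) + pc) - mean_ref log2(RPM_ref(c) + pc)

Replicates are averaged at the LFC level (arithmetic mean per condition).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParseError, UserInputError
from .library import CountMatrix

logger = logging.getLogger("pairscan")


@dataclass
class LfcTable:
    """Construct-level log2 fold changes.

    ``values``: index construct_id, one column per endpoint sample (or per
    condition after :func:`average_replicates`). ``samples`` carries the
    per-column metadata while columns are individual samples; after
    averaging, ``replicate_counts`` records how many replicates each
    condition column is a mean of.
    """

    values: pd.DataFrame
    pseudocount: float
    reference_ids: list[str]
    samples: pd.DataFrame | None = None
    replicate_counts: dict[str, int] = field(default_factory=dict)

    @property
    def conditions(self) -> list[str]:
        if self.replicate_counts:
            return list(self.values.columns)
        return list(dict.fromkeys(self.samples["condition"]))

    def to_tsv(self, path, catalog=None) -> None:
        out = self.values.copy()
        if catalog is not None:
            meta = catalog.constructs.set_index("construct_id")[["sp_guide_id", "sa_guide_id"]]
            out = meta.join(out, how="right")
        out.insert(0, "construct_id", out.index)
        out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def counts_to_log2rpm(counts: CountMatrix, pseudocount: float = 1.0) -> pd.DataFrame:
    """Per-sample log2(reads-per-million + pseudocount)."""
    if pseudocount <= 0:
        raise UserInputError(f"pseudocount must be positive, got {pseudocount}")
    totals = counts.counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ParseError(f"sample {zero.index[0]!r} has zero total count")
    rpm = counts.counts / totals * 1e6
    return np.log2(rpm + pseudocount)


def compute_lfc(
    log2rpm: pd.DataFrame,
    samples: pd.DataFrame,
    pseudocount: float = 1.0,
) -> LfcTable:
    """Subtract the (replicate-averaged) reference column from every endpoint sample."""
    ref_ids = list(samples.loc[samples["is_reference"], "sample_id"])
    if not ref_ids:
        raise UserInputError("no reference (pDNA) sample designated")
    missing = [r for r in ref_ids if r not in log2rpm.columns]
    if missing:
        raise UserInputError(f"reference sample(s) not in table: {missing}")
    ref = log2rpm[ref_ids].mean(axis=1)

    bad = ref.isna()
    if bad.any():
        logger.warning("compute_lfc: excluded %d construct(s) missing from reference", bad.sum())
    keep = log2rpm.index[~bad]

    endpoint = samples.loc[~samples["is_reference"], "sample_id"]
    values = log2rpm.loc[keep, list(endpoint)].sub(ref.loc[keep], axis=0)
    return LfcTable(
        values=values,
        pseudocount=pseudocount,
        reference_ids=ref_ids,
        samples=samples.loc[~samples["is_reference"]].reset_index(drop=True),
    )


def average_replicates(lfc: LfcTable) -> LfcTable:
    """Arithmetic mean of per-replicate LFCs within each condition."""
    if lfc.replicate_counts:
        return lfc  # already averaged
    cond = lfc.samples.set_index("sample_id")["condition"]
    grouped = lfc.values.T.groupby(lfc.values.columns.map(cond)).mean().T
    order = list(dict.fromkeys(cond[c] for c in lfc.values.columns))
    grouped = grouped[order]
    counts = {c: int((cond == c).sum()) for c in order}
    return LfcTable(
        values=grouped,
        pseudocount=lfc.pseudocount,
        reference_ids=lfc.reference_ids,
        samples=lfc.samples,
        replicate_counts=counts,
    )
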