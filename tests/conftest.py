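import numpy as np
import pandas as pd
import pytest

from pairscan.library import GuideLibrary, build_all_by_all_catalog


def make_library(n_genes=3, guides_per=2, n_nt=2, n_ess=0) -> GuideLibrary:
    """Small synthetic dual-ortholog library for unit tests."""
    rows = []
    for orth, tag in (("SpCas9", "sp"), ("SaCas9", "sa")):
        for i in range(n_genes):
            g = f"GENE{i + 1}"
            for k in range(guides_per):
                rows.append((f"{g}_{tag}{k + 1}", orth, "targeting", g, ""))
        for k in range(n_nt):
            rows.append((f"NT_{tag}{k + 1}", orth, "non_targeting", "", ""))
        for k in range(n_ess):
            rows.append((f"ESS_{tag}{k + 1}", orth, "essential_control", f"ESSC{k + 1}", ""))
    return GuideLibrary(pd.DataFrame(
        rows, columns=["guide_id", "ortholog", "category", "target_gene", "note"]))


@pytest.fixture
def toy_library() -> GuideLibrary:
    return make_library()


@pytest.fixture
def toy_catalog(toy_library):
    return build_all_by_all_catalog(toy_library)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
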