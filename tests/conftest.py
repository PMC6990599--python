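import numpy as np
import pandas as pd
import pytest

from prstress.io import CountMatrix, GeneCatalog, GeneRecord


@pytest.fixture
def small_counts() -> CountMatrix:
    """3 genes x 6 samples, two time points, three replicates each."""
    rng = np.random.default_rng(0)
    samples = [f"s{i}" for i in range(6)]
    counts = pd.DataFrame(
        rng.integers(10, 1000, size=(3, 6)),
        index=["g1", "g2", "g3"],
        columns=samples,
    )
    meta = pd.DataFrame(
        {
            "condition": ["WF"] * 6,
            "timepoint": [0, 0, 0, 14, 14, 14],
            "replicate": [1, 2, 3, 1, 2, 3],
        },
        index=pd.Index(samples, name="sample"),
    )
    return CountMatrix(counts, meta)


@pytest.fixture
def toy_catalog() -> GeneCatalog:
    return GeneCatalog(
        [
            GeneRecord("a1", family="PR-2", chromosome="chr1", start=100, end=199, strand="+"),
            GeneRecord("a2", family="PR-2", chromosome="chr1", start=10_000, end=10_999, strand="+"),
            GeneRecord("a3", family="PR-2", chromosome="chr2", start=100, end=199, strand="-"),
            GeneRecord("b1", family="PR-5", chromosome="chr1", start=5_000, end=5_999, strand="+"),
            GeneRecord("u1", family="PR-5"),  # unplaced
        ]
    )


def make_deg_table(rows, condition="WF"):
    """rows: iterable of (gene, timepoint, log2fc, fdr)."""
    from prstress.deg import call_deg_status

    df = pd.DataFrame(rows, columns=["gene", "timepoint", "log2fc", "fdr"])
    df.insert(1, "condition", condition)
    df["status"] = [call_deg_status(l, f) for l, f in zip(df["log2fc"], df["fdr"])]
    return df
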