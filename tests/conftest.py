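import numpy as np
import pandas as pd
import pytest

from mprakit import synthetic_data
from mprakit.genomic_core import GenomicInterval


@pytest.fixture(scope="session")
def toy_genome():
    """A deterministic 30 kb single-contig genome for design tests."""
    rec = synthetic_data.make_toy_genome(30_000, gc=0.41, seed=42, contig="chrT")
    return {rec.id: rec.seq}


@pytest.fixture(scope="session")
def toy_region():
    return GenomicInterval("chrT", 5_001, 15_000)


def null_manifest(n_test: int, n_null: int) -> pd.DataFrame:
    """A manifest of inert test elements plus scrambled controls."""
    rows = []
    for i in range(n_test):
        rows.append(
            dict(oligo_id=f"el{i}", allele_class="ref", chrom="chrT", start=1,
                 end=219, strand="+", focal_pos=None, variant_key=None, length=219)
        )
    for i in range(n_null):
        rows.append(
            dict(oligo_id=f"scr{i}", allele_class="scramble", chrom="chrT", start=1,
                 end=219, strand="+", focal_pos=None, variant_key=None, length=219)
        )
    return pd.DataFrame(rows)
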