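import numpy as np
import pytest

from cpgoe.seqio import GeneRecord


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20130917)


@pytest.fixture
def ten_gene_records():
    """Hand-made records exercising every filter: taxon, dedup, length."""
    mk = lambda i, n, iso, taxon: GeneRecord(
        gene_id=f"g{i:02d}", sequence="ACGT" * (n // 4), isogroup_id=iso, taxon_label=taxon
    )
    return [
        mk(0, 400, "isoA", "insect"),
        mk(1, 400, "isoA", "insect"),   # same isogroup as g00: one survives
        mk(2, 400, "isoA", "insect"),   # same isogroup as g00
        mk(3, 296, "isoB", "insect"),   # too short (<300)
        mk(4, 300, "isoC", "insect"),   # exactly 300: kept
        mk(5, 400, "isoD", "protist"),  # wrong taxon
        mk(6, 400, "isoE", "insect"),
        mk(7, 400, None, "insect"),     # singleton: never deduped
        mk(8, 400, None, "insect"),
        mk(9, 400, "isoF", None),       # unannotated taxon: dropped
    ]
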