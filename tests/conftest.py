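import pandas as pd
import pytest

from conifersnp import CallerParams


@pytest.fixture
def params():
    return CallerParams()


def make_snp_row(isotig="iso1", pos=10, ref="A", dataset_id="ds1", alt="G",
                 alt_count=5, depth=25, p_snp=1e-3, mapq=50.0):
    return {
        "isotig": isotig, "pos": pos, "ref": ref, "dataset_id": dataset_id,
        "alt": alt, "alt_count": alt_count, "depth": depth,
        "freq": alt_count / depth, "p_snp": p_snp, "mapq": mapq,
    }


@pytest.fixture
def snp_row_factory():
    return make_snp_row


def snp_table(rows):
    cols = ["isotig", "pos", "ref", "dataset_id", "alt", "alt_count",
            "depth", "freq", "p_snp", "mapq"]
    return pd.DataFrame(rows, columns=cols)


@pytest.fixture
def snp_table_factory():
    return snp_table
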