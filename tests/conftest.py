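import numpy as np
import pandas as pd
import pytest

from obelisktools import SegregationParams
from obelisktools.rank_abundance import AbundanceTable


@pytest.fixture
def default_params() -> SegregationParams:
    """The model's default parameterisation: N=10 copies, capacity 1000."""
    return SegregationParams(N=10, Nstar=1000, r2=1.0)


def make_table(rows, sample_id="s1") -> AbundanceTable:
    """Build a small AbundanceTable from (id, class, length, est_counts) rows.

    TPM is left at zero (unpopulated) unless given as a fifth element.
    """
    df = pd.DataFrame(
        [
            {
                "feature_id": r[0],
                "feature_class": r[1],
                "length": r[2],
                "eff_length": float(max(r[2] - 100, 1)),
                "est_counts": float(r[3]),
                "tpm": float(r[4]) if len(r) > 4 else 0.0,
            }
            for r in rows
        ]
    )
    return AbundanceTable(sample_id=sample_id, data=df)


@pytest.fixture
def small_table() -> AbundanceTable:
    """Three mRNAs, one rRNA decoy and the focal feature."""
    return make_table(
        [
            ("g1", "mRNA", 900, 500.0),
            ("g2", "mRNA", 1200, 50.0),
            ("g3", "mRNA", 600, 5.0),
            ("rrn1", "rRNA", 2900, 1e6),
            ("focal1", "focal", 1137, 100.0),
        ]
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20251001)
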