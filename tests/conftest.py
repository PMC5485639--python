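import numpy as np
import pytest

from dairygap.survey import FarmRecord, SurveyTable


@pytest.fixture
def small_table():
    """Three farms in two zones with one output and two inputs."""
    recs = [
        FarmRecord("f1", "LG", 300.0, {"milk": 300.0}, {"land": 2.0, "herd": 4.0}),
        FarmRecord("f2", "LG", 500.0, {"milk": 500.0}, {"land": 1.5, "herd": 3.0}),
        FarmRecord("f3", "MRD", 200.0, {"milk": 200.0}, {"land": 0.8, "herd": 2.0}),
    ]
    return SurveyTable(recs, output_names=["milk"], input_names=["land", "herd"])


@pytest.fixture
def yields_table():
    def make(yields, zone="Z"):
        recs = [
            FarmRecord(f"f{i}", zone, float(y)) for i, y in enumerate(yields)
        ]
        return SurveyTable(recs)

    return make


def table_with_exact_means(zone, top, overall, n=10):
    """n-farm zone whose top-decile mean and overall mean are exactly as given.

    One farm sits at the top-decile value; the other n-1 share the remainder,
    so mean = overall and the single top farm is the ceil(n/10) decile.
    """
    assert top > overall > 0
    rest = (n * overall - top) / (n - 1)
    assert rest < top
    recs = [FarmRecord(f"{zone}-top", zone, float(top))]
    recs += [FarmRecord(f"{zone}-{i}", zone, float(rest)) for i in range(n - 1)]
    return SurveyTable(recs)
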