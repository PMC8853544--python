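import numpy as np
import pandas as pd
import pytest

from mirstab import CountMatrix, make_fixture
from mirstab.datamodel import probe_annotation_frame

HK_IDS = ["ACTB", "B2M", "GAPDH", "RPL19", "RPLP0"]
POS_IDS = [f"POS_{c}" for c in "ABCDEF"]
NEG_IDS = [f"NEG_{c}" for c in "ABCDEFGH"]


def build_matrix(
    endog: dict[str, list[int]],
    groups: list[str],
    hk: dict[str, list[int]] | None = None,
    pos: dict[str, list[int]] | None = None,
    neg: dict[str, list[int]] | None = None,
) -> CountMatrix:
    """Hand-built CountMatrix with a full control complement.

    ``endog`` maps probe id -> per-sample counts; controls default to
    constants so normalizer totals are predictable.
    """
    n = len(groups)
    hk = hk if hk is not None else {pid: [1000] * n for pid in HK_IDS}
    pos = pos if pos is not None else {pid: [500] * n for pid in POS_IDS}
    neg = neg if neg is not None else {pid: [5] * n for pid in NEG_IDS}
    counts = pd.DataFrame(
        {**endog, **hk, **pos, **neg},
        index=[f"s{i}" for i in range(n)],
    ).T
    probes = probe_annotation_frame(list(endog), list(hk), list(pos), list(neg))
    samples = pd.DataFrame(
        {"group": groups}, index=pd.Index([f"s{i}" for i in range(n)], name="sample_id")
    )
    return CountMatrix(counts=counts, probes=probes, samples=samples)


@pytest.fixture(scope="session")
def tiny():
    return make_fixture("tiny", seed=0)


@pytest.fixture(scope="session")
def tiny_matrix(tiny):
    return tiny[0]


@pytest.fixture(scope="session")
def paper_like():
    return make_fixture("paper_like", seed=0)
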