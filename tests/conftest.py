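"""Shared fixtures and deterministic hypothesis configuration."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from promlink import pipeline, synthdata
from promlink.annotation import TranscriptModel
from promlink.quant import CountMatrix

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_tx(tid, gene, exons, strand="+", chrom="chr1"):
    return TranscriptModel(
        transcript_id=tid, gene_id=gene, chrom=chrom, strand=strand,
        exons=tuple(tuple(e) for e in exons),
    )


def make_meta(samples, regions=None, donors=None):
    n = len(samples)
    regions = regions or ["R1"] * n
    donors = donors or [f"D{i + 1}" for i in range(n)]
    return pd.DataFrame(
        {
            "sample_id": samples,
            "donor": donors,
            "region": regions,
            "broad_region": regions,
            "cell_type": ["neuronal"] * n,
        }
    ).set_index("sample_id")


def make_counts(mat, features, samples, kind="gene", meta=None):
    meta = meta if meta is not None else make_meta(samples)
    return CountMatrix(
        pd.DataFrame(np.asarray(mat), index=features, columns=samples), meta, kind
    )


@pytest.fixture(scope="session")
def default_bundle():
    return synthdata.simulate(synthdata.SimConfig(seed=1))


@pytest.fixture(scope="session")
def default_outputs(default_bundle):
    return pipeline.run_bundle(default_bundle)
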