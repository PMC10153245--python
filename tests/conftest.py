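import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from lysoscape import SyntheticSpec, generate_cohort, train_classifier
from lysoscape.config import RunConfig
from lysoscape.detect import (
    MarkerHitProvider,
    encode_markers,
    label_orfs_by_truth,
    orf_feature_table,
)

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

TRAIN_SEED = 101
RUN_CONFIG = RunConfig(seed=7)


@pytest.fixture(scope="session")
def run_config():
    return RUN_CONFIG


@pytest.fixture(scope="session")
def train_cohort():
    """A small fully realised cohort used to fit the ORF classifier."""
    spec = SyntheticSpec(n_genomes=4, seed=TRAIN_SEED)
    records, metadata, truth = generate_cohort(spec)
    return spec, records, metadata, truth


@pytest.fixture(scope="session")
def marker_vocab(train_cohort):
    spec = train_cohort[0]
    markers = spec.marker_set()
    return markers, encode_markers(markers, spec.kmer_k)


@pytest.fixture(scope="session")
def training_table(train_cohort, marker_vocab):
    _, records, _, truth = train_cohort
    _, codes = marker_vocab
    tables, labels = [], []
    for rec in records:
        t = orf_feature_table(rec, codes)
        tables.append(t)
        labels.append(
            label_orfs_by_truth(t, truth.regions[truth.regions.accession == rec.accession])
        )
    return pd.concat(tables, ignore_index=True), np.concatenate(labels)


@pytest.fixture(scope="session")
def model(training_table):
    table, labels = training_table
    return train_classifier(table, labels, n_trees=500, seed=RUN_CONFIG.seed)


@pytest.fixture(scope="session")
def hit_provider(marker_vocab):
    markers, _ = marker_vocab
    return MarkerHitProvider(markers)


@pytest.fixture(scope="session")
def unique_dna():
    """A de Bruijn sequence of order 8: every 8-mer occurs exactly once.

    Any repeated >=10 bp substring would imply a repeated 8-mer, so
    substrings carved from disjoint parts of this sequence contain no
    direct-repeat pair >= 10 bp other than what a test plants itself.
    """
    k, n = 4, 8
    a = [0] * (k * n)
    seq: list[int] = []

    def db(t, p):
        if t > n:
            if n % p == 0:
                seq.extend(a[1 : p + 1])
        else:
            a[t] = a[t - p]
            db(t + 1, p)
            for j in range(a[t - p] + 1, k):
                a[t] = j
                db(t + 1, t)

    db(1, 1)
    bases = "ACGT"
    return "".join(bases[c] for c in seq)
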