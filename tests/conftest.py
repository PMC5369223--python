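import numpy as np
import pytest

from cpseg.encoding import encode_alignment
from cpseg.model import ModelConfig, gibbs_sample
from cpseg.simulate import TruthConfig, generate_alignment

MAF_TEXT = """##maf version=1
a score=1.0
s danRer7.chr1 100 8 + 1000 ACGT--ACGT
s mm9.chr5 20 10 + 500 ACGTGGACGT
s hg19.chr2 30 10 - 800 ACGTCCACGT
s oryLat2.chr3 5 10 + 300 ACGTAAACGT

a score=2.0
s danRer7.chr1 200 4 + 1000 ACGT
s mm9.chr5 40 4 + 500 ACGT

a score=3.0
s danRer7.chr1 300 4 - 1000 AACC
s mm9.chr5 50 4 + 500 AACC
s hg19.chr2 60 4 + 800 AACC
"""


@pytest.fixture
def maf_text():
    return MAF_TEXT


@pytest.fixture(scope="session")
def small_truth():
    """A compact synthetic alignment with planted structure (fast)."""
    config = TruthConfig(
        total_length=6000,
        n_exons=2,
        n_elements=2,
        gene_margin=500,
        mean_segment_length=400,
        seed=42,
    )
    return generate_alignment(config)


@pytest.fixture(scope="session")
def small_encoded(small_truth):
    return encode_alignment(small_truth.alignment)


@pytest.fixture(scope="session")
def small_trace(small_encoded):
    """A short sampler run on the compact benchmark (T = 3)."""
    config = ModelConfig(T=3, seed=9, n_iter=400, cp_prior_phi="sample")
    return gibbs_sample(small_encoded, config)


@pytest.fixture(scope="session")
def two_class_trace():
    """Well-separated two-class data and its trace, with truth labels."""
    config = TruthConfig(
        T_true=2,
        conservation=(0.45, 0.75),
        gc=(0.40, 0.50),
        total_length=8000,
        mean_segment_length=800,
        n_exons=2,
        n_elements=2,
        gene_margin=500,
        seed=7,
    )
    truth = generate_alignment(config)
    seq = encode_alignment(truth.alignment)
    trace = gibbs_sample(seq, ModelConfig(T=2, seed=3, n_iter=600, cp_prior_phi="sample"))
    return truth, seq, trace
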