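import numpy as np
import pytest

from seednet.formats_io import AnnotationTable, PromoterRecord
from seednet.pwm_scan import WeightMatrix
from seednet.synthetic_data import SyntheticConfig, generate_dataset


def random_matrix(rng, length=None, mid="M$RAND_01", genes=("TFX",)):
    """A random, moderately sharp weight matrix."""
    if length is None:
        length = int(rng.integers(5, 11))
    freq = rng.dirichlet(np.full(4, 0.5), size=length)
    # avoid exactly-zero rowsums / fully flat rows
    freq = (freq + 0.01) / (freq + 0.01).sum(axis=1, keepdims=True)
    return WeightMatrix(mid, freq, genes)


def random_seq(rng, length):
    return "".join(rng.choice(list("ACGT"), size=length))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_pos_matrix():
    """The worked two-position example matrix."""
    return WeightMatrix(
        "M$TWO_01", [[0.5, 0.3, 0.1, 0.1], [0.1, 0.1, 0.3, 0.5]], ("TFX",)
    )


@pytest.fixture
def toy_annotation():
    """Five promoters over two TF genes and three nonTF genes, on chrT."""
    promoters = {}
    genes = ["TFA", "TFB", "G1", "G2", "G2"]
    for i, gene in enumerate(genes):
        pid = f"P{i + 1}"
        start = i * 2000
        promoters[pid] = PromoterRecord(
            pid, gene, f"NM_{i}", "chrT", "+", start, start + 1000
        )
    return AnnotationTable(
        promoters, {"TFA": "TF", "TFB": "TF", "G1": "nonTF", "G2": "nonTF"}
    )


@pytest.fixture(scope="session")
def default_dataset():
    """One mid-sized synthetic dataset shared by read-only tests."""
    return generate_dataset(SyntheticConfig(seed=7))


@pytest.fixture(scope="session")
def fully_conserved_dataset():
    """Every planted site replicated in all orthologs; ChIP at perfect
    sensitivity without noise."""
    cfg = SyntheticConfig(
        seed=11, conservation_prob=1.0, chip_sensitivity=1.0,
        chip_noise_rate=0.0,
    )
    return generate_dataset(cfg)
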