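import dataclasses

import numpy as np
import pytest

from asmscan.api import AmyloidMotifModel
from asmscan.model import TrainConfig
from asmscan.synthetic import SyntheticBenchmarkConfig, build_benchmark


@pytest.fixture(scope="session")
def small_benchmark():
    """A reduced synthetic benchmark for fast unit tests."""
    cfg = SyntheticBenchmarkConfig(
        n_train_families=2,
        n_heldout_families=1,
        motifs_per_family=30,
        test_motifs_per_family=10,
        n_negative_windows=300,
        n_test_negative_windows=100,
        n_negative_domains=30,
        seed=11,
    )
    return build_benchmark(cfg)


@pytest.fixture(scope="session")
def small_results(small_benchmark):
    """A quickly trained 3-fold ensemble on the reduced benchmark."""
    model = AmyloidMotifModel(
        small_benchmark.train_pos,
        small_benchmark.train_neg,
        train_config=TrainConfig(epochs=8, batch_size=16, seed=3),
    )
    return model.fit(k=3)


@pytest.fixture
def write_fasta_file(tmp_path):
    def _write(entries, name="seqs.fasta"):
        path = tmp_path / name
        path.write_text("".join(f">{h}\n{s}\n" for h, s in entries))
        return path

    return _write
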