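import numpy as np
import pytest

from gpmoe.data_io import PairedDataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_dataset():
    """Four samples, two labels, small raw tables with a few zeros."""
    return PairedDataset(
        sample_ids=["s1", "s2", "s3", "s4"],
        microbial=np.array(
            [
                [1.0, 0.0, 3.0, 0.0],
                [2.0, 5.0, 0.0, 0.0],
                [4.0, 2.0, 1.0, 0.0],
                [8.0, 1.0, 2.0, 7.0],
            ]
        ),
        metabolite=np.array(
            [
                [1.0, 2.0],
                [3.0, 1.0],
                [2.0, 4.0],
                [5.0, 3.0],
            ]
        ),
        microbial_names=["t1", "t2", "t3", "t4"],
        metabolite_names=["m1", "m2"],
        labels=np.array(["A", "A", "B", "B"]),
    )


@pytest.fixture
def toy_files(tmp_path, toy_dataset):
    """The toy dataset written as the three TSV inputs."""
    from gpmoe.data_io import write_paired_tables

    paths = {
        "microbial": tmp_path / "microbial.tsv",
        "metabolite": tmp_path / "metabolite.tsv",
        "metadata": tmp_path / "metadata.tsv",
    }
    write_paired_tables(
        toy_dataset,
        paths["microbial"],
        paths["metabolite"],
        paths["metadata"],
        label_column="label",
    )
    return paths
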