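import shutil
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from cypome.pipeline import RunConfig, run_pipeline
from cypome.synth import SynthConfig, generate_reference_db, write_dataset


@pytest.fixture(scope="session")
def default_config() -> SynthConfig:
    return SynthConfig(seed=42)


@pytest.fixture(scope="session")
def reference(default_config):
    """Seed-42 synthetic reference database (families, refs, domain alignment)."""
    return generate_reference_db(default_config)


@pytest.fixture(scope="session")
def dataset_dir(tmp_path_factory, default_config) -> Path:
    """Seed-42 dataset on disk: genomes/, ref_cyps.faa, domain alignment, manifest."""
    out = tmp_path_factory.mktemp("dataset")
    return write_dataset(out / "data", default_config)


@pytest.fixture(scope="session")
def manifest(dataset_dir) -> pd.DataFrame:
    return pd.read_csv(dataset_dir / "truth_manifest.tsv", sep="\t").fillna("")


@pytest.fixture(scope="session")
def pipeline_run(dataset_dir, tmp_path_factory):
    """One full seed-42 pipeline run shared across tests: (summary, out_dir)."""
    out = tmp_path_factory.mktemp("pipeline") / "out"
    config = RunConfig(
        input_dir=str(dataset_dir / "genomes"),
        ref_cyps=str(dataset_dir / "ref_cyps.faa"),
        ref_domains=str(dataset_dir / "domain_alignment.fasta"),
        out_dir=str(out),
        seed=42,
    )
    summary = run_pipeline(config)
    return summary, out


def random_gcm_counts(rng: np.random.Generator, n_cyps=6, n_genomes=5, density=0.5):
    """Random non-negative count matrix with every row occupied somewhere."""
    counts = rng.integers(0, 4, size=(n_cyps, n_genomes))
    counts[rng.random(counts.shape) > density] = 0
    for i in range(n_cyps):
        if not counts[i].any():
            counts[i, rng.integers(0, n_genomes)] = 1 + int(rng.integers(0, 3))
    return counts


def gcm_from_counts(counts: np.ndarray, level="family"):
    from cypome.gcm import GCM

    table = pd.DataFrame(
        counts,
        index=[f"CYP{i + 1}" for i in range(counts.shape[0])],
        columns=[f"g{j + 1}" for j in range(counts.shape[1])],
    )
    return GCM(level=level, table=table)
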