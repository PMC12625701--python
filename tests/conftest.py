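import numpy as np
import pandas as pd
import pytest

from cnpskit.ontology import CycleMapping, ProcessDef, load_mapping
from cnpskit.synth_bench import SynthConfig, generate_dataset
from cnpskit.table_io import GroupTable, KOTable


@pytest.fixture(scope="session")
def default_mapping():
    return load_mapping()


@pytest.fixture()
def toy_mapping():
    """Two-element toy with one KO shared between two carbon processes."""
    return CycleMapping(
        processes=[
            ProcessDef("proc_a", "Process A", "C", ("K00001", "K00002")),
            ProcessDef("proc_b", "Process B", "C", ("K00002", "K00003")),
            ProcessDef("proc_n", "Process N", "N", ("K00010",)),
        ]
    )


@pytest.fixture()
def example(default_mapping):
    """Deterministic synthetic bundle + truth (2 groups x 3 samples, seed 42)."""
    return generate_dataset(SynthConfig(seed=42), default_mapping)


def random_ko_table(rng, ko_ids, n_samples, zero_fraction=0.2):
    values = rng.lognormal(0, 1, size=(len(ko_ids), n_samples))
    values[rng.random(values.shape) < zero_fraction] = 0.0
    samples = [f"s{i + 1}" for i in range(n_samples)]
    df = pd.DataFrame(values, index=pd.Index(ko_ids, name="KO"), columns=samples)
    desc = pd.Series(["" for _ in ko_ids], index=df.index)
    return KOTable(values=df, descriptions=desc)


def group_of(samples, labels):
    return GroupTable(assignments=pd.Series(labels, index=samples, name="Group"))
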