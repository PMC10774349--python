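import numpy as np
import pytest

from refsig import AsvTable, SyntheticConfig, generate_discovery

RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")


def _seq(rng: np.random.Generator, length: int = 60) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


@pytest.fixture
def toy_table() -> AsvTable:
    """3 samples x 4 ASVs with hand-set counts."""
    rng = np.random.default_rng(123)
    asv_ids = [f"asv{j}" for j in range(4)]
    return AsvTable(
        sample_ids=["s1", "s2", "s3"],
        asv_ids=asv_ids,
        counts=np.array([[5, 0, 2, 9], [1, 3, 0, 4], [0, 7, 6, 2]]),
        sequences={a: _seq(rng) for a in asv_ids},
        labels={"s1": "case", "s2": "control", "s3": "case"},
    )


@pytest.fixture(scope="session")
def small_cohort():
    """50 samples x 80 ASVs with 6 planted features (session-wide, read-only)."""
    cfg = SyntheticConfig(
        n_case=25, n_control=25, n_asv=80, n_informative=6, effect_size=2.0, seed=11
    )
    table, truth = generate_discovery(cfg)
    return cfg, table, truth


def write_cohort(table: AsvTable, tmp_path, stem="cohort"):
    """Write a table to TSV/FASTA/labels under tmp_path; returns the 3 paths."""
    from refsig import write_asv_table

    paths = (
        tmp_path / f"{stem}_counts.tsv",
        tmp_path / f"{stem}.fasta",
        tmp_path / f"{stem}_labels.tsv",
    )
    write_asv_table(table, *paths)
    return paths
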