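import pandas as pd
import pytest

from tertscape import SimConfig, simulate_cohort
from tertscape.io import PathwayLibrary


@pytest.fixture
def tiny_counts() -> pd.DataFrame:
    return pd.DataFrame(
        {"t1": [5, 10, 0, 30], "t2": [0, 20, 2, 60], "c1": [1, 10, 1, 30], "c2": [3, 10, 3, 30]},
        index=["TERT", "A", "B", "C"],
    )


@pytest.fixture
def tiny_samples() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "tumor_type": ["lung", "lung", "lung", "lung"],
            "role": ["tumor", "tumor", "control", "control"],
            "tert_stratum": ["unset"] * 4,
            "mutation_status": ["wt", "unknown", "unknown", "unknown"],
        },
        index=pd.Index(["t1", "t2", "c1", "c2"], name="sample_id"),
    )


@pytest.fixture
def tiny_library() -> PathwayLibrary:
    return PathwayLibrary(
        {"P1": {"A": 1, "B": -1, "C": 0}, "P2": {"A": 1, "C": 1}},
        {"P1": "mixed roles", "P2": "all activators"},
    )


@pytest.fixture(scope="session")
def cohort200():
    """Default-scale synthetic cohort (~200 tumors across 5 types)."""
    return simulate_cohort(SimConfig(seed=11))


@pytest.fixture(scope="session")
def pipeline200(cohort200, tmp_path_factory):
    """Full pipeline run on the default synthetic cohort."""
    from tertscape.pipeline import RunConfig, run_pipeline
    from tertscape.simulate import write_cohort

    base = tmp_path_factory.mktemp("cohort200")
    paths = write_cohort(cohort200, base / "in")
    cfg = RunConfig(
        counts=str(paths["counts"]),
        samples=str(paths["samples"]),
        pathways=str(paths["pathways"]),
        te_counts=str(paths["te_counts"]),
        tf_list=str(paths["tf"]),
        out_dir=str(base / "run"),
        min_reads=10_000,  # synthetic library sizes are ~1e5 reads
        seed=11,
    )
    out_dir = run_pipeline(cfg)
    return {"cfg": cfg, "out": out_dir, "paths": paths}
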