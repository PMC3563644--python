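import numpy as np
import pandas as pd
import pytest

from ergmeta import (
    GroupAssignment,
    SimConfig,
    StudyMatrix,
    collapse_probes,
    generate_study_set,
)


@pytest.fixture
def tiny_gene_study() -> StudyMatrix:
    """3 genes x 6 samples at gene level, 3 cancer + 3 benign."""
    values = pd.DataFrame(
        {
            "s1": [8.0, 5.0, 10.0],
            "s2": [8.2, 5.1, 10.3],
            "s3": [7.9, 5.2, 9.8],
            "s4": [9.1, 5.0, 10.1],
            "s5": [9.3, 5.1, 10.0],
            "s6": [9.0, 5.2, 10.2],
        },
        index=["GA", "GB", "GC"],
    )
    phenos = {s: ("cancer" if s in ("s1", "s2", "s3") else "benign") for s in values}
    return StudyMatrix(
        study_id="tiny", values=values, feature_level="gene", sample_phenotypes=phenos
    )


@pytest.fixture
def tiny_groups() -> GroupAssignment:
    return GroupAssignment(
        labels={
            "s1": "positive",
            "s2": "positive",
            "s3": "positive",
            "s4": "negative",
            "s5": "negative",
            "s6": "negative",
        }
    )


@pytest.fixture(scope="session")
def small_bundle():
    """3-study synthetic set with subgroup and cancer effects, strong marker."""
    cfg = SimConfig(
        n_studies=3,
        genes=300,
        samples_per_study=((40, 15), (45, 20), (50, 10)),
        seed=7,
    )
    studies, maps, truth = generate_study_set(cfg)
    return cfg, studies, maps, truth


@pytest.fixture(scope="session")
def small_gene_studies(small_bundle):
    _, studies, maps, _ = small_bundle
    return [collapse_probes(s, maps[s.study_id]) for s in studies]
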