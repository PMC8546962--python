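import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from terroirseq import CountTable, DistanceMatrix, SampleMetadata, ScenarioConfig

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def tiny_table():
    """5 ASVs x 4 samples with taxonomy, one chloroplast lineage."""
    counts = pd.DataFrame(
        {
            "s1": [10, 5, 0, 3, 2],
            "s2": [8, 0, 1, 4, 7],
            "s3": [12, 2, 2, 0, 4],
            "s4": [9, 1, 3, 2, 5],
        },
        index=[f"asv{i}" for i in range(1, 6)],
    )
    taxonomy = pd.Series(
        {
            "asv1": "Bacteria;Proteobacteria;Gammaproteobacteria;Enterobacterales;Erwiniaceae;Tatumella;Tatumella ptyseos",
            "asv2": "Bacteria,Cyanobacteria,Cyanobacteriia,Chloroplast",
            "asv3": "Bacteria;Firmicutes;Bacilli;Lactobacillales;Lactobacillaceae;Lactobacillus;Lactobacillus plantarum",
            "asv4": "Bacteria;Proteobacteria;Alphaproteobacteria;Acetobacterales;Acetobacteraceae;Gluconobacter;Gluconobacter oxydans",
            "asv5": "Bacteria;Actinobacteriota;ClassX;OrderX;FamilyX;GenusX;GenusX incognita",
        }
    )
    return CountTable(counts=counts, marker="16S", taxonomy=taxonomy)


@pytest.fixture
def tiny_meta():
    frame = pd.DataFrame(
        {
            "site": ["S1", "S1", "S2", "S2"],
            "region": ["R1", "R1", "R2", "R2"],
            "vintage": ["2017"] * 4,
            "tank": ["T1", "T2", "T1", "T2"],
        },
        index=["s1", "s2", "s3", "s4"],
    )
    return SampleMetadata(frame)


@pytest.fixture
def random_distance():
    def make(n: int, seed: int = 0) -> DistanceMatrix:
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(n, 3))
        from scipy.spatial.distance import pdist, squareform

        return DistanceMatrix(
            [f"s{i}" for i in range(n)], squareform(pdist(pts)), "euclidean"
        )

    return make


@pytest.fixture(scope="session")
def large_effect_study():
    """One large-effect synthetic study shared across the session."""
    from terroirseq import generate_study

    return generate_study(ScenarioConfig.large_effect(seed=7))


@pytest.fixture(scope="session")
def rna_feature_matrix(large_effect_study):
    from terroirseq.signatures import summarize_timeseries

    return summarize_timeseries(
        large_effect_study.transcript_counts, large_effect_study.metadata
    )
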