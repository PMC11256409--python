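import numpy as np
import pytest
from hypothesis import settings

from virowas.synthgen import SimConfig, generate_cohort
from virowas.triage import ContigFeatures

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


def random_contig_features(rng: np.random.Generator, n: int) -> list[ContigFeatures]:
    """Random contig feature rows spanning all triage decision boundaries."""
    rows = []
    for i in range(n):
        viral = int(rng.integers(0, 20))
        host = int(rng.integers(0, 20))
        extra = int(rng.integers(0, 10))
        total = viral + host + extra
        busco = int(rng.integers(0, total + 1)) if total else 0
        rows.append(
            ContigFeatures(
                contig_id=f"c{i:04d}",
                length=int(rng.integers(1000, 4000)),
                viral_gene_count=viral,
                host_gene_count=host,
                total_gene_count=total,
                dvf_score=float(np.round(rng.uniform(0.80, 1.0), 3)),
                dvf_pvalue=float(np.round(rng.uniform(0.0, 0.02), 4)),
                vibrant_viral=bool(rng.random() < 0.3),
                busco_count=busco,
                completeness=float(np.round(rng.uniform(0.0, 100.0), 1)),
                contamination=float(np.round(rng.uniform(0.0, 100.0), 1)),
            )
        )
    return rows


@pytest.fixture(scope="session")
def small_study():
    """Small fast-path cohort shared by structural tests."""
    cfg = SimConfig(
        n_case=15,
        n_control=15,
        n_votus=30,
        n_planted_case_enriched=6,
        n_planted_control_enriched=6,
        seed=11,
    )
    return generate_cohort(cfg, simulate_depth=False)


@pytest.fixture(scope="session")
def small_profiles(small_study):
    return small_study.profiles()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240718)
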