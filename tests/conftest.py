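import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from neurofuse import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Compact multimodal cohort shared by read-only tests."""
    spec = CohortSpec(
        n_patients=80,
        n_ehr_features=20,
        n_snp_sites=60,
        n_causal_per_modality=5,
        modality_coverage={"snp": 0.5, "imaging": 0.3},
        effect_size=1.5,
        seed=42,
    )
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def tiny_imaging_cohort():
    """Small-volume cohort for imaging tests (cheap atlas grid)."""
    spec = CohortSpec(
        n_patients=30,
        n_ehr_features=10,
        n_snp_sites=20,
        n_causal_per_modality=3,
        n_regions=3,
        region_shape=(10, 9, 8),
        modality_coverage={"snp": 0.3, "imaging": 1.0},
        effect_size=1.5,
        seed=7,
    )
    return generate_cohort(spec)
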