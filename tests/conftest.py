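import pytest

from metgate import (
    CohortConfig,
    GCNProfile,
    MetStatus,
    from_matrix,
    published_model,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def model():
    return published_model()


@pytest.fixture(scope="session")
def study_confusion():
    """The 3x3 FISH-vs-NGS matrix implied by the reported per-class metrics.

    Diagonal (12, 6, 53) follows from sensitivities (85.7%, 37.5%, 80.3%)
    times FISH class sizes (14, 16, 66); off-diagonals complete the rows
    consistently with the reported specificities.
    """
    return from_matrix([[12, 2, 0], [2, 6, 8], [3, 10, 53]])


def profile(sample_id="s", **gcn):
    return GCNProfile(sample_id=sample_id, gcn=gcn)


@pytest.fixture(scope="session")
def separable_cohort():
    """Tiny noise-free cohort: 2 focal amplifications, 2 polysomies, 3 negatives."""
    profiles = [
        profile("amp1", MET=8, EGFR=2, BRAF=2, CDK6=2, PMS2=2, ABCB1=2, CYP3A4=2),
        profile("amp2", MET=12, EGFR=3, BRAF=3, CDK6=3, PMS2=3, ABCB1=3, CYP3A4=3),
        profile("poly1", MET=5, EGFR=5, BRAF=5, CDK6=5, PMS2=5, ABCB1=5, CYP3A4=5),
        profile("poly2", MET=6, EGFR=6, BRAF=6, CDK6=6, PMS2=6, ABCB1=6, CYP3A4=6),
        profile("neg1", MET=2, EGFR=2, BRAF=2, CDK6=2, PMS2=2, ABCB1=2, CYP3A4=2),
        profile("neg2", MET=2.1, EGFR=2, BRAF=2, CDK6=2, PMS2=2, ABCB1=2, CYP3A4=2),
        profile("neg3", MET=1.8, EGFR=2, BRAF=2, CDK6=2, PMS2=2, ABCB1=2, CYP3A4=2),
    ]
    labels = [
        MetStatus.AMPLIFICATION, MetStatus.AMPLIFICATION,
        MetStatus.POLYSOMY, MetStatus.POLYSOMY,
        MetStatus.NEGATIVE, MetStatus.NEGATIVE, MetStatus.NEGATIVE,
    ]
    return profiles, labels


@pytest.fixture(scope="session")
def zero_noise_cohort():
    """Noise-free, purity-1 cohort with whole-chromosome gains >= 5 copies."""
    config = CohortConfig(
        n=300, gcn_noise_sd=0.0, purity_range=(1.0, 1.0), polysomy_range=(5, 6), seed=7
    )
    return simulate_cohort(config)
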