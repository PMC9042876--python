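import numpy as np
import pytest

import mirdrugsurv as mds

try:
    from hypothesis import settings

    settings.register_profile("ci", deadline=None, derandomize=True)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass


@pytest.fixture(scope="session")
def demo_cohort():
    """Small deterministic cohort with one strong planted marker and one
    inhibitory target gene, reused across tests."""
    cfg = mds.SimConfig(
        n_cancer_types=2,
        patients_per_cancer=300,
        drugs_per_cancer=2,
        drug_exposure_prob=0.15,
        n_mirnas=30,
        n_genes=25,
        planted_markers=[
            mds.PlantedMarker("CT1", "drugA", "mir-plant-1", 6.0, ("gene-plant-1",))
        ],
        censoring_rate=1.0 / 20000.0,
        seed=2025,
    )
    return cfg, mds.generate_cohort(cfg)


@pytest.fixture(scope="session")
def demo_screen(demo_cohort):
    """Thresholds, groups and the full miRNA screen on the demo cohort."""
    _, cohort = demo_cohort
    thresholds = mds.fit_all_thresholds(cohort.mirna)
    groups = mds.build_groups(cohort.clinical, cohort.drugs, cohort.mirna)
    clinical_by_id = {r.patient_id: r for r in cohort.clinical}
    results = []
    for g in groups:
        results.extend(
            mds.screen_group(g, cohort.mirna, thresholds, clinical_by_id)
        )
    results = mds.drug_specific_filter(
        results, cohort.clinical, cohort.mirna, thresholds
    )
    return {
        "cohort": cohort,
        "thresholds": thresholds,
        "groups": groups,
        "clinical_by_id": clinical_by_id,
        "results": results,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
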