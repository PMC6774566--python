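"""Shared fixtures: one synthetic cohort and pipeline run per session."""

import pytest

from germfuse.pipeline import PhenotypeConfig, PipelineConfig, run_pipeline
from germfuse.simulate import SimConfig, simulate_cohort

COHORT_SEED = 7


@pytest.fixture(scope="session")
def cohort():
    return simulate_cohort(SimConfig(seed=COHORT_SEED))


@pytest.fixture(scope="session")
def pipeline_result(cohort):
    ph = cohort.phenotype
    config = PipelineConfig(
        per_patient=cohort.patients,
        index=cohort.reference.index,
        hits=cohort.hits,
        control_sets=cohort.control_sets,
        homologs=cohort.reference.homologs,
        phenotype=PhenotypeConfig(
            ontology=ph.ontology(),
            gene_terms_table=ph.gene_terms,
            patient_terms=ph.patient_terms,
            cutoff=0.05,
        ),
    )
    return run_pipeline(config)


@pytest.fixture(scope="session")
def reference(cohort):
    return cohort.reference


@pytest.fixture(scope="session")
def gene_index(reference):
    return reference.index
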