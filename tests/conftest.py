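import numpy as np
import pandas as pd
import pytest

from luscage import SimulationConfig, default_catalog, simulate_cohort, simulate_maf
from luscage.maf import MutationRecord


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture(scope="session")
def small_cohort(catalog, tmp_path_factory):
    """A 25-patient synthetic cohort with its MAF written to disk."""
    config = SimulationConfig(n_patients=25, seed=11)
    clinical, truth = simulate_cohort(config)
    maf = simulate_maf(clinical, truth, catalog, config)
    path = tmp_path_factory.mktemp("cohort") / "mutations.maf"
    maf.to_csv(path, sep="\t", index=False)
    return {"config": config, "clinical": clinical, "truth": truth,
            "maf_frame": maf, "maf_path": path}


def make_record(
    patient="TCGA-AA-0001",
    sample=None,
    genes=("GENE1",),
    chrom="1",
    pos=100,
    ref="C",
    alt="T",
    context="ACGTACTGCAT",
    classification="Missense_Mutation",
    vtype="SNP",
):
    """Hand-built MutationRecord with a repeat-clean default context (center C)."""
    return MutationRecord(
        patient_id=patient,
        sample_id=sample or f"{patient}-01A",
        genes=frozenset(genes),
        chrom=chrom,
        pos=pos,
        ref_allele=ref,
        alt_allele=alt,
        ref_context=context,
        variant_classification=classification,
        variant_type=vtype,
    )


@pytest.fixture
def record_factory():
    return make_record
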