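import numpy as np
import pandas as pd
import pytest

import micromet as mm


@pytest.fixture(scope="session")
def cohort():
    """One default synthetic cohort shared across read-only tests."""
    cfg = mm.SynthConfig(seed=42)
    counts, raw, cov, truth = mm.generate_cohort(cfg)
    return {"config": cfg, "counts": counts, "raw": raw, "cov": cov, "truth": truth}


@pytest.fixture(scope="session")
def processed(cohort):
    """Profiled species matrix, processed metabolites and model matrix."""
    percent = mm.profile_relative_abundance(cohort["counts"])
    species_log = mm.filter_and_transform_species(percent, min_nonzero=100)
    mets = mm.process_metabolites(cohort["raw"], min_measured=100)
    Z = mm.build_model_matrix(cohort["cov"])
    return {"percent": percent, "species_log": species_log, "mets": mets, "Z": Z}


def toy_counts(counts_matrix, species_of_gene, lengths, samples=None):
    """Small SignatureGeneCounts fixture from explicit arrays."""
    counts_matrix = np.asarray(counts_matrix)
    genes = [f"g{i}" for i in range(counts_matrix.shape[1])]
    samples = samples or [f"s{i}" for i in range(counts_matrix.shape[0])]
    return mm.SignatureGeneCounts(
        counts=pd.DataFrame(counts_matrix, index=samples, columns=genes),
        gene_meta=pd.DataFrame(
            {"species_id": species_of_gene, "effective_length": lengths},
            index=pd.Index(genes, name="gene_id"),
        ),
    )
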