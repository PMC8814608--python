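import numpy as np
import pandas as pd
import pytest

from mutscape import (
    SimulationConfig, simulate_cohort, simulate_binding_table,
    cohort_from_simulation, default_signatures,
)

MAF_HEADER = [
    "Hugo_Symbol", "Chromosome", "Start_Position", "Reference_Allele",
    "Tumor_Seq_Allele2", "Variant_Classification", "Variant_Type",
    "Tumor_Sample_Barcode", "Context_5prime", "Context_3prime",
]


def write_maf(path, rows):
    """Write MAF rows (tuples in MAF_HEADER order) to a TSV file."""
    pd.DataFrame(rows, columns=MAF_HEADER).to_csv(path, sep="\t", index=False)
    return path


@pytest.fixture
def toy_maf(tmp_path):
    rows = [
        ("TP53", "17", 7577120, "C", "T", "Missense_Mutation", "SNP", "P1", "AC", "GA"),
        ("TTN", "2", 1000, "G", "A", "Silent", "SNP", "P1", "TT", "CC"),
        ("ZNF750", "17", 500, "AG", "-", "Frame_Shift_Del", "DEL", "P2", "TTTTT", "CACAC"),
    ]
    return write_maf(tmp_path / "toy.maf", rows)


@pytest.fixture(scope="session")
def sim_small():
    """A 40-sample synthetic cohort shared across read-only tests."""
    config = SimulationConfig(n_samples=40, seed=11)
    maf, clinical, truth = simulate_cohort(config)
    cohort = cohort_from_simulation(maf, clinical)
    return {"config": config, "maf": maf, "clinical": clinical,
            "truth": truth, "cohort": cohort}


@pytest.fixture(scope="session")
def sim_binding(sim_small):
    table, truth = simulate_binding_table(sim_small["config"], sim_small["cohort"])
    return {"table": table, "truth": truth}


@pytest.fixture(scope="session")
def planted_catalog():
    """50 samples x 2000 mutations drawn from two disjoint-support signatures."""
    rng = np.random.default_rng(42)
    sigs = default_signatures()
    P = sigs.to_numpy().T
    n = 50
    mixture = rng.dirichlet([1.0, 1.0], n)
    X = np.vstack([rng.multinomial(2000, mixture[i] @ P) for i in range(n)])
    catalog = pd.DataFrame(X, columns=sigs.index,
                           index=[f"S{i:03d}" for i in range(n)])
    return {"catalog": catalog, "signatures": sigs, "mixture": mixture}
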