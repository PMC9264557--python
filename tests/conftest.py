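import numpy as np
import pandas as pd
import pytest

from irgp import SimulationConfig
from irgp.datatypes import ClinicalTable, ExpressionMatrix
from irgp.io import load_packaged_signature
from irgp.maf import MafRecord
from irgp.simulate import default_planted_pairs, simulate_cohort


@pytest.fixture(scope="session")
def sig17():
    """The packaged 17-pair signature."""
    return load_packaged_signature()


@pytest.fixture()
def toy_expression():
    """3 genes x 4 samples, 2 tumor + 2 normal, handcrafted values."""
    values = pd.DataFrame(
        [[10.0, 30.0, 5.0, 8.0],
         [30.0, 10.0, 6.0, 6.0],
         [60.0, 60.0, 7.0, 4.0]],
        index=["GA", "GB", "GC"], columns=["T1", "T2", "N1", "N2"])
    group = pd.Series(["tumor", "tumor", "normal", "normal"],
                      index=values.columns)
    return ExpressionMatrix(values, group)


@pytest.fixture()
def toy_clinical():
    data = pd.DataFrame(
        {"time": [100.0, 400.0, 250.0, 800.0, 90.0, 600.0],
         "event": [1, 0, 1, 1, 0, 0],
         "age": [60, 70, 55, 65, 72, 58],
         "gender": ["male", "female", "male", "male", "female", "male"],
         "grade": [2, 3, 1, 4, 2, 3],
         "stage": [1, 3, 2, 4, 2, 1],
         "t_stage": [1, 2, 2, 3, 1, 2],
         "n_stage": [0, 1, 0, 2, 1, 0]},
        index=pd.Index([f"S{i}" for i in range(6)], name="sample_id"))
    return ClinicalTable(data)


@pytest.fixture(scope="session")
def planted_cohort():
    """A small cohort with 3 planted pairs, shared across tests."""
    base = SimulationConfig(n_tumor=160, n_normal=20, n_genes=120,
                            immune_fraction=0.5, n_de_genes=12, seed=11)
    cfg = SimulationConfig(n_tumor=160, n_normal=20, n_genes=120,
                           immune_fraction=0.5, n_de_genes=12, seed=11,
                           planted_pairs=default_planted_pairs(base, 3,
                                                               beta=1.2))
    em, clinical, truth, maf = simulate_cohort(cfg)
    return cfg, em, clinical, truth, maf


@pytest.fixture()
def toy_maf_records():
    """10 records whose every summary field is hand-countable."""
    rows = [
        ("TNC", "S1", "Missense_Mutation", "SNP", "C", "T"),
        ("TNC", "S1", "Nonsense_Mutation", "SNP", "G", "A"),
        ("TNC", "S2", "Missense_Mutation", "SNP", "A", "C"),
        ("SPP1", "S2", "Splice_Site", "SNP", "T", "A"),
        ("SPP1", "S3", "Missense_Mutation", "SNP", "G", "C"),
        ("PLAU", "S3", "Frame_Shift_Del", "DEL", "A", "-"),
        ("DEFB1", "S4", "Missense_Mutation", "SNP", "C", "A"),
        ("MMP9", "S4", "Silent", "SNP", "T", "C"),
        ("TNC", "S5", "Missense_Mutation", "SNP", "G", "T"),
        ("IL1A", "S1", "In_Frame_Del", "DEL", "TTG", "-"),
    ]
    return [MafRecord(*r) for r in rows]


@pytest.fixture()
def survival_20():
    """A 20-sample survival fixture with tied event times."""
    rng = np.random.default_rng(3)
    X = rng.normal(size=(20, 2))
    t = np.ceil(rng.exponential(1 / (0.02 * np.exp(0.8 * X[:, 0]
                                                   - 0.5 * X[:, 1]))) / 10)
    t = np.clip(t, 1, None) * 10.0
    e = (rng.random(20) < 0.7).astype(int)
    return X, t, e
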