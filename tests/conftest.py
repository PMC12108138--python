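import numpy as np
import pandas as pd

from stabprs import GenotypeMatrix, PhenotypeTable


def make_genotypes(dosage, chrom=None, pos=None, info=None, ids=None,
                   effect=None, other=None, samples=None) -> GenotypeMatrix:
    """Hand-built genotype matrix for unit tests."""
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    return GenotypeMatrix(
        dosage=dosage,
        samples=np.array([f"s{i}" for i in range(n)]) if samples is None else np.asarray(samples),
        variants=pd.DataFrame(
            {
                "id": [f"v{j}" for j in range(m)] if ids is None else list(ids),
                "chrom": ["1"] * m if chrom is None else list(chrom),
                "pos": list(range(1000, 1000 + m)) if pos is None else list(pos),
                "effect_allele": ["A"] * m if effect is None else list(effect),
                "other_allele": ["G"] * m if other is None else list(other),
                "info": [1.0] * m if info is None else list(info),
            }
        ),
    )


def make_phenotypes(samples, height, sex=None, age=None, **extra) -> PhenotypeTable:
    n = len(samples)
    rng = np.random.default_rng(0)
    data = {
        "sample_id": list(samples),
        "height_cm": np.asarray(height, dtype=float),
        "sex": (np.arange(n) % 2) if sex is None else np.asarray(sex),
        "age_years": rng.uniform(30, 80, n) if age is None else np.asarray(age, dtype=float),
        "weight_kg": np.full(n, 75.0),
        "bmi": np.full(n, 27.0),
        "sbp": 120 + rng.standard_normal(n),
        "dbp": 80 + rng.standard_normal(n),
        "antihtn": np.zeros(n, dtype=int),
    }
    data.update(extra)
    return PhenotypeTable(pd.DataFrame(data))
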