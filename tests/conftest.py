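import numpy as np
import pandas as pd
import pytest

from teaheterosis import ExpressionMatrix, VolatileTable
from teaheterosis.patterns import ROLES

# Published per-compound mean concentrations (ng/g) for the four genotypes
# of the HD x TGY cross.  Order: (HGY, JGY, TGY, HD).
TABLE1_MEANS = {
    "GLV": {
        "Hexanal": (56.1, 91.4, 43.92, 42.33),
        "(E)-2-Hexenal": (72.5, 225.95, 127.13, 60.23),
        "(E)-3-Hexen-1-ol": (92.84, 80.86, 77.22, 84.44),
        "(Z)-2-Hexen-1-ol": (10.66, 13.78, 5.83, 3.28),
        "1-Hexanol": (84.97, 69.65, 33.79, 27.11),
        "(Z)-3-Hexen-1-ol acetate": (116.31, 102.98, 115.78, 66.79),
    },
    "monoterpene": {
        "Linalool oxide 1": (289.92, 284.78, 115.73, 190.75),
        "Linalool oxide 2": (509.3, 287.01, 241.48, 116.86),
        "Linalool": (387.86, 447.12, 222.01, 310.64),
        "beta-Cyclocitral": (11.72, 4.15, 3.55, 2.34),
        "cis-Citral": (8.83, 20.42, 8.31, 2.97),
        "(Z)-Geraniol": (4.88, 6.75, 7.69, 32.9),
        "Geraniol": (288.28, 505.67, 164.19, 257.69),
    },
    "sesquiterpene": {
        "Germacrene D": (5.49, 1.27, 0.34, 0.47),
        "Germacrene B": (6.14, 1.47, 1.39, 1.02),
        "alpha-Farnesene": (0.0, 7.5, 0.0, 0.0),
        "Cubenene": (10.21, 0.0, 6.4, 0.0),
        "Nerolidol 2": (20.74, 14.74, 14.15, 14.69),
    },
}

# Published class sums (ng/g), same genotype order, used as trait inputs for
# the heterosis indices.
TABLE1_SUMS = {
    "GLV": (432.93, 584.62, 400.67, 284.18),
    "monoterpene": (1500.79, 1555.90, 766.43, 916.7),
    "sesquiterpene": (42.58, 24.98, 22.28, 16.18),
}

GENOTYPES = ("HGY", "JGY", "TGY", "HD")


@pytest.fixture(scope="session")
def table1() -> VolatileTable:
    """The published compound means as a single-replicate volatile table."""
    rows = []
    for cls, compounds in TABLE1_MEANS.items():
        for compound, means in compounds.items():
            for genotype, mean in zip(GENOTYPES, means):
                rows.append(
                    {
                        "compound": compound,
                        "compound_class": cls,
                        "genotype": genotype,
                        "replicate": 1,
                        "concentration": mean,
                    }
                )
    return VolatileTable(pd.DataFrame(rows))


def matrix_from_means(
    means: dict[str, tuple[float, float, float, float]],
    n_replicates: int = 3,
    cv: float = 0.0,
    seed: int = 0,
) -> ExpressionMatrix:
    """Build an ExpressionMatrix from per-gene (p1, p2, h1, h2) means."""
    rng = np.random.default_rng(seed)
    sample_ids = [f"{r}_r{i + 1}" for r in ROLES for i in range(n_replicates)]
    rows = {}
    for gene, group_means in means.items():
        per_sample = np.repeat(np.asarray(group_means, float), n_replicates)
        if cv > 0:
            sigma2 = np.log1p(cv * cv)
            per_sample = per_sample * np.exp(
                rng.normal(-sigma2 / 2, np.sqrt(sigma2), per_sample.shape)
            )
        rows[gene] = per_sample
    values = pd.DataFrame.from_dict(rows, orient="index", columns=sample_ids)
    design = pd.DataFrame(
        {
            "genotype_role": [r for r in ROLES for _ in range(n_replicates)],
            "replicate": [i + 1 for _ in ROLES for i in range(n_replicates)],
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return ExpressionMatrix(values=values, design=design)


@pytest.fixture()
def tiny_matrix() -> ExpressionMatrix:
    """Four noise-free genes, one per broad category."""
    return matrix_from_means(
        {
            "g_c9": (10.0, 10.0, 40.0, 40.0),   # hybrids above both parents
            "g_c5": (40.0, 10.0, 40.0, 40.0),   # hybrids at the high parent
            "g_c1": (640.0, 10.0, 160.0, 40.0), # hybrids between parents
            "g_none": (10.0, 10.0, 10.0, 10.0),
        }
    )
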