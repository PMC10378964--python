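import numpy as np
import pandas as pd
import pytest

from spastigen.kinship import Pedigree
from spastigen.sim import SimConfig, _polygenic_cascade, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Desk-scale cohort reused across read-only tests."""
    cfg = SimConfig(n_chromosomes=3, snps_per_chromosome=150,
                    chromosome_length_bp=30_000_000, n_qtl=2,
                    qtl_effect_sd=0.5, missing_rate=0.01, seed=42)
    return simulate_cohort(cfg)


def make_halfsib_cohort(n_fam: int, dams_per_sire: int, h2: float,
                        prevalence: float, seed: int):
    """Paternal half-sib cohort with liability-threshold statuses.

    One offspring per (sire, dam) mating; only offspring are phenotyped.
    Returns (pedigree, status frame).
    """
    rng = np.random.default_rng(seed)
    animal, sire, dam = [], [], []
    for s in range(n_fam):
        animal.append(f"S{s}"); sire.append("0"); dam.append("0")
    for s in range(n_fam):
        for d in range(dams_per_sire):
            animal.append(f"D{s}_{d}"); sire.append("0"); dam.append("0")
    offspring = []
    for s in range(n_fam):
        for d in range(dams_per_sire):
            aid = f"O{s}_{d}"
            animal.append(aid); sire.append(f"S{s}"); dam.append(f"D{s}_{d}")
            offspring.append(aid)
    ped = Pedigree(animal, sire, dam)
    s2u = h2 / (1.0 - h2)
    u = _polygenic_cascade(ped, s2u, rng)
    by_id = dict(zip(ped.animal, u))
    liab = np.array([by_id[a] for a in offspring]) \
        + rng.normal(0.0, 1.0, len(offspring))
    thr = np.quantile(liab, 1.0 - prevalence)
    status = pd.DataFrame({"animal": offspring,
                           "status": (liab > thr).astype(int)})
    return ped, status
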