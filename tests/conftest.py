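import numpy as np
import pytest

from msatpop.core import MISSING, GenotypeMatrix
from msatpop.simulate import SimConfig, simulate_island


def make_matrix(pop_genotypes, loci=None, prefix="S"):
    """Build a GenotypeMatrix from per-subsample genotype lists.

    ``pop_genotypes`` is a list (one entry per subsample) of lists of
    per-locus genotype tuples: pop -> individual -> locus -> (a1, a2).
    Use (None, None) or MISSING for blanks.
    """
    n_loci = len(pop_genotypes[0][0])
    loci = loci or [f"L{j + 1}" for j in range(n_loci)]
    individuals, groups, rows = [], {}, []
    for g, pop in enumerate(pop_genotypes):
        label = f"{prefix}{g + 1}"
        for i, geno in enumerate(pop):
            uid = f"{label}_{i + 1}"
            individuals.append(uid)
            groups[uid] = (label, label, label)
            row = []
            for pair in geno:
                if pair is None or pair[0] is None:
                    row.append((MISSING, MISSING))
                else:
                    row.append((min(pair), max(pair)))
            rows.append(row)
    calls = np.array(rows, dtype=np.int64)
    return GenotypeMatrix(individuals, loci, calls, groups)


def island(seed, sizes=(30, 30, 30), n_loci=5, fst=0.10, **kw):
    """Convenience island-model draw with flat site/country labels."""
    k = len(sizes)
    cfg = SimConfig(subsample_sizes=tuple(sizes), n_loci=n_loci,
                    target_fst=fst, seed=seed,
                    sites=tuple(f"site{i}" for i in range(k)),
                    countries=tuple(f"c{i % 2}" for i in range(k)), **kw)
    return simulate_island(cfg)


@pytest.fixture
def small_matrix():
    """Two subsamples, one locus, fully typed."""
    return make_matrix([
        [[(100, 100)], [(100, 102)], [(102, 102)], [(100, 102)]],
        [[(100, 102)], [(102, 104)], [(104, 104)], [(100, 104)]],
    ])


@pytest.fixture
def study_matrix():
    from msatpop.simulate import simulate_study, study_config

    m, truth = simulate_study(study_config(seed=42))
    return m, truth
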