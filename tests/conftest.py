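import itertools
from collections import Counter

import numpy as np
import pytest

from circaparam.config import SimulationConfig
from circaparam.simulate import generate_dataset


def enumerate_kendall_null(group_sizes):
    """Brute-force null of Kendall S against a reference with tied groups.

    Enumerates all permutations of the data ranks; pairs tied in the
    reference contribute nothing.  Independent oracle for the
    generating-function construction.
    """
    ref = [g for g, size in enumerate(group_sizes) for _ in range(size)]
    n = len(ref)
    counts = Counter()
    for perm in itertools.permutations(range(n)):
        s = 0
        for i in range(n):
            for j in range(i + 1, n):
                if ref[i] != ref[j]:
                    s += int(np.sign(perm[j] - perm[i]))
        counts[s] += 1
    total = sum(counts.values())
    return {s: c / total for s, c in counts.items()}


@pytest.fixture(scope="session")
def cosine_benchmark():
    """200 planted cosine genes (amplitude ratio 2-5, noise 0.05) among 800
    flat genes, 48 hourly timepoints, one probe per locus, fixed seed."""
    config = SimulationConfig(
        n_loci=1_000,
        probes_per_locus_range=(1, 1),
        rhythmic_fraction=0.2,
        waveform_mix={"cosine": 1.0},
        noise_sd=0.05,
        seed=101,
    )
    return generate_dataset(config)


@pytest.fixture(scope="session")
def noncosine_benchmark():
    """Planted spike/box genes for the non-cosine rescue check."""
    config = SimulationConfig(
        n_loci=1_000,
        probes_per_locus_range=(1, 1),
        rhythmic_fraction=0.2,
        waveform_mix={"spike": 0.5, "box": 0.5},
        noise_sd=0.05,
        seed=202,
    )
    return generate_dataset(config)


@pytest.fixture(scope="session")
def jtk_on_cosine_benchmark(cosine_benchmark):
    from circaparam.rhythm import jtk_scan

    return jtk_scan(cosine_benchmark.timecourse)
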