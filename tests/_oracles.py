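"""Independent oracles used by the test suite (msprime-backed simulator)."""

from __future__ import annotations

import numpy as np

TRANSITION_MATRIX = [
    [0.0, 0.0, 1.0, 0.0],  # A -> G
    [0.0, 0.0, 0.0, 1.0],  # C -> T
    [1.0, 0.0, 0.0, 0.0],  # G -> A
    [0.0, 1.0, 0.0, 0.0],  # T -> C
]


def msprime_replicate(model, mutation, seed):
    """Simulate one replicate of a DemographicModel with msprime.

    Haploid samples (pair coalescence rate 1/Ne with ploidy=1 and
    initial_size=Ne); divergences and pulses become backward-time mass
    migrations; the finite-sites transition-only mutation model mirrors the
    package's scheme.  Returns {"deme@age": genotype matrix} where columns
    are sites carrying at least one mutation (equal elsewhere).
    """
    import msprime

    g = model.generation_time
    dem = msprime.Demography()
    for name, ne in model.demes.items():
        dem.add_population(name=name, initial_size=ne)
    events = []
    for ev in model.pulses:
        events.append((ev.age / g, 0, "pulse", ev))
    for ev in model.divergences:
        events.append((ev.age / g, 1, "div", ev))
    for t, _, kind, ev in sorted(events, key=lambda e: (e[0], e[1])):
        if kind == "pulse":
            dem.add_mass_migration(
                time=t, source=ev.sink, dest=ev.source, proportion=ev.proportion
            )
        else:
            dem.add_mass_migration(
                time=t, source=ev.child, dest=ev.parent, proportion=1.0
            )
    dem.sort_events()
    samples = [
        msprime.SampleSet(ev.n, population=ev.deme, time=ev.age / g, ploidy=1)
        for ev in model.sampling
    ]
    ts = msprime.sim_ancestry(
        samples=samples,
        demography=dem,
        sequence_length=mutation.length,
        ploidy=1,
        random_seed=seed % (2**31 - 2) + 1,
    )
    mut_model = msprime.MatrixMutationModel(
        alleles=["A", "C", "G", "T"],
        root_distribution=[0.25, 0.25, 0.25, 0.25],
        transition_matrix=TRANSITION_MATRIX,
    )
    mts = msprime.sim_mutations(
        ts,
        rate=mutation.rate * g,
        model=mut_model,
        random_seed=seed % (2**31 - 2) + 1,
    )
    geno = mts.genotype_matrix().T  # samples x segregating sites
    out = {}
    offset = 0
    for ev in model.sampling:
        key = f"{ev.deme}@{ev.age:g}"
        out[key] = geno[offset:offset + ev.n]
        offset += ev.n
    return out


def pop_pi_and_s(x: np.ndarray) -> tuple[float, int]:
    """Mean pairwise differences and segregating sites of a genotype/code
    matrix (samples x sites)."""
    n = x.shape[0]
    if n < 2:
        return 0.0, 0
    d = (x[:, None, :] != x[None, :, :]).sum(-1)
    pi = d[np.triu_indices(n, 1)].mean()
    s = int((x != x[0]).any(axis=0).sum())
    return float(pi), s
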