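"""Synthetic multi-population HVS-I datasets for end-to-end exercises.

Scenario datasets are simulated under one of the registry's demographic
models, anchored on the packaged 334-bp reference so that motif notation,
haplogroup calling and network construction operate identically on real
and synthetic data.  Default scenario parameters are the study's posterior
means (a convenient, documented operating point - not ground truth).

Null datasets (one panmictic deme arbitrarily split into two labelled
populations) calibrate the PhiST permutation test: their true PhiST is 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .coalsim import (
    DEFAULT_PRIOR,
    DemographicModel,
    MutationModel,
    SamplingEvent,
    decode_sequences,
    model_registry,
    simulate_arrays,
)
from .core import (
    EMPTY_MOTIF,
    HVS1_LENGTH,
    HVS1_WINDOW,
    PopulationDataset,
    Sample,
    SequenceBlock,
    load_reference,
    sequence_to_motif,
    write_dataset,
    write_fasta,
)

__all__ = [
    "ScenarioConfig",
    "DEFAULT_SCENARIO_PARAMS",
    "make_scenario",
    "make_null_pair",
    "write_scenario",
    "read_manifest",
]

#: Study posterior means used as the default scenario operating point.
DEFAULT_SCENARIO_PARAMS = {
    "N_MOGOU": 799.0,
    "N_HENGBEI": 1489.0,
    "N_HAN": 657.0,
    "T1": 5472.0,
    "T2": 3505.0,
    "a": 0.146,
}


@dataclass
class ScenarioConfig:
    """A fully specified simulation scenario."""

    model: str = "model1"
    params: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SCENARIO_PARAMS)
    )
    sample_sizes: tuple[int, int, int] = (46, 64, 521)
    mutation: MutationModel = field(default_factory=MutationModel)
    seed: int = 0

    def __post_init__(self) -> None:
        for name, value in self.params.items():
            lo, hi = DEFAULT_PRIOR.bounds.get(name, (-np.inf, np.inf))
            if not lo <= value <= hi:
                raise ValueError(
                    f"scenario parameter {name}={value} outside the prior "
                    f"support [{lo}, {hi}]"
                )


def make_scenario(
    config: ScenarioConfig,
) -> tuple[PopulationDataset, dict[str, SequenceBlock], dict]:
    """Simulate a scenario and package it as a full dataset.

    Returns the dataset (samples carry motifs relative to the packaged
    reference, synthetic IDs and singleton graves), the per-population
    sequence blocks, and a truth manifest with the generating parameters
    and genealogy summaries.
    """
    registry = model_registry(config.sample_sizes)
    if config.model not in registry:
        raise ValueError(f"unknown model {config.model!r}")
    template = registry[config.model]
    missing = [p for p in template.parameters if p not in config.params]
    if missing:
        raise ValueError(f"scenario missing parameters: {missing}")
    model = template.build(config.params)
    model.validate()
    reference = load_reference()[: config.mutation.length]
    rng = np.random.default_rng(config.seed)
    arrays, tmrca, total_bl = simulate_arrays(
        model, config.mutation, rng, reference
    )
    window = HVS1_WINDOW if config.mutation.length == HVS1_LENGTH else (
        1,
        config.mutation.length,
    )

    samples: list[Sample] = []
    blocks: dict[str, SequenceBlock] = {}
    populations: dict[str, int] = {}
    hap_ids: dict[str, str] = {}
    ages = {ev.deme: int(ev.age) for ev in model.sampling}
    for key, arr in arrays.items():
        deme = key.split("@")[0]
        populations[deme] = ages[deme]
        seqs = decode_sequences(arr)
        labels = []
        for i, seq in enumerate(seqs):
            sid = f"SYN-{deme}-{i + 1:03d}"
            labels.append(sid)
            if seq not in hap_ids:
                hap_ids[seq] = f"sht{len(hap_ids) + 1}"
            motif = (
                sequence_to_motif(seq, reference)
                if config.mutation.length == HVS1_LENGTH
                else EMPTY_MOTIF
            )
            samples.append(
                Sample(
                    sample_id=sid,
                    population=deme,
                    motif=motif,
                    grave_id=f"GRV-{sid}",
                    sampling_age=ages[deme],
                    haplotype_id=hap_ids[seq],
                )
            )
        blocks[deme] = SequenceBlock(labels=labels, sequences=seqs, window=window)

    manifest = {
        "model": config.model,
        "params": {k: float(v) for k, v in config.params.items()},
        "sample_sizes": list(config.sample_sizes),
        "mutation_rate": config.mutation.rate,
        "sequence_length": config.mutation.length,
        "seed": config.seed,
        "tmrca_generations": tmrca,
        "total_branch_length_generations": total_bl,
        "n_haplotypes": len(hap_ids),
    }
    return PopulationDataset(samples, populations), blocks, manifest


def make_null_pair(
    n_per_pop: int,
    length: int = 100,
    theta: float = 5.0,
    seed: int | None = None,
) -> tuple[SequenceBlock, SequenceBlock]:
    """Two labelled populations drawn from one panmictic deme.

    ``theta`` is the expected mean pairwise difference per locus
    (2 * Ne * mu_gen * L); the split is arbitrary, so the true PhiST is 0.
    """
    if n_per_pop < 2:
        raise ValueError("need at least 2 sequences per population")
    mutation = MutationModel(length=length)
    mu_gen = mutation.rate * 25.0
    ne = theta / (2.0 * mu_gen * length)
    model = DemographicModel(
        demes={"null": ne},
        sampling=[SamplingEvent("null", 0.0, 2 * n_per_pop)],
        generation_time=25.0,
        label="null",
    )
    reference = load_reference()[:length]
    arrays, _, _ = simulate_arrays(
        model, mutation, np.random.default_rng(seed), reference
    )
    seqs = decode_sequences(arrays["null@0"])
    window = (1, length)
    return (
        SequenceBlock(
            labels=[f"A_{i}" for i in range(n_per_pop)],
            sequences=seqs[:n_per_pop],
            window=window,
        ),
        SequenceBlock(
            labels=[f"B_{i}" for i in range(n_per_pop)],
            sequences=seqs[n_per_pop:],
            window=window,
        ),
    )


def write_scenario(
    dataset: PopulationDataset,
    blocks: Mapping[str, SequenceBlock],
    manifest: dict,
    out_dir: str | Path,
) -> None:
    """Emit the dataset table, per-population FASTA and the truth manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_dataset(dataset, out / "samples.tsv")
    for name, block in blocks.items():
        write_fasta(block, out / f"{name}.fasta")
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_manifest(path: str | Path) -> dict:
    with open(Path(path)) as fh:
        return json.load(fh)
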