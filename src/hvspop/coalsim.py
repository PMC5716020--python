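"""Serial-sampling structured coalescent simulator for haploid mtDNA data.

Demographic models are sets of constant-size haploid demes with three kinds
of events, all dated in years BP at the interface and converted once to
generations internally:

* sampling events — n lineages enter the process in a deme at their age
  (serial sampling: a 4000-yr-BP sample joins the genealogy 4000/g
  generations in the past);
* admixture pulses — one-generation events in which, backward in time, each
  lineage in the *sink* deme moves to the *source* deme with probability a
  (forward in time: a fraction a of the sink derives from the source);
* divergences — backward in time, all lineages of the child deme move into
  the parent deme.

Within a deme of haploid size Ne each lineage pair coalesces at rate 1/Ne
per generation, so k lineages coalesce at rate k(k-1)/(2 Ne).  Mutations
are dropped on branches as a Poisson process (rate mu * L per year
equivalent) under a finite-sites, transition-only scheme (matching HVS-I
hypermutability; multiple hits allowed) and sequences are propagated from
a root sequence (the packaged HVS-I reference by default).

The four study demographic scenarios relating the Mogou (sampled ~4000 yr
BP), Hengbei (~3000 yr BP) and present-day Northern Han populations are
provided by :func:`model_registry`; their free parameters (three haploid
sizes, divergence time T1, admixture/origin time T2 and admixture
proportion a) are drawn from uniform priors via :func:`draw_from_prior`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .core import HVS1_LENGTH, HVS1_WINDOW, SequenceBlock, load_reference

__all__ = [
    "DemographicModel",
    "PriorSpec",
    "MutationModel",
    "SimulationReplicate",
    "ModelTemplate",
    "simulate",
    "simulate_arrays",
    "draw_from_prior",
    "model_registry",
    "DEFAULT_PRIOR",
    "encode_sequence",
    "decode_sequences",
]

#: Default generation time in years (common mtDNA convention; the study
#: does not state one, so it is exposed as configuration).
GENERATION_TIME = 25.0

#: Ancient-DNA-calibrated control-region substitution rate, per site per year.
MUTATION_RATE_PER_YEAR = 9.883e-8

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


def encode_sequence(seq: str) -> np.ndarray:
    """Encode ACGT to uint8 codes 0..3 (transition partner = code ^ 2)."""
    arr = _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if (arr == 255).any():
        raise ValueError("sequence contains non-ACGT characters")
    return arr


def decode_sequences(codes: np.ndarray) -> list[str]:
    return [_BASES[row].tobytes().decode() for row in np.atleast_2d(codes)]


class ModelValidationError(ValueError):
    """The demographic model is internally inconsistent."""


@dataclass(frozen=True)
class SamplingEvent:
    deme: str
    age: float  # years BP
    n: int


@dataclass(frozen=True)
class DivergenceEvent:
    age: float  # years BP
    child: str
    parent: str


@dataclass(frozen=True)
class AdmixturePulse:
    age: float  # years BP
    source: str  # forward-time donor
    sink: str  # forward-time recipient
    proportion: float


@dataclass
class DemographicModel:
    """Constant-size haploid demes with dated sampling/divergence/pulse events."""

    demes: dict[str, float]  # name -> haploid Ne
    sampling: list[SamplingEvent] = field(default_factory=list)
    divergences: list[DivergenceEvent] = field(default_factory=list)
    pulses: list[AdmixturePulse] = field(default_factory=list)
    generation_time: float = GENERATION_TIME
    label: str = "model"

    def divergence_age(self, deme: str) -> float:
        """Age at which ``deme`` merges into its parent (inf for the root)."""
        for ev in self.divergences:
            if ev.child == deme:
                return ev.age
        return float("inf")

    def validate(self) -> None:
        for name, ne in self.demes.items():
            if ne <= 0:
                raise ModelValidationError(f"deme {name}: Ne must be positive")
        for ev in self.sampling:
            if ev.deme not in self.demes:
                raise ModelValidationError(f"sampling in unknown deme {ev.deme}")
            if ev.age >= self.divergence_age(ev.deme):
                raise ModelValidationError(
                    f"deme {ev.deme} sampled at {ev.age} but diverges at "
                    f"{self.divergence_age(ev.deme)}"
                )
        children = [ev.child for ev in self.divergences]
        if len(children) != len(set(children)):
            raise ModelValidationError("a deme diverges more than once")
        for ev in self.divergences:
            if ev.child not in self.demes or ev.parent not in self.demes:
                raise ModelValidationError("divergence names an unknown deme")
            if ev.age >= self.divergence_age(ev.parent):
                raise ModelValidationError(
                    f"parent {ev.parent} is gone before child {ev.child} merges"
                )
        roots = set(self.demes) - set(children)
        if len(roots) != 1:
            raise ModelValidationError(
                f"model must have exactly one root deme, found {sorted(roots)}"
            )
        for ev in self.pulses:
            if not 0 <= ev.proportion <= 1:
                raise ModelValidationError("pulse proportion must be in [0, 1]")
            for deme in (ev.source, ev.sink):
                if deme not in self.demes:
                    raise ModelValidationError(f"pulse names unknown deme {deme}")
                # a pulse at exactly the divergence age is allowed: pulses
                # are processed before divergences at the same instant
                if ev.age > self.divergence_age(deme):
                    raise ModelValidationError(
                        f"pulse at {ev.age} involves {deme}, gone at "
                        f"{self.divergence_age(deme)}"
                    )


@dataclass
class MutationModel:
    """Finite-sites mutation model (transition-only by default)."""

    rate: float = MUTATION_RATE_PER_YEAR  # per site per year
    length: int = HVS1_LENGTH
    scheme: str = "transition"  # or "jc" (equal rates to the 3 other bases)

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError("mutation rate must be nonnegative")
        if self.length < 1:
            raise ValueError("sequence length must be >= 1")
        if self.scheme not in ("transition", "jc"):
            raise ValueError("scheme must be 'transition' or 'jc'")


@dataclass
class SimulationReplicate:
    """One simulated dataset with its genealogy summaries."""

    params: dict[str, float]
    blocks: dict[str, SequenceBlock]
    tmrca: float  # generations
    total_branch_length: float  # generations
    arrays: dict[str, np.ndarray] | None = None


# ---------------------------------------------------------------------------
# core simulation


def _simulate_tree(
    model: DemographicModel, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, dict[str, np.ndarray]]:
    """Run the backward-in-time process; returns (parent, time, tips per
    sampling event key) with times in generations."""
    g = model.generation_time
    events: list[tuple[float, int, object]] = []
    for ev in model.sampling:
        events.append((ev.age / g, 0, ev))
    for ev in model.pulses:
        events.append((ev.age / g, 1, ev))
    for ev in model.divergences:
        events.append((ev.age / g, 2, ev))
    events.sort(key=lambda t: (t[0], t[1]))

    n_tips = sum(ev.n for ev in model.sampling)
    max_nodes = 2 * n_tips  # n_tips leaves + at most n_tips - 1 internal
    parent = np.full(max_nodes, -1, dtype=np.int64)
    time = np.zeros(max_nodes, dtype=float)
    next_node = 0

    lineages: dict[str, list[int]] = {d: [] for d in model.demes}
    tips: dict[str, np.ndarray] = {}
    alive_demes = dict(model.demes)  # deme -> Ne while extant

    t = 0.0
    ei = 0
    n_alive = 0
    while True:
        rates = []
        demes_with_pairs = []
        for deme, lin in lineages.items():
            k = len(lin)
            if k >= 2:
                rates.append(k * (k - 1) / (2.0 * alive_demes[deme]))
                demes_with_pairs.append(deme)
        total_rate = float(sum(rates))
        t_event = events[ei][0] if ei < len(events) else float("inf")

        t_coal = t + rng.exponential(1.0 / total_rate) if total_rate > 0 else float("inf")
        if t_coal < t_event:
            t = t_coal
            u = rng.random() * total_rate
            acc = 0.0
            deme = demes_with_pairs[-1]
            for d, r in zip(demes_with_pairs, rates):
                acc += r
                if u < acc:
                    deme = d
                    break
            lin = lineages[deme]
            i, j = rng.choice(len(lin), size=2, replace=False)
            a, b = lin[i], lin[j]
            node = next_node
            next_node += 1
            parent[a] = parent[b] = node
            time[node] = t
            for idx in sorted((i, j), reverse=True):
                lin.pop(idx)
            lin.append(node)
            n_alive -= 1
            continue

        if ei >= len(events):
            if n_alive <= 1:
                break
            raise ModelValidationError(
                "lineages isolated in disconnected demes with no events left"
            )
        t = t_event
        _, _, ev = events[ei]
        ei += 1
        if isinstance(ev, SamplingEvent):
            ids = np.arange(next_node, next_node + ev.n)
            next_node += ev.n
            time[ids] = t
            lineages[ev.deme].extend(int(i) for i in ids)
            tips[f"{ev.deme}@{ev.age:g}"] = ids
            n_alive += ev.n
        elif isinstance(ev, AdmixturePulse):
            sink = lineages[ev.sink]
            if sink and ev.proportion > 0:
                move = rng.random(len(sink)) < ev.proportion
                stay = [l for l, m in zip(sink, move) if not m]
                moved = [l for l, m in zip(sink, move) if m]
                lineages[ev.sink] = stay
                lineages[ev.source].extend(moved)
        else:  # divergence
            lineages[ev.parent].extend(lineages[ev.child])
            lineages[ev.child] = []
            alive_demes.pop(ev.child, None)
            del lineages[ev.child]

    parent = parent[:next_node]
    time = time[:next_node]
    # leaf ids precede internal nodes of later sampling events; tips gives
    # the authoritative mapping
    return parent, time, tips


def _drop_mutations(
    parent: np.ndarray,
    time: np.ndarray,
    mutation: MutationModel,
    generation_time: float,
    root_codes: np.ndarray,
    rng: np.random.Generator,
    scheme: str,
) -> np.ndarray:
    """Place Poisson mutations on branches and propagate sequences from the
    root; returns the codes array for every node."""
    n_nodes = len(parent)
    L = mutation.length
    rate_per_gen = mutation.rate * generation_time  # per site per generation
    has_parent = parent >= 0
    bl = np.zeros(n_nodes)
    bl[has_parent] = time[parent[has_parent]] - time[has_parent]
    total = bl.sum()
    n_mut = rng.poisson(total * rate_per_gen * L)
    codes = np.empty((n_nodes, L), dtype=np.uint8)

    # assign mutations to branches proportionally to length, sites uniformly
    if n_mut > 0 and total > 0:
        cum = np.cumsum(bl)
        branch = np.searchsorted(cum, rng.random(n_mut) * total, side="right")
        site = rng.integers(0, L, size=n_mut)
        order = np.argsort(branch, kind="stable")
        branch = branch[order]
        site = site[order]
        bounds = np.searchsorted(branch, np.arange(n_nodes + 1))
    else:
        branch = site = np.empty(0, dtype=np.int64)
        bounds = np.zeros(n_nodes + 1, dtype=np.int64)

    order = np.argsort(time)[::-1]  # root (largest time) first
    root = order[0]
    codes[root] = root_codes
    for node in order:
        p = parent[node]
        if p < 0:
            if node != root:  # isolated root of a disconnected piece
                codes[node] = root_codes
            continue
        seq = codes[p].copy()
        lo, hi = bounds[node], bounds[node + 1]
        if hi > lo:
            sites = site[lo:hi]
            if scheme == "transition":
                np.bitwise_xor.at(seq, sites, 2)
            else:  # jc: each hit draws one of the three other bases
                for s in sites:
                    seq[s] = (seq[s] + rng.integers(1, 4)) % 4
        codes[node] = seq
    return codes


def simulate_arrays(
    model: DemographicModel,
    mutation: MutationModel | None = None,
    rng: np.random.Generator | int | None = None,
    reference: str | None = None,
) -> tuple[dict[str, np.ndarray], float, float]:
    """Fast path: simulate and return per-sampling-event uint8 code arrays.

    Returns ``(arrays, tmrca, total_branch_length)`` with arrays keyed by
    ``"deme@age"`` and times in generations.
    """
    if mutation is None:
        mutation = MutationModel()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    model.validate()
    if reference is None:
        reference = load_reference()[: mutation.length]
    root_codes = encode_sequence(reference)
    if len(root_codes) != mutation.length:
        raise ValueError("reference length does not match the mutation model")
    parent, time, tips = _simulate_tree(model, rng)
    has_parent = parent >= 0
    total_bl = float((time[parent[has_parent]] - time[has_parent]).sum())
    codes = _drop_mutations(
        parent, time, mutation, model.generation_time, root_codes, rng,
        mutation.scheme,
    )
    arrays = {key: codes[ids] for key, ids in tips.items()}
    return arrays, float(time.max()), total_bl


def simulate(
    model: DemographicModel,
    mutation: MutationModel | None = None,
    seed: int | np.random.Generator | None = None,
    reference: str | None = None,
    params: Mapping[str, float] | None = None,
) -> SimulationReplicate:
    """Simulate one replicate, returning aligned sequences per population."""
    arrays, tmrca, total_bl = simulate_arrays(model, mutation, seed, reference)
    length = next(iter(arrays.values())).shape[1] if arrays else 0
    window = (
        HVS1_WINDOW if length == HVS1_LENGTH else (1, length)
    )
    blocks = {}
    for key, arr in arrays.items():
        deme = key.split("@")[0]
        labels = [f"{deme}_{i}" for i in range(arr.shape[0])]
        blocks[key] = SequenceBlock(
            labels=labels, sequences=decode_sequences(arr), window=window
        )
    return SimulationReplicate(
        params=dict(params or {}),
        blocks=blocks,
        tmrca=tmrca,
        total_branch_length=total_bl,
        arrays=arrays,
    )


# ---------------------------------------------------------------------------
# priors and the model registry


@dataclass
class PriorSpec:
    """Independent uniform priors with simple order constraints.

    ``bounds`` maps parameter name -> (low, high); ``constraints`` are
    predicates over the parameter dict, satisfied by rejection.
    """

    bounds: dict[str, tuple[float, float]]
    constraints: list[Callable[[dict[str, float]], bool]] = field(
        default_factory=list
    )

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.bounds.items():
            if not (np.isfinite(lo) and np.isfinite(hi) and lo <= hi):
                raise ValueError(f"prior for {name}: bad bounds ({lo}, {hi})")

    def sample(self, rng: np.random.Generator, max_tries: int = 10_000) -> dict[str, float]:
        for _ in range(max_tries):
            draw = {
                name: float(rng.uniform(lo, hi)) if hi > lo else float(lo)
                for name, (lo, hi) in self.bounds.items()
            }
            if all(c(draw) for c in self.constraints):
                return draw
        raise RuntimeError(
            "prior constraint rejection rate too high (>99.99%): "
            "check the constraint set"
        )


#: Study priors: uniform haploid sizes 1-100,000; times 1-20,000 yr BP
#: with T2 < T1; admixture proportion 0.01-1.
DEFAULT_PRIOR = PriorSpec(
    bounds={
        "N_MOGOU": (1.0, 100_000.0),
        "N_HENGBEI": (1.0, 100_000.0),
        "N_HAN": (1.0, 100_000.0),
        "T1": (1.0, 20_000.0),
        "T2": (1.0, 20_000.0),
        "a": (0.01, 1.0),
    },
    constraints=[lambda p: p["T2"] < p["T1"]],
)

MOGOU, HENGBEI, HAN = "Mogou", "Hengbei", "NorthernHan"
SAMPLING_AGES = {MOGOU: 4000.0, HENGBEI: 3000.0, HAN: 0.0}
DEFAULT_SAMPLE_SIZES = (46, 64, 521)


@dataclass
class ModelTemplate:
    """A demographic scenario: a builder from a parameter dict to a model."""

    label: str
    parameters: list[str]
    build: Callable[[Mapping[str, float]], DemographicModel]
    description: str = ""

    def is_valid(self, params: Mapping[str, float]) -> bool:
        try:
            self.build(params).validate()
            return True
        except ModelValidationError:
            return False


def _base(params: Mapping[str, float], sizes: Sequence[int]) -> tuple[dict, list]:
    demes = {
        MOGOU: float(params["N_MOGOU"]),
        HENGBEI: float(params["N_HENGBEI"]),
        HAN: float(params["N_HAN"]),
    }
    sampling = [
        SamplingEvent(MOGOU, SAMPLING_AGES[MOGOU], int(sizes[0])),
        SamplingEvent(HENGBEI, SAMPLING_AGES[HENGBEI], int(sizes[1])),
        SamplingEvent(HAN, SAMPLING_AGES[HAN], int(sizes[2])),
    ]
    return demes, [s for s in sampling if s.n > 0]


def model_registry(
    sample_sizes: Sequence[int] = DEFAULT_SAMPLE_SIZES,
    generation_time: float = GENERATION_TIME,
) -> dict[str, ModelTemplate]:
    """The four study demographic scenarios.

    * model1 — Mogou and the Hengbei lineage split at T1; Northern Han
      descends from the Hengbei lineage (its branch springs from the
      sampled Hengbei point at 3000 yr BP); at T2 an admixture pulse of
      proportion a flows from Mogou into the Hengbei/Han ancestry (the
      common stem when T2 predates the Hengbei sampling, the Han deme
      afterwards).
    * model2 — mirror image: Han descends from the Mogou lineage (branch
      point at the 4000-yr-BP Mogou sampling), Hengbei splits at T1, and
      the pulse of proportion a flows from Hengbei into the Mogou/Han
      ancestry at T2.
    * model3 — Han is a Hengbei offshoot at T2 with no admixture; Mogou
      splits at T1.
    * model4 — Mogou and Hengbei are a sister pair splitting at T2; their
      ancestor split from the Han lineage at T1.

    Models are data, not code: callers may register alternatives.
    """

    def build1(p: Mapping[str, float]) -> DemographicModel:
        demes, sampling = _base(p, sample_sizes)
        sink = HENGBEI if p["T2"] >= SAMPLING_AGES[HENGBEI] else HAN
        return DemographicModel(
            demes=demes,
            sampling=sampling,
            divergences=[
                DivergenceEvent(SAMPLING_AGES[HENGBEI], HAN, HENGBEI),
                DivergenceEvent(p["T1"], MOGOU, HENGBEI),
            ],
            pulses=[AdmixturePulse(p["T2"], MOGOU, sink, p["a"])],
            generation_time=generation_time,
            label="model1",
        )

    def build2(p: Mapping[str, float]) -> DemographicModel:
        demes, sampling = _base(p, sample_sizes)
        sink = MOGOU if p["T2"] >= SAMPLING_AGES[MOGOU] else HAN
        return DemographicModel(
            demes=demes,
            sampling=sampling,
            divergences=[
                DivergenceEvent(SAMPLING_AGES[MOGOU], HAN, MOGOU),
                DivergenceEvent(p["T1"], HENGBEI, MOGOU),
            ],
            pulses=[AdmixturePulse(p["T2"], HENGBEI, sink, p["a"])],
            generation_time=generation_time,
            label="model2",
        )

    def build3(p: Mapping[str, float]) -> DemographicModel:
        demes, sampling = _base(p, sample_sizes)
        return DemographicModel(
            demes=demes,
            sampling=sampling,
            divergences=[
                DivergenceEvent(p["T2"], HAN, HENGBEI),
                DivergenceEvent(p["T1"], MOGOU, HENGBEI),
            ],
            generation_time=generation_time,
            label="model3",
        )

    def build4(p: Mapping[str, float]) -> DemographicModel:
        demes, sampling = _base(p, sample_sizes)
        return DemographicModel(
            demes=demes,
            sampling=sampling,
            divergences=[
                DivergenceEvent(p["T2"], MOGOU, HENGBEI),
                DivergenceEvent(p["T1"], HENGBEI, HAN),
            ],
            generation_time=generation_time,
            label="model4",
        )

    shared = ["N_MOGOU", "N_HENGBEI", "N_HAN", "T1", "T2"]
    return {
        "model1": ModelTemplate(
            "model1", shared + ["a"], build1,
            "Han = Hengbei offshoot at T2 with proportion a from Mogou",
        ),
        "model2": ModelTemplate(
            "model2", shared + ["a"], build2,
            "Han = Mogou offshoot at T2 with proportion a from Hengbei",
        ),
        "model3": ModelTemplate(
            "model3", shared, build3, "Han = Hengbei offshoot, no admixture"
        ),
        "model4": ModelTemplate(
            "model4", shared, build4, "Mogou/Hengbei sister pair, Han outgroup"
        ),
    }


def draw_from_prior(
    prior: PriorSpec,
    template: ModelTemplate,
    rng: np.random.Generator | int | None = None,
    max_tries: int = 10_000,
) -> tuple[DemographicModel, dict[str, float]]:
    """Draw parameters until the template yields a valid model.

    Besides the prior's own constraints (T2 < T1), draws are rejected when
    the built model is invalid, e.g. a divergence predating a sampled
    deme's sampling age.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    restricted = PriorSpec(
        bounds={k: v for k, v in prior.bounds.items() if k in template.parameters},
        constraints=[
            c for c in prior.constraints
        ],
    )
    for _ in range(max_tries):
        try:
            draw = restricted.sample(rng, max_tries=1)
        except RuntimeError:
            continue
        if template.is_valid(draw):
            model = template.build(draw)
            return model, draw
    raise RuntimeError(
        f"could not draw a valid parameter set for {template.label} "
        f"in {max_tries} tries"
    )
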