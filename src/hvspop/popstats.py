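"""Kinship correction, haplogroup frequencies, PhiST / AMOVA, MDS and PCA.

The frequency unit is the kinship-corrected *haplotype unit*: a haplotype
shared by individuals buried in the same grave is counted once per grave,
so matrilineal relatives do not inflate haplogroup frequencies.

PhiST is the sequence analogue of Fst, obtained from an analysis of
molecular variance (AMOVA) on the matrix of pairwise nucleotide
differences; significance comes from permuting individuals among
populations.  The hierarchical AMOVA partitions variance among groups
(PhiCT), among populations within groups (PhiSC) and within populations
(PhiST).  Distances are raw numbers of differences (a gap run counts one
event) with no substitution-model correction, the standard convention for
haplotype-level mtDNA data.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import Sample, SequenceBlock, sequence_distance

logger = logging.getLogger(__name__)

__all__ = [
    "HaplotypeUnit",
    "DistanceMatrix",
    "AmovaResult",
    "kinship_correct",
    "haplogroup_frequencies",
    "pairwise_phist",
    "amova",
    "mds",
    "pca_frequencies",
    "difference_matrix",
    "phist_from_distances",
]


@dataclass
class HaplotypeUnit:
    """A haplotype with its carriers and kinship-corrected weight."""

    haplotype_id: str
    haplogroup: str | None
    carriers: list[str]
    weight: int

    def __post_init__(self) -> None:
        if not 1 <= self.weight <= len(self.carriers):
            raise ValueError("weight must be in [1, number of carriers]")


@dataclass
class DistanceMatrix:
    """Labelled symmetric nonnegative matrix with zero diagonal."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(v, v.T):
            raise ValueError("matrix must be symmetric")
        if not np.allclose(np.diag(v), 0):
            raise ValueError("diagonal must be zero")
        if (v < -1e-12).any():
            raise ValueError("distances must be nonnegative")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


@dataclass
class AmovaResult:
    """Hierarchical variance decomposition with Phi statistics."""

    variance_components: dict[str, float]
    percentages: dict[str, float]
    phi: dict[str, float]
    p_values: dict[str, float] = field(default_factory=dict)
    df: dict[str, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for level in self.variance_components:
            rows.append(
                {
                    "level": level,
                    "df": self.df.get(level),
                    "variance": self.variance_components[level],
                    "percent": self.percentages[level],
                }
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# kinship correction and frequencies


def kinship_correct(samples: Sequence[Sample]) -> list[HaplotypeUnit]:
    """Collapse same-haplotype carriers within a grave to a single unit.

    A haplotype carried in g distinct graves contributes weight g; samples
    without a grave ID count as singleton graves; samples without a
    haplotype ID are excluded with a warning.  Idempotent and ordered by
    haplotype ID.
    """
    by_hap: dict[str, list[Sample]] = {}
    for s in samples:
        if s.haplotype_id is None:
            logger.warning("kinship_correct: %s has no haplotype ID, excluded",
                           s.sample_id)
            continue
        by_hap.setdefault(s.haplotype_id, []).append(s)

    def _sort_key(hid: str):
        digits = "".join(ch for ch in hid if ch.isdigit())
        return (int(digits) if digits else 0, hid)

    units = []
    for hid in sorted(by_hap, key=_sort_key):
        carriers = by_hap[hid]
        graves = {
            s.grave_id if s.grave_id is not None else f"__solo_{s.sample_id}"
            for s in carriers
        }
        haplogroups = {s.haplogroup for s in carriers if s.haplogroup}
        units.append(
            HaplotypeUnit(
                haplotype_id=hid,
                haplogroup=sorted(haplogroups)[0] if haplogroups else None,
                carriers=[s.sample_id for s in carriers],
                weight=len(graves),
            )
        )
    return units


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (0.125 -> 0.13 at 2 digits)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def haplogroup_frequencies(
    units: Sequence[HaplotypeUnit],
    collapse: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Haplogroup frequencies over kinship-corrected units.

    Returns a frame indexed by haplogroup with columns ``count``, ``freq``
    and ``percent`` (percent rounded half-up to 2 decimals).  ``collapse``
    folds sublineages into macro-haplogroups (default D*, D4, D5 -> D).
    """
    if not units:
        raise ValueError("empty unit list")
    if collapse is None:
        collapse = {"D*": "D", "D4": "D", "D5": "D"}
    counts: dict[str, int] = {}
    for u in units:
        label = collapse.get(u.haplogroup or "unassigned", u.haplogroup or "unassigned")
        counts[label] = counts.get(label, 0) + u.weight
    total = sum(counts.values())
    df = pd.DataFrame(
        {
            "count": pd.Series(counts).sort_index(),
        }
    )
    df["freq"] = df["count"] / total
    df["percent"] = [round_half_up(100 * f) for f in df["freq"]]
    return df


# ---------------------------------------------------------------------------
# distances and PhiST


def difference_matrix(block: SequenceBlock) -> np.ndarray:
    """Pairwise difference counts (gap run = one event)."""
    n = len(block)
    d = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = sequence_distance(
                block.sequences[i], block.sequences[j]
            )
    return d


def _ssd(d: np.ndarray, idx: np.ndarray) -> float:
    """Sum of squared deviations of a set of sequences, from the pairwise
    (squared-distance) matrix: SSD = (1/n) * sum_{i<j} d_ij."""
    sub = d[np.ix_(idx, idx)]
    return float(sub.sum() / (2 * len(idx)))


def phist_from_distances(d: np.ndarray, sizes: Sequence[int]) -> float:
    """One-level AMOVA PhiST from a pooled difference matrix.

    ``d`` is ordered population-by-population with the given sizes; the
    difference counts play the role of squared Euclidean distances.
    """
    sizes = list(sizes)
    n_total = sum(sizes)
    k = len(sizes)
    offsets = np.cumsum([0] + sizes)
    ssd_within = 0.0
    for a in range(k):
        idx = np.arange(offsets[a], offsets[a + 1])
        ssd_within += _ssd(d, idx)
    ssd_total = _ssd(d, np.arange(n_total))
    ssd_among = ssd_total - ssd_within
    df_within = n_total - k
    sigma_w = ssd_within / df_within if df_within > 0 else 0.0
    n_eff = (n_total - sum(s * s for s in sizes) / n_total) / (k - 1)
    sigma_a = (ssd_among / (k - 1) - sigma_w) / n_eff
    denom = sigma_a + sigma_w
    if denom <= 0:
        return 0.0
    return float(sigma_a / denom)


def pairwise_phist(
    block: SequenceBlock,
    pop_assignment: Sequence[str],
    permutations: int = 1000,
    seed: int | None = None,
) -> tuple[DistanceMatrix, pd.DataFrame, pd.DataFrame]:
    """Pairwise PhiST between populations with permutation p-values.

    Returns ``(distances, p_values, raw)``: negative PhiST estimates are
    floored at 0 in the distance matrix but kept in ``raw``; permutation
    p-values use the (b+1)/(m+1) estimator (fraction of permutations with
    PhiST >= observed).
    """
    pops = list(dict.fromkeys(pop_assignment))
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    assignment = np.asarray(pop_assignment)
    for p in pops:
        if (assignment == p).sum() < 2:
            raise ValueError(f"population {p!r} has fewer than 2 sequences")
    d_full = difference_matrix(block)
    rng = np.random.default_rng(seed)

    k = len(pops)
    raw = np.zeros((k, k))
    pvals = np.ones((k, k))
    for a in range(k):
        for b in range(a + 1, k):
            ia = np.flatnonzero(assignment == pops[a])
            ib = np.flatnonzero(assignment == pops[b])
            idx = np.concatenate([ia, ib])
            d = d_full[np.ix_(idx, idx)]
            sizes = [len(ia), len(ib)]
            obs = phist_raw = _phist_raw(d, sizes)
            hits = 0
            n_pair = len(idx)
            for _ in range(permutations):
                perm = rng.permutation(n_pair)
                dp = d[np.ix_(perm, perm)]
                if _phist_raw(dp, sizes) >= obs - 1e-12:
                    hits += 1
            raw[a, b] = raw[b, a] = phist_raw
            pvals[a, b] = pvals[b, a] = (hits + 1) / (permutations + 1)
    floored = np.maximum(raw, 0.0)
    np.fill_diagonal(floored, 0.0)
    np.fill_diagonal(pvals, 1.0)
    dist = DistanceMatrix(labels=pops, values=floored)
    return (
        dist,
        pd.DataFrame(pvals, index=pops, columns=pops),
        pd.DataFrame(raw, index=pops, columns=pops),
    )


def _phist_raw(d: np.ndarray, sizes: Sequence[int]) -> float:
    """PhiST without the nonnegativity guard (for permutation nulls)."""
    sizes = list(sizes)
    n_total = sum(sizes)
    k = len(sizes)
    offsets = np.cumsum([0] + sizes)
    ssd_within = 0.0
    for a in range(k):
        idx = np.arange(offsets[a], offsets[a + 1])
        ssd_within += _ssd(d, idx)
    ssd_total = _ssd(d, np.arange(n_total))
    ssd_among = ssd_total - ssd_within
    sigma_w = ssd_within / (n_total - k)
    n_eff = (n_total - sum(s * s for s in sizes) / n_total) / (k - 1)
    sigma_a = (ssd_among / (k - 1) - sigma_w) / n_eff
    denom = sigma_a + sigma_w
    if denom == 0:
        return 0.0
    return float(sigma_a / denom)


# ---------------------------------------------------------------------------
# hierarchical AMOVA


def amova(
    block: SequenceBlock,
    pop_assignment: Sequence[str],
    grouping: Mapping[str, Sequence[str]],
    permutations: int = 1000,
    seed: int | None = None,
) -> AmovaResult:
    """Two-level (group / population / individual) AMOVA.

    ``grouping`` maps group label -> populations.  Permutation tests:
    populations among groups for PhiCT, individuals among populations
    within groups for PhiSC, individuals among populations for PhiST.
    A single group reduces to the one-level decomposition with a notice.
    """
    assignment = np.asarray(pop_assignment)
    pops = [p for group in grouping.values() for p in group]
    if len(pops) != len(set(pops)):
        raise ValueError("populations assigned to more than one group")
    missing = set(assignment) - set(pops)
    if missing:
        raise ValueError(f"populations missing from grouping: {sorted(missing)}")
    d = difference_matrix(block)

    if len(grouping) < 2:
        warnings.warn("single group: reducing to one-level AMOVA", stacklevel=2)
        return _one_level_amova(d, assignment, permutations, seed)

    rng = np.random.default_rng(seed)
    comp = _three_level_components(d, assignment, grouping)
    sigma_a, sigma_b, sigma_c = comp
    total = sigma_a + sigma_b + sigma_c
    phi = {
        "PhiCT": sigma_a / total if total else 0.0,
        "PhiSC": sigma_b / (sigma_b + sigma_c) if (sigma_b + sigma_c) else 0.0,
        "PhiST": (sigma_a + sigma_b) / total if total else 0.0,
    }

    # permutation tests
    hits = {"PhiCT": 0, "PhiSC": 0, "PhiST": 0}
    pop_list = list(pops)
    group_of = {p: g for g, members in grouping.items() for p in members}
    n = len(assignment)
    for _ in range(permutations):
        # PhiCT: permute whole populations among groups
        perm_pops = rng.permutation(pop_list)
        g_perm = {
            p: group_of[pop_list[i]] for i, p in enumerate(perm_pops)
        }
        grouping_perm: dict[str, list[str]] = {g: [] for g in grouping}
        for p, g in g_perm.items():
            grouping_perm[g].append(p)
        a_p, b_p, c_p = _three_level_components(d, assignment, grouping_perm)
        tot = a_p + b_p + c_p
        if tot and a_p / tot >= phi["PhiCT"] - 1e-12:
            hits["PhiCT"] += 1
        # PhiSC: permute individuals among populations within each group
        assignment_sc = assignment.copy()
        for g, members in grouping.items():
            idx = np.flatnonzero(np.isin(assignment, list(members)))
            assignment_sc[idx] = assignment[rng.permutation(idx)]
        a_p, b_p, c_p = _three_level_components(d, assignment_sc, grouping)
        if (b_p + c_p) and b_p / (b_p + c_p) >= phi["PhiSC"] - 1e-12:
            hits["PhiSC"] += 1
        # PhiST: permute individuals among all populations
        assignment_st = assignment[rng.permutation(n)]
        a_p, b_p, c_p = _three_level_components(d, assignment_st, grouping)
        tot = a_p + b_p + c_p
        if tot and (a_p + b_p) / tot >= phi["PhiST"] - 1e-12:
            hits["PhiST"] += 1

    p_values = {k: (v + 1) / (permutations + 1) for k, v in hits.items()}
    total = sigma_a + sigma_b + sigma_c
    return AmovaResult(
        variance_components={
            "among_groups": sigma_a,
            "among_populations_within_groups": sigma_b,
            "within_populations": sigma_c,
        },
        percentages={
            "among_groups": 100 * sigma_a / total if total else 0.0,
            "among_populations_within_groups": 100 * sigma_b / total if total else 0.0,
            "within_populations": 100 * sigma_c / total if total else 100.0,
        },
        phi=phi,
        p_values=p_values,
        df={
            "among_groups": len(grouping) - 1,
            "among_populations_within_groups": len(pops) - len(grouping),
            "within_populations": len(assignment) - len(pops),
        },
    )


def _three_level_components(
    d: np.ndarray,
    assignment: np.ndarray,
    grouping: Mapping[str, Sequence[str]],
) -> tuple[float, float, float]:
    """Variance components (among groups, among pops within groups, within
    pops) from the pairwise squared-distance matrix."""
    n_total = len(assignment)
    pops = [p for members in grouping.values() for p in members]
    n_pops = len(pops)
    n_groups = len(grouping)

    pop_idx = {p: np.flatnonzero(assignment == p) for p in pops}
    group_idx = {
        g: np.concatenate([pop_idx[p] for p in members]) if members else np.array([], int)
        for g, members in grouping.items()
    }

    ssd_wp = sum(_ssd(d, idx) for idx in pop_idx.values() if len(idx))
    ssd_wg = sum(_ssd(d, idx) for idx in group_idx.values() if len(idx))
    ssd_total = _ssd(d, np.arange(n_total))
    ssd_ap_wg = ssd_wg - ssd_wp
    ssd_ag = ssd_total - ssd_wg

    df_wp = n_total - n_pops
    df_ap = n_pops - n_groups
    df_ag = n_groups - 1

    sigma_c = ssd_wp / df_wp if df_wp > 0 else 0.0

    sizes = {p: len(pop_idx[p]) for p in pops}
    group_sizes = {g: len(group_idx[g]) for g in grouping}
    # expected mean-square coefficients (unbalanced design)
    n_coef = (
        n_total
        - sum(
            sum(sizes[p] ** 2 for p in members) / group_sizes[g]
            for g, members in grouping.items()
            if group_sizes[g]
        )
    ) / df_ap if df_ap > 0 else 0.0
    n_prime = (
        sum(
            sum(sizes[p] ** 2 for p in members) / group_sizes[g]
            for g, members in grouping.items()
            if group_sizes[g]
        )
        - sum(sizes[p] ** 2 for p in pops) / n_total
    ) / df_ag
    n_dprime = (
        n_total - sum(group_sizes[g] ** 2 for g in grouping) / n_total
    ) / df_ag

    sigma_b = (ssd_ap_wg / df_ap - sigma_c) / n_coef if df_ap > 0 and n_coef else 0.0
    sigma_a = (
        (ssd_ag / df_ag - sigma_c - n_prime * sigma_b) / n_dprime
        if n_dprime
        else 0.0
    )
    return sigma_a, sigma_b, sigma_c


def _one_level_amova(
    d: np.ndarray,
    assignment: np.ndarray,
    permutations: int,
    seed: int | None,
) -> AmovaResult:
    pops = list(dict.fromkeys(assignment))
    order = np.concatenate([np.flatnonzero(assignment == p) for p in pops])
    sizes = [int((assignment == p).sum()) for p in pops]
    d_ord = d[np.ix_(order, order)]
    phist = _phist_raw(d_ord, sizes)
    n_total = len(assignment)
    k = len(pops)
    ssd_within = 0.0
    offsets = np.cumsum([0] + sizes)
    for a in range(k):
        idx = np.arange(offsets[a], offsets[a + 1])
        ssd_within += _ssd(d_ord, idx)
    ssd_total = _ssd(d_ord, np.arange(n_total))
    sigma_w = ssd_within / (n_total - k)
    n_eff = (n_total - sum(s * s for s in sizes) / n_total) / (k - 1)
    sigma_a = ((ssd_total - ssd_within) / (k - 1) - sigma_w) / n_eff
    total = sigma_a + sigma_w
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(permutations):
        perm = rng.permutation(n_total)
        if _phist_raw(d_ord[np.ix_(perm, perm)], sizes) >= phist - 1e-12:
            hits += 1
    return AmovaResult(
        variance_components={
            "among_populations": sigma_a,
            "within_populations": sigma_w,
        },
        percentages={
            "among_populations": 100 * sigma_a / total if total else 0.0,
            "within_populations": 100 * sigma_w / total if total else 100.0,
        },
        phi={"PhiST": phist},
        p_values={"PhiST": (hits + 1) / (permutations + 1)},
        df={
            "among_populations": k - 1,
            "within_populations": n_total - k,
        },
    )


# ---------------------------------------------------------------------------
# ordination


def mds(
    dist: DistanceMatrix, dims: int = 2, seed: int | None = None
) -> tuple[pd.DataFrame, float]:
    """Metric MDS: classical scaling refined by SMACOF stress majorisation.

    Returns centred coordinates (sign fixed so the first nonzero loading of
    each axis is positive) and the Kruskal stress-1 of the configuration.
    """
    n = len(dist.labels)
    if dims < 1:
        raise ValueError("dims must be >= 1")
    if dims >= n:
        raise ValueError("dims must be smaller than the number of labels")
    d = dist.values
    # classical (Torgerson) solution
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:dims]
    lam = np.clip(vals[order], 0, None)
    init = vecs[:, order] * np.sqrt(lam)

    from sklearn.manifold import smacof

    coords, _ = smacof(
        d,
        n_components=dims,
        init=init,
        n_init=1,
        metric=True,
        random_state=seed if seed is not None else 0,
        normalized_stress=False,
    )
    coords = coords - coords.mean(axis=0)
    for c in range(dims):
        col = coords[:, c]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if len(nz) and col[nz[0]] < 0:
            coords[:, c] = -col
    conf = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
    denom = (d**2).sum()
    stress1 = float(np.sqrt(((conf - d) ** 2).sum() / denom)) if denom else 0.0
    frame = pd.DataFrame(
        coords,
        index=dist.labels,
        columns=[f"dim{i + 1}" for i in range(dims)],
    )
    return frame, stress1


def pca_frequencies(freq: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of a populations x haplogroups frequency table.

    Column-centred SVD; returns scores (PC1, PC2, ...) and the explained-
    variance ratios.  A constant table yields empty scores with a warning.
    """
    x = freq.to_numpy(dtype=float)
    if x.shape[0] < 2:
        raise ValueError("need at least two populations")
    xc = x - x.mean(axis=0)
    if np.allclose(xc, 0):
        warnings.warn("constant frequency matrix: zero variance", stacklevel=2)
        return pd.DataFrame(index=freq.index), np.array([])
    u, s, _ = np.linalg.svd(xc, full_matrices=False)
    keep = s > 1e-12 * s[0]
    scores = u[:, keep] * s[keep]
    for c in range(scores.shape[1]):
        nz = np.flatnonzero(np.abs(scores[:, c]) > 1e-12)
        if len(nz) and scores[nz[0], c] < 0:
            scores[:, c] = -scores[:, c]
    var = s[keep] ** 2
    ratios = var / (xc**2).sum()
    frame = pd.DataFrame(
        scores,
        index=freq.index,
        columns=[f"PC{i + 1}" for i in range(scores.shape[1])],
    )
    return frame, ratios
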