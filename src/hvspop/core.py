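"""Data model and IO for ancient-mtDNA HVS-I variant tables.

The hypervariable segment I (HVS-I) of the mitochondrial control region,
here the closed rCRS window [16051, 16384] (334 bp), is the classic marker
for ancient-DNA population studies.  A sample is recorded as a *motif*: the
set of positions where it differs from the reference, written in the usual
"16000+X" shorthand ("093" = transition at 16093, "183C" = transversion to
C at 16183), plus any diagnostic coding-region SNPs typed outside the
window and special length markers such as the COII/tRNA-Lys 9-bp deletion.

This module provides the domain types (:class:`Variant`,
:class:`VariantMotif`, :class:`Sample`, :class:`PopulationDataset`,
:class:`SequenceBlock`), the motif shorthand parser/formatter, motif <->
sequence conversion against a packaged reference, delimited-text and FASTA
IO, and loaders for the packaged study fixtures (the 55-sample mtDNA table
and the 6-male Y-SNP genotype table).
"""

from __future__ import annotations

import hashlib
import logging
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: Closed 1-based rCRS interval of the HVS-I window.
HVS1_WINDOW = (16051, 16384)
#: Window length in bp.
HVS1_LENGTH = HVS1_WINDOW[1] - HVS1_WINDOW[0] + 1
#: Length of the mitochondrial genome (rCRS numbering).
MT_GENOME_LENGTH = 16569

#: Transition partners (purine<->purine, pyrimidine<->pyrimidine).
TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}

VARIANT_KINDS = ("transition", "transversion", "deletion", "insertion")

#: Shorthand phrases recognised as special length markers.
SPECIAL_MARKERS = {
    "9bpdeletion": "9bp_del",
    "9bpdel": "9bp_del",
    "9bp_del": "9bp_del",
    "-5bp": "5bp_del",
    "−5bp": "5bp_del",
    "5bp_del": "5bp_del",
}

#: Recorded digests of the packaged fixtures (integrity guard).
_SHA256 = {
    "table3_mogou.tsv":
        "92badb9acec2d421bd3e67a2d6a7d267ef71d0fc635d49e203618420e1506f2a",
    "table4_ysnp.tsv":
        "6dca63feaa24e1bbcaf5e2bc0c9f87048978449027cf6455871e08f6eae51d22",
    "hvs1_reference_synthetic.fasta":
        "4ae928c871ee1225f2fbf1d5ebf35f1fe3dd1571934d5ab14339b74e0b457a72",
}


class MotifParseError(ValueError):
    """A shorthand token could not be interpreted."""


class CoordinateError(ValueError):
    """A variant position falls outside the sequence window."""


class FixtureIntegrityError(RuntimeError):
    """A packaged fixture does not match its recorded checksum."""


@dataclass(frozen=True, order=True)
class Variant:
    """A single mtDNA variant in 1-based rCRS coordinates.

    ``derived_base`` is required for transversions and insertions; ``span``
    is the deleted length for deletions (default 1).
    """

    position: int
    kind: str
    derived_base: str | None = None
    span: int = 1

    def __post_init__(self) -> None:
        if not 1 <= self.position <= MT_GENOME_LENGTH:
            raise CoordinateError(
                f"position {self.position} outside [1, {MT_GENOME_LENGTH}]"
            )
        if self.kind not in VARIANT_KINDS:
            raise ValueError(f"unknown variant kind {self.kind!r}")
        if self.kind in ("transversion", "insertion"):
            if self.derived_base not in ("A", "C", "G", "T"):
                raise ValueError(
                    f"{self.kind} at {self.position} needs a derived base in ACGT"
                )
        if self.span < 1:
            raise ValueError("span must be >= 1")


def _in_window(pos: int, window: tuple[int, int] = HVS1_WINDOW) -> bool:
    return window[0] <= pos <= window[1]


@dataclass(frozen=True)
class VariantMotif:
    """A sample's HVS-I variant set plus coding-region diagnostics."""

    hvs1_variants: frozenset[Variant] = frozenset()
    coding_variants: frozenset[Variant] = frozenset()
    special_markers: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        for v in self.hvs1_variants:
            if not _in_window(v.position):
                raise CoordinateError(
                    f"HVS-I variant at {v.position} outside {HVS1_WINDOW}"
                )
        for varset in (self.hvs1_variants, self.coding_variants):
            positions = [v.position for v in varset]
            if len(positions) != len(set(positions)):
                raise ValueError("duplicate positions within a variant set")

    @property
    def hvs1_positions(self) -> frozenset[int]:
        return frozenset(v.position for v in self.hvs1_variants)

    @property
    def coding_positions(self) -> frozenset[int]:
        return frozenset(v.position for v in self.coding_variants)

    def is_empty(self) -> bool:
        return not (self.hvs1_variants or self.coding_variants or self.special_markers)


EMPTY_MOTIF = VariantMotif()


@dataclass
class Sample:
    """One individual: identity, provenance and its variant motif."""

    sample_id: str
    population: str
    motif: VariantMotif = EMPTY_MOTIF
    grave_id: str | None = None
    sampling_age: int = 0
    sex: str = "unknown"
    haplotype_id: str | None = None
    haplogroup: str | None = None
    haplotype_tag: str | None = None

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female", "unknown"):
            raise ValueError(f"sex must be male/female/unknown, got {self.sex!r}")
        if self.sampling_age < 0:
            raise ValueError("sampling_age must be >= 0 (years BP)")


@dataclass
class PopulationDataset:
    """Samples grouped into populations with sampling ages (years BP)."""

    samples: list[Sample]
    populations: dict[str, int]

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(ids) != len(set(ids)):
            raise ValueError("sample_id values must be unique within a dataset")
        for s in self.samples:
            if s.population not in self.populations:
                raise ValueError(
                    f"sample {s.sample_id}: population {s.population!r} "
                    "missing from the population map"
                )

    def by_population(self) -> dict[str, list[Sample]]:
        out: dict[str, list[Sample]] = {p: [] for p in self.populations}
        for s in self.samples:
            out[s.population].append(s)
        return out

    def __len__(self) -> int:
        return len(self.samples)


@dataclass
class SequenceBlock:
    """Aligned nucleotide strings over a common rCRS window."""

    labels: list[str]
    sequences: list[str]
    window: tuple[int, int] = HVS1_WINDOW

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.sequences):
            raise ValueError("labels and sequences differ in length")
        span = self.window[1] - self.window[0] + 1
        for lab, seq in zip(self.labels, self.sequences):
            if len(seq) != span:
                raise ValueError(
                    f"sequence {lab}: length {len(seq)} != window span {span}"
                )

    def __len__(self) -> int:
        return len(self.labels)


# ---------------------------------------------------------------------------
# motif shorthand


_TOKEN_RE = re.compile(r"^(\d+)([ACGT]?)$")


def parse_motif(shorthand: str, offset: int = 16000) -> VariantMotif:
    """Parse dash-separated "16000+X" shorthand into a :class:`VariantMotif`.

    Numeric tokens become transitions at ``offset + N``; a trailing base
    letter marks a transversion to that base; recognised phrases ("9 bp
    deletion", "-5 bp") become special markers.  Positions falling outside
    the HVS-I window are routed to the coding set.  An empty string yields
    the empty motif.
    """
    text = shorthand.strip()
    if not text:
        return EMPTY_MOTIF
    hvs1: set[Variant] = set()
    coding: set[Variant] = set()
    special: set[str] = set()
    for raw in text.split("-"):
        token = raw.strip().replace(" ", "")
        if not token:
            continue
        normalized = token.lower()
        if normalized in SPECIAL_MARKERS:
            special.add(SPECIAL_MARKERS[normalized])
            continue
        m = _TOKEN_RE.match(token)
        if m is None:
            raise MotifParseError(f"cannot parse motif token {raw!r}")
        pos = offset + int(m.group(1))
        if not 1 <= pos <= MT_GENOME_LENGTH:
            raise MotifParseError(
                f"token {raw!r}: position {pos} outside [1, {MT_GENOME_LENGTH}]"
            )
        base = m.group(2)
        var = (
            Variant(pos, "transversion", base) if base else Variant(pos, "transition")
        )
        (hvs1 if _in_window(pos) else coding).add(var)
    return VariantMotif(frozenset(hvs1), frozenset(coding), frozenset(special))


def format_motif(motif: VariantMotif, offset: int = 16000) -> str:
    """Inverse of :func:`parse_motif` for motifs expressible in shorthand."""
    tokens: list[tuple[int, str]] = []
    for v in sorted(motif.hvs1_variants | motif.coding_variants):
        if v.kind == "transition":
            tokens.append((v.position, f"{v.position - offset:03d}"))
        elif v.kind == "transversion":
            tokens.append((v.position, f"{v.position - offset:03d}{v.derived_base}"))
        else:
            raise ValueError(f"{v.kind} at {v.position} has no shorthand form")
    body = "-".join(t for _, t in sorted(tokens))
    markers = sorted(motif.special_markers)
    return "-".join([body] + markers) if body else "-".join(markers)


def parse_coding(text: str) -> tuple[frozenset[Variant], frozenset[str]]:
    """Parse a comma-separated coding-SNP list (absolute rCRS positions,
    optional trailing allele, e.g. ``"10400,15487T"``), returning variants
    and special markers."""
    variants: set[Variant] = set()
    special: set[str] = set()
    for raw in str(text).split(","):
        token = raw.strip().replace(" ", "")
        if not token:
            continue
        if token.lower() in SPECIAL_MARKERS:
            special.add(SPECIAL_MARKERS[token.lower()])
            continue
        m = _TOKEN_RE.match(token)
        if m is None:
            raise MotifParseError(f"cannot parse coding token {raw!r}")
        pos = int(m.group(1))
        if not 1 <= pos <= MT_GENOME_LENGTH:
            raise MotifParseError(f"coding position {pos} outside the genome")
        base = m.group(2)
        variants.add(
            Variant(pos, "transversion", base) if base else Variant(pos, "transition")
        )
    return frozenset(variants), frozenset(special)


# ---------------------------------------------------------------------------
# motif <-> sequence


def motif_to_sequence(
    motif: VariantMotif,
    reference: str,
    window: tuple[int, int] = HVS1_WINDOW,
) -> str:
    """Apply a motif's HVS-I variants to a reference window.

    Transitions flip A<->G / C<->T, transversions set the derived base and
    deletions become gap runs.  Coding variants and special markers are
    outside the window and are skipped with a debug notice.
    """
    span = window[1] - window[0] + 1
    if len(reference) != span:
        raise CoordinateError("reference length does not match the window span")
    seq = list(reference)
    if motif.coding_variants or motif.special_markers:
        logger.debug(
            "motif_to_sequence: ignoring %d coding variants / %d markers "
            "outside the window",
            len(motif.coding_variants),
            len(motif.special_markers),
        )
    for v in sorted(motif.hvs1_variants):
        i = v.position - window[0]
        if not 0 <= i < span:
            raise CoordinateError(f"variant position {v.position} outside {window}")
        if v.kind == "transition":
            seq[i] = TRANSITION[seq[i]]
        elif v.kind == "transversion":
            seq[i] = v.derived_base  # type: ignore[assignment]
        elif v.kind == "deletion":
            for j in range(i, min(i + v.span, span)):
                seq[j] = "-"
        else:  # insertion: not representable in a fixed alignment window
            logger.debug("skipping insertion at %d (fixed window)", v.position)
    return "".join(seq)


def sequence_to_motif(
    sequence: str,
    reference: str,
    window: tuple[int, int] = HVS1_WINDOW,
) -> VariantMotif:
    """Recover the HVS-I variant set of ``sequence`` relative to ``reference``.

    Substitutions are classified as transition/transversion; each maximal
    gap run becomes one deletion variant.
    """
    if len(sequence) != len(reference):
        raise CoordinateError("sequence and reference lengths differ")
    variants: set[Variant] = set()
    i = 0
    n = len(sequence)
    while i < n:
        s, r = sequence[i], reference[i]
        if s == "-":
            j = i
            while j < n and sequence[j] == "-":
                j += 1
            variants.add(Variant(window[0] + i, "deletion", span=j - i))
            i = j
            continue
        if s != r and s in "ACGT" and r in "ACGT":
            kind = "transition" if TRANSITION[r] == s else "transversion"
            if kind == "transition":
                variants.add(Variant(window[0] + i, "transition"))
            else:
                variants.add(Variant(window[0] + i, "transversion", s))
        i += 1
    return VariantMotif(hvs1_variants=frozenset(variants))


def sequence_distance(a: str, b: str) -> int:
    """Number of differing events between two aligned sequences.

    A shared-boundary gap run (one sequence gapped, the other not) counts
    as a single event regardless of its length; ``N`` matches any base.
    """
    if len(a) != len(b):
        raise CoordinateError("aligned sequences must have equal length")
    diffs = 0
    in_gap = False
    for x, y in zip(a, b):
        gap = (x == "-") != (y == "-")
        if gap:
            if not in_gap:
                diffs += 1
            in_gap = True
            continue
        in_gap = False
        if x == "-" and y == "-":
            continue
        if x == "N" or y == "N":
            continue
        if x != y:
            diffs += 1
    return diffs


# ---------------------------------------------------------------------------
# IO

DATASET_COLUMNS = [
    "sample_id",
    "population",
    "grave_id",
    "age_bp",
    "sex",
    "hvs1_motif",
    "coding_snps",
    "haplotype_id",
    "haplogroup",
]


def write_dataset(dataset: PopulationDataset, path: str | Path) -> None:
    """Write a dataset as delimited text (one row per sample)."""
    rows = []
    for s in dataset.samples:
        coding_tokens = sorted(
            [
                f"{v.position}{v.derived_base or ''}"
                for v in s.motif.coding_variants
            ]
        ) + sorted(s.motif.special_markers)
        rows.append(
            {
                "sample_id": s.sample_id,
                "population": s.population,
                "grave_id": s.grave_id or "",
                "age_bp": s.sampling_age,
                "sex": s.sex,
                "hvs1_motif": format_motif(
                    VariantMotif(hvs1_variants=s.motif.hvs1_variants)
                ),
                "coding_snps": ",".join(coding_tokens),
                "haplotype_id": s.haplotype_id or "",
                "haplogroup": s.haplogroup or "",
            }
        )
    pd.DataFrame(rows, columns=DATASET_COLUMNS).to_csv(path, sep="\t", index=False)


def read_dataset(path: str | Path) -> PopulationDataset:
    """Read a delimited-text dataset written by :func:`write_dataset`."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    samples = []
    populations: dict[str, int] = {}
    for _, row in df.iterrows():
        hvs = parse_motif(row["hvs1_motif"])
        coding, special = parse_coding(row.get("coding_snps", ""))
        motif = VariantMotif(
            hvs1_variants=hvs.hvs1_variants,
            coding_variants=coding,
            special_markers=hvs.special_markers | special,
        )
        age = int(row["age_bp"]) if row["age_bp"] else 0
        samples.append(
            Sample(
                sample_id=row["sample_id"],
                population=row["population"],
                motif=motif,
                grave_id=row["grave_id"] or None,
                sampling_age=age,
                sex=row["sex"] or "unknown",
                haplotype_id=row["haplotype_id"] or None,
                haplogroup=row["haplogroup"] or None,
            )
        )
        populations.setdefault(row["population"], age)
    return PopulationDataset(samples, populations)


def write_fasta(block: SequenceBlock, path: str | Path) -> None:
    """Write a :class:`SequenceBlock` as FASTA (window noted in headers)."""
    records = [
        SeqRecord(
            Seq(seq),
            id=lab,
            description=f"window={block.window[0]}-{block.window[1]}",
        )
        for lab, seq in zip(block.labels, block.sequences)
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path, window: tuple[int, int] = HVS1_WINDOW) -> SequenceBlock:
    records = list(SeqIO.parse(str(path), "fasta"))
    return SequenceBlock(
        labels=[r.id for r in records],
        sequences=[str(r.seq).upper() for r in records],
        window=window,
    )


# ---------------------------------------------------------------------------
# packaged fixtures


def _data_path(name: str):
    return resources.files("hvspop.data").joinpath(name)


def _read_data_text(name: str) -> str:
    text = _data_path(name).read_text()
    expected = _SHA256.get(name)
    if expected is not None:
        digest = hashlib.sha256(text.encode()).hexdigest()
        if digest != expected:
            raise FixtureIntegrityError(
                f"packaged fixture {name} checksum mismatch: {digest}"
            )
    return text


def load_reference(name: str = "hvs1_reference_synthetic.fasta") -> str:
    """Return the packaged 334-bp HVS-I reference window string.

    The packaged reference is a synthetic stand-in for the rCRS window
    (seeded random draw; the fixture's transversion positions are pinned to
    the true rCRS alleles) -- motif algebra only requires consistency with
    itself, not the database sequence.
    """
    text = _read_data_text(name)
    seq = "".join(
        line.strip() for line in text.splitlines() if not line.startswith(">")
    )
    if len(seq) != HVS1_LENGTH:
        raise FixtureIntegrityError("packaged reference has the wrong length")
    return seq


#: Males typed in the Y-SNP genotype fixture.
_TABLE4_MALES = ("MG3", "MG9", "MG18", "MG44", "MG48", "MG53")


def load_table3_fixture() -> PopulationDataset:
    """Load the packaged 55-sample Mogou mtDNA table.

    Haplotype identity is carried by the printed haplotype ID (rows with
    identical motifs but distinct IDs differ at untyped sites and keep a
    ``haplotype_tag``).  Carriers of one haplotype share one synthetic
    grave, matching the reported within-grave haplotype sharing.
    """
    from io import StringIO

    text = _read_data_text("table3_mogou.tsv")
    df = pd.read_csv(StringIO(text), sep="\t", comment="#", dtype=str,
                     keep_default_na=False)
    samples: list[Sample] = []
    for _, row in df.iterrows():
        hvs = parse_motif(row["hvs1"])
        coding, special = parse_coding(row["coding"])
        motif = VariantMotif(
            hvs1_variants=hvs.hvs1_variants,
            coding_variants=coding,
            special_markers=hvs.special_markers | special,
        )
        grave = f"GRV-{row['haplotype_id']}"
        for specimen in row["specimens"].split(","):
            specimen = specimen.strip()
            samples.append(
                Sample(
                    sample_id=specimen,
                    population="Mogou",
                    motif=motif,
                    grave_id=grave,
                    sampling_age=4000,
                    sex="male" if specimen in _TABLE4_MALES else "unknown",
                    haplotype_id=row["haplotype_id"],
                    haplogroup=row["haplogroup"],
                    haplotype_tag=row["haplotype_tag"] or None,
                )
            )
    return PopulationDataset(samples, {"Mogou": 4000})


def load_table4_fixture() -> pd.DataFrame:
    """Load the packaged 6 x 9 Y-SNP genotype table (specimen-indexed)."""
    from io import StringIO

    text = _read_data_text("table4_ysnp.tsv")
    df = pd.read_csv(StringIO(text), sep="\t", comment="#", dtype=str)
    return df.set_index("specimen")


def dataset_to_block(
    dataset: PopulationDataset,
    reference: str | None = None,
    samples: Iterable[Sample] | None = None,
) -> SequenceBlock:
    """Reconstruct aligned HVS-I sequences for a dataset's samples."""
    if reference is None:
        reference = load_reference()
    chosen = list(samples) if samples is not None else dataset.samples
    return SequenceBlock(
        labels=[s.sample_id for s in chosen],
        sequences=[motif_to_sequence(s.motif, reference) for s in chosen],
    )


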