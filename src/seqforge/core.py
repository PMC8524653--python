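"""Domain types and sequence primitives shared across the package.

The central objects are:

* :class:`AnnotatedSequence` — a DNA string together with its CDS features,
  the immutable reference design the optimizer starts from;
* :class:`Solution` — a candidate design ``z = (s, b)``: a (possibly recoded)
  sequence plus an ordered block partition destined for fragment synthesis,
  with a cached objective vector;
* :class:`CodonUsageTable` — per-codon relative frequencies grouped by the
  encoded amino acid, used by the codon-usage objective and operator.

Coordinates are 0-based, half-open throughout; GenBank 1-based inclusive
coordinates are converted at the I/O boundary. All sequence edits in the
package are silent (synonymous) and length-preserving, so CDS coordinates
are valid for every solution derived from the same reference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

__all__ = [
    "DNA_ALPHABET",
    "CODON_TO_AA",
    "AA_TO_CODONS",
    "STOP_CODONS",
    "CDSAnnotation",
    "AnnotatedSequence",
    "Block",
    "Solution",
    "CodonUsageTable",
    "OptimizerConfig",
    "ValidationReport",
    "gc_content",
    "gc_count",
    "translate",
    "synonymous_codons",
    "reverse_complement",
    "validate_solution",
]

DNA_ALPHABET = frozenset("ACGT")

#: sense codon -> amino acid, standard genetic code
CODON_TO_AA: Mapping[str, str] = dict(standard_dna_table.forward_table)
STOP_CODONS = frozenset(standard_dna_table.stop_codons)

#: amino acid -> tuple of codons encoding it (lexicographic order)
_aa_groups: dict[str, list[str]] = {}
for _codon in sorted(CODON_TO_AA):
    _aa_groups.setdefault(CODON_TO_AA[_codon], []).append(_codon)
AA_TO_CODONS: Mapping[str, tuple[str, ...]] = {
    aa: tuple(codons) for aa, codons in _aa_groups.items()
}

#: codon -> number of G/C bases (0..3)
CODON_GC: Mapping[str, int] = {
    c: c.count("G") + c.count("C") for c in list(CODON_TO_AA) + list(STOP_CODONS)
}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T}."""
    return seq.translate(_COMPLEMENT)[::-1]


def gc_count(seq: str) -> int:
    """Number of G/C bases in ``seq``."""
    return seq.count("G") + seq.count("C")


def gc_content(seq: str) -> float:
    """GC fraction of a DNA string.

    Raises
    ------
    ValueError
        If the sequence is empty or contains characters outside {A,C,G,T}.
    """
    if not seq:
        raise ValueError("cannot compute GC content of an empty sequence")
    if not DNA_ALPHABET.issuperset(seq):
        bad = sorted(set(seq) - DNA_ALPHABET)
        raise ValueError(f"sequence contains non-ACGT characters: {bad}")
    return gc_count(seq) / len(seq)


def translate(cds: str) -> str:
    """Translate a coding sequence under the standard genetic code.

    Stop codons are rendered as ``*``. The input length must be a multiple
    of three.
    """
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} is not a multiple of 3")
    return str(Seq(cds).translate())


def synonymous_codons(codon: str) -> tuple[str, ...]:
    """All codons (including ``codon`` itself) encoding the same amino acid.

    Stop codons are rejected: they are never candidates for recoding.
    """
    aa = CODON_TO_AA.get(codon)
    if aa is None:
        if codon in STOP_CODONS:
            raise ValueError(f"{codon} is a stop codon and has no synonym set")
        raise ValueError(f"{codon!r} is not a valid sense codon")
    return AA_TO_CODONS[aa]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CDSAnnotation:
    """A protein-coding feature: 0-based half-open interval plus strand."""

    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        length = self.end - self.start
        if length <= 0 or length % 3 != 0:
            raise ValueError(
                f"CDS [{self.start}, {self.end}) length must be a positive "
                f"multiple of 3, got {length}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class AnnotatedSequence:
    """A DNA sequence with annotated CDS features (the reference design)."""

    seq: str
    cds_features: tuple[CDSAnnotation, ...] = ()
    name: str = "construct"

    def __post_init__(self) -> None:
        if not DNA_ALPHABET.issuperset(self.seq):
            bad = sorted(set(self.seq) - DNA_ALPHABET)
            raise ValueError(f"sequence contains non-ACGT characters: {bad}")
        feats = tuple(sorted(self.cds_features, key=lambda f: f.start))
        object.__setattr__(self, "cds_features", feats)
        prev_end = 0
        for f in feats:
            if f.start < 0 or f.end > len(self.seq):
                raise ValueError(f"CDS [{f.start}, {f.end}) outside sequence")
            if f.start < prev_end:
                raise ValueError("CDS features overlap")
            prev_end = f.end

    def __len__(self) -> int:
        return len(self.seq)

    def cds_sequence(self, feature: CDSAnnotation) -> str:
        """Coding-strand sequence of a CDS (reverse-complemented for '-')."""
        sub = self.seq[feature.start : feature.end]
        return reverse_complement(sub) if feature.strand == "-" else sub


@dataclass(frozen=True)
class Block:
    """A contiguous interval of the construct, synthesized as one fragment."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty block [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class Solution:
    """A candidate design: sequence plus block partition, ``z = (s, b)``.

    ``objectives`` caches the evaluated objective vector (``None`` before
    evaluation); edits always produce a fresh Solution with the cache
    cleared for whatever changed. ``cds_features`` is shared with the
    reference — all edits are length-preserving, so coordinates never move.
    """

    sequence: str
    blocks: tuple[Block, ...]
    cds_features: tuple[CDSAnnotation, ...] = ()
    objectives: np.ndarray | None = None

    def block_sequences(self) -> list[str]:
        return [self.sequence[b.start : b.end] for b in self.blocks]

    def cds_sequence(self, feature: CDSAnnotation) -> str:
        sub = self.sequence[feature.start : feature.end]
        return reverse_complement(sub) if feature.strand == "-" else sub

    def clone(self) -> "Solution":
        """Shallow copy sharing the immutable sequence/blocks, cache kept."""
        obj = None if self.objectives is None else self.objectives.copy()
        return Solution(self.sequence, self.blocks, self.cds_features, obj)


@dataclass(frozen=True)
class CodonUsageTable:
    """Relative codon frequencies grouped by encoded amino acid.

    All 61 sense codons must be present and frequencies within each
    amino-acid family must sum to 1 (tolerance 1e-6).
    """

    frequencies: Mapping[str, float]

    def __post_init__(self) -> None:
        missing = set(CODON_TO_AA) - set(self.frequencies)
        if missing:
            raise ValueError(f"usage table missing {len(missing)} sense codons")
        for aa, codons in AA_TO_CODONS.items():
            total = sum(self.frequencies[c] for c in codons)
            if not math.isclose(total, 1.0, abs_tol=1e-6):
                raise ValueError(
                    f"frequencies for amino acid {aa} sum to {total:.8f}, not 1"
                )
        object.__setattr__(self, "frequencies", dict(self.frequencies))
        modal: dict[str, str] = {}
        minimal: dict[str, str] = {}
        for aa, codons in AA_TO_CODONS.items():
            modal[aa] = max(codons, key=lambda c: (self.frequencies[c], c))
            minimal[aa] = min(codons, key=lambda c: (self.frequencies[c], c))
        object.__setattr__(self, "_modal", modal)
        object.__setattr__(self, "_minimal", minimal)
        # codon -> Q(aa(c)) - q(c), the per-codon usage penalty
        penalty = {
            c: self.frequencies[modal[CODON_TO_AA[c]]] - self.frequencies[c]
            for c in CODON_TO_AA
        }
        object.__setattr__(self, "_penalty", penalty)

    def frequency(self, codon: str) -> float:
        return self.frequencies[codon]

    def modal_codon(self, aa: str) -> str:
        """Most frequent codon for an amino acid."""
        return self._modal[aa]  # type: ignore[attr-defined]

    def rarest_codon(self, aa: str) -> str:
        return self._minimal[aa]  # type: ignore[attr-defined]

    def penalty(self, codon: str) -> float:
        """Q(aa(codon)) - q(codon): distance from the modal synonym."""
        return self._penalty[codon]  # type: ignore[attr-defined]

    @classmethod
    def from_counts(cls, counts: Mapping[str, float]) -> "CodonUsageTable":
        """Build a table from raw codon counts (normalized per family)."""
        freqs: dict[str, float] = {}
        for aa, codons in AA_TO_CODONS.items():
            total = sum(counts.get(c, 0.0) for c in codons)
            if total <= 0:
                raise ValueError(f"no counts for amino acid {aa}")
            for c in codons:
                freqs[c] = counts.get(c, 0.0) / total
        return cls(freqs)

    @classmethod
    def random(cls, rng: np.random.Generator) -> "CodonUsageTable":
        """Random table: uniform weights per family, normalized."""
        freqs: dict[str, float] = {}
        for aa, codons in AA_TO_CODONS.items():
            w = rng.random(len(codons))
            w /= w.sum()
            for c, wi in zip(codons, w):
                freqs[c] = float(wi)
        return cls(freqs)


@dataclass(frozen=True)
class OptimizerConfig:
    """Run parameters for the evolutionary optimizer.

    Parameters
    ----------
    n : pool size (solutions kept per iteration).
    t_max : iteration budget.
    m : archive capacity (typically m >> n).
    l_min, l_max : admissible synthesized-fragment length bounds (nt).
    sigma_gc : maximum GC change (absolute fraction) per GC-operator call.
    sigma_c : per-codon recoding probability of the codon operator.
    sigma_b : block length step (nt); split/join cut points are multiples.
    t_gc : target GC fraction.
    overlap : Gibson assembly overlap length for fragment export (nt).
    objectives : ordered objective identifiers (subset of
        {"gc", "codon_usage", "block_variance", "block_count"}).
    seed : RNG seed for the whole run.
    """

    n: int = 100
    t_max: int = 200
    m: int = 100
    l_min: int = 500
    l_max: int = 3000
    sigma_gc: float = 0.05
    sigma_c: float = 0.25
    sigma_b: int = 100
    t_gc: float = 0.55
    overlap: int = 40
    objectives: tuple[str, ...] = ("gc", "block_count")
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.l_min <= self.l_max):
            raise ValueError("require 0 < l_min <= l_max")
        if self.sigma_b <= 0:
            raise ValueError("sigma_b must be positive")
        if not (0.0 <= self.t_gc <= 1.0):
            raise ValueError("t_gc must lie in [0, 1]")
        if not (0.0 <= self.sigma_c <= 1.0):
            raise ValueError("sigma_c must lie in [0, 1]")
        if self.n < 1:
            raise ValueError("pool size n must be >= 1")
        if self.m < self.n:
            raise ValueError("archive capacity m must be >= pool size n")
        object.__setattr__(self, "objectives", tuple(self.objectives))

    def with_(self, **kwargs) -> "OptimizerConfig":
        return replace(self, **kwargs)


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_solution`: pass/fail plus reasons."""

    ok: bool
    reasons: list[str] = field(default_factory=list)

    def __bool__(self) -> bool:
        return self.ok


def validate_solution(
    z: Solution, ref: AnnotatedSequence, cfg: OptimizerConfig
) -> ValidationReport:
    """Check all Solution invariants against the reference design.

    Verifies length preservation, exact partition coverage by the blocks,
    block length bounds, and the silent-edit property (every CDS translates
    to the same protein as in the reference).
    """
    reasons: list[str] = []
    if len(z.sequence) != len(ref.seq):
        reasons.append(
            f"length changed: {len(z.sequence)} vs reference {len(ref.seq)}"
        )
    if not z.blocks:
        reasons.append("solution has no blocks")
    else:
        if z.blocks[0].start != 0:
            reasons.append(f"first block starts at {z.blocks[0].start}, not 0")
        if z.blocks[-1].end != len(z.sequence):
            reasons.append(
                f"last block ends at {z.blocks[-1].end}, not {len(z.sequence)}"
            )
        for a, b in zip(z.blocks, z.blocks[1:]):
            if a.end != b.start:
                kind = "gap" if a.end < b.start else "overlap"
                reasons.append(f"{kind} between blocks at {a.end}/{b.start}")
        for b in z.blocks:
            if not (cfg.l_min <= len(b) <= cfg.l_max):
                reasons.append(
                    f"block [{b.start}, {b.end}) length {len(b)} outside "
                    f"[{cfg.l_min}, {cfg.l_max}]"
                )
    if len(z.sequence) == len(ref.seq):
        for f in ref.cds_features:
            if translate(z.cds_sequence(f)) != translate(ref.cds_sequence(f)):
                reasons.append(
                    f"non-silent edit: CDS [{f.start}, {f.end}) translation "
                    "differs from reference"
                )
    return ValidationReport(ok=not reasons, reasons=reasons)
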