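"""Design and manufacturing objective functions (all minimized).

Four objectives are provided:

``gc``
    Sum over blocks of the absolute deviation of the block GC fraction from
    the target ``t_gc``. Zero exactly when every block sits at the target.
``codon_usage``
    Sum over CDS codons of ``Q(aa(c)) - q(c)``, where ``Q`` is the usage
    frequency of the most frequent synonym for the codon's amino acid and
    ``q`` the frequency of the codon actually used. Zero when every codon
    is the modal synonym; both frequencies come from the reference table.
``block_variance``
    Population variance of block lengths; zero for equal-length blocks.
``block_count``
    Number of blocks in the partition.

:func:`estimate_bounds` supplies the ideal/nadir values used to normalize
hypervolume: analytic where a closed form exists, and a heuristic worst-case
recoding for the GC objective (every CDS codon replaced by the synonym
farthest from the target, partitioned into the maximum admissible number of
blocks).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .core import (
    AA_TO_CODONS,
    CODON_GC,
    CODON_TO_AA,
    AnnotatedSequence,
    CodonUsageTable,
    OptimizerConfig,
    Solution,
)

__all__ = [
    "OBJECTIVE_IDS",
    "ObjectiveSpec",
    "f_gc",
    "f_codon_usage",
    "f_block_variance",
    "f_block_count",
    "estimate_bounds",
    "build_objective_specs",
]

OBJECTIVE_IDS = ("gc", "codon_usage", "block_variance", "block_count")

_G = ord("G")
_C = ord("C")


def _gc_prefix(seq: str) -> np.ndarray:
    """Prefix sums of the GC indicator; P[j] = #GC bases in seq[:j]."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    mask = (arr == _G) | (arr == _C)
    out = np.zeros(len(seq) + 1, dtype=np.int64)
    np.cumsum(mask, out=out[1:])
    return out


def f_gc(z: Solution, t_gc: float) -> float:
    """GC-content objective: sum over blocks of |t_gc - GC(block)|."""
    if not z.blocks:
        raise ValueError("solution has no blocks")
    prefix = _gc_prefix(z.sequence)
    total = 0.0
    for b in z.blocks:
        total += abs(t_gc - (prefix[b.end] - prefix[b.start]) / len(b))
    return total


def f_codon_usage(
    z: Solution,
    table: CodonUsageTable,
    cds_features: Sequence | None = None,
) -> float:
    """Codon-usage objective: sum over CDS codons of Q(aa(c)) - q(c).

    Stop codons carry no amino acid and contribute nothing.
    """
    feats = z.cds_features if cds_features is None else cds_features
    penalty = table.penalty
    total = 0.0
    for f in feats:
        cds = z.cds_sequence(f)
        for i in range(0, len(cds), 3):
            codon = cds[i : i + 3]
            if codon in CODON_TO_AA:
                total += penalty(codon)
    return total


def f_block_variance(z: Solution) -> float:
    """Population variance of block lengths."""
    if not z.blocks:
        raise ValueError("solution has no blocks")
    lengths = np.array([len(b) for b in z.blocks], dtype=float)
    return float(np.mean((lengths - lengths.mean()) ** 2))


def f_block_count(z: Solution) -> int:
    """Number of blocks in the partition."""
    return len(z.blocks)


# ---------------------------------------------------------------------------
# bounds
# ---------------------------------------------------------------------------


def _worst_gc_codon(codon: str, t_gc: float) -> str:
    """Synonym maximizing |GC - t_gc| at the codon level (deterministic)."""
    fam = AA_TO_CODONS[CODON_TO_AA[codon]]
    return max(fam, key=lambda c: (abs(CODON_GC[c] / 3.0 - t_gc), c))


def worst_case_gc_sequence(ref: AnnotatedSequence, t_gc: float) -> str:
    """Reference sequence with every CDS codon pushed away from the target.

    Each sense codon of each CDS is replaced by the synonym whose own GC
    fraction is farthest from ``t_gc``; non-coding regions are untouched.
    """
    seq = list(ref.seq)
    for feat in ref.cds_features:
        cds = list(ref.cds_sequence(feat))
        for i in range(0, len(cds), 3):
            codon = "".join(cds[i : i + 3])
            if codon in CODON_TO_AA:
                cds[i : i + 3] = _worst_gc_codon(codon, t_gc)
        recoded = "".join(cds)
        if feat.strand == "-":
            from .core import reverse_complement

            recoded = reverse_complement(recoded)
        seq[feat.start : feat.end] = recoded
    return "".join(seq)


def max_blocks_partition(length: int, l_min: int, l_max: int) -> tuple:
    """Partition into the maximum admissible number of blocks.

    Uses floor(length / l_min) blocks with lengths as equal as possible;
    every block then lies in [l_min, l_max].
    """
    from .core import Block

    if length < l_min:
        raise ValueError(f"sequence length {length} shorter than l_min={l_min}")
    nb = length // l_min
    base, rem = divmod(length, nb)
    if base + (1 if rem else 0) > l_max:
        raise ValueError("bounds admit no maximal partition")
    blocks = []
    pos = 0
    for i in range(nb):
        ln = base + (1 if i < rem else 0)
        blocks.append(Block(pos, pos + ln))
        pos += ln
    return tuple(blocks)


def estimate_bounds(
    identifier: str,
    ref: AnnotatedSequence,
    cfg: OptimizerConfig,
    table: CodonUsageTable | None = None,
) -> tuple[float, float]:
    """(ideal, nadir) bounds for one objective on a given reference design.

    * ``gc``: ideal 0; nadir from the heuristic worst-case recoding of the
      reference, split into the maximum admissible number of blocks. Being
      a heuristic, it is an estimate, not a proven bound.
    * ``codon_usage``: ideal 0; nadir with every codon at its rarest synonym.
    * ``block_variance``: ideal 0; nadir (l_max - l_min)^2 / 4.
    * ``block_count``: ideal ceil(L / l_max); nadir floor(L / l_min).
    """
    length = len(ref.seq)
    if length < cfg.l_min:
        raise ValueError(
            f"sequence length {length} shorter than l_min={cfg.l_min}"
        )
    if identifier == "gc":
        worst = worst_case_gc_sequence(ref, cfg.t_gc)
        blocks = max_blocks_partition(length, cfg.l_min, cfg.l_max)
        z = Solution(worst, blocks, ref.cds_features)
        return 0.0, f_gc(z, cfg.t_gc)
    if identifier == "codon_usage":
        if table is None:
            raise ValueError("codon_usage bounds require a usage table")
        total = 0.0
        for feat in ref.cds_features:
            cds = ref.cds_sequence(feat)
            for i in range(0, len(cds), 3):
                codon = cds[i : i + 3]
                aa = CODON_TO_AA.get(codon)
                if aa is not None:
                    total += table.penalty(table.rarest_codon(aa))
        return 0.0, total
    if identifier == "block_variance":
        return 0.0, (cfg.l_max - cfg.l_min) ** 2 / 4.0
    if identifier == "block_count":
        return float(math.ceil(length / cfg.l_max)), float(length // cfg.l_min)
    raise ValueError(f"unknown objective identifier {identifier!r}")


@dataclass(frozen=True)
class ObjectiveSpec:
    """A bound objective: identifier, evaluation callable and (ideal, nadir)."""

    identifier: str
    evaluate: Callable[[Solution], float]
    ideal: float
    nadir: float

    def __post_init__(self) -> None:
        if self.ideal > self.nadir:
            raise ValueError(
                f"{self.identifier}: ideal {self.ideal} exceeds nadir {self.nadir}"
            )


def build_objective_specs(
    names: Sequence[str],
    ref: AnnotatedSequence,
    cfg: OptimizerConfig,
    table: CodonUsageTable | None = None,
) -> list[ObjectiveSpec]:
    """Resolve objective identifiers into evaluatable specs with bounds."""
    specs: list[ObjectiveSpec] = []
    for name in names:
        if name not in OBJECTIVE_IDS:
            raise ValueError(
                f"unknown objective {name!r}; expected one of {OBJECTIVE_IDS}"
            )
        ideal, nadir = estimate_bounds(name, ref, cfg, table)
        if name == "gc":
            t = cfg.t_gc
            fn: Callable[[Solution], float] = lambda z, _t=t: f_gc(z, _t)
        elif name == "codon_usage":
            assert table is not None
            fn = lambda z, _tab=table: f_codon_usage(z, _tab)
        elif name == "block_variance":
            fn = f_block_variance
        else:
            fn = lambda z: float(f_block_count(z))
        specs.append(ObjectiveSpec(name, fn, ideal, nadir))
    return specs
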