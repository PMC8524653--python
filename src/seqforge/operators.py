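"""Stochastic edit operators: local search moves over candidate designs.

Four operators are provided, each taking a Solution and returning a new
Solution (the input is never mutated):

* :func:`op_gc` — greedy synonymous recoding of one random CDS toward the
  target GC fraction, with total drift capped at ``sigma_gc``;
* :func:`op_codon` — per-codon replacement with the modal synonym from the
  usage table, each codon independently with probability ``sigma_c``;
* :func:`op_block_split` — split one block at a cut on the ``sigma_b`` grid;
* :func:`op_block_join` — merge an adjacent block pair, re-splitting on the
  grid when the merged block would exceed ``l_max``.

Sequence operators touch exactly one CDS and never move block boundaries;
block operators never touch the sequence. All edits are silent: translations
of every CDS are preserved. New operators can be registered in
:data:`OPERATORS` under the same ``(z, ctx, rng) -> Solution`` contract.
"""

from __future__ import annotations

from typing import Callable, Mapping

import numpy as np

from .core import (
    AA_TO_CODONS,
    CODON_GC,
    CODON_TO_AA,
    Block,
    CodonUsageTable,
    OptimizerConfig,
    Solution,
    reverse_complement,
)

__all__ = [
    "OPERATORS",
    "op_gc",
    "op_codon",
    "op_block_split",
    "op_block_join",
    "random_edit",
    "dispatch_set",
]

#: codon -> highest/lowest-GC synonym (ties broken lexicographically)
_MAX_GC_SYN: Mapping[str, str] = {
    c: max(AA_TO_CODONS[aa], key=lambda s: (CODON_GC[s], s))
    for c, aa in CODON_TO_AA.items()
}
_MIN_GC_SYN: Mapping[str, str] = {
    c: min(AA_TO_CODONS[aa], key=lambda s: (CODON_GC[s], s))
    for c, aa in CODON_TO_AA.items()
}


def _codons_of(cds: str) -> list[str]:
    return [cds[i : i + 3] for i in range(0, len(cds), 3)]


def _implant_cds(z: Solution, feat, cds: str) -> Solution:
    if feat.strand == "-":
        cds = reverse_complement(cds)
    seq = z.sequence[: feat.start] + cds + z.sequence[feat.end :]
    return Solution(seq, z.blocks, z.cds_features)


def op_gc(z: Solution, cfg: OptimizerConfig, rng: np.random.Generator) -> Solution:
    """Recode one random CDS toward the GC target by synonymous moves.

    Iterated single-codon substitutions: when the CDS GC is below the
    target the highest-GC synonym of a random codon is used, above the
    target the lowest-GC one. The walk stops when the CDS GC is within
    half a codon's resolution of the target, when no move would keep the
    total drift within ``sigma_gc`` of the starting GC, or when no synonym
    improves. Returns an unmodified copy if the solution has no CDS.
    """
    if not z.cds_features:
        return z.clone()
    feat = z.cds_features[rng.integers(len(z.cds_features))]
    cds = z.cds_sequence(feat)
    codons = _codons_of(cds)
    length = len(cds)
    # position 0 (initial codon) and non-sense codons are never recoded
    candidates = [i for i in range(1, len(codons)) if codons[i] in CODON_TO_AA]
    if not candidates:
        return z.clone()
    gc = sum(CODON_GC[c] for c in codons)
    g0 = gc / length
    g = g0
    half_codon = 1.5 / length
    budget = cfg.sigma_gc
    target = cfg.t_gc
    misses, moves = 0, 0
    limit = 10 * len(codons)
    up: bool | None = None
    pool: list[int] = []
    while misses < limit and moves < limit:
        if abs(g - target) <= half_codon:
            break
        new_up = target >= g
        if up != new_up:
            # (re)build the indices whose synonyms can move GC this way
            up = new_up
            if up:
                pool = [
                    i
                    for i in candidates
                    if CODON_GC[_MAX_GC_SYN[codons[i]]] > CODON_GC[codons[i]]
                ]
            else:
                pool = [
                    i
                    for i in candidates
                    if CODON_GC[_MIN_GC_SYN[codons[i]]] < CODON_GC[codons[i]]
                ]
        if not pool:
            break  # no synonym improves
        step = (1.0 if up else -1.0) / length
        if abs(g + step - g0) > budget:
            break  # even the smallest admissible move busts the drift cap
        j = int(rng.integers(len(pool)))
        i = pool[j]
        new = _MAX_GC_SYN[codons[i]] if up else _MIN_GC_SYN[codons[i]]
        delta = (CODON_GC[new] - CODON_GC[codons[i]]) / length
        if abs(g + delta - g0) > budget:
            misses += 1
            continue
        codons[i] = new
        g += delta
        moves += 1
        misses = 0
        pool.pop(j)  # now at this direction's family extreme
    if moves == 0:
        return z.clone()
    return _implant_cds(z, feat, "".join(codons))


def op_codon(
    z: Solution,
    cfg: OptimizerConfig,
    table: CodonUsageTable,
    rng: np.random.Generator,
) -> Solution:
    """Recode a random CDS: each codon becomes the modal synonym w.p. sigma_c."""
    if not z.cds_features:
        return z.clone()
    feat = z.cds_features[rng.integers(len(z.cds_features))]
    cds = z.cds_sequence(feat)
    codons = _codons_of(cds)
    hit = rng.random(len(codons)) < cfg.sigma_c
    changed = False
    for i in range(1, len(codons)):
        codon = codons[i]
        if hit[i] and codon in CODON_TO_AA:
            modal = table.modal_codon(CODON_TO_AA[codon])
            if modal != codon:
                codons[i] = modal
                changed = True
    if not changed:
        return z.clone()
    return _implant_cds(z, feat, "".join(codons))


def _grid_cuts(length: int, cfg: OptimizerConfig) -> range:
    """Admissible left-part lengths: multiples of sigma_b with both parts
    inside [l_min, l_max]."""
    lo = max(cfg.l_min, length - cfg.l_max)
    hi = min(cfg.l_max, length - cfg.l_min)
    step = cfg.sigma_b
    first = -(-lo // step) * step  # ceil to grid
    if first > hi:
        return range(0)
    return range(first, hi + 1, step)


def op_block_split(
    z: Solution, cfg: OptimizerConfig, rng: np.random.Generator
) -> Solution:
    """Split one random block at a uniformly chosen grid cut.

    Only blocks admitting a cut with both parts in [l_min, l_max] are
    eligible; if none exists the solution is returned unmodified.
    """
    options = [
        (idx, cuts)
        for idx, b in enumerate(z.blocks)
        if len(cuts := _grid_cuts(len(b), cfg)) > 0
    ]
    if not options:
        return z.clone()
    idx, cuts = options[rng.integers(len(options))]
    left = cuts[rng.integers(len(cuts))]
    b = z.blocks[idx]
    new_blocks = (
        z.blocks[:idx]
        + (Block(b.start, b.start + left), Block(b.start + left, b.end))
        + z.blocks[idx + 1 :]
    )
    return Solution(z.sequence, new_blocks, z.cds_features)


def op_block_join(
    z: Solution, cfg: OptimizerConfig, rng: np.random.Generator
) -> Solution:
    """Merge a random adjacent block pair.

    If the merged block fits within ``l_max`` the pair becomes one block;
    otherwise the merged interval is re-split at a grid cut (the boundary
    moves but the count is unchanged). Single-block solutions, and merges
    admitting no grid re-split, are returned unmodified.
    """
    if len(z.blocks) < 2:
        return z.clone()
    i = int(rng.integers(len(z.blocks) - 1))
    a, b = z.blocks[i], z.blocks[i + 1]
    merged = Block(a.start, b.end)
    if len(merged) <= cfg.l_max:
        new_blocks = z.blocks[:i] + (merged,) + z.blocks[i + 2 :]
    else:
        cuts = _grid_cuts(len(merged), cfg)
        if len(cuts) == 0:
            return z.clone()
        left = cuts[rng.integers(len(cuts))]
        new_blocks = (
            z.blocks[:i]
            + (
                Block(merged.start, merged.start + left),
                Block(merged.start + left, merged.end),
            )
            + z.blocks[i + 2 :]
        )
    return Solution(z.sequence, new_blocks, z.cds_features)


OPERATORS: dict[str, Callable] = {
    "gc": op_gc,
    "codon": op_codon,
    "block_split": op_block_split,
    "block_join": op_block_join,
}


def dispatch_set(objectives) -> tuple[str, ...]:
    """Operator identifiers relevant to a set of objectives.

    Block operators are always active; the GC (codon) recoding operator is
    active only when the GC (codon-usage) objective is configured.
    """
    ops: list[str] = []
    if "gc" in objectives:
        ops.append("gc")
    if "codon_usage" in objectives:
        ops.append("codon")
    ops += ["block_split", "block_join"]
    return tuple(ops)


def random_edit(
    z: Solution,
    cfg: OptimizerConfig,
    table: CodonUsageTable | None,
    rng: np.random.Generator,
) -> Solution:
    """Apply exactly one operator drawn uniformly from the relevant set."""
    ops = dispatch_set(cfg.objectives)
    name = ops[rng.integers(len(ops))]
    if name == "codon":
        if table is None:
            raise ValueError("codon operator requires a usage table")
        return op_codon(z, cfg, table, rng)
    return OPERATORS[name](z, cfg, rng)
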