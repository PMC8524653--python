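"""Evolutionary multi-objective optimizer over candidate DNA designs.

The main loop (:func:`run`) maintains a pool of ``n`` solutions. Each
iteration clones the pool, applies one random edit to each clone, evaluates
the configured objectives, and selects ``n`` survivors from the combined
2n solutions by (domination rank ascending, crowding distance descending).
All evaluated solutions also feed a bounded non-dominated archive of
capacity ``m >> n``, so non-dominated designs discarded by selection are
not lost.

Ranking counts, for each solution, how many others dominate it; rank 0 is
the current non-dominated set. Crowding distance follows the usual
normalized nearest-neighbour gap per objective, with extreme solutions
assigned infinite distance; normalization uses the running per-objective
extremes observed so far in the run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .core import (
    AnnotatedSequence,
    Block,
    CodonUsageTable,
    OptimizerConfig,
    Solution,
)
from .objectives import ObjectiveSpec, build_objective_specs
from .operators import random_edit

__all__ = [
    "dominates",
    "domination_rank",
    "crowding_distance",
    "select",
    "initialize_pool",
    "ParetoArchive",
    "archive_update",
    "RunResult",
    "run",
]


def dominates(u: np.ndarray, v: np.ndarray) -> bool:
    """True iff u <= v componentwise with strict improvement somewhere."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"objective vectors differ in length: {u.shape} vs {v.shape}")
    return bool(np.all(u <= v) and np.any(u < v))


def _domination_matrix(F: np.ndarray) -> np.ndarray:
    """D[i, j] = True iff vector i dominates vector j."""
    le = np.all(F[:, None, :] <= F[None, :, :], axis=-1)
    lt = np.any(F[:, None, :] < F[None, :, :], axis=-1)
    return le & lt


def domination_rank(F: np.ndarray) -> np.ndarray:
    """rank[i] = number of pool members dominating member i (0 = non-dominated)."""
    F = np.atleast_2d(np.asarray(F, dtype=float))
    if F.shape[0] == 0:
        return np.zeros(0, dtype=int)
    return _domination_matrix(F).sum(axis=0).astype(int)


def crowding_distance(
    F: np.ndarray,
    f_min: np.ndarray | None = None,
    f_max: np.ndarray | None = None,
) -> np.ndarray:
    """Crowding distance of each member of a set of objective vectors.

    For each objective, members are sorted and the normalized gap between
    each member's two neighbours is accumulated; the two extreme members
    get infinite distance. ``f_min``/``f_max`` normalize each objective
    (defaults: the extremes of ``F`` itself); a degenerate objective
    (zero span) contributes nothing.
    """
    F = np.atleast_2d(np.asarray(F, dtype=float))
    n, k = F.shape
    if n == 0:
        return np.zeros(0)
    f_min = F.min(axis=0) if f_min is None else np.asarray(f_min, dtype=float)
    f_max = F.max(axis=0) if f_max is None else np.asarray(f_max, dtype=float)
    d = np.zeros(n)
    for i in range(k):
        span = f_max[i] - f_min[i]
        if span <= 0:
            continue
        order = np.argsort(F[:, i], kind="stable")
        vals = F[order, i]
        d[order[0]] = np.inf
        d[order[-1]] = np.inf
        if n > 2:
            d[order[1:-1]] += (vals[2:] - vals[:-2]) / span
    return d


def select(
    parents: Sequence[Solution],
    offspring: Sequence[Solution],
    n: int,
    f_min: np.ndarray | None = None,
    f_max: np.ndarray | None = None,
) -> list[Solution]:
    """Survivor selection: top n of parents+offspring by (rank, crowding).

    Ranks are recomputed on the union; crowding distance is computed within
    each rank group, normalized by the running objective extremes. Ties are
    broken by position (stable sort) for reproducibility.
    """
    union = list(parents) + list(offspring)
    if any(z.objectives is None for z in union):
        raise ValueError("all solutions must be evaluated before selection")
    F = np.vstack([z.objectives for z in union])
    ranks = domination_rank(F)
    crowd = np.zeros(len(union))
    for r in np.unique(ranks):
        idx = np.flatnonzero(ranks == r)
        crowd[idx] = crowding_distance(F[idx], f_min, f_max)
    order = sorted(range(len(union)), key=lambda i: (ranks[i], -crowd[i]))
    return [union[i] for i in order[:n]]


def random_partition(
    length: int, cfg: OptimizerConfig, rng: np.random.Generator
) -> tuple[Block, ...]:
    """A random admissible partition of ``[0, length)`` into blocks.

    The block count is drawn so the mean block length is uniform over
    [l_min, l_max]; boundaries start equal and are jittered in sigma_b
    steps while keeping every block inside the bounds.
    """
    nb_lo = -(-length // cfg.l_max)  # ceil
    nb_hi = length // cfg.l_min
    if nb_hi < 1:
        raise ValueError(f"sequence length {length} shorter than l_min={cfg.l_min}")
    if nb_lo > nb_hi:
        raise ValueError(
            f"no partition of {length} nt into blocks of {cfg.l_min}-{cfg.l_max} nt"
        )
    mean_target = rng.uniform(cfg.l_min, cfg.l_max)
    nb = int(np.clip(round(length / mean_target), nb_lo, nb_hi))
    base, rem = divmod(length, nb)
    lengths = [base + 1 if i < rem else base for i in range(nb)]
    for _ in range(2 * nb):
        if nb == 1:
            break
        i = int(rng.integers(nb - 1))
        shift = int(cfg.sigma_b) * (1 if rng.random() < 0.5 else -1)
        if (
            cfg.l_min <= lengths[i] + shift <= cfg.l_max
            and cfg.l_min <= lengths[i + 1] - shift <= cfg.l_max
        ):
            lengths[i] += shift
            lengths[i + 1] -= shift
    blocks = []
    pos = 0
    for ln in lengths:
        blocks.append(Block(pos, pos + ln))
        pos += ln
    return tuple(blocks)


def initialize_pool(
    ref: AnnotatedSequence, cfg: OptimizerConfig, rng: np.random.Generator
) -> list[Solution]:
    """n clones of the reference, each with an independent random partition."""
    return [
        Solution(ref.seq, random_partition(len(ref.seq), cfg, rng), ref.cds_features)
        for _ in range(cfg.n)
    ]


@dataclass
class ParetoArchive:
    """Bounded store of mutually non-dominated solutions.

    Merging new candidates removes dominated members; when capacity is
    exceeded, members with the smallest crowding distance are discarded.
    Exact duplicates (same sequence and partition) are kept once.
    """

    capacity: int
    solutions: list[Solution] = field(default_factory=list)

    def objective_matrix(self) -> np.ndarray:
        if not self.solutions:
            return np.zeros((0, 0))
        return np.vstack([z.objectives for z in self.solutions])

    def update(
        self,
        candidates: Sequence[Solution],
        f_min: np.ndarray | None = None,
        f_max: np.ndarray | None = None,
    ) -> None:
        merged = list(self.solutions)
        seen = {(z.sequence, z.blocks) for z in merged}
        for z in candidates:
            if z.objectives is None:
                raise ValueError("archive candidates must be evaluated")
            key = (z.sequence, z.blocks)
            if key not in seen:
                merged.append(z)
                seen.add(key)
        if not merged:
            return
        F = np.vstack([z.objectives for z in merged])
        keep = np.flatnonzero(domination_rank(F) == 0)
        survivors = [merged[i] for i in keep]
        if len(survivors) > self.capacity:
            crowd = crowding_distance(F[keep], f_min, f_max)
            order = sorted(range(len(survivors)), key=lambda i: -crowd[i])
            survivors = [survivors[i] for i in sorted(order[: self.capacity])]
        self.solutions = survivors

    def __len__(self) -> int:
        return len(self.solutions)


def archive_update(
    archive: ParetoArchive,
    candidates: Sequence[Solution],
    f_min: np.ndarray | None = None,
    f_max: np.ndarray | None = None,
) -> ParetoArchive:
    """Functional wrapper around :meth:`ParetoArchive.update`."""
    archive.update(candidates, f_min, f_max)
    return archive


class RunResult(NamedTuple):
    pool: list[Solution]
    archive: ParetoArchive
    history: pd.DataFrame
    specs: list[ObjectiveSpec]


def _evaluate(
    solutions: Sequence[Solution], specs: Sequence[ObjectiveSpec]
) -> None:
    for z in solutions:
        if z.objectives is None:
            z.objectives = np.array([s.evaluate(z) for s in specs], dtype=float)


def run(
    ref: AnnotatedSequence,
    cfg: OptimizerConfig,
    table: CodonUsageTable | None = None,
    evaluation_log: list[Solution] | None = None,
    progress: Callable[[int], None] | None = None,
) -> RunResult:
    """Execute the full optimization loop.

    Parameters
    ----------
    ref : reference design (sequence plus CDS annotations).
    cfg : optimizer configuration; ``cfg.seed`` fixes all randomness, so
        identical configurations give bit-identical results.
    table : codon usage table; required when the codon-usage objective is
        configured.
    evaluation_log : optional list that every evaluated solution is
        appended to (diagnostic; lets callers audit the archive against
        the complete evaluation history).
    progress : optional callback invoked with the iteration number.

    Returns
    -------
    RunResult
        Final pool, archive, per-iteration objective statistics (tidy
        table: iteration, objective, min, mean, max) and the resolved
        objective specs with their ideal/nadir bounds.
    """
    if not cfg.objectives:
        raise ValueError("at least one objective must be configured")
    if "codon_usage" in cfg.objectives and table is None:
        raise ValueError("codon_usage objective requires a usage table")
    rng = np.random.default_rng(cfg.seed)
    specs = build_objective_specs(cfg.objectives, ref, cfg, table)
    pool = initialize_pool(ref, cfg, rng)
    _evaluate(pool, specs)
    if evaluation_log is not None:
        evaluation_log.extend(pool)
    F = np.vstack([z.objectives for z in pool])
    f_min = F.min(axis=0)
    f_max = F.max(axis=0)
    archive = ParetoArchive(cfg.m)
    archive.update(pool, f_min, f_max)
    rows = []

    def record(t: int, members: Sequence[Solution]) -> None:
        M = np.vstack([z.objectives for z in members])
        for j, spec in enumerate(specs):
            rows.append(
                {
                    "iteration": t,
                    "objective": spec.identifier,
                    "min": M[:, j].min(),
                    "mean": M[:, j].mean(),
                    "max": M[:, j].max(),
                }
            )

    record(0, pool)
    for t in range(1, cfg.t_max + 1):
        offspring = [random_edit(z, cfg, table, rng) for z in pool]
        _evaluate(offspring, specs)
        if evaluation_log is not None:
            evaluation_log.extend(offspring)
        R = np.vstack([z.objectives for z in offspring])
        f_min = np.minimum(f_min, R.min(axis=0))
        f_max = np.maximum(f_max, R.max(axis=0))
        pool = select(pool, offspring, cfg.n, f_min, f_max)
        archive.update(pool + offspring, f_min, f_max)
        record(t, pool)
        if progress is not None:
            progress(t)
    history = pd.DataFrame(rows, columns=["iteration", "objective", "min", "mean", "max"])
    return RunResult(pool=pool, archive=archive, history=history, specs=specs)
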