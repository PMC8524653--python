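"""Design-quality studies: normalized hypervolume over benchmark constructs.

A thin driver that wires the benchmark generator, the optimizer and the
hypervolume metric together: generate a set of synthetic constructs, run
the optimizer on a design problem for several seeds, and score each final
archive by its normalized hypervolume against the analytic/heuristic
ideal–nadir bounds.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .benchmark import BenchmarkSpec, design_problem, generate_construct
from .core import AnnotatedSequence, CodonUsageTable, OptimizerConfig
from .metrics import non_dominated_filter, normalized_hypervolume
from .optimizer import run

__all__ = ["generate_study_constructs", "archive_front", "design_quality_study"]


def generate_study_constructs(
    num_constructs: int, num_tus: int, seed: int
) -> list[AnnotatedSequence]:
    """Independent benchmark constructs from one master seed."""
    rng = np.random.default_rng(seed)
    return [
        generate_construct(BenchmarkSpec(num_tus=num_tus), rng)
        for _ in range(num_constructs)
    ]


def archive_front(result) -> np.ndarray:
    """Objective vectors of a run's archive, filtered to the front."""
    return non_dominated_filter(result.archive.objective_matrix())


def design_quality_study(
    problem_ids,
    constructs,
    seeds,
    base_cfg: OptimizerConfig | None = None,
    table: CodonUsageTable | None = None,
    sigma_c: float | None = None,
) -> pd.DataFrame:
    """Run each problem on each construct for each seed; score NV per run.

    Returns a tidy table (problem, construct, seed, nv, front_size). The
    codon usage table is required for problems including the codon-usage
    objective; ``sigma_c`` optionally overrides the codon operator's
    recoding probability.
    """
    base_cfg = base_cfg or OptimizerConfig()
    rows = []
    for pid in problem_ids:
        objectives = design_problem(pid)
        cfg0 = base_cfg.with_(objectives=objectives)
        if sigma_c is not None:
            cfg0 = cfg0.with_(sigma_c=sigma_c)
        for ci, ref in enumerate(constructs):
            for seed in seeds:
                cfg = cfg0.with_(seed=int(seed))
                result = run(ref, cfg, table=table)
                ideal = np.array([s.ideal for s in result.specs])
                nadir = np.array([s.nadir for s in result.specs])
                front = archive_front(result)
                nv = normalized_hypervolume(front, ideal, nadir)
                rows.append(
                    {
                        "problem": pid,
                        "construct": ci,
                        "seed": int(seed),
                        "nv": nv,
                        "front_size": front.shape[0],
                    }
                )
    return pd.DataFrame(rows)
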