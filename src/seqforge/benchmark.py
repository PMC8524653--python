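"""Synthetic construct generator and the four standard design problems.

Constructs emulate modular designs: a chain of transcription units (TUs),
each a promoter + CDS + terminator. Component lengths are Poisson
distributed — regulatory regions with a mean of 500 bp, CDS length as a
Poisson(250) codon count (roughly an average bacterial gene) — and each
component's GC target is drawn from Beta(k*t, k*(1-t)) with k=150 and
t=0.55, giving components centred at 55% GC with ~4% spread.

Regulatory sequence is sampled per-base (each position G/C with the target
probability); CDS sequence is sampled per-codon with an exponential tilt on
the codon GC count calibrated so the expected GC matches the target, which
respects the genetic code while steering composition. CDSs start with ATG
and end with a single stop codon, included in the codon count.

The four benchmark design problems pair the GC objective with different
manufacturing objectives: P1 = {gc, block_count}, P2 = {gc,
block_variance}, P3 = {gc, block_variance, block_count}, P4 = {gc,
codon_usage, block_count}.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .core import (
    AA_TO_CODONS,
    CODON_GC,
    AnnotatedSequence,
    CDSAnnotation,
)

__all__ = [
    "BenchmarkSpec",
    "DESIGN_PROBLEMS",
    "random_dna_with_gc",
    "random_cds",
    "generate_construct",
    "generate_dataset",
    "design_problem",
]

DESIGN_PROBLEMS = {
    "P1": ("gc", "block_count"),
    "P2": ("gc", "block_variance"),
    "P3": ("gc", "block_variance", "block_count"),
    "P4": ("gc", "codon_usage", "block_count"),
}

_STOPS = ("TAA", "TAG", "TGA")
_AAS = tuple(sorted(AA_TO_CODONS))  # the 20 amino acids


@dataclass(frozen=True)
class BenchmarkSpec:
    """Generator parameters for one synthetic construct.

    ``lambda_codons`` and ``lambda_regulatory`` are the Poisson means of
    the CDS codon count and of promoter/terminator lengths (bp);
    ``beta_k``/``beta_t`` parameterize the per-component GC-target Beta
    distribution as Beta(k*t, k*(1-t)).
    """

    num_tus: int = 5
    lambda_codons: float = 250.0
    lambda_regulatory: float = 500.0
    beta_k: float = 150.0
    beta_t: float = 0.55
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.num_tus < 1:
            raise ValueError("num_tus must be >= 1")
        if not (0.0 < self.beta_t < 1.0):
            raise ValueError("beta_t must lie in (0, 1)")
        if self.beta_k <= 0:
            raise ValueError("beta_k must be positive")


def random_dna_with_gc(
    length: int, gc_target: float, rng: np.random.Generator
) -> str:
    """Random DNA with each base G/C with probability ``gc_target``.

    Within the GC and AT pairs the two bases are equiprobable.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if not (0.0 <= gc_target <= 1.0):
        raise ValueError("gc_target must lie in [0, 1]")
    strong = rng.random(length) < gc_target
    pick = rng.integers(2, size=length)
    codes = np.where(
        strong,
        np.where(pick == 0, ord("G"), ord("C")),
        np.where(pick == 0, ord("A"), ord("T")),
    ).astype(np.uint8)
    return codes.tobytes().decode("ascii")


# per-amino-acid codon GC counts, for the tilted sampler
_FAM_CODONS = {aa: np.array(AA_TO_CODONS[aa], dtype=object) for aa in _AAS}
_FAM_GC = {
    aa: np.array([CODON_GC[c] for c in AA_TO_CODONS[aa]], dtype=float)
    for aa in _AAS
}


def _expected_gc(theta: float) -> float:
    """Expected codon GC fraction under exp(theta * gc_count) tilting,
    averaging uniformly over the 20 amino acids."""
    total = 0.0
    for aa in _AAS:
        w = np.exp(theta * _FAM_GC[aa])
        total += float(np.dot(w, _FAM_GC[aa]) / w.sum())
    return total / (3 * len(_AAS))


def _solve_tilt(gc_target: float) -> float:
    lo, hi = -30.0, 30.0
    if gc_target <= _expected_gc(lo):
        return lo
    if gc_target >= _expected_gc(hi):
        return hi
    return float(brentq(lambda t: _expected_gc(t) - gc_target, lo, hi, xtol=1e-6))


def random_cds(n_codons: int, gc_target: float, rng: np.random.Generator) -> str:
    """Random CDS of ``n_codons`` codons with GC steered toward a target.

    Starts with ATG, ends with one stop codon; interior amino acids are
    uniform over the 20 and each synonym is drawn with probability
    proportional to exp(theta * GC(codon)), with theta calibrated so the
    expected codon GC matches ``gc_target`` (clamped to the achievable
    range of the code).
    """
    if n_codons < 3:
        raise ValueError("a CDS needs at least 3 codons (start, one aa, stop)")
    theta = _solve_tilt(gc_target)
    weights = {}
    for aa in _AAS:
        w = np.exp(theta * _FAM_GC[aa])
        weights[aa] = w / w.sum()
    interior = rng.choice(len(_AAS), size=n_codons - 2)
    parts = ["ATG"]
    for ai in interior:
        aa = _AAS[ai]
        fam = _FAM_CODONS[aa]
        parts.append(fam[rng.choice(len(fam), p=weights[aa])])
    parts.append(_STOPS[rng.integers(len(_STOPS))])
    return "".join(parts)


def generate_construct(
    spec: BenchmarkSpec, rng: np.random.Generator | None = None
) -> AnnotatedSequence:
    """One synthetic construct: ``num_tus`` promoter+CDS+terminator units."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    alpha = spec.beta_k * spec.beta_t
    beta = spec.beta_k * (1.0 - spec.beta_t)
    parts: list[str] = []
    features: list[CDSAnnotation] = []
    pos = 0
    for _ in range(spec.num_tus):
        p_len = max(1, int(rng.poisson(spec.lambda_regulatory)))
        promoter = random_dna_with_gc(p_len, float(rng.beta(alpha, beta)), rng)
        n_codons = max(3, int(rng.poisson(spec.lambda_codons)))
        cds = random_cds(n_codons, float(rng.beta(alpha, beta)), rng)
        t_len = max(1, int(rng.poisson(spec.lambda_regulatory)))
        terminator = random_dna_with_gc(t_len, float(rng.beta(alpha, beta)), rng)
        parts += [promoter, cds, terminator]
        cds_start = pos + p_len
        features.append(CDSAnnotation(cds_start, cds_start + len(cds), "+"))
        pos = cds_start + len(cds) + t_len
    return AnnotatedSequence("".join(parts), tuple(features))


def generate_dataset(
    tu_counts=(5, 10, 20),
    per_count: int = 10,
    seed: int = 0,
    outdir: str | Path | None = None,
) -> tuple[list[AnnotatedSequence], pd.DataFrame]:
    """A reproducible dataset of constructs, optionally written as GenBank.

    Returns the constructs plus a manifest table (name, TU count, length,
    CDS count, GC fraction); with ``outdir`` set, each construct is written
    to ``<outdir>/<name>.gb`` and the manifest records the file name.
    """
    rng = np.random.default_rng(seed)
    constructs: list[AnnotatedSequence] = []
    rows = []
    for count in tu_counts:
        for i in range(per_count):
            spec = BenchmarkSpec(num_tus=count)
            ann = generate_construct(spec, rng)
            name = f"construct_{count:02d}tu_{i + 1:02d}"
            ann = AnnotatedSequence(ann.seq, ann.cds_features, name=name)
            constructs.append(ann)
            row = {
                "name": name,
                "tu_count": count,
                "length": len(ann.seq),
                "n_cds": len(ann.cds_features),
                "gc": round((ann.seq.count("G") + ann.seq.count("C")) / len(ann.seq), 4),
            }
            if outdir is not None:
                from .io import write_genbank

                path = Path(outdir) / f"{name}.gb"
                path.parent.mkdir(parents=True, exist_ok=True)
                write_genbank(path, ann)
                row["file"] = path.name
            rows.append(row)
    return constructs, pd.DataFrame(rows)


def design_problem(problem_id: str) -> tuple[str, ...]:
    """Objective identifiers of one of the standard problems P1-P4."""
    try:
        return DESIGN_PROBLEMS[problem_id]
    except KeyError:
        raise ValueError(
            f"unknown design problem {problem_id!r}; expected one of "
            f"{sorted(DESIGN_PROBLEMS)}"
        ) from None
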