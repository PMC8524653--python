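"""File I/O: GenBank in/out, codon usage tables, YAML run configuration,
and fragment export with Gibson-assembly overlaps.

GenBank CDS locations (1-based, inclusive) are converted to 0-based
half-open intervals on read and back on write. Fragment export extends
each block forward into its successor by the configured overlap length,
so consecutive fragments share exact terminal homology and overlap-merging
them reconstructs the design sequence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .core import (
    AnnotatedSequence,
    CDSAnnotation,
    CodonUsageTable,
    DNA_ALPHABET,
    OptimizerConfig,
    Solution,
)

__all__ = [
    "read_genbank",
    "write_genbank",
    "read_codon_usage",
    "write_codon_usage",
    "export_design",
    "RunConfig",
    "load_run_config",
]


def read_genbank(path: str | Path) -> AnnotatedSequence:
    """Read a GenBank record into an :class:`AnnotatedSequence`.

    The sequence is upper-cased; ambiguity codes are rejected. CDS
    features are extracted with their strand; a record without any CDS is
    usable for block-only objectives but triggers a warning.
    """
    record = SeqIO.read(str(path), "genbank")
    seq = str(record.seq).upper()
    if not DNA_ALPHABET.issuperset(seq):
        bad = sorted(set(seq) - DNA_ALPHABET)
        raise ValueError(
            f"{path}: sequence contains ambiguity codes or non-DNA characters: {bad}"
        )
    features = []
    for feat in record.features:
        if feat.type != "CDS":
            continue
        start = int(feat.location.start)
        end = int(feat.location.end)
        strand = "-" if feat.location.strand == -1 else "+"
        features.append(CDSAnnotation(start, end, strand))
    if not features:
        warnings.warn(
            f"{path}: no CDS features found; sequence objectives will be inert",
            stacklevel=2,
        )
    return AnnotatedSequence(seq, tuple(features), name=record.id or "construct")


def _record_from(ann: AnnotatedSequence, blocks=None) -> SeqRecord:
    record = SeqRecord(
        Seq(ann.seq),
        id=ann.name[:16] or "construct",
        name=ann.name[:16] or "construct",
        description="",
        annotations={"molecule_type": "DNA"},
    )
    for f in ann.cds_features:
        record.features.append(
            SeqFeature(
                FeatureLocation(f.start, f.end, strand=-1 if f.strand == "-" else 1),
                type="CDS",
            )
        )
    if blocks:
        for i, b in enumerate(blocks):
            record.features.append(
                SeqFeature(
                    FeatureLocation(b.start, b.end, strand=1),
                    type="misc_feature",
                    qualifiers={"label": [f"block_{i + 1:03d}"]},
                )
            )
    return record


def write_genbank(
    path: str | Path, design: AnnotatedSequence | Solution, name: str | None = None
) -> None:
    """Write a reference design or a solution (with block features) as GenBank."""
    if isinstance(design, Solution):
        ann = AnnotatedSequence(
            design.sequence, design.cds_features, name=name or "design"
        )
        record = _record_from(ann, design.blocks)
    else:
        if name is not None:
            design = AnnotatedSequence(design.seq, design.cds_features, name=name)
        record = _record_from(design)
    SeqIO.write([record], str(path), "genbank")


def read_codon_usage(path: str | Path) -> CodonUsageTable:
    """Read a two-column (codon, relative frequency) text file.

    Lines starting with '#' and blank lines are ignored; columns are
    whitespace-separated. Frequencies are re-normalized within each
    amino-acid family, so raw counts are accepted too.
    """
    counts: dict[str, float] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 2:
            raise ValueError(f"{path}: malformed line {line!r}")
        counts[fields[0].upper().replace("U", "T")] = float(fields[1])
    return CodonUsageTable.from_counts(counts)


def write_codon_usage(path: str | Path, table: CodonUsageTable) -> None:
    lines = ["# codon\trelative_frequency"]
    for codon in sorted(table.frequencies):
        lines.append(f"{codon}\t{table.frequencies[codon]:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")


def export_design(
    z: Solution,
    cfg: OptimizerConfig,
    outdir: str | Path,
    name: str = "design",
) -> list[Path]:
    """Write a solution as GenBank plus per-fragment FASTA.

    Fragment i is block i extended ``cfg.overlap`` nt into the next block
    (the last block is unextended), so adjacent fragments share an exact
    terminal overlap for Gibson assembly.
    """
    if cfg.overlap >= min(len(b) for b in z.blocks):
        raise ValueError(
            f"overlap {cfg.overlap} must be shorter than the smallest block"
        )
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gb_path = outdir / f"{name}.gb"
    write_genbank(gb_path, z, name=name)
    records = []
    for i, b in enumerate(z.blocks):
        end = b.end + (cfg.overlap if i < len(z.blocks) - 1 else 0)
        records.append(
            SeqRecord(
                Seq(z.sequence[b.start : end]),
                id=f"{name}_fragment_{i + 1:03d}",
                description=f"block {b.start}..{b.end} overlap {cfg.overlap}",
            )
        )
    fa_path = outdir / f"{name}_fragments.fasta"
    SeqIO.write(records, str(fa_path), "fasta")
    return [gb_path, fa_path]


@dataclass
class RunConfig:
    """A full run specification loaded from YAML.

    Schema (all optimizer/operator keys optional, with package defaults)::

        input: path/to/construct.gb
        output: results/
        problem: P1                  # or: objectives: [gc, block_count]
        gc_target: 0.55
        codon_usage_table: path.tsv  # omit for a seeded random table
        optimizer: {n: 100, t_max: 200, archive: 100, seed: 0}
        operators: {sigma_gc: 0.05, sigma_c: 0.25, sigma_b: 100}
        blocks: {l_min: 500, l_max: 3000, overlap: 40}
    """

    input: Path
    output: Path = field(default_factory=lambda: Path("results"))
    optimizer: OptimizerConfig = field(default_factory=OptimizerConfig)
    codon_usage_table: Path | None = None
    raw: dict = field(default_factory=dict)


def load_run_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run configuration."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if "input" not in raw:
        raise ValueError(f"{path}: missing required key 'input'")
    base = Path(path).parent
    input_path = (base / raw["input"]).resolve()
    if not input_path.exists():
        raise FileNotFoundError(f"{path}: input file {input_path} does not exist")
    if "problem" in raw:
        from .benchmark import design_problem

        objectives = design_problem(str(raw["problem"]))
    elif "objectives" in raw:
        objectives = tuple(raw["objectives"])
    else:
        objectives = ("gc", "block_count")
    opt = raw.get("optimizer", {}) or {}
    ops = raw.get("operators", {}) or {}
    blk = raw.get("blocks", {}) or {}
    cfg = OptimizerConfig(
        n=int(opt.get("n", 100)),
        t_max=int(opt.get("t_max", 200)),
        m=int(opt.get("archive", max(100, int(opt.get("n", 100))))),
        l_min=int(blk.get("l_min", 500)),
        l_max=int(blk.get("l_max", 3000)),
        sigma_gc=float(ops.get("sigma_gc", 0.05)),
        sigma_c=float(ops.get("sigma_c", 0.25)),
        sigma_b=int(ops.get("sigma_b", 100)),
        t_gc=float(raw.get("gc_target", 0.55)),
        overlap=int(blk.get("overlap", 40)),
        objectives=objectives,
        seed=int(opt.get("seed", 0)),
    )
    table_path = raw.get("codon_usage_table")
    if table_path is not None:
        table_path = (base / table_path).resolve()
        if not table_path.exists():
            raise FileNotFoundError(
                f"{path}: codon usage table {table_path} does not exist"
            )
    output = base / raw.get("output", "results")
    return RunConfig(
        input=input_path,
        output=output,
        optimizer=cfg,
        codon_usage_table=table_path,
        raw=raw,
    )
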