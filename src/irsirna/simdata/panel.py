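"""Synthetic accession panels carrying structural variants of the IR locus.

Each accession starts from the same base genome (same seed-derived sequence)
and applies a random subset of allowed edits -- intergenic deletion,
arm-internal inversion, intron tandem-repeat copy-number change, TE-fragment
insertion -- so that accessions differ from the base only by the planted
variants.  Per-accession truth records first-intron lengths and a structural
class label.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from irsirna.intervals import GenomicInterval, revcomp
from irsirna.seqio import Gff3Feature
from irsirna.simdata.config import ConfigurationError, GroundTruth, SimulationConfig
from irsirna.simdata.genome import generate_ir_genome, random_seq

#: Edit type -> structural class label recorded in truth (and expected from
#: sequence-level comparison against the base genome).
CLASS_LABELS = {
    "intergenic_deletion": "shortened-spacer",
    "arm_inversion": "inversion",
    "intron_copy_change": "intron-repeat-variant",
    "te_insertion": "te-insertion",
}

DEFAULT_VARIANT_SPEC = [
    {"type": "intergenic_deletion", "length": 2700},
    {"type": "arm_inversion", "length": 1000},
    {"type": "intron_copy_change", "gene": "geneB", "copies": 7},
    {"type": "te_insertion", "length": 400},
]

PANEL_TRUTH_COLUMNS = [
    "accession",
    "intron1_length_geneA",
    "intron1_length_geneB",
    "symmetric",
    "structural_class",
    "edits",
]


@dataclass
class _SpliceOp:
    """Replace base-genome interval [start, end) with ``replacement``."""

    start: int
    end: int
    replacement: str

    @property
    def delta(self) -> int:
        return len(self.replacement) - (self.end - self.start)


def _apply_ops(seq: str, ops: list[_SpliceOp]) -> str:
    for op in sorted(ops, key=lambda o: o.start, reverse=True):
        seq = seq[: op.start] + op.replacement + seq[op.end :]
    return seq


def _shift_interval(start: int, end: int, ops: list[_SpliceOp]) -> tuple[int, int]:
    """Map a base-genome interval into edited coordinates.

    Ops are either entirely inside the interval (it stretches/shrinks) or
    entirely outside it (it shifts); partial overlap is a construction error.
    """
    shift = stretch = 0
    for op in ops:  # op coordinates are all in base-genome space
        if op.end <= start:
            shift += op.delta
        elif op.start >= end:
            continue
        elif start <= op.start and op.end <= end:
            stretch += op.delta
        else:
            raise ConfigurationError("edit partially overlaps an annotated feature")
    return start + shift, end + shift + stretch


@dataclass
class AccessionRecord:
    name: str
    genome: dict[str, str]
    features: list[Gff3Feature]
    intron1_length: dict[str, int]
    symmetric: bool
    structural_class: str
    edits: list[str] = field(default_factory=list)


def _ops_for_edits(
    edits: list[dict], truth: GroundTruth, rng: np.random.Generator
) -> list[_SpliceOp]:
    ops: list[_SpliceOp] = []
    for edit in edits:
        kind = edit["type"]
        if kind == "intergenic_deletion":
            length = edit.get("length", 2700)
            offset = 60
            start = truth.spacer.start + offset
            if start + length > truth.spacer.end:
                raise ConfigurationError(
                    f"intergenic deletion of {length} bp does not fit in the "
                    f"{len(truth.spacer)}-bp spacer"
                )
            ops.append(_SpliceOp(start, start + length, ""))
        elif kind == "te_insertion":
            length = edit.get("length", 400)
            pos = truth.spacer.start + 20
            ops.append(_SpliceOp(pos, pos, random_seq(rng, length)))
        elif kind == "arm_inversion":
            length = edit.get("length", 1000)
            gene_b = truth.genes["geneB"]
            start = gene_b.exon1.start + 600
            if start + length > gene_b.exon1.end + gene_b.intron1_length:
                raise ConfigurationError("arm inversion block exceeds the arm")
            ops.append(_SpliceOp(start, start + length, ""))  # placeholder, filled later
        elif kind == "intron_copy_change":
            gene = truth.genes[edit.get("gene", "geneB")]
            copies = edit["copies"]
            block = gene.intron_repeat_interval
            unit = (
                truth.intron_repeat_unit
                if gene.strand == "+"
                else revcomp(truth.intron_repeat_unit)
            )
            ops.append(_SpliceOp(block.start, block.end, unit * copies))
        else:
            raise ConfigurationError(f"unknown edit type {kind!r}")
    return ops


def generate_accession_panel(
    config: SimulationConfig,
    n_accessions: int,
    variant_spec: list[dict] | None = None,
    seed: int | None = None,
) -> tuple[list[AccessionRecord], pd.DataFrame, tuple]:
    """Panel of accession genomes with planted structural variants.

    Returns ``(records, panel_truth, (base_genome, base_features,
    base_truth))``.  Each accession applies an independent random subset of
    the allowed edits; the edit positions are fixed so that the panel truth
    is exactly recoverable.
    """
    variant_spec = DEFAULT_VARIANT_SPEC if variant_spec is None else variant_spec
    base_genome, base_features, truth = generate_ir_genome(config)
    seq = base_genome[truth.chrom]
    rng = config.rng("panel") if seed is None else np.random.default_rng([4, seed])

    records: list[AccessionRecord] = []
    rows = []
    for idx in range(n_accessions):
        mask = rng.random(len(variant_spec)) < 0.5
        chosen = [variant_spec[i] for i in range(len(variant_spec)) if mask[i]]
        ops = _ops_for_edits(chosen, truth, rng)
        # inversion replacement needs the base sequence
        for op, edit in zip(ops, chosen):
            if edit["type"] == "arm_inversion":
                op.replacement = revcomp(seq[op.start : op.end])
        acc_seq = _apply_ops(seq, ops)

        shifted_features = []
        for f in base_features:
            start, end = _shift_interval(f.start, f.end, ops)
            shifted_features.append(
                Gff3Feature(f.seq_id, f.type, start, end, f.strand, dict(f.attributes))
            )
        intron_lengths = {}
        intron_seqs = {}
        for name in ("geneA", "geneB"):
            intron = truth.genes[name].intron1
            start, end = _shift_interval(intron.start, intron.end, ops)
            intron_lengths[name] = end - start
            piece = acc_seq[start:end]
            intron_seqs[name] = revcomp(piece) if intron.strand == "-" else piece
        symmetric = intron_seqs["geneA"] == intron_seqs["geneB"]

        edit_types = [e["type"] for e in chosen]
        label = (
            "+".join(sorted({CLASS_LABELS[t] for t in edit_types}))
            if edit_types
            else "reference-like"
        )
        name = f"acc{idx:03d}"
        records.append(
            AccessionRecord(
                name=name,
                genome={truth.chrom: acc_seq},
                features=shifted_features,
                intron1_length=intron_lengths,
                symmetric=symmetric,
                structural_class=label,
                edits=edit_types,
            )
        )
        rows.append(
            (
                name,
                intron_lengths["geneA"],
                intron_lengths["geneB"],
                symmetric,
                label,
                ",".join(edit_types) if edit_types else "",
            )
        )

    panel_truth = pd.DataFrame(rows, columns=PANEL_TRUTH_COLUMNS)
    return records, panel_truth, (base_genome, base_features, truth)
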