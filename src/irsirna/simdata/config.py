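"""Simulation configuration and ground-truth containers."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from irsirna.intervals import GenomicInterval

#: Default per-(region, context) methylation probabilities.  The IR arms
#: carry RdDM-style non-CG methylation on top of moderate CG methylation;
#: the genomic background carries low methylation in every context.
DEFAULT_METH_PROB: dict[tuple[str, str], float] = {
    ("ir_arm", "CG"): 0.60,
    ("ir_arm", "CHG"): 0.30,
    ("ir_arm", "CHH"): 0.30,
    ("spacer", "CG"): 0.60,
    ("spacer", "CHG"): 0.30,
    ("spacer", "CHH"): 0.30,
    ("background", "CG"): 0.10,
    ("background", "CHG"): 0.02,
    ("background", "CHH"): 0.02,
}

#: Default small-RNA size composition: a 21-nt-dominated population with
#: minor 20/22-nt species and a small 24-nt fraction.
DEFAULT_SIZE_WEIGHTS: dict[int, float] = {20: 0.10, 21: 0.60, 22: 0.15, 23: 0.05, 24: 0.10}

# fixed spawn indices so adding one simulation never perturbs another
_STREAMS = {"genome": 0, "srna": 1, "wgbs": 2, "race": 3, "panel": 4, "aux": 5}


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


@dataclass
class SimulationConfig:
    """All tunable parameters of the synthetic locus and its libraries.

    Coordinates handed to :attr:`tss_positions` are start-codon-relative in
    the convention without a zero (-1 abuts +1, the A of ATG is +1).
    """

    seed: int = 0
    # locus geometry
    arm_length: int = 3200
    arm_identity: float = 1.0
    spacer_length: int = 50
    intron_repeat_period: int = 80
    intron_repeat_copies_per_gene: tuple[int, int] = (4, 4)
    distal_paralog_exon1_identity: float = 0.94
    trans_target_present: bool = True
    utr5_length: int = 100
    exon1_length: int = 1500
    intron_flank: int = 20
    gene_tail_length: int = 800
    background_left: int = 2000
    background_mid: int = 1000
    background_right: int = 2000
    # small-RNA library
    srna_size_weights: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_SIZE_WEIGHTS)
    )
    loop_depletion: float = 10.0
    dosage: int = 2
    library_size: int = 100_000
    ir_fraction_per_allele: float = 0.5
    background_fraction: float = 0.0
    # bisulfite library
    wgbs_coverage: float = 50.0
    wgbs_read_length: int = 80
    meth_prob: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_METH_PROB)
    )
    conversion_rate: float = 0.995
    # 5'RACE library
    tss_positions: list[int] = field(default_factory=lambda: [-45])
    tss_jitter_sd: float = 3.0
    race_tag_count: int = 1000
    race_cleavage_fraction: float = 0.2
    race_adapter: str = "GTTCAGAGTTCTACAGTCCGACGATC"
    race_tag_length: int = 80

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        weight_sum = sum(self.srna_size_weights.values())
        if abs(weight_sum - 1.0) > 1e-9:
            raise ConfigurationError(f"sRNA size weights sum to {weight_sum}, not 1")
        if any(size not in range(20, 25) for size in self.srna_size_weights):
            raise ConfigurationError("sRNA sizes must lie in 20..24")
        for name in (
            "arm_identity",
            "distal_paralog_exon1_identity",
            "conversion_rate",
            "background_fraction",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name}={value} outside [0, 1]")
        for (_, _), prob in self.meth_prob.items():
            if not 0.0 <= prob <= 1.0:
                raise ConfigurationError(f"methylation probability {prob} outside [0, 1]")
        if not self.arm_length >= self.spacer_length >= 0:
            raise ConfigurationError(
                f"need arm_length >= spacer_length >= 0, got {self.arm_length}, {self.spacer_length}"
            )
        if not 75 <= self.intron_repeat_period <= 83:
            raise ConfigurationError(
                f"intron repeat period {self.intron_repeat_period} outside [75, 83]"
            )
        if self.loop_depletion < 1.0:
            raise ConfigurationError("loop_depletion must be >= 1")
        if self.dosage not in (0, 1, 2):
            raise ConfigurationError(f"dosage must be 0, 1, or 2, got {self.dosage}")
        if 0 in self.tss_positions:
            raise ConfigurationError("start-codon-relative position 0 does not exist")
        intron_len = self.intron1_length(max(self.intron_repeat_copies_per_gene))
        body = self.utr5_length + self.exon1_length + intron_len
        if body > self.arm_length:
            raise ConfigurationError(
                f"arm_length {self.arm_length} too short for UTR+exon1+intron1 = {body}"
            )

    def intron1_length(self, copies: int) -> int:
        return 2 * self.intron_flank + self.intron_repeat_period * copies

    def rng(self, stream: str) -> np.random.Generator:
        """Independent child generator for one sub-simulation."""
        return np.random.default_rng([_STREAMS[stream], self.seed])


@dataclass
class GeneModel:
    """Planted coordinates of one simulated gene.

    ``interval`` spans the whole gene on the genome; transcript-oriented
    segment coordinates are resolved through :meth:`transcript_to_genomic`.
    """

    name: str
    interval: GenomicInterval
    start_codon: int  # genomic position of the A of ATG
    utr5: GenomicInterval
    exon1: GenomicInterval  # first exon including the 5'UTR
    intron1: GenomicInterval | None
    exon2: GenomicInterval | None
    cdna: str  # spliced transcript, 5'->3'
    intron_repeat_interval: GenomicInterval | None = None
    intron_repeat_copies: int = 0

    @property
    def strand(self) -> str:
        return self.interval.strand

    def transcript_to_genomic(self, t: int) -> int:
        if self.strand == "+":
            return self.interval.start + t
        return self.interval.end - 1 - t

    def genomic_to_transcript(self, g: int) -> int:
        if self.strand == "+":
            return g - self.interval.start
        return self.interval.end - 1 - g

    @property
    def intron1_length(self) -> int:
        return 0 if self.intron1 is None else len(self.intron1)


@dataclass
class GroundTruth:
    """Planted simulation parameters consumed by recovery tests."""

    chrom: str
    genome_length: int
    ir_arm_a: GenomicInterval
    ir_arm_b: GenomicInterval
    spacer: GenomicInterval
    genes: dict[str, GeneModel]
    diagnostic_snps_exon1: list[int]  # coding-exon1-relative positions (0-based)
    diagnostic_snps_genomic: dict[str, list[int]]  # per paralog gene name
    srna_source: str | None  # 21-mer siRNA complementary to the trans-target site
    target_site: GenomicInterval | None  # planted site on the trans-target gene
    cleavage_transcript_pos: int | None  # 0-based on the trans-target cDNA
    cleavage_genomic_pos: int | None
    tss: list[dict]  # gene, rel (codon-relative), genomic, strand
    intron_repeat_unit: str

    def region_of(self, pos: int) -> str:
        """Methylation region label of a genomic position."""
        if self.ir_arm_a.contains(pos) or self.ir_arm_b.contains(pos):
            return "ir_arm"
        if self.spacer.contains(pos):
            return "spacer"
        return "background"
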