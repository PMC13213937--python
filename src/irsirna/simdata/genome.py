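"""Construction of the synthetic IR locus genome and its annotation.

The simulated chromosome carries, left to right: background sequence, gene A
on the minus strand (5' end facing right), the nonpalindromic spacer, gene B
on the plus strand (5' end facing left), more background, a distal paralog C
whose first exon differs from gene A's by planted diagnostic SNPs, an
optional trans-silencing target gene D carrying a site perfectly
complementary to a gene-A-derived 21-mer, and trailing background.  The
first-exon-plus-upstream "arms" of genes A and B are reverse complements of
one another at the configured identity, so the locus forms a head-to-head
inverted repeat of total extent ``2 * arm_length + spacer_length``.
"""

from __future__ import annotations

import numpy as np

from irsirna.intervals import GenomicInterval, revcomp
from irsirna.seqio import Gff3Feature
from irsirna.simdata.config import (
    ConfigurationError,
    GeneModel,
    GroundTruth,
    SimulationConfig,
)

CHROM = "chr1"
_BASES = np.array(list("ACGT"))


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n))


def mutate(
    seq: str,
    n_subs: int,
    rng: np.random.Generator,
    protected: range | None = None,
) -> tuple[str, list[int]]:
    """Apply exactly ``n_subs`` substitutions at distinct positions.

    Returns the mutated sequence and the sorted substituted positions.
    """
    candidates = [i for i in range(len(seq)) if protected is None or i not in protected]
    if n_subs > len(candidates):
        raise ConfigurationError(
            f"cannot place {n_subs} substitutions in {len(candidates)} positions"
        )
    positions = sorted(rng.choice(len(candidates), size=n_subs, replace=False))
    positions = [candidates[i] for i in positions]
    out = list(seq)
    for pos in positions:
        alternatives = [b for b in "ACGT" if b != out[pos]]
        out[pos] = alternatives[rng.integers(len(alternatives))]
    return "".join(out), positions


def _nonpalindromic_seq(rng: np.random.Generator, n: int) -> str:
    """Random sequence with low identity to its own reverse complement.

    The outermost bases must not be mutually complementary, otherwise the
    flanking palindrome would legitimately extend into the segment and the
    planted spacer length would not be the maximal-palindrome spacer.
    """
    for _ in range(200):
        seq = random_seq(rng, n)
        rc = revcomp(seq)
        if n >= 2 and (seq[0] == rc[0] or seq[-1] == rc[-1]):
            continue
        if sum(a == b for a, b in zip(seq, rc)) / max(n, 1) < 0.6:
            return seq
    raise ConfigurationError(f"could not draw a nonpalindromic {n}-bp segment")


def _arm_transcript(
    config: SimulationConfig, rng: np.random.Generator, unit: str
) -> tuple[str, dict[str, int]]:
    """Gene A's arm in transcript orientation plus its segment layout."""
    u, e1 = config.utr5_length, config.exon1_length
    copies = config.intron_repeat_copies_per_gene[0]
    intron = (
        random_seq(rng, config.intron_flank)
        + unit * copies
        + random_seq(rng, config.intron_flank)
    )
    utr5 = random_seq(rng, u)
    exon1 = "ATG" + random_seq(rng, e1 - 3)
    fill = config.arm_length - u - e1 - len(intron)
    exon2a = random_seq(rng, fill)
    layout = {
        "utr5": u,
        "exon1": e1,
        "intron1": len(intron),
        "repeat_offset": u + e1 + config.intron_flank,
        "copies": copies,
    }
    return utr5 + exon1 + intron + exon2a, layout


def generate_ir_genome(
    config: SimulationConfig,
) -> tuple[dict[str, str], list[Gff3Feature], GroundTruth]:
    """Build the synthetic genome, its GFF3 annotation, and the ground truth.

    Returns ``({chrom: sequence}, features, truth)``.  Deterministic under
    ``config.seed``.
    """
    rng = config.rng("genome")
    u, e1 = config.utr5_length, config.exon1_length
    tail_len = config.gene_tail_length
    unit = random_seq(rng, config.intron_repeat_period)

    arm_a, layout = _arm_transcript(config, rng, unit)
    copies_a, copies_b = config.intron_repeat_copies_per_gene

    # gene B's arm: same parts with its own repeat copy number, then
    # substitutions down to the configured arm identity (start codon kept)
    intron_b = (
        arm_a[u + e1 : u + e1 + config.intron_flank]
        + unit * copies_b
        + arm_a[u + e1 + layout["intron1"] - config.intron_flank : u + e1 + layout["intron1"]]
    )
    arm_b = arm_a[: u + e1] + intron_b + arm_a[u + e1 + layout["intron1"] :]
    n_subs = round((1.0 - config.arm_identity) * len(arm_b))
    arm_b, _ = mutate(arm_b, n_subs, rng, protected=range(u, u + 3))

    # gene bodies beyond the arms diverge: the inverted repeat is exactly
    # the two arms, so its planted extent is recoverable; the first tail
    # bases must differ or the palindrome would extend past the arms
    tail_a = random_seq(rng, tail_len)
    tail_b = random_seq(rng, tail_len)
    if tail_len and tail_b[0] == tail_a[0]:
        tail_b = ("A" if tail_a[0] != "A" else "C") + tail_b[1:]
    spacer_seq = _nonpalindromic_seq(rng, config.spacer_length)

    # distal paralog C: gene A's coding exon 1 at the configured identity
    exon1_a = arm_a[u : u + e1]
    n_snp = round((1.0 - config.distal_paralog_exon1_identity) * e1)
    exon1_c, snp_positions = mutate(exon1_a, n_snp, rng, protected=range(0, 3))
    utr_c = random_seq(rng, u)
    tail_c = random_seq(rng, 400)
    transcript_c = utr_c + exon1_c + tail_c

    # trans-target D with a site perfectly complementary to an arm 21-mer
    srna_source = target_site_t = None
    transcript_d = ""
    if config.trans_target_present:
        source_offset = min(300, e1 - 21)
        srna_source = exon1_a[source_offset : source_offset + 21]
        d_rng_seq = list("ATG" + random_seq(rng, 497))
        target_site_t = 250
        d_rng_seq[target_site_t : target_site_t + 21] = revcomp(srna_source)
        transcript_d = random_seq(rng, 100) + "".join(d_rng_seq)

    bg_left = random_seq(rng, config.background_left)
    bg_mid = random_seq(rng, config.background_mid)
    bg_mid2 = random_seq(rng, 500)
    bg_right = random_seq(rng, config.background_right)

    # assemble the chromosome left to right
    parts: list[str] = []
    cursor = 0

    def push(seq: str) -> GenomicInterval:
        nonlocal cursor
        parts.append(seq)
        iv = GenomicInterval(CHROM, cursor, cursor + len(seq))
        cursor += len(seq)
        return iv

    push(bg_left)
    tail_a_iv = push(revcomp(tail_a))
    arm_a_iv = push(revcomp(arm_a))
    spacer_iv = push(spacer_seq)
    arm_b_iv = push(arm_b)
    tail_b_iv = push(tail_b)
    push(bg_mid)
    gene_c_iv_raw = push(transcript_c)
    push(bg_mid2)
    gene_d_iv_raw = push(transcript_d) if transcript_d else None
    push(bg_right)
    genome_seq = "".join(parts)

    def build_gene(
        name: str,
        interval: GenomicInterval,
        arm: str,
        tail: str,
        intron_len: int,
        copies: int,
    ) -> GeneModel:
        total = len(interval)
        t_exon1_end = u + e1
        t_intron_end = t_exon1_end + intron_len
        transcript = arm + tail
        cdna = transcript[:t_exon1_end] + transcript[t_intron_end:]

        def seg(t0: int, t1: int) -> GenomicInterval:
            if interval.strand == "+":
                return GenomicInterval(CHROM, interval.start + t0, interval.start + t1, "+")
            return GenomicInterval(CHROM, interval.end - t1, interval.end - t0, "-")

        repeat_t0 = t_exon1_end + config.intron_flank
        return GeneModel(
            name=name,
            interval=interval,
            start_codon=(
                interval.start + u if interval.strand == "+" else interval.end - 1 - u
            ),
            utr5=seg(0, u),
            exon1=seg(0, t_exon1_end),
            intron1=seg(t_exon1_end, t_intron_end),
            exon2=seg(t_intron_end, total),
            cdna=cdna,
            intron_repeat_interval=seg(repeat_t0, repeat_t0 + len(unit) * copies),
            intron_repeat_copies=copies,
        )

    gene_a = build_gene(
        "geneA",
        GenomicInterval(CHROM, tail_a_iv.start, arm_a_iv.end, "-"),
        arm_a,
        tail_a,
        layout["intron1"],
        copies_a,
    )
    gene_b = build_gene(
        "geneB",
        GenomicInterval(CHROM, arm_b_iv.start, tail_b_iv.end, "+"),
        arm_b,
        tail_b,
        config.intron1_length(copies_b),
        copies_b,
    )

    gene_c = GeneModel(
        name="geneC",
        interval=GenomicInterval(CHROM, gene_c_iv_raw.start, gene_c_iv_raw.end, "+"),
        start_codon=gene_c_iv_raw.start + u,
        utr5=GenomicInterval(CHROM, gene_c_iv_raw.start, gene_c_iv_raw.start + u, "+"),
        exon1=GenomicInterval(CHROM, gene_c_iv_raw.start, gene_c_iv_raw.start + u + e1, "+"),
        intron1=None,
        exon2=None,
        cdna=transcript_c,
    )

    genes = {"geneA": gene_a, "geneB": gene_b, "geneC": gene_c}
    target_site = cleavage_t = cleavage_g = None
    if gene_d_iv_raw is not None:
        gene_d = GeneModel(
            name="geneD",
            interval=GenomicInterval(CHROM, gene_d_iv_raw.start, gene_d_iv_raw.end, "+"),
            start_codon=gene_d_iv_raw.start + 100,
            utr5=GenomicInterval(CHROM, gene_d_iv_raw.start, gene_d_iv_raw.start + 100, "+"),
            exon1=GenomicInterval(CHROM, gene_d_iv_raw.start, gene_d_iv_raw.end, "+"),
            intron1=None,
            exon2=None,
            cdna=transcript_d,
        )
        genes["geneD"] = gene_d
        site_t0 = 100 + target_site_t
        target_site = GenomicInterval(
            CHROM, gene_d_iv_raw.start + site_t0, gene_d_iv_raw.start + site_t0 + 21, "+"
        )
        # the slicing site: target base paired to sRNA position 10
        cleavage_t = site_t0 + 21 - 10
        cleavage_g = gene_d_iv_raw.start + cleavage_t

    # planted TSSs live on gene A (the gene transcribing across the IR)
    tss_records = []
    for rel in config.tss_positions:
        t = u + (rel - 1 if rel > 0 else rel)
        g = gene_a.transcript_to_genomic(t)
        if not 0 <= g < len(genome_seq):
            raise ConfigurationError(f"TSS {rel} falls outside the simulated genome")
        tss_records.append({"gene": "geneA", "rel": rel, "genomic": g, "strand": "-"})

    truth = GroundTruth(
        chrom=CHROM,
        genome_length=len(genome_seq),
        ir_arm_a=GenomicInterval(CHROM, arm_a_iv.start, arm_a_iv.end, "-"),
        ir_arm_b=GenomicInterval(CHROM, arm_b_iv.start, arm_b_iv.end, "+"),
        spacer=GenomicInterval(CHROM, spacer_iv.start, spacer_iv.end),
        genes=genes,
        diagnostic_snps_exon1=snp_positions,
        diagnostic_snps_genomic={
            "geneA": [gene_a.transcript_to_genomic(u + p) for p in snp_positions],
            "geneC": [gene_c.interval.start + u + p for p in snp_positions],
        },
        srna_source=srna_source,
        target_site=target_site,
        cleavage_transcript_pos=cleavage_t,
        cleavage_genomic_pos=cleavage_g,
        tss=tss_records,
        intron_repeat_unit=unit,
    )
    return {CHROM: genome_seq}, features_from_truth(truth), truth


def features_from_truth(truth: GroundTruth) -> list[Gff3Feature]:
    """GFF3 feature list (gene/mRNA/five_prime_UTR/exon/intron) for the locus."""
    features: list[Gff3Feature] = []
    for name, gene in truth.genes.items():
        strand = gene.strand
        gene_id = name
        features.append(
            Gff3Feature(truth.chrom, "gene", gene.interval.start, gene.interval.end,
                        strand, {"ID": gene_id, "Name": name})
        )
        mrna_id = f"{name}.1"
        features.append(
            Gff3Feature(truth.chrom, "mRNA", gene.interval.start, gene.interval.end,
                        strand, {"ID": mrna_id, "Parent": gene_id})
        )
        features.append(
            Gff3Feature(truth.chrom, "five_prime_UTR", gene.utr5.start, gene.utr5.end,
                        strand, {"ID": f"{mrna_id}.utr5", "Parent": mrna_id})
        )
        features.append(
            Gff3Feature(truth.chrom, "exon", gene.exon1.start, gene.exon1.end,
                        strand, {"ID": f"{mrna_id}.exon1", "Parent": mrna_id})
        )
        if gene.intron1 is not None:
            features.append(
                Gff3Feature(truth.chrom, "intron", gene.intron1.start, gene.intron1.end,
                            strand, {"ID": f"{mrna_id}.intron1", "Parent": mrna_id})
            )
        if gene.exon2 is not None:
            features.append(
                Gff3Feature(truth.chrom, "exon", gene.exon2.start, gene.exon2.end,
                            strand, {"ID": f"{mrna_id}.exon2", "Parent": mrna_id})
            )
    return features
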