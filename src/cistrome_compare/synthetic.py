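"""Synthetic genomes, ChIP-seq tracks and expression cohorts with ground truth.

The simulator emulates the study design the pipeline is built to analyse:
several cell lines share a common set of promoter-proximal binding sites,
while one "special" line (an MCF-7-like, co-factor-recruited cistrome)
carries a disjoint, TSS-distal site set with a planted co-factor motif
occurrence in every peak. A matching patient cohort carries two
opposite-signed, hormone-receptor-linked signature activities, one of which
drives survival.

Every operation is deterministic under the configuration seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from cistrome_compare.formats import (
    ExpressionCohort,
    GeneRecord,
    GenomicInterval,
    PWM,
    Peak,
    SignalTrack,
    ValidationError,
)

PLANTED_CONSENSUS = "TACGCTGACA"  # sharp non-palindromic 10-mer


def planted_pwm(motif_id: str = "M_planted", consensus: str = PLANTED_CONSENSUS) -> PWM:
    """A near-deterministic PWM (0.97 on the consensus base)."""
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    m = np.full((len(consensus), 4), 0.01)
    for i, base in enumerate(consensus):
        m[i, idx[base]] = 0.97
    return PWM(motif_id, m)


def shuffled_decoy(pwm: PWM, seed: int = 0) -> PWM:
    """Column-shuffled decoy with the same composition, no planted signal."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pwm))
    m = pwm.matrix[order].copy()
    for row in m:
        rng.shuffle(row)
    return PWM(pwm.motif_id + "_decoy", m)


@dataclass
class SimulationConfig:
    """Study-design parameters for the synthetic datasets.

    Defaults give a 2 Mb genome (2 chromosomes), 200 genes, 4 cell lines x 2
    replicates with 30 binding sites each, and a 500-patient cohort —
    everything runs in seconds while preserving the qualitative structure of
    a multi-cell-line cistrome comparison.
    """

    n_chroms: int = 2
    chrom_length: int = 1_000_000
    n_genes: int = 200
    n_cell_lines: int = 4
    n_replicates_per_line: int = 2
    n_sites_per_line: int = 10
    shared_site_fraction: float = 0.8
    special_line_id: str = "MCF7_like"
    planted_pwm_ids: tuple[str, ...] = ("M_planted",)
    peak_signal_mean: float = 8.0
    noise_sd: float = 0.5
    peak_halfwidth: int = 200
    coverage_step: int = 10
    n_patients: int = 500
    effect_up: float = 1.0
    hazard_log_hr: float = 0.7
    baseline_hazard: float = 0.01  # events per month
    censoring_window: float = 300.0  # months
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_chroms", "chrom_length", "n_genes", "n_cell_lines",
            "n_replicates_per_line", "n_sites_per_line", "n_patients",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if not 0.0 <= self.shared_site_fraction <= 1.0:
            raise ValidationError("shared_site_fraction must be in [0, 1]")
        if self.n_chroms * self.chrom_length < 10_000 * self.n_genes:
            raise ValidationError("genome too short for the requested gene count")

    @property
    def cell_lines(self) -> list[str]:
        others = [f"line{i}" for i in range(2, self.n_cell_lines + 1)]
        return [self.special_line_id] + others

    @property
    def replicates(self) -> list[tuple[str, int]]:
        return [
            (line, rep)
            for line in self.cell_lines
            for rep in range(1, self.n_replicates_per_line + 1)
        ]


@dataclass
class GroundTruth:
    """Planted truth against which downstream recovery is evaluated."""

    true_peaks: dict[str, list[Peak]]
    true_targets: dict[str, frozenset[str]]
    planted_motif_positions: list[tuple[str, int, str, str]]
    patient_activities: pd.DataFrame | None = None  # a_special, a_other per sample
    er_labels: pd.Series | None = None
    pwms: list[PWM] = field(default_factory=list)


def generate_genome(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[dict[str, str], list[GeneRecord]]:
    """I.i.d.-uniform ACGT chromosomes with regularly spaced genes.

    Genes are distributed evenly across chromosomes, TSSs at regular
    spacing, strands alternating.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    genome: dict[str, str] = {}
    genes: list[GeneRecord] = []
    per_chrom = config.n_genes // config.n_chroms
    remainder = config.n_genes % config.n_chroms
    bases = np.frombuffer(b"ACGT", dtype="S1")
    gene_idx = 0
    for c in range(config.n_chroms):
        chrom = f"chr{c + 1}"
        seq = bases[rng.integers(0, 4, size=config.chrom_length)]
        genome[chrom] = seq.tobytes().decode("ascii")
        n_here = per_chrom + (1 if c < remainder else 0)
        if n_here == 0:
            continue
        spacing = config.chrom_length // n_here
        if spacing < 10_000:
            raise ValidationError(f"{chrom} too short for {n_here} genes")
        for i in range(n_here):
            tss = spacing // 2 + i * spacing
            strand = "+" if gene_idx % 2 == 0 else "-"
            genes.append(GeneRecord(f"gene{gene_idx:04d}", chrom, tss, strand))
            gene_idx += 1
    return genome, genes


def plant_binding(
    config: SimulationConfig,
    genes: list[GeneRecord],
    genome: dict[str, str],
    rng: np.random.Generator | None = None,
) -> GroundTruth:
    """Assign binding sites per cell line and plant motif instances.

    Non-special lines draw ``shared_site_fraction`` of their sites from a
    common pool placed promoter-proximally (~80% within +/-1 kb of a TSS);
    the special line receives a disjoint set placed mostly TSS-distal
    (~75% beyond +/-2 kb) with one planted-motif consensus written into the
    genome at each summit.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    n_sites = config.n_sites_per_line
    n_shared = int(round(config.shared_site_fraction * n_sites))
    n_own = n_sites - n_shared
    n_other_lines = config.n_cell_lines - 1
    needed = n_sites + n_shared + n_own * n_other_lines
    # sites go to interior genes so no target's TSS window is truncated
    margin = 10_100
    eligible = [
        i for i, g in enumerate(genes)
        if margin <= g.tss <= len(genome[g.chrom]) - margin
    ]
    if needed > len(eligible):
        raise ValidationError(
            f"need {needed} placement-eligible genes, have {len(eligible)}"
        )
    order = rng.permutation(eligible)
    cursor = 0

    def take(k: int) -> list[GeneRecord]:
        nonlocal cursor
        out = [genes[i] for i in order[cursor:cursor + k]]
        cursor += k
        return out

    special_genes = take(n_sites)
    shared_genes = take(n_shared)
    own_genes = {line: take(n_own) for line in config.cell_lines[1:]}

    chrom_len = {c: len(s) for c, s in genome.items()}
    mutable = {c: bytearray(s, "ascii") for c, s in genome.items()}
    pwms = [planted_pwm(mid) for mid in config.planted_pwm_ids]

    def proximal_offset() -> int:
        return int(rng.integers(-800, 801))

    def distal_offset() -> int:
        return int(rng.integers(2200, 4501)) * (1 if rng.random() < 0.5 else -1)

    def make_peak(gene: GeneRecord, offset: int, name: str) -> Peak:
        summit = int(np.clip(gene.tss + offset, config.peak_halfwidth,
                             chrom_len[gene.chrom] - config.peak_halfwidth - 1))
        iv = GenomicInterval(
            gene.chrom, summit - config.peak_halfwidth, summit + config.peak_halfwidth
        )
        return Peak(iv, summit, score=config.peak_signal_mean, name=name)

    true_peaks: dict[str, list[Peak]] = {}
    true_targets: dict[str, frozenset[str]] = {}
    planted: list[tuple[str, int, str, str]] = []

    # special line: mostly distal, motif planted at each summit
    special = config.special_line_id
    peaks: list[Peak] = []
    for i, gene in enumerate(special_genes):
        offset = distal_offset() if rng.random() < 0.75 else proximal_offset()
        peak = make_peak(gene, offset, f"{special}_site{i}")
        pwm = pwms[i % len(pwms)]
        pos = peak.summit - len(pwm) // 2
        mutable[gene.chrom][pos:pos + len(pwm)] = pwm.consensus.encode("ascii")
        planted.append((gene.chrom, pos, pwm.motif_id, "+"))
        peaks.append(peak)
    true_peaks[special] = sorted(
        peaks, key=lambda p: (p.interval.chrom, p.interval.start)
    )
    true_targets[special] = frozenset(g.gene_id for g in special_genes)

    # non-special lines: shared pool plus line-specific extras, mostly proximal
    shared_offsets = [
        proximal_offset() if rng.random() < 0.8 else distal_offset()
        for _ in shared_genes
    ]
    for line in config.cell_lines[1:]:
        peaks = [
            make_peak(g, off, f"{line}_shared{i}")
            for i, (g, off) in enumerate(zip(shared_genes, shared_offsets))
        ]
        for i, gene in enumerate(own_genes[line]):
            offset = proximal_offset() if rng.random() < 0.8 else distal_offset()
            peaks.append(make_peak(gene, offset, f"{line}_own{i}"))
        true_peaks[line] = sorted(
            peaks, key=lambda p: (p.interval.chrom, p.interval.start)
        )
        true_targets[line] = frozenset(
            g.gene_id for g in shared_genes + own_genes[line]
        )

    for chrom in genome:
        genome[chrom] = mutable[chrom].decode("ascii")
    return GroundTruth(true_peaks, true_targets, planted, pwms=pwms)


def simulate_coverage(
    truth: GroundTruth,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> dict[tuple[str, int], SignalTrack]:
    """Coverage tracks per replicate: truncated-normal background plus a
    triangular bump of height ``peak_signal_mean`` at each true summit.

    Coverage is piecewise constant over ``coverage_step``-bp blocks;
    replicates of a line share peaks and differ only in background noise.
    """
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    step = config.coverage_step
    chroms = [f"chr{c + 1}" for c in range(config.n_chroms)]
    n_blocks = config.chrom_length // step
    tracks: dict[tuple[str, int], SignalTrack] = {}
    for line, rep in config.replicates:
        chrom_data = {}
        total = 0.0
        for chrom in chroms:
            blocks = np.clip(
                rng.normal(1.0, config.noise_sd, size=n_blocks), 0.0, None
            ) if config.noise_sd > 0 else np.ones(n_blocks)
            for peak in truth.true_peaks[line]:
                if peak.interval.chrom != chrom:
                    continue
                lo, hi = peak.interval.start, peak.interval.end
                pos = np.arange(lo, hi)
                bump = config.peak_signal_mean * (
                    1.0 - np.abs(pos - peak.summit) / config.peak_halfwidth
                )
                b_lo, b_hi = lo // step, (hi - 1) // step + 1
                idx = pos // step - b_lo
                block_max = np.zeros(b_hi - b_lo)
                np.maximum.at(block_max, idx, bump)
                blocks[b_lo:b_hi] += block_max
            starts = np.arange(n_blocks, dtype=np.int64) * step
            ends = starts + step
            keep = blocks > 0
            chrom_data[chrom] = (starts[keep], ends[keep], blocks[keep])
            total += blocks.sum() * step
        tracks[(line, rep)] = SignalTrack(
            chrom_data,
            total_reads=max(total, 1.0),
            chrom_lengths={c: config.chrom_length for c in chroms},
        )
    return tracks


def simulate_cohort(
    truth: GroundTruth,
    config: SimulationConfig,
    genes: list[GeneRecord],
    rng: np.random.Generator | None = None,
) -> ExpressionCohort:
    """Expression + survival cohort with two planted signature activities.

    Per sample, the special-line signature activity is N(+1, 0.5) in ER+
    samples and N(-1, 0.5) in ER- samples; the other-lines signature is
    anti-correlated with ER. Target-gene expression is shifted by
    ``effect_up`` times the activity; survival is exponential with log-hazard
    ``hazard_log_hr`` times the other-lines activity, with independent
    uniform censoring.
    """
    rng = np.random.default_rng(config.seed + 3) if rng is None else rng
    gene_ids = [g.gene_id for g in genes]
    samples = [f"S{i:04d}" for i in range(config.n_patients)]
    er = rng.random(config.n_patients) < 0.5

    a_special = rng.normal(np.where(er, 1.0, -1.0), 0.5)
    a_other = rng.normal(np.where(er, -1.0, 1.0), 0.5)

    targets_special = truth.true_targets[config.special_line_id]
    targets_other: set[str] = set()
    for line, t in truth.true_targets.items():
        if line != config.special_line_id:
            targets_other |= t
    overlap = targets_special & targets_other
    if overlap:
        import logging

        logging.getLogger(__name__).info(
            "simulate_cohort: %d genes shared between signatures", len(overlap)
        )

    in_special = np.array([g in targets_special for g in gene_ids])
    in_other = np.array([g in targets_other for g in gene_ids])
    expr = rng.normal(0.0, 1.0, size=(len(gene_ids), config.n_patients))
    expr += config.effect_up * (
        np.outer(in_special, a_special) + np.outer(in_other, a_other)
    )

    rate = config.baseline_hazard * np.exp(config.hazard_log_hr * a_other)
    event_time = rng.exponential(1.0 / rate)
    censor_time = rng.uniform(0.0, config.censoring_window, size=config.n_patients)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)

    clinical = pd.DataFrame(
        {
            "time": time,
            "event": event,
            "er_status": np.where(er, "+", "-"),
            "age": np.round(rng.normal(60.0, 10.0, config.n_patients), 1),
        },
        index=pd.Index(samples, name="sample_id"),
    )
    truth.patient_activities = pd.DataFrame(
        {"a_special": a_special, "a_other": a_other},
        index=pd.Index(samples, name="sample_id"),
    )
    truth.er_labels = clinical["er_status"].copy()
    expression = pd.DataFrame(expr, index=gene_ids, columns=samples)
    return ExpressionCohort(expression, clinical)


def make_pathways(
    truth: GroundTruth,
    genes: list[GeneRecord],
    rng: np.random.Generator,
    pathway_size: int = 60,
    n_decoys: int = 2,
):
    """Pathway-like gene sets for enrichment testing.

    Each cell line's true target set is embedded in a pathway padded with
    random non-target genes up to ``pathway_size`` (emulating a curated
    pathway that contains the signature), plus random decoy pathways of the
    same size.
    """
    from cistrome_compare.formats import GeneSetCollection

    gene_ids = [g.gene_id for g in genes]
    sets: dict[str, frozenset[str]] = {}
    for line, targets in truth.true_targets.items():
        pool = [g for g in gene_ids if g not in targets]
        pad = pathway_size - len(targets)
        extra = list(rng.choice(pool, size=max(pad, 0), replace=False))
        sets[f"pathway_{line}"] = frozenset(targets) | frozenset(extra)
    for d in range(n_decoys):
        sets[f"pathway_decoy{d + 1}"] = frozenset(
            rng.choice(gene_ids, size=pathway_size, replace=False)
        )
    return GeneSetCollection(sets)


@dataclass
class SimulationResult:
    config: SimulationConfig
    genome: dict[str, str]
    genes: list[GeneRecord]
    truth: GroundTruth
    tracks: dict[tuple[str, int], SignalTrack]
    cohort: ExpressionCohort


def simulate(config: SimulationConfig) -> SimulationResult:
    """Run the full generator with a single seeded stream."""
    genome, genes = generate_genome(config)
    truth = plant_binding(config, genes, genome)
    tracks = simulate_coverage(truth, config)
    cohort = simulate_cohort(truth, config, genes)
    return SimulationResult(config, genome, genes, truth, tracks, cohort)


def write_simulation(result: SimulationResult, outdir) -> dict[str, str]:
    """Write every simulated artifact to ``outdir``; returns path map."""
    import json
    from pathlib import Path

    from cistrome_compare import formats

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    formats.write_fasta(result.genome, outdir / "genome.fa")
    paths["genome"] = str(outdir / "genome.fa")
    formats.write_tss_table(result.genes, outdir / "tss.tsv")
    paths["tss"] = str(outdir / "tss.tsv")

    for (line, rep), track in result.tracks.items():
        stem = f"{line}_rep{rep}"
        formats.write_bedgraph(track, outdir / f"{stem}.bedGraph")
        formats.write_narrowpeak(
            result.truth.true_peaks[line], outdir / f"{stem}.narrowPeak"
        )
        paths[f"track:{stem}"] = str(outdir / f"{stem}.bedGraph")
        paths[f"peaks:{stem}"] = str(outdir / f"{stem}.narrowPeak")

    pwms = list(result.truth.pwms) + [
        shuffled_decoy(p, seed=result.config.seed) for p in result.truth.pwms
    ]
    formats.write_meme(pwms, outdir / "motifs.meme")
    paths["motifs"] = str(outdir / "motifs.meme")

    formats.write_gmt(
        formats.GeneSetCollection(
            {f"targets_{k}": frozenset(v) for k, v in result.truth.true_targets.items()}
        ),
        outdir / "true_targets.gmt",
    )
    paths["true_targets"] = str(outdir / "true_targets.gmt")

    pathways = make_pathways(
        result.truth, result.genes, np.random.default_rng(result.config.seed + 4)
    )
    formats.write_gmt(pathways, outdir / "pathways.gmt")
    paths["pathways"] = str(outdir / "pathways.gmt")

    formats.write_cohort(
        result.cohort, outdir / "expression.tsv", outdir / "clinical.tsv"
    )
    paths["expression"] = str(outdir / "expression.tsv")
    paths["clinical"] = str(outdir / "clinical.tsv")

    gt = {
        "true_targets": {k: sorted(v) for k, v in result.truth.true_targets.items()},
        "planted_motifs": [list(t) for t in result.truth.planted_motif_positions],
        "patient_activities": result.truth.patient_activities.round(6)
        .reset_index()
        .to_dict(orient="list"),
    }
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(gt, fh, indent=1, sort_keys=True)
    paths["ground_truth"] = str(outdir / "ground_truth.json")
    return paths
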