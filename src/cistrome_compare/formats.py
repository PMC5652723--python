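"""Domain types and strict readers/writers for the pipeline's file formats.

All genomic coordinates are 0-based half-open (BED convention) everywhere
inside the package. Parsers never silently coerce: every rejection names the
offending record and line.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

BASES = "ACGT"


class FormatError(ValueError):
    """Malformed record in an input file."""


class ValidationError(ValueError):
    """Well-formed input violating a domain invariant."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval [start, end)."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("empty chromosome name")
        if self.start < 0:
            raise ValidationError(f"negative start {self.start} on {self.chrom}")
        if self.end <= self.start:
            raise ValidationError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class Peak:
    """A called binding peak with its summit (absolute bp position)."""

    interval: GenomicInterval
    summit: int
    score: float = 0.0
    name: str = "."

    def __post_init__(self) -> None:
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ValidationError(
                f"summit {self.summit} outside peak "
                f"{self.interval.chrom}:{self.interval.start}-{self.interval.end}"
            )


@dataclass(frozen=True)
class GeneRecord:
    """A gene reduced to its transcription start site."""

    gene_id: str
    chrom: str
    tss: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(
                f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        if self.tss < 0:
            raise ValidationError(f"gene {self.gene_id}: negative TSS {self.tss}")


@dataclass(frozen=True)
class PWM:
    """A position weight matrix of base probabilities over A, C, G, T."""

    motif_id: str
    matrix: np.ndarray  # L x 4, rows sum to 1

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        if m.ndim != 2 or m.shape[1] != 4 or m.shape[0] < 4:
            raise ValidationError(
                f"motif {self.motif_id}: matrix must be Lx4 with L >= 4, got {m.shape}"
            )
        if (m < 0).any():
            raise ValidationError(f"motif {self.motif_id}: negative probability")
        sums = m.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            raise ValidationError(
                f"motif {self.motif_id}: row sums deviate from 1 by more than 1e-6"
            )

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=1))


class SignalTrack:
    """Genome-wide coverage as sorted, non-overlapping valued intervals.

    Parameters
    ----------
    chrom_data
        Mapping chrom -> (starts, ends, values) arrays, 0-based half-open.
    total_reads
        Library size used for per-million normalization; must be positive.
    chrom_lengths
        Optional chromosome lengths; default is the last interval end.
    """

    def __init__(
        self,
        chrom_data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]],
        total_reads: float,
        chrom_lengths: dict[str, int] | None = None,
    ) -> None:
        if total_reads <= 0:
            raise ValidationError(f"total_reads must be positive, got {total_reads}")
        self.chrom_data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, (starts, ends, values) in chrom_data.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            values = np.asarray(values, dtype=float)
            if (values < 0).any():
                raise ValidationError(f"negative coverage value on {chrom}")
            if np.any(ends <= starts):
                raise ValidationError(f"empty interval on {chrom}")
            order = np.argsort(starts, kind="stable")
            starts, ends, values = starts[order], ends[order], values[order]
            if np.any(starts[1:] < ends[:-1]):
                raise ValidationError(f"overlapping intervals on {chrom}")
            self.chrom_data[chrom] = (starts, ends, values)
        self.total_reads = float(total_reads)
        self.chrom_lengths = dict(chrom_lengths or {})
        for chrom, (_, ends, _) in self.chrom_data.items():
            self.chrom_lengths.setdefault(chrom, int(ends[-1]) if len(ends) else 0)

    @property
    def chroms(self) -> list[str]:
        return sorted(self.chrom_data)

    def coverage_array(self, chrom: str, length: int | None = None) -> np.ndarray:
        """Dense per-bp coverage for one chromosome."""
        if length is None:
            length = self.chrom_lengths.get(chrom, 0)
        cov = np.zeros(length, dtype=float)
        if chrom in self.chrom_data:
            starts, ends, values = self.chrom_data[chrom]
            for s, e, v in zip(starts, ends, values):
                cov[s:min(e, length)] += v
        return cov

    @classmethod
    def from_dense(
        cls,
        coverage: dict[str, np.ndarray],
        total_reads: float,
        step: int = 1,
    ) -> "SignalTrack":
        """Build a track from dense per-bp arrays, run-length encoding values."""
        chrom_data = {}
        for chrom, cov in coverage.items():
            cov = np.asarray(cov, dtype=float)
            change = np.flatnonzero(np.diff(cov)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(cov)]))
            values = cov[starts]
            keep = values != 0
            chrom_data[chrom] = (starts[keep], ends[keep], values[keep])
        lengths = {c: len(cov) for c, cov in coverage.items()}
        return cls(chrom_data, total_reads, lengths)


@dataclass
class GeneSetCollection:
    """Named gene sets (pathways or target-gene signatures)."""

    sets: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValidationError(f"gene set {name!r} is empty")
            self.sets[name] = frozenset(genes)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets)

    def items(self):
        return self.sets.items()


@dataclass
class ExpressionCohort:
    """Genes x samples expression matrix with aligned clinical annotations.

    ``expression`` is a DataFrame indexed by gene_id with sample columns;
    ``clinical`` is indexed by sample_id and carries at least ``time``
    (follow-up), ``event`` (0/1) and ``er_status`` ('+'/'-').
    """

    expression: pd.DataFrame
    clinical: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.expression.columns) != list(self.clinical.index):
            raise ValidationError("expression columns and clinical index misaligned")
        if self.expression.isna().any().any():
            raise ValidationError("missing expression values after alignment")
        if (self.clinical["time"] < 0).any():
            bad = self.clinical.index[self.clinical["time"] < 0][0]
            raise ValidationError(f"negative survival time for sample {bad!r}")

    @property
    def genes(self) -> list[str]:
        return list(self.expression.index)

    @property
    def samples(self) -> list[str]:
        return list(self.expression.columns)

    @property
    def n_samples(self) -> int:
        return self.expression.shape[1]


# ---------------------------------------------------------------------------
# bedGraph


def read_bedgraph(path, total_reads: float | None = None) -> SignalTrack:
    """Read a 4-column bedGraph into a :class:`SignalTrack`.

    Library size is taken from a ``#total_reads=N`` header comment unless
    supplied explicitly.
    """
    per_chrom: dict[str, list[tuple[int, int, float]]] = {}
    header_reads = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if line.startswith("#total_reads="):
                    header_reads = float(line.split("=", 1)[1])
                continue
            if line.startswith("track"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise FormatError(
                    f"{path}:{lineno}: expected 4 tab-separated columns, "
                    f"got {len(parts)}: {line!r}"
                )
            chrom, s, e, v = parts
            try:
                start, end, value = int(s), int(e), float(v)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            if value < 0:
                raise ValidationError(f"{path}:{lineno}: negative value {value}")
            per_chrom.setdefault(chrom, []).append((start, end, value))
    if total_reads is None:
        total_reads = header_reads
    if total_reads is None:
        raise ValidationError(
            f"{path}: no '#total_reads=' header and no total_reads supplied"
        )
    chrom_data = {}
    for chrom, rows in per_chrom.items():
        arr = np.array(rows, dtype=float)
        chrom_data[chrom] = (
            arr[:, 0].astype(np.int64),
            arr[:, 1].astype(np.int64),
            arr[:, 2],
        )
    return SignalTrack(chrom_data, total_reads)


def write_bedgraph(track: SignalTrack, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#total_reads={track.total_reads:g}\n")
        for chrom in track.chroms:
            starts, ends, values = track.chrom_data[chrom]
            for s, e, v in zip(starts, ends, values):
                fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


# ---------------------------------------------------------------------------
# peaks (narrowPeak / BED)


def read_peaks(path) -> list[Peak]:
    """Read MACS2-style narrowPeak (BED6+4, summit offset in column 10).

    Six-column BED is accepted with the summit defaulting to the interval
    midpoint. Peaks are returned sorted by (chrom, start).
    """
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else "."
            score = float(parts[4]) if len(parts) > 4 and parts[4] != "." else 0.0
            interval = GenomicInterval(chrom, start, end)
            if len(parts) >= 10:
                offset = int(parts[9])
                if not (0 <= offset < end - start):
                    raise ValidationError(
                        f"{path}:{lineno}: summit offset {offset} outside "
                        f"{end - start}-bp peak"
                    )
                summit = start + offset
            else:
                summit = start + (end - start) // 2
            peaks.append(Peak(interval, summit, score, name))
    peaks.sort(key=lambda p: (p.interval.chrom, p.interval.start, p.interval.end))
    return peaks


def write_narrowpeak(peaks: list[Peak], path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            iv = p.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.name}\t{p.score:g}\t.\t"
                f"0\t-1\t-1\t{p.summit - iv.start}\n"
            )


# ---------------------------------------------------------------------------
# MEME motifs


def read_meme(path) -> list[PWM]:
    """Read PWMs from MEME minimal motif format."""
    pwms: list[PWM] = []
    motif_id = None
    rows: list[list[float]] = []
    in_matrix = False

    def flush():
        nonlocal motif_id, rows, in_matrix
        if motif_id is not None and rows:
            m = np.array(rows, dtype=float)
            sums = m.sum(axis=1)
            if np.any(np.abs(sums - 1.0) > 1e-3):
                bad = int(np.argmax(np.abs(sums - 1.0)))
                raise ValidationError(
                    f"{path}: motif {motif_id}: row {bad + 1} sums to "
                    f"{sums[bad]:.4f} (off by more than 1e-3)"
                )
            m = m / sums[:, None]
            pwms.append(PWM(motif_id, m))
        motif_id, rows, in_matrix = None, [], False

    with open(path) as fh:
        for line in fh:
            stripped = line.strip()
            if stripped.startswith("MOTIF"):
                flush()
                parts = stripped.split()
                if len(parts) < 2:
                    raise FormatError(f"{path}: MOTIF line without identifier")
                motif_id = parts[1]
            elif stripped.startswith("letter-probability matrix"):
                in_matrix = True
            elif in_matrix and stripped:
                fields = stripped.split()
                try:
                    row = [float(x) for x in fields]
                except ValueError:
                    in_matrix = False
                    continue
                if len(row) != 4:
                    raise FormatError(
                        f"{path}: motif {motif_id}: matrix row has {len(row)} columns"
                    )
                rows.append(row)
            elif in_matrix and not stripped:
                in_matrix = False
    flush()
    return pwms


def write_meme(pwms: list[PWM], path) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\n")
        fh.write("Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n")
        for pwm in pwms:
            fh.write(f"MOTIF {pwm.motif_id}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {len(pwm)} "
                f"nsites= 20 E= 0\n"
            )
            for row in pwm.matrix:
                fh.write(" " + " ".join(f"{x:.6f}" for x in row) + "\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gmt(path) -> GeneSetCollection:
    """Read tab-separated GMT (name, description, genes...)."""
    sets: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(
                    f"{path}:{lineno}: gene set {parts[0]!r} has no genes"
                )
            name = parts[0]
            genes = frozenset(g for g in parts[2:] if g)
            if not genes:
                raise ValidationError(f"{path}:{lineno}: gene set {name!r} is empty")
            sets[name] = genes
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.items():
            fh.write(name + "\tna\t" + "\t".join(sorted(genes)) + "\n")


# ---------------------------------------------------------------------------
# FASTA and TSS tables


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(genome: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=chrom, description="") for chrom, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")


def read_tss_table(path) -> list[GeneRecord]:
    """Read a 4-column TSV: gene_id, chrom, tss, strand."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    required = {"gene_id", "chrom", "tss", "strand"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: TSS table needs columns {sorted(required)}")
    if df["gene_id"].duplicated().any():
        dup = df["gene_id"][df["gene_id"].duplicated()].iloc[0]
        raise ValidationError(f"{path}: duplicate gene_id {dup!r}")
    return [
        GeneRecord(r.gene_id, r.chrom, int(r.tss), r.strand)
        for r in df.itertuples(index=False)
    ]


def write_tss_table(genes: list[GeneRecord], path) -> None:
    pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "chrom": [g.chrom for g in genes],
            "tss": [g.tss for g in genes],
            "strand": [g.strand for g in genes],
        }
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# expression + clinical cohort


def read_cohort(expr_path, clinical_path) -> ExpressionCohort:
    """Read genes x samples expression TSV plus a clinical TSV.

    Samples present in only one table are dropped (count logged); at least
    one shared sample is required.
    """
    expr = pd.read_csv(expr_path, sep="\t", index_col=0)
    clin = pd.read_csv(clinical_path, sep="\t", index_col="sample_id")
    shared = [s for s in expr.columns if s in clin.index]
    if not shared:
        raise ValidationError(
            f"no overlapping samples between {expr_path} and {clinical_path}"
        )
    dropped = (len(expr.columns) - len(shared)) + (len(clin.index) - len(shared))
    if dropped:
        logger.info("read_cohort: dropped %d unmatched samples", dropped)
    expr = expr[shared]
    clin = clin.loc[shared]
    return ExpressionCohort(expr, clin)


def write_cohort(cohort: ExpressionCohort, expr_path, clinical_path) -> None:
    cohort.expression.to_csv(expr_path, sep="\t")
    clin = cohort.clinical.copy()
    clin.index.name = "sample_id"
    clin.to_csv(clinical_path, sep="\t")
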