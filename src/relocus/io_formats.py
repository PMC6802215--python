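"""Genomic text formats and the shared coordinate types.

All internal coordinates are 0-based half-open intervals.  The only 1-based
surface is :attr:`Variant.pos` (as printed in GWAS summary statistics) and
report output; the conversion happens at the parser boundary and nowhere else.
Chromosome names are passed through verbatim -- no ``chr`` normalization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "FormatError",
    "GenomicInterval",
    "Variant",
    "GeneModel",
    "SignalTrack",
    "ContactRecord",
    "PWMRecord",
    "read_bed",
    "write_bed",
    "read_gwas_tsv",
    "write_gwas_tsv",
    "read_bedgraph",
    "write_bedgraph",
    "read_bedpe",
    "write_bedpe",
    "read_pfm",
    "write_pfm",
    "read_counts",
    "write_counts",
    "read_genes_tsv",
    "write_genes_tsv",
    "read_fasta",
    "write_fasta",
    "check_chrom_consistency",
]

_STRANDS = {"+", "-", "."}
_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


class FormatError(ValueError):
    """Raised for malformed or invalid input files."""


def _normalize_strand(s: str) -> str:
    # Unicode minus occasionally appears in hand-edited BED files.
    if s in ("−", "-"):
        return "-"
    if s in _STRANDS:
        return s
    raise FormatError(f"invalid strand {s!r}")


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic span ``[start, end)``.

    Point positions are width-1 intervals; ``start == end`` is forbidden.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}: "
                "require 0 <= start < end"
            )
        object.__setattr__(self, "strand", _normalize_strand(self.strand))

    @property
    def width(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, chrom: str, pos: int) -> bool:
        """True iff the 0-based base ``pos`` lies inside the interval."""
        return chrom == self.chrom and self.start <= pos < self.end


@dataclass(frozen=True)
class Variant:
    """A single-nucleotide variant as read from summary statistics.

    ``pos`` is 1-based (summary-statistics convention); :attr:`interval`
    gives the equivalent 0-based width-1 span, and the round trip
    ``interval.start + 1 == pos`` is lossless.
    """

    rsid: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    pvalue: float

    def __post_init__(self) -> None:
        if not (0.0 < self.pvalue <= 1.0):
            raise ValueError(f"{self.rsid}: pvalue {self.pvalue} not in (0, 1]")
        if self.pos < 1:
            raise ValueError(f"{self.rsid}: pos must be >= 1 (1-based)")
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"{self.rsid}: ref and alt alleles are identical")

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.pos - 1, self.pos)


@dataclass(frozen=True)
class GeneModel:
    """A gene with its body span and transcription start site.

    ``tss`` is the 0-based coordinate of the first transcribed base: the
    leftmost base of the body on the + strand, the rightmost on the - strand.
    """

    gene_id: str
    symbol: str
    chrom: str
    body: GenomicInterval
    strand: str
    tss: int

    def __post_init__(self) -> None:
        strand = _normalize_strand(self.strand)
        object.__setattr__(self, "strand", strand)
        if strand == "+" and self.tss != self.body.start:
            raise ValueError(f"{self.gene_id}: + strand TSS must equal body.start")
        if strand == "-" and self.tss != self.body.end - 1:
            raise ValueError(f"{self.gene_id}: - strand TSS must equal body.end - 1")

    @classmethod
    def from_body(
        cls, gene_id: str, symbol: str, chrom: str, start: int, end: int, strand: str
    ) -> "GeneModel":
        body = GenomicInterval(chrom, start, end, strand)
        tss = start if _normalize_strand(strand) == "+" else end - 1
        return cls(gene_id, symbol, chrom, body, strand, tss)

    def promoter(self, upstream: int = 1500, downstream: int = 500) -> GenomicInterval:
        """Strand-oriented promoter window around the TSS, inclusive ends.

        On + the window covers bases ``[tss - upstream, tss + downstream]``;
        on - it is mirrored.  Returned as a half-open interval clipped at 0.
        """
        if self.strand == "-":
            lo, hi = self.tss - downstream, self.tss + upstream
        else:
            lo, hi = self.tss - upstream, self.tss + downstream
        return GenomicInterval(self.chrom, max(0, lo), hi + 1, self.strand)


@dataclass(frozen=True)
class ContactRecord:
    """A chromatin contact between two anchors, e.g. a PCHi-C interaction."""

    anchor_a: GenomicInterval
    anchor_b: GenomicInterval
    score: float = 1.0
    target_gene_id: str | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.score <= 1.0):
            raise ValueError(f"contact score {self.score} not in [0, 1]")


class SignalTrack:
    """Run-length encoded per-base signal: sorted, non-overlapping runs.

    Stored per chromosome as parallel numpy arrays (starts, ends, values).
    Bases not covered by any run have signal 0.
    """

    def __init__(
        self, runs: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]]
    ) -> None:
        self._runs: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, (starts, ends, values) in runs.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            values = np.asarray(values, dtype=np.float64)
            if not (len(starts) == len(ends) == len(values)):
                raise ValueError(f"{chrom}: run arrays have unequal lengths")
            if np.any(ends <= starts):
                raise FormatError(f"{chrom}: run with end <= start")
            if np.any(starts[1:] < ends[:-1]):
                raise FormatError(f"{chrom}: overlapping or unsorted runs")
            if np.any(values < 0):
                raise ValueError(f"{chrom}: negative signal value")
            self._runs[chrom] = (starts, ends, values)

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, int, int, float]]
    ) -> "SignalTrack":
        by_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, value in records:
            by_chrom.setdefault(chrom, []).append((start, end, value))
        runs = {}
        for chrom, rows in by_chrom.items():
            rows.sort()
            s, e, v = zip(*rows)
            runs[chrom] = (np.array(s), np.array(e), np.array(v))
        return cls(runs)

    @property
    def chroms(self) -> list[str]:
        return list(self._runs)

    def runs(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        if chrom not in self._runs:
            z = np.array([], dtype=np.int64)
            return z, z, np.array([], dtype=np.float64)
        return self._runs[chrom]

    def iter_records(self) -> Iterator[tuple[str, int, int, float]]:
        for chrom in self._runs:
            s, e, v = self._runs[chrom]
            for i in range(len(s)):
                yield chrom, int(s[i]), int(e[i]), float(v[i])

    def extent(self, chrom: str) -> int:
        """One past the last covered base (0 for uncovered chromosomes)."""
        _, e, _ = self.runs(chrom)
        return int(e[-1]) if len(e) else 0

    def value_at(self, chrom: str, pos: int) -> float:
        s, e, v = self.runs(chrom)
        if len(s) == 0:
            return 0.0
        i = int(np.searchsorted(s, pos, side="right")) - 1
        if i >= 0 and pos < e[i]:
            return float(v[i])
        return 0.0

    def values_at(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        s, e, v = self.runs(chrom)
        positions = np.asarray(positions, dtype=np.int64)
        if len(s) == 0:
            return np.zeros(len(positions))
        i = np.searchsorted(s, positions, side="right") - 1
        ok = (i >= 0) & (positions < e[np.clip(i, 0, len(e) - 1)])
        out = np.where(ok, v[np.clip(i, 0, len(v) - 1)], 0.0)
        return out

    def _integral(self, chrom: str, x: np.ndarray) -> np.ndarray:
        """Integral of the signal over [0, x) for each x (vectorized)."""
        s, e, v = self.runs(chrom)
        x = np.asarray(x, dtype=np.int64)
        if len(s) == 0:
            return np.zeros(len(x))
        cum = np.concatenate([[0.0], np.cumsum(v * (e - s))])
        j = np.searchsorted(e, x, side="right")  # runs fully before x
        jc = np.clip(j, 0, len(s) - 1)
        partial = np.where(
            (j < len(s)) & (x > s[jc]), v[jc] * np.maximum(0, x - s[jc]), 0.0
        )
        return cum[j] + partial

    def mean_over(self, chrom: str, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
        """Coverage-weighted mean signal over each [start, end); gaps count 0."""
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        if np.any(ends <= starts):
            raise ValueError("mean_over requires end > start")
        return (self._integral(chrom, ends) - self._integral(chrom, starts)) / (
            ends - starts
        )

    def merged(self) -> "SignalTrack":
        """Merge contiguous runs of identical value (drop zero-value runs)."""
        out = {}
        for chrom, (s, e, v) in self._runs.items():
            keep_s, keep_e, keep_v = [], [], []
            for i in range(len(s)):
                if v[i] == 0.0:
                    continue
                if keep_v and keep_v[-1] == v[i] and keep_e[-1] == s[i]:
                    keep_e[-1] = e[i]
                else:
                    keep_s.append(s[i])
                    keep_e.append(e[i])
                    keep_v.append(v[i])
            out[chrom] = (np.array(keep_s), np.array(keep_e), np.array(keep_v))
        return SignalTrack(out)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SignalTrack):
            return NotImplemented
        a, b = self.merged()._runs, other.merged()._runs
        keys = set(a) | set(b)
        for chrom in keys:
            sa = a.get(chrom, (np.array([]),) * 3)
            sb = b.get(chrom, (np.array([]),) * 3)
            if not all(np.array_equal(x, y) for x, y in zip(sa, sb)):
                return False
        return True


@dataclass
class PWMRecord:
    """A position frequency/weight matrix for one transcription factor.

    ``matrix`` has shape (4, L): rows A, C, G, T; entries are counts or
    probabilities.  ``background`` is the assumed base composition.
    """

    tf_name: str
    matrix: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        self.background = np.asarray(self.background, dtype=np.float64)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != 4:
            raise ValueError(f"{self.tf_name}: matrix must be 4 x L")
        if self.matrix.shape[1] < 1:
            raise ValueError(f"{self.tf_name}: matrix needs >= 1 position")
        if np.any(self.matrix < 0):
            raise ValueError(f"{self.tf_name}: negative matrix entry")

    @property
    def length(self) -> int:
        return int(self.matrix.shape[1])

    def probabilities(self, pseudocount: float = 0.5) -> np.ndarray:
        """Per-position base probabilities after adding a pseudocount."""
        m = self.matrix + pseudocount
        return m / m.sum(axis=0, keepdims=True)

    def log_odds(self, pseudocount: float = 0.5) -> np.ndarray:
        """log2 odds of each base vs. background, shape (4, L)."""
        p = self.probabilities(pseudocount)
        return np.log2(p / self.background[:, None])

    def max_score(self, pseudocount: float = 0.5) -> float:
        return float(self.log_odds(pseudocount).max(axis=0).sum())

    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.matrix.argmax(axis=0))


# ---------------------------------------------------------------------------
# BED


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a BED3/BED6 file into 0-based half-open intervals."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= 3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            strand = fields[5] if len(fields) >= 6 else "."
            try:
                intervals.append(GenomicInterval(fields[0], start, end, strand))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return intervals


def write_bed(
    intervals: Sequence[GenomicInterval],
    path: str | Path,
    names: Sequence[str] | None = None,
) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names is not None else "."
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# GWAS summary statistics

_GWAS_COLUMNS = ["chrom", "pos", "rsid", "ref", "alt", "pvalue"]


def read_gwas_tsv(path: str | Path) -> list[Variant]:
    """Read summary statistics (TSV with header) into :class:`Variant` rows.

    Positions are kept 1-based; duplicate rsids are warned about but kept.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _GWAS_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    dup = df["rsid"][df["rsid"].duplicated()]
    if len(dup):
        warnings.warn(f"{path}: duplicate rsids kept: {sorted(set(dup))[:5]}...")
    variants = []
    for row in df.itertuples(index=False):
        try:
            variants.append(
                Variant(
                    rsid=str(row.rsid),
                    chrom=str(row.chrom),
                    pos=int(row.pos),
                    ref_allele=str(row.ref),
                    alt_allele=str(row.alt),
                    pvalue=float(row.pvalue),
                )
            )
        except ValueError as exc:
            raise FormatError(f"{path}: {exc}") from exc
    return variants


def write_gwas_tsv(variants: Sequence[Variant], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "chrom": [v.chrom for v in variants],
            "pos": [v.pos for v in variants],
            "rsid": [v.rsid for v in variants],
            "ref": [v.ref_allele for v in variants],
            "alt": [v.alt_allele for v in variants],
            "pvalue": [f"{v.pvalue:.6g}" for v in variants],
        }
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# bedGraph


def read_bedgraph(path: str | Path) -> SignalTrack:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns")
            try:
                records.append(
                    (fields[0], int(fields[1]), int(fields[2]), float(fields[3]))
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad field") from exc
    try:
        return SignalTrack.from_records(records)
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_bedgraph(track: SignalTrack, path: str | Path) -> None:
    """Write a bedGraph; contiguous equal-value runs are merged, values %.6g."""
    with open(path, "w") as fh:
        for chrom, start, end, value in track.merged().iter_records():
            fh.write(f"{chrom}\t{start}\t{end}\t{value:.6g}\n")


# ---------------------------------------------------------------------------
# BEDPE


def read_bedpe(path: str | Path) -> list[ContactRecord]:
    """Read contacts: 6 coordinate columns + optional score + target_gene_id."""
    contacts = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise FormatError(f"{path}:{lineno}: expected >= 6 columns")
            try:
                a = GenomicInterval(f[0], int(f[1]), int(f[2]))
                b = GenomicInterval(f[3], int(f[4]), int(f[5]))
                score = float(f[6]) if len(f) >= 7 and f[6] != "." else 1.0
                target = f[7] if len(f) >= 8 and f[7] != "." else None
                contacts.append(ContactRecord(a, b, score, target))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return contacts


def write_bedpe(contacts: Sequence[ContactRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for c in contacts:
            target = c.target_gene_id if c.target_gene_id is not None else "."
            fh.write(
                f"{c.anchor_a.chrom}\t{c.anchor_a.start}\t{c.anchor_a.end}\t"
                f"{c.anchor_b.chrom}\t{c.anchor_b.start}\t{c.anchor_b.end}\t"
                f"{c.score:.6g}\t{target}\n"
            )


# ---------------------------------------------------------------------------
# JASPAR PFM


def read_pfm(path: str | Path) -> list[PWMRecord]:
    """Read JASPAR-style PFMs: '>name' header then four rows A/C/G/T.

    Rows may be bare numbers or 'A [ 1 2 3 ]' style.
    """
    pwms: list[PWMRecord] = []
    name: str | None = None
    rows: list[list[float]] = []

    def flush() -> None:
        nonlocal name, rows
        if name is None:
            return
        if len(rows) != 4:
            raise FormatError(f"{path}: PFM {name!r} has {len(rows)} rows, need 4")
        lengths = {len(r) for r in rows}
        if len(lengths) != 1:
            raise FormatError(f"{path}: PFM {name!r} rows have unequal lengths")
        pwms.append(PWMRecord(name, np.array(rows)))
        name, rows = None, []

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                name = line[1:].strip().split()[-1] if line[1:].strip() else "PWM"
                continue
            cleaned = line.replace("[", " ").replace("]", " ")
            fields = cleaned.split()
            if fields and fields[0].upper() in ("A", "C", "G", "T"):
                fields = fields[1:]
            try:
                rows.append([float(x) for x in fields])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric PFM entry") from exc
    flush()
    return pwms


def write_pfm(pwms: Sequence[PWMRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.tf_name}\n")
            for i, base in enumerate(_BASES):
                row = " ".join(f"{x:g}" for x in pwm.matrix[i])
                fh.write(f"{base} [ {row} ]\n")


# ---------------------------------------------------------------------------
# Counts / genes / generic tables


def read_counts(path: str | Path) -> pd.DataFrame:
    """Read a gene x sample count table (TSV, first column = gene id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            raise FormatError(
                f"{path}: non-numeric value at gene {bad[0]!r}, sample {col!r}"
            )
        df[col] = coerced
    return df


def write_counts(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t")


def read_genes_tsv(path: str | Path) -> list[GeneModel]:
    """Read gene annotation: gene_id, symbol, chrom, start, end, strand."""
    df = pd.read_csv(path, sep="\t")
    required = ["gene_id", "symbol", "chrom", "start", "end", "strand"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    genes = []
    for row in df.itertuples(index=False):
        genes.append(
            GeneModel.from_body(
                str(row.gene_id),
                str(row.symbol),
                str(row.chrom),
                int(row.start),
                int(row.end),
                str(row.strand),
            )
        )
    return genes


def write_genes_tsv(genes: Sequence[GeneModel], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "symbol": [g.symbol for g in genes],
            "chrom": [g.chrom for g in genes],
            "start": [g.body.start for g in genes],
            "end": [g.body.end for g in genes],
            "strand": [g.strand for g in genes],
            "tss": [g.tss for g in genes],
        }
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=chrom, description="")
        for chrom, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------


def check_chrom_consistency(**named_chrom_sets: Iterable[str]) -> None:
    """Raise if the chromosome name sets of the inputs are pairwise disjoint.

    Inputs that legitimately cover a subset of chromosomes are fine; what this
    guards against is e.g. 'chr1' vs. '1' mismatches where nothing intersects.
    """
    sets = {name: set(chroms) for name, chroms in named_chrom_sets.items()}
    nonempty = {k: v for k, v in sets.items() if v}
    if len(nonempty) < 2:
        return
    names = list(nonempty)
    base = nonempty[names[0]]
    for other in names[1:]:
        if base & nonempty[other]:
            return
    raise FormatError(
        "no chromosome names shared between inputs: "
        + "; ".join(f"{k}={sorted(v)[:4]}" for k, v in nonempty.items())
    )
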