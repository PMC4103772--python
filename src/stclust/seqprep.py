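"""Phase 1 - sequence preparation.

Parses raw amplicon reads, demultiplexes them by dual barcodes, trims
barcodes and primers, applies the minimum-length filter and assembles
per-sample libraries.  Base qualities are never used: the stepwise
clustering operates purely on sequences and read counts, so FASTQ
qualities are discarded on input.

Reads are assumed to have the layout

    fwd_barcode + fwd_primer + insert + revcomp(rev_primer) + revcomp(rev_barcode)

and are stored in forward orientation.  Filters are applied in a fixed
order - barcode identification first, then the length filter - so that
the preparation report attributes every discarded read to exactly one
cause.
"""

from __future__ import annotations

import gzip
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

_VALID = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class RawRead:
    """One sequencing read: an identifier and its base calls (ACGTN)."""

    read_id: str
    bases: str


@dataclass(frozen=True)
class BarcodeMap:
    """Sample -> (forward barcode, reverse barcode) assignments.

    All barcodes must share one declared length and every
    (forward, reverse) combination must identify a unique sample.
    """

    entries: tuple[tuple[str, str, str], ...]  # (sample_id, fwd, rev)

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("barcode map is empty")
        lengths = {len(f) for _, f, r in self.entries} | {
            len(r) for _, f, r in self.entries
        }
        if len(lengths) != 1:
            raise ValueError(f"barcodes have mixed lengths: {sorted(lengths)}")
        combos = [(f, r) for _, f, r in self.entries]
        if len(set(combos)) != len(combos):
            raise ValueError("duplicate (forward, reverse) barcode combination")

    @property
    def barcode_length(self) -> int:
        return len(self.entries[0][1])

    @classmethod
    def from_tsv(cls, path: str | Path) -> "BarcodeMap":
        """Read a 3-column TSV (sample_id, fwd_barcode, rev_barcode) with
        header."""
        import pandas as pd

        df = pd.read_csv(path, sep="\t", dtype=str)
        cols = list(df.columns[:3])
        entries = tuple(
            (str(r[cols[0]]), str(r[cols[1]]).upper(), str(r[cols[2]]).upper())
            for _, r in df.iterrows()
        )
        return cls(entries)


@dataclass
class SampleLibrary:
    """Multiset of primer/barcode-free amplicon sequences for one sample."""

    sample_id: str
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for seq, n in self.counts.items():
            if n <= 0:
                raise ValueError(f"zero/negative count for {seq[:20]}...")

    @property
    def library_size(self) -> int:
        return sum(self.counts.values())

    @property
    def n_unique(self) -> int:
        return len(self.counts)

    def add(self, seq: str, n: int = 1) -> None:
        self.counts[seq] = self.counts.get(seq, 0) + n

    # -- plain-text round trips -------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("sequence\tcount\n")
            for seq in sorted(self.counts, key=lambda s: (-self.counts[s], s)):
                fh.write(f"{seq}\t{self.counts[seq]}\n")

    @classmethod
    def from_tsv(cls, path: str | Path, sample_id: str | None = None) -> "SampleLibrary":
        counts: dict[str, int] = {}
        with open(path) as fh:
            header = fh.readline()
            if not header.lower().startswith("sequence"):
                raise ValueError(f"{path}: expected 'sequence\\tcount' header")
            for line in fh:
                if not line.strip():
                    continue
                seq, n = line.split("\t")
                counts[seq.strip().upper()] = counts.get(seq.strip().upper(), 0) + int(n)
        return cls(sample_id or Path(path).stem, counts)

    def to_fasta(self, path: str | Path) -> None:
        """Write one record per read instance (count-expanded)."""
        with open(path, "w") as fh:
            i = 0
            for seq in sorted(self.counts, key=lambda s: (-self.counts[s], s)):
                for _ in range(self.counts[seq]):
                    fh.write(f">{self.sample_id}_read{i}\n{seq}\n")
                    i += 1

    @classmethod
    def from_fasta(cls, path: str | Path, sample_id: str | None = None) -> "SampleLibrary":
        counts: dict[str, int] = {}
        for read in parse_reads(path, "fasta"):
            counts[read.bases] = counts.get(read.bases, 0) + 1
        return cls(sample_id or Path(path).stem, counts)


@dataclass
class PrepReport:
    """Read accounting for one demultiplexing run.

    Invariant: n_input_reads = n_failed_barcode + n_failed_length +
    n_assigned (barcode identification is applied before the length
    filter).
    """

    n_input_reads: int = 0
    n_failed_barcode: int = 0
    n_failed_length: int = 0
    n_assigned: int = 0
    per_sample_sizes: dict[str, int] = field(default_factory=dict)

    def validate(self) -> None:
        if self.n_input_reads != (
            self.n_failed_barcode + self.n_failed_length + self.n_assigned
        ):
            raise AssertionError("prep report does not balance")
        if self.n_assigned != sum(self.per_sample_sizes.values()):
            raise AssertionError("assigned reads do not match sample sizes")

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("metric\tvalue\n")
            fh.write(f"n_input_reads\t{self.n_input_reads}\n")
            fh.write(f"n_failed_barcode\t{self.n_failed_barcode}\n")
            fh.write(f"n_failed_length\t{self.n_failed_length}\n")
            fh.write(f"n_assigned\t{self.n_assigned}\n")
            for sid in sorted(self.per_sample_sizes):
                fh.write(f"sample:{sid}\t{self.per_sample_sizes[sid]}\n")


# ---------------------------------------------------------------------------
# parsing


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _infer_format(path: str | Path) -> str:
    name = Path(path).name.lower()
    if name.endswith(".gz"):
        name = name[:-3]
    if name.endswith((".fq", ".fastq")):
        return "fastq"
    return "fasta"


def parse_reads(path: str | Path, fmt: str | None = None) -> list[RawRead]:
    """Parse FASTA or FASTQ into RawReads, order preserved.

    Qualities of FASTQ records are discarded.  A record containing a
    character outside ACGTN raises a ValueError naming the record.
    """
    fmt = (fmt or _infer_format(path)).lower()
    if fmt not in ("fasta", "fastq"):
        raise ValueError(f"unsupported format: {fmt}")
    reads: list[RawRead] = []
    with _open_text(path) as fh:
        for i, rec in enumerate(SeqIO.parse(fh, fmt)):
            bases = str(rec.seq).upper()
            if not bases or set(bases) - _VALID:
                bad = sorted(set(bases) - _VALID)
                raise ValueError(
                    f"record {i} ({rec.id}): invalid characters {bad or 'empty'}"
                )
            reads.append(RawRead(rec.id, bases))
    if not reads:
        warnings.warn(f"{path}: no records parsed", stacklevel=2)
    return reads


# ---------------------------------------------------------------------------
# demultiplexing


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def demultiplex(
    reads: Iterable[RawRead],
    barcodes: BarcodeMap,
    fwd_primer: str,
    rev_primer: str,
    max_barcode_mismatch: int = 0,
    min_length: int = 200,
) -> tuple[dict[str, SampleLibrary], PrepReport]:
    """Assign reads to samples by dual barcodes, trim and length-filter.

    A read is assigned only when exactly one barcode-map entry matches
    both its 5' forward barcode and its 3' reverse barcode (as reverse
    complement) at minimal total mismatch distance within
    ``max_barcode_mismatch`` per barcode; equally good matches to two
    samples discard the read as non-unique.  Surviving reads are
    stripped of barcodes and primers; intra-primer sequences shorter
    than ``min_length`` are discarded and counted separately.
    """
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    if max_barcode_mismatch < 0:
        raise ValueError("max_barcode_mismatch must be >= 0")
    L = barcodes.barcode_length
    fwd_primer = fwd_primer.upper()
    rev_primer = rev_primer.upper()
    head = L + len(fwd_primer)
    tail = L + len(rev_primer)

    report = PrepReport()
    libs: dict[str, SampleLibrary] = {}
    for read in reads:
        report.n_input_reads += 1
        if len(read.bases) < head + tail:
            # cannot even carry both barcodes + primers
            report.n_failed_barcode += 1
            continue
        prefix = read.bases[:L]
        suffix = revcomp(read.bases[-L:])
        best: tuple[int, str] | None = None
        tied = False
        for sample_id, fwd, rev in barcodes.entries:
            df = _hamming(prefix, fwd)
            if df > max_barcode_mismatch:
                continue
            dr = _hamming(suffix, rev)
            if dr > max_barcode_mismatch:
                continue
            d = df + dr
            if best is None or d < best[0]:
                best = (d, sample_id)
                tied = False
            elif d == best[0] and sample_id != best[1]:
                tied = True
        if best is None or tied:
            report.n_failed_barcode += 1
            continue
        insert = read.bases[head : len(read.bases) - tail]
        if len(insert) < min_length:
            report.n_failed_length += 1
            continue
        sid = best[1]
        if sid not in libs:
            libs[sid] = SampleLibrary(sid, {})
        libs[sid].add(insert)
        report.n_assigned += 1
    report.per_sample_sizes = {sid: lib.library_size for sid, lib in libs.items()}
    report.validate()
    return libs, report


def subsample_library(lib: SampleLibrary, cap: int, seed: int) -> SampleLibrary:
    """Draw exactly ``cap`` reads without replacement (multiset over read
    instances); libraries at or under the cap are returned unchanged."""
    if cap < 1:
        raise ValueError("cap must be >= 1")
    if lib.library_size <= cap:
        return lib
    seqs = sorted(lib.counts)
    counts = np.array([lib.counts[s] for s in seqs])
    instances = np.repeat(np.arange(len(seqs)), counts)
    rng = np.random.default_rng(seed)
    kept = rng.choice(instances, size=cap, replace=False)
    new_counts = np.bincount(kept, minlength=len(seqs))
    return SampleLibrary(
        lib.sample_id,
        {s: int(n) for s, n in zip(seqs, new_counts) if n > 0},
    )


def filter_min_library(
    libs: Mapping[str, SampleLibrary], min_reads: int
) -> dict[str, SampleLibrary]:
    """Keep samples whose library holds at least ``min_reads`` reads."""
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    kept: dict[str, SampleLibrary] = {}
    for sid, lib in libs.items():
        if lib.library_size >= min_reads:
            kept[sid] = lib
        else:
            logger.info(
                "sample %s not genotyped: %d reads < %d",
                sid,
                lib.library_size,
                min_reads,
            )
    return kept
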