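"""Sequence, annotation, count-track and interval IO.

Coordinate convention: 0-based half-open everywhere internally (BED-native);
GTF and VCF positions are shifted at the file boundary.  RNA data is stranded,
so every interval carries a strand and minus-strand windows are returned in
transcript (5'→3') orientation: sequence reverse-complemented, counts
reversed.

Count tracks are sparse per-(chromosome, strand) integer arrays; bedGraph is
the canonical text format, with optional bigWig support when pyBigWig is
importable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from pyfaidx import Fasta

logger = logging.getLogger(__name__)

BASE_ORDER = "ACGT"
_ENCODE = {
    "A": 0, "C": 1, "G": 2, "T": 3, "U": 3,
    "a": 0, "c": 1, "g": 2, "t": 3, "u": 3,
}
_COMPLEMENT = str.maketrans("ACGTUacgtuNn", "TGCAAtgcaaNn")


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open stranded interval."""

    chrom: str
    start: int
    end: int
    strand: str
    name: str = "."

    def __post_init__(self):
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end ({self.end}) must exceed start ({self.start})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


def reverse_complement(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]


def one_hot_encode(sequence: str) -> np.ndarray:
    """One-hot encode a nucleotide string as a (length, 4) float32 matrix.

    Base order is A, C, G, U/T; unknown base N maps to an all-zero row.
    Characters outside {A, C, G, T, U, N} are rejected with their position.
    """
    out = np.zeros((len(sequence), 4), dtype=np.float32)
    for i, base in enumerate(sequence):
        if base in ("N", "n"):
            continue
        idx = _ENCODE.get(base)
        if idx is None:
            raise ValueError(
                f"invalid nucleotide {base!r} at position {i}; "
                "alphabet is A/C/G/T/U/N"
            )
        out[i, idx] = 1.0
    return out


def decode_one_hot(matrix: np.ndarray, rna: bool = False) -> str:
    """Inverse of :func:`one_hot_encode`; all-zero rows decode to N."""
    alphabet = "ACGU" if rna else "ACGT"
    chars = []
    for row in np.asarray(matrix):
        if row.sum() == 0:
            chars.append("N")
        else:
            chars.append(alphabet[int(np.argmax(row))])
    return "".join(chars)


class CountTrack:
    """Stranded per-base 5' read-start counts, addressable by interval.

    Values are stored per (chromosome, strand) as dense int64 arrays covering
    ``[0, max_covered_position)``; queries beyond the covered range return
    zeros (sparse-track contract).
    """

    def __init__(self):
        self._arrays: dict[tuple[str, str], np.ndarray] = {}

    @property
    def chroms(self) -> set[str]:
        return {c for c, _ in self._arrays}

    def add_counts(self, chrom: str, strand: str, start: int,
                   values: np.ndarray) -> None:
        values = np.asarray(values)
        if np.any(values < 0) or not np.issubdtype(values.dtype, np.integer):
            values = values.astype(np.int64)
            if np.any(values < 0):
                raise ValueError("counts must be non-negative integers")
        key = (chrom, strand)
        end = start + len(values)
        arr = self._arrays.get(key)
        if arr is None or len(arr) < end:
            new = np.zeros(end, dtype=np.int64)
            if arr is not None:
                new[: len(arr)] = arr
            self._arrays[key] = new
        self._arrays[key][start:end] += values

    def fetch(self, interval: GenomicInterval) -> np.ndarray:
        """Counts over ``interval`` in genomic orientation (not strand-flipped)."""
        arr = self._arrays.get((interval.chrom, interval.strand))
        out = np.zeros(len(interval), dtype=np.int64)
        if arr is None:
            return out
        lo = min(interval.start, len(arr))
        hi = min(interval.end, len(arr))
        if hi > lo:
            out[: hi - lo] = arr[lo:hi]
        return out

    # -- bedGraph ------------------------------------------------------------

    @classmethod
    def from_bedgraph(cls, plus_path=None, minus_path=None) -> "CountTrack":
        track = cls()
        for path, strand in ((plus_path, "+"), (minus_path, "-")):
            if path is None:
                continue
            with open(path) as fh:
                for line in fh:
                    line = line.strip()
                    if not line or line.startswith(("track", "#", "browser")):
                        continue
                    chrom, start, end, value = line.split()[:4]
                    start, end = int(start), int(end)
                    val = float(value)
                    ival = int(round(abs(val)))  # minus tracks often negated
                    if ival:
                        track.add_counts(
                            chrom, strand, start,
                            np.full(end - start, ival, dtype=np.int64),
                        )
        return track

    def to_bedgraph(self, plus_path, minus_path) -> None:
        for path, strand in ((plus_path, "+"), (minus_path, "-")):
            with open(path, "w") as fh:
                for (chrom, s), arr in sorted(self._arrays.items()):
                    if s != strand:
                        continue
                    # run-length encode non-zero stretches
                    nz = np.flatnonzero(arr)
                    for start, end in _runs(nz, arr):
                        fh.write(f"{chrom}\t{start}\t{end}\t{arr[start]}\n")

    # -- bigWig (optional) ---------------------------------------------------

    @classmethod
    def from_bigwig(cls, plus_path=None, minus_path=None) -> "CountTrack":
        import pyBigWig  # optional dependency

        track = cls()
        for path, strand in ((plus_path, "+"), (minus_path, "-")):
            if path is None:
                continue
            bw = pyBigWig.open(str(path))
            try:
                for chrom, length in bw.chroms().items():
                    vals = np.nan_to_num(
                        np.asarray(bw.values(chrom, 0, length), dtype=float)
                    )
                    ivals = np.rint(np.abs(vals)).astype(np.int64)
                    if ivals.any():
                        track.add_counts(chrom, strand, 0, ivals)
            finally:
                bw.close()
        return track


def _runs(nonzero_idx: np.ndarray, arr: np.ndarray):
    """Yield (start, end) of maximal runs with constant non-zero value."""
    i = 0
    n = len(nonzero_idx)
    while i < n:
        start = nonzero_idx[i]
        j = i
        while (
            j + 1 < n
            and nonzero_idx[j + 1] == nonzero_idx[j] + 1
            and arr[nonzero_idx[j + 1]] == arr[start]
        ):
            j += 1
        yield int(start), int(nonzero_idx[j]) + 1
        i = j + 1


class SequenceSource:
    """Random-access nucleotide sequences from a FASTA file or a dict."""

    def __init__(self, source):
        if isinstance(source, dict):
            self._seqs = {k: str(v) for k, v in source.items()}
            self._fasta = None
        else:
            self._fasta = Fasta(str(source))
            self._seqs = None

    @property
    def chroms(self):
        if self._seqs is not None:
            return set(self._seqs)
        return set(self._fasta.keys())

    def chrom_length(self, chrom: str) -> int:
        if chrom not in self.chroms:
            raise KeyError(f"chromosome {chrom!r} not in sequence source")
        if self._seqs is not None:
            return len(self._seqs[chrom])
        return len(self._fasta[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Plus-strand sequence, 0-based half-open."""
        if chrom not in self.chroms:
            raise KeyError(f"chromosome {chrom!r} not in sequence source")
        if self._seqs is not None:
            return self._seqs[chrom][start:end].upper()
        return str(self._fasta[chrom][start:end]).upper()


def fetch_window(sequence_source: SequenceSource, track: CountTrack | None,
                 interval: GenomicInterval):
    """Fetch (one-hot sequence, count vector) for an interval, 5'→3' oriented.

    For minus-strand intervals the sequence is reverse-complemented and the
    count vector reversed, so index 0 is always the 5'-most transcript
    position.
    """
    if interval.chrom not in sequence_source.chroms:
        raise KeyError(f"chromosome {interval.chrom!r} absent from sequence source")
    if interval.end > sequence_source.chrom_length(interval.chrom):
        raise ValueError(
            f"interval {interval.chrom}:{interval.start}-{interval.end} exceeds "
            f"chromosome length {sequence_source.chrom_length(interval.chrom)}"
        )
    seq = sequence_source.fetch(interval.chrom, interval.start, interval.end)
    counts = (track.fetch(interval) if track is not None
              else np.zeros(len(interval), dtype=np.int64))
    if interval.strand == "-":
        seq = reverse_complement(seq)
        counts = counts[::-1].copy()
    return one_hot_encode(seq), counts


def read_annotations(path, fmt: str = "auto") -> list[GenomicInterval]:
    """Read gene intervals from BED6 or GTF.

    GTF 1-based inclusive coordinates are converted to 0-based half-open and
    only ``gene`` records are retained.  Records without a usable strand are
    skipped with a warning.
    """
    path = str(path)
    if fmt == "auto":
        fmt = "gtf" if path.endswith((".gtf", ".gff", ".gtf.gz")) else "bed"
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            fields = line.split("\t")
            if fmt == "bed":
                if len(fields) < 6:
                    raise ValueError(f"{path}:{ln}: BED6 requires 6 columns")
                chrom, start, end, name, _score, strand = fields[:6]
                start, end = int(start), int(end)
            else:  # gtf
                if len(fields) < 8:
                    raise ValueError(f"{path}:{ln}: malformed GTF line")
                chrom, _src, feature, start, end, _score, strand = fields[:7]
                if feature != "gene":
                    continue
                start, end = int(start) - 1, int(end)
                name = _gtf_attr(fields[8] if len(fields) > 8 else "", "gene_id")
            if strand not in ("+", "-"):
                logger.warning("%s:%d: strand %r, record skipped", path, ln, strand)
                continue
            intervals.append(GenomicInterval(chrom, start, end, strand, name))
    return intervals


def _gtf_attr(attributes: str, key: str) -> str:
    for part in attributes.split(";"):
        part = part.strip()
        if part.startswith(key):
            return part.split(maxsplit=1)[1].strip('"')
    return "."


def write_bed(intervals, path, extra_columns=None) -> None:
    """Write intervals as BED6 (+ optional extra columns, one list per row)."""
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            row = [iv.chrom, str(iv.start), str(iv.end), iv.name, "0", iv.strand]
            if extra_columns is not None:
                row.extend(str(x) for x in extra_columns[i])
            fh.write("\t".join(row) + "\n")
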