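"""High-attribution k-mer extraction, consensus motifs, and motif comparison.

The discovery route: for each selected window, the k-mer (k=5 by default)
with the highest summed attribution (IG_sum) is extracted from its
attribution map; k-mers are ranked by aggregate relevance (the sum of IG_sum
over occurrences); ranked k-mers are then greedily aligned without gaps into
consensus position-frequency matrices, each k-mer joining the first earlier
alignment where it matches the running majority consensus in at least 3
overlapping columns, or seeding a new alignment otherwise.

Comparison routes: similarity of a k-mer to a reference PWM is
1 - mean position-wise base-2 Jensen-Shannon divergence, maximised over all
sliding offsets with >= 3 overlapping columns and over all reference PWMs;
in-vitro k-mer tables (RBNS R-scores, RNAcompete 7-mer z-scores) are
standardised, 7-mer tables converted to 5-mer scores by occurrence-weighted
averaging, and compared to the model ranking by top-k recall.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import jensenshannon

from .attribution import AttributionMap
from .genomic_io import one_hot_encode

__all__ = [
    "KmerScore", "KmerRanking", "MotifMatrix", "ConsensusMotif",
    "extract_top_kmer", "aggregate_relevance", "build_consensus",
    "kmer_pwm_similarity", "convert_7mer_to_5mer", "rscores_to_z",
    "top_k_recall", "read_motifs", "write_meme_minimal",
]

_RNA = "ACGU"


@dataclass(frozen=True)
class KmerScore:
    kmer: str
    ig_sum: float
    start: int = -1


@dataclass
class KmerRanking:
    """(k-mer, score) pairs sorted descending; ties broken lexicographically."""

    items: list                      # list[(kmer, score)]
    provenance: str = "attribution"

    def __post_init__(self):
        self.items = sorted(self.items, key=lambda kv: (-kv[1], kv[0]))

    def top(self, k: int) -> list:
        return [kmer for kmer, _ in self.items[:k]]

    def __len__(self):
        return len(self.items)

    def __iter__(self):
        return iter(self.items)


@dataclass
class MotifMatrix:
    """Position-frequency matrix: (length, 4) rows over A/C/G/U summing to 1."""

    probs: np.ndarray
    identifier: str = "motif"
    source: str = "reference"

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("motif matrix must be (length, 4)")
        sums = self.probs.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-3):
            raise ValueError("each motif position must sum to 1")
        self.probs = self.probs / sums[:, None]

    def __len__(self):
        return self.probs.shape[0]

    def consensus_string(self) -> str:
        return "".join(_RNA[i] for i in self.probs.argmax(axis=1))


@dataclass
class ConsensusMotif:
    matrix: MotifMatrix
    support: int                      # number of member k-mers
    support_fraction: float
    members: list = field(default_factory=list)   # list[(kmer, offset)]


# -- k-mer extraction --------------------------------------------------------

def extract_top_kmer(attribution_map: AttributionMap, sequence: str,
                     k: int = 5) -> KmerScore:
    """The k-mer with the highest summed observed-base attribution.

    Ties are broken by the leftmost start; windows containing an unknown base
    (N) are skipped in favour of the next-best window.
    """
    if len(sequence) < k:
        raise ValueError(f"sequence shorter than k={k}")
    if len(sequence) != attribution_map.scores.shape[0]:
        raise ValueError("sequence and attribution map lengths differ")
    pos_scores = attribution_map.per_position(one_hot_encode(sequence))
    window_sums = np.convolve(pos_scores, np.ones(k), mode="valid")
    order = np.argsort(-window_sums, kind="stable")   # stable => leftmost ties
    seq = sequence.upper().replace("T", "U")
    for start in order:
        kmer = seq[start: start + k]
        if "N" in kmer:
            continue
        return KmerScore(kmer, float(window_sums[start]), int(start))
    raise ValueError("no window free of unknown bases")


def aggregate_relevance(kmer_scores) -> KmerRanking:
    """Group per-window k-mer scores and sum IG_sum into a relevance ranking."""
    kmer_scores = list(kmer_scores)
    if not kmer_scores:
        raise ValueError("no k-mer scores to aggregate")
    totals: dict[str, float] = defaultdict(float)
    for ks in kmer_scores:
        totals[ks.kmer] += ks.ig_sum
    return KmerRanking(list(totals.items()), provenance="attribution")


# -- consensus construction --------------------------------------------------

class _Alignment:
    """A growing gapless alignment of k-mers relative to its seed (offset 0)."""

    def __init__(self, seed: str):
        self.members: list[tuple[str, int]] = [(seed, 0)]

    @property
    def span(self) -> tuple[int, int]:
        lo = min(off for _, off in self.members)
        hi = max(off + len(kmer) for kmer, off in self.members)
        return lo, hi

    def _column_bases(self, col: int):
        """Bases covering an absolute column, in member insertion order."""
        for kmer, off in self.members:
            if off <= col < off + len(kmer):
                yield kmer[col - off]

    def majority(self, col: int) -> str | None:
        counts: dict[str, int] = {}
        first_seen: dict[str, int] = {}
        for i, base in enumerate(self._column_bases(col)):
            counts[base] = counts.get(base, 0) + 1
            first_seen.setdefault(base, i)
        if not counts:
            return None
        best = max(counts.values())
        # majority ties resolve to the base that entered the column earliest
        return min((b for b, c in counts.items() if c == best),
                   key=lambda b: first_seen[b])

    def best_offset(self, kmer: str, min_overlap: int = 3):
        """(matches, offset) maximising majority matches; None if no offset
        reaches ``min_overlap`` overlapping columns."""
        lo, hi = self.span
        k = len(kmer)
        best = None
        for off in range(lo - k + min_overlap, hi - min_overlap + 1):
            cols = range(max(off, lo), min(off + k, hi))
            matches = sum(
                1 for c in cols if kmer[c - off] == self.majority(c)
            )
            key = (-matches, abs(off), off)
            if best is None or key < best[0]:
                best = (key, matches, off)
        if best is None:
            return None
        return best[1], best[2]

    def add(self, kmer: str, offset: int) -> None:
        self.members.append((kmer, offset))

    def to_motif(self, total_kmers: int, identifier: str) -> ConsensusMotif:
        lo, hi = self.span
        probs = np.zeros((hi - lo, 4))
        for col in range(lo, hi):
            for base in self._column_bases(col):
                probs[col - lo, _RNA.index(base)] += 1
        probs /= probs.sum(axis=1, keepdims=True)
        matrix = MotifMatrix(probs, identifier=identifier, source="consensus")
        members = [(kmer, off - lo) for kmer, off in self.members]
        return ConsensusMotif(matrix, len(self.members),
                              len(self.members) / total_kmers, members)


def build_consensus(ranking: KmerRanking, min_matches: int = 3
                    ) -> list[ConsensusMotif]:
    """Greedy gapless alignment of ranked k-mers into consensus motifs.

    K-mers are processed from the top of the ranking; each is tried against
    existing alignments in creation order and joins the first one admitting at
    least ``min_matches`` majority matches at its best offset (max matches,
    ties to the smallest absolute then most upstream offset); otherwise it
    seeds a new alignment.  Output motifs are sorted by supporting k-mer
    count.
    """
    kmers = [kmer for kmer, _ in ranking]
    if not kmers:
        return []
    if len({len(k) for k in kmers}) != 1:
        raise ValueError("all k-mers must have the same length")
    alignments: list[_Alignment] = []
    for kmer in kmers:
        placed = False
        for aln in alignments:
            hit = aln.best_offset(kmer, min_overlap=min_matches)
            if hit is not None and hit[0] >= min_matches:
                aln.add(kmer, hit[1])
                placed = True
                break
        if not placed:
            alignments.append(_Alignment(kmer))
    motifs = [
        aln.to_motif(len(kmers), identifier=f"consensus_{i + 1}")
        for i, aln in enumerate(alignments)
    ]
    return sorted(motifs, key=lambda m: -m.support)


# -- PWM similarity ----------------------------------------------------------

def _kmer_matrix(kmer: str) -> np.ndarray:
    out = np.zeros((len(kmer), 4))
    for i, base in enumerate(kmer.upper().replace("T", "U")):
        out[i, _RNA.index(base)] = 1.0
    return out


def kmer_pwm_similarity(kmer: str, references, min_overlap: int = 3) -> float:
    """Max over references and offsets of 1 - mean base-2 JSD per column.

    Returns a value in [0, 1]; 1 means some admissible offset aligns the
    k-mer's one-hot columns perfectly with the reference.  References shorter
    than ``min_overlap`` columns are skipped.
    """
    if isinstance(references, MotifMatrix):
        references = [references]
    km = _kmer_matrix(kmer)
    k = len(kmer)
    best = None
    for ref in references:
        probs = ref.probs
        n = len(ref)
        if n < min_overlap:
            continue
        for off in range(-(k - min_overlap), n - min_overlap + 1):
            cols = range(max(0, off), min(n, off + k))
            if len(cols) < min_overlap:
                continue
            divs = [
                jensenshannon(km[c - off], probs[c], base=2) ** 2 for c in cols
            ]
            sim = 1.0 - float(np.mean(divs))
            if best is None or sim > best:
                best = sim
    if best is None:
        raise ValueError("no reference PWM with at least 3 columns")
    return min(1.0, max(0.0, best))


# -- in vitro k-mer tables ---------------------------------------------------

def convert_7mer_to_5mer(z7: KmerRanking, k: int = 5) -> KmerRanking:
    """Occurrence-weighted mean of 7-mer scores over contained 5-mers.

    A 7-mer containing a 5-mer m times contributes m copies of its score to
    that 5-mer's mean.
    """
    sums: dict[str, float] = defaultdict(float)
    counts: dict[str, int] = defaultdict(int)
    for sevenmer, score in z7:
        if len(sevenmer) <= k:
            raise ValueError("expected k-mers longer than the target length")
        for start in range(len(sevenmer) - k + 1):
            sub = sevenmer[start: start + k]
            sums[sub] += score
            counts[sub] += 1
    items = [(kmer, sums[kmer] / counts[kmer]) for kmer in sums]
    return KmerRanking(items, provenance=z7.provenance)


def rscores_to_z(scores: dict) -> dict:
    """Standardise a k-mer score table: z = (score - mean) / population sd."""
    values = np.asarray(list(scores.values()), dtype=float)
    if len(values) < 2:
        raise ValueError("need at least 2 scores")
    sd = values.std()  # population convention
    if sd == 0:
        raise ValueError("scores are constant; z-scores undefined")
    mean = values.mean()
    return {kmer: (score - mean) / sd for kmer, score in scores.items()}


def top_k_recall(model_ranking: KmerRanking, invitro_ranking: KmerRanking,
                 k: int = 20) -> float:
    """|top-k(model) ∩ top-k(in vitro)| / k."""
    if len(model_ranking) < k or len(invitro_ranking) < k:
        raise ValueError(f"both rankings must cover at least {k} items")
    return len(set(model_ranking.top(k)) & set(invitro_ranking.top(k))) / k


# -- motif file IO -----------------------------------------------------------

def read_motifs(path, fmt: str = "minimal") -> list[MotifMatrix]:
    """Read reference PWMs from MEME minimal or TRANSFAC files (Bio.motifs)."""
    from Bio import motifs as bio_motifs

    with open(path) as fh:
        records = bio_motifs.parse(fh, fmt)
    out = []
    for i, rec in enumerate(records):
        counts = np.array([
            [rec.counts[base][pos] for base in "ACGT"]
            for pos in range(rec.length)
        ], dtype=float)
        sums = counts.sum(axis=1, keepdims=True)
        if np.any(sums == 0):
            raise ValueError(f"motif {i + 1} in {path} has an empty column")
        name = getattr(rec, "name", None) or f"motif_{i + 1}"
        out.append(MotifMatrix(counts / sums, identifier=str(name)))
    return out


def write_meme_minimal(motifs, path, alphabet: str = "ACGU") -> None:
    """Write motifs in MEME minimal format (RNA alphabet by default)."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\n")
        fh.write(f"ALPHABET= {alphabet}\n\n")
        fh.write("strands: +\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{b} 0.25000" for b in alphabet) + "\n\n")
        for m in motifs:
            matrix = m.matrix if isinstance(m, ConsensusMotif) else m
            fh.write(f"MOTIF {matrix.identifier}\n")
            # nsites is auxiliary; downstream parsers quantise probabilities
            # to 1/nsites, so bare matrices get a high-resolution default
            # (exact k-mer support is written to the TSV sidecar instead)
            nsites = max(int(getattr(m, "support", 0)), 1000)
            fh.write(
                f"letter-probability matrix: alength= 4 w= {len(matrix)} "
                f"nsites= {nsites} E= 0\n"
            )
            for row in matrix.probs:
                fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")
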