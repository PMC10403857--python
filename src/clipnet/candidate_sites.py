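"""Training-site selection: sliding-window Poisson enrichment filter.

A 100-nt window slides over each gene at stride 1.  A window becomes a
candidate when (i) its count total is significantly enriched under a Poisson
null whose rate is the gene-level count density, (ii) the total reaches a
minimum count N, and (iii) the maximum position-wise count (the "height")
reaches H.  On acceptance the scan jumps 50 nt forward, which prevents
clusters of near-duplicate candidates.  Accepted 100-nt cores are finally
extended symmetrically to 300 nt for training.

Chromosome-wise data split: chr2/9/16 validation, chr1/8/15 hold-out test,
all other autosomes train; non-autosomes are excluded.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
from scipy.stats import poisson

from .genomic_io import GenomicInterval

logger = logging.getLogger(__name__)

VALIDATION_CHROMS = frozenset({"chr2", "chr9", "chr16"})
TEST_CHROMS = frozenset({"chr1", "chr8", "chr15"})


@dataclass(frozen=True)
class SiteSelectionParams:
    """Filter thresholds; defaults are eCLIP mode, ``iclip()`` lowers N to 4."""

    window_len: int = 100
    scan_stride: int = 1
    accept_jump: int = 50
    p_threshold: float = 0.01
    min_count: int = 8
    min_height: int = 2
    final_len: int = 300

    def __post_init__(self):
        if self.final_len < self.window_len:
            raise ValueError("final_len must be >= window_len")
        if not 0.0 < self.p_threshold < 1.0:
            raise ValueError("p_threshold must be in (0, 1)")
        if self.min_count < 0 or self.min_height < 0:
            raise ValueError("count thresholds must be non-negative")

    @classmethod
    def iclip(cls, **overrides) -> "SiteSelectionParams":
        overrides.setdefault("min_count", 4)
        return cls(**overrides)


@dataclass(frozen=True)
class CandidateSite:
    interval: GenomicInterval
    gene_id: str
    p_value: float
    window_count: int
    window_height: int
    core_start: int  # gene-local start of the accepted 100-nt core window


def poisson_upper_p(window_count: int, gene_count: int, gene_len: int,
                    window_len: int) -> float:
    """Upper-tail Poisson probability P(X >= window_count).

    The null rate is the gene count mass scaled to the window:
    lambda = gene_count * window_len / gene_len.
    """
    if window_len <= 0 or gene_len < window_len:
        raise ValueError("require gene_len >= window_len > 0")
    if window_count < 0 or gene_count < 0:
        raise ValueError("counts must be non-negative")
    if window_count == 0:
        return 1.0
    lam = gene_count * window_len / gene_len
    if lam == 0.0:
        return 0.0
    return float(poisson.sf(window_count - 1, lam))


def select_candidate_sites(gene: GenomicInterval, counts: np.ndarray,
                           params: SiteSelectionParams = SiteSelectionParams(),
                           ) -> list[CandidateSite]:
    """Scan one gene and return accepted sites in genomic scan order.

    ``counts`` must cover the gene 5'→3' (index 0 = gene 5' end).  Genes
    shorter than ``final_len`` yield no sites (fixed-length training tensors).
    """
    counts = np.asarray(counts)
    if len(counts) != len(gene):
        raise ValueError("counts length must equal gene length")
    L, W = len(counts), params.window_len
    if L < W or L < params.final_len:
        return []
    gene_count = int(counts.sum())
    if gene_count == 0:
        return []

    # stride-1 window sums and heights, vectorised once per gene
    csum = np.concatenate([[0], np.cumsum(counts)])
    win_sums = csum[W:] - csum[:-W]
    win_heights = _sliding_max(counts, W)
    lam = gene_count * W / L
    pvals = poisson.sf(win_sums - 1, lam)

    accepted: list[tuple[int, float, int, int]] = []
    pos = 0
    last = L - W
    while pos <= last:
        if (
            pvals[pos] < params.p_threshold
            and win_sums[pos] >= params.min_count
            and win_heights[pos] >= params.min_height
        ):
            accepted.append((pos, float(pvals[pos]), int(win_sums[pos]),
                             int(win_heights[pos])))
            pos += params.accept_jump
        else:
            pos += params.scan_stride

    sites = []
    pad = params.final_len - W
    for core, p, total, height in accepted:
        start = core - pad // 2
        # shift inward so the 300-nt window stays within the gene
        start = min(max(start, 0), L - params.final_len)
        # map gene-local 5'→3' coordinates back to genomic coordinates
        if gene.strand == "+":
            gstart = gene.start + start
        else:
            gstart = gene.end - start - params.final_len
        interval = GenomicInterval(
            gene.chrom, gstart, gstart + params.final_len, gene.strand, gene.name
        )
        sites.append(CandidateSite(interval, gene.name, p, total, height, core))
    return sites


def _sliding_max(values: np.ndarray, width: int) -> np.ndarray:
    from numpy.lib.stride_tricks import sliding_window_view

    return sliding_window_view(values, width).max(axis=1)


def assign_split(site_or_chrom) -> str | None:
    """Partition by chromosome: validation / test / train; None = excluded."""
    chrom = getattr(site_or_chrom, "interval", None)
    if chrom is not None:
        chrom = chrom.chrom
    elif isinstance(site_or_chrom, GenomicInterval):
        chrom = site_or_chrom.chrom
    else:
        chrom = str(site_or_chrom)
    name = chrom.lower()
    if not name.startswith("chr"):
        name = "chr" + name
    if not re.fullmatch(r"chr\d+", name):
        logger.warning("non-autosome %r excluded from split", chrom)
        return None
    if name in VALIDATION_CHROMS:
        return "validation"
    if name in TEST_CHROMS:
        return "test"
    return "train"


def dedupe_sites(sites: list[CandidateSite]) -> list[CandidateSite]:
    """Drop duplicate (interval, strand) sites from overlapping genes."""
    seen = set()
    out = []
    for s in sites:
        key = (s.interval.chrom, s.interval.start, s.interval.end, s.interval.strand)
        if key not in seen:
            seen.add(key)
            out.append(s)
    return out
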