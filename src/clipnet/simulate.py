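"""Synthetic CLIP data with known ground truth.

The generator emulates exactly the statistical structure the profile model
assumes: each window carries a latent protein-specific ("target") count
distribution anchored at planted binding-motif instances, a background
("control") distribution anchored at planted U-rich bias motifs plus a
uniform floor, and observed signal counts drawn multinomially from the
additive mixture ``pi * p_target + (1 - pi) * p_control``.  A paired control
library is drawn from ``p_control`` alone with its own sequencing depth.

The per-window mixing coefficient pi is tied to the number of planted motif
copies (more copies → higher signal fraction), since a sequence-only model
can recover pi only if the sequence carries it — mirroring the real-data
situation where the signal fraction tracks motif strength.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genomic_io import one_hot_encode

__all__ = ["SyntheticConfig", "SyntheticDataset", "simulate_windows",
           "simulate_gene_track"]

_RNA = "ACGU"


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; defaults are the package's standard study conditions.

    ``pi_levels`` / ``copies_per_level`` couple the mixing coefficient to the
    number of planted target-motif copies.  Total counts per window are
    negative-binomially distributed (mean 50, dispersion 5) so sequencing
    depth varies across windows, as in real libraries.
    """

    n_windows: int = 2000
    window_len: int = 300
    target_motif: str = "ACUAAC"
    bias_motif: str = "UUUUU"
    pi_levels: tuple = (0.2, 0.5, 0.8)
    copies_per_level: tuple = (1, 2, 3)
    n_bias_sites: int = 3
    count_mean: float = 50.0
    count_dispersion: float = 5.0
    control_count_mean: float = 50.0
    peak_offset: int = -3      # profile bump centre relative to motif start
    peak_width: float = 2.0    # bump standard deviation, nt
    control_floor: float = 0.5  # uniform fraction of the control distribution
    edge_margin: int = 15
    seed: int | None = None

    def __post_init__(self):
        if not all(0.0 <= p <= 1.0 for p in self.pi_levels):
            raise ValueError("pi levels must lie in [0, 1]")
        if len(self.pi_levels) != len(self.copies_per_level):
            raise ValueError("pi_levels and copies_per_level must align")
        if len(self.target_motif) > self.window_len:
            raise ValueError("motif longer than window")


@dataclass
class SyntheticDataset:
    """Simulated windows plus full ground truth."""

    config: SyntheticConfig
    sequences_str: list
    sequences: np.ndarray        # (n, L, 4) one-hot
    p_target: np.ndarray         # (n, L) true target distribution
    p_control: np.ndarray        # (n, L) true control distribution
    pi: np.ndarray               # (n,) true mixing coefficients
    signal_counts: np.ndarray    # (n, L) observed CLIP counts
    control_counts: np.ndarray   # (n, L) observed control-library counts
    motif_positions: list = field(default_factory=list)  # per window, starts
    bias_positions: list = field(default_factory=list)

    def __len__(self):
        return len(self.sequences_str)

    @property
    def p_mixture(self) -> np.ndarray:
        return self.pi[:, None] * self.p_target + (1 - self.pi[:, None]) * self.p_control

    def stacked_counts(self) -> np.ndarray:
        """Counts as (n, L, 2): signal in channel 0, control in channel 1."""
        return np.stack([self.signal_counts, self.control_counts], axis=-1)

    def in_motif_mask(self) -> np.ndarray:
        """Boolean (n, L): positions covered by a planted target motif."""
        mask = np.zeros(self.signal_counts.shape, dtype=bool)
        k = len(self.config.target_motif)
        for i, starts in enumerate(self.motif_positions):
            for s in starts:
                mask[i, s: s + k] = True
        return mask

    def subset(self, idx) -> "SyntheticDataset":
        idx = np.asarray(idx)
        return SyntheticDataset(
            config=self.config,
            sequences_str=[self.sequences_str[i] for i in idx],
            sequences=self.sequences[idx],
            p_target=self.p_target[idx], p_control=self.p_control[idx],
            pi=self.pi[idx], signal_counts=self.signal_counts[idx],
            control_counts=self.control_counts[idx],
            motif_positions=[self.motif_positions[i] for i in idx],
            bias_positions=[self.bias_positions[i] for i in idx],
        )


def _bump(length: int, centre: float, width: float) -> np.ndarray:
    x = np.arange(length)
    return np.exp(-0.5 * ((x - centre) / width) ** 2)


def _draw_total(rng, mean: float, dispersion: float) -> int:
    """Negative binomial with the given mean and dispersion (size) parameter."""
    p = dispersion / (dispersion + mean)
    return int(rng.negative_binomial(dispersion, p))


def simulate_windows(config: SyntheticConfig = SyntheticConfig()) -> SyntheticDataset:
    """Generate windows; fully reproducible given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    L = config.window_len
    k_t, k_b = len(config.target_motif), len(config.bias_motif)
    n = config.n_windows

    seq_strs, p_ts, p_cs, pis = [], [], [], []
    sig_counts = np.zeros((n, L), dtype=np.int64)
    ctl_counts = np.zeros((n, L), dtype=np.int64)
    motif_pos, bias_pos = [], []

    for i in range(n):
        level = int(rng.integers(len(config.pi_levels)))
        pi = float(config.pi_levels[level])
        n_copies = int(config.copies_per_level[level])

        seq = rng.integers(0, 4, size=L)
        occupied = np.zeros(L, dtype=bool)
        starts_t = _plant(rng, seq, occupied, config.target_motif, n_copies,
                          config.edge_margin, L)
        starts_b = _plant(rng, seq, occupied, config.bias_motif,
                          config.n_bias_sites, config.edge_margin, L)

        p_target = np.full(L, 1e-4)
        for s in starts_t:
            p_target += _bump(L, s + config.peak_offset, config.peak_width)
        p_target /= p_target.sum()

        p_control = np.full(L, config.control_floor / L)
        bump_mass = 1.0 - config.control_floor
        if starts_b:
            bumps = np.zeros(L)
            for s in starts_b:
                bumps += _bump(L, s + k_b / 2.0, config.peak_width)
            p_control += bump_mass * bumps / bumps.sum()
        else:
            p_control += bump_mass / L
        p_control /= p_control.sum()

        mix = pi * p_target + (1 - pi) * p_control
        n_sig = _draw_total(rng, config.count_mean, config.count_dispersion)
        n_ctl = _draw_total(rng, config.control_count_mean, config.count_dispersion)
        if n_sig:
            sig_counts[i] = rng.multinomial(n_sig, mix)
        if n_ctl:
            ctl_counts[i] = rng.multinomial(n_ctl, p_control)

        seq_strs.append("".join(_RNA[b] for b in seq))
        p_ts.append(p_target)
        p_cs.append(p_control)
        pis.append(pi)
        motif_pos.append(starts_t)
        bias_pos.append(starts_b)

    return SyntheticDataset(
        config=config,
        sequences_str=seq_strs,
        sequences=np.stack([one_hot_encode(s) for s in seq_strs]),
        p_target=np.asarray(p_ts), p_control=np.asarray(p_cs),
        pi=np.asarray(pis), signal_counts=sig_counts, control_counts=ctl_counts,
        motif_positions=motif_pos, bias_positions=bias_pos,
    )


def _plant(rng, seq: np.ndarray, occupied: np.ndarray, motif: str,
           n_copies: int, margin: int, L: int) -> list:
    """Write ``n_copies`` of ``motif`` at random non-overlapping positions."""
    k = len(motif)
    if k > L:
        raise ValueError("motif longer than window")
    encoded = [_RNA.index(b) for b in motif.upper().replace("T", "U")]
    starts = []
    for _ in range(n_copies):
        for _attempt in range(200):
            s = int(rng.integers(margin, L - k - margin + 1))
            if not occupied[s: s + k].any():
                break
        else:
            continue  # window too crowded; plant fewer copies
        seq[s: s + k] = encoded
        occupied[max(0, s - k): s + 2 * k] = True  # keep copies separated
        starts.append(s)
    return sorted(starts)


def simulate_gene_track(gene_length: int, site_positions, heights,
                        background_rate: float = 0.0,
                        seed: int | None = None):
    """Poisson background plus count spikes at given positions.

    Returns ``(counts, truth)`` where ``truth`` lists the 100-nt window starts
    that the sliding-window enrichment filter should accept at its default
    thresholds, computed by direct enumeration (window sums and heights by
    direct summation, Poisson upper tail by pmf summation, then greedy
    earliest-first suppression of starts within the 50-nt accept jump).
    """
    rng = np.random.default_rng(seed)
    counts = rng.poisson(background_rate, size=gene_length).astype(np.int64)
    for pos, h in zip(site_positions, heights):
        if not 0 <= pos < gene_length:
            raise ValueError(f"site position {pos} outside gene")
        counts[pos] += int(h)
    truth = brute_force_window_starts(counts)
    return counts, truth


def brute_force_window_starts(counts: np.ndarray, window_len: int = 100,
                              accept_jump: int = 50, p_threshold: float = 0.01,
                              min_count: int = 8, min_height: int = 2) -> list:
    """Reference enumeration of accepted window starts (independent oracle).

    Every stride-1 window is tested directly; the Poisson upper tail is a pmf
    summation, not a survival-function call.  Accepted starts closer than
    ``accept_jump`` downstream of a previous acceptance are suppressed, which
    is equivalent to the production scanner's jump rule at stride 1.
    """
    counts = np.asarray(counts)
    L = len(counts)
    if L < window_len:
        return []
    gene_count = int(counts.sum())
    lam = gene_count * window_len / L
    passing = []
    for s in range(L - window_len + 1):
        window = counts[s: s + window_len]
        total = int(sum(int(c) for c in window))
        height = max(int(c) for c in window)
        if total < min_count or height < min_height:
            continue
        if _poisson_tail_by_pmf(total, lam) >= p_threshold:
            continue
        passing.append(s)
    accepted, last = [], None
    for s in passing:
        if last is None or s >= last + accept_jump:
            accepted.append(s)
            last = s
    return accepted


def _poisson_tail_by_pmf(k: int, lam: float) -> float:
    """P(X >= k) for X ~ Poisson(lam) via direct pmf summation."""
    if k == 0:
        return 1.0
    if lam == 0.0:
        return 0.0
    # sum P(X < k) term by term: pmf(0) = e^-lam, pmf(j) = pmf(j-1) * lam / j
    term = np.exp(-lam)
    cdf = term
    for j in range(1, k):
        term *= lam / j
        cdf += term
    return max(0.0, 1.0 - cdf)
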