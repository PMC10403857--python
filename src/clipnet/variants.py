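"""Variant impact scoring: divergence between REF and ALT predicted profiles.

A single-nucleotide variant inside a binding-relevant sequence feature shifts
the predicted count distribution; the impact score quantifies that shift as
the KL divergence KLD(p_REF || p_ALT) in nats (REF-first, no
symmetrisation), or alternatively as the L2 norm of the profile difference.
Scores default to the de-biased target track for paired models and the total
track otherwise.  Saturation mutagenesis scores every position of a window
against each of its 3 alternative bases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import rel_entr

from .genomic_io import (GenomicInterval, SequenceSource, one_hot_encode,
                         reverse_complement)
from .model import ProfileNet

__all__ = ["VariantRecord", "VariantImpact", "read_vcf", "apply_variant",
           "impact_kld", "impact_l2", "saturation_mutagenesis",
           "score_variants"]

_BASES = "ACGU"


@dataclass(frozen=True)
class VariantRecord:
    """Single-nucleotide variant in VCF convention (1-based position)."""

    chrom: str
    pos: int                  # 1-based
    ref: str
    alt: str
    id: str = "."

    def __post_init__(self):
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise ValueError("only single-base substitutions are supported")
        if self.ref.upper() == self.alt.upper():
            raise ValueError("ref and alt alleles must differ")

    @property
    def pos0(self) -> int:
        return self.pos - 1


@dataclass(frozen=True)
class VariantImpact:
    variant: VariantRecord
    score_kld: float
    score_l2: float
    track: str
    window: GenomicInterval


def read_vcf(path) -> list[VariantRecord]:
    """Read single-nucleotide variants from a VCF (multi-allelic split)."""
    from cyvcf2 import VCF

    records = []
    for v in VCF(str(path)):
        for alt in v.ALT:
            if len(v.REF) == 1 and len(alt) == 1:
                records.append(VariantRecord(
                    v.CHROM, v.POS, v.REF, alt, v.ID or "."
                ))
    return records


def _default_track(model: ProfileNet) -> str:
    return "target" if model.paired else "total"


def apply_variant(sequence_source: SequenceSource, variant: VariantRecord,
                  window: GenomicInterval) -> tuple[str, str]:
    """(REF sequence, ALT sequence) for a window, in transcript orientation.

    The fetched genomic base must equal the declared REF allele (T/U treated
    as equivalent); minus-strand windows are reverse-complemented, so the
    substituted base appears as the complement at the mapped position.
    """
    if not window.start <= variant.pos0 < window.end:
        raise ValueError(
            f"variant position {variant.pos} outside window "
            f"{window.chrom}:{window.start}-{window.end}"
        )
    seq = sequence_source.fetch(window.chrom, window.start, window.end)
    offset = variant.pos0 - window.start
    found = seq[offset].upper().replace("U", "T")
    declared = variant.ref.upper().replace("U", "T")
    if found != declared:
        raise ValueError(
            f"reference mismatch at {variant.chrom}:{variant.pos}: "
            f"genome has {found!r}, variant declares {declared!r}"
        )
    alt_seq = seq[:offset] + variant.alt.upper() + seq[offset + 1:]
    if window.strand == "-":
        seq = reverse_complement(seq)
        alt_seq = reverse_complement(alt_seq)
    return seq, alt_seq


def _profile(model: ProfileNet, sequence, track: str) -> np.ndarray:
    return model.predict_profile(sequence).track(track)


def impact_kld(model: ProfileNet, ref_seq, alt_seq,
               track: str | None = None) -> float:
    """KLD(p_REF || p_ALT) in nats; finite because profiles are positive."""
    track = track or _default_track(model)
    p_ref, p_alt = _pair_profiles(model, ref_seq, alt_seq, track)
    return float(rel_entr(p_ref, p_alt).sum())


def impact_l2(model: ProfileNet, ref_seq, alt_seq,
              track: str | None = None) -> float:
    """Euclidean norm of the REF-ALT profile difference."""
    track = track or _default_track(model)
    p_ref, p_alt = _pair_profiles(model, ref_seq, alt_seq, track)
    return float(np.linalg.norm(p_ref - p_alt))


def _pair_profiles(model, ref_seq, alt_seq, track):
    ref_oh = ref_seq if not isinstance(ref_seq, str) else one_hot_encode(ref_seq)
    alt_oh = alt_seq if not isinstance(alt_seq, str) else one_hot_encode(alt_seq)
    ref_oh, alt_oh = np.asarray(ref_oh), np.asarray(alt_oh)
    if ref_oh.shape != alt_oh.shape:
        raise ValueError("REF and ALT sequences must have equal length")
    preds = model.predict_profiles(np.stack([ref_oh, alt_oh]))
    return preds[0].track(track), preds[1].track(track)


def saturation_mutagenesis(model: ProfileNet, sequence,
                           track: str | None = None) -> pd.DataFrame:
    """Score all 3L single-base substitutions of a window.

    Returns a table with columns position (0-based), ref_base, alt_base and
    score_kld; substitutions to the reference base itself are not emitted.
    """
    track = track or _default_track(model)
    one_hot = (one_hot_encode(sequence) if isinstance(sequence, str)
               else np.asarray(sequence, dtype=np.float32))
    L = one_hot.shape[0]
    p_ref = model.predict_profiles(one_hot[None])[0].track(track)

    alt_batch = []
    rows = []
    for pos in range(L):
        ref_idx = int(one_hot[pos].argmax()) if one_hot[pos].sum() else None
        for alt_idx in range(4):
            if alt_idx == ref_idx:
                continue
            if ref_idx is None and alt_idx > 2:
                break  # unknown base: still 3 alternatives (A, C, G)
            mutated = one_hot.copy()
            mutated[pos] = 0.0
            mutated[pos, alt_idx] = 1.0
            alt_batch.append(mutated)
            rows.append((pos, _BASES[ref_idx] if ref_idx is not None else "N",
                         _BASES[alt_idx]))
    preds = model.predict_profiles(np.stack(alt_batch))
    scores = [float(rel_entr(p_ref, pred.track(track)).sum()) for pred in preds]
    return pd.DataFrame(
        {"position": [r[0] for r in rows],
         "ref_base": [r[1] for r in rows],
         "alt_base": [r[2] for r in rows],
         "score_kld": scores}
    )


def score_variants(model: ProfileNet, sequence_source: SequenceSource,
                   variants, window_len: int = 300,
                   strand_by_chrom: dict | None = None,
                   track: str | None = None) -> list[VariantImpact]:
    """Score variants on model-native windows centred on each variant.

    ``strand_by_chrom`` assigns a strand context per chromosome (default all
    plus strand).  Divergence is computed over the whole predicted window.
    """
    track = track or _default_track(model)
    impacts = []
    for v in variants:
        strand = (strand_by_chrom or {}).get(v.chrom, "+")
        half = window_len // 2
        chrom_len = sequence_source.chrom_length(v.chrom)
        start = min(max(v.pos0 - half, 0), max(chrom_len - window_len, 0))
        window = GenomicInterval(v.chrom, start, start + window_len, strand)
        ref_seq, alt_seq = apply_variant(sequence_source, v, window)
        impacts.append(VariantImpact(
            variant=v,
            score_kld=impact_kld(model, ref_seq, alt_seq, track),
            score_l2=impact_l2(model, ref_seq, alt_seq, track),
            track=track,
            window=window,
        ))
    return impacts
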