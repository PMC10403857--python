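"""Variable-length prediction and expected-count disentanglement.

Because the network is purely convolutional with global position-wise
normalisation, a trained model predicts a probability vector over any input
length in a single forward pass — including whole transcripts.  Predicted
position-wise probabilities are comparable only *within* one transcript
(they sum to 1 per input), never across transcripts; no function here ever
concatenates scores across inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genomic_io import GenomicInterval, SequenceSource, fetch_window
from .model import ProfileNet, ProfilePrediction

__all__ = ["ExpectedCounts", "predict_profile", "expected_counts",
           "predict_transcript"]


@dataclass
class ExpectedCounts:
    """Observed total N split into expected target and control counts."""

    e_target: np.ndarray
    e_control: np.ndarray
    n_total: float

    def __post_init__(self):
        total = float(self.e_target.sum() + self.e_control.sum())
        if not np.isclose(total, self.n_total, atol=1e-6 * max(1.0, self.n_total)):
            raise ValueError(
                f"expected counts sum to {total}, not N={self.n_total}"
            )


def predict_profile(model: ProfileNet, sequence) -> ProfilePrediction:
    """Deterministic single-window prediction (dropout off, BN running stats)."""
    return model.predict_profile(sequence)


def expected_counts(pred: ProfilePrediction, n_total: float) -> ExpectedCounts:
    """Disentangle an observed count total into target and control components:

    E_target = pi * p_target * N and E_control = (1 - pi) * p_control * N,
    so that the two components always sum back to N.
    """
    if n_total < 0:
        raise ValueError("total count must be non-negative")
    if pred.pi is None:
        raise ValueError("expected-count disentanglement requires a paired model")
    e_t = pred.pi * pred.p_target * n_total
    e_c = (1.0 - pred.pi) * pred.p_control * n_total
    return ExpectedCounts(e_t, e_c, float(n_total))


def predict_transcript(model: ProfileNet, gene: GenomicInterval,
                       sequence_source: SequenceSource) -> ProfilePrediction:
    """Whole-transcript prediction in one forward pass.

    Minus-strand genes are processed on the reverse complement; the returned
    vectors are in transcript (5'→3') orientation, i.e. index ``i`` maps to
    genomic position ``gene.start + i`` on plus-strand genes and
    ``gene.end - 1 - i`` on minus-strand genes.

    Lengths above ``model.length_cap`` are rejected rather than tiled: the
    network normalises over the whole input, and stitching tiles would change
    the normalisation semantics.
    """
    if len(gene) > model.length_cap:
        raise ValueError(
            f"gene length {len(gene)} exceeds length_cap ({model.length_cap}); "
            "split the request or raise length_cap explicitly"
        )
    one_hot, _ = fetch_window(sequence_source, None, gene)
    return model.predict_profiles(one_hot[None])[0]
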