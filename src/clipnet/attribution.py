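"""Profile-level Integrated Gradients.

Classic IG explains a scalar output.  A profile model emits a probability
vector, so the scalar functional used here is the self-weighted profile sum

    F(x) = sum_i p_i * stop_grad(p_i),

numerically ``sum_i p_i**2`` with the second factor held constant during
differentiation: high-probability positions dominate the attribution without
requiring observed counts.  The count-weighted alternative
``F(x) = sum_i p_i c_i`` (which needs true counts and can up-weight bias
positions) is available behind the ``counts`` argument for completeness.

IG integrates the gradient of F along the straight path from a baseline x'
(all-zero one-hot by default — the "absent" sequence) to the input x, and
multiplies by (x - x').  The path integral is approximated with a midpoint
Riemann sum; the completeness residual |sum IG - (F(x) - F(x'))| shrinks as
the number of steps grows and is recorded on every map.

For a paired model the three track functionals are additive under the
mixture weighting: F_total = F_target + F_control with
F_target = pi * sum_i p_target_i * w_i and
F_control = (1 - pi) * sum_i p_control_i * w_i, where w_i are the
stop-gradient total-profile weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor
from .genomic_io import one_hot_encode
from .model import ProfileNet, ProfilePrediction

__all__ = ["IGConfig", "AttributionMap", "profile_functional",
           "integrated_gradients", "track_decomposition"]

_TRACKS = ("total", "target", "control")


@dataclass(frozen=True)
class IGConfig:
    steps: int = 50
    baseline: str = "zeros"        # "zeros" | "uniform"
    track: str = "target"

    def __post_init__(self):
        if self.steps < 8:
            raise ValueError("need at least 8 integration steps")
        if self.baseline not in ("zeros", "uniform"):
            raise ValueError(f"unknown baseline policy {self.baseline!r}")
        if self.track not in _TRACKS:
            raise ValueError(f"track must be one of {_TRACKS}")


@dataclass
class AttributionMap:
    """Per-(position, base) importance scores for one output track."""

    scores: np.ndarray          # (L, 4)
    track: str
    f_input: float              # F(x)
    f_baseline: float           # F(x')

    @property
    def completeness_residual(self) -> float:
        return abs(float(self.scores.sum()) - (self.f_input - self.f_baseline))

    def per_position(self, one_hot: np.ndarray) -> np.ndarray:
        """Display score per position: the score at the observed base."""
        return (self.scores * np.asarray(one_hot)).sum(axis=1)


def profile_functional(pred: ProfilePrediction, track: str = "target") -> float:
    """F = sum_i p_i * const(p_i) for the chosen track; lies in (0, 1]."""
    p = pred.track(track)
    return float((p * p).sum())


def _as_one_hot(sequence) -> np.ndarray:
    if isinstance(sequence, str):
        return one_hot_encode(sequence)
    return np.asarray(sequence, dtype=np.float32)


def _baseline_for(x: np.ndarray, policy: str) -> np.ndarray:
    if policy == "zeros":
        return np.zeros_like(x)
    return np.full_like(x, 0.25)


def _track_probability(model: ProfileNet, x: Tensor, track: str) -> Tensor:
    out = model.network_.forward(x, training=False)
    if track == "total":
        return out["logp_total"].exp()
    if not model.paired:
        raise ValueError("target/control tracks require a paired model")
    key = "logp_target" if track == "target" else "logp_control"
    return out[key].exp()


def _functional_value(model: ProfileNet, x: np.ndarray, track: str,
                      counts: np.ndarray | None) -> float:
    p = _track_probability(model, Tensor(x[None]), track).data[0]
    w = p if counts is None else np.asarray(counts, dtype=float)
    return float((p * w).sum())


def integrated_gradients(model: ProfileNet, sequence,
                         config: IGConfig = IGConfig(),
                         counts: np.ndarray | None = None,
                         _chunk: int = 32) -> AttributionMap:
    """IG attribution map of one window for the configured output track.

    ``counts`` switches the functional to the count-weighted form; when None
    (default) the stop-gradient self-weighting is used.  Interpolation points
    are processed in chunks along the batch axis; midpoint rule.
    """
    # the path graph runs in float64 so the quadrature error, not float32
    # round-off, limits the completeness residual
    x = _as_one_hot(sequence).astype(np.float64)
    baseline = _baseline_for(x, config.baseline)
    delta = x - baseline
    alphas = (np.arange(config.steps) + 0.5) / config.steps

    # the stop-gradient weights are constants of the observed input: with
    # w = p(x) frozen along the whole path, F(z) = sum_i p_i(z) * w_i is a
    # genuine scalar functional, its gradient field is conservative, and the
    # completeness identity sum(IG) -> F(x) - F(x') holds as steps grow
    if counts is None:
        weights = _track_probability(model, Tensor(x[None]),
                                     config.track).data[0]
    else:
        weights = np.asarray(counts, dtype=np.float64)

    grad_sum = np.zeros_like(x, dtype=np.float64)
    for lo in range(0, config.steps, _chunk):
        chunk_alphas = alphas[lo: lo + _chunk]
        points = baseline[None] + chunk_alphas[:, None, None] * delta[None]
        xt = Tensor(points, requires_grad=True)
        p = _track_probability(model, xt, config.track)
        f = (p * Tensor(weights[None])).sum()  # rows independent: one backward
        f.backward()
        if xt.grad is None or not np.all(np.isfinite(xt.grad)):
            raise RuntimeError("non-finite gradients during integrated gradients")
        grad_sum += xt.grad.sum(axis=0)

    scores = delta * (grad_sum / config.steps)
    return AttributionMap(
        scores=scores.astype(np.float64),
        track=config.track,
        f_input=_functional_value(model, x, config.track, weights),
        f_baseline=_functional_value(model, baseline, config.track, weights),
    )


@dataclass(frozen=True)
class TrackFunctionals:
    f_total: float
    f_target: float
    f_control: float

    @property
    def additivity_residual(self) -> float:
        return abs(self.f_total - (self.f_target + self.f_control))


def track_decomposition(model: ProfileNet, sequence) -> TrackFunctionals:
    """Disentangled functionals of the three tracks under shared weighting.

    With weights w = stop_grad(p_total), F_total = sum p_total * w splits
    exactly into the pi-weighted target term and the (1-pi)-weighted control
    term, because p_total is the additive mixture of the two tracks.
    """
    if not model.paired:
        raise ValueError("track decomposition requires a paired model")
    pred = model.predict_profile(_as_one_hot(sequence))
    w = pred.p_total
    f_total = float((pred.p_total * w).sum())
    f_target = float(pred.pi * (pred.p_target * w).sum())
    f_control = float((1.0 - pred.pi) * (pred.p_control * w).sum())
    return TrackFunctionals(f_total, f_target, f_control)
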