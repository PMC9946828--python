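"""The multicomponent hallucination loss.

Two terms are combined.  Structurally conserved residue pairs are
scored by the *restraint* term: the cross-entropy of the predicted
geometry distributions against the family profile (cross-entropy and
KL against a fixed profile differ by the profile's constant entropy,
so they share minimizer and move deltas).  Pairs touching variable
regions are scored by the *confidence* term: the negative mean KL
divergence of the prediction from the background, so minimizing the
total pushes variable-region predictions to be sharp and unlike the
background.  Both terms are means over their pair sets and channels,
which keeps insertion/deletion moves from changing the loss scale
merely by changing pair counts.  All values are in nats.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .family import FamilyProfile, SequenceMapping
from .geometry import BASE_OF, PAIR_CHANNELS
from .predictor import BackgroundGeometry, PredictedGeometry

__all__ = [
    "LossConfig",
    "LossReport",
    "kl_divergence",
    "restraint_loss",
    "confidence_loss",
    "total_loss",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LossConfig:
    """Weights and numerical floors for the combined loss."""

    w_restraint: float = 1.0
    w_confidence: float = 1.0
    channel_weights: dict = field(
        default_factory=lambda: {"d": 1.0, "omega": 1.0, "theta": 1.0, "phi": 1.0}
    )
    kl_floor: float = 1e-8

    def __post_init__(self):
        if not (np.isfinite(self.w_restraint) and self.w_restraint >= 0):
            raise ValueError("w_restraint must be finite and >= 0")
        if not (np.isfinite(self.w_confidence) and self.w_confidence >= 0):
            raise ValueError("w_confidence must be finite and >= 0")
        if not self.kl_floor > 0:
            raise ValueError("kl_floor must be > 0")

    def directional_weights(self) -> np.ndarray:
        """Weights for the six directional channels, in PAIR_CHANNELS order."""
        return np.array(
            [self.channel_weights.get(BASE_OF[ch], 1.0) for ch in PAIR_CHANNELS]
        )


@dataclass
class LossReport:
    """Components and weighted total of one loss evaluation."""

    restraint: float
    confidence: float
    total: float
    n_restraint_pairs: int = 0
    n_confidence_pairs: int = 0
    per_pair_restraint: np.ndarray | None = None
    per_pair_confidence: np.ndarray | None = None


def kl_divergence(p: np.ndarray, q: np.ndarray, floor: float = 1e-8) -> float:
    """KL(p || q) in nats; q is floored at ``floor`` and renormalized.

    Zero entries of p contribute nothing (0·ln 0 = 0); the result is
    non-negative up to the flooring perturbation of q.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {q.shape}")
    q = np.maximum(q, floor)
    q = q / q.sum(axis=-1, keepdims=True)
    ratio = np.where(p > 0, p / q, 1.0)
    return float(np.sum(np.where(p > 0, p * np.log(ratio), 0.0)))


def _kl_rows(p: np.ndarray, q: np.ndarray, floor: float) -> np.ndarray:
    """Row-wise KL(p || q) for (n, K) stacks."""
    q = np.maximum(q, floor)
    q = q / q.sum(axis=-1, keepdims=True)
    ratio = np.where(p > 0, p / q, 1.0)
    return np.sum(np.where(p > 0, p * np.log(ratio), 0.0), axis=-1)


def restraint_loss(pred: PredictedGeometry, profile: FamilyProfile,
                   mapping: SequenceMapping, cfg: LossConfig | None = None,
                   keep_per_pair: bool = False):
    """Channel-weighted mean cross-entropy over conserved pairs.

    For every conserved-column pair of the profile, the prediction at
    the mapped sequence positions is scored by −Σ_bin restraint·ln(pred)
    (prediction floored); lower means more consistent with the family.
    """
    cfg = cfg or LossConfig()
    for a, b in profile.pairs:
        if int(a) not in mapping.conserved or int(b) not in mapping.conserved:
            raise ValueError(f"conserved column pair ({a}, {b}) unmapped")
    ii = np.array([mapping.conserved[int(a)] for a in profile.pairs[:, 0]])
    jj = np.array([mapping.conserved[int(b)] for b in profile.pairs[:, 1]])
    w = cfg.directional_weights()
    per_pair = np.zeros(profile.n_pairs)
    for ch, wc in zip(PAIR_CHANNELS, w):
        rows = pred.dists[ch][ii, jj]  # forward channels oriented a -> b
        ce = -np.sum(
            profile.restraints[ch] * np.log(np.maximum(rows, cfg.kl_floor)),
            axis=-1,
        )
        per_pair += wc * ce
    per_pair /= w.sum()
    value = float(per_pair.mean()) if len(per_pair) else 0.0
    if keep_per_pair:
        return value, per_pair
    return value


def confidence_loss(pred: PredictedGeometry, background: BackgroundGeometry,
                    variable_pairs: np.ndarray, cfg: LossConfig | None = None,
                    keep_per_pair: bool = False):
    """Negative mean KL(prediction || background) over variable pairs.

    More negative = sharper, more confident predictions.  An empty pair
    set yields 0 with a logged notice.
    """
    cfg = cfg or LossConfig()
    variable_pairs = np.asarray(variable_pairs, dtype=int).reshape(-1, 2)
    if len(variable_pairs) == 0:
        logger.info("confidence_loss: empty variable pair set; returning 0")
        return (0.0, np.zeros(0)) if keep_per_pair else 0.0
    ii, jj = variable_pairs[:, 0], variable_pairs[:, 1]
    w = cfg.directional_weights()
    per_pair = np.zeros(len(variable_pairs))
    for ch, wc in zip(PAIR_CHANNELS, w):
        rows = pred.dists[ch][ii, jj]
        bg = background.for_pairs(ch, ii, jj)
        per_pair += wc * _kl_rows(rows, bg, cfg.kl_floor)
    per_pair /= w.sum()
    value = -float(per_pair.mean())
    if keep_per_pair:
        return value, per_pair
    return value


def total_loss(pred: PredictedGeometry, profile: FamilyProfile,
               background: BackgroundGeometry, mapping: SequenceMapping,
               cfg: LossConfig | None = None,
               keep_per_pair: bool = False) -> LossReport:
    """Combine the restraint and confidence terms into a LossReport."""
    cfg = cfg or LossConfig()
    r, r_pp = restraint_loss(pred, profile, mapping, cfg, keep_per_pair=True)
    vpairs = mapping.variable_pairs()
    c, c_pp = confidence_loss(pred, background, vpairs, cfg, keep_per_pair=True)
    total = cfg.w_restraint * r + cfg.w_confidence * c
    return LossReport(
        restraint=r,
        confidence=c,
        total=total,
        n_restraint_pairs=profile.n_pairs,
        n_confidence_pairs=len(vpairs),
        per_pair_restraint=r_pp if keep_per_pair else None,
        per_pair_confidence=c_pp if keep_per_pair else None,
    )
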