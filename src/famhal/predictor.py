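"""Structure-prediction oracle contract, surrogate oracle and background.

The design loop never sees a neural network directly: it talks to a
*predictor*, any object mapping an amino-acid sequence to normalized
categorical distributions over the binned 6D geometry of every residue
pair.  Real networks can be wrapped as adapters and registered by name;
the shipped :class:`SurrogatePredictor` is a fully deterministic
stand-in whose output interpolates between a family template geometry
and an uninformative distribution according to how compatible the query
sequence is with a per-position score table.  The surrogate makes the
whole search machinery testable: a sequence planted at the top of the
score table is, by construction, the most confidently "predicted" one.

The *background* — the reference against which prediction confidence is
measured — is defined operationally as the mean predictor output over
uniformly random sequences, pooled per channel and floored away from
zero so KL terms stay finite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .family import FamilyProfile, build_mapping
from .geometry import GeometryMap, PAIR_CHANNELS, geometry_to_onehot

__all__ = [
    "DEFAULT_ALPHABET",
    "PredictedGeometry",
    "BackgroundGeometry",
    "Predictor",
    "SurrogatePredictor",
    "PredictorError",
    "register_predictor",
    "get_predictor",
    "make_surrogate",
    "compute_background",
    "save_background",
    "load_background",
    "logistic",
]

DEFAULT_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

_REGISTRY: dict[str, type] = {}


class PredictorError(ValueError):
    """Raised for sequences outside a predictor's contract."""


def register_predictor(name: str):
    """Class decorator registering a predictor implementation by name."""

    def deco(cls):
        _REGISTRY[name] = cls
        return cls

    return deco


def get_predictor(name: str) -> type:
    if name not in _REGISTRY:
        raise KeyError(f"no predictor registered under {name!r}; "
                       f"have {sorted(_REGISTRY)}")
    return _REGISTRY[name]


def logistic(x: float) -> float:
    # exp-form split keeps the function overflow-free on both tails
    if x >= 0:
        return 1.0 / (1.0 + np.exp(-x))
    z = np.exp(x)
    return z / (1.0 + z)


@dataclass
class PredictedGeometry:
    """Predictor output: per ordered pair, per channel, a distribution.

    ``dists[channel]`` has shape (L, L, K); rows on the diagonal are
    unused and hold the uniform distribution.
    """

    length: int
    dists: dict[str, np.ndarray]

    def channel(self, name: str) -> np.ndarray:
        return self.dists[name]


@dataclass
class BackgroundGeometry:
    """Per-channel reference distributions for the confidence loss.

    Without separation bands ``dists[channel]`` is (K,); with bands it
    is (n_bands, K) and ``band_edges`` holds the |i−j| lower edges.
    """

    dists: dict[str, np.ndarray]
    band_edges: tuple[int, ...] | None = None

    def band_index(self, separation: np.ndarray) -> np.ndarray:
        if self.band_edges is None:
            return np.zeros_like(separation)
        return np.searchsorted(np.asarray(self.band_edges), separation,
                               side="right") - 1

    def for_pairs(self, channel: str, i_idx: np.ndarray,
                  j_idx: np.ndarray) -> np.ndarray:
        """(n, K) background rows for pairs (i, j)."""
        dist = self.dists[channel]
        if self.band_edges is None:
            return np.broadcast_to(dist, (len(i_idx), dist.shape[-1]))
        return dist[self.band_index(np.abs(i_idx - j_idx))]


class Predictor:
    """Contract base: deterministic sequence -> PredictedGeometry."""

    alphabet: str = DEFAULT_ALPHABET

    def _check(self, sequence: str) -> None:
        if len(sequence) < 2:
            raise PredictorError("sequence must have length >= 2")
        bad = set(sequence) - set(self.alphabet)
        if bad:
            raise PredictorError(f"letters {sorted(bad)} outside alphabet")

    def predict(self, sequence: str) -> PredictedGeometry:  # pragma: no cover
        raise NotImplementedError


@register_predictor("surrogate")
class SurrogatePredictor(Predictor):
    """Deterministic template-mixture oracle.

    For a query sequence the output for pair (i, j) is

        s * onehot(template geometry at mapped pair) + (1 - s) * uniform

    with ``s = logistic(kappa * mean per-position compatibility)``, the
    compatibility of position p being ``weights[template_position(p),
    alphabet_index(query[p])]`` (0 for unmapped positions).  Conserved
    segments map 1:1 to the template; variable-loop residues map to the
    template loop by proportional position, and loops longer than the
    template's are left unmapped, so their pairs stay uninformative.
    """

    def __init__(self, profile: FamilyProfile, template: GeometryMap,
                 template_loop_lengths: list[int],
                 compatibility_weights: np.ndarray, kappa: float = 3.0,
                 alphabet: str = DEFAULT_ALPHABET):
        ann = profile.annotation
        tmap = build_mapping(ann, list(template_loop_lengths))
        if tmap.length != template.length:
            raise PredictorError(
                f"template length {template.length} != annotation layout "
                f"{tmap.length}"
            )
        W = np.asarray(compatibility_weights, dtype=float)
        if W.shape != (template.length, len(alphabet)):
            raise PredictorError(
                f"compatibility_weights must be ({template.length}, "
                f"{len(alphabet)}); got {W.shape}"
            )
        self.profile = profile
        self.annotation = ann
        self.bin_spec = profile.bin_spec
        self.template_loop_lengths = list(template_loop_lengths)
        self.template_mapping = tmap
        self.weights = W
        self.kappa = float(kappa)
        self.alphabet = alphabet
        self._aa_index = {a: i for i, a in enumerate(alphabet)}
        self._onehot = geometry_to_onehot(template, self.bin_spec)
        self._cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}

    # -- query-length handling -------------------------------------------
    def _allocate_loops(self, length: int) -> list[int]:
        """Distribute the non-conserved residues of a query over loops.

        Proportional to template loop lengths, largest-remainder rounding,
        ties to the earlier loop.  Deterministic in ``length``.
        """
        nc = self.annotation.n_conserved
        extra = length - nc
        if extra < 0:
            raise PredictorError(
                f"sequence length {length} below conserved length {nc}"
            )
        t = np.asarray(self.template_loop_lengths, dtype=float)
        if len(t) == 0:
            if extra:
                raise PredictorError("no variable loops but extra residues")
            return []
        share = t / t.sum() * extra if t.sum() > 0 else np.full(len(t), extra / len(t))
        base = np.floor(share).astype(int)
        rem = extra - base.sum()
        order = np.argsort(-(share - base), kind="stable")
        for k in order[:rem]:
            base[k] += 1
        return base.tolist()

    def query_to_template(self, length: int) -> tuple[np.ndarray, np.ndarray]:
        """Mapped query positions and their template positions, for a length."""
        if length in self._cache:
            return self._cache[length]
        q_loops = self._allocate_loops(length)
        qmap = build_mapping(self.annotation, q_loops)
        tmap = self.template_mapping
        q_pos, t_pos = [], []
        for col, qp in qmap.conserved.items():
            q_pos.append(qp)
            t_pos.append(tmap.conserved[col])
        t_loop_starts: dict[int, list[int]] = {}
        for pos, (k, local) in tmap.loop_of.items():
            t_loop_starts.setdefault(k, []).append(pos)
        for pos, (k, local) in qmap.loop_of.items():
            ql = q_loops[k]
            tl = self.template_loop_lengths[k]
            if tl == 0 or ql > tl:
                continue  # background-only: loop longer than template's
            t_local = 0 if ql == 1 else round(local * (tl - 1) / (ql - 1))
            q_pos.append(pos)
            t_pos.append(sorted(t_loop_starts[k])[t_local])
        out = (np.array(q_pos, dtype=int), np.array(t_pos, dtype=int))
        self._cache[length] = out
        return out

    # -- contract --------------------------------------------------------
    def compatibility(self, sequence: str) -> float:
        """Mean per-position compatibility score of a query."""
        q_pos, t_pos = self.query_to_template(len(sequence))
        total = 0.0
        for qp, tp in zip(q_pos, t_pos):
            total += self.weights[tp, self._aa_index[sequence[qp]]]
        return total / len(sequence)

    def mixture_coefficient(self, sequence: str) -> float:
        return logistic(self.kappa * self.compatibility(sequence))

    def predict(self, sequence: str) -> PredictedGeometry:
        self._check(sequence)
        L = len(sequence)
        s = self.mixture_coefficient(sequence)
        q_pos, t_pos = self.query_to_template(L)
        dists = {}
        for ch in PAIR_CHANNELS:
            K = self.bin_spec.n_bins(ch)
            out = np.full((L, L, K), 1.0 / K)
            sub = self._onehot[ch][np.ix_(t_pos, t_pos)]
            out[np.ix_(q_pos, q_pos)] = s * sub + (1.0 - s) / K
            out[np.arange(L), np.arange(L)] = 1.0 / K
            dists[ch] = out
        return PredictedGeometry(L, dists)


def make_surrogate(profile: FamilyProfile, template: GeometryMap,
                   template_loop_lengths: list[int],
                   compatibility_weights: np.ndarray, kappa: float = 3.0,
                   alphabet: str = DEFAULT_ALPHABET) -> SurrogatePredictor:
    """Convenience constructor for the surrogate oracle."""
    return SurrogatePredictor(profile, template, template_loop_lengths,
                              compatibility_weights, kappa, alphabet)


def symmetrize(pred: PredictedGeometry) -> PredictedGeometry:
    """Average the d and ω channels over pair swap (for external adapters)."""
    dists = dict(pred.dists)
    for ch in ("d", "omega"):
        dists[ch] = 0.5 * (pred.dists[ch] + pred.dists[ch].transpose(1, 0, 2))
    return PredictedGeometry(pred.length, dists)


def save_background(background: BackgroundGeometry, path) -> None:
    """Persist a background as JSON next to the profile container."""
    import json

    doc = {
        "format": "famhal-background",
        "band_edges": (
            None if background.band_edges is None
            else list(background.band_edges)
        ),
        "dists": {ch: background.dists[ch].tolist()
                  for ch in background.dists},
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_background(path) -> BackgroundGeometry:
    import json

    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format") != "famhal-background":
        raise ValueError(f"{path} is not a famhal background container")
    edges = doc["band_edges"]
    return BackgroundGeometry(
        {ch: np.array(v, dtype=float) for ch, v in doc["dists"].items()},
        None if edges is None else tuple(edges),
    )


def compute_background(predictor: Predictor, lengths: list[int],
                       n_sequences: int = 100, seed: int = 0,
                       band_edges: tuple[int, ...] | None = None,
                       floor: float = 1e-8) -> BackgroundGeometry:
    """Mean prediction over uniformly random sequences.

    Distributions are pooled over all ordered pairs (optionally per
    |i−j| band), floored at ``floor`` and renormalized so that every
    bin is strictly positive.  Reproducible given ``seed``.
    """
    if n_sequences < 1:
        raise ValueError("n_sequences must be >= 1")
    rng = np.random.default_rng(seed)
    alphabet = np.array(list(predictor.alphabet))
    n_bands = 1 if band_edges is None else len(band_edges)
    sums: dict[str, np.ndarray] = {}
    counts = np.zeros(n_bands)
    for _ in range(n_sequences):
        L = int(rng.choice(np.asarray(lengths)))
        seq = "".join(rng.choice(alphabet, size=L))
        pred = predictor.predict(seq)
        i_idx, j_idx = np.where(~np.eye(L, dtype=bool))
        sep = np.abs(i_idx - j_idx)
        if band_edges is None:
            band = np.zeros(len(i_idx), dtype=int)
        else:
            band = np.searchsorted(np.asarray(band_edges), sep, side="right") - 1
        for ch in PAIR_CHANNELS:
            rows = pred.dists[ch][i_idx, j_idx]
            acc = sums.setdefault(
                ch, np.zeros((n_bands, rows.shape[-1]))
            )
            np.add.at(acc, band, rows)
        np.add.at(counts, band, 1.0)
    dists = {}
    for ch, acc in sums.items():
        mean = acc / np.maximum(counts[:, None], 1.0)
        mean = np.maximum(mean, floor)
        mean /= mean.sum(axis=1, keepdims=True)
        dists[ch] = mean[0] if band_edges is None else mean
    return BackgroundGeometry(dists, band_edges)
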