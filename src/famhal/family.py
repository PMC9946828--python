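"""Family-wide restraint profiles over binned inter-residue geometry.

A family of homologous backbones, mapped through a common multiple
sequence alignment, defines for every pair of structurally conserved
alignment columns a categorical distribution over geometry bins (one
per channel).  Conserved columns are those shared by most members
(low gap fraction); the remaining variable columns — typically loops —
are left to the confidence loss and may change length during design.

Distributions are pooled histograms over the member structures with a
Laplace-style pseudocount so every bin has positive mass and KL terms
stay finite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .geometry import BinSpec, PAIR_CHANNELS, bin_geometry, compute_geometry
from .structio import BackboneStructure

__all__ = [
    "RegionAnnotation",
    "FamilyProfile",
    "SequenceMapping",
    "AlignmentError",
    "ProfileFormatError",
    "ProfileVersionError",
    "classify_regions",
    "build_profile",
    "save_profile",
    "load_profile",
    "build_mapping",
]

PROFILE_FORMAT_VERSION = 1

GAP_CHARS = ("-", ".")


class AlignmentError(ValueError):
    """Raised for ragged, empty or inconsistent alignments."""


class ProfileFormatError(ValueError):
    """Raised for corrupt or inconsistent profile files."""


class ProfileVersionError(ProfileFormatError):
    """Raised when a profile file declares an unsupported format version."""


@dataclass
class RegionAnnotation:
    """Column classification of a family alignment.

    ``column_class`` holds True for conserved columns.
    ``conserved_segments`` / ``variable_segments`` are ordered, disjoint
    half-open column intervals covering their respective columns.
    ``member_maps`` map alignment column -> residue index (0-based) for
    each member, defined on that member's non-gap columns.
    ``loop_length_bounds`` give per variable segment the allowed residue
    count interval (min, max), inclusive.
    """

    alignment_length: int
    column_class: np.ndarray
    conserved_segments: list[tuple[int, int]]
    variable_segments: list[tuple[int, int]]
    member_maps: list[dict[int, int]]
    loop_length_bounds: list[tuple[int, int]] = field(default_factory=list)

    @property
    def conserved_columns(self) -> np.ndarray:
        return np.flatnonzero(self.column_class)

    @property
    def n_conserved(self) -> int:
        return int(self.column_class.sum())

    def to_dict(self) -> dict:
        return {
            "alignment_length": self.alignment_length,
            "column_class": [int(c) for c in self.column_class],
            "conserved_segments": [list(s) for s in self.conserved_segments],
            "variable_segments": [list(s) for s in self.variable_segments],
            "member_maps": [
                {str(k): v for k, v in m.items()} for m in self.member_maps
            ],
            "loop_length_bounds": [list(b) for b in self.loop_length_bounds],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RegionAnnotation":
        return cls(
            alignment_length=int(d["alignment_length"]),
            column_class=np.array(d["column_class"], dtype=bool),
            conserved_segments=[tuple(s) for s in d["conserved_segments"]],
            variable_segments=[tuple(s) for s in d["variable_segments"]],
            member_maps=[
                {int(k): int(v) for k, v in m.items()} for m in d["member_maps"]
            ],
            loop_length_bounds=[tuple(b) for b in d["loop_length_bounds"]],
        )


def _segments_from_mask(mask: np.ndarray, value: bool) -> list[tuple[int, int]]:
    segs = []
    start = None
    for i, v in enumerate(mask):
        if bool(v) == value and start is None:
            start = i
        elif bool(v) != value and start is not None:
            segs.append((start, i))
            start = None
    if start is not None:
        segs.append((start, len(mask)))
    return segs


def classify_regions(alignment: list[str], gap_threshold: float = 0.3,
                     min_segment_length: int = 3) -> RegionAnnotation:
    """Split alignment columns into conserved and variable regions.

    A column is conserved when its gap fraction is at most
    ``gap_threshold``; conserved runs shorter than ``min_segment_length``
    are demoted to variable.  Each variable segment gets loop-length
    bounds (observed minimum − 1, observed maximum + 1), clamped at 0.
    """
    seqs = [str(s) for s in alignment]
    if not seqs:
        raise AlignmentError("empty alignment")
    width = len(seqs[0])
    if width == 0 or any(len(s) != width for s in seqs):
        raise AlignmentError("alignment members have unequal lengths")

    arr = np.array([list(s) for s in seqs])
    gaps = np.isin(arr, GAP_CHARS)
    gap_frac = gaps.mean(axis=0)
    conserved = gap_frac <= gap_threshold
    for start, end in _segments_from_mask(conserved, True):
        if end - start < min_segment_length:
            conserved[start:end] = False

    member_maps = []
    for m in range(len(seqs)):
        non_gap = np.flatnonzero(~gaps[m])
        member_maps.append({int(col): i for i, col in enumerate(non_gap)})

    variable_segments = _segments_from_mask(conserved, False)
    bounds = []
    for start, end in variable_segments:
        lengths = (~gaps[:, start:end]).sum(axis=1)
        bounds.append((max(int(lengths.min()) - 1, 0), int(lengths.max()) + 1))
    return RegionAnnotation(
        alignment_length=width,
        column_class=conserved,
        conserved_segments=_segments_from_mask(conserved, True),
        variable_segments=variable_segments,
        member_maps=member_maps,
        loop_length_bounds=bounds,
    )


@dataclass
class FamilyProfile:
    """Per conserved-column-pair geometry restraint distributions.

    ``restraints[channel]`` is (n_pairs, K) with rows normalized to 1;
    ``pairs`` lists the unordered conserved column pairs (a, b), a < b,
    in row order, with forward channels oriented a -> b.  ``support``
    counts the family members that contributed an observation per pair.
    """

    annotation: RegionAnnotation
    bin_spec: BinSpec
    pairs: np.ndarray  # (n_pairs, 2) int columns (a, b), a < b
    restraints: dict[str, np.ndarray]
    support: np.ndarray
    pseudocount: float

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def pair_rows(self) -> dict[tuple[int, int], int]:
        return {(int(a), int(b)): r for r, (a, b) in enumerate(self.pairs)}


def build_profile(structures: list[BackboneStructure], alignment: list[str],
                  annotation: RegionAnnotation, spec: BinSpec | None = None,
                  pseudocount: float | None = None) -> FamilyProfile:
    """Pool binned geometries of family members into restraints.

    For each unordered conserved-column pair and channel, the observed
    bins across members where both columns are non-gap are counted,
    ``pseudocount`` is added to every bin, and the result normalized.
    Pairs never observed carry the uniform distribution and support 0.

    ``pseudocount=None`` selects the default 1/K per channel.
    """
    spec = spec or BinSpec.default()
    seqs = [str(s) for s in alignment]
    if len(structures) != len(seqs):
        raise AlignmentError(
            f"{len(structures)} structures vs {len(seqs)} alignment members"
        )
    if not seqs or annotation.alignment_length != len(seqs[0]):
        raise AlignmentError("annotation does not match alignment width")
    for m, (st, seq) in enumerate(zip(structures, seqs)):
        non_gap = sum(c not in GAP_CHARS for c in seq)
        if len(st) != non_gap:
            raise AlignmentError(
                f"member {m}: {len(st)} residues vs {non_gap} non-gap columns"
            )

    cons = annotation.conserved_columns
    a_idx, b_idx = np.triu_indices(len(cons), k=1)
    pairs = np.stack([cons[a_idx], cons[b_idx]], axis=1)
    n_pairs = len(pairs)

    counts = {
        ch: np.zeros((n_pairs, spec.n_bins(ch)), dtype=float)
        for ch in PAIR_CHANNELS
    }
    support = np.zeros(n_pairs, dtype=int)

    for m, st in enumerate(structures):
        cmap = annotation.member_maps[m]
        present = np.array([c in cmap for c in pairs[:, 0]]) & np.array(
            [c in cmap for c in pairs[:, 1]]
        )
        if not present.any():
            continue
        gmap = compute_geometry(st, spec)
        bins = bin_geometry(gmap, spec)
        rows = np.flatnonzero(present)
        ii = np.array([cmap[int(pairs[r, 0])] for r in rows])
        jj = np.array([cmap[int(pairs[r, 1])] for r in rows])
        for ch in PAIR_CHANNELS:
            np.add.at(counts[ch], (rows, bins[ch][ii, jj]), 1.0)
        support[rows] += 1

    restraints = {}
    for ch in PAIR_CHANNELS:
        K = spec.n_bins(ch)
        eps = (1.0 / K) if pseudocount is None else float(pseudocount)
        c = counts[ch] + eps
        total = c.sum(axis=1, keepdims=True)
        zero = total[:, 0] == 0.0  # only possible with eps == 0 and support 0
        c[zero] = 1.0 / K
        total[zero] = 1.0
        restraints[ch] = c / total
    eps_stored = -1.0 if pseudocount is None else float(pseudocount)
    return FamilyProfile(annotation, spec, pairs, restraints, support,
                         eps_stored)


def save_profile(profile: FamilyProfile, path) -> None:
    """Persist a profile as versioned JSON (distributions at full precision)."""
    doc = {
        "format": "famhal-profile",
        "version": PROFILE_FORMAT_VERSION,
        "bin_spec": profile.bin_spec.to_dict(),
        "annotation": profile.annotation.to_dict(),
        "pairs": profile.pairs.tolist(),
        "support": profile.support.tolist(),
        "pseudocount": profile.pseudocount,
        "restraints": {
            ch: profile.restraints[ch].tolist() for ch in PAIR_CHANNELS
        },
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_profile(path) -> FamilyProfile:
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ProfileFormatError(f"corrupt profile file {path}: {exc}") from exc
    if doc.get("format") != "famhal-profile":
        raise ProfileFormatError(f"{path} is not a famhal profile container")
    if doc.get("version") != PROFILE_FORMAT_VERSION:
        raise ProfileVersionError(
            f"profile version {doc.get('version')} unsupported "
            f"(expected {PROFILE_FORMAT_VERSION})"
        )
    spec = BinSpec.from_dict(doc["bin_spec"])
    restraints = {}
    for ch in PAIR_CHANNELS:
        arr = np.array(doc["restraints"][ch], dtype=float)
        if arr.ndim != 2 or arr.shape[1] != spec.n_bins(ch):
            raise ProfileFormatError(
                f"channel {ch}: expected {spec.n_bins(ch)} bins, file has "
                f"{arr.shape[1] if arr.ndim == 2 else '?'}"
            )
        restraints[ch] = arr
    return FamilyProfile(
        annotation=RegionAnnotation.from_dict(doc["annotation"]),
        bin_spec=spec,
        pairs=np.array(doc["pairs"], dtype=int).reshape(-1, 2),
        restraints=restraints,
        support=np.array(doc["support"], dtype=int),
        pseudocount=float(doc["pseudocount"]),
    )


@dataclass
class SequenceMapping:
    """Current-sequence bookkeeping against the family annotation.

    ``conserved`` maps alignment column -> sequence position (0-based)
    for every conserved column; ``variable_positions`` lists sequence
    positions that belong to variable loops; ``loop_of`` maps those
    positions to (loop index, local index).
    """

    length: int
    conserved: dict[int, int]
    variable_positions: list[int]
    loop_of: dict[int, tuple[int, int]]

    def variable_pairs(self) -> np.ndarray:
        """(n, 2) array of unordered pairs (i < j) touching a variable position."""
        var = set(self.variable_positions)
        pairs = [
            (i, j)
            for i in range(self.length)
            for j in range(i + 1, self.length)
            if i in var or j in var
        ]
        return np.array(pairs, dtype=int).reshape(-1, 2)


def build_mapping(annotation: RegionAnnotation,
                  loop_lengths: list[int]) -> SequenceMapping:
    """Lay out a sequence as alternating conserved/variable segments.

    Conserved segments contribute one residue per column; variable
    segment ``k`` contributes ``loop_lengths[k]`` residues.  Segments are
    interleaved in alignment-column order.
    """
    if len(loop_lengths) != len(annotation.variable_segments):
        raise AlignmentError(
            f"{len(loop_lengths)} loop lengths for "
            f"{len(annotation.variable_segments)} variable segments"
        )
    events = [(s, e, "C", None) for (s, e) in annotation.conserved_segments]
    events += [
        (s, e, "V", k) for k, (s, e) in enumerate(annotation.variable_segments)
    ]
    events.sort()
    conserved: dict[int, int] = {}
    variable_positions: list[int] = []
    loop_of: dict[int, tuple[int, int]] = {}
    pos = 0
    for start, end, kind, k in events:
        if kind == "C":
            for col in range(start, end):
                conserved[col] = pos
                pos += 1
        else:
            for local in range(loop_lengths[k]):
                variable_positions.append(pos)
                loop_of[pos] = (k, local)
                pos += 1
    return SequenceMapping(pos, conserved, variable_positions, loop_of)
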