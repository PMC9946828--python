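"""Synthetic protein families and toy inputs.

Everything the framework needs to be exercised without downloads is
generated here: idealized backbones built from torsion angles by
internal-to-Cartesian chain extension, toy structure families whose
members share jittered conserved segments but differ in loop lengths,
the matching alignments and truth annotations, and fully wired
"planted optimum" problems whose known best sequence lets search
behaviour be verified end to end.

Also provided is a *synthetic* stand-in design model for the
inspection utilities: a 117-residue mixed α/β chain with an arginine at
position 65 and a DTZ-named hetero group whose N1 atom sits 4.2 Å from
the arginine's CZ.  Its properties are construction inputs, not
measurements of any deposited structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .family import (FamilyProfile, RegionAnnotation, build_mapping,
                     build_profile)
from .geometry import GeometryMap, compute_geometry
from .losses import LossConfig, total_loss
from .predictor import (BackgroundGeometry, DEFAULT_ALPHABET,
                        SurrogatePredictor, compute_background, make_surrogate)
from .structio import (BackboneStructure, ONE_TO_THREE, Residue,
                       place_internal, reconstruct_cb)

__all__ = [
    "ToyFamilySpec",
    "ToyFamily",
    "PlantedProblem",
    "VerificationError",
    "SEGMENT_TORSIONS",
    "CHAIN_GEOMETRY",
    "build_backbone_from_torsions",
    "make_toy_family",
    "make_planted_problem",
    "make_synthetic_design_model",
    "SYNTHETIC_MODEL_SEQUENCE",
]


class VerificationError(RuntimeError):
    """Raised when a planted problem fails its construction check."""


#: Ideal main-chain internal coordinates used for chain extension:
#: bond lengths in Å, planar angles in degrees.
CHAIN_GEOMETRY = {
    "N-CA": 1.458,
    "CA-C": 1.525,
    "C-N": 1.329,
    "C-O": 1.231,
    "N-CA-C": 111.2,
    "CA-C-N": 116.2,
    "C-N-CA": 121.7,
    "CA-C-O": 120.5,
}

#: Canonical (phi, psi, omega) in degrees per secondary-structure kind.
SEGMENT_TORSIONS = {
    "helix": (-57.0, -47.0, 180.0),
    "strand": (-139.0, 135.0, 180.0),
    "loop": (-75.0, 145.0, 180.0),
}


def build_backbone_from_torsions(torsions, sequence: str | None = None,
                                 chain_id: str = "A") -> BackboneStructure:
    """Build N/CA/C/O (+ ideal Cβ) coordinates from per-residue torsions.

    ``torsions`` is a sequence of (phi, psi, omega) triples in degrees;
    phi of the first residue and psi/omega of the last are unused.  The
    first residue is placed canonically: N at the origin, CA on +x, C in
    the xy-plane.
    """
    torsions = [tuple(map(float, t)) for t in torsions]
    if len(torsions) < 2:
        raise ValueError("need at least 2 residues")
    for t in torsions:
        if not all(np.isfinite(v) for v in t):
            raise ValueError(f"non-finite torsion {t}")
    g = CHAIN_GEOMETRY
    if sequence is None:
        sequence = "A" * len(torsions)
    if len(sequence) != len(torsions):
        raise ValueError("sequence length must match torsion count")

    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([g["N-CA"], 0.0, 0.0])
    ang = np.radians(g["N-CA-C"])
    c0 = ca0 + g["CA-C"] * np.array([-np.cos(ang), np.sin(ang), 0.0])
    n_xyz, ca_xyz, c_xyz = [n0], [ca0], [c0]
    for i in range(1, len(torsions)):
        phi_i = torsions[i][0]
        psi_prev, omega_prev = torsions[i - 1][1], torsions[i - 1][2]
        n_i = place_internal(n_xyz[-1], ca_xyz[-1], c_xyz[-1],
                             g["C-N"], g["CA-C-N"], psi_prev)
        ca_i = place_internal(ca_xyz[-1], c_xyz[-1], n_i,
                              g["N-CA"], g["C-N-CA"], omega_prev)
        c_i = place_internal(c_xyz[-1], n_i, ca_i,
                             g["CA-C"], g["N-CA-C"], phi_i)
        n_xyz.append(n_i)
        ca_xyz.append(ca_i)
        c_xyz.append(c_i)

    residues = []
    for i in range(len(torsions)):
        psi_i = torsions[i][1]
        o_i = place_internal(n_xyz[i], ca_xyz[i], c_xyz[i],
                             g["C-O"], g["CA-C-O"], psi_i + 180.0)
        residues.append(
            Residue(
                ONE_TO_THREE[sequence[i]],
                i + 1,
                {"N": n_xyz[i], "CA": ca_xyz[i], "C": c_xyz[i], "O": o_i},
            )
        )
    return reconstruct_cb(BackboneStructure(residues, [], chain_id))


@dataclass(frozen=True)
class ToyFamilySpec:
    """Blueprint of a synthetic structure family.

    ``segment_plan`` is an ordered list of (kind, length) entries where
    kind is helix/strand/loop; helix and strand lengths are fixed
    integers (the conserved regions), loop lengths are (min, max)
    ranges sampled per member (the variable regions).
    """

    n_members: int = 6
    segment_plan: tuple = (("helix", 10), ("loop", (2, 4)), ("strand", 8))
    coordinate_jitter: float = 0.05
    loop_length_seed: int = 0
    jitter_seed: int = 0
    planted_sequence: str | None = None
    kappa: float = 3.0
    alphabet: str = DEFAULT_ALPHABET

    def __post_init__(self):
        kinds = [k for k, _ in self.segment_plan]
        if not any(k in ("helix", "strand") for k in kinds):
            raise ValueError("need at least one conserved (helix/strand) segment")
        if self.coordinate_jitter < 0:
            raise ValueError("jitter must be >= 0")

    @property
    def conserved_length(self) -> int:
        return sum(
            length for kind, length in self.segment_plan if kind != "loop"
        )

    @property
    def loop_ranges(self) -> list[tuple[int, int]]:
        return [tuple(length) for kind, length in self.segment_plan
                if kind == "loop"]

    def reference_loop_lengths(self) -> list[int]:
        return [(lo + hi) // 2 for lo, hi in self.loop_ranges]


@dataclass
class ToyFamily:
    structures: list[BackboneStructure]
    alignment: list[str]
    annotation: RegionAnnotation
    member_loop_lengths: list[list[int]]
    reference: BackboneStructure
    reference_loop_lengths: list[int]
    spec: ToyFamilySpec


def _plan_torsions(spec: ToyFamilySpec, loop_lengths: list[int]) -> list:
    torsions = []
    li = 0
    for kind, length in spec.segment_plan:
        n = loop_lengths[li] if kind == "loop" else length
        if kind == "loop":
            li += 1
        torsions.extend([SEGMENT_TORSIONS[kind]] * n)
    return torsions


def make_toy_family(spec: ToyFamilySpec) -> ToyFamily:
    """Generate member structures, their alignment and truth annotation.

    Members share the conserved-segment torsions (coordinates jittered
    by ``coordinate_jitter`` Å) and draw each loop length uniformly from
    its range; alignment gaps encode exactly the loop-length
    differences (loop letters left-aligned within max-width columns).
    Deterministic given the spec's seeds.
    """
    rng_loop = np.random.default_rng(spec.loop_length_seed)
    rng_jit = np.random.default_rng(spec.jitter_seed)
    alphabet = np.array(list(spec.alphabet))
    ranges = spec.loop_ranges

    member_loops = [
        [int(rng_loop.integers(lo, hi + 1)) for lo, hi in ranges]
        for _ in range(spec.n_members)
    ]
    member_seqs = []
    for loops in member_loops:
        L = spec.conserved_length + sum(loops)
        member_seqs.append("".join(rng_loop.choice(alphabet, size=L)))

    structures = []
    for m, loops in enumerate(member_loops):
        st = build_backbone_from_torsions(
            _plan_torsions(spec, loops), member_seqs[m]
        )
        if spec.coordinate_jitter > 0:
            for r in st.residues:
                for name in r.atoms:
                    r.atoms[name] = r.atoms[name] + rng_jit.normal(
                        0.0, spec.coordinate_jitter, size=3
                    )
        structures.append(st)

    # alignment: conserved segments column-per-residue, loops padded to
    # the widest observed length with trailing gaps
    loop_widths = [
        max(loops[k] for loops in member_loops) for k in range(len(ranges))
    ]
    aligned = []
    for m, loops in enumerate(member_loops):
        row, pos, li = [], 0, 0
        for kind, length in spec.segment_plan:
            if kind == "loop":
                ell = loops[li]
                row.append(member_seqs[m][pos:pos + ell]
                           + "-" * (loop_widths[li] - ell))
                pos += ell
                li += 1
            else:
                row.append(member_seqs[m][pos:pos + length])
                pos += length
        aligned.append("".join(row))

    # truth annotation straight from the construction
    width = len(aligned[0])
    column_class = np.zeros(width, dtype=bool)
    conserved_segments, variable_segments, bounds = [], [], []
    col, li = 0, 0
    for kind, length in spec.segment_plan:
        if kind == "loop":
            w = loop_widths[li]
            if w > 0:
                variable_segments.append((col, col + w))
                obs = [loops[li] for loops in member_loops]
                bounds.append((max(min(obs) - 1, 0), max(obs) + 1))
            col += w
            li += 1
        else:
            column_class[col:col + length] = True
            conserved_segments.append((col, col + length))
            col += length
    member_maps = []
    for row in aligned:
        non_gap = [i for i, c in enumerate(row) if c != "-"]
        member_maps.append({c: i for i, c in enumerate(non_gap)})
    annotation = RegionAnnotation(
        width, column_class, conserved_segments, variable_segments,
        member_maps, bounds,
    )

    ref_loops = spec.reference_loop_lengths()
    reference = build_backbone_from_torsions(
        _plan_torsions(spec, ref_loops),
        "A" * (spec.conserved_length + sum(ref_loops)),
    )
    return ToyFamily(structures, aligned, annotation, member_loops,
                     reference, ref_loops, spec)


@dataclass
class PlantedProblem:
    """A fully wired toy design problem with a known optimal sequence."""

    profile: FamilyProfile
    background: BackgroundGeometry
    predictor: SurrogatePredictor
    start_sequence: str
    planted_sequence: str  # full-length, planted letters on conserved positions
    annotation: RegionAnnotation
    template: GeometryMap
    reference_loop_lengths: list[int]
    family: ToyFamily
    loss_cfg: LossConfig = field(default_factory=LossConfig)

    def planted_conserved(self) -> str:
        return self.family.spec.planted_sequence

    def conserved_letters(self, state_sequence: str,
                          loop_lengths: list[int]) -> str:
        """Extract the conserved-region letters of a sequence."""
        mapping = build_mapping(self.annotation, loop_lengths)
        cols = sorted(mapping.conserved)
        return "".join(state_sequence[mapping.conserved[c]] for c in cols)


def make_planted_problem(spec: ToyFamilySpec, seed: int = 0,
                         n_verify: int = 1000) -> PlantedProblem:
    """Bundle profile, surrogate, background and a random start sequence.

    The surrogate's compatibility weights are +1 at the planted letters
    on conserved positions, −1 elsewhere, 0 on loop positions, so the
    planted sequence maximizes the mixture sharpness.  At construction
    the planted sequence's total loss is checked against ``n_verify``
    random sequences of the same length; failure raises
    :class:`VerificationError`.
    """
    if spec.planted_sequence is None:
        raise ValueError("spec.planted_sequence is required")
    if len(spec.planted_sequence) != spec.conserved_length:
        raise ValueError(
            f"planted sequence length {len(spec.planted_sequence)} != "
            f"conserved length {spec.conserved_length}"
        )
    family = make_toy_family(spec)
    annotation = family.annotation
    profile = build_profile(family.structures, family.alignment, annotation)
    template = compute_geometry(family.reference, profile.bin_spec)

    ref_loops = family.reference_loop_lengths
    tmap = build_mapping(annotation, ref_loops)
    A = len(spec.alphabet)
    aa_index = {a: i for i, a in enumerate(spec.alphabet)}
    W = np.zeros((tmap.length, A))
    for c_idx, col in enumerate(sorted(tmap.conserved)):
        pos = tmap.conserved[col]
        W[pos, :] = -1.0
        W[pos, aa_index[spec.planted_sequence[c_idx]]] = 1.0
    predictor = make_surrogate(profile, template, ref_loops, W,
                               kappa=spec.kappa, alphabet=spec.alphabet)

    rng = np.random.default_rng(seed)
    background = compute_background(
        predictor, [tmap.length], n_sequences=100,
        seed=int(rng.integers(2**31)),
    )
    alphabet = np.array(list(spec.alphabet))
    start_sequence = "".join(rng.choice(alphabet, size=tmap.length))

    planted_full = list(rng.choice(alphabet, size=tmap.length))
    for c_idx, col in enumerate(sorted(tmap.conserved)):
        planted_full[tmap.conserved[col]] = spec.planted_sequence[c_idx]
    planted_full = "".join(planted_full)

    cfg = LossConfig()
    problem = PlantedProblem(profile, background, predictor, start_sequence,
                             planted_full, annotation, template, ref_loops,
                             family, cfg)

    def loss_of(seq: str) -> float:
        pred = predictor.predict(seq)
        return total_loss(pred, profile, background, tmap, cfg).total

    planted_loss = loss_of(planted_full)
    random_losses = [
        loss_of("".join(rng.choice(alphabet, size=tmap.length)))
        for _ in range(n_verify)
    ]
    if planted_loss >= min(random_losses):
        raise VerificationError(
            f"planted loss {planted_loss:.4f} not below the minimum "
            f"({min(random_losses):.4f}) of {n_verify} random sequences"
        )
    return problem


@dataclass
class TwoSiteProblem:
    """A fully enumerable sampling testbed: 2 positions x 2 letters.

    With a two-letter alphabet and no variable loops the sequence space
    has exactly four states, so long-run Metropolis state frequencies
    can be compared against the exact Boltzmann distribution computed by
    exhaustive enumeration of the partition function.
    """

    profile: FamilyProfile
    background: BackgroundGeometry
    predictor: SurrogatePredictor
    annotation: RegionAnnotation
    alphabet: str

    def sequences(self) -> list[str]:
        a = self.alphabet
        return [x + y for x in a for y in a]


def make_two_site_problem(seed: int = 0) -> TwoSiteProblem:
    """Build the 2x2 enumerable problem with fixed, asymmetric scores."""
    spec = ToyFamilySpec(
        n_members=3,
        segment_plan=(("helix", 2),),
        coordinate_jitter=0.0,
        alphabet="AV",
    )
    fam = make_toy_family(spec)
    profile = build_profile(fam.structures, fam.alignment, fam.annotation)
    template = compute_geometry(fam.reference, profile.bin_spec)
    # distinct per-position scores so all four sequences differ in loss
    W = np.array([[0.8, -0.4], [0.2, -0.9]])
    predictor = make_surrogate(profile, template, [], W, kappa=2.0,
                               alphabet="AV")
    background = compute_background(predictor, [2], n_sequences=50, seed=seed)
    return TwoSiteProblem(profile, background, predictor, fam.annotation, "AV")


#: Frozen sequence of the synthetic stand-in design model: 117 residues,
#: arginine at position 65, average chain mass 13902.1 Da (13.9 kDa).
SYNTHETIC_MODEL_SEQUENCE = (
    "WIMNWSYWIEFKSPRQTHLGMKDYQHAQLMIPWLDPNCRAVTLCSMVRICGIMQNDKCKMWVNV"
    "RCRCNGKPEDFADAQEFITWAGKDYWQEDAADLNYMATHALIRCLPMYNSNID"
)

_SYNTHETIC_MODEL_PLAN = (
    ("helix", 14), ("loop", 3), ("strand", 8), ("loop", 2), ("strand", 9),
    ("loop", 3), ("helix", 12), ("loop", 4), ("strand", 8), ("loop", 3),
    ("strand", 9), ("loop", 2), ("strand", 10), ("loop", 3), ("helix", 12),
    ("loop", 3), ("strand", 12),
)  # lengths sum to 117


def make_synthetic_design_model() -> BackboneStructure:
    """SYNTHETIC stand-in for a small luciferase design model.

    This is *not* a deposited or published structure: it is a
    deterministic, idealized 117-residue mixed α/β chain whose
    inspection-relevant properties are planted by construction — an
    arginine at residue 65 with a full guanidinium group, and a
    DTZ-named hetero group whose N1 atom lies exactly 4.2 Å from the
    Arg65 CZ atom.  Use it to exercise the inspection utilities when no
    real design model is at hand.
    """
    torsions = []
    for kind, length in _SYNTHETIC_MODEL_PLAN:
        torsions.extend([SEGMENT_TORSIONS[kind]] * length)
    assert len(torsions) == 117
    st = build_backbone_from_torsions(torsions, SYNTHETIC_MODEL_SEQUENCE)

    # arginine side chain out to the guanidinium, ideal internal coords
    arg = st.residues[64]
    n, ca, cb = arg.atoms["N"], arg.atoms["CA"], arg.atoms["CB"]
    cg = place_internal(n, ca, cb, 1.520, 114.1, -65.0)
    cd = place_internal(ca, cb, cg, 1.520, 111.3, 180.0)
    ne = place_internal(cb, cg, cd, 1.461, 112.0, 180.0)
    cz = place_internal(cg, cd, ne, 1.329, 124.2, 180.0)
    nh1 = place_internal(cd, ne, cz, 1.326, 120.0, 0.0)
    nh2 = place_internal(cd, ne, cz, 1.326, 120.0, 180.0)
    for name, xyz in [("CG", cg), ("CD", cd), ("NE", ne), ("CZ", cz),
                      ("NH1", nh1), ("NH2", nh2)]:
        arg.atoms[name] = xyz

    # DTZ-named hetero group: N1 exactly 4.2 Å from Arg65 CZ, plus a few
    # neighbouring atoms sketching an imidazopyrazinone core
    u = cz - ne
    u = u / np.linalg.norm(u)
    n1 = cz + 4.2 * u
    c2 = n1 + 1.38 * np.array([0.94, 0.34, 0.0])
    c3 = c2 + 1.40 * np.array([0.31, 0.95, 0.0])
    o1 = c2 + 1.23 * np.array([0.55, -0.84, 0.0])
    st.hetero_atoms.extend(
        [("DTZ", "N1", n1), ("DTZ", "C2", c2), ("DTZ", "C3", c3),
         ("DTZ", "O1", o1)]
    )
    return st
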