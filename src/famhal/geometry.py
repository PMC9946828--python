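"""Inter-residue 6D geometry and its discretization.

For every residue pair the relative placement of the two side chains is
summarized by six real-valued features: the Cβ–Cβ distance d, the
dihedral ω = (CAi, CBi, CBj, CAj), the directional dihedrals
θ→ = (Ni, CAi, CBi, CBj) and θ← (i, j swapped), and the directional
planar angles φ→ = (CAi, CBi, CBj) and φ← .  These are the standard
distogram coordinates used by structure-prediction networks; restraint
profiles, predictor outputs and losses all live in the binned version
of this space defined by :class:`BinSpec`.

Conventions: distances in Å; dihedrals in (−180°, 180°] with +180°
assigned to the last angular bin; planar angles in [0°, 180°].  Pairs
with d at or beyond the no-contact cutoff occupy a dedicated
no-contact bin in every channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structio import BackboneStructure, MissingBackboneAtomError

__all__ = [
    "CHANNELS",
    "PAIR_CHANNELS",
    "BinSpec",
    "GeometryMap",
    "compute_geometry",
    "bin_value",
    "bin_geometry",
    "geometry_to_onehot",
    "dihedral",
    "planar_angle",
]

#: Base channels; each angular base channel has fwd/rev directional maps.
CHANNELS = ("d", "omega", "theta", "phi")

#: Directional channel keys used for per-pair maps and distributions.
PAIR_CHANNELS = ("d", "omega", "theta_fwd", "theta_rev", "phi_fwd", "phi_rev")

#: Base channel of each directional channel (for bin-count lookups).
BASE_OF = {
    "d": "d",
    "omega": "omega",
    "theta_fwd": "theta",
    "theta_rev": "theta",
    "phi_fwd": "phi",
    "phi_rev": "phi",
}


@dataclass(frozen=True)
class BinSpec:
    """Bin edges per channel, plus one trailing no-contact bin each.

    ``distance_edges`` must end at the no-contact cutoff; any distance at
    or beyond the last edge falls in the no-contact bin, and the angular
    channels of such pairs fall in their own paired no-contact bin.
    """

    distance_edges: tuple[float, ...]
    omega_edges: tuple[float, ...]
    theta_edges: tuple[float, ...]
    phi_edges: tuple[float, ...]

    def __post_init__(self):
        for name in ("distance_edges", "omega_edges", "theta_edges", "phi_edges"):
            edges = np.asarray(getattr(self, name), dtype=float)
            if edges.ndim != 1 or len(edges) < 2 or np.any(np.diff(edges) <= 0):
                raise ValueError(f"{name} must be strictly ascending with >=2 values")
        for name in ("omega_edges", "theta_edges"):
            edges = getattr(self, name)
            if not (edges[0] == -180.0 and edges[-1] == 180.0):
                raise ValueError(f"{name} must cover (-180, 180] exactly")
        if not (self.phi_edges[0] == 0.0 and self.phi_edges[-1] == 180.0):
            raise ValueError("phi_edges must cover [0, 180] exactly")

    @classmethod
    def default(cls) -> "BinSpec":
        """36 distance bins of 0.5 Å over [2, 20) Å; 15° angular bins."""
        return cls(
            distance_edges=tuple(np.round(np.arange(2.0, 20.0 + 0.25, 0.5), 6)),
            omega_edges=tuple(np.round(np.arange(-180.0, 180.0 + 7.5, 15.0), 6)),
            theta_edges=tuple(np.round(np.arange(-180.0, 180.0 + 7.5, 15.0), 6)),
            phi_edges=tuple(np.round(np.arange(0.0, 180.0 + 7.5, 15.0), 6)),
        )

    @property
    def no_contact_cutoff(self) -> float:
        return float(self.distance_edges[-1])

    def edges(self, channel: str) -> np.ndarray:
        base = BASE_OF.get(channel, channel)
        return np.asarray(
            {
                "d": self.distance_edges,
                "omega": self.omega_edges,
                "theta": self.theta_edges,
                "phi": self.phi_edges,
            }[base],
            dtype=float,
        )

    def n_bins(self, channel: str) -> int:
        """Total bins for a channel, including its no-contact bin."""
        return len(self.edges(channel))  # (len-1) value bins + 1 no-contact

    def no_contact_bin(self, channel: str) -> int:
        return self.n_bins(channel) - 1

    def to_dict(self) -> dict:
        return {
            "distance_edges": [float(x) for x in self.distance_edges],
            "omega_edges": [float(x) for x in self.omega_edges],
            "theta_edges": [float(x) for x in self.theta_edges],
            "phi_edges": [float(x) for x in self.phi_edges],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BinSpec":
        return cls(
            tuple(d["distance_edges"]),
            tuple(d["omega_edges"]),
            tuple(d["theta_edges"]),
            tuple(d["phi_edges"]),
        )


@dataclass
class GeometryMap:
    """Real-valued pairwise geometry of one structure.

    Angular matrices hold NaN outside the contact mask and on the
    diagonal; ``d`` is defined everywhere.
    """

    length: int
    d: np.ndarray
    omega: np.ndarray
    theta_fwd: np.ndarray
    theta_rev: np.ndarray
    phi_fwd: np.ndarray
    phi_rev: np.ndarray
    contact_mask: np.ndarray

    def channel(self, name: str) -> np.ndarray:
        return getattr(self, name)

    def to_table(self, path) -> None:
        """Dump as TSV (i, j, d, omega, theta_fwd, theta_rev, phi_fwd, phi_rev)."""
        with open(path, "w") as fh:
            fh.write("i\tj\td\tomega\ttheta_fwd\ttheta_rev\tphi_fwd\tphi_rev\n")
            for i in range(self.length):
                for j in range(self.length):
                    if i == j:
                        continue
                    vals = [self.channel(c)[i, j] for c in PAIR_CHANNELS]
                    fh.write(
                        f"{i}\t{j}\t" + "\t".join(f"{v:.6f}" for v in vals) + "\n"
                    )


def dihedral(p0, p1, p2, p3) -> np.ndarray:
    """Signed dihedral angle in degrees, IUPAC convention, in (−180, 180].

    Accepts broadcastable (..., 3) arrays.
    """
    b0 = np.asarray(p0) - np.asarray(p1)
    b1 = np.asarray(p2) - np.asarray(p1)
    b1 = b1 / np.linalg.norm(b1, axis=-1, keepdims=True)
    b2 = np.asarray(p3) - np.asarray(p2)
    v = b0 - np.sum(b0 * b1, axis=-1, keepdims=True) * b1
    w = b2 - np.sum(b2 * b1, axis=-1, keepdims=True) * b1
    x = np.sum(v * w, axis=-1)
    y = np.sum(np.cross(b1, v) * w, axis=-1)
    ang = np.degrees(np.arctan2(y, x))
    # map -180 -> +180 so the range is (-180, 180]
    return np.where(ang <= -180.0, ang + 360.0, ang)


def planar_angle(p0, p1, p2) -> np.ndarray:
    """Planar angle at p1 in degrees, in [0, 180]."""
    v1 = np.asarray(p0) - np.asarray(p1)
    v2 = np.asarray(p2) - np.asarray(p1)
    cosang = np.sum(v1 * v2, axis=-1) / (
        np.linalg.norm(v1, axis=-1) * np.linalg.norm(v2, axis=-1)
    )
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


def compute_geometry(structure: BackboneStructure,
                     spec: BinSpec | None = None) -> GeometryMap:
    """Compute the full 6D pairwise geometry of a backbone with Cβ atoms."""
    spec = spec or BinSpec.default()
    for r in structure.residues:
        if "CB" not in r.atoms:
            raise MissingBackboneAtomError(
                f"residue {r.name}{r.number} lacks CB; run reconstruct_cb first"
            )
    n_xyz = structure.coords("N")
    ca = structure.coords("CA")
    cb = structure.coords("CB")
    L = len(structure)

    diff = cb[:, None, :] - cb[None, :, :]
    d = np.linalg.norm(diff, axis=-1)
    contact = (d < spec.no_contact_cutoff) & ~np.eye(L, dtype=bool)

    cai = np.broadcast_to(ca[:, None, :], (L, L, 3))
    caj = np.broadcast_to(ca[None, :, :], (L, L, 3))
    cbi = np.broadcast_to(cb[:, None, :], (L, L, 3))
    cbj = np.broadcast_to(cb[None, :, :], (L, L, 3))
    ni = np.broadcast_to(n_xyz[:, None, :], (L, L, 3))

    with np.errstate(invalid="ignore", divide="ignore"):
        omega = dihedral(cai, cbi, cbj, caj)
        theta_fwd = dihedral(ni, cai, cbi, cbj)
        phi_fwd = planar_angle(cai, cbi, cbj)
    omega = np.where(contact, omega, np.nan)
    theta_fwd = np.where(contact, theta_fwd, np.nan)
    phi_fwd = np.where(contact, phi_fwd, np.nan)
    return GeometryMap(
        length=L,
        d=d,
        omega=omega,
        theta_fwd=theta_fwd,
        theta_rev=theta_fwd.T.copy(),
        phi_fwd=phi_fwd,
        phi_rev=phi_fwd.T.copy(),
        contact_mask=contact,
    )


def bin_value(value: float, channel: str, spec: BinSpec) -> int:
    """Bin index of one value; half-open [lower, upper) bins.

    Distances at or beyond the cutoff map to the no-contact bin; values
    below the first distance edge clamp to bin 0.  Dihedral +180° (and
    planar 180°) map to the last value bin.
    """
    if not np.isfinite(value):
        raise ValueError(f"non-finite value for channel {channel}")
    edges = spec.edges(channel)
    base = BASE_OF.get(channel, channel)
    if base == "d":
        if value >= edges[-1]:
            return spec.no_contact_bin(channel)
        return int(max(np.searchsorted(edges, value, side="right") - 1, 0))
    if value < edges[0] or value > edges[-1]:
        raise ValueError(
            f"{channel} value {value} outside [{edges[0]}, {edges[-1]}]"
        )
    if value == edges[-1]:
        return len(edges) - 2
    return int(np.searchsorted(edges, value, side="right") - 1)


def bin_geometry(gmap: GeometryMap, spec: BinSpec) -> dict[str, np.ndarray]:
    """(L, L) integer bin indices per directional channel.

    Diagonal and non-contact pairs carry the channel's no-contact bin
    (the diagonal is never used downstream).
    """
    L = gmap.length
    out: dict[str, np.ndarray] = {}
    contact = gmap.contact_mask
    for channel in PAIR_CHANNELS:
        edges = spec.edges(channel)
        vals = gmap.channel(channel)
        nc = spec.no_contact_bin(channel)
        if channel == "d":
            idx = np.searchsorted(edges, vals, side="right") - 1
            idx = np.clip(idx, 0, len(edges) - 2)
            idx = np.where(vals >= edges[-1], nc, idx)
        else:
            safe = np.where(np.isfinite(vals), vals, edges[0])
            idx = np.searchsorted(edges, safe, side="right") - 1
            idx = np.clip(idx, 0, len(edges) - 2)
            idx = np.where(safe == edges[-1], len(edges) - 2, idx)
        idx = np.where(contact, idx, nc)
        out[channel] = idx.astype(np.int64)
    return out


def geometry_to_onehot(gmap: GeometryMap, spec: BinSpec) -> dict[str, np.ndarray]:
    """One-hot (L, L, K) distributions per channel from observed bins."""
    bins = bin_geometry(gmap, spec)
    out = {}
    for channel, idx in bins.items():
        K = spec.n_bins(channel)
        out[channel] = np.eye(K)[idx]
    return out
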