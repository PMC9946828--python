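"""Independent oracles used to cross-check the implementation.

Each function here deliberately re-derives a quantity by a different
route (linear search, explicit cross products, naive double loops,
plain summation, 2-D planar construction) so that agreement with the
package is informative.
"""

import math

import numpy as np


def linear_search_bin(value, edges, *, is_distance=False, n_total=None):
    """Bin index by explicit scan over [lower, upper) intervals.

    Distances at/above the last edge go to the no-contact bin
    (``n_total - 1``); the top angular edge value belongs to the last
    value bin.
    """
    edges = list(edges)
    if is_distance:
        if value >= edges[-1]:
            return n_total - 1
        if value < edges[0]:
            return 0
    if value == edges[-1] and not is_distance:
        return len(edges) - 2
    for k in range(len(edges) - 1):
        if edges[k] <= value < edges[k + 1]:
            return k
    raise AssertionError(f"value {value} not covered by edges")


def dihedral_cross(p0, p1, p2, p3):
    """Signed dihedral in degrees via the two-plane-normal formula.

    Sign from the triple product of the first normal with the second
    bond — a different construction from the atan2 form in the package.
    """
    p0, p1, p2, p3 = (np.asarray(p) for p in (p0, p1, p2, p3))
    b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    cosang = np.dot(n1, n2) / (np.linalg.norm(n1) * np.linalg.norm(n2))
    ang = math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
    if np.dot(np.cross(n1, n2), b2) < 0:
        ang = -ang
    if ang <= -180.0:
        ang += 360.0
    return ang


def kl_direct(p, q, floor=1e-8):
    """Plain-python KL(p || q) in nats with floored, renormalized q."""
    q = [max(v, floor) for v in q]
    z = sum(q)
    q = [v / z for v in q]
    total = 0.0
    for pi, qi in zip(p, q):
        if pi > 0:
            total += pi * math.log(pi / qi)
    return total


def recount_profile(structures, alignment, annotation, spec):
    """Naive double-loop recount of per-pair per-channel bin counts.

    Returns ``counts[(a, b)][channel]`` as plain lists, with forward
    channels oriented a -> b, plus per-pair support.
    """
    from famhal.geometry import PAIR_CHANNELS, bin_geometry, compute_geometry

    cons = [int(c) for c in annotation.conserved_columns]
    counts = {}
    support = {}
    for ai in range(len(cons)):
        for bi in range(ai + 1, len(cons)):
            a, b = cons[ai], cons[bi]
            counts[(a, b)] = {
                ch: [0] * spec.n_bins(ch) for ch in PAIR_CHANNELS
            }
            support[(a, b)] = 0
    for m, st in enumerate(structures):
        cmap = annotation.member_maps[m]
        bins = bin_geometry(compute_geometry(st, spec), spec)
        for (a, b) in counts:
            if a in cmap and b in cmap:
                i, j = cmap[a], cmap[b]
                for ch in PAIR_CHANNELS:
                    counts[(a, b)][ch][bins[ch][i, j]] += 1
                support[(a, b)] += 1
    return counts, support


def place_by_rotation(a, b, c, bond, angle_deg, dihedral_deg):
    """Internal-to-Cartesian placement via explicit Rodrigues rotations.

    Start from the extension of b->c, bend by (180 - angle) about the
    normal of the a-b-c plane, then twist by the dihedral about b->c.
    Independent of the NeRF frame construction in the package.
    """
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))

    def rotate(v, axis, theta):
        axis = axis / np.linalg.norm(axis)
        return (
            v * math.cos(theta)
            + np.cross(axis, v) * math.sin(theta)
            + axis * np.dot(axis, v) * (1 - math.cos(theta))
        )

    bc = (c - b) / np.linalg.norm(c - b)
    n = np.cross(b - a, bc)
    d = bond * bc  # straight extension; trans (180) after the in-plane bend
    d = rotate(d, n, -math.radians(180.0 - angle_deg))
    d = rotate(d, bc, math.radians(dihedral_deg - 180.0))
    return c + d


def helix_rise(ca_coords):
    """Rise per residue from an SVD axis fit of the CA trace."""
    ca = np.asarray(ca_coords, dtype=float)
    centered = ca - ca.mean(axis=0)
    _, _, vt = np.linalg.svd(centered)
    axis = vt[0]
    proj = np.sort(centered @ axis)
    return float(np.diff(proj).mean())


def planar_ca_ca_distance(geometry):
    """Consecutive CA–CA distance of an ideal trans peptide by 2-D
    construction in the peptide plane (law-of-cosines chain)."""
    r1 = geometry["CA-C"]
    r2 = geometry["C-N"]
    r3 = geometry["N-CA"]
    a1 = math.radians(geometry["CA-C-N"])
    a2 = math.radians(geometry["C-N-CA"])
    # place CA at origin, C on +x; trans omega keeps everything planar
    ca = np.array([0.0, 0.0])
    c = np.array([r1, 0.0])
    n = c + r2 * np.array([-math.cos(a1), math.sin(a1)])
    u = (c - n) / np.linalg.norm(c - n)
    # rotate u by the C-N-CA angle within the plane (away from C side)
    rot = np.array(
        [
            [math.cos(a2), -math.sin(a2)],
            [math.sin(a2), math.cos(a2)],
        ]
    )
    ca2 = n + r3 * (rot @ u)
    return float(np.linalg.norm(ca2 - ca))


def boltzmann_distribution(losses, temperature):
    """Exact Boltzmann weights by exhaustive partition-function sum."""
    weights = {k: math.exp(-v / temperature) for k, v in losses.items()}
    z = sum(weights.values())
    return {k: w / z for k, w in weights.items()}
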