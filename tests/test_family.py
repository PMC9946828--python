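"""Region classification, restraint pooling and profile persistence."""

import numpy as np
import pytest

from famhal.family import (AlignmentError, ProfileFormatError,
                           ProfileVersionError, build_mapping, build_profile,
                           classify_regions, load_profile, save_profile)
from famhal.fixtures import (SEGMENT_TORSIONS, ToyFamilySpec,
                             build_backbone_from_torsions, make_toy_family)
from famhal.geometry import PAIR_CHANNELS, bin_geometry, compute_geometry
from oracles import recount_profile


class TestClassifyRegions:
    def test_gap_free_alignment_single_conserved_segment(self):
        ann = classify_regions(["MKVLA", "MRVLA"], min_segment_length=3)
        assert ann.column_class.all()
        assert ann.conserved_segments == [(0, 5)]
        assert ann.variable_segments == []

    def test_gap_fraction_threshold(self):
        # central column gapped in 3/5 members: variable at threshold 0.5
        seqs = ["AAAXAAA".replace("X", c) + "" for c in "A--A-"]
        seqs = [f"AAA{c}AAA" for c in ["A", "-", "-", "A", "-"]]
        ann = classify_regions(seqs, gap_threshold=0.5, min_segment_length=3)
        assert not ann.column_class[3]
        assert ann.column_class[[0, 1, 2, 4, 5, 6]].all()

    def test_toy_central_loop_bounds_by_hand_enumeration(self):
        # loops of lengths {2, 3, 3, 4} between two conserved blocks;
        # exhaustive inspection gives bounds (min-1, max+1) = (1, 5)
        rows = [
            "MKVL" + "-S-P" + "WITN",
            "MKVL" + "G-AP" + "WITN",
            "MKVL" + "GSA-" + "WITN",
            "MKVL" + "GSAP" + "WITN",
        ]
        ann = classify_regions(rows, gap_threshold=0.2, min_segment_length=3)
        assert ann.conserved_segments == [(0, 4), (8, 12)]
        assert ann.variable_segments == [(4, 8)]
        assert ann.loop_length_bounds == [(1, 5)]
        # per-member maps are strictly increasing over non-gap columns
        for m in ann.member_maps:
            cols = sorted(m)
            assert all(m[a] < m[b] for a, b in zip(cols, cols[1:]))

    def test_short_conserved_run_demoted(self):
        rows = ["A--AB--", "A--AB--", "AZ-AB-Q"]
        ann = classify_regions(rows, gap_threshold=0.3, min_segment_length=3)
        assert not ann.column_class.any()

    def test_errors(self):
        with pytest.raises(AlignmentError):
            classify_regions([])
        with pytest.raises(AlignmentError):
            classify_regions(["AAA", "AA"])


def _two_column_family(distances):
    """One 2-residue structure per requested Cβ–Cβ distance."""
    structures = []
    for dist in distances:
        # bend psi to vary the Cβ separation indirectly is fiddly; instead
        # scale a straight dipeptide along x
        st = build_backbone_from_torsions([SEGMENT_TORSIONS["strand"]] * 2)
        cb0 = st.residues[0].atoms["CB"]
        cb1 = st.residues[1].atoms["CB"]
        u = (cb1 - cb0) / np.linalg.norm(cb1 - cb0)
        shift = (dist - np.linalg.norm(cb1 - cb0)) * u
        for name in st.residues[1].atoms:
            st.residues[1].atoms[name] = st.residues[1].atoms[name] + shift
        structures.append(st)
    return structures, ["AA"] * len(distances)


class TestBuildProfile:
    def test_single_structure_zero_pseudocount_is_onehot(self):
        structures, aln = _two_column_family([6.0])
        ann = classify_regions(aln, min_segment_length=2)
        prof = build_profile(structures, aln, ann, pseudocount=0.0)
        for ch in PAIR_CHANNELS:
            row = prof.restraints[ch][0]
            assert sorted(row)[-1] == 1.0 and row.sum() == pytest.approx(1.0)
        assert prof.support[0] == 1

    def test_two_identical_structures_idempotent(self):
        structures, aln = _two_column_family([6.0, 6.0])
        ann = classify_regions(aln, min_segment_length=2)
        prof2 = build_profile(structures, aln, ann, pseudocount=0.0)
        prof1 = build_profile(structures[:1], aln[:1],
                              classify_regions(aln[:1], min_segment_length=2),
                              pseudocount=0.0)
        for ch in PAIR_CHANNELS:
            assert np.allclose(prof2.restraints[ch], prof1.restraints[ch])

    def test_two_distance_bins_split_half_half(self):
        structures, aln = _two_column_family([6.1, 9.7])
        ann = classify_regions(aln, min_segment_length=2)
        prof = build_profile(structures, aln, ann, pseudocount=0.0)
        row = prof.restraints["d"][0]
        occupied = np.flatnonzero(row)
        assert len(occupied) == 2
        assert np.allclose(row[occupied], 0.5)

    def test_structure_alignment_mismatch(self):
        structures, aln = _two_column_family([6.0])
        ann = classify_regions(aln, min_segment_length=2)
        with pytest.raises(AlignmentError):
            build_profile(structures, ["AAA"], ann)

    def test_normalization_any_pseudocount(self, toy_family):
        for eps in (0.0, 1e-3, 0.5, None):
            prof = build_profile(toy_family.structures, toy_family.alignment,
                                 toy_family.annotation, pseudocount=eps)
            for ch in PAIR_CHANNELS:
                assert np.allclose(prof.restraints[ch].sum(axis=1), 1.0,
                                   atol=1e-9)

    def test_monotone_smoothing(self, toy_family):
        mins = []
        for eps in (0.0, 0.01, 0.1, 1.0):
            prof = build_profile(toy_family.structures, toy_family.alignment,
                                 toy_family.annotation, pseudocount=eps)
            mins.append(min(prof.restraints[ch].min() for ch in PAIR_CHANNELS))
        assert all(a <= b + 1e-12 for a, b in zip(mins, mins[1:]))

    def test_counts_match_naive_recount(self, toy_family):
        prof = build_profile(toy_family.structures, toy_family.alignment,
                             toy_family.annotation, pseudocount=0.0)
        counts, support = recount_profile(
            toy_family.structures, toy_family.alignment,
            toy_family.annotation, prof.bin_spec,
        )
        rows = prof.pair_rows()
        for (a, b), per_channel in counts.items():
            r = rows[(a, b)]
            assert prof.support[r] == support[(a, b)]
            for ch in PAIR_CHANNELS:
                n = support[(a, b)]
                if n == 0:
                    continue
                assert np.allclose(
                    prof.restraints[ch][r],
                    np.array(per_channel[ch], dtype=float) / n,
                )

    def test_member_beats_random_structure_cross_entropy(self, toy_family):
        """The pooled member's own geometry is more consistent with the
        profile than an unrelated random-torsion structure."""
        prof = build_profile(toy_family.structures, toy_family.alignment,
                             toy_family.annotation)
        spec = prof.bin_spec

        def cross_entropy(structure, member_map):
            bins = bin_geometry(compute_geometry(structure, spec), spec)
            total = 0.0
            for r, (a, b) in enumerate(prof.pairs):
                i, j = member_map[int(a)], member_map[int(b)]
                for ch in PAIR_CHANNELS:
                    total += -np.log(
                        max(prof.restraints[ch][r][bins[ch][i, j]], 1e-8)
                    )
            return total

        member = toy_family.structures[0]
        cmap = toy_family.annotation.member_maps[0]
        rng = np.random.default_rng(7)
        torsions = [
            (float(rng.uniform(-180, 180)), float(rng.uniform(-180, 180)), 180.0)
            for _ in range(len(member))
        ]
        random_struct = build_backbone_from_torsions(torsions)
        assert cross_entropy(member, cmap) <= cross_entropy(random_struct, cmap)


class TestProfileIO:
    def test_roundtrip(self, toy_family, tmp_path):
        prof = build_profile(toy_family.structures, toy_family.alignment,
                             toy_family.annotation)
        path = tmp_path / "prof.json"
        save_profile(prof, path)
        loaded = load_profile(path)
        for ch in PAIR_CHANNELS:
            assert np.allclose(loaded.restraints[ch], prof.restraints[ch],
                               atol=1e-12)
        assert np.array_equal(loaded.pairs, prof.pairs)
        assert np.array_equal(loaded.support, prof.support)

    def test_wrong_bin_count_is_corrupt(self, toy_family, tmp_path):
        import json

        prof = build_profile(toy_family.structures, toy_family.alignment,
                             toy_family.annotation)
        path = tmp_path / "prof.json"
        save_profile(prof, path)
        doc = json.loads(path.read_text())
        doc["restraints"]["d"] = [row[:-1] for row in doc["restraints"]["d"]]
        path.write_text(json.dumps(doc))
        with pytest.raises(ProfileFormatError):
            load_profile(path)

    def test_version_mismatch(self, toy_family, tmp_path):
        import json

        prof = build_profile(toy_family.structures, toy_family.alignment,
                             toy_family.annotation)
        path = tmp_path / "prof.json"
        save_profile(prof, path)
        doc = json.loads(path.read_text())
        doc["version"] = 0
        path.write_text(json.dumps(doc))
        with pytest.raises(ProfileVersionError):
            load_profile(path)


def test_build_mapping_layout(toy_family):
    ann = toy_family.annotation
    mapping = build_mapping(ann, [3])
    # conserved positions strictly increasing with columns
    cols = sorted(mapping.conserved)
    positions = [mapping.conserved[c] for c in cols]
    assert positions == sorted(positions)
    assert mapping.length == ann.n_conserved + 3
    assert len(mapping.variable_positions) == 3
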