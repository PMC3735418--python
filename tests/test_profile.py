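import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import seqevolve as sv
from seqevolve.errors import ConsistencyError, DegenerateInputError
from seqevolve.profile import (CLASS_NAMES, Alignment, background_profile,
                               tm_d0)
from seqevolve.structio import AMINO_ACIDS


class TestClassMap:
    def test_default_partition(self):
        cm = sv.ClassMap()
        assert cm.class_of("H") == "histidine"
        assert cm.class_of("D") == cm.class_of("E") == "negative"
        assert cm.class_of("K") == cm.class_of("R") == "positive"
        assert {cm.class_of(a) for a in "FWY"} == {"aromatic"}
        assert {cm.class_of(a) for a in AMINO_ACIDS} == set(CLASS_NAMES)

    def test_background_sums_to_one(self):
        bg = sv.ClassMap().class_background(sv.default_frequency_table())
        assert bg.shape == (7,)
        assert abs(bg.sum() - 1.0) < 1e-9

    def test_histidine_must_be_alone(self):
        mapping = sv.ClassMap().mapping.copy()
        mapping["H"] = "positive"
        with pytest.raises(ValueError):
            sv.ClassMap(mapping=mapping)


class TestSuperpose:
    def test_identity(self):
        pts = np.random.default_rng(0).normal(size=(10, 3))
        r, t, rmsd = sv.superpose(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(r, np.eye(3), atol=1e-9)

    def test_recovers_pure_rotation(self):
        pts = np.random.default_rng(1).normal(size=(20, 3))
        rot = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        moved = pts @ rot.T
        r, t, rmsd = sv.superpose(pts, moved)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(moved @ r.T + t, pts, atol=1e-9)
        assert np.linalg.det(r) == pytest.approx(1.0)

    def test_matches_scipy_on_noisy_data(self):
        rng = np.random.default_rng(2)
        rmsds = []
        for _ in range(100):
            a = rng.normal(size=(50, 3)) * 5
            b = a + rng.normal(scale=0.5, size=(50, 3))
            r, t, rmsd = sv.superpose(a, b)
            rot, rssd = Rotation.align_vectors(a - a.mean(0), b - b.mean(0))
            assert rmsd == pytest.approx(rssd / np.sqrt(50), abs=1e-6)
            rmsds.append(rmsd)
        # per-axis noise 0.5 A -> expected rmsd between sqrt(2)*0.5 and
        # sqrt(3)*0.5 after removing the 6 rigid degrees of freedom
        assert 0.5 * np.sqrt(2) * 0.8 < np.mean(rmsds) < 0.5 * np.sqrt(3)

    def test_too_few_points(self):
        with pytest.raises(DegenerateInputError):
            sv.superpose(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear_points(self):
        line = np.array([[float(i), 0, 0] for i in range(5)])
        with pytest.raises(DegenerateInputError):
            sv.superpose(line, line)


class TestTMScore:
    def test_self_alignment_is_one(self, helix60):
        structure, _ = helix60
        ca = structure.ca_coords()
        pairs = [(i, i) for i in range(60)]
        assert sv.tm_score(pairs, ca, ca, 60) == pytest.approx(1.0, abs=1e-9)

    def test_all_distances_at_d0_score_half_per_residue(self):
        from seqevolve.profile import _tm_sum

        # every aligned pair exactly at d0 contributes 1/(1+1) = 1/2
        for n, L in [(10, 10), (40, 60)]:
            d = np.full(n, tm_d0(L))
            assert _tm_sum(d, tm_d0(L)) / L == pytest.approx(0.5 * n / L)
        # a rigid-mode-orthogonal all-at-d0 displacement field: the search
        # must score at least the identity superposition's 0.5, and may
        # exceed it by fitting subsets
        theta = np.linspace(0, 2 * np.pi, 20, endpoint=False)
        a = np.stack([50 * np.cos(theta), 50 * np.sin(theta),
                      np.zeros(20)], axis=1)
        d0 = tm_d0(20)
        b = a.copy()
        b[:, 2] = d0 * (-1.0) ** np.arange(20)
        score = sv.tm_score([(i, i) for i in range(20)], a, b, 20)
        assert score >= 0.5 - 1e-9

    def test_jittered_helix_scores_high(self):
        structure, _ = sv.make_helix(60, seed=4)
        jit = sv.jitter_structure(structure, 0.3, sv.make_rng(5))
        pairs = [(i, i) for i in range(60)]
        score = sv.tm_score(pairs, structure.ca_coords(), jit.ca_coords(), 60)
        assert score > 0.9

    def test_rigid_motion_invariance(self, helix60):
        structure, _ = helix60
        ca = structure.ca_coords()
        jit = sv.jitter_structure(structure, 0.3, sv.make_rng(6)).ca_coords()
        pairs = [(i, i) for i in range(60)]
        base = sv.tm_score(pairs, ca, jit, 60)
        rot = Rotation.from_euler("xyz", [31, -57, 113],
                                  degrees=True).as_matrix()
        moved = jit @ rot.T + np.array([10.0, -30.0, 5.0])
        assert sv.tm_score(pairs, ca, moved, 60) == pytest.approx(base,
                                                                  abs=1e-6)


class TestAligner:
    def test_self_alignment(self, helix60):
        structure, _ = helix60
        aln = sv.align_structures(structure, structure)
        assert aln.tm_score == pytest.approx(1.0, abs=1e-6)
        assert len(aln.pairs) == 60
        assert aln.rmsd == pytest.approx(0.0, abs=1e-9)

    def test_disjoint_topologies_below_significance(self):
        helix, _ = sv.make_helix(26, seed=1)
        sheet, _ = sv.make_sheet_pair(12, seed=1)  # also 26 residues
        aln = sv.align_structures(helix, sheet)
        assert aln.tm_score < 0.4

    def test_jittered_copy_recovered(self):
        original, _ = sv.make_helix(50, seed=9)
        jit = sv.jitter_structure(original, 0.3, sv.make_rng(10))
        aln = sv.align_structures(original, jit)
        assert aln.tm_score > 0.9
        assert len(aln.pairs) >= 45
        matched = sum(i == j for i, j in aln.pairs)
        assert matched >= 45

    def test_both_normalizations_reported(self):
        target, _ = sv.make_helix(30, seed=2)
        analog, _ = sv.make_helix(60, seed=2)
        aln = sv.align_structures(target, analog)
        assert aln.tm_score > aln.tm_by_analog  # shorter norm gives more
        assert 0 < aln.tm_by_analog <= 1

    def test_alignment_pairs_strictly_increasing(self):
        with pytest.raises(ConsistencyError):
            Alignment(pairs=[(0, 1), (1, 1)], tm_score=0.5, rmsd=1.0)


class TestBuildProfile:
    def _fake_alignment(self, length, tm):
        return Alignment(pairs=[(i, i) for i in range(length)],
                         tm_score=tm, rmsd=1.0)

    def test_threshold_is_inclusive_at_04(self, helix60):
        structure, _ = helix60
        analog = sv.make_helix(60, seed=8)
        library = [(analog[0], "D" * 60), (analog[0], "K" * 60),
                   (analog[0], "W" * 60)]
        alignments = [self._fake_alignment(60, 0.5),
                      self._fake_alignment(60, 0.39),
                      self._fake_alignment(60, 0.4)]
        profile = sv.build_profile(structure, library,
                                   alignments=alignments)
        cm = sv.ClassMap()
        neg, pos, aro = (cm._index["negative"], cm._index["positive"],
                         cm._index["aromatic"])
        counts = profile.n_contributors
        assert counts[0] == 2  # the 0.39 analog is excluded
        assert profile.freqs[0, neg] > 0 and profile.freqs[0, aro] > 0
        assert profile.freqs[0, pos] == pytest.approx(
            0.5 / (2 + 0.5 * 7))  # pseudocount only

    def test_all_asp_analog_dominates_negative_class(self, helix60):
        structure, _ = helix60
        library = [(structure, "D" * 60)]
        alignments = [self._fake_alignment(60, 1.0)]
        profile = sv.build_profile(structure, library, alignments=alignments)
        neg = sv.ClassMap()._index["negative"]
        assert np.all(np.argmax(profile.freqs, axis=1) == neg)

    def test_counts_match_brute_force_tally(self, helix60):
        structure, native = helix60
        library = sv.make_homologs(structure, native, 10, seed=21)
        alignments = [sv.align_structures(structure, st)
                      for st, _ in library]
        profile = sv.build_profile(structure, library, alignments=alignments)
        assert np.allclose(profile.freqs.sum(axis=1), 1.0, atol=1e-9)
        cm = sv.ClassMap()
        counts = np.zeros((60, 7))
        for (st, seq), aln in zip(library, alignments):
            if aln.tm_score >= 0.4:
                for i, j in aln.pairs:
                    counts[i, cm.index_of(seq[j])] += 1
        expect = (counts + 0.5) / (counts.sum(1, keepdims=True) + 3.5)
        assert np.allclose(profile.freqs, expect, atol=1e-12)

    def test_no_analog_passing_gives_background(self, helix60, caplog):
        structure, _ = helix60
        sheet = sv.make_sheet_pair(29, seed=1)  # 60 residues, wrong fold
        profile = sv.build_profile(structure, [sheet])
        assert np.allclose(profile.freqs, profile.freqs[0], atol=1e-12)
        assert profile.n_contributors.sum() == 0

    def test_empty_library_rejected(self, helix60):
        with pytest.raises(DegenerateInputError):
            sv.build_profile(helix60[0], [])


class TestEvaluateProfile:
    def test_background_profile_scores_zero(self):
        bg = sv.ClassMap().class_background(sv.default_frequency_table())
        profile = background_profile(25, bg)
        rng = sv.make_rng(3)
        for _ in range(5):
            seq = sv.random_sequence(25, sv.default_frequency_table(), rng)
            assert sv.evaluate_profile(seq, profile) == pytest.approx(0.0,
                                                                      abs=1e-9)

    def test_single_position_closed_form(self):
        cm = sv.ClassMap()
        bg = np.full(7, 1 / 7)
        row = np.full(7, (1 - 2 / 7) / 6)
        neg = cm._index["negative"]
        row[neg] = 2 / 7  # twice the background
        profile = sv.Profile(freqs=row[None, :],
                             n_contributors=np.array([10]), background=bg)
        assert sv.evaluate_profile("D", profile) == pytest.approx(np.log(2))

    def test_native_like_beats_random_on_homolog_profile(self, helix60):
        structure, native = helix60
        library = sv.make_homologs(structure, native, 8, seed=31,
                                   mutation_rate=0.2)
        profile = sv.build_profile(structure, library)
        rng = sv.make_rng(32)
        table = sv.default_frequency_table()
        native_score = sv.evaluate_profile(native, profile)
        random_scores = [
            sv.evaluate_profile(sv.random_sequence(60, table, rng), profile)
            for _ in range(100)]
        assert native_score > max(random_scores)

    def test_length_mismatch(self):
        bg = sv.ClassMap().class_background(sv.default_frequency_table())
        with pytest.raises(ConsistencyError):
            sv.evaluate_profile("ACD", background_profile(5, bg))
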