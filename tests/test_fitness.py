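import numpy as np
import pytest
from hypothesis import given, strategies as st

import seqevolve as sv
from seqevolve.errors import CalibrationError
from seqevolve.fitness import TERMS, optimize_weights
from seqevolve.profile import background_profile


@pytest.fixture()
def model_copy(helix60, library10):
    structure, _ = helix60
    model = sv.build_energy_model(structure, library10)
    model.normalizers = sv.calibrate_normalizers(
        structure, model, n_random=100, rng=sv.make_rng(1))
    return model


class TestNormalizers:
    def test_degenerate_term_raises(self, helix60, model_copy):
        structure, _ = helix60
        bg = model_copy.class_map.class_background(model_copy.freq_table)
        model_copy.profile = background_profile(60, bg)  # profile term == 0
        model_copy.normalizers = None
        with pytest.raises(CalibrationError):
            sv.calibrate_normalizers(structure, model_copy, n_random=40,
                                     rng=sv.make_rng(3))

    def test_fresh_random_sequences_center_at_zero(self, helix60, model60,
                                                   ctx60):
        structure, _ = helix60
        rng = sv.make_rng(10)
        n = 150
        zs = {t: [] for t in TERMS}
        for _ in range(n):
            seq = sv.random_sequence(60, model60.freq_table, rng)
            raws = sv.raw_terms(seq, structure, model60, ctx60)
            for t in TERMS:
                zs[t].append(model60.normalizers[t].normalize(raws[t]))
        for t in TERMS:
            assert abs(np.mean(zs[t])) < 3 / np.sqrt(n)

    def test_identical_seed_identical_calibration(self, helix60, model60):
        structure, _ = helix60
        a = sv.calibrate_normalizers(structure, model60, n_random=40,
                                     rng=sv.make_rng(5))
        b = sv.calibrate_normalizers(structure, model60, n_random=40,
                                     rng=sv.make_rng(5))
        for t in TERMS:
            assert a[t].mu == b[t].mu and a[t].sigma == b[t].sigma

    def test_minimum_sample_size_enforced(self, helix60, model60):
        with pytest.raises(CalibrationError):
            sv.calibrate_normalizers(helix60[0], model60, n_random=10)


class TestFitness:
    def test_random_sequences_fluctuate_around_one(self, helix60, model60,
                                                   ctx60):
        structure, _ = helix60
        rng = sv.make_rng(2)
        scores = [sv.fitness(sv.random_sequence(60, model60.freq_table, rng),
                             structure, model60, ctx60)
                  for _ in range(200)]
        assert np.mean(scores) == pytest.approx(1.0, abs=0.1)

    def test_sequence_at_term_mean_scores_one(self, helix60, model_copy):
        structure, native = helix60
        raws = sv.raw_terms(native, structure, model_copy)
        model_copy.weights = np.array([0, 0, 0, 0, 1.0, 0])
        model_copy.normalizers["profile"] = sv.TermNormalizer(
            mu=raws["profile"], sigma=1.0, orientation=1.0)
        assert sv.fitness(native, structure, model_copy) == pytest.approx(1.0)

    def test_uncalibrated_model_rejected(self, helix60, library10):
        structure, _ = helix60
        model = sv.build_energy_model(structure, library10)
        with pytest.raises(CalibrationError):
            sv.fitness("A" * 60, structure, model)

    def test_constant_shift_of_raw_term_absorbed(self, helix60, library10):
        """Adding a constant to any raw table leaves fitness unchanged."""
        structure, native = helix60
        scores = []
        for shift in (0.0, 5.0):
            model = sv.build_energy_model(structure, library10)
            model.burial.table = model.burial.table + shift
            model.normalizers = sv.calibrate_normalizers(
                structure, model, n_random=50, rng=sv.make_rng(4))
            scores.append(sv.fitness(native, structure, model))
        assert scores[0] == pytest.approx(scores[1], abs=1e-9)

    def test_native_beats_shuffle_on_most_fixtures(self):
        """Natives are built term-favorable; the full model must see it."""
        shared = sv.make_library(12, 3)
        rng = sv.make_rng(4)
        wins, n_cases = 0, 30
        for k in range(n_cases):
            if k % 2 == 0:
                structure, native = sv.make_helix(30, 100 + k)
            else:
                structure, native = sv.make_sheet_pair(12, 100 + k)
            homologs = sv.make_homologs(structure, native, 6, 200 + k)
            model = sv.build_energy_model(structure, shared + homologs,
                                          fit_length=False)
            model.normalizers = sv.calibrate_normalizers(
                structure, model, n_random=60, rng=sv.make_rng(300 + k))
            ctx = sv.StructureContext(structure, model)
            f_native = sv.fitness(native, structure, model, ctx)
            f_shuffle = sv.fitness(sv.shuffle_sequence(native, rng),
                                   structure, model, ctx)
            wins += f_native > f_shuffle
        assert wins >= 0.8 * n_cases


class TestIncremental:
    @given(pos=st.integers(0, 59), new_aa=st.integers(0, 19),
           seed=st.integers(0, 2**20))
    def test_single_mutation_matches_full_evaluation(self, helix60, model60,
                                                     ctx60, pos, new_aa,
                                                     seed):
        structure, _ = helix60
        seq = sv.random_sequence(60, model60.freq_table, sv.make_rng(seed))
        state = sv.FitnessState(seq, structure, model60, ctx60)
        before = state.fitness
        delta = state.delta_fitness(pos, new_aa)
        state.apply(pos, new_aa)
        mutated = state.sequence
        full = sv.fitness(mutated, structure, model60, ctx60)
        assert state.fitness == pytest.approx(full, abs=1e-9)
        assert before + delta == pytest.approx(full, abs=1e-9)

    def test_drift_stays_tiny_over_many_mutations(self, helix60, model60,
                                                  ctx60):
        structure, _ = helix60
        rng = sv.make_rng(8)
        seq = sv.random_sequence(60, model60.freq_table, rng)
        state = sv.FitnessState(seq, structure, model60, ctx60)
        for _ in range(300):
            pos = int(rng.integers(60))
            new = int(rng.integers(20))
            state.apply(pos, new)
        full = sv.fitness(state.sequence, structure, model60, ctx60)
        assert state.fitness == pytest.approx(full, abs=1e-9)

    def test_raw_term_additivity(self, helix60, model60, ctx60):
        """Raw terms decompose into per-position / per-pair contributions."""
        structure, _ = helix60
        seq = sv.random_sequence(60, model60.freq_table, sv.make_rng(12))
        raws = sv.raw_terms(seq, structure, model60, ctx60)
        # burial: position-wise oracle
        states = sv.burial_states(structure, model60.burial)
        burial = sum(model60.burial.table[s, sv.structio.AA_INDEX[a]]
                     for s, a in zip(states, seq))
        assert raws["burial"] == pytest.approx(burial, abs=1e-9)
        # contact CA: pair-wise oracle
        ii, jj, bins = sv.potentials.contact_pairs(structure,
                                                   model60.contact_ca)
        aa = [sv.structio.AA_INDEX[a] for a in seq]
        contact = sum(model60.contact_ca.energies[aa[i], aa[j], b]
                      for i, j, b in zip(ii, jj, bins))
        contact -= ctx60.offsets["contact_ca"]
        assert raws["contact_ca"] == pytest.approx(contact, abs=1e-9)


class TestWeights:
    def _synthetic_cases(self, separating_term, n_cases=6, n_decoys=20):
        rng = np.random.default_rng(0)
        cases = []
        for _ in range(n_cases):
            zn = rng.normal(size=6)
            zd = rng.normal(size=(n_decoys, 6))
            zn[separating_term] = 4.0 + rng.normal(scale=0.2)
            zd[:, separating_term] = rng.normal(scale=1.0, size=n_decoys)
            cases.append((zn, zd))
        return cases

    def test_perfectly_separating_term_dominates(self):
        w = optimize_weights(self._synthetic_cases(separating_term=2))
        assert w[2] > 0.8
        assert w.sum() == pytest.approx(1.0, abs=1e-9)
        assert (w >= 0).all()

    def test_identical_terms_give_uniform(self, caplog):
        rng = np.random.default_rng(1)
        cases = []
        for _ in range(5):
            zn = np.full(6, rng.normal())
            zd = np.tile(rng.normal(size=(15, 1)), (1, 6))
            cases.append((zn, zd))
        w = optimize_weights(cases)
        assert np.allclose(w, 1 / 6)

    def test_case_order_irrelevant(self):
        cases = self._synthetic_cases(separating_term=4)
        a = optimize_weights(cases)
        b = optimize_weights(list(reversed(cases)))
        assert np.array_equal(a, b)

    def test_full_calibration_path(self, helix60, library10, model_copy):
        structure, native = helix60
        rng = sv.make_rng(6)
        cases = []
        for k in range(5):
            decoys = [sv.shuffle_sequence(native, rng) for _ in range(5)]
            decoys += [sv.random_sequence(60, model_copy.freq_table, rng)
                       for _ in range(5)]
            cases.append((model_copy, structure, native, decoys))
        w = sv.calibrate_weights(cases)
        assert w.shape == (6,)
        assert w.sum() == pytest.approx(1.0, abs=1e-9)
        assert (w >= 0).all()

    def test_too_few_cases_rejected(self, helix60, model_copy):
        with pytest.raises(CalibrationError):
            sv.calibrate_weights([(model_copy, helix60[0], helix60[1],
                                   ["A" * 60] * 10)] * 3)


class TestSerialization:
    def test_model_roundtrip_preserves_fitness(self, helix60, model60,
                                               tmp_path):
        structure, native = helix60
        path = tmp_path / "model.tsv"
        sv.save_model(model60, path)
        loaded = sv.load_model(path)
        rng = sv.make_rng(7)
        for _ in range(5):
            seq = sv.random_sequence(60, model60.freq_table, rng)
            assert sv.fitness(seq, structure, loaded) == pytest.approx(
                sv.fitness(seq, structure, model60), abs=1e-12)

    def test_version_header_checked(self, tmp_path):
        bad = tmp_path / "bad.tsv"
        bad.write_text("not a model\n")
        with pytest.raises(sv.ConsistencyError):
            sv.load_model(bad)
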