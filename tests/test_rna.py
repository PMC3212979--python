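"""RNA folding: MFE, partition function, entropy, centroid, hairpin
morphology — checked against exhaustive structure enumeration."""

import math

import numpy as np
import pytest

from _oracles import brute_force_partition
from satmir import rna


def _random_rna(rng, n):
    return "".join("ACGU"[i] for i in rng.integers(0, 4, n))


class TestMfe:
    def test_unpairable_sequence_stays_open(self):
        st, e = rna.mfe_fold("AAAAAAAAAA")
        assert st.dotbracket == "." * 10 and e == 0.0

    def test_perfect_stem(self):
        st, e = rna.mfe_fold("GGGGGAAAACCCCC")
        pairs = set(st.pairs)
        assert (0, 13) in pairs and (4, 9) in pairs and len(pairs) == 5
        assert e < 0

    @pytest.mark.parametrize("n", [8, 10, 12, 14, 16])
    def test_mfe_matches_enumeration(self, n):
        rng = np.random.default_rng(100 + n)
        for _ in range(5):
            seq = _random_rna(rng, n)
            _lz, _pp, _up, emin = brute_force_partition(seq)
            _st, e = rna.mfe_fold(seq)
            assert abs(e - emin) < 1e-6

    def test_short_sequence_no_structure(self):
        st, e = rna.mfe_fold("ACGU")
        assert st.dotbracket == "...." and e == 0.0


class TestPartition:
    def test_open_chain_only(self):
        logZ, bp = rna.partition("AAAA")
        assert logZ == 0.0
        assert np.allclose(bp.q, 1.0)

    def test_matches_enumeration_small(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            n = int(rng.integers(8, 13))
            seq = _random_rna(rng, n)
            logZo, ppo, upo, _e = brute_force_partition(seq)
            logZ, bp = rna.partition(seq)
            assert abs(logZ - logZo) <= 1e-8 * max(1.0, abs(logZo)) + 1e-9
            for (i, j), p in ppo.items():
                assert abs(bp.P[i, j] - p) < 1e-8
            for i in range(n):
                assert abs(bp.q[i] - upo[i]) < 1e-8

    def test_mfe_weight_bounded_by_Z(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            seq = _random_rna(rng, 30)
            logZ, _bp = rna.partition(seq)
            _st, e = rna.mfe_fold(seq)
            RT = 0.0019872 * rna.TEMPERATURE
            assert -e / RT <= logZ + 1e-9

    def test_normalization_and_symmetry(self):
        rng = np.random.default_rng(3)
        for n in (20, 60, 120):
            seq = _random_rna(rng, n)
            _z, bp = rna.partition(seq)
            assert np.allclose(bp.P, bp.P.T, atol=1e-12)
            assert ((bp.P >= -1e-12) & (bp.P <= 1 + 1e-12)).all()
            # q is defined as the complement of the pairing probability mass
            assert np.allclose(bp.q + bp.P.sum(axis=1), 1.0, atol=1e-9)

    def test_long_sequence_no_overflow(self):
        rng = np.random.default_rng(5)
        seq = _random_rna(rng, 400)
        logZ, bp = rna.partition(seq)
        assert np.isfinite(logZ) and np.isfinite(bp.P).all()

    def test_entropy_increases_with_temperature(self):
        seq = "GGGGGGGGAAAACCCCCCCC" + "AUAUAUGCGC"
        means = []
        for T in (290.15, 310.15, 330.15, 350.15):
            _z, bp = rna.partition(seq, temperature=T)
            means.append(rna.positional_entropy(bp).S.mean())
        assert all(b >= a - 1e-12 for a, b in zip(means, means[1:]))


class TestEntropyCentroid:
    def test_certain_positions_have_zero_entropy(self):
        _z, bp = rna.partition("AAAA")
        S = rna.positional_entropy(bp).S
        assert np.allclose(S, 0.0)

    def test_two_state_position_closed_form(self):
        P = np.zeros((3, 3))
        P[0, 1] = P[1, 0] = 0.5
        P[0, 2] = P[2, 0] = 0.5
        q = 1.0 - P.sum(axis=1)
        S = rna.positional_entropy(rna.BasePairMatrix(P, q)).S
        assert abs(S[0] - math.log(2)) < 1e-12

    def test_centroid_contains_exactly_majority_pairs(self):
        rng = np.random.default_rng(19)
        seq = "GGGGGGGGGGAAAACCCCCCCCCC"
        _z, bp = rna.partition(seq)
        cent = rna.centroid(bp)
        assert set(cent.pairs) == {
            (i, j) for i in range(len(seq)) for j in range(i + 1, len(seq))
            if bp.P[i, j] > 0.5
        }
        # strong stem: all stem pairs near-certain
        stem_ps = [bp.P[i, j] for (i, j) in cent.pairs]
        assert min(stem_ps) > 0.9

    def test_empty_centroid_for_unpaired_ensemble(self):
        _z, bp = rna.partition("AAAAAA")
        assert rna.centroid(bp).pairs == ()


class TestHairpinFeatures:
    def test_clean_hairpin(self):
        st = rna.SecondaryStructure("((((....))))",
                                    ((0, 11), (1, 10), (2, 9), (3, 8)))
        f = rna.hairpin_features(st, (0, 12))
        assert (f.stem_length, f.loop_length) == (4, 4)
        assert f.n_symmetric_bulges == 0 and f.n_asymmetric_bulges == 0
        assert f.left_arm_nt == f.right_arm_nt == 4

    def test_asymmetric_bulge_detected_and_arm_balance(self):
        # ((.((....)))) : 1-nt bulge on the left side
        pairs = ((0, 12), (1, 11), (3, 10), (4, 9))
        st = rna.SecondaryStructure("((.((....))))", pairs)
        f = rna.hairpin_features(st, (0, 13))
        assert f.n_asymmetric_bulges == 1
        assert f.left_arm_nt - f.right_arm_nt == 1

    def test_ambiguous_region_raises(self):
        st = rna.SecondaryStructure("((...))((...))",
                                    ((0, 6), (1, 5), (7, 13), (8, 12)))
        with pytest.raises(rna.AmbiguousHairpinError):
            rna.hairpin_features(st, (0, 14))


class TestMasterUnits:
    """The designed mouse unit folds into a perfect 41-bp stem; the rat
    derivation shifts the register and creates asymmetric bulges."""

    def test_mouse_master_hairpin(self, mouse_master):
        st, _e = rna.mfe_fold(mouse_master.sequence)
        f = rna.hairpin_features(st, mouse_master.hairpin_region)
        assert f.stem_length == 41
        assert f.n_asymmetric_bulges == 0
        assert f.left_arm_nt == f.right_arm_nt == 41

    def test_mouse_master_is_premirna_like(self, mouse_master):
        st, _e = rna.mfe_fold(mouse_master.sequence)
        f = rna.hairpin_features(st, mouse_master.hairpin_region)
        _z, bp = rna.partition(mouse_master.sequence)
        ok, _reasons = rna.is_premirna_like(f, rna.positional_entropy(bp))
        assert ok

    def test_rat_master_fails_with_bulge_and_flank_reasons(self, rat_master):
        st, _e = rna.mfe_fold(rat_master.sequence)
        f = rna.hairpin_features(st, rat_master.hairpin_region)
        _z, bp = rna.partition(rat_master.sequence)
        ok, reasons = rna.is_premirna_like(f, rna.positional_entropy(bp))
        assert not ok
        assert not reasons["asymmetric_bulges"][0]
        assert not reasons["flank5"][0]

    def test_rat_arm_imbalance_and_pairing_shift(self, mouse_master, rat_master):
        st_m, _ = rna.mfe_fold(mouse_master.sequence)
        st_r, _ = rna.mfe_fold(rat_master.sequence)
        f_r = rna.hairpin_features(st_r, rat_master.hairpin_region)
        assert f_r.left_arm_nt - f_r.right_arm_nt == 4
        assert f_r.n_asymmetric_bulges >= 1
        # pairing register shift at the probe position (left-arm offset 20)
        rd = __import__("satmir.synth", fromlist=["DEFAULT_RAT_DERIVATION"])
        shift = _register_shift(mouse_master, rat_master, st_m, st_r)
        assert 6 <= shift <= 14

    def test_rat_hairpin_less_committed_than_mouse(self, mouse_master, rat_master):
        ratios = {}
        for name, master in (("mouse", mouse_master), ("rat", rat_master)):
            _z, bp = rna.partition(master.sequence)
            S = rna.positional_entropy(bp).S
            a, b = master.hairpin_region
            flank = np.concatenate([S[:a], S[b:]])
            ratios[name] = S[a:b].mean() / flank.mean()
        assert ratios["mouse"] < ratios["rat"]


def _register_shift(mouse_master, rat_master, st_m, st_r):
    """Partner shift (in mouse coordinates) at a mid-arm probe position."""
    from satmir.synth import DEFAULT_RAT_DERIVATION as rd

    ra0 = mouse_master.hairpin_design.right_arm[0]
    deleted = sorted(d for off in rd.deletions for d in (ra0 + off, ra0 + off + 1))

    def rat_of_mouse(m):
        if m in deleted:
            return None
        r = m - rd.trim5
        return r - sum(1 for d in deleted if d < m)

    def mouse_of_rat(r):
        m = r + rd.trim5
        for d in deleted:
            if d <= m:
                m += 1
        return m

    pm = st_m.partner_array()
    pr = st_r.partner_array()
    probe = mouse_master.hairpin_design.left_arm[0] + 20
    rp = rat_of_mouse(probe)
    assert rp is not None and pm[probe] >= 0 and pr[rp] >= 0
    return mouse_of_rat(pr[rp]) - pm[probe]
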