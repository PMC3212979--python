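"""Synthetic cluster generator: master units, mutation process, cluster
assembly, ground truth and round-trip I/O."""

import numpy as np
import pytest

from satmir import synth
from satmir._util import revcomp


class TestMouseMaster:
    def test_default_layout(self, mouse_master):
        assert len(mouse_master.sequence) == 296
        label, iv = mouse_master.segments[0]
        assert label == "b1f3_fragment" and iv == (0, 75)

    def test_segments_tile_sequence(self, mouse_master):
        pos = 0
        for _label, (s, e) in mouse_master.segments:
            assert s == pos
            pos = e
        assert pos == len(mouse_master.sequence)

    def test_msat_arms_are_reverse_complementary(self, mouse_master):
        la = mouse_master.segment("msat_left")
        ra = mouse_master.segment("msat_right")
        left = mouse_master.sequence[la[0]: la[1]]
        right = mouse_master.sequence[ra[0]: ra[1]]
        assert right == revcomp(left)
        assert set(left) == {"A", "C"}

    def test_minimal_design_folds_designed_stem(self):
        from satmir import rna

        d = synth.MasterUnitDesign(b1f3_len=75, spacer_len=0, arm_len=5,
                                   loop_seq="AACAA", tail_len=0, total_len=None)
        m = synth.build_mouse_master(d, seed=1)
        assert len(m.sequence) == 75 + 5 + 5 + 5
        st, _e = rna.mfe_fold(m.sequence[75:])
        f = rna.hairpin_features(st, (0, 15))
        assert f.stem_length == 5

    def test_seed_changes_random_segments_not_msats(self):
        m1 = synth.build_mouse_master(seed=1)
        m2 = synth.build_mouse_master(seed=2)
        assert [s for s, _ in m1.segments] == [s for s, _ in m2.segments]
        la = m1.segment("msat_left")
        assert (m1.sequence[la[0]: la[1]] == m2.sequence[la[0]: la[1]])
        assert m1.sequence != m2.sequence

    def test_inconsistent_design_rejected(self):
        with pytest.raises(synth.ConfigurationError):
            synth.MasterUnitDesign(b1f3_len=75, total_len=200)

    def test_bad_loop_rejected(self):
        with pytest.raises(synth.ConfigurationError):
            synth.MasterUnitDesign(loop_seq="AA", total_len=None)


class TestRatMaster:
    def test_default_length_197(self, rat_master):
        assert len(rat_master.sequence) == 197

    def test_hairpin_region_83nt_with_short_5prime_flank(self, rat_master):
        a, b = rat_master.hairpin_region
        assert b - a == 83
        assert a < 20  # the rat unit lost its 5' flanking sequence

    def test_truncation_only_keeps_mouse_hairpin(self, mouse_master):
        from satmir import rna

        cfg = synth.RatDerivation(deletions=(), substitutions=((0, "A"),),
                                  n_random_subs=0, trim5=90, trim3=9)
        rat = synth.build_rat_master(mouse_master, cfg, seed=1)
        assert len(rat.sequence) == 197
        st, _e = rna.mfe_fold(rat.sequence)
        f = rna.hairpin_features(st, rat.hairpin_region)
        assert f.n_asymmetric_bulges == 0
        assert f.stem_length == 41

    def test_deletion_outside_arm_rejected(self, mouse_master):
        cfg = synth.RatDerivation(deletions=(40,))
        with pytest.raises(synth.ConfigurationError):
            synth.build_rat_master(mouse_master, cfg, seed=1)

    def test_alignment_to_mouse_shows_two_2nt_gaps_in_hairpin(
            self, mouse_master, rat_master):
        from satmir import scan as sc

        a = sc.smith_waterman(rat_master.sequence, mouse_master.sequence)
        # collect gap runs in the rat (query) inside the mouse hairpin region
        hp = mouse_master.hairpin_region
        runs = []
        cur = 0
        for qi, tj in a.aligned_pairs:
            if qi < 0 and tj >= 0 and hp[0] <= tj < hp[1]:
                cur += 1
            else:
                if cur:
                    runs.append(cur)
                cur = 0
        if cur:
            runs.append(cur)
        # 4 nt of rat-specific deletion inside the hairpin; the aligner may
        # place the two 2-nt events with some latitude inside the repeats
        assert sum(runs) == 4 and len(runs) <= 2


class TestMutate:
    def test_zero_rates_identity(self):
        rng = np.random.default_rng(0)
        s = "ACGTACGTACGT"
        assert synth.mutate(s, 0.0, 0.0, rng) == s

    def test_substitution_rate_monte_carlo(self):
        """Observed mismatch fraction tracks the nominal rate."""
        rng = np.random.default_rng(1)
        n = 10_000
        s = "".join("ACGT"[i] for i in rng.integers(0, 4, n))
        fracs = []
        for _ in range(30):
            m = synth.mutate(s, 0.05, 0.0, rng)
            fracs.append(np.mean([a != b for a, b in zip(s, m)]))
        assert abs(np.mean(fracs) - 0.05) < 0.01

    def test_full_substitution_leaves_no_base_in_place(self):
        rng = np.random.default_rng(2)
        s = "ACGT" * 50
        m = synth.mutate(s, 1.0, 0.0, rng)
        assert len(m) == len(s)
        assert all(a != b for a, b in zip(s, m))  # kernel excludes identity

    def test_non_acgt_rejected(self):
        with pytest.raises(ValueError):
            synth.mutate("ACGX", 0.1, 0.0, np.random.default_rng(0))

    def test_bad_rate_rejected(self):
        with pytest.raises(ValueError):
            synth.mutate("ACGT", 1.5, 0.0, np.random.default_rng(0))


class TestCluster:
    def test_copy_and_block_counts(self, mouse_cluster_default):
        cl = mouse_cluster_default
        assert len(cl.truth_copies) == 193
        assert len(cl.truth_blocks) == 13
        assert len(cl.truth_mirna_units) == 65

    def test_copy_count_conservation(self, mouse_cluster_default):
        cl = mouse_cluster_default
        cfg = cl.config
        assert len(cl.truth_copies) == (
            cfg.n_left_flank + cfg.n_right_flank
            + cfg.n_higher_order * cfg.units_per_block
            - len(cl.truth_degraded)
        )

    def test_copies_sorted_nonoverlapping_plus_strand(self, mouse_cluster_default):
        prev = -1
        for c in mouse_cluster_default.truth_copies:
            assert c.start >= prev
            assert c.strand == "+"
            prev = c.end

    def test_flanks_more_diverged_than_center(self, mouse_cluster_default):
        cl = mouse_cluster_default
        fl = [c.identity_to_master for c in cl.truth_copies
              if c.label.startswith("flank")]
        ce = [c.identity_to_master for c in cl.truth_copies
              if c.label.startswith("block")]
        assert np.mean(fl) < np.mean(ce)

    def test_positional_signal(self, mouse_cluster_default):
        """Same-position copies are closer than different-position copies."""
        from satmir import phylo

        cl = mouse_cluster_default
        rng = np.random.default_rng(0)
        by_pos = {}
        for c in cl.truth_copies:
            if c.label.startswith("block"):
                pos = c.label.split("/")[1]
                by_pos.setdefault(pos, []).append(
                    cl.sequence[c.start: c.end])
        same, diff = [], []
        poss = sorted(by_pos)
        from satmir import scan as sc

        def dist(a, b):
            aln = sc.smith_waterman(a, b)
            return 1 - aln.identity

        for p in poss[:3]:
            seqs = by_pos[p]
            same.append(dist(seqs[0], seqs[1]))
            other = poss[(poss.index(p) + 1) % len(poss)]
            diff.append(dist(seqs[0], by_pos[other][0]))
        assert np.mean(same) < np.mean(diff)

    def test_zero_rate_cluster_copies_identical(self):
        cfg = synth.EvolutionConfig(
            sub_rate_flank=0.0, sub_rate_within_block=1e-9,
            sub_rate_between_blocks=0.0, indel_rate=0.0,
            degrade_positions=(), n_corrupted=0,
            mirna_positions=tuple(range(1, 11)),
            n_compensatory_pairs=0,
            n_higher_order=3, units_per_block=4,
            n_left_flank=2, n_right_flank=2, seed=1,
        )
        master = synth.build_mouse_master(seed=1)
        cl = synth.simulate_cluster(master, None, cfg)
        central = [c for c in cl.truth_copies if c.label.startswith("block")]
        assert central
        for c in central:
            assert cl.sequence[c.start: c.end] == master.sequence
        # flank copies keep their length even though their hairpin decays
        for c in cl.truth_copies:
            assert c.end - c.start == len(master.sequence)

    def test_determinism(self):
        a = synth.mouse_cluster(seed=7)
        b = synth.mouse_cluster(seed=7)
        assert a.sequence == b.sequence
        assert a.truth_copies == b.truth_copies

    def test_invalid_rate_ordering_rejected(self):
        with pytest.raises(synth.ConfigurationError):
            synth.EvolutionConfig(sub_rate_within_block=0.02,
                                  sub_rate_between_blocks=0.05)

    def test_rat_cluster_composition(self, rat_cluster_default):
        cl = rat_cluster_default
        assert len(cl.truth_copies) == 236
        assert len(cl.truth_mirna_units) == 1
        intact = cl.truth_copies[cl.truth_mirna_units[0]]
        assert intact.label == "mouse_like"


class TestIO:
    def test_write_reload_roundtrip(self, mouse_cluster_default, tmp_path):
        cl = mouse_cluster_default
        paths = synth.write_cluster(cl, tmp_path / "mouse")
        from satmir._util import read_fasta

        recs = read_fasta(paths["fasta"])
        assert recs[0][1] == cl.sequence
        # GFF3 uses 1-based inclusive coordinates
        first = cl.truth_copies[0]
        with open(paths["gff3"]) as fh:
            for line in fh:
                if "\trepeat_copy\t" in line:
                    f = line.split("\t")
                    assert int(f[3]) == first.start + 1
                    assert int(f[4]) == first.end
                    break

    def test_regenerate_from_record_bitwise(self, mouse_cluster_default, tmp_path):
        paths = synth.write_cluster(mouse_cluster_default, tmp_path / "m")
        again = synth.regenerate_cluster(paths["record"])
        assert again.sequence == mouse_cluster_default.sequence

    def test_rat_record_roundtrip(self, rat_cluster_default, tmp_path):
        paths = synth.write_cluster(rat_cluster_default, tmp_path / "r")
        again = synth.regenerate_cluster(paths["record"])
        assert again.sequence == rat_cluster_default.sequence
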