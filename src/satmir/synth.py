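"""Synthetic tandem-repeat miRNA cluster generator.

Generates mouse-style and rat-style repeat clusters with the statistical
structure assumed by the downstream decomposition pipeline, together with
ground truth for every copy, higher-order block and intact-hairpin unit.

The generative model is a dual-phase duplication process:

* phase 1 — an elementary ~0.3 kb master unit (a 3' SINE fragment, a pair of
  self-complementary (AC)n/(GT)n microsatellites forming a designed hairpin,
  and flanking sequence) is dispersed copy-by-copy into the cluster flanks,
  each copy diverging independently (gene-conversion-like accumulation);
* phase 2 — a block of ``units_per_block`` adjacent copies, each already
  carrying position-specific divergence, is fixed as a higher-order unit and
  tandemly duplicated ``n_higher_order`` times with much smaller per-duplicate
  divergence. The position-specific mutations therefore act as sub-cluster
  synapomorphies: copies occupying the same within-block position are closer
  to each other than to any other copy.

Degradation: all copies of one within-block position have decayed to a short
unrecognizable remnant (sequence loss + mutation beyond recognition), a few
central copies are corrupted below any reasonable detection threshold, and in
every copy that is not a designated miRNA unit a seeded tract of the hairpin
has decayed beyond pairing ability (an N tract). Designated miRNA units keep
a fully paired stem, varied only by position-specific compensatory pair
swaps.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

from ._util import check_acgt, decode, encode, random_dna, revcomp, write_fasta


class ConfigurationError(ValueError):
    """Inconsistent generator design or evolution configuration."""


# ---------------------------------------------------------------------------
# master units
# ---------------------------------------------------------------------------

#: length of the full SINE-like reference element (rodent B1 elements are
#: ~140 bp); the master unit carries its 3' fragment.
B1F3_FULL_LEN = 140


@dataclass(frozen=True)
class MasterUnitDesign:
    """Segment lengths of the elementary repeat unit (defaults: 296 nt)."""

    b1f3_len: int = 75
    spacer_len: int = 30
    arm_len: int = 41
    loop_seq: str = "AACAA"
    tail_len: int = 104
    msat_unit: str = "AC"
    total_len: int | None = 296

    def __post_init__(self):
        if self.arm_len < 1:
            raise ConfigurationError("arm_len must be positive")
        if len(self.loop_seq) < 3:
            raise ConfigurationError("hairpin loop must be >= 3 nt")
        if not (1 <= len(self.msat_unit) <= 6):
            raise ConfigurationError("microsatellite unit must be 1-6 nt")
        check_acgt(self.msat_unit)
        total = (self.b1f3_len + self.spacer_len + 2 * self.arm_len
                 + len(self.loop_seq) + self.tail_len)
        if self.total_len is not None and total != self.total_len:
            raise ConfigurationError(
                f"segment lengths sum to {total}, design says {self.total_len}"
            )

    @property
    def length(self) -> int:
        return (self.b1f3_len + self.spacer_len + 2 * self.arm_len
                + len(self.loop_seq) + self.tail_len)


@dataclass(frozen=True)
class HairpinDesign:
    left_arm: tuple   # (start, end), 0-based half-open
    right_arm: tuple
    designed_stem_len: int


@dataclass(frozen=True)
class MasterUnit:
    sequence: str
    segments: tuple          # ordered ((label, (start, end)), ...)
    hairpin_design: HairpinDesign
    b1f3_reference: str = ""  # full-length SINE-like reference element

    def __post_init__(self):
        pos = 0
        for _label, (s, e) in self.segments:
            if s != pos or e <= s:
                raise ConfigurationError("segments must tile the sequence")
            pos = e
        if pos != len(self.sequence):
            raise ConfigurationError("segments do not cover the sequence")

    def segment(self, label: str) -> tuple:
        for lab, iv in self.segments:
            if lab == label:
                return iv
        raise KeyError(label)

    @property
    def hairpin_region(self) -> tuple:
        """(start, end) spanning both arms and the loop."""
        return (self.hairpin_design.left_arm[0], self.hairpin_design.right_arm[1])


def _msat_tract(unit: str, length: int) -> str:
    return (unit * (length // len(unit) + 1))[:length]


def build_mouse_master(design: MasterUnitDesign | None = None, seed: int = 1) -> MasterUnit:
    """Design the mouse-style elementary repeat unit.

    The unit is: 3' fragment of a SINE-like reference | spacer | (AC)n arm |
    loop | (GT)n arm | tail, with the two microsatellite arms exactly
    reverse-complementary so the transcript folds into a perfect stem.
    """
    d = design or MasterUnitDesign()
    rng = np.random.default_rng(seed)
    b1f3_ref = random_dna(rng, max(B1F3_FULL_LEN, d.b1f3_len))
    frag = b1f3_ref[len(b1f3_ref) - d.b1f3_len:]
    spacer = random_dna(rng, d.spacer_len)
    left = _msat_tract(d.msat_unit, d.arm_len)
    right = revcomp(left)
    tail = random_dna(rng, d.tail_len)
    seq = frag + spacer + left + d.loop_seq + right + tail
    o = 0
    segs = []
    for label, ln in (
        ("b1f3_fragment", d.b1f3_len),
        ("spacer", d.spacer_len),
        ("msat_left", d.arm_len),
        ("hairpin_loop", len(d.loop_seq)),
        ("msat_right", d.arm_len),
        ("tail", d.tail_len),
    ):
        if ln:
            segs.append((label, (o, o + ln)))
        o += ln
    left_iv = (d.b1f3_len + d.spacer_len, d.b1f3_len + d.spacer_len + d.arm_len)
    right_iv = (left_iv[1] + len(d.loop_seq), left_iv[1] + len(d.loop_seq) + d.arm_len)
    return MasterUnit(
        sequence=seq,
        segments=tuple(segs),
        hairpin_design=HairpinDesign(left_iv, right_iv, d.arm_len),
        b1f3_reference=b1f3_ref,
    )


@dataclass(frozen=True)
class RatDerivation:
    """How the rat elementary unit derives from the mouse master.

    The rat unit lost the 5' SINE fragment and most of the spacer (trim5),
    carries two 2-nt deletions inside the hairpin's right arm, plus designed
    point substitutions; a final 3' trim brings it to 197 nt. The deletion
    offsets are relative to the right arm start; substitutions are
    (mouse-master position, base). The default substitutions were calibrated
    once so that the folded rat hairpin shows asymmetric bulges and a shifted
    pairing register rather than a cleanly slipped shorter stem (a pure
    dinucleotide stem would otherwise absorb the deletions silently).
    """

    trim5: int = 90
    trim3: int = 5
    deletions: tuple = (10, 24)         # right-arm offsets; each removes 2 nt
    substitutions: tuple = ()           # ((mouse position, base), ...); empty
    #                                     means the calibrated default design
    n_random_subs: int = 4              # extra seeded point substitutions

    def resolved_substitutions(self, mouse_master: "MasterUnit") -> tuple:
        if self.substitutions:
            return self.substitutions
        return _default_rat_substitutions(mouse_master)


def _default_rat_substitutions(mouse_master: MasterUnit) -> tuple:
    """Calibrated rat-specific changes inside the hairpin region.

    Three elements (frozen after a one-off calibration of the fold):

    * a near-loop "dead zone": the first 6 nt of the right arm become A's,
      so pairing resumes deeper in the arm and the register of the upper
      stem shifts ~10 nt toward the 3' end;
    * three short compensatory anchor words (C/G on the left arm, their
      complements on the right arm) at staggered registers (+6, +8, +10).
      A pure dinucleotide stem would silently absorb 2-nt deletions by
      slippage (G:U wobble defeats single-base anchors); the anchor words
      pin the local register so the deletions must bulge out;
    * together with the two 2-nt right-arm deletions this yields a stem with
      an enlarged terminal loop, a 4-nt arm-length imbalance and asymmetric
      bulges, while the left arm stays homologous to the mouse unit.
    """
    L = mouse_master.hairpin_design.left_arm[0]
    R = mouse_master.hairpin_design.right_arm[0]
    subs = [(R + off, "A") for off in range(6)]
    for left_offs, right_offs, lb, rb in (
        ((8, 9, 10), (36, 37, 38), "CGC", "GCG"),
        ((14, 15), (33, 34), "CG", "CG"),
        ((18, 19, 20), (30, 31, 32), "CGC", "GCG"),
    ):
        subs.extend((L + a, b) for a, b in zip(left_offs, lb))
        subs.extend((R + a, b) for a, b in zip(right_offs, rb))
    return tuple(subs)


def build_rat_master(
    mouse_master: MasterUnit,
    cfg: RatDerivation | None = None,
    seed: int = 1,
) -> MasterUnit:
    """Derive the rat-style (197 nt by default) unit from the mouse master."""
    cfg = cfg or RatDerivation()
    rng = np.random.default_rng(seed)
    seq = list(mouse_master.sequence)
    la, ra = mouse_master.hairpin_design.left_arm, mouse_master.hairpin_design.right_arm
    arm_len = ra[1] - ra[0]
    for off in cfg.deletions:
        if not (0 <= off and off + 2 <= arm_len):
            raise ConfigurationError(
                f"deletion at right-arm offset {off} lies outside the hairpin arm"
            )
    for pos, base in cfg.resolved_substitutions(mouse_master):
        seq[pos] = base
    # extra random substitutions outside the hairpin region
    hp = mouse_master.hairpin_region
    candidates = [i for i in range(len(seq)) if not hp[0] <= i < hp[1]]
    if cfg.n_random_subs:
        for pos in rng.choice(len(candidates), size=cfg.n_random_subs, replace=False):
            i = candidates[int(pos)]
            others = [b for b in "ACGT" if b != seq[i]]
            seq[i] = others[int(rng.integers(0, 3))]
    # apply right-arm deletions 3'-most first so offsets stay valid
    for off in sorted(cfg.deletions, reverse=True):
        del seq[ra[0] + off : ra[0] + off + 2]
    seq = "".join(seq)
    n_del = 2 * len(cfg.deletions)
    out = seq[cfg.trim5 : len(seq) - cfg.trim3]
    # rat-local segment map
    sp_len = la[0] - cfg.trim5
    if sp_len < 0:
        raise ConfigurationError("trim5 removes part of the hairpin")
    left_iv = (sp_len, sp_len + (la[1] - la[0]))
    loop_len = ra[0] - la[1]
    right_iv = (left_iv[1] + loop_len, left_iv[1] + loop_len + arm_len - n_del)
    segs = []
    if sp_len:
        segs.append(("spacer", (0, sp_len)))
    segs.append(("msat_left", left_iv))
    segs.append(("hairpin_loop", (left_iv[1], right_iv[0])))
    segs.append(("msat_right", right_iv))
    if right_iv[1] < len(out):
        segs.append(("tail", (right_iv[1], len(out))))
    return MasterUnit(
        sequence=out,
        segments=tuple(segs),
        hairpin_design=HairpinDesign(left_iv, right_iv, arm_len - n_del),
        b1f3_reference=mouse_master.b1f3_reference,
    )


# ---------------------------------------------------------------------------
# mutation machinery
# ---------------------------------------------------------------------------


def _mutate_tracked(codes, sub_rate, indel_rate, rng, protect=None,
                    geom_p=0.5, max_indel=10, protect_indel=None):
    """Substitutions + indels with an old->new coordinate map.

    protect: boolean mask; protected positions receive no substitutions and
    no indel events, and deletions truncate at protected boundaries.
    protect_indel: additional mask shielding positions from indel events
    only (substitutions still occur there).
    Returns (new codes, coord map with -1 for deleted positions, n_subs).
    """
    n = codes.shape[0]
    if protect is None:
        protect = np.zeros(n, dtype=bool)
    no_indel = protect if protect_indel is None else (protect | protect_indel)
    out = codes.copy()
    subs = (rng.random(n) < sub_rate) & (out < 4) & ~protect
    n_subs = int(subs.sum())
    if n_subs:
        shift = rng.integers(1, 4, size=n_subs)
        out[subs] = (out[subs] + shift) % 4
    events = np.flatnonzero((rng.random(n) < indel_rate) & ~no_indel)
    pieces = []
    coord = np.full(n, -1, dtype=np.int64)
    pos = 0
    cursor = 0
    ev = set(int(e) for e in events)
    i = 0
    while i < n:
        if i in ev:
            size = min(int(rng.geometric(geom_p)), max_indel)
            if rng.random() < 0.5:  # insertion before i
                ins = rng.integers(0, 4, size=size)
                pieces.append(ins)
                cursor += size
            else:  # deletion of [i, i+size), truncated at protected positions
                j = i
                while j < n and j < i + size and not no_indel[j]:
                    j += 1
                i = j
                continue
        coord[i] = cursor
        pieces.append(out[i : i + 1])
        cursor += 1
        i += 1
    new = np.concatenate(pieces) if pieces else np.empty(0, dtype=codes.dtype)
    return new, coord, n_subs


def mutate(seq: str, sub_rate: float, indel_rate: float, rng) -> str:
    """Neutral divergence: uniform substitutions over the three alternative
    bases plus geometric(0.5) indels (1-10 nt), events Poisson-like with mean
    ``indel_rate * length``."""
    if not (0.0 <= sub_rate <= 1.0 and 0.0 <= indel_rate <= 1.0):
        raise ValueError("rates must be in [0, 1]")
    check_acgt(seq)
    codes = encode(seq)
    new, _coord, _ = _mutate_tracked(codes, sub_rate, indel_rate, rng)
    return decode(new)


def _identity_to_master(master_codes, new, coord):
    """Fraction of master positions that survived unchanged."""
    ok = 0
    for i, c in enumerate(coord):
        if c >= 0 and new[c] == master_codes[i]:
            ok += 1
    return ok / master_codes.shape[0]


# ---------------------------------------------------------------------------
# cluster simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EvolutionConfig:
    """Parameters of the dual-phase cluster growth model (mouse defaults).

    Defaults encode the published cluster anatomy: 13 higher-order blocks of
    10 elementary units, 31 + 48 flank copies, one degraded within-block
    position and 3 corrupted central copies (193 recognizable copies total),
    and 5 intact-hairpin positions x 13 blocks = 65 miRNA units.
    """

    n_higher_order: int = 13
    units_per_block: int = 10
    n_left_flank: int = 31
    n_right_flank: int = 48
    sub_rate_flank: float = 0.13
    sub_rate_within_block: float = 0.08
    sub_rate_between_blocks: float = 0.025
    indel_rate: float = 0.0015
    indel_geom_p: float = 0.5
    degrade_positions: tuple = (6,)      # 1-based within-block positions
    n_corrupted: int = 3
    corrupt_sub_rate: float = 0.55
    mirna_positions: tuple = (2, 4, 7, 9, 10)
    n_compensatory_pairs: int = 6
    remnant_len: int = 70
    disruption_len: tuple = (16, 22)     # hairpin decay tract size range
    flank_spacer: tuple = (10, 25)
    margin: int = 60
    # rat-cluster composition (used when a rat master is supplied)
    rat_n_ratlike: int = 220
    rat_n_mouselike: int = 16
    rat_sub_rate: float = 0.07
    rat_spacer: tuple = (0, 6)
    seed: int = 42

    def __post_init__(self):
        for r in (self.sub_rate_flank, self.sub_rate_within_block,
                  self.sub_rate_between_blocks, self.indel_rate,
                  self.corrupt_sub_rate):
            if not 0.0 <= r <= 1.0:
                raise ConfigurationError("rates must be in [0, 1]")
        for c in (self.n_higher_order, self.units_per_block,
                  self.n_left_flank, self.n_right_flank):
            if c <= 0:
                raise ConfigurationError("counts must be positive")
        if self.sub_rate_between_blocks >= self.sub_rate_within_block:
            raise ConfigurationError(
                "between-block divergence must be smaller than within-block "
                "divergence (otherwise the positional sub-cluster signal is lost)"
            )
        bad = set(self.mirna_positions) & set(self.degrade_positions)
        if bad:
            raise ConfigurationError(f"miRNA positions {bad} are degraded")


@dataclass(frozen=True)
class TruthCopy:
    start: int
    end: int
    strand: str
    label: str               # "block{b}/pos{p}" or "flank_left"/"flank_right"
    identity_to_master: float
    intact_hairpin: bool
    hairpin: tuple | None    # (start, end) in cluster coordinates


@dataclass
class SyntheticCluster:
    sequence: str
    truth_copies: list       # recognizable copies only, sorted, non-overlapping
    truth_blocks: list       # (start, end) of higher-order units
    truth_mirna_units: list  # indices into truth_copies
    truth_degraded: list     # (start, end, kind) for remnants/corrupted copies
    config: EvolutionConfig
    master: MasterUnit
    rat_master: MasterUnit | None = None
    species: str = "mouse"


def _compensatory_stem_substitutions(anc, coord, hp_design, offs):
    """Swap the stem base pairs at left-arm offsets ``offs`` for other
    Watson-Crick pairs.

    Applied in place through the ancestor's coordinate map: A:U pairs become
    G:C and C:G pairs become U:A, so the designed pairing register is intact
    while the arm sequences diverge between positions. Offsets are drawn
    disjointly across positions so no two positions share a derived pair."""
    la, ra = hp_design.left_arm, hp_design.right_arm
    arm_len = la[1] - la[0]
    swap = {0: 2, 1: 3, 2: 0, 3: 1}          # A->G, C->T on the left arm
    comp = {0: 3, 1: 2, 2: 1, 3: 0}
    for a in offs:
        li = coord[la[0] + int(a)]
        ri = coord[ra[0] + (arm_len - 1 - int(a))]
        if li < 0 or ri < 0:
            continue
        anc[li] = swap[int(anc[li]) % 4]
        anc[ri] = comp[int(anc[li])]


def _disrupt_hairpin(codes, hp_start, hp_end, rng, size_range):
    """Mark a seeded chunk of the hairpin as decayed (ambiguous bases).

    Models hairpin decay — mutation beyond pairing ability — as an N tract,
    the way masked/unalignable repeat DNA is conventionally represented.
    Copy length is preserved (the array period stays one unit), alignments
    score the tract as mismatches, pairwise-deletion distances ignore it,
    and the structure classifier treats it as unfoldable."""
    size = int(rng.integers(size_range[0], size_range[1] + 1))
    width = hp_end - hp_start
    if width <= size + 2:
        return codes
    off = int(rng.integers(0, width - size))
    s = hp_start + off
    out = codes.copy()
    out[s: s + size] = 4  # N
    return out



def _mapped_interval(coord, lo, hi):
    """Map a half-open [lo, hi) master interval through a coordinate map,
    tolerating deleted boundary positions."""
    a = lo
    while a < hi and coord[a] < 0:
        a += 1
    b = hi - 1
    while b > a and coord[b] < 0:
        b -= 1
    return int(coord[a]), int(coord[b])


def simulate_cluster(
    master: MasterUnit,
    rat_master: MasterUnit | None = None,
    cfg: EvolutionConfig | None = None,
) -> SyntheticCluster:
    cfg = cfg or EvolutionConfig()
    if rat_master is not None:
        return _simulate_rat(master, rat_master, cfg)
    return _simulate_mouse(master, cfg)


def _simulate_mouse(master: MasterUnit, cfg: EvolutionConfig) -> SyntheticCluster:
    rng = np.random.default_rng(cfg.seed)
    mcodes = encode(master.sequence)
    hp = master.hairpin_region
    n = len(mcodes)
    protect = np.zeros(n, dtype=bool)
    protect[hp[0]: hp[1]] = True

    def evolved_copy(base, base_coord, rate, keep_hairpin):
        """One more round of divergence on top of an ancestor."""
        pr = np.zeros(base.shape[0], dtype=bool)
        pri = np.zeros(base.shape[0], dtype=bool)
        lo, hi = _mapped_interval(base_coord, hp[0], hp[1])
        pri[lo: hi + 1] = True
        if keep_hairpin:
            pr[lo: hi + 1] = True
        new, coord2, _ = _mutate_tracked(
            base, rate, cfg.indel_rate, rng, protect=pr,
            geom_p=cfg.indel_geom_p, protect_indel=pri,
        )
        coord = np.array([coord2[c] if c >= 0 else -1 for c in base_coord])
        return new, coord

    # phase-2 position ancestors (the fixed higher-order unit). miRNA
    # positions keep a fully paired hairpin but acquire position-specific
    # compensatory stem substitutions (a base pair swapped for another
    # Watson-Crick pair) — the classic signature of conserved hairpin
    # evolution — so positions stay distinguishable without any copy
    # losing its processable stem.
    ancestors = {}
    arm_len = (master.hairpin_design.left_arm[1]
               - master.hairpin_design.left_arm[0])
    n_comp = min(cfg.n_compensatory_pairs,
                 arm_len // max(1, len(cfg.mirna_positions)))
    pool = rng.permutation(arm_len)
    comp_offsets = {
        pos: pool[k * n_comp: (k + 1) * n_comp]
        for k, pos in enumerate(sorted(cfg.mirna_positions))
    }
    for pos in range(1, cfg.units_per_block + 1):
        keep = pos in cfg.mirna_positions
        anc, coord, _ = _mutate_tracked(
            mcodes, cfg.sub_rate_within_block, cfg.indel_rate, rng,
            protect=protect if keep else None, geom_p=cfg.indel_geom_p,
            protect_indel=protect,
        )
        if keep:
            _compensatory_stem_substitutions(
                anc, coord, master.hairpin_design, comp_offsets[pos])
        ancestors[pos] = (anc, coord)

    # choose corrupted (block, position) slots among non-miRNA, non-degraded
    ok_pos = [p for p in range(1, cfg.units_per_block + 1)
              if p not in cfg.mirna_positions and p not in cfg.degrade_positions]
    corrupt_pos = rng.choice(ok_pos, size=min(cfg.n_corrupted, len(ok_pos)),
                             replace=False)
    corrupt_blocks = rng.choice(cfg.n_higher_order, size=len(corrupt_pos),
                                replace=False) + 1
    corrupted = set(zip((int(b) for b in corrupt_blocks),
                        (int(p) for p in corrupt_pos)))

    pieces = []
    cursor = 0
    copies = []
    blocks = []
    degraded = []

    def emit(seqcodes):
        nonlocal cursor
        pieces.append(seqcodes)
        start = cursor
        cursor += seqcodes.shape[0]
        return start, cursor

    def emit_random(ln):
        return emit(rng.integers(0, 4, size=ln))

    def flank_copy(side):
        new, coord = evolved_copy(mcodes, np.arange(n), cfg.sub_rate_flank, False)
        ident = _identity_to_master(mcodes, new, coord)
        lo, hi = _mapped_interval(coord, hp[0], hp[1])
        new = _disrupt_hairpin(new, lo, hi + 1, rng, cfg.disruption_len)
        s, e = emit(new)
        copies.append(TruthCopy(s, e, "+", f"flank_{side}", ident, False, None))

    emit_random(cfg.margin)
    for _ in range(cfg.n_left_flank):
        flank_copy("left")
        emit_random(int(rng.integers(*cfg.flank_spacer)))

    for b in range(1, cfg.n_higher_order + 1):
        bstart = cursor
        for pos in range(1, cfg.units_per_block + 1):
            if pos in cfg.degrade_positions:
                # decayed beyond recognition: short, heavily mutated remnant
                rem = ancestors[pos][0][: cfg.remnant_len].copy()
                rem = (rem + rng.integers(1, 4, size=rem.shape[0]) *
                       (rng.random(rem.shape[0]) < 0.5)) % 4
                s, e = emit(rem.astype(mcodes.dtype))
                degraded.append((s, e, "remnant"))
                continue
            keep = pos in cfg.mirna_positions
            anc, coordA = ancestors[pos]
            new, coord = evolved_copy(anc, coordA, cfg.sub_rate_between_blocks, keep)
            if (b, pos) in corrupted:
                new, coord2, _ = _mutate_tracked(
                    new, cfg.corrupt_sub_rate, 0.02, rng
                )
                s, e = emit(new)
                degraded.append((s, e, "corrupted"))
                continue
            ident = _identity_to_master(mcodes, new, coord)
            if keep:
                lo, hi = _mapped_interval(coord, hp[0], hp[1])
                hp_iv = (cursor + lo, cursor + hi + 1)
                s, e = emit(new)
                copies.append(TruthCopy(s, e, "+", f"block{b}/pos{pos}",
                                        ident, True, hp_iv))
            else:
                lo, hi = _mapped_interval(coord, hp[0], hp[1])
                new = _disrupt_hairpin(new, lo, hi + 1, rng, cfg.disruption_len)
                s, e = emit(new)
                copies.append(TruthCopy(s, e, "+", f"block{b}/pos{pos}",
                                        ident, False, None))
        blocks.append((bstart, cursor))

    for _ in range(cfg.n_right_flank):
        flank_copy("right")
        emit_random(int(rng.integers(*cfg.flank_spacer)))

    # full-length SINE-like element marks the 3' cluster border
    b1f3 = encode(master.b1f3_reference)
    b1f3_mut, _, _ = _mutate_tracked(b1f3, 0.02, 0.0, rng)
    emit(b1f3_mut)
    emit_random(cfg.margin)

    seq = decode(np.concatenate(pieces))
    mirna_idx = [i for i, c in enumerate(copies) if c.intact_hairpin]
    return SyntheticCluster(
        sequence=seq,
        truth_copies=copies,
        truth_blocks=blocks,
        truth_mirna_units=mirna_idx,
        truth_degraded=degraded,
        config=cfg,
        master=master,
        species="mouse",
    )


def _simulate_rat(master: MasterUnit, rat_master: MasterUnit,
                  cfg: EvolutionConfig) -> SyntheticCluster:
    """Rat-style cluster: a less strictly ordered tandem array.

    Mostly rat-like (truncated) units plus a minority of ancestral,
    mouse-like units; exactly one mouse-like unit keeps an intact,
    processable hairpin (the rat's single miRNA gene).
    """
    rng = np.random.default_rng(cfg.seed + 1)
    rcodes = encode(rat_master.sequence)
    mcodes = encode(master.sequence)
    rhp = rat_master.hairpin_region
    mhp = master.hairpin_region
    n_total = cfg.rat_n_ratlike + cfg.rat_n_mouselike
    mouse_slots = set(
        int(x) for x in rng.choice(n_total, size=cfg.rat_n_mouselike, replace=False)
    )
    intact_slot = sorted(mouse_slots)[len(mouse_slots) // 2]

    pieces = []
    cursor = 0
    copies = []

    def emit(seqcodes):
        nonlocal cursor
        pieces.append(seqcodes)
        start = cursor
        cursor += seqcodes.shape[0]
        return start, cursor

    emit(rng.integers(0, 4, size=cfg.margin))
    for slot in range(n_total):
        mouse_like = slot in mouse_slots
        base = mcodes if mouse_like else rcodes
        hp = mhp if mouse_like else rhp
        keep = slot == intact_slot
        pr = np.zeros(base.shape[0], dtype=bool)
        pri = np.zeros(base.shape[0], dtype=bool)
        pri[hp[0]: hp[1]] = True
        if keep:
            pr[hp[0]: hp[1]] = True
        new, coord, _ = _mutate_tracked(
            base, cfg.rat_sub_rate, cfg.indel_rate, rng, protect=pr,
            geom_p=cfg.indel_geom_p, protect_indel=pri,
        )
        ident = _identity_to_master(base, new, coord)
        if keep:
            lo, hi = _mapped_interval(coord, hp[0], hp[1])
            hp_iv = (cursor + lo, cursor + hi + 1)
            s, e = emit(new)
            copies.append(TruthCopy(s, e, "+",
                                    "mouse_like" if mouse_like else "rat_like",
                                    ident, True, hp_iv))
        else:
            lo, hi = _mapped_interval(coord, hp[0], hp[1])
            new = _disrupt_hairpin(new, lo, hi + 1, rng, cfg.disruption_len)
            s, e = emit(new)
            copies.append(TruthCopy(s, e, "+",
                                    "mouse_like" if mouse_like else "rat_like",
                                    ident, False, None))
        emit(rng.integers(0, 4, size=int(rng.integers(*cfg.rat_spacer))))

    b1f3 = encode(master.b1f3_reference)
    b1f3_mut, _, _ = _mutate_tracked(b1f3, 0.05, 0.0, rng)
    emit(b1f3_mut)
    emit(rng.integers(0, 4, size=cfg.margin))

    seq = decode(np.concatenate(pieces))
    mirna_idx = [i for i, c in enumerate(copies) if c.intact_hairpin]
    return SyntheticCluster(
        sequence=seq,
        truth_copies=copies,
        truth_blocks=[],
        truth_mirna_units=mirna_idx,
        truth_degraded=[],
        config=cfg,
        master=master,
        rat_master=rat_master,
        species="rat",
    )


# ---------------------------------------------------------------------------
# presets and I/O
# ---------------------------------------------------------------------------

#: calibrated rat hairpin design; see build_rat_master and docs/methods.md
DEFAULT_RAT_DERIVATION = RatDerivation()


def mouse_cluster(seed: int = 42, cfg: EvolutionConfig | None = None) -> SyntheticCluster:
    """Default mouse-preset cluster (master seed 1, evolution seed ``seed``)."""
    cfg = cfg or EvolutionConfig(seed=seed)
    master = build_mouse_master(seed=1)
    return simulate_cluster(master, None, cfg)


def rat_cluster(seed: int = 42, cfg: EvolutionConfig | None = None) -> SyntheticCluster:
    cfg = cfg or EvolutionConfig(seed=seed)
    master = build_mouse_master(seed=1)
    rat = build_rat_master(master, DEFAULT_RAT_DERIVATION, seed=1)
    return simulate_cluster(master, rat, cfg)


def write_cluster(cluster: SyntheticCluster, out_prefix) -> dict:
    """Write FASTA + GFF3 + JSON run record; returns the paths written."""
    import os

    prefix = str(out_prefix)
    os.makedirs(os.path.dirname(prefix) or ".", exist_ok=True)
    name = f"synthetic_{cluster.species}_cluster"
    fasta = prefix + ".fa"
    gff = prefix + ".gff3"
    rec = prefix + ".json"
    write_fasta(fasta, [(name, cluster.sequence)])
    with open(gff, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {name} 1 {len(cluster.sequence)}\n")

        def line(type_, s, e, attrs, score="."):
            fh.write(f"{name}\tsatmir\t{type_}\t{s + 1}\t{e}\t{score}\t+\t.\t{attrs}\n")

        for i, c in enumerate(cluster.truth_copies):
            attrs = (f"ID=copy{i};label={c.label};"
                     f"identity={c.identity_to_master:.4f};"
                     f"intact_hairpin={'1' if c.intact_hairpin else '0'}")
            line("repeat_copy", c.start, c.end, attrs,
                 score=f"{c.identity_to_master:.4f}")
            if c.intact_hairpin and c.hairpin:
                line("mirna_hairpin", c.hairpin[0], c.hairpin[1],
                     f"ID=hairpin{i};Parent=copy{i}")
        for k, (s, e) in enumerate(cluster.truth_blocks):
            line("higher_order_unit", s, e, f"ID=block{k + 1}")
        for s, e, kind in cluster.truth_degraded:
            line("degraded_copy", s, e, f"ID=deg_{s};kind={kind}")
    record = {
        "species": cluster.species,
        "config": dataclasses.asdict(cluster.config),
        "master_seed": 1,
        "rat": cluster.rat_master is not None,
        "rat_derivation": dataclasses.asdict(DEFAULT_RAT_DERIVATION)
        if cluster.rat_master is not None else None,
        "format_version": 1,
    }
    with open(rec, "w") as fh:
        json.dump(record, fh, indent=1, default=list)
    return {"fasta": fasta, "gff3": gff, "record": rec}


def regenerate_cluster(record_path) -> SyntheticCluster:
    """Rebuild a cluster bit-identically from its JSON run record."""
    with open(record_path) as fh:
        record = json.load(fh)
    cfgd = dict(record["config"])
    for key in ("degrade_positions", "mirna_positions", "disruption_len",
                "flank_spacer", "rat_spacer"):
        cfgd[key] = tuple(cfgd[key])
    cfg = EvolutionConfig(**cfgd)
    master = build_mouse_master(seed=record["master_seed"])
    if record["rat"]:
        rd = dict(record["rat_derivation"])
        rd["deletions"] = tuple(rd["deletions"])
        rd["substitutions"] = tuple(tuple(s) for s in rd["substitutions"])
        rat = build_rat_master(master, RatDerivation(**rd), seed=record["master_seed"])
        return simulate_cluster(master, rat, cfg)
    return simulate_cluster(master, None, cfg)
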