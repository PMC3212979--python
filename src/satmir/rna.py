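"""RNA secondary structure: MFE folding, partition function, positional
entropy, centroid structure, and hairpin morphology.

The thermodynamic machinery behind the mouse-vs-rat hairpin contrast: the
pre-miRNA hairpin of the mouse repeat unit folds into a long, symmetric,
low-entropy stem, while the rat unit's truncations and deletions shift the
pairing register and introduce energy-rich asymmetric bulges. This module
measures those properties.

DNA input is transcribed internally (T == U); all coordinates are reported on
the input sequence. Entropies are in nats.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _fold_kernels as _fk
from ._util import encode

#: default folding temperature, Kelvin (37 C)
TEMPERATURE = 310.15
_GAS = 0.0019872  # kcal / (mol K)


class AmbiguousHairpinError(ValueError):
    """Raised when a region does not contain exactly one terminal hairpin loop."""


@dataclass(frozen=True)
class SecondaryStructure:
    """A pseudoknot-free secondary structure as dot-bracket + pair list."""

    dotbracket: str
    pairs: tuple  # of (i, j), 0-based, i < j

    @classmethod
    def from_partner(cls, partner: np.ndarray) -> "SecondaryStructure":
        chars = []
        pairs = []
        for i, j in enumerate(partner):
            if j < 0:
                chars.append(".")
            elif j > i:
                chars.append("(")
                pairs.append((i, int(j)))
            else:
                chars.append(")")
        return cls("".join(chars), tuple(pairs))

    def partner_array(self) -> np.ndarray:
        partner = np.full(len(self.dotbracket), -1, dtype=np.int64)
        for i, j in self.pairs:
            partner[i] = j
            partner[j] = i
        return partner

    def __len__(self) -> int:
        return len(self.dotbracket)


@dataclass(frozen=True)
class BasePairMatrix:
    """Equilibrium pair probabilities P[i, j] and unpaired probabilities q."""

    P: np.ndarray
    q: np.ndarray

    def __post_init__(self):
        n = self.P.shape[0]
        assert self.P.shape == (n, n) and self.q.shape == (n,)


@dataclass(frozen=True)
class EntropyProfile:
    S: np.ndarray  # per-position entropy, nats


@dataclass(frozen=True)
class HairpinFeatures:
    stem_length: int          # base pairs in the terminal helix (bulges spanned)
    loop_length: int          # unpaired nt in the terminal loop
    left_arm_nt: int          # nt between outermost and loop-closing pair, 5' arm
    right_arm_nt: int         # same for the 3' arm
    n_symmetric_bulges: int
    n_asymmetric_bulges: int
    pairing_map: tuple        # chain of (i, j) pairs, outermost first
    region: tuple             # the (start, end) interval examined


@dataclass(frozen=True)
class PremirnaThresholds:
    min_stem: int = 30
    max_asymmetric_bulges: int = 1
    max_entropy_ratio: float = 0.5   # mean hairpin S / mean flank S
    min_flank5: int = 20             # nt of sequence 5' of the hairpin


def _encode_rna(seq: str) -> np.ndarray:
    codes = encode(seq)
    if (codes > 3).any():
        raise ValueError("fold input must be A/C/G/T/U only")
    return codes


def mfe_fold(seq: str, temperature: float = TEMPERATURE):
    """Minimum-free-energy structure under the module's energy model.

    Returns (SecondaryStructure, energy in kcal/mol). Sequences shorter than
    5 nt cannot pair (min loop 3) and fold to the open chain at energy 0.
    """
    if len(seq) < 5:
        return SecondaryStructure("." * len(seq), ()), 0.0
    codes = _encode_rna(seq)
    energy, partner = _fk.mfe_kernel(codes)
    return SecondaryStructure.from_partner(partner), float(energy)


def partition(seq: str, temperature: float = TEMPERATURE):
    """McCaskill partition function.

    Returns (log Z, BasePairMatrix). Computed in a rescaled linear domain so
    Z itself never overflows; log Z is exact up to rounding.
    """
    n = len(seq)
    if n == 0:
        return 0.0, BasePairMatrix(np.zeros((0, 0)), np.zeros(0))
    if n < 5:
        return 0.0, BasePairMatrix(np.zeros((n, n)), np.ones(n))
    codes = _encode_rna(seq)
    RT = _GAS * temperature
    emfe, _ = _fk.mfe_kernel(codes)
    kappa = float(np.exp(-1.07 * emfe / (RT * n))) if emfe < 0 else 1.0
    QB, QM, QM1, qe, qr = _fk.inside_kernel(codes, RT, kappa)
    P = _fk.outside_kernel(codes, RT, kappa, QB, QM, qe, qr)
    logZ = float(np.log(qe[n]) + n * np.log(kappa))
    q = 1.0 - P.sum(axis=1)
    np.clip(q, 0.0, 1.0, out=q)
    return logZ, BasePairMatrix(P, q)


def positional_entropy(bp: BasePairMatrix) -> EntropyProfile:
    """Shannon entropy of each position's pairing-state distribution (nats).

    S_i = -q_i ln q_i - sum_j P_ij ln P_ij, with 0 ln 0 = 0.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        termP = np.where(bp.P > 0, -bp.P * np.log(bp.P), 0.0).sum(axis=1)
        termq = np.where(bp.q > 0, -bp.q * np.log(bp.q), 0.0)
    return EntropyProfile(termP + termq)


def centroid(bp: BasePairMatrix) -> SecondaryStructure:
    """Centroid structure: all pairs with P_ij > 0.5.

    This is the structure minimizing the expected base-pair distance to the
    ensemble; pairs with P > 0.5 can never cross (their joint probability
    would exceed 1), so the result is a valid structure.
    """
    n = bp.P.shape[0]
    partner = np.full(n, -1, dtype=np.int64)
    ii, jj = np.where(np.triu(bp.P) > 0.5)
    for i, j in zip(ii, jj):
        partner[i] = j
        partner[j] = i
    return SecondaryStructure.from_partner(partner)


def hairpin_features(structure: SecondaryStructure, region: tuple) -> HairpinFeatures:
    """Morphology of the single hairpin formed inside ``region`` (half-open).

    Walks the terminal helix from the loop-closing pair outward, classifying
    every disruption as a symmetric or asymmetric interior loop/bulge (a side
    of length 0 counts as a one-sided, i.e. asymmetric, bulge). Only pairs
    falling entirely inside the region are considered.
    """
    lo, hi = region
    pairs = sorted((i, j) for i, j in structure.pairs if lo <= i and j < hi)
    if not pairs:
        raise AmbiguousHairpinError("region contains no base pairs")
    # terminal loops: pairs with no other pair nested inside
    inner = []
    for (i, j) in pairs:
        if not any(i < k and l < j for (k, l) in pairs if (k, l) != (i, j)):
            inner.append((i, j))
    if len(inner) != 1:
        raise AmbiguousHairpinError(
            f"region contains {len(inner)} terminal hairpin loops, expected 1"
        )
    closing = inner[0]
    # walk outward: parent = tightest enclosing pair with nothing else between
    chain = [closing]
    nsym = 0
    nasym = 0
    cur = closing
    while True:
        i, j = cur
        parents = [(p, q) for (p, q) in pairs if p < i and q > j]
        if not parents:
            break
        p, q = max(parents, key=lambda x: x[0])
        # another branch between (p,q) and (i,j) means a multiloop: stop here
        if any(p < k < i or j < k < q for (k, _l) in pairs):
            break
        l1 = i - p - 1
        l2 = q - j - 1
        if l1 == 0 and l2 == 0:
            pass  # stack
        elif l1 == l2:
            nsym += 1
        else:
            nasym += 1
        chain.append((p, q))
        cur = (p, q)
    outer = chain[-1]
    return HairpinFeatures(
        stem_length=len(chain),
        loop_length=closing[1] - closing[0] - 1,
        left_arm_nt=closing[0] - outer[0] + 1,
        right_arm_nt=outer[1] - closing[1] + 1,
        n_symmetric_bulges=nsym,
        n_asymmetric_bulges=nasym,
        pairing_map=tuple(reversed(chain)),
        region=(lo, hi),
    )


def is_premirna_like(
    features: HairpinFeatures,
    entropy: EntropyProfile,
    thresholds: PremirnaThresholds = PremirnaThresholds(),
):
    """Classify a hairpin as a plausible miRNA precursor.

    Criteria: a long stem, at most one asymmetric bulge, hairpin positions
    thermodynamically committed relative to their flanks, and enough 5'
    flanking sequence for processing. Returns (bool, {criterion: (ok, detail)}).
    """
    outer_i = features.pairing_map[0][0]
    outer_j = features.pairing_map[0][1]
    flank5_len = features.region[0]
    S = entropy.S
    hp = S[outer_i : outer_j + 1]
    flank = np.concatenate([S[:outer_i], S[outer_j + 1 :]])
    mean_hp = float(hp.mean()) if hp.size else 0.0
    mean_fl = float(flank.mean()) if flank.size else 0.0
    ratio = mean_hp / mean_fl if mean_fl > 0 else np.inf
    reasons = {
        "stem_length": (
            features.stem_length >= thresholds.min_stem,
            f"stem {features.stem_length} bp (need >= {thresholds.min_stem})",
        ),
        "asymmetric_bulges": (
            features.n_asymmetric_bulges <= thresholds.max_asymmetric_bulges,
            f"{features.n_asymmetric_bulges} asymmetric bulges "
            f"(allow <= {thresholds.max_asymmetric_bulges})",
        ),
        "entropy_contrast": (
            ratio <= thresholds.max_entropy_ratio,
            f"hairpin/flank entropy ratio {ratio:.3f} "
            f"(need <= {thresholds.max_entropy_ratio})",
        ),
        "flank5": (
            flank5_len >= thresholds.min_flank5,
            f"{flank5_len} nt 5' of hairpin region "
            f"(need >= {thresholds.min_flank5})",
        ),
    }
    return all(ok for ok, _ in reasons.values()), reasons


def write_dotbracket(path, seq: str, structure: SecondaryStructure, energy=None):
    with open(path, "w") as fh:
        fh.write(seq + "\n")
        tag = f" ({energy:.2f})" if energy is not None else ""
        fh.write(structure.dotbracket + tag + "\n")


def write_bpp(path, bp: BasePairMatrix, min_p: float = 1e-5):
    """Pair probabilities as tab-separated ``i  j  p`` (1-based, p > min_p)."""
    with open(path, "w") as fh:
        fh.write("i\tj\tp\n")
        n = bp.P.shape[0]
        for i in range(n):
            for j in range(i + 1, n):
                if bp.P[i, j] > min_p:
                    fh.write(f"{i + 1}\t{j + 1}\t{bp.P[i, j]:.6g}\n")


def write_entropy_wig(path, S: np.ndarray, chrom: str = "seq"):
    with open(path, "w") as fh:
        fh.write(f"fixedStep chrom={chrom} start=1 step=1\n")
        for v in S:
            fh.write(f"{v:.6g}\n")
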