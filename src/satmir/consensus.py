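"""Consensus building for tandem repeat units.

Progressive multiple alignment (k-mer guide tree + profile-profile merging),
similarity profiling, majority consensus calling, and the iterative
scan/realign/trim cycle that sharpens consensus boundaries — the classic
multiple-alignment + similarity-graph + repeated-annotation workflow used to
derive repeat family consensi.

A tandem-repeat consensus is intrinsically circular: any rotation tiles the
array equally well. ``refine_consensus`` therefore anchors the unit length to
the array's modal start-to-start spacing and places the boundary at the
least-conserved columns (the inter-copy joint), which converges to a stable,
uniquely-phased unit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _align_kernels as _ak
from . import scan as _scan
from ._util import decode, encode


class RefinementError(RuntimeError):
    pass


@dataclass(frozen=True)
class AlignParams:
    """Progressive-aligner parameters.

    Gap penalties follow the classic ClustalX DNA defaults (open 10,
    extend 0.2) and the match weight the IUB matrix (1.9; mismatches 0)."""

    match: float = 1.9
    mismatch: float = 0.0
    gap_open: float = 10.0
    gap_ext: float = 0.2


DEFAULT_ALIGN = AlignParams()
_GAP = 5


@dataclass(frozen=True)
class MSA:
    ids: tuple
    codes: np.ndarray  # (n_rows, n_cols) int8; 0-3 bases, 4 N, 5 gap

    @property
    def n_cols(self) -> int:
        return self.codes.shape[1]

    @property
    def n_rows(self) -> int:
        return self.codes.shape[0]

    def row(self, i: int) -> str:
        return decode(self.codes[i])

    def ungapped_row(self, i: int) -> str:
        r = self.codes[i]
        return decode(r[r != _GAP])

    def rows(self):
        return [(self.ids[i], self.row(i)) for i in range(self.n_rows)]


@dataclass(frozen=True)
class Consensus:
    sequence: str
    per_column_support: tuple
    source_copy_count: int

    def __len__(self):
        return len(self.sequence)


def _kmer_distance_matrix(seq_codes, k=4):
    """1 - fraction of shared k-mers; quick guide-tree distances."""
    n = len(seq_codes)
    profs = np.zeros((n, 4 ** k), dtype=np.float64)
    mult = 4 ** np.arange(k)
    for i, codes in enumerate(seq_codes):
        c = codes[codes < 4]
        if c.shape[0] < k:
            continue
        idx = np.lib.stride_tricks.sliding_window_view(c, k) @ mult
        np.add.at(profs[i], idx.astype(np.int64), 1.0)
    norms = np.sqrt((profs ** 2).sum(axis=1)) + 1e-12
    sim = (profs @ profs.T) / np.outer(norms, norms)
    D = 1.0 - sim
    np.fill_diagonal(D, 0.0)
    return np.maximum(D, 0.0)


def _profile(rows: np.ndarray) -> np.ndarray:
    """(L, 5) frequency profile; N counts spread over the four bases."""
    n, L = rows.shape
    prof = np.zeros((L, 5), dtype=np.float64)
    for b in range(4):
        prof[:, b] = (rows == b).sum(axis=0)
    prof[:, :4] += 0.25 * (rows == 4).sum(axis=0)[:, None]
    prof[:, 4] = (rows == _GAP).sum(axis=0)
    return prof / n


def progressive_msa(seqs, params: AlignParams = DEFAULT_ALIGN,
                    ids=None) -> MSA:
    """Progressive alignment: k-mer distances -> NJ guide tree -> profile
    merging in join order. Deterministic."""
    if len(seqs) < 2:
        raise ValueError("need >= 2 sequences to align")
    if ids is None:
        ids = tuple(f"seq{i}" for i in range(len(seqs)))
    seq_codes = [encode(s) for s in seqs]
    n = len(seqs)
    if n == 2:
        order = [(0, 1)]
    else:
        D = _kmer_distance_matrix(seq_codes)
        left, right, _, _ = _ak.nj_kernel(D)
        order = [(int(left[k]), int(right[k]))
                 for k in range(n, left.shape[0]) if left[k] >= 0]
    # clusters: node id -> (row indices, row matrix)
    clusters = {i: ([i], seq_codes[i].reshape(1, -1).copy())
                for i in range(n)}
    nxt = n
    for a, b in order:
        ra, rows_a = clusters.pop(a)
        rb, rows_b = clusters.pop(b)
        ops = _ak.profile_align(
            _profile(rows_a), _profile(rows_b),
            params.gap_open, params.gap_ext, params.match, params.mismatch,
        )
        L = ops.shape[0]
        new_a = np.full((rows_a.shape[0], L), _GAP, dtype=np.int8)
        new_b = np.full((rows_b.shape[0], L), _GAP, dtype=np.int8)
        cols_a = np.flatnonzero(ops != 2)
        cols_b = np.flatnonzero(ops != 1)
        new_a[:, cols_a] = rows_a
        new_b[:, cols_b] = rows_b
        clusters[nxt] = (ra + rb, np.vstack([new_a, new_b]))
        nxt += 1
    (_, (idx, rows)), = clusters.items()
    # restore input order of rows
    inv = np.argsort(np.array(idx))
    return MSA(tuple(ids[i] for i in np.array(idx)[inv]), rows[inv])


def similarity_profile(msa: MSA, window: int = 5) -> np.ndarray:
    """Per-column fraction of rows matching the modal residue, smoothed."""
    if window < 1:
        raise ValueError("window must be >= 1")
    counts = np.zeros((msa.n_cols, 6), dtype=np.float64)
    for v in range(6):
        counts[:, v] = (msa.codes == v).sum(axis=0)
    raw = counts[:, :4].max(axis=1) / msa.n_rows
    kernel = np.ones(window) / window
    return np.convolve(raw, kernel, mode="same")


def majority_consensus(msa: MSA, min_support: float = 0.5) -> Consensus:
    """Column-wise modal residue; columns that are mostly gap or weakly
    supported are dropped. Ties resolve in base order A<C<G<T."""
    if msa.n_rows == 0:
        raise ValueError("empty MSA")
    counts = np.zeros((msa.n_cols, 4), dtype=np.float64)
    for b in range(4):
        counts[:, b] = (msa.codes == b).sum(axis=0)
    gapfrac = (msa.codes == _GAP).sum(axis=0) / msa.n_rows
    nongap = counts.sum(axis=1) + (msa.codes == 4).sum(axis=0)
    best = counts.argmax(axis=1)  # argmax takes the first max: A<C<G<T
    support = counts.max(axis=1) / np.maximum(nongap, 1)
    keep = (gapfrac < 0.5) & (support >= min_support) & (nongap > 0)
    seq = decode(best[keep].astype(np.int8))
    return Consensus(seq, tuple(float(s) for s in support[keep]), msa.n_rows)


def _column_stats(msa: MSA):
    counts = np.zeros((msa.n_cols, 4), dtype=np.float64)
    for b in range(4):
        counts[:, b] = (msa.codes == b).sum(axis=0)
    nongap = counts.sum(axis=1)
    support = counts.max(axis=1) / np.maximum(nongap, 1)
    occupancy = nongap / msa.n_rows
    return support, occupancy


def refine_consensus(
    seed_consensus: Consensus | str,
    sequence: str,
    max_cycles: int = 10,
    flank: int = 50,
    min_identity: float = 0.65,
    align_params: AlignParams = DEFAULT_ALIGN,
    trim_support: float = 0.6,
    trim_occupancy: float = 0.5,
    trim_end_support: float = 0.75,
):
    """Iteratively sharpen a repeat consensus against its source sequence.

    Each cycle: scan with the current consensus, extract hit sequences with
    ``flank`` nt of context, re-align, call the majority consensus, then trim
    the ends — first columns below the support/occupancy thresholds, then
    down to the array's modal start-to-start period (the natural length of a
    tandem unit), dropping whichever end is less conserved. Stops when the
    length changes by <= 2 nt, or after ``max_cycles``. Returns
    (Consensus, cycle log).
    """
    cons = (seed_consensus.sequence
            if isinstance(seed_consensus, Consensus) else seed_consensus)
    log = []
    result = None
    for cycle in range(max_cycles):
        cs = _scan.scan(cons, sequence, min_identity=min_identity)
        if len(cs) < 2:
            raise RefinementError(
                f"cycle {cycle}: only {len(cs)} copies found with the current "
                f"consensus (length {len(cons)}); cannot refine"
            )
        windows = []
        for h in cs.hits:
            s_, e_ = h.target_interval
            windows.append(
                sequence[max(0, s_ - flank): min(len(sequence), e_ + flank)])
        msa = progressive_msa(windows, align_params)
        support, occupancy = _column_stats(msa)
        counts = np.zeros((msa.n_cols, 4), dtype=np.float64)
        for b in range(4):
            counts[:, b] = (msa.codes == b).sum(axis=0)
        modal = counts.argmax(axis=1).astype(np.int8)
        keep_mask = occupancy >= trim_occupancy
        # end trimming on support/occupancy
        good = np.flatnonzero(keep_mask & (support >= trim_support))
        if good.size == 0:
            raise RefinementError(f"cycle {cycle}: alignment has no well-"
                                  "supported columns")
        lo, hi = int(good[0]), int(good[-1]) + 1
        cols = [c for c in range(lo, hi) if keep_mask[c]]
        # length anchor: a tandem unit is one array period minus the
        # inter-copy gap; both medians share the same end-trimming bias,
        # so the difference estimates the unit length without bias.
        target_len = _unit_length_estimate(cs, sequence)
        sup = support.copy()
        if target_len and len(cols) > target_len:
            # best contiguous period-length window by total support: the
            # boundary falls at the least-conserved columns (the joint)
            colsup = np.array([sup[c] for c in cols])
            sums = np.convolve(colsup, np.ones(target_len), "valid")
            best = int(np.argmax(sums))
            cols = cols[best: best + target_len]
        # inter-copy spacer columns smear across rows (random content,
        # variable length) and sit below the conservation of true unit
        # ends: strip them from the window boundaries
        while cols and sup[cols[0]] < trim_end_support:
            cols.pop(0)
        while cols and sup[cols[-1]] < trim_end_support:
            cols.pop()
        new_cons = decode(modal[np.array(cols, dtype=int)])
        sup_kept = tuple(float(sup[c]) for c in cols)
        log.append({"cycle": cycle, "copies": len(cs), "length": len(new_cons)})
        prev_len = len(result.sequence) if result is not None else None
        cons = new_cons
        result = Consensus(cons, sup_kept, len(cs))
        if prev_len is not None and abs(len(new_cons) - prev_len) <= 2:
            break
    return result, log


def _unit_length_estimate(cs, sequence: str | None = None) -> int | None:
    """Unit length of a tandem array from a scan.

    Median near-modal start-to-start spacing minus the median inter-copy
    spacer. The raw inter-hit gap overstates the spacer because local
    alignment trims mismatching copy ends; the unaligned query tails of the
    two flanking hits measure that trimming, so it is subtracted out.

    A large apparent spacer is only subtracted when the gap sequences are
    mutually dissimilar: similar gap contents mean the gaps are unit
    material the current (too short) consensus does not yet cover, and the
    unit is then one full period long.
    """
    hits = cs.hits
    if len(hits) < 3:
        return None
    m = cs.thresholds.get("query_length",
                          max(h.query_interval[1] for h in hits))
    starts = np.array([h.target_interval[0] for h in hits], dtype=float)
    spac = np.diff(starts)
    bins = np.floor(spac / 5.0).astype(int)
    vals, counts = np.unique(bins, return_counts=True)
    modal_bin = vals[np.argmax(counts)]
    near = np.abs(bins - modal_bin) <= 1
    if not near.any():
        return None
    spacing_med = float(np.median(spac[near]))
    spacers = []
    gap_ivs = []
    for k in np.flatnonzero(near):
        left, right = hits[k], hits[k + 1]
        gap = right.target_interval[0] - left.target_interval[1]
        trim = (m - left.query_interval[1]) + right.query_interval[0]
        spacers.append(max(0.0, gap - trim))
        gap_ivs.append((left.target_interval[1], right.target_interval[0]))
    spacer_med = float(np.median(spacers)) if spacers else 0.0
    if spacer_med > 8 and sequence is not None:
        if _gaps_are_unit_material(sequence, gap_ivs):
            spacer_med = 0.0
    # the period is an upper bound for the unit; the spacer estimate is
    # unreliable below ~8 nt (hit end-trimming noise of the same size), so
    # small apparent spacers are left to the support-based end trim
    if spacer_med <= 8:
        spacer_med = 0.0
    return int(round(spacing_med - spacer_med))


def _gaps_are_unit_material(sequence, gap_ivs, max_pairs=12):
    """True when inter-hit gap sequences look homologous to each other.

    Homologous gaps align to each other over most of their length; random
    spacers produce only short spurious local alignments."""
    gaps = [sequence[a:b] for a, b in gap_ivs if b - a >= 12]
    if len(gaps) < 4:
        return False
    fracs = []
    idents = []
    for a, b in zip(gaps[:max_pairs], gaps[1: max_pairs + 1]):
        aln = _scan.smith_waterman(a, b)
        fracs.append(aln.target_length / min(len(a), len(b)))
        idents.append(aln.identity)
    return (float(np.median(fracs)) >= 0.5
            and float(np.median(idents)) >= 0.65)


def derive_seed_consensus(sequence: str, period_band=(150, 500),
                          n_windows: int = 3,
                          align_params: AlignParams = DEFAULT_ALIGN) -> Consensus:
    """Blind seed consensus for a tandem array.

    Estimates the elementary period by FFT autocorrelation of the one-hot
    encoded sequence, cuts ``n_windows`` consecutive period-length windows
    from the center of the array (a few kb is enough), aligns them and takes
    the majority consensus. The downstream refinement cycle fixes boundaries
    and length.
    """
    codes = encode(sequence)
    n = codes.shape[0]
    onehot = np.zeros((4, n), dtype=np.float64)
    for b in range(4):
        onehot[b] = (codes == b) - 0.25
    m = 1 << int(np.ceil(np.log2(2 * n)))
    spec = np.zeros(m // 2 + 1)
    for b in range(4):
        f = np.fft.rfft(onehot[b], m)
        spec += (f * f.conj()).real
    acf = np.fft.irfft(spec)[:n]
    lo, hi = period_band
    hi = min(hi, n // (n_windows + 1))
    if hi <= lo:
        raise ValueError("sequence too short for the requested period band")
    period = int(lo + np.argmax(acf[lo:hi]))
    c = n // 2
    windows = [sequence[c + k * period: c + (k + 1) * period]
               for k in range(n_windows)]
    msa = progressive_msa(windows, align_params)
    return majority_consensus(msa, min_support=0.34)


def write_msa_fasta(path, msa: MSA):
    from ._util import write_fasta

    write_fasta(path, msa.rows())


def read_msa_fasta(path) -> MSA:
    from ._util import read_fasta

    recs = read_fasta(path)
    rows = np.vstack([encode(s) for _i, s in recs])
    return MSA(tuple(i for i, _s in recs), rows)


def write_consensus(path_prefix, cons: Consensus, name="consensus"):
    from ._util import write_fasta

    write_fasta(str(path_prefix) + ".fa", [(name, cons.sequence)])
    with open(str(path_prefix) + ".support.wig", "w") as fh:
        fh.write(f"fixedStep chrom={name} start=1 step=1\n")
        for v in cons.per_column_support:
            fh.write(f"{v:.4f}\n")
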