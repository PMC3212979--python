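"""Censor-style repeat annotation: local alignment of a consensus against a
long target, greedy non-overlapping hit selection, coverage and periodicity
statistics, and inference of the higher-order (multi-unit) repeat.

The scanner is exact Smith-Waterman (affine gaps). For long targets a linear
-memory score sweep locates candidate end points; each candidate is then
re-aligned with full traceback in a local window. Hits are accepted greedily
by descending score (ties: leftmost target start) subject to non-overlap, and
remaining free gaps are re-scanned so no qualifying copy is lost.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _align_kernels as _ak
from ._util import encode, revcomp


class InsufficientDataError(ValueError):
    pass


@dataclass(frozen=True)
class SchemeParams:
    """Alignment scoring; gap of length k costs gap_open + k * gap_ext."""

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -2.0
    gap_ext: float = -1.0


DEFAULT_SCHEME = SchemeParams()


@dataclass(frozen=True)
class LocalAlignment:
    query_interval: tuple      # 0-based half-open on the query (consensus)
    target_interval: tuple     # 0-based half-open on the (+) target
    strand: str                # "+" or "-"
    score: float
    identity: float            # identical columns / aligned columns
    aligned_pairs: tuple       # ((qpos|-1, tpos|-1), ...) in + orientation

    @property
    def target_length(self) -> int:
        return self.target_interval[1] - self.target_interval[0]


@dataclass(frozen=True)
class CopySet:
    hits: tuple                # sorted by target start, non-overlapping
    consensus_id: str = "consensus"
    thresholds: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.hits)


def _pairs_and_identity(q, t, qs, ts, ops):
    """Build aligned pair list + identity from a traceback ops array."""
    pairs = []
    qi, tj = qs, ts
    ident = 0
    ncols = len(ops)
    for op in ops:
        if op == 0:
            pairs.append((qi, tj))
            if q[qi] == t[tj] and q[qi] < 4:
                ident += 1
            qi += 1
            tj += 1
        elif op == 1:  # gap in target: query char consumed
            pairs.append((qi, -1))
            qi += 1
        else:          # gap in query: target char consumed
            pairs.append((-1, tj))
            tj += 1
    return tuple(pairs), (ident / ncols if ncols else 0.0)


def smith_waterman(
    query: str,
    target: str,
    scoring: SchemeParams = DEFAULT_SCHEME,
    both_strands: bool = False,
) -> LocalAlignment:
    """Optimal local alignment of query vs target under affine-gap scoring.

    With ``both_strands`` the reverse complement of the target is also
    searched and the better hit is reported with its strand; coordinates are
    always on the forward target.
    """
    if not query or not target:
        raise ValueError("empty sequence")
    q = encode(query)
    results = []
    for strand in ("+", "-") if both_strands else ("+",):
        tseq = target if strand == "+" else revcomp(target)
        t = encode(tseq)
        score, qs, qe, ts, te, ops = _ak.sw_align(
            q, t, scoring.match, scoring.mismatch,
            -scoring.gap_open, -scoring.gap_ext,
        )
        pairs, ident = _pairs_and_identity(q, t, qs, ts, ops)
        if strand == "-":
            n = len(target)
            ts, te = n - te, n - ts
            pairs = tuple(
                (qi, (n - 1 - tj) if tj >= 0 else -1) for qi, tj in pairs
            )
        results.append(LocalAlignment((qs, qe), (ts, te), strand,
                                      float(score), ident, pairs))
    return max(results, key=lambda a: (a.score, a.strand == "+"))


def _align_window(q, t_codes, lo, hi, scoring):
    """Full-traceback SW of query vs target[lo:hi]; global coordinates."""
    score, qs, qe, ts, te, ops = _ak.sw_align(
        q, t_codes[lo:hi], scoring.match, scoring.mismatch,
        -scoring.gap_open, -scoring.gap_ext,
    )
    return score, qs, qe, ts + lo, te + lo, ops


def scan(
    consensus: str,
    sequence: str,
    min_identity: float = 0.65,
    min_length: int | None = None,
    scoring: SchemeParams = DEFAULT_SCHEME,
    both_strands: bool = True,
    consensus_id: str = "consensus",
) -> CopySet:
    """Annotate ``sequence`` with non-overlapping copies of ``consensus``.

    Greedy best-score-first selection; each surviving hit meets both the
    identity and the length threshold. Deterministic given its inputs.
    """
    m = len(consensus)
    if min_length is None:
        min_length = m // 2
    thresholds = {"min_identity": min_identity, "min_length": min_length,
                  "query_length": m,
                  "scoring": (scoring.match, scoring.mismatch,
                              scoring.gap_open, scoring.gap_ext)}
    if m > len(sequence) or m == 0:
        return CopySet((), consensus_id, thresholds)
    q = encode(consensus)
    n = len(sequence)
    # minimal plausible score of a qualifying hit
    min_score = min_length * (min_identity * scoring.match
                              + (1.0 - min_identity) * scoring.mismatch)
    strands = ("+", "-") if both_strands else ("+",)
    tcodes = {}
    candidates = []
    for strand in strands:
        tseq = sequence if strand == "+" else revcomp(sequence)
        t = encode(tseq)
        tcodes[strand] = t
        best = _ak.sw_end_scores(q, t, scoring.match, scoring.mismatch,
                                 -scoring.gap_open, -scoring.gap_ext)
        w = max(min_length // 2, 20)
        for j in np.flatnonzero(best >= min_score):
            lo = max(0, j - w)
            if best[j] == best[lo: j + w + 1].max() and \
                    (j == 0 or best[j] > best[j - 1] or best[j - 1] < min_score):
                candidates.append((float(best[j]), strand, int(j)))
    # greedy by descending score; ties by position
    candidates.sort(key=lambda c: (-c[0], c[2], c[1]))
    accepted = []       # (start, end) on + strand, kept sorted
    hits = []
    win = int(2.2 * m) + 16

    def overlaps(s, e):
        for (a, b) in accepted:
            if s < b and a < e:
                return True
        return False

    def free_subintervals(s, e):
        """Parts of [s, e) not covered by accepted intervals."""
        out = []
        cur = s
        for (a, b) in sorted(accepted):
            if b <= cur or a >= e:
                continue
            if a > cur:
                out.append((cur, a))
            cur = max(cur, b)
        if cur < e:
            out.append((cur, e))
        return out

    def to_plus(strand, ts, te, pairs):
        if strand == "+":
            return ts, te, pairs
        return (n - te, n - ts,
                tuple((qi, (n - 1 - tj) if tj >= 0 else -1) for qi, tj in pairs))

    def try_accept(strand, lo, hi):
        """Best hit of the window [lo, hi) on ``strand``; accept if it passes."""
        t = tcodes[strand]
        score, qs, qe, ts, te, ops = _align_window(q, t, lo, hi, scoring)
        if score <= 0 or te - ts < min_length:
            return None
        pairs, ident = _pairs_and_identity(q, t, qs, ts, ops)
        ps, pe, pairs = to_plus(strand, ts, te, pairs)
        if ident < min_identity:
            return None
        if overlaps(ps, pe):
            return "overlap"
        accepted.append((ps, pe))
        hits.append(LocalAlignment((qs, qe), (ps, pe), strand,
                                   float(score), ident, pairs))
        return "ok"

    for score, strand, j in candidates:
        t_end = j + 1
        lo = max(0, t_end - win)
        # map candidate window to + coordinates to test for prior coverage
        if strand == "+":
            plo, phi = lo, t_end
        else:
            plo, phi = n - t_end, n - lo
        frees = free_subintervals(plo, phi)
        if not frees:
            continue
        status = try_accept(strand, lo, t_end)
        if status == "overlap":
            # re-align inside the largest still-free part of the window
            s2, e2 = max(frees, key=lambda iv: iv[1] - iv[0])
            if e2 - s2 >= min_length:
                if strand == "+":
                    try_accept(strand, s2, e2)
                else:
                    try_accept(strand, n - e2, n - s2)
    # cleanup: re-scan remaining free gaps until nothing qualifies
    work = free_subintervals(0, n)
    while work:
        s, e = work.pop()
        if e - s < min_length:
            continue
        got = None
        for strand in strands:
            if strand == "+":
                lo, hi = s, e
            else:
                lo, hi = n - e, n - s
            t = tcodes[strand]
            score, qs, qe, ts, te, ops = _align_window(q, t, lo, hi, scoring)
            if score <= 0 or te - ts < min_length:
                continue
            pairs, ident = _pairs_and_identity(q, t, qs, ts, ops)
            ps, pe, pairs = to_plus(strand, ts, te, pairs)
            if ident < min_identity or overlaps(ps, pe):
                continue
            cand = LocalAlignment((qs, qe), (ps, pe), strand,
                                  float(score), ident, pairs)
            if got is None or cand.score > got.score:
                got = cand
        if got is not None:
            accepted.append(got.target_interval)
            hits.append(got)
            gs, ge = got.target_interval
            work.append((s, gs))
            work.append((ge, e))
    hits.sort(key=lambda h: h.target_interval)
    return CopySet(tuple(hits), consensus_id, thresholds)


def coverage(copies: CopySet, region: tuple) -> float:
    """Fraction of ``region`` covered by hits."""
    s, e = region
    if e <= s:
        raise ValueError("empty region")
    cov = 0
    for h in copies.hits:
        a, b = h.target_interval
        cov += max(0, min(b, e) - max(a, s))
    return cov / (e - s)


@dataclass(frozen=True)
class PeriodEstimate:
    primary_period: float
    higher_order_period: float | None
    support: float


def _modal_spacing(starts, binsize=10):
    spac = np.diff(starts)
    bins = np.round(spac / binsize).astype(int)
    vals, counts = np.unique(bins, return_counts=True)
    modal_bin = vals[np.argmax(counts)]
    modal = float(spac[bins == modal_bin].mean())
    support = float(np.mean(np.abs(spac - modal) <= 0.1 * modal))
    return spac, modal, support


def detect_period(copies: CopySet, sequence: str | None = None) -> PeriodEstimate:
    """Primary (unit) and higher-order (multi-unit block) periodicity.

    The primary period is the modal adjacent start-to-start spacing (10-nt
    bins). The higher-order period is found from the lag profile of
    copy-to-copy dissimilarity: copies are projected onto consensus
    coordinates through their alignments and compared at each lag; a lag
    whose mean dissimilarity drops well below the overall level marks a
    repeating cycle of more than one unit.
    """
    hits = copies.hits
    if len(hits) < 3:
        raise InsufficientDataError("need >= 3 hits to estimate a period")
    starts = np.array([h.target_interval[0] for h in hits], dtype=float)
    spac, modal, support = _modal_spacing(starts)
    higher = None
    if sequence is not None and len(hits) >= 6:
        t = encode(sequence)
        qlen = max(h.query_interval[1] for h in hits)
        projs = np.full((len(hits), qlen), -1, dtype=np.int16)
        for k, h in enumerate(hits):
            for qi, tj in h.aligned_pairs:
                if qi >= 0 and tj >= 0:
                    projs[k, qi] = t[tj]
        maxlag = min(20, len(hits) - 2)
        d = np.full(maxlag + 1, np.nan)
        for lag in range(1, maxlag + 1):
            a = projs[:-lag]
            b = projs[lag:]
            valid = (a >= 0) & (b >= 0)
            nv = valid.sum()
            if nv:
                d[lag] = ((a != b) & valid).sum() / nv
        dv = d[1:]
        med = np.nanmedian(dv)
        if med > 0:
            lag_best = int(np.nanargmin(dv)) + 1
            if lag_best > 1 and dv[lag_best - 1] < 0.8 * med:
                gaps = starts[lag_best:] - starts[:-lag_best]
                bins = np.round(gaps / 50.0).astype(int)
                vals, counts = np.unique(bins, return_counts=True)
                modal_bin = vals[np.argmax(counts)]
                higher = float(np.median(gaps[bins == modal_bin]))
    return PeriodEstimate(primary_period=modal, higher_order_period=higher,
                          support=support)


@dataclass(frozen=True)
class HigherOrderModel:
    copies_per_unit: int
    n_units: int
    unit_length: float


def infer_higher_order_unit(copies: CopySet, subcluster_labels: dict):
    """Reconstruct the higher-order unit from sub-cluster labels.

    ``subcluster_labels`` maps hit index (position in ``copies.hits``) to a
    sub-cluster id; unlabelled (flank) copies are excluded. Finds the label
    cycle tiling the central labelled run, tolerating occasional missing
    copies, and adds degraded positions inferred from a consistent extra
    spacing at a fixed cyclic phase. Returns a HigherOrderModel, or None if
    no label cycle repeats.
    """
    idx = [i for i in range(len(copies.hits)) if i in subcluster_labels]
    if len(idx) < 2:
        return None
    labels = [subcluster_labels[i] for i in idx]
    starts = [copies.hits[i].target_interval[0] for i in idx]
    ends = [copies.hits[i].target_interval[1] for i in idx]
    # candidate cycle: distinct labels in first-occurrence order
    cycle = []
    for lab in labels:
        if lab in cycle:
            break
        cycle.append(lab)
    c = len(cycle)
    if c < 2 or c == len(labels):
        return None
    # walk the run, matching the cycle and tolerating skips
    pos_in_cycle = {lab: p for p, lab in enumerate(cycle)}
    n_units = 0
    prev_phase = None
    misfits = 0
    for lab in labels:
        if lab not in pos_in_cycle:
            misfits += 1
            continue
        ph = pos_in_cycle[lab]
        if prev_phase is None or ph <= prev_phase:
            n_units += 1
        prev_phase = ph
    if misfits > 0.2 * len(labels):
        return None
    # per-phase spacing excess -> degraded positions hidden in the cycle
    unit_est = float(np.median(np.diff(sorted(starts))))
    phase_gap = {p: [] for p in range(c)}
    for k in range(len(idx) - 1):
        lab = labels[k]
        if lab in pos_in_cycle and labels[k + 1] in pos_in_cycle:
            phase_gap[pos_in_cycle[lab]].append(starts[k + 1] - ends[k])
    inferred = 0
    unit_len_full = unit_est
    for p in range(c):
        gaps = phase_gap[p]
        if not gaps:
            continue
        med = float(np.median(gaps))
        if med >= 0.15 * unit_est:
            inferred += max(1, round(med / unit_est))
    block_starts = []
    prev_phase = None
    for k, lab in enumerate(labels):
        if lab in pos_in_cycle:
            ph = pos_in_cycle[lab]
            if prev_phase is None or ph <= prev_phase:
                block_starts.append(starts[k])
            prev_phase = ph
    if len(block_starts) >= 2:
        unit_len_full = float(np.median(np.diff(block_starts)))
    return HigherOrderModel(copies_per_unit=c + inferred, n_units=n_units,
                            unit_length=unit_len_full)


def write_hits_gff3(path, copies: CopySet, seqid: str = "target"):
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for k, h in enumerate(copies.hits):
            s, e = h.target_interval
            fh.write(
                f"{seqid}\tsatmir\trepeat_copy\t{s + 1}\t{e}\t"
                f"{h.identity * 1000:.0f}\t{h.strand}\t.\t"
                f"ID=hit{k};consensus={copies.consensus_id};"
                f"identity={h.identity:.4f}\n"
            )


def write_hits_bed(path, copies: CopySet, seqid: str = "target"):
    with open(path, "w") as fh:
        for k, h in enumerate(copies.hits):
            s, e = h.target_interval
            fh.write(f"{seqid}\t{s}\t{e}\thit{k}\t"
                     f"{min(1000, int(h.identity * 1000))}\t{h.strand}\n")
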