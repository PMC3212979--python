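"""Microsatellite detection, self-complementarity pairing, masking, and
segmental annotation of a repeat-unit consensus.

Microsatellites here are tandem repeats with a 1-6 bp unit. The pair of
mutually reverse-complementary tracts — canonically (AC)n and (GT)n — is what
lets the transcribed unit fold back into the pre-miRNA hairpin, so pairing
and masking these tracts are first-class operations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._util import check_acgt, revcomp
from . import scan as _scan


@dataclass(frozen=True)
class MicrosatelliteInterval:
    start: int
    end: int                # 0-based half-open
    unit: str               # canonical (lexicographically minimal) rotation
    n_copies: float
    purity: float

    @property
    def interval(self):
        return (self.start, self.end)

    def __len__(self):
        return self.end - self.start


def _primitive(motif: str) -> str:
    """Reduce a motif to its primitive root (e.g. GTGT -> GT)."""
    n = len(motif)
    for d in range(1, n):
        if n % d == 0 and motif == motif[:d] * (n // d):
            return motif[:d]
    return motif


def _canonical_rotation(motif: str) -> str:
    motif = _primitive(motif)
    return min(motif[i:] + motif[:i] for i in range(len(motif)))


def _is_rotation(a: str, b: str) -> bool:
    return len(a) == len(b) and a in b + b


def find_microsats(seq: str, max_unit: int = 6, min_total_len: int = 10,
                   min_purity: float = 0.8):
    """Detect maximal microsatellite tracts by purity-scored extension.

    For each unit size u the sequence is compared against itself at offset u
    (match +1, mismatch -2); a run is closed when the running score drops 5
    below its maximum. Overlapping calls with different units resolve to the
    higher purity, then the longer tract, then the smaller unit.
    """
    check_acgt(seq, allow_n=True)
    n = len(seq)
    calls = []
    for u in range(1, max_unit + 1):
        i = u
        while i < n:
            # find next match to start a run
            if seq[i] != seq[i - u] or seq[i] == "N":
                i += 1
                continue
            score = 0.0
            best_score = 0.0
            best_end = i
            start = i - u
            j = i
            while j < n:
                if seq[j] == "N":
                    score -= 2.0
                elif seq[j] == seq[j - u]:
                    score += 1.0
                else:
                    score -= 2.0
                if score > best_score:
                    best_score = score
                    best_end = j
                if score < best_score - 5.0:
                    break
                j += 1
            end = best_end + 1
            if end - start >= max(min_total_len, 2 * u):
                motif = seq[start: start + u]
                perfect = (motif * ((end - start) // u + 1))[: end - start]
                matches = sum(1 for a, b in zip(seq[start:end], perfect) if a == b)
                purity = matches / (end - start)
                if purity >= min_purity and "N" not in motif:
                    calls.append(MicrosatelliteInterval(
                        start, end, _canonical_rotation(motif),
                        (end - start) / u, purity,
                    ))
                    i = max(i + 1, best_end + 1)
                    continue
            # failed runs advance by one position only: a spurious prefix
            # run must not swallow the true start of a following tract
            i += 1
    # resolve overlaps: higher purity, longer, smaller unit wins
    calls.sort(key=lambda c: (-c.purity, -(len(c)), len(c.unit), c.start))
    chosen = []
    for c in calls:
        if all(c.end <= d.start or d.end <= c.start for d in chosen):
            chosen.append(c)
    chosen.sort(key=lambda c: c.start)
    return chosen


def pair_self_complementary(calls, max_separation: int = 60):
    """Pairs (a, b) of tracts whose units are reverse complements (up to
    rotation) separated by at most ``max_separation`` nt — the (AC)n/(GT)n
    arrangement that forms a hairpin stem. A tract whose unit is its own
    reverse complement (e.g. (AT)n) is flagged as a self-pairing candidate
    (a, a)."""
    out = []
    for i, a in enumerate(calls):
        rc = _canonical_rotation(revcomp(a.unit))
        if rc == a.unit:
            out.append((a, a))
        for b in calls[i + 1:]:
            if b.start - a.end > max_separation or b.start < a.end:
                continue
            if _is_rotation(rc, b.unit):
                out.append((a, b))
    return out


def mask_repeats(seq: str, calls) -> str:
    """Replace called positions with N (length preserved; idempotent)."""
    arr = list(seq)
    for c in calls:
        if c.start < 0 or c.end > len(seq):
            raise ValueError("call outside sequence bounds")
        for i in range(c.start, c.end):
            arr[i] = "N"
    return "".join(arr)


@dataclass(frozen=True)
class UnitAnnotation:
    """Segmental annotation of a repeat-unit consensus.

    ``segments`` is a non-overlapping ordered tiling with labels in
    {b1f3_like, msat, other}; ``hairpin`` is the (possibly msat-overlapping)
    fold-competent region; ``msat_pairs`` lists self-complementary tract
    pairs; ``provenance`` records how each call was made.
    """

    segments: tuple          # ((label, (start, end)), ...)
    hairpin: tuple | None    # (start, end)
    msats: tuple
    msat_pairs: tuple
    provenance: dict = field(default_factory=dict)


def segment_unit(consensus: str, b1f3_ref: str | None = None,
                 hairpin_region: tuple | None = None,
                 min_b1f3_identity: float = 0.6) -> UnitAnnotation:
    """Annotate a consensus: SINE-fragment segment (by local alignment of
    the 3' portion of the reference element), microsatellites, and the
    hairpin region (caller-supplied, from the self-complementary msat pair,
    or from the MFE fold as a fallback)."""
    prov = {}
    segments = []
    b1f3_iv = None
    if b1f3_ref:
        aln = _scan.smith_waterman(b1f3_ref, consensus)
        if aln.identity >= min_b1f3_identity and aln.target_length >= 40:
            b1f3_iv = aln.target_interval
            prov["b1f3_like"] = {
                "identity": aln.identity,
                "ref_interval": aln.query_interval,
            }
    else:
        prov["b1f3_like"] = "omitted: no reference element supplied"
    msats = tuple(find_microsats(consensus))
    pairs = tuple(pair_self_complementary(msats))
    hairpin = hairpin_region
    if hairpin is None:
        recip = [(a, b) for a, b in pairs if a is not b]
        if recip:
            a, b = max(recip, key=lambda p: len(p[0]) + len(p[1]))
            hairpin = (a.start, b.end)
            prov["hairpin"] = "from self-complementary microsatellite pair"
        else:
            from . import rna

            st, _e = rna.mfe_fold(consensus)
            spans = _longest_stem_span(st)
            if spans is not None:
                hairpin = spans
                prov["hairpin"] = "from MFE fold (longest terminal helix)"
    # non-overlapping tiling: b1f3_like, msats, remainder "other"
    marks = []
    if b1f3_iv:
        marks.append(("b1f3_like", b1f3_iv))
    for m in msats:
        if b1f3_iv and not (m.end <= b1f3_iv[0] or m.start >= b1f3_iv[1]):
            continue
        marks.append(("msat", m.interval))
    marks.sort(key=lambda x: x[1])
    pos = 0
    for label, (s, e) in marks:
        if s > pos:
            segments.append(("other", (pos, s)))
        segments.append((label, (s, e)))
        pos = e
    if pos < len(consensus):
        segments.append(("other", (pos, len(consensus))))
    return UnitAnnotation(tuple(segments), hairpin, msats, pairs, prov)


def _longest_stem_span(structure):
    """Outer span of the stem (bulges included) with the most base pairs.

    Walks outward from each terminal loop through stacked pairs and interior
    loops, stopping at multiloops, and returns the outermost pair's span of
    the longest such chain."""
    pairs = sorted(structure.pairs)
    if not pairs:
        return None
    best = None
    best_len = 0
    for closing in pairs:
        i, j = closing
        if any(i < k and l < j for (k, l) in pairs if (k, l) != closing):
            continue  # not a terminal loop
        chain = 1
        cur = closing
        while True:
            ci, cj = cur
            parents = [(p, q) for (p, q) in pairs if p < ci and q > cj]
            if not parents:
                break
            p, q = max(parents, key=lambda x: x[0])
            if any(p < k < ci or cj < k < q for (k, _l) in pairs):
                break  # multiloop
            chain += 1
            cur = (p, q)
        if chain > best_len:
            best_len = chain
            best = (cur[0], cur[1] + 1)
    return best


def write_msats_gff3(path, calls, seqid: str = "seq"):
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for k, c in enumerate(calls):
            fh.write(
                f"{seqid}\tsatmir\tmicrosatellite\t{c.start + 1}\t{c.end}\t"
                f"{c.purity:.3f}\t+\t.\tID=msat{k};unit={c.unit};"
                f"n_copies={c.n_copies:.1f}\n"
            )
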