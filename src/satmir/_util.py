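"""Shared small helpers: sequence encoding, reverse complement, FASTA I/O."""

from __future__ import annotations

import numpy as np

# Base encoding used by every numeric kernel: A=0, C=1, G=2, T/U=3.
_CODE = np.full(256, -1, dtype=np.int8)
for i, b in enumerate("ACGT"):
    _CODE[ord(b)] = i
    _CODE[ord(b.lower())] = i
_CODE[ord("U")] = 3
_CODE[ord("u")] = 3
_CODE[ord("N")] = 4  # masked / unknown
_CODE[ord("n")] = 4
_CODE[ord("-")] = 5  # alignment gap

_DECODE = np.array(list("ACGTN-"))

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N", "U": "A"}


def encode(seq: str) -> np.ndarray:
    """Encode a DNA/RNA string to int8 codes (A=0,C=1,G=2,T/U=3,N=4,-=5)."""
    arr = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr < 0).any():
        bad = seq[int(np.argmax(arr < 0))]
        raise ValueError(f"non-nucleotide character {bad!r} in sequence")
    return arr


def decode(codes: np.ndarray) -> str:
    return "".join(_DECODE[np.asarray(codes, dtype=np.int64)])


def revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq.upper()))


def check_acgt(seq: str, *, allow_n: bool = False) -> None:
    allowed = set("ACGTU") | ({"N"} if allow_n else set())
    extra = set(seq.upper()) - allowed
    if extra:
        raise ValueError(f"sequence contains non-ACGT characters: {sorted(extra)}")


def random_dna(rng: np.random.Generator, n: int) -> str:
    return decode(rng.integers(0, 4, size=n))


def write_fasta(path, records, width: int = 60) -> None:
    """Write (id, seq) pairs as wrapped FASTA."""
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path):
    """Read FASTA into a list of (id, seq) pairs (Biopython-backed)."""
    from Bio import SeqIO

    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
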