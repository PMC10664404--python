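"""Circular genome container and coordinate handling.

Giant-virus genomes in the Pithoviridae family are circular dsDNA
molecules that are deposited as artificially linearized sequences.  All
coordinates in this package are 0-based, half-open on the linearized
sequence; the :class:`CircularGenome` records the rotation (``offset``)
applied relative to the deposited sequence so analyses run at different
linearization points remain comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

VALID_BASES = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N self-complements)."""
    return seq.translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    """G+C fraction of *seq*, ignoring Ns; 0.0 for an all-N sequence."""
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        return 0.0
    return (seq.count("G") + seq.count("C")) / acgt


@dataclass
class CircularGenome:
    """A (usually circular) DNA sequence with a linearization offset.

    Parameters
    ----------
    id
        Sequence identifier.
    seq
        Uppercase DNA over the alphabet {A, C, G, T, N}.
    circular
        Whether coordinates are allowed to wrap the origin.
    offset
        Rotation (in nt) applied relative to the deposited sequence; a
        genome rotated to start at deposited position *k* has offset *k*.
    """

    id: str
    seq: str
    circular: bool = True
    offset: int = 0

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        if len(self.seq) == 0:
            raise ValueError(f"genome {self.id!r} has empty sequence")
        bad = set(self.seq) - VALID_BASES
        if bad:
            raise ValueError(f"genome {self.id!r} contains invalid bases {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.seq)

    def fetch(self, start: int, end: int) -> str:
        """Subsequence [start, end); wraps the origin on circular genomes.

        Negative *start* and *end* past the sequence length are
        interpreted circularly.
        """
        L = len(self.seq)
        if not self.circular:
            if start < 0 or end > L or end < start:
                raise IndexError(f"[{start}, {end}) outside linear genome of length {L}")
            return self.seq[start:end]
        span = end - start
        if span > L or span < 0:
            raise IndexError(f"requested span {span} invalid for genome length {L}")
        start %= L
        end = start + span
        if end <= L:
            return self.seq[start:end]
        return self.seq[start:] + self.seq[: end - L]

    def base_counts(self) -> dict[str, int]:
        return {b: self.seq.count(b) for b in "ACGTN"}


def rotate_linearize(
    genome: CircularGenome, new_start: int, reverse_complement: bool = False
) -> CircularGenome:
    """Cut a circular genome at *new_start* and relinearize there.

    Mirrors the comparative-genomics convention of cutting and swapping
    each genome at a shared reference position so that homologous
    regions line up across isolates; optionally the sequence is
    reverse-complemented afterwards (used for isolates assembled on the
    opposite strand).

    Length and base composition are unchanged; the cumulative rotation
    is recorded in ``offset``.
    """
    L = len(genome)
    if not 0 <= new_start < L:
        raise IndexError(f"new_start {new_start} outside [0, {L})")
    seq = genome.seq[new_start:] + genome.seq[:new_start]
    if reverse_complement:
        seq = revcomp(seq)
    return replace(genome, seq=seq, offset=(genome.offset + new_start) % L)


def seq_to_array(seq: str) -> np.ndarray:
    """Encode DNA as uint8 codes A=0 C=1 G=2 T=3 N=4 (vector ops)."""
    lut = np.full(256, 4, dtype=np.uint8)
    for i, b in enumerate("ACGT"):
        lut[ord(b)] = i
    return lut[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
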