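"""Small nucleotide-sequence helpers used across the package."""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
_COMP = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def canonical(kmer: str) -> str:
    """Lexicographically smaller of a k-mer and its reverse complement."""
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def canonical_rotation(monomer: str) -> str:
    """Least string among all rotations of a monomer and of its reverse
    complement — the strand/phase-free representative of a tandem unit."""
    n = len(monomer)
    rc = revcomp(monomer)
    candidates = [monomer[i:] + monomer[:i] for i in range(n)]
    candidates += [rc[i:] + rc[:i] for i in range(n)]
    return min(candidates)


def circular_kmers(monomer: str, k: int) -> list[str]:
    """All k-length windows of the monomer read circularly (len(monomer) of them)."""
    doubled = monomer + monomer
    return [doubled[i : i + k] for i in range(len(monomer))]


def random_seq(length: int, rng: np.random.Generator) -> str:
    base_bytes = np.frombuffer(b"ACGT", dtype="S1")
    return base_bytes[rng.integers(0, 4, size=length)].tobytes().decode()
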