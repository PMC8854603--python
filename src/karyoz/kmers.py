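"""Sex-specific satellite discovery from female vs male k-mer spectra.

The W chromosome is female-specific, so k-mers from a W-borne tandem
satellite are abundant in female reads and absent in male reads. The
pipeline counts canonical k-mers per sex, selects female-specific k-mers,
reconstructs the tandem monomer as a simple cycle in a de Bruijn-style
overlap graph on the selected k-mers, and estimates the array copy number
from the k-mer counts and sequencing depth.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from .sequtil import canonical, canonical_rotation, circular_kmers, revcomp
from .simulate import ReadSet


@dataclass
class KmerTable:
    """Canonical k-mer counts from one read set.

    Keys are canonical (lexicographic min of k-mer and reverse complement);
    k must be odd so no k-mer is its own reverse complement. ``total`` is
    the number of k-mer instances counted, including those later dropped by
    the ``min_count`` floor (the floor keeps huge spectra streamable).
    """

    k: int
    counts: dict[str, int]
    total: int
    sex: str = ""


def count_kmers(
    reads: ReadSet | list[str], k: int = 21, sex: str | None = None, min_count: int = 1
) -> KmerTable:
    """Count canonical k-mers over a read set.

    Reads containing non-ACGT symbols contribute only their valid k-length
    windows. k-mers with final count below ``min_count`` are discarded
    (``min_count=2`` drops singletons, the usual floor for error-containing
    spectra; the default keeps everything).
    """
    if isinstance(reads, ReadSet):
        seqs = reads.reads
        sex = sex if sex is not None else reads.sex
        read_length = reads.read_length
    else:
        seqs = reads
        read_length = min((len(r) for r in seqs), default=k)
    if k % 2 == 0:
        raise ValueError("k must be odd (avoids palindromic self-complementary k-mers)")
    if seqs and k > read_length:
        raise ValueError("k exceeds read length")
    if k > 31:
        raise ValueError("k must be <= 31 (2-bit packing into 64-bit codes)")

    # group reads by length so each group packs into one 2-D byte array
    by_len: dict[int, list[str]] = defaultdict(list)
    for read in seqs:
        by_len[len(read)].append(read.upper())

    all_codes: list[np.ndarray] = []
    total = 0
    for L, group in sorted(by_len.items()):
        if L < k:
            continue
        arr = np.frombuffer("".join(group).encode(), dtype=np.uint8).reshape(
            len(group), L
        )
        codes = _encode_windows(arr, k)
        total += codes.size
        all_codes.append(codes)
    if not all_codes:
        return KmerTable(k=k, counts={}, total=0, sex=sex or "")
    uniq, cnt = np.unique(np.concatenate(all_codes), return_counts=True)
    if min_count > 1:
        keep = cnt >= min_count
        uniq, cnt = uniq[keep], cnt[keep]
    counts = dict(zip(_decode(uniq, k), (int(c) for c in cnt)))
    return KmerTable(k=k, counts=counts, total=total, sex=sex or "")


# 2-bit base codes; 255 flags a non-ACGT symbol
_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i


def _encode_windows(arr: np.ndarray, k: int) -> np.ndarray:
    """Canonical 2-bit codes of every valid k-window of a (reads x length)
    byte array.

    Works on the flattened concatenation so every slice is contiguous;
    windows spanning a read boundary or containing a non-ACGT symbol are
    dropped.
    """
    n, L = arr.shape
    base = _BASE_CODE[arr.ravel()]
    bad = base == 255
    b = np.where(bad, 0, base).astype(np.uint64)
    nw_flat = b.size - k + 1
    fwd = np.zeros(nw_flat, dtype=np.uint64)
    rev = np.zeros(nw_flat, dtype=np.uint64)
    # cache-sized blocks keep the k accumulation passes off main memory
    block = 1 << 18
    tmp = np.empty(block, dtype=np.uint64)
    for s in range(0, nw_flat, block):
        e = min(s + block, nw_flat)
        t = tmp[: e - s]
        fw, rv = fwd[s:e], rev[s:e]
        for j in range(k):
            col = b[s + j : e + j]
            np.left_shift(col, np.uint64(2 * (k - 1 - j)), out=t)
            np.bitwise_or(fw, t, out=fw)
            np.subtract(np.uint64(3), col, out=t)
            np.left_shift(t, np.uint64(2 * j), out=t)
            np.bitwise_or(rv, t, out=rv)
    bad_cum = np.concatenate([[0], np.cumsum(bad)])
    clean = (bad_cum[k:] - bad_cum[:nw_flat]) == 0
    inside = (np.arange(nw_flat) % L) <= L - k  # window stays in one read
    return np.minimum(fwd, rev)[clean & inside]


def _decode(codes: np.ndarray, k: int) -> list[str]:
    """Integer codes back to k-mer strings (vectorised)."""
    shifts = np.uint64(2) * np.arange(k - 1, -1, -1, dtype=np.uint64)
    digits = (codes[:, None] >> shifts[None, :]) & np.uint64(3)
    letters = np.frombuffer(b"ACGT", dtype=np.uint8)[digits.astype(np.uint8)]
    flat = letters.tobytes().decode()
    return [flat[i : i + k] for i in range(0, len(flat), k)]


def female_specific_kmers(
    female: KmerTable,
    male: KmerTable,
    min_female_count: int = 10,
    max_male_count: int = 0,
    top_n: int | None = None,
) -> list[tuple[str, int]]:
    """k-mers abundant in the female spectrum and (near-)absent in the male.

    Ranked by female count descending, ties broken lexicographically;
    truncated to ``top_n`` when given. ``max_male_count=0`` is the strict
    "absent in males" criterion; raise it to tolerate contamination.
    """
    if female.k != male.k:
        raise ValueError(f"k mismatch: {female.k} vs {male.k}")
    hits = [
        (km, c)
        for km, c in female.counts.items()
        if c >= min_female_count and male.counts.get(km, 0) <= max_male_count
    ]
    hits.sort(key=lambda x: (-x[1], x[0]))
    return hits[:top_n] if top_n is not None else hits


# ---------------------------------------------------------------------------
# monomer assembly
# ---------------------------------------------------------------------------


@dataclass
class SatelliteMonomer:
    """A tandem-repeat unit reconstructed from its circular k-mers.

    ``sequence`` is the canonical rotation (least among rotations of the
    monomer and of its reverse complement); both strand spellings are kept
    in ``strands``.
    """

    sequence: str
    supporting_kmers: set[str] = field(default_factory=set)
    total_count: int = 0
    copy_number: float | None = None
    #: other monomer spellings with the same canonical k-mer set; non-empty
    #: when the k-mer evidence cannot distinguish them (partial strand-flip
    #: preimages), in which case ``sequence`` is the lexicographically least
    alternatives: tuple[str, ...] = ()

    @property
    def ambiguous(self) -> bool:
        return bool(self.alternatives)

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def strands(self) -> tuple[str, str]:
        return self.sequence, revcomp(self.sequence)


@dataclass
class MonomerResult:
    monomers: list[SatelliteMonomer]  # ranked by summed k-mer count
    diagnostic_path: str = ""  # longest non-branching path when no cycle

    @property
    def found(self) -> bool:
        return bool(self.monomers)


def assemble_monomer(kmers: dict[str, int] | list[tuple[str, int]]) -> MonomerResult:
    """Reconstruct tandem monomer(s) from a selected canonical k-mer set.

    Builds the overlap graph whose edges are the selected k-mers in both
    orientations ((k-1)-suffix -> (k-1)-prefix overlaps). A perfect tandem
    repeat appears as a simple cycle; the cycle is spelled into a monomer
    of length equal to the number of distinct canonical k-mers on it and
    reported in canonical rotation. Disjoint satellites yield multiple
    cycles, ranked by summed count. If the k-mers do not close a cycle, an
    empty result is returned with the longest simple path as a
    diagnostic.

    Canonical (strand-merged) k-mers occasionally admit several distinct
    monomers with the same k-mer set (partial strand-flip preimages); all
    equally supported spellings are then reported, the lexicographically
    least as ``sequence`` and the rest in ``alternatives``.
    """
    table = dict(kmers)
    if not table:
        raise ValueError("empty k-mer set")
    # oriented k-mer universe: each canonical k-mer in both spellings
    oriented: dict[str, str] = {}  # oriented k-mer -> canonical key
    for km in table:
        oriented[km] = km
        oriented[revcomp(km)] = km
    by_prefix: dict[str, list[str]] = defaultdict(list)
    for okm in oriented:
        by_prefix[okm[:-1]].append(okm)

    used: set[str] = set()  # canonical keys consumed by reported cycles
    monomers: list[SatelliteMonomer] = []
    longest_path: list[str] = []
    work_cap = 200_000  # guards against pathological branching

    for start in sorted(oriented):
        if oriented[start] in used:
            continue
        # Depth-first search with backtracking for a simple cycle through
        # oriented k-mers. Both spellings of one canonical k-mer may appear
        # on the same cycle (a monomer can contain a k-mer and its reverse
        # complement), so visited state is per oriented k-mer.
        path = [start]
        visited = {start}
        # stack of candidate-successor lists, parallel to path
        pending = [sorted(by_prefix.get(start[1:], []))]
        # strand-mixing chimeras can also close a cycle, so enumerate and
        # keep the cycle covering the most canonical k-mers in the fewest
        # nodes (a perfect tandem uses every circular k-mer, nothing twice)
        best_key: tuple[int, int] | None = None
        best_cycles: dict[str, list[str]] = {}  # spelling -> node path
        steps = 0
        while pending and steps < work_cap:
            steps += 1
            if not pending[-1]:
                pending.pop()
                visited.discard(path.pop())
                continue
            nxt = pending[-1].pop(0)
            if nxt == start and len(path) > 1:
                coverage = len({oriented[okm] for okm in path})
                key = (-coverage, len(path))
                spelling = canonical_rotation("".join(okm[-1] for okm in path))
                if best_key is None or key < best_key:
                    best_key = key
                    best_cycles = {spelling: list(path)}
                elif key == best_key:
                    best_cycles.setdefault(spelling, list(path))
                continue
            if nxt in visited or oriented[nxt] in used:
                continue
            path.append(nxt)
            visited.add(nxt)
            pending.append(sorted(by_prefix.get(nxt[1:], [])))
            if len(path) > len(longest_path):
                longest_path = list(path)
        if best_key is not None:
            spellings = sorted(best_cycles)
            cycle = best_cycles[spellings[0]]
            canon_keys = {oriented[okm] for okm in cycle}
            used |= canon_keys
            monomers.append(
                SatelliteMonomer(
                    sequence=spellings[0],
                    supporting_kmers=canon_keys,
                    total_count=sum(table[c] for c in canon_keys),
                    alternatives=tuple(spellings[1:]),
                )
            )

    monomers.sort(key=lambda m: (-m.total_count, m.sequence))
    diag = ""
    if not monomers and longest_path:
        diag = longest_path[0] + "".join(okm[-1] for okm in longest_path[1:])
    return MonomerResult(monomers=monomers, diagnostic_path=diag)


def estimate_copy_number(
    monomer: SatelliteMonomer | str,
    table: KmerTable,
    haploid_depth: float,
    read_length: int | None = None,
) -> float:
    """Genome copy number of a tandem monomer from its k-mer counts.

    In a perfect array of C copies every circular k-mer of the monomer
    occurs C times per genome copy, so C = median(count) / k-mer depth.
    The median over the monomer's circular k-mers is robust to array-edge
    k-mers and sequencing errors. When ``read_length`` is given the
    haploid base depth is converted to k-mer depth by the edge factor
    (read_length - k + 1) / read_length; otherwise ``haploid_depth`` is
    taken as the k-mer depth directly.
    """
    if haploid_depth <= 0:
        raise ValueError("haploid_depth must be > 0")
    seq = monomer.sequence if isinstance(monomer, SatelliteMonomer) else monomer
    kmer_depth = haploid_depth
    if read_length is not None:
        if read_length < table.k:
            raise ValueError("read_length < k")
        kmer_depth = haploid_depth * (read_length - table.k + 1) / read_length
    counts = []
    for km in circular_kmers(seq, table.k):
        c = table.counts.get(canonical(km))
        if c is None:
            raise ValueError(f"monomer k-mer {km} absent from table")
        counts.append(c)
    return float(np.median(counts) / kmer_depth)
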