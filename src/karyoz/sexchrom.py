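"""Neo-sex-chromosome differentiation from coverage, and Z-W strata.

Two independent signals are combined. Female read depth on the Z halves
over fully differentiated (hemizygous) regions relative to autosomes and
the pseudoautosomal region (PAR), so a windowed female:autosome coverage
ratio classifies the Z into hemizygous vs PAR segments and locates the PAR
boundary. Orthogonally, windowed Z-W alignment identity along the Z is
piecewise-constant by evolutionary stratum; least-squares changepoint
segmentation recovers the stratum boundaries and mean identities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# ---------------------------------------------------------------------------
# windowing and coverage
# ---------------------------------------------------------------------------


def tile_windows(length: int, window: int) -> list[tuple[int, int]]:
    """Non-overlapping windows over [0, length).

    A trailing partial window longer than half a window is kept on its own;
    otherwise it is merged into the previous window (so the last window may
    be up to 1.5x the nominal size).
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    if length <= 0:
        raise ValueError("length must be > 0")
    n_full, tail = divmod(length, window)
    bounds = [i * window for i in range(n_full + 1)]
    if tail > window / 2 or n_full == 0:
        bounds.append(length)
    else:
        bounds[-1] = length
    return list(zip(bounds[:-1], bounds[1:]))


@dataclass
class CoverageTrack:
    """Windowed mean depth along one chromosome."""

    chrom: str
    windows: list[tuple[int, int]]
    depth: np.ndarray  # mean depth (or ratio) per window
    sex: str = "female"

    def __len__(self) -> int:
        return len(self.windows)


def windowed_coverage(
    per_base_depth: np.ndarray, window: int, chrom: str = "chrZ", sex: str = "female"
) -> CoverageTrack:
    """Mean depth per tiling window from a per-base depth vector."""
    depth = np.asarray(per_base_depth, dtype=float)
    if depth.size == 0:
        raise ValueError("empty depth input")
    wins = tile_windows(depth.size, window)
    means = np.array([depth[s:e].mean() for s, e in wins])
    return CoverageTrack(chrom=chrom, windows=wins, depth=means, sex=sex)


def normalize_to_autosomes(
    track: CoverageTrack, autosomal_tracks: list[CoverageTrack]
) -> CoverageTrack:
    """Divide each window's depth by the genome-wide autosomal median depth."""
    auto = np.concatenate([t.depth for t in autosomal_tracks])
    med = float(np.median(auto))
    if med <= 0:
        raise ValueError("autosomal median depth is zero")
    return CoverageTrack(
        chrom=track.chrom,
        windows=list(track.windows),
        depth=track.depth / med,
        sex=track.sex,
    )


# ---------------------------------------------------------------------------
# differentiation classes
# ---------------------------------------------------------------------------

HEMIZYGOUS = "hemizygous"
PAR = "PAR"
AMBIGUOUS = "ambiguous"


@dataclass
class DiffSegment:
    start: int
    end: int
    label: str
    mean_ratio: float


@dataclass
class DifferentiationResult:
    segments: list[DiffSegment]
    par_boundaries: list[int]  # coordinates where the class switches
    ambiguous: bool


def classify_differentiation(
    ratio_track: CoverageTrack, low: float = 0.65, high: float = 0.85
) -> DifferentiationResult:
    """Classify Z windows as hemizygous (ratio <= low) or PAR-like
    (ratio >= high); intermediate windows join the nearer flanking class.

    Adjacent same-class windows merge into segments; every coordinate where
    the class switches is reported as a candidate PAR boundary. An
    all-intermediate track yields one flagged ambiguous segment.
    """
    if not 0 < low < high:
        raise ValueError("need 0 < low < high")
    r = ratio_track.depth
    cls = np.full(r.size, -1, dtype=int)  # -1 intermediate, 0 hemi, 1 par
    cls[r <= low] = 0
    cls[r >= high] = 1
    if (cls == -1).all():
        seg = DiffSegment(
            ratio_track.windows[0][0],
            ratio_track.windows[-1][1],
            AMBIGUOUS,
            float(r.mean()),
        )
        return DifferentiationResult([seg], [], True)

    # resolve intermediate runs to the nearer classified flank
    classified = np.nonzero(cls >= 0)[0]
    for i in np.nonzero(cls == -1)[0]:
        j = classified[np.argmin(np.abs(classified - i))]
        cls[i] = cls[j]

    segments: list[DiffSegment] = []
    boundaries: list[int] = []
    start_i = 0
    for i in range(1, r.size + 1):
        if i == r.size or cls[i] != cls[start_i]:
            s = ratio_track.windows[start_i][0]
            e = ratio_track.windows[i - 1][1]
            label = HEMIZYGOUS if cls[start_i] == 0 else PAR
            segments.append(DiffSegment(s, e, label, float(r[start_i:i].mean())))
            if i < r.size:
                boundaries.append(e)
            start_i = i
    return DifferentiationResult(segments, boundaries, False)


# ---------------------------------------------------------------------------
# Z-W alignment identity
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AlignmentRecord:
    """One local Z-W alignment; identity on the 0-100 scale."""

    z_start: int
    z_end: int
    w_start: int
    w_end: int
    length: int
    identity: float

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("alignment length must be > 0")


MIN_ALN_LENGTH = 65
MIN_IDENTITY = 60.0
MAX_IDENTITY = 96.0


def filter_alignments(
    records: list[AlignmentRecord],
    min_length: int = MIN_ALN_LENGTH,
    min_identity: float = MIN_IDENTITY,
    max_identity: float = MAX_IDENTITY,
) -> list[AlignmentRecord]:
    """Drop short (< 65 bp), low-identity (< 60%) and implausibly high
    identity (> 96%, typically unmasked simple repeats) alignments.
    Boundary values are kept; the operation is idempotent and preserves
    input order."""
    return [
        r
        for r in records
        if r.length >= min_length and min_identity <= r.identity <= max_identity
    ]


def windowed_identity(
    records: list[AlignmentRecord], z_length: int, window: int = 100_000
) -> tuple[list[tuple[int, int]], np.ndarray]:
    """Length-weighted mean alignment identity per tiling window on the Z.

    Each record's aligned length is apportioned to windows by Z-interval
    overlap; windows with no aligned bp get NaN.
    """
    wins = tile_windows(z_length, window)
    weight = np.zeros(len(wins))
    wsum = np.zeros(len(wins))
    for r in records:
        span = r.z_end - r.z_start
        if span <= 0:
            continue
        for i, (ws, we) in enumerate(wins):
            ov = min(r.z_end, we) - max(r.z_start, ws)
            if ov > 0:
                wlen = r.length * ov / span
                weight[i] += wlen
                wsum[i] += wlen * r.identity
    with np.errstate(invalid="ignore"):
        ident = np.where(weight > 0, wsum / np.maximum(weight, 1e-300), np.nan)
    return wins, ident


# ---------------------------------------------------------------------------
# changepoint segmentation into strata
# ---------------------------------------------------------------------------


@dataclass
class StratumSegment:
    start: int  # bp
    end: int
    first_window: int
    last_window: int  # inclusive, in the original window indexing
    mean_identity: float
    label: str = ""


def _segment_cost_matrix(y: np.ndarray) -> np.ndarray:
    """cost[i, j] = SSE of y[i:j] around its mean, via prefix sums."""
    n = y.size
    c1 = np.concatenate([[0.0], np.cumsum(y)])
    c2 = np.concatenate([[0.0], np.cumsum(y * y)])
    cost = np.full((n + 1, n + 1), np.inf)
    for i in range(n):
        for j in range(i + 1, n + 1):
            m = j - i
            s = c1[j] - c1[i]
            cost[i, j] = (c2[j] - c2[i]) - s * s / m
    return cost


def optimal_partition(y: np.ndarray, max_segments: int) -> tuple[list[float], list[list[int]]]:
    """Exact least-squares partition of a series into 1..max_segments
    piecewise-constant segments (O(K n^2) dynamic programming).

    Returns, for each k, the minimal SSE and the segment start indices.
    """
    n = y.size
    K = min(max_segments, n)
    cost = _segment_cost_matrix(y)
    dp = np.full((K + 1, n + 1), np.inf)
    back = np.zeros((K + 1, n + 1), dtype=int)
    dp[0, 0] = 0.0
    for k in range(1, K + 1):
        for j in range(k, n + 1):
            cand = dp[k - 1, k - 1 : j] + cost[k - 1 : j, j]
            i = int(np.argmin(cand)) + k - 1
            dp[k, j] = cand[i - (k - 1)]
            back[k, j] = i
    costs, starts_list = [], []
    for k in range(1, K + 1):
        costs.append(float(dp[k, n]))
        starts = []
        j = n
        for kk in range(k, 0, -1):
            i = int(back[kk, j])
            starts.append(i)
            j = i
        starts_list.append(sorted(starts))
    return costs, starts_list


def segment_strata(
    windows: list[tuple[int, int]],
    identity: np.ndarray,
    max_segments: int = 6,
    penalty: float | None = None,
) -> list[StratumSegment]:
    """Segment a windowed identity track into evolutionary strata.

    Missing (NaN) windows are skipped for the fit and absorbed into the
    containing segment on output. The number of segments is chosen by a
    BIC-style penalised least-squares criterion
    ``n log(SSE/n) + penalty * p log(n)`` with p = 2k-1 free parameters
    (k means, k-1 boundaries), capped at ``max_segments``. The default
    penalty multiplier of 2 follows the usual changepoint practice of
    penalising harder than plain BIC, which is prone to spurious splits.
    Segments are labelled S0, S1, ... in order of increasing mean identity
    (older strata are more diverged).
    """
    y = np.asarray(identity, float)
    keep = np.nonzero(~np.isnan(y))[0]
    if keep.size < 2:
        raise ValueError("need >= 2 non-missing windows")
    yk = y[keep]
    costs, starts_list = optimal_partition(yk, max_segments)
    n = yk.size
    pen = 2.0 if penalty is None else penalty
    best_k, best_bic = 1, np.inf
    for k, sse in enumerate(costs, start=1):
        p = 2 * k - 1
        bic = n * np.log(sse / n + 1e-12) + pen * p * np.log(n)
        if bic < best_bic - 1e-9:
            best_bic, best_k = bic, k
    starts = starts_list[best_k - 1]

    bounds = starts + [n]
    segments: list[StratumSegment] = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        first = int(keep[a])
        last = int(keep[b - 1])
        segments.append(
            StratumSegment(
                start=windows[first][0],
                end=windows[last][1],
                first_window=first,
                last_window=last,
                mean_identity=float(yk[a:b].mean()),
            )
        )
    order = np.argsort([s.mean_identity for s in segments], kind="stable")
    for rank, idx in enumerate(order):
        segments[idx].label = f"S{rank}"
    return segments
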