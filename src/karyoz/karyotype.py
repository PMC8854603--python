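"""Marker-block karyotypes and fusion/fission event logs.

A genome is modelled as a set of chromosomes, each an ordered list of
oriented conserved marker blocks. Markers are the unit of synteny: every
marker occurs at most once genome-wide and carries a fixed length in bp,
so chromosome sizes (and the 20-Mb micro/macrochromosome convention of
avian cytogenetics) are defined without simulating base-level sequence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Iterator

#: orientation constants
FWD = 1
REV = -1

# default avian micro/macro size threshold (bp)
MACRO_THRESHOLD = 20_000_000


@dataclass(frozen=True)
class OrientedMarker:
    """A marker id with an orientation (+1 forward, -1 reverse)."""

    marker: str
    orient: int

    def __post_init__(self) -> None:
        if self.orient not in (FWD, REV):
            raise ValueError(f"orientation must be +1 or -1, got {self.orient}")

    def flipped(self) -> "OrientedMarker":
        return OrientedMarker(self.marker, -self.orient)

    def __str__(self) -> str:  # pragma: no cover - repr aid
        return f"{'+' if self.orient == FWD else '-'}{self.marker}"


class MarkerGenome:
    """Ordered, oriented marker blocks grouped into chromosomes.

    Parameters
    ----------
    chromosomes
        Mapping chromosome id -> ordered list of ``(marker, orient)`` pairs
        or :class:`OrientedMarker`.
    marker_lengths
        Mapping marker id -> length in bp. Every marker used by a
        chromosome must have a length.
    """

    def __init__(
        self,
        chromosomes: dict[str, Iterable],
        marker_lengths: dict[str, int],
    ) -> None:
        self.chromosomes: dict[str, list[OrientedMarker]] = {}
        seen: set[str] = set()
        for chrom, markers in chromosomes.items():
            row = []
            for m in markers:
                om = m if isinstance(m, OrientedMarker) else OrientedMarker(*m)
                if om.marker in seen:
                    raise ValueError(f"marker {om.marker!r} appears more than once")
                seen.add(om.marker)
                row.append(om)
            self.chromosomes[chrom] = row
        missing = seen - set(marker_lengths)
        if missing:
            raise ValueError(f"no length for markers: {sorted(missing)[:5]}...")
        self.marker_lengths = dict(marker_lengths)

    # -- basic queries ---------------------------------------------------

    def __len__(self) -> int:
        return len(self.chromosomes)

    def markers(self) -> Iterator[str]:
        for row in self.chromosomes.values():
            for om in row:
                yield om.marker

    def marker_set(self) -> set[str]:
        return set(self.markers())

    def chrom_size(self, chrom: str) -> int:
        return sum(self.marker_lengths[om.marker] for om in self.chromosomes[chrom])

    @property
    def sizes(self) -> dict[str, int]:
        return {c: self.chrom_size(c) for c in self.chromosomes}

    def locate(self, marker: str) -> tuple[str, int, int]:
        """Return (chromosome, index, orientation) of a marker."""
        for chrom, row in self.chromosomes.items():
            for i, om in enumerate(row):
                if om.marker == marker:
                    return chrom, i, om.orient
        raise KeyError(marker)

    def copy(self) -> "MarkerGenome":
        return MarkerGenome(
            {c: list(row) for c, row in self.chromosomes.items()},
            self.marker_lengths,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MarkerGenome):
            return NotImplemented
        return self.canonical_form() == other.canonical_form()

    def canonical_form(self) -> frozenset:
        """Chromosome content up to chromosome naming and whole-chromosome flips.

        A chromosome read right-to-left with orientations flipped is the same
        molecule, so each chromosome is represented by the lexicographically
        smaller of its two readings.
        """
        out = []
        for row in self.chromosomes.values():
            fwd = tuple((om.marker, om.orient) for om in row)
            rev = tuple((om.marker, -om.orient) for om in reversed(row))
            out.append(min(fwd, rev))
        return frozenset(out)

    # -- adjacency encoding ----------------------------------------------
    # Each marker m has two extremities, its tail "m.t" and head "m.h";
    # read in the + orientation a marker runs tail -> head. An adjacency is
    # the unordered pair of extremities that abut between two consecutive
    # markers on a chromosome. This signed-end encoding distinguishes the
    # two possible junction orientations of a fusion.

    def adjacencies(self) -> set[frozenset]:
        adj: set[frozenset] = set()
        for row in self.chromosomes.values():
            for left, right in zip(row, row[1:]):
                adj.add(adjacency(left, right))
        return adj


def _right_end(om: OrientedMarker) -> str:
    return f"{om.marker}.h" if om.orient == FWD else f"{om.marker}.t"


def _left_end(om: OrientedMarker) -> str:
    return f"{om.marker}.t" if om.orient == FWD else f"{om.marker}.h"


def adjacency(left: OrientedMarker, right: OrientedMarker) -> frozenset:
    """The unordered extremity pair joining two consecutive oriented markers."""
    return frozenset((_right_end(left), _left_end(right)))


@dataclass
class RearrangementEvent:
    """One fusion or fission, optionally assigned to a tree branch.

    For a fusion, ``operands`` are the two participating chromosome ids and
    ``junction`` the signed-end adjacency created. For a fission, ``operands``
    is the single split chromosome and ``junction`` the adjacency destroyed;
    ``breakpoint_index`` is the marker index after which the split occurred.
    """

    kind: str  # "fusion" | "fission"
    branch: str | None
    operands: tuple[str, ...]
    junction: frozenset
    breakpoint_index: int | None = None
    result: tuple[str, ...] = ()
    flips: tuple[bool, bool] = (False, False)
    skipped: bool = False
    note: str = ""

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "branch": self.branch,
            "operands": list(self.operands),
            "junction": sorted(self.junction),
            "breakpoint_index": self.breakpoint_index,
            "result": list(self.result),
            "skipped": self.skipped,
            "note": self.note,
        }


@dataclass
class EventLog:
    """Ordered record of rearrangements applied along tree branches.

    Replaying the log from the ancestral genome along any root-to-tip path
    reproduces that tip exactly (round-trip invariant, tested).
    """

    events: list[RearrangementEvent] = field(default_factory=list)

    def __iter__(self) -> Iterator[RearrangementEvent]:
        return iter(self.events)

    def __len__(self) -> int:
        return len([e for e in self.events if not e.skipped])

    def append(self, event: RearrangementEvent) -> None:
        self.events.append(event)

    def on_branch(self, branch: str) -> list[RearrangementEvent]:
        return [e for e in self.events if e.branch == branch and not e.skipped]

    def to_json(self, **kwargs) -> str:
        return json.dumps([e.to_dict() for e in self.events], **kwargs)


# -- event application --------------------------------------------------


def apply_fusion(
    genome: MarkerGenome,
    chrom_a: str,
    chrom_b: str,
    flip_a: bool = False,
    flip_b: bool = False,
    new_name: str | None = None,
) -> tuple[MarkerGenome, RearrangementEvent]:
    """Concatenate two chromosomes end to end.

    ``flip_a``/``flip_b`` reverse a chromosome before joining, selecting
    which telomeric ends meet at the junction.
    """
    if chrom_a == chrom_b:
        raise ValueError("fusion requires two distinct chromosomes")
    g = genome.copy()
    row_a = g.chromosomes.pop(chrom_a)
    row_b = g.chromosomes.pop(chrom_b)
    if flip_a:
        row_a = [om.flipped() for om in reversed(row_a)]
    if flip_b:
        row_b = [om.flipped() for om in reversed(row_b)]
    name = new_name or f"{chrom_a}+{chrom_b}"
    g.chromosomes[name] = row_a + row_b
    ev = RearrangementEvent(
        kind="fusion",
        branch=None,
        operands=(chrom_a, chrom_b),
        junction=adjacency(row_a[-1], row_b[0]),
        result=(name,),
        flips=(flip_a, flip_b),
    )
    return g, ev


def apply_fission(
    genome: MarkerGenome,
    chrom: str,
    breakpoint_index: int,
    new_names: tuple[str, str] | None = None,
) -> tuple[MarkerGenome, RearrangementEvent]:
    """Split a chromosome between markers ``breakpoint_index`` and +1."""
    row = genome.chromosomes[chrom]
    if len(row) < 2:
        raise ValueError(f"cannot split single-marker chromosome {chrom!r}")
    if not 0 <= breakpoint_index < len(row) - 1:
        raise ValueError("breakpoint must be an internal junction index")
    g = genome.copy()
    row = g.chromosomes.pop(chrom)
    names = new_names or (f"{chrom}a", f"{chrom}b")
    g.chromosomes[names[0]] = row[: breakpoint_index + 1]
    g.chromosomes[names[1]] = row[breakpoint_index + 1 :]
    ev = RearrangementEvent(
        kind="fission",
        branch=None,
        operands=(chrom,),
        junction=adjacency(row[breakpoint_index], row[breakpoint_index + 1]),
        breakpoint_index=breakpoint_index,
        result=names,
    )
    return g, ev


def replay(ancestor: MarkerGenome, log: EventLog, path_branches: list[str]) -> MarkerGenome:
    """Apply the logged events of the given branches, in log order."""
    wanted = set(path_branches)
    g = ancestor.copy()
    for ev in log:
        if ev.branch not in wanted or ev.skipped:
            continue
        if ev.kind == "fusion":
            a, b = ev.operands
            g, _ = apply_fusion(g, a, b, *ev.flips, new_name=ev.result[0])
        elif ev.kind == "fission":
            g, _ = apply_fission(g, ev.operands[0], ev.breakpoint_index, new_names=tuple(ev.result))
        else:  # pragma: no cover
            raise ValueError(f"unknown event kind {ev.kind!r}")
    return g
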