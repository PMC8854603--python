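"""Synteny blocks, pairwise fusion/fission calls, and branch assignment.

The inference here inverts the karyotype simulator: given marker genomes
(or anchors imported from whole-genome alignments), build collinear synteny
blocks, call inter-chromosomal events between genome pairs, encode each
junction as a signed-end adjacency character, and place events on the
branches of a rooted species tree by Fitch small parsimony with the root
state taken from the outgroup/ancestral genome.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

from .karyotype import (
    MACRO_THRESHOLD,
    MarkerGenome,
    OrientedMarker,
    adjacency,
)
from .trees import RootedTree

# ---------------------------------------------------------------------------
# anchors and blocks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntenyAnchor:
    """One marker present in both genomes, with its position in each."""

    marker: str
    chrom_a: str
    index_a: int
    orient_a: int
    chrom_b: str
    index_b: int
    orient_b: int

    @property
    def relative_orient(self) -> int:
        return self.orient_a * self.orient_b


@dataclass
class SyntenyBlock:
    """A maximal collinear run of anchors between two chromosomes."""

    chrom_a: str
    a_start: int  # marker indices, inclusive
    a_end: int
    chrom_b: str
    b_start: int
    b_end: int
    orient: int  # +1 collinear, -1 inverted
    anchors: list[SyntenyAnchor] = field(default_factory=list)

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)


def find_anchors(a: MarkerGenome, b: MarkerGenome) -> list[SyntenyAnchor]:
    """One anchor per marker present in both genomes, ordered by position
    in genome A (the one-to-one best-hit abstraction of a whole-genome
    alignment)."""
    pos_b: dict[str, tuple[str, int, int]] = {}
    for chrom, row in b.chromosomes.items():
        for i, om in enumerate(row):
            pos_b[om.marker] = (chrom, i, om.orient)
    anchors: list[SyntenyAnchor] = []
    for chrom, row in sorted(a.chromosomes.items()):
        for i, om in enumerate(row):
            hit = pos_b.get(om.marker)
            if hit is None:
                continue
            anchors.append(
                SyntenyAnchor(om.marker, chrom, i, om.orient, hit[0], hit[1], hit[2])
            )
    return anchors


def chain_anchors(
    anchors: list[SyntenyAnchor], max_gap: int = 2, min_block: int = 1
) -> list[SyntenyBlock]:
    """Chain anchors into maximal collinear runs.

    A run extends while consecutive anchors share chromosomes and relative
    orientation, genome-B indices move monotonically in the direction the
    orientation dictates, and the skipped-marker gap in *either* genome is
    at most ``max_gap``. Runs with fewer than ``min_block`` anchors are
    discarded.
    """
    if max_gap < 0 or min_block < 1:
        raise ValueError("max_gap >= 0 and min_block >= 1 required")
    by_pair: dict[tuple[str, str], list[SyntenyAnchor]] = defaultdict(list)
    for anc in anchors:
        by_pair[(anc.chrom_a, anc.chrom_b)].append(anc)

    blocks: list[SyntenyBlock] = []
    for (ca, cb), group in sorted(by_pair.items()):
        group = sorted(group, key=lambda x: x.index_a)
        run: list[SyntenyAnchor] = []
        for anc in group:
            if run:
                prev = run[-1]
                gap_a = anc.index_a - prev.index_a - 1
                step_b = (anc.index_b - prev.index_b) * prev.relative_orient
                gap_b = step_b - 1
                ok = (
                    anc.relative_orient == prev.relative_orient
                    and gap_a <= max_gap
                    and step_b > 0
                    and gap_b <= max_gap
                )
                if not ok:
                    blocks.append(_close_run(run))
                    run = []
            run.append(anc)
        if run:
            blocks.append(_close_run(run))
    blocks = [b for b in blocks if b.n_anchors >= min_block]
    blocks.sort(key=lambda b: (b.chrom_a, b.a_start))
    return blocks


def _close_run(run: list[SyntenyAnchor]) -> SyntenyBlock:
    b_idx = [a.index_b for a in run]
    return SyntenyBlock(
        chrom_a=run[0].chrom_a,
        a_start=run[0].index_a,
        a_end=run[-1].index_a,
        chrom_b=run[0].chrom_b,
        b_start=min(b_idx),
        b_end=max(b_idx),
        orient=run[0].relative_orient,
        anchors=list(run),
    )


# ---------------------------------------------------------------------------
# pairwise event calls
# ---------------------------------------------------------------------------


@dataclass
class PairwiseEvent:
    """A fusion or fission inferred between a reference and a query genome.

    ``junction`` is the signed-end marker adjacency present in the genome
    where the two segments are joined (the query for a fusion, the
    reference for a fission): a ref->qry fusion and the reciprocal qry->ref
    fission carry the same junction.
    """

    kind: str  # "fusion" | "fission"
    ref_chroms: tuple[str, ...]
    qry_chroms: tuple[str, ...]
    junction: frozenset


@dataclass
class PairwiseCalls:
    events: list[PairwiseEvent]
    inversions: list[SyntenyBlock]
    unplaced: list[str]  # chromosomes with zero blocks


def call_pairwise_events(
    ref: MarkerGenome, qry: MarkerGenome, blocks: list[SyntenyBlock]
) -> PairwiseCalls:
    """Call inter-chromosomal events from synteny blocks.

    Two ref chromosomes whose blocks are adjacent on one qry chromosome is
    a fusion; one ref chromosome split across several qry chromosomes is a
    fission. Inverted blocks (orientation flips within the same chromosome
    pair) are intra-chromosomal and reported separately, never as events.
    """
    events: list[PairwiseEvent] = []
    inversions = [b for b in blocks if b.orient == -1]

    placed_ref = {b.chrom_a for b in blocks}
    placed_qry = {b.chrom_b for b in blocks}
    unplaced = sorted(
        [c for c in ref.chromosomes if c not in placed_ref]
        + [c for c in qry.chromosomes if c not in placed_qry]
    )

    # fusions: walk each qry chromosome in qry order
    by_qry: dict[str, list[SyntenyBlock]] = defaultdict(list)
    for b in blocks:
        by_qry[b.chrom_b].append(b)
    for qc, group in sorted(by_qry.items()):
        group = sorted(group, key=lambda b: b.b_start)
        for left, right in zip(group, group[1:]):
            if left.chrom_a != right.chrom_a:
                pos = left.b_end  # junction between qry positions b_end, next
                row = qry.chromosomes[qc]
                junc = adjacency(row[pos], row[pos + 1]) if pos + 1 < len(row) else frozenset()
                events.append(
                    PairwiseEvent(
                        kind="fusion",
                        ref_chroms=(left.chrom_a, right.chrom_a),
                        qry_chroms=(qc,),
                        junction=junc,
                    )
                )

    # fissions: walk each ref chromosome in ref order
    by_ref: dict[str, list[SyntenyBlock]] = defaultdict(list)
    for b in blocks:
        by_ref[b.chrom_a].append(b)
    for rc, group in sorted(by_ref.items()):
        group = sorted(group, key=lambda b: b.a_start)
        for left, right in zip(group, group[1:]):
            if left.chrom_b != right.chrom_b:
                pos = left.a_end
                row = ref.chromosomes[rc]
                junc = adjacency(row[pos], row[pos + 1]) if pos + 1 < len(row) else frozenset()
                events.append(
                    PairwiseEvent(
                        kind="fission",
                        ref_chroms=(rc,),
                        qry_chroms=(left.chrom_b, right.chrom_b),
                        junction=junc,
                    )
                )
    return PairwiseCalls(events=events, inversions=inversions, unplaced=unplaced)


# ---------------------------------------------------------------------------
# Fitch parsimony on adjacency characters
# ---------------------------------------------------------------------------


@dataclass
class AdjacencyCharacter:
    """Presence/absence of one signed-end adjacency across tips."""

    junction: frozenset
    tip_states: dict[str, int]  # tip label -> 0/1
    root_state: int


@dataclass
class AssignedEvent:
    kind: str  # gain -> fusion, loss -> fission
    branch: str
    junction: frozenset
    ambiguous: bool  # True when equally parsimonious placements exist


@dataclass
class BranchAssignment:
    events: list[AssignedEvent]
    per_branch: dict[str, int]
    n_tip_specific: int
    n_internal: int
    ambiguous_characters: list[frozenset]

    @property
    def n_events(self) -> int:
        return len(self.events)


def adjacency_characters(
    tip_genomes: dict[str, MarkerGenome], root_genome: MarkerGenome
) -> list[AdjacencyCharacter]:
    """Score every adjacency seen in any tip or in the root genome."""
    tip_adj = {t: g.adjacencies() for t, g in tip_genomes.items()}
    root_adj = root_genome.adjacencies()
    universe = set().union(root_adj, *tip_adj.values())
    chars = []
    for junc in sorted(universe, key=sorted):
        chars.append(
            AdjacencyCharacter(
                junction=junc,
                tip_states={t: int(junc in adj) for t, adj in tip_adj.items()},
                root_state=int(junc in root_adj),
            )
        )
    return chars


def fitch_assign(
    char: AdjacencyCharacter, tree: RootedTree
) -> tuple[list[AssignedEvent], int, bool]:
    """Minimum-change placement of one binary character on a rooted tree.

    Dynamic programming over states {absent, present} with the root state
    fixed to the outgroup/ancestral state; also counts the number of
    optimal labelings so ties are reported, not silently resolved.
    Returns (events, min_changes, unique).
    """
    cost: dict[str, list[float]] = {}
    nsol: dict[str, list[int]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            s = char.tip_states.get(node.label)
            if s is None:
                raise KeyError(f"tip {node.label!r} not scored")
            cost[node.label] = [0.0 if s == 0 else float("inf"),
                                0.0 if s == 1 else float("inf")]
            nsol[node.label] = [1 if s == 0 else 0, 1 if s == 1 else 0]
        else:
            c0 = c1 = 0.0
            n0 = n1 = 1
            for child in node.children:
                cc, cn = cost[child.label], nsol[child.label]
                for s, acc in ((0, None), (1, None)):
                    stay, switch = cc[s], cc[1 - s] + 1
                    best = min(stay, switch)
                    ways = (cn[s] if stay == best else 0) + (
                        cn[1 - s] if switch == best else 0
                    )
                    if s == 0:
                        c0, n0 = c0 + best, n0 * ways
                    else:
                        c1, n1 = c1 + best, n1 * ways
            cost[node.label] = [c0, c1]
            nsol[node.label] = [n0, n1]

    root = tree.root.label
    min_changes = cost[root][char.root_state]
    unique = nsol[root][char.root_state] == 1

    # traceback: parent-state-first tie break, flag ambiguity
    events: list[AssignedEvent] = []
    state: dict[str, int] = {root: char.root_state}
    for node in tree.preorder():
        if node.parent is None:
            continue
        ps = state[node.parent.label]
        cc = cost[node.label]
        stay, switch = cc[ps], cc[1 - ps] + 1
        s = ps if stay <= switch else 1 - ps
        state[node.label] = s
        if s != ps:
            kind = "fusion" if s == 1 else "fission"
            events.append(
                AssignedEvent(
                    kind=kind, branch=node.label, junction=char.junction,
                    ambiguous=not unique,
                )
            )
    return events, int(min_changes), unique


def assign_events_to_branches(
    tip_genomes: dict[str, MarkerGenome],
    root_genome: MarkerGenome,
    tree: RootedTree | str,
) -> BranchAssignment:
    """Place fusion (adjacency gain) and fission (adjacency loss) events on
    tree branches by Fitch parsimony, rooted at the ancestral adjacency set.

    Characters whose optimal placement is not unique are flagged and their
    events marked ambiguous rather than silently resolved.
    """
    if isinstance(tree, str):
        tree = RootedTree.from_newick(tree)
    chars = adjacency_characters(tip_genomes, root_genome)
    all_events: list[AssignedEvent] = []
    ambiguous: list[frozenset] = []
    for char in chars:
        evs, _, unique = fitch_assign(char, tree)
        if not unique:
            ambiguous.append(char.junction)
        all_events.extend(evs)

    per_branch: dict[str, int] = defaultdict(int)
    for ev in all_events:
        per_branch[ev.branch] += 1
    tips = set(tree.leaf_labels())
    n_tip = sum(1 for ev in all_events if ev.branch in tips)
    return BranchAssignment(
        events=all_events,
        per_branch=dict(per_branch),
        n_tip_specific=n_tip,
        n_internal=len(all_events) - n_tip,
        ambiguous_characters=ambiguous,
    )


# ---------------------------------------------------------------------------
# size classification
# ---------------------------------------------------------------------------

MICRO_MACRO = "micro-macro"
MICRO_MICRO = "micro-micro"
MACRO_MACRO = "macro-macro"


def classify_fusion_sizes(
    fusion_sizes: list[tuple[int, int]], threshold: int = MACRO_THRESHOLD
) -> dict[str, int]:
    """Classify fusions by operand size at the time of fusion.

    A chromosome of size >= ``threshold`` (default 20 Mb) is a
    macrochromosome; the boundary value itself counts as macro.
    """
    counts = {MICRO_MACRO: 0, MICRO_MICRO: 0, MACRO_MACRO: 0}
    for a, b in fusion_sizes:
        macro_a, macro_b = a >= threshold, b >= threshold
        if macro_a and macro_b:
            counts[MACRO_MACRO] += 1
        elif macro_a or macro_b:
            counts[MICRO_MACRO] += 1
        else:
            counts[MICRO_MICRO] += 1
    return counts


def fusion_operand_sizes(
    ancestor: MarkerGenome, tree: RootedTree | str, log
) -> list[tuple[int, int]]:
    """Replay a simulated event log and record both operand sizes (bp) at
    the moment of each fusion."""
    from .karyotype import apply_fission, apply_fusion

    if isinstance(tree, str):
        tree = RootedTree.from_newick(tree)
    sizes: dict[int, tuple[int, int]] = {}
    genomes = {tree.root.label: ancestor.copy()}
    by_branch: dict[str, list] = defaultdict(list)
    order: dict[int, int] = {}
    for i, ev in enumerate(log.events):
        by_branch[ev.branch].append(ev)
        order[id(ev)] = i
    for node in tree.preorder():
        if node.parent is None:
            continue
        g = genomes[node.parent.label].copy()
        for ev in by_branch.get(node.label, []):
            if ev.skipped:
                continue
            if ev.kind == "fusion":
                a, b = ev.operands
                sizes[order[id(ev)]] = (g.chrom_size(a), g.chrom_size(b))
                g, _ = apply_fusion(g, a, b, *ev.flips, new_name=ev.result[0])
            else:
                g, _ = apply_fission(
                    g, ev.operands[0], ev.breakpoint_index, new_names=tuple(ev.result)
                )
        genomes[node.label] = g
    return [sizes[i] for i in sorted(sizes)]
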