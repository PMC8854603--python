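"""Forward simulators with known ground truth for every analysis stage.

Each generator emulates the statistical structure one downstream analysis
assumes — marker karyotypes evolving by fusion/fission on a tree, a Z/W
pair with stepwise-diverged strata and a pseudoautosomal region, sexed
short-read sets, a W-specific tandem satellite, a binned Hi-C-like contact
matrix with TAD structure, and negative-binomial expression counts with
copy-number dosage effects. All randomness flows from one integer seed;
sub-stage seeds are derived deterministically from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .karyotype import (
    EventLog,
    MarkerGenome,
    RearrangementEvent,
    apply_fission,
    apply_fusion,
)
from .sequtil import BASES, random_seq, revcomp
from .trees import RootedTree

# ---------------------------------------------------------------------------
# karyotype evolution
# ---------------------------------------------------------------------------


def random_ancestor(
    n_macro: int = 10,
    n_micro: int = 28,
    markers_per_macro: int = 20,
    markers_per_micro: int = 4,
    macro_marker_bp: int = 3_000_000,
    micro_marker_bp: int = 1_500_000,
    seed: int | np.random.Generator = 0,
) -> MarkerGenome:
    """A typical avian-like ancestral karyotype: ~10 macrochromosomes
    (>=20 Mb) and ~28 microchromosomes (<20 Mb), built from fixed-length
    marker blocks."""
    chroms: dict[str, list] = {}
    lengths: dict[str, int] = {}
    mid = 0
    for i in range(n_macro):
        row = []
        for _ in range(markers_per_macro):
            name = f"m{mid}"
            mid += 1
            lengths[name] = macro_marker_bp
            row.append((name, 1))
        chroms[f"chr{i + 1}"] = row
    for i in range(n_micro):
        row = []
        for _ in range(markers_per_micro):
            name = f"m{mid}"
            mid += 1
            lengths[name] = micro_marker_bp
            row.append((name, 1))
        chroms[f"chr{n_macro + i + 1}"] = row
    return MarkerGenome(chroms, lengths)


def simulate_karyotype_evolution(
    ancestor: MarkerGenome,
    tree: RootedTree | str,
    fusion_rate: float = 0.5,
    fission_rate: float = 0.5,
    seed: int = 0,
    n_events: int | None = None,
) -> tuple[dict[str, MarkerGenome], EventLog]:
    """Evolve an ancestral karyotype along a rooted tree by fusions/fissions.

    Events per branch are Poisson with mean ``rate x branch length``; when
    ``n_events`` is given, exactly that many events are placed instead,
    multinomially across branches proportional to branch length, with the
    fusion:fission mix set by the two rates. A fusion concatenates two
    uniformly chosen chromosomes with a random junction orientation; a
    fission splits a uniformly chosen chromosome at a uniform internal
    junction. A fission drawn for a genome whose chromosomes are all
    single-marker is recorded as skipped.

    Returns the map tip label -> genome and the :class:`EventLog`, whose
    replay from the ancestor reproduces every tip exactly.
    """
    if isinstance(tree, str):
        tree = RootedTree.from_newick(tree)
    if len(ancestor) == 0:
        raise ValueError("ancestor genome is empty")
    if fusion_rate < 0 or fission_rate < 0:
        raise ValueError("rates must be >= 0")
    rng = np.random.default_rng(seed)

    branches = tree.branches()
    blens = np.array([max(tree.nodes[b].edge_length, 0.0) for b in branches])
    if n_events is not None:
        if blens.sum() == 0:
            blens = np.ones_like(blens)
        counts = rng.multinomial(n_events, blens / blens.sum())
        per_branch = dict(zip(branches, counts))
    else:
        total_rate = fusion_rate + fission_rate
        per_branch = {
            b: int(rng.poisson(total_rate * L)) for b, L in zip(branches, blens)
        }
    p_fusion = (
        fusion_rate / (fusion_rate + fission_rate)
        if fusion_rate + fission_rate > 0
        else 0.0
    )

    log = EventLog()
    genomes: dict[str, MarkerGenome] = {tree.root.label: ancestor.copy()}
    tip_genomes: dict[str, MarkerGenome] = {}
    counter = [0]

    for node in tree.preorder():
        if node.parent is None:
            continue
        g = genomes[node.parent.label].copy()
        for _ in range(per_branch[node.label]):
            do_fusion = rng.random() < p_fusion
            if do_fusion and len(g) < 2:
                do_fusion = False  # cannot fuse a single chromosome
            if do_fusion:
                a, b = rng.choice(sorted(g.chromosomes), size=2, replace=False)
                counter[0] += 1
                g, ev = apply_fusion(
                    g,
                    a,
                    b,
                    flip_a=bool(rng.random() < 0.5),
                    flip_b=bool(rng.random() < 0.5),
                    new_name=f"fus{counter[0]}",
                )
            else:
                splittable = sorted(
                    c for c, row in g.chromosomes.items() if len(row) >= 2
                )
                if not splittable:
                    log.append(
                        RearrangementEvent(
                            kind="fission",
                            branch=node.label,
                            operands=(),
                            junction=frozenset(),
                            skipped=True,
                            note="no multi-marker chromosome to split",
                        )
                    )
                    continue
                c = rng.choice(splittable)
                idx = int(rng.integers(0, len(g.chromosomes[c]) - 1))
                counter[0] += 1
                g, ev = apply_fission(
                    g, c, idx, new_names=(f"fis{counter[0]}a", f"fis{counter[0]}b")
                )
            ev.branch = node.label
            log.append(ev)
        genomes[node.label] = g
        if node.is_leaf:
            tip_genomes[node.label] = g
    return tip_genomes, log


# ---------------------------------------------------------------------------
# Z/W divergence strata
# ---------------------------------------------------------------------------


@dataclass
class StrataSpec:
    """Ordered strata tiling the Z: ``(start, end, target_identity)`` in bp,
    identities on [0, 1]; the PAR is the interval with identity 1.0."""

    intervals: list[tuple[int, int, float]]

    def validate(self, z_length: int) -> None:
        ivs = sorted(self.intervals)
        if not ivs or ivs[0][0] != 0 or ivs[-1][1] != z_length:
            raise ValueError("strata must tile [0, z_length)")
        for (s0, e0, p0), (s1, e1, p1) in zip(ivs, ivs[1:]):
            if e0 != s1:
                raise ValueError("strata must tile without gaps or overlap")
        for s, e, p in ivs:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"identity {p} outside [0, 1]")

    @property
    def boundaries(self) -> list[int]:
        ivs = sorted(self.intervals)
        return [e for _, e, _ in ivs[:-1]]


def simulate_zw(
    z_length: int,
    spec: StrataSpec,
    seed: int = 0,
) -> tuple[str, str, list[int]]:
    """Simulate a Z sequence and its diverged W gametolog.

    Within each stratum, the W copy differs from the Z by i.i.d. per-site
    substitutions at rate ``1 - target_identity`` (substitutions only, no
    indels — the downstream statistic is windowed percent identity). A
    stratum with identity 1.0 (the PAR) is copied verbatim.
    """
    spec.validate(z_length)
    rng = np.random.default_rng(seed)
    z = random_seq(z_length, rng)
    z_arr = np.frombuffer(z.encode(), dtype="S1").copy()
    w_arr = z_arr.copy()
    base_bytes = np.frombuffer(b"ACGT", dtype="S1")
    for start, end, ident in sorted(spec.intervals):
        rate = 1.0 - ident
        if rate <= 0:
            continue
        span = end - start
        hits = np.nonzero(rng.random(span) < rate)[0] + start
        # substitute to a uniformly chosen *different* base
        offs = rng.integers(1, 4, size=hits.size)
        cur = np.searchsorted(base_bytes, w_arr[hits])
        w_arr[hits] = base_bytes[(cur + offs) % 4]
    return z, w_arr.tobytes().decode(), spec.boundaries


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------


@dataclass
class ReadSet:
    """Uniform-length reads with a sex label and nominal per-copy depth."""

    reads: list[str]
    sex: str
    depth: float
    read_length: int


def simulate_reads(
    sequences: dict[str, str],
    copy_numbers: dict[str, int],
    depth: float = 30.0,
    read_length: int = 100,
    sex: str = "female",
    seed: int = 0,
) -> ReadSet:
    """Draw error-free reads uniformly, weighting each sequence by its
    copy number (ZZ male / ZW female / diploid autosomes). ``depth`` is the
    per-haploid-copy coverage; the read count is Poisson around
    total weighted length x depth / read length. Reads come off either
    strand with equal probability.
    """
    if depth <= 0:
        raise ValueError("depth must be > 0")
    names = sorted(n for n in sequences if copy_numbers.get(n, 0) > 0)
    if not names:
        raise ValueError("no sequence with positive copy number")
    shortest = min(len(sequences[n]) for n in names)
    if read_length > shortest:
        raise ValueError("read_length exceeds shortest sequence")
    rng = np.random.default_rng(seed)
    weights = np.array([len(sequences[n]) * copy_numbers[n] for n in names], float)
    total = weights.sum()
    n_reads = int(rng.poisson(total * depth / read_length))
    per_seq = rng.multinomial(n_reads, weights / total)
    reads: list[str] = []
    for name, count in zip(names, per_seq):
        seq = sequences[name]
        starts = rng.integers(0, len(seq) - read_length + 1, size=count)
        flip = rng.random(count) < 0.5
        for start, fl in zip(starts, flip):
            read = seq[start : start + read_length]
            reads.append(revcomp(read) if fl else read)
    # interleave deterministically so read order carries no sequence signal
    order = rng.permutation(len(reads))
    reads = [reads[i] for i in order]
    return ReadSet(reads=reads, sex=sex, depth=depth, read_length=read_length)


def simulate_satellite_array(
    w: str,
    monomer: str,
    copies: int,
    insertion_point: int | None = None,
    per_copy_mutation: float = 0.0,
    seed: int = 0,
) -> str:
    """Insert a perfect (optionally lightly mutated) tandem array of
    ``copies`` monomer repeats into a W sequence."""
    if copies < 0:
        raise ValueError("copies must be >= 0")
    if insertion_point is None:
        insertion_point = len(w)
    if copies == 0:
        return w
    if per_copy_mutation > 0:
        rng = np.random.default_rng(seed)
        units = []
        for _ in range(copies):
            unit = list(monomer)
            for j in range(len(unit)):
                if rng.random() < per_copy_mutation:
                    unit[j] = BASES[int(rng.integers(0, 4))]
            units.append("".join(unit))
        array = "".join(units)
    else:
        array = monomer * copies
    return w[:insertion_point] + array + w[insertion_point:]


# ---------------------------------------------------------------------------
# Hi-C-like contact matrix
# ---------------------------------------------------------------------------


def simulate_contact_matrix(
    n_bins: int,
    tad_boundaries: list[int],
    decay: float = 1.0,
    boundary_contrast: float = 0.5,
    scale: float = 1000.0,
    noise: str = "poisson",
    seed: int = 0,
) -> tuple[np.ndarray, list[int]]:
    """A symmetric binned contact matrix with distance decay and TADs.

    The expected contact between bins i and j is
    ``scale * (|i-j| + 1)^(-decay) * boundary_contrast^(#boundaries crossed)``;
    counts are Poisson around that expectation (``noise="none"`` returns the
    expectation itself). ``boundary_contrast = 1`` gives no TAD structure.
    """
    if not 0 < boundary_contrast <= 1:
        raise ValueError("boundary_contrast must be in (0, 1]")
    rng = np.random.default_rng(seed)
    idx = np.arange(n_bins)
    dist = np.abs(idx[:, None] - idx[None, :])
    expected = scale * (dist + 1.0) ** (-decay)
    # domain index of each bin; |domain_i - domain_j| = boundaries crossed
    domain = np.zeros(n_bins, dtype=int)
    for b in sorted(tad_boundaries):
        domain[b:] += 1
    crossed = np.abs(domain[:, None] - domain[None, :])
    expected = expected * boundary_contrast**crossed
    if noise == "none":
        return expected, sorted(tad_boundaries)
    upper = rng.poisson(np.triu(expected))
    mat = np.triu(upper, 1) + np.triu(upper, 1).T + np.diag(np.diag(upper))
    return mat.astype(float), sorted(tad_boundaries)


# ---------------------------------------------------------------------------
# expression counts with dosage effects
# ---------------------------------------------------------------------------

# per-sex gene copy number by class (female is the heterogametic ZW sex)
GENE_CLASS_COPIES = {
    "autosomal": {"male": 2, "female": 2},
    "Z-hemizygous": {"male": 2, "female": 1},
    "Z-PAR": {"male": 2, "female": 2},
    "Z-gametolog": {"male": 2, "female": 1},
    "W-gametolog": {"male": 0, "female": 1},
}


def simulate_expression(
    n_genes: dict[str, int],
    tissues: list[str] | None = None,
    replicates: int = 2,
    baseline_mean: float = 200.0,
    dispersion: float = 0.1,
    gene_length_bp: tuple[int, int] = (500, 5000),
    zw_pairs: int = 0,
    w_factor: float = 0.5,
    upregulated_pairs: tuple[int, ...] = (),
    upregulated_factor: float = 1.5,
    seed: int = 0,
):
    """Count table for a no-dosage-compensation model: expression scales
    with copy number, so Z-hemizygous genes are expected 2:1 male:female.

    ``zw_pairs`` adds surviving Z-W gametolog pairs (classes
    ``Z-gametolog``/``W-gametolog``) whose per-tissue baselines are shared
    within each pair, making their expression profiles concordant across
    tissues; the W copy is globally downregulated by ``w_factor`` except
    for the pair indices in ``upregulated_pairs``, which get
    ``upregulated_factor`` instead.

    Counts are negative-binomial around copy-scaled per-gene baseline means
    (log-normal across genes and tissues); ``dispersion = 0`` returns the
    deterministic means, the exact-ratio limit. Returns
    ``(counts, samples, genes)`` as pandas DataFrames: genes x samples
    integer counts, a sample sheet with sex and tissue, and per-gene class
    and length (paired gametologs carry their ``pair`` index).
    """
    import pandas as pd

    tissues = tissues or ["tissue1"]
    rng = np.random.default_rng(seed)
    rows, classes, lengths, pair_ids = [], [], [], []
    for cls in sorted(n_genes):
        if cls not in GENE_CLASS_COPIES:
            raise ValueError(f"unknown gene class {cls!r}")
        for i in range(n_genes[cls]):
            rows.append(f"{cls}_g{i}")
            classes.append(cls)
            lengths.append(int(rng.integers(*gene_length_bp)))
            pair_ids.append(-1)
    for i in range(zw_pairs):
        length = int(rng.integers(*gene_length_bp))
        for cls in ("Z-gametolog", "W-gametolog"):
            rows.append(f"{cls}_p{i}")
            classes.append(cls)
            lengths.append(length)
            pair_ids.append(i)

    n_total = len(rows)
    # per-gene, per-tissue baseline; gametolog pairs share their Z partner's
    base = baseline_mean * rng.lognormal(0.0, 0.5, size=(n_total, len(tissues)))
    w_scale = np.ones(n_total)
    for idx in range(n_total):
        if classes[idx] == "W-gametolog" and pair_ids[idx] >= 0:
            z_idx = rows.index(f"Z-gametolog_p{pair_ids[idx]}")
            base[idx] = base[z_idx]
            w_scale[idx] = (
                upregulated_factor
                if pair_ids[idx] in upregulated_pairs
                else w_factor
            )

    sample_names, sexes, tissue_col = [], [], []
    for tissue in tissues:
        for sex in ("female", "male"):
            for r in range(replicates):
                sample_names.append(f"{tissue}_{sex}_{r + 1}")
                sexes.append(sex)
                tissue_col.append(tissue)

    counts = np.zeros((n_total, len(sample_names)), dtype=int)
    tissue_index = {t: i for i, t in enumerate(tissues)}
    for j, (sex, tis) in enumerate(zip(sexes, tissue_col)):
        cps = np.array([GENE_CLASS_COPIES[c][sex] for c in classes], float)
        mu = base[:, tissue_index[tis]] * cps / 2.0 * w_scale
        if dispersion <= 0:
            counts[:, j] = np.round(mu).astype(int)
        else:
            r = 1.0 / dispersion
            with np.errstate(divide="ignore", invalid="ignore"):
                p = r / (r + mu)
            draw = np.where(mu > 0, rng.negative_binomial(r, np.clip(p, 1e-12, 1.0)), 0)
            counts[:, j] = draw
    genes = pd.DataFrame(
        {"gene": rows, "class": classes, "length": lengths, "pair": pair_ids}
    ).set_index("gene")
    samples = pd.DataFrame(
        {"sample": sample_names, "sex": sexes, "tissue": tissue_col}
    ).set_index("sample")
    counts_df = pd.DataFrame(counts, index=genes.index, columns=samples.index)
    return counts_df, samples, genes
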