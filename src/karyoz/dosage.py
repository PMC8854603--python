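"""Expression dosage and repeat-composition summaries for sex chromosomes.

Avian sex chromosomes lack chromosome-wide dosage compensation, so genes
whose W copy has been lost (hemizygous in females) are expressed at about
twice the level in ZZ males as in ZW females. This module computes TPM
from raw counts, summarises male:female ratios per gene class and tissue,
measures Z-W gametolog expression concordance, and tabulates TE content
per evolutionary stratum and W-gametolog retention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

# ---------------------------------------------------------------------------
# TPM
# ---------------------------------------------------------------------------


def tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts per million: (count/length) scaled to sum 1e6 per sample."""
    lengths = lengths.reindex(counts.index)
    if (lengths <= 0).any() or lengths.isna().any():
        raise ValueError("all gene lengths must be positive")
    rate = counts.div(lengths, axis=0)
    lib = rate.sum(axis=0)
    if (lib <= 0).any():
        bad = lib.index[lib <= 0].tolist()
        raise ValueError(f"zero library size in samples: {bad}")
    return rate.div(lib, axis=1) * 1e6


def group_means(
    tpm_matrix: pd.DataFrame, samples: pd.DataFrame
) -> pd.DataFrame:
    """Mean TPM over biological replicates, per (tissue, sex) group.

    Columns become a MultiIndex (tissue, sex).
    """
    keys = samples.loc[tpm_matrix.columns, ["tissue", "sex"]]
    grouped = tpm_matrix.T.groupby([keys["tissue"], keys["sex"]]).mean().T
    grouped.columns.names = ["tissue", "sex"]
    return grouped


# ---------------------------------------------------------------------------
# male:female dosage ratios
# ---------------------------------------------------------------------------


def mf_ratio(
    means: pd.DataFrame,
    classes: pd.Series,
    expression_floor: float = 1.0,
    pseudocount: float = 0.1,
) -> pd.DataFrame:
    """Median male:female TPM ratio per gene class and tissue.

    Per gene and tissue, ratio = (male mean + eps)/(female mean + eps);
    genes below the expression floor in both sexes are excluded. Returns a
    class x tissue table of medians (NaN where a class is empty after
    filtering).
    """
    if expression_floor < 0:
        raise ValueError("floor must be >= 0")
    classes = classes.reindex(means.index)
    tissues = sorted(means.columns.get_level_values("tissue").unique())
    out = {}
    for tissue in tissues:
        male = means[(tissue, "male")]
        female = means[(tissue, "female")]
        expressed = (male >= expression_floor) | (female >= expression_floor)
        ratio = (male + pseudocount) / (female + pseudocount)
        col = {}
        for cls in sorted(classes.dropna().unique()):
            sel = (classes == cls) & expressed
            col[cls] = float(ratio[sel].median()) if sel.any() else np.nan
        out[tissue] = col
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Z-W gametolog concordance
# ---------------------------------------------------------------------------


@dataclass
class GametologConcordance:
    per_pair: pd.DataFrame  # correlation + W:Z ratio per pair
    pooled_correlation: float  # rank correlation over all (pair, tissue) points
    slope: float  # OLS slope of W on Z, log1p scale
    upregulated: list[str]  # pairs with mean W expression above Z


def zw_gametolog_concordance(
    means: pd.DataFrame, pairs: list[tuple[str, str]]
) -> GametologConcordance:
    """Expression concordance of Z-W gametolog pairs across tissues.

    For each (z_gene, w_gene) pair: Spearman correlation of log(1+TPM)
    across tissues and the mean W:Z ratio; pooled over pairs, the Spearman
    correlation of log(1+TPM) and the OLS slope of W on Z on the TPM
    scale. Pairs whose mean W expression exceeds the Z copy are flagged
    as upregulated.
    """
    tissues = sorted(means.columns.get_level_values("tissue").unique())
    # W genes are female-only; compare against the Z copy in females
    rows = []
    zs, ws = [], []
    upregulated = []
    for z_gene, w_gene in pairs:
        z = np.array([means.loc[z_gene, (t, "female")] for t in tissues], float)
        w = np.array([means.loc[w_gene, (t, "female")] for t in tissues], float)
        lz, lw = np.log1p(z), np.log1p(w)
        if len(tissues) >= 3 and np.std(lz) > 0 and np.std(lw) > 0:
            rho = float(stats.spearmanr(lz, lw).statistic)
        elif np.array_equal(lz, lw):
            rho = 1.0
        else:
            rho = np.nan
        wz = float((w.mean() + 1e-9) / (z.mean() + 1e-9))
        rows.append({"z_gene": z_gene, "w_gene": w_gene, "rho": rho, "wz_ratio": wz})
        zs.append(z)
        ws.append(w)
        if w.mean() > z.mean():
            upregulated.append(w_gene)
    zcat, wcat = np.concatenate(zs), np.concatenate(ws)
    pooled = (
        float(stats.spearmanr(np.log1p(zcat), np.log1p(wcat)).statistic)
        if np.std(zcat) > 0
        else np.nan
    )
    slope = float(np.polyfit(zcat, wcat, 1)[0]) if np.std(zcat) > 0 else np.nan
    return GametologConcordance(
        per_pair=pd.DataFrame(rows).set_index("z_gene"),
        pooled_correlation=pooled,
        slope=slope,
        upregulated=upregulated,
    )


# ---------------------------------------------------------------------------
# TE content by stratum
# ---------------------------------------------------------------------------

#: overlap resolution priority, highest first
REPEAT_PRIORITY = ("satellite", "LTR", "CR1", "other-TE")
NO_REPEAT = "none"


def te_content_by_stratum(
    repeats: list[tuple[int, int, str]],
    strata: list[tuple[int, int, str]],
    priority: tuple[str, ...] = REPEAT_PRIORITY,
) -> pd.DataFrame:
    """Percent of each stratum covered by each repeat class.

    ``repeats`` are (start, end, class) intervals; overlapping annotations
    are resolved per base by the priority order (satellite > LTR > CR1 >
    other-TE by default). Unannotated bases count as "none"; percentages
    per stratum sum to 100. Strata must tile the analysed region.
    """
    strata = sorted(strata)
    for (s0, e0, _), (s1, e1, _) in zip(strata, strata[1:]):
        if e0 != s1:
            raise ValueError("strata must tile the region without gaps")
    region_start, region_end = strata[0][0], strata[-1][1]
    rank = {cls: i for i, cls in enumerate(priority)}

    # paint classes onto breakpoint-delimited segments, priority-resolved
    cuts = sorted(
        {region_start, region_end}
        | {b for s, e, _ in strata for b in (s, e)}
        | {min(max(x, region_start), region_end) for s, e, _ in repeats for x in (s, e)}
    )
    seg_class: list[tuple[int, int, str]] = []
    for a, b in zip(cuts[:-1], cuts[1:]):
        best = None
        for s, e, cls in repeats:
            if s < b and e > a:  # covers the whole [a,b) segment by construction
                if cls not in rank:
                    raise ValueError(f"unknown repeat class {cls!r}")
                if best is None or rank[cls] < rank[best]:
                    best = cls
        seg_class.append((a, b, best or NO_REPEAT))

    classes = list(priority) + [NO_REPEAT]
    out = {}
    for s, e, name in strata:
        cover = dict.fromkeys(classes, 0.0)
        for a, b, cls in seg_class:
            ov = min(b, e) - max(a, s)
            if ov > 0:
                cover[cls] += ov
        length = e - s
        out[name] = {cls: 100.0 * bp / length for cls, bp in cover.items()}
    return pd.DataFrame(out).T[classes]


def gene_retention(ancestral: dict[str, int], surviving: dict[str, int]) -> pd.Series:
    """Percent of ancestral gene content retained on the W, per stratum.

    Takes externally supplied ancestral and surviving gametolog counts
    (no gene annotation is performed here).
    """
    out = {}
    for stratum, n_anc in ancestral.items():
        n_sur = surviving.get(stratum, 0)
        if n_anc <= 0:
            raise ValueError(f"ancestral count must be > 0 for {stratum!r}")
        if n_sur > n_anc:
            raise ValueError(f"surviving > ancestral for {stratum!r}")
        out[stratum] = 100.0 * n_sur / n_anc
    return pd.Series(out, name="retention_pct")
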