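"""Multi-omics integration: differential RNA, protein LFQ and bound-gene sets.

Implements the proteomics missing-value/ratio rules of a 4-vs-4 label-free
design, significance-set construction and intersections (the "validated
target" logic), Fisher overlap tests with odds ratios and Woolf confidence
intervals, Wilcoxon rank-sum fold-change shift tests, published-transcriptome
membership rules, the >=3-of-8 dendritic consensus, row z-scoring for
heatmaps, and background-restricted hypergeometric gene-set enrichment with
Benjamini-Hochberg correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

RNA_PADJ_THRESHOLD = 0.01
PROTEIN_PADJ_THRESHOLD = 0.05
PUBLISHED_FDR_THRESHOLD = 0.01


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# proteomics missing-value / ratio rules
# ---------------------------------------------------------------------------

KD_COLS = [f"KD{i}" for i in range(1, 5)]
CTRL_COLS = [f"CTRL{i}" for i in range(1, 5)]


def proteomics_ratios(
    table: pd.DataFrame,
    kd_cols: Optional[List[str]] = None,
    ctrl_cols: Optional[List[str]] = None,
    log2_transform: bool = True,
) -> pd.DataFrame:
    """Apply the 4v4 missing-value rules and compute log2 KD/CTRL ratios.

    Per protein: all four values missing in one condition (with a
    quantifiable other condition) -> flag ``infinite`` with the sign of the
    observed condition; two or three missing in a condition ->
    ``non_quantifiable``; at most one missing per condition -> ratio =
    mean(log2 KD present) - mean(log2 CTRL present) over the present samples.

    ``log2_transform=False`` treats the stored intensities as already log2.
    """
    kd_cols = kd_cols or KD_COLS
    ctrl_cols = ctrl_cols or CTRL_COLS
    if len(kd_cols) != 4 or len(ctrl_cols) != 4:
        raise ValueError("the missing-value rules are defined for a 4-vs-4 design")

    out = table.copy()
    ratios: List[float] = []
    flags: List[str] = []
    for _, row in table.iterrows():
        kd = row[kd_cols].to_numpy(dtype=float)
        ctrl = row[ctrl_cols].to_numpy(dtype=float)
        if log2_transform:
            with np.errstate(divide="ignore", invalid="ignore"):
                kd = np.log2(kd)
                ctrl = np.log2(ctrl)
        kd_n = int(np.sum(~np.isnan(kd)))
        ctrl_n = int(np.sum(~np.isnan(ctrl)))
        if kd_n == 0 and ctrl_n == 0:
            flags.append("non_quantifiable")
            ratios.append(np.nan)
        elif kd_n == 0:
            if ctrl_n >= 3:
                flags.append("infinite")
                ratios.append(-np.inf)  # absent in KD => down upon knockdown
            else:
                flags.append("non_quantifiable")
                ratios.append(np.nan)
        elif ctrl_n == 0:
            if kd_n >= 3:
                flags.append("infinite")
                ratios.append(np.inf)
            else:
                flags.append("non_quantifiable")
                ratios.append(np.nan)
        elif kd_n <= 2 or ctrl_n <= 2:
            flags.append("non_quantifiable")
            ratios.append(np.nan)
        else:
            flags.append("quantified")
            ratios.append(float(np.nanmean(kd) - np.nanmean(ctrl)))
    out["ratio_flag"] = flags
    out["log2_ratio"] = ratios
    return out


# ---------------------------------------------------------------------------
# significance sets and intersections
# ---------------------------------------------------------------------------

@dataclass
class TargetSets:
    rna_significant: Set[str]
    protein_significant: Set[str]
    bound: Set[str]
    rna_and_protein: Set[str]
    validated: Set[str]  # bound AND rna AND protein
    validated_concordant: Set[str]
    concordant_fraction: float  # among rna+protein genes with a numeric ratio


def build_sets(
    diff: pd.DataFrame,
    prot: pd.DataFrame,
    bound_genes: Iterable[str],
    rna_threshold: float = RNA_PADJ_THRESHOLD,
    protein_threshold: float = PROTEIN_PADJ_THRESHOLD,
) -> TargetSets:
    """Significance sets and their intersections over shared gene identifiers.

    ``diff`` carries gene_id/log2FoldChange/padj; ``prot`` must already carry
    ratio flags (see :func:`proteomics_ratios`) plus gene_id and padj.
    Infinite-ratio proteins count as significant regulation (extreme change)
    but are excluded from the numeric concordance fraction denominator only
    when their sign is undefined.
    """
    for name, frame, col in (("RNA", diff, "gene_id"), ("protein", prot, "gene_id")):
        dup = frame[col][frame[col].duplicated()].tolist()
        if dup:
            raise ValueError(f"duplicate {name} gene identifiers: {sorted(set(dup))}")

    rna_sig = set(diff.loc[diff["padj"] < rna_threshold, "gene_id"])
    quantifiable = prot["ratio_flag"].isin(["quantified", "infinite"])
    prot_sig = set(
        prot.loc[(prot["padj"] < protein_threshold) & quantifiable, "gene_id"]
    )
    bound = set(bound_genes)

    both = rna_sig & prot_sig
    validated = both & bound

    rna_fc = diff.set_index("gene_id")["log2FoldChange"]
    prot_fc = prot.set_index("gene_id")["log2_ratio"]
    concordant = set()
    n_compared = 0
    for g in sorted(both):
        r, q = rna_fc.get(g), prot_fc.get(g)
        if r is None or q is None or np.isnan(q):
            continue
        n_compared += 1
        if np.sign(r) == np.sign(q):
            concordant.add(g)
    frac = len(concordant) / n_compared if n_compared else float("nan")
    return TargetSets(
        rna_significant=rna_sig,
        protein_significant=prot_sig,
        bound=bound,
        rna_and_protein=both,
        validated=validated,
        validated_concordant=validated & concordant,
        concordant_fraction=frac,
    )


# ---------------------------------------------------------------------------
# overlap and shift tests
# ---------------------------------------------------------------------------

@dataclass
class OverlapResult:
    table: Tuple[Tuple[int, int], Tuple[int, int]]
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float


def overlap_test(
    set_a: Iterable[str], set_b: Iterable[str], universe: Iterable[str]
) -> OverlapResult:
    """Fisher's exact test for the overlap of two sets within a universe.

    The odds ratio is the cross-product (ad)/(bc); a Haldane-Anscombe 0.5
    correction is applied if (and only if) any cell is zero, and the 95% CI
    is Woolf's ``exp(log OR +- 1.96 * sqrt(sum 1/cell))`` on the corrected
    table.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    a_set, b_set = set(set_a) & universe, set(set_b) & universe
    a = len(a_set & b_set)
    b = len(a_set - b_set)
    c = len(b_set - a_set)
    d = len(universe) - a - b - c
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    cells = np.array([a, b, c, d], dtype=float)
    if np.any(cells == 0):
        cells = cells + 0.5
    or_ = (cells[0] * cells[3]) / (cells[1] * cells[2])
    se = float(np.sqrt(np.sum(1.0 / cells)))
    ci_low = float(np.exp(np.log(or_) - 1.96 * se))
    ci_high = float(np.exp(np.log(or_) + 1.96 * se))
    return OverlapResult(((a, b), (c, d)), float(or_), ci_low, ci_high, float(p))


def shift_test(group: Sequence[float], complement: Sequence[float]) -> Tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test with tie correction.

    Returns (p-value, median difference group - complement).
    """
    group = np.asarray(group, dtype=float)
    complement = np.asarray(complement, dtype=float)
    if group.size == 0 or complement.size == 0:
        raise ValueError("both groups must be nonempty")
    if min(group.size, complement.size) < 3:
        warnings.warn("group smaller than 3; rank-sum p-value is unreliable")
    res = stats.mannwhitneyu(group, complement, alternative="two-sided")
    return float(res.pvalue), float(np.median(group) - np.median(complement))


# ---------------------------------------------------------------------------
# published transcriptome membership rules
# ---------------------------------------------------------------------------

def published_membership(
    table: pd.DataFrame,
    fdr_threshold: float = PUBLISHED_FDR_THRESHOLD,
    l2fc_threshold: float = 0.0,
    fdr_col: str = "FDR",
    l2fc_col: str = "l2fc",
    gene_col: str = "gene_id",
) -> Set[str]:
    """Genes with FDR below threshold and positive log2 fold change."""
    for col in (fdr_col, l2fc_col, gene_col):
        if col not in table.columns:
            raise ValueError(f"missing column {col!r}")
    sel = (table[fdr_col] < fdr_threshold) & (table[l2fc_col] > l2fc_threshold)
    return set(table.loc[sel, gene_col])


def dendritic_consensus(
    flags: pd.DataFrame,
    min_studies: int = 3,
    orthologs: Optional[Iterable[str]] = None,
    expressed: Optional[Iterable[str]] = None,
    gene_col: str = "gene_id",
) -> Set[str]:
    """Genes flagged enriched in >= ``min_studies`` of the study columns,
    optionally intersected with one-to-one ortholog and expression sets."""
    study_cols = [c for c in flags.columns if c != gene_col]
    hits = flags.loc[flags[study_cols].sum(axis=1) >= min_studies, gene_col]
    out = set(hits)
    if orthologs is not None:
        out &= set(orthologs)
    if expressed is not None:
        out &= set(expressed)
    return out


# ---------------------------------------------------------------------------
# heatmap row z-scores
# ---------------------------------------------------------------------------

def zscore_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Row-wise z-scores (sample SD); constant rows become zeros with a warning."""
    if matrix.shape[1] < 2:
        raise ValueError("row z-scores need at least 2 columns")
    values = matrix.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    flat = (sd == 0).ravel()
    if flat.any():
        warnings.warn(f"{int(flat.sum())} constant rows z-scored to zeros")
        sd[flat] = 1.0
    out = (values - mean) / sd
    out[flat, :] = 0.0
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


# ---------------------------------------------------------------------------
# hypergeometric gene-set enrichment
# ---------------------------------------------------------------------------

def hypergeom_enrichment(
    query: Iterable[str],
    gene_sets: Dict[str, Iterable[str]],
    background: Iterable[str],
) -> pd.DataFrame:
    """Over-representation test with background-restricted term sets.

    Each term set is first restricted to the background; with ``k`` query
    genes in the restricted term set ``T``, ``p = P(X >= k)`` for
    ``X ~ Hypergeom(|background|, |T|, |query|)``. The gene ratio is
    ``k / |T|``; BH adjustment runs across terms; rows sort by FDR.
    """
    background = set(background)
    query = set(query) & background
    if not query:
        raise ValueError("query set is empty after background restriction")
    rows = []
    for term in sorted(gene_sets):
        restricted = set(gene_sets[term]) & background
        if not restricted:
            continue
        k = len(query & restricted)
        p = float(stats.hypergeom.sf(k - 1, len(background), len(restricted), len(query)))
        rows.append(
            dict(
                term=term,
                overlap=k,
                term_size=len(restricted),
                gene_ratio=k / len(restricted),
                p=min(p, 1.0),
            )
        )
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    df["fdr"] = benjamini_hochberg(df["p"].to_numpy())
    return df.sort_values(["fdr", "p", "term"], kind="mergesort").reset_index(drop=True)


def top_terms(enrichment: pd.DataFrame, n: int = 25) -> pd.DataFrame:
    """The ``n`` most significant terms by FDR (export convention)."""
    return enrichment.head(n).reset_index(drop=True)
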