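"""RPKM normalization, DEG thresholding, and gene-set overlap statistics.

The overlap machinery implements over-representation testing of an internal
gene set (e.g. differentially expressed genes) against external curated sets
over an explicit background universe: a hypergeometric tail test with
Benjamini-Hochberg adjustment across the family of external sets, validated
by a two-way permutation scheme that re-draws either the external set (from
the background) or the internal set (from the expressed universe).

The differential-expression model itself is pluggable input (per-gene log2
fold change and raw p-value); this module only applies the downstream
filters and statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import GeneSetCollection, OverlapResult, normalize_symbols

__all__ = [
    "ExpressionTable",
    "rpkm",
    "expression_filter",
    "deg_filter",
    "bh_adjust",
    "hypergeom_overlap",
    "permute_external",
    "permute_internal",
    "overlap_report",
]


@dataclass
class ExpressionTable:
    """Gene-level counts with gene lengths and per-sample group labels."""

    counts: pd.DataFrame  # genes x samples, non-negative integers
    gene_lengths_bp: pd.Series  # indexed like counts
    group_labels: list[str]  # one per sample column

    def __post_init__(self) -> None:
        if len(self.group_labels) != self.counts.shape[1]:
            raise ValueError("one group label per sample column required")
        self.gene_lengths_bp = self.gene_lengths_bp.reindex(self.counts.index)
        if self.gene_lengths_bp.isna().any() or (self.gene_lengths_bp <= 0).any():
            raise ValueError("every gene needs a positive length")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if len(set(self.group_labels)) < 1:
            raise ValueError("at least one group required")


def rpkm(table: ExpressionTable) -> pd.DataFrame:
    """Reads per kilobase per million mapped reads.

    ``RPKM[g, s] = 1e9 * count[g, s] / (length_bp[g] * total_counts[s])``.
    """
    totals = table.counts.sum(axis=0)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"zero library size for samples: {bad}")
    return 1e9 * table.counts.div(totals, axis=1).div(table.gene_lengths_bp, axis=0)


def expression_filter(
    rpkm_matrix: pd.DataFrame,
    group_labels: list[str],
    min_rpkm: float = 0.5,
    *,
    per_sample: bool = False,
) -> list[str]:
    """Genes whose expression exceeds ``min_rpkm`` in at least one group.

    Default reading: group-mean RPKM strictly greater than ``min_rpkm`` in
    the treatment group or in the control group (or any group, when there
    are more than two). ``per_sample=True`` switches to requiring a single
    sample above the cutoff instead of the group mean.
    """
    if len(group_labels) != rpkm_matrix.shape[1]:
        raise ValueError("one group label per sample column required")
    labels = np.asarray(group_labels)
    keep = np.zeros(len(rpkm_matrix), dtype=bool)
    for g in dict.fromkeys(group_labels):
        block = rpkm_matrix.loc[:, labels == g]
        stat = block.max(axis=1) if per_sample else block.mean(axis=1)
        keep |= (stat > min_rpkm).to_numpy()
    return list(rpkm_matrix.index[keep])


def deg_filter(
    deg_table: pd.DataFrame,
    min_abs_lfc: float = 0.3,
    max_fdr: float = 0.05,
) -> dict[str, list[str]]:
    """Split genes passing |log2FC| and FDR cutoffs into up/down/all lists.

    ``deg_table`` is indexed by gene with columns ``log2fc`` plus ``fdr``
    (computed from ``pvalue`` via :func:`bh_adjust` when absent). Both cutoffs
    are strict: a gene is kept iff ``|log2fc| > min_abs_lfc`` and
    ``fdr < max_fdr``.
    """
    if "log2fc" not in deg_table.columns:
        raise ValueError("deg_table needs a 'log2fc' column")
    if "fdr" in deg_table.columns:
        fdr = deg_table["fdr"].to_numpy(dtype=float)
    elif "pvalue" in deg_table.columns:
        fdr = bh_adjust(deg_table["pvalue"].to_numpy(dtype=float))
    else:
        raise ValueError("deg_table needs an 'fdr' or 'pvalue' column")
    lfc = deg_table["log2fc"].to_numpy(dtype=float)
    passed = (np.abs(lfc) > min_abs_lfc) & (fdr < max_fdr)
    genes = deg_table.index.to_numpy()
    up = list(genes[passed & (lfc > 0)])
    down = list(genes[passed & (lfc < 0)])
    return {"up": up, "down": down, "all": up + down}


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def hypergeom_overlap(
    internal, external, background
) -> tuple[int, float, str | None]:
    """Over-representation tail probability of the observed set overlap.

    Both sets are first intersected with the background. With ``N`` background
    genes, ``K`` external genes, ``n`` internal genes and ``k`` shared genes,
    returns ``k`` and ``P(X >= k)`` for ``X ~ Hypergeometric(N, K, n)``.
    An empty set after intersection yields ``k=0, p=1`` with a warning flag.
    """
    bg = set(normalize_symbols(background))
    if not bg:
        raise ValueError("background is empty")
    internal = set(normalize_symbols(internal)) & bg
    external = set(normalize_symbols(external)) & bg
    warning = None
    if not internal or not external:
        return 0, 1.0, "empty set after background intersection"
    k = len(internal & external)
    p = float(stats.hypergeom.sf(k - 1, len(bg), len(external), len(internal)))
    return k, min(p, 1.0), warning


def _perm_pvalue(exceed: int, n_perm: int) -> float:
    # reciprocal floor: zero exceedances report 1/n_perm, never 0
    return max(exceed, 1) / n_perm


def permute_external(
    internal,
    external,
    background,
    n_perm: int = 1000,
    seed: int = 0,
) -> float:
    """Permutation p-value re-drawing the external set from the background.

    Each replicate draws ``|external|`` genes uniformly without replacement
    from the background and records its overlap with the internal set;
    ``p = max(m, 1) / n_perm`` where ``m`` counts replicates whose overlap is
    at least the observed one.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    bg = normalize_symbols(background)
    if len(set(normalize_symbols(external))) > len(bg):
        raise ValueError("background smaller than the external set")
    internal = set(normalize_symbols(internal)) & set(bg)
    external = set(normalize_symbols(external)) & set(bg)
    observed = len(internal & external)
    rng = np.random.default_rng(seed)
    is_internal = np.fromiter((g in internal for g in bg), dtype=bool, count=len(bg))
    m = 0
    size = len(external)
    for _ in range(n_perm):
        draw = rng.choice(len(bg), size=size, replace=False)
        if int(is_internal[draw].sum()) >= observed:
            m += 1
    return _perm_pvalue(m, n_perm)


def permute_internal(
    internal,
    external,
    expressed_universe,
    n_perm: int = 1000,
    seed: int = 0,
) -> float:
    """Permutation p-value re-drawing the internal set from expressed genes.

    Mirror image of :func:`permute_external`: random internal sets of the
    observed size are drawn from the expressed-gene universe. Same
    reciprocal-floor convention.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    uni = normalize_symbols(expressed_universe)
    if len(set(normalize_symbols(internal))) > len(uni):
        raise ValueError("expressed universe smaller than the internal set")
    internal = set(normalize_symbols(internal)) & set(uni)
    external = set(normalize_symbols(external))
    observed = len(internal & external)
    rng = np.random.default_rng(seed)
    is_external = np.fromiter((g in external for g in uni), dtype=bool, count=len(uni))
    m = 0
    size = len(internal)
    for _ in range(n_perm):
        draw = rng.choice(len(uni), size=size, replace=False)
        if int(is_external[draw].sum()) >= observed:
            m += 1
    return _perm_pvalue(m, n_perm)


def overlap_report(
    deg_sets: dict[str, list[str]],
    collections: GeneSetCollection,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Full overlap statistics for every (internal DEG set x external set) pair.

    For each internal set, hypergeometric p-values across the family of
    external sets are BH-adjusted together; both permutation p-values are
    computed with per-pair seeds derived from ``seed``. Returns one row per
    pair with all :class:`~synquant.types.OverlapResult` fields.
    """
    bg = collections.background
    universe = collections.expressed_universe or bg
    results: list[OverlapResult] = []
    seed_seq = np.random.SeedSequence(seed)
    child_seeds = iter(seed_seq.generate_state(2 * len(deg_sets) * len(collections.sets)))
    for internal_name, internal in deg_sets.items():
        block: list[OverlapResult] = []
        for set_name, external in collections.sets.items():
            k, p, warning = hypergeom_overlap(internal, external, bg)
            n_int = len(set(normalize_symbols(internal)) & set(bg))
            n_ext = len(set(normalize_symbols(external)) & set(bg))
            s_ext = int(next(child_seeds)) % 2**31
            s_int = int(next(child_seeds)) % 2**31
            p_ext = permute_external(internal, external, bg, n_perm, s_ext)
            p_int = permute_internal(internal, external, universe, n_perm, s_int)
            block.append(
                OverlapResult(
                    set_name=f"{internal_name}|{set_name}",
                    n_internal=n_int,
                    n_external=n_ext,
                    n_background=len(bg),
                    k_overlap=k,
                    p_hypergeom=p,
                    p_bh=None,
                    p_perm_external=p_ext,
                    p_perm_internal=p_int,
                    n_perm=n_perm,
                    seed=seed,
                    warning=warning,
                )
            )
        adjusted = bh_adjust([r.p_hypergeom for r in block])
        for r, q in zip(block, adjusted):
            r.p_bh = float(q)
        results.extend(block)
    rows = []
    for r in results:
        internal_name, set_name = r.set_name.split("|", 1)
        rows.append(
            {
                "internal_set": internal_name,
                "external_set": set_name,
                "n_internal": r.n_internal,
                "n_external": r.n_external,
                "n_background": r.n_background,
                "k_overlap": r.k_overlap,
                "p_hypergeom": r.p_hypergeom,
                "p_bh": r.p_bh,
                "p_perm_external": r.p_perm_external,
                "p_perm_internal": r.p_perm_internal,
                "n_perm": r.n_perm,
                "seed": r.seed,
                "warning": r.warning or "",
            }
        )
    return pd.DataFrame(rows)
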