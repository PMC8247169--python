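"""Marker detection and the spatial-region x cell-type intersection analysis.

Markers are found one group versus the rest with a one-tailed Wilcoxon
rank-sum test (normal approximation with tie correction), gated by a
detection-fraction filter (>= 25% in either population) and a natural-log
mean-difference filter, and Bonferroni-corrected over the genes actually
tested per group.

The spatial intersection grid asks, for every (cell type, region) pair,
whether the two marker sets overlap more than chance on a shared
background gene universe, using the upper tail of the hypergeometric
distribution.  A pair is called *enriched* when p < alpha and *depleted*
otherwise — the display convention of the source analysis, not a
lower-tail test.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import NormMatrix
from .signatures import ScoreMatrix

__all__ = [
    "MarkerTable",
    "EnrichmentGrid",
    "find_markers",
    "hypergeometric_overlap",
    "intersection_grid",
    "filter_state_signature",
    "compare_region_scores",
    "profile_correlation",
]

logger = logging.getLogger(__name__)


@dataclass
class MarkerTable:
    """Per-group marker genes with effect sizes and adjusted p-values."""

    table: pd.DataFrame  # gene, group, ln_fc, frac_in, frac_out, p_raw, p_adj

    def significant(self, alpha: float = 0.05) -> "MarkerTable":
        return MarkerTable(self.table[self.table["p_adj"] < alpha].copy())

    def gene_sets(self, alpha: float = 0.05) -> dict[str, set[str]]:
        sig = self.table[self.table["p_adj"] < alpha]
        return {g: set(t["gene"]) for g, t in sig.groupby("group", observed=True)}


def find_markers(
    x: NormMatrix,
    groups: pd.Series | np.ndarray,
    min_frac: float = 0.25,
    min_lnfc: float = 0.3,
) -> MarkerTable:
    """One-vs-rest up-regulated markers per group.

    A gene is tested for a group only if it is detected in at least
    ``min_frac`` of cells on either side *and* its mean ln-normalized
    expression exceeds the rest by at least ``min_lnfc``.  P-values come
    from the one-tailed (greater) Wilcoxon rank-sum test and are
    Bonferroni-adjusted over the genes tested within the group.
    """
    labels = pd.Series(np.asarray(groups, dtype=object), index=x.cell_ids)
    uniq = labels.unique()
    if len(uniq) < 2:
        raise ValueError("need at least two groups")
    counts = labels.value_counts()
    small = counts[counts < 3]
    if len(small):
        raise ValueError(f"groups with fewer than 3 members: {list(small.index)}")

    dense = x.dense()
    detected = dense > 0
    rows = []
    for group in uniq:
        mask = (labels == group).to_numpy()
        n_in, n_out = int(mask.sum()), int((~mask).sum())
        frac_in = detected[mask].mean(axis=0)
        frac_out = detected[~mask].mean(axis=0)
        mean_in = dense[mask].mean(axis=0)
        mean_out = dense[~mask].mean(axis=0)
        ln_fc = mean_in - mean_out
        testable = ((frac_in >= min_frac) | (frac_out >= min_frac)) & (
            ln_fc >= min_lnfc
        )
        idx = np.flatnonzero(testable)
        if len(idx) == 0:
            logger.info("group %s: no testable genes", group)
            continue
        pvals = np.ones(len(idx))
        for j, g in enumerate(idx):
            a, b = dense[mask, g], dense[~mask, g]
            if np.ptp(np.concatenate([a, b])) == 0:
                pvals[j] = 1.0
                continue
            res = stats.mannwhitneyu(a, b, alternative="greater", method="asymptotic")
            pvals[j] = res.pvalue
        p_adj = np.minimum(pvals * len(idx), 1.0)  # Bonferroni over tested genes
        for j, g in enumerate(idx):
            rows.append(
                {
                    "gene": x.gene_ids[g],
                    "group": group,
                    "ln_fc": ln_fc[g],
                    "frac_in": frac_in[g],
                    "frac_out": frac_out[g],
                    "p_raw": pvals[j],
                    "p_adj": p_adj[j],
                }
            )
    table = pd.DataFrame(
        rows, columns=["gene", "group", "ln_fc", "frac_in", "frac_out", "p_raw", "p_adj"]
    )
    return MarkerTable(table)


def hypergeometric_overlap(
    set_a: set[str], set_b: set[str], background: set[str]
) -> tuple[int, float]:
    """Overlap size and upper-tail hypergeometric p (P(X >= k), k included).

    X ~ Hypergeometric(N=|background|, K=|A|, n=|B|).  Both sets must be
    subsets of the background.
    """
    set_a, set_b, background = set(set_a), set(set_b), set(background)
    for name, s in (("A", set_a), ("B", set_b)):
        extra = s - background
        if extra:
            raise ValueError(
                f"set {name} has {len(extra)} gene(s) outside the background, "
                f"e.g. {sorted(extra)[:3]}"
            )
    k = len(set_a & set_b)
    N, K, n = len(background), len(set_a), len(set_b)
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return k, min(p, 1.0)


@dataclass
class EnrichmentGrid:
    """Overlap counts, hypergeometric p and enrichment calls per pair."""

    table: pd.DataFrame  # cell_type, region, k, size_a, size_b, n_background,
    #                      p_hyper, call, display
    alpha: float = 0.05

    def pivot(self, value: str = "display") -> pd.DataFrame:
        return self.table.pivot(index="cell_type", columns="region", values=value)


def intersection_grid(
    cell_markers: MarkerTable,
    region_markers: MarkerTable,
    background: set[str],
    alpha: float = 0.05,
) -> EnrichmentGrid:
    """Hypergeometric overlap of every (cell type, region) marker-set pair.

    Marker tables are first reduced to p_adj < ``alpha`` genes and
    intersected with the shared background.  Display value is -log10(p)
    for enriched pairs and 0 for depleted ones.
    """
    background = set(background)
    if not background:
        raise ValueError("empty background gene set")
    a_sets = {
        g: s & background for g, s in cell_markers.gene_sets(alpha).items()
    }
    b_sets = {
        g: s & background for g, s in region_markers.gene_sets(alpha).items()
    }
    if not a_sets or not b_sets:
        raise ValueError("a marker table is empty after p_adj filtering")
    rows = []
    for (ct, a), (rg, b) in itertools.product(a_sets.items(), b_sets.items()):
        if not a or not b:
            logger.info("skipping empty marker set (%s / %s)", ct, rg)
            continue
        k, p = hypergeometric_overlap(a, b, background)
        call = "enriched" if p < alpha else "depleted"
        rows.append(
            {
                "cell_type": ct,
                "region": rg,
                "k": k,
                "size_a": len(a),
                "size_b": len(b),
                "n_background": len(background),
                "p_hyper": p,
                "call": call,
                "display": -np.log10(max(p, 1e-300)) if call == "enriched" else 0.0,
            }
        )
    return EnrichmentGrid(pd.DataFrame(rows), alpha=alpha)


def filter_state_signature(
    state_degs: dict[str, set[str]],
    module_genes: dict[str, set[str]],
    confounder_markers: set[str],
) -> dict[str, set[str]]:
    """Per state: (DEGs ∩ module genes) minus confounder markers.

    Retains genes specific to the granule-lineage states by removing
    markers shared with other cell types; errors if any state resolves
    to the empty set.
    """
    if set(state_degs) != set(module_genes):
        raise ValueError(
            f"state keys differ: {sorted(set(state_degs) ^ set(module_genes))}"
        )
    out = {}
    for state in state_degs:
        genes = (set(state_degs[state]) & set(module_genes[state])) - set(
            confounder_markers
        )
        if not genes:
            raise ValueError(f"state {state!r} resolves to an empty signature")
        out[state] = genes
    union = set().union(*out.values())
    logger.info("filtered signature union: %d genes", len(union))
    return out


def compare_region_scores(
    spot_scores: ScoreMatrix, layers: pd.Series | np.ndarray
) -> pd.DataFrame:
    """Two-sided rank-sum comparison of each signature between layer pairs.

    Returns a frame with one row per (signature, layer_a, layer_b):
    the W statistic, two-sided p, and the median difference (a - b).
    Layers with fewer than 2 spots are excluded (logged).
    """
    labels = pd.Series(np.asarray(layers, dtype=object), index=spot_scores.values.index)
    counts = labels.value_counts()
    usable = sorted(counts[counts >= 2].index.tolist())
    dropped = counts[counts < 2].index.tolist()
    if dropped:
        logger.warning("excluding layers with < 2 spots: %s", dropped)
    if len(usable) < 2:
        raise ValueError("need at least two layers with >= 2 spots")
    rows = []
    for sig in spot_scores.signature_names:
        vals = spot_scores.values[sig]
        for la, lb in itertools.combinations(usable, 2):
            a = vals[labels == la].to_numpy()
            b = vals[labels == lb].to_numpy()
            if np.ptp(np.concatenate([a, b])) == 0:
                stat, p = float(len(a) * len(b) / 2), 1.0
            else:
                res = stats.mannwhitneyu(a, b, alternative="two-sided",
                                         method="asymptotic")
                stat, p = float(res.statistic), float(res.pvalue)
            rows.append(
                {
                    "signature": sig,
                    "layer_a": la,
                    "layer_b": lb,
                    "statistic": stat,
                    "p_value": p,
                    "median_diff": float(np.median(a) - np.median(b)),
                }
            )
    return pd.DataFrame(rows)


def profile_correlation(
    cell_state_profiles: pd.DataFrame,
    region_profiles: pd.DataFrame,
    genes: set[str] | list[str],
) -> pd.DataFrame:
    """Pearson r between averaged state and region profiles over a gene list.

    Profiles are (state x gene) and (region x gene) mean-expression
    frames; correlation uses only ``genes``.  Zero-variance profiles give
    NaN (logged), not an error.
    """
    genes = [g for g in genes if g in cell_state_profiles.columns
             and g in region_profiles.columns]
    if not genes:
        raise ValueError("no shared genes between the two profile frames")
    a = cell_state_profiles[genes]
    b = region_profiles[genes]
    out = pd.DataFrame(index=a.index, columns=b.index, dtype=float)
    for state, va in a.iterrows():
        for region, vb in b.iterrows():
            if va.std() == 0 or vb.std() == 0:
                logger.warning("zero-variance profile (%s / %s)", state, region)
                out.loc[state, region] = np.nan
            else:
                out.loc[state, region] = float(np.corrcoef(va, vb)[0, 1])
    return out
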