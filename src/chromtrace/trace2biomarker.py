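"""Trace2Biomarker: marker genomic regions, candidate-progression-driver
(CPD) gene sets, expression homogeneity, and the regulator gene-list export.

Marker regions are found by two-sided Wilcoxon rank-sum tests on
rank-normalized scA/B scores between two progression states, thresholded at
raw P < 0.1.  CPD genes are upregulated genes (mean count > 10, fold change
> 3, FDR < 0.05) located in marker regions whose scA/B score increases;
control genes are equally upregulated genes in regions with unchanged scA/B
(P >= 0.1).  Expression homogeneity of a gene is the cosine similarity of
its cross-cell expression vector with the uniform vector, which equals
1/sqrt(1 + CV^2) with population moments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .metrics.compartments import ScABMatrix

__all__ = [
    "MarkerRegions",
    "GeneSets",
    "rank_normalize",
    "find_markers",
    "call_gene_sets",
    "expression_homogeneity",
    "regulator_gene_list",
    "knockdown_concordance",
    "scab_shift",
]


@dataclass
class MarkerRegions:
    """Per-region rank-sum test results between two cell groups.

    ``table`` columns: ``p`` (two-sided rank-sum P; NaN for untested
    regions), ``direction`` (+1 scA/B up in the target group, -1 down;
    only defined for markers), ``marker`` (P < p_thresh).
    """

    table: pd.DataFrame
    p_thresh: float
    group_a: str
    group_b: str

    @property
    def up_regions(self) -> np.ndarray:
        t = self.table
        return t.index[(t["marker"]) & (t["direction"] > 0)].to_numpy()

    @property
    def unchanged_regions(self) -> np.ndarray:
        """Tested regions with P >= threshold (the control-region pool)."""
        t = self.table
        return t.index[t["p"].notna() & ~t["marker"]].to_numpy()


@dataclass
class GeneSets:
    """CPD / control / upregulated gene sets and their top-k signatures."""

    cpd: list[str]
    control_unchanged: list[str]
    up_only: list[str]
    signature_cpd: list[str]
    signature_control: list[str]
    signature_up: list[str]
    k: int


def rank_normalize(scab: ScABMatrix, min_regions: int = 325) -> pd.DataFrame:
    """Rank-normalize scA/B scores within each retained cell.

    Cells with more than ``min_regions`` defined entries are kept (a cell
    with exactly ``min_regions`` is dropped); within each cell the defined
    values are replaced by average ranks (ties share the mean rank) and
    missing values stay missing.
    """
    defined = scab.values.notna().sum(axis=1)
    keep = defined > min_regions
    if not keep.any():
        raise ValueError(
            f"no cells with more than {min_regions} defined regions")
    sub = scab.values.loc[keep]
    out = sub.copy()
    for cid, row in sub.iterrows():
        vals = row.to_numpy(dtype=float)
        ok = np.isfinite(vals)
        ranks = np.full(len(vals), np.nan)
        ranks[ok] = stats.rankdata(vals[ok], method="average")
        out.loc[cid] = ranks
    return out


def find_markers(ranked: pd.DataFrame, group_a: list[str],
                 group_b: list[str], p_thresh: float = 0.1,
                 min_cells: int = 3) -> MarkerRegions:
    """Marker genomic regions between two cell groups.

    Per region, a two-sided Wilcoxon rank-sum test on per-cell
    rank-normalized scA/B values; regions defined in fewer than
    ``min_cells`` cells of either group are excluded from testing.  The raw
    (unadjusted) P is thresholded; direction is the sign of the group-B
    median minus the group-A median.
    """
    a_ids = [c for c in group_a if c in ranked.index]
    b_ids = [c for c in group_b if c in ranked.index]
    if not a_ids or not b_ids:
        raise ValueError("both groups must be non-empty after filtering")
    pvals, direction = {}, {}
    for region in ranked.columns:
        a = ranked.loc[a_ids, region].dropna().to_numpy()
        b = ranked.loc[b_ids, region].dropna().to_numpy()
        if len(a) < min_cells or len(b) < min_cells:
            pvals[region] = np.nan
            direction[region] = np.nan
            continue
        try:
            _, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        except ValueError:   # all values identical
            p = 1.0
        pvals[region] = float(p)
        direction[region] = float(np.sign(np.median(b) - np.median(a)))
    table = pd.DataFrame({"p": pd.Series(pvals),
                          "direction": pd.Series(direction)})
    table["marker"] = table["p"] < p_thresh
    table.loc[~table["marker"], "direction"] = np.nan
    return MarkerRegions(table=table, p_thresh=p_thresh,
                         group_a="A", group_b="B")


def _upregulated(de: pd.DataFrame, fc_min: float, fdr_max: float,
                 count_min: float) -> pd.DataFrame:
    required = {"gene", "region_index", "mean_count", "log2fc", "fdr"}
    missing = required - set(de.columns)
    if missing:
        raise ValueError(f"DE table missing columns {sorted(missing)}")
    return de[(de["mean_count"] > count_min)
              & (2.0 ** de["log2fc"] > fc_min)
              & (de["fdr"] < fdr_max)]


def call_gene_sets(markers: MarkerRegions, de: pd.DataFrame,
                   fc_min: float = 3.0, fdr_max: float = 0.05,
                   count_min: float = 10.0, k: int = 21) -> GeneSets:
    """Partition upregulated genes into CPD / control / up-only sets.

    Fold change is thresholded on the linear scale (2**log2fc > fc_min).
    Signatures are the top-``k`` genes of each set by fold change.
    """
    up = _upregulated(de, fc_min, fdr_max, count_min)
    up_sorted = up.sort_values("log2fc", ascending=False)
    up_regions = set(markers.up_regions.tolist())
    unchanged = set(markers.unchanged_regions.tolist())

    def in_set(row, regions) -> bool:
        ri = row["region_index"]
        return np.isfinite(ri) and int(ri) in regions

    cpd = [r["gene"] for _, r in up_sorted.iterrows()
           if in_set(r, up_regions)]
    control = [r["gene"] for _, r in up_sorted.iterrows()
               if in_set(r, unchanged)]
    up_only = up_sorted["gene"].tolist()
    return GeneSets(cpd=cpd, control_unchanged=control, up_only=up_only,
                    signature_cpd=cpd[:k], signature_control=control[:k],
                    signature_up=up_only[:k], k=k)


def expression_homogeneity(expr: pd.DataFrame,
                           genes: list[str] | None = None) -> pd.Series:
    """Per-gene expression homogeneity across cells, in (0, 1].

    Cosine similarity between the gene's expression vector and the all-ones
    vector: mean / root-mean-square, identically 1/sqrt(1 + CV^2) with
    population moments.  All-zero genes are NaN.
    """
    if expr.shape[1] < 2:
        raise ValueError("need at least 2 cells")
    if genes is not None:
        missing = [g for g in genes if g not in expr.index]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing}")
        expr = expr.loc[genes]
    x = expr.to_numpy(dtype=float)
    mean = x.mean(axis=1)
    rms = np.sqrt((x ** 2).mean(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        h = np.where(rms > 0, mean / rms, np.nan)
    return pd.Series(h, index=expr.index, name="homogeneity")


def regulator_gene_list(markers: MarkerRegions, de: pd.DataFrame,
                        fdr_max: float = 0.1, fc_min: float = 1.0,
                        count_min: float = 0.0,
                        path=None) -> list[str]:
    """Gene list for external regulator-enrichment tools.

    Genes with increased expression (FDR < ``fdr_max``, fold change >
    ``fc_min``) located in regions with increased scA/B scores (marker
    regions, direction up).  Written one gene per line when ``path`` is
    given; the enrichment tool itself is not run here.
    """
    up = _upregulated(de, fc_min, fdr_max, count_min)
    up_regions = set(markers.up_regions.tolist())
    genes = [r["gene"] for _, r in
             up.sort_values("log2fc", ascending=False).iterrows()
             if np.isfinite(r["region_index"])
             and int(r["region_index"]) in up_regions]
    if not genes:
        warnings.warn("regulator gene list is empty")
    if path is not None:
        with open(path, "w") as fh:
            fh.write("\n".join(genes) + ("\n" if genes else ""))
    return genes


def scab_shift(scab_values: pd.DataFrame, group_a: list[str],
               group_b: list[str]) -> pd.Series:
    """Per-region mean scA/B change from group A to group B."""
    a = scab_values.loc[[c for c in group_a if c in scab_values.index]]
    b = scab_values.loc[[c for c in group_b if c in scab_values.index]]
    return b.mean(axis=0, skipna=True) - a.mean(axis=0, skipna=True)


def knockdown_concordance(change_a: pd.Series,
                          change_b: pd.Series) -> tuple[float, float]:
    """Spearman correlation between two per-region scA/B change vectors.

    Used to compare perturbation-induced compartment changes with the
    progression-associated changes; shuffle nulls are built by recomputing
    one change vector on permuted group labels.
    """
    joined = pd.concat([change_a, change_b], axis=1, join="inner").dropna()
    if len(joined) < 10:
        raise ValueError("fewer than 10 shared regions")
    rho, p = stats.spearmanr(joined.iloc[:, 0], joined.iloc[:, 1])
    return float(rho), float(p)
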