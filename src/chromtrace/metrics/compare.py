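"""Group comparisons of structural metrics, trend classification over ordered
progression states, and subsampling stability.

Comparisons follow the study's statistical conventions: matched units use the
two-sided Wilcoxon signed-rank test, unmatched groups the two-sided rank-sum
test, dispersion comparisons (demixing) a two-sided Levene test; fold changes
are reported as log2 and multiple testing is controlled by Benjamini-Hochberg
across the comparison's blocks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ..types import CellRecord, Codebook
from .distances import DistanceSummary, distance_summary

__all__ = [
    "metric_table",
    "compare_states",
    "classify_trends",
    "subsample_stability",
    "chromosome_log2fc",
]

TREND_CATEGORIES = ("down_then_up", "up_then_down", "monotone_up",
                    "monotone_down", "flat")


def metric_table(summary: DistanceSummary, which: str = "mean") -> pd.DataFrame:
    """Long-form per locus-pair table of a distance summary.

    Columns: ``block`` (chromosome), ``unit`` (region-index pair), ``value``
    (mean distance for ``which='mean'``, COV for ``'cov'``); masked pairs are
    dropped.
    """
    rows = []
    for chrom in summary.chroms:
        mat = summary.masked_mean(chrom) if which == "mean" \
            else summary.masked_cov(chrom)
        ridx = summary.region_indices[chrom]
        iu, ju = np.triu_indices(len(ridx), k=1)
        for a, b in zip(iu, ju):
            v = mat[a, b]
            if np.isfinite(v):
                rows.append((chrom, (int(ridx[a]), int(ridx[b])), float(v)))
    return pd.DataFrame(rows, columns=["block", "unit", "value"])


def compare_states(group: pd.DataFrame, reference: pd.DataFrame,
                   matched: bool = True, test: str | None = None,
                   ) -> pd.DataFrame:
    """Blockwise comparison of two long-form metric tables.

    Both inputs need columns ``block``, ``unit``, ``value``.  With
    ``matched=True`` only units present in both tables enter each block's
    paired test.  ``test`` defaults to ``'signed-rank'`` (matched) or
    ``'rank-sum'`` (unmatched); ``'levene'`` selects the dispersion test used
    for demixing comparisons.

    Returns a DataFrame indexed by block with columns ``log2fc``, ``stat``,
    ``p``, ``fdr``, ``n_units``.
    """
    if test is None:
        test = "signed-rank" if matched else "rank-sum"
    blocks = sorted(set(group["block"]) & set(reference["block"]))
    if not blocks:
        raise ValueError("no shared blocks between the two tables")
    rows = []
    for block in blocks:
        g = group[group["block"] == block]
        r = reference[reference["block"] == block]
        if matched:
            merged = pd.merge(g, r, on="unit", suffixes=("_g", "_r"))
            if len(merged) < 2:
                continue
            gv = merged["value_g"].to_numpy()
            rv = merged["value_r"].to_numpy()
            with np.errstate(divide="ignore", invalid="ignore"):
                l2 = float(np.nanmean(np.log2(gv / rv)))
            n_units = len(merged)
        else:
            gv = g["value"].to_numpy()
            rv = r["value"].to_numpy()
            if len(gv) < 2 or len(rv) < 2:
                continue
            l2 = float(np.log2(gv.mean() / rv.mean()))
            n_units = len(gv)
        if test == "signed-rank":
            if np.allclose(gv, rv):
                stat, p = 0.0, 1.0
            else:
                stat, p = stats.wilcoxon(gv, rv)
        elif test == "rank-sum":
            stat, p = stats.mannwhitneyu(gv, rv, alternative="two-sided")
        elif test == "levene":
            stat, p = stats.levene(gv, rv)
        else:
            raise ValueError(f"unknown test {test!r}")
        rows.append((block, l2, float(stat), float(p), n_units))
    if len(rows) < 2:
        raise ValueError("fewer than 2 comparable blocks")
    out = pd.DataFrame(rows, columns=["block", "log2fc", "stat", "p",
                                      "n_units"]).set_index("block")
    out["fdr"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


def classify_trends(values: pd.DataFrame, state_order: list[str],
                    tol: float = 0.02) -> tuple[pd.Series, dict[str, float]]:
    """Classify each unit's trajectory over ordered progression states.

    ``values`` is units x states; the first state is the normal reference,
    the last the invasive endpoint, and intermediate states are averaged as
    the adenoma stage.  The signs of log2(adenoma/normal) and
    log2(invasive/adenoma), thresholded at ``tol``, define the categories;
    a down-then-up trajectory is the bottleneck pattern.

    Returns ``(per-unit category, category fractions)``.
    """
    if len(state_order) < 3:
        raise ValueError("need at least 3 ordered states")
    missing = [s for s in state_order if s not in values.columns]
    if missing:
        raise ValueError(f"missing states {missing}")
    normal = values[state_order[0]]
    invasive = values[state_order[-1]]
    adenoma = values[state_order[1:-1]].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        d1 = np.log2(adenoma / normal)
        d2 = np.log2(invasive / adenoma)

    def sgn(x: float) -> int:
        return 0 if abs(x) <= tol else (1 if x > 0 else -1)

    cats = []
    for a, b in zip(d1, d2):
        if not (np.isfinite(a) and np.isfinite(b)):
            cats.append("flat")
            continue
        s1, s2 = sgn(a), sgn(b)
        if s1 < 0 and s2 > 0:
            cats.append("down_then_up")
        elif s1 > 0 and s2 < 0:
            cats.append("up_then_down")
        elif s1 == 0 and s2 == 0:
            cats.append("flat")
        elif s1 >= 0 and s2 >= 0:
            cats.append("monotone_up")
        else:
            cats.append("monotone_down")
    cats = pd.Series(cats, index=values.index, name="trend")
    fracs = {c: float((cats == c).mean()) for c in TREND_CATEGORIES}
    return cats, fracs


def chromosome_log2fc(cells: list[CellRecord], codebook: Codebook,
                      reference_state: str, min_pairs: int = 5,
                      ) -> pd.DataFrame:
    """Chromosome-level decompaction log2(FC) of each state vs the reference.

    Matched over locus pairs unmasked in both groups; rows are chromosomes,
    columns the non-reference states.
    """
    by_state: dict[str, list[CellRecord]] = {}
    for c in cells:
        by_state.setdefault(c.state, []).append(c)
    if reference_state not in by_state:
        raise ValueError(f"no cells in reference state {reference_state!r}")
    ref_tab = metric_table(distance_summary(by_state[reference_state],
                                            codebook, min_pairs=min_pairs))
    cols = {}
    for state, group in by_state.items():
        if state == reference_state:
            continue
        tab = metric_table(distance_summary(group, codebook,
                                            min_pairs=min_pairs))
        cmp = compare_states(tab, ref_tab, matched=True)
        cols[state] = cmp["log2fc"]
    return pd.DataFrame(cols)


def subsample_stability(cells: list[CellRecord], codebook: Codebook,
                        reference_state: str, n: int = 100, reps: int = 10,
                        seed: int = 0, min_pairs: int = 5) -> dict:
    """Stability of chromosome-level compaction log2(FC) under subsampling.

    For each repetition, ``n`` cells per state are drawn without replacement
    and the chromosome-level log2(FC) versus the reference state recomputed;
    sign concordance and Pearson correlation with the full-data values are
    reported (mean over repetitions and states).
    """
    by_state: dict[str, list[CellRecord]] = {}
    for c in cells:
        by_state.setdefault(c.state, []).append(c)
    for state, group in by_state.items():
        if len(group) < n:
            raise ValueError(f"state {state!r} has fewer than n={n} cells")
    full = chromosome_log2fc(cells, codebook, reference_state,
                             min_pairs=min_pairs)
    rng = np.random.default_rng(seed)
    concord, corr = [], []
    for _ in range(reps):
        sub: list[CellRecord] = []
        for state in sorted(by_state):
            group = by_state[state]
            pick = rng.choice(len(group), size=n, replace=False)
            sub.extend(group[i] for i in pick)
        part = chromosome_log2fc(sub, codebook, reference_state,
                                 min_pairs=min_pairs)
        for state in full.columns:
            a = full[state]
            b = part[state].reindex(a.index)
            ok = a.notna() & b.notna()
            if ok.sum() < 2:
                continue
            concord.append(float((np.sign(a[ok]) == np.sign(b[ok])).mean()))
            corr.append(float(np.corrcoef(a[ok], b[ok])[0, 1]))
    return dict(sign_concordance=float(np.mean(concord)),
                correlation=float(np.mean(corr)),
                n=n, reps=reps, per_rep_concordance=concord)
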