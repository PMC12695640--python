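"""A/B compartment scores, single-cell A/B (scA/B) scores, and
compartment-stratified proximity frequencies.

Population compartment scores per chromosome: the mean interloci distance
matrix is normalized by the power-law expectation at each pair's genomic
separation; the Pearson correlation matrix of its columns is decomposed by
PCA and the first-component coefficients are the compartment scores.  Signs
are fixed per chromosome so that the scores correlate positively with a
chromatin-activity reference profile; regions with positive score are A.

The scA/B score of a locus in a cell is the mean population compartment
score of all other detected loci strictly within a 1,200-nm 3D neighborhood
(any chromosome, any copy).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from ..types import CellRecord, Codebook, ReferenceProfile
from .distances import DistanceSummary, fit_power_law

__all__ = [
    "CompartmentResult",
    "ScABMatrix",
    "compartment_scores",
    "scab_scores",
    "trans_proximity_frequencies",
    "cis_proximity_frequencies",
]


@dataclass
class CompartmentResult:
    """Per-region compartment scores and A/B labels.

    ``scores[r]`` is NaN for regions on chromosomes skipped as degenerate.
    ``is_a`` is True where the score is positive.
    """

    scores: np.ndarray
    degenerate_chroms: list[int] = field(default_factory=list)

    @property
    def is_a(self) -> np.ndarray:
        return self.scores > 0

    def chrom_scores(self, codebook: Codebook, chrom: int) -> np.ndarray:
        return self.scores[codebook.region_indices_on(chrom)]


@dataclass
class ScABMatrix:
    """Cells x regions single-cell A/B scores (NaN = missing)."""

    values: pd.DataFrame      # index: cell_id, columns: region_index
    radius: float

    def defined_per_cell(self) -> pd.Series:
        return self.values.notna().sum(axis=1)


def compartment_scores(summary: DistanceSummary, codebook: Codebook,
                       reference: ReferenceProfile,
                       min_regions: int = 4) -> CompartmentResult:
    """Population A/B compartment scores from a distance summary."""
    from sklearn.decomposition import PCA

    if len(reference) != len(codebook):
        raise ValueError("reference profile length must match codebook")
    scores = np.full(len(codebook), np.nan)
    degenerate = []
    for chrom in summary.chroms:
        ridx = summary.region_indices[chrom]
        mean = summary.masked_mean(chrom)
        usable = (~np.isnan(mean)).sum(axis=0) > 0
        if usable.sum() < min_regions:
            warnings.warn(f"chr{chrom}: fewer than {min_regions} usable "
                          "regions; skipped")
            degenerate.append(chrom)
            continue
        try:
            fit = fit_power_law(summary, chrom)
        except ValueError:
            degenerate.append(chrom)
            continue
        mids = summary.midpoints_mb[chrom]
        seps = np.abs(mids[:, None] - mids[None, :])
        with np.errstate(invalid="ignore", divide="ignore"):
            normed = mean / fit.expected(seps)
        corr = pd.DataFrame(normed).corr(min_periods=2).to_numpy()
        if np.isnan(corr).all():
            degenerate.append(chrom)
            continue
        corr = np.nan_to_num(corr, nan=0.0)
        if np.allclose(corr.std(axis=0), 0):
            degenerate.append(chrom)
            continue
        pc1 = PCA(n_components=1).fit(corr).components_[0]
        ref = reference.values[ridx]
        ok = np.isfinite(ref)
        if ok.sum() >= 2 and np.corrcoef(pc1[ok], ref[ok])[0, 1] < 0:
            pc1 = -pc1
        scores[ridx] = pc1
    return CompartmentResult(scores=scores, degenerate_chroms=degenerate)


def scab_scores(cells: list[CellRecord], compartments: CompartmentResult,
                radius: float = 1200.0, trans_only: bool = False,
                ) -> ScABMatrix:
    """Single-cell A/B score per region per cell.

    Neighbors are all other detected loci of the same cell strictly within
    ``radius`` (same-trace loci included; the locus itself excluded); the
    locus score is the mean of the neighbors' population compartment scores,
    and the per-region cell value averages over chromosome copies.  Loci with
    no neighbor, and regions whose compartment score is undefined as a
    neighbor contribution, yield missing values.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    pop = compartments.scores
    n_regions = len(pop)
    rows = {}
    for cell in cells:
        regs, xyz, chroms = cell.loci_arrays()
        row = np.full(n_regions, np.nan)
        if len(regs) >= 2:
            tree = cKDTree(xyz)
            # query at a slightly padded radius, then enforce strict < radius
            pairs = tree.query_pairs(r=radius * (1 + 1e-12),
                                     output_type="ndarray")
            if len(pairs):
                d = np.linalg.norm(xyz[pairs[:, 0]] - xyz[pairs[:, 1]],
                                   axis=1)
                pairs = pairs[d < radius]
            acc = np.zeros(len(regs))
            num = np.zeros(len(regs))
            if len(pairs):
                if trans_only:
                    pairs = pairs[chroms[pairs[:, 0]] != chroms[pairs[:, 1]]]
                q = np.concatenate([pairs[:, 0], pairs[:, 1]])
                nb = np.concatenate([pairs[:, 1], pairs[:, 0]])
                val = pop[regs[nb]]
                ok = np.isfinite(val)
                np.add.at(acc, q[ok], val[ok])
                np.add.at(num, q[ok], 1)
            locus_scab = np.where(num > 0, acc / np.maximum(num, 1), np.nan)
            for ri in np.unique(regs):
                vals = locus_scab[regs == ri]
                vals = vals[np.isfinite(vals)]
                if len(vals):
                    row[ri] = vals.mean()
        rows[cell.cell_id] = row
    df = pd.DataFrame.from_dict(rows, orient="index",
                                columns=range(n_regions))
    return ScABMatrix(values=df, radius=radius)


def trans_proximity_frequencies(cells: list[CellRecord],
                                compartments: CompartmentResult,
                                codebook: Codebook,
                                cutoff: float = 500.0) -> dict[str, float]:
    """Fraction of trans locus pairs within ``cutoff``, by A/B label pair."""
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    return _proximity(cells, compartments, codebook, cutoff, trans=True)


def cis_proximity_frequencies(cells: list[CellRecord],
                              compartments: CompartmentResult,
                              codebook: Codebook, cutoff: float = 500.0,
                              min_sep_mb: float = 25.0) -> dict[str, float]:
    """Long-range cis variant: same-trace pairs at >= ``min_sep_mb`` apart."""
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    return _proximity(cells, compartments, codebook, cutoff, trans=False,
                      min_sep_mb=min_sep_mb)


def _proximity(cells, compartments, codebook, cutoff, trans,
               min_sep_mb=0.0) -> dict[str, float]:
    labels = np.where(np.isnan(compartments.scores), -1,
                      compartments.is_a.astype(int))
    mids = codebook.midpoints_mb()
    within = {"AA": 0, "AB": 0, "BB": 0}
    total = {"AA": 0, "AB": 0, "BB": 0}
    for cell in cells:
        regs, xyz, chroms = cell.loci_arrays()
        if len(regs) < 2:
            continue
        diff = xyz[:, None, :] - xyz[None, :, :]
        d = np.sqrt((diff ** 2).sum(axis=2))
        iu, ju = np.triu_indices(len(regs), k=1)
        if trans:
            sel = chroms[iu] != chroms[ju]
        else:
            sel = (chroms[iu] == chroms[ju]) & (
                np.abs(mids[regs[iu]] - mids[regs[ju]]) >= min_sep_mb)
        li, lj = labels[regs[iu[sel]]], labels[regs[ju[sel]]]
        ok = (li >= 0) & (lj >= 0)
        key = np.where(li + lj == 2, 0, np.where(li + lj == 1, 1, 2))
        dd = d[iu[sel], ju[sel]]
        for knum, kname in enumerate(("AA", "AB", "BB")):
            m = ok & (key == knum)
            total[kname] += int(m.sum())
            within[kname] += int((m & (dd < cutoff)).sum())
    return {k: (within[k] / total[k] if total[k] else float("nan"))
            for k in within} | {f"n_{k}": total[k] for k in total}
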