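"""Population distance statistics: mean/COV interloci distance matrices,
cell-pair heterogeneity, demixing, power-law scaling, interchromosomal
distances.

Each chromosome copy is treated as an independent observation when pooling
distances over a cell group, so the COV of a locus pair measures variation
among chromosome copies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.stats import linregress

from ..types import CellRecord, Codebook

__all__ = [
    "DistanceSummary",
    "PowerLawFit",
    "distance_summary",
    "cellpair_heterogeneity",
    "demixing_score",
    "fit_power_law",
    "interchromosomal_distances",
]


@dataclass
class DistanceSummary:
    """Per-chromosome mean / count / COV interloci distance matrices.

    Matrices are indexed by position within ``region_indices[chrom]`` (the
    global region indices present on that chromosome).  ``mean`` holds the
    decompaction score of each locus pair; ``cov`` the heterogeneity score
    (sample s.d. / mean); pairs observed fewer than ``min_pairs`` times are
    masked in :meth:`masked_mean` / :meth:`masked_cov`.
    """

    group: str
    min_pairs: int
    mean: dict[int, np.ndarray] = field(default_factory=dict)
    count: dict[int, np.ndarray] = field(default_factory=dict)
    cov: dict[int, np.ndarray] = field(default_factory=dict)
    region_indices: dict[int, np.ndarray] = field(default_factory=dict)
    midpoints_mb: dict[int, np.ndarray] = field(default_factory=dict)

    @property
    def chroms(self) -> list[int]:
        return sorted(self.mean)

    def masked_mean(self, chrom: int) -> np.ndarray:
        m = self.mean[chrom].copy()
        m[self.count[chrom] < self.min_pairs] = np.nan
        return m

    def masked_cov(self, chrom: int) -> np.ndarray:
        c = self.cov[chrom].copy()
        c[self.count[chrom] < self.min_pairs] = np.nan
        return c

    def pair_table(self, chrom: int, which: str = "mean",
                   masked: bool = True) -> tuple[np.ndarray, np.ndarray]:
        """Upper-triangle values with their genomic separations (Mb).

        Returns ``(genomic_sep_mb, values)`` for pairs that are unmasked.
        """
        mat = (self.masked_mean(chrom) if masked else self.mean[chrom]) \
            if which == "mean" else \
            (self.masked_cov(chrom) if masked else self.cov[chrom])
        mids = self.midpoints_mb[chrom]
        iu, ju = np.triu_indices(len(mids), k=1)
        vals = mat[iu, ju]
        seps = np.abs(mids[iu] - mids[ju])
        ok = np.isfinite(vals)
        return seps[ok], vals[ok]


@dataclass(frozen=True)
class PowerLawFit:
    """Least-squares fit of log(mean distance) on log(genomic distance)."""

    amplitude: float    # nm * Mb**(-exponent)
    exponent: float
    residual: float     # sum of squared log-space residuals

    def expected(self, genomic_mb: np.ndarray) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return self.amplitude * np.asarray(genomic_mb) ** self.exponent


def distance_summary(cells: list[CellRecord], codebook: Codebook,
                     group: str = "all", min_pairs: int = 5,
                     ) -> DistanceSummary:
    """Pool intrachromosomal pair distances over all traces of a cell group."""
    if not cells:
        raise ValueError("empty cell group")
    mids = codebook.midpoints_mb()
    out = DistanceSummary(group=group, min_pairs=min_pairs)
    for chrom in codebook.chroms:
        ridx = codebook.region_indices_on(chrom)
        n = len(ridx)
        local = {int(r): k for k, r in enumerate(ridx)}
        s = np.zeros((n, n))
        s2 = np.zeros((n, n))
        cnt = np.zeros((n, n), dtype=int)
        for cell in cells:
            for trace in cell.traces:
                if trace.chrom != chrom or len(trace) < 2:
                    continue
                li = np.array([local[int(r)] for r in trace.region_indices])
                d = pdist(trace.xyz)
                iu, ju = np.triu_indices(len(li), k=1)
                a, b = li[iu], li[ju]
                np.add.at(s, (a, b), d)
                np.add.at(s2, (a, b), d * d)
                np.add.at(cnt, (a, b), 1)
        s += s.T
        s2 += s2.T
        cnt += cnt.T
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = np.where(cnt > 0, s / np.maximum(cnt, 1), np.nan)
            var = np.where(cnt > 1,
                           (s2 - cnt * mean ** 2) / np.maximum(cnt - 1, 1),
                           np.nan)
            cov = np.sqrt(np.clip(var, 0, None)) / mean
        np.fill_diagonal(mean, np.nan)
        np.fill_diagonal(cov, np.nan)
        out.mean[chrom] = mean
        out.count[chrom] = cnt
        out.cov[chrom] = cov
        out.region_indices[chrom] = ridx
        out.midpoints_mb[chrom] = mids[ridx]
    return out


def _cell_pair_means(cell: CellRecord, chrom: int) -> dict[tuple[int, int], float]:
    """Per locus pair, the mean distance over the cell's copies of ``chrom``."""
    acc: dict[tuple[int, int], list[float]] = {}
    for trace in cell.traces:
        if trace.chrom != chrom or len(trace) < 2:
            continue
        regs = trace.region_indices
        d = squareform(pdist(trace.xyz))
        for i in range(len(regs)):
            for j in range(i + 1, len(regs)):
                acc.setdefault((int(regs[i]), int(regs[j])), []).append(
                    float(d[i, j]))
    return {k: float(np.mean(v)) for k, v in acc.items()}


def cellpair_heterogeneity(cell1: CellRecord, cell2: CellRecord, chrom: int,
                           min_shared: int = 10) -> float:
    """Cell-pair 3D genome heterogeneity on one chromosome.

    RMS of interloci distance differences over shared locus pairs, normalized
    by the mean of those distances over both cells.  NaN when fewer than
    ``min_shared`` pairs are measured in both cells.
    """
    m1 = _cell_pair_means(cell1, chrom)
    m2 = _cell_pair_means(cell2, chrom)
    shared = sorted(set(m1) & set(m2))
    if len(shared) < min_shared:
        return float("nan")
    d1 = np.array([m1[k] for k in shared])
    d2 = np.array([m2[k] for k in shared])
    rms = np.sqrt(np.mean((d1 - d2) ** 2))
    grand = np.mean(np.concatenate([d1, d2]))
    return float(rms / grand)


def demixing_score(summary: DistanceSummary, chrom: int) -> float:
    """s.d. of mean-normalized mean interloci distances on a chromosome.

    Normalization by the chromosome-wide mean removes compaction, leaving
    only how unevenly distances are distributed (demixing).
    """
    _, vals = summary.pair_table(chrom, "mean")
    if len(vals) < 2:
        raise ValueError(f"chr{chrom}: fewer than 2 unmasked pairs")
    norm = vals / vals.mean()
    return float(np.std(norm, ddof=1))


def fit_power_law(summary: DistanceSummary,
                  chrom: int | None = None) -> PowerLawFit:
    """Fit ``distance = A * g**alpha`` over unmasked pairs (log-log LS)."""
    if chrom is None:
        seps, vals = [], []
        for c in summary.chroms:
            s, v = summary.pair_table(c, "mean")
            seps.append(s)
            vals.append(v)
        seps = np.concatenate(seps)
        vals = np.concatenate(vals)
    else:
        seps, vals = summary.pair_table(chrom, "mean")
    ok = (seps > 0) & (vals > 0)
    seps, vals = seps[ok], vals[ok]
    if len(vals) < 3:
        raise ValueError("need at least 3 unmasked pairs for a power-law fit")
    if np.allclose(seps, seps[0]):
        raise ValueError("degenerate fit: all genomic separations identical")
    lx, ly = np.log(seps), np.log(vals)
    fit = linregress(lx, ly)
    resid = float(np.sum((ly - (fit.intercept + fit.slope * lx)) ** 2))
    return PowerLawFit(amplitude=float(np.exp(fit.intercept)),
                       exponent=float(fit.slope), residual=resid)


def interchromosomal_distances(cells: list[CellRecord], codebook: Codebook,
                               ) -> tuple[np.ndarray, np.ndarray]:
    """Mean distance per trans region pair, pooled over copy combinations.

    Returns ``(mean, count)`` as full region x region matrices with NaN for
    cis and unobserved pairs.
    """
    if not cells:
        raise ValueError("empty cell group")
    n = len(codebook)
    chrom_of = codebook.chrom_of_region()
    s = np.zeros(n * n)
    cnt = np.zeros(n * n, dtype=np.int64)
    for cell in cells:
        regs, xyz, chroms = cell.loci_arrays()
        if len(regs) < 2:
            continue
        diff = xyz[:, None, :] - xyz[None, :, :]
        d = np.sqrt((diff ** 2).sum(axis=2))
        trans = chroms[:, None] != chroms[None, :]
        ii, jj = np.nonzero(trans)
        flat = regs[ii] * n + regs[jj]
        s += np.bincount(flat, weights=d[ii, jj], minlength=n * n)
        cnt += np.bincount(flat, minlength=n * n)
    s = s.reshape(n, n)
    cnt = cnt.reshape(n, n)
    with np.errstate(invalid="ignore"):
        mean = np.where(cnt > 0, s / np.maximum(cnt, 1), np.nan)
    mean[chrom_of[:, None] == chrom_of[None, :]] = np.nan
    return mean, cnt
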