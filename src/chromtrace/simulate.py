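"""Synthetic multi-state chromatin-trace populations with retained ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: per-cell chromosome territories inside a nucleus, two copies per
autosome, loci positions whose expected pairwise distance follows a power law
``A * g**alpha`` of genomic separation ``g`` (Mb), A/B compartment
polarization within each territory, an inward radial bias for A loci, per-cell
conformational heterogeneity, and random locus dropout.

The positional model is a territory-anchored fractional-Brownian-motion walk
per coordinate (Hurst index = the scaling exponent ``alpha``), which realizes
``E[distance] = A * g**alpha`` exactly, rather than a full polymer simulation:
every downstream metric depends only on distance statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import (
    Barcode,
    CellRecord,
    ChromatinTrace,
    Codebook,
    GenomicRegion,
    Locus3D,
    N_BITS,
    ReferenceProfile,
)

__all__ = [
    "StateParams",
    "SimTruth",
    "FociSet",
    "synthetic_codebook",
    "ab_block_labels",
    "default_states",
    "simulate_population",
    "simulate_foci",
    "simulate_expression",
    "reference_profile_from_truth",
]

# 3D chi mean factor: E|N(0, s^2 I_3)| = s * sqrt(8/pi)
_CHI3 = math.sqrt(8.0 / math.pi)


@dataclass(frozen=True)
class StateParams:
    """Generative parameters of one cell state.

    Parameters
    ----------
    compaction_scale
        ``A`` in the power law ``A * g**alpha``, nm per Mb**alpha.
    scaling_exponent
        Power-law exponent ``alpha`` (the observed genomic-to-spatial
        scaling is about one-tenth).
    heterogeneity_sd
        Relative s.d. of the per-cell multiplicative conformation factor
        (lognormal with mean 1).
    compartment_strength
        0..1; strength of A/B pole segregation within a territory.
    radial_bias
        Signed; positive moves A loci toward the nuclear interior and B
        loci outward.
    territory_spread
        Radius (nm) of the ball in which territory centers are placed;
        controls interchromosomal distances.
    nuclear_radius
        Nucleus radius in nm.
    locus_detection_rate
        Per-locus independent detection probability.
    """

    label: str
    n_cells: int
    compaction_scale: float = 1500.0
    scaling_exponent: float = 0.1
    heterogeneity_sd: float = 0.25
    compartment_strength: float = 0.6
    radial_bias: float = 0.3
    territory_spread: float = 2500.0
    nuclear_radius: float = 4000.0
    locus_detection_rate: float = 0.8

    def __post_init__(self) -> None:
        if self.scaling_exponent <= 0 or self.scaling_exponent > 1:
            raise ValueError("scaling_exponent must be in (0, 1]")
        if not (0.0 <= self.locus_detection_rate <= 1.0):
            raise ValueError("locus_detection_rate must be in [0, 1]")
        if not (0.0 <= self.compartment_strength <= 1.0):
            raise ValueError("compartment_strength must be in [0, 1]")
        for name in ("compaction_scale", "territory_spread", "nuclear_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.heterogeneity_sd < 0:
            raise ValueError("heterogeneity_sd must be >= 0")


@dataclass
class SimTruth:
    """Ground truth retained by the generators for parameter-recovery tests."""

    region_a: np.ndarray | None = None          # bool per region: True = A
    states: list[str] = field(default_factory=list)   # per cell
    full_cells: list[CellRecord] = field(default_factory=list)  # pre-dropout
    foci: list[dict] | None = None              # per cell: true loci + emission
    gene_class: pd.Series | None = None         # per gene: cpd/control/null
    gene_log2fc: pd.Series | None = None
    params: dict = field(default_factory=dict)


@dataclass
class FociSet:
    """Per-bit 3D foci of one nucleus: 100 arrays of (x, y, z, intensity)."""

    bits: list[np.ndarray]

    @classmethod
    def empty(cls) -> "FociSet":
        return cls(bits=[np.empty((0, 4)) for _ in range(N_BITS)])

    def n_foci(self) -> int:
        return sum(len(b) for b in self.bits)


def synthetic_codebook(n_regions: int = 473, n_chroms: int = 19,
                       spacing_mb: float = 5.0,
                       region_mb: float = 1.0) -> Codebook:
    """Build a codebook mirroring the imaging panel's shape.

    ``n_regions`` TAD-scale regions spread over ``n_chroms`` autosomes at
    ``spacing_mb`` midpoint spacing, with weight-2 barcodes assigned in
    lexicographic on-bit order.
    """
    per = [n_regions // n_chroms + (1 if c < n_regions % n_chroms else 0)
           for c in range(n_chroms)]
    pairs = [(i, j) for i in range(N_BITS) for j in range(i + 1, N_BITS)]
    if n_regions > len(pairs):
        raise ValueError("too many regions for the barcode space")
    regions, barcodes = [], []
    k = 0
    for c, n_on in enumerate(per, start=1):
        for r in range(n_on):
            start = int(3e6 + r * spacing_mb * 1e6)
            regions.append(GenomicRegion(
                chrom=c, start_bp=start,
                end_bp=start + int(region_mb * 1e6), region_index=k))
            barcodes.append(Barcode(on_bits=pairs[k]))
            k += 1
    return Codebook(regions=regions, barcodes=barcodes)


def ab_block_labels(codebook: Codebook, block: int = 5) -> np.ndarray:
    """Alternating A/B truth labels in blocks of ``block`` regions per chromosome."""
    out = np.zeros(len(codebook), dtype=bool)
    for chrom in codebook.chroms:
        idx = codebook.region_indices_on(chrom)
        for pos, ri in enumerate(idx):
            out[ri] = (pos // block) % 2 == 0
    return out


def default_states(n_cells: int = 150) -> list[StateParams]:
    """The default multi-state study population (normal / adenoma / invasive).

    Adenoma states are compacted (0.8x compaction scale), less heterogeneous
    and more polarized than the normal state; the invasive state recovers
    compaction and spreads territories further apart (larger nuclei).
    """
    base = dict(scaling_exponent=0.1, nuclear_radius=4000.0,
                locus_detection_rate=0.8)
    adeno = dict(base, compaction_scale=1200.0, heterogeneity_sd=0.15,
                 compartment_strength=0.7, radial_bias=0.3,
                 territory_spread=2200.0)
    return [
        StateParams(label="AT2", n_cells=n_cells, compaction_scale=1500.0,
                    heterogeneity_sd=0.25, compartment_strength=0.6,
                    radial_bias=0.3, territory_spread=2500.0, **base),
        StateParams(label="AdenomaR", n_cells=n_cells, **adeno),
        StateParams(label="AdenomaY", n_cells=n_cells, **adeno),
        StateParams(label="AdenomaG", n_cells=n_cells, **adeno),
        StateParams(label="LUAD", n_cells=n_cells, compaction_scale=1500.0,
                    heterogeneity_sd=0.30, compartment_strength=0.6,
                    radial_bias=0.3, territory_spread=3000.0,
                    scaling_exponent=0.1, nuclear_radius=4500.0,
                    locus_detection_rate=0.8),
    ]


def _fbm_cholesky(t_mb: np.ndarray, alpha: float,
                  amplitude: float) -> np.ndarray:
    """Cholesky factor of the per-coordinate fBm covariance over loci.

    Scaled so that the 3D mean distance between loci at genomic separation
    ``g`` equals ``amplitude * g**alpha``.
    """
    t = np.asarray(t_mb, dtype=float) - t_mb[0]
    h2 = 2.0 * alpha
    sigma2 = amplitude ** 2 / _CHI3 ** 2   # per-coordinate variance scale
    tt = np.abs(t[:, None] - t[None, :])
    cov = 0.5 * sigma2 * (t[:, None] ** h2 + t[None, :] ** h2 - tt ** h2)
    cov += np.eye(len(t)) * (1e-9 * max(sigma2, 1.0))
    return np.linalg.cholesky(cov)


def _uniform_ball(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    r = radius * rng.random(n) ** (1.0 / 3.0)
    return v * r[:, None]


def _unit_vectors(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def simulate_cell(state: StateParams, codebook: Codebook,
                  region_a: np.ndarray, rng: np.random.Generator,
                  chol_cache: dict | None = None,
                  ) -> tuple[list[ChromatinTrace], list[ChromatinTrace]]:
    """Generate one cell; returns (detected_traces, full_traces).

    ``full_traces`` carry every locus before dropout (ground truth).
    Passing the same freshly seeded ``rng`` twice reproduces the cell exactly.
    """
    if state.territory_spread > 2 * state.nuclear_radius:
        raise ValueError("territory_spread exceeds the nuclear diameter: "
                         "unsatisfiable geometry")
    if chol_cache is None:
        chol_cache = {}
    A = state.compaction_scale
    mids = codebook.midpoints_mb()
    # per-cell multiplicative conformation factor, lognormal with mean 1
    if state.heterogeneity_sd > 0:
        s2 = math.log1p(state.heterogeneity_sd ** 2)
        f_cell = math.exp(rng.normal(-0.5 * s2, math.sqrt(s2)))
    else:
        f_cell = 1.0
        rng.normal()  # keep the stream aligned regardless of the branch

    detected, full = [], []
    for chrom in codebook.chroms:
        ridx = codebook.region_indices_on(chrom)
        key = (chrom, A, state.scaling_exponent)
        if key not in chol_cache:
            chol_cache[key] = _fbm_cholesky(mids[ridx],
                                            state.scaling_exponent, A)
        chol = chol_cache[key]
        for copy_id in (0, 1):
            center = _uniform_ball(rng, 1, state.territory_spread)[0]
            walk = chol @ rng.normal(size=(len(ridx), 3))
            pos = center + f_cell * walk
            sign = np.where(region_a[ridx], 1.0, -1.0)
            if state.compartment_strength != 0:
                pole = _unit_vectors(rng, 1)[0]
                pos = pos + (state.compartment_strength * 0.5 * A
                             ) * sign[:, None] * pole
            else:
                _unit_vectors(rng, 1)
            if state.radial_bias != 0:
                rnorm = np.linalg.norm(pos, axis=1, keepdims=True)
                rhat = np.divide(pos, rnorm, out=np.zeros_like(pos),
                                 where=rnorm > 0)
                pos = pos - (state.radial_bias * 0.5 * A
                             ) * sign[:, None] * rhat
            keep = rng.random(len(ridx)) < state.locus_detection_rate
            full_loci = [Locus3D(region_index=int(ri), x=float(p[0]),
                                 y=float(p[1]), z=float(p[2]))
                         for ri, p in zip(ridx, pos)]
            det_loci = [l for l, k in zip(full_loci, keep) if k]
            full.append(ChromatinTrace(chrom=chrom, copy_id=copy_id,
                                       loci=full_loci))
            detected.append(ChromatinTrace(chrom=chrom, copy_id=copy_id,
                                           loci=det_loci))
    return detected, full


def simulate_population(states: list[StateParams], codebook: Codebook,
                        seed: int, ab_block: int = 5,
                        n_sources: int = 4,
                        ) -> tuple[list[CellRecord], SimTruth]:
    """Generate a multi-state population of cells with retained ground truth.

    All randomness flows from ``seed``; per-cell substreams are derived
    deterministically, so identical seeds give bit-identical output.
    """
    region_a = ab_block_labels(codebook, block=ab_block)
    total = sum(s.n_cells for s in states)
    children = np.random.SeedSequence(seed).spawn(total)
    cells: list[CellRecord] = []
    truth = SimTruth(region_a=region_a,
                     params={s.label: s for s in states})
    chol_cache: dict = {}
    k = 0
    for state in states:
        for i in range(state.n_cells):
            rng = np.random.default_rng(children[k])
            det, full = simulate_cell(state, codebook, region_a, rng,
                                      chol_cache)
            cid = f"{state.label}_{i:05d}"
            src = f"{state.label}_src{i % n_sources}"
            cells.append(CellRecord(cell_id=cid, state=state.label,
                                    traces=det, source_id=src))
            truth.full_cells.append(CellRecord(cell_id=cid,
                                               state=state.label,
                                               traces=full, source_id=src))
            truth.states.append(state.label)
            k += 1
    return cells, truth


def simulate_foci(cells: list[CellRecord], codebook: Codebook,
                  localization_sd: float = 50.0,
                  false_positive_rate: float = 2.0,
                  miss_rate: float = 0.1, seed: int = 0,
                  nuclear_radius: float = 4000.0,
                  ) -> tuple[list[FociSet], SimTruth]:
    """Emit per-bit foci point clouds from cells carrying true locus positions.

    Each locus emits one focus into each of its barcode's two on-bits,
    jittered by an isotropic Gaussian of s.d. ``localization_sd`` and dropped
    independently with probability ``miss_rate``; spurious foci are added per
    bit as Poisson(``false_positive_rate``) uniform points in the nucleus.
    """
    if localization_sd < 0 or false_positive_rate < 0 or not (
            0 <= miss_rate <= 1):
        raise ValueError("rates must be nonnegative (miss_rate in [0, 1])")
    onbits = {r.region_index: bc.on_bits
              for r, bc in zip(codebook.regions, codebook.barcodes)}
    children = np.random.SeedSequence(seed).spawn(max(len(cells), 1))
    out: list[FociSet] = []
    truth = SimTruth(foci=[], params=dict(
        localization_sd=localization_sd,
        false_positive_rate=false_positive_rate, miss_rate=miss_rate))
    for cell, child in zip(cells, children):
        rng = np.random.default_rng(child)
        fs = FociSet.empty()
        regs, xyz, _ = cell.loci_arrays()
        per_bit: list[list[np.ndarray]] = [[] for _ in range(N_BITS)]
        emitted = np.zeros((len(regs), 2), dtype=bool)
        for li, (ri, p) in enumerate(zip(regs, xyz)):
            for side, bit in enumerate(onbits[int(ri)]):
                if rng.random() < miss_rate:
                    rng.normal(size=3)   # keep stream aligned
                    continue
                jit = rng.normal(scale=localization_sd, size=3) \
                    if localization_sd > 0 else rng.normal(size=3) * 0.0
                per_bit[bit].append(np.array([*(p + jit), 1.0]))
                emitted[li, side] = True
        for bit in range(N_BITS):
            n_fp = rng.poisson(false_positive_rate)
            if n_fp:
                pts = _uniform_ball(rng, n_fp, nuclear_radius)
                for p in pts:
                    per_bit[bit].append(np.array([*p, 0.5]))
            fs.bits[bit] = (np.vstack(per_bit[bit]) if per_bit[bit]
                            else np.empty((0, 4)))
        out.append(fs)
        truth.foci.append(dict(cell_id=cell.cell_id, regions=regs.copy(),
                               xyz=xyz.copy(),
                               both_emitted=emitted.all(axis=1)))
    return out, truth


def simulate_expression(n_genes: int = 200, cpd_fraction: float = 0.1,
                        n_cells: tuple[int, int] = (100, 100),
                        effect_log2fc: float = 2.0,
                        homogeneity_contrast: bool = True,
                        seed: int = 0,
                        ) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Simulate a two-group expression matrix plus a matched DE summary table.

    Candidate-progression-driver (CPD) class genes are upregulated in the
    second group with low dispersion (homogeneous expression); an equally
    sized control class gets the same mean shift but with a high-variance
    bimodal mixture (heterogeneous); remaining genes are null.  The DE table
    rows carry the true generative means and fold changes.
    """
    if not (0 <= cpd_fraction <= 1):
        raise ValueError("cpd_fraction must be in [0, 1]")
    n_a, n_b = n_cells
    if n_a <= 0 or n_b <= 0:
        raise ValueError("both groups need at least one cell")
    rng = np.random.default_rng(seed)
    n_cpd = int(round(cpd_fraction * n_genes))
    n_ctrl = min(n_cpd, n_genes - n_cpd)
    classes = np.array(["cpd"] * n_cpd + ["control"] * n_ctrl
                       + ["null"] * (n_genes - n_cpd - n_ctrl))
    base = np.exp(rng.uniform(np.log(20.0), np.log(100.0), n_genes))
    fc = np.where(classes == "null", 0.0, effect_log2fc)

    def nb(mu: np.ndarray, r: float) -> np.ndarray:
        mu = np.clip(mu, 1e-9, None)
        return rng.negative_binomial(r, r / (r + mu))

    counts = np.zeros((n_genes, n_a + n_b))
    for g in range(n_genes):
        mu_a, mu_b = base[g], base[g] * 2.0 ** fc[g]
        if classes[g] == "cpd":
            counts[g, :n_a] = nb(np.full(n_a, mu_a), 20.0)
            counts[g, n_a:] = nb(np.full(n_b, mu_b), 20.0)
        elif classes[g] == "control" and homogeneity_contrast:
            counts[g, :n_a] = nb(np.full(n_a, mu_a), 2.0)
            comp = rng.random(n_b) < 0.5
            mu_mix = np.where(comp, 1.8 * mu_b, 0.2 * mu_b)
            counts[g, n_a:] = nb(mu_mix, 2.0)
        else:
            r = 20.0 if classes[g] == "control" else 5.0
            counts[g, :n_a] = nb(np.full(n_a, mu_a), r)
            counts[g, n_a:] = nb(np.full(n_b, mu_b), r)

    genes = [f"gene{g:04d}" for g in range(n_genes)]
    cols = [f"A_{i}" for i in range(n_a)] + [f"B_{i}" for i in range(n_b)]
    expr = pd.DataFrame(counts, index=genes, columns=cols)

    region = np.full(n_genes, np.nan)
    region[classes == "cpd"] = np.arange(n_cpd)
    region[classes == "control"] = np.arange(n_cpd, n_cpd + n_ctrl)
    mean_count = (n_a * base + n_b * base * 2.0 ** fc) / (n_a + n_b)
    fdr = np.where(classes == "null", rng.random(n_genes), 1e-4)
    de = pd.DataFrame(dict(gene=genes, region_index=region,
                           mean_count=mean_count, log2fc=fc, fdr=fdr))
    truth = SimTruth(gene_class=pd.Series(classes, index=genes),
                     gene_log2fc=pd.Series(fc, index=genes),
                     params=dict(effect_log2fc=effect_log2fc,
                                 n_cells=n_cells))
    return expr, de, truth


def reference_profile_from_truth(truth: SimTruth, noise_sd: float = 0.2,
                                 seed: int = 0) -> ReferenceProfile:
    """Activity profile consistent with the simulated A/B labels (+noise)."""
    rng = np.random.default_rng(seed)
    vals = np.where(truth.region_a, 1.0, -1.0)
    return ReferenceProfile(values=vals + rng.normal(0, noise_sd, len(vals)))
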