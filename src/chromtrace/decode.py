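"""Barcode decoding and trace linking from per-bit foci point clouds.

A target locus appears in exactly the two imaging bits of its weight-2
barcode, so decoding reduces to pairing foci across the two on-bits of each
codebook region.  Candidate pairs within ``pair_radius`` are accepted greedily
by ascending pair distance, consuming each focus at most once; the decoded
position is the midpoint of the pair and the pair distance is kept as a
quality score (smaller is better).

Decoded loci are then linked into chromosome copies by a 2-means spatial
split per chromosome, accepted only when it reduces within-cluster dispersion
enough; this linking algorithm is a stated stand-in honoring the decoded-loci
to per-copy-traces contract.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import FociSet, SimTruth
from .types import ChromatinTrace, Codebook, Locus3D

__all__ = ["DecodeParams", "decode_foci", "link_traces", "decode_benchmark"]


@dataclass(frozen=True)
class DecodeParams:
    """Decoding thresholds (nm)."""

    pair_radius: float = 300.0
    link_radius: float = 2000.0
    max_copies: int = 2
    split_factor: float = 2.0   # required dispersion reduction for a 2-way split

    def __post_init__(self) -> None:
        if self.pair_radius <= 0 or self.link_radius <= 0:
            raise ValueError("radii must be > 0")


def decode_foci(foci: FociSet, codebook: Codebook,
                params: DecodeParams | None = None) -> list[Locus3D]:
    """Decode one nucleus's foci into loci by greedy nearest-pair matching.

    Candidates from all regions are pooled and accepted by ascending pair
    distance; ties are broken by (region_index, bit-i focus order) so the
    result is deterministic.
    """
    params = params or DecodeParams()
    candidates = []  # (distance, region_index, idx_i, idx_j, bits)
    for region, bc in zip(codebook.regions, codebook.barcodes):
        bi, bj = bc.on_bits
        fi, fj = foci.bits[bi], foci.bits[bj]
        if len(fi) == 0 or len(fj) == 0:
            continue
        d = np.linalg.norm(fi[:, None, :3] - fj[None, :, :3], axis=2)
        ii, jj = np.nonzero(d <= params.pair_radius)
        for a, b in zip(ii, jj):
            candidates.append((float(d[a, b]), region.region_index,
                               int(a), int(b), bi, bj))
    candidates.sort(key=lambda c: (c[0], c[1], c[2], c[3]))

    # a region may legitimately be decoded more than once (one call per
    # chromosome copy); per-trace duplicates are resolved in link_traces
    used: set[tuple[int, int]] = set()
    out: list[Locus3D] = []
    for dist, ri, a, b, bi, bj in candidates:
        if (bi, a) in used or (bj, b) in used:
            continue
        used.add((bi, a))
        used.add((bj, b))
        mid = 0.5 * (foci.bits[bi][a, :3] + foci.bits[bj][b, :3])
        out.append(Locus3D(region_index=ri, x=float(mid[0]), y=float(mid[1]),
                           z=float(mid[2]), quality=dist))
    out.sort(key=lambda l: (l.region_index, l.quality))
    return out


def _two_means(xyz: np.ndarray, max_iter: int = 50) -> np.ndarray:
    """Deterministic 2-means: seeded from the two most distant points."""
    d = np.linalg.norm(xyz[:, None] - xyz[None, :], axis=2)
    i, j = np.unravel_index(np.argmax(d), d.shape)
    centers = xyz[[i, j]].astype(float)
    labels = np.zeros(len(xyz), dtype=int)
    for _ in range(max_iter):
        dist = np.linalg.norm(xyz[:, None] - centers[None], axis=2)
        new = np.argmin(dist, axis=1)
        if (new == labels).all() and _ > 0:
            break
        labels = new
        for k in (0, 1):
            if (labels == k).any():
                centers[k] = xyz[labels == k].mean(axis=0)
    return labels


def link_traces(loci: list[Locus3D], codebook: Codebook,
                params: DecodeParams | None = None) -> list[ChromatinTrace]:
    """Partition decoded loci into at most ``max_copies`` traces per chromosome.

    A 2-cluster split is kept only if it reduces the mean within-cluster
    squared dispersion by at least ``split_factor``; duplicate regions within
    a cluster keep the best-quality (smallest pair distance) locus.
    """
    params = params or DecodeParams()
    chrom_of = codebook.chrom_of_region()
    by_chrom: dict[int, list[Locus3D]] = {}
    for l in loci:
        by_chrom.setdefault(int(chrom_of[l.region_index]), []).append(l)

    traces: list[ChromatinTrace] = []
    for chrom in sorted(by_chrom):
        group = by_chrom[chrom]
        xyz = np.array([[l.x, l.y, l.z] for l in group])
        if len(group) < 4 or params.max_copies < 2:
            labels = np.zeros(len(group), dtype=int)
        else:
            one = ((xyz - xyz.mean(axis=0)) ** 2).sum(axis=1).mean()
            labels2 = _two_means(xyz)
            disp2 = 0.0
            for k in (0, 1):
                sub = xyz[labels2 == k]
                if len(sub):
                    disp2 += ((sub - sub.mean(axis=0)) ** 2).sum()
            disp2 /= len(group)
            if disp2 > 0 and one / disp2 >= params.split_factor:
                labels = labels2
            else:
                labels = np.zeros(len(group), dtype=int)
        for copy_id in sorted(set(labels.tolist())):
            members = [l for l, lab in zip(group, labels) if lab == copy_id]
            best: dict[int, Locus3D] = {}
            for l in members:
                cur = best.get(l.region_index)
                if cur is None or l.quality < cur.quality:
                    best[l.region_index] = l
            ordered = [best[k] for k in sorted(best)]
            traces.append(ChromatinTrace(chrom=chrom, copy_id=int(copy_id),
                                         loci=ordered))
    return traces


def decode_benchmark(truth: SimTruth, decoded_by_cell: list,
                     match_radius: float = 300.0) -> dict:
    """Score decoded loci against the foci-simulation ground truth.

    ``decoded_by_cell`` holds, per cell, either the raw decoded loci
    (:class:`Locus3D` list, measuring the decoder alone) or linked
    :class:`ChromatinTrace` objects (measuring decode + linking; linking
    merges homolog copies whose territories overlap, so its recall is
    bounded away from 1 even on noiseless input).

    A decoded locus is a true positive if it lies within ``match_radius`` of
    an unmatched same-region true locus.  Returns:

    ``recall``
        true positives / all true loci;
    ``recall_detectable``
        true positives / loci whose two on-bit foci were both emitted
        (the information-theoretic ceiling when foci are missing);
    ``precision``
        true positives / decoded loci (1.0 by convention when nothing was
        decoded, with ``n_decoded`` reported so the case is visible);
    ``rms_error``
        RMS position error over true positives.
    """
    if truth.foci is None:
        raise ValueError("truth must come from simulate_foci")
    if len(truth.foci) != len(decoded_by_cell):
        raise ValueError("cell count mismatch between truth and decoded set")
    tp = 0
    n_true = 0
    n_detectable = 0
    n_decoded = 0
    sq = 0.0
    for cell_truth, traces in zip(truth.foci, decoded_by_cell):
        regs = cell_truth["regions"]
        xyz = cell_truth["xyz"]
        n_true += len(regs)
        n_detectable += int(cell_truth["both_emitted"].sum())
        loci = []
        for item in traces:
            if isinstance(item, Locus3D):
                loci.append(item)
            else:
                loci.extend(item.loci)
        taken = np.zeros(len(regs), dtype=bool)
        for locus in loci:
            n_decoded += 1
            cand = np.nonzero((regs == locus.region_index) & ~taken)[0]
            if len(cand) == 0:
                continue
            d = np.linalg.norm(xyz[cand] - locus.xyz, axis=1)
            k = int(np.argmin(d))
            if d[k] <= match_radius:
                taken[cand[k]] = True
                tp += 1
                sq += float(d[k] ** 2)
    return dict(
        recall=tp / n_true if n_true else 0.0,
        recall_detectable=tp / n_detectable if n_detectable else 0.0,
        precision=tp / n_decoded if n_decoded else 1.0,
        rms_error=float(np.sqrt(sq / tp)) if tp else 0.0,
        n_true=n_true, n_detectable=n_detectable, n_decoded=n_decoded,
    )
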