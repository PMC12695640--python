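"""Domain types for single-cell chromatin-tracing data.

The data model follows the imaging design: a panel of genomic regions (one per
TAD-scale target locus), each carrying a weight-2 binary barcode over 100
imaging bits; decoded 3D loci grouped into per-homolog chromatin traces; and
cells holding the traces together with a state label (e.g. a tumor progression
stage).

Conventions
-----------
* Genomic intervals are 0-based half-open internally.
* All spatial coordinates are nanometres.
* Missing loci are represented by absence, never by sentinel coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GenomicRegion",
    "Barcode",
    "Codebook",
    "Locus3D",
    "ChromatinTrace",
    "CellRecord",
    "ReferenceProfile",
    "CodebookError",
    "N_BITS",
]

#: number of imaging bits in the combinatorial barcode design
N_BITS = 100


class CodebookError(ValueError):
    """Raised when a codebook violates the barcoding contract."""


@dataclass(frozen=True)
class GenomicRegion:
    """One target genomic region (a TAD-scale locus on an autosome).

    Coordinates are 0-based half-open base pairs.
    """

    chrom: int
    start_bp: int
    end_bp: int
    region_index: int

    def __post_init__(self) -> None:
        if self.start_bp >= self.end_bp:
            raise ValueError(
                f"region {self.region_index}: start_bp must be < end_bp "
                f"({self.start_bp} >= {self.end_bp})"
            )

    @property
    def midpoint_bp(self) -> float:
        return 0.5 * (self.start_bp + self.end_bp)


@dataclass(frozen=True)
class Barcode:
    """A weight-2 binary barcode: exactly two '1' bits out of ``N_BITS``."""

    on_bits: tuple[int, int]

    def __post_init__(self) -> None:
        i, j = self.on_bits
        if not (0 <= i < N_BITS and 0 <= j < N_BITS) or i == j:
            raise CodebookError(f"invalid on-bit pair {self.on_bits}")
        if i > j:
            object.__setattr__(self, "on_bits", (j, i))

    @property
    def bits(self) -> np.ndarray:
        out = np.zeros(N_BITS, dtype=np.uint8)
        out[list(self.on_bits)] = 1
        return out

    @classmethod
    def from_bitstring(cls, s: str) -> "Barcode":
        s = s.strip()
        if len(s) != N_BITS or set(s) - {"0", "1"}:
            raise CodebookError(f"barcode must be a {N_BITS}-char bit string")
        on = tuple(k for k, c in enumerate(s) if c == "1")
        if len(on) != 2:
            raise CodebookError(
                f"barcode weight must be 2, got weight {len(on)}"
            )
        return cls(on_bits=on)  # type: ignore[arg-type]


@dataclass
class Codebook:
    """Parallel lists of target regions and their barcodes.

    All on-bit pairs are distinct across regions so decoding is unambiguous.
    """

    regions: list[GenomicRegion]
    barcodes: list[Barcode]

    def __post_init__(self) -> None:
        if len(self.regions) != len(self.barcodes):
            raise CodebookError("regions and barcodes must be parallel lists")
        seen: dict[tuple[int, int], int] = {}
        for r, bc in zip(self.regions, self.barcodes):
            if bc.on_bits in seen:
                raise CodebookError(
                    f"duplicate barcode {bc.on_bits} in rows "
                    f"{seen[bc.on_bits]} and {r.region_index}"
                )
            seen[bc.on_bits] = r.region_index
        order = sorted(range(len(self.regions)),
                       key=lambda k: (self.regions[k].chrom,
                                      self.regions[k].start_bp))
        if order != list(range(len(self.regions))):
            raise CodebookError("regions must be sorted by (chrom, start)")

    def __len__(self) -> int:
        return len(self.regions)

    @property
    def chroms(self) -> list[int]:
        return sorted({r.chrom for r in self.regions})

    def region_indices_on(self, chrom: int) -> np.ndarray:
        return np.array([r.region_index for r in self.regions
                         if r.chrom == chrom], dtype=int)

    def midpoints_mb(self) -> np.ndarray:
        """Region midpoints in megabases, indexed by region_index."""
        out = np.empty(len(self.regions))
        for r in self.regions:
            out[r.region_index] = r.midpoint_bp / 1e6
        return out

    def chrom_of_region(self) -> np.ndarray:
        out = np.empty(len(self.regions), dtype=int)
        for r in self.regions:
            out[r.region_index] = r.chrom
        return out


@dataclass(frozen=True)
class Locus3D:
    """A decoded genomic locus: region identity plus a 3D position in nm."""

    region_index: int
    x: float
    y: float
    z: float
    quality: float = 0.0

    def __post_init__(self) -> None:
        if not all(math.isfinite(v) for v in (self.x, self.y, self.z)):
            raise ValueError("locus coordinates must be finite")

    @property
    def xyz(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


@dataclass
class ChromatinTrace:
    """Ordered loci of one chromosome copy (homolog) in one cell."""

    chrom: int
    copy_id: int
    loci: list[Locus3D] = field(default_factory=list)

    def __post_init__(self) -> None:
        idx = [l.region_index for l in self.loci]
        if len(idx) != len(set(idx)):
            raise ValueError(
                f"trace chr{self.chrom}/{self.copy_id}: duplicate region"
            )

    def __len__(self) -> int:
        return len(self.loci)

    @property
    def region_indices(self) -> np.ndarray:
        return np.array([l.region_index for l in self.loci], dtype=int)

    @property
    def xyz(self) -> np.ndarray:
        if not self.loci:
            return np.empty((0, 3))
        return np.array([[l.x, l.y, l.z] for l in self.loci])

    @property
    def qualities(self) -> np.ndarray:
        return np.array([l.quality for l in self.loci])


@dataclass
class CellRecord:
    """One cell: a state label and its chromatin traces."""

    cell_id: str
    state: str
    traces: list[ChromatinTrace] = field(default_factory=list)
    source_id: str = ""
    immune_adjacent: bool | None = None

    def n_traces(self) -> int:
        return len([t for t in self.traces if len(t) > 0])

    def loci_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """All detected loci of the cell as flat arrays.

        Returns ``(region_indices, xyz, chroms)``.
        """
        regs, xyzs, chroms = [], [], []
        for t in self.traces:
            if len(t) == 0:
                continue
            regs.append(t.region_indices)
            xyzs.append(t.xyz)
            chroms.append(np.full(len(t), t.chrom, dtype=int))
        if not regs:
            return (np.empty(0, dtype=int), np.empty((0, 3)),
                    np.empty(0, dtype=int))
        return np.concatenate(regs), np.vstack(xyzs), np.concatenate(chroms)


@dataclass
class ReferenceProfile:
    """Per-region chromatin-activity values used to orient compartment signs.

    Built by averaging standardized densities of active chromatin marks
    (H3K4me1/H3K4me3 peaks, DNase hypersensitivity, gene density) over the
    codebook regions; active (A) regions score high.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("reference profile must be 1-D")
        if np.allclose(self.values, self.values[0]):
            raise ValueError("reference profile must not be constant")

    def __len__(self) -> int:
        return len(self.values)
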