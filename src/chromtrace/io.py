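"""Readers and writers for codebooks, trace tables, foci, and reference tracks.

Trace tables use an FOF-CT-inspired flat CSV: one row per decoded locus, with
a ``#unit:`` header line declaring the spatial unit of the file (``nm`` or
``um``).  Internally everything is nanometres.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    Barcode,
    CellRecord,
    ChromatinTrace,
    Codebook,
    CodebookError,
    GenomicRegion,
    Locus3D,
    ReferenceProfile,
)

__all__ = [
    "load_codebook",
    "read_traces",
    "write_traces",
    "read_foci",
    "write_foci",
    "region_activity_from_bed",
    "read_de_table",
    "read_expression",
]

TRACE_COLUMNS = ["Cell_ID", "State", "Source_ID", "Chrom", "Chrom_Start",
                 "Chrom_End", "Trace_ID", "X", "Y", "Z", "Quality"]


def _parse_chrom(value) -> int:
    s = str(value)
    if s.lower().startswith("chr"):
        s = s[3:]
    try:
        return int(s)
    except ValueError:
        raise ValueError(f"unknown chromosome {value!r}") from None


def load_codebook(path, one_based: bool = False) -> Codebook:
    """Load a codebook CSV into a validated :class:`Codebook`.

    Expected columns: ``chrom``, ``start``, ``end`` and either ``barcode``
    (a 100-character bit string) or ``bit_i``/``bit_j`` (the two on-bit
    indices).  Set ``one_based=True`` when the table uses 1-based inclusive
    coordinates (the published-table convention); internal storage is 0-based
    half-open.
    """
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"chrom", "start", "end"}
    if not required <= set(df.columns):
        raise CodebookError(f"codebook must have columns {sorted(required)}")
    has_string = "barcode" in df.columns
    has_bits = {"bit_i", "bit_j"} <= set(df.columns)
    if not (has_string or has_bits):
        raise CodebookError("codebook needs 'barcode' or 'bit_i'/'bit_j'")

    rows = []
    for irow, row in df.iterrows():
        chrom = _parse_chrom(row["chrom"])
        try:
            start = int(row["start"])
            end = int(row["end"])
        except (TypeError, ValueError):
            raise CodebookError(f"row {irow}: malformed coordinates") from None
        if one_based:
            start -= 1
        if has_string:
            try:
                bc = Barcode.from_bitstring(str(row["barcode"]))
            except CodebookError as exc:
                raise CodebookError(f"row {irow}: {exc}") from None
        else:
            bc = Barcode(on_bits=(int(row["bit_i"]), int(row["bit_j"])))
        rows.append((chrom, start, end, bc))

    rows.sort(key=lambda r: (r[0], r[1]))
    regions = [GenomicRegion(chrom=c, start_bp=s, end_bp=e, region_index=k)
               for k, (c, s, e, _) in enumerate(rows)]
    return Codebook(regions=regions, barcodes=[r[3] for r in rows])


def _unit_scale(path) -> float:
    with open(path) as fh:
        first = fh.readline().strip()
    if first.startswith("#unit:"):
        unit = first.split(":", 1)[1].strip().lower()
        if unit in ("nm",):
            return 1.0
        if unit in ("um", "µm", "micron"):
            return 1000.0
        raise ValueError(f"unknown spatial unit {unit!r}")
    return 1.0


def read_traces(path, codebook: Codebook) -> list[CellRecord]:
    """Read an FOF-CT-style trace CSV into :class:`CellRecord` objects.

    Rows are grouped by ``Cell_ID`` and then by ``(Chrom, Trace_ID)``; the
    region of each row is resolved against the codebook by exact
    ``(chrom, start)`` match.  Coordinates declared in µm are converted to nm.
    """
    scale = _unit_scale(path)
    df = pd.read_csv(path, comment="#")
    missing = set(TRACE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trace file missing columns {sorted(missing)}")

    lookup = {(r.chrom, r.start_bp): r.region_index for r in codebook.regions}
    dup = df.duplicated(subset=["Cell_ID", "Chrom", "Trace_ID", "Chrom_Start"])
    if dup.any():
        bad = df.loc[dup.idxmax()]
        raise ValueError(
            f"duplicate locus rows for cell {bad.Cell_ID} "
            f"trace {bad.Trace_ID} start {bad.Chrom_Start}"
        )

    cells: list[CellRecord] = []
    for cell_id, cdf in df.groupby("Cell_ID", sort=True):
        state = str(cdf["State"].iloc[0])
        source = str(cdf["Source_ID"].iloc[0])
        traces = []
        for (chrom, trace_id), tdf in cdf.groupby(["Chrom", "Trace_ID"],
                                                  sort=True):
            ichrom = _parse_chrom(chrom)
            loci = []
            for _, row in tdf.iterrows():
                key = (ichrom, int(row["Chrom_Start"]))
                if key not in lookup:
                    raise ValueError(
                        f"no codebook region at chr{ichrom}:{key[1]}"
                    )
                loci.append(Locus3D(region_index=lookup[key],
                                    x=float(row["X"]) * scale,
                                    y=float(row["Y"]) * scale,
                                    z=float(row["Z"]) * scale,
                                    quality=float(row["Quality"])))
            loci.sort(key=lambda l: l.region_index)
            traces.append(ChromatinTrace(chrom=ichrom, copy_id=int(trace_id),
                                         loci=loci))
        cells.append(CellRecord(cell_id=str(cell_id), state=state,
                                traces=traces, source_id=source))
    return cells


def write_traces(cells: list[CellRecord], path, codebook: Codebook) -> None:
    """Write cells to an FOF-CT-style CSV (always in nm).

    Row order is deterministic: (cell_id, chrom, copy_id, region start).
    """
    region_of = {r.region_index: r for r in codebook.regions}
    rows = []
    for cell in sorted(cells, key=lambda c: c.cell_id):
        for trace in sorted(cell.traces, key=lambda t: (t.chrom, t.copy_id)):
            for locus in sorted(trace.loci, key=lambda l: l.region_index):
                reg = region_of[locus.region_index]
                rows.append((cell.cell_id, cell.state, cell.source_id,
                             reg.chrom, reg.start_bp, reg.end_bp,
                             trace.copy_id, locus.x, locus.y, locus.z,
                             locus.quality))
    df = pd.DataFrame(rows, columns=TRACE_COLUMNS)
    with open(path, "w") as fh:
        fh.write("#unit: nm\n")
        df.to_csv(fh, index=False)


def read_foci(path) -> dict:
    """Read a foci CSV (Cell_ID, Bit, X, Y, Z, Intensity) into FociSets.

    Returns a mapping cell_id -> :class:`~chromtrace.simulate.FociSet`
    (100 per-bit arrays of x, y, z, intensity in nm).
    """
    from .simulate import FociSet  # local import to avoid a cycle

    scale = _unit_scale(path)
    df = pd.read_csv(path, comment="#")
    out: dict = {}
    for cell_id, cdf in df.groupby("Cell_ID", sort=True):
        fs = FociSet.empty()
        for bit, bdf in cdf.groupby("Bit"):
            pts = bdf[["X", "Y", "Z", "Intensity"]].to_numpy(dtype=float)
            pts[:, :3] *= scale
            fs.bits[int(bit)] = pts
        out[str(cell_id)] = fs
    return out


def write_foci(foci_by_cell: dict, path) -> None:
    rows = []
    for cell_id in sorted(foci_by_cell):
        fs = foci_by_cell[cell_id]
        for bit, pts in enumerate(fs.bits):
            for x, y, z, inten in np.atleast_2d(pts).reshape(-1, 4):
                rows.append((cell_id, bit, x, y, z, inten))
    df = pd.DataFrame(rows,
                      columns=["Cell_ID", "Bit", "X", "Y", "Z", "Intensity"])
    with open(path, "w") as fh:
        fh.write("#unit: nm\n")
        df.to_csv(fh, index=False)


def _coverage_fraction(codebook: Codebook, intervals: pd.DataFrame) -> np.ndarray:
    """Fraction of each codebook region covered by a set of BED intervals."""
    out = np.zeros(len(codebook))
    for r in codebook.regions:
        sub = intervals[intervals["chrom"] == r.chrom]
        if sub.empty:
            continue
        lo = np.maximum(sub["start"].to_numpy(), r.start_bp)
        hi = np.minimum(sub["end"].to_numpy(), r.end_bp)
        out[r.region_index] = np.clip(hi - lo, 0, None).sum() / (
            r.end_bp - r.start_bp)
    return out


def _read_bed3(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=r"\s+", comment="#", header=None,
                     usecols=[0, 1, 2], names=["chrom", "start", "end"])
    df["chrom"] = df["chrom"].map(_parse_chrom)
    return df


def region_activity_from_bed(bed_paths: list, codebook: Codebook,
                             gene_density: np.ndarray | None = None,
                             ) -> ReferenceProfile:
    """Build a chromatin-activity reference profile from BED tracks.

    Each track's per-region coverage density is standardized to zero mean and
    unit variance across regions; standardized tracks (plus an optional
    per-region gene-density track) are averaged.
    """
    tracks = []
    for p in bed_paths:
        cov = _coverage_fraction(codebook, _read_bed3(p))
        tracks.append(cov)
    if gene_density is not None:
        gd = np.asarray(gene_density, dtype=float)
        if len(gd) != len(codebook):
            raise ValueError("gene density length must match codebook")
        tracks.append(gd)
    if not tracks:
        raise ValueError("no tracks provided")
    if all(np.allclose(t, 0) for t in tracks):
        raise ValueError("all tracks have empty overlap with the codebook")

    # sanity check against assembly mismatch
    max_end = max(r.end_bp for r in codebook.regions)
    for p in bed_paths:
        bed = _read_bed3(p)
        if (bed["start"] > 10 * max_end).any():
            warnings.warn(f"{p}: coordinates far beyond codebook regions; "
                          "possible assembly mismatch")

    stds = []
    for t in tracks:
        sd = t.std()
        if sd == 0:
            warnings.warn("track with zero variance across regions skipped")
            continue
        stds.append((t - t.mean()) / sd)
    if not stds:
        raise ValueError("no track varies across regions")
    return ReferenceProfile(values=np.mean(stds, axis=0))


def read_de_table(path) -> pd.DataFrame:
    """Read a differential-expression TSV.

    Required columns: ``gene``, ``mean_count``, ``log2fc``, ``fdr``;
    ``region_index`` optional (NaN where a gene lies outside all regions).
    """
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"gene", "mean_count", "log2fc", "fdr"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"DE table missing columns {sorted(missing)}")
    if "region_index" not in df.columns:
        df["region_index"] = np.nan
    if ((df["fdr"] < 0) | (df["fdr"] > 1)).any():
        raise ValueError("fdr values must lie in [0, 1]")
    if (df["mean_count"] < 0).any():
        raise ValueError("mean_count must be nonnegative")
    return df


def read_expression(path, genes_path=None, cells_path=None) -> pd.DataFrame:
    """Read a gene x cell expression matrix (MTX triplet or dense TSV).

    For MTX input, ``genes_path``/``cells_path`` give one name per line.
    Returns a genes x cells DataFrame of nonnegative values.
    """
    path = Path(path)
    if path.suffix == ".mtx":
        from scipy.io import mmread
        mat = np.asarray(mmread(str(path)).todense())
        genes = [l.strip() for l in open(genes_path)] if genes_path else [
            f"g{i}" for i in range(mat.shape[0])]
        cols = [l.strip() for l in open(cells_path)] if cells_path else [
            f"c{i}" for i in range(mat.shape[1])]
        df = pd.DataFrame(mat, index=genes, columns=cols)
    else:
        df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.to_numpy() < 0).any():
        raise ValueError("expression matrix has negative entries")
    return df
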