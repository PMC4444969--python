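"""Genome-track readers/writers and training-set construction.

Coordinate conventions are uniform across the package: every stored interval
is 0-based half-open (the BED/bedGraph convention), every user-facing SNP or
matrix position is 1-based.  The two helpers :func:`to_zero_based` and
:func:`to_one_based` are the only conversion points.

This module also implements the training-set construction rules used to build
the annotation matrix from raw tracks: peak binarization across cell lines
(signal in at least one cell line codes the annotation as 1), the 1 kb window
around each GWAS SNP (500 bp upstream through 499 bp downstream), interval
merging, and assembly of the per-position annotation matrix with missingness
recorded for continuous tracks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .annotation_model import AnnotationMatrix, AnnotationSchema, ModelError


class TrackError(ValueError):
    """Raised for malformed track files or inconsistent coordinates."""


def to_zero_based(pos1: int) -> int:
    """1-based coordinate -> 0-based coordinate."""
    return int(pos1) - 1


def to_one_based(pos0: int) -> int:
    """0-based coordinate -> 1-based coordinate."""
    return int(pos0) + 1


# ---------------------------------------------------------------------------
# Intervals
# ---------------------------------------------------------------------------

class Interval(NamedTuple):
    chrom: str
    start: int  # 0-based inclusive
    end: int    # exclusive
    name: str | None = None
    score: float | None = None

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class IntervalSet:
    """A set of genomic intervals, 0-based half-open."""

    records: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        for iv in self.records:
            if iv.start >= iv.end:
                raise TrackError(f"empty or inverted interval: {iv}")
            if iv.start < 0:
                raise TrackError(f"negative start: {iv}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def sorted(self) -> "IntervalSet":
        return IntervalSet(sorted(self.records, key=lambda iv: (iv.chrom, iv.start, iv.end)))

    def total_length(self) -> int:
        """Covered bases (after merging overlaps)."""
        return sum(iv.length for iv in merge_intervals(self))

    def chroms(self) -> list[str]:
        return sorted({iv.chrom for iv in self.records})

    def membership(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Boolean membership of 0-based positions in this set (after merge)."""
        merged = [iv for iv in merge_intervals(self) if iv.chrom == chrom]
        positions = np.asarray(positions, dtype=int)
        out = np.zeros(positions.shape, dtype=bool)
        if not merged:
            return out
        starts = np.array([iv.start for iv in merged])
        ends = np.array([iv.end for iv in merged])
        idx = np.searchsorted(starts, positions, side="right") - 1
        ok = idx >= 0
        out[ok] = positions[ok] < ends[idx[ok]]
        return out


def merge_intervals(intervals: IntervalSet | Iterable[Interval]) -> IntervalSet:
    """Minimal sorted set of disjoint intervals with identical base coverage.

    Idempotent and order-invariant; touching intervals ([0,5) + [5,9)) are
    joined.
    """
    records = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[Interval] = []
    for iv in records:
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = Interval(last.chrom, last.start, iv.end)
        else:
            merged.append(Interval(iv.chrom, iv.start, iv.end))
    return IntervalSet(merged)


def read_bed(path) -> IntervalSet:
    """Read BED3+ (0-based half-open). Malformed lines raise with their number."""
    records: list[Interval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise TrackError(f"{path}:{lineno}: expected >= 3 BED columns")
            try:
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            except ValueError:
                raise TrackError(f"{path}:{lineno}: non-integer coordinates") from None
            if start >= end:
                raise TrackError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            name = parts[3] if len(parts) > 3 and parts[3] != "." else None
            score = None
            if len(parts) > 4 and parts[4] != ".":
                score = float(parts[4])
            records.append(Interval(chrom, start, end, name, score))
    return IntervalSet(records)


def write_bed(intervals: IntervalSet, path) -> None:
    with open(path, "w") as fh:
        for iv in intervals.sorted():
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.score is not None:
                fields.append(iv.name if iv.name is not None else ".")
            if iv.score is not None:
                fields.append(f"{iv.score:.6f}")
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Score tracks
# ---------------------------------------------------------------------------

@dataclass
class ScoreTrack:
    """Per-position real-valued track; positions 0-based, sorted within chrom."""

    chroms: np.ndarray
    positions: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.chroms = np.asarray(self.chroms, dtype=object)
        self.positions = np.asarray(self.positions, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if not (len(self.chroms) == len(self.positions) == len(self.values)):
            raise TrackError("track arrays must have equal length")
        for chrom in np.unique(self.chroms):
            pos = self.positions[self.chroms == chrom]
            if len(pos) != len(np.unique(pos)):
                raise TrackError(f"duplicate positions on {chrom}")
            if not np.all(np.diff(pos) > 0):
                raise TrackError(f"positions not sorted on {chrom}")

    def __len__(self) -> int:
        return len(self.positions)

    @classmethod
    def from_positions(cls, chrom: str, positions: np.ndarray,
                       values: np.ndarray) -> "ScoreTrack":
        positions = np.asarray(positions, dtype=int)
        order = np.argsort(positions)
        return cls(np.array([chrom] * len(positions), dtype=object),
                   positions[order], np.asarray(values, dtype=float)[order])

    def values_at(self, chrom: str, positions: np.ndarray,
                  ) -> tuple[np.ndarray, np.ndarray]:
        """Values at 0-based positions and an observed mask (False = absent)."""
        positions = np.asarray(positions, dtype=int)
        sel = self.chroms == chrom
        track_pos = self.positions[sel]
        track_val = self.values[sel]
        idx = np.searchsorted(track_pos, positions)
        found = (idx < len(track_pos))
        found[found] = track_pos[idx[found]] == positions[found]
        out = np.full(len(positions), np.nan)
        out[found] = track_val[idx[found]]
        return out, found


def read_bedgraph(path, expand: bool = True) -> ScoreTrack:
    """Read 4-column bedGraph; interval records are expanded to per-position
    values.  Records that cover a position twice with conflicting values are an
    error."""
    chroms: list[str] = []
    positions: list[int] = []
    values: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise TrackError(f"{path}:{lineno}: expected 4 bedGraph columns")
            try:
                chrom, start, end, value = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            except ValueError:
                raise TrackError(f"{path}:{lineno}: malformed record") from None
            if start >= end:
                raise TrackError(f"{path}:{lineno}: start >= end")
            span = range(start, end) if expand else [start]
            for p in span:
                chroms.append(chrom)
                positions.append(p)
                values.append(value)
    frame = pd.DataFrame({"chrom": chroms, "pos": positions, "value": values})
    dup = frame.duplicated(subset=["chrom", "pos"], keep=False)
    if dup.any():
        conflicts = frame[dup].groupby(["chrom", "pos"])["value"].nunique()
        if (conflicts > 1).any():
            where = conflicts[conflicts > 1].index[0]
            raise TrackError(f"{path}: conflicting values at {where[0]}:{where[1]}")
        frame = frame.drop_duplicates(subset=["chrom", "pos"])
    frame = frame.sort_values(["chrom", "pos"], kind="stable")
    return ScoreTrack(frame["chrom"].to_numpy(dtype=object),
                      frame["pos"].to_numpy(), frame["value"].to_numpy())


def write_bedgraph(track: ScoreTrack, path, precision: int = 6) -> None:
    """Write a per-position track, collapsing runs of adjacent positions whose
    printed value (at ``precision`` decimals) is identical."""
    with open(path, "w") as fh:
        run_chrom = None
        run_start = run_end = 0
        run_val = ""
        for chrom, pos, val in zip(track.chroms, track.positions, track.values):
            sval = f"{val:.{precision}f}"
            if (chrom == run_chrom and pos == run_end and sval == run_val):
                run_end = pos + 1
                continue
            if run_chrom is not None:
                fh.write(f"{run_chrom}\t{run_start}\t{run_end}\t{run_val}\n")
            run_chrom, run_start, run_end, run_val = chrom, int(pos), int(pos) + 1, sval
        if run_chrom is not None:
            fh.write(f"{run_chrom}\t{run_start}\t{run_end}\t{run_val}\n")


# ---------------------------------------------------------------------------
# Training-set construction rules
# ---------------------------------------------------------------------------

def binarize_peaks(per_cell_line: Sequence[IntervalSet],
                   positions: Sequence[tuple[str, int]] | np.ndarray,
                   ) -> np.ndarray:
    """Union rule: a position codes 1 iff it falls in at least one peak of at
    least one cell line.  ``positions`` are (chrom, 0-based position) pairs.
    """
    if len(per_cell_line) < 1:
        raise TrackError("need at least one cell line")
    union = merge_intervals([iv for cl in per_cell_line for iv in cl])
    chroms = np.array([c for c, _ in positions], dtype=object)
    pos = np.array([p for _, p in positions], dtype=int)
    out = np.zeros(len(pos), dtype=float)
    for chrom in np.unique(chroms):
        sel = chroms == chrom
        out[sel] = union.membership(chrom, pos[sel]).astype(float)
    return out


def expand_snp_intervals(snp_positions: Sequence[tuple[str, int]]) -> IntervalSet:
    """1 kb window per SNP: 500 bp upstream through 499 bp downstream.

    A SNP at 1-based position p becomes the 0-based half-open interval
    [p - 501, p + 499), spanning exactly 1,000 bases (1-based p-500 ... p+499).
    SNPs within 500 bp of the chromosome start yield clipped intervals flagged
    with name ``"clipped"``.
    """
    records: list[Interval] = []
    n_clipped = 0
    for chrom, p in snp_positions:
        p = int(p)
        if p < 1:
            raise TrackError(f"SNP position must be >= 1, got {p}")
        start = to_zero_based(p) - 500
        end = to_zero_based(p) + 500
        if start < 0:
            records.append(Interval(chrom, 0, end, "clipped"))
            n_clipped += 1
        else:
            records.append(Interval(chrom, start, end))
    if n_clipped:
        warnings.warn(f"{n_clipped} SNP interval(s) clipped at the chromosome start",
                      stacklevel=2)
    return IntervalSet(records)


def read_snp_positions(path) -> list[tuple[str, int]]:
    """TSV SNP list: chrom, 1-based position[, id]; optional header."""
    out: list[tuple[str, int]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "chrom":
                continue
            if len(parts) < 2:
                raise TrackError(f"{path}:{lineno}: expected chrom and position")
            out.append((parts[0], int(parts[1])))
    return out


def write_snp_positions(snps: Sequence[tuple[str, int]], path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tid\n")
        for i, (chrom, p) in enumerate(snps):
            fh.write(f"{chrom}\t{p}\tsnp{i}\n")


# ---------------------------------------------------------------------------
# Annotation-matrix assembly and TSV round trip
# ---------------------------------------------------------------------------

def build_annotation_matrix(positions: Sequence[tuple[str, int]],
                            continuous_tracks: dict[str, ScoreTrack],
                            binary_tracks_per_cell_line: dict[str, Sequence[IntervalSet]],
                            schema: AnnotationSchema) -> AnnotationMatrix:
    """Collect all annotations at each (chrom, 1-based) position.

    Continuous values come from per-position tracks with the mask recording
    track gaps; binary columns come from cross-cell-line peak binarization and
    must be defined everywhere.
    """
    if len(positions) == 0:
        raise TrackError("empty position list")
    n = len(positions)
    m = len(schema)
    values = np.zeros((n, m))
    mask = np.ones((n, m), dtype=bool)
    chroms = np.array([c for c, _ in positions], dtype=object)
    pos0 = np.array([to_zero_based(p) for _, p in positions], dtype=int)
    pos_pairs = list(zip(chroms, pos0))
    for col, entry in enumerate(schema.entries):
        if entry.kind == "continuous":
            if entry.name not in continuous_tracks:
                raise TrackError(f"missing continuous track for {entry.name!r}")
            track = continuous_tracks[entry.name]
            col_vals = np.full(n, np.nan)
            col_obs = np.zeros(n, dtype=bool)
            for chrom in np.unique(chroms):
                sel = chroms == chrom
                vals, obs = track.values_at(chrom, pos0[sel])
                col_vals[sel] = vals
                col_obs[sel] = obs
            values[:, col] = np.where(col_obs, col_vals, np.nan)
            mask[:, col] = col_obs
        else:
            if entry.name not in binary_tracks_per_cell_line:
                raise TrackError(f"missing peak tracks for {entry.name!r}")
            values[:, col] = binarize_peaks(binary_tracks_per_cell_line[entry.name],
                                            pos_pairs)
    try:
        return AnnotationMatrix(schema, values, mask, positions=list(positions))
    except ModelError as exc:
        raise TrackError(str(exc)) from exc


def write_annotation_matrix(matrix: AnnotationMatrix, path) -> None:
    """TSV with header: chrom, pos (1-based), then schema columns; NA = missing."""
    n = matrix.n_rows
    positions = matrix.positions or [("unknown", i + 1) for i in range(n)]
    frame = pd.DataFrame({"chrom": [c for c, _ in positions],
                          "pos": [p for _, p in positions]})
    for col, entry in enumerate(matrix.schema.entries):
        if entry.kind == "binary":
            frame[entry.name] = matrix.values[:, col].astype(int)
        else:
            vals = np.where(matrix.mask[:, col],
                            np.char.mod("%.17g", matrix.values[:, col]), "NA")
            frame[entry.name] = vals
    frame.to_csv(path, sep="\t", index=False)


def read_annotation_matrix(path, schema: AnnotationSchema) -> AnnotationMatrix:
    frame = pd.read_csv(path, sep="\t", dtype={"chrom": str},
                        na_values=["NA"], keep_default_na=False)
    missing_cols = [n for n in schema.names if n not in frame.columns]
    if missing_cols:
        raise TrackError(f"matrix file lacks columns: {missing_cols}")
    n = len(frame)
    values = np.zeros((n, len(schema)))
    mask = np.ones((n, len(schema)), dtype=bool)
    for col, entry in enumerate(schema.entries):
        series = pd.to_numeric(frame[entry.name], errors="coerce")
        arr = series.to_numpy(dtype=float)
        if entry.kind == "continuous":
            obs = ~np.isnan(arr)
            values[:, col] = np.where(obs, arr, np.nan)
            mask[:, col] = obs
        else:
            if np.isnan(arr).any():
                raise TrackError(f"binary column {entry.name!r} has missing values")
            values[:, col] = arr
    positions = list(zip(frame["chrom"], frame["pos"].astype(int)))
    try:
        return AnnotationMatrix(schema, values, mask, positions=positions)
    except ModelError as exc:
        raise TrackError(str(exc)) from exc


def write_schema(schema: AnnotationSchema, path) -> None:
    with open(path, "w") as fh:
        fh.write("name\tkind\tgroup\n")
        for e in schema.entries:
            fh.write(f"{e.name}\t{e.kind}\t{e.group}\n")


def read_schema(path) -> AnnotationSchema:
    from .annotation_model import AnnotationEntry
    entries = []
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("name\t"):
                continue
            name, kind, group = line.split("\t")
            entries.append(AnnotationEntry(name, kind, group))
    return AnnotationSchema(tuple(entries))
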