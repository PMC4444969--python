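"""Synthetic data with exactly the statistical structure the model assumes.

Two generators are provided.  ``simulate_dataset`` draws flat labelled rows
from the generative model (latent Bernoulli class, then class-conditional
Normal/Bernoulli annotations) for parameter-recovery and scoring tests.
``simulate_toy_genome`` lays functional intervals on a toy chromosome and
emits the full raw-track bundle — per-cell-line peak BEDs, per-position
conservation bedGraphs, SNP lists — so the whole pipeline from track files to
scores can run without any download.

Positions are independent given the truth labels; the only spatial structure
is interval-level (functional segments), matching the model's positionwise
independence assumption.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .annotation_model import (
    AnnotationMatrix,
    AnnotationSchema,
    ModelError,
    ModelParameters,
)
from .genome_tracks_io import (
    Interval,
    IntervalSet,
    ScoreTrack,
    write_annotation_matrix,
    write_bed,
    write_bedgraph,
    write_schema,
    write_snp_positions,
)

# Class-conditional Bernoulli rates for the default 20 binary annotations, in
# schema order.  The functional class shows clearly elevated peak rates except
# for one deliberately near-uninformative repressive histone mark (H3K27me3,
# 0.72 vs 0.80) whose signal is almost class-independent.
_DEFAULT_BINARY_RATES: dict[str, tuple[float, float]] = {
    "DNase": (0.10, 0.60),
    "FAIRE": (0.08, 0.40),
    "H3K4me1": (0.15, 0.70),
    "H3K4me2": (0.10, 0.60),
    "H3K4me3": (0.08, 0.55),
    "H3K9ac": (0.06, 0.50),
    "H3K27ac": (0.10, 0.65),
    "H3K27me3": (0.72, 0.80),
    "H3K36me3": (0.20, 0.55),
    "H4K20me1": (0.12, 0.45),
    "CTCF": (0.05, 0.40),
    "POLR2A": (0.04, 0.45),
    "MYC": (0.03, 0.35),
    "MAX": (0.03, 0.32),
    "JUN": (0.02, 0.30),
    "REST": (0.02, 0.30),
    "YY1": (0.03, 0.38),
    "SP1": (0.04, 0.42),
    "EP300": (0.05, 0.44),
    "RAD21": (0.04, 0.36),
}


def default_parameters(schema: AnnotationSchema | None = None) -> ModelParameters:
    """Deterministic generating parameters.

    Prior 0.4; each continuous annotation is Normal(0, 1) in the background
    class and Normal(1.5, 1) in the functional class (a 1.5 SD shift, the
    qualitative shape of real conservation scores); binary rates are fixed per
    annotation with background rates in [0.02, 0.3] and functional rates in
    [0.3, 0.9], plus one near-uninformative mark (0.72 vs 0.80).  Unrecognized
    binary annotations get rates cycled deterministically from their column
    index.
    """
    schema = schema or AnnotationSchema.default()
    nc = schema.n_continuous
    p0 = []
    p1 = []
    for j, idx in enumerate(schema.binary_indices):
        name = schema.entries[idx].name
        if name in _DEFAULT_BINARY_RATES:
            a, b = _DEFAULT_BINARY_RATES[name]
        else:
            a = 0.02 + 0.028 * (j % 10)
            b = 0.30 + 0.06 * (j % 10)
        p0.append(a)
        p1.append(b)
    return ModelParameters(
        schema=schema, pi=0.4,
        mu0=np.zeros(nc), sigma0=np.ones(nc),
        mu1=np.full(nc, 1.5), sigma1=np.ones(nc),
        p0=np.array(p0), p1=np.array(p1),
    )


@dataclass
class SimulatedDataset:
    labels: np.ndarray          # truth z per row
    matrix: AnnotationMatrix
    params_true: ModelParameters
    seed: int


def simulate_dataset(params: ModelParameters, n: int, missing_rate: float = 0.0,
                     seed: int = 0) -> SimulatedDataset:
    """Draw ``n`` labelled rows from the generative model.

    Each row first draws its latent class ``z ~ Bernoulli(pi)``, then each
    annotation from its class-conditional law; each continuous cell is then
    masked independently with probability ``missing_rate``.
    """
    if n < 1:
        raise ModelError("n must be >= 1")
    if not (0.0 <= missing_rate < 1.0):
        raise ModelError("missing_rate must lie in [0, 1)")
    params.require_valid()
    rng = np.random.default_rng(seed)
    schema = params.schema
    z = (rng.random(n) < params.pi).astype(int)
    values = np.zeros((n, len(schema)))
    mask = np.ones((n, len(schema)), dtype=bool)
    ci = schema.continuous_indices
    if ci.size:
        mu = np.where(z[:, None] == 1, params.mu1, params.mu0)
        sigma = np.where(z[:, None] == 1, params.sigma1, params.sigma0)
        values[:, ci] = rng.normal(mu, sigma)
        if missing_rate > 0.0:
            miss = rng.random((n, ci.size)) < missing_rate
            cols = values[:, ci]
            cols[miss] = np.nan
            values[:, ci] = cols
            mask[:, ci] = ~miss
    bi = schema.binary_indices
    if bi.size:
        p = np.where(z[:, None] == 1, params.p1, params.p0)
        values[:, bi] = (rng.random((n, bi.size)) < p).astype(float)
    matrix = AnnotationMatrix(schema, values, mask)
    return SimulatedDataset(labels=z, matrix=matrix, params_true=params, seed=seed)


# ---------------------------------------------------------------------------
# Toy genome fixture
# ---------------------------------------------------------------------------

@dataclass
class ToyGenomeFixture:
    chrom: str
    chrom_length: int
    functional_intervals: IntervalSet
    labels: np.ndarray                              # per-position truth
    matrix: AnnotationMatrix                        # positions (chrom, 1-based)
    peaks: dict[str, list[IntervalSet]]             # annotation -> per-cell-line peaks
    continuous_tracks: dict[str, ScoreTrack]
    snp_positions: list[tuple[str, int]]            # 1-based
    params_true: ModelParameters
    seed: int

    def write(self, out_dir) -> dict[str, object]:
        """Write the fixture as standard files (BED, bedGraph, TSV); returns
        the path map."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths: dict[str, object] = {}
        write_bed(self.functional_intervals, out / "truth_intervals.bed")
        paths["truth_intervals"] = out / "truth_intervals.bed"
        peak_paths: dict[str, list[Path]] = {}
        for name, cell_lines in self.peaks.items():
            peak_paths[name] = []
            for i, ivs in enumerate(cell_lines):
                p = out / f"peaks_{name}_cell{i}.bed"
                write_bed(ivs, p)
                peak_paths[name].append(p)
        paths["peaks"] = peak_paths
        track_paths: dict[str, Path] = {}
        for name, track in self.continuous_tracks.items():
            p = out / f"track_{name}.bedgraph"
            write_bedgraph(track, p, precision=6)
            track_paths[name] = p
        paths["continuous_tracks"] = track_paths
        write_snp_positions(self.snp_positions, out / "snps.tsv")
        paths["snps"] = out / "snps.tsv"
        write_annotation_matrix(self.matrix, out / "annotation_matrix.tsv")
        paths["matrix"] = out / "annotation_matrix.tsv"
        write_schema(self.matrix.schema, out / "schema.tsv")
        paths["schema"] = out / "schema.tsv"
        return paths


def _place_intervals(chrom_length: int, n_intervals: int, rng: np.random.Generator,
                     min_len: int = 200, max_len: int = 1500) -> list[tuple[int, int]]:
    """Place non-overlapping intervals uniformly; lengths uniform in
    [min_len, max_len]."""
    lengths = rng.integers(min_len, max_len + 1, size=n_intervals)
    total = int(lengths.sum())
    free = chrom_length - total
    if free < n_intervals:  # need at least 1 bp gap per interval
        raise ModelError("functional intervals cannot fit in the chromosome")
    # distribute the free space as random gaps before each interval and after the last
    cuts = np.sort(rng.integers(0, free + 1, size=n_intervals))
    starts = cuts + np.concatenate([[0], np.cumsum(lengths)[:-1]])
    return [(int(s), int(s + L)) for s, L in zip(starts, lengths)]


def simulate_toy_genome(chrom_length: int, n_functional_intervals: int,
                        n_cell_lines: int, params: ModelParameters | None = None,
                        seed: int = 0, n_snps: int = 40,
                        chrom: str = "chrS") -> ToyGenomeFixture:
    """Simulate a toy chromosome with known functional intervals.

    Truth intervals are placed uniformly without overlap; every position's
    annotations are drawn from ``params`` conditional on interval membership.
    Each binary annotation's positive positions are split into per-cell-line
    peak sets whose union reconstructs the positive set exactly, so the
    cross-cell-line binarization rule is exercised nontrivially.  SNP
    positions are sampled both inside and outside the truth intervals.
    """
    if chrom_length < 1000:
        raise ModelError("chrom_length must be >= 1000")
    params = params or default_parameters()
    params.require_valid()
    rng = np.random.default_rng(seed)
    schema = params.schema

    spans = _place_intervals(chrom_length, n_functional_intervals, rng) \
        if n_functional_intervals > 0 else []
    truth = IntervalSet([Interval(chrom, s, e, f"func{i}")
                         for i, (s, e) in enumerate(spans)])
    labels = np.zeros(chrom_length, dtype=int)
    for s, e in spans:
        labels[s:e] = 1

    n = chrom_length
    values = np.zeros((n, len(schema)))
    mask = np.ones((n, len(schema)), dtype=bool)
    ci = schema.continuous_indices
    if ci.size:
        mu = np.where(labels[:, None] == 1, params.mu1, params.mu0)
        sigma = np.where(labels[:, None] == 1, params.sigma1, params.sigma0)
        values[:, ci] = rng.normal(mu, sigma)
    bi = schema.binary_indices
    if bi.size:
        p = np.where(labels[:, None] == 1, params.p1, params.p0)
        values[:, bi] = (rng.random((n, bi.size)) < p).astype(float)

    positions1 = [(chrom, i + 1) for i in range(n)]
    matrix = AnnotationMatrix(schema, values, mask, positions=positions1)

    # continuous tracks cover every position
    tracks = {}
    for j, idx in enumerate(ci):
        name = schema.entries[idx].name
        tracks[name] = ScoreTrack.from_positions(chrom, np.arange(n), values[:, idx])

    # split each binary annotation's positive runs across cell lines (union-preserving)
    peaks: dict[str, list[IntervalSet]] = {}
    for idx in bi:
        name = schema.entries[idx].name
        positive = values[:, idx] == 1.0
        runs = _runs(positive)
        cell_records: list[list[Interval]] = [[] for _ in range(n_cell_lines)]
        for s, e in runs:
            members = rng.random(n_cell_lines) < 0.5
            if not members.any():
                members[rng.integers(0, n_cell_lines)] = True
            for c in np.flatnonzero(members):
                cell_records[c].append(Interval(chrom, s, e))
        peaks[name] = [IntervalSet(rec) for rec in cell_records]

    # SNPs: half inside truth intervals (if any), half outside
    snps: list[tuple[str, int]] = []
    inside = np.flatnonzero(labels == 1)
    outside = np.flatnonzero(labels == 0)
    n_in = min(n_snps // 2, inside.size)
    n_out = min(n_snps - n_in, outside.size)
    for p0 in rng.choice(inside, size=n_in, replace=False) if n_in else []:
        snps.append((chrom, int(p0) + 1))
    for p0 in rng.choice(outside, size=n_out, replace=False) if n_out else []:
        snps.append((chrom, int(p0) + 1))
    snps.sort(key=lambda t: t[1])

    return ToyGenomeFixture(chrom=chrom, chrom_length=chrom_length,
                            functional_intervals=truth, labels=labels,
                            matrix=matrix, peaks=peaks,
                            continuous_tracks=tracks, snp_positions=snps,
                            params_true=params, seed=seed)


def _runs(flag: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, end) half-open pairs."""
    if not flag.any():
        return []
    padded = np.concatenate([[False], flag, [False]])
    diff = np.diff(padded.astype(int))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return list(zip(starts.tolist(), ends.tolist()))
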