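"""Latent-class generative model over mixed continuous/binary genomic annotations.

The model: each genomic position carries an unobserved binary indicator of
function ``Z`` with prior ``P(Z=1) = pi``.  Conditional on ``Z``, the
annotations are independent; continuous annotations (conservation scores)
follow class-conditional Normal laws and binary annotations (peak indicators)
follow class-conditional Bernoulli laws.  The per-position functional score is
the posterior probability ``P(Z=1 | observed annotations)``.

This module holds the domain types (schema, parameters, annotation matrix) and
every closed-form computation on them: class-conditional log densities,
posterior scores, group-conditional posteriors, marginal odds ratios,
parameter counting, validation and plain-text (de)serialization.

All density work happens in log space: with 22 factors per position, raw
products underflow double precision.
"""

from __future__ import annotations

import hashlib
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

LOG_2PI = math.log(2.0 * math.pi)

#: Bernoulli parameters are kept inside [CLAMP, 1 - CLAMP] so log terms stay finite.
BERNOULLI_CLAMP = 1e-6
#: Class-conditional standard deviations are floored here to avoid degenerate spikes.
VARIANCE_FLOOR = 1e-3

KINDS = ("continuous", "binary")
GROUPS = ("conservation", "open_chromatin", "histone", "tfbs", "other")


class ModelError(ValueError):
    """Raised for invalid model inputs (bad parameters, uninformative rows...)."""


# ---------------------------------------------------------------------------
# Schema
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnnotationEntry:
    name: str
    kind: str
    group: str

    def __post_init__(self) -> None:
        if not self.name:
            raise ModelError("annotation name must be non-empty")
        if self.kind not in KINDS:
            raise ModelError(f"unknown annotation kind {self.kind!r}")
        if self.group not in GROUPS:
            raise ModelError(f"unknown annotation group {self.group!r}")


@dataclass(frozen=True)
class AnnotationSchema:
    """Ordered annotation description; the order fixes matrix column order."""

    entries: tuple[AnnotationEntry, ...]

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise ModelError("annotation names must be unique")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(e.name for e in self.entries)

    @property
    def kinds(self) -> tuple[str, ...]:
        return tuple(e.kind for e in self.entries)

    @property
    def continuous_indices(self) -> np.ndarray:
        return np.array([i for i, e in enumerate(self.entries) if e.kind == "continuous"], dtype=int)

    @property
    def binary_indices(self) -> np.ndarray:
        return np.array([i for i, e in enumerate(self.entries) if e.kind == "binary"], dtype=int)

    @property
    def n_continuous(self) -> int:
        return len(self.continuous_indices)

    @property
    def n_binary(self) -> int:
        return len(self.binary_indices)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise ModelError(f"unknown annotation {name!r}") from None

    def entry(self, name: str) -> AnnotationEntry:
        return self.entries[self.index(name)]

    def group_names(self, group: str) -> tuple[str, ...]:
        if group not in GROUPS:
            raise ModelError(f"unknown annotation group {group!r}")
        return tuple(e.name for e in self.entries if e.group == group)

    def subset_schema(self, names: Iterable[str]) -> "AnnotationSchema":
        """Schema restricted to ``names``, preserving the original order."""
        keep = set(names)
        unknown = keep - set(self.names)
        if unknown:
            raise ModelError(f"unknown annotations: {sorted(unknown)}")
        return AnnotationSchema(tuple(e for e in self.entries if e.name in keep))

    def schema_hash(self) -> str:
        payload = ";".join(f"{e.name},{e.kind},{e.group}" for e in self.entries)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def default(cls) -> "AnnotationSchema":
        """The 22-annotation layout: 2 conservation scores, 2 open-chromatin,
        8 histone-modification and 10 TFBS peak indicators."""
        entries = [
            AnnotationEntry("GERP", "continuous", "conservation"),
            AnnotationEntry("PhyloP", "continuous", "conservation"),
            AnnotationEntry("DNase", "binary", "open_chromatin"),
            AnnotationEntry("FAIRE", "binary", "open_chromatin"),
        ]
        histones = ["H3K4me1", "H3K4me2", "H3K4me3", "H3K9ac",
                    "H3K27ac", "H3K27me3", "H3K36me3", "H4K20me1"]
        entries += [AnnotationEntry(h, "binary", "histone") for h in histones]
        tfs = ["CTCF", "POLR2A", "MYC", "MAX", "JUN",
               "REST", "YY1", "SP1", "EP300", "RAD21"]
        entries += [AnnotationEntry(t, "binary", "tfbs") for t in tfs]
        return cls(tuple(entries))


def parameter_count(schema: AnnotationSchema) -> int:
    """Number of free parameters: the prior plus (mu0, sigma0, mu1, sigma1)
    per continuous annotation and (p0, p1) per binary annotation."""
    return 1 + 4 * schema.n_continuous + 2 * schema.n_binary


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelParameters:
    """Prior plus class-conditional emission parameters, aligned to a schema.

    Continuous arrays are indexed by the schema's continuous annotations in
    order; binary arrays by the binary annotations in order.  Dispersion is
    stored as a standard deviation, not a variance.
    """

    schema: AnnotationSchema
    pi: float
    mu0: np.ndarray
    sigma0: np.ndarray
    mu1: np.ndarray
    sigma1: np.ndarray
    p0: np.ndarray
    p1: np.ndarray
    warnings_: tuple[str, ...] = field(default=(), compare=False)

    def __post_init__(self) -> None:
        for name in ("mu0", "sigma0", "mu1", "sigma1", "p0", "p1"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))

    def validate(self) -> list[str]:
        return validate_parameters(self, self.schema)

    def require_valid(self) -> None:
        report = self.validate()
        if report:
            raise ModelError("invalid parameters: " + "; ".join(report))

    def with_pi(self, pi_new: float) -> "ModelParameters":
        return replace(self, pi=float(pi_new))

    # -- lookup by annotation name -------------------------------------------------
    def continuous_params(self, name: str) -> tuple[float, float, float, float]:
        entry = self.schema.entry(name)
        if entry.kind != "continuous":
            raise ModelError(f"{name!r} is not a continuous annotation")
        j = int(np.where(self.schema.continuous_indices == self.schema.index(name))[0][0])
        return float(self.mu0[j]), float(self.sigma0[j]), float(self.mu1[j]), float(self.sigma1[j])

    def binary_params(self, name: str) -> tuple[float, float]:
        entry = self.schema.entry(name)
        if entry.kind != "binary":
            raise ModelError(f"{name!r} is not a binary annotation")
        j = int(np.where(self.schema.binary_indices == self.schema.index(name))[0][0])
        return float(self.p0[j]), float(self.p1[j])

    def subset(self, names: Iterable[str]) -> "ModelParameters":
        """Parameters restricted to a subset of annotations (same prior)."""
        sub = self.schema.subset_schema(names)
        keep_cont = [n for n in sub.names if sub.entry(n).kind == "continuous"]
        keep_bin = [n for n in sub.names if sub.entry(n).kind == "binary"]
        cps = [self.continuous_params(n) for n in keep_cont]
        bps = [self.binary_params(n) for n in keep_bin]
        return ModelParameters(
            schema=sub, pi=self.pi,
            mu0=np.array([c[0] for c in cps]), sigma0=np.array([c[1] for c in cps]),
            mu1=np.array([c[2] for c in cps]), sigma1=np.array([c[3] for c in cps]),
            p0=np.array([b[0] for b in bps]), p1=np.array([b[1] for b in bps]),
        )

    # -- serialization -------------------------------------------------------------
    def to_text(self) -> str:
        """Flat key-value text form; floats printed with repr (17 significant
        digits) so the round trip is bit-exact."""
        lines = [
            "# funcscore model parameters v1",
            f"# schema_hash\t{self.schema.schema_hash()}",
            f"pi\t{float(self.pi)!r}",
        ]
        ci = bi = 0
        for e in self.schema.entries:
            if e.kind == "continuous":
                for fname, arr in (("mu0", self.mu0), ("sigma0", self.sigma0),
                                   ("mu1", self.mu1), ("sigma1", self.sigma1)):
                    lines.append(f"{e.name}\t{e.kind}\t{e.group}\t{fname}\t{float(arr[ci])!r}")
                ci += 1
            else:
                for fname, arr in (("p0", self.p0), ("p1", self.p1)):
                    lines.append(f"{e.name}\t{e.kind}\t{e.group}\t{fname}\t{float(arr[bi])!r}")
                bi += 1
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "ModelParameters":
        pi = None
        entries: list[AnnotationEntry] = []
        values: dict[str, dict[str, float]] = {}
        for raw in text.splitlines():
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "pi":
                pi = float(parts[1])
                continue
            if len(parts) != 5:
                raise ModelError(f"malformed parameter line: {raw!r}")
            name, kind, group, fname, value = parts
            if name not in values:
                entries.append(AnnotationEntry(name, kind, group))
                values[name] = {}
            values[name][fname] = float(value)
        if pi is None:
            raise ModelError("parameter file lacks a pi line")
        schema = AnnotationSchema(tuple(entries))
        cont = [values[n] for n in schema.names if schema.entry(n).kind == "continuous"]
        binr = [values[n] for n in schema.names if schema.entry(n).kind == "binary"]
        return cls(
            schema=schema, pi=pi,
            mu0=np.array([d["mu0"] for d in cont]), sigma0=np.array([d["sigma0"] for d in cont]),
            mu1=np.array([d["mu1"] for d in cont]), sigma1=np.array([d["sigma1"] for d in cont]),
            p0=np.array([d["p0"] for d in binr]), p1=np.array([d["p1"] for d in binr]),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_text())

    @classmethod
    def load(cls, path) -> "ModelParameters":
        with open(path) as fh:
            return cls.from_text(fh.read())


def validate_parameters(params: ModelParameters, schema: AnnotationSchema) -> list[str]:
    """Report every violated invariant; empty report iff valid."""
    report: list[str] = []
    if params.schema.names != schema.names or params.schema.kinds != schema.kinds:
        report.append("parameter schema does not match the supplied schema")
    if not (0.0 <= params.pi <= 1.0) or not np.isfinite(params.pi):
        report.append(f"pi out of [0, 1]: {params.pi}")
    nc, nb = schema.n_continuous, schema.n_binary
    for fname in ("mu0", "sigma0", "mu1", "sigma1"):
        if len(getattr(params, fname)) != nc:
            report.append(f"{fname}: expected {nc} values, got {len(getattr(params, fname))}")
    for fname in ("p0", "p1"):
        if len(getattr(params, fname)) != nb:
            report.append(f"{fname}: expected {nb} values, got {len(getattr(params, fname))}")
    cont_names = [schema.entries[i].name for i in schema.continuous_indices]
    for fname in ("sigma0", "sigma1"):
        arr = getattr(params, fname)
        for j in range(min(len(arr), nc)):
            if not (arr[j] > 0.0) or not np.isfinite(arr[j]):
                report.append(f"{cont_names[j]}.{fname} must be positive, got {arr[j]}")
    for fname in ("mu0", "mu1"):
        arr = getattr(params, fname)
        for j in range(min(len(arr), nc)):
            if not np.isfinite(arr[j]):
                report.append(f"{cont_names[j]}.{fname} is not finite")
    bin_names = [schema.entries[i].name for i in schema.binary_indices]
    for fname in ("p0", "p1"):
        arr = getattr(params, fname)
        for j in range(min(len(arr), nb)):
            if not (0.0 < arr[j] < 1.0):
                report.append(f"{bin_names[j]}.{fname} must lie strictly in (0, 1), got {arr[j]}")
    return report


# ---------------------------------------------------------------------------
# Annotation matrix
# ---------------------------------------------------------------------------

@dataclass
class AnnotationMatrix:
    """n-position x m-annotation value table with a missingness mask.

    ``mask[r, c]`` is True where the value is observed.  Binary columns must be
    fully observed and contain only 0/1; missingness is allowed only in
    continuous columns (in real data only the conservation tracks have gaps).
    Positions are (chrom, 1-based coordinate) pairs, or None for flat datasets.
    """

    schema: AnnotationSchema
    values: np.ndarray
    mask: np.ndarray
    positions: list[tuple[str, int]] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.ndim != 2:
            raise ModelError("values must be a 2-D array")
        n, m = self.values.shape
        if n < 1:
            raise ModelError("annotation matrix needs at least one row")
        if m != len(self.schema):
            raise ModelError(f"matrix has {m} columns but schema has {len(self.schema)} annotations")
        if self.mask.shape != self.values.shape:
            raise ModelError("mask shape must match values shape")
        bi = self.schema.binary_indices
        if bi.size:
            if not self.mask[:, bi].all():
                raise ModelError("binary columns must be fully observed")
            vals = self.values[:, bi]
            if not np.isin(vals, (0.0, 1.0)).all():
                raise ModelError("binary columns must contain only 0/1")
        ci = self.schema.continuous_indices
        if ci.size:
            obs = self.values[:, ci][self.mask[:, ci]]
            if obs.size and not np.isfinite(obs).all():
                raise ModelError("observed continuous values must be finite")
        if self.positions is not None and len(self.positions) != n:
            raise ModelError("positions length must equal row count")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    def row(self, r: int) -> tuple[np.ndarray, np.ndarray]:
        return self.values[r], self.mask[r]

    def impute_neutral_zero(self) -> "AnnotationMatrix":
        """Replace missing continuous values with the neutral score 0 and mark
        them observed (the scoring-time convention for conservation gaps)."""
        values = self.values.copy()
        values[~self.mask] = 0.0
        return AnnotationMatrix(self.schema, values, np.ones_like(self.mask),
                                positions=self.positions)

    def complete_cases(self) -> tuple["AnnotationMatrix", np.ndarray]:
        """Rows with every annotation observed, plus their original indices."""
        keep = self.mask.all(axis=1)
        if not keep.any():
            raise ModelError("no complete rows in the matrix")
        idx = np.flatnonzero(keep)
        positions = [self.positions[i] for i in idx] if self.positions is not None else None
        return AnnotationMatrix(self.schema, self.values[keep], self.mask[keep],
                                positions=positions), idx


# ---------------------------------------------------------------------------
# Densities and posteriors
# ---------------------------------------------------------------------------

def _check_params(params: ModelParameters) -> None:
    if params.validate():
        raise ModelError("invalid parameters: " + "; ".join(params.validate()))


def _log_densities_raw(values: np.ndarray, mask: np.ndarray,
                       params: ModelParameters) -> tuple[np.ndarray, np.ndarray]:
    """``(log f0, log f1)`` per row on raw arrays; any annotation may be
    masked (masked terms are marginalized out of the product)."""
    schema = params.schema
    n = values.shape[0]
    log_f0 = np.zeros(n)
    log_f1 = np.zeros(n)
    ci = schema.continuous_indices
    if ci.size:
        x = values[:, ci]
        obs = mask[:, ci]
        xs = np.where(obs, x, 0.0)  # placeholder; masked terms are zeroed below
        for mu, sigma, out in ((params.mu0, params.sigma0, log_f0),
                               (params.mu1, params.sigma1, log_f1)):
            term = -0.5 * ((xs - mu) / sigma) ** 2 - np.log(sigma) - 0.5 * LOG_2PI
            out += np.where(obs, term, 0.0).sum(axis=1)
    bi = schema.binary_indices
    if bi.size:
        y = values[:, bi]
        obs = mask[:, bi]
        if obs.all():
            for p, out in ((params.p0, log_f0), (params.p1, log_f1)):
                out += y @ np.log(p) + (1.0 - y) @ np.log1p(-p)
        else:
            ys = np.where(obs, y, 0.0)
            for p, out in ((params.p0, log_f0), (params.p1, log_f1)):
                term = ys * np.log(p) + (1.0 - ys) * np.log1p(-p)
                out += np.where(obs, term, 0.0).sum(axis=1)
    return log_f0, log_f1


def class_log_densities(matrix: AnnotationMatrix, params: ModelParameters,
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized ``(log f0, log f1)`` over observed annotations, per row.

    Missing entries contribute zero: under conditional independence they are
    marginalized out of the product.
    """
    _check_params(params)
    if params.schema.names != matrix.schema.names:
        raise ModelError("matrix schema does not match parameter schema")
    return _log_densities_raw(matrix.values, matrix.mask, params)


def class_log_density(row: np.ndarray, mask: np.ndarray, params: ModelParameters,
                      z: int) -> float:
    """Log class-conditional density of one observation row given ``Z = z``."""
    if z not in (0, 1):
        raise ModelError(f"z must be 0 or 1, got {z!r}")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ModelError("row has no observed annotations")
    _check_params(params)
    log_f0, log_f1 = _log_densities_raw(np.asarray(row, dtype=float)[None, :],
                                        mask[None, :], params)
    return float(log_f1[0] if z == 1 else log_f0[0])


def posterior_scores(matrix: AnnotationMatrix, params: ModelParameters,
                     ) -> np.ndarray:
    """Posterior functional probability ``P(Z=1 | row)`` for every row.

    Computed in log space with log-sum-exp; rows where the two class densities
    agree on the observed entries score exactly ``pi``.
    """
    log_f0, log_f1 = class_log_densities(matrix, params)
    return _posterior_from_log_densities(log_f0, log_f1, params.pi)


def _posterior_from_log_densities(log_f0: np.ndarray, log_f1: np.ndarray,
                                  pi: float) -> np.ndarray:
    if pi <= 0.0:
        return np.zeros_like(log_f1)
    if pi >= 1.0:
        return np.ones_like(log_f1)
    # stabilised Bayes ratio: shift by the larger log density before
    # exponentiating, so the result is exactly pi when log f1 == log f0
    d = log_f1 - log_f0
    out = np.empty_like(d)
    neg = d <= 0
    r = np.exp(d[neg])
    out[neg] = pi * r / (pi * r + (1.0 - pi))
    r = np.exp(-d[~neg])
    out[~neg] = pi / (pi + (1.0 - pi) * r)
    return out


def posterior_score(row: np.ndarray, mask: np.ndarray, params: ModelParameters) -> float:
    """Posterior functional probability for a single observation row."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ModelError("row has no observed annotations")
    _check_params(params)
    log_f0, log_f1 = _log_densities_raw(np.asarray(row, dtype=float)[None, :],
                                        mask[None, :], params)
    return float(_posterior_from_log_densities(log_f0, log_f1, params.pi)[0])


def group_posterior(row: np.ndarray, mask: np.ndarray, params: ModelParameters,
                    subset: Sequence[str]) -> float:
    """Posterior using only the named annotations, everything else unobserved.

    The empty subset is an error: the annotation-free posterior is just the
    prior and is read off ``params.pi`` directly.
    """
    subset = list(subset)
    if not subset:
        raise ModelError("subset must be non-empty; the prior is params.pi")
    schema = params.schema
    keep = np.zeros(len(schema), dtype=bool)
    for name in subset:
        keep[schema.index(name)] = True
    mask = np.asarray(mask, dtype=bool) & keep
    if not mask.any():
        raise ModelError("no subset annotation is observed in this row")
    return posterior_score(row, mask, params)


def marginal_odds_ratio(params: ModelParameters, name: str) -> float:
    """Factor by which observing a binary annotation (vs not) multiplies the
    posterior odds of function: ``p1 (1 - p0) / (p0 (1 - p1))``."""
    p0, p1 = params.binary_params(name)
    if not (0.0 < p0 < 1.0 and 0.0 < p1 < 1.0):
        raise ModelError(f"{name!r}: Bernoulli parameters must lie in (0, 1)")
    if min(p0, p1) <= BERNOULLI_CLAMP or max(p0, p1) >= 1.0 - BERNOULLI_CLAMP:
        warnings.warn(f"{name}: Bernoulli parameter at clamp boundary; "
                      "odds ratio may be saturated", stacklevel=2)
    return (p1 * (1.0 - p0)) / (p0 * (1.0 - p1))
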