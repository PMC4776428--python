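"""Intensity-matrix input/output, prevalence filtering, run configuration and seeding.

The package consumes aligned sample x feature intensity matrices as produced by
non-targeted mass-spectrometry pre-processing (peak alignment and formula
annotation).  Absent masses are stored as zero intensity rather than as missing
values, so the prevalence filter counts nonzero entries.

All stochastic stages of the pipeline draw their randomness from child seeds
derived deterministically from a single master seed via :func:`derive_seed`,
which makes an inherently stochastic consensus procedure exactly reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("stabica.data_io")

__all__ = [
    "IntensityMatrix",
    "RunConfig",
    "MatrixParseError",
    "MatrixValidationError",
    "read_matrix",
    "write_matrix",
    "prevalence_filter",
    "derive_seed",
]


class MatrixParseError(ValueError):
    """A delimited-text matrix contained a cell that could not be parsed."""


class MatrixValidationError(ValueError):
    """A matrix violated a structural invariant (shape, labels, finiteness)."""


@dataclass
class IntensityMatrix:
    """A sample x feature intensity matrix with identifiers.

    Parameters
    ----------
    values : ndarray of shape (n_samples, n_features)
        Non-negative intensities; absent measurements are zeros.
    sample_ids : list of str
        Unique row identifiers.
    feature_ids : list of str
        Unique column identifiers (m/z values or annotated formulas).
    """

    values: np.ndarray
    sample_ids: list[str]
    feature_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        if self.values.ndim != 2:
            raise MatrixValidationError("values must be a 2-D array")
        n, p = self.values.shape
        if n < 3:
            raise MatrixValidationError(f"need at least 3 samples, got {n}")
        if p < 1:
            raise MatrixValidationError("matrix has no features")
        if len(self.sample_ids) != n or len(self.feature_ids) != p:
            raise MatrixValidationError("identifier lengths do not match shape")
        if len(set(self.sample_ids)) != n:
            dupes = _duplicates(self.sample_ids)
            raise MatrixValidationError(f"duplicate sample identifiers: {dupes}")
        if len(set(self.feature_ids)) != p:
            dupes = _duplicates(self.feature_ids)
            raise MatrixValidationError(f"duplicate feature identifiers: {dupes}")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise MatrixValidationError(
                f"non-finite value at sample {self.sample_ids[bad[0]]!r}, "
                f"feature {self.feature_ids[bad[1]]!r}"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_ids)


def _duplicates(items: Sequence[str]) -> list[str]:
    seen: set[str] = set()
    dup: list[str] = []
    for it in items:
        if it in seen and it not in dup:
            dup.append(it)
        seen.add(it)
    return dup


@dataclass
class RunConfig:
    """Pipeline configuration with the method's published defaults.

    Attributes
    ----------
    variance_threshold : float
        Fraction of variance the PCA denoising step must retain (default 0.90).
    n_runs : int
        Number m of FastICA restarts pooled into the source bank (default 800).
    cluster_range : tuple[int, int] or None
        Inclusive range of cluster counts scanned by model selection;
        ``None`` means 2..k where k is the denoised dimension.
    n_bootstrap : int
        Number B of bootstrap datasets for the reliability score (default 100).
    n_replace : int
        Rows of X overwritten in each bootstrap dataset (default 5).
    n_inits : int
        Number of randomized initial demixing matrices W0 used when scoring
        reliability (default 50).
    master_seed : int
        Root of all derived randomness.
    """

    variance_threshold: float = 0.90
    n_runs: int = 800
    cluster_range: tuple[int, int] | None = None
    n_bootstrap: int = 100
    n_replace: int = 5
    n_inits: int = 50
    master_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.variance_threshold <= 1.0:
            raise ValueError("variance_threshold must lie in (0, 1]")
        if self.n_runs < 2:
            raise ValueError("n_runs must be at least 2")
        if self.n_bootstrap < 1:
            raise ValueError("n_bootstrap must be at least 1")
        if self.n_replace < 0:
            raise ValueError("n_replace must be non-negative")
        if self.n_inits < 1:
            raise ValueError("n_inits must be at least 1")
        if self.cluster_range is not None:
            lo, hi = self.cluster_range
            if not (2 <= lo <= hi):
                raise ValueError("cluster_range must satisfy 2 <= lo <= hi")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def derive_seed(master_seed: int, task: str, index: int = 0) -> int:
    """Derive a child seed for one stochastic task.

    The child is a stable hash of ``"{master_seed}:{task}:{index}"`` reduced
    modulo 2**31, so every stage of the pipeline has its own independent,
    reproducible random stream regardless of execution order.
    """
    key = f"{master_seed}:{task}:{index}".encode()
    digest = hashlib.blake2b(key, digest_size=8).digest()
    return int.from_bytes(digest, "big") % (2**31)


# ---------------------------------------------------------------------------
# Delimited-text I/O
# ---------------------------------------------------------------------------

def _sniff_delimiter(header: str) -> str | None:
    """Pick the delimiter: tab, then comma, then semicolon; None = whitespace."""
    for cand in ("\t", ",", ";"):
        if cand in header:
            return cand
    return None


def read_matrix(path: str | Path, orientation: str = "samples-in-rows") -> IntensityMatrix:
    """Read a delimited intensity matrix.

    The file must have one header row of labels and one leading label column.
    ``orientation`` says what the file's rows are; the returned matrix is
    always samples-in-rows.
    """
    if orientation not in ("samples-in-rows", "samples-in-columns"):
        raise ValueError(f"unknown orientation {orientation!r}")
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    delim = _sniff_delimiter(header)
    sep = delim if delim is not None else r"\s+"
    # pandas silently mangles duplicate header labels, so check the raw header
    header_labels = (header.rstrip("\n").split(delim) if delim is not None
                     else header.split())[1:]
    if len(set(header_labels)) != len(header_labels):
        raise MatrixValidationError("duplicate labels in the header row")
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.shape[1] < 2 or df.shape[0] < 2:
        raise MatrixValidationError("matrix files need at least 2 rows and 2 columns")
    # locate any non-numeric cell and name it
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            row = df.index[bad.to_numpy().argmax()]
            raise MatrixParseError(
                f"non-numeric value {df.loc[row, col]!r} at row {row!r}, column {col!r}"
            )
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise MatrixValidationError("duplicate row or column labels in input file")
    if orientation == "samples-in-columns":
        df = df.T
    logger.info("read matrix %s: %d samples x %d features", path.name, *df.shape)
    return IntensityMatrix(df.to_numpy(dtype=float), list(df.index), list(df.columns))


def write_matrix(X: IntensityMatrix, path: str | Path) -> None:
    """Write a matrix as TSV, preserving values to 12 significant digits."""
    X.to_dataframe().to_csv(path, sep="\t", float_format="%.12g")


def prevalence_filter(X: IntensityMatrix, min_fraction: float = 0.10) -> IntensityMatrix:
    """Drop features observed in fewer than ``min_fraction`` of samples.

    A feature is retained when its nonzero count is at least
    ``ceil(min_fraction * n_samples)``; zeros encode absent masses.  Feature
    order is preserved and the operation is idempotent.
    """
    if not 0.0 <= min_fraction <= 1.0:
        raise ValueError("min_fraction must lie in [0, 1]")
    n = X.n_samples
    # round before ceil so 0.1 * 10 -> 1, not 2, despite binary float fuzz
    need = int(math.ceil(round(min_fraction * n, 9)))
    counts = np.count_nonzero(X.values, axis=0)
    keep = counts >= need
    if not np.any(keep):
        raise MatrixValidationError(
            f"prevalence filter at min_fraction={min_fraction} removed every "
            "feature; lower the threshold"
        )
    dropped = int((~keep).sum())
    if dropped:
        logger.info("prevalence filter dropped %d of %d features", dropped, X.n_features)
    return IntensityMatrix(
        X.values[:, keep],
        X.sample_ids,
        [f for f, k in zip(X.feature_ids, keep) if k],
    )
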