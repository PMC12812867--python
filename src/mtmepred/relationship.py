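"""Genomic (G) and phenomic (H) relationship matrices and Cholesky factors.

G follows VanRaden's first method: G = WW' / (2 Σ p_k (1 - p_k)) with
W = M - 2P the dosage matrix centred at twice the observed allele
frequencies. H is the analogous similarity built from column-standardised
spectra: H = SS'/w, where S has zero-mean, unit-variance columns
(population denominator n) and w is the number of retained wavelengths.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data_io import DataError, MarkerMatrix, SpectraMatrix

log = logging.getLogger(__name__)

_SYM_TOL = 1e-10


@dataclass
class RelationshipMatrix:
    """Square symmetric similarity among individuals."""

    sample_ids: list[str]
    values: np.ndarray
    kind: str = "user"  # one of {"G", "H", "user"}
    jitter: float = 0.0  # total diagonal jitter added by ensure_pd

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise DataError(f"relationship matrix shape {self.values.shape} != ({n}, {n})")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise DataError("relationship matrix is not symmetric (tolerance 1e-8)")
        # enforce exact symmetry so downstream Cholesky is well-posed
        self.values = (self.values + self.values.T) / 2.0
        if (np.diag(self.values) < -_SYM_TOL).any():
            raise DataError("relationship matrix has negative diagonal entries")

    @property
    def n(self) -> int:
        return len(self.sample_ids)


@dataclass
class CholeskyFactor:
    """Upper-triangular Q with Qᵗ·Q equal to the source relationship matrix."""

    upper: np.ndarray
    source_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.upper = np.asarray(self.upper, dtype=float)
        if not np.allclose(self.upper, np.triu(self.upper)):
            raise ValueError("Cholesky factor must be upper-triangular")


def vanraden_g(mm: MarkerMatrix) -> RelationshipMatrix:
    """Genomic relationship matrix from a complete dosage matrix.

    Allele frequencies are estimated from the data itself. Raises if the
    markers carry no polymorphism (zero denominator).
    """
    M = np.asarray(mm.dosages, dtype=float)
    if not np.isfinite(M).all():
        raise DataError("dosage matrix has missing values; impute before vanraden_g")
    p = M.mean(axis=0) / 2.0
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom <= 0:
        raise DataError("all markers are monomorphic; G denominator is zero")
    W = M - 2.0 * p
    G = W @ W.T / denom
    return RelationshipMatrix(list(mm.sample_ids), G, kind="G")


def spectral_h(sm: SpectraMatrix) -> RelationshipMatrix:
    """Phenomic relationship matrix from column-standardised spectra.

    Zero-variance wavelengths are dropped with a warning; at least two
    informative wavelengths are required.
    """
    R = np.asarray(sm.reflectance, dtype=float)
    sd = R.std(axis=0)  # population denominator n
    usable = sd > 0
    n_dropped = int((~usable).sum())
    if n_dropped:
        log.warning("dropping %d zero-variance wavelengths before H construction", n_dropped)
    if usable.sum() < 2:
        raise DataError("fewer than 2 wavelengths with nonzero variance; cannot build H")
    S = (R[:, usable] - R[:, usable].mean(axis=0)) / sd[usable]
    w = int(usable.sum())
    H = S @ S.T / w
    return RelationshipMatrix(list(sm.sample_ids), H, kind="H")


def ensure_pd(rm: RelationshipMatrix, epsilon: float = 1e-6) -> RelationshipMatrix:
    """Add diagonal jitter (doubling from ``epsilon``) until Cholesky succeeds.

    Off-diagonal entries are never touched. Total jitter above 1e-2 aborts:
    such a matrix is pathologically far from positive definite.
    """
    A = rm.values.copy()
    total = 0.0
    jit = float(epsilon)
    while True:
        try:
            np.linalg.cholesky(A)
            break
        except np.linalg.LinAlgError:
            if total + jit > 1e-2:
                raise DataError(
                    f"matrix not positive definite after jitter {total:.3g}; "
                    "input is pathologically non-PD"
                )
            A[np.diag_indices_from(A)] += jit
            total += jit
            jit *= 2.0
    out = RelationshipMatrix(list(rm.sample_ids), A, kind=rm.kind)
    out.jitter = rm.jitter + total
    return out


def chol_upper(rm: RelationshipMatrix) -> CholeskyFactor:
    """Upper-triangular factor Q with Qᵗ·Q = rm.values.

    NumPy returns the lower factor L with L·Lᵗ = A; its transpose is the
    upper factor in the Qᵗ·Q convention used throughout covariate assembly.
    """
    try:
        L = np.linalg.cholesky(rm.values)
    except np.linalg.LinAlgError as exc:
        raise DataError(
            "relationship matrix is not positive definite; call ensure_pd first"
        ) from exc
    return CholeskyFactor(upper=L.T, source_ids=list(rm.sample_ids))


def read_relationship(path: str | Path, kind: str = "user") -> RelationshipMatrix:
    """Read a square relationship matrix CSV with ids as header row and column."""
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    if list(df.index.astype(str)) != [str(c) for c in df.columns]:
        raise DataError(f"{path}: row and column ids differ; not a square relationship matrix")
    A = df.to_numpy(dtype=float)
    if not np.allclose(A, A.T, atol=1e-8):
        raise DataError(f"{path}: matrix is not symmetric to 1e-8")
    return RelationshipMatrix(list(df.index.astype(str)), A, kind=kind)


def write_relationship(rm: RelationshipMatrix, path: str | Path) -> None:
    pd.DataFrame(rm.values, index=rm.sample_ids, columns=rm.sample_ids).to_csv(
        path, index_label="id"
    )
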