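"""Input readers, marker quality control, and alignment of samples across inputs.

Genotypes are additive allele dosages (0/1/2 copies of the alternate allele),
one row per individual and one column per SNP. Spectra are reflectance values,
one row per individual and one column per wavelength. Phenotypes are a long
table of records — one row per (individual, environment) pair in the
multi-environment case — with one column per trait.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

_VALID_DOSAGES = (0.0, 1.0, 2.0)


class DataError(ValueError):
    """Raised for malformed or inconsistent input data."""


def _check_unique(ids, what: str) -> list[str]:
    ids = [str(x) for x in ids]
    if len(set(ids)) != len(ids):
        dupes = sorted({x for x in ids if ids.count(x) > 1})
        raise DataError(f"duplicate {what} ids: {dupes[:5]}")
    return ids


@dataclass
class MarkerMatrix:
    """Individuals × markers dosage matrix with missing values as NaN."""

    sample_ids: list[str]
    marker_ids: list[str]
    dosages: np.ndarray  # float array, entries in {0,1,2} or NaN

    def __post_init__(self) -> None:
        self.sample_ids = _check_unique(self.sample_ids, "sample")
        self.marker_ids = _check_unique(self.marker_ids, "marker")
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.sample_ids), len(self.marker_ids)):
            raise DataError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.marker_ids)} markers"
            )
        finite = self.dosages[np.isfinite(self.dosages)]
        if finite.size and not np.isin(finite, _VALID_DOSAGES).all():
            bad = finite[~np.isin(finite, _VALID_DOSAGES)]
            raise DataError(f"dosages must be 0, 1 or 2; found {bad[:5]}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosages, index=self.sample_ids, columns=self.marker_ids)


@dataclass
class SpectraMatrix:
    """Individuals × wavelengths reflectance matrix (no missing values)."""

    sample_ids: list[str]
    wavelengths: np.ndarray  # strictly increasing, nm
    reflectance: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = _check_unique(self.sample_ids, "sample")
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        if np.any(np.diff(self.wavelengths) <= 0):
            raise DataError("wavelengths must be strictly increasing")
        if self.reflectance.shape != (len(self.sample_ids), self.wavelengths.size):
            raise DataError("reflectance shape does not match ids/wavelengths")
        if not np.isfinite(self.reflectance).all():
            raise DataError("spectra contain missing or non-finite values")
        if (self.reflectance < 0).any():
            raise DataError("reflectance must be non-negative")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


@dataclass
class PhenotypeTable:
    """Phenotype records: one row per (individual, environment) observation.

    ``environment`` is None for single-environment data. Trait values may be
    missing (NaN) before :func:`complete_case_alignment`.
    """

    sample_ids: list[str]
    traits: pd.DataFrame  # records x traits
    environment: list[str] | None = None

    def __post_init__(self) -> None:
        self.sample_ids = [str(x) for x in self.sample_ids]
        self.traits = pd.DataFrame(self.traits).reset_index(drop=True)
        if self.traits.shape[1] < 1:
            raise DataError("at least one trait column is required")
        if len(self.sample_ids) != len(self.traits):
            raise DataError("sample_ids and trait rows differ in length")
        if self.environment is not None:
            self.environment = [str(x) for x in self.environment]
            if len(self.environment) != len(self.sample_ids):
                raise DataError("environment labels and records differ in length")
            keys = list(zip(self.sample_ids, self.environment))
        else:
            keys = list(self.sample_ids)
        if len(set(keys)) != len(keys):
            raise DataError("duplicate (sample, environment) records")

    @property
    def trait_names(self) -> list[str]:
        return list(self.traits.columns)

    @property
    def n_records(self) -> int:
        return len(self.sample_ids)


@dataclass
class QCReport:
    """Counts of markers removed by each quality filter, in precedence order."""

    n_monomorphic_removed: int = 0
    n_low_callrate_removed: int = 0
    n_low_maf_removed: int = 0
    n_samples_dropped_incomplete: int = 0
    thresholds: dict = field(default_factory=dict)

    @property
    def n_markers_removed(self) -> int:
        return self.n_monomorphic_removed + self.n_low_callrate_removed + self.n_low_maf_removed


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _read_table(path: str | Path) -> pd.DataFrame:
    """Read a delimited matrix file, sniffing comma vs tab."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    except Exception as exc:  # pragma: no cover - pandas message varies
        raise DataError(f"could not parse {path}: {exc}") from exc
    return df


def read_markers(path: str | Path, format: str = "matrix-csv") -> MarkerMatrix:
    """Read a dosage matrix from CSV/TSV, or extract dosages from a VCF.

    The matrix format has a header row of marker ids and sample ids in the
    first column. VCF genotypes are converted to alternate-allele dosage;
    multiallelic records are skipped with a warning.
    """
    if format == "matrix-csv":
        df = _read_table(path)
        try:
            return MarkerMatrix(list(df.index), list(df.columns), df.to_numpy(dtype=float))
        except (TypeError, ValueError) as exc:
            if isinstance(exc, DataError):
                raise
            raise DataError(f"non-numeric dosage values in {path}: {exc}") from exc
    if format == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown marker format {format!r}; expected 'matrix-csv' or 'vcf'")


def _read_vcf(path: str | Path) -> MarkerMatrix:
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise ImportError("VCF input requires the optional cyvcf2 dependency") from exc
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    marker_ids: list[str] = []
    columns: list[np.ndarray] = []
    for rec in vcf:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            log.warning("skipping non-biallelic-SNP record at %s:%s", rec.CHROM, rec.POS)
            continue
        # genotypes: [allele0, allele1, phased]; -1 marks a missing allele
        gts = np.array([g[:2] for g in rec.genotypes], dtype=int)
        dose = np.where((gts < 0).any(axis=1), np.nan, (gts > 0).sum(axis=1)).astype(float)
        marker_ids.append(rec.ID or f"{rec.CHROM}_{rec.POS}")
        columns.append(dose)
    if not columns:
        raise DataError(f"no biallelic SNP records found in {path}")
    return MarkerMatrix(samples, marker_ids, np.column_stack(columns))


def write_markers(mm: MarkerMatrix, path: str | Path) -> None:
    mm.to_frame().to_csv(path, index_label="id")


def read_spectra(path: str | Path) -> SpectraMatrix:
    """Read a spectra matrix; column headers are wavelengths in nm."""
    df = _read_table(path)
    try:
        wl = np.asarray([float(c) for c in df.columns])
    except ValueError as exc:
        raise DataError(f"spectra column headers must be numeric wavelengths: {exc}") from exc
    return SpectraMatrix(list(df.index), wl, df.to_numpy(dtype=float))


def write_spectra(sm: SpectraMatrix, path: str | Path) -> None:
    pd.DataFrame(sm.reflectance, index=sm.sample_ids, columns=sm.wavelengths).to_csv(
        path, index_label="id"
    )


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    """Read a phenotype CSV with columns ``id``, optional ``env``, then traits."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=None, engine="python")
    if "id" not in df.columns:
        raise DataError(f"{path}: phenotype file must have an 'id' column")
    env = df["env"].astype(str).tolist() if "env" in df.columns else None
    traits = df.drop(columns=[c for c in ("id", "env") if c in df.columns])
    return PhenotypeTable(df["id"].astype(str).tolist(), traits.astype(float), env)


def write_phenotypes(ph: PhenotypeTable, path: str | Path) -> None:
    out = pd.DataFrame({"id": ph.sample_ids})
    if ph.environment is not None:
        out["env"] = ph.environment
    for c in ph.trait_names:
        out[c] = ph.traits[c].to_numpy()
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# quality control
# ---------------------------------------------------------------------------


def filter_markers(
    mm: MarkerMatrix,
    maf_min: float = 0.05,
    call_rate_min: float = 0.90,
    drop_monomorphic: bool = True,
) -> tuple[MarkerMatrix, QCReport]:
    """Apply standard SNP quality filters.

    Filters in precedence order: monomorphic markers, markers with
    non-missing fraction below ``call_rate_min``, markers with minor allele
    frequency below ``maf_min``. MAF is computed on non-missing dosages as
    min(p, 1-p) with p = mean(dosage)/2. Both thresholds are inclusive
    (a marker exactly at the threshold is retained).
    """
    for name, thr in (("maf_min", maf_min), ("call_rate_min", call_rate_min)):
        if not 0.0 <= thr <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {thr}")

    D = mm.dosages
    n = D.shape[0]
    observed = np.isfinite(D)
    n_obs = observed.sum(axis=0)
    with np.errstate(invalid="ignore"):
        col_mean = np.where(n_obs > 0, np.nansum(D, axis=0) / np.maximum(n_obs, 1), np.nan)
    p = col_mean / 2.0
    maf = np.minimum(p, 1.0 - p)
    # a marker is monomorphic when all observed calls are identical
    mono = np.array(
        [n_obs[j] == 0 or np.nanstd(D[:, j]) == 0.0 for j in range(D.shape[1])]
    )

    removed_mono = mono & drop_monomorphic
    callrate = n_obs / n
    removed_cr = ~removed_mono & (callrate < call_rate_min)
    removed_maf = ~removed_mono & ~removed_cr & (maf < maf_min)
    keep = ~(removed_mono | removed_cr | removed_maf)

    report = QCReport(
        n_monomorphic_removed=int(removed_mono.sum()),
        n_low_callrate_removed=int(removed_cr.sum()),
        n_low_maf_removed=int(removed_maf.sum()),
        thresholds={"maf_min": maf_min, "call_rate_min": call_rate_min,
                    "drop_monomorphic": drop_monomorphic},
    )
    if not keep.any():
        raise DataError("all markers removed by quality filters")
    out = MarkerMatrix(
        mm.sample_ids,
        [m for m, k in zip(mm.marker_ids, keep) if k],
        D[:, keep],
    )
    return out, report


def mean_impute(mm: MarkerMatrix) -> MarkerMatrix:
    """Fill missing dosages with the per-marker mean of observed dosages.

    Imputed values are continuous (not rounded back to 0/1/2); they are used
    only for relationship-matrix construction and as raw covariates.
    """
    D = mm.dosages.copy()
    col_mean = np.nanmean(np.where(np.isfinite(D), D, np.nan), axis=0)
    idx = np.where(~np.isfinite(D))
    D[idx] = col_mean[idx[1]]
    out = MarkerMatrix.__new__(MarkerMatrix)  # bypass {0,1,2} check: imputed values are fractional
    out.sample_ids = list(mm.sample_ids)
    out.marker_ids = list(mm.marker_ids)
    out.dosages = D
    return out


def complete_case_alignment(ph: PhenotypeTable, environments: list[str]) -> PhenotypeTable:
    """Keep only individuals fully observed in every listed environment.

    An individual is complete in an environment when it has a record there
    with no missing trait values. The output is ordered individual-major
    with environments in the order given.
    """
    if not environments:
        raise ValueError("environments must be non-empty")
    if ph.environment is None:
        raise DataError("phenotype table has no environment labels")
    environments = [str(e) for e in environments]
    unknown = set(environments) - set(ph.environment)
    if unknown:
        raise DataError(f"environments not present in data: {sorted(unknown)}")

    complete_rows = ph.traits.notna().all(axis=1).to_numpy()
    rec_index: dict[tuple[str, str], int] = {}
    for i, (s, e) in enumerate(zip(ph.sample_ids, ph.environment)):
        if complete_rows[i]:
            rec_index[(s, e)] = i

    seen: list[str] = []
    for s in ph.sample_ids:
        if s not in seen:
            seen.append(s)
    kept = [s for s in seen if all((s, e) in rec_index for e in environments)]
    if not kept:
        raise DataError("no individual has complete data in all environments")

    order = [rec_index[(s, e)] for s in kept for e in environments]
    return PhenotypeTable(
        [ph.sample_ids[i] for i in order],
        ph.traits.iloc[order].reset_index(drop=True),
        [ph.environment[i] for i in order],
    )


def align_samples(ids_a: list[str], ids_b: list[str], what: str = "input") -> None:
    """Require identical id sets between two inputs; report offenders."""
    a, b = set(ids_a), set(ids_b)
    if a != b:
        only_a = sorted(a - b)[:5]
        only_b = sorted(b - a)[:5]
        raise DataError(
            f"sample ids do not match between inputs ({what}): "
            f"missing from second: {only_a}; missing from first: {only_b}"
        )
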