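"""Covariate assembly for the four prediction approaches.

Approaches combine uni-/multi-trait (UT/MT) with uni-/multi-environment
(UE/ME). For multi-environment data the covariate matrix is the block
concatenation X = [Z_E, Z_G, Z_GE] of environment, genotype, and
genotype-by-environment terms, where the genotype design matrix is
post-multiplied by the transpose of the upper-triangular Cholesky factor
of the relationship matrix (Z_G Qᵗ, so that the block's Gram matrix
reproduces Z_G G Z_Gᵗ) or by the raw feature matrix R, and the interaction
design is post-multiplied by the Kronecker product I_e ⊗ Qᵗ (or I_e ⊗ R).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data_io import DataError, MarkerMatrix, PhenotypeTable, SpectraMatrix, align_samples
from .relationship import CholeskyFactor, RelationshipMatrix, chol_upper, ensure_pd

APPROACHES = ("UTUE", "UTME", "MTUE", "MTME")


@dataclass
class IncidenceMatrix:
    """0/1 design matrix mapping records to factor levels (one 1 per row)."""

    rows: list[str]
    cols: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.rows), len(self.cols)):
            raise ValueError("incidence shape does not match row/col labels")
        if not np.isin(self.values, (0.0, 1.0)).all() or not (self.values.sum(axis=1) == 1).all():
            raise ValueError("incidence matrix must have exactly one 1 per row")


def make_incidence(labels: list[str]) -> IncidenceMatrix:
    """One-hot incidence with columns in first-appearance order of the levels."""
    labels = [str(x) for x in labels]
    if not labels:
        raise ValueError("labels must be non-empty")
    levels: list[str] = []
    for x in labels:
        if x not in levels:
            levels.append(x)
    Z = np.zeros((len(labels), len(levels)))
    pos = {lv: j for j, lv in enumerate(levels)}
    for i, x in enumerate(labels):
        Z[i, pos[x]] = 1.0
    return IncidenceMatrix(labels, levels, Z)


@dataclass
class PreparedDataset:
    """Assembled covariates X and responses Y, ready for model training.

    ``blocks`` maps block names ("env", "genotype", "gxe") to half-open
    column ranges of X. Records are ordered individual-major with
    environments in the order listed at preparation time.
    """

    X: np.ndarray
    Y: np.ndarray
    approach: str
    blocks: dict[str, tuple[int, int]]
    sample_ids: list[str]  # per record
    env_labels: list[str] | None  # per record, None for UE
    individuals: list[str] = field(default_factory=list)  # distinct, in record order
    env_order: list[str] = field(default_factory=list)
    trait_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.Y = np.asarray(self.Y, dtype=float)
        if self.Y.ndim == 1:
            self.Y = self.Y[:, None]
        if self.approach not in APPROACHES:
            raise ValueError(f"approach must be one of {APPROACHES}")
        if self.X.shape[0] != self.Y.shape[0]:
            raise ValueError("X and Y row counts differ")
        width = sum(b - a for a, b in self.blocks.values())
        if width != self.X.shape[1]:
            raise ValueError("block widths do not sum to X column count")

    @property
    def n_records(self) -> int:
        return self.X.shape[0]

    @property
    def n_traits(self) -> int:
        return self.Y.shape[1]

    def block(self, name: str) -> np.ndarray:
        a, b = self.blocks[name]
        return self.X[:, a:b]

    # -- serialisation ------------------------------------------------------

    def to_dir(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(self.X).to_csv(path / "X.csv", index=False)
        pd.DataFrame(self.Y, columns=self.trait_names or None).to_csv(
            path / "Y.csv", index=False
        )
        meta = {
            "approach": self.approach,
            "blocks": {k: [int(a), int(b)] for k, (a, b) in self.blocks.items()},
            "sample_ids": self.sample_ids,
            "env_labels": self.env_labels,
            "individuals": self.individuals,
            "env_order": self.env_order,
            "trait_names": self.trait_names,
        }
        (path / "meta.yaml").write_text(yaml.safe_dump(meta))

    @classmethod
    def from_dir(cls, path: str | Path) -> "PreparedDataset":
        path = Path(path)
        meta = yaml.safe_load((path / "meta.yaml").read_text())
        X = pd.read_csv(path / "X.csv").to_numpy(dtype=float)
        Y = pd.read_csv(path / "Y.csv").to_numpy(dtype=float)
        return cls(
            X=X,
            Y=Y,
            approach=meta["approach"],
            blocks={k: tuple(v) for k, v in meta["blocks"].items()},
            sample_ids=meta["sample_ids"],
            env_labels=meta["env_labels"],
            individuals=meta.get("individuals", []),
            env_order=meta.get("env_order", []),
            trait_names=meta.get("trait_names", []),
        )


def assemble_covariates(
    ze: IncidenceMatrix,
    zg: IncidenceMatrix,
    zge: IncidenceMatrix,
    transform: CholeskyFactor | np.ndarray,
) -> tuple[np.ndarray, dict[str, tuple[int, int]]]:
    """Concatenate X = [Z_E, Z_G·T, Z_GE·(I_e ⊗ T)] for T = Qᵗ or raw R.

    ``zge`` columns must be ordered environment-major (column index
    = env_index · n_individuals + individual_index) to conform with the
    Kronecker product.
    """
    T = transform.upper.T if isinstance(transform, CholeskyFactor) else np.asarray(transform, float)
    n_env = len(ze.cols)
    n_ind = len(zg.cols)
    if T.shape[0] != n_ind:
        raise ValueError(
            f"transform rows ({T.shape[0]}) must equal genotype levels ({n_ind})"
        )
    if len(zge.cols) != n_ind * n_env:
        raise ValueError(
            f"Z_GE has {len(zge.cols)} columns; expected "
            f"{n_ind} individuals x {n_env} environments = {n_ind * n_env}"
        )
    genotype_block = zg.values @ T
    gxe_block = zge.values @ np.kron(np.eye(n_env), T)
    X = np.hstack([ze.values, genotype_block, gxe_block])
    blocks = {
        "env": (0, n_env),
        "genotype": (n_env, n_env + T.shape[1]),
        "gxe": (n_env + T.shape[1], X.shape[1]),
    }
    return X, blocks


def _feature_matrix(inp, individuals: list[str]) -> np.ndarray:
    """Row-align a raw feature matrix (dosages or spectra) to `individuals`."""
    if isinstance(inp, MarkerMatrix):
        ids, M = inp.sample_ids, inp.dosages
        if not np.isfinite(M).all():
            raise DataError("marker matrix has missing values; run mean_impute first")
    else:
        ids, M = inp.sample_ids, inp.reflectance
    align_samples(individuals, ids, what="phenotypes vs features")
    order = [ids.index(s) for s in individuals]
    return M[order]


def prepare_data(
    traits: PhenotypeTable,
    input,
    environments: list[str] | None = None,
    multi_trait: bool = False,
    trait: str | None = None,
) -> PreparedDataset:
    """Assemble the covariates and responses for one prediction approach.

    Parameters
    ----------
    traits
        Phenotype records. For multi-environment analyses this must already
        be complete-case aligned (every individual observed in every
        environment).
    input
        Raw features (:class:`MarkerMatrix` or :class:`SpectraMatrix`) or a
        precomputed :class:`RelationshipMatrix`. A relationship matrix is
        converted to features through its upper Cholesky factor so that the
        feature Gram matrix reproduces the relationship.
    environments
        Environment labels in model order; presence selects the ME approach.
    multi_trait
        Use all trait columns jointly (MT) instead of a single trait (UT).
    trait
        Trait column for UT when the table has several traits.
    """
    if multi_trait:
        Yfull = traits.traits
        trait_names = traits.trait_names
    else:
        if trait is None:
            if len(traits.trait_names) != 1:
                raise ValueError(
                    "uni-trait preparation on a multi-trait table requires `trait`"
                )
            trait = traits.trait_names[0]
        if trait not in traits.trait_names:
            raise ValueError(f"unknown trait {trait!r}; have {traits.trait_names}")
        Yfull = traits.traits[[trait]]
        trait_names = [trait]

    is_rel = isinstance(input, RelationshipMatrix)

    if environments is None:
        # single environment: one record per individual
        approach = "MTUE" if multi_trait else "UTUE"
        if traits.environment is not None and len(set(traits.environment)) > 1:
            raise DataError("multiple environments present but none requested; pass environments=")
        individuals = list(traits.sample_ids)
        if len(set(individuals)) != len(individuals):
            raise DataError("duplicate individuals in single-environment phenotypes")
        if is_rel:
            align_samples(individuals, input.sample_ids, what="phenotypes vs relationship")
            order = [input.sample_ids.index(s) for s in individuals]
            rm = RelationshipMatrix(
                [input.sample_ids[i] for i in order],
                input.values[np.ix_(order, order)],
                kind=input.kind,
            )
            Q = chol_upper(ensure_pd(rm))
            X = Q.upper.T  # Z_G = I for one record per individual
        else:
            X = _feature_matrix(input, individuals)
        Y = Yfull.to_numpy(dtype=float)
        if not np.isfinite(Y).all():
            raise DataError("missing trait values; filter incomplete records first")
        return PreparedDataset(
            X=X,
            Y=Y,
            approach=approach,
            blocks={"genotype": (0, X.shape[1])},
            sample_ids=individuals,
            env_labels=None,
            individuals=individuals,
            env_order=[],
            trait_names=trait_names,
        )

    # multi-environment
    approach = "MTME" if multi_trait else "UTME"
    if traits.environment is None:
        raise DataError("multi-environment preparation requires environment labels")
    environments = [str(e) for e in environments]

    individuals: list[str] = []
    for s in traits.sample_ids:
        if s not in individuals:
            individuals.append(s)
    rec_index = {
        (s, e): i for i, (s, e) in enumerate(zip(traits.sample_ids, traits.environment))
    }
    missing = [(s, e) for s in individuals for e in environments if (s, e) not in rec_index]
    if missing:
        raise DataError(
            f"records missing for {missing[:5]}; apply complete_case_alignment first"
        )
    order = [rec_index[(s, e)] for s in individuals for e in environments]
    Y = Yfull.to_numpy(dtype=float)[order]
    if not np.isfinite(Y).all():
        raise DataError("missing trait values; apply complete_case_alignment first")
    rec_samples = [individuals[i // len(environments)] for i in range(len(order))]
    rec_envs = [environments[i % len(environments)] for i in range(len(order))]

    ze = make_incidence(rec_envs)
    # force genotype/environment level order explicitly
    ze = IncidenceMatrix(rec_envs, environments,
                         np.array([[1.0 if e == lv else 0.0 for lv in environments]
                                   for e in rec_envs]))
    zg = IncidenceMatrix(
        rec_samples,
        individuals,
        np.array([[1.0 if s == iv else 0.0 for iv in individuals] for s in rec_samples]),
    )
    ge_levels = [f"{iv}:{lv}" for lv in environments for iv in individuals]
    n_ind, n_env = len(individuals), len(environments)
    Zge = np.zeros((len(order), n_ind * n_env))
    for r, (s, e) in enumerate(zip(rec_samples, rec_envs)):
        Zge[r, environments.index(e) * n_ind + individuals.index(s)] = 1.0
    zge = IncidenceMatrix([f"{s}:{e}" for s, e in zip(rec_samples, rec_envs)], ge_levels, Zge)

    if is_rel:
        align_samples(individuals, input.sample_ids, what="phenotypes vs relationship")
        idx = [input.sample_ids.index(s) for s in individuals]
        rm = RelationshipMatrix(
            [input.sample_ids[i] for i in idx],
            input.values[np.ix_(idx, idx)],
            kind=input.kind,
        )
        transform: CholeskyFactor | np.ndarray = chol_upper(ensure_pd(rm))
    else:
        transform = _feature_matrix(input, individuals)

    X, blocks = assemble_covariates(ze, zg, zge, transform)
    return PreparedDataset(
        X=X,
        Y=Y,
        approach=approach,
        blocks=blocks,
        sample_ids=rec_samples,
        env_labels=rec_envs,
        individuals=individuals,
        env_order=environments,
        trait_names=trait_names,
    )
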