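"""Synthetic breeding study generator with known ground truth.

Generates biallelic SNP dosages, additive multi-trait phenotypes with
per-trait heritability, genetic correlation among traits, environment main
effects and genotype-by-environment deviations, and NIR-like spectra whose
variation partially tracks genetic values. Every module of the package is
testable against these data because the simulator records the true breeding
values, environment effects and realized heritabilities.

The genetic architecture is purely additive: per-trait marker effects are
drawn jointly across traits with the requested genetic correlation, the
shared breeding value of each individual is the centred-dosage weighted sum
of effects, and G×E is an independent additive deviation per environment
(compound symmetry across environments, matching a G ⊗ I covariance).
All randomness flows from one seed through named substreams, so each data
layer can be regenerated independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import MarkerMatrix, PhenotypeTable, SpectraMatrix

_STREAMS = {"genotypes": 1, "effects": 2, "env": 3, "residual": 4, "spectra": 5}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STREAMS[stream]]))


@dataclass
class SimConfig:
    """Study conditions for the synthetic generator.

    Defaults describe a mid-sized breeding trial: 200 genotyped individuals,
    500 polymorphic SNPs with minor allele frequencies between 0.05 and 0.5,
    one trait of heritability 0.6, two environments with main-effect
    standard deviation 1.0 (trait units), G×E variance at 20% of the
    additive variance, and 100-band spectra in which 80% of the per-band
    signal amplitude is genetic.
    """

    n_individuals: int = 200
    n_markers: int = 500
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_traits: int = 1
    heritabilities: tuple[float, ...] = (0.6,)
    genetic_correlation: np.ndarray | None = None  # t×t, unit diagonal; identity if None
    n_environments: int = 2
    env_effect_sd: float = 1.0
    gxe_variance_fraction: float = 0.2
    n_wavelengths: int = 512
    spectra_signal_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if len(self.heritabilities) != self.n_traits:
            raise ValueError("one heritability per trait is required")
        if any(not 0 <= h <= 1 for h in self.heritabilities):
            raise ValueError("heritabilities must be in [0, 1]")
        if not 0 <= self.spectra_signal_fraction <= 1:
            raise ValueError("spectra_signal_fraction must be in [0, 1]")
        if self.genetic_correlation is None:
            self.genetic_correlation = np.eye(self.n_traits)
        else:
            S = np.asarray(self.genetic_correlation, dtype=float)
            if S.shape != (self.n_traits, self.n_traits):
                raise ValueError("genetic_correlation must be t×t")
            if not np.allclose(np.diag(S), 1.0):
                raise ValueError("genetic_correlation must have unit diagonal")
            if np.linalg.eigvalsh(S).min() <= 0:
                raise ValueError("genetic_correlation must be positive definite")
            self.genetic_correlation = S

    @property
    def env_names(self) -> list[str]:
        return [f"E{k + 1}" for k in range(self.n_environments)]


@dataclass
class SimulatedStudy:
    """A complete synthetic dataset with its ground truth."""

    markers: MarkerMatrix
    spectra: SpectraMatrix
    phenotypes: PhenotypeTable
    truth: dict = field(default_factory=dict)


def simulate_genotypes(cfg: SimConfig) -> MarkerMatrix:
    """Dosages drawn Binomial(2, p_k) with p_k uniform over the MAF range.

    Half the markers (at random) carry the mirrored frequency 1 − p so the
    alternate allele is not systematically minor.
    """
    rng = _rng(cfg.seed, "genotypes")
    lo, hi = cfg.maf_range
    p = rng.uniform(lo, hi, size=cfg.n_markers)
    flip = rng.random(cfg.n_markers) < 0.5
    p = np.where(flip, 1.0 - p, p)
    D = rng.binomial(2, p, size=(cfg.n_individuals, cfg.n_markers)).astype(float)
    ids = [f"ind{i + 1:04d}" for i in range(cfg.n_individuals)]
    mids = [f"snp{k + 1:05d}" for k in range(cfg.n_markers)]
    return MarkerMatrix(ids, mids, D)


def simulate_traits(mm: MarkerMatrix, cfg: SimConfig) -> tuple[PhenotypeTable, dict]:
    """Additive phenotypes with known heritability, correlation, and G×E.

    Shared breeding values are scaled to unit variance per trait; per-
    environment deviations carry ``gxe_variance_fraction`` of that variance;
    the residual variance is set from the realized genetic variance so each
    trait's per-environment heritability matches its target. A target of 0
    produces pure noise around the environment means.
    """
    rng_eff = _rng(cfg.seed, "effects")
    rng_env = _rng(cfg.seed, "env")
    rng_res = _rng(cfg.seed, "residual")
    n, m, t, e = mm.n_samples, mm.n_markers, cfg.n_traits, cfg.n_environments

    M = mm.dosages
    W = M - M.mean(axis=0)
    chol = np.linalg.cholesky(cfg.genetic_correlation)
    B = (rng_eff.standard_normal((m, t)) / np.sqrt(m)) @ chol.T
    g = W @ B
    g_sd = g.std(axis=0)
    g_sd = np.where(g_sd > 0, g_sd, 1.0)
    g = g / g_sd  # unit-variance shared breeding values

    gxe_sd = np.sqrt(cfg.gxe_variance_fraction)
    d = {}
    for env in cfg.env_names:
        Be = rng_eff.standard_normal((m, t)) / np.sqrt(m)
        de = W @ Be
        sd = de.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        d[env] = de / sd * gxe_sd

    alpha = rng_env.normal(0.0, cfg.env_effect_sd, size=(e, t))

    h2 = np.asarray(cfg.heritabilities, dtype=float)
    records = []
    realized = []
    env_values = {}
    for k, env in enumerate(cfg.env_names):
        u = np.where(h2 > 0, 1.0, 0.0) * (g + d[env])  # total genetic value in this env
        var_u = u.var(axis=0)
        with np.errstate(divide="ignore"):
            res_var = np.where(h2 > 0, var_u * (1.0 - h2) / np.where(h2 > 0, h2, 1.0), 1.0)
        eps = rng_res.standard_normal((n, t)) * np.sqrt(res_var)
        y = alpha[k] + u + eps
        env_values[env] = u
        realized.append(var_u / y.var(axis=0))
        records.append(y)

    trait_names = [f"trait{j + 1}" for j in range(t)]
    if e == 1:
        table = PhenotypeTable(
            list(mm.sample_ids),
            pd.DataFrame(records[0], columns=trait_names),
            None,
        )
    else:
        rows = np.stack(records, axis=1).reshape(n * e, t)  # individual-major
        table = PhenotypeTable(
            [s for s in mm.sample_ids for _ in range(e)],
            pd.DataFrame(rows, columns=trait_names),
            [env for _ in mm.sample_ids for env in cfg.env_names],
        )
    truth = {
        "true_g": pd.DataFrame(g, index=mm.sample_ids, columns=trait_names),
        "true_d": {env: pd.DataFrame(d[env], index=mm.sample_ids, columns=trait_names)
                   for env in cfg.env_names},
        "env_effects": pd.DataFrame(alpha, index=cfg.env_names, columns=trait_names),
        "true_genetic_value": {env: pd.DataFrame(env_values[env], index=mm.sample_ids,
                                                 columns=trait_names)
                               for env in cfg.env_names},
        "realized_h2": pd.DataFrame(realized, index=cfg.env_names, columns=trait_names),
        "centered_genotypes": W,
    }
    return table, truth


def simulate_spectra(truth: dict, cfg: SimConfig) -> SpectraMatrix:
    """Spectra = smooth baseline + genetic signal + noise, per wavelength.

    The genetic part projects latent additive scores (built from the
    centred genotypes) through smooth wavelength loadings, weighted by
    ``spectra_signal_fraction``; the orthogonal remainder is i.i.d. noise,
    so a signal fraction of 0 yields spectra carrying no genetic
    information at all.
    """
    rng = _rng(cfg.seed, "spectra")
    W = np.asarray(truth["centered_genotypes"], dtype=float)
    n, m = W.shape
    w = cfg.n_wavelengths
    # enough latent components that the spectra-borne estimate of the genomic
    # relationship is not dominated by latent-sampling noise
    k = min(200, m, w)
    U = W @ (rng.standard_normal((m, k)) / np.sqrt(m))
    sd = U.std(axis=0)
    U = U / np.where(sd > 0, sd, 1.0)

    # lightly smoothed loadings: adjacent bands respond similarly, but the
    # spectrum as a whole keeps enough independent directions to carry the
    # latent genetic space
    L = rng.standard_normal((k, w))
    kernel = np.hanning(5)
    kernel /= kernel.sum()
    L = np.apply_along_axis(lambda v: np.convolve(v, kernel, mode="same"), 1, L)
    L /= np.maximum(L.std(axis=1, keepdims=True), 1e-12)

    wavelengths = np.linspace(950.0, 1650.0, w)
    baseline = 1.5 + 0.4 * np.sin((wavelengths - 950.0) / 180.0) \
        + 0.2 * np.cos((wavelengths - 950.0) / 55.0)

    sf = cfg.spectra_signal_fraction
    signal = (U @ L) / np.sqrt(k)
    noise = rng.standard_normal((n, w))
    amp = 0.08
    R = baseline + amp * (sf * signal + np.sqrt(max(0.0, 1.0 - sf**2)) * noise)
    R = np.clip(R, 0.0, None)
    ids = [f"ind{i + 1:04d}" for i in range(n)]
    return SpectraMatrix(ids, wavelengths, R)


def simulate_study(cfg: SimConfig) -> SimulatedStudy:
    """Full study: genotypes, traits with truth, and matched spectra."""
    mm = simulate_genotypes(cfg)
    table, truth = simulate_traits(mm, cfg)
    sm = simulate_spectra(truth, cfg)
    return SimulatedStudy(mm, sm, table, truth)
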