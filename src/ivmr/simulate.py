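"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generator emulates the sampling process behind published summary
statistics rather than individual-level genotypes.  For an instrument with
minor-allele frequency p:

* exposure (quantitative, SD scale):  β̂_x ~ N(β_x, se_x²) with
  se_x = 1/√(2p(1-p)·n_exposure);
* outcome (binary, log-odds scale):   β̂_y ~ N(θ·β_x + a, se_y²) with
  se_y = 1/√(2p(1-p)·N·K(1-K)), N the outcome sample size and K the case
  fraction — the same effective-sample-size approximation the power module
  uses, so analytic power and simulated rejection rates are directly
  comparable;

θ is the true causal log-odds per SD of exposure and a is a per-SNP direct
(pleiotropic) effect on the outcome, drawn N(pleiotropy_mean, pleiotropy_sd²).

Defaults mirror the discovery design of the packaged IL18 → IBD example:
three instruments with SD-scale effects (0.243, 0.312, 0.267) at minor-allele
frequencies (0.36, 0.05, 0.24), an exposure GWAS of 3,636 and an outcome GWAS
of 12,882 cases / 21,770 controls, and a true effect of ln(1.2) — the
odds-ratio increase per SD that the corresponding power calculations target.

:func:`simulate_coloc_region` generates correlated regional summary
statistics for two traits under an AR(1)-style LD structure, with the causal
configuration (shared / distinct / single-trait / null) chosen explicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .exceptions import ConfigurationError
from .summary_stats import SnpAssociation, variance_explained
from .coloc import RegionStats

__all__ = [
    "SimConfig",
    "RegionSimConfig",
    "TwoSampleTruth",
    "RegionTruth",
    "simulate_two_sample_study",
    "simulate_coloc_region",
    "simulate_phewas_catalogue",
]

_TINY = np.finfo(float).tiny

# Discovery-design defaults: Table-style instrument effects and frequencies.
_DEFAULT_BETAS = (0.243, 0.312, 0.267)
_DEFAULT_MAFS = (0.36, 0.05, 0.24)


@dataclass(frozen=True)
class SimConfig:
    """Design of one simulated two-sample MR study."""

    seed: int = 0
    n_instruments: int = 3
    maf_range: tuple[float, float] = (0.05, 0.5)
    exposure_betas: tuple[float, ...] | None = _DEFAULT_BETAS
    mafs: tuple[float, ...] | None = _DEFAULT_MAFS
    n_exposure: int = 3636
    n_cases: int = 12_882
    n_controls: int = 21_770
    theta_true: float = math.log(1.2)
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    palindromic_fraction: float = 0.0
    shuffle_outcome_alleles: bool = True

    def __post_init__(self) -> None:
        if self.n_instruments < 1:
            raise ConfigurationError("n_instruments must be >= 1")
        if min(self.n_exposure, self.n_cases, self.n_controls) <= 0:
            raise ConfigurationError("sample sizes must be > 0")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigurationError("maf_range must lie within (0, 0.5]")
        for name, vals in (("exposure_betas", self.exposure_betas), ("mafs", self.mafs)):
            if vals is not None and len(vals) != self.n_instruments:
                raise ConfigurationError(
                    f"{name} has {len(vals)} entries for {self.n_instruments} instruments"
                )
        if self.mafs is not None and not all(0.0 < m <= 0.5 for m in self.mafs):
            raise ConfigurationError("mafs must lie within (0, 0.5]")
        if not 0.0 <= self.palindromic_fraction <= 1.0:
            raise ConfigurationError("palindromic_fraction must be in [0,1]")
        if self.pleiotropy_sd < 0:
            raise ConfigurationError("pleiotropy_sd must be >= 0")


@dataclass(frozen=True)
class TwoSampleTruth:
    """Latent quantities behind one simulated study."""

    theta: float
    exposure_betas: tuple[float, ...]
    mafs: tuple[float, ...]
    pleiotropy: tuple[float, ...]
    r2: float

    def to_dict(self) -> dict:
        return {
            "theta": self.theta,
            "exposure_betas": list(self.exposure_betas),
            "mafs": list(self.mafs),
            "pleiotropy": list(self.pleiotropy),
            "r2": self.r2,
        }


_NONPALINDROMIC_PAIRS = (("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"))
_PALINDROMIC_PAIRS = (("A", "T"), ("C", "G"))


def _pvalue(beta: float, se: float) -> float:
    return max(2.0 * float(stats.norm.sf(abs(beta) / se)), _TINY)


def simulate_two_sample_study(
    config: SimConfig,
) -> tuple[list[SnpAssociation], list[SnpAssociation], TwoSampleTruth]:
    """Draw one exposure GWAS and one outcome GWAS over shared instruments.

    Returns (exposure records, outcome records, truth).  Outcome records are
    emitted with randomly swapped allele labels (and the matching sign change)
    when ``shuffle_outcome_alleles`` is set, so the harmonization step is
    exercised on realistic input.  Identical configs give identical output.
    """
    rng = np.random.default_rng(config.seed)
    k = config.n_instruments
    mafs = (
        np.array(config.mafs)
        if config.mafs is not None
        else rng.uniform(*config.maf_range, size=k)
    )
    betas = (
        np.array(config.exposure_betas)
        if config.exposure_betas is not None
        else rng.uniform(0.15, 0.35, size=k)
    )
    n_out = config.n_cases + config.n_controls
    case_frac = config.n_cases / n_out
    se_x = 1.0 / np.sqrt(2.0 * mafs * (1.0 - mafs) * config.n_exposure)
    se_y = 1.0 / np.sqrt(2.0 * mafs * (1.0 - mafs) * n_out * case_frac * (1.0 - case_frac))
    pleio = rng.normal(config.pleiotropy_mean, config.pleiotropy_sd, size=k) \
        if config.pleiotropy_sd > 0 or config.pleiotropy_mean != 0 \
        else np.zeros(k)

    beta_x_hat = rng.normal(betas, se_x)
    beta_y_hat = rng.normal(config.theta_true * betas + pleio, se_y)

    exposure, outcome = [], []
    for j in range(k):
        palindromic = rng.random() < config.palindromic_fraction
        pairs = _PALINDROMIC_PAIRS if palindromic else _NONPALINDROMIC_PAIRS
        ea, oa = pairs[rng.integers(len(pairs))]
        rsid = f"rs{1000001 + j}"
        exposure.append(
            SnpAssociation(
                rsid=rsid,
                chrom=str(j + 1),
                effect_allele=ea,
                other_allele=oa,
                eaf=float(mafs[j]),
                beta=float(beta_x_hat[j]),
                se=float(se_x[j]),
                pvalue=_pvalue(beta_x_hat[j], se_x[j]),
                n=config.n_exposure,
                trait="simulated exposure",
                trait_type="quantitative",
            )
        )
        out_ea, out_oa, out_beta, out_eaf = ea, oa, beta_y_hat[j], mafs[j]
        if config.shuffle_outcome_alleles and rng.random() < 0.5 and not palindromic:
            out_ea, out_oa = oa, ea
            out_beta = -out_beta
            out_eaf = 1.0 - out_eaf
        outcome.append(
            SnpAssociation(
                rsid=rsid,
                chrom=str(j + 1),
                effect_allele=out_ea,
                other_allele=out_oa,
                eaf=float(out_eaf),
                beta=float(out_beta),
                se=float(se_y[j]),
                pvalue=_pvalue(out_beta, se_y[j]),
                n=n_out,
                trait="simulated outcome",
                trait_type="binary",
            )
        )

    truth = TwoSampleTruth(
        theta=config.theta_true,
        exposure_betas=tuple(float(b) for b in betas),
        mafs=tuple(float(m) for m in mafs),
        pleiotropy=tuple(float(a) for a in pleio),
        r2=float(sum(variance_explained(m, b) for m, b in zip(mafs, betas))),
    )
    return exposure, outcome, truth


def simulate_phewas_catalogue(
    config: SimConfig, n_outcomes: int, null: bool = True
) -> tuple[list[SnpAssociation], dict[str, list[SnpAssociation]]]:
    """One exposure study plus a catalogue of independent outcome studies.

    With ``null=True`` every outcome is generated at θ = 0 (and no
    pleiotropy), giving a fully null catalogue for family-wise error checks.
    Outcome studies are mutually independent; the exposure study is shared,
    as in a real phenome-wide scan of one instrument set.
    """
    if n_outcomes < 1:
        raise ConfigurationError("n_outcomes must be >= 1")
    from dataclasses import replace as dc_replace

    exposure, _, _ = simulate_two_sample_study(config)
    by_rsid = {r.rsid: r for r in exposure}
    catalogue: dict[str, list[SnpAssociation]] = {}
    for i in range(n_outcomes):
        sub_seed = (config.seed * 100_003 + 7 * i + 1) % (2**31)
        sub = dc_replace(
            config,
            seed=sub_seed,
            theta_true=0.0 if null else config.theta_true,
            pleiotropy_mean=0.0 if null else config.pleiotropy_mean,
            pleiotropy_sd=0.0 if null else config.pleiotropy_sd,
            shuffle_outcome_alleles=False,
        )
        _, outcome, _ = simulate_two_sample_study(sub)
        # All outcome studies describe the same physical instruments, so they
        # must carry the exposure study's allele pairs.
        catalogue[f"outcome_{i:03d}"] = [
            dc_replace(
                rec,
                effect_allele=by_rsid[rec.rsid].effect_allele,
                other_allele=by_rsid[rec.rsid].other_allele,
                eaf=by_rsid[rec.rsid].eaf,
                trait=f"outcome_{i:03d}",
            )
            for rec in outcome
        ]
    return exposure, catalogue


# ---------------------------------------------------------------------------
# Colocalization regions

CausalConfig = Literal["shared", "distinct", "trait1_only", "null"]


@dataclass(frozen=True)
class RegionSimConfig:
    """Design of one simulated two-trait region.

    LD follows an AR(1) structure: corr(z_i, z_j) = ld_decay^|i-j|, which is
    positive definite for 0 <= ld_decay < 1.  ``causal_positions`` places the
    causal SNP(s); for ``distinct`` the first entry drives trait 1 and the
    second trait 2, so adjacent positions give pairwise LD = ld_decay.
    """

    seed: int = 0
    n_snps: int = 50
    ld_decay: float = 0.9
    causal_config: CausalConfig = "shared"
    causal_positions: tuple[int, ...] | None = None
    beta1: float = 0.25
    beta2: float = 0.08
    n1: int = 3636
    n2: int = 30_000

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise ConfigurationError("n_snps must be >= 1")
        if not 0.0 <= self.ld_decay < 1.0:
            raise ConfigurationError("ld_decay must be in [0, 1)")
        if self.causal_config not in ("shared", "distinct", "trait1_only", "null"):
            raise ConfigurationError(f"unknown causal_config {self.causal_config!r}")
        if self.causal_config == "distinct" and self.n_snps < 2:
            raise ConfigurationError("a distinct-causal-variant region needs >= 2 SNPs")
        if min(self.n1, self.n2) <= 0:
            raise ConfigurationError("sample sizes must be > 0")
        if self.causal_positions is not None:
            need = 2 if self.causal_config == "distinct" else 1
            if len(self.causal_positions) < need:
                raise ConfigurationError(
                    f"causal_config={self.causal_config} needs {need} causal position(s)"
                )
            if any(not 0 <= c < self.n_snps for c in self.causal_positions):
                raise ConfigurationError("causal_positions out of range")


@dataclass(frozen=True)
class RegionTruth:
    causal_config: str
    causal1: int | None
    causal2: int | None
    ld_between_causals: float | None

    def to_dict(self) -> dict:
        return {
            "causal_config": self.causal_config,
            "causal1": self.causal1,
            "causal2": self.causal2,
            "ld_between_causals": self.ld_between_causals,
        }


def _default_positions(config: RegionSimConfig) -> tuple[int, ...]:
    if config.causal_config == "distinct":
        return (config.n_snps // 3, 2 * config.n_snps // 3)
    return (config.n_snps // 2,)


def simulate_coloc_region(
    config: RegionSimConfig,
) -> tuple[RegionStats, RegionTruth]:
    """Draw correlated regional z-scores for two traits and convert to β/SE.

    Marginal z-score means are √n · R[:, c] · b for causal SNP c with
    standardized effect b, and the noise is MVN(0, R) per trait with R the LD
    correlation matrix; β = z·se with se = 1/√n.
    """
    rng = np.random.default_rng(config.seed)
    m = config.n_snps
    idx = np.arange(m)
    ld = config.ld_decay ** np.abs(idx[:, None] - idx[None, :])
    try:
        chol = np.linalg.cholesky(ld)
    except np.linalg.LinAlgError as exc:
        raise ConfigurationError("LD matrix is not positive definite") from exc

    positions = config.causal_positions or _default_positions(config)
    lam1 = np.zeros(m)
    lam2 = np.zeros(m)
    causal1 = causal2 = None
    if config.causal_config == "shared":
        causal1 = causal2 = positions[0]
        lam1[causal1] = config.beta1
        lam2[causal2] = config.beta2
    elif config.causal_config == "distinct":
        causal1, causal2 = positions[0], positions[1]
        lam1[causal1] = config.beta1
        lam2[causal2] = config.beta2
    elif config.causal_config == "trait1_only":
        causal1 = positions[0]
        lam1[causal1] = config.beta1

    z1 = math.sqrt(config.n1) * ld @ lam1 + chol @ rng.standard_normal(m)
    z2 = math.sqrt(config.n2) * ld @ lam2 + chol @ rng.standard_normal(m)
    se1 = np.full(m, 1.0 / math.sqrt(config.n1))
    se2 = np.full(m, 1.0 / math.sqrt(config.n2))

    region = RegionStats(
        rsids=tuple(f"rs{2000001 + j}" for j in range(m)),
        beta1=z1 * se1,
        se1=se1,
        beta2=z2 * se2,
        se2=se2,
    )
    ld_cc = (
        float(ld[causal1, causal2])
        if causal1 is not None and causal2 is not None and causal1 != causal2
        else None
    )
    truth = RegionTruth(
        causal_config=config.causal_config,
        causal1=causal1,
        causal2=causal2,
        ld_between_causals=ld_cc,
    )
    return region, truth
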