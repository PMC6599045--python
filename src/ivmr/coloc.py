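"""Approximate-Bayes-factor colocalization of two association signals.

Given per-SNP summary statistics for two traits over one region, assuming at
most one causal variant per trait, the method weighs five hypotheses:

    H0  no association with either trait
    H1  causal variant for trait 1 only
    H2  causal variant for trait 2 only
    H3  two distinct causal variants
    H4  one shared causal variant

Each SNP's evidence of association with each trait is a Wakefield
approximate Bayes factor computed from the estimate β̂ and its SE alone:
with z = β̂/se, V = se², W the prior effect variance, r = W/(W+V),

    log ABF = ½ [ log(1-r) + r z² ].

Hypothesis likelihoods are sums of per-SNP (pairs of) ABFs weighted by the
per-configuration priors p1, p2 (single-trait causal) and p12 (shared), and
are normalized to posterior probabilities PP0–PP4.  All accumulation is in
log space (log-sum-exp); a region of one SNP has PP3 = 0 structurally.

In Mendelian randomization this guards against confounding by linkage
disequilibrium: an instrument whose region favours H3 over H4 is tagging a
distinct outcome-trait causal variant rather than acting through the
exposure (:func:`confounding_by_ld_check`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .exceptions import DomainError, ValidationError

__all__ = [
    "RegionStats",
    "ColocResult",
    "LdCheck",
    "wakefield_abf",
    "coloc_abf",
    "confounding_by_ld_check",
    "read_region",
]

#: Default prior probabilities per SNP: single-trait causal and shared causal.
DEFAULT_P1 = 1e-4
DEFAULT_P2 = 1e-4
DEFAULT_P12 = 1e-5

#: Default prior effect-scale SDs by trait type.
PRIOR_SD_QUANTITATIVE = 0.15
PRIOR_SD_BINARY = 0.2


@dataclass(frozen=True)
class RegionStats:
    """Parallel per-SNP summary statistics for two traits over one region."""

    rsids: tuple[str, ...]
    beta1: np.ndarray
    se1: np.ndarray
    beta2: np.ndarray
    se2: np.ndarray
    trait1_type: str = "quantitative"
    trait2_type: str = "binary"

    def __post_init__(self) -> None:
        arrays = {
            "beta1": np.asarray(self.beta1, dtype=float),
            "se1": np.asarray(self.se1, dtype=float),
            "beta2": np.asarray(self.beta2, dtype=float),
            "se2": np.asarray(self.se2, dtype=float),
        }
        for name, arr in arrays.items():
            object.__setattr__(self, name, arr)
        n = len(self.rsids)
        if n < 1:
            raise ValidationError("a region needs at least one SNP")
        for name, arr in arrays.items():
            if arr.shape != (n,):
                raise ValidationError(f"{name} must have one value per SNP")
        if not (arrays["se1"] > 0).all() or not (arrays["se2"] > 0).all():
            raise ValidationError("all standard errors must be > 0")
        if len(set(self.rsids)) != n:
            raise ValidationError("duplicate rsIDs in region")

    def __len__(self) -> int:
        return len(self.rsids)

    def reordered(self, order: Sequence[int]) -> "RegionStats":
        idx = np.asarray(order)
        return RegionStats(
            rsids=tuple(self.rsids[i] for i in idx),
            beta1=self.beta1[idx],
            se1=self.se1[idx],
            beta2=self.beta2[idx],
            se2=self.se2[idx],
            trait1_type=self.trait1_type,
            trait2_type=self.trait2_type,
        )


@dataclass(frozen=True)
class ColocResult:
    """Posterior probabilities of the five hypotheses plus per-SNP log-ABFs."""

    pp0: float
    pp1: float
    pp2: float
    pp3: float
    pp4: float
    labf1: np.ndarray
    labf2: np.ndarray

    @property
    def posteriors(self) -> np.ndarray:
        return np.array([self.pp0, self.pp1, self.pp2, self.pp3, self.pp4])

    def per_snp_pp4(self) -> np.ndarray:
        """Posterior weight of each SNP within the shared-variant hypothesis."""
        joint = self.labf1 + self.labf2
        return np.exp(joint - logsumexp(joint))


@dataclass(frozen=True)
class LdCheck:
    """Outcome of the distinct-signal (confounding-by-LD) screen."""

    flagged: bool
    result: ColocResult


def wakefield_abf(beta: float, se: float, prior_sd: float) -> float:
    """Log approximate Bayes factor for association of one SNP with one trait.

    The ABF compares a normal effect prior N(0, prior_sd²) against the point
    null; it depends on the data only through z = beta/se and V = se².
    """
    if se <= 0:
        raise DomainError(f"se must be > 0, got {se}")
    if prior_sd <= 0:
        raise DomainError(f"prior_sd must be > 0, got {prior_sd}")
    v = se * se
    w = prior_sd * prior_sd
    r = w / (w + v)
    z = beta / se
    return 0.5 * (math.log1p(-r) + r * z * z)


def _labf_vector(beta: np.ndarray, se: np.ndarray, prior_sd: float) -> np.ndarray:
    v = se**2
    w = prior_sd**2
    r = w / (w + v)
    z2 = (beta / se) ** 2
    return 0.5 * (np.log1p(-r) + r * z2)


def _prior_sd_for(trait_type: str) -> float:
    return PRIOR_SD_BINARY if trait_type == "binary" else PRIOR_SD_QUANTITATIVE


def coloc_abf(
    region: RegionStats,
    p1: float = DEFAULT_P1,
    p2: float = DEFAULT_P2,
    p12: float = DEFAULT_P12,
    prior_sd1: float | None = None,
    prior_sd2: float | None = None,
) -> ColocResult:
    """Posterior probabilities PP0–PP4 for a region under the one-causal-
    variant-per-trait model.

    Priors are per configuration: each SNP is the sole trait-1 (trait-2)
    causal variant with prior p1 (p2), each ordered pair of distinct SNPs has
    prior p1·p2, and each SNP is the shared variant with prior p12.  Prior
    effect SDs default to 0.15 (quantitative) / 0.2 (binary) per trait type.
    """
    if min(p1, p2, p12) <= 0:
        raise DomainError("priors must be positive")
    if p1 + p2 + p12 >= 1:
        raise DomainError("priors must sum to well below 1")
    l1 = _labf_vector(region.beta1, region.se1, prior_sd1 or _prior_sd_for(region.trait1_type))
    l2 = _labf_vector(region.beta2, region.se2, prior_sd2 or _prior_sd_for(region.trait2_type))

    log_l1 = float(logsumexp(l1))
    log_l2 = float(logsumexp(l2))
    log_l4 = float(logsumexp(l1 + l2))
    # H3 sums over ordered pairs i != j: total cross-sum minus the diagonal.
    if len(region) > 1:
        diff = log_l4 - (log_l1 + log_l2)  # <= 0 by positivity of the terms
        if math.exp(diff) < 1.0:
            log_l3 = log_l1 + log_l2 + math.log1p(-math.exp(diff))
        else:
            # One SNP dominates both traits so the subtraction cancels;
            # fall back to the explicit off-diagonal pairwise sum.
            cross = l1[:, None] + l2[None, :]
            np.fill_diagonal(cross, -np.inf)
            log_l3 = float(logsumexp(cross))
    else:
        log_l3 = -math.inf

    log_post = np.array(
        [
            0.0,
            math.log(p1) + log_l1,
            math.log(p2) + log_l2,
            math.log(p1) + math.log(p2) + log_l3,
            math.log(p12) + log_l4,
        ]
    )
    pp = np.exp(log_post - logsumexp(log_post))
    pp /= pp.sum()
    return ColocResult(*pp, labf1=l1, labf2=l2)


def confounding_by_ld_check(
    region: RegionStats,
    instrument_rsid: str,
    pp4_threshold: float = 0.5,
    **coloc_kwargs,
) -> LdCheck:
    """Screen an instrument's region for distinct exposure/outcome signals.

    The instrument is flagged when the posterior favours two distinct causal
    variants over a shared one (PP3 > PP4) — the numeric analogue of
    inspecting colocalization plots for a separate outcome signal in LD with
    the instrument.  When PP4 ≥ ``pp4_threshold`` the shared-signal evidence
    is taken as conclusive and the instrument is never flagged (with the
    default 0.5 this is equivalent to the bare PP3 > PP4 rule, since the
    posteriors sum to one).
    """
    if instrument_rsid not in region.rsids:
        raise ValidationError(f"instrument {instrument_rsid} absent from region")
    result = coloc_abf(region, **coloc_kwargs)
    flagged = result.pp4 < pp4_threshold and result.pp3 > result.pp4
    return LdCheck(flagged=flagged, result=result)


def read_region(path: str | Path) -> RegionStats:
    """Read a two-trait region table (rsid, beta1, se1, beta2, se2 [, types])."""
    frame = pd.read_csv(path, sep=None, engine="python")
    required = {"rsid", "beta1", "se1", "beta2", "se2"}
    missing = required - set(frame.columns)
    if missing:
        raise ValidationError(f"{path}: missing region columns {sorted(missing)}")
    return RegionStats(
        rsids=tuple(frame["rsid"].astype(str)),
        beta1=frame["beta1"].to_numpy(float),
        se1=frame["se1"].to_numpy(float),
        beta2=frame["beta2"].to_numpy(float),
        se2=frame["se2"].to_numpy(float),
    )


def region_to_frame(region: RegionStats, result: ColocResult | None = None) -> pd.DataFrame:
    """Per-SNP export (optionally with log-ABFs) for plotting."""
    data = {
        "rsid": region.rsids,
        "beta1": region.beta1,
        "se1": region.se1,
        "beta2": region.beta2,
        "se2": region.se2,
    }
    if result is not None:
        data["labf1"] = result.labf1
        data["labf2"] = result.labf2
        data["pp4_conditional"] = result.per_snp_pp4()
    return pd.DataFrame(data)
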