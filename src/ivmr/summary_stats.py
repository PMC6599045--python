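"""GWAS summary-statistic records, file I/O, effect-scale conversions, and
allele harmonization.

The atomic unit is :class:`SnpAssociation` — one SNP's association with one
trait, with the effect expressed per copy of the effect allele on either the
standard-deviation scale (quantitative traits) or the log-odds scale (binary
traits).  Two-sample Mendelian randomization pairs an exposure record with an
outcome record for the same SNP; :func:`harmonize` aligns the pair to a common
effect allele and orients it to the exposure-increasing allele.

Binary-trait GWAS are often published as odds ratios with 95% confidence
intervals rather than log-odds and standard errors; :func:`or_ci_to_logor`
and :func:`logor_to_or_ci` convert between the two conventions.  Because a
CI printed to two decimals carries ~1% relative rounding error into the
reconstructed SE, estimates recomputed from published tables can differ from
the originals in the last printed digit.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    ConfigurationError,
    DomainError,
    FrequencyRequiredError,
    HarmonizationError,
    InconsistencyError,
    ValidationError,
)

__all__ = [
    "SnpAssociation",
    "HarmonizedInstrument",
    "StudyMeta",
    "or_ci_to_logor",
    "logor_to_or_ci",
    "harmonize",
    "variance_explained",
    "read_sumstats",
    "write_sumstats",
    "se_from_beta_pvalue",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_ALLELES = frozenset(_COMPLEMENT)

TraitType = Literal["quantitative", "binary"]


def _norm_quantile(level: float) -> float:
    """Two-sided standard-normal quantile for a confidence level (1.959964 at 95%)."""
    if not 0.0 < level < 1.0:
        raise DomainError(f"confidence level must be in (0,1), got {level}")
    return float(stats.norm.ppf(0.5 + level / 2.0))


@dataclass(frozen=True)
class SnpAssociation:
    """One SNP's summary association with one trait.

    ``beta`` is the effect per effect-allele copy: SD units for
    ``trait_type='quantitative'``, log-odds for ``'binary'``.
    """

    rsid: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pvalue: float
    chrom: str | None = None
    eaf: float | None = None
    n: int | None = None
    trait: str = ""
    trait_type: TraitType = "quantitative"

    def __post_init__(self) -> None:
        problems = []
        if self.effect_allele not in _ALLELES:
            problems.append(f"effect_allele {self.effect_allele!r} not in A/C/G/T")
        if self.other_allele not in _ALLELES:
            problems.append(f"other_allele {self.other_allele!r} not in A/C/G/T")
        if self.effect_allele == self.other_allele:
            problems.append("effect_allele equals other_allele")
        if not self.se > 0:
            problems.append(f"se must be > 0, got {self.se}")
        if not 0.0 < self.pvalue <= 1.0:
            problems.append(f"pvalue must be in (0,1], got {self.pvalue}")
        if self.eaf is not None and not 0.0 <= self.eaf <= 1.0:
            problems.append(f"eaf must be in [0,1], got {self.eaf}")
        if self.trait_type not in ("quantitative", "binary"):
            problems.append(f"unknown trait_type {self.trait_type!r}")
        if problems:
            raise ValidationError(f"{self.rsid}: " + "; ".join(problems))

    @property
    def alleles(self) -> frozenset[str]:
        return frozenset((self.effect_allele, self.other_allele))

    def is_palindromic(self) -> bool:
        """A/T or G/C SNPs cannot be strand-resolved from alleles alone."""
        return self.other_allele == _COMPLEMENT[self.effect_allele]

    def flipped(self) -> "SnpAssociation":
        """The same association expressed for the other allele."""
        return replace(
            self,
            effect_allele=self.other_allele,
            other_allele=self.effect_allele,
            beta=-self.beta,
            eaf=None if self.eaf is None else 1.0 - self.eaf,
        )

    def strand_complemented(self) -> "SnpAssociation":
        """The same association reported on the opposite strand."""
        return replace(
            self,
            effect_allele=_COMPLEMENT[self.effect_allele],
            other_allele=_COMPLEMENT[self.other_allele],
        )


@dataclass(frozen=True)
class HarmonizedInstrument:
    """An exposure/outcome pair aligned to the same effect allele.

    After harmonization both records share an effect allele and the exposure
    effect is non-negative, i.e. the pair is oriented to the
    exposure-increasing allele.  ``action_taken`` records the decisive step;
    ``dropped_palindromic`` marks pairs that must be excluded because strand
    could not be resolved.
    """

    exposure: SnpAssociation
    outcome: SnpAssociation
    action_taken: Literal["none", "sign_flip", "strand_flip", "dropped_palindromic"]

    def __post_init__(self) -> None:
        if self.exposure.rsid != self.outcome.rsid:
            raise ValidationError(
                f"rsid mismatch: {self.exposure.rsid} vs {self.outcome.rsid}"
            )
        if self.action_taken != "dropped_palindromic":
            if self.exposure.effect_allele != self.outcome.effect_allele:
                raise ValidationError(
                    f"{self.exposure.rsid}: effect alleles differ after harmonization"
                )
            if self.exposure.beta < 0:
                raise ValidationError(
                    f"{self.exposure.rsid}: exposure beta must be oriented >= 0"
                )

    @property
    def dropped(self) -> bool:
        return self.action_taken == "dropped_palindromic"


@dataclass(frozen=True)
class StudyMeta:
    """Descriptive metadata for one GWAS (used for power calculations/reports)."""

    label: str
    n_cases: int = 0
    n_controls: int = 0
    ancestry: str = ""

    def __post_init__(self) -> None:
        if self.n_cases < 0 or self.n_controls < 0:
            raise ValidationError("n_cases and n_controls must be >= 0")


def or_ci_to_logor(
    or_point: float, ci_low: float, ci_high: float, level: float = 0.95
) -> tuple[float, float]:
    """Convert an odds ratio with a symmetric-on-log-scale CI to (log-odds, SE).

    The SE is reconstructed as ``(ln ci_high - ln ci_low) / (2 z)`` with ``z``
    the two-sided normal quantile at ``level``.
    """
    if min(or_point, ci_low, ci_high) <= 0:
        raise DomainError("odds ratios and CI bounds must be positive")
    if not ci_low <= or_point <= ci_high:
        raise InconsistencyError(
            f"point estimate {or_point} outside CI [{ci_low}, {ci_high}]"
        )
    z = _norm_quantile(level)
    logor = math.log(or_point)
    se = (math.log(ci_high) - math.log(ci_low)) / (2.0 * z)
    return logor, se


def logor_to_or_ci(
    logor: float, se: float, level: float = 0.95
) -> tuple[float, float, float]:
    """Exponentiate a log-odds estimate and its normal CI to the OR scale."""
    if se < 0:
        raise DomainError(f"se must be >= 0, got {se}")
    z = _norm_quantile(level)
    return (
        math.exp(logor),
        math.exp(logor - z * se),
        math.exp(logor + z * se),
    )


def se_from_beta_pvalue(beta: float, pvalue: float) -> float:
    """Reconstruct an SE from an estimate and its two-sided normal p-value.

    Used when a source table prints the effect and p but not the SE.
    """
    if not 0.0 < pvalue < 1.0:
        raise DomainError(f"pvalue must be in (0,1), got {pvalue}")
    if beta == 0:
        raise DomainError("cannot reconstruct an SE for a zero effect")
    z = float(stats.norm.isf(pvalue / 2.0))
    return abs(beta) / z


def variance_explained(eaf: float, beta: float) -> float:
    """Variance of a standardized trait explained by one SNP: 2p(1-p)β².

    ``beta`` must be on the SD scale.  Summed over independent instruments this
    is the R² that the power module takes as instrument strength.  Frequency is
    required: a missing ``eaf`` cannot be guessed.
    """
    if eaf is None:
        raise FrequencyRequiredError("variance_explained needs an effect-allele frequency")
    if not 0.0 <= eaf <= 1.0:
        raise DomainError(f"eaf must be in [0,1], got {eaf}")
    return 2.0 * eaf * (1.0 - eaf) * beta * beta


def _orient_to_exposure_increasing(
    exposure: SnpAssociation, outcome: SnpAssociation
) -> tuple[SnpAssociation, SnpAssociation]:
    if exposure.beta < 0:
        return exposure.flipped(), outcome.flipped()
    return exposure, outcome


def harmonize(
    exposure: SnpAssociation,
    outcome: SnpAssociation,
    palindrome_eaf_window: float = 0.08,
) -> HarmonizedInstrument:
    """Align an exposure/outcome pair to a shared, exposure-increasing allele.

    Resolution order:

    1. palindromic SNPs (A/T or G/C) with either trait's EAF within
       ``palindrome_eaf_window`` of 0.5 are returned as ``dropped_palindromic``
       (strand is unresolvable near 0.5); otherwise their strand is inferred
       from EAF concordance;
    2. outcome alleles identical to the exposure's → no action;
    3. outcome alleles swapped → outcome beta sign-flipped;
    4. outcome alleles on the opposite strand → complemented (and sign-flipped
       if also swapped);
    5. finally, both records are flipped together if needed so that
       ``exposure.beta >= 0``.
    """
    if exposure.rsid != outcome.rsid:
        raise ValidationError(
            f"rsid mismatch: {exposure.rsid} vs {outcome.rsid}"
        )

    if exposure.is_palindromic():
        if not outcome.is_palindromic() or exposure.alleles != outcome.alleles:
            raise HarmonizationError(
                f"{exposure.rsid}: outcome alleles {sorted(outcome.alleles)} do not "
                f"match palindromic exposure {sorted(exposure.alleles)}"
            )
        if exposure.eaf is None or outcome.eaf is None:
            raise FrequencyRequiredError(
                f"{exposure.rsid}: palindromic SNP needs EAF in both studies"
            )
        near_half = any(
            abs(f - 0.5) <= palindrome_eaf_window
            for f in (exposure.eaf, outcome.eaf)
        )
        if near_half:
            return HarmonizedInstrument(exposure, outcome, "dropped_palindromic")
        # Strand inferred from frequency: the reported labels denote the same
        # physical allele iff the two EAFs fall on the same side of 0.5.
        same_side = (exposure.eaf - 0.5) * (outcome.eaf - 0.5) > 0
        if outcome.effect_allele == exposure.effect_allele:
            if same_side:
                out, action = outcome, "none"
            else:
                # Same label, discordant frequency: label is on the opposite
                # strand, i.e. physically the other allele.
                out, action = outcome.strand_complemented().flipped(), "sign_flip"
        else:
            if same_side:
                # Swapped label, concordant frequency: a strand artefact only.
                out, action = outcome.strand_complemented(), "strand_flip"
            else:
                out, action = outcome.flipped(), "sign_flip"
        exposure, out = _orient_to_exposure_increasing(exposure, out)
        return HarmonizedInstrument(exposure, out, action)

    candidates = [
        (outcome, "none"),
        (outcome.flipped(), "sign_flip"),
        (outcome.strand_complemented(), "strand_flip"),
        (outcome.strand_complemented().flipped(), "sign_flip"),
    ]
    for cand, action in candidates:
        if (
            cand.effect_allele == exposure.effect_allele
            and cand.other_allele == exposure.other_allele
        ):
            exposure, cand = _orient_to_exposure_increasing(exposure, cand)
            return HarmonizedInstrument(exposure, cand, action)

    raise HarmonizationError(
        f"{exposure.rsid}: alleles {exposure.effect_allele}/{exposure.other_allele} vs "
        f"{outcome.effect_allele}/{outcome.other_allele} are irreconcilable"
    )


# ---------------------------------------------------------------------------
# File I/O

#: Canonical column-map keys.  A column map is {concept: file column name}.
#: ``beta``/``se`` columns are used directly; when ``or``/``ci_low``/``ci_high``
#: are mapped instead, the record is converted with or_ci_to_logor.
_KNOWN_KEYS = {
    "rsid", "chrom", "effect_allele", "other_allele", "eaf",
    "beta", "se", "or", "ci_low", "ci_high", "pvalue", "n",
}

DEFAULT_COLUMN_MAP: dict[str, str] = {
    "rsid": "rsid",
    "chrom": "chrom",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "eaf": "eaf",
    "beta": "beta",
    "se": "se",
    "pvalue": "pvalue",
    "n": "n",
}


def _read_table(path: str | Path) -> pd.DataFrame:
    """Read a header-labeled TSV/CSV, auto-detecting the delimiter."""
    path = Path(path)
    with open(path, "r", newline="") as fh:
        sample = fh.read(4096)
    if not sample.strip():
        raise ConfigurationError(f"{path}: file is empty (no header row)")
    try:
        dialect = csv.Sniffer().sniff(sample.splitlines()[0], delimiters="\t,")
        sep = dialect.delimiter
    except csv.Error:
        sep = "\t"
    return pd.read_csv(path, sep=sep, dtype=str, skip_blank_lines=True)


def read_sumstats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    trait_type: TraitType = "quantitative",
    trait: str = "",
    level: float = 0.95,
) -> list[SnpAssociation]:
    """Parse a summary-statistics table into validated :class:`SnpAssociation`.

    ``column_map`` maps canonical keys (``rsid``, ``effect_allele``,
    ``other_allele``, ``beta``, ``se``, ``or``, ``ci_low``, ``ci_high``,
    ``pvalue``, ``eaf``, ``chrom``, ``n``) to the file's column names.  Mapping
    ``or``/``ci_low``/``ci_high`` declares odds-ratio scale; the reader then
    converts to log-odds with a ``level`` CI.  Malformed rows are reported with
    their line numbers, all at once.
    """
    column_map = dict(column_map or DEFAULT_COLUMN_MAP)
    unknown = set(column_map) - _KNOWN_KEYS
    if unknown:
        raise ConfigurationError(f"unknown column-map keys: {sorted(unknown)}")
    or_scale = "or" in column_map
    if or_scale and not {"ci_low", "ci_high"} <= set(column_map):
        raise ConfigurationError("odds-ratio input needs 'or', 'ci_low' and 'ci_high'")
    required = {"rsid", "effect_allele", "other_allele", "pvalue"}
    required |= {"or"} if or_scale else {"beta", "se"}
    missing_keys = required - set(column_map)
    if missing_keys:
        raise ConfigurationError(f"column map lacks required keys: {sorted(missing_keys)}")

    frame = _read_table(path)
    missing_cols = [c for k, c in column_map.items() if c not in frame.columns and k in required]
    if missing_cols:
        raise ConfigurationError(f"{path}: mapped columns absent from header: {missing_cols}")

    def get(row: pd.Series, key: str) -> str | None:
        col = column_map.get(key)
        if col is None or col not in row.index:
            return None
        val = row[col]
        if pd.isna(val) or str(val).strip() in ("", "NA", "nan", "."):
            return None
        return str(val).strip()

    records: list[SnpAssociation] = []
    errors: list[str] = []
    for i, (_, row) in enumerate(frame.iterrows()):
        lineno = i + 2  # header is line 1
        try:
            if or_scale:
                or_point = float(get(row, "or"))
                ci_low = float(get(row, "ci_low"))
                ci_high = float(get(row, "ci_high"))
                beta, se = or_ci_to_logor(or_point, ci_low, ci_high, level)
                if se == 0.0:
                    raise ValidationError("degenerate CI gives se = 0")
            else:
                beta = float(get(row, "beta"))
                se = float(get(row, "se"))
            eaf = get(row, "eaf")
            n = get(row, "n")
            records.append(
                SnpAssociation(
                    rsid=get(row, "rsid"),
                    chrom=get(row, "chrom"),
                    effect_allele=(get(row, "effect_allele") or "").upper(),
                    other_allele=(get(row, "other_allele") or "").upper(),
                    eaf=None if eaf is None else float(eaf),
                    beta=beta,
                    se=se,
                    pvalue=float(get(row, "pvalue")),
                    n=None if n is None else int(float(n)),
                    trait=trait,
                    trait_type=trait_type,
                )
            )
        except (ValidationError, DomainError, InconsistencyError, TypeError, ValueError) as exc:
            errors.append(f"line {lineno}: {exc}")
    if errors:
        raise ValidationError(f"{path}: " + " | ".join(errors))
    return records


def write_sumstats(records: Iterable[SnpAssociation], path: str | Path) -> None:
    """Write records in the canonical tab-separated dialect the reader consumes."""
    rows = [
        {
            "rsid": r.rsid,
            "chrom": r.chrom if r.chrom is not None else "NA",
            "effect_allele": r.effect_allele,
            "other_allele": r.other_allele,
            "eaf": "NA" if r.eaf is None else repr(r.eaf),
            "beta": repr(r.beta),
            "se": repr(r.se),
            "pvalue": repr(r.pvalue),
            "n": "NA" if r.n is None else r.n,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
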