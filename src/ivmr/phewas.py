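"""Phenome-wide MR scan: one instrument set against a catalogue of outcomes.

Each outcome in the catalogue gets an independent IVW MR fit with the shared
exposure instruments; family-wise error over the scan is controlled by a
Bonferroni threshold α/m.  By default m counts *catalogue* outcomes, not
successful fits — an outcome skipped for lack of instrument overlap still
inflates the denominator (conservative, and matching the convention of
dividing the family-wise level by the number of outcomes attempted).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping, Sequence

import pandas as pd

from .exceptions import DomainError, EmptyIntersectionError, IvmrError
from .mr import IvwResult, MrConfig, mr_analysis
from .summary_stats import SnpAssociation, read_sumstats

__all__ = [
    "OutcomeCatalogue",
    "PhewasRow",
    "bonferroni_threshold",
    "phewas_scan",
    "scan_frame",
]


@dataclass(frozen=True)
class OutcomeCatalogue:
    """Uniquely labelled outcome summary statistics, instrument SNPs only."""

    outcomes: tuple[tuple[str, tuple[SnpAssociation, ...]], ...]

    def __post_init__(self) -> None:
        labels = [label for label, _ in self.outcomes]
        if len(set(labels)) != len(labels):
            raise DomainError("outcome labels must be unique")

    def __len__(self) -> int:
        return len(self.outcomes)

    @classmethod
    def from_mapping(
        cls, mapping: Mapping[str, Sequence[SnpAssociation]]
    ) -> "OutcomeCatalogue":
        return cls(tuple((k, tuple(v)) for k, v in mapping.items()))

    @classmethod
    def read_long_tsv(
        cls, path: str | Path, column_map=None, outcome_column: str = "outcome"
    ) -> "OutcomeCatalogue":
        """Single long-format table with an outcome-label column."""
        frame = pd.read_csv(path, sep=None, engine="python")
        if outcome_column not in frame.columns:
            raise DomainError(f"{path}: no {outcome_column!r} column")
        entries = {}
        import tempfile, os

        for label, sub in frame.groupby(outcome_column, sort=False):
            with tempfile.NamedTemporaryFile(
                "w", suffix=".tsv", delete=False
            ) as tmp:
                sub.drop(columns=[outcome_column]).to_csv(tmp, sep="\t", index=False)
                tmp_path = tmp.name
            try:
                entries[str(label)] = read_sumstats(
                    tmp_path, column_map, trait_type="binary", trait=str(label)
                )
            finally:
                os.unlink(tmp_path)
        return cls.from_mapping(entries)

    @classmethod
    def read_directory(
        cls, directory: str | Path, column_map=None, pattern: str = "*.tsv"
    ) -> "OutcomeCatalogue":
        """One file per outcome; the stem is the outcome label."""
        entries = {}
        for path in sorted(Path(directory).glob(pattern)):
            entries[path.stem] = read_sumstats(
                path, column_map, trait_type="binary", trait=path.stem
            )
        if not entries:
            raise DomainError(f"no {pattern} files under {directory}")
        return cls.from_mapping(entries)


@dataclass(frozen=True)
class PhewasRow:
    """One outcome's scan result.  ``result`` is None when skipped."""

    outcome: str
    result: IvwResult | None
    bonferroni_alpha: float
    significant: bool
    skipped: bool = False
    reason: str = ""

    def __post_init__(self) -> None:
        if self.result is None:
            if self.significant:
                raise DomainError(f"{self.outcome}: a skipped row cannot be significant")
        elif self.significant != (self.result.pvalue < self.bonferroni_alpha):
            raise DomainError(f"{self.outcome}: significance flag inconsistent with p")


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise level α split over m tests: α/m."""
    if m < 1:
        raise DomainError(f"m must be >= 1, got {m}")
    if not 0.0 < alpha < 1.0:
        raise DomainError(f"alpha must be in (0,1), got {alpha}")
    return alpha / m


def phewas_scan(
    exposure_stats: Sequence[SnpAssociation],
    catalogue: OutcomeCatalogue,
    alpha: float = 0.05,
    config: MrConfig | None = None,
    denominator: Literal["catalogue", "tested"] = "catalogue",
) -> list[PhewasRow]:
    """IVW MR of the instrument set against every catalogued outcome.

    Rows are sorted by p-value, skipped outcomes (no instrument overlap or a
    failed fit) last with their reason.  The Bonferroni denominator is the
    catalogue size by default; ``denominator="tested"`` divides by the number
    of successful fits instead.
    """
    if len(catalogue) == 0:
        raise DomainError("catalogue is empty")
    fits: list[tuple[str, IvwResult | None, str]] = []
    for label, outcome_stats in catalogue.outcomes:
        try:
            _, pooled = mr_analysis(exposure_stats, list(outcome_stats), config)
            fits.append((label, pooled, ""))
        except (EmptyIntersectionError, IvmrError) as exc:
            fits.append((label, None, str(exc)))

    m = len(catalogue) if denominator == "catalogue" else max(
        1, sum(1 for _, r, _ in fits if r is not None)
    )
    threshold = bonferroni_threshold(alpha, m)
    rows = [
        PhewasRow(
            outcome=label,
            result=res,
            bonferroni_alpha=threshold,
            significant=res is not None and res.pvalue < threshold,
            skipped=res is None,
            reason=reason,
        )
        for label, res, reason in fits
    ]
    rows.sort(key=lambda r: (r.skipped, r.result.pvalue if r.result else 1.0))
    return rows


def scan_frame(rows: Sequence[PhewasRow]) -> pd.DataFrame:
    """Report table: outcome, OR, CI, p, significance (skips marked)."""
    records = []
    for r in rows:
        if r.result is None:
            records.append(
                {
                    "outcome": r.outcome,
                    "or": float("nan"),
                    "ci_low": float("nan"),
                    "ci_high": float("nan"),
                    "pvalue": float("nan"),
                    "k": 0,
                    "significant": False,
                    "skipped": True,
                    "reason": r.reason,
                }
            )
        else:
            records.append(
                {
                    "outcome": r.outcome,
                    "or": r.result.or_point,
                    "ci_low": r.result.ci_low,
                    "ci_high": r.result.ci_high,
                    "pvalue": r.result.pvalue,
                    "k": r.result.k,
                    "significant": r.significant,
                    "skipped": False,
                    "reason": "",
                }
            )
    return pd.DataFrame(records)
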