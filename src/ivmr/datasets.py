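"""Packaged example data: the IL18 → IBD instrument set.

Three independent SNPs are genome-wide significant for circulating IL18 in a
cytokine GWAS of 3,636 Finnish individuals — rs385076 (*NLRC4*), rs17229943
(*OCLN*) and rs71478720 (*IL18*) — and their effects on inflammatory bowel
disease come from the International IBD Genetics Consortium GWAS (12,882
cases, 21,770 controls).  The packaged tables carry exactly the published
per-SNP numbers: SD-scale IL18 effects with p-values, and IBD odds ratios
with 95% CIs.

Two reconstructions are applied on load, both standard when working from
published tables:

* IBD log-odds and SEs are recovered from the printed OR and 95% CI
  (``or_ci_to_logor``); 2-d.p. CIs carry ~1% relative rounding error into
  the SE, so downstream estimates can differ from the originals in the last
  printed digit.
* IL18 SEs are recovered from beta and p (``se_from_beta_pvalue``), since the
  source table prints no SE.

The published table does not state the non-effect allele; the fixture fills
in ``T`` as a synthetic placeholder (non-palindromic with every effect allele
``C``, so harmonization is unaffected and no estimate depends on it).
"""

from __future__ import annotations

from dataclasses import replace
from importlib import resources

from .summary_stats import (
    SnpAssociation,
    StudyMeta,
    read_sumstats,
    se_from_beta_pvalue,
)

__all__ = [
    "load_il18_instruments",
    "load_ibd_outcomes",
    "IL18_STUDY_N",
    "IBD_STUDY",
    "IBD_REPLICATION_STUDY",
]

#: Sample size of the cytokine (IL18) discovery GWAS.
IL18_STUDY_N = 3636

#: Case/control counts of the IBD discovery GWAS.
IBD_STUDY = StudyMeta("IIBDGC IBD", n_cases=12_882, n_controls=21_770, ancestry="European")

#: Case/control counts of the IBD replication meta-analysis.
IBD_REPLICATION_STUDY = StudyMeta(
    "IBD replication meta-analysis", n_cases=25_042, n_controls=34_915, ancestry="European"
)

_OUTCOME_MAP = {
    "rsid": "rsid",
    "chrom": "chrom",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "eaf": "eaf",
    "or": "or",
    "ci_low": "ci_low",
    "ci_high": "ci_high",
    "pvalue": "pvalue",
}


def _data_path(name: str):
    return resources.files("ivmr.data").joinpath(name)


def load_il18_instruments() -> list[SnpAssociation]:
    """The three IL18 instruments, SD-scale betas, SEs reconstructed from p."""
    with resources.as_file(_data_path("il18_cytokine_gwas.tsv")) as path:
        import pandas as pd

        frame = pd.read_csv(path, sep="\t")
    records = []
    for _, row in frame.iterrows():
        se = se_from_beta_pvalue(float(row["beta"]), float(row["pvalue"]))
        records.append(
            SnpAssociation(
                rsid=row["rsid"],
                chrom=str(row["chrom"]),
                effect_allele=row["effect_allele"],
                other_allele=row["other_allele"],
                eaf=float(row["eaf"]),
                beta=float(row["beta"]),
                se=se,
                pvalue=float(row["pvalue"]),
                n=IL18_STUDY_N,
                trait="IL18",
                trait_type="quantitative",
            )
        )
    return records


def load_ibd_outcomes() -> list[SnpAssociation]:
    """IBD associations of the three instruments, log-odds scale from OR/CI."""
    with resources.as_file(_data_path("ibd_iibdgc_gwas.tsv")) as path:
        records = read_sumstats(
            path, _OUTCOME_MAP, trait_type="binary", trait="IBD"
        )
    n = IBD_STUDY.n_cases + IBD_STUDY.n_controls
    return [replace(r, n=n) for r in records]
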