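"""Co-occurrence of rare qualifying variants with the risk-SNP allele.

For each candidate gene and its associated risk SNP, this scan asks whether
rare qualifying variants in the gene sit preferentially on the risk-allele
side of the SNP, separately within cases and within controls. Risk-allele
carriage is coded dominantly by default (dosage >= 1), with an additive
allele-count option; each stratum gives a 2x2 table (risk-allele carrier x
rare-variant carrier) tested with the two-sided Fisher exact test, and
family-wise significance is controlled by Bonferroni across every test the
scan emits. Raw p values are always reported alongside the adjusted call —
the adjustment procedure is a labelled reconstruction, recorded in the scan
metadata, not a published algorithm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .burden import CarrierMatrix
from .classify import classify_variant
from .exact import fisher_two_sided_p
from .types import (
    Cohort,
    CohortDataset,
    ConsequenceClass,
    ContingencyTable2x2,
    InteractionRow,
    SnpDosageRecord,
    ValidationError,
)

logger = logging.getLogger(__name__)


@dataclass
class InteractionConfig:
    allele_coding: str = "dominant"  # "dominant" (dosage >= 1) or "allele-count"
    classes: tuple = (ConsequenceClass.LOF, ConsequenceClass.MISSENSE)
    alpha: float = 0.05
    maf_threshold: float = 0.001

    def __post_init__(self) -> None:
        if self.allele_coding not in ("dominant", "allele-count"):
            raise ValidationError(f"unknown allele coding {self.allele_coding!r}")


def _dosage_map(dosages: Iterable[SnpDosageRecord]) -> dict:
    out: dict[tuple[str, str], int] = {}
    for d in dosages:
        key = (d.subject_id, d.snp_id)
        if key in out:
            raise ValidationError(f"duplicate dosage record for {key}")
        out[key] = d.risk_allele_count
    return out


def _stratum_table(
    dataset: CohortDataset,
    matrix: CarrierMatrix,
    dosage: dict,
    gene: str,
    snp_id: str,
    cls,
    stratum: Cohort,
    coding: str,
) -> tuple[ContingencyTable2x2, int]:
    classes = (
        (ConsequenceClass.LOF, ConsequenceClass.MISSENSE)
        if cls == "COMBINED"
        else (cls,)
    )
    rare_carriers = matrix.carrier_subjects({gene}, classes)
    a = b = c_cell = d_cell = 0
    excluded = 0
    for s in dataset.subjects:
        if s.cohort is not stratum:
            continue
        dose = dosage.get((s.subject_id, snp_id))
        if dose is None:
            excluded += 1
            continue
        rare = s.subject_id in rare_carriers
        if coding == "dominant":
            # rows: risk-allele carrier (dosage >= 1) vs non-carrier subjects
            if dose >= 1:
                a += rare
                b += not rare
            else:
                c_cell += rare
                d_cell += not rare
        else:
            # allele-count coding: rows are risk vs alternate allele counts
            if rare:
                a += dose
                c_cell += 2 - dose
            else:
                b += dose
                d_cell += 2 - dose
    return ContingencyTable2x2(a, b, c_cell, d_cell), excluded


def rare_by_allele_table(
    dataset: CohortDataset,
    dosages: Sequence[SnpDosageRecord],
    gene: str,
    cls,
    stratum: Cohort,
    snp_id: Optional[str] = None,
    config: Optional[InteractionConfig] = None,
) -> ContingencyTable2x2:
    """2x2 table of risk-allele carriage vs rare-variant carriage.

    Rows: risk-allele carriers (dosage >= 1) vs non-carriers; columns:
    rare qualifying variant carriers in the gene/class vs non-carriers,
    restricted to the requested cohort stratum. Subjects without a dosage
    record for the SNP are excluded and logged.
    """
    config = config or InteractionConfig()
    gene_rec = next((g for g in dataset.manifest if g.symbol == gene), None)
    if gene_rec is None:
        raise ValidationError(f"gene {gene!r} not in manifest")
    if not gene_rec.snp_ids:
        raise ValidationError(f"gene {gene!r} has no associated SNP")
    snp_id = snp_id or gene_rec.snp_ids[0]
    classified = [classify_variant(v, config.maf_threshold) for v in dataset.variants]
    matrix = CarrierMatrix(classified, dataset.subjects)
    table, excluded = _stratum_table(
        dataset, matrix, _dosage_map(dosages), gene, snp_id, cls, stratum,
        config.allele_coding,
    )
    if excluded:
        logger.info(
            "stage=interaction gene=%s snp=%s stratum=%s excluded_no_dosage=%d",
            gene, snp_id, stratum.value, excluded,
        )
    return table


def interaction_scan(
    dataset: CohortDataset,
    dosages: Sequence[SnpDosageRecord],
    config: Optional[InteractionConfig] = None,
) -> list[InteractionRow]:
    """One Fisher test per (gene, SNP) x stratum x class, Bonferroni-adjusted.

    Rows are ordered by gene symbol, SNP, stratum, class; the Bonferroni
    factor is the number of emitted tests.
    """
    config = config or InteractionConfig()
    if not dosages:
        raise ValidationError("empty dosage input")
    dosage = _dosage_map(dosages)
    classified = [classify_variant(v, config.maf_threshold) for v in dataset.variants]
    matrix = CarrierMatrix(classified, dataset.subjects)

    jobs = []
    for gene in sorted(dataset.manifest, key=lambda g: g.symbol):
        for snp_id in gene.snp_ids:
            for stratum in (Cohort.CASE, Cohort.CONTROL):
                for cls in config.classes:
                    jobs.append((gene.symbol, snp_id, stratum, cls))

    results = []
    for gene, snp_id, stratum, cls in jobs:
        table, excluded = _stratum_table(
            dataset, matrix, dosage, gene, snp_id, cls, stratum, config.allele_coding
        )
        results.append((gene, snp_id, stratum, cls, table, excluded, fisher_two_sided_p(table)))

    m = len(results)
    rows = [
        InteractionRow(
            gene=gene,
            snp_id=snp_id,
            stratum=stratum,
            consequence_class=cls.value if isinstance(cls, ConsequenceClass) else str(cls),
            table=table,
            p=p,
            adjusted_significant=min(1.0, p * m) <= config.alpha,
            n_excluded=excluded,
        )
        for gene, snp_id, stratum, cls, table, excluded, p in results
    ]
    logger.info("stage=interaction_scan tests=%d bonferroni_factor=%d", m, m)
    return rows
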