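"""Subject-level carrier collapsing and burden comparisons.

Carriers, not variants, are the unit of analysis: a subject with one or
more qualifying variants (QC-passing, rare) of a consequence class in a
gene counts exactly once for that gene and class, and once for any gene
set containing the gene. Every 2x2 comparison uses the full cohort sizes
as denominators regardless of per-gene coverage. Per-gene comparisons and
LoF aggregates use the two-sided Fisher exact test; missense aggregates
and the prediction-stratified comparisons use the Yates-corrected
chi-square, with both choices exposed in the configuration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

from .classify import MAF_THRESHOLD, classify_variant
from .exact import chisq_yates_p, exact_ci, fisher_two_sided_p, sample_odds_ratio
from .types import (
    BurdenReport,
    BurdenRow,
    ClassifiedVariant,
    Cohort,
    CohortDataset,
    ConsequenceClass,
    ContingencyTable2x2,
    Criterion,
    ExactCI,
    SubjectRecord,
    TestKind,
    ValidationError,
)

logger = logging.getLogger(__name__)

SET_NAMES = ("GWAS_PROPOSED", "NEIGHBOURING", "TOTAL")

# Table-4-style prediction strata -> classified-variant predicate
STRATA = {
    "ALL": lambda cv: True,
    "CONDEL": lambda cv: cv.tool_flags["condel"],
    "POLYPHEN": lambda cv: cv.tool_flags["polyphen"],
    "CADD15": lambda cv: cv.tool_flags["cadd"],
    "SIFT": lambda cv: cv.tool_flags["sift"],
    "REVEL05": lambda cv: cv.tool_flags["revel"],
    "ALL_FIVE": lambda cv: cv.all_five_deleterious,
}


@dataclass
class AnalysisConfig:
    maf_threshold: float = MAF_THRESHOLD
    lof_set_test: TestKind = TestKind.FISHER
    missense_set_test: TestKind = TestKind.CHISQ_YATES
    stratum_test: TestKind = TestKind.CHISQ_YATES
    ci_level: float = 0.95
    bonferroni: bool = False  # adds an adjusted-p column to written reports


class CarrierMatrix:
    """Qualifying carrier status per (subject, gene, consequence class)."""

    def __init__(
        self,
        classified: Iterable[ClassifiedVariant],
        subjects: Sequence[SubjectRecord],
    ) -> None:
        self._cohort = {s.subject_id: s.cohort for s in subjects}
        self._cells: set[tuple[str, str, ConsequenceClass]] = set()
        self._variants: dict[tuple[str, str, ConsequenceClass], list[ClassifiedVariant]] = {}
        for cv in classified:
            if not cv.qualifying:
                continue
            key = (cv.source.subject_id, cv.source.gene, cv.consequence_class)
            self._cells.add(key)
            self._variants.setdefault(key, []).append(cv)

    def carriers(
        self,
        genes: Iterable[str],
        cls: ConsequenceClass,
        predicate=None,
    ) -> tuple[int, int]:
        """Distinct (case, control) carriers across ``genes`` for ``cls``.

        ``predicate`` optionally restricts to subjects carrying at least one
        qualifying variant satisfying it (used for prediction strata).
        """
        gene_set = set(genes)
        hit: set[str] = set()
        for (subject_id, gene, c), cvs in self._variants.items():
            if c is not cls or gene not in gene_set:
                continue
            if predicate is None or any(predicate(cv) for cv in cvs):
                hit.add(subject_id)
        n_case = sum(1 for s in hit if self._cohort[s] is Cohort.CASE)
        return n_case, len(hit) - n_case

    def carrier_subjects(
        self, genes: Iterable[str], classes: Iterable[ConsequenceClass]
    ) -> set[str]:
        """Subjects with >= 1 qualifying variant of any listed class in ``genes``."""
        gene_set, cls_set = set(genes), set(classes)
        return {
            subject_id
            for (subject_id, gene, c) in self._cells
            if gene in gene_set and c in cls_set
        }


def collapse_carriers(
    classified: Iterable[ClassifiedVariant],
    subjects: Sequence[SubjectRecord],
    scope: Union[str, Iterable[str]],
    cls: ConsequenceClass,
    manifest=None,
) -> tuple[int, int]:
    """Distinct case/control carriers of ``cls`` variants within ``scope``.

    ``scope`` is a gene symbol, a set name (GWAS_PROPOSED / NEIGHBOURING /
    TOTAL, requires ``manifest``), or an explicit iterable of genes. Only
    QC-passing rare variants contribute; a subject counts once per scope no
    matter how many genes or variants are involved.
    """
    genes = _resolve_scope(scope, manifest)
    return CarrierMatrix(classified, subjects).carriers(genes, cls)


def _resolve_scope(scope, manifest) -> set[str]:
    if isinstance(scope, str):
        if scope in SET_NAMES:
            if manifest is None:
                raise ValidationError(f"set scope {scope!r} requires a manifest")
            return _set_genes(manifest, scope)
        if manifest is not None and scope not in {g.symbol for g in manifest}:
            raise ValidationError(f"unknown gene {scope!r}")
        return {scope}
    genes = set(scope)
    if not genes:
        raise ValidationError("empty gene scope")
    if manifest is not None:
        unknown = genes - {g.symbol for g in manifest}
        if unknown:
            raise ValidationError(f"unknown genes in scope: {sorted(unknown)}")
    return genes


def _set_genes(manifest, set_name: str) -> set[str]:
    if set_name == "TOTAL":
        return {g.symbol for g in manifest}
    criterion = Criterion(set_name)
    return {g.symbol for g in manifest if g.criterion is criterion}


def _make_row(
    scope: str,
    cls: str,
    a: int,
    c: int,
    n_case: int,
    n_control: int,
    test: TestKind,
    level: float,
    criterion: Optional[str] = None,
) -> BurdenRow:
    table = ContingencyTable2x2(a, n_case - a, c, n_control - c)
    p = fisher_two_sided_p(table) if test is TestKind.FISHER else chisq_yates_p(table)
    return BurdenRow(
        scope=scope,
        criterion=criterion,
        consequence_class=cls,
        carriers_case=a,
        carriers_control=c,
        n_case=n_case,
        n_control=n_control,
        p=p,
        or_estimate=sample_odds_ratio(table),
        ci=exact_ci(table, level),
        test=test,
    )


def _prepare(dataset: CohortDataset, config: AnalysisConfig):
    classified = [classify_variant(v, config.maf_threshold) for v in dataset.variants]
    n_qc = sum(cv.passed_qc for cv in classified)
    n_rare = sum(cv.qualifying for cv in classified)
    by_class = {
        cls: sum(1 for cv in classified if cv.qualifying and cv.consequence_class is cls)
        for cls in ConsequenceClass
    }
    logger.info(
        "stage=classify records_in=%d qc_pass=%d rare=%d lof=%d missense=%d other=%d",
        len(classified), n_qc, n_rare,
        by_class[ConsequenceClass.LOF], by_class[ConsequenceClass.MISSENSE],
        by_class[ConsequenceClass.OTHER],
    )
    matrix = CarrierMatrix(classified, dataset.subjects)
    return classified, matrix


def gene_burden(
    dataset: CohortDataset,
    gene: str,
    cls: ConsequenceClass,
    config: Optional[AnalysisConfig] = None,
) -> BurdenRow:
    """Fisher exact burden comparison for one gene and consequence class."""
    config = config or AnalysisConfig()
    if gene not in {g.symbol for g in dataset.manifest}:
        raise ValidationError(f"gene {gene!r} not in manifest")
    _, matrix = _prepare(dataset, config)
    return _gene_row(dataset, matrix, gene, cls, config)


def _gene_row(dataset, matrix, gene, cls, config) -> BurdenRow:
    a, c = matrix.carriers({gene}, cls)
    criterion = next(g.criterion.value for g in dataset.manifest if g.symbol == gene)
    return _make_row(
        gene, cls.value, a, c, len(dataset.cases), len(dataset.controls),
        TestKind.FISHER, config.ci_level, criterion,
    )


def set_burden(
    dataset: CohortDataset,
    set_name: str,
    cls: ConsequenceClass,
    config: Optional[AnalysisConfig] = None,
    test_override: Optional[TestKind] = None,
) -> BurdenRow:
    """Burden comparison over a gene set with unique-subject collapsing."""
    config = config or AnalysisConfig()
    genes = _set_genes(dataset.manifest, set_name)
    if not genes:
        raise ValidationError(f"gene set {set_name!r} is empty")
    _, matrix = _prepare(dataset, config)
    return _set_row(dataset, matrix, set_name, genes, cls, config, test_override)


def _set_row(dataset, matrix, set_name, genes, cls, config, test_override=None) -> BurdenRow:
    test = test_override or (
        config.lof_set_test if cls is ConsequenceClass.LOF else config.missense_set_test
    )
    a, c = matrix.carriers(genes, cls)
    return _make_row(
        set_name, cls.value, a, c, len(dataset.cases), len(dataset.controls),
        test, config.ci_level,
    )


def stratified_missense_burden(
    dataset: CohortDataset,
    stratum: str,
    config: Optional[AnalysisConfig] = None,
) -> BurdenRow:
    """Missense burden restricted to one in-silico prediction stratum.

    Carriers are subjects with >= 1 qualifying missense variant passing the
    stratum's tool flag; denominators stay the full cohort sizes.
    """
    config = config or AnalysisConfig()
    if stratum not in STRATA:
        raise ValidationError(f"unknown stratum {stratum!r}; valid: {sorted(STRATA)}")
    _, matrix = _prepare(dataset, config)
    return _stratum_row(dataset, matrix, stratum, config)


def _stratum_row(dataset, matrix, stratum, config) -> BurdenRow:
    genes = {g.symbol for g in dataset.manifest}
    a, c = matrix.carriers(genes, ConsequenceClass.MISSENSE, STRATA[stratum])
    return _make_row(
        stratum, ConsequenceClass.MISSENSE.value, a, c,
        len(dataset.cases), len(dataset.controls), config.stratum_test, config.ci_level,
    )


def run_full_analysis(
    dataset: CohortDataset,
    config: Optional[AnalysisConfig] = None,
) -> BurdenReport:
    """The complete deterministic report: all genes x classes, 3 set rows per
    class, and the 7 prediction strata, classified once and reused."""
    config = config or AnalysisConfig()
    _, matrix = _prepare(dataset, config)

    gene_rows = [
        _gene_row(dataset, matrix, g.symbol, cls, config)
        for g in dataset.manifest
        for cls in (ConsequenceClass.LOF, ConsequenceClass.MISSENSE)
    ]
    set_rows = [
        _set_row(dataset, matrix, name, _set_genes(dataset.manifest, name), cls, config)
        for name in SET_NAMES
        for cls in (ConsequenceClass.LOF, ConsequenceClass.MISSENSE)
    ]
    stratum_rows = [_stratum_row(dataset, matrix, s, config) for s in STRATA]

    metadata = {
        "n_case": len(dataset.cases),
        "n_control": len(dataset.controls),
        "maf_threshold": config.maf_threshold,
        "ci_level": config.ci_level,
        "seed": dataset.metadata.get("seed"),
    }
    if config.bonferroni:
        n_tests = len(gene_rows) + len(set_rows) + len(stratum_rows)
        metadata["bonferroni_factor"] = n_tests
    logger.info(
        "stage=report gene_rows=%d set_rows=%d stratum_rows=%d",
        len(gene_rows), len(set_rows), len(stratum_rows),
    )
    return BurdenReport(gene_rows, set_rows, stratum_rows, metadata)
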