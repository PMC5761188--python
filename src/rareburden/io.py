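"""Readers and writers for manifests, variant tables, VCF and burden reports.

Two front-ends feed the same in-memory model: a fixed-header TSV of
annotated per-subject variant calls, and an annotated VCF 4.2 whose
per-sample genotypes define carriage and whose consequence / frequency /
prediction annotations live in a configurable INFO field. Missing numeric
cells parse to None, never 0 — absence from a reference database must stay
distinguishable from an observed frequency of zero.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .types import (
    BurdenReport,
    BurdenRow,
    Cohort,
    CondelCall,
    Criterion,
    ExactCI,
    FrequencyAnnotation,
    GeneRecord,
    OddsRatioEstimate,
    OddsRatioKind,
    PolyphenCall,
    PredictionProfile,
    RawVariantRecord,
    SiftCall,
    SnpDosageRecord,
    SubjectRecord,
    TestKind,
    ValidationError,
)

VARIANT_TSV_COLUMNS = [
    "subject_id", "cohort", "gene", "cds_change", "protein_change",
    "consequence", "caller_support", "total_depth", "alt_fraction",
    "exac_overall", "exac_nfe", "evs_overall", "evs_european",
    "condel", "polyphen", "sift", "cadd", "revel",
]

REPORT_COLUMNS = [
    "scope", "criterion", "class", "carriers_case", "carriers_control",
    "n_case", "n_control", "p", "or", "ci_low", "ci_high", "test",
]


def read_gene_manifest(path) -> list[GeneRecord]:
    """Read a gene manifest TSV (columns: symbol, criterion, snp_ids)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"symbol", "criterion", "snp_ids"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"manifest {path}: missing columns {sorted(required - set(df.columns))}"
        )
    records: list[GeneRecord] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        symbol = row.symbol.strip()
        if symbol in seen:
            raise ValidationError(f"manifest {path} line {i}: duplicate symbol {symbol!r}")
        seen.add(symbol)
        try:
            criterion = Criterion(row.criterion.strip())
        except ValueError:
            raise ValidationError(
                f"manifest {path} line {i}: unknown criterion {row.criterion!r}"
            ) from None
        snps = tuple(s for s in row.snp_ids.strip().split(";") if s)
        records.append(GeneRecord(symbol=symbol, criterion=criterion, snp_ids=snps))
    return records


def _opt_float(cell: str, name: str, line: int) -> Optional[float]:
    cell = cell.strip()
    if cell in ("", "NA", "nan", "."):
        return None
    try:
        return float(cell)
    except ValueError:
        raise ValidationError(f"line {line}: cannot parse {name}={cell!r}") from None


def _enum_cell(cell: str, enum_cls, line: int):
    cell = cell.strip().upper()
    if cell in ("", "NA", "."):
        return enum_cls.MISSING
    try:
        return enum_cls(cell)
    except ValueError:
        raise ValidationError(
            f"line {line}: unknown {enum_cls.__name__} value {cell!r}"
        ) from None


def read_variant_table(path, subjects: Sequence[SubjectRecord]) -> list[RawVariantRecord]:
    """Parse the fixed-header variant TSV against a known subject list."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in VARIANT_TSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"variant table {path}: missing columns {missing}")
    known = {s.subject_id for s in subjects}
    records: list[RawVariantRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        if row.subject_id not in known:
            raise ValidationError(f"line {i}: unknown subject_id {row.subject_id!r}")
        try:
            rec = RawVariantRecord(
                subject_id=row.subject_id,
                gene=row.gene,
                cds_change=row.cds_change,
                protein_change=row.protein_change,
                consequence_term=row.consequence,
                caller_support=int(row.caller_support),
                total_depth=int(row.total_depth),
                alt_fraction=float(row.alt_fraction),
                frequencies=FrequencyAnnotation(
                    exac_overall=_opt_float(row.exac_overall, "exac_overall", i),
                    exac_nfe=_opt_float(row.exac_nfe, "exac_nfe", i),
                    evs_overall=_opt_float(row.evs_overall, "evs_overall", i),
                    evs_european=_opt_float(row.evs_european, "evs_european", i),
                ),
                predictions=PredictionProfile(
                    condel_call=_enum_cell(row.condel, CondelCall, i),
                    polyphen_call=_enum_cell(row.polyphen, PolyphenCall, i),
                    sift_call=_enum_cell(row.sift, SiftCall, i),
                    cadd_score=_opt_float(row.cadd, "cadd", i),
                    revel_score=_opt_float(row.revel, "revel", i),
                ),
            )
        except (ValueError, ValidationError) as exc:
            raise ValidationError(f"variant table {path} line {i}: {exc}") from None
        records.append(rec)
    return records


def write_variant_table(
    records: Sequence[RawVariantRecord],
    subjects: Sequence[SubjectRecord],
    path,
) -> None:
    cohort_of = {s.subject_id: s.cohort.value for s in subjects}

    def fmt(v) -> str:
        return "" if v is None else (f"{v:g}" if isinstance(v, float) else str(v))

    rows = []
    for r in records:
        p, f = r.predictions, r.frequencies
        rows.append({
            "subject_id": r.subject_id,
            "cohort": cohort_of.get(r.subject_id, ""),
            "gene": r.gene,
            "cds_change": r.cds_change,
            "protein_change": r.protein_change,
            "consequence": r.consequence_term,
            "caller_support": r.caller_support,
            "total_depth": r.total_depth,
            "alt_fraction": f"{r.alt_fraction:g}",
            "exac_overall": fmt(f.exac_overall),
            "exac_nfe": fmt(f.exac_nfe),
            "evs_overall": fmt(f.evs_overall),
            "evs_european": fmt(f.evs_european),
            "condel": "" if p.condel_call is CondelCall.MISSING else p.condel_call.value,
            "polyphen": "" if p.polyphen_call is PolyphenCall.MISSING else p.polyphen_call.value,
            "sift": "" if p.sift_call is SiftCall.MISSING else p.sift_call.value,
            "cadd": fmt(p.cadd_score),
            "revel": fmt(p.revel_score),
        })
    pd.DataFrame(rows, columns=VARIANT_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def read_subject_table(path) -> list[SubjectRecord]:
    """Subjects from a TSV with subject_id and cohort columns (or a variant TSV)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if not {"subject_id", "cohort"}.issubset(df.columns):
        raise ValidationError(f"{path}: need subject_id and cohort columns")
    out, seen = [], set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        if row.subject_id in seen:
            continue
        seen.add(row.subject_id)
        try:
            out.append(SubjectRecord(row.subject_id, Cohort(row.cohort.strip().upper())))
        except ValueError:
            raise ValidationError(f"{path} line {i}: unknown cohort {row.cohort!r}") from None
    return out


def read_dosage_table(path) -> list[SnpDosageRecord]:
    """SNP risk-allele dosages: subject_id, snp_id, risk_allele_count."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if not {"subject_id", "snp_id", "risk_allele_count"}.issubset(df.columns):
        raise ValidationError(f"{path}: need subject_id/snp_id/risk_allele_count columns")
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            out.append(SnpDosageRecord(row.subject_id, row.snp_id, int(row.risk_allele_count)))
        except (ValueError, ValidationError) as exc:
            raise ValidationError(f"{path} line {i}: {exc}") from None
    return out


# ---------------------------------------------------------------------------
# Annotated VCF front-end


def read_variant_vcf(
    path,
    subjects: Sequence[SubjectRecord],
    ann_field: str = "CSQ",
    subfields: Optional[Sequence[str]] = None,
) -> list[RawVariantRecord]:
    """Map an annotated VCF onto RawVariantRecords, one per carrier sample.

    Per-sample non-reference genotypes define carriage. Annotations are read
    from the pipe-delimited INFO field ``ann_field`` whose subfield order is
    given by ``subfields`` (defaults to gene|consequence|cds|protein|
    exac_overall|exac_nfe|evs_overall|evs_european|condel|polyphen|sift|
    cadd|revel). Caller support, depth and alt fraction come from the
    per-sample NCALLERS/DP/AD FORMAT fields when present, else from defaults
    that pass QC (the VCF is assumed pre-filtered otherwise).
    """
    from cyvcf2 import VCF

    if subfields is None:
        subfields = [
            "gene", "consequence", "cds", "protein",
            "exac_overall", "exac_nfe", "evs_overall", "evs_european",
            "condel", "polyphen", "sift", "cadd", "revel",
        ]
    known = {s.subject_id for s in subjects}
    vcf = VCF(str(path))
    for sample in vcf.samples:
        if sample not in known:
            raise ValidationError(f"VCF sample {sample!r} not in subject list")
    idx = {name: i for i, name in enumerate(subfields)}

    def sub(parts: list[str], name: str) -> str:
        i = idx.get(name)
        return parts[i] if i is not None and i < len(parts) else ""

    records: list[RawVariantRecord] = []
    for var in vcf:
        ann = var.INFO.get(ann_field)
        if ann is None:
            raise ValidationError(f"VCF record {var.CHROM}:{var.POS} lacks INFO/{ann_field}")
        parts = str(ann).split("|")
        freqs = FrequencyAnnotation(
            exac_overall=_opt_float(sub(parts, "exac_overall"), "exac_overall", var.POS),
            exac_nfe=_opt_float(sub(parts, "exac_nfe"), "exac_nfe", var.POS),
            evs_overall=_opt_float(sub(parts, "evs_overall"), "evs_overall", var.POS),
            evs_european=_opt_float(sub(parts, "evs_european"), "evs_european", var.POS),
        )
        preds = PredictionProfile(
            condel_call=_enum_cell(sub(parts, "condel"), CondelCall, var.POS),
            polyphen_call=_enum_cell(sub(parts, "polyphen"), PolyphenCall, var.POS),
            sift_call=_enum_cell(sub(parts, "sift"), SiftCall, var.POS),
            cadd_score=_opt_float(sub(parts, "cadd"), "cadd", var.POS),
            revel_score=_opt_float(sub(parts, "revel"), "revel", var.POS),
        )
        depths = var.format("DP")
        callers = var.format("NCALLERS")
        ads = var.format("AD")
        gts = var.gt_types  # 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        for si, sample in enumerate(vcf.samples):
            if gts[si] in (0, 2):
                continue
            depth = int(depths[si][0]) if depths is not None else 100
            support = int(callers[si][0]) if callers is not None else 3
            if ads is not None and depth > 0:
                alt_frac = float(ads[si][1]) / depth
            else:
                alt_frac = 0.5
            records.append(
                RawVariantRecord(
                    subject_id=sample,
                    gene=sub(parts, "gene"),
                    cds_change=sub(parts, "cds"),
                    protein_change=sub(parts, "protein"),
                    consequence_term=sub(parts, "consequence"),
                    caller_support=support,
                    total_depth=depth,
                    alt_fraction=min(1.0, alt_frac),
                    frequencies=freqs,
                    predictions=preds,
                )
            )
    return records


# ---------------------------------------------------------------------------
# Burden report round-trip


def write_burden_report(report: BurdenReport, path) -> None:
    """Serialise a report to TSV with deterministic column order.

    Odds ratios follow the table typography: "Und" for an undefined
    estimate (empty control cell) and "0" for an empty case cell; an open
    upper CI bound is written "inf". Statistics carry 6 decimals so the
    reader round-trips them losslessly at that precision.
    """
    rows = []
    for r in report.rows:
        orr = r.or_estimate
        if orr.kind is OddsRatioKind.UNDEFINED:
            or_cell = "Und"
        elif orr.kind is OddsRatioKind.ZERO:
            or_cell = "0"
        else:
            or_cell = f"{orr.value:.6f}"
        rows.append({
            "scope": r.scope,
            "criterion": r.criterion or "",
            "class": r.consequence_class,
            "carriers_case": r.carriers_case,
            "carriers_control": r.carriers_control,
            "n_case": r.n_case,
            "n_control": r.n_control,
            "p": f"{r.p:.6f}",
            "or": or_cell,
            "ci_low": f"{r.ci.low:.6f}",
            "ci_high": "inf" if math.isinf(r.ci.high) else f"{r.ci.high:.6f}",
            "test": r.test.value,
        })
    pd.DataFrame(rows, columns=REPORT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_burden_report(path) -> list[BurdenRow]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in REPORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"report {path}: missing columns {missing}")
    rows = []
    for _, row in df.iterrows():  # "or"/"class" are keywords, so no itertuples
        or_cell = row["or"]
        if or_cell in (OddsRatioKind.UNDEFINED.value, "Und"):
            orr = OddsRatioEstimate(OddsRatioKind.UNDEFINED)
        elif or_cell in ("0", OddsRatioKind.ZERO.value):
            orr = OddsRatioEstimate(OddsRatioKind.ZERO, 0.0)
        else:
            orr = OddsRatioEstimate(OddsRatioKind.FINITE, float(or_cell))
        rows.append(
            BurdenRow(
                scope=row["scope"],
                criterion=row["criterion"] or None,
                consequence_class=row["class"],
                carriers_case=int(row["carriers_case"]),
                carriers_control=int(row["carriers_control"]),
                n_case=int(row["n_case"]),
                n_control=int(row["n_control"]),
                p=float(row["p"]),
                or_estimate=orr,
                ci=ExactCI(float(row["ci_low"]), float(row["ci_high"])),
                test=TestKind(row["test"]),
            )
        )
    return rows
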