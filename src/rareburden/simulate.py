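"""Synthetic case-control cohort generator.

The generator reproduces the statistical structure the burden analysis
assumes, without any sequence-level simulation. Carrier status is the unit
of simulation: each subject is independently a carrier of a qualifying
loss-of-function and/or missense variant in each gene, with a per-gene
control-arm Bernoulli rate and a case-arm rate derived through the odds
transform

    odds_case = OR * odds_control,   p_case = odds_case / (1 + odds_case)

so that the true carrier odds ratio equals the configured effect size.
Every simulated carrier receives at least one variant record that passes
the QC, rarity and consequence filters; decoy records that fail exactly one
named QC criterion, or that are too common for the rarity filter, can be
attached anywhere to exercise the filtering stages. Ground truth (carrier
status and the intended fate of every record) is emitted alongside.

Defaults emulate the study conditions: 1043 cases vs 944 controls, per-gene
control carrier rates calibrated to the printed control-arm totals
(~2.5e-4 for LoF, ~7.4e-3 for missense across 56 genes), pooled odds ratios
1.83 (LoF) and 1.07 (missense), and a point mass of ~0.65 at
"absent from the reference databases" in the MAF model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import yaml

from . import fixtures
from .types import (
    Cohort,
    CohortDataset,
    CondelCall,
    ConsequenceClass,
    FrequencyAnnotation,
    GeneRecord,
    PolyphenCall,
    PredictionProfile,
    RawVariantRecord,
    SiftCall,
    SnpDosageRecord,
    SubjectRecord,
    ValidationError,
)

LOF_TERM_CHOICES = (
    "stop_gained",
    "frameshift_variant",
    "splice_donor_variant",
    "splice_acceptor_variant",
)

# record-fate labels used in SimulationTruth
LABEL_QUALIFYING = "qualifying"
LABEL_SPIKED = "spiked"
LABEL_QC_FAIL = {
    "caller": "qc_fail_caller",
    "depth": "qc_fail_depth",
    "vaf": "qc_fail_vaf",
}
LABEL_COMMON = "common"


class ConfigurationError(ValidationError):
    """Raised when a simulation configuration is internally inconsistent."""


@dataclass(frozen=True)
class GeneSimSettings:
    """Per-gene carrier rates (control arm) and odds-ratio effects."""

    control_carrier_rate_lof: float = 2.5e-4
    control_carrier_rate_missense: float = 7.4e-3
    odds_ratio_lof: float = 1.83
    odds_ratio_missense: float = 1.07


@dataclass(frozen=True)
class MafModel:
    """Mixture for qualifying-variant database frequencies.

    With probability ``absent_weight`` a database field is null (the variant
    was never observed there); otherwise the frequency is log-uniform on
    [10^log10_min, 10^log10_max], which stays within the rarity threshold.
    """

    absent_weight: float = 0.65
    log10_min: float = -5.0
    log10_max: float = -3.0


@dataclass(frozen=True)
class PredictionModel:
    """Correlated five-tool deleteriousness calls for missense variants.

    A latent truly-pathogenic indicator (probability ``pathogenic_fraction``)
    drives all five tools, each flagging with ``sensitivity`` on pathogenic
    and ``false_positive_rate`` on benign variants; this induces the
    between-tool agreement real ensembles show. Scores are drawn on the
    flag's side of the tool threshold. Calls go missing independently at
    ``missing_rate``.
    """

    pathogenic_fraction: float = 0.25
    sensitivity: float = 0.8
    false_positive_rate: float = 0.25
    missing_rate: float = 0.02


@dataclass
class SimulationConfig:
    n_cases: int = fixtures.N_CASES
    n_controls: int = fixtures.N_CONTROLS
    manifest: Optional[list[GeneRecord]] = None  # defaults to the packaged panel
    default_gene: GeneSimSettings = field(default_factory=GeneSimSettings)
    gene_overrides: dict = field(default_factory=dict)  # symbol -> GeneSimSettings
    maf_model: MafModel = field(default_factory=MafModel)
    prediction_model: PredictionModel = field(default_factory=PredictionModel)
    qc_artifact_rate: float = 0.0     # per-subject probability of one QC-failing decoy
    common_variant_rate: float = 0.0  # per-subject probability of one too-common decoy
    multi_variant_rate: float = 0.0   # probability a carrier gets a second variant
    seed: int = 0

    def settings_for(self, symbol: str) -> GeneSimSettings:
        return self.gene_overrides.get(symbol, self.default_gene)

    def validate(self) -> None:
        if self.n_cases < 0 or self.n_controls < 0:
            raise ConfigurationError("cohort sizes must be >= 0")
        for prob, name in (
            (self.qc_artifact_rate, "qc_artifact_rate"),
            (self.common_variant_rate, "common_variant_rate"),
            (self.multi_variant_rate, "multi_variant_rate"),
            (self.maf_model.absent_weight, "maf_model.absent_weight"),
            (self.prediction_model.pathogenic_fraction, "pathogenic_fraction"),
            (self.prediction_model.sensitivity, "sensitivity"),
            (self.prediction_model.false_positive_rate, "false_positive_rate"),
            (self.prediction_model.missing_rate, "missing_rate"),
        ):
            if not 0.0 <= prob <= 1.0:
                raise ConfigurationError(f"{name}={prob} outside [0, 1]")
        manifest = self.manifest or fixtures.load_gene_manifest()
        for g in manifest:
            s = self.settings_for(g.symbol)
            for rate, odds_ratio, cls in (
                (s.control_carrier_rate_lof, s.odds_ratio_lof, "lof"),
                (s.control_carrier_rate_missense, s.odds_ratio_missense, "missense"),
            ):
                if not 0.0 <= rate <= 1.0:
                    raise ConfigurationError(f"{g.symbol} {cls}: rate {rate} outside [0, 1]")
                if not np.isfinite(odds_ratio) or odds_ratio < 0:
                    raise ConfigurationError(f"{g.symbol} {cls}: invalid OR {odds_ratio}")
                p = _case_rate(rate, odds_ratio)
                if not 0.0 <= p <= 1.0:
                    raise ConfigurationError(
                        f"{g.symbol} {cls}: derived case probability {p} outside [0, 1]"
                    )

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for key in ("n_cases", "n_controls", "seed", "qc_artifact_rate",
                    "common_variant_rate", "multi_variant_rate"):
            if key in raw:
                setattr(cfg, key, raw[key])
        if "default_gene" in raw:
            cfg.default_gene = GeneSimSettings(**raw["default_gene"])
        if "gene_overrides" in raw:
            cfg.gene_overrides = {
                sym: GeneSimSettings(**kw) for sym, kw in raw["gene_overrides"].items()
            }
        if "maf_model" in raw:
            cfg.maf_model = MafModel(**raw["maf_model"])
        if "prediction_model" in raw:
            cfg.prediction_model = PredictionModel(**raw["prediction_model"])
        return cfg


@dataclass
class SimulationTruth:
    """Ground truth for one simulated dataset.

    ``carriers`` holds every (subject_id, gene, class) with a true
    qualifying variant; ``record_labels`` is aligned index-for-index with
    ``dataset.variants`` and names each record's intended fate.
    """

    carriers: set = field(default_factory=set)
    record_labels: list = field(default_factory=list)

    def is_carrier(self, subject_id: str, gene: str, cls: ConsequenceClass) -> bool:
        return (subject_id, gene, cls) in self.carriers


def _case_rate(control_rate: float, odds_ratio: float) -> float:
    if control_rate >= 1.0:
        return 1.0 if odds_ratio > 0 else 0.0
    odds = odds_ratio * control_rate / (1.0 - control_rate)
    return odds / (1.0 + odds)


def _draw_frequencies(rng: np.random.Generator, m: MafModel) -> FrequencyAnnotation:
    vals = []
    for _ in range(4):
        if rng.random() < m.absent_weight:
            vals.append(None)
        else:
            vals.append(float(10.0 ** rng.uniform(m.log10_min, m.log10_max)))
    return FrequencyAnnotation(*vals)


def _draw_predictions(rng: np.random.Generator, pm: PredictionModel) -> PredictionProfile:
    pathogenic = rng.random() < pm.pathogenic_fraction
    p_flag = pm.sensitivity if pathogenic else pm.false_positive_rate
    flags = rng.random(5) < p_flag
    miss = rng.random(5) < pm.missing_rate

    condel = CondelCall.MISSING if miss[0] else (
        CondelCall.DELETERIOUS if flags[0] else CondelCall.NEUTRAL
    )
    if miss[1]:
        polyphen = PolyphenCall.MISSING
    elif flags[1]:
        polyphen = PolyphenCall.PROBABLY if rng.random() < 0.5 else PolyphenCall.POSSIBLY
    else:
        polyphen = PolyphenCall.BENIGN
    sift = SiftCall.MISSING if miss[2] else (
        SiftCall.DELETERIOUS if flags[2] else SiftCall.TOLERATED
    )
    cadd = None if miss[3] else float(
        rng.uniform(15.0, 40.0) if flags[3] else rng.uniform(0.0, 14.9)
    )
    revel = None if miss[4] else float(
        rng.uniform(0.5, 1.0) if flags[4] else rng.uniform(0.0, 0.499)
    )
    return PredictionProfile(condel, polyphen, sift, cadd, revel)


def _qualifying_record(
    rng: np.random.Generator,
    subject_id: str,
    gene: str,
    cls: ConsequenceClass,
    config: SimulationConfig,
    serial: int,
) -> RawVariantRecord:
    if cls is ConsequenceClass.LOF:
        term = LOF_TERM_CHOICES[rng.integers(len(LOF_TERM_CHOICES))]
        preds = PredictionProfile()
    else:
        term = "missense_variant"
        preds = _draw_predictions(rng, config.prediction_model)
    return RawVariantRecord(
        subject_id=subject_id,
        gene=gene,
        cds_change=f"c.{serial}A>G",
        protein_change="",
        consequence_term=term,
        caller_support=int(2 + rng.integers(2)),
        total_depth=int(max(10, rng.poisson(170.0))),
        alt_fraction=float(np.round(rng.uniform(0.35, 0.65), 3)),
        frequencies=_draw_frequencies(rng, config.maf_model),
        predictions=preds,
    )


def simulate_cohort(config: SimulationConfig) -> tuple[CohortDataset, SimulationTruth]:
    """Generate a cohort and its ground truth, reproducibly from the seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    manifest = list(config.manifest or fixtures.load_gene_manifest())

    subjects = [
        SubjectRecord(f"CASE_{i + 1:05d}", Cohort.CASE) for i in range(config.n_cases)
    ] + [
        SubjectRecord(f"CONTROL_{i + 1:05d}", Cohort.CONTROL)
        for i in range(config.n_controls)
    ]
    case_ids = [s.subject_id for s in subjects if s.cohort is Cohort.CASE]
    control_ids = [s.subject_id for s in subjects if s.cohort is Cohort.CONTROL]

    truth = SimulationTruth()
    variants: list[RawVariantRecord] = []
    serial = 0

    for gene in manifest:
        s = config.settings_for(gene.symbol)
        for cls, rate, odds_ratio in (
            (ConsequenceClass.LOF, s.control_carrier_rate_lof, s.odds_ratio_lof),
            (ConsequenceClass.MISSENSE, s.control_carrier_rate_missense, s.odds_ratio_missense),
        ):
            p_case = _case_rate(rate, odds_ratio)
            for ids, p in ((case_ids, p_case), (control_ids, rate)):
                mask = rng.random(len(ids)) < p
                for subject_id in (ids[i] for i in np.flatnonzero(mask)):
                    truth.carriers.add((subject_id, gene.symbol, cls))
                    n_var = 1 + int(rng.random() < config.multi_variant_rate)
                    for _ in range(n_var):
                        serial += 1
                        variants.append(
                            _qualifying_record(rng, subject_id, gene.symbol, cls, config, serial)
                        )
                        truth.record_labels.append(LABEL_QUALIFYING)

    dataset = CohortDataset(subjects=subjects, variants=variants, manifest=manifest,
                            metadata={"seed": config.seed})
    if config.qc_artifact_rate > 0:
        inject_qc_failures(dataset, config, truth, rng)
    if config.common_variant_rate > 0:
        _inject_common_variants(dataset, config, truth, rng)
    return dataset, truth


def inject_qc_failures(
    dataset: CohortDataset,
    config: SimulationConfig,
    truth: Optional[SimulationTruth] = None,
    rng: Optional[np.random.Generator] = None,
) -> CohortDataset:
    """Attach decoy records that each violate exactly one QC criterion.

    Every subject independently receives one decoy with probability
    ``config.qc_artifact_rate``; the violated criterion cycles through
    single-caller support (caller_support = 1), low depth (total_depth = 9)
    and low allele fraction (alt_fraction = 0.19), with the other two fields
    kept passing. Decoys are labelled in the truth so leakage into carrier
    counts is detectable.
    """
    rate = config.qc_artifact_rate
    if not 0.0 <= rate <= 1.0:
        raise ConfigurationError(f"qc_artifact_rate={rate} outside [0, 1]")
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    genes = [g.symbol for g in dataset.manifest]
    modes = ("caller", "depth", "vaf")
    serial = len(dataset.variants)
    n_added = 0
    for subject in dataset.subjects:
        if rng.random() >= rate:
            continue
        mode = modes[n_added % len(modes)]
        n_added += 1
        serial += 1
        base = _qualifying_record(
            rng, subject.subject_id, genes[rng.integers(len(genes))],
            ConsequenceClass.LOF if rng.random() < 0.5 else ConsequenceClass.MISSENSE,
            config, serial,
        )
        if mode == "caller":
            rec = replace(base, caller_support=1)
        elif mode == "depth":
            rec = replace(base, total_depth=9)
        else:
            rec = replace(base, alt_fraction=0.19)
        dataset.variants.append(rec)
        if truth is not None:
            truth.record_labels.append(LABEL_QC_FAIL[mode])
    return dataset


def _inject_common_variants(dataset, config, truth, rng) -> None:
    """Decoys that pass QC but carry a database frequency above the rarity cut."""
    genes = [g.symbol for g in dataset.manifest]
    serial = len(dataset.variants)
    for subject in dataset.subjects:
        if rng.random() >= config.common_variant_rate:
            continue
        serial += 1
        base = _qualifying_record(
            rng, subject.subject_id, genes[rng.integers(len(genes))],
            ConsequenceClass.MISSENSE, config, serial,
        )
        rec = replace(
            base,
            frequencies=FrequencyAnnotation(
                exac_overall=float(rng.uniform(0.005, 0.2)),
                exac_nfe=float(rng.uniform(0.005, 0.2)),
            ),
        )
        dataset.variants.append(rec)
        if truth is not None:
            truth.record_labels.append(LABEL_COMMON)


def spike_fixture_variants(
    dataset: CohortDataset, truth: Optional[SimulationTruth] = None
) -> CohortDataset:
    """Embed the packaged LoF variant list with its printed carrier counts.

    Each fixture variant is assigned to distinct, previously unspiked
    subjects (cases in order, controls in order), so the pooled carrier
    split reproduces the published 26-case / 13-control partition after the
    full QC -> rarity -> consequence -> collapse pipeline. Spiking the same
    dataset twice raises, preventing double counting.
    """
    if dataset.metadata.get("lof_fixture_spiked"):
        raise ValidationError("dataset already carries the spiked LoF fixture")
    rows = fixtures.load_lof_fixture()
    need_cases = sum(r.case_carriers for r in rows)
    need_controls = sum(r.control_carriers for r in rows)
    cases = [s.subject_id for s in dataset.cases]
    controls = [s.subject_id for s in dataset.controls]
    if len(cases) < need_cases or len(controls) < need_controls:
        raise ValidationError(
            f"need >= {need_cases} cases and {need_controls} controls to spike the fixture"
        )
    case_iter = iter(cases)
    control_iter = iter(controls)
    for row in rows:
        targets = [next(case_iter) for _ in range(row.case_carriers)] + [
            next(control_iter) for _ in range(row.control_carriers)
        ]
        for subject_id in targets:
            dataset.variants.append(
                RawVariantRecord(
                    subject_id=subject_id,
                    gene=row.symbol,
                    cds_change=row.cds_change,
                    protein_change=row.protein_change or "",
                    consequence_term=row.consequence_term,
                    caller_support=3,
                    total_depth=150,
                    alt_fraction=0.45,
                    frequencies=FrequencyAnnotation(
                        exac_nfe=row.exac_nfe_maf,
                        evs_european=row.evs_european_maf,
                    ),
                )
            )
            if truth is not None:
                truth.record_labels.append(LABEL_SPIKED)
                truth.carriers.add((subject_id, row.symbol, ConsequenceClass.LOF))
    dataset.metadata["lof_fixture_spiked"] = True
    return dataset


def simulate_dosages(
    dataset: CohortDataset,
    seed: int = 0,
    risk_allele_frequency: float = 0.3,
) -> list[SnpDosageRecord]:
    """Hardy-Weinberg risk-allele dosages for every subject x manifest SNP."""
    if not 0.0 <= risk_allele_frequency <= 1.0:
        raise ConfigurationError(f"risk_allele_frequency={risk_allele_frequency}")
    rng = np.random.default_rng(seed)
    snps = sorted({snp for g in dataset.manifest for snp in g.snp_ids})
    out = []
    for snp in snps:
        dosages = rng.binomial(2, risk_allele_frequency, size=len(dataset.subjects))
        out.extend(
            SnpDosageRecord(s.subject_id, snp, int(d))
            for s, d in zip(dataset.subjects, dosages)
        )
    return out
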