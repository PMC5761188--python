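"""Domain types for the candidate-gene rare-variant burden pipeline.

The data model mirrors a targeted-sequencing analysis of a gene panel in a
case-control design: a gene manifest (each candidate gene tied to one or more
risk SNPs), per-subject annotated variant calls with quality-control evidence
and population-frequency / in-silico-pathogenicity annotations, and 2x2
carrier contingency tables for exact conditional inference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional


class ValidationError(ValueError):
    """Raised when an input record or file violates a model invariant."""


class Criterion(str, Enum):
    """How a candidate gene entered the panel."""

    GWAS_PROPOSED = "GWAS_PROPOSED"  # nominated as the likely SNP target gene
    NEIGHBOURING = "NEIGHBOURING"    # within +/-500 kb of the risk SNP only


class Cohort(str, Enum):
    CASE = "CASE"
    CONTROL = "CONTROL"


class ConsequenceClass(str, Enum):
    LOF = "LOF"
    MISSENSE = "MISSENSE"
    OTHER = "OTHER"


class CondelCall(str, Enum):
    DELETERIOUS = "DELETERIOUS"
    NEUTRAL = "NEUTRAL"
    MISSING = "MISSING"


class PolyphenCall(str, Enum):
    PROBABLY = "PROBABLY"
    POSSIBLY = "POSSIBLY"
    BENIGN = "BENIGN"
    MISSING = "MISSING"


class SiftCall(str, Enum):
    DELETERIOUS = "DELETERIOUS"
    TOLERATED = "TOLERATED"
    MISSING = "MISSING"


@dataclass(frozen=True)
class GeneRecord:
    """One candidate gene with its selection criterion and associated SNPs."""

    symbol: str
    criterion: Criterion
    snp_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.symbol:
            raise ValidationError("gene symbol must be non-empty")
        if not isinstance(self.criterion, Criterion):
            raise ValidationError(f"invalid criterion: {self.criterion!r}")


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    cohort: Cohort


@dataclass(frozen=True)
class TranscriptAnnotation:
    """Transcript-level context used for canonical-transcript selection.

    ``translation_length`` is in amino acids; 0 marks a non-protein-coding
    transcript. ``consequence_term`` optionally carries the per-transcript
    consequence so that classification can follow the canonical transcript.
    """

    transcript_id: str
    translation_length: int = 0
    contains_stop_in_translation: bool = False
    is_ccds: bool = False
    is_merged_ensembl_havana: bool = False
    transcript_length: int = 0
    consequence_term: Optional[str] = None

    def __post_init__(self) -> None:
        if self.translation_length < 0 or self.transcript_length < 0:
            raise ValidationError(
                f"{self.transcript_id}: transcript lengths must be >= 0"
            )

    @property
    def is_protein_coding(self) -> bool:
        return self.translation_length > 0


@dataclass(frozen=True)
class FrequencyAnnotation:
    """Reference-database minor-allele frequencies (None = absent)."""

    exac_overall: Optional[float] = None
    exac_nfe: Optional[float] = None
    evs_overall: Optional[float] = None
    evs_european: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("exac_overall", "exac_nfe", "evs_overall", "evs_european"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}={v} outside [0, 1]")

    def values(self) -> list[Optional[float]]:
        return [self.exac_overall, self.exac_nfe, self.evs_overall, self.evs_european]


@dataclass(frozen=True)
class PredictionProfile:
    """Outputs of the five in-silico pathogenicity tools for one variant."""

    condel_call: CondelCall = CondelCall.MISSING
    polyphen_call: PolyphenCall = PolyphenCall.MISSING
    sift_call: SiftCall = SiftCall.MISSING
    cadd_score: Optional[float] = None
    revel_score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.revel_score is not None and not 0.0 <= self.revel_score <= 1.0:
            raise ValidationError(f"revel_score={self.revel_score} outside [0, 1]")


@dataclass(frozen=True)
class RawVariantRecord:
    """One called variant in one subject, with QC evidence and annotations."""

    subject_id: str
    gene: str
    consequence_term: str
    caller_support: int
    total_depth: int
    alt_fraction: float
    cds_change: str = ""
    protein_change: str = ""
    transcripts: tuple[TranscriptAnnotation, ...] = ()
    frequencies: FrequencyAnnotation = field(default_factory=FrequencyAnnotation)
    predictions: PredictionProfile = field(default_factory=PredictionProfile)

    def __post_init__(self) -> None:
        if self.caller_support < 0:
            raise ValidationError(f"caller_support={self.caller_support} < 0")
        if self.total_depth < 0:
            raise ValidationError(f"total_depth={self.total_depth} < 0")
        if not 0.0 <= self.alt_fraction <= 1.0:
            raise ValidationError(f"alt_fraction={self.alt_fraction} outside [0, 1]")


@dataclass
class CohortDataset:
    """Subjects, their variant calls, and the gene manifest, as one unit."""

    subjects: list[SubjectRecord]
    variants: list[RawVariantRecord]
    manifest: list[GeneRecord]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        subject_ids = {s.subject_id for s in self.subjects}
        if len(subject_ids) != len(self.subjects):
            raise ValidationError("duplicate subject_id in cohort")
        genes = {g.symbol for g in self.manifest}
        for v in self.variants:
            if v.subject_id not in subject_ids:
                raise ValidationError(f"variant subject {v.subject_id!r} not in cohort")
            if v.gene not in genes:
                raise ValidationError(f"variant gene {v.gene!r} not in manifest")

    @property
    def cases(self) -> list[SubjectRecord]:
        return [s for s in self.subjects if s.cohort is Cohort.CASE]

    @property
    def controls(self) -> list[SubjectRecord]:
        return [s for s in self.subjects if s.cohort is Cohort.CONTROL]

    def cohort_of(self, subject_id: str) -> Cohort:
        try:
            return next(s.cohort for s in self.subjects if s.subject_id == subject_id)
        except StopIteration:
            raise KeyError(subject_id) from None


@dataclass(frozen=True)
class ClassifiedVariant:
    """A raw record plus the QC / rarity / consequence / prediction verdicts."""

    source: RawVariantRecord
    passed_qc: bool
    canonical_transcript_id: Optional[str]
    consequence_class: ConsequenceClass
    is_rare: bool
    tool_flags: dict
    any_deleterious: bool
    all_five_deleterious: bool

    @property
    def qualifying(self) -> bool:
        """QC-passing and rare, i.e. eligible for carrier counting."""
        return self.passed_qc and self.is_rare


# ---------------------------------------------------------------------------
# 2x2 inference types


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Carrier vs non-carrier counts in cases and controls.

    a = case carriers, b = case non-carriers,
    c = control carriers, d = control non-carriers.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValidationError("contingency cells must be non-negative")

    @property
    def n1(self) -> int:
        return self.a + self.b

    @property
    def n2(self) -> int:
        return self.c + self.d

    @property
    def total_carriers(self) -> int:
        return self.a + self.c

    @property
    def n(self) -> int:
        return self.n1 + self.n2


class OddsRatioKind(str, Enum):
    FINITE = "FINITE"
    ZERO = "ZERO"          # a = 0 with c > 0; printed as "0"
    UNDEFINED = "UNDEFINED"  # c = 0 with a > 0, or a = c = 0; printed "Und"


@dataclass(frozen=True)
class OddsRatioEstimate:
    kind: OddsRatioKind
    value: Optional[float] = None

    def render(self, decimals: int = 2) -> str:
        if self.kind is OddsRatioKind.UNDEFINED:
            return "Und"
        if self.kind is OddsRatioKind.ZERO:
            return "0"
        return f"{self.value:.{decimals}f}"


@dataclass(frozen=True)
class ExactCI:
    low: float
    high: float  # math.inf for an open upper bound
    level: float = 0.95

    def __post_init__(self) -> None:
        if self.low > self.high:
            raise ValidationError(f"CI low {self.low} > high {self.high}")

    def render(self, decimals: int = 2) -> str:
        hi = "inf" if math.isinf(self.high) else f"{self.high:.{decimals}f}"
        return f"{self.low:.{decimals}f}-{hi}"


class TestKind(str, Enum):
    __test__ = False  # statistical test label, not a pytest collectable

    FISHER = "FISHER"
    CHISQ_YATES = "CHISQ_YATES"


@dataclass(frozen=True)
class BurdenRow:
    """One gene's / gene-set's / prediction-stratum's burden comparison."""

    scope: str
    consequence_class: str
    carriers_case: int
    carriers_control: int
    n_case: int
    n_control: int
    p: float
    or_estimate: OddsRatioEstimate
    ci: ExactCI
    test: TestKind
    criterion: Optional[str] = None

    def __post_init__(self) -> None:
        if self.carriers_case > self.n_case or self.carriers_control > self.n_control:
            raise ValidationError("carrier count exceeds cohort denominator")
        if not 0.0 <= self.p <= 1.0:
            raise ValidationError(f"p={self.p} outside [0, 1]")

    @property
    def table(self) -> ContingencyTable2x2:
        return ContingencyTable2x2(
            self.carriers_case,
            self.n_case - self.carriers_case,
            self.carriers_control,
            self.n_control - self.carriers_control,
        )


@dataclass
class BurdenReport:
    gene_rows: list[BurdenRow]
    set_rows: list[BurdenRow]
    stratum_rows: list[BurdenRow]
    metadata: dict = field(default_factory=dict)

    @property
    def rows(self) -> list[BurdenRow]:
        return [*self.gene_rows, *self.set_rows, *self.stratum_rows]


# ---------------------------------------------------------------------------
# SNP co-occurrence types


@dataclass(frozen=True)
class SnpDosageRecord:
    subject_id: str
    snp_id: str
    risk_allele_count: int

    def __post_init__(self) -> None:
        if self.risk_allele_count not in (0, 1, 2):
            raise ValidationError(
                f"risk_allele_count={self.risk_allele_count} not in {{0, 1, 2}}"
            )


@dataclass(frozen=True)
class InteractionRow:
    """Risk-allele carriage vs rare-variant carriage within one stratum."""

    gene: str
    snp_id: str
    stratum: Cohort
    consequence_class: str
    table: ContingencyTable2x2
    p: float
    adjusted_significant: bool
    n_excluded: int = 0
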