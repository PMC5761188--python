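"""Variant-level decision cascade.

Each called variant passes through four independent verdicts before it can
contribute to a carrier count:

1. QC consensus — called by >= 2 callers, total depth >= 10, alternate-read
   fraction >= 20% (all boundaries inclusive).
2. Canonical transcript — the transcript against which the consequence is
   interpreted, chosen by the ordered preference CCDS > Ensembl/Havana
   merged > longest translation > longest non-coding transcript.
3. Consequence class — loss-of-function (stop-gained, frameshift, essential
   splice site, i.e. the two intronic bases at donor/acceptor), missense,
   or other.
4. Rarity — minor allele frequency <= 0.001 in every reference-database
   column present (ExAC overall/NFE, EVS overall/European); a variant absent
   from a database is treated as unobserved there (frequency 0).

Missense variants additionally get a five-tool in-silico profile: Condel,
PolyPhen-2 and SIFT categorical calls, CADD >= 15 and REVEL >= 0.5 score
thresholds (inclusive). A missing call or score never flags a tool.
"""

from __future__ import annotations

import logging
from typing import Iterable, Optional, Sequence

from .types import (
    ClassifiedVariant,
    CondelCall,
    ConsequenceClass,
    FrequencyAnnotation,
    PolyphenCall,
    PredictionProfile,
    RawVariantRecord,
    SiftCall,
    TranscriptAnnotation,
)

logger = logging.getLogger(__name__)

MIN_CALLER_SUPPORT = 2
MIN_TOTAL_DEPTH = 10
MIN_ALT_FRACTION = 0.20
MAF_THRESHOLD = 0.001
CADD_THRESHOLD = 15.0
REVEL_THRESHOLD = 0.5

LOF_TERMS = frozenset(
    {
        "stop_gained",
        "frameshift_variant",
        "splice_donor_variant",
        "splice_acceptor_variant",
    }
)

_KNOWN_TERMS = LOF_TERMS | {
    "missense_variant",
    "synonymous_variant",
    "splice_region_variant",
    "intron_variant",
    "inframe_deletion",
    "inframe_insertion",
    "stop_lost",
    "start_lost",
    "5_prime_UTR_variant",
    "3_prime_UTR_variant",
}

TOOL_NAMES = ("condel", "polyphen", "sift", "cadd", "revel")


def passes_qc(record: RawVariantRecord) -> bool:
    """Caller-consensus QC: >=2 callers, depth >=10, alt fraction >=0.20."""
    return (
        record.caller_support >= MIN_CALLER_SUPPORT
        and record.total_depth >= MIN_TOTAL_DEPTH
        and record.alt_fraction >= MIN_ALT_FRACTION
    )


def select_canonical_transcript(transcripts: Sequence[TranscriptAnnotation]) -> str:
    """Pick the canonical transcript by the ordered four-rule preference.

    (1) longest CCDS translation without internal stops; (2) else longest
    Ensembl/Havana-merged translation without stops; (3) else longest
    translation without stops; (4) else longest non-protein-coding
    transcript. Length ties break to the lexicographically smallest
    transcript_id so the choice is deterministic.
    """
    if not transcripts:
        raise ValueError("cannot select a canonical transcript from an empty list")

    def best(candidates: Iterable[TranscriptAnnotation], key) -> Optional[TranscriptAnnotation]:
        pool = list(candidates)
        if not pool:
            return None
        return min(pool, key=lambda t: (-key(t), t.transcript_id))

    translated = [
        t
        for t in transcripts
        if t.is_protein_coding and not t.contains_stop_in_translation
    ]
    for rule in (
        lambda: best((t for t in translated if t.is_ccds), lambda t: t.translation_length),
        lambda: best(
            (t for t in translated if t.is_merged_ensembl_havana),
            lambda t: t.translation_length,
        ),
        lambda: best(translated, lambda t: t.translation_length),
        lambda: best(transcripts, lambda t: t.transcript_length),
    ):
        chosen = rule()
        if chosen is not None:
            return chosen.transcript_id
    raise AssertionError("unreachable: rule (4) accepts any transcript")


def classify_consequence(term: str) -> ConsequenceClass:
    """Map a consequence term to LOF / MISSENSE / OTHER."""
    if term in LOF_TERMS:
        return ConsequenceClass.LOF
    if term == "missense_variant":
        return ConsequenceClass.MISSENSE
    if term not in _KNOWN_TERMS:
        logger.warning("unknown consequence term %r classified as OTHER", term)
    return ConsequenceClass.OTHER


def is_rare(freq: FrequencyAnnotation, threshold: float = MAF_THRESHOLD) -> bool:
    """True iff every reported database frequency is <= threshold.

    A null field means the variant is absent from that database and counts
    as frequency 0, i.e. it never disqualifies the variant.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold={threshold} outside (0, 1)")
    return all(v is None or v <= threshold for v in freq.values())


def classify_predictions(profile: PredictionProfile) -> dict:
    """Per-tool deleteriousness flags plus any/all-five summaries.

    PolyPhen-2 counts both "probably" and "possibly" damaging as flagged;
    CADD and REVEL thresholds are inclusive. MISSING calls and null scores
    contribute False everywhere.
    """
    flags = {
        "condel": profile.condel_call is CondelCall.DELETERIOUS,
        "polyphen": profile.polyphen_call in (PolyphenCall.PROBABLY, PolyphenCall.POSSIBLY),
        "sift": profile.sift_call is SiftCall.DELETERIOUS,
        "cadd": profile.cadd_score is not None and profile.cadd_score >= CADD_THRESHOLD,
        "revel": profile.revel_score is not None and profile.revel_score >= REVEL_THRESHOLD,
    }
    flags["any"] = any(flags[t] for t in TOOL_NAMES)
    flags["all_five"] = all(flags[t] for t in TOOL_NAMES)
    return flags


def classify_variant(
    record: RawVariantRecord, maf_threshold: float = MAF_THRESHOLD
) -> ClassifiedVariant:
    """Run the full cascade on one record.

    When the record carries per-transcript consequence terms the class is
    read off the canonical transcript; otherwise the record-level term is
    used as-is.
    """
    canonical_id: Optional[str] = None
    term = record.consequence_term
    if record.transcripts:
        canonical_id = select_canonical_transcript(record.transcripts)
        per_tx = {t.transcript_id: t.consequence_term for t in record.transcripts}
        if per_tx.get(canonical_id) is not None:
            term = per_tx[canonical_id]

    flags = classify_predictions(record.predictions)
    return ClassifiedVariant(
        source=record,
        passed_qc=passes_qc(record),
        canonical_transcript_id=canonical_id,
        consequence_class=classify_consequence(term),
        is_rare=is_rare(record.frequencies, maf_threshold),
        tool_flags={t: flags[t] for t in TOOL_NAMES},
        any_deleterious=flags["any"],
        all_five_deleterious=flags["all_five"],
    )
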