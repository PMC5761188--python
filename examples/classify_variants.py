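"""Classify annotated variant records.

Each record passes through caller-consensus QC (>= 2 callers, depth >= 10,
alt fraction >= 20%), the dual-database rarity filter (MAF <= 0.001), the
consequence classifier (LoF / missense / other) and the five-tool in-silico
deleteriousness ensemble.
"""

from rareburden.classify import classify_variant
from rareburden.types import (
    CondelCall,
    FrequencyAnnotation,
    PolyphenCall,
    PredictionProfile,
    RawVariantRecord,
    SiftCall,
)

records = [
    RawVariantRecord(
        subject_id="S1", gene="ADAM29", cds_change="c.2020A>T",
        consequence_term="stop_gained", caller_support=3, total_depth=150,
        alt_fraction=0.45, frequencies=FrequencyAnnotation(),  # absent everywhere
    ),
    RawVariantRecord(
        subject_id="S2", gene="CASP8", cds_change="c.100G>A",
        consequence_term="missense_variant", caller_support=2, total_depth=80,
        alt_fraction=0.38,
        frequencies=FrequencyAnnotation(exac_nfe=0.0004),
        predictions=PredictionProfile(
            condel_call=CondelCall.DELETERIOUS,
            polyphen_call=PolyphenCall.PROBABLY,
            sift_call=SiftCall.DELETERIOUS,
            cadd_score=24.1,
            revel_score=0.72,
        ),
    ),
    RawVariantRecord(
        subject_id="S3", gene="TET2", cds_change="c.50C>T",
        consequence_term="missense_variant", caller_support=1, total_depth=200,
        alt_fraction=0.5,  # single caller: fails QC despite high depth
    ),
]

for rec in records:
    cv = classify_variant(rec)
    print(
        f"{rec.gene} {rec.cds_change}: qc={cv.passed_qc} rare={cv.is_rare} "
        f"class={cv.consequence_class.value} all_five={cv.all_five_deleterious}"
    )

# Only records with qc=True and rare=True ("qualifying") reach carrier
# counting; the all_five flag marks missense variants every tool calls
# deleterious.
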