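"""Carrier collapsing and the per-gene / per-set / stratified burden rows."""

import math

import pytest

from rareburden import fixtures
from rareburden.burden import (
    AnalysisConfig,
    CarrierMatrix,
    collapse_carriers,
    gene_burden,
    run_full_analysis,
    set_burden,
    stratified_missense_burden,
)
from rareburden.classify import classify_variant
from rareburden.simulate import GeneSimSettings, SimulationConfig, simulate_cohort
from rareburden.types import (
    Cohort,
    CohortDataset,
    CondelCall,
    ConsequenceClass,
    Criterion,
    FrequencyAnnotation,
    GeneRecord,
    OddsRatioKind,
    PolyphenCall,
    PredictionProfile,
    RawVariantRecord,
    SiftCall,
    SubjectRecord,
    TestKind,
    ValidationError,
)
from tests.conftest import null_config

LOF = ConsequenceClass.LOF
MISSENSE = ConsequenceClass.MISSENSE


def subjects(n_case=4, n_control=4):
    return [SubjectRecord(f"CA{i}", Cohort.CASE) for i in range(n_case)] + [
        SubjectRecord(f"CO{i}", Cohort.CONTROL) for i in range(n_control)
    ]


def variant(subject, gene, term="missense_variant", preds=None):
    return RawVariantRecord(
        subject_id=subject,
        gene=gene,
        consequence_term=term,
        caller_support=3,
        total_depth=100,
        alt_fraction=0.4,
        frequencies=FrequencyAnnotation(),
        predictions=preds or PredictionProfile(),
    )


def tiny_manifest():
    return [
        GeneRecord("NRIP1", Criterion.GWAS_PROPOSED, ("rs2823093",)),
        GeneRecord("TET2", Criterion.GWAS_PROPOSED, ("rs9790517",)),
        GeneRecord("SNX32", Criterion.NEIGHBOURING, ("rs3903072",)),
    ]


class TestCollapsing:
    def test_two_variants_same_gene_count_once(self):
        subs = subjects()
        recs = [variant("CA0", "NRIP1"), variant("CA0", "NRIP1")]
        classified = [classify_variant(v) for v in recs]
        assert collapse_carriers(classified, subs, "NRIP1", MISSENSE) == (1, 0)

    def test_cross_set_subject_counts_once_in_total(self):
        subs = subjects()
        recs = [
            variant("CA0", "TET2", term="stop_gained"),    # GWAS-proposed gene
            variant("CA0", "SNX32", term="stop_gained"),   # neighbouring gene
        ]
        classified = [classify_variant(v) for v in recs]
        manifest = tiny_manifest()
        assert collapse_carriers(classified, subs, "GWAS_PROPOSED", LOF, manifest) == (1, 0)
        assert collapse_carriers(classified, subs, "NEIGHBOURING", LOF, manifest) == (1, 0)
        assert collapse_carriers(classified, subs, "TOTAL", LOF, manifest) == (1, 0)

    def test_unknown_gene_scope_rejected(self):
        classified = [classify_variant(variant("CA0", "TET2"))]
        with pytest.raises(ValidationError, match="unknown gene"):
            collapse_carriers(classified, subjects(), "NOPE", LOF, tiny_manifest())

    def test_set_union_oracle_on_simulated_truth(self):
        cfg = SimulationConfig(
            n_cases=300, n_controls=300,
            default_gene=GeneSimSettings(0.01, 0.03, 1.5, 1.2), seed=13,
        )
        dataset, truth = simulate_cohort(cfg)
        classified = [classify_variant(v) for v in dataset.variants]
        matrix = CarrierMatrix(classified, dataset.subjects)
        genes = {g.symbol for g in dataset.manifest}
        for cls in (LOF, MISSENSE):
            per_gene = {g: matrix.carriers({g}, cls) for g in genes}
            total = matrix.carriers(genes, cls)
            for arm in (0, 1):
                sums = sum(v[arm] for v in per_gene.values())
                biggest = max(v[arm] for v in per_gene.values())
                assert biggest <= total[arm] <= sums
            # unique-subject oracle straight from the truth labels
            expected = {s for (s, g, c) in truth.carriers if c is cls}
            exp_case = sum(1 for s in expected if s.startswith("CASE"))
            assert total == (exp_case, len(expected) - exp_case)


class TestGeneBurden:
    def test_tet2_lof_matches_published_row(self, spiked_dataset):
        dataset, _ = spiked_dataset
        row = gene_burden(dataset, "TET2", LOF)
        assert (row.carriers_case, row.carriers_control) == (5, 2)
        assert round(row.p, 3) == 0.456
        assert row.or_estimate.value == pytest.approx(2.27, abs=0.005)
        assert row.ci.low == pytest.approx(0.37, abs=0.005)
        assert row.ci.high == pytest.approx(23.87, abs=0.01)

    def test_nrip1_lof_zero_control_cell(self, spiked_dataset):
        dataset, _ = spiked_dataset
        row = gene_burden(dataset, "NRIP1", LOF)
        assert (row.carriers_case, row.carriers_control) == (3, 0)
        assert round(row.p, 3) == 0.251
        assert row.or_estimate.render() == "Und"
        assert row.ci.low == pytest.approx(0.37, abs=0.005)
        assert math.isinf(row.ci.high)

    def test_gene_without_carriers(self, spiked_dataset):
        dataset, _ = spiked_dataset
        row = gene_burden(dataset, "FGFR2", LOF)  # no LoF variants detected
        assert (row.carriers_case, row.carriers_control) == (0, 0)
        assert row.p == 1.0
        assert row.or_estimate.kind is OddsRatioKind.UNDEFINED
        assert row.ci.low == 0.0 and math.isinf(row.ci.high)

    def test_unknown_gene_rejected(self, spiked_dataset):
        dataset, _ = spiked_dataset
        with pytest.raises(ValidationError):
            gene_burden(dataset, "BRCA1", LOF)


class TestSetBurden:
    def test_gwas_proposed_lof_significant_excess(self, spiked_dataset):
        dataset, _ = spiked_dataset
        row = set_burden(dataset, "GWAS_PROPOSED", LOF)
        assert (row.carriers_case, row.carriers_control) == (17, 4)
        assert round(row.p, 3) == 0.008
        assert row.or_estimate.value == pytest.approx(3.89, abs=0.005)
        assert row.ci.low == pytest.approx(1.26, abs=0.005)
        assert row.ci.high == pytest.approx(15.95, abs=0.01)
        assert row.test is TestKind.FISHER

    def test_neighbouring_lof_balanced(self, spiked_dataset):
        dataset, _ = spiked_dataset
        row = set_burden(dataset, "NEIGHBOURING", LOF)
        assert (row.carriers_case, row.carriers_control) == (9, 9)

    def test_missense_aggregate_uses_yates_by_default(self, spiked_dataset):
        dataset, _ = spiked_dataset
        row = set_burden(dataset, "TOTAL", MISSENSE)
        assert row.test is TestKind.CHISQ_YATES

    def test_test_override(self, spiked_dataset):
        dataset, _ = spiked_dataset
        row = set_burden(dataset, "TOTAL", LOF, test_override=TestKind.CHISQ_YATES)
        assert row.test is TestKind.CHISQ_YATES

    def test_empty_set_rejected(self):
        manifest = [g for g in tiny_manifest() if g.criterion is Criterion.GWAS_PROPOSED]
        dataset = CohortDataset(subjects=subjects(), variants=[], manifest=manifest)
        with pytest.raises(ValidationError, match="empty"):
            set_burden(dataset, "NEIGHBOURING", LOF)


def deleterious_profile():
    return PredictionProfile(
        condel_call=CondelCall.DELETERIOUS,
        polyphen_call=PolyphenCall.PROBABLY,
        sift_call=SiftCall.DELETERIOUS,
        cadd_score=25.0,
        revel_score=0.8,
    )


class TestStrata:
    def make_dataset(self):
        subs = subjects(6, 6)
        recs = [
            variant("CA0", "TET2", preds=deleterious_profile()),
            variant("CA1", "TET2",
                    preds=PredictionProfile(condel_call=CondelCall.DELETERIOUS)),
            variant("CO0", "TET2", preds=PredictionProfile(cadd_score=14.0)),
        ]
        return CohortDataset(subjects=subs, variants=recs, manifest=tiny_manifest())

    def test_stratum_counts_follow_tool_flags(self):
        ds = self.make_dataset()
        assert (stratified_missense_burden(ds, "ALL").carriers_case,
                stratified_missense_burden(ds, "ALL").carriers_control) == (2, 1)
        condel = stratified_missense_burden(ds, "CONDEL")
        assert (condel.carriers_case, condel.carriers_control) == (2, 0)
        all_five = stratified_missense_burden(ds, "ALL_FIVE")
        assert (all_five.carriers_case, all_five.carriers_control) == (1, 0)
        cadd = stratified_missense_burden(ds, "CADD15")
        assert (cadd.carriers_case, cadd.carriers_control) == (1, 0)

    def test_all_scores_below_cadd_threshold_empty_stratum(self):
        subs = subjects(3, 3)
        recs = [variant("CA0", "TET2", preds=PredictionProfile(cadd_score=10.0))]
        ds = CohortDataset(subjects=subs, variants=recs, manifest=tiny_manifest())
        row = stratified_missense_burden(ds, "CADD15")
        assert (row.carriers_case, row.carriers_control) == (0, 0)

    def test_unknown_stratum_rejected(self):
        with pytest.raises(ValidationError, match="stratum"):
            stratified_missense_burden(self.make_dataset(), "SPLICEAI")

    def test_strata_nested_within_all_on_simulated_cohort(self):
        cfg = SimulationConfig(
            n_cases=400, n_controls=400,
            default_gene=GeneSimSettings(0.0, 0.02, 1.0, 1.3), seed=8,
        )
        dataset, _ = simulate_cohort(cfg)
        report = run_full_analysis(dataset)
        all_row = next(r for r in report.stratum_rows if r.scope == "ALL")
        for row in report.stratum_rows:
            assert row.carriers_case <= all_row.carriers_case
            assert row.carriers_control <= all_row.carriers_control


class TestFullAnalysis:
    def test_spiked_cohort_reproduces_published_lof_table(self, spiked_report):
        """Per-gene LoF counts and statistics match the published table for
        all 20 genes with at least one LoF carrier (one cell of the published
        table is internally inconsistent and is a missense cell anyway)."""
        printed = fixtures.load_gene_carrier_counts().dropna(subset=["lof_case"])
        rows = {
            r.scope: r for r in spiked_report.gene_rows if r.consequence_class == "LOF"
        }
        assert len(printed) == 20
        for _, exp in printed.iterrows():
            row = rows[exp.gene]
            assert (row.carriers_case, row.carriers_control) == (
                int(exp.lof_case), int(exp.lof_control)
            ), exp.gene
            assert row.p == pytest.approx(float(exp.lof_p), abs=6e-4)
            lo_s, hi_s = str(exp.lof_ci).split("-")
            assert row.ci.low == pytest.approx(float(lo_s), abs=6e-3)
            if hi_s == "inf":
                assert math.isinf(row.ci.high)
            else:
                assert row.ci.high == pytest.approx(float(hi_s), rel=2e-3)
            if str(exp.lof_or) == "Und":
                assert row.or_estimate.kind is OddsRatioKind.UNDEFINED
            elif str(exp.lof_or) == "0":
                assert row.or_estimate.kind is OddsRatioKind.ZERO
            else:
                assert row.or_estimate.value == pytest.approx(
                    float(exp.lof_or), abs=6e-3
                )

    def test_pooled_rows_match_published_aggregates(self, spiked_report):
        rows = {(r.scope, r.consequence_class): r for r in spiked_report.set_rows}
        total = rows[("TOTAL", "LOF")]
        assert (total.carriers_case, total.carriers_control) == (26, 13)
        assert round(total.p, 3) == 0.077
        gwas = rows[("GWAS_PROPOSED", "LOF")]
        assert (gwas.carriers_case, gwas.carriers_control) == (17, 4)
        assert round(gwas.p, 3) == 0.008

    def test_report_covers_every_gene_and_class_once(self, spiked_report):
        manifest = fixtures.load_gene_manifest()
        seen = {(r.scope, r.consequence_class) for r in spiked_report.gene_rows}
        assert len(spiked_report.gene_rows) == len(seen) == 2 * len(manifest)
        assert len(spiked_report.set_rows) == 6
        assert len(spiked_report.stratum_rows) == 7

    def test_denominators_constant_across_rows(self, spiked_report):
        for row in spiked_report.rows:
            assert (row.n_case, row.n_control) == (1043, 944)

    def test_null_cohort_gives_empty_unit_rows(self):
        dataset, _ = simulate_cohort(null_config(seed=99))
        report = run_full_analysis(dataset)
        for row in report.rows:
            assert (row.carriers_case, row.carriers_control) == (0, 0)
            assert row.p == 1.0

    def test_label_swap_inverts_finite_odds_ratios(self):
        cfg = SimulationConfig(
            n_cases=500, n_controls=500,
            default_gene=GeneSimSettings(0.0, 0.05, 1.0, 2.0), seed=31,
        )
        dataset, _ = simulate_cohort(cfg)
        flipped = CohortDataset(
            subjects=[
                SubjectRecord(
                    s.subject_id,
                    Cohort.CONTROL if s.cohort is Cohort.CASE else Cohort.CASE,
                )
                for s in dataset.subjects
            ],
            variants=dataset.variants,
            manifest=dataset.manifest,
        )
        orig = run_full_analysis(dataset)
        swap = run_full_analysis(flipped)
        pairs = 0
        for r1, r2 in zip(orig.set_rows, swap.set_rows):
            if r1.or_estimate.kind is OddsRatioKind.FINITE and r1.or_estimate.value:
                assert r2.or_estimate.value == pytest.approx(
                    1.0 / r1.or_estimate.value, rel=1e-9
                )
                pairs += 1
        assert pairs > 0

    def test_report_is_deterministic_and_serialisable(self, spiked_dataset, tmp_path):
        from rareburden.io import write_burden_report

        dataset, _ = spiked_dataset
        r1 = run_full_analysis(dataset)
        r2 = run_full_analysis(dataset)
        assert r1.rows == r2.rows
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_burden_report(r1, p1)
        write_burden_report(r2, p2)
        assert p1.read_bytes() == p2.read_bytes()


class TestRecomputedFromPrintedCounts:
    def test_gene_missense_statistics_match_printed_table(self):
        """Recompute every per-gene missense Fisher comparison from the
        packaged counts; one printed p (NRIP1) is inconsistent with its own
        printed counts and OR, so that single cell is skipped."""
        from rareburden.exact import exact_ci, fisher_two_sided_p, sample_odds_ratio
        from rareburden.types import ContingencyTable2x2

        df = fixtures.load_gene_carrier_counts()
        for _, exp in df.iterrows():
            a, c = int(exp.mis_case), int(exp.mis_control)
            t = ContingencyTable2x2(a, 1043 - a, c, 944 - c)
            if exp.gene != "NRIP1":
                assert fisher_two_sided_p(t) == pytest.approx(
                    float(exp.mis_p), abs=6e-4
                ), exp.gene
            est = sample_odds_ratio(t)
            if str(exp.mis_or) == "0":
                assert est.kind is OddsRatioKind.ZERO
            else:
                assert est.value == pytest.approx(float(exp.mis_or), abs=6e-3)
            ci = exact_ci(t)
            lo_s, hi_s = str(exp.mis_ci).split("-")
            assert ci.low == pytest.approx(float(lo_s), abs=6e-3)
            assert ci.high == pytest.approx(float(hi_s), rel=2e-3, abs=6e-3)

    def test_prediction_strata_match_printed_table(self):
        from rareburden.exact import chisq_yates_p, exact_ci, sample_odds_ratio
        from rareburden.types import ContingencyTable2x2

        df = fixtures.load_prediction_strata()
        for _, exp in df.iterrows():
            a, c = int(exp.case_carriers), int(exp.control_carriers)
            t = ContingencyTable2x2(a, 1043 - a, c, 944 - c)
            assert chisq_yates_p(t) == pytest.approx(float(exp.p), abs=6e-4), exp.stratum
            assert sample_odds_ratio(t).value == pytest.approx(float(exp["or"]), abs=6e-3)
            lo_s, hi_s = str(exp.ci).split("-")
            ci = exact_ci(t)
            assert ci.low == pytest.approx(float(lo_s), abs=6e-3)
            assert ci.high == pytest.approx(float(hi_s), rel=2e-3, abs=6e-3)
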