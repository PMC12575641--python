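"""Second-hit detection, allele-resolved LOH and the category cascade."""

import math

import numpy as np
import pytest

from gbmgermline.config import LOHParams, PipelineConfig
from gbmgermline.evidence import (
    assign_category,
    call_loh,
    compute_tmb,
    detect_second_hit,
    is_common_arm_event,
)
from gbmgermline.types import (
    CopyNumberSegment,
    GenomicInterval,
    GermlineCall,
    LOHCall,
    LostAllele,
    PGV,
    SecondHitEvidence,
    SomaticCall,
    TumorPhenotype,
    ZygosityContext,
)


def _pgv(panel, gene="BRCA1", patient="p1", zygosity="dominant_monoallelic",
         tumor_reads=(40, 95), genotype="het"):
    region = panel.regions[gene][0]
    call = GermlineCall(
        patient_id=patient, gene=gene, variant_id=f"{patient}:{gene}:v",
        kind="snv", effect="nonsense", genotype=genotype,
        chrom=region.chrom, pos=(region.start + region.end) // 2,
        tumor_reads=tumor_reads, normal_reads=(15, 31),
    )
    return PGV(call=call, final_class=5, gene_def=panel.gene(gene),
               zygosity_context=ZygosityContext(zygosity))


def _segment(panel, gene, patient="p1", total=1.0, minor=0.0):
    return CopyNumberSegment(patient_id=patient, interval=panel.regions[gene][0],
                             total_cn=total, minor_cn=minor)


class TestTMB:
    def test_zero_calls(self):
        assert compute_tmb([], 2900) == 0.0

    def test_simple_rate(self):
        calls = [SomaticCall(patient_id="p", variant_id=f"s{i}", kind="indel",
                             effect="frameshift") for i in range(8700)]
        assert compute_tmb(calls, 2900) == pytest.approx(3.0)

    def test_zero_genome_size_errors(self):
        with pytest.raises(ValueError):
            compute_tmb([], 0)

    def test_poisson_sampling_recovers_rate(self):
        rng = np.random.default_rng(0)
        lam, mb = 3.0, 500.0
        n = rng.poisson(lam * mb)
        calls = [SomaticCall(patient_id="p", variant_id=f"s{i}", kind="snv",
                             effect="missense", context="ACA>AAA") for i in range(n)]
        se = math.sqrt(lam / mb)
        assert abs(compute_tmb(calls, mb) - lam) < 3 * se


class TestCallLOH:
    def test_pure_tumor_single_copy_alt_means_wildtype_lost(self, panel):
        pgv = _pgv(panel, tumor_reads=(30, 30))
        loh = call_loh(pgv, (30, 30), 1.0, _segment(panel, "BRCA1"))
        assert loh.loh_present and loh.lost_allele is LostAllele.WILDTYPE
        assert loh.mutant_copies_hat == 1

    def test_pure_tumor_zero_alt_means_variant_lost(self, panel):
        pgv = _pgv(panel, tumor_reads=(0, 30))
        loh = call_loh(pgv, (0, 30), 1.0, _segment(panel, "BRCA1"))
        assert loh.loh_present and loh.lost_allele is LostAllele.MUTANT
        assert "variant lost in tumor" in loh.note

    def test_balanced_segment_no_loh(self, panel):
        pgv = _pgv(panel, tumor_reads=(48, 95))
        loh = call_loh(pgv, (48, 95), 0.8, _segment(panel, "BRCA1", total=2.0, minor=1.0))
        assert not loh.loh_present
        assert loh.lost_allele is LostAllele.UNDETERMINED

    def test_low_purity_undetermined(self, panel):
        pgv = _pgv(panel)
        loh = call_loh(pgv, (20, 30), 0.1, _segment(panel, "BRCA1"))
        assert loh.loh_present and loh.lost_allele is LostAllele.UNDETERMINED

    def test_homozygous_germline_undetermined(self, panel):
        pgv = _pgv(panel, genotype="hom")
        loh = call_loh(pgv, (30, 30), 1.0, _segment(panel, "BRCA1"))
        assert loh.lost_allele is LostAllele.UNDETERMINED
        assert "homozygous" in loh.note

    def test_zero_reads_error(self, panel):
        with pytest.raises(ValueError):
            call_loh(_pgv(panel), (0, 0), 1.0, _segment(panel, "BRCA1"))

    def test_matches_enumeration_oracle(self, panel):
        """The m-hat decision equals an independent exhaustive-likelihood scan."""
        rng = np.random.default_rng(11)
        pgv = _pgv(panel)
        params = LOHParams()
        for _ in range(500):
            purity = float(rng.uniform(0.0, 1.0))
            cn = float(rng.choice([0.0, 1.0, 1.7, 2.0, 3.0, 4.2]))
            minor = float(rng.uniform(0, cn / 2)) if cn > 0 else 0.0
            depth = int(rng.integers(20, 120))
            alt = int(rng.integers(0, depth + 1))
            seg = _segment(panel, "BRCA1", total=cn, minor=minor)
            loh = call_loh(pgv, (alt, depth), purity, seg, params)
            m_hat = _oracle_mhat(alt, depth, purity, cn)
            assert loh.mutant_copies_hat == m_hat

    def test_simulated_loci_recover_lost_allele(self, panel):
        rng = np.random.default_rng(5)
        pgv_template = _pgv(panel)
        correct = total = 0
        for _ in range(1500):
            purity = float(rng.uniform(0.2, 1.0))
            m_true = int(rng.integers(0, 2))
            f = (purity * m_true + (1 - purity)) / (purity + (1 - purity) * 2)
            alt = int(rng.binomial(90, f))
            loh = call_loh(pgv_template, (alt, 90), purity, _segment(panel, "BRCA1"))
            want = LostAllele.MUTANT if m_true == 0 else LostAllele.WILDTYPE
            correct += loh.lost_allele is want
            total += 1
        assert correct / total >= 0.95


def _oracle_mhat(alt, depth, purity, cn):
    """Naive log-binomial scan over mutant-copy hypotheses."""
    denom = purity * cn + (1 - purity) * 2
    best, best_ll = 0, -math.inf
    for m in range(int(round(cn)) + 1):
        f = (purity * m + (1 - purity)) / denom if denom > 0 else 0.5
        f = min(max(f, 1e-9), 1 - 1e-9)
        ll = (math.lgamma(depth + 1) - math.lgamma(alt + 1)
              - math.lgamma(depth - alt + 1)
              + alt * math.log(f) + (depth - alt) * math.log(1 - f))
        if ll > best_ll:
            best, best_ll = m, ll
    return best


class TestDetectSecondHit:
    def test_same_gene_truncating_calls_give_biallelic(self, panel):
        pgv = _pgv(panel, gene="MSH6", tumor_reads=(48, 95))
        hits = [SomaticCall(patient_id="p1", variant_id=f"h{i}", kind="snv",
                            effect="nonsense", gene="MSH6", context="ACA>ATA")
                for i in range(2)]
        ev = detect_second_hit(pgv, hits, [_segment(panel, "MSH6", total=2, minor=1)], 0.8)
        assert ev.somatic_small_hit is not None
        assert ev.biallelic_inactivation

    def test_no_events_diploid_balanced_no_hit(self, panel):
        pgv = _pgv(panel, gene="MSH6", tumor_reads=(48, 95))
        ev = detect_second_hit(pgv, [], [_segment(panel, "MSH6", total=2, minor=1)], 0.8)
        assert ev.somatic_small_hit is None
        assert not ev.biallelic_inactivation
        assert not ev.loh.loh_present

    def test_focal_deletion_counts_as_hit(self, panel):
        pgv = _pgv(panel, gene="MSH6", tumor_reads=(1, 95))
        ev = detect_second_hit(pgv, [], [_segment(panel, "MSH6", total=0.1, minor=0.0)], 0.8)
        assert ev.focal_deletion and ev.biallelic_inactivation

    def test_only_same_gene_calls_cited(self, panel):
        """Permutation property: evidence never cites another gene's events."""
        rng = np.random.default_rng(2)
        genes = panel.symbols
        pgv = _pgv(panel, gene="MSH6", tumor_reads=(48, 95))
        for _ in range(20):
            calls = [SomaticCall(patient_id="p1", variant_id=f"h{i}", kind="indel",
                                 effect="frameshift", gene=str(rng.choice(genes)))
                     for i in range(10)]
            ev = detect_second_hit(pgv, calls, [], 0.8)
            if ev.somatic_small_hit is not None:
                assert ev.somatic_small_hit.gene == "MSH6"

    def test_synonymous_somatic_ignored(self, panel):
        pgv = _pgv(panel, gene="MSH6", tumor_reads=(48, 95))
        calls = [SomaticCall(patient_id="p1", variant_id="syn", kind="snv",
                             effect="synonymous", gene="MSH6", context="ACA>ATA")]
        ev = detect_second_hit(pgv, calls, [], 0.8)
        assert ev.somatic_small_hit is None


class TestCommonArmEvent:
    def test_chr10_arm_loh_in_glioblastoma(self):
        seg = CopyNumberSegment(patient_id="p",
                                interval=GenomicInterval("chr10", 0, 135_000_000),
                                total_cn=1.0, minor_cn=0.0, arm_label="chr10")
        assert is_common_arm_event(seg, "glioblastoma")

    def test_focal_deletion_is_not_arm_event(self):
        seg = CopyNumberSegment(patient_id="p",
                                interval=GenomicInterval("chr10", 0, 2_000_000),
                                total_cn=0.0, minor_cn=0.0, arm_label="chr10")
        assert not is_common_arm_event(seg, "glioblastoma")

    def test_chr7_requires_gain(self):
        lost = CopyNumberSegment(patient_id="p",
                                 interval=GenomicInterval("chr7", 0, 150_000_000),
                                 total_cn=3.0, minor_cn=1.0, arm_label="chr7")
        assert is_common_arm_event(lost, "glioblastoma")

    def test_unknown_tumor_type_false_with_warning(self):
        seg = CopyNumberSegment(patient_id="p",
                                interval=GenomicInterval("chr10", 0, 135_000_000),
                                total_cn=1.0, minor_cn=0.0)
        with pytest.warns(UserWarning):
            assert not is_common_arm_event(seg, "meningioma")


class TestAssignCategory:
    def test_all_fixture_rows_match_printed_categories(self, table1_run, fixture):
        printed = {v.variant_id: v.category for v in fixture.variants if v.is_pgv}
        assigned = {r.pgv.call.variant_id: r.category.value for r in table1_run.results}
        assert assigned == printed

    def test_associated_gene_without_somatic_data_is_category_2(self, panel):
        pgv = _pgv(panel, gene="NF1")
        cat = assign_category(pgv, SecondHitEvidence(), TumorPhenotype())
        assert cat.value == 2 and cat.rationale.startswith("d:")

    def test_chek2_without_second_hit_is_category_3(self, panel):
        pgv = _pgv(panel, gene="CHEK2")
        assert assign_category(pgv, SecondHitEvidence(), TumorPhenotype()).value == 3

    def test_recessive_monoallelic_is_3_even_with_second_hit(self, panel):
        pgv = _pgv(panel, gene="BUB1B", zygosity="recessive_monoallelic")
        ev = SecondHitEvidence(focal_deletion=True, biallelic_inactivation=True)
        cat = assign_category(pgv, ev, TumorPhenotype())
        assert cat.value == 3
        assert "somatic second hit present" in cat.rationale

    def test_arm_loh_counts_as_hit_flag(self, panel):
        pgv = _pgv(panel, gene="SUFU")
        loh = LOHCall(loh_present=True, lost_allele="wildtype", focal=False,
                      arm_event_label="chr10")
        ev = SecondHitEvidence(loh=loh, biallelic_inactivation=True)
        assert assign_category(pgv, ev, TumorPhenotype()).value == 2
        config = PipelineConfig()
        config.categories.arm_loh_counts_as_hit = True
        assert assign_category(pgv, ev, TumorPhenotype(), config).value == 1

    def test_adding_somatic_hit_never_weakens_category(self, panel):
        """Monotonicity: a same-gene somatic hit can only strengthen causality."""
        hit = SomaticCall(patient_id="p1", variant_id="h", kind="indel",
                          effect="frameshift", gene="X")
        phen_msi = TumorPhenotype(msi_rate=5.0, msi_status="msi",
                                  exposures={"SBS6": 0.5, "SBS1": 0.5})
        for gene in ("MSH6", "BRCA1", "NF1", "SUFU", "CHEK2", "BLM"):
            for zyg in ("dominant_monoallelic", "recessive_monoallelic"):
                for phen in (TumorPhenotype(), phen_msi):
                    pgv = _pgv(panel, gene=gene, zygosity=zyg)
                    without = assign_category(pgv, SecondHitEvidence(), phen)
                    ev = SecondHitEvidence(somatic_small_hit=hit,
                                           biallelic_inactivation=True)
                    with_hit = assign_category(pgv, ev, phen)
                    assert with_hit.value <= without.value
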