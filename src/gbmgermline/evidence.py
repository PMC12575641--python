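"""Per-PGV somatic evidence and causality categories.

Tumor-suppressor predisposition follows the two-hit model: the germline
variant is the first hit, and causality in the tumor is supported by a second
somatic hit — a small variant, a focal deletion, or loss of heterozygosity
(LOH) that removed the *wild-type* allele.  Which allele was lost is decided
by maximum binomial likelihood over the number of mutant copies, mixing tumor
and normal cells by purity:

    f(m) = (purity * m + (1 - purity) * 1) / (purity * CN + (1 - purity) * 2)

for a heterozygous germline variant on a segment of tumor total copy number
CN.  m_hat = 0 means the mutant allele was lost; m_hat = round(CN) > 0 with
low minor copy number means the wild-type allele was lost.

Causality categories (1 = causal, 2 = known predisposition gene without
demonstrated causality, 3 = unlikely contributor) are assigned by a pure rule
cascade over zygosity context, gene association, second-hit evidence and the
genome-wide phenotype (MSI, mutational signatures).  Arm-level LOH on arms
that are near-universally altered in the tumor type (chr10 loss, chr7 gain in
glioblastoma) is not accepted as a demonstrated second hit by default.
"""

from __future__ import annotations

import warnings
from typing import List, Optional

import numpy as np
from scipy.stats import binom

from .config import CategoryParams, LOHParams, PipelineConfig
from .phenotypes import phenotype_match
from .types import (
    CausalityCategory,
    CopyNumberSegment,
    Effect,
    Genotype,
    LOHCall,
    LostAllele,
    MSIStatus,
    PGV,
    PhenotypeClass,
    SecondHitEvidence,
    SomaticCall,
    TumorPhenotype,
    VariantKind,
    ZygosityContext,
)

SMALL_KINDS = (VariantKind.SNV, VariantKind.MNV, VariantKind.INDEL)


def compute_tmb(somatic_calls: List[SomaticCall], genome_size_mb: float) -> float:
    """Tumor mutational burden: small somatic variants per megabase."""
    if genome_size_mb <= 0:
        raise ValueError("genome_size_mb must be > 0")
    n = sum(1 for c in somatic_calls if c.kind in SMALL_KINDS)
    return n / genome_size_mb


def call_loh(
    pgv: PGV,
    tumor_reads: tuple,
    purity: float,
    segment: CopyNumberSegment,
    params: Optional[LOHParams] = None,
) -> LOHCall:
    """Allele-resolved LOH call at a PGV locus.

    LOH is present when the segment's minor copy number falls below the
    threshold.  The lost-allele identity comes from the binomial likelihood of
    the tumor alt read count under each mutant-copy hypothesis
    m in {0, ..., round(CN)}; the call is undetermined when the best m is
    interior, when purity is below the usable minimum, or when the germline
    genotype is homozygous (no heterozygosity to lose).
    """
    params = params or LOHParams()
    alt, total = int(tumor_reads[0]), int(tumor_reads[1])
    if total <= 0:
        raise ValueError("call_loh: tumor read total must be > 0")
    if not (0.0 <= purity <= 1.0):
        raise ValueError(f"call_loh: purity {purity} outside [0,1]")

    focal = segment.interval.length < params.focal_max_mb * 1e6
    arm_label = None
    if segment.interval.length >= params.arm_min_mb * 1e6:
        arm_label = segment.arm_label or segment.interval.chrom

    loh_present = segment.minor_cn < params.minor_cn_threshold
    if pgv.call.genotype is Genotype.HOM:
        return LOHCall(
            loh_present=loh_present,
            lost_allele=LostAllele.UNDETERMINED,
            focal=focal,
            arm_event_label=arm_label,
            note="homozygous germline genotype; allele identity undetermined",
        )

    cn = max(float(segment.total_cn), 0.0)
    m_max = max(int(round(cn)), 0)
    denom = purity * cn + (1.0 - purity) * 2.0
    logliks = np.full(m_max + 1, -np.inf)
    if denom > 0:
        for m in range(m_max + 1):
            f = (purity * m + (1.0 - purity) * 1.0) / denom
            f = min(max(f, 1e-9), 1.0 - 1e-9)
            logliks[m] = binom.logpmf(alt, total, f)
    m_hat = int(np.argmax(logliks))
    fit_ll = float(logliks[m_hat])

    if not loh_present:
        lost, note = LostAllele.UNDETERMINED, ""
    elif purity < params.min_purity:
        lost, note = LostAllele.UNDETERMINED, f"purity {purity:.2f} below usable minimum"
    elif denom <= 0:
        lost, note = LostAllele.UNDETERMINED, "degenerate copy state"
    elif m_hat == 0:
        lost, note = LostAllele.MUTANT, "variant lost in tumor"
    elif m_hat == m_max and m_max > 0:
        lost, note = LostAllele.WILDTYPE, ""
    else:
        lost, note = LostAllele.UNDETERMINED, "intermediate mutant copy number"

    return LOHCall(
        loh_present=loh_present,
        lost_allele=lost,
        focal=focal,
        arm_event_label=arm_label,
        fit_loglik=fit_ll,
        mutant_copies_hat=m_hat,
        note=note,
    )


def _segment_at(segments: List[CopyNumberSegment], chrom, pos) -> Optional[CopyNumberSegment]:
    if chrom is None or pos is None:
        return None
    for seg in segments:
        if seg.interval.contains(chrom, pos):
            return seg
    return None


def _gene_focal_deletion(
    segments: List[CopyNumberSegment], chrom, pos, params: LOHParams
) -> bool:
    seg = _segment_at(segments, chrom, pos)
    if seg is None:
        return False
    return seg.total_cn < 0.5 and seg.interval.length < params.focal_max_mb * 1e6


def detect_second_hit(
    pgv: PGV,
    somatic_calls: List[SomaticCall],
    segments: List[CopyNumberSegment],
    purity: float,
    params: Optional[LOHParams] = None,
) -> SecondHitEvidence:
    """Assemble same-gene somatic evidence for one PGV.

    Only events in the PGV's own gene count: a non-synonymous somatic small
    variant, a focal homozygous deletion, or LOH with the wild-type allele
    lost.
    """
    params = params or LOHParams()
    small_hits = [
        c for c in somatic_calls
        if c.patient_id == pgv.patient_id
        and c.gene == pgv.gene
        and c.kind in SMALL_KINDS
        and c.effect is not Effect.SYNONYMOUS
    ]
    patient_segments = [s for s in segments if s.patient_id == pgv.patient_id]
    chrom, pos = pgv.call.chrom, pgv.call.pos
    focal_del = _gene_focal_deletion(patient_segments, chrom, pos, params)

    seg = _segment_at(patient_segments, chrom, pos)
    if seg is not None and pgv.call.tumor_reads[1] > 0:
        loh = call_loh(pgv, pgv.call.tumor_reads, purity, seg, params)
    else:
        loh = LOHCall(loh_present=False, note="no covering copy-number segment")

    evidence = SecondHitEvidence(
        somatic_small_hit=small_hits[0] if small_hits else None,
        loh=loh,
        focal_deletion=focal_del,
        notes=f"{len(small_hits)} same-gene somatic small hit(s)",
    )
    evidence.biallelic_inactivation = bool(
        evidence.somatic_small_hit or evidence.focal_deletion or evidence.wildtype_lost
    )
    return evidence


def is_common_arm_event(
    segment: CopyNumberSegment,
    tumor_type: str,
    config: Optional[CategoryParams] = None,
    minor_cn_threshold: float = 0.5,
    arm_min_mb: float = 10.0,
) -> bool:
    """Whether a segment matches the tumor type's configured common arm events.

    Focal segments never qualify; an arm qualifies when its direction matches
    (loss means reduced total copy number or LOH, gain means elevated copy
    number).  Unknown tumor types return False with a warning.
    """
    config = config or CategoryParams()
    events = config.common_arm_events.get(tumor_type)
    if events is None:
        warnings.warn(f"no common arm events configured for tumor type {tumor_type!r}")
        return False
    if segment.interval.length < arm_min_mb * 1e6:
        return False
    arm = segment.arm_label or segment.interval.chrom
    direction = events.get(arm)
    if direction is None:
        return False
    if direction == "loss":
        return segment.total_cn < 1.8 or segment.minor_cn < minor_cn_threshold
    if direction == "gain":
        return segment.total_cn > 2.5
    raise ValueError(f"unknown arm-event direction {direction!r}")


def _arm_explained(loh: LOHCall, tumor_type: str, params: CategoryParams) -> bool:
    if params.arm_loh_counts_as_hit:
        return False
    events = params.common_arm_events.get(tumor_type, {})
    return loh.arm_event_label is not None and loh.arm_event_label in events


def assign_category(
    pgv: PGV,
    evidence: SecondHitEvidence,
    phenotype: TumorPhenotype,
    config: Optional[PipelineConfig] = None,
    tumor_type: str = "glioblastoma",
) -> CausalityCategory:
    """Causality category 1/2/3 for a PGV (pure, total rule cascade).

    (a) monoallelic PGVs in recessive-pattern genes are category 3 — only
        biallelic germline inactivation confers risk there, whatever the tumor
        shows; (b) mismatch-repair genes are causal when the tumor is MSI (or
        MSI-elevated with a same-gene second hit); (c) HRD genes are causal
        with a matching signature plus biallelic inactivation; (d) other
        glioblastoma/medulloblastoma-associated genes are causal with a
        demonstrated second hit not explained by a common arm event;
        (e) non-associated genes are at most category 2 (matching findings
        without association).
    """
    config = config or PipelineConfig()
    gd = pgv.gene_def
    matched, match_label = phenotype_match(gd, phenotype, config.signatures)
    same_gene_hit = bool(
        evidence.somatic_small_hit or evidence.focal_deletion or evidence.wildtype_lost
    )
    strong_second_hit = bool(
        evidence.somatic_small_hit
        or evidence.focal_deletion
        or (evidence.wildtype_lost
            and not _arm_explained(evidence.loh, tumor_type, config.categories))
    )

    # (a) recessive-pattern monoallelic: no hereditary risk, even with a
    # somatic second hit (which is then coincidental and kept in the trace)
    if pgv.zygosity_context is ZygosityContext.RECESSIVE_MONOALLELIC:
        extra = "; somatic second hit present" if same_gene_hit else ""
        return CausalityCategory(3, f"a:recessive_monoallelic{extra}")

    # (b) mismatch-repair genes: the genome-wide MSI footprint decides
    if gd.phenotype_class is PhenotypeClass.MMR:
        if phenotype.msi_status is MSIStatus.MSI:
            return CausalityCategory(1, "b:msi_diagnostic")
        if phenotype.msi_status is MSIStatus.ELEVATED and same_gene_hit:
            return CausalityCategory(1, "b:msi_elevated_with_second_hit")
        if gd.brain_tumor_associated:
            return CausalityCategory(2, "b:mmr_without_msi")
        return CausalityCategory(3, "b:mmr_not_associated_no_msi")

    # (c) homologous-recombination genes: signature plus biallelic loss
    if gd.phenotype_class is PhenotypeClass.HRD:
        if matched and evidence.biallelic_inactivation:
            return CausalityCategory(1, f"c:biallelic_with_{match_label}")
        return CausalityCategory(2, "c:hrd_gene_without_matching_evidence")

    # (d) other brain-tumor-associated genes: need a demonstrated second hit
    if gd.brain_tumor_associated:
        if strong_second_hit:
            return CausalityCategory(1, "d:second_hit")
        if evidence.wildtype_lost:
            return CausalityCategory(2, "d:arm_level_loh_only")
        return CausalityCategory(2, "d:association_without_evidence")

    # (e) non-associated genes
    if matched or strong_second_hit:
        return CausalityCategory(2, "e:matching_findings_without_association")
    return CausalityCategory(3, "e:no_association_no_findings")
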