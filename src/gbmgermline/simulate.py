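"""Synthetic paired tumor-normal cohorts with planted ground truth.

The generator emulates the call-level structure of the study cohort: tumor
purity 0.2-1.0 with tumor depth 90-110x and normal depth 30-35x, a small
IDH-mutant fraction that the pipeline must exclude, PGV carriers at the
study's carrier fraction with per-gene weights mirroring the observed gene
spectrum, planted somatic second hits and allele-resolved LOH (tumor read
counts drawn binomially at the purity-mixed expected allele fraction),
mismatch-repair-deficient tumors with high microsatellite-indel and mutation
rates and dMMR-heavy signature mixtures, an HRD-like signature for biallelic
BRCA1, and decoy germline variants covering every filter's removal reason.

Per-Mb rates are kept at study levels while the genome is represented by a
configurable 100 Mb footprint, which keeps cohort-scale simulation fast
without changing any rate-based statistic.

Every planted fact is recorded in a ``GroundTruth`` whose expected causality
categories are derived by running the category rule cascade on the noise-free
planted evidence — so pipeline-vs-truth comparisons isolate read-sampling
noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .config import PipelineConfig
from .evidence import assign_category
from .phenotypes import COSMIC_CHANNELS, SignatureMatrix, toy_signature_matrix
from .fixtures import panel_fixture
from .types import (
    ClinSigRecord,
    CopyNumberSegment,
    GenomicInterval,
    GenePanel,
    GermlineCall,
    LOHCall,
    LostAllele,
    PGV,
    PhenotypeClass,
    SamplePair,
    SecondHitEvidence,
    SomaticCall,
    TumorPhenotype,
    ZygosityContext,
)

# observed PGV gene spectrum used as default sampling weights
_DEFAULT_GENE_WEIGHTS = {
    "MSH6": 3, "PMS2": 5, "MSH2": 1, "NF1": 1, "BRCA1": 1, "SUFU": 1,
    "CHEK2": 3, "ATR": 1, "SDHA": 1, "MITF": 1,
    "BLM": 4, "MUTYH": 2, "ERCC3": 1, "SBDS": 1, "FANCF": 1, "WRN": 1, "BUB1B": 1,
}

_SIGNATURE_MIXTURES = {
    "background": {"SBS1": 0.8, "flat": 0.2},
    "mmr_deficient": {"SBS6": 0.45, "SBS15": 0.25, "SBS1": 0.2, "flat": 0.1},
    "hrd": {"SBS3": 0.5, "SBS1": 0.4, "flat": 0.1},
}

_ARM_SIZES_MB = {"chr7": 159.0, "chr10": 135.0}


@dataclass
class SimulationConfig:
    n_patients: int = 98
    seed: int = 0
    purity_range: Tuple[float, float] = (0.2, 1.0)
    tumor_depth_range: Tuple[int, int] = (90, 110)
    normal_depth_range: Tuple[int, int] = (30, 35)
    idh_mutant_fraction: float = 6 / 98
    pgv_carrier_fraction: float = 24 / 98
    gene_weights: Dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_GENE_WEIGHTS))
    p_sv_pgv: float = 3 / 29                # fraction of PGVs that are SVs
    p_second_hit: float = 0.6               # biallelic inactivation given a PGV
    p_loh_given_hit: float = 0.5            # LOH (vs somatic small hit) as the mode
    p_second_pgv_same_gene: float = 0.08    # CMMRD-like double hit in PMS2
    p_arm_loss_chr10: float = 0.8
    p_arm_gain_chr7: float = 0.7
    msi_rate_deficient: float = 10.0        # ms-indels per Mb
    msi_rate_proficient: float = 0.1
    somatic_rate_background: float = 3.0    # small variants per Mb (TMB)
    somatic_rate_mmr: float = 40.0
    genome_size_mb: float = 100.0           # scaled genome footprint
    age_mean: float = 61.0
    age_sd: float = 10.0
    age_bounds: Tuple[float, float] = (18.0, 85.0)
    carrier_age_shift: float = -9.0
    pretreated_fraction: float = 0.5
    signature_mixtures: Dict[str, Dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in _SIGNATURE_MIXTURES.items()})

    def __post_init__(self) -> None:
        for name in ("idh_mutant_fraction", "pgv_carrier_fraction", "p_sv_pgv",
                     "p_second_hit", "p_loh_given_hit", "p_second_pgv_same_gene",
                     "p_arm_loss_chr10", "p_arm_gain_chr7", "pretreated_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.pgv_carrier_fraction > 0 and not self.gene_weights:
            raise ValueError("carrier fraction > 0 requires non-empty gene weights")
        if self.genome_size_mb <= 0:
            raise ValueError("genome_size_mb must be > 0")
        for mix in self.signature_mixtures.values():
            if abs(sum(mix.values()) - 1.0) > 1e-6:
                raise ValueError(f"signature mixture must sum to 1: {mix}")


@dataclass
class PlantedPGV:
    patient_id: str
    gene: str
    variant_id: str
    kind: str
    zygosity: ZygosityContext
    biallelic: bool
    hit_mode: Optional[str]          # "somatic_hit" | "loh" | None
    lost_allele: Optional[str]       # for hit_mode == "loh"
    phenotype: str                   # "background" | "mmr_deficient" | "hrd"
    expected_category: int = 0


@dataclass
class GroundTruth:
    planted: List[PlantedPGV] = field(default_factory=list)
    patient_phenotype: Dict[str, str] = field(default_factory=dict)

    def by_variant(self) -> Dict[str, PlantedPGV]:
        return {p.variant_id: p for p in self.planted}


@dataclass
class CohortData:
    samples: List[SamplePair]
    germline_small: List[GermlineCall]
    germline_svs: List[GermlineCall]
    clinsig: Dict[str, ClinSigRecord]
    somatic_calls: List[SomaticCall]
    segments: List[CopyNumberSegment]
    truth: GroundTruth
    signature_matrix: SignatureMatrix
    genome_size_mb: float = 2900.0


def _channel_to_context(channel: str) -> str:
    # "A[C>A]G" -> "ACG>AAG"
    five, rest = channel[0], channel[2:]
    ref, alt = rest[0], rest[2]
    three = channel[-1]
    return f"{five}{ref}{three}>{five}{alt}{three}"


def _mixture_channel_probs(mix: Dict[str, float], matrix: SignatureMatrix) -> np.ndarray:
    probs = np.zeros(96)
    for name, weight in mix.items():
        probs += weight * matrix.column(name)
    return probs / probs.sum()


def _truncated_normal(rng, mean, sd, lo, hi) -> float:
    for _ in range(100):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(min(max(mean, lo), hi))


def generate_cohort(config: Optional[SimulationConfig] = None,
                    panel: Optional[GenePanel] = None) -> CohortData:
    """Simulate a full pipeline input set plus its ground truth.

    Deterministic given ``config.seed``.
    """
    config = config or SimulationConfig()
    panel = panel or panel_fixture()
    rng = np.random.default_rng(config.seed)
    matrix = toy_signature_matrix()

    genes = [g for g in config.gene_weights if g in panel]
    if len(genes) < len(config.gene_weights):
        missing = sorted(set(config.gene_weights) - set(genes))
        raise ValueError(f"gene_weights reference genes absent from panel: {missing}")
    weights = np.array([config.gene_weights[g] for g in genes], dtype=float)
    weights /= weights.sum()

    channel_probs = {
        name: _mixture_channel_probs(mix, matrix)
        for name, mix in config.signature_mixtures.items()
    }

    truth = GroundTruth()
    samples: List[SamplePair] = []
    germline_small: List[GermlineCall] = []
    germline_svs: List[GermlineCall] = []
    clinsig: Dict[str, ClinSigRecord] = {}
    somatic: List[SomaticCall] = []
    segments: List[CopyNumberSegment] = []

    n_mutant = int(round(config.idh_mutant_fraction * config.n_patients))
    for i in range(config.n_patients):
        pid = f"SIM{i:04d}"
        idh_mutant = i >= config.n_patients - n_mutant
        carrier = (not idh_mutant) and rng.random() < config.pgv_carrier_fraction
        purity = float(rng.uniform(*config.purity_range))
        age_mean = config.age_mean + (config.carrier_age_shift if carrier else 0.0)
        samples.append(SamplePair(
            patient_id=pid,
            sex="male" if rng.random() < 0.7 else "female",
            age_at_biopsy=_truncated_normal(rng, age_mean, config.age_sd,
                                            *config.age_bounds),
            purity=purity,
            idh_status="mutant" if idh_mutant else "wildtype",
            pretreated=bool(rng.random() < config.pretreated_fraction),
        ))

        # background arm events common in IDH-wildtype glioblastoma
        arm_cn: Dict[str, Tuple[float, float]] = {}
        if rng.random() < config.p_arm_loss_chr10:
            arm_cn["chr10"] = (1.0, 0.0)
        if rng.random() < config.p_arm_gain_chr7:
            arm_cn["chr7"] = (3.0, 1.0)

        planted_here: List[PlantedPGV] = []
        if carrier:
            gene = str(rng.choice(genes, p=weights))
            planted_here.append(_plant_pgv(rng, config, panel, pid, gene, idx=0))
            if (panel.gene(gene).phenotype_class is PhenotypeClass.MMR
                    and rng.random() < config.p_second_pgv_same_gene):
                planted_here.append(_plant_pgv(rng, config, panel, pid, gene, idx=1,
                                               force_no_hit=True))
        truth.planted.extend(planted_here)

        # phenotype driven by the (first) planted PGV's functional state
        phenotype = "background"
        for p in planted_here:
            cls = panel.gene(p.gene).phenotype_class
            if p.biallelic and cls is PhenotypeClass.MMR:
                phenotype = "mmr_deficient"
            elif p.biallelic and cls is PhenotypeClass.HRD and phenotype == "background":
                phenotype = "hrd"
        # CMMRD-like double germline hit is mismatch-repair deficient
        if len(planted_here) >= 2 and panel.gene(planted_here[0].gene).phenotype_class is PhenotypeClass.MMR:
            phenotype = "mmr_deficient"
        truth.patient_phenotype[pid] = phenotype
        for p in planted_here:
            p.phenotype = phenotype

        # copy-number segments: PGV-locus LOH segments first, then arm events
        for p in planted_here:
            region = panel.regions[p.gene][0]
            if p.hit_mode == "loh":
                segments.append(CopyNumberSegment(
                    patient_id=pid,
                    interval=region, total_cn=1.0, minor_cn=0.0,
                    arm_label=None,
                ))
        for arm, (total, minor) in arm_cn.items():
            size = int(_ARM_SIZES_MB[arm] * 1e6)
            segments.append(CopyNumberSegment(
                patient_id=pid, interval=GenomicInterval(arm, 0, size),
                total_cn=total, minor_cn=minor, arm_label=arm,
            ))

        # germline calls: planted PGVs + decoys covering each filter
        for p in planted_here:
            call = _pgv_call(rng, config, panel, p, purity, segments, pid)
            (germline_svs if p.kind == "sv" else germline_small).append(call)
            clinsig[p.variant_id] = ClinSigRecord(
                variant_id=p.variant_id, clinvar_class="pathogenic")
        _add_decoys(rng, config, panel, pid, germline_small, germline_svs, clinsig)

        # somatic landscape
        if not idh_mutant:
            somatic.extend(_somatic_calls(
                rng, config, pid, phenotype, channel_probs, planted_here, panel))

    # expected categories from noise-free planted evidence (closed loop)
    pgv_objects = _truth_pgvs(truth, panel)
    pipeline_config = PipelineConfig()
    for p, pgv in zip(truth.planted, pgv_objects):
        evidence = _noise_free_evidence(p, panel, segments)
        phen = _noise_free_phenotype(truth.patient_phenotype[p.patient_id], config)
        p.expected_category = assign_category(pgv, evidence, phen, pipeline_config).value

    return CohortData(
        samples=samples, germline_small=germline_small, germline_svs=germline_svs,
        clinsig=clinsig, somatic_calls=somatic, segments=segments, truth=truth,
        signature_matrix=matrix, genome_size_mb=config.genome_size_mb,
    )


def _plant_pgv(rng, config, panel, pid, gene, idx, force_no_hit=False) -> PlantedPGV:
    gd = panel.gene(gene)
    kind = "sv" if (idx == 0 and rng.random() < config.p_sv_pgv) else "small"
    biallelic = (not force_no_hit) and rng.random() < config.p_second_hit
    hit_mode = None
    lost = None
    if biallelic:
        if rng.random() < config.p_loh_given_hit:
            hit_mode, lost = "loh", "wildtype"
        else:
            hit_mode = "somatic_hit"
    zygosity = (
        ZygosityContext.RECESSIVE_MONOALLELIC if gd.inheritance.recessive_pattern
        else ZygosityContext.DOMINANT_MONOALLELIC
    )
    return PlantedPGV(
        patient_id=pid, gene=gene, variant_id=f"{pid}:{gene}:pgv{idx}",
        kind=kind, zygosity=zygosity, biallelic=biallelic,
        hit_mode=hit_mode, lost_allele=lost, phenotype="",
    )


def _covering_cn(segments, pid, chrom, pos) -> Tuple[float, float]:
    for seg in segments:
        if seg.patient_id == pid and seg.interval.contains(chrom, pos):
            return seg.total_cn, seg.minor_cn
    return 2.0, 1.0


def _pgv_call(rng, config, panel, planted: PlantedPGV, purity, segments, pid) -> GermlineCall:
    region = panel.regions[planted.gene][0]
    pos = (region.start + region.end) // 2 + int(planted.variant_id[-1])
    cn, _minor = _covering_cn(segments, pid, region.chrom, pos)
    if planted.hit_mode == "loh":
        m = 1 if planted.lost_allele == "wildtype" else 0
    else:
        m_max = max(int(round(cn)), 1)
        m = int(rng.integers(1, m_max + 1)) if m_max > 1 else 1
    denom = purity * cn + (1 - purity) * 2.0
    f = (purity * m + (1 - purity) * 1.0) / denom if denom > 0 else 0.5
    tumor_depth = int(rng.integers(*config.tumor_depth_range))
    normal_depth = int(rng.integers(*config.normal_depth_range))
    if planted.kind == "sv":
        kind, effect = "sv", "sv_loss"
    else:
        kind, effect = ("indel", "frameshift") if rng.random() < 0.5 else ("snv", "nonsense")
    return GermlineCall(
        patient_id=pid, gene=planted.gene, variant_id=planted.variant_id,
        kind=kind, effect=effect, genotype="het",
        chrom=region.chrom, pos=pos, ref="N", alt="N",
        gnomad_af=float(rng.uniform(0, 1e-4)), cohort_count=int(rng.integers(0, 5)),
        qual=float(np.clip(rng.normal(500, 50), 400, None)),
        normal_reads=(int(rng.binomial(normal_depth, 0.5)), normal_depth),
        tumor_reads=(int(rng.binomial(tumor_depth, min(max(f, 0.0), 1.0))), tumor_depth),
    )


def _add_decoys(rng, config, panel, pid, germline_small, germline_svs, clinsig) -> None:
    """One decoy per removal reason, plus a rare benign passenger.

    Guarantees every filter and the classification stage have live work in a
    default cohort.
    """
    symbols = panel.symbols
    hi_q = lambda: float(np.clip(rng.normal(500, 50), 350, None))
    lo_q = lambda: float(np.clip(rng.normal(100, 20), 1, 200))
    depth = lambda: int(rng.integers(*config.normal_depth_range))

    def decoy(tag, effect, gnomad, cohort, qual):
        gene = str(rng.choice(symbols))
        region = panel.regions[gene][0]
        vid = f"{pid}:{gene}:{tag}"
        d = depth()
        germline_small.append(GermlineCall(
            patient_id=pid, gene=gene, variant_id=vid, kind="snv", effect=effect,
            genotype="het", chrom=region.chrom,
            pos=int(rng.integers(region.start, region.end)),
            gnomad_af=gnomad, cohort_count=cohort, qual=qual,
            normal_reads=(int(rng.binomial(d, 0.5)), d),
            tumor_reads=(int(rng.binomial(d, 0.5)), d),
        ))
        return vid

    decoy("syn", "synonymous", 1e-4, 0, hi_q())
    decoy("common", "missense", float(rng.uniform(0.02, 0.2)), 0, hi_q())
    decoy("lowq", "missense", 1e-4, 0, lo_q())
    decoy("cohort", "missense", 1e-4, int(rng.integers(300, 1000)), hi_q())
    benign = decoy("benign", "missense", 1e-4, 0, hi_q())
    clinsig[benign] = ClinSigRecord(variant_id=benign, clinvar_class="benign")

    # one common germline SV decoy per ~10 patients
    if rng.random() < 0.1:
        gene = str(rng.choice(symbols))
        region = panel.regions[gene][0]
        vid = f"{pid}:{gene}:svcommon"
        germline_svs.append(GermlineCall(
            patient_id=pid, gene=gene, variant_id=vid, kind="sv", effect="sv_other",
            genotype="het", chrom=region.chrom, pos=region.start,
            gnomad_af=None, cohort_count=int(rng.integers(289, 2000)),
            qual=hi_q(), normal_reads=(10, 30), tumor_reads=(30, 100),
        ))


def _somatic_calls(rng, config, pid, phenotype, channel_probs, planted, panel):
    calls: List[SomaticCall] = []
    mb = config.genome_size_mb
    snv_rate = (config.somatic_rate_mmr if phenotype == "mmr_deficient"
                else config.somatic_rate_background)
    n_snv = int(rng.poisson(snv_rate * mb))
    channels = rng.choice(96, size=n_snv, p=channel_probs[phenotype])
    for j, ch in enumerate(channels):
        calls.append(SomaticCall(
            patient_id=pid, variant_id=f"{pid}:snv{j}", kind="snv",
            effect="missense", context=_channel_to_context(COSMIC_CHANNELS[ch]),
        ))
    ms_rate = (config.msi_rate_deficient if phenotype == "mmr_deficient"
               else config.msi_rate_proficient)
    n_ms = int(rng.poisson(ms_rate * mb))
    for j in range(n_ms):
        calls.append(SomaticCall(
            patient_id=pid, variant_id=f"{pid}:msindel{j}", kind="indel",
            effect="frameshift", at_microsatellite=True,
        ))
    # planted same-gene somatic second hits
    for p in planted:
        if p.hit_mode == "somatic_hit":
            region = panel.regions[p.gene][0]
            calls.append(SomaticCall(
                patient_id=pid, variant_id=f"{pid}:{p.gene}:somatichit",
                kind="indel", effect="frameshift", gene=p.gene,
                chrom=region.chrom, pos=(region.start + region.end) // 2,
                driver_flag=True,
            ))
    return calls


def _truth_pgvs(truth: GroundTruth, panel: GenePanel) -> List[PGV]:
    by_patient_gene: Dict[tuple, int] = {}
    for p in truth.planted:
        by_patient_gene[(p.patient_id, p.gene)] = \
            by_patient_gene.get((p.patient_id, p.gene), 0) + 1
    pgvs = []
    for p in truth.planted:
        gd = panel.gene(p.gene)
        double = by_patient_gene[(p.patient_id, p.gene)] >= 2
        zygosity = p.zygosity
        if gd.inheritance.recessive_pattern and double:
            zygosity = ZygosityContext.RECESSIVE_BIALLELIC
        pgvs.append(PGV(
            call=GermlineCall(
                patient_id=p.patient_id, gene=p.gene, variant_id=p.variant_id,
                kind="sv" if p.kind == "sv" else "snv",
                effect="sv_loss" if p.kind == "sv" else "nonsense",
            ),
            final_class=5, gene_def=gd, zygosity_context=zygosity,
            cmmrd_candidate=double and gd.phenotype_class is PhenotypeClass.MMR,
        ))
    return pgvs


def _noise_free_evidence(p: PlantedPGV, panel: GenePanel, segments) -> SecondHitEvidence:
    region = panel.regions[p.gene][0]
    pos = (region.start + region.end) // 2
    hit = None
    if p.hit_mode == "somatic_hit":
        hit = SomaticCall(
            patient_id=p.patient_id, variant_id=f"{p.patient_id}:{p.gene}:somatichit",
            kind="indel", effect="frameshift", gene=p.gene,
        )
    if p.hit_mode == "loh":
        loh = LOHCall(loh_present=True, lost_allele=LostAllele.WILDTYPE,
                      focal=region.length < 3e6, arm_event_label=None)
    else:
        # background arm events can impose LOH at the locus (e.g. chr10 genes)
        cn, minor = _covering_cn(segments, p.patient_id, region.chrom, pos)
        if minor < 0.5:
            lost = LostAllele.WILDTYPE if cn >= 0.5 else LostAllele.UNDETERMINED
            loh = LOHCall(loh_present=True, lost_allele=lost, focal=False,
                          arm_event_label=region.chrom)
        else:
            loh = LOHCall(loh_present=False)
    ev = SecondHitEvidence(somatic_small_hit=hit, loh=loh)
    ev.biallelic_inactivation = bool(hit or ev.wildtype_lost)
    return ev


def _noise_free_phenotype(phenotype: str, config: SimulationConfig) -> TumorPhenotype:
    from .phenotypes import msi_status

    rate = (config.msi_rate_deficient if phenotype == "mmr_deficient"
            else config.msi_rate_proficient)
    tmb = (config.somatic_rate_mmr if phenotype == "mmr_deficient"
           else config.somatic_rate_background)
    return TumorPhenotype(
        tmb=tmb, msi_rate=rate, msi_status=msi_status(rate),
        exposures=dict(config.signature_mixtures[phenotype]),
    )


# --- cohort directory round-trip ------------------------------------------

def write_cohort(cohort: CohortData, outdir) -> None:
    """Materialise a simulated cohort as the pipeline's TSV input file set."""
    from pathlib import Path

    from . import io as gio
    from .phenotypes import write_signature_matrix

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gio.write_samples(cohort.samples, outdir / "samples.tsv")
    gio.write_variant_table(cohort.germline_small, outdir / "germline_small.tsv", "germline")
    gio.write_variant_table(cohort.germline_svs, outdir / "germline_svs.tsv", "germline")
    gio.write_variant_table(cohort.somatic_calls, outdir / "somatic.tsv", "somatic")
    gio.write_segments(cohort.segments, outdir / "segments.tsv")
    gio.write_clinsig(cohort.clinsig.values(), outdir / "clinsig.tsv")
    write_signature_matrix(cohort.signature_matrix, outdir / "signatures.tsv")
    with open(outdir / "cohort_meta.tsv", "w") as fh:
        fh.write(f"genome_size_mb\t{cohort.genome_size_mb!r}\n")
    with open(outdir / "ground_truth.tsv", "w") as fh:
        fh.write("patient_id\tgene\tvariant_id\tkind\tzygosity\tbiallelic\t"
                 "hit_mode\tlost_allele\tphenotype\texpected_category\n")
        for p in cohort.truth.planted:
            fh.write(f"{p.patient_id}\t{p.gene}\t{p.variant_id}\t{p.kind}\t"
                     f"{p.zygosity.value}\t{int(p.biallelic)}\t{p.hit_mode or ''}\t"
                     f"{p.lost_allele or ''}\t"
                     f"{cohort.truth.patient_phenotype[p.patient_id]}\t"
                     f"{p.expected_category}\n")


def load_cohort(indir) -> CohortData:
    """Read a cohort directory written by :func:`write_cohort`."""
    import csv
    from pathlib import Path

    from . import io as gio
    from .phenotypes import read_signature_matrix

    indir = Path(indir)
    genome_size_mb = 2900.0
    meta = indir / "cohort_meta.tsv"
    if meta.exists():
        for line in meta.read_text().splitlines():
            key, value = line.split("\t")
            if key == "genome_size_mb":
                genome_size_mb = float(value)
    truth = GroundTruth()
    truth_path = indir / "ground_truth.tsv"
    if truth_path.exists():
        with open(truth_path) as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                truth.planted.append(PlantedPGV(
                    patient_id=row["patient_id"], gene=row["gene"],
                    variant_id=row["variant_id"], kind=row["kind"],
                    zygosity=ZygosityContext(row["zygosity"]),
                    biallelic=bool(int(row["biallelic"])),
                    hit_mode=row["hit_mode"] or None,
                    lost_allele=row["lost_allele"] or None,
                    phenotype=row["phenotype"],
                    expected_category=int(row["expected_category"]),
                ))
                truth.patient_phenotype[row["patient_id"]] = row["phenotype"]
    return CohortData(
        samples=gio.read_samples(indir / "samples.tsv"),
        germline_small=list(gio.read_variant_table(indir / "germline_small.tsv", "germline").raise_on_errors()),
        germline_svs=list(gio.read_variant_table(indir / "germline_svs.tsv", "germline").raise_on_errors()),
        clinsig={r.variant_id: r for r in gio.read_clinsig(indir / "clinsig.tsv")},
        somatic_calls=list(gio.read_variant_table(indir / "somatic.tsv", "somatic").raise_on_errors()),
        segments=gio.read_segments(indir / "segments.tsv"),
        truth=truth,
        signature_matrix=read_signature_matrix(indir / "signatures.tsv"),
        genome_size_mb=genome_size_mb,
    )
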