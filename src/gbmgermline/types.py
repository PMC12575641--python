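"""Shared domain types for the germline-predisposition pipeline.

Everything downstream (filtering, classification, tumor evidence, phenotypes,
cohort statistics) speaks in these records.  Coordinates are 0-based half-open
throughout; VCF positions (1-based) are converted on ingest.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional


class Inheritance(str, enum.Enum):
    DOMINANT = "dominant"
    RECESSIVE = "recessive"
    DOMINANT_AND_RECESSIVE = "dominant_and_recessive"

    @property
    def recessive_pattern(self) -> bool:
        """Whether monoallelic carriers are considered unaffected.

        Genes annotated dominant_and_recessive are resolved per-variant as
        recessive-pattern: a single heterozygous variant does not by itself
        establish dominant risk.
        """
        return self in (Inheritance.RECESSIVE, Inheritance.DOMINANT_AND_RECESSIVE)


class Mechanism(str, enum.Enum):
    TUMOR_SUPPRESSOR = "tumor_suppressor"
    ONCOGENE = "oncogene"


class PhenotypeClass(str, enum.Enum):
    """Expected genome-wide footprint when the gene is inactivated."""

    MMR = "mmr"    # mismatch repair -> microsatellite instability, dMMR signatures
    HRD = "hrd"    # homologous recombination deficiency -> SBS3-like signature
    NONE = "none"


MMR_GENES = frozenset({"MLH1", "MSH2", "MSH6", "PMS2"})
HRD_GENES = frozenset({"BRCA1", "BRCA2", "PALB2"})


class VariantKind(str, enum.Enum):
    SNV = "snv"
    MNV = "mnv"
    INDEL = "indel"
    SV = "sv"


class Effect(str, enum.Enum):
    SYNONYMOUS = "synonymous"
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    INFRAME_INDEL = "inframe_indel"
    SPLICE = "splice"
    SV_LOSS = "sv_loss"
    SV_OTHER = "sv_other"


class Genotype(str, enum.Enum):
    HET = "het"
    HOM = "hom"


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class IDHStatus(str, enum.Enum):
    WILDTYPE = "wildtype"
    MUTANT = "mutant"
    UNKNOWN = "unknown"


class ClinVarClass(str, enum.Enum):
    """IARC/ACMG 5-tier classes plus ClinVar bookkeeping states."""

    BENIGN = "benign"                      # class 1
    LIKELY_BENIGN = "likely_benign"        # class 2
    VUS = "vus"                            # class 3
    LIKELY_PATHOGENIC = "likely_pathogenic"  # class 4
    PATHOGENIC = "pathogenic"              # class 5
    CONFLICTING = "conflicting"
    ABSENT = "absent"

    @property
    def numeric(self) -> Optional[int]:
        return {
            ClinVarClass.BENIGN: 1,
            ClinVarClass.LIKELY_BENIGN: 2,
            ClinVarClass.VUS: 3,
            ClinVarClass.LIKELY_PATHOGENIC: 4,
            ClinVarClass.PATHOGENIC: 5,
        }.get(self)

    @property
    def is_pathogenic(self) -> bool:
        return self in (ClinVarClass.LIKELY_PATHOGENIC, ClinVarClass.PATHOGENIC)


class ZygosityContext(str, enum.Enum):
    DOMINANT_MONOALLELIC = "dominant_monoallelic"
    RECESSIVE_MONOALLELIC = "recessive_monoallelic"
    RECESSIVE_BIALLELIC = "recessive_biallelic_or_compound_het"


class LostAllele(str, enum.Enum):
    WILDTYPE = "wildtype"
    MUTANT = "mutant"
    UNDETERMINED = "undetermined"


class MSIStatus(str, enum.Enum):
    MSS = "mss"
    ELEVATED = "elevated"
    MSI = "msi"


class Association(str, enum.Enum):
    GLIOBLASTOMA = "glioblastoma"
    MEDULLOBLASTOMA = "medulloblastoma"
    OTHER_CANCER = "other_cancer"


BRAIN_TUMOR_ASSOCIATIONS = frozenset(
    {Association.GLIOBLASTOMA, Association.MEDULLOBLASTOMA}
)


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end ({self.end}) must be > start ({self.start})")

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GeneDef:
    symbol: str
    inheritance: Inheritance
    mechanism: Mechanism
    association: frozenset = frozenset()
    phenotype_class: PhenotypeClass = PhenotypeClass.NONE

    def __post_init__(self) -> None:
        object.__setattr__(self, "inheritance", Inheritance(self.inheritance))
        object.__setattr__(self, "mechanism", Mechanism(self.mechanism))
        object.__setattr__(self, "phenotype_class", PhenotypeClass(self.phenotype_class))
        if self.phenotype_class is PhenotypeClass.MMR and self.symbol not in MMR_GENES:
            raise ValueError(f"{self.symbol}: phenotype_class=mmr reserved for {sorted(MMR_GENES)}")
        if self.phenotype_class is PhenotypeClass.HRD and self.symbol not in HRD_GENES:
            raise ValueError(f"{self.symbol}: phenotype_class=hrd reserved for {sorted(HRD_GENES)}")
        object.__setattr__(self, "association", frozenset(Association(a) for a in self.association))

    @property
    def brain_tumor_associated(self) -> bool:
        return bool(self.association & BRAIN_TUMOR_ASSOCIATIONS)


@dataclass
class GenePanel:
    genes: list
    regions: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        symbols = [g.symbol for g in self.genes]
        if len(symbols) != len(set(symbols)):
            dupes = sorted({s for s in symbols if symbols.count(s) > 1})
            raise ValueError(f"duplicate gene symbols in panel: {dupes}")
        self._by_symbol = {g.symbol: g for g in self.genes}
        for symbol, ivs in self.regions.items():
            if symbol not in self._by_symbol:
                raise ValueError(f"region gene {symbol!r} not in panel")
            ordered = sorted(ivs, key=lambda iv: (iv.chrom, iv.start))
            for a, b in zip(ordered, ordered[1:]):
                if a.overlaps(b):
                    raise ValueError(f"overlapping regions for {symbol}: {a} / {b}")
            self.regions[symbol] = ordered

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._by_symbol

    def gene(self, symbol: str) -> GeneDef:
        try:
            return self._by_symbol[symbol]
        except KeyError:
            raise KeyError(f"gene {symbol!r} not in panel") from None

    @property
    def symbols(self) -> list:
        return [g.symbol for g in self.genes]


def _check_reads(name: str, reads) -> tuple:
    alt, total = int(reads[0]), int(reads[1])
    if alt < 0 or total < 0 or alt > total:
        raise ValueError(f"{name}: invalid read counts (alt={alt}, total={total})")
    return (alt, total)


@dataclass
class GermlineCall:
    """One annotated germline variant observation (small variant or SV)."""

    patient_id: str
    gene: str
    variant_id: str
    kind: VariantKind
    effect: Effect
    genotype: Genotype = Genotype.HET
    chrom: Optional[str] = None
    pos: Optional[int] = None          # 0-based
    ref: Optional[str] = None
    alt: Optional[str] = None
    hgvs_c: Optional[str] = None
    hgvs_p: Optional[str] = None
    gnomad_af: Optional[float] = None
    cohort_count: int = 0
    qual: float = 0.0
    normal_reads: tuple = (0, 0)
    tumor_reads: tuple = (0, 0)

    def __post_init__(self) -> None:
        self.kind = VariantKind(self.kind)
        self.effect = Effect(self.effect)
        self.genotype = Genotype(self.genotype)
        if self.gnomad_af is not None and not (0.0 <= self.gnomad_af <= 1.0):
            raise ValueError(f"{self.variant_id}: gnomad_af {self.gnomad_af} outside [0,1]")
        if self.cohort_count < 0:
            raise ValueError(f"{self.variant_id}: negative cohort_count")
        if self.qual < 0:
            raise ValueError(f"{self.variant_id}: negative qual")
        self.normal_reads = _check_reads(self.variant_id, self.normal_reads)
        self.tumor_reads = _check_reads(self.variant_id, self.tumor_reads)


@dataclass
class SomaticCall:
    """One somatic variant observation in the tumor sample."""

    patient_id: str
    variant_id: str
    kind: VariantKind
    effect: Effect
    gene: Optional[str] = None
    chrom: Optional[str] = None
    pos: Optional[int] = None
    context: Optional[str] = None       # "ACA>AAA": ref triplet > alt triplet
    at_microsatellite: bool = False
    driver_flag: bool = False

    def __post_init__(self) -> None:
        self.kind = VariantKind(self.kind)
        self.effect = Effect(self.effect)
        if self.kind is VariantKind.SNV and not self.context:
            raise ValueError(f"{self.variant_id}: SNV requires trinucleotide context")
        if self.kind is not VariantKind.SNV and self.context:
            raise ValueError(f"{self.variant_id}: context only meaningful for SNVs")


@dataclass
class CopyNumberSegment:
    patient_id: str
    interval: GenomicInterval
    total_cn: float
    minor_cn: float
    arm_label: Optional[str] = None
    _CN_TOL = 0.05

    def __post_init__(self) -> None:
        if self.total_cn < 0:
            raise ValueError("total_cn must be >= 0")
        if self.minor_cn < 0:
            raise ValueError("minor_cn must be >= 0")
        if self.minor_cn > self.total_cn / 2.0 + self._CN_TOL:
            raise ValueError(
                f"minor_cn {self.minor_cn} exceeds total_cn/2 ({self.total_cn / 2.0})"
            )


@dataclass
class SamplePair:
    patient_id: str
    sex: Sex = Sex.UNKNOWN
    age_at_biopsy: float = 60.0
    purity: float = 1.0
    idh_status: IDHStatus = IDHStatus.UNKNOWN
    tumor_type: str = "glioblastoma"
    pretreated: bool = False

    def __post_init__(self) -> None:
        self.sex = Sex(self.sex)
        self.idh_status = IDHStatus(self.idh_status)
        if not (0.0 <= self.purity <= 1.0):
            raise ValueError(f"{self.patient_id}: purity {self.purity} outside [0,1]")
        if self.age_at_biopsy <= 0:
            raise ValueError(f"{self.patient_id}: non-positive age")


@dataclass
class ClinSigRecord:
    variant_id: str
    clinvar_class: ClinVarClass = ClinVarClass.ABSENT
    curation_override: Optional[ClinVarClass] = None
    rationale: str = ""

    def __post_init__(self) -> None:
        self.clinvar_class = ClinVarClass(self.clinvar_class)
        if self.curation_override is not None:
            self.curation_override = ClinVarClass(self.curation_override)


@dataclass
class PGV:
    """A curated pathogenic germline variant (class 4/5) with its gene context."""

    call: GermlineCall
    final_class: int
    gene_def: GeneDef
    zygosity_context: Optional[ZygosityContext] = None
    cmmrd_candidate: bool = False

    def __post_init__(self) -> None:
        if self.final_class not in (4, 5):
            raise ValueError(f"final_class must be 4 or 5, got {self.final_class}")

    @property
    def patient_id(self) -> str:
        return self.call.patient_id

    @property
    def gene(self) -> str:
        return self.call.gene


@dataclass
class LOHCall:
    loh_present: bool
    lost_allele: LostAllele = LostAllele.UNDETERMINED
    focal: bool = False
    arm_event_label: Optional[str] = None
    fit_loglik: float = 0.0
    mutant_copies_hat: Optional[int] = None
    note: str = ""

    def __post_init__(self) -> None:
        self.lost_allele = LostAllele(self.lost_allele)
        if not self.loh_present and self.lost_allele is not LostAllele.UNDETERMINED:
            raise ValueError("lost_allele must be undetermined when loh_present is False")


@dataclass
class SecondHitEvidence:
    somatic_small_hit: Optional[SomaticCall] = None
    loh: LOHCall = field(default_factory=lambda: LOHCall(loh_present=False))
    focal_deletion: bool = False
    biallelic_inactivation: bool = False
    notes: str = ""

    @property
    def wildtype_lost(self) -> bool:
        return self.loh.loh_present and self.loh.lost_allele is LostAllele.WILDTYPE


@dataclass
class TumorPhenotype:
    tmb: float = 0.0
    msi_rate: float = 0.0
    msi_status: MSIStatus = MSIStatus.MSS
    exposures: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.msi_status = MSIStatus(self.msi_status)
        if self.tmb < 0 or self.msi_rate < 0:
            raise ValueError("tmb and msi_rate must be >= 0")
        if self.exposures:
            total = sum(self.exposures.values())
            if total > 0 and abs(total - 1.0) > 1e-6:
                raise ValueError(f"relative exposures sum to {total}, expected 1")


@dataclass(frozen=True)
class CausalityCategory:
    value: int
    rationale: str

    def __post_init__(self) -> None:
        if self.value not in (1, 2, 3):
            raise ValueError(f"category must be 1, 2 or 3, got {self.value}")
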