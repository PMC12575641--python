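"""Pipeline configuration: every threshold the analysis uses, with defaults.

Defaults encode the study conditions: gnomAD non-cancer cumulative frequency
>1% removed, reference-cohort frequency >=5% of n=5778 removed, recalibrated
Phred quality cutoff 235.6 (fallback when the density plot is unimodal or the
score set is too small), MSI thresholds >1.3 (elevated) and >=4 (diagnostic)
microsatellite indels per Mb, and usable tumor purity >=0.2.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Union

import yaml


@dataclass
class FilterParams:
    gnomad_max: float = 0.01
    cohort_max_fraction: float = 0.05
    reference_cohort_n: int = 5778
    qual_cutoff: Union[float, str] = "auto"   # numeric, or "auto" -> density valley
    qual_fallback: float = 235.6
    drop_synonymous: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.gnomad_max < 1.0):
            raise ValueError(f"gnomad_max must be in (0,1), got {self.gnomad_max}")
        if not (0.0 < self.cohort_max_fraction < 1.0):
            raise ValueError(
                f"cohort_max_fraction must be in (0,1), got {self.cohort_max_fraction}"
            )
        if self.reference_cohort_n <= 0:
            raise ValueError("reference_cohort_n must be positive")
        if isinstance(self.qual_cutoff, str):
            if self.qual_cutoff != "auto":
                raise ValueError(f"qual_cutoff must be numeric or 'auto', got {self.qual_cutoff!r}")
        elif self.qual_cutoff <= 0:
            raise ValueError("numeric qual_cutoff must be > 0")
        if self.qual_fallback <= 0:
            raise ValueError("qual_fallback must be > 0")


@dataclass
class LOHParams:
    minor_cn_threshold: float = 0.5
    min_purity: float = 0.2
    focal_max_mb: float = 3.0   # deletions shorter than this count as focal
    arm_min_mb: float = 10.0    # segments at least this long are arm-level events

    def __post_init__(self) -> None:
        if self.minor_cn_threshold <= 0:
            raise ValueError("minor_cn_threshold must be > 0")
        if not (0.0 <= self.min_purity <= 1.0):
            raise ValueError("min_purity must be in [0,1]")


@dataclass
class MSIParams:
    elevated_min: float = 1.3   # exclusive: rate > 1.3 -> elevated
    diagnostic_min: float = 4.0  # inclusive: rate >= 4 -> msi

    def __post_init__(self) -> None:
        if not (0.0 <= self.elevated_min < self.diagnostic_min):
            raise ValueError("need 0 <= elevated_min < diagnostic_min")


@dataclass
class SignatureParams:
    dmmr_group: tuple = ("SBS6", "SBS14", "SBS15", "SBS20", "SBS21", "SBS26")
    pole_group: tuple = ("SBS9", "SBS10")
    include_pole: bool = False
    hrd_signature: str = "SBS3"
    dmmr_min: float = 0.1
    hrd_min: float = 0.2

    def __post_init__(self) -> None:
        for name, v in (("dmmr_min", self.dmmr_min), ("hrd_min", self.hrd_min)):
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must be in (0,1), got {v}")

    @property
    def dmmr_signatures(self) -> tuple:
        return self.dmmr_group + (self.pole_group if self.include_pole else ())


@dataclass
class CategoryParams:
    # arm-level LOH of the wild-type allele that coincides with a common
    # tumor-type arm event (e.g. chr10 loss in glioblastoma) does not count
    # as a demonstrated second hit unless this flag is set
    arm_loh_counts_as_hit: bool = False
    # tumor type -> {arm label: expected direction}; chr10 loss/LOH and chr7
    # gain are near-ubiquitous in IDH-wildtype glioblastoma, so arm-level LOH
    # on these arms is weak evidence for any single gene they carry
    common_arm_events: dict = field(
        default_factory=lambda: {"glioblastoma": {"chr10": "loss", "chr7": "gain"}}
    )


@dataclass
class CohortParams:
    n_total: Optional[int] = None      # default: inferred from the sample list
    genome_size_mb: float = 2900.0     # TMB / MSI denominator
    keep_unknown_idh: bool = True

    def __post_init__(self) -> None:
        if self.genome_size_mb <= 0:
            raise ValueError("genome_size_mb must be > 0")


@dataclass
class PipelineConfig:
    filters: FilterParams = field(default_factory=FilterParams)
    loh: LOHParams = field(default_factory=LOHParams)
    msi: MSIParams = field(default_factory=MSIParams)
    signatures: SignatureParams = field(default_factory=SignatureParams)
    categories: CategoryParams = field(default_factory=CategoryParams)
    cohort: CohortParams = field(default_factory=CohortParams)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


_SECTIONS = {
    "filters": FilterParams,
    "loh": LOHParams,
    "msi": MSIParams,
    "signatures": SignatureParams,
    "categories": CategoryParams,
    "cohort": CohortParams,
}


class ConfigError(ValueError):
    pass


def _build_section(cls, mapping: dict, section: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - known
    if unknown:
        raise ConfigError(f"unknown keys in [{section}]: {sorted(unknown)}")
    coerced = {}
    for key, value in mapping.items():
        if isinstance(value, list):
            value = tuple(value)
        coerced[key] = value
    try:
        return cls(**coerced)
    except ValueError as exc:
        raise ConfigError(f"[{section}] {exc}") from exc


def config_from_dict(data: Optional[dict]) -> PipelineConfig:
    """Build a validated configuration from a (possibly empty) nested mapping."""
    data = dict(data or {})
    unknown = set(data) - set(_SECTIONS)
    if unknown:
        raise ConfigError(f"unknown config sections: {sorted(unknown)}")
    kwargs = {}
    for section, cls in _SECTIONS.items():
        mapping = data.get(section, {})
        if mapping is None:
            mapping = {}
        if not isinstance(mapping, dict):
            raise ConfigError(f"section [{section}] must be a mapping")
        kwargs[section] = _build_section(cls, mapping, section)
    return PipelineConfig(**kwargs)


def load_config(path) -> PipelineConfig:
    """Load a YAML/JSON config file; missing keys fall back to defaults.

    Unknown sections or keys are rejected, as are out-of-range thresholds
    (e.g. a population frequency above 1).
    """
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"config root must be a mapping, got {type(data).__name__}")
    return config_from_dict(data)
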