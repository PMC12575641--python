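"""Cohort-level tallies, prevalences and statistics.

Denominator conventions follow the study design: prevalence of dominant PGVs
in glioblastoma/medulloblastoma-associated genes uses the *analyzed* cohort
(post-IDH-exclusion, n = 92 in the reference cohort), while the MMR-carrier
percentage and the evidence-table scope use the *full* cohort (n = 98).  Every
percentage is stored with its numerator and denominator so it can always be
reconstructed, and rounding (integer percent for headline prevalence, one
decimal for the MMR percentage) is explicit.
"""

from __future__ import annotations

import csv
import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
from scipy.stats import norm, rankdata

from .config import MSIParams
from .types import (
    CausalityCategory,
    PGV,
    SamplePair,
    SecondHitEvidence,
    TumorPhenotype,
    VariantKind,
    ZygosityContext,
)

EXACT_MAX_N = 12


@dataclass
class PGVResult:
    """One PGV with its gathered tumor evidence and assigned category."""

    pgv: PGV
    evidence: SecondHitEvidence
    category: CausalityCategory
    phenotype_matched: bool = False
    match_label: str = ""

    @property
    def evidence_supported(self) -> bool:
        """Second somatic event and/or matching genome-wide phenotype."""
        return bool(
            self.evidence.somatic_small_hit
            or self.evidence.focal_deletion
            or self.evidence.wildtype_lost
            or self.phenotype_matched
        )


@dataclass
class Percentage:
    numerator: int
    denominator: int
    decimals: int = 0

    @property
    def raw(self) -> float:
        return 100.0 * self.numerator / self.denominator

    @property
    def value(self) -> float:
        return round(self.raw, self.decimals if self.decimals else None)

    def __str__(self) -> str:
        return f"{self.value:g}% ({self.numerator}/{self.denominator})"


@dataclass
class CohortReport:
    n_total: int
    n_analyzed: int
    n_pgv: int = 0
    n_pgv_sv: int = 0
    n_pgv_genes: int = 0
    unique_carriers: int = 0
    carrier_prevalence: Optional[Percentage] = None
    n_dominant: int = 0
    n_dominant_patients: int = 0
    dominant_prevalence: Optional[Percentage] = None
    n_recessive_monoallelic: int = 0
    n_recessive_biallelic: int = 0
    n_associated_pgvs: int = 0
    n_associated_carriers: int = 0
    associated_prevalence: Optional[Percentage] = None
    n_evidence_supported: int = 0
    proven_causality: Optional[Percentage] = None
    n_mmr_carriers: int = 0
    mmr_percentage: Optional[Percentage] = None
    n_msi_elevated: int = 0
    n_msi_diagnostic: int = 0
    n_cmmrd_candidates: int = 0
    category_counts: Dict[int, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        def pct(p):
            if p is None:
                return None
            return {"value": p.value, "numerator": p.numerator,
                    "denominator": p.denominator, "raw": p.raw}
        out = {}
        for key, value in self.__dict__.items():
            out[key] = pct(value) if isinstance(value, Percentage) else value
        return out


def _unique_patients(results) -> set:
    return {r.pgv.patient_id for r in results}


def summarize(
    results: List[PGVResult],
    samples: List[SamplePair],
    phenotypes: Dict[str, TumorPhenotype],
    n_total: Optional[int] = None,
    n_analyzed: Optional[int] = None,
    msi_params: Optional[MSIParams] = None,
) -> CohortReport:
    """Cohort tallies and prevalence percentages from assigned PGV results."""
    msi_params = msi_params or MSIParams()
    if n_total is None:
        n_total = len(samples)
    if n_analyzed is None:
        n_analyzed = len(samples)
    if n_total <= 0 or n_analyzed <= 0:
        raise ValueError("cohort denominators must be positive")

    report = CohortReport(n_total=n_total, n_analyzed=n_analyzed)
    report.n_pgv = len(results)
    report.n_pgv_sv = sum(1 for r in results if r.pgv.call.kind is VariantKind.SV)
    report.n_pgv_genes = len({r.pgv.gene for r in results})
    report.unique_carriers = len(_unique_patients(results))
    report.carrier_prevalence = Percentage(report.unique_carriers, n_analyzed)

    dominant = [r for r in results
                if r.pgv.zygosity_context is ZygosityContext.DOMINANT_MONOALLELIC]
    report.n_dominant = len(dominant)
    report.n_dominant_patients = len(_unique_patients(dominant))
    report.dominant_prevalence = Percentage(report.n_dominant_patients, n_analyzed)
    report.n_recessive_monoallelic = sum(
        1 for r in results
        if r.pgv.zygosity_context is ZygosityContext.RECESSIVE_MONOALLELIC
    )
    report.n_recessive_biallelic = sum(
        1 for r in results
        if r.pgv.zygosity_context is ZygosityContext.RECESSIVE_BIALLELIC
    )

    associated = [r for r in dominant if r.pgv.gene_def.brain_tumor_associated]
    report.n_associated_pgvs = len(associated)
    report.n_associated_carriers = len(_unique_patients(associated))
    report.associated_prevalence = Percentage(report.n_associated_carriers, n_analyzed)
    report.n_evidence_supported = sum(1 for r in associated if r.evidence_supported)
    if report.n_associated_carriers:
        report.proven_causality = proven_causality_rate(results)

    mmr = [r for r in results if r.pgv.gene_def.phenotype_class.value == "mmr"]
    report.n_mmr_carriers = len(_unique_patients(mmr))
    report.mmr_percentage = Percentage(report.n_mmr_carriers, n_total, decimals=1)
    report.n_cmmrd_candidates = len({r.pgv.patient_id for r in results
                                     if r.pgv.cmmrd_candidate})

    rates = [p.msi_rate for p in phenotypes.values()]
    report.n_msi_elevated = sum(1 for r in rates if r > msi_params.elevated_min)
    report.n_msi_diagnostic = sum(1 for r in rates if r >= msi_params.diagnostic_min)

    report.category_counts = {k: 0 for k in (1, 2, 3)}
    for r in results:
        report.category_counts[r.category.value] += 1
    return report


def proven_causality_rate(results: List[PGVResult]) -> Percentage:
    """Fraction of associated-gene carriers with at least one category-1 PGV."""
    associated = [
        r for r in results
        if r.pgv.gene_def.brain_tumor_associated
        and r.pgv.zygosity_context is ZygosityContext.DOMINANT_MONOALLELIC
    ]
    carriers = _unique_patients(associated)
    if not carriers:
        raise ValueError("no associated-gene carriers: empty denominator")
    causal = {r.pgv.patient_id for r in associated if r.category.value == 1}
    return Percentage(len(causal), len(carriers))


def mann_whitney_u(group_a, group_b, alternative: str = "two_sided"):
    """Mann-Whitney U (rank-sum) test with midrank ties.

    Small samples (n_a + n_b <= 12) use exact enumeration of all
    C(n, n_a) labelings of the pooled values (a permutation test, which
    handles ties naturally); larger samples use the normal approximation with
    tie-corrected variance and continuity correction.  Returns (U, p) where U
    counts pairs won by ``group_a``.
    """
    if alternative not in ("two_sided", "less", "greater"):
        raise ValueError(f"unknown alternative {alternative!r}")
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n_a, n_b = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    u_obs = float(ranks[:n_a].sum() - n_a * (n_a + 1) / 2.0)

    if n_a + n_b <= EXACT_MAX_N:
        mu = n_a * n_b / 2.0
        total = 0
        hits = 0
        base = n_a * (n_a + 1) / 2.0
        for combo in itertools.combinations(range(n_a + n_b), n_a):
            u = ranks[list(combo)].sum() - base
            total += 1
            if alternative == "two_sided":
                hits += abs(u - mu) >= abs(u_obs - mu) - 1e-9
            elif alternative == "greater":
                hits += u >= u_obs - 1e-9
            else:
                hits += u <= u_obs + 1e-9
        return u_obs, hits / total

    mu = n_a * n_b / 2.0
    n = n_a + n_b
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts ** 3) - tie_counts).sum()) / (n * (n - 1))
    sigma2 = n_a * n_b / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return u_obs, 1.0
    sigma = np.sqrt(sigma2)
    if alternative == "two_sided":
        z = max(abs(u_obs - mu) - 0.5, 0.0) / sigma
        p = min(2.0 * float(norm.sf(z)), 1.0)
    elif alternative == "greater":
        p = float(norm.sf((u_obs - mu - 0.5) / sigma))
    else:
        p = float(norm.cdf((u_obs - mu + 0.5) / sigma))
    return u_obs, p


ONCOPRINT_COLUMNS = [
    "patient_id", "sex", "age_at_biopsy", "tmb", "msi_rate", "msi_status",
    "dmmr_exposure", "tmz_exposure", "hrd_exposure", "clock_exposure",
    "germline_genes", "categories", "somatic_drivers", "pretreated",
]


def oncoprint_table(
    results: List[PGVResult],
    samples: List[SamplePair],
    phenotypes: Dict[str, TumorPhenotype],
    path=None,
    msi_params: Optional[MSIParams] = None,
    drivers: Optional[Dict[str, List[str]]] = None,
    dmmr_signatures=("SBS6", "SBS14", "SBS15", "SBS20", "SBS21", "SBS26"),
) -> List[dict]:
    """Per-patient summary rows: one row per patient carrying a PGV and/or
    showing an elevated ms-indel rate.  Optionally written as TSV."""
    msi_params = msi_params or MSIParams()
    drivers = drivers or {}
    by_patient: Dict[str, List[PGVResult]] = {}
    for r in results:
        by_patient.setdefault(r.pgv.patient_id, []).append(r)

    rows = []
    for sample in samples:
        pid = sample.patient_id
        phen = phenotypes.get(pid, TumorPhenotype())
        has_pgv = pid in by_patient
        if not has_pgv and phen.msi_rate <= msi_params.elevated_min:
            continue
        patient_results = by_patient.get(pid, [])
        rows.append({
            "patient_id": pid,
            "sex": sample.sex.value,
            "age_at_biopsy": sample.age_at_biopsy,
            "tmb": phen.tmb,
            "msi_rate": phen.msi_rate,
            "msi_status": phen.msi_status.value,
            "dmmr_exposure": round(sum(phen.exposures.get(s, 0.0) for s in dmmr_signatures), 4),
            "tmz_exposure": round(phen.exposures.get("SBS11", 0.0), 4),
            "hrd_exposure": round(phen.exposures.get("SBS3", 0.0), 4),
            "clock_exposure": round(phen.exposures.get("SBS1", 0.0), 4),
            "germline_genes": ";".join(r.pgv.gene for r in patient_results),
            "categories": ";".join(str(r.category.value) for r in patient_results),
            "somatic_drivers": ";".join(drivers.get(pid, [])),
            "pretreated": int(sample.pretreated),
        })

    if path is not None:
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=ONCOPRINT_COLUMNS,
                                    delimiter="\t", lineterminator="\n")
            writer.writeheader()
            writer.writerows(rows)
    return rows
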