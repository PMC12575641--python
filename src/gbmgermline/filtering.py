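"""Germline variant filters.

Small variants pass four predicates, applied in a fixed order for reproducible
ledgers (the kept set is order-invariant, being a conjunction):

1. synonymous-only canonical coding effect removed;
2. gnomAD non-cancer cumulative frequency strictly above 1% removed
   (population variance);
3. recalibrated Phred quality below the cutoff removed — the cutoff is the
   deepest density valley between the two dominant modes of the cohort's
   quality distribution, with 235.6 as the fallback when the distribution is
   unimodal or too small to estimate;
4. reference-cohort carriers at or above 5% of the reference cohort
   (n = 5778) removed as likely population-specific variants.

Structural variants use only the cohort-frequency filter (gnomAD carries no
non-cancer SV frequencies): SVs seen in >= ceil(0.05 * 5778) = 289 reference
patients are discarded.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.stats import gaussian_kde

from .config import FilterParams
from .types import Effect, GenePanel, GermlineCall, IDHStatus, SamplePair, VariantKind

MIN_SCORES_FOR_DENSITY = 50


@dataclass
class FilterLedger:
    """Per-variant filter outcome; conservation: len(input) = kept + removed."""

    kept: List[GermlineCall] = field(default_factory=list)
    removed: Dict[str, List[GermlineCall]] = field(default_factory=dict)
    reasons: Dict[str, str] = field(default_factory=dict)   # variant key -> first failing filter
    qual_cutoff_used: Optional[float] = None

    def remove(self, call: GermlineCall, reason: str) -> None:
        self.removed.setdefault(reason, []).append(call)
        self.reasons[self._key(call)] = reason

    def keep(self, call: GermlineCall) -> None:
        self.kept.append(call)
        self.reasons[self._key(call)] = "kept"

    @staticmethod
    def _key(call: GermlineCall) -> str:
        return f"{call.patient_id}|{call.variant_id}"

    @property
    def n_removed(self) -> int:
        return sum(len(v) for v in self.removed.values())

    @property
    def n_input(self) -> int:
        return len(self.kept) + self.n_removed

    def removal_counts(self) -> Dict[str, int]:
        return {reason: len(calls) for reason, calls in self.removed.items()}

    def to_rows(self) -> List[tuple]:
        rows = [(c.patient_id, c.variant_id, "kept", "") for c in self.kept]
        for reason, calls in self.removed.items():
            rows.extend((c.patient_id, c.variant_id, "removed", reason) for c in calls)
        return rows


def estimate_quality_cutoff(
    scores,
    bandwidth="auto",
    fallback: float = 235.6,
    grid_size: int = 1024,
) -> float:
    """Phred-quality cutoff from the density of recalibrated scores.

    Fits a Gaussian kernel density (Silverman bandwidth when ``bandwidth`` is
    ``"auto"``) and returns the score at the deepest density minimum between
    the two largest modes.  Fewer than 50 scores, or a unimodal density,
    returns ``fallback`` (with a warning in the unimodal case).
    """
    scores = np.asarray(list(scores), dtype=float)
    if scores.size == 0:
        raise ValueError("estimate_quality_cutoff: empty score list")
    if scores.size < MIN_SCORES_FOR_DENSITY:
        return fallback
    if np.ptp(scores) == 0.0:
        warnings.warn("quality scores are degenerate (all identical); using fallback cutoff")
        return fallback

    bw = None if bandwidth == "auto" else float(bandwidth) / scores.std(ddof=1)
    kde = gaussian_kde(scores, bw_method=bw)
    pad = 0.05 * np.ptp(scores)
    grid = np.linspace(scores.min() - pad, scores.max() + pad, grid_size)
    dens = kde(grid)

    interior = np.arange(1, grid_size - 1)
    is_max = (dens[interior] >= dens[interior - 1]) & (dens[interior] > dens[interior + 1])
    maxima = interior[is_max]
    if maxima.size < 2:
        warnings.warn("quality density is unimodal; using fallback cutoff")
        return fallback
    top_two = maxima[np.argsort(dens[maxima])[-2:]]
    lo, hi = int(top_two.min()), int(top_two.max())
    valley = lo + int(np.argmin(dens[lo:hi + 1]))
    return float(grid[valley])


def resolve_quality_cutoff(scores, params: FilterParams) -> float:
    """The cutoff actually applied: numeric config value, or density estimate."""
    if not isinstance(params.qual_cutoff, str):
        return float(params.qual_cutoff)
    return estimate_quality_cutoff(scores, fallback=params.qual_fallback)


def filter_small_variants(
    calls: List[GermlineCall],
    panel: GenePanel,
    params: Optional[FilterParams] = None,
    qual_cutoff: Optional[float] = None,
) -> FilterLedger:
    """Apply the four small-variant filters; every removal is ledgered under
    its first failing filter.

    Calls must already be panel-scoped; a call in a gene absent from the panel
    is an error (it would silently escape the gene-level category logic).
    """
    params = params or FilterParams()
    for call in calls:
        if call.gene not in panel:
            raise ValueError(f"call {call.variant_id} in gene {call.gene!r} not in panel")

    if qual_cutoff is None:
        qual_cutoff = resolve_quality_cutoff([c.qual for c in calls], params)
    cohort_cutoff = sv_count_threshold(params.cohort_max_fraction, params.reference_cohort_n)

    ledger = FilterLedger(qual_cutoff_used=qual_cutoff)
    for call in calls:
        if params.drop_synonymous and call.effect is Effect.SYNONYMOUS:
            ledger.remove(call, "synonymous")
        elif (call.gnomad_af or 0.0) > params.gnomad_max:
            # missing gnomAD frequency is treated as rare (absent from gnomAD)
            ledger.remove(call, "population_variance")
        elif call.qual < qual_cutoff:
            ledger.remove(call, "low_quality")
        elif call.cohort_count >= cohort_cutoff:
            ledger.remove(call, "cohort_frequency")
        else:
            ledger.keep(call)
    return ledger


def sv_count_threshold(cohort_max_fraction: float, reference_cohort_n: int) -> int:
    """Smallest integer carrier count c with c >= fraction * n.

    With the defaults (0.05, 5778) this is 289: SVs seen in >= 289 reference
    patients are discarded.
    """
    if reference_cohort_n <= 0:
        raise ValueError("reference_cohort_n must be positive")
    if not (0.0 < cohort_max_fraction < 1.0):
        raise ValueError("cohort_max_fraction must be in (0,1)")
    # guard against binary-float overshoot (0.05 * 100 -> 5.000000000000001)
    return int(math.ceil(cohort_max_fraction * reference_cohort_n - 1e-9))


def filter_svs(svs: List[GermlineCall], params: Optional[FilterParams] = None) -> FilterLedger:
    """Cohort-frequency filter for germline SVs (no gnomAD filter applies)."""
    params = params or FilterParams()
    cutoff = sv_count_threshold(params.cohort_max_fraction, params.reference_cohort_n)
    ledger = FilterLedger()
    for sv in svs:
        if sv.kind is not VariantKind.SV:
            raise ValueError(f"{sv.variant_id}: filter_svs expects kind=sv, got {sv.kind.value}")
        if sv.cohort_count is None:
            raise ValueError(f"{sv.variant_id}: missing cohort_count")
        if sv.cohort_count >= cutoff:
            ledger.remove(sv, "cohort_frequency")
        else:
            ledger.keep(sv)
    return ledger


def exclude_idh_mutant(
    samples: List[SamplePair], keep_unknown: bool = True
) -> Tuple[List[SamplePair], List[SamplePair]]:
    """Split the cohort into analyzed (IDH-wildtype) and excluded samples.

    Tumors with a somatic IDH1/2 mutation are astrocytoma WHO grade 4, not
    IDH-wildtype glioblastoma, and leave the analysis set.  Unknown status is
    kept with a warning by default.
    """
    kept, excluded = [], []
    for s in samples:
        if s.idh_status is IDHStatus.MUTANT:
            excluded.append(s)
        elif s.idh_status is IDHStatus.UNKNOWN and not keep_unknown:
            excluded.append(s)
        else:
            if s.idh_status is IDHStatus.UNKNOWN:
                warnings.warn(f"{s.patient_id}: IDH status unknown, kept in analysis set")
            kept.append(s)
    return kept, excluded
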