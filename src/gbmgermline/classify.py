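"""Pathogenicity classification and zygosity resolution.

Variants arrive with a ClinVar-style class and an optional expert-curation
override (the curated call always wins and is logged).  Class 4 (likely
pathogenic) and class 5 (pathogenic) variants become PGVs; everything else —
including conflicting or absent ClinVar states — is treated as VUS-equivalent
and never travels further down the pipeline.

Zygosity context is resolved per patient-gene group:

* dominant genes: each PGV is dominant_monoallelic;
* recessive(-pattern) genes: monoallelic unless the patient carries two or
  more PGVs in the gene, or a homozygous one (biallelic / compound het);
* a patient with >= 2 PGVs in a single mismatch-repair gene is flagged as a
  constitutional mismatch repair deficiency (CMMRD) candidate, regardless of
  that gene's (dominant, Lynch-type) inheritance annotation.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from typing import Dict, List, Optional

from .types import (
    ClinSigRecord,
    ClinVarClass,
    GenePanel,
    Genotype,
    GermlineCall,
    PGV,
    PhenotypeClass,
    ZygosityContext,
)

logger = logging.getLogger(__name__)


def classify_variant(call: GermlineCall, record: Optional[ClinSigRecord]) -> ClinVarClass:
    """Final clinical class for one variant (total function).

    The curation override replaces the ClinVar class when present; absent or
    conflicting ClinVar states resolve to VUS-equivalent (not a PGV).
    """
    if record is None:
        return ClinVarClass.ABSENT
    if record.curation_override is not None:
        logger.info(
            "curation override for %s: %s -> %s (%s)",
            call.variant_id, record.clinvar_class.value,
            record.curation_override.value, record.rationale or "no rationale given",
        )
        return record.curation_override
    if record.clinvar_class is ClinVarClass.CONFLICTING:
        return ClinVarClass.VUS
    return record.clinvar_class


def select_pgvs(
    calls: List[GermlineCall],
    clinsig: Dict[str, ClinSigRecord],
    panel: GenePanel,
) -> List[PGV]:
    """Keep class-4/5 calls as PGVs with their panel gene definition attached.

    Zygosity context is left unresolved; :func:`resolve_zygosity` sets it.
    """
    pgvs = []
    for call in calls:
        final = classify_variant(call, clinsig.get(call.variant_id))
        if not final.is_pathogenic:
            continue
        if call.gene not in panel:
            raise ValueError(f"PGV {call.variant_id} in gene {call.gene!r} absent from panel")
        pgvs.append(PGV(call=call, final_class=final.numeric, gene_def=panel.gene(call.gene)))
    return pgvs


def resolve_zygosity(pgvs: List[PGV]) -> List[PGV]:
    """Set zygosity_context and cmmrd_candidate per (patient, gene) group."""
    groups = defaultdict(list)
    for pgv in pgvs:
        groups[(pgv.patient_id, pgv.gene)].append(pgv)

    for (_, _), group in groups.items():
        biallelic = len(group) >= 2 or any(p.call.genotype is Genotype.HOM for p in group)
        cmmrd = len(group) >= 2 and group[0].gene_def.phenotype_class is PhenotypeClass.MMR
        for pgv in group:
            if pgv.gene_def.inheritance.recessive_pattern:
                pgv.zygosity_context = (
                    ZygosityContext.RECESSIVE_BIALLELIC if biallelic
                    else ZygosityContext.RECESSIVE_MONOALLELIC
                )
            else:
                pgv.zygosity_context = ZygosityContext.DOMINANT_MONOALLELIC
            pgv.cmmrd_candidate = cmmrd
    return pgvs
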