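"""Readers and writers for the call-level formats the pipeline touches.

Supported formats:

* TSV with header — the primary interchange format for every record type.
* Minimal VCF 4.2 — germline/somatic small-variant calls with annotations in
  INFO (GENE, EFFECT, GNOMAD_AF, COHORT_COUNT, ...) and read support in the
  per-sample AD field (ref,alt convention).  Read via pysam.
* BED3+1 — gene panel regions, 0-based half-open, sorted.

Rows that fail the schema are collected with their row number and reason,
never silently dropped; a missing required column raises ``SchemaError``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional

import pysam

from .types import (
    ClinSigRecord,
    ClinVarClass,
    CopyNumberSegment,
    GenomicInterval,
    GenePanel,
    GermlineCall,
    SamplePair,
    SomaticCall,
)


class SchemaError(ValueError):
    pass


@dataclass
class RowError:
    row: int
    message: str


@dataclass
class ParseResult:
    """Parsed records plus the rows that failed the schema."""

    records: List = field(default_factory=list)
    errors: List[RowError] = field(default_factory=list)

    def __iter__(self):
        return iter(self.records)

    def __len__(self):
        return len(self.records)

    def __getitem__(self, idx):
        return self.records[idx]

    def raise_on_errors(self) -> "ParseResult":
        if self.errors:
            detail = "; ".join(f"row {e.row}: {e.message}" for e in self.errors[:5])
            raise SchemaError(f"{len(self.errors)} malformed rows ({detail})")
        return self


GERMLINE_COLUMNS = [
    "patient_id", "gene", "variant_id", "kind", "effect", "genotype",
    "chrom", "pos", "ref", "alt", "hgvs_c", "hgvs_p",
    "gnomad_af", "cohort_count", "qual",
    "normal_alt", "normal_total", "tumor_alt", "tumor_total",
]
GERMLINE_REQUIRED = [
    "patient_id", "gene", "variant_id", "kind", "effect",
    "gnomad_af", "cohort_count", "qual",
]

SOMATIC_COLUMNS = [
    "patient_id", "variant_id", "kind", "effect", "gene",
    "chrom", "pos", "context", "at_microsatellite", "driver_flag",
]
SOMATIC_REQUIRED = ["patient_id", "variant_id", "kind", "effect"]


def _none_if_blank(value: Optional[str]) -> Optional[str]:
    if value is None:
        return None
    value = value.strip()
    return value or None


def _parse_bool(value: Optional[str]) -> bool:
    return (value or "").strip().lower() in ("1", "true", "yes")


def _read_tsv_rows(path):
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file, expected a header line")
        header = [h.strip() for h in reader.fieldnames]
        rows = [dict(zip(header, [row.get(h) for h in reader.fieldnames])) for row in reader]
    return header, rows


def _require_columns(header, required, path) -> None:
    missing = [c for c in required if c not in header]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")


def _germline_from_row(row: dict) -> GermlineCall:
    def reads(prefix):
        alt = _none_if_blank(row.get(f"{prefix}_alt"))
        total = _none_if_blank(row.get(f"{prefix}_total"))
        if alt is None and total is None:
            return (0, 0)
        try:
            return (int(alt), int(total))
        except (TypeError, ValueError):
            raise ValueError(f"malformed {prefix} read counts: alt={alt!r}, total={total!r}")

    gnomad = _none_if_blank(row.get("gnomad_af"))
    pos = _none_if_blank(row.get("pos"))
    return GermlineCall(
        patient_id=row["patient_id"].strip(),
        gene=row["gene"].strip(),
        variant_id=row["variant_id"].strip(),
        kind=row["kind"].strip(),
        effect=row["effect"].strip(),
        genotype=_none_if_blank(row.get("genotype")) or "het",
        chrom=_none_if_blank(row.get("chrom")),
        pos=int(pos) if pos is not None else None,
        ref=_none_if_blank(row.get("ref")),
        alt=_none_if_blank(row.get("alt")),
        hgvs_c=_none_if_blank(row.get("hgvs_c")),
        hgvs_p=_none_if_blank(row.get("hgvs_p")),
        gnomad_af=float(gnomad) if gnomad is not None else None,
        cohort_count=int(_none_if_blank(row.get("cohort_count")) or 0),
        qual=float(_none_if_blank(row.get("qual")) or 0.0),
        normal_reads=reads("normal"),
        tumor_reads=reads("tumor"),
    )


def _somatic_from_row(row: dict) -> SomaticCall:
    pos = _none_if_blank(row.get("pos"))
    return SomaticCall(
        patient_id=row["patient_id"].strip(),
        variant_id=row["variant_id"].strip(),
        kind=row["kind"].strip(),
        effect=row["effect"].strip(),
        gene=_none_if_blank(row.get("gene")),
        chrom=_none_if_blank(row.get("chrom")),
        pos=int(pos) if pos is not None else None,
        context=_none_if_blank(row.get("context")),
        at_microsatellite=_parse_bool(row.get("at_microsatellite")),
        driver_flag=_parse_bool(row.get("driver_flag")),
    )


def read_variant_table(path, schema: str) -> ParseResult:
    """Read germline or somatic calls from TSV (or minimal VCF 4.2).

    ``schema`` is ``"germline"`` or ``"somatic"``.  Files ending in ``.vcf``
    are parsed as VCF; anything else as TSV with header.
    """
    if schema not in ("germline", "somatic"):
        raise ValueError(f"schema must be 'germline' or 'somatic', got {schema!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix == ".vcf":
        return _read_vcf(path, schema)

    required = GERMLINE_REQUIRED if schema == "germline" else SOMATIC_REQUIRED
    parse = _germline_from_row if schema == "germline" else _somatic_from_row
    header, rows = _read_tsv_rows(path)
    _require_columns(header, required, path)
    result = ParseResult()
    for i, row in enumerate(rows, start=2):  # 1-based file lines, after header
        try:
            result.records.append(parse(row))
        except (ValueError, KeyError, AttributeError) as exc:
            result.errors.append(RowError(row=i, message=str(exc)))
    return result


def write_variant_table(calls, path, schema: str) -> None:
    """Write calls as TSV; loss-free inverse of :func:`read_variant_table`."""
    columns = GERMLINE_COLUMNS if schema == "germline" else SOMATIC_COLUMNS
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(columns)
        for c in calls:
            if schema == "germline":
                writer.writerow([
                    c.patient_id, c.gene, c.variant_id, c.kind.value, c.effect.value,
                    c.genotype.value, c.chrom or "", "" if c.pos is None else c.pos,
                    c.ref or "", c.alt or "", c.hgvs_c or "", c.hgvs_p or "",
                    "" if c.gnomad_af is None else repr(c.gnomad_af),
                    c.cohort_count, repr(c.qual),
                    c.normal_reads[0], c.normal_reads[1],
                    c.tumor_reads[0], c.tumor_reads[1],
                ])
            else:
                writer.writerow([
                    c.patient_id, c.variant_id, c.kind.value, c.effect.value,
                    c.gene or "", c.chrom or "", "" if c.pos is None else c.pos,
                    c.context or "", int(c.at_microsatellite), int(c.driver_flag),
                ])


# --- minimal VCF 4.2 -------------------------------------------------------

_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=EFFECT,Number=1,Type=String,Description="Canonical coding effect">
##INFO=<ID=KIND,Number=1,Type=String,Description="Variant kind (snv/mnv/indel/sv)">
##INFO=<ID=GNOMAD_AF,Number=1,Type=Float,Description="gnomAD non-cancer cumulative frequency">
##INFO=<ID=COHORT_COUNT,Number=1,Type=Integer,Description="Carriers in the reference cohort">
##INFO=<ID=HGVSC,Number=1,Type=String,Description="HGVS coding">
##INFO=<ID=HGVSP,Number=1,Type=String,Description="HGVS protein">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt)">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tNORMAL\tTUMOR
"""


def write_vcf(calls, path, patient_id: Optional[str] = None) -> None:
    """Write germline small-variant calls as a minimal single-patient VCF 4.2.

    Positions are written 1-based per the VCF convention (internal coordinates
    are 0-based half-open).
    """
    calls = [c for c in calls if patient_id is None or c.patient_id == patient_id]
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for c in sorted(calls, key=lambda c: (c.chrom or "", c.pos or 0)):
            if c.chrom is None or c.pos is None:
                raise ValueError(f"{c.variant_id}: VCF output requires chrom/pos")
            info = (
                f"GENE={c.gene};EFFECT={c.effect.value};KIND={c.kind.value};"
                f"GNOMAD_AF={0.0 if c.gnomad_af is None else c.gnomad_af:g};"
                f"COHORT_COUNT={c.cohort_count}"
            )
            if c.hgvs_c:
                info += f";HGVSC={c.hgvs_c}"
            if c.hgvs_p:
                info += f";HGVSP={c.hgvs_p}"
            gt = "1/1" if c.genotype.value == "hom" else "0/1"
            nr = f"{c.normal_reads[1] - c.normal_reads[0]},{c.normal_reads[0]}"
            tr = f"{c.tumor_reads[1] - c.tumor_reads[0]},{c.tumor_reads[0]}"
            fh.write(
                f"{c.chrom}\t{c.pos + 1}\t{c.variant_id}\t{c.ref or 'N'}\t"
                f"{c.alt or 'N'}\t{c.qual:g}\tPASS\t{info}\tGT:AD\t{gt}:{nr}\t{gt}:{tr}\n"
            )


def _read_vcf(path, schema: str) -> ParseResult:
    result = ParseResult()
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for i, rec in enumerate(vcf.fetch()):
            try:
                result.records.append(_call_from_vcf_record(rec, samples, schema, path))
            except (ValueError, KeyError) as exc:
                result.errors.append(RowError(row=i + 1, message=str(exc)))
    return result


def _ad_to_reads(fmt) -> tuple:
    ad = fmt.get("AD")
    if ad is None:
        return (0, 0)
    ref, alt = int(ad[0]), int(ad[1])
    if ref < 0 or alt < 0:
        raise ValueError(f"malformed AD field: {ad}")
    return (alt, ref + alt)


def _call_from_vcf_record(rec, samples, schema, path):
    info = dict(rec.info)
    for key in ("GENE", "EFFECT"):
        if key not in info:
            raise SchemaError(f"{path}: VCF record {rec.id or rec.pos} missing INFO/{key}")
    if schema == "somatic":
        return SomaticCall(
            patient_id=samples[0] if samples else "unknown",
            variant_id=rec.id or f"{rec.chrom}:{rec.pos}:{rec.ref}:{rec.alts[0]}",
            kind=info.get("KIND", "snv"),
            effect=info["EFFECT"],
            gene=info.get("GENE"),
            chrom=rec.chrom,
            pos=rec.pos - 1,
            context=info.get("CONTEXT"),
            at_microsatellite=bool(info.get("MS", False)),
            driver_flag=bool(info.get("DRIVER", False)),
        )
    normal = _ad_to_reads(rec.samples["NORMAL"]) if "NORMAL" in rec.samples else (0, 0)
    tumor = _ad_to_reads(rec.samples["TUMOR"]) if "TUMOR" in rec.samples else (0, 0)
    gt = rec.samples["NORMAL"].get("GT") if "NORMAL" in rec.samples else None
    genotype = "hom" if gt is not None and all(a == 1 for a in gt if a is not None) else "het"
    return GermlineCall(
        patient_id=info.get("PATIENT", "NORMAL"),
        gene=str(info["GENE"]),
        variant_id=rec.id or f"{rec.chrom}:{rec.pos}:{rec.ref}:{rec.alts[0]}",
        kind=str(info.get("KIND", "snv")),
        effect=str(info["EFFECT"]),
        genotype=genotype,
        chrom=rec.chrom,
        pos=rec.pos - 1,
        ref=rec.ref,
        alt=rec.alts[0] if rec.alts else None,
        hgvs_c=info.get("HGVSC"),
        hgvs_p=info.get("HGVSP"),
        gnomad_af=float(info["GNOMAD_AF"]) if "GNOMAD_AF" in info else None,
        cohort_count=int(info.get("COHORT_COUNT", 0)),
        qual=float(rec.qual or 0.0),
        normal_reads=normal,
        tumor_reads=tumor,
    )


# --- BED -------------------------------------------------------------------

def write_panel_bed(panel: GenePanel, path) -> None:
    """Write the panel regions as BED3+1 (chrom, start, end, gene).

    0-based half-open, sorted by chrom then start; no header line.
    """
    lines = []
    for symbol, intervals in panel.regions.items():
        for iv in intervals:
            lines.append((iv.chrom, iv.start, iv.end, symbol))
    lines.sort(key=lambda t: (t[0], t[1], t[2]))
    with open(path, "w") as fh:
        for chrom, start, end, symbol in lines:
            fh.write(f"{chrom}\t{start}\t{end}\t{symbol}\n")


def read_panel_bed(path) -> dict:
    """Read a BED3+1 panel file back into ``{gene: [GenomicInterval, ...]}``."""
    regions: dict = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise SchemaError(f"{path}:{line_no}: expected 4 BED columns, got {len(parts)}")
            chrom, start, end, gene = parts[:4]
            regions.setdefault(gene, []).append(
                GenomicInterval(chrom=chrom, start=int(start), end=int(end))
            )
    return regions


# --- auxiliary tables ------------------------------------------------------

def read_samples(path) -> List[SamplePair]:
    header, rows = _read_tsv_rows(path)
    _require_columns(header, ["patient_id"], path)
    out = []
    for row in rows:
        out.append(SamplePair(
            patient_id=row["patient_id"].strip(),
            sex=_none_if_blank(row.get("sex")) or "unknown",
            age_at_biopsy=float(_none_if_blank(row.get("age_at_biopsy")) or 60.0),
            purity=float(_none_if_blank(row.get("purity")) or 1.0),
            idh_status=_none_if_blank(row.get("idh_status")) or "unknown",
            tumor_type=_none_if_blank(row.get("tumor_type")) or "glioblastoma",
            pretreated=_parse_bool(row.get("pretreated")),
        ))
    return out


def write_samples(samples, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["patient_id", "sex", "age_at_biopsy", "purity",
                         "idh_status", "tumor_type", "pretreated"])
        for s in samples:
            writer.writerow([s.patient_id, s.sex.value, repr(s.age_at_biopsy),
                             repr(s.purity), s.idh_status.value, s.tumor_type,
                             int(s.pretreated)])


def read_segments(path) -> List[CopyNumberSegment]:
    header, rows = _read_tsv_rows(path)
    _require_columns(header, ["patient_id", "chrom", "start", "end",
                              "total_cn", "minor_cn"], path)
    out = []
    for row in rows:
        out.append(CopyNumberSegment(
            patient_id=row["patient_id"].strip(),
            interval=GenomicInterval(row["chrom"].strip(), int(row["start"]), int(row["end"])),
            total_cn=float(row["total_cn"]),
            minor_cn=float(row["minor_cn"]),
            arm_label=_none_if_blank(row.get("arm_label")),
        ))
    return out


def write_segments(segments, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["patient_id", "chrom", "start", "end",
                         "total_cn", "minor_cn", "arm_label"])
        for s in segments:
            writer.writerow([s.patient_id, s.interval.chrom, s.interval.start,
                             s.interval.end, repr(s.total_cn), repr(s.minor_cn),
                             s.arm_label or ""])


def read_clinsig(path) -> List[ClinSigRecord]:
    header, rows = _read_tsv_rows(path)
    _require_columns(header, ["variant_id", "clinvar_class"], path)
    out = []
    for row in rows:
        override = _none_if_blank(row.get("override"))
        out.append(ClinSigRecord(
            variant_id=row["variant_id"].strip(),
            clinvar_class=ClinVarClass(row["clinvar_class"].strip()),
            curation_override=ClinVarClass(override) if override else None,
            rationale=_none_if_blank(row.get("rationale")) or "",
        ))
    return out


def write_clinsig(records, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["variant_id", "clinvar_class", "override", "rationale"])
        for r in records:
            writer.writerow([
                r.variant_id, r.clinvar_class.value,
                r.curation_override.value if r.curation_override else "",
                r.rationale,
            ])
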