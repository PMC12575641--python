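"""Genome-wide tumor phenotypes: microsatellite instability and SBS signatures.

MSI is scored MSIsensor-style at the call level: somatic indels lying in (or
flagged at) short tandem repeat tracts, per megabase.  Two thresholds define
the status: a rate strictly above 1.3 ms-indels/Mb is *elevated*, and at or
above the diagnostic cutoff of 4 ms-indels/Mb is *MSI*.

Single-base-substitution catalogs use the standard 96 trinucleotide channels
(pyrimidine-reference convention, COSMIC ordering); exposures against a
signature matrix are fitted by non-negative least squares, which is
deterministic and exact for noiseless mixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.optimize import nnls

from .config import MSIParams, SignatureParams
from .types import (
    GeneDef,
    GenomicInterval,
    MSIStatus,
    PhenotypeClass,
    SomaticCall,
    TumorPhenotype,
    VariantKind,
)

# --- 96-channel catalog ----------------------------------------------------

_SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: the 96 trinucleotide-substitution channels in COSMIC order
COSMIC_CHANNELS: List[str] = [
    f"{five}[{sub}]{three}"
    for sub in _SUBSTITUTIONS
    for five in _BASES
    for three in _BASES
]
_CHANNEL_INDEX = {label: i for i, label in enumerate(COSMIC_CHANNELS)}


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def context_to_channel(context: str) -> str:
    """Map a ``"ACA>AAA"``-style context (ref triplet > alt triplet, or ref
    triplet > alt base) to its pyrimidine-convention channel label.

    Purine-reference contexts are reverse-complemented.
    """
    try:
        ref, alt = context.split(">")
    except (ValueError, AttributeError):
        raise ValueError(f"malformed context {context!r}: expected 'REF>ALT'")
    ref, alt = ref.strip().upper(), alt.strip().upper()
    if len(ref) != 3 or any(b not in _BASES for b in ref):
        raise ValueError(f"malformed context {context!r}: reference triplet required")
    if len(alt) == 3:
        if alt[0] != ref[0] or alt[2] != ref[2]:
            raise ValueError(f"malformed context {context!r}: flanks must match")
        alt_base = alt[1]
    elif len(alt) == 1:
        alt_base = alt
    else:
        raise ValueError(f"malformed context {context!r}: alt must be a base or triplet")
    if alt_base not in _BASES:
        raise ValueError(f"malformed context {context!r}: invalid alt base")
    if alt_base == ref[1]:
        raise ValueError(f"malformed context {context!r}: ref and alt base identical")

    if ref[1] in "AG":  # purine reference: fold to pyrimidine strand
        ref = _revcomp(ref)
        alt_base = alt_base.translate(_COMPLEMENT)
    return f"{ref[0]}[{ref[1]}>{alt_base}]{ref[2]}"


def build_catalog(snvs: List[SomaticCall]) -> np.ndarray:
    """96-channel count vector from somatic SNVs with trinucleotide contexts.

    Conservation: the channel sums always equal the number of input SNVs.
    Malformed contexts raise a single error listing every offender.
    """
    counts = np.zeros(96, dtype=float)
    offenders = []
    for call in snvs:
        if call.kind is not VariantKind.SNV:
            continue
        try:
            counts[_CHANNEL_INDEX[context_to_channel(call.context)]] += 1
        except ValueError:
            offenders.append(f"{call.variant_id}:{call.context!r}")
    if offenders:
        raise ValueError(f"malformed trinucleotide contexts: {', '.join(offenders)}")
    return counts


# --- signature matrix and exposures ---------------------------------------

@dataclass
class SignatureMatrix:
    """Named non-negative signature profiles over the 96 COSMIC channels."""

    names: List[str]
    matrix: np.ndarray                     # shape (96, n_signatures)
    channels: List[str] = field(default_factory=lambda: list(COSMIC_CHANNELS))

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if len(self.channels) != 96:
            raise ValueError(f"expected 96 channels, got {len(self.channels)}")
        if self.matrix.shape != (96, len(self.names)):
            raise ValueError(
                f"matrix shape {self.matrix.shape} != (96, {len(self.names)})"
            )
        if (self.matrix < 0).any():
            raise ValueError("signature weights must be non-negative")
        sums = self.matrix.sum(axis=0)
        bad = [n for n, s in zip(self.names, sums) if abs(s - 1.0) > 1e-6]
        if bad:
            raise ValueError(f"signature columns must sum to 1: {bad}")

    def column(self, name: str) -> np.ndarray:
        return self.matrix[:, self.names.index(name)]


@dataclass
class SignatureExposure:
    absolute: Dict[str, float]
    relative: Dict[str, float]
    residual_norm: float

    def group_exposure(self, names) -> float:
        return sum(self.relative.get(n, 0.0) for n in names)


def fit_exposures(catalog: np.ndarray, matrix: SignatureMatrix) -> SignatureExposure:
    """Non-negative least-squares decomposition of a 96-channel catalog.

    Minimises ``||catalog - M @ e||_2`` over e >= 0; relative exposures are the
    absolute ones normalised by their total (all zero when the catalog is
    empty).
    """
    catalog = np.asarray(catalog, dtype=float)
    if catalog.shape != (96,):
        raise ValueError(f"catalog must have 96 channels, got shape {catalog.shape}")
    exposures, residual = nnls(matrix.matrix, catalog)
    total = exposures.sum()
    relative = exposures / total if total > 0 else np.zeros_like(exposures)
    return SignatureExposure(
        absolute=dict(zip(matrix.names, exposures.tolist())),
        relative=dict(zip(matrix.names, relative.tolist())),
        residual_norm=float(residual),
    )


def write_signature_matrix(matrix: SignatureMatrix, path) -> None:
    """COSMIC-layout TSV: one row per channel label, one column per signature."""
    with open(path, "w") as fh:
        fh.write("Type\t" + "\t".join(matrix.names) + "\n")
        for i, channel in enumerate(matrix.channels):
            fh.write(channel + "\t" + "\t".join(repr(float(v)) for v in matrix.matrix[i]) + "\n")


def read_signature_matrix(path) -> SignatureMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        names = header[1:]
        rows: Dict[str, List[float]] = {}
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            rows[parts[0]] = [float(v) for v in parts[1:]]
    missing = [c for c in COSMIC_CHANNELS if c not in rows]
    if missing:
        raise ValueError(f"signature matrix missing {len(missing)} channels, e.g. {missing[:3]}")
    matrix = np.array([rows[c] for c in COSMIC_CHANNELS])
    return SignatureMatrix(names=names, matrix=matrix)


def toy_signature_matrix() -> SignatureMatrix:
    """Synthetic six-signature reference matrix for tests and simulations.

    The columns are *stylised stand-ins*, not the measured COSMIC profiles:
    they occupy distinct channel supports so that mixtures are identifiable —
    an SBS1-like NpCpG C>T spike, an SBS6-like C>T profile, an SBS11-like and
    an SBS15-like profile, a broad SBS3-like profile and a flat noise column.
    Any real COSMIC-format matrix can be supplied instead.
    """
    def profile(weights: Dict[str, float]) -> np.ndarray:
        col = np.zeros(96)
        for label, w in weights.items():
            col[_CHANNEL_INDEX[label]] = w
        return col / col.sum()

    ncg = [f"{b}[C>T]G" for b in _BASES]
    ct_other = [f"{f}[C>T]{t}" for f in _BASES for t in "ACT"]
    ca_all = [f"{f}[C>A]{t}" for f in _BASES for t in _BASES]
    tc_all = [f"{f}[T>C]{t}" for f in _BASES for t in _BASES]
    cg_ta = [f"{f}[C>G]{t}" for f in _BASES for t in _BASES] + \
            [f"{f}[T>A]{t}" for f in _BASES for t in _BASES]

    cols = {
        "SBS1": profile({**{c: 0.24 for c in ncg},
                         **{c: 0.04 / len(ct_other) for c in ct_other}}),
        "SBS3": profile({c: 1.0 for c in cg_ta}),
        "SBS6": profile({c: 1.0 for c in ct_other}),
        "SBS11": profile({c: 1.0 for c in ca_all}),
        "SBS15": profile({c: 1.0 for c in tc_all}),
        "flat": np.full(96, 1.0 / 96),
    }
    return SignatureMatrix(names=list(cols), matrix=np.column_stack(list(cols.values())))


# --- microsatellites -------------------------------------------------------

@dataclass(frozen=True)
class MicrosatelliteSite:
    interval: GenomicInterval
    unit: str
    unit_count: int

    def __post_init__(self) -> None:
        if self.interval.length != len(self.unit) * self.unit_count:
            raise ValueError("interval length must equal len(unit) * unit_count")


@dataclass
class MSIResult:
    ms_indels_per_mb: float
    status: MSIStatus
    elevated_min: float
    diagnostic_min: float


def _is_primitive(unit: str) -> bool:
    n = len(unit)
    for d in range(1, n):
        if n % d == 0 and unit == unit[:d] * (n // d):
            return False
    return True


def detect_microsatellites(
    sequence: str,
    min_repeats: int = 5,
    max_unit: int = 5,
    chrom: str = "seq",
) -> List[MicrosatelliteSite]:
    """Maximal non-overlapping perfect repeat tracts in a nucleotide sequence.

    Units are primitive (smallest rotational period); tracts need at least
    ``min_repeats`` full units.  Overlaps between candidate tracts of
    different unit lengths are resolved greedily by start position, shorter
    unit first.  ``N`` breaks tracts; any other non-nucleotide character is an
    error.
    """
    seq = sequence.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"non-nucleotide characters in sequence: {sorted(bad)}")

    n = len(seq)
    candidates: List[Tuple[int, int, str, int]] = []  # (start, unit_len, unit, count)
    for u in range(1, max_unit + 1):
        i = 0
        while i + u * min_repeats <= n:
            unit = seq[i:i + u]
            if "N" in unit or not _is_primitive(unit):
                i += 1
                continue
            if i >= u and seq[i - u:i] == unit:
                i += 1  # not leftmost: the maximal tract started earlier
                continue
            count = 1
            j = i + u
            while seq[j:j + u] == unit:
                count += 1
                j += u
            if count >= min_repeats:
                candidates.append((i, u, unit, count))
            # advance by one: rotated tracts starting just inside this one
            # (e.g. GGAT... after TGGA...) are still legal candidates, and
            # interior starts are rejected cheaply by the leftmost check
            i += 1

    candidates.sort(key=lambda c: (c[0], c[1]))
    sites: List[MicrosatelliteSite] = []
    last_end = -1
    for start, u, unit, count in candidates:
        end = start + u * count
        if start >= last_end:
            sites.append(MicrosatelliteSite(
                interval=GenomicInterval(chrom, start, end), unit=unit, unit_count=count,
            ))
            last_end = end
    return sites


def count_ms_indels(
    indels: List[SomaticCall],
    sites: Optional[List[MicrosatelliteSite]] = None,
    genome_size_mb: float = 2900.0,
    params: Optional[MSIParams] = None,
) -> MSIResult:
    """Microsatellite-indel rate and MSI status for one patient.

    An indel counts when it is flagged ``at_microsatellite`` or its position
    falls inside a detected repeat tract.  Indel *events* are counted, not
    unique sites.
    """
    if genome_size_mb <= 0:
        raise ValueError("genome_size_mb must be > 0")
    params = params or MSIParams()
    sites = sites or []
    count = 0
    for call in indels:
        if call.kind is not VariantKind.INDEL:
            continue
        if call.at_microsatellite:
            count += 1
        elif call.chrom is not None and call.pos is not None and any(
            s.interval.contains(call.chrom, call.pos) for s in sites
        ):
            count += 1
    rate = count / genome_size_mb
    return MSIResult(
        ms_indels_per_mb=rate,
        status=msi_status(rate, params),
        elevated_min=params.elevated_min,
        diagnostic_min=params.diagnostic_min,
    )


def msi_status(rate: float, params: Optional[MSIParams] = None) -> MSIStatus:
    """Step function of the ms-indel rate: > elevated_min exclusive,
    >= diagnostic_min inclusive."""
    params = params or MSIParams()
    if rate >= params.diagnostic_min:
        return MSIStatus.MSI
    if rate > params.elevated_min:
        return MSIStatus.ELEVATED
    return MSIStatus.MSS


# --- phenotype matching ----------------------------------------------------

def phenotype_match(
    gene_def: GeneDef,
    phenotype: TumorPhenotype,
    params: Optional[SignatureParams] = None,
) -> Tuple[bool, str]:
    """Whether the genome-wide phenotype matches the gene's expected footprint.

    MMR genes match on MSI status or a dMMR-group signature exposure at or
    above ``dmmr_min``; HRD genes on SBS3-like exposure at or above
    ``hrd_min``; genes with no expected footprint never match.
    """
    params = params or SignatureParams()
    if gene_def.phenotype_class is PhenotypeClass.MMR:
        if phenotype.msi_status is MSIStatus.MSI:
            return True, "MSI"
        dmmr = sum(phenotype.exposures.get(s, 0.0) for s in params.dmmr_signatures)
        if dmmr >= params.dmmr_min:
            return True, "dMMR signature"
        return False, ""
    if gene_def.phenotype_class is PhenotypeClass.HRD:
        if phenotype.exposures.get(params.hrd_signature, 0.0) >= params.hrd_min:
            return True, "HRD signature"
        return False, ""
    return False, ""
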