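"""Microsatellite scanning, SBS catalogs, exposure fitting, phenotype match."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gbmgermline.config import SignatureParams
from gbmgermline.phenotypes import (
    COSMIC_CHANNELS,
    MSIParams,
    build_catalog,
    context_to_channel,
    count_ms_indels,
    detect_microsatellites,
    fit_exposures,
    msi_status,
    phenotype_match,
    read_signature_matrix,
    toy_signature_matrix,
    write_signature_matrix,
    _is_primitive,
)
from gbmgermline.types import MSIStatus, SomaticCall, TumorPhenotype


def _snv(context, i=0):
    return SomaticCall(patient_id="p", variant_id=f"s{i}", kind="snv",
                       effect="missense", context=context)


def _indel(i=0, at_ms=True):
    return SomaticCall(patient_id="p", variant_id=f"i{i}", kind="indel",
                       effect="frameshift", at_microsatellite=at_ms)


class TestMicrosatellites:
    def test_homopolymer(self):
        (site,) = detect_microsatellites("AAAAAA", min_repeats=5)
        assert (site.unit, site.unit_count) == ("A", 6)
        assert (site.interval.start, site.interval.end) == (0, 6)

    def test_minimal_unit_reported(self):
        (site,) = detect_microsatellites("ACACACACAC", min_repeats=5)
        assert (site.unit, site.unit_count) == ("AC", 5)

    def test_no_sites_below_min_repeats(self):
        assert detect_microsatellites("ACACACAC", min_repeats=5) == []

    def test_n_breaks_tracts(self):
        assert detect_microsatellites("AAANAAA", min_repeats=5) == []

    def test_invalid_characters_error(self):
        with pytest.raises(ValueError, match="non-nucleotide"):
            detect_microsatellites("ACGTX")

    def test_matches_brute_force_on_random_sequence(self):
        rng = np.random.default_rng(13)
        # repeat-enriched random sequence: occasional unit expansions
        parts = []
        for _ in range(2000):
            if rng.random() < 0.05:
                unit = "".join(rng.choice(list("ACGT"), size=rng.integers(1, 6)))
                parts.append(unit * int(rng.integers(3, 12)))
            else:
                parts.append("".join(rng.choice(list("ACGT"), size=50)))
        seq = "".join(parts)[:100_000]
        fast = detect_microsatellites(seq)
        slow = _brute_force_sites(seq, min_repeats=5, max_unit=5)
        assert [(s.interval.start, s.interval.end, s.unit, s.unit_count)
                for s in fast] == slow


def _brute_force_sites(seq, min_repeats, max_unit):
    """Quadratic reference scanner: test every (start, unit) pair."""
    n = len(seq)
    candidates = []
    for start in range(n):
        for u in range(1, max_unit + 1):
            unit = seq[start:start + u]
            if len(unit) < u or "N" in unit or not _is_primitive(unit):
                continue
            if start >= u and seq[start - u:start] == unit:
                continue  # not the leftmost start of this tract
            count = 0
            while seq[start + count * u:start + (count + 1) * u] == unit:
                count += 1
            if count >= min_repeats:
                candidates.append((start, u, unit, count))
    candidates.sort(key=lambda c: (c[0], c[1]))
    chosen, last_end = [], -1
    for start, u, unit, count in candidates:
        if start >= last_end:
            chosen.append((start, start + u * count, unit, count))
            last_end = start + u * count
    return chosen


class TestMSICounting:
    def test_zero_indels_mss(self):
        result = count_ms_indels([], genome_size_mb=2900)
        assert result.ms_indels_per_mb == 0 and result.status is MSIStatus.MSS

    def test_rate_counts_events_per_mb(self):
        indels = [_indel(i) for i in range(50)] + [_indel(99, at_ms=False)]
        result = count_ms_indels(indels, genome_size_mb=10)
        assert result.ms_indels_per_mb == pytest.approx(5.0)
        assert result.status is MSIStatus.MSI

    @pytest.mark.parametrize("rate,status", [
        (0.0, MSIStatus.MSS),
        (1.3, MSIStatus.MSS),       # elevated threshold is exclusive
        (1.31, MSIStatus.ELEVATED),
        (3.99, MSIStatus.ELEVATED),
        (4.0, MSIStatus.MSI),       # diagnostic threshold is inclusive
        (48.2, MSIStatus.MSI),
    ])
    def test_status_step_function(self, rate, status):
        assert msi_status(rate) is status

    def test_fixture_rates_reproduce_7_elevated_6_diagnostic(self, fixture):
        rates = [row.msi_rate for row in fixture.rows]
        assert sum(r > 1.3 for r in rates) == 7
        assert sum(r >= 4 for r in rates) == 6


class TestCatalog:
    def test_single_context(self):
        catalog = build_catalog([_snv("ACA>AAA")])
        assert catalog[COSMIC_CHANNELS.index("A[C>A]A")] == 1
        assert catalog.sum() == 1

    def test_purine_reference_folded(self):
        # TGT with G>A == revcomp ACA with C>T
        catalog = build_catalog([_snv("TGT>TAT")])
        assert catalog[COSMIC_CHANNELS.index("A[C>T]A")] == 1

    def test_malformed_context_lists_offenders(self):
        with pytest.raises(ValueError, match="s1"):
            build_catalog([_snv("ACA>AAA", 0), _snv("AC>AA", 1)])

    def test_channel_labels_cover_all_96(self):
        folded = {context_to_channel(f"{f}{r}{t}>{f}{a}{t}")
                  for f in "ACGT" for t in "ACGT"
                  for r in "ACGT" for a in "ACGT" if a != r}
        assert folded == set(COSMIC_CHANNELS)

    @given(st.lists(st.integers(0, 95), max_size=200))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_catalog_conserves_snv_count(self, channels):
        calls = []
        for i, ch in enumerate(channels):
            label = COSMIC_CHANNELS[ch]
            five, ref, alt, three = label[0], label[2], label[4], label[6]
            calls.append(_snv(f"{five}{ref}{three}>{five}{alt}{three}", i))
        assert build_catalog(calls).sum() == len(channels)


class TestExposures:
    def test_exact_single_signature_recovered(self, toy_matrix):
        catalog = 300 * toy_matrix.column("SBS1")
        exposure = fit_exposures(catalog, toy_matrix)
        assert exposure.absolute["SBS1"] == pytest.approx(300, abs=1e-6)
        assert exposure.residual_norm == pytest.approx(0, abs=1e-9)
        others = [v for k, v in exposure.absolute.items() if k != "SBS1"]
        assert max(others) < 1e-9

    def test_two_signature_mixture_recovered(self, toy_matrix):
        rng = np.random.default_rng(21)
        mix = 0.7 * toy_matrix.column("SBS6") + 0.3 * toy_matrix.column("SBS3")
        catalog = rng.multinomial(5000, mix).astype(float)
        exposure = fit_exposures(catalog, toy_matrix)
        assert abs(exposure.relative["SBS6"] - 0.7) < 0.05
        assert abs(exposure.relative["SBS3"] - 0.3) < 0.05

    def test_matches_simplex_grid_search(self, toy_matrix):
        """NNLS beats (or ties) a fine grid search over 3-signature mixtures."""
        from gbmgermline.phenotypes import SignatureMatrix

        rng = np.random.default_rng(3)
        names = ["SBS1", "SBS6", "SBS3"]
        cols = np.column_stack([toy_matrix.column(n) for n in names])
        small = SignatureMatrix(names=names, matrix=cols)
        catalog = rng.multinomial(2000, cols @ np.array([0.5, 0.3, 0.2])).astype(float)
        exposure = fit_exposures(catalog, small)

        total = catalog.sum()
        best, best_resid = None, np.inf
        steps = np.linspace(0, 1, 51)
        for a, b in itertools.product(steps, steps):
            if a + b > 1:
                continue
            weights = np.array([a, b, 1 - a - b]) * total
            resid = np.linalg.norm(catalog - cols @ weights)
            if resid < best_resid:
                best, best_resid = weights, resid
        assert exposure.residual_norm <= best_resid + 1e-6
        fitted = np.array([exposure.absolute[n] for n in names])
        assert np.allclose(fitted / total, best / total, atol=0.03)

    def test_zero_catalog_zero_relative(self, toy_matrix):
        exposure = fit_exposures(np.zeros(96), toy_matrix)
        assert all(v == 0 for v in exposure.relative.values())

    def test_channel_mismatch_errors(self, toy_matrix):
        with pytest.raises(ValueError):
            fit_exposures(np.zeros(95), toy_matrix)

    def test_matrix_tsv_round_trip(self, toy_matrix, tmp_path):
        path = tmp_path / "sigs.tsv"
        write_signature_matrix(toy_matrix, path)
        back = read_signature_matrix(path)
        assert back.names == toy_matrix.names
        assert np.allclose(back.matrix, toy_matrix.matrix)


class TestPhenotypeMatch:
    def test_brca1_high_sbs3(self, panel):
        phen = TumorPhenotype(exposures={"SBS3": 0.4, "SBS1": 0.6})
        matched, label = phenotype_match(panel.gene("BRCA1"), phen)
        assert matched and label == "HRD signature"

    def test_msh6_msi_status(self, panel):
        phen = TumorPhenotype(msi_rate=7.8, msi_status="msi",
                              exposures={"SBS1": 1.0})
        matched, label = phenotype_match(panel.gene("MSH6"), phen)
        assert matched and label == "MSI"

    def test_msh6_dmmr_signature_without_msi(self, panel):
        phen = TumorPhenotype(exposures={"SBS6": 0.15, "SBS1": 0.85})
        matched, label = phenotype_match(panel.gene("MSH6"), phen)
        assert matched and label == "dMMR signature"

    def test_chek2_never_matches(self, panel):
        phen = TumorPhenotype(msi_rate=50, msi_status="msi",
                              exposures={"SBS3": 1.0})
        assert phenotype_match(panel.gene("CHEK2"), phen) == (False, "")

    def test_pole_group_only_when_enabled(self):
        params = SignatureParams()
        assert "SBS10" not in params.dmmr_signatures
        params = SignatureParams(include_pole=True)
        assert "SBS10" in params.dmmr_signatures
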