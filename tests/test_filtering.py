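"""Germline filters: quality-cutoff estimation, predicate filters, ledgers."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import gaussian_kde

from gbmgermline.config import FilterParams
from gbmgermline.filtering import (
    estimate_quality_cutoff,
    exclude_idh_mutant,
    filter_small_variants,
    filter_svs,
    sv_count_threshold,
)
from gbmgermline.types import GermlineCall, SamplePair


def _call(i, gene="MSH6", effect="missense", gnomad=0.0001, cohort=0, qual=500.0,
          kind="snv"):
    return GermlineCall(
        patient_id=f"P{i}", gene=gene, variant_id=f"v{i}", kind=kind,
        effect=effect, gnomad_af=gnomad, cohort_count=cohort, qual=qual,
    )


class TestQualityCutoff:
    def test_bimodal_cutoff_lies_between_modes(self):
        rng = np.random.default_rng(0)
        scores = np.concatenate([rng.normal(100, 15, 300), rng.normal(300, 25, 300)])
        cutoff = estimate_quality_cutoff(scores)
        assert 130 < cutoff < 270
        # independent oracle: exhaustive scan of a fine-grained KDE valley
        kde = gaussian_kde(scores)
        grid = np.linspace(scores.min(), scores.max(), 20000)
        dens = kde(grid)
        inner = (grid > 100) & (grid < 300)
        oracle = grid[inner][np.argmin(dens[inner])]
        assert abs(cutoff - oracle) < 5.0

    def test_small_sample_returns_fallback(self):
        assert estimate_quality_cutoff(list(range(10))) == 235.6

    def test_degenerate_scores_fallback_with_warning(self):
        with pytest.warns(UserWarning, match="degenerate|unimodal"):
            assert estimate_quality_cutoff([250.0] * 100) == 235.6

    def test_unimodal_fallback_with_warning(self):
        rng = np.random.default_rng(1)
        with pytest.warns(UserWarning, match="unimodal"):
            cutoff = estimate_quality_cutoff(rng.normal(250, 1e-3, 200))
        assert cutoff == 235.6

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            estimate_quality_cutoff([])


class TestSmallVariantFilters:
    def test_population_variance_boundary(self, panel):
        params = FilterParams(qual_cutoff=235.6)
        ledger = filter_small_variants(
            [_call(0, gnomad=0.02), _call(1, gnomad=0.01)], panel, params)
        assert [c.variant_id for c in ledger.removed["population_variance"]] == ["v0"]
        assert [c.variant_id for c in ledger.kept] == ["v1"]

    def test_quality_boundary_inclusive(self, panel):
        params = FilterParams(qual_cutoff=235.6)
        ledger = filter_small_variants(
            [_call(0, qual=235.5), _call(1, qual=235.6)], panel, params)
        assert [c.variant_id for c in ledger.removed["low_quality"]] == ["v0"]
        assert [c.variant_id for c in ledger.kept] == ["v1"]

    def test_unknown_gene_errors(self, panel):
        with pytest.raises(ValueError, match="NOTAGENE"):
            filter_small_variants([_call(0, gene="NOTAGENE")], panel)

    def test_kept_set_equals_brute_force_conjunction(self, panel):
        rng = np.random.default_rng(7)
        params = FilterParams(qual_cutoff=235.6)
        calls = []
        for i in range(200):
            calls.append(_call(
                i,
                effect=str(rng.choice(["missense", "synonymous", "nonsense"])),
                gnomad=float(rng.choice([0.0, 0.005, 0.02, 0.3])),
                cohort=int(rng.choice([0, 3, 289, 600])),
                qual=float(rng.uniform(50, 600)),
            ))
        ledger = filter_small_variants(calls, panel, params)
        threshold = sv_count_threshold(0.05, 5778)
        expected = [
            c for c in calls
            if c.effect.value != "synonymous"
            and (c.gnomad_af or 0) <= 0.01
            and c.qual >= 235.6
            and c.cohort_count < threshold
        ]
        assert ledger.kept == expected
        # removal order is fixed: a synonymous+common call is ledgered as synonymous
        assert ledger.n_input == len(calls)

    @given(rows=st.lists(
        st.tuples(st.sampled_from(["missense", "synonymous"]),
                  st.floats(0, 0.5), st.integers(0, 600), st.floats(0, 600)),
        max_size=60))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_ledger_conservation_property(self, rows, panel):
        calls = [_call(i, effect=e, gnomad=g, cohort=c, qual=q)
                 for i, (e, g, c, q) in enumerate(rows)]
        ledger = filter_small_variants(calls, panel, FilterParams(qual_cutoff=235.6))
        assert len(ledger.kept) + ledger.n_removed == len(calls)
        assert set(ledger.reasons) == {f"{c.patient_id}|{c.variant_id}" for c in calls}


class TestSVFilters:
    @pytest.mark.parametrize("frac,n,expected", [
        (0.05, 5778, 289),
        (0.05, 100, 5),
        (0.05, 101, 6),
        (0.5, 10, 5),
    ])
    def test_threshold_values(self, frac, n, expected):
        assert sv_count_threshold(frac, n) == expected

    def test_threshold_monotone_in_cohort_size(self):
        values = [sv_count_threshold(0.05, n) for n in range(1, 2000)]
        assert all(b >= a for a, b in zip(values, values[1:]))
        assert all(c >= 0.05 * n - 1e-9 for n, c in enumerate(values, start=1))

    def test_sv_boundary_at_289(self):
        svs = [_call(0, kind="sv", effect="sv_loss", cohort=289),
               _call(1, kind="sv", effect="sv_loss", cohort=288)]
        ledger = filter_svs(svs)
        assert [c.variant_id for c in ledger.removed["cohort_frequency"]] == ["v0"]
        assert [c.variant_id for c in ledger.kept] == ["v1"]

    def test_sv_filter_ignores_gnomad(self):
        sv = _call(0, kind="sv", effect="sv_loss", gnomad=0.5, cohort=0)
        assert filter_svs([sv]).kept == [sv]

    def test_mixed_list_matches_brute_force(self):
        rng = np.random.default_rng(3)
        svs = [_call(i, kind="sv", effect="sv_loss", cohort=int(rng.integers(0, 600)))
               for i in range(20)]
        ledger = filter_svs(svs)
        assert ledger.kept == [s for s in svs if s.cohort_count < 289]

    def test_non_sv_input_rejected(self):
        with pytest.raises(ValueError, match="kind=sv"):
            filter_svs([_call(0, kind="snv")])


class TestIDHExclusion:
    def test_fixture_cohort_92_of_98(self, fixture):
        kept, excluded = exclude_idh_mutant(fixture.samples())
        assert (len(kept), len(excluded)) == (92, 6)

    def test_all_wildtype_identity(self):
        samples = [SamplePair(patient_id=f"p{i}", idh_status="wildtype")
                   for i in range(5)]
        kept, excluded = exclude_idh_mutant(samples)
        assert kept == samples and excluded == []

    def test_all_mutant_empty(self):
        samples = [SamplePair(patient_id=f"p{i}", idh_status="mutant")
                   for i in range(5)]
        kept, excluded = exclude_idh_mutant(samples)
        assert kept == [] and len(excluded) == 5

    def test_unknown_kept_with_warning_by_default(self):
        samples = [SamplePair(patient_id="p", idh_status="unknown")]
        with pytest.warns(UserWarning):
            kept, _ = exclude_idh_mutant(samples)
        assert len(kept) == 1
        kept, excluded = exclude_idh_mutant(samples, keep_unknown=False)
        assert kept == [] and len(excluded) == 1
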