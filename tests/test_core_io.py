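"""Domain types, TSV/VCF/BED round-trips and config validation."""

import pytest

from gbmgermline import io
from gbmgermline.config import ConfigError, config_from_dict, load_config
from gbmgermline.types import (
    GenomicInterval,
    GeneDef,
    GenePanel,
    GermlineCall,
    SomaticCall,
)


def _mk_germline(i: int, **kw) -> GermlineCall:
    base = dict(
        patient_id=f"P{i % 7}", gene="MSH6", variant_id=f"var{i}",
        kind="snv", effect="missense", genotype="het",
        chrom="chr2", pos=48010221 + i, ref="C", alt="T",
        hgvs_c=f"c.{i}C>T", hgvs_p=None,
        gnomad_af=round(0.0001 * i, 6) if i % 3 else None,
        cohort_count=i % 11, qual=100.0 + 7.5 * i,
        normal_reads=(i % 15, 30), tumor_reads=(2 * (i % 20), 95),
    )
    base.update(kw)
    return GermlineCall(**base)


class TestTypes:
    def test_interval_invariants(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -1, 10)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 10, 10)
        with pytest.raises(ValueError):
            GenomicInterval("", 0, 10)
        iv = GenomicInterval("chr1", 100, 200)
        assert iv.length == 100
        assert iv.contains("chr1", 100) and not iv.contains("chr1", 200)

    def test_read_counts_validated(self):
        with pytest.raises(ValueError):
            _mk_germline(0, normal_reads=(31, 30))
        with pytest.raises(ValueError):
            _mk_germline(0, gnomad_af=1.5)

    def test_somatic_context_only_for_snv(self):
        with pytest.raises(ValueError):
            SomaticCall(patient_id="p", variant_id="v", kind="snv", effect="missense")
        with pytest.raises(ValueError):
            SomaticCall(patient_id="p", variant_id="v", kind="indel",
                        effect="frameshift", context="ACA>AAA")

    def test_phenotype_class_restricted_to_known_genes(self):
        with pytest.raises(ValueError):
            GeneDef(symbol="CHEK2", inheritance="dominant",
                    mechanism="tumor_suppressor", phenotype_class="mmr")

    def test_panel_rejects_duplicates_and_overlaps(self):
        g = GeneDef(symbol="MSH6", inheritance="dominant", mechanism="tumor_suppressor")
        with pytest.raises(ValueError):
            GenePanel(genes=[g, g])
        with pytest.raises(ValueError):
            GenePanel(genes=[g], regions={"MSH6": [
                GenomicInterval("chr2", 0, 100), GenomicInterval("chr2", 50, 150)]})


class TestVariantTables:
    def test_tsv_round_trip_is_lossless(self, tmp_path):
        calls = [_mk_germline(i) for i in range(50)]
        path = tmp_path / "calls.tsv"
        io.write_variant_table(calls, path, "germline")
        back = io.read_variant_table(path, "germline")
        assert not back.errors
        assert list(back) == calls

    def test_somatic_tsv_round_trip(self, tmp_path):
        calls = [
            SomaticCall(patient_id="p1", variant_id=f"s{i}", kind="snv",
                        effect="missense", gene="TP53", chrom="chr17",
                        pos=7571720 + i, context="ACA>AAA",
                        at_microsatellite=False, driver_flag=bool(i % 2))
            for i in range(20)
        ] + [
            SomaticCall(patient_id="p1", variant_id="ind1", kind="indel",
                        effect="frameshift", at_microsatellite=True)
        ]
        path = tmp_path / "somatic.tsv"
        io.write_variant_table(calls, path, "somatic")
        back = io.read_variant_table(path, "somatic")
        assert not back.errors
        assert list(back) == calls

    def test_missing_required_column_names_it(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("patient_id\tgene\tvariant_id\n" "p\tMSH6\tv1\n")
        with pytest.raises(io.SchemaError, match="kind"):
            io.read_variant_table(path, "germline")

    def test_malformed_rows_collected_not_dropped(self, tmp_path):
        calls = [_mk_germline(i) for i in range(3)]
        path = tmp_path / "calls.tsv"
        io.write_variant_table(calls, path, "germline")
        text = path.read_text().splitlines()
        text[2] = text[2].replace("\t30\t", "\tthirty\t")  # corrupt read total
        path.write_text("\n".join(text) + "\n")
        result = io.read_variant_table(path, "germline")
        assert len(result) == 2
        assert len(result.errors) == 1 and result.errors[0].row == 3
        with pytest.raises(io.SchemaError):
            result.raise_on_errors()

    def test_vcf_round_trip_and_ad_convention(self, tmp_path):
        calls = [_mk_germline(i, patient_id="NORMAL", normal_reads=(15, 25))
                 for i in range(5)]
        path = tmp_path / "calls.vcf"
        io.write_vcf(calls, path)
        back = io.read_variant_table(path, "germline")
        assert not back.errors
        assert len(back) == 5
        # AD "10,15" (ref,alt) must parse to (alt=15, total=25)
        assert all(c.normal_reads == (15, 25) for c in back)
        got = {c.variant_id: c for c in back}
        for c in calls:
            b = got[c.variant_id]
            assert (b.chrom, b.pos, b.gene, b.effect, b.qual) == \
                (c.chrom, c.pos, c.gene, c.effect, c.qual)


class TestBed:
    def test_single_region_line_format(self, tmp_path, panel):
        sub = GenePanel(
            genes=[GeneDef(symbol="GENE", inheritance="dominant",
                           mechanism="tumor_suppressor")],
            regions={"GENE": [GenomicInterval("chrom1", 100, 200)]},
        )
        path = tmp_path / "p.bed"
        io.write_panel_bed(sub, path)
        assert path.read_text() == "chrom1\t100\t200\tGENE\n"

    def test_empty_panel_empty_file(self, tmp_path):
        path = tmp_path / "empty.bed"
        io.write_panel_bed(GenePanel(genes=[], regions={}), path)
        assert path.read_text() == ""

    def test_panel_round_trip_sorted(self, tmp_path, panel):
        path = tmp_path / "panel.bed"
        io.write_panel_bed(panel, path)
        lines = path.read_text().splitlines()
        n_regions = sum(len(v) for v in panel.regions.values())
        assert len(lines) == n_regions
        keys = [(l.split("\t")[0], int(l.split("\t")[1])) for l in lines]
        assert keys == sorted(keys)
        back = io.read_panel_bed(path)
        assert back == panel.regions


class TestConfig:
    def test_empty_config_gives_defaults(self, tmp_path):
        path = tmp_path / "empty.yaml"
        path.write_text("")
        config = load_config(path)
        assert config.filters.gnomad_max == 0.01
        assert config.filters.cohort_max_fraction == 0.05
        assert config.filters.reference_cohort_n == 5778
        assert config.filters.qual_fallback == 235.6
        assert config.msi.elevated_min == 1.3 and config.msi.diagnostic_min == 4.0

    def test_override_echoed(self, tmp_path):
        path = tmp_path / "c.yaml"
        path.write_text("msi:\n  diagnostic_min: 4\nfilters:\n  gnomad_max: 0.005\n")
        config = load_config(path)
        assert config.msi.diagnostic_min == 4
        assert config.filters.gnomad_max == 0.005

    @pytest.mark.parametrize("data", [
        {"filters": {"gnomad_max": 1.5}},
        {"filters": {"nonsense_key": 1}},
        {"unknown_section": {}},
        {"msi": {"elevated_min": 5, "diagnostic_min": 4}},
    ])
    def test_invalid_configs_rejected(self, data):
        with pytest.raises(ConfigError):
            config_from_dict(data)
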