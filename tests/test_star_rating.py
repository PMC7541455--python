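"""Threshold evaluation, star arithmetic, report and VCF round trips."""

import dataclasses
import math

import pytest

from wgsqc import (
    CallableResult,
    EvennessMetrics,
    PairIntegrityMetrics,
    QCThresholds,
    SampleMetrics,
    annotate_vcf_header,
    award_stars,
    evaluate_measures,
    load_thresholds,
    parse_report,
    strip_vcf_annotation,
    write_report,
)


def sample(mean=40.0, mom=1.0, fwhm=0.1, inter=0.5, r1=1000, r2=1000):
    return SampleMetrics(
        mean_coverage=mean,
        evenness=EvennessMetrics(mom_10kb=mom, mom_5mb=mom, fwhm=fwhm),
        pair_integrity=PairIntegrityMetrics(interchrom_pct=inter,
                                            r1_edits=r1, r2_edits=r2),
    )


def joint(fraction=1.0, total=1_000_000):
    return CallableResult(callable_bases=int(fraction * total),
                          total_known_bases=total)


def outcomes_for(normal, tumour, callable_result=None, thresholds=None):
    return evaluate_measures(normal, tumour, callable_result or joint(),
                             thresholds or QCThresholds())


class TestEvaluateMeasures:
    def test_all_clean_pair_passes_everything(self):
        for o in outcomes_for(sample(), sample()):
            assert o.normal_pass and o.tumour_pass

    def test_fwhm_trips_evenness_despite_good_mom(self):
        o = outcomes_for(sample(mom=1.00, fwhm=0.25), sample())[1]
        assert o.measure == "evenness" and not o.normal_pass and o.tumour_pass

    def test_callable_is_joint(self):
        o = outcomes_for(sample(), sample(), joint(0.5))[2]
        assert o.measure == "callable"
        assert not o.normal_pass and not o.tumour_pass and o.stars == 0.0

    def test_infinite_edit_ratio_fails(self):
        o = outcomes_for(sample(r1=0, r2=10), sample())[4]
        assert math.isinf(sample(r1=0, r2=10).pair_integrity.edit_ratio)
        assert not o.normal_pass

    def test_absolute_callable_threshold(self):
        t = QCThresholds(callable_threshold_bases=900_000,
                         callable_threshold_fraction=None)
        o = outcomes_for(sample(), sample(), joint(0.89), t)[2]
        assert not o.normal_pass
        o = outcomes_for(sample(), sample(), joint(0.91), t)[2]
        assert o.normal_pass


class TestAwardStars:
    def test_all_pass_is_five_stars(self):
        report = award_stars(outcomes_for(sample(), sample()))
        assert report.total_stars == 5.0

    def test_half_stars_for_normal_only(self):
        # normal passes the four paired measures, callable fails
        report = award_stars(outcomes_for(
            sample(), sample(mean=10.0, mom=0.5, fwhm=0.9, inter=50.0, r1=3000),
            joint(0.5)))
        assert report.total_stars == 2.0

    def test_tumour_only_passing_earns_nothing_on_paired_measures(self):
        report = award_stars(outcomes_for(
            sample(mean=10.0, mom=0.5, fwhm=0.9, inter=50.0, r1=3000),
            sample(), joint(1.0)))
        assert report.total_stars == 1.0  # only the joint callable star

    def test_duplicate_measures_rejected(self):
        outs = outcomes_for(sample(), sample())
        outs[1] = dataclasses.replace(outs[0])
        with pytest.raises(ValueError, match="one outcome per measure"):
            award_stars(outs)

    def test_monotone_in_single_metric(self):
        worse = award_stars(outcomes_for(sample(mean=20.0), sample())).total_stars
        better = award_stars(outcomes_for(sample(mean=26.0), sample())).total_stars
        assert better >= worse


class TestThresholdConfig:
    def test_yaml_overrides_and_roundtrip(self, tmp_path):
        cfg = tmp_path / "t.yaml"
        cfg.write_text("min_mean_cov_normal: 20\nmax_fwhm_tumour: 0.5\n"
                       "mom_range_normal: [0.95, 1.10]\n")
        t = load_thresholds(cfg)
        assert t.min_mean_cov_normal == 20
        assert t.max_fwhm_tumour == 0.5
        assert t.mom_range_normal == (0.95, 1.10)
        assert t.max_interchrom_pct == 3.0  # untouched default

    def test_bases_key_clears_default_fraction(self, tmp_path):
        cfg = tmp_path / "t.yaml"
        cfg.write_text("callable_threshold_bases: 2600000000\n")
        t = load_thresholds(cfg)
        assert t.callable_threshold_bases == 2_600_000_000
        assert t.callable_threshold_fraction is None

    def test_mutually_exclusive_callable_keys(self):
        with pytest.raises(ValueError, match="mutually exclusive"):
            QCThresholds(callable_threshold_bases=1,
                         callable_threshold_fraction=0.5)

    def test_unknown_key_rejected(self, tmp_path):
        cfg = tmp_path / "t.yaml"
        cfg.write_text("min_mean_cov: 20\n")
        with pytest.raises(ValueError, match="unknown"):
            load_thresholds(cfg)


class TestReportSerialization:
    def test_roundtrip(self, tmp_path):
        report = award_stars(outcomes_for(sample(), sample(fwhm=0.4), joint(0.95)))
        path = tmp_path / "report.tsv"
        write_report(report, path)
        back = parse_report(path)
        assert back.total_stars == report.total_stars
        assert back.thresholds == report.thresholds
        for a, b in zip(back.outcomes, report.outcomes):
            assert a.measure == b.measure and a.stars == b.stars
            assert a.normal_value == pytest.approx(b.normal_value)

    def test_five_star_total_formats_as_5_point_0(self, tmp_path):
        report = award_stars(outcomes_for(sample(), sample()))
        path = tmp_path / "report.tsv"
        write_report(report, path)
        lines = path.read_text().splitlines()
        header = lines[-2].split("\t")
        values = lines[-1].split("\t")
        assert values[header.index("total_stars")] == "5.0"


VCF = ("##fileformat=VCFv4.2\n"
       "##contig=<ID=1,length=1000>\n"
       "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
       "1\t100\t.\tA\tT\t50\tPASS\t.\n")


class TestVcfAnnotation:
    def test_annotate_then_strip_is_identity(self, tmp_path):
        src = tmp_path / "in.vcf"
        src.write_text(VCF)
        report = award_stars(outcomes_for(sample(), sample()))
        annotated = tmp_path / "ann.vcf"
        restored = tmp_path / "back.vcf"
        annotate_vcf_header(src, report, annotated)
        text = annotated.read_text()
        assert "wgsqc_star_rating" in text
        assert text.index("wgsqc_star_rating") < text.index("#CHROM")
        strip_vcf_annotation(annotated, restored)
        assert restored.read_bytes() == src.read_bytes()

    def test_malformed_vcf_rejected(self, tmp_path):
        src = tmp_path / "bad.vcf"
        src.write_text("##fileformat=VCFv4.2\n1\t100\t.\tA\tT\t50\tPASS\t.\n")
        report = award_stars(outcomes_for(sample(), sample()))
        with pytest.raises(ValueError, match="#CHROM"):
            annotate_vcf_header(src, report, tmp_path / "out.vcf")
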