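"""Somatic-variant rejection ledger: boundaries, presets, monotonicity."""

import dataclasses

import numpy as np
import pytest

from mutread.spectrum import Snv
from mutread.variant_filter import (
    PRESETS,
    FilterProfile,
    VariantMetrics,
    apply_filters,
    filter_records,
    filter_vcf,
    get_profile,
)

CLEAN = dict(
    VariantAlleleCount=25,
    VariantAlleleCountControl=0,
    ReadCountControl=30,
    VariantAlleleFrequency=0.30,
    VariantMapQualMedian=60.0,
    MapQualDiffMedian=0.0,
    LowMapQual=0.0,
    VariantBaseQualMedian=37.0,
    VariantStrandBias=0.5,
    ReferenceStrandBias=0.5,
)


def metrics(**overrides):
    return VariantMetrics(**{**CLEAN, **overrides})


def test_clean_record_passes_every_preset():
    for preset in PRESETS.values():
        passed, fired = apply_filters(metrics(), preset)
        assert passed and fired == []


class TestFixedRuleBoundaries:
    """Each printed inequality at its boundary and one unit beyond."""

    @pytest.mark.parametrize("preset", sorted(PRESETS))
    @pytest.mark.parametrize(
        "overrides,rule,fires",
        [
            # VariantAlleleCountControl > 1 : strict
            (dict(VariantAlleleCountControl=1), "VariantAlleleCountControl", False),
            (dict(VariantAlleleCountControl=2), "VariantAlleleCountControl", True),
            # VariantMapQualMedian < 40.0 : strict
            (dict(VariantMapQualMedian=40.0), "VariantMapQualMedian", False),
            (dict(VariantMapQualMedian=39.9), "VariantMapQualMedian", True),
            # MapQualDiffMedian < -5.0 or > 5.0 : strict both sides
            (dict(MapQualDiffMedian=-5.0), "MapQualDiffMedian", False),
            (dict(MapQualDiffMedian=5.0), "MapQualDiffMedian", False),
            (dict(MapQualDiffMedian=-5.1), "MapQualDiffMedian", True),
            (dict(MapQualDiffMedian=5.1), "MapQualDiffMedian", True),
            # LowMapQual > 0.05 : strict
            (dict(LowMapQual=0.05), "LowMapQual", False),
            (dict(LowMapQual=0.06), "LowMapQual", True),
            # VariantBaseQualMedian < 30.0 : strict
            (dict(VariantBaseQualMedian=30.0), "VariantBaseQualMedian", False),
            (dict(VariantBaseQualMedian=29.9), "VariantBaseQualMedian", True),
            # strand-bias compound: VariantAlleleCount >= 7 && VSB < 0.05 && RSB >= 0.2
            (
                dict(VariantAlleleCount=7, VariantStrandBias=0.04, ReferenceStrandBias=0.2),
                "StrandBias",
                True,
            ),
            (
                dict(VariantAlleleCount=6, VariantStrandBias=0.04, ReferenceStrandBias=0.2),
                "StrandBias",
                False,
            ),
            (
                dict(VariantAlleleCount=7, VariantStrandBias=0.05, ReferenceStrandBias=0.2),
                "StrandBias",
                False,
            ),
            (
                dict(VariantAlleleCount=7, VariantStrandBias=0.04, ReferenceStrandBias=0.19),
                "StrandBias",
                False,
            ),
        ],
    )
    def test_rule_boundary(self, preset, overrides, rule, fires):
        record = metrics(**overrides)
        passed, fired = apply_filters(record, preset)
        if fires:
            assert rule in fired and not passed
        else:
            assert rule not in fired


class TestProfileThresholdBoundaries:
    @pytest.mark.parametrize(
        "preset,min_reads,min_vaf",
        [
            ("mutread_ff", 5, 0.03),
            ("wes", 7, 0.01),
            ("swgs10x", 5, 0.11),
            ("mutread_ffpe", 10, 0.13),
            ("strelka_ff", 20, 0.11),
            ("strelka_ffpe", 11, 0.03),
        ],
    )
    def test_preset_thresholds_at_boundary(self, preset, min_reads, min_vaf):
        profile = PRESETS[preset]
        assert (profile.min_variant_reads, profile.min_vaf) == (min_reads, min_vaf)
        at = metrics(VariantAlleleCount=min_reads, VariantAlleleFrequency=min_vaf)
        below = metrics(
            VariantAlleleCount=min_reads - 1, VariantAlleleFrequency=min_vaf - 0.001
        )
        passed_at, fired_at = apply_filters(at, profile)
        _, fired_below = apply_filters(below, profile)
        assert "MinVariantReads" not in fired_at and "MinVAF" not in fired_at
        assert "MinVariantReads" in fired_below and "MinVAF" in fired_below

    @pytest.mark.parametrize("depth_threshold", [20, 10])
    def test_control_depth_boundary(self, depth_threshold):
        profile = FilterProfile(5, 0.03, min_control_depth=depth_threshold)
        at = metrics(ReadCountControl=depth_threshold)
        below = metrics(ReadCountControl=depth_threshold - 1)
        assert apply_filters(at, profile)[0]
        assert "ReadCountControl" in apply_filters(below, profile)[1]

    def test_unknown_preset_rejected(self):
        with pytest.raises(KeyError):
            get_profile("nonexistent")


def test_missing_metric_is_conservative_fail():
    record = VariantMetrics(VariantAlleleCount=10)
    passed, fired = apply_filters(record, "mutread_ff")
    assert not passed
    assert "missing_metric" in fired


def test_invalid_metric_values_rejected():
    with pytest.raises(ValueError):
        VariantMetrics(VariantAlleleCount=-1)
    with pytest.raises(ValueError):
        VariantMetrics(LowMapQual=1.2)


def _random_cohort(n, seed):
    rng = np.random.default_rng(seed)
    cohort = []
    for i in range(n):
        record = metrics(
            VariantAlleleCount=int(rng.integers(0, 40)),
            VariantAlleleFrequency=float(rng.random()),
            ReadCountControl=int(rng.integers(0, 60)),
            VariantAlleleCountControl=int(rng.integers(0, 4)),
            VariantMapQualMedian=float(rng.uniform(20, 60)),
            MapQualDiffMedian=float(rng.uniform(-10, 10)),
            LowMapQual=float(rng.random() * 0.2),
            VariantBaseQualMedian=float(rng.uniform(20, 40)),
            VariantStrandBias=float(rng.random() * 0.2),
            ReferenceStrandBias=float(rng.random()),
        )
        cohort.append((Snv("chr1", i + 1, "C", "T"), record))
    return cohort


def test_monotonic_under_threshold_tightening():
    """Tightening any per-cohort threshold never lets more records pass."""
    cohort = _random_cohort(1000, seed=8)
    base = FilterProfile(5, 0.03, 20)
    n_base = len(filter_records(cohort, base)[0])
    for tightened in (
        FilterProfile(6, 0.03, 20),
        FilterProfile(5, 0.05, 20),
        FilterProfile(5, 0.03, 25),
        FilterProfile(10, 0.13, 30),
    ):
        assert len(filter_records(cohort, tightened)[0]) <= n_base


def test_planted_artifact_classes_removed_by_designated_rule():
    """Each planted artifact class is caught by its own rule, all of it."""
    classes = {
        "VariantAlleleCountControl": dict(VariantAlleleCountControl=5),
        "VariantMapQualMedian": dict(VariantMapQualMedian=10.0),
        "LowMapQual": dict(LowMapQual=0.5),
        "StrandBias": dict(
            VariantAlleleCount=20, VariantStrandBias=0.01, ReferenceStrandBias=0.6
        ),
    }
    for rule, overrides in classes.items():
        cohort = [(Snv("chr1", i + 1, "C", "T"), metrics(**overrides)) for i in range(50)]
        passing, counts = filter_records(cohort, "mutread_ff")
        assert passing == []
        assert counts[rule] == 50


def test_record_failing_two_rules_counted_once_in_output():
    record = metrics(VariantAlleleCountControl=3, LowMapQual=0.5)
    cohort = [(Snv("chr1", 1, "C", "T"), record)]
    passing, counts = filter_records(cohort, "mutread_ff")
    assert passing == []
    assert counts["VariantAlleleCountControl"] == 1 and counts["LowMapQual"] == 1


def test_pure_function_no_cross_record_state():
    record = metrics()
    first = apply_filters(record, "mutread_ff")
    cohort = _random_cohort(100, seed=1)
    filter_records(cohort, "mutread_ff")
    assert apply_filters(record, "mutread_ff") == first


class TestFilterVcf:
    def _write_vcf(self, path, rows):
        keys = list(CLEAN)
        lines = ["##fileformat=VCFv4.2", "##contig=<ID=chr1,length=100000>"]
        for key in keys:
            lines.append(f'##INFO=<ID={key},Number=1,Type=Float,Description="m">')
        lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
        for pos, overrides in rows:
            values = {**CLEAN, **overrides}
            info = ";".join(f"{k}={values[k]}" for k in keys)
            lines.append(f"chr1\t{pos}\t.\tC\tT\t.\t.\t{info}")
        path.write_text("\n".join(lines) + "\n")

    def test_stream_filtering_and_rule_counts(self, tmp_path):
        vcf = tmp_path / "in.vcf"
        rows = [(i + 1, {}) for i in range(7)]
        rows += [
            (100, dict(VariantAlleleCountControl=3)),
            (200, dict(LowMapQual=0.5)),
            (300, dict(VariantAlleleCountControl=3, LowMapQual=0.5)),
        ]
        self._write_vcf(vcf, rows)
        out = tmp_path / "out.vcf"
        passing, counts = filter_vcf(vcf, "mutread_ff", out=out)
        assert len(passing) == 7
        assert counts["VariantAlleleCountControl"] == 2
        assert counts["LowMapQual"] == 2
        text = out.read_text()
        assert "VariantAlleleCountControl;LowMapQual" in text
        assert text.count("PASS") >= 7

    def test_empty_vcf(self, tmp_path):
        vcf = tmp_path / "empty.vcf"
        self._write_vcf(vcf, [])
        passing, counts = filter_vcf(vcf, "mutread_ff")
        assert passing == [] and sum(counts.values()) == 0

    def test_metric_map_renames_info_keys(self, tmp_path):
        vcf = tmp_path / "in.vcf"
        lines = [
            "##fileformat=VCFv4.2",
            "##contig=<ID=chr1,length=1000>",
            '##INFO=<ID=VAC,Number=1,Type=Float,Description="m">',
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
            "chr1\t10\t.\tC\tT\t.\t.\tVAC=3",
        ]
        vcf.write_text("\n".join(lines) + "\n")
        passing, counts = filter_vcf(
            vcf, "mutread_ff", metric_map={"VariantAlleleCount": "VAC"}
        )
        # VAC=3 < min reads 5 fires; everything else is missing
        assert passing == []
        assert counts["MinVariantReads"] == 1 and counts["missing_metric"] == 1

    def test_unknown_metric_in_map_rejected(self, tmp_path):
        vcf = tmp_path / "in.vcf"
        self._write_vcf(vcf, [])
        with pytest.raises(ValueError):
            filter_vcf(vcf, "mutread_ff", metric_map={"NotAMetric": "X"})
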