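"""Post-calling somatic-variant filtering.

Somatic SNV calls arrive annotated with per-site quality metrics (from the
caller or an auxiliary table); this module applies a fixed ledger of
rejection rules plus three per-cohort thresholds (minimum supporting reads,
minimum VAF, minimum control depth).  Each rule is a REJECTION trigger:
a record is removed iff at least one rule fires, and every fired rule is
reported by name.

The fixed rejection rules (inequalities applied exactly as stated):

* ``VariantAlleleCountControl > 1``            -- germline leakage
* ``VariantMapQualMedian < 40.0``              -- poorly mapped variant reads
* ``MapQualDiffMedian < -5.0 or > 5.0``        -- mapping-quality imbalance
* ``LowMapQual > 0.05``                        -- too many low-MAPQ reads
* ``VariantBaseQualMedian < 30.0``             -- low base quality
* ``VariantAlleleCount >= 7 and VariantStrandBias < 0.05
  and ReferenceStrandBias >= 0.2``             -- strand-bias artifact

Caller-side read selection (minimum MAPQ 1, minimum base quality 10,
overlapping-mate consensus) is upstream caller configuration, not part of
this filter.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, fields
from pathlib import Path
from typing import IO, Iterable, Mapping

from .spectrum import Snv

__all__ = [
    "VariantMetrics",
    "FilterProfile",
    "PRESETS",
    "apply_filters",
    "filter_records",
    "filter_vcf",
]


@dataclass(frozen=True)
class VariantMetrics:
    """Per-call quality metrics consumed by the filter ledger."""

    VariantAlleleCount: float | None = None
    VariantAlleleCountControl: float | None = None
    ReadCountControl: float | None = None
    VariantAlleleFrequency: float | None = None
    VariantMapQualMedian: float | None = None
    MapQualDiffMedian: float | None = None
    LowMapQual: float | None = None
    VariantBaseQualMedian: float | None = None
    VariantStrandBias: float | None = None
    ReferenceStrandBias: float | None = None

    def __post_init__(self) -> None:
        for name in ("VariantAlleleCount", "VariantAlleleCountControl", "ReadCountControl"):
            value = getattr(self, name)
            if value is not None and value < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in (
            "VariantAlleleFrequency",
            "LowMapQual",
            "VariantStrandBias",
            "ReferenceStrandBias",
        ):
            value = getattr(self, name)
            if value is not None and not 0 <= value <= 1:
                raise ValueError(f"{name} must be a fraction in [0, 1]")


@dataclass(frozen=True)
class FilterProfile:
    """Per-cohort thresholds: minimum variant reads, minimum VAF, control depth."""

    min_variant_reads: int
    min_vaf: float
    min_control_depth: int = 20
    name: str = "custom"


#: Named per-cohort presets (minimum supporting reads, minimum VAF).
PRESETS: dict[str, FilterProfile] = {
    "mutread_ff": FilterProfile(5, 0.03, 20, "mutread_ff"),
    "wes": FilterProfile(7, 0.01, 20, "wes"),
    "swgs10x": FilterProfile(5, 0.11, 20, "swgs10x"),
    "mutread_ffpe": FilterProfile(10, 0.13, 20, "mutread_ffpe"),
    "strelka_ff": FilterProfile(20, 0.11, 20, "strelka_ff"),
    "strelka_ffpe": FilterProfile(11, 0.03, 20, "strelka_ffpe"),
}


def get_profile(preset: str | FilterProfile) -> FilterProfile:
    if isinstance(preset, FilterProfile):
        return preset
    try:
        return PRESETS[preset]
    except KeyError:
        raise KeyError(f"unknown filter preset {preset!r}; have {sorted(PRESETS)}") from None


_METRIC_FIELDS = tuple(f.name for f in fields(VariantMetrics))

# (rule name, required metrics, predicate returning True when the rule FIRES)
_FIXED_RULES = (
    (
        "VariantAlleleCountControl",
        ("VariantAlleleCountControl",),
        lambda m, p: m.VariantAlleleCountControl > 1,
    ),
    (
        "VariantMapQualMedian",
        ("VariantMapQualMedian",),
        lambda m, p: m.VariantMapQualMedian < 40.0,
    ),
    (
        "MapQualDiffMedian",
        ("MapQualDiffMedian",),
        lambda m, p: m.MapQualDiffMedian < -5.0 or m.MapQualDiffMedian > 5.0,
    ),
    ("LowMapQual", ("LowMapQual",), lambda m, p: m.LowMapQual > 0.05),
    (
        "VariantBaseQualMedian",
        ("VariantBaseQualMedian",),
        lambda m, p: m.VariantBaseQualMedian < 30.0,
    ),
    (
        "StrandBias",
        ("VariantAlleleCount", "VariantStrandBias", "ReferenceStrandBias"),
        lambda m, p: m.VariantAlleleCount >= 7
        and m.VariantStrandBias < 0.05
        and m.ReferenceStrandBias >= 0.2,
    ),
    (
        "ReadCountControl",
        ("ReadCountControl",),
        lambda m, p: m.ReadCountControl < p.min_control_depth,
    ),
    (
        "MinVariantReads",
        ("VariantAlleleCount",),
        lambda m, p: m.VariantAlleleCount < p.min_variant_reads,
    ),
    (
        "MinVAF",
        ("VariantAlleleFrequency",),
        lambda m, p: m.VariantAlleleFrequency < p.min_vaf,
    ),
)

RULE_NAMES = tuple(name for name, _, _ in _FIXED_RULES) + ("missing_metric",)


def apply_filters(
    metrics: VariantMetrics, profile: str | FilterProfile
) -> tuple[bool, list[str]]:
    """Evaluate the rejection ledger on one record.

    Returns ``(passed, fired_rules)``; the record passes iff no rule fires.
    A metric required by a rule but absent fires ``missing_metric``
    (conservative: un-assessable records are removed).
    """
    profile = get_profile(profile)
    fired: list[str] = []
    missing = False
    for name, required, predicate in _FIXED_RULES:
        if any(getattr(metrics, r) is None for r in required):
            missing = True
            continue
        if predicate(metrics, profile):
            fired.append(name)
    if missing:
        fired.append("missing_metric")
    return (not fired), fired


def filter_records(
    records: Iterable[tuple[Snv, VariantMetrics]], profile: str | FilterProfile
) -> tuple[list[Snv], Counter]:
    """Filter a stream of (SNV, metrics); returns passing SNVs and fired-rule counts.

    A record failing several rules is removed once but contributes to every
    fired rule's count.  Input order is preserved.
    """
    profile = get_profile(profile)
    passing: list[Snv] = []
    counts: Counter = Counter()
    for snv, metrics in records:
        passed, fired = apply_filters(metrics, profile)
        if passed:
            passing.append(snv)
        counts.update(fired)
    return passing, counts


def filter_vcf(
    path: str | Path,
    profile: str | FilterProfile,
    metric_map: Mapping[str, str] | None = None,
    out: str | Path | IO[str] | None = None,
) -> tuple[list[Snv], Counter]:
    """Filter a VCF whose INFO fields carry the quality metrics.

    ``metric_map`` maps each :class:`VariantMetrics` field to the INFO key
    holding it (identity mapping by default).  When ``out`` is given, a
    filtered VCF is written with fired rule names in the FILTER column.
    """
    from cyvcf2 import VCF

    profile = get_profile(profile)
    metric_map = dict(metric_map or {})
    for field_name in metric_map:
        if field_name not in _METRIC_FIELDS:
            raise ValueError(f"metric map names unknown metric {field_name!r}")

    vcf = VCF(str(path))
    header_lines = vcf.raw_header.rstrip("\n").split("\n")
    passing: list[Snv] = []
    counts: Counter = Counter()
    out_lines: list[str] = []
    for record in vcf:
        values = {}
        for field_name in _METRIC_FIELDS:
            key = metric_map.get(field_name, field_name)
            value = record.INFO.get(key)
            if value is not None:
                values[field_name] = float(value)
        metrics = VariantMetrics(**values)
        passed, fired = apply_filters(metrics, profile)
        counts.update(fired)
        snv = Snv(record.CHROM, record.start, record.REF, record.ALT[0])
        if passed:
            passing.append(snv)
        if out is not None:
            parts = str(record).rstrip("\n").split("\t")
            parts[6] = "PASS" if passed else ";".join(fired)
            out_lines.append("\t".join(parts))
    vcf.close()

    if out is not None:
        own = isinstance(out, (str, Path))
        handle = open(out, "w") if own else out
        try:
            for line in header_lines:
                if line.startswith("#CHROM"):
                    for rule in RULE_NAMES:
                        handle.write(
                            f'##FILTER=<ID={rule},Description="Rejection rule {rule}">\n'
                        )
                handle.write(line + "\n")
            for line in out_lines:
                handle.write(line + "\n")
        finally:
            if own:
                handle.close()
    return passing, counts
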