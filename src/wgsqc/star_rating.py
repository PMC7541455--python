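"""Thresholds, per-measure pass/fail and the 0-5 half-star rating.

For each of the five measures (mean coverage, evenness, callable
coverage, inter-chromosomal pairs, edit ratio) a normal/tumour pair
earns one star if both samples pass, half a star if only the normal
passes, and nothing otherwise; the callable measure is joint and worth
a whole star or none.  The extra weight on the normal sample reflects
that there is no biological excuse for a failing normal, and a clean
normal is what somatic calling leans on.

Boundary semantics follow the measure definitions: minima and MoM
ranges are inclusive, FWHM and the inter-chromosomal percentage pass at
their thresholds, and an edit ratio of exactly 2.0 (two-fold or
greater) fails.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Optional

import yaml

from . import __version__
from .callable_coverage import (
    DEFAULT_THRESHOLD_FRACTION,
    CallableResult,
)
from .gc_evenness import EvennessMetrics
from .pair_integrity import PairIntegrityMetrics

__all__ = [
    "QCThresholds",
    "SampleMetrics",
    "MeasureOutcome",
    "StarReport",
    "load_thresholds",
    "evaluate_measures",
    "award_stars",
    "write_report",
    "parse_report",
    "annotate_vcf_header",
    "strip_vcf_annotation",
]

MEASURE_IDS = ("mean_coverage", "evenness", "callable", "interchrom", "edit_ratio")


@dataclass(frozen=True)
class QCThresholds:
    """All pass/fail cut-offs, with whole-genome cancer-pair defaults."""

    min_mean_cov_normal: float = 25.0
    min_mean_cov_tumour: float = 30.0
    mom_range_normal: tuple = (0.99, 1.06)
    mom_range_tumour: tuple = (0.92, 1.09)
    max_fwhm_normal: float = 0.20
    max_fwhm_tumour: float = 0.34
    max_interchrom_pct: float = 3.0
    max_edit_ratio: float = 2.0  # fail at >= this value
    callable_threshold_bases: Optional[int] = None
    callable_threshold_fraction: Optional[float] = DEFAULT_THRESHOLD_FRACTION

    def __post_init__(self):
        if self.callable_threshold_bases is not None \
                and self.callable_threshold_fraction is not None:
            raise ValueError(
                "callable_threshold_bases and callable_threshold_fraction "
                "are mutually exclusive"
            )
        if self.callable_threshold_bases is None \
                and self.callable_threshold_fraction is None:
            raise ValueError("one callable threshold must be set")
        for lo, hi in (self.mom_range_normal, self.mom_range_tumour):
            if not lo < hi:
                raise ValueError("MoM range must be well-ordered")

    def callable_threshold(self, total_known_bases: int) -> float:
        if self.callable_threshold_bases is not None:
            return float(self.callable_threshold_bases)
        return self.callable_threshold_fraction * total_known_bases


_TUPLE_KEYS = {"mom_range_normal", "mom_range_tumour"}


def load_thresholds(path) -> QCThresholds:
    """Read thresholds from a flat YAML key/value file.

    Keys mirror the QCThresholds fields; missing keys keep their
    defaults.  Setting ``callable_threshold_bases`` clears the default
    fraction (they are mutually exclusive).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(QCThresholds)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown threshold keys: {sorted(unknown)}")
    if "callable_threshold_bases" in raw and "callable_threshold_fraction" not in raw:
        raw["callable_threshold_fraction"] = None
    for key in _TUPLE_KEYS & set(raw):
        raw[key] = tuple(raw[key])
    return QCThresholds(**raw)


@dataclass
class SampleMetrics:
    """All per-sample QC values for one BAM."""

    mean_coverage: float
    evenness: EvennessMetrics
    pair_integrity: PairIntegrityMetrics


@dataclass
class MeasureOutcome:
    measure: str
    normal_value: dict
    tumour_value: dict
    normal_pass: bool
    tumour_pass: bool

    @property
    def stars(self) -> float:
        if self.measure == "callable":
            return 1.0 if (self.normal_pass and self.tumour_pass) else 0.0
        if self.normal_pass and self.tumour_pass:
            return 1.0
        if self.normal_pass:
            return 0.5
        return 0.0


@dataclass
class StarReport:
    outcomes: list
    thresholds: QCThresholds
    normal_id: str = "normal"
    tumour_id: str = "tumour"
    tool_version: str = __version__

    @property
    def total_stars(self) -> float:
        return sum(o.stars for o in self.outcomes)

    def outcome(self, measure: str) -> MeasureOutcome:
        for o in self.outcomes:
            if o.measure == measure:
                return o
        raise KeyError(measure)


def evaluate_measures(normal: SampleMetrics, tumour: SampleMetrics,
                      joint_callable: CallableResult,
                      thresholds: QCThresholds = QCThresholds()) -> list:
    """Apply the thresholds to both samples' metrics.

    Returns one MeasureOutcome per measure, in canonical order.  The
    callable measure is a joint pass/fail recorded identically on both
    sides.
    """
    t = thresholds
    outcomes = []

    outcomes.append(MeasureOutcome(
        measure="mean_coverage",
        normal_value={"mean_coverage": normal.mean_coverage},
        tumour_value={"mean_coverage": tumour.mean_coverage},
        normal_pass=normal.mean_coverage >= t.min_mean_cov_normal,
        tumour_pass=tumour.mean_coverage >= t.min_mean_cov_tumour,
    ))

    def _evenness_pass(ev: EvennessMetrics, mom_range, max_fwhm):
        lo, hi = mom_range
        return (lo <= ev.mom_10kb <= hi) and (ev.fwhm <= max_fwhm)

    outcomes.append(MeasureOutcome(
        measure="evenness",
        normal_value={"mom_10kb": normal.evenness.mom_10kb,
                      "mom_5mb": normal.evenness.mom_5mb,
                      "fwhm": normal.evenness.fwhm},
        tumour_value={"mom_10kb": tumour.evenness.mom_10kb,
                      "mom_5mb": tumour.evenness.mom_5mb,
                      "fwhm": tumour.evenness.fwhm},
        normal_pass=_evenness_pass(normal.evenness, t.mom_range_normal, t.max_fwhm_normal),
        tumour_pass=_evenness_pass(tumour.evenness, t.mom_range_tumour, t.max_fwhm_tumour),
    ))

    callable_ok = joint_callable.callable_bases >= \
        t.callable_threshold(joint_callable.total_known_bases)
    outcomes.append(MeasureOutcome(
        measure="callable",
        normal_value={"callable_bases": joint_callable.callable_bases,
                      "callable_fraction": joint_callable.callable_fraction},
        tumour_value={"callable_bases": joint_callable.callable_bases,
                      "callable_fraction": joint_callable.callable_fraction},
        normal_pass=callable_ok,
        tumour_pass=callable_ok,
    ))

    outcomes.append(MeasureOutcome(
        measure="interchrom",
        normal_value={"interchrom_pct": normal.pair_integrity.interchrom_pct},
        tumour_value={"interchrom_pct": tumour.pair_integrity.interchrom_pct},
        normal_pass=normal.pair_integrity.interchrom_pct <= t.max_interchrom_pct,
        tumour_pass=tumour.pair_integrity.interchrom_pct <= t.max_interchrom_pct,
    ))

    outcomes.append(MeasureOutcome(
        measure="edit_ratio",
        normal_value={"edit_ratio": normal.pair_integrity.edit_ratio,
                      "r1_edits": normal.pair_integrity.r1_edits,
                      "r2_edits": normal.pair_integrity.r2_edits},
        tumour_value={"edit_ratio": tumour.pair_integrity.edit_ratio,
                      "r1_edits": tumour.pair_integrity.r1_edits,
                      "r2_edits": tumour.pair_integrity.r2_edits},
        normal_pass=normal.pair_integrity.edit_ratio < t.max_edit_ratio,
        tumour_pass=tumour.pair_integrity.edit_ratio < t.max_edit_ratio,
    ))
    return outcomes


def award_stars(outcomes: list, thresholds: QCThresholds = QCThresholds(),
                normal_id: str = "normal", tumour_id: str = "tumour") -> StarReport:
    """Sum the per-measure stars into a report; 0-5 in half-star steps."""
    ids = [o.measure for o in outcomes]
    if sorted(ids) != sorted(MEASURE_IDS):
        raise ValueError(f"expected exactly one outcome per measure, got {ids}")
    ordered = sorted(outcomes, key=lambda o: MEASURE_IDS.index(o.measure))
    return StarReport(outcomes=ordered, thresholds=thresholds,
                      normal_id=normal_id, tumour_id=tumour_id)


# --- report serialization -------------------------------------------------

_REPORT_COLUMNS = ["normal_id", "tumour_id", "total_stars"]


def _fmt(v) -> str:
    if isinstance(v, float):
        return repr(v)
    return str(v)


def write_report(report: StarReport, path) -> None:
    """Write a one-row TSV with every raw value, pass flag and star count.

    Provenance (tool version, thresholds) goes into ``#``-prefixed header
    lines; intervals are 0-based half-open.
    """
    cols, vals = list(_REPORT_COLUMNS), [
        report.normal_id, report.tumour_id, _fmt(report.total_stars)]
    for o in report.outcomes:
        for side, values in (("normal", o.normal_value), ("tumour", o.tumour_value)):
            for key, v in values.items():
                cols.append(f"{o.measure}.{side}.{key}")
                vals.append(_fmt(v))
        cols += [f"{o.measure}.normal_pass", f"{o.measure}.tumour_pass",
                 f"{o.measure}.stars"]
        vals += [str(o.normal_pass), str(o.tumour_pass), _fmt(o.stars)]
    with open(path, "w") as fh:
        fh.write(f"# wgsqc version {report.tool_version}\n")
        fh.write("# coordinates: 0-based, half-open\n")
        fh.write("# thresholds: "
                 + yaml.safe_dump(_thresholds_dict(report.thresholds),
                                  default_flow_style=True,
                                  width=1_000_000).strip() + "\n")
        fh.write("\t".join(cols) + "\n")
        fh.write("\t".join(vals) + "\n")


def _thresholds_dict(t: QCThresholds) -> dict:
    d = dataclasses.asdict(t)
    d["mom_range_normal"] = list(d["mom_range_normal"])
    d["mom_range_tumour"] = list(d["mom_range_tumour"])
    return d


def parse_report(path) -> StarReport:
    """Read back a TSV written by write_report."""
    header_lines, cols, vals = [], None, None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                header_lines.append(line)
            elif cols is None:
                cols = line.split("\t")
            else:
                vals = line.split("\t")
    if cols is None or vals is None:
        raise ValueError(f"{path}: not a QC report")
    version = header_lines[0].split("version")[-1].strip()
    tdict = yaml.safe_load(header_lines[2].split("thresholds:", 1)[1])
    for key in _TUPLE_KEYS:
        tdict[key] = tuple(tdict[key])
    thresholds = QCThresholds(**tdict)
    row = dict(zip(cols, vals))
    outcomes = []
    for m in MEASURE_IDS:
        nvals, tvals = {}, {}
        for col, v in row.items():
            if col.startswith(f"{m}.normal.") :
                nvals[col.split(".", 2)[2]] = _parse_number(v)
            elif col.startswith(f"{m}.tumour."):
                tvals[col.split(".", 2)[2]] = _parse_number(v)
        outcomes.append(MeasureOutcome(
            measure=m, normal_value=nvals, tumour_value=tvals,
            normal_pass=row[f"{m}.normal_pass"] == "True",
            tumour_pass=row[f"{m}.tumour_pass"] == "True",
        ))
    return StarReport(outcomes=outcomes, thresholds=thresholds,
                      normal_id=row["normal_id"], tumour_id=row["tumour_id"],
                      tool_version=version)


def _parse_number(s: str):
    try:
        i = int(s)
        return i
    except ValueError:
        pass
    if s == "inf":
        return math.inf
    return float(s)


# --- VCF annotation -------------------------------------------------------

_VCF_KEY = "##wgsqc_star_rating="


def annotate_vcf_header(vcf_in, report: StarReport, vcf_out) -> None:
    """Insert one QC header line before #CHROM; bytes otherwise unchanged."""
    per_measure = ",".join(f"{o.measure}={_fmt(o.stars)}" for o in report.outcomes)
    line = f"{_VCF_KEY}total={_fmt(report.total_stars)},{per_measure}\n"
    wrote = False
    with open(vcf_in, "rb") as src, open(vcf_out, "wb") as dst:
        for raw in src:
            if not wrote and raw.startswith(b"#CHROM"):
                dst.write(line.encode("ascii"))
                wrote = True
            dst.write(raw)
    if not wrote:
        raise ValueError(f"{vcf_in}: malformed VCF, no #CHROM line")


def strip_vcf_annotation(vcf_in, vcf_out) -> None:
    """Remove the QC header line, restoring the pre-annotation bytes."""
    with open(vcf_in, "rb") as src, open(vcf_out, "wb") as dst:
        for raw in src:
            if raw.startswith(_VCF_KEY.encode("ascii")):
                continue
            dst.write(raw)
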