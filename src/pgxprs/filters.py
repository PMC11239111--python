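"""Variant prioritisation cascade and panel coverage QC.

Two independent prioritisation tracks are applied to annotated variants:

* filter a (``filter_evidence``): clinically validated variants with a
  PharmGKB-style evidence tier in {1, 2, 3};
* filter b (``filter_rare_damaging``): rare or novel variants (MAF < 2%,
  missing reference MAF counts as novel) that are putatively deleterious —
  loss-of-function (nonsense/frameshift), splice-altering (ensemble ADA
  score >= 0.6), or missense with at least 3 of 6 in-silico predictors
  calling damaging.

The union of both tracks then passes per-call quality control
(``filter_call_quality``: depth >= 8 and, for heterozygotes, alternate-allele
read fraction >= 0.25).  ``coverage_qc`` summarises the fraction of target
bases reaching depth thresholds of 10/20/50/100/200/500x.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import TargetRegion, VariantRecord

__all__ = [
    "FilterReport",
    "COVERAGE_THRESHOLDS",
    "MAF_RARE_THRESHOLD",
    "ADA_CUTOFF",
    "PREDICTOR_VOTES_REQUIRED",
    "MIN_CALL_DEPTH",
    "MIN_HET_ALLELE_BALANCE",
    "filter_evidence",
    "filter_rare_damaging",
    "filter_call_quality",
    "apply_cascade",
    "coverage_qc",
    "drop_monomorphic",
]

COVERAGE_THRESHOLDS = (10, 20, 50, 100, 200, 500)
MAF_RARE_THRESHOLD = 0.02
ADA_CUTOFF = 0.6
PREDICTOR_VOTES_REQUIRED = 3
MIN_CALL_DEPTH = 8
MIN_HET_ALLELE_BALANCE = 0.25


@dataclass
class FilterReport:
    """Cascade bookkeeping: per-variant outcomes, stage survivor counts and
    the coverage summary."""

    outcomes: pd.DataFrame = field(default_factory=pd.DataFrame)  # variant x rule, bool
    stage_counts: dict[str, int] = field(default_factory=dict)
    coverage_summary: pd.DataFrame = field(default_factory=pd.DataFrame)
    dropped_monomorphic: list[str] = field(default_factory=list)


def filter_evidence(records: list[VariantRecord]) -> list[VariantRecord]:
    """Filter a: keep clinically validated variants (evidence tier 1-3).

    A missing tier fails; provenance is stamped on every record.
    """
    kept = []
    for rec in records:
        ok = rec.evidence_tier in (1, 2, 3)
        rec.filter_provenance.append(("evidence_tier", "pass" if ok else "fail"))
        if ok:
            kept.append(rec)
    return kept


def _is_damaging(rec: VariantRecord) -> bool:
    if rec.consequence in ("nonsense", "frameshift"):
        return True
    if rec.consequence == "splicing":
        return rec.ada_score is not None and rec.ada_score >= ADA_CUTOFF
    if rec.consequence == "missense":
        # a missing predictor call is not a damaging vote
        votes = sum(1 for p in rec.predictor_calls if p == "damaging")
        return votes >= PREDICTOR_VOTES_REQUIRED
    return False


def filter_rare_damaging(records: list[VariantRecord]) -> list[VariantRecord]:
    """Filter b: rare/novel (MAF < 2%, missing MAF = novel) AND putatively
    deleterious (LoF, splice ADA >= 0.6, or missense with >= 3/6 damaging
    predictor votes)."""
    kept = []
    for rec in records:
        rare = rec.maf is None or rec.maf < MAF_RARE_THRESHOLD
        ok = rare and _is_damaging(rec)
        rec.filter_provenance.append(("rare_damaging", "pass" if ok else "fail"))
        if ok:
            kept.append(rec)
    return kept


def call_passes_quality(gt: str, dp: int | None, ad: tuple[int, int] | None) -> tuple[bool, str]:
    """Quality rule for a single sample call.

    Depth must reach 8x; heterozygous calls additionally need an
    alternate-allele read fraction of at least 0.25 (the balance rule applies
    to heterozygotes only).  Returns (passes, reason).
    """
    if gt == "./.":
        return False, "missing_genotype"
    if dp is None or dp < MIN_CALL_DEPTH:
        return False, "low_depth"
    if gt in ("0/1", "1/0"):
        if ad is None:
            return False, "no_AD"
        total = ad[0] + ad[1]
        if total == 0 or ad[1] / total < MIN_HET_ALLELE_BALANCE:
            return False, "allele_balance"
    return True, "ok"


def filter_call_quality(records: list[VariantRecord]) -> list[VariantRecord]:
    """Apply the per-call quality rule; failing calls become missing (./.)
    and a record is dropped only if no call survives."""
    kept = []
    for rec in records:
        new_calls = []
        n_pass = 0
        for gt, dp, ad in rec.calls:
            ok, _reason = call_passes_quality(gt, dp, ad)
            if ok:
                n_pass += 1
                new_calls.append((gt, dp, ad))
            else:
                new_calls.append(("./.", dp, ad))
        rec.calls = new_calls
        ok_rec = n_pass > 0
        rec.filter_provenance.append(("call_quality", "pass" if ok_rec else "fail"))
        if ok_rec:
            kept.append(rec)
    return kept


def apply_cascade(records: list[VariantRecord]) -> tuple[list[VariantRecord], FilterReport]:
    """Run filter a and filter b as independent tracks, take their union,
    then apply call-level quality control.

    Survivor counts per stage are monotone non-increasing from the union
    onward; the two prioritisation tracks themselves are reported separately.
    """
    report = FilterReport()
    report.stage_counts["input"] = len(records)

    a = filter_evidence(list(records))
    report.stage_counts["filter_a_evidence"] = len(a)
    b = filter_rare_damaging(list(records))
    report.stage_counts["filter_b_rare_damaging"] = len(b)

    seen: dict[str, VariantRecord] = {}
    for rec in [*a, *b]:
        seen.setdefault(rec.variant_id, rec)
    union = [rec for rec in records if rec.variant_id in seen]
    report.stage_counts["union_a_b"] = len(union)

    final = filter_call_quality(union)
    report.stage_counts["call_quality"] = len(final)

    rows = {}
    ids_a = {r.variant_id for r in a}
    ids_b = {r.variant_id for r in b}
    ids_f = {r.variant_id for r in final}
    for rec in records:
        rows[rec.variant_id] = {
            "filter_a_evidence": rec.variant_id in ids_a,
            "filter_b_rare_damaging": rec.variant_id in ids_b,
            "union_a_b": rec.variant_id in {r.variant_id for r in union},
            "call_quality": rec.variant_id in ids_f,
        }
    report.outcomes = pd.DataFrame.from_dict(rows, orient="index")
    return final, report


def coverage_qc(
    depth: pd.DataFrame,
    targets: list[TargetRegion],
    thresholds: tuple[int, ...] = COVERAGE_THRESHOLDS,
) -> pd.DataFrame:
    """Fraction of target bases reaching each depth threshold.

    ``depth`` has columns chrom, pos (1-based), depth; bases of a target with
    no depth row count as depth 0.  Returns one row per target plus a
    ``panel`` row, with a ``frac_{t}x`` column per threshold.
    """
    by_chrom = {c: g.set_index("pos")["depth"] for c, g in depth.groupby("chrom")}
    rows = []
    panel_base_depths = []
    for tgt in targets:
        track = by_chrom.get(tgt.chrom)
        # BED is 0-based half-open; depth positions are 1-based
        positions = np.arange(tgt.start + 1, tgt.end + 1)
        if track is None:
            warnings.warn(f"target {tgt.name}: no depth data, coverage set to 0", stacklevel=2)
            depths = np.zeros(len(positions))
        else:
            depths = track.reindex(positions).fillna(0).to_numpy()
            if np.all(depths == 0):
                warnings.warn(f"target {tgt.name}: no depth data, coverage set to 0", stacklevel=2)
        panel_base_depths.append(depths)
        row = {"target": tgt.name, "n_bases": len(positions)}
        for t in thresholds:
            row[f"frac_{t}x"] = float(np.mean(depths >= t))
        rows.append(row)
    all_depths = np.concatenate(panel_base_depths) if panel_base_depths else np.array([])
    panel_row = {"target": "panel", "n_bases": len(all_depths)}
    for t in thresholds:
        panel_row[f"frac_{t}x"] = float(np.mean(all_depths >= t)) if len(all_depths) else 0.0
    rows.append(panel_row)
    return pd.DataFrame(rows)


def drop_monomorphic(cohort):
    """Remove variants whose dosage column has zero variance (every subject
    wild-type, or every subject the same genotype); returns (cohort, dropped)."""
    var = cohort.dosages.var(axis=0, ddof=0)
    dropped = [c for c in cohort.dosages.columns if var[c] == 0]
    out = cohort.copy()
    out.dosages = out.dosages.drop(columns=dropped)
    if out.variant_meta is not None:
        out.variant_meta = out.variant_meta.drop(index=dropped, errors="ignore")
    return out, dropped
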