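"""Readers and writers for the pipeline's on-disk formats.

VCF 4.2 (per-sample GT:DP:AD, biallelic after splitting), BED3+ target
regions, tab-separated phenotype and reference allele-frequency tables, and
TSV/JSON result reports.  Coordinates are half-open 0-based internally;
VCF positions are 1-based as mandated by the format.  Numeric text is parsed
accepting both '.' and ',' decimal separators (clinical tables are often
exported with decimal commas) but always written with '.'.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

__all__ = [
    "VariantRecord",
    "TargetRegion",
    "CONSEQUENCE_CLASSES",
    "PREDICTOR_NAMES",
    "read_vcf",
    "read_bed",
    "read_phenotypes",
    "read_reference_af",
    "read_depth_tsv",
    "cohort_from_files",
    "write_simple_vcf",
    "write_records_vcf",
    "write_results",
    "parse_decimal",
]

CONSEQUENCE_CLASSES = {"missense", "nonsense", "frameshift", "splicing", "synonymous", "other"}

#: the six in-silico missense predictors whose calls are consumed as input
PREDICTOR_NAMES = ("SIFT", "PolyPhen2", "MutationTaster", "MutationAssessor", "FATHMM", "FATHMM-MKL")

#: default INFO-key mapping for annotations written/read by this package
DEFAULT_FIELD_MAP = {
    "maf": "MAF",
    "consequence": "CSQ_CLASS",
    "predictors": "PRED",  # comma-joined six calls, e.g. "D,B,D,.,D,B"
    "ada": "ADA",
    "tier": "TIER",
}

_PRED_CODE = {"D": "damaging", "B": "benign", ".": "missing"}
_PRED_CODE_INV = {v: k for k, v in _PRED_CODE.items()}


@dataclass
class VariantRecord:
    """One annotated biallelic variant with per-sample calls.

    ``calls`` holds one ``(gt, dp, ad)`` triple per sample where ``gt`` is a
    VCF genotype string in {0/0, 0/1, 1/1, ./.}, ``dp`` the total depth (or
    None) and ``ad`` the (ref, alt) allele depths (or None).
    ``predictor_calls`` is a six-tuple over SIFT, PolyPhen2, MutationTaster,
    MutationAssessor, FATHMM and FATHMM-MKL with values in
    {damaging, benign, missing}.  ``filter_provenance`` accumulates
    (filter_name, outcome) pairs as the record moves through the cascade.
    """

    variant_id: str
    chrom: str
    pos: int  # 1-based, as in VCF
    ref: str
    alt: str
    calls: list[tuple[str, int | None, tuple[int, int] | None]] = field(default_factory=list)
    maf: float | None = None
    consequence: str = "other"
    predictor_calls: tuple[str, ...] = ("missing",) * 6
    ada_score: float | None = None
    evidence_tier: int | None = None  # PharmGKB clinical evidence level 1-3, None = untiered
    filter_provenance: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"{self.variant_id}: VCF position must be >= 1")
        if len(self.predictor_calls) != 6:
            raise ValueError(f"{self.variant_id}: predictor_calls must have exactly 6 entries")
        if self.consequence not in CONSEQUENCE_CLASSES:
            raise ValueError(f"{self.variant_id}: unknown consequence {self.consequence!r}")
        for gt, dp, ad in self.calls:
            if dp is not None and ad is not None and sum(ad) > dp:
                raise ValueError(f"{self.variant_id}: AD sums above DP in a call")

    def dosages(self) -> np.ndarray:
        """Alternate-allele dosage per sample; NaN for missing genotypes."""
        table = {"0/0": 0.0, "0/1": 1.0, "1/0": 1.0, "1/1": 2.0, "./.": np.nan}
        return np.array([table.get(gt, np.nan) for gt, _, _ in self.calls])


@dataclass(frozen=True)
class TargetRegion:
    """Half-open 0-based interval on a chromosome (BED convention)."""

    chrom: str
    start: int
    end: int
    name: str = ""

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"region {self.name or self.chrom}: start must be < end")

    def __len__(self) -> int:
        return self.end - self.start


def parse_decimal(text) -> float:
    """Parse a number accepting either '.' or ',' as the decimal separator."""
    if isinstance(text, (int, float, np.floating, np.integer)):
        return float(text)
    return float(str(text).strip().replace(",", "."))


def _parse_gt(gt_str: str) -> str:
    gt = gt_str.replace("|", "/")
    return gt if gt in {"0/0", "0/1", "1/0", "1/1", "./."} else "./."


def read_vcf(path, annotation_field_map: dict | None = None):
    """Read a VCF into ``(records, samples)``.

    ``annotation_field_map`` names the INFO keys carrying the annotation
    columns (defaults: MAF, CSQ_CLASS, PRED, ADA, TIER).  Multi-allelic lines
    are split into one record per alternate allele with a warning; missing
    annotations stay missing (never coerced to 0).
    """
    fmap = dict(DEFAULT_FIELD_MAP)
    if annotation_field_map:
        fmap.update(annotation_field_map)

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # pragma: no cover - cyvcf2 error surface
        raise ValueError(f"cannot open VCF {path}: {exc}") from exc

    samples = list(vcf.samples)
    records: list[VariantRecord] = []
    for var in vcf:
        alts = var.ALT or []
        if len(alts) > 1:
            warnings.warn(
                f"multi-allelic site {var.CHROM}:{var.POS} split into {len(alts)} records",
                stacklevel=2,
            )
        n_alt = len(alts)
        genotypes = var.genotypes  # [[a, b, phased], ...]
        try:
            dp_arr = var.format("DP")
        except Exception:
            dp_arr = None
        try:
            ad_arr = var.format("AD")
        except Exception:
            ad_arr = None

        info = dict(var.INFO)

        for alt_index, alt in enumerate(alts, start=1):
            calls = []
            for si in range(len(samples)):
                a, b = genotypes[si][0], genotypes[si][1]
                if a < 0 or b < 0:
                    gt = "./."
                else:
                    a_bi = 1 if a == alt_index else 0
                    b_bi = 1 if b == alt_index else 0
                    gt = f"{min(a_bi, b_bi)}/{max(a_bi, b_bi)}"
                dp = None
                if dp_arr is not None:
                    v = int(np.asarray(dp_arr[si]).ravel()[0])
                    dp = v if v >= 0 else None
                ad = None
                if ad_arr is not None:
                    row = np.asarray(ad_arr[si]).ravel()
                    if len(row) > alt_index and row[0] >= 0:
                        ad = (int(row[0]), int(row[alt_index]))
                calls.append((gt, dp, ad))

            vid = var.ID or f"{var.CHROM}:{var.POS}:{var.REF}:{alt}"
            if n_alt > 1:
                vid = f"{vid}" if var.ID is None else f"{var.ID}_{alt_index}"

            def _scalar(key, idx=alt_index - 1):
                raw = info.get(fmap[key])
                if raw is None:
                    return None
                if isinstance(raw, tuple):
                    raw = raw[idx] if idx < len(raw) else raw[0]
                return raw

            maf_raw = _scalar("maf")
            maf = None if maf_raw in (None, ".") else parse_decimal(maf_raw)
            ada_raw = _scalar("ada")
            ada = None if ada_raw in (None, ".") else parse_decimal(ada_raw)
            tier_raw = _scalar("tier")
            tier = None if tier_raw in (None, ".", 0, "0") else int(tier_raw)
            csq = _scalar("consequence")
            csq = str(csq) if csq is not None else "other"
            pred_raw = info.get(fmap["predictors"])
            if pred_raw is None:
                preds = ("missing",) * 6
            else:
                codes = str(pred_raw).split(",")
                preds = tuple(_PRED_CODE.get(c.strip(), "missing") for c in codes)
                preds = (preds + ("missing",) * 6)[:6]

            records.append(
                VariantRecord(
                    variant_id=vid,
                    chrom=var.CHROM,
                    pos=var.POS,
                    ref=var.REF,
                    alt=alt,
                    calls=calls,
                    maf=maf,
                    consequence=csq if csq in CONSEQUENCE_CLASSES else "other",
                    predictor_calls=preds,
                    ada_score=ada,
                    evidence_tier=tier,
                )
            )
    return records, samples


def read_bed(path) -> list[TargetRegion]:
    """Read BED3+ target regions (0-based half-open, as BED defines)."""
    regions = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: BED line needs >= 3 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else f"{chrom}:{start}-{end}"
            if start >= end:
                raise ValueError(f"{path}:{ln}: inverted coordinates {start} >= {end}")
            regions.append(TargetRegion(chrom, start, end, name))
    return regions


def read_phenotypes(path) -> pd.DataFrame:
    """Read the phenotype TSV (sample_id, ct_seconds, htpr, covariates...).

    Decimal commas and decimal points both parse; duplicate sample ids are an
    error.  The returned frame is indexed by sample_id.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: phenotype table must have a 'sample_id' column")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"{path}: duplicate sample ids {dups}")
    df = df.set_index("sample_id")
    for col in df.columns:
        df[col] = df[col].map(parse_decimal)
    if "htpr" in df.columns:
        df["htpr"] = df["htpr"].astype(int)
    return df


def read_reference_af(path) -> pd.Series:
    """Reference (e.g. gnomAD-derived) alternate-allele frequencies by id."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"variant_id", "ref_af_alt"} <= set(df.columns):
        raise ValueError(f"{path}: need columns variant_id, ref_af_alt")
    return pd.Series(
        [parse_decimal(x) for x in df["ref_af_alt"]],
        index=df["variant_id"].tolist(),
        name="ref_af_alt",
    )


def read_depth_tsv(path) -> pd.DataFrame:
    """Per-base depth track: columns chrom, pos (1-based), depth."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = {"chrom", "pos", "depth"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: depth TSV missing columns {sorted(missing)}")
    return df


def cohort_from_files(vcf_path, pheno_path=None, htpr_threshold: float = 106.0):
    """Build a :class:`~pgxprs.simulate.Cohort` from VCF (+ phenotype TSV)."""
    from .simulate import Cohort

    records, samples = read_vcf(vcf_path)
    dos = pd.DataFrame(
        {r.variant_id: r.dosages() for r in records}, index=samples
    )
    meta = pd.DataFrame(
        {
            "chrom": [r.chrom for r in records],
            "pos": [r.pos for r in records],
            "ref": [r.ref for r in records],
            "alt": [r.alt for r in records],
        },
        index=[r.variant_id for r in records],
    )
    ct = htpr = cov = None
    if pheno_path is not None:
        pheno = read_phenotypes(pheno_path).reindex(samples)
        if pheno.isna().any().any():
            raise ValueError("phenotype table does not cover all VCF samples")
        ct = pheno["ct_seconds"] if "ct_seconds" in pheno.columns else None
        htpr = pheno["htpr"].astype(int) if "htpr" in pheno.columns else None
        cov_cols = [c for c in pheno.columns if c not in ("ct_seconds", "htpr")]
        cov = pheno[cov_cols] if cov_cols else None
    if dos.isna().any().any():
        # keep NaN for missing genotypes; downstream decides policy
        pass
    else:
        dos = dos.astype(np.int64)
    return Cohort(
        sample_ids=samples,
        dosages=dos,
        ct=ct,
        htpr=htpr,
        covariates=cov,
        htpr_threshold=htpr_threshold,
        variant_meta=meta,
    )


_VCF_HEADER = """##fileformat=VCFv4.2
##INFO=<ID=MAF,Number=A,Type=Float,Description="Reference minor/alternate allele frequency">
##INFO=<ID=CSQ_CLASS,Number=1,Type=String,Description="Consequence class">
##INFO=<ID=PRED,Number=1,Type=String,Description="Six in-silico predictor calls, comma-joined (D/B/.)">
##INFO=<ID=ADA,Number=A,Type=Float,Description="Ensemble splice-altering score">
##INFO=<ID=TIER,Number=A,Type=Integer,Description="Clinical evidence tier (1-3)">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt)">
"""


def write_simple_vcf(records: list[dict], samples: list[str], path) -> None:
    """Write plain biallelic records (dicts with variant_id/chrom/pos/ref/alt/
    calls and optional annotation keys) as a VCF 4.2 text file."""
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for rec in records:
            info_parts = []
            if rec.get("maf") is not None:
                info_parts.append(f"MAF={rec['maf']:.6g}")
            if rec.get("consequence"):
                info_parts.append(f"CSQ_CLASS={rec['consequence']}")
            if rec.get("predictors"):
                info_parts.append("PRED=" + ",".join(rec["predictors"]))
            if rec.get("ada") is not None:
                info_parts.append(f"ADA={rec['ada']:.6g}")
            if rec.get("tier") is not None:
                info_parts.append(f"TIER={rec['tier']}")
            info = ";".join(info_parts) or "."
            fields = [
                str(rec["chrom"]),
                str(rec["pos"]),
                str(rec["variant_id"]),
                rec["ref"],
                rec["alt"],
                ".",
                "PASS",
                info,
                "GT:DP:AD",
            ]
            for gt, dp, ad in rec["calls"]:
                dp_s = "." if dp is None else str(dp)
                ad_s = "." if ad is None else f"{ad[0]},{ad[1]}"
                fields.append(f"{gt}:{dp_s}:{ad_s}")
            fh.write("\t".join(fields) + "\n")


def write_records_vcf(records: list[VariantRecord], samples: list[str], path) -> None:
    """Serialise :class:`VariantRecord` objects back to VCF 4.2."""
    dicts = []
    for r in records:
        dicts.append(
            {
                "variant_id": r.variant_id,
                "chrom": r.chrom,
                "pos": r.pos,
                "ref": r.ref,
                "alt": r.alt,
                "calls": r.calls,
                "maf": r.maf,
                "consequence": r.consequence,
                "predictors": tuple(_PRED_CODE_INV[p] for p in r.predictor_calls),
                "ada": r.ada_score,
                "tier": r.evidence_tier,
            }
        )
    write_simple_vcf(dicts, samples, path)


def write_results(tables: dict[str, pd.DataFrame], out_dir, summary: dict | None = None) -> None:
    """Write each table as ``<name>.tsv`` (full precision, '.' decimals) plus
    an optional ``summary.json``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, table in tables.items():
        table.to_csv(out / f"{name}.tsv", sep="\t", index=False, float_format="%.12g")
    if summary is not None:
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, default=float)
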