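import numpy as np
import pandas as pd
import pytest

from pgxprs.io import VariantRecord
from pgxprs.simulate import Cohort


def make_record(vid="v1", maf=None, consequence="other", predictors=None,
                ada=None, tier=None, calls=None, pos=100):
    """Convenience constructor for an annotated variant record."""
    if predictors is None:
        predictors = ("missing",) * 6
    if calls is None:
        calls = [("0/1", 30, (15, 15))]
    return VariantRecord(
        variant_id=vid, chrom="chr1", pos=pos, ref="A", alt="G",
        calls=list(calls), maf=maf, consequence=consequence,
        predictor_calls=tuple(predictors), ada_score=ada, evidence_tier=tier,
    )


def make_cohort(dosages: dict, ct=None, htpr=None, covariates=None,
                threshold=106.0) -> Cohort:
    """Build a small in-memory cohort from per-variant dosage lists."""
    n = len(next(iter(dosages.values())))
    samples = [f"S{i+1:03d}" for i in range(n)]
    dos = pd.DataFrame(dosages, index=samples, dtype=float)
    if not dos.isna().any().any():
        dos = dos.astype(np.int64)
    ct_s = None if ct is None else pd.Series(np.asarray(ct, float), index=samples,
                                             name="ct_seconds")
    if htpr is None and ct is not None:
        htpr = (np.asarray(ct, float) < threshold).astype(int)
    htpr_s = None if htpr is None else pd.Series(np.asarray(htpr, int), index=samples,
                                                 name="htpr")
    cov = None if covariates is None else pd.DataFrame(covariates, index=samples)
    return Cohort(sample_ids=samples, dosages=dos, ct=ct_s, htpr=htpr_s,
                  covariates=cov, htpr_threshold=threshold)


@pytest.fixture
def rng():
    return np.random.default_rng(20240612)


GOOD_CALL = [("0/1", 30, (15, 15))]

# 20-record prioritisation fixture with hand-tabulated expectations.
# Track a (evidence tier 1-3): v01 v02 v03 v18
# Track b (MAF<2% or novel AND damaging): v04 v05 v08 v09 v10 v14 v18
# Union: 10 distinct records; call quality then drops v09 (DP 7) and
# v14 (het balance 0.20), leaving 8.
FILTER_FIXTURE_SPEC = [
    # (vid, maf, consequence, n_damaging/n_benign/n_missing, ada, tier, calls)
    ("v01", 0.30, "other", (0, 0, 6), None, 1, GOOD_CALL),
    ("v02", 0.10, "missense", (1, 5, 0), None, 2, GOOD_CALL),
    ("v03", 0.25, "synonymous", (0, 0, 6), None, 3, GOOD_CALL),
    ("v04", 0.010, "missense", (4, 2, 0), None, None, [("0/1", 10, (7, 3))]),
    ("v05", 0.019, "missense", (3, 3, 0), None, None, GOOD_CALL),
    ("v06", 0.020, "missense", (6, 0, 0), None, None, GOOD_CALL),  # MAF boundary: not < 2%
    ("v07", 0.050, "missense", (6, 0, 0), None, None, GOOD_CALL),
    ("v08", None, "nonsense", (0, 0, 6), None, None, [("1/1", 8, (0, 8))]),
    ("v09", 0.001, "frameshift", (0, 0, 6), None, None, [("0/1", 7, (4, 3))]),  # depth fails
    ("v10", 0.001, "splicing", (0, 0, 6), 0.60, None, [("0/1", 8, (6, 2))]),  # both boundaries pass
    ("v11", 0.001, "splicing", (0, 0, 6), 0.59, None, GOOD_CALL),
    ("v12", 0.001, "splicing", (0, 0, 6), None, None, GOOD_CALL),
    ("v13", 0.001, "missense", (2, 4, 0), None, None, GOOD_CALL),
    ("v14", 0.001, "missense", (3, 0, 3), None, None, [("0/1", 10, (8, 2))]),  # balance fails
    ("v15", 0.001, "missense", (2, 0, 4), None, None, GOOD_CALL),
    ("v16", 0.001, "synonymous", (0, 0, 6), None, None, GOOD_CALL),
    ("v17", 0.001, "other", (0, 0, 6), None, None, GOOD_CALL),
    ("v18", 0.001, "nonsense", (0, 0, 6), None, 1, GOOD_CALL),
    ("v19", None, "missense", (0, 6, 0), None, None, GOOD_CALL),
    ("v20", 0.50, "other", (0, 0, 6), None, None, GOOD_CALL),
]

EXPECTED_FILTER_A = {"v01", "v02", "v03", "v18"}
EXPECTED_FILTER_B = {"v04", "v05", "v08", "v09", "v10", "v14", "v18"}
EXPECTED_FINAL = (EXPECTED_FILTER_A | EXPECTED_FILTER_B) - {"v09", "v14"}


def build_filter_fixture():
    records = []
    for i, (vid, maf, csq, (nd, nb, nm), ada, tier, calls) in enumerate(FILTER_FIXTURE_SPEC):
        preds = ("damaging",) * nd + ("benign",) * nb + ("missing",) * nm
        records.append(
            make_record(vid, maf=maf, consequence=csq, predictors=preds,
                        ada=ada, tier=tier, calls=calls, pos=100 + i)
        )
    return records
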