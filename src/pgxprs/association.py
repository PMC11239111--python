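"""Genetic-model contingency association with HTPR status and closure-time
comparisons by genotype group.

Three genotype groupings are supported for a biallelic variant with dosage
in {0, 1, 2}:

* ``codominant`` — three categories (0 vs 1 vs 2 alternate alleles);
* ``carrier`` — homozygous reference vs carriers of at least one alternate
  allele ({0} vs {1, 2});
* ``homozygote_contrast`` — homozygous reference vs homozygous alternate
  ({0} vs {2}); heterozygotes are excluded from the table.

For 2x2 tables the odds ratio is reported with a Woolf (log-scale)
95% confidence interval; codominant 3x2 tables get a chi-square with 2
degrees of freedom and no OR.  CT comparisons between genotype groups use
the Mann-Whitney U test (exact when both groups are small and untied).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GENETIC_MODELS",
    "AssociationResult",
    "genotype_groups",
    "build_contingency",
    "pearson_chi2",
    "odds_ratio_woolf",
    "mann_whitney_ct",
    "association_scan",
    "ct_by_genotype",
]

GENETIC_MODELS = ("codominant", "carrier", "homozygote_contrast")

_Z975 = 1.959963984540054  # standard normal 97.5% quantile


@dataclass
class AssociationResult:
    variant_id: str
    model: str
    table: pd.DataFrame  # categories x (non_case, case) counts
    chi2: float
    p: float
    odds_ratio: float | None
    ci95: tuple[float, float] | None
    odds_ratio_inverse: float | None
    ci95_inverse: tuple[float, float] | None
    n_used: int
    small_cells: bool  # any expected count < 5
    haldane_corrected: bool = False


def genotype_groups(dosage: np.ndarray, model: str):
    """Map dosages to category labels under a genetic model.

    Returns (labels, category_order); excluded subjects (heterozygotes under
    homozygote_contrast, missing genotypes always) get label None.
    """
    if model not in GENETIC_MODELS:
        raise ValueError(f"unknown genetic model {model!r}")
    d = np.asarray(dosage, float)
    labels = np.full(len(d), None, dtype=object)
    if model == "codominant":
        order = ["0", "1", "2"]
        for g in (0, 1, 2):
            labels[d == g] = str(g)
    elif model == "carrier":
        order = ["0", "1+2"]
        labels[d == 0] = "0"
        labels[(d == 1) | (d == 2)] = "1+2"
    else:  # homozygote_contrast
        order = ["0", "2"]
        labels[d == 0] = "0"
        labels[d == 2] = "2"
    return labels, order


def build_contingency(dosage, outcome, model: str) -> pd.DataFrame:
    """Category x outcome integer table (columns non_case, case).

    Degenerate tables (a single observed category) are returned as-is and
    flagged downstream; percentages as printed in clinical tables are
    column-wise and available via :func:`table_percentages`.
    """
    labels, order = genotype_groups(dosage, model)
    y = np.asarray(outcome)
    rows = []
    for cat in order:
        m = labels == cat
        rows.append({"category": cat, "non_case": int(((y == 0) & m).sum()),
                     "case": int(((y == 1) & m).sum())})
    table = pd.DataFrame(rows).set_index("category")
    return table[table.sum(axis=1) > 0] if model == "homozygote_contrast" else table


def table_percentages(table: pd.DataFrame) -> pd.DataFrame:
    """Column-wise percentages of a contingency table."""
    return 100.0 * table / table.sum(axis=0)


def pearson_chi2(table) -> tuple[float, float]:
    """Pearson chi-square with df = (r-1)(c-1), no continuity correction."""
    obs = np.asarray(table, dtype=float)
    obs = obs[obs.sum(axis=1) > 0][:, obs.sum(axis=0) > 0]
    if obs.shape[0] < 2 or obs.shape[1] < 2:
        return 0.0, 1.0
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    expected = row @ col / obs.sum()
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return chi2, float(stats.chi2.sf(chi2, df))


def expected_counts(table) -> np.ndarray:
    obs = np.asarray(table, dtype=float)
    return obs.sum(axis=1, keepdims=True) @ obs.sum(axis=0, keepdims=True) / obs.sum()


def odds_ratio_woolf(a: float, b: float, c: float, d: float):
    """Odds ratio with Woolf 95% CI from a 2x2 table laid out as
    a = exposed cases, b = exposed non-cases, c = unexposed cases,
    d = unexposed non-cases.

    OR = (a*d)/(b*c); CI = exp(ln OR +/- 1.96 * sqrt(1/a + 1/b + 1/c + 1/d)).
    If any single cell is zero the Haldane-Anscombe correction (+0.5 to all
    cells) is applied and flagged; two zero cells in one diagonal line leave
    the OR undefined.

    Returns (or, ci_low, ci_high, haldane_applied) or (None, None, None,
    False) when undefined.
    """
    cells = np.array([a, b, c, d], dtype=float)
    if np.any(cells < 0):
        raise ValueError("table cells must be nonnegative")
    n_zero = int((cells == 0).sum())
    haldane = False
    if n_zero >= 2:
        return None, None, None, False
    if n_zero == 1:
        cells = cells + 0.5
        haldane = True
    a_, b_, c_, d_ = cells
    or_ = (a_ * d_) / (b_ * c_)
    se = np.sqrt(1 / a_ + 1 / b_ + 1 / c_ + 1 / d_)
    lo = float(np.exp(np.log(or_) - _Z975 * se))
    hi = float(np.exp(np.log(or_) + _Z975 * se))
    return float(or_), lo, hi, haldane


def mann_whitney_ct(group_a, group_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U comparing two CT vectors.

    Exact null distribution when the smaller group has <= 8 observations and
    there are no ties; otherwise the normal approximation with tie and
    continuity corrections.  Returns (U of group_a, p).
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (min(len(a), len(b)) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def _associate_binary(name, exposure, outcome, model_label) -> AssociationResult:
    """Association of a pre-binarised exposure (2 categories) with outcome."""
    table = pd.DataFrame(
        {
            "non_case": [int(((outcome == 0) & (exposure == 0)).sum()),
                         int(((outcome == 0) & (exposure == 1)).sum())],
            "case": [int(((outcome == 1) & (exposure == 0)).sum()),
                     int(((outcome == 1) & (exposure == 1)).sum())],
        },
        index=["0", "1"],
    )
    return _result_from_table(name, model_label, table)


def _result_from_table(variant_id, model, table) -> AssociationResult:
    chi2, p = pearson_chi2(table)
    n_used = int(table.to_numpy().sum())
    small = bool((expected_counts(table) < 5).any()) if table.shape[0] >= 2 else True
    or_ = ci = or_inv = ci_inv = None
    hald = False
    if table.shape[0] == 2:
        # exposed = second (variant-carrying / listed) category, case = HTPR
        a = table.iloc[1]["case"]
        b = table.iloc[1]["non_case"]
        c = table.iloc[0]["case"]
        d = table.iloc[0]["non_case"]
        o, lo, hi, hald = odds_ratio_woolf(a, b, c, d)
        if o is not None:
            or_, ci = o, (lo, hi)
            # inverse orientation: exposure predicting non-case status
            oi, loi, hii, _ = odds_ratio_woolf(b, a, d, c)
            or_inv, ci_inv = oi, (loi, hii)
    return AssociationResult(
        variant_id=variant_id, model=model, table=table, chi2=chi2, p=p,
        odds_ratio=or_, ci95=ci, odds_ratio_inverse=or_inv, ci95_inverse=ci_inv,
        n_used=n_used, small_cells=small, haldane_corrected=hald,
    )


def associate_variant(dosage, outcome, variant_id: str, model: str) -> AssociationResult:
    table = build_contingency(dosage, outcome, model)
    return _result_from_table(variant_id, model, table)


def ct_by_genotype(dosage, ct, model: str) -> pd.DataFrame:
    """Mean CT and count per genotype group, plus the Mann-Whitney p between
    the two extreme groups (or the two groups of a binary model)."""
    labels, order = genotype_groups(dosage, model)
    ct = np.asarray(ct, float)
    rows = []
    groups = {}
    for cat in order:
        m = labels == cat
        if m.sum() == 0:
            continue
        groups[cat] = ct[m]
        rows.append({"category": cat, "n": int(m.sum()), "ct_mean": float(ct[m].mean())})
    out = pd.DataFrame(rows)
    if len(groups) >= 2:
        cats = list(groups)
        _, p = mann_whitney_ct(groups[cats[0]], groups[cats[-1]])
        out.attrs["mann_whitney_p"] = p
    else:
        out.attrs["mann_whitney_p"] = np.nan
    return out


def association_scan(
    cohort,
    models=GENETIC_MODELS,
    include_covariates: bool = True,
    bh_correction: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Test every variant under every genetic model (plus binary covariates)
    for HTPR association and CT location shift.

    Returns (association table, CT-by-genotype table), both sorted by p.
    The Benjamini-Hochberg column is supplementary output, not part of the
    primary per-test statistics.
    """
    if cohort.htpr is None:
        raise ValueError("cohort has no HTPR labels")
    y = cohort.htpr.to_numpy()
    assoc_rows, ct_rows = [], []

    def _push(res: AssociationResult, kind: str):
        assoc_rows.append(
            {
                "variant_id": res.variant_id,
                "kind": kind,
                "model": res.model,
                "chi2": res.chi2,
                "p": res.p,
                "odds_ratio": res.odds_ratio,
                "ci_low": None if res.ci95 is None else res.ci95[0],
                "ci_high": None if res.ci95 is None else res.ci95[1],
                "odds_ratio_inverse": res.odds_ratio_inverse,
                "ci_low_inverse": None if res.ci95_inverse is None else res.ci95_inverse[0],
                "ci_high_inverse": None if res.ci95_inverse is None else res.ci95_inverse[1],
                "n_used": res.n_used,
                "small_cells": res.small_cells,
                "haldane_corrected": res.haldane_corrected,
            }
        )

    for vid in cohort.dosages.columns:
        d = cohort.dosages[vid].to_numpy(float)
        for model in models:
            _push(associate_variant(d, y, vid, model), "variant")
            if cohort.ct is not None:
                tab = ct_by_genotype(d, cohort.ct.to_numpy(), model)
                for _, row in tab.iterrows():
                    ct_rows.append(
                        {
                            "variant_id": vid,
                            "model": model,
                            "category": row["category"],
                            "n": row["n"],
                            "ct_mean": row["ct_mean"],
                            "mann_whitney_p": tab.attrs["mann_whitney_p"],
                        }
                    )

    if include_covariates and cohort.covariates is not None:
        for cov in cohort.covariates.columns:
            x = cohort.covariates[cov].to_numpy()
            _push(_associate_binary(cov, x, y, "binary_covariate"), "covariate")
            if cohort.ct is not None:
                ct_arr = cohort.ct.to_numpy()
                g0, g1 = ct_arr[x == 0], ct_arr[x == 1]
                if len(g0) and len(g1):
                    _, p = mann_whitney_ct(g0, g1)
                    for lbl, g in (("0", g0), ("1", g1)):
                        ct_rows.append(
                            {"variant_id": cov, "model": "binary_covariate",
                             "category": lbl, "n": len(g), "ct_mean": float(g.mean()),
                             "mann_whitney_p": p}
                        )

    assoc_cols = ["variant_id", "kind", "model", "chi2", "p", "odds_ratio",
                  "ci_low", "ci_high", "odds_ratio_inverse", "ci_low_inverse",
                  "ci_high_inverse", "n_used", "small_cells", "haldane_corrected"]
    assoc = pd.DataFrame(assoc_rows, columns=assoc_cols)
    assoc = assoc.sort_values("p", kind="mergesort").reset_index(drop=True)
    if bh_correction and len(assoc):
        from statsmodels.stats.multitest import multipletests

        assoc["p_bh_supplementary"] = multipletests(assoc["p"], method="fdr_bh")[1]
    ct_table = pd.DataFrame(ct_rows)
    if len(ct_table):
        ct_table = ct_table.sort_values(
            ["mann_whitney_p", "variant_id"], kind="mergesort"
        ).reset_index(drop=True)
    return assoc, ct_table
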