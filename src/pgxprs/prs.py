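"""Pharmacogenomic polygenic risk score (PgxPRS).

The score of subject j is the weighted allele-dosage sum

    PgxPRS_j = sum_i beta_i * dosage_ij

over the variants retained by the penalised model, with beta_i the fitted
effect size.  For carrier-encoded features the "dosage" entering the score
is the 0/1 carrier indicator used in the fit, keeping scoring consistent
with estimation.  Clinical covariates are excluded from the score by
default (genetic-only score); a flag includes them.

Validation statistics mirror standard practice for a score validated
against a continuous response and a dichotomised outcome: Mann-Whitney U
between outcome classes, Spearman rank correlation with the response, and
the ordinary-least-squares coefficient of determination (R^2) of response
on score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .association import mann_whitney_ct
from .lasso import FeatureMatrix

__all__ = ["PRSWeights", "PRSResult", "compute_pgxprs",
           "evaluate_discrimination", "correlate_ct", "score_and_validate"]


@dataclass
class PRSWeights:
    """(feature id, beta, encoding) triples defining the score."""

    table: pd.DataFrame  # columns: feature_id, beta, encoding

    def __post_init__(self) -> None:
        need = {"feature_id", "beta", "encoding"}
        if not need <= set(self.table.columns):
            raise ValueError(f"weights table needs columns {sorted(need)}")
        if not np.isfinite(self.table["beta"]).all():
            raise ValueError("all beta values must be finite")

    @classmethod
    def from_results(cls, results, feature_matrix: FeatureMatrix,
                     include_covariates: bool = False) -> "PRSWeights":
        meta = feature_matrix.column_meta
        betas = results.prs_weights(
            include_covariates=include_covariates, feature_kinds=meta["kind"]
        )
        return cls(pd.DataFrame({
            "feature_id": betas.index,
            "beta": betas.to_numpy(),
            "encoding": [meta.loc[f, "encoding"] for f in betas.index],
        }))

    @classmethod
    def from_tsv(cls, path) -> "PRSWeights":
        from .io import parse_decimal

        df = pd.read_csv(path, sep="\t", dtype=str)
        df["beta"] = df["beta"].map(parse_decimal)
        return cls(df)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.12g")


@dataclass
class PRSResult:
    scores: pd.Series  # per-subject PgxPRS
    group_summary: pd.DataFrame | None = None  # median/IQR per outcome class
    mann_whitney_p: float | None = None
    spearman_rho: float | None = None
    spearman_p: float | None = None
    ols_r2: float | None = None

    def summary(self) -> str:
        lines = [f"PgxPRS over {len(self.scores)} subjects: "
                 f"range [{self.scores.min():.4f}, {self.scores.max():.4f}]"]
        if self.group_summary is not None:
            for _, row in self.group_summary.iterrows():
                lines.append(
                    f"  {row['group']:<10s} n={int(row['n']):3d} "
                    f"median={row['median']:.4f} IQR=({row['q1']:.4f}, {row['q3']:.4f})"
                )
        if self.mann_whitney_p is not None:
            lines.append(f"  Mann-Whitney p (HTPR vs non-HTPR) = {self.mann_whitney_p:.4g}")
        if self.spearman_rho is not None:
            lines.append(f"  Spearman rho (score vs CT) = {self.spearman_rho:+.3f} "
                         f"(p = {self.spearman_p:.4g})")
        if self.ols_r2 is not None:
            lines.append(f"  OLS R^2 (CT on score) = {self.ols_r2:.3f}")
        return "\n".join(lines)

    def plot(self, ct=None, htpr=None, axes=None):
        """Boxplot of score by outcome class and score-vs-CT scatter."""
        import matplotlib.pyplot as plt

        if axes is None:
            _, axes = plt.subplots(1, 2, figsize=(9, 4))
        if htpr is not None:
            data = [self.scores[np.asarray(htpr) == 0], self.scores[np.asarray(htpr) == 1]]
            axes[0].boxplot(data, tick_labels=["non-HTPR", "HTPR"])
            axes[0].set_ylabel("PgxPRS")
        if ct is not None:
            axes[1].scatter(self.scores, ct, s=12)
            axes[1].set_xlabel("PgxPRS")
            axes[1].set_ylabel("CT (s)")
        return axes


def compute_pgxprs(weights: PRSWeights, feature_matrix: FeatureMatrix,
                   impute_missing: bool = False) -> pd.Series:
    """Per-subject score: sum of beta_i times the encoded dosage of feature i.

    Every weighted feature must exist in the matrix with a matching encoding;
    missing values raise unless mean-imputation is requested.
    """
    data = feature_matrix.data
    meta = feature_matrix.column_meta
    scores = np.zeros(len(data))
    for _, row in weights.table.iterrows():
        fid = row["feature_id"]
        if fid not in data.columns:
            raise KeyError(f"weighted feature {fid!r} not in the cohort")
        enc = meta.loc[fid, "encoding"]
        if enc != row["encoding"]:
            raise ValueError(
                f"{fid}: weight encoding {row['encoding']!r} does not match "
                f"cohort encoding {enc!r}"
            )
        col = data[fid].to_numpy(float)
        if np.isnan(col).any():
            if not impute_missing:
                raise ValueError(f"{fid}: missing dosages; set impute_missing=True")
            col = np.where(np.isnan(col), np.nanmean(col), col)
        scores += row["beta"] * col
    return pd.Series(scores, index=data.index, name="pgxprs")


def evaluate_discrimination(scores, htpr) -> tuple[float, pd.DataFrame]:
    """Mann-Whitney p between outcome classes plus boxplot-ready summaries."""
    s = np.asarray(scores, float)
    y = np.asarray(htpr)
    if len(np.unique(y)) != 2:
        raise ValueError("both outcome classes must be present")
    g0, g1 = s[y == 0], s[y == 1]
    _, p = mann_whitney_ct(g0, g1)
    rows = []
    for name, g in (("non-HTPR", g0), ("HTPR", g1)):
        rows.append({"group": name, "n": len(g), "median": float(np.median(g)),
                     "q1": float(np.percentile(g, 25)), "q3": float(np.percentile(g, 75))})
    return p, pd.DataFrame(rows)


def correlate_ct(scores, ct) -> tuple[float, float, float]:
    """Spearman rho (average ranks on ties, t-approximation p) and OLS R^2 of
    CT regressed on the score."""
    s = np.asarray(scores, float)
    c = np.asarray(ct, float)
    if len(s) < 3:
        raise ValueError("need at least 3 subjects")
    rho, p = stats.spearmanr(s, c)
    if np.var(s) == 0:
        r2 = 0.0
    else:
        slope, intercept = np.polyfit(s, c, 1)
        resid = c - (intercept + slope * s)
        r2 = 1.0 - resid.var() / c.var()
    return float(rho), float(p), float(r2)


def score_and_validate(weights: PRSWeights, feature_matrix: FeatureMatrix,
                       ct=None, htpr=None) -> PRSResult:
    """Compute the score and run the full validation battery."""
    scores = compute_pgxprs(weights, feature_matrix)
    res = PRSResult(scores=scores)
    if htpr is not None:
        res.mann_whitney_p, res.group_summary = evaluate_discrimination(scores, htpr)
    if ct is not None:
        res.spearman_rho, res.spearman_p, res.ols_r2 = correlate_ct(scores, ct)
    return res
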