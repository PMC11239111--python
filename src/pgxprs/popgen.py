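"""Population-genetic statistics: allele frequencies, Hardy-Weinberg
equilibrium, reference-frequency comparison and pairwise linkage
disequilibrium.

HWE uses the plain Pearson goodness-of-fit chi-square on the three genotype
classes against expectations p^2, 2pq, q^2 with 1 degree of freedom (two
free genotype classes minus one estimated allele frequency); an exact test
(mid-p not applied) is available as an option.  Allele-frequency comparison
against an external reference uses a Yates-corrected chi-square on the 2x2
allele-count table.  Two-locus haplotype frequencies are estimated from
unphased genotypes by EM, from which D, D' and r^2 follow.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "HWEResult",
    "LDResult",
    "allele_frequencies",
    "hwe_test",
    "hwe_exact_test",
    "hwe_scan",
    "compare_reference_af",
    "em_haplotype_frequencies",
    "ld_pairwise",
]


@dataclass
class HWEResult:
    variant_id: str
    n_hom_ref: int
    n_het: int
    n_hom_alt: int
    expected: tuple[float, float, float]
    chi2: float
    p: float
    in_equilibrium: bool  # at alpha = 0.05

    @property
    def allele_freq_alt(self) -> float:
        n = self.n_hom_ref + self.n_het + self.n_hom_alt
        return (self.n_het + 2 * self.n_hom_alt) / (2 * n)


@dataclass
class LDResult:
    variant_a: str
    variant_b: str
    d: float | None
    d_prime: float | None
    r2: float | None

    @property
    def defined(self) -> bool:
        return self.d is not None


def allele_frequencies(cohort) -> pd.Series:
    """Alternate-allele frequency per variant: sum of dosages over 2x the
    number of non-missing calls."""
    dos = cohort.dosages
    n_obs = dos.notna().sum(axis=0)
    return dos.sum(axis=0, skipna=True) / (2 * n_obs)


def hwe_test(n_hom_ref: int, n_het: int, n_hom_alt: int, variant_id: str = "") -> HWEResult:
    """Pearson chi-square goodness-of-fit test for HWE (df = 1).

    Monomorphic counts (estimated allele frequency 0 or 1) return chi2 = 0,
    p = 1 by convention.
    """
    counts = np.array([n_hom_ref, n_het, n_hom_alt], dtype=float)
    if np.any(counts < 0) or counts.sum() <= 0:
        raise ValueError("genotype counts must be nonnegative with positive total")
    n = counts.sum()
    q = (n_het + 2 * n_hom_alt) / (2 * n)  # alt allele frequency
    p = 1.0 - q
    expected = np.array([n * p * p, 2 * n * p * q, n * q * q])
    if q in (0.0, 1.0):
        return HWEResult(variant_id, n_hom_ref, n_het, n_hom_alt,
                         tuple(expected), 0.0, 1.0, True)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = float(np.sum((counts - expected) ** 2 / expected))
    pval = float(stats.chi2.sf(chi2, df=1))
    return HWEResult(
        variant_id, n_hom_ref, n_het, n_hom_alt, tuple(expected), chi2, pval, pval >= 0.05
    )


def hwe_chi2_vectorized(n_hom_ref, n_het, n_hom_alt):
    """Vectorised HWE chi-square and p over arrays of genotype counts."""
    c0 = np.asarray(n_hom_ref, float)
    c1 = np.asarray(n_het, float)
    c2 = np.asarray(n_hom_alt, float)
    n = c0 + c1 + c2
    q = (c1 + 2 * c2) / (2 * n)
    p = 1 - q
    e = np.stack([n * p * p, 2 * n * p * q, n * q * q])
    o = np.stack([c0, c1, c2])
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where((q == 0) | (q == 1), 0.0, np.nansum((o - e) ** 2 / e, axis=0))
    pval = np.where((q == 0) | (q == 1), 1.0, stats.chi2.sf(chi2, df=1))
    return chi2, pval


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact HWE test p-value: sum of probabilities of heterozygote counts no
    more likely than observed, conditional on allele counts (standard exact
    formulation)."""
    n = n_hom_ref + n_het + n_hom_alt
    n_alt = n_het + 2 * n_hom_alt
    n_alt = min(n_alt, 2 * n - n_alt)  # rarer allele count
    if n_alt == 0:
        return 1.0

    def log_prob(het):
        if (n_alt - het) % 2 or het > n_alt or (n_alt - het) // 2 + het + (n - (n_alt + het) // 2 - (n_alt - het) // 2) < 0:
            return -np.inf
        hom_rare = (n_alt - het) // 2
        hom_common = n - het - hom_rare
        if hom_common < 0:
            return -np.inf
        from scipy.special import gammaln

        return (
            het * np.log(2)
            + gammaln(n + 1) - gammaln(het + 1) - gammaln(hom_rare + 1) - gammaln(hom_common + 1)
            - (gammaln(2 * n + 1) - gammaln(n_alt + 1) - gammaln(2 * n - n_alt + 1))
        )

    het_obs = n_het
    hets = [h for h in range(n_alt % 2, n_alt + 1, 2)]
    logps = np.array([log_prob(h) for h in hets])
    probs = np.exp(logps - logps.max())
    probs /= probs.sum()
    p_obs = probs[hets.index(het_obs)]
    return float(probs[probs <= p_obs + 1e-12].sum())


def hwe_scan(cohort, exact: bool = False) -> pd.DataFrame:
    """HWE test for every variant in a cohort (missing genotypes excluded)."""
    rows = []
    for vid in cohort.dosages.columns:
        d = cohort.dosages[vid].dropna()
        c = [(d == g).sum() for g in (0, 1, 2)]
        res = hwe_test(*c, variant_id=vid)
        row = {
            "variant_id": vid,
            "n_hom_ref": c[0],
            "n_het": c[1],
            "n_hom_alt": c[2],
            "af_alt": res.allele_freq_alt,
            "chi2": res.chi2,
            "p": res.p,
            "in_equilibrium": res.in_equilibrium,
        }
        if exact:
            row["p_exact"] = hwe_exact_test(*c)
        rows.append(row)
    return pd.DataFrame(rows)


def compare_reference_af(
    cohort_af: float, ref_af: float, n_cohort: int, n_ref: int
) -> tuple[float, float, int]:
    """Yates-corrected chi-square comparing cohort vs reference allele counts.

    Allele counts are 2n per group (each diploid subject contributes two
    alleles).  Returns (chi2, p, direction) with direction the sign of
    cohort_af - ref_af.
    """
    a1 = round(2 * n_cohort * cohort_af)
    a2 = 2 * n_cohort - a1
    b1 = round(2 * n_ref * ref_af)
    b2 = 2 * n_ref - b1
    table = np.array([[a1, a2], [b1, b2]])
    direction = int(np.sign(cohort_af - ref_af))
    if table[:, 0].sum() == 0 or table[:, 1].sum() == 0:
        return 0.0, 1.0, direction
    chi2, p, _, _ = stats.chi2_contingency(table, correction=True)
    return float(chi2), float(p), direction


def compare_reference_af_scan(cohort, ref_af: pd.Series) -> pd.DataFrame:
    """Per-variant Yates comparison of cohort vs reference allele frequency.

    ``ref_af`` carries the reference frequencies; a companion ``n_ref`` of
    5000 subjects is assumed unless the Series has an ``n_ref`` attribute.
    """
    n_ref = getattr(ref_af, "n_ref", 5000)
    afs = allele_frequencies(cohort)
    rows = []
    for vid, af in afs.items():
        if vid not in ref_af.index:
            continue
        n = int(cohort.dosages[vid].notna().sum())
        chi2, p, direction = compare_reference_af(float(af), float(ref_af[vid]), n, n_ref)
        rows.append(
            {"variant_id": vid, "cohort_af": float(af), "ref_af": float(ref_af[vid]),
             "chi2_yates": chi2, "p": p, "direction": direction,
             "significant": p < 0.05}
        )
    return pd.DataFrame(rows)


def em_haplotype_frequencies(
    dos_a: np.ndarray, dos_b: np.ndarray, max_iter: int = 100, tol: float = 1e-10
) -> np.ndarray:
    """EM estimate of the four haplotype frequencies (AB, Ab, aB, ab) from
    unphased two-locus genotypes, where allele 'a'/'b' denote the alternate
    alleles.

    Only double heterozygotes are phase-ambiguous; their cis/trans split is
    re-estimated each iteration from current haplotype frequencies.  Starts
    from the uniform distribution; stops after ``max_iter`` iterations or
    when the largest frequency change drops below ``tol``.
    """
    mask = ~(np.isnan(dos_a) | np.isnan(dos_b))
    a = dos_a[mask].astype(int)
    b = dos_b[mask].astype(int)
    n = len(a)
    if n == 0:
        raise ValueError("no complete genotype pairs")

    # haplotype order: 0 = RefRef, 1 = RefAlt, 2 = AltRef, 3 = AltAlt
    # counts contributed unambiguously by each genotype combination
    joint = np.zeros((3, 3))
    for ga, gb in zip(a, b):
        joint[ga, gb] += 1

    f = np.full(4, 0.25)
    base = np.zeros(4)
    # unambiguous haplotype counts (everything except double hets)
    contrib = {
        (0, 0): {0: 2}, (0, 1): {0: 1, 1: 1}, (0, 2): {1: 2},
        (1, 0): {0: 1, 2: 1}, (1, 2): {1: 1, 3: 1},
        (2, 0): {2: 2}, (2, 1): {2: 1, 3: 1}, (2, 2): {3: 2},
    }
    for (ga, gb), hap_counts in contrib.items():
        for h, c in hap_counts.items():
            base[h] += c * joint[ga, gb]
    n_dh = joint[1, 1]  # double heterozygotes: cis (0,3) or trans (1,2)

    for _ in range(max_iter):
        p_cis = f[0] * f[3]
        p_trans = f[1] * f[2]
        denom = p_cis + p_trans
        w = 0.5 if denom == 0 else p_cis / denom
        counts = base.copy()
        counts[0] += w * n_dh
        counts[3] += w * n_dh
        counts[1] += (1 - w) * n_dh
        counts[2] += (1 - w) * n_dh
        new_f = counts / (2 * n)
        if np.max(np.abs(new_f - f)) < tol:
            f = new_f
            break
        f = new_f
    return f


def ld_pair(dos_a: np.ndarray, dos_b: np.ndarray, id_a: str = "A", id_b: str = "B") -> LDResult:
    """D, D' and r^2 for one variant pair from EM haplotype frequencies.

    A monomorphic member leaves LD undefined (None fields).
    """
    mask = ~(np.isnan(dos_a) | np.isnan(dos_b))
    a = np.asarray(dos_a, float)[mask]
    b = np.asarray(dos_b, float)[mask]
    pa = a.sum() / (2 * len(a))
    pb = b.sum() / (2 * len(b))
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        return LDResult(id_a, id_b, None, None, None)
    f = em_haplotype_frequencies(a, b)
    p_ab = f[3]  # Alt-Alt haplotype
    d = p_ab - pa * pb
    if d >= 0:
        dmax = min(pa * (1 - pb), (1 - pa) * pb)
    else:
        dmax = min(pa * pb, (1 - pa) * (1 - pb))
    d_prime = d / dmax if dmax > 0 else 0.0
    r2 = d * d / (pa * (1 - pa) * pb * (1 - pb))
    return LDResult(id_a, id_b, float(d), float(d_prime), float(min(r2, 1.0)))


def ld_pairwise(cohort, pairs=None) -> list[LDResult]:
    """Pairwise LD for the given variant-id pairs (default: all pairs)."""
    ids = list(cohort.dosages.columns)
    if pairs is None:
        pairs = list(itertools.combinations(ids, 2))
    out = []
    for ida, idb in pairs:
        out.append(
            ld_pair(
                cohort.dosages[ida].to_numpy(float),
                cohort.dosages[idb].to_numpy(float),
                ida,
                idb,
            )
        )
    return out
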