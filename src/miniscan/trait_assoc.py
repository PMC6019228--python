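"""Genotype-phenotype association for candidate body-size loci.

Single-locus fits treat genotype as a categorical factor in a one-way
fixed-effects linear model and report R², F, p and least-squares means
(here: class means with pooled-residual standard errors).  The joint model
regresses the trait on per-locus allele counts (additive terms), optionally
with heterozygote-indicator dominance terms, and summarises the multi-locus
architecture as the total trait difference between the all-mutant and
all-wild-type homozygotes, 2·Σa_k.  Inter-locus linkage is measured as the
squared Pearson correlation of allele counts, and the miniature-size
classifier encodes the synergistic genotype rule: all four loci homozygous
mutant, or three homozygous mutant and the fourth heterozygous.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .genomics_io import TraitRecord


@dataclass
class GlmResult:
    locus: str
    r_square: float
    f_value: float
    p_value: float
    lsmeans: Dict[int, float]  # genotype code -> least-squares mean
    lsmean_se: Dict[int, float]
    n: int


@dataclass
class JointModel:
    loci: List[str]
    intercept: float
    additive_cm: Dict[str, float]
    additive_se: Dict[str, float]
    additive_p: Dict[str, float]
    dominance_cm: Dict[str, float]
    r_square: float
    n: int

    @property
    def total_reduction_cm(self) -> float:
        """Trait span between all-hom-wild-type and all-hom-mutant:
        |2 * sum of additive effects|."""
        return abs(2.0 * sum(self.additive_cm.values()))


def _trait_value(record: TraitRecord, trait: str) -> Optional[float]:
    if trait == "height":
        return record.height_cm
    if trait == "cannon":
        return record.cannon_cm
    raise ValueError(f"unknown trait {trait!r}")


def fit_single_locus(
    records: Sequence[TraitRecord], locus: str, trait: str = "height"
) -> GlmResult:
    """One-way fixed-effects linear model trait ~ genotype (categorical).

    Missing genotypes and missing trait values are dropped.  R² is
    SS_model/SS_total; F has (k-1, n-k) degrees of freedom; least-squares
    means are the class means, with SE = s*sqrt(1/n_class) from the pooled
    residual standard deviation s.
    """
    pairs = []
    for r in records:
        y = _trait_value(r, trait)
        g = r.genotypes.get(locus, -1)
        if y is not None and g != -1:
            pairs.append((g, y))
    if len(pairs) < 3:
        raise ValueError(f"need >= 3 records with data at {locus}")
    g = np.array([p[0] for p in pairs])
    y = np.array([p[1] for p in pairs])
    classes = np.unique(g)
    if len(classes) < 2:
        raise ValueError(f"no variance in genotype at {locus}")
    n, k = len(y), len(classes)
    grand = y.mean()
    ss_total = float(((y - grand) ** 2).sum())
    means = {int(c): float(y[g == c].mean()) for c in classes}
    fitted = np.array([means[int(c)] for c in g])
    ss_resid = float(((y - fitted) ** 2).sum())
    ss_model = ss_total - ss_resid
    r2 = ss_model / ss_total if ss_total > 0 else 0.0
    df_model, df_resid = k - 1, n - k
    if ss_resid <= 1e-12 * max(ss_total, 1.0):
        f_value, p_value = np.inf, 0.0
        s = 0.0
    else:
        ms_model = ss_model / df_model
        ms_resid = ss_resid / df_resid
        f_value = ms_model / ms_resid
        p_value = float(stats.f.sf(f_value, df_model, df_resid))
        s = float(np.sqrt(ms_resid))
    ses = {int(c): s * float(np.sqrt(1.0 / (g == c).sum())) for c in classes}
    return GlmResult(
        locus=locus,
        r_square=float(r2),
        f_value=float(f_value),
        p_value=float(p_value),
        lsmeans=means,
        lsmean_se=ses,
        n=n,
    )


def fit_joint_additive(
    records: Sequence[TraitRecord],
    loci: Sequence[str],
    trait: str = "height",
    dominance_for: Sequence[str] = (),
) -> JointModel:
    """OLS of trait on per-locus allele counts, plus heterozygote-indicator
    dominance terms for the listed loci.

    Raises on rank deficiency (collinear loci are named).
    """
    import statsmodels.api as sm

    loci = list(loci)
    if len(loci) < 1:
        raise ValueError("need at least one locus")
    dominance_for = [l for l in dominance_for if l in loci]
    rows, ys = [], []
    for r in records:
        y = _trait_value(r, trait)
        codes = [r.genotypes.get(l, -1) for l in loci]
        if y is None or any(c == -1 for c in codes):
            continue
        row = list(codes) + [1.0 if r.genotypes[l] == 1 else 0.0 for l in dominance_for]
        rows.append(row)
        ys.append(y)
    X = np.asarray(rows, dtype=float)
    y = np.asarray(ys, dtype=float)
    if len(y) <= X.shape[1] + 1:
        raise ValueError("too few complete records for the design")
    Xc = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
        # name the offending additive columns
        bad = []
        for j, name in enumerate(loci):
            others = np.delete(Xc, 1 + j, axis=1)
            if np.linalg.matrix_rank(others) == np.linalg.matrix_rank(Xc):
                bad.append(name)
        raise ValueError(f"design matrix rank deficient; collinear loci: {bad or loci}")
    fit = sm.OLS(y, Xc).fit()
    params = fit.params
    bse = fit.bse
    pvals = fit.pvalues
    additive = {l: float(params[1 + j]) for j, l in enumerate(loci)}
    additive_se = {l: float(bse[1 + j]) for j, l in enumerate(loci)}
    additive_p = {l: float(pvals[1 + j]) for j, l in enumerate(loci)}
    dominance = {
        l: float(params[1 + len(loci) + j]) for j, l in enumerate(dominance_for)
    }
    return JointModel(
        loci=loci,
        intercept=float(params[0]),
        additive_cm=additive,
        additive_se=additive_se,
        additive_p=additive_p,
        dominance_cm=dominance,
        r_square=float(fit.rsquared),
        n=len(y),
    )


def ld_r2(
    records: Sequence[TraitRecord], locus_a: str, locus_b: str
) -> Optional[float]:
    """Squared Pearson correlation of allele counts at two loci over samples
    complete at both.  None when either locus is monomorphic."""
    a, b = [], []
    for r in records:
        ga = r.genotypes.get(locus_a, -1)
        gb = r.genotypes.get(locus_b, -1)
        if ga != -1 and gb != -1:
            a.append(ga)
            b.append(gb)
    if len(a) < 2:
        raise ValueError("need >= 2 samples complete at both loci")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.std() == 0 or b.std() == 0:
        return None
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def miniature_classifier(codes: Sequence[int]) -> bool:
    """Synergistic four-locus miniature rule: all four homozygous mutant, or
    three homozygous mutant and one heterozygous."""
    codes = list(codes)
    if len(codes) != 4:
        raise ValueError("classifier needs exactly 4 genotype codes")
    if any(c not in (0, 1, 2) for c in codes):
        raise ValueError(f"missing or invalid genotype code in {codes}")
    n_hom = sum(c == 2 for c in codes)
    n_het = sum(c == 1 for c in codes)
    return n_hom == 4 or (n_hom == 3 and n_het == 1)


def ceiling_check(
    records: Sequence[TraitRecord],
    loci: Sequence[str],
    classifier: Callable[[Sequence[int]], bool] = miniature_classifier,
    ceiling_cm: float = 87.0,
) -> List[TraitRecord]:
    """Records the classifier marks as miniature whose height exceeds the
    ceiling.  An empty list means the size-ceiling claim holds."""
    violations = []
    for r in records:
        codes = [r.genotypes.get(l, -1) for l in loci]
        if any(c == -1 for c in codes) or r.height_cm is None:
            continue
        if classifier(codes) and r.height_cm > ceiling_cm:
            violations.append(r)
    return violations
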