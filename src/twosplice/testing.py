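"""Screening and confirmatory tests with gene-level OFDR control.

The testing framework is hierarchical.  A gene-level *screening* test asks
whether anything at all differs across conditions:

* Type 1 (differential expression or splicing): H0: beta_j^C = beta_jl^IC = 0,
  a likelihood-ratio test of the full model against the isoform-only model,
  with (J-1)*L degrees of freedom;
* Type 2 (differential splicing only): H0: beta_jl^IC = 0, full model against
  the additive model, with (J-1)*(L-1) degrees of freedom.

For genes passing the screen, per-isoform *confirmatory* tests of
H0: beta_j^C - beta_1^C + beta_jl^IC - beta_1l^IC = 0 (j = 2..J) ask which
isoforms are differentially expressed, via a Wald contrast on the mixed-model
fit or a simple t-test / one-way ANOVA.

The two-step procedure controls the overall false discovery rate (OFDR),
E[V/R], where R genes are discovered and V of them carry at least one
incorrectly rejected null: BH at level alpha on the M screening p-values,
then for each of the R passing genes a per-gene FWER adjustment
(Bonferroni, Holm, or Hochberg) of its L confirmatory tests at the reduced
level R*alpha/M.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .data_io import GeneData
from .mixed_model import FittedGeneModel, n_fixed_params

logger = logging.getLogger("twosplice")

__all__ = [
    "ScreeningResult",
    "ConfirmatoryResult",
    "TwoStepResult",
    "FWER_METHODS",
    "lrt_screening",
    "wald_isoform_test",
    "simple_isoform_test",
    "adjust_bh",
    "adjust_fwer",
    "two_step_decisions",
    "two_step_procedure",
    "signed_fold_change",
    "screening_frame",
    "confirmatory_frame",
]

FWER_METHODS = ("bonferroni", "holm", "hochberg")


@dataclass
class ScreeningResult:
    gene_id: str
    test_type: str  # "type1" | "type2"
    statistic: float
    df: int
    pvalue: float  # NaN when either fit failed to converge
    fdr: float | None = None
    passed: bool | None = None


@dataclass
class ConfirmatoryResult:
    gene_id: str
    isoform_id: str
    method: str  # "wald" | "ttest" | "anova"
    statistic: float
    df: float
    pvalue: float
    threshold: float | None = None
    rejected: bool | None = None
    fold_change: float = np.nan


@dataclass
class TwoStepResult:
    """Joint outcome of the screening and confirmatory stages."""

    alpha: float
    M: int  # screened genes entering BH (non-missing p-values)
    R: int  # genes passing screening
    fwer_method: str
    confirm_level: float  # R * alpha / M
    screening: list[ScreeningResult] = field(default_factory=list)
    confirmatory: dict[str, list[ConfirmatoryResult]] = field(default_factory=dict)


def signed_fold_change(log_diff: float) -> float:
    """Fold change on the raw scale with the sign carrying direction.

    exp(d) for d >= 0, -exp(-d) for d < 0, so |fold change| >= 1 and a value
    of -14.65 means 14.65-fold *down* in the non-reference condition.
    """
    d = float(log_diff)
    return float(np.exp(d)) if d >= 0 else float(-np.exp(-d))


def lrt_screening(fit_full: FittedGeneModel, fit_null: FittedGeneModel) -> ScreeningResult:
    """Likelihood-ratio screening test of nested fixed-effect structures.

    Statistic 2*(l_full - l_null) (clipped at 0) against chi-square with
    df equal to the difference in free fixed-effect counts.  If either fit
    did not converge the p-value is NaN and the gene is later excluded from
    the BH stage.
    """
    if fit_full.gene_id != fit_null.gene_id:
        raise ValueError(f"fits are for different genes: {fit_full.gene_id} vs {fit_null.gene_id}")
    if fit_full.structure != fit_null.structure:
        raise ValueError("screening LRT requires the same covariance structure in both fits")
    if fit_full.form != "full" or fit_null.form not in ("null_type1", "null_type2"):
        raise ValueError(f"need a full fit and a null fit, got {fit_full.form!r} vs {fit_null.form!r}")
    J, L = fit_full.J, fit_full.L
    test_type = "type1" if fit_null.form == "null_type1" else "type2"
    df = n_fixed_params("full", J, L) - n_fixed_params(fit_null.form, J, L)
    if not (fit_full.converged and fit_null.converged):
        logger.warning("gene %s: non-convergent fit, screening p-value set to missing", fit_full.gene_id)
        return ScreeningResult(fit_full.gene_id, test_type, np.nan, df, np.nan)
    stat = max(2.0 * (fit_full.loglik - fit_null.loglik), 0.0)
    p = float(stats.chi2.sf(stat, df))
    return ScreeningResult(fit_full.gene_id, test_type, stat, df, p)


def _contrast_matrix(J: int, L: int, isoform_index: int) -> np.ndarray:
    """Rows j-1 select beta_j^C + beta_jl^IC (interaction absent for l = 1)."""
    p = n_fixed_params("full", J, L)
    C = np.zeros((J - 1, p))
    l = isoform_index + 1  # 1-based isoform label
    for j in range(2, J + 1):
        C[j - 2, 1 + (j - 2)] = 1.0  # beta_j^C
        if l >= 2:
            C[j - 2, J + L - 1 + (j - 2) * (L - 1) + (l - 2)] = 1.0  # beta_jl^IC
    return C


def wald_isoform_test(fit_full: FittedGeneModel, isoform_index: int) -> ConfirmatoryResult:
    """Wald chi-square contrast for differential expression of one isoform.

    Uses the plug-in covariance of the fixed-effect estimates with a
    chi-square(J-1) reference; anticonservative at small sample sizes.
    """
    if fit_full.form != "full":
        raise ValueError("Wald isoform test requires the full-model fit")
    J, L = fit_full.J, fit_full.L
    if not 0 <= isoform_index < L:
        raise IndexError(f"isoform_index {isoform_index} out of range for L={L}")
    C = _contrast_matrix(J, L, isoform_index)
    est = C @ fit_full.beta
    V = C @ fit_full.cov_beta @ C.T
    try:
        stat = float(est @ np.linalg.solve(V, est))
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"gene {fit_full.gene_id}: singular contrast covariance") from exc
    stat = max(stat, 0.0)
    p = float(stats.chi2.sf(stat, J - 1))
    fc = signed_fold_change(est[0]) if J == 2 else np.nan
    iso = fit_full.isoform_ids[isoform_index] if fit_full.isoform_ids else str(isoform_index)
    return ConfirmatoryResult(fit_full.gene_id, iso, "wald", stat, J - 1, p, fold_change=fc)


def simple_isoform_test(gene: GeneData, isoform_index: int, variant: str = "ttest") -> ConfirmatoryResult:
    """Per-isoform Welch t-test (J = 2) or one-way ANOVA on log abundances."""
    if variant not in ("ttest", "anova"):
        raise ValueError(f"unknown variant {variant!r}")
    if variant == "ttest" and gene.J != 2:
        raise ValueError("t-test confirmatory requires exactly two conditions; use anova")
    if any(k < 2 for k in gene.K):
        raise ValueError(f"gene {gene.gene_id}: every condition needs >= 2 samples")
    groups = [a[:, isoform_index] for a in gene.y]
    if variant == "ttest":
        res = stats.ttest_ind(groups[1], groups[0], equal_var=False)
        stat, p, df = float(res.statistic), float(res.pvalue), float(res.df)
    else:
        res = stats.f_oneway(*groups)
        stat, p, df = float(res.statistic), float(res.pvalue), float(gene.J - 1)
    if not np.isfinite(stat):  # zero variance in both groups, equal means
        stat, p = 0.0, 1.0
    fc = signed_fold_change(groups[1].mean() - groups[0].mean()) if gene.J == 2 else np.nan
    return ConfirmatoryResult(gene.gene_id, gene.isoform_ids[isoform_index], variant, stat, df, p, fold_change=fc)


def adjust_bh(pvalues, alpha: float = 0.05):
    """Benjamini-Hochberg step-up over the non-missing p-values.

    Returns ``(qvalues, reject)``: the monotone BH-adjusted values and the
    step-up rejection set (reject all p <= p_(k*), k* the largest k with
    p_(k) <= k*alpha/M).  NaN entries are excluded from M, get NaN adjusted
    values, and are never rejected.
    """
    if not (0 < alpha < 1):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    p = np.asarray(pvalues, dtype=float)
    ok = ~np.isnan(p)
    m = int(ok.sum())
    q = np.full(p.shape, np.nan)
    reject = np.zeros(p.shape, dtype=bool)
    if m == 0:
        return q, reject
    ps = p[ok]
    order = np.argsort(ps, kind="stable")
    ranked = ps[order]
    qv = ranked * m / np.arange(1, m + 1)
    qv = np.minimum(np.minimum.accumulate(qv[::-1])[::-1], 1.0)
    qs = np.empty(m)
    qs[order] = qv
    passes = ranked <= np.arange(1, m + 1) * alpha / m
    if passes.any():
        cutoff = ranked[int(np.flatnonzero(passes)[-1])]
        rej = ps <= cutoff
    else:
        rej = np.zeros(m, dtype=bool)
    q[ok] = qs
    reject[ok] = rej
    return q, reject


def adjust_fwer(pvalues, method: str = "hochberg", level: float = 0.05, return_thresholds: bool = False):
    """Family-wise error rate control over one gene's L confirmatory p-values.

    Bonferroni compares every p to level/L; Holm is the step-down and
    Hochberg the step-up variant with rank-k threshold level/(L-k+1).
    NaN p-values are treated as 1 (never rejected).
    """
    if method not in FWER_METHODS:
        raise ValueError(f"unknown FWER method {method!r}; choose from {FWER_METHODS}")
    if not (0 < level < 1):
        raise ValueError(f"level must be in (0, 1), got {level}")
    p = np.asarray(pvalues, dtype=float)
    p = np.where(np.isnan(p), 1.0, p)
    L = len(p)
    if L == 0:
        out = np.zeros(0, dtype=bool)
        return (out, np.zeros(0)) if return_thresholds else out
    if method == "bonferroni":
        thr = np.full(L, level / L)
        reject = p <= thr
    else:
        order = np.argsort(p, kind="stable")
        ranked = p[order]
        steps = level / (L - np.arange(L))  # rank k (0-based): level/(L-k)
        reject = np.zeros(L, dtype=bool)
        if method == "holm":
            fail = np.flatnonzero(ranked > steps)
            k = int(fail[0]) if fail.size else L
            reject[order[:k]] = True
        else:  # hochberg
            passes = np.flatnonzero(ranked <= steps)
            if passes.size:
                cutoff = ranked[int(passes[-1])]
                reject = p <= cutoff
        thr = np.empty(L)
        thr[order] = steps
    return (reject, thr) if return_thresholds else reject


def two_step_decisions(screening_pvalues, confirmatory_pvalues, alpha: float = 0.05, method: str = "hochberg"):
    """Array core of the two-step OFDR procedure.

    ``confirmatory_pvalues`` is a per-gene sequence of length-L p-value
    arrays.  Returns ``(fdr, passed, rejections, R, M, level)`` where
    ``rejections[i]`` is the boolean confirmatory decision vector of gene i
    (all False for genes failing the screen) and level = R*alpha/M.
    """
    p = np.asarray(screening_pvalues, dtype=float)
    fdr, passed = adjust_bh(p, alpha)
    M = int((~np.isnan(p)).sum())
    R = int(passed.sum())
    level = R * alpha / M if M else 0.0
    rejections = []
    for i in range(len(p)):
        cp = np.asarray(confirmatory_pvalues[i], dtype=float)
        if passed[i] and level > 0:
            rejections.append(adjust_fwer(cp, method, level))
        else:
            rejections.append(np.zeros(len(cp), dtype=bool))
    return fdr, passed, rejections, R, M, level


def two_step_procedure(
    screening: list[ScreeningResult],
    confirmatory: dict[str, list[ConfirmatoryResult]],
    alpha: float = 0.05,
    method: str = "hochberg",
) -> TwoStepResult:
    """Run BH screening then per-gene FWER confirmation at level R*alpha/M.

    ``confirmatory`` maps every gene that can pass screening to its L
    per-isoform results (p-values computed up front; decisions are only
    recorded for passing genes).  Screening results are annotated in place
    with their BH-adjusted FDR and pass flag.
    """
    n_missing = sum(1 for s in screening if np.isnan(s.pvalue))
    if n_missing:
        logger.info("two_step_procedure: %d gene(s) with missing screening p-values excluded from BH", n_missing)
    p = np.array([s.pvalue for s in screening], dtype=float)
    fdr, passed = adjust_bh(p, alpha)
    M = int((~np.isnan(p)).sum())
    R = int(passed.sum())
    level = R * alpha / M if M else 0.0
    out_confirm: dict[str, list[ConfirmatoryResult]] = {}
    for s, f, ok in zip(screening, fdr, passed):
        s.fdr = float(f) if not np.isnan(f) else None
        s.passed = bool(ok)
        if not ok:
            continue
        results = confirmatory.get(s.gene_id)
        if results is None:
            raise ValueError(f"gene {s.gene_id} passed screening but has no confirmatory p-values")
        cp = np.array([r.pvalue for r in results], dtype=float)
        if level > 0:
            reject, thr = adjust_fwer(cp, method, level, return_thresholds=True)
        else:
            reject, thr = np.zeros(len(cp), dtype=bool), np.full(len(cp), 0.0)
        for r, rej, t in zip(results, reject, thr):
            r.rejected = bool(rej)
            r.threshold = float(t)
        out_confirm[s.gene_id] = results
    return TwoStepResult(alpha, M, R, method, level, screening, out_confirm)


def screening_frame(screening: list[ScreeningResult]):
    """Screening results as a tidy table (gene_id, type, LRT, df, p, FDR, passed)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "gene_id": [s.gene_id for s in screening],
            "test_type": [s.test_type for s in screening],
            "lrt_statistic": [s.statistic for s in screening],
            "df": [s.df for s in screening],
            "pvalue": [s.pvalue for s in screening],
            "fdr": [s.fdr for s in screening],
            "passed": [s.passed for s in screening],
        }
    )


def confirmatory_frame(confirmatory: dict[str, list[ConfirmatoryResult]]):
    """Confirmatory results for passing genes as a tidy table."""
    import pandas as pd

    rows = [r for results in confirmatory.values() for r in results]
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in rows],
            "isoform_id": [r.isoform_id for r in rows],
            "method": [r.method for r in rows],
            "statistic": [r.statistic for r in rows],
            "df": [r.df for r in rows],
            "pvalue": [r.pvalue for r in rows],
            "threshold": [r.threshold for r in rows],
            "rejected": [r.rejected for r in rows],
            "fold_change": [r.fold_change for r in rows],
        }
    )
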