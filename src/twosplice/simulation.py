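"""Simulation engine for OFDR and power evaluation of the two-step procedure.

Datasets are generated gene by gene from the split-plot mixed model: a
*template* parameter set (fixed effects plus unequal-variance covariance for
a full and a reduced model, as fitted to one real gene or taken from a
built-in fixture) seeds M genes per dataset.  m0 of them are null-hypothesis
genes (NHGs), drawn from the reduced model; the rest are false-null genes
(FNHGs), half *full* (every isoform differentially expressed) and half
*partial* (the trailing floor((L+1)/2)+1..L isoforms forced exactly null by
setting beta_2l^IC = -beta_2^C).  FNHG condition and interaction effects are
drawn uniformly from effect-size intervals around the template estimates b:
[0, b], [b/2, 3b/2] or [b, 2b] for the small/medium/large scenarios
(mirrored when b < 0).

Each replicate is analyzed with the two-step procedure (Type 1 LRT screen,
Wald or t-test confirmation, Bonferroni/Holm/Hochberg FWER adjustment) and
with the simple-BH comparator (isoform-by-isoform Welch t-tests, BH over all
M*L p-values, a gene "discovered" when any of its isoforms is rejected).
Reported metrics per method: OFDR = mean V/R (0 when R = 0), power(I) = the
proportion of truly differential isoforms rejected, and power(II) = the
proportion of FNHGs that pass screening with every isoform decision correct.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import GeneData
from .mixed_model import (
    OptimizerSettings,
    build_covariance,
    build_design_matrix,
    fit_gene_model,
)
from .testing import (
    FWER_METHODS,
    adjust_bh,
    lrt_screening,
    two_step_decisions,
    wald_isoform_test,
)

logger = logging.getLogger("twosplice")

__all__ = [
    "TemplateParams",
    "SimulationConfig",
    "TruthTable",
    "DecisionSet",
    "ReplicateMetrics",
    "MethodSummary",
    "SimulationSummary",
    "template_fixture",
    "estimate_template",
    "draw_effect_sizes",
    "make_partial_fnhg",
    "simulate_dataset",
    "simple_bh_comparator",
    "evaluate_replicate",
    "run_simulation_study",
]

EFFECT_SCENARIOS = ("small", "medium", "large")


@dataclass(frozen=True)
class TemplateParams:
    """Full- and reduced-model parameters of a template gene (J = 2).

    ``full_beta`` has the 2L entries (b^G, b_2^C, b_2^I..b_L^I,
    b_22^IC..b_2L^IC) in design-column order; ``reduced_beta`` the L entries
    (b^G, b_2^I..b_L^I).  Variance parameters are unequal-variance:
    (sigma_1^2..sigma_L^2, sigma_rho^2).
    """

    L: int
    full_beta: np.ndarray
    reduced_beta: np.ndarray
    full_var: np.ndarray
    reduced_var: np.ndarray
    structure: str = "unequal_variance"
    source: str = "fixture"

    def __post_init__(self) -> None:
        object.__setattr__(self, "full_beta", np.asarray(self.full_beta, dtype=float))
        object.__setattr__(self, "reduced_beta", np.asarray(self.reduced_beta, dtype=float))
        object.__setattr__(self, "full_var", np.asarray(self.full_var, dtype=float))
        object.__setattr__(self, "reduced_var", np.asarray(self.reduced_var, dtype=float))
        if len(self.full_beta) != 2 * self.L:
            raise ValueError(f"full model needs 2L = {2 * self.L} fixed effects, got {len(self.full_beta)}")
        if len(self.reduced_beta) != self.L:
            raise ValueError(f"reduced model needs L = {self.L} fixed effects, got {len(self.reduced_beta)}")
        for v in (self.full_var, self.reduced_var):
            build_covariance(v, self.structure, self.L)  # validates


# Synthetic template fixtures with log-FPKM-scale magnitudes for genes with
# 5, 7 and 11 isoforms.  They are stand-ins for templates fitted to real
# tumor RNA-seq genes (use estimate_template on your own data for those);
# the L = 7 set carries the weakest condition effects of the three.
_FIXTURES: dict[int, dict] = {
    5: dict(
        full_beta=[3.0, 0.5, -0.4, -1.0, -1.8, -2.5, 0.4, -0.7, 0.6, -0.5],
        reduced_beta=[3.1, -0.4, -1.0, -1.8, -2.5],
        full_var=[0.35, 0.45, 0.60, 0.80, 0.90, 0.15],
        reduced_var=[0.40, 0.50, 0.65, 0.85, 0.95, 0.16],
    ),
    7: dict(
        full_beta=[2.0, 0.35, -0.3, -0.6, -0.9, -1.3, -1.7, -2.2,
                   0.30, -0.45, 0.35, -0.30, 0.40, -0.35],
        reduced_beta=[2.1, -0.3, -0.6, -0.9, -1.3, -1.7, -2.2],
        full_var=[0.40, 0.50, 0.55, 0.65, 0.75, 0.90, 1.00, 0.12],
        reduced_var=[0.45, 0.55, 0.60, 0.70, 0.80, 0.95, 1.05, 0.13],
    ),
    11: dict(
        full_beta=[1.5, 0.6, -0.2, -0.4, -0.55, -0.75, -0.95, -1.2, -1.45, -1.7, -2.0, -2.3,
                   0.50, -0.40, 0.60, -0.45, 0.55, -0.50, 0.60, -0.40, 0.50, -0.55],
        reduced_beta=[1.6, -0.2, -0.4, -0.55, -0.75, -0.95, -1.2, -1.45, -1.7, -2.0, -2.3],
        full_var=[0.30, 0.40, 0.45, 0.55, 0.60, 0.70, 0.75, 0.85, 0.95, 1.05, 1.10, 0.10],
        reduced_var=[0.35, 0.45, 0.50, 0.60, 0.65, 0.75, 0.80, 0.90, 1.00, 1.10, 1.15, 0.11],
    ),
}


def template_fixture(L: int) -> TemplateParams:
    """Built-in synthetic template parameter set for L in {5, 7, 11}."""
    if L not in _FIXTURES:
        raise ValueError(f"no template fixture for L={L}; available: {sorted(_FIXTURES)}")
    f = _FIXTURES[L]
    return TemplateParams(L=L, source="fixture", **f)


def estimate_template(gene: GeneData, settings: OptimizerSettings | None = None) -> TemplateParams:
    """Fit the full and the reduced model to one real gene and wrap the estimates."""
    if gene.J != 2:
        raise ValueError("template estimation requires exactly two conditions")
    fit_full = fit_gene_model(gene, "full", "unequal_variance", settings)
    fit_red = fit_gene_model(gene, "null_type1", "unequal_variance", settings)
    if not (fit_full.converged and fit_red.converged):
        raise RuntimeError(
            f"gene {gene.gene_id}: template fits did not converge; consider a built-in fixture"
        )
    return TemplateParams(
        L=gene.L,
        full_beta=fit_full.beta,
        reduced_beta=fit_red.beta,
        full_var=fit_full.var_params,
        reduced_var=fit_red.var_params,
        source="fitted-from-data",
    )


@dataclass(frozen=True)
class SimulationConfig:
    """One simulation scenario (J = 2 conditions)."""

    M: int = 1000
    m0: int = 500
    n: int = 200
    effect_size: str = "medium"
    replications: int = 100
    alpha: float = 0.05
    template: TemplateParams = field(default_factory=lambda: template_fixture(7))
    fwer_methods: tuple[str, ...] = FWER_METHODS
    confirmatory: str = "wald"  # "wald" | "ttest"
    screening: str = "type1"  # "type1" | "type2"
    structure: str = "unequal_variance"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.m0 <= self.M:
            raise ValueError(f"m0 must be in [0, M], got m0={self.m0}, M={self.M}")
        if (self.M - self.m0) % 2:
            raise ValueError("M - m0 must be even (half full FNHG, half partial FNHG)")
        if self.effect_size not in EFFECT_SCENARIOS:
            raise ValueError(f"effect_size must be one of {EFFECT_SCENARIOS}")
        if self.confirmatory not in ("wald", "ttest"):
            raise ValueError(f"confirmatory must be 'wald' or 'ttest', got {self.confirmatory!r}")
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        bad = [m for m in self.fwer_methods if m not in FWER_METHODS]
        if bad:
            raise ValueError(f"unknown FWER method(s) {bad}")


@dataclass
class TruthTable:
    """Generating truth per gene: class label and per-isoform mean differences."""

    classes: list[str]  # "NHG" | "full_FNHG" | "partial_FNHG"
    diffs: np.ndarray  # (M, L) realized mu_2l - mu_1l
    de: np.ndarray  # (M, L) bool, diff != 0

    @property
    def M(self) -> int:
        return len(self.classes)

    @property
    def is_fnhg(self) -> np.ndarray:
        return np.array([c != "NHG" for c in self.classes])


@dataclass
class DecisionSet:
    """Gene discovery flags and per-isoform rejections, aligned to a TruthTable."""

    discovered: np.ndarray  # (M,) bool
    rejected: np.ndarray  # (M, L) bool


@dataclass
class ReplicateMetrics:
    R: int
    V: int
    n_de: int
    n_de_rejected: int
    n_fnhg: int
    n_fnhg_correct: int

    @property
    def ofdr(self) -> float:
        return self.V / self.R if self.R else 0.0

    @property
    def power1(self) -> float:
        return self.n_de_rejected / self.n_de if self.n_de else np.nan

    @property
    def power2(self) -> float:
        return self.n_fnhg_correct / self.n_fnhg if self.n_fnhg else np.nan


@dataclass
class MethodSummary:
    ofdr: float
    ofdr_se: float
    power1: float
    power1_se: float
    power2: float
    power2_se: float


@dataclass
class SimulationSummary:
    config: SimulationConfig
    methods: dict[str, MethodSummary]
    replicates: dict[str, list[ReplicateMetrics]]
    holm_hochberg_agreement: float = np.nan  # fraction of confirmatory families with identical decisions
    bonferroni_subset_violations: int = 0  # families where Bonferroni rejects outside Holm

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, s in self.methods.items():
            rows.append(
                dict(method=name, m0=self.config.m0, effect_size=self.config.effect_size,
                     ofdr=s.ofdr, ofdr_se=s.ofdr_se, power1=s.power1, power1_se=s.power1_se,
                     power2=s.power2, power2_se=s.power2_se)
            )
        return pd.DataFrame(rows)


def draw_effect_sizes(template: TemplateParams, scenario: str, rng: np.random.Generator) -> np.ndarray:
    """Draw one full-FNHG fixed-effect vector from the effect-size intervals.

    Only beta_2^C and the interactions beta_22^IC..beta_2L^IC are drawn; the
    baseline and isoform effects are copied from the template unchanged.  For
    a template estimate b > 0 the small/medium/large intervals are [0, b],
    [b/2, 3b/2] and [b, 2b]; for b < 0 they are mirrored.
    """
    if scenario not in EFFECT_SCENARIOS:
        raise ValueError(f"unknown effect-size scenario {scenario!r}")
    L = template.L
    beta = template.full_beta.copy()
    draw_idx = [1] + list(range(L + 1, 2 * L))  # beta_2^C and the interactions
    for i in draw_idx:
        b = beta[i]
        if b == 0.0:
            logger.warning("template coefficient %d is 0: degenerate effect-size interval", i)
            continue
        a = abs(b)
        if scenario == "small":
            lo, hi = 0.0, a
        elif scenario == "medium":
            lo, hi = a / 2.0, 1.5 * a
        else:
            lo, hi = a, 2.0 * a
        beta[i] = np.sign(b) * rng.uniform(lo, hi)
    return beta


def make_partial_fnhg(effects: np.ndarray, L: int) -> np.ndarray:
    """Force the trailing isoforms of a full-FNHG effect vector exactly null.

    Sets beta_2l^IC = -beta_2^C for l = floor((L+1)/2)+1 .. L, which cancels
    the mean difference mu_2l - mu_1l = beta_2^C + beta_2l^IC for those
    isoforms.
    """
    out = np.asarray(effects, dtype=float).copy()
    b2c = out[1]
    for l in range((L + 1) // 2 + 1, L + 1):
        out[L + 1 + (l - 2)] = -b2c
    return out


def _mean_diffs(beta: np.ndarray, L: int) -> np.ndarray:
    """Realized mu_2l - mu_1l per isoform: beta_2^C, then beta_2^C + beta_2l^IC."""
    d = np.empty(L)
    d[0] = beta[1]
    d[1:] = beta[1] + beta[L + 1 : 2 * L]
    return d


def simulate_dataset(config: SimulationConfig, rng: np.random.Generator | None = None):
    """Generate one dataset of M genes and its generating truth.

    Genes 0..m0-1 are NHGs (reduced-model fixed effects and covariance),
    then (M-m0)/2 full FNHGs and (M-m0)/2 partial FNHGs (drawn effects,
    full-model covariance); n independent sample vectors per condition.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    t = config.template
    L, n = t.L, config.n
    X = build_design_matrix((2, L), "full")
    Sigma_red = build_covariance(t.reduced_var, t.structure, L)
    Sigma_full = build_covariance(t.full_var, t.structure, L)
    chol_red = np.linalg.cholesky(Sigma_red)
    chol_full = np.linalg.cholesky(Sigma_full)
    mu_null = np.concatenate([[t.reduced_beta[0]], t.reduced_beta[0] + t.reduced_beta[1:]])

    n_fnhg = config.M - config.m0
    classes = ["NHG"] * config.m0 + ["full_FNHG"] * (n_fnhg // 2) + ["partial_FNHG"] * (n_fnhg // 2)
    genes: list[GeneData] = []
    diffs = np.zeros((config.M, L))
    iso_ids = [f"iso{l:02d}" for l in range(1, L + 1)]
    for i, cls in enumerate(classes):
        if cls == "NHG":
            mu1 = mu2 = mu_null
            chol = chol_red
        else:
            beta = draw_effect_sizes(t, config.effect_size, rng)
            if cls == "partial_FNHG":
                beta = make_partial_fnhg(beta, L)
            mu1, mu2 = X[0] @ beta, X[1] @ beta
            diffs[i] = _mean_diffs(beta, L)
            chol = chol_full
        y1 = mu1 + rng.standard_normal((n, L)) @ chol.T
        y2 = mu2 + rng.standard_normal((n, L)) @ chol.T
        genes.append(GeneData(f"g{i:04d}", iso_ids, ["c1", "c2"], [y1, y2]))
    truth = TruthTable(classes=classes, diffs=diffs, de=diffs != 0.0)
    return genes, truth


def simple_bh_comparator(genes: list[GeneData], alpha: float = 0.05) -> DecisionSet:
    """Isoform-by-isoform Welch t-tests with one BH correction over all M*L tests.

    A gene is discovered when at least one of its isoforms is rejected; the
    isoform decisions are the BH rejections themselves.
    """
    if any(g.J != 2 for g in genes):
        raise ValueError("simple BH comparator requires exactly two conditions")
    L = genes[0].L
    a1 = np.stack([g.y[0] for g in genes])  # (M, K1, L)
    a2 = np.stack([g.y[1] for g in genes])
    res = stats.ttest_ind(a2, a1, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float).reshape(len(genes), L)
    p = np.where(np.isnan(p), 1.0, p)
    _, reject = adjust_bh(p.ravel(), alpha)
    rejected = reject.reshape(len(genes), L)
    return DecisionSet(discovered=rejected.any(axis=1), rejected=rejected)


def evaluate_replicate(truth: TruthTable, decisions: DecisionSet) -> ReplicateMetrics:
    """Score one replicate's decisions against the generating truth.

    A discovered gene counts toward V when it is an NHG (screening null
    incorrectly rejected) or when any of its truly-null isoforms was
    rejected.  power(I) counts rejected truly-differential isoforms over all
    truly-differential isoforms in the dataset; power(II) counts FNHGs that
    were discovered with every isoform decision correct.
    """
    if decisions.rejected.shape != truth.de.shape:
        raise ValueError(
            f"decision matrix shape {decisions.rejected.shape} does not match truth {truth.de.shape}"
        )
    disc = decisions.discovered
    rej = decisions.rejected
    if (rej & ~disc[:, None]).any():
        raise ValueError("isoform rejections present for undiscovered genes")
    is_nhg = ~truth.is_fnhg
    false_iso = (rej & ~truth.de).any(axis=1)
    V = int((disc & (is_nhg | false_iso)).sum())
    R = int(disc.sum())
    n_de = int(truth.de.sum())
    n_de_rej = int((rej & truth.de).sum())
    fnhg = truth.is_fnhg
    correct = disc & fnhg & (rej == truth.de).all(axis=1)
    return ReplicateMetrics(
        R=R, V=V, n_de=n_de, n_de_rejected=n_de_rej,
        n_fnhg=int(fnhg.sum()), n_fnhg_correct=int(correct.sum()),
    )


def _analyze_replicate(genes, truth, config, settings):
    """Fit every gene, screen, confirm; return per-method DecisionSets."""
    null_form = "null_type1" if config.screening == "type1" else "null_type2"
    screen_p = np.empty(len(genes))
    confirm_p = np.empty((len(genes), config.template.L))
    for i, g in enumerate(genes):
        fit_full = fit_gene_model(g, "full", config.structure, settings)
        fit_null = fit_gene_model(g, null_form, config.structure, settings)
        screen_p[i] = lrt_screening(fit_full, fit_null).pvalue
        if config.confirmatory == "wald":
            confirm_p[i] = [wald_isoform_test(fit_full, l).pvalue for l in range(g.L)]
        else:
            res = stats.ttest_ind(g.y[1], g.y[0], axis=0, equal_var=False)
            confirm_p[i] = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
    out = {}
    for method in config.fwer_methods:
        _, passed, rejections, _, _, _ = two_step_decisions(screen_p, confirm_p, config.alpha, method)
        out[f"twostep_{method}"] = DecisionSet(discovered=passed, rejected=np.array(rejections))
    out["simple_bh"] = simple_bh_comparator(genes, config.alpha)
    return out


def run_simulation_study(config: SimulationConfig, settings: OptimizerSettings | None = None) -> SimulationSummary:
    """Replicate the generate -> fit -> test -> score loop and average metrics.

    Fully reproducible from ``config.seed``: each replicate draws from its
    own deterministically spawned random stream.
    """
    method_names = [f"twostep_{m}" for m in config.fwer_methods] + ["simple_bh"]
    replicates: dict[str, list[ReplicateMetrics]] = {m: [] for m in method_names}
    agree = 0
    families = 0
    bonf_violations = 0
    streams = np.random.SeedSequence(config.seed).spawn(config.replications)
    for rep, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        genes, truth = simulate_dataset(config, rng)
        decisions = _analyze_replicate(genes, truth, config, settings)
        for name in method_names:
            replicates[name].append(evaluate_replicate(truth, decisions[name]))
        if "twostep_holm" in decisions and "twostep_hochberg" in decisions:
            dh, dg = decisions["twostep_holm"], decisions["twostep_hochberg"]
            passing = np.flatnonzero(dh.discovered)
            families += len(passing)
            agree += int((dh.rejected[passing] == dg.rejected[passing]).all(axis=1).sum())
        if "twostep_bonferroni" in decisions and "twostep_holm" in decisions:
            db, dh = decisions["twostep_bonferroni"], decisions["twostep_holm"]
            bonf_violations += int((db.rejected & ~dh.rejected).any(axis=1).sum())
        logger.info("replicate %d/%d done", rep + 1, config.replications)

    methods = {}
    for name, reps in replicates.items():
        ofdr = np.array([r.ofdr for r in reps])
        p1 = np.array([r.power1 for r in reps])
        p2 = np.array([r.power2 for r in reps])
        k = len(reps)
        with np.errstate(invalid="ignore"):
            methods[name] = MethodSummary(
                ofdr=float(ofdr.mean()), ofdr_se=float(ofdr.std(ddof=1) / np.sqrt(k)) if k > 1 else np.nan,
                power1=float(np.nanmean(p1)) if not np.isnan(p1).all() else np.nan,
                power1_se=float(np.nanstd(p1, ddof=1) / np.sqrt(k)) if k > 1 and not np.isnan(p1).all() else np.nan,
                power2=float(np.nanmean(p2)) if not np.isnan(p2).all() else np.nan,
                power2_se=float(np.nanstd(p2, ddof=1) / np.sqrt(k)) if k > 1 and not np.isnan(p2).all() else np.nan,
            )
    return SimulationSummary(
        config=config,
        methods=methods,
        replicates=replicates,
        holm_hochberg_agreement=agree / families if families else np.nan,
        bonferroni_subset_violations=bonf_violations,
    )
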