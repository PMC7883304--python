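"""Statistical inference for the crossover study.

Trial-level outcomes are modelled with linear mixed models (LMMs) carrying a
participant random intercept, which absorbs stable inter-individual
differences.  Two-level factors (stimulus: disgust/neutral, drug:
domperidone/placebo, phase: earlier/later) use sum-to-zero (+1/-1) coding and
the trial index is z-scored; when ``standardize`` is set the outcome is
z-scored too, so reported coefficients are standardized betas.  Inference on
fixed effects is by Wald Z.

Model estimation delegates to :class:`statsmodels` ``MixedLM``, fitted by
maximum likelihood (not REML) so that AIC/BIC are comparable across models
with different fixed effects — required by the null-evidence workflow, which
compares each model against an intercept-only null via Akaike evidence
ratios and BIC Bayes factors.

Also provided: per-trial paired comparisons of disgust vs. neutral dwell
with Holm-Bonferroni step-down correction, post hoc drug-difference models
on post-minus-pre changes, and a Table-1-style null-evidence summary for
control-task measures.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .model_comparison import ComparisonResult, compare_models

__all__ = [
    "ModelSpec",
    "EffectEstimate",
    "MixedModelFit",
    "PosthocResult",
    "InferenceError",
    "fit_mixed_model",
    "fit_with_null",
    "posthoc_drug_difference",
    "per_trial_tests",
    "holm_bonferroni",
    "null_evidence_table",
    "dwell_to_long",
]

_OUTCOME_COLUMNS = {
    "dwell_proportion": "dwell",
    "avoidance_difference": "value",
    "self_report": "rating",
    "rl_parameter_difference": "value",
}

#: canonical phase ordering used to orient the +/-1 phase contrast
_PHASE_RANK = {
    "baseline": 0, "pre_admin": 0,
    "post_admin": 1,
    "pre_incentive": 2, "incentive": 3, "post_incentive": 4,
}

_FACTOR_COLUMNS = {"stimulus": "stimulus", "drug": "visit",
                   "phase": "phase", "trial": "trial"}


class InferenceError(RuntimeError):
    """Mixed-model estimation failed to converge."""


@dataclass(frozen=True)
class ModelSpec:
    """What to model: outcome, fixed factors (fully crossed), coding.

    ``fixed`` lists factor names among {stimulus, drug, phase, trial}; all
    interactions are included.  Trial must not appear for self-report
    outcomes (ratings carry no trial structure).
    """

    outcome: str
    fixed: tuple[str, ...] = ()
    standardize: bool = True
    coding: str = "sum"

    def __post_init__(self) -> None:
        if self.outcome not in _OUTCOME_COLUMNS:
            raise ValueError(f"unknown outcome {self.outcome!r}")
        unknown = set(self.fixed) - set(_FACTOR_COLUMNS)
        if unknown:
            raise ValueError(f"unknown factors: {sorted(unknown)}")
        if self.outcome == "self_report" and "trial" in self.fixed:
            raise ValueError("trial is not a factor for self-report outcomes")
        if self.coding != "sum":
            raise ValueError("only sum-to-zero coding is implemented")

    @property
    def outcome_column(self) -> str:
        return _OUTCOME_COLUMNS[self.outcome]


@dataclass(frozen=True)
class EffectEstimate:
    """One fixed-effect row: standardized beta, 95% CI, Wald Z, p."""

    term: str
    beta: float
    ci_low: float
    ci_high: float
    z: float
    p: float


@dataclass(frozen=True)
class MixedModelFit:
    """Fitted LMM summary: effects plus ML information criteria."""

    effects: tuple[EffectEstimate, ...]
    aic: float
    bic: float
    n_obs: int
    llf: float
    k: int
    singular: bool

    def effect(self, term: str) -> EffectEstimate:
        """Look up an effect by term name, e.g. ``'stimulus:drug:phase'``."""
        for e in self.effects:
            if e.term == term:
                return e
        raise KeyError(f"no term {term!r}; have {[e.term for e in self.effects]}")


def dwell_to_long(dwell: pd.DataFrame) -> pd.DataFrame:
    """Reshape a wide dwell table (p_disgust/p_neutral columns) to trial-level
    rows per stimulus, with the dwell proportion in column ``dwell``."""
    keep = [c for c in ("participant", "visit", "phase", "trial") if c in dwell.columns]
    long = dwell.melt(id_vars=keep, value_vars=["p_disgust", "p_neutral"],
                      var_name="stimulus", value_name="dwell")
    long["stimulus"] = long["stimulus"].map({"p_disgust": "disgust",
                                             "p_neutral": "neutral"})
    return long


def _code_factor(series: pd.Series, name: str) -> pd.Series:
    levels = sorted(series.dropna().unique().tolist())
    if len(levels) != 2:
        raise ValueError(f"factor {name} must have exactly 2 levels, got {levels}")
    if name == "stimulus":
        order = {"neutral": -1.0, "disgust": 1.0}
    elif name == "drug":
        order = {"placebo": -1.0, "domperidone": 1.0}
    elif name == "phase":
        try:
            lo, hi = sorted(levels, key=lambda s: _PHASE_RANK[s])
        except KeyError:
            lo, hi = levels  # unknown labels: alphabetical, earlier negative
        order = {lo: -1.0, hi: 1.0}
    else:  # pragma: no cover
        raise ValueError(name)
    coded = series.map(order)
    if coded.isna().any():
        raise ValueError(f"factor {name} has levels outside {sorted(order)}")
    return coded.astype(float)


def _prepare(data: pd.DataFrame, spec: ModelSpec) -> tuple[pd.DataFrame, str]:
    ycol = spec.outcome_column
    if ycol not in data.columns:
        raise ValueError(f"outcome column {ycol!r} missing from data")
    df = data.copy()
    df["_y"] = df[ycol].astype(float)
    if spec.standardize:
        sd = df["_y"].std(ddof=0)
        if sd > 0:
            df["_y"] = (df["_y"] - df["_y"].mean()) / sd
    terms = []
    for f in spec.fixed:
        col = _FACTOR_COLUMNS[f]
        if col not in df.columns:
            raise ValueError(f"factor column {col!r} missing from data")
        if f == "trial":
            t = df[col].astype(float)
            sd = t.std(ddof=0)
            df["_trial_z"] = (t - t.mean()) / sd if sd > 0 else 0.0
            terms.append("_trial_z")
        else:
            df[f"_{f}_c"] = _code_factor(df[col], f)
            terms.append(f"_{f}_c")
    formula = "_y ~ " + (" * ".join(terms) if terms else "1")
    return df, formula


def fit_mixed_model(data: pd.DataFrame, spec: ModelSpec) -> MixedModelFit:
    """Fit the LMM with a participant random intercept by ML.

    Returns fixed-effect estimates (Wald Z inference) and AIC/BIC computed
    from the ML log-likelihood with ``k`` = number of fixed effects + 2
    variance parameters (random-intercept and residual variance).  A
    near-zero random-intercept variance is reported as ``singular`` (with a
    warning) but the fit is retained.
    """
    if data["participant"].nunique() < 2:
        raise ValueError("need at least 2 participants")
    df, formula = _prepare(data, spec)
    model = smf.mixedlm(formula, df, groups=df["participant"])
    result = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        # statsmodels flags singular RE covariance via UserWarning; we report
        # singularity ourselves on the returned fit
        warnings.simplefilter("ignore", UserWarning)
        # gradient-free fallbacks handle boundary (singular) optima, where
        # the profiled likelihood's gradient methods stall
        for method in ("lbfgs", "nm", "powell", "bfgs", "cg"):
            try:
                cand = model.fit(reml=False, method=method, maxiter=200)
            except (np.linalg.LinAlgError, ValueError):
                continue
            if cand.converged and np.isfinite(cand.llf):
                result = cand
                break
            if result is None and np.isfinite(getattr(cand, "llf", np.nan)):
                result = cand
    if result is None:
        raise InferenceError(f"mixed model failed to converge for {formula!r}")
    if not result.converged:
        raise InferenceError(
            f"mixed model did not converge for {formula!r}; "
            f"llf={result.llf:.3f}, method diagnostics: {result.summary()}")

    singular = float(result.cov_re.iloc[0, 0]) < 1e-8
    if singular:
        warnings.warn("random-intercept variance is ~0 (singular fit retained)",
                      stacklevel=2)
    fe = result.fe_params
    bse = result.bse_fe
    zcrit = stats.norm.ppf(0.975)
    effects = []
    for raw_term in fe.index:
        beta = float(fe[raw_term])
        se = float(bse[raw_term])
        z = beta / se if se > 0 else math.nan
        p = float(2.0 * stats.norm.sf(abs(z))) if np.isfinite(z) else math.nan
        p = min(max(p, np.nextafter(0, 1)), 1.0)
        effects.append(EffectEstimate(
            term=_clean_term(raw_term), beta=beta,
            ci_low=beta - zcrit * se, ci_high=beta + zcrit * se, z=z, p=p))
    k = len(fe) + 2
    n = int(result.nobs)
    llf = float(result.llf)
    return MixedModelFit(effects=tuple(effects), aic=2 * k - 2 * llf,
                         bic=k * math.log(n) - 2 * llf, n_obs=n, llf=llf,
                         k=k, singular=singular)


def _clean_term(raw: str) -> str:
    if raw == "Intercept":
        return "intercept"
    parts = raw.split(":")
    out = []
    for p in parts:
        p = p.strip().removeprefix("_")
        out.append("trial" if p in ("trial_z", "_trial_z") else p.removesuffix("_c"))
    return ":".join(out)


def fit_with_null(data: pd.DataFrame, spec: ModelSpec) -> tuple[MixedModelFit, MixedModelFit, ComparisonResult]:
    """Fit ``spec`` and its intercept-only null (same random structure) and
    compare them: the returned :class:`ComparisonResult` carries ER_0 and
    BF_01 in favour of the null."""
    full = fit_mixed_model(data, spec)
    null = fit_mixed_model(data, ModelSpec(outcome=spec.outcome, fixed=(),
                                           standardize=spec.standardize))
    comp = compare_models(null.aic, full.aic, null.bic, full.bic)
    return full, null, comp


@dataclass(frozen=True)
class PosthocResult:
    """Post hoc drug-effect model on post-minus-pre differences."""

    estimate: EffectEstimate
    comparison: ComparisonResult
    n_obs: int
    full: MixedModelFit = field(repr=False, default=None)  # type: ignore[assignment]
    null: MixedModelFit = field(repr=False, default=None)  # type: ignore[assignment]


def posthoc_drug_difference(data: pd.DataFrame, value_col: str,
                            phase_pair: tuple[str, str],
                            phase_col: str = "phase") -> PosthocResult:
    """Main effect of drug on the later-minus-earlier phase difference.

    Averages ``value_col`` within participant x visit x phase, differences
    the two phases in ``phase_pair`` (second minus first), and fits the
    difference on drug with a participant random intercept; the returned
    comparison scores the drug model against its intercept-only null.
    """
    lo, hi = phase_pair
    cell = (data[data[phase_col].isin(phase_pair)]
            .groupby(["participant", "visit", phase_col])[value_col]
            .mean().unstack(phase_col))
    if lo not in cell.columns or hi not in cell.columns:
        raise ValueError(f"phases {phase_pair} not both present")
    diff = (cell[hi] - cell[lo]).dropna().rename("value").reset_index()
    if diff["visit"].nunique() != 2:
        raise ValueError("both drug conditions must be present")
    spec = ModelSpec(outcome="avoidance_difference", fixed=("drug",))
    full, null, comp = fit_with_null(diff, spec)
    return PosthocResult(estimate=full.effect("drug"), comparison=comp,
                         n_obs=full.n_obs, full=full, null=null)


def per_trial_tests(dwell: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Paired disgust-vs-neutral dwell comparison per trial and drug condition.

    A two-sided paired t-test across participants is run for every (visit,
    phase, trial) cell; cells with fewer than 3 contributing participants or
    zero variance in the paired differences are flagged ``untestable``
    (p = NaN).  Holm-Bonferroni flags are added per visit (the test family
    the per-condition display uses).
    """
    rows = []
    for (visit, phase, trial), g in dwell.groupby(["visit", "phase", "trial"]):
        g = g.dropna(subset=["p_disgust", "p_neutral"])
        d = (g["p_disgust"] - g["p_neutral"]).to_numpy(dtype=float)
        if d.size < 3:
            rows.append((visit, phase, trial, d.size, math.nan, math.nan, True))
            continue
        if np.allclose(d, d[0]):
            if d[0] == 0.0:
                rows.append((visit, phase, trial, d.size, 0.0, 1.0, False))
            else:
                rows.append((visit, phase, trial, d.size, math.nan, math.nan, True))
            continue
        t, p = stats.ttest_rel(g["p_disgust"], g["p_neutral"])
        rows.append((visit, phase, trial, d.size, float(t), float(p), False))
    out = pd.DataFrame(rows, columns=["visit", "phase", "trial", "n", "t", "p",
                                      "untestable"])
    out["significant_uncorrected"] = out["p"] < alpha
    flags = np.zeros(len(out), dtype=bool)
    for visit, g in out.groupby("visit"):
        ok = g["p"].notna()
        flags[g.index[ok]] = holm_bonferroni(g.loc[ok, "p"].to_numpy(), alpha)
    out["significant_holm"] = flags
    return out


def holm_bonferroni(p_values, alpha: float = 0.05) -> np.ndarray:
    """Holm-Bonferroni step-down rejection flags, in input order.

    Sort the m p-values ascending and reject the i-th smallest while
    ``p_(i) <= alpha / (m - i + 1)``; stop at the first failure.  Controls
    family-wise error at ``alpha``.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be 1-D")
    if ((p <= 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    reject = np.zeros(m, dtype=bool)
    for i, idx in enumerate(order):
        if p[idx] <= alpha / (m - i):
            reject[idx] = True
        else:
            break
    return reject


def null_evidence_table(rl_summary: pd.DataFrame, measures: tuple[str, ...],
                        phase_pair: tuple[str, str] = ("pre_admin", "post_admin")
                        ) -> pd.DataFrame:
    """Null-evidence summary for control-task measures, one row per measure.

    For each measure column in ``rl_summary`` (one row per participant x
    visit x rl_phase): (a) an LMM of the measure on drug x phase is compared
    against its intercept-only null (columns ``er0_null``/``bf01_null``,
    values over 1 favour the null); (b) a post hoc LMM of the
    post-minus-pre difference on drug is compared against its null
    (``er0_drug``/``bf01_drug``), alongside the drug, phase and interaction
    betas and p-values from (a).
    """
    rows = []
    for measure in measures:
        data = rl_summary.rename(columns={measure: "value",
                                          "rl_phase": "phase"})
        spec = ModelSpec(outcome="rl_parameter_difference",
                         fixed=("drug", "phase"))
        full, _null, comp = fit_with_null(data, spec)
        post = posthoc_drug_difference(data, "value", phase_pair)
        rows.append({
            "measure": measure,
            "beta_drug": full.effect("drug").beta,
            "p_drug": full.effect("drug").p,
            "beta_phase": full.effect("phase").beta,
            "p_phase": full.effect("phase").p,
            "beta_interaction": full.effect("drug:phase").beta,
            "p_interaction": full.effect("drug:phase").p,
            "er0_null": comp.er_0, "bf01_null": comp.bf_01,
            "log_er0_null": comp.log_er_0, "log_bf01_null": comp.log_bf_01,
            "beta_drug_posthoc": post.estimate.beta,
            "p_drug_posthoc": post.estimate.p,
            "er0_drug": post.comparison.er_0, "bf01_drug": post.comparison.bf_01,
        })
    return pd.DataFrame(rows)
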