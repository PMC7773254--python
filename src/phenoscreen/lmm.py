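"""Continuous-response framework: linear mixed model with a batch random
intercept, AICc-driven term selection, and sexual-dimorphism sub-models.

The screening model is

    Response = Genotype + Sex + Genotype x Sex + BodyWeight  (fixed)
             + Batch (random intercept) + error

fitted on complete cases of the variables the model uses.  Candidate
fixed-effect structures are compared by AICc on maximum-likelihood fits
(REML likelihoods are not comparable across fixed effects); the final
reported model is refit by REML.  Inference on fixed effects uses Wald
normal-approximation intervals and p-values throughout — no
degrees-of-freedom correction is applied, a documented limitation at
screening sample sizes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .phen_data import GENOTYPE, SEX, ModelSpec, PhenDataset, ValidationError

Z95 = float(sps.norm.ppf(0.975))
AICC_TIE_TOL = 1e-8


class FitError(RuntimeError):
    """A model could not be fitted on the given data."""


# ---------------------------------------------------------------------------
# design matrix
# ---------------------------------------------------------------------------

def _term_block(df: pd.DataFrame, col: str, reference: str | None
                ) -> tuple[np.ndarray, list[str]]:
    """Columns encoding one main effect: the column itself if numeric,
    treatment-coded dummies otherwise (reference level omitted)."""
    s = df[col]
    if pd.api.types.is_numeric_dtype(s):
        return s.to_numpy(float)[:, None], [col]
    vals = s.astype(str)
    levels = sorted(vals.unique())
    if reference is not None and reference in levels:
        levels.remove(reference)
        levels.insert(0, reference)
    cols, names = [], []
    for lev in levels[1:]:
        cols.append((vals == lev).to_numpy(float)[:, None])
        names.append(f"{col}[{lev}]")
    if not cols:  # single observed level: contributes nothing
        return np.empty((len(df), 0)), []
    return np.hstack(cols), names


@dataclass
class DesignInfo:
    exog: np.ndarray
    names: list[str]
    term_of: dict[str, str]          # design column -> originating term
    aliased: list[str]               # design columns dropped as rank-deficient
    predictor_sd: dict[str, float]   # per retained design column


def build_design(df: pd.DataFrame, terms: Sequence[str],
                 reference_genotype: str) -> DesignInfo:
    """Assemble the fixed-effects design matrix with an intercept,
    treatment coding, interaction products, and aliased-column removal."""
    blocks: list[np.ndarray] = [np.ones((len(df), 1))]
    names: list[str] = ["Intercept"]
    term_of: dict[str, str] = {"Intercept": "Intercept"}
    cache: dict[str, tuple[np.ndarray, list[str]]] = {}

    def block_for(col: str) -> tuple[np.ndarray, list[str]]:
        if col not in cache:
            ref = reference_genotype if col == GENOTYPE else None
            cache[col] = _term_block(df, col, ref)
        return cache[col]

    for term in terms:
        parts = term.split(":")
        if len(parts) == 1:
            mat, cn = block_for(parts[0])
        elif len(parts) == 2:
            (ma, na), (mb, nb) = block_for(parts[0]), block_for(parts[1])
            cols, cn = [], []
            for i, an in enumerate(na):
                for j, bn in enumerate(nb):
                    cols.append((ma[:, i] * mb[:, j])[:, None])
                    cn.append(f"{an}:{bn}")
            mat = np.hstack(cols) if cols else np.empty((len(df), 0))
        else:
            raise ValidationError(f"only pairwise interactions supported: {term!r}")
        blocks.append(mat)
        for c in cn:
            term_of[c] = term
        names.extend(cn)

    X = np.hstack(blocks)
    # greedy rank filter: keep columns that increase the rank
    keep: list[int] = []
    aliased: list[str] = []
    rank = 0
    for j in range(X.shape[1]):
        cand = X[:, keep + [j]]
        r = np.linalg.matrix_rank(cand)
        if r > rank:
            keep.append(j)
            rank = r
        else:
            aliased.append(names[j])
    kept_names = [names[j] for j in keep]
    Xk = X[:, keep]
    sds = {n: float(np.std(Xk[:, i], ddof=1)) if len(df) > 1 else 0.0
           for i, n in enumerate(kept_names)}
    return DesignInfo(exog=Xk, names=kept_names,
                      term_of={n: term_of[n] for n in kept_names},
                      aliased=aliased, predictor_sd=sds)


def model_frame(ds: PhenDataset, terms: Sequence[str],
                random_groups: Sequence[str]) -> pd.DataFrame:
    """Complete-case rows on exactly the variables this model uses."""
    cols = [ds.spec.response, GENOTYPE]
    for t in terms:
        for c in t.split(":"):
            if c not in cols:
                cols.append(c)
    for g in random_groups:
        if g not in cols:
            cols.append(g)
    return ds.data[cols].dropna().reset_index(drop=True)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class FittedLMM:
    """A fitted (or fallback fixed-only) model with Wald inference."""

    fixed_estimates: dict[str, dict[str, float]]
    variance_components: dict[str, float]
    loglik: float
    n_obs: int
    k_params: int
    converged: bool
    fallback_fixed_only: bool
    terms: list[str]
    random_groups: list[str]
    criterion_mode: str
    aliased: list[str]
    term_of: dict[str, str] = field(default_factory=dict)
    predictor_sd: dict[str, float] = field(default_factory=dict)
    response_sd: float = 0.0
    residuals: np.ndarray = field(default_factory=lambda: np.empty(0))
    cov_fixed: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))
    fixed_names: list[str] = field(default_factory=list)

    def genotype_columns(self) -> list[str]:
        return [n for n, t in self.term_of.items() if t == GENOTYPE]

    def estimate(self, name: str) -> dict[str, float]:
        return self.fixed_estimates[name]

    def to_dict(self) -> dict[str, Any]:
        return {
            "terms": list(self.terms),
            "random_groups": list(self.random_groups),
            "criterion_mode": self.criterion_mode,
            "fixed_estimates": {k: dict(v) for k, v in self.fixed_estimates.items()},
            "variance_components": dict(self.variance_components),
            "loglik": self.loglik,
            "n_obs": self.n_obs,
            "k_params": self.k_params,
            "converged": self.converged,
            "fallback_fixed_only": self.fallback_fixed_only,
            "aliased_columns": list(self.aliased),
        }


def _wald_table(params: np.ndarray, ses: np.ndarray, names: Sequence[str]
                ) -> dict[str, dict[str, float]]:
    out = {}
    for n, b, s in zip(names, params, ses):
        z = b / s if s > 0 else np.nan
        out[n] = {
            "estimate": float(b),
            "se": float(s),
            "ci_low": float(b - Z95 * s),
            "ci_high": float(b + Z95 * s),
            "p": float(2.0 * sps.norm.sf(abs(z))) if np.isfinite(z) else float("nan"),
        }
    return out


def fit_lmm(ds: PhenDataset, terms: Sequence[str] | None = None,
            random_groups: Sequence[str] | None = None,
            criterion_mode: str = "REML") -> FittedLMM:
    """Fit the mixed (or fallback fixed-only) model for the given terms.

    ``criterion_mode`` selects the likelihood: ``"ML"`` for model
    comparison, ``"REML"`` for final reporting.  Non-convergence is
    retried once from an alternative optimizer and otherwise flagged on
    the result rather than raised, so a screening run never halts on one
    dataset.
    """
    if criterion_mode not in ("ML", "REML"):
        raise ValidationError("criterion_mode must be 'ML' or 'REML'")
    terms = list(terms if terms is not None else ds.spec.fixed_terms)
    random_groups = list(random_groups if random_groups is not None
                         else ds.spec.random_groups)
    frame = model_frame(ds, terms, random_groups)
    y = frame[ds.spec.response].to_numpy(float)
    n = len(frame)

    groups = None
    if random_groups:
        g = frame[random_groups[0]].astype(str)
        if g.nunique() >= 2:
            groups = g
    fallback = groups is None

    design = build_design(frame, terms, ds.reference_genotype)
    k_fixed = design.exog.shape[1]
    k = k_fixed + (1 if fallback else 2)
    if n - k_fixed < 2:
        raise FitError("insufficient data: fewer than 2 residual degrees of freedom")

    if fallback:
        res = sm.OLS(y, design.exog).fit()
        resid_var = float(res.scale)
        params = np.asarray(res.params, float)
        cov = res.cov_params() * 1.0
        ses = np.sqrt(np.diag(cov))
        fitted = design.exog @ params
        out = FittedLMM(
            fixed_estimates=_wald_table(params, ses, design.names),
            variance_components={"batch": 0.0, "residual": resid_var},
            loglik=float(res.llf), n_obs=n, k_params=k,
            converged=True, fallback_fixed_only=True,
            terms=terms, random_groups=[], criterion_mode=criterion_mode,
            aliased=design.aliased, term_of=design.term_of,
            predictor_sd=design.predictor_sd,
            response_sd=float(np.std(y, ddof=1)),
            residuals=y - fitted, cov_fixed=np.asarray(cov),
            fixed_names=design.names)
        return out

    reml = criterion_mode == "REML"
    model = MixedLM(y, design.exog, groups=groups)
    converged = False
    res = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        for method in ("bfgs", "cg", "powell"):
            try:
                res = model.fit(reml=reml, method=method, maxiter=200)
            except Exception:
                res = None
                continue
            if res is not None and res.converged and np.isfinite(res.llf):
                converged = True
                break
    if res is None:
        raise FitError("mixed-model optimizer failed on this dataset")

    params = np.asarray(res.fe_params, float)
    cov = np.asarray(res.cov_params())[:k_fixed, :k_fixed]
    ses = np.sqrt(np.diag(cov))
    batch_var = float(np.asarray(res.cov_re)[0, 0])
    resid_var = float(res.scale)
    try:
        resid = np.asarray(res.resid, float)  # conditional residuals
    except (ValueError, np.linalg.LinAlgError):
        # singular random-effect covariance (variance shrunk to zero):
        # the BLUPs are zero, so conditional = marginal residuals
        resid = y - design.exog @ params

    return FittedLMM(
        fixed_estimates=_wald_table(params, ses, design.names),
        variance_components={"batch": batch_var, "residual": resid_var},
        loglik=float(res.llf), n_obs=n, k_params=k,
        converged=converged, fallback_fixed_only=False,
        terms=terms, random_groups=random_groups,
        criterion_mode=criterion_mode,
        aliased=design.aliased, term_of=design.term_of,
        predictor_sd=design.predictor_sd,
        response_sd=float(np.std(y, ddof=1)),
        residuals=resid, cov_fixed=cov, fixed_names=design.names)


def compute_aicc(fit: FittedLMM) -> float:
    """AICc = -2 loglik + 2k + 2k(k+1)/(n-k-1), k counting fixed
    coefficients plus variance components."""
    n, k = fit.n_obs, fit.k_params
    if n - k - 1 <= 0:
        raise FitError("AICc undefined at this sample size")
    return -2.0 * fit.loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


# ---------------------------------------------------------------------------
# stepwise selection
# ---------------------------------------------------------------------------

@dataclass
class SelectionTrace:
    direction: str
    steps: list[dict[str, Any]] = field(default_factory=list)
    final_terms: list[str] = field(default_factory=list)

    def record(self, terms: Sequence[str], aicc: float | None,
               accepted: bool, note: str = "") -> None:
        self.steps.append({"terms": list(terms), "aicc": aicc,
                           "accepted": accepted, "note": note})

    def to_dict(self) -> dict[str, Any]:
        return {"direction": self.direction, "final_terms": list(self.final_terms),
                "steps": [dict(s) for s in self.steps]}


def _removable(term: str, current: Sequence[str]) -> bool:
    if term == GENOTYPE:
        return False
    if ":" in term:
        return True
    return not any(":" in t and term in t.split(":") for t in current)


def _addable(term: str, current: Sequence[str]) -> bool:
    if term in current:
        return False
    parts = term.split(":")
    if len(parts) == 2:
        return all(p in current for p in parts)
    return True


def stepwise_select(ds: PhenDataset, spec: ModelSpec | None = None
                    ) -> tuple[SelectionTrace, FittedLMM]:
    """Select fixed-effect terms by AICc on maximum-likelihood fits.

    Genotype is never a removal candidate, interactions obey the
    hierarchy rule, and AICc ties (within 1e-8) resolve in favour of the
    smaller model.  Every candidate evaluation is recorded in the trace;
    a candidate whose fit fails is skipped and recorded.
    """
    spec = spec if spec is not None else ds.spec
    full = list(spec.fixed_terms)
    if GENOTYPE not in full:
        full.insert(0, GENOTYPE)
    direction = spec.optimize

    def fitted(terms: Sequence[str]) -> FittedLMM:
        return fit_lmm(ds, terms, spec.random_groups, criterion_mode="ML")

    trace = SelectionTrace(direction=direction)
    if direction == "none":
        fit = fitted(full)
        trace.record(full, compute_aicc(fit), True, "full model")
        trace.final_terms = full
        return trace, fit

    if direction in ("backward", "stepwise"):
        current = list(full)
    else:
        current = [GENOTYPE]
    fit = fitted(current)
    aicc = compute_aicc(fit)
    trace.record(current, aicc, True, "start")
    removed_pool = [t for t in full if t not in current]

    def try_moves(kind: str) -> tuple[list[str], FittedLMM, float] | None:
        """Best single move of the given kind; None if nothing acceptable."""
        best: tuple[list[str], FittedLMM, float] | None = None
        if kind == "remove":
            candidates = [[t for t in current if t != r]
                          for r in current if _removable(r, current)]
        else:
            candidates = [current + [a] for a in removed_pool
                          if _addable(a, current)]
        for cand in candidates:
            try:
                cfit = fitted(cand)
                caicc = compute_aicc(cfit)
            except FitError as exc:
                trace.record(cand, None, False, f"fit failed: {exc}")
                continue
            if kind == "remove":
                ok = caicc <= aicc + AICC_TIE_TOL  # tie favours smaller model
            else:
                ok = caicc < aicc - AICC_TIE_TOL
            trace.record(cand, caicc, False, f"candidate {kind}")
            if ok and (best is None or caicc < best[2] - AICC_TIE_TOL
                       or (abs(caicc - best[2]) <= AICC_TIE_TOL
                           and len(cand) < len(best[0]))):
                best = (cand, cfit, caicc)
        return best

    seen = {tuple(sorted(current))}
    while True:
        moved = False
        order = (["remove"] if direction == "backward"
                 else ["add"] if direction == "forward"
                 else ["remove", "add"])
        for kind in order:
            best = try_moves(kind)
            if best is None:
                continue
            cand, cfit, caicc = best
            key = tuple(sorted(cand))
            if key in seen:
                continue
            seen.add(key)
            removed_pool = [t for t in full if t not in cand]
            current, fit, aicc = cand, cfit, caicc
            trace.record(current, aicc, True, f"accepted {kind}")
            moved = True
            break
        if not moved:
            break

    trace.final_terms = list(current)
    return trace, fit


# ---------------------------------------------------------------------------
# sub-models, effect sizes, diagnostics
# ---------------------------------------------------------------------------

def _primary_genotype_entry(fit: FittedLMM) -> tuple[str, dict[str, float]] | None:
    cols = fit.genotype_columns()
    if not cols:
        return None
    return cols[0], fit.fixed_estimates[cols[0]]


def sex_specific_effects(ds: PhenDataset, final: FittedLMM) -> dict[str, Any]:
    """Genotype contrasts overall and per sex, plus the interaction test.

    The overall contrast comes from a model without the Genotype x Sex
    interaction; the sex-specific effects come from the interaction
    parameterisation (reference-sex effect, and its sum with the
    interaction using a delta-method standard error).  Entries other than
    the overall contrast are absent when only one sex is observed.
    """
    interaction = f"{GENOTYPE}:{SEX}"
    base_terms = [t for t in final.terms if t != interaction]
    overall_fit = fit_lmm(ds, base_terms, final.random_groups, "REML")
    out: dict[str, Any] = {}
    prim = _primary_genotype_entry(overall_fit)
    if prim is not None:
        out["overall"] = {"contrast": prim[0], **prim[1]}

    frame = model_frame(ds, final.terms, final.random_groups)
    both_sexes = SEX in frame.columns and frame[SEX].nunique() >= 2
    if not both_sexes:
        return out

    int_terms = list(final.terms)
    for t in (SEX, interaction):
        if t not in int_terms:
            int_terms.append(t)
    ifit = fit_lmm(ds, int_terms, final.random_groups, "REML")
    gcol = next((c for c, t in ifit.term_of.items() if t == GENOTYPE), None)
    icol = next((c for c, t in ifit.term_of.items() if t == interaction), None)
    if gcol is None or icol is None:
        return out

    names = ifit.fixed_names
    gi, ii = names.index(gcol), names.index(icol)
    cov = ifit.cov_fixed
    g = ifit.fixed_estimates[gcol]
    # sex levels sorted, so the reference sex is Female and gcol is the
    # female-specific effect; female + interaction is the male effect
    out["female"] = {"contrast": gcol, **g}
    male_est = g["estimate"] + ifit.fixed_estimates[icol]["estimate"]
    male_se = float(np.sqrt(cov[gi, gi] + cov[ii, ii] + 2.0 * cov[gi, ii]))
    z = male_est / male_se if male_se > 0 else np.nan
    out["male"] = {
        "contrast": f"{gcol}+{icol}",
        "estimate": float(male_est), "se": male_se,
        "ci_low": float(male_est - Z95 * male_se),
        "ci_high": float(male_est + Z95 * male_se),
        "p": float(2.0 * sps.norm.sf(abs(z))) if np.isfinite(z) else float("nan"),
    }
    out["interaction"] = {"contrast": icol, **ifit.fixed_estimates[icol]}
    return out


def lmm_effect_sizes(fit: FittedLMM) -> dict[str, dict[str, float]]:
    """Standardized coefficients, and a Cohen's-d analogue for genotype.

    Numeric predictors: estimate * SD(x) / SD(y).  Genotype contrast:
    estimate / sqrt(batch variance + residual variance).  Confidence
    bounds are the Wald CI scaled by the same factor.
    """
    if fit.response_sd <= 0:
        raise FitError("degenerate response: zero variance")
    total_sd = float(np.sqrt(fit.variance_components["batch"]
                             + fit.variance_components["residual"]))
    out: dict[str, dict[str, float]] = {}
    for name, est in fit.fixed_estimates.items():
        term = fit.term_of.get(name, name)
        if name == "Intercept":
            continue
        if term == GENOTYPE:
            scale = 1.0 / total_sd if total_sd > 0 else np.nan
            kind = "cohens_d"
        else:
            scale = fit.predictor_sd.get(name, 0.0) / fit.response_sd
            kind = "standardized_coefficient"
        out[name] = {
            "value": float(est["estimate"] * scale),
            "ci_low": float(est["ci_low"] * scale),
            "ci_high": float(est["ci_high"] * scale),
            "kind": kind,
        }
        if out[name]["ci_low"] > out[name]["ci_high"]:
            out[name]["ci_low"], out[name]["ci_high"] = (
                out[name]["ci_high"], out[name]["ci_low"])
    return out


def residual_diagnostics(fit: FittedLMM, seed: int | None = None,
                         max_shapiro: int = 5000) -> dict[str, Any]:
    """Shapiro–Wilk and Kolmogorov–Smirnov normality checks on the
    conditional residuals, plus a residual summary.

    Shapiro–Wilk is computed on a seeded subsample of ``max_shapiro``
    residuals when n exceeds the test's valid range, and is absent (with
    a reason) below n = 3.
    """
    r = np.asarray(fit.residuals, float)
    out: dict[str, Any] = {
        "n_residuals": int(r.size),
        "residual_min": float(r.min()) if r.size else None,
        "residual_max": float(r.max()) if r.size else None,
        "residual_skewness": float(sps.skew(r)) if r.size > 2 else None,
    }
    if r.size >= 3:
        sample = r
        if r.size > max_shapiro:
            rng = np.random.default_rng(seed)
            sample = rng.choice(r, size=max_shapiro, replace=False)
        w, p = sps.shapiro(sample)
        out["shapiro_wilk"] = {"statistic": float(w), "p": float(p),
                               "n_used": int(sample.size)}
    else:
        out["shapiro_wilk"] = None
        out["shapiro_wilk_reason"] = "fewer than 3 residuals"
    if r.size >= 2 and np.std(r) > 0:
        d, p = sps.kstest(r, "norm", args=(float(np.mean(r)), float(np.std(r, ddof=1))))
        out["kolmogorov_smirnov"] = {"statistic": float(d), "p": float(p)}
    else:
        out["kolmogorov_smirnov"] = None
    return out


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

@dataclass
class LMMResult:
    final: FittedLMM
    trace: SelectionTrace
    submodels: dict[str, Any]
    effect_sizes: dict[str, dict[str, float]]
    diagnostics: dict[str, Any]

    @property
    def genotype_p(self) -> float | None:
        prim = _primary_genotype_entry(self.final)
        return None if prim is None else prim[1]["p"]

    def to_dict(self) -> dict[str, Any]:
        return {
            "framework": "LMM",
            "final_model": self.final.to_dict(),
            "selection": self.trace.to_dict(),
            "submodels": self.submodels,
            "effect_sizes": self.effect_sizes,
            "diagnostics": self.diagnostics,
            "genotype_p": self.genotype_p,
        }


def analyze_continuous(ds: PhenDataset) -> LMMResult:
    """Run term selection (ML), refit the final model by REML, and attach
    sub-models, effect sizes and residual diagnostics."""
    trace, _ = stepwise_select(ds, ds.spec)
    final = fit_lmm(ds, trace.final_terms, ds.spec.random_groups, "REML")
    submodels = sex_specific_effects(ds, final)
    effect_sizes = lmm_effect_sizes(final)
    diagnostics = residual_diagnostics(final, seed=ds.spec.seed)
    return LMMResult(final=final, trace=trace, submodels=submodels,
                     effect_sizes=effect_sizes, diagnostics=diagnostics)
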