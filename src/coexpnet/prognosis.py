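"""Survival modeling: normalization, univariate Cox screening, Kaplan-Meier
comparisons, and a cross-validated LASSO-Cox signature.

Expression inputs for the estimators here are samples x genes (the
scikit-learn orientation); the helpers :func:`fpkm_to_tpm`,
:func:`normalize_reference` and :func:`zscore_genes` operate on the
pipeline's genes x samples matrices.  Survival tables carry one row per
sample with positive ``time`` and ``event`` in {0, 1}.

Cox ties use the Efron approximation (the lifelines default), stated
explicitly for reproducibility.  The LASSO-Cox path is the coordinate-
descent elastic-net path of scikit-survival restricted to the pure L1
penalty, with the penalty weight chosen by k-fold cross-validated
partial-likelihood deviance (the ``lambda.min`` rule).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test
from sklearn.base import BaseEstimator
from sklearn.model_selection import StratifiedKFold
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

__all__ = [
    "CoxScreen",
    "LassoCoxCV",
    "LassoResult",
    "fpkm_to_tpm",
    "normalize_reference",
    "zscore_genes",
    "univariate_cox",
    "filter_prognostic",
    "km_logrank",
    "lasso_cox",
    "breslow_loglik",
]

log = logging.getLogger(__name__)


def _check_survival(surv: pd.DataFrame) -> pd.DataFrame:
    surv = surv.copy()
    if "sample" in surv.columns:
        surv = surv.set_index("sample")
    if not {"time", "event"} <= set(surv.columns):
        raise ValueError("survival table needs 'time' and 'event' columns")
    if (surv["time"] <= 0).any():
        raise ValueError("survival times must be positive")
    if not surv["event"].isin((0, 1)).all():
        raise ValueError("event indicator must be 0/1")
    return surv


def fpkm_to_tpm(fpkm: pd.DataFrame) -> pd.DataFrame:
    """Rescale FPKM columns so each sample sums to one million (TPM)."""
    if (fpkm.to_numpy() < 0).any():
        raise ValueError("FPKM values must be non-negative")
    colsum = fpkm.sum(axis=0)
    dead = colsum.index[colsum <= 0]
    if len(dead):
        raise ValueError(f"all-zero sample(s): {list(dead)}")
    return fpkm / colsum * 1e6


def normalize_reference(expr: pd.DataFrame, ref_gene: str = "GAPDH") -> pd.DataFrame:
    """Reference-gene normalization on log2 scale with a +1 offset.

    ``expr'_gs = log2(expr_gs + 1) - log2(expr_ref,s + 1)``; the +1
    offset tolerates zeros in RNA-Seq abundances.  The reference gene
    row is removed from the output.
    """
    if ref_gene not in expr.index:
        raise ValueError(f"reference gene {ref_gene!r} not in expression matrix")
    ref = expr.loc[ref_gene].to_numpy(float)
    if (ref <= 0).any():
        raise ValueError(f"reference gene {ref_gene!r} has non-positive values")
    out = np.log2(expr.to_numpy(float) + 1.0) - np.log2(ref + 1.0)[None, :]
    out = pd.DataFrame(out, index=expr.index, columns=expr.columns)
    return out.drop(index=ref_gene)


def zscore_genes(expr: pd.DataFrame) -> pd.DataFrame:
    """Row-wise z-score (mean 0, sample SD 1); zero-variance genes dropped."""
    if expr.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    sd = expr.std(axis=1, ddof=1)
    dead = sd.index[sd == 0]
    if len(dead):
        warnings.warn(f"dropping {len(dead)} zero-variance gene(s)", stacklevel=2)
        expr = expr.drop(index=dead)
        sd = sd.drop(index=dead)
    return expr.sub(expr.mean(axis=1), axis=0).div(sd, axis=0)


def univariate_cox(gene_values: pd.Series, surv: pd.DataFrame) -> dict:
    """Single-covariate Cox proportional-hazards fit (Efron ties).

    Returns gene, Wald p, hazard ratio ``exp(beta)`` and its normal 95%
    CI, plus a ``converged`` flag; non-convergent fits are flagged
    rather than raised so callers can exclude them downstream.
    """
    surv = _check_survival(surv)
    if len(surv) < 10:
        raise ValueError("need at least 10 samples")
    if surv["event"].sum() < 2:
        raise ValueError("need at least 2 events")
    values = pd.Series(gene_values).loc[surv.index]
    df = pd.DataFrame({"x": values.to_numpy(float),
                       "time": surv["time"].to_numpy(float),
                       "event": surv["event"].to_numpy(int)})
    name = gene_values.name if gene_values.name is not None else "gene"
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = CoxPHFitter().fit(df, "time", "event")
        beta = float(fit.params_["x"])
        se = float(fit.standard_errors_["x"])
        return {"gene": name, "p": float(fit.summary.loc["x", "p"]),
                "HR": float(np.exp(beta)), "ci_low": float(np.exp(beta - 1.96 * se)),
                "ci_high": float(np.exp(beta + 1.96 * se)), "converged": True}
    except ConvergenceError:
        log.warning("Cox fit for %s did not converge; flagged", name)
        return {"gene": name, "p": np.nan, "HR": np.nan, "ci_low": np.nan,
                "ci_high": np.nan, "converged": False}


class CoxScreen(BaseEstimator):
    """Per-gene univariate Cox screen (estimator form).

    ``fit(X, surv)`` with X samples x genes.  ``results_`` holds one row
    per gene (p, HR, 95% CI, convergence flag); ``selected_`` the genes
    with p < ``alpha`` sorted by p ascending.
    """

    def __init__(self, alpha: float = 0.05):
        self.alpha = alpha

    def fit(self, X: pd.DataFrame, surv: pd.DataFrame):
        surv = _check_survival(surv)
        rows = [univariate_cox(X[g], surv) for g in X.columns]
        self.results_ = pd.DataFrame(rows)
        self.selected_ = filter_prognostic(self.results_, self.alpha)
        return self


def filter_prognostic(rows, alpha: float = 0.05) -> list:
    """Genes with converged fits and p < alpha, sorted by p ascending."""
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    df = pd.DataFrame(rows)
    if df.empty:
        return []
    df = df[df.get("converged", True) & (df["p"] < alpha)]
    return list(df.sort_values(["p", "gene"], kind="mergesort")["gene"])


def km_logrank(gene_values: pd.Series, surv: pd.DataFrame) -> tuple[float, dict, pd.DataFrame]:
    """Median-split Kaplan-Meier comparison with a two-group log-rank test.

    Samples at or below the median expression form the low group (ties
    to low).  Returns ``(p, group_sizes, curves)`` where ``curves`` has
    columns group/time/survival.  The split depends only on ranks, so
    the p-value is invariant to monotone transformations of the values.
    """
    surv = _check_survival(surv)
    values = pd.Series(gene_values).loc[surv.index].to_numpy(float)
    low = values <= np.median(values)
    if low.all() or not low.any():
        raise ValueError("degenerate median split: one group is empty")
    t, e = surv["time"].to_numpy(float), surv["event"].to_numpy(int)
    res = logrank_test(t[low], t[~low], e[low], e[~low])
    curves = []
    for name, mask in (("low", low), ("high", ~low)):
        km = KaplanMeierFitter().fit(t[mask], e[mask], label=name)
        sf = km.survival_function_
        curves.append(pd.DataFrame({"group": name, "time": sf.index.to_numpy(),
                                    "survival": sf[name].to_numpy()}))
    return float(res.p_value), {"low": int(low.sum()), "high": int((~low).sum())}, pd.concat(curves, ignore_index=True)


def breslow_loglik(X: np.ndarray, time: np.ndarray, event: np.ndarray,
                   coef: np.ndarray) -> float:
    """Breslow partial log-likelihood at a fixed coefficient vector.

    Used to evaluate held-out folds on the LASSO path; ties share a
    common risk set (Breslow), evaluated with a stable log-sum-exp.
    """
    eta = np.asarray(X, float) @ np.asarray(coef, float)
    order = np.argsort(time, kind="stable")
    eta, time, event = eta[order], np.asarray(time, float)[order], np.asarray(event, int)[order]
    M = eta.max() if len(eta) else 0.0
    suffix = np.cumsum(np.exp(eta - M)[::-1])[::-1]
    start = np.searchsorted(time, time, side="left")
    lse = np.log(suffix[start]) + M
    return float(np.sum((eta - lse)[event == 1]))


@dataclass
class LassoResult:
    """Cross-validated LASSO-Cox path summary."""

    lambda_path: np.ndarray
    cv_deviance: np.ndarray
    cv_deviance_se: np.ndarray
    lambda_opt: float
    coefficients: pd.Series
    selected_genes: list


class LassoCoxCV(BaseEstimator):
    """L1-penalized Cox regression with k-fold cross-validated lambda.

    The lambda path is log-spaced from the smallest penalty that zeroes
    every coefficient down to ``alpha_min_ratio`` times it (at most
    ``n_alphas`` values; the underlying coordinate-descent solver may
    stop the path early once it saturates).  Fold assignment is seeded
    and stratified by event status; a fold without events is re-drawn
    with a derived seed (up to ``max_refolds`` times).  ``lambda_opt``
    minimizes the mean held-out partial-likelihood deviance
    ``-2 * loglik`` (the ``lambda.min`` rule).

    ``fit(X, surv)`` with X samples x genes (z-scored upstream).
    ``predict(X)`` returns the linear risk score at ``lambda_opt``.
    """

    def __init__(self, n_folds: int = 10, random_state: int = 0, n_alphas: int = 100,
                 alpha_min_ratio: float = 0.001, max_refolds: int = 5):
        self.n_folds = n_folds
        self.random_state = random_state
        self.n_alphas = n_alphas
        self.alpha_min_ratio = alpha_min_ratio
        self.max_refolds = max_refolds

    def fit(self, X: pd.DataFrame, surv: pd.DataFrame):
        X = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, float))
        surv = _check_survival(surv)
        surv = surv.loc[X.index] if set(X.index) <= set(surv.index) else surv
        time = surv["time"].to_numpy(float)
        event = surv["event"].to_numpy(int)
        if event.sum() < self.n_folds:
            raise ValueError(f"need at least n_folds={self.n_folds} events, have {event.sum()}")
        Xm = X.to_numpy(float)
        y = Surv.from_arrays(event.astype(bool), time)
        path = CoxnetSurvivalAnalysis(l1_ratio=1.0, n_alphas=self.n_alphas,
                                      alpha_min_ratio=self.alpha_min_ratio)
        path.fit(Xm, y)
        alphas = np.asarray(path.alphas_)

        dev = self._cv_deviance(Xm, time, event, alphas)
        mean_dev = np.nanmean(dev, axis=0)
        se_dev = np.nanstd(dev, axis=0, ddof=1) / np.sqrt(dev.shape[0])
        opt = int(np.nanargmin(mean_dev))
        coef = pd.Series(path.coef_[:, opt], index=X.columns, name="coef")

        self.alphas_ = alphas
        self.cv_deviance_ = mean_dev
        self.cv_deviance_se_ = se_dev
        self.alpha_opt_ = float(alphas[opt])
        self.coef_ = coef
        self.coef_path_ = pd.DataFrame(path.coef_, index=X.columns, columns=alphas)
        self.selected_genes_ = list(coef.index[coef != 0])
        return self

    def _cv_deviance(self, Xm, time, event, alphas):
        for attempt in range(self.max_refolds):
            seed = self.random_state + 1_000_003 * attempt
            skf = StratifiedKFold(self.n_folds, shuffle=True, random_state=seed)
            folds = list(skf.split(Xm, event))
            if all(event[te].sum() > 0 and event[tr].sum() > 0 for tr, te in folds):
                break
            log.warning("fold without events; re-drawing fold assignment (attempt %d)", attempt + 1)
        else:
            raise ValueError("could not build folds with events in every fold")
        dev = np.full((self.n_folds, len(alphas)), np.nan)
        for f, (tr, te) in enumerate(folds):
            m = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=alphas)
            m.fit(Xm[tr], Surv.from_arrays(event[tr].astype(bool), time[tr]))
            for ai, alpha in enumerate(np.asarray(m.alphas_)):
                j = int(np.argmin(np.abs(alphas - alpha)))
                dev[f, j] = -2.0 * breslow_loglik(Xm[te], time[te], event[te], m.coef_[:, ai])
        return dev

    def predict(self, X) -> np.ndarray:
        X = X.to_numpy(float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
        return X @ self.coef_.to_numpy()

    def result(self) -> LassoResult:
        return LassoResult(lambda_path=self.alphas_, cv_deviance=self.cv_deviance_,
                           cv_deviance_se=self.cv_deviance_se_, lambda_opt=self.alpha_opt_,
                           coefficients=self.coef_, selected_genes=self.selected_genes_)


def lasso_cox(expr_subset: pd.DataFrame, surv: pd.DataFrame, n_folds: int = 10,
              seed: int = 0) -> LassoResult:
    """Functional wrapper over :class:`LassoCoxCV`.

    ``expr_subset`` is genes x samples (pipeline orientation) and is
    transposed internally.
    """
    model = LassoCoxCV(n_folds=n_folds, random_state=seed)
    model.fit(expr_subset.T, surv)
    return model.result()
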