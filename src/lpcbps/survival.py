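"""Survival-analysis evaluation of a BPS matrix.

An L1-penalized Cox proportional-hazards model h(t|X) = h0(t) exp(beta' X) is
fitted with the process scores as features; the Prognostic Index PI = beta' X
is used as a per-sample risk score.  Samples are dichotomized at the PI
quantile matching the training event fraction, compared by (optionally
Wilcoxon/Gehan-weighted) log-rank test, and summarized by the ROC AUC of PI
against event status.  Leave-one-out cross-validation refits the model on
each reduced cohort and pools the held-out PI values.  Hierarchical
clustering of the BPS matrix plus chi-square tests quantifies association
with categorical clinical factors.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd
from lifelines.statistics import logrank_test as _lifelines_logrank
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import chi2_contingency
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import KFold
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.metrics import concordance_index_censored
from sksurv.util import Surv

from .io import BPSMatrix, ClinicalTable

logger = logging.getLogger(__name__)

FeatureInput = Union[BPSMatrix, pd.DataFrame]


@dataclass
class CoxModel:
    """Fitted L1-penalized Cox model over process features."""

    beta: pd.Series  # coefficient per feature
    penalty: float

    @property
    def selected(self) -> list:
        return list(self.beta.index[self.beta != 0])


def _align(features: FeatureInput, clinical: ClinicalTable):
    """Sample-align features (processes x samples) with the clinical table."""
    if isinstance(features, BPSMatrix):
        frame = features.to_frame()
    else:
        frame = features
    missing = set(clinical.sample_ids) - set(frame.columns)
    if missing:
        raise ValueError(f"clinical samples absent from features: {sorted(missing)[:5]}")
    X = frame[clinical.sample_ids].T  # samples x features
    return X, clinical.time, clinical.status


def _select_alpha_cv(
    X: np.ndarray, y, alphas: np.ndarray, n_splits: int, seed: int
) -> float:
    """Pick the penalty maximizing mean held-out concordance over K folds.

    Ties favor the larger (sparser) penalty.
    """
    kf = KFold(n_splits=n_splits, shuffle=True, random_state=seed)
    scores = np.full((n_splits, len(alphas)), np.nan)
    for f, (tr, te) in enumerate(kf.split(X)):
        if y["event"][tr].sum() < 2 or y["event"][te].sum() < 1:
            continue
        est = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=alphas)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est.fit(X[tr], y[tr])
        for a_idx, a in enumerate(est.alphas_):
            pred = est.predict(X[te], alpha=a)
            if np.ptp(pred) == 0:
                scores[f, a_idx] = 0.5
            else:
                scores[f, a_idx] = concordance_index_censored(
                    y["event"][te], y["time"][te], pred
                )[0]
    mean_scores = np.nanmean(scores, axis=0)
    if np.all(np.isnan(mean_scores)):
        raise ValueError("cross-validation failed on every fold")
    best = np.nanmax(mean_scores)
    # alphas are descending; first index attaining the max is the sparsest
    return float(alphas[int(np.nanargmax(mean_scores >= best - 1e-12))])


def fit_cox_lasso(
    features: FeatureInput,
    clinical: ClinicalTable,
    penalty_selection: str = "cv",
    alpha: Optional[float] = None,
    n_alphas: int = 30,
    cv_folds: int = 5,
    seed: int = 0,
) -> CoxModel:
    """Maximize the L1-penalized Cox partial likelihood on the BPS features.

    ``penalty_selection='cv'`` picks the penalty by internal K-fold
    cross-validated concordance (deterministic fold seed); ``'fixed'`` uses
    the supplied ``alpha``.
    """
    X, time, status = _align(features, clinical)
    feature_names = list(X.columns)
    Xv = X.to_numpy(dtype=float)
    if not np.all(np.isfinite(Xv)):
        raise ValueError("features contain non-finite values")
    if int(status.sum()) < 2:
        raise ValueError(f"need >= 2 events, got {int(status.sum())}")
    y = Surv.from_arrays(event=status.astype(bool), time=time)

    if penalty_selection == "fixed":
        if alpha is None:
            raise ValueError("penalty_selection='fixed' requires alpha")
        chosen = float(alpha)
    elif penalty_selection == "cv":
        path = CoxnetSurvivalAnalysis(
            l1_ratio=1.0, n_alphas=n_alphas, alpha_min_ratio=0.01
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            path.fit(Xv, y)
        chosen = _select_alpha_cv(Xv, y, path.alphas_, cv_folds, seed)
    else:
        raise ValueError("penalty_selection must be 'cv' or 'fixed'")

    est = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=[chosen])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est.fit(Xv, y)
    beta = pd.Series(est.coef_.ravel(), index=feature_names, name="beta")
    return CoxModel(beta=beta, penalty=chosen)


def prognostic_index(model: CoxModel, features: FeatureInput) -> pd.Series:
    """PI_k = beta' X^k for every sample."""
    if isinstance(features, BPSMatrix):
        frame = features.to_frame()
    else:
        frame = features
    missing = set(model.beta.index) - set(frame.index)
    if missing:
        raise ValueError(f"features missing model terms: {sorted(missing)[:5]}")
    X = frame.loc[list(model.beta.index)].T  # samples x features
    return pd.Series(X.to_numpy() @ model.beta.to_numpy(), index=X.index, name="pi")


def pi_cutoff(pi_train: np.ndarray, status_train: np.ndarray) -> float:
    """Risk cutoff matching the training event fraction.

    With event fraction d, the cutoff is the (1 - d) quantile of the training
    PI, so the fraction labeled high-risk (pi > cutoff) equals d within 1/n.
    """
    pi_train = np.asarray(pi_train, dtype=float)
    status_train = np.asarray(status_train)
    if status_train.min() == status_train.max():
        raise ValueError("need both events and non-events to set a cutoff")
    d = float(np.mean(status_train))
    cutoff = float(np.quantile(pi_train, 1.0 - d))
    if np.ptp(pi_train) == 0:
        logger.warning("all PI values equal; every sample falls in one group")
    return cutoff


def risk_groups(pi: np.ndarray, cutoff: float) -> np.ndarray:
    """'high' where pi > cutoff, else 'low'."""
    return np.where(np.asarray(pi, dtype=float) > cutoff, "high", "low")


def logrank_test(
    time: np.ndarray,
    status: np.ndarray,
    group: np.ndarray,
    weighted: bool = False,
) -> float:
    """Two-sample log-rank p-value between the two risk groups.

    ``weighted`` switches to the Wilcoxon (Gehan-Breslow) weighting.
    """
    time = np.asarray(time, dtype=float)
    status = np.asarray(status)
    group = np.asarray(group)
    labels = np.unique(group)
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 non-empty groups, got {list(labels)}")
    a = group == labels[0]
    res = _lifelines_logrank(
        time[a],
        time[~a],
        event_observed_A=status[a],
        event_observed_B=status[~a],
        weightings="wilcoxon" if weighted else None,
    )
    return float(res.p_value)


def roc_auc(pi: np.ndarray, status: np.ndarray) -> float:
    """AUC of PI as a score for event status (midrank tie handling)."""
    status = np.asarray(status)
    if len(np.unique(status)) < 2:
        raise ValueError("both classes must be present")
    pi = np.asarray(pi, dtype=float)
    if np.ptp(pi) == 0:
        return 0.5
    return float(roc_auc_score(status, pi))


def loocv_evaluate(
    features: FeatureInput,
    clinical: ClinicalTable,
    penalty_selection: str = "cv",
    alpha: Optional[float] = None,
    seed: int = 0,
) -> dict:
    """Leave-one-out cross-validation of the Cox/PI pipeline.

    Each fold refits the model on n-1 samples, computes the held-out PI with
    the training coefficients, and labels it against the training-derived
    cutoff.  Held-out PI values are pooled for a single AUC; pooled groups
    feed a log-rank test.
    """
    X, time, status = _align(features, clinical)
    n = len(X)
    if n < 10:
        raise ValueError("LOOCV needs at least 10 samples")
    frame = X.T  # processes x samples, for refitting

    pi_out = np.full(n, np.nan)
    group_out = np.empty(n, dtype=object)
    skipped = []
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        clin_tr = ClinicalTable(clinical.frame.iloc[mask].reset_index(drop=True))
        if int(clin_tr.status.sum()) < 2:
            logger.warning("fold %d skipped: too few events in training", i)
            skipped.append(i)
            continue
        model = fit_cox_lasso(
            frame.loc[:, clin_tr.sample_ids],
            clin_tr,
            penalty_selection=penalty_selection,
            alpha=alpha,
            seed=seed,
        )
        pi_tr = prognostic_index(model, frame.loc[:, clin_tr.sample_ids]).to_numpy()
        cutoff = pi_cutoff(pi_tr, clin_tr.status)
        pi_i = float(model.beta.to_numpy() @ X.iloc[i].loc[model.beta.index].to_numpy())
        pi_out[i] = pi_i
        group_out[i] = "high" if pi_i > cutoff else "low"

    done = ~np.isnan(pi_out)
    auc = roc_auc(pi_out[done], status[done])
    groups_done = group_out[done].astype(str)
    if len(np.unique(groups_done)) == 2:
        p = logrank_test(time[done], status[done], groups_done)
    else:
        p = float("nan")
        logger.warning("pooled LOOCV produced a single risk group; log-rank undefined")
    per_sample = pd.DataFrame(
        {
            "sample": X.index,
            "pi": pi_out,
            "group": [g if g is not None else "" for g in group_out],
            "time": time,
            "status": status,
        }
    )
    return {
        "auc": auc,
        "logrank_p": p,
        "per_sample": per_sample,
        "n_folds": n,
        "skipped_folds": skipped,
    }


def transfer_evaluate(
    model: CoxModel,
    cutoff: float,
    features_test: FeatureInput,
    clinical_test: ClinicalTable,
) -> dict:
    """Apply a trained model and its unchanged PI cutoff to a second cohort."""
    X, time, status = _align(features_test, clinical_test)
    pi = prognostic_index(model, X.T).to_numpy()
    group = risk_groups(pi, cutoff)
    result = {"auc": roc_auc(pi, status), "cutoff": cutoff}
    if len(np.unique(group)) == 2:
        result["logrank_p"] = logrank_test(time, status, group)
    else:
        result["logrank_p"] = float("nan")
    return result


def _permutation_chi2_p(
    table_labels: np.ndarray, factor: np.ndarray, n_perm: int, seed: int
) -> float:
    """Monte-Carlo chi-square p-value (used when expected counts hit zero)."""
    rng = np.random.default_rng(seed)

    def stat(f):
        ct = pd.crosstab(pd.Series(table_labels), pd.Series(f)).to_numpy()
        expected = ct.sum(1, keepdims=True) * ct.sum(0, keepdims=True) / ct.sum()
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(expected > 0, (ct - expected) ** 2 / expected, 0.0)
        return terms.sum()

    observed = stat(factor)
    perm = np.array([stat(rng.permutation(factor)) for _ in range(n_perm)])
    return float((1 + (perm >= observed).sum()) / (1 + n_perm))


def cluster_association(
    features: FeatureInput,
    clinical_factors: pd.DataFrame,
    method: str = "average",
    metric: str = "euclidean",
    n_clusters: int = 2,
    n_perm: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Hierarchical clustering of samples + chi-square association per factor.

    Samples (columns of the BPS matrix) are clustered with agglomerative
    linkage and cut at ``n_clusters`` groups; each categorical clinical factor
    is tested for association with the cluster labels by chi-square
    (permutation fallback when an expected cell count is zero).
    """
    if isinstance(features, BPSMatrix):
        frame = features.to_frame()
    else:
        frame = features
    samples = [s for s in frame.columns if s in set(clinical_factors.index)]
    if len(samples) < 2:
        raise ValueError("need >= 2 samples shared between features and factors")
    X = frame[samples].T.to_numpy(dtype=float)
    Z = linkage(X, method=method, metric=metric)
    labels = fcluster(Z, t=n_clusters, criterion="maxclust")

    rows = []
    single = len(np.unique(labels)) < 2
    for col in clinical_factors.columns:
        factor = clinical_factors.loc[samples, col].to_numpy()
        if single:
            rows.append((col, np.nan, "error: single cluster"))
            continue
        ct = pd.crosstab(pd.Series(labels), pd.Series(factor))
        expected = (
            ct.to_numpy().sum(1, keepdims=True)
            * ct.to_numpy().sum(0, keepdims=True)
            / ct.to_numpy().sum()
        )
        if (expected == 0).any():
            p = _permutation_chi2_p(labels, factor, n_perm, seed)
            rows.append((col, p, "permutation"))
        else:
            stat, p, _, _ = chi2_contingency(ct)
            rows.append((col, float(p), "chi2"))
    return pd.DataFrame(rows, columns=["factor", "p_value", "method"])
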