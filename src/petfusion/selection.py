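"""Cross-cohort feature-selection cascade and latent-feature ranking.

Stage 1 (stability): drop columns with near-zero variance in either cohort
or with inconsistent distributions across cohorts (two-sample
Kolmogorov–Smirnov test).  Stage 2 (elastic net): one-vs-rest penalized
regression per class at alpha = 0.5 with k-fold cross-validation and the
minimum-mean-squared-error rule for lambda; the retained set is the union
of nonzero supports over classes; a second pass at alpha = 1.0 per cohort
keeps features whose per-class coefficient profiles correlate across
cohorts (Pearson r above threshold).  Stage 3 (redundancy): a greedy pass
ordered by |weight| removes features highly collinear (|r| > threshold)
with an already-kept feature.  Latent dimensions from the two network
channels are ranked by the same elastic-net machinery and the top-k per
channel join the fused feature specification.

The penalized loss is ``(1/2n)||y - Xb||^2 + lambda*(alpha*||b||_1 +
(1-alpha)/2*||b||^2)``, solved by coordinate descent (scikit-learn backend;
``lambda`` maps to sklearn's ``alpha`` and ``alpha`` to ``l1_ratio``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import ElasticNet, enet_path
from sklearn.model_selection import KFold

__all__ = ["SelectionResult", "FusedFeatureSpec", "stability_filter",
           "elastic_net_path", "elastic_net_fit", "cross_cohort_refine",
           "prune_redundant", "select_features", "SelectionConfig"]


@dataclass
class SelectionResult:
    """Outcome of one elastic-net screening over a feature table."""

    retained: list[str]
    weights: pd.DataFrame          # features x classes coefficient profiles
    lambda_star: float
    lambda_path: np.ndarray
    cv_mse: np.ndarray             # mean CV MSE per lambda (averaged over classes)
    alpha: float

    def weight_magnitude(self) -> pd.Series:
        return self.weights.abs().max(axis=1)


@dataclass
class FusedFeatureSpec:
    """Ordered fused feature list: radiomics, then local, then global latents."""

    radiomics: list[str]
    local: list[str]
    global_: list[str]
    audit: dict = field(default_factory=dict)

    @property
    def columns(self) -> list[str]:
        return list(self.radiomics) + list(self.local) + list(self.global_)

    @property
    def width(self) -> int:
        return len(self.columns)


@dataclass(frozen=True)
class SelectionConfig:
    alpha_phase1: float = 0.5
    alpha_phase2: float = 1.0
    var_threshold: float = 1e-8
    ks_alpha: float = 0.01
    intercohort_r: float = 0.6
    redundancy_r: float = 0.5
    n_lambdas: int = 60
    lambda_decades: float = 3.0
    cv_folds: int = 10
    k_local: int = 5
    k_global: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        for nm in ("alpha_phase1", "alpha_phase2", "intercohort_r", "redundancy_r"):
            v = getattr(self, nm)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{nm}={v} outside [0, 1]")


def stability_filter(table_a: pd.DataFrame, table_b: pd.DataFrame,
                     var_threshold: float = 1e-8, ks_alpha: float = 0.01):
    """Keep columns stable in variance and distribution across both cohorts.

    Returns ``(retained_names, audit)`` where audit maps each removed column
    to the rule that fired ('variance' or 'distribution').
    """
    if list(table_a.columns) != list(table_b.columns):
        raise ValueError("column mismatch between cohorts")
    retained: list[str] = []
    audit: dict[str, str] = {}
    var_a = table_a.var(axis=0, ddof=0)
    var_b = table_b.var(axis=0, ddof=0)
    for col in table_a.columns:
        if var_a[col] < var_threshold or var_b[col] < var_threshold:
            audit[col] = "variance"
            continue
        p = stats.ks_2samp(table_a[col].to_numpy(), table_b[col].to_numpy()).pvalue
        if p < ks_alpha:
            audit[col] = "distribution"
            continue
        retained.append(col)
    return retained, audit


def elastic_net_fit(X: np.ndarray, y: np.ndarray, lam: float, alpha: float) -> np.ndarray:
    """Coordinate-descent solution of the penalized loss (no intercept).

    Minimizes ``(1/2n)||y - Xb||^2 + lam*(alpha*||b||_1 + (1-alpha)/2*||b||^2)``.
    ``lam = 0`` returns the least-squares solution.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if lam == 0:
        return np.linalg.lstsq(X, y, rcond=None)[0]
    model = ElasticNet(alpha=lam, l1_ratio=alpha, fit_intercept=False,
                       max_iter=50000, tol=1e-12)
    model.fit(X, y)
    return model.coef_


def _lambda_grid(X: np.ndarray, y: np.ndarray, alpha: float,
                 n_lambdas: int, decades: float) -> np.ndarray:
    n = X.shape[0]
    lam_max = np.max(np.abs(X.T @ (y - y.mean()))) / (n * max(alpha, 1e-3))
    lam_max = max(lam_max, 1e-6)
    return np.logspace(np.log10(lam_max), np.log10(lam_max) - decades, n_lambdas)


def elastic_net_path(X: pd.DataFrame, y, alpha: float,
                     lambdas: np.ndarray | None = None, folds: int = 10,
                     seed: int = 0, n_lambdas: int = 60,
                     lambda_decades: float = 3.0) -> SelectionResult:
    """One-vs-rest elastic net with CV-selected lambda (min mean MSE rule).

    ``y`` is a vector of class labels; each class is screened against the
    rest with a binary response, the CV curves are averaged over classes,
    lambda* minimizes the mean CV MSE, and the retained set is the union of
    nonzero supports at lambda*.
    """
    cols = list(X.columns)
    Xm = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    responses = [(y == c).astype(np.float64) for c in classes]
    if lambdas is None:
        grids = [_lambda_grid(Xm, r, alpha, n_lambdas, lambda_decades) for r in responses]
        lam_hi = max(g[0] for g in grids)
        lambdas = np.logspace(np.log10(lam_hi), np.log10(lam_hi) - lambda_decades, n_lambdas)
    lambdas = np.asarray(sorted(lambdas, reverse=True), dtype=np.float64)

    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    mse = np.zeros((len(classes), len(lambdas)))
    for ci, r in enumerate(responses):
        for tr, te in kf.split(Xm):
            if len(np.unique(r[tr])) < 2:
                raise ValueError("degenerate CV fold: a single class")
            x_mu = Xm[tr].mean(axis=0)
            r_mu = r[tr].mean()
            _, coefs, _ = enet_path(Xm[tr] - x_mu, r[tr] - r_mu,
                                    l1_ratio=max(alpha, 1e-3),
                                    alphas=lambdas, max_iter=3000)
            pred = (Xm[te] - x_mu) @ coefs + r_mu
            mse[ci] += np.mean((pred - r[te][:, None]) ** 2, axis=0)
    mse /= folds
    cv_curve = mse.mean(axis=0)
    best = int(np.argmin(cv_curve))
    lam_star = float(lambdas[best])

    weights = np.zeros((len(cols), len(classes)))
    for ci, r in enumerate(responses):
        model = ElasticNet(alpha=lam_star, l1_ratio=max(alpha, 1e-3), max_iter=5000)
        model.fit(Xm, r)
        weights[:, ci] = model.coef_
    wdf = pd.DataFrame(weights, index=cols, columns=[str(c) for c in classes])
    retained = [c for c in cols if np.any(np.abs(wdf.loc[c]) > 0)]
    return SelectionResult(retained=retained, weights=wdf, lambda_star=lam_star,
                           lambda_path=lambdas, cv_mse=cv_curve, alpha=alpha)


def cross_cohort_refine(result_a: SelectionResult, result_b: SelectionResult,
                        r_threshold: float = 0.6):
    """Keep features in both supports whose class-coefficient profiles agree.

    For each feature retained in both cohorts' alpha=1.0 screens, the
    Pearson correlation of its per-class weight profile across cohorts must
    exceed ``r_threshold``.  Returns ``(retained, audit)``.
    """
    common = [c for c in result_a.retained if c in set(result_b.retained)]
    if not common:
        raise ValueError("empty intersection of cohort supports")
    retained, audit = [], {}
    for col in common:
        wa = result_a.weights.loc[col].to_numpy(dtype=np.float64)
        wb = result_b.weights.loc[col].to_numpy(dtype=np.float64)
        if np.std(wa) == 0 or np.std(wb) == 0:
            audit[col] = "degenerate_profile"
            continue
        r = float(np.corrcoef(wa, wb)[0, 1])
        if r > r_threshold:
            retained.append(col)
        else:
            audit[col] = f"intercohort_r={r:.3f}"
    only_a = set(result_a.retained) - set(common)
    only_b = set(result_b.retained) - set(common)
    for col in sorted(only_a | only_b):
        audit[col] = "absent_in_other_cohort"
    return retained, audit


def prune_redundant(table: pd.DataFrame, weights: pd.Series, r_threshold: float = 0.5):
    """Greedy collinearity pruning ordered by |weight| descending.

    A feature is kept iff its absolute Pearson correlation with every
    already-kept feature does not exceed ``r_threshold``.
    Returns ``(retained, audit)``.
    """
    candidates = [c for c in weights.abs().sort_values(ascending=False, kind="stable").index
                  if c in table.columns]
    kept: list[str] = []
    audit: dict[str, str] = {}
    for col in candidates:
        ok = True
        for ref in kept:
            r = float(np.corrcoef(table[col].to_numpy(), table[ref].to_numpy())[0, 1])
            if abs(r) > r_threshold:
                audit[col] = f"collinear_with={ref}"
                ok = False
                break
        if ok:
            kept.append(col)
    return kept, audit


def _rank_latents(latents: pd.DataFrame, y, k: int, alpha: float, folds: int,
                  seed: int, n_lambdas: int, decades: float) -> list[str]:
    if k == 0 or latents.shape[1] == 0:
        return []
    res = elastic_net_path(latents, y, alpha=alpha, folds=folds, seed=seed,
                           n_lambdas=n_lambdas, lambda_decades=decades)
    mag = res.weight_magnitude()
    informative = mag[mag > 0]
    if len(informative) < k:
        raise ValueError(f"only {len(informative)} informative latent dimensions, requested {k}")
    ranked = informative.sort_values(ascending=False, kind="stable").index
    top = sorted(ranked[:k], key=lambda c: list(latents.columns).index(c))
    return list(top)


def select_features(tables_by_cohort: dict[str, pd.DataFrame],
                    labels_by_cohort: dict[str, np.ndarray],
                    local_latents: pd.DataFrame | None = None,
                    global_latents: pd.DataFrame | None = None,
                    latent_labels=None,
                    config: SelectionConfig = SelectionConfig()) -> FusedFeatureSpec:
    """Run the full cascade and emit the ordered fused feature specification.

    With two cohorts the cross-cohort rules (stage 1 distribution filter,
    stage 2b inter-cohort weight-profile correlation) apply; with a single
    cohort they are skipped and recorded as skipped in the audit.
    """
    names = sorted(tables_by_cohort)
    if not names:
        raise ValueError("need at least one cohort")
    primary = names[0]
    audit: dict = {"cohorts": names}
    table_a = tables_by_cohort[primary]
    y_a = labels_by_cohort[primary]

    # ---- stage 1: stability across cohorts
    if len(names) >= 2:
        table_b = tables_by_cohort[names[1]]
        stable, s1_audit = stability_filter(table_a, table_b,
                                            config.var_threshold, config.ks_alpha)
    else:
        var = table_a.var(axis=0, ddof=0)
        stable = [c for c in table_a.columns if var[c] >= config.var_threshold]
        s1_audit = {c: "variance" for c in table_a.columns if c not in set(stable)}
        s1_audit["__distribution_rule__"] = "skipped: single cohort"
    audit["stage1_removed"] = s1_audit
    if not stable:
        raise ValueError("no columns survive the stability filter")

    # ---- stage 2a: elastic-net screen (alpha = 0.5), min-MSE lambda
    res_a = elastic_net_path(table_a[stable], y_a, alpha=config.alpha_phase1,
                             folds=config.cv_folds, seed=config.seed,
                             n_lambdas=config.n_lambdas, lambda_decades=config.lambda_decades)
    screened = res_a.retained
    audit["stage2a"] = {"lambda_star": res_a.lambda_star, "n_retained": len(screened)}
    if len(names) >= 2:
        res_b0 = elastic_net_path(tables_by_cohort[names[1]][stable],
                                  labels_by_cohort[names[1]], alpha=config.alpha_phase1,
                                  folds=config.cv_folds, seed=config.seed,
                                  n_lambdas=config.n_lambdas,
                                  lambda_decades=config.lambda_decades)
        screened = [c for c in stable if c in set(res_a.retained) | set(res_b0.retained)]
        audit["stage2a"]["n_retained_union"] = len(screened)
    if not screened:
        raise ValueError("elastic-net screen retained no features")

    # ---- stage 2b: lasso refinement + inter-cohort weight-profile correlation
    lasso_a = elastic_net_path(table_a[screened], y_a, alpha=config.alpha_phase2,
                               folds=config.cv_folds, seed=config.seed,
                               n_lambdas=config.n_lambdas, lambda_decades=config.lambda_decades)
    if len(names) >= 2:
        lasso_b = elastic_net_path(tables_by_cohort[names[1]][screened],
                                   labels_by_cohort[names[1]], alpha=config.alpha_phase2,
                                   folds=config.cv_folds, seed=config.seed,
                                   n_lambdas=config.n_lambdas,
                                   lambda_decades=config.lambda_decades)
        refined, s2_audit = cross_cohort_refine(lasso_a, lasso_b, config.intercohort_r)
        weights = (lasso_a.weight_magnitude()[refined]
                   + lasso_b.weight_magnitude()[refined]) / 2.0
    else:
        refined = lasso_a.retained
        s2_audit = {"__intercohort_rule__": "skipped: single cohort"}
        weights = lasso_a.weight_magnitude()[refined]
    audit["stage2b_removed"] = s2_audit
    if not refined:
        raise ValueError("cross-cohort refinement retained no features")

    # ---- stage 3: redundancy pruning
    final, s3_audit = prune_redundant(table_a[refined], weights, config.redundancy_r)
    audit["stage3_removed"] = s3_audit
    audit["counts"] = {"input": table_a.shape[1], "stage1": len(stable),
                       "stage2a": len(screened), "stage2b": len(refined),
                       "stage3": len(final)}

    # ---- latent ranking by the same machinery
    yl = latent_labels if latent_labels is not None else y_a
    loc = _rank_latents(local_latents, yl, config.k_local, config.alpha_phase1,
                        config.cv_folds, config.seed, config.n_lambdas,
                        config.lambda_decades) if local_latents is not None else []
    glo = _rank_latents(global_latents, yl, config.k_global, config.alpha_phase1,
                        config.cv_folds, config.seed, config.n_lambdas,
                        config.lambda_decades) if global_latents is not None else []
    return FusedFeatureSpec(radiomics=final, local=loc, global_=glo, audit=audit)
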