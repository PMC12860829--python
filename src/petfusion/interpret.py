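"""Shapley-value attribution, cross-cohort concordance, group maps.

Shapley values use the interventional (marginal) value function:
``v(S)`` is the mean model output over background rows whose features in S
are replaced by the explained instance's values.  The exact estimator
enumerates all coalitions (feasible up to ~20 features); the sampled
estimator averages marginal contributions over random feature permutations
(each permutation telescopes, so additivity holds by construction) and
reports Monte-Carlo standard errors.  Cross-cohort reproducibility is
quantified as the Pearson correlation of per-class mean-|SHAP| importance
profiles between cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .volume import AttributionVolume

__all__ = ["ShapMatrix", "ImportanceProfile", "shapley_exact", "shapley_sampled",
           "importance_profile", "cohort_concordance", "group_average_map",
           "explain_instances"]


@dataclass
class ShapMatrix:
    """Per class: instances x features attribution matrix plus base values."""

    values: np.ndarray        # (classes, instances, features)
    base: np.ndarray          # (classes,) expected model output on background
    feature_names: list[str]
    class_names: list[str]
    standard_errors: np.ndarray | None = None

    def check_additivity(self, outputs: np.ndarray, atol: float = 1e-6) -> float:
        """Max |sum_j phi_j + base - f(x)| over instances and classes."""
        recon = self.values.sum(axis=2) + self.base[:, None]
        return float(np.max(np.abs(recon - outputs.T)))


@dataclass
class ImportanceProfile:
    """Per class: mean |phi| per feature."""

    table: pd.DataFrame       # features x classes, non-negative

    def ranked(self, class_name: str) -> pd.Series:
        return self.table[class_name].sort_values(ascending=False, kind="stable")


def _model_fn(model):
    if hasattr(model, "predict_proba"):
        return lambda X: np.asarray(model.predict_proba(X), dtype=np.float64)
    return lambda X: np.atleast_2d(np.asarray(model(X), dtype=np.float64).T).T


def _v_of_masks(fn, background: np.ndarray, instance: np.ndarray, masks: np.ndarray):
    """Mean model output for each coalition mask (rows of ``masks``)."""
    B, F = background.shape
    M = len(masks)
    hybrid = np.where(masks[:, None, :], instance[None, None, :],
                      background[None, :, :])                   # (M, B, F)
    out = fn(hybrid.reshape(M * B, F))
    return out.reshape(M, B, -1).mean(axis=1)                   # (M, n_outputs)


def shapley_exact(model, background, instance, feature_names=None):
    """Exact Shapley values by coalition enumeration (interventional v)."""
    background = np.asarray(background, dtype=np.float64)
    instance = np.asarray(instance, dtype=np.float64).ravel()
    if background.ndim != 2 or background.shape[0] == 0:
        raise ValueError("background must be a nonempty (rows, features) matrix")
    F = background.shape[1]
    if F > 20:
        raise ValueError(f"{F} features too many for exact enumeration (max 20)")
    fn = _model_fn(model)
    masks = ((np.arange(2 ** F)[:, None] >> np.arange(F)) & 1).astype(bool)
    v = _v_of_masks(fn, background, instance, masks)            # (2^F, C)
    n_out = v.shape[1]
    from math import factorial

    wt = np.array([factorial(s) * factorial(F - s - 1) / factorial(F) for s in range(F)])
    phi = np.zeros((F, n_out))
    sizes = masks.sum(axis=1)
    for i in range(F):
        without = ~masks[:, i]
        idx_wo = np.flatnonzero(without)
        idx_wi = idx_wo + (1 << i)
        w = wt[sizes[idx_wo]]
        phi[i] = (w[:, None] * (v[idx_wi] - v[idx_wo])).sum(axis=0)
    base = v[0]
    return phi, base


def shapley_sampled(model, background, instance, n_permutations: int = 500,
                    seed: int = 0):
    """Permutation-sampling Shapley estimates with Monte-Carlo standard errors.

    Additivity holds per permutation by telescoping; a final normalization
    distributes any residual numerical error uniformly across features.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    background = np.asarray(background, dtype=np.float64)
    if background.ndim != 2 or background.shape[0] == 0:
        raise ValueError("background must be a nonempty (rows, features) matrix")
    instance = np.asarray(instance, dtype=np.float64).ravel()
    F = background.shape[1]
    fn = _model_fn(model)
    rng = np.random.default_rng(seed)
    base = fn(background).mean(axis=0)
    fx = fn(instance[None, :])[0]
    n_out = len(base)
    contrib = np.zeros((n_permutations, F, n_out))
    for p in range(n_permutations):
        order = rng.permutation(F)
        masks = np.zeros((F + 1, F), dtype=bool)
        for step, j in enumerate(order, start=1):
            masks[step] = masks[step - 1]
            masks[step, j] = True
        v = _v_of_masks(fn, background, instance, masks)
        contrib[p, order] = v[1:] - v[:-1]
    phi = contrib.mean(axis=0)
    se = contrib.std(axis=0, ddof=1) / np.sqrt(n_permutations) if n_permutations > 1 \
        else np.zeros_like(phi)
    residual = (fx - base) - phi.sum(axis=0)
    phi += residual[None, :] / F
    return phi, base, se


def explain_instances(model, background, instances, n_permutations: int = 200,
                      seed: int = 0, feature_names=None, class_names=None,
                      exact: bool = False) -> ShapMatrix:
    """ShapMatrix over a batch of instances (rows)."""
    instances = np.asarray(instances, dtype=np.float64)
    background = np.asarray(background, dtype=np.float64)
    n, F = instances.shape
    fn = _model_fn(model)
    n_out = fn(background[:1]).shape[1]
    values = np.zeros((n_out, n, F))
    ses = np.zeros((n_out, n, F))
    base = None
    rng = np.random.default_rng(seed)
    for i in range(n):
        if exact:
            phi, base = shapley_exact(model, background, instances[i])
            se = np.zeros_like(phi)
        else:
            phi, base, se = shapley_sampled(model, background, instances[i],
                                            n_permutations=n_permutations,
                                            seed=int(rng.integers(2 ** 31 - 1)))
        values[:, i, :] = phi.T
        ses[:, i, :] = se.T
    fnames = list(feature_names) if feature_names is not None else [f"f{j}" for j in range(F)]
    cnames = list(class_names) if class_names is not None else [str(c) for c in range(n_out)]
    return ShapMatrix(values=values, base=np.asarray(base), feature_names=fnames,
                      class_names=cnames, standard_errors=ses)


def importance_profile(shap_matrix: ShapMatrix) -> ImportanceProfile:
    """Mean absolute Shapley value per feature, per class."""
    if shap_matrix.values.size == 0:
        raise ValueError("empty ShapMatrix")
    imp = np.abs(shap_matrix.values).mean(axis=1).T   # features x classes
    table = pd.DataFrame(imp, index=shap_matrix.feature_names,
                         columns=shap_matrix.class_names)
    return ImportanceProfile(table=table)


def cohort_concordance(profile_a: ImportanceProfile, profile_b: ImportanceProfile) -> pd.DataFrame:
    """Per-class Pearson r (with two-sided p) between mean-|SHAP| profiles."""
    shared = [f for f in profile_a.table.index if f in set(profile_b.table.index)]
    if len(shared) < 3:
        raise ValueError("need at least 3 shared features")
    classes = [c for c in profile_a.table.columns if c in profile_b.table.columns]
    rows = []
    for c in classes:
        a = profile_a.table.loc[shared, c].to_numpy()
        b = profile_b.table.loc[shared, c].to_numpy()
        r, p = stats.pearsonr(a, b)
        rows.append({"class": c, "pearson_r": float(r), "p_value": float(p)})
    return pd.DataFrame(rows).set_index("class")


def group_average_map(maps: list[AttributionVolume]) -> AttributionVolume:
    """Voxelwise mean of subject maps, re-normalized to [0, 1]."""
    if not maps:
        raise ValueError("empty map list")
    shapes = {m.data.shape for m in maps}
    if len(shapes) > 1:
        raise ValueError("geometry mismatch across maps")
    mean = np.mean([m.data for m in maps], axis=0)
    lo, hi = float(mean.min()), float(mean.max())
    norm = (mean - lo) / (hi - lo) if hi > lo else np.zeros_like(mean)
    first = maps[0]
    return AttributionVolume(norm, target_class=first.target_class,
                             source=first.source, spacing=first.spacing)


def summary_plot(profile: ImportanceProfile, class_name: str, path: str, top: int = 15) -> None:
    """Bar summary of the top mean-|SHAP| features for one class."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ranked = profile.ranked(class_name).head(top)[::-1]
    fig, ax = plt.subplots(figsize=(6, 0.3 * len(ranked) + 1))
    ax.barh(ranked.index, ranked.to_numpy())
    ax.set_xlabel("mean |SHAP|")
    ax.set_title(f"feature importance: {class_name}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
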