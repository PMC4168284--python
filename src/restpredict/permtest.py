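"""Permutation inference and max-statistic FWE feature identification.

Significance of a LOOCV statistic (classification accuracy or predicted-vs-
actual correlation) is assessed by rerunning the *entire* MVPA procedure —
feature selection included — under randomly permuted labels/scores.  The
default p-value uses the add-one formula (k+1)/(n_perm+1); the plain
proportion of null values >= observed is available with ``plain_p=True``.

Informative features are identified from fold-averaged, min-max-normalised
absolute model weights: per permutation the maximum of the averaged weight
map forms the null distribution, and the (1-alpha) quantile of those maxima
is the family-wise-error-corrected weight threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .mvpa import ClassificationResults, FoldResult, child_seed


@dataclass
class PermutationNull:
    """Null distribution of a LOOCV statistic under label/score permutation."""

    statistic_name: str
    null_values: np.ndarray
    observed: float
    p_value: float


@dataclass
class WeightMapSummary:
    """Max-statistic FWE identification of informative features."""

    modality: str
    mean_map: np.ndarray
    null_max_weights: np.ndarray
    fwe_threshold: float
    informative: np.ndarray


def _statistic(results) -> float:
    if isinstance(results, ClassificationResults):
        return results.accuracy
    return results.r_t1


def permutation_p(null_values, observed, plain_p: bool = False) -> float:
    null_values = np.asarray(null_values, dtype=float)
    k = int((null_values >= observed).sum())
    if plain_p:
        return k / null_values.size
    return (k + 1) / (null_values.size + 1)


def permutation_test(model, n_perm: int = 1000, seed: int = 0, *,
                     plain_p: bool = False, collect_weight_maps=None):
    """Permutation test of a :class:`GroupClassifier` / :class:`SymptomPredictor`.

    ``model.fit()`` gives the observed statistic; each permutation shuffles
    the targets and refits from scratch.  When ``collect_weight_maps`` is a
    ``(n_alff_features, n_fc_features)`` tuple, per-permutation averaged
    weight maps are gathered for FWE thresholding, and the function returns
    ``(PermutationNull, {"alff": [maps...], "fc": [maps...]})``; otherwise it
    returns the :class:`PermutationNull` alone.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    observed_res = model.fit()
    observed = _statistic(observed_res)
    name = "accuracy" if isinstance(observed_res, ClassificationResults) else "pearson_r"
    null_values = np.empty(n_perm)
    null_maps: dict[str, list[np.ndarray]] = {"alff": [], "fc": []}
    for b in range(n_perm):
        rng = np.random.default_rng(child_seed(seed, b))
        perm = rng.permutation(model.y)
        res = model.fit(perm, seed=child_seed(seed, b, 1))
        null_values[b] = _statistic(res)
        if collect_weight_maps is not None:
            n_alff, n_fc = collect_weight_maps
            null_maps["alff"].append(build_weight_map(res.fold_results, "alff", n_alff))
            null_maps["fc"].append(build_weight_map(res.fold_results, "fc", n_fc))
    null = PermutationNull(name, null_values, observed,
                           permutation_p(null_values, observed, plain_p))
    if collect_weight_maps is not None:
        return null, null_maps
    return null


def build_weight_map(fold_results: list[FoldResult], modality: str,
                     n_features: int) -> np.ndarray:
    """Fold-averaged normalised absolute model weights, full feature length.

    Per fold: the absolute SVM/SVR weights of the modality's *selected*
    features are min-max normalised to [0, 1] and scattered into a
    full-length map (never-selected features get 0); maps are then averaged
    across folds.  A fold whose weights are all equal normalises to all 1
    (degenerate min-max; documented rule).
    """
    if not fold_results:
        raise ValueError("need at least one fold")
    if modality not in ("alff", "fc"):
        raise ValueError(f"unknown modality {modality!r}")
    acc = np.zeros(n_features)
    for fold in fold_results:
        n_alff = len(fold.selected_alff)
        if modality == "alff":
            idx, w = fold.selected_alff, fold.model_weights[:n_alff]
        else:
            idx, w = fold.selected_fc, fold.model_weights[n_alff:]
        if len(idx) == 0:
            continue
        aw = np.abs(np.asarray(w, dtype=float))
        span = aw.max() - aw.min()
        norm = (aw - aw.min()) / span if span > 0 else np.ones_like(aw)
        fold_map = np.zeros(n_features)
        fold_map[np.asarray(idx, dtype=int)] = norm
        acc += fold_map
    return acc / len(fold_results)


def fwe_threshold(null_mean_maps, alpha: float = 0.05) -> float:
    """(1 - alpha) quantile ("higher" interpolation) of per-map maxima."""
    maxima = np.array([np.max(m) for m in null_mean_maps], dtype=float)
    if maxima.size == 0:
        raise ValueError("need at least one null map")
    return float(np.quantile(maxima, 1 - alpha, method="higher"))


def identify_informative(model, n_features: tuple[int, int], n_perm: int = 1000,
                         alpha: float = 0.05, seed: int = 0,
                         ) -> dict[str, WeightMapSummary]:
    """Run the full max-statistic FWE procedure for both modalities.

    Returns ``{"alff": WeightMapSummary, "fc": WeightMapSummary}`` built from
    the model's observed fit and ``n_perm`` permutation refits.
    """
    observed = model.fit()
    _, null_maps = permutation_test(model, n_perm=n_perm, seed=seed,
                                    collect_weight_maps=n_features)
    out = {}
    for modality, n_feat in zip(("alff", "fc"), n_features):
        mean_map = build_weight_map(observed.fold_results, modality, n_feat)
        thr = fwe_threshold(null_maps[modality], alpha=alpha)
        out[modality] = WeightMapSummary(
            modality=modality, mean_map=mean_map,
            null_max_weights=np.array([m.max() for m in null_maps[modality]]),
            fwe_threshold=thr,
            informative=np.flatnonzero(mean_map >= thr))
    return out


def edge_network_affiliation(edge_ids, n_regions: int, region_networks: dict,
                             default: str = "other") -> list[str]:
    """Network label per FC edge from a user-supplied region -> network map.

    An edge joining two regions of the same network inherits that network's
    name; mixed edges are labelled "netA-netB" (sorted); regions absent from
    the map fall back to ``default``.  Typical maps assign regions to the
    fronto-striato-thalamic or default-mode networks.
    """
    from .connectivity import upper_triangle_index_pairs

    pairs = upper_triangle_index_pairs(n_regions)
    out = []
    for e in np.asarray(edge_ids, dtype=int):
        i, j = pairs[e]
        a = region_networks.get(int(i) + 1, default)
        b = region_networks.get(int(j) + 1, default)
        out.append(a if a == b else "-".join(sorted((a, b))))
    return out


def correlate_informative(feature_table: np.ndarray, scores: np.ndarray,
                          features, alpha: float = 0.05,
                          feature_ids=None) -> pd.DataFrame:
    """Pearson r, p and significance class per informative feature.

    For the longitudinal variant pass feature *changes* and score *changes*.
    Each feature is classed ``significant-negative`` / ``significant-positive``
    (two-sided p < alpha) or ``non-significant``; constant features are
    reported as ``degenerate``.
    """
    feature_table = np.asarray(feature_table, dtype=float)
    scores = np.asarray(scores, dtype=float)
    features = np.asarray(features, dtype=int)
    rows = []
    for f in features:
        col = feature_table[:, f]
        fid = f if feature_ids is None else feature_ids[f]
        if col.std() == 0 or scores.std() == 0:
            rows.append({"feature": fid, "r": np.nan, "p": np.nan, "class": "degenerate"})
            continue
        r, p = scipy.stats.pearsonr(col, scores)
        if p < alpha:
            cls = "significant-negative" if r < 0 else "significant-positive"
        else:
            cls = "non-significant"
        rows.append({"feature": fid, "r": float(r), "p": float(p), "class": cls})
    return pd.DataFrame(rows)
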