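"""Wavelength selection and feature extraction on difference spectra.

Three reductions besides the wavelet route:

* SPA (successive projections algorithm): forward selection that, starting
  from a seed band, repeatedly picks the band whose projection orthogonal
  to the previously selected one has the largest norm, minimizing
  collinearity; candidate chains are then scored by cross-validated OLS
  RMSE and pruned by backward elimination.
* PCA: principal-component scores of the difference spectra, loadings
  fitted on the training split only.
* IRIV (iteratively retaining informative variables) with a synergy
  interval-PLS pre-screen: the 600-band grid is tiled into 30 intervals of
  20 bands; the best 4-interval combination by 10-fold PLS RMSECV seeds an
  iterative random-inclusion design whose per-band with/without RMSECV
  contrast (mean difference plus Mann-Whitney U test) keeps informative
  bands; highly inter-correlated survivors are finally collapsed to one
  representative each.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.sparse.csgraph import connected_components
from scipy.sparse import csr_matrix
from scipy.stats import mannwhitneyu
from sklearn.decomposition import PCA

from ._pls import kfold_indices, ols_cv_rmse, pls_cv_rmse, simpls_from_gram
from .differencing import DifferenceSet
from .features import FeatureSet
from .grid import N_BANDS, WL_MIN, band_wavelength

__all__ = [
    "spa_project",
    "spa_chain",
    "spa_select",
    "spa_features",
    "PcaResult",
    "pca_extract",
    "iriv_intervals",
    "interval_bounds",
    "SiplsResult",
    "sipls_joint_interval",
    "IrivResult",
    "iriv_iterate",
    "correlation_prune",
    "iriv_features",
]


# ---------------------------------------------------------------------------
# SPA
# ---------------------------------------------------------------------------

def spa_project(X: np.ndarray, k_prev: int,
                S: Sequence[int]) -> np.ndarray:
    """Project the columns in S onto the complement of column ``k_prev``.

    Returns the projected columns (n x |S|); each is orthogonal to
    ``X[:, k_prev]``.
    """
    X = np.asarray(X, dtype=float)
    pivot = X[:, k_prev]
    denom = float(pivot @ pivot)
    if denom <= 1e-300:
        raise ValueError(f"pivot column {k_prev} is zero")
    cols = X[:, list(S)]
    return cols - np.outer(pivot, (pivot @ cols) / denom)


def spa_chain(X: np.ndarray, k0: int, N: int) -> tuple[list[int], int]:
    """Forward SPA chain of N distinct band positions starting at ``k0``.

    Returns ``(chain, n_projections)``; the projection counter increments
    once per column projected, totalling (N-1)(J - N/2) for a full run.
    """
    X = np.asarray(X, dtype=float).copy()
    n, J = X.shape
    if not 1 <= N <= min(n, J):
        raise ValueError(f"N={N} exceeds min(samples, bands)={min(n, J)}")
    chain = [int(k0)]
    n_projections = 0
    for _ in range(1, N):
        S = [j for j in range(J) if j not in chain]
        proj = spa_project(X, chain[-1], S)
        n_projections += len(S)
        X[:, S] = proj
        norms = np.linalg.norm(proj, axis=0)
        best = int(np.argmax(norms))
        if norms[best] <= 1e-12:
            raise ValueError("design became rank deficient before reaching N")
        chain.append(S[best])
    return chain, n_projections


def spa_select(X: np.ndarray, y: np.ndarray,
               candidate_N_range: Sequence[int] = (5,),
               folds: int = 10, seed: int = 0,
               k0_candidates: Sequence[int] | None = None,
               prune: bool = True, prune_tol: float = 0.01) -> list[int]:
    """Full three-stage SPA band selection on a training set.

    Stage 1 builds a chain from every starting band; stage 2 scores each
    (k0, N) candidate subset by cross-validated OLS RMSE of ΔN on the
    subset and keeps the minimum; stage 3 backward-eliminates bands whose
    removal does not worsen RMSECV by more than ``prune_tol`` (relative).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, J = X.shape
    Ns = sorted(set(int(N) for N in candidate_N_range))
    if Ns[0] < 1 or Ns[-1] > min(n, J):
        raise ValueError("candidate N range outside rank limits")
    if k0_candidates is None:
        k0_candidates = range(J)
    fold_idx = kfold_indices(n, folds, seed)

    best_rmse, best_bands = np.inf, None
    for k0 in k0_candidates:
        chain, _ = spa_chain(X, k0, Ns[-1])
        for N in Ns:
            bands = chain[:N]
            rmse = ols_cv_rmse(X[:, bands], y, fold_idx=fold_idx)
            if rmse < best_rmse:
                best_rmse, best_bands = rmse, list(bands)
    assert best_bands is not None

    if prune:
        while len(best_bands) > 1:
            trials = []
            for i in range(len(best_bands)):
                sub = best_bands[:i] + best_bands[i + 1:]
                trials.append((ols_cv_rmse(X[:, sub], y, fold_idx=fold_idx), i))
            rmse_drop, i_drop = min(trials)
            if rmse_drop <= best_rmse * (1.0 + prune_tol):
                best_rmse = min(best_rmse, rmse_drop)
                del best_bands[i_drop]
            else:
                break
    return sorted(best_bands)


def spa_features(diffs: DifferenceSet,
                 candidate_N_range: Sequence[int] = (5,),
                 folds: int = 10, seed: int = 0,
                 prune: bool = True) -> FeatureSet:
    """SPA-selected band differences as model features (bands fit on train)."""
    bands = spa_select(diffs.delta_r[diffs.train_mask],
                       diffs.delta_n[diffs.train_mask],
                       candidate_N_range=candidate_N_range,
                       folds=folds, seed=seed, prune=prune)
    return FeatureSet(
        X=diffs.delta_r[:, bands],
        sample_ids=diffs.sample_ids,
        method="spa",
        split=diffs.split,
        meta={"bands": bands,
              "wavelengths_nm": [band_wavelength(b) for b in bands]},
    )


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PcaResult:
    """Training-set principal components of the difference spectra."""

    loadings: np.ndarray          # (600, k), orthonormal columns
    scores: np.ndarray            # (n_all, k), train-fitted projection
    explained_variance: np.ndarray  # (k,), decreasing
    mean: np.ndarray              # (600,), training mean spectrum


def pca_extract(diffs: DifferenceSet,
                n_components: int = 5) -> tuple[PcaResult, FeatureSet]:
    """Principal-component scores as features.

    Loadings and centering are fitted on the training split only; held-out
    samples are projected with the training loadings (no leakage).
    """
    Xtr = diffs.delta_r[diffs.train_mask]
    if n_components >= len(Xtr):
        raise ValueError("n_components must be smaller than the number of "
                         "training samples")
    if n_components > min(Xtr.shape):
        raise ValueError("n_components exceeds the rank limit")
    pca = PCA(n_components=n_components, svd_solver="full")
    pca.fit(Xtr)
    scores = pca.transform(diffs.delta_r)
    result = PcaResult(
        loadings=pca.components_.T,
        scores=scores,
        explained_variance=pca.explained_variance_,
        mean=pca.mean_,
    )
    feats = FeatureSet(
        X=scores,
        sample_ids=diffs.sample_ids,
        method="pca",
        split=diffs.split,
        meta={"n_components": n_components,
              "explained_variance_ratio":
                  pca.explained_variance_ratio_.tolist()},
    )
    return result, feats


# ---------------------------------------------------------------------------
# IRIV with synergy-interval-PLS pre-screen
# ---------------------------------------------------------------------------

N_INTERVALS = 30
INTERVAL_WIDTH = 20


def iriv_intervals(n_bands: int = N_BANDS) -> list[np.ndarray]:
    """Tile the grid into 30 contiguous 20-band intervals (0-based indices)."""
    if n_bands != N_INTERVALS * INTERVAL_WIDTH:
        raise ValueError(f"grid must have {N_INTERVALS * INTERVAL_WIDTH} bands")
    return [np.arange(k * INTERVAL_WIDTH, (k + 1) * INTERVAL_WIDTH)
            for k in range(N_INTERVALS)]


def interval_bounds(k: int) -> tuple[int, int]:
    """Wavelength bounds (nm) of 1-based interval k: 401+20(k-1) .. 400+20k."""
    if not 1 <= k <= N_INTERVALS:
        raise ValueError(f"interval index {k} outside 1-{N_INTERVALS}")
    lo = WL_MIN + INTERVAL_WIDTH * (k - 1)
    return lo, lo + INTERVAL_WIDTH - 1


@dataclass(frozen=True)
class SiplsResult:
    combo: tuple[int, ...]        # 1-based interval ids, ascending
    bands: np.ndarray             # 0-based band indices of the joint interval
    rmsecv: float
    n_combinations: int


def sipls_joint_interval(X: np.ndarray, y: np.ndarray,
                         n_intervals_joint: int = 4,
                         folds: int = 10, seed: int = 0,
                         n_components: int = 5,
                         intervals: Sequence[np.ndarray] | None = None
                         ) -> SiplsResult:
    """Best joint interval by exhaustive synergy-interval PLS.

    Evaluates every combination of ``n_intervals_joint`` intervals with a
    seeded K-fold PLS RMSECV and returns the minimizer.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if intervals is None:
        intervals = iriv_intervals(X.shape[1])
    if folds > len(y):
        raise ValueError("fold count exceeds sample count")
    n = len(y)
    fold_idx = kfold_indices(n, folds, seed)

    # Per-fold centered cross-products, computed once; every interval
    # combination then slices them instead of refitting from raw data.
    folds_pre = []
    for test in fold_idx:
        train = np.setdiff1d(np.arange(n), test)
        Xtr, ytr = X[train], y[train]
        xm, ym = Xtr.mean(axis=0), float(ytr.mean())
        Xc = Xtr - xm
        folds_pre.append({
            "G": Xc.T @ Xc, "s0": Xc.T @ (ytr - ym),
            "xm": xm, "ym": ym,
            "Xte": X[test], "yte": y[test],
        })

    best = (np.inf, None)
    count = 0
    for combo in itertools.combinations(range(len(intervals)),
                                        n_intervals_joint):
        count += 1
        bands = np.concatenate([intervals[k] for k in combo])
        ix = np.ix_(bands, bands)
        sq = 0.0
        for f in folds_pre:
            beta = simpls_from_gram(f["G"][ix], f["s0"][bands], n_components)
            pred = (f["Xte"][:, bands] - f["xm"][bands]) @ beta + f["ym"]
            sq += float(np.sum((f["yte"] - pred) ** 2))
        rmse = float(np.sqrt(sq / n))
        if rmse < best[0]:
            best = (rmse, combo)
    rmse, combo = best
    assert combo is not None
    bands = np.concatenate([intervals[k] for k in combo])
    return SiplsResult(combo=tuple(k + 1 for k in combo), bands=bands,
                       rmsecv=float(rmse), n_combinations=count)


@dataclass(frozen=True)
class IrivResult:
    retained: list[int]                   # surviving 0-based band indices
    history: list[dict] = field(default_factory=list)  # per-round diagnostics


def iriv_iterate(X: np.ndarray, y: np.ndarray, bands: Sequence[int],
                 max_rounds: int = 5, n_rows: int = 50,
                 include_prob: float = 0.5, folds: int = 5,
                 n_components: int = 5, alpha: float = 0.05,
                 seed: int = 0) -> IrivResult:
    """Iteratively retain informative variables among ``bands``.

    Each round draws a random binary inclusion matrix over the current
    bands, scores every row (variable combination) by PLS RMSECV, and for
    each band contrasts the RMSECV of rows including it against rows
    excluding it: a positive mean difference (exclusion hurts) marks the
    band informative ("strong" if the Mann-Whitney U test is significant
    at ``alpha``, "weak" otherwise); bands with non-positive difference
    (uninformative or interfering) are dropped.  Iterates until the set is
    stable or ``max_rounds``; a final backward-elimination pass removes
    bands whose removal improves RMSECV.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    current = list(dict.fromkeys(int(b) for b in bands))
    if len(current) < 1:
        raise ValueError("need at least one band")
    if len(current) == 1:
        return IrivResult(retained=current)
    rng = np.random.default_rng(seed)
    history: list[dict] = []

    for round_no in range(1, max_rounds + 1):
        p = len(current)
        if p <= 2:
            break
        B = rng.random((n_rows, p)) < include_prob
        # ensure usable rows and both arms for every band
        B[B.sum(axis=1) < 2] = True
        for j in range(p):
            if B[:, j].all():
                B[rng.integers(n_rows), j] = False
            elif not B[:, j].any():
                B[rng.integers(n_rows), j] = True
        fold_idx = kfold_indices(len(y), folds,
                                 int(rng.integers(2**31 - 1)))
        rmse_rows = np.array([
            pls_cv_rmse(X[:, np.asarray(current)[row]], y,
                        n_components=n_components, fold_idx=fold_idx)
            for row in B
        ])
        dmean = np.empty(p)
        pvals = np.empty(p)
        for j in range(p):
            with_j = rmse_rows[B[:, j]]
            without_j = rmse_rows[~B[:, j]]
            dmean[j] = float(without_j.mean() - with_j.mean())
            pvals[j] = float(mannwhitneyu(with_j, without_j,
                                          alternative="two-sided").pvalue)
        keep = dmean > 0
        classes = np.where(keep,
                           np.where(pvals < alpha, "strong", "weak"),
                           np.where(pvals < alpha, "interfering",
                                    "uninformative"))
        history.append({"round": round_no, "bands": list(current),
                        "dmean": dmean.tolist(), "p_values": pvals.tolist(),
                        "classes": classes.tolist()})
        new = [b for b, k in zip(current, keep) if k]
        if len(new) == 0:
            raise ValueError(
                "IRIV dropped every band; the response appears unrelated to "
                f"the candidates (round {round_no}, dmean max {dmean.max():.3g})")
        if new == current:
            current = new
            break
        current = new

    # one backward-elimination pass over the survivors
    if len(current) > 1:
        fold_idx = kfold_indices(len(y), folds, int(rng.integers(2**31 - 1)))
        base = pls_cv_rmse(X[:, current], y, n_components=n_components,
                           fold_idx=fold_idx)
        for b in list(current):
            if len(current) == 1:
                break
            trial = [c for c in current if c != b]
            rmse = pls_cv_rmse(X[:, trial], y, n_components=n_components,
                               fold_idx=fold_idx)
            if rmse < base:
                current = trial
                base = rmse
    return IrivResult(retained=current, history=history)


def correlation_prune(X: np.ndarray, y: np.ndarray, bands: Sequence[int],
                      r_threshold: float = 0.9) -> list[int]:
    """Collapse groups of mutually correlated bands to one representative.

    Bands whose pairwise |r| exceeds the threshold are grouped (transitively);
    each group keeps the band most correlated with ΔN.
    """
    bands = list(dict.fromkeys(int(b) for b in bands))
    if len(bands) == 0:
        raise ValueError("need at least one band")
    if len(bands) == 1:
        return bands
    Xb = np.asarray(X, dtype=float)[:, bands]
    y = np.asarray(y, dtype=float)
    C = np.corrcoef(Xb, rowvar=False)
    adj = (np.abs(C) > r_threshold).astype(int)
    np.fill_diagonal(adj, 0)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    y_corr = np.abs([np.corrcoef(Xb[:, j], y)[0, 1] for j in range(len(bands))])
    kept = []
    for g in range(n_comp):
        members = np.flatnonzero(labels == g)
        kept.append(bands[members[np.argmax(y_corr[members])]])
    return sorted(kept)


def iriv_features(diffs: DifferenceSet,
                  folds_sipls: int = 10, folds_iriv: int = 5,
                  r_threshold: float = 0.9, seed: int = 0) -> FeatureSet:
    """Full IRIV reduction: siPLS pre-screen, IRIV rounds, correlation prune.

    All selection runs on the training split; the feature matrix is the
    difference reflectance at the surviving bands for every sample.
    """
    Xtr = diffs.delta_r[diffs.train_mask]
    ytr = diffs.delta_n[diffs.train_mask]
    sipls = sipls_joint_interval(Xtr, ytr, folds=folds_sipls, seed=seed)
    iriv = iriv_iterate(Xtr, ytr, sipls.bands, folds=folds_iriv, seed=seed)
    bands = correlation_prune(Xtr, ytr, iriv.retained,
                              r_threshold=r_threshold)
    return FeatureSet(
        X=diffs.delta_r[:, bands],
        sample_ids=diffs.sample_ids,
        method="iriv",
        split=diffs.split,
        meta={"joint_intervals": list(sipls.combo),
              "bands_after_iriv": iriv.retained,
              "bands": bands,
              "wavelengths_nm": [band_wavelength(b) for b in bands]},
    )
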