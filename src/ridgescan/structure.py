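"""Fine-scale population structure from dominant (presence/absence) markers.

Workflow: minor-variant frequency QC, K-means with the Calinski-Harabasz
criterion to choose the number of gene pools, repeated fuzzy c-means runs
(fuzzification m close to 1, as appropriate for well-separated binary pools),
greedy label alignment across runs (CLUMPP-style, similarity
G = 1 - ||Q1 - Q2||_F / sqrt(2 n)), and thresholded assignment: membership to
population A above 0.8 -> A, below 0.2 -> B, otherwise admixed.

No Hardy-Weinberg or dosage assumptions are made anywhere: genotypes enter as
raw 0/1 band indicators, which is the appropriate treatment for dominant
markers in polyploids.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

__all__ = ["StructureResult", "qc_filter", "choose_k", "cmeans_run",
           "align_runs", "assign", "run_structure"]


@dataclass
class StructureResult:
    K: int
    calinski: dict[int, float]
    membership: np.ndarray        # mean coefficient to population A, per individual
    membership_sd: np.ndarray     # SD across aligned runs
    assignment: np.ndarray        # "A" | "B" | "admixed"
    similarity: float             # mean pairwise G among aligned runs
    ids: list[str] | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "id": self.ids if self.ids is not None else np.arange(len(self.membership)),
            "membership": self.membership,
            "membership_sd": self.membership_sd,
            "assignment": self.assignment,
        })


# ---------------------------------------------------------------------------
# QC

def qc_filter(raw: pd.DataFrame, maf_min: float = 0.05) -> pd.DataFrame:
    """Drop loci whose minor-variant frequency is <= ``maf_min`` (computed on
    non-missing calls) and report the removals in ``DataFrame.attrs``."""
    freq = raw.mean(axis=0, skipna=True)
    keep = np.minimum(freq, 1.0 - freq) > maf_min
    if not keep.any():
        raise ValueError("no locus survives the minor-variant frequency filter")
    out = raw.loc[:, keep.to_numpy()]
    out.attrs["n_removed"] = int((~keep).sum())
    out.attrs["removed_loci"] = list(raw.columns[~keep.to_numpy()])
    return out


def _impute(gm: pd.DataFrame) -> np.ndarray:
    """Per-locus mean imputation of missing genotypes (clustering only; the
    association scan never sees imputed values)."""
    x = gm.to_numpy(dtype=float)
    if np.isnan(x).any():
        means = np.nanmean(x, axis=0)
        idx = np.where(np.isnan(x))
        x[idx] = means[idx[1]]
    return x


# ---------------------------------------------------------------------------
# Number of clusters

def calinski_harabasz(x: np.ndarray, labels: np.ndarray) -> float:
    """[between-SS / (k-1)] / [within-SS / (n-k)]."""
    n = x.shape[0]
    ks = np.unique(labels)
    k = len(ks)
    overall = x.mean(axis=0)
    between = 0.0
    within = 0.0
    for lab in ks:
        xs = x[labels == lab]
        c = xs.mean(axis=0)
        between += len(xs) * float(((c - overall) ** 2).sum())
        within += float(((xs - c) ** 2).sum())
    if k == 1 or within == 0:
        return np.inf
    return (between / (k - 1)) / (within / (n - k))


def choose_k(gm: pd.DataFrame, k_range: range = range(2, 21), n_init: int = 10,
             seed: int = 0) -> tuple[int, dict[int, float]]:
    """K-means over ``k_range`` with ``n_init`` restarts; returns the
    Calinski-Harabasz-maximizing K and the full criterion map."""
    x = _impute(gm)
    crit: dict[int, float] = {}
    for k in k_range:
        if k >= x.shape[0]:
            break
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
        labels = km.fit_predict(x)
        if len(np.unique(labels)) < k:
            continue  # degenerate empty cluster
        crit[k] = calinski_harabasz(x, labels)
    if not crit:
        raise ValueError("no valid K in range")
    best = max(crit, key=lambda k: (crit[k], -k))
    return best, crit


# ---------------------------------------------------------------------------
# Fuzzy c-means

def cmeans_run(gm: pd.DataFrame, K: int = 2, m: float = 1.02,
               max_iter: int = 1_000_000, seed: int = 0, tol: float = 1e-8,
               ) -> np.ndarray:
    """One fuzzy c-means run; returns the n x K membership matrix (rows sum
    to 1).

    Standard updates: memberships proportional to squared distance to each
    centroid raised to -1/(m-1), centroids as membership^m-weighted means;
    iterate until centroid movement < ``tol`` or ``max_iter``.  With m near 1
    the memberships are close to hard and convergence is fast.  Memberships
    are computed in log space to stay finite at small m.
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    rng = np.random.default_rng(seed)
    x = _impute(gm)
    n = x.shape[0]
    centroids = x[rng.choice(n, size=K, replace=False)]
    expo = 1.0 / (m - 1.0)
    u = np.full((n, K), 1.0 / K)
    for _ in range(max_iter):
        d2 = ((x[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        d2 = np.maximum(d2, 1e-12)
        logu = -expo * np.log(d2)
        logu -= logu.max(axis=1, keepdims=True)
        u = np.exp(logu)
        u /= u.sum(axis=1, keepdims=True)
        w = u ** m
        new_centroids = (w.T @ x) / w.sum(axis=0)[:, None]
        move = np.abs(new_centroids - centroids).max()
        centroids = new_centroids
        if move < tol:
            break
    return u


# ---------------------------------------------------------------------------
# Run alignment (label switching)

def _similarity(q1: np.ndarray, q2: np.ndarray) -> float:
    """CLUMPP-style G: 1 - ||Q1 - Q2||_F / sqrt(2 n), in [0, 1]."""
    n = q1.shape[0]
    return 1.0 - np.linalg.norm(q1 - q2) / np.sqrt(2.0 * n)


def _best_perm(reference: np.ndarray, run: np.ndarray) -> tuple[int, ...]:
    K = run.shape[1]
    best, best_g = None, -np.inf
    for perm in itertools.permutations(range(K)):
        g = _similarity(reference, run[:, perm])
        if g > best_g:
            best_g, best = g, perm
    return best


def align_runs(runs: list[np.ndarray], n_repeats: int = 10_000, seed: int = 0,
               ids: list[str] | None = None, calinski: dict[int, float] | None = None,
               ) -> StructureResult:
    """Greedy alignment of membership matrices across runs.

    Runs are added one at a time in random order; each new run's column
    permutation is chosen to maximize G against the running average.  The
    procedure is repeated over ``n_repeats`` random input orders and the
    ordering with the best mean pairwise G is kept.  The output membership is
    the mean (and SD) of the aligned coefficients to the first cluster
    column, oriented deterministically (column A = the column with the larger
    loading of the first individual in the best alignment).
    """
    if len(runs) < 2:
        raise ValueError("need at least two runs to align")
    K = runs[0].shape[1]
    if any(r.shape != runs[0].shape for r in runs):
        raise ValueError("runs have inconsistent shapes (K or n differ)")
    rng = np.random.default_rng(seed)
    best_sim, best_aligned = -np.inf, None
    for _ in range(n_repeats):
        order = rng.permutation(len(runs))
        aligned = [runs[order[0]]]
        total = runs[order[0]].copy()
        for idx in order[1:]:
            perm = _best_perm(total / len(aligned), runs[idx])
            a = runs[idx][:, perm]
            aligned.append(a)
            total += a
        sims = [_similarity(a, b) for a, b in itertools.combinations(aligned, 2)]
        mean_sim = float(np.mean(sims))
        if mean_sim > best_sim:
            best_sim = mean_sim
            best_aligned = np.stack(aligned)
    assert best_aligned is not None
    mean = best_aligned.mean(axis=0)
    col = int(np.argmax(mean[0]))  # deterministic orientation
    membership = best_aligned[:, :, col].mean(axis=0)
    sd = best_aligned[:, :, col].std(axis=0, ddof=0)
    return StructureResult(
        K=K, calinski=calinski or {}, membership=membership, membership_sd=sd,
        assignment=assign(membership), similarity=best_sim, ids=ids,
    )


def assign(membership: np.ndarray) -> np.ndarray:
    """Thresholded labels: > 0.8 -> A, < 0.2 -> B, otherwise admixed (strict
    inequalities: exactly 0.2 or 0.8 is admixed)."""
    m = np.asarray(membership)
    out = np.full(m.shape, "admixed", dtype=object)
    out[m > 0.8] = "A"
    out[m < 0.2] = "B"
    return out


# ---------------------------------------------------------------------------
# Convenience driver

def run_structure(gm: pd.DataFrame, k_range: range = range(2, 21),
                  n_runs: int = 50, greedy_repeats: int = 200, m: float = 1.02,
                  seed: int = 0, maf_min: float = 0.05, force_k: int | None = None,
                  ) -> StructureResult:
    """QC -> choose K -> repeated c-means -> alignment, in one call."""
    gm = qc_filter(gm, maf_min)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 7]))
    if force_k is None:
        K, crit = choose_k(gm, k_range, seed=int(rng.integers(2**31)))
    else:
        K, crit = force_k, {}
    runs = [cmeans_run(gm, K=K, m=m, seed=int(rng.integers(2**31)))
            for _ in range(n_runs)]
    return align_runs(runs, n_repeats=greedy_repeats,
                      seed=int(rng.integers(2**31)),
                      ids=list(gm.index), calinski=crit)
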