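"""Region PCA and its group-discrimination readouts.

PCA is run on mean-centered (not variance-scaled) second-derivative
region matrices. Group discrimination is read off the scores the way
spectroscopists do by eye on a scores plot: which side of a component
each group falls on, and which quadrant of a two-component plane, with
the loading extrema naming the wavenumbers that drive the separation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectra_io import SpectraSet

__all__ = [
    "PCAResult",
    "SideSeparation",
    "QuadrantReport",
    "LoadingPeak",
    "pca",
    "pc_side_separation",
    "quadrant_assign",
    "loading_peaks",
]


@dataclass
class PCAResult:
    scores: np.ndarray                 # n_samples x k
    loadings: np.ndarray               # k x n_points, rows unit-norm
    explained_variance_pct: np.ndarray  # length k
    grid: np.ndarray                   # region wavenumbers
    labels: list[str]
    sample_ids: list[str]
    centering_mean: np.ndarray

    @property
    def k(self) -> int:
        return self.scores.shape[1]


def pca(sset: SpectraSet, k: int = 4) -> "PCAResult":
    """Principal component analysis of a spectra matrix by SVD.

    The matrix is column-mean centered only; explained variance per
    component is 100*sigma_i^2 / sum(sigma^2) over ALL singular values.
    Deterministic sign convention: each loading row is flipped so that
    its largest-magnitude element is positive (scores flipped to match).
    """
    X = sset.matrix
    n = X.shape[0]
    if n < 2:
        raise ValueError("PCA needs at least 2 samples")
    if k < 1 or k > min(n - 1, X.shape[1]):
        raise ValueError(f"k={k} out of range; must be 1..min(n_samples-1, n_points)")
    mean = X.mean(axis=0)
    Xc = X - mean
    if not np.any(np.abs(Xc) > 1e-14 * max(1.0, np.max(np.abs(X)))):
        raise ValueError("zero-variance matrix: all rows identical")
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2
    expl = 100.0 * var / var.sum()
    scores = U[:, :k] * s[:k]
    loadings = Vt[:k]
    # sign convention for reproducibility across BLAS/platforms
    for i in range(k):
        j = int(np.argmax(np.abs(loadings[i])))
        if loadings[i, j] < 0:
            loadings[i] = -loadings[i]
            scores[:, i] = -scores[:, i]
    return PCAResult(
        scores=scores, loadings=loadings, explained_variance_pct=expl[:k],
        grid=sset.grid.copy(), labels=list(sset.labels),
        sample_ids=list(sset.sample_ids), centering_mean=mean,
    )


# ---------------------------------------------------------------------------
# discrimination readouts
# ---------------------------------------------------------------------------

@dataclass
class SideSeparation:
    """Per-group sign structure of one component's scores."""
    pc_index: int                       # 1-based
    positive_fraction: dict[str, float]  # group -> fraction of samples with score > 0
    clean_separation: bool
    positive_groups: tuple[str, ...]     # the separating bipartition, if clean
    negative_groups: tuple[str, ...]


def pc_side_separation(result: PCAResult, pc_index: int) -> SideSeparation:
    """Which side of component ``pc_index`` (1-based) each group occupies.

    ``clean_separation`` is true iff the groups can be bipartitioned so
    that every sample's score sign matches its group's side. A score of
    exactly zero counts as nonpositive.
    """
    if not 1 <= pc_index <= result.k:
        raise ValueError(f"pc_index {pc_index} out of range 1..{result.k}")
    sc = result.scores[:, pc_index - 1]
    groups = sorted(set(result.labels))
    pos_frac = {}
    all_pos, all_neg = set(), set()
    for g in groups:
        vals = sc[[i for i, lbl in enumerate(result.labels) if lbl == g]]
        pos_frac[g] = float(np.mean(vals > 0))
        if np.all(vals > 0):
            all_pos.add(g)
        elif np.all(vals <= 0):
            all_neg.add(g)
    clean = bool(all_pos and all_neg and len(all_pos) + len(all_neg) == len(groups))
    return SideSeparation(
        pc_index=pc_index, positive_fraction=pos_frac, clean_separation=clean,
        positive_groups=tuple(sorted(all_pos)) if clean else (),
        negative_groups=tuple(sorted(all_neg)) if clean else (),
    )


@dataclass
class QuadrantReport:
    """Quadrant membership of samples on a (PC-i, PC-j) score plane.

    Quadrants follow the mathematical convention on (score_i, score_j):
    Q1=(+,+), Q2=(-,+), Q3=(-,-), Q4=(+,-). Samples with a zero score on
    either axis are flagged on-axis and excluded from group purity.
    """
    pc_pair: tuple[int, int]
    quadrant: list[str | None]           # per sample: "Q1".."Q4" or None if on-axis
    on_axis: list[bool]
    majority_quadrant: dict[str, str]
    purity: dict[str, float]


def quadrant_assign(result: PCAResult, pc_i: int, pc_j: int) -> QuadrantReport:
    """Assign every sample to a quadrant of the (pc_i, pc_j) score plane."""
    for p in (pc_i, pc_j):
        if not 1 <= p <= result.k:
            raise ValueError(f"PC index {p} out of range 1..{result.k}")
    si = result.scores[:, pc_i - 1]
    sj = result.scores[:, pc_j - 1]
    quadrant: list[str | None] = []
    on_axis: list[bool] = []
    for a, b in zip(si, sj):
        if a == 0 or b == 0:
            quadrant.append(None)
            on_axis.append(True)
        else:
            quadrant.append("Q1" if (a > 0 and b > 0) else
                            "Q2" if (a < 0 and b > 0) else
                            "Q3" if (a < 0 and b < 0) else "Q4")
            on_axis.append(False)
    majority, purity = {}, {}
    for g in sorted(set(result.labels)):
        qs = [q for q, lbl in zip(quadrant, result.labels) if lbl == g and q is not None]
        if not qs:
            continue
        counts = {q: qs.count(q) for q in set(qs)}
        best = max(sorted(counts), key=counts.get)
        majority[g] = best
        purity[g] = counts[best] / len(qs)
    return QuadrantReport(pc_pair=(pc_i, pc_j), quadrant=quadrant, on_axis=on_axis,
                          majority_quadrant=majority, purity=purity)


@dataclass
class LoadingPeak:
    wavenumber: float
    value: float          # signed loading value at the extremum
    side: str             # "positive" (local max) or "negative" (local min)


def loading_peaks(result: PCAResult, pc_index: int, min_prominence: float = 0.1) -> list[LoadingPeak]:
    """Local extrema of one loading row, the bands that drive a component.

    Local maxima are reported as side "positive", local minima as side
    "negative"; only extrema with |value| >= min_prominence * max|loading|
    are kept, sorted by |value| descending. A flat loading yields [].
    """
    if not 1 <= pc_index <= result.k:
        raise ValueError(f"pc_index {pc_index} out of range 1..{result.k}")
    v = result.loadings[pc_index - 1]
    vmax = np.max(np.abs(v))
    if vmax <= 0:
        return []
    peaks: list[LoadingPeak] = []
    for i in range(1, v.size - 1):
        if v[i] > v[i - 1] and v[i] >= v[i + 1] and v[i] > 0:
            peaks.append(LoadingPeak(float(result.grid[i]), float(v[i]), "positive"))
        elif v[i] < v[i - 1] and v[i] <= v[i + 1] and v[i] < 0:
            peaks.append(LoadingPeak(float(result.grid[i]), float(v[i]), "negative"))
    peaks = [p for p in peaks if abs(p.value) >= min_prominence * vmax]
    return sorted(peaks, key=lambda p: -abs(p.value))


def best_separating_pc(result: PCAResult, max_pc: int | None = None) -> SideSeparation | None:
    """First component (lowest index) whose score signs cleanly bipartition
    the groups, or None when no component up to ``max_pc`` separates."""
    upper = min(result.k, max_pc or result.k)
    for idx in range(1, upper + 1):
        sep = pc_side_separation(result, idx)
        if sep.clean_separation:
            return sep
    return None
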