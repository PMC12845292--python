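"""Physiology computations: chlorophyll fluorescence, chlorosis scoring,
metal percent-change, correlation PCA, and ANOSIM.

Fluorescence parameters follow the standard pulse-amplitude-modulation
definitions: the maximum quantum yield of photosystem II from dark-adapted
leaves is Fv/Fm = (Fm - F0)/Fm, and the effective quantum yield under
actinic light is Y(II) = (Fm' - Fs)/Fm'.  Both are dimensionless ratios in
[0, 1] and invariant to the instrument's arbitrary fluorescence units.

Chlorosis is scored from RGB leaf images via the mean HSV hue angle of the
central leaflet region: a region of at least 5000 pixels whose circular
mean hue lies in the yellow-green band [55 deg, 70 deg] and is shifted by
more than 10 deg from a healthy reference hue is called chlorotic.

PCA is run in correlation mode (variables standardized to unit variance,
matching R's prcomp with scale = TRUE), so eigenvalues sum to the number
of variables and each variance fraction is eigenvalue / n_variables.
ANOSIM is the rank-based permutation statistic
R = (mean between-group rank - mean within-group rank) / (M / 2) with
M = n(n-1)/2 pairwise distances.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Literal, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

__all__ = [
    "fv_fm",
    "yield_ii",
    "percent_change",
    "ChlorosisCall",
    "hue_chlorosis",
    "circular_mean_hue",
    "PCAResult",
    "pca_correlation",
    "eigenvalue_from_fraction",
    "fraction_from_eigenvalue",
    "AnosimResult",
    "anosim",
]


def fv_fm(f0: float, fm: float) -> float:
    """Maximum PSII quantum yield (Fm - F0) / Fm from dark-adapted readings."""
    if fm <= 0:
        raise ValueError("Fm must be > 0")
    if not 0 <= f0 <= fm:
        raise ValueError("require 0 <= F0 <= Fm")
    return (fm - f0) / fm


def yield_ii(fm_prime: float, fs: float) -> float:
    """Effective PSII quantum yield (Fm' - Fs) / Fm' under actinic light."""
    if fm_prime <= 0:
        raise ValueError("Fm' must be > 0")
    if fs < 0:
        raise ValueError("Fs must be >= 0")
    return (fm_prime - fs) / fm_prime


def percent_change(control_mean: float, treated_mean: float) -> float:
    """100 * (treated - control) / control."""
    if control_mean <= 0:
        raise ValueError("control mean must be > 0")
    return 100.0 * (treated_mean - control_mean) / control_mean


# ---------------------------------------------------------------------------
# chlorosis scoring

#: Minimum region size for a reliable hue estimate.
MIN_ROI_PIXELS = 5000
#: Chlorotic hue band (deg) and minimum shift from reference.
CHLOROSIS_BAND = (55.0, 70.0)
MIN_SHIFT_DEG = 10.0


@dataclass(frozen=True)
class ChlorosisCall:
    roi_pixels: int
    mean_hue: float | None  # degrees, HSV
    reference_hue: float
    shift: float | None  # circular distance in degrees
    verdict: Literal["chlorotic", "not-chlorotic", "insufficient-roi"]


def circular_mean_hue(hues_deg: np.ndarray) -> float:
    """Circular mean of hue angles in degrees, result in [0, 360)."""
    rad = np.deg2rad(np.asarray(hues_deg, dtype=float))
    ang = math.atan2(np.sin(rad).mean(), np.cos(rad).mean())
    return math.degrees(ang) % 360.0


def _circular_distance(a: float, b: float) -> float:
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)


def hue_chlorosis(
    image: np.ndarray,
    reference_hue: float,
    min_saturation: float = 0.15,
    min_value: float = 0.1,
    min_pixels: int = MIN_ROI_PIXELS,
) -> ChlorosisCall:
    """Score leaf chlorosis from the central region's mean hue angle.

    The foreground is the largest connected component of sufficiently
    saturated, sufficiently bright pixels whose centroid lies in the
    central 50 % of the frame (the central leaflet); regions below
    ``min_pixels`` give an ``insufficient-roi`` verdict.  Chlorosis
    requires the circular mean hue to land inside the yellow-green band
    [55 deg, 70 deg] AND to be shifted by more than 10 deg from
    ``reference_hue``.
    """
    from skimage.color import rgb2hsv
    from skimage.measure import label, regionprops

    if not 0.0 <= reference_hue < 360.0:
        raise ValueError("reference hue must lie in [0, 360)")
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an RGB image")
    hsv = rgb2hsv(img)
    fg = (hsv[..., 1] > min_saturation) & (hsv[..., 2] > min_value)
    lab = label(fg)
    H, W = fg.shape
    central = None
    for region in sorted(regionprops(lab), key=lambda r: -r.area):
        cy, cx = region.centroid
        if 0.25 * H <= cy <= 0.75 * H and 0.25 * W <= cx <= 0.75 * W:
            central = region
            break
    if central is None or central.area < min_pixels:
        return ChlorosisCall(
            roi_pixels=0 if central is None else int(central.area),
            mean_hue=None,
            reference_hue=reference_hue,
            shift=None,
            verdict="insufficient-roi",
        )
    mask = lab == central.label
    mean_hue = circular_mean_hue(hsv[..., 0][mask] * 360.0)
    shift = _circular_distance(mean_hue, reference_hue)
    lo, hi = CHLOROSIS_BAND
    chlorotic = shift > MIN_SHIFT_DEG and lo <= mean_hue <= hi
    return ChlorosisCall(
        roi_pixels=int(central.area),
        mean_hue=mean_hue,
        reference_hue=reference_hue,
        shift=shift,
        verdict="chlorotic" if chlorotic else "not-chlorotic",
    )


# ---------------------------------------------------------------------------
# PCA


@dataclass
class PCAResult:
    eigenvalues: np.ndarray  # descending
    variance_fractions: np.ndarray
    scores: np.ndarray  # samples x components
    loadings: np.ndarray  # variables x components
    n_variables: int
    mode: Literal["correlation", "covariance"]


def pca_correlation(data) -> PCAResult:
    """Correlation-mode PCA (unit-variance standardization, prcomp scale=TRUE).

    Zero-variance variables are dropped with a warning.  Eigenvalues are
    returned in descending order; in correlation mode they sum to the
    number of retained variables, and each variance fraction equals
    eigenvalue / n_variables.  Component signs are fixed so each loading
    vector's largest-magnitude entry is positive.
    """
    X = np.asarray(getattr(data, "values", data), dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a samples x variables matrix with >= 2 samples")
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} zero-variance variable(s)")
        X = X[:, keep]
        sd = sd[keep]
    n_vars = X.shape[1]
    Z = (X - X.mean(axis=0)) / sd
    corr = (Z.T @ Z) / (X.shape[0] - 1)
    vals, vecs = np.linalg.eigh(corr)
    order = np.argsort(vals)[::-1]
    vals = np.maximum(vals[order], 0.0)
    vecs = vecs[:, order]
    # orient each component: largest-|loading| entry positive
    for k in range(vecs.shape[1]):
        j = np.argmax(np.abs(vecs[:, k]))
        if vecs[j, k] < 0:
            vecs[:, k] = -vecs[:, k]
    return PCAResult(
        eigenvalues=vals,
        variance_fractions=vals / n_vars,
        scores=Z @ vecs,
        loadings=vecs,
        n_variables=n_vars,
        mode="correlation",
    )


def eigenvalue_from_fraction(fraction_percent: float, n_variables: int) -> float:
    """Eigenvalue implied by a variance percentage in correlation-mode PCA.

    Correlation-mode eigenvalues sum to the number of variables, so a
    component explaining f % of the variance has eigenvalue
    f/100 * n_variables.
    """
    if not 0 <= fraction_percent <= 100:
        raise ValueError("fraction must be a percentage in [0, 100]")
    return fraction_percent / 100.0 * n_variables


def fraction_from_eigenvalue(eigenvalue: float, n_variables: int) -> float:
    """Variance percentage of a correlation-mode eigenvalue."""
    if eigenvalue < 0 or n_variables <= 0:
        raise ValueError("eigenvalue must be >= 0 and n_variables > 0")
    return 100.0 * eigenvalue / n_variables


# ---------------------------------------------------------------------------
# ANOSIM


@dataclass
class AnosimResult:
    r: float
    p: float
    n_permutations: int
    exhaustive: bool
    seed: int | None
    group_sizes: dict


def _anosim_r(rank_matrix: np.ndarray, labels: np.ndarray) -> float:
    n = len(labels)
    same = labels[:, None] == labels[None, :]
    iu = np.triu_indices(n, k=1)
    ranks = rank_matrix[iu]
    within = same[iu]
    m = n * (n - 1) // 2
    return float((ranks[~within].mean() - ranks[within].mean()) / (m / 2.0))


def _distinct_labelings(labels: Sequence) -> list[np.ndarray]:
    """All distinct arrangements of a label multiset (positions of each label)."""
    labels = list(labels)
    n = len(labels)
    uniq = sorted(set(labels), key=str)
    counts = {u: labels.count(u) for u in uniq}

    out: list[np.ndarray] = []

    def rec(remaining: list, positions: set, current: dict):
        if not remaining:
            arr = np.empty(n, dtype=object)
            for u, pos in current.items():
                for p in pos:
                    arr[p] = u
            out.append(arr)
            return
        u = remaining[0]
        for combo in combinations(sorted(positions), counts[u]):
            current[u] = combo
            rec(remaining[1:], positions - set(combo), current)
        current.pop(u, None)

    rec(uniq, set(range(n)), {})
    return out


def anosim(
    data=None,
    groups: Sequence | None = None,
    distances: np.ndarray | None = None,
    n_permutations: int = 999,
    seed: int | None = 0,
    metric: str = "euclidean",
    standardize: bool = True,
) -> AnosimResult:
    """Analysis of similarities on a data matrix or distance matrix.

    R ranges over [-1, 1]; positive values mean between-group distances
    outrank within-group distances.  The permutation p-value is
    (1 + #{R* >= R}) / (1 + n_permutations); when the number of distinct
    labelings does not exceed ``n_permutations`` the null distribution is
    enumerated exhaustively and p = #{R* >= R} / #labelings.
    """
    if groups is None:
        raise ValueError("groups are required")
    labels = np.asarray(groups)
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need >= 2 groups")
    if (counts < 2).any():
        raise ValueError("every group needs >= 2 members")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if distances is None:
        X = np.asarray(getattr(data, "values", data), dtype=float)
        if standardize:
            sd = X.std(axis=0, ddof=1)
            sd[sd == 0] = 1.0
            X = (X - X.mean(axis=0)) / sd
        dm = squareform(pdist(X, metric=metric))
    else:
        dm = np.asarray(distances, dtype=float)
        if dm.shape[0] != dm.shape[1]:
            dm = squareform(dm)
    n = dm.shape[0]
    if n != len(labels):
        raise ValueError("distance matrix and groups disagree on n")
    iu = np.triu_indices(n, k=1)
    rank_flat = rankdata(dm[iu])
    rank_matrix = np.zeros_like(dm)
    rank_matrix[iu] = rank_flat
    rank_matrix = rank_matrix + rank_matrix.T

    r_obs = _anosim_r(rank_matrix, labels)

    from math import factorial

    n_labelings = factorial(n)
    for c in counts:
        n_labelings //= factorial(int(c))

    if n_labelings <= n_permutations:
        labelings = _distinct_labelings(list(labels))
        rs = np.array([_anosim_r(rank_matrix, lab) for lab in labelings])
        p = float((rs >= r_obs - 1e-12).sum() / len(rs))
        return AnosimResult(
            r=r_obs,
            p=p,
            n_permutations=len(rs),
            exhaustive=True,
            seed=seed,
            group_sizes={str(u): int(c) for u, c in zip(uniq, counts)},
        )
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        if _anosim_r(rank_matrix, perm) >= r_obs - 1e-12:
            hits += 1
    p = (1 + hits) / (1 + n_permutations)
    return AnosimResult(
        r=r_obs,
        p=float(p),
        n_permutations=n_permutations,
        exhaustive=False,
        seed=seed,
        group_sizes={str(u): int(c) for u, c in zip(uniq, counts)},
    )
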