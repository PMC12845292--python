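"""Differential expression and opposite-trend Fe-responsive set algebra.

Two test paths mirror the two assays of the study design:

* miRNA: an exact binomial comparison of pooled normalized counts
  (Audic-Claverie style).  Under H0 the count in library b out of the
  pooled total is Binomial(x_a + x_b, N_b / (N_a + N_b)); the two-sided p
  doubles the smaller tail (capped at 1).  Calling thresholds: raw
  p <= 0.05 and |log2FC| >= 0.5 (inclusive).
* mRNA: a negative-binomial Wald test on CPM-scaled replicate counts with
  a moment-estimated dispersion (variance = mu + phi * mu^2), BH-adjusted
  q <= 0.05 and |log2FC| >= 1 (inclusive).

Fold-changes are log2((mean_b + c) / (mean_a + c)) on the CPM scale with
pseudocount c = 1; positive means up in the test condition.

The "Fe-responsive" sets capture the opposite-trend logic of a
deficiency/resupply design: pattern A = up under deficiency and down after
both resupply routes (relative to the deficient state); pattern B is the
mirror image.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datagen import CountData

__all__ = [
    "DESet",
    "FeResponsiveSets",
    "normalize_cpm",
    "log2_fold_change",
    "ac_exact_test",
    "nb_wald_test",
    "estimate_common_dispersion",
    "bh_adjust",
    "call_de",
    "fe_responsive_sets",
]


def normalize_cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million: count * 1e6 / library size, per column."""
    libsize = counts.sum(axis=0)
    if (libsize <= 0).any():
        bad = list(libsize.index[libsize <= 0])
        raise ValueError(f"zero library size for samples {bad}")
    return counts * 1e6 / libsize


def log2_fold_change(mean_a: float, mean_b: float, pseudocount: float = 1.0):
    """log2((mean_b + c) / (mean_a + c)); positive = up in condition b."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    mean_a = np.asarray(mean_a, dtype=float)
    mean_b = np.asarray(mean_b, dtype=float)
    if (mean_a < 0).any() or (mean_b < 0).any():
        raise ValueError("means must be >= 0")
    out = np.log2((mean_b + pseudocount) / (mean_a + pseudocount))
    return float(out) if out.ndim == 0 else out


def median_of_ratios_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (composition-robust normalization).

    Each sample's factor is the median across features of its ratio to the
    per-feature geometric mean, using only features expressed in every
    sample.  Robust to asymmetric differential expression, which biases
    plain library-size scaling.
    """
    x = counts.to_numpy(dtype=float)
    ok = (x > 0).all(axis=1)
    if not ok.any():
        raise ValueError("no feature expressed in every sample")
    logx = np.log(x[ok])
    ref = logx.mean(axis=1, keepdims=True)
    sf = np.exp(np.median(logx - ref, axis=0))
    return pd.Series(sf, index=counts.columns)


def ac_exact_test(x_a: int, x_b: int, n_a: float, n_b: float) -> float:
    """Exact binomial two-sided p for pooled counts from two libraries.

    Doubles the smaller binomial tail of x_b out of (x_a + x_b) at success
    probability N_b / (N_a + N_b), capped at 1.  Both counts zero -> p = 1.
    """
    if x_a < 0 or x_b < 0:
        raise ValueError("counts must be >= 0")
    if n_a <= 0 or n_b <= 0:
        raise ValueError("library sizes must be > 0")
    total = x_a + x_b
    if total == 0:
        return 1.0
    p_b = n_b / (n_a + n_b)
    lower = stats.binom.cdf(x_b, total, p_b)
    upper = stats.binom.sf(x_b - 1, total, p_b)
    return float(min(1.0, 2.0 * min(lower, upper)))


_LN2_SQ = math.log(2.0) ** 2


def estimate_common_dispersion(
    cpm_a: np.ndarray, cpm_b: np.ndarray, scale: float = 1.0
) -> float:
    """Common moment dispersion pooled across features and both groups.

    Solves the moment identity var = scale * mu + phi * mu^2 by the
    ratio-of-sums estimator phi = sum(s^2 - scale * mu) / sum(mu^2 - s^2/n)
    over all feature/group cells (``scale`` converts the Poisson part of
    the raw-count variance onto the CPM scale, 1e6 / library size; the
    s^2/n term unbiases the squared sample mean).  Ratio-of-sums is far
    more stable than per-feature estimates at 2-3 replicates.
    """
    num = 0.0
    den = 0.0
    for grp in (np.atleast_2d(cpm_a), np.atleast_2d(cpm_b)):
        mu = grp.mean(axis=1)
        s2 = grp.var(axis=1, ddof=1)
        n = grp.shape[1]
        ok = mu > 0
        num += float((s2[ok] - scale * mu[ok]).sum())
        den += float((mu[ok] ** 2 - s2[ok] / n).sum())
    if den <= 0:
        return 0.0
    return max(0.0, num / den)


def nb_wald_test(
    counts_a: np.ndarray,
    counts_b: np.ndarray,
    libsizes_a: np.ndarray,
    libsizes_b: np.ndarray,
    dispersion: float | None = None,
    pseudocount: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """NB Wald test of group b vs group a on CPM-scaled replicate counts.

    Accepts one feature (1-D inputs) or a feature x replicate matrix.
    The log2 fold-change uses the shared pseudocount; its delta-method
    standard error derives from the NB variance on the CPM scale,
    var(cpm) = scale * mu + phi * mu^2 with scale = 1e6 / mean library
    size.  When ``dispersion`` is None it is moment-estimated from the data
    supplied (a single feature gives a noisy estimate; matrix callers
    should pass a common dispersion, as :func:`call_de` does).  Features
    with all-zero counts on both sides return (0, 1).

    Returns (log2FC, two-sided normal p), scalars for 1-D input.
    """
    a = np.atleast_2d(np.asarray(counts_a, dtype=float))
    b = np.atleast_2d(np.asarray(counts_b, dtype=float))
    scalar = np.asarray(counts_a).ndim == 1
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("need >= 2 replicates per side")
    la = np.asarray(libsizes_a, dtype=float)
    lb = np.asarray(libsizes_b, dtype=float)
    scale_a = 1e6 / la.mean()
    scale_b = 1e6 / lb.mean()
    cpm_a = a * 1e6 / la
    cpm_b = b * 1e6 / lb
    mu_a = cpm_a.mean(axis=1)
    mu_b = cpm_b.mean(axis=1)
    if dispersion is None:
        dispersion = estimate_common_dispersion(cpm_a, cpm_b, (scale_a + scale_b) / 2)
    lfc = np.log2((mu_b + pseudocount) / (mu_a + pseudocount))
    # delta method: var(log2 mu_hat) = var(mu_hat) / ((mu + c)^2 ln2^2)
    var_a = (scale_a * mu_a + dispersion * mu_a**2) / a.shape[1]
    var_b = (scale_b * mu_b + dispersion * mu_b**2) / b.shape[1]
    se2 = (var_a / (mu_a + pseudocount) ** 2 + var_b / (mu_b + pseudocount) ** 2) / _LN2_SQ
    zero = (mu_a == 0) & (mu_b == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = lfc / np.sqrt(se2)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.where(se2 == 0, 1.0, p)
    p = np.where(zero, 1.0, p)
    lfc = np.where(zero, 0.0, lfc)
    p = np.minimum(1.0, p)
    if scalar:
        return float(lfc[0]), float(p[0])
    return lfc, p


def threshold_calls(lfc, significance, alpha: float, lfc_min: float) -> np.ndarray:
    """Inclusive calling semantics: significance <= alpha AND |lfc| >= lfc_min."""
    lfc = np.asarray(lfc, dtype=float)
    sig = np.asarray(significance, dtype=float)
    return (sig <= alpha) & (np.abs(lfc) >= lfc_min)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving with input."""
    p = np.asarray(pvals, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class DESet:
    """One contrast's differential-expression call set."""

    contrast: str  # "<test>_vs_<ref>"
    table: pd.DataFrame  # index feature; columns lfc, p, q, called
    up: set = field(default_factory=set)
    down: set = field(default_factory=set)
    lfc_min: float = 1.0
    alpha: float = 0.05
    use_adjusted: bool = True

    def __post_init__(self) -> None:
        if self.up & self.down:
            raise ValueError("up and down sets must be disjoint")


def _group_samples(meta: pd.DataFrame, group: str) -> list[str]:
    sel = meta.index[meta["group"] == group]
    if len(sel) == 0:
        raise ValueError(f"group {group!r} absent from sample metadata")
    return list(sel)


def call_de(
    data: CountData,
    test: str,
    ref: str,
    assay: str = "mRNA",
    alpha: float = 0.05,
    lfc_min: float | None = None,
    pseudocount: float = 1.0,
    norm: str = "cpm",
) -> DESet:
    """Call differential expression for one contrast (test vs reference).

    ``assay="miRNA"``: exact binomial test on replicate-pooled counts with
    pooled library sizes, raw p <= alpha and |lfc| >= 0.5 (both bounds
    inclusive).  ``assay="mRNA"``: NB Wald test per feature with a common
    dispersion estimated across all features, BH q <= alpha and
    |lfc| >= 1.  Fold-changes are computed on mean normalized counts with
    the shared pseudocount for both assays.  ``norm`` selects library-size
    scaling ("cpm", the default) or composition-robust "median-of-ratios"
    for designs where many features move in one direction.
    """
    if assay not in ("miRNA", "mRNA"):
        raise ValueError("assay must be 'miRNA' or 'mRNA'")
    if norm not in ("cpm", "median-of-ratios"):
        raise ValueError("norm must be 'cpm' or 'median-of-ratios'")
    cols_a = _group_samples(data.meta, ref)
    cols_b = _group_samples(data.meta, test)
    counts = data.counts
    lib = counts.sum(axis=0)
    if norm == "median-of-ratios":
        sf = median_of_ratios_size_factors(counts[cols_a + cols_b])
        # pseudo library sizes: size factors scaled to the mean true
        # library size keep normalized magnitudes on the CPM scale
        lib = sf * float(lib[cols_a + cols_b].mean())
    if lfc_min is None:
        lfc_min = 0.5 if assay == "miRNA" else 1.0

    cpm = counts[cols_a + cols_b] * 1e6 / lib[cols_a + cols_b]
    mu_a = cpm[cols_a].mean(axis=1).to_numpy()
    mu_b = cpm[cols_b].mean(axis=1).to_numpy()
    lfc = log2_fold_change(mu_a, mu_b, pseudocount)

    if assay == "miRNA":
        xa = counts[cols_a].sum(axis=1).to_numpy()
        xb = counts[cols_b].sum(axis=1).to_numpy()
        na = float(lib[cols_a].sum())
        nb = float(lib[cols_b].sum())
        p = np.array([ac_exact_test(int(a), int(b), na, nb) for a, b in zip(xa, xb)])
        q = bh_adjust(p)
        use_adjusted = False
    else:
        a = counts[cols_a].to_numpy(dtype=float)
        b = counts[cols_b].to_numpy(dtype=float)
        la = lib[cols_a].to_numpy(dtype=float)
        lbv = lib[cols_b].to_numpy(dtype=float)
        scale = 1e6 / lib[cols_a + cols_b].to_numpy(dtype=float).mean()
        phi = estimate_common_dispersion(a * 1e6 / la, b * 1e6 / lbv, scale)
        lfc_w, p = nb_wald_test(a, b, la, lbv, dispersion=phi, pseudocount=pseudocount)
        lfc = lfc_w
        q = bh_adjust(p)
        use_adjusted = True

    called = threshold_calls(lfc, q if use_adjusted else p, alpha, lfc_min)
    table = pd.DataFrame(
        {"lfc": lfc, "p": p, "q": q, "called": called}, index=counts.index
    )
    up = set(table.index[called & (lfc > 0)])
    down = set(table.index[called & (lfc < 0)])
    return DESet(
        contrast=f"{test}_vs_{ref}",
        table=table,
        up=up,
        down=down,
        lfc_min=lfc_min,
        alpha=alpha,
        use_adjusted=use_adjusted,
    )


@dataclass
class FeResponsiveSets:
    """Opposite-trend gene sets for one organ.

    pattern A: up under deficiency AND down after both resupply routes;
    pattern B: the mirror.  ``down_after_resupply`` pools the union of the
    two resupply down-sets (and ``up_after_resupply`` the mirror union).
    """

    organ: str
    pattern_a: set
    pattern_b: set
    up_deficiency: set
    down_deficiency: set
    down_after_resupply: set
    up_after_resupply: set


def fe_responsive_sets(
    de_sets: dict[str, DESet],
    organ: str,
    resupply_baseline: str = "FeD",
) -> FeResponsiveSets:
    """Intersect deficiency and resupply call sets into the two patterns.

    Requires the contrasts ``FeD_vs_CK``, ``RE_vs_<baseline>`` and
    ``Fol_vs_<baseline>`` for the organ (keys
    ``"<test>_<organ>_vs_<ref>_<organ>"``); ``resupply_baseline`` selects
    whether resupply is contrasted against the deficient state (default)
    or the control.
    """
    base = resupply_baseline
    k_fed = f"FeD_{organ}_vs_CK_{organ}"
    k_re = f"RE_{organ}_vs_{base}_{organ}"
    k_fol = f"Fol_{organ}_vs_{base}_{organ}"
    for k in (k_fed, k_re, k_fol):
        if k not in de_sets:
            raise ValueError(f"missing contrast {k!r}")
    fed, re_, fol = de_sets[k_fed], de_sets[k_re], de_sets[k_fol]
    pattern_a = fed.up & re_.down & fol.down
    pattern_b = fed.down & re_.up & fol.up
    return FeResponsiveSets(
        organ=organ,
        pattern_a=pattern_a,
        pattern_b=pattern_b,
        up_deficiency=set(fed.up),
        down_deficiency=set(fed.down),
        down_after_resupply=re_.down | fol.down,
        up_after_resupply=re_.up | fol.up,
    )
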