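"""Correspondence analysis and detrending, built from first principles.

The engine is classical (chi-square) correspondence analysis of a
nonnegative species × site matrix:

1. normalize the matrix to proportions ``P`` with row masses ``r`` and
   column masses ``c``;
2. form the standardized residual matrix
   ``S = D_r^{-1/2} (P - r cᵀ) D_c^{-1/2}``;
3. take its singular value decomposition; the squared singular values are
   the CA eigenvalues (each in (0, 1]), and the singular vectors scaled by
   the inverse square-root masses give the standard coordinates.

Site scores are reported in *principal* coordinates (mass-weighted variance
of an axis equals its eigenvalue); species scores are the abundance-weighted
means of the site standard coordinates, which coincides with the reciprocal
averaging solution.

Detrended correspondence analysis (DCA) post-processes the CA solution:
rare species may first be downweighted (Hill's rule, as implemented in the
classic decorana program), and the second and higher axes are detrended
against axis 1 by the method of segments — the axis-1 range is cut into
equal-width segments, within-segment means of the higher axis are smoothed
by a running average over adjacent segments and subtracted.  Nonlinear
rescaling of axis units is intentionally not implemented.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class OrdinationResult:
    site_scores: pd.DataFrame  # sites × axes, columns "axis1", "axis2", ...
    species_scores: pd.DataFrame  # species × axes
    eigenvalues: np.ndarray  # per reported CA axis, non-increasing
    axis_inertia_fraction: np.ndarray  # eigenvalue / total inertia
    detrended: bool
    downweighted: bool


def _as_frame(matrix) -> pd.DataFrame:
    if isinstance(matrix, pd.DataFrame):
        return matrix.astype(float)
    m = np.asarray(matrix, dtype=float)
    return pd.DataFrame(
        m,
        index=[f"sp{i}" for i in range(m.shape[0])],
        columns=[f"site{j}" for j in range(m.shape[1])],
    )


def correspondence_analysis(matrix, n_axes: int = 2) -> OrdinationResult:
    """Classical CA of a nonnegative species × site matrix.

    All-zero rows or columns are filtered with a warning; if the matrix
    rank supports fewer than ``n_axes`` nontrivial axes, the available
    axes are returned with a warning.
    """
    mat = _as_frame(matrix)
    if (mat.to_numpy() < 0).any():
        raise ValueError("correspondence analysis requires a nonnegative matrix")
    if n_axes < 1:
        raise ValueError("n_axes must be >= 1")

    row_ok = mat.sum(axis=1) > 0
    col_ok = mat.sum(axis=0) > 0
    if not row_ok.all() or not col_ok.all():
        warnings.warn(
            f"dropping {int((~row_ok).sum())} all-zero row(s) and "
            f"{int((~col_ok).sum())} all-zero column(s) before CA",
            stacklevel=2,
        )
        mat = mat.loc[row_ok, col_ok]
    if mat.shape[0] < 2 or mat.shape[1] < 2:
        raise ValueError("need at least a 2x2 matrix after filtering")

    M = mat.to_numpy()
    P = M / M.sum()
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, sigma, Vt = np.linalg.svd(S, full_matrices=False)

    # numerical rank: discard axes with negligible singular values
    keep = sigma > 1e-10
    sigma, U, Vt = sigma[keep], U[:, keep], Vt[keep, :]
    available = len(sigma)
    if available < n_axes:
        warnings.warn(
            f"matrix supports only {available} nontrivial axes "
            f"(requested {n_axes})",
            stacklevel=2,
        )
    k = min(n_axes, available)
    total_inertia = float((sigma**2).sum())

    eig = sigma[:k] ** 2
    site_std = Vt[:k].T / np.sqrt(c)[:, None]  # sites × k, weighted var 1
    site_principal = site_std * sigma[:k]
    # reciprocal averaging: species score = row-profile-weighted mean of
    # site standard coordinates (= principal species coordinates)
    species_principal = (P / r[:, None]) @ site_std

    axes = [f"axis{i + 1}" for i in range(k)]
    site_scores = pd.DataFrame(site_principal, index=mat.columns, columns=axes)
    species_scores = pd.DataFrame(species_principal, index=mat.index, columns=axes)
    _orient(site_scores, species_scores)
    return OrdinationResult(
        site_scores=site_scores,
        species_scores=species_scores,
        eigenvalues=eig,
        axis_inertia_fraction=eig / total_inertia,
        detrended=False,
        downweighted=False,
    )


def _orient(site_scores: pd.DataFrame, species_scores: pd.DataFrame) -> None:
    """Fix the arbitrary sign of each axis: the site with the
    lexicographically smallest label gets a non-negative score (falling
    through zero scores to the next label)."""
    order = sorted(site_scores.index.astype(str))
    for ax in site_scores.columns:
        for label in order:
            v = float(site_scores.loc[label, ax])
            if v != 0.0:
                if v < 0:
                    site_scores[ax] *= -1.0
                    species_scores[ax] *= -1.0
                break


def downweight_rare(matrix, fraction: float = 5.0):
    """Downweight rare species before ordination (Hill's rule).

    A species' *effective frequency* is ``(Σx)² / Σx²`` over sites — the
    Hill N2 number of its occurrences, which behaves like a presence count
    for count data but remains meaningful for relative abundances.  Species
    whose effective frequency falls below ``max/fraction`` are scaled down
    by ``effective_frequency / (max/fraction)``.  Returns the same type as
    the input (DataFrame in, DataFrame out).
    """
    mat = _as_frame(matrix)
    M = mat.to_numpy()
    if (M < 0).any():
        raise ValueError("downweighting requires a nonnegative matrix")
    if fraction < 1:
        fraction = 1.0 / fraction
    totals = M.sum(axis=1)
    sumsq = (M**2).sum(axis=1) + 1e-10
    eff_freq = totals**2 / sumsq
    threshold = eff_freq.max() / fraction
    weights = np.ones(M.shape[0])
    rare = eff_freq < threshold
    weights[rare] = eff_freq[rare] / threshold
    out = mat.mul(weights, axis=0)
    return out if isinstance(matrix, pd.DataFrame) else out.to_numpy()


def detrend_by_segments(
    site_scores_axis1, site_scores_axis2, n_segments: int = 26
) -> np.ndarray:
    """Remove the arch dependence of axis 2 on axis 1.

    The axis-1 range is divided into ``n_segments`` equal-width segments;
    the mean axis-2 score of each nonempty segment is computed, empty
    segments borrow the nearest nonempty mean (neighbor merging), the
    segment means are smoothed with a (1, 2, 1)/4 running average, and each
    site's smoothed segment mean is subtracted from its axis-2 score.
    """
    x1 = np.asarray(site_scores_axis1, dtype=float)
    x2 = np.asarray(site_scores_axis2, dtype=float)
    if x1.shape != x2.shape or x1.ndim != 1:
        raise ValueError("axis score vectors must be 1-D and of equal length")
    if n_segments < 2:
        raise ValueError("n_segments must be >= 2")
    lo, hi = x1.min(), x1.max()
    if hi == lo:
        raise ValueError("axis-1 scores span a zero range; cannot detrend")

    # segment assignment; the right edge belongs to the last segment
    seg = np.floor((x1 - lo) / (hi - lo) * n_segments).astype(int)
    seg = np.clip(seg, 0, n_segments - 1)

    means = np.full(n_segments, np.nan)
    for s in range(n_segments):
        mask = seg == s
        if mask.any():
            means[s] = x2[mask].mean()
    # merge empty segments with neighbors: take the nearest nonempty mean
    nonempty = np.flatnonzero(~np.isnan(means))
    for s in np.flatnonzero(np.isnan(means)):
        nearest = nonempty[np.argmin(np.abs(nonempty - s))]
        means[s] = means[nearest]

    padded = np.concatenate(([means[0]], means, [means[-1]]))
    smoothed = (padded[:-2] + 2 * padded[1:-1] + padded[2:]) / 4.0
    return x2 - smoothed[seg]


def dca(
    ivi,
    n_axes: int = 2,
    downweight: bool = True,
    *,
    n_segments: int = 26,
    fraction: float = 5.0,
) -> OrdinationResult:
    """Detrended correspondence analysis of a species × site matrix.

    Pipeline: optional rare-species downweighting → correspondence
    analysis → detrending of every axis beyond the first against axis 1 by
    the method of segments.  With ``n_axes=1`` no detrending happens and
    the pure CA axis is returned.  Species scores are recomputed as
    abundance-weighted means of the (detrended) site scores so the biplot
    stays internally consistent.
    """
    mat = _as_frame(ivi)
    if downweight:
        mat = downweight_rare(mat, fraction=fraction)
    res = correspondence_analysis(mat, n_axes=n_axes)
    if n_axes < 2 or res.site_scores.shape[1] < 2:
        return OrdinationResult(
            site_scores=res.site_scores,
            species_scores=res.species_scores,
            eigenvalues=res.eigenvalues,
            axis_inertia_fraction=res.axis_inertia_fraction,
            detrended=False,
            downweighted=downweight,
        )

    site = res.site_scores.copy()
    x1 = site["axis1"].to_numpy()
    for ax in site.columns[1:]:
        site[ax] = detrend_by_segments(x1, site[ax].to_numpy(), n_segments=n_segments)

    # rebuild species scores from the detrended site configuration
    kept = mat.loc[res.species_scores.index, res.site_scores.index].to_numpy()
    profiles = kept / kept.sum(axis=1, keepdims=True)
    species = pd.DataFrame(
        profiles @ site.to_numpy(), index=res.species_scores.index, columns=site.columns
    )
    return OrdinationResult(
        site_scores=site,
        species_scores=species,
        eigenvalues=res.eigenvalues,
        axis_inertia_fraction=res.axis_inertia_fraction,
        detrended=True,
        downweighted=downweight,
    )


def biplot(
    result: OrdinationResult,
    path,
    *,
    top_species: int = 10,
    species_weight: pd.Series | None = None,
) -> None:
    """Write an SVG/PNG biplot of sites (dots) and the highest-weight
    species (crosses).  Requires matplotlib."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 6))
    ss = result.site_scores
    ax.scatter(ss["axis1"], ss["axis2"], color="tab:blue", zorder=3)
    for label, row in ss.iterrows():
        ax.annotate(str(label), (row["axis1"], row["axis2"]), fontsize=8)
    sp = result.species_scores
    if species_weight is not None:
        keep = species_weight.reindex(sp.index).fillna(0.0).nlargest(top_species).index
        sp = sp.loc[keep]
    ax.scatter(sp["axis1"], sp["axis2"], marker="x", color="tab:red", zorder=2)
    for label, row in sp.iterrows():
        ax.annotate(
            str(label), (row["axis1"], row["axis2"]), fontsize=7, color="tab:red"
        )
    ax.axhline(0, lw=0.5, color="grey")
    ax.axvline(0, lw=0.5, color="grey")
    ax.set_xlabel("axis 1")
    ax.set_ylabel("axis 2")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
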