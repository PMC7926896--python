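"""PCA of log-normalized expression with variable cos2 and group ellipses.

PCA is run on the samples x genes matrix of log normalized expression,
centred and (by default) scaled to unit variance — i.e. an
eigendecomposition of the sample correlation matrix.  Variable
coordinates follow the correlation-circle convention (eigenvector times
the square root of its eigenvalue, so a coordinate is the correlation of
the gene with the component under scaling); cos2 is a variable's squared
coordinate normalised by its total over all components, the squared
quality of representation, which sums to one per gene.  With n samples,
components beyond min(n - 1, p) have exactly zero variance and are
reported as such.

Group ellipses are normal-theory ellipses of the score cloud in the
first two dimensions (mean, covariance, chi-square radius); with the
study's n = 4 per group they are descriptive only and flagged as such.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2


@dataclass
class GroupEllipse:
    group: str
    center: np.ndarray  # (2,) mean score on Dim1/Dim2
    covariance: np.ndarray  # (2, 2) score covariance
    radius: float  # chi-square radius at the confidence level
    level: float
    n: int
    degenerate: bool
    descriptive_only: bool


@dataclass
class PCAResult:
    eigenvalues: np.ndarray  # (p,) nonincreasing, zero beyond rank
    percent_variance: np.ndarray  # (p,) sums to 100
    scores: pd.DataFrame  # samples x components
    variable_coords: pd.DataFrame  # genes x components
    genes: list[str]
    scaled: bool

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)


def fit_pca(matrix: pd.DataFrame, scale: bool = True) -> PCAResult:
    """Centred (and optionally scaled) PCA of a samples x genes matrix.

    Missing cells are not allowed (apply listwise deletion upstream).
    Component signs are fixed so each component's largest-magnitude
    variable coordinate is positive.
    """
    X = matrix.to_numpy(dtype=float)
    n, p = X.shape
    if n < 2 or p < 2:
        raise ValueError("PCA requires at least 2 samples and 2 genes")
    if np.isnan(X).any():
        raise ValueError("PCA input contains missing cells; apply listwise deletion first")
    Xc = X - X.mean(axis=0)
    if scale:
        sd = Xc.std(axis=0, ddof=1)
        zero = np.flatnonzero(sd == 0)
        if zero.size:
            raise ValueError(
                f"zero-variance gene(s) under scaling: {[matrix.columns[i] for i in zero]}"
            )
        Xc = Xc / sd
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    eig = np.zeros(p)
    rank = min(n - 1, p)
    eig[: len(S)] = S**2 / (n - 1)
    eig[rank:] = 0.0
    # sign convention: largest-magnitude loading positive per component
    for c in range(len(S)):
        i = np.argmax(np.abs(Vt[c]))
        if Vt[c, i] < 0:
            Vt[c] *= -1.0
            U[:, c] *= -1.0
    scores = U * S  # (n, rank-ish)
    coords = Vt.T * np.sqrt(np.maximum(eig[: len(S)], 0.0))
    comp_names = [f"Dim{i + 1}" for i in range(len(S))]
    total = eig.sum()
    return PCAResult(
        eigenvalues=eig,
        percent_variance=100.0 * eig / total,
        scores=pd.DataFrame(scores, index=matrix.index, columns=comp_names),
        variable_coords=pd.DataFrame(coords, index=matrix.columns, columns=comp_names),
        genes=list(matrix.columns),
        scaled=scale,
    )


def variable_cos2(result: PCAResult) -> pd.DataFrame:
    """cos2(gene, comp): squared coordinate over the gene's total squared
    coordinates; each gene's row sums to one."""
    sq = result.variable_coords**2
    return sq.div(sq.sum(axis=1), axis=0)


def group_ellipses(
    scores: pd.DataFrame,
    groups: pd.Series,
    level: float = 0.95,
) -> list[GroupEllipse]:
    """Normal-theory confidence ellipses of the Dim1/Dim2 score cloud per group.

    Groups of size < 3 (or with a singular score covariance) are returned
    with ``degenerate=True`` rather than erroring.  Small groups are
    flagged ``descriptive_only``.
    """
    dims = scores.iloc[:, :2]
    out = []
    radius = float(np.sqrt(chi2.ppf(level, df=2)))
    for grp in sorted(groups.unique()):
        sub = dims[groups.values == grp].to_numpy()
        n = len(sub)
        center = sub.mean(axis=0) if n else np.full(2, np.nan)
        if n < 3:
            out.append(
                GroupEllipse(grp, center, np.full((2, 2), np.nan), radius, level, n, True, True)
            )
            continue
        cov = np.cov(sub, rowvar=False, ddof=1)
        degenerate = bool(np.linalg.matrix_rank(cov) < 2)
        out.append(
            GroupEllipse(grp, center, cov, radius, level, n, degenerate, n < 10)
        )
    return out


def ellipse_frame(ellipses: list[GroupEllipse]) -> pd.DataFrame:
    rows = []
    for e in ellipses:
        rows.append(
            {
                "group": e.group,
                "center_dim1": e.center[0],
                "center_dim2": e.center[1],
                "cov_11": e.covariance[0, 0],
                "cov_12": e.covariance[0, 1],
                "cov_22": e.covariance[1, 1],
                "radius": e.radius,
                "level": e.level,
                "n": e.n,
                "degenerate": e.degenerate,
                "descriptive_only": e.descriptive_only,
            }
        )
    return pd.DataFrame(rows)
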