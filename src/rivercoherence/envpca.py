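"""Rotated PCA of environmental variables and OTU/class responses to the
two leading axes.

Variables are standardized and components extracted from the correlation
matrix; the 2-component solution is obliquely rotated (oblimin) so each
axis aligns with an interpretable environmental gradient (seasonal vs
spatial in a dam-regulated river).  Oblique components may correlate; the
inter-component correlation is reported, never assumed zero.  Factor
scores use the regression method (scores are not unique for oblique
solutions; this choice is stated so output is reproducible).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.multivariate.factor_rotation import rotate_factors

from .datatypes import EnvMatrix, JoinError, OtuTable

__all__ = ["PcaResult", "env_pca", "correlate_with_axes"]


@dataclass
class PcaResult:
    """Two-component (optionally rotated) PCA of an environment table."""

    loadings: pd.DataFrame  # variable x (PC1, PC2) pattern loadings
    scores: pd.DataFrame  # sample x (PC1, PC2)
    proportion_variance: tuple[float, float]  # per unrotated component
    total_variance: float  # 2-component communality / n variables
    rotation: str
    component_correlation: float  # inter-component r (0 when unrotated)


def env_pca(env: EnvMatrix, n_components: int = 2, rotation: str = "oblimin") -> PcaResult:
    """PCA of standardized environmental variables with optional oblimin
    rotation of the 2-component solution.

    Component signs are fixed so each component's largest-|loading|
    variable loads positively.
    """
    X = env.frame.to_numpy(dtype=float)
    n, p = X.shape
    if n < 3:
        raise ValueError(f"need >= 3 samples for PCA, got {n}")
    if p < 2:
        raise ValueError(f"need >= 2 variables for PCA, got {p}")
    if n_components > p:
        raise ValueError(f"{n_components} components > {p} variables")
    sd = X.std(axis=0, ddof=1)
    zero_var = [v for v, s in zip(env.variables, sd) if s == 0]
    if zero_var:
        raise ValueError(f"zero-variance variables rejected: {zero_var}")
    Z = (X - X.mean(axis=0)) / sd
    R = np.corrcoef(Z, rowvar=False)
    eigval, eigvec = np.linalg.eigh(R)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    prop = tuple(float(e / p) for e in eigval[:n_components])
    A = eigvec[:, :n_components] * np.sqrt(eigval[:n_components])  # unrotated loadings

    if rotation == "none":
        L, phi = A, np.eye(n_components)
    elif rotation == "oblimin":
        L, T = rotate_factors(A, "oblimin", 0.0, "oblique")
        phi = T.T @ T
    else:
        raise ValueError(f"unknown rotation {rotation!r}")

    # sign convention: largest-|loading| variable positive per component
    for k in range(n_components):
        top = np.argmax(np.abs(L[:, k]))
        if L[top, k] < 0:
            L[:, k] = -L[:, k]
            phi[k, :] = -phi[k, :]
            phi[:, k] = -phi[:, k]

    structure = L @ phi
    # regression-method scores; pinv tolerates collinear variables
    weights = np.linalg.pinv(R) @ structure
    scores = Z @ weights

    comps = [f"PC{k + 1}" for k in range(n_components)]
    communality = float(((L @ phi) * L).sum() / p)
    return PcaResult(
        loadings=pd.DataFrame(L, index=env.variables, columns=comps),
        scores=pd.DataFrame(scores, index=env.sample_ids, columns=comps),
        proportion_variance=prop,
        total_variance=communality,
        rotation=rotation,
        component_correlation=float(phi[0, 1]) if n_components >= 2 else 0.0,
    )


def correlate_with_axes(
    abundances: OtuTable | pd.DataFrame,
    scores: pd.DataFrame,
    alpha: float = 0.05,
    adjust: str = "none",
) -> pd.DataFrame:
    """Pearson correlation of each entity's abundance with each component's
    sample scores.

    ``abundances`` is an OtuTable (entities = OTUs) or a DataFrame with
    entities as rows and samples as columns (e.g. class abundance
    vectors).  Entities with zero variance over the shared samples are
    excluded as untestable.  ``adjust='bonferroni'`` multiplies p-values
    by (number of tested entities x number of axes).

    Returns a frame with entity, r/p per axis and significance flags.
    """
    if isinstance(abundances, OtuTable):
        frame = abundances.to_dataframe()
    else:
        frame = abundances
    shared = [s for s in frame.columns if s in scores.index]
    if len(shared) < 4:
        raise JoinError(
            f"only {len(shared)} samples shared between abundances and scores",
            [],
        )
    X = frame[shared].to_numpy(dtype=float)
    S = scores.loc[shared].to_numpy(dtype=float)
    n = len(shared)
    testable = X.std(axis=1) > 0
    entities = [e for e, ok in zip(frame.index, testable) if ok]
    X = X[testable]

    axes = list(scores.columns)
    n_tests = len(entities) * len(axes)
    rows = []
    for entity, vec in zip(entities, X):
        row: dict[str, object] = {"entity": entity, "n": n}
        for k, ax in enumerate(axes):
            r, p = stats.pearsonr(vec, S[:, k])
            p_adj = min(1.0, p * n_tests) if adjust == "bonferroni" else p
            row[f"r_{ax.lower()}"] = float(r)
            row[f"p_{ax.lower()}"] = float(p_adj)
            row[f"sig_{ax.lower()}"] = bool(p_adj < alpha)
        rows.append(row)
    return pd.DataFrame(rows)
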