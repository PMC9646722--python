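"""Post-hoc identifiability analytics on converged parameter ensembles.

Two tools: principal-component analysis of the final scaling-factor
vectors, computed by the variance-maximizing deflation scheme (each
loading is the leading eigenvector of the residual after projecting out
the earlier components), and least-squares hyperplane fits that expose
complementary relationships — directions in sf space along which several
currents trade off while producing nearly identical AP waveforms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigError, DegenerateInputError


@dataclass
class PCAResult:
    """Loadings (rows of ``loadings``), scores, and explained variance."""

    loadings: np.ndarray          # (p, p), row k = unit loading w_(k)
    scores: np.ndarray            # (n, p), centered X projected on loadings
    explained_variance: np.ndarray
    mean: np.ndarray
    X: np.ndarray

    @property
    def explained_variance_ratio(self) -> np.ndarray:
        return self.explained_variance / self.explained_variance.sum()


def _dominant_eigvec(A: np.ndarray, n_iter: int = 500,
                     tol: float = 1e-13) -> np.ndarray:
    """Power iteration for the leading eigenvector of symmetric PSD A."""
    rng = np.random.default_rng(12345)
    w = rng.standard_normal(A.shape[0])
    w /= np.linalg.norm(w)
    lam = 0.0
    for _ in range(n_iter):
        w_new = A @ w
        norm = np.linalg.norm(w_new)
        if norm == 0.0:
            return w  # residual exactly zero: any direction
        w_new /= norm
        if np.linalg.norm(w_new - w) < tol or np.linalg.norm(w_new + w) < tol:
            w = w_new
            break
        w = w_new
        lam = norm
    return w


def _fix_sign(w: np.ndarray) -> np.ndarray:
    i = int(np.argmax(np.abs(w)))
    return w if w[i] >= 0 else -w


def pca(X: np.ndarray) -> PCAResult:
    """PCA by deflation: w_(k) maximizes the variance of X_k w.

    X is column-centered internally (no variance scaling: the sf
    components share units).  Each loading's sign is fixed so its
    largest-magnitude entry is positive.  Raises on zero-variance input.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 1:
        raise ConfigError("X must be n x p with n >= 2, p >= 1")
    mean = X.mean(axis=0)
    Xc = X - mean
    if np.allclose(Xc, 0.0):
        raise DegenerateInputError("all columns have zero variance")
    n, p = Xc.shape
    residual = Xc.copy()
    loadings = np.empty((p, p))
    for k in range(p):
        w = _dominant_eigvec(residual.T @ residual)
        # enforce orthogonality to earlier components; on rank-deficient
        # data the residual is ~0 and any orthogonal completion is valid
        if k:
            w = w - loadings[:k].T @ (loadings[:k] @ w)
        norm = np.linalg.norm(w)
        if norm < 1e-9:
            for e in np.eye(p):
                cand = e - loadings[:k].T @ (loadings[:k] @ e)
                if np.linalg.norm(cand) > 1e-6:
                    w, norm = cand, np.linalg.norm(cand)
                    break
        w = _fix_sign(w / norm)
        loadings[k] = w
        residual = residual - np.outer(residual @ w, w)
    scores = Xc @ loadings.T
    var = scores.var(axis=0, ddof=1)
    return PCAResult(loadings=loadings, scores=scores,
                     explained_variance=var, mean=mean, X=X)


@dataclass
class PlaneFit:
    """A fitted hyperplane ``coef . x = constant`` with unit-norm coef.

    ``coef`` comes from the total-least-squares (orthogonal) fit: the
    smallest-variance direction of the centered point cloud, so the
    printed equation is symmetric in the variables.  ``r2_ols`` is the
    ordinary multiple-regression R^2 with ``response`` regressed on the
    remaining columns; ``r2_orth`` is 1 minus the fraction of total
    variance lying along the plane normal.
    """

    names: tuple
    coef: np.ndarray
    constant: float
    r2_ols: float
    r2_orth: float
    response: str
    points: np.ndarray

    def equation(self) -> str:
        terms = " ".join(
            f"{c:+.3f}*sf_{n}" for c, n in zip(self.coef, self.names))
        return f"{terms} = {self.constant:.6f}"


def fit_plane(points: np.ndarray, names, response: str | None = None) -> PlaneFit:
    """Fit a hyperplane to rows of selected sf values.

    ``response`` picks the column for the OLS R^2 report; by default the
    column with the largest-magnitude TLS coefficient (the best-explained
    variable).  Raises when underdetermined or when the regressor block
    is rank-deficient (naming the collinear columns).
    """
    pts = np.asarray(points, dtype=float)
    names = tuple(names)
    if pts.ndim != 2 or pts.shape[1] != len(names):
        raise ConfigError("points must be (n, len(names))")
    n, p = pts.shape
    if n < p + 1:
        raise ConfigError(f"need >= {p + 1} points for a {p}-variable plane")
    mean = pts.mean(axis=0)
    centered = pts - mean
    cov = centered.T @ centered
    if np.allclose(cov, 0.0):
        raise DegenerateInputError("all points identical (zero variance)")
    evals, evecs = np.linalg.eigh(cov)
    normal = _fix_sign(evecs[:, 0])
    constant = float(normal @ mean)
    total = float(np.trace(cov))
    r2_orth = 1.0 - float(evals[0]) / total if total > 0 else 0.0

    if response is None:
        response = names[int(np.argmax(np.abs(normal)))]
    if response not in names:
        raise ConfigError(f"response {response!r} not among {names}")
    ri = names.index(response)
    keep = [i for i in range(p) if i != ri]
    A = np.column_stack([centered[:, keep], np.ones(n)])
    rank = np.linalg.matrix_rank(A)
    if rank < A.shape[1]:
        bad = [names[i] for i in keep]
        raise DegenerateInputError(
            f"rank-deficient regressors among {bad}")
    y = centered[:, ri]
    beta, res, *_ = np.linalg.lstsq(A, y, rcond=None)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0.0:
        r2_ols = 1.0
    else:
        ss_res = float(((y - A @ beta) ** 2).sum())
        r2_ols = 1.0 - ss_res / ss_tot
    return PlaneFit(names=names, coef=normal, constant=constant,
                    r2_ols=float(r2_ols), r2_orth=float(r2_orth),
                    response=response, points=pts)


def composite_replot_r2(fit: PlaneFit, inward: tuple, outward: str) -> float:
    """R^2 of the 2-D replot: summed inward terms vs the outward term.

    Abscissa: sum over ``inward`` of |coef_i| * sf_i; ordinate:
    |coef_outward| * sf_outward.  Collapses the fitted hyperplane onto the
    physiologically paired in/out currents.
    """
    for nm in (*inward, outward):
        if nm not in fit.names:
            raise ConfigError(f"{nm!r} not among plane variables {fit.names}")
    idx = {n: i for i, n in enumerate(fit.names)}
    x = sum(abs(fit.coef[idx[n]]) * fit.points[:, idx[n]] for n in inward)
    y = abs(fit.coef[idx[outward]]) * fit.points[:, idx[outward]]
    r = np.corrcoef(x, y)[0, 1]
    return float(r ** 2)


def complementarity_report(orp_result, currents, k: int = 20) -> dict:
    """Plane fit + composite replot on the top-k final sf values.

    ``currents``: the trade-off candidates; outward K-type currents are
    placed on the replot ordinate, the remaining (inward) ones summed on
    the abscissa.  Requires all chosen currents to have been optimized.
    """
    currents = tuple(currents)
    missing = set(currents) - set(orp_result.names)
    if missing:
        raise ConfigError(
            f"currents not optimized in this orp result: {sorted(missing)}")
    idx = orp_result.top_k_indices(k)
    table = orp_result.final_table()[idx]
    cols = [orp_result.names.index(c) for c in currents]
    pts = table[:, cols]
    fit = fit_plane(pts, currents)
    out = {"plane": fit, "r2_ols": fit.r2_ols, "r2_orth": fit.r2_orth}
    outward = [c for c in currents if c.startswith("K")]
    inward = tuple(c for c in currents if not c.startswith("K"))
    if len(outward) == 1 and len(inward) >= 1:
        out["composite_r2"] = composite_replot_r2(fit, inward, outward[0])
    return out
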