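"""Smooth-in-time multi-view factor analysis.

The model decomposes V scaled views :math:`Y_v` (features x samples) into a
shared sample-by-factor score matrix Z and per-view weight matrices
:math:`W_v`, with factor scores encouraged to vary smoothly along the
treatment-time covariate:

.. math::

    \\min_{W, Z}\\; \\sum_v \\lVert Y_v - W_v Z^\\top \\rVert_F^2
    + \\lambda \\sum_k \\lVert w_k \\rVert^2 \\sum_i
      \\big(z_k(t_{i+1}) - z_k(t_i)\\big)^2

where samples are ordered by time (the penalty therefore also ties replicates
at the same time point together) and :math:`w_k` stacks factor k's weights
over all views.  Weighting each factor's roughness by its loading norm makes
the penalty invariant to how scale splits between W and Z; an unweighted
roughness penalty could be evaded by shrinking Z into W.  The problem is solved by alternating exact
least-squares updates — a ridge-free solve for each ``W_v`` and a coupled
linear solve for Z — so the objective is non-increasing by construction.
This is a deterministic, penalised stand-in for a full Bayesian smooth factor
model (GP priors, ARD): it preserves the downstream decision surface
(variance decomposition per view and factor, weight ranking, factor-to-wave
timing) at a fraction of the machinery.

Views may cover different subsets of the global sample axis (e.g. 3 RNA vs 4
proteomic replicates); each view contributes only its own samples to the fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def scale_views(views: dict[str, pd.DataFrame]) -> dict[str, pd.DataFrame]:
    """Standardise every feature to mean 0, sd 1; drop constant features."""
    out = {}
    for name, mat in views.items():
        if mat.shape[1] < 2:
            raise ValueError(f"view {name!r} has fewer than 2 samples")
        vals = mat.to_numpy(dtype=float)
        sd = vals.std(axis=1, ddof=0)
        keep = sd > 1e-12
        dropped = int((~keep).sum())
        if dropped:
            logger.warning("scale_views[%s]: dropped %d constant features",
                           name, dropped)
        vals = vals[keep]
        scaled = (vals - vals.mean(axis=1, keepdims=True)) / sd[keep][:, None]
        out[name] = pd.DataFrame(scaled, index=mat.index[keep], columns=mat.columns)
    return out


@dataclass
class FactorModel:
    W: dict[str, pd.DataFrame]       # per view: feature x K
    Z: pd.DataFrame                  # global samples x K (NaN if sample in no view)
    time: pd.Series                  # per global sample, minutes
    K: int
    lam: float
    converged: bool
    objective_trace: list[float] = field(default_factory=list)

    @property
    def factor_names(self) -> list[str]:
        return list(self.Z.columns)

    def view_samples(self, view: str) -> pd.Index:
        return self.W[view].attrs["samples"]


def _varimax(W: np.ndarray, tol: float = 1e-10, max_iter: int = 200) -> np.ndarray:
    """Orthogonal varimax rotation matrix for a loading matrix.

    The bilinear least-squares fit is invariant to orthogonal rotations of
    (W, Z); varimax picks the rotation with maximally sparse loadings, which
    is what identifies factors whose true weights concentrate on disjoint
    feature blocks (the deterministic counterpart of sparsity priors in
    Bayesian factor models).
    """
    p, k = W.shape
    R = np.eye(k)
    if k < 2:
        return R
    var = 0.0
    for _ in range(max_iter):
        L = W @ R
        grad = W.T @ (L ** 3 - L @ np.diag((L ** 2).sum(axis=0)) / p)
        u, s, vt = np.linalg.svd(grad)
        R = u @ vt
        new_var = s.sum()
        if new_var < var * (1 + tol):
            break
        var = new_var
    return R


def _difference_penalty(order: np.ndarray, n: int) -> np.ndarray:
    """L = D'D for first differences along the time-sorted sample order."""
    D = np.zeros((n - 1, n))
    for i in range(n - 1):
        D[i, order[i]] = -1.0
        D[i, order[i + 1]] = 1.0
    return D.T @ D


def fit_tfa(views: dict[str, pd.DataFrame], time, K: int, lam: float = 0.01,
            max_iter: int = 500, tol: float = 1e-6, seed: int = 0) -> FactorModel:
    """Fit the penalised multi-view factor model by alternating least squares.

    ``views`` are scaled matrices (features x samples) whose columns are
    subsets of a common sample axis; ``time`` maps every sample to its
    covariate value in minutes.  Initialisation is the truncated SVD of the
    row-concatenated views (zero-filled for view-absent samples), so the fit
    is deterministic; ``seed`` only matters for optional degenerate restarts.
    """
    time = pd.Series(time)
    samples = list(time.index)
    pos = {s: i for i, s in enumerate(samples)}
    S = len(samples)
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > min(m.shape[0] for m in views.values()):
        raise ValueError("K exceeds the smallest view's feature count")

    Ys, idxs = {}, {}
    for name, mat in views.items():
        cols = list(mat.columns)
        if not set(cols) <= set(samples):
            raise ValueError(f"view {name!r} has samples outside the time covariate")
        Ys[name] = mat.to_numpy(dtype=float)
        idxs[name] = np.array([pos[c] for c in cols])

    order = np.argsort(time.to_numpy(dtype=float), kind="stable")
    L = _difference_penalty(order, S)

    # SVD initialisation on the zero-filled concatenation
    stack = np.zeros((sum(y.shape[0] for y in Ys.values()), S))
    r = 0
    for name in views:
        stack[r:r + Ys[name].shape[0], idxs[name]] = Ys[name]
        r += Ys[name].shape[0]
    _, s, vt = np.linalg.svd(stack, full_matrices=False)
    Z = (vt[:K].T * s[:K]) / np.sqrt(S)

    eye = np.eye(K)

    def roughness():
        # per-factor first-difference penalty of the current scores
        d = Z[order][1:] - Z[order][:-1]
        return (d ** 2).sum(axis=0)

    def update_W():
        # exact minimiser given Z: per-view ridge with per-factor penalty
        # lam * roughness(z_k) on the stacked weight norms
        P = np.diag(lam * roughness())
        Ws = {}
        for name in views:
            Zv = Z[idxs[name]]
            G = Zv.T @ Zv + P + 1e-12 * eye
            Ws[name] = np.linalg.solve(G, Zv.T @ Ys[name].T).T
        return Ws

    def update_Z(Ws):
        # exact minimiser given W: blockdiag(sum_v W_v'W_v) over samples
        # + lam * (L kron diag(||w_k||^2)), sample-major vectorisation
        wn = sum((Ws[name] ** 2).sum(axis=0) for name in views)
        A = np.kron(L, lam * np.diag(wn))
        b = np.zeros(S * K)
        gram = {name: Ws[name].T @ Ws[name] for name in views}
        rhs = {name: Ws[name].T @ Ys[name] for name in views}
        for name in views:
            for jj, s_idx in enumerate(idxs[name]):
                sl = slice(s_idx * K, (s_idx + 1) * K)
                A[sl, sl] += gram[name]
                b[sl.start:sl.stop] += rhs[name][:, jj]
        for s_idx in range(S):
            sl = slice(s_idx * K, (s_idx + 1) * K)
            A[sl, sl] += 1e-12 * eye
        return np.linalg.solve(A, b).reshape(S, K)

    def objective(Ws):
        val = sum(np.sum((Ys[n] - Ws[n] @ Z[idxs[n]].T) ** 2) for n in views)
        wn = sum((Ws[name] ** 2).sum(axis=0) for name in views)
        val += lam * float(roughness() @ wn)
        return val

    Wcur = update_W()
    prev = objective(Wcur)
    trace = [prev]
    converged = False
    for _ in range(max_iter):
        Z = update_Z(Wcur)
        Wcur = update_W()
        cur = objective(Wcur)
        # exact alternating minimisation: non-increase up to round-off
        assert cur <= prev + 1e-9 * (abs(trace[0]) + 1.0), \
            "objective increased during ALS"
        trace.append(cur)
        if prev > 0 and (prev - cur) / prev < tol:
            converged = True
            break
        prev = cur
    if not converged:
        logger.warning("fit_tfa: not converged in %d iterations", max_iter)

    # identifiability: varimax-rotated loadings, unit-variance factor scores,
    # variance-ranked, sign-fixed
    R = _varimax(np.vstack([Wcur[name] for name in views]))
    Z = Z @ R
    for name in views:
        Wcur[name] = Wcur[name] @ R
    sd = Z.std(axis=0, ddof=0)
    sd[sd < 1e-12] = 1.0
    Z = Z / sd
    for name in views:
        Wcur[name] = Wcur[name] * sd
    totals = np.zeros(K)
    for name in views:
        Zv = Z[idxs[name]]
        for k in range(K):
            rec = np.outer(Wcur[name][:, k], Zv[:, k])
            totals[k] += np.sum(Ys[name] ** 2) - np.sum((Ys[name] - rec) ** 2)
    rank = np.argsort(-totals, kind="stable")
    Z = Z[:, rank]
    for name in views:
        Wcur[name] = Wcur[name][:, rank]
    wstack = np.vstack([Wcur[name] for name in views])
    for k in range(K):
        if wstack[np.argmax(np.abs(wstack[:, k])), k] < 0:
            Z[:, k] *= -1
            for name in views:
                Wcur[name][:, k] *= -1

    cols = [f"factor{k + 1}" for k in range(K)]
    Wd = {}
    for name, mat in views.items():
        df = pd.DataFrame(Wcur[name], index=mat.index, columns=cols)
        df.attrs["samples"] = mat.columns
        Wd[name] = df
    Zd = pd.DataFrame(Z, index=samples, columns=cols)
    return FactorModel(W=Wd, Z=Zd, time=time.astype(float), K=K, lam=lam,
                       converged=converged, objective_trace=trace)


@dataclass
class VarianceDecomposition:
    per_view_total: pd.Series          # R^2 in [0, 1] per view
    per_view_factor: pd.DataFrame      # views x factors, clipped at 0
    zscores: pd.DataFrame              # z of variance explained across factors

    def validate(self) -> None:
        if (self.per_view_factor.to_numpy() < 0).any():
            raise ValueError("per-factor R^2 must be >= 0")
        for v in self.per_view_factor.index:
            if (self.per_view_factor.loc[v] > self.per_view_total[v] + 1e-9).any():
                raise ValueError("per-factor R^2 exceeds the view total")


def variance_explained(model: FactorModel,
                       views: dict[str, pd.DataFrame]) -> VarianceDecomposition:
    """Per-view total and per-factor fraction of variance explained.

    Per factor: ``R2_vk = 1 - ||Y_v - w_vk z_k'||^2 / ||Y_v||^2`` (clipped at
    zero); the view total uses the full K-factor reconstruction.  z-scores are
    computed across factors within each view.
    """
    totals, perf = {}, {}
    for name, mat in views.items():
        Y = mat.to_numpy(dtype=float)
        Zv = model.Z.loc[mat.columns].to_numpy()
        W = model.W[name].to_numpy()
        denom = np.sum(Y ** 2)
        totals[name] = 1.0 - np.sum((Y - W @ Zv.T) ** 2) / denom
        r2 = []
        for k in range(model.K):
            rec = np.outer(W[:, k], Zv[:, k])
            r2.append(max(0.0, 1.0 - np.sum((Y - rec) ** 2) / denom))
        perf[name] = r2
    per_view_factor = pd.DataFrame(perf, index=model.factor_names).T
    mu = per_view_factor.mean(axis=1)
    sd = per_view_factor.std(axis=1, ddof=1).replace(0.0, np.nan)
    z = per_view_factor.sub(mu, axis=0).div(sd, axis=0).fillna(0.0)
    vd = VarianceDecomposition(per_view_total=pd.Series(totals),
                               per_view_factor=per_view_factor, zscores=z)
    vd.validate()
    return vd


def select_factors(var_decomp: VarianceDecomposition) -> list[str]:
    """Keep factors whose variance-explained z-score is > 0 in >= 1 view."""
    z = var_decomp.zscores
    if z.shape[1] < 2:
        raise ValueError("need >= 2 candidate factors to z-score")
    kept = [k for k in z.columns if (z[k] > 0).any()]
    if not kept:
        logger.warning("select_factors: no factor has z > 0 in any view")
    return kept


def select_model(views: dict[str, pd.DataFrame], time, k_max: int = 15,
                 k_min: int = 2, **fit_kwargs):
    """Fit candidate models for K = k_min..k_max and keep the largest K whose
    factors all pass the z > 0 rule in at least one view.

    All candidate K are scanned (a weak factor can reappear at larger K).
    If no candidate passes completely, the model keeping the most factors is
    returned (its failing factors are simply not selected downstream).
    """
    best = None
    fallback = None
    n_fallback = -1
    misses = 0
    for K in range(k_min, k_max + 1):
        model = fit_tfa(views, time, K=K, **fit_kwargs)
        vd = variance_explained(model, views)
        kept = select_factors(vd)
        if len(kept) == K:
            best = (model, vd)
            misses = 0
        else:
            if len(kept) > n_fallback:
                fallback, n_fallback = (model, vd), len(kept)
            misses += 1
    if best is None:
        logger.warning("select_model: no K passed the z > 0 rule for all "
                       "factors; returning the model keeping the most")
        best = fallback
    return best


def factor_correlation(model: FactorModel) -> pd.DataFrame:
    """Pearson correlation between factor score columns (diagonal 1)."""
    Z = model.Z.to_numpy()
    if Z.shape[1] == 1:
        return pd.DataFrame([[1.0]], index=model.factor_names,
                            columns=model.factor_names)
    corr = np.corrcoef(Z.T)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=model.factor_names, columns=model.factor_names)


def select_features(model: FactorModel, view: str, factor: str,
                    z_thresh: float = 1.0) -> pd.DataFrame:
    """Features whose weight z-score (within view and factor) is |z| > z_thresh.

    Returns a table (feature, weight, z, direction) where direction is the
    sign of the weight relative to the factor's orientation.
    """
    w = model.W[view][factor]
    if len(w) == 0:
        raise ValueError(f"view {view!r} is empty")
    sd = w.std(ddof=0)
    z = (w - w.mean()) / sd if sd > 0 else w * 0.0
    sel = z.abs() > z_thresh
    return pd.DataFrame({"feature": w.index[sel], "weight": w[sel].to_numpy(),
                         "z": z[sel].to_numpy(),
                         "direction": np.sign(w[sel]).astype(int)})


@dataclass
class WaveAssignment:
    wave_time: dict[str, float]              # factor -> assigned time point
    excluded_views: dict[str, list[str]]     # factor -> views below threshold
    unassigned: list[str]


def assign_waves(model: FactorModel, var_decomp: VarianceDecomposition,
                 factors: list[str] | None = None,
                 exclusion_z: float = 0.0) -> WaveAssignment:
    """Assign each factor to the earliest time point where its mean score has
    moved from the time-0 baseline by more than half its maximum excursion.

    A view is excluded from a factor's dissection when the view's
    variance-explained z-score for that factor falls below ``exclusion_z``
    (default 0: the view explains less of this factor than its average
    factor does).  A raw-R^2 cutoff is unusable here because least-squares
    scores give every view a noise floor of about 1/n_samples per factor.
    """
    factors = factors or model.factor_names
    times = model.time
    tgrid = sorted(times.unique())
    wave_time: dict[str, float] = {}
    excluded: dict[str, list[str]] = {}
    unassigned: list[str] = []
    for k in factors:
        z = model.Z[k]
        base = z[times == tgrid[0]].mean()
        dev = {t: abs(z[times == t].mean() - base) for t in tgrid[1:]}
        peak = max(dev.values())
        if peak < 1e-8:
            unassigned.append(k)
            logger.warning("assign_waves: factor %s has a flat trajectory", k)
            continue
        wave_time[k] = next(t for t in tgrid[1:] if dev[t] >= peak / 2)
        z = var_decomp.zscores[k]
        excluded[k] = sorted(z.index[z < exclusion_z])
    return WaveAssignment(wave_time=wave_time, excluded_views=excluded,
                          unassigned=unassigned)
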