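"""Partial least squares regression of scalar references on spectra, with VIP.

A spectra matrix X (samples × wavenumbers) and a scalar reference y (e.g.
thermal–optical OC or the GC–MS PAH sum) are related by PLS1 fitted with the
NIPALS algorithm: components are extracted sequentially, each with a
unit-norm weight vector w_a = X_aᵀy_a / ‖X_aᵀy_a‖, scores t_a = X_a w_a,
y-loading q_a = t_aᵀy_a / t_aᵀt_a, and deflation of both X and y.  X is
mean-centered but NOT variance-scaled — the absorbance scale is physically
meaningful, so a wavenumber's variance should count.

Variable importance in projection (VIP) summarises each wavenumber's
contribution to the explained y-variance:

    VIP_j = sqrt( p · Σ_a SSY_a w_aj² / Σ_a SSY_a ),   SSY_a = q_a² t_aᵀt_a

with p the number of wavenumber variables and w_a unit-norm, which gives the
normalization identity Σ_j VIP_j² = p.  Wavenumbers with VIP > 1 (the
conventional greater-than-one rule) are flagged influential and merged into
contiguous intervals for annotation against the band table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bands import BandDefinition

__all__ = ["PLSRModel", "VipResult", "fit_plsr", "vip_scores", "band_report"]


class ChemometricsError(ValueError):
    pass


@dataclass(frozen=True)
class PLSRModel:
    """A fitted NIPALS PLS1 model (mean-centered, unscaled X)."""

    n_components: int
    weights: np.ndarray        # (A, p), rows unit-norm
    x_scores: np.ndarray       # (n, A)
    x_loadings: np.ndarray     # (A, p)
    y_loadings: np.ndarray     # (A,)
    ssy: np.ndarray            # (A,) explained y sum-of-squares per component
    x_mean: np.ndarray         # (p,)
    y_mean: float
    cv_rmse: dict[int, float] = field(default_factory=dict)  # candidate A → CV RMSE
    cv_seed: int | None = None
    truncated: bool = False    # requested A exceeded the data rank

    @property
    def coef(self) -> np.ndarray:
        """Regression vector b with ŷ = y_mean + (x − x_mean)·b."""
        W = self.weights.T          # (p, A)
        P = self.x_loadings.T       # (p, A)
        q = self.y_loadings         # (A,)
        R = W @ np.linalg.pinv(P.T @ W)
        return R @ q

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return self.y_mean + (X - self.x_mean) @ self.coef


def _nipals_pls1(Xc: np.ndarray, yc: np.ndarray, A: int):
    n, p = Xc.shape
    W = np.zeros((A, p))
    T = np.zeros((n, A))
    P = np.zeros((A, p))
    q = np.zeros(A)
    ssy = np.zeros(A)
    Xa, ya = Xc.copy(), yc.copy()
    a_used = 0
    for a in range(A):
        w = Xa.T @ ya
        nw = np.linalg.norm(w)
        if nw <= 1e-12 * max(1.0, np.abs(ya).max(initial=0.0)):
            break  # nothing left to extract
        w /= nw
        t = Xa @ w
        tt = float(t @ t)
        if tt <= 0:
            break
        qa = float(t @ ya) / tt
        pa = (Xa.T @ t) / tt
        Xa = Xa - np.outer(t, pa)
        ya = ya - qa * t
        W[a], T[:, a], P[a], q[a] = w, t, pa, qa
        ssy[a] = qa**2 * tt
        a_used += 1
    return W[:a_used], T[:, :a_used], P[:a_used], q[:a_used], ssy[:a_used]


def fit_plsr(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int | str = "cv",
    max_components: int = 10,
    cv_folds: int = 5,
    cv_seed: int = 0,
) -> PLSRModel:
    """Fit a mean-centered NIPALS PLS1 model.

    Parameters
    ----------
    X, y : arrays (n × p) and (n,)
        Spectra matrix and scalar reference per sample.
    n_components : int or "cv"
        Fixed component count, or "cv" to pick A minimising k-fold
        cross-validated RMSE with a one-standard-error parsimony rule
        (the smallest A whose CV RMSE is within one SE of the minimum).
    cv_seed : int
        Seed for the fold assignment, recorded in the model.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ChemometricsError(f"shape mismatch: X {X.shape}, y {y.shape}")
    if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
        raise ChemometricsError("non-finite values in X or y")
    if np.ptp(y) == 0:
        raise ChemometricsError("constant y — nothing to regress")
    n, p = X.shape

    cv_rmse: dict[int, float] = {}
    if isinstance(n_components, str):
        if n_components != "cv":
            raise ChemometricsError(f"n_components must be an int or 'cv', got {n_components!r}")
        A_max = min(max_components, n - 2, p)
        if A_max < 1:
            raise ChemometricsError(f"too few samples (n={n}) for cross-validation")
        A = _select_components_cv(X, y, A_max, cv_folds, cv_seed, cv_rmse)
    else:
        A = int(n_components)
        if n < A + 2:
            raise ChemometricsError(f"need n ≥ A + 2 samples (n={n}, A={A})")

    xm = X.mean(axis=0)
    ym = float(y.mean())
    W, T, P, q, ssy = _nipals_pls1(X - xm, y - ym, A)
    truncated = W.shape[0] < A
    return PLSRModel(
        n_components=W.shape[0], weights=W, x_scores=T, x_loadings=P,
        y_loadings=q, ssy=ssy, x_mean=xm, y_mean=ym,
        cv_rmse=cv_rmse, cv_seed=cv_seed if cv_rmse else None,
        truncated=truncated,
    )


def _select_components_cv(X, y, A_max, k, seed, cv_rmse_out) -> int:
    n = X.shape[0]
    rng = np.random.default_rng(seed)
    folds = rng.permutation(n) % min(k, n)
    press = np.zeros(A_max)       # squared-error accumulator per A
    sq_errs: list[list[float]] = [[] for _ in range(A_max)]
    for f in range(min(k, n)):
        test = folds == f
        if test.all() or not test.any():
            continue
        Xtr, ytr = X[~test], y[~test]
        xm, ym = Xtr.mean(axis=0), ytr.mean()
        W, T, P, q, _ = _nipals_pls1(Xtr - xm, ytr - ym, A_max)
        for A in range(1, A_max + 1):
            Au = min(A, W.shape[0])
            Wp, Pp, qp = W[:Au].T, P[:Au].T, q[:Au]
            R = Wp @ np.linalg.pinv(Pp.T @ Wp)
            b = R @ qp
            pred = ym + (X[test] - xm) @ b
            errs = (pred - y[test]) ** 2
            press[A - 1] += float(errs.sum())
            sq_errs[A - 1].extend(errs.tolist())
    rmse = np.sqrt(press / n)
    for A in range(1, A_max + 1):
        cv_rmse_out[A] = float(rmse[A - 1])
    best = int(np.argmin(rmse))
    # one-standard-error rule on the per-sample squared errors of the best A
    se = float(np.std(sq_errs[best], ddof=1) / np.sqrt(len(sq_errs[best]))) if len(sq_errs[best]) > 1 else 0.0
    rmse_cut = float(np.sqrt(rmse[best] ** 2 + se))
    for A in range(1, best + 2):
        if rmse[A - 1] <= rmse_cut:
            return A
    return best + 1


@dataclass(frozen=True)
class VipResult:
    """Per-wavenumber VIP scores and the intervals exceeding the threshold."""

    vip: np.ndarray                              # (p,), ≥ 0, Σ vip² = p
    wavenumbers: np.ndarray | None               # (p,) if known
    threshold: float
    influential_bands: tuple[tuple[float, float], ...]  # (lo, hi) cm⁻¹ intervals


def vip_scores(
    model: PLSRModel,
    wavenumbers: np.ndarray | None = None,
    threshold: float = 1.0,
) -> VipResult:
    """Variable-importance-in-projection scores of a fitted PLS1 model.

    Satisfies Σ_j VIP_j² = p exactly (unit-norm weights).  When a wavenumber
    axis is supplied, contiguous runs of VIP > threshold are merged into
    influential intervals.
    """
    ssy_tot = float(model.ssy.sum())
    if ssy_tot <= 0:
        raise ChemometricsError("model explains zero y-variance — VIP undefined")
    p = model.weights.shape[1]
    contrib = (model.weights**2 * model.ssy[:, None]).sum(axis=0)
    vip = np.sqrt(p * contrib / ssy_tot)

    intervals: list[tuple[float, float]] = []
    if wavenumbers is not None:
        wn = np.asarray(wavenumbers, dtype=float)
        if wn.size != p:
            raise ChemometricsError("wavenumber axis length does not match VIP length")
        above = vip > threshold
        i = 0
        while i < p:
            if above[i]:
                j = i
                while j + 1 < p and above[j + 1]:
                    j += 1
                lo = float(min(wn[i], wn[j]))
                hi = float(max(wn[i], wn[j]))
                intervals.append((lo, hi))
                i = j + 1
            else:
                i += 1
        intervals.sort()
    return VipResult(
        vip=vip, wavenumbers=None if wavenumbers is None else np.asarray(wavenumbers, float),
        threshold=threshold, influential_bands=tuple(intervals),
    )


def band_report(
    vip: VipResult,
    band_table: tuple[BandDefinition, ...] | list[BandDefinition],
) -> list[dict]:
    """Annotate each influential VIP interval with overlapping band names.

    A band claims the interval when it overlaps the band's ±2σ_max extent
    around its nominal center (clipped to the band's fit window); intervals
    touching no band are labelled "unassigned".
    """
    rows = []
    for lo, hi in vip.influential_bands:
        names = []
        for b in band_table:
            b_lo = max(b.center - 2 * b.sigma_bounds[1], min(b.window))
            b_hi = min(b.center + 2 * b.sigma_bounds[1], max(b.window))
            if hi >= b_lo and lo <= b_hi:
                names.append(b.name)
        rows.append({
            "interval_lo": lo, "interval_hi": hi,
            "bands": tuple(names) if names else ("unassigned",),
        })
    return rows
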