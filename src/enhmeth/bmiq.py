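"""Beta-mixture quantile (BMIQ) normalization of type II probe bias.

Infinium arrays mix two probe chemistries whose β distributions differ:
type II probes are compressed toward 0.5 relative to type I. BMIQ fits a
three-state beta mixture (unmethylated U, hemimethylated H, methylated M)
to each probe type separately, then maps type II values onto the type I
distribution: U- and M-state values through the component-wise quantile
map F1^{-1}(F2(x)), H-state values through a linear dilation between the
transformed state boundaries. The map is monotone, so probe ranking within
a sample is never changed.

The mixture is fitted by a generalized EM: the E-step is exact, the M-step
maximizes each component's weighted beta log-likelihood numerically and
keeps the previous parameters whenever the optimizer fails to improve, so
the observed-data log-likelihood is non-decreasing by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats

from .errors import DegenerateInputError, InsufficientDataError, InvalidFitError

EPS = 1e-6  # values are clipped into [EPS, 1-EPS] before fitting


@dataclass
class BetaMixtureFit:
    """Fitted k-component beta mixture with components sorted by mean."""

    k: int
    weights: np.ndarray
    shape_a: np.ndarray
    shape_b: np.ndarray
    log_likelihood: float
    n_iter: int
    converged: bool
    ll_trace: list[float] = field(default_factory=list)

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        self.shape_a = np.asarray(self.shape_a, dtype=float)
        self.shape_b = np.asarray(self.shape_b, dtype=float)
        if abs(self.weights.sum() - 1.0) > 1e-8 or (self.weights < 0).any():
            raise InvalidFitError("mixture weights must be >= 0 and sum to 1")
        if (self.shape_a <= 0).any() or (self.shape_b <= 0).any():
            raise InvalidFitError("beta shape parameters must be positive")
        means = self.component_means()
        if not np.all(np.diff(means) >= 0):
            raise InvalidFitError("components must be sorted by ascending mean")

    def component_means(self) -> np.ndarray:
        return self.shape_a / (self.shape_a + self.shape_b)

    def log_density(self, x: np.ndarray) -> np.ndarray:
        """Per-component weighted log density, shape (len(x), k)."""
        x = x[:, None]
        return (
            np.log(self.weights)[None, :]
            + stats.beta.logpdf(x, self.shape_a[None, :], self.shape_b[None, :])
        )

    def responsibilities(self, x: np.ndarray) -> np.ndarray:
        ld = self.log_density(np.asarray(x, dtype=float))
        ld -= special.logsumexp(ld, axis=1, keepdims=True)
        return np.exp(ld)


def _weighted_beta_mle(
    x: np.ndarray, r: np.ndarray, a0: float, b0: float
) -> tuple[float, float]:
    """Maximize sum_i r_i * log Beta(x_i; a, b); falls back to (a0, b0)."""
    sw = r.sum()
    if sw <= 0:
        return a0, b0
    slx = float(r @ np.log(x))
    sl1x = float(r @ np.log1p(-x))

    def nll(log_ab):
        a, b = np.exp(log_ab)
        return -((a - 1) * slx + (b - 1) * sl1x - sw * special.betaln(a, b))

    def grad(log_ab):
        a, b = np.exp(log_ab)
        dga, dgb, dgab = special.digamma((a, b, a + b))
        da = -(slx - sw * (dga - dgab))
        db = -(sl1x - sw * (dgb - dgab))
        return np.array([da * a, db * b])  # chain rule for log-parameters

    x0 = np.log([a0, b0])
    res = optimize.minimize(
        nll, x0, jac=grad, method="L-BFGS-B",
        bounds=[(-10.0, 10.0)] * 2, options={"maxiter": 60},
    )
    if np.isfinite(res.fun) and res.fun <= nll(x0):
        a, b = np.exp(res.x)
        return float(a), float(b)
    return a0, b0


def _moment_init(x: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Initialize by splitting at the i/k empirical quantiles, moments per slice."""
    edges = np.quantile(x, np.linspace(0, 1, k + 1))
    a = np.empty(k)
    b = np.empty(k)
    for i in range(k):
        lo, hi = edges[i], edges[i + 1]
        sel = (x >= lo) & (x <= hi) if i == k - 1 else (x >= lo) & (x < hi)
        vals = x[sel] if sel.sum() >= 2 else x
        m, v = vals.mean(), max(vals.var(ddof=1), 1e-6)
        v = min(v, m * (1 - m) * 0.999)  # beta variance bound
        phi = m * (1 - m) / v - 1
        a[i] = max(m * phi, 1e-2)
        b[i] = max((1 - m) * phi, 1e-2)
    return np.full(k, 1.0 / k), a, b


def fit_beta_mixture(
    values: np.ndarray,
    k: int = 3,
    tol: float = 1e-5,
    max_iter: int = 500,
    seed: int = 0,
) -> BetaMixtureFit:
    """Fit a k-component beta mixture to β-values by generalized EM.

    Requires at least ``50 * k`` values strictly inside (0, 1) after
    clipping to [1e-6, 1-1e-6]; an all-equal input raises
    :class:`DegenerateInputError`. Convergence is declared when the mean
    log-likelihood improvement per observation falls below ``tol`` (a
    per-observation criterion keeps the stopping rule sample-size
    invariant). Components are relabeled by ascending mean before
    returning; ``seed`` is accepted for interface stability (the default
    initialization is deterministic).
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    x = np.clip(x, EPS, 1 - EPS)
    if len(x) < 50 * k:
        raise InsufficientDataError(
            f"beta-mixture fit needs >= {50 * k} values, got {len(x)}"
        )
    if np.ptp(x) < 1e-12:
        raise DegenerateInputError("all values equal; cannot fit a mixture")

    w, a, b = _moment_init(x, k)
    ll_prev = -np.inf
    trace: list[float] = []
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        fit = BetaMixtureFit.__new__(BetaMixtureFit)  # unvalidated scratch state
        fit.weights, fit.shape_a, fit.shape_b = w, a, b
        ld = fit.log_density(x)
        ll = float(special.logsumexp(ld, axis=1).sum())
        trace.append(ll)
        if ll - ll_prev < tol * len(x) and n_iter > 1:
            converged = True
            break
        ll_prev = ll
        resp = np.exp(ld - special.logsumexp(ld, axis=1, keepdims=True))
        w = resp.mean(axis=0)
        w = np.maximum(w, 1e-10)
        w /= w.sum()
        for j in range(k):
            a[j], b[j] = _weighted_beta_mle(x, resp[:, j], a[j], b[j])

    order = np.argsort(a / (a + b))
    return BetaMixtureFit(
        k=k,
        weights=w[order],
        shape_a=a[order],
        shape_b=b[order],
        log_likelihood=trace[-1],
        n_iter=n_iter,
        converged=converged,
        ll_trace=trace,
    )


def bmiq_transform(
    type2_values: np.ndarray,
    fit_type1: BetaMixtureFit,
    fit_type2: BetaMixtureFit,
) -> np.ndarray:
    """Map type II β-values onto the type I distribution.

    State assignment is by maximum posterior responsibility under the type
    II fit (ties resolved toward the lower-mean component). U and M states
    go through the component quantile map; H-state values are linearly
    rescaled between the empirical state boundaries and their images. A
    final isotonic pass over the sorted inputs guarantees the output never
    inverts the order of two inputs. NaNs pass through unchanged.
    """
    for fit in (fit_type1, fit_type2):
        if not fit.converged:
            raise InvalidFitError("bmiq_transform requires converged fits")
        if fit.k != 3:
            raise InvalidFitError("bmiq_transform requires k = 3 fits")
    x_in = np.asarray(type2_values, dtype=float)
    ok = np.isfinite(x_in)
    x = np.clip(x_in[ok], EPS, 1 - EPS)
    if x.size == 0:
        return x_in.copy()

    resp = fit_type2.responsibilities(x)
    state = np.argmax(resp, axis=1)  # argmax takes the first (lower-mean) on ties
    y = np.empty_like(x)

    a1, b1 = fit_type1.shape_a, fit_type1.shape_b
    a2, b2 = fit_type2.shape_a, fit_type2.shape_b
    u = state == 0
    m = state == 2
    h = state == 1
    if u.any():
        y[u] = stats.beta.ppf(stats.beta.cdf(x[u], a2[0], b2[0]), a1[0], b1[0])
    if m.any():
        y[m] = stats.beta.isf(stats.beta.sf(x[m], a2[2], b2[2]), a1[2], b1[2])
    if h.any():
        # dilation: map [max U-state input, min M-state input] onto the image
        # interval spanned by the transformed U and M extremes
        left2 = x[u].max() if u.any() else 0.0
        right2 = x[m].min() if m.any() else 1.0
        left1 = y[u].max() if u.any() else 0.0
        right1 = y[m].min() if m.any() else 1.0
        span2 = max(right2 - left2, 1e-12)
        y[h] = left1 + (x[h] - left2) * (right1 - left1) / span2

    y = np.clip(y, 0.0, 1.0)
    order = np.argsort(x, kind="mergesort")
    y_sorted = np.maximum.accumulate(y[order])  # enforce global monotonicity
    y[order] = y_sorted

    out = x_in.copy()
    out[ok] = y
    return out


def normalize_matrix(matrix, annotation, k: int = 3, tol: float = 1e-5,
                     max_iter: int = 500, seed: int = 0):
    """Per-sample BMIQ over a probe-level matrix.

    Returns the normalized :class:`~enhmeth.core_io.BetaMatrix` (type I
    probes untouched, type II probes transformed) plus a per-sample fit
    summary table.
    """
    import pandas as pd

    from .core_io import BetaMatrix, validate_probe_annotation

    validate_probe_annotation(annotation)
    design = annotation.set_index("probe_id")["design_type"].reindex(matrix.row_ids)
    if design.isna().any():
        missing = design.index[design.isna()].tolist()[:5]
        raise InsufficientDataError(f"probes without design_type: {missing}")
    is2 = (design == "II").to_numpy()
    values = matrix.values.copy()
    rows = []
    for sample in matrix.sample_ids:
        col = values[sample].to_numpy(dtype=float)
        fit1 = fit_beta_mixture(col[~is2], k=k, tol=tol, max_iter=max_iter, seed=seed)
        fit2 = fit_beta_mixture(col[is2], k=k, tol=tol, max_iter=max_iter, seed=seed)
        values.loc[is2, sample] = bmiq_transform(col[is2], fit1, fit2)
        rows.append(
            {
                "sample_id": sample,
                "ll_type1": fit1.log_likelihood,
                "ll_type2": fit2.log_likelihood,
                "iter_type1": fit1.n_iter,
                "iter_type2": fit2.n_iter,
                "means_type1": ",".join(f"{v:.4f}" for v in fit1.component_means()),
                "means_type2": ",".join(f"{v:.4f}" for v in fit2.component_means()),
            }
        )
    return BetaMatrix(values, matrix.feature_level), pd.DataFrame(rows)
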