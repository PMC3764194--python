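"""Signal-to-beta conversion, quantile normalization, and BMIQ.

The methylation level at a CpG is summarized as a beta value,
``beta = M / (M + U + offset)`` with methylated/unmethylated channel
intensities after background subtraction and a stabilizing offset
(default 100). Cohort normalization is: per-sample background floor ->
per-channel median scaling -> quantile normalization of the pooled
M+U signals across samples -> beta recomputation -> BMIQ, which fits a
three-state (unmethylated / hemimethylated / methylated) beta mixture
to each design type and quantile-maps type II probes onto the type I
reference distribution. For X-chromosome analyses the cohort is
normalized separately per sex and BMIQ is skipped, because the female
inactive X produces a genuinely different beta distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

DEFAULT_OFFSET = 100.0
EPS = 1e-6


# ---------------------------------------------------------------------------
# beta computation and quantile normalization
# ---------------------------------------------------------------------------

def compute_beta(M, U, offset: float = DEFAULT_OFFSET):
    """beta = M / (M + U + offset); negative intensities floored at 0.

    With offset > 0 the result lies in [0, 1); 0/0 is defined as 0.
    """
    if offset < 0:
        raise ValueError("offset must be >= 0")
    M = np.maximum(np.asarray(M, dtype=float), 0.0)
    U = np.maximum(np.asarray(U, dtype=float), 0.0)
    denom = M + U + offset
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(denom > 0, M / denom, 0.0)
    if isinstance(M, np.ndarray) and M.ndim == 0:
        return float(beta)
    return beta


def quantile_normalize(signals: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize columns (samples) to the mean-quantile reference.

    Every sample's sorted value vector becomes the across-sample mean of
    sorted columns; within-sample rank order is preserved (ties broken
    by position, which makes the operation idempotent).
    """
    if signals.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    X = signals.to_numpy(dtype=float)
    order = np.argsort(X, axis=0, kind="stable")
    ref = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    rows = np.arange(X.shape[0])
    for j in range(X.shape[1]):
        out[order[:, j], j] = ref[rows]
    return pd.DataFrame(out, index=signals.index, columns=signals.columns)


def channel_adjust(
    M: pd.DataFrame, U: pd.DataFrame, channel: pd.Series
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample, per-channel median scaling to the cross-channel median.

    ``channel`` maps probe id -> 'red'/'green'. Both channels of a
    sample are rescaled so their medians agree with the sample's
    overall median signal (M and U pooled).
    """
    ch = channel.reindex(M.index)
    Mo, Uo = M.copy().astype(float), U.copy().astype(float)
    for col in M.columns:
        pooled = np.concatenate([M[col].to_numpy(float), U[col].to_numpy(float)])
        target = np.median(pooled)
        for c in ch.dropna().unique():
            sel = (ch == c).to_numpy()
            vals = np.concatenate([M.loc[sel, col], U.loc[sel, col]])
            med = np.median(vals)
            if med > 0:
                f = target / med
                Mo.loc[sel, col] *= f
                Uo.loc[sel, col] *= f
    return Mo, Uo


def background_floor(signals: pd.DataFrame, quantile: float = 0.01) -> pd.DataFrame:
    """Subtract a per-sample constant (the given signal quantile, a
    proxy for negative-control background) and floor at 0."""
    bg = signals.quantile(quantile, axis=0)
    return (signals - bg).clip(lower=0.0)


# ---------------------------------------------------------------------------
# three-state beta mixture (EM)
# ---------------------------------------------------------------------------

@dataclass
class BetaMixtureFit:
    """A fitted K-component beta mixture.

    Components are ordered by mean (unmethylated, hemimethylated,
    methylated for K=3). ``loglik_trace`` is the per-iteration observed
    log-likelihood, non-decreasing by construction (exact M-steps
    warm-started from the previous parameters).
    """

    a: np.ndarray
    b: np.ndarray
    weights: np.ndarray
    loglik_trace: list = field(default_factory=list)
    converged: bool = True

    @property
    def means(self) -> np.ndarray:
        return self.a / (self.a + self.b)

    def logpdf(self, x: np.ndarray) -> np.ndarray:
        """n x K matrix of weighted component log densities."""
        x = x[:, None]
        return (
            np.log(self.weights)[None, :]
            + (self.a - 1) * np.log(x)
            + (self.b - 1) * np.log1p(-x)
            - special.betaln(self.a, self.b)[None, :]
        )

    def responsibilities(self, x: np.ndarray) -> np.ndarray:
        lp = self.logpdf(x)
        lp -= lp.max(axis=1, keepdims=True)
        r = np.exp(lp)
        return r / r.sum(axis=1, keepdims=True)

    def assign_states(self, x: np.ndarray, tie_state: int = 1) -> np.ndarray:
        """Max-posterior state per value; exact ties resolved to the
        hemimethylated state."""
        r = self.responsibilities(x)
        states = r.argmax(axis=1)
        is_tie = (r == r.max(axis=1, keepdims=True)).sum(axis=1) > 1
        states[is_tie] = tie_state
        return states


def _beta_mle(s1: float, s2: float, a0: float, b0: float) -> tuple[float, float]:
    """MLE of beta(a, b) given sufficient stats s1=E[log x], s2=E[log(1-x)],
    warm-started at (a0, b0); never returns a worse likelihood point."""

    def nll(theta):
        a, b = np.exp(theta)
        return -((a - 1) * s1 + (b - 1) * s2 - special.betaln(a, b))

    def grad(theta):
        a, b = np.exp(theta)
        dab = special.digamma(a + b)
        da = s1 - (special.digamma(a) - dab)
        db = s2 - (special.digamma(b) - dab)
        return np.array([-da * a, -db * b])

    x0 = np.log([a0, b0])
    res = optimize.minimize(nll, x0, jac=grad, method="L-BFGS-B")
    if res.fun <= nll(x0):
        a, b = np.exp(res.x)
        return float(a), float(b)
    return a0, b0


def _moment_init(x: np.ndarray) -> tuple[float, float]:
    m, v = float(np.mean(x)), float(np.var(x))
    v = max(v, 1e-6)
    c = max(m * (1 - m) / v - 1, 0.1)
    return max(m * c, 0.05), max((1 - m) * c, 0.05)


def fit_beta_mixture(
    betas,
    n_states: int = 3,
    tol: float = 1e-6,
    max_iter: int = 500,
    seed: int | None = None,
    warn: bool = True,
) -> BetaMixtureFit:
    """EM fit of an ``n_states``-component beta mixture.

    Initialization is quantile-based (hard assignment at fixed beta
    thresholds) and deterministic; ``seed`` is accepted for interface
    symmetry but unused. Values are clipped to (EPS, 1-EPS). Warns on
    non-convergence and returns the best iterate.
    """
    x = np.asarray(betas, dtype=float).ravel()
    x = x[~np.isnan(x)]
    if x.size < 100:
        raise ValueError("need at least 100 values to fit the mixture")
    x = np.clip(x, EPS, 1 - EPS)

    edges = np.linspace(0, 1, n_states + 1)[1:-1]
    if n_states == 3:
        edges = np.array([0.25, 0.75])  # U / H / M split
    labels = np.searchsorted(edges, x)
    a = np.empty(n_states)
    b = np.empty(n_states)
    w = np.empty(n_states)
    for k in range(n_states):
        grp = x[labels == k]
        if grp.size < 5:  # empty stratum: seed from global quantile band
            lo = k / n_states
            grp = np.quantile(x, [lo + 0.1 / n_states, lo + 0.9 / n_states])
        a[k], b[k] = _moment_init(grp)
        w[k] = max((labels == k).mean(), 1e-3)
    w /= w.sum()

    fit = BetaMixtureFit(a, b, w, loglik_trace=[])
    prev = -np.inf
    converged = False
    for _ in range(max_iter):
        lp = fit.logpdf(x)
        ll = float(special.logsumexp(lp, axis=1).sum())
        fit.loglik_trace.append(ll)
        r = fit.responsibilities(x)
        R = r.sum(axis=0)
        w = np.maximum(R / x.size, 1e-8)
        w /= w.sum()
        for k in range(n_states):
            if R[k] < 1e-8:
                continue
            s1 = float((r[:, k] * np.log(x)).sum() / R[k])
            s2 = float((r[:, k] * np.log1p(-x)).sum() / R[k])
            a[k], b[k] = _beta_mle(s1, s2, a[k], b[k])
        fit.a, fit.b, fit.weights = a, b, w
        if np.isfinite(prev) and abs(ll - prev) <= tol * (abs(prev) + 1.0):
            converged = True
            break
        prev = ll
    if not converged and warn:
        warnings.warn("beta mixture EM did not converge; returning best fit")
    order = np.argsort(fit.means)
    fit.a, fit.b, fit.weights = fit.a[order], fit.b[order], fit.weights[order]
    fit.converged = converged
    return fit


# ---------------------------------------------------------------------------
# BMIQ
# ---------------------------------------------------------------------------

#: EM iterations used for the BMIQ state fits. Deliberately few: the
#: fits must stay anchored to the threshold-based U/H/M initialization
#: (a fully converged ML fit on sharply bimodal data can reassign
#: components away from their state semantics).
BMIQ_EM_ITER = 8


def bmiq(
    betas_type1,
    betas_type2,
    fit1: BetaMixtureFit | None = None,
    fit2: BetaMixtureFit | None = None,
) -> np.ndarray:
    """Map type II beta values onto the type I distribution.

    Three-state mixtures are fitted to each design type; type II values
    assigned to the unmethylated (U) and methylated (M) states are
    quantile-mapped through the fitted beta CDFs onto the corresponding
    type I component, and hemimethylated (H) values are rescaled by a
    dilation between the mapped U and M boundaries. Type I values are
    never modified; the transform is monotone within each state.
    """
    x1 = np.clip(np.asarray(betas_type1, float), EPS, 1 - EPS)
    x2 = np.clip(np.asarray(betas_type2, float), EPS, 1 - EPS)
    fit1 = fit1 or fit_beta_mixture(x1, max_iter=BMIQ_EM_ITER, warn=False)
    fit2 = fit2 or fit_beta_mixture(x2, max_iter=BMIQ_EM_ITER, warn=False)

    states = fit2.assign_states(x2)
    out = x2.copy()

    U, H, M = 0, 1, 2
    for k, comp1 in ((U, 0), (M, 2)):
        sel = states == k
        if not sel.any():
            continue
        q = stats.beta.cdf(x2[sel], fit2.a[k], fit2.b[k])
        q = np.clip(q, EPS, 1 - EPS)
        out[sel] = stats.beta.ppf(q, fit1.a[comp1], fit1.b[comp1])

    selH = states == H
    if selH.any():
        h = x2[selH]
        lo, hi = float(h.min()), float(h.max())
        # boundaries of the mapped U and M classes
        nlo = float(out[states == U].max()) if (states == U).any() else lo
        nhi = float(out[states == M].min()) if (states == M).any() else hi
        if hi > lo and nhi > nlo:
            out[selH] = nlo + (h - lo) * (nhi - nlo) / (hi - lo)
    return np.clip(out, 0.0, 1.0)


# ---------------------------------------------------------------------------
# cohort pipeline
# ---------------------------------------------------------------------------

def normalize_cohort(
    M: pd.DataFrame,
    U: pd.DataFrame,
    manifest: pd.DataFrame,
    sheet: pd.DataFrame | None = None,
    stratify_by_sex: bool = False,
    offset: float = DEFAULT_OFFSET,
    bmiq_adjust: bool = True,
) -> pd.DataFrame:
    """Full normalization: background floor, channel adjustment,
    pooled-channel quantile normalization, beta recomputation and
    (autosomal path) per-sample BMIQ.

    With ``stratify_by_sex`` the quantile normalization runs on males
    and females separately and BMIQ is skipped (X-chromosome path).
    ``manifest`` provides ``design_type`` and ``channel`` per probe.
    """
    if not M.index.equals(U.index) or list(M.columns) != list(U.columns):
        raise ValueError("M and U matrices must share probes and samples")

    pooled = pd.concat([M, U], keys=["M", "U"])
    pooled = background_floor(pooled)
    Mb = pooled.loc["M"]
    Ub = pooled.loc["U"]
    Mb, Ub = channel_adjust(Mb, Ub, manifest["channel"])
    pooled = pd.concat([Mb, Ub], keys=["M", "U"])

    if stratify_by_sex:
        if sheet is None or "sex" not in sheet.columns:
            raise ValueError("sex-stratified normalization needs a sample sheet with sex")
        parts = []
        for _, cols in sheet.groupby("sex").groups.items():
            cols = [c for c in pooled.columns if c in set(cols)]
            sub = pooled[cols]
            parts.append(quantile_normalize(sub) if len(cols) >= 2 else sub)
        pooled = pd.concat(parts, axis=1)[M.columns]
    else:
        pooled = quantile_normalize(pooled)

    beta = pd.DataFrame(
        compute_beta(pooled.loc["M"].to_numpy(), pooled.loc["U"].to_numpy(), offset),
        index=M.index,
        columns=M.columns,
    )

    if bmiq_adjust and not stratify_by_sex:
        design = manifest["design_type"].reindex(beta.index)
        is2 = (design == "II").to_numpy()
        # both design groups must be large enough to anchor the state fits
        if is2.sum() >= 100 and (~is2).sum() >= 100:
            for col in beta.columns:
                v = beta[col].to_numpy(float)
                v2 = bmiq(v[~is2], v[is2])
                v = v.copy()
                v[is2] = v2
                beta[col] = v
    return beta
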