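"""Four-class mixture regression engine: EM warm start, Gibbs sampler,
posterior inclusion probabilities, and scheduled variant dropping with
Dirichlet prior compensation.

Model:  y = X b + Z a + W v + e,  e ~ N(0, E sigma_e2) with E = diag(1/w_j),
a ~ N(0, A sigma_a2), and each variant effect v_i drawn from one of four
normals with variances gamma_k * sigma_g2 (gamma = [0, 1e-4, 1e-3, 1e-2])
under mixing proportions P ~ Dirichlet(alpha).

The EM stage is a mean-field variational scheme (spike-and-slab-mixture
coordinate ascent) whose objective (ELBO) is non-decreasing; its point
estimates seed the sampler.  The sampler runs without burn-in and averages
over all iterations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from ._kernels import em_sweep, gibbs_sweep, polygenic_sweep

DEFAULT_GAMMA = (0.0, 1e-4, 1e-3, 1e-2)


class ConvergenceWarning(UserWarning):
    pass


# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------

@dataclass
class MixtureSpec:
    """Effect-variance classes (multiples of sigma_g2) and Dirichlet prior."""

    gamma: tuple = DEFAULT_GAMMA
    sigma_g2: float = 1.0
    alpha: tuple = (1.0, 1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        g = np.asarray(self.gamma, dtype=np.float64)
        a = np.asarray(self.alpha, dtype=np.float64)
        if g[0] != 0.0:
            raise ValueError("first mixture class must have zero variance")
        if (np.diff(g) < 0).any():
            raise ValueError("gamma must be non-decreasing")
        if g.shape != a.shape:
            raise ValueError("gamma and alpha must have equal length")
        if (a <= 0).any():
            raise ValueError("Dirichlet alpha must be positive")
        if self.sigma_g2 <= 0:
            raise ValueError("sigma_g2 must be positive")
        self.gamma = tuple(g)
        self.alpha = tuple(a)

    @property
    def n_classes(self) -> int:
        return len(self.gamma)

    def tau(self) -> np.ndarray:
        """Per-class effect variances."""
        return np.asarray(self.gamma) * self.sigma_g2


@dataclass
class ModelData:
    """Assembled model inputs.  ``Wt`` is variant-major (m x n) and centered."""

    y: np.ndarray
    X: np.ndarray
    Wt: np.ndarray
    weights: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    variant_id: np.ndarray
    centers: np.ndarray
    Ainv: np.ndarray | None = None
    rec_of: np.ndarray | None = None  # pedigree row -> record index, -1 if none

    def __post_init__(self) -> None:
        self.y = np.ascontiguousarray(self.y, dtype=np.float64)
        self.X = np.ascontiguousarray(self.X, dtype=np.float64)
        self.Wt = np.ascontiguousarray(self.Wt, dtype=np.float64)
        self.weights = np.ascontiguousarray(self.weights, dtype=np.float64)
        n = self.y.shape[0]
        if self.X.shape[0] != n or self.Wt.shape[1] != n or self.weights.shape[0] != n:
            raise ValueError("records of y, X, Wt and weights must be conformable")
        if (self.weights <= 0).any():
            raise ValueError("record weights must be positive")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("fixed-effect design is rank deficient")
        if (self.Ainv is None) != (self.rec_of is None):
            raise ValueError("Ainv and rec_of must be supplied together")

    @property
    def n_records(self) -> int:
        return self.y.shape[0]

    @property
    def n_variants(self) -> int:
        return self.Wt.shape[0]

    def diag_wtw(self) -> np.ndarray:
        """Weighted sum of squares of each variant column."""
        return (self.Wt ** 2) @ self.weights

    def sweep_order(self) -> np.ndarray:
        """Fixed ascending genome order (chrom, pos, index) for variant sweeps."""
        m = self.Wt.shape[0]
        return np.lexsort((np.arange(m), self.pos, self.chrom)).astype(np.int64)


@dataclass
class ModelState:
    """Current parameter values of the sampler (or EM point estimates)."""

    b: np.ndarray
    a: np.ndarray
    v: np.ndarray
    cls: np.ndarray
    P: np.ndarray
    sigma_e2: float
    sigma_a2: float
    active: np.ndarray
    em_responsibility: np.ndarray | None = None
    objective_trace: np.ndarray | None = None

    def copy(self) -> "ModelState":
        return ModelState(
            b=self.b.copy(), a=self.a.copy(), v=self.v.copy(), cls=self.cls.copy(),
            P=self.P.copy(), sigma_e2=self.sigma_e2, sigma_a2=self.sigma_a2,
            active=self.active.copy(),
            em_responsibility=None if self.em_responsibility is None
            else self.em_responsibility.copy(),
            objective_trace=self.objective_trace,
        )


@dataclass
class DropSchedule:
    """When and how much to drop: proportion d at 'em' or an MCMC iteration."""

    proportion: float = 0.0
    drop_point: int | str | None = None  # "em" or a 1-based MCMC iteration

    def __post_init__(self) -> None:
        if not (0 <= self.proportion < 1):
            raise ValueError("drop proportion must lie in [0, 1)")
        if self.drop_point is not None and self.drop_point != "em":
            if int(self.drop_point) <= 0:
                raise ValueError("drop iteration must be positive")
            self.drop_point = int(self.drop_point)


@dataclass
class PosteriorSummary:
    variant_id: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    v_mean: np.ndarray
    pip: np.ndarray
    class_prob: np.ndarray
    occupancy: np.ndarray
    P_mean: np.ndarray
    b_mean: np.ndarray
    a_mean: np.ndarray
    sigma_e2_mean: float
    sigma_a2_mean: float
    n_iter: int
    active: np.ndarray
    drop_iter: np.ndarray
    trace: dict | None = None
    marker_var_mean: float | None = None

    def effect_table(self, centers: np.ndarray | None = None) -> pd.DataFrame:
        df = pd.DataFrame({
            "variant_id": self.variant_id, "chrom": self.chrom, "pos": self.pos,
            "posterior_mean_effect": self.v_mean, "pip": self.pip,
        })
        for k in range(self.class_prob.shape[1]):
            df[f"p_class{k + 1}"] = self.class_prob[:, k]
        df["dropped"] = ~self.active
        df["drop_iter"] = self.drop_iter
        if centers is not None:
            df["center"] = centers
        return df


@dataclass
class VarianceComponents:
    h_M2: float
    h_A2: float
    sigma_e2: float
    sigma_a2: float
    class_occupancy: tuple

    @property
    def h2(self) -> float:
        return self.h_M2 + self.h_A2

    def to_dict(self) -> dict:
        return {"h_M2": self.h_M2, "h_A2": self.h_A2, "h2": self.h2,
                "sigma_e2": self.sigma_e2, "sigma_a2": self.sigma_a2,
                "class_occupancy": list(self.class_occupancy)}


# ---------------------------------------------------------------------------
# EM (mean-field warm start)
# ---------------------------------------------------------------------------

def _solve_fixed(data: ModelData, resid_plus_xb: np.ndarray) -> np.ndarray:
    Xw = data.X * data.weights[:, None]
    return np.linalg.solve(data.X.T @ Xw, Xw.T @ resid_plus_xb)


def _solve_polygenic(data: ModelData, resid_plus_za: np.ndarray,
                     sigma_e2: float, sigma_a2: float) -> np.ndarray:
    n_ped = data.Ainv.shape[0]
    lhs = data.Ainv / sigma_a2
    rhs = np.zeros(n_ped)
    has_rec = data.rec_of >= 0
    recs = data.rec_of[has_rec]
    lhs[has_rec, has_rec] += data.weights[recs] / sigma_e2
    rhs[has_rec] = data.weights[recs] * resid_plus_za[recs] / sigma_e2
    return np.linalg.solve(lhs, rhs)


def run_em(data: ModelData, spec: MixtureSpec, max_iter: int = 100,
           tol: float = 1e-6, sigma_a2_init: float | None = None) -> ModelState:
    """Mean-field EM warm start; returns point estimates for the sampler.

    Iterates coordinate updates of the per-variant mixture posteriors, the
    fixed effects, the polygenic values (when a pedigree is attached), the
    mixing proportions and the residual variance until the variational
    objective improves by less than ``tol`` (relative) or ``max_iter`` is
    reached (with a ``ConvergenceWarning``).
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    n, m = data.n_records, data.n_variants
    K = spec.n_classes
    tau = spec.tau()
    alpha = np.asarray(spec.alpha)

    v = np.zeros(m)
    varv = np.zeros(m)
    resp = np.zeros((m, K))
    resp[:, 0] = 1.0
    b = _solve_fixed(data, data.y)
    n_ped = 0 if data.Ainv is None else data.Ainv.shape[0]
    a = np.zeros(n_ped)
    P = alpha / alpha.sum()
    r = data.y - data.X @ b
    sigma_e2 = float(np.average(r ** 2, weights=data.weights))
    if n_ped:
        sigma_a2 = sigma_a2_init if sigma_a2_init is not None else 0.05 * sigma_e2
    else:
        sigma_a2 = 0.0

    C = data.diag_wtw()
    active_idx = data.sweep_order()
    logw_const = 0.5 * np.log(data.weights).sum() - 0.5 * n * np.log(2.0 * np.pi)

    objective = []
    prev = -np.inf
    converged = False
    for _ in range(max_iter):
        logP = np.log(np.maximum(P, 1e-300))
        pen_gauss, ent_class = em_sweep(data.Wt, data.weights, r, v, varv,
                                        active_idx, logP, tau, sigma_e2, C, resp)
        if n_ped:
            rec_term = np.zeros(n)
            has_rec = data.rec_of >= 0
            rec_term[data.rec_of[has_rec]] = a[has_rec]
            a = _solve_polygenic(data, r + rec_term, sigma_e2, sigma_a2)
            new_term = np.zeros(n)
            new_term[data.rec_of[has_rec]] = a[has_rec]
            r += rec_term - new_term
        b_new = _solve_fixed(data, r + data.X @ b)
        r += data.X @ (b - b_new)
        b = b_new
        class_sum = resp.sum(axis=0)
        P = class_sum + alpha - 1.0
        P = np.maximum(P, 1e-12)
        P /= P.sum()
        S = float((data.weights * r ** 2).sum() + (C * varv).sum())
        sigma_e2 = S / n

        elbo = (logw_const - 0.5 * n * np.log(sigma_e2) - S / (2.0 * sigma_e2)
                + pen_gauss + ent_class
                + float((class_sum + alpha - 1.0) @ np.log(np.maximum(P, 1e-300))))
        if n_ped:
            elbo -= float(a @ data.Ainv @ a) / (2.0 * sigma_a2)
        objective.append(elbo)
        if np.isfinite(prev) and abs(elbo - prev) <= tol * (1.0 + abs(prev)):
            converged = True
            break
        prev = elbo
    if not converged:
        warnings.warn("EM did not converge within max_iter; returning last state",
                      ConvergenceWarning)

    cls = np.argmax(resp, axis=1).astype(np.int64)
    return ModelState(
        b=b, a=a, v=v, cls=cls, P=P, sigma_e2=sigma_e2, sigma_a2=sigma_a2,
        active=np.ones(m, dtype=bool), em_responsibility=resp,
        objective_trace=np.asarray(objective),
    )


# ---------------------------------------------------------------------------
# PIP and dropping
# ---------------------------------------------------------------------------

def compute_pip(class_trace: np.ndarray | None = None,
                responsibilities: np.ndarray | None = None) -> np.ndarray:
    """PIP per variant: fraction of samples in a non-zero-variance class,
    or the summed responsibility over those classes when given EM output."""
    if (class_trace is None) == (responsibilities is None):
        raise ValueError("supply exactly one of class_trace or responsibilities")
    if class_trace is not None:
        trace = np.asarray(class_trace)
        if trace.ndim != 2 or trace.shape[0] == 0:
            raise ValueError("class_trace must be a non-empty (iterations x variants) array")
        return (trace != 0).mean(axis=0)
    resp = np.asarray(responsibilities, dtype=np.float64)
    if resp.ndim != 2 or resp.shape[1] < 2:
        raise ValueError("responsibilities must be (variants x classes)")
    return resp[:, 1:].sum(axis=1)


def _select_lowest_pip(active: np.ndarray, pip: np.ndarray, d: float) -> np.ndarray:
    """Indices of the round(d * n_active) lowest-PIP active variants.

    Ties are broken by ascending variant index (lexsort order).
    """
    if not (0 <= d < 1):
        raise ValueError("drop proportion must lie in [0, 1)")
    act = np.nonzero(active)[0]
    n_drop = int(round(d * act.shape[0]))
    if n_drop == 0:
        return np.empty(0, dtype=np.int64)
    order = np.lexsort((act, pip[act]))
    return np.sort(act[order[:n_drop]])


def drop_variants(state: ModelState, spec: MixtureSpec, pip: np.ndarray, d: float,
                  compensation: str = "pseudo_counts"
                  ) -> tuple[ModelState, MixtureSpec, np.ndarray]:
    """Deactivate the lowest-PIP variants and compensate the Dirichlet prior.

    With ``compensation='pseudo_counts'`` (default) the prior becomes
    alpha_k + n_dropped * P_k, absorbing the dropped variants as expected
    pseudo-counts at the current mixing proportions; ``'literal'`` adds the
    bare proportions instead.  Returns the new state, spec and the dropped
    variant indices (the caller owns any running-residual adjustment).
    """
    if compensation not in ("pseudo_counts", "literal"):
        raise ValueError("compensation must be 'pseudo_counts' or 'literal'")
    dropped = _select_lowest_pip(state.active, np.asarray(pip), d)
    if dropped.size == 0:
        return state, spec, dropped
    new_state = state.copy()
    new_state.active[dropped] = False
    new_state.v[dropped] = 0.0
    new_state.cls[dropped] = 0
    scale = float(dropped.size) if compensation == "pseudo_counts" else 1.0
    new_alpha = np.asarray(spec.alpha) + scale * state.P
    new_spec = replace(spec, alpha=tuple(new_alpha))
    return new_state, new_spec, dropped


# ---------------------------------------------------------------------------
# Gibbs sampler
# ---------------------------------------------------------------------------

def run_mcmc(state: ModelState, data: ModelData, spec: MixtureSpec, n_iter: int,
             schedule: DropSchedule | None = None,
             seed: int | np.random.SeedSequence | None = 0,
             store_class_trace: bool = False,
             compensation: str = "pseudo_counts") -> PosteriorSummary:
    """Gibbs sampler started from ``state``; no burn-in, means over all draws.

    Per iteration: sweep classes and effects of all active variants, draw
    P ~ Dirichlet(alpha + class counts), update polygenic values single-site
    (if a pedigree is attached) and their variance, the fixed effects, and
    the residual variance from their scaled inverse chi-square conditionals.
    Scheduled dropping deactivates the lowest-PIP variants at the drop point
    and folds their expected class occupancy into the Dirichlet prior.
    """
    if n_iter < 0:
        raise ValueError("n_iter must be non-negative")
    if schedule is not None and isinstance(schedule.drop_point, int):
        if schedule.drop_point > max(n_iter, 0):
            raise ValueError("drop point lies beyond the number of iterations")

    n, m = data.n_records, data.n_variants
    K = spec.n_classes
    tau = spec.tau()
    alpha = np.asarray(spec.alpha, dtype=np.float64)
    rng = np.random.default_rng(seed)

    b = state.b.copy()
    a = state.a.copy()
    v = state.v.copy()
    cls = state.cls.copy()
    active = state.active.copy()
    P = state.P.copy()
    sigma_e2 = float(state.sigma_e2)
    sigma_a2 = float(state.sigma_a2)
    drop_iter = np.full(m, -1, dtype=np.int64)

    n_ped = 0 if data.Ainv is None else data.Ainv.shape[0]
    has_rec = data.rec_of >= 0 if n_ped else None

    def rec_vector(avec: np.ndarray) -> np.ndarray:
        out = np.zeros(n)
        if n_ped:
            out[data.rec_of[has_rec]] = avec[has_rec]
        return out

    r = data.y - data.X @ b - rec_vector(a) - data.Wt.T @ v
    C = data.diag_wtw()

    # fixed-effect sampling pieces (X'WX constant across iterations)
    Xw = data.X * data.weights[:, None]
    XtWX = data.X.T @ Xw
    XtWX_inv = np.linalg.inv(XtWX)
    L_b = np.linalg.cholesky(XtWX_inv)

    if n_iter == 0:
        return PosteriorSummary(
            variant_id=data.variant_id, chrom=data.chrom, pos=data.pos,
            v_mean=v.copy(), pip=np.zeros(m), class_prob=np.eye(K)[cls],
            occupancy=np.bincount(cls[active], minlength=K).astype(np.float64),
            P_mean=P.copy(), b_mean=b.copy(), a_mean=a.copy(),
            sigma_e2_mean=sigma_e2, sigma_a2_mean=sigma_a2, n_iter=0,
            active=active, drop_iter=drop_iter)

    def apply_drop(pip_now: np.ndarray, at_iter: int) -> None:
        nonlocal active, alpha, r
        if schedule is None or schedule.proportion == 0:
            return
        pseudo = ModelState(b=b, a=a, v=v, cls=cls, P=P, sigma_e2=sigma_e2,
                            sigma_a2=sigma_a2, active=active)
        new_state, new_spec, dropped = drop_variants(
            pseudo, replace(spec, alpha=tuple(alpha)), pip_now,
            schedule.proportion, compensation)
        if dropped.size:
            r += data.Wt[dropped].T @ v[dropped]
            v[dropped] = 0.0
            cls[dropped] = 0
            active = new_state.active
            alpha = np.asarray(new_spec.alpha, dtype=np.float64)
            drop_iter[dropped] = at_iter

    if schedule is not None and schedule.drop_point == "em":
        if state.em_responsibility is None:
            raise ValueError("dropping after EM requires EM responsibilities in the state")
        apply_drop(compute_pip(responsibilities=state.em_responsibility), 0)

    v_sum = np.zeros(m)
    pip_counts = np.zeros(m, dtype=np.int64)
    class_counts = np.zeros((m, K), dtype=np.int64)
    occupancy_sum = np.zeros(K)
    P_sum = np.zeros(K)
    b_sum = np.zeros(b.shape[0])
    a_sum = np.zeros(n_ped)
    se_sum = 0.0
    sa_sum = 0.0
    trace = {"P": np.zeros((n_iter, K)), "sigma_e2": np.zeros(n_iter),
             "sigma_a2": np.zeros(n_iter), "marker_var": np.zeros(n_iter)}
    # projection for fixed-effect-adjusted marker variance
    pinvX = np.linalg.solve(data.X.T @ data.X, data.X.T)
    class_trace = np.zeros((n_iter, m), dtype=np.int8) if store_class_trace else None
    row_idx = np.arange(m)

    order = data.sweep_order()
    for it in range(1, n_iter + 1):
        active_idx = order[active[order]]
        u_cls = rng.random(active_idx.shape[0])
        z_eff = rng.standard_normal(active_idx.shape[0])
        counts = np.zeros(K, dtype=np.int64)
        logP = np.log(np.maximum(P, 1e-300))
        gibbs_sweep(data.Wt, data.weights, r, v, cls, active_idx, logP, tau,
                    sigma_e2, C, u_cls, z_eff, counts)
        P = rng.dirichlet(alpha + counts)

        if n_ped:
            z = rng.standard_normal(n_ped)
            polygenic_sweep(data.Ainv, a, r, data.weights,
                            data.rec_of.astype(np.int64), sigma_a2, sigma_e2, z)
            quad = float(a @ data.Ainv @ a)
            df_a = max(n_ped - 2, 1)
            sigma_a2 = quad / max(rng.chisquare(df_a), 1e-12)

        r_b = r + data.X @ b
        b_mean = XtWX_inv @ (Xw.T @ r_b)
        b = b_mean + np.sqrt(sigma_e2) * (L_b @ rng.standard_normal(b.shape[0]))
        r = r_b - data.X @ b

        sse = float((data.weights * r ** 2).sum())
        df_e = max(n - 2, 1)
        sigma_e2 = sse / max(rng.chisquare(df_e), 1e-12)

        v_sum += v
        nz = cls != 0
        pip_counts += nz
        class_counts[row_idx, cls] += 1
        occupancy_sum += counts
        P_sum += P
        b_sum += b
        if n_ped:
            a_sum += a
        se_sum += sigma_e2
        sa_sum += sigma_a2
        trace["P"][it - 1] = P
        trace["sigma_e2"][it - 1] = sigma_e2
        trace["sigma_a2"][it - 1] = sigma_a2
        # marker score of this draw, recovered from the running residual
        g = data.y - data.X @ b - rec_vector(a) - r
        g_adj = g - data.X @ (pinvX @ g)
        trace["marker_var"][it - 1] = g_adj.var()
        if store_class_trace:
            class_trace[it - 1] = cls

        if schedule is not None and schedule.drop_point == it:
            apply_drop(pip_counts / it, it)

    if store_class_trace:
        trace["class"] = class_trace
    return PosteriorSummary(
        variant_id=data.variant_id, chrom=data.chrom, pos=data.pos,
        v_mean=v_sum / n_iter, pip=pip_counts / n_iter,
        class_prob=class_counts / n_iter, occupancy=occupancy_sum / n_iter,
        P_mean=P_sum / n_iter, b_mean=b_sum / n_iter,
        a_mean=a_sum / n_iter if n_ped else np.zeros(0),
        sigma_e2_mean=se_sum / n_iter, sigma_a2_mean=sa_sum / n_iter,
        n_iter=n_iter, active=active, drop_iter=drop_iter, trace=trace,
        marker_var_mean=float(trace["marker_var"].mean()))


def variance_components(summary: PosteriorSummary, data: ModelData) -> VarianceComponents:
    """Fractions of the fixed-effect-adjusted phenotypic variance explained.

    h_M2 is the posterior mean of var(W v) over the sampler draws (falling
    back to the variance of the posterior-mean marker score when no trace
    is available); h_A2 = sigma_a2 / the same denominator; h2 is their sum.
    """
    y_adj = data.y - data.X @ summary.b_mean
    var_adj = float(y_adj.var())
    if var_adj == 0:
        raise ValueError("zero phenotypic variance")
    if summary.marker_var_mean is not None:
        marker_var = summary.marker_var_mean
    else:
        g = data.Wt.T @ summary.v_mean
        g_adj = g - data.X @ np.linalg.solve(data.X.T @ data.X, data.X.T @ g)
        marker_var = float(g_adj.var())
    h_m2 = marker_var / var_adj
    h_a2 = float(summary.sigma_a2_mean) / var_adj
    return VarianceComponents(
        h_M2=h_m2, h_A2=h_a2, sigma_e2=float(summary.sigma_e2_mean),
        sigma_a2=float(summary.sigma_a2_mean),
        class_occupancy=tuple(float(x) for x in summary.occupancy))
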