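"""Beta + Pareto finite mixture for the tumour site frequency spectrum.

The model for n mutation frequencies x_i in (0, 1) is a univariate finite
mixture with one optional Pareto Type-I component (index 0, the neutral
power-law tail predicted by population genetics of expanding populations)
and k >= 1 Beta components (ongoing clonal expansions):

    f(x | theta, pi) = pi_0 * Pareto(x | x*, alpha)
                       + sum_w pi_w * Beta(x | a_w, b_w)

The Pareto scale x* is fixed at the minimum retained frequency (the MLE of
the scale is the sample minimum; fixing it stabilises model selection and
it is not counted among the free parameters). The fit alternates a
responsibility (E-like) step with component refits: weighted
moment-matching for the Beta peaks and the weighted closed-form MLE for
the Pareto shape (default), or a full weighted maximum-likelihood Beta
update which makes the procedure an exact EM with a non-increasing
negative log-likelihood trace.

The estimator follows the scikit-learn API: ``BetaParetoMixture`` has
``fit`` / ``predict`` / ``predict_proba`` / ``score_samples`` / ``sample``
and fitted attributes with a trailing underscore. Module-level functions
(:func:`pareto_density`, :func:`mixture_nll`, :func:`fit_mixture`, ...)
are thin wrappers kept for pipeline-style use.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import betaln, digamma, logsumexp
from sklearn.base import BaseEstimator, DensityMixin

from ._utils import derive_seed, logger, norm_seed
from .errors import (
    DegenerateClusterError,
    DegenerateTailError,
    FitError,
    ValidationError,
)
from .io import VAF, FrequencyDataset

#: numerical bounds on the Pareto shape during fitting (documented guard;
#: generative values in practice lie well inside)
ALPHA_BOUNDS = (1e-2, 1e2)
_MIN_WEIGHT = 1e-10


# ----------------------------------------------------------------------------
# component parameter containers
# ----------------------------------------------------------------------------
@dataclass(frozen=True)
class ParetoComponent:
    """Pareto Type-I tail: density alpha * scale^alpha / x^(alpha+1) on
    [scale, inf), zero below the scale."""

    scale: float
    shape: float

    def __post_init__(self) -> None:
        if not (self.scale > 0 and self.shape > 0):
            raise ValidationError("Pareto scale and shape must be positive")

    @property
    def mean(self) -> float:
        """Closed-form mean (infinite for shape <= 1)."""
        if self.shape <= 1:
            return np.inf
        return self.shape * self.scale / (self.shape - 1)


@dataclass(frozen=True)
class BetaComponent:
    """Standard Beta(a, b) component describing one clonal peak."""

    a: float
    b: float

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0):
            raise ValidationError("Beta shapes must be positive")

    @property
    def mean(self) -> float:
        return self.a / (self.a + self.b)

    @property
    def variance(self) -> float:
        s = self.a + self.b
        return self.a * self.b / (s * s * (s + 1.0))


# ----------------------------------------------------------------------------
# densities
# ----------------------------------------------------------------------------
def pareto_log_density(x, component: ParetoComponent) -> np.ndarray:
    """log Pareto Type-I density; -inf below the scale."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    out = np.full(x.shape, -np.inf)
    ok = x >= component.scale
    if np.any(ok):
        out[ok] = (
            np.log(component.shape)
            + component.shape * np.log(component.scale)
            - (component.shape + 1.0) * np.log(x[ok])
        )
    return out


def pareto_density(x, component: ParetoComponent) -> np.ndarray:
    return np.exp(pareto_log_density(x, component))


def beta_log_density(x, component: BetaComponent) -> np.ndarray:
    """log Beta density; raises for points outside the open interval (0, 1)."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    if np.any((x <= 0.0) | (x >= 1.0)):
        raise ValidationError("Beta density is defined on the open interval (0, 1)")
    return (
        (component.a - 1.0) * np.log(x)
        + (component.b - 1.0) * np.log1p(-x)
        - betaln(component.a, component.b)
    )


def beta_density(x, component: BetaComponent) -> np.ndarray:
    return np.exp(beta_log_density(x, component))


# ----------------------------------------------------------------------------
# weighted component estimators
# ----------------------------------------------------------------------------
def fit_beta_moment_match(x, w) -> BetaComponent:
    """Weighted moment-matching Beta estimator.

    With weighted mean m and variance v, a = m*(m(1-m)/v - 1) and
    b = (1-m)*(m(1-m)/v - 1); requires 0 < v < m(1-m).
    """
    x = np.asarray(x, dtype=float)
    w = np.asarray(w, dtype=float)
    sw = w.sum()
    if sw <= 0:
        raise DegenerateClusterError("component has zero total responsibility")
    m = float((w * x).sum() / sw)
    v = float((w * (x - m) ** 2).sum() / sw)
    # the lower bound also rejects numerically-zero variance (a point mass),
    # whose matched shape parameters would be meaninglessly large
    if not (0.0 < m < 1.0) or v <= 1e-10 * m * (1.0 - m) or v >= m * (1.0 - m):
        raise DegenerateClusterError(
            f"degenerate Beta moments: mean={m:.6g}, var={v:.6g}"
        )
    c = m * (1.0 - m) / v - 1.0
    return BetaComponent(a=m * c, b=(1.0 - m) * c)


def fit_beta_mle(x, w, start: BetaComponent | None = None) -> BetaComponent:
    """Weighted maximum-likelihood Beta estimator (L-BFGS on log-shapes).

    Falls back to the starting point if the optimiser fails to improve the
    weighted log-likelihood, which preserves EM monotonicity.
    """
    x = np.asarray(x, dtype=float)
    w = np.asarray(w, dtype=float)
    sw = w.sum()
    if sw <= 0:
        raise DegenerateClusterError("component has zero total responsibility")
    slx = float((w * np.log(x)).sum())
    sl1x = float((w * np.log1p(-x)).sum())
    if start is None:
        start = fit_beta_moment_match(x, w)

    def negloglik_and_grad(p):
        a, b = np.exp(p)
        nll = -(
            (a - 1.0) * slx + (b - 1.0) * sl1x - sw * betaln(a, b)
        )
        da = -(slx - sw * (digamma(a) - digamma(a + b)))
        db = -(sl1x - sw * (digamma(b) - digamma(a + b)))
        return nll, np.array([da * a, db * b])

    p0 = np.log([start.a, start.b])
    res = minimize(negloglik_and_grad, p0, jac=True, method="L-BFGS-B")
    f0, _ = negloglik_and_grad(p0)
    if res.success and np.isfinite(res.fun) and res.fun <= f0:
        a, b = np.exp(res.x)
        return BetaComponent(a=float(a), b=float(b))
    return start


def fit_pareto_shape(x, w, scale: float) -> float:
    """Weighted Hill-type MLE of the Pareto shape with fixed scale:
    alpha = sum(w) / sum(w * log(x / scale))."""
    x = np.asarray(x, dtype=float)
    w = np.asarray(w, dtype=float)
    if np.any(x < scale - 1e-12):
        raise ValidationError("all points must be >= the Pareto scale")
    sw = w.sum()
    if sw <= 0:
        raise DegenerateTailError("tail has zero total responsibility")
    denom = float((w * np.log(np.maximum(x, scale) / scale)).sum())
    if denom <= 0:
        raise DegenerateTailError("all tail mass at the scale point")
    return float(sw / denom)


# ----------------------------------------------------------------------------
# the estimator
# ----------------------------------------------------------------------------
class _Degenerate(Exception):
    pass


class BetaParetoMixture(DensityMixin, BaseEstimator):
    """Mixture of one optional Pareto Type-I tail and ``n_beta`` Beta peaks.

    Parameters
    ----------
    n_beta : int
        Number of Beta components (k >= 1).
    tail : bool
        Whether to include the power-law tail (component index 0).
    beta_estimator : {"moment_match", "mle"}
        Beta M-step: weighted moment matching (default) or full weighted
        maximum likelihood (exact EM; monotone NLL trace).
    n_init : int
        Number of restarts from random initialisations; the best final
        NLL wins. Restart seeds are derived from ``random_state`` so the
        result is independent of execution order.
    max_iter, tol : int, float
        Iteration cap and relative-NLL convergence tolerance.
    random_state : int or None
        Seed for initialisation (None draws fresh entropy).

    Fitted attributes (canonical order: tail first, then Betas by
    decreasing mean): ``weights_``, ``tail_``, ``betas_``,
    ``responsibilities_``, ``nll_``, ``fit_trace_``, ``n_iter_``,
    ``converged_``, ``lambda_``, ``n_``, ``scores_`` (set by model
    selection).
    """

    def __init__(
        self,
        n_beta: int = 1,
        tail: bool = True,
        beta_estimator: str = "moment_match",
        n_init: int = 10,
        max_iter: int = 500,
        tol: float = 1e-6,
        random_state: int | None = None,
    ):
        self.n_beta = n_beta
        self.tail = tail
        self.beta_estimator = beta_estimator
        self.n_init = n_init
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    # -- helpers ------------------------------------------------------------
    @property
    def n_components_(self) -> int:
        return len(self.betas_) + (1 if self.tail_ is not None else 0)

    def _validate_x(self, X) -> np.ndarray:
        x = np.asarray(X, dtype=float)
        if x.ndim == 2 and x.shape[1] == 1:
            x = x[:, 0]
        if x.ndim != 1:
            raise ValidationError("expected a 1-d array of frequencies")
        if not np.all(np.isfinite(x)):
            raise ValidationError("frequencies must be finite")
        if np.any((x <= 0.0) | (x >= 1.0)):
            raise ValidationError(
                "fitting frequencies must lie strictly inside (0, 1); "
                "filter the dataset first"
            )
        return x

    def _log_component_matrix(self, x: np.ndarray) -> np.ndarray:
        cols = []
        if self.tail_ is not None:
            cols.append(pareto_log_density(x, self.tail_))
        for c in self.betas_:
            cols.append(beta_log_density(x, c))
        return np.column_stack(cols)

    def _log_weighted(self, x: np.ndarray) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return self._log_component_matrix(x) + np.log(self.weights_)[None, :]

    # -- core EM-like loop --------------------------------------------------
    # per-restart spread of the initial Beta variance, as a fraction of the
    # maximal variance m(1-m): broad inits explore, narrow inits prevent the
    # merge-collapse of overlapping peaks under moment matching
    _INIT_VAR_FACTORS = (0.05, 0.25)

    def _init_params(self, x: np.ndarray, rng: np.random.Generator,
                     restart: int = 0):
        k = self.n_beta
        scale = float(np.min(x))
        qs = np.quantile(x, (np.arange(1, k + 1)) / (k + 1.0))
        means = np.clip(qs + rng.normal(0.0, 0.03, size=k), 0.02, 0.98)
        var_factor = self._INIT_VAR_FACTORS[restart % len(self._INIT_VAR_FACTORS)]
        betas = []
        for m in means:
            v = var_factor * m * (1.0 - m)
            c = m * (1.0 - m) / v - 1.0
            betas.append(BetaComponent(a=m * c, b=(1.0 - m) * c))
        tail = (
            ParetoComponent(scale=scale, shape=float(rng.uniform(0.5, 3.0)))
            if self.tail
            else None
        )
        n_comp = k + (1 if self.tail else 0)
        weights = np.full(n_comp, 1.0 / n_comp)
        return tail, betas, weights

    def _m_step(self, x: np.ndarray, z: np.ndarray):
        weights = z.mean(axis=0)
        if np.any(weights < _MIN_WEIGHT):
            raise _Degenerate("a mixing proportion collapsed to zero")
        weights = weights / weights.sum()
        off = 1 if self.tail_ is not None else 0
        tail = self.tail_
        if tail is not None:
            try:
                shape = fit_pareto_shape(x, z[:, 0], tail.scale)
            except DegenerateTailError as e:
                raise _Degenerate(str(e))
            tail = ParetoComponent(
                scale=tail.scale, shape=float(np.clip(shape, *ALPHA_BOUNDS))
            )
        betas = []
        for j in range(self.n_beta):
            w = z[:, off + j]
            try:
                if self.beta_estimator == "mle":
                    betas.append(fit_beta_mle(x, w, start=self.betas_[j]))
                else:
                    betas.append(fit_beta_moment_match(x, w))
            except DegenerateClusterError as e:
                raise _Degenerate(str(e))
        return tail, betas, weights

    def _single_fit(self, x: np.ndarray, seed: int, restart: int = 0):
        rng = np.random.default_rng(seed)
        self.tail_, self.betas_, self.weights_ = self._init_params(x, rng, restart)
        trace: list[float] = []
        converged = False
        n_iter = 0
        for it in range(1, self.max_iter + 1):
            n_iter = it
            lw = self._log_weighted(x)
            ll_i = logsumexp(lw, axis=1)
            if not np.all(np.isfinite(ll_i)):
                bad = int(np.flatnonzero(~np.isfinite(ll_i))[0])
                raise FitError(
                    f"mixture density is zero at point index {bad} (x={x[bad]:.6g})"
                )
            nll = float(-ll_i.sum())
            trace.append(nll)
            z = np.exp(lw - ll_i[:, None])
            if len(trace) >= 2 and abs(trace[-2] - nll) <= self.tol * abs(trace[-2]):
                converged = True
                break
            self.tail_, self.betas_, self.weights_ = self._m_step(x, z)
        return trace, z, converged, n_iter

    def fit(self, X, y=None) -> "BetaParetoMixture":
        x = self._validate_x(X)
        if self.n_beta < 1:
            raise ValidationError("n_beta must be >= 1")
        n_comp = self.n_beta + (1 if self.tail else 0)
        if x.size < n_comp:
            raise ValidationError(
                f"need at least {n_comp} points to fit {n_comp} components"
            )
        base_seed = norm_seed(self.random_state)
        best = None
        failures: list[str] = []
        for r in range(self.n_init):
            seed = derive_seed(base_seed, r)
            try:
                trace, z, converged, n_iter = self._single_fit(x, seed, r)
            except _Degenerate as e:
                failures.append(str(e))
                continue
            if best is None or trace[-1] < best[0]:
                best = (
                    trace[-1],
                    self.tail_,
                    [*self.betas_],
                    self.weights_.copy(),
                    trace,
                    converged,
                    n_iter,
                )
        if best is None:
            raise FitError(
                f"all {self.n_init} restarts degenerate "
                f"(last reason: {failures[-1] if failures else 'unknown'})"
            )
        (_, self.tail_, self.betas_, self.weights_, trace, converged, n_iter) = best
        self._canonicalise()
        # final E-step so responsibilities/NLL are consistent with the
        # canonical parameters
        lw = self._log_weighted(x)
        ll_i = logsumexp(lw, axis=1)
        self.responsibilities_ = np.exp(lw - ll_i[:, None])
        self.nll_ = float(-ll_i.sum())
        self.fit_trace_ = np.asarray(trace + [self.nll_])
        self.converged_ = converged
        self.n_iter_ = n_iter
        self.n_ = x.size
        self.lambda_ = self._lambda()
        self.scores_ = None
        self.n_failed_restarts_ = len(failures)
        return self

    def _lambda(self) -> int:
        k = len(self.betas_)
        has_tail = self.tail_ is not None
        n_comp = k + (1 if has_tail else 0)
        return 2 * k + (1 if has_tail else 0) + (n_comp - 1)

    def _canonicalise(self) -> None:
        """Sort Beta components by decreasing mean (tail stays first)."""
        off = 1 if self.tail_ is not None else 0
        order = np.argsort([-c.mean for c in self.betas_], kind="stable")
        self.betas_ = [self.betas_[i] for i in order]
        w = self.weights_.copy()
        w[off:] = w[off:][order]
        self.weights_ = w

    # -- inference ----------------------------------------------------------
    def _check_fitted(self) -> None:
        if not hasattr(self, "weights_"):
            raise FitError("model is not fitted")

    def score_samples(self, X) -> np.ndarray:
        """Log mixture density per point (points below the Pareto scale get
        Beta mass only)."""
        self._check_fitted()
        x = self._validate_x(X)
        return logsumexp(self._log_weighted(x), axis=1)

    def nll(self, X) -> float:
        """Negative log-likelihood of X under the fitted parameters."""
        ll = self.score_samples(X)
        if not np.all(np.isfinite(ll)):
            bad = int(np.flatnonzero(~np.isfinite(ll))[0])
            raise FitError(f"mixture density is zero at point index {bad}")
        return float(-ll.sum())

    def predict_proba(self, X) -> np.ndarray:
        """Responsibility matrix z (rows sum to 1; tail column is exactly 0
        below the Pareto scale)."""
        self._check_fitted()
        x = self._validate_x(X)
        lw = self._log_weighted(x)
        ll_i = logsumexp(lw, axis=1)
        if not np.all(np.isfinite(ll_i)):
            bad = int(np.flatnonzero(~np.isfinite(ll_i))[0])
            raise FitError(f"mixture density is zero at point index {bad}")
        return np.exp(lw - ll_i[:, None])

    def predict(self, X) -> np.ndarray:
        """Hard assignment: argmax responsibility, ties broken toward the
        lowest component index (tail first)."""
        return np.argmax(self.predict_proba(X), axis=1)

    def cluster_names(self) -> list[str]:
        self._check_fitted()
        names = ["Tail"] if self.tail_ is not None else []
        names += [f"C{j + 1}" for j in range(len(self.betas_))]
        return names

    def sample(self, n_samples: int, random_state: int | None = None):
        """Draw (x, component_labels) from the fitted mixture; Pareto draws
        are truncated to (scale, 1) by inverse-CDF."""
        self._check_fitted()
        rng = np.random.default_rng(norm_seed(random_state))
        labels = rng.choice(self.n_components_, size=n_samples, p=self.weights_)
        x = np.empty(n_samples)
        off = 0
        if self.tail_ is not None:
            off = 1
            m = labels == 0
            if m.any():
                c = self.tail_
                fmax = 1.0 - c.scale**c.shape  # CDF at 1
                u = rng.uniform(0.0, fmax, size=int(m.sum()))
                x[m] = c.scale * (1.0 - u) ** (-1.0 / c.shape)
        for j, c in enumerate(self.betas_):
            m = labels == off + j
            if m.any():
                x[m] = rng.beta(c.a, c.b, size=int(m.sum()))
        # guard against boundary values from floating point
        x = np.clip(x, np.nextafter(0.0, 1.0), np.nextafter(1.0, 0.0))
        return x, labels

    # -- serialisation ------------------------------------------------------
    def to_dict(self) -> dict:
        self._check_fitted()
        from .selection import ScoreSet  # local import to avoid a cycle

        d = {
            "n_beta": len(self.betas_),
            "tail": self.tail_ is not None,
            "weights": list(map(float, self.weights_)),
            "betas": [{"a": c.a, "b": c.b, "mean": c.mean, "variance": c.variance}
                      for c in self.betas_],
            "tail_params": None
            if self.tail_ is None
            else {"scale": self.tail_.scale, "shape": self.tail_.shape},
            "nll": self.nll_,
            "lambda": self.lambda_,
            "n": self.n_,
            "converged": bool(self.converged_),
            "n_iter": int(self.n_iter_),
            "beta_estimator": self.beta_estimator,
            "random_state": self.random_state,
            "scores": None if self.scores_ is None else self.scores_.to_dict(),
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "BetaParetoMixture":
        from .selection import ScoreSet

        m = cls(
            n_beta=d["n_beta"],
            tail=d["tail"],
            beta_estimator=d.get("beta_estimator", "moment_match"),
            random_state=d.get("random_state"),
        )
        m.betas_ = [BetaComponent(a=b["a"], b=b["b"]) for b in d["betas"]]
        m.tail_ = (
            None
            if d["tail_params"] is None
            else ParetoComponent(scale=d["tail_params"]["scale"],
                                 shape=d["tail_params"]["shape"])
        )
        m.weights_ = np.asarray(d["weights"], dtype=float)
        m.nll_ = d["nll"]
        m.lambda_ = d["lambda"]
        m.n_ = d["n"]
        m.converged_ = d["converged"]
        m.n_iter_ = d["n_iter"]
        m.fit_trace_ = np.asarray([d["nll"]])
        m.responsibilities_ = None
        m.scores_ = None if d.get("scores") is None else ScoreSet(**d["scores"])
        return m


# ----------------------------------------------------------------------------
# module-level operations (thin wrappers)
# ----------------------------------------------------------------------------
def _as_x(data) -> np.ndarray:
    if isinstance(data, FrequencyDataset):
        return data.frequencies
    return np.asarray(data, dtype=float)


def mixture_nll(data, model: BetaParetoMixture) -> float:
    """-log f(D | theta, pi) for a dataset under a (fitted) model."""
    return model.nll(_as_x(data))


def responsibilities(data, model: BetaParetoMixture) -> np.ndarray:
    """Posterior component membership z_ic by Bayes' rule."""
    return model.predict_proba(_as_x(data))


def fit_mixture(
    data,
    k: int,
    tail: bool = True,
    config=None,
    **kwargs,
) -> BetaParetoMixture:
    """Fit a (k Betas [+ tail]) mixture; see :class:`BetaParetoMixture`."""
    from .selection import FitConfig

    cfg = config if config is not None else FitConfig(**kwargs)
    model = BetaParetoMixture(
        n_beta=k,
        tail=tail,
        beta_estimator=cfg.beta_estimator,
        n_init=cfg.restarts,
        max_iter=cfg.max_iter,
        tol=cfg.epsilon,
        random_state=cfg.seed,
    )
    return model.fit(_as_x(data))


def random_model(
    k: int,
    tail: bool = True,
    seed: int | None = None,
    min_separation: float = 0.08,
) -> BetaParetoMixture:
    """Draw a random generative mixture (for synthetic benchmarking).

    Beta means are drawn uniformly in [0.15, 0.85] with pairwise separation
    at least ``min_separation``; variances uniform in [0.001, 0.005]; the
    tail shape uniform in [1, 3] with scale in [0.03, 0.08]; mixing
    proportions Dirichlet with every component at least 5%.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    rng = np.random.default_rng(norm_seed(seed))
    for _ in range(1000):
        means = np.sort(rng.uniform(0.15, 0.85, size=k))[::-1]
        if k == 1 or np.min(np.abs(np.diff(means))) >= min_separation:
            break
    betas = []
    for m in means:
        v = rng.uniform(0.001, 0.005)
        c = m * (1 - m) / v - 1.0
        betas.append(BetaComponent(a=m * c, b=(1 - m) * c))
    n_comp = k + (1 if tail else 0)
    for _ in range(1000):
        weights = rng.dirichlet(np.full(n_comp, 2.0))
        if weights.min() >= 0.05:
            break
    model = BetaParetoMixture(n_beta=k, tail=tail, random_state=seed)
    model.betas_ = betas
    model.tail_ = (
        ParetoComponent(
            scale=float(rng.uniform(0.03, 0.08)), shape=float(rng.uniform(1.0, 3.0))
        )
        if tail
        else None
    )
    model.weights_ = weights
    model.nll_ = np.nan
    model.lambda_ = model._lambda()
    model.n_ = 0
    model.converged_ = True
    model.n_iter_ = 0
    model.fit_trace_ = np.asarray([])
    model.responsibilities_ = None
    model.scores_ = None
    return model


def sample_from(model: BetaParetoMixture, n: int, seed: int | None = None):
    """Sample a dataset of n frequencies from a model.

    Returns ``(dataset, labels)`` where labels are the true component
    indices (tail = 0 when present).
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    x, labels = model.sample(n, random_state=seed)
    ds = FrequencyDataset.from_frequencies(x, frequency_kind=VAF)
    return ds, labels
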