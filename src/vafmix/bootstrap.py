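"""Parametric and non-parametric bootstrap for fit confidence.

The non-parametric bootstrap resamples the n input mutations with
replacement; the parametric bootstrap samples n fresh datasets from the
fitted mixture. Each resample is refit with full model selection, which
yields (i) the model frequency — how often each (k, tail) signature wins,
(ii) bootstrap distributions and percentile confidence intervals for the
parameters of resamples matching the input model's signature (components
matched across resamples by their mean-sorted canonical order), and, for
the non-parametric flavour only, (iii) the pairwise co-clustering
probability. Under the default normalisation the co-clustering entry for
a pair is the fraction of *all* resamples in which the two mutations both
appear and share a hard cluster, so it is bounded above by the pair's
empirical co-sampling frequency.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from joblib import Parallel, delayed

from ._utils import derive_seed, logger, norm_seed
from .errors import ConfigurationError, FitError, ValidationError
from .mixture import BetaParetoMixture, _as_x
from .selection import FitConfig, model_signature, select_model


@dataclass
class BootstrapResult:
    kind: str  # "parametric" | "nonparametric"
    n_boot: int
    alpha_level: float
    target_signature: str
    signatures: list[str | None]  # per-resample best signature (None = failed)
    model_frequency: dict[str, float]
    parameter_draws: dict[str, np.ndarray]
    ci: dict[str, tuple[float, float]]
    cocluster: np.ndarray | None = None
    co_sampling: np.ndarray | None = None
    n_failures: int = 0
    seed: int | None = None

    @property
    def target_frequency(self) -> float:
        return self.model_frequency.get(self.target_signature, 0.0)

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "n_boot": self.n_boot,
            "alpha_level": self.alpha_level,
            "target_signature": self.target_signature,
            "target_frequency": self.target_frequency,
            "model_frequency": self.model_frequency,
            "n_failures": self.n_failures,
            "ci": {k: [float(a), float(b)] for k, (a, b) in self.ci.items()},
            "parameter_draws": {k: list(map(float, v))
                                for k, v in self.parameter_draws.items()},
            "seed": self.seed,
        }


def _param_record(model: BetaParetoMixture) -> dict[str, float]:
    rec: dict[str, float] = {}
    if model.tail_ is not None:
        rec["tail_shape"] = model.tail_.shape
        rec["pi_tail"] = float(model.weights_[0])
    off = 1 if model.tail_ is not None else 0
    for j, b in enumerate(model.betas_, start=1):
        rec[f"beta{j}_mean"] = b.mean
        rec[f"beta{j}_var"] = b.variance
        rec[f"pi_beta{j}"] = float(model.weights_[off + j - 1])
    return rec


def _one_resample(x, model, kind, cfg, seed, b):
    """Fit one bootstrap resample; returns (signature, params, idx, labels)."""
    rng = np.random.default_rng(derive_seed(seed, b, 0))
    if kind == "nonparametric":
        idx = rng.integers(0, x.size, size=x.size)
        xb = x[idx]
    else:
        xb, _ = model.sample(x.size, random_state=derive_seed(seed, b, 1))
        idx = None
    cfg_b = replace(cfg, seed=derive_seed(seed, b, 2), parallel=1)
    try:
        rep = select_model(xb, cfg_b)
    except FitError as e:
        logger.warning("bootstrap resample %d failed: %s", b, e)
        return None, None, idx, None
    best = rep.best
    labels = best.model.predict(xb) if idx is not None else None
    return best.signature, _param_record(best.model), idx, labels


def bootstrap_fit(
    data,
    model: BetaParetoMixture,
    kind: str = "nonparametric",
    n_boot: int = 100,
    alpha_level: float = 0.05,
    config: FitConfig | None = None,
    seed: int | None = None,
) -> BootstrapResult:
    """Bootstrap a fitted model; see the module docstring.

    Resample seeds are derived from ``seed`` and the resample index, so
    the result is reproducible and independent of execution order.
    """
    if kind not in ("parametric", "nonparametric"):
        raise ConfigurationError("kind must be 'parametric' or 'nonparametric'")
    if n_boot < 1:
        raise ConfigurationError("n_boot must be >= 1")
    if not (0.0 < alpha_level < 1.0):
        raise ConfigurationError("alpha_level must be in (0, 1)")
    cfg = config if config is not None else FitConfig()
    x = _as_x(data)
    n = x.size
    base = norm_seed(seed if seed is not None else cfg.seed)
    target = model_signature(len(model.betas_), model.tail_ is not None)

    if cfg.parallel > 1:
        results = Parallel(n_jobs=cfg.parallel)(
            delayed(_one_resample)(x, model, kind, cfg, base, b)
            for b in range(n_boot)
        )
    else:
        results = [_one_resample(x, model, kind, cfg, base, b) for b in range(n_boot)]

    signatures = [r[0] for r in results]
    n_fail = sum(s is None for s in signatures)
    if n_fail > 0.2 * n_boot:
        raise FitError(
            f"{n_fail}/{n_boot} bootstrap resamples failed to fit"
        )
    ok = [s for s in signatures if s is not None]
    freq = {s: ok.count(s) / len(ok) for s in sorted(set(ok))}

    draws: dict[str, list[float]] = {}
    for sig, rec, _, _ in results:
        if sig == target and rec is not None:
            for k, v in rec.items():
                draws.setdefault(k, []).append(v)
    draws_arr = {k: np.asarray(v) for k, v in draws.items()}
    lo, hi = 100 * alpha_level / 2.0, 100 * (1.0 - alpha_level / 2.0)
    ci = {
        k: (float(np.percentile(v, lo)), float(np.percentile(v, hi)))
        for k, v in draws_arr.items()
        if v.size
    }

    cocluster = co_sampling = None
    if kind == "nonparametric":
        idx_lists = [r[2] for r in results if r[0] is not None]
        lab_lists = [r[3] for r in results if r[0] is not None]
        cocluster, co_sampling = cocluster_matrix(
            idx_lists, lab_lists, n, n_boot=len(idx_lists), return_co_sampling=True
        )

    return BootstrapResult(
        kind=kind,
        n_boot=n_boot,
        alpha_level=alpha_level,
        target_signature=target,
        signatures=signatures,
        model_frequency=freq,
        parameter_draws=draws_arr,
        ci=ci,
        cocluster=cocluster,
        co_sampling=co_sampling,
        n_failures=n_fail,
        seed=seed,
    )


def cocluster_matrix(
    index_lists: Sequence[np.ndarray],
    label_lists: Sequence[np.ndarray],
    n: int,
    n_boot: int | None = None,
    normalisation: str = "total",
    return_co_sampling: bool = False,
):
    """Pairwise co-clustering probability from non-parametric resamples.

    entry (i, j) = #resamples where i and j both appear and share a hard
    cluster, divided by the total number of resamples (``"total"``,
    default — this is the normalisation under which the co-clustering
    probability is bounded by the co-sampling frequency) or by the number
    of resamples where both appear (``"conditional"``).
    """
    if normalisation not in ("total", "conditional"):
        raise ConfigurationError("normalisation must be 'total' or 'conditional'")
    if any(i is None for i in index_lists):
        raise ValidationError(
            "co-clustering requires non-parametric resamples "
            "(parametric resamples do not resample the input mutations)"
        )
    if n_boot is None:
        n_boot = len(index_lists)
    same = np.zeros((n, n))
    cooc = np.zeros((n, n))
    for idx, labs in zip(index_lists, label_lists):
        idx = np.asarray(idx)
        labs = np.asarray(labs)
        u, first = np.unique(idx, return_index=True)
        lab_u = labs[first]
        cooc[np.ix_(u, u)] += 1.0
        for c in np.unique(lab_u):
            uc = u[lab_u == c]
            same[np.ix_(uc, uc)] += 1.0
    co_sampling = cooc / n_boot
    if normalisation == "total":
        mat = same / n_boot
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            mat = np.where(cooc > 0, same / np.maximum(cooc, 1), 0.0)
    if return_co_sampling:
        return mat, co_sampling
    return mat
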