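"""Model selection over (k, tail) candidates and post-hoc heuristics.

Every candidate model is scored by

    NLL   = -log f(D | theta, pi)
    BIC   = 2 * NLL + lambda * log(n)
    ICL   = BIC + H(z)
    reICL = BIC + H(z_hat)

where H(z) is the (natural-log) entropy of the latent responsibility
matrix and z_hat is z after removal of the mutations hard-assigned to the
tail and of the tail column itself, with the remaining rows renormalised
over the Beta columns. H(z_hat) <= H(z), so BIC <= reICL <= ICL. The
reduced entropy penalises overlap between Beta components only, promoting
models with well-separated subclonal peaks; reICL is the default
selection criterion. A model with k = 1 Beta describes a monoclonal
tumour (no evidence of ongoing subclonal selection); k > 1 is polyclonal.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from joblib import Parallel, delayed

from ._utils import derive_seed, logger, norm_seed
from .errors import ConfigurationError, FitError, ValidationError
from .io import FrequencyDataset
from .mixture import BetaParetoMixture, _as_x

_SCORES = ("nll", "bic", "icl", "reicl")


# ----------------------------------------------------------------------------
# configuration
# ----------------------------------------------------------------------------
@dataclass
class FitConfig:
    """All fitting / model-selection knobs.

    k_range : candidate numbers of Beta components (all >= 1).
    tail_mode : "auto" (try with and without), "on", or "off".
    score : selection criterion, one of NLL/BIC/ICL/reICL (case-insensitive);
        reICL is the default. NLL is allowed for debugging only — it always
        prefers the largest model.
    restarts : random restarts per candidate.
    epsilon : relative-NLL convergence tolerance of the inner fit.
    beta_estimator : "moment_match" (default) or "mle".
    parallel : joblib worker count for the candidate grid (1 = serial);
        results are independent of the worker count.
    """

    k_range: Sequence[int] = (1, 2, 3)
    tail_mode: str = "auto"
    score: str = "reicl"
    restarts: int = 10
    max_iter: int = 500
    epsilon: float = 1e-6
    beta_estimator: str = "moment_match"
    seed: int | None = None
    parallel: int = 1

    def __post_init__(self) -> None:
        if not self.k_range or any(k < 1 for k in self.k_range):
            raise ConfigurationError("k_range must be non-empty with all k >= 1")
        if self.tail_mode not in ("auto", "on", "off"):
            raise ConfigurationError("tail_mode must be auto/on/off")
        self.score = self.score.lower()
        if self.score not in _SCORES:
            raise ConfigurationError(f"score must be one of {_SCORES}")
        if self.epsilon <= 0:
            raise ConfigurationError("epsilon must be > 0")
        if self.restarts < 1:
            raise ConfigurationError("restarts must be >= 1")


# ----------------------------------------------------------------------------
# entropies and scores
# ----------------------------------------------------------------------------
def entropy(z) -> float:
    """H(z) = -sum z log z (natural log, 0 log 0 = 0), summed over the
    whole responsibility matrix."""
    z = np.asarray(z, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(z > 0.0, z * np.log(z), 0.0)
    return float(-t.sum())


def reduced_entropy(z, has_tail: bool = True, tail_index: int = 0) -> float:
    """Entropy of z after stripping tail-assigned rows and the tail column.

    Rows whose hard assignment (argmax) is the tail are dropped; the tail
    column is removed and surviving rows are renormalised over the Beta
    columns. Without a tail this is just H(z).
    """
    z = np.asarray(z, dtype=float)
    if not has_tail:
        return entropy(z)
    hard = np.argmax(z, axis=1)
    keep = hard != tail_index
    if not keep.any():
        logger.warning("reduced_entropy: every point hard-assigned to the tail")
        return 0.0
    zb = np.delete(z[keep], tail_index, axis=1)
    zb = zb / zb.sum(axis=1, keepdims=True)
    return entropy(zb)


@dataclass
class ScoreSet:
    """The four model-selection scores plus the two entropies."""

    nll: float
    bic: float
    icl: float
    reicl: float
    entropy_full: float
    entropy_reduced: float

    def to_dict(self) -> dict:
        return {
            "nll": self.nll,
            "bic": self.bic,
            "icl": self.icl,
            "reicl": self.reicl,
            "entropy_full": self.entropy_full,
            "entropy_reduced": self.entropy_reduced,
        }


def score_model(data, model: BetaParetoMixture) -> ScoreSet:
    """Compute NLL/BIC/ICL/reICL for a fitted model on a dataset."""
    x = _as_x(data)
    n = x.size
    z = model.predict_proba(x)
    nll = model.nll(x)
    bic = 2.0 * nll + model.lambda_ * np.log(n)
    h = entropy(z)
    hr = reduced_entropy(z, has_tail=model.tail_ is not None, tail_index=0)
    return ScoreSet(
        nll=nll,
        bic=float(bic),
        icl=float(bic + h),
        reicl=float(bic + hr),
        entropy_full=h,
        entropy_reduced=hr,
    )


# ----------------------------------------------------------------------------
# selection
# ----------------------------------------------------------------------------
@dataclass
class CandidateFit:
    k: int
    tail: bool
    model: BetaParetoMixture | None
    scores: ScoreSet | None
    error: str | None = None

    @property
    def signature(self) -> str:
        return model_signature(self.k, self.tail)

    @property
    def architecture(self) -> str:
        """"monoclonal" for k = 1, else "polyclonal"."""
        return "monoclonal" if self.k == 1 else "polyclonal"


def model_signature(k: int, tail: bool) -> str:
    return f"K{k}+tail" if tail else f"K{k}"


@dataclass
class ModelSelectionReport:
    candidates: list[CandidateFit]
    best: CandidateFit
    score_used: str

    @property
    def best_model(self) -> BetaParetoMixture:
        return self.best.model

    def ranked(self) -> list[CandidateFit]:
        ok = [c for c in self.candidates if c.model is not None]
        return sorted(ok, key=lambda c: _rank_key(c, self.score_used))

    def to_dict(self) -> dict:
        return {
            "score_used": self.score_used,
            "best": {
                "signature": self.best.signature,
                "architecture": self.best.architecture,
            },
            "candidates": [
                {
                    "signature": c.signature,
                    "architecture": c.architecture,
                    "error": c.error,
                    "scores": None if c.scores is None else c.scores.to_dict(),
                }
                for c in self.candidates
            ],
        }

    def summary(self) -> str:
        lines = [f"{'model':<10}{'NLL':>12}{'BIC':>12}{'ICL':>12}{'reICL':>12}"]
        for c in self.ranked():
            s = c.scores
            mark = " *" if c is self.best else ""
            lines.append(
                f"{c.signature:<10}{s.nll:>12.3f}{s.bic:>12.3f}"
                f"{s.icl:>12.3f}{s.reicl:>12.3f}{mark}"
            )
        return "\n".join(lines)


def _rank_key(c: CandidateFit, score: str):
    val = getattr(c.scores, score)
    # deterministic tie-break: smaller model first, tail-free first
    return (val, c.model.lambda_, c.k, int(c.tail))


def _fit_candidate(x, k, tail, cfg: FitConfig, seed: int) -> CandidateFit:
    model = BetaParetoMixture(
        n_beta=k,
        tail=tail,
        beta_estimator=cfg.beta_estimator,
        n_init=cfg.restarts,
        max_iter=cfg.max_iter,
        tol=cfg.epsilon,
        random_state=seed,
    )
    try:
        model.fit(x)
    except FitError as e:
        return CandidateFit(k=k, tail=tail, model=None, scores=None, error=str(e))
    scores = score_model(x, model)
    model.scores_ = scores
    return CandidateFit(k=k, tail=tail, model=model, scores=scores)


def select_model(data, config: FitConfig | None = None, **kwargs) -> ModelSelectionReport:
    """Fit every (k, tail) candidate and rank by the configured score.

    Each candidate is fit with ``config.restarts`` restarts (the best-NLL
    restart is kept by the inner estimator); candidates are then ranked by
    the selection criterion (default reICL, minimised). Candidate seeds
    are derived from the master seed, so the report does not depend on the
    execution order or on ``config.parallel``.
    """
    cfg = config if config is not None else FitConfig(**kwargs)
    x = _as_x(data)
    tails = {"auto": (True, False), "on": (True,), "off": (False,)}[cfg.tail_mode]
    base = norm_seed(cfg.seed)
    grid = [
        (k, tail, derive_seed(base, k, int(tail)))
        for k in sorted(set(cfg.k_range))
        for tail in tails
    ]
    if cfg.parallel > 1:
        candidates = Parallel(n_jobs=cfg.parallel)(
            delayed(_fit_candidate)(x, k, tail, cfg, seed) for k, tail, seed in grid
        )
    else:
        candidates = [_fit_candidate(x, k, tail, cfg, seed) for k, tail, seed in grid]
    ok = [c for c in candidates if c.model is not None]
    if not ok:
        msgs = "; ".join(f"{c.signature}: {c.error}" for c in candidates)
        raise FitError(f"every candidate fit failed — {msgs}")
    best = min(ok, key=lambda c: _rank_key(c, cfg.score))
    return ModelSelectionReport(candidates=list(candidates), best=best,
                                score_used=cfg.score)


# ----------------------------------------------------------------------------
# post-hoc heuristics
# ----------------------------------------------------------------------------
def filter_clusters(
    model: BetaParetoMixture,
    data,
    min_pi: float = 0.02,
    min_count: int = 10,
    refit: bool = False,
    config: FitConfig | None = None,
) -> BetaParetoMixture:
    """Remove Beta clusters that are too small (pi < min_pi) or hold too
    few hard-assigned mutations (< min_count); the tail is never removed.

    By default the surviving mixture is renormalised and responsibilities
    are recomputed under the retained parameters; ``refit=True`` refits the
    surviving architecture from scratch instead.
    """
    if min_pi < 0 or min_count < 0:
        raise ConfigurationError("thresholds must be >= 0")
    x = _as_x(data)
    z = model.predict_proba(x)
    hard = np.argmax(z, axis=1)
    off = 1 if model.tail_ is not None else 0
    counts = np.array([(hard == off + j).sum() for j in range(len(model.betas_))])
    pis = model.weights_[off:]
    keep = (pis >= min_pi) & (counts >= min_count)
    if not keep.any():
        raise FitError(
            "cluster filtering would remove every Beta component; "
            "relax min_pi/min_count"
        )
    if keep.all():
        return model
    if refit:
        cfg = config if config is not None else FitConfig()
        from .mixture import fit_mixture

        return fit_mixture(x, k=int(keep.sum()), tail=model.tail_ is not None,
                           config=cfg)
    new = BetaParetoMixture(
        n_beta=int(keep.sum()),
        tail=model.tail_ is not None,
        beta_estimator=model.beta_estimator,
        random_state=model.random_state,
    )
    new.betas_ = [b for b, k_ in zip(model.betas_, keep) if k_]
    new.tail_ = model.tail_
    w = np.concatenate([model.weights_[:off], pis[keep]])
    new.weights_ = w / w.sum()
    new.nll_ = new.nll(x)
    new.lambda_ = new._lambda()
    new.n_ = x.size
    new.converged_ = model.converged_
    new.n_iter_ = model.n_iter_
    new.fit_trace_ = np.asarray([new.nll_])
    new.responsibilities_ = new.predict_proba(x)
    new.scores_ = score_model(x, new)
    return new


def assign_new(model: BetaParetoMixture, x):
    """Assign previously unseen mutations to the fitted clusters.

    Returns (responsibilities, hard_labels) under the fixed fitted
    parameters; the model itself is unchanged.
    """
    x = _as_x(x)
    if np.any((x <= 0.0) | (x >= 1.0)):
        raise ValidationError("new frequencies must lie strictly inside (0, 1)")
    z = model.predict_proba(x)
    return z, np.argmax(z, axis=1)
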