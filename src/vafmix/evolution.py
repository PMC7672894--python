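"""Post-clustering evolutionary parameters: mutation rate, subclone age
and selection coefficient.

Under neutral growth, population genetics predicts that the number of
subclonal mutations with frequency above f grows like
M(f) = mu * (1/f - 1/f_max): the within-clone site frequency spectrum is
a power law, which is exactly what the mixture's Pareto tail captures.
Counting the tail-assigned mutations inside a frequency window
[f_min, f_max] therefore estimates the effective mutation rate

    mu_hat = N_tail(f_min, f_max) / (1/f_min - 1/f_max)

in mutations per effective tumour doubling (frequency here is whatever the
dataset carries, VAF for diploid-heterozygous input).

A subclone that was founded t doublings into the growth carries the
mutations its founder lineage accumulated up to that time, so its hard-
assigned mutation count dates it: t_hat = N_sub / mu_hat. Its selection
coefficient (relative growth-rate, ancestor = 1) follows from how far the
subclone swept by sampling time T (in doublings): with subclone cell
fraction x, x/(1-x) = 2^((s-1)(T-t)) under exponential outgrowth, giving

    s_hat = 1 + log2(x / (1 - x)) / (T - t_hat).

For diploid-heterozygous VAF input x = 2 * (subclonal Beta mean); for
halved-CCF input the same doubling restores the original CCF. When T is
not supplied it is estimated as N_clonal / mu_hat from the clonal
(highest-mean) Beta cluster. These conventions are shared with the
branching-process simulator in :mod:`vafmix.simulate`, and recovery is
verified by self-consistency against it; they can differ from other
tools' conventions by constant factors.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._utils import logger
from .errors import ConfigurationError, FitError, ValidationError
from .io import FrequencyDataset
from .mixture import BetaParetoMixture, _as_x

_X_TOL = 1e-6  # cell fractions within this of 1 are undefined for s


@dataclass
class SubcloneEstimate:
    """Evolutionary parameters of one subclonal Beta cluster."""

    t_origin: float  # tumour doublings since growth start
    s: float | None  # selection coefficient (ancestor = 1); None if undefined
    cell_fraction: float
    n_mutations: int
    beta_mean: float


@dataclass
class EvolutionaryEstimates:
    mu: float
    f_window: tuple[float, float]
    n_tail_window: int
    sampling_time: float
    subclones: list[SubcloneEstimate] = field(default_factory=list)

    @property
    def t_subclone(self) -> float | None:
        return self.subclones[0].t_origin if self.subclones else None

    @property
    def s_subclone(self) -> float | None:
        return self.subclones[0].s if self.subclones else None

    def to_dict(self) -> dict:
        return {
            "mu": self.mu,
            "f_window": list(self.f_window),
            "n_tail_window": self.n_tail_window,
            "sampling_time": self.sampling_time,
            "subclones": [
                {
                    "t_origin": s.t_origin,
                    "s": s.s,
                    "cell_fraction": s.cell_fraction,
                    "n_mutations": s.n_mutations,
                    "beta_mean": s.beta_mean,
                }
                for s in self.subclones
            ],
        }


def _tail_points(model: BetaParetoMixture, x: np.ndarray) -> np.ndarray:
    if model.tail_ is None:
        raise FitError(
            "mutation rate is undefined without a neutral tail in the model"
        )
    labels = model.predict(x)
    return x[labels == 0]


def estimate_mutation_rate(
    model: BetaParetoMixture,
    data,
    f_min: float | None = None,
    f_max: float | None = None,
) -> tuple[float, tuple[float, float], int]:
    """Estimate mu from tail-assigned mutations in [f_min, f_max].

    Defaults: f_min = max(dataset cutoff, 5th percentile of tail points),
    f_max = 95th percentile of tail points (the extremes of the tail are
    dominated by detection noise and by the Beta peaks' shoulders).
    Returns (mu, (f_min, f_max), window count).
    """
    x = _as_x(data)
    tail = _tail_points(model, x)
    if tail.size == 0:
        raise ValidationError("no mutations are hard-assigned to the tail")
    ds_min = data.min_frequency if isinstance(data, FrequencyDataset) else float(np.min(x))
    if f_min is None:
        f_min = max(ds_min, float(np.percentile(tail, 5.0)))
    if f_max is None:
        f_max = float(np.percentile(tail, 95.0))
    if not (0.0 < f_min < f_max):
        raise ConfigurationError(f"need 0 < f_min < f_max, got [{f_min}, {f_max}]")
    n_window = int(((tail >= f_min) & (tail <= f_max)).sum())
    if n_window == 0:
        raise ValidationError(
            f"no tail mutations inside the window [{f_min:.4g}, {f_max:.4g}]"
        )
    mu = n_window / (1.0 / f_min - 1.0 / f_max)
    return float(mu), (float(f_min), float(f_max)), n_window


def estimate_subclone_parameters(
    model: BetaParetoMixture,
    data,
    mu: float,
    sampling_time_doublings: float | None = None,
    strict: bool = True,
) -> tuple[float, list[SubcloneEstimate]]:
    """Date each subclonal Beta and estimate its selection coefficient.

    The clonal cluster is the highest-mean Beta; every other Beta is a
    subclone. Returns (T, subclone estimates) with T the sampling time in
    doublings (supplied, or N_clonal / mu when not). With ``strict=True``
    an undefined selection coefficient (subclone fraction >= 1, or
    T <= t_hat) raises; with ``strict=False`` the subclone age is still
    reported and ``s`` is None.
    """
    if mu <= 0:
        raise ConfigurationError("mu must be > 0")
    if len(model.betas_) < 2:
        raise FitError("no subclonal Beta component in the model (k < 2)")
    x = _as_x(data)
    labels = model.predict(x)
    off = 1 if model.tail_ is not None else 0
    # canonical order: betas_[0] has the highest mean = clonal cluster
    n_clonal = int((labels == off).sum())
    T = (
        float(sampling_time_doublings)
        if sampling_time_doublings is not None
        else n_clonal / mu
    )
    out: list[SubcloneEstimate] = []
    for j in range(1, len(model.betas_)):
        beta = model.betas_[j]
        n_sub = int((labels == off + j).sum())
        t_hat = n_sub / mu
        xf = 2.0 * beta.mean
        s: float | None
        if xf >= 1.0 - _X_TOL:
            msg = (
                f"subclone cell fraction {xf:.4f} >= 1: selection coefficient "
                "undefined (check ploidy/purity conventions)"
            )
            if strict:
                raise FitError(msg)
            logger.warning(msg)
            s = None
        elif T <= t_hat:
            msg = (
                f"sampling time T={T:.3g} <= subclone age t={t_hat:.3g} "
                "doublings: selection coefficient undefined"
            )
            if strict:
                raise FitError(msg)
            logger.warning(msg)
            s = None
        else:
            xf = float(np.clip(xf, _X_TOL, 1.0 - _X_TOL))
            s = float(1.0 + np.log2(xf / (1.0 - xf)) / (T - t_hat))
        out.append(
            SubcloneEstimate(
                t_origin=float(t_hat),
                s=s,
                cell_fraction=min(xf, 1.0),
                n_mutations=n_sub,
                beta_mean=beta.mean,
            )
        )
    return T, out


def evolutionary_analysis(
    model: BetaParetoMixture,
    data,
    f_min: float | None = None,
    f_max: float | None = None,
    sampling_time_doublings: float | None = None,
) -> EvolutionaryEstimates:
    """Full post-clustering analysis: mu, then per-subclone (t, s).

    Subclone parameters are reported only when the model has at least two
    Beta components (a monoclonal fit has no subclone to date).
    """
    mu, window, n_window = estimate_mutation_rate(model, data, f_min, f_max)
    subclones: list[SubcloneEstimate] = []
    T = sampling_time_doublings
    if len(model.betas_) >= 2:
        T, subclones = estimate_subclone_parameters(
            model, data, mu, sampling_time_doublings, strict=False
        )
    elif T is None:
        x = _as_x(data)
        labels = model.predict(x)
        off = 1 if model.tail_ is not None else 0
        T = int((labels == off).sum()) / mu
    return EvolutionaryEstimates(
        mu=mu,
        f_window=window,
        n_tail_window=n_window,
        sampling_time=float(T),
        subclones=subclones,
    )
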