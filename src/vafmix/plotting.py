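"""Visualisation of data, fits, scores, latent variables and bootstrap
output.

Every plot function returns the exact numeric series it draws (and the
figure), so tests can assert the data rather than pixels; rendering goes
through matplotlib. :class:`PlotSpec` + :func:`render` provide a uniform
file-producing entry point for the CLI.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigurationError, ValidationError
from .mixture import (
    BetaParetoMixture,
    _as_x,
    beta_density,
    pareto_density,
)
from .selection import ModelSelectionReport

_KINDS = (
    "fit_histogram",
    "score_panel",
    "entropy_profile",
    "latent_heatmap",
    "bootstrap_distributions",
    "cocluster_heatmap",
    "coverage_histogram",
    "mixing_barplot",
)


def _grid(model: BetaParetoMixture, num: int = 512) -> np.ndarray:
    lo = model.tail_.scale if model.tail_ is not None else 1e-3
    return np.linspace(max(lo, 1e-3), 1.0 - 1e-3, num)


def component_density_series(model: BetaParetoMixture, grid=None) -> dict:
    """Per-component and total mixture density on a grid.

    total[g] = sum_c pi_c * f_c(grid[g]) pointwise.
    """
    grid = _grid(model) if grid is None else np.asarray(grid, dtype=float)
    comps = []
    if model.tail_ is not None:
        comps.append(pareto_density(grid, model.tail_))
    for b in model.betas_:
        comps.append(beta_density(grid, b))
    comps = np.asarray(comps)
    total = (model.weights_[:, None] * comps).sum(axis=0)
    return {
        "grid": grid,
        "components": comps,
        "weights": model.weights_.copy(),
        "names": model.cluster_names(),
        "total": total,
    }


def fit_histogram_series(model: BetaParetoMixture, data, bins: int = 100) -> dict:
    """Histogram of the data coloured by hard assignment, with the fitted
    density overlay. Returns bin edges, per-cluster bin counts and the
    density series."""
    x = _as_x(data)
    labels = model.predict(x)
    edges = np.linspace(0.0, 1.0, bins + 1)
    counts = np.stack(
        [np.histogram(x[labels == c], bins=edges)[0]
         for c in range(model.n_components_)]
    )
    out = component_density_series(model)
    out.update({"edges": edges, "counts": counts, "labels": labels})
    return out


def entropy_profile_series(model: BetaParetoMixture, grid=None) -> dict:
    """Pointwise assignment entropy over the frequency domain.

    At each grid point the responsibilities z(x) follow from the relative
    weighted component densities; the standard profile is their entropy,
    the reduced profile renormalises over the Beta columns and is zero
    where the hard assignment is the tail. The reduced profile is bounded
    above by the standard one.
    """
    grid = _grid(model) if grid is None else np.asarray(grid, dtype=float)
    z = model.predict_proba(grid)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(z > 0, z * np.log(z), 0.0)
    standard = -t.sum(axis=1)
    if model.tail_ is None:
        reduced = standard.copy()
    else:
        zb = z[:, 1:]
        s = zb.sum(axis=1, keepdims=True)
        zb = np.divide(zb, s, out=np.zeros_like(zb), where=s > 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            tb = np.where(zb > 0, zb * np.log(zb), 0.0)
        reduced = -tb.sum(axis=1)
        reduced[np.argmax(z, axis=1) == 0] = 0.0
    return {"grid": grid, "standard": standard, "reduced": reduced}


def score_panel_series(report: ModelSelectionReport) -> dict:
    """Score table across candidates (the ranked panel of a fit report)."""
    rows = [c for c in report.candidates if c.scores is not None]
    return {
        "signature": [c.signature for c in rows],
        "nll": [c.scores.nll for c in rows],
        "bic": [c.scores.bic for c in rows],
        "icl": [c.scores.icl for c in rows],
        "reicl": [c.scores.reicl for c in rows],
        "best": report.best.signature,
        "score_used": report.score_used,
    }


def latent_heatmap_series(model: BetaParetoMixture, data) -> dict:
    """Responsibility matrix ordered by hard assignment (then frequency)."""
    x = _as_x(data)
    z = model.predict_proba(x)
    labels = np.argmax(z, axis=1)
    order = np.lexsort((x, labels))
    return {"z": z[order], "order": order, "labels": labels[order]}


def cocluster_heatmap_series(bootstrap_result, model=None, data=None) -> dict:
    """Co-clustering matrix, optionally reordered by cluster assignment."""
    if bootstrap_result.cocluster is None:
        raise ValidationError(
            "co-clustering requires a non-parametric bootstrap result"
        )
    mat = bootstrap_result.cocluster
    order = np.arange(mat.shape[0])
    if model is not None and data is not None:
        x = _as_x(data)
        order = np.lexsort((x, model.predict(x)))
    return {"matrix": mat[np.ix_(order, order)], "order": order}


def mixing_barplot_series(model: BetaParetoMixture) -> dict:
    return {"names": model.cluster_names(), "weights": model.weights_.copy()}


def coverage_histogram_series(data, bins: int = 50) -> dict:
    df = data.df
    if "depth" not in df.columns or df["depth"].isna().all():
        raise ValidationError("dataset carries no depth information")
    depth = df["depth"].to_numpy(dtype=float)
    counts, edges = np.histogram(depth, bins=bins)
    return {"edges": edges, "counts": counts, "median": float(np.median(depth))}


def bootstrap_distribution_series(bootstrap_result) -> dict:
    return {
        "model_frequency": dict(bootstrap_result.model_frequency),
        "parameter_draws": {k: np.asarray(v)
                            for k, v in bootstrap_result.parameter_draws.items()},
        "ci": dict(bootstrap_result.ci),
    }


@dataclass
class PlotSpec:
    """Declarative description of one figure (used by the CLI)."""

    kind: str
    inputs: dict = field(default_factory=dict)
    path: str | Path | None = None
    bins: int = 100
    dpi: int = 150

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ConfigurationError(f"unknown plot kind {self.kind!r}")


def render(spec: PlotSpec):
    """Compute the plot's numeric series, draw it, and (optionally) write
    the figure file. Returns (figure, series)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    model = spec.inputs.get("model")
    data = spec.inputs.get("data")
    report = spec.inputs.get("report")
    boot = spec.inputs.get("bootstrap")
    if model is not None and data is not None and hasattr(model, "n_"):
        n = len(_as_x(data))
        if model.n_ and model.responsibilities_ is not None and \
                model.responsibilities_.shape[0] != n and spec.kind == "latent_heatmap":
            raise ValidationError("model and dataset sizes disagree")

    fig, ax = plt.subplots(figsize=(5.5, 4))
    if spec.kind == "fit_histogram":
        series = fit_histogram_series(model, data, bins=spec.bins)
        centers = 0.5 * (series["edges"][:-1] + series["edges"][1:])
        bottom = np.zeros_like(centers, dtype=float)
        width = series["edges"][1] - series["edges"][0]
        scale = len(_as_x(data)) * width
        for name, row in zip(series["names"], series["counts"]):
            ax.bar(centers, row, width=width, bottom=bottom, label=name)
            bottom += row
        ax.plot(series["grid"], series["total"] * scale, "k-", lw=1.5)
        ax.set_xlabel("observed frequency")
        ax.set_ylabel("mutations")
        ax.legend(fontsize=7)
    elif spec.kind == "score_panel":
        series = score_panel_series(report)
        xs = np.arange(len(series["signature"]))
        for key in ("bic", "icl", "reicl"):
            ax.plot(xs, series[key], "o-", label=key.upper(), ms=4)
        ax.set_xticks(xs, series["signature"], rotation=45, fontsize=7)
        ax.legend(fontsize=7)
        ax.set_ylabel("score (lower is better)")
    elif spec.kind == "entropy_profile":
        series = entropy_profile_series(model)
        ax.plot(series["grid"], series["standard"], "-", label="entropy")
        ax.plot(series["grid"], series["reduced"], "--", label="reduced entropy")
        ax.set_xlabel("frequency")
        ax.set_ylabel("assignment entropy (nats)")
        ax.legend(fontsize=7)
    elif spec.kind == "latent_heatmap":
        series = latent_heatmap_series(model, data)
        im = ax.imshow(series["z"], aspect="auto", interpolation="nearest")
        fig.colorbar(im, ax=ax, label="z")
        ax.set_xlabel("component")
        ax.set_ylabel("mutation (ordered by cluster)")
    elif spec.kind == "bootstrap_distributions":
        series = bootstrap_distribution_series(boot)
        keys = list(series["parameter_draws"])[:6]
        for k in keys:
            ax.hist(series["parameter_draws"][k], bins=30, alpha=0.5, label=k)
        ax.legend(fontsize=6)
        ax.set_xlabel("bootstrap draw")
    elif spec.kind == "cocluster_heatmap":
        series = cocluster_heatmap_series(boot, model, data)
        im = ax.imshow(series["matrix"], vmin=0, vmax=1, interpolation="nearest")
        fig.colorbar(im, ax=ax, label="co-clustering probability")
    elif spec.kind == "coverage_histogram":
        series = coverage_histogram_series(data, bins=spec.bins)
        centers = 0.5 * (series["edges"][:-1] + series["edges"][1:])
        ax.bar(centers, series["counts"],
               width=series["edges"][1] - series["edges"][0])
        ax.set_xlabel("depth")
        ax.set_ylabel("mutations")
    elif spec.kind == "mixing_barplot":
        series = mixing_barplot_series(model)
        ax.bar(series["names"], series["weights"])
        ax.set_ylabel("mixing proportion")
    fig.tight_layout()
    if spec.path is not None:
        fig.savefig(spec.path, dpi=spec.dpi)
    return fig, series
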