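"""Stochastic branching-process tumour growth with sequencing noise.

The tumour grows in discrete, non-overlapping generations from a single
founder cell. Each generation every cell first survives with probability
1 - death_prob and each survivor then divides with probability
birth_prob; both daughters inherit the parent's mutations and each gains
a Poisson(mu_sim) load of new, unique mutations (infinite-sites). With
the default birth_prob = 1 the baseline clone roughly doubles every
generation, so one generation is one tumour doubling and the neutral
within-clone spectrum follows the population-genetics power law
M(f) ~ mu * (1/f): the shape the mixture's Pareto tail encodes. The
founder starts with ``n_clonal`` pre-existing mutations (the truncal
load accumulated before growth), which appear at cell fraction 1.

At ``driver_time`` one uniformly chosen live cell founds a driver
lineage. Its advantage is a multiplied per-generation division *rate*:
driver cells pass through ``fitness_multiplier`` division rounds per
generation (fractional parts are spread deterministically across
generations), the discrete analogue of a birth-rate ratio in a
continuous-time branching process. A probability multiplier capped at
one could never let a clone founded a few doublings before sampling
reach a detectable cell fraction, whereas a rate multiplier reproduces
the canonical picture of a late subclonal sweep.

A biopsy at ``sampling_time`` is sequenced in silico: each mutation's
true VAF is purity * carriers / (2 * N) (diploid heterozygous), depth is
Poisson(coverage_rate), variant reads Binomial(depth, true VAF), and
observed VAF = alt/depth, filtered at ``vaf_cutoff`` (strictly above).

Genealogy bookkeeping is block-based: every daughter cell creates one
"block" holding its newly acquired mutations, so all mutations in a
block are perfectly linked and share one carrier count (the number of
live sampled cells below that block). The per-mutation expansion happens
only at sequencing time and only for blocks whose true VAF could
plausibly pass the detection cutoff.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from ._utils import logger, norm_seed
from .errors import ConfigurationError, SimulationError, ValidationError
from .io import VAF, FrequencyDataset

CLONAL, SUBCLONE, TAIL_LABEL = "clonal", "subclone", "tail"


@dataclass
class SimulationConfig:
    """Growth, driver and sequencing parameters.

    birth_prob, death_prob : per-generation division / death probabilities
        of baseline cells (death is applied first); growth must be
        supercritical.
    mu_sim : mean new mutations per daughter per division (Poisson).
    n_clonal : truncal mutations carried by the founder cell.
    driver_time : generation at which the driver lineage is founded
        (None = no driver, a monoclonal tumour).
    fitness_multiplier : division rounds per generation of driver cells
        (> 1; baseline cells do one round).
    sampling_time : generation of the biopsy.
    coverage_rate : mean sequencing depth (Poisson rate).
    purity : tumour cell fraction of the sample.
    vaf_cutoff : detection threshold on observed VAF (strictly above).
    population_cap : growth stops early if the population exceeds this.
    establishment_size : cell death is disabled while a clone is smaller
        than this — the branching process is conditioned on clone
        establishment, which removes founder-effect variance in the final
        clone sizes without touching the per-lineage branching noise that
        shapes the neutral tail.
    expansion_floor : minimum true VAF at which mutations are expanded
        individually for sequencing (None = vaf_cutoff / 5; mutations far
        below the cutoff have negligible probability of being observed).
    """

    birth_prob: float = 0.5
    death_prob: float = 0.1
    mu_sim: float = 20.0
    n_clonal: int = 500
    driver_time: Optional[int] = 13
    fitness_multiplier: float = 3.8
    sampling_time: int = 17
    coverage_rate: float = 120.0
    purity: float = 1.0
    vaf_cutoff: float = 0.05
    population_cap: int = 1_000_000
    establishment_size: int = 32
    expansion_floor: Optional[float] = None
    seed: Optional[int] = None
    max_retries: int = 20

    def __post_init__(self) -> None:
        for name in ("birth_prob", "death_prob", "purity"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.mu_sim < 0:
            raise ConfigurationError("mu_sim must be >= 0")
        if self.sampling_time < 1:
            raise ConfigurationError("sampling_time must be >= 1")
        if self.driver_time is not None:
            if self.driver_time < 1 or self.driver_time > self.sampling_time:
                raise ConfigurationError(
                    "driver_time must lie in [1, sampling_time]"
                )
            if self.fitness_multiplier <= 1.0:
                raise ConfigurationError("fitness_multiplier must be > 1")
        if (1.0 - self.death_prob) * (1.0 + self.birth_prob) <= 1.0:
            raise ConfigurationError(
                "expected growth must be supercritical: "
                "(1 - death_prob) * (1 + birth_prob) > 1"
            )
        if not (0.0 <= self.vaf_cutoff < 1.0):
            raise ConfigurationError("vaf_cutoff must be in [0, 1)")

    @property
    def growth_factor(self) -> float:
        """Mean per-generation population growth (1 - d) * (1 + b)."""
        return (1.0 - self.death_prob) * (1.0 + self.birth_prob)

    @property
    def effective_mutation_rate(self) -> float:
        """Mutations per effective tumour doubling.

        ``mu_sim`` counts new mutations per daughter per division; a
        surviving lineage (size-biased over the population) passes through
        a division with probability 2 b (1-d) / m per generation, so it
        accumulates ``mu_sim * 2 b (1-d) / m`` mutations per generation —
        one generation being one effective population doubling. This is
        the rate in the units the tail-based estimator measures, and the
        quantity against which recovery is assessed.
        """
        m = self.growth_factor
        return (
            self.mu_sim
            * 2.0
            * self.birth_prob
            * (1.0 - self.death_prob)
            / m
        )

    def to_dict(self) -> dict:
        return {
            k: getattr(self, k)
            for k in (
                "birth_prob death_prob mu_sim n_clonal driver_time "
                "fitness_multiplier sampling_time coverage_rate purity "
                "vaf_cutoff population_cap establishment_size "
                "expansion_floor seed max_retries"
            ).split()
        }


@dataclass
class SimulatedTumour:
    """Grown (and optionally sequenced) tumour with full ground truth."""

    mutation_catalog: pd.DataFrame  # one row per linked block of mutations
    population: pd.DataFrame  # per-generation clone sizes and event counts
    truth: SimulationConfig
    n_cells: int
    subclone_size: int
    attempt: int  # which retry produced a surviving tumour
    stopped_early: bool
    observed: FrequencyDataset | None = None

    @property
    def n_mutations(self) -> int:
        return int(self.mutation_catalog["n_mutations"].sum())

    @property
    def subclone_fraction(self) -> float:
        return self.subclone_size / self.n_cells if self.n_cells else 0.0


class _Extinct(Exception):
    pass


def _grow_once(cfg: SimulationConfig, rng: np.random.Generator) -> SimulatedTumour:
    parents: list[np.ndarray] = [np.array([-1], dtype=np.int64)]
    mut_counts: list[np.ndarray] = [np.array([cfg.n_clonal], dtype=np.int64)]
    clone_of: list[np.ndarray] = [np.array([0], dtype=np.int8)]
    round_slices: list[tuple[int, int]] = [(0, 1)]
    n_nodes = 1

    live = {0: np.array([0], dtype=np.int64), 1: np.empty(0, dtype=np.int64)}
    founder_node = -1
    pop_rows = []
    stopped_early = False

    def step(ids: np.ndarray, clone: int, with_death: bool = True,
             div_prob: float | None = None):
        """One death/division round; returns (live_ids, deaths, divisions)."""
        nonlocal n_nodes
        if ids.size == 0:
            return ids, 0, 0
        established = ids.size >= cfg.establishment_size
        if with_death and established:
            survive = rng.random(ids.size) >= cfg.death_prob
            alive = ids[survive]
        else:
            alive = ids
        deaths = int(ids.size - alive.size)
        if div_prob is not None:
            p_div = div_prob
        else:
            # below the establishment size every cell divides: the clone is
            # conditioned on rapid establishment
            p_div = cfg.birth_prob if established else 1.0
        div = rng.random(alive.size) < p_div
        dividers = alive[div]
        persist = alive[~div]
        n_child = 2 * dividers.size
        if n_child:
            parents.append(np.repeat(dividers, 2))
            mut_counts.append(rng.poisson(cfg.mu_sim, n_child).astype(np.int64))
            clone_of.append(np.full(n_child, clone, dtype=np.int8))
            child_ids = np.arange(n_nodes, n_nodes + n_child, dtype=np.int64)
            round_slices.append((n_nodes, n_nodes + n_child))
            n_nodes += n_child
        else:
            child_ids = np.empty(0, dtype=np.int64)
        return np.concatenate([persist, child_ids]), deaths, int(dividers.size)

    for g in range(1, cfg.sampling_time + 1):
        deaths = {0: 0, 1: 0}
        divisions = {0: 0, 1: 0}
        live[0], d0, b0 = step(live[0], 0)
        deaths[0] += d0
        divisions[0] += b0
        if cfg.driver_time is not None and g > cfg.driver_time and live[1].size:
            # driver cells face the per-generation death once, then divide
            # through fitness_multiplier division rounds (a rate advantage);
            # the fractional part is one per-cell partial round
            k0 = int(np.floor(cfg.fitness_multiplier))
            frac = cfg.fitness_multiplier - k0
            for r in range(k0):
                live[1], d1, b1 = step(live[1], 1, with_death=(r == 0))
                deaths[1] += d1
                divisions[1] += b1
                if live[1].size == 0:
                    break
            if frac > 0 and live[1].size:
                live[1], d1, b1 = step(
                    live[1], 1, with_death=False,
                    div_prob=frac * cfg.birth_prob,
                )
                deaths[1] += d1
                divisions[1] += b1
        if live[0].size + live[1].size == 0:
            raise _Extinct("population extinct")
        if cfg.driver_time is not None and g == cfg.driver_time:
            if live[0].size == 0:
                raise _Extinct("baseline clone extinct at driver founding")
            pick = int(rng.integers(live[0].size))
            founder_node = int(live[0][pick])
            live[1] = live[0][pick : pick + 1].copy()
            live[0] = np.delete(live[0], pick)
        pop_rows.append(
            dict(
                generation=g,
                n_baseline=int(live[0].size),
                n_driver=int(live[1].size),
                deaths_baseline=deaths[0],
                deaths_driver=deaths[1],
                divisions_baseline=divisions[0],
                divisions_driver=divisions[1],
            )
        )
        if live[0].size + live[1].size > cfg.population_cap:
            stopped_early = True
            logger.warning(
                "population cap %d reached at generation %d; stopping early",
                cfg.population_cap,
                g,
            )
            break

    if cfg.driver_time is not None and live[1].size == 0:
        raise _Extinct("driver lineage extinct before sampling")

    parent = np.concatenate(parents)
    muts = np.concatenate(mut_counts)
    clone = np.concatenate(clone_of)

    # carrier counts: number of live sampled cells below each block
    leaf = np.zeros(n_nodes, dtype=np.int64)
    all_live = np.concatenate([live[0], live[1]])
    leaf[all_live] = 1
    for start, end in reversed(round_slices[1:]):
        np.add.at(leaf, parent[start:end], leaf[start:end])

    labels = np.full(n_nodes, TAIL_LABEL, dtype=object)
    labels[0] = CLONAL
    if founder_node >= 0:
        node = founder_node
        while node > 0:
            labels[node] = SUBCLONE
            node = int(parent[node])

    n_cells = int(all_live.size)
    keep = muts > 0
    catalog = pd.DataFrame(
        {
            "block": np.flatnonzero(keep),
            "n_mutations": muts[keep],
            "carriers": leaf[keep],
            "true_vaf": cfg.purity * leaf[keep] / (2.0 * n_cells),
            "clone_label": labels[keep],
            "origin_clone": np.where(clone[keep] == 1, "driver", "baseline"),
        }
    )
    catalog = catalog[catalog["carriers"] > 0].reset_index(drop=True)
    return SimulatedTumour(
        mutation_catalog=catalog,
        population=pd.DataFrame(pop_rows),
        truth=cfg,
        n_cells=n_cells,
        subclone_size=int(live[1].size),
        attempt=0,
        stopped_early=stopped_early,
    )


def simulate_growth(cfg: SimulationConfig) -> SimulatedTumour:
    """Grow a tumour; extinct runs (including driver-lineage extinction)
    are re-drawn from derived seeds up to ``cfg.max_retries`` times."""
    base = norm_seed(cfg.seed)
    last = "?"
    for attempt in range(cfg.max_retries):
        rng = np.random.default_rng([base, attempt])
        try:
            sim = _grow_once(cfg, rng)
            sim.attempt = attempt
            if attempt:
                logger.info("simulation survived on retry %d", attempt)
            return sim
        except _Extinct as e:
            last = str(e)
    raise SimulationError(
        f"simulation extinct in {cfg.max_retries} attempts ({last}); "
        "increase growth or lower death_prob"
    )


def sequence_tumour(
    sim: SimulatedTumour, cfg: SimulationConfig | None = None
) -> FrequencyDataset:
    """Simulate a WGS assay of the grown tumour; returns the observed
    dataset (with ground-truth columns) filtered at the VAF cutoff."""
    cfg = cfg if cfg is not None else sim.truth
    cat = sim.mutation_catalog
    empty_cols = [
        "id", "chrom", "pos", "ref", "alt", "depth", "alt_reads", "vaf",
        "freq", "true_vaf", "carriers", "clone_label", "block",
    ]
    if len(cat) == 0 or sim.n_cells == 0:
        logger.warning("sequence_tumour: no mutations to sequence")
        ds = FrequencyDataset(
            pd.DataFrame(columns=empty_cols), frequency_kind=VAF,
            min_frequency=cfg.vaf_cutoff,
        )
        sim.observed = ds
        return ds
    floor = (
        cfg.expansion_floor
        if cfg.expansion_floor is not None
        else cfg.vaf_cutoff / 5.0
    )
    sel = cat[cat["true_vaf"] >= floor]
    reps = sel["n_mutations"].to_numpy()
    tv = np.repeat(sel["true_vaf"].to_numpy(), reps)
    labels = np.repeat(sel["clone_label"].to_numpy(), reps)
    carriers = np.repeat(sel["carriers"].to_numpy(), reps)
    blocks = np.repeat(sel["block"].to_numpy(), reps)

    rng = np.random.default_rng([norm_seed(cfg.seed), sim.attempt, 7919])
    depth = rng.poisson(cfg.coverage_rate, tv.size)
    alt = rng.binomial(np.maximum(depth, 1), tv)
    alt[depth == 0] = 0
    with np.errstate(invalid="ignore", divide="ignore"):
        obs = np.where(depth > 0, alt / np.maximum(depth, 1), np.nan)
    n_zero = int((depth == 0).sum())
    keep = (depth > 0) & (obs > cfg.vaf_cutoff) & (obs < 1.0)
    if n_zero:
        logger.info("sequence_tumour: %d mutations at zero depth dropped", n_zero)
    if not keep.any():
        logger.warning("sequence_tumour: no mutation passes the VAF cutoff")
    idx = np.flatnonzero(keep)
    df = pd.DataFrame(
        {
            "id": [f"m{i:06d}" for i in idx],
            "chrom": "1",
            "pos": idx + 1,
            "ref": "A",
            "alt": "T",
            "depth": depth[keep],
            "alt_reads": alt[keep],
            "vaf": obs[keep],
            "freq": obs[keep],
            "true_vaf": tv[keep],
            "carriers": carriers[keep],
            "clone_label": labels[keep],
            "block": blocks[keep],
        }
    )
    ds = FrequencyDataset(df, frequency_kind=VAF, min_frequency=cfg.vaf_cutoff)
    sim.observed = ds
    return ds


def simulate_tumour(cfg: SimulationConfig | None = None, **kwargs) -> SimulatedTumour:
    """Grow and sequence a tumour in one call."""
    if cfg is None:
        cfg = SimulationConfig(**kwargs)
    sim = simulate_growth(cfg)
    sequence_tumour(sim, cfg)
    return sim


def write_truth(sim: SimulatedTumour, path) -> Path:
    """Write the ground-truth sidecar TSV (observed mutations only)."""
    path = Path(path)
    if sim.observed is None:
        raise ValidationError("tumour has not been sequenced yet")
    cols = ["id", "clone_label", "true_vaf", "carriers", "block"]
    sim.observed.df[cols].to_csv(path, sep="\t", index=False)
    return path
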