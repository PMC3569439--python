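"""Stochastic single-molecule simulator and synthetic decay-table generator.

Molecules are born by a Poisson process and walk the degradation chain with
exact competing exponential clocks, so ensembles are exact draws from the
model.  The simulator is the package's end-to-end Monte-Carlo oracle (for
decay patterns and copy-number laws) and the generator of Table-style
synthetic fixtures for closed-loop fitting studies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .decay_patterns import steady_state_pattern
from .lifetime_models import (
    DecayChain,
    lifetime_exponential,
    lifetime_first_step,
    lifetime_from_chain,
    lifetime_last_step,
)

__all__ = [
    "SimConfig",
    "SimResult",
    "sample_lifetime",
    "sample_lifetimes",
    "run_experiment",
    "make_decay_tables",
    "random_truth_panel",
    "TABLE_TIME_GRID",
]

#: default measurement grid (minutes) of the decay tables
TABLE_TIME_GRID = np.array([0.0, 5.0, 10.0, 15.0, 20.0, 30.0, 40.0, 50.0, 60.0])

MAX_NOISE_SIGMA = 0.3


@dataclass
class SimConfig:
    chain: DecayChain
    nu: float = 5.0
    protocol: str = "steady_stop"  # or "pulse"
    t_equilibrate: float | None = None
    sample_times: np.ndarray = field(default_factory=lambda: TABLE_TIME_GRID.copy())
    n_cells: int = 1000
    seed: int | None = None
    noise_sigma: float = 0.0

    def __post_init__(self):
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.protocol not in ("steady_stop", "pulse"):
            raise ValueError(f"unknown protocol {self.protocol!r}")
        if self.seed is None:
            raise ValueError("seed is mandatory: no silent nondeterminism")
        self.sample_times = np.asarray(self.sample_times, dtype=float)
        if np.any(self.sample_times < 0):
            raise ValueError("sample times must be non-negative")


@dataclass
class SimResult:
    counts: np.ndarray  # (n_cells, n_sample_times)
    sample_times: np.ndarray
    ages_at_stop: np.ndarray | None  # ages of alive molecules (burn-in path)
    config: SimConfig


def sample_lifetimes(chain: DecayChain, size: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``size`` absorption times by exact competing-clock simulation."""
    total = np.append(chain.omega, 0.0) + chain.delta
    state = rng.choice(chain.n, size=size, p=chain.initial_state)
    times = np.zeros(size)
    for k in range(chain.n):
        here = state == k
        m = int(here.sum())
        if m == 0:
            continue
        if total[k] == 0:  # unreachable dead end (guarded by build_chain)
            raise RuntimeError(f"molecule stuck in state {k + 1} with zero rates")
        times[here] += rng.exponential(1.0 / total[k], size=m)
        if k < chain.n - 1:
            absorbed = rng.random(m) < chain.delta[k] / total[k]
            move = np.nonzero(here)[0][~absorbed]
            state[move] = k + 1
    return times


def sample_lifetime(chain: DecayChain, rng: np.random.Generator) -> float:
    """Single absorption-time draw."""
    return float(sample_lifetimes(chain, 1, rng)[0])


def _stationary_residuals(lt, size: int, rng: np.random.Generator) -> np.ndarray:
    """Sample residual lifetimes of alive molecules at steady state.

    Their survival function equals the steady-state decay pattern, so we
    invert a dense tabulation of it.
    """
    pattern = steady_state_pattern(lt)
    hi = 10.0 * lt.mean
    while float(pattern.value(hi)) > 1e-10:
        hi *= 2.0
    grid = np.concatenate([[0.0], np.geomspace(hi * 1e-6, hi, 4000)])
    vals = np.atleast_1d(pattern.value(grid))
    # pattern is decreasing from 1; invert by interpolation on (vals -> grid)
    u = rng.random(size)
    return np.interp(u, vals[::-1], grid[::-1])


def run_experiment(cfg: SimConfig, init: str = "stationary") -> SimResult:
    """Simulate an ensemble of cells through a decay assay.

    ``steady_stop``: establish steady state (either by the exact stationary
    construction, ``init='stationary'``, or by explicit burn-in of the birth
    process, ``init='burnin'``), stop transcription at t=0 and count
    survivors at each sample time.  ``pulse``: each cell receives a
    Poisson(nu) cohort born at t=0.  Deterministic given the seed.
    """
    rng = np.random.default_rng(cfg.seed)
    lt = lifetime_from_chain(cfg.chain)
    n_t = len(cfg.sample_times)
    counts = np.zeros((cfg.n_cells, n_t), dtype=np.int64)
    ages = None

    if cfg.protocol == "pulse":
        sizes = rng.poisson(cfg.nu, size=cfg.n_cells)
        lifetimes = sample_lifetimes(cfg.chain, int(sizes.sum()), rng)
        cell = np.repeat(np.arange(cfg.n_cells), sizes)
        for j, t in enumerate(cfg.sample_times):
            np.add.at(counts[:, j], cell[lifetimes > t], 1)
        return SimResult(counts, cfg.sample_times, None, cfg)

    if init == "stationary":
        n_alive = rng.poisson(cfg.nu * lt.mean, size=cfg.n_cells)
        residuals = _stationary_residuals(lt, int(n_alive.sum()), rng)
        cell = np.repeat(np.arange(cfg.n_cells), n_alive)
    elif init == "burnin":
        t_eq = cfg.t_equilibrate if cfg.t_equilibrate is not None else 25.0 * lt.mean
        if t_eq < 20.0 * lt.mean:
            warnings.warn(
                f"t_equilibrate={t_eq:.1f} min is short (< 20 mean lifetimes); "
                "the ensemble may not be stationary",
                stacklevel=2,
            )
        births = rng.poisson(cfg.nu * t_eq, size=cfg.n_cells)
        n_tot = int(births.sum())
        age_at_stop = rng.uniform(0.0, t_eq, size=n_tot)
        lifetimes = sample_lifetimes(cfg.chain, n_tot, rng)
        alive = lifetimes > age_at_stop
        residuals = (lifetimes - age_at_stop)[alive]
        cell = np.repeat(np.arange(cfg.n_cells), births)[alive]
        ages = age_at_stop[alive]
    else:
        raise ValueError(f"unknown init {init!r}")

    for j, t in enumerate(cfg.sample_times):
        np.add.at(counts[:, j], cell[residuals > t], 1)
    return SimResult(counts, cfg.sample_times, ages, cfg)


_VARIANT_BUILDERS = {
    "exponential": lambda p: lifetime_exponential(p["delta1"]),
    "first_step": lambda p: lifetime_first_step(p["omega"], p["delta1"], p["delta2"]),
    "last_step": lambda p: lifetime_last_step(
        p["omega"], p.get("delta1", 0.0), p["delta2"], n=int(p.get("n", 5))
    ),
}


def lifetime_from_params(variant: str, params: dict):
    """Build a lifetime model from a flat parameter record."""
    try:
        return _VARIANT_BUILDERS[variant](params)
    except KeyError:
        raise ValueError(f"unknown variant {variant!r}") from None


def random_truth_panel(
    n_genes: int,
    seed: int,
    mix: Sequence[float] = (1 / 3, 1 / 3, 1 / 3),
    n_states: int = 5,
) -> list[dict]:
    """Random generating parameters for a synthetic gene panel.

    ``mix`` gives the proportions of (exponential, slow-fast, fast-slow)
    genes — pass integer counts summing to ``n_genes`` for an exact split;
    rates are drawn so that half-lives fall in the measurable range of the
    default 0-60 min grid.
    """
    rng = np.random.default_rng(seed)
    mix_arr = np.asarray(mix, dtype=float)
    if np.all(mix_arr == np.round(mix_arr)) and int(mix_arr.sum()) == n_genes:
        cats = np.repeat(np.arange(3), mix_arr.astype(int))
    else:
        cats = rng.choice(3, size=n_genes, p=mix_arr / mix_arr.sum())
    truths = []
    for g, cat in enumerate(cats):
        gene = f"SYN{g:04d}"
        if cat == 0:
            delta = rng.uniform(0.02, 0.15)
            truths.append(
                {"gene_id": gene, "variant": "exponential", "category": 0,
                 "omega": 0.0, "delta1": delta, "delta2": delta, "n": 1}
            )
        elif cat == 1:  # slow-fast: maturation then efficient terminal decay
            omega = rng.uniform(0.1, 0.5)
            delta_last = rng.uniform(0.05, 0.3)
            truths.append(
                {"gene_id": gene, "variant": "last_step", "category": 1,
                 "omega": omega, "delta1": 0.0, "delta2": delta_last, "n": n_states}
            )
        else:  # fast-slow: unstable at birth, stabilising with age
            omega = rng.uniform(0.02, 0.2)
            delta2 = rng.uniform(0.005, 0.03)
            delta1 = delta2 + rng.uniform(0.1, 0.4)
            truths.append(
                {"gene_id": gene, "variant": "first_step", "category": 2,
                 "omega": omega, "delta1": delta1, "delta2": delta2, "n": 2}
            )
    return truths


def make_decay_tables(cfg: SimConfig, truths: Sequence[dict]):
    """Generate Table-style synthetic decay tables plus a truth manifest.

    For each truth record the analytic steady-state pattern is evaluated on
    ``cfg.sample_times``; Gaussian noise of sd ``cfg.noise_sigma`` is added
    (truncated so levels stay positive) and the t=0 level renormalised to 1.

    Returns ``(tables, manifest)`` where tables are :class:`~mrnadecay.fitting.DecayTable`
    and the manifest is a pandas DataFrame of the generating parameters.
    """
    import pandas as pd

    from .decay_patterns import pattern_half_life
    from .fitting import DecayTable

    if cfg.noise_sigma >= MAX_NOISE_SIGMA:
        raise ValueError(
            f"noise_sigma={cfg.noise_sigma} would destroy the curve shape "
            f"(limit {MAX_NOISE_SIGMA})"
        )
    if cfg.sample_times[0] != 0.0:
        raise ValueError("decay tables require a t=0 column")
    rng = np.random.default_rng(cfg.seed)
    tables, rows = [], []
    for rec in truths:
        lt = lifetime_from_params(rec["variant"], rec)
        pattern = steady_state_pattern(lt)
        clean = np.atleast_1d(pattern.value(cfg.sample_times))
        if cfg.noise_sigma > 0:
            levels = np.empty_like(clean)
            for j, mu in enumerate(clean):
                while True:  # truncate: resample until positive
                    v = mu + rng.normal(0.0, cfg.noise_sigma)
                    if v > 0:
                        break
                levels[j] = v
            levels = levels / levels[0]
        else:
            levels = clean.copy()
        tables.append(DecayTable(rec["gene_id"], cfg.sample_times.copy(), levels))
        rows.append(
            {
                "gene_id": rec["gene_id"],
                "variant": rec["variant"],
                "category": rec.get("category"),
                "omega": rec["omega"],
                "delta1": rec["delta1"],
                "delta2": rec["delta2"],
                "n": rec.get("n", 5),
                "mean_lifetime": lt.mean,
                "half_life": pattern_half_life(pattern),
            }
        )
    return tables, pd.DataFrame(rows)
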