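"""Synthetic paired control/query screens with known ground truth.

Emulates a spotted-culture fitness screen: a deletion/DAmP library arrayed in
384-spot format, ~8 replicate cultures per genotype, colonies imaged every
4 h over 5 days, growth following the generalized logistic model with
strain-specific (r, K, nu) and a shared inoculum density x0. The query
background multiplies every strain's growth rate by ``m_true`` (a uniformly
sicker background, as for a temperature-sensitive query allele at its
semi-permissive temperature), and a planted minority of genes carry an
additional multiplicative interaction effect. Measurement noise on density
is multiplicative log-normal, since colony-intensity errors scale with
signal.

Because MDR is exactly linear in r for fixed (x0, K, nu), scaling r scales
fitness by the same factor, so the generative slope ``m_true`` is the ground
truth for the slope recovered by the interaction stage.

Two generators are provided: ``generate_screen_pair`` emits raw growth
curves for exercising the full pipeline, and ``simulate_fitness_screens``
emits replicate fitnesses directly for statistical calibration experiments
at screen scale, where fitting hundreds of thousands of curves would be
pointless.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .growth_model import GrowthCurve, GrowthParams, density_at

__all__ = [
    "SimulationConfig",
    "generate_screen_pair",
    "simulate_fitness_screens",
    "write_simulated_raw",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic screen pair.

    Defaults emulate the study conditions: 8 replicate cultures per genotype,
    384-format plates, imaging every 4 h (1/6 day) for 5 days, and a query
    background reducing fitness to ~50% of control. Units: time in days,
    density in arbitrary colony-intensity units.
    """

    n_genes: int = 96
    n_replicates: int = 8
    plate_rows: int = 16
    plate_cols: int = 24
    n_plates: int | None = None  # None: as many as needed
    t_max: float = 5.0
    dt: float = 1.0 / 6.0  # every 4 hours
    x0: float = 0.002
    # per-gene parameter distributions (log-normal: median, sigma of log)
    r_median: float = 5.0
    r_sigma: float = 0.3
    k_median: float = 0.15
    k_sigma: float = 0.2
    nu_median: float = 1.0
    nu_sigma: float = 0.25
    nu_clip: tuple[float, float] = (0.2, 5.0)
    m_true: float = 0.5
    planted_fraction: float = 0.0
    planted_effect_range: tuple[float, float] = (0.5, 0.5)
    noise_sigma: float = 0.05  # sd of log multiplicative density noise
    dropout_fraction: float = 0.0  # random culture loss (SGA/QFA failures)
    temperature: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.planted_fraction <= 1.0):
            raise ValueError("planted_fraction must lie in [0, 1]")
        if not (0.0 <= self.dropout_fraction <= 1.0):
            raise ValueError("dropout_fraction must lie in [0, 1]")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        for name in ("x0", "r_median", "k_median", "nu_median", "m_true",
                     "t_max", "dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def timepoints(self) -> np.ndarray:
        return np.arange(0.0, self.t_max + 1e-9, self.dt)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("nu_clip", "planted_effect_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _draw_truth(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    genes = [f"YSG{i + 1:04d}" for i in range(cfg.n_genes)]
    r = cfg.r_median * np.exp(rng.normal(0.0, cfg.r_sigma, cfg.n_genes))
    k = cfg.k_median * np.exp(rng.normal(0.0, cfg.k_sigma, cfg.n_genes))
    nu = np.clip(
        cfg.nu_median * np.exp(rng.normal(0.0, cfg.nu_sigma, cfg.n_genes)),
        *cfg.nu_clip,
    )
    n_planted = int(round(cfg.planted_fraction * cfg.n_genes))
    planted = np.zeros(cfg.n_genes, dtype=bool)
    if n_planted:
        planted[rng.choice(cfg.n_genes, size=n_planted, replace=False)] = True
    lo, hi = cfg.planted_effect_range
    effect = np.ones(cfg.n_genes)
    effect[planted] = rng.uniform(lo, hi, n_planted) if hi > lo else lo
    return pd.DataFrame(
        dict(
            gene=genes, r=r, K=k, nu=nu, effect=effect,
            interacting=effect != 1.0,
        )
    )


def _plate_positions(cfg: SimulationConfig, n_cultures: int):
    """Deterministic row-major assignment of cultures to 384-format plates."""
    capacity = cfg.plate_rows * cfg.plate_cols
    needed = math.ceil(n_cultures / capacity)
    if cfg.n_plates is not None and cfg.n_plates < needed:
        raise ValueError(
            f"{n_cultures} cultures do not fit on {cfg.n_plates} "
            f"plates of {capacity} spots"
        )
    for i in range(n_cultures):
        plate = i // capacity + 1
        pos = i % capacity
        yield plate, pos // cfg.plate_cols + 1, pos % cfg.plate_cols + 1


def _simulate_screen(
    cfg: SimulationConfig,
    truth: pd.DataFrame,
    background: str,
    r_scale: np.ndarray,
    rng: np.random.Generator,
) -> list[GrowthCurve]:
    t = cfg.timepoints
    keep = (
        rng.random(cfg.n_genes * cfg.n_replicates) >= cfg.dropout_fraction
        if cfg.dropout_fraction > 0
        else np.ones(cfg.n_genes * cfg.n_replicates, dtype=bool)
    )
    curves: list[GrowthCurve] = []
    positions = _plate_positions(cfg, cfg.n_genes * cfg.n_replicates)
    idx = 0
    for g in range(cfg.n_genes):
        params = GrowthParams(
            x0=cfg.x0,
            r=float(truth.r.iloc[g] * r_scale[g]),
            K=float(truth.K.iloc[g]),
            nu=float(truth.nu.iloc[g]),
        )
        clean = density_at(params, t)
        for _ in range(cfg.n_replicates):
            plate, row, col = next(positions)
            take = keep[idx]
            idx += 1
            if not take:
                continue
            if cfg.noise_sigma > 0:
                dens = clean * np.exp(rng.normal(0.0, cfg.noise_sigma, t.size))
            else:
                dens = clean.copy()
            curves.append(
                GrowthCurve(
                    culture_id=f"{background}_P{plate:03d}_R{row:02d}C{col:02d}",
                    plate=f"{background}_P{plate:03d}",
                    row=row,
                    col=col,
                    gene=str(truth.gene.iloc[g]),
                    background=background,
                    temperature=cfg.temperature,
                    observations=tuple(zip(t.tolist(), dens.tolist())),
                )
            )
    return curves


def generate_screen_pair(
    cfg: SimulationConfig,
) -> tuple[list[GrowthCurve], list[GrowthCurve], pd.DataFrame]:
    """Simulate raw growth curves for a (control, query) screen pair.

    Control cultures grow with the gene's true (r, K, nu); query cultures
    have r scaled by ``m_true`` times the gene's interaction effect, so the
    expected query fitness is m_true x control fitness for non-interacting
    genes. Fully reproducible from ``cfg.seed``.
    """
    root = np.random.SeedSequence(cfg.seed)
    truth_rng, ctrl_rng, qry_rng = (
        np.random.default_rng(s) for s in root.spawn(3)
    )
    truth = _draw_truth(cfg, truth_rng)
    ones = np.ones(cfg.n_genes)
    control = _simulate_screen(cfg, truth, "control", ones, ctrl_rng)
    query = _simulate_screen(
        cfg, truth, "query", cfg.m_true * truth.effect.to_numpy(), qry_rng
    )
    return control, query, truth


def simulate_fitness_screens(
    n_genes: int = 2000,
    n_replicates: int = 8,
    m_true: float = 0.5,
    planted_fraction: float = 0.0,
    planted_effect_range: tuple[float, float] = (0.5, 0.5),
    noise_sigma: float = 0.05,
    fitness_median: float = 40.0,
    fitness_sigma: float = 0.3,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Replicate-level fitnesses for a screen pair, skipping curve simulation.

    Per gene, a true control fitness F is drawn log-normally
    (median ``fitness_median``, log-sd ``fitness_sigma``); replicate
    fitnesses are F times multiplicative log-normal noise of log-sd
    ``noise_sigma``. Query replicates use m_true x effect x F. Returns
    (control, query, truth) with control/query as long tables of columns
    ``gene`` and ``fitness``.
    """
    root = np.random.SeedSequence(seed)
    rng_truth, rng_ctrl, rng_qry = (np.random.default_rng(s) for s in root.spawn(3))
    genes = [f"YSG{i + 1:04d}" for i in range(n_genes)]
    base = fitness_median * np.exp(rng_truth.normal(0.0, fitness_sigma, n_genes))
    n_planted = int(round(planted_fraction * n_genes))
    planted = np.zeros(n_genes, dtype=bool)
    if n_planted:
        planted[rng_truth.choice(n_genes, size=n_planted, replace=False)] = True
    lo, hi = planted_effect_range
    effect = np.ones(n_genes)
    effect[planted] = rng_truth.uniform(lo, hi, n_planted) if hi > lo else lo

    def _replicates(mean: np.ndarray, rng: np.random.Generator) -> pd.DataFrame:
        noise = np.exp(rng.normal(0.0, noise_sigma, (n_genes, n_replicates)))
        vals = mean[:, None] * noise
        return pd.DataFrame(
            dict(
                gene=np.repeat(genes, n_replicates),
                fitness=vals.ravel(),
            )
        )

    control = _replicates(base, rng_ctrl)
    query = _replicates(m_true * effect * base, rng_qry)
    truth = pd.DataFrame(
        dict(gene=genes, fitness=base, effect=effect, interacting=effect != 1.0)
    )
    return control, query, truth


def write_simulated_raw(
    control: list[GrowthCurve],
    query: list[GrowthCurve],
    truth: pd.DataFrame,
    outdir: str | Path,
) -> dict[str, Path]:
    """Write the screen pair in the raw time-course format plus the truth table."""
    from .io import write_timecourses  # local import to avoid a cycle

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "control": outdir / "control_timecourse.txt",
        "query": outdir / "query_timecourse.txt",
        "truth": outdir / "truth.txt",
    }
    write_timecourses(control, paths["control"])
    write_timecourses(query, paths["query"])
    truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
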