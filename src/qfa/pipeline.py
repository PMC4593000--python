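"""High-level glue: fit a whole screen, run the interaction stage end-to-end.

Thin orchestration over growth_model and interaction so that the CLI, the
analysis drivers and the tests all execute the same code path.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .growth_model import (
    FitConfig,
    FitnessRecord,
    FitResult,
    GrowthCurve,
    choose_x0,
    fit_curve,
    fitness_of,
)
from .interaction import (
    GeneLocus,
    GISRecord,
    StrainSummary,
    estimate_slope,
    strip_genes,
    summarize_screen,
    test_interactions,
)

logger = logging.getLogger(__name__)

__all__ = ["fit_screen", "fitness_frame", "run_gis"]


def fit_screen(
    curves: Sequence[GrowthCurve],
    x0: float | None = None,
    fit_cfg: FitConfig | None = None,
    x0_quantile: float = 0.05,
) -> list[tuple[GrowthCurve, FitResult, FitnessRecord]]:
    """Fit every culture of a screen with a shared inoculum density.

    When ``x0`` is not given it is chosen once for the whole screen as the
    ``x0_quantile`` quantile of first-timepoint densities.
    """
    if not curves:
        return []
    if x0 is None:
        x0 = choose_x0([c.observations[0][1] for c in curves], x0_quantile)
        logger.info("fit_screen: shared x0 = %.6g (q=%.2f)", x0, x0_quantile)
    out = []
    n_failed = 0
    for curve in curves:
        fit = fit_curve(curve, x0, fit_cfg)
        if not fit.converged:
            n_failed += 1
        out.append((curve, fit, fitness_of(fit, curve.culture_id)))
    logger.info("fit_screen: %d curves fitted, %d not converged",
                len(out), n_failed)
    return out


def fitness_frame(
    entries: Sequence[tuple[GrowthCurve, FitResult, FitnessRecord]]
) -> pd.DataFrame:
    """Long per-culture table with the columns the interaction stage needs."""
    return pd.DataFrame(
        [
            dict(culture_id=r.culture_id, gene=c.gene, background=c.background,
                 fitness=r.fitness)
            for c, _, r in entries
        ]
    )


def run_gis(
    control_fitness: pd.DataFrame,
    query_fitness: pd.DataFrame,
    q_threshold: float = 0.05,
    loci: Mapping[str, GeneLocus] | None = None,
    query_loci: Iterable[GeneLocus] = (),
    exclusions: Iterable[str] = (),
    window: int = 20_000,
    sign_convention: str = "obs_minus_pred",
    slope_after_stripping: bool = True,
) -> tuple[list[GISRecord], float]:
    """Summarise both screens, strip linked genes, fit m, call interactions.

    Returns the GIS records and the fitted multiplicative-model slope m.
    """
    ctrl = summarize_screen(control_fitness, background="control")
    qry = summarize_screen(query_fitness, background="query")

    def _strip(summaries):
        if loci is None and not exclusions:
            return dict(summaries)
        return strip_genes(summaries, loci or {}, query_loci, window, exclusions)

    def _slope(c, q):
        shared = sorted(set(c) & set(q))
        return estimate_slope(
            [(c[g].mean_fitness, q[g].mean_fitness) for g in shared]
        )

    if slope_after_stripping:
        ctrl, qry = _strip(ctrl), _strip(qry)
        m = _slope(ctrl, qry)
    else:
        m = _slope(ctrl, qry)
        ctrl, qry = _strip(ctrl), _strip(qry)

    records = test_interactions(ctrl, qry, m, q_threshold, sign_convention)
    return records, m
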