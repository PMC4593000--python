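"""Genetic interaction strength (GIS) estimation between paired screens.

A query screen (library crossed into a mutant background) is compared with a
control screen at the same temperature. Under Fisher's multiplicative model
of genetic independence the mean query fitness of a non-interacting strain is
proportional to its mean control fitness:

    query_mean = m * control_mean

The slope ``m`` is fitted through the origin over all strains (most strains
are assumed not to interact). Per-strain predicted query fitnesses are
``m`` times each observed control replicate fitness; a Welch two-sample
two-tailed t-test compares observed query replicates against the predicted
sample, p-values are FDR-corrected by Benjamini-Hochberg across the tested
strains, and genes with q below the threshold are called interactors:

    GIS = observed query mean - predicted query mean

with GIS < 0 a negative (enhancer/sick) interaction and GIS > 0 a positive
(suppressor) interaction. Genes genetically linked to the query locus
(within 20 kb) and explicit SGA-failure lists are stripped before testing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "StrainSummary",
    "GISRecord",
    "GeneLocus",
    "summarize_screen",
    "estimate_slope",
    "adjust_fdr",
    "test_interactions",
    "strip_genes",
    "gis_records_to_frame",
]


@dataclass(frozen=True)
class StrainSummary:
    """Replicate fitnesses and their mean for one gene in one screen."""

    gene: str
    background: str
    replicate_fitnesses: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.replicate_fitnesses) < 1:
            raise ValueError(f"{self.gene}: at least one replicate required")

    @property
    def n(self) -> int:
        return len(self.replicate_fitnesses)

    @property
    def mean_fitness(self) -> float:
        return float(np.mean(self.replicate_fitnesses))


@dataclass(frozen=True)
class GISRecord:
    """Per-gene interaction result against a query background."""

    gene: str
    n_control: int
    n_query: int
    control_mean: float
    query_mean_obs: float
    query_mean_pred: float
    gis: float
    p: float  # NaN when untestable (n < 2 on either side)
    q: float
    call: str  # one of {"negative", "positive", "none"}


@dataclass(frozen=True)
class GeneLocus:
    """Chromosomal interval of a gene, 1-based inclusive coordinates."""

    gene: str
    chromosome: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene}: start ({self.start}) > end ({self.end})")


def summarize_screen(
    fitness: pd.DataFrame, background: str = ""
) -> dict[str, StrainSummary]:
    """Collapse per-culture fitnesses to per-gene replicate summaries.

    ``fitness`` needs columns ``gene`` and ``fitness``. Non-finite fitness
    values are dropped before averaging; genes left with no finite replicate
    are excluded with a warning.
    """
    out: dict[str, StrainSummary] = {}
    n_dropped = 0
    for gene, grp in fitness.groupby("gene", sort=True):
        vals = grp["fitness"].to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        n_dropped += vals.size - finite.size
        if finite.size == 0:
            logger.warning("gene %s: no finite fitness replicates, excluded", gene)
            continue
        out[str(gene)] = StrainSummary(
            gene=str(gene),
            background=background,
            replicate_fitnesses=tuple(float(v) for v in finite),
        )
    if n_dropped:
        logger.info("summarize_screen: dropped %d non-finite fitness values", n_dropped)
    return out


def estimate_slope(pairs: Sequence[tuple[float, float]]) -> float:
    """Through-origin least-squares slope m = sum(c*q)/sum(c^2).

    ``pairs`` are (control_mean, query_mean) per strain. The regression has
    no intercept: the independence model is purely multiplicative.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("need at least 2 (control, query) pairs")
    c, q = arr[:, 0], arr[:, 1]
    denom = float(np.sum(c * c))
    if denom == 0.0:
        raise ValueError("all control means are zero; slope undefined")
    return float(np.sum(c * q) / denom)


def adjust_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def test_interactions(
    control: Mapping[str, StrainSummary],
    query: Mapping[str, StrainSummary],
    m: float,
    q_threshold: float = 0.05,
    sign_convention: str = "obs_minus_pred",
) -> list[GISRecord]:
    """Welch-test every shared gene for deviation from the multiplicative model.

    Predicted query replicate fitnesses are ``m`` times the observed control
    replicates, so the prediction inherits the control replicate spread. The
    p-values of all testable genes (>= 2 replicates on both sides) form the
    FDR vector; untestable genes are reported with ``call="none"`` and NaN
    p/q and do not inflate the BH denominator.
    """
    if not np.isfinite(m):
        raise ValueError("slope m must be finite")
    if sign_convention not in ("obs_minus_pred", "pred_minus_obs"):
        raise ValueError(f"unknown sign convention {sign_convention!r}")

    genes = sorted(set(control) & set(query))
    rows: list[dict] = []
    testable_idx: list[int] = []
    welch_stats: list[tuple[float, float, float, float, int, int]] = []

    for i, gene in enumerate(genes):
        ctrl = control[gene]
        qry = query[gene]
        pred = m * np.asarray(ctrl.replicate_fitnesses)
        obs = np.asarray(qry.replicate_fitnesses)
        gis = float(obs.mean() - pred.mean())
        if sign_convention == "pred_minus_obs":
            gis = -gis
        row = dict(
            gene=gene,
            n_control=ctrl.n,
            n_query=qry.n,
            control_mean=ctrl.mean_fitness,
            query_mean_obs=float(obs.mean()),
            query_mean_pred=float(pred.mean()),
            gis=gis,
            p=np.nan,
            q=np.nan,
            call="none",
        )
        if ctrl.n >= 2 and qry.n >= 2:
            testable_idx.append(i)
            welch_stats.append(
                (float(obs.mean()), float(obs.var(ddof=1)),
                 float(pred.mean()), float(pred.var(ddof=1)),
                 qry.n, ctrl.n)
            )
        rows.append(row)

    # Welch two-sample t, vectorised over all testable genes
    pvals: list[float] = []
    if welch_stats:
        m1, v1, m2, v2, n1, n2 = (np.asarray(a, dtype=float)
                                  for a in zip(*welch_stats))
        se2 = v1 / n1 + v2 / n2
        with np.errstate(divide="ignore", invalid="ignore"):
            t_stat = (m1 - m2) / np.sqrt(se2)
            df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
            p_arr = 2.0 * stats.t.sf(np.abs(t_stat), df)
        # zero spread on both sides: t undefined; identical means -> p = 1
        degenerate = se2 == 0.0
        p_arr[degenerate & (m1 == m2)] = 1.0
        keep = np.isfinite(p_arr)
        testable_idx = [idx for idx, k in zip(testable_idx, keep) if k]
        pvals = p_arr[keep].tolist()
        for idx, p in zip(testable_idx, pvals):
            rows[idx]["p"] = float(p)

    if pvals:
        qvals = adjust_fdr(pvals)
        for idx, qv in zip(testable_idx, qvals):
            rows[idx]["q"] = float(qv)
            gis = rows[idx]["gis"]
            if qv < q_threshold and gis != 0.0:
                if sign_convention == "obs_minus_pred":
                    rows[idx]["call"] = "negative" if gis < 0 else "positive"
                else:
                    rows[idx]["call"] = "positive" if gis < 0 else "negative"

    n_neg = sum(r["call"] == "negative" for r in rows)
    n_pos = sum(r["call"] == "positive" for r in rows)
    logger.info(
        "test_interactions: %d genes tested, %d negative, %d positive (q < %g)",
        len(testable_idx), n_neg, n_pos, q_threshold,
    )
    return [GISRecord(**r) for r in rows]


def _interval_gap(a: GeneLocus, b: GeneLocus) -> int:
    """Gap in bp between two 1-based inclusive intervals; 0 when overlapping."""
    return max(0, max(a.start, b.start) - min(a.end, b.end))


def strip_genes(
    summaries: Mapping[str, StrainSummary],
    loci: Mapping[str, GeneLocus],
    query_loci: Iterable[GeneLocus],
    window: int = 20_000,
    exclusions: Iterable[str] = (),
) -> dict[str, StrainSummary]:
    """Remove linkage-window neighbours of the query loci and explicit exclusions.

    A gene is stripped when it lies on the same chromosome as a query locus
    with an interval gap <= ``window`` bp (inclusive at exactly the window),
    or when it appears in the explicit exclusion list (SGA failures). Genes
    missing from the loci table cannot be distance-checked and are retained
    with a logged warning. Idempotent.
    """
    excl = set(exclusions)
    q_loci = list(query_loci)
    kept: dict[str, StrainSummary] = {}
    n_linked = n_excluded = n_unlocated = 0
    for gene, summ in summaries.items():
        if gene in excl:
            n_excluded += 1
            continue
        locus = loci.get(gene)
        if locus is None:
            n_unlocated += 1
            logger.warning("strip_genes: no locus for %s; retained", gene)
            kept[gene] = summ
            continue
        linked = any(
            locus.chromosome == ql.chromosome and _interval_gap(locus, ql) <= window
            for ql in q_loci
        )
        if linked:
            n_linked += 1
            continue
        kept[gene] = summ
    logger.info(
        "strip_genes: %d linked within %d bp, %d excluded by list, "
        "%d without loci retained, %d kept",
        n_linked, window, n_excluded, n_unlocated, len(kept),
    )
    return kept


def gis_records_to_frame(records: Sequence[GISRecord]) -> pd.DataFrame:
    """Tabular view of GIS results (column order matches the report file)."""
    return pd.DataFrame(
        [
            dict(
                gene=r.gene, n_control=r.n_control, n_query=r.n_query,
                control_mean=r.control_mean, query_mean_obs=r.query_mean_obs,
                query_mean_pred=r.query_mean_pred, gis=r.gis, p=r.p, q=r.q,
                call=r.call,
            )
            for r in records
        ],
        columns=[
            "gene", "n_control", "n_query", "control_mean", "query_mean_obs",
            "query_mean_pred", "gis", "p", "q", "call",
        ],
    )
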