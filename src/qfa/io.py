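"""Readers and writers for the pipeline's tabular plain-text formats.

All tables are UTF-8 TSV with a header row. The raw time-course format (one
row per culture x timepoint) is the shape produced downstream of colony
image quantification:

    barcode  row  col  gene  background  temperature  expt_time_days  density

Derived formats: the fitness table (one row per culture, fitted parameters
plus MDR/MDP/fitness), the GIS report (``*.gis.txt``, one row per gene), the
wide profile table (gene x screens), and the Venn report. Gene loci come
from a 4-column TSV (gene, chromosome, start, end) or a GFF3 file;
exclusion lists are one gene per line.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .growth_model import FitResult, FitnessRecord, GrowthCurve
from .interaction import GeneLocus, GISRecord, gis_records_to_frame
from .profiles import ProfileSet, VennAssignment

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "SchemaError",
    "read_timecourses",
    "write_timecourses",
    "write_fitness_table",
    "read_fitness_table",
    "write_gis_report",
    "read_gis_report",
    "read_loci",
    "read_exclusions",
    "write_profile_table",
    "write_venn_report",
]

TIMECOURSE_COLUMNS = [
    "barcode", "row", "col", "gene", "background", "temperature",
    "expt_time_days", "density",
]

FITNESS_COLUMNS = [
    "culture_id", "plate", "row", "col", "gene", "background",
    "r", "K", "nu", "rss", "converged", "MDR", "MDP", "fitness",
]


class SchemaError(ValueError):
    """Input file does not match the documented schema."""


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings (YAML-serialisable).

    ``x0_quantile`` sets the shared-inoculum policy (quantile of
    first-timepoint densities); ``q_threshold`` is the FDR significance
    cut-off for interaction calls; ``strip_window`` the linkage window in bp;
    ``gis_sign`` one of {"obs_minus_pred", "pred_minus_obs"};
    ``slope_after_stripping`` controls whether the multiplicative-model slope
    is fitted before or after gene stripping.
    """

    x0_quantile: float = 0.05
    q_threshold: float = 0.05
    gis_sign: str = "obs_minus_pred"
    strip_window: int = 20_000
    slope_after_stripping: bool = True
    screens: dict = field(default_factory=dict)  # name -> {query, control, temperature}

    def __post_init__(self) -> None:
        if not (0.0 < self.q_threshold < 1.0):
            raise ValueError("q_threshold must lie in (0, 1)")
        if self.strip_window < 0:
            raise ValueError("strip_window must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=False)


def read_timecourses(path: str | Path) -> list[GrowthCurve]:
    """Parse a raw time-course table into one GrowthCurve per (barcode,row,col).

    Observations are sorted by time within each culture. Rows with
    non-numeric or negative density/time are rejected and counted in the
    log; a missing column is a schema error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, encoding="utf-8")
    missing = [c for c in TIMECOURSE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")

    n_raw = len(df)
    for col in ("expt_time_days", "density", "temperature"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in ("row", "col"):
        df[col] = pd.to_numeric(df[col], errors="coerce").astype("Int64")
    bad = (
        df[["expt_time_days", "density", "temperature", "row", "col"]].isna().any(axis=1)
        | (df["density"] < 0)
        | (df["expt_time_days"] < 0)
    )
    if bad.any():
        lines = (df.index[bad] + 2).tolist()  # +2: header + 1-based
        logger.warning(
            "%s: rejected %d malformed rows (file lines %s%s)",
            path, int(bad.sum()), lines[:10], "..." if len(lines) > 10 else "",
        )
        df = df[~bad]

    curves: list[GrowthCurve] = []
    for (barcode, row, col), grp in df.groupby(["barcode", "row", "col"], sort=True):
        grp = grp.sort_values("expt_time_days")
        curves.append(
            GrowthCurve(
                culture_id=f"{barcode}_R{int(row):02d}C{int(col):02d}",
                plate=str(barcode),
                row=int(row),
                col=int(col),
                gene=str(grp["gene"].iloc[0]),
                background=str(grp["background"].iloc[0]),
                temperature=float(grp["temperature"].iloc[0]),
                observations=tuple(
                    zip(grp["expt_time_days"].astype(float), grp["density"].astype(float))
                ),
            )
        )
    logger.info("%s: %d rows -> %d curves (%d rows rejected)",
                path, n_raw, len(curves), int(bad.sum()))
    return curves


def write_timecourses(curves: Sequence[GrowthCurve], path: str | Path) -> None:
    rows = [
        (c.plate, c.row, c.col, c.gene, c.background, c.temperature, t, x)
        for c in curves
        for t, x in c.observations
    ]
    pd.DataFrame(rows, columns=TIMECOURSE_COLUMNS).to_csv(
        path, sep="\t", index=False, encoding="utf-8"
    )


def write_fitness_table(
    entries: Sequence[tuple[GrowthCurve, FitResult, FitnessRecord]],
    path: str | Path,
) -> None:
    """One row per culture: identity, fitted (r, K, nu), rss, MDR/MDP/fitness."""
    rows = []
    for curve, fit, rec in entries:
        p = fit.params
        rows.append(
            (curve.culture_id, curve.plate, curve.row, curve.col, curve.gene,
             curve.background, p.r, p.K, p.nu, fit.rss, fit.converged,
             rec.mdr, rec.mdp, rec.fitness)
        )
    pd.DataFrame(rows, columns=FITNESS_COLUMNS).to_csv(
        path, sep="\t", index=False, encoding="utf-8"
    )


def read_fitness_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", encoding="utf-8")
    missing = [c for c in FITNESS_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    return df


def write_gis_report(records: Sequence[GISRecord], path: str | Path) -> None:
    """GIS report (``*.gis.txt``): one row per gene, q-sorted calls last column."""
    gis_records_to_frame(records).to_csv(path, sep="\t", index=False, encoding="utf-8")


def read_gis_report(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", encoding="utf-8")
    expected = [
        "gene", "n_control", "n_query", "control_mean", "query_mean_obs",
        "query_mean_pred", "gis", "p", "q", "call",
    ]
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    return df


def read_loci(path: str | Path) -> dict[str, GeneLocus]:
    """Gene loci from a 4-column TSV (gene, chromosome, start, end) or GFF3.

    In GFF3, ``gene`` features are used and the identifier is taken from the
    ``gene=`` attribute, falling back to ``Name=`` then ``ID=``.
    """
    path = Path(path)
    if path.suffix.lower() in (".gff", ".gff3"):
        return _read_loci_gff3(path)
    df = pd.read_csv(path, sep="\t", encoding="utf-8")
    missing = [c for c in ("gene", "chromosome", "start", "end") if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    return {
        str(r.gene): GeneLocus(str(r.gene), str(r.chromosome), int(r.start), int(r.end))
        for r in df.itertuples()
    }


def _read_loci_gff3(path: Path) -> dict[str, GeneLocus]:
    cols = ["seqid", "source", "type", "start", "end", "score", "strand",
            "phase", "attributes"]
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=cols,
                     encoding="utf-8")
    out: dict[str, GeneLocus] = {}
    for r in df[df["type"] == "gene"].itertuples():
        attrs = dict(
            kv.split("=", 1) for kv in str(r.attributes).split(";") if "=" in kv
        )
        name = attrs.get("gene") or attrs.get("Name") or attrs.get("ID")
        if name is None:
            logger.warning("%s: gene feature without identifier skipped", path)
            continue
        out[name] = GeneLocus(name, str(r.seqid), int(r.start), int(r.end))
    return out


def read_exclusions(path: str | Path) -> set[str]:
    """Plain-text exclusion list, one gene per line; blanks and '#' comments ignored."""
    genes = set()
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                genes.add(line)
    return genes


def write_profile_table(profile_set: ProfileSet, path: str | Path) -> None:
    """Wide gene x screens table of raw mean fitnesses."""
    profile_set.raw.to_csv(path, sep="\t", encoding="utf-8")


def write_venn_report(assignments: Sequence[VennAssignment], path: str | Path) -> None:
    pd.DataFrame(
        [
            (a.gene, ",".join(a.member_screens), a.area)
            for a in assignments
        ],
        columns=["gene", "member_screens", "area"],
    ).to_csv(path, sep="\t", index=False, encoding="utf-8")
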