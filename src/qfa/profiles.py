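"""Fitness profiles across screens, Venn classification and similarity search.

A gene's fitness profile is its vector of mean fitnesses across named screens
(control, query mutants, drug conditions). Screens measure fitness on
different scales, so distances are computed on per-screen z-standardized
values; the similarity search then ranks candidate genes by Euclidean
distance to the query profile over a chosen subset of screens.

Venn classification assigns each significantly interacting gene to exactly
one area of the multi-screen Venn diagram according to the exact set of
screens in which it is called.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .interaction import StrainSummary

logger = logging.getLogger(__name__)

__all__ = [
    "FitnessProfile",
    "VennAssignment",
    "ProfileSet",
    "build_profiles",
    "profile_distance",
    "nearest_profiles",
    "venn_classify",
]


@dataclass(frozen=True)
class FitnessProfile:
    """Per-gene mapping screen name -> summary fitness (NaN when absent)."""

    gene: str
    values: tuple[tuple[str, float], ...]

    def as_dict(self) -> dict[str, float]:
        return dict(self.values)


@dataclass(frozen=True)
class VennAssignment:
    """Membership pattern of one gene over the classified screens."""

    gene: str
    member_screens: tuple[str, ...]
    area: str


class ProfileSet:
    """Profiles of many genes over the same ordered set of screens.

    Holds raw mean fitnesses (gene x screen) and a per-screen z-standardized
    copy used only for distance computations, so that screens with different
    fitness scales are commensurable.
    """

    def __init__(self, raw: pd.DataFrame):
        self.raw = raw
        mu = raw.mean(axis=0, skipna=True)
        sd = raw.std(axis=0, ddof=0, skipna=True).replace(0.0, 1.0)
        self.standardized = (raw - mu) / sd

    @property
    def screens(self) -> list[str]:
        return list(self.raw.columns)

    @property
    def genes(self) -> list[str]:
        return list(self.raw.index)

    def profile(self, gene: str) -> FitnessProfile:
        row = self.raw.loc[gene]
        return FitnessProfile(
            gene=gene, values=tuple((s, float(row[s])) for s in self.raw.columns)
        )

    def __len__(self) -> int:
        return len(self.raw)


def build_profiles(
    screens: Sequence[tuple[str, Mapping[str, StrainSummary]]]
) -> ProfileSet:
    """Assemble one profile per gene appearing in any screen.

    Screens missing a gene leave NaN in that gene's profile. Standardization
    (mean 0, unit variance across genes within each screen) is computed once
    and used for distances only; raw values are preserved for reporting.
    """
    if len(screens) < 1:
        raise ValueError("need at least one screen")
    names = [name for name, _ in screens]
    if len(set(names)) != len(names):
        raise ValueError("screen names must be unique")
    genes = sorted({g for _, summ in screens for g in summ})
    data = {
        name: [summ[g].mean_fitness if g in summ else np.nan for g in genes]
        for name, summ in screens
    }
    raw = pd.DataFrame(data, index=pd.Index(genes, name="gene"), columns=names)
    return ProfileSet(raw)


def _included_screens(
    profile_set: ProfileSet, excluded_screens: Iterable[str]
) -> list[str]:
    excluded = set(excluded_screens)
    included = [s for s in profile_set.screens if s not in excluded]
    if not included:
        raise ValueError("no screens left after exclusion")
    return included


def profile_distance(
    a: FitnessProfile,
    b: FitnessProfile,
    included_screens: Sequence[str],
) -> float:
    """Euclidean distance between two profiles over the included screens.

    Values are expected on a common (standardized) scale; symmetric, zero
    iff the profiles agree on every included screen.
    """
    if not included_screens:
        raise ValueError("no shared included screens; distance undefined")
    da, db = a.as_dict(), b.as_dict()
    va = np.array([da[s] for s in included_screens], dtype=float)
    vb = np.array([db[s] for s in included_screens], dtype=float)
    if np.any(~np.isfinite(va)) or np.any(~np.isfinite(vb)):
        raise ValueError("profiles must be finite on every included screen")
    return float(np.linalg.norm(va - vb))


def nearest_profiles(
    query_gene: str,
    profile_set: ProfileSet,
    k: int,
    excluded_screens: Iterable[str] = (),
) -> list[tuple[str, float]]:
    """The k genes with fitness profiles closest to the query gene's.

    Distances are Euclidean on per-screen standardized fitnesses over the
    non-excluded screens. Candidates missing any included screen are dropped
    (no imputation). Ties are broken lexicographically by gene name; the
    query itself is excluded from the ranking.
    """
    included = _included_screens(profile_set, excluded_screens)
    z = profile_set.standardized[included]
    if query_gene not in z.index:
        raise KeyError(f"no profile for query gene {query_gene!r}")
    qv = z.loc[query_gene].to_numpy(dtype=float)
    if np.any(~np.isfinite(qv)):
        raise ValueError(
            f"query gene {query_gene!r} lacks values on included screens"
        )
    cand = z.drop(index=query_gene).dropna(axis=0, how="any")
    d = np.linalg.norm(cand.to_numpy(dtype=float) - qv, axis=1)
    order = sorted(zip(cand.index, d), key=lambda gd: (gd[1], gd[0]))
    if k > len(order):
        logger.info(
            "nearest_profiles: k=%d exceeds %d candidates; returning all",
            k, len(order),
        )
    return [(g, float(dist)) for g, dist in order[:k]]


def venn_classify(
    sets: Mapping[str, Iterable[str]]
) -> list[VennAssignment]:
    """Partition the union of per-screen gene sets by exact membership pattern.

    Every gene in the union lands in exactly one area; the area label joins
    the member screens in the input screen order.
    """
    named = {name: set(genes) for name, genes in sets.items()}
    order = list(named)
    assignments = []
    for gene in sorted(set().union(*named.values()) if named else set()):
        members = tuple(s for s in order if gene in named[s])
        assignments.append(
            VennAssignment(gene=gene, member_screens=members,
                           area=" ∩ ".join(members))
        )
    return assignments
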