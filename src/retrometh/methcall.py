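"""Unite per-sample cytosine counts and summarize methylation levels.

A site enters the analysis only when it is detected with at least
``min_coverage`` reads (default 10) in *every* sample of the design; the
methylation level of a site in a sample is the fraction of methylated
reads, C/(C+T).  Descriptive group means are means of per-sample means, so
each animal contributes equally regardless of its coverage; per-chromosome
group comparisons are two-sample equal-variance Student t tests on the
per-sample chromosome means.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import GenomicInterval, SiteCounts, chromosome_sort_key

logger = logging.getLogger(__name__)

CONTROL = "control"
EXPOSED = "exposed"


@dataclass(frozen=True)
class GroupDesign:
    """Two-group sample design: sample id -> {control, exposed}."""

    groups: Mapping[str, str]
    order: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        order = tuple(self.order) if self.order else tuple(self.groups)
        object.__setattr__(self, "order", order)
        labels = set(self.groups.values())
        if labels != {CONTROL, EXPOSED}:
            raise ValueError(
                f"design must contain exactly the groups "
                f"{{{CONTROL!r}, {EXPOSED!r}}}, got {sorted(labels)}"
            )
        if set(order) != set(self.groups):
            raise ValueError("sample order does not match design samples")

    @property
    def samples(self) -> tuple[str, ...]:
        return self.order

    def members(self, group: str) -> tuple[str, ...]:
        return tuple(s for s in self.order if self.groups[s] == group)

    def group_mask(self, group: str) -> np.ndarray:
        return np.array([self.groups[s] == group for s in self.order])


@dataclass
class MethylMatrix:
    """United per-CpG counts across all samples.

    ``sites`` is a DataFrame with columns ``chrom``, ``pos``, ``strand``
    (1-based positions), sorted by (chromosome in natural order, position).
    ``n_meth``/``n_total`` are (n_sites, n_samples) integer arrays with
    columns ordered as ``design.samples``.
    """

    sites: pd.DataFrame
    n_meth: np.ndarray
    n_total: np.ndarray
    design: GroupDesign
    min_coverage: int = 10

    def __post_init__(self) -> None:
        n_sites = len(self.sites)
        n_samples = len(self.design.samples)
        if self.n_meth.shape != (n_sites, n_samples):
            raise ValueError("n_meth shape does not match sites/design")
        if self.n_total.shape != (n_sites, n_samples):
            raise ValueError("n_total shape does not match sites/design")
        if n_sites and (self.n_total < self.min_coverage).any():
            raise ValueError("united matrix contains sites below min_coverage")

    def __len__(self) -> int:
        return len(self.sites)

    def levels(self) -> np.ndarray:
        """Per-site per-sample methylation levels in [0, 1]."""
        return self.n_meth / self.n_total

    def subset(self, mask: np.ndarray) -> "MethylMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return MethylMatrix(
            self.sites.iloc[idx].reset_index(drop=True),
            self.n_meth[idx], self.n_total[idx],
            self.design, self.min_coverage,
        )

    def chrom_mask(self, chrom: str) -> np.ndarray:
        return (self.sites["chrom"] == chrom).to_numpy()

    def region_mask(self, region: GenomicInterval) -> np.ndarray:
        return (
            (self.sites["chrom"] == region.chrom)
            & (self.sites["pos"] > region.start)
            & (self.sites["pos"] <= region.end)
        ).to_numpy()

    def chromosomes(self) -> list[str]:
        return sorted(self.sites["chrom"].unique(), key=chromosome_sort_key)


def methylation_level(n_meth: int, n_total: int) -> float:
    """Methylation level C/(C+T) of one cytosine in one sample."""
    if n_total < 1:
        raise ValueError("methylation level undefined for zero coverage")
    return n_meth / n_total


def unite_sites(
    per_sample_sites: Mapping[str, Sequence[SiteCounts]],
    design: GroupDesign,
    min_coverage: int = 10,
) -> MethylMatrix:
    """Intersect sites covered >= min_coverage in every sample of the design.

    The result is independent of sample input order (set intersection) and
    sorted by (chromosome, position).
    """
    missing = [s for s in design.samples if s not in per_sample_sites]
    if missing:
        raise ValueError(f"design samples without site lists: {missing}")

    frames = {}
    for sample in design.samples:
        recs = per_sample_sites[sample]
        df = pd.DataFrame(
            {
                "chrom": [r.chrom for r in recs],
                "pos": [r.pos for r in recs],
                "strand": [r.strand for r in recs],
                "m": [r.n_meth for r in recs],
                "t": [r.n_total for r in recs],
            }
        )
        df = df[df["t"] >= min_coverage]
        if df.duplicated(["chrom", "pos", "strand"]).any():
            raise ValueError(f"sample {sample!r} has duplicate sites")
        frames[sample] = df.set_index(["chrom", "pos", "strand"])

    common: Optional[pd.Index] = None
    for df in frames.values():
        common = df.index if common is None else common.intersection(df.index)
    assert common is not None
    if len(common) == 0:
        logger.warning("no sites shared by all %d samples at coverage >= %d",
                       len(design.samples), min_coverage)

    sites = pd.DataFrame(
        [(c, p, s) for c, p, s in common], columns=["chrom", "pos", "strand"]
    )
    keys = [chromosome_sort_key(c) for c in sites["chrom"]]
    order = sorted(range(len(sites)),
                   key=lambda i: (keys[i], int(sites["pos"].iloc[i])))
    sites = sites.iloc[order].reset_index(drop=True)
    common = pd.MultiIndex.from_frame(sites)

    n_samples = len(design.samples)
    n_meth = np.zeros((len(sites), n_samples), dtype=np.int64)
    n_total = np.zeros_like(n_meth)
    for j, sample in enumerate(design.samples):
        sub = frames[sample].loc[common]
        n_meth[:, j] = sub["m"].to_numpy()
        n_total[:, j] = sub["t"].to_numpy()
    return MethylMatrix(sites, n_meth, n_total, design, min_coverage)


def sample_means(matrix: MethylMatrix, mask: Optional[np.ndarray] = None) -> pd.Series:
    """Per-sample mean methylation level over the selected sites."""
    sub = matrix if mask is None else matrix.subset(mask)
    if len(sub) == 0:
        raise ValueError("mean methylation of an empty site subset is undefined")
    return pd.Series(sub.levels().mean(axis=0), index=matrix.design.samples)


def mean_methylation(
    matrix: MethylMatrix,
    mask: Optional[np.ndarray] = None,
    scope: Optional[str] = None,
    pooled: bool = False,
) -> dict[str, float]:
    """Per-group mean methylation level over a site subset.

    Default: mean of per-sample mean levels, so each animal weighs equally.
    ``pooled=True`` instead pools counts over sites and samples per group.
    ``scope`` restricts to one chromosome (combined with ``mask`` if given).
    """
    if scope is not None:
        cmask = matrix.chrom_mask(scope)
        mask = cmask if mask is None else (mask & cmask)
    sub = matrix if mask is None else matrix.subset(mask)
    if len(sub) == 0:
        raise ValueError("mean methylation of an empty site subset is undefined")
    out = {}
    for group in (CONTROL, EXPOSED):
        gmask = matrix.design.group_mask(group)
        if pooled:
            out[group] = sub.n_meth[:, gmask].sum() / sub.n_total[:, gmask].sum()
        else:
            out[group] = float(sub.levels()[:, gmask].mean(axis=0).mean())
    return out


def chromosome_mean_test(matrix: MethylMatrix) -> pd.DataFrame:
    """Per-chromosome group means and equal-variance two-sample t test.

    Operates on per-sample chromosome mean levels (n per group animals).
    Chromosomes with zero united sites are omitted with a warning.
    """
    design = matrix.design
    cmask = design.group_mask(CONTROL)
    emask = design.group_mask(EXPOSED)
    if cmask.sum() < 2 or emask.sum() < 2:
        raise ValueError("t test needs at least two samples per group")
    rows = []
    for chrom in matrix.chromosomes():
        sub = matrix.subset(matrix.chrom_mask(chrom))
        if len(sub) == 0:
            logger.warning("chromosome %s has no united sites; omitted", chrom)
            continue
        per_sample = sub.levels().mean(axis=0)
        ctrl, expo = per_sample[cmask], per_sample[emask]
        if np.ptp(per_sample) == 0:  # all samples identical: no evidence
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_ind(ctrl, expo, equal_var=True)
        rows.append({
            "chrom": chrom,
            "n_cpg": len(sub),
            "mean_control": float(ctrl.mean()),
            "mean_exposed": float(expo.mean()),
            "t": float(t),
            "p": float(p),
        })
    return pd.DataFrame(rows)


def region_mean_methylation(
    matrix: MethylMatrix, regions: Sequence[GenomicInterval]
) -> pd.DataFrame:
    """Per-region per-group mean level (unweighted across sites).

    Regions containing no united CpG are reported with missing values.
    """
    rows = []
    for region in regions:
        mask = matrix.region_mask(region)
        row = {
            "region": region.name or f"{region.chrom}:{region.start}-{region.end}",
            "chrom": region.chrom,
            "start": region.start,
            "end": region.end,
            "n_cpg": int(mask.sum()),
        }
        if mask.any():
            means = mean_methylation(matrix, mask)
            row["mean_control"] = means[CONTROL]
            row["mean_exposed"] = means[EXPOSED]
        else:
            row["mean_control"] = np.nan
            row["mean_exposed"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
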