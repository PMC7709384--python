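"""Over/underrepresentation of DMCs in annotation categories.

Each test is a two-sided Fisher's exact test (point-probability rule) on
the 2x2 table [DMC vs non-DMC] x [in category vs not], where the
background is the full set of united CpGs (DMCs included).  Following the
source analysis convention, raw p values are compared against a fixed
alpha (0.001 genome-wide, 0.01 for per-chromosome analyses); a BH-adjusted
column is emitted additionally for convenience but is not used for the
significance flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .diffmeth import adjust_q


@dataclass(frozen=True)
class EnrichmentResult:
    category: str
    n_dmc_in: int
    n_dmc_out: int
    n_bg_in: int
    n_bg_out: int
    odds_ratio: float
    p: float
    significant: bool

    @property
    def table(self) -> np.ndarray:
        return np.array([[self.n_dmc_in, self.n_dmc_out],
                         [self.n_bg_in, self.n_bg_out]])


def _odds_ratio(a: int, b: int, c: int, d: int) -> float:
    """Sample odds ratio with the 0.5 Haldane correction on zero cells only.

    When a full row or column is empty there is no contrast to estimate;
    the odds ratio is reported as 1 (the test p is 1 for such tables).
    """
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        return 1.0
    if 0 in (a, b, c, d):
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
    return (a * d) / (b * c)


def fisher_test(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p on [[a, b], [c, d]] (point-probability rule)."""
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def fisher_enrichment(
    dmc_in_category: np.ndarray,
    background_in_category: np.ndarray,
    category: str = "",
    alpha: float = 0.001,
) -> EnrichmentResult:
    """Fisher enrichment of a category among DMCs vs non-DMC background CpGs.

    ``dmc_in_category``: boolean membership of each DMC in the category;
    ``background_in_category``: likewise for *all* united CpGs (the DMCs
    are a subset of the background; non-DMC counts are derived by
    subtraction).
    """
    dmc_in_category = np.asarray(dmc_in_category, dtype=bool)
    background_in_category = np.asarray(background_in_category, dtype=bool)
    if dmc_in_category.size == 0:
        raise ValueError("empty DMC set")
    if dmc_in_category.size > background_in_category.size:
        raise ValueError("DMC set larger than background")
    a = int(dmc_in_category.sum())
    b = int(dmc_in_category.size - a)
    c = int(background_in_category.sum()) - a
    d = int((~background_in_category).sum()) - b
    if c < 0 or d < 0:
        raise ValueError("DMC counts exceed background counts per category")
    p = fisher_test(a, b, c, d)
    return EnrichmentResult(category, a, b, c, d, _odds_ratio(a, b, c, d),
                            p, p < alpha)


def category_distribution(
    background: pd.DataFrame,
    dmcs: pd.DataFrame,
    label_col: str = "basic",
    categories: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Percentage of each category among background CpGs, hypoDMCs, hyperDMCs.

    Each column sums to 100 (when its set is non-empty).
    """
    if categories is None:
        categories = sorted(background[label_col].unique())
    sets = {
        "all_cpgs": background[label_col],
        "hypo_dmcs": dmcs.loc[dmcs["call"] == "hypo", label_col],
        "hyper_dmcs": dmcs.loc[dmcs["call"] == "hyper", label_col],
    }
    rows = []
    for cat in categories:
        row = {"category": cat}
        for name, labels in sets.items():
            n = len(labels)
            row[name] = 100.0 * (labels == cat).sum() / n if n else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def enrichment_table(
    background: pd.DataFrame,
    dmcs: pd.DataFrame,
    label_col: str = "group",
    alpha: float = 0.001,
    categories: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Fisher enrichment of every category of ``label_col`` among the DMCs."""
    if len(dmcs) == 0:
        raise ValueError("empty DMC set")
    if categories is None:
        categories = sorted(background[label_col].unique())
    bg_labels = background[label_col].to_numpy()
    dmc_labels = dmcs[label_col].to_numpy()
    rows = []
    for cat in categories:
        res = fisher_enrichment(dmc_labels == cat, bg_labels == cat,
                                category=cat, alpha=alpha)
        rows.append({
            "category": cat,
            "n_dmc_in": res.n_dmc_in, "n_dmc_out": res.n_dmc_out,
            "n_bg_in": res.n_bg_in, "n_bg_out": res.n_bg_out,
            "odds_ratio": res.odds_ratio, "p": res.p,
            "significant": res.significant,
        })
    df = pd.DataFrame(rows)
    df["q_bh"] = adjust_q(df["p"].to_numpy())
    return df


def subfamily_enrichment(
    background: pd.DataFrame,
    dmcs: pd.DataFrame,
    class_filter: Optional[str] = None,
    alpha: float = 0.001,
) -> pd.DataFrame:
    """Per-subfamily enrichment within one repeat class (LINE or LTR).

    When ``class_filter`` is set, both DMC and background CpGs are first
    restricted to that group; one Fisher test is then run per subfamily
    present in the background.  Raw p values are compared against alpha
    (no correction, per the fixed-cutoff convention).
    """
    if class_filter is not None:
        background = background[background["group"] == class_filter]
        dmcs = dmcs[dmcs["group"] == class_filter]
    if len(dmcs) == 0:
        raise ValueError("empty DMC set after class filtering")
    return enrichment_table(background, dmcs, label_col="detailed", alpha=alpha)


def chromosome_enrichment(
    background: pd.DataFrame,
    dmcs: pd.DataFrame,
    chrom: str,
    label_col: str = "group",
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Per-category enrichment restricted to one chromosome (alpha 0.01)."""
    bg = background[background["chrom"] == chrom]
    if len(bg) == 0:
        raise ValueError(f"chromosome {chrom!r} absent from background")
    dm = dmcs[dmcs["chrom"] == chrom]
    if len(dm) == 0:
        # no DMCs on the chromosome: every category is trivially unenriched
        rows = []
        for cat in sorted(bg[label_col].unique()):
            n_in = int((bg[label_col] == cat).sum())
            rows.append({"category": cat, "n_dmc_in": 0, "n_dmc_out": 0,
                         "n_bg_in": n_in, "n_bg_out": len(bg) - n_in,
                         "odds_ratio": np.nan, "p": 1.0, "significant": False})
        df = pd.DataFrame(rows)
        df["q_bh"] = 1.0
        return df
    return enrichment_table(bg, dm, label_col=label_col, alpha=alpha)
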