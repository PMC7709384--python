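"""DMC and DMR calling between two exposure groups.

Per CpG, methylated counts are modeled by binomial logistic regression on
the group indicator and tested against the intercept-only model with a
likelihood-ratio chi-square (1 df).  With a single binary covariate the
maximum-likelihood fitted proportions are the pooled per-group proportions,
so the deviance is evaluated in closed form from the per-sample binomial
log-likelihoods; this is the exact logistic-regression LRT, computed
without iterative fitting.  No overdispersion correction is applied.

Calls:

* hypoDMC:  q <= q_threshold and meth_diff <= -diff_threshold (inclusive),
* hyperDMC: q <= q_threshold and meth_diff >= +diff_threshold,

where meth_diff is the exposed-minus-control difference of pooled group
proportions in percentage points and q is the Benjamini-Hochberg adjusted
p value.

DMRs are chains of consecutive united CpGs (inter-CpG gap <= max_gap)
containing >= min_cpg CpGs and >= 1 DMC, whose pooled region-level group
difference exceeds diff_threshold in magnitude (strictly) and whose
Stouffer-combined per-CpG p values survive BH at q_threshold across
candidate regions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import xlogy
from statsmodels.stats.multitest import multipletests

from .methcall import EXPOSED, MethylMatrix

HYPO = "hypo"
HYPER = "hyper"
NONE = "none"


def _binom_loglik(m: np.ndarray, t: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Sum over samples of the binomial log-likelihood kernel, per site.

    Combinatorial terms are omitted; they cancel in likelihood ratios.
    ``p`` broadcasts against (n_sites, n_samples) count arrays.
    """
    return (xlogy(m, p) + xlogy(t - m, 1.0 - p)).sum(axis=-1)


def lrt_statistics(
    n_meth: np.ndarray, n_total: np.ndarray, exposed_mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized per-site logistic-regression LRT.

    Returns (statistic, p, meth_diff) arrays; meth_diff is in percentage
    points, exposed minus control.
    """
    n_meth = np.atleast_2d(n_meth)
    n_total = np.atleast_2d(n_total)
    exposed_mask = np.asarray(exposed_mask, dtype=bool)
    control_mask = ~exposed_mask

    mc = n_meth[:, control_mask]
    tc = n_total[:, control_mask]
    me = n_meth[:, exposed_mask]
    te = n_total[:, exposed_mask]

    p_ctrl = mc.sum(axis=1) / tc.sum(axis=1)
    p_expo = me.sum(axis=1) / te.sum(axis=1)
    p_null = n_meth.sum(axis=1) / n_total.sum(axis=1)

    ll_alt = (_binom_loglik(mc, tc, p_ctrl[:, None])
              + _binom_loglik(me, te, p_expo[:, None]))
    ll_null = _binom_loglik(n_meth, n_total, p_null[:, None])
    stat = np.maximum(2.0 * (ll_alt - ll_null), 0.0)
    p = stats.chi2.sf(stat, df=1)
    meth_diff = 100.0 * (p_expo - p_ctrl)
    return stat, p, meth_diff


def dmc_test(
    n_meth: np.ndarray, n_total: np.ndarray, exposed_mask: np.ndarray
) -> tuple[float, float, float]:
    """LRT for one site: (statistic, p, meth_diff in percentage points)."""
    n_total = np.asarray(n_total)
    if (n_total <= 0).any():
        raise ValueError("dmc_test requires positive coverage in every sample")
    stat, p, diff = lrt_statistics(
        np.asarray(n_meth)[None, :], n_total[None, :], exposed_mask
    )
    return float(stat[0]), float(p[0]), float(diff[0])


def adjust_q(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def dmc_test_all(matrix: MethylMatrix) -> pd.DataFrame:
    """Per-CpG DMC table: site key, statistic, p, q, meth_diff, call=none.

    Calls are assigned separately by :func:`call_dmcs`.
    """
    exposed_mask = matrix.design.group_mask(EXPOSED)
    stat, p, diff = lrt_statistics(matrix.n_meth, matrix.n_total, exposed_mask)
    df = matrix.sites.copy()
    df["statistic"] = stat
    df["p"] = p
    df["q"] = adjust_q(p)
    df["meth_diff"] = diff
    df["call"] = NONE
    return df


def call_dmcs(
    records: pd.DataFrame,
    q_threshold: float = 0.01,
    diff_threshold: float = 10.0,
) -> pd.DataFrame:
    """Assign hypo/hyper/none calls; both thresholds are inclusive."""
    df = records.copy()
    sig = df["q"] <= q_threshold
    df["call"] = NONE
    df.loc[sig & (df["meth_diff"] <= -diff_threshold), "call"] = HYPO
    df.loc[sig & (df["meth_diff"] >= diff_threshold), "call"] = HYPER
    return df


def call_dmrs(
    matrix: MethylMatrix,
    dmc_records: pd.DataFrame,
    max_gap: int = 100,
    min_cpg: int = 3,
    diff_threshold: float = 10.0,
    q_threshold: float = 0.01,
) -> pd.DataFrame:
    """Call DMRs on chains of nearby united CpGs.

    Candidate regions chain consecutive united CpGs with inter-CpG distance
    <= ``max_gap`` on the same chromosome and require >= ``min_cpg`` CpGs.
    A candidate is kept when it contains >= 1 DMC, its pooled region-level
    group difference satisfies |diff| > diff_threshold (strict), and its
    Stouffer-combined per-CpG p value survives BH at ``q_threshold`` across
    all candidates.  Direction is the sign of the region difference.
    """
    if list(dmc_records["pos"]) != list(matrix.sites["pos"]) or list(
        dmc_records["chrom"]
    ) != list(matrix.sites["chrom"]):
        raise ValueError("dmc_records must be aligned with matrix sites")

    exposed = matrix.design.group_mask(EXPOSED)
    control = ~exposed
    chroms = matrix.sites["chrom"].to_numpy()
    pos = matrix.sites["pos"].to_numpy()

    candidates: list[dict] = []
    i = 0
    n = len(matrix)
    while i < n:
        j = i
        while (j + 1 < n and chroms[j + 1] == chroms[i]
               and pos[j + 1] - pos[j] <= max_gap):
            j += 1
        if j - i + 1 >= min_cpg:
            idx = np.arange(i, j + 1)
            mc = matrix.n_meth[idx][:, control].sum()
            tc = matrix.n_total[idx][:, control].sum()
            me = matrix.n_meth[idx][:, exposed].sum()
            te = matrix.n_total[idx][:, exposed].sum()
            region_diff = 100.0 * (me / te - mc / tc)
            p_vals = dmc_records["p"].to_numpy()[idx]
            _, p_comb = stats.combine_pvalues(
                np.clip(p_vals, 1e-300, 1.0), method="stouffer"
            )
            n_dmc = int((dmc_records["call"].to_numpy()[idx] != NONE).sum())
            candidates.append({
                "chrom": chroms[i],
                "start": int(pos[i]) - 1,      # BED 0-based
                "end": int(pos[j]),
                "n_cpg": len(idx),
                "n_dmc": n_dmc,
                "meth_diff": region_diff,
                "p": float(p_comb),
            })
        i = j + 1

    df = pd.DataFrame(candidates, columns=[
        "chrom", "start", "end", "n_cpg", "n_dmc", "meth_diff", "p"])
    if df.empty:
        df["q"] = pd.Series(dtype=float)
        df["call"] = pd.Series(dtype=object)
        return df
    df["q"] = adjust_q(df["p"].to_numpy())
    # strict "> threshold", made robust to float round-off at the boundary
    keep = (
        (df["n_dmc"] >= 1)
        & (df["meth_diff"].abs() > diff_threshold + 1e-9)
        & (df["q"] <= q_threshold)
    )
    df = df[keep].reset_index(drop=True)
    df["call"] = np.where(df["meth_diff"] < 0, HYPO, HYPER)
    # invariants asserted on output
    assert (df["n_cpg"] >= min_cpg).all() and (df["n_dmc"] >= 1).all()
    return df


def dmc_chromosome_summary(dmcs: pd.DataFrame, matrix: MethylMatrix) -> pd.DataFrame:
    """Per-chromosome DMC counts and percentages among united CpGs."""
    rows = []
    chrom_col = dmcs["chrom"]
    for chrom in matrix.chromosomes():
        n_cpg = int(matrix.chrom_mask(chrom).sum())
        sub = dmcs[chrom_col == chrom]
        n_hypo = int((sub["call"] == HYPO).sum())
        n_hyper = int((sub["call"] == HYPER).sum())
        rows.append({
            "chrom": chrom,
            "n_cpg": n_cpg,
            "n_hypo": n_hypo,
            "n_hyper": n_hyper,
            "pct_hypo": 100.0 * n_hypo / n_cpg if n_cpg else 0.0,
            "pct_hyper": 100.0 * n_hyper / n_cpg if n_cpg else 0.0,
        })
    return pd.DataFrame(rows)
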