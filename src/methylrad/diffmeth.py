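"""Negative-binomial differential methylation between two sample groups.

The count model follows the standard RNA-seq-style NB formulation: the tag
count :math:`K_{ij}` for site *i* in sample *j* is

.. math::  K_{ij} \\sim \\mathrm{NB}(\\mu_{ij},\\ \\alpha_i), \\qquad
           \\mu_{ij} = s_j \\, q_{i,\\rho(j)}, \\qquad
           \\mathrm{Var}(K_{ij}) = \\mu_{ij} + \\alpha_i \\mu_{ij}^2,

with per-sample size factors :math:`s_j` (median-of-ratios), a per-group
mean :math:`q_{ig}` and a per-site dispersion :math:`\\alpha_i`.  The test
statistic is a Wald test on the group coefficient of a log-link NB GLM
with :math:`\\log s_j` offset; two-sided p-values use a t reference with
the residual degrees of freedom (a small-sample correction; the designs
here have 4-20 samples per group), and Benjamini-Hochberg adjustment is
applied across sites with non-missing p.

Dispersion is estimated in three steps, a deliberately compact version of
the empirical-Bayes machinery of the large RNA-seq packages: (1) per-site
method-of-moments on normalized counts with the group structure removed,
(2) a log-linear mean-dispersion trend fitted across sites, (3) 50/50
shrinkage of each per-site estimate toward the trend in log space.  Sites
whose moment estimate is non-positive (apparent under-dispersion) take the
trend value.  There is no outlier replacement and no independent
filtering.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from methylrad.quantification import CountMatrix

__all__ = [
    "DifferentialMethylation",
    "DiffMethResults",
    "estimate_size_factors",
    "estimate_dispersions",
    "nb_wald_test",
    "bh_adjust",
    "fisher_go_enrichment",
    "standard_contrasts",
]

logger = logging.getLogger(__name__)

DISPERSION_FLOOR = 1e-8
DISPERSION_CAP = 10.0
ALPHA_SIGNIFICANCE = 0.05


def estimate_size_factors(counts: CountMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    For every site with nonzero counts in *all* samples, each sample's
    count is divided by the site's geometric mean across samples; the
    sample's size factor is the median of those ratios.  If no site is
    nonzero everywhere, library-size ratios (column sums scaled to
    geometric mean 1) are used instead, with a warning.
    """
    table = counts.counts if isinstance(counts, CountMatrix) else counts
    arr = table.to_numpy(dtype=float)
    all_nonzero = (arr > 0).all(axis=1)
    if all_nonzero.any():
        sub = arr[all_nonzero]
        log_geomean = np.log(sub).mean(axis=1, keepdims=True)
        ratios = np.exp(np.log(sub) - log_geomean)
        factors = np.median(ratios, axis=0)
    else:
        logger.warning(
            "no site has nonzero counts in every sample; "
            "falling back to library-size ratios"
        )
        libsizes = arr.sum(axis=0)
        if (libsizes <= 0).any():
            raise ValueError("a sample has zero total counts")
        factors = libsizes / np.exp(np.mean(np.log(libsizes)))
    return pd.Series(factors, index=table.columns, name="size_factor")


def estimate_dispersions(
    table: pd.DataFrame,
    size_factors: pd.Series,
    groups: pd.Series,
) -> pd.DataFrame:
    """Per-site NB dispersions: method of moments, trend, 50/50 shrinkage.

    Returns a DataFrame with columns ``mom`` (raw moment estimate, NaN when
    non-positive), ``trend`` and ``final``.
    """
    s = size_factors.reindex(table.columns).to_numpy(dtype=float)
    q = table.to_numpy(dtype=float) / s  # normalized counts
    group_labels = groups.reindex(table.columns).to_numpy()
    levels = pd.unique(group_labels)

    n = q.shape[1]
    n_params = len(levels)
    resid_ss = np.zeros(len(table))
    mu_bar = q.mean(axis=1)
    for lvl in levels:
        mask = group_labels == lvl
        sub = q[:, mask]
        resid_ss += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    df_resid = max(n - n_params, 1)
    var_hat = resid_ss / df_resid
    # Var(q_ij) = mu/s_j + alpha mu^2  =>  alpha = (var - mu*mean(1/s)) / mu^2
    shot_noise = mu_bar * np.mean(1.0 / s)
    with np.errstate(divide="ignore", invalid="ignore"):
        mom = (var_hat - shot_noise) / (mu_bar**2)
    mom = np.where(mu_bar > 0, mom, np.nan)
    mom_pos = np.where(np.nan_to_num(mom, nan=0.0) > 0, mom, np.nan)

    # log-linear mean-dispersion trend across sites with a positive estimate
    usable = np.isfinite(mom_pos) & (mu_bar > 0)
    if usable.sum() >= 5:
        x = np.log(mu_bar[usable])
        y = np.log(mom_pos[usable])
        slope, intercept = np.polyfit(x, y, 1)
        with np.errstate(divide="ignore"):
            trend = np.exp(intercept + slope * np.log(np.maximum(mu_bar, 1e-12)))
    elif usable.any():
        trend = np.full(len(table), np.exp(np.nanmean(np.log(mom_pos[usable]))))
    else:  # counts look Poisson everywhere
        trend = np.full(len(table), DISPERSION_FLOOR)
    trend = np.clip(trend, DISPERSION_FLOOR, DISPERSION_CAP)

    final = np.where(
        np.isfinite(mom_pos),
        np.exp(0.5 * np.log(np.where(np.isfinite(mom_pos), mom_pos, 1.0))
               + 0.5 * np.log(trend)),
        trend,
    )
    final = np.clip(final, DISPERSION_FLOOR, DISPERSION_CAP)
    return pd.DataFrame(
        {"mom": mom, "trend": trend, "final": final}, index=table.index
    )


def _wald_one_site(
    y: np.ndarray,
    design: np.ndarray,
    offset: np.ndarray,
    alpha: float,
    df_resid: int,
) -> tuple[float, float, float, float]:
    """Fit the NB GLM for one site; return (log2FC, SE(log2FC), stat, p)."""
    fam = sm.families.NegativeBinomial(alpha=max(alpha, DISPERSION_FLOOR))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.GLM(y, design, family=fam, offset=offset).fit(maxiter=100)
        except Exception:
            return np.nan, np.nan, np.nan, np.nan
    beta = fit.params[1]
    se = fit.bse[1]
    ln2 = np.log(2.0)
    if not np.isfinite(se) or se <= 0:
        return beta / ln2, np.nan, np.nan, np.nan
    stat = beta / se
    p = 2.0 * scipy.stats.t.sf(abs(stat), df=max(df_resid, 1))
    return beta / ln2, se / ln2, stat, p


def nb_wald_test(
    counts: CountMatrix,
    groups: pd.Series | Mapping[str, str],
    level1: str,
    level2: str,
    size_factors: pd.Series | None = None,
    alpha: float = ALPHA_SIGNIFICANCE,
) -> pd.DataFrame:
    """Two-group NB Wald test per site (``level2`` versus ``level1``).

    Returns a site-indexed DataFrame with ``base_mean``,
    ``log2_fold_change`` (positive = higher in ``level2``), ``lfc_se``,
    ``wald_stat``, ``wald_p``, ``padj`` and ``significant`` (padj below
    ``alpha``).  All-zero sites get NA p-values and are excluded from the
    BH denominator.  Each group needs at least two samples.
    """
    groups = pd.Series(groups)
    table = counts.counts
    in_test = groups.reindex(table.columns).isin([level1, level2])
    cols = [c for c in table.columns if in_test.get(c, False)]
    table = table[cols]
    grp = groups.reindex(cols)
    n1 = int((grp == level1).sum())
    n2 = int((grp == level2).sum())
    if n1 < 2 or n2 < 2:
        raise ValueError(
            f"each group needs >= 2 samples (got {level1}: {n1}, {level2}: {n2})"
        )

    if size_factors is None:
        size_factors = estimate_size_factors(table)
    s = size_factors.reindex(cols).to_numpy(dtype=float)
    if not np.isfinite(s).all() or (s <= 0).any():
        raise ValueError("size factors must be finite and positive")

    disp = estimate_dispersions(table, size_factors, grp)
    design = np.column_stack(
        [np.ones(len(cols)), (grp == level2).to_numpy(dtype=float)]
    )
    offset = np.log(s)
    df_resid = n1 + n2 - 2

    arr = table.to_numpy(dtype=float)
    base_mean = (arr / s).mean(axis=1)
    records = []
    for i, site in enumerate(table.index):
        y = arr[i]
        if y.sum() == 0:
            records.append((site, 0.0, np.nan, np.nan, np.nan, np.nan))
            continue
        l2fc, se, stat, p = _wald_one_site(
            y, design, offset, disp["final"].iloc[i], df_resid
        )
        records.append((site, base_mean[i], l2fc, se, stat, p))
    out = pd.DataFrame(
        records,
        columns=["site_id", "base_mean", "log2_fold_change", "lfc_se",
                 "wald_stat", "wald_p"],
    ).set_index("site_id")
    out["padj"] = bh_adjust(out["wald_p"].to_numpy())
    out["significant"] = out["padj"] < alpha
    out.loc[out["padj"].isna(), "significant"] = False
    out["dispersion"] = disp["final"].to_numpy()
    return out


def bh_adjust(pvals: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment; NaNs are passed through and
    excluded from the denominator."""
    p = np.asarray(pvals, dtype=float)
    ok = np.isfinite(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full_like(p, np.nan)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# Model / Results interface


@dataclass
class DiffMethResults:
    """Fitted differential-methylation results for one two-group contrast."""

    table: pd.DataFrame
    size_factors: pd.Series
    contrast: tuple[str, str, str]  # (factor, level1, level2)
    n_samples: tuple[int, int]
    alpha: float = ALPHA_SIGNIFICANCE

    @property
    def significant_sites(self) -> list[str]:
        return list(self.table.index[self.table["significant"]])

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())

    def summary(self, max_rows: int = 10) -> str:
        factor, l1, l2 = self.contrast
        tested = int(self.table["wald_p"].notna().sum())
        lines = [
            "Differential methylation (negative-binomial Wald test)",
            "=" * 56,
            f"Contrast:        {factor}: {l2} vs {l1}",
            f"Samples:         {self.n_samples[0]} ({l1}) + {self.n_samples[1]} ({l2})",
            f"Sites tested:    {tested} of {len(self.table)}",
            f"Significant:     {self.n_significant} at BH padj < {self.alpha:g}",
            "",
        ]
        top = self.table.dropna(subset=["wald_p"]).sort_values("padj").head(max_rows)
        if len(top):
            lines.append(
                top[["base_mean", "log2_fold_change", "wald_p", "padj"]]
                .round(4)
                .to_string()
            )
        return "\n".join(lines)

    def to_tsv(self, path, annotations: Mapping[str, Mapping] | None = None) -> None:
        out = self.table.copy()
        if annotations:
            out["gene_id"] = [
                (annotations.get(s) or {}).get("gene_id", ".") for s in out.index
            ]
            out["context"] = [
                (annotations.get(s) or {}).get("context", ".") for s in out.index
            ]
        out.to_csv(path, sep="\t", na_rep="NA")


class DifferentialMethylation:
    """Two-group NB differential-methylation model on a raw count matrix.

    Parameters
    ----------
    counts
        Raw (unfiltered or coverage-filtered) tag counts with sample
        metadata attached.
    factor
        Metadata column defining the grouping (``origin``, ``cultivation``
        or ``temperature_C``).
    level1, level2
        The two factor levels to contrast; fold changes are reported as
        ``level2`` over ``level1``.
    subset
        Optional ``{factor: level}`` restriction applied before testing,
        e.g. ``{"cultivation": "lab"}`` to compare origins within
        laboratory samples only.
    """

    def __init__(
        self,
        counts: CountMatrix,
        factor: str,
        level1: str,
        level2: str,
        subset: Mapping[str, str] | None = None,
        alpha: float = ALPHA_SIGNIFICANCE,
    ):
        if counts.metadata is None:
            raise ValueError("count matrix needs sample metadata")
        self.factor = factor
        self.level1, self.level2 = str(level1), str(level2)
        self.alpha = alpha
        meta = counts.metadata
        keep = pd.Series(True, index=pd.Index(meta.sample_ids))
        for sub_factor, sub_level in (subset or {}).items():
            keep &= meta.factor(sub_factor).astype(str) == str(sub_level)
        kept = list(keep.index[keep])
        self.counts = counts.subset_samples(kept)
        self.groups = self.counts.metadata.factor(factor).astype(str)

    @classmethod
    def from_dataframe(
        cls,
        counts: pd.DataFrame,
        metadata,
        factor: str,
        level1: str,
        level2: str,
        **kwargs,
    ) -> "DifferentialMethylation":
        return cls(CountMatrix(counts, metadata=metadata), factor,
                   level1, level2, **kwargs)

    def fit(self, size_factors: pd.Series | None = None) -> DiffMethResults:
        table = nb_wald_test(
            self.counts,
            self.groups,
            self.level1,
            self.level2,
            size_factors=size_factors,
            alpha=self.alpha,
        )
        if size_factors is None:
            in_test = self.groups.isin([self.level1, self.level2])
            cols = [c for c in self.counts.sample_ids if in_test.get(c, False)]
            size_factors = estimate_size_factors(self.counts.counts[cols])
        n1 = int((self.groups == self.level1).sum())
        n2 = int((self.groups == self.level2).sum())
        return DiffMethResults(
            table=table,
            size_factors=size_factors,
            contrast=(self.factor, self.level1, self.level2),
            n_samples=(n1, n2),
            alpha=self.alpha,
        )


def standard_contrasts() -> list[dict]:
    """The full two-group contrast grid of the study design, expressed
    through the single two-group interface plus sample subsetting:
    origin within all/field/lab samples, cultivation within all/origin,
    temperature pairs (combined and per origin), and origin at each
    temperature."""
    grid: list[dict] = []
    grid.append(dict(name="origin_all", factor="origin",
                     level1="Helgoland", level2="Spitsbergen", subset=None))
    for cult in ("field", "lab"):
        grid.append(dict(name=f"origin_{cult}", factor="origin",
                         level1="Helgoland", level2="Spitsbergen",
                         subset={"cultivation": cult}))
    grid.append(dict(name="cultivation_all", factor="cultivation",
                     level1="field", level2="lab", subset=None))
    for origin in ("Helgoland", "Spitsbergen"):
        grid.append(dict(name=f"cultivation_{origin}", factor="cultivation",
                         level1="field", level2="lab",
                         subset={"origin": origin}))
    temp_pairs = [("5", "10"), ("5", "15"), ("10", "15")]
    for t1, t2 in temp_pairs:
        grid.append(dict(name=f"temp_{t1}v{t2}_both", factor="temperature_C",
                         level1=t1, level2=t2, subset={"cultivation": "lab"}))
        for origin in ("Helgoland", "Spitsbergen"):
            grid.append(dict(name=f"temp_{t1}v{t2}_{origin}",
                             factor="temperature_C", level1=t1, level2=t2,
                             subset={"cultivation": "lab", "origin": origin}))
    for t in ("5", "10", "15"):
        grid.append(dict(name=f"origin_at_{t}C", factor="origin",
                         level1="Helgoland", level2="Spitsbergen",
                         subset={"cultivation": "lab", "temperature_C": t}))
    return grid


# ---------------------------------------------------------------------------
# GO enrichment


def fisher_go_enrichment(
    foreground_genes: Sequence[str],
    background_genes: Sequence[str],
    go_map: Mapping[str, Sequence[str]],
    alpha: float = ALPHA_SIGNIFICANCE,
) -> pd.DataFrame:
    """Classic one-sided Fisher enrichment of GO terms in a gene set.

    For every term annotated to at least one background gene, a 2x2 table
    (in/out foreground x has/hasn't term) is tested for enrichment
    (one-sided, greater), with BH adjustment across terms.  Terms absent
    from every gene are skipped.
    """
    fg = set(map(str, foreground_genes))
    bg = set(map(str, background_genes))
    if not bg:
        raise ValueError("background gene set is empty")
    if not fg <= bg:
        raise ValueError("foreground must be a subset of the background")
    terms: dict[str, set[str]] = {}
    for gene, gene_terms in go_map.items():
        if str(gene) not in bg:
            continue
        for term in gene_terms:
            terms.setdefault(term, set()).add(str(gene))
    rows = []
    n_fg, n_bg = len(fg), len(bg)
    for term, genes_with in sorted(terms.items()):
        a = len(fg & genes_with)                # fg with term
        b = n_fg - a                            # fg without
        c = len(genes_with) - a                 # bg-only with term
        d = (n_bg - n_fg) - c                   # bg-only without
        _, p = scipy.stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        rows.append({"go_term": term, "n_foreground": a,
                     "n_background": len(genes_with), "p": p})
    out = pd.DataFrame(rows, columns=["go_term", "n_foreground",
                                      "n_background", "p"])
    if len(out):
        out["padj"] = bh_adjust(out["p"].to_numpy())
        out["significant"] = out["padj"] < alpha
    else:
        out["padj"] = []
        out["significant"] = []
    return out
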