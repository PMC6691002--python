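"""Drought differential-expression stage.

Count filtering, median-of-ratios normalization, per-gene negative-binomial
likelihood-ratio tests with Benjamini-Hochberg FDR control, and expression
grouping by hierarchical clustering (manhattan distance, Ward.D2 linkage).

The DE model is a deliberately simple negative-binomial GLM: gene-wise
dispersion estimated by the method of moments on normalized counts (no
shrinkage, no outlier refitting), full mean model = sampling day plus
treatment plus treatment-specific day effects, reduced model = day only.
The LRT statistic 2*(llf_full - llf_reduced) is referred to a chi-square
with df equal to the parameter-count difference.  The reported log2 fold
change is drought versus control at the final sampling day (day 22 by
default).  This simplification relative to full DE packages is recorded in
the run metadata of every DE report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy
import scipy.spatial.distance
import scipy.stats
import statsmodels.api as sm

from .seqio import SampleSheet

log = logging.getLogger(__name__)

MODEL_NOTE = (
    "negative-binomial GLM LRT with method-of-moments gene-wise dispersion; "
    "no dispersion shrinkage, no outlier filtering"
)


@dataclass
class CountMatrix:
    """Non-negative integer counts, genes x libraries, with a sample sheet."""

    counts: pd.DataFrame
    sheet: SampleSheet

    def __post_init__(self) -> None:
        if list(self.counts.columns) != self.sheet.library_ids:
            if set(self.counts.columns) != set(self.sheet.library_ids):
                raise ValueError("count matrix columns do not match sample sheet")
            self.counts = self.counts[self.sheet.library_ids]
        arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise ValueError("negative counts")
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(int)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @classmethod
    def read_tsv(cls, counts_path: str | Path, sheet_path: str | Path) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        return cls(counts, SampleSheet.read_tsv(sheet_path))

    def write_tsv(self, counts_path: str | Path, sheet_path: str | Path | None = None) -> None:
        self.counts.to_csv(counts_path, sep="\t", index_label="gene_id")
        if sheet_path is not None:
            self.sheet.write_tsv(sheet_path)


def filter_low_counts(cm: CountMatrix, min_count: int = 5, min_libraries: int = 2) -> CountMatrix:
    """Keep genes with counts strictly greater than ``min_count`` in at
    least ``min_libraries`` libraries."""
    mask = (cm.counts > min_count).sum(axis=1) >= min_libraries
    kept = cm.counts.loc[mask]
    log.info("filter_low_counts: kept %d of %d genes", len(kept), len(cm.counts))
    return CountMatrix(kept, cm.sheet)


def size_factors(cm: CountMatrix) -> pd.Series:
    """Median-of-ratios library size factors.

    Reference = per-gene geometric mean over libraries, computed over
    genes with no zero count; s_j = median over those genes of
    count_ij / reference_i.
    """
    arr = cm.counts.to_numpy(dtype=float)
    nonzero = (arr > 0).all(axis=1)
    if not nonzero.any():
        raise ValueError("no gene is zero-free; cannot compute size factors")
    sub = arr[nonzero]
    log_geo = np.log(sub).mean(axis=1)
    sf = np.exp(np.median(np.log(sub) - log_geo[:, None], axis=0))
    return pd.Series(sf, index=cm.counts.columns, name="size_factor")


def normalized_counts(cm: CountMatrix, sf: pd.Series | None = None) -> pd.DataFrame:
    if sf is None:
        sf = size_factors(cm)
    return cm.counts / sf


# ---------------------------------------------------------------------------
# Design matrices

def _day_dummies(days: pd.Series, levels: Sequence[int]) -> np.ndarray:
    return np.column_stack([(days == d).astype(float) for d in levels[1:]])


def design_matrices(
    sheet: SampleSheet, genotype_covariate: bool = False
) -> tuple[np.ndarray, np.ndarray, list[str], list[int]]:
    """Full and reduced design matrices for the drought LRT.

    Full: intercept + day + treatment + treatment:day (treatment-specific
    day effects).  Reduced: intercept + day.  With
    ``genotype_covariate=True`` genotype main effects are added to both
    models (and cancel in the LRT df).
    """
    t = sheet.table
    days = sorted(t["day"].unique())
    drought = (t["treatment"] == "drought").astype(float).to_numpy()
    day_cols = _day_dummies(t["day"], days)
    cols_reduced = [np.ones(len(t)), *day_cols.T]
    names_reduced = ["intercept"] + [f"day{d}" for d in days[1:]]
    if genotype_covariate:
        genotypes = sorted(t["genotype"].unique())
        for g in genotypes[1:]:
            cols_reduced.append((t["genotype"] == g).astype(float).to_numpy())
            names_reduced.append(f"genotype{g}")
    X_reduced = np.column_stack(cols_reduced)
    trt_day = day_cols * drought[:, None]
    X_full = np.column_stack([X_reduced, drought, trt_day])
    names_full = names_reduced + ["drought"] + [f"drought:day{d}" for d in days[1:]]
    return X_full, X_reduced, names_full, days


@dataclass(frozen=True)
class DEResult:
    gene_id: str
    log2_fold_change: float
    lrt_statistic: float
    df: int
    pvalue: float
    padj: float
    status: str  # up / down / ns


def moment_dispersion(y: np.ndarray, sf: np.ndarray, floor: float = 1e-8) -> float:
    """Method-of-moments NB dispersion alpha from normalized counts."""
    z = y / sf
    m = z.mean()
    if m <= 0:
        return floor
    v = z.var(ddof=1)
    return max((v - m) / (m * m), floor)


def _fit_glm(y, X, alpha, offset):
    model = sm.GLM(y, X, family=sm.families.NegativeBinomial(alpha=alpha), offset=offset)
    return model.fit(maxiter=200, tol=1e-8)


def nb_lrt(
    cm: CountMatrix,
    sf: pd.Series | None = None,
    genotype_covariate: bool = False,
    fdr: float = 0.05,
    lfc_day: int | None = None,
) -> pd.DataFrame:
    """Per-gene negative-binomial LRT for a treatment effect.

    Returns a DataFrame indexed by gene with log2 fold change (drought vs
    control at ``lfc_day``, default the last sampling day), the LRT
    statistic, raw and BH-adjusted p-values and an up/down/ns status at
    ``padj < fdr``.  Genes whose GLM fails to converge are reported with
    NaN statistics and excluded from the FDR adjustment; all-zero genes
    are excluded with a log entry.
    """
    if sf is None:
        sf = size_factors(cm)
    sf_arr = sf.to_numpy(dtype=float)
    offset = np.log(sf_arr)
    X_full, X_reduced, names_full, days = design_matrices(cm.sheet, genotype_covariate)
    df_diff = X_full.shape[1] - X_reduced.shape[1]
    if lfc_day is None:
        lfc_day = days[-1]
    i_drought = names_full.index("drought")
    i_inter = names_full.index(f"drought:day{lfc_day}") if lfc_day != days[0] else None

    rows = []
    skipped_zero = 0
    failed = 0
    for gene, y in cm.counts.iterrows():
        y = y.to_numpy(dtype=float)
        if y.sum() == 0:
            skipped_zero += 1
            continue
        alpha = moment_dispersion(y, sf_arr)
        try:
            fit_full = _fit_glm(y, X_full, alpha, offset)
            fit_reduced = _fit_glm(y, X_reduced, alpha, offset)
            stat = max(2.0 * (fit_full.llf - fit_reduced.llf), 0.0)
            p = float(scipy.stats.chi2.sf(stat, df_diff))
            log_fc = fit_full.params[i_drought]
            if i_inter is not None:
                log_fc = log_fc + fit_full.params[i_inter]
            l2fc = float(log_fc / np.log(2.0))
        except Exception as exc:  # non-convergence, separation, etc.
            log.warning("nb_lrt: gene %s failed (%s)", gene, exc)
            failed += 1
            rows.append((gene, np.nan, np.nan, df_diff, np.nan))
            continue
        rows.append((gene, l2fc, float(stat), df_diff, p))
    if skipped_zero:
        log.info("nb_lrt: excluded %d all-zero genes", skipped_zero)
    if failed:
        log.info("nb_lrt: %d genes failed to converge", failed)

    out = pd.DataFrame(
        rows, columns=["gene_id", "log2_fold_change", "lrt_statistic", "df", "pvalue"]
    ).set_index("gene_id")
    tested = out["pvalue"].notna()
    out["padj"] = np.nan
    out.loc[tested, "padj"] = bh_adjust(out.loc[tested, "pvalue"].to_numpy())
    out["status"] = "ns"
    sig = out["padj"] < fdr
    out.loc[sig & (out["log2_fold_change"] > 0), "status"] = "up"
    out.loc[sig & (out["log2_fold_change"] < 0), "status"] = "down"
    out.attrs["model"] = MODEL_NOTE
    out.attrs["lfc_day"] = lfc_day
    return out


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


# ---------------------------------------------------------------------------
# Expression grouping

@dataclass(frozen=True)
class ExpressionGroup:
    index: int
    gene_ids: tuple[str, ...]
    mean_profile: np.ndarray = field(compare=False)


def expression_profiles(
    gene_ids: Sequence[str], cm: CountMatrix, sf: pd.Series | None = None
) -> pd.DataFrame:
    """Per-gene z-scored log2(normalized count + 1) profiles."""
    norm = normalized_counts(cm, sf).loc[list(gene_ids)]
    logc = np.log2(norm + 1.0)
    mu = logc.mean(axis=1)
    sd = logc.std(axis=1, ddof=0).replace(0.0, 1.0)
    return logc.sub(mu, axis=0).div(sd, axis=0)


def expression_groups(
    gene_ids: Sequence[str],
    cm: CountMatrix,
    sf: pd.Series | None = None,
    k: int = 14,
) -> list[ExpressionGroup]:
    """Cut a manhattan/Ward.D2 dendrogram of DE-gene profiles into k groups.

    scipy's 'ward' linkage on a precomputed condensed distance matrix
    implements the Ward.D2 criterion (distances are squared inside the
    Lance-Williams update).  Group indices 1..k are assigned in order of
    first appearance in the input, so the partition is stable under
    permutation of the gene list up to relabeling.
    """
    gene_ids = list(gene_ids)
    if not gene_ids:
        return []
    k = min(k, len(gene_ids))
    profiles = expression_profiles(gene_ids, cm, sf)
    if len(gene_ids) == 1:
        return [ExpressionGroup(1, (gene_ids[0],), profiles.to_numpy()[0])]
    condensed = scipy.spatial.distance.pdist(profiles.to_numpy(), metric="cityblock")
    linkage = scipy.cluster.hierarchy.linkage(condensed, method="ward")
    labels = scipy.cluster.hierarchy.fcluster(linkage, t=k, criterion="maxclust")
    # relabel deterministically by first appearance
    relabel: dict[int, int] = {}
    for lab in labels:
        if lab not in relabel:
            relabel[lab] = len(relabel) + 1
    groups: dict[int, list[str]] = {}
    for gene, lab in zip(gene_ids, labels):
        groups.setdefault(relabel[lab], []).append(gene)
    return [
        ExpressionGroup(
            idx,
            tuple(members),
            profiles.loc[members].mean(axis=0).to_numpy(),
        )
        for idx, members in sorted(groups.items())
    ]


def subfamily_de_summary(de: pd.DataFrame, categories: pd.Series) -> pd.DataFrame:
    """Per-subfamily DE summary: counts, direction and log2FC range.

    ``categories`` maps gene id -> subfamily category.  Only genes with a
    non-ns status count as DE.
    """
    de_genes = de[de["status"] != "ns"]
    if de_genes.empty:
        return pd.DataFrame(
            columns=["n_de", "n_up", "n_down", "log2fc_min", "log2fc_max", "up_fraction"]
        )
    cats = categories.reindex(de_genes.index).fillna("UNDETERMINED")
    rows = {}
    for cat, sub in de_genes.groupby(cats):
        n_up = int((sub["status"] == "up").sum())
        n_down = int((sub["status"] == "down").sum())
        rows[cat] = {
            "n_de": len(sub),
            "n_up": n_up,
            "n_down": n_down,
            "log2fc_min": float(sub["log2_fold_change"].min()),
            "log2fc_max": float(sub["log2_fold_change"].max()),
            "up_fraction": n_up / len(sub),
        }
    return pd.DataFrame.from_dict(rows, orient="index").sort_index()
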