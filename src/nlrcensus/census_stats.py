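"""Per-species category census and cross-species statistics.

Builds the architecture-by-species census table (counts of full and
truncated CNL/CNL2/RNL/TNL forms plus atypical and undetermined NLRs),
derives transcriptome ratios and the cross-species subfamily distribution,
and provides the chi-square homogeneity test and the RNL-versus-TNL
ordinary-least-squares regression used to compare repertoires across
species.

Rounding follows the census table's printed convention: half-up, two
decimals for ratios (percent of the assembled transcriptome) and integer
for the distribution (percent of all assigned sequences across species).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .classify import SubfamilyCall, architecture_row

#: Census architecture rows in table order, grouped by subfamily.
ROWS_CNL = ("NB_CNL-(LRR)",)
ROWS_CNL2 = ("NB_CNL2-(LRR)",)
ROWS_RNL = ("RPW8", "NB_RNL-(LRR)", "RPW8-NB_RNL-(LRR)")
ROWS_TNL = ("TIR", "NB_TNL-(LRR)", "TIR-NB_TNL-(LRR)", "TIR-LRR")
ROWS_OTHER = ("Atypical", "Undetermined")
ALL_ROWS = ROWS_CNL + ROWS_CNL2 + ROWS_RNL + ROWS_TNL + ROWS_OTHER

SUBFAMILY_ROWS = {
    "CNL": ROWS_CNL,
    "CNL2": ROWS_CNL2,
    "RNL": ROWS_RNL,
    "TNL": ROWS_TNL,
}


def round_half_up(value: float, decimals: int = 0) -> float:
    """Decimal half-up rounding (2.5 -> 3), as printed census tables use."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def nlr_ratio(count: int, transcriptome_size: int, decimals: int = 2) -> float:
    """Percent of the assembled transcriptome, half-up rounded."""
    if transcriptome_size <= 0:
        raise ValueError("transcriptome size must be positive")
    return round_half_up(100.0 * count / transcriptome_size, decimals)


@dataclass
class CensusTable:
    """Architecture-row counts per species plus transcriptome sizes."""

    counts: pd.DataFrame             # rows = ALL_ROWS, columns = species
    transcriptome_sizes: pd.Series   # per species

    def __post_init__(self) -> None:
        self.counts = self.counts.reindex(ALL_ROWS).fillna(0).astype(int)
        self.transcriptome_sizes = self.transcriptome_sizes.reindex(
            self.counts.columns
        )

    @property
    def species(self) -> list[str]:
        return list(self.counts.columns)

    def subfamily_totals(self, species: str | None = None) -> pd.Series:
        """CNL/CNL2/RNL/TNL totals, truncated forms included."""
        frames = {}
        for fam, rows in SUBFAMILY_ROWS.items():
            sub = self.counts.loc[list(rows)]
            frames[fam] = sub[species].sum() if species else sub.sum(axis=1).sum()
        return pd.Series(frames)

    def total_nlr(self, species: str) -> int:
        return int(self.counts[species].sum())

    def ratios(self, species: str) -> dict[str, float]:
        """Transcriptome ratios (%) for total NLR and each subfamily."""
        size = int(self.transcriptome_sizes[species])
        out = {"TOTAL": nlr_ratio(self.total_nlr(species), size)}
        for fam in SUBFAMILY_ROWS:
            out[fam] = nlr_ratio(int(self.subfamily_totals(species)[fam]), size)
        return out

    def distribution(self) -> dict[str, int]:
        """Subfamily distribution (%) over assigned sequences, all species.

        Assigned = CNL + CNL2 + RNL-related + TNL-related (atypical and
        undetermined excluded); percentages half-up rounded to integer.
        """
        totals = self.subfamily_totals()
        grand = totals.sum()
        if grand == 0:
            return {fam: 0 for fam in SUBFAMILY_ROWS}
        return {
            fam: int(round_half_up(100.0 * totals[fam] / grand))
            for fam in SUBFAMILY_ROWS
        }

    def to_frame(self) -> pd.DataFrame:
        """Full report table with derived totals, ratios and distribution."""
        df = self.counts.copy().astype(object)
        dist = self.distribution()
        df["Dist_pct"] = ""
        for fam, rows in SUBFAMILY_ROWS.items():
            df.loc[rows[0], "Dist_pct"] = dist[fam]
        header = pd.DataFrame(
            [self.transcriptome_sizes.tolist() + [""]],
            index=["transcriptome_size"], columns=df.columns,
        )
        totals = pd.DataFrame(
            [[self.total_nlr(s) for s in self.species] + [""]],
            index=["TOTAL_NLR"], columns=df.columns,
        )
        ratios = pd.DataFrame(
            [[self.ratios(s)["TOTAL"] for s in self.species] + [""]],
            index=["Ratio_pct"], columns=df.columns,
        )
        return pd.concat([header, totals, ratios, df])

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="row")


def build_census(
    calls_per_species: Mapping[str, Sequence[SubfamilyCall]],
    transcriptome_sizes: Mapping[str, int],
) -> CensusTable:
    """Tabulate classification calls into the census layout.

    EXCLUDED calls are not part of the census (they are not NLRs).
    """
    species = list(calls_per_species)
    counts = pd.DataFrame(0, index=list(ALL_ROWS), columns=species)
    for sp, calls in calls_per_species.items():
        for call in calls:
            row = architecture_row(call)
            if row is not None:
                counts.loc[row, sp] += 1
    return CensusTable(counts, pd.Series({s: transcriptome_sizes[s] for s in species}))


def build_census_from_counts(
    counts: pd.DataFrame, transcriptome_sizes: pd.Series
) -> CensusTable:
    return CensusTable(counts, transcriptome_sizes)


def load_table1_fixture() -> CensusTable:
    """The packaged seven-conifer census count fixture."""
    source = importlib.resources.files("nlrcensus.data") / "table1_conifer_nlr_census.tsv"
    with importlib.resources.as_file(source) as path:
        df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    sizes = df.loc["transcriptome_size"]
    counts = df.drop(index="transcriptome_size")
    return CensusTable(counts, sizes)


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    pvalue: float
    observed: pd.DataFrame
    expected: pd.DataFrame


def chi_square_homogeneity(table: pd.DataFrame) -> ChiSquareResult:
    """Pearson chi-square of homogeneity, no continuity correction.

    Rows are species, columns are categories.  Degenerate tables (any
    expected cell zero) are rejected.
    """
    observed = table.astype(float)
    if (observed.sum(axis=1) == 0).any() or (observed.sum(axis=0) == 0).any():
        raise ValueError("degenerate table: a row or column sums to zero")
    stat, p, df, expected = scipy.stats.chi2_contingency(
        observed.to_numpy(), correction=False
    )
    return ChiSquareResult(
        statistic=float(stat),
        df=int(df),
        pvalue=float(p),
        observed=observed,
        expected=pd.DataFrame(expected, index=observed.index, columns=observed.columns),
    )


@dataclass(frozen=True)
class RegressionResult:
    n: int
    slope: float
    intercept: float
    r_squared: float
    f_statistic: float
    df: tuple[int, int]
    pvalue: float


def ols_regression(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """OLS of y on x with intercept; F-test on (1, n-2) degrees of freedom."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 points")
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    return RegressionResult(
        n=n,
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        r_squared=float(fit.rsquared),
        f_statistic=float(fit.fvalue),
        df=(1, n - 2),
        pvalue=float(fit.f_pvalue),
    )
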