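"""Roll-up summaries and cross-mutant dependence analysis.

Contingency tables of per-site behaviour across two classifications (e.g.
two editing-factor mutants) are tested for independence with the Pearson
chi-square; standardized residuals (O−E)/sqrt(E) locate the cells driving a
significant statistic.  Printed percentages use half-away-from-zero rounding.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ArgumentError, InputError

logger = logging.getLogger(__name__)

DEFAULT_CATEGORIES = ("increased", "decreased", "invariant")


def round_percent(numerator: int, denominator: int) -> int:
    """Integer percentage with half-away-from-zero rounding, computed in
    exact rational arithmetic (79/576 -> 14, 83/86 -> 97)."""
    if denominator <= 0:
        raise ArgumentError("denominator must be positive")
    if numerator < 0:
        raise ArgumentError("numerator must be non-negative")
    frac = Fraction(100 * numerator, denominator)
    return int(math.floor(frac + Fraction(1, 2)))


@dataclass
class ContingencyResult:
    """Chi-square independence test on a labelled contingency table."""

    observed: pd.DataFrame
    expected: pd.DataFrame
    statistic: float
    df: int
    pvalue: float
    residuals: pd.DataFrame  # standardized (O-E)/sqrt(E)

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "df": self.df,
            "pvalue": self.pvalue,
            "observed": {r: self.observed.loc[r].to_dict()
                         for r in self.observed.index},
            "expected": {r: self.expected.loc[r].round(4).to_dict()
                         for r in self.expected.index},
            "residuals": {r: self.residuals.loc[r].round(4).to_dict()
                          for r in self.residuals.index},
        }


def contingency_table(class_a: pd.Series, class_b: pd.Series,
                      categories_a: tuple[str, ...] = DEFAULT_CATEGORIES,
                      categories_b: tuple[str, ...] = DEFAULT_CATEGORIES,
                      ) -> pd.DataFrame:
    """Cross-tabulate two per-site category series over their shared site
    universe.  Cell (i, j) counts sites in category i under A and j under B;
    sites falling outside either category list (e.g. not_assayed) are
    dropped from the co-classified universe."""
    if set(class_a.index) != set(class_b.index):
        raise InputError("classifications cover different site sets")
    if len(set(categories_a)) != len(categories_a) \
            or len(set(categories_b)) != len(categories_b):
        raise InputError("category lists must not overlap themselves")
    class_b = class_b.reindex(class_a.index)
    mask = class_a.isin(categories_a) & class_b.isin(categories_b)
    table = pd.crosstab(class_a[mask], class_b[mask])
    table = table.reindex(index=list(categories_a),
                          columns=list(categories_b), fill_value=0)
    table.index.name = "A"
    table.columns.name = "B"
    return table


def collapse_to_affected(table: pd.DataFrame) -> pd.DataFrame:
    """2x2 collapse of a 3x3 dependence table: affected (increased or
    decreased) vs invariant on each axis."""
    aff_r = [r for r in ("increased", "decreased") if r in table.index]
    aff_c = [c for c in ("increased", "decreased") if c in table.columns]
    out = pd.DataFrame(
        [[table.loc[aff_r, aff_c].to_numpy().sum(),
          table.loc[aff_r, ["invariant"]].to_numpy().sum()],
         [table.loc[["invariant"], aff_c].to_numpy().sum(),
          int(table.loc["invariant", "invariant"])]],
        index=["affected", "invariant"], columns=["affected", "invariant"])
    out.index.name, out.columns.name = table.index.name, table.columns.name
    return out.astype(int)


def chisq_independence(table: pd.DataFrame) -> ContingencyResult:
    """Pearson chi-square test of independence with standardized residuals.

    Zero-marginal rows/columns carry no information and are dropped with a
    warning; a table degenerate after dropping returns statistic 0, p 1.
    """
    obs = table.astype(float)
    row_keep = obs.sum(axis=1) > 0
    col_keep = obs.sum(axis=0) > 0
    if not row_keep.all() or not col_keep.all():
        logger.warning("dropping zero-marginal rows %s / columns %s",
                       list(obs.index[~row_keep]), list(obs.columns[~col_keep]))
        obs = obs.loc[row_keep, col_keep]
    if obs.shape[0] < 2 or obs.shape[1] < 2:
        empty = pd.DataFrame(np.zeros_like(obs), index=obs.index,
                             columns=obs.columns)
        return ContingencyResult(observed=table.astype(int), expected=obs,
                                 statistic=0.0, df=0, pvalue=1.0,
                                 residuals=empty)
    stat, p, df, expected = stats.chi2_contingency(obs.to_numpy(),
                                                   correction=False)
    expected = pd.DataFrame(expected, index=obs.index, columns=obs.columns)
    residuals = (obs - expected) / np.sqrt(expected)
    return ContingencyResult(observed=obs.astype(int), expected=expected,
                             statistic=float(stat), df=int(df),
                             pvalue=float(p), residuals=residuals)


def per_transcript_summary(classification: pd.DataFrame,
                           annotation: pd.DataFrame) -> pd.DataFrame:
    """Affected-site counts and percentages per transcript.

    ``classification`` needs a ``category`` column indexed by site_id;
    ``annotation`` supplies transcript and complex_group.  Transcripts with
    mixed responses report both directions.  The percentage is of affected
    (increased + decreased) among assayed sites on the transcript.
    """
    cat = classification["category"]
    missing = set(cat.index) - set(annotation.index)
    if missing:
        raise InputError(f"sites without annotation: {sorted(missing)[:5]} ...")
    joined = pd.DataFrame({
        "category": cat,
        "transcript": annotation.loc[cat.index, "transcript"],
        "complex_group": annotation.loc[cat.index, "complex_group"]
        if "complex_group" in annotation.columns else "",
    })
    rows = []
    for transcript, grp in joined.groupby("transcript", sort=True):
        assayed = grp[grp["category"] != "not_assayed"]
        n_inc = int((assayed["category"] == "increased").sum())
        n_dec = int((assayed["category"] == "decreased").sum())
        n = len(assayed)
        rows.append({
            "transcript": transcript,
            "complex_group": grp["complex_group"].iloc[0],
            "n_sites": int(len(grp)),
            "n_assayed": n,
            "n_increased": n_inc,
            "n_decreased": n_dec,
            "pct_affected": round_percent(n_inc + n_dec, n) if n else 0,
            "pct_increased": round_percent(n_inc, n) if n else 0,
            "pct_decreased": round_percent(n_dec, n) if n else 0,
        })
    return pd.DataFrame(rows).set_index("transcript")


def complex_group_summary(per_transcript: pd.DataFrame) -> pd.DataFrame:
    """Roll the per-transcript table up by the complex each transcript
    encodes (complex I..V, cytochrome c biogenesis, ribosome, ...)."""
    grouped = per_transcript.groupby("complex_group")[
        ["n_sites", "n_assayed", "n_increased", "n_decreased"]].sum()
    grouped["pct_affected"] = [
        round_percent(int(r.n_increased + r.n_decreased), int(r.n_assayed))
        if r.n_assayed else 0 for r in grouped.itertuples()]
    return grouped
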