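"""Transgenic complementation analysis.

A transgenic line (a single plant carrying the rescue construct in a mutant
background) is tested site by site against each replicate of its background
mutant with the same 2x2 chi-square and thresholds used for the
mutant-vs-wildtype contrast; every pairwise test must pass.  A site
*responds* when it is significant, the extent change |Δ_T| reaches the
effect floor, and the change runs in the expected direction — opposite to
the mutant's defect (sites increased in the mutant should decrease in the
transgenic, and vice versa).

The complementation effect normalises the transgenic-vs-mutant change to the
wildtype-vs-mutant gap:

    CE = (E_T − E_M) / (E_WT − E_M)

CE = 1 is full rescue to the wild-type level, CE = 0 no rescue, CE > 1 a
transgressive overshoot (typical under strong-promoter overexpression).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .differential import (DifferentialEditingResults, TestConfig,
                           _pearson_2x2, chisq_2x2)
from .errors import ArgumentError, DesignError, InputError
from .quant import EditingMatrix
from .summaries import round_percent

DIRECTIONS = ("decrease", "increase")


def expected_direction(mutant_category: str) -> str:
    """Direction a mutant-affected site should move in a rescued line:
    increased -> decrease, decreased -> increase."""
    if mutant_category == "increased":
        return "decrease"
    if mutant_category == "decreased":
        return "increase"
    raise ArgumentError(
        f"no expected direction for category {mutant_category!r}; "
        "invariant sites are handled by invariant_site_response")


def complementation_effect(e_t: float, e_m: float, e_wt: float) -> float:
    """(E_T − E_M) / (E_WT − E_M); NaN when the wild type and mutant do not
    differ (the site was not differentially edited, so the normalisation is
    undefined)."""
    if e_wt == e_m:
        return math.nan
    return (e_t - e_m) / (e_wt - e_m)


def transgenic_site_test(tg_counts: tuple[int, int],
                         mut_counts: Sequence[tuple[int, int]],
                         config: TestConfig = TestConfig(),
                         ) -> tuple[list[float] | None, float]:
    """P-values of the transgenic sample against each background-mutant
    replicate, plus Δ_T = extent(transgenic) − pooled mutant extent.

    Returns (None, NaN) when any involved sample fails the depth floor.
    """
    te, tu = tg_counts
    if te + tu < config.min_depth or te + tu == 0:
        return None, math.nan
    for me, mu in mut_counts:
        if me + mu < config.min_depth or me + mu == 0:
            return None, math.nan
    pvals = [chisq_2x2(te, tu, me, mu,
                       continuity=config.continuity_correction)[1]
             for me, mu in mut_counts]
    pooled_me = sum(e for e, _ in mut_counts)
    pooled_mu = sum(u for _, u in mut_counts)
    delta_t = te / (te + tu) - pooled_me / (pooled_me + pooled_mu)
    return pvals, delta_t


class ComplementationAnalysis:
    """Site-level rescue analysis for transgenic lines.

    Parameters
    ----------
    matrix : EditingMatrix
        Counts including transgenic, mutant and wildtype samples.
    mutant_results : DifferentialEditingResults
        The mutant-vs-wildtype classification providing each site's category
        (hence the expected rescue direction).
    transgenics : sequence of str
        Sample ids of the transgenic lines (each a single plant).
    config : TestConfig, optional; defaults to the configuration of
        ``mutant_results`` so the same nominal threshold applies.
    """

    def __init__(self, matrix: EditingMatrix,
                 mutant_results: DifferentialEditingResults,
                 transgenics: Sequence[str],
                 config: TestConfig | None = None):
        self.matrix = matrix
        self.mutant_results = mutant_results
        missing = [t for t in transgenics if t not in set(matrix.sample_ids)]
        if missing:
            raise DesignError(f"transgenic samples not in matrix: {missing}")
        self.transgenics = list(transgenics)
        self.config = config or mutant_results.config

    def fit(self) -> "ComplementationResults":
        cfg = self.config
        m = self.matrix
        res = self.mutant_results
        mut_cols = res.mut_samples or m.samples_of(res.mutant)
        wt_cols = res.wt_samples or m.samples_of(res.wildtype)
        alpha = res.alpha_nominal

        E = m.edited
        U = m.unedited
        dep = m.depth()
        sites = m.site_ids
        categories = res.table["category"].reindex(sites)

        # pooled mutant / wildtype extents per site
        me = E[mut_cols].sum(axis=1).to_numpy(dtype=float)
        mu = U[mut_cols].sum(axis=1).to_numpy(dtype=float)
        we = E[wt_cols].sum(axis=1).to_numpy(dtype=float)
        wu = U[wt_cols].sum(axis=1).to_numpy(dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            e_m = me / (me + mu)
            e_wt = we / (we + wu)

        records = []
        for tg in self.transgenics:
            te = E[tg].to_numpy(dtype=float)
            tu = U[tg].to_numpy(dtype=float)
            assayed = (te + tu >= max(cfg.min_depth, 1))
            for col in mut_cols:
                assayed &= dep[col].to_numpy() >= max(cfg.min_depth, 1)
            pvals = np.stack([
                _pearson_2x2(te, tu, E[col].to_numpy(dtype=float),
                             U[col].to_numpy(dtype=float),
                             continuity=cfg.continuity_correction)[1]
                for col in mut_cols])
            with np.errstate(invalid="ignore", divide="ignore"):
                e_t = te / (te + tu)
            delta_t = e_t - e_m
            all_sig = (pvals < alpha).all(axis=0)
            significant = all_sig & (np.abs(delta_t) >= cfg.min_delta) & assayed
            with np.errstate(invalid="ignore", divide="ignore"):
                ce = np.where(e_wt != e_m, (e_t - e_m) /
                              np.where(e_wt != e_m, e_wt - e_m, 1.0), np.nan)
            rec = pd.DataFrame({
                "site_id": sites,
                "transgenic_id": tg,
                "category_mutant": categories.to_numpy(),
                "delta_T": np.where(assayed, delta_t, np.nan),
                "significant": significant,
                "complementation_effect": np.where(assayed, ce, np.nan),
                "assayed": assayed,
            })
            for k in range(pvals.shape[0]):
                rec[f"p{k + 1}"] = np.where(assayed, pvals[k], np.nan)
            exp = rec["category_mutant"].map(
                {"increased": "decrease", "decreased": "increase"})
            rec["expected_direction"] = exp
            moved = np.where(rec["delta_T"] > 0, "increase",
                             np.where(rec["delta_T"] < 0, "decrease", "none"))
            rec["responded"] = (rec["significant"]
                                & exp.notna() & (moved == exp))
            rec["transgressive"] = rec["responded"] \
                & (rec["complementation_effect"] > 1.0)
            records.append(rec)
        table = pd.concat(records, ignore_index=True)
        return ComplementationResults(table=table, mutant_results=res,
                                      transgenics=self.transgenics,
                                      config=cfg, alpha_nominal=alpha)


@dataclass
class ComplementationResults:
    table: pd.DataFrame
    mutant_results: DifferentialEditingResults
    transgenics: list[str]
    config: TestConfig
    alpha_nominal: float

    def _affected(self) -> pd.Index:
        cat = self.mutant_results.table["category"]
        return cat.index[cat.isin(["increased", "decreased"])]

    def _responded_count(self, site_ids: pd.Index) -> pd.Series:
        """Number of transgenic lines in which each site responded."""
        sub = self.table[self.table["site_id"].isin(site_ids)]
        return (sub.groupby("site_id")["responded"].sum()
                .reindex(site_ids, fill_value=0))

    def complementation_summary(self) -> dict:
        """Both / only-one / neither partition of the mutant-affected sites,
        per direction and combined, with rounded percentage fractions.

        Requires two transgenic lines for the three-way partition; with one
        line a reduced {responded, not} partition is returned with a note.
        """
        out: dict = {"transgenics": list(self.transgenics)}
        reduced = len(self.transgenics) < 2
        if reduced:
            out["note"] = ("fewer than two transgenic lines: reduced "
                           "partition {responded, not_responded}")
        mcat = self.mutant_results.table["category"]
        strata: dict[str, pd.Index] = {
            "increased": mcat.index[mcat == "increased"],
            "decreased": mcat.index[mcat == "decreased"],
            "combined": self._affected(),
        }
        for name, ids in strata.items():
            n = len(ids)
            entry: dict = {"n_sites": n}
            if n:
                k = self._responded_count(ids)
                if reduced:
                    entry["responded"] = int((k >= 1).sum())
                    entry["not_responded"] = int((k == 0).sum())
                    entry["pct_responded"] = round_percent(entry["responded"], n)
                else:
                    entry["both"] = int((k >= 2).sum())
                    entry["only_one"] = int((k == 1).sum())
                    entry["neither"] = int((k == 0).sum())
                    entry["pct_both"] = round_percent(entry["both"], n)
                    entry["pct_at_least_one"] = round_percent(
                        entry["both"] + entry["only_one"], n)
            out[name] = entry
        return out

    def invariant_site_response(self) -> dict:
        """Among sites invariant in the mutant, count those significantly
        moved in the transgenics (same thresholds), by direction, stratified
        by whether one or both lines moved them."""
        mcat = self.mutant_results.table["category"]
        inv = mcat.index[mcat == "invariant"]
        sub = self.table[self.table["site_id"].isin(inv)].copy()
        sub["direction"] = np.where(sub["delta_T"] > 0, "increase", "decrease")
        hit = sub[sub["significant"]]
        per_site = hit.groupby("site_id").agg(
            n_lines=("transgenic_id", "nunique"),
            directions=("direction", lambda d: set(d)))
        out = {
            "n_invariant": int(len(inv)),
            "n_affected_any": int(len(per_site)),
            "n_affected_both": int((per_site["n_lines"] >= 2).sum()),
            "n_affected_one": int((per_site["n_lines"] == 1).sum()),
            "decrease": int(per_site["directions"]
                            .apply(lambda s: s == {"decrease"}).sum()),
            "increase": int(per_site["directions"]
                            .apply(lambda s: s == {"increase"}).sum()),
            "mixed": int(per_site["directions"]
                         .apply(lambda s: len(s) > 1).sum()),
        }
        return out

    def summary(self) -> str:
        s = self.complementation_summary()
        lines = [f"Complementation: {', '.join(self.transgenics)} vs "
                 f"{self.mutant_results.mutant} "
                 f"(alpha {self.alpha_nominal:.3g})"]
        for name in ("increased", "decreased", "combined"):
            e = s.get(name, {})
            if not e.get("n_sites"):
                continue
            if "both" in e:
                lines.append(
                    f"  {name}: {e['n_sites']} sites — both {e['both']} "
                    f"({e['pct_both']}%), one {e['only_one']}, "
                    f"neither {e['neither']}")
            else:
                lines.append(f"  {name}: {e['n_sites']} sites — responded "
                             f"{e['responded']} ({e['pct_responded']}%)")
        inv = self.invariant_site_response()
        lines.append(f"  invariant sites newly affected: {inv['n_affected_any']}"
                     f" (decrease {inv['decrease']}, increase {inv['increase']})")
        return "\n".join(lines)

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)
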