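"""Differential-editing classification between wild-type and mutant.

The test of record is deliberately conservative: for a site to be called, the
2x2 Pearson chi-square (1 df) on (edited, unedited) counts must be significant
for *every* wildtype-replicate x mutant-replicate pair — four tests in the
standard two-replicate design — each at a Bonferroni-style nominal level
``alpha_family / n_tests`` (1e-3 / 612 sites ≈ 1.6e-6 in the reference
design), and in addition the editing-extent difference Δ (mutant − wildtype)
must reach the effect floor |Δ| >= 0.1.  Sites passing with Δ >= +0.1 are
``increased``, with Δ <= −0.1 ``decreased``, all others ``invariant``;
sites with insufficient depth in any replicate are ``not_assayed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import annotation as ann
from .errors import ArgumentError, DesignError, InputError
from .quant import EditingMatrix

CATEGORIES = ("increased", "decreased", "invariant", "not_assayed")
DELTA_MODES = ("pooled", "mean")


def bonferroni_threshold(alpha_family: float, n_tests: int) -> float:
    """Nominal per-test error rate achieving the desired family-wise rate
    over ``n_tests`` sites: ``alpha_family / n_tests``."""
    if not 0.0 < alpha_family < 1.0:
        raise ArgumentError("alpha_family must be in (0, 1)")
    if n_tests < 1:
        raise ArgumentError("n_tests must be >= 1")
    return alpha_family / n_tests


@dataclass(frozen=True)
class TestConfig:
    """Thresholds for the differential-editing test.

    ``n_tests`` sets the Bonferroni divisor; ``None`` means "the number of
    assayed sites in the current run" and is resolved at fit time.
    ``alpha_nominal`` overrides the derived threshold when set explicitly.
    """

    alpha_family: float = 1e-3
    n_tests: int | None = None
    alpha_nominal: float | None = None
    min_delta: float = 0.1
    min_depth: int = 100
    continuity_correction: bool = False
    delta_mode: str = "pooled"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha_family < 1.0:
            raise ArgumentError("alpha_family must be in (0, 1)")
        if not 0.0 < self.min_delta < 1.0:
            raise ArgumentError("min_delta must be in (0, 1)")
        if self.min_depth < 0:
            raise ArgumentError("min_depth must be >= 0")
        if self.delta_mode not in DELTA_MODES:
            raise ArgumentError(f"delta_mode must be one of {DELTA_MODES}")

    def nominal_alpha(self, n_assayed: int | None = None) -> float:
        """Resolve the per-test threshold, preferring an explicit override,
        then an explicit ``n_tests``, then the assayed-site count."""
        if self.alpha_nominal is not None:
            return self.alpha_nominal
        n = self.n_tests if self.n_tests is not None else n_assayed
        if n is None:
            raise ArgumentError(
                "n_tests unset and no assayed-site count supplied")
        return bonferroni_threshold(self.alpha_family, n)


# ---------------------------------------------------------------------------
# the 2x2 chi-square

def _pearson_2x2(e1, u1, e2, u2, continuity: bool = False):
    """Vectorised Pearson statistic for tables [[e1,u1],[e2,u2]] using the
    closed form N(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d)); Yates-adjusted when
    ``continuity``.  Degenerate margins give statistic 0 / p 1."""
    a = np.asarray(e1, dtype=float)
    b = np.asarray(u1, dtype=float)
    c = np.asarray(e2, dtype=float)
    d = np.asarray(u2, dtype=float)
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    det = a * d - b * c
    if continuity:
        adj = np.maximum(np.abs(det) - n / 2.0, 0.0)
        num = n * adj * adj
    else:
        num = n * det * det
    with np.errstate(invalid="ignore", divide="ignore"):
        stat = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)
    p = stats.chi2.sf(stat, df=1)
    p = np.where(denom > 0, p, 1.0)
    return stat, p


def chisq_2x2(e1: int, u1: int, e2: int, u2: int,
              continuity: bool = False) -> tuple[float, float]:
    """Pearson chi-square (1 df) comparing two (edited, unedited) pairs.

    A zero row or column margin carries no evidence of a difference and is
    returned as (statistic 0, p 1).
    """
    for v in (e1, u1, e2, u2):
        if v < 0:
            raise ArgumentError("cell counts must be non-negative")
    stat, p = _pearson_2x2(e1, u1, e2, u2, continuity=continuity)
    return float(stat), float(p)


# ---------------------------------------------------------------------------
# scalar (per-site) operations

def replicate_pvalues(wt_counts: Sequence[tuple[int, int]],
                      mut_counts: Sequence[tuple[int, int]],
                      config: TestConfig = TestConfig()) -> list[float] | None:
    """One chi-square p-value per (wildtype replicate, mutant replicate)
    pair, wildtype-major order — four values in the 2x2 replicate design.

    Returns ``None`` (site not assayed) if any replicate's informative depth
    is below ``config.min_depth``.
    """
    if not wt_counts or not mut_counts:
        raise ArgumentError("at least one replicate per genotype required")
    for e, u in list(wt_counts) + list(mut_counts):
        if e + u < config.min_depth:
            return None
    out = []
    for we, wu in wt_counts:
        for me, mu in mut_counts:
            out.append(chisq_2x2(we, wu, me, mu,
                                 continuity=config.continuity_correction)[1])
    return out


def effect_delta(wt_counts: Sequence[tuple[int, int]],
                 mut_counts: Sequence[tuple[int, int]],
                 mode: str = "pooled") -> float:
    """Signed editing-extent difference Δ = mutant − wildtype.

    ``pooled`` (default) sums counts across replicates before taking extents;
    ``mean`` averages per-replicate extents.  NaN when an extent is undefined.
    """
    if mode not in DELTA_MODES:
        raise ArgumentError(f"mode must be one of {DELTA_MODES}")
    if mode == "pooled":
        we = sum(e for e, _ in wt_counts)
        wu = sum(u for _, u in wt_counts)
        me = sum(e for e, _ in mut_counts)
        mu = sum(u for _, u in mut_counts)
        if we + wu == 0 or me + mu == 0:
            return math.nan
        return me / (me + mu) - we / (we + wu)
    wt_ext = [e / (e + u) for e, u in wt_counts if e + u > 0]
    mut_ext = [e / (e + u) for e, u in mut_counts if e + u > 0]
    if len(wt_ext) < len(wt_counts) or len(mut_ext) < len(mut_counts):
        return math.nan
    return float(np.mean(mut_ext) - np.mean(wt_ext))


def classify_site(pvalues: Sequence[float], delta: float,
                  config: TestConfig = TestConfig(),
                  n_assayed: int | None = None) -> str:
    """Apply the all-tests-significant + effect-floor rule to one site."""
    if not len(pvalues):
        raise ArgumentError("pvalues must be nonempty")
    if math.isnan(delta):
        return "not_assayed"
    alpha = config.nominal_alpha(n_assayed)
    all_sig = all(p < alpha for p in pvalues)  # strict: P < threshold
    if all_sig and delta >= config.min_delta:
        return "increased"
    if all_sig and delta <= -config.min_delta:
        return "decreased"
    return "invariant"


# ---------------------------------------------------------------------------
# model / results

class DifferentialEditing:
    """Differential-editing model for one wildtype / mutant contrast.

    Parameters
    ----------
    matrix : EditingMatrix
        Counts with an attached sample design.
    wildtype, mutant : str
        Genotype labels present in the design.
    config : TestConfig, optional

    ``fit()`` runs the replicate-intersection test at every site and returns
    a :class:`DifferentialEditingResults`.
    """

    def __init__(self, matrix: EditingMatrix, wildtype: str, mutant: str,
                 config: TestConfig | None = None):
        self.matrix = matrix
        self.config = config or TestConfig()
        genotypes = set(matrix.design["genotype"])
        for g, what in ((wildtype, "wildtype"), (mutant, "mutant")):
            if g not in genotypes:
                raise DesignError(f"{what} genotype {g!r} not in design")
        self.wildtype = wildtype
        self.mutant = mutant

    @classmethod
    def from_tables(cls, counts: pd.DataFrame, design: pd.DataFrame,
                    wildtype: str, mutant: str,
                    sites: pd.DataFrame | None = None,
                    config: TestConfig | None = None) -> "DifferentialEditing":
        from .quant import assemble_matrix
        return cls(assemble_matrix(counts, design, sites=sites),
                   wildtype, mutant, config=config)

    def fit(self) -> "DifferentialEditingResults":
        cfg = self.config
        m = self.matrix
        wt_cols = m.samples_of(self.wildtype)
        mut_cols = m.samples_of(self.mutant)
        E = m.edited.to_numpy(dtype=float)
        U = m.unedited.to_numpy(dtype=float)
        col_idx = {c: i for i, c in enumerate(m.sample_ids)}
        wt_i = [col_idx[c] for c in wt_cols]
        mut_i = [col_idx[c] for c in mut_cols]

        depth = E + U
        used = wt_i + mut_i
        assayed = (depth[:, used] >= max(cfg.min_depth, 1)).all(axis=1)
        # pooled denominators are positive whenever assayed (min_depth>=1 floor)
        n_assayed = int(assayed.sum())
        alpha = cfg.nominal_alpha(n_assayed if n_assayed else None) \
            if (cfg.alpha_nominal is not None or cfg.n_tests is not None
                or n_assayed) else math.nan

        pmat = np.empty((len(wt_i) * len(mut_i), E.shape[0]))
        k = 0
        for i in wt_i:
            for j in mut_i:
                _, p = _pearson_2x2(E[:, i], U[:, i], E[:, j], U[:, j],
                                    continuity=cfg.continuity_correction)
                pmat[k] = p
                k += 1

        with np.errstate(invalid="ignore", divide="ignore"):
            if cfg.delta_mode == "pooled":
                wt_ext = E[:, wt_i].sum(axis=1) / depth[:, wt_i].sum(axis=1)
                mut_ext = E[:, mut_i].sum(axis=1) / depth[:, mut_i].sum(axis=1)
            else:
                wt_ext = (E[:, wt_i] / depth[:, wt_i]).mean(axis=1)
                mut_ext = (E[:, mut_i] / depth[:, mut_i]).mean(axis=1)
        delta = mut_ext - wt_ext

        all_sig = (pmat < alpha).all(axis=0) if not math.isnan(alpha) \
            else np.zeros(E.shape[0], dtype=bool)
        category = np.full(E.shape[0], "invariant", dtype=object)
        category[all_sig & (delta >= cfg.min_delta)] = "increased"
        category[all_sig & (delta <= -cfg.min_delta)] = "decreased"
        category[~assayed] = "not_assayed"
        delta = np.where(assayed, delta, np.nan)

        table = pd.DataFrame(index=m.site_ids.copy())
        for col in ("transcript", "organelle", "complex_group"):
            if col in m.sites.columns:
                table[col] = m.sites[col]
        for k in range(pmat.shape[0]):
            table[f"p{k + 1}"] = np.where(assayed, pmat[k], np.nan)
        table["delta"] = delta
        table["category"] = category
        table.index.name = "site_id"
        return DifferentialEditingResults(
            table=table, wildtype=self.wildtype, mutant=self.mutant,
            config=cfg, alpha_nominal=float(alpha), n_assayed=n_assayed,
            wt_samples=wt_cols, mut_samples=mut_cols)


@dataclass
class DifferentialEditingResults:
    """Per-site classifications plus per-organelle summary counts."""

    table: pd.DataFrame
    wildtype: str
    mutant: str
    config: TestConfig
    alpha_nominal: float
    n_assayed: int
    wt_samples: list[str] = field(default_factory=list)
    mut_samples: list[str] = field(default_factory=list)

    @property
    def categories(self) -> pd.Series:
        return self.table["category"]

    def sites_in(self, category: str) -> list[str]:
        if category not in CATEGORIES:
            raise ArgumentError(f"unknown category {category!r}")
        return [str(s) for s in
                self.table.index[self.table["category"] == category]]

    def summary_counts(self) -> dict:
        """Category counts, overall and per organelle; not_assayed sites are
        excluded from every category count but reported separately."""
        tab = self.table
        out: dict = {"n_sites": int(len(tab)),
                     "n_assayed": int(self.n_assayed),
                     "alpha_nominal": self.alpha_nominal}
        for cat in ("increased", "decreased", "invariant", "not_assayed"):
            out[cat] = int((tab["category"] == cat).sum())
        if "organelle" in tab.columns:
            out["by_organelle"] = {
                org: {cat: int(((tab["organelle"] == org)
                                & (tab["category"] == cat)).sum())
                      for cat in CATEGORIES}
                for org in sorted(tab["organelle"].unique())
            }
        return out

    def summary(self) -> str:
        s = self.summary_counts()
        lines = [
            "Differential editing: "
            f"{self.mutant} vs {self.wildtype}",
            f"  sites: {s['n_sites']}  assayed: {s['n_assayed']}  "
            f"nominal alpha: {self.alpha_nominal:.3g} "
            f"(family {self.config.alpha_family:g})",
            f"  increased: {s['increased']}  decreased: {s['decreased']}  "
            f"invariant: {s['invariant']}  not_assayed: {s['not_assayed']}",
        ]
        for org, cnt in s.get("by_organelle", {}).items():
            lines.append(f"    {org}: +{cnt['increased']} / -{cnt['decreased']}"
                         f" / ={cnt['invariant']}")
        return "\n".join(lines)

    def to_tsv(self, path: str | Path) -> None:
        self.table.reset_index().to_csv(path, sep="\t", index=False)

    def plot_delta(self, ax=None):
        """Volcano-style view: Δ against the largest pairwise p-value."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        pcols = [c for c in self.table.columns if c.startswith("p")
                 and c[1:].isdigit()]
        pmax = self.table[pcols].max(axis=1)
        colors = self.table["category"].map(
            {"increased": "tab:red", "decreased": "tab:blue",
             "invariant": "0.6", "not_assayed": "0.9"})
        with np.errstate(divide="ignore"):
            ax.scatter(self.table["delta"], -np.log10(pmax), s=8, c=colors)
        ax.axvline(self.config.min_delta, ls="--", c="k", lw=0.5)
        ax.axvline(-self.config.min_delta, ls="--", c="k", lw=0.5)
        ax.set_xlabel("editing-extent difference (mutant − wildtype)")
        ax.set_ylabel("−log10 max pairwise P")
        return ax


def classify_all(matrix: EditingMatrix, wildtype: str, mutant: str,
                 config: TestConfig | None = None) -> DifferentialEditingResults:
    """Classify every site for one wildtype/mutant contrast."""
    return DifferentialEditing(matrix, wildtype, mutant, config=config).fit()


def intersect_classifications(res_a: DifferentialEditingResults,
                              res_b: DifferentialEditingResults) -> dict:
    """Common-site comparison of two mutant classifications against the same
    wild type: sites increased (decreased) in both, plus single-mutant and
    discordant sets."""
    a, b = res_a.table["category"], res_b.table["category"]
    if set(a.index) != set(b.index):
        raise InputError("classifications cover different site sets")
    b = b.reindex(a.index)
    out = {
        "common_increased": [str(s) for s in
                             a.index[(a == "increased") & (b == "increased")]],
        "common_decreased": [str(s) for s in
                             a.index[(a == "decreased") & (b == "decreased")]],
        "a_only": {
            "increased": [str(s) for s in
                          a.index[(a == "increased") & (b != "increased")]],
            "decreased": [str(s) for s in
                          a.index[(a == "decreased") & (b != "decreased")]],
        },
        "b_only": {
            "increased": [str(s) for s in
                          a.index[(b == "increased") & (a != "increased")]],
            "decreased": [str(s) for s in
                          a.index[(b == "decreased") & (a != "decreased")]],
        },
        "discordant": [str(s) for s in a.index[
            ((a == "increased") & (b == "decreased"))
            | ((a == "decreased") & (b == "increased"))]],
    }
    out["n_common_increased"] = len(out["common_increased"])
    out["n_common_decreased"] = len(out["common_decreased"])
    return out
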