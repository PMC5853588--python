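"""Intron splicing efficiency from junction-informative reads.

Splicing efficiency is the spliced fraction among junction-informative
signal:

    SE = spliced / (spliced + unspliced)

From alignments, *spliced* counts reads whose reference skip (CIGAR N)
matches the annotated intron exactly with anchored flanking exon bases;
*unspliced* counts ungapped reads straddling an exon-intron boundary with
anchored bases on both sides (both boundaries counted and summed).  The same
ratio applies unchanged to relative amplicon expression levels from a
spliced-junction vs exon-intron qRT-PCR assay, which may be non-integer.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Sequence

import pandas as pd
import pysam
from scipy import stats

from .annotation import IntronModel
from .errors import AnnotationError, ArgumentError

logger = logging.getLogger(__name__)


def splicing_efficiency(spliced: float, unspliced: float) -> float:
    """spliced/(spliced+unspliced); NaN when both signals are zero.
    Accepts read counts or relative expression levels."""
    if spliced < 0 or unspliced < 0:
        raise ArgumentError("signals must be non-negative")
    total = spliced + unspliced
    if total == 0:
        return math.nan
    return spliced / total


def junction_counts(alignments: str | Path | pysam.AlignmentFile,
                    intron: IntronModel,
                    anchor: int = 6,
                    tolerance: int = 0) -> tuple[int, int]:
    """Count spliced and unspliced junction-informative alignments for one
    intron.

    spliced: alignment contains a reference skip whose span equals the
    intron interval (within ``tolerance`` nt at each edge, default exact)
    with >= ``anchor`` aligned bases on each flanking exon side.

    unspliced: ungapped alignment covering the 5' or 3' exon-intron boundary
    with >= ``anchor`` aligned bases on both the exon and the intron side;
    a read spanning both boundaries counts at each.
    """
    if anchor < 1:
        raise ArgumentError("anchor must be >= 1")
    own = False
    if not isinstance(alignments, pysam.AlignmentFile):
        alignments = pysam.AlignmentFile(str(alignments), "r")
        own = True
    try:
        refs = set(alignments.references or [])
        if intron.contig not in refs:
            raise AnnotationError(
                f"intron contig {intron.contig!r} absent from alignment header")
        is0 = intron.intron_start - 1   # 0-based intron start
        ie0 = intron.intron_end         # 0-based exclusive intron end
        n_spliced = 0
        n_unspliced = 0
        for read in alignments:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.reference_name != intron.contig:
                continue
            cig = read.cigartuples or []
            skips = _reference_skips(read.reference_start, cig)
            if skips:
                for (s0, e0, left_m, right_m) in skips:
                    if abs(s0 - is0) <= tolerance and abs(e0 - ie0) <= tolerance \
                            and left_m >= anchor and right_m >= anchor:
                        n_spliced += 1
                        break
                continue  # gapped reads never count as unspliced
            start, end = read.reference_start, read.reference_end
            for boundary in (is0, ie0):
                if start <= boundary - anchor and end >= boundary + anchor:
                    n_unspliced += 1
        return n_spliced, n_unspliced
    finally:
        if own:
            alignments.close()


def _reference_skips(ref_start: int, cigartuples) -> list[tuple[int, int, int, int]]:
    """(skip start, skip end, aligned bases immediately left, right) for each
    N operation; coordinates 0-based half-open on the reference.  Deletions
    and insertions break an aligned run."""
    ref = ref_start
    segs: list[tuple[int, int, int]] = []  # (start, end, left_run)
    current = 0
    for op, length in cigartuples:
        if op in (0, 7, 8):      # M/=/X consume reference and query
            current += length
            ref += length
        elif op == 2:            # D consumes reference only
            ref += length
            current = 0
        elif op == 3:            # N reference skip
            segs.append((ref, ref + length, current))
            ref += length
            current = 0
        elif op == 1:            # I consumes query only
            current = 0
        # S/H/P consume neither
    out = []
    for i, (s0, e0, left) in enumerate(segs):
        right = segs[i + 1][2] if i + 1 < len(segs) else current
        out.append((s0, e0, left, right))
    return out


def splicing_records(sam_by_sample: dict[str, str | Path],
                     intron: IntronModel,
                     design: pd.DataFrame | None = None,
                     anchor: int = 6,
                     tolerance: int = 0) -> pd.DataFrame:
    """Per-sample SplicingRecord table for one intron."""
    rows = []
    for sample_id, path in sam_by_sample.items():
        spliced, unspliced = junction_counts(path, intron, anchor=anchor,
                                             tolerance=tolerance)
        rows.append({
            "intron_id": intron.intron_id,
            "sample_id": sample_id,
            "genotype": (design.loc[sample_id, "genotype"]
                         if design is not None else sample_id),
            "spliced": spliced,
            "unspliced": unspliced,
            "efficiency": splicing_efficiency(spliced, unspliced),
        })
    return pd.DataFrame(rows)


def splicing_report(records: pd.DataFrame) -> dict:
    """Per-genotype mean efficiency ± SD plus pairwise Welch two-sample t
    statistics between genotypes.

    The t statistics are display statistics over few biological replicates
    and are flagged descriptive-only.  Records with undefined efficiency are
    excluded with a log entry.
    """
    rec = records.copy()
    undefined = rec["efficiency"].isna()
    if undefined.any():
        logger.info("excluding %d records with undefined efficiency",
                    int(undefined.sum()))
        rec = rec[~undefined]
    if rec.empty:
        raise ArgumentError("no defined splicing records")
    per_geno = rec.groupby("genotype")["efficiency"].agg(["mean", "std", "count"])
    out: dict = {
        "per_genotype": {
            g: {"mean": float(r["mean"]),
                "sd": float(r["std"]) if r["count"] > 1 else None,
                "n": int(r["count"])}
            for g, r in per_geno.iterrows()},
        "comparisons": [],
        "note": "t statistics are descriptive only (few replicates)",
    }
    genotypes = list(per_geno.index)
    for i, ga in enumerate(genotypes):
        for gb in genotypes[i + 1:]:
            xa = rec.loc[rec["genotype"] == ga, "efficiency"]
            xb = rec.loc[rec["genotype"] == gb, "efficiency"]
            if len(xa) < 2 or len(xb) < 2:
                continue
            t, p = stats.ttest_ind(xa, xb, equal_var=False)
            out["comparisons"].append({
                "genotypes": [ga, gb],
                "t_statistic": float(t) if not math.isnan(t) else 0.0,
                "pvalue": float(p) if not math.isnan(p) else 1.0,
                "difference": float(xa.mean() - xb.mean()),
            })
    return out
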