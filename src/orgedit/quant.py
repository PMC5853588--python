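"""Editing-extent quantification.

The editing extent at a C target is the fraction of reads showing the edited
base (U, read as T on the sense strand) among reads showing either C or T:

    E = edited / (edited + unedited)

Reads with any other base at the target ("other") are excluded from the
denominator.  Counts come either from a long count table (one row per
site x sample) or from a pileup over strand-specific alignments at annotated
positions.
"""

from __future__ import annotations

import logging
import math
from bisect import bisect_left, bisect_right
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from . import annotation as ann
from .errors import AnnotationError, ArgumentError, InputError

logger = logging.getLogger(__name__)

COUNT_TABLE_COLUMNS = ["site_id", "sample_id", "edited", "unedited", "other"]

#: base classification on the annotated sense strand.  For a '-' strand site
#: the sense base appears reverse-complemented on the forward reference, so
#: edited U reads as A and unedited C reads as G.
_EDITED_BASE = {"+": "T", "-": "A"}
_UNEDITED_BASE = {"+": "C", "-": "G"}


def editing_extent(edited: int, unedited: int) -> float:
    """Editing extent ``edited/(edited+unedited)``; NaN when the denominator
    is zero (no informative reads)."""
    if edited < 0 or unedited < 0:
        raise ArgumentError("read counts must be non-negative")
    denom = edited + unedited
    if denom == 0:
        return math.nan
    return edited / denom


class EditingMatrix:
    """Sites x samples table of (edited, unedited, other) read counts.

    The matrix is rectangular by construction: a (site, sample) cell missing
    from the input is recorded as zero depth, never dropped silently.
    Carries the site annotation frame and the sample design frame.
    """

    def __init__(self, edited: pd.DataFrame, unedited: pd.DataFrame,
                 other: pd.DataFrame | None = None,
                 sites: pd.DataFrame | None = None,
                 design: pd.DataFrame | None = None):
        if not edited.index.equals(unedited.index) or \
                not edited.columns.equals(unedited.columns):
            raise InputError("edited/unedited tables must share sites and samples")
        if other is None:
            other = pd.DataFrame(0, index=edited.index, columns=edited.columns)
        if (edited.values < 0).any() or (unedited.values < 0).any() \
                or (other.values < 0).any():
            raise InputError("negative read counts")
        self.edited = edited.astype(np.int64)
        self.unedited = unedited.astype(np.int64)
        self.other = other.astype(np.int64)
        for frame in (self.edited, self.unedited, self.other):
            frame.index.name = "site_id"
            frame.columns.name = None
        self.sites = sites if sites is not None else pd.DataFrame(index=edited.index)
        self.design = design if design is not None else pd.DataFrame(index=edited.columns)

    # -- basic derived quantities ------------------------------------------
    @property
    def site_ids(self) -> pd.Index:
        return self.edited.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.edited.columns

    def depth(self) -> pd.DataFrame:
        """Informative depth (edited + unedited) per cell."""
        return self.edited + self.unedited

    def extent(self) -> pd.DataFrame:
        """Per-cell editing extent; NaN where informative depth is zero."""
        depth = self.depth().to_numpy(dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            ext = self.edited.to_numpy(dtype=float) / depth
        return pd.DataFrame(ext, index=self.site_ids, columns=self.sample_ids)

    @property
    def zero_depth_sites(self) -> list[str]:
        """Sites with zero informative depth in at least one sample; these are
        reported not_assayed downstream."""
        mask = (self.depth() == 0).any(axis=1)
        return [str(s) for s in self.site_ids[mask]]

    def samples_of(self, genotype: str) -> list[str]:
        return ann.samples_of(self.design, genotype)

    def select_samples(self, sample_ids: Sequence[str]) -> "EditingMatrix":
        cols = list(sample_ids)
        return EditingMatrix(self.edited[cols], self.unedited[cols],
                             self.other[cols], self.sites,
                             self.design.loc[cols])

    # -- I/O ----------------------------------------------------------------
    def to_long(self) -> pd.DataFrame:
        frames = {"edited": self.edited, "unedited": self.unedited,
                  "other": self.other}
        long = pd.concat(
            {k: v.stack() for k, v in frames.items()}, axis=1).reset_index()
        long.columns = ["site_id", "sample_id", "edited", "unedited", "other"]
        return long

    def to_tsv(self, path: str | Path) -> None:
        self.to_long().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_long(cls, table: pd.DataFrame,
                  design: pd.DataFrame | None = None,
                  sites: pd.DataFrame | None = None) -> "EditingMatrix":
        missing = set(COUNT_TABLE_COLUMNS) - {"other"} - set(table.columns)
        if missing:
            raise InputError(f"count table missing columns {sorted(missing)}")
        if table.duplicated(["site_id", "sample_id"]).any():
            dups = table[table.duplicated(["site_id", "sample_id"])]
            raise InputError(
                "duplicate (site, sample) rows: "
                + ", ".join(f"({r.site_id},{r.sample_id})" for r in dups.itertuples()))
        if "other" not in table.columns:
            table = table.assign(other=0)
        site_order = (list(sites.index) if sites is not None
                      else sorted(table["site_id"].unique()))
        sample_order = (list(design.index) if design is not None
                        else sorted(table["sample_id"].unique()))
        pivots = {}
        for col in ("edited", "unedited", "other"):
            piv = table.pivot(index="site_id", columns="sample_id", values=col)
            piv = piv.reindex(index=site_order, columns=sample_order)
            n_missing = int(piv.isna().sum().sum())
            if n_missing and col == "edited":
                logger.warning("%d missing (site,sample) cells recorded as zero depth",
                               n_missing)
            pivots[col] = piv.fillna(0)
        return cls(pivots["edited"], pivots["unedited"], pivots["other"],
                   sites=sites, design=design)

    @classmethod
    def from_tsv(cls, path: str | Path, design: pd.DataFrame | None = None,
                 sites: pd.DataFrame | None = None) -> "EditingMatrix":
        table = pd.read_csv(path, sep="\t",
                            dtype={"site_id": str, "sample_id": str})
        return cls.from_long(table, design=design, sites=sites)

    @classmethod
    def from_wide(cls, path: str | Path,
                  column_map: Mapping[str, tuple[str, str]],
                  site_column: str = "site_id",
                  design: pd.DataFrame | None = None,
                  sites: pd.DataFrame | None = None) -> "EditingMatrix":
        """Read a wide count layout (one edited/unedited column pair per
        sample, as in published per-plant read-count supplements).

        ``column_map`` maps sample_id -> (edited column, unedited column).
        """
        wide = pd.read_csv(path, sep="\t", dtype={site_column: str})
        rows = []
        for sample_id, (ecol, ucol) in column_map.items():
            for col in (ecol, ucol):
                if col not in wide.columns:
                    raise InputError(f"wide table missing column {col!r}")
            rows.append(pd.DataFrame({
                "site_id": wide[site_column],
                "sample_id": sample_id,
                "edited": wide[ecol].fillna(0).astype(int),
                "unedited": wide[ucol].fillna(0).astype(int),
                "other": 0,
            }))
        return cls.from_long(pd.concat(rows, ignore_index=True),
                             design=design, sites=sites)


# ---------------------------------------------------------------------------
# pileup

def pileup_counts(alignments: str | Path | pysam.AlignmentFile,
                  sites: pd.DataFrame,
                  min_base_anchor: int = 3,
                  sample_id: str | None = None) -> pd.DataFrame:
    """Count edited/unedited/other bases at annotated C targets from a
    strand-specific alignment file.

    A read contributes to a site only if it is mapped, aligns an actual base
    (no deletion/skip) at the target with at least ``min_base_anchor`` aligned
    bases on each side, and lies on the transcript sense strand ('-' sites
    require reverse-strand alignments).  The base is classified on the sense
    strand: T -> edited, C -> unedited, anything else -> other.

    Returns a long DataFrame with one row per site.
    """
    own = False
    if not isinstance(alignments, pysam.AlignmentFile):
        alignments = pysam.AlignmentFile(str(alignments), "r")
        own = True
    try:
        return _pileup(alignments, sites, min_base_anchor, sample_id)
    finally:
        if own:
            alignments.close()


def _pileup(af: pysam.AlignmentFile, sites: pd.DataFrame,
            min_base_anchor: int, sample_id: str | None) -> pd.DataFrame:
    refs = set(af.references or [])
    by_contig: dict[str, tuple[list[int], list[tuple[str, str]]]] = {}
    for site_id, row in sites.iterrows():
        contig = str(row["organelle"])
        if contig not in refs:
            raise AnnotationError(
                f"site {site_id}: contig {contig!r} absent from alignment header")
        pos0 = int(row["genome_position"]) - 1
        length = af.get_reference_length(contig)
        if not 0 <= pos0 < length:
            raise AnnotationError(
                f"site {site_id}: position {pos0 + 1} outside {contig} (len {length})")
        by_contig.setdefault(contig, ([], []))[0].append(pos0)
        by_contig[contig][1].append((str(site_id), str(row["strand"])))
    for contig, (positions, meta) in by_contig.items():
        order = np.argsort(positions)
        by_contig[contig] = ([positions[i] for i in order],
                             [meta[i] for i in order])

    counts = {str(s): [0, 0, 0] for s in sites.index}  # edited, unedited, other
    n_unmapped = 0
    for read in af:
        if read.is_unmapped:
            n_unmapped += 1
            continue
        if read.is_secondary or read.is_supplementary:
            continue
        entry = by_contig.get(read.reference_name)
        if entry is None:
            continue
        positions, meta = entry
        lo = bisect_left(positions, read.reference_start)
        hi = bisect_right(positions, read.reference_end - 1)
        if lo >= hi:
            continue
        pairs = read.get_aligned_pairs(matches_only=True)
        if not pairs:
            continue
        ref_cols = [p[1] for p in pairs]
        seq = read.query_sequence
        read_reverse = read.is_reverse
        for k in range(lo, hi):
            pos0 = positions[k]
            site_id, strand = meta[k]
            # strand-specific library: only sense-strand evidence counts
            if (strand == "+") == read_reverse:
                continue
            idx = bisect_left(ref_cols, pos0)
            if idx >= len(ref_cols) or ref_cols[idx] != pos0:
                continue  # deletion or reference skip over the target
            if idx < min_base_anchor or len(ref_cols) - 1 - idx < min_base_anchor:
                continue  # insufficient aligned anchor on one side
            base = seq[pairs[idx][0]].upper()
            if base == _EDITED_BASE[strand]:
                counts[site_id][0] += 1
            elif base == _UNEDITED_BASE[strand]:
                counts[site_id][1] += 1
            else:
                counts[site_id][2] += 1
    if n_unmapped:
        logger.info("pileup skipped %d unmapped reads", n_unmapped)

    out = pd.DataFrame(
        [(s, c[0], c[1], c[2]) for s, c in counts.items()],
        columns=["site_id", "edited", "unedited", "other"])
    out["sample_id"] = sample_id if sample_id is not None else "sample"
    return out[COUNT_TABLE_COLUMNS]


def assemble_matrix(tables: pd.DataFrame | Sequence[pd.DataFrame],
                    design: pd.DataFrame,
                    sites: pd.DataFrame | None = None) -> EditingMatrix:
    """Assemble per-sample count tables into a rectangular EditingMatrix.

    Accepts one long table or a sequence of per-sample tables (each with a
    sample_id column, e.g. pileup outputs).  Every sample in the design must
    appear; missing cells become zero depth and the affected sites are
    reported by ``EditingMatrix.zero_depth_sites``.
    """
    if not isinstance(tables, pd.DataFrame):
        tables = pd.concat(list(tables), ignore_index=True)
    unknown = set(tables["sample_id"].unique()) - set(map(str, design.index))
    if unknown:
        raise InputError(f"count table contains samples not in design: {sorted(unknown)}")
    matrix = EditingMatrix.from_long(tables, design=design, sites=sites)
    totals = matrix.depth().sum(axis=0)
    for sample, total in totals.items():
        logger.info("sample %s: %d informative reads over %d sites",
                    sample, int(total), len(matrix.site_ids))
    return matrix
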