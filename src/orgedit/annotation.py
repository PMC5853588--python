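"""Site, intron and sample-design annotations.

An editing site is an annotated cytidine target on an organellar transcript,
named ``<transcript>_C<tx_position>`` (e.g. ``nad7_C789``).  Annotations are
held as pandas DataFrames indexed by ``site_id``; light dataclasses are
provided for construction and for single-record use.

Coordinate conventions: the native annotation is 1-based inclusive
(``genome_position`` is the position of the C on the organelle reference, in
transcript-sense orientation).  BED export is 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import AnnotationError, InputError

ORGANELLES = ("mito", "plastid")
STRANDS = ("+", "-")
ROLES = ("wildtype", "mutant", "transgenic")

#: columns of the native tab-separated site-annotation file
SITE_TABLE_COLUMNS = [
    "site_id", "transcript", "organelle", "complex_group", "strand",
    "genome_position",
]


@dataclass(frozen=True)
class SiteAnnotation:
    """One annotated C target on an organellar transcript."""

    site_id: str
    transcript: str
    organelle: str
    complex_group: str
    strand: str
    tx_position: int
    genome_position: int

    def __post_init__(self) -> None:
        if self.organelle not in ORGANELLES:
            raise AnnotationError(f"unknown organelle {self.organelle!r}")
        if self.strand not in STRANDS:
            raise AnnotationError(f"unknown strand {self.strand!r}")
        if self.tx_position < 1 or self.genome_position < 1:
            raise AnnotationError("positions are 1-based and must be >= 1")


@dataclass(frozen=True)
class SampleDesign:
    """Metadata for one sequenced plant.

    ``role`` is one of wildtype / mutant / transgenic; transgenic samples name
    the ``background`` mutant they were transformed into and the construct.
    """

    sample_id: str
    genotype: str
    replicate: int
    role: str
    background: str | None = None
    construct: str | None = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise InputError(f"unknown role {self.role!r}")
        if self.role == "transgenic" and not self.background:
            raise InputError(
                f"transgenic sample {self.sample_id!r} needs a background mutant")


@dataclass(frozen=True)
class IntronModel:
    """A single intron on a toy reference, with per-genotype true splicing
    efficiency (fraction of transcripts spliced, in [0, 1]).

    Coordinates are 1-based inclusive on ``contig``; exon1 < intron < exon2
    must be strictly ordered and contiguous is not required.
    """

    intron_id: str
    contig: str
    exon1_start: int
    exon1_end: int
    intron_start: int
    intron_end: int
    exon2_start: int
    exon2_end: int
    efficiency: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        coords = (self.exon1_start, self.exon1_end, self.intron_start,
                  self.intron_end, self.exon2_start, self.exon2_end)
        if not all(a < b for a, b in zip(coords, coords[1:])):
            raise AnnotationError(
                f"{self.intron_id}: exon/intron boundaries must be strictly ordered")
        if self.intron_end < self.intron_start:
            raise AnnotationError(f"{self.intron_id}: intron shorter than 1 nt")
        for g, se in self.efficiency.items():
            if not 0.0 <= se <= 1.0:
                raise AnnotationError(
                    f"{self.intron_id}: efficiency for {g!r} outside [0,1]")

    @property
    def length(self) -> int:
        return self.intron_end - self.intron_start + 1


# ---------------------------------------------------------------------------
# frame conversions and I/O

def sites_to_frame(sites: Iterable[SiteAnnotation]) -> pd.DataFrame:
    """Tabulate site annotations, indexed by site_id."""
    rows = [vars(s) for s in sites]
    frame = pd.DataFrame(
        rows,
        columns=["site_id", "transcript", "organelle", "complex_group",
                 "strand", "tx_position", "genome_position"],
    )
    if frame["site_id"].duplicated().any():
        dups = frame.loc[frame["site_id"].duplicated(), "site_id"].tolist()
        raise AnnotationError(f"duplicate site ids: {dups}")
    return frame.set_index("site_id")


def frame_to_sites(frame: pd.DataFrame) -> list[SiteAnnotation]:
    out = []
    for site_id, row in frame.iterrows():
        out.append(SiteAnnotation(
            site_id=str(site_id),
            transcript=row["transcript"],
            organelle=row["organelle"],
            complex_group=row.get("complex_group", ""),
            strand=row["strand"],
            tx_position=int(row.get("tx_position", row["genome_position"])),
            genome_position=int(row["genome_position"]),
        ))
    return out


def write_site_table(frame: pd.DataFrame, path: str | Path) -> None:
    """Write the native 6-column site annotation TSV."""
    cols = [c for c in SITE_TABLE_COLUMNS if c != "site_id"]
    frame.reset_index()[SITE_TABLE_COLUMNS].to_csv(path, sep="\t", index=False)
    del cols


def read_site_table(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype={"site_id": str})
    missing = set(SITE_TABLE_COLUMNS) - set(frame.columns)
    if missing:
        raise InputError(f"site table {path} missing columns {sorted(missing)}")
    if "tx_position" not in frame.columns:
        frame["tx_position"] = frame["genome_position"]
    return frame.set_index("site_id")


def write_bed(frame: pd.DataFrame, path: str | Path) -> None:
    """Export sites as BED (0-based half-open), one interval per C target."""
    with open(path, "w") as fh:
        for site_id, row in frame.iterrows():
            start = int(row["genome_position"]) - 1
            fh.write(f"{row['organelle']}\t{start}\t{start + 1}"
                     f"\t{site_id}\t0\t{row['strand']}\n")


def read_bed_sites(path: str | Path,
                   transcript_of: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read a BED file of C targets back into the native 1-based frame."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 6:
                raise InputError(f"BED line with <6 fields in {path}")
            chrom, start, _end, name, _score, strand = f[:6]
            rows.append({
                "site_id": name,
                "transcript": (transcript_of or {}).get(name, name.split("_C")[0]),
                "organelle": chrom,
                "complex_group": "",
                "strand": strand,
                "tx_position": int(start) + 1,
                "genome_position": int(start) + 1,
            })
    return pd.DataFrame(rows).set_index("site_id")


def design_to_frame(design: Iterable[SampleDesign]) -> pd.DataFrame:
    rows = [vars(s) for s in design]
    frame = pd.DataFrame(rows)
    if frame.empty:
        raise InputError("empty sample design")
    if frame["sample_id"].duplicated().any():
        raise InputError("duplicate sample ids in design")
    return frame.set_index("sample_id")


def frame_to_design(frame: pd.DataFrame) -> list[SampleDesign]:
    out = []
    for sample_id, row in frame.iterrows():
        bg = row.get("background")
        con = row.get("construct")
        out.append(SampleDesign(
            sample_id=str(sample_id),
            genotype=row["genotype"],
            replicate=int(row["replicate"]),
            role=row["role"],
            background=None if pd.isna(bg) else bg,
            construct=None if pd.isna(con) else con,
        ))
    return out


def write_design_table(frame: pd.DataFrame, path: str | Path) -> None:
    frame.reset_index().to_csv(path, sep="\t", index=False)


def read_design_table(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    for col in ("sample_id", "genotype", "replicate", "role"):
        if col not in frame.columns:
            raise InputError(f"design table {path} missing column {col!r}")
    return frame.set_index("sample_id")


def samples_of(design: pd.DataFrame, genotype: str) -> list[str]:
    """Sample ids of a genotype, ordered by replicate index."""
    sub = design[design["genotype"] == genotype].sort_values("replicate")
    if sub.empty:
        raise InputError(f"genotype {genotype!r} not in design")
    return [str(s) for s in sub.index]
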