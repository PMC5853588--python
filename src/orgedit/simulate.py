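"""Synthetic data emulating a strand- and transcript-specific editing assay.

The generator produces, from a seed: a site annotation (mitochondrial +
plastid C targets distributed over organellar transcripts), a truth table of
per-genotype editing extents with increased/decreased/invariant effect
classes, binomially sampled read counts at configurable depth, and
strand-specific SAM alignments (spliced/unspliced junction reads for one
intron plus site-covering reads) with truth sidecars, so every downstream
stage is testable without external data.

Counts are binomial by default (the 2x2 chi-square assumes binomial
sampling); a beta-binomial dispersion parameter is available for robustness
testing.  All outputs are deterministic for a fixed seed.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .annotation import (IntronModel, SampleDesign, SiteAnnotation,
                         design_to_frame, sites_to_frame)
from .errors import ArgumentError, DesignError, GenerationError
from .quant import EditingMatrix

# transcript name pools with the respiratory-complex groups they encode
_MITO_POOL = [
    ("nad1", "complex I"), ("nad2", "complex I"), ("nad3", "complex I"),
    ("nad4", "complex I"), ("nad4L", "complex I"), ("nad5", "complex I"),
    ("nad6", "complex I"), ("nad7", "complex I"), ("nad9", "complex I"),
    ("cob", "complex III"), ("cox1", "complex IV"), ("cox2", "complex IV"),
    ("cox3", "complex IV"), ("atp1", "complex V"), ("atp4", "complex V"),
    ("atp6", "complex V"), ("atp8", "complex V"), ("atp9", "complex V"),
    ("ccmB", "cytochrome c biogenesis"), ("ccmC", "cytochrome c biogenesis"),
    ("ccmFn", "cytochrome c biogenesis"), ("rps3", "ribosome"),
    ("rps4", "ribosome"), ("rps12", "ribosome"), ("rps14", "ribosome"),
    ("rpl5", "ribosome"), ("matR", "maturase"), ("mttB", "transport"),
]
_PLASTID_POOL = [
    ("ndhB", "NDH complex"), ("ndhD", "NDH complex"), ("ndhF", "NDH complex"),
    ("rpoB", "RNA polymerase"), ("rpoC1", "RNA polymerase"),
    ("accD", "acetyl-CoA carboxylase"), ("matK", "maturase"),
    ("psbE", "photosystem II"), ("petL", "cytochrome b6f"),
    ("clpP", "protease"), ("rps2", "ribosome"), ("rpl23", "ribosome"),
]

#: genome spacing between consecutive sites on a contig; kept larger than any
#: simulated read so one read never covers two sites
SITE_SPACING = 400


def _round_half_away(x: float) -> int:
    """Round half away from zero (matches printed percentage roll-ups)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def _spread(n_sites: int, n_transcripts: int, rng: np.random.Generator) -> np.ndarray:
    """Number of sites per transcript: each transcript gets >= 1 when
    possible, the rest multinomially."""
    if n_sites == 0:
        return np.zeros(n_transcripts, dtype=int)
    n_tx = min(n_transcripts, n_sites)
    base = np.ones(n_tx, dtype=int)
    extra = n_sites - n_tx
    if extra > 0:
        base += rng.multinomial(extra, np.full(n_tx, 1.0 / n_tx))
    return base


def gen_sites(n_mito: int, n_plastid: int, n_transcripts: int,
              seed: int) -> list[SiteAnnotation]:
    """Generate a toy site annotation: ``n_mito`` mitochondrial plus
    ``n_plastid`` plastid C targets, the mitochondrial ones spread over
    ``n_transcripts`` transcripts (plastid sites use their own smaller pool).
    Deterministic for a fixed seed."""
    if n_mito < 0 or n_plastid < 0:
        raise ArgumentError("site counts must be non-negative")
    if (n_mito or n_plastid) and n_transcripts < 1:
        raise ArgumentError("need at least one transcript when sites requested")
    rng = np.random.default_rng(seed)
    sites: list[SiteAnnotation] = []
    for organelle, n_sites, pool, n_tx in (
            ("mito", n_mito, _MITO_POOL, n_transcripts),
            ("plastid", n_plastid, _PLASTID_POOL,
             min(len(_PLASTID_POOL), max(1, n_plastid // 4 or 1)))):
        if n_sites == 0:
            continue
        n_tx = min(n_tx, n_sites)
        names = list(pool)
        while len(names) < n_tx:  # extend pool with numbered ORFs if needed
            names.append((f"orf{organelle[0]}{len(names) + 1}", "unassigned"))
        chosen = [names[i] for i in rng.choice(len(names), size=n_tx,
                                               replace=False)]
        per_tx = _spread(n_sites, n_tx, rng)
        genome_pos = SITE_SPACING
        for (transcript, group), k in zip(chosen, per_tx):
            strand = "+" if rng.random() < 0.5 else "-"
            tx_pos = 0
            for _ in range(int(k)):
                tx_pos += int(rng.integers(20, 160))
                sites.append(SiteAnnotation(
                    site_id=f"{transcript}_C{tx_pos}",
                    transcript=transcript, organelle=organelle,
                    complex_group=group, strand=strand,
                    tx_position=tx_pos, genome_position=genome_pos))
                genome_pos += SITE_SPACING
    return sites


class TruthTable:
    """True editing extents per (site, genotype) plus the per-site effect
    class and signed true Δ of the mutant relative to the wild type."""

    def __init__(self, extents: pd.DataFrame, effect_class: pd.Series,
                 delta_true: pd.Series, sites: pd.DataFrame | None = None):
        self.extents = extents
        self.effect_class = effect_class
        self.delta_true = delta_true
        self.sites = sites if sites is not None else pd.DataFrame(index=extents.index)

    @property
    def genotypes(self) -> list[str]:
        return list(self.extents.columns)

    def add_genotype(self, name: str, extents: pd.Series | np.ndarray) -> None:
        vals = np.clip(np.asarray(extents, dtype=float), 0.0, 1.0)
        self.extents[name] = vals

    def copy_genotype(self, source: str, name: str) -> None:
        """A second genotype sharing the same true extents (e.g. an
        independent mutant allele of the same gene)."""
        self.extents[name] = self.extents[source]

    def add_rescued(self, name: str, mutant: str = "mutant",
                    wildtype: str = "wildtype", level: float = 1.0) -> None:
        """A transgenic genotype moved a fraction ``level`` of the way from
        the mutant back to the wild-type extent (1 = full rescue, >1 =
        transgressive overshoot)."""
        e = self.extents
        self.add_genotype(name, e[mutant] + level * (e[wildtype] - e[mutant]))

    def shift_sites(self, name: str, base: str, site_ids: Sequence[str],
                    shift: float) -> None:
        """Genotype ``name`` equal to ``base`` except the listed sites are
        shifted by ``shift`` (clipped to [0,1]); models overexpression
        touching otherwise-invariant sites."""
        vals = self.extents[base].copy()
        vals.loc[list(site_ids)] = np.clip(vals.loc[list(site_ids)] + shift, 0, 1)
        self.add_genotype(name, vals)

    def to_tsv(self, path: str | Path) -> None:
        out = self.extents.copy()
        out["effect_class"] = self.effect_class
        out["delta_true"] = self.delta_true
        out.rename_axis("site_id").reset_index().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path,
                 sites: pd.DataFrame | None = None) -> "TruthTable":
        t = pd.read_csv(path, sep="\t", dtype={"site_id": str}).set_index("site_id")
        eff = t.pop("effect_class")
        delta = t.pop("delta_true")
        return cls(t, eff, delta, sites=sites)


def gen_truth(sites: Sequence[SiteAnnotation] | pd.DataFrame,
              base_extent_range: tuple[float, float] = (0.2, 0.9),
              frac_increased: float = 0.14,
              frac_decreased: float = 0.03,
              delta_range: tuple[float, float] = (0.15, 0.4),
              min_effect: float = 0.1,
              seed: int = 0,
              effect_sites: Sequence[str] | None = None) -> TruthTable:
    """Draw true wild-type extents and assign effect classes.

    Class counts are ``round(frac x n)`` (half away from zero) over the
    effect pool (``effect_sites`` or all sites).  The mutant extent is the
    wild-type extent plus a signed Δ drawn from ``delta_range``; base extents
    are drawn so no clipping can push a realised |Δ| below ``min_effect``.
    """
    frame = sites if isinstance(sites, pd.DataFrame) else sites_to_frame(sites)
    if frac_increased < 0 or frac_decreased < 0 \
            or frac_increased + frac_decreased > 1:
        raise ArgumentError("effect fractions must be >= 0 and sum to <= 1")
    lo_d, hi_d = delta_range
    if lo_d < min_effect:
        raise ArgumentError(
            f"delta_range low {lo_d} below the non-invariant floor {min_effect}")
    if hi_d >= 1.0:
        raise GenerationError("effect sizes >= 1 cannot fit in [0,1] extents")
    lo_b, hi_b = base_extent_range
    if not 0.0 <= lo_b < hi_b <= 1.0:
        raise ArgumentError("base_extent_range must satisfy 0 <= lo < hi <= 1")

    rng = np.random.default_rng(seed)
    all_ids = list(frame.index)
    pool = list(effect_sites) if effect_sites is not None else all_ids
    unknown = set(pool) - set(all_ids)
    if unknown:
        raise ArgumentError(f"effect_sites not in annotation: {sorted(unknown)}")
    n_inc = _round_half_away(frac_increased * len(pool))
    n_dec = _round_half_away(frac_decreased * len(pool))
    if n_inc + n_dec > len(pool):
        raise GenerationError("rounded class counts exceed the effect pool")
    perm = rng.permutation(len(pool))
    inc_ids = {pool[i] for i in perm[:n_inc]}
    dec_ids = {pool[i] for i in perm[n_inc:n_inc + n_dec]}

    wt = rng.uniform(lo_b, hi_b, size=len(all_ids))
    delta = np.zeros(len(all_ids))
    classes = np.full(len(all_ids), "invariant", dtype=object)
    for i, sid in enumerate(all_ids):
        if sid in inc_ids:
            sign, classes[i] = 1.0, "increased"
        elif sid in dec_ids:
            sign, classes[i] = -1.0, "decreased"
        else:
            continue
        d = rng.uniform(lo_d, hi_d)
        # redraw the base extent inside the feasible band so wt + signed d
        # stays in [0,1] without clipping
        if sign > 0:
            lo_f, hi_f = lo_b, min(hi_b, 1.0 - d)
            if hi_f <= lo_f:
                lo_f, hi_f = 0.0, 1.0 - d
        else:
            lo_f, hi_f = max(lo_b, d), hi_b
            if hi_f <= lo_f:
                lo_f, hi_f = d, 1.0
        if hi_f <= lo_f:
            raise GenerationError(
                f"no feasible base extent for site {sid} with delta {sign * d:+.3f}")
        wt[i] = rng.uniform(lo_f, hi_f)
        delta[i] = sign * d

    extents = pd.DataFrame({"wildtype": wt,
                            "mutant": np.clip(wt + delta, 0.0, 1.0)},
                           index=pd.Index(all_ids, name="site_id"))
    return TruthTable(extents,
                      pd.Series(classes, index=extents.index, name="effect_class"),
                      pd.Series(delta, index=extents.index, name="delta_true"),
                      sites=frame)


def default_design(replicates: int = 2,
                   genotypes: Sequence[str] = ("wildtype", "mutant"),
                   roles: Mapping[str, str] | None = None) -> list[SampleDesign]:
    """Convenience design: ``replicates`` plants per genotype, sample ids
    ``<genotype>-<rep>``."""
    roles = roles or {}
    out = []
    for g in genotypes:
        role = roles.get(g, "wildtype" if g == "wildtype" else "mutant")
        for r in range(1, replicates + 1):
            out.append(SampleDesign(sample_id=f"{g}-{r}", genotype=g,
                                    replicate=r, role=role,
                                    background=None if role != "transgenic"
                                    else roles.get(f"{g}::background")))
    return out


def gen_counts(truth: TruthTable,
               design: Sequence[SampleDesign] | pd.DataFrame,
               depth: int | Mapping[str, int],
               seed: int = 0,
               error_rate: float = 0.0,
               dispersion: float | None = None) -> EditingMatrix:
    """Binomially sample (edited, unedited, other) counts for every
    (site, sample).

    ``edited ~ Binomial(informative depth, true extent)`` independently per
    cell; "other" miscalls are drawn first at ``error_rate`` and excluded
    from the informative denominator, so edited + unedited = depth when
    ``error_rate`` is 0.  ``dispersion`` (rho in (0,1)) switches to a
    beta-binomial by jittering the per-cell success probability.
    """
    dframe = design if isinstance(design, pd.DataFrame) else design_to_frame(design)
    rng = np.random.default_rng(seed)
    n_sites = len(truth.extents.index)
    edited, unedited, other = {}, {}, {}
    for sample_id, row in dframe.iterrows():
        genotype = row["genotype"]
        if genotype not in truth.extents.columns:
            raise DesignError(f"genotype {genotype!r} absent from the truth table")
        d = depth[sample_id] if isinstance(depth, Mapping) else int(depth)
        if d < 0:
            raise ArgumentError("depth must be >= 0")
        p = truth.extents[genotype].to_numpy()
        oth = rng.binomial(d, error_rate, size=n_sites) if error_rate > 0 \
            else np.zeros(n_sites, dtype=np.int64)
        informative = d - oth
        if dispersion:
            if not 0.0 < dispersion < 1.0:
                raise ArgumentError("dispersion must be in (0, 1)")
            conc = (1.0 - dispersion) / dispersion
            a = np.clip(p * conc, 1e-9, None)
            b = np.clip((1.0 - p) * conc, 1e-9, None)
            p = rng.beta(a, b)
        e = rng.binomial(informative, p)
        edited[sample_id] = e
        unedited[sample_id] = informative - e
        other[sample_id] = oth
    idx = truth.extents.index
    return EditingMatrix(pd.DataFrame(edited, index=idx),
                         pd.DataFrame(unedited, index=idx),
                         pd.DataFrame(other, index=idx),
                         sites=truth.sites, design=dframe)


# ---------------------------------------------------------------------------
# synthetic alignments

def default_intron(efficiency: Mapping[str, float] | None = None) -> IntronModel:
    """Toy single-intron transcript: 400 nt exon, 300 nt intron, 400 nt exon
    on its own contig.  The intron is longer than any simulated read so an
    unspliced read can span exactly one boundary."""
    return IntronModel(intron_id="nad5_i1", contig="nad5_region",
                       exon1_start=1, exon1_end=400,
                       intron_start=401, intron_end=700,
                       exon2_start=701, exon2_end=1100,
                       efficiency=dict(efficiency or
                                       {"wildtype": 0.95, "mutant": 0.5}))


def _sam_header(truth: TruthTable, intron: IntronModel | None) -> dict:
    sq = []
    if len(truth.sites):
        for organelle in ("mito", "plastid"):
            sub = truth.sites[truth.sites["organelle"] == organelle] \
                if "organelle" in truth.sites.columns else truth.sites.iloc[0:0]
            if len(sub):
                length = int(sub["genome_position"].max()) + SITE_SPACING
                sq.append({"SN": organelle, "LN": length})
    if intron is not None:
        sq.append({"SN": intron.contig, "LN": intron.exon2_end + 100})
    return {"HD": {"VN": "1.6", "SO": "unsorted"}, "SQ": sq}


def gen_reads(truth: TruthTable,
              design: Sequence[SampleDesign] | pd.DataFrame,
              intron: IntronModel | None,
              n_reads_per_sample: int,
              read_length: int = 100,
              site_depth: int = 0,
              error_rate: float = 0.0,
              seed: int = 0,
              out_dir: str | Path = ".") -> dict[str, Path]:
    """Write one strand-specific SAM per sample plus truth sidecars.

    Junction reads over ``intron``: spliced (CIGAR with an N gap exactly
    matching the intron) vs unspliced (ungapped across one boundary) in
    proportions ``Binomial(n_reads_per_sample, SE_genotype)``.  Site reads:
    ``site_depth`` reads centred on each C target whose base is the edited
    sense base with probability equal to the true extent ('-' strand sites
    are emitted as reverse-strand alignments with complemented bases).
    """
    if n_reads_per_sample < 0 or site_depth < 0:
        raise ArgumentError("read counts must be >= 0")
    anchor_split = read_length // 2
    if intron is not None and read_length < 4:
        raise ArgumentError("read_length too short to anchor a junction")
    if intron is not None and intron.length < read_length - anchor_split:
        raise GenerationError("intron shorter than the intron-side read arm; "
                              "unspliced reads would overrun both boundaries")
    dframe = design if isinstance(design, pd.DataFrame) else design_to_frame(design)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    header = _sam_header(truth, intron)
    paths: dict[str, Path] = {}

    for sample_id, row in dframe.iterrows():
        genotype = row["genotype"]
        if genotype not in truth.extents.columns:
            raise DesignError(f"genotype {genotype!r} absent from the truth table")
        path = out_dir / f"{sample_id}.sam"
        with pysam.AlignmentFile(str(path), "w", header=header) as sam:
            serial = 0
            if intron is not None:
                if genotype not in intron.efficiency:
                    raise DesignError(
                        f"no splicing efficiency for genotype {genotype!r}")
                se = intron.efficiency[genotype]
                n_spliced = int(rng.binomial(n_reads_per_sample, se))
                serial = _write_junction_reads(
                    sam, intron, n_spliced,
                    n_reads_per_sample - n_spliced, read_length, rng, serial)
            if site_depth > 0 and len(truth.sites):
                serial = _write_site_reads(
                    sam, truth, genotype, site_depth, read_length,
                    error_rate, rng, serial)
        paths[sample_id] = path

    truth.to_tsv(out_dir / "sites_truth.tsv")
    if intron is not None:
        pd.DataFrame(
            [{"intron_id": intron.intron_id, "genotype": g, "efficiency": se}
             for g, se in intron.efficiency.items()]
        ).to_csv(out_dir / "intron_truth.tsv", sep="\t", index=False)
    return paths


def _aligned(sam, name, contig, start0, cigar, seq, reverse=False):
    a = pysam.AlignedSegment(sam.header)
    a.query_name = name
    a.reference_name = contig
    a.reference_start = start0
    a.cigartuples = cigar
    a.query_sequence = seq
    a.mapping_quality = 60
    a.flag = 16 if reverse else 0
    sam.write(a)


def _write_junction_reads(sam, intron: IntronModel, n_spliced: int,
                          n_unspliced: int, read_length: int,
                          rng: np.random.Generator, serial: int) -> int:
    a = read_length // 2  # exon-1 arm of a spliced read
    is0 = intron.intron_start - 1      # 0-based intron start
    ie0 = intron.intron_end            # 0-based exclusive intron end
    for _ in range(n_spliced):
        start0 = is0 - a
        cigar = [(0, a), (3, intron.length), (0, read_length - a)]
        _aligned(sam, f"sp{serial}", intron.contig, start0, cigar,
                 "A" * read_length)
        serial += 1
    for _ in range(n_unspliced):
        # unspliced reads straddle the 5' or 3' boundary at random
        if rng.random() < 0.5:
            start0 = is0 - a
        else:
            start0 = ie0 - (read_length - a)
        _aligned(sam, f"un{serial}", intron.contig, start0,
                 [(0, read_length)], "A" * read_length)
        serial += 1
    return serial


_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _write_site_reads(sam, truth: TruthTable, genotype: str, depth: int,
                      read_length: int, error_rate: float,
                      rng: np.random.Generator, serial: int) -> int:
    half = read_length // 2
    for site_id, row in truth.sites.iterrows():
        contig = row["organelle"]
        strand = row["strand"]
        pos0 = int(row["genome_position"]) - 1
        start0 = max(0, pos0 - half)
        offset = pos0 - start0
        p = float(truth.extents.loc[site_id, genotype])
        edited = rng.random(depth) < p
        miscall = (rng.random(depth) < error_rate) if error_rate > 0 \
            else np.zeros(depth, dtype=bool)
        for i in range(depth):
            if miscall[i]:
                sense = "G"  # neither C nor T on the sense strand
            else:
                sense = "T" if edited[i] else "C"
            base = sense if strand == "+" else _COMPLEMENT[sense]
            seq = "A" * offset + base + "A" * (read_length - offset - 1)
            _aligned(sam, f"st{serial}", contig, start0,
                     [(0, read_length)], seq, reverse=(strand == "-"))
            serial += 1
    return serial
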