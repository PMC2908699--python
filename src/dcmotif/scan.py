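"""Genome-wide application: scanning, ChIP peak calling and gene categories.

Peaks are called where four or more tiles inside a 500-bp sliding window
exceed a cutoff expressed as a fraction of a hypothetical maximum (the
tile-signal mean plus six standard deviations); each peak gets an
empirical FDR score from seeded within-chromosome randomizations of the
tile values.

Genes (or operon heads) are placed into five categories from the
combination of expression call, intergenic ChIP peak and predicted
binding site, mirroring the genome-wide summary of the method; the
empirical method FDR is the site-positive fraction among genes with
neither expression nor a peak.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .classify import MultiClassifier
from .encode import ScoredHit, scan_window
from .errors import EmptyInputError, ValidationError
from .fuse import RuleBase, infer
from .seqio import GenomeAnnotation, Region

logger = logging.getLogger(__name__)

CATEGORIES = ("expr+peak", "expr-only", "peak-only", "neither", "coding-peak")


@dataclass
class Tile:
    chromosome: str
    start: int
    end: int
    log2_ratio: float


@dataclass
class TilingSignal:
    """Sorted, non-overlapping tiling-array signal records."""

    tiles: list[Tile]

    def __post_init__(self) -> None:
        by_chrom: dict[str, list[Tile]] = {}
        for t in self.tiles:
            if not np.isfinite(t.log2_ratio):
                raise ValidationError("tile ratios must be finite")
            by_chrom.setdefault(t.chromosome, []).append(t)
        for chrom, ts in by_chrom.items():
            ts.sort(key=lambda t: t.start)
            for a, b in zip(ts, ts[1:]):
                if b.start < a.end:
                    raise ValidationError(
                        f"overlapping tiles on {chrom} at {a.start}/{b.start}"
                    )
        self.tiles = [t for chrom in sorted(by_chrom) for t in by_chrom[chrom]]

    @property
    def values(self) -> np.ndarray:
        return np.array([t.log2_ratio for t in self.tiles])

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("chromosome\tstart\tend\tlog2_ratio\n")
            for t in self.tiles:
                fh.write(f"{t.chromosome}\t{t.start}\t{t.end}\t{t.log2_ratio:.4f}\n")

    @classmethod
    def read_tsv(cls, path) -> "TilingSignal":
        tiles = []
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("chromosome"):
                raise ValidationError("tiling TSV must have a header line")
            for line in fh:
                c, s, e, v = line.rstrip("\n").split("\t")
                tiles.append(Tile(c, int(s), int(e), float(v)))
        return cls(tiles)


@dataclass
class ChipPeak:
    chromosome: str
    start: int
    end: int
    n_tiles: int
    max_signal: float
    fdr_score: float = 0.0


def _peak_tiles(
    values: np.ndarray,
    starts: np.ndarray,
    ends: np.ndarray,
    cutoff: float,
    window_bp: int,
    min_tiles: int,
) -> list[list[int]]:
    """Indices of above-cutoff tiles grouped into peaks.

    A group is a maximal run of above-cutoff tiles in which each tile
    starts within ``window_bp`` of the previous one; groups with fewer
    than ``min_tiles`` tiles are discarded.
    """
    above = np.flatnonzero(values >= cutoff)
    groups: list[list[int]] = []
    for i in above:
        if groups and starts[i] - starts[groups[-1][-1]] <= window_bp:
            groups[-1].append(int(i))
        else:
            groups.append([int(i)])
    return [grp for grp in groups if len(grp) >= min_tiles]


def call_chip_peaks(
    signal: TilingSignal,
    window_bp: int = 500,
    min_tiles: int = 4,
    cutoff_fraction: float = 0.5,
    n_randomizations: int = 20,
    seed: int = 0,
) -> list[ChipPeak]:
    """Call peaks of >= ``min_tiles`` above-cutoff tiles per sliding window.

    The cutoff is ``cutoff_fraction`` of the hypothetical maximum (mean +
    6 sd of all tile signals).  Each peak's ``fdr_score`` is the fraction
    of seeded within-chromosome permutations of the tile values producing
    a peak with at least as many tiles.
    """
    if not signal.tiles:
        raise EmptyInputError("empty tiling signal")
    if not (0.0 < cutoff_fraction <= 1.0):
        raise ValidationError("cutoff_fraction must lie in (0, 1]")
    values = signal.values
    cutoff = cutoff_fraction * (values.mean() + 6.0 * values.std())
    peaks: list[ChipPeak] = []
    rng = np.random.default_rng(seed)
    chroms = sorted({t.chromosome for t in signal.tiles})
    for chrom in chroms:
        idx = [i for i, t in enumerate(signal.tiles) if t.chromosome == chrom]
        v = values[idx]
        starts = np.array([signal.tiles[i].start for i in idx])
        ends = np.array([signal.tiles[i].end for i in idx])
        groups = _peak_tiles(v, starts, ends, cutoff, window_bp, min_tiles)
        # null distribution of the maximum peak size under permutation
        null_max = np.zeros(n_randomizations, dtype=int)
        for r in range(n_randomizations):
            perm = rng.permutation(v)
            null_groups = _peak_tiles(perm, starts, ends, cutoff, window_bp, min_tiles)
            null_max[r] = max((len(g) for g in null_groups), default=0)
        for grp in groups:
            peaks.append(
                ChipPeak(
                    chromosome=chrom,
                    start=int(starts[grp[0]]),
                    end=int(ends[grp[-1]]),
                    n_tiles=len(grp),
                    max_signal=float(v[grp].max()),
                    fdr_score=float((null_max >= len(grp)).mean()),
                )
            )
    return peaks


def write_peaks_bed(peaks: list[ChipPeak], path) -> None:
    with open(path, "w") as fh:
        for i, p in enumerate(peaks):
            fh.write(
                f"{p.chromosome}\t{p.start}\t{p.end}\tpeak{i + 1}\t"
                f"{int(round((1 - p.fdr_score) * 1000))}\t.\n"
            )


# ---------------------------------------------------------------------------
# region scanning


@dataclass
class RegionHit:
    region_id: str
    gene: str | None
    hit: ScoredHit
    genome_position: int
    tss_distance: int | None = None


def scan_regions(
    classifier: MultiClassifier | RuleBase,
    genome: dict[str, str],
    annotation: GenomeAnnotation,
    kinds: tuple[str, ...] = ("intergenic",),
) -> list[RegionHit]:
    """Scan eligible annotated regions with the classifier.

    Regions flagged excluded (too-short intergenic gaps) are skipped and
    logged.  Hits carry submotif identity, strand, genome coordinates and,
    when the region's gene has a known TSS, the signed TSS distance of
    the site's TSS-proximal edge.  For a :class:`RuleBase` classifier the
    TSS distance is part of the antecedent, so regions without a TSS are
    skipped.
    """
    hits: list[RegionHit] = []
    gene_tss = {r.gene: r.tss for r in annotation.genes if r.gene}
    gene_strand = {r.gene: r.strand for r in annotation.genes if r.gene}
    for region in annotation.regions:
        if region.kind not in kinds:
            continue
        if region.excluded:
            logger.info("skipping excluded region %s (%d bp)",
                        region.region_id, region.length)
            continue
        chrom_seq = genome.get(region.chromosome)
        if chrom_seq is None or region.end > len(chrom_seq):
            raise ValidationError(
                f"region {region.region_id} outside genome sequence"
            )
        seq = chrom_seq[region.start : region.end]
        tss = gene_tss.get(region.gene)
        strand = gene_strand.get(region.gene, "+")
        if isinstance(classifier, MultiClassifier):
            region_hits = _scan_with_classifier(classifier, seq)
        else:
            if tss is None:
                logger.info("region %s has no TSS; skipped for rule scan",
                            region.region_id)
                continue
            region_hits = _scan_with_rules(
                classifier, seq, region.start, tss, strand
            )
        for h in region_hits:
            pos = region.start + h.position
            dist = None
            if tss is not None:
                dist = _tss_distance_interval(
                    pos, pos + _hit_length(classifier, h), tss, strand
                )
            hits.append(
                RegionHit(
                    region_id=region.region_id,
                    gene=region.gene,
                    hit=h,
                    genome_position=pos,
                    tss_distance=dist,
                )
            )
    return hits


def _hit_length(classifier, h: ScoredHit) -> int:
    if isinstance(classifier, MultiClassifier):
        for v in classifier.voters:
            if v.pwm.name == h.submotif:
                return v.pwm.length
    else:
        for r in classifier.rules:
            if r.submotif.label == h.submotif.split("&")[0]:
                return r.submotif.pwm.length
    raise ValidationError(f"unknown submotif {h.submotif}")


def _tss_distance_interval(start: int, end: int, tss: int, strand: str) -> int:
    """Signed offset of the site's TSS-proximal edge from the TSS."""
    if strand == "-":
        return tss - start if start > tss else tss - (end - 1)
    return (end - 1) - tss if end - 1 < tss else start - tss


def _scan_with_classifier(mc: MultiClassifier, seq: str) -> list[ScoredHit]:
    out = []
    for v in mc.active_voters:
        pwm = v.pwm
        old = pwm.threshold
        pwm.threshold = v.threshold
        try:
            out.extend(scan_window(pwm, seq))
        finally:
            pwm.threshold = old
    out.sort(key=lambda h: (-h.score, h.position))
    return out


def _scan_with_rules(
    rb: RuleBase, seq: str, region_start: int, tss: int, strand: str
) -> list[ScoredHit]:
    out = []
    lengths = {r.submotif.pwm.length for r in rb.rules}
    for L in lengths:
        for off in range(0, len(seq) - L + 1):
            window = seq[off : off + L]
            start = region_start + off
            dist = _tss_distance_interval(start, start + L, tss, strand)
            pos_ok, degree, fired = infer(rb, window, dist)
            if pos_ok:
                name = max(fired, key=lambda x: x[1])[0]
                out.append(ScoredHit(score=degree, position=off, strand="+",
                                     submotif=name))
            from .seqio import reverse_complement

            pos_ok, degree, fired = infer(rb, reverse_complement(window), dist)
            if pos_ok:
                name = max(fired, key=lambda x: x[1])[0]
                out.append(ScoredHit(score=degree, position=off, strand="-",
                                     submotif=name))
    out.sort(key=lambda h: (-h.score, h.position))
    return out


# ---------------------------------------------------------------------------
# gene categorization


@dataclass
class GeneCategoryTable:
    """Per-gene flags and the resulting five-way category."""

    rows: dict[str, dict] = field(default_factory=dict)

    def counts(self) -> dict[str, int]:
        out = {c: 0 for c in CATEGORIES}
        for row in self.rows.values():
            out[row["category"]] += 1
        return out

    def bs_fraction(self, category: str) -> float:
        rows = [r for r in self.rows.values() if r["category"] == category]
        if not rows:
            return float("nan")
        return sum(r["bs_found"] for r in rows) / len(rows)

    @property
    def method_fdr(self) -> float:
        """Site-positive fraction among genes with neither signal."""
        return self.bs_fraction("neither")

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("gene\texpression\tchip_peak\tbs_found\tcategory\n")
            for gene in sorted(self.rows):
                r = self.rows[gene]
                fh.write(
                    f"{gene}\t{int(r['expression'])}\t{int(r['chip_peak'])}\t"
                    f"{int(r['bs_found'])}\t{r['category']}\n"
                )


def categorize_genes(
    hits: list[RegionHit],
    expression_calls: dict[str, bool],
    peaks: list[ChipPeak],
    annotation: GenomeAnnotation,
    coding_hits: list[RegionHit] | None = None,
) -> GeneCategoryTable:
    """Assign each annotated gene to exactly one of the five categories.

    A gene's ChIP flag requires a peak overlapping its (non-excluded)
    intergenic region; genes with a coding-region peak but no expression
    go to the ``coding-peak`` category.  Unknown gene ids in the
    expression table raise a validation error.
    """
    genes = {r.gene: r for r in annotation.genes if r.gene}
    unknown = sorted(set(expression_calls) - set(genes))
    if unknown:
        raise ValidationError(f"unknown gene ids in expression calls: {unknown}")
    ig_by_gene = {
        r.gene: r for r in annotation.intergenic if r.gene and not r.excluded
    }
    hit_genes = {h.gene for h in hits if h.gene}
    coding_hit_genes = {h.gene for h in (coding_hits or []) if h.gene}
    table = GeneCategoryTable()
    for gene, grec in genes.items():
        expr = bool(expression_calls.get(gene, False))
        ig = ig_by_gene.get(gene)
        ig_peak = ig is not None and any(
            p.chromosome == ig.chromosome and p.start < ig.end and p.end > ig.start
            for p in peaks
        )
        coding_peak = any(
            p.chromosome == grec.chromosome
            and p.start < grec.end
            and p.end > grec.start
            for p in peaks
        )
        if expr and ig_peak:
            cat, bs = "expr+peak", gene in hit_genes
        elif expr:
            cat, bs = "expr-only", gene in hit_genes
        elif ig_peak:
            cat, bs = "peak-only", gene in hit_genes
        elif coding_peak:
            cat, bs = "coding-peak", gene in coding_hit_genes
        else:
            cat, bs = "neither", gene in hit_genes
        table.rows[gene] = {
            "expression": expr,
            "chip_peak": ig_peak or coding_peak,
            "bs_found": bool(bs),
            "category": cat,
        }
    return table


def submotif_presence_matrix(
    classifier: MultiClassifier,
    promoter_sets: dict[str, dict[str, str]],
    ortholog_table: dict[str, dict[str, str]] | None = None,
    tree=None,
    compress_families: bool = False,
):
    """Species x submotif matrix of promoter counts carrying each submotif.

    ``promoter_sets`` maps species -> {gene: promoter sequence}.  When an
    ortholog table (gene -> {species: ortholog gene}) is supplied only
    mapped genes are scanned; species missing from the table are excluded
    with a warning.  With ``compress_families`` counts roll up to each
    submotif's most general family via the supplied tree.
    """
    import pandas as pd

    names = [v.pwm.name for v in classifier.voters]
    if compress_families and tree is not None:
        fam = {n: tree.most_general_family(n) if n in tree.nodes else n
               for n in names}
    else:
        fam = {n: n for n in names}
    columns = sorted(set(fam.values()))
    rows = {}
    for species, promoters in promoter_sets.items():
        genes = promoters
        if ortholog_table is not None:
            mapped = {}
            for gene, per_species in ortholog_table.items():
                og = per_species.get(species)
                if og and og in promoters:
                    mapped[og] = promoters[og]
            genes = mapped
        counts = dict.fromkeys(columns, 0)
        for gene, seq in sorted(genes.items()):
            present = set()
            for v in classifier.active_voters:
                pwm = v.pwm
                old = pwm.threshold
                pwm.threshold = v.threshold
                try:
                    if scan_window(pwm, seq):
                        present.add(fam[pwm.name])
                finally:
                    pwm.threshold = old
            for f in present:
                counts[f] += 1
        rows[species] = counts
    return pd.DataFrame.from_dict(rows, orient="index", columns=columns).fillna(0)
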