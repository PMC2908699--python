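"""Data model and I/O for binding sites, annotations and motif files.

Binding sites are short, equal-length, pre-aligned DNA sequences carrying
promoter/genome metadata.  A :class:`SiteCollection` is the unit that the
clustering, classification and optimization stages operate on; it is encoded
into a binary indicator :class:`FeatureMatrix` (one column per base per
position) so that Euclidean geometry on rows reflects Hamming distance on
sequences.

Coordinates are 0-based half-open everywhere internally; GFF3's 1-based
closed intervals are converted at the parsing boundary.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
from Bio import SeqIO

from .errors import (
    AlphabetError,
    EmptyInputError,
    LengthMismatchError,
    ValidationError,
)

ALPHABET = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: columns of the fixed TSV site-table dialect
SITE_TSV_COLUMNS = ("site_id", "gene", "genome", "sequence", "tss_offset", "strand")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _check_alphabet(seq: str, where: str = "") -> None:
    bad = set(seq) - set(ALPHABET)
    if bad:
        raise AlphabetError(
            f"non-ACGT character(s) {sorted(bad)} in sequence {where or seq!r}"
        )


@dataclass
class BindingSite:
    """One aligned binding-site instance with its promoter metadata.

    ``tss_offset`` is the signed distance (bp) of the site from the
    transcription start site on the gene's strand; ``strand`` is the site's
    orientation relative to the annotated gene.
    """

    sequence: str
    site_id: str
    gene: str | None = None
    genome: str | None = None
    tss_offset: int | None = None
    strand: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValidationError(f"site {self.site_id!r}: empty sequence")
        self.sequence = self.sequence.upper()
        _check_alphabet(self.sequence, where=self.site_id)
        if self.strand not in (None, "+", "-"):
            raise ValidationError(
                f"site {self.site_id!r}: strand must be '+' or '-', got {self.strand!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class SiteCollection:
    """Ordered set of equal-length binding sites with unique ids."""

    sites: list[BindingSite]

    def __post_init__(self) -> None:
        if self.sites:
            lengths = {len(s) for s in self.sites}
            if len(lengths) > 1:
                raise LengthMismatchError(
                    f"sites have mixed lengths {sorted(lengths)}"
                )
            ids = [s.site_id for s in self.sites]
            if len(set(ids)) != len(ids):
                dup = sorted({i for i in ids if ids.count(i) > 1})
                raise ValidationError(f"duplicate site_ids: {dup}")

    @property
    def length(self) -> int:
        """Common site length L (0 for an empty collection)."""
        return len(self.sites[0]) if self.sites else 0

    @property
    def site_ids(self) -> list[str]:
        return [s.site_id for s in self.sites]

    @property
    def sequences(self) -> list[str]:
        return [s.sequence for s in self.sites]

    def __len__(self) -> int:
        return len(self.sites)

    def __iter__(self) -> Iterator[BindingSite]:
        return iter(self.sites)

    def __getitem__(self, key) -> BindingSite:
        return self.sites[key]

    def subset(self, site_ids: Sequence[str]) -> "SiteCollection":
        """Sites with the given ids, in collection order."""
        wanted = set(site_ids)
        missing = wanted - set(self.site_ids)
        if missing:
            raise ValidationError(f"unknown site_ids: {sorted(missing)}")
        return SiteCollection([s for s in self.sites if s.site_id in wanted])

    def partition_by_genome(self) -> dict[str, "SiteCollection"]:
        out: dict[str, list[BindingSite]] = {}
        for s in self.sites:
            out.setdefault(s.genome or "", []).append(s)
        return {g: SiteCollection(ss) for g, ss in out.items()}


@dataclass
class FeatureMatrix:
    """Binary indicator encoding: one row per site, 4·L columns.

    Column ``4*p + b`` is 1 iff the site has base ``ALPHABET[b]`` at
    position ``p``.  Squared Euclidean distance between rows equals twice
    the Hamming distance between the underlying sequences.
    """

    data: np.ndarray
    site_ids: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.site_ids):
            raise ValidationError("feature matrix shape inconsistent with site ids")

    @property
    def n_sites(self) -> int:
        return self.data.shape[0]

    @property
    def site_length(self) -> int:
        return self.data.shape[1] // 4


def one_hot_encode(collection: SiteCollection) -> FeatureMatrix:
    """Encode a collection as a binary indicator matrix (dummy variables)."""
    if len(collection) == 0:
        raise EmptyInputError("cannot encode an empty collection")
    L = collection.length
    data = np.zeros((len(collection), 4 * L))
    for r, site in enumerate(collection):
        for p, base in enumerate(site.sequence):
            data[r, 4 * p + BASE_INDEX[base]] = 1.0
    return FeatureMatrix(data, collection.site_ids)


def decode_features(row: np.ndarray) -> str:
    """Inverse of :func:`one_hot_encode` for a single (possibly soft) row."""
    L = row.size // 4
    blocks = np.asarray(row, dtype=float).reshape(L, 4)
    return "".join(ALPHABET[i] for i in blocks.argmax(axis=1))


# ---------------------------------------------------------------------------
# site tables


def read_sites(path: str | Path, length_policy: str = "strict") -> SiteCollection:
    """Read binding sites from FASTA or from the TSV site-table dialect.

    Format is chosen by extension (``.fa/.fasta/.fna`` -> FASTA, anything
    else -> TSV).  Under ``length_policy="trim"`` all sequences are
    right-trimmed to the shortest; under ``"strict"`` ragged input raises
    :class:`LengthMismatchError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if length_policy not in ("strict", "trim"):
        raise ValidationError(f"unknown length_policy {length_policy!r}")
    if path.suffix.lower() in (".fa", ".fasta", ".fna"):
        sites = [
            BindingSite(sequence=str(rec.seq), site_id=rec.id)
            for rec in SeqIO.parse(str(path), "fasta")
        ]
    else:
        sites = _read_sites_tsv(path)
    if not sites:
        raise EmptyInputError(f"no sites in {path}")
    lengths = {len(s) for s in sites}
    if len(lengths) > 1:
        if length_policy == "strict":
            raise LengthMismatchError(
                f"{path}: site lengths {sorted(lengths)} (policy=strict)"
            )
        L = min(lengths)
        for s in sites:
            s.sequence = s.sequence[:L]
    return SiteCollection(sites)


def _read_sites_tsv(path: Path) -> list[BindingSite]:
    sites = []
    with open(path) as fh:
        reader = csv.DictReader(
            (line for line in fh if not line.startswith("#")), delimiter="\t"
        )
        if reader.fieldnames is None or "sequence" not in reader.fieldnames:
            raise ValidationError(f"{path}: missing 'sequence' column")
        for row in reader:
            off = row.get("tss_offset")
            sites.append(
                BindingSite(
                    sequence=row["sequence"],
                    site_id=row.get("site_id") or f"site{len(sites) + 1}",
                    gene=row.get("gene") or None,
                    genome=row.get("genome") or None,
                    tss_offset=int(off) if off not in (None, "", "NA") else None,
                    strand=row.get("strand") or None,
                )
            )
    return sites


def write_sites(collection: SiteCollection, path: str | Path) -> None:
    """Write the TSV site-table dialect (lossless round-trip)."""
    with open(path, "w") as fh:
        fh.write("\t".join(SITE_TSV_COLUMNS) + "\n")
        for s in collection:
            fh.write(
                "\t".join(
                    [
                        s.site_id,
                        s.gene or "",
                        s.genome or "",
                        s.sequence,
                        "" if s.tss_offset is None else str(s.tss_offset),
                        s.strand or "",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# genome annotation


@dataclass
class Region:
    """Genomic interval, 0-based half-open."""

    region_id: str
    chromosome: str
    start: int
    end: int
    strand: str = "+"
    kind: str = "coding"  # {"coding", "intergenic"}
    gene: str | None = None
    operon_head: bool = True
    tss: int | None = None
    excluded: bool = False

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(
                f"region {self.region_id}: start {self.start} >= end {self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GenomeAnnotation:
    """Gene and intergenic regions of one or more chromosomes."""

    regions: list[Region] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.region_id for r in self.regions]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate region_ids: {dup}")

    def of_kind(self, kind: str) -> list[Region]:
        return [r for r in self.regions if r.kind == kind]

    @property
    def genes(self) -> list[Region]:
        return self.of_kind("coding")

    @property
    def intergenic(self) -> list[Region]:
        return self.of_kind("intergenic")


def compute_intergenic(
    genes: list[Region], min_length: int = 20
) -> list[Region]:
    """Gaps between consecutive genes per chromosome.

    Gaps of at most ``min_length`` bp are kept but flagged ``excluded``
    (the downstream scan requires strictly longer regions).
    """
    out: list[Region] = []
    by_chrom: dict[str, list[Region]] = {}
    for g in genes:
        by_chrom.setdefault(g.chromosome, []).append(g)
    for chrom, gs in by_chrom.items():
        gs = sorted(gs, key=lambda r: (r.start, r.end))
        for a, b in zip(gs, gs[1:]):
            if b.start < a.end:
                if b.start < a.start:  # overlapping genes tolerated; gap only
                    raise ValidationError(
                        f"malformed overlapping records: {a.region_id}, {b.region_id}"
                    )
                continue
            if b.start == a.end:
                continue
            region = Region(
                region_id=f"ig_{a.region_id}_{b.region_id}",
                chromosome=chrom,
                start=a.end,
                end=b.start,
                kind="intergenic",
                gene=b.gene,
                excluded=(b.start - a.end) <= min_length,
            )
            out.append(region)
    return out


def read_annotation(
    path: str | Path, min_intergenic: int = 20
) -> GenomeAnnotation:
    """Read gene annotation from GFF3 or BED and derive intergenic regions.

    BED intervals are taken as-is (0-based half-open).  GFF3 rows of type
    ``gene`` (or any row when no ``gene`` rows exist) are converted from
    1-based closed coordinates.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".bed":
        genes = _read_bed(path)
    else:
        genes = _read_gff3(path)
    if not genes:
        raise EmptyInputError(f"no gene records in {path}")
    regions = list(genes) + compute_intergenic(genes, min_length=min_intergenic)
    return GenomeAnnotation(regions)


def _read_bed(path: Path) -> list[Region]:
    genes = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            name = f[3] if len(f) > 3 else f"region{i + 1}"
            strand = f[5] if len(f) > 5 else "+"
            genes.append(
                Region(
                    region_id=name,
                    chromosome=f[0],
                    start=int(f[1]),
                    end=int(f[2]),
                    strand=strand,
                    kind="coding",
                    gene=name,
                    tss=int(f[1]) if strand == "+" else int(f[2]) - 1,
                )
            )
    return genes


def _read_gff3(path: Path) -> list[Region]:
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 8:
                raise ValidationError(f"{path}: malformed GFF3 line: {line!r}")
            attrs = {}
            if len(f) > 8:
                for kv in f[8].split(";"):
                    if "=" in kv:
                        k, v = kv.split("=", 1)
                        attrs[k.strip()] = v.strip()
            rows.append((f[0], f[2], int(f[3]), int(f[4]), f[6], attrs))
    gene_rows = [r for r in rows if r[1] == "gene"] or rows
    genes = []
    for i, (chrom, _, start1, end1, strand, attrs) in enumerate(gene_rows):
        name = attrs.get("ID") or attrs.get("Name") or f"gene{i + 1}"
        start, end = start1 - 1, end1  # GFF3 1-based closed -> half-open
        genes.append(
            Region(
                region_id=name,
                chromosome=chrom,
                start=start,
                end=end,
                strand=strand if strand in "+-" else "+",
                kind="coding",
                gene=name,
                operon_head=attrs.get("operon_head", "1") not in ("0", "false"),
                tss=start if strand != "-" else end - 1,
            )
        )
    return genes


def read_genome(path: str | Path) -> dict[str, str]:
    """Chromosome id -> uppercase sequence from a FASTA file."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def write_genome(genome: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# PWM files (the PWMModel class itself lives in dcmotif.encode)


def write_pwm(pwm, path: str | Path, format: str = "meme-minimal") -> None:
    """Write a PWM in MEME minimal motif format or as a plain TSV."""
    if format == "meme-minimal":
        _write_meme([pwm], path)
    elif format == "tsv":
        with open(path, "w") as fh:
            fh.write("# name\t" + pwm.name + "\n")
            fh.write("pos\tA\tC\tG\tT\n")
            for p in range(pwm.length):
                vals = "\t".join(f"{pwm.freqs[b, p]:.6f}" for b in range(4))
                fh.write(f"{p}\t{vals}\n")
    else:
        raise ValidationError(f"unknown PWM format {format!r}")


def write_pwms(pwms, path: str | Path) -> None:
    """Write several PWMs into one MEME-minimal file."""
    _write_meme(list(pwms), path)


def _write_meme(pwms, path) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        bg = pwms[0].background
        fh.write("Background letter frequencies\n")
        fh.write(
            " ".join(f"{b} {bg[i]:.6f}" for i, b in enumerate(ALPHABET)) + "\n\n"
        )
        for pwm in pwms:
            fh.write(f"MOTIF {pwm.name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {pwm.length} "
                f"nsites= 20 E= 0\n"
            )
            for p in range(pwm.length):
                fh.write(
                    " " + " ".join(f"{pwm.freqs[b, p]:.6f}" for b in range(4)) + "\n"
                )
            fh.write("\n")


def read_pwms(path: str | Path) -> list:
    """Read PWMs back from MEME minimal or the TSV dialect of write_pwm."""
    from .encode import PWMModel  # local import: avoid cycle

    path = Path(path)
    text = path.read_text()
    if text.startswith("MEME"):
        return _read_meme(text, PWMModel)
    # TSV dialect
    name = "pwm"
    cols = []
    for line in text.splitlines():
        if line.startswith("# name"):
            name = line.split("\t")[1]
        elif line and not line.startswith(("#", "pos")):
            f = line.split("\t")
            cols.append([float(x) for x in f[1:5]])
    freqs = np.array(cols).T
    return [PWMModel(freqs=freqs, name=name)]


def _read_meme(text: str, PWMModel) -> list:
    lines = text.splitlines()
    background = np.full(4, 0.25)
    pwms = []
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            parts = lines[i + 1].split()
            background = np.array([float(parts[2 * k + 1]) for k in range(4)])
            i += 2
            continue
        if line.startswith("MOTIF"):
            name = line.split()[1]
            i += 1
            while not lines[i].strip().startswith("letter-probability"):
                i += 1
            header = lines[i]
            w = int(header.split("w=")[1].split()[0])
            cols = []
            for p in range(w):
                i += 1
                cols.append([float(x) for x in lines[i].split()])
            pwms.append(
                PWMModel(
                    freqs=np.array(cols).T, background=background.copy(), name=name
                )
            )
        i += 1
    return pwms
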