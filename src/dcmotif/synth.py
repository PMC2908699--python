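"""Seeded synthetic-data generators for the whole pipeline.

Every generator is a pure function of (config, seed): planted submotif
PWMs with family structure, site samples, Markov background, decoy
negatives, and a full genome fixture (annotation, planted sites, tiling
signal with planted peaks, expression calls, ortholog table) with ground
truth recorded alongside.  Fixtures are statistical stand-ins, not
imitations of any real regulon.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .divide import SubmotifTree, TreeNode
from .encode import PWMModel
from .errors import ConfigurationError
from .seqio import (
    ALPHABET,
    BindingSite,
    GenomeAnnotation,
    Region,
    SiteCollection,
    compute_intergenic,
    write_genome,
    write_sites,
)
from .scan import Tile, TilingSignal

#: default distance-class apexes (bp upstream of the TSS) per family
DEFAULT_APEXES = (-34.0, -44.0, -68.0)


@dataclass
class SynthConfig:
    """Knobs of the synthetic fixture; ``seed`` is mandatory."""

    seed: int
    n_families: int = 3
    submotifs_per_family: int = 1
    site_length: int = 19
    sites_per_submotif: int = 20
    parent_conservation: float = 0.85
    child_conservation: float = 0.95
    weak_tandem_families: tuple[int, ...] = ()  # families with one weak tandem
    gc: float = 0.5
    background_order: int = 0
    n_negatives: int = 60
    n_decoy_pwms: int = 3
    distance_apexes: tuple[float, ...] = DEFAULT_APEXES
    distance_halfwidth: float = 8.0
    genome_length: int = 42000
    gene_length: int = 400
    intergenic_length: int = 200
    n_planted_genes: int = 6
    tile_width: int = 50
    peak_height: float = 4.0
    noise_sd: float = 0.3

    def __post_init__(self) -> None:
        if not (0.0 < self.gc < 1.0):
            raise ConfigurationError("GC content must lie in (0, 1)")
        if min(self.n_families, self.sites_per_submotif, self.n_negatives) < 0:
            raise ConfigurationError("counts must be >= 0")

    @property
    def composition(self) -> np.ndarray:
        at = (1.0 - self.gc) / 2.0
        return np.array([at, self.gc / 2.0, self.gc / 2.0, at])


AT_RICH_COMPOSITION = np.array([0.35, 0.15, 0.15, 0.35])  # pi_AT = 0.7


def _hexamer_blocks(L: int) -> tuple[slice, slice]:
    """The two direct-repeat tandem blocks of an L-bp box (hexamer+spacer+hexamer)."""
    return slice(0, 6), slice(9, 15)


def _pwm_from_consensus(
    consensus: str,
    strong: np.ndarray,
    strong_p: float,
    weak_p: float,
) -> np.ndarray:
    L = len(consensus)
    freqs = np.empty((4, L))
    for p, base in enumerate(consensus):
        target = strong_p if strong[p] else weak_p
        rest = (1.0 - target) / 3.0
        freqs[:, p] = rest
        freqs[ALPHABET.index(base), p] = target
    return freqs


def make_submotif_pwms(
    config: SynthConfig,
) -> tuple[list[PWMModel], SubmotifTree, dict[str, str]]:
    """Family-structured planted PWMs plus their ground-truth hierarchy.

    Family parents conserve both tandem blocks at ``parent_conservation``
    (families listed in ``weak_tandem_families`` conserve only the second
    tandem, mirroring a one-strong-repeat profile); children sharpen one
    tandem to ``child_conservation``.  Returns (pwms, tree, family_of).
    """
    rng = np.random.default_rng(config.seed)
    L = config.site_length
    t1, t2 = _hexamer_blocks(L)
    pwms: list[PWMModel] = []
    family_of: dict[str, str] = {}
    nodes = {"root": TreeNode(node_id="root", member_ids=frozenset(), source="truth")}
    for fam in range(config.n_families):
        consensus = "".join(rng.choice(list(ALPHABET), size=L))
        strong = np.zeros(L, dtype=bool)
        strong[t2] = True
        if fam not in config.weak_tandem_families:
            strong[t1] = True
        parent_name = f"F{fam + 1}"
        freqs = _pwm_from_consensus(
            consensus, strong, config.parent_conservation, 0.30
        )
        pwms.append(PWMModel(freqs=freqs, name=parent_name))
        family_of[parent_name] = parent_name
        nodes[parent_name] = TreeNode(
            node_id=parent_name, member_ids=frozenset(), parent="root",
            source="truth",
        )
        nodes["root"].children.append(parent_name)
        for child in range(config.submotifs_per_family - 1):
            sharpen = t1 if child % 2 == 0 else t2
            strong_c = strong.copy()
            cons_c = list(consensus)
            # children differentiate by one tandem substitution
            swap_pos = (sharpen.start + child) % L
            cons_c[swap_pos] = rng.choice(
                [b for b in ALPHABET if b != cons_c[swap_pos]]
            )
            freqs_c = _pwm_from_consensus(
                "".join(cons_c), strong_c, config.parent_conservation, 0.30
            )
            block = np.zeros(L, dtype=bool)
            block[sharpen] = True
            freqs_sharp = _pwm_from_consensus(
                "".join(cons_c), block, config.child_conservation, 0.30
            )
            freqs_c[:, block] = freqs_sharp[:, block]
            name = f"{parent_name}.{child + 1}"
            pwms.append(PWMModel(freqs=freqs_c, name=name))
            family_of[name] = parent_name
            nodes[name] = TreeNode(
                node_id=name, member_ids=frozenset(), parent=parent_name,
                source="truth",
            )
            nodes[parent_name].children.append(name)
    return pwms, SubmotifTree(nodes=nodes, root="root"), family_of


def sample_sites(
    pwm: PWMModel, n: int, seed: int, prefix: str = "site", **site_kwargs
) -> SiteCollection:
    """Draw ``n`` i.i.d. sites column-wise from a PWM."""
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    rng = np.random.default_rng(seed)
    sites = []
    for i in range(n):
        seq = "".join(
            ALPHABET[rng.choice(4, p=pwm.freqs[:, p])] for p in range(pwm.length)
        )
        sites.append(
            BindingSite(sequence=seq, site_id=f"{prefix}{i + 1}", **site_kwargs)
        )
    return SiteCollection(sites)


def sample_background(
    order: int,
    composition,
    length: int,
    n: int,
    seed: int,
    autocorrelation: float = 0.2,
) -> list[str]:
    """Markov-chain background sequences matching a target composition.

    Order 0 draws i.i.d. bases; orders 1-2 condition on the previous base
    (previous two bases collapse to the last one) with a mild
    self-transition boost, keeping the stationary composition close to
    the target.
    """
    if order not in (0, 1, 2):
        raise ConfigurationError("order must be 0, 1 or 2")
    if length < 1 or n < 1:
        raise ConfigurationError("length and n must be >= 1")
    comp = np.asarray(composition, dtype=float)
    comp = comp / comp.sum()
    rng = np.random.default_rng(seed)
    out = []
    if order == 0:
        for _ in range(n):
            out.append("".join(ALPHABET[i] for i in rng.choice(4, size=length, p=comp)))
        return out
    trans = np.tile(comp, (4, 1))
    trans[np.arange(4), np.arange(4)] *= 1.0 + autocorrelation
    trans /= trans.sum(axis=1, keepdims=True)
    for _ in range(n):
        seq = [int(rng.choice(4, p=comp))]
        for _ in range(length - 1):
            seq.append(int(rng.choice(4, p=trans[seq[-1]])))
        out.append("".join(ALPHABET[i] for i in seq))
    return out


def sample_distances(
    apex: float, n: int, seed: int, halfwidth: float = 8.0
) -> np.ndarray:
    """Integer TSS offsets from a triangular distribution around an apex."""
    rng = np.random.default_rng(seed)
    vals = rng.triangular(apex - halfwidth, apex, apex + halfwidth, size=n)
    return np.round(vals).astype(int)


def make_decoy_pwms(
    pwms: list[PWMModel], n: int, seed: int
) -> list[PWMModel]:
    """Decoy PWMs: column permutations of real submotif PWMs.

    A column-shuffled motif keeps the composition statistics of a genuine
    binding site — the stand-in for "binding sites of other TFs" as a
    stringent negative class.
    """
    rng = np.random.default_rng(seed)
    decoys = []
    for d in range(n):
        src = pwms[d % len(pwms)]
        L = src.length
        perm = rng.permutation(L)
        while (perm == np.arange(L)).all():
            perm = rng.permutation(L)
        decoys.append(
            PWMModel(
                freqs=src.freqs[:, perm],
                background=src.background.copy(),
                name=f"decoy{d + 1}",
            )
        )
    return decoys


def make_negatives(
    config: SynthConfig, pwms: list[PWMModel] | None = None
) -> SiteCollection:
    """Decoy negatives: other-TF-like PWM sites plus background windows."""
    rng = np.random.default_rng(config.seed + 101)
    L = config.site_length
    sites = []
    n_decoy = config.n_negatives // 2 if config.n_decoy_pwms else 0
    if config.n_decoy_pwms:
        if pwms:
            decoys = make_decoy_pwms(pwms, config.n_decoy_pwms, config.seed + 151)
        else:
            decoys = []
            for d in range(config.n_decoy_pwms):
                consensus = "".join(rng.choice(list(ALPHABET), size=L))
                decoys.append(
                    PWMModel(
                        freqs=_pwm_from_consensus(
                            consensus, np.ones(L, dtype=bool), 0.70, 0.30
                        ),
                        name=f"decoy{d + 1}",
                    )
                )
        per = max(1, n_decoy // config.n_decoy_pwms)
        for d, decoy in enumerate(decoys):
            for s in sample_sites(
                decoy, per, seed=config.seed + 211 + d, prefix=f"neg_d{d + 1}_"
            ):
                sites.append(s)
    n_bg = config.n_negatives - len(sites)
    for i, seq in enumerate(
        sample_background(
            config.background_order, config.composition, L, max(n_bg, 0),
            seed=config.seed + 307,
        )
    ):
        sites.append(BindingSite(sequence=seq, site_id=f"neg_bg{i + 1}"))
    return SiteCollection(sites[: config.n_negatives])


@dataclass
class SynthDataset:
    """Full cross-referenced fixture with ground truth."""

    config: SynthConfig
    pwms: list[PWMModel]
    tree: SubmotifTree
    family_of: dict[str, str]
    positives: SiteCollection
    site_family: dict[str, str]
    negatives: SiteCollection
    genome: dict[str, str]
    annotation: GenomeAnnotation
    planted: list[dict] = field(default_factory=list)
    signal: TilingSignal | None = None
    expression_calls: dict[str, bool] = field(default_factory=dict)
    category_truth: dict[str, str] = field(default_factory=dict)
    ortholog_table: dict[str, dict[str, str]] = field(default_factory=dict)


def make_dataset(config: SynthConfig) -> SynthDataset:
    """Generate the complete pipeline fixture from one config + seed."""
    rng = np.random.default_rng(config.seed)
    L = config.site_length
    pwms, tree, family_of = make_submotif_pwms(config)
    families = sorted({family_of[p.name] for p in pwms})
    apexes = dict(
        zip(
            families,
            list(config.distance_apexes)
            * (len(families) // max(len(config.distance_apexes), 1) + 1),
        )
    )

    # positives with planted distances, alternating between two genome labels
    positives_sites = []
    site_family: dict[str, str] = {}
    for k, pwm in enumerate(pwms):
        fam = family_of[pwm.name]
        dists = sample_distances(
            apexes[fam],
            config.sites_per_submotif,
            seed=config.seed + 13 + k,
            halfwidth=config.distance_halfwidth,
        )
        coll = sample_sites(
            pwm, config.sites_per_submotif, seed=config.seed + 17 + k,
            prefix=f"{pwm.name}_s",
        )
        for i, s in enumerate(coll):
            s.gene = f"gene_{pwm.name}_{i + 1}"
            s.genome = "spA" if i % 2 == 0 else "spB"
            s.tss_offset = int(np.clip(dists[i], -90, 10))
            s.strand = "+"
            positives_sites.append(s)
            site_family[s.site_id] = fam
    positives = SiteCollection(positives_sites)
    negatives = make_negatives(config, pwms=pwms)

    # genome with regular gene/intergenic layout on one chromosome
    unit = config.gene_length + config.intergenic_length
    n_genes = max((config.genome_length - config.intergenic_length) // unit, 0)
    if config.n_planted_genes > n_genes:
        raise ConfigurationError(
            f"{config.n_planted_genes} planted genes exceed genome capacity {n_genes}"
        )
    chrom = list(
        sample_background(
            config.background_order, config.composition, config.genome_length, 1,
            seed=config.seed + 401,
        )[0]
    )
    genes = []
    for g in range(n_genes):
        start = config.intergenic_length + g * unit
        genes.append(
            Region(
                region_id=f"g{g + 1}",
                chromosome="chr1",
                start=start,
                end=start + config.gene_length,
                strand="+",
                kind="coding",
                gene=f"g{g + 1}",
                tss=start,
            )
        )
    planted = []
    planted_gene_idx = rng.choice(n_genes, size=config.n_planted_genes, replace=False)
    for j, gi in enumerate(sorted(planted_gene_idx)):
        pwm = pwms[j % len(pwms)]
        fam = family_of[pwm.name]
        site_seq = sample_sites(pwm, 1, seed=config.seed + 601 + j)[0].sequence
        d = int(
            np.clip(
                sample_distances(apexes[fam], 1, seed=config.seed + 701 + j)[0],
                -90,
                -int(L),
            )
        )
        tss = genes[gi].tss
        end = tss + d + 1
        start = end - L
        chrom[start:end] = list(site_seq)
        planted.append(
            {
                "gene": genes[gi].gene,
                "submotif": pwm.name,
                "family": fam,
                "start": start,
                "end": end,
                "tss_offset": d,
                "strand": "+",
            }
        )
    genome = {"chr1": "".join(chrom)}
    regions = genes + compute_intergenic(genes, min_length=20)
    annotation = GenomeAnnotation(regions)

    # category ground truth: planted genes are expressed with a peak;
    # a sprinkle of expression-only and peak-only among the rest
    planted_genes = {p["gene"] for p in planted}
    category_truth = {}
    expression_calls = {}
    peak_genes = set()
    others = [g.gene for g in genes if g.gene not in planted_genes]
    rng.shuffle(others)
    n_expr_only = min(3, len(others))
    n_peak_only = min(3, max(len(others) - n_expr_only, 0))
    for g in genes:
        name = g.gene
        if name in planted_genes:
            category_truth[name] = "expr+peak"
            expression_calls[name] = True
            peak_genes.add(name)
        elif name in others[:n_expr_only]:
            category_truth[name] = "expr-only"
            expression_calls[name] = True
        elif name in others[n_expr_only : n_expr_only + n_peak_only]:
            category_truth[name] = "peak-only"
            expression_calls[name] = False
            peak_genes.add(name)
        else:
            category_truth[name] = "neither"
            expression_calls[name] = False

    # tiling signal: noise plus a 6-tile boxcar over peak genes' intergenic
    tiles = []
    gene_by_name = {g.gene: g for g in genes}
    boxcar: dict[int, float] = {}
    for name in sorted(peak_genes):
        g = gene_by_name[name]
        first_tile = max((g.start - config.intergenic_length) // config.tile_width, 0)
        for t in range(first_tile, first_tile + 6):
            boxcar[t] = config.peak_height
    n_tiles = config.genome_length // config.tile_width
    noise = rng.normal(0.0, config.noise_sd, size=n_tiles)
    for t in range(n_tiles):
        tiles.append(
            Tile(
                chromosome="chr1",
                start=t * config.tile_width,
                end=(t + 1) * config.tile_width,
                log2_ratio=float(noise[t] + boxcar.get(t, 0.0)),
            )
        )
    signal = TilingSignal(tiles)

    # ortholog table: planted genes shared by both synthetic species
    ortholog_table = {
        p["gene"]: {"spA": p["gene"], "spB": p["gene"]} for p in planted
    }

    return SynthDataset(
        config=config,
        pwms=pwms,
        tree=tree,
        family_of=family_of,
        positives=positives,
        site_family=site_family,
        negatives=negatives,
        genome=genome,
        annotation=annotation,
        planted=planted,
        signal=signal,
        expression_calls=expression_calls,
        category_truth=category_truth,
        ortholog_table=ortholog_table,
    )


def write_dataset(dataset: SynthDataset, outdir: str | Path) -> list[Path]:
    """Write the fixture in the same text formats the pipeline reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    p = outdir / "positives.tsv"
    write_sites(dataset.positives, p)
    written.append(p)
    p = outdir / "negatives.tsv"
    write_sites(dataset.negatives, p)
    written.append(p)
    p = outdir / "genome.fa"
    write_genome(dataset.genome, p)
    written.append(p)

    p = outdir / "annotation.gff3"
    with open(p, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in dataset.annotation.genes:
            fh.write(
                f"{g.chromosome}\tsynth\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene}\n"
            )
    written.append(p)

    if dataset.signal is not None:
        p = outdir / "tiling_signal.tsv"
        dataset.signal.write_tsv(p)
        written.append(p)

    p = outdir / "expression_calls.tsv"
    with open(p, "w") as fh:
        fh.write("gene\texpressed\n")
        for gene in sorted(dataset.expression_calls):
            fh.write(f"{gene}\t{'yes' if dataset.expression_calls[gene] else 'no'}\n")
    written.append(p)

    p = outdir / "ortholog_table.tsv"
    with open(p, "w") as fh:
        fh.write("gene\tspA\tspB\n")
        for gene in sorted(dataset.ortholog_table):
            row = dataset.ortholog_table[gene]
            fh.write(f"{gene}\t{row.get('spA', '')}\t{row.get('spB', '')}\n")
    written.append(p)

    p = outdir / "ground_truth.yaml"
    truth = {
        "seed": dataset.config.seed,
        "families": sorted(set(dataset.family_of.values())),
        "site_family": dict(sorted(dataset.site_family.items())),
        "planted": dataset.planted,
        "category_truth": dict(sorted(dataset.category_truth.items())),
    }
    with open(p, "w") as fh:
        yaml.safe_dump(truth, fh, sort_keys=True)
    written.append(p)

    p = outdir / "submotifs.tree.json"
    p.write_text(dataset.tree.to_json())
    written.append(p)
    return written
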