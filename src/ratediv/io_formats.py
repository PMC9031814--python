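"""Readers and writers for the standard formats the pipeline touches.

Coordinate conventions: VCF positions are 1-based (as in the standard);
feature intervals, windows and all internal arithmetic use the 0-based
half-open frame. Genetic maps are tables of physical position (bp) against
cumulative genetic position (cM).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import dendropy
import pandas as pd

logger = logging.getLogger("ratediv")

FEATURE_LABELS = ("exon", "utr5", "utr3", "intron", "intergenic")


class FormatError(ValueError):
    """Raised when an input file cannot be parsed as its declared format."""


@dataclass
class GeneTree:
    """A gene's inferred phylogeny reduced to its branch-length multiset.

    ``branch_lengths`` holds every branch of the tree once (substitutions per
    site); the number of alignment columns behind the tree is
    ``alignment_length``. ML gene trees are effectively unrooted, so no root
    edge is ever synthesized and the two child branches of a rooted newick's
    root are kept as distinct branches.
    """

    gene_id: str
    branch_lengths: list[float]
    taxon_labels: list[str]
    alignment_length: int
    branch_ids: list[str] | None = None

    def __post_init__(self) -> None:
        if len(self.branch_lengths) < 1:
            raise ValueError(f"{self.gene_id}: tree must have at least one branch")
        if any(b < 0 for b in self.branch_lengths):
            raise ValueError(f"{self.gene_id}: negative branch length")
        if self.alignment_length < 1:
            raise ValueError(f"{self.gene_id}: alignment length must be >= 1")

    @property
    def n_branches(self) -> int:
        return len(self.branch_lengths)


@dataclass
class VariantRecord:
    """A biallelic SNP record: one alternate allele at one site."""

    chrom: str
    pos: int  # 1-based, VCF convention
    alt_allele_count: int
    total_chromosomes: int
    is_de_novo: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.alt_allele_count <= self.total_chromosomes):
            raise ValueError(
                f"{self.chrom}:{self.pos}: allele count {self.alt_allele_count} "
                f"outside [0, {self.total_chromosomes}]"
            )

    @property
    def pos0(self) -> int:
        """Position in the 0-based frame."""
        return self.pos - 1


@dataclass
class FeatureInterval:
    """A 0-based half-open genomic interval carrying a feature label."""

    chrom: str
    start: int
    end: int
    feature: str
    gene_id: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty interval {self.chrom}:{self.start}-{self.end}")
        if self.feature not in FEATURE_LABELS:
            raise ValueError(f"unknown feature label {self.feature!r}")

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass
class GeneticMap:
    """Physical position (bp) -> cumulative genetic position (cM) table."""

    chrom: str
    positions: list[int]
    cumulative_cM: list[float]

    def __post_init__(self) -> None:
        if len(self.positions) != len(self.cumulative_cM):
            raise ValueError("positions and cumulative_cM must have equal length")
        if any(b <= a for a, b in zip(self.positions, self.positions[1:])):
            raise ValueError(f"{self.chrom}: map positions must be strictly increasing")
        if any(b < a for a, b in zip(self.cumulative_cM, self.cumulative_cM[1:])):
            raise ValueError(f"{self.chrom}: cumulative cM must be non-decreasing")


# ---------------------------------------------------------------------------
# gene trees
# ---------------------------------------------------------------------------

def _tree_branches(tree: dendropy.Tree) -> tuple[list[float], list[str]]:
    """Branch lengths and leaf labels of a parsed tree.

    Every edge with a length is kept, including zero-length internal edges;
    the root's own edge (a stub with no length in standard newick) is not a
    branch of the tree.
    """
    lengths = []
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        lengths.append(float(node.edge.length) if node.edge.length is not None else 0.0)
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    return lengths, labels


def read_gene_trees(
    paths: Sequence[str | Path],
    alignment_lengths: dict[str, int],
) -> list[GeneTree]:
    """Read one newick tree per file; gene_id is the file stem.

    ``alignment_lengths`` is the sidecar table keyed by gene_id; a missing
    key is an error because downstream scaling needs the gene length.
    """
    trees = []
    for path in paths:
        path = Path(path)
        gene_id = path.stem
        try:
            tree = dendropy.Tree.get(path=str(path), schema="newick")
        except Exception as exc:  # dendropy raises several parse error types
            raise FormatError(f"unparsable newick in {path}: {exc}") from exc
        if gene_id not in alignment_lengths:
            raise KeyError(f"no alignment length for gene {gene_id!r}")
        lengths, labels = _tree_branches(tree)
        trees.append(
            GeneTree(
                gene_id=gene_id,
                branch_lengths=lengths,
                taxon_labels=labels,
                alignment_length=int(alignment_lengths[gene_id]),
            )
        )
    return trees


def read_alignment_lengths(path: str | Path) -> dict[str, int]:
    """Sidecar TSV with columns gene_id, alignment_length."""
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["gene_id"].astype(str), df["alignment_length"].astype(int)))


def write_gene_tree(tree: GeneTree, path: str | Path) -> None:
    """Write a GeneTree as newick preserving the branch-length multiset.

    Only the branch multiset and taxon labels are part of a GeneTree's
    contract, so an arbitrary deterministic topology is used: a star over the
    taxa carrying the first T branch lengths, wrapped in unary internal nodes
    that carry the remaining M - T lengths. Requires M >= T.
    """
    bl, labels = tree.branch_lengths, tree.taxon_labels
    if len(bl) < len(labels):
        raise ValueError("cannot place fewer branches than taxa in a newick tree")
    newick = "(" + ",".join(f"{lab}:{b:.12g}" for lab, b in zip(labels, bl)) + ")"
    for b in bl[len(labels):]:
        newick = f"({newick}:{b:.12g})"
    Path(path).write_text(newick + ";\n")


# ---------------------------------------------------------------------------
# variants
# ---------------------------------------------------------------------------

_SNP_ALLELES = frozenset("ACGT")


def read_variants(
    vcf_path: str | Path,
    region: tuple[str, int, int] | None = None,
    de_novo: bool = False,
) -> Iterator[VariantRecord]:
    """Stream biallelic SNP records from a VCF.

    Multi-allelic sites are split into one record per alternate allele.
    Allele counts come from INFO AC/AN when present, otherwise from
    genotypes. Indels and other non-SNP alleles are skipped with a logged
    counter. ``region`` is (chrom, start, end) in the 0-based half-open
    frame.
    """
    import pysam

    skipped = 0
    with pysam.VariantFile(str(vcf_path)) as vf:
        for rec in vf:
            if region is not None:
                chrom, start, end = region
                if rec.chrom != chrom or not (start <= rec.pos - 1 < end):
                    continue
            if rec.ref is None or len(rec.ref) != 1 or rec.ref not in _SNP_ALLELES:
                skipped += 1
                continue
            alts = rec.alts or ()
            acs, an = _allele_counts(rec)
            if acs is None:
                raise FormatError(
                    f"{vcf_path}:{rec.chrom}:{rec.pos}: no AC/AN and no genotypes"
                )
            for alt, ac in zip(alts, acs):
                if len(alt) != 1 or alt not in _SNP_ALLELES:
                    skipped += 1
                    continue
                yield VariantRecord(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    alt_allele_count=int(ac),
                    total_chromosomes=int(an),
                    is_de_novo=de_novo,
                )
    if skipped:
        logger.warning("read_variants: skipped %d non-SNP alleles in %s", skipped, vcf_path)


def _allele_counts(rec) -> tuple[list[int] | None, int]:
    """Per-alt allele counts and total chromosomes for a pysam record."""
    info = rec.info
    if "AC" in info and "AN" in info:
        ac = info["AC"]
        if isinstance(ac, int):
            ac = (ac,)
        return [int(a) for a in ac], int(info["AN"])
    if rec.samples:
        n_alts = len(rec.alts or ())
        counts = [0] * n_alts
        an = 0
        for sample in rec.samples.values():
            for allele in sample.allele_indices or ():
                if allele is None:
                    continue
                an += 1
                if allele >= 1:
                    counts[allele - 1] += 1
        return counts, an
    return None, 0


def write_variants_vcf(records: Iterable[VariantRecord], path: str | Path) -> None:
    """Write records as a minimal sites-only VCF with AC/AN in INFO."""
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=AC,Number=A,Type=Integer,Description="Alternate allele count">',
        '##INFO=<ID=AN,Number=1,Type=Integer,Description="Total alleles">',
    ]
    contigs = {}
    records = list(records)
    for r in records:
        contigs[r.chrom] = max(contigs.get(r.chrom, 0), r.pos)
    for chrom, maxpos in contigs.items():
        lines.append(f"##contig=<ID={chrom},length={maxpos + 1000}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for r in records:
        lines.append(
            f"{r.chrom}\t{r.pos}\t.\tA\tG\t.\t.\tAC={r.alt_allele_count};AN={r.total_chromosomes}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# feature tracks and genetic maps
# ---------------------------------------------------------------------------

def read_features(path: str | Path) -> list[FeatureInterval]:
    """BED5-like track: chrom start end feature gene_id (whitespace-separated).

    Intervals come back sorted by (chrom, start); overlaps are preserved —
    overlap resolution belongs to window feature assignment, not ingestion.
    """
    df = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        names=["chrom", "start", "end", "feature", "gene_id"],
        dtype={"chrom": str, "feature": str},
        na_filter=False,
    )
    bad = set(df["feature"]) - set(FEATURE_LABELS)
    if bad:
        raise FormatError(f"{path}: unknown feature labels {sorted(bad)}")
    df = df.sort_values(["chrom", "start"], kind="stable")
    return [
        FeatureInterval(r.chrom, int(r.start), int(r.end), r.feature, str(r.gene_id))
        for r in df.itertuples(index=False)
    ]


def read_genetic_map(path: str | Path, chrom: str = "chr1") -> GeneticMap:
    """Two-column whitespace table: position_bp cumulative_cM."""
    df = pd.read_csv(path, sep=r"\s+", header=None, names=["pos", "cM"], comment="#")
    positions = [int(p) for p in df["pos"]]
    if any(b <= a for a, b in zip(positions, positions[1:])):
        raise FormatError(f"{path}: map positions not strictly increasing")
    return GeneticMap(chrom=chrom, positions=positions, cumulative_cM=[float(c) for c in df["cM"]])


def read_tracks(
    feature_path: str | Path, map_path: str | Path, chrom: str = "chr1"
) -> tuple[list[FeatureInterval], GeneticMap]:
    return read_features(feature_path), read_genetic_map(map_path, chrom=chrom)


def write_features(features: Iterable[FeatureInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for f in features:
            fh.write(f"{f.chrom}\t{f.start}\t{f.end}\t{f.feature}\t{f.gene_id}\n")


def write_genetic_map(gmap: GeneticMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for pos, cm in zip(gmap.positions, gmap.cumulative_cM):
            fh.write(f"{pos}\t{cm:.10g}\n")


def read_gene_sets(path: str | Path) -> dict[str, list[str]]:
    """Gene-set definitions as a two-column TSV: set_id, gene_id."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return {sid: list(sub["gene_id"]) for sid, sub in df.groupby("set_id", sort=True)}


def write_gene_sets(sets: dict[str, list[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("set_id\tgene_id\n")
        for sid in sets:
            for gid in sets[sid]:
                fh.write(f"{sid}\t{gid}\n")
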