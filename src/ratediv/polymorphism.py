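"""Per-gene and per-window intraspecific diversity statistics.

The primary diversity measure is q, the proportion of segregating sites of a
gene (segregating sites K over gene length L). Nucleotide diversity pi is
computed per fixed-width window as the unbiased mean pairwise difference per
site. Windows are labelled with the genomic feature class they mostly
overlap, and their genetic-map position supports recombination-distance
lookups for the background-selection model.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_formats import FeatureInterval, GeneticMap, VariantRecord

logger = logging.getLogger("ratediv")

WINDOW_WIDTH = 1000
INTERGENIC_DISTANCE = 100_000
# on exact majority ties the more constrained class wins
FEATURE_PRECEDENCE = ("exon", "utr5", "utr3", "intron")


@dataclass
class GenePolymorphism:
    """Per-gene polymorphism counts; q = K / L is the diversity measure."""

    gene_id: str
    K: int
    singletons: int
    de_novo: int
    L: int
    chrom: str
    is_X: bool

    @property
    def q(self) -> float:
        return self.K / self.L


@dataclass
class WindowDiversity:
    """One fixed-width window's diversity, feature label and map position."""

    chrom: str
    start: int  # 0-based, half-open window [start, start + WINDOW_WIDTH)
    pi: float
    feature: str = "intergenic"
    map_cM: float = float("nan")


def singleton_allele_frequency(n_diploid_individuals: int) -> float:
    """Allele frequency of an autosomal singleton in a diploid cohort.

    A singleton sits on exactly one of the 2n sampled chromosomes, e.g.
    1/5008 for a 2504-individual cohort.
    """
    return 1.0 / (2 * n_diploid_individuals)


def _is_segregating(v: VariantRecord) -> bool:
    return 0 < v.alt_allele_count < v.total_chromosomes


def _is_singleton_site(alt_counts: list[int], total: int) -> bool:
    """A site where some allele is observed on exactly one chromosome.

    Either an alternate allele has count 1, or the reference remains on a
    single chromosome; polarity by ancestral allele is not used.
    """
    ref_count = total - sum(alt_counts)
    return any(c == 1 for c in alt_counts) or ref_count == 1


def tabulate_gene_variation(
    variants: Iterable[VariantRecord],
    genes: Sequence[FeatureInterval],
    denovo: Iterable[VariantRecord] = (),
    x_chroms: frozenset[str] = frozenset({"X", "chrX"}),
    count_shared_sites_once_per_gene: bool = True,
) -> pd.DataFrame:
    """Per-gene segregating-site / singleton / de-novo counts.

    A gene's length L is the union width of its intervals; K counts distinct
    polymorphic positions inside that union (a multi-allelic position counts
    once), singletons count positions carrying an allele seen on exactly one
    chromosome, and de-novo records are tallied separately. A site inside
    two overlapping genes counts once in each by default.
    """
    gene_ivs: dict[str, list[FeatureInterval]] = {}
    for iv in genes:
        if iv.gene_id:
            gene_ivs.setdefault(iv.gene_id, []).append(iv)

    lengths, chroms = {}, {}
    for gid, ivs in gene_ivs.items():
        merged = _merge_intervals([(iv.start, iv.end) for iv in ivs])
        lengths[gid] = sum(e - s for s, e in merged)
        chroms[gid] = ivs[0].chrom
        gene_ivs[gid] = merged  # type: ignore[assignment]

    zero_len = [g for g, L in lengths.items() if L == 0]
    for g in zero_len:
        logger.warning("gene %s has zero length; excluded", g)
        del lengths[g]

    # group alt alleles by site so multi-allelic positions count once for K
    by_site: dict[tuple[str, int], list[VariantRecord]] = {}
    for v in variants:
        by_site.setdefault((v.chrom, v.pos), []).append(v)

    K = {g: 0 for g in lengths}
    singles = {g: 0 for g in lengths}
    dn = {g: 0 for g in lengths}

    for (chrom, pos), recs in by_site.items():
        seg = any(_is_segregating(r) for r in recs)
        if not seg:
            continue
        single = _is_singleton_site(
            [r.alt_allele_count for r in recs], recs[0].total_chromosomes
        )
        for gid in lengths:
            if chroms[gid] == chrom and _in_union(pos - 1, gene_ivs[gid]):
                K[gid] += 1
                if single:
                    singles[gid] += 1
                if not count_shared_sites_once_per_gene:
                    break

    for v in denovo:
        for gid in lengths:
            if chroms[gid] == v.chrom and _in_union(v.pos - 1, gene_ivs[gid]):
                dn[gid] += 1

    gids = sorted(lengths)
    return pd.DataFrame(
        {
            "gene_id": gids,
            "K": [K[g] for g in gids],
            "singletons": [singles[g] for g in gids],
            "de_novo": [dn[g] for g in gids],
            "L": [lengths[g] for g in gids],
            "q": [K[g] / lengths[g] for g in gids],
            "chrom": [chroms[g] for g in gids],
            "is_X": [chroms[g] in x_chroms for g in gids],
        }
    )


def _merge_intervals(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for s, e in sorted(ivs):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def _in_union(pos0: int, merged: list[tuple[int, int]]) -> bool:
    for s, e in merged:
        if s <= pos0 < e:
            return True
    return False


def window_pi(
    variants: Iterable[VariantRecord],
    chrom_length: int,
    chrom: str = "chr1",
    width: int = WINDOW_WIDTH,
) -> list[WindowDiversity]:
    """Nucleotide diversity per fixed-width window.

    Per site, the unbiased heterozygosity is 2 p (1 - p) n / (n - 1) with p
    the alternate-allele frequency among n chromosomes; a window's pi is the
    sum over its sites divided by the window width. Sites with n < 2 are
    skipped with a warning.
    """
    n_windows = max(1, math.ceil(chrom_length / width))
    het = np.zeros(n_windows)
    skipped = 0
    for v in variants:
        if v.chrom != chrom:
            continue
        n = v.total_chromosomes
        if n < 2:
            skipped += 1
            continue
        w = v.pos0 // width
        if w >= n_windows:
            continue
        p = v.alt_allele_count / n
        het[w] += 2.0 * p * (1.0 - p) * n / (n - 1)
    if skipped:
        logger.warning("window_pi: skipped %d sites with < 2 chromosomes", skipped)
    return [
        WindowDiversity(chrom=chrom, start=w * width, pi=het[w] / width)
        for w in range(n_windows)
    ]


def assign_window_feature(
    windows: list[WindowDiversity],
    features: Sequence[FeatureInterval],
    intergenic_distance: int = INTERGENIC_DISTANCE,
) -> list[WindowDiversity]:
    """Label each window with its majority-overlap feature class.

    A window farther than ``intergenic_distance`` from every gene boundary
    (interval start or end of any gene-associated feature) is intergenic.
    Otherwise the label is the feature class covering the most bases of the
    window, with the precedence exon > utr5 > utr3 > intron on exact ties;
    a window overlapping no feature at all is also intergenic.
    """
    boundaries: dict[str, list[int]] = {}
    by_chrom: dict[str, list[FeatureInterval]] = {}
    for f in features:
        by_chrom.setdefault(f.chrom, []).append(f)
        if f.gene_id:
            boundaries.setdefault(f.chrom, []).extend((f.start, f.end))

    for w in windows:
        ws, we = w.start, w.start + WINDOW_WIDTH
        bnds = boundaries.get(w.chrom, [])
        dist = min((_interval_point_distance(ws, we, b) for b in bnds), default=math.inf)
        if dist > intergenic_distance:
            w.feature = "intergenic"
            continue
        overlap = {f: 0 for f in FEATURE_PRECEDENCE}
        for iv in by_chrom.get(w.chrom, []):
            if iv.feature in overlap:
                overlap[iv.feature] += max(0, min(we, iv.end) - max(ws, iv.start))
        best = max(overlap.values())
        if best == 0:
            w.feature = "intergenic"
        else:
            # precedence order breaks exact ties
            w.feature = next(f for f in FEATURE_PRECEDENCE if overlap[f] == best)
    return windows


def _interval_point_distance(start: int, end: int, point: int) -> int:
    if point < start:
        return start - point
    if point >= end:
        return point - (end - 1)
    return 0


def interpolate_cM(gmap: GeneticMap, pos: int) -> float:
    """Cumulative genetic position at a physical position, linearly
    interpolated (and linearly extrapolated beyond the map's ends)."""
    if not gmap.positions:
        raise ValueError("empty genetic map")
    xp = np.asarray(gmap.positions, dtype=float)
    fp = np.asarray(gmap.cumulative_cM, dtype=float)
    if len(xp) == 1:
        return float(fp[0])
    if pos <= xp[0]:
        slope = (fp[1] - fp[0]) / (xp[1] - xp[0])
        return float(fp[0] + slope * (pos - xp[0]))
    if pos >= xp[-1]:
        slope = (fp[-1] - fp[-2]) / (xp[-1] - xp[-2])
        return float(fp[-1] + slope * (pos - xp[-1]))
    return float(np.interp(pos, xp, fp))


def haldane_fraction(d_cM: float) -> float:
    """Haldane map function: cM distance -> recombination fraction < 0.5."""
    return 0.5 * (1.0 - math.exp(-2.0 * abs(d_cM) / 100.0))


def window_recombination(
    window: WindowDiversity, gmap: GeneticMap, target_pos: int
) -> float:
    """Recombination fraction between a window's midpoint and a target locus.

    Distances are taken on the genetic map (linear interpolation of
    cumulative cM) and converted with the Haldane map function, so the
    result lies in [0, 0.5).
    """
    mid = window.start + WINDOW_WIDTH // 2
    d = interpolate_cM(gmap, target_pos) - interpolate_cM(gmap, mid)
    return haldane_fraction(d)


def attach_map_positions(
    windows: list[WindowDiversity], gmap: GeneticMap
) -> list[WindowDiversity]:
    for w in windows:
        w.map_cM = interpolate_cM(gmap, w.start + WINDOW_WIDTH // 2)
    return windows


def windows_to_frame(windows: list[WindowDiversity]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [w.chrom for w in windows],
            "start": [w.start for w in windows],
            "pi": [w.pi for w in windows],
            "feature": [w.feature for w in windows],
            "map_cM": [w.map_cM for w in windows],
        }
    )
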