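"""Region→gene association via regulatory domains, expression summaries,
and term enrichment.

Genes receive a basal regulatory domain (5 kb upstream / 1 kb downstream of
the TSS, strand-aware) extended toward the nearest neighboring basal domain
up to a 1 Mb cap — the "basal plus extension" association rule.  Peaks are
assigned to every gene whose extended domain contains the peak midpoint.
Enrichment of gene sets over a cluster's peaks is tested two ways: a
region-based binomial test against the genomic fraction covered by the term's
domains, and a gene-based hypergeometric test on associated genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .clustering import ClusterResult
from .intervals import GenomicInterval, GenomicIntervalSet, midpoint_assign
from .matrix import SampleMatrix

__all__ = [
    "GeneModel",
    "RegulatoryDomain",
    "read_gene_models",
    "read_gmt",
    "build_domains",
    "domains_interval_set",
    "region_log2fc_filter",
    "peak_anova",
    "associate_regions",
    "cluster_expression_summary",
    "term_enrichment",
]


@dataclass(frozen=True)
class GeneModel:
    """Gene anchored by its transcription start site."""

    gene_id: str
    chrom: str
    tss: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be + or -, got {self.strand!r}")
        if self.tss < 0:
            raise ValueError(f"{self.gene_id}: negative TSS")


@dataclass(frozen=True)
class RegulatoryDomain:
    gene_id: str
    basal: GenomicInterval
    extended: GenomicInterval

    def __post_init__(self) -> None:
        if not (
            self.extended.start <= self.basal.start
            and self.basal.end <= self.extended.end
        ):
            raise ValueError(f"{self.gene_id}: basal domain not inside extended domain")


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read a gene model table: gene_id, chrom, tss, strand (TSV, header)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    required = {"gene_id", "chrom", "tss", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"gene model table missing columns: {sorted(missing)}")
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"duplicate gene id: {dup}")
    return [
        GeneModel(r.gene_id, r.chrom, int(r.tss), r.strand) for r in df.itertuples()
    ]


def write_gene_models(genes: Sequence[GeneModel], path: str | Path) -> None:
    pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "chrom": [g.chrom for g in genes],
            "tss": [g.tss for g in genes],
            "strand": [g.strand for g in genes],
        }
    ).to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read GMT gene sets: term <TAB> description <TAB> gene ids..."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line {lineno}: need term, description, genes")
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: Mapping[str, Sequence[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for term, genes in sets.items():
            fh.write("\t".join([term, term] + list(genes)) + "\n")


def build_domains(
    genes: Sequence[GeneModel],
    genome: Mapping[str, int],
    up: int = 5000,
    down: int = 1000,
    max_ext: int = 1_000_000,
) -> list[RegulatoryDomain]:
    """Basal-plus-extension regulatory domains.

    The basal domain spans ``up`` bp upstream to ``down`` bp downstream of
    the TSS (strand-aware) clipped to the chromosome.  The extended domain
    grows from the basal domain in both directions until the nearest
    flanking basal domain boundary, at most ``max_ext`` bp from the TSS.
    Extensions never shrink below the gene's own basal domain, so basal
    domains of close neighbors may still overlap.
    """
    domains: list[RegulatoryDomain] = []
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        if g.chrom not in genome:
            raise ValueError(f"{g.gene_id}: chromosome {g.chrom!r} not in genome")
        if g.tss >= genome[g.chrom]:
            raise ValueError(f"{g.gene_id}: TSS {g.tss} outside chromosome")
        by_chrom.setdefault(g.chrom, []).append(g)

    for chrom, chrom_genes in by_chrom.items():
        chrom_len = genome[chrom]
        chrom_genes = sorted(chrom_genes, key=lambda g: (g.tss, g.gene_id))
        basal: list[tuple[int, int]] = []
        for g in chrom_genes:
            if g.strand == "+":
                b_start, b_end = g.tss - up, g.tss + down
            else:
                b_start, b_end = g.tss - down, g.tss + up
            basal.append((max(0, b_start), min(chrom_len, b_end)))
        for i, g in enumerate(chrom_genes):
            b_start, b_end = basal[i]
            left_limit = max(0, g.tss - max_ext)
            if i > 0:
                left_limit = max(left_limit, basal[i - 1][1])
            right_limit = min(chrom_len, g.tss + max_ext)
            if i < len(chrom_genes) - 1:
                right_limit = min(right_limit, basal[i + 1][0])
            e_start = min(b_start, left_limit)
            e_end = max(b_end, right_limit)
            domains.append(
                RegulatoryDomain(
                    gene_id=g.gene_id,
                    basal=GenomicInterval(chrom, b_start, b_end, id=g.gene_id),
                    extended=GenomicInterval(chrom, e_start, e_end, id=g.gene_id),
                )
            )
    return domains


def domains_interval_set(
    domains: Sequence[RegulatoryDomain],
    genome: Mapping[str, int] | None = None,
    which: str = "extended",
) -> GenomicIntervalSet:
    ivs = [getattr(d, which) for d in domains]
    return GenomicIntervalSet(ivs, genome=genome)


def region_log2fc_filter(
    fpkm: SampleMatrix,
    numerator: Iterable[str] = ("early", "late"),
    denominator: str = "invitro",
    min_lfc: float = 1.0,
    pseudocount: float = 1.0,
) -> list[str]:
    """Keep peaks gained in vivo: log2 fold-change of any in vivo condition
    mean over the in vitro mean above ``min_lfc`` (pseudocount-stabilized)."""
    means = fpkm.condition_means()
    if denominator not in means.columns:
        raise ValueError(f"condition {denominator!r} absent")
    denom = means[denominator] + pseudocount
    keep = pd.Series(False, index=means.index)
    for cond in numerator:
        if cond not in means.columns:
            raise ValueError(f"condition {cond!r} absent")
        lfc = np.log2((means[cond] + pseudocount) / denom)
        keep |= lfc > min_lfc
    return list(means.index[keep])


def peak_anova(m: SampleMatrix) -> pd.DataFrame:
    """One-way ANOVA per peak across condition groups.

    Degenerate rows are handled by sentinel: zero within-group variance with
    unequal group means gives p = 0 (infinitely strong separation); a row
    where all values are identical gives F = 0, p = 1.

    Returns a frame indexed by peak id with columns ``F`` and ``p``.
    """
    conditions = m.conditions
    groups = [m.values.loc[:, conditions == c].values for c in m.condition_means().columns]
    if len(groups) < 2:
        raise ValueError("ANOVA requires at least 2 conditions")
    if not any(g.shape[1] >= 2 for g in groups):
        raise ValueError("ANOVA requires at least one condition with 2+ samples")
    sizes = np.array([g.shape[1] for g in groups])
    n_total = sizes.sum()
    k = len(groups)
    grand = m.values.mean(axis=1).values
    group_means = np.stack([g.mean(axis=1) for g in groups], axis=1)
    ss_between = (sizes[None, :] * (group_means - grand[:, None]) ** 2).sum(axis=1)
    ss_within = np.stack(
        [((g - g.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) for g in groups],
        axis=1,
    ).sum(axis=1)
    df_between, df_within = k - 1, n_total - k
    with np.errstate(divide="ignore", invalid="ignore"):
        f_stat = (ss_between / df_between) / (ss_within / df_within)
    p = stats.f.sf(f_stat, df_between, df_within)
    # sentinels for degenerate rows
    zero_within = ss_within <= 0
    zero_between = ss_between <= 1e-12 * np.maximum(grand**2, 1.0)
    all_equal = zero_within & zero_between
    p = np.where(zero_within & ~all_equal, 0.0, p)
    f_stat = np.where(zero_within & ~all_equal, np.inf, f_stat)
    p = np.where(all_equal, 1.0, p)
    f_stat = np.where(all_equal, 0.0, f_stat)
    return pd.DataFrame({"F": f_stat, "p": p}, index=m.values.index)


def associate_regions(
    regions: GenomicIntervalSet,
    domains: Sequence[RegulatoryDomain],
    genome: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Region↔gene pairs: region midpoint inside the gene's extended domain.

    Returns a two-column frame (``region_id``, ``gene_id``); a region mapping
    to several overlapping domains yields one row per gene.
    """
    dom_set = domains_interval_set(domains, genome=genome, which="extended")
    assign = midpoint_assign(regions, dom_set)
    rows = [(rid, gid) for rid, gids in assign.items() for gid in gids]
    return pd.DataFrame(rows, columns=["region_id", "gene_id"])


def cluster_expression_summary(
    clusters: ClusterResult,
    pairs: pd.DataFrame,
    expr: SampleMatrix,
) -> pd.DataFrame:
    """Distribution of associated-gene expression z-scores per cluster.

    Gene-level z is computed on condition means of TPM (row z-score across
    conditions, ddof=1); a gene linked through several peaks of one cluster
    counts once for that cluster.  The output has one row per
    (cluster, condition) with the boxplot summary used for trajectory plots:
    median, quartiles, 1.5×IQR whiskers clipped to the data range, and n.
    """
    cond_means = expr.condition_means()
    sd = cond_means.std(axis=1, ddof=1)
    ok = sd > 0
    z = cond_means.loc[ok].sub(cond_means.loc[ok].mean(axis=1), axis=0).div(sd[ok], axis=0)

    rows = []
    pair_map = pairs.groupby("region_id")["gene_id"].apply(list)
    for cluster in sorted(clusters.centroids.index):
        member_peaks = clusters.members(cluster)
        genes: set[str] = set()
        for pk in member_peaks:
            genes.update(pair_map.get(pk, []))
        genes &= set(z.index)
        for cond in cond_means.columns:
            vals = z.loc[sorted(genes), cond].values if genes else np.array([])
            if len(vals) == 0:
                rows.append(
                    dict(cluster=cluster, condition=cond, n=0, median=np.nan,
                         q1=np.nan, q3=np.nan, whisker_low=np.nan,
                         whisker_high=np.nan, empty=True)
                )
                continue
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            iqr = q3 - q1
            lo = vals[vals >= q1 - 1.5 * iqr].min()
            hi = vals[vals <= q3 + 1.5 * iqr].max()
            rows.append(
                dict(cluster=cluster, condition=cond, n=len(vals), median=med,
                     q1=q1, q3=q3, whisker_low=lo, whisker_high=hi, empty=False)
            )
    return pd.DataFrame(rows)


def _covered_union(intervals: list[GenomicInterval]) -> int:
    """Total bases covered by a union of intervals."""
    total = 0
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    for spans in by_chrom.values():
        spans.sort()
        cur_s, cur_e = spans[0]
        for s, e in spans[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                total += cur_e - cur_s
                cur_s, cur_e = s, e
        total += cur_e - cur_s
    return total


def term_enrichment(
    cluster_regions: GenomicIntervalSet,
    domains: Sequence[RegulatoryDomain],
    gene_sets: Mapping[str, Sequence[str]],
    genome: Mapping[str, int],
    all_genes: Sequence[str] | None = None,
    associations: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Binomial (region-based) and hypergeometric (gene-based) term tests.

    Binomial: with ``p_term`` the genomic fraction covered by the union of
    the term genes' extended domains, ``n`` cluster regions and ``x`` of them
    whose midpoint lands in that union, report ``P(Bin(n, p_term) >= x)``.

    Hypergeometric: population = all modeled genes, successes = term genes,
    draws = genes associated with the cluster regions, observed = overlap;
    report the upper tail ``P(X >= observed)``.

    Both p-value families are BH-adjusted across terms.  Terms with no known
    genes are skipped.
    """
    import warnings

    genome_size = sum(genome.values())
    dom_by_gene: dict[str, RegulatoryDomain] = {d.gene_id: d for d in domains}
    if all_genes is None:
        all_genes = list(dom_by_gene)
    if associations is None:
        associations = associate_regions(cluster_regions, domains, genome=genome)
    cluster_genes = set(associations["gene_id"]) & set(all_genes)

    n = len(cluster_regions)
    rows = []
    for term, term_genes in gene_sets.items():
        known = [g for g in term_genes if g in dom_by_gene]
        if not known:
            warnings.warn(f"term {term!r} has no known genes; skipped")
            continue
        union_ivs = [dom_by_gene[g].extended for g in known]
        covered = _covered_union(union_ivs)
        p_term = covered / genome_size
        term_set = GenomicIntervalSet(union_ivs)
        assign = midpoint_assign(cluster_regions, term_set)
        x = sum(1 for gids in assign.values() if gids)
        p_binom = float(stats.binom.sf(x - 1, n, p_term)) if n > 0 else 1.0

        term_in_pop = set(known) & set(all_genes)
        overlap = len(cluster_genes & term_in_pop)
        p_hyper = float(
            stats.hypergeom.sf(
                overlap - 1, len(all_genes), len(term_in_pop), len(cluster_genes)
            )
        )
        rows.append(
            dict(term=term, x=x, n=n, p_term=p_term, p_binom=p_binom,
                 genes_overlap=overlap, genes_term=len(term_in_pop),
                 genes_cluster=len(cluster_genes), p_hyper=p_hyper)
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["q_binom"] = multipletests(out["p_binom"], method="fdr_bh")[1]
        out["q_hyper"] = multipletests(out["p_hyper"], method="fdr_bh")[1]
        out = out.sort_values("p_binom", kind="stable").reset_index(drop=True)
    return out
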