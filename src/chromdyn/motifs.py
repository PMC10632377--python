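"""PWM motif scanning and per-cluster differential motif enrichment.

Position frequency matrices (JASPAR text format) are regularized to
probability matrices, converted to log2-odds against a background, and
scanned over region sequences on both strands.  A region is a "hit" when its
best window score reaches a fraction of the maximum achievable score.
Per-cluster enrichment of hits is scored with a signed hypergeometric
z-statistic; motifs whose best cluster |z| clears a display threshold
(default 6) are the reported regulators.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs as bio_motifs
from scipy import stats
from scipy.special import ndtri

from .clustering import ClusterResult
from .matrix import SampleMatrix

__all__ = [
    "MotifPWM",
    "read_jaspar",
    "read_fasta",
    "scan_sequences",
    "scan_all",
    "differential_enrichment",
    "tf_concordance",
]

BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: z-scores are capped at ±Z_CAP to guard against p-value underflow.
Z_CAP = 10.0


@dataclass
class MotifPWM:
    """A probability PWM with background model.

    ``matrix`` holds per-position base probabilities (positions × ACGT),
    already pseudocount-regularized so every cell is positive and every row
    sums to one.
    """

    motif_id: str
    matrix: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 0.01

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError(f"{self.motif_id}: PWM must be positions × 4")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError(f"{self.motif_id}: PWM rows must sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-6):
            raise ValueError(f"{self.motif_id}: background must sum to 1")

    @classmethod
    def from_counts(
        cls,
        motif_id: str,
        counts: np.ndarray,
        background: np.ndarray | None = None,
        pseudocount: float = 0.01,
    ) -> "MotifPWM":
        """Column-normalize counts, add pseudocount per cell, renormalize."""
        counts = np.asarray(counts, dtype=float)
        probs = counts / counts.sum(axis=1, keepdims=True)
        probs = probs + pseudocount
        probs /= probs.sum(axis=1, keepdims=True)
        bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
        return cls(motif_id=motif_id, matrix=probs, background=bg, pseudocount=pseudocount)

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        """positions × 5 log2-odds; the 5th column is the N score (0)."""
        lo = np.log2(self.matrix / self.background[None, :])
        return np.hstack([lo, np.zeros((len(self), 1))])

    @property
    def max_score(self) -> float:
        return float(self.log_odds[:, :4].max(axis=1).sum())

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=1))


def read_jaspar(path: str | Path) -> list[MotifPWM]:
    """Read JASPAR-format PFMs; counts are converted to regularized PWMs."""
    with open(path) as fh:
        parsed = bio_motifs.parse(fh, "jaspar")
    out = []
    for m in parsed:
        counts = np.array([list(m.counts[b]) for b in BASES], dtype=float).T
        out.append(MotifPWM.from_counts(m.matrix_id or m.name, counts))
    return out


def write_jaspar(pwms: Mapping[str, np.ndarray], path: str | Path) -> None:
    """Write count matrices (positions × 4) in JASPAR text format."""
    with open(path, "w") as fh:
        for motif_id, counts in pwms.items():
            fh.write(f">{motif_id}\t{motif_id}\n")
            for b, col in zip(BASES, np.asarray(counts).T):
                cells = "  ".join(f"{v:6.2f}" for v in col)
                fh.write(f"{b}  [ {cells} ]\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def _encode(seq: str) -> np.ndarray:
    idx = np.full(len(seq), 4, dtype=np.int8)
    for i, b in enumerate(BASES):
        idx[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(b)] = i
    return idx


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _best_window(code: np.ndarray, lodds: np.ndarray) -> tuple[float, int]:
    """Best log-odds window score and its start position on one strand."""
    L = lodds.shape[0]
    n = len(code) - L + 1
    if n <= 0:
        raise ValueError("sequence shorter than motif")
    windows = np.lib.stride_tricks.sliding_window_view(code, L)
    scores = lodds[np.arange(L)[None, :], windows].sum(axis=1)
    best = int(np.argmax(scores))
    return float(scores[best]), best


def scan_sequences(
    seqs: Mapping[str, str],
    pwm: MotifPWM,
    rel_threshold: float = 0.8,
) -> pd.DataFrame:
    """Scan sequences on both strands for PWM matches.

    Score = summed per-position log2(p/background); ``N`` bases contribute 0
    (the background log-odds).  A sequence is a hit when its best window
    score is at least ``rel_threshold`` times the maximum achievable score.

    Returns a frame indexed by region id with columns ``hit``, ``best_score``,
    ``position`` (0-based start on the forward strand) and ``strand``.
    """
    lodds = pwm.log_odds
    cutoff = rel_threshold * pwm.max_score
    rows = []
    for rid, seq in seqs.items():
        if len(seq) == 0:
            raise ValueError(f"empty sequence: {rid}")
        code_f = _encode(seq)
        code_r = _encode(reverse_complement(seq))
        score_f, pos_f = _best_window(code_f, lodds)
        score_r, pos_r = _best_window(code_r, lodds)
        if score_f >= score_r:
            best, pos, strand = score_f, pos_f, "+"
        else:
            best, pos = score_r, len(seq) - len(pwm) - pos_r
            strand = "-"
        rows.append(
            dict(region_id=rid, hit=best >= cutoff, best_score=best,
                 position=pos, strand=strand)
        )
    return pd.DataFrame(rows).set_index("region_id")


def scan_all(
    seqs: Mapping[str, str],
    pwms: Sequence[MotifPWM],
    rel_threshold: float = 0.8,
) -> pd.DataFrame:
    """Hit matrix (regions × motifs, boolean) for a PWM collection."""
    cols = {p.motif_id: scan_sequences(seqs, p, rel_threshold)["hit"] for p in pwms}
    return pd.DataFrame(cols)


def _signed_z(p_enr: float, p_dep: float) -> float:
    """Map the smaller of the enrichment/depletion tails to a signed normal
    quantile, capped at ±Z_CAP."""
    if p_enr <= p_dep:
        z = -ndtri(max(p_enr, 1e-300))
    else:
        z = ndtri(max(p_dep, 1e-300))
    return float(np.clip(z, -Z_CAP, Z_CAP))


def differential_enrichment(
    hits: pd.DataFrame,
    clusters: ClusterResult,
) -> pd.DataFrame:
    """Per-(motif, cluster) hypergeometric enrichment/depletion z-scores.

    For cluster c and motif m, draw |c| regions from the clustered universe
    (N regions, K of them hits); ``p_enr = P(X >= x)`` and
    ``p_dep = P(X <= x)`` for the observed hit count x.  The signed z is the
    normal quantile of whichever tail is smaller, positive for enrichment.
    """
    universe = [pid for pid in clusters.labels.index if pid in hits.index]
    if len(universe) < len(clusters.labels):
        missing = set(clusters.labels.index) - set(universe)
        raise ValueError(f"regions missing motif hit calls: {sorted(missing)[:3]}...")
    hit_mat = hits.loc[universe]
    labels = clusters.labels.loc[universe]
    N = len(universe)
    rows = []
    for motif in hit_mat.columns:
        K = int(hit_mat[motif].sum())
        for cluster in sorted(clusters.centroids.index):
            members = labels.index[labels == cluster]
            n = len(members)
            if n == 0:
                raise ValueError(f"cluster {cluster} has no regions")
            x = int(hit_mat.loc[members, motif].sum())
            p_enr = float(stats.hypergeom.sf(x - 1, N, K, n))
            p_dep = float(stats.hypergeom.cdf(x, N, K, n))
            rows.append(
                dict(motif=motif, cluster=cluster, hits=x, cluster_size=n,
                     universe_hits=K, universe_size=N,
                     p_enr=p_enr, p_dep=p_dep, z=_signed_z(p_enr, p_dep))
            )
    return pd.DataFrame(rows)


def reported_motifs(enrichment: pd.DataFrame, z_threshold: float = 6.0) -> list[str]:
    """Motifs whose best cluster |z| reaches the display threshold."""
    best = enrichment.groupby("motif")["z"].apply(lambda s: s.abs().max())
    return sorted(best.index[best >= z_threshold])


def tf_concordance(
    enriched_tfs: Iterable[str],
    expr: SampleMatrix,
    clusters: ClusterResult,
    min_r: float = 0.9,
) -> pd.DataFrame:
    """Correlate TF expression dynamics with cluster accessibility centroids.

    For each (TF, cluster) pair, r is the Pearson correlation between the
    TF's condition-mean expression profile and the cluster centroid across
    the shared conditions.  A pair is concordant when ``r >= min_r``.  TFs
    missing from the expression matrix, or with flat (zero-variance)
    profiles, are flagged rather than dropped.
    """
    cond_means = expr.condition_means()
    conds = [c for c in clusters.centroids.columns if c in cond_means.columns]
    if len(conds) < 2:
        raise ValueError("need at least 2 shared conditions")
    rows = []
    for tf in enriched_tfs:
        for cluster in sorted(clusters.centroids.index):
            centroid = clusters.centroids.loc[cluster, conds].values.astype(float)
            if tf not in cond_means.index:
                rows.append(dict(tf=tf, cluster=cluster, r=np.nan,
                                 concordant=False, status="missing"))
                continue
            prof = cond_means.loc[tf, conds].values.astype(float)
            if np.std(prof) == 0 or np.std(centroid) == 0:
                rows.append(dict(tf=tf, cluster=cluster, r=np.nan,
                                 concordant=False, status="flat"))
                continue
            r = float(np.corrcoef(prof, centroid)[0, 1])
            rows.append(dict(tf=tf, cluster=cluster, r=r,
                             concordant=bool(r >= min_r), status="ok"))
    return pd.DataFrame(rows)
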