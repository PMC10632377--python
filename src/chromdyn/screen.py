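"""Paired in vitro / in vivo CRISPR dropout-screen analysis.

Guide counts at the final time point of each arm are compared to the day-0
input library: counts-per-million normalization, guide- then gene-level log2
fold-change, a one-sided depletion p-value from a resampled non-targeting
null, BH FDR per arm over targeted genes, and the conjunction hit rule
(FDR < 0.05 and log2FC < −1).  Hits are classified as in vivo-specific,
in vitro-specific, common, or none.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ScreenTable",
    "read_screen_table",
    "normalize_counts",
    "gene_lfc",
    "nontarget_null_test",
    "call_hits",
    "analyze_screen",
]

ROLES = ("target", "positive_control", "nontargeting")
CONDITIONS = ("input_d0", "invitro_final", "invivo_final")


@dataclass
class ScreenTable:
    """Guide-level counts with gene mapping and sample metadata.

    ``counts``: guides × samples integer counts.
    ``guides``: frame indexed by guide id with columns ``gene_id`` and
    ``role`` (target / positive_control / nontargeting; non-targeting guides
    carry a placeholder gene id).
    ``samples``: frame indexed by sample id with columns ``condition`` (one
    of input_d0 / invitro_final / invivo_final) and ``replicate``.
    """

    counts: pd.DataFrame
    guides: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be nonnegative")
        if not self.counts.index.equals(self.guides.index):
            self.guides = self.guides.loc[self.counts.index]
        bad = set(self.guides["role"]) - set(ROLES)
        if bad:
            raise ValueError(f"unknown guide roles: {sorted(bad)}")
        self.samples = self.samples.loc[self.counts.columns]
        if "input_d0" not in set(self.samples["condition"]):
            raise ValueError("screen requires at least one input_d0 sample")

    def guide_ids(self, role: str) -> pd.Index:
        return self.guides.index[self.guides["role"] == role]

    def genes(self, roles: Sequence[str] = ("target",)) -> list[str]:
        mask = self.guides["role"].isin(roles)
        return sorted(self.guides.loc[mask, "gene_id"].unique())

    def write(self, counts_path: str | Path, metadata_path: str | Path) -> None:
        out = self.guides.join(self.counts)
        out.index.name = "guide_id"
        out.to_csv(counts_path, sep="\t")
        meta = self.samples.copy()
        meta.index.name = "sample_id"
        meta.to_csv(metadata_path, sep="\t")


def read_screen_table(counts_path: str | Path, metadata_path: str | Path) -> ScreenTable:
    df = pd.read_csv(counts_path, sep="\t", index_col=0)
    guides = df[["gene_id", "role"]]
    counts = df.drop(columns=["gene_id", "role"])
    samples = pd.read_csv(metadata_path, sep="\t", index_col=0)
    samples.index = samples.index.astype(str)
    counts.columns = counts.columns.astype(str)
    return ScreenTable(counts=counts, guides=guides, samples=samples)


def normalize_counts(t: ScreenTable, pseudocount: float = 0.5) -> pd.DataFrame:
    """Counts-per-million with a pseudocount floor.

    ``cpm(g, s) = (count + pc) / sum_g(count + pc) * 1e6``
    """
    if (t.counts.sum(axis=0) == 0).any():
        bad = t.counts.columns[t.counts.sum(axis=0) == 0][0]
        raise ValueError(f"all-zero sample: {bad}")
    shifted = t.counts.astype(float) + pseudocount
    return shifted / shifted.sum(axis=0) * 1e6


def _guide_lfc(cpm: pd.DataFrame, samples: pd.DataFrame, condition: str) -> pd.Series:
    """Per-guide mean log2(final/input).

    When the final-arm replicate indices match input replicate indices
    one-to-one, replicates are paired; otherwise each final replicate is
    compared to the mean input profile.
    """
    cond_cols = samples.index[samples["condition"] == condition]
    input_cols = samples.index[samples["condition"] == "input_d0"]
    if len(cond_cols) == 0:
        raise ValueError(f"no samples for condition {condition!r}")
    cond_reps = samples.loc[cond_cols, "replicate"]
    input_reps = samples.loc[input_cols, "replicate"]
    paired = (
        len(cond_cols) == len(input_cols)
        and sorted(cond_reps) == sorted(input_reps)
        and not cond_reps.duplicated().any()
    )
    if paired:
        input_by_rep = {samples.loc[c, "replicate"]: c for c in input_cols}
        ratios = [
            np.log2(cpm[c] / cpm[input_by_rep[samples.loc[c, "replicate"]]])
            for c in cond_cols
        ]
    else:
        input_mean = cpm[input_cols].mean(axis=1)
        ratios = [np.log2(cpm[c] / input_mean) for c in cond_cols]
    return pd.concat(ratios, axis=1).mean(axis=1)


def gene_lfc(
    t: ScreenTable,
    condition: str,
    pseudocount: float = 0.5,
) -> tuple[pd.Series, pd.Series]:
    """Gene-level log2 fold-change vs the day-0 input.

    Returns ``(gene_lfc, guide_lfc)``: the per-gene mean over its guides and
    the underlying per-guide values (all roles included; non-targeting guides
    are grouped under their placeholder gene ids).
    """
    cpm = normalize_counts(t, pseudocount=pseudocount)
    guide = _guide_lfc(cpm, t.samples, condition)
    gene = guide.groupby(t.guides["gene_id"]).mean()
    return gene, guide


def nontarget_null_test(
    gene_guide_lfcs: Mapping[str, np.ndarray],
    nt_guide_lfcs: np.ndarray,
    B: int = 10_000,
    seed: int = 0,
) -> pd.Series:
    """One-sided depletion p-values against a resampled non-targeting null.

    For a gene with m guides, the null statistic is the mean of m values
    resampled with replacement from the non-targeting guide fold-changes;
    ``p = (1 + #{null <= observed}) / (B + 1)``.
    """
    if B < 100:
        raise ValueError("B must be at least 100")
    nt = np.asarray(nt_guide_lfcs, dtype=float)
    if len(nt) < 5:
        raise ValueError("need at least 5 non-targeting guides")
    rng = np.random.default_rng(seed)
    sizes = sorted({len(v) for v in gene_guide_lfcs.values()})
    null_by_m: dict[int, np.ndarray] = {}
    for m in sizes:
        draws = rng.choice(nt, size=(B, m), replace=True)
        null_by_m[m] = draws.mean(axis=1)
    p = {}
    for gene, lfcs in gene_guide_lfcs.items():
        obs = float(np.mean(lfcs))
        null = null_by_m[len(lfcs)]
        p[gene] = (1 + int((null <= obs).sum())) / (B + 1)
    return pd.Series(p, name="p")


def call_hits(
    results: pd.DataFrame,
    fdr_threshold: float = 0.05,
    lfc_threshold: float = -1.0,
) -> pd.DataFrame:
    """Apply the FDR ∧ fold-change hit rule and classify context specificity.

    ``results`` must carry, per gene, ``lfc_invitro``, ``lfc_invivo``,
    ``p_invitro`` and ``p_invivo``.  BH FDR is computed per arm over the
    genes present (pass targeted genes only).  A gene is a hit in an arm
    when ``fdr < fdr_threshold`` and ``lfc < lfc_threshold``; the class is
    ``common`` (both arms), ``invivo_specific``, ``invitro_specific`` or
    ``none``.
    """
    out = results.copy()
    out["fdr_invitro"] = multipletests(out["p_invitro"], method="fdr_bh")[1]
    out["fdr_invivo"] = multipletests(out["p_invivo"], method="fdr_bh")[1]
    hit_vitro = (out["fdr_invitro"] < fdr_threshold) & (out["lfc_invitro"] < lfc_threshold)
    hit_vivo = (out["fdr_invivo"] < fdr_threshold) & (out["lfc_invivo"] < lfc_threshold)
    out["hit_invitro"] = hit_vitro
    out["hit_invivo"] = hit_vivo
    out["class"] = np.select(
        [hit_vivo & hit_vitro, hit_vivo, hit_vitro],
        ["common", "invivo_specific", "invitro_specific"],
        default="none",
    )
    return out


def analyze_screen(
    t: ScreenTable,
    fdr_threshold: float = 0.05,
    lfc_threshold: float = -1.0,
    B: int = 10_000,
    seed: int = 0,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Full dropout analysis of both arms.

    Targeted and positive-control genes get fold-changes in both arms and
    depletion p-values against the non-targeting null; BH FDR and the hit
    classification are computed over targeted genes only, and
    positive-control rows are appended afterwards with their own hit calls
    evaluated at the targeted-gene FDR machinery (flagged via ``role``).
    """
    nt_ids = t.guide_ids("nontargeting")
    arms = {"invitro": "invitro_final", "invivo": "invivo_final"}
    arm_seed_offset = {"invitro": 1, "invivo": 2}
    per_gene: dict[str, pd.Series] = {}
    for arm, condition in arms.items():
        gene, guide = gene_lfc(t, condition, pseudocount=pseudocount)
        nt_lfcs = guide.loc[nt_ids].values
        grouped = {
            g: guide.loc[idx].values
            for g, idx in t.guides.groupby("gene_id").groups.items()
        }
        pvals = nontarget_null_test(grouped, nt_lfcs, B=B, seed=seed + arm_seed_offset[arm])
        per_gene[f"lfc_{arm}"] = gene
        per_gene[f"p_{arm}"] = pvals
    res = pd.DataFrame(per_gene)
    role = t.guides.drop_duplicates("gene_id").set_index("gene_id")["role"]
    res["role"] = role.loc[res.index]

    targeted = res[res["role"] == "target"].drop(columns="role")
    called = call_hits(targeted, fdr_threshold, lfc_threshold)
    called["role"] = "target"
    controls = res[res["role"] == "positive_control"]
    if len(controls):
        ctrl_called = call_hits(
            controls.drop(columns="role"), fdr_threshold, lfc_threshold
        )
        ctrl_called["role"] = "positive_control"
        called = pd.concat([called, ctrl_called])
    called.index.name = "gene_id"
    return called
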