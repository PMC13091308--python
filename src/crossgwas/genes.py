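"""Gene-based association from summary statistics and competitive set tests.

The gene statistic is the mean chi-squared of the SNPs mapped to the gene
(strand-aware 35 kb upstream / 10 kb downstream windows by default). Under
the null the statistic is a weighted sum of one-degree chi-squares with
weights given by the eigenvalues of the local LD matrix; the p-value uses
Satterthwaite two-moment matching, which is exact for independent SNPs and
for a gene in perfect LD.

Set-level inference is a one-sided Welch t-test of member gene Z against
the genome-wide background, with Bonferroni and Benjamini-Hochberg
corrections across the panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._util import bh_fdr

#: largest probit Z we emit before clamping (roughly p = 1e-308)
_Z_CLAMP = 37.5


@dataclass
class GeneSet:
    name: str
    priority_rank: int
    genes: list[str]
    provenance: str = ""


@dataclass
class GeneSetPanel:
    """Ordered, priority-ranked collection of named gene sets."""

    sets: list[GeneSet]

    def __post_init__(self):
        ranks = [s.priority_rank for s in self.sets]
        if len(set(ranks)) != len(ranks):
            raise ValueError("priority ranks must be unique")

    def __iter__(self):
        return iter(self.sets)

    def __len__(self):
        return len(self.sets)

    def by_name(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)

    def unique_genes(self) -> set[str]:
        out: set[str] = set()
        for s in self.sets:
            out.update(s.genes)
        return out


def dedup_panel(panel: GeneSetPanel) -> tuple[GeneSetPanel, int]:
    """Keep each gene only in its highest-priority (lowest-rank) set.

    Returns the deduplicated panel and the total unique gene count.
    Idempotent; post-dedup sets are pairwise disjoint.
    """
    claimed: set[str] = set()
    new_sets = []
    for s in sorted(panel.sets, key=lambda s: s.priority_rank):
        kept = [g for g in s.genes if g not in claimed]
        claimed.update(kept)
        new_sets.append(
            GeneSet(name=s.name, priority_rank=s.priority_rank, genes=kept,
                    provenance=s.provenance)
        )
    return GeneSetPanel(new_sets), len(claimed)


def read_gmt(path) -> GeneSetPanel:
    """Read a panel from GMT lines: name <tab> provenance <tab> members..."""
    sets = []
    with open(path) as fh:
        for rank, line in enumerate(fh, start=1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets.append(
                GeneSet(name=parts[0], priority_rank=rank, genes=parts[2:],
                        provenance=parts[1])
            )
    return GeneSetPanel(sets)


def write_gmt(panel: GeneSetPanel, path) -> None:
    with open(path, "w") as fh:
        for s in sorted(panel.sets, key=lambda s: s.priority_rank):
            fh.write("\t".join([s.name, s.provenance or "."] + list(s.genes)) + "\n")


# ---------------------------------------------------------------------------
# SNP -> gene mapping
# ---------------------------------------------------------------------------

def map_snps_to_genes(
    variants: pd.DataFrame,
    genes: pd.DataFrame,
    window_up: int = 35_000,
    window_down: int = 10_000,
) -> dict[str, np.ndarray]:
    """Map SNPs into strand-aware gene windows.

    A + strand gene [start, end] collects SNPs in
    [start - window_up, end + window_down] inclusive; for - strand genes the
    windows are mirrored (upstream is 5' of the gene). A SNP may map to
    several genes. Genes with zero mapped SNPs are omitted from the result.
    """
    out: dict[str, np.ndarray] = {}
    by_chrom = {}
    for chrom, sub in variants.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        order = np.argsort(pos, kind="stable")
        by_chrom[str(chrom)] = (pos[order], sub.index.to_numpy()[order])
    for row in genes.itertuples(index=False):
        entry = by_chrom.get(str(row.chrom))
        if entry is None:
            continue
        pos, idx = entry
        if row.strand == "-":
            lo, hi = row.start - window_down, row.end + window_up
        else:
            lo, hi = row.start - window_up, row.end + window_down
        a = np.searchsorted(pos, lo, side="left")
        b = np.searchsorted(pos, hi, side="right")
        if b > a:
            out[row.gene_id] = idx[a:b]
    return out


# ---------------------------------------------------------------------------
# Gene-level test
# ---------------------------------------------------------------------------

def gene_test(snp_z: np.ndarray, ld: np.ndarray, psd_tol: float = 1e-6):
    """Mean-chi2 gene statistic with an LD-aware null.

    Null: t = mean(z^2) ~ (1/m) * sum_i lambda_i * chi2_1, lambda_i the
    eigenvalues of the LD matrix. The p-value matches the first two moments
    of m*t to a scaled chi-square with scale g = S2/S1 and df = S1^2/S2
    (S1 = sum lambda, S2 = sum lambda^2). Small negative eigenvalues (within
    ``psd_tol * m``) are clipped to zero; worse indefiniteness is an error.

    Returns (t_stat, pvalue).
    """
    z = np.asarray(snp_z, dtype=float)
    m = len(z)
    if m < 1:
        raise ValueError("need at least one SNP")
    ld = np.asarray(ld, dtype=float)
    if ld.shape != (m, m):
        raise ValueError("LD matrix dimension does not match z")
    lam = np.linalg.eigvalsh(ld)
    if lam.min() < -psd_tol * m:
        raise ValueError(
            "LD matrix is not positive semi-definite beyond tolerance; "
            "clip its negative eigenvalues (or rebuild it) before testing"
        )
    lam = np.clip(lam, 0.0, None)
    s1 = lam.sum()
    s2 = float(np.sum(lam**2))
    if s1 <= 0:
        raise ValueError("degenerate LD matrix (all-zero spectrum)")
    t_stat = float(np.mean(z**2))
    q = m * t_stat
    g = s2 / s1
    df = s1**2 / s2
    pvalue = float(stats.chi2.sf(q / g, df))
    return t_stat, max(pvalue, np.nextafter(0.0, 1.0))


def gene_z(pvalue) -> float:
    """Probit gene Z: z = Phi^-1(1 - p), clamped at the representable extreme."""
    p = float(pvalue)
    if not 0 < p <= 1:
        raise ValueError("p-value must lie in (0, 1]")
    z = float(stats.norm.isf(p))
    return float(np.clip(z, -_Z_CLAMP, _Z_CLAMP))


def run_gene_analysis(
    variants: pd.DataFrame,
    genes: pd.DataFrame,
    ld_lookup,
    window_up: int = 35_000,
    window_down: int = 10_000,
) -> pd.DataFrame:
    """Gene-level association for every gene with at least one mapped SNP.

    ``ld_lookup(variant_row_indices) -> correlation matrix`` supplies the
    local LD (e.g. ``LdBlocks.corr_submatrix`` composed with the variant
    table's row order).

    Returns a frame with gene_id, n_snps, t_stat, pvalue, z.
    """
    mapping = map_snps_to_genes(variants, genes, window_up, window_down)
    zcol = variants["z"].to_numpy()
    rows = []
    for gid, idx in mapping.items():
        t_stat, p = gene_test(zcol[idx], ld_lookup(idx))
        rows.append((gid, len(idx), t_stat, p, gene_z(p)))
    return pd.DataFrame(rows, columns=["gene_id", "n_snps", "t_stat", "pvalue", "z"])


# ---------------------------------------------------------------------------
# Competitive gene-set testing
# ---------------------------------------------------------------------------

def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise significance threshold alpha/m."""
    if not 0 < alpha < 1 or m < 1:
        raise ValueError("need alpha in (0,1) and m >= 1")
    return alpha / m


def competitive_set_test(gene_results: pd.DataFrame, gene_set: GeneSet) -> dict:
    """One-sided Welch t-test of member gene Z against the background.

    Reports the set mean/median Z, the count of members individually nominal
    at p < 0.05, and the number of set members absent from the tested genes.
    Degenerate inputs (zero variance in both groups) yield p = 1 with a flag.
    """
    tested = set(gene_results["gene_id"])
    members = [g for g in gene_set.genes if g in tested]
    n_missing = len(gene_set.genes) - len(members)
    is_member = gene_results["gene_id"].isin(members).to_numpy()
    z_in = gene_results.loc[is_member, "z"].to_numpy()
    z_out = gene_results.loc[~is_member, "z"].to_numpy()
    if len(z_in) < 2 or len(z_out) < 2:
        raise ValueError("need at least 2 member and 2 background genes")
    degenerate = np.var(z_in) == 0 and np.var(z_out) == 0
    if degenerate:
        p = 1.0
    else:
        p = float(
            stats.ttest_ind(z_in, z_out, equal_var=False, alternative="greater").pvalue
        )
    p_in = gene_results.loc[is_member, "pvalue"].to_numpy()
    return {
        "set": gene_set.name,
        "n_genes": len(z_in),
        "n_missing": n_missing,
        "mean_z": float(np.mean(z_in)),
        "median_z": float(np.median(z_in)),
        "n_nominal": int(np.sum(p_in < 0.05)),
        "p_raw": p,
        "degenerate": bool(degenerate),
    }


def competitive_panel_test(
    gene_results: pd.DataFrame, panel: GeneSetPanel, alpha: float = 0.05
) -> pd.DataFrame:
    """Competitive test for every set, corrected across the panel.

    Adds Bonferroni and Benjamini-Hochberg columns; the Bonferroni
    significance threshold for the family is alpha / n_sets.
    """
    rows = [competitive_set_test(gene_results, s) for s in panel]
    out = pd.DataFrame(rows)
    k = len(out)
    out["p_bonferroni"] = np.minimum(out["p_raw"] * k, 1.0)
    out["p_fdr"] = bh_fdr(out["p_raw"].to_numpy())
    out["significant_bonferroni"] = out["p_raw"] < bonferroni_threshold(alpha, k)
    return out
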