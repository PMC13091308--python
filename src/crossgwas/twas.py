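"""Summary-based transcriptome-wide association and set-level enrichment.

The gene statistic follows the summary-TWAS construction: with prediction
weights w_l, reference SNP standard deviations sigma_l and SNP covariance
Sigma, the gene Z is

    Z_gene = sum_l w_l sigma_l z_l / sqrt(w' Sigma w)

evaluated over the model SNPs present in the GWAS. Missing model SNPs are
dropped and the prediction variance recomputed over the retained subset
(the standard fallback; a strict mode raises instead). With standardized
synthetic genotypes sigma_l = 1 and Sigma is the LD correlation.

Set-level enrichment is a one-sided Mann-Whitney U comparing member |Z|
against the background within each tissue, with per-tissue BH FDR; the
enrichment ratio is the ratio of mean |Z| (member vs background).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._util import bh_fdr


@dataclass
class PredictionModel:
    """Expression prediction model for one gene in one tissue."""

    gene_id: str
    tissue: str
    snps: list[str]
    weights: np.ndarray
    covariance: np.ndarray  # SNP covariance from the LD reference

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        self.covariance = np.asarray(self.covariance, dtype=float)
        k = len(self.snps)
        if self.weights.shape != (k,) or self.covariance.shape != (k, k):
            raise ValueError("weights/covariance dimensions do not match snps")


def load_models(
    weights: pd.DataFrame, covariances: dict
) -> dict[str, list[PredictionModel]]:
    """Build per-tissue model lists from a weights table and covariance map.

    ``weights`` columns: gene, tissue, snp, weight. ``covariances`` maps
    gene -> (snp id list, covariance matrix).
    """
    out: dict[str, list[PredictionModel]] = {}
    for (gene, tissue), sub in weights.groupby(["gene", "tissue"], sort=True):
        snps, sigma = covariances[gene]
        index = {s: i for i, s in enumerate(snps)}
        rows = [index[s] for s in sub["snp"]]
        model = PredictionModel(
            gene_id=gene,
            tissue=tissue,
            snps=list(sub["snp"]),
            weights=sub["weight"].to_numpy(),
            covariance=sigma[np.ix_(rows, rows)],
        )
        out.setdefault(tissue, []).append(model)
    return out


def load_covariance_table(path_or_df) -> dict:
    """Read a (gene, snp1, snp2, value) covariance table into dense blocks."""
    df = path_or_df if isinstance(path_or_df, pd.DataFrame) else pd.read_csv(
        path_or_df, sep="\t"
    )
    out = {}
    for gene, sub in df.groupby("gene", sort=True):
        snps = sorted(set(sub["snp1"]) | set(sub["snp2"]),
                      key=lambda s: (len(s), s))
        index = {s: i for i, s in enumerate(snps)}
        sigma = np.zeros((len(snps), len(snps)))
        for s1, s2, v in zip(sub["snp1"], sub["snp2"], sub["value"]):
            sigma[index[s1], index[s2]] = v
            sigma[index[s2], index[s1]] = v
        out[gene] = (snps, sigma)
    return out


def twas_z(
    model: PredictionModel,
    snp_z: dict[str, float],
    snp_sd: dict[str, float] | None = None,
    strict: bool = False,
) -> dict:
    """Gene-level association Z for one prediction model.

    ``snp_z`` maps SNP id to its (harmonized) GWAS z-score; ``snp_sd`` maps
    SNP id to its reference standard deviation (defaults to 1, the
    standardized-genotype convention). Returns a result record; raises if
    no model SNP is present or the retained prediction variance is zero.
    """
    present = [i for i, s in enumerate(model.snps) if s in snp_z]
    n_missing = len(model.snps) - len(present)
    if strict and n_missing:
        raise ValueError(f"{model.gene_id}/{model.tissue}: missing model SNPs")
    if not present:
        raise ValueError(f"{model.gene_id}/{model.tissue}: no overlapping SNPs")
    idx = np.array(present)
    w = model.weights[idx]
    sigma = model.covariance[np.ix_(idx, idx)]
    sd = np.array([1.0 if snp_sd is None else snp_sd[model.snps[i]] for i in idx])
    var = float(w @ sigma @ w)
    if var <= 0:
        raise ValueError(f"{model.gene_id}/{model.tissue}: zero prediction variance")
    z = np.array([snp_z[model.snps[i]] for i in idx])
    z_gene = float(np.sum(w * sd * z) / np.sqrt(var))
    return {
        "gene_id": model.gene_id,
        "tissue": model.tissue,
        "z": z_gene,
        "pvalue": float(2.0 * stats.norm.sf(abs(z_gene))),
        "n_snps_used": len(present),
        "n_snps_missing": n_missing,
    }


def run_twas(
    study: pd.DataFrame,
    models: dict[str, list[PredictionModel]],
    snp_sd: dict[str, float] | None = None,
) -> pd.DataFrame:
    """All (gene, tissue) TWAS results with a per-tissue BH FDR column.

    ``study`` is a harmonized variant table whose effect alleles match the
    model convention (use sumstats harmonization first when they may not).
    Genes without usable SNPs are skipped; tissues with zero testable genes
    are omitted with a warning.
    """
    snp_z = dict(zip(study["rsid"], study["z"]))
    frames = []
    for tissue in sorted(models):
        rows = []
        for model in models[tissue]:
            try:
                rows.append(twas_z(model, snp_z, snp_sd))
            except ValueError:
                continue
        if not rows:
            warnings.warn(f"tissue {tissue}: no testable genes; omitted")
            continue
        sub = pd.DataFrame(rows)
        sub["q_tissue"] = bh_fdr(sub["pvalue"].to_numpy())
        frames.append(sub)
    if not frames:
        raise ValueError("no tissue produced any TWAS result")
    return pd.concat(frames, ignore_index=True)


def set_enrichment_mw(
    results: pd.DataFrame, gene_set, tissue: str, fdr_alpha: float = 0.05
) -> dict:
    """Mann-Whitney enrichment of a gene set's |Z| within one tissue.

    One-sided (members stochastically greater); the enrichment ratio is
    mean |Z| of members over mean |Z| of background. Fully tied inputs are
    degenerate and reported with p = 1.
    """
    sub = results[results["tissue"] == tissue]
    member_names = set(gene_set.genes)
    is_member = sub["gene_id"].isin(member_names).to_numpy()
    a = np.abs(sub.loc[is_member, "z"].to_numpy())
    b = np.abs(sub.loc[~is_member, "z"].to_numpy())
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 member and 2 background genes")
    degenerate = len(np.unique(np.concatenate([a, b]))) == 1
    if degenerate:
        p = 1.0
    else:
        p = float(stats.mannwhitneyu(a, b, alternative="greater").pvalue)
    sig = sub.loc[is_member, "q_tissue"].to_numpy() < fdr_alpha
    return {
        "set": gene_set.name,
        "tissue": tissue,
        "n_genes": int(len(a)),
        "n_fdr_significant": int(sig.sum()),
        "enrichment_ratio": float(np.mean(a) / np.mean(b)),
        "mw_p": p,
        "degenerate": bool(degenerate),
    }


def panel_enrichment(
    results: pd.DataFrame, panel, fdr_alpha: float = 0.05
) -> pd.DataFrame:
    """MW enrichment for every (set, tissue) combination, with best gene."""
    best = best_tissue_summary(results).set_index("gene_id")
    rows = []
    for tissue in sorted(results["tissue"].unique()):
        for s in panel:
            try:
                rec = set_enrichment_mw(results, s, tissue, fdr_alpha)
            except ValueError:
                continue
            members_best = best[best.index.isin(s.genes)]
            if len(members_best):
                top = members_best.loc[members_best["z"].abs().idxmax()]
                rec["best_gene"] = top.name
                rec["best_gene_tissue"] = top["tissue"]
                rec["best_gene_z"] = float(top["z"])
            rows.append(rec)
    return pd.DataFrame(rows)


def best_tissue_summary(results: pd.DataFrame) -> pd.DataFrame:
    """Per gene, the tissue with the largest |Z| (ties: first tissue label)."""
    df = results.copy()
    df["abs_z"] = df["z"].abs()
    df = df.sort_values(["gene_id", "abs_z", "tissue"],
                        ascending=[True, False, True], kind="stable")
    out = df.drop_duplicates("gene_id", keep="first")
    return out[["gene_id", "tissue", "z", "pvalue"]].reset_index(drop=True)
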