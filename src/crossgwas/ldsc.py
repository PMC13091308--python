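"""LD score regression: heritability, partitioned enrichment, and rg.

Built on the standard regression identity for polygenic architectures:
E[chi2_j] = 1 + n * h2 * l_j / m with l_j the LD score of SNP j, and its
bivariate analogue E[z_aj z_bj] = sqrt(n_a n_b) * gencov * l_j / m +
cross-intercept. Slopes come from weighted least squares with weights
1/max(1, l_j) (a simple heteroskedasticity proxy); standard errors come
from a delete-one block jackknife over contiguous SNP blocks (200 by
default). Annotation enrichment is the share of heritability carried by an
annotation divided by its share of SNPs, from a multivariate regression on
per-annotation LD scores; a simplified fallback ratio of per-unit-LD excess
chi-squared is provided as a cross-check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._util import JackknifeWLS, bh_fdr, block_bounds, jackknife_se


# ---------------------------------------------------------------------------
# LD scores and annotation intervals
# ---------------------------------------------------------------------------

def compute_ld_scores(
    ld, annotations: dict[str, np.ndarray] | None = None
) -> pd.DataFrame:
    """Per-SNP LD scores (and per-annotation scores) from an LdBlocks reference.

    l_j = sum_k r_jk^2 within the block, self term included; per-annotation
    scores restrict k to annotation members. A jackknife ``block`` id column
    is attached.
    """
    out = pd.DataFrame({"l2": ld.ld_scores(), "block": ld.block_ids()})
    for name, mask in (annotations or {}).items():
        out[f"l2_{name}"] = ld.ld_scores(np.asarray(mask, dtype=bool))
    return out


def make_annotation_bed(genes: pd.DataFrame, pad: int = 10_000) -> pd.DataFrame:
    """Pad gene bodies and merge overlaps into BED intervals.

    Input coordinates are 1-based inclusive; output is BED (0-based
    half-open), sorted, one merged interval per row.
    """
    rows = []
    for chrom, sub in genes.groupby("chrom", sort=True):
        start = np.maximum(1, sub["start"].to_numpy() - pad)
        end = sub["end"].to_numpy() + pad
        order = np.argsort(start, kind="stable")
        start, end = start[order], end[order]
        cur_s, cur_e = int(start[0]), int(end[0])
        for s, e in zip(start[1:], end[1:]):
            if s <= cur_e + 1:  # abutting 1-based intervals merge too
                cur_e = max(cur_e, int(e))
            else:
                rows.append((str(chrom), cur_s - 1, cur_e))
                cur_s, cur_e = int(s), int(e)
        rows.append((str(chrom), cur_s - 1, cur_e))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def write_bed(bed: pd.DataFrame, path) -> None:
    bed.to_csv(path, sep="\t", header=False, index=False)


def snps_in_bed(variants: pd.DataFrame, bed: pd.DataFrame) -> np.ndarray:
    """Boolean mask over variant rows falling inside BED intervals."""
    mask = np.zeros(len(variants), dtype=bool)
    pos = variants["pos"].to_numpy()  # 1-based
    chroms = variants["chrom"].astype(str).to_numpy()
    for chrom, sub in bed.groupby("chrom", sort=False):
        sel = chroms == str(chrom)
        if not sel.any():
            continue
        p = pos[sel]
        inside = np.zeros(len(p), dtype=bool)
        for s, e in zip(sub["start"], sub["end"]):
            inside |= (p > s) & (p <= e)  # BED half-open on 0-based coords
        mask[np.where(sel)[0][inside]] = True
    return mask


# ---------------------------------------------------------------------------
# Univariate heritability
# ---------------------------------------------------------------------------

@dataclass
class H2Result:
    h2: float
    h2_se: float
    intercept: float
    intercept_se: float
    mean_chi2: float
    n_snps: int
    n_blocks: int


def _design(l2: np.ndarray, scale: float, m: int) -> np.ndarray:
    x = np.empty((len(l2), 2))
    x[:, 0] = scale * l2 / m
    x[:, 1] = 1.0
    return x


def estimate_h2(
    chi2: np.ndarray,
    l2: np.ndarray,
    n: float,
    m: int | None = None,
    n_blocks: int = 200,
) -> H2Result:
    """Univariate LD score regression of chi2 on n*l/m with free intercept."""
    chi2 = np.asarray(chi2, dtype=float)
    l2 = np.asarray(l2, dtype=float)
    m = m or len(chi2)
    if m < 2000:
        warnings.warn("fewer than 2000 SNPs: LDSC estimates will be unstable")
    if np.ptp(l2) == 0:
        raise ValueError("constant LD scores cannot identify the slope")
    w = 1.0 / np.maximum(1.0, l2)
    x = _design(l2, n, m)
    jk = JackknifeWLS(x, chi2, w, block_bounds(len(chi2), n_blocks))
    coef = jk.fit()
    deleted = jk.delete_one()
    return H2Result(
        h2=float(coef[0]),
        h2_se=jackknife_se(deleted[:, 0]),
        intercept=float(coef[1]),
        intercept_se=jackknife_se(deleted[:, 1]),
        mean_chi2=float(chi2.mean()),
        n_snps=len(chi2),
        n_blocks=jk.n_blocks,
    )


# ---------------------------------------------------------------------------
# Partitioned heritability
# ---------------------------------------------------------------------------

def partitioned_h2(
    chi2: np.ndarray,
    ld_scores: pd.DataFrame,
    annotations: dict[str, np.ndarray],
    n: float,
    n_blocks: int = 200,
    n_genes: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Stratified LD score regression with overlap-friendly proportions.

    Fits chi2 on the base (all-SNP) LD score column plus one column per
    annotation, all scaled by n. Per-SNP heritability is the
    coefficient-weighted sum of annotation memberships, so overlapping
    annotations are handled by construction. Enrichment is
    prop_h2 / prop_snps with a one-tailed jackknife-normal p for
    enrichment > 1; a per-SNP chi2 Mann-Whitney accompanies each
    annotation. Bonferroni and BH corrections run across the annotations.
    """
    chi2 = np.asarray(chi2, dtype=float)
    m_total = len(chi2)
    all_masks = {k: np.asarray(v, dtype=bool) for k, v in annotations.items()}
    # an all-SNP annotation duplicates the base column; its share of h2 is 1
    # by construction, so report it exactly and fit the rest
    full = [k for k, v in all_masks.items() if v.all()]
    names = [k for k in all_masks if k not in full]
    masks = {k: all_masks[k] for k in names}
    base_l2 = np.asarray(ld_scores["l2"], dtype=float)
    # when the annotations exactly partition the SNPs their columns sum to
    # the base column, so the base is dropped to keep the design full rank
    coverage = (
        np.sum([masks[k] for k in names], axis=0) if names else np.zeros(m_total)
    )
    is_partition = bool(names) and (coverage == 1).all()
    annot_cols = [np.asarray(ld_scores[f"l2_{k}"], dtype=float) for k in names]
    cols = annot_cols if is_partition else [base_l2] + annot_cols
    x = np.column_stack([n * c for c in cols] + [np.ones(m_total)])
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        raise ValueError(
            "annotation design is rank deficient; check for collinear "
            f"annotations among {names}"
        )
    w = 1.0 / np.maximum(1.0, base_l2)
    jk = JackknifeWLS(x, chi2, w, block_bounds(m_total, n_blocks))
    coef_full = jk.fit()
    deleted = jk.delete_one()

    # membership matrix (base first unless dropped); per-SNP h2_j is the
    # coefficient-weighted sum of memberships
    a_cols = [masks[k].astype(float) for k in names]
    if not is_partition:
        a_cols = [np.ones(m_total)] + a_cols
    a = np.column_stack(a_cols)
    counts = a.sum(axis=0)
    first_annot = 0 if is_partition else 1

    def derive(coef):
        tau = coef[:-1]
        per_snp = a @ tau
        total = per_snp.sum()
        prop = np.array([per_snp[a[:, c] > 0].sum() for c in range(len(tau))])
        return prop / total if total != 0 else np.full(len(tau), np.nan)

    prop_full = derive(coef_full)
    prop_del = np.array([derive(c) for c in deleted])
    pct = counts / m_total
    enr_full = prop_full / pct
    enr_del = prop_del / pct[None, :]

    rows = []
    for c, name in enumerate(names, start=first_annot):
        se = jackknife_se(enr_del[:, c])
        enr = enr_full[c]
        p_one = float(stats.norm.sf((enr - 1.0) / se)) if se > 0 else (
            0.0 if enr > 1 else 1.0
        )
        in_mask = masks[name]
        mw = stats.mannwhitneyu(
            chi2[in_mask], chi2[~in_mask], alternative="greater"
        )
        rows.append(
            {
                "annotation": name,
                "n_genes": (n_genes or {}).get(name, np.nan),
                "n_snps": int(counts[c]),
                "pct_snps": float(pct[c]),
                "prop_h2": float(prop_full[c]),
                "enrichment": float(enr),
                "se_jackknife": se,
                "p_one_tailed": p_one,
                "mw_p": float(mw.pvalue),
            }
        )
    for name in full:
        rows.append(
            {"annotation": name, "n_genes": (n_genes or {}).get(name, np.nan),
             "n_snps": m_total, "pct_snps": 1.0, "prop_h2": 1.0,
             "enrichment": 1.0, "se_jackknife": 0.0, "p_one_tailed": 1.0,
             "mw_p": np.nan}
        )
    out = pd.DataFrame(rows)
    k = len(out)
    out["p_bonferroni"] = np.minimum(out["p_one_tailed"] * k, 1.0)
    out["p_fdr"] = bh_fdr(out["p_one_tailed"].to_numpy())
    return out


def fallback_enrichment(
    chi2: np.ndarray, mask: np.ndarray, l2: np.ndarray, eps: float = 1e-6
) -> dict:
    """Simplified enrichment: per-unit-LD excess chi2, annotated vs not.

    ratio = [(mean chi2_in - 1)/mean l_in] / [(mean chi2_out - 1)/mean l_out].
    Negative excess signal is floored at ``eps`` with a flag. A Mann-Whitney
    on the per-SNP chi2 values is reported alongside.
    """
    chi2 = np.asarray(chi2, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    l2 = np.asarray(l2, dtype=float)
    if not mask.any() or mask.all():
        raise ValueError("both strata must be nonempty")
    num_in = chi2[mask].mean() - 1.0
    num_out = chi2[~mask].mean() - 1.0
    floored = num_in < eps or num_out < eps
    num_in, num_out = max(num_in, eps), max(num_out, eps)
    ratio = (num_in / l2[mask].mean()) / (num_out / l2[~mask].mean())
    mw = stats.mannwhitneyu(chi2[mask], chi2[~mask], alternative="greater")
    return {"ratio": float(ratio), "mw_p": float(mw.pvalue), "floored": bool(floored)}


# ---------------------------------------------------------------------------
# Cross-trait genetic correlation
# ---------------------------------------------------------------------------

@dataclass
class RgResult:
    rg: float
    se: float
    pvalue: float
    gencov: float
    h2_a: float
    h2_b: float
    intercept_a: float
    intercept_b: float
    cross_intercept: float
    n_snps_used: int
    n_blocks: int
    out_of_range: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


def genetic_correlation(
    z_a: np.ndarray,
    z_b: np.ndarray,
    l2: np.ndarray,
    n_a: float,
    n_b: float,
    m: int | None = None,
    n_blocks: int = 200,
) -> RgResult:
    """Cross-trait rg by bivariate LD score regression with block jackknife.

    gencov is the slope of z_a*z_b on sqrt(n_a n_b)*l/m (free cross-trait
    intercept, which absorbs sample overlap); per-trait h2 comes from
    univariate regressions on the same SNPs; rg = gencov / sqrt(h2_a h2_b).
    The SE and p are from a delete-one jackknife of the full rg statistic
    over ``n_blocks`` contiguous blocks.
    """
    z_a = np.asarray(z_a, dtype=float)
    z_b = np.asarray(z_b, dtype=float)
    l2 = np.asarray(l2, dtype=float)
    m = m or len(z_a)
    if n_blocks < 20:
        raise ValueError("need at least 20 jackknife blocks")
    w = 1.0 / np.maximum(1.0, l2)
    bounds = block_bounds(len(z_a), n_blocks)
    jk_a = JackknifeWLS(_design(l2, n_a, m), z_a**2, w, bounds)
    jk_b = JackknifeWLS(_design(l2, n_b, m), z_b**2, w, bounds)
    jk_ab = JackknifeWLS(
        _design(l2, float(np.sqrt(n_a * n_b)), m), z_a * z_b, w, bounds
    )
    ca, cb, cab = jk_a.fit(), jk_b.fit(), jk_ab.fit()
    h2_a, h2_b, gencov = ca[0], cb[0], cab[0]
    if h2_a <= 0 or h2_b <= 0:
        raise ValueError(
            f"rg undefined: nonpositive heritability (h2_a={h2_a:.4g}, "
            f"h2_b={h2_b:.4g})"
        )
    rg = gencov / np.sqrt(h2_a * h2_b)
    da, db, dab = jk_a.delete_one(), jk_b.delete_one(), jk_ab.delete_one()
    valid = (da[:, 0] > 0) & (db[:, 0] > 0)
    rg_del = np.where(
        valid, dab[:, 0] / np.sqrt(np.abs(da[:, 0] * db[:, 0])), rg
    )
    se = jackknife_se(rg_del)
    p = float(2.0 * stats.norm.sf(abs(rg) / se)) if se > 0 else 0.0
    return RgResult(
        rg=float(rg),
        se=se,
        pvalue=p,
        gencov=float(gencov),
        h2_a=float(h2_a),
        h2_b=float(h2_b),
        intercept_a=float(ca[1]),
        intercept_b=float(cb[1]),
        cross_intercept=float(cab[1]),
        n_snps_used=len(z_a),
        n_blocks=jk_a.n_blocks,
        out_of_range=bool(abs(rg) > 1),
    )
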