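"""Two-trait GWAS summary-statistics generator with ground truth.

The generator works directly in z-score space: per LD block, the marginal
association z-vector is drawn as multivariate normal with mean
``sqrt(n) * R @ beta`` and covariance ``R`` — the sampling model that
gene-based tests, LD score regression and summary TWAS all assume.
Genotypes are standardized, so per-SNP effect variances are allele-frequency
free and the LD reference is a correlation matrix.

A scene bundles everything downstream layers need: two studies' variant
tables (writable in both file dialects), true per-SNP effects, gene
coordinates, an 8-set gene panel with configurable overlap, expression
prediction weights with their SNP covariance, and annotation masks with
known heritability multipliers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .sumstats import TraitMeta, validate_variants

#: ordered non-palindromic allele pairs (effect, other)
_ALLELE_PAIRS = [
    ("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
    ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T"),
]

#: the eight pathway names used for default panels, mirroring the kind of
#: curated hierarchy (controls first) used in cross-disorder studies
DEFAULT_SET_NAMES = [
    "housekeeping",
    "monoaminergic",
    "neurosteroid",
    "glutamatergic",
    "synaptic_pruning",
    "autophagy_proteostasis",
    "rna_processing",
    "immune_neuroinflammation",
]


def default_blocks(
    m_snps: int = 20_000,
    block_size: int = 100,
    rhos: tuple[float, ...] = (0.2, 0.35, 0.5, 0.65, 0.8),
) -> list[tuple[int, float]]:
    """Equal-size AR(1) blocks with heterogeneous correlation.

    Cycling rho across blocks spreads the LD-score distribution, which is
    what identifies the LD score regression slope; a genome with a single
    uniform rho would leave the regressor nearly constant.
    """
    n_blocks, rem = divmod(m_snps, block_size)
    if rem:
        raise ValueError("m_snps must be a multiple of block_size")
    return [(block_size, rhos[i % len(rhos)]) for i in range(n_blocks)]


def ar1_corr(size: int, rho: float) -> np.ndarray:
    """AR(1) correlation matrix: r_ij = rho^|i-j|."""
    if abs(rho) >= 1:
        raise ValueError("|rho| must be < 1")
    if size < 1:
        raise ValueError("block size must be >= 1")
    idx = np.arange(size)
    return rho ** np.abs(idx[:, None] - idx[None, :])


class LdBlocks:
    """Block-diagonal LD reference built from AR(1) blocks."""

    def __init__(self, blocks: list[tuple[int, float]]):
        self.blocks = [(int(s), float(r)) for s, r in blocks]
        for s, r in self.blocks:
            if s < 1:
                raise ValueError("block size must be >= 1")
            if abs(r) >= 1:
                raise ValueError("|rho| must be < 1")
        sizes = np.array([s for s, _ in self.blocks])
        self.starts = np.concatenate([[0], np.cumsum(sizes)])
        self.m = int(sizes.sum())
        self._mat: dict[int, np.ndarray] = {}
        self._chol: dict[int, np.ndarray] = {}

    def __len__(self) -> int:
        return len(self.blocks)

    def matrix(self, i: int) -> np.ndarray:
        if i not in self._mat:
            size, rho = self.blocks[i]
            self._mat[i] = ar1_corr(size, rho)
        return self._mat[i]

    def chol(self, i: int) -> np.ndarray:
        if i not in self._chol:
            self._chol[i] = np.linalg.cholesky(self.matrix(i))
        return self._chol[i]

    def block_slices(self):
        for i in range(len(self.blocks)):
            yield i, slice(self.starts[i], self.starts[i + 1])

    def block_ids(self) -> np.ndarray:
        out = np.empty(self.m, dtype=int)
        for i, sl in self.block_slices():
            out[sl] = i
        return out

    def ld_scores(self, mask: np.ndarray | None = None) -> np.ndarray:
        """l_j = sum_k r_jk^2 over the block (self term included).

        With ``mask``, the sum runs only over SNPs k in the mask
        (per-annotation LD scores).
        """
        out = np.empty(self.m)
        for i, sl in self.block_slices():
            r2 = self.matrix(i) ** 2
            if mask is None:
                out[sl] = r2.sum(axis=1)
            else:
                out[sl] = r2 @ mask[sl].astype(float)
        return out

    def corr_submatrix(self, idx: np.ndarray) -> np.ndarray:
        """Correlation matrix for an arbitrary SNP index set (cross-block r = 0)."""
        idx = np.asarray(idx)
        k = len(idx)
        out = np.zeros((k, k))
        bid = np.searchsorted(self.starts, idx, side="right") - 1
        for b in np.unique(bid):
            sel = np.where(bid == b)[0]
            local = idx[sel] - self.starts[b]
            out[np.ix_(sel, sel)] = self.matrix(b)[np.ix_(local, local)]
        return out


@dataclass
class AnnotationSpec:
    """A named SNP annotation with a per-SNP heritability multiplier.

    ``fraction`` assigns whole LD blocks (deterministically spaced) until
    the requested share of SNPs is covered; alternatively give explicit
    ``snp_indices``.
    """

    name: str
    multiplier: float = 1.0
    fraction: float | None = None
    snp_indices: np.ndarray | None = None

    def mask(self, ld: LdBlocks) -> np.ndarray:
        out = np.zeros(ld.m, dtype=bool)
        if self.snp_indices is not None:
            out[np.asarray(self.snp_indices)] = True
            return out
        if self.fraction is None:
            raise ValueError(f"annotation {self.name}: need fraction or snp_indices")
        n_blocks = len(ld)
        take = max(1, round(self.fraction * n_blocks))
        step = max(1, n_blocks // take)
        chosen = list(range(0, n_blocks, step))[:take]
        for i in chosen:
            out[ld.starts[i]:ld.starts[i + 1]] = True
        return out


@dataclass
class SimulationConfig:
    """Full generative specification of a synthetic two-trait scene.

    Defaults describe the standard desk-scale scene: m = 20,000 SNPs in 200
    AR(1) blocks of 100, per-trait h2 = 0.3, n = 50,000 per trait.
    """

    m_snps: int = 20_000
    blocks: list[tuple[int, float]] | None = None
    h2: tuple[float, float] = (0.3, 0.3)
    rg_true: float = 0.0
    n: tuple[int, int] = (50_000, 50_000)
    annotations: list[AnnotationSpec] = field(default_factory=list)
    n_genes: int = 400
    snps_per_gene: int = 20
    n_sets: int = 8
    genes_per_set: int = 30
    set_overlap: dict[tuple[int, int], int] = field(default_factory=dict)
    n_tissues: int = 3
    snps_per_model: int = 4
    snp_spacing: int = 1_000
    trait_names: tuple[str, str] = ("trait_a", "trait_b")
    seed: int = 0

    def __post_init__(self):
        if np.isscalar(self.h2):
            self.h2 = (float(self.h2), float(self.h2))
        if np.isscalar(self.n):
            self.n = (int(self.n), int(self.n))
        for h in self.h2:
            if not 0 <= h < 1:
                raise ValueError("h2 must lie in [0, 1)")
        if abs(self.rg_true) > 1:
            raise ValueError("|rg_true| must be <= 1")
        if self.blocks is None:
            self.blocks = default_blocks(self.m_snps)
        if sum(s for s, _ in self.blocks) != self.m_snps:
            raise ValueError("block sizes must sum to m_snps")
        if self.n_genes * self.snps_per_gene > self.m_snps:
            raise ValueError("gene demand exceeds coordinate space")


def multiplier_vector(config: SimulationConfig, ld: LdBlocks) -> np.ndarray:
    """Per-SNP variance multipliers, normalized to mean 1 so h2 is preserved."""
    mult = np.ones(ld.m)
    for spec in config.annotations:
        if spec.multiplier <= 0:
            raise ValueError("multipliers must be positive")
        mult[spec.mask(ld)] *= spec.multiplier
    return mult / mult.mean()


def simulate_effects(
    config: SimulationConfig, rng: np.random.Generator, ld: LdBlocks | None = None
) -> np.ndarray:
    """Draw standardized per-SNP effect pairs; returns shape (m, 2).

    Effects are bivariate normal with per-SNP variance (h2/m)*multiplier per
    trait and cross-trait correlation rg_true, then rescaled so each trait's
    realized sum of squared effects equals h2 exactly.
    """
    ld = ld or LdBlocks(config.blocks)
    m = ld.m
    mult = multiplier_vector(config, ld)
    sd = np.sqrt(mult / m)
    x = rng.standard_normal(m)
    y = rng.standard_normal(m)
    rg = config.rg_true
    raw1 = sd * x
    raw2 = sd * (rg * x + np.sqrt(max(0.0, 1 - rg**2)) * y)
    out = np.empty((m, 2))
    for t, raw in enumerate((raw1, raw2)):
        h2 = config.h2[t]
        if h2 == 0:
            out[:, t] = 0.0
        else:
            out[:, t] = raw * np.sqrt(h2 / np.sum(raw**2))
    return out


def simulate_z(
    beta: np.ndarray, ld: LdBlocks, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Marginal z-scores: per block, N(sqrt(n) * R @ beta, R)."""
    z = np.empty(ld.m)
    for i, sl in ld.block_slices():
        mean = np.sqrt(n) * ld.matrix(i) @ beta[sl]
        z[sl] = mean + ld.chol(i) @ rng.standard_normal(sl.stop - sl.start)
    return z


def draw_alleles(m: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    pairs = np.array(_ALLELE_PAIRS)
    pick = rng.integers(0, len(pairs), size=m)
    return pairs[pick, 0], pairs[pick, 1]


def variant_table(
    z: np.ndarray,
    n: int,
    effect_allele: np.ndarray,
    other_allele: np.ndarray,
    snp_spacing: int = 1_000,
    chrom: str = "1",
) -> pd.DataFrame:
    """Assemble a validated variant table from simulated z-scores."""
    m = len(z)
    se = np.full(m, 1.0 / np.sqrt(n))
    df = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": (np.arange(m) + 1) * snp_spacing,
            "rsid": [f"rs{j + 1}" for j in range(m)],
            "effect_allele": effect_allele,
            "other_allele": other_allele,
            "beta": z * se,
            "se": se,
            "pvalue": 2.0 * stats.norm.sf(np.abs(z)),
            "n": float(n),
        }
    )
    return validate_variants(df)


def simulate_gene_tracks(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, "GeneSetPanel", pd.DataFrame, dict]:
    """Gene coordinates, an 8-set panel with configured overlap, and
    per-gene expression-prediction weights with their true SNP covariance.

    Gene bodies are non-overlapping runs of consecutive SNPs tiled over the
    coordinate space; strand alternates. Returns
    (genes, panel, weights table, covariance dict gene -> (snp ids, Sigma)).
    """
    from .genes import GeneSet, GeneSetPanel

    ld = LdBlocks(config.blocks)
    m, spacing = config.m_snps, config.snp_spacing
    stride = m // config.n_genes
    rows = []
    gene_snps = {}
    for g in range(config.n_genes):
        first = g * stride
        last = first + config.snps_per_gene - 1
        gid = f"G{g + 1:04d}"
        rows.append(
            (
                gid,
                "1",
                (first + 1) * spacing,
                (last + 1) * spacing,
                "+" if g % 2 == 0 else "-",
            )
        )
        gene_snps[gid] = np.arange(first, last + 1)
    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])

    all_ids = genes["gene_id"].to_numpy()
    n_sets = config.n_sets
    need = n_sets * config.genes_per_set
    if need > len(all_ids):
        raise ValueError("panel demands more genes than exist")
    chosen = rng.choice(all_ids, size=need, replace=False)
    members = {
        i: list(chosen[i * config.genes_per_set:(i + 1) * config.genes_per_set])
        for i in range(n_sets)
    }
    for (i, j), k in config.set_overlap.items():
        # plant k of set i's genes into set j, displacing j's own members
        shared = members[i][:k]
        members[j] = shared + members[j][k:]
    names = (DEFAULT_SET_NAMES * ((n_sets // 8) + 1))[:n_sets]
    panel = GeneSetPanel(
        [
            GeneSet(name=names[i], priority_rank=i + 1, genes=list(members[i]),
                    provenance="synthetic")
            for i in range(n_sets)
        ]
    )

    tissues = [f"tissue_{t + 1}" for t in range(config.n_tissues)]
    wrows = []
    covs = {}
    for gid, snps in gene_snps.items():
        model_snps = snps[: config.snps_per_model]
        covs[gid] = (
            [f"rs{s + 1}" for s in model_snps],
            ld.corr_submatrix(model_snps),
        )
        for t in tissues:
            w = rng.standard_normal(len(model_snps))
            for s, wl in zip(model_snps, w):
                wrows.append((gid, t, f"rs{s + 1}", wl))
    weights = pd.DataFrame(wrows, columns=["gene", "tissue", "snp", "weight"])
    return genes, panel, weights, covs


@dataclass
class SyntheticStudy:
    """A fully specified synthetic scene with ground truth attached."""

    config: SimulationConfig
    ld: LdBlocks
    effects: np.ndarray          # (m, 2) true standardized effects
    studies: dict               # trait name -> variant DataFrame
    metas: dict                 # trait name -> TraitMeta
    genes: pd.DataFrame
    panel: object
    weights: pd.DataFrame
    covariances: dict
    annotation_masks: dict      # name -> boolean mask over SNPs

    @property
    def trait_names(self):
        return list(self.studies)


def simulate_study(
    config: SimulationConfig,
    expression_signal: dict[str, float] | None = None,
) -> SyntheticStudy:
    """Generate the full scene deterministically from ``config.seed``.

    ``expression_signal`` maps gene_id -> alpha: before z-simulation, alpha
    times the gene's tissue_1 normalized weight vector is added to trait 1's
    effects, creating a genuine expression-mediated association for TWAS.
    """
    rng = np.random.default_rng(config.seed)
    ld = LdBlocks(config.blocks)
    ea, oa = draw_alleles(config.m_snps, rng)
    genes, panel, weights, covs = simulate_gene_tracks(config, rng)
    beta = simulate_effects(config, rng, ld)
    if expression_signal:
        t1 = weights[weights["tissue"] == "tissue_1"]
        for gid, alpha in expression_signal.items():
            sub = t1[t1["gene"] == gid]
            snp_idx = sub["snp"].str.removeprefix("rs").astype(int).to_numpy() - 1
            w = sub["weight"].to_numpy()
            sigma = covs[gid][1]
            var = float(w @ sigma @ w)
            beta[snp_idx, 0] += alpha * w / np.sqrt(var)
    studies, metas = {}, {}
    for t, name in enumerate(config.trait_names):
        z = simulate_z(beta[:, t], ld, config.n[t], rng)
        studies[name] = variant_table(z, config.n[t], ea, oa, config.snp_spacing)
        metas[name] = TraitMeta(trait_name=name, n_effective=float(config.n[t]))
    masks = {spec.name: spec.mask(ld) for spec in config.annotations}
    return SyntheticStudy(
        config=config, ld=ld, effects=beta, studies=studies, metas=metas,
        genes=genes, panel=panel, weights=weights, covariances=covs,
        annotation_masks=masks,
    )


def inject_allele_corruption(
    df: pd.DataFrame,
    rng: np.random.Generator,
    swap_frac: float = 0.05,
    strand_frac: float = 0.0,
    palindromic_frac: float = 0.03,
) -> tuple[pd.DataFrame, dict]:
    """Corrupt a variant table for harmonization tests, recording the truth.

    Swapped rows exchange the allele columns and negate beta (an equivalent
    encoding of the same association); strand rows complement both alleles;
    palindromic rows get A/T alleles and become unrecoverable by design.
    Categories are disjoint.
    """
    from .sumstats import _complement

    df = df.copy().reset_index(drop=True)
    m = len(df)
    order = rng.permutation(m)
    n_swap = int(round(swap_frac * m))
    n_strand = int(round(strand_frac * m))
    n_pal = int(round(palindromic_frac * m))
    swap_idx = order[:n_swap]
    strand_idx = order[n_swap:n_swap + n_strand]
    pal_idx = order[n_swap + n_strand:n_swap + n_strand + n_pal]

    ea = df["effect_allele"].to_numpy().copy()
    oa = df["other_allele"].to_numpy().copy()
    beta = df["beta"].to_numpy().copy()
    ea[swap_idx], oa[swap_idx] = oa[swap_idx].copy(), ea[swap_idx].copy()
    beta[swap_idx] = -beta[swap_idx]
    for i in strand_idx:
        ea[i], oa[i] = _complement(ea[i]), _complement(oa[i])
    ea[pal_idx] = "A"
    oa[pal_idx] = "T"

    df["effect_allele"], df["other_allele"], df["beta"] = ea, oa, beta
    df = validate_variants(df)
    return df, {"swapped": swap_idx, "strand": strand_idx, "palindromic": pal_idx}


# ---------------------------------------------------------------------------
# Scene serialization (for the CLI / pipeline layer)
# ---------------------------------------------------------------------------

def write_scene(study: SyntheticStudy, outdir, dialects=("tsv", "tsv")) -> dict:
    """Write a scene to disk as plain-text inputs for the pipeline.

    Returns a path manifest. ``dialects`` picks, per trait, 'tsv' (dialect A)
    or 'vcf' (GWAS-VCF dialect B).
    """
    from .genes import write_gmt
    from .sumstats import write_gwas_vcf, write_pgc_tsv

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for (name, df), dialect in zip(study.studies.items(), dialects):
        if dialect == "vcf":
            p = outdir / f"{name}.vcf"
            write_gwas_vcf(df, p, study.metas[name])
        else:
            p = outdir / f"{name}.tsv"
            write_pgc_tsv(df, p, study.metas[name])
        paths[f"study_{name}"] = str(p)
    study.genes.to_csv(outdir / "genes.tsv", sep="\t", index=False)
    paths["genes"] = str(outdir / "genes.tsv")
    write_gmt(study.panel, outdir / "panel.gmt")
    paths["panel"] = str(outdir / "panel.gmt")
    study.weights.to_csv(outdir / "twas_weights.tsv", sep="\t", index=False)
    paths["twas_weights"] = str(outdir / "twas_weights.tsv")
    cov_rows = []
    for gid, (snps, sigma) in study.covariances.items():
        for i, s1 in enumerate(snps):
            for j, s2 in enumerate(snps):
                if j >= i:
                    cov_rows.append((gid, s1, s2, sigma[i, j]))
    pd.DataFrame(cov_rows, columns=["gene", "snp1", "snp2", "value"]).to_csv(
        outdir / "twas_covariance.tsv", sep="\t", index=False
    )
    paths["twas_covariance"] = str(outdir / "twas_covariance.tsv")
    with open(outdir / "ld_blocks.yaml", "w") as fh:
        yaml.safe_dump(
            {"blocks": [[s, r] for s, r in study.ld.blocks]}, fh
        )
    paths["ld_blocks"] = str(outdir / "ld_blocks.yaml")
    annot = pd.DataFrame(
        {name: mask.astype(int) for name, mask in study.annotation_masks.items()}
    )
    if len(annot.columns):
        annot.insert(0, "snp", [f"rs{j + 1}" for j in range(study.ld.m)])
        annot.to_csv(outdir / "annotations.tsv", sep="\t", index=False)
        paths["annotations"] = str(outdir / "annotations.tsv")
    return paths


def read_ld_blocks(path) -> LdBlocks:
    with open(path) as fh:
        spec = yaml.safe_load(fh)
    return LdBlocks([(int(s), float(r)) for s, r in spec["blocks"]])
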