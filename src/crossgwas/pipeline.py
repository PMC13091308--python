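"""End-to-end orchestration of the four analysis layers.

``run_all`` executes harmonization -> gene-based association -> GSEA/DGSEA
-> TWAS -> LDSC on two studies, writing one CSV bundle per layer plus a
run manifest. Layers are individually resumable: when a layer's outputs
already exist under the output directory they are reused, so deleting one
layer's files and re-running recomputes only that layer and its dependents.

The LD reference is a block-correlation description (``ld_blocks.yaml``)
whose blocks tile the variants of each study in genomic order; study files
must carry the same variant set as the reference.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._util import derive_seed
from .genes import (
    competitive_panel_test,
    dedup_panel,
    read_gmt,
    run_gene_analysis,
)
from .gsea import RankedList, dgsea, gsea, pivot_report
from .ldsc import (
    compute_ld_scores,
    estimate_h2,
    fallback_enrichment,
    genetic_correlation,
    make_annotation_bed,
    partitioned_h2,
    snps_in_bed,
    write_bed,
)
from .simulate import read_ld_blocks
from .sumstats import harmonize_pair, read_sumstats
from .twas import load_covariance_table, load_models, panel_enrichment, run_twas


@dataclass
class RunConfig:
    """Validated configuration of a full pipeline run."""

    study_a: str
    study_b: str
    genes: str
    panel: str
    ld_blocks: str
    twas_weights: str | None = None
    twas_covariance: str | None = None
    outdir: str = "crossgwas_out"
    window_up: int = 35_000
    window_down: int = 10_000
    n_perm: int = 10_000
    min_size: int = 5
    max_size: int = 500
    weight_exponent: float = 1.0
    annotation_pad: int = 10_000
    n_jackknife_blocks: int = 200
    alpha: float = 0.05
    seed: int = 0
    trait_names: tuple[str, str] = ("study_a", "study_b")

    def __post_init__(self):
        self.validate()

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for key in ("study_a", "study_b", "genes", "panel", "ld_blocks",
                    "twas_weights", "twas_covariance"):
            val = getattr(self, key)
            if val is not None and not Path(val).exists():
                raise FileNotFoundError(f"{key}: {val}")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_perm < 1 or self.min_size < 1 or self.max_size < self.min_size:
            raise ValueError("permutation/size parameters out of range")
        if self.n_jackknife_blocks < 20:
            raise ValueError("need at least 20 jackknife blocks")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    version: str = __version__
    seeds: dict = field(default_factory=dict)
    files: dict = field(default_factory=dict)
    timings: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    failed_layer: str | None = None

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)


def _csv(df: pd.DataFrame, path: Path) -> str:
    df.to_csv(path, index=False)
    return str(path)


class Pipeline:
    """Stateful runner holding loaded inputs and per-layer logic."""

    def __init__(self, config: RunConfig):
        config.validate()
        self.cfg = config
        self.out = Path(config.outdir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.manifest = RunManifest(config_hash=config.config_hash())
        self.studies = {}
        self.metas = {}
        self.ledgers = {}
        for name, path in zip(config.trait_names, (config.study_a, config.study_b)):
            df, meta, ledger = read_sumstats(path, trait_name=name)
            self.studies[name] = df
            self.metas[name] = meta
            self.ledgers[name] = ledger
        self.ld = read_ld_blocks(config.ld_blocks)
        for name, df in self.studies.items():
            if len(df) != self.ld.m:
                raise ValueError(
                    f"{name}: {len(df)} variants but LD reference covers {self.ld.m}"
                )
        self.genes = pd.read_csv(config.genes, sep="\t")
        self.panel, _ = dedup_panel(read_gmt(config.panel))
        self.gene_results = {}

    # -- layers -------------------------------------------------------------

    def _done(self, *names) -> bool:
        return all((self.out / n).exists() for n in names)

    def harmonize(self, resume=False):
        files = ["harmonized.csv", "exclusion_ledger.csv"]
        if resume and self._done(*files):
            return
        na, nb = self.cfg.trait_names
        pair = harmonize_pair(
            self.studies[na], self.studies[nb], self.metas[na], self.metas[nb]
        )
        self.manifest.files["harmonize"] = [
            _csv(pair.table, self.out / files[0]),
            _csv(pair.ledger_frame(), self.out / files[1]),
        ]

    def gene_scores(self, resume=False):
        paths = {}
        for name, df in self.studies.items():
            fn = f"genes_{name}.csv"
            if resume and self._done(fn):
                self.gene_results[name] = pd.read_csv(
                    self.out / fn, float_precision="round_trip"
                )
            else:
                res = run_gene_analysis(
                    df, self.genes, self.ld.corr_submatrix,
                    self.cfg.window_up, self.cfg.window_down,
                )
                self.gene_results[name] = res
                paths[fn] = _csv(res, self.out / fn)
            st = f"set_tests_{name}.csv"
            if not (resume and self._done(st)):
                paths[st] = _csv(
                    competitive_panel_test(
                        self.gene_results[name], self.panel, self.cfg.alpha
                    ),
                    self.out / st,
                )
        self.manifest.files["gene_analysis"] = sorted(paths.values())

    def enrichment(self, resume=False):
        na, nb = self.cfg.trait_names
        files = [f"gsea_{na}.csv", f"gsea_{nb}.csv", "gsea_pivot.csv", "dgsea.csv"]
        if resume and self._done(*files):
            return
        seed = derive_seed(self.cfg.seed, "gsea")
        ranked = {
            name: RankedList.from_gene_results(res)
            for name, res in self.gene_results.items()
        }
        results = {}
        out_files = []
        for name in (na, nb):
            res = gsea(
                ranked[name], self.panel, self.cfg.n_perm, self.cfg.min_size,
                self.cfg.max_size, self.cfg.weight_exponent,
                seed=derive_seed(seed, name),
            )
            results[name] = res
            out_files.append(_csv(res, self.out / f"gsea_{name}.csv"))
        out_files.append(_csv(pivot_report(results), self.out / "gsea_pivot.csv"))
        dg = dgsea(
            ranked[na], ranked[nb], self.panel, self.cfg.n_perm,
            seed=derive_seed(seed, "dgsea"),
            weight_exponent=self.cfg.weight_exponent, labels=(na, nb),
        )
        out_files.append(_csv(dg, self.out / "dgsea.csv"))
        self.manifest.seeds["gsea"] = seed
        self.manifest.files["enrichment"] = out_files

    def twas(self, resume=False):
        if self.cfg.twas_weights is None or self.cfg.twas_covariance is None:
            self.manifest.warnings.append("twas: no models configured; skipped")
            return
        files = []
        weights = pd.read_csv(self.cfg.twas_weights, sep="\t")
        covs = load_covariance_table(self.cfg.twas_covariance)
        models = load_models(weights, covs)
        for name, df in self.studies.items():
            fns = [f"twas_{name}.csv", f"twas_sets_{name}.csv", f"twas_best_{name}.csv"]
            if resume and self._done(*fns):
                continue
            res = run_twas(df, models)
            from .twas import best_tissue_summary

            files += [
                _csv(res, self.out / fns[0]),
                _csv(panel_enrichment(res, self.panel, self.cfg.alpha), self.out / fns[1]),
                _csv(best_tissue_summary(res), self.out / fns[2]),
            ]
        self.manifest.files["twas"] = files

    def ldsc(self, resume=False):
        na, nb = self.cfg.trait_names
        files = [f"partitioned_{na}.csv", f"partitioned_{nb}.csv",
                 "ldsc_summary.csv", "rg.csv"]
        if resume and self._done(*files):
            return
        beds = {}
        masks = {}
        n_genes = {}
        ref_variants = self.studies[na]
        for s in self.panel:
            sub = self.genes[self.genes["gene_id"].isin(s.genes)]
            if not len(sub):
                continue
            bed = make_annotation_bed(sub, self.cfg.annotation_pad)
            bed_path = self.out / f"annotation_{s.name}.bed"
            write_bed(bed, bed_path)
            beds[s.name] = str(bed_path)
            masks[s.name] = snps_in_bed(ref_variants, bed)
            n_genes[s.name] = len(sub)
        scores = compute_ld_scores(self.ld, masks)
        out_files = list(beds.values())

        summary_rows = []
        for name, df in self.studies.items():
            chi2 = df["chi2"].to_numpy()
            h2 = estimate_h2(
                chi2, scores["l2"].to_numpy(), self.metas[name].n_effective,
                n_blocks=self.cfg.n_jackknife_blocks,
            )
            summary_rows.append({"trait": name, **h2.__dict__})
            if masks:
                part = partitioned_h2(
                    chi2, scores, masks, self.metas[name].n_effective,
                    self.cfg.n_jackknife_blocks, n_genes,
                )
                fb = [
                    {"annotation": k,
                     **fallback_enrichment(chi2, m, scores["l2"].to_numpy())}
                    for k, m in masks.items()
                ]
                part = part.merge(
                    pd.DataFrame(fb).rename(
                        columns={"ratio": "fallback_ratio", "mw_p": "fallback_mw_p",
                                 "floored": "fallback_floored"}
                    ),
                    on="annotation",
                )
                out_files.append(_csv(part, self.out / f"partitioned_{name}.csv"))
        out_files.append(
            _csv(pd.DataFrame(summary_rows), self.out / "ldsc_summary.csv")
        )

        harm = pd.read_csv(self.out / "harmonized.csv", float_precision="round_trip")
        merged = harm.merge(
            ref_variants.reset_index()[["index", "rsid"]], on="rsid", how="inner"
        )
        rg = genetic_correlation(
            merged["z_a"].to_numpy(), merged["z_b"].to_numpy(),
            scores["l2"].to_numpy()[merged["index"].to_numpy()],
            self.metas[na].n_effective, self.metas[nb].n_effective,
            m=self.ld.m, n_blocks=self.cfg.n_jackknife_blocks,
        )
        out_files.append(_csv(rg.to_frame(), self.out / "rg.csv"))
        self.manifest.files["ldsc"] = out_files

    LAYERS = ("harmonize", "gene_scores", "enrichment", "twas", "ldsc")

    def run_all(self, resume=False) -> RunManifest:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            for layer in self.LAYERS:
                t0 = time.time()
                try:
                    getattr(self, layer)(resume=resume)
                except Exception as exc:  # record failure point, stop downstream
                    self.manifest.failed_layer = layer
                    self.manifest.warnings.append(f"{layer}: {exc}")
                    break
                self.manifest.timings[layer] = round(time.time() - t0, 3)
            self.manifest.warnings += [str(w.message) for w in caught]
        self.manifest.seeds["global"] = self.cfg.seed
        self.manifest.save(self.out / "manifest.json")
        return self.manifest


def run_all(config: RunConfig, resume: bool = False) -> RunManifest:
    return Pipeline(config).run_all(resume=resume)


def simulate_and_validate(
    sim_config, outdir, n_perm: int = 2_000, dialects=("tsv", "vcf")
) -> pd.DataFrame:
    """Generate a scene, run the full pipeline on it, and compare estimates
    with the generator's ground truth.

    Reports estimated vs true h2 per trait, rg (flagged ``consistent with
    zero`` when |rg| < 2 SE), and per-annotation enrichment against the
    configured multipliers. Refuses configs with no truth to validate
    (zero heritability on both traits and no annotations).
    """
    from .simulate import multiplier_vector, simulate_study, write_scene

    if all(h == 0 for h in sim_config.h2) and not sim_config.annotations:
        raise ValueError(
            "nothing to validate: give the simulation nonzero h2, rg or "
            "annotation multipliers"
        )
    outdir = Path(outdir)
    study = simulate_study(sim_config)
    paths = write_scene(study, outdir / "scene", dialects=dialects)
    cfg = RunConfig(
        study_a=paths[f"study_{sim_config.trait_names[0]}"],
        study_b=paths[f"study_{sim_config.trait_names[1]}"],
        genes=paths["genes"],
        panel=paths["panel"],
        ld_blocks=paths["ld_blocks"],
        twas_weights=paths.get("twas_weights"),
        twas_covariance=paths.get("twas_covariance"),
        outdir=str(outdir / "run"),
        n_perm=n_perm,
        seed=sim_config.seed,
        trait_names=sim_config.trait_names,
    )
    run_all(cfg)
    out = Path(cfg.outdir)
    summary = pd.read_csv(out / "ldsc_summary.csv")
    rg = pd.read_csv(out / "rg.csv").iloc[0]
    rows = []
    for t, name in enumerate(sim_config.trait_names):
        row = summary[summary["trait"] == name].iloc[0]
        rows.append(
            {"quantity": f"h2_{name}", "truth": sim_config.h2[t],
             "estimate": row["h2"], "se": row["h2_se"],
             "within_2se": abs(row["h2"] - sim_config.h2[t]) < 2 * row["h2_se"]}
        )
    rows.append(
        {"quantity": "rg", "truth": sim_config.rg_true, "estimate": rg["rg"],
         "se": rg["se"],
         "within_2se": abs(rg["rg"] - sim_config.rg_true) < 2 * rg["se"],
         "flag": "consistent with zero" if abs(rg["rg"]) < 2 * rg["se"] else ""}
    )
    if sim_config.annotations:
        ld = study.ld
        mult = multiplier_vector(sim_config, ld)
        from .ldsc import compute_ld_scores as _cls

        scores = _cls(ld, study.annotation_masks)
        for t, name in enumerate(sim_config.trait_names):
            chi2 = study.studies[name]["chi2"].to_numpy()
            part = partitioned_h2(
                chi2, scores, study.annotation_masks,
                sim_config.n[t], n_genes=None,
            )
            for spec in sim_config.annotations:
                mask = study.annotation_masks[spec.name]
                true_enr = float(mult[mask].mean())
                row = part[part["annotation"] == spec.name].iloc[0]
                rows.append(
                    {"quantity": f"enrichment_{spec.name}_{name}",
                     "truth": true_enr, "estimate": row["enrichment"],
                     "se": row["se_jackknife"],
                     "within_2se": abs(row["enrichment"] - true_enr)
                     < 2 * row["se_jackknife"]}
                )
    report = pd.DataFrame(rows)
    report.to_csv(out / "validation.csv", index=False)
    return report
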