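"""Reading, validation and harmonization of GWAS summary statistics.

Two dialects are supported:

* **Dialect A** — PGC-style tab-separated text with per-variant effect, SE,
  p-value and sample size (or case/control counts).
* **Dialect B** — GWAS-VCF: VCF 4.x with a single sample column carrying
  ``ES:SE:LP`` FORMAT fields (effect size, standard error, -log10 p).
  ALT is the effect allele.

Variant tables are plain :class:`pandas.DataFrame` objects with the columns
in :data:`VARIANT_COLUMNS`; ``z`` and ``chi2`` are derived on read.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

VARIANT_COLUMNS = [
    "chrom",
    "pos",
    "rsid",
    "effect_allele",
    "other_allele",
    "beta",
    "se",
    "pvalue",
    "n",
    "z",
    "chi2",
]

#: smallest positive double; p-values that underflow are floored here, never 0
MIN_PVALUE = np.nextafter(0.0, 1.0)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: default logical -> header mapping for dialect A
DEFAULT_COLUMN_MAP = {
    "SNP": "SNP",
    "CHR": "CHR",
    "BP": "BP",
    "A1": "A1",
    "A2": "A2",
    "BETA": "BETA",
    "OR": "OR",
    "SE": "SE",
    "P": "P",
    "N": "N",
    "NCA": "NCA",
    "NCO": "NCO",
}


@dataclass
class TraitMeta:
    """Study-level metadata carried alongside a variant table."""

    trait_name: str
    n_effective: float
    n_cases: int | None = None
    n_controls: int | None = None
    genome_build: str = "GRCh37"

    def __post_init__(self):
        if self.n_effective is not None and self.n_effective <= 0:
            raise ValueError("n_effective must be positive")
        if self.n_cases is not None and self.n_controls is not None:
            expected = effective_sample_size(self.n_cases, self.n_controls)
            if abs(self.n_effective - expected) > 1:
                raise ValueError(
                    f"n_effective {self.n_effective} inconsistent with "
                    f"effective size {expected} from case/control counts"
                )


@dataclass
class HarmonizedPair:
    """Two studies aligned onto a shared variant set.

    ``table`` is keyed by chrom:pos and carries study-1 allele orientation;
    study-2 z-scores have been sign-aligned to study 1's effect allele.
    """

    table: pd.DataFrame
    ledger: Counter = field(default_factory=Counter)
    meta_a: TraitMeta | None = None
    meta_b: TraitMeta | None = None

    def ledger_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.ledger.items()), columns=["reason", "count"]
        )


def effective_sample_size(n_cases: int, n_controls: int) -> int:
    """Effective N of a case-control design: round(4 / (1/Nca + 1/Nco))."""
    if n_cases <= 0 or n_controls <= 0:
        raise ValueError("case and control counts must be positive")
    return round(4.0 / (1.0 / n_cases + 1.0 / n_controls))


def is_palindromic(a1, a2) -> bool:
    """A/T and C/G pairs cannot be strand-resolved from alleles alone."""
    return {str(a1).upper(), str(a2).upper()} in ({"A", "T"}, {"C", "G"})


def _complement(allele: str) -> str:
    try:
        return "".join(_COMPLEMENT[b] for b in allele.upper())
    except KeyError:
        return "?"  # non-ACGT alleles (indels) have no strand complement


def validate_variants(df: pd.DataFrame, ledger: Counter | None = None) -> pd.DataFrame:
    """Apply row-level invariants, dropping and counting failures.

    Ensures se > 0, p in (0, 1] (underflowed p floored at the smallest
    positive double, with ``pvalue_floored`` flag), alleles distinct;
    derives z = beta/se and chi2 = z^2.
    """
    if ledger is None:
        ledger = Counter()
    df = df.copy()

    bad = ~(df["se"] > 0) | ~np.isfinite(df["se"])
    ledger["nonpositive_se"] += int(bad.sum())
    df = df[~bad]

    bad = ~np.isfinite(df["beta"])
    ledger["missing_beta"] += int(bad.sum())
    df = df[~bad]

    floored = df["pvalue"] == 0
    df.loc[floored, "pvalue"] = MIN_PVALUE
    df["pvalue_floored"] = floored

    bad = ~((df["pvalue"] > 0) & (df["pvalue"] <= 1))
    ledger["invalid_pvalue"] += int(bad.sum())
    df = df[~bad]

    bad = (
        df["effect_allele"].str.upper() == df["other_allele"].str.upper()
    )
    ledger["identical_alleles"] += int(bad.sum())
    df = df[~bad]

    df["z"] = df["beta"] / df["se"]
    df["chi2"] = df["z"] ** 2
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Dialect A: PGC-style TSV
# ---------------------------------------------------------------------------

def read_pgc_tsv(
    path,
    column_map: dict | None = None,
    trait_name: str | None = None,
    genome_build: str = "GRCh37",
) -> tuple[pd.DataFrame, TraitMeta, Counter]:
    """Read a dialect-A summary-statistics file.

    Required logical columns: SNP, CHR, BP, A1 (effect), A2, BETA (or OR),
    SE, P, and N or (NCA, NCO). With case/control counts the per-variant
    effective N is computed; ``OR`` columns are log-transformed to beta.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    raw = pd.read_csv(
        path, sep="\t", dtype={cmap["CHR"]: str}, float_precision="round_trip"
    )
    ledger: Counter = Counter()

    def col(logical):
        name = cmap[logical]
        return raw[name] if name in raw.columns else None

    for logical in ("SNP", "CHR", "BP", "A1", "A2", "SE", "P"):
        if cmap[logical] not in raw.columns:
            raise ValueError(f"missing mandatory column {cmap[logical]!r} ({logical})")

    beta = col("BETA")
    if beta is None:
        odds = col("OR")
        if odds is None:
            raise ValueError("need a BETA or OR column")
        beta = np.log(odds.astype(float))

    nca, nco = col("NCA"), col("NCO")
    if col("N") is not None:
        n = col("N").astype(float)
        n_cases = n_controls = None
    elif nca is not None and nco is not None:
        nca_f, nco_f = nca.astype(float), nco.astype(float)
        n = 4.0 / (1.0 / nca_f + 1.0 / nco_f)
        n_cases, n_controls = int(nca_f.iloc[0]), int(nco_f.iloc[0])
    else:
        raise ValueError("need N or both NCA and NCO columns")

    df = pd.DataFrame(
        {
            "chrom": col("CHR").astype(str),
            "pos": col("BP").astype(int),
            "rsid": col("SNP").astype(str),
            "effect_allele": col("A1").astype(str).str.upper(),
            "other_allele": col("A2").astype(str).str.upper(),
            "beta": beta.astype(float),
            "se": col("SE").astype(float),
            "pvalue": col("P").astype(float),
            "n": n,
        }
    )
    df = validate_variants(df, ledger)
    meta = TraitMeta(
        trait_name=trait_name or Path(path).stem,
        n_effective=float(np.median(df["n"])) if len(df) else 1.0,
        n_cases=n_cases,
        n_controls=n_controls,
        genome_build=genome_build,
    )
    return df, meta, ledger


def write_pgc_tsv(df: pd.DataFrame, path, meta: TraitMeta | None = None) -> None:
    """Write a variant table as dialect-A TSV (full float precision)."""
    out = pd.DataFrame(
        {
            "SNP": df["rsid"],
            "CHR": df["chrom"],
            "BP": df["pos"],
            "A1": df["effect_allele"],
            "A2": df["other_allele"],
            "BETA": df["beta"],
            "SE": df["se"],
            "P": df["pvalue"],
            "N": df["n"],
        }
    )
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Dialect B: GWAS-VCF (ES:SE:LP, single sample)
# ---------------------------------------------------------------------------

def write_gwas_vcf(df: pd.DataFrame, path, meta: TraitMeta) -> None:
    """Write a variant table as a GWAS-VCF text file.

    ALT carries the effect allele, REF the other allele; per-variant sample
    size goes in the SS field. Floats are written with shortest round-trip
    precision so read-back is bit-exact.
    """
    sample = meta.trait_name.replace(" ", "_") or "study"
    contigs = list(dict.fromkeys(df["chrom"].astype(str)))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##genome_build={meta.genome_build}\n")
        fh.write(f"##trait_n_effective={meta.n_effective!r}\n")
        if meta.n_cases is not None:
            fh.write(f"##trait_n_cases={meta.n_cases}\n")
        if meta.n_controls is not None:
            fh.write(f"##trait_n_controls={meta.n_controls}\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=ES,Number=A,Type=Float,Description="Effect size estimate relative to the alternative allele">\n')
        fh.write('##FORMAT=<ID=SE,Number=A,Type=Float,Description="Standard error of effect size estimate">\n')
        fh.write('##FORMAT=<ID=LP,Number=A,Type=Float,Description="-log10 p-value for effect estimate">\n')
        fh.write('##FORMAT=<ID=SS,Number=A,Type=Float,Description="Sample size used to estimate genetic effect">\n')
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n")
        lp = -np.log10(df["pvalue"].to_numpy())
        for row, lp_i in zip(df.itertuples(index=False), lp):
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.rsid or '.'}\t{row.other_allele}\t"
                f"{row.effect_allele}\t.\tPASS\t.\tES:SE:LP:SS\t"
                f"{float(row.beta)!r}:{float(row.se)!r}:{float(lp_i)!r}:{float(row.n)!r}\n"
            )


def read_gwas_vcf(
    path, trait_name: str | None = None
) -> tuple[pd.DataFrame, TraitMeta, Counter]:
    """Read a GWAS-VCF file (single sample, ES:SE:LP[:SS] FORMAT).

    The sample fields are parsed at text level so beta/SE round-trip at full
    double precision (binary Float encodings would truncate to 32 bits).
    Multi-allelic records are skipped and counted; a missing LP is replaced
    by the two-sided normal p of beta/SE.
    """
    ledger: Counter = Counter()
    build = "GRCh37"
    n_eff_header = None
    n_cases = n_controls = None
    sample = None
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##"):
                if line.startswith("##genome_build="):
                    build = line.split("=", 1)[1]
                elif line.startswith("##trait_n_effective="):
                    n_eff_header = float(line.split("=", 1)[1])
                elif line.startswith("##trait_n_cases="):
                    n_cases = int(line.split("=", 1)[1])
                elif line.startswith("##trait_n_controls="):
                    n_controls = int(line.split("=", 1)[1])
                continue
            if line.startswith("#CHROM"):
                header = line.split("\t")
                if len(header) != 10:
                    raise ValueError("expected exactly one sample column")
                sample = header[9]
                continue
            parts = line.split("\t")
            chrom, pos, vid, ref, alt = parts[0], int(parts[1]), parts[2], parts[3], parts[4]
            if "," in alt:
                ledger["multiallelic"] += 1
                continue
            fmt = parts[8].split(":")
            vals = dict(zip(fmt, parts[9].split(":")))
            try:
                beta = float(vals["ES"])
                se = float(vals["SE"])
            except (KeyError, ValueError):
                ledger["unparseable_row"] += 1
                continue
            lp = vals.get("LP", ".")
            if lp in (".", ""):
                p = 2.0 * stats.norm.sf(abs(beta / se)) if se > 0 else np.nan
            else:
                p = 10.0 ** (-float(lp))
            n = float(vals["SS"]) if vals.get("SS", ".") not in (".", "") else np.nan
            rows.append(
                (chrom, pos, None if vid == "." else vid, alt.upper(), ref.upper(), beta, se, p, n)
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "chrom", "pos", "rsid", "effect_allele", "other_allele",
            "beta", "se", "pvalue", "n",
        ],
    )
    df = validate_variants(df, ledger)
    n_eff = n_eff_header
    if n_eff is None:
        n_eff = float(np.median(df["n"])) if len(df) and np.isfinite(df["n"]).all() else 1.0
    meta = TraitMeta(
        trait_name=trait_name or sample or Path(path).stem,
        n_effective=n_eff,
        n_cases=n_cases,
        n_controls=n_controls,
        genome_build=build,
    )
    return df, meta, ledger


def read_sumstats(path, **kwargs) -> tuple[pd.DataFrame, TraitMeta, Counter]:
    """Auto-detect dialect from the file contents and dispatch."""
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("##fileformat=VCF"):
        kwargs.pop("column_map", None)
        return read_gwas_vcf(path, **kwargs)
    return read_pgc_tsv(path, **kwargs)


# ---------------------------------------------------------------------------
# Harmonization
# ---------------------------------------------------------------------------

def _dedup_key(df: pd.DataFrame, ledger: Counter, tag: str) -> pd.DataFrame:
    key = df["chrom"].astype(str) + ":" + df["pos"].astype(str)
    dup = key.duplicated(keep="first")
    ledger[f"duplicate_key_{tag}"] += int(dup.sum())
    df = df[~dup].copy()
    df["key"] = key[~dup].to_numpy()
    return df


def harmonize_pair(
    a: pd.DataFrame,
    b: pd.DataFrame,
    meta_a: TraitMeta | None = None,
    meta_b: TraitMeta | None = None,
) -> HarmonizedPair:
    """Align two validated studies onto a shared variant set.

    Matching is on chrom:pos with rsID as a fallback for keys absent from
    the positional index; an rsID match whose coordinates conflict is
    rejected. Allele handling on each match: exact -> keep; swapped ->
    negate study-2 z; strand-complemented -> complement, then the same two
    rules. Palindromic (A/T, C/G) variants are always excluded, as are
    allele-incompatible pairs. Every input variant lands either in the
    shared table or in exactly one exclusion category of the ledger.
    """
    if meta_a is not None and meta_b is not None:
        if meta_a.genome_build != meta_b.genome_build:
            raise ValueError(
                f"genome builds differ: {meta_a.genome_build} vs {meta_b.genome_build}"
            )
    ledger: Counter = Counter()

    def drop_palindromic(df, tag):
        if not len(df):
            return df
        ea = df["effect_allele"].str.upper()
        oa = df["other_allele"].str.upper()
        pal = ((ea == "A") & (oa == "T")) | ((ea == "T") & (oa == "A")) | (
            (ea == "C") & (oa == "G")
        ) | ((ea == "G") & (oa == "C"))
        ledger[f"palindromic_{tag}"] += int(pal.sum())
        return df[~pal.to_numpy()]

    a = drop_palindromic(a, "a")
    b = drop_palindromic(b, "b")
    a = _dedup_key(a, ledger, "a")
    b = _dedup_key(b, ledger, "b")

    merged = a[a["pos"].notna()].merge(
        b[b["pos"].notna()], on="key", how="inner", suffixes=("_a", "_b")
    )

    # rsID fallback only for rows absent from the positional match
    left_a = a[~a["key"].isin(merged["key"])]
    left_b = b[~b["key"].isin(merged["key"])]
    rescued = (
        left_a[left_a["rsid"].notna()]
        .merge(left_b[left_b["rsid"].notna()], on="rsid", how="inner", suffixes=("_a", "_b"))
    )
    if len(rescued):
        conflict = (
            rescued["pos_a"].notna()
            & rescued["pos_b"].notna()
            & (
                (rescued["chrom_a"].astype(str) != rescued["chrom_b"].astype(str))
                | (rescued["pos_a"] != rescued["pos_b"])
            )
        )
        ledger["position_conflict"] += int(conflict.sum())
        rescued = rescued[~conflict].copy()
        rescued["rsid_a"] = rescued["rsid"]

    rescued_keys_a = set(rescued["key_a"]) if len(rescued) else set()
    rescued_keys_b = set(rescued["key_b"]) if len(rescued) else set()
    conflict_n = ledger["position_conflict"]
    ledger["unmatched_a"] += int(
        (~left_a["key"].isin(rescued_keys_a)).sum() - conflict_n
    )
    ledger["unmatched_b"] += int(
        (~left_b["key"].isin(rescued_keys_b)).sum() - conflict_n
    )

    if len(rescued):
        rescued = rescued.rename(columns={"key_a": "key"})
        common = [c for c in merged.columns if c in rescued.columns]
        merged = pd.concat([merged[common], rescued[common]], ignore_index=True)

    if not len(merged):
        table = pd.DataFrame(
            columns=["key", "chrom", "pos", "rsid", "effect_allele", "other_allele",
                     "z_a", "z_b", "n_a", "n_b"]
        )
        return HarmonizedPair(table=table, ledger=ledger, meta_a=meta_a, meta_b=meta_b)

    ea_a = merged["effect_allele_a"].to_numpy()
    oa_a = merged["other_allele_a"].to_numpy()
    ea_b = merged["effect_allele_b"].to_numpy()
    oa_b = merged["other_allele_b"].to_numpy()
    ea_bc = np.array([_complement(x) or "?" for x in ea_b])
    oa_bc = np.array([_complement(x) or "?" for x in oa_b])

    exact = (ea_a == ea_b) & (oa_a == oa_b)
    swapped = (ea_a == oa_b) & (oa_a == ea_b)
    comp = ~exact & ~swapped & (ea_a == ea_bc) & (oa_a == oa_bc)
    comp_swapped = ~exact & ~swapped & (ea_a == oa_bc) & (oa_a == ea_bc)
    keep = exact | swapped | comp | comp_swapped
    flip = swapped | comp_swapped

    ledger["allele_mismatch"] += int((~keep).sum())

    table = pd.DataFrame(
        {
            "key": merged["key"],
            "chrom": merged["chrom_a"],
            "pos": merged["pos_a"],
            "rsid": merged["rsid_a"],
            "effect_allele": ea_a,
            "other_allele": oa_a,
            "z_a": merged["z_a"].to_numpy(),
            "z_b": np.where(flip, -merged["z_b"].to_numpy(), merged["z_b"].to_numpy()),
            "beta_a": merged["beta_a"].to_numpy(),
            "beta_b": np.where(flip, -merged["beta_b"].to_numpy(), merged["beta_b"].to_numpy()),
            "n_a": merged["n_a"].to_numpy(),
            "n_b": merged["n_b"].to_numpy(),
        }
    )[keep].reset_index(drop=True)
    table = table.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    return HarmonizedPair(table=table, ledger=ledger, meta_a=meta_a, meta_b=meta_b)


def pair_to_tables(pair: HarmonizedPair) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Re-expand a harmonized pair into two aligned variant tables.

    Useful for checking that harmonization is an involution: running
    :func:`harmonize_pair` on the result changes nothing.
    """
    base = pair.table
    def mk(side):
        se = 1.0 / np.sqrt(base[f"n_{side}"].to_numpy(dtype=float))
        z = base[f"z_{side}"].to_numpy()
        return validate_variants(pd.DataFrame(
            {
                "chrom": base["chrom"],
                "pos": base["pos"],
                "rsid": base["rsid"],
                "effect_allele": base["effect_allele"],
                "other_allele": base["other_allele"],
                "beta": z * se,
                "se": se,
                "pvalue": 2.0 * stats.norm.sf(np.abs(z)),
                "n": base[f"n_{side}"],
            }
        ))
    return mk("a"), mk("b")
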