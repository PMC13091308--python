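"""Weighted Kolmogorov-Smirnov gene-set enrichment on ranked gene Z-scores.

Implements preranked GSEA with gene-label permutation nulls (no
individual-level data exists for summary statistics, so phenotype
permutation is unavailable), normalized enrichment scores, the (1+b)/(1+n)
permutation p-value rule, and BH FDR across the sets of a run. The
differential layer (DGSEA) compares normalized enrichment between two
disorders' rankings over every pair of distinct sets, with a permutation
null on the NES difference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import bh_fdr


@dataclass
class RankedList:
    """Genes ordered by descending score; ties broken by gene id (stable)."""

    genes: np.ndarray
    scores: np.ndarray

    @classmethod
    def from_scores(cls, genes, scores) -> "RankedList":
        genes = np.asarray(genes, dtype=object)
        scores = np.asarray(scores, dtype=float)
        if len(set(genes)) != len(genes):
            raise ValueError("gene ids must be unique")
        order = np.lexsort((genes, -scores))
        return cls(genes=genes[order], scores=scores[order])

    @classmethod
    def from_gene_results(cls, gene_results: pd.DataFrame) -> "RankedList":
        return cls.from_scores(
            gene_results["gene_id"].to_numpy(), gene_results["z"].to_numpy()
        )

    def __len__(self):
        return len(self.genes)

    def positions_of(self, members) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.genes)}
        return np.array(sorted(lookup[g] for g in members if g in lookup), dtype=int)


def _hit_extrema(positions, weights, n_total):
    """Candidate running-sum extrema from hit positions alone.

    The running profile is piecewise linear between hits, so its maximum is
    attained at a hit and its minimum immediately before a hit. Works on a
    batch: positions/weights of shape (..., n).
    """
    n = positions.shape[-1]
    miss_dec = 1.0 / (n_total - n)
    cum = np.cumsum(weights, axis=-1)
    total = cum[..., -1:]
    i = np.arange(1, n + 1)
    at_hit = cum / total - (positions + 1 - i) * miss_dec
    before_hit = (cum - weights) / total - (positions - i + 1) * miss_dec
    return at_hit, before_hit


def enrichment_score(
    ranked: RankedList, members, weight_exponent: float = 1.0
):
    """Weighted KS enrichment score of a gene set in a ranked list.

    Hits increment the running sum by |score|^weight_exponent normalized by
    the set total; misses decrement by 1/(N - n_set). The ES is the
    maximum-magnitude excursion (ties resolved toward the positive side).

    Returns (es, running_profile, leading_edge_genes). With
    ``weight_exponent=0`` and distinct scores this reduces to the classic
    two-sample KS statistic between member and non-member ranks.
    """
    n_total = len(ranked)
    pos = ranked.positions_of(members)
    n = len(pos)
    if n == 0:
        raise ValueError("gene set does not intersect the ranked universe")
    if n >= n_total:
        raise ValueError("gene set covers the whole universe")
    w = np.abs(ranked.scores[pos]) ** weight_exponent
    if w.sum() == 0:
        w = np.ones(n)  # all-zero scores at the hits: fall back to equal mass
    at_hit, before_hit = _hit_extrema(pos, w, n_total)
    i_max = int(np.argmax(at_hit))
    i_min = int(np.argmin(before_hit))
    es_pos, es_neg = float(at_hit[i_max]), float(before_hit[i_min])
    # exact ties (frequent at weight 0) resolve to the positive excursion
    es = es_pos if es_pos >= -es_neg - 1e-12 else es_neg

    hit_mask = np.zeros(n_total, dtype=bool)
    hit_mask[pos] = True
    steps = np.where(hit_mask, 0.0, -1.0 / (n_total - n))
    steps[pos] = w / w.sum()
    running = np.cumsum(steps)
    if es >= 0:
        leading = ranked.genes[pos[: i_max + 1]]
    else:
        leading = ranked.genes[pos[i_min:]]
    return es, running, list(leading)


def _null_es(
    scores: np.ndarray,
    set_size: int,
    n_perm: int,
    weight_exponent: float,
    rng: np.random.Generator,
    chunk: int = 512,
) -> np.ndarray:
    """Null ES distribution for random same-size gene sets (vectorized)."""
    n_total = len(scores)
    w_all = np.abs(scores) ** weight_exponent
    out = np.empty(n_perm)
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        u = rng.random((b, n_total))
        pos = np.argpartition(u, set_size, axis=1)[:, :set_size]
        pos.sort(axis=1)
        w = w_all[pos]
        zero = w.sum(axis=1) == 0
        if zero.any():
            w[zero] = 1.0
        at_hit, before_hit = _hit_extrema(pos, w, n_total)
        es_pos = at_hit.max(axis=1)
        es_neg = before_hit.min(axis=1)
        out[done:done + b] = np.where(es_pos >= -es_neg - 1e-12, es_pos, es_neg)
        done += b
    return out


def _normalize(es: float, null: np.ndarray):
    """NES and permutation p against the same-sign half of the null."""
    same = null >= 0 if es >= 0 else null < 0
    n_same = int(same.sum())
    if n_same == 0:
        return np.nan, 1.0, n_same
    denom = float(np.mean(np.abs(null[same])))
    nes = es / denom if denom > 0 else np.nan
    b = int(np.sum(np.abs(null[same]) >= abs(es)))
    p = (1 + b) / (1 + n_same)
    return nes, p, n_same


def gsea(
    ranked: RankedList,
    panel,
    n_perm: int = 10_000,
    min_size: int = 5,
    max_size: int = 500,
    weight_exponent: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Preranked GSEA over a panel with gene-label permutation nulls.

    Sets whose intersection with the universe falls outside
    [min_size, max_size] are reported with a skip reason. Null draws are
    shared across sets of equal size. NES normalizes ES by the mean |null
    ES| of matching sign; p uses the +1 counting rule; q is BH across the
    sets tested in this run.
    """
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives unstable NES estimates")
    rng = np.random.default_rng(seed)
    sets = list(panel)
    sizes = {}
    for s in sets:
        sizes[s.name] = len(ranked.positions_of(s.genes))
    null_cache: dict[int, np.ndarray] = {}
    for size in sorted({v for v in sizes.values() if min_size <= v <= max_size}):
        null_cache[size] = _null_es(
            ranked.scores, size, n_perm, weight_exponent, rng
        )
    rows = []
    for s in sets:
        size = sizes[s.name]
        if size < min_size or size > max_size:
            reason = "too_small" if size < min_size else "too_large"
            rows.append(
                {"set": s.name, "n_genes": size, "es": np.nan, "nes": np.nan,
                 "p_perm": np.nan, "leading_edge": "", "n_perm": n_perm,
                 "seed": seed, "skipped": reason}
            )
            continue
        es, _, leading = enrichment_score(ranked, s.genes, weight_exponent)
        nes, p, _ = _normalize(es, null_cache[size])
        rows.append(
            {"set": s.name, "n_genes": size, "es": es, "nes": nes,
             "p_perm": p, "leading_edge": "|".join(map(str, leading)),
             "n_perm": n_perm, "seed": seed, "skipped": ""}
        )
    out = pd.DataFrame(rows)
    out["fdr_q"] = bh_fdr(out["p_perm"].to_numpy())
    return out


def nes_difference(nes_a: float, nes_b: float) -> float:
    """Descriptive NES difference between two set/disorder combinations."""
    return float(nes_a) - float(nes_b)


def dgsea(
    ranked_a: RankedList,
    ranked_b: RankedList,
    panel,
    n_perm: int = 10_000,
    seed: int = 0,
    weight_exponent: float = 1.0,
    labels: tuple[str, str] = ("disorder_a", "disorder_b"),
    mode: str = "cross",
) -> pd.DataFrame:
    """Differential GSEA over every pairwise combination of panel sets.

    mode='cross' (default): ordered distinct pairs, set_a scored on
    ranking a and set_b on ranking b — k(k-1) comparisons (56 for k=8).
    mode='within': unordered distinct pairs scored within each disorder's
    own ranking — 2*C(k,2) comparisons, the same count.

    The null permutes gene labels independently in both rankings (paired
    null NES draws per permutation index); p_diff is two-sided with the +1
    rule, corrected across comparisons by BH.
    """
    rng = np.random.default_rng(seed)
    sets = list(panel)

    def prepare(ranked):
        obs, nulls = {}, {}
        for s in sets:
            pos = ranked.positions_of(s.genes)
            if len(pos) == 0 or len(pos) >= len(ranked):
                obs[s.name] = None
                continue
            es, _, _ = enrichment_score(ranked, s.genes, weight_exponent)
            if len(pos) not in nulls:
                nulls[len(pos)] = _null_es(
                    ranked.scores, len(pos), n_perm, weight_exponent, rng
                )
            null = nulls[len(pos)]
            nes, _, _ = _normalize(es, null)
            pos_mean = np.mean(null[null >= 0]) if (null >= 0).any() else np.nan
            neg_mean = np.mean(np.abs(null[null < 0])) if (null < 0).any() else np.nan
            null_nes = np.where(null >= 0, null / pos_mean, null / neg_mean)
            obs[s.name] = (nes, null_nes)
        return obs

    obs_a = prepare(ranked_a)
    obs_b = prepare(ranked_b)

    if mode == "cross":
        combos = [
            (sa.name, labels[0], obs_a, sb.name, labels[1], obs_b)
            for sa in sets for sb in sets if sa.name != sb.name
        ]
    elif mode == "within":
        combos = []
        for lab, obs in ((labels[0], obs_a), (labels[1], obs_b)):
            for i, sa in enumerate(sets):
                for sb in sets[i + 1:]:
                    combos.append((sa.name, lab, obs, sb.name, lab, obs))
    else:
        raise ValueError("mode must be 'cross' or 'within'")

    rows = []
    for name_a, lab_a, oa, name_b, lab_b, ob in combos:
        ra, rb = oa[name_a], ob[name_b]
        if ra is None or rb is None:
            rows.append(
                {"set_a": name_a, "disorder_a": lab_a, "set_b": name_b,
                 "disorder_b": lab_b, "delta_nes": np.nan, "p_diff": np.nan,
                 "n_perm": n_perm, "seed": seed, "skipped": "missing_set"}
            )
            continue
        delta = ra[0] - rb[0]
        null_delta = ra[1] - rb[1]
        ok = np.isfinite(null_delta)
        b = int(np.sum(np.abs(null_delta[ok]) >= abs(delta)))
        p = (1 + b) / (1 + int(ok.sum()))
        rows.append(
            {"set_a": name_a, "disorder_a": lab_a, "set_b": name_b,
             "disorder_b": lab_b, "delta_nes": delta, "p_diff": p,
             "n_perm": n_perm, "seed": seed, "skipped": ""}
        )
    out = pd.DataFrame(rows)
    out["p_adj"] = bh_fdr(out["p_diff"].to_numpy())
    return out


def pivot_report(results_by_disorder: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Cross-disorder pivot: one row per set, NES/p columns per disorder."""
    if not results_by_disorder:
        raise ValueError("need at least one disorder's results")
    pieces = []
    for disorder, df in results_by_disorder.items():
        piece = df.set_index("set")[["nes", "p_perm", "fdr_q", "leading_edge"]]
        piece.columns = [f"{c}_{disorder}" for c in piece.columns]
        pieces.append(piece)
    out = pd.concat(pieces, axis=1, join="outer")
    out.index.name = "set"
    return out.reset_index()
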