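"""Enrichment statistics: weighted Kolmogorov-Smirnov gene-set enrichment
with a permutation-normalized enrichment score (NES), hypergeometric
over-representation, and regulon-based transcription-factor activity NES.

The GSEA running sum follows the classic weighted form: at each hit the sum
rises by |stat|^w normalized over hits, at each miss it falls by
1/(N - n_hits); the enrichment score is the signed extremum. NES uses
gene-set label permutations (random same-size sets), which stay well defined
at the small per-arm sample sizes where phenotype permutation degenerates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def rank_genes(gene_stats: dict[str, float] | pd.Series) -> pd.Series:
    """Descending ranking with deterministic tie-breaking by gene symbol."""
    s = pd.Series(gene_stats, dtype=float)
    if s.index.duplicated().any():
        raise ValueError("duplicate gene symbols in ranking")
    return s.sort_index().sort_values(ascending=False, kind="stable")


def _es_from_mask(weights: np.ndarray, in_set: np.ndarray) -> float:
    """Signed extremum of the weighted KS running sum for a hit mask."""
    n = len(weights)
    n_hits = int(in_set.sum())
    hit_w = np.where(in_set, weights, 0.0)
    total = hit_w.sum()
    if total == 0:  # all hit stats are exactly zero: uniform hit steps
        hit_steps = in_set / n_hits
    else:
        hit_steps = hit_w / total
    miss_steps = np.where(in_set, 0.0, 1.0 / (n - n_hits))
    running = np.cumsum(hit_steps - miss_steps)
    return float(running[np.argmax(np.abs(running))])


def gsea_es(
    ranked: pd.Series, geneset: set[str], weight_exponent: float = 1.0
) -> float:
    """Enrichment score of ``geneset`` on a descending ranked list."""
    genes = ranked.index.to_numpy()
    in_set = np.isin(genes, list(geneset))
    n_hits = int(in_set.sum())
    if n_hits == 0 or n_hits == len(genes):
        raise ValueError("gene set must intersect the ranking properly")
    weights = np.abs(ranked.to_numpy()) ** weight_exponent
    return _es_from_mask(weights, in_set)


@dataclass
class GSEAResult:
    set_name: str
    es: float
    nes: float
    p: float
    q: float
    direction: str  # up / down / ns


def gsea_nes(
    ranked: pd.Series,
    genesets: dict[str, set[str]],
    n_perm: int = 1000,
    seed: int = 0,
    weight_exponent: float = 1.0,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """GSEA over a collection of gene sets with permutation NES and BH q.

    For each set, ``n_perm`` random same-size gene sets are scored; the NES
    is es / mean(|es_perm| of the same sign) and the permutation p-value is
    (1 + #{same-sign |es_perm| >= |es|}) / (1 + n_same_sign). A set is
    classified up when NES > 0 and p < 0.05, down when NES < 0 and p < 0.05.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    genes = ranked.index.to_numpy()
    n = len(genes)
    weights = np.abs(ranked.to_numpy()) ** weight_exponent
    rows = []
    for name in sorted(genesets):
        members = set(genesets[name]) & set(genes)
        es = gsea_es(ranked, members, weight_exponent)
        size = len(members)
        perm_es = np.empty(n_perm)
        mask = np.zeros(n, dtype=bool)
        for i in range(n_perm):
            idx = rng.choice(n, size=size, replace=False)
            mask[:] = False
            mask[idx] = True
            perm_es[i] = _es_from_mask(weights, mask)
        same_sign = perm_es * np.sign(es) > 0
        n_same = int(same_sign.sum())
        if n_same == 0:
            import warnings

            warnings.warn(f"{name}: no same-sign permutations; p set to 1")
            nes, p = np.sign(es), 1.0
        else:
            nes = es / np.mean(np.abs(perm_es[same_sign]))
            p = (1 + int((np.abs(perm_es[same_sign]) >= abs(es)).sum())) / (
                1 + n_same
            )
        rows.append({"set_name": name, "es": es, "nes": nes, "p": p})
    out = pd.DataFrame(rows)
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    out["direction"] = np.where(
        (out["nes"] > 0) & (out["p"] < p_threshold),
        "up",
        np.where((out["nes"] < 0) & (out["p"] < p_threshold), "down", "ns"),
    )
    return out


def ora_hypergeometric(
    hit_list: set[str], geneset: set[str], universe: set[str]
) -> float:
    """Upper-tail hypergeometric P(X >= overlap) for over-representation."""
    if not hit_list <= universe:
        raise ValueError("hit genes outside the universe")
    geneset = geneset & universe
    overlap = len(hit_list & geneset)
    # P(X >= k) with M = |universe|, n = |geneset| successes, N = |hits| draws
    return float(
        stats.hypergeom.sf(overlap - 1, len(universe), len(geneset), len(hit_list))
    )


def ora_collection(
    hit_list: set[str], genesets: dict[str, set[str]], universe: set[str]
) -> pd.DataFrame:
    """Hypergeometric ORA across a collection with BH adjustment."""
    rows = [
        {
            "set_name": name,
            "overlap": len(hit_list & gs & universe),
            "set_size": len(gs & universe),
            "p": ora_hypergeometric(hit_list, gs, universe),
        }
        for name, gs in sorted(genesets.items())
    ]
    out = pd.DataFrame(rows)
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


def normal_scores(gene_stats: pd.Series) -> pd.Series:
    """Rank-based inverse-normal transform (van der Waerden scores)."""
    s = pd.Series(gene_stats, dtype=float).sort_index()
    ranks = stats.rankdata(s.to_numpy(), method="average")
    return pd.Series(
        stats.norm.ppf((ranks - 0.5) / len(s)), index=s.index
    )


def tf_nes(
    gene_stats: dict[str, float] | pd.Series,
    regulons: pd.DataFrame,
    min_targets: int = 5,
    p_adj_threshold: float = 0.05,
) -> pd.DataFrame:
    """Regulon NES per transcription factor.

    Gene statistics (by convention signed -log10(p) * sign(log2FC) from the
    bulk DEG stage) are converted to normal scores; each TF's NES is
    sum(mode * z_target) / sqrt(n_targets), a standard normal under the null
    of exchangeable targets. Two-sided p, BH across TFs; direction requires
    p_adj < 0.05. TFs with fewer than ``min_targets`` scored targets are
    reported as ns with reason ``too_few_targets``.
    """
    z = normal_scores(pd.Series(gene_stats, dtype=float))
    rows = []
    for tf, sub in regulons.groupby("tf"):
        present = sub[sub["target"].isin(z.index)]
        n = len(present)
        if n < min_targets:
            rows.append(
                {"tf": tf, "nes": np.nan, "p": np.nan, "n_targets": n,
                 "reason": "too_few_targets"}
            )
            continue
        nes = float(
            (present["mode"].to_numpy() * z[present["target"]].to_numpy()).sum()
            / np.sqrt(n)
        )
        rows.append(
            {"tf": tf, "nes": nes, "p": float(2 * stats.norm.sf(abs(nes))),
             "n_targets": n, "reason": ""}
        )
    out = pd.DataFrame(rows)
    tested = out["p"].notna()
    out["p_adj"] = np.nan
    if tested.any():
        out.loc[tested, "p_adj"] = multipletests(
            out.loc[tested, "p"], method="fdr_bh"
        )[1]
    out["direction"] = "ns"
    out.loc[(out["nes"] > 0) & (out["p_adj"] < p_adj_threshold), "direction"] = "up"
    out.loc[(out["nes"] < 0) & (out["p_adj"] < p_adj_threshold), "direction"] = "down"
    return out
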