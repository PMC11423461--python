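"""Bulk RNA stages: median-of-ratios normalization, carrier vs non-carrier
differential expression, and cytokine ligand-receptor (LR) annotation of the
DEG calls.

Differential expression is a Welch two-sample t-test on log2(normalized
count + 1), with Benjamini-Hochberg q-values. A gene is called "up" when
log2FC > 0.5 and p < 0.05, "down" when log2FC < -0.5 and p < 0.05
(thresholds configurable; the pseudo-bulk path reuses this machinery with
0.25). At the cohort sizes this pipeline targets (6-8 samples per arm) the
t-test is an auditable, adequate engine; a negative-binomial GLM can be
swapped in behind the same interface.
"""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from lysompn.io import LRDatabase

LOG2FC_THRESHOLD = 0.5
P_THRESHOLD = 0.05


def remove_zero_genes(counts: pd.DataFrame) -> pd.DataFrame:
    """Drop genes with zero total count across all samples."""
    return counts.loc[counts.sum(axis=1) > 0]


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (geometric-mean reference over genes
    positive in every sample). Falls back to library-size scaling, with a
    warning, when no gene is positive in all samples."""
    mat = counts.to_numpy(dtype=float)
    positive = (mat > 0).all(axis=1)
    if not positive.any():
        warnings.warn("no gene positive in all samples; using library-size scaling")
        libs = mat.sum(axis=0)
        sf = libs / np.exp(np.mean(np.log(libs)))
    else:
        logmat = np.log(mat[positive])
        ref = logmat.mean(axis=1, keepdims=True)  # log geometric mean per gene
        sf = np.exp(np.median(logmat - ref, axis=0))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def normalize_counts(counts: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Return (normalized matrix, size factors); normalized = count / sf."""
    if counts.shape[1] < 2:
        raise ValueError("need >= 2 samples to normalize")
    sf = size_factors(counts)
    return counts / sf, sf


def run_deg(
    counts: pd.DataFrame,
    metadata: pd.DataFrame,
    *,
    group_col: str = "ld_status",
    case: str = "carrier",
    control: str = "noncarrier",
    subset: str | None = None,
    subtype_col: str = "subtype",
    log2fc_threshold: float = LOG2FC_THRESHOLD,
    p_threshold: float = P_THRESHOLD,
) -> pd.DataFrame:
    """Per-gene differential expression, case minus control.

    ``metadata`` needs (sample_id, ld_status[, subtype]); ``subset``
    restricts to one subtype before testing. Returns a table with gene,
    log2fc, p, q (BH) and call in {up, down, ns}.
    """
    meta = metadata.set_index("sample_id")
    if subset is not None:
        meta = meta[meta[subtype_col] == subset]
    case_ids = meta.index[meta[group_col] == case]
    ctrl_ids = meta.index[meta[group_col] == control]
    for name, ids in (("case", case_ids), ("control", ctrl_ids)):
        if len(ids) < 2:
            raise ValueError(f"{name} arm has {len(ids)} samples; need >= 2")

    counts = remove_zero_genes(counts[list(case_ids) + list(ctrl_ids)])
    norm, _ = normalize_counts(counts)
    log = np.log2(norm + 1.0)
    x = log[case_ids].to_numpy()
    y = log[ctrl_ids].to_numpy()

    log2fc = x.mean(axis=1) - y.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.ttest_ind(x, y, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)  # zero-variance genes: no evidence
    q = multipletests(p, method="fdr_bh")[1]

    call = np.where(
        (log2fc > log2fc_threshold) & (p < p_threshold),
        "up",
        np.where((log2fc < -log2fc_threshold) & (p < p_threshold), "down", "ns"),
    )
    return pd.DataFrame(
        {"gene": counts.index, "log2fc": log2fc, "p": p, "q": q, "call": call}
    ).reset_index(drop=True)


def classify_lr_cytokine(degs: pd.DataFrame, db: LRDatabase) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flag DEGs that are LR genes, and cytokine-LR genes, per the database.

    Returns (annotated table, counts of up/down calls among LR and
    cytokine-LR genes)."""
    if db.pairs.empty:
        raise ValueError("empty ligand-receptor database")
    out = degs.copy()
    lr_genes = db.lr_genes
    out["is_lr"] = out["gene"].isin(lr_genes)
    out["is_cytokine_lr"] = out["is_lr"] & out["gene"].isin(db.cytokine_genes)
    rows = []
    for flag in ("is_lr", "is_cytokine_lr"):
        sub = out[out[flag]]
        rows.append(
            {
                "set": flag.removeprefix("is_"),
                "n_up": int((sub["call"] == "up").sum()),
                "n_down": int((sub["call"] == "down").sum()),
            }
        )
    return out, pd.DataFrame(rows)


def overlap_sets(genesets: dict[str, set[str]]) -> pd.DataFrame:
    """Venn partition of >= 2 named gene sets.

    One row per non-empty combination of groups: the genes belonging to
    exactly those groups. Region counts sum to the size of the union."""
    if len(genesets) < 2:
        raise ValueError("need >= 2 groups for an overlap table")
    names = list(genesets)
    rows = []
    for k in range(1, len(names) + 1):
        for combo in combinations(names, k):
            inside = set.intersection(*(genesets[n] for n in combo))
            outside = set.union(
                set(), *(genesets[n] for n in names if n not in combo)
            )
            region = inside - outside
            rows.append(
                {
                    "groups": "&".join(combo),
                    "n_groups": k,
                    "count": len(region),
                    "genes": ",".join(sorted(region)),
                }
            )
    return pd.DataFrame(rows)
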