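"""Single-cell analysis stages over an :class:`anndata.AnnData` of raw
counts (cells x genes) with obs columns ``sample_id``, ``group`` (carrier /
noncarrier / healthy) and, after typing, ``cell_type``.

Stages: QC filtering (UMI / detected-gene / mitochondrial thresholds plus an
optional PCA outlier screen), marker-based cell typing, cell-type proportion
permutation + bootstrap tests, per-cell-type Wilcoxon differential
expression, pseudo-bulk aggregation, ligand-receptor communication
probability, co-expression module scoring, and regulon (TF) activity.

Expression is log-normalized as log1p(count * 10,000 / cell total), the
de facto droplet-data convention; the scale is configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from statsmodels.stats.multitest import multipletests

from lysompn import bulkrna
from lysompn.io import LRDatabase

LOGNORM_SCALE = 1e4
LOG2FD_THRESHOLD = 0.3
SC_LOG2FC_THRESHOLD = 0.25
PSEUDOBULK_LOG2FC_THRESHOLD = 0.25
P_THRESHOLD = 0.05
DETECTION_FRACTION = 0.05
HILL_KH = 0.5


def _dense(x) -> np.ndarray:
    return np.asarray(x.todense()) if sp.issparse(x) else np.asarray(x)


def compute_qc(adata: ad.AnnData, mito_prefix: str = "MT-") -> ad.AnnData:
    """Annotate per-cell QC: n_umi, n_genes_detected, pct_mito."""
    x = sp.csr_matrix(adata.X)
    adata.obs["n_umi"] = np.asarray(x.sum(axis=1)).ravel()
    adata.obs["n_genes_detected"] = np.asarray((x > 0).sum(axis=1)).ravel()
    mito = adata.var_names.str.startswith(mito_prefix)
    mito_counts = (
        np.asarray(x[:, mito].sum(axis=1)).ravel() if mito.any() else 0.0
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(
            adata.obs["n_umi"] > 0, mito_counts / adata.obs["n_umi"], 0.0
        )
    adata.obs["pct_mito"] = pct
    return adata


def log_normalize(adata: ad.AnnData, scale: float = LOGNORM_SCALE) -> np.ndarray:
    """Dense log1p(count * scale / cell_total) matrix, cells x genes."""
    x = _dense(adata.X).astype(float)
    totals = x.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    return np.log1p(x * scale / totals)


def qc_filter(
    adata: ad.AnnData,
    min_umi: float = 0,
    max_umi: float = np.inf,
    min_genes: float = 0,
    max_pct_mito: float = 1.0,
    pca_outlier_z: float | None = None,
    mito_prefix: str = "MT-",
) -> tuple[ad.AnnData, pd.DataFrame]:
    """Remove cells failing any QC threshold; optionally remove PCA
    outliers (robust |z| > ``pca_outlier_z`` on either of the first two
    principal components of log-normalized data). Returns the filtered
    dataset and a per-cell removal report."""
    adata = compute_qc(adata.copy(), mito_prefix)
    obs = adata.obs
    reasons = pd.Series("", index=obs.index, dtype=object)
    reasons[obs["pct_mito"] > max_pct_mito] = "high_mito"
    reasons[obs["n_genes_detected"] < min_genes] = "low_genes"
    reasons[obs["n_umi"] > max_umi] = "high_umi"
    reasons[obs["n_umi"] < min_umi] = "low_umi"

    if pca_outlier_z is not None:
        keep_mask = (reasons == "").to_numpy()
        log = log_normalize(adata[keep_mask])
        centered = log - log.mean(axis=0)
        # top-2 PCs via thin SVD; robust z with the MAD scale
        u, s, _ = np.linalg.svd(centered, full_matrices=False)
        pcs = u[:, :2] * s[:2]
        med = np.median(pcs, axis=0)
        mad = np.median(np.abs(pcs - med), axis=0) * 1.4826
        mad[mad == 0] = 1.0
        z = np.abs(pcs - med) / mad
        outlier = (z > pca_outlier_z).any(axis=1)
        idx = np.flatnonzero(keep_mask)[outlier]
        reasons.iloc[idx] = "pca_outlier"

    report = pd.DataFrame({"cell_id": obs.index, "removed_reason": reasons.values})
    kept = adata[(reasons == "").to_numpy()].copy()
    if kept.n_obs == 0:
        raise ValueError("QC removed every cell")
    return kept, report


def _zscore_columns(mat: np.ndarray, cap: float | None = None) -> np.ndarray:
    mu = mat.mean(axis=0)
    sd = mat.std(axis=0)
    sd[sd == 0] = 1.0
    z = (mat - mu) / sd
    if cap is not None:
        z = np.clip(z, -cap, cap)
    return z


def assign_cell_types(
    adata: ad.AnnData, markers: dict[str, set[str] | list[str]]
) -> ad.AnnData:
    """Argmax marker scoring: per-cell score for each type is the mean
    z-scored log-normalized expression of that type's markers; exact ties
    (including all-zero cells) are left ``unassigned``."""
    if not markers:
        raise ValueError("empty marker map")
    z = _zscore_columns(log_normalize(adata))
    var_index = pd.Index(adata.var_names)
    scores = np.full((adata.n_obs, len(markers)), -np.inf)
    names = list(markers)
    for j, name in enumerate(names):
        present = var_index.get_indexer_for(
            [g for g in markers[name] if g in var_index]
        )
        if len(present) == 0:
            warnings.warn(f"no marker of type {name!r} present in the data")
            continue
        scores[:, j] = z[:, present].mean(axis=1)
    best = scores.argmax(axis=1)
    sorted_scores = np.sort(scores, axis=1)
    tied = sorted_scores[:, -1] - sorted_scores[:, -2] <= 1e-12
    assigned = np.array(names, dtype=object)[best]
    assigned[tied] = "unassigned"
    adata = adata.copy()
    adata.obs["cell_type"] = assigned
    return adata


def proportion_test(
    adata: ad.AnnData,
    group_a: str,
    group_b: str,
    n_perm: int = 1000,
    n_boot: int = 1000,
    seed: int = 0,
    *,
    group_col: str = "group",
    type_col: str = "cell_type",
    min_cells: int = 100,
    log2fd_threshold: float = LOG2FD_THRESHOLD,
    p_adj_threshold: float = P_THRESHOLD,
) -> pd.DataFrame:
    """Cell-type proportion comparison between two groups.

    log2FD = log2(prop_a / prop_b) with a +1 pseudo-count on cell counts.
    The two-sided permutation p-value refers to shuffling pooled group
    labels while preserving group sizes; per cell type the permuted count in
    group A then follows a hypergeometric law, which is sampled directly.
    Bootstrap 95% CIs resample cells within each group (multinomial over
    type counts). BH adjustment across cell types.
    """
    rng = np.random.default_rng(seed)
    obs = adata.obs
    in_a = (obs[group_col] == group_a).to_numpy()
    in_b = (obs[group_col] == group_b).to_numpy()
    n_a, n_b = int(in_a.sum()), int(in_b.sum())
    if n_a < min_cells or n_b < min_cells:
        raise ValueError(f"both groups need >= {min_cells} cells")

    types = sorted(set(obs.loc[in_a | in_b, type_col]))
    counts_a = obs.loc[in_a, type_col].value_counts()
    counts_b = obs.loc[in_b, type_col].value_counts()

    def _log2fd(ca, cb):
        return np.log2(((ca + 1) / n_a) / ((cb + 1) / n_b))

    rows = []
    boot_a = rng.multinomial(
        n_a, np.array([counts_a.get(t, 0) for t in types]) / n_a, size=n_boot
    )
    boot_b = rng.multinomial(
        n_b, np.array([counts_b.get(t, 0) for t in types]) / n_b, size=n_boot
    )
    for j, t in enumerate(types):
        ca, cb = int(counts_a.get(t, 0)), int(counts_b.get(t, 0))
        total = ca + cb
        if total == 0:
            continue
        observed = _log2fd(ca, cb)
        perm_a = rng.hypergeometric(total, n_a + n_b - total, n_a, size=n_perm)
        perm_stat = _log2fd(perm_a, total - perm_a)
        p = (1 + int((np.abs(perm_stat) >= abs(observed)).sum())) / (1 + n_perm)
        ci = np.percentile(_log2fd(boot_a[:, j], boot_b[:, j]), [2.5, 97.5])
        rows.append(
            {
                "cell_type": t,
                "n_a": ca,
                "n_b": cb,
                "prop_a": ca / n_a,
                "prop_b": cb / n_b,
                "log2fd": observed,
                "p_perm": p,
                "boot_ci_low": ci[0],
                "boot_ci_high": ci[1],
            }
        )
    out = pd.DataFrame(rows)
    out["p_adj"] = multipletests(out["p_perm"], method="fdr_bh")[1]
    out["call"] = np.where(
        (out["log2fd"] > log2fd_threshold) & (out["p_adj"] < p_adj_threshold),
        "up",
        np.where(
            (out["log2fd"] < -log2fd_threshold) & (out["p_adj"] < p_adj_threshold),
            "down",
            "ns",
        ),
    )
    return out


def sc_deg(
    adata: ad.AnnData,
    cell_type: str,
    group_a: str,
    group_b: str,
    *,
    group_col: str = "group",
    type_col: str = "cell_type",
    min_cells: int = 20,
    log2fc_threshold: float = SC_LOG2FC_THRESHOLD,
    p_threshold: float = P_THRESHOLD,
    scale: float = LOGNORM_SCALE,
) -> pd.DataFrame:
    """Wilcoxon rank-sum DEG within one cell type, group A vs group B.

    avg_log2fc is computed on the de-logged normalized scale with a small
    pseudo-count; calls use |avg_log2FC| > 0.25 and p < 0.05.
    """
    mask_type = (adata.obs[type_col] == cell_type).to_numpy()
    sub = adata[mask_type]
    a = (sub.obs[group_col] == group_a).to_numpy()
    b = (sub.obs[group_col] == group_b).to_numpy()
    if a.sum() < min_cells or b.sum() < min_cells:
        raise ValueError(
            f"{cell_type}: need >= {min_cells} cells per arm "
            f"(got {int(a.sum())} vs {int(b.sum())})"
        )
    log = log_normalize(sub, scale)
    xa, xb = log[a], log[b]
    eps = 1e-9 * scale
    mean_a = np.expm1(xa).mean(axis=0)
    mean_b = np.expm1(xb).mean(axis=0)
    avg_log2fc = np.log2((mean_a + eps) / (mean_b + eps))
    p = np.ones(adata.n_vars)
    varying = (xa.std(axis=0) > 0) | (xb.std(axis=0) > 0)
    if varying.any():
        res = stats.mannwhitneyu(
            xa[:, varying], xb[:, varying], axis=0, alternative="two-sided"
        )
        p[varying] = res.pvalue
    q = multipletests(p, method="fdr_bh")[1]
    call = np.where(
        (avg_log2fc > log2fc_threshold) & (p < p_threshold),
        "up",
        np.where((avg_log2fc < -log2fc_threshold) & (p < p_threshold), "down", "ns"),
    )
    return pd.DataFrame(
        {
            "gene": adata.var_names,
            "avg_log2fc": avg_log2fc,
            "p": p,
            "q": q,
            "call": call,
        }
    ).reset_index(drop=True)


def pseudobulk(
    adata: ad.AnnData,
    cell_type: str | None = None,
    *,
    sample_col: str = "sample_id",
    type_col: str = "cell_type",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sum raw counts per sample (optionally within one cell type).

    Returns (genes x samples counts, per-sample metadata with the sample's
    group label). Column sums equal the summed counts of contributing cells.
    """
    if cell_type is not None:
        adata = adata[(adata.obs[type_col] == cell_type).to_numpy()]
    x = sp.csr_matrix(adata.X)
    samples = adata.obs[sample_col].astype(str)
    cols, meta_rows = {}, []
    for s in sorted(samples.unique()):
        mask = (samples == s).to_numpy()
        cols[s] = np.asarray(x[mask].sum(axis=0)).ravel()
        groups = adata.obs.loc[mask, "group"].unique()
        meta_rows.append(
            {"sample_id": s, "ld_status": groups[0], "n_cells": int(mask.sum())}
        )
    counts = pd.DataFrame(cols, index=adata.var_names)
    return counts, pd.DataFrame(meta_rows)


def pseudobulk_deg(
    adata: ad.AnnData,
    cell_type: str,
    group_a: str,
    group_b: str,
    *,
    log2fc_threshold: float = PSEUDOBULK_LOG2FC_THRESHOLD,
    p_threshold: float = P_THRESHOLD,
) -> pd.DataFrame:
    """Pseudo-bulk DEG: per-sample aggregation followed by the bulk engine
    with the 0.25 / 0.05 thresholds."""
    counts, meta = pseudobulk(adata, cell_type)
    return bulkrna.run_deg(
        counts,
        meta,
        case=group_a,
        control=group_b,
        log2fc_threshold=log2fc_threshold,
        p_threshold=p_threshold,
    )


@dataclass
class InteractionResult:
    ligand: str
    receptor: str
    sender_type: str
    receiver_type: str
    group: str
    mean_l: float
    mean_r: float
    prob: float
    passed_detection: bool


def _trimean(values: np.ndarray) -> float:
    q1, q2, q3 = np.percentile(values, [25, 50, 75])
    return float((q1 + 2 * q2 + q3) / 4)


def interaction_probability(
    adata: ad.AnnData,
    db: LRDatabase,
    sender_type: str,
    receiver_type: str,
    group: str,
    *,
    kh: float = HILL_KH,
    detection_fraction: float = DETECTION_FRACTION,
    group_col: str = "group",
    type_col: str = "cell_type",
) -> pd.DataFrame:
    """Communication probability for every secreted-signaling LR pair from
    ``sender_type`` to ``receiver_type`` within one group.

    A pair is tested when the ligand is detected (count > 0) in at least 5%
    of sender cells and the receptor in at least 5% of receiver cells.
    mean_l / mean_r are Tukey trimeans of log-normalized expression and
    prob = mean_l*mean_r / (Kh + mean_l*mean_r), a saturating Hill form in
    [0, 1) strictly increasing in each mean.
    """
    obs = adata.obs
    in_group = (obs[group_col] == group).to_numpy()
    senders = in_group & (obs[type_col] == sender_type).to_numpy()
    receivers = in_group & (obs[type_col] == receiver_type).to_numpy()
    if senders.sum() == 0 or receivers.sum() == 0:
        raise ValueError("sender or receiver type absent in group")
    log = log_normalize(adata)
    raw = _dense(adata.X)
    var_index = pd.Index(adata.var_names)
    rows = []
    pairs = db.pairs[db.pairs["category"] == "secreted signaling"]
    for pair in pairs.itertuples(index=False):
        if pair.ligand not in var_index or pair.receptor not in var_index:
            continue
        li = var_index.get_loc(pair.ligand)
        ri = var_index.get_loc(pair.receptor)
        det_l = (raw[senders, li] > 0).mean()
        det_r = (raw[receivers, ri] > 0).mean()
        passed = det_l >= detection_fraction and det_r >= detection_fraction
        mean_l = _trimean(log[senders, li])
        mean_r = _trimean(log[receivers, ri])
        product = mean_l * mean_r
        rows.append(
            InteractionResult(
                ligand=pair.ligand,
                receptor=pair.receptor,
                sender_type=sender_type,
                receiver_type=receiver_type,
                group=group,
                mean_l=mean_l,
                mean_r=mean_r,
                prob=product / (kh + product),
                passed_detection=bool(passed),
            ).__dict__
        )
    out = pd.DataFrame(rows)
    return out[out["passed_detection"]].reset_index(drop=True)


def interaction_delta(
    adata: ad.AnnData,
    db: LRDatabase,
    sender_type: str,
    receiver_type: str,
    group_a: str,
    group_b: str,
    **kwargs,
) -> pd.DataFrame:
    """Per-pair communication probability difference, group A minus B.
    Pairs must pass detection in both groups."""
    pa = interaction_probability(adata, db, sender_type, receiver_type, group_a, **kwargs)
    pb = interaction_probability(adata, db, sender_type, receiver_type, group_b, **kwargs)
    merged = pa.merge(
        pb, on=["ligand", "receptor", "sender_type", "receiver_type"],
        suffixes=("_a", "_b"),
    )
    merged["delta"] = merged["prob_a"] - merged["prob_b"]
    return merged


def module_score_test(
    adata: ad.AnnData,
    modules: dict[int, list[str]],
    cell_type: str,
    group_a: str,
    group_b: str,
    *,
    group_col: str = "group",
    type_col: str = "cell_type",
    z_cap: float = 10.0,
    min_genes: int = 3,
    p_adj_threshold: float = P_THRESHOLD,
) -> pd.DataFrame:
    """Per-cell module scores (mean capped z of log-normalized expression
    over module genes, z-scored across the cell type's cells) compared
    between groups by Wilcoxon rank-sum, BH across modules."""
    mask = (adata.obs[type_col] == cell_type).to_numpy()
    sub = adata[mask]
    z = _zscore_columns(log_normalize(sub), cap=z_cap)
    var_index = pd.Index(sub.var_names)
    a = (sub.obs[group_col] == group_a).to_numpy()
    b = (sub.obs[group_col] == group_b).to_numpy()
    rows = []
    for mid, genes in modules.items():
        idx = var_index.get_indexer_for([g for g in genes if g in var_index])
        if len(idx) < min_genes:
            continue
        score = z[:, idx].mean(axis=1)
        sa, sb = score[a], score[b]
        if np.ptp(np.concatenate([sa, sb])) == 0:
            p = 1.0
        else:
            p = float(
                stats.mannwhitneyu(sa, sb, alternative="two-sided").pvalue
            )
        rows.append(
            {
                "module": mid,
                "n_genes": len(idx),
                "median_a": float(np.median(sa)),
                "median_b": float(np.median(sb)),
                "p": p,
            }
        )
    out = pd.DataFrame(rows)
    out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
    diff = out["median_a"] - out["median_b"]
    out["direction"] = np.where(
        out["p_adj"] >= p_adj_threshold, "ns", np.where(diff > 0, "up", "down")
    )
    return out


def grn_activity(
    adata: ad.AnnData,
    regulons: pd.DataFrame,
    cell_type: str,
    *,
    group_col: str = "group",
    type_col: str = "cell_type",
    min_targets: int = 5,
) -> pd.DataFrame:
    """Regulon (TF) activity per group within one cell type.

    Per-cell activity of a TF = mean over its targets of mode * z, with z
    the expression z-score across the cell type's cells; the group score is
    the mean over the group's cells and ranks are dense, descending, within
    each group (rank 1 = most active)."""
    mask = (adata.obs[type_col] == cell_type).to_numpy()
    sub = adata[mask]
    z = _zscore_columns(log_normalize(sub))
    var_index = pd.Index(sub.var_names)
    groups = sub.obs[group_col].astype(str)
    rows = []
    for tf, reg in regulons.groupby("tf"):
        present = reg[reg["target"].isin(var_index)]
        if len(present) < min_targets:
            continue
        idx = var_index.get_indexer_for(present["target"].tolist())
        per_cell = (z[:, idx] * present["mode"].to_numpy()).mean(axis=1)
        for g in sorted(groups.unique()):
            rows.append(
                {
                    "tf": tf,
                    "group": g,
                    "activity": float(per_cell[(groups == g).to_numpy()].mean()),
                    "n_targets": len(present),
                }
            )
    out = pd.DataFrame(rows, columns=["tf", "group", "activity", "n_targets"])
    out["rank"] = (
        out.groupby("group")["activity"].rank(ascending=False, method="dense")
        .astype(int)
        if len(out)
        else pd.Series(dtype=int)
    )
    return out
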