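"""Tiered classification of germline variants in a lysosomal-gene panel and
carrier calling.

A subject is a lysosomal-dysfunction (LD) carrier when they harbour at least
one qualifying rare variant in the panel. Qualifying variants must pass
coverage and population-frequency filters (depth of coverage > 10, alternate
reads > 5, gnomAD allele frequency <= 0.5% or unreported) and fall in one of
two tiers:

* Tier 1 — protein-truncating variants (stop gain, frameshift, canonical
  splice-site, start loss) and frameshift indels;
* Tier 2 — variants with a pathogenic/likely-pathogenic ClinVar record.

A variant may carry both tiers. Both vocabularies are overridable.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

DEFAULT_PTV_TERMS = frozenset(
    {
        "stop_gained",
        "frameshift_variant",
        "splice_acceptor_variant",
        "splice_donor_variant",
        "start_lost",
    }
)

DEFAULT_PATHOGENIC_TERMS = frozenset(
    {"Pathogenic", "Likely_pathogenic", "Pathogenic/Likely_pathogenic"}
)

KNOWN_CONSEQUENCES = DEFAULT_PTV_TERMS | {
    "missense_variant",
    "synonymous_variant",
    "inframe_insertion",
    "inframe_deletion",
    "intron_variant",
    "5_prime_UTR_variant",
    "3_prime_UTR_variant",
    "stop_lost",
    "splice_region_variant",
}

# coverage / frequency thresholds; all strict inequalities
MIN_DEPTH = 10          # depth of coverage must exceed this
MIN_ALT_READS = 5       # alternate-allele reads must exceed this
MAX_GNOMAD_AF = 0.005   # variants commoner than this are excluded


def filter_variants(
    variants: pd.DataFrame,
    panel: list[str] | set[str],
    *,
    min_depth: int = MIN_DEPTH,
    min_alt_reads: int = MIN_ALT_READS,
    max_af: float = MAX_GNOMAD_AF,
) -> pd.DataFrame:
    """Apply panel, coverage and population-frequency filters.

    Returns the input with an ``excluded_reason`` column: empty string for
    retained variants, otherwise one of ``off_panel``, ``low_depth``,
    ``low_alt``, ``common_af`` (first failing check, in that order).
    Missing gnomAD AF is treated as rare (the variant is retained): absence
    from gnomAD implies a frequency below the reporting threshold.
    """
    if not len(panel):
        raise ValueError("gene panel is empty")
    panel = set(panel)
    df = variants.copy()
    af = pd.to_numeric(df["gnomad_af"], errors="coerce")
    reason = np.full(len(df), "", dtype=object)
    reason[(af > max_af).to_numpy()] = "common_af"
    reason[(df["alt_reads"] <= min_alt_reads).to_numpy()] = "low_alt"
    reason[(df["depth"] <= min_depth).to_numpy()] = "low_depth"
    reason[~df["gene"].isin(panel).to_numpy()] = "off_panel"
    df["excluded_reason"] = reason
    return df


def assign_tiers(
    variants: pd.DataFrame,
    ptv_terms: frozenset[str] | set[str] = DEFAULT_PTV_TERMS,
    pathogenic_terms: frozenset[str] | set[str] = DEFAULT_PATHOGENIC_TERMS,
) -> pd.DataFrame:
    """Assign Tier-1/Tier-2 labels to filtered variants.

    Adds boolean ``tier1``/``tier2`` columns and updates ``excluded_reason``
    to ``non_qualifying`` for retained variants in neither tier. Unknown
    consequence terms raise a warning and are treated as non-qualifying.
    """
    df = variants.copy()
    if "excluded_reason" not in df.columns:
        df["excluded_reason"] = ""
    retained = (df["excluded_reason"] == "").to_numpy()

    unknown = ~df["consequence"].isin(KNOWN_CONSEQUENCES | set(ptv_terms))
    if (unknown & retained).any():
        terms = sorted(df.loc[unknown & retained, "consequence"].unique())
        warnings.warn(f"unknown consequence terms treated as non-qualifying: {terms}")

    is_ptv = df["consequence"].isin(ptv_terms)
    is_fs_indel = df["is_indel"].astype(bool) & (
        df["consequence"] == "frameshift_variant"
    )
    df["tier1"] = (is_ptv | is_fs_indel).to_numpy() & retained
    clinsig = df["clinvar_significance"].fillna("").astype(str)
    df["tier2"] = clinsig.isin(pathogenic_terms).to_numpy() & retained

    nonq = retained & ~df["tier1"].to_numpy() & ~df["tier2"].to_numpy()
    df.loc[nonq, "excluded_reason"] = "non_qualifying"
    return df


def call_carriers(tiered: pd.DataFrame, roster: pd.DataFrame) -> pd.DataFrame:
    """Classify every subject in the roster as LD carrier or non-carrier.

    ``roster`` needs columns (subject_id, group). A subject is a carrier iff
    they have >= 1 variant in Tier 1 or Tier 2; subjects absent from the
    variant table are non-carriers. Variants naming unknown subjects raise.
    """
    if roster["subject_id"].duplicated().any():
        dups = roster.loc[roster["subject_id"].duplicated(), "subject_id"]
        raise ValueError(f"duplicate subjects in roster: {sorted(set(dups))}")
    unknown = set(tiered["subject_id"]) - set(roster["subject_id"])
    if unknown:
        raise ValueError(f"variants for subjects not in roster: {sorted(unknown)}")

    qualifying = tiered[tiered["tier1"] | tiered["tier2"]]
    ids_by_subject = {
        subj: list(sub.index.astype(str))
        for subj, sub in qualifying.groupby("subject_id")
    }
    cohort = roster[["subject_id", "group"]].copy()
    cohort["is_carrier"] = cohort["subject_id"].isin(ids_by_subject).to_numpy()
    cohort["qualifying_variant_ids"] = [
        ",".join(ids_by_subject.get(s, [])) for s in cohort["subject_id"]
    ]
    return cohort.reset_index(drop=True)


def tier_summary(tiered: pd.DataFrame) -> dict[str, object]:
    """Counts of distinct qualifying variants by tier.

    Satisfies the inclusion-exclusion identity
    ``n_distinct = n_tier1 + n_tier2 - n_both``.
    """
    qualifying = tiered[tiered["tier1"] | tiered["tier2"]]
    n_tier1 = int(qualifying["tier1"].sum())
    n_tier2 = int(qualifying["tier2"].sum())
    n_both = int((qualifying["tier1"] & qualifying["tier2"]).sum())
    return {
        "n_distinct": len(qualifying),
        "n_tier1": n_tier1,
        "n_tier2": n_tier2,
        "n_both": n_both,
        "genes_hit": sorted(qualifying["gene"].unique()),
    }
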