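"""Shared readers and writers for every external file format the pipeline
touches: flat TSV tables (with provenance comment headers), gene-list and
GMT gene-set files, ligand-receptor and regulon tables, STRING-format
template edge lists, and 10x-style MTX trios."""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

COMMENT_CHAR = "#"


def write_tsv(df: pd.DataFrame, path: str, provenance: dict | None = None) -> None:
    """Write a TSV with optional ``# key=value`` provenance header lines."""
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    with open(path, "w") as fh:
        for key, value in (provenance or {}).items():
            fh.write(f"{COMMENT_CHAR} {key}={value}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path: str, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment=COMMENT_CHAR, **kwargs)


def read_gene_list(path: str) -> list[str]:
    """One symbol per line; blank lines and ``#`` comments ignored."""
    genes: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith(COMMENT_CHAR):
                genes.append(line)
    return genes


def write_gene_list(genes, path: str) -> None:
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")


def read_gmt(path: str) -> dict[str, set[str]]:
    """MSigDB GMT: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def write_gmt(gene_sets: dict[str, set[str]], path: str) -> None:
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    with open(path, "w") as fh:
        for name, genes in gene_sets.items():
            fh.write("\t".join([name, "na", *sorted(genes)]) + "\n")


@dataclass
class LRDatabase:
    """Curated ligand-receptor interactions plus a cytokine gene flag set.

    ``pairs`` columns: ligand, receptor, category (e.g. "secreted signaling").
    """

    pairs: pd.DataFrame
    cytokine_genes: set[str] = field(default_factory=set)

    def __post_init__(self):
        if self.pairs.duplicated(["ligand", "receptor"]).any():
            raise ValueError("duplicate (ligand, receptor) rows in LR database")

    @property
    def lr_genes(self) -> set[str]:
        return set(self.pairs["ligand"]) | set(self.pairs["receptor"])


def read_lr_database(pairs_path: str, cytokine_path: str | None = None) -> LRDatabase:
    pairs = read_tsv(pairs_path)
    required = {"ligand", "receptor", "category"}
    missing = required - set(pairs.columns)
    if missing:
        raise ValueError(f"LR database missing columns: {sorted(missing)}")
    cytokines = set(read_gene_list(cytokine_path)) if cytokine_path else set()
    return LRDatabase(pairs=pairs, cytokine_genes=cytokines)


def read_regulons(path: str, min_targets: int = 5) -> pd.DataFrame:
    """Regulon TSV with columns (tf, target, mode); mode in {+1, -1}."""
    df = read_tsv(path)
    missing = {"tf", "target", "mode"} - set(df.columns)
    if missing:
        raise ValueError(f"regulon table missing columns: {sorted(missing)}")
    bad = ~df["mode"].isin([1, -1])
    if bad.any():
        raise ValueError("regulon mode must be +1 or -1")
    sizes = df.groupby("tf")["target"].size()
    keep = sizes[sizes >= min_targets].index
    return df[df["tf"].isin(keep)].reset_index(drop=True)


def read_string_template(path: str) -> pd.DataFrame:
    """STRING-format TSV: protein1, protein2, combined_score (0-1000),
    returned deduplicated with endpoints in canonical (sorted) order."""
    df = read_tsv(path)
    missing = {"protein1", "protein2", "combined_score"} - set(df.columns)
    if missing:
        raise ValueError(f"template missing columns: {sorted(missing)}")
    a = df[["protein1", "protein2"]].min(axis=1)
    b = df[["protein1", "protein2"]].max(axis=1)
    out = pd.DataFrame(
        {"gene_a": a, "gene_b": b, "score": df["combined_score"].astype(int)}
    )
    out = out.sort_values("score", ascending=False)
    out = out.drop_duplicates(["gene_a", "gene_b"], keep="first")
    return out.reset_index(drop=True)


def write_mtx_dir(adata: ad.AnnData, out_dir: str) -> None:
    """Write a 10x-style trio: matrix.mtx (genes x cells), features.tsv,
    barcodes.tsv, plus cell_metadata.tsv with the obs table."""
    os.makedirs(out_dir, exist_ok=True)
    mat = sp.csr_matrix(adata.X)
    scipy.io.mmwrite(os.path.join(out_dir, "matrix.mtx"), mat.T.astype(int))
    pd.Series(adata.var_names).to_csv(
        os.path.join(out_dir, "features.tsv"), sep="\t", index=False, header=False
    )
    pd.Series(adata.obs_names).to_csv(
        os.path.join(out_dir, "barcodes.tsv"), sep="\t", index=False, header=False
    )
    adata.obs.reset_index(names="cell_id").to_csv(
        os.path.join(out_dir, "cell_metadata.tsv"), sep="\t", index=False
    )


def read_mtx_dir(in_dir: str) -> ad.AnnData:
    """Read the trio written by :func:`write_mtx_dir` into cells x genes."""
    mat = sp.csr_matrix(scipy.io.mmread(os.path.join(in_dir, "matrix.mtx"))).T
    features = pd.read_csv(
        os.path.join(in_dir, "features.tsv"), sep="\t", header=None
    )[0].astype(str)
    barcodes = pd.read_csv(
        os.path.join(in_dir, "barcodes.tsv"), sep="\t", header=None
    )[0].astype(str)
    adata = ad.AnnData(
        X=mat.tocsr(),
        obs=pd.DataFrame(index=barcodes.values),
        var=pd.DataFrame(index=features.values),
    )
    meta_path = os.path.join(in_dir, "cell_metadata.tsv")
    if os.path.exists(meta_path):
        meta = pd.read_csv(meta_path, sep="\t").set_index("cell_id")
        adata.obs = meta.loc[adata.obs_names]
    return adata


def read_counts_tsv(path: str) -> pd.DataFrame:
    """Genes x samples raw count matrix; first column = gene symbols."""
    df = pd.read_csv(path, sep="\t", comment=COMMENT_CHAR, index_col=0)
    if (df.values < 0).any():
        raise ValueError("negative values in count matrix")
    return df


def write_counts_tsv(counts: pd.DataFrame, path: str) -> None:
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    counts.to_csv(path, sep="\t", index_label="gene")


VARIANT_COLUMNS = [
    "subject_id",
    "gene",
    "chrom",
    "pos",
    "ref",
    "alt",
    "consequence",
    "is_indel",
    "clinvar_significance",
    "gnomad_af",
    "depth",
    "alt_reads",
]


def read_variant_table(path: str) -> pd.DataFrame:
    """Annotated variant TSV with the columns in :data:`VARIANT_COLUMNS`.

    ``gnomad_af`` and ``clinvar_significance`` may be empty (absent
    annotation). Malformed rows raise with the offending line number.
    """
    df = read_tsv(path, dtype={"chrom": str})
    missing = set(VARIANT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"variant table missing columns: {sorted(missing)}")
    for i, row in enumerate(df.itertuples(index=False), start=2):
        if row.alt_reads > row.depth:
            raise ValueError(f"line {i}: alt_reads > depth")
        if row.pos < 1:
            raise ValueError(f"line {i}: pos < 1")
    return df


def read_variant_vcf(path: str, info_keys: dict[str, str] | None = None) -> pd.DataFrame:
    """Read annotated variants from a VCF, one row per sample carrying a
    non-reference genotype.

    ``info_keys`` maps logical names (gene, consequence, clinvar, gnomad_af)
    to INFO field names; defaults: GENE, CSQ, CLNSIG, AF_gnomad. Depth and
    alt reads come from FORMAT DP/AD.
    """
    import pysam  # optional dependency, imported lazily

    keys = {"gene": "GENE", "consequence": "CSQ", "clinvar": "CLNSIG",
            "gnomad_af": "AF_gnomad"}
    keys.update(info_keys or {})
    rows = []
    with pysam.VariantFile(path) as vcf:
        for rec in vcf:
            info = rec.info
            for sample, call in rec.samples.items():
                gt = call.get("GT")
                if gt is None or not any(a and a > 0 for a in gt if a is not None):
                    continue
                depth = call.get("DP") or 0
                adv = call.get("AD")
                alt_reads = adv[1] if adv is not None and len(adv) > 1 else 0
                def _scalar(v):
                    return v[0] if isinstance(v, tuple) else v
                rows.append({
                    "subject_id": sample,
                    "gene": _scalar(info.get(keys["gene"], "")),
                    "chrom": rec.chrom,
                    "pos": rec.pos,
                    "ref": rec.ref,
                    "alt": rec.alts[0] if rec.alts else "",
                    "consequence": _scalar(info.get(keys["consequence"], "")),
                    "is_indel": len(rec.ref) != len(rec.alts[0]) if rec.alts else False,
                    "clinvar_significance": _scalar(info.get(keys["clinvar"], "")) or np.nan,
                    "gnomad_af": _scalar(info.get(keys["gnomad_af"], np.nan)),
                    "depth": depth,
                    "alt_reads": alt_reads,
                })
    return pd.DataFrame(rows, columns=VARIANT_COLUMNS)
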