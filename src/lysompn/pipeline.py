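"""End-to-end orchestration over the synthetic flow.

Stages run in dependency order (simulate -> tier -> assoc -> bulk ->
diffnet -> sc); a provenance manifest records parameter values, the seed and
the SHA-256 of every input and output, and a stage whose recorded input
hashes and parameters are unchanged is skipped on rerun.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os

import pandas as pd

from lysompn import assoc, bulkrna, diffnet, sccore, synthio, variants
from lysompn.config import PipelineConfig
from lysompn import io as lio

log = logging.getLogger("lysompn")

STAGE_ORDER = ["simulate", "tier", "assoc", "bulk", "diffnet", "sc"]


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _hash_map(paths: list[str]) -> dict[str, str]:
    return {p: _sha256(p) for p in sorted(paths) if os.path.exists(p)}


class PipelineRunner:
    def __init__(self, config: PipelineConfig):
        self.config = config
        self.out = config.paths.out_dir
        os.makedirs(self.out, exist_ok=True)
        self.manifest_path = os.path.join(self.out, "manifest.json")
        self.manifest = {}
        if os.path.exists(self.manifest_path):
            with open(self.manifest_path) as fh:
                self.manifest = json.load(fh)

    # stage inputs/outputs by file name under out_dir
    def _p(self, name: str) -> str:
        return os.path.join(self.out, name)

    def _stage_record(self, name, inputs, outputs):
        return {
            "inputs": _hash_map(inputs),
            "outputs": _hash_map(outputs),
            "params": self.config.params.__dict__,
            "seed": self.config.seed,
        }

    def _cached(self, name, inputs, outputs) -> bool:
        rec = self.manifest.get(name)
        if rec is None:
            return False
        fresh = self._stage_record(name, inputs, outputs)
        return (
            rec.get("inputs") == fresh["inputs"]
            and rec.get("params") == fresh["params"]
            and rec.get("seed") == fresh["seed"]
            and all(os.path.exists(p) for p in outputs)
        )

    def run(self, stages: list[str] | None = None) -> dict:
        stages = stages or STAGE_ORDER
        unknown = set(stages) - set(STAGE_ORDER)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        for stage in STAGE_ORDER:
            if stage in stages:
                getattr(self, f"stage_{stage}")()
        with open(self.manifest_path, "w") as fh:
            json.dump(self.manifest, fh, indent=1, sort_keys=True)
        return self.manifest

    def _finish(self, name, inputs, outputs):
        self.manifest[name] = self._stage_record(name, inputs, outputs)
        log.info("stage %s done (%d outputs)", name, len(outputs))

    # ------------------------------------------------------------------
    def stage_simulate(self):
        outputs = [
            self._p("cohort.tsv"),
            self._p("ground_truth_cohort.json"),
            self._p("variants.tsv"),
            self._p("panel.txt"),
            self._p("bulk_counts.tsv"),
            self._p("bulk_metadata.tsv"),
            self._p("ground_truth_bulk.json"),
            self._p("template.tsv"),
            os.path.join(self._p("sc"), "matrix.mtx"),
        ]
        if self._cached("simulate", [], outputs):
            log.info("stage simulate cached; skipping")
            return
        sim = synthio.SimConfig(seed=self.config.seed)
        cohort, truth_c = synthio.simulate_cohort(sim)
        synthio.write_cohort(cohort, truth_c, self.out)
        lio.write_gene_list(synthio.LD_PANEL, self._p("panel.txt"))
        table = synthio.simulate_variant_table(cohort, synthio.LD_PANEL, sim)
        lio.write_tsv(table, self._p("variants.tsv"))
        counts, meta, truth_b = synthio.simulate_bulk_counts(sim)
        synthio.write_bulk(counts, meta, truth_b, self.out)
        synthio.write_template(synthio.make_template(truth_b, sim), self._p("template.tsv"))
        adata, truth_s = synthio.simulate_sc_dataset(sim)
        synthio.write_sc(adata, truth_s, self._p("sc"))
        self._finish("simulate", [], outputs)

    def stage_tier(self):
        inputs = [self._p("variants.tsv"), self._p("panel.txt"), self._p("cohort.tsv")]
        outputs = [self._p("tiered.tsv"), self._p("carriers.tsv")]
        if self._cached("tier", inputs, outputs):
            log.info("stage tier cached; skipping")
            return
        p = self.config.params
        table = lio.read_variant_table(self._p("variants.tsv"))
        panel = lio.read_gene_list(self._p("panel.txt"))
        filtered = variants.filter_variants(
            table, panel, min_depth=p.min_depth,
            min_alt_reads=p.min_alt_reads, max_af=p.gnomad_af_max,
        )
        tiered = variants.assign_tiers(filtered)
        roster = lio.read_tsv(self._p("cohort.tsv"))
        carriers = variants.call_carriers(tiered, roster)
        lio.write_tsv(tiered, self._p("tiered.tsv"))
        lio.write_tsv(carriers, self._p("carriers.tsv"))
        self._finish("tier", inputs, outputs)

    def stage_assoc(self):
        inputs = [self._p("carriers.tsv")]
        outputs = [self._p("association.tsv")]
        if self._cached("assoc", inputs, outputs):
            log.info("stage assoc cached; skipping")
            return
        carriers = lio.read_tsv(self._p("carriers.tsv"))
        result = assoc.associate_groups(carriers, control_label="CONTROL")
        lio.write_tsv(result, self._p("association.tsv"))
        self._finish("assoc", inputs, outputs)

    def stage_bulk(self):
        inputs = [self._p("bulk_counts.tsv"), self._p("bulk_metadata.tsv")]
        outputs = [self._p("bulk_deg.tsv"), self._p("bulk_lr_counts.tsv")]
        if self._cached("bulk", inputs, outputs):
            log.info("stage bulk cached; skipping")
            return
        p = self.config.params
        counts = lio.read_counts_tsv(self._p("bulk_counts.tsv"))
        meta = lio.read_tsv(self._p("bulk_metadata.tsv"))
        degs = bulkrna.run_deg(
            counts, meta, log2fc_threshold=p.bulk_log2fc, p_threshold=p.p_threshold
        )
        db = self._lr_database()
        annotated, lr_counts = bulkrna.classify_lr_cytokine(degs, db)
        lio.write_tsv(annotated, self._p("bulk_deg.tsv"))
        lio.write_tsv(lr_counts, self._p("bulk_lr_counts.tsv"))
        self._finish("bulk", inputs, outputs)

    def _lr_database(self):
        paths = self.config.paths
        if paths.lr_pairs:
            return lio.read_lr_database(paths.lr_pairs, paths.cytokines)
        return synthio.make_lr_database()

    def stage_diffnet(self):
        inputs = [
            self._p("bulk_counts.tsv"),
            self._p("bulk_metadata.tsv"),
            self._p("template.tsv"),
        ]
        outputs = [self._p("diffnet_edges.tsv"), self._p("diffnet_modules.tsv")]
        if self._cached("diffnet", inputs, outputs):
            log.info("stage diffnet cached; skipping")
            return
        p = self.config.params
        counts = lio.read_counts_tsv(self._p("bulk_counts.tsv"))
        meta = lio.read_tsv(self._p("bulk_metadata.tsv")).set_index("sample_id")
        norm, _ = bulkrna.normalize_counts(bulkrna.remove_zero_genes(counts))
        import numpy as np

        logc = np.log2(norm + 1)
        carrier_ids = meta.index[meta["ld_status"] == "carrier"]
        noncarrier_ids = meta.index[meta["ld_status"] == "noncarrier"]
        net_c = diffnet.correlation_network(
            logc[list(carrier_ids)], p.r_threshold, group="carrier"
        )
        net_n = diffnet.correlation_network(
            logc[list(noncarrier_ids)], p.r_threshold, group="noncarrier"
        )
        template = lio.read_string_template(self._p("template.tsv"))
        dn = diffnet.differential_edges(net_c, net_n, template, p.template_min_score)
        lio.write_tsv(dn.edges, self._p("diffnet_edges.tsv"))
        modules = diffnet.detect_modules(dn) if dn.n_edges else {}
        rows = [
            {"module": mid, "gene": g, "rank": r}
            for mid, genes in modules.items()
            for g, r in zip(
                diffnet.rank_hubs(genes, dn)["gene"],
                diffnet.rank_hubs(genes, dn)["rank"],
            )
        ]
        lio.write_tsv(pd.DataFrame(rows, columns=["module", "gene", "rank"]),
                      self._p("diffnet_modules.tsv"))
        self._finish("diffnet", inputs, outputs)

    def stage_sc(self):
        inputs = [os.path.join(self._p("sc"), "matrix.mtx")]
        outputs = [
            self._p("sc_proportions.tsv"),
            self._p("sc_deg_monocyte.tsv"),
            self._p("sc_interactions.tsv"),
            self._p("sc_grn.tsv"),
        ]
        if self._cached("sc", inputs, outputs):
            log.info("stage sc cached; skipping")
            return
        p = self.config.params
        adata = lio.read_mtx_dir(self._p("sc"))
        sim = synthio.SimConfig(seed=self.config.seed)
        props = sccore.proportion_test(
            adata, "carrier", "noncarrier",
            n_perm=p.n_perm, n_boot=p.n_boot, seed=self.config.seed,
            log2fd_threshold=p.log2fd_threshold, p_adj_threshold=p.p_adj_threshold,
        )
        lio.write_tsv(props, self._p("sc_proportions.tsv"))
        degs = sccore.sc_deg(
            adata, sim.sc.sender_type, "carrier", "noncarrier",
            log2fc_threshold=p.sc_log2fc, p_threshold=p.p_threshold,
        )
        lio.write_tsv(degs, self._p("sc_deg_monocyte.tsv"))
        delta = sccore.interaction_delta(
            adata, self._lr_database(), sim.sc.sender_type, sim.sc.receiver_type,
            "carrier", "noncarrier",
            kh=p.hill_kh, detection_fraction=p.detection_fraction,
        )
        lio.write_tsv(delta, self._p("sc_interactions.tsv"))
        grn = sccore.grn_activity(
            adata, synthio.make_regulons(sim), sim.sc.sender_type,
            min_targets=p.min_regulon_targets,
        )
        lio.write_tsv(grn, self._p("sc_grn.tsv"))
        self._finish("sc", inputs, outputs)


def run_pipeline(config: PipelineConfig, stages: list[str] | None = None) -> dict:
    logging.basicConfig(level=config.log_level)
    return PipelineRunner(config).run(stages)
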