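"""End-to-end orchestration over synthetic or user-provided inputs.

Each stage writes TSV/JSON artifacts into ``<outdir>-<confighash>``; every
file carries a provenance header (package version, seed, config hash) so
that a rerun with the same configuration is byte-identical for the
deterministic stages.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .trees import paramecium_species_tree

logger = logging.getLogger(__name__)


class MissingArtifactError(RuntimeError):
    def __init__(self, stage: str, artifact: str):
        super().__init__(
            f"stage '{stage}' requires missing artifact '{artifact}' — "
            f"enable the upstream stage or provide the file")


def _provenance(config: PipelineConfig) -> str:
    return (f"# iesevo {__version__} seed={config.seed} "
            f"config={config.config_hash()}\n")


def _write_tsv(path: Path, frame: pd.DataFrame, config: PipelineConfig):
    with open(path, "w") as fh:
        fh.write(_provenance(config))
        frame.to_csv(fh, sep="\t", index=False)


def run(config: PipelineConfig) -> Path:
    """Run enabled stages in dependency order; returns the artifact dir."""
    outdir = Path(f"{config.outdir}-{config.config_hash()}")
    outdir.mkdir(parents=True, exist_ok=True)
    species_tree = paramecium_species_tree()
    t0 = time.time()
    state: dict = {}

    if config.stages.simulate:
        from .simulate import (GenomeConfig, build_genome_pair,
                               simulate_gene_families, simulate_ies_history,
                               simulate_reads)
        fams = simulate_gene_families(species_tree, config.n_families,
                                      config.dup_rate,
                                      config.gene_loss_rate,
                                      seed=config.seed,
                                      with_sequences=False)
        histories = []
        for i, fam in enumerate(fams):
            m, h = simulate_ies_history(
                fam.tree, config.gain_rate_per_kb, config.loss_rate_per_ies,
                config.alignment_kb, seed=config.seed * 100_000 + i,
                root_density_per_kb=config.root_density_per_kb,
                species_tree=species_tree)
            histories.append((fam, m, h))
        state["histories"] = histories
        gpair = build_genome_pair(
            GenomeConfig(scaffold_length=config.genome_scaffold_length,
                         ies_per_kb=config.genome_ies_per_kb),
            seed=config.seed + 7)
        state["genome"] = gpair
        reads, irs_truth = simulate_reads(
            gpair, config.read_depth, 0.0, config.mac_contamination,
            config.read_length, seed=config.seed + 11)
        state["reads"], state["irs_truth"] = reads, irs_truth
        _write_tsv(outdir / "irs_truth.tsv", irs_truth, config)
        logger.info("simulate: %d families, %d IESs, %d reads (%.1fs)",
                    len(fams), len(gpair.catalog), len(reads),
                    time.time() - t0)

    if config.stages.ksize:
        from .kmer import (correct_for_mac_contamination, count_kmers,
                           estimate_genome_size, estimate_mac_fraction)
        if "reads" not in state:
            raise MissingArtifactError("ksize", "reads")
        hist = count_kmers(state["reads"], k=config.thresholds.kmer_k)
        est = estimate_genome_size(hist)
        irs = state["irs_truth"]["irs"].dropna().to_numpy()
        result = {"depth": est.depth, "raw_size_bp": est.raw_size_bp,
                  "error_cutoff": est.error_cutoff}
        if config.mac_contamination > 0 and irs.size >= 100:
            frac = estimate_mac_fraction(irs)
            corr = correct_for_mac_contamination(hist, frac)
            result.update({"mac_fraction": frac,
                           "corrected_size_bp": corr.corrected_size_bp,
                           "irs_mean": float(np.mean(irs))})
        with open(outdir / "genome_size.json", "w") as fh:
            json.dump({"provenance": _provenance(config).strip("# \n"),
                       **result}, fh, indent=2)

    if config.stages.catalog:
        from .catalog import (assign_compartment, call_weak, catalog_to_frame,
                              classify_length, detect_floating)
        if "genome" not in state:
            raise MissingArtifactError("catalog", "genome pair")
        gpair = state["genome"]
        irs_map = dict(zip(state["irs_truth"].ies_id,
                           state["irs_truth"].irs)) \
            if "irs_truth" in state else {}
        for rec in gpair.catalog:
            rec.compartment = assign_compartment(rec, gpair.annotation)
            rec.irs = irs_map.get(rec.id)
            rec.weak = call_weak(rec.irs) if rec.irs is not None else None
            mic_pos = gpair.mic_positions[rec.id]
            rec.floating_offsets = detect_floating(
                gpair.mic[rec.scaffold], rec, mic_pos,
                window=config.thresholds.floating_window)
        frame = catalog_to_frame(gpair.catalog)
        frame["length_class"] = [classify_length(r.length)[1]
                                 for r in gpair.catalog]
        _write_tsv(outdir / "ies_catalog.tsv", frame, config)
        state["catalog_frame"] = frame

    if config.stages.infer or config.stages.rates:
        from .gainloss import mcmc_sample
        from .rates import FamilyData, branch_rate_table
        if "histories" not in state:
            raise MissingArtifactError("infer", "simulated histories")
        fam_data = []
        for i, (fam, matrix, _) in enumerate(state["histories"]):
            if matrix.n_loci == 0:
                continue
            res = mcmc_sample(matrix.as_tip_states(), fam.tree,
                              n_iter=config.mcmc.n_iter,
                              tuning_iter=config.mcmc.tuning_iter,
                              tuning_interval=config.mcmc.tuning_interval,
                              seed=config.seed * 1_000 + i,
                              thin=config.mcmc.thin,
                              burnin_frac=config.mcmc.burnin_frac,
                              root_prior=config.mcmc.root_prior)
            if res.posteriors is None:
                continue
            fam_data.append(FamilyData(fam.tree, res.posteriors,
                                       config.alignment_kb, matrix.n_loci))
        table = branch_rate_table(fam_data, species_tree)
        _write_tsv(outdir / "branch_rates.tsv", table.rows, config)
        state["branch_rates"] = table

    if config.stages.mobile:
        from .mobile import all_vs_all, boundary_rule
        if "genome" not in state:
            raise MissingArtifactError("mobile", "genome pair")
        seqs = {r.id: r.excised_sequence for r in state["genome"].catalog}
        hits = all_vs_all(seqs,
                          max_evalue=config.thresholds.allvsall_evalue,
                          seed=config.seed + 13)
        rows = [{**h.__dict__,
                 "boundary_pass": boundary_rule(
                     h, len(seqs[h.query]), len(seqs[h.subject]),
                     config.thresholds.boundary_margin_nt)}
                for h in hits]
        _write_tsv(outdir / "ies_similarity_hits.tsv",
                   pd.DataFrame(rows), config)

    if config.stages.report and "catalog_frame" in state:
        from .report import proportions_report
        frame = state["catalog_frame"].copy()
        frame["weak"] = frame["weak"].astype("boolean")
        rep = proportions_report(frame.dropna(subset=["weak"]),
                                 "compartment", "weak") \
            if frame["weak"].notna().any() else None
        if rep is not None:
            _write_tsv(outdir / "weak_by_compartment.tsv",
                       rep["table"].reset_index(), config)
    logger.info("pipeline done in %.1fs -> %s", time.time() - t0, outdir)
    return outdir
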