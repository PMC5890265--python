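"""End-to-end pipeline: simulate -> call -> analyze; annotate -> cluster ->
dollo -> kaks. Produces stage outputs plus a machine-readable summary."""

from __future__ import annotations

import json
import logging
import os

import numpy as np

from . import calling, experiments, methylome, simulate
from .config import RunConfig, report_skeleton, write_config

log = logging.getLogger(__name__)


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, float) and np.isnan(x):
        return None
    if isinstance(x, dict):
        return {str(k): _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    return x


def run_pipeline(config: RunConfig) -> dict:
    """Run the requested stages in dependency order and write the report.

    Stage outputs land under ``config.outdir``; the summary collects the
    global context levels, the DMR counts, per-family O/E medians with the
    depletion rank-sum p, subfamily counts, Dollo gain/loss totals and the
    Ka/Ks calibration. Identical seeds give identical summaries.
    """
    logging.basicConfig(level=config.log_level)
    os.makedirs(config.outdir, exist_ok=True)
    write_config(config, os.path.join(config.outdir, "effective_config.yaml"))
    report = report_skeleton(config)
    res = report["results"]
    seed = config.seed

    sim_params = config.effective("simulate")
    sim_cfg = experiments.demo_config(seed, **sim_params)

    if "call" in config.stages or "analyze" in config.stages:
        meth = experiments.run_methylome_experiment(sim_cfg,
                                                    workdir=config.outdir)
        sim = meth["sim"]
        simulate.write_fasta(sim.genome,
                             os.path.join(config.outdir, "genome.fa"))
        simulate.write_gff3(sim.features,
                            os.path.join(config.outdir, "features.gff3"))
        simulate.write_bed(sim.features,
                           os.path.join(config.outdir, "features.bed"))
        simulate.write_expression_tsv(
            sim.features, os.path.join(config.outdir, "expression.tsv"))
        simulate.write_truth_tsv(
            meth["truth"], os.path.join(config.outdir, "truth_methylome.tsv"))
        calling.write_methylome(
            meth["table"], os.path.join(config.outdir, "methylome.tsv"))
        meth["te_profile"].to_frame().to_csv(
            os.path.join(config.outdir, "te_metaprofile.tsv"), sep="\t",
            index=False)
        meth["te_enrichment"].to_csv(
            os.path.join(config.outdir, "te_3prime_enrichment.tsv"), sep="\t",
            index=False)
        res["global_levels"] = {k: _jsonable(v)
                                for k, v in meth["global_levels"].items()}
        res["non_conversion"] = _jsonable(meth["nonconversion"])
        res["cg_site_zero_fraction"] = _jsonable(
            meth["site_distribution"]["zero_fraction"])
        res["cg_site_gt02_fraction"] = _jsonable(
            meth["site_distribution"]["gt02_fraction"])
        res["symmetric_cg_pearson"] = _jsonable(meth["symmetry"]["pearson"])
        res["expression_spearman"] = _jsonable(
            meth["expression_correlation"][0])

    if "dmr" in config.stages:
        dmr_params = config.effective("dmr")
        dmr = experiments.run_dmr_experiments(seed=seed)
        with open(os.path.join(config.outdir, "dmrs.bed"), "w") as fh:
            for d in dmr["dmrs"]:
                fh.write(f"{d.contig}\t{d.start}\t{d.end}\t"
                         f"{d.direction}\t{d.n_cg}\t{d.delta:.3f}\t"
                         f"{d.p_value:.3g}\n")
        res["dmr"] = {
            "parameters": dmr_params,
            "planted_recovered": len(dmr["dmrs"]),
            "planted_boundary_offset_sites": _jsonable(
                dmr["boundary_offset_sites"]),
            "null_count": len(dmr["null_dmrs"]),
        }

    if "te_structure" in config.stages:
        st = experiments.run_structure_experiment(seed=seed)
        st["report"].to_csv(os.path.join(config.outdir, "te_elements.tsv"),
                            sep="\t", index=False)
        fam_oe = st["report"].groupby("family")["cg_oe"].median()
        res["te_structure"] = {
            "classification_accuracy": _jsonable(
                st["classification_accuracy"]),
            "family_oe_median": {k: _jsonable(v)
                                 for k, v in fam_oe.items()},
            "depletion_ranksum_p": _jsonable(st["depletion_p"]),
            "depletion_significant": bool(st["depletion_significant"]),
        }

    if "evolution" in config.stages:
        ev_params = config.effective("evolution")
        ev = experiments.run_evolution_experiment(
            seed=seed, n_subfamilies=ev_params["n_subfamilies"],
            loss_prob=ev_params["loss_prob"])
        ev["presence_matrix"].to_csv(
            os.path.join(config.outdir, "presence_matrix.tsv"), sep="\t")
        ev["branch_totals"].to_csv(
            os.path.join(config.outdir, "dollo_branch_totals.tsv"), sep="\t",
            index=False)
        kk = experiments.run_kaks_calibration(
            seed=seed, omegas=tuple(ev_params["kaks_omegas"]),
            n_pairs=ev_params["kaks_pairs"], codons=ev_params["kaks_codons"])
        res["evolution"] = {
            "n_subfamily_components": ev["n_components"],
            "components_pure_fraction": _jsonable(
                ev["components_pure_fraction"]),
            "dollo_total_losses": ev["total_inferred_losses"],
            "dollo_loss_bound_violations": ev["loss_bound_violations"],
            "kaks_median_by_omega": {str(k): _jsonable(v)
                                     for k, v in kk["medians"].items()},
            "kaks_spearman_vs_omega": _jsonable(kk["spearman_vs_omega"]),
            "kaks_purifying_fraction": _jsonable(
                kk["purifying_fraction_at_lowest_omega"]),
        }

    write_report(report, os.path.join(config.outdir, "summary.json"))
    return report


def write_report(report: dict, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(_jsonable(report), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_report(path: str) -> dict:
    with open(path) as fh:
        return json.load(fh)
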