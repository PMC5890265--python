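"""Reusable synthetic experiments composing the analysis stages.

Each function runs one self-contained study on generated data and returns a
plain dict of computed quantities. The numbered analysis scripts, the
pipeline runner and the acceptance checks all call these, so every reported
number comes from the same code path.
"""

from __future__ import annotations

import dataclasses
import os
import tempfile

import numpy as np
import pandas as pd

from . import calling, methylome, simulate, te_evolution, te_structure
from .simulate import SimulationConfig, TEFamilySpec

__all__ = [
    "default_te_families",
    "demo_config",
    "run_methylome_experiment",
    "run_symmetry_contrast",
    "run_dmr_experiments",
    "run_genotype_experiment",
    "run_structure_experiment",
    "run_evolution_experiment",
    "run_kaks_calibration",
]

SPECIES_TREE = "((speciesA,speciesB),(speciesC,speciesD));"


def default_te_families() -> tuple:
    """The planted element families of the demo genome.

    A DNMT-bearing LINE (methyltransferase ORF upstream of the reverse
    transcriptase ORF, 8-bp TSD, no polyA), a DNMT-bearing DIRS (single Pol
    ORF carrying RVT, RNase H, the methyltransferase and a tyrosine
    recombinase, A-coding-B-A-B repeats), a plain Gypsy-like LTR element,
    and an old LINE family whose copies carry heavy CpG deamination —
    the family used to demonstrate CG depletion.
    """
    return (
        TEFamilySpec(name="LineDnmt", architecture="LINE",
                     orf_layout=(("DNA_methylase",),
                                 ("Exo_endo_phos", "RVT_1")),
                     n_copies=5, tsd_length=8),
        TEFamilySpec(name="DirsDnmt3", architecture="DIRS",
                     orf_layout=(("RVT_1", "RNase_H", "DNA_methylase",
                                  "Phage_integrase"),),
                     n_copies=4, ltr_length=250),
        TEFamilySpec(name="GypsyLtr", architecture="LTR",
                     orf_layout=(("RVT_1", "RNase_H"),),
                     n_copies=4, ltr_length=220, tsd_length=4),
        TEFamilySpec(name="LineOld", architecture="LINE",
                     orf_layout=(("RVT_1",),),
                     n_copies=6, tsd_length=6, cg_deamination_rate=0.5),
    )

EXPECTED_CLASSIFICATION = {
    "LineDnmt": "LINE-DNMT",
    "DirsDnmt3": "DIRS-DNMT",
    "GypsyLtr": "LTR",
}


def demo_config(seed: int = 1, **overrides) -> SimulationConfig:
    """Study conditions of the demo genome: 200 kb, 20 genes, the default
    element families, saturated CG methylation (0.7), low 3'-biased CH
    (0.01, 5x tail bias), non-conversion 0.5%, 30x single-end 100-bp reads."""
    kw = dict(seed=seed, genome_length=200_000, n_genes=20,
              te_families=default_te_families(), cg_level=0.7, ch_level=0.01,
              ch_te_3prime_bias=5.0, heterogeneity=2.0, non_conversion=0.005,
              coverage=30.0, read_length=100)
    kw.update(overrides)
    return SimulationConfig(**kw)


def _call_library(genome: dict, truth, config: SimulationConfig,
                  workdir: str | None = None,
                  sam_name: str = "reads.sam",
                  reference: dict | None = None) -> calling.MethylomeTable:
    """Simulate reads against ``genome`` and pile them up on ``reference``
    (defaults to the same contigs)."""
    reads = simulate.simulate_bisulfite_reads(genome, truth, config)
    own_tmp = workdir is None
    tmp = tempfile.mkdtemp() if own_tmp else workdir
    sam = os.path.join(tmp, sam_name)
    simulate.write_sam(reads, genome, sam)
    table = calling.pileup_cytosines(sam, reference or genome)
    if own_tmp:
        os.unlink(sam)
        os.rmdir(tmp)
    return table


def run_methylome_experiment(config: SimulationConfig | None = None,
                             seed: int = 1,
                             workdir: str | None = None) -> dict:
    """Simulate one library end to end and compute the methylome statistics:
    global context levels, lambda non-conversion, the site-level
    distribution, CG-strand concordance, metaprofiles and TE 3' CH
    enrichment."""
    config = config or demo_config(seed)
    sim = simulate.simulate_genome(config)
    truth = simulate.simulate_truth_methylome(sim.sample_genome, sim.features,
                                              config)
    own_tmp = workdir is None
    tmp = tempfile.mkdtemp() if own_tmp else workdir
    sam = os.path.join(tmp, "library1.sam")
    reads = simulate.simulate_bisulfite_reads(sim.sample_genome, truth, config)
    simulate.write_sam(reads, sim.sample_genome, sam)
    table = calling.pileup_cytosines(sam, sim.genome)
    table = calling.genotype_filter(table)
    nonconv = calling.estimate_nonconversion(table, config.control_contig)

    main = calling.MethylomeTable(
        table.table[table.table["contig"] != config.control_contig],
        table.metadata)
    levels = methylome.global_levels(main)
    site = methylome.site_level_distribution(main, "CG", min_cov=10)
    sym = methylome.symmetric_cg_concordance(main, min_cov=10)
    feats = methylome.FeatureSet.from_dataframe(sim.features)
    genes = methylome.FeatureSet(feats.subset("gene"))
    tes = methylome.FeatureSet(feats.subset("TE"))
    prof_te = methylome.metaplot(main, tes, body_bins=20, flank_bp=1000,
                                 flank_bins=10, contexts=("CG", "CH"))
    enrich = methylome.te_3prime_ch_enrichment(main, tes)
    read_levels = methylome.read_level_distribution(
        sam, {config.main_contig: sim.genome[config.main_contig]})
    gene_levels = methylome.gene_body_levels(main, genes)
    r_expr, n_expr = methylome.expression_methylation_correlation(
        gene_levels["level"], gene_levels["tpm"])

    if own_tmp:
        os.unlink(sam)
        os.rmdir(tmp)

    truth_main = truth.table[truth.table["contig"] == config.main_contig]
    return {
        "config": config,
        "sim": sim,
        "truth": truth,
        "table": table,
        "nonconversion": nonconv,
        "global_levels": levels,
        "truth_mean_cg": float(
            truth_main.loc[truth_main["context"] == "CG", "p"].mean()),
        "truth_mean_ch": float(truth_main.loc[
            truth_main["context"].isin(("CHG", "CHH")), "p"].mean()),
        "site_distribution": site,
        "symmetry": sym,
        "te_profile": prof_te,
        "te_enrichment": enrich,
        "read_levels": read_levels,
        "expression_correlation": (r_expr, n_expr),
    }


def run_symmetry_contrast(seed: int = 1, genome_length: int = 60_000,
                          coverage: float = 30.0) -> dict:
    """CG-strand concordance under independent-strand versus symmetric truth.

    Small kappa keeps per-site draws dispersed so the contrast is sharp.
    """
    out = {}
    for mode in (False, True):
        cfg = SimulationConfig(seed=seed, genome_length=genome_length,
                               n_genes=0, te_families=(), cg_level=0.5,
                               ch_level=0.0, heterogeneity=0.5,
                               non_conversion=0.0, coverage=coverage,
                               symmetric_cg=mode, lambda_length=1000)
        sim = simulate.simulate_genome(cfg)
        truth = simulate.simulate_truth_methylome(sim.genome, sim.features, cfg)
        table = _call_library(sim.genome, truth, cfg)
        sym = methylome.symmetric_cg_concordance(table, min_cov=10)
        out["symmetric" if mode else "independent"] = sym
    return out


def run_dmr_experiments(seed: int = 1, genome_length: int = 60_000,
                        coverage: float = 30.0, window: tuple = (20_000, 21_000),
                        level_in: float = 0.9, level_out: float = 0.5) -> dict:
    """Planted-DMR recovery and a same-truth null comparison.

    Library A carries CG level ``level_in`` over ``window`` (both strands);
    library B ``level_out`` there; elsewhere both share one truth. The null
    pair re-sequences library A's truth with an independent read draw.
    """
    cfg = SimulationConfig(seed=seed, genome_length=genome_length, n_genes=0,
                           te_families=(), cg_level=0.7, ch_level=0.0,
                           heterogeneity=2.0, non_conversion=0.002,
                           coverage=coverage, lambda_length=1000)
    sim = simulate.simulate_genome(cfg)
    truth_a = simulate.simulate_truth_methylome(sim.genome, sim.features, cfg)
    ta = truth_a.table
    in_win = ((ta["contig"] == cfg.main_contig) & (ta["context"] == "CG")
              & (ta["pos"] - 1 >= window[0]) & (ta["pos"] - 1 < window[1]))
    n_cg_window = int(in_win.sum()) // 2  # dinucleotides, both strands listed
    tb = ta.copy()
    ta.loc[in_win, "p"] = level_in
    tb.loc[in_win, "p"] = level_out
    truth_b = simulate.TruthMethylome(tb)

    table_a = _call_library(sim.genome, truth_a, cfg, sam_name="a.sam")
    table_b = _call_library(sim.genome, truth_b,
                            dataclasses.replace(cfg, seed=seed + 1000),
                            sam_name="b.sam")
    dmrs = methylome.find_dmrs(table_a, table_b)

    table_a2 = _call_library(sim.genome, truth_a,
                             dataclasses.replace(cfg, seed=seed + 2000),
                             sam_name="a2.sam")
    null_dmrs = methylome.find_dmrs(table_a, table_a2)

    boundary = np.nan
    if dmrs:
        best = max(dmrs, key=lambda d: d.n_cg)
        cg_pos = np.sort(ta.loc[(ta["context"] == "CG")
                                & (ta["strand"] == "+")
                                & (ta["contig"] == cfg.main_contig),
                                "pos"].to_numpy() - 1)
        # boundary error in CG sites, not bp
        start_off = int(np.abs(np.searchsorted(cg_pos, best.start)
                               - np.searchsorted(cg_pos, window[0])))
        end_off = int(np.abs(np.searchsorted(cg_pos, best.end)
                             - np.searchsorted(cg_pos, window[1])))
        boundary = max(start_off, end_off)
    return {"dmrs": dmrs, "null_dmrs": null_dmrs,
            "n_cg_window": n_cg_window, "boundary_offset_sites": boundary,
            "window": window}


def run_genotype_experiment(seed: int = 1, n_snvs: int = 100,
                            genome_length: int = 60_000,
                            coverage: float = 30.0) -> dict:
    """Plant C->T / G->A variants and measure genotype-filter recall and
    false removal of true cytosines."""
    cfg = SimulationConfig(seed=seed, genome_length=genome_length, n_genes=0,
                           te_families=(), n_snvs=n_snvs, cg_level=0.7,
                           ch_level=0.01, coverage=coverage,
                           non_conversion=0.002, lambda_length=1000)
    sim = simulate.simulate_genome(cfg)
    truth = simulate.simulate_truth_methylome(sim.sample_genome, sim.features,
                                              cfg)
    table = _call_library(sim.sample_genome, truth, cfg,
                          reference=sim.genome)
    filtered = calling.genotype_filter(table)
    snv_keys = {(c, p + 1, "+" if ref == "C" else "-")
                for c, p, ref, alt in sim.snvs}

    def keys(tab):
        df = tab.table
        return set(zip(df["contig"], df["pos"], df["strand"]))

    before, after = keys(table), keys(filtered)
    snv_present = snv_keys & before
    snv_removed = snv_present - after
    true_before = before - snv_keys
    true_removed = true_before - after
    return {
        "n_snvs_called": len(snv_present),
        "snv_removed_fraction": len(snv_removed) / max(len(snv_present), 1),
        "true_removed_fraction": len(true_removed) / max(len(true_before), 1),
    }


def run_structure_experiment(seed: int = 1) -> dict:
    """Recover the planted element structures and the CG-depletion signal.

    Every zero-divergence copy is annotated from scratch (ORFs, domains via
    the planted-hit bridge, repeats, TSD) and classified; the deaminated
    family's CG O/E is compared with the untouched families by one-sided
    rank-sum test.
    """
    cfg = demo_config(seed, genome_length=120_000, n_genes=5,
                      coverage=1.0, lambda_length=1000)
    sim = simulate.simulate_genome(cfg)
    genome = sim.genome[cfg.main_contig]

    orfs_by_element = {}
    elements = {}
    for te in sim.te_registry:
        seq = genome[te.start:te.end]
        orfs = te_structure.find_orfs(seq, min_aa=100,
                                      id_prefix=f"{te.id}|orf")
        orfs_by_element[te.id] = orfs
    domain_table = simulate.domain_table_for_elements(sim.te_registry,
                                                      orfs_by_element)
    rows = []
    for te in sim.te_registry:
        seq = genome[te.start:te.end]
        sub = domain_table[domain_table["target_name"].str.startswith(
            te.id + "|")]
        elt = te_structure.annotate_element(
            seq, element_id=te.id, genome_seq=genome,
            interval=(te.start, te.end), domain_table=sub)
        elements[te.id] = elt
        expected = EXPECTED_CLASSIFICATION.get(te.family, None)
        rows.append((te.id, te.family, te.architecture, elt.classification,
                     expected, elt.arrangement, elt.tsd, elt.polya, elt.cg_oe))
    report = pd.DataFrame(rows, columns=[
        "id", "family", "true_architecture", "classification", "expected",
        "arrangement", "tsd", "polya", "cg_oe"])

    scored = report.dropna(subset=["expected"])
    accuracy = float((scored["classification"] == scored["expected"]).mean())
    dea = report.loc[report["family"] == "LineOld", "cg_oe"]
    ctrl = report.loc[report["family"] != "LineOld", "cg_oe"]
    p_dep, sig = te_structure.compare_cg_depletion(dea, ctrl)
    return {"report": report, "elements": elements, "sim": sim,
            "classification_accuracy": accuracy,
            "n_scored": int(len(scored)),
            "oe_deaminated_median": float(dea.median()),
            "oe_control_median": float(ctrl.median()),
            "depletion_p": p_dep, "depletion_significant": sig}


def run_evolution_experiment(seed: int = 1, n_subfamilies: int = 40,
                             loss_prob: float = 0.25) -> dict:
    """Identity clustering of planted families plus Dollo dynamics on a
    simulated 4-taxon subfamily history."""
    cfg = demo_config(seed, genome_length=120_000, n_genes=0,
                      coverage=1.0, lambda_length=1000)
    sim = simulate.simulate_genome(cfg)
    genome = sim.genome[cfg.main_contig]
    proteins = {}
    for te in sim.te_registry:
        orfs = te_structure.find_orfs(genome[te.start:te.end], min_aa=30,
                                      id_prefix=f"{te.id}|orf")
        if orfs:
            longest = max(orfs, key=lambda o: len(o.protein))
            proteins[te.id] = longest.protein
    graph = te_evolution.pairwise_identity(seqs=proteins)
    comps = te_evolution.cluster_components(graph, threshold=0.8)
    families = {te.id: te.family for te in sim.te_registry}
    pure = sum(1 for c in comps
               if len({families[m] for m in c}) == 1)

    matrix, events = simulate.simulate_family_history(
        SPECIES_TREE, n_subfamilies, loss_prob, seed=seed)
    per_subfam, totals = te_evolution.dollo_parsimony(SPECIES_TREE, matrix)
    true_losses = {e["subfamily"]: len(e["losses"]) for e in events}
    merged = per_subfam.assign(
        true_losses=per_subfam["subfamily"].map(true_losses))
    informative = merged[merged["gain_node"].notna()]
    excess = (informative["true_losses"] - informative["n_losses"])
    return {
        "n_components": len(comps),
        "n_families_planted": len({te.family for te in sim.te_registry}),
        "components_pure_fraction": pure / len(comps) if comps else np.nan,
        "presence_matrix": matrix,
        "dollo": per_subfam,
        "branch_totals": totals,
        "loss_bound_violations": int((excess < 0).sum()),
        "mean_loss_undercount": float(excess.mean()) if len(excess) else np.nan,
        "total_inferred_losses": int(per_subfam["n_losses"].sum()),
        "total_true_losses": int(sum(true_losses.values())),
    }


def run_kaks_calibration(seed: int = 1, omegas=(0.1, 0.5, 1.0),
                         n_pairs: int = 30, codons: int = 150) -> dict:
    """Estimated Ka/Ks across simulated selection regimes."""
    from scipy import stats

    medians = {}
    ratios_by_omega = {}
    for i, w in enumerate(omegas):
        pairs = simulate.simulate_codon_pair_set(
            n_pairs, codons, omega=w, seed=seed + i)
        ratios = []
        for a, b in pairs:
            cp = te_evolution.kaks_ng86(a, b)
            if not np.isnan(cp.ratio):
                ratios.append(cp.ratio)
        ratios_by_omega[w] = ratios
        medians[w] = float(np.median(ratios)) if ratios else np.nan
    xs = [w for w in omegas for _ in ratios_by_omega[w]]
    ys = [r for w in omegas for r in ratios_by_omega[w]]
    rho = float(stats.spearmanr(xs, ys).statistic) if len(set(xs)) > 1 else np.nan
    frac_purifying = float(np.mean(np.asarray(ratios_by_omega[omegas[0]]) < 0.2))
    return {"medians": medians, "spearman_vs_omega": rho,
            "purifying_fraction_at_lowest_omega": frac_purifying,
            "ratios": ratios_by_omega}
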