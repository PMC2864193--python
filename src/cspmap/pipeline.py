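"""End-to-end orchestration of the mapping and candidate-gene screens.

The default run is fully synthetic: it plants a two-locus epistatic
breakdown in an introgression panel, simulates the double-mating trials,
recovers breakdown flags by baseline t-tests, infers the co-required locus
set, selects broad-sense candidates from a generated annotation table, runs
the expression and selection screens on planted signals, and merges
everything into a final report.  Every stage derives its seed from the
single pipeline seed by fixed offsets, so a rerun with the same seed is
byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import candidates as cand
from . import expression as expr
from . import igmap
from . import io as cio
from . import paternity as pat
from . import selection as sel
from . import synthetic as syn
from .bands import CytoBand, CytoInterval, parse_band
from .codonmodel import PhyloTree

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline",
           "region_to_interval"]

log = logging.getLogger("cspmap")

# Fixed per-stage seed offsets from the global seed (logged at run time).
_SEED_OFFSETS = {"panel": 1, "trials": 2, "annotation": 3, "qpcr": 4,
                 "bootstrap": 5, "codon": 6, "fit": 7}


@dataclass
class PipelineConfig:
    """Stage parameters for a synthetic end-to-end run."""

    seed: int = 0
    out_dir: Optional[str] = None
    # paternity
    alpha: float = 0.05
    policy: str = "full"
    mating: syn.MatingSimConfig = field(default_factory=syn.MatingSimConfig)
    # mapping
    panel: syn.PanelSimConfig = field(default_factory=syn.PanelSimConfig)
    max_set_size: int = 3
    # expression
    n_boot: int = 1000
    tails: Tuple[float, ...] = (0.05, 0.10)
    n_genes_in_loci: int = 135
    n_genes_outside: int = 65
    fraction_male_reproductive: float = 0.6
    n_overexpressed: int = 5
    n_underexpressed: int = 5
    overexpressed_fold: float = 4.0
    underexpressed_fold: float = 0.2
    replicate_sd: float = 0.15
    n_replicates: int = 2
    # selection
    run_selection: bool = True
    n_selection_genes: int = 2
    selection_n_codons: int = 500
    selection_n_starts: int = 2
    selection_branch_lengths: Tuple[float, float, float] = (0.2, 0.1, 0.3)
    foreground: str = "sim"


@dataclass
class PipelineResult:
    trials: pd.DataFrame
    panel: pd.DataFrame
    flags: pd.DataFrame
    ancova: pat.AnovaTable
    correlation: pat.CorrelationResult
    hypotheses: List[igmap.LocusHypothesis]
    loci: List[CytoInterval]
    annotation: pd.DataFrame
    folds: pd.DataFrame
    thresholds: expr.ScreenThresholds
    screened: pd.DataFrame
    selection_results: pd.DataFrame
    report: Dict
    truth: Dict


def region_to_interval(region: igmap.Region) -> CytoInterval:
    """Convert a derived region's cut bounds back to a band interval."""
    def band(cut, is_end):
        division, letter, sub, _side = cut
        if not 0 < sub < 10**6:
            sub = None
        return CytoBand(division, letter, sub)
    return CytoInterval(band(region.cut_lo, False), band(region.cut_hi, True))


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full synthetic pipeline; optionally write artifacts."""
    seed = config.seed
    seeds = {k: seed + off for k, off in _SEED_OFFSETS.items()}
    log.info("pipeline seed=%d per-stage seeds=%s", seed, seeds)

    # --- simulate panel and trials -------------------------------------
    panel_cfg = syn.PanelSimConfig(**{**config.panel.__dict__, "seed": seeds["panel"]})
    panel, panel_truth = syn.gen_introgression_panel(panel_cfg)
    mating_cfg = syn.MatingSimConfig(**{**config.mating.__dict__,
                                        "n_lines": panel_cfg.n_lines,
                                        "seed": seeds["trials"]})
    trials, mating_truth = syn.gen_mating_trials(
        mating_cfg, baseline_line_ids=panel_truth["breakdown_ids"])

    # --- paternity statistics ------------------------------------------
    records = pat.filter_trials(pat.add_paternity_records(trials), config.policy)
    baseline_id = mating_cfg.baseline_sample_id
    ig_records = records[records["line_id"] != baseline_id]
    base_records = records[records["line_id"] == baseline_id]
    anova = pat.fit_ancova(ig_records)
    corr = pat.pearson_correlation(ig_records["p2"], ig_records["fecundity"])
    flags = pat.flag_breakdown_lines(ig_records, base_records, alpha=config.alpha)

    # --- interval mapping ----------------------------------------------
    flag_map = dict(zip(flags["line_id"], flags["breakdown_flag"]))
    lines = [igmap.IntrogressionLine(
        line_id=str(r.line_id),
        interval=CytoInterval(parse_band(r.start_band), parse_band(r.end_band)),
        breakdown_flag=bool(flag_map.get(str(r.line_id), False)))
        for r in panel.itertuples()]
    partition = igmap.derive_regions(lines)
    coverage = igmap.coverage_matrix(lines, partition)
    observed_flags = [bool(flag_map.get(ln.line_id, False)) for ln in lines]
    hypotheses = igmap.infer_corequired(coverage, observed_flags,
                                        line_ids=[ln.line_id for ln in lines],
                                        max_set_size=config.max_set_size)
    top = hypotheses[0]
    loci = [region_to_interval(partition.regions[r - 1])
            for r in sorted(top.required_regions)]

    # --- candidate annotation ------------------------------------------
    annotation, ann_truth = syn.gen_gene_annotation_table(
        loci, config.n_genes_in_loci, config.n_genes_outside,
        config.fraction_male_reproductive, seed=seeds["annotation"])
    gene_records = [cand.GeneRecord.from_row(row) for _, row in annotation.iterrows()]
    broad = cand.broad_candidates(gene_records, loci)
    broad_ids = [g.gene_id for g in broad]

    # --- expression screen ----------------------------------------------
    # planted differential expression in both directions, as in real screens
    n_up = min(config.n_overexpressed, len(broad_ids))
    n_down = min(config.n_underexpressed, max(len(broad_ids) - n_up, 0))
    true_folds = {}
    for i, g in enumerate(broad_ids):
        if i < n_up:
            true_folds[g] = config.overexpressed_fold
        elif i < n_up + n_down:
            true_folds[g] = config.underexpressed_fold
        else:
            true_folds[g] = 1.0
    ct = syn.gen_qpcr_table(broad_ids, [true_folds[g] for g in broad_ids],
                            replicate_sd=config.replicate_sd,
                            n_replicates=config.n_replicates, seed=seeds["qpcr"])
    folds = expr.fold_table(ct, species1="sim", species2="mau")
    pooled = [f for fl in folds["replicate_folds"] for f in fl]
    thresholds = expr.bootstrap_thresholds(pooled, n_boot=config.n_boot,
                                           tails=config.tails,
                                           sample_size=config.n_replicates,
                                           seed=seeds["bootstrap"])
    screened = expr.screen_genes(folds, thresholds)

    # --- selection screen ------------------------------------------------
    sel_rows = []
    planted_selection: List[str] = []
    if config.run_selection and broad_ids:
        n_sel = min(config.n_selection_genes, len(broad_ids))
        sel_genes = broad_ids[-n_sel:]       # disjoint from expression plants
        tree = PhyloTree(taxa=["sim", "sec", "mel"],
                         branch_lengths=np.array(config.selection_branch_lengths),
                         foreground=config.foreground)
        for i, gene in enumerate(sel_genes):
            positive = i == 0
            if positive:
                cfg = syn.CodonSimConfig(
                    tree=tree, model="branch_site",
                    omegas={"omega0": 0.1, "omega2": 8.0}, proportions=(0.5, 0.1),
                    kappa=2.0, n_codons=config.selection_n_codons,
                    seed=seeds["codon"] + i)
                planted_selection.append(gene)
            else:
                cfg = syn.CodonSimConfig(
                    tree=tree, model="one_ratio", omegas={"omega": 0.2},
                    kappa=2.0, n_codons=config.selection_n_codons,
                    seed=seeds["codon"] + i)
            aln = syn.simulate_codon_alignment(cfg)
            result = sel.branch_site_test(aln, tree,
                                          n_starts=config.selection_n_starts,
                                          seed=seeds["fit"] + i)
            sel_rows.append({"gene": gene, "foreground": config.foreground,
                             "two_delta_ell": result.lrt.two_delta_ell,
                             "p_value": result.lrt.p_value,
                             "omega2": min(result.omega2, sel.OMEGA_MAX),
                             "significant": result.lrt.p_value < config.alpha,
                             "classification": ""})
    selection_results = pd.DataFrame(
        sel_rows, columns=["gene", "foreground", "two_delta_ell", "p_value",
                           "omega2", "significant", "classification"])

    # --- final report -----------------------------------------------------
    report = cand.final_report(broad, expression_flags=screened,
                               selection_results=selection_results, loci=loci)
    report["ancova"] = {
        "F_line": anova.f_stat("line_id"), "p_line": anova.p_value("line_id"),
        "F_block": anova.f_stat("block"), "p_block": anova.p_value("block"),
    }
    report["correlation"] = {"r": corr.r, "n": corr.n, "p": corr.p_value}
    report["n_breakdown_lines"] = int(flags["breakdown_flag"].sum())
    report["top_hypothesis"] = {
        "required_regions": sorted(top.required_regions),
        "score": top.n_consistent,
        "exceptions": [list(e) for e in top.exceptions],
    }
    report["loci"] = [str(loc) for loc in loci]

    truth = {"panel": panel_truth, "mating": mating_truth,
             "annotation": ann_truth,
             "expression_candidate_ids": sorted(g for g, f in true_folds.items()
                                                if f != 1.0),
             "selection_candidate_ids": sorted(planted_selection)}

    result = PipelineResult(
        trials=trials, panel=panel, flags=flags, ancova=anova,
        correlation=corr, hypotheses=hypotheses, loci=loci,
        annotation=annotation, folds=folds, thresholds=thresholds,
        screened=screened, selection_results=selection_results,
        report=report, truth=truth)
    if config.out_dir is not None:
        _write_artifacts(result, Path(config.out_dir))
    return result


def _write_artifacts(result: PipelineResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    cio.write_tsv(result.trials, out / "trials.tsv")
    cio.write_tsv(result.panel, out / "panel.tsv")
    cio.write_tsv(result.flags, out / "line_flags.tsv")
    cio.write_tsv(result.ancova.table.reset_index(), out / "ancova.tsv")
    folds = result.folds.copy()
    folds["replicate_folds"] = folds["replicate_folds"].map(
        lambda v: ";".join(f"{x:.6g}" for x in v))
    cio.write_tsv(folds, out / "folds.tsv")
    screened = result.screened.copy()
    screened["replicate_folds"] = screened["replicate_folds"].map(
        lambda v: ";".join(f"{x:.6g}" for x in v))
    cio.write_tsv(screened, out / "expression_flags.tsv")
    cio.write_tsv(result.annotation, out / "annotation.tsv")
    cio.write_tsv(result.selection_results, out / "selection.tsv")
    cio.write_json(result.report, out / "report.json")
    cio.write_json(result.truth, out / "truth.json")
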