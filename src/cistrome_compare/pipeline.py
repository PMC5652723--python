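"""File-based orchestration of the full cistrome comparison.

Stages communicate through TSV/JSON files in the run directory so each one
is independently inspectable and resumable: simulate -> signal PCA -> peak
overlap + genomic distribution -> motif enrichment -> target genes ->
pathway enrichment -> activity scores (iRAS) -> survival analysis. A
machine-readable ``summary.json`` collects the headline numbers of every
stage; runs are byte-identical under a fixed seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from cistrome_compare import (
    base_activity,
    formats,
    motif_enrichment as motifs_mod,
    pathway_enrichment as pathways_mod,
    peak_analysis,
    signal_analysis,
    survival_analysis,
    synthetic,
    target_genes,
)
from cistrome_compare.formats import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Validated parameters for every stage of a run."""

    outdir: str = "cistrome_run"
    seed: int = 0
    simulation: synthetic.SimulationConfig | None = None
    bin_width: int = 100
    pca_components: int = 2
    promoter_halfwidth: int = 1000
    genebody_length: int = 10_000
    refine_flank: int = 250
    motif_p_threshold: float = 1e-4
    target_fdr: float = 0.01
    tip_window: int = 5_000  # half the synthetic genome's 10 kb TSS spacing
    tip_bin: int = 100
    min_pathway_size: int = 40
    n_perm: int = 1000

    def __post_init__(self) -> None:
        if self.simulation is None:
            self.simulation = synthetic.SimulationConfig(seed=self.seed)
        checks = {
            "bin_width": self.bin_width > 0,
            "pca_components": self.pca_components >= 1,
            "refine_flank": self.refine_flank > 0,
            "motif_p_threshold": 0 < self.motif_p_threshold < 1,
            "target_fdr": 0 < self.target_fdr < 1,
            "min_pathway_size": self.min_pathway_size >= 1,
            "n_perm": self.n_perm >= 100,
        }
        bad = [k for k, ok in checks.items() if not ok]
        if bad:
            raise ValidationError(f"invalid pipeline parameters: {bad}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("simulation", None)
        cfg = cls(**raw)
        if sim_raw:
            sim_raw.setdefault("seed", cfg.seed)
            if "planted_pwm_ids" in sim_raw:
                sim_raw["planted_pwm_ids"] = tuple(sim_raw["planted_pwm_ids"])
            cfg.simulation = synthetic.SimulationConfig(**sim_raw)
        return cfg


@dataclass
class PipelineResult:
    outdir: Path
    summary: dict
    summary_path: Path
    simulation: synthetic.SimulationResult | None = None
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)


def _round(obj, ndigits: int = 6):
    if isinstance(obj, dict):
        return {k: _round(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round(v, ndigits) for v in obj]
    if isinstance(obj, (float, np.floating)):
        return round(float(obj), ndigits)
    if isinstance(obj, (int, np.integer)):
        return int(obj)
    return obj


def run_all(config: PipelineConfig) -> PipelineResult:
    """Run every stage on a fresh synthetic dataset; see module docstring."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {}
    tables: dict[str, pd.DataFrame] = {}
    stage = "simulate"
    try:
        sim = synthetic.simulate(config.simulation)
        synthetic.write_simulation(sim, outdir / "inputs")
        special = config.simulation.special_line_id
        lines = config.simulation.cell_lines
        exp_names = {
            (line, rep): f"{line}_rep{rep}" for line, rep in config.simulation.replicates
        }

        # --- signal level: binning + PCA -------------------------------
        stage = "signal_pca"
        tracks = {exp_names[k]: t for k, t in sim.tracks.items()}
        matrix = signal_analysis.assemble_matrix(tracks, config.bin_width)
        pca_res = signal_analysis.pca(matrix, config.pca_components)
        pca_df = pca_res.scores.copy()
        pca_df.index.name = "experiment"
        pca_df.to_csv(outdir / "pca_scores.tsv", sep="\t")
        tables["pca"] = pca_df
        summary["signal_pca"] = {
            "n_bins_retained": len(matrix.bins),
            "variance_explained": list(pca_res.variance_explained),
            "pc1_variance_pct": 100.0 * float(pca_res.variance_explained[0]),
        }

        # --- peak level: overlap + genomic distribution ----------------
        stage = "peak_overlap"
        peak_sets = {exp_names[k]: sim.truth.true_peaks[k[0]] for k in sim.tracks}
        ov = peak_analysis.overlap_matrix(peak_sets)
        ov.coefficients.to_csv(outdir / "peak_overlap.tsv", sep="\t")
        tables["overlap"] = ov.coefficients
        dist_rows = {}
        for name, peaks in peak_sets.items():
            d = peak_analysis.annotate_distribution(
                peaks, sim.genes, config.promoter_halfwidth, config.genebody_length
            )
            dist_rows[name] = {
                k: d.fraction(k) for k in ("promoter", "gene_body", "intergenic")
            }
        dist_df = pd.DataFrame(dist_rows).T
        dist_df.index.name = "experiment"
        dist_df.to_csv(outdir / "genomic_distribution.tsv", sep="\t")
        tables["distribution"] = dist_df
        summary["peak_overlap"] = {
            "cluster_order": ov.cluster_order,
            "promoter_fraction": {
                line: dist_rows[f"{line}_rep1"]["promoter"] for line in lines
            },
        }

        # --- motif level ------------------------------------------------
        stage = "motif_enrichment"
        pwms = list(sim.truth.pwms) + [
            synthetic.shuffled_decoy(p, seed=config.simulation.seed)
            for p in sim.truth.pwms
        ]
        motif_rows = []
        for line in lines:
            for res in motifs_mod.enrich_all(
                sim.truth.true_peaks[line],
                sim.genome,
                pwms,
                config.motif_p_threshold,
                flank=config.refine_flank,
            ):
                motif_rows.append(
                    {
                        "cell_line": line,
                        "motif_id": res.motif_id,
                        "hits_peak": res.hits_peak,
                        "hits_control": res.hits_control,
                        "es": res.es,
                        "log2_es": res.log2_es,
                        "p": res.p,
                        "q": res.q,
                    }
                )
        motif_df = pd.DataFrame(motif_rows)
        motif_df.to_csv(outdir / "motif_enrichment.tsv", sep="\t", index=False)
        tables["motifs"] = motif_df
        planted_id = config.simulation.planted_pwm_ids[0]
        planted = motif_df[motif_df.motif_id == planted_id].set_index("cell_line")
        summary["motif_enrichment"] = {
            "planted_motif": planted_id,
            "log2_es_by_line": planted["log2_es"].to_dict(),
            "q_by_line": planted["q"].to_dict(),
        }

        # --- target genes -----------------------------------------------
        stage = "target_genes"
        universe = [g.gene_id for g in sim.genes]
        per_exp_targets: dict[str, set[str]] = {}
        for key, track in sim.tracks.items():
            results = target_genes.call_targets(
                track, sim.genes, config.target_fdr, config.tip_window, config.tip_bin
            )
            per_exp_targets[exp_names[key]] = {
                r.gene_id for r in results if r.is_target
            }
        affinities = pd.DataFrame(
            {
                line: target_genes.merge_cell_line_targets(
                    [
                        per_exp_targets[exp_names[(line, rep)]]
                        for rep in range(1, config.simulation.n_replicates_per_line + 1)
                    ],
                    universe,
                )
                for line in lines
            }
        )
        affinities.to_csv(outdir / "binding_affinities.tsv", sep="\t")
        tables["affinities"] = affinities
        tov = target_genes.target_overlap_matrix(per_exp_targets, len(universe))
        tov.neg_log10_p.to_csv(outdir / "target_overlap.tsv", sep="\t")
        tables["target_overlap"] = tov.neg_log10_p
        summary["target_genes"] = {
            "n_targets_per_line": {line: int(affinities[line].sum()) for line in lines},
            "overlap_cluster_order": tov.cluster_order,
        }

        # --- pathway enrichment -----------------------------------------
        stage = "pathway_enrichment"
        gmt = formats.read_gmt(outdir / "inputs" / "pathways.gmt")
        pathway_rows = []
        for line in lines:
            targets = set(affinities.index[affinities[line] == 1])
            if not targets:
                continue
            for r in pathways_mod.pathway_enrichment(
                targets, gmt, set(universe), config.min_pathway_size
            ):
                pathway_rows.append(
                    {
                        "cell_line": line,
                        "pathway_id": r.pathway_id,
                        "overlap": r.overlap,
                        "es": r.es,
                        "p": r.p,
                        "signed_log_p": r.signed_log_p,
                    }
                )
        pathway_df = pd.DataFrame(pathway_rows)
        pathway_df.to_csv(outdir / "pathway_enrichment.tsv", sep="\t", index=False)
        tables["pathways"] = pathway_df
        summary["pathway_enrichment"] = {"n_rows": len(pathway_df)}

        # --- activity scores --------------------------------------------
        stage = "iras"
        n_genes = len(affinities)
        usable = [
            c for c in affinities.columns
            if 0 < affinities[c].sum() < n_genes
        ]
        dropped = sorted(set(affinities.columns) - set(usable))
        if dropped:
            logger.warning("iras: dropping degenerate affinity columns %s", dropped)
        iras_df = base_activity.iras_matrix(
            affinities[usable], sim.cohort, n_perm=config.n_perm, seed=config.seed
        )
        iras_df.to_csv(outdir / "iras.tsv", sep="\t")
        tables["iras"] = iras_df
        special_col = f"iRAS_{special}"
        other_line = lines[1]
        other_col = f"iRAS_{other_line}"
        er = sim.cohort.clinical["er_status"]
        summary["iras"] = {
            "columns": list(iras_df.columns),
            "mean_special_er_pos": float(iras_df.loc[er == "+", special_col].mean()),
            "mean_special_er_neg": float(iras_df.loc[er == "-", special_col].mean()),
            "mean_other_er_pos": float(iras_df.loc[er == "+", other_col].mean()),
            "mean_other_er_neg": float(iras_df.loc[er == "-", other_col].mean()),
        }

        # --- survival ----------------------------------------------------
        stage = "survival"
        clin = sim.cohort.clinical
        surv_summary: dict = {}
        for label, col in (("special", special_col), ("other", other_col)):
            strat = survival_analysis.stratify_sign(iras_df[col], er)
            lr = survival_analysis.logrank(strat.labels, clin["time"], clin["event"])
            surv_summary[f"logrank_p_{label}"] = lr.p
        quad = survival_analysis.stratify_quadrant(
            iras_df[special_col], iras_df[other_col], er
        )
        lr4 = survival_analysis.logrank(quad.labels, clin["time"], clin["event"])
        for g, curve in lr4.km_curves.items():
            curve.to_csv(outdir / f"km_quadrant{g}.tsv", sep="\t", index=False)
        covs = pd.DataFrame(
            {
                "iras_other": iras_df[other_col],
                "er_status": survival_analysis.encode_binary(er),
                "age": clin["age"],
            }
        )
        cox = survival_analysis.cox_multivariate(covs, clin["time"], clin["event"])
        surv_summary.update(
            {
                "logrank_p_quadrant": lr4.p,
                "quadrant_sizes": {k: int(v) for k, v in quad.group_sizes.items()},
                "quadrant_er_pos_fraction": quad.er_positive_fraction,
                "cox_coef_iras_other": float(cox.coefficients["iras_other"]),
                "cox_p_iras_other": float(cox.p_values["iras_other"]),
            }
        )
        summary["survival"] = surv_summary
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    summary_path = outdir / "summary.json"
    with open(summary_path, "w") as fh:
        json.dump(_round(summary), fh, indent=1, sort_keys=True)
        fh.write("\n")
    return PipelineResult(outdir, summary, summary_path, sim, tables)
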