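"""End-to-end orchestration: one config in, a run directory of tables out.

Stage order mirrors the analysis: trait validation -> tree calibration ->
signal / phylogenetic ANOVA / correlations -> ancestral states + stochastic
maps -> phylogenetic & standard PCA -> permutation and range-resampling
tests -> geography and disparity contrasts. Every stage writes CSV tables
plus a machine-readable ``results.json``; the config (with all seeds
explicit) is serialized into the run directory, and a stage is skipped on
rerun when its outputs already exist under an identical config hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .color_evolution import compare_models, marginal_asr, stochastic_map
from .comparative import blomberg_k, pagel_lambda, phyl_anova, spearman_holm
from .geo import (art_two_way, build_pairwise_table, build_range,
                  clean_and_thin, fit_albers, kruskal_wallis,
                  overlap_disparity_correlation, rank_ancova)
from .morphospace import group_summaries, phylogenetic_pca, standard_pca
from .phylo import (ASR_CALIBRATION, PPCA_CALIBRATION, cophenetic_distances,
                    make_ultrametric, read_newick, write_newick)
from .resampling import all_pairwise_color_tests, resampled_ppca_summary
from .synthetic import SyntheticScenario, simulate_study
from .trait_data import load_trait_table, summarize_by_color, write_trait_table

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_all"]

STAGES = ("traits", "tree", "stats", "asr", "ppca", "permutation", "geo")


@dataclass
class RunConfig:
    """All inputs and knobs for one full run; every seed is explicit."""

    out_dir: str = "campion_run"
    # inputs: either file paths or a synthetic scenario seed
    traits_csv: str | None = None
    tree_newick: str | None = None
    occurrences_csv: str | None = None
    scenario_seed: int | None = 0
    calibration: str = "ppca"            # "ppca" | "asr" preset
    n_perm: int = 1000
    n_sim_anova: int = 1000
    n_simmap: int = 1000
    n_datasets: int = 1000
    buffer_km: float = 10.0
    thin_km: float = 1.0
    seed: int = 0

    def validate(self):
        for name in ("n_perm", "n_sim_anova", "n_simmap", "n_datasets"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.calibration not in ("ppca", "asr"):
            raise ValueError("calibration preset must be 'ppca' or 'asr'")
        synthetic = self.scenario_seed is not None
        if not synthetic and not (self.traits_csv and self.tree_newick):
            raise ValueError("provide traits_csv and tree_newick, or a scenario_seed")
        return self

    def content_hash(self) -> str:
        payload = asdict(self)
        payload.pop("out_dir")  # where results land is not an analysis input
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml
            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _stage_done(out: Path, stage: str, h: str) -> bool:
    marker = out / f".{stage}.done"
    return marker.exists() and marker.read_text().strip() == h


def _mark(out: Path, stage: str, h: str):
    (out / f".{stage}.done").write_text(h)


def run_all(config: RunConfig) -> dict:
    """Execute the full analysis; returns the results dictionary that is
    also written to ``results.json`` in the run directory."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    h = config.content_hash()
    (out / "config.json").write_text(json.dumps(asdict(config), indent=2, default=str))
    log_lines = [f"campion {__version__}", f"config hash {h}", f"seed {config.seed}"]
    results: dict = {"config_hash": h, "version": __version__}
    ss = np.random.SeedSequence(config.seed)
    seeds = {name: int(s.generate_state(1)[0] % (2**31))
             for name, s in zip(STAGES, ss.spawn(len(STAGES)))}

    # ---- inputs -------------------------------------------------------
    synthetic = config.scenario_seed is not None
    if synthetic:
        scenario = SyntheticScenario(seed=config.scenario_seed)
        tree0, table, occurrences, truth = simulate_study(scenario)
    else:
        table = load_trait_table(config.traits_csv)
        tree0 = read_newick(config.tree_newick)
        occurrences = None
        if config.occurrences_csv:
            from .geo import OccurrenceSet
            occ_df = pd.read_csv(config.occurrences_csv)
            occurrences = {
                sid: OccurrenceSet(sid, sub[["decimalLongitude",
                                             "decimalLatitude"]].to_numpy())
                for sid, sub in occ_df.groupby("species")
            }

    try:
        # ---- stage: traits -------------------------------------------
        stage = "traits"
        if not _stage_done(out, stage, h):
            write_trait_table(table, out / "traits_validated.csv",
                              encoding_path=out / "encoding_map.json")
            summary = summarize_by_color(table)
            summary.continuous.to_csv(out / "summary_continuous.csv", index=False)
            summary.categorical.to_csv(out / "summary_categorical.csv", index=False)
            _mark(out, stage, h)
        results["n_species"] = len(table)

        # ---- stage: tree ---------------------------------------------
        stage = "tree"
        bounds = PPCA_CALIBRATION if config.calibration == "ppca" else ASR_CALIBRATION
        tree = make_ultrametric(tree0, bounds=bounds)
        if not _stage_done(out, stage, h):
            write_newick(tree, out / "tree_calibrated.nwk")
            _mark(out, stage, h)
        results["tree_root_age"] = float(tree.tip_depths().max())
        results["n_tips"] = tree.n_tips

        # species entering multivariate stages: complete + on the tree
        complete = table.complete_subset()
        X_all = complete.encoded_matrix()
        shared = [s for s in tree.tip_labels if s in X_all.index]
        colors = table.colors

        # ---- stage: stats --------------------------------------------
        stage = "stats"
        sig_rows = []
        anova_rows = []
        X_shared = X_all.loc[shared]
        for trait in X_shared.columns:
            x = X_shared[trait]
            lam = pagel_lambda(tree, x)
            k = blomberg_k(tree, x, n_perm=config.n_perm, seed=seeds["stats"])
            sig_rows.append({"trait": trait, "lambda": lam.estimate,
                             "lambda_p": lam.p_value, "K": k.estimate,
                             "K_p": k.p_value})
            an = phyl_anova(tree, x, colors.loc[shared],
                            n_sim=config.n_sim_anova, seed=seeds["stats"])
            anova_rows.append({"trait": trait, "F": an.F, "df_between": an.df_between,
                               "df_within": an.df_within, "p": an.p_value})
        signal_df = pd.DataFrame(sig_rows)
        anova_df = pd.DataFrame(anova_rows)
        corr_all = spearman_holm(X_all)
        if not _stage_done(out, stage, h):
            signal_df.to_csv(out / "phylo_signal.csv", index=False)
            anova_df.to_csv(out / "phyl_anova.csv", index=False)
            corr_all.to_csv(out / "correlations_all.csv", index=False)
            for g in ("white", "pink", "red"):
                members = colors[colors == g].index
                sub = X_all.loc[[s for s in X_all.index if s in set(members)]]
                if len(sub) >= 3:
                    spearman_holm(sub).to_csv(out / f"correlations_{g}.csv", index=False)
            _mark(out, stage, h)
        results["signal"] = signal_df.to_dict("records")

        # ---- stage: asr ----------------------------------------------
        stage = "asr"
        tips = colors.loc[tree.tip_labels]
        comparison = compare_models(tree, tips)
        fits = comparison.attrs["fits"]
        best = fits[comparison["model"].iloc[0]]
        asr = marginal_asr(tree, tips, best)
        simmap = stochastic_map(tree, tips, best, n_sims=config.n_simmap,
                                seed=seeds["asr"],
                                root_prior=np.full(3, 1 / 3))
        if not _stage_done(out, stage, h):
            comparison.to_csv(out / "mk_model_comparison.csv", index=False)
            asr.node_probs.to_csv(out / "asr_node_probs.csv")
            # node ids in the CSVs key into this annotated newick
            (out / "asr_tree_annotated.nwk").write_text(
                tree.to_newick(internal_ids=True) + "\n")
            simmap.node_frequencies.to_csv(out / "simmap_node_frequencies.csv")
            simmap.transition_counts.describe().T.to_csv(out / "simmap_transitions.csv")
            one_map = stochastic_map(tree, tips, best, n_sims=1, seed=seeds["asr"],
                                     root_prior=np.full(3, 1 / 3),
                                     keep_histories=True)
            from .color_evolution import history_to_simmap_newick
            (out / "simmap_example.nwk").write_text(
                history_to_simmap_newick(tree, one_map.histories[0],
                                         best.model.states) + "\n")
            _mark(out, stage, h)
        results["best_mk_model"] = str(comparison["model"].iloc[0])
        results["retained_models"] = comparison.loc[comparison["retained"], "model"].tolist()
        results["mean_transitions"] = simmap.mean_counts().to_dict()

        # ---- stage: ppca ---------------------------------------------
        stage = "ppca"
        X = X_all.loc[shared]
        ppca = phylogenetic_pca(X, tree)
        pca = standard_pca(X)
        means, ellipses = group_summaries(ppca, colors.loc[shared])
        if not _stage_done(out, stage, h):
            ppca.loadings.to_csv(out / "ppca_loadings.csv")
            scores = ppca.scores.copy()
            scores["color"] = colors.loc[scores.index]
            scores["ploidy"] = table.ploidy.loc[scores.index]
            scores.to_csv(out / "ppca_scores.csv")
            pd.DataFrame({"component": ppca.scores.columns,
                          "eigenvalue": ppca.eigenvalues,
                          "proportion": ppca.variance_explained}).to_csv(
                out / "ppca_variance.csv", index=False)
            pca.scores.to_csv(out / "pca_scores.csv")
            from .morphospace import plot_morphospace
            plot_morphospace(ppca, colors.loc[shared],
                             ploidy=table.ploidy.loc[shared],
                             path=out / "morphospace.svg")
            _mark(out, stage, h)
        results["ppca_lambda"] = ppca.lam
        results["ppca_variance_explained"] = ppca.variance_explained[:3].tolist()
        results["group_means"] = means.to_dict("index")

        # ---- stage: permutation --------------------------------------
        stage = "permutation"
        perm = all_pairwise_color_tests(ppca, colors.loc[shared],
                                        n_perm=config.n_perm,
                                        seed=seeds["permutation"])
        resample = resampled_ppca_summary(complete, tree, colors=colors,
                                          n_datasets=config.n_datasets,
                                          seed=seeds["permutation"])
        if not _stage_done(out, stage, h):
            perm.to_csv(out / "permutation_tests.csv", index=False)
            hists = {}
            for key, res in perm.attrs["results"].items():
                counts, edges = np.histogram(
                    res.null_distribution[np.isfinite(res.null_distribution)],
                    bins=30)
                hists["|".join(map(str, key))] = {
                    "observed": res.observed, "p_value": res.p_value,
                    "bin_edges": edges.tolist(), "counts": counts.tolist()}
            (out / "permutation_null_histograms.json").write_text(
                json.dumps(hists, indent=1))
            resample.summary.to_csv(out / "resampled_ppca_summary.csv", index=False)
            _mark(out, stage, h)
        results["permutation_tests"] = perm.drop(columns=["exhaustive"]).to_dict("records")

        # ---- stage: geo ----------------------------------------------
        stage = "geo"
        if occurrences:
            cleaned = {sid: clean_and_thin(o, min_distance_km=config.thin_km)
                       for sid, o in occurrences.items()}
            cleaned = {s: o for s, o in cleaned.items() if len(o)}
            pooled = np.vstack([o.points for o in cleaned.values()])
            proj = fit_albers(pooled)
            ranges = {s: build_range(o, buffer_km=config.buffer_km, projection=proj)
                      for s, o in cleaned.items()}
            dists = cophenetic_distances(tree)
            dist_df = pd.DataFrame(dists, index=tree.tip_labels, columns=tree.tip_labels)
            pairs = build_pairwise_table(ranges, ppca.scores, colors, dist_df)
            geo_stats: dict = {}
            for comp in ("pPC1", "pPC2"):
                hstat, df_, p = kruskal_wallis(pairs[f"{comp}_disparity"],
                                               pairs["sympatric"])
                geo_stats[f"kw_{comp}"] = {"H": hstat, "df": df_, "p": p}
                F, p = rank_ancova(pairs[f"{comp}_disparity"], pairs["sympatric"],
                                   pairs["phylo_distance"])
                geo_stats[f"ancova_{comp}"] = {"F": F, "p": p}
                art = art_two_way(pairs[f"{comp}_disparity"], pairs["color_pair"],
                                  pairs["sympatric"])
                geo_stats[f"art_{comp}"] = art.reset_index().to_dict("records")
            corr = overlap_disparity_correlation(pairs)
            if not _stage_done(out, stage, h):
                pairs.to_csv(out / "pairwise_geo_disparity.csv", index=False)
                corr.to_csv(out / "overlap_disparity_correlation.csv", index=False)
                from .geo import ranges_to_geojson
                ranges_to_geojson(ranges, out / "range_polygons.geojson")
                _mark(out, stage, h)
            results["n_sympatric_pairs"] = int(pairs["sympatric"].sum())
            results["n_allopatric_pairs"] = int((~pairs["sympatric"]).sum())
            results["geo_stats"] = geo_stats
    except Exception as exc:
        (out / "run.log").write_text("\n".join(log_lines + [f"FAILED at stage {stage}: {exc}"]))
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    (out / "results.json").write_text(json.dumps(results, indent=2, sort_keys=True,
                                                 default=float))
    log_lines.append("all stages complete")
    (out / "run.log").write_text("\n".join(log_lines))
    return results
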