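"""End-to-end orchestration: filters, beta partition, permutation tests,
ordination, species response models and wing PGLS, written as CSV tables.

Every stage draws its randomness from the single configured seed, so a
re-run with identical inputs reproduces every table exactly.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import abundance as ab
from . import beta, ordination, permtests, response, wing
from .io import (GEOGRAPHIC_VARS, HABITAT_VARS, PipelineConfig, load_island_table,
                 read_capture_records, read_continental_abundance,
                 read_effort_records, read_island_descriptors, read_newick,
                 read_trait_table, write_table)
from .simulate import (SyntheticConfig, simulate_ringing, simulate_traits,
                       simulate_tree)
from .transforms import chord_transform, filter_species, filter_years, pivot

logger = logging.getLogger("stopover")

ALL_STAGES = ("beta", "abundance", "permtest", "rda", "respond", "pgls")


def run_pipeline(config: PipelineConfig,
                 synthetic_config: SyntheticConfig | None = None,
                 stages: tuple[str, ...] = ALL_STAGES) -> dict[str, pd.DataFrame]:
    """Run the configured stages and write result tables under ``outdir``.

    If no capture file is configured, a synthetic dataset is generated
    (``synthetic_config`` or defaults, seeded from the pipeline seed) so the
    whole pipeline is exercisable without field data. Returns the result
    tables keyed by output name; any stage failure raises with the stage
    name and cause.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict[str, pd.DataFrame] = {}
    abund = None
    traits = tree = None

    if config.captures:
        captures = read_capture_records(config.captures)
        effort = read_effort_records(config.effort) if config.effort else None
    else:
        syn = synthetic_config or SyntheticConfig(seed=config.seed)
        captures, effort, truth = simulate_ringing(
            syn, read_island_descriptors(config.descriptors)
            if config.descriptors else None)
        abund = truth["abundance"]
        traits = simulate_traits(syn, truth)
        tree = simulate_tree(syn.n_species, seed=syn.seed)
    descriptors = (read_island_descriptors(config.descriptors)
                   if config.descriptors else load_island_table())
    if config.abundance:
        abund = read_continental_abundance(config.abundance)
    if config.traits:
        traits = read_trait_table(config.traits)
    if config.tree:
        tree = read_newick(config.tree)

    def _stage(name):
        return name in stages

    try:
        captures, dropped = filter_species(captures, config.min_years,
                                           config.min_islands)
        if effort is not None:
            eligible = filter_years(effort, config.season_start,
                                    config.season_end,
                                    config.min_days_per_fortnight)
            key = pd.MultiIndex.from_tuples(eligible)
            captures = captures.set_index(["island", "year"]) \
                .loc[lambda d: d.index.isin(key)].reset_index()
        cm = pivot(captures)
        tm = chord_transform(cm)
    except Exception as exc:
        raise RuntimeError(f"stage 'filter' failed: {exc}") from exc

    if _stage("beta"):
        try:
            part = beta.partition_beta(tm)
            table = part.summary()
            global_row = pd.DataFrame(
                {"years": [part.n_samples], "bd_ti": [np.nan],
                 "mean_lcbd": [np.nan], "bd_total": [part.bd_total],
                 "bd_island": [part.bd_island], "bd_temp": [part.bd_temp]},
                index=["(all)"])
            results["beta_partition"] = pd.concat([table, global_row])
            results["lcbd"] = part.lcbd.to_frame()
            results["scbd"] = part.scbd.to_frame()
        except Exception as exc:
            raise RuntimeError(f"stage 'beta' failed: {exc}") from exc

    if _stage("abundance") and abund is not None:
        try:
            means = ab.island_species_means(cm)
            results["model_comparison"] = ab.fit_loglog_models(means, abund)
            fit = ab.fit_final_regression(ab.species_totals(cm), abund)
            results["final_fit"] = pd.DataFrame([{
                k: v for k, v in fit.items() if k != "influential"}])
        except Exception as exc:
            raise RuntimeError(f"stage 'abundance' failed: {exc}") from exc

    if _stage("permtest"):
        try:
            res = permtests.permanova(tm, n_perm=config.n_permutations,
                                      seed=config.seed)
            disp = permtests.dispersion_test(tm, n_perm=config.n_permutations,
                                            seed=config.seed + 1)
            results["permanova"] = pd.DataFrame([vars(res), vars(disp)])
            results["pairwise_adjusted"] = permtests.pairwise_permanova(
                tm, n_perm=config.n_permutations, seed=config.seed + 2)
        except Exception as exc:
            raise RuntimeError(f"stage 'permtest' failed: {exc}") from exc

    if _stage("rda"):
        try:
            geo = ordination.prepare_predictors(descriptors, GEOGRAPHIC_VARS)
            hab = ordination.prepare_predictors(descriptors, HABITAT_VARS)
            geo, geo_trace = ordination.vif_filter(geo, config.vif_threshold)
            hab, hab_trace = ordination.vif_filter(hab, config.vif_threshold)
            logger.info("vif removals: geo=%s hab=%s", geo_trace, hab_trace)
            geo_s = ordination.expand_to_samples(geo, tm.values.index)
            hab_s = ordination.expand_to_samples(hab, tm.values.index)
            sel_geo = ordination.forward_select(tm, geo_s, n_perm=199,
                                                seed=config.seed + 3)
            sel_hab = ordination.forward_select(tm, hab_s, n_perm=199,
                                                seed=config.seed + 4)
            pred = pd.concat([geo_s[sel_geo], hab_s[sel_hab]], axis=1)
            if pred.shape[1] == 0:
                pred = pd.concat([geo_s, hab_s], axis=1)
            rr = ordination.rda(tm, pred, n_perm=199, seed=config.seed + 5)
            results["rda_axes"] = pd.DataFrame({
                "eigenvalue": rr.eigenvalues,
                "pct_total": rr.prop_total,
                "pct_constrained": rr.prop_constrained,
                "p": rr.axis_p if rr.axis_p is not None else np.nan,
            }, index=[f"RDA{i+1}" for i in range(rr.n_axes)])
            results["species_corr"] = ordination.species_axis_correlations(rr, tm)
            results["variable_corr"] = ordination.axis_variable_association(rr, pred)
            vp = ordination.varpart2(tm, geo_s, hab_s)
            results["varpart"] = pd.DataFrame([vars(vp)])
        except Exception as exc:
            raise RuntimeError(f"stage 'rda' failed: {exc}") from exc

    if _stage("respond"):
        try:
            variables = [c for c in ["long_km", "str_dist_africa", "min_dist_land",
                                     "min_d_south_land", "area", "max_alt", "ndvi"]
                         if c in descriptors.columns]
            summary = response.select_models(cm, descriptors, variables,
                                             mode="percentage")
            results["species_models"] = summary
            results["table6_summary"] = response.summarize_table6(summary)
            if effort is not None:
                rate = response.select_models(
                    cm, descriptors, variables, mode="rate", effort=effort,
                    excluded_islands=tuple(config.excluded_islands))
                results["species_models_rate"] = rate
                results["table6_summary_rate"] = response.summarize_table6(rate)
        except Exception as exc:
            raise RuntimeError(f"stage 'respond' failed: {exc}") from exc

    if _stage("pgls") and traits is not None and tree is not None \
            and "species_models" in results:
        try:
            summary = results["species_models"]
            plaus = summary[summary["plausible"]]
            area_set = set(plaus.loc[(plaus.variable == "area")
                                     & (plaus.sign == "+"), "species"])
            dsouth_set = set(plaus.loc[(plaus.variable == "min_d_south_land")
                                       & (plaus.sign == "+"), "species"])
            spp = traits.index
            groups = pd.DataFrame({
                "area_responder": [s in area_set for s in spp],
                "dsouth_responder": [s in dsouth_set for s in spp],
            }, index=spp).astype(int)
            # an indicator needs >=2 members on each side to be testable
            ok = [c for c in groups.columns
                  if 2 <= groups[c].sum() <= len(groups) - 2]
            dropped_groups = [c for c in groups.columns if c not in ok]
            if dropped_groups:
                logger.warning("pgls: dropping untestable grouping(s) %s",
                               dropped_groups)
            if ok:
                results["pgls_results"] = wing.group_tests(
                    traits[["kipp_mean", "wing_aspect_ratio"]],
                    groups[ok], tree)
            else:
                logger.warning("pgls: no testable grouping; stage skipped")
        except Exception as exc:
            raise RuntimeError(f"stage 'pgls' failed: {exc}") from exc

    for name, table in results.items():
        write_table(table, out / f"{name}.csv")
    return results
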