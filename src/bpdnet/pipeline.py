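"""End-to-end pipeline orchestration.

Runs the stages in order — simulate/load, preprocess, diversity, per-group
network inference, pairwise network comparison, ordinal outcome model — and
writes every per-stage artifact (TSV / GraphML / JSON) plus a manifest under
one output directory.  Every random draw flows from the config seed through a
stage-named sub-seed, so a rerun with the same config is bit-identical and
individual stages are reproducible in isolation.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import defaults
from .diversity import (alpha_diversity, anosim, anosim_pairwise, bray_curtis,
                        permanova, permdisp)
from .io import (GROUP_LEVELS, CountTable, SampleMetadata, TaxonomyTable,
                 read_count_table, read_metadata, read_taxonomy,
                 write_count_table, write_metadata, write_network,
                 write_taxonomy)
from .netbuild import (build_network, downsample_groups, keystone_scores,
                       mean_relative_abundance, threshold_sensitivity, topology)
from .netcompare import (PipelineParams, method_agreement, network_dissimilarity,
                         network_from_table, permute_compare)
from .outcome import FitError, design_matrix, fit_proportional_odds, forward_stepwise, standardize
from .preprocess import (abundance_prevalence_filter, rarefy,
                         remove_organelles, remove_singletons)
from .sparcc import CorrelationResult, spearman_correlation
from .synth import CohortConfig, generate_cohort

log = logging.getLogger(__name__)

#: covariates in the order of clinical importance used by the stepwise model
COVARIATE_ORDER = ["gender", "gestational_age", "birth_weight", "delivery_mode",
                   "antibiotic_type", "ACS", "MSF", "EUGR",
                   "intrauterine_distress", "length_of_stay"]


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run; defaults are the study's settings.

    Either give the three input table paths or leave them ``None`` to
    simulate a synthetic cohort from ``cohort``.
    """

    counts_path: str | None = None
    taxonomy_path: str | None = None
    metadata_path: str | None = None
    cohort: CohortConfig = field(default_factory=CohortConfig)
    outdir: str = "results/pipeline"
    seed: int = 0
    rarefaction_depth: int = defaults.RAREFACTION_DEPTH
    min_rel_total: float = defaults.MIN_REL_TOTAL
    min_prev_frac: float = defaults.MIN_PREV_FRAC
    threshold: float = defaults.CORRELATION_THRESHOLD
    alpha: float = defaults.EDGE_ALPHA
    n_outer: int = defaults.SPARCC_OUTER_ITERATIONS
    n_resamples: int = defaults.SPARCC_RESAMPLES
    resampling_mode: str = "permutation"
    downsample_to: int | None = None  # None -> smallest group
    sensitivity_thresholds: tuple = defaults.SENSITIVITY_THRESHOLDS
    keystone_weights: tuple = defaults.KEYSTONE_WEIGHTS
    diversity_permutations: int = defaults.DIVERSITY_PERMUTATIONS
    # between-group comparison: 100 reduced-fidelity permutations by default
    # (the library function defaults to 1,000; see docs/methods.md)
    compare_permutations: int = 100
    # cheap O(E) metrics by default so the permutation null stays fast;
    # any TopologyReport field may be listed
    compare_metrics: tuple = ("edges", "density", "average_degree")
    path_mode: str = "unweighted"
    network_predictor_mode: str = "leave_one_out"  # or "group_assigned"
    max_keystone_models: int = 4

    def to_jsonable(self) -> dict:
        d = asdict(self)
        d["cohort"] = asdict(self.cohort)
        d.pop("outdir")  # output location is not a scientific parameter
        return d


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed derived from the config seed."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


def _load_or_simulate(config: PipelineConfig, outdir: Path, manifest: dict):
    if config.counts_path:
        table = read_count_table(config.counts_path)
        taxonomy = read_taxonomy(config.taxonomy_path)
        metadata = read_metadata(config.metadata_path)
        manifest["stages"]["input"] = {"source": "files",
                                       "shape": list(table.counts.shape)}
    else:
        cohort = CohortConfig(**{**asdict(config.cohort),
                                 "seed": stage_seed(config.seed, "simulate")})
        table, taxonomy, metadata = generate_cohort(cohort)
        write_count_table(table, outdir / "counts.tsv")
        write_taxonomy(taxonomy, outdir / "taxonomy.tsv")
        write_metadata(metadata, outdir / "metadata.tsv")
        manifest["stages"]["simulate"] = {"source": "synthetic",
                                          "shape": list(table.counts.shape),
                                          "seed": cohort.seed}
    return table, taxonomy, metadata


def _preprocess(config, table, taxonomy, outdir, manifest):
    n0 = table.n_taxa
    table = remove_singletons(table)
    n1 = table.n_taxa
    table = remove_organelles(table, taxonomy)
    n2 = table.n_taxa
    write_count_table(table, outdir / "counts_clean.tsv")
    manifest["stages"]["preprocess"] = {
        "taxa_in": n0, "after_singletons": n1, "after_organelles": n2}
    log.info("preprocess: %d -> %d taxa (singletons), -> %d (organelles)",
             n0, n1, n2)
    return table


def _diversity(config, table, metadata, outdir, manifest):
    seed = stage_seed(config.seed, "diversity")
    rare = rarefy(table, config.rarefaction_depth, seed)
    alpha = alpha_diversity(rare)
    alpha.to_csv(outdir / "alpha_diversity.tsv", sep="\t")
    dm = bray_curtis(rare)
    groups = metadata.groups().loc[list(dm.ids)]
    n_perm = config.diversity_permutations
    r_anosim, p_anosim = anosim(dm, groups, n_perm=n_perm, seed=seed)
    f_perm, r2_perm, p_perm = permanova(dm, groups, n_perm=n_perm, seed=seed + 1)
    f_disp, p_disp = permdisp(dm, groups, n_perm=n_perm, seed=seed + 2)
    stats = pd.DataFrame([
        {"statistic": "anosim_R", "value": r_anosim, "p": p_anosim},
        {"statistic": "permanova_pseudo_F", "value": f_perm, "p": p_perm},
        {"statistic": "permanova_R2", "value": r2_perm, "p": float("nan")},
        {"statistic": "permdisp_F", "value": f_disp, "p": p_disp},
    ])
    stats["n_perm"] = n_perm
    stats["seed"] = seed
    stats.to_csv(outdir / "beta_stats.tsv", sep="\t", index=False)
    anosim_pairwise(dm, groups, n_perm=n_perm, seed=seed + 3).to_csv(
        outdir / "anosim_pairwise.tsv", sep="\t", index=False)
    manifest["stages"]["diversity"] = {
        "rarefied_samples": rare.n_samples, "depth": config.rarefaction_depth,
        "anosim_R": r_anosim, "permanova_R2": r2_perm, "seed": seed}


def _network_stage(config, table, metadata, outdir, manifest):
    seed = stage_seed(config.seed, "network")
    filtered = abundance_prevalence_filter(table, config.min_rel_total,
                                           config.min_prev_frac)
    write_count_table(filtered, outdir / "counts_filtered.tsv")
    groups = downsample_groups(filtered, metadata,
                               target_n=config.downsample_to, seed=seed)
    params = PipelineParams(n_outer=config.n_outer,
                            n_resamples=config.n_resamples,
                            threshold=config.threshold, alpha=config.alpha,
                            path_mode=config.path_mode)
    netdir = outdir / "network"
    netdir.mkdir(exist_ok=True)
    networks, topo_cols, keystone_rows, sens_rows = {}, {}, [], []
    agreement_rows = []
    from .sparcc import edge_significance, sparcc_correlation
    for k, (g, sub) in enumerate(groups.items()):
        gseed = seed + 10 * (k + 1)
        r = sparcc_correlation(sub, n_outer=config.n_outer, seed=gseed)
        p = edge_significance(sub, r, n_resamples=config.n_resamples,
                              mode=config.resampling_mode, seed=gseed + 1)
        cor = CorrelationResult(list(sub.taxon_ids), r, p,
                                n_outer_iterations=config.n_outer,
                                n_resamples=config.n_resamples,
                                resampling_mode=config.resampling_mode)
        net = build_network(cor, threshold=config.threshold, alpha=config.alpha,
                            abundance=mean_relative_abundance(sub), group=g)
        networks[g] = (net, sub)
        write_network(net, netdir / f"{g}.graphml", "graphml")
        write_network(net, netdir / f"{g}_edges.tsv", "edge_list_tsv")
        topo_cols[g] = topology(net, mode=config.path_mode, seed=gseed).to_series()
        scores = keystone_scores(net, config.keystone_weights)
        scores["group"] = g
        keystone_rows.append(scores)
        # threshold sensitivity reuses the same correlation estimate
        sens = threshold_sensitivity(cor, config.sensitivity_thresholds,
                                     alpha=config.alpha, mode=config.path_mode,
                                     weights=config.keystone_weights, seed=gseed)
        s = sens["topology"].copy()
        s.insert(0, "group", g)
        sens_rows.append(s)
        # SparCC vs Spearman method agreement
        spear = spearman_correlation(sub, n_resamples=config.n_resamples,
                                     seed=gseed + 2)
        agree = method_agreement(cor, spear, threshold=config.threshold,
                                 alpha=config.alpha)
        agree["group"] = g
        agreement_rows.append(agree)

    pd.DataFrame(topo_cols).to_csv(outdir / "topology.tsv", sep="\t")
    pd.concat(keystone_rows).to_csv(outdir / "keystones.tsv", sep="\t")
    pd.concat(sens_rows).to_csv(outdir / "threshold_sensitivity.tsv", sep="\t")
    pd.DataFrame(agreement_rows).to_csv(outdir / "method_agreement.tsv",
                                        sep="\t", index=False)
    manifest["stages"]["network"] = {
        "taxa_after_filter": filtered.n_taxa,
        "downsampled_to": {g: sub.n_samples for g, (_, sub) in networks.items()},
        "nodes": {g: net.n_nodes for g, (net, _) in networks.items()},
        "edges": {g: net.n_edges for g, (net, _) in networks.items()},
        "seed": seed}
    return filtered, networks


def _compare_stage(config, networks, outdir, manifest):
    seed = stage_seed(config.seed, "compare")
    params = PipelineParams(n_outer=config.n_outer,
                            n_resamples=config.n_resamples,
                            threshold=config.threshold, alpha=config.alpha,
                            path_mode=config.path_mode)
    # permutation nulls re-run the pipeline; keep them threshold-only at
    # reduced SparCC fidelity (see docs/methods.md)
    null_params = PipelineParams(n_outer=1, n_resamples=0, significance=False,
                                 threshold=config.threshold, alpha=config.alpha,
                                 path_mode=config.path_mode)
    present = [g for g in GROUP_LEVELS if g in networks]
    rows, dis = [], pd.DataFrame(np.nan, index=present, columns=present)
    for i, a in enumerate(present):
        dis.loc[a, a] = 0.0
        for b in present[i + 1:]:
            net_a, tab_a = networks[a]
            net_b, tab_b = networks[b]
            res = permute_compare(tab_a, tab_b, params=params,
                                  metrics=config.compare_metrics,
                                  n_perm=config.compare_permutations,
                                  seed=seed + 7 * len(rows),
                                  null_params=null_params,
                                  observed=(net_a, net_b))
            frame = res.to_frame()
            frame.insert(0, "pair", f"{a}_vs_{b}")
            rows.append(frame)
            d = (network_dissimilarity(net_a, net_b)
                 if net_a.n_nodes and net_b.n_nodes else float("nan"))
            dis.loc[a, b] = dis.loc[b, a] = d
    cmpdir = outdir / "compare"
    cmpdir.mkdir(exist_ok=True)
    pd.concat(rows).to_csv(cmpdir / "pairwise.tsv", sep="\t")
    dis.to_csv(cmpdir / "dissimilarity.tsv", sep="\t")
    manifest["stages"]["compare"] = {
        "pairs": len(rows), "n_perm": config.compare_permutations,
        "seed": seed}


def _per_sample_network_metric(config, filtered, metadata, metric="density"):
    """Per-sample predictor from group networks.

    Networks are always built on equal-sized sample subsets (the smallest
    group's size governs, as in the group down-sampling normalisation) so the
    predictor is not confounded by the strong dependence of spurious edge
    counts on n.  ``group_assigned``: every sample inherits the metric of one
    fixed equal-sized network of its group.  ``leave_one_out``: each sample
    gets the metric of an equal-sized network drawn from its group excluding
    that sample (reduced fidelity, threshold-only).
    """
    seed = stage_seed(config.seed, "model_loo")
    values = pd.Series(np.nan, index=filtered.sample_ids)
    loo_params = PipelineParams(n_outer=2, n_resamples=0, significance=False,
                                threshold=config.threshold, alpha=config.alpha,
                                path_mode=config.path_mode)
    members_of = {g: [s for s in metadata.samples_in_group(g)
                      if s in filtered.sample_ids] for g in GROUP_LEVELS}
    sizes = [len(m) for m in members_of.values() if len(m) >= 3]
    if not sizes:
        return values
    target = config.downsample_to or min(sizes)
    rng = np.random.default_rng(seed)
    for g in GROUP_LEVELS:
        members = members_of[g]
        if len(members) < 3:
            continue
        if config.network_predictor_mode == "group_assigned":
            chosen = sorted(rng.choice(members, size=min(target, len(members)),
                                       replace=False))
            net = network_from_table(filtered.select_samples(chosen),
                                     loo_params, seed=seed)
            val = topology(net, mode=config.path_mode,
                           metrics={metric}).to_series()[metric]
            values.loc[members] = val
        else:
            m = min(target - 1, len(members) - 1)
            for s in members:
                pool = [x for x in members if x != s]
                chosen = sorted(rng.choice(pool, size=m, replace=False))
                net = network_from_table(filtered.select_samples(chosen),
                                         loo_params, seed=seed)
                values.loc[s] = topology(net, mode=config.path_mode,
                                         metrics={metric}).to_series()[metric]
    return values


def _model_stage(config, filtered, metadata, networks, outdir, manifest):
    mdir = outdir / "model"
    mdir.mkdir(exist_ok=True)
    meta = metadata.table.loc[[s for s in filtered.sample_ids
                               if s in metadata.table.index]]
    y = meta["group"]
    covars = design_matrix(meta, [c for c in COVARIATE_ORDER
                                  if c in meta.columns])

    # topology-metric model: per-sample density predictor
    density = _per_sample_network_metric(config, filtered, metadata, "density")
    density = density.loc[meta.index]
    records = {}
    data = covars.copy()
    try:
        data["density"] = standardize(density.to_numpy())
        fit = forward_stepwise(y, data, ["density"], list(covars.columns))
        records["density"] = fit
    except FitError as exc:
        log.warning("density model failed: %s", exc)

    # keystone-abundance models: one per keystone ASV (capped)
    keystones = []
    for g, (net, _) in networks.items():
        scores = keystone_scores(net, config.keystone_weights)
        if len(scores):
            flagged = scores[scores["keystone_flag"]]
            keystones.extend(
                flagged.sort_values("keystone_composite", ascending=False).index)
    seen = []
    for t in keystones:
        if t not in seen:
            seen.append(t)
    fractions = filtered.counts / filtered.depths[:, None].astype(float)
    frac = pd.DataFrame(fractions, index=filtered.sample_ids,
                        columns=filtered.taxon_ids).loc[meta.index]
    for taxon in seen[:config.max_keystone_models]:
        try:
            data = covars.copy()
            data[taxon] = standardize(frac[taxon].to_numpy(), log_transform=True)
            records[taxon] = forward_stepwise(y, data, [taxon],
                                              list(covars.columns))
        except FitError as exc:
            log.warning("keystone model for %s failed: %s", taxon, exc)

    rows = []
    for base, fit in records.items():
        summary = fit.summary()
        summary.insert(0, "model", base)
        summary["converged"] = fit.converged
        summary["dropped"] = "; ".join(f"{c} ({r})" for c, r in fit.dropped)
        rows.append(summary)
    if rows:
        pd.concat(rows).to_csv(mdir / "coefficients.tsv", sep="\t")
    manifest["stages"]["model"] = {
        "models": list(records),
        "keystones": seen[:config.max_keystone_models],
        "predictor_mode": config.network_predictor_mode}


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage and return the output directory.

    Writes a ``manifest.json`` (config, package version, per-stage shapes and
    sub-seeds, parameter hash); a rerun with an identical config produces a
    bit-identical manifest and artifacts.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    from . import __version__
    config_json = json.dumps(config.to_jsonable(), sort_keys=True)
    manifest = {"package": "bpdnet", "version": __version__,
                "seed": config.seed,
                "parameter_hash": hashlib.sha256(config_json.encode()).hexdigest(),
                "config": config.to_jsonable(), "stages": {}}
    try:
        table, taxonomy, metadata = _load_or_simulate(config, outdir, manifest)
        table = _preprocess(config, table, taxonomy, outdir, manifest)
        _diversity(config, table, metadata, outdir, manifest)
        filtered, networks = _network_stage(config, table, metadata, outdir,
                                            manifest)
        _compare_stage(config, networks, outdir, manifest)
        _model_stage(config, filtered, metadata, networks, outdir, manifest)
    except Exception as exc:
        stage = list(manifest["stages"])[-1] if manifest["stages"] else "input"
        raise RuntimeError(f"pipeline failed after stage {stage!r}: {exc}") from exc
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return outdir
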