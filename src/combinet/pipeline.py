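"""End-to-end pipeline runner: responses → networks → clusters → design → synergy.

One nested config dict (file + CLI overrides) drives every stage; each stage
writes its artefacts immediately, so a failing stage aborts with its name
while earlier artefacts survive.  All randomness is funnelled through the
single ``seed`` entry, recorded with the config hash in ``manifest.json`` —
a rerun of the same config is byte-identical for the deterministic stages.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import io, measures, synthetic
from .design import compare_groups
from .homogeneity import (
    compare_distributions,
    dice_similarity,
    mutation_profile,
    random_grouping_null,
    within_cluster_pairs,
)
from .model import BipartiteScreenModel
from .synergy import score_combination

DEFAULT_CONFIG = {
    "seed": None,
    "out_dir": "combinet_out",
    "synthetic": None,          # CohortSpec overrides, or None to read responses_csv
    "responses_csv": None,
    "weight_transform": "reciprocal",
    "algorithms": ["fastgreedy"],
    "fit_measures": False,      # 4PL fits for the per-pair measure table
    "k": 5,
    "n_perm": 200,
    "homogeneity_metrics": ["dice"],
    "synergy_models": ["bliss", "hsa"],
    "run_homogeneity": True,
    "run_synergy": True,
}


def _validated(config: dict) -> dict:
    cfg = {**DEFAULT_CONFIG, **(config or {})}
    stochastic = cfg["run_homogeneity"] or cfg["run_synergy"] or cfg["synthetic"] is not None \
        or any(a in ("infomap", "spinglass", "leiden") for a in cfg["algorithms"])
    if stochastic and cfg["seed"] is None:
        raise ValueError("config must set a seed for stochastic stages")
    if cfg["synthetic"] is None and cfg["responses_csv"] is None:
        raise ValueError("config needs either 'synthetic' spec or 'responses_csv'")
    if cfg["responses_csv"] is not None and not Path(cfg["responses_csv"]).exists():
        raise ValueError(f"responses_csv not found: {cfg['responses_csv']}")
    return cfg


def run_pipeline(config: dict) -> dict:
    """Execute all stages; returns a dict of in-memory artefacts.

    Artefacts written: measures.csv, incidence.csv, bipartite.graphml,
    dsn/psn GraphML + edge-list TSV, clusters.csv, homogeneity_<metric>.csv,
    design.csv, synergy.csv and manifest.json under ``out_dir``.
    """
    cfg = _validated(config)
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    artefacts: dict = {}
    stage = "setup"
    try:
        stage = "responses"
        spec = None
        if cfg["synthetic"] is not None:
            spec = synthetic.CohortSpec(**{**cfg["synthetic"], "seed": cfg["seed"]})
            responses, truth = synthetic.generate_responses(spec)
            responses.to_csv(out / "responses.csv", index=False)
            pd.concat([
                truth["drug_clusters"].rename("cluster").rename_axis("id").reset_index().assign(side="drugs"),
                truth["sample_clusters"].rename("cluster").rename_axis("id").reset_index().assign(side="samples"),
            ]).to_csv(out / "truth.csv", index=False)
            artefacts["truth"] = truth
        else:
            responses = io.read_response_csv(cfg["responses_csv"])
        artefacts["responses"] = responses

        stage = "measures"
        series = measures.series_from_long(responses)
        mtable = measures.measures_table(series, with_fit=cfg["fit_measures"])
        io.write_measures_csv(mtable, out / "measures.csv")
        artefacts["measures"] = mtable

        stage = "network"
        model = BipartiteScreenModel(responses, weight_transform=cfg["weight_transform"])
        results = model.fit(algorithms=tuple(cfg["algorithms"]), seed=cfg["seed"])
        io.write_incidence_csv(results.incidence, out / "incidence.csv")
        io.write_graphml(results.bipartite, out / "bipartite.graphml")
        for name, net in (("dsn", results.dsn), ("psn", results.psn)):
            io.write_graphml(net.graph, out / f"{name}.graphml")
            io.write_edgelist_tsv(net, out / f"{name}_edges.tsv")
        artefacts["results"] = results

        stage = "community"
        io.write_partition_csv(
            {"drugs": results.drug_partition, "samples": results.sample_partition},
            out / "clusters.csv",
        )

        if cfg["run_homogeneity"] and spec is not None:
            stage = "homogeneity"
            ann = synthetic.generate_annotations(spec)
            if "dice" in cfg["homogeneity_metrics"]:
                fps = ann.fingerprints
                clusters = results.drug_clusters
                pairs = within_cluster_pairs(clusters)
                within = {
                    c: np.array([dice_similarity(fps[a], fps[b]) for a, b in ps])
                    for c, ps in pairs.items() if len(ps) >= 3
                }
                null = random_grouping_null(
                    list(fps), lambda a, b: dice_similarity(fps[a], fps[b]),
                    [len(m) for m in clusters.values()],
                    n_perm=cfg["n_perm"], seed=cfg["seed"], max_values=10000,
                )
                report = compare_distributions(within, null, metric="dice")
                report.summary().assign(
                    kruskal_p_adjusted=report.kruskal_p_adjusted
                ).to_csv(out / "homogeneity_dice.csv", index=False)
                artefacts["homogeneity_dice"] = report
            prof = mutation_profile(ann.mutations, results.sample_partition.assignment)
            prof.to_csv(out / "mutation_profile.csv", index=False)
            artefacts["mutation_profile"] = prof

        stage = "design"
        design = results.design(k=cfg["k"])
        design.to_frame().to_csv(out / "design.csv", index=False)
        artefacts["design"] = design

        if cfg["run_synergy"] and spec is not None:
            stage = "synergy"
            matrices, combo_truth = synthetic.generate_combinations(
                spec, design, sample_ids=spec.sample_ids[:1],
            )
            summaries = [score_combination(m, models=tuple(cfg["synergy_models"])) for m in matrices]
            io.write_synergy_csv(summaries, out / "synergy.csv")
            score_rows = pd.DataFrame([
                {"drug_a": s.drug_a, "drug_b": s.drug_b, **s.means} for s in summaries
            ])
            artefacts["synergy"] = score_rows
            artefacts["synergy_comparison"] = compare_groups(
                score_rows, design, test="t", alternative="greater",
            )
            artefacts["synergy_comparison"].to_csv(out / "synergy_comparison.csv", index=False)

        stage = "manifest"
        inputs = [cfg["responses_csv"]] if cfg["responses_csv"] else []
        io.write_manifest(out / "manifest.json", cfg, cfg["seed"], input_paths=inputs)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return artefacts
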