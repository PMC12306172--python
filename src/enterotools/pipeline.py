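"""End-to-end orchestration: simulate/load -> diversity -> enterotype ->
association -> classifier (-> pathway differential testing), with a run
manifest recording seeds, parameters and input digests.

A single global seed fans out to per-stage sub-seeds by a fixed counter
offset, so any stage can be reproduced in isolation. All stage results are
computed in memory first and written together, so a failing stage leaves
no partial output directory.
"""

from __future__ import annotations

import hashlib
import json
import sys
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import association, classifier, diffpath, diversity, enterotype, io, simulate

STAGE_OFFSETS = {"simulate": 0, "rarefy": 1, "classify": 2, "oversample": 3}


def stage_seed(seed: int, stage: str) -> int:
    return (int(seed) + STAGE_OFFSETS[stage]) % (2**31 - 1)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def segatella_positive(labels: np.ndarray, drivers: dict[int, str]) -> np.ndarray:
    """Binary outcome with the Segatella-dominated cluster coded 1.

    Falls back to cluster index 1 when no cluster is driven by Segatella
    (e.g. non-default synthetic genus names).
    """
    seg = [c for c, g in drivers.items() if g == simulate.SEGATELLA]
    positive = seg[0] if seg else 1
    return (np.asarray(labels) == positive).astype(int)


def run_all(
    out_dir: str | Path,
    table_path: str | Path | None = None,
    metadata_path: str | Path | None = None,
    pathway_path: str | Path | None = None,
    simulate_config: simulate.GeneratorConfig | None = None,
    seed: int = 0,
    pseudocount: float = enterotype.DEFAULT_PSEUDOCOUNT,
    k_max: int = 10,
    covariates: tuple[str, ...] = ("sex_role", "age", "bmi"),
    tune: bool = False,
    adjust: str = "none",
) -> dict:
    """Run every pipeline stage and write outputs plus a manifest.

    Either ``simulate_config`` (synthetic run) or both ``table_path`` and
    ``metadata_path`` must be given. Returns the manifest dict.
    """
    out_dir = Path(out_dir)
    t0 = time.time()
    manifest: dict = {
        "command": " ".join(sys.argv),
        "seed": int(seed),
        "stage_seeds": {s: stage_seed(seed, s) for s in STAGE_OFFSETS},
        "inputs": {},
        "outputs": {},
        "parameters": {
            "pseudocount": pseudocount, "k_max": k_max,
            "covariates": list(covariates), "tune": tune, "adjust": adjust,
        },
    }

    # ---- pre-flight & load ------------------------------------------------
    if simulate_config is not None:
        simulate_config.seed = stage_seed(seed, "simulate")
        dataset = simulate.generate(simulate_config)
        table, metadata = dataset.table, dataset.metadata
        truth = dataset.true_labels
        manifest["inputs"]["simulated"] = simulate.config_to_dict(simulate_config)
    else:
        if table_path is None or metadata_path is None:
            raise FileNotFoundError(
                "need --input and --metadata (or a simulation config)"
            )
        for p in (table_path, metadata_path):
            if not Path(p).exists():
                raise FileNotFoundError(f"missing input file: {p}")
        table = io.read_abundance_table(table_path)
        if table.lineages is not None:
            table = io.aggregate_to_genus(table)
        metadata = io.read_metadata(metadata_path)
        truth = None
        manifest["inputs"]["table"] = _digest(Path(table_path))
        manifest["inputs"]["metadata"] = _digest(Path(metadata_path))
    pathway_table = None
    if pathway_path is not None:
        if not Path(pathway_path).exists():
            raise FileNotFoundError(f"missing pathway table: {pathway_path}")
        pathway_table = diffpath.read_pathway_table(pathway_path)
        manifest["inputs"]["pathways"] = _digest(Path(pathway_path))
    metadata = io.align_metadata(table, metadata)
    profiles = io.to_relative(table)

    # ---- stages (in memory) ----------------------------------------------
    def _stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc

    def _diversity():
        rarefied = diversity.rarefy(table, seed=stage_seed(seed, "rarefy"))
        return diversity.alpha_diversity(rarefied)

    div = _stage("diversity", _diversity)

    def _enterotype():
        D = enterotype.jsd_matrix(profiles, pseudocount)
        res = enterotype.select_k(D, k_max=k_max)
        enterotype.annotate_drivers(res, profiles)
        coords, evals = enterotype.pcoa(D, 2)
        return D, res, coords

    D, etype, coords = _stage("enterotype", _enterotype)
    labels = pd.Series(etype.labels, index=table.sample_ids, name="cluster")
    labels.index.name = "sample_id"
    alpha_cmp = (
        diversity.compare_alpha(div, labels) if etype.k == 2 else None
    )

    def _associate():
        y = segatella_positive(etype.labels, etype.driver_genus)
        X, names = association.build_design(metadata, covariates)
        fit = association.fit_logistic(y, X, names)
        conting = association.cluster_contingency(metadata, labels)
        return fit, conting

    fit, conting = _stage("association", _associate)

    def _classify():
        return classifier.run_classifier(
            profiles, metadata["sex_role"], etype.labels, tune=tune,
            seed=stage_seed(seed, "classify"),
        )

    report = _stage("classifier", _classify)

    path_results = None
    if pathway_table is not None:
        path_results = _stage(
            "diffpath",
            lambda: diffpath.compare_pathways(pathway_table, labels, adjust=adjust),
        )

    # ---- write ------------------------------------------------------------
    out_dir.mkdir(parents=True, exist_ok=True)

    def _save(name, writer):
        path = out_dir / name
        writer(path)
        manifest["outputs"][name.split(".")[0]] = str(path)

    _save("diversity.csv", lambda p: div.to_csv(p))
    if alpha_cmp is not None:
        _save("alpha_comparison.csv", lambda p: alpha_cmp.to_csv(p, index=False))
    _save("enterotype_labels.csv", lambda p: labels.to_frame().to_csv(p))
    _save("ch_by_k.csv", lambda p: pd.Series(etype.ch_by_k, name="ch_index")
          .rename_axis("k").to_csv(p))
    _save("medoids.txt", lambda p: p.write_text("\n".join(etype.medoid_ids) + "\n"))
    _save("pcoa.csv", lambda p: pd.DataFrame(
        coords, index=table.sample_ids,
        columns=[f"PCo{i+1}" for i in range(coords.shape[1])])
        .rename_axis("sample_id").to_csv(p))
    _save("or_table.csv", lambda p: association.or_table(fit).to_csv(p, index=False)
          if fit.converged else p.write_text("unconverged fit (separation)\n"))
    _save("contingency.csv", lambda p: pd.DataFrame(
        [{"variable": c.variable, "method": c.method,
          "statistic": c.statistic, "p_value": c.p_value} for c in conting]
    ).to_csv(p, index=False))
    _save("classifier_report.json", lambda p: p.write_text(
        json.dumps(report.to_dict(), indent=2, default=float) + "\n"))
    if truth is not None:
        _save("truth.csv", lambda p: pd.Series(
            truth, index=table.sample_ids, name="true_cluster")
            .rename_axis("sample_id").to_csv(p))
    if path_results is not None:
        _save("diffpath.csv", lambda p: path_results[0].to_csv(p, index=False))
        manifest["diffpath"] = {
            "n_significant": path_results[1], "percent": path_results[2],
        }

    manifest["selected_k"] = etype.k
    manifest["cluster_sizes"] = np.bincount(etype.labels).tolist()
    manifest["driver_genera"] = {str(k): v for k, v in etype.driver_genus.items()}
    manifest["macro_auc"] = report.macro_auc
    manifest["runtime_s"] = round(time.time() - t0, 2)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
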