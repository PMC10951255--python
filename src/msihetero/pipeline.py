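"""End-to-end pipeline orchestration with a reproducibility manifest.

Stages: simulate -> preprocess -> segment -> diversity -> survival grid ->
differential -> annotate/enrich/network. Outputs are plain TSV/JSON; the
manifest records the config snapshot, seeds, package version and a SHA-256
hash per output file. Stages whose recorded input hashes are unchanged are
skipped on re-runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from typing import Any

import numpy as np
import pandas as pd

import msihetero
from msihetero import io
from msihetero.annotation import (
    annotate_peaks,
    correlation_network,
    enrich_pathways,
    load_demo_mass_table,
    load_demo_pathways,
)
from msihetero.differential import differential_metabolites, direction_counts
from msihetero.heterogeneity import optimize_diversity_cutoff, simpson_index
from msihetero.preprocessing import preprocess_cohort
from msihetero.segmentation import compositions, segment_cohort
from msihetero.survival import aic_grid, km_estimate, pairwise_subpop_survival, presence_matrix
from msihetero.synthetic import CohortConfig, generate_cohort

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict[str, Any] = {
    "cohort": {},  # CohortConfig overrides
    "n_peaks": 150,
    "denoise_window": 3,
    "k_min": 2,
    "k_max": 10,
    "k_report": None,  # default: AIC-optimal K
    "threshold_min": 0.04,
    "threshold_max": 0.40,
    "threshold_step": 0.02,
    "n_init": 10,
    "tol_ppm": 4.0,
    "seed": 0,
}


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def load_config(path: str | None) -> dict[str, Any]:
    cfg = dict(DEFAULT_CONFIG)
    if path is not None:
        import yaml

        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        unknown = set(user) - set(cfg)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg.update(user)
    return cfg


def run_pipeline(
    config: dict[str, Any] | str | None = None,
    out_dir: str = "msihetero_run",
    seed: int | None = None,
) -> dict[str, Any]:
    """Run the full synthetic-cohort pipeline; returns the manifest dict."""
    cfg = load_config(config) if (config is None or isinstance(config, str)) else {
        **DEFAULT_CONFIG,
        **config,
    }
    if seed is not None:
        cfg["seed"] = seed
    # JSON round-trip so the in-memory config compares equal to the manifest
    # snapshot on re-runs (tuples become lists exactly once)
    cfg = json.loads(json.dumps(cfg))
    os.makedirs(out_dir, exist_ok=True)
    manifest_path = os.path.join(out_dir, "manifest.json")
    previous = {}
    if os.path.exists(manifest_path):
        with open(manifest_path) as fh:
            previous = json.load(fh)
    manifest: dict[str, Any] = {
        "config": cfg,
        "version": msihetero.__version__,
        "stages": {},
        "warnings": [
            "diversity-cutoff p-value is selection-biased (cutoff optimised to minimise p)",
            "pixel-wise differential tests are pseudoreplicated across pixels of a patient",
            "survival p-values are not adjusted for multiplicity",
        ],
    }

    def record(stage: str, outputs: list[str]) -> None:
        manifest["stages"][stage] = {os.path.basename(p): _sha256(p) for p in outputs}

    def cached(stage: str, outputs: list[str]) -> bool:
        if previous.get("config") != cfg:
            return False
        prev = previous.get("stages", {}).get(stage)
        if not prev:
            return False
        ok = all(
            os.path.exists(p) and _sha256(p) == prev.get(os.path.basename(p))
            for p in outputs
        )
        if ok:
            manifest["stages"][stage] = prev
            logger.info("stage %s: cached, skipping", stage)
        return ok

    def path(name: str) -> str:
        return os.path.join(out_dir, name)

    # ---- simulate -------------------------------------------------------
    ccfg = CohortConfig(**cfg["cohort"], seed=cfg["seed"]) if "seed" not in cfg[
        "cohort"
    ] else CohortConfig(**cfg["cohort"])
    sim_out = [path("pixels.tsv"), path("meta.tsv"), path("truth_labels.tsv"), path("truth_composition.tsv")]
    try:
        if not cached("simulate", sim_out):
            cohort = generate_cohort(ccfg)
            io.write_datacubes_tsv(cohort.datacubes, sim_out[0])
            io.write_survival_tsv(cohort.survival, sim_out[1])
            io.write_truth_tsv(cohort, sim_out[2], sim_out[3])
            record("simulate", sim_out)
    except Exception as exc:  # noqa: BLE001
        raise StageError("simulate", exc) from exc

    cubes = io.read_datacubes_tsv(sim_out[0])
    surv = io.read_survival_tsv(sim_out[1], response_cutoff=ccfg.response_cutoff)

    # ---- preprocess -----------------------------------------------------
    pre_out = [path("cube.tsv"), path("peaks.tsv")]
    try:
        if not cached("preprocess", pre_out):
            n_peaks = min(cfg["n_peaks"], cubes[0].n_channels)
            processed, peaks = preprocess_cohort(
                cubes, n_peaks=n_peaks, denoise_window=cfg["denoise_window"]
            )
            io.write_datacubes_tsv(processed, pre_out[0])
            pd.DataFrame({"mz": peaks.mz, "mean_intensity": peaks.provenance}).to_csv(
                pre_out[1], sep="\t", index=False
            )
            record("preprocess", pre_out)
    except Exception as exc:  # noqa: BLE001
        raise StageError("preprocess", exc) from exc
    processed = io.read_datacubes_tsv(pre_out[0])

    # ---- segment --------------------------------------------------------
    k_range = range(cfg["k_min"], cfg["k_max"] + 1)
    seg_out = [path("labels.tsv"), path("segmentation_summary.tsv")]
    try:
        if not cached("segment", seg_out):
            segs = segment_cohort(processed, k_range, seed=cfg["seed"], n_init=cfg["n_init"])
            io.write_labels_tsv(
                {k: s.labels for k, s in segs.items()},
                {c.patient_id: c.coords for c in processed},
                seg_out[0],
            )
            pd.DataFrame(
                [(k, s.inertia, s.n_dropped_pixels) for k, s in segs.items()],
                columns=["k", "inertia", "n_dropped_pixels"],
            ).to_csv(seg_out[1], sep="\t", index=False)
            record("segment", seg_out)
    except Exception as exc:  # noqa: BLE001
        raise StageError("segment", exc) from exc

    labels_by_k = {k: io.read_labels_tsv(seg_out[0], k) for k in k_range}

    def comps_for(k: int):
        from msihetero.types import ClusterComposition

        out = []
        for pid in sorted(labels_by_k[k]):
            lab = labels_by_k[k][pid]
            counts = np.bincount(lab - 1, minlength=k)
            out.append(ClusterComposition(pid, counts / lab.size, int(lab.size)))
        return out

    # ---- survival grid --------------------------------------------------
    surv_out = [path("aic_grid.tsv"), path("grid_optimum.json"), path("pairwise_wald.tsv"), path("km_curves.tsv")]
    try:
        if not cached("survival_grid", surv_out):
            thresholds = np.round(
                np.arange(cfg["threshold_min"], cfg["threshold_max"] + 1e-9, cfg["threshold_step"]),
                10,
            )
            grid = aic_grid({k: comps_for(k) for k in k_range}, surv, thresholds)
            grid.scaled().to_csv(surv_out[0], sep="\t", index=False)
            k_star, t_star = grid.optimum
            with open(surv_out[1], "w") as fh:
                json.dump(
                    {"k_star": k_star, "threshold_star": t_star, "null_aic": grid.null_aic,
                     **grid.metadata},
                    fh,
                    indent=2,
                )
            pm = presence_matrix(comps_for(k_star), t_star)
            pairwise_subpop_survival(pm, surv).to_csv(surv_out[2], sep="\t", index=False)
            km_rows = []
            by_id = {r.patient_id: r for r in surv}
            for cl in range(1, k_star + 1):
                members = [by_id[p] for p in pm.members(cl) if p in by_id]
                if not members:
                    continue
                km = km_estimate([m.time for m in members], [m.event for m in members])
                km.insert(0, "cluster", cl)
                km_rows.append(km)
            pd.concat(km_rows, ignore_index=True).to_csv(surv_out[3], sep="\t", index=False)
            record("survival_grid", surv_out)
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError("survival_grid", exc) from exc

    with open(surv_out[1]) as fh:
        optimum = json.load(fh)
    k_report = cfg["k_report"] or optimum["k_star"]

    # ---- diversity ------------------------------------------------------
    div_out = [path("diversity.tsv"), path("diversity_split.json")]
    try:
        if not cached("diversity", div_out):
            scores = [simpson_index(c) for c in comps_for(k_report)]
            split = optimize_diversity_cutoff(scores, surv)
            pd.DataFrame(
                {
                    "patient_id": [s.patient_id for s in scores],
                    "D": [s.D for s in scores],
                    "group": [split.groups[s.patient_id] for s in scores],
                }
            ).to_csv(div_out[0], sep="\t", index=False)
            with open(div_out[1], "w") as fh:
                json.dump(
                    {
                        "k_used": k_report,
                        "cutoff": split.cutoff,
                        "p_logrank": split.p_logrank,
                        "robustness": split.robustness,
                        **split.metadata,
                    },
                    fh,
                    indent=2,
                )
            record("diversity", div_out)
    except Exception as exc:  # noqa: BLE001
        raise StageError("diversity", exc) from exc

    # ---- differential ---------------------------------------------------
    diff_out = [path("differential.tsv"), path("differential_counts.tsv")]
    try:
        if not cached("differential", diff_out):
            pooled = np.vstack([c.intensities for c in sorted(processed, key=lambda c: c.patient_id)])
            lab = np.concatenate([labels_by_k[k_report][c.patient_id] for c in sorted(processed, key=lambda c: c.patient_id)])
            channels = processed[0].channels
            tables = []
            for sp in range(1, k_report + 1):
                try:
                    tables.append(
                        differential_metabolites(pooled, lab, sp, channels=channels)
                    )
                except ValueError as err:
                    logger.warning("subpopulation %d skipped: %s", sp, err)
            pd.concat(tables, ignore_index=True).to_csv(diff_out[0], sep="\t", index=False)
            direction_counts(tables).to_csv(diff_out[1], sep="\t", index=False)
            record("differential", diff_out)
    except Exception as exc:  # noqa: BLE001
        raise StageError("differential", exc) from exc

    # ---- annotation / enrichment / network ------------------------------
    ann_out = [path("annotation.tsv"), path("enrichment.tsv"), path("network_edges.tsv")]
    try:
        if not cached("annotation", ann_out):
            peaks_df = pd.read_csv(pre_out[1], sep="\t")
            masses = load_demo_mass_table()
            hits = annotate_peaks(peaks_df["mz"].to_numpy(), masses, tol_ppm=cfg["tol_ppm"])
            hits.to_csv(ann_out[0], sep="\t", index=False)
            diff = pd.read_csv(diff_out[0], sep="\t")
            mz_to_met = dict(zip(hits["observed_mz"], hits["metabolite"]))
            universe = set(hits["metabolite"])
            sig_mz = diff.loc[diff["direction"].isin(["increased", "decreased"]), "channel"]
            query = {mz_to_met[mz] for mz in sig_mz if mz in mz_to_met}
            if universe:
                enrich_pathways(query, universe, load_demo_pathways()).to_csv(
                    ann_out[1], sep="\t", index=False
                )
            else:
                pd.DataFrame().to_csv(ann_out[1], sep="\t", index=False)
            # network within the largest subpopulation over significant channels
            pooled = np.vstack([c.intensities for c in sorted(processed, key=lambda c: c.patient_id)])
            lab = np.concatenate([labels_by_k[k_report][c.patient_id] for c in sorted(processed, key=lambda c: c.patient_id)])
            channels = processed[0].channels
            sp = int(np.argmax(np.bincount(lab)[1:]) + 1)
            sub = diff[(diff["subpop"] == sp) & diff["direction"].isin(["increased", "decreased"])]
            sig_idx = [int(np.argmin(np.abs(channels - mz))) for mz in sub["channel"]]
            if len(sig_idx) >= 2:
                _, pairs = correlation_network(
                    pooled[lab == sp][:, sig_idx], channel_names=[channels[i] for i in sig_idx]
                )
                pairs.to_csv(ann_out[2], sep="\t", index=False)
            else:
                pd.DataFrame(columns=["a", "b", "rho", "p", "q"]).to_csv(
                    ann_out[2], sep="\t", index=False
                )
            record("annotation", ann_out)
    except Exception as exc:  # noqa: BLE001
        raise StageError("annotation", exc) from exc

    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
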