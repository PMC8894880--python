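"""End-to-end orchestration of the synthetic fixation-network analysis.

``run_all`` executes the full seeded pipeline on synthetic inputs:

1. cohort generation (planted directed MVAR networks per condition),
2. epoch capping (cohort-minimum plus margin, deterministic thinning),
3. per-participant MVAR + GPDC with surrogate thresholds,
4. group binomial test, condition contrast and node-degree nulls,
5. the source-mesh arm: planted-cluster contrast -> SCPT -> ROI definition
   -> ROI time-course extraction,
6. the behaviour arm: trial filtering, FWHM windows and the amplitude/RT
   correlation with FDR control.

Every knob is echoed into a run manifest and all randomness derives from one
integer seed, so identical configurations produce byte-identical outputs.
"""

from __future__ import annotations

import copy
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import epochs as ep
from . import io, netstats, rtcorr, scpt, synthgen
from . import mvar_gpdc as mg
from ._seeding import child_seed
from .errors import InvalidArgumentError
from .roitc import extract_roi_timecourses, prepare_roi

__all__ = ["DEFAULTS", "validate_config", "run_all", "analyze_cohort_connectivity"]

log = logging.getLogger(__name__)

#: Defaults pin the method's fixed analysis parameters (surrogate percentile
#: 99.99, binomial alpha 0.001, the band grid, the +10% epoch margin, the
#: five-vertex / 20 ms cluster rules, the 15% label rule, the 12.4 mm
#: neighborhood radius) and use desk-scale sizes for the compute-bound knobs
#: (permutation, surrogate and randomization counts).
DEFAULTS: dict = {
    "seed": 0,
    "conditions": ["FV", "VS"],
    "bands": {name: list(b) for name, b in mg.BANDS.items()},
    "cohort": {
        "n_participants": 12,
        "n_channels": 6,
        "order": 2,
        "edges": {
            "FV": [[0, 1, "alpha", 0.4], [2, 3, "beta2", 0.4]],
            "VS": [[0, 1, "alpha", 0.4], [0, 2, "gamma", 0.4], [0, 3, "gamma", 0.4]],
        },
        "edge_prevalence": 0.9,
        "noise_sd": 1.0,
        "n_epochs": 60,
        "epoch_length": 250,
        "sampling_rate": 250.0,
        "jitter_sd": 0.1,
    },
    "epochs": {"cap_margin": 0.1},
    "scpt": {
        "grid": [20, 20],
        "spacing_mm": 6.2,
        "n_runs": 30,
        "noise_sd": 1.0,
        "planted_amplitude": 6.0,
        "planted_vertices": 12,
        "planted_window_ms": [40, 160],
        "n_samples": 60,
        "sampling_rate": 250.0,
        "window_ms": [0, 200],
        "n_permutations": 500,
        "alpha": 0.05,
        "cluster_p": 0.05,
        "min_vertices": 5,
        "min_duration_ms": 20.0,
        "min_fraction": 0.15,
    },
    "roitc": {"peak_window_ms": [50, 180], "radius_mm": 12.4},
    "rtcorr": {
        "n_trials": 400,
        "r_target": -0.141,
        "rt_mean_ms": 489.0,
        "rt_sd_ms": 197.0,
        "invalid_fraction": 0.1,
        "max_rt_ms": 1000.0,
        "search_window_ms": [30, 200],
        "fdr_alpha": 0.05,
    },
    "mvar": {"p_max": 5, "difference": "auto", "whiteness_lags": 20},
    "netstats": {
        "n_surrogates": 100,
        "percentile": 99.99,
        "binomial_alpha": 0.001,
        "n_randomizations": 20000,
        "degree_percentile": 95.0,
    },
}

# (group, key) -> (low, high, high_inclusive)
_RANGE_CHECKS = {
    ("scpt", "alpha"): (0.0, 1.0, False),
    ("scpt", "cluster_p"): (0.0, 1.0, False),
    ("rtcorr", "fdr_alpha"): (0.0, 1.0, False),
    ("netstats", "binomial_alpha"): (0.0, 1.0, False),
    ("netstats", "percentile"): (0.0, 100.0, True),
    ("netstats", "degree_percentile"): (0.0, 100.0, True),
    ("cohort", "edge_prevalence"): (0.0, 1.0, True),
}


class RunConfig(dict):
    """Validated configuration; plain nested dict with attribute-free access."""


def _merge(defaults: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, value in override.items():
        where = f"{path}.{key}" if path else str(key)
        if key not in defaults:
            raise InvalidArgumentError(f"unknown config key: {where}")
        if key in ("edges", "bands"):
            # keyed by free names (band/condition): shallow-merge, no schema
            if not isinstance(value, dict):
                raise InvalidArgumentError(f"{where} must be a mapping")
            out[key] = {**copy.deepcopy(defaults[key]), **copy.deepcopy(value)}
        elif isinstance(defaults[key], dict):
            if not isinstance(value, dict):
                raise InvalidArgumentError(f"{where} must be a mapping")
            out[key] = _merge(defaults[key], value, where)
        else:
            out[key] = copy.deepcopy(value)
    return out


def validate_config(cfg: str | dict | None = None) -> RunConfig:
    """Parse and validate a config (YAML text, mapping, or None for defaults).

    Unknown keys, wrong types and out-of-range significance levels are
    rejected; everything omitted falls back to the defaults above.
    """
    if cfg is None:
        raw: dict = {}
    elif isinstance(cfg, str):
        raw = yaml.safe_load(cfg) or {}
        if not isinstance(raw, dict):
            raise InvalidArgumentError("config must parse to a mapping")
    elif isinstance(cfg, dict):
        raw = cfg
    else:
        raise InvalidArgumentError(f"unsupported config type {type(cfg)!r}")
    merged = _merge(DEFAULTS, raw)
    for (group, key), (lo, hi, hi_incl) in _RANGE_CHECKS.items():
        v = float(merged[group][key])
        ok = lo < v <= hi if hi_incl else lo < v < hi
        if not ok:
            raise InvalidArgumentError(f"{group}.{key} = {v} out of range ({lo}, {hi})")
    for name, band in merged["bands"].items():
        if len(band) != 2 or band[0] >= band[1]:
            raise InvalidArgumentError(f"band {name} must be [low, high] with low < high")
    if not isinstance(merged["seed"], int):
        raise InvalidArgumentError("seed must be an integer")
    return RunConfig(merged)


# ---------------------------------------------------------------------------
# connectivity arm
# ---------------------------------------------------------------------------

def analyze_cohort_connectivity(participants, *, order: int | None = None,
                                p_max: int = 5, n_surrogates: int = 200,
                                percentile: float = 99.99, alpha: float = 0.001,
                                bands=None, seed: int = 0, condition: str = "",
                                difference: str = "never",
                                keep_indices=None):
    """Per-participant MVAR + GPDC + surrogate thresholding + group binomial.

    ``participants`` is a list of EpochSet/ROIEpochSet-like objects (one per
    participant).  When ``order`` is None the Hannan-Quinn criterion picks a
    per-participant order up to ``p_max``.  ``difference`` ("auto" / "always"
    / "never") controls first-differencing; "auto" differences only when a
    majority of channels test non-stationary.  Returns (GroupNetwork,
    per-participant banded CausalityMatrix list, per-participant thresholds).
    """
    bands = dict(bands or mg.BANDS)
    masks, strengths, banded_list, thresholds_list = [], [], [], []
    for i, part in enumerate(participants):
        e = part
        if keep_indices is not None:
            from dataclasses import replace
            e = replace(part, data=part.data[keep_indices[i]])
        if difference != "never":
            diffed, rep = mg.difference_and_test(e)
            apply_diff = difference == "always" or \
                (difference == "auto"
                 and np.mean(rep.stationary_before) < 0.5)
            if apply_diff:
                e = diffed
        p = order if order is not None else mg.select_order(e, p_max)
        model = mg.fit_mvar(e, p)
        cm = mg.gpdc(model, participant=i, condition=condition)
        banded = mg.band_average(cm, bands)
        thr = netstats.surrogate_threshold(
            e, p, n_surrogates=n_surrogates, percentile=percentile, bands=bands,
            seed=child_seed(seed, f"surrogates-{condition}-{i}"))
        mask = netstats.threshold_matrix(banded, thr)
        masks.append(mask)
        strengths.append(np.where(mask, banded.values, 0.0))
        banded_list.append(banded)
        thresholds_list.append(thr)
    group = netstats.group_binomial(np.asarray(masks), alpha=alpha,
                                    strengths=np.asarray(strengths),
                                    bands=bands, condition=condition)
    return group, banded_list, thresholds_list


# ---------------------------------------------------------------------------
# full run
# ---------------------------------------------------------------------------

def run_all(cfg: RunConfig | dict | str | None = None,
            out_dir: str | Path | None = None) -> dict:
    """Execute every stage on synthetic inputs; return results and a manifest."""
    cfg = cfg if isinstance(cfg, RunConfig) else validate_config(cfg)
    seed = cfg["seed"]
    bands = {k: tuple(v) for k, v in cfg["bands"].items()}
    manifest: dict = {"config": copy.deepcopy(dict(cfg)), "stages": {}}
    results: dict = {"config": cfg}
    t_start = time.perf_counter()

    def stage(name):
        log.info("stage %s starting", name)
        manifest["stages"][name] = {"status": "running"}
        return time.perf_counter()

    def done(name, t0, **info):
        manifest["stages"][name] = {"status": "ok", **io._plain(info)}
        log.info("stage %s done in %.2f s", name, time.perf_counter() - t0)

    try:
        # --- cohorts ------------------------------------------------------
        t0 = stage("cohort")
        cc = cfg["cohort"]
        cohorts = {}
        for cond in cfg["conditions"]:
            edge_list = tuple(synthgen.Edge(int(s), int(t), b, float(w))
                              for s, t, b, w in cc["edges"].get(cond, []))
            spec = synthgen.CohortSpec(
                n_participants=cc["n_participants"], n_channels=cc["n_channels"],
                order=cc["order"], edge_list=edge_list,
                edge_prevalence=cc["edge_prevalence"], noise_sd=cc["noise_sd"],
                n_epochs_per_participant=cc["n_epochs"],
                epoch_length=cc["epoch_length"], sampling_rate=cc["sampling_rate"],
                seed=child_seed(seed, f"cohort-{cond}"), jitter_sd=cc["jitter_sd"])
            cohorts[cond] = synthgen.simulate_mvar_cohort(spec)
        results["cohorts"] = cohorts
        done("cohort", t0, n_participants=cc["n_participants"],
             conditions=list(cohorts))

        # --- epoch cap ----------------------------------------------------
        t0 = stage("epoch_cap")
        counts = [p.n_epochs for cond in cohorts for p in cohorts[cond].participants]
        cap, _ = ep.cap_epochs(counts, cfg["epochs"]["cap_margin"])
        keep = {cond: [ep.thin_indices(p.n_epochs, cap)
                       for p in cohorts[cond].participants]
                for cond in cohorts}
        results["epoch_cap"] = cap
        done("epoch_cap", t0, cap=cap, min_count=int(min(counts)))

        # --- connectivity + group stats ------------------------------------
        t0 = stage("connectivity")
        ns = cfg["netstats"]
        groups = {}
        for cond in cohorts:
            group, banded, thr = analyze_cohort_connectivity(
                cohorts[cond].participants, order=None, p_max=cfg["mvar"]["p_max"],
                n_surrogates=ns["n_surrogates"], percentile=ns["percentile"],
                alpha=ns["binomial_alpha"], bands=bands,
                seed=seed, condition=cond,
                difference=cfg["mvar"]["difference"], keep_indices=keep[cond])
            groups[cond] = group
        results["groups"] = groups
        done("connectivity", t0,
             significant_edges={c: int(g.significant.sum()) for c, g in groups.items()})

        t0 = stage("group_stats")
        conds = list(groups)
        if len(conds) >= 2:
            results["contrast"] = netstats.expand_and_contrast(groups[conds[0]],
                                                               groups[conds[1]])
        results["degree"] = {
            cond: netstats.node_degree_test(
                groups[cond], n_randomizations=ns["n_randomizations"],
                percentile=ns["degree_percentile"],
                seed=child_seed(seed, f"degree-{cond}"))
            for cond in groups}
        done("group_stats", t0,
             hubs={c: [r for r, h in zip(d.roi_names, d.high_degree) if h]
                   for c, d in results["degree"].items()})

        # --- source-mesh arm ------------------------------------------------
        t0 = stage("scpt")
        sc = cfg["scpt"]
        mesh = synthgen.grid_mesh(sc["grid"][0], sc["grid"][1], sc["spacing_mm"])
        rng = np.random.default_rng(child_seed(seed, "planted-cluster"))
        start = int(rng.integers(0, mesh.n_vertices))
        planted_vertices = _grow_patch(mesh, start, sc["planted_vertices"])
        planted = synthgen.PlantedCluster(
            vertex_set=planted_vertices,
            time_window_ms=tuple(sc["planted_window_ms"]),
            amplitude=sc["planted_amplitude"])
        image, cross = synthgen.simulate_vertex_fra(
            mesh, planted, sc["n_runs"], sc["noise_sd"],
            seed=child_seed(seed, "vertex-fra"),
            sampling_rate=sc["sampling_rate"], n_samples=sc["n_samples"])
        contrast = scpt.make_contrast(image, cross)
        clusters = scpt.cluster_test(contrast, tuple(sc["window_ms"]),
                                     n_permutations=sc["n_permutations"],
                                     alpha=sc["alpha"], cluster_p=sc["cluster_p"],
                                     seed=child_seed(seed, "scpt-perms"))
        surviving = scpt.filter_clusters(clusters, sc["min_vertices"],
                                         sc["min_duration_ms"])
        rois = scpt.partition_rois(surviving, mesh.labels, sc["min_fraction"])
        results["planted_cluster"] = planted
        results["clusters"] = surviving
        results["rois"] = rois
        done("scpt", t0, n_significant_clusters=len(surviving.clusters),
             n_rois=len(rois), planted_vertices=len(planted_vertices))

        t0 = stage("roitc")
        avg = contrast.values.mean(axis=0)
        for roi in rois:
            prepare_roi(roi, avg, mesh.coords,
                        window_ms=tuple(cfg["roitc"]["peak_window_ms"]),
                        radius=cfg["roitc"]["radius_mm"],
                        sampling_rate=sc["sampling_rate"], t0_index=0)
        if rois:
            results["roi_timecourses"] = extract_roi_timecourses(
                contrast.values, rois, sc["sampling_rate"], t0_index=0)
        done("roitc", t0, peaks={r.label: int(r.peak_vertex) for r in rois})

        # --- behaviour arm --------------------------------------------------
        t0 = stage("rtcorr")
        rc = cfg["rtcorr"]
        trials = synthgen.simulate_target_trials(
            rc["n_trials"], rc["r_target"], rc["rt_mean_ms"], rc["rt_sd_ms"],
            seed=child_seed(seed, "trials"),
            invalid_fraction=rc["invalid_fraction"])
        kept = rtcorr.filter_trials(trials, rc["max_rt_ms"])
        roi_ep = synthgen.trials_to_roi_epochs(kept,
                                               seed=child_seed(seed, "trial-noise"),
                                               noise_sd=0.5)
        grand = np.abs(roi_ep.data[:, 0, :]).mean(axis=0)
        interval = rtcorr.fwhm_interval(grand, roi_ep.sampling_rate,
                                        roi_ep.t0_index,
                                        tuple(rc["search_window_ms"]))
        report = rtcorr.amplitude_rt_correlation(
            roi_ep, kept, {roi_ep.roi_names[0]: interval}, rc["fdr_alpha"])
        results["trials"] = trials
        results["correlation"] = report
        done("rtcorr", t0, n_trials=len(trials), n_kept=len(kept),
             r=float(report["r"].iloc[0]),
             fwhm_ms=[float(interval[0]), float(interval[1])])
    except Exception as exc:
        failing = [k for k, v in manifest["stages"].items()
                   if v.get("status") == "running"]
        raise RuntimeError(f"stage {failing[0] if failing else '?'} failed: {exc}") from exc

    manifest["elapsed_note"] = "timings are logged, not stored, to keep manifests reproducible"
    results["manifest"] = manifest

    if out_dir is not None:
        _write_outputs(results, groups, Path(out_dir))
    log.info("run_all finished in %.1f s", time.perf_counter() - t_start)
    return results


def _grow_patch(mesh, start: int, size: int) -> np.ndarray:
    """Deterministic connected patch of ``size`` vertices grown from ``start``."""
    adj = mesh.adjacency.tolil().rows
    patch = [start]
    seen = {start}
    frontier = [start]
    while len(patch) < size and frontier:
        nxt = []
        for v in frontier:
            for u in sorted(adj[v]):
                if u not in seen:
                    seen.add(u)
                    patch.append(u)
                    nxt.append(u)
                    if len(patch) >= size:
                        return np.array(sorted(patch))
        frontier = nxt
    return np.array(sorted(patch))


def _write_outputs(results: dict, groups: dict, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    io.write_manifest(results["manifest"], out_dir / "manifest.yaml")

    rows = []
    for cond, g in groups.items():
        for b, band in enumerate(g.bands):
            src, tgt = np.nonzero(g.counts[b])
            for m, n in zip(src, tgt):
                rows.append({"condition": cond, "band": band,
                             "source": g.roi_names[n], "target": g.roi_names[m],
                             "count": int(g.counts[b, m, n]),
                             "p": g.p_values[b, m, n],
                             "significant": bool(g.significant[b, m, n]),
                             "mean_strength": g.mean_strength[b, m, n]})
    io.write_tsv(pd.DataFrame(rows, columns=["condition", "band", "source",
                                             "target", "count", "p",
                                             "significant", "mean_strength"]),
                 out_dir / "edges.tsv")

    deg_frames = []
    for cond, rep in results.get("degree", {}).items():
        df = rep.to_frame()
        df.insert(0, "condition", cond)
        deg_frames.append(df)
    if deg_frames:
        io.write_tsv(pd.concat(deg_frames, ignore_index=True), out_dir / "degree.tsv")

    roi_rows = [{"label": r.label, "n_vertices": int(r.member_vertices.size),
                 "significant_fraction": r.significant_fraction,
                 "peak_vertex": int(r.peak_vertex) if r.peak_vertex is not None else -1,
                 "n_neighborhood": int(r.neighborhood.size) if r.neighborhood is not None else 0,
                 "n_flipped": int(np.sum(np.asarray(r.signs) < 0)) if r.signs is not None else 0}
                for r in results.get("rois", [])]
    io.write_tsv(pd.DataFrame(roi_rows, columns=["label", "n_vertices",
                                                 "significant_fraction",
                                                 "peak_vertex", "n_neighborhood",
                                                 "n_flipped"]),
                 out_dir / "rois.tsv")

    if "correlation" in results:
        io.write_tsv(results["correlation"], out_dir / "correlation.tsv")
    if "roi_timecourses" in results:
        io.save_roi_epochs(results["roi_timecourses"], out_dir / "arrays.h5",
                           key="roi_timecourses")
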