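"""Config-driven orchestration of the full connectivity analysis.

Stages: ``simulate`` (synthetic cohort) -> ``preprocess`` ->
``ica`` (multi-order decomposition + hierarchical partner matching) ->
``groupstats`` (cluster-extent corrected group maps, severity
correlation) -> ``granger`` (per-subject GCI table and group tests) ->
``classify`` (LOOCV with MLDA and kernel SVM).

Every stage derives its randomness from the master seed, records its
parameters and outputs in a JSON manifest, and persists intermediates
(NIfTI maps, TSV tables, JSON summaries, plus binary state snapshots
for fast stage re-runs) under the run directory.
"""

from __future__ import annotations

import copy
import dataclasses
import hashlib
import json
import logging
import pickle
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify as _classify
from . import granger as _granger
from . import groupstats as _groupstats
from . import hpmica as _hpmica
from . import preprocess as _preprocess
from . import synth as _synth

__all__ = ["DEFAULT_CONFIG", "RunConfig", "validate_config", "run_pipeline",
           "STAGES"]

log = logging.getLogger("restconn")

STAGES = ["simulate", "preprocess", "ica", "groupstats", "granger", "classify"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "persist": True,    # write NIfTI/TSV/JSON outputs and state snapshots
    "outdir": "restconn_run",
    "stages": list(STAGES),
    "cohort": {},                       # overrides for synth.CohortConfig
    "preprocess": {"smooth_fwhm_mm": 0.0},
    "ica": {"orders": None,             # default: planted K, K+2, K+4
            "n_restarts": 3,
            "match_threshold": 0.4,
            "min_orders": None},
    "groupstats": {"voxel_p": 0.01,
                   "corrected_alpha": 0.05,
                   "n_sims": 500,
                   "mask_p": 0.001,
                   "sim_fwhm_mm": None},   # default: cohort source smoothness
    "granger": {"order": 1, "relay": None},
    "classify": {"alpha": 0.05, "svm_width": 0.5, "svm_c": 1.0,
                 "positive_group": "patient"},
}


class RunConfig(dict):
    """A validated pipeline configuration (a nested dict with helpers)."""

    @classmethod
    def with_defaults(cls, overrides: dict | None = None) -> "RunConfig":
        cfg = copy.deepcopy(DEFAULT_CONFIG)
        for key, val in (overrides or {}).items():
            if isinstance(val, dict) and isinstance(cfg.get(key), dict):
                cfg[key].update(val)
            else:
                cfg[key] = val
        return cls(cfg)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.with_defaults(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dict(self)))


def validate_config(config: dict) -> list[str]:
    """Structured issues ('error: ...' / 'warning: ...'); never raises."""
    issues: list[str] = []
    known = set(DEFAULT_CONFIG)
    for key in config:
        if key not in known:
            near = min(known, key=lambda k: _edit_distance(key, k))
            issues.append(f"warning: unknown key {key!r} (did you mean {near!r}?)")
    for section in ("preprocess", "ica", "groupstats", "granger", "classify"):
        sub = config.get(section, {})
        if isinstance(sub, dict):
            for key in sub:
                if key not in DEFAULT_CONFIG[section]:
                    near = min(DEFAULT_CONFIG[section],
                               key=lambda k: _edit_distance(key, k))
                    issues.append(f"warning: unknown key {section}.{key!r} "
                                  f"(did you mean {near!r}?)")
    stages = config.get("stages", STAGES)
    for s in stages:
        if s not in STAGES:
            issues.append(f"error: unknown stage {s!r}")
    orders = config.get("ica", {}).get("orders")
    if orders is not None and len(orders) < 2:
        issues.append("error: ica.orders must list >= 2 model orders — "
                      "hierarchical matching needs clusters from at least two "
                      "orders (min_orders rule)")
    cohort = config.get("cohort", {})
    if cohort:
        try:
            _synth.CohortConfig(**cohort).validate()
        except _synth.UnstableCouplingError as exc:
            issues.append(f"error: unstable coupling — {exc}")
        except (TypeError, ValueError) as exc:
            issues.append(f"error: invalid cohort config — {exc}")
    gs = config.get("groupstats", {})
    vp = gs.get("voxel_p", 0.01)
    if not (0 < vp < 1):
        issues.append("error: groupstats.voxel_p must lie in (0, 1)")
    return issues


def _edit_distance(a: str, b: str) -> int:
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


# ---------------------------------------------------------------------------


def _stage_seed(master: int, stage: str) -> np.random.SeedSequence:
    return np.random.SeedSequence(master, spawn_key=(STAGES.index(stage),))


def _int_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


class PipelineState:
    """In-memory carrier of stage outputs, picklable for stage re-runs."""

    def __init__(self):
        self.runs = None
        self.truth = None
        self.mask = None
        self.std_runs = None
        self.component_sets = None      # {order: [ComponentSet]}
        self.selected = None            # [ComponentCluster]
        self.first_level = None
        self.groupstats = None          # per-component dicts
        self.extent_k = None
        self.gci_table = None
        self.gci_compare = None
        self.features = None
        self.results = None

    def save(self, path: Path) -> None:
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "wb") as fh:
            pickle.dump(self.__dict__, fh)

    @classmethod
    def load(cls, path: Path) -> "PipelineState":
        state = cls()
        with open(path, "rb") as fh:
            state.__dict__.update(pickle.load(fh))
        return state


def run_pipeline(config: dict, state: PipelineState | None = None) -> dict:
    """Execute the enabled stages in order; return the run manifest."""
    config = RunConfig.with_defaults(config)
    issues = validate_config(config)
    errors = [i for i in issues if i.startswith("error")]
    for issue in issues:
        log.warning(issue)
    if errors:
        raise ValueError("invalid configuration:\n" + "\n".join(errors))

    outdir = Path(config["outdir"])
    if config["persist"]:
        outdir.mkdir(parents=True, exist_ok=True)
    state = state or PipelineState()
    manifest = {"seed": config["seed"], "config": _jsonable(dict(config)),
                "stages": {}}
    manifest_path = outdir / "manifest.json"

    runners = {"simulate": _stage_simulate, "preprocess": _stage_preprocess,
               "ica": _stage_ica, "groupstats": _stage_groupstats,
               "granger": _stage_granger, "classify": _stage_classify}
    for stage in STAGES:
        if stage not in config["stages"]:
            continue
        log.info("stage %s ...", stage)
        try:
            record = runners[stage](config, state, outdir)
        except Exception as exc:
            manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
            if config["persist"]:
                manifest_path.write_text(json.dumps(manifest, indent=2))
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        record["status"] = "ok"
        manifest["stages"][stage] = record
        if config["persist"]:
            state.save(outdir / "state" / f"after_{stage}.pkl")
            manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


# ---------------------------------------------------------------------------
# stages


def _stage_simulate(config, state, outdir):
    cohort_kwargs = dict(config["cohort"])
    cohort_kwargs.setdefault("seed", _int_seed(_stage_seed(config["seed"], "simulate")))
    cc = _synth.CohortConfig(**cohort_kwargs)
    runs, truth = _synth.generate_cohort(cc)
    state.runs, state.truth = runs, truth
    record = {"n_subjects": len(runs),
              "params": _jsonable(dataclasses.asdict(cc.resolve()))}
    if config["persist"]:
        paths = _synth.write_cohort(runs, truth, cc, outdir / "cohort")
        files = {"participants": paths["participants"],
                 "ground_truth": paths["ground_truth"]}
        record["outputs"] = {k: _sha256(v) for k, v in files.items()}
    return record


def _stage_preprocess(config, state, outdir):
    fwhm = config["preprocess"]["smooth_fwhm_mm"]
    std = []
    for run in state.runs:
        r = _preprocess.smooth_run(run, fwhm) if fwhm > 0 else run
        r = _preprocess._replace_data(r, r.data, _preprocess.default_mask(r.data))
        std.append(_preprocess.standardize_timecourses(r))
    mask = np.logical_and.reduce([r.mask for r in std])
    if not mask.any():
        raise ValueError("empty intersection mask across subjects")
    state.std_runs = [_preprocess._replace_data(r, r.data, mask) for r in std]
    state.mask = mask
    return {"smooth_fwhm_mm": fwhm, "mask_voxels": int(mask.sum())}


def _default_orders(config, state):
    orders = config["ica"]["orders"]
    if orders is None:
        k = state.truth.source_maps.shape[0] if state.truth is not None else 6
        orders = [k, k + 2, k + 4]
    return [int(o) for o in orders]


def _stage_ica(config, state, outdir):
    icfg = config["ica"]
    orders = _default_orders(config, state)
    threshold = icfg["match_threshold"]
    seed = _stage_seed(config["seed"], "ica")
    first_level = {}
    component_sets = {}
    for oi, order in enumerate(orders):
        sets = []
        for si, run in enumerate(state.std_runs):
            child = np.random.SeedSequence(config["seed"],
                                           spawn_key=(STAGES.index("ica"), oi, si))
            sets.append(_hpmica.decompose_subject(
                run, order, seed=_int_seed(child),
                n_restarts=icfg["n_restarts"]))
        component_sets[order] = sets
        first_level[order] = _hpmica.match_components(sets, threshold=threshold)
    groups = _hpmica.hierarchical_match(first_level, threshold=threshold,
                                        min_orders=icfg["min_orders"])
    selected = _hpmica.select_reproducible(groups)
    state.component_sets = component_sets
    state.first_level = first_level
    state.selected = selected

    summary = []
    for rank, cl in enumerate(selected):
        summary.append({"component": f"IC{rank}", "order": cl.order,
                        "alpha": cl.alpha, "n_members": len(cl),
                        "mean_similarity": cl.mean_similarity,
                        "members": [[m[0], m[1], m[2]] for m in cl.members]})
    if config["persist"]:
        import nibabel as nib

        icadir = outdir / "ica"
        icadir.mkdir(parents=True, exist_ok=True)
        (icadir / "selected_clusters.json").write_text(json.dumps(summary, indent=2))
        # representative maps as a 4D NIfTI (one volume per selected cluster)
        vols = np.stack([_embed(c.representative_map, state.mask)
                         for c in selected], axis=-1)
        affine = np.diag(list(state.std_runs[0].voxel_size_mm) + [1.0])
        nib.save(nib.Nifti1Image(vols.astype(np.float32), affine),
                 str(icadir / "selected_representative_maps.nii.gz"))
        # matched component time courses per subject, TSV
        tc_rows = {}
        for rank, cl in enumerate(selected):
            csets = {cs.subject_id: cs for cs in component_sets[cl.order]}
            for sid, comp_idx, sign in cl.members:
                tc_rows.setdefault(sid, {})[f"IC{rank}"] = (
                    sign * csets[sid].time_courses[:, comp_idx])
        tcdir = icadir / "timecourses"
        tcdir.mkdir(exist_ok=True)
        for sid, cols in tc_rows.items():
            pd.DataFrame(cols).to_csv(tcdir / f"{sid}.tsv", sep="\t",
                                      index=False)
    return {"orders": orders, "n_selected": len(selected),
            "alphas": [c.alpha for c in selected]}


def _complete_clusters(state):
    """Selected clusters with one member for every subject, with labels."""
    all_ids = {r.subject_id for r in state.std_runs}
    out = []
    for rank, cl in enumerate(state.selected):
        if set(cl.owner_ids) == all_ids:
            out.append((f"IC{rank}", cl))
        else:
            warnings.warn(f"cluster IC{rank} lacks members for "
                          f"{len(all_ids) - len(cl)} subject(s); excluded from "
                          "group statistics and features")
    return out


def _stage_groupstats(config, state, outdir):
    gcfg = config["groupstats"]
    runs = {r.subject_id: r for r in state.std_runs}
    mask = state.mask
    grid = mask.shape
    voxel_size = state.std_runs[0].voxel_size_mm
    sim_fwhm = gcfg["sim_fwhm_mm"]
    if sim_fwhm is None:
        sim_fwhm = config["cohort"].get("smooth_fwhm_mm",
                                        _synth.CohortConfig().smooth_fwhm_mm)
    seed = _int_seed(_stage_seed(config["seed"], "groupstats"))
    extent_k = _groupstats.mc_cluster_extent(
        grid, mask, gcfg["voxel_p"], sim_fwhm, voxel_size,
        n_sims=gcfg["n_sims"], corrected_alpha=gcfg["corrected_alpha"],
        seed=seed)
    state.extent_k = extent_k

    results = {}
    for label, cl in _complete_clusters(state):
        order_ids = [r.subject_id for r in state.std_runs]
        by_id = {m[0]: i for i, m in enumerate(cl.members)}
        maps2d = np.array([cl.member_maps[by_id[s]] for s in order_ids])
        t1, df1 = _hpmica.cluster_onesample_map(maps2d)
        one = _groupstats.StatMap(values=_embed(t1, mask), df=df1)
        rsn = _groupstats.make_rsn_mask(one, gcfg["mask_p"], base_mask=mask)
        groups = [1 if runs[s].group == "patient" else 0 for s in order_ids]
        glm = _groupstats.fit_group_glm(
            np.array([_embed(m, mask) for m in maps2d]), groups,
            [runs[s].age for s in order_ids], [runs[s].sex for s in order_ids])
        thr = _groupstats.apply_threshold(glm, gcfg["voxel_p"], extent_k,
                                          mask=rsn)
        entry = {"onesample": one, "rsn_mask": rsn, "glm": glm,
                 "thresholded": thr, "subject_order": order_ids,
                 "member_maps": maps2d}
        if thr.clusters:
            top = thr.clusters[0]
            pat = [s for s in order_ids if runs[s].group == "patient"]
            scores = [float(np.mean(_embed(maps2d[order_ids.index(s)], mask)[top["mask"]]))
                      for s in pat]
            sev = [runs[s].severity for s in pat]
            if all(v is not None for v in sev):
                r, p = _groupstats.severity_correlation(scores, sev)
                entry["severity_r"], entry["severity_p"] = r, p
        results[label] = entry
    state.groupstats = results

    table = []
    for label, e in results.items():
        for c in e["thresholded"].clusters:
            table.append({"component": label, "size": c["size"],
                          "peak_index": list(c["peak_index"]),
                          "peak_t": c["peak_t"]})
    if config["persist"]:
        import nibabel as nib

        gsdir = outdir / "groupstats"
        gsdir.mkdir(parents=True, exist_ok=True)
        affine = np.diag(list(voxel_size) + [1.0])
        for label, e in results.items():
            nib.save(nib.Nifti1Image(
                e["thresholded"].values.astype(np.float32), affine),
                str(gsdir / f"{label}_group_t_thresholded.nii.gz"))
        (gsdir / "clusters.json").write_text(json.dumps(
            {"extent_k": extent_k, "clusters": table,
             "severity": {label: {"r": e.get("severity_r"),
                                  "p": e.get("severity_p")}
                          for label, e in results.items()
                          if "severity_r" in e}},
            indent=2))
    return {"extent_k": extent_k,
            "n_significant_clusters": sum(len(e["thresholded"].clusters)
                                          for e in results.values())}


def _embed(flat, mask):
    vol = np.zeros(mask.shape)
    vol[mask] = flat
    return vol


def _stage_granger(config, state, outdir):
    gcfg = config["granger"]
    complete = _complete_clusters(state)
    if len(complete) < 2:
        raise ValueError("need >= 2 complete component clusters for GC")
    labels = [label for label, _ in complete]
    tcs = {}
    for run in state.std_runs:
        cols = []
        for label, cl in complete:
            member = {m[0]: m for m in cl.members}[run.subject_id]
            _, comp_idx, sign = member
            sets = state.component_sets[cl.order]
            cset = {s.subject_id: s for s in sets}[run.subject_id]
            cols.append(sign * cset.time_courses[:, comp_idx])
        tcs[run.subject_id] = np.column_stack(cols)
    relay = gcfg["relay"]
    relay_idx = labels.index(relay) if isinstance(relay, str) else relay
    table = _granger.compute_gci_table(tcs, order=gcfg["order"],
                                       relay=relay_idx, node_names=labels)
    groups = {r.subject_id: r.group for r in state.std_runs}
    compare = _granger.compare_gci_table_groups(table, groups)
    state.gci_table, state.gci_compare = table, compare

    if config["persist"]:
        gdir = outdir / "granger"
        gdir.mkdir(parents=True, exist_ok=True)
        table.to_csv(gdir / "gci_table.tsv", sep="\t", index=False)
        compare.to_csv(gdir / "gci_group_comparison.tsv", sep="\t", index=False)
    return {"order": gcfg["order"], "n_connections": int(
        table.groupby(["source", "target", "relay"]).ngroups),
        "n_significant": int((compare["p"] < 0.05).sum())}


def _stage_classify(config, state, outdir):
    ccfg = config["classify"]
    runs = {r.subject_id: r for r in state.std_runs}
    groups = {s: r.group for s, r in runs.items()}
    subject_ids = [r.subject_id for r in state.std_runs]

    fc = {}
    for label, e in (state.groupstats or {}).items():
        for ci, c in enumerate(e["thresholded"].clusters):
            name = f"{label}cl{ci}"
            order_ids = e["subject_order"]
            vals = {s: float(np.mean(_embed(e["member_maps"][order_ids.index(s)],
                                            state.mask)[c["mask"]]))
                    for s in order_ids}
            fc[name] = vals
    fc_frame = pd.DataFrame(fc if fc else {}, index=subject_ids)
    table = _classify.build_features(fc_frame, state.gci_table, groups,
                                     positive_group=ccfg["positive_group"])
    results = {}
    for clf in ("mlda", "ksvm"):
        results[clf] = _classify.loocv(table, classifier=clf,
                                       alpha=ccfg["alpha"],
                                       svm_width=ccfg["svm_width"],
                                       svm_c=ccfg["svm_c"])
    state.features, state.results = table, results

    summary = {clf: {"accuracy": res.accuracy, "sensitivity": res.sensitivity,
                     "specificity": res.specificity}
               for clf, res in results.items()}
    if config["persist"]:
        cdir = outdir / "classify"
        cdir.mkdir(parents=True, exist_ok=True)
        weights = pd.DataFrame({
            "feature": table.feature_names,
            "mean_weight": results["mlda"].mean_weights,
            "selection_count": results["mlda"].selected_counts})
        weights.to_csv(cdir / "mlda_feature_weights.tsv", sep="\t", index=False)
        (cdir / "classification.json").write_text(json.dumps(summary, indent=2))
    return {"n_features": table.features.shape[1], **_jsonable(summary)}
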