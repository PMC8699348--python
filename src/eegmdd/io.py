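"""Text-based serialization: feature tables, SBS traces, fitted models and
run manifests.

Everything is plain delimited text or JSON, so artifacts diff cleanly and
round-trip exactly (model decision values reproduce to full float precision
after a save/load cycle).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import classifiers as clf
from .features import FeatureDescriptor, FeatureTable
from .model_selection import SBSStep, SBSTrace

META_COLUMNS = ("subject_id", "site_id", "class_label")


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------

def write_feature_table(table: FeatureTable, path: "str | Path") -> None:
    """CSV with subject_id, site_id, class_label plus one column per feature
    descriptor string (e.g. ``COH|alpha|F8-FT7``)."""
    table.to_frame().to_csv(path, index=False)


def read_feature_table(path: "str | Path") -> FeatureTable:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"feature table lacks metadata columns {missing}")
    feature_cols = [c for c in df.columns if c not in META_COLUMNS]
    descriptors = [FeatureDescriptor.parse(c) for c in feature_cols]
    return FeatureTable(
        subject_ids=[str(s) for s in df["subject_id"]],
        site_ids=[str(s) for s in df["site_id"]],
        class_labels=[str(s) for s in df["class_label"]],
        descriptors=descriptors,
        values=df[feature_cols].to_numpy(dtype=float),
    )


# ---------------------------------------------------------------------------
# SBS traces
# ---------------------------------------------------------------------------

def write_sbs_trace(trace: SBSTrace, path: "str | Path") -> None:
    """TSV trace (step, removed_feature, subset_size, cv_mean, cv_std) plus a
    JSON manifest sidecar holding the seed, descriptors, per-step surviving
    subsets and the optimal subset."""
    path = Path(path)
    rows = []
    for s in trace.steps:
        removed = trace.removed_descriptor(s)
        rows.append({
            "step": s.step,
            "removed_feature": "" if removed is None else str(removed),
            "subset_size": len(s.subset),
            "cv_mean": s.cv_mean,
            "cv_std": s.cv_std,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.17g")
    manifest = {
        "seed": trace.seed,
        "descriptors": None if trace.descriptors is None
        else [str(d) for d in trace.descriptors],
        "steps": [
            {"step": s.step, "removed_index": s.removed_index,
             "subset": list(s.subset), "cv_mean": s.cv_mean,
             "cv_std": s.cv_std, "hyperparams": list(map(list, s.hyperparams))}
            for s in trace.steps
        ],
        "optimal_subset": list(trace.optimal_subset),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(manifest, indent=1))


def read_sbs_trace(path: "str | Path") -> SBSTrace:
    manifest = json.loads(Path(path).with_suffix(Path(path).suffix + ".json").read_text())
    descriptors = None
    if manifest["descriptors"] is not None:
        descriptors = [FeatureDescriptor.parse(t) for t in manifest["descriptors"]]
    steps = [
        SBSStep(step=s["step"], removed_index=s["removed_index"],
                subset=tuple(s["subset"]), cv_mean=s["cv_mean"],
                cv_std=s["cv_std"],
                hyperparams=tuple(tuple(h) for h in s["hyperparams"]))
        for s in manifest["steps"]
    ]
    return SBSTrace(steps=steps, descriptors=descriptors, seed=manifest["seed"])


# ---------------------------------------------------------------------------
# Models
# ---------------------------------------------------------------------------

def _arr(a) -> list:
    return np.asarray(a).tolist()


def save_model(model, path: "str | Path",
               descriptors: "list[FeatureDescriptor] | None" = None) -> None:
    """Self-describing JSON container for any fitted classifier."""
    payload: dict = {
        "format": "eegmdd-model",
        "version": 1,
        "train_subject_ids": getattr(model, "train_subject_ids", None),
        "feature_descriptors": None if descriptors is None
        else [str(d) for d in descriptors],
    }
    if isinstance(model, clf.KNNModel):
        payload.update(kind="knn", k=model.k, X=_arr(model.train.X),
                       y=_arr(model.train.y))
    elif isinstance(model, clf.LDAModel):
        payload.update(kind="lda", weight=_arr(model.weight), bias=model.bias,
                       mean_mdd=_arr(model.mean_mdd), mean_hc=_arr(model.mean_hc),
                       covariance=_arr(model.covariance),
                       penalty_ratio=model.penalty_ratio,
                       priors=list(model.priors), ridge=model.ridge)
    elif isinstance(model, clf.CKSVMModel):
        payload.update(
            kind="cksvm", C=model.C, gamma=model.gamma, ne=model.ne,
            base_support_vectors=_arr(model.base.support_vectors),
            base_dual_coef=_arr(model.base.dual_coef),
            base_sv_labels=_arr(model.base.sv_labels),
            base_bias=model.base.bias,
            anchors=_arr(model.anchors), tau=_arr(model.tau),
            c_train=_arr(model.c_train),
            sv2_vectors=_arr(model.sv2_vectors),
            sv2_dual_coef=_arr(model.sv2_dual_coef),
            sv2_c=_arr(model.sv2_c), bias2=model.bias2,
        )
    elif isinstance(model, clf.SVMModel):
        payload.update(kind="svm", C=model.C, gamma=model.gamma,
                       support_vectors=_arr(model.support_vectors),
                       dual_coef=_arr(model.dual_coef),
                       sv_labels=_arr(model.sv_labels), bias=model.bias)
    else:
        raise TypeError(f"cannot serialize model of type {type(model).__name__}")
    Path(path).write_text(json.dumps(payload))


def load_model(path: "str | Path"):
    p = json.loads(Path(path).read_text())
    if p.get("format") != "eegmdd-model":
        raise ValueError(f"{path} is not an eegmdd model container")
    ids = p.get("train_subject_ids")
    kind = p["kind"]
    if kind == "knn":
        train = clf.LabeledDataset(np.array(p["X"]), np.array(p["y"]),
                                   subject_ids=ids)
        return clf.KNNModel(train=train, k=p["k"], train_subject_ids=ids)
    if kind == "lda":
        return clf.LDAModel(
            weight=np.array(p["weight"]), bias=p["bias"],
            mean_mdd=np.array(p["mean_mdd"]), mean_hc=np.array(p["mean_hc"]),
            covariance=np.array(p["covariance"]),
            penalty_ratio=p["penalty_ratio"], priors=tuple(p["priors"]),
            ridge=p["ridge"], train_subject_ids=ids)
    if kind == "svm":
        return clf.SVMModel(
            support_vectors=np.array(p["support_vectors"]),
            dual_coef=np.array(p["dual_coef"]),
            sv_labels=np.array(p["sv_labels"]), bias=p["bias"],
            C=p["C"], gamma=p["gamma"], train_subject_ids=ids)
    if kind == "cksvm":
        base = clf.SVMModel(
            support_vectors=np.array(p["base_support_vectors"]),
            dual_coef=np.array(p["base_dual_coef"]),
            sv_labels=np.array(p["base_sv_labels"]), bias=p["base_bias"],
            C=p["C"], gamma=p["gamma"], train_subject_ids=ids)
        return clf.CKSVMModel(
            base=base, anchors=np.array(p["anchors"]), tau=np.array(p["tau"]),
            ne=p["ne"], c_train=np.array(p["c_train"]),
            sv2_vectors=np.array(p["sv2_vectors"]),
            sv2_dual_coef=np.array(p["sv2_dual_coef"]),
            sv2_c=np.array(p["sv2_c"]), bias2=p["bias2"],
            train_subject_ids=ids)
    raise ValueError(f"unknown model kind {kind!r}")


def model_feature_descriptors(path: "str | Path"):
    p = json.loads(Path(path).read_text())
    descs = p.get("feature_descriptors")
    return None if descs is None else [FeatureDescriptor.parse(t) for t in descs]


# ---------------------------------------------------------------------------
# Run manifests
# ---------------------------------------------------------------------------

def config_hash(config: dict) -> str:
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def write_manifest(path: "str | Path", config: dict, seed: int | None,
                   timings: dict | None = None, extra: dict | None = None) -> None:
    from . import __version__

    manifest = {
        "config": config,
        "config_hash": config_hash(config),
        "seed": seed,
        "package_version": __version__,
        "stage_timings_s": timings or {},
    }
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=1, default=str))
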