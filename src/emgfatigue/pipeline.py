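"""One-config orchestration: simulate → preprocess → decompose → features → embed → classify.

The pipeline is driven by a TOML file with one section per stage::

    master_seed = 7
    output_dir = "out"
    stages = ["simulate", "preprocess", "decompose", "features", "embed", "classify"]

    [synthetic]
    n_subjects = 2
    n_trials = 2
    duration = 20.0

    [preprocess]
    [decompose]
    variant = "ICEEMDAN"
    ensemble_size = 20

    [features]
    [tsne]
    [classify]
    classifier = "svm"

Every artifact (record CSVs, IMF CSVs, feature table, embedding, eval
report) is written under ``output_dir`` and indexed in a manifest with a
SHA-256 content hash, so end-to-end determinism is checkable by comparing
manifests.  A timestamped plaintext log records stage boundaries and the
seeds in effect.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import tomllib
import warnings
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from emgfatigue import classify as clf_mod
from emgfatigue.emd import DecompParams, decompose
from emgfatigue.features import WindowConfig, extract_feature_table, write_feature_table
from emgfatigue.preprocess import PreprocessConfig, preprocess_record
from emgfatigue.records import read_record, write_manifest, write_record, record_basename
from emgfatigue.synthetic import SynthConfig, generate_dataset
from emgfatigue.tsne import tsne_embed

STAGE_SECTIONS = {
    "simulate": "synthetic",
    "preprocess": "preprocess",
    "decompose": "decompose",
    "features": "features",
    "embed": "tsne",
    "classify": "classify",
}
STAGE_ORDER = tuple(STAGE_SECTIONS)

_TSNE_DEFAULTS = {"perplexity": 30.0, "learning_rate": 200.0, "n_iter": 1000, "dims": 3}
_CLASSIFY_DEFAULTS = {
    "classifier": "svm",
    "scheme": "stratified-window",
    "k_folds": 5,
    "representation": "features",
}
_FEATURES_EXTRA = {"k_keep": 5}


class SchemaError(ValueError):
    """A pipeline config names an unknown key or omits a required section."""


def _load_toml(config_path: str | Path) -> dict:
    path = Path(config_path)
    try:
        with path.open("rb") as fh:
            return tomllib.load(fh)
    except tomllib.TOMLDecodeError as err:
        raise SchemaError(f"cannot parse {path}: {err}") from err


def _section_defaults(section: str) -> dict:
    if section == "synthetic":
        return {f.name: f.default for f in dataclasses.fields(SynthConfig)}
    if section == "preprocess":
        return {f.name: f.default for f in dataclasses.fields(PreprocessConfig)}
    if section == "decompose":
        return {f.name: f.default for f in dataclasses.fields(DecompParams)}
    if section == "features":
        return {
            **{f.name: f.default for f in dataclasses.fields(WindowConfig)},
            **_FEATURES_EXTRA,
        }
    if section == "tsne":
        return dict(_TSNE_DEFAULTS)
    if section == "classify":
        return dict(_CLASSIFY_DEFAULTS)
    raise KeyError(section)


def validate_config(config_path: str | Path) -> pd.DataFrame:
    """Echo every resolved parameter with its source (user or default).

    Unknown sections or keys raise a warning naming them; nothing is
    written to disk.
    """
    raw = _load_toml(config_path)
    rows = []
    for key, default in (("master_seed", 0), ("output_dir", "emgfatigue_out"), ("stages", None)):
        user = key in raw
        rows.append(
            {
                "section": "",
                "key": key,
                "value": repr(raw.get(key, default)),
                "source": "user" if user else "default",
            }
        )
    known_top = {"master_seed", "output_dir", "stages", *STAGE_SECTIONS.values()}
    for key in raw:
        if key not in known_top:
            warnings.warn(f"unknown config key: {key!r}", stacklevel=2)
    for section in STAGE_SECTIONS.values():
        user_section = raw.get(section, {})
        defaults = _section_defaults(section)
        for key in user_section:
            if key not in defaults:
                warnings.warn(f"unknown config key: {section}.{key}", stacklevel=2)
        for key, default in defaults.items():
            rows.append(
                {
                    "section": section,
                    "key": key,
                    "value": repr(user_section.get(key, default)),
                    "source": "user" if key in user_section else "default",
                }
            )
    return pd.DataFrame(rows)


def _build(section: str, raw: dict, master_seed: int):
    user = dict(raw.get(section, {}))
    defaults = _section_defaults(section)
    for key in user:
        if key not in defaults:
            raise SchemaError(f"unknown key {key!r} in section [{section}]")
    if section == "synthetic":
        user.setdefault("master_seed", master_seed)
        return SynthConfig(**user)
    if section == "preprocess":
        return PreprocessConfig(**user)
    if section == "decompose":
        user.setdefault("seed", master_seed)
        return DecompParams(**user)
    if section == "features":
        k_keep = user.pop("k_keep", _FEATURES_EXTRA["k_keep"])
        return WindowConfig(**user), k_keep
    merged = dict(defaults)
    merged.update(user)
    return merged


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _RunLog:
    def __init__(self, path: Path):
        self.path = path
        self.path.write_text("")

    def write(self, message: str) -> None:
        stamp = datetime.now(timezone.utc).isoformat(timespec="seconds")
        with self.path.open("a") as fh:
            fh.write(f"{stamp}  {message}\n")


def run(config_path: str | Path) -> dict:
    """Execute the configured stages; returns the artifact manifest.

    Stages default to those whose section appears in the file (always
    including ``simulate``); an explicitly listed stage whose section is
    absent is a schema error naming the section.
    """
    raw = _load_toml(config_path)
    master_seed = int(raw.get("master_seed", 0))
    out_dir = Path(raw.get("output_dir", "emgfatigue_out"))
    if "stages" in raw:
        stages = list(raw["stages"])
        unknown = [s for s in stages if s not in STAGE_SECTIONS]
        if unknown:
            raise SchemaError(f"unknown stages: {unknown}")
        for stage in stages:
            section = STAGE_SECTIONS[stage]
            if stage != "simulate" and section not in raw:
                raise SchemaError(f"stage {stage!r} enabled but section [{section}] missing")
    else:
        stages = [s for s in STAGE_ORDER if s == "simulate" or STAGE_SECTIONS[s] in raw]
    stages = [s for s in STAGE_ORDER if s in stages]

    out_dir.mkdir(parents=True, exist_ok=True)
    log = _RunLog(out_dir / "run.log")
    log.write(f"run start, master_seed={master_seed}, stages={stages}")
    artifacts: list[Path] = []
    manifest_path = out_dir / "artifact_manifest.json"

    records = None
    imf_sets = None
    table = None

    def fail(stage: str, err: Exception):
        log.write(f"stage {stage} FAILED: {err}")
        _write_manifest(artifacts, manifest_path, partial=True)
        raise

    def _write_manifest(paths: list[Path], path: Path, partial: bool = False) -> dict:
        manifest = {
            "partial": partial,
            "master_seed": master_seed,
            "artifacts": {
                str(p.relative_to(out_dir)): _sha256(p) for p in sorted(set(paths))
            },
        }
        path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
        return manifest

    try:
        if "simulate" in stages:
            log.write("stage simulate start")
            config = _build("synthetic", raw, master_seed)
            records = generate_dataset(config)
            rec_dir = out_dir / "records"
            for r in records:
                csv_path, json_path = write_record(r, rec_dir)
                artifacts += [csv_path, json_path]
            artifacts.append(write_manifest(records, rec_dir))
            log.write(f"stage simulate done ({len(records)} records)")

        if "preprocess" in stages:
            log.write("stage preprocess start")
            if records is None:
                records = _load_records(out_dir / "records")
            pp = _build("preprocess", raw, master_seed)
            records = [preprocess_record(r, pp) for r in records]
            pp_dir = out_dir / "preprocessed"
            for r in records:
                csv_path, json_path = write_record(r, pp_dir)
                artifacts += [csv_path, json_path]
            log.write("stage preprocess done")

        if "decompose" in stages:
            log.write("stage decompose start")
            if records is None:
                records = _load_records(out_dir / "records")
            params = _build("decompose", raw, master_seed)
            imf_dir = out_dir / "imfs"
            imf_dir.mkdir(exist_ok=True)
            imf_sets = {}
            for r in records:
                dec = decompose(r.samples, params)
                imf_sets[r.key] = dec
                path = imf_dir / f"{record_basename(r)}_imfs.csv"
                dec.write_csv(path, fs=r.fs)
                artifacts.append(path)
            sidecar = imf_dir / "decomposition_params.json"
            sidecar.write_text(json.dumps(dataclasses.asdict(params), indent=1))
            artifacts.append(sidecar)
            log.write(f"stage decompose done (variant={params.variant})")

        if "features" in stages:
            log.write("stage features start")
            if records is None:
                records = _load_records(out_dir / "records")
            wcfg, k_keep = _build("features", raw, master_seed)
            table = extract_feature_table(records, wcfg, imf_sets, k_keep=k_keep)
            path = out_dir / "features.csv"
            write_feature_table(table, path)
            artifacts.append(path)
            log.write(f"stage features done ({len(table)} rows)")

        if "embed" in stages:
            log.write("stage embed start")
            if table is None:
                raise SchemaError("embed stage requires the features stage")
            tsne_cfg = _build("tsne", raw, master_seed)
            x, y, _, index = clf_mod.pivot_features(table)
            emb = tsne_embed(
                x,
                dims=int(tsne_cfg["dims"]),
                perplexity=float(tsne_cfg["perplexity"]),
                learning_rate=float(tsne_cfg["learning_rate"]),
                n_iter=int(tsne_cfg["n_iter"]),
                seed=master_seed,
            )
            emb_frame = index.copy()
            for d in range(emb.coords.shape[1]):
                emb_frame[f"y{d + 1}"] = emb.coords[:, d]
            emb_frame["label"] = y
            path = out_dir / "embedding.csv"
            emb_frame.to_csv(path, index=False, float_format="%.8g")
            trace_path = out_dir / "tsne_cost_trace.csv"
            pd.DataFrame({"iteration": range(len(emb.cost_trace)), "kl_cost": emb.cost_trace}).to_csv(
                trace_path, index=False
            )
            artifacts += [path, trace_path]
            log.write("stage embed done")

        if "classify" in stages:
            log.write("stage classify start")
            if table is None:
                raise SchemaError("classify stage requires the features stage")
            ccfg = _build("classify", raw, master_seed)
            report = clf_mod.cross_validate(
                table,
                scheme=ccfg["scheme"],
                k_folds=int(ccfg["k_folds"]),
                kind=ccfg["classifier"],
                seed=master_seed,
                representation=ccfg["representation"],
            )
            path = out_dir / "eval_report.json"
            report.write_json(path)
            acc_path = out_dir / "fold_accuracies.csv"
            pd.DataFrame(report.folds).to_csv(acc_path, index=False)
            artifacts += [path, acc_path]
            log.write(f"stage classify done (mean accuracy {report.mean_accuracy:.3f})")
    except SchemaError:
        raise
    except Exception as err:  # abort with stage context and partial manifest
        fail("pipeline", err)

    manifest = _write_manifest(artifacts, manifest_path)
    log.write("run complete")
    return manifest


def _load_records(directory: Path):
    manifest = pd.read_csv(directory / "manifest.csv")
    return [read_record(directory / name) for name in manifest["file"]]
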