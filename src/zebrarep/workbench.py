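"""I/O, inclusion rules, configuration and the end-to-end pipeline driver.

The annotation CSV (columns ``call_id,file,onset_s,offset_s,call_type,
individual_id,sex,location``) is the single source of call labels. Two
inclusion rules are applied depending on the analysis:

- repertoire mode drops calls longer than 1.25 s (the spectrogram-length
  rule; strictly greater, so a 1.25 s call is kept);
- individuality mode drops, per call type, every individual with fewer
  than 5 calls of that type (strong-imbalance rule; ">= 5 calls" kept).

Every exclusion is logged with its rule so kept + excluded = input.
"""

from __future__ import annotations

import dataclasses
import json
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from zebrarep import features as feat
from zebrarep import repertoire as rep
from zebrarep import specprep
from zebrarep.individuality import dfa, kmo, nested_pdfa, pca_reduce
from zebrarep.synth import CALL_TYPES, CallRecord, SynthConfig, generate_dataset

MAX_REPERTOIRE_DURATION_S = 1.25
MIN_CALLS_PER_INDIVIDUAL = 5

ANNOTATION_COLUMNS = ["call_id", "file", "onset_s", "offset_s", "call_type",
                      "individual_id", "sex", "location"]


@dataclass
class ExclusionLog:
    """Per-call exclusion records: rule in {too_long, too_few_per_individual,
    missing_feature, bad_audio}."""

    entries: list[dict] = field(default_factory=list)

    def add(self, call_id: str, rule: str, detail: str = "") -> None:
        self.entries.append(dict(call_id=call_id, rule=rule, detail=detail))

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["call_id", "rule", "detail"])

    def __len__(self) -> int:
        return len(self.entries)


def load_annotations(csv_path: str | Path) -> tuple[list[CallRecord], pd.DataFrame]:
    """Load the annotation table into typed records.

    Malformed rows (offset <= onset, unknown call type) are collected and
    returned separately rather than aborting; a missing required column is
    fatal.
    """
    df = pd.read_csv(csv_path)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"annotation file missing required columns: {missing}")
    records, flagged = [], []
    for _, row in df.iterrows():
        try:
            records.append(CallRecord(
                call_id=str(row["call_id"]), file=str(row["file"]),
                onset_s=float(row["onset_s"]), offset_s=float(row["offset_s"]),
                call_type=str(row["call_type"]),
                individual_id=str(row["individual_id"]),
                sex=str(row["sex"]), location=str(row["location"])))
        except (ValueError, TypeError) as exc:
            flagged.append(dict(row=row.to_dict(), reason=str(exc)))
    return records, pd.DataFrame(flagged, columns=["row", "reason"])


def apply_inclusion_rules(records: list[CallRecord], mode: str
                          ) -> tuple[list[CallRecord], ExclusionLog]:
    """Apply the per-analysis inclusion rules; log every exclusion."""
    log = ExclusionLog()
    if mode == "repertoire":
        kept = []
        for r in records:
            if r.duration_s > MAX_REPERTOIRE_DURATION_S:
                log.add(r.call_id, "too_long",
                        f"duration {r.duration_s:.3f} s > {MAX_REPERTOIRE_DURATION_S} s")
            else:
                kept.append(r)
    elif mode == "individuality":
        counts: dict[tuple[str, str], int] = {}
        for r in records:
            key = (r.call_type, r.individual_id)
            counts[key] = counts.get(key, 0) + 1
        kept = []
        for r in records:
            n = counts[(r.call_type, r.individual_id)]
            if n < MIN_CALLS_PER_INDIVIDUAL:
                log.add(r.call_id, "too_few_per_individual",
                        f"{r.individual_id} has {n} {r.call_type} calls")
            else:
                kept.append(r)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if not kept:
        raise ValueError(f"no calls survive the {mode} inclusion rules")
    return kept, log


@dataclass
class PipelineConfig:
    """All knobs of an end-to-end run; validated before any stage starts."""

    output_dir: str = "results/pipeline"
    audio_dir: str | None = None          # None -> synthesize
    annotations: str | None = None
    seed: int = 0
    synth: dict = field(default_factory=dict)
    mel: dict = field(default_factory=dict)
    feature_split: dict = field(default_factory=lambda: dict(train=0.7, validation=0.0, test=0.3))
    spectrogram_split: dict = field(default_factory=lambda: dict(train=0.49, validation=0.21, test=0.30))
    shap_threshold: float = 1.0
    tuning_trials: int = 20
    k_max: int = 8
    pdfa: dict = field(default_factory=lambda: dict(n_permutations=1000, n_selections=100))
    individuality_types: tuple[str, ...] = ("snort", "squeal")
    restriction_factors: tuple[str, ...] = ("sex", "location")

    _KNOWN = None

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def __post_init__(self) -> None:
        for name, block in (("feature_split", self.feature_split),
                            ("spectrogram_split", self.spectrogram_split)):
            total = sum(block.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} fractions sum to {total}, expected 1")
        if self.tuning_trials < 1 or self.k_max < 2:
            raise ValueError("tuning_trials >= 1 and k_max >= 2 required")
        for t in self.individuality_types:
            if t not in CALL_TYPES:
                raise ValueError(f"unknown individuality call type {t!r}")


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run synth (optional) -> features/spectrograms -> repertoire ->
    individuality; write every artifact plus a manifest under the output
    directory. Returns the report bundle as a dict."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = dict(seed=config.seed)

    # --- data ------------------------------------------------------------
    if config.annotations is None:
        synth_cfg = SynthConfig(seed=config.seed, **config.synth)
        data_dir = out / "data"
        _, records, truth = generate_dataset(synth_cfg, data_dir)
        annotations_path = data_dir / "annotations.csv"
        bundle["synth"] = dict(n_calls=len(records))
    else:
        annotations_path = Path(config.annotations)
        records, flagged = load_annotations(annotations_path)
        bundle["flagged_rows"] = len(flagged)

    # resolve audio paths relative to the annotation file's directory
    root = Path(annotations_path).parent
    records = [dataclasses.replace(r, file=str(p if (p := Path(r.file)).is_absolute()
                                               else root / p))
               for r in records]

    # --- features --------------------------------------------------------
    table, failures = feat.extract_feature_table(records)
    table.to_csv(out / "features.csv", index=False)
    failures.to_csv(out / "feature_failures.csv", index=False)
    bundle["features"] = dict(n_extracted=len(table), n_failed=len(failures))

    # --- repertoire: supervised (features) -------------------------------
    rep_records, rep_log = apply_inclusion_rules(records, "repertoire")
    rep_ids = {r.call_id for r in rep_records}
    rep_table = table[table.call_id.isin(rep_ids)].copy()
    complete = rep_table.dropna(subset=list(rep.REPERTOIRE_FEATURES))
    for cid in rep_table.loc[rep_table[list(rep.REPERTOIRE_FEATURES)].isna().any(axis=1),
                             "call_id"]:
        rep_log.add(cid, "missing_feature", "incomplete repertoire features")
    rep_log.as_frame().to_csv(out / "exclusions_repertoire.csv", index=False)

    X = complete[list(rep.REPERTOIRE_FEATURES)]
    y = complete["call_type"].values
    selected, scores = rep.select_features_by_importance(
        X, y, threshold=config.shap_threshold, seed=config.seed)
    scores.to_csv(out / "shap_importances.csv", header=["importance"])
    model = rep.train_feature_classifier(
        X[selected], y, rep.SplitSpec(**config.feature_split, seed=config.seed),
        n_trials=config.tuning_trials, seed=config.seed)
    bundle["feature_classifier"] = dict(selected_features=selected,
                                        best_params=model.best_params,
                                        report=model.report.as_dict())

    # --- repertoire: supervised (spectrograms) ----------------------------
    by_id = {r.call_id: r for r in rep_records}
    specs = []
    for r in rep_records:
        wave = feat.read_wav(r.file)
        specs.append(specprep.mel_spectrogram(
            wave, specprep.MelParams(**config.mel), call_id=r.call_id))
    specs = specprep.pad_and_align(specs)
    spec_labels = np.array([by_id[s.call_id].call_type for s in specs])
    cnn_model = rep.train_spectrogram_classifier(
        specs, spec_labels,
        rep.SplitSpec(**config.spectrogram_split, seed=config.seed),
        seed=config.seed)
    bundle["spectrogram_classifier"] = dict(report=cnn_model.report.as_dict())

    # --- repertoire: unsupervised ----------------------------------------
    Xsel = (X[selected] - X[selected].mean()) / X[selected].std()
    clust = rep.repertoire_unsupervised(Xsel.values, y, mode="features",
                                        k_max=config.k_max, seed=config.seed)
    clust.type_cluster_matrix.to_csv(out / "clusters_features.csv")
    bundle["feature_clustering"] = dict(
        k=clust.k, overlap_coefficient=clust.overlap_coefficient,
        inertia=clust.inertia_by_k.tolist())

    # --- individuality ----------------------------------------------------
    ind_records, ind_log = apply_inclusion_rules(records, "individuality")
    ind_log.as_frame().to_csv(out / "exclusions_individuality.csv", index=False)
    ind_ids = {r.call_id for r in ind_records}
    bundle["individuality"] = {}
    for call_type in config.individuality_types:
        sub = table[(table.call_id.isin(ind_ids)) & (table.call_type == call_type)]
        cols = [c for c in feat.INDIVIDUALITY_FIELDS if sub[c].notna().all()]
        sub = sub.dropna(subset=cols)
        if sub.individual_id.nunique() < 2:
            bundle["individuality"][call_type] = dict(skipped="too few individuals")
            continue
        kmo_res = kmo(sub[cols])
        pca = pca_reduce(sub[kmo_res.retained])
        dfa_model = dfa(pca.scores, sub.individual_id.values,
                        component_names=pca.retained_components)
        entry = dict(
            kmo_overall=kmo_res.overall_msa, kmo_retained=kmo_res.retained,
            n_components=len(pca.retained_components),
            df_percent_variance=dfa_model.percent_variance.tolist())
        for factor in config.restriction_factors:
            res = nested_pdfa(pca.scores, sub.individual_id.values,
                              sub[factor].values, seed=config.seed,
                              restriction_name=factor, **config.pdfa)
            entry[f"pdfa_{factor}"] = dataclasses.asdict(res)
        bundle["individuality"][call_type] = entry

    # --- manifest ----------------------------------------------------------
    manifest = dict(
        config=dataclasses.asdict(config),
        annotations=str(annotations_path),
        annotations_hash=_hash_file(Path(annotations_path)),
        features_hash=_hash_file(out / "features.csv"),
        n_records=len(records),
    )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    (out / "report.json").write_text(json.dumps(bundle, indent=2, default=str))
    return bundle
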