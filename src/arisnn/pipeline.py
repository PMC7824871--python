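"""End-to-end pipeline: simulate -> encode -> train -> subtract -> features
-> classify -> anova -> report.

Each stage reads from and writes to a run directory so stages can be run
individually from the CLI; ``run_pipeline`` chains them.  Every run logs the
fully resolved configuration, and identical configurations reproduce all
numeric outputs.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import pathlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import io as aio
from . import readout as rd
from . import reservoir as rv
from . import stats as st
from . import synthetic as syn
from .encoding import EncodingParams, encode_tbr

log = logging.getLogger(__name__)

CLASSES = (st.RESPONDER, st.NONRESPONDER)


@dataclass
class PipelineConfig:
    """Resolved configuration for a full run (YAML-serializable)."""

    cohort: syn.CohortSpec = field(default_factory=syn.CohortSpec)
    encoding: EncodingParams = field(default_factory=EncodingParams)
    swc: rv.SWCParams = field(default_factory=rv.SWCParams)
    lif: rv.LIFParams = field(default_factory=rv.LIFParams)
    stdp: rv.STDPParams = field(default_factory=rv.STDPParams)
    readout: rd.ReadoutParams = field(default_factory=rd.ReadoutParams)
    window: int = 192
    epochs: int = 1
    exclusions: list[str] = field(default_factory=list)
    cv_unit: str = "sample"  # or "subject"
    template_path: str | None = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        kwargs = {}
        for name, sub_cls in [
            ("cohort", syn.CohortSpec),
            ("encoding", EncodingParams),
            ("swc", rv.SWCParams),
            ("lif", rv.LIFParams),
            ("stdp", rv.STDPParams),
            ("readout", rd.ReadoutParams),
        ]:
            if name in d:
                kwargs[name] = sub_cls(**d.pop(name))
        kwargs.update(d)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def _outdir(outdir, sub: str) -> pathlib.Path:
    p = pathlib.Path(outdir) / sub
    p.mkdir(parents=True, exist_ok=True)
    return p


def stage_simulate(config: PipelineConfig, outdir) -> list[syn.SubjectRecordingSet]:
    """Generate the synthetic cohort and write EEG + loudness CSVs."""
    data_dir = _outdir(outdir, "data")
    cohort = syn.generate_cohort(config.cohort)
    for subj in cohort:
        for (condition, timepoint), rec in sorted(subj.recordings.items()):
            path = data_dir / f"{subj.subject_id}_{condition}_{timepoint}.csv"
            aio.write_eeg_csv(rec, path)
        for condition, series in sorted(subj.loudness.items()):
            pd.DataFrame(
                {
                    "minute": range(len(series.ratings)),
                    "rating": series.ratings,
                    "phase": series.phases,
                }
            ).to_csv(data_dir / f"{subj.subject_id}_{condition}_loudness.csv", index=False)
    log.info("simulate: wrote %d subjects to %s", len(cohort), data_dir)
    return cohort


def load_cohort_dir(config: PipelineConfig, outdir) -> list[syn.SubjectRecordingSet]:
    """Rehydrate a cohort from a run directory written by ``stage_simulate``."""
    data_dir = pathlib.Path(outdir) / "data"
    subjects: dict[str, syn.SubjectRecordingSet] = {}
    for path in sorted(data_dir.glob("S*_*_T*.csv")):
        if path.name.endswith(".meta.txt"):
            continue
        rec = aio.read_eeg_csv(path)
        sid = rec.meta["subject"]
        subj = subjects.get(sid)
        if subj is None:
            subj = syn.SubjectRecordingSet(
                subject_id=sid, label=rec.meta["label"], recordings={}
            )
            subjects[sid] = subj
        subj.recordings[(rec.meta["condition"], rec.meta["timepoint"])] = rec
    if not subjects:
        raise FileNotFoundError(f"no recordings found under {data_dir}")
    return [subjects[k] for k in sorted(subjects)]


def stage_encode(config: PipelineConfig, dataset: aio.Dataset, outdir=None):
    """Encode every segment into spike trains (thresholds per sample)."""
    spikes = []
    for s in dataset.samples:
        sp = encode_tbr(
            s.data,
            config.encoding,
            channels=dataset.channel_labels,
            meta={
                "subject": s.subject,
                "condition": s.condition,
                "timepoint": s.timepoint,
                "index": s.index,
                "label": s.label,
                "sample_id": s.sample_id,
            },
        )
        spikes.append(sp)
    if outdir is not None:
        enc_dir = _outdir(outdir, "spikes")
        from .encoding import write_spikes_dense

        for sp in spikes:
            write_spikes_dense(sp, enc_dir / f"{sp.meta['sample_id']}.csv")
    log.info("encode: %d spike samples (alpha=%s)", len(spikes), config.encoding.alpha)
    return spikes


def _base_model(config: PipelineConfig) -> rv.ReservoirModel:
    template = rv.load_talairach_template(config.template_path)
    mapping = rv.default_input_mapping(template)
    return rv.init_swc(template, config.swc, mapping, config.lif, config.stdp)


def stage_train(
    config: PipelineConfig, spikes, outdir=None
) -> tuple[dict, dict, rv.ReservoirModel]:
    """Train the group and per-subject reservoir models.

    Group models: one per (label, condition, timepoint) on the concatenated
    samples of that cell (eight for a two-class cohort).  Subject models:
    one per (subject, condition, timepoint).  All models share one SWC
    initialization so weight structures are comparable/subtractable.
    """
    base = _base_model(config)
    group_models: dict[tuple[str, str, str], rv.ReservoirModel] = {}
    subject_models: dict[tuple[str, str, str], rv.ReservoirModel] = {}

    def bucket(keyfn):
        out: dict = {}
        for sp in spikes:
            out.setdefault(keyfn(sp.meta), []).append(sp)
        return out

    for (label, condition, timepoint), group in sorted(
        bucket(lambda m: (m["label"], m["condition"], m["timepoint"])).items()
    ):
        model = rv.train_stdp(base, group, epochs=config.epochs)
        model.trained_on.update(
            {"group": label, "condition": condition, "timepoint": timepoint}
        )
        group_models[(label, condition, timepoint)] = model
    for (subject, condition, timepoint), group in sorted(
        bucket(lambda m: (m["subject"], m["condition"], m["timepoint"])).items()
    ):
        model = rv.train_stdp(base, group, epochs=config.epochs)
        model.trained_on.update(
            {"subject": subject, "condition": condition, "timepoint": timepoint}
        )
        subject_models[(subject, condition, timepoint)] = model
    if outdir is not None:
        mdir = _outdir(outdir, "models")
        for (a, b, c), m in group_models.items():
            rv.save_model(m, mdir / f"group_{a}_{b}_{c}.csv")
        for (a, b, c), m in subject_models.items():
            rv.save_model(m, mdir / f"subject_{a}_{b}_{c}.csv")
    log.info(
        "train: %d group models, %d subject models (%d connections)",
        len(group_models),
        len(subject_models),
        base.n_connections,
    )
    return group_models, subject_models, base


def stage_subtract(group_models: dict, outdir=None) -> dict:
    """Connectivity deltas Wij(T2) - Wij(T1) per (label, condition)."""
    deltas = {}
    for (label, condition, timepoint), model in group_models.items():
        if timepoint != "T2":
            continue
        t1 = group_models.get((label, condition, "T1"))
        if t1 is None:
            continue
        deltas[(label, condition)] = rv.subtract_models(model, t1)
    if outdir is not None:
        mdir = _outdir(outdir, "models")
        for (a, b), d in deltas.items():
            rv.save_model(d, mdir / f"delta_{a}_{b}_T2-T1.csv")
    return deltas


def stage_features(
    config: PipelineConfig, subject_models: dict, labels: dict, outdir=None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-channel weight profiles and the hemisphere x site table."""
    prof_rows = []
    site_rows = []
    for (subject, condition, timepoint), model in sorted(subject_models.items()):
        profile = st.channel_weight_profile(model)
        for ch, val in profile.items():
            prof_rows.append(
                {
                    "subject": subject,
                    "condition": condition,
                    "timepoint": timepoint,
                    "channel": ch,
                    "weight": val,
                }
            )
        sites = st.group_sites(profile)
        for _, row in sites.iterrows():
            site_rows.append(
                {
                    "subject": subject,
                    "group": labels[subject],
                    "condition": condition,
                    "timepoint": timepoint,
                    "hemisphere": row["hemisphere"],
                    "site": row["site"],
                    "weight": row["value"],
                }
            )
    profiles = pd.DataFrame(prof_rows)
    site_table = pd.DataFrame(site_rows)
    if outdir is not None:
        fdir = _outdir(outdir, "features")
        profiles.to_csv(fdir / "channel_profiles.csv", index=False)
        site_table.to_csv(fdir / "site_table.csv", index=False)
    return profiles, site_table


def stage_classify(
    config: PipelineConfig, spikes, base: rv.ReservoirModel, outdir=None
) -> dict[str, rd.CVResult]:
    """Per condition: STDP-train a reservoir on all baseline (T1) samples,
    collect rasters, and run leave-one-out classification of the T2 label."""
    results: dict[str, rd.CVResult] = {}
    for condition in aio.CONDITIONS:
        t1 = [
            sp
            for sp in spikes
            if sp.meta["condition"] == condition and sp.meta["timepoint"] == "T1"
        ]
        if not t1:
            continue
        trained = rv.train_stdp(base, t1, epochs=config.epochs)
        rasters = [rv.run_sample(trained, sp) for sp in t1]
        labels = [sp.meta["label"] for sp in t1]
        ids = [sp.meta["sample_id"] for sp in t1]
        groups = [sp.meta["subject"] for sp in t1] if config.cv_unit == "subject" else None
        res = rd.loocv(
            rasters,
            labels,
            config.readout,
            sample_ids=ids,
            groups=groups,
            classes=CLASSES,
        )
        res.meta["condition"] = condition
        results[condition] = res
    if outdir is not None:
        cdir = _outdir(outdir, "classify")
        for condition, res in results.items():
            res.folds_frame().to_csv(cdir / f"{condition}_folds.csv", index=False)
            with (cdir / f"{condition}_summary.json").open("w") as fh:
                json.dump(_cv_summary(res), fh, indent=2)
    return results


def _cv_summary(res: rd.CVResult) -> dict:
    """Confusion matrix in the actual-rows / predicted-columns layout with
    per-class and total accuracies, plus a chance-level flag."""
    n = int(res.confusion.sum())
    counts = {c: int(res.confusion[i].sum()) for i, c in enumerate(res.classes)}
    # exchangeability null for a 1-NN style readout plus the majority rate
    p_null = sum(k * (k - 1) for k in counts.values()) / (n * (n - 1)) if n > 1 else 0.0
    p_major = max(counts.values()) / n
    acc = res.total_accuracy / 100.0
    half_width = 1.96 * np.sqrt(p_null * (1 - p_null) / n)
    at_chance = bool(acc <= max(p_null + half_width,
                                p_major + 1.96 * np.sqrt(p_major * (1 - p_major) / n)))
    return {
        "classes": list(res.classes),
        "confusion": {
            f"{actual} (actual)": {
                f"{predicted} (predicted)": int(res.confusion[i, j])
                for j, predicted in enumerate(res.classes)
            }
            for i, actual in enumerate(res.classes)
        },
        "class_accuracy_pct": res.class_accuracy,
        "total_accuracy_pct": res.total_accuracy,
        "n_samples": n,
        "chance_rate_nn": round(p_null, 4),
        "majority_rate": round(p_major, 4),
        "at_chance_level": at_chance,
    }


def stage_anova(site_table: pd.DataFrame, outdir=None) -> pd.DataFrame:
    """Mixed repeated-measures ANOVA on the site table (within: hemisphere,
    site, timepoint, condition; between: group)."""
    result = st.rm_anova(
        site_table,
        dv="weight",
        subject="subject",
        within=["hemisphere", "site", "timepoint", "condition"],
        between="group",
    )
    if outdir is not None:
        result.to_csv(_outdir(outdir, "anova") / "anova.csv", index=False)
    return result


def stage_report(
    config: PipelineConfig,
    cohort,
    group_models: dict,
    deltas: dict,
    cv_results: dict,
    anova: pd.DataFrame | None,
    subject_models: dict | None = None,
    outdir=None,
) -> dict:
    """Aggregate run outputs into a JSON report."""
    ari = {}
    for subj in cohort:
        changes = {c: st.ari_change(s) for c, s in subj.loudness.items()}
        ari[subj.subject_id] = {
            "changes": changes,
            "label": st.classify_responder(
                changes.get("C", 0), changes.get("AM", 0)
            ),
        }
    report = {
        "config": config.to_dict(),
        "ari": ari,
        "activation_levels": {
            "_".join(k): rv.activation_level(m) for k, m in sorted(group_models.items())
        },
        "delta_activation": {
            "_".join(k): rv.activation_level(d) for k, d in sorted(deltas.items())
        },
        "classification": {c: _cv_summary(r) for c, r in cv_results.items()},
    }
    if subject_models:
        temporal = {}
        for (subject, condition, timepoint), model in subject_models.items():
            if timepoint != "T2":
                continue
            t1 = subject_models.get((subject, condition, "T1"))
            if t1 is None:
                continue
            p1 = st.channel_weight_profile(t1)
            p2 = st.channel_weight_profile(model)
            temporal[f"{subject}_{condition}"] = st.temporal_delta(p1, p2)
        report["temporal_deltas"] = temporal
    if anova is not None:
        report["anova"] = anova.to_dict(orient="records")
    if outdir is not None:
        rdir = _outdir(outdir, "report")
        with (rdir / "report.json").open("w") as fh:
            json.dump(report, fh, indent=2, default=float)
    return report


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute the full pipeline into ``outdir`` and return the report."""
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config_resolved.yaml")
    log.info("run: resolved config written to %s", outdir / "config_resolved.yaml")

    def _stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # pragma: no cover - error path
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    cohort = _stage("simulate", stage_simulate, config, outdir)
    dataset = _stage(
        "assemble", aio.assemble_dataset, cohort, config.exclusions, config.window
    )
    spikes = _stage("encode", stage_encode, config, dataset, outdir)
    group_models, subject_models, base = _stage("train", stage_train, config, spikes, outdir)
    deltas = _stage("subtract", stage_subtract, group_models, outdir)
    labels = {subj.subject_id: subj.label for subj in cohort}
    _, site_table = _stage(
        "features", stage_features, config, subject_models, labels, outdir
    )
    cv_results = _stage("classify", stage_classify, config, spikes, base, outdir)
    anova = _stage("anova", stage_anova, site_table, outdir)
    return _stage(
        "report",
        stage_report,
        config,
        cohort,
        group_models,
        deltas,
        cv_results,
        anova,
        subject_models,
        outdir,
    )
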