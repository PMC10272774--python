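"""End-to-end pipeline: sessions -> synergies -> angle model -> reports.

Mirrors the experimental protocol: synergies are extracted per subject
and per session; the angle regressor is trained per amplitude group on
day-1 data (first set) pooled across the group's subjects, then applied
to every later session; accuracy is reported per day and stability as
matched-synergy CC across each subject's days.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .config import PipelineConfig
from .decompose import StoppingRule, _decompose, select_order
from .errors import ArgumentError, SynergyKitError
from .evaluate import AccuracyReport, accuracy_report, synergy_stability
from .kinematics import AngleTrace, angle_from_accel
from .preprocess import EnvelopeMatrix, concat_trials, make_envelope, normalize_channels
from .regress import BiLSTMRegressor, RegressorConfig, build_features, predict, train
from .synthetic import Recording, SessionSet, make_protocol


@dataclass
class PipelineResult:
    config: PipelineConfig
    r_selected: int
    accuracy: dict[str, AccuracyReport]
    stability: dict[str, dict] = field(default_factory=dict)
    models: dict[str, BiLSTMRegressor] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "config": self.config.to_dict(),
            "r_selected": self.r_selected,
            "accuracy": {g: rep.to_dict() for g, rep in self.accuracy.items()},
            "stability": self.stability,
        }


class _Stage:
    """Context manager labelling errors with the failing stage."""

    def __init__(self, name):
        self.name = name

    def __enter__(self):
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc is not None and isinstance(exc, SynergyKitError):
            exc.args = (f"[{self.name}] {exc.args[0]}",) + exc.args[1:]
        return False


def _prepare(rec: Recording, cfg: PipelineConfig) -> EnvelopeMatrix:
    env = rec.emg
    if not cfg.envelope_input:
        env = make_envelope(
            env.values, env.sampling_rate,
            band=(cfg.band_low, cfg.band_high), env_cutoff=cfg.env_cutoff,
        )
    return normalize_channels(env, cfg.normalize)


def _session_seed(base: int, subject: int, day: int, set_index: int) -> int:
    return int(
        np.random.SeedSequence([base, subject, day, set_index]).generate_state(1)[0]
        % (2**31)
    )


def run_pipeline(
    config: PipelineConfig,
    sessions: SessionSet | None = None,
    out_dir=None,
) -> PipelineResult:
    """Execute simulate/load -> preprocess -> decompose -> train -> predict
    -> evaluate and return the per-group reports.

    NMF decompositions draw a fresh random initialization per session
    (the instability the deterministic MCR-ALS initialization removes);
    MCR-ALS and PCA have no random state.
    """
    cfg = config
    stop = StoppingRule(cfg.q_tol, cfg.max_iter)

    with _Stage("simulate"):
        if sessions is None:
            sessions = make_protocol(
                n_subjects=cfg.n_subjects,
                n_days=cfg.n_days,
                seed=cfg.seed,
                group_split=cfg.group_split,
                amplitude_ratio=cfg.amplitude_ratio,
                n_channels=cfg.n_channels,
                r=cfg.n_synergies_true,
                n_cycles=cfg.n_cycles,
                samples_per_cycle=cfg.samples_per_cycle,
                noise_sigma=cfg.noise_sigma,
                sampling_rate=cfg.sampling_rate,
            )
        day1 = sessions.select(day=1, set_index=1)
        if not day1:
            raise ArgumentError("sessions contain no day-1 set-1 recording")

    with _Stage("preprocess"):
        prepared = {
            (r.subject, r.day, r.set_index): _prepare(r, cfg)
            for r in sessions.recordings
        }

    with _Stage("select_order"):
        if cfg.r == "auto":
            pooled = concat_trials([prepared[(r.subject, 1, 1)] for r in day1])
            r_selected = select_order(
                pooled.values,
                method=cfg.method,
                vaf_threshold=cfg.vaf_threshold,
                stop=stop,
                alpha=cfg.alpha,
                seed=cfg.seed,
            )
        else:
            r_selected = int(cfg.r)

    with _Stage("decompose"):
        decomps = {}
        for rec in sessions.recordings:
            key = (rec.subject, rec.day, rec.set_index)
            decomps[key] = _decompose(
                prepared[key].values,
                cfg.method,
                r_selected,
                stop=stop,
                alpha=cfg.alpha,
                seed=_session_seed(cfg.seed, *key),
            )

    with _Stage("angle"):
        angles = {
            (r.subject, r.day, r.set_index): angle_from_accel(
                r.accel, cutoff=cfg.angle_cutoff
            )
            for r in sessions.recordings
        }

    reg_cfg = RegressorConfig(
        n_layers=cfg.n_layers,
        hidden_units=cfg.hidden_units,
        dropout=cfg.dropout,
        window_length=cfg.window_length,
        stride=cfg.stride,
        epochs=cfg.epochs,
        learning_rate=cfg.learning_rate,
        batch_size=cfg.batch_size,
        seed=cfg.seed,
    )

    accuracy: dict[str, AccuracyReport] = {}
    stability: dict[str, dict] = {}
    models: dict[str, BiLSTMRegressor] = {}
    for group in sessions.group_labels:
        members = sorted({r.subject for r in sessions.recordings if r.group == group})

        # Features of deterministic methods are matched to the subject's
        # day-1 reference so feature k means the same synergy on every
        # day.  NMF features keep their native per-session order: the
        # random initialization makes that order unstable, which is the
        # baseline behaviour under study.
        deterministic = cfg.method in ("mcr_als", "mcr", "pca")

        with _Stage("train"):
            feats, angs = [], []
            for subj in members:
                ref = decomps[(subj, 1, 1)]
                feats.append(build_features(ref, reference=ref))
                angs.append(angles[(subj, 1, 1)].theta)
            features = np.hstack(feats)
            target = AngleTrace(np.concatenate(angs), sessions.sampling_rate)
            model = train(features, target, reg_cfg)
            models[group] = model

        with _Stage("predict"):
            preds: dict[int, AngleTrace] = {}
            actuals: dict[int, AngleTrace] = {}
            test_keys = [
                (r.subject, r.day, r.set_index)
                for r in sessions.recordings
                if r.group == group and not (r.day == 1 and r.set_index == 1)
            ]
            by_day: dict[int, list] = {}
            for key in sorted(test_keys):
                by_day.setdefault(key[1], []).append(key)
            for day, keys in sorted(by_day.items()):
                p_parts, a_parts = [], []
                for key in keys:
                    ref = decomps[(key[0], 1, 1)] if deterministic else None
                    F = build_features(decomps[key], reference=ref)
                    p_parts.append(
                        predict(model, F, sessions.sampling_rate).theta
                    )
                    a_parts.append(angles[key].theta)
                preds[day] = AngleTrace(
                    np.concatenate(p_parts), sessions.sampling_rate
                )
                actuals[day] = AngleTrace(
                    np.concatenate(a_parts), sessions.sampling_rate
                )

        with _Stage("evaluate"):
            accuracy[group] = accuracy_report(preds, actuals)
            per_subject = {}
            for subj in members:
                subj_decs = [decomps[(subj, 1, 1)]] + [
                    decomps[(subj, d, 1)]
                    for d in sessions.days
                    if d > 1 and (subj, d, 1) in decomps
                ]
                if len(subj_decs) >= 2:
                    rep = synergy_stability(subj_decs)
                    per_subject[str(subj)] = {"mean": rep.mean, "sd": rep.sd}
            group_means = [v["mean"] for v in per_subject.values()]
            stability[group] = {
                "per_subject": per_subject,
                "mean": float(np.mean(group_means)) if group_means else None,
                "method": cfg.method,
            }

    result = PipelineResult(
        config=cfg,
        r_selected=r_selected,
        accuracy=accuracy,
        stability=stability,
        models=models,
    )
    if out_dir is not None:
        _write_run(result, out_dir)
    return result


def _write_run(result: PipelineResult, out_dir):
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    result.config.to_yaml(out_dir / "config.yaml")
    report_path = out_dir / "report.json"
    report_path.write_text(
        json.dumps(result.to_dict(), indent=1, sort_keys=True)
    )
    manifest = {}
    for p in sorted(out_dir.iterdir()):
        if p.name == "manifest.json" or not p.is_file():
            continue
        manifest[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True)
    )
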