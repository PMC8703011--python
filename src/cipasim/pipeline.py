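"""End-to-end orchestration: dose-response fits -> paced simulations ->
biomarkers -> ANN training -> bootstrap evaluation.

A single :class:`RunConfig` drives the whole run.  Two scale presets exist:
``paper`` (2,000 bootstrap samples per drug, 1,000 beats per run, last 250
recorded, 10,000 test datasets) and ``desk`` (8 samples, 24 beats started from
the cached drug-free steady state, last 4 recorded, 500 datasets) sized so a
full synthetic-panel run finishes in minutes on one CPU.

Per-stage seeds are derived deterministically from one master seed; the ODE
stage is seed-free, so changing the master seed changes bootstrap draws and
dataset sampling but never the simulated trajectories.  Averaged feature rows
are cached per configuration hash, so classifier/evaluation iteration never
re-runs the ODE sweep.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import biomarkers as bm
from . import cardiac_sim as cs
from . import dose_response as dr
from . import evaluation as ev
from . import risk_classifier as rc
from . import synthetic_data as sd

log = logging.getLogger("cipasim")

CONC_MULTIPLES = (1.0, 2.0, 3.0, 4.0)


@dataclass(frozen=True)
class ScalePreset:
    n_samples: int
    n_beats_drug: int
    record_last: int
    n_datasets: int


PRESETS = {
    "paper": ScalePreset(n_samples=2000, n_beats_drug=1000, record_last=250,
                         n_datasets=10000),
    "desk": ScalePreset(n_samples=8, n_beats_drug=24, record_last=4,
                        n_datasets=500),
}


@dataclass
class RunConfig:
    out_dir: str
    scale: str = "desk"
    master_seed: int = 0
    # synthetic-panel settings (ignored when CSV inputs are given)
    n_train_per_class: int = 4
    n_test: tuple = (5, 6, 5)
    dr_noise_sd: float = 0.05
    # optional external inputs
    dose_response_csv: str | None = None
    metadata_csv: str | None = None
    conc_multiples: tuple = CONC_MULTIPLES
    cell: cs.CellModelConfig = field(default_factory=cs.CellModelConfig)
    control_protocol: cs.PacingProtocol = field(default_factory=cs.PacingProtocol)
    ann: rc.AnnConfig = field(default_factory=rc.AnnConfig)
    custom_preset: ScalePreset | None = None

    @property
    def preset(self) -> ScalePreset:
        return self.custom_preset or PRESETS[self.scale]

    def stage_seeds(self) -> dict:
        ss = np.random.SeedSequence(self.master_seed)
        names = ("library", "noise", "bootstrap", "ann", "datasets")
        children = ss.spawn(len(names))
        return {
            n: int(c.generate_state(1)[0] % (2**31 - 1))
            for n, c in zip(names, children)
        }

    def content_hash(self) -> str:
        doc = dataclasses.asdict(self)
        doc.pop("out_dir")
        blob = json.dumps(doc, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


class StageError(RuntimeError):
    def __init__(self, stage, detail, cause):
        super().__init__(f"stage {stage!r} failed at {detail}: {cause}")
        self.stage = stage
        self.detail = detail


def make_synthetic_inputs(config: RunConfig):
    """Synthetic panel -> (dose-response frame, metadata frame)."""
    seeds = config.stage_seeds()
    drugs = sd.gen_drug_panel(
        seed=seeds["library"],
        n_train_per_class=config.n_train_per_class,
        n_test=tuple(config.n_test),
    )
    return sd.library_to_frames(
        drugs, noise_sd=config.dr_noise_sd, seed=seeds["noise"]
    )


def load_inputs(config: RunConfig):
    if config.dose_response_csv and config.metadata_csv:
        return (
            pd.read_csv(config.dose_response_csv),
            pd.read_csv(config.metadata_csv),
        )
    return make_synthetic_inputs(config)


def fit_samples(config: RunConfig, dr_frame: pd.DataFrame,
                meta: pd.DataFrame) -> list[dr.DrugSampleSet]:
    seeds = config.stage_seeds()
    rng = np.random.default_rng(seeds["bootstrap"])
    tables = sd.frames_to_tables(dr_frame)
    meta_i = meta.set_index("drug")
    sets = []
    for drug in meta["drug"]:
        try:
            sets.append(
                dr.fit_drug(
                    tables.get(drug, {}),
                    cmax=float(meta_i.loc[drug, "cmax_nM"]),
                    risk_label=str(meta_i.loc[drug, "label"]),
                    drug=str(drug),
                    n_samples=config.preset.n_samples,
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
            )
        except Exception as e:  # noqa: BLE001 - annotate and re-raise
            raise StageError("dose_response", f"drug={drug}", e) from e
    return sets


def control_run(config: RunConfig, cache_dir: str | None = None):
    """Drug-free reference: steady state, capture amplitude, representative
    beat features and (AUC_INaL, AUC_ICaL)."""
    state, amp = cs.steady_state_control(
        config.cell, config.control_protocol, cache_dir=cache_dir
    )
    proto = cs.PacingProtocol(
        bcl=config.control_protocol.bcl,
        n_beats=config.preset.n_beats_drug,
        record_last=config.preset.record_last,
        stim_duration=config.control_protocol.stim_duration,
        stim_amplitude=config.control_protocol.stim_amplitude,
        dt_out=config.control_protocol.dt_out,
    )
    traces = cs.run_paced(config.cell, cs.NO_BLOCK, proto,
                          initial_state=state, stim_amplitude=amp)
    i = bm.select_ap(traces)
    if i == bm.NO_VALID_BEAT:
        raise StageError("cardiac_sim", "control run", "no valid control beat")
    beat = traces[i]
    control_auc = (beat.auc_inal, beat.auc_ical)
    fv = bm.compute_features(beat, control_auc, proto.bcl)
    return state, amp, proto, control_auc, fv


def simulate_features(
    config: RunConfig,
    sample_sets: list[dr.DrugSampleSet],
    cache_dir: str | None = None,
) -> pd.DataFrame:
    """Per-(drug, sample) averaged feature rows over the 1-4x Cmax sweep.

    Columns: drug, label, split (joined later), sample_id, the nine features,
    and a status flag; rows where any concentration lost all beats are flagged
    missing and dropped from downstream stages (with a logged count).
    """
    state, amp, proto, control_auc, _ = control_run(config, cache_dir)
    rows = []
    n_missing = 0
    t0 = time.time()
    for ss in sample_sets:
        for sid, sample in enumerate(ss.samples):
            fvs = []
            for mult in config.conc_multiples:
                d = mult * ss.cmax
                try:
                    block = cs.scale_conductances(config.cell, sample, d)
                    traces = cs.run_paced(
                        config.cell, block, proto,
                        initial_state=state, stim_amplitude=amp,
                    )
                except Exception as e:  # noqa: BLE001
                    raise StageError(
                        "cardiac_sim",
                        f"(drug={ss.drug}, sample={sid}, conc={d:.3g} nM)", e,
                    ) from e
                i = bm.select_ap(traces)
                if i == bm.NO_VALID_BEAT:
                    fvs.append(None)
                else:
                    fvs.append(
                        bm.compute_features(traces[i], control_auc, proto.bcl)
                    )
            avg = bm.average_concentrations(fvs)
            row = {"drug": ss.drug, "label": ss.risk_label, "sample_id": sid}
            if avg is None:
                n_missing += 1
                row["status"] = "missing"
                for f in bm.FEATURE_NAMES:
                    row[f] = np.nan
            else:
                row["status"] = "ok"
                row.update(dict(zip(bm.FEATURE_NAMES, avg.to_array())))
            rows.append(row)
        log.info("simulated %s (%d samples), %.1f s elapsed",
                 ss.drug, len(ss.samples), time.time() - t0)
    if n_missing:
        log.warning("%d (drug, sample) rows flagged missing and excluded",
                    n_missing)
    return pd.DataFrame(rows)


def run_all(config: RunConfig, cache_dir: str | None = None) -> dict:
    """Execute every stage and write the artifact set to ``config.out_dir``.

    Artifacts: samples.csv, features_avg.csv, loo_report.csv, model.json,
    eval_report.json, manifest.json.  Idempotent: if features_avg.csv for the
    same configuration hash already exists it is reused.
    """
    os.makedirs(config.out_dir, exist_ok=True)
    chash = config.content_hash()
    seeds = config.stage_seeds()

    dr_frame, meta = load_inputs(config)
    sample_sets = fit_samples(config, dr_frame, meta)
    dr.samples_to_frame(sample_sets).to_csv(
        os.path.join(config.out_dir, "samples.csv"), index=False
    )

    feat_path = os.path.join(config.out_dir, "features_avg.csv")
    manifest_path = os.path.join(config.out_dir, "manifest.json")
    features = None
    if os.path.exists(feat_path) and os.path.exists(manifest_path):
        with open(manifest_path) as fh:
            if json.load(fh).get("config_hash") == chash:
                features = pd.read_csv(feat_path)
                log.info("reusing cached features for config %s", chash)
    if features is None:
        features = simulate_features(config, sample_sets, cache_dir)
        features = features.merge(meta[["drug", "split"]], on="drug")
        features.to_csv(feat_path, index=False)

    ok = features[features["status"] == "ok"]
    train_tab = ok[ok["split"] == "TRAINING"]
    test_tab = ok[ok["split"] == "TESTING"].reset_index(drop=True)

    ann_cfg = rc.AnnConfig(
        **{**dataclasses.asdict(config.ann), "seed": seeds["ann"]}
    )
    loo = rc.loo_cv(train_tab, ann_cfg)
    loo.to_csv(os.path.join(config.out_dir, "loo_report.csv"), index=False)
    model, scaler = rc.train_final(train_tab, ann_cfg)
    with open(os.path.join(config.out_dir, "model.json"), "w") as fh:
        fh.write(model.to_json(scaler))

    preds = rc.predict_proba(
        model, scaler, test_tab[list(bm.FEATURE_NAMES)].to_numpy()
    )
    proba = np.array([p.class_probs for p in preds])
    predicted = [p.predicted_class for p in preds]
    report = ev.evaluate_model(
        test_tab, proba, predicted,
        n_datasets=config.preset.n_datasets, seed=seeds["datasets"],
    )
    with open(os.path.join(config.out_dir, "eval_report.json"), "w") as fh:
        json.dump(report, fh, indent=1)

    manifest = {
        "config_hash": chash,
        "stage_seeds": seeds,
        "scale": config.scale,
        "preset": dataclasses.asdict(config.preset),
        "conc_multiples": list(config.conc_multiples),
        "n_drugs": int(meta.shape[0]),
        "n_train_rows": int(len(train_tab)),
        "n_test_rows": int(len(test_tab)),
        "n_missing_rows": int((features["status"] == "missing").sum()),
    }
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1)
    return {
        "features": features,
        "loo": loo,
        "model": model,
        "scaler": scaler,
        "report": report,
        "manifest": manifest,
    }


def paper_arithmetic(n_train_drugs: int = 12, n_test_drugs: int = 16) -> dict:
    """Bookkeeping of the paper-scale protocol, computed from the presets
    without simulation."""
    p = PRESETS["paper"]
    return {
        "train_rows": n_train_drugs * p.n_samples,
        "recorded_beats": p.record_last,
        "total_beats": cs.PacingProtocol().n_beats,
        "n_datasets": p.n_datasets,
        "rows_per_dataset": n_test_drugs,
    }
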