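"""Run configuration: YAML round-trip, validation, seeding, and the
end-to-end experiment driver (calibration then copy-spelling).

Every stochastic step derives its seed from the master seed through a
``numpy.random.SeedSequence`` spawn, so an identical config + seed yields
an identical result bundle. All output files embed a hash of the config.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from charstream import decoding, paradigm, preprocess, sequential, synth
from charstream.features import fit_pipeline

logger = logging.getLogger(__name__)


@dataclass
class GeneratorConfig:
    montage: int = 16  # 16 or 63 EEG channels (plus 2 EOG)
    fs: float = 200.0
    noise_scale: float = 4.0
    noise_exponent: float = 1.0
    neighbor_gain: float | None = None  # None = condition default
    eye_artifact_rate: float = 0.0  # events/min
    eye_artifact_amplitude: float = 60.0
    eye_artifact_p_target_locked: float = 0.5

    def channels(self) -> tuple[str, ...]:
        if self.montage == 16:
            return synth.MONTAGE_16
        if self.montage == 63:
            return synth.MONTAGE_63
        raise ValueError("generator.montage must be 16 or 63")


@dataclass
class PreprocessConfig:
    highpass: float = 0.2
    lowpass: float = 25.0
    window: tuple[float, float] = (-1000.0, 1000.0)
    baseline: tuple[float, float] | None = None
    reject_threshold: float = 70.0
    projection: bool = True


@dataclass
class ClassifierConfig:
    n_intervals: int = 5
    m_grid: tuple[int, ...] = tuple(range(10))
    algorithms: tuple[str, ...] = ("lda", "sparse-lda")
    lam: float = 0.01
    cv_folds: int = 5


@dataclass
class StoppingConfig:
    min_iterations: int = 5
    alpha: float = 0.05
    budget_iterations_smallest: int = 15


@dataclass
class RunConfig:
    seed: int = 0
    output_dir: str = "charstream_run"
    condition: str = "C"
    soa_group: float | None = None
    n_iterations: int = 14
    n_calibration_trials: int = 15
    sentence: str = decoding.PROTOCOL_SENTENCE
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    preprocessing: PreprocessConfig = field(default_factory=PreprocessConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    stopping: StoppingConfig = field(default_factory=StoppingConfig)

    def to_dict(self) -> dict:
        return asdict(self)

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


_SECTIONS = {
    "generator": GeneratorConfig,
    "preprocessing": PreprocessConfig,
    "classifier": ClassifierConfig,
    "stopping": StoppingConfig,
}


def config_from_dict(d: dict) -> RunConfig:
    d = dict(d or {})
    kwargs = {}
    for section, cls in _SECTIONS.items():
        sub = d.pop(section, {})
        if not isinstance(sub, dict):
            raise ValueError(f"config section {section!r} must be a mapping")
        valid = cls.__dataclass_fields__
        for key in sub:
            if key not in valid:
                raise ValueError(f"unknown field {section}.{key!r}")
        sub = {
            k: tuple(v) if isinstance(v, list) else v for k, v in sub.items()
        }
        kwargs[section] = cls(**sub)
    valid = RunConfig.__dataclass_fields__
    for key in d:
        if key not in valid:
            raise ValueError(f"unknown config field {key!r}")
    return RunConfig(**d, **kwargs)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh))


def save_config(config: RunConfig, path) -> None:
    plain = json.loads(json.dumps(config.to_dict()))  # tuples -> lists
    with open(path, "w") as fh:
        yaml.safe_dump(plain, fh, sort_keys=False)


def draw_calibration_targets(
    alphabet, n_trials: int, rng: np.random.Generator
) -> list[str]:
    """Draw calibration targets covering all three streams.

    Group-resolved sub-classifiers (groupwise, spatial) can only be trained
    for streams that contain at least one calibration target, so targets
    are dealt round-robin across L/M/R before drawing symbols within each
    stream.
    """
    groups = ["L", "M", "R"]
    per_group = [n_trials // 3 + (1 if i < n_trials % 3 else 0) for i in range(3)]
    targets: list[str] = []
    for g, n_g in zip(groups, per_group):
        pool = alphabet.group_symbols(g)
        targets.extend(rng.choice(pool, size=n_g, replace=n_g > len(pool)))
    perm = rng.permutation(len(targets))
    return [targets[i] for i in perm]


def _spawn_seeds(master: int, n: int) -> list[int]:
    return [
        int(s.generate_state(1)[0] % (2**31 - 1))
        for s in np.random.SeedSequence(master).spawn(n)
    ]


@dataclass
class CalibratedModels:
    """Everything fit on calibration data (and nothing else)."""

    bank: sequential.SubClassifierBank
    meta: sequential.MetaModel
    standard: object  # FittedPipeline: the non-sequential baseline
    projection: preprocess.ProjectionOperator | None
    filter_spec: preprocess.FilterSpec
    rejection_report: dict


def simulate_calibration(config: RunConfig, seed: int | None = None):
    """Generate a calibration session: schedule + synthetic recording."""
    seed = config.seed if seed is None else seed
    s_targets, s_sched, s_eeg, s_art = _spawn_seeds(seed, 4)
    rng = np.random.default_rng(s_targets)
    alphabet = paradigm.build_alphabet()
    targets = draw_calibration_targets(alphabet, config.n_calibration_trials, rng)
    pconf = paradigm.ParadigmConfig(
        condition=config.condition,
        soa_group=config.soa_group,
        n_iterations=config.n_iterations,
        seed=s_sched,
    )
    schedule = paradigm.generate_schedule(pconf, targets, alphabet)
    profile = synth.default_profile(config.condition, config.generator.neighbor_gain)
    recording = synth.synthesize(
        schedule,
        profile,
        fs=config.generator.fs,
        channels=config.generator.channels(),
        noise_scale=config.generator.noise_scale,
        noise_exponent=config.generator.noise_exponent,
        seed=s_eeg,
    )
    if config.generator.eye_artifact_rate > 0:
        recording = synth.inject_eye_artifacts(
            recording,
            rate=config.generator.eye_artifact_rate,
            amplitude=config.generator.eye_artifact_amplitude,
            p_target_locked=config.generator.eye_artifact_p_target_locked,
            seed=s_art,
        )
    return schedule, recording


def calibrate(config: RunConfig, recording=None) -> CalibratedModels:
    """Fit preprocessing operators and classifiers on calibration data."""
    if recording is None:
        _, recording = simulate_calibration(config)
    pp = config.preprocessing
    spec = preprocess.FilterSpec(highpass=pp.highpass, lowpass=pp.lowpass)
    filtered = preprocess.bandpass(recording, spec)
    projection = None
    if pp.projection:
        projection = preprocess.fit_ocular_projection(filtered)
        filtered = preprocess.apply_projection(projection, filtered)
    epochs = preprocess.epoch(filtered, window=tuple(pp.window),
                              baseline=pp.baseline)
    epochs, report = preprocess.minmax_reject(epochs, threshold=pp.reject_threshold)

    cc = config.classifier
    sets = sequential.build_training_sets(epochs)
    bank = sequential.train_bank(sets, k=cc.cv_folds, n_intervals=cc.n_intervals)
    meta = sequential.train_meta(
        bank, epochs, m_grid=cc.m_grid, algorithms=cc.algorithms,
        k=cc.cv_folds, lam=cc.lam,
    )
    standard = fit_pipeline(epochs, n_intervals=cc.n_intervals)
    return CalibratedModels(
        bank=bank,
        meta=meta,
        standard=standard,
        projection=projection,
        filter_spec=spec,
        rejection_report=report,
    )


def make_online_preprocessor(config: RunConfig, models: CalibratedModels):
    """Online preprocessing closure: filter + fixed projection + epoching."""
    pp = config.preprocessing

    def _preprocess(recording):
        filtered = preprocess.bandpass(recording, models.filter_spec)
        if models.projection is not None:
            filtered = preprocess.apply_projection(models.projection, filtered)
        return preprocess.epoch(filtered, window=tuple(pp.window),
                                baseline=pp.baseline)

    return _preprocess


def make_synth_fn(config: RunConfig):
    profile = synth.default_profile(config.condition, config.generator.neighbor_gain)

    def _synth(schedule, seed):
        return synth.synthesize(
            schedule,
            profile,
            fs=config.generator.fs,
            channels=config.generator.channels(),
            noise_scale=config.generator.noise_scale,
            noise_exponent=config.generator.noise_exponent,
            seed=seed,
        )

    return _synth


def spell(config: RunConfig, models: CalibratedModels, classifier: str = "meta",
          seed: int | None = None) -> decoding.SpellingResult:
    """Run the copy-spelling simulation with calibration-trained models."""
    seed = (config.seed + 1) if seed is None else seed
    if classifier == "meta":
        def score_fn(epochs):
            return sequential.apply_sequential(models.meta, models.bank, epochs)
    elif classifier == "standard":
        def score_fn(epochs):
            return models.standard.outputs(epochs)
    else:
        raise ValueError("classifier must be 'meta' or 'standard'")
    alphabet = paradigm.build_alphabet()
    budget = paradigm.stimulus_budget(
        alphabet,
        config.soa_group or paradigm.CONDITION_DEFAULTS[config.condition][0],
        min_iter=config.stopping.min_iterations,
        budget_iterations_smallest=config.stopping.budget_iterations_smallest,
    )
    rule = decoding.StoppingRule(
        min_iterations=config.stopping.min_iterations,
        max_iterations={g: mx for g, (_, mx) in budget.items()},
        alpha=config.stopping.alpha,
    )
    pconf = paradigm.ParadigmConfig(
        condition=config.condition, soa_group=config.soa_group,
        n_iterations=config.n_iterations,
    )
    return decoding.copy_spell_simulation(
        config.sentence,
        score_fn,
        pconf,
        make_synth_fn(config),
        make_online_preprocessor(config, models),
        rule=rule,
        alphabet=alphabet,
        seed=seed,
    )


def run_experiment(config: RunConfig) -> dict:
    """Full protocol: calibrate, spell, and write the result bundle."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.hash()
    try:
        save_config(config, out / "config.yaml")
        schedule, recording = simulate_calibration(config)
        schedule.to_tsv(out / "calibration_events.tsv")
        models = calibrate(config, recording)
        sequential.save_bundle(out / "models.json", models.bank, models.meta, chash)
        result = spell(config, models, classifier="meta")
        result.table.to_csv(out / "spelling.csv", index=False)
        summary = {
            "config_hash": chash,
            "meta_m": models.meta.m,
            "meta_algorithm": models.meta.algorithm,
            "active_families": list(models.bank.active_families),
            "rejection": models.rejection_report,
            **result.summary(),
        }
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=1)
        return summary
    except Exception:
        # remove partial outputs so a failed run leaves no stale bundle
        for name in ("models.json", "spelling.csv", "summary.json"):
            p = out / name
            if p.exists():
                p.unlink()
        raise
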