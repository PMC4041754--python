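"""Sub-classifier bank, accuracy gate, sequence features, and the meta model."""

import numpy as np
import pandas as pd
import pytest

import charstream as cs
from charstream.config import draw_calibration_targets
from charstream.features import FittedPipeline, IntervalSet, LinearModel, fit_pipeline
from charstream.preprocess import EpochSet
from charstream.sequential import (
    SubClassifier,
    SubClassifierBank,
    apply_sequential,
    assemble_sequence_features,
    build_training_sets,
    train_bank,
    train_meta,
)
from charstream.synth import default_profile


class TestBuildTrainingSets:
    @pytest.fixture(scope="class")
    def full_calibration_sets(self):
        """Condition-C calibration at protocol scale: 15 trials x 14 iters.

        Built from the schedule metadata only (synthetic epochs with tiny
        data payload) so the counting checks are exact and fast.
        """
        alpha = cs.build_alphabet()
        targets = ["A"] * 5 + ["K"] * 5 + ["U"] * 5  # 5 per group
        sched = cs.generate_schedule(
            cs.ParadigmConfig(condition="C", n_iterations=14), targets, alpha
        )
        rows = []
        for ti, trial in enumerate(sched.trials):
            for e in trial.events:
                rows.append(
                    {
                        "trial": ti,
                        "sample": int(e.onset * 10) + ti * 10**6,
                        "symbol": e.symbol,
                        "group": e.group,
                        "iteration": e.iteration,
                        "is_target": e.is_target,
                        "is_pretarget": e.is_pretarget,
                        "is_posttarget": e.is_posttarget,
                        "trial_target": trial.target,
                        "trial_target_group": alpha.group_of[trial.target],
                    }
                )
        md = pd.DataFrame(rows)
        eset = EpochSet(
            data=np.zeros((len(md), 1, 2)),
            window=(-1000.0, 1000.0),
            fs=100.0,
            channels=("Cz",),
            metadata=md,
        )
        return build_training_sets(eset)

    def test_global_ratio_is_one_to_29(self, full_calibration_sets):
        _, y, _ = full_calibration_sets["global"]
        assert y.sum() == 210
        assert len(y) - y.sum() == 6090

    def test_pretarget_pairing(self, full_calibration_sets):
        _, y, _ = full_calibration_sets["pretarget"]
        n_targets = y.sum()
        n_pre = len(y) - n_targets
        # class 2 size equals the number of targets with an in-trial
        # same-group predecessor
        assert n_targets - 15 <= n_pre <= n_targets

    def test_posttarget_pairing(self, full_calibration_sets):
        _, y, _ = full_calibration_sets["posttarget"]
        assert y.sum() - 15 <= len(y) - y.sum() <= y.sum()

    def test_groupwise_ratio(self, full_calibration_sets):
        _, y, _ = full_calibration_sets["groupwise_M"]
        # group M: 10 symbols, 1 target per iteration
        assert y.sum() == 5 * 14
        assert len(y) == 15 * 10 * 14

    def test_spatial_ratio_five_of_fifteen(self, full_calibration_sets):
        """5 of 15 targets in group L: class ratio 5*126 : 10*126."""
        _, y, _ = full_calibration_sets["spatial_L"]
        assert y.sum() == 5 * 126
        assert len(y) - y.sum() == 10 * 126

    def test_empty_class_skipped_with_warning(self, cal_epochs):
        md = cal_epochs.metadata
        only_L = cal_epochs.subset((md["trial_target_group"] == "L").to_numpy())
        with pytest.warns(UserWarning):
            sets = build_training_sets(only_L)
        assert "spatial_L" not in sets  # class 2 would be empty


def _toy_bank(n_families=1):
    """A bank whose members are irrelevant; used with explicit outputs."""
    member = SubClassifier(
        name="global",
        pipeline=FittedPipeline(
            intervals=IntervalSet(((0.0, 10.0),)),
            model=LinearModel(w=np.ones(1), b=0.0, kind="lda", regularization=0.0),
        ),
        cv_accuracy=1.0,
        gated_in=True,
        out_mean=0.0,
        out_sd=1.0,
    )
    return SubClassifierBank(members={"global": member})


def _flag_epochs(n_iterations=3, targets=("E", "M")):
    alpha = cs.build_alphabet()
    sched = cs.generate_schedule(
        cs.ParadigmConfig(condition="C", n_iterations=n_iterations), list(targets), alpha
    )
    rows = []
    for ti, trial in enumerate(sched.trials):
        for e in trial.events:
            rows.append(
                {
                    "trial": ti,
                    "sample": int(e.onset * 10) + ti * 10**7,
                    "symbol": e.symbol,
                    "group": e.group,
                    "iteration": e.iteration,
                    "is_target": e.is_target,
                    "is_pretarget": e.is_pretarget,
                    "is_posttarget": e.is_posttarget,
                    "trial_target": trial.target,
                    "trial_target_group": alpha.group_of[trial.target],
                }
            )
    md = pd.DataFrame(rows)
    return EpochSet(
        data=np.zeros((len(md), 1, 2)),
        window=(-1000.0, 1000.0),
        fs=100.0,
        channels=("Cz",),
        metadata=md,
    )


class TestAssembleSequenceFeatures:
    def test_dimension_formula(self):
        eset = _flag_epochs()
        outputs = np.zeros((eset.n_epochs, 5))
        X = assemble_sequence_features(_toy_bank(), eset, 9, family_outputs=outputs)
        assert X.shape[1] == 5 * (2 * 9 + 1)

    def test_m_zero_is_identity(self):
        eset = _flag_epochs()
        outputs = np.random.default_rng(0).normal(size=(eset.n_epochs, 1))
        X = assemble_sequence_features(_toy_bank(), eset, 0, family_outputs=outputs)
        assert np.array_equal(X, outputs)

    def test_window_carries_neighbour_outputs(self):
        """With one-hot outputs on the flagged triple, the target's window
        shows its same-group neighbours at pooled offsets ±3."""
        eset = _flag_epochs()
        md = eset.metadata
        marked = (md.is_target | md.is_pretarget | md.is_posttarget).to_numpy()
        outputs = marked.astype(float)[:, None]
        X = assemble_sequence_features(_toy_bank(), eset, 3, family_outputs=outputs)
        tgt = md.is_target.to_numpy()
        win = X[tgt].mean(axis=0)
        assert win[3] == 1.0  # itself
        assert win[0] > 0.9 and win[6] > 0.9  # pre / post at ±3
        assert win[1] < 0.2 and win[2] < 0.2  # other-group positions

    def test_trial_boundary_zero_padding(self):
        eset = _flag_epochs(n_iterations=2)
        outputs = np.ones((eset.n_epochs, 1))
        X = assemble_sequence_features(_toy_bank(), eset, 2, family_outputs=outputs)
        md = eset.metadata
        first_idx = md.sort_values(["trial", "sample"]).index[0]
        assert np.array_equal(X[first_idx], [0.0, 0.0, 1.0, 1.0, 1.0])

    def test_invalid_m_rejected(self):
        eset = _flag_epochs()
        with pytest.raises(ValueError):
            assemble_sequence_features(_toy_bank(), eset, 10)


@pytest.fixture(scope="module")
def trained_bank_meta(cal_epochs):
    sets = build_training_sets(cal_epochs)
    bank = train_bank(sets)
    meta = train_meta(bank, cal_epochs, m_grid=(0, 1, 2, 3))
    return bank, meta


class TestBankAndGate:
    def test_shuffled_labels_are_gated_out(self, cal_epochs):
        rng = np.random.default_rng(0)
        sets = build_training_sets(cal_epochs)
        sub, y, idx = sets["global"]
        y_shuffled = rng.permutation(y)
        bank = train_bank({"global": (sub, y_shuffled, idx)})
        member = bank.members["global"]
        assert abs(member.cv_accuracy - 0.5) < 0.08
        assert not member.gated_in

    def test_separable_data_is_gated_in(self, trained_bank_meta):
        bank, _ = trained_bank_meta
        assert bank.members["global"].gated_in
        assert "global" in bank.active_families

    def test_gate_is_strictly_greater_than_65(self):
        member = SubClassifier(
            name="x",
            pipeline=None,
            cv_accuracy=0.65,
            gated_in=0.65 > 0.65,  # the bank's gate rule
            out_mean=0.0,
            out_sd=1.0,
        )
        bank = SubClassifierBank(members={"global": member})
        assert not member.gated_in
        assert "global" not in bank.active_families

    def test_gate_threshold_parameter(self, cal_epochs):
        sets = build_training_sets(cal_epochs)
        subset = {k: sets[k] for k in ("global",)}
        all_out = train_bank(subset, gate=1.0)
        assert not all_out.members["global"].gated_in
        all_in = train_bank(subset, gate=0.0)
        assert all_in.members["global"].gated_in


class TestMetaModel:
    def test_meta_improves_or_matches_global_cv(self, trained_bank_meta):
        bank, meta = trained_bank_meta
        table = meta.cv_table
        assert {"m", "algorithm", "cv_accuracy"} <= set(table.columns)
        assert meta.m in range(4)
        assert meta.algorithm in ("lda", "sparse-lda")

    def test_no_sequential_structure_meta_matches_global(self):
        """With stimulation so slow that epochs never overlap and without
        neighbour responses, the window carries no information and the
        selected meta performs like the global classifier."""
        from conftest import make_calibration

        # SOA 6 s: adjacent epochs (±1 s windows) share no samples
        profile = default_profile("A", neighbor_gain=0.0)

        def session(seed):
            alpha = cs.build_alphabet()
            rng = np.random.default_rng(seed)
            targets = draw_calibration_targets(alpha, 4, rng)
            config = cs.ParadigmConfig(
                condition="A", soa_group=6000.0, n_iterations=4, seed=seed
            )
            sched = cs.generate_schedule(config, targets, alpha)
            rec = cs.bandpass(
                cs.synthesize(sched, profile, fs=100.0, noise_scale=3.0, seed=seed)
            )
            return alpha, cs.epoch(rec)

        alpha, cal = session(23)
        bank = train_bank(build_training_sets(cal), k=4)
        meta = train_meta(bank, cal, m_grid=(0, 1, 2), k=4)
        std = fit_pipeline(cal)
        _, test = session(24)
        from charstream.decoding import aggregate_scores, decide_and_rank

        rates = {}
        for name, out in (
            ("meta", apply_sequential(meta, bank, test)),
            ("std", std.outputs(test)),
        ):
            md = test.metadata
            hits = []
            for t in sorted(md["trial"].unique()):
                mask = (md["trial"] == t).to_numpy()
                scores = aggregate_scores(out[mask], md[mask], alpha)
                _, rank = decide_and_rank(
                    scores, md[mask]["trial_target"].iloc[0]
                )
                hits.append(rank == 1)
            rates[name] = np.mean(hits)
        assert abs(rates["meta"] - rates["std"]) <= 0.25

    def test_apply_is_deterministic(self, trained_bank_meta, cal_epochs):
        bank, meta = trained_bank_meta
        o1 = apply_sequential(meta, bank, cal_epochs)
        o2 = apply_sequential(meta, bank, cal_epochs)
        assert np.array_equal(o1, o2)

    def test_order_sensitivity_for_positive_m(self, trained_bank_meta, cal_epochs):
        """Permuting epochs within a trial changes outputs when m >= 1."""
        bank, _ = trained_bank_meta
        meta = train_meta(bank, cal_epochs, m_grid=(2,))
        # reassign the within-trial presentation order (keep epoch content)
        shuffled = cal_epochs.subset(np.arange(cal_epochs.n_epochs))
        rng = np.random.default_rng(1)
        md = shuffled.metadata
        for t in md["trial"].unique():
            rows = np.flatnonzero((md["trial"] == t).to_numpy())
            samples = md.loc[rows, "sample"].to_numpy()
            md.loc[rows, "sample"] = rng.permutation(samples)
        o_orig = apply_sequential(meta, bank, cal_epochs)
        o_perm = apply_sequential(meta, bank, shuffled)
        assert not np.allclose(o_orig, o_perm)

    def test_no_leakage_models_depend_only_on_calibration(self, cal_epochs):
        """Retraining after generating unrelated test data is bit-identical."""
        import json

        from conftest import make_calibration

        def fingerprint():
            sets = build_training_sets(cal_epochs)
            bank = train_bank(sets)
            meta = train_meta(bank, cal_epochs, m_grid=(0, 1))
            return json.dumps(
                {"bank": bank.to_dict(), "meta": meta.to_dict()}, sort_keys=True
            )

        fp1 = fingerprint()
        make_calibration(seed=99, n_trials=2, n_iterations=2)  # unrelated data
        fp2 = fingerprint()
        assert fp1 == fp2
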