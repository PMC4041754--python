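"""Sequential meta-classification for fixed-order stimulus streams.

With a fixed alphabetical stimulus order, the classifier outputs of the
stimuli immediately before and after a target behave target-like, which
systematically distorts the 30-class decision. This module implements the
remedy: a bank of five binary sub-classifier families trained on different
slices of the calibration data, a cross-validated accuracy gate, and a
second-level ("sequential") discriminant over the windowed sub-classifier
outputs of stimuli i-m ... i+m.

Sub-classifier families (class 1 : class 2 ratios in parentheses):

* ``global`` — all targets vs. all non-targets (1/29);
* ``groupwise`` — one classifier per stream L/M/R, targets vs. non-targets
  of that stream (≈1/9);
* ``pretarget`` — targets vs. the same-stream stimuli presented one SOA
  before a target (1/1);
* ``posttarget`` — targets vs. the same-stream stimuli one SOA after a
  target (1/1);
* ``spatial`` — one classifier per stream, stimuli of that stream from
  trials whose target lives in the stream vs. from other trials (≈1/2).

Only families whose cross-validated balanced accuracy exceeds 65% feed the
meta-classifier, which therefore sees up to 5 x (2m + 1) dimensions. The
window half-width m in {0..9} and the algorithm (dense vs. sparse LDA) are
chosen by trial-blocked 5-fold cross-validation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


from charstream.features import (
    FittedPipeline,
    LinearModel,
    balanced_accuracy,
    fit_pipeline,
    _blocked_folds,
)
from charstream.preprocess import EpochSet

FAMILIES = ("global", "groupwise", "pretarget", "posttarget", "spatial")
GROUPS = ("L", "M", "R")

GATE_THRESHOLD = 0.65  # strictly-greater gate on CV balanced accuracy


def build_training_sets(epochs: EpochSet) -> dict[str, tuple[EpochSet, np.ndarray]]:
    """Per-sub-classifier training sets as (epoch subset, labels) pairs.

    Keys: ``global``, ``groupwise_L/M/R``, ``pretarget``, ``posttarget``,
    ``spatial_L/M/R``. Specs whose classes would be empty are skipped with
    a warning.
    """
    md = epochs.metadata
    is_t = md["is_target"].to_numpy().astype(bool)
    is_pre = md["is_pretarget"].to_numpy().astype(bool)
    is_post = md["is_posttarget"].to_numpy().astype(bool)
    group = md["group"].to_numpy()
    tgt_group = md["trial_target_group"].to_numpy()

    sets: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    sets["global"] = (is_t, ~is_t)
    for g in GROUPS:
        in_g = group == g
        sets[f"groupwise_{g}"] = (is_t & in_g, ~is_t & in_g)
    sets["pretarget"] = (is_t, is_pre & ~is_t)
    sets["posttarget"] = (is_t, is_post & ~is_t)
    for g in GROUPS:
        in_g = group == g
        sets[f"spatial_{g}"] = (in_g & (tgt_group == g), in_g & (tgt_group != g))

    out: dict[str, tuple[EpochSet, np.ndarray, np.ndarray]] = {}
    for name, (c1, c2) in sets.items():
        if not c1.any() or not c2.any():
            warnings.warn(f"sub-classifier {name!r}: empty class, skipped")
            continue
        mask = c1 | c2
        out[name] = (
            epochs.subset(mask),
            c1[mask].astype(int),
            np.flatnonzero(mask),  # row indices into the parent epoch set
        )
    return out


@dataclass
class SubClassifier:
    """One trained member of the bank with its gate and output scaling.

    ``oof_outputs`` are the member's out-of-fold outputs on its own
    training epochs (``train_indices`` rows of the calibration epoch set).
    Stacked training of the meta-classifier uses these instead of
    in-sample outputs, which would be optimistically separated and teach
    the meta miscalibrated weights.
    """

    name: str
    pipeline: FittedPipeline
    cv_accuracy: float
    gated_in: bool
    out_mean: float  # standardization constants (background class, OOF)
    out_sd: float
    train_indices: np.ndarray | None = None
    oof_outputs: np.ndarray | None = None

    def standardized_outputs(self, epochs: EpochSet) -> np.ndarray:
        raw = self.pipeline.outputs(epochs)
        return (raw - self.out_mean) / self.out_sd


@dataclass
class SubClassifierBank:
    """The five sub-classifier families (nine trained discriminants).

    ``members`` maps the training-set keys to trained sub-classifiers.
    A family is active if at least one of its members passed the >65%
    cross-validated accuracy gate; gated-out members contribute zeros.
    """

    members: dict[str, SubClassifier]

    def member_for(self, family: str, group: str) -> SubClassifier | None:
        key = family if family in ("global", "pretarget", "posttarget") else f"{family}_{group}"
        return self.members.get(key)

    @property
    def active_families(self) -> tuple[str, ...]:
        active = []
        for fam in FAMILIES:
            keys = (
                [fam]
                if fam in ("global", "pretarget", "posttarget")
                else [f"{fam}_{g}" for g in GROUPS]
            )
            if any(
                k in self.members and self.members[k].gated_in for k in keys
            ):
                active.append(fam)
        return tuple(active)

    def family_outputs(self, epochs: EpochSet, oof: bool = False) -> np.ndarray:
        """Standardized gated outputs, one column per active family.

        Group-resolved families (groupwise, spatial) evaluate each epoch
        with the classifier of the epoch's own stream; epochs whose stream
        classifier is missing or gated out get 0 (the standardized scale's
        neutral value).

        With ``oof=True`` the epochs must be the calibration set the bank
        was trained on; outputs on each member's own training rows are
        replaced by its out-of-fold predictions (stacked generalization),
        removing in-sample optimism before meta training.
        """
        groups = epochs.metadata["group"].to_numpy()
        fams = self.active_families
        out = np.zeros((epochs.n_epochs, len(fams)))

        def member_out(member: SubClassifier, rows: np.ndarray) -> np.ndarray:
            vals = member.standardized_outputs(epochs.subset(rows))
            if oof and member.oof_outputs is not None:
                if member.train_indices.max() >= epochs.n_epochs:
                    raise ValueError(
                        "oof outputs require the bank's calibration epochs"
                    )
                std_oof = (member.oof_outputs - member.out_mean) / member.out_sd
                oof_of_row = dict(zip(member.train_indices, std_oof))
                for i, r in enumerate(rows):
                    if r in oof_of_row:
                        vals[i] = oof_of_row[r]
            return vals

        all_rows = np.arange(epochs.n_epochs)
        for j, fam in enumerate(fams):
            if fam in ("global", "pretarget", "posttarget"):
                member = self.members.get(fam)
                if member is not None and member.gated_in:
                    out[:, j] = member_out(member, all_rows)
            else:
                for g in GROUPS:
                    member = self.members.get(f"{fam}_{g}")
                    if member is None or not member.gated_in:
                        continue
                    rows = np.flatnonzero(groups == g)
                    if rows.size:
                        out[rows, j] = member_out(member, rows)
        return out

    def to_dict(self) -> dict:
        return {
            name: {
                "cv_accuracy": m.cv_accuracy,
                "gated_in": m.gated_in,
                "out_mean": m.out_mean,
                "out_sd": m.out_sd,
                "intervals": [list(iv) for iv in m.pipeline.intervals],
                "model": m.pipeline.model.to_dict(),
            }
            for name, m in self.members.items()
        }


def _cv_pipeline_accuracy(
    epochs: EpochSet, y: np.ndarray, k: int, n_intervals: int
) -> tuple[float, np.ndarray]:
    """CV balanced accuracy plus out-of-fold real-valued outputs."""
    groups = epochs.metadata["trial"].to_numpy()
    accs = []
    oof = np.zeros(len(y))
    for tr, te in _blocked_folds(groups, y, k):
        pipe = fit_pipeline(epochs.subset(tr), y[tr], n_intervals=n_intervals)
        out_te = pipe.outputs(epochs.subset(te))
        oof[te] = out_te
        accs.append(balanced_accuracy(y[te], (out_te > 0).astype(int)))
    return float(np.mean(accs)), oof


def train_bank(
    training_sets: dict[str, tuple[EpochSet, np.ndarray]],
    k: int = 5,
    n_intervals: int = 5,
    gate: float = GATE_THRESHOLD,
) -> SubClassifierBank:
    """Train every sub-classifier with the identical automated procedure.

    For each training set: trial-blocked k-fold CV of the full pipeline
    (interval selection re-run inside each fold), refit on the whole set,
    store the CV balanced accuracy and the mean/sd of the training outputs
    for standardization. The gate admits only accuracies strictly greater
    than ``gate`` (default 65%).
    """
    members: dict[str, SubClassifier] = {}
    for name, (sub_epochs, y, parent_idx) in training_sets.items():
        counts = np.bincount(y, minlength=2)
        if counts.min() < 4:
            warnings.warn(f"sub-classifier {name!r}: too few samples, skipped")
            continue
        try:
            cv_acc, oof = _cv_pipeline_accuracy(sub_epochs, y, k, n_intervals)
        except ValueError as err:
            warnings.warn(f"sub-classifier {name!r}: CV failed ({err}), skipped")
            continue
        pipe = fit_pipeline(sub_epochs, y, n_intervals=n_intervals)
        # standardize on the out-of-fold background (class 2) outputs so
        # that group-resolved classifiers are comparable across streams
        # and the scale is honest about generalization
        ref = oof[y == 0]
        sd = float(ref.std())
        members[name] = SubClassifier(
            name=name,
            pipeline=pipe,
            cv_accuracy=cv_acc,
            gated_in=cv_acc > gate,
            out_mean=float(ref.mean()),
            out_sd=sd if sd > 0 else 1.0,
            train_indices=parent_idx,
            oof_outputs=oof,
        )
    return SubClassifierBank(members=members)


def _epoch_order(epochs: EpochSet) -> tuple[np.ndarray, np.ndarray]:
    """(trial ids, permutation sorting epochs by trial then onset sample)."""
    md = epochs.metadata
    trials = md["trial"].to_numpy()
    order = np.lexsort((md["sample"].to_numpy(), trials))
    return trials, order


def assemble_sequence_features(
    bank: SubClassifierBank,
    epochs: EpochSet,
    m: int,
    family_outputs: np.ndarray | None = None,
) -> np.ndarray:
    """Windowed sub-classifier outputs for each epoch.

    For epoch i the feature vector concatenates, for j = i-m ... i+m in
    within-trial stimulus order, the standardized outputs of every active
    family evaluated on epoch j. Positions outside the trial contribute 0,
    keeping the dimensionality fixed at n_active_families x (2m + 1).
    """
    if not 0 <= m <= 9:
        raise ValueError("m must be in {0, ..., 9}")
    out = bank.family_outputs(epochs) if family_outputs is None else family_outputs
    n, f = out.shape
    trials, order = _epoch_order(epochs)
    feats = np.zeros((n, f * (2 * m + 1)))
    pos_in_order = np.empty(n, int)
    pos_in_order[order] = np.arange(n)
    ordered_trials = trials[order]
    ordered_out = out[order]
    for offset in range(-m, m + 1):
        col = offset + m
        src = np.arange(n) + offset
        valid = (src >= 0) & (src < n)
        src_c = np.clip(src, 0, n - 1)
        same_trial = ordered_trials[src_c] == ordered_trials
        take = valid & same_trial
        block = np.zeros((n, f))
        block[take] = ordered_out[src_c[take]]
        feats[order, col * f : (col + 1) * f] = block
    return feats


@dataclass
class MetaModel:
    """The sequential classifier: window half-width, algorithm, weights."""

    m: int
    algorithm: str  # "lda" | "sparse-lda"
    model: LinearModel
    active_families: tuple[str, ...]
    cv_table: pd.DataFrame | None = None  # CV accuracy over the (m, algo) grid

    def to_dict(self) -> dict:
        return {
            "m": self.m,
            "algorithm": self.algorithm,
            "active_families": list(self.active_families),
            "model": self.model.to_dict(),
            "cv_table": None
            if self.cv_table is None
            else self.cv_table.to_dict(orient="records"),
        }


def _fit_meta(X: np.ndarray, y: np.ndarray, algorithm: str, lam: float) -> LinearModel:
    from charstream.features import train_shrinkage_lda, train_sparse_lda

    if algorithm == "lda":
        return train_shrinkage_lda(X, y)
    return train_sparse_lda(X, y, lam=lam)


def _fold_rank_metric(
    outputs: np.ndarray, md: pd.DataFrame
) -> tuple[float, float]:
    """(rank-1 rate, mean target rank) of per-trial 30-class decisions.

    Symbol scores are the mean outputs over each symbol's occurrences;
    ranking ties break alphabetically, as in the online decision rule.
    """
    rank1 = []
    ranks = []
    for t in md["trial"].unique():
        rows = (md["trial"] == t).to_numpy()
        sub = md[rows]
        target = sub["trial_target"].iloc[0]
        means = (
            pd.Series(outputs[rows], index=sub["symbol"].to_numpy())
            .groupby(level=0)
            .mean()
        )
        order = sorted(means.index, key=lambda s: (-means[s], s))
        r = order.index(target) + 1
        ranks.append(r)
        rank1.append(r == 1)
    return float(np.mean(rank1)), float(np.mean(ranks))


def train_meta(
    bank: SubClassifierBank,
    epochs: EpochSet,
    labels: np.ndarray | None = None,
    m_grid: tuple[int, ...] = tuple(range(10)),
    algorithms: tuple[str, ...] = ("lda", "sparse-lda"),
    k: int = 5,
    lam: float = 0.01,
    family_outputs: np.ndarray | None = None,
    selection: str = "rank",
) -> MetaModel:
    """Select (m, algorithm) by trial-blocked 5-fold CV and refit.

    The meta discriminant is trained on the bank's out-of-fold outputs
    (stacked generalization), so its weights reflect how the
    sub-classifiers behave on data they were not fit to.

    Model selection maximizes, per held-out fold, the speller's own target
    metric: the rank-1 rate of the 30-class decision, with mean target
    rank as first tie-break (``selection="rank"``, default). Binary
    balanced accuracy is available via ``selection="binary"``; both CV
    metrics are kept in the returned table. Remaining ties break toward
    smaller m, then dense LDA. The final model is refit on the full
    calibration set.
    """
    if selection not in ("rank", "binary"):
        raise ValueError("selection must be 'rank' or 'binary'")
    y = epochs.labels if labels is None else np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("degenerate labels for meta training")
    fam_out = (
        bank.family_outputs(epochs, oof=True)
        if family_outputs is None
        else family_outputs
    )
    if fam_out.shape[1] == 0:
        raise ValueError("no sub-classifier family passed the accuracy gate")
    md = epochs.metadata
    groups = md["trial"].to_numpy()
    rows = []
    best = None
    for m in sorted(m_grid):
        X = assemble_sequence_features(bank, epochs, m, family_outputs=fam_out)
        folds = _blocked_folds(groups, y, k)
        for algo in algorithms:
            accs, rank1s, mranks = [], [], []
            for tr, te in folds:
                model = _fit_meta(X[tr], y[tr], algo, lam)
                from charstream.features import score as _score

                out_te = _score(model, X[te])
                accs.append(balanced_accuracy(y[te], (out_te > 0).astype(int)))
                r1, mr = _fold_rank_metric(out_te, md.iloc[te])
                rank1s.append(r1)
                mranks.append(mr)
            acc = float(np.mean(accs))
            r1 = float(np.mean(rank1s))
            mr = float(np.mean(mranks))
            rows.append({"m": m, "algorithm": algo, "cv_accuracy": acc,
                         "cv_rank1": r1, "cv_mean_rank": mr})
            key = (r1, -mr) if selection == "rank" else (acc,)
            # strict > keeps the first (smaller m, dense-LDA-first) optimum
            if best is None or key > best[0]:
                best = (key, m, algo)
    _, m_star, algo_star = best
    X = assemble_sequence_features(bank, epochs, m_star, family_outputs=fam_out)
    model = _fit_meta(X, y, algo_star, lam)
    return MetaModel(
        m=m_star,
        algorithm=algo_star,
        model=model,
        active_families=bank.active_families,
        cv_table=pd.DataFrame(rows),
    )


def nested_cv_accuracy(
    bank: SubClassifierBank,
    epochs: EpochSet,
    labels: np.ndarray | None = None,
    m_grid: tuple[int, ...] = tuple(range(10)),
    algorithms: tuple[str, ...] = ("lda", "sparse-lda"),
    k_outer: int = 5,
    k_inner: int = 4,
    lam: float = 0.01,
) -> float:
    """Nested CV estimate of the sequential classifier's binary accuracy.

    The outer folds are held out entirely; (m, algorithm) is selected by
    inner CV on each outer training set, so the reported accuracy carries
    no model-selection optimism.
    """
    y = epochs.labels if labels is None else np.asarray(labels).astype(int)
    groups = epochs.metadata["trial"].to_numpy()
    fam_out = bank.family_outputs(epochs, oof=True)
    accs = []
    for tr, te in _blocked_folds(groups, y, k_outer):
        inner = epochs.subset(tr)
        meta = train_meta(
            bank, inner, y[tr], m_grid=m_grid, algorithms=algorithms,
            k=k_inner, lam=lam, family_outputs=fam_out[tr],
        )
        X_te = assemble_sequence_features(bank, epochs, meta.m, family_outputs=fam_out)[te]
        from charstream.features import score as _score

        pred = (_score(meta.model, X_te) > 0).astype(int)
        accs.append(balanced_accuracy(y[te], pred))
    return float(np.mean(accs))


def apply_sequential(
    meta: MetaModel,
    bank: SubClassifierBank,
    epochs: EpochSet,
) -> np.ndarray:
    """Per-epoch sequential classifier outputs (higher = more target-like)."""
    if tuple(meta.active_families) != bank.active_families:
        raise ValueError("meta model was trained with a different family gating")
    X = assemble_sequence_features(bank, epochs, meta.m)
    from charstream.features import score as _score

    return _score(meta.model, X)


def train_sequential_classifier(
    epochs: EpochSet,
    m_grid: tuple[int, ...] = tuple(range(10)),
    algorithms: tuple[str, ...] = ("lda", "sparse-lda"),
    k: int = 5,
    lam: float = 0.01,
) -> tuple[SubClassifierBank, MetaModel]:
    """Convenience wrapper: build training sets, train the bank, train the meta."""
    sets = build_training_sets(epochs)
    bank = train_bank(sets, k=k)
    meta = train_meta(bank, epochs, m_grid=m_grid, algorithms=algorithms, k=k, lam=lam)
    return bank, meta


def save_bundle(path, bank: SubClassifierBank, meta: MetaModel, config_hash: str = "") -> None:
    """Serialize bank + meta model to a single JSON bundle."""
    with open(path, "w") as fh:
        json.dump(
            {"config_hash": config_hash, "bank": bank.to_dict(), "meta": meta.to_dict()},
            fh,
            indent=1,
        )
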