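"""Stimulus paradigm: 30-symbol alphabet, three-group split, and timed schedules.

The speller presents the 26 letters plus 4 command items as three parallel
streams (left / middle / right voice). Streams are interleaved at equal
phase offsets of ``soa_group / 3`` so the pooled stimulus rate is three
times the within-group rate, while no two stimuli ever share an onset.

Three experimental conditions are supported:

========= ============ ======================
condition soa_group     within-group order
========= ============ ======================
A         750 ms        pseudo-random
B         250 ms        pseudo-random
C         250 ms        fixed (alphabetical)
========= ============ ======================

Condition C is the sequential paradigm proper: the user always knows when
the target symbol will be presented.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

GROUPS = ("L", "M", "R")

LETTERS = tuple(chr(ord("A") + i) for i in range(26))
COMMANDS = ("<SPACE>", "<DEL>", "<UNDO>", "<END>")
SYMBOLS = LETTERS + COMMANDS

DEFAULT_SPLIT = (9, 10, 11)

#: condition -> (soa_group ms, order)
CONDITION_DEFAULTS = {
    "A": (750.0, "pseudo-random"),
    "B": (250.0, "pseudo-random"),
    "C": (250.0, "alphabetical"),
}


class ConfigurationError(ValueError):
    """Raised for invalid paradigm configurations."""


@dataclass(frozen=True)
class Alphabet:
    """The 30-symbol alphabet and its partition into groups L, M, R."""

    symbols: tuple[str, ...]
    group_of: dict[str, str]

    def group_symbols(self, group: str) -> list[str]:
        """Symbols of one group, in alphabet order."""
        return [s for s in self.symbols if self.group_of[s] == group]

    @property
    def group_sizes(self) -> dict[str, int]:
        sizes = {g: 0 for g in GROUPS}
        for g in self.group_of.values():
            sizes[g] += 1
        return sizes


def build_alphabet(split: tuple[int, int, int] = DEFAULT_SPLIT) -> Alphabet:
    """Split the 30 symbols into three consecutive groups of sizes 9/10/11.

    Parameters
    ----------
    split
        Sizes of groups L, M, R. Must be ``(9, 10, 11)`` and cover all 30
        symbols; the split is consecutive (A–I / J–S / T–Z plus commands by
        default).
    """
    if tuple(split) != DEFAULT_SPLIT:
        raise ConfigurationError(
            f"group sizes must be {DEFAULT_SPLIT} (got {tuple(split)})"
        )
    if sum(split) != len(SYMBOLS):
        raise ConfigurationError("split must cover all 30 symbols")
    group_of: dict[str, str] = {}
    start = 0
    for g, size in zip(GROUPS, split):
        for s in SYMBOLS[start : start + size]:
            group_of[s] = g
        start += size
    return Alphabet(symbols=SYMBOLS, group_of=group_of)


@dataclass(frozen=True)
class ParadigmConfig:
    """Timing and ordering parameters for one stimulation condition."""

    condition: str = "C"
    soa_group: float | None = None  # ms; None -> condition default
    n_iterations: int = 14
    order: str | None = None  # None -> condition default
    seed: int = 0
    stimulus_duration: float = 225.0  # ms, metadata only

    def __post_init__(self):
        if self.condition not in CONDITION_DEFAULTS:
            raise ConfigurationError(f"unknown condition {self.condition!r}")
        soa_default, order_default = CONDITION_DEFAULTS[self.condition]
        if self.soa_group is None:
            object.__setattr__(self, "soa_group", soa_default)
        if self.order is None:
            object.__setattr__(self, "order", order_default)
        if self.soa_group <= 0:
            raise ConfigurationError("soa_group must be positive")
        if self.condition == "C" and self.order != "alphabetical":
            raise ConfigurationError("condition C requires alphabetical order")
        if self.condition in ("A", "B") and self.order != "pseudo-random":
            raise ConfigurationError(
                f"condition {self.condition} requires pseudo-random order"
            )
        if self.n_iterations < 1:
            raise ConfigurationError("n_iterations must be >= 1")


@dataclass(frozen=True)
class StimulusEvent:
    """One auditory stimulus within a trial."""

    onset: float  # ms from trial start
    symbol: str
    group: str
    iteration: int
    is_target: bool = False
    is_pretarget: bool = False  # same-group predecessor of a target
    is_posttarget: bool = False  # same-group successor of a target


@dataclass(frozen=True)
class Trial:
    target: str
    events: tuple[StimulusEvent, ...]

    @property
    def duration(self) -> float:
        return max(e.onset for e in self.events)


@dataclass(frozen=True)
class StimulusSchedule:
    """Timed, labelled stimulus events for one or more trials."""

    trials: tuple[Trial, ...]
    config: ParadigmConfig
    alphabet: Alphabet

    @property
    def n_events(self) -> int:
        return sum(len(t.events) for t in self.trials)

    @property
    def n_targets(self) -> int:
        return sum(sum(e.is_target for e in t.events) for t in self.trials)

    def to_records(self) -> list[dict]:
        rows = []
        for i, trial in enumerate(self.trials):
            for e in trial.events:
                rows.append(
                    {
                        "trial": i,
                        "onset_ms": e.onset,
                        "symbol": e.symbol,
                        "group": e.group,
                        "iteration": e.iteration,
                        "is_target": int(e.is_target),
                        "is_pretarget": int(e.is_pretarget),
                        "is_posttarget": int(e.is_posttarget),
                    }
                )
        return rows

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.to_records()).to_csv(path, sep="\t", index=False)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "config": {
                        "condition": self.config.condition,
                        "soa_group": self.config.soa_group,
                        "n_iterations": self.config.n_iterations,
                        "order": self.config.order,
                        "seed": self.config.seed,
                    },
                    "events": self.to_records(),
                },
                fh,
                indent=1,
            )


def _group_orders(
    alphabet: Alphabet,
    group: str,
    n_iterations: int,
    order: str,
    rng: np.random.Generator,
) -> list[list[str]]:
    """Within-group symbol order for each iteration.

    Pseudo-random orders draw a fresh permutation per iteration with the
    constraint that the last symbol of iteration k never reopens iteration
    k+1 (avoids back-to-back repeats of the same sound).
    """
    symbols = alphabet.group_symbols(group)
    if order == "alphabetical":
        return [list(symbols) for _ in range(n_iterations)]
    orders: list[list[str]] = []
    prev_last: str | None = None
    for _ in range(n_iterations):
        perm = list(rng.permutation(symbols))
        if perm[0] == prev_last:
            perm[0], perm[1] = perm[1], perm[0]
        orders.append(perm)
        prev_last = perm[-1]
    return orders


def generate_schedule(
    config: ParadigmConfig,
    targets: list[str],
    alphabet: Alphabet | None = None,
    n_iterations_per_group: dict[str, int] | None = None,
) -> StimulusSchedule:
    """Build the stimulus schedule for a sequence of target symbols.

    Each trial presents every symbol of every group once per iteration.
    Groups L/M/R run at phase offsets 0, soa/3, 2·soa/3 so that the pooled
    onset series cycles L, M, R, ... and no two events coincide.

    Parameters
    ----------
    config
        Condition, group-wise SOA, iteration count, ordering and seed.
    targets
        One target symbol per trial.
    alphabet
        Defaults to the standard 9/10/11 split.
    n_iterations_per_group
        Optional per-group iteration counts (used by dynamic stopping,
        where smaller groups may iterate more often). Defaults to
        ``config.n_iterations`` for every group.
    """
    if alphabet is None:
        alphabet = build_alphabet()
    for t in targets:
        if t not in alphabet.symbols:
            raise ConfigurationError(f"unknown target symbol {t!r}")
    soa = config.soa_group
    offsets = {g: i * soa / 3.0 for i, g in enumerate(GROUPS)}
    rng = np.random.default_rng(config.seed)

    trials = []
    for target in targets:
        tgt_group = alphabet.group_of[target]
        events: list[StimulusEvent] = []
        for g in GROUPS:
            n_iter = (
                n_iterations_per_group[g]
                if n_iterations_per_group is not None
                else config.n_iterations
            )
            orders = _group_orders(alphabet, g, n_iter, config.order, rng)
            flat = [
                (it, sym) for it, iteration in enumerate(orders) for sym in iteration
            ]
            # locate targets in the flat stream, then flag +-1 neighbours
            tgt_idx = {
                k for k, (_, sym) in enumerate(flat) if g == tgt_group and sym == target
            }
            for k, (it, sym) in enumerate(flat):
                events.append(
                    StimulusEvent(
                        onset=offsets[g] + k * soa,
                        symbol=sym,
                        group=g,
                        iteration=it,
                        is_target=k in tgt_idx,
                        is_pretarget=(k + 1) in tgt_idx,
                        is_posttarget=(k - 1) in tgt_idx,
                    )
                )
        events.sort(key=lambda e: e.onset)
        trials.append(Trial(target=target, events=tuple(events)))
    return StimulusSchedule(trials=tuple(trials), config=config, alphabet=alphabet)


def perceived_soa(schedule: StimulusSchedule) -> float:
    """Pooled stimulus onset asynchrony across all three streams, in ms.

    Computed as the median difference between consecutive onsets pooled
    across groups (within trials). For equal phase offsets this equals
    ``soa_group / 3``.
    """
    diffs: list[np.ndarray] = []
    for trial in schedule.trials:
        onsets = np.sort([e.onset for e in trial.events])
        if len(onsets) >= 2:
            diffs.append(np.diff(onsets))
    if not diffs:
        raise ValueError("perceived SOA undefined for schedules with < 2 events")
    return float(np.median(np.concatenate(diffs)))


def stimulus_budget(
    alphabet: Alphabet,
    soa_group: float,
    min_iter: int = 5,
    budget_iterations_smallest: int = 15,
) -> dict[str, tuple[int, int]]:
    """Per-group (min, max) iteration bounds for dynamic stopping.

    Every group gets the same floor (default 5 iterations). The ceiling is
    derived from a shared stimulation-time budget — the time the smallest
    group needs for ``budget_iterations_smallest`` iterations — so larger
    groups get proportionally fewer maximal repetitions (12–15 for group
    sizes 9/10/11).
    """
    if min_iter < 1:
        raise ConfigurationError("min_iter must be >= 1")
    sizes = alphabet.group_sizes
    smallest = min(sizes.values())
    budget_ms = budget_iterations_smallest * smallest * soa_group
    out: dict[str, tuple[int, int]] = {}
    for g, size in sizes.items():
        max_iter = int(budget_ms // (size * soa_group))
        if max_iter < min_iter:
            raise ConfigurationError(
                f"stimulation budget allows only {max_iter} iterations for "
                f"group {g} (size {size}); minimum is {min_iter}"
            )
        out[g] = (min_iter, max_iter)
    return out


def with_seed(config: ParadigmConfig, seed: int) -> ParadigmConfig:
    """Copy of a config with a different seed."""
    return replace(config, seed=seed)
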