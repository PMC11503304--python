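"""Procedural generation and scoring for the two stressor tasks.

CVT (cognitive vigilance task): each trial shows a panel of 8 two-digit
numbers; a *critical* number is one whose digits differ by 0 or 1. The
participant presses on a lone critical number (positive trial), withholds
when none is present (negative trial) or when a no-go cue accompanies the
critical number (no-go trial). The response window is a constant 2.5 s.

MMIT (multi-modal integration task): each trial shows a procedurally
generated suspect whose attributes must be matched against a rule list;
press when all rules match (positive), withhold on a rule violation
(negative) or when a cue appears despite a full match (no-go). Trials come
in blocks of 10 (6 positive, 2 negative, 2 no-go) and the trial duration
adapts to performance: 9-10 correct shortens it by 1 s (floor 1 s), <= 7
correct lengthens it by 1 s, exactly 8 leaves it unchanged, starting from
5 s.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from typing import Sequence

import numpy as np

from .errors import ResponseMismatchError

CVT_WINDOW_S = 2.5
BLOCK_SIZE = 10
#: (positive, negative, no_go) per block of 10. Printed for the MMIT;
#: adopted for the CVT too, where critical numbers occur "infrequently".
DEFAULT_CLASS_MIX = (6, 2, 2)

#: Abstract MMIT suspect vocabulary: attribute -> categorical domain.
DEFAULT_ATTRIBUTES: dict[str, tuple[str, ...]] = {
    "nationality": ("arstotzka", "kolechia", "obristan", "impor"),
    "purpose": ("work", "visit", "transit", "immigrate"),
    "document": ("passport", "permit", "visa", "id_card"),
    "duration": ("3_days", "2_weeks", "3_months", "1_year"),
}


class TrialClass(str, Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    NO_GO = "no_go"


@dataclass(frozen=True)
class CVTTrial:
    numbers: tuple[int, ...]        # 8 two-digit integers
    trial_class: TrialClass
    window_s: float = CVT_WINDOW_S

    @property
    def has_cue(self) -> bool:
        return self.trial_class is TrialClass.NO_GO


@dataclass(frozen=True)
class MMITTrial:
    rules: tuple[tuple[str, str], ...]     # (attribute, required value)
    suspect: tuple[tuple[str, str], ...]   # (attribute, actual value)
    trial_class: TrialClass
    duration_s: int

    @property
    def has_cue(self) -> bool:
        return self.trial_class is TrialClass.NO_GO

    def rules_match(self) -> bool:
        suspect = dict(self.suspect)
        return all(suspect[attr] == want for attr, want in self.rules)


@dataclass(frozen=True)
class DifficultyState:
    duration_s: int = 5
    floor_s: int = 1
    start_s: int = 5

    def __post_init__(self) -> None:
        if self.duration_s < self.floor_s:
            raise ValueError("duration_s below floor")


@dataclass(frozen=True)
class TrialEvent:
    """One scored trial in the behavioral event log."""

    block: int
    trial: int
    trial_class: TrialClass
    onset_s: float
    duration_s: float
    pressed: bool
    rt_s: float | None      # None when timed out
    correct: bool


def is_critical(n: int) -> bool:
    """A two-digit number is critical when its digits differ by 0 or 1."""
    if not 10 <= n <= 99:
        raise ValueError(f"{n} is not a two-digit number")
    tens, units = divmod(n, 10)
    return abs(tens - units) <= 1


def _draw_noncritical(rng: np.random.Generator) -> int:
    while True:
        n = int(rng.integers(10, 100))
        if not is_critical(n):
            return n


def _draw_critical(rng: np.random.Generator) -> int:
    while True:
        n = int(rng.integers(10, 100))
        if is_critical(n):
            return n


def _shuffled_classes(
    rng: np.random.Generator, class_mix: tuple[int, int, int]
) -> list[TrialClass]:
    classes = (
        [TrialClass.POSITIVE] * class_mix[0]
        + [TrialClass.NEGATIVE] * class_mix[1]
        + [TrialClass.NO_GO] * class_mix[2]
    )
    rng.shuffle(classes)
    return classes


def generate_cvt_block(
    rng: np.random.Generator,
    class_mix: tuple[int, int, int] = DEFAULT_CLASS_MIX,
) -> list[CVTTrial]:
    """Generate one block of CVT trials (panel of 8 numbers each).

    Positive and no-go trials contain exactly one critical number;
    negative trials contain none. Deterministic under a fixed generator
    state.
    """
    if sum(class_mix) != BLOCK_SIZE:
        raise ValueError(f"class mix must sum to {BLOCK_SIZE}")
    trials = []
    for cls in _shuffled_classes(rng, class_mix):
        numbers = [_draw_noncritical(rng) for _ in range(8)]
        if cls is not TrialClass.NEGATIVE:
            numbers[int(rng.integers(8))] = _draw_critical(rng)
        trials.append(CVTTrial(tuple(numbers), cls))
    return trials


def generate_mmit_block(
    rng: np.random.Generator,
    state: DifficultyState,
    attributes: dict[str, tuple[str, ...]] | None = None,
) -> list[MMITTrial]:
    """Generate one block of MMIT trials at the current difficulty.

    Every trial's rule list covers all attributes; negative suspects
    violate at least one rule, positive and no-go suspects satisfy all.
    """
    attrs = attributes or DEFAULT_ATTRIBUTES
    trials = []
    for cls in _shuffled_classes(rng, DEFAULT_CLASS_MIX):
        rules = tuple(
            (a, domain[int(rng.integers(len(domain)))])
            for a, domain in attrs.items()
        )
        suspect = dict(rules)
        if cls is TrialClass.NEGATIVE:
            n_viol = 1 + int(rng.integers(len(attrs)))
            which = rng.choice(len(rules), size=n_viol, replace=False)
            for j in which:
                attr, want = rules[j]
                others = [v for v in attrs[attr] if v != want]
                suspect[attr] = others[int(rng.integers(len(others)))]
        trials.append(MMITTrial(
            rules=rules, suspect=tuple(suspect.items()),
            trial_class=cls, duration_s=state.duration_s,
        ))
    return trials


def is_correct(trial_class: TrialClass, pressed: bool) -> bool:
    """Positive trials require a press inside the window; negative and
    no-go trials are correct only when allowed to time out."""
    if trial_class is TrialClass.POSITIVE:
        return pressed
    return not pressed


def score_block(
    trials: Sequence[CVTTrial | MMITTrial],
    responses: Sequence[bool],
) -> int:
    """Count correct trials in a block given pressed/timed-out responses."""
    if len(trials) != len(responses):
        raise ResponseMismatchError(
            f"{len(responses)} responses for {len(trials)} trials"
        )
    return sum(
        is_correct(t.trial_class, pressed)
        for t, pressed in zip(trials, responses)
    )


def update_difficulty(state: DifficultyState, correct: int) -> DifficultyState:
    """Adapt trial duration from the block score.

    9-10 correct: shorten by 1 s (clipped at the floor); 7 or fewer:
    lengthen by 1 s; exactly 8: unchanged.
    """
    if not 0 <= correct <= BLOCK_SIZE:
        raise ValueError(f"block score {correct} outside 0..{BLOCK_SIZE}")
    if correct >= 9:
        return replace(state, duration_s=max(state.duration_s - 1, state.floor_s))
    if correct <= 7:
        return replace(state, duration_s=state.duration_s + 1)
    return state


# ---------------------------------------------------------------------------
# Simulated responder + behavioral metrics

@dataclass
class SimulatedResponder:
    """A stochastic participant for driving the closed loop.

    Presses on positive trials after a lognormal response time; withholds
    on negative/no-go trials except for occasional lapses (false presses)
    and misses.
    """

    median_rt_s: float = 1.2
    rt_sigma: float = 0.35
    miss_rate: float = 0.05
    false_press_rate: float = 0.05

    def respond(
        self, trial_class: TrialClass, window_s: float, rng: np.random.Generator
    ) -> tuple[bool, float | None]:
        """Return (pressed, rt_s); rt is None on a timeout."""
        if trial_class is TrialClass.POSITIVE:
            if rng.random() < self.miss_rate:
                return False, None
            rt = float(rng.lognormal(np.log(self.median_rt_s), self.rt_sigma))
            if rt < window_s:
                return True, rt
            return False, None
        if rng.random() < self.false_press_rate:
            rt = float(rng.uniform(0.2, window_s))
            return True, rt
        return False, None


def run_session(
    task: str,
    n_blocks: int,
    rng: np.random.Generator,
    responder: SimulatedResponder | None = None,
    inter_block_gap_s: float = 3.0,
    inter_trial_gap_s: float = 3.0,
) -> tuple[list[TrialEvent], list[tuple[float, float]], list[int]]:
    """Simulate a full closed-loop session of either task.

    Each trial occupies its response window plus ``inter_trial_gap_s`` of
    stimulus turnover, which puts a 10-trial block near the observed
    1-1.5 min. Returns the trial event log, the per-block
    ``(start_s, end_s)`` windows, and the per-block trial durations
    (constant for the CVT, adaptive for the MMIT).
    """
    responder = responder or SimulatedResponder()
    events: list[TrialEvent] = []
    windows: list[tuple[float, float]] = []
    durations: list[int] = []
    clock = 0.0
    state = DifficultyState()
    for block in range(n_blocks):
        if task == "CVT":
            trials: Sequence[CVTTrial | MMITTrial] = generate_cvt_block(rng)
            trial_len = CVT_WINDOW_S
        elif task == "MMIT":
            trials = generate_mmit_block(rng, state)
            trial_len = float(state.duration_s)
        else:
            raise ValueError(f"unknown task {task!r}")
        start = clock
        pressed_flags = []
        for i, trial in enumerate(trials):
            window = trial.window_s if isinstance(trial, CVTTrial) else trial.duration_s
            pressed, rt = responder.respond(trial.trial_class, window, rng)
            pressed_flags.append(pressed)
            events.append(TrialEvent(
                block=block, trial=i, trial_class=trial.trial_class,
                onset_s=clock, duration_s=float(window), pressed=pressed,
                rt_s=rt, correct=is_correct(trial.trial_class, pressed),
            ))
            clock += trial_len + inter_trial_gap_s
        windows.append((start, clock))
        durations.append(int(trial_len) if task == "MMIT" else 0)
        correct = score_block(trials, pressed_flags)
        if task == "MMIT":
            state = update_difficulty(state, correct)
        clock += inter_block_gap_s
    return events, windows, durations


@dataclass
class BlockMetrics:
    block: int
    accuracy: float           # fraction of the 10 trials correct
    mean_rt_s: float | None   # None when no eligible positive trials
    trial_length_s: float


def behavioral_metrics(events: Sequence[TrialEvent]) -> list[BlockMetrics]:
    """Per-block accuracy and mean reaction time.

    Reaction time averages only correctly answered positive trials;
    timeouts and wrong presses are excluded. Blocks without an eligible
    positive trial report ``mean_rt_s = None``.
    """
    out = []
    blocks = sorted({e.block for e in events})
    for b in blocks:
        evs = [e for e in events if e.block == b]
        rts = [e.rt_s for e in evs
               if e.trial_class is TrialClass.POSITIVE and e.correct
               and e.rt_s is not None]
        out.append(BlockMetrics(
            block=b,
            accuracy=sum(e.correct for e in evs) / len(evs),
            mean_rt_s=float(np.mean(rts)) if rts else None,
            trial_length_s=evs[0].duration_s,
        ))
    return out


def events_to_frame(events: Sequence[TrialEvent]):
    """Event log as a DataFrame matching the on-disk event CSV schema."""
    import pandas as pd

    return pd.DataFrame([
        {"block": e.block, "trial": e.trial, "class": e.trial_class.value,
         "onset_s": round(e.onset_s, 3), "duration_s": e.duration_s,
         "pressed": int(e.pressed),
         "rt_s": round(e.rt_s, 4) if e.rt_s is not None else "",
         "correct": int(e.correct)}
        for e in events
    ])
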