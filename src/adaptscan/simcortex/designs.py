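"""Experiment designs for the two scanning paradigms.

Two paradigms are modelled:

* a category **localizer** — five stimulus categories (faces, objects, words,
  houses, scrambled) shown in 16-stimulus blocks with inter-block rests, used
  to define category-selective ROIs; and
* an **adaptation** paradigm — three categories (faces, Greeble-like objects,
  pseudowords) crossed with three repetition conditions (same / alternating /
  different) in short mini-blocks, used to measure repetition suppression.

Designs are fully deterministic given their parameters (and, for the
adaptation paradigm, a seed controlling the pseudo-randomised block order).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "LOCALIZER_CATEGORIES",
    "ADAPTATION_CATEGORIES",
    "ADAPTATION_CONDITIONS",
    "ADAPTATION_BLOCK_TYPES",
    "StimulusEvent",
    "ExperimentDesign",
    "LocalizerTiming",
    "AdaptationTiming",
    "SchedulingError",
    "build_localizer_design",
    "build_adaptation_design",
]

LOCALIZER_CATEGORIES = ("faces", "objects", "words", "houses", "scrambled")
ADAPTATION_CATEGORIES = ("faces", "objects", "words")
ADAPTATION_CONDITIONS = ("same", "alternating", "different")
#: the nine block types, in canonical (category-major) order
ADAPTATION_BLOCK_TYPES = tuple(
    f"{cat}_{cond}" for cat in ADAPTATION_CATEGORIES for cond in ADAPTATION_CONDITIONS
)

# Exemplar pool sizes per category in the adaptation paradigm: the different
# condition reuses the same 12 exemplars across runs, the alternating condition
# the same pair, and the same condition draws one of 4 dedicated exemplars per
# block (each used once per run).  Pools are disjoint, so 12 + 2 + 4 = 18
# unique exemplars per category.
_N_DIFFERENT, _N_ALTERNATING, _N_SAME = 12, 2, 4

_LOCALIZER_ORDER_SEED = 7391  # pins the shared pseudo-random block order


class SchedulingError(RuntimeError):
    """Raised when no block order satisfying the design constraints is found."""


@dataclass(frozen=True)
class StimulusEvent:
    """One stimulus presentation within a run."""

    onset: float
    duration: float
    category: str
    condition: str = "none"
    exemplar_id: str = ""
    is_repeat_probe: bool = False

    @property
    def trial_type(self) -> str:
        if self.condition == "none":
            return self.category
        return f"{self.category}_{self.condition}"


@dataclass(frozen=True)
class ExperimentDesign:
    """A timed event schedule for one run of one paradigm."""

    paradigm: str  # {"localizer", "adaptation"}
    tr: float
    n_volumes: int
    events: tuple[StimulusEvent, ...]
    run_index: int = 0
    fixation_color_changes: tuple[float, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        prev_end = 0.0
        for ev in self.events:
            if ev.onset < 0 or ev.duration <= 0:
                raise ValueError("events must have onset >= 0 and duration > 0")
            if ev.onset < prev_end - 1e-9:
                raise ValueError("events must be sorted and non-overlapping")
            prev_end = ev.onset + ev.duration
        if self.n_volumes * self.tr < prev_end - 1e-9:
            raise ValueError("run too short for its events")

    @property
    def duration(self) -> float:
        return self.n_volumes * self.tr

    @property
    def condition_labels(self) -> tuple[str, ...]:
        if self.paradigm == "adaptation":
            return ADAPTATION_BLOCK_TYPES
        seen: list[str] = []
        for ev in self.events:
            if ev.trial_type not in seen:
                seen.append(ev.trial_type)
        return tuple(sorted(seen))

    def events_table(self) -> pd.DataFrame:
        """BIDS-style events table (onset, duration, trial_type, exemplar_id)."""
        return pd.DataFrame(
            {
                "onset": [e.onset for e in self.events],
                "duration": [e.duration for e in self.events],
                "trial_type": [e.trial_type for e in self.events],
                "exemplar_id": [e.exemplar_id for e in self.events],
                "is_repeat_probe": [e.is_repeat_probe for e in self.events],
            }
        )


@dataclass(frozen=True)
class LocalizerTiming:
    """Timing parameters of the localizer paradigm (defaults per the study)."""

    stim_duration: float = 0.8
    isi: float = 0.2
    stims_per_block: int = 16
    rest_duration: float = 8.0
    blocks_per_category: int = 3
    tr: float = 2.0

    def validate(self) -> None:
        if min(self.stim_duration, self.isi, self.rest_duration, self.tr) <= 0:
            raise ValueError("localizer durations must be positive")
        if self.stims_per_block < 1 or self.blocks_per_category < 0:
            raise ValueError("invalid localizer block counts")

    @property
    def block_duration(self) -> float:
        return self.stims_per_block * (self.stim_duration + self.isi)


@dataclass(frozen=True)
class AdaptationTiming:
    """Timing parameters of the adaptation paradigm (defaults per the study)."""

    stim_duration: float = 0.25
    isi: float = 0.05
    stims_per_block: int = 12
    n_cycles: int = 4
    fixation_durations: tuple[float, ...] = (6.0, 7.5, 9.0)
    final_rest: float = 6.0
    tr: float = 1.5

    def validate(self) -> None:
        if min(self.stim_duration, self.isi, self.tr) <= 0:
            raise ValueError("adaptation durations must be positive")
        if self.stims_per_block < 1 or self.n_cycles < 1:
            raise ValueError("invalid adaptation block counts")
        if any(d <= 0 for d in self.fixation_durations):
            raise ValueError("fixation durations must be positive")

    @property
    def block_duration(self) -> float:
        """Stimulus span of one mini-block (no trailing gap): 3.55 s by default."""
        n = self.stims_per_block
        return n * self.stim_duration + (n - 1) * self.isi


def _localizer_block_order(timing: LocalizerTiming) -> list[str]:
    # one fixed pseudo-random order, identical for every participant and run
    rng = np.random.default_rng(_LOCALIZER_ORDER_SEED)
    order = [c for c in LOCALIZER_CATEGORIES for _ in range(timing.blocks_per_category)]
    rng.shuffle(order)
    return order


def build_localizer_design(
    timing: LocalizerTiming | None = None, run_index: int = 0
) -> ExperimentDesign:
    """Build one localizer run: 15 blocks (5 categories x 3) of 16 stimuli.

    An 8-s rest precedes every block (including the first) and one follows the
    last, giving a 368-s (6 min 8 s) run at the default timing.  Within each
    block 15 exemplars are unique and one is immediately repeated (the
    one-back probe); the repeat position is deterministic per (run, block).
    """
    timing = timing or LocalizerTiming()
    timing.validate()
    order = _localizer_block_order(timing)
    events: list[StimulusEvent] = []
    t = timing.rest_duration  # initial rest
    soa = timing.stim_duration + timing.isi
    for b, cat in enumerate(order):
        rng = np.random.default_rng(
            np.random.SeedSequence(_LOCALIZER_ORDER_SEED, spawn_key=(run_index, b))
        )
        n = timing.stims_per_block
        exemplars = [f"{cat}_run{run_index}_b{b:02d}_{i:02d}" for i in range(n - 1)]
        repeat_pos = int(rng.integers(1, n)) if n > 1 else 0
        ids: list[str] = []
        k = 0
        for i in range(n):
            if i == repeat_pos and n > 1:
                ids.append(ids[i - 1])
            else:
                ids.append(exemplars[k])
                k += 1
        for i in range(n):
            events.append(
                StimulusEvent(
                    onset=t + i * soa,
                    duration=timing.stim_duration,
                    category=cat,
                    exemplar_id=ids[i],
                    is_repeat_probe=(i == repeat_pos and n > 1),
                )
            )
        t += timing.block_duration + timing.rest_duration
    total = t if order else timing.rest_duration
    n_volumes = math.ceil(round(total / timing.tr, 9))
    return ExperimentDesign(
        paradigm="localizer",
        tr=timing.tr,
        n_volumes=n_volumes,
        events=tuple(events),
        run_index=run_index,
    )


def _adaptation_block_order(
    timing: AdaptationTiming, rng: np.random.Generator, max_tries: int = 5000
) -> list[tuple[str, str]]:
    """Order of (category, condition) blocks: every cycle contains each of the
    nine types once, and no two consecutive blocks share a category (including
    across cycle boundaries)."""
    types = [(c, k) for c in ADAPTATION_CATEGORIES for k in ADAPTATION_CONDITIONS]
    order: list[tuple[str, str]] = []
    for _ in range(timing.n_cycles):
        prev_cat = order[-1][0] if order else None
        for _try in range(max_tries):
            perm = [types[i] for i in rng.permutation(len(types))]
            ok = perm[0][0] != prev_cat and all(
                perm[i][0] != perm[i + 1][0] for i in range(len(perm) - 1)
            )
            if ok:
                order.extend(perm)
                break
        else:
            raise SchedulingError(
                "no constraint-satisfying adaptation block order found "
                f"within {max_tries} tries"
            )
    return order


def exemplar_pool(category: str, condition: str) -> list[str]:
    """The fixed, disjoint exemplar set for one (category, condition) pair."""
    sizes = {"different": _N_DIFFERENT, "alternating": _N_ALTERNATING, "same": _N_SAME}
    tag = {"different": "d", "alternating": "a", "same": "s"}[condition]
    return [f"{category}_{tag}{i + 1:02d}" for i in range(sizes[condition])]


def build_adaptation_design(
    timing: AdaptationTiming | None = None,
    run_index: int = 0,
    seed: int = 0,
) -> ExperimentDesign:
    """Build one adaptation run: 36 mini-blocks (4 cycles of the 9 block types).

    Three baseline fixation periods (6, 7.5 and 9 s) are randomly interspersed
    among the blocks.  Exemplar assignment uses the fixed disjoint pools (12
    different / 2 alternating / 4 same per category, 18 in total); the four
    same-condition exemplars each serve one same block per run in a random
    order.  The fixation dot changes colour nine times per run, once per block
    type, with three cycles carrying two changes and one carrying three.
    """
    timing = timing or AdaptationTiming()
    timing.validate()
    rng = np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=(run_index,)))
    order = _adaptation_block_order(timing, rng)
    n_blocks = len(order)

    # same-condition exemplar rotation: each of the 4 exemplars once per run
    same_rotation = {
        cat: list(rng.permutation(exemplar_pool(cat, "same")))
        for cat in ADAPTATION_CATEGORIES
    }
    same_counter = {cat: 0 for cat in ADAPTATION_CATEGORIES}

    # fixation periods inserted before a sampled set of distinct blocks
    n_fix = len(timing.fixation_durations)
    fix_positions = rng.choice(n_blocks, size=min(n_fix, n_blocks), replace=False)
    fix_durs = list(rng.permutation(np.asarray(timing.fixation_durations)))
    fixation_before = dict(zip(sorted(int(p) for p in fix_positions), fix_durs))

    soa = timing.stim_duration + timing.isi
    events: list[StimulusEvent] = []
    block_spans: list[tuple[str, str, int, float]] = []  # (cat, cond, cycle, start)
    t = 0.0
    for b, (cat, cond) in enumerate(order):
        if b in fixation_before:
            t += fixation_before[b]
        if cond == "different":
            ids = list(rng.permutation(exemplar_pool(cat, "different")))[
                : timing.stims_per_block
            ]
            while len(ids) < timing.stims_per_block:  # oversized blocks recycle
                ids.extend(ids[: timing.stims_per_block - len(ids)])
        elif cond == "alternating":
            pair = exemplar_pool(cat, "alternating")
            if rng.integers(2):
                pair = pair[::-1]
            ids = [pair[i % 2] for i in range(timing.stims_per_block)]
        else:  # same
            rot = same_rotation[cat]
            ex = rot[same_counter[cat] % len(rot)]
            same_counter[cat] += 1
            ids = [ex] * timing.stims_per_block
        for i in range(timing.stims_per_block):
            events.append(
                StimulusEvent(
                    onset=t + i * soa,
                    duration=timing.stim_duration,
                    category=cat,
                    condition=cond,
                    exemplar_id=ids[i],
                )
            )
        block_spans.append((cat, cond, b // 9 if n_blocks == timing.n_cycles * 9 else 0, t))
        t += timing.block_duration + timing.isi
    total = t - timing.isi + timing.final_rest

    # dot colour-change schedule: one change per block type, cycle counts 2/2/2/3
    changes: list[float] = []
    if timing.n_cycles >= 1 and n_blocks == timing.n_cycles * 9:
        base, extra = divmod(9, timing.n_cycles)
        counts = [base] * timing.n_cycles
        for c in rng.choice(timing.n_cycles, size=extra, replace=False):
            counts[int(c)] += 1
        type_order = [ADAPTATION_BLOCK_TYPES[i] for i in rng.permutation(9)]
        cycle_of: dict[str, int] = {}
        pos = 0
        for cyc, cnt in enumerate(counts):
            for bt in type_order[pos : pos + cnt]:
                cycle_of[bt] = cyc
            pos += cnt
        for cat, cond, cyc, start in block_spans:
            if cycle_of.get(f"{cat}_{cond}") == cyc:
                changes.append(start + rng.uniform(0, timing.block_duration))

    n_volumes = math.ceil(round(total / timing.tr, 9))
    return ExperimentDesign(
        paradigm="adaptation",
        tr=timing.tr,
        n_volumes=n_volumes,
        events=tuple(events),
        run_index=run_index,
        fixation_color_changes=tuple(sorted(changes)),
    )
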