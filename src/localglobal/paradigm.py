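"""Local-global auditory oddball sequence generation.

The local-global paradigm presents five-tone patterns that are either
locally standard (``xxxxx``, five identical tones) or locally deviant
(``xxxxY``, the fifth tone differs).  Within a block one pattern type is
frequent (80% of test patterns) and the other rare (20%); a habituation
phase presents only the frequent ("global standard") pattern.  Crossing
local and global deviance dissociates stimulus-probability deviance from
sequence-structure deviance.

This module generates reproducible event tables for blocks and whole
experiments (sessions x counterbalanced blocks) as tidy pandas frames
that every downstream analysis consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

PATTERN_STANDARD = "xxxxx"
PATTERN_DEVIANT = "xxxxY"
PATTERNS = (PATTERN_STANDARD, PATTERN_DEVIANT)

#: Column order of every event table produced by this module.
EVENT_COLUMNS = [
    "onset",
    "duration",
    "pattern",
    "global_role",
    "local_deviant",
    "sound_set",
    "block_index",
    "session_index",
]


class PlacementInfeasibleError(ValueError):
    """Rare patterns cannot be placed under the minimum-gap constraint."""


class UnsupportedDesignError(ValueError):
    """Requested session structure is not a supported counterbalanced design."""


@dataclass(frozen=True)
class ToneSet:
    """A three-component complex tone used as the x or Y sound.

    The low-pitched set A uses 350/700/1400 Hz components and the
    high-pitched set B uses 500/1000/2000 Hz; each tone lasts 50 ms.
    """

    name: str = "A"
    component_frequencies: tuple[float, float, float] = (350.0, 700.0, 1400.0)
    tone_duration: float = 0.050

    def __post_init__(self) -> None:
        if len(self.component_frequencies) != 3:
            raise ValueError("a tone set has exactly 3 component frequencies")
        if any(f <= 0 for f in self.component_frequencies):
            raise ValueError("component frequencies must be positive")
        if self.tone_duration <= 0:
            raise ValueError("tone_duration must be positive")


TONE_SET_A = ToneSet("A", (350.0, 700.0, 1400.0))
TONE_SET_B = ToneSet("B", (500.0, 1000.0, 2000.0))


@dataclass(frozen=True)
class BlockSpec:
    """Specification of one block of the task.

    Defaults reproduce the study design: 25 habituation patterns followed
    by a test phase of 88 frequent and 22 rare patterns (135 total),
    650 ms patterns separated by 1.5 s silent gaps.
    """

    standard_pattern: str = PATTERN_STANDARD
    standard_tone_set: str = "A"
    n_habituation: int = 25
    n_test_frequent: int = 88
    n_test_rare: int = 22
    pattern_duration: float = 0.650
    inter_pattern_interval: float = 1.500
    min_gap_between_rares: int = 1
    tone_duration: float = 0.050
    seed: int = 0

    def __post_init__(self) -> None:
        if self.standard_pattern not in PATTERNS:
            raise ValueError(f"unknown pattern {self.standard_pattern!r}")
        for name in ("n_habituation", "n_test_frequent", "n_test_rare"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.pattern_duration < 5 * self.tone_duration:
            raise ValueError("pattern_duration must fit five tones")
        if self.n_test_rare > self.n_test_frequent:
            raise ValueError("rare patterns cannot outnumber frequent ones")

    @property
    def deviant_pattern(self) -> str:
        return PATTERN_DEVIANT if self.standard_pattern == PATTERN_STANDARD else PATTERN_STANDARD

    @property
    def stimulus_onset_asynchrony(self) -> float:
        return self.pattern_duration + self.inter_pattern_interval


def _rare_positions(n_test: int, n_rare: int, gap: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform sample of rare positions with >= ``gap`` frequent patterns between rares.

    Uses the standard bijection between gap-constrained and unconstrained
    combinations: sample sorted positions from the reduced range and
    re-expand, which is uniform over all feasible placements.
    """
    if n_rare == 0:
        return np.empty(0, dtype=int)
    reduced = n_test - (n_rare - 1) * gap
    if reduced < n_rare:
        raise PlacementInfeasibleError(
            f"cannot place {n_rare} rare patterns in {n_test} test slots "
            f"with a minimum gap of {gap}"
        )
    base = np.sort(rng.choice(reduced, size=n_rare, replace=False))
    return base + gap * np.arange(n_rare)


def generate_block(
    spec: BlockSpec,
    start_time: float = 0.0,
    *,
    block_index: int = 0,
    session_index: int = 0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Generate the event table of one block.

    Habituation patterns (all of the block's standard type) come first,
    then the test phase with rare patterns interleaved uniformly at
    random subject to the minimum-gap constraint.  Onsets advance by the
    stimulus onset asynchrony (pattern duration + inter-pattern interval).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n_test = spec.n_test_frequent + spec.n_test_rare
    rare_pos = _rare_positions(n_test, spec.n_test_rare, spec.min_gap_between_rares, rng)
    is_rare = np.zeros(n_test, dtype=bool)
    is_rare[rare_pos] = True

    patterns = [spec.standard_pattern] * spec.n_habituation
    roles = ["habituation"] * spec.n_habituation
    for rare in is_rare:
        patterns.append(spec.deviant_pattern if rare else spec.standard_pattern)
        roles.append("rare" if rare else "frequent")

    n_rows = len(patterns)
    onsets = start_time + spec.stimulus_onset_asynchrony * np.arange(n_rows)
    return pd.DataFrame(
        {
            "onset": onsets,
            "duration": np.full(n_rows, spec.pattern_duration),
            "pattern": patterns,
            "global_role": roles,
            "local_deviant": [p == PATTERN_DEVIANT for p in patterns],
            "sound_set": spec.standard_tone_set,
            "block_index": block_index,
            "session_index": session_index,
        }
    )[EVENT_COLUMNS]


def generate_experiment(
    n_sessions: int = 4,
    blocks_per_session: int = 2,
    base_spec: BlockSpec | None = None,
    seed: int = 0,
    *,
    session_lead_in: float = 0.0,
    inter_block_gap: float = 10.0,
) -> pd.DataFrame:
    """Generate a full experiment of counterbalanced sessions.

    Each session holds one ``xxxxx``-standard and one ``xxxxY``-standard
    block; block order alternates across sessions and tone-set assignment
    is counterbalanced so that over four sessions every combination of
    (order, tone set) occurs once.  Onsets are relative to session start.
    """
    if blocks_per_session not in (1, 2):
        raise UnsupportedDesignError("blocks_per_session must be 1 or 2")
    if n_sessions < 1:
        raise ValueError("n_sessions must be >= 1")
    if base_spec is None:
        base_spec = BlockSpec()
    rng = np.random.default_rng(seed)

    frames: list[pd.DataFrame] = []
    block_counter = 0
    for s in range(n_sessions):
        if blocks_per_session == 2:
            order = (PATTERN_STANDARD, PATTERN_DEVIANT) if s % 2 == 0 else (
                PATTERN_DEVIANT, PATTERN_STANDARD)
        else:
            order = ((PATTERN_STANDARD, PATTERN_DEVIANT)[s % 2],)
        # Tone set of the xxxxx-standard block: A,B,B,A cycle crossed with
        # the alternating order gives all four (order, set) combinations.
        set_x = "A" if s % 4 in (0, 3) else "B"
        set_y = "B" if set_x == "A" else "A"
        t = session_lead_in
        for standard in order:
            tone = set_x if standard == PATTERN_STANDARD else set_y
            spec = replace(base_spec, standard_pattern=standard, standard_tone_set=tone)
            block = generate_block(
                spec,
                start_time=t,
                block_index=block_counter,
                session_index=s,
                rng=rng,
            )
            frames.append(block)
            t = block["onset"].iloc[-1] + spec.stimulus_onset_asynchrony + inter_block_gap
            block_counter += 1
    return pd.concat(frames, ignore_index=True)


def empirical_tone_frequencies(events: pd.DataFrame, test_phase_only: bool = True) -> dict[str, float]:
    """Empirical per-tone frequency of the deviant sound over all five-tone slots.

    For an ``xxxxx``-standard block at default counts this is
    22 / (5 * 110) = 0.04 in the test phase; for the ``xxxxY``-standard
    block the dominant sound occupies 0.84 of slots in the test phase
    (the generator reports what it emitted rather than a printed value).
    """
    df = events
    if test_phase_only:
        df = df[df["global_role"] != "habituation"]
    n_slots = 5 * len(df)
    n_deviant_tones = int(df["local_deviant"].sum())
    return {
        "deviant_tone": n_deviant_tones / n_slots,
        "dominant_tone": 1.0 - n_deviant_tones / n_slots,
    }


def write_events(events: pd.DataFrame, path) -> None:
    """Write a BIDS-events-like tab-separated file (one table, any sessions).

    ``trial_type`` is the pattern/role composite, e.g. ``xxxxY_rare``.
    """
    out = events.copy()
    out.insert(2, "trial_type", out["pattern"] + "_" + out["global_role"])
    out.to_csv(path, sep="\t", index=False)


def read_events(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "trial_type" in df.columns and "pattern" not in df.columns:
        parts = df["trial_type"].str.rsplit("_", n=1, expand=True)
        df["pattern"] = parts[0]
        df["global_role"] = parts[1]
        df["local_deviant"] = df["pattern"] == PATTERN_DEVIANT
    return df[[c for c in EVENT_COLUMNS if c in df.columns]]
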