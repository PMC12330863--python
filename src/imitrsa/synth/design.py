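"""Trial/event timelines for one subject-run of the speech-imitation task.

Each run presents 28 words of one language. A trial consists of three
consecutive listen-then-imitate cycles for the same word: the auditory
stimulus plays for 1.5 s (perception), the participant imitates it in the
next 1.5 s (production), and a jitter screen follows. After the third
jitter a 3 s fixation baseline is shown, followed by a fourth jitter, and
the next trial begins. Jitters are drawn uniformly from {1, 2, 3, 4, 5} s
(mean 3 s). Volumes are acquired every TR = 2 s.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

LANGUAGES = ("chinese", "spanish")
REPETITIONS = ("t1", "t2", "t3")
WORD_PHASES = ("perception", "production")

N_WORDS = 28
N_REPS = 3
STIM_DURATION = 1.5
IMIT_DURATION = 1.5
BASELINE_DURATION = 3.0
JITTER_CHOICES = (1.0, 2.0, 3.0, 4.0, 5.0)
DEFAULT_TR = 2.0
HRF_TAIL = 16.0  # run is padded so the last response is fully sampled


@dataclass(frozen=True)
class Event:
    onset: float
    duration: float
    phase: str  # perception | production | baseline | jitter
    word_id: str | None = None
    repetition: str | None = None

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("event duration must be positive")
        is_word = self.phase in WORD_PHASES
        if is_word != (self.word_id is not None):
            raise ValueError("word_id present iff phase is perception/production")


@dataclass
class ExperimentDesign:
    subject_id: str
    language: str
    events: list[Event]
    tr: float = DEFAULT_TR
    n_volumes: int = 0
    grid_shape: tuple[int, int, int] = (20, 20, 20)
    voxel_size: tuple[float, float, float] = (3.0, 3.0, 3.0)
    seed: int | None = None

    @property
    def word_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.events:
            if e.word_id is not None:
                seen.setdefault(e.word_id, None)
        return list(seen)

    def word_events(self, phase: str) -> list[Event]:
        if phase not in WORD_PHASES:
            raise ValueError(f"phase must be one of {WORD_PHASES}")
        return [e for e in self.events if e.phase == phase]

    def jitter_durations(self) -> np.ndarray:
        return np.array([e.duration for e in self.events if e.phase == "jitter"])

    def validate(self) -> None:
        for phase in WORD_PHASES:
            events = self.word_events(phase)
            if len(events) != N_WORDS * N_REPS:
                raise ValueError(f"expected {N_WORDS * N_REPS} {phase} events")
            counts = pd.Series([e.word_id for e in events]).value_counts()
            if len(counts) != N_WORDS or not (counts == N_REPS).all():
                raise ValueError(f"each word must appear {N_REPS} times per phase")
        onsets = np.array([e.onset for e in self.events])
        if not (np.diff(onsets) > 0).all():
            raise ValueError("event onsets must be strictly increasing")
        last = self.events[-1]
        if last.onset + last.duration >= self.n_volumes * self.tr:
            raise ValueError("last event must end before the run does")
        for e in self.events:
            if e.phase == "jitter" and not (1.0 <= e.duration <= 5.0):
                raise ValueError("jitter durations must lie in [1, 5] s")

    def to_events_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "onset": [e.onset for e in self.events],
                "duration": [e.duration for e in self.events],
                "word_id": [e.word_id if e.word_id is not None else "n/a" for e in self.events],
                "repetition": [e.repetition if e.repetition is not None else "n/a" for e in self.events],
                "phase": [e.phase for e in self.events],
            }
        )

    def config(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "language": self.language,
            "tr": self.tr,
            "n_volumes": self.n_volumes,
            "grid_shape": list(self.grid_shape),
            "voxel_size": list(self.voxel_size),
            "seed": self.seed,
        }


def generate_design(
    subject_id: str,
    language: str,
    seed: int,
    tr: float = DEFAULT_TR,
    grid_shape: tuple[int, int, int] = (20, 20, 20),
    voxel_size: tuple[float, float, float] = (3.0, 3.0, 3.0),
) -> ExperimentDesign:
    """Generate one subject-run timeline.

    Word (trial) order is randomized per seed. Returns a design with exactly
    28 x 3 perception events and 28 x 3 production events; the imitation
    epoch starts when the stimulus epoch ends.
    """
    if language not in LANGUAGES:
        raise ValueError(f"language must be one of {LANGUAGES}")
    rng = np.random.default_rng(seed)
    prefix = {"chinese": "cn", "spanish": "es"}[language]
    words = [f"{prefix}_w{i:02d}" for i in range(1, N_WORDS + 1)]
    order = rng.permutation(N_WORDS)

    events: list[Event] = []
    t = 0.0
    for trial in order:
        word = words[trial]
        for rep in REPETITIONS:
            events.append(Event(t, STIM_DURATION, "perception", word, rep))
            t += STIM_DURATION
            events.append(Event(t, IMIT_DURATION, "production", word, rep))
            t += IMIT_DURATION
            jit = float(rng.choice(JITTER_CHOICES))
            events.append(Event(t, jit, "jitter"))
            t += jit
        events.append(Event(t, BASELINE_DURATION, "baseline"))
        t += BASELINE_DURATION
        jit = float(rng.choice(JITTER_CHOICES))
        events.append(Event(t, jit, "jitter"))
        t += jit

    n_volumes = int(np.ceil((t + HRF_TAIL) / tr))
    design = ExperimentDesign(
        subject_id=subject_id,
        language=language,
        events=events,
        tr=tr,
        n_volumes=n_volumes,
        grid_shape=tuple(grid_shape),
        voxel_size=tuple(voxel_size),
        seed=seed,
    )
    design.validate()
    return design


def write_events(design: ExperimentDesign, path: str | Path, config_path: str | Path | None = None) -> None:
    """Write the event table as TSV (and optionally the run config as JSON)."""
    design.to_events_table().to_csv(path, sep="\t", index=False)
    if config_path is not None:
        Path(config_path).write_text(json.dumps(design.config(), indent=1))


def read_events(path: str | Path, config_path: str | Path | None = None, **kwargs) -> ExperimentDesign:
    """Rebuild an :class:`ExperimentDesign` from a TSV event table.

    Run geometry comes from ``config_path`` if given, else from ``kwargs``
    (subject_id, language, tr, n_volumes, grid_shape, voxel_size).
    """
    table = pd.read_csv(path, sep="\t", na_values=["n/a"])
    meta: dict = {}
    if config_path is not None:
        meta.update(json.loads(Path(config_path).read_text()))
    meta.update(kwargs)
    events = [
        Event(
            onset=float(row.onset),
            duration=float(row.duration),
            phase=row.phase,
            word_id=None if pd.isna(row.word_id) else row.word_id,
            repetition=None if pd.isna(row.repetition) else row.repetition,
        )
        for row in table.itertuples()
    ]
    return ExperimentDesign(
        subject_id=meta.get("subject_id", "unknown"),
        language=meta.get("language", "spanish"),
        events=events,
        tr=float(meta.get("tr", DEFAULT_TR)),
        n_volumes=int(meta["n_volumes"]),
        grid_shape=tuple(meta.get("grid_shape", (20, 20, 20))),
        voxel_size=tuple(meta.get("voxel_size", (3.0, 3.0, 3.0))),
        seed=meta.get("seed"),
    )
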