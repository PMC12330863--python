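"""Measurement-level acoustic tables: VOT of voiced stops and vowel formants.

Values are generated at the measurement level (as if extracted from
recordings by raters), not synthesized as audio. Seven Spanish-like words
carry the voiced stops /b/ and /d/ and together cover the five Spanish
vowels. A native-speaker reference token set is emitted alongside the
participant measurements. Group means encode the study conditions: children
produce more negative (more native-like) VOT than control adults, and
control adults sit farther from the native (F1, F2) position for /o/ (and,
with the children, for /i/) than singing-trained adults.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GROUPS = ("children", "control_adults", "singers")
CONSONANTS = ("b", "d")
VOWELS = ("a", "e", "i", "o", "u")
REPETITIONS = (1, 2, 3)

# word -> (stop consonant, vowel slots); covers /b/, /d/ and all five vowels
WORDS: dict[str, tuple[str, tuple[str, ...]]] = {
    "bebe": ("b", ("e", "e")),
    "bueno": ("b", ("u", "e", "o")),
    "brazo": ("b", ("a", "o")),
    "bonito": ("b", ("o", "i", "o")),
    "dado": ("d", ("a", "o")),
    "dedo": ("d", ("e", "o")),
    "dificil": ("d", ("i", "i")),
}


@dataclass
class AcousticGroundTruth:
    """Generative means and dispersions for the acoustic measurements.

    ``vot_mean[group][consonant]`` is in seconds (negative: prevoiced);
    ``formant_mean[group][vowel]`` is an (F1, F2) pair in Hz. The native
    reference is a single speaker at ``native_vot`` / ``native_formant``.
    """

    vot_mean: dict[str, dict[str, float]]
    formant_mean: dict[str, dict[str, tuple[float, float]]]
    native_vot: dict[str, float]
    native_formant: dict[str, tuple[float, float]]
    vot_between_sd: float = 0.012
    vot_within_sd: float = 0.008
    formant_between_sd: tuple[float, float] = (40.0, 80.0)
    formant_within_sd: tuple[float, float] = (25.0, 50.0)
    vot_rater_sd: float = 0.004
    formant_rater_sd: tuple[float, float] = (8.0, 16.0)
    digit_span_mean: dict[str, float] = field(
        default_factory=lambda: {"children": 6.0, "control_adults": 8.0, "singers": 8.5}
    )
    digit_span_sd: float = 1.2
    seed: int = 0

    def __post_init__(self):
        for v in list(self.native_vot.values()) + [f for pair in self.native_formant.values() for f in pair]:
            if not np.isfinite(v):
                raise ValueError("native reference must be finite")
        for sd in (
            self.vot_between_sd,
            self.vot_within_sd,
            *self.formant_between_sd,
            *self.formant_within_sd,
        ):
            if sd < 0:
                raise ValueError("standard deviations must be non-negative")


def default_acoustic_ground_truth(seed: int = 0) -> AcousticGroundTruth:
    """Study-condition defaults (seconds and Hz)."""
    native_formant = {
        "a": (800.0, 1400.0),
        "e": (500.0, 2100.0),
        "i": (320.0, 2600.0),
        "o": (500.0, 950.0),
        "u": (350.0, 800.0),
    }

    def offset(vowel, d1, d2):
        f1, f2 = native_formant[vowel]
        return (f1 + d1, f2 + d2)

    formant_mean = {
        "children": {v: offset(v, 25.0, 50.0) for v in VOWELS},
        "control_adults": {v: offset(v, 35.0, 70.0) for v in VOWELS},
        "singers": {v: offset(v, 15.0, 30.0) for v in VOWELS},
    }
    # group-specific difficulty: /o/ hardest for control adults; /i/ hard
    # for both children and control adults
    formant_mean["control_adults"]["o"] = offset("o", 120.0, 240.0)
    formant_mean["children"]["o"] = offset("o", 45.0, 90.0)
    formant_mean["singers"]["o"] = offset("o", 30.0, 60.0)
    formant_mean["control_adults"]["i"] = offset("i", 70.0, 170.0)
    formant_mean["children"]["i"] = offset("i", 60.0, 140.0)
    formant_mean["singers"]["i"] = offset("i", 15.0, 30.0)

    return AcousticGroundTruth(
        vot_mean={
            "children": {"b": -0.068, "d": -0.070},
            "control_adults": {"b": -0.045, "d": -0.040},
            "singers": {"b": -0.058, "d": -0.055},
        },
        formant_mean=formant_mean,
        native_vot={"b": -0.075, "d": -0.080},
        native_formant=native_formant,
        seed=seed,
    )


@dataclass
class AcousticDataset:
    measurements: pd.DataFrame  # subject x word x phoneme token x repetition x rater
    native: pd.DataFrame  # native speaker tokens, one per word x phoneme slot
    subjects: pd.DataFrame  # subject_id, group, digit_span


def generate_acoustics(
    ground_truth: AcousticGroundTruth,
    groups=GROUPS,
    n_per_group: int = 20,
    n_raters: int = 2,
    seed: int | None = None,
) -> AcousticDataset:
    """Draw per-subject measurement tables plus the native reference.

    Each subject has a random speaker offset (between-speaker sd), each
    token a within-speaker deviation, and each rater an independent
    measurement error. The native reference tokens are noiseless.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be at least 2")
    for g in groups:
        if g not in ground_truth.vot_mean:
            raise ValueError(f"unknown group label: {g}")
    rng = np.random.default_rng(ground_truth.seed if seed is None else seed)

    rows = []
    subj_rows = []
    for group in groups:
        for i in range(n_per_group):
            sid = f"{group}_{i + 1:02d}"
            vot_off = rng.normal(0.0, ground_truth.vot_between_sd)
            f_off = rng.normal(0.0, ground_truth.formant_between_sd, size=2)
            subj_rows.append(
                {
                    "subject_id": sid,
                    "group": group,
                    "digit_span": rng.normal(
                        ground_truth.digit_span_mean[group], ground_truth.digit_span_sd
                    ),
                }
            )
            for word, (cons, vowels) in WORDS.items():
                for rep in REPETITIONS:
                    true_vot = (
                        ground_truth.vot_mean[group][cons]
                        + vot_off
                        + rng.normal(0.0, ground_truth.vot_within_sd)
                    )
                    for rater in range(1, n_raters + 1):
                        rows.append(
                            {
                                "subject_id": sid,
                                "group": group,
                                "word": word,
                                "kind": "consonant",
                                "phoneme": cons,
                                "token": 0,
                                "repetition": rep,
                                "rater": rater,
                                "vot": true_vot + rng.normal(0.0, ground_truth.vot_rater_sd),
                                "f1": np.nan,
                                "f2": np.nan,
                            }
                        )
                    for slot, vowel in enumerate(vowels):
                        mean = np.asarray(ground_truth.formant_mean[group][vowel])
                        true_f = (
                            mean + f_off + rng.normal(0.0, ground_truth.formant_within_sd, size=2)
                        )
                        for rater in range(1, n_raters + 1):
                            meas = true_f + rng.normal(0.0, ground_truth.formant_rater_sd, size=2)
                            f1, f2 = float(min(meas)), float(max(meas))
                            rows.append(
                                {
                                    "subject_id": sid,
                                    "group": group,
                                    "word": word,
                                    "kind": "vowel",
                                    "phoneme": vowel,
                                    "token": slot,
                                    "repetition": rep,
                                    "rater": rater,
                                    "vot": np.nan,
                                    "f1": f1,
                                    "f2": f2,
                                }
                            )

    native_rows = []
    for word, (cons, vowels) in WORDS.items():
        native_rows.append(
            {
                "subject_id": "native",
                "group": "native",
                "word": word,
                "kind": "consonant",
                "phoneme": cons,
                "token": 0,
                "repetition": 1,
                "rater": 0,
                "vot": ground_truth.native_vot[cons],
                "f1": np.nan,
                "f2": np.nan,
            }
        )
        for slot, vowel in enumerate(vowels):
            f1, f2 = ground_truth.native_formant[vowel]
            native_rows.append(
                {
                    "subject_id": "native",
                    "group": "native",
                    "word": word,
                    "kind": "vowel",
                    "phoneme": vowel,
                    "token": slot,
                    "repetition": 1,
                    "rater": 0,
                    "vot": np.nan,
                    "f1": f1,
                    "f2": f2,
                }
            )

    return AcousticDataset(
        measurements=pd.DataFrame(rows),
        native=pd.DataFrame(native_rows),
        subjects=pd.DataFrame(subj_rows),
    )
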