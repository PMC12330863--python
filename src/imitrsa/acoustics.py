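"""Imitation scoring from acoustic measurement tables.

Raters' measurements are averaged (with inter-rater agreement reported);
vowel formants are Lobanov-normalized (per-speaker z-score of F1 and F2
across that speaker's vowel tokens, removing gender/age differences in
vocal-tract scale); imitation quality is the Euclidean distance to the
native speaker's vowel position in the normalized (F1, F2) plane, and the
absolute difference to the native VOT for the voiced stops. Distances are
averaged across the words containing each phoneme and analyzed in a mixed
ANOVA of group by imitation order with Bonferroni post-hoc contrasts.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pingouin as pg

ID_COLS = ["subject_id", "group", "word", "kind", "phoneme", "token", "repetition"]
MEASURES = ["vot", "f1", "f2"]


class RaterAgreementUndefined(ValueError):
    """No overlapping measurements between raters."""


def merge_raters(table: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, float]]:
    """Average measurements over raters; report inter-rater Pearson r.

    Returns the merged table (one row per measurement) and a dict of
    inter-rater correlations per measure (NaN when only one rater, averaged
    over rater pairs when more than two).
    """
    merged = table.groupby(ID_COLS, as_index=False, sort=False)[MEASURES].mean()
    raters = sorted(table["rater"].unique())
    agreement: dict[str, float] = {}
    for measure in MEASURES:
        if len(raters) < 2:
            agreement[measure] = np.nan
            continue
        wide = table.pivot_table(index=ID_COLS, columns="rater", values=measure)
        wide = wide.dropna()
        if wide.empty:
            raise RaterAgreementUndefined(
                f"no overlapping {measure} measurements between raters"
            )
        rs = []
        for i in range(len(raters)):
            for j in range(i + 1, len(raters)):
                rs.append(wide[raters[i]].corr(wide[raters[j]]))
        agreement[measure] = float(np.mean(rs))
    return merged, agreement


def lobanov_normalize(table: pd.DataFrame) -> pd.DataFrame:
    """Per-speaker z-score of F1 and F2 across each speaker's vowel tokens.

    Requires at least two distinct values per formant per speaker (the
    native reference is normalized within its own token distribution).
    Returns the vowel rows with added ``zf1``/``zf2`` columns.
    """
    vowels = table[table["kind"] == "vowel"].copy()
    if vowels.empty:
        raise ValueError("no vowel rows in table")
    for col, zcol in (("f1", "zf1"), ("f2", "zf2")):
        grp = vowels.groupby("subject_id")[col]
        mean = grp.transform("mean")
        sd = grp.transform("std")
        dead = vowels.loc[sd == 0, "subject_id"].unique()
        if len(dead):
            raise ValueError(f"zero {col} variance for speaker(s): {sorted(dead)}")
        vowels[zcol] = (vowels[col] - mean) / sd
    return vowels


def vowel_distance(
    normalized: pd.DataFrame, normalized_native: pd.DataFrame
) -> pd.DataFrame:
    """Euclidean distance to the native vowel in the normalized (F1, F2) plane.

    The native reference position per vowel is the mean of the native
    speaker's normalized tokens. Token distances are averaged across the
    words containing each vowel, yielding one row per subject x vowel x
    repetition.
    """
    ref = normalized_native.groupby("phoneme")[["zf1", "zf2"]].mean()
    missing = set(normalized["phoneme"]) - set(ref.index)
    if missing:
        raise ValueError(f"missing native reference for vowel(s): {sorted(missing)}")
    df = normalized.merge(
        ref.rename(columns={"zf1": "ref_zf1", "zf2": "ref_zf2"}),
        left_on="phoneme",
        right_index=True,
    )
    df["distance"] = np.hypot(df["zf1"] - df["ref_zf1"], df["zf2"] - df["ref_zf2"])
    out = (
        df.groupby(["subject_id", "group", "phoneme", "repetition"], as_index=False)[
            "distance"
        ]
        .mean()
        .rename(columns={"phoneme": "vowel"})
    )
    return out


def vot_distance(table: pd.DataFrame, native_vot: dict[str, float]) -> pd.DataFrame:
    """Absolute difference to the native VOT, averaged across words.

    ``native_vot`` maps consonant -> native VOT in seconds. Consonants
    absent from the reference are skipped with a warning. Also carries the
    subject's mean raw VOT per consonant and repetition.
    """
    cons = table[table["kind"] == "consonant"].copy()
    if cons.empty:
        raise ValueError("no consonant rows in table")
    known = cons["phoneme"].isin(native_vot)
    if (~known).any():
        skipped = sorted(cons.loc[~known, "phoneme"].unique())
        warnings.warn(f"no native VOT for consonant(s) {skipped}; skipped", RuntimeWarning)
        cons = cons[known]
    cons["distance"] = (cons["vot"] - cons["phoneme"].map(native_vot)).abs()
    out = (
        cons.groupby(["subject_id", "group", "phoneme", "repetition"], as_index=False)
        .agg(distance=("distance", "mean"), vot=("vot", "mean"))
        .rename(columns={"phoneme": "consonant"})
    )
    return out


def group_by_order_anova(
    distances: pd.DataFrame, dv: str = "distance"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mixed ANOVA of group (between) by repetition (within) on one phoneme's scores.

    Expects one row per subject x repetition (pass one consonant or vowel at
    a time). Returns the ANOVA table (with partial eta squared, ``np2``) and
    Bonferroni-corrected pairwise group contrasts with partial eta squared.
    """
    counts = distances.groupby("group")["subject_id"].nunique()
    if (counts < 2).any():
        raise ValueError("need at least 2 subjects per group")
    cells = distances.groupby(["subject_id", "repetition"])[dv].count().unstack()
    if cells.isna().any().any() or (cells != 1).any().any():
        raise ValueError("each subject needs exactly one value per repetition")
    aov = pg.mixed_anova(
        data=distances, dv=dv, within="repetition", subject="subject_id", between="group"
    )
    posthoc = pg.pairwise_tests(
        data=distances,
        dv=dv,
        within="repetition",
        subject="subject_id",
        between="group",
        padjust="bonf",
    )
    posthoc = posthoc[posthoc["Contrast"] == "group"].copy()
    posthoc["np2"] = posthoc["T"] ** 2 / (posthoc["T"] ** 2 + posthoc["dof"])
    return aov, posthoc


def read_acoustic_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_acoustic_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)
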