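"""Reading, 20-s reintegration and alignment of count and observation data.

The pipeline pairs accelerometer epochs with momentary-time-sampling
observation codes: raw 10-s count epochs are summed in consecutive pairs to
20-s analysis epochs, matched to the 20-s observation interval grid, screened
for invalid (out-of-hall) or implausibly large records, and split by session
into calibration and held-out validation participants.

Canonical in-memory containers are pandas DataFrames with the column schemas

* count epochs:   participant, session, offset_s, vertical_counts, vm_counts
* observations:   participant, session, interval, category, valid
* aligned epochs: participant, session, interval, vertical_counts_20s,
  vm_counts_20s, category, valid
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

COUNT_COLUMNS = ["participant", "session", "offset_s", "vertical_counts", "vm_counts"]
PAIRED_COLUMNS = ["participant", "session", "interval", "vertical_counts_20s", "vm_counts_20s"]
SOFIT_COLUMNS = ["participant", "session", "interval", "category", "valid"]
ALIGNED_COLUMNS = PAIRED_COLUMNS + ["category", "valid"]


def _empty(columns) -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=object) for c in columns})


def _maybe_numeric(series: pd.Series) -> pd.Series:
    try:
        return pd.to_numeric(series)
    except (ValueError, TypeError):
        return series


def _read_delimited(path, sep: str) -> Optional[pd.DataFrame]:
    try:
        return pd.read_csv(path, sep=sep)
    except pd.errors.EmptyDataError:
        return None


def read_count_epochs(path, sep: str = ",") -> pd.DataFrame:
    """Read a delimited epoch-count export into the canonical count schema.

    The file must have a header with columns ``participant``, ``session``,
    ``offset_s`` and either ``axis1`` plus ``vm`` (vertical-axis and
    vector-magnitude counts per 10-s epoch) or three raw axis columns
    ``axis1, axis2, axis3``, in which case the vector magnitude is the
    rounded Euclidean norm of the three.  Rows with non-numeric counts are
    dropped with a logged warning naming their line numbers; negative counts
    raise.  Rows out of time order are re-sorted with a warning.
    """
    df = _read_delimited(path, sep)
    if df is None or df.empty:
        logger.warning("count-epoch file %s is empty", path)
        return _empty(COUNT_COLUMNS)

    required = {"participant", "session", "offset_s"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"count-epoch file missing required columns: {sorted(missing)}")
    three_axis = {"axis1", "axis2", "axis3"} <= set(df.columns)
    if "vm" in df.columns and "axis1" in df.columns:
        value_cols = ["axis1", "vm"]
    elif three_axis:
        value_cols = ["axis1", "axis2", "axis3"]
    else:
        raise ValueError(
            "count-epoch file needs either columns {axis1, vm} or {axis1, axis2, axis3}"
        )

    numeric = df[["offset_s"] + value_cols].apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().any(axis=1)
    if bad.any():
        lines = [int(i) + 2 for i in df.index[bad]]  # +2: header + 1-based
        logger.warning("dropping %d malformed count rows at lines %s", bad.sum(), lines)
        df = df[~bad].copy()
        numeric = numeric[~bad]
    if df.empty:
        return _empty(COUNT_COLUMNS)
    for col in value_cols:
        neg = numeric[col] < 0
        if neg.any():
            line = int(df.index[neg][0]) + 2
            raise ValueError(f"negative counts in column {col!r} at line {line}")

    out = pd.DataFrame(
        {
            "participant": df["participant"].astype(str).to_numpy(),
            "session": _maybe_numeric(df["session"]),
            "offset_s": numeric["offset_s"].astype(np.int64).to_numpy(),
        }
    )
    if (out["offset_s"] % 10 != 0).any():
        raise ValueError("epoch offsets must be multiples of 10 s")
    out["vertical_counts"] = numeric["axis1"].round().astype(np.int64).to_numpy()
    if three_axis and "vm" not in df.columns:
        norm = np.sqrt((numeric[["axis1", "axis2", "axis3"]] ** 2).sum(axis=1))
        out["vm_counts"] = np.rint(norm).astype(np.int64)
    else:
        out["vm_counts"] = numeric["vm"].round().astype(np.int64).to_numpy()

    if (out["vm_counts"] < out["vertical_counts"]).any():
        n = int((out["vm_counts"] < out["vertical_counts"]).sum())
        logger.warning("%d epochs have vector-magnitude counts below vertical counts", n)

    sorted_out = out.sort_values(["participant", "session", "offset_s"], kind="mergesort")
    if not sorted_out.index.equals(out.index):
        logger.warning("count epochs were out of time order; re-sorted")
    return sorted_out.reset_index(drop=True)


def read_sofit_log(path, sep: str = ",") -> pd.DataFrame:
    """Read a delimited observation log (one row per 20-s interval).

    Columns: participant, session, interval, category and optionally valid
    (absent means every record is valid).  Categories outside 1..5 and
    duplicate (participant, session, interval) rows raise.
    """
    df = _read_delimited(path, sep)
    if df is None or df.empty:
        logger.warning("observation log %s is empty", path)
        return _empty(SOFIT_COLUMNS)

    required = {"participant", "session", "interval", "category"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"observation log missing required columns: {sorted(missing)}")

    cat = pd.to_numeric(df["category"], errors="coerce")
    bad = cat.isna() | (cat != cat.round()) | (cat < 1) | (cat > 5)
    if bad.any():
        line = int(df.index[bad][0]) + 2
        raise ValueError(f"observation category outside 1..5 at line {line}")

    out = pd.DataFrame(
        {
            "participant": df["participant"].astype(str).to_numpy(),
            "session": _maybe_numeric(df["session"]),
            "interval": pd.to_numeric(df["interval"]).astype(np.int64).to_numpy(),
            "category": cat.astype(np.int64).to_numpy(),
        }
    )
    if "valid" in df.columns:
        out["valid"] = pd.to_numeric(df["valid"]).astype(np.int64).to_numpy() != 0
    else:
        out["valid"] = True

    dup = out.duplicated(["participant", "session", "interval"])
    if dup.any():
        key = out.loc[dup.idxmax(), ["participant", "session", "interval"]].tolist()
        raise ValueError(f"duplicate observation record for (participant, session, interval)={key}")
    return out.sort_values(["participant", "session", "interval"], kind="mergesort").reset_index(drop=True)


def sum_to_20s(counts: pd.DataFrame) -> pd.DataFrame:
    """Sum consecutive pairs of 10-s epochs into 20-s analysis epochs.

    Pairing starts at each participant's first epoch; pair (2k, 2k+1) maps to
    interval k.  A gap in the 10-s offset grid raises (alignment cannot be
    guaranteed); an unpaired trailing epoch is dropped with a warning.
    """
    if counts.empty:
        return _empty(PAIRED_COLUMNS)
    frames = []
    for (pid, sess), g in counts.groupby(["participant", "session"], sort=True):
        g = g.sort_values("offset_s", kind="mergesort")
        off = g["offset_s"].to_numpy()
        if len(off) > 1 and not np.all(np.diff(off) == 10):
            raise ValueError(
                f"gap in 10-s epoch offsets for participant {pid!r} session {sess!r}"
            )
        n_pairs = len(g) // 2
        if len(g) % 2:
            logger.warning(
                "dropping unpaired trailing 10-s epoch for participant %s session %s", pid, sess
            )
        if n_pairs == 0:
            continue
        v = g["vertical_counts"].to_numpy()[: 2 * n_pairs]
        m = g["vm_counts"].to_numpy()[: 2 * n_pairs]
        frames.append(
            pd.DataFrame(
                {
                    "participant": pid,
                    "session": sess,
                    "interval": np.arange(n_pairs, dtype=np.int64),
                    "vertical_counts_20s": v[0::2] + v[1::2],
                    "vm_counts_20s": m[0::2] + m[1::2],
                }
            )
        )
    if not frames:
        return _empty(PAIRED_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def align(paired: pd.DataFrame, sofit: pd.DataFrame,
          start_offset_intervals: int = 0) -> tuple[pd.DataFrame, dict]:
    """Inner-join 20-s count epochs with observation records.

    ``start_offset_intervals`` shifts the observation interval indices
    relative to the count intervals (observation interval i matches count
    interval i + offset), making the study's manual video synchronisation an
    explicit, reproducible parameter.  Intervals present in only one source
    are dropped and tallied in the returned report.
    """
    s = sofit.copy()
    s["interval"] = s["interval"] + int(start_offset_intervals)
    merged = paired.merge(
        s[["participant", "session", "interval", "category", "valid"]],
        on=["participant", "session", "interval"],
        how="inner",
    )
    if merged.empty:
        raise ValueError("zero overlapping intervals between counts and observations")
    report = {
        "aligned": int(len(merged)),
        "counts_unmatched": int(len(paired) - len(merged)),
        "observations_unmatched": int(len(s) - len(merged)),
    }
    merged = merged.sort_values(["participant", "session", "interval"], kind="mergesort")
    return merged.reset_index(drop=True), report


@dataclass(frozen=True)
class ScreenRules:
    """Epoch screening rules.

    ``respect_validity`` drops records flagged invalid (participant out of the
    hall during the interval).  The maximum plausible 20-s counts implement
    the spurious-score screen; they default to None (no exclusion) so that no
    data is silently discarded unless a limit is set explicitly.
    """

    respect_validity: bool = True
    max_vertical_20s: Optional[int] = None
    max_vm_20s: Optional[int] = None


def screen(aligned: pd.DataFrame, rules: ScreenRules = ScreenRules()) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply screening rules; return (retained epochs, exclusion report).

    The report counts exclusions per rule per participant; an epoch failing
    several rules is tallied once, validity first.
    """
    excluded = pd.Series("", index=aligned.index, dtype=object)
    if rules.respect_validity and "valid" in aligned.columns:
        excluded[~aligned["valid"].astype(bool)] = "invalid"
    spurious = pd.Series(False, index=aligned.index)
    if rules.max_vertical_20s is not None:
        spurious |= aligned["vertical_counts_20s"] > rules.max_vertical_20s
    if rules.max_vm_20s is not None:
        spurious |= aligned["vm_counts_20s"] > rules.max_vm_20s
    excluded[spurious & (excluded == "")] = "spurious"

    mask = excluded == ""
    retained = aligned[mask].reset_index(drop=True)
    rep = (
        aligned.loc[~mask]
        .assign(rule=excluded[~mask])
        .groupby(["participant", "rule"], sort=True)
        .size()
        .rename("n_excluded")
        .reset_index()
    )
    if rep.empty:
        rep = pd.DataFrame({"participant": pd.Series(dtype=object),
                            "rule": pd.Series(dtype=object),
                            "n_excluded": pd.Series(dtype=np.int64)})
    return retained, rep


def split_calibration_validation(aligned: pd.DataFrame, per_session: int = 2,
                                 seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Session-stratified hold-out split.

    Exactly ``per_session`` participants are drawn (seeded, without
    replacement) from each session for the validation group; all their epochs
    move together.  A session with too few participants raises.  Returns
    (calibration epochs, validation epochs, manifest).
    """
    if aligned.empty:
        raise ValueError("cannot split an empty aligned set")
    rng = np.random.default_rng(seed)
    validation_sel: dict = {}
    calibration_sel: dict = {}
    for sess in sorted(aligned["session"].unique()):
        parts = sorted(aligned.loc[aligned["session"] == sess, "participant"].unique())
        if per_session > 0 and len(parts) <= per_session:
            raise ValueError(
                f"session {sess!r} has {len(parts)} participants; need more than {per_session}"
            )
        chosen = sorted(rng.choice(np.array(parts, dtype=object), size=per_session, replace=False)) \
            if per_session > 0 else []
        validation_sel[sess] = [str(p) for p in chosen]
        calibration_sel[sess] = [str(p) for p in parts if p not in chosen]

    keys = aligned[["session", "participant"]].astype(str).agg("/".join, axis=1)
    val_keys = {f"{s}/{p}" for s, ps in validation_sel.items() for p in ps}
    mask = keys.isin(val_keys)
    manifest = {
        "seed": int(seed),
        "per_session": int(per_session),
        "validation": {str(s): v for s, v in validation_sel.items()},
        "calibration": {str(s): v for s, v in calibration_sel.items()},
    }
    return (
        aligned[~mask].reset_index(drop=True),
        aligned[mask].reset_index(drop=True),
        manifest,
    )


def counts20_to_cpm(value):
    """Convert a counts/20-s threshold to counts per minute (x 3)."""
    arr = np.asarray(value)
    if np.any(arr < 0):
        raise ValueError("counts must be nonnegative")
    out = arr * 3
    if np.isscalar(value) or np.ndim(value) == 0:
        return out.item()
    return out
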