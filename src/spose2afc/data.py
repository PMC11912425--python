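"""Data model, I/O, and worker-level quality control for triplet 2-AFC tables.

A *trial* shows a reference image on top and two option images below; the
participant picks the option more similar to the reference.  Trials live in
delimited text with the header

    worker_id,reference,option_a,option_b,choice,rt_ms,position[,repeat_block]

where ``choice`` is ``A`` or ``B`` (which option was picked), ``rt_ms`` the
response time in milliseconds, and ``position`` (optional) records whether the
chosen option sat on the ``left`` or ``right`` of the screen.  Image metadata
is a CSV with header ``image_id,class_label,exemplar_index``.

Worker exclusion follows crowdsourcing practice for this task family: workers
with at least 60 trials are dropped if more than 25% of their responses were
faster than 600 ms or more than 50% faster than 900 ms; workers with at least
160 trials are additionally dropped if more than 60% of their responses landed
on one of the two option positions.  All thresholds are strict inequalities
and exclusion removes every trial of an excluded worker.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import format_pct

logger = logging.getLogger(__name__)

TRIAL_COLUMNS = ["worker_id", "reference", "option_a", "option_b", "choice", "rt_ms"]
OPTIONAL_TRIAL_COLUMNS = ["position", "repeat_block"]
IMAGE_COLUMNS = ["image_id", "class_label", "exemplar_index"]

#: QC thresholds (strict inequalities; boundary values are kept)
MIN_TRIALS_RT_RULE = 60
MIN_TRIALS_POSITION_RULE = 160
FAST_RT_MS = 600.0
SLOW_RT_MS = 900.0
FAST_FRAC = 0.25
SLOW_FRAC = 0.50
POSITION_FRAC = 0.60


def _sep_for(path: str) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab")) else ","


def read_images(path) -> pd.DataFrame:
    """Read the image-metadata table (image_id, class_label, exemplar_index)."""
    images = pd.read_csv(path, sep=_sep_for(path), dtype={"image_id": str, "class_label": str})
    missing = [c for c in IMAGE_COLUMNS if c not in images.columns]
    if missing:
        raise ValueError(f"image table missing columns: {missing}")
    if images["image_id"].duplicated().any():
        dupes = images.loc[images["image_id"].duplicated(), "image_id"].tolist()
        raise ValueError(f"duplicate image ids: {dupes}")
    return images


def write_images(images: pd.DataFrame, path) -> None:
    images.to_csv(path, sep=_sep_for(path), index=False)


def _check_header(path, sep: str) -> None:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
    seen, dup = set(), []
    for name in header:
        if name in seen:
            dup.append(name)
        seen.add(name)
    if dup:
        raise ValueError(f"duplicate header column(s): {dup}")


def read_trials(path, images: pd.DataFrame | None = None) -> pd.DataFrame:
    """Read and validate a triplet-trial table.

    Parameters
    ----------
    path : str or path-like
        CSV (or ``.tsv``) file with the documented header.
    images : DataFrame, optional
        Image-metadata table; when given, every referenced image id must
        exist in it (unknown ids raise with the offending row number).

    Returns
    -------
    DataFrame with one validated row per trial, row order preserved.
    """
    sep = _sep_for(path)
    _check_header(path, sep)
    trials = pd.read_csv(
        path, sep=sep,
        dtype={"worker_id": str, "reference": str, "option_a": str, "option_b": str,
               "choice": str},
    )
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")
    if len(trials) == 0:
        logger.warning("trial file %s contains a header but no trials", path)
        return trials
    return validate_trials(trials, images)


def validate_trials(trials: pd.DataFrame, images: pd.DataFrame | None = None) -> pd.DataFrame:
    """Validate trial invariants; raises on the first malformed row."""
    bad_choice = ~trials["choice"].isin(["A", "B"])
    if bad_choice.any():
        row = int(np.flatnonzero(bad_choice)[0])
        raise ValueError(f"row {row}: choice must be 'A' or 'B', got {trials['choice'].iloc[row]!r}")
    same = (
        (trials["reference"] == trials["option_a"])
        | (trials["reference"] == trials["option_b"])
        | (trials["option_a"] == trials["option_b"])
    )
    if same.any():
        row = int(np.flatnonzero(same)[0])
        raise ValueError(f"row {row}: reference and options must be pairwise distinct")
    if images is not None:
        known = set(images["image_id"])
        for col in ("reference", "option_a", "option_b"):
            unknown = ~trials[col].isin(known)
            if unknown.any():
                row = int(np.flatnonzero(unknown)[0])
                raise ValueError(
                    f"row {row}: unknown image id {trials[col].iloc[row]!r} in column {col}"
                )
    if (trials["rt_ms"].dropna() < 0).any():
        raise ValueError("negative rt_ms encountered")
    return trials


def write_trials(trials: pd.DataFrame, path) -> None:
    trials.to_csv(path, sep=_sep_for(path), index=False)


def summarize_workers(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-worker trial counts and the QC fractions.

    Returns one row per worker with ``n_trials``, ``frac_rt_below_600``,
    ``frac_rt_below_900`` and ``frac_position_majority`` (the share of
    responses at the more-chosen of the two option positions; NaN when the
    worker has no position data).  Workers with any missing response time are
    flagged ``unfilterable`` rather than silently passed.
    """
    rows = []
    for worker, grp in trials.groupby("worker_id", sort=True):
        n = len(grp)
        rt = grp["rt_ms"]
        unfilterable = bool(rt.isna().any())
        if unfilterable:
            f600 = f900 = np.nan
            logger.warning("worker %s has trials with missing rt_ms; flagged unfilterable", worker)
        else:
            f600 = float((rt < FAST_RT_MS).mean())
            f900 = float((rt < SLOW_RT_MS).mean())
        if "position" in grp.columns and grp["position"].notna().any():
            pos = grp["position"].dropna()
            fpos = float(pos.value_counts(normalize=True).max())
        else:
            fpos = np.nan
        rows.append(
            dict(worker_id=worker, n_trials=n, frac_rt_below_600=f600,
                 frac_rt_below_900=f900, frac_position_majority=fpos,
                 unfilterable=unfilterable)
        )
    return pd.DataFrame(
        rows,
        columns=["worker_id", "n_trials", "frac_rt_below_600", "frac_rt_below_900",
                 "frac_position_majority", "unfilterable"],
    )


@dataclass
class ExclusionReport:
    """Summary of a worker-exclusion pass."""

    excluded_workers: list = field(default_factory=list)
    unfilterable_workers: list = field(default_factory=list)
    n_trials_total: int = 0
    n_trials_excluded: int = 0

    @property
    def percent_excluded(self) -> float:
        if self.n_trials_total == 0:
            return 0.0
        return 100.0 * self.n_trials_excluded / self.n_trials_total

    def format_percent(self) -> str:
        return format_pct(self.n_trials_excluded, self.n_trials_total)

    def to_dict(self) -> dict:
        return dict(
            excluded_workers=list(self.excluded_workers),
            unfilterable_workers=list(self.unfilterable_workers),
            n_trials_total=self.n_trials_total,
            n_trials_excluded=self.n_trials_excluded,
            percent_excluded=round(self.percent_excluded, 2),
        )


def exclusion_mask(summaries: pd.DataFrame) -> pd.Series:
    """Boolean mask over the summary rows: True where the worker is excluded."""
    n = summaries["n_trials"]
    rt_rule = (n >= MIN_TRIALS_RT_RULE) & (
        (summaries["frac_rt_below_600"] > FAST_FRAC)
        | (summaries["frac_rt_below_900"] > SLOW_FRAC)
    )
    pos_rule = (n >= MIN_TRIALS_POSITION_RULE) & (
        summaries["frac_position_majority"].fillna(0.0) > POSITION_FRAC
    )
    return (rt_rule.fillna(False)) | pos_rule


def exclude_workers(
    trials: pd.DataFrame, summaries: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Drop every trial of workers failing the QC rules.

    A worker is excluded iff ``n_trials >= 60`` and (>25% of RTs < 600 ms or
    >50% of RTs < 900 ms), or ``n_trials >= 160`` and >60% of responses on one
    option position.  Workers with missing position data are exempt from the
    position rule (logged) but still subject to the RT rules.

    Returns the kept trials and an :class:`ExclusionReport`; kept + excluded
    trials partition the input exactly.
    """
    if summaries is None:
        summaries = summarize_workers(trials)
    excluded = summaries.loc[exclusion_mask(summaries), "worker_id"].tolist()
    unfilterable = summaries.loc[summaries["unfilterable"], "worker_id"].tolist()
    no_pos = summaries["frac_position_majority"].isna() & (
        summaries["n_trials"] >= MIN_TRIALS_POSITION_RULE
    )
    if no_pos.any():
        logger.warning(
            "%d worker(s) lack position data and are exempt from the position rule",
            int(no_pos.sum()),
        )
    drop = trials["worker_id"].isin(excluded)
    report = ExclusionReport(
        excluded_workers=excluded,
        unfilterable_workers=unfilterable,
        n_trials_total=len(trials),
        n_trials_excluded=int(drop.sum()),
    )
    return trials.loc[~drop].copy(), report
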