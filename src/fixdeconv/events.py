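"""Fixation-category labeling and oculomotor covariate extraction.

Free-viewing scanpaths contain *refixations* — returns of the gaze to a
location visited earlier in the trial — and, symmetrically, *precursor
fixations*: the first visits to locations that are later refixated.
Everything this module does flows from a single spatial criterion: a
refixation lands within ``radius`` (default 2 degrees of visual angle) of an
earlier fixation, after the gaze has actually left that region.

The labeling rules, in the order they are applied per trial:

1. A fixation *qualifies* as a refixation of the earliest previous fixation
   ``i`` such that (a) it lies within ``radius`` of ``i``, (b) at least one
   intervening fixation lay outside the radius of ``i`` (the region was
   left), and (c) it is itself at least ``radius`` away from the immediately
   preceding fixation (it arrives by a real displacement, not a drift).
2. Chains of consecutive returns: if the immediately preceding fixation also
   qualified as a refixation, the current one is stripped — only the first
   return of a chain keeps the refixation label.
3. A refixation within radius of several mutually close earlier fixations is
   scored once, attributed to the earliest qualifying one; that fixation
   becomes its precursor.
4. A fixation that would carry both a precursor and a refixation label is
   assigned to neither and falls into the leftover "other" category.
5. Optionally (default on) the fixation immediately preceding a refixation
   is reassigned to "other": it carries preparatory activity specific to the
   upcoming return.  It is reassigned, not deleted, because the
   deconvolution model must see every fixation.
6. Ordinary fixations are fixations "without history": no other fixation of
   the trial, earlier or later, lies within ``radius`` of them.
7. Everything else is "other".

Fixation tables are plain :class:`pandas.DataFrame` objects with columns
``trial``, ``rank``, ``onset``, ``duration``, ``x``, ``y`` (and optionally
``participant``); saccade tables have ``trial``, ``onset``, ``amplitude``,
``angle``, ``from_rank``, ``to_rank``.  Positions and amplitudes are in
degrees of visual angle, times in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

PRECURSOR = "precursor"
REFIXATION = "refixation"
ORDINARY = "ordinary"
OTHER = "other"
CATEGORIES = (PRECURSOR, REFIXATION, ORDINARY, OTHER)

FIXATION_COLUMNS = ("trial", "rank", "onset", "duration", "x", "y")
SACCADE_COLUMNS = ("trial", "onset", "amplitude", "angle", "from_rank", "to_rank")


@dataclass(frozen=True)
class LabelConfig:
    """Parameters of the categorization rules.

    radius
        Spatial revisit criterion in degrees of visual angle.
    drop_pre_refixation
        Reassign the fixation immediately before each refixation to "other".
    merge_ordinary_other
        Collapse ordinary fixations into the "other" reference category
        (the merged-category variant of the model).
    """

    radius: float = 2.0
    drop_pre_refixation: bool = True
    merge_ordinary_other: bool = False

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValueError("radius must be positive")


def _validate_fixations(fix: pd.DataFrame) -> None:
    missing = [c for c in FIXATION_COLUMNS if c not in fix.columns]
    if missing:
        raise ValueError(f"fixation table missing columns: {missing}")
    if not np.isfinite(fix[["x", "y"]].to_numpy()).all():
        raise ValueError("non-finite fixation positions")
    if (fix["duration"] <= 0).any():
        raise ValueError("fixation durations must be positive")
    keys = ["participant", "trial"] if "participant" in fix.columns else ["trial"]
    for trial, g in fix.groupby(keys, sort=False):
        ranks = g["rank"].to_numpy()
        if not np.array_equal(ranks, np.arange(1, len(g) + 1)):
            raise ValueError(
                f"trial {trial}: ranks must be consecutive from 1 in sorted order"
            )
        onsets = g["onset"].to_numpy()
        ends = onsets + g["duration"].to_numpy()
        if np.any(onsets[1:] < ends[:-1] - 1e-9):
            raise ValueError(f"trial {trial}: overlapping fixation intervals")


def _label_positions(x: np.ndarray, y: np.ndarray, radius: float,
                     drop_pre_refixation: bool) -> tuple[np.ndarray, np.ndarray]:
    """Label one trial. Returns (categories, precursor index per refixation or -1)."""
    n = len(x)
    cat = np.array([OTHER] * n, dtype=object)
    link = np.full(n, -1, dtype=int)
    if n == 0:
        return cat, link
    pos = np.column_stack([x, y])
    d = squareform(pdist(pos)) if n > 1 else np.zeros((1, 1))

    qualifies = np.zeros(n, dtype=bool)
    for j in range(1, n):
        if d[j, j - 1] < radius:
            continue  # gaze has not left the immediate neighbourhood
        for i in range(j - 1):
            if d[i, j] < radius and np.any(d[i, i + 1:j] >= radius):
                qualifies[j] = True
                link[j] = i
                break  # earliest qualifying precursor

    # only the first return of a chain of consecutive returns keeps its label
    refix = qualifies & ~np.r_[False, qualifies[:-1]]

    # a fixation cannot be both a precursor and a refixation
    targets = {link[j] for j in np.flatnonzero(refix)}
    double = np.array([refix[j] and j in targets for j in range(n)])
    refix &= ~double
    link[~refix] = -1

    # precursors: targets of surviving refixations that never qualified as
    # refixations themselves (chain-stripped or double-role targets stay other)
    precursors = {link[j] for j in np.flatnonzero(refix) if not qualifies[link[j]]}

    cat[refix] = REFIXATION
    for p in precursors:
        cat[p] = PRECURSOR

    pre_reassigned = np.zeros(n, dtype=bool)
    if drop_pre_refixation:
        for j in np.flatnonzero(refix):
            k = j - 1
            if k >= 0 and cat[k] == OTHER:
                pre_reassigned[k] = True

    # ordinary = isolated: no other fixation of the trial within the radius
    for j in range(n):
        if cat[j] != OTHER or pre_reassigned[j]:
            continue
        dj = np.delete(d[j], j) if n > 1 else np.array([])
        if dj.size == 0 or np.all(dj >= radius):
            cat[j] = ORDINARY
    return cat, link


def label_fixations(fixations: pd.DataFrame,
                    config: LabelConfig | None = None) -> pd.DataFrame:
    """Assign a category to every fixation.

    Returns a copy of the input with two added columns: ``category`` (one of
    ``precursor``, ``refixation``, ``ordinary``, ``other``) and
    ``precursor_rank`` (for refixations, the rank of the linked precursor
    fixation; NaN elsewhere).  Grouping is per ``trial`` (and ``participant``
    when present); input must be sorted by trial and rank.
    """
    config = config or LabelConfig()
    _validate_fixations(fixations)
    out = fixations.copy()
    out["category"] = OTHER
    out["precursor_rank"] = np.nan
    keys = ["participant", "trial"] if "participant" in out.columns else ["trial"]
    for _, g in out.groupby(keys, sort=False):
        cat, link = _label_positions(
            g["x"].to_numpy(float), g["y"].to_numpy(float),
            config.radius, config.drop_pre_refixation,
        )
        ranks = g["rank"].to_numpy()
        out.loc[g.index, "category"] = cat
        prec_rank = np.where(link >= 0, ranks[np.clip(link, 0, None)], np.nan)
        out.loc[g.index, "precursor_rank"] = prec_rank
    if config.merge_ordinary_other:
        out.loc[out["category"] == ORDINARY, "category"] = OTHER
        out["category_merged"] = True
    return out


def compute_covariates(fixations: pd.DataFrame,
                       saccades: pd.DataFrame) -> pd.DataFrame:
    """Extract per-fixation oculomotor covariates for the deconvolution model.

    For each labeled fixation: its rank and duration, x/y position, size and
    angle of the incoming saccade (the one arriving at it) and of the
    outgoing saccade (the one leaving it), and the duration of the
    immediately following fixation — the latter only when that next fixation
    is of the ordinary or "other" category, NaN otherwise.  The first
    fixation of a trial has no incoming saccade; those entries are NaN and
    can be imputed with :func:`impute_covariates`.
    """
    if "category" not in fixations.columns:
        raise ValueError("fixations must be labeled first (missing 'category')")
    missing = [c for c in SACCADE_COLUMNS if c not in saccades.columns]
    if missing:
        raise ValueError(f"saccade table missing columns: {missing}")
    if (saccades["amplitude"] < 0).any():
        raise ValueError("saccade amplitudes must be nonnegative")

    keys = ["participant", "trial"] if "participant" in fixations.columns else ["trial"]
    fix = fixations.reset_index(drop=True)
    cov = fix[keys + ["rank", "duration", "x", "y", "category"]].copy()
    cov = cov.rename(columns={"duration": "fixation_duration",
                              "rank": "fixation_rank"})

    inc = saccades.rename(columns={"to_rank": "fixation_rank",
                                   "amplitude": "incoming_saccade_size",
                                   "angle": "incoming_saccade_angle"})
    out_ = saccades.rename(columns={"from_rank": "fixation_rank",
                                    "amplitude": "outgoing_saccade_size",
                                    "angle": "outgoing_saccade_angle"})
    merge_keys = keys + ["fixation_rank"]
    cov = cov.merge(
        inc[merge_keys + ["incoming_saccade_size", "incoming_saccade_angle"]],
        on=merge_keys, how="left")
    cov = cov.merge(
        out_[merge_keys + ["outgoing_saccade_size", "outgoing_saccade_angle"]],
        on=merge_keys, how="left")

    nxt = fix[keys + ["rank", "duration", "category"]].copy()
    nxt["rank"] -= 1
    nxt = nxt.rename(columns={"rank": "fixation_rank",
                              "duration": "following_fixation_duration",
                              "category": "_next_category"})
    cov = cov.merge(nxt, on=merge_keys, how="left")
    restricted = ~cov["_next_category"].isin([ORDINARY, OTHER])
    cov.loc[restricted, "following_fixation_duration"] = np.nan
    cov = cov.drop(columns=["_next_category"])
    return cov


COVARIATE_NAMES = (
    "fixation_rank", "fixation_duration",
    "incoming_saccade_size", "outgoing_saccade_size",
    "incoming_saccade_angle", "outgoing_saccade_angle",
    "x", "y",
)


def impute_covariates(cov: pd.DataFrame,
                      columns: tuple[str, ...] = ("incoming_saccade_size",
                                                  "incoming_saccade_angle",
                                                  "outgoing_saccade_size",
                                                  "outgoing_saccade_angle")) -> pd.DataFrame:
    """Fill absent covariates at the participant median.

    Trial-initial fixations lack an incoming saccade and trial-final ones an
    outgoing saccade; imputing (rather than dropping) keeps every fixation
    in the deconvolution model.
    """
    out = cov.copy()
    group = out["participant"] if "participant" in out.columns else pd.Series(
        0, index=out.index)
    for c in columns:
        med = out.groupby(group)[c].transform("median")
        out[c] = out[c].fillna(med)
    return out


def summarize_eye_movements(fixations: pd.DataFrame,
                            covariates: pd.DataFrame) -> pd.DataFrame:
    """Per-participant, per-category descriptive statistics.

    One row per (participant, category): event count, mean duration of the
    current and of the following fixation, mean incoming/outgoing saccade
    size, mean fixation rank, and — on precursor rows — the mean number of
    fixations intervening between a precursor and its first refixation.
    Categories with zero events get count 0 and NaN means.
    """
    if "category" not in fixations.columns:
        raise ValueError("fixations must be labeled first")
    fix = fixations.copy()
    if "participant" not in fix.columns:
        fix["participant"] = 0
    cov = covariates.copy()
    if "participant" not in cov.columns:
        cov["participant"] = 0

    rows = []
    for pid, g in fix.groupby("participant"):
        gc = cov[cov["participant"] == pid]
        # intervening fixations between each precursor and its first refixation
        gaps = []
        refix = g[g["category"] == REFIXATION].dropna(subset=["precursor_rank"])
        for (_, prank), grp in refix.groupby(["trial", "precursor_rank"]):
            first = grp["rank"].min()
            gaps.append(first - prank - 1)
        mean_gap = float(np.mean(gaps)) if gaps else np.nan
        for cat in CATEGORIES:
            sel = g["category"] == cat
            selc = gc["category"] == cat
            n = int(sel.sum())
            rows.append({
                "participant": pid,
                "category": cat,
                "n": n,
                "mean_duration": g.loc[sel, "duration"].mean() if n else np.nan,
                "mean_following_duration":
                    gc.loc[selc, "following_fixation_duration"].mean() if n else np.nan,
                "mean_incoming_saccade_size":
                    gc.loc[selc, "incoming_saccade_size"].mean() if n else np.nan,
                "mean_outgoing_saccade_size":
                    gc.loc[selc, "outgoing_saccade_size"].mean() if n else np.nan,
                "mean_rank": g.loc[sel, "rank"].mean() if n else np.nan,
                "mean_intervening":
                    mean_gap if cat == PRECURSOR and n else np.nan,
            })
    return pd.DataFrame(rows)


def read_fixation_table(path, sep: str | None = None,
                        pixels_per_degree: float | None = None) -> pd.DataFrame:
    """Read a fixation report (CSV/TSV with a header).

    Expected columns ``trial, rank, onset, duration, x, y`` (aliases
    ``onset_s``/``duration_s``/``x_deg``/``y_deg`` accepted).  When the file
    stores pixel coordinates, pass ``pixels_per_degree`` to convert to
    degrees of visual angle.
    """
    df = pd.read_csv(path, sep=sep, engine="python")
    df = df.rename(columns={"onset_s": "onset", "duration_s": "duration",
                            "x_deg": "x", "y_deg": "y",
                            "x_px": "x", "y_px": "y"})
    if pixels_per_degree is not None:
        df["x"] = df["x"] / pixels_per_degree
        df["y"] = df["y"] / pixels_per_degree
    return df


def read_saccade_table(path, sep: str | None = None,
                       pixels_per_degree: float | None = None) -> pd.DataFrame:
    """Read a saccade report; see :func:`read_fixation_table`."""
    df = pd.read_csv(path, sep=sep, engine="python")
    df = df.rename(columns={"onset_s": "onset", "amplitude_deg": "amplitude",
                            "amplitude_px": "amplitude", "angle_deg": "angle"})
    if pixels_per_degree is not None and "amplitude" in df.columns:
        df["amplitude"] = df["amplitude"] / pixels_per_degree
    return df
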