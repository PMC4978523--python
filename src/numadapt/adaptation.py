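"""Adaptation-index analysis of magnitude-estimation trials.

The adaptation index (AI) quantifies, in percent, how much larger the mean
perceived numerosity is after slow (low) adaptation than after fast (high)
adaptation, normalized per numerosity level:

    AI = (100 / n) · Σ_j (RL̄_j − RH̄_j) / ((RL̄_j + RH̄_j) / 2)

where RL̄_j and RH̄_j are the mean responses to the j-th numerosity after
low and high adaptation and n is the number of numerosity levels.  The
per-level percent differences are averaged — not the percent difference of
grand means, which differs under noise.

The module offers both a functional surface (:func:`summarize_responses`,
:func:`adaptation_index`, :func:`per_subject_adaptation`) and a fitted-model
surface (:class:`AdaptationIndexModel` → :class:`AdaptationIndexResults`)
for the group-level analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import InvalidParameterError, MissingCellError

__all__ = [
    "ResponseSummary",
    "AdaptationIndexResult",
    "summarize_responses",
    "adaptation_index",
    "per_subject_adaptation",
    "AdaptationIndexModel",
    "AdaptationIndexResults",
]

LOW_LEVEL = "slow"   # low adaptation = slow tapping
HIGH_LEVEL = "fast"  # high adaptation = fast tapping


@dataclass(frozen=True)
class ResponseSummary:
    """Mean response per numerosity for one analysis group."""

    keys: dict
    numerosities: tuple
    mean_response: tuple
    n_trials: tuple
    sem: tuple

    def as_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "n_true": self.numerosities,
            "mean_response": self.mean_response,
            "n_trials": self.n_trials,
            "sem": self.sem,
        })
        for k, v in self.keys.items():
            df.insert(0, k, v)
        return df


@dataclass(frozen=True)
class AdaptationIndexResult:
    """The AI statistic with its ingredients (per-numerosity means)."""

    n: int
    rl_means: tuple
    rh_means: tuple
    ai_percent: float


def summarize_responses(
    trials: pd.DataFrame,
    group_by: tuple = ("subject_id", "condition_label", "adaptation", "congruent"),
) -> list[ResponseSummary]:
    """Mean/SEM response per numerosity within each group.

    Raises :class:`MissingCellError` if, within any group, some numerosity
    present elsewhere in that group's condition has zero trials.
    """
    if trials.empty:
        raise InvalidParameterError("trial table is empty")
    group_by = [g for g in group_by if g in trials.columns]
    all_nums = np.sort(trials["n_true"].unique())
    out = []
    for keys, sub in trials.groupby(list(group_by), sort=True):
        if not isinstance(keys, tuple):
            keys = (keys,)
        agg = sub.groupby("n_true")["response"].agg(["mean", "count", "sem"])
        missing = [n for n in all_nums if n not in agg.index]
        if missing:
            raise MissingCellError(
                [dict(zip(group_by, keys)) | {"n_true": int(n)} for n in missing]
            )
        agg = agg.reindex(all_nums)
        out.append(ResponseSummary(
            keys=dict(zip(group_by, keys)),
            numerosities=tuple(int(n) for n in all_nums),
            mean_response=tuple(agg["mean"]),
            n_trials=tuple(int(c) for c in agg["count"]),
            sem=tuple(agg["sem"].fillna(0.0)),
        ))
    return out


def adaptation_index(rl_means, rh_means) -> AdaptationIndexResult:
    """Compute the adaptation index from per-numerosity mean responses.

    ``rl_means`` are means after low (slow-tapping) adaptation, ``rh_means``
    after high (fast-tapping) adaptation, aligned by numerosity level.
    """
    rl = np.asarray(rl_means, dtype=float)
    rh = np.asarray(rh_means, dtype=float)
    if rl.shape != rh.shape or rl.ndim != 1 or rl.size == 0:
        raise InvalidParameterError("rl_means and rh_means must be equal-length 1-D")
    if np.any(rl <= 0) or np.any(rh <= 0):
        raise InvalidParameterError("all mean responses must be positive")
    ai = float(100.0 / rl.size * np.sum((rl - rh) / ((rl + rh) / 2.0)))
    return AdaptationIndexResult(
        n=rl.size, rl_means=tuple(rl), rh_means=tuple(rh), ai_percent=ai
    )


def _ai_for_group(sub: pd.DataFrame) -> float:
    """AI from one group's trials containing both adaptation levels."""
    levels = set(sub["adaptation"])
    if not {LOW_LEVEL, HIGH_LEVEL} <= levels:
        raise MissingCellError(
            [{"adaptation": lv} for lv in (LOW_LEVEL, HIGH_LEVEL) if lv not in levels]
        )
    pivot = (
        sub[sub["adaptation"].isin([LOW_LEVEL, HIGH_LEVEL])]
        .groupby(["n_true", "adaptation"])["response"].mean().unstack()
    )
    if pivot.isna().any().any():
        bad = pivot[pivot.isna().any(axis=1)].index.tolist()
        raise MissingCellError([{"n_true": int(n)} for n in bad])
    return adaptation_index(pivot[LOW_LEVEL], pivot[HIGH_LEVEL]).ai_percent


def per_subject_adaptation(
    trials: pd.DataFrame,
    group_by: tuple = ("subject_id", "condition_label", "congruent"),
) -> pd.DataFrame:
    """One AI per subject × condition × congruency.

    Returns a table with the grouping columns plus ``ai_percent``.
    """
    if trials.empty:
        raise InvalidParameterError("trial table is empty")
    group_by = [g for g in group_by if g in trials.columns]
    records = []
    for keys, sub in trials.groupby(list(group_by), sort=True):
        if not isinstance(keys, tuple):
            keys = (keys,)
        records.append(dict(zip(group_by, keys)) | {"ai_percent": _ai_for_group(sub)})
    return pd.DataFrame.from_records(records)


class AdaptationIndexModel:
    """Group-level adaptation analysis over an estimation trial table.

    Parameters
    ----------
    trials : DataFrame
        One row per estimation trial (columns as written by the simulator:
        subject_id, condition_label, adaptation, test_side, congruent,
        n_true, response).
    pooled : bool
        If True the group AI is computed from trial-pooled mean responses;
        the default averages per-subject AIs (matching how individual-subject
        adaptation magnitudes are usually aggregated).
    """

    def __init__(self, trials: pd.DataFrame, pooled: bool = False):
        if trials.empty:
            raise InvalidParameterError("trial table is empty")
        self.trials = trials
        self.pooled = pooled

    @classmethod
    def from_csv(cls, path, **kwargs) -> "AdaptationIndexModel":
        return cls(pd.read_csv(path), **kwargs)

    def fit(self) -> "AdaptationIndexResults":
        subject_ai = per_subject_adaptation(self.trials)
        group_keys = [k for k in ("condition_label", "congruent") if k in subject_ai]
        if self.pooled:
            records = []
            for keys, sub in self.trials.groupby(group_keys, sort=True):
                if not isinstance(keys, tuple):
                    keys = (keys,)
                records.append(
                    dict(zip(group_keys, keys)) | {"ai_percent": _ai_for_group(sub)}
                )
            group = pd.DataFrame.from_records(records)
            group["sem"] = np.nan
            group["n_subjects"] = self.trials.groupby(group_keys)["subject_id"].nunique().values
        else:
            g = subject_ai.groupby(group_keys)["ai_percent"]
            group = g.agg(["mean", "sem", "count"]).reset_index()
            group = group.rename(
                columns={"mean": "ai_percent", "count": "n_subjects"}
            )
        return AdaptationIndexResults(self, subject_ai, group)


class AdaptationIndexResults:
    """Per-subject and group adaptation indices with a printable summary."""

    def __init__(self, model, subject_ai: pd.DataFrame, group_ai: pd.DataFrame):
        self.model = model
        self.subject_ai = subject_ai
        self.group_ai = group_ai

    def ai_for(self, congruent: bool = True, condition_label=None) -> float:
        """Group AI (percent) for one congruency (and optional condition)."""
        sel = self.group_ai[self.group_ai["congruent"] == congruent]
        if condition_label is not None and "condition_label" in sel:
            sel = sel[sel["condition_label"] == condition_label]
        if sel.empty:
            raise InvalidParameterError("no group matches the requested selection")
        return float(sel["ai_percent"].iloc[0])

    def summary(self) -> str:
        lines = ["Adaptation index (percent change, slow vs fast tapping)",
                 "=" * 56]
        for _, row in self.group_ai.iterrows():
            label = " ".join(
                f"{k}={row[k]}" for k in ("condition_label", "congruent") if k in row
            )
            sem = row.get("sem")
            sem_txt = f" ± {sem:.2f} (SEM)" if np.isfinite(sem) else ""
            lines.append(
                f"{label}: AI = {row['ai_percent']:.2f}%{sem_txt} "
                f"[n={int(row['n_subjects'])} subjects]"
            )
        return "\n".join(lines)

    def __repr__(self):
        return f"<AdaptationIndexResults: {len(self.group_ai)} groups>"
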