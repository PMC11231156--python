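"""Data model for two-agent survival bioassays with stage-resolved fates.

The central object is :class:`AssayDataset`: one row per subject (here, one
in-vitro-reared honey bee larva) carrying its exposure status for two agents,
its fate (death, emergence as an adult, or removal from the assay), and the
developmental stage in which death occurred.  Risk tables derived from the
dataset feed the binomial GLMs in :mod:`blissassay.glm`.

Fates
-----
``died``     the subject died during observation; ``fate_day`` and
             ``fate_stage`` record when/where.
``emerged``  the subject survived every developmental stage and emerged as a
             viable adult; ``fate_day`` may be missing (emerged-at-end
             convention).
``removed``  the subject was censored (e.g. contamination of the rearing
             well) on ``fate_day``; it contributes only to stages fully
             completed before removal.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "AssayValidationError",
    "StageSchedule",
    "DEFAULT_SCHEDULE",
    "SubjectRecord",
    "AssayDataset",
    "RiskTable",
    "GroupSummary",
    "read_assay_csv",
    "write_assay_csv",
    "attribute_stage",
    "build_risk_table",
    "summarize_groups",
    "km_estimate",
    "KaplanMeierCurve",
]

FATES = ("died", "emerged", "removed")

CSV_COLUMNS = [
    "subject_id",
    "trial_id",
    "group_label",
    "x_A",
    "x_B",
    "dose_A_ng_ml",
    "dose_B_ng_ml",
    "fate",
    "fate_day",
    "fate_stage",
]


class AssayValidationError(ValueError):
    """Raised when assay records violate the dataset invariants.

    Carries row-indexed diagnostics in ``.problems`` (list of strings).
    """

    def __init__(self, problems):
        self.problems = list(problems)
        super().__init__(
            "invalid assay data:\n" + "\n".join(f"  - {p}" for p in self.problems)
        )


@dataclass(frozen=True)
class StageSchedule:
    """Ordered developmental stages with inclusive day ranges.

    The default mirrors a larval-rearing assay: larva days 1-6, prepupa days
    7-9, pupa days 10-14, with daily observation continuing to day 22 so that
    late pre-emergence deaths are attributed to the pupal stage.
    """

    stages: tuple[str, ...] = ("larva", "prepupa", "pupa")
    day_ranges: tuple[tuple[int, int], ...] = ((1, 6), (7, 9), (10, 14))
    terminal_event: str = "emerged"
    last_observation_day: int = 22

    def __post_init__(self):
        if len(self.stages) != len(self.day_ranges) or not self.stages:
            raise ValueError("stages and day_ranges must be non-empty and conformable")
        prev_end = 0
        for name, (a, b) in zip(self.stages, self.day_ranges):
            if a != prev_end + 1 or b < a:
                raise ValueError(
                    f"stage {name!r}: day ranges must be ordered, disjoint and "
                    f"contiguous from day 1 (got {a}-{b} after day {prev_end})"
                )
            prev_end = b
        if self.last_observation_day < prev_end:
            raise ValueError("last_observation_day must cover the final stage")

    def stage_index(self, stage: str) -> int:
        try:
            return self.stages.index(stage)
        except ValueError:
            raise KeyError(f"unknown stage {stage!r}; known: {self.stages}") from None

    def stage_end(self, stage: str) -> int:
        return self.day_ranges[self.stage_index(stage)][1]


DEFAULT_SCHEDULE = StageSchedule()


def attribute_stage(fate_day: int, schedule: StageSchedule = DEFAULT_SCHEDULE) -> str:
    """Map an observation day to the developmental stage containing it.

    Days after the final stage's nominal range but within the observation
    window attribute to the final stage (a subject still unemerged on day 15
    is, by elimination, in the pupal stage).
    """
    day = int(fate_day)
    if day < 1 or day > schedule.last_observation_day:
        raise ValueError(
            f"day {day} outside observation window 1-{schedule.last_observation_day}"
        )
    for name, (a, b) in zip(schedule.stages, schedule.day_ranges):
        if a <= day <= b:
            return name
    return schedule.stages[-1]


@dataclass(frozen=True)
class SubjectRecord:
    """A single subject's exposure and fate."""

    subject_id: str
    trial_id: str
    group_label: str
    x_A: int
    x_B: int
    dose_A_ng_ml: float
    dose_B_ng_ml: float
    fate: str
    fate_day: int | None = None
    fate_stage: str | None = None


def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records.copy()
    return pd.DataFrame([r.__dict__ for r in records])


class AssayDataset:
    """Validated collection of subject records plus the stage schedule.

    Parameters
    ----------
    records :
        DataFrame with the columns of the assay CSV dialect, or an iterable
        of :class:`SubjectRecord`.
    schedule :
        The :class:`StageSchedule` governing stage attribution.
    control_group :
        Label of the group used as the baseline in GLM fits (by convention
        the solvent-treated control, since every treatment also contains the
        solvent).
    """

    def __init__(
        self,
        records,
        schedule: StageSchedule = DEFAULT_SCHEDULE,
        control_group: str | None = None,
    ):
        df = _as_frame(records)
        missing = [c for c in CSV_COLUMNS if c not in df.columns]
        if missing:
            raise AssayValidationError([f"missing columns: {missing}"])
        df = df[CSV_COLUMNS].reset_index(drop=True)
        df["subject_id"] = df["subject_id"].astype(str)
        df["trial_id"] = df["trial_id"].astype(str)
        df["group_label"] = df["group_label"].astype(str)
        for c in ("x_A", "x_B"):
            df[c] = pd.to_numeric(df[c], errors="coerce")
        for c in ("dose_A_ng_ml", "dose_B_ng_ml"):
            df[c] = pd.to_numeric(df[c], errors="coerce")
        df["fate_day"] = pd.to_numeric(df["fate_day"], errors="coerce")

        self.df = df
        self.schedule = schedule
        self.control_group = control_group
        self._validate()
        # resolve missing fate_stage for deaths from the day
        died = df["fate"] == "died"
        needs = died & df["fate_stage"].isna()
        if needs.any():
            df.loc[needs, "fate_stage"] = [
                attribute_stage(d, schedule) for d in df.loc[needs, "fate_day"]
            ]

    def _validate(self):
        df = self.df
        problems = []
        dup = df["subject_id"][df["subject_id"].duplicated()].unique()
        if len(dup):
            problems.append(f"duplicate subject_id values: {sorted(dup)[:5]}")
        for row in df.itertuples():
            i = row.Index
            if row.fate not in FATES:
                problems.append(f"row {i}: unknown fate {row.fate!r}")
                continue
            for label, x, dose in (
                ("A", row.x_A, row.dose_A_ng_ml),
                ("B", row.x_B, row.dose_B_ng_ml),
            ):
                if pd.isna(x) or x not in (0, 1):
                    problems.append(f"row {i}: x_{label} must be 0 or 1")
                elif pd.isna(dose) or dose < 0:
                    problems.append(f"row {i}: dose_{label} must be a number >= 0")
                elif (x == 1) != (dose > 0):
                    problems.append(
                        f"row {i}: x_{label}={int(x)} inconsistent with "
                        f"dose_{label}={dose}"
                    )
            if row.fate in ("died", "removed"):
                if pd.isna(row.fate_day):
                    problems.append(f"row {i}: fate={row.fate} requires fate_day")
                elif not float(row.fate_day).is_integer() or not (
                    1 <= row.fate_day <= self.schedule.last_observation_day
                ):
                    problems.append(
                        f"row {i}: unparseable or out-of-window fate_day "
                        f"{row.fate_day!r}"
                    )
                elif (
                    row.fate == "died"
                    and isinstance(row.fate_stage, str)
                    and row.fate_stage not in self.schedule.stages
                ):
                    problems.append(f"row {i}: unknown fate_stage {row.fate_stage!r}")
        if problems:
            raise AssayValidationError(problems)
        # group label -> exposure combination must be one-to-one
        combos = df.groupby("group_label")[
            ["x_A", "x_B", "dose_A_ng_ml", "dose_B_ng_ml"]
        ].nunique()
        bad = combos[(combos > 1).any(axis=1)].index.tolist()
        if bad:
            raise AssayValidationError(
                [f"group {g!r} maps to multiple exposure combinations" for g in bad]
            )

    # -- convenience accessors -------------------------------------------
    @property
    def n_subjects(self) -> int:
        return len(self.df)

    @property
    def trials(self) -> list[str]:
        return sorted(self.df["trial_id"].unique())

    @property
    def groups(self) -> list[str]:
        return sorted(self.df["group_label"].unique())

    def group_doses(self) -> dict[str, tuple[float, float]]:
        """Map group label -> (dose_A, dose_B) in ng/ml."""
        g = self.df.groupby("group_label")[["dose_A_ng_ml", "dose_B_ng_ml"]].first()
        return {
            k: (float(v["dose_A_ng_ml"]), float(v["dose_B_ng_ml"]))
            for k, v in g.iterrows()
        }

    def group_counts(self) -> dict[str, int]:
        return self.df["group_label"].value_counts().to_dict()

    @property
    def n_removed(self) -> int:
        return int((self.df["fate"] == "removed").sum())

    def records(self) -> list[SubjectRecord]:
        out = []
        for row in self.df.itertuples(index=False):
            d = row._asdict()
            d["fate_day"] = None if pd.isna(d["fate_day"]) else int(d["fate_day"])
            if not isinstance(d["fate_stage"], str):
                d["fate_stage"] = None
            out.append(SubjectRecord(**d))
        return out


@dataclass
class RiskTable:
    """Binary survival outcomes for one analysis scope.

    ``scope`` is ``"overall"`` or a stage name.  ``df`` has one row per
    subject at risk in the scope, with ``outcome`` = 1 for surviving the
    scope and 0 for dying within it.
    """

    scope: str
    df: pd.DataFrame
    n_removed_excluded: int = 0

    def __len__(self):
        return len(self.df)


@dataclass(frozen=True)
class GroupSummary:
    group_label: str
    trial_id: str  # "pooled" when trials are pooled
    n_at_risk: int
    n_survived: int

    @property
    def proportion(self) -> float:
        return self.n_survived / self.n_at_risk


def build_risk_table(dataset: AssayDataset, scope: str = "overall") -> RiskTable:
    """Construct the risk set and binary outcomes for a scope.

    Overall scope: every non-removed subject, outcome 1 iff it emerged.
    Stage scope: every subject alive at stage entry; removed subjects appear
    only in stages fully completed before their removal day, always with
    outcome 1.  Deaths count against the stage recorded in ``fate_stage``.
    """
    df = dataset.df
    sched = dataset.schedule
    base_cols = ["subject_id", "trial_id", "group_label", "x_A", "x_B"]
    if scope == "overall":
        keep = df["fate"] != "removed"
        out = df.loc[keep, base_cols].copy()
        out["outcome"] = (df.loc[keep, "fate"] == "emerged").astype(int)
        return RiskTable("overall", out.reset_index(drop=True),
                         n_removed_excluded=int((~keep).sum()))

    s = sched.stage_index(scope)  # KeyError for unknown stage
    stage_end = sched.day_ranges[s][1]
    death_idx = df["fate_stage"].map(
        lambda v: sched.stage_index(v) if isinstance(v, str) else np.inf
    )
    died = df["fate"] == "died"
    removed = df["fate"] == "removed"
    # at risk: did not die in an earlier stage; removed only if the stage was
    # fully completed before removal
    at_risk = (~died | (death_idx >= s)) & (
        ~removed | (df["fate_day"] > stage_end)
    )
    out = df.loc[at_risk, base_cols].copy()
    out["outcome"] = (~(died & (death_idx == s)))[at_risk].astype(int)
    return RiskTable(scope, out.reset_index(drop=True),
                     n_removed_excluded=int((removed & ~at_risk).sum()))


def summarize_groups(table: RiskTable, pool_trials: bool = True) -> list[GroupSummary]:
    """Per-group (optionally per-trial) survival counts and proportions."""
    if len(table) == 0:
        raise ValueError("empty risk table")
    keys = ["group_label"] if pool_trials else ["group_label", "trial_id"]
    out = []
    for key, sub in table.df.groupby(keys, sort=True):
        if len(sub) == 0:  # pragma: no cover - groupby drops empties
            warnings.warn(f"empty group {key}; omitted")
            continue
        group = key[0] if isinstance(key, tuple) else key
        trial = key[1] if (isinstance(key, tuple) and len(key) > 1) else "pooled"
        out.append(
            GroupSummary(group, trial, int(len(sub)), int(sub["outcome"].sum()))
        )
    return out


def summaries_to_frame(summaries: list[GroupSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "group_label": [s.group_label for s in summaries],
            "trial_id": [s.trial_id for s in summaries],
            "n_at_risk": [s.n_at_risk for s in summaries],
            "n_survived": [s.n_survived for s in summaries],
            "proportion": [s.proportion for s in summaries],
        }
    )


class KaplanMeierCurve:
    """Right-continuous non-increasing product-limit survival step function."""

    def __init__(self, days: np.ndarray, survival: np.ndarray):
        self.days = np.asarray(days, dtype=float)
        self.survival = np.asarray(survival, dtype=float)

    def __call__(self, day: float) -> float:
        idx = np.searchsorted(self.days, day, side="right") - 1
        if idx < 0:
            return 1.0
        return float(self.survival[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"day": self.days, "survival": self.survival})


def km_estimate(fate_days, event_flags) -> KaplanMeierCurve:
    """Kaplan-Meier estimate from death days and event indicators.

    ``event_flags[i]`` is 1 when subject i died on ``fate_days[i]`` and 0
    when it was censored (removed or emerged) on that day.  With no
    censoring this equals one minus the empirical CDF of the death days.
    """
    days = np.asarray(fate_days, dtype=float)
    events = np.asarray(event_flags, dtype=int)
    if days.size == 0:
        raise ValueError("empty input")
    if days.size != events.size:
        raise ValueError("fate_days and event_flags must have equal length")
    if (days < 1).any():
        raise ValueError("days must be >= 1")
    from lifelines import KaplanMeierFitter

    kmf = KaplanMeierFitter()
    kmf.fit(days, event_observed=events)
    sf = kmf.survival_function_
    return KaplanMeierCurve(sf.index.to_numpy(), sf.iloc[:, 0].to_numpy())


# -- CSV dialect ----------------------------------------------------------

def read_assay_csv(
    path,
    schedule: StageSchedule = DEFAULT_SCHEDULE,
    control_group: str | None = None,
) -> AssayDataset:
    """Read the assay CSV dialect (UTF-8, comma, header, "NA" missing).

    Lines starting with ``#`` are provenance comments and are skipped.
    """
    df = pd.read_csv(
        path,
        comment="#",
        na_values=["NA"],
        keep_default_na=False,
        dtype={"subject_id": str, "trial_id": str, "group_label": str},
        encoding="utf-8",
    )
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise AssayValidationError([f"missing columns: {missing}"])
    df["fate_stage"] = df["fate_stage"].where(df["fate_stage"].notna(), None)
    return AssayDataset(df, schedule=schedule, control_group=control_group)


def write_assay_csv(dataset: AssayDataset, path, header_comment: str | None = None):
    """Write a dataset in the assay CSV dialect (round-trips bit-exactly)."""
    df = dataset.df.copy()
    df["fate_day"] = df["fate_day"].map(
        lambda v: "NA" if pd.isna(v) else str(int(v))
    )
    df["fate_stage"] = df["fate_stage"].map(
        lambda v: v if isinstance(v, str) else "NA"
    )
    buf = io.StringIO()
    if header_comment:
        for line in header_comment.splitlines():
            buf.write(f"# {line}\n")
    df.to_csv(buf, index=False, na_rep="NA")
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(buf.getvalue())
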