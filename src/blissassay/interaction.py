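"""Bliss-independence interaction testing for two-agent bioassays.

Under Bliss independence, two agents with independent action and
uncorrelated individual susceptibilities satisfy

    s_combined = s0 * sA * sB,

where s0 is control survival and sA, sB are the Abbott-corrected survival
rates of the single-agent groups (treated survival divided by s0).  In a
log-binomial GLM

    log(p_surv) = b0 + bA*xA + bB*xB + bAB*xA*xB (+ trial effects)

that null is exactly bAB = 0, so a likelihood-ratio test of the interaction
coefficient is a test of Bliss independence: a significant negative bAB
means the combination kills more than independence predicts (synergism), a
significant positive bAB means less (antagonism).

Tests across dosages and developmental stages form families whose p-values
are adjusted by Holm's step-down procedure.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assay import AssayDataset, RiskTable, build_risk_table
from .glm import (
    BinomialGlmFit,
    DegenerateGroupError,
    DesignMatrix,
    chi2_upper_tail,
    fit_binomial_glm,
    lr_statistic,
)

__all__ = [
    "BlissRates",
    "InteractionTestSpec",
    "InteractionTestResult",
    "FamilyResult",
    "abbott_corrected_survival",
    "expected_bliss_survival",
    "bliss_rates_from_proportions",
    "bliss_lr_test",
    "classify_interaction",
    "holm_adjust",
    "resolve_test_specs",
    "run_interaction_family",
]

SYNERGISM = "synergism"
ANTAGONISM = "antagonism"
INDEPENDENT = "not-distinguishable-from-independence"


def abbott_corrected_survival(s_treated: float, s0: float) -> float:
    """Treated survival rescaled by control survival (removes natural
    mortality); capped at 1 with a warning when the ratio exceeds 1."""
    if not 0 <= s_treated <= 1:
        raise ValueError("s_treated must lie in [0, 1]")
    if not 0 < s0 <= 1:
        raise ValueError("control survival s0 must lie in (0, 1]")
    ratio = s_treated / s0
    if ratio > 1:
        warnings.warn(
            f"treated survival {s_treated} exceeds control {s0}; "
            "Abbott-corrected rate capped at 1"
        )
        return 1.0
    return ratio


def expected_bliss_survival(s0: float, sA: float, sB: float) -> float:
    """Combined survival under Bliss independence: s0 * sA * sB.

    Observed combination survival below this indicates synergism, above it
    antagonism.
    """
    for name, v in (("s0", s0), ("sA", sA), ("sB", sB)):
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must lie in [0, 1]")
    return s0 * sA * sB


@dataclass(frozen=True)
class BlissRates:
    """Control, single-agent and Bliss-expected survival rates."""

    s0: float
    raw_a: float  # s0 * sA as observed
    raw_b: float  # s0 * sB as observed
    sA: float = field(init=False)
    sB: float = field(init=False)
    expected_combined: float = field(init=False)

    def __post_init__(self):
        object.__setattr__(self, "sA", abbott_corrected_survival(self.raw_a, self.s0))
        object.__setattr__(self, "sB", abbott_corrected_survival(self.raw_b, self.s0))
        object.__setattr__(
            self, "expected_combined",
            expected_bliss_survival(self.s0, self.sA, self.sB),
        )


def bliss_rates_from_proportions(s0: float, raw_a: float, raw_b: float) -> BlissRates:
    return BlissRates(s0, raw_a, raw_b)


@dataclass(frozen=True)
class InteractionTestSpec:
    """Which four groups form one 2x2 interaction test, and in which scope."""

    control_group: str
    group_a: str  # agent A alone
    group_b: str  # agent B alone
    group_ab: str  # combination
    scope: str = "overall"
    include_trial_effects: bool = True
    label: str = ""

    def __post_init__(self):
        groups = {self.control_group, self.group_a, self.group_b, self.group_ab}
        if len(groups) != 4:
            raise ValueError("the four groups of an interaction test must be distinct")


@dataclass
class InteractionTestResult:
    spec: InteractionTestSpec
    beta_ab: float
    lr: float
    p_raw: float
    df: int = 1
    p_holm: float | None = None
    direction: str | None = None
    boundary: bool = False
    group_sizes: dict = field(default_factory=dict)
    error: str | None = None

    @property
    def failed(self) -> bool:
        return self.error is not None

    def to_dict(self) -> dict:
        return {
            "label": self.spec.label,
            "scope": self.spec.scope,
            "groups": {
                "control": self.spec.control_group,
                "A": self.spec.group_a,
                "B": self.spec.group_b,
                "AB": self.spec.group_ab,
            },
            "group_sizes": self.group_sizes,
            "beta_AB": None if self.failed else float(self.beta_ab),
            "LR": None if self.failed else float(self.lr),
            "df": self.df,
            "p_raw": None if self.failed else float(self.p_raw),
            "p_holm": None if self.p_holm is None else float(self.p_holm),
            "direction": self.direction,
            "boundary": bool(self.boundary),
            "error": self.error,
        }


def _trial_dummies(trials: pd.Series) -> tuple[np.ndarray, list[str]]:
    """Reference-coded trial indicators, first trial (sorted) as reference."""
    levels = sorted(trials.unique())
    cols, names = [], []
    for t in levels[1:]:
        cols.append((trials == t).to_numpy(dtype=float))
        names.append(f"trial[{t}]")
    if cols:
        return np.column_stack(cols), names
    return np.empty((len(trials), 0)), names


def _build_design(table: RiskTable, spec: InteractionTestSpec):
    df = table.df
    sub = df[df["group_label"].isin(
        [spec.control_group, spec.group_a, spec.group_b, spec.group_ab]
    )]
    sizes = sub["group_label"].value_counts().to_dict()
    for g in (spec.control_group, spec.group_a, spec.group_b, spec.group_ab):
        if sizes.get(g, 0) < 1:
            raise ValueError(f"group {g!r} has no subjects in scope {spec.scope!r}")
    xa = sub["group_label"].isin([spec.group_a, spec.group_ab]).to_numpy(float)
    xb = sub["group_label"].isin([spec.group_b, spec.group_ab]).to_numpy(float)
    cols = [np.ones(len(sub)), xa, xb, xa * xb]
    names = ["intercept", "x_A", "x_B", "x_A:x_B"]
    if spec.include_trial_effects and sub["trial_id"].nunique() > 1:
        tmat, tnames = _trial_dummies(sub["trial_id"])
        if tmat.shape[1]:
            cols.append(tmat)
            names.extend(tnames)
    full_mat = np.column_stack(cols)
    y = sub["outcome"].to_numpy(dtype=float)
    # zero-survivor exposure groups make the log-link MLE diverge
    for g in (spec.control_group, spec.group_a, spec.group_b, spec.group_ab):
        if sub.loc[sub["group_label"] == g, "outcome"].sum() == 0:
            raise DegenerateGroupError(
                f"group {g!r} has zero survivors in scope {spec.scope!r}"
            )
    return DesignMatrix(full_mat, tuple(names)), y, sizes


def bliss_lr_test(dataset: AssayDataset, spec: InteractionTestSpec) -> InteractionTestResult:
    """Likelihood-ratio test of the Bliss-independence null b_AB = 0.

    Builds the scope's risk table restricted to the test's four groups, fits
    the full log-binomial model (intercept, x_A, x_B, interaction, trial
    effects) and the reduced model without the interaction, and refers
    2*(ll_full - ll_reduced) to chi-square with 1 df.
    """
    table = build_risk_table(dataset, spec.scope)
    design, y, sizes = _build_design(table, spec)
    full = fit_binomial_glm(design, y, link="log")
    keep = [i for i, c in enumerate(design.columns) if c != "x_A:x_B"]
    red_design = DesignMatrix(
        design.matrix[:, keep], tuple(design.columns[i] for i in keep)
    )
    reduced = fit_binomial_glm(red_design, y, link="log")
    lr = lr_statistic(full, reduced)
    return InteractionTestResult(
        spec=spec,
        beta_ab=full.coef("x_A:x_B"),
        lr=lr,
        p_raw=chi2_upper_tail(lr, 1),
        boundary=full.boundary or reduced.boundary,
        group_sizes=sizes,
    )


def classify_interaction(result: InteractionTestResult, alpha: float = 0.05) -> str:
    """Direction call from the interaction sign and the adjusted p-value."""
    if result.p_holm is None:
        raise ValueError("adjusted p-value not set; run within a family first")
    if result.p_holm < alpha:
        if result.beta_ab < 0:
            return SYNERGISM
        if result.beta_ab > 0:
            return ANTAGONISM
    return INDEPENDENT


def holm_adjust(p_values) -> list[float]:
    """Holm step-down adjustment.

    Sort ascending, multiply the i-th smallest by (m - i), enforce monotone
    non-decreasing adjusted values, cap at 1, return in the original order.
    Uniformly dominates (is no larger than) Bonferroni's m*p.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj.tolist()


@dataclass
class FamilyResult:
    """A battery of interaction tests with per-family Holm adjustment."""

    results: list[InteractionTestResult]
    families: dict[str, list[int]]  # family name -> indices into results
    alpha: float = 0.05

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            d = r.to_dict()
            rows.append(
                {
                    "label": d["label"],
                    "scope": d["scope"],
                    "group_AB": d["groups"]["AB"],
                    "n_total": sum(r.group_sizes.values()) if r.group_sizes else 0,
                    "beta_AB": d["beta_AB"],
                    "LR": d["LR"],
                    "df": d["df"],
                    "p_raw": d["p_raw"],
                    "p_holm": d["p_holm"],
                    "call": d["direction"],
                    "boundary": d["boundary"],
                    "error": d["error"],
                }
            )
        return pd.DataFrame(rows)

    def to_tsv(self, path):
        self.to_frame().to_csv(path, sep="\t", index=False)

    def to_json(self, **kw) -> str:
        return json.dumps(
            {
                "alpha": self.alpha,
                "families": self.families,
                "tests": [r.to_dict() for r in self.results],
            },
            **kw,
        )


def resolve_test_specs(
    dataset: AssayDataset,
    dosage_labels,
    scopes,
    control_group: str | None = None,
    include_trial_effects: bool = True,
) -> list[InteractionTestSpec]:
    """Resolve (dosage, scope) pairs to four-group test specs via the
    dataset's group -> dose map.

    ``dosage_labels`` maps a label to the agent-B dose (ng/ml) of the
    combination of interest; the agent-A single-exposure group is matched by
    the combination's agent-A dose.
    """
    control = control_group or dataset.control_group
    if control is None:
        raise ValueError("no control group designated")
    doses = dataset.group_doses()
    specs = []
    for label, dose_b in dict(dosage_labels).items():
        combo = [g for g, (da, db) in doses.items() if da > 0 and db == dose_b]
        if len(combo) != 1:
            raise ValueError(
                f"dosage {label!r}: expected exactly one combination group with "
                f"agent-B dose {dose_b}, found {combo}"
            )
        combo = combo[0]
        da_combo = doses[combo][0]
        ga = [g for g, (da, db) in doses.items() if da == da_combo and db == 0]
        gb = [g for g, (da, db) in doses.items() if da == 0 and db == dose_b]
        if len(ga) != 1 or len(gb) != 1:
            raise ValueError(
                f"dosage {label!r}: could not resolve single-agent groups "
                f"(A candidates {ga}, B candidates {gb})"
            )
        for scope in scopes:
            specs.append(
                InteractionTestSpec(
                    control_group=control,
                    group_a=ga[0],
                    group_b=gb[0],
                    group_ab=combo,
                    scope=scope,
                    include_trial_effects=include_trial_effects,
                    label=f"{label}:{scope}",
                )
            )
    return specs


def run_interaction_family(
    dataset: AssayDataset,
    dosage_labels,
    scopes=("overall", "larva", "prepupa", "pupa"),
    alpha: float = 0.05,
    control_group: str | None = None,
    families: dict[str, list[str]] | None = None,
    include_trial_effects: bool = True,
) -> FamilyResult:
    """Run the interaction-test battery and Holm-adjust within families.

    By default the stage-specific tests (dosages x stages) form one Holm
    family and the overall-survival tests form a second; pass ``families``
    mapping family name -> list of test labels to override.  A member test
    that fails (degenerate group, missing group) is recorded with its error
    and excluded from its family's adjustment, never silently dropped.
    """
    specs = resolve_test_specs(
        dataset, dosage_labels, scopes, control_group, include_trial_effects
    )
    results = []
    for spec in specs:
        try:
            results.append(bliss_lr_test(dataset, spec))
        except (DegenerateGroupError, ValueError) as exc:
            results.append(
                InteractionTestResult(
                    spec=spec, beta_ab=np.nan, lr=np.nan, p_raw=np.nan,
                    error=str(exc),
                )
            )
    if families is None:
        fam_indices = {
            "overall": [i for i, r in enumerate(results) if r.spec.scope == "overall"],
            "stage-specific": [
                i for i, r in enumerate(results) if r.spec.scope != "overall"
            ],
        }
    else:
        by_label = {r.spec.label: i for i, r in enumerate(results)}
        fam_indices = {
            name: [by_label[lab] for lab in labels]
            for name, labels in families.items()
        }
    for name, idx in fam_indices.items():
        ok = [i for i in idx if not results[i].failed]
        if not ok:
            continue
        adjusted = holm_adjust([results[i].p_raw for i in ok])
        for i, p in zip(ok, adjusted):
            results[i].p_holm = p
            results[i].direction = classify_interaction(results[i], alpha)
    fam_indices = {k: v for k, v in fam_indices.items() if v}
    return FamilyResult(results=results, families=fam_indices, alpha=alpha)
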