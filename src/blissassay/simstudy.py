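"""Monte-Carlo operating characteristics of the Bliss interaction test.

Type-I error under the null, power against injected interactions, and
bias/RMSE of the interaction-coefficient estimator.  Replicates with a
degenerate group (zero survivors, on which the log-link test is undefined)
are excluded from the rejection-rate denominator and counted explicitly —
silent inclusion would bias the rates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .generate import GeneratorConfig, GroupSpec, StageCoefficients, inject_interaction
from .generate import simulate_assay
from .assay import DEFAULT_SCHEDULE
from .glm import DegenerateGroupError, GlmError
from .interaction import InteractionTestSpec, bliss_lr_test

__all__ = [
    "StudyResult",
    "four_group_design",
    "type1_error_study",
    "power_study",
    "recovery_study",
    "familywise_error_study",
    "results_to_frame",
]


@dataclass
class StudyResult:
    scenario: str
    beta_ab_true: float
    replicates: int
    n_used: int  # replicates that produced a valid test
    rejections: int
    alpha: float
    mean_beta_ab: float
    rmse_beta_ab: float
    n_degenerate: int
    seed: int

    @property
    def rejection_rate(self) -> float:
        return self.rejections / self.n_used

    @property
    def mc_se(self) -> float:
        r = self.rejection_rate
        return float(np.sqrt(r * (1 - r) / self.n_used))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["rejection_rate"] = self.rejection_rate
        d["mc_se"] = self.mc_se
        return d


def four_group_design(
    n_per_group_per_trial: int = 200,
    n_trials: int = 3,
    s0: float = 0.74,
    sA: float = 0.506,
    sB: float = 0.428,
    beta_ab: float = 0.0,
    trial_effects: tuple[float, ...] | None = None,
    seed: int = 0,
) -> GeneratorConfig:
    """Minimal control / A / B / A+B design for operating-characteristic runs.

    ``s0``, ``sA``, ``sB`` are overall (across-stage) survivals of the
    control and the Abbott-corrected single-agent groups; they are split
    evenly across stages on the log scale.  ``beta_ab`` is the overall
    interaction, likewise split across stages.
    """
    import math

    n_stages = len(DEFAULT_SCHEDULE.stages)
    coefs = {
        stage: StageCoefficients(
            beta0=math.log(s0) / n_stages,
            beta_a=math.log(sA) / n_stages,
            beta_b=math.log(sB) / n_stages,
            beta_ab=beta_ab / n_stages,
        )
        for stage in DEFAULT_SCHEDULE.stages
    }
    if trial_effects is None:
        trial_effects = tuple([0.0] + [-0.01 * t for t in range(1, n_trials)])
    n = (n_per_group_per_trial,) * n_trials
    groups = (
        GroupSpec("control", 0.0, 0.0, n),
        GroupSpec("agent_a", 2000.0, 0.0, n),
        GroupSpec("agent_b", 0.0, 1440.0, n),
        GroupSpec("combo", 2000.0, 1440.0, n),
    )
    return GeneratorConfig(
        groups=groups,
        stage_coefs=coefs,
        trial_effects=trial_effects,
        seed=seed,
        control_group="control",
    )


_DEFAULT_SPEC = dict(
    control_group="control", group_a="agent_a", group_b="agent_b", group_ab="combo"
)


def _run_replicates(
    config: GeneratorConfig,
    reps: int,
    alpha: float,
    seed: int,
    scope: str = "overall",
    scenario: str = "",
    beta_ab_true: float = 0.0,
) -> StudyResult:
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(0, 2**31 - 1, size=reps)
    spec = InteractionTestSpec(scope=scope, label=scenario, **_DEFAULT_SPEC)
    rejections = 0
    betas = []
    degenerate = 0
    for s in rep_seeds:
        data = simulate_assay(config, seed=int(s))
        try:
            res = bliss_lr_test(data, spec)
        except (DegenerateGroupError, GlmError):
            degenerate += 1
            continue
        betas.append(res.beta_ab)
        if res.p_raw < alpha:
            rejections += 1
    betas = np.asarray(betas)
    return StudyResult(
        scenario=scenario,
        beta_ab_true=beta_ab_true,
        replicates=reps,
        n_used=len(betas),
        rejections=rejections,
        alpha=alpha,
        mean_beta_ab=float(betas.mean()) if len(betas) else float("nan"),
        rmse_beta_ab=(
            float(np.sqrt(((betas - beta_ab_true) ** 2).mean()))
            if len(betas)
            else float("nan")
        ),
        n_degenerate=degenerate,
        seed=seed,
    )


def _total_beta_ab(config: GeneratorConfig) -> float:
    return sum(c.beta_ab for c in config.stage_coefs.values())


def type1_error_study(
    config: GeneratorConfig,
    reps: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    scope: str = "overall",
) -> StudyResult:
    """Rejection rate of the interaction test when the Bliss null holds."""
    if any(c.beta_ab != 0 for c in config.stage_coefs.values()):
        raise ValueError("type-I study requires beta_AB = 0 in every stage")
    return _run_replicates(
        config, reps, alpha, seed, scope=scope,
        scenario=f"type1(alpha={alpha})", beta_ab_true=0.0,
    )


def power_study(
    config: GeneratorConfig,
    beta_ab_grid,
    reps: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    stage: str | None = None,
    scope: str = "overall",
) -> list[StudyResult]:
    """Rejection rates across a grid of injected interaction strengths.

    When ``stage`` is None the overall interaction is injected by spreading
    it evenly across stages; otherwise only the named stage receives it.
    """
    out = []
    for i, b in enumerate(beta_ab_grid):
        if stage is None:
            n_stages = len(config.schedule.stages)
            cfg = config
            for st in config.schedule.stages:
                cfg = inject_interaction(cfg, st, b / n_stages)
            true_b = b
        else:
            cfg = inject_interaction(config, stage, b)
            true_b = _total_beta_ab(cfg)
        out.append(
            _run_replicates(
                cfg, reps, alpha, seed + i, scope=scope,
                scenario=f"power(beta_AB={b})", beta_ab_true=true_b,
            )
        )
    return out


def recovery_study(
    config: GeneratorConfig,
    beta_ab_true: float,
    reps: int = 500,
    seed: int = 0,
    scope: str = "overall",
) -> StudyResult:
    """Bias and RMSE of the estimated overall interaction coefficient."""
    n_stages = len(config.schedule.stages)
    cfg = config
    for st in config.schedule.stages:
        cfg = inject_interaction(cfg, st, beta_ab_true / n_stages)
    return _run_replicates(
        cfg, reps, alpha=0.05, seed=seed, scope=scope,
        scenario=f"recovery(beta_AB={beta_ab_true})", beta_ab_true=beta_ab_true,
    )


def familywise_error_study(
    config: GeneratorConfig,
    dosage_labels,
    reps: int = 300,
    alpha: float = 0.05,
    seed: int = 0,
    scopes=("overall", "larva", "prepupa", "pupa"),
    families: dict | None = None,
) -> StudyResult:
    """Family-wise error of the Holm-corrected battery under the global null.

    A replicate counts as a rejection when any member test of the battery is
    called synergism or antagonism after Holm adjustment.  Replicates whose
    member tests all fail (degenerate groups) are excluded and counted.
    """
    from .interaction import INDEPENDENT, run_interaction_family

    if any(c.beta_ab != 0 for c in config.stage_coefs.values()):
        raise ValueError("family-wise error study requires beta_AB = 0 everywhere")
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(0, 2**31 - 1, size=reps)
    rejections = 0
    degenerate = 0
    used = 0
    for s in rep_seeds:
        data = simulate_assay(config, seed=int(s))
        fam = run_interaction_family(
            data, dosage_labels, scopes=scopes, alpha=alpha, families=families
        )
        calls = [r.direction for r in fam.results if not r.failed]
        if not calls:
            degenerate += 1
            continue
        used += 1
        if any(c != INDEPENDENT for c in calls):
            rejections += 1
    return StudyResult(
        scenario=f"familywise(alpha={alpha})",
        beta_ab_true=0.0,
        replicates=reps,
        n_used=used,
        rejections=rejections,
        alpha=alpha,
        mean_beta_ab=float("nan"),
        rmse_beta_ab=float("nan"),
        n_degenerate=degenerate,
        seed=seed,
    )


def results_to_frame(results) -> pd.DataFrame:
    if isinstance(results, StudyResult):
        results = [results]
    return pd.DataFrame([r.to_dict() for r in results])


def results_to_json(results, **kw) -> str:
    if isinstance(results, StudyResult):
        results = [results]
    return json.dumps([r.to_dict() for r in results], **kw)
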