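"""Shared fixtures: toy designs, toy datasets, and an independent
barrier-method oracle for the constrained log-binomial likelihood."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from blissassay.assay import AssayDataset, DEFAULT_SCHEDULE
from blissassay.glm import DesignMatrix

# canonical 2x2 toy: survivors per 100 in control / A / B / A+B
TOY_COUNTS = (90, 72, 63, 40)
# combination survival exactly at the Bliss product 0.9*0.8*0.7 = 0.504
BLISS_EXACT_COUNTS = (900, 720, 630, 504)

CELLS = [(0, 0), (1, 0), (0, 1), (1, 1)]


def counts_design(counts, n_per_cell, interaction=True):
    """Single-trial 2x2 design matrix and outcome vector from cell counts."""
    rows, y = [], []
    for (xa, xb), k in zip(CELLS, counts):
        for i in range(n_per_cell):
            row = [1, xa, xb] + ([xa * xb] if interaction else [])
            rows.append(row)
            y.append(1.0 if i < k else 0.0)
    names = ("intercept", "x_A", "x_B") + (("x_A:x_B",) if interaction else ())
    return DesignMatrix(np.array(rows, dtype=float), names), np.array(y)


def four_group_dataset(counts, n_per_cell, trial_id="trial1"):
    """Single-trial AssayDataset whose overall survival matches cell counts.

    Non-survivors die on day 3 (larval stage); survivors emerge.
    """
    labels = ["control", "agent_a", "agent_b", "combo"]
    doses = [(0.0, 0.0), (2000.0, 0.0), (0.0, 1440.0), (2000.0, 1440.0)]
    rows = []
    for label, (da, db), (xa, xb), k in zip(labels, doses, CELLS, counts):
        for i in range(n_per_cell):
            survived = i < k
            rows.append(
                {
                    "subject_id": f"{trial_id}_{label}_{i}",
                    "trial_id": trial_id,
                    "group_label": label,
                    "x_A": xa,
                    "x_B": xb,
                    "dose_A_ng_ml": da,
                    "dose_B_ng_ml": db,
                    "fate": "emerged" if survived else "died",
                    "fate_day": np.nan if survived else 3,
                    "fate_stage": None if survived else "larva",
                }
            )
    return AssayDataset(pd.DataFrame(rows), DEFAULT_SCHEDULE, control_group="control")


def aggregate(design, y):
    pats, inv = np.unique(design.matrix, axis=0, return_inverse=True)
    n = np.bincount(inv, minlength=len(pats)).astype(float)
    k = np.bincount(inv, weights=y, minlength=len(pats)).astype(float)
    return pats, n, k


def oracle_max_loglik(design, y):
    """Barrier-method maximization of the log-link binomial likelihood over
    {beta : P beta < 0}, using Nelder-Mead — an algorithmic route independent
    of the package's SLSQP/Newton fitter."""
    P, n, k = aggregate(design, y)

    def ll(beta):
        eta = P @ beta
        if (eta >= 0).any():
            return -np.inf
        return k @ eta + (n - k) @ np.log1p(-np.exp(eta))

    def nll_barrier(beta, mu):
        eta = P @ beta
        if (eta >= 0).any():
            return np.inf
        return -(k @ eta + (n - k) @ np.log1p(-np.exp(eta))
                 + mu * np.log(-eta).sum())

    p0 = (k + 0.5) / (n + 1.0)
    beta, *_ = np.linalg.lstsq(P, np.log(p0), rcond=None)
    if (P @ beta).max() >= 0:
        beta = np.zeros(P.shape[1])
        beta[0] = np.log(p0.mean())
    for mu in (1e-1, 1e-3, 1e-5, 1e-7, 1e-9):
        res = minimize(
            nll_barrier, beta, args=(mu,), method="Nelder-Mead",
            options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 20000},
        )
        beta = res.x
    return ll(beta), beta


@pytest.fixture
def toy_design():
    return counts_design(TOY_COUNTS, 100)


@pytest.fixture
def toy_dataset():
    return four_group_dataset(TOY_COUNTS, 100)
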