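"""Node-level analysis: degree centrality and permutation regression.

Centrality here is weighted degree of a dyadic rate matrix: *outdegree*
(row sum) is behaviour the focal directs at conspecifics, *indegree*
(column sum) behaviour conspecifics direct at the focal.  Inference on a
node-level outcome uses outcome-vector permutation: node labels are
exchangeable under the null, so shuffling the outcome across nodes builds
a valid reference distribution while keeping the covariate structure
intact.  With few nodes (n! up to 5040) the shuffle is exhaustive.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrices import DyadMatrix
from .mrqap import EXHAUSTIVE_THRESHOLD, _TIE_RTOL, _fit_ols, _name_collinear

__all__ = [
    "NodeRegressionResult",
    "degree",
    "node_permutation_regression",
    "run_centrality_model",
]


@dataclass
class NodeRegressionResult:
    outcome_name: str
    predictor_names: list[str]
    coefficients: np.ndarray
    standardized_coefficients: np.ndarray
    std_errors: np.ndarray
    p_values: np.ndarray
    r_squared: float
    n_permutations: int
    seed: int | None
    n_nodes: int
    exhaustive: bool = False
    intercept: float = 0.0

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome_name,
            "predictors": list(self.predictor_names),
            "coefficients": [float(b) for b in self.coefficients],
            "standardized_coefficients": [
                float(b) for b in self.standardized_coefficients
            ],
            "std_errors": [float(s) for s in self.std_errors],
            "p_values": [float(p) for p in self.p_values],
            "r_squared": float(self.r_squared),
            "intercept": float(self.intercept),
            "n_permutations": int(self.n_permutations),
            "seed": self.seed,
            "n_nodes": int(self.n_nodes),
            "exhaustive": bool(self.exhaustive),
        }


def degree(matrix: DyadMatrix, direction: str = "out") -> pd.Series:
    """Weighted degree: ``out`` = row sums, ``in`` = column sums."""
    if direction == "out":
        vals = matrix.values.sum(axis=1)
    elif direction == "in":
        vals = matrix.values.sum(axis=0)
    else:
        raise ValueError(f"direction must be 'out' or 'in', got {direction!r}")
    return pd.Series(vals, index=matrix.labels, name=f"{matrix.name}_{direction}degree")


def node_permutation_regression(
    y,
    X: pd.DataFrame,
    n_perm: int = 2000,
    seed: int | None = None,
    exhaustive: bool | str = "auto",
    exhaustive_threshold: int = EXHAUSTIVE_THRESHOLD,
    outcome_name: str | None = None,
) -> NodeRegressionResult:
    """OLS of a node outcome on node covariates, null by permuting y.

    p-values are two-sided with the (1 + hits)/(1 + n_perm) estimator, or
    the exact proportion over all n! outcome orderings in exhaustive mode.
    """
    y = np.asarray(y, dtype=float).ravel()
    names = [str(c) for c in X.columns]
    Xv = X.to_numpy(dtype=float)
    n = len(y)
    if Xv.shape[0] != n:
        raise ValueError("outcome and covariate table differ in length")
    if np.isnan(y).any() or np.isnan(Xv).any():
        raise ValueError("missing values in outcome or covariates")
    if y.std() == 0:
        raise ValueError("outcome is constant across nodes")

    design = np.column_stack([np.ones(n), Xv])
    bad = _name_collinear(design, ["(intercept)", *names])
    if bad:
        raise ValueError(f"rank-deficient design; collinear predictors: {bad}")

    beta_full, r2, se = _fit_ols(y, design)
    intercept, coefs = beta_full[0], beta_full[1:]
    std_coefs = coefs * Xv.std(axis=0, ddof=1) / y.std(ddof=1)

    if exhaustive == "auto":
        exh = math.factorial(n) <= exhaustive_threshold
    else:
        exh = bool(exhaustive)
    if exh:
        perms = np.array(list(itertools.permutations(range(n))), dtype=np.intp)
    else:
        rng = np.random.default_rng(seed)
        perms = np.empty((n_perm, n), dtype=np.intp)
        for k in range(n_perm):
            perms[k] = rng.permutation(n)

    # beta* = pinv(design) @ y_perm for every permutation at once
    G = np.linalg.pinv(design)          # (k+1, n)
    B = y[perms] @ G.T                  # (P, k+1)
    abs_null = np.abs(B[:, 1:])
    abs_obs = np.abs(coefs)
    hits = (abs_null >= abs_obs * (1.0 - _TIE_RTOL)).sum(axis=0)
    if exh:
        p_values = hits / len(perms)
    else:
        p_values = (1 + hits) / (1 + len(perms))

    return NodeRegressionResult(
        outcome_name=outcome_name or (y if isinstance(y, str) else "outcome"),
        predictor_names=names,
        coefficients=coefs,
        standardized_coefficients=std_coefs,
        std_errors=se[1:],
        p_values=np.asarray(p_values, dtype=float),
        r_squared=r2,
        n_permutations=len(perms),
        seed=seed,
        n_nodes=n,
        exhaustive=exh,
        intercept=float(intercept),
    )


def run_centrality_model(
    networks: dict[str, DyadMatrix],
    attrs: pd.DataFrame,
    n_perm: int = 2000,
    seed: int | None = 0,
    sex_age_coding: str = "separate",
) -> NodeRegressionResult:
    """Proximity outdegree regressed on communication degrees and controls.

    Outcome: proximity outdegree (total minutes-per-party-hour the focal
    spends within 10 m of the 11 others).  Predictors: out- and in-degree
    of the rapid, single and persistence rate matrices, plus controls —
    time in proximity to cycling females, time in proximity to maternal
    kin, and the focal's sex and age.

    ``sex_age_coding``: ``"separate"`` (default) enters sex (male = 1) and
    age as two columns; ``"composite"`` enters their product (male x
    z-scored age) as a single column, for designs that want one df spent on
    demography.
    """
    needed = ["proximity", "rapid", "single", "persistence", "kin_similarity"]
    missing = sorted(set(needed) - set(networks))
    if missing:
        raise KeyError(f"missing networks for centrality model: {missing}")
    for col in ("id", "sex", "age", "reproductive_status"):
        if col not in attrs.columns:
            raise ValueError(f"attribute table lacks required column {col!r}")

    prox = networks["proximity"]
    labels = prox.labels
    attrs = attrs.set_index(attrs["id"].astype(str)).loc[labels]

    y = degree(prox, "out")
    cols: dict[str, np.ndarray] = {}
    cycling = (attrs["reproductive_status"].astype(str) == "cycling").to_numpy(float)
    kin = networks["kin_similarity"].aligned_to(labels).values
    # proximity time restricted to cycling-female / kin partners
    cols["oestrous_proximity"] = prox.values @ cycling
    cols["kin_proximity"] = (prox.values * kin).sum(axis=1)
    sex = (attrs["sex"].astype(str) == "male").to_numpy(float)
    age = attrs["age"].to_numpy(float)
    if sex_age_coding == "separate":
        cols["sex_male"] = sex
        cols["age"] = age
    elif sex_age_coding == "composite":
        z_age = (age - age.mean()) / age.std(ddof=1)
        cols["sex_age"] = sex * z_age
    else:
        raise ValueError(f"unknown sex_age_coding {sex_age_coding!r}")
    for cls in ("rapid", "single", "persistence"):
        net = networks[cls].aligned_to(labels)
        cols[f"{cls}_outdegree"] = degree(net, "out").to_numpy()
        cols[f"{cls}_indegree"] = degree(net, "in").to_numpy()

    X = pd.DataFrame(cols, index=labels)
    return node_permutation_regression(
        y.to_numpy(), X, n_perm=n_perm, seed=seed,
        outcome_name="proximity_outdegree",
    )
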