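"""Quadratic-assignment permutation inference for dyadic matrices.

Dyadic observations are not independent: every dyad shares a node with
2(n-2) other dyads, so OLS p-values on vectorized matrices are invalid.
QAP builds the null distribution by relabelling the *nodes* — applying one
random permutation simultaneously to rows and columns — which preserves
the dyadic dependence structure exactly.

For multiple regression we use Double-Dekker semi-partialling (DSP): each
predictor's null is built by residualizing its matrix on the remaining
predictors dyad-wise, permuting the re-formed residual *matrix* by node
relabelling, substituting it for the predictor, and refitting.  Permuting
residuals rather than the raw predictor makes the per-coefficient test
robust to network autocorrelation and collinearity among predictors.

For node communities small enough (n! up to 5040, i.e. n <= 7) the sampled
null is replaced by exhaustive enumeration over all n! relabelings, which
is exact and serves as the engine's primary correctness oracle.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .matrices import DyadMatrix, offdiag_indices

__all__ = [
    "MRQAPResult",
    "qap_correlation",
    "mrqap_dsp",
    "run_hypothesis_models",
    "HYPOTHESIS_MODELS",
]

#: enumerate all n! relabelings instead of sampling when n! is at most this
EXHAUSTIVE_THRESHOLD = 5040

#: relative tie tolerance: |b*| within this relative band of |b| counts as
#: extreme (ties reject, the conservative reading of ">=")
_TIE_RTOL = 1e-12


@dataclass
class MRQAPResult:
    """Fit and permutation inference for one dyadic regression."""

    outcome_name: str
    predictor_names: list[str]
    coefficients: np.ndarray
    standardized_coefficients: np.ndarray
    std_errors: np.ndarray          # classical OLS, not permutation-based
    p_values: np.ndarray
    r_squared: float
    n_permutations: int
    seed: int | None
    n_dyads: int
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
            "n_dyads": int(self.n_dyads),
            "exhaustive": bool(self.exhaustive),
        }


def _check_labels(matrices: list[DyadMatrix]) -> list[str]:
    labels = matrices[0].labels
    for m in matrices[1:]:
        if m.labels != labels:
            raise ValueError(
                f"matrix {m.name!r} has different node labels; align matrices first"
            )
    return labels


def _permutations(
    n: int, n_perm: int, seed, exhaustive: bool
) -> tuple[np.ndarray, bool]:
    """Relabeling matrix (P, n): exhaustive enumeration or seeded sampling."""
    if exhaustive:
        perms = np.array(list(itertools.permutations(range(n))), dtype=np.intp)
        return perms, True
    rng = np.random.default_rng(seed)
    perms = np.empty((n_perm, n), dtype=np.intp)
    for k in range(n_perm):
        perms[k] = rng.permutation(n)
    return perms, False


def _decide_exhaustive(n: int, exhaustive: bool | str, threshold: int) -> bool:
    if exhaustive == "auto":
        return math.factorial(n) <= threshold
    return bool(exhaustive)


def _p_from_null(abs_null: np.ndarray, abs_obs: float, exhaustive: bool) -> float:
    hits = int(np.sum(abs_null >= abs_obs * (1.0 - _TIE_RTOL)))
    if exhaustive:
        return hits / len(abs_null)   # identity relabeling is in the set, p > 0
    return (1 + hits) / (1 + len(abs_null))


def qap_correlation(
    X: DyadMatrix,
    Y: DyadMatrix,
    n_perm: int = 2000,
    seed: int | None = None,
    exhaustive: bool | str = "auto",
    exhaustive_threshold: int = EXHAUSTIVE_THRESHOLD,
) -> tuple[float, float]:
    """Pearson correlation of two dyadic matrices with a QAP p-value.

    The observed r is compared two-sidedly (|r*| >= |r|) against r under
    simultaneous row-and-column relabelings of X.
    """
    _check_labels([X, Y])
    n = X.n
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    i, j = offdiag_indices(n)
    x, y = X.values[i, j], Y.values[i, j]
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        raise ValueError("correlation undefined: zero-variance dyad vector")
    xc, yc = x - x.mean(), y - y.mean()
    r = float(xc @ yc / (len(x) * sx * sy))

    exh = _decide_exhaustive(n, exhaustive, exhaustive_threshold)
    perms, exh = _permutations(n, n_perm, seed, exh)
    # node relabeling maps off-diagonal cells onto off-diagonal cells, so the
    # permuted vector has the same mean and sd as x
    Xp = X.values[perms[:, i], perms[:, j]]
    r_null = (Xp - x.mean()) @ yc / (len(x) * sx * sy)
    p = _p_from_null(np.abs(r_null), abs(r), exh)
    return r, p


def _fit_ols(y: np.ndarray, design: np.ndarray) -> tuple[np.ndarray, float, np.ndarray]:
    """beta, R^2 and classical standard errors for a full-rank design."""
    beta, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    dof = len(y) - design.shape[1]
    if dof > 0:
        sigma2 = ss_res / dof
        cov = sigma2 * np.linalg.inv(design.T @ design)
        se = np.sqrt(np.diag(cov))
    else:
        se = np.full(design.shape[1], np.nan)
    return beta, r2, se


def _name_collinear(design: np.ndarray, names: list[str]) -> list[str]:
    """Columns adding (numerically) no new direction, by greedy QR order."""
    _, R = np.linalg.qr(design)
    d = np.abs(np.diag(R))
    scale = d.max() if d.size else 1.0
    return [names[k] for k in range(len(names)) if d[k] <= 1e-10 * scale]


def mrqap_dsp(
    Y: DyadMatrix,
    Xs: list[DyadMatrix],
    n_perm: int = 2000,
    seed: int | None = None,
    exhaustive: bool | str = "auto",
    exhaustive_threshold: int = EXHAUSTIVE_THRESHOLD,
    mask: np.ndarray | None = None,
) -> MRQAPResult:
    """Multiple-regression QAP with Double-Dekker semi-partialling.

    Point estimates are OLS of the vectorized outcome on the vectorized
    predictors with an intercept (the intercept is fitted, never tested).
    Each predictor's permutation null substitutes its node-relabelled
    dyad-wise residual matrix and refits; p-values use the two-sided
    (1 + hits)/(1 + n_perm) estimator, or the exact proportion over all n!
    relabelings in exhaustive mode.  Residualization is done on raw
    (unstandardized) vectors so p-values do not depend on scaling;
    standardized coefficients are reported alongside.

    ``mask`` (n x n boolean, True = keep) drops flagged dyads from every
    vector consistently; masked cells enter permuted residual matrices as 0.
    """
    if not Xs:
        raise ValueError("at least one predictor matrix is required")
    labels = _check_labels([Y, *Xs])
    n = Y.n
    i, j = offdiag_indices(n)
    keep = None
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (n, n):
            raise ValueError("mask shape does not match matrices")
        keep = mask[i, j]

    def vec(m: DyadMatrix) -> np.ndarray:
        v = m.values[i, j]
        return v[keep] if keep is not None else v

    y = vec(Y)
    if y.std() == 0:
        raise ValueError(f"outcome {Y.name!r} is constant across dyads")
    X = np.column_stack([vec(x) for x in Xs])
    names = [x.name or f"x{k}" for k, x in enumerate(Xs)]
    m_dyads, k_pred = X.shape

    design = np.column_stack([np.ones(m_dyads), X])
    bad = _name_collinear(design, ["(intercept)", *names])
    if bad:
        raise ValueError(f"rank-deficient design; collinear predictors: {bad}")

    beta_full, r2, se_full = _fit_ols(y, design)
    intercept, coefs = beta_full[0], beta_full[1:]
    sy = y.std(ddof=1)
    sx = X.std(axis=0, ddof=1)
    std_coefs = coefs * sx / sy

    exh = _decide_exhaustive(n, exhaustive, exhaustive_threshold)
    if exh:
        perms, _ = _permutations(n, n_perm, None, True)
        streams = [None] * k_pred
    else:
        # one independent stream per predictor: results do not depend on the
        # order predictors are processed in
        streams = np.random.SeedSequence(seed).spawn(k_pred)

    p_values = np.empty(k_pred)
    for t in range(k_pred):
        Z = np.delete(design, t + 1, axis=1)
        G = np.linalg.pinv(Z)              # (k, m)
        e = X[:, t] - Z @ (G @ X[:, t])    # residual of predictor on the rest
        r_y = y - Z @ (G @ y)
        beta_obs = float(e @ r_y / (e @ e))

        # re-form residuals as a matrix and relabel nodes
        R = np.zeros((n, n))
        if keep is not None:
            full = np.zeros(len(i))
            full[keep] = e
            R[i, j] = full
        else:
            R[i, j] = e
        if not exh:
            perms, _ = _permutations(n, n_perm, streams[t], False)
        E = R[perms[:, i], perms[:, j]]
        if keep is not None:
            E = E[:, keep]
        # FWL: coefficient on the substituted column in the refit equals
        # (e~* . r_y) / ||e~*||^2 with e~* the residual of e* on Z
        Etil = E - (E @ G.T) @ Z.T
        num = Etil @ r_y
        den = np.einsum("pm,pm->p", Etil, Etil)
        with np.errstate(divide="ignore", invalid="ignore"):
            beta_null = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
        p_values[t] = _p_from_null(np.abs(beta_null), abs(beta_obs), exh)

    return MRQAPResult(
        outcome_name=Y.name,
        predictor_names=names,
        coefficients=coefs,
        standardized_coefficients=std_coefs,
        std_errors=se_full[1:],
        p_values=p_values,
        r_squared=r2,
        n_permutations=len(perms),
        seed=seed,
        n_dyads=m_dyads,
        exhaustive=exh,
        intercept=float(intercept),
    )


#: the six dyadic model recipes: outcome and predictors by matrix name.
#: H1: does proximity track sequence-type rates; H2 (three outcomes): do
#: response types track sequence type; H3: response presence vs proximity;
#: H4: response type vs proximity.
_SIMS = ["age_similarity", "sex_similarity", "kin_similarity", "oestrous_similarity"]
_RESPONSE_TYPES = [
    "response_visual_tactile_gesture",
    "response_activity_change",
    "response_vocalisation",
]
HYPOTHESIS_MODELS: dict[str, tuple[str, list[str]]] = {
    "H1_proximity_by_sequence_type": (
        "proximity", _SIMS + ["rapid", "single", "persistence"]
    ),
    "H2_rapid_by_response_type": ("rapid", _SIMS + _RESPONSE_TYPES),
    "H2_persistence_by_response_type": ("persistence", _SIMS + _RESPONSE_TYPES),
    "H2_single_by_response_type": ("single", _SIMS + _RESPONSE_TYPES),
    "H3_proximity_by_response_presence": (
        "proximity", _SIMS + ["response_absent", "response_present"]
    ),
    "H4_proximity_by_response_type": ("proximity", _SIMS + _RESPONSE_TYPES),
}


def run_hypothesis_models(
    networks: dict[str, DyadMatrix],
    n_perm: int = 2000,
    seed: int | None = 0,
    mask: np.ndarray | None = None,
    models: dict[str, tuple[str, list[str]]] | None = None,
) -> dict[str, MRQAPResult]:
    """Run the six dyadic hypothesis models as a batch with one seed policy.

    Each model draws its permutations from an independent child stream of
    ``seed`` (in fixed model order), so adding or removing one model never
    changes another's p-values.
    """
    models = models or HYPOTHESIS_MODELS
    needed = {name for _, (y, xs) in models.items() for name in [y, *xs]}
    missing = sorted(needed - set(networks))
    if missing:
        raise KeyError(f"missing networks for hypothesis models: {missing}")

    streams = np.random.SeedSequence(seed).spawn(len(models))
    results: dict[str, MRQAPResult] = {}
    for stream, (model_name, (y_name, x_names)) in zip(streams, models.items()):
        child_seed = int(stream.generate_state(1)[0] % (2**31))
        results[model_name] = mrqap_dsp(
            networks[y_name],
            [networks[x] for x in x_names],
            n_perm=n_perm,
            seed=child_seed,
            mask=mask,
        )
        results[model_name].seed = child_seed
    return results
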