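"""Three-class multinomial logistic model over binary symptom predictors.

The suspicion index's underlying risk model: a single-layer softmax
(multinomial logistic) classifier mapping a binary symptom pattern to
probabilities of (case, control, non_case). The fit maximises the multinomial
log-likelihood minus a ridge penalty on the slopes (intercepts unpenalised)
with a damped Newton iteration from a zero start — the objective is concave,
so no random restarts are needed and the fit is fully deterministic.

The ridge default (1e-2) matters: development-cohort-like data exhibit
quasi-complete separation (e.g. mixed dyslipidemia in virtually every
non-case, splenomegaly in almost none), under which the unpenalised MLE
diverges; a small ridge keeps coefficients finite without materially moving
interior estimates.

Because predictors are binary, observations are aggregated to unique symptom
patterns with per-class counts before fitting, which makes the repeated fits
of the subset-selection and bootstrap modules cheap.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import Cohort

CLASS_ORDER = ("case", "control", "non_case")
_SCHEMA_VERSION = 1


class SchemaError(ValueError):
    """Model file does not match the expected serialisation schema."""


@dataclass(frozen=True)
class ModelSpec:
    """Variables and fitting hyper-parameters of a multinomial symptom model."""

    variables: tuple[str, ...]
    reference_class: str = "non_case"
    ridge_penalty: float = 1e-2
    max_iterations: int = 200
    tolerance: float = 1e-8

    def __post_init__(self) -> None:
        if len(self.variables) != len(set(self.variables)):
            raise ValueError("spec variables must be unique")
        if self.reference_class not in CLASS_ORDER:
            raise ValueError(f"reference_class must be one of {CLASS_ORDER}")
        if self.ridge_penalty < 0:
            raise ValueError("ridge_penalty must be non-negative")
        if self.max_iterations <= 0 or self.tolerance <= 0:
            raise ValueError("max_iterations and tolerance must be positive")


def _softmax_probs(eta_nonref: np.ndarray) -> np.ndarray:
    """Class probabilities from non-reference linear predictors (ref logit 0)."""
    full = np.concatenate([eta_nonref, np.zeros((len(eta_nonref), 1))], axis=1)
    full -= full.max(axis=1, keepdims=True)
    e = np.exp(full)
    return e / e.sum(axis=1, keepdims=True)


def _newton_fit(counts: np.ndarray, patterns: np.ndarray, ridge: float,
                tol: float, max_iter: int):
    """Damped Newton fit on aggregated data.

    counts: (U, K) per-class counts for each unique pattern, with the
    REFERENCE class in the last column; patterns: (U, p) binary designs
    (no intercept column). Returns (beta, llf, converged, llf_history, hess)
    with beta of shape (K-1, p+1), intercept first.
    """
    U, K = counts.shape
    X = np.hstack([np.ones((U, 1)), patterns.astype(float)])
    p = X.shape[1]
    n_u = counts.sum(axis=1)
    npar = (K - 1) * p
    pen = np.full(npar, ridge)
    pen[::p] = 0.0  # intercepts unpenalised
    beta = np.zeros((K - 1, p))

    def objective(b):
        eta = X @ b.T
        probs = _softmax_probs(eta)
        with np.errstate(divide="ignore"):
            ll = float(np.where(counts > 0, counts * np.log(
                np.clip(probs, 1e-300, None)), 0.0).sum())
        return ll - 0.5 * float(pen @ (b.ravel() ** 2)), probs, ll

    obj, probs, ll = objective(beta)
    history = [ll]
    converged = False
    H = None
    for _ in range(max_iter):
        G = counts[:, :K - 1] - n_u[:, None] * probs[:, :K - 1]
        grad = (X.T @ G).T.ravel() - pen * beta.ravel()
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        H = np.empty((npar, npar))
        for i in range(K - 1):
            for j in range(i, K - 1):
                w = n_u * probs[:, i] * ((i == j) - probs[:, j])
                blk = X.T @ (w[:, None] * X)
                H[i * p:(i + 1) * p, j * p:(j + 1) * p] = blk
                H[j * p:(j + 1) * p, i * p:(i + 1) * p] = blk
        H[np.diag_indices_from(H)] += pen
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        # damped update: halve until the penalised objective does not decrease
        t = 1.0
        for _ls in range(40):
            cand = beta + t * step.reshape(K - 1, p)
            cand_obj, cand_probs, cand_ll = objective(cand)
            if cand_obj >= obj - 1e-12:
                break
            t *= 0.5
        beta, obj, probs, ll = cand, cand_obj, cand_probs, cand_ll
        history.append(ll)
    if H is None:  # gradient already below tolerance at start
        H = np.eye(npar)
    return beta, ll, converged, history, H


class MultinomialSymptomModel:
    """Penalised multinomial logistic model built from a cohort.

    Parameters
    ----------
    endog : array of class codes in ``CLASS_ORDER`` indexing
    exog : (n, k) binary predictor matrix
    spec : ModelSpec with variable names and hyper-parameters
    """

    def __init__(self, endog, exog, spec: ModelSpec):
        if not spec.variables and np.size(exog, 1) != 0:
            raise ValueError("exog has columns but spec names no variables")
        y = np.asarray(endog, dtype=np.int64)
        X = np.asarray(exog, dtype=np.int64)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("endog/exog shape mismatch")
        if X.size and not np.isin(X, (0, 1)).all():
            raise ValueError("predictors must be binary 0/1")
        present = np.unique(y)
        if len(present) < 2:
            raise ValueError("need at least two classes with observations")
        self.endog = y
        self.exog = X
        self.spec = spec
        self.n_excluded = 0

    @classmethod
    def from_cohort(cls, cohort: Cohort, spec: ModelSpec) -> "MultinomialSymptomModel":
        """Build from a cohort; records with unknown values in any model
        variable are excluded (complete-case) and counted in ``n_excluded``."""
        for v in spec.variables:
            if v not in cohort.catalog:
                raise ValueError(f"variable {v!r} not in catalog")
        M = cohort.symptom_matrix(list(spec.variables))
        keep = ~np.isnan(M).any(axis=1) if M.size else np.ones(len(cohort), bool)
        y = cohort.group_codes(CLASS_ORDER)[keep]
        model = cls(y, M[keep].astype(np.int64), spec)
        model.n_excluded = int((~keep).sum())
        return model

    def fit(self) -> "MultinomialSymptomResults":
        spec = self.spec
        ref = CLASS_ORDER.index(spec.reference_class)
        nonref = [i for i in range(len(CLASS_ORDER)) if i != ref]
        order = nonref + [ref]  # reference class last for the core
        K = len(CLASS_ORDER)
        k = len(spec.variables)
        # aggregate to unique patterns
        if k:
            codes = self.exog @ (1 << np.arange(k, dtype=np.int64))
        else:
            codes = np.zeros(len(self.endog), dtype=np.int64)
        ucodes, inv = np.unique(codes, return_inverse=True)
        counts = np.zeros((len(ucodes), K))
        for pos, cls_idx in enumerate(order):
            counts[:, pos] = np.bincount(
                inv[self.endog == cls_idx], minlength=len(ucodes))
        patterns = ((ucodes[:, None] >> np.arange(k)) & 1).astype(np.int64) \
            if k else np.zeros((len(ucodes), 0), dtype=np.int64)
        beta, llf, converged, history, hess = _newton_fit(
            counts, patterns, spec.ridge_penalty, spec.tolerance,
            spec.max_iterations)
        try:
            cov = np.linalg.inv(hess)
            bse = np.sqrt(np.clip(np.diag(cov), 0, None)).reshape(beta.shape)
        except np.linalg.LinAlgError:
            bse = np.full_like(beta, np.nan)
        return MultinomialSymptomResults(
            model=self, params=beta, bse=bse, llf=llf, converged=converged,
            llf_history=history, nonref_classes=tuple(CLASS_ORDER[i] for i in nonref),
            n_obs=len(self.endog),
        )


@dataclass
class MultinomialSymptomResults:
    """Fitted multinomial symptom model.

    ``params``/``bse`` have one row per non-reference class (order given by
    ``nonref_classes``) and columns (intercept, *variables*).
    """

    model: MultinomialSymptomModel
    params: np.ndarray
    bse: np.ndarray
    llf: float
    converged: bool
    llf_history: list[float]
    nonref_classes: tuple[str, ...]
    n_obs: int

    @property
    def spec(self) -> ModelSpec:
        return self.model.spec

    def _pattern_matrix(self, pattern) -> np.ndarray:
        variables = self.spec.variables
        if isinstance(pattern, dict):
            missing = [v for v in variables if v not in pattern]
            if missing:
                raise KeyError(f"pattern lacks variable(s) {missing}")
            arr = np.array([[pattern[v] for v in variables]], dtype=float)
        elif isinstance(pattern, pd.DataFrame):
            missing = [v for v in variables if v not in pattern.columns]
            if missing:
                raise KeyError(f"pattern lacks variable(s) {missing}")
            arr = pattern[list(variables)].to_numpy(dtype=float)
        else:
            arr = np.atleast_2d(np.asarray(pattern, dtype=float))
        if arr.shape[1] != len(variables):
            raise ValueError(
                f"expected {len(variables)} variables, got {arr.shape[1]}")
        if not np.isin(arr, (0.0, 1.0)).all():
            raise ValueError("pattern values must be 0/1")
        return arr

    def predict_proba(self, pattern) -> np.ndarray:
        """Probability vectors over ``CLASS_ORDER`` = (case, control, non_case).

        ``pattern`` may be a mapping symptom_id -> 0/1, a DataFrame with the
        model variables as columns, or a 0/1 array in spec-variable order.
        """
        arr = self._pattern_matrix(pattern)
        X = np.hstack([np.ones((len(arr), 1)), arr])
        eta = X @ self.params.T
        probs_nonref_last = _softmax_probs(eta)
        out = np.empty((len(arr), len(CLASS_ORDER)))
        for pos, cname in enumerate(self.nonref_classes):
            out[:, CLASS_ORDER.index(cname)] = probs_nonref_last[:, pos]
        ref = self.spec.reference_class
        out[:, CLASS_ORDER.index(ref)] = probs_nonref_last[:, -1]
        return out if out.shape[0] > 1 else out[0]

    def summary(self) -> str:
        lines = [
            "Multinomial symptom model (softmax, ridge-penalised)",
            "=" * 58,
            f"classes:          case / control / non_case "
            f"(reference: {self.spec.reference_class})",
            f"observations:     {self.n_obs}"
            + (f"  (excluded incomplete: {self.model.n_excluded})"
               if self.model.n_excluded else ""),
            f"ridge penalty:    {self.spec.ridge_penalty:g} (slopes only)",
            f"log-likelihood:   {self.llf:.4f}",
            f"converged:        {self.converged}",
            "-" * 58,
            f"{'class':<10s}{'term':<34s}{'coef':>10s}{'se':>10s}",
        ]
        terms = ("intercept",) + self.spec.variables
        for row, cname in enumerate(self.nonref_classes):
            for col, term in enumerate(terms):
                lines.append(
                    f"{cname:<10s}{term:<34s}{self.params[row, col]:>10.4f}"
                    f"{self.bse[row, col]:>10.4f}")
        lines.append("=" * 58)
        return "\n".join(lines)

    # -- serialisation -----------------------------------------------------
    def save(self, path, provenance: dict | None = None) -> None:
        doc = {
            "schema_version": _SCHEMA_VERSION,
            "variables": list(self.spec.variables),
            "reference_class": self.spec.reference_class,
            "ridge_penalty": self.spec.ridge_penalty,
            "nonref_classes": list(self.nonref_classes),
            "coefficients": self.params.tolist(),
            "bse": self.bse.tolist(),
            "llf": self.llf,
            "converged": self.converged,
            "n_obs": self.n_obs,
            "provenance": provenance or {},
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)

    @classmethod
    def load(cls, path) -> "MultinomialSymptomResults":
        try:
            with open(path) as fh:
                doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise SchemaError(f"{path}: not a valid model file: {exc}") from exc
        if not isinstance(doc, dict) or doc.get("schema_version") != _SCHEMA_VERSION:
            raise SchemaError(
                f"{path}: schema_version {doc.get('schema_version') if isinstance(doc, dict) else None!r}"
                f" != {_SCHEMA_VERSION}")
        required = {"variables", "reference_class", "coefficients", "nonref_classes"}
        missing = required - doc.keys()
        if missing:
            raise SchemaError(f"{path}: missing fields {sorted(missing)}")
        spec = ModelSpec(
            variables=tuple(doc["variables"]),
            reference_class=doc["reference_class"],
            ridge_penalty=float(doc.get("ridge_penalty", 1e-2)),
        )
        params = np.asarray(doc["coefficients"], dtype=float)
        model = MultinomialSymptomModel(
            np.array([CLASS_ORDER.index(spec.reference_class),
                      (CLASS_ORDER.index(spec.reference_class) + 1) % 3]),
            np.zeros((2, len(spec.variables)), dtype=np.int64), spec)
        return cls(
            model=model, params=params,
            bse=np.asarray(doc.get("bse", np.full_like(params, np.nan)), dtype=float),
            llf=float(doc.get("llf", np.nan)),
            converged=bool(doc.get("converged", True)),
            llf_history=[],
            nonref_classes=tuple(doc["nonref_classes"]),
            n_obs=int(doc.get("n_obs", 0)),
        )


# -- functional surface ----------------------------------------------------

def fit_multinomial(cohort: Cohort, spec: ModelSpec) -> MultinomialSymptomResults:
    """Fit the penalised multinomial model on a cohort (complete cases)."""
    return MultinomialSymptomModel.from_cohort(cohort, spec).fit()


def predict_proba(results: MultinomialSymptomResults, pattern) -> np.ndarray:
    return results.predict_proba(pattern)


def save_model(results: MultinomialSymptomResults, path, provenance=None) -> None:
    results.save(path, provenance)


def load_model(path) -> MultinomialSymptomResults:
    return MultinomialSymptomResults.load(path)
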