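"""Soft-margin RBF-kernel support vector machine for low-BMD screening.

The classifier follows the statsmodels model/results convention:
``CorticalWidthSVM`` holds the training data and hyper-parameters, ``fit()``
solves the dual quadratic program and returns an :class:`SVMResults` carrying
the support vectors, dual coefficients, bias, diagnostics and a ``summary()``
table, plus prediction, operating-point selection and screening-metric
evaluation.

Kernel convention
-----------------
K(xi, xj) = exp(-||xi - xj||^2 / (2 * gamma^2))

with gamma the RBF width (default 1), i.e. the 2*gamma^2 denominator form —
not the exp(-gamma*||.||^2) parameterization common elsewhere. The cost
parameter C (default 1) bounds the dual coefficients, 0 <= alpha_i <= C.

Labels
------
+1 marks the positive screening class (low BMD, DXA T-score <= -1.0) and
-1 the normal class. 0/1 encodings are accepted and mapped 1 -> +1, 0 -> -1.
The decision function is f(x) = sum_i alpha_i y_i K(x, x_i) + b, with
sign(0) taken as +1 so borderline cases screen positive.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.distance import cdist

from cortiscan.errors import DegenerateTrainingError, ParameterError, SolverError

_Z95 = 1.959963984540054  # two-sided 95% normal quantile


# ---------------------------------------------------------------------------
# kernel
# ---------------------------------------------------------------------------

def rbf_kernel(xi, xj, gamma: float = 1.0) -> float:
    """RBF kernel value exp(-||xi - xj||^2 / (2*gamma^2))."""
    if gamma <= 0:
        raise ParameterError(f"gamma must be positive, got {gamma}")
    xi = np.asarray(xi, dtype=float)
    xj = np.asarray(xj, dtype=float)
    d2 = float(np.sum((xi - xj) ** 2))
    return float(np.exp(-d2 / (2.0 * gamma * gamma)))


def _kernel_matrix(A: np.ndarray, B: np.ndarray, gamma: float) -> np.ndarray:
    d2 = cdist(A, B, metric="sqeuclidean")
    return np.exp(-d2 / (2.0 * gamma * gamma))


def _coerce_labels(y) -> np.ndarray:
    y = np.asarray(y)
    vals = set(np.unique(y).tolist())
    if vals <= {-1, 1}:
        return y.astype(np.int64)
    if vals <= {0, 1}:
        return np.where(y == 1, 1, -1).astype(np.int64)
    raise ParameterError(f"labels must be in {{-1,+1}} or {{0,1}}, got {sorted(vals)}")


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def _prop_ci(p: float, m: int) -> tuple[float, float]:
    if m == 0:
        return (float("nan"), float("nan"))
    half = _Z95 * np.sqrt(p * (1.0 - p) / m)
    return (max(0.0, p - half), min(1.0, p + half))


@dataclass(frozen=True)
class Metrics:
    """Screening-test performance with 95% confidence intervals.

    Proportion CIs use the normal approximation p +/- 1.96*sqrt(p(1-p)/m)
    clipped to [0, 1]; the positive likelihood ratio CI uses the standard
    log method. LR+ is infinite when specificity is 1 (flagged, not raised).
    """

    tp: int
    fn: int
    fp: int
    tn: int
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    accuracy: float
    lr_plus: float
    ci: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fn": self.fn, "fp": self.fp, "tn": self.tn,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "ppv": self.ppv, "npv": self.npv, "accuracy": self.accuracy,
            "lr_plus": self.lr_plus,
            "ci": {k: list(v) for k, v in self.ci.items()},
        }

    def __str__(self) -> str:
        rows = [("Sensitivity", self.sensitivity), ("Specificity", self.specificity),
                ("PPV", self.ppv), ("NPV", self.npv), ("Accuracy", self.accuracy),
                ("LR+", self.lr_plus)]
        lines = [f"{'Statistic':<12}{'Value':>9}   95% CI"]
        for name, v in rows:
            lo, hi = self.ci.get(name.lower().replace("+", "_plus"), (float("nan"),) * 2)
            val = f"{v:9.3f}" if np.isfinite(v) else f"{'inf':>9}"
            ci = f"({lo:.3f}, {hi:.3f})" if np.isfinite(lo) else "(-, -)"
            lines.append(f"{name:<12}{val}   {ci}")
        return "\n".join(lines)


def evaluate(predictions, labels) -> Metrics:
    """Screening metrics from predicted and true labels in {-1, +1} (or {0,1})."""
    pred = _coerce_labels(predictions)
    lab = _coerce_labels(labels)
    if pred.shape != lab.shape:
        raise ParameterError("predictions and labels differ in length")
    if not ((lab == 1).any() and (lab == -1).any()):
        raise ParameterError("labels must contain both classes")
    tp = int(np.sum((pred == 1) & (lab == 1)))
    fn = int(np.sum((pred == -1) & (lab == 1)))
    fp = int(np.sum((pred == 1) & (lab == -1)))
    tn = int(np.sum((pred == -1) & (lab == -1)))
    n = tp + fn + fp + tn
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    ppv = tp / (tp + fp) if (tp + fp) else float("nan")
    npv = tn / (tn + fn) if (tn + fn) else float("nan")
    acc = (tp + tn) / n
    lr = sens / (1.0 - spec) if spec < 1.0 else float("inf")
    ci = {
        "sensitivity": _prop_ci(sens, tp + fn),
        "specificity": _prop_ci(spec, tn + fp),
        "ppv": _prop_ci(ppv, tp + fp) if (tp + fp) else (float("nan"),) * 2,
        "npv": _prop_ci(npv, tn + fn) if (tn + fn) else (float("nan"),) * 2,
        "accuracy": _prop_ci(acc, n),
    }
    if np.isfinite(lr) and tp > 0 and fp > 0:
        se_log = np.sqrt(1.0 / tp - 1.0 / (tp + fn) + 1.0 / fp - 1.0 / (fp + tn))
        ci["lr_plus"] = (float(lr * np.exp(-_Z95 * se_log)),
                         float(lr * np.exp(_Z95 * se_log)))
    else:
        ci["lr_plus"] = (float("inf"), float("inf")) if not np.isfinite(lr) \
            else (float("nan"), float("nan"))
    return Metrics(tp=tp, fn=fn, fp=fp, tn=tn, sensitivity=sens, specificity=spec,
                   ppv=ppv, npv=npv, accuracy=acc, lr_plus=lr, ci=ci)


# ---------------------------------------------------------------------------
# operating point
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OperatingPoint:
    """Decision-score cutoff and the sensitivity achieved at it."""

    cutoff: float
    achieved_sensitivity: float


def choose_cutoff(scores, labels, target_sensitivity: float = 0.90) -> OperatingPoint:
    """Largest cutoff whose sensitivity reaches the target.

    A sample is screened positive when its score >= cutoff. Candidates are
    the midpoints between consecutive distinct sorted scores plus a sentinel
    below the minimum score (sensitivity 1 is always attainable); among
    candidates with sensitivity >= target the largest is returned, maximizing
    specificity at the required sensitivity.
    """
    if not (0.0 < target_sensitivity <= 1.0):
        raise ParameterError(
            f"target sensitivity must be in (0, 1], got {target_sensitivity}")
    s = np.asarray(scores, dtype=float)
    y = _coerce_labels(labels)
    if s.shape != y.shape:
        raise ParameterError("scores and labels differ in length")
    pos = s[y == 1]
    if pos.size == 0:
        raise ParameterError("at least one positive label is required")
    uniq = np.unique(s)
    candidates = np.concatenate(([uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0))
    best = None
    for cut in candidates:
        sens = float(np.mean(pos >= cut))
        if sens >= target_sensitivity and (best is None or cut > best[0]):
            best = (float(cut), sens)
    return OperatingPoint(cutoff=best[0], achieved_sensitivity=best[1])


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

class CorticalWidthSVM:
    """Soft-margin RBF SVM on (mean width, width variance) features.

    Parameters
    ----------
    features : (n, p) array-like
        Feature vectors; canonically p = 2 with columns
        (mean_width_mm, var_width_mm2).
    labels : length-n array-like
        Class labels in {-1, +1} or {0, 1} (1 = low BMD).
    gamma, C : float
        RBF width (2*gamma^2 denominator convention) and box constraint.
    standardize : bool
        Z-score features on the training set before the kernel (the two
        features live on different scales, mm vs mm^2). The transform is
        stored with the model and applied to any prediction input.
    """

    def __init__(self, features, labels, gamma: float = 1.0, C: float = 1.0,
                 standardize: bool = True):
        X = np.atleast_2d(np.asarray(features, dtype=float))
        y = _coerce_labels(labels)
        if X.shape[0] != y.shape[0]:
            raise ParameterError("features and labels differ in length")
        if not np.isfinite(X).all():
            raise ParameterError("features must be finite")
        if gamma <= 0 or C <= 0:
            raise ParameterError("gamma and C must be positive")
        if X.shape[0] < 2 or not ((y == 1).any() and (y == -1).any()):
            raise DegenerateTrainingError(
                "training requires >= 2 samples with both classes present")
        self.X = X
        self.y = y
        self.gamma = float(gamma)
        self.C = float(C)
        self.standardize = bool(standardize)

    @classmethod
    def from_dataframe(cls, df, feature_cols=("mean_width_mm", "var_width_mm2"),
                       label_col: str = "label", **kwargs) -> "CorticalWidthSVM":
        missing = [c for c in (*feature_cols, label_col) if c not in df.columns]
        if missing:
            raise ParameterError(f"missing columns: {missing}")
        return cls(df.loc[:, list(feature_cols)].to_numpy(dtype=float),
                   df[label_col].to_numpy(), **kwargs)

    def fit(self, tol: float = 1e-12, maxiter: int = 1000) -> "SVMResults":
        """Solve the dual QP: maximize sum(a) - 1/2 a' (yy'*K) a
        subject to sum(a*y) = 0 and 0 <= a <= C."""
        X, y = self.X, self.y
        n = len(y)
        if self.standardize:
            mu = X.mean(axis=0)
            sd = X.std(axis=0)
            sd = np.where(sd > 0, sd, 1.0)
        else:
            mu = np.zeros(X.shape[1])
            sd = np.ones(X.shape[1])
        Z = (X - mu) / sd
        K = _kernel_matrix(Z, Z, self.gamma)
        Q = (y[:, None] * y[None, :]) * K

        def fun(a):
            return 0.5 * a @ Q @ a - a.sum()

        def jac(a):
            return Q @ a - 1.0

        yf = y.astype(float)
        res = minimize(fun, np.zeros(n), jac=jac, method="SLSQP",
                       bounds=[(0.0, self.C)] * n,
                       constraints=[{"type": "eq", "fun": lambda a: a @ yf,
                                     "jac": lambda a: yf}],
                       options={"ftol": tol, "maxiter": maxiter})
        if not res.success and abs(res.x @ yf) > 1e-6:
            raise SolverError(
                f"dual QP failed after {res.nit} iterations: {res.message}")
        alpha = np.clip(res.x, 0.0, self.C)
        dual_objective = float(alpha.sum() - 0.5 * alpha @ Q @ alpha)

        floor = 1e-8 * self.C
        sv = alpha > floor
        margin = sv & (alpha < self.C - floor)
        f_no_b = K @ (alpha * yf)
        if margin.any():
            bias = float(np.mean(yf[margin] - f_no_b[margin]))
        else:
            # all alphas at bounds: take the midpoint of the KKT-feasible interval
            lo = -np.inf
            hi = np.inf
            for i in range(n):
                g = yf[i] - f_no_b[i]
                at_zero = alpha[i] <= floor
                at_c = alpha[i] >= self.C - floor
                if (y[i] == 1 and at_zero) or (y[i] == -1 and at_c):
                    hi = min(hi, g)   # y_i*(f+b) >= 1 puts an upper bound on b
                if (y[i] == -1 and at_zero) or (y[i] == 1 and at_c):
                    lo = max(lo, g)
            if np.isfinite(lo) and np.isfinite(hi):
                bias = float((lo + hi) / 2.0)
            else:
                bias = float(lo) if np.isfinite(lo) else float(hi)

        return SVMResults(model=self, alpha=alpha, bias=bias,
                          support_mask=sv, feature_mean=mu, feature_scale=sd,
                          dual_objective=dual_objective, n_iter=int(res.nit),
                          converged=bool(res.success))


class SVMResults:
    """Fitted SVM: dual coefficients, support vectors, bias, diagnostics."""

    def __init__(self, model: CorticalWidthSVM, alpha, bias, support_mask,
                 feature_mean, feature_scale, dual_objective, n_iter, converged,
                 operating_point: OperatingPoint | None = None):
        self.model = model
        self.alpha = np.asarray(alpha, dtype=float)
        self.bias = float(bias)
        self.support_mask = np.asarray(support_mask, dtype=bool)
        self.feature_mean = np.asarray(feature_mean, dtype=float)
        self.feature_scale = np.asarray(feature_scale, dtype=float)
        self.dual_objective = float(dual_objective)
        self.n_iter = int(n_iter)
        self.converged = bool(converged)
        self.operating_point = operating_point

    # -- basic accessors ---------------------------------------------------
    @property
    def gamma(self) -> float:
        return self.model.gamma

    @property
    def C(self) -> float:
        return self.model.C

    @property
    def support_vectors_(self) -> np.ndarray:
        return self.model.X[self.support_mask]

    @property
    def support_alphas_(self) -> np.ndarray:
        return self.alpha[self.support_mask]

    @property
    def support_labels_(self) -> np.ndarray:
        return self.model.y[self.support_mask]

    @property
    def n_support_(self) -> int:
        return int(self.support_mask.sum())

    # -- prediction --------------------------------------------------------
    def _standardized(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return (X - self.feature_mean) / self.feature_scale

    def decision_score(self, X) -> np.ndarray:
        """f(x) = sum_i alpha_i y_i K(x, x_i) + b (the pre-sign score)."""
        Z = self._standardized(X)
        Zsv = self._standardized(self.support_vectors_)
        K = _kernel_matrix(Z, Zsv, self.gamma)
        return K @ (self.support_alphas_ * self.support_labels_) + self.bias

    def predict(self, X, cutoff: float | None = None) -> np.ndarray:
        """Labels in {-1, +1}; positive when score >= cutoff (default: the
        stored operating point, else 0; score exactly at the cutoff screens
        positive)."""
        if cutoff is None:
            cutoff = self.operating_point.cutoff if self.operating_point else 0.0
        return np.where(self.decision_score(X) >= cutoff, 1, -1)

    def set_operating_point(self, target_sensitivity: float = 0.90) -> OperatingPoint:
        """Choose the score cutoff at the target sensitivity on training scores."""
        scores = self.decision_score(self.model.X)
        op = choose_cutoff(scores, self.model.y, target_sensitivity)
        self.operating_point = op
        return op

    def evaluate(self, X, labels, cutoff: float | None = None) -> Metrics:
        return evaluate(self.predict(X, cutoff=cutoff), labels)

    def evaluate_at_sensitivity(self, X, labels,
                                target_sensitivity: float = 0.90
                                ) -> tuple[Metrics, OperatingPoint]:
        """Specificity-at-target-sensitivity evaluation.

        The cutoff is pinned on the scores of the cohort being evaluated so
        that its sensitivity reaches the target (the screening-literature
        "specificity at ~90% sensitivity" protocol). Because the cutoff is
        chosen on the same data it is scored on, the resulting sensitivity is
        at-target by construction; use :meth:`set_operating_point` plus
        :meth:`evaluate` for a prospective assessment instead.
        """
        scores = self.decision_score(X)
        op = choose_cutoff(scores, labels, target_sensitivity)
        m = evaluate(np.where(scores >= op.cutoff, 1, -1), labels)
        return m, op

    # -- reporting ---------------------------------------------------------
    def summary(self) -> str:
        n = len(self.model.y)
        n_pos = int(np.sum(self.model.y == 1))
        lines = [
            "RBF-SVM low-BMD screening model",
            "=" * 47,
            f"{'n training samples':<28}{n:>8}",
            f"{'  low BMD (+1) / normal (-1)':<28}{n_pos:>4} /{n - n_pos:>4}",
            f"{'gamma (2*gamma^2 kernel)':<28}{self.gamma:>8.3f}",
            f"{'C (box constraint)':<28}{self.C:>8.3f}",
            f"{'support vectors':<28}{self.n_support_:>8}",
            f"{'bias b':<28}{self.bias:>8.4f}",
            f"{'dual objective':<28}{self.dual_objective:>8.4f}",
            f"{'solver iterations':<28}{self.n_iter:>8}",
            f"{'converged':<28}{str(self.converged):>8}",
        ]
        if self.operating_point is not None:
            lines.append(f"{'score cutoff':<28}{self.operating_point.cutoff:>8.4f}")
            lines.append(f"{'train sensitivity at cutoff':<28}"
                         f"{self.operating_point.achieved_sensitivity:>8.3f}")
        return "\n".join(lines)

    # -- serialization -----------------------------------------------------
    def save(self, path) -> None:
        """Serialize the fitted model as a documented JSON file."""
        payload = {
            "format": "cortiscan-svm-model",
            "version": 1,
            "gamma": self.gamma,
            "C": self.C,
            "bias": self.bias,
            "support_vectors": self.support_vectors_.tolist(),
            "alphas": self.support_alphas_.tolist(),
            "labels": self.support_labels_.tolist(),
            "feature_mean": self.feature_mean.tolist(),
            "feature_scale": self.feature_scale.tolist(),
            "dual_objective": self.dual_objective,
            "cutoff": None if self.operating_point is None
                      else self.operating_point.cutoff,
            "target_sensitivity_achieved": None if self.operating_point is None
                      else self.operating_point.achieved_sensitivity,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @staticmethod
    def load(path) -> "SVMResults":
        with open(path) as fh:
            d = json.load(fh)
        if d.get("format") != "cortiscan-svm-model":
            raise ParameterError(f"{path} is not a cortiscan SVM model file")
        sv = np.asarray(d["support_vectors"], dtype=float)
        alphas = np.asarray(d["alphas"], dtype=float)
        labels = np.asarray(d["labels"], dtype=int)
        model = CorticalWidthSVM.__new__(CorticalWidthSVM)
        model.X = sv
        model.y = labels
        model.gamma = float(d["gamma"])
        model.C = float(d["C"])
        model.standardize = True
        op = None
        if d.get("cutoff") is not None:
            op = OperatingPoint(cutoff=float(d["cutoff"]),
                                achieved_sensitivity=float(
                                    d.get("target_sensitivity_achieved") or np.nan))
        return SVMResults(model=model, alpha=alphas, bias=d["bias"],
                          support_mask=np.ones(len(alphas), dtype=bool),
                          feature_mean=d["feature_mean"],
                          feature_scale=d["feature_scale"],
                          dual_objective=d["dual_objective"], n_iter=0,
                          converged=True, operating_point=op)


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def train_svm(features, labels, C: float = 1.0, gamma: float = 1.0,
              standardize: bool = True) -> SVMResults:
    """Fit the dual soft-margin RBF SVM (functional form of the model API)."""
    return CorticalWidthSVM(features, labels, gamma=gamma, C=C,
                            standardize=standardize).fit()


def decision_score(results: SVMResults, x) -> np.ndarray:
    """Decision score(s) of ``x`` under a fitted model."""
    return results.decision_score(x)
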