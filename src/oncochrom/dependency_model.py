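"""Concentration-dependency model linking pre-existing H3K27me3 (x) and
oncohistone occupancy (y) to the resulting mutant H3K27me3 (z).

The model is a degree-7 polynomial in the difference d = x - y:

    Z = A0 + A1 * sum_{n=1..7} A_{n+1} * d**n

Only the products B_n = A1 * A_{n+1} are identifiable, so fitting is ordinary
least squares on the reduced form Z = B0 + sum_n B_n * d**n; the result is
mapped back into the A slots with A1 := 1. The published coefficient set is
packaged and available as :data:`REFERENCE_MODEL`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .errors import FitError, ValidationError

DEGREE = 7
N_COEFFS = DEGREE + 2  # A0 intercept, A1 global scale, A2..A8 power weights


@dataclass(frozen=True)
class DependencyModel:
    """Coefficients A0..A8 of the dependency polynomial."""

    coefficients: tuple[float, ...]

    def __post_init__(self):
        if len(self.coefficients) != N_COEFFS:
            raise ValidationError(
                f"expected {N_COEFFS} coefficients A0..A8, got {len(self.coefficients)}"
            )
        if not np.all(np.isfinite(self.coefficients)):
            raise ValidationError("non-finite model coefficients")
        object.__setattr__(self, "coefficients", tuple(float(c) for c in self.coefficients))

    @property
    def a0(self) -> float:
        return self.coefficients[0]

    @property
    def a1(self) -> float:
        return self.coefficients[1]

    def reduced_form(self) -> np.ndarray:
        """B0..B7 with B0 = A0 and B_n = A1 * A_{n+1} for n = 1..7."""
        a = np.asarray(self.coefficients)
        return np.concatenate([[a[0]], a[1] * a[2:]])

    def evaluate(self, x, y):
        return evaluate(self, x, y)

    def to_dict(self) -> dict[str, float]:
        return {f"A{i}": c for i, c in enumerate(self.coefficients)}

    @classmethod
    def from_dict(cls, d: dict) -> "DependencyModel":
        return cls(tuple(float(d[f"A{i}"]) for i in range(N_COEFFS)))

    @classmethod
    def from_json(cls, path) -> "DependencyModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)
            fh.write("\n")


def load_reference_model() -> DependencyModel:
    """The packaged published coefficient set (A0 = -0.709110206, ...)."""
    text = resources.files("oncochrom.data").joinpath("table1.json").read_text()
    return DependencyModel.from_dict(json.loads(text))


REFERENCE_MODEL = load_reference_model()


def evaluate(model: DependencyModel, x, y):
    """Vectorized Z = A0 + A1 * sum_{n=1..7} A_{n+1} (x - y)^n.

    At x == y every power term vanishes, so the result is exactly A0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValidationError("evaluate requires finite x and y")
    d = x - y
    a = model.coefficients
    acc = np.zeros_like(d)
    power = np.ones_like(d)
    for n in range(1, DEGREE + 1):
        power = power * d
        acc = acc + a[n + 1] * power
    out = a[0] + a[1] * acc
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class FitResult:
    model: DependencyModel  # reduced form mapped back with A1 = 1
    r_squared: float  # 1 - SSE/TSS of the fit
    sse: float
    n_bins: int

    @property
    def reduced_coefficients(self) -> np.ndarray:
        return self.model.reduced_form()


def fit(x, y, z, degree: int = DEGREE) -> FitResult:
    """Least-squares fit of the reduced-form polynomial in d = x - y.

    The design is built on internally rescaled d (numpy's windowed polynomial
    fit) to keep the degree-7 Vandermonde well conditioned; coefficients are
    converted back to plain powers of d.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    z = np.asarray(z, dtype=float).ravel()
    if not (x.size == y.size == z.size):
        raise ValidationError("x, y, z must have equal length")
    if x.size < N_COEFFS:
        raise ValidationError(f"need at least {N_COEFFS} points, got {x.size}")
    if not all(np.all(np.isfinite(v)) for v in (x, y, z)):
        raise ValidationError("fit requires finite inputs")
    if not 1 <= degree <= DEGREE:
        raise ValidationError(f"degree must be in 1..{DEGREE}, got {degree}")
    d = x - y
    if np.unique(d).size < degree + 1:
        raise FitError(
            f"design is rank-deficient: only {np.unique(d).size} distinct d = x - y "
            f"values for a degree-{degree} polynomial"
        )
    poly = np.polynomial.Polynomial.fit(d, z, deg=degree)
    b = poly.convert().coef
    b = np.pad(b, (0, DEGREE + 1 - b.size))
    fitted = poly(d)
    sse = float(np.sum((fitted - z) ** 2))
    tss = float(np.sum((z - z.mean()) ** 2))
    r2 = 1.0 if tss == 0.0 else 1.0 - sse / tss
    r2 = float(min(max(r2, 0.0), 1.0))
    a = np.concatenate([[b[0]], [1.0], b[1:]])
    return FitResult(DependencyModel(tuple(a)), r2, sse, int(x.size))


@dataclass(frozen=True)
class GoodnessOfFit:
    r_squared: float  # squared Pearson correlation of model vs observed
    r_squared_regression: float  # 1 - SSE/TSS variant
    sse: float
    n_bins: int
    defined: bool = True  # False when a zero-variance side makes r undefined


def goodness_of_fit(model: DependencyModel, x, y, z) -> GoodnessOfFit:
    """SSE = sum_i (Z_i - z_i)^2 and the squared Pearson correlation between
    model predictions Z and observations z (with the regression variant
    1 - SSE/TSS also reported; the two coincide for an OLS fit with intercept
    but diverge under cross-dataset application)."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    z = np.asarray(z, dtype=float).ravel()
    if not (x.size == y.size == z.size):
        raise ValidationError("x, y, z must have equal length")
    if not all(np.all(np.isfinite(v)) for v in (x, y, z)):
        raise ValidationError("goodness_of_fit requires finite inputs")
    pred = np.asarray(evaluate(model, x, y))
    resid = pred - z
    sse = float(np.sum(resid**2))
    tss = float(np.sum((z - z.mean()) ** 2))
    r2_reg = float("nan") if tss == 0 else 1.0 - sse / tss
    if np.std(pred) == 0 or np.std(z) == 0:
        if sse == 0.0:
            # identical constant vectors: a perfect, if degenerate, fit
            return GoodnessOfFit(1.0, 1.0, 0.0, int(z.size), defined=False)
        return GoodnessOfFit(float("nan"), r2_reg, sse, int(z.size), defined=False)
    r = float(np.corrcoef(pred, z)[0, 1])
    return GoodnessOfFit(r * r, r2_reg, sse, int(z.size))
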