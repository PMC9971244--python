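"""Bivariate polynomial IC50 model on the (D, zeta) descriptor plane.

The anti-tyrosinase potency of a flavonoid with molecular graph G is modelled
as a cubic polynomial in its external activity D = D(G) and internal activity
z = zeta(G), with the D**3 term omitted:

    ic50(D, z) = a1 + a2*D + a3*z + a4*D**2 + a5*D*z + a6*z**2
                 + a7*D**2*z + a8*D*z**2 + a9*z**3

Nine coefficients, nine training compounds: fitting is exact interpolation.
The design matrix mixes columns of order 1 down to 1e-5 and its condition
number is ~1e9, so the square solve is done in exact rational arithmetic and
only converted to floats at the end; double-precision elimination alone can
lose several significant figures of the coefficients.

Two coefficient provenances ship with the package:

``refit``
    the exact interpolant of the bundled nine-compound training table,
    the set that actually regenerates the bundled 26-compound screening
    ranking (use this one);
``printed``
    the same coefficients rounded to 4 significant figures, as quoted in the
    reference source.  The rounding is lossy enough to shift predictions by
    hundreds of micromolar near the training region — kept for transparency,
    not for prediction.

The API follows the statsmodels convention: a model object built from data
whose :meth:`Ic50PolynomialModel.fit` returns a results object carrying
coefficients, diagnostics and prediction/ranking methods.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from fractions import Fraction
from numbers import Rational
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "FEATURE_NAMES",
    "PRINTED_COEFFICIENTS",
    "feature_vector",
    "Ic50PolynomialModel",
    "Ic50PolynomialResults",
    "FitDiagnostics",
    "CompoundRecord",
    "printed_results",
    "goodness_of_fit",
    "rank_compounds",
    "ModelError",
    "SingularFitError",
    "UnderdeterminedError",
    "UndefinedRSquaredError",
]

logger = logging.getLogger(__name__)

#: Fixed feature order paired with coefficients a1..a9.
FEATURE_NAMES = ("1", "D", "z", "D^2", "D*z", "z^2", "D^2*z", "D*z^2", "z^3")

#: 4-significant-figure coefficients as quoted in the reference source.
PRINTED_COEFFICIENTS = (
    4.571e5,
    -9.612e7,
    1.027e6,
    1.197e9,
    8.704e8,
    -4.565e7,
    -7.457e9,
    -1.715e9,
    1.363e8,
)


class ModelError(ValueError):
    """Base class for model-layer errors."""


class SingularFitError(ModelError):
    """Design matrix is rank deficient (e.g. duplicated (D, zeta) rows)."""


class UnderdeterminedError(ModelError):
    """Fewer training records than coefficients."""


class UndefinedRSquaredError(ModelError):
    """All observed responses equal: total sum of squares is zero."""


def feature_vector(D, zeta):
    """The 9 polynomial features ``[1, D, z, D^2, Dz, z^2, D^2 z, D z^2, z^3]``.

    Exact inputs (int/Fraction) give exact outputs; floats give floats.
    """
    for x in (D, zeta):
        if not isinstance(x, Rational) and not math.isfinite(float(x)):
            raise ModelError(f"non-finite descriptor value {x!r}")
    one = D - D + 1  # 1 in the arithmetic of the inputs
    return [
        one,
        D,
        zeta,
        D * D,
        D * zeta,
        zeta * zeta,
        D * D * zeta,
        D * zeta * zeta,
        zeta * zeta * zeta,
    ]


def _as_fraction(x) -> Fraction:
    """Exact rational view of an input value.

    Strings and Decimals convert exactly.  A float is re-read through its
    shortest decimal representation (``repr``), which recovers the printed
    decimal for table-derived values instead of the binary approximation.
    """
    if isinstance(x, Rational):
        return Fraction(x)
    if isinstance(x, (float, np.floating)):
        return Fraction(repr(float(x)))
    return Fraction(str(x))


@dataclass(frozen=True)
class FitDiagnostics:
    """Residual diagnostics of a fitted (or frozen) coefficient set."""

    sse: float
    r_squared: float
    residuals: np.ndarray

    def __post_init__(self):  # noqa: D105
        object.__setattr__(self, "residuals", np.asarray(self.residuals, float))


@dataclass
class CompoundRecord:
    """One compound in a training or screening table."""

    name: str
    D: float
    zeta: float
    ic50_observed: float | None = None
    ic50_predicted: float | None = None
    rank: int | None = None


class Ic50PolynomialModel:
    """Polynomial IC50 model bound to a training table.

    Parameters
    ----------
    D, zeta:
        Descriptor columns (any mix of float / Fraction / decimal string).
    ic50:
        Observed IC50 values in micromolar.
    names:
        Optional compound labels (used in error messages and summaries).
    """

    def __init__(
        self,
        D: Sequence,
        zeta: Sequence,
        ic50: Sequence,
        names: Sequence[str] | None = None,
    ):
        if not (len(D) == len(zeta) == len(ic50)):
            raise ModelError("D, zeta and ic50 must have equal length")
        self.D = list(D)
        self.zeta = list(zeta)
        self.ic50 = list(ic50)
        self.names = list(names) if names is not None else [
            f"compound-{i}" for i in range(len(D))
        ]
        self.nobs = len(D)

    @classmethod
    def from_dataframe(cls, df) -> "Ic50PolynomialModel":
        """Build from a DataFrame with columns ``name, D, zeta, ic50``."""
        missing = {"name", "D", "zeta", "ic50"} - set(df.columns)
        if missing:
            raise ModelError(f"training table misses columns {sorted(missing)}")
        return cls(
            list(df["D"]), list(df["zeta"]), list(df["ic50"]), list(df["name"])
        )

    @classmethod
    def from_records(cls, records: Iterable[CompoundRecord]) -> "Ic50PolynomialModel":
        recs = [r for r in records if r.ic50_observed is not None]
        return cls(
            [r.D for r in recs],
            [r.zeta for r in recs],
            [r.ic50_observed for r in recs],
            [r.name for r in recs],
        )

    # -----------------------------------------------------------------

    def _duplicate_rows(self) -> list[tuple[str, str]]:
        seen: dict[tuple, str] = {}
        dups = []
        for name, d, z in zip(self.names, self.D, self.zeta):
            key = (_as_fraction(d), _as_fraction(z))
            if key in seen:
                dups.append((seen[key], name))
            else:
                seen[key] = name
        return dups

    def fit(self) -> "Ic50PolynomialResults":
        """Solve for the nine coefficients.

        Exactly nine records: exact rational solve of the square system
        (interpolation).  More than nine: double-precision least squares.
        Fewer: error.
        """
        if self.nobs < 9:
            raise UnderdeterminedError(
                f"need at least 9 training records, got {self.nobs}"
            )
        if self.nobs == 9:
            params_exact = self._solve_exact()
            params = np.array([float(a) for a in params_exact])
            provenance = "refit"
        else:
            X = np.array(
                [
                    [float(f) for f in feature_vector(float(d), float(z))]
                    for d, z in zip(self.D, self.zeta)
                ]
            )
            y = np.array([float(v) for v in self.ic50])
            params, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
            if rank < 9:
                raise SingularFitError(
                    f"design matrix has rank {rank} < 9; "
                    f"duplicated rows: {self._duplicate_rows()}"
                )
            params_exact = None
            provenance = "refit"
        diagnostics = goodness_of_fit_arrays(
            params, self.D, self.zeta, self.ic50
        )
        return Ic50PolynomialResults(
            params=params,
            params_exact=params_exact,
            provenance=provenance,
            model=self,
            diagnostics=diagnostics,
        )

    def _solve_exact(self) -> list[Fraction]:
        import sympy as sp

        rows = []
        for d, z in zip(self.D, self.zeta):
            rows.append(
                [sp.Rational(f) for f in feature_vector(_as_fraction(d), _as_fraction(z))]
            )
        A = sp.Matrix(rows)
        b = sp.Matrix([sp.Rational(_as_fraction(v)) for v in self.ic50])
        if A.rank() < 9:
            raise SingularFitError(
                "9x9 design matrix is singular; duplicated (D, zeta) rows: "
                f"{self._duplicate_rows()}"
            )
        sol = A.LUsolve(b)
        return [Fraction(int(x.p), int(x.q)) for x in sol]


class Ic50PolynomialResults:
    """Fitted (or frozen) coefficient set with diagnostics.

    Attributes
    ----------
    params:
        ``numpy`` array of the nine coefficients a1..a9 (feature order
        :data:`FEATURE_NAMES`).
    params_exact:
        The exact rational coefficients when the fit was an exact square
        solve, else ``None``.
    provenance:
        ``"refit"``, ``"printed"`` or ``"custom"``.
    """

    def __init__(
        self,
        params: np.ndarray,
        provenance: str = "custom",
        params_exact: list[Fraction] | None = None,
        model: Ic50PolynomialModel | None = None,
        diagnostics: FitDiagnostics | None = None,
    ):
        params = np.asarray(params, dtype=float)
        if params.shape != (9,):
            raise ModelError("expected exactly 9 coefficients")
        self.params = params
        self.params_exact = params_exact
        self.provenance = provenance
        self.model = model
        self.diagnostics = diagnostics

    # -- diagnostics passthrough --------------------------------------

    @property
    def sse(self) -> float:
        return self.diagnostics.sse if self.diagnostics else float("nan")

    @property
    def rsquared(self) -> float:
        return self.diagnostics.r_squared if self.diagnostics else float("nan")

    @property
    def resid(self) -> np.ndarray:
        if self.diagnostics is None:
            return np.array([])
        return self.diagnostics.residuals

    # -- prediction ----------------------------------------------------

    def predict(self, D, zeta):
        """Predicted IC50 (micromolar) at one or many (D, zeta) points.

        Predictions can be negative: the polynomial extrapolates freely
        outside the training region and the reference ranking interprets
        relative magnitudes only.  Negative values are reported as-is with a
        logged applicability-domain warning, never clipped.
        """
        D_arr = np.atleast_1d(np.asarray(D, dtype=float))
        z_arr = np.atleast_1d(np.asarray(zeta, dtype=float))
        if not (np.isfinite(D_arr).all() and np.isfinite(z_arr).all()):
            raise ModelError("non-finite descriptor values")
        X = np.column_stack(
            [np.asarray([float(f) for f in feature_vector(d, z)]) for d, z in zip(D_arr, z_arr)]
        ).T
        pred = X @ self.params
        if (pred < 0).any():
            logger.warning(
                "%d prediction(s) are negative: outside the applicability domain",
                int((pred < 0).sum()),
            )
        if np.isscalar(D) and np.isscalar(zeta):
            return float(pred[0])
        return pred

    # -- presentation --------------------------------------------------

    def summary(self) -> str:
        lines = [
            "IC50 polynomial model (cubic in D and zeta, D^3 term omitted)",
            f"provenance: {self.provenance}    nobs: "
            f"{self.model.nobs if self.model else 'n/a'}",
            "-" * 46,
            f"{'term':>8s} {'coefficient':>18s}",
        ]
        for name, a in zip(FEATURE_NAMES, self.params):
            lines.append(f"{name:>8s} {a:>18.6e}")
        lines.append("-" * 46)
        if self.diagnostics is not None:
            lines.append(f"SSE: {self.sse:.3e}    R^2: {self.rsquared:.10f}")
        return "\n".join(lines)

    def to_json(self, path=None) -> str:
        payload = {
            "provenance": self.provenance,
            **{f"alpha{i}": float(a) for i, a in enumerate(self.params, 1)},
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, path) -> "Ic50PolynomialResults":
        with open(path) as fh:
            payload = json.load(fh)
        params = [payload[f"alpha{i}"] for i in range(1, 10)]
        return cls(np.array(params), provenance=payload.get("provenance", "custom"))


def printed_results() -> Ic50PolynomialResults:
    """The 4-significant-figure quoted coefficient set (provenance "printed")."""
    return Ic50PolynomialResults(
        np.array(PRINTED_COEFFICIENTS), provenance="printed"
    )


def goodness_of_fit_arrays(params, D, zeta, ic50) -> FitDiagnostics:
    """SSE and R^2 of a coefficient vector against observed responses."""
    X = np.array(
        [[float(f) for f in feature_vector(float(d), float(z))] for d, z in zip(D, zeta)]
    )
    y = np.array([float(v) for v in ic50])
    resid = y - X @ np.asarray(params, float)
    sse = float(resid @ resid)
    sst = float(((y - y.mean()) ** 2).sum())
    if sst == 0.0:
        raise UndefinedRSquaredError("all observed IC50 equal; R^2 undefined")
    return FitDiagnostics(sse=sse, r_squared=1.0 - sse / sst, residuals=resid)


def goodness_of_fit(
    results: Ic50PolynomialResults, training: Iterable[CompoundRecord]
) -> FitDiagnostics:
    """Diagnostics of ``results`` on records carrying observed IC50."""
    recs = [r for r in training if r.ic50_observed is not None]
    return goodness_of_fit_arrays(
        results.params,
        [r.D for r in recs],
        [r.zeta for r in recs],
        [r.ic50_observed for r in recs],
    )


def rank_compounds(
    results: Ic50PolynomialResults, compounds: Iterable[CompoundRecord]
) -> list[CompoundRecord]:
    """Sort ascending by predicted IC50 (strongest inhibitor first).

    Ties break lexicographically by name; ranks are assigned 1..N.  Input
    records are not mutated.
    """
    recs = list(compounds)
    if not recs:
        return []
    preds = results.predict([r.D for r in recs], [r.zeta for r in recs])
    ranked = sorted(
        (
            CompoundRecord(
                name=r.name,
                D=r.D,
                zeta=r.zeta,
                ic50_observed=r.ic50_observed,
                ic50_predicted=float(p),
            )
            for r, p in zip(recs, preds)
        ),
        key=lambda r: (r.ic50_predicted, r.name),
    )
    for i, r in enumerate(ranked, 1):
        r.rank = i
    return ranked
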