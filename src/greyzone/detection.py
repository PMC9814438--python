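"""Grey-zone detection: the delta criterion, its threshold, and the decision.

A grey zone — systematic rater-perception disagreement between two adjacent
ordinal levels — inflates one off-diagonal cell next to the main diagonal.
The criterion scales each symmetry-model standardized residual by the
unweighted Cohen's kappa,

    delta_ij = r_ij / kappa,          Delta = max_ij delta_ij,

so that asymmetry is judged relative to the overall level of agreement.
Because the residual matrix is antisymmetric, the signed maximum equals the
maximum absolute value.  ``Delta`` is compared with a calibrated threshold
``tau(kappa, n)``: a back-transformed polynomial regression of the
no-grey-zone Monte-Carlo reference distribution of ``Delta`` on ``kappa``
squared and the sample size.  ``Delta > tau`` declares a grey zone at the
argmax cell; other cells whose delta also exceeds tau are reported as
secondary grey zones.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .coefficients import cohen_kappa, make_weights
from .exceptions import AgreementTooLowError, ThresholdDomainError
from .symmetry import symmetry_fit
from .tables import AgreementTable

__all__ = [
    "DeltaMatrix",
    "ThresholdModel",
    "GreyZoneReport",
    "DEFAULT_THRESHOLD_MODEL",
    "CHAIN_THRESHOLD_MODEL",
    "delta_matrix",
    "delta_statistic",
    "threshold",
    "detect_grey_zones",
]


@dataclass(frozen=True)
class DeltaMatrix:
    """Residual-over-kappa matrix ``delta_ij = r_ij / kappa``."""

    delta: np.ndarray
    kappa: float
    residuals: np.ndarray

    @property
    def R(self) -> int:
        return self.delta.shape[0]


@dataclass(frozen=True)
class ThresholdModel:
    """The threshold function ``tau(kappa, n)``.

    The model is a least-squares fit of the Box-Cox transformed reference
    ``Delta`` on ``(1, kappa^2, n, n^2)``; ``tau`` is its back-transform
    ``(pred * lambda + 1) ** (1/lambda)``.  When ``inner`` is set, tau is
    evaluated directly from those published back-transformed polynomial
    constants and ``exponent`` (the package default); otherwise the exact
    Box-Cox chain from ``beta`` and ``lambda_`` is used.
    """

    lambda_: float
    beta: tuple[float, float, float, float]
    inner: tuple[float, float, float, float] | None = None
    exponent: float | None = None
    source: str = "refit"
    valid_n_range: tuple[float, float] = (50.0, 1000.0)
    valid_kappa_range: tuple[float, float] = (0.2, 0.85)
    adj_r2: float | None = None
    pvalues: tuple[float, ...] | None = None

    def base(self, kappa: float, n: float) -> float:
        """The quantity raised to the back-transform power."""
        if self.inner is not None:
            a0, a1, a2, a3 = self.inner
            return a0 + a1 * kappa**2 + a2 * n + a3 * n**2
        b0, b1, b2, b3 = self.beta
        pred = b0 + b1 * kappa**2 + b2 * n + b3 * n**2
        return pred * self.lambda_ + 1.0

    def tau(self, kappa: float, n: float) -> float:
        base = self.base(kappa, n)
        if base <= 0:
            raise ThresholdDomainError(
                f"threshold undefined at kappa={kappa}, n={n}: back-transform "
                f"base {base:.6g} <= 0 (outside the calibration envelope "
                f"kappa in {self.valid_kappa_range}, n in {self.valid_n_range})"
            )
        expo = self.exponent if self.inner is not None else 1.0 / self.lambda_
        return float(base**expo)

    def to_dict(self) -> dict:
        return {
            "lambda": self.lambda_,
            "beta": list(self.beta),
            "inner": list(self.inner) if self.inner is not None else None,
            "exponent": self.exponent,
            "source": self.source,
            "valid_n_range": list(self.valid_n_range),
            "valid_kappa_range": list(self.valid_kappa_range),
            "adj_r2": self.adj_r2,
            "pvalues": list(self.pvalues) if self.pvalues is not None else None,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_dict(cls, d: dict) -> "ThresholdModel":
        return cls(
            lambda_=d["lambda"],
            beta=tuple(d["beta"]),
            inner=tuple(d["inner"]) if d.get("inner") is not None else None,
            exponent=d.get("exponent"),
            source=d.get("source", "loaded"),
            valid_n_range=tuple(d.get("valid_n_range", (50.0, 1000.0))),
            valid_kappa_range=tuple(d.get("valid_kappa_range", (0.2, 0.85))),
            adj_r2=d.get("adj_r2"),
            pvalues=tuple(d["pvalues"]) if d.get("pvalues") else None,
        )

    @classmethod
    def load(cls, path: str | Path) -> "ThresholdModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


#: Published rounded back-transform constants (the default: every worked
#: threshold value in the reference analyses uses these).
DEFAULT_THRESHOLD_MODEL = ThresholdModel(
    lambda_=-1.59596,
    beta=(0.6319, -0.2563, -2.087e-5, 1.546e-8),
    inner=(-0.0080, 0.4090, 3.331e-5, -2.467e-8),
    exponent=-0.6266,
    source="printed-constants",
)

#: The same regression evaluated through the exact Box-Cox chain instead of
#: the rounded constants; agrees with the default to ~0.01 on the envelope.
CHAIN_THRESHOLD_MODEL = ThresholdModel(
    lambda_=-1.59596,
    beta=(0.6319, -0.2563, -2.087e-5, 1.546e-8),
    source="boxcox-chain",
)


def delta_matrix(table: AgreementTable) -> DeltaMatrix:
    """Compute ``delta_ij = r_ij / kappa`` for a table.

    Raises
    ------
    AgreementTooLowError
        If the unweighted kappa is <= 0; the criterion is meaningless when
        agreement does not exceed chance.
    """
    kappa = cohen_kappa(table, make_weights("identity", table.R)).value
    if kappa <= 0:
        raise AgreementTooLowError(
            f"kappa = {kappa:.4f} <= 0: agreement too low for grey-zone analysis"
        )
    if kappa < 0.2:
        warnings.warn(
            f"kappa = {kappa:.3f} is below the calibration envelope (~0.2); "
            "grey zones are not expected to be distinguishable from "
            "disagreement at this agreement level and the threshold is "
            "uncalibrated here",
            stacklevel=2,
        )
    fit = symmetry_fit(table)
    return DeltaMatrix(delta=fit.residuals / kappa, kappa=kappa, residuals=fit.residuals)


def delta_statistic(dm: DeltaMatrix) -> tuple[float, list[tuple[int, int]]]:
    """The criterion ``Delta = max(delta_ij)`` and its 1-based argmax cells.

    Ties are all returned in row-major order.  For an exactly symmetric
    table (all-zero delta) every off-diagonal cell attains the maximum.
    """
    off = ~np.eye(dm.R, dtype=bool)
    values = np.where(off, dm.delta, -np.inf)
    delta_max = float(values.max())
    cells = [
        (i + 1, j + 1)
        for i in range(dm.R)
        for j in range(dm.R)
        if i != j and values[i, j] == delta_max
    ]
    return delta_max, cells


def threshold(
    kappa: float, n: float, model: ThresholdModel = DEFAULT_THRESHOLD_MODEL
) -> float:
    """Evaluate the grey-zone threshold ``tau(kappa, n)``.

    Warns (without failing) when ``n`` or ``kappa`` falls outside the
    calibration envelope; raises :class:`ThresholdDomainError` when the
    back-transform base is non-positive.
    """
    n_lo, n_hi = model.valid_n_range
    k_lo, k_hi = model.valid_kappa_range
    if not (n_lo <= n <= n_hi):
        warnings.warn(
            f"n = {n} is outside the threshold calibration range "
            f"[{n_lo:g}, {n_hi:g}]; interpret tau cautiously",
            stacklevel=2,
        )
    if not (k_lo <= kappa <= k_hi):
        warnings.warn(
            f"kappa = {kappa:.3f} is outside the threshold calibration range "
            f"[{k_lo:g}, {k_hi:g}]; interpret tau cautiously",
            stacklevel=2,
        )
    return model.tau(kappa, n)


@dataclass(frozen=True)
class GreyZoneReport:
    """Full outcome of a grey-zone analysis of one agreement table."""

    Delta: float
    tau: float
    detected: bool
    primary_cell: tuple[int, int] | None
    argmax_cells: list[tuple[int, int]]
    secondary_cells: list[tuple[int, int]]
    direction: str
    delta: np.ndarray
    residuals: np.ndarray
    kappa: float
    n: int
    model_source: str

    def to_dict(self) -> dict:
        return {
            "Delta": self.Delta,
            "tau": self.tau,
            "detected": self.detected,
            "primary_cell": list(self.primary_cell) if self.primary_cell else None,
            "argmax_cells": [list(c) for c in self.argmax_cells],
            "secondary_cells": [list(c) for c in self.secondary_cells],
            "direction": self.direction,
            "delta_matrix": self.delta.round(6).tolist(),
            "residuals": self.residuals.round(6).tolist(),
            "kappa": self.kappa,
            "n": self.n,
            "threshold_model": self.model_source,
        }


def _cell_direction(table: AgreementTable, cell: tuple[int, int]) -> str:
    i, j = cell
    lo, hi = table.level_name(min(i, j)), table.level_name(max(i, j))
    who = "Rater I" if i > j else "Rater II"
    return (
        f"grey zone between levels {lo} and {hi} at cell ({i}, {j}): "
        f"{who} tends to rate higher"
    )


def detect_grey_zones(
    table: AgreementTable, model: ThresholdModel = DEFAULT_THRESHOLD_MODEL
) -> GreyZoneReport:
    """Run the full detection pipeline on one agreement table.

    A grey zone is declared iff ``Delta > tau(kappa, n)``.  When the decision
    is positive, the argmax cell is the primary grey zone and every other
    off-diagonal cell with ``delta_ij > tau`` is reported as a secondary
    grey zone; secondary cells are only searched for after a positive
    primary decision.
    """
    dm = delta_matrix(table)
    delta_max, argmax_cells = delta_statistic(dm)
    tau = threshold(dm.kappa, table.n, model)
    detected = delta_max > tau
    primary = argmax_cells[0] if detected else None
    secondary: list[tuple[int, int]] = []
    if detected:
        secondary = [
            (i + 1, j + 1)
            for i in range(dm.R)
            for j in range(dm.R)
            if i != j
            and (i + 1, j + 1) not in argmax_cells
            and dm.delta[i, j] > tau
        ]
    if detected:
        lines = [_cell_direction(table, c) for c in argmax_cells + secondary]
        direction = "; ".join(lines)
    elif delta_max == 0.0:
        direction = "no asymmetry: the table is exactly symmetric"
    else:
        direction = "no grey zone detected"
    return GreyZoneReport(
        Delta=delta_max,
        tau=tau,
        detected=detected,
        primary_cell=primary,
        argmax_cells=argmax_cells,
        secondary_cells=secondary,
        direction=direction,
        delta=dm.delta,
        residuals=dm.residuals,
        kappa=dm.kappa,
        n=table.n,
        model_source=model.source,
    )
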