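"""Weighted agreement coefficients.

All coefficients share the chance-corrected form ``(P_o - P_e) / (1 - P_e)``
with observed agreement ``P_o = sum_ij w_ij p_ij``; they differ only in the
chance term ``P_e``:

* Cohen's kappa uses the product of the observed margins,
  ``P_e = sum_ij w_ij p_i. p_.j``.
* Gwet's AC2 uses ``P_e = [T_w / (R(R-1))] * sum_k pi_k (1 - pi_k)`` with
  ``pi_k = (p_k. + p_.k)/2`` and ``T_w = sum_ij w_ij``.
* Brennan-Prediger's S uses the uniform chance term ``P_e = T_w / R^2``.

Weights are identity (``w_ij = 1`` iff ``i = j``, the classical unweighted
case), linear (``1 - |i-j|/(R-1)``), or quadratic (``1 - (i-j)^2/(R-1)^2``),
indexed by 1..R ordinal positions regardless of the level labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import TableValidationError, UndefinedCoefficientError
from .tables import AgreementTable

__all__ = [
    "WeightScheme",
    "CoefficientResult",
    "make_weights",
    "observed_agreement",
    "cohen_kappa",
    "gwet_ac2",
    "brennan_prediger_s",
    "all_coefficients",
]

SCHEMES = ("identity", "linear", "quadratic")


@dataclass(frozen=True)
class WeightScheme:
    """An R x R symmetric agreement-weight matrix with unit diagonal."""

    name: str
    w: np.ndarray

    @property
    def R(self) -> int:
        return self.w.shape[0]


@dataclass(frozen=True)
class CoefficientResult:
    """A chance-corrected agreement coefficient and its ingredients."""

    name: str
    weight_scheme: str
    value: float
    P_o: float
    P_e: float


def make_weights(scheme: str, R: int) -> WeightScheme:
    """Build the weight matrix for one of the standard schemes."""
    if R < 2:
        raise TableValidationError("weights need R >= 2")
    i = np.arange(R)[:, None]
    j = np.arange(R)[None, :]
    if scheme == "identity":
        w = (i == j).astype(float)
    elif scheme == "linear":
        w = 1.0 - np.abs(i - j) / (R - 1)
    elif scheme == "quadratic":
        w = 1.0 - (i - j) ** 2 / (R - 1) ** 2
    else:
        raise TableValidationError(
            f"unknown weight scheme {scheme!r}; expected one of {SCHEMES}"
        )
    return WeightScheme(scheme, w)


def _check_dims(table: AgreementTable, weights: WeightScheme) -> None:
    if weights.R != table.R:
        raise TableValidationError(
            f"weight matrix is {weights.R}x{weights.R} but table is "
            f"{table.R}x{table.R}"
        )


def observed_agreement(table: AgreementTable, weights: WeightScheme) -> float:
    """Weighted observed agreement ``P_o = sum_ij w_ij p_ij``."""
    _check_dims(table, weights)
    return float(np.sum(weights.w * table.p))


def _chance_corrected(name: str, weights: WeightScheme, p_o: float, p_e: float):
    if p_e >= 1.0:
        raise UndefinedCoefficientError(
            f"{name} undefined: chance agreement P_e = {p_e} leaves no room "
            "for chance correction"
        )
    return CoefficientResult(name, weights.name, (p_o - p_e) / (1.0 - p_e), p_o, p_e)


def cohen_kappa(table: AgreementTable, weights: WeightScheme) -> CoefficientResult:
    """Cohen's (weighted) kappa; identity weights give the classical kappa."""
    p_o = observed_agreement(table, weights)
    p_e = float(np.sum(weights.w * np.outer(table.row_margins, table.col_margins)))
    return _chance_corrected("cohen_kappa", weights, p_o, p_e)


def gwet_ac2(table: AgreementTable, weights: WeightScheme) -> CoefficientResult:
    """Gwet's AC2 (the weighted generalization of AC1)."""
    p_o = observed_agreement(table, weights)
    R = table.R
    pi = (table.row_margins + table.col_margins) / 2.0
    t_w = float(weights.w.sum())
    p_e = t_w / (R * (R - 1)) * float(np.sum(pi * (1.0 - pi)))
    return _chance_corrected("gwet_ac2", weights, p_o, p_e)


def brennan_prediger_s(
    table: AgreementTable, weights: WeightScheme
) -> CoefficientResult:
    """Brennan-Prediger's S with the uniform chance term ``T_w / R^2``."""
    p_o = observed_agreement(table, weights)
    p_e = float(weights.w.sum()) / table.R**2
    return _chance_corrected("brennan_prediger_s", weights, p_o, p_e)


def all_coefficients(table: AgreementTable, scheme: str) -> list[CoefficientResult]:
    """Kappa, AC2 and S under one weight scheme."""
    w = make_weights(scheme, table.R)
    return [cohen_kappa(table, w), gwet_ac2(table, w), brennan_prediger_s(table, w)]
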