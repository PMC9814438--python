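"""Maximum-likelihood fit of the symmetry model and its standardized residuals.

The symmetry model for a square table asserts ``p_ij = p_ji``; its ML
expected frequencies are ``mu_ij = (n_ij + n_ji) / 2``.  The standardized
residual of cell ``(i, j)`` is ``(n_ij - mu_ij) / sqrt(mu_ij)``, set to 0
when ``mu_ij = 0`` (i.e. when both paired cells are empty) and exactly 0 on
the diagonal.  Residuals are antisymmetric: ``r_ij = -r_ji``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tables import AgreementTable

__all__ = ["SymmetryFit", "symmetry_fit"]


@dataclass(frozen=True)
class SymmetryFit:
    """Fitted symmetry-model expectations and standardized residuals."""

    mu_hat: np.ndarray
    residuals: np.ndarray


def symmetry_fit(table: AgreementTable) -> SymmetryFit:
    """Fit the symmetry model to an agreement table.

    Returns expectations ``mu_hat`` (symmetric, summing to n) and the
    standardized residual matrix (antisymmetric, zero diagonal).
    """
    c = table.counts.astype(float)
    mu = (c + c.T) / 2.0
    r = np.zeros_like(mu)
    off = mu > 0
    r[off] = (c[off] - mu[off]) / np.sqrt(mu[off])
    np.fill_diagonal(r, 0.0)
    # enforce exact antisymmetry against floating fuzz
    r = (r - r.T) / 2.0
    return SymmetryFit(mu_hat=mu, residuals=r)
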