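"""Latent-variable table generation, grey-zone injection, and accuracy study.

Tables without a grey zone are generated by categorizing a standard
bivariate normal pair (X, Y) with correlation ``rho`` at shared strictly
increasing cutpoints: cell ``(i, j)`` receives probability
``P(c_{i-1} < X <= c_i, c_{j-1} < Y <= c_j)`` and a table of ``n`` subjects
is one multinomial draw from that grid.  Because both raters share the same
latent scale and cutpoints, the grid is exactly symmetric — the symmetry
model holds and any asymmetry in a draw is sampling noise.

A grey zone is injected by moving a fraction of the probability mass of a
diagonal donor cell into an adjacent off-diagonal cell, with the fraction
chosen by root-finding so that the plug-in kappa of the modified grid
matches a target value: the injected and clean arms of the accuracy study
then share the same level of agreement and differ only in the presence of
the grey zone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize
from scipy.stats import multivariate_normal, norm

from .detection import DEFAULT_THRESHOLD_MODEL, ThresholdModel, detect_grey_zones
from .exceptions import (
    AgreementTooLowError,
    InfeasibleInjectionError,
    TableValidationError,
    ThresholdDomainError,
)
from .tables import AgreementTable, from_counts

__all__ = [
    "LatentConfig",
    "AccuracyResult",
    "default_cutpoints",
    "cell_probs_from_latent",
    "kappa_from_probs",
    "generate_table",
    "calibrate_rho",
    "inject_grey_zone",
    "accuracy_study",
    "summarize_replicates",
    "matthews_corrcoef",
]

logger = logging.getLogger(__name__)


def default_cutpoints(R: int) -> np.ndarray:
    """Equal-marginal-probability cutpoints: normal quantiles at k/R."""
    if R < 2:
        raise TableValidationError("need R >= 2 levels")
    return norm.ppf(np.arange(1, R) / R)


@dataclass(frozen=True)
class LatentConfig:
    """Configuration of the latent bivariate-normal table generator."""

    rho: float
    R: int
    n: int
    cutpoints: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not -1.0 < self.rho < 1.0:
            raise TableValidationError(f"rho must be in (-1, 1), got {self.rho}")
        cuts = (
            default_cutpoints(self.R)
            if self.cutpoints is None
            else np.asarray(self.cutpoints, dtype=float)
        )
        if len(cuts) != self.R - 1:
            raise TableValidationError(
                f"{len(cuts)} cutpoints supplied for R = {self.R} levels"
            )
        if np.any(np.diff(cuts) <= 0):
            raise TableValidationError("cutpoints must be strictly increasing")
        object.__setattr__(self, "cutpoints", cuts)


def cell_probs_from_latent(config: LatentConfig) -> np.ndarray:
    """Exact cell probabilities of the categorized bivariate normal.

    Rectangle probabilities are assembled from the bivariate normal CDF by
    inclusion-exclusion over the (R+1)^2 grid of cut corners.
    """
    R = config.R
    edges = np.concatenate([[-np.inf], config.cutpoints, [np.inf]])
    mvn = multivariate_normal(
        mean=[0.0, 0.0], cov=[[1.0, config.rho], [config.rho, 1.0]]
    )
    F = np.zeros((R + 1, R + 1))
    for a in range(R + 1):
        for b in range(R + 1):
            x, y = edges[a], edges[b]
            if x == -np.inf or y == -np.inf:
                F[a, b] = 0.0
            elif x == np.inf and y == np.inf:
                F[a, b] = 1.0
            elif x == np.inf:
                F[a, b] = norm.cdf(y)
            elif y == np.inf:
                F[a, b] = norm.cdf(x)
            else:
                F[a, b] = mvn.cdf([x, y])
    probs = F[1:, 1:] - F[:-1, 1:] - F[1:, :-1] + F[:-1, :-1]
    probs = np.clip(probs, 0.0, None)
    return probs / probs.sum()


def kappa_from_probs(probs: np.ndarray) -> float:
    """Plug-in (population) unweighted kappa of a probability grid."""
    p = np.asarray(probs, dtype=float)
    p_o = float(np.trace(p))
    p_e = float(p.sum(axis=1) @ p.sum(axis=0))
    return (p_o - p_e) / (1.0 - p_e)


def generate_table(
    config: LatentConfig, rng: np.random.Generator
) -> AgreementTable:
    """One multinomial draw of ``n`` subjects from the latent cell grid."""
    probs = cell_probs_from_latent(config)
    counts = rng.multinomial(config.n, probs.ravel()).reshape(config.R, config.R)
    return from_counts(counts)


def calibrate_rho(
    target_kappa: float,
    R: int,
    cutpoints: np.ndarray | None = None,
    bracket: tuple[float, float] = (0.01, 0.999),
) -> float:
    """Find the latent correlation whose plug-in kappa equals a target.

    Plug-in kappa is strictly increasing in rho for fixed cutpoints, so a
    scalar root-find suffices.
    """

    def gap(rho: float) -> float:
        cfg = LatentConfig(rho=rho, R=R, n=1, cutpoints=cutpoints)
        return kappa_from_probs(cell_probs_from_latent(cfg)) - target_kappa

    lo, hi = bracket
    if gap(lo) > 0 or gap(hi) < 0:
        raise InfeasibleInjectionError(
            f"target kappa {target_kappa} not attainable for rho in {bracket}"
        )
    return float(optimize.brentq(gap, lo, hi, xtol=1e-8))


def inject_grey_zone(
    probs: np.ndarray,
    cell: tuple[int, int],
    target_kappa: float,
    tol: float = 1e-6,
    donor: tuple[int, int] | None = None,
) -> np.ndarray:
    """Move diagonal mass into an adjacent cell until kappa hits a target.

    ``cell`` is 1-based ``(i, j)`` with ``|i - j| = 1``.  Unless ``donor``
    overrides it, mass is taken from the diagonal cell of the lower of the
    two levels — ``(j, j)`` when ``j < i``, else ``(i, i)`` — so the
    inflated cell sits directly beside its diagonal source.  Moving a
    fraction ``f`` of the donor mass lowers the plug-in kappa monotonically,
    so the matching ``f`` is located by bisection.

    Raises
    ------
    InfeasibleInjectionError
        If no ``f`` in (0, 1] brings kappa within ``tol`` of the target.
    """
    p = np.asarray(probs, dtype=float).copy()
    i, j = cell
    if abs(i - j) != 1:
        raise TableValidationError(
            f"grey-zone cell must be adjacent to the diagonal, got ({i}, {j})"
        )
    if donor is None:
        d = min(i, j)
        donor = (d, d)
    di, dj = donor
    donor_mass = p[di - 1, dj - 1]
    if donor_mass <= 0:
        raise InfeasibleInjectionError(
            f"donor cell ({di}, {dj}) has no probability mass to move"
        )

    def modified(f: float) -> np.ndarray:
        q = p.copy()
        moved = f * donor_mass
        q[di - 1, dj - 1] -= moved
        q[i - 1, j - 1] += moved
        return q

    k0 = kappa_from_probs(modified(0.0))
    k1 = kappa_from_probs(modified(1.0))
    if not (k1 - tol <= target_kappa <= k0 - tol):
        raise InfeasibleInjectionError(
            f"target kappa {target_kappa:.4f} outside the attainable range "
            f"[{k1:.4f}, {k0:.4f}) for injection at cell {cell}"
        )
    f = float(
        optimize.brentq(
            lambda f: kappa_from_probs(modified(f)) - target_kappa,
            0.0,
            1.0,
            xtol=1e-12,
        )
    )
    if f <= 0:
        raise InfeasibleInjectionError(
            "injection fraction collapsed to zero; the modified grid would "
            "not inflate the grey-zone cell"
        )
    out = modified(f)
    assert abs(out.sum() - 1.0) < 1e-12
    return out


# ---------------------------------------------------------------------------
# vectorized Monte-Carlo internals

def _batch_counts(
    probs: np.ndarray, n: int, reps: int, rng: np.random.Generator
) -> np.ndarray:
    R = probs.shape[0]
    return rng.multinomial(n, probs.ravel(), size=reps).reshape(reps, R, R)


def _batch_kappa_delta(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-replicate unweighted kappa and max symmetry residual.

    Equivalent to running the single-table pipeline on every slice; kept
    vectorized because the Monte-Carlo studies draw 10^4-10^5 tables.
    """
    c = counts.astype(float)
    n = c.sum(axis=(1, 2))[:, None, None]
    p = c / n
    p_o = np.trace(p, axis1=1, axis2=2)
    p_e = np.einsum("ri,ri->r", p.sum(axis=2), p.sum(axis=1))
    kappa = (p_o - p_e) / (1.0 - p_e)
    mu = (c + np.transpose(c, (0, 2, 1))) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(mu > 0, (c - mu) / np.sqrt(mu), 0.0)
    idx = np.arange(counts.shape[1])
    r[:, idx, idx] = 0.0
    return kappa, r.max(axis=(1, 2))


def _batch_decisions(
    counts: np.ndarray, n: int, model: ThresholdModel
) -> np.ndarray:
    """Grey-zone decisions for a stack of tables.

    Replicates with kappa <= 0 (no declarable grey zone) or with the
    threshold outside its domain count as negative decisions.
    """
    kappa, rmax = _batch_kappa_delta(counts)
    ok = kappa > 0
    delta = np.where(ok, rmax / np.where(ok, kappa, 1.0), np.nan)
    base = np.array([model.base(k, n) if o else -1.0 for k, o in zip(kappa, ok)])
    expo = model.exponent if model.inner is not None else 1.0 / model.lambda_
    tau = np.full(base.shape, np.inf)
    pos = base > 0
    tau[pos] = base[pos] ** expo
    return ok & pos & (delta > tau)


def matthews_corrcoef(tp: int, fp: int, fn: int, tn: int) -> tuple[float, bool]:
    """MCC of a 2x2 decision table; (0.0, True) when a margin is zero."""
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0, True
    return (tp * tn - fp * fn) / float(np.sqrt(denom)), False


@dataclass(frozen=True)
class AccuracyResult:
    """Decision counts and derived rates for one simulation scenario."""

    rho: float
    n: int
    R: int
    cell: tuple[int, int]
    reps: int
    seed_entropy: int
    TP: int
    FP: int
    FN: int
    TN: int
    target_kappa: float
    mcc_undefined: bool = False

    @property
    def sensitivity(self) -> float:
        return self.TP / (self.TP + self.FN)

    @property
    def specificity(self) -> float:
        return self.TN / (self.TN + self.FP)

    @property
    def mcc(self) -> float:
        return matthews_corrcoef(self.TP, self.FP, self.FN, self.TN)[0]


def accuracy_study(
    scenarios: Iterable[tuple[float, int, int, tuple[int, int]]],
    reps: int,
    rng: np.random.Generator,
    model: ThresholdModel = DEFAULT_THRESHOLD_MODEL,
    cutpoints: np.ndarray | None = None,
    boost: float = 0.5,
) -> list[AccuracyResult]:
    """Sensitivity/specificity/MCC of the detector over (rho, n, R, cell) scenarios.

    For each scenario, ``reps`` clean tables are drawn from the latent grid
    at ``rho`` and ``reps`` grey-zone tables from a grid whose latent
    correlation is boosted to ``rho + boost * (1 - rho)`` and then injected
    at ``cell`` until its plug-in kappa falls back to the clean grid's — so
    both arms share the same agreement level.  Infeasible injections are
    logged and the scenario skipped.  Each scenario runs on an independent
    child stream of ``rng`` so results are reproducible in isolation.
    """
    if reps < 1:
        raise TableValidationError("reps must be >= 1")
    scenarios = list(scenarios)
    streams = rng.spawn(len(scenarios))
    results: list[AccuracyResult] = []
    for (rho, n, R, cell), stream in zip(scenarios, streams):
        cfg = LatentConfig(rho=rho, R=R, n=n, cutpoints=cutpoints)
        clean = cell_probs_from_latent(cfg)
        target = kappa_from_probs(clean)
        rho_hi = rho + boost * (1.0 - rho)
        boosted = cell_probs_from_latent(
            LatentConfig(rho=rho_hi, R=R, n=n, cutpoints=cutpoints)
        )
        try:
            injected = inject_grey_zone(boosted, cell, target_kappa=target)
        except InfeasibleInjectionError as exc:
            logger.warning(
                "scenario (rho=%.3f, n=%d, R=%d, cell=%s) skipped: %s",
                rho, n, R, cell, exc,
            )
            continue
        neg = _batch_decisions(_batch_counts(clean, n, reps, stream), n, model)
        pos = _batch_decisions(_batch_counts(injected, n, reps, stream), n, model)
        tp, fn = int(pos.sum()), int((~pos).sum())
        fp, tn = int(neg.sum()), int((~neg).sum())
        mcc_val, undef = matthews_corrcoef(tp, fp, fn, tn)
        results.append(
            AccuracyResult(
                rho=rho, n=n, R=R, cell=tuple(cell), reps=reps,
                seed_entropy=int(stream.bit_generator.seed_seq.entropy or 0),
                TP=tp, FP=fp, FN=fn, TN=tn,
                target_kappa=target, mcc_undefined=undef,
            )
        )
    return results


def summarize_replicates(
    rho_set: Sequence[float],
    n_set: Sequence[int],
    reps: int,
    rng: np.random.Generator,
    R: int = 3,
    cutpoints: np.ndarray | None = None,
):
    """Descriptive statistics of (kappa, Delta) over no-grey-zone replicates.

    Returns a DataFrame with one row per (rho, n): min/median/max of kappa
    and min/median/90th/95th/max of Delta.  Replicates with kappa <= 0 are
    kept in the kappa summaries but excluded from the Delta summaries
    (Delta is undefined there); the exclusion count is reported per row.
    Percentiles use linear interpolation (numpy's default convention).
    """
    import pandas as pd

    if reps < 2:
        raise TableValidationError("summaries need reps >= 2")
    rows = []
    for rho in rho_set:
        probs = cell_probs_from_latent(
            LatentConfig(rho=rho, R=R, n=1, cutpoints=cutpoints)
        )
        for n in n_set:
            counts = _batch_counts(probs, int(n), reps, rng)
            kappa, rmax = _batch_kappa_delta(counts)
            ok = kappa > 0
            delta = rmax[ok] / kappa[ok]
            n_excl = int((~ok).sum())
            if n_excl:
                logger.info(
                    "(rho=%.2f, n=%d): %d replicate(s) with kappa <= 0 "
                    "excluded from Delta summaries", rho, n, n_excl,
                )
            row = {
                "rho": rho,
                "n": int(n),
                "kappa_min": kappa.min(),
                "kappa_med": float(np.median(kappa)),
                "kappa_max": kappa.max(),
                "n_excluded": n_excl,
            }
            if delta.size:
                q = np.percentile(delta, [0, 50, 90, 95, 100])
                row.update(
                    delta_min=q[0], delta_med=q[1], delta_p90=q[2],
                    delta_p95=q[3], delta_max=q[4],
                )
            else:  # pragma: no cover - requires every replicate at kappa <= 0
                row.update(
                    delta_min=np.nan, delta_med=np.nan, delta_p90=np.nan,
                    delta_p95=np.nan, delta_max=np.nan,
                )
            rows.append(row)
    return pd.DataFrame(rows)
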