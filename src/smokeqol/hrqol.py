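"""Health-related quality-of-life scoring.

* SGRQ: respiratory-specific instrument; activity, impacts, symptom and total
  scores on 0-100 (higher = worse).  The official item weights are licensed
  and therefore supplied by the user as a configuration table, never shipped.
* SF-36: generic instrument; eight 0-100 domain scores (higher = better),
  scored with the public-domain item recoding (0-100 recode per item, then the
  per-domain mean of answered items).
* A confirmatory two-correlated-factor model reduces the eight SF-36 domains
  to standardized physical- and mental-health factor scores.  The simple
  structure is fixed a priori (physical: physical functioning, role physical,
  bodily pain, general health; mental: mental health, role emotional, social
  functioning, vitality), estimation is maximum likelihood on the 8×8
  covariance, and factor scores use the regression method.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "SGRQ_DOMAINS",
    "SF36_DOMAINS",
    "PHYSICAL_DOMAINS",
    "MENTAL_DOMAINS",
    "score_sgrq",
    "score_sf36",
    "fit_two_factor",
    "TwoFactorResult",
]

SGRQ_DOMAINS = ("symptom", "activity", "impacts")

# ---------------------------------------------------------------------------
# SGRQ

def score_sgrq(
    responses: Mapping[str, bool],
    weights: Mapping[str, Mapping[str, float]],
    missing_cap: float = 0.25,
) -> dict[str, float]:
    """Score the SGRQ from endorsed items and a user-supplied weight table.

    ``weights`` maps each domain ('symptom', 'activity', 'impacts') to
    {item_key: weight}; ``responses`` maps item keys to endorsed (True) /
    not endorsed (False); items absent from ``responses`` are treated as
    missing.  Each domain score is 100 × (weight sum of endorsed items) /
    (maximum possible weight sum); missing items are dropped from both sums
    (max-sum renormalization) up to ``missing_cap`` of the domain's total
    weight, beyond which the score is NaN.  The total score pools the weights
    of all domains.
    """
    known = {item for dom in weights.values() for item in dom}
    unknown = set(responses) - known
    if unknown:
        raise KeyError(f"response items absent from the weight table: {sorted(unknown)[:5]}")

    def one(domain_weights: Mapping[str, float]) -> float:
        full = sum(domain_weights.values())
        if full <= 0:
            raise ValueError("weight table domain has non-positive total weight")
        answered_max = sum(w for item, w in domain_weights.items() if item in responses)
        if full - answered_max > missing_cap * full:
            return float("nan")
        if answered_max == 0:
            return float("nan")
        endorsed = sum(w for item, w in domain_weights.items() if responses.get(item, False))
        return 100.0 * endorsed / answered_max

    scores = {dom: one(wts) for dom, wts in weights.items()}
    pooled = {item: w for dom in weights.values() for item, w in dom.items()}
    scores["total"] = one(pooled)
    return scores


# ---------------------------------------------------------------------------
# SF-36 (public-domain 36-item scoring: recode each item to 0-100, then the
# per-domain mean of answered items)

_RECODE_5_REV = {1: 100, 2: 75, 3: 50, 4: 25, 5: 0}
_RECODE_3 = {1: 0, 2: 50, 3: 100}
_RECODE_2 = {1: 0, 2: 100}
_RECODE_6_REV = {1: 100, 2: 80, 3: 60, 4: 40, 5: 20, 6: 0}
_RECODE_6 = {1: 0, 2: 20, 3: 40, 4: 60, 5: 80, 6: 100}
_RECODE_5 = {1: 0, 2: 25, 3: 50, 4: 75, 5: 100}

_ITEM_RECODE: dict[int, dict[int, int]] = {}
for q in (1, 2, 20, 22, 34, 36):
    _ITEM_RECODE[q] = _RECODE_5_REV
for q in range(3, 13):
    _ITEM_RECODE[q] = _RECODE_3
for q in range(13, 20):
    _ITEM_RECODE[q] = _RECODE_2
for q in (21, 23, 26, 27, 30):
    _ITEM_RECODE[q] = _RECODE_6_REV
for q in (24, 25, 28, 29, 31):
    _ITEM_RECODE[q] = _RECODE_6
for q in (32, 33, 35):
    _ITEM_RECODE[q] = _RECODE_5

SF36_DOMAINS: dict[str, tuple[int, ...]] = {
    "physical_functioning": tuple(range(3, 13)),
    "role_physical": (13, 14, 15, 16),
    "role_emotional": (17, 18, 19),
    "vitality": (23, 27, 29, 31),
    "mental_health": (24, 25, 26, 28, 30),
    "social_functioning": (20, 32),
    "bodily_pain": (21, 22),
    "general_health": (1, 33, 34, 35, 36),
}

PHYSICAL_DOMAINS = ("physical_functioning", "role_physical", "bodily_pain", "general_health")
MENTAL_DOMAINS = ("mental_health", "role_emotional", "social_functioning", "vitality")


def score_sf36(items: Mapping[int | str, int | None]) -> dict[str, float]:
    """Eight SF-36 domain scores (0-100, higher = better) from raw item codes.

    ``items`` maps the item number (1-36, int or 'q7'-style string) to its raw
    response code, or None / absent for missing.  Out-of-range codes raise;
    a domain is NaN only if all of its items are missing.
    """
    recoded: dict[int, float] = {}
    for key, raw in items.items():
        q = int(str(key).lstrip("qQ"))
        if q not in _ITEM_RECODE:
            raise KeyError(f"unknown SF-36 item {key!r}")
        if raw is None:
            continue
        table = _ITEM_RECODE[q]
        if raw not in table:
            raise ValueError(f"item {q}: raw code {raw!r} outside valid range "
                             f"{sorted(table)}")
        recoded[q] = float(table[raw])
    out = {}
    for domain, qs in SF36_DOMAINS.items():
        vals = [recoded[q] for q in qs if q in recoded]
        out[domain] = float(np.mean(vals)) if vals else float("nan")
    return out


# ---------------------------------------------------------------------------
# Two-correlated-factor confirmatory model on the 8 domain scores

_DOMAIN_ORDER = PHYSICAL_DOMAINS + MENTAL_DOMAINS


@dataclass
class TwoFactorResult:
    loadings: pd.Series          # standardized loading of each domain on its factor
    uniquenesses: pd.Series
    factor_corr: float
    scores: pd.DataFrame         # physical_factor, mental_factor; mean 0, SD 1
    loglik: float
    n_iter: int
    converged: bool
    heywood: list[str]

    def implied_corr(self) -> np.ndarray:
        lam = self.loadings.loc[list(_DOMAIN_ORDER)].to_numpy()
        L = np.zeros((8, 2))
        L[:4, 0] = lam[:4]
        L[4:, 1] = lam[4:]
        phi = np.array([[1.0, self.factor_corr], [self.factor_corr, 1.0]])
        return L @ phi @ L.T + np.diag(self.uniquenesses.loc[list(_DOMAIN_ORDER)].to_numpy())


def _sigma(params: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    lam = params[:8]
    psi = np.exp(params[8:16])
    phi = math.tanh(params[16])
    L = np.zeros((8, 2))
    L[:4, 0] = lam[:4]
    L[4:, 1] = lam[4:]
    P = np.array([[1.0, phi], [phi, 1.0]])
    return L @ P @ L.T + np.diag(psi), lam, psi, phi


def fit_two_factor(
    domain_matrix: pd.DataFrame,
    max_iter: int = 2000,
    uniqueness_floor: float = 1e-3,
) -> TwoFactorResult:
    """ML fit of the fixed-structure two-correlated-factor model.

    ``domain_matrix`` is n × 8 with the SF-36 domain columns.  Rows with any
    missing domain are dropped.  Domains are standardized before fitting, so
    the returned loadings are standardized and the fitted matrix is a
    correlation matrix.  Factor scores use the regression method
    (Λ'Σ⁻¹ z) and are re-standardized to mean 0, SD 1 on the fitting sample.
    """
    missing_cols = [c for c in _DOMAIN_ORDER if c not in domain_matrix.columns]
    if missing_cols:
        raise ValueError(f"missing SF-36 domain columns: {missing_cols}")
    X = domain_matrix.loc[:, list(_DOMAIN_ORDER)].dropna()
    n = len(X)
    if n < 50:
        raise ValueError(f"n = {n} < 50: too few complete rows for a stable factor fit")
    sd = X.std(ddof=1)
    if (sd == 0).any():
        raise ValueError(f"constant domain(s): {list(sd.index[sd == 0])}")
    Z = (X - X.mean()) / sd
    S = np.cov(Z.to_numpy(), rowvar=False, ddof=1)

    sign, logdet_S = np.linalg.slogdet(S)
    if sign <= 0:
        raise ValueError("sample covariance is singular")

    def discrepancy(params: np.ndarray) -> float:
        sigma, _, psi, _ = _sigma(params)
        try:
            sign_m, logdet = np.linalg.slogdet(sigma)
            if sign_m <= 0:
                return 1e10
            tr = np.trace(np.linalg.solve(sigma, S))
        except np.linalg.LinAlgError:
            return 1e10
        return logdet + tr - logdet_S - 8.0

    x0 = np.concatenate([np.full(8, 0.7), np.log(np.full(8, 0.5)), [np.arctanh(0.5)]])
    bounds = [(-2.0, 2.0)] * 8 + [(math.log(uniqueness_floor), math.log(4.0))] * 8 \
        + [(-5.0, 5.0)]
    res = optimize.minimize(discrepancy, x0, method="L-BFGS-B", bounds=bounds,
                            options={"maxiter": max_iter, "ftol": 1e-12, "gtol": 1e-9})
    if not res.success and res.fun > 1e9:
        raise RuntimeError(f"two-factor ML fit failed to converge: {res.message}; "
                           f"condition number of S = {np.linalg.cond(S):.3g}")

    sigma, lam, psi, phi = _sigma(res.x)
    # loadings are sign-indeterminate per factor; orient them positive
    for block in (slice(0, 4), slice(4, 8)):
        if lam[block].sum() < 0:
            lam[block] = -lam[block]
    heywood = [d for d, p in zip(_DOMAIN_ORDER, psi) if p <= uniqueness_floor * 1.01]

    L = np.zeros((8, 2))
    L[:4, 0] = lam[:4]
    L[4:, 1] = lam[4:]
    P = np.array([[1.0, phi], [phi, 1.0]])
    sigma = L @ P @ L.T + np.diag(psi)
    # regression-method factor scores: F = Z Σ⁻¹ Λ Φ
    B = np.linalg.solve(sigma, L @ P)
    F = Z.to_numpy() @ B
    F = (F - F.mean(axis=0)) / F.std(axis=0, ddof=1)
    scores = pd.DataFrame(F, columns=["physical_factor", "mental_factor"], index=X.index)

    # multivariate-normal log-likelihood at the fitted parameters
    sign_m, logdet = np.linalg.slogdet(sigma)
    loglik = -0.5 * n * (8 * math.log(2 * math.pi) + logdet
                         + np.trace(np.linalg.solve(sigma, S)) * (n - 1) / n)

    return TwoFactorResult(
        loadings=pd.Series(lam, index=list(_DOMAIN_ORDER)),
        uniquenesses=pd.Series(psi, index=list(_DOMAIN_ORDER)),
        factor_corr=float(phi),
        scores=scores,
        loglik=float(loglik),
        n_iter=int(res.nit),
        converged=bool(res.success),
        heywood=heywood,
    )
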