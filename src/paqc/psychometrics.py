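"""Score-property diagnostics: tetrachoric correlations, redundancy, PSD.

The tetrachoric correlation is the correlation of a latent bivariate
normal assumed to underlie two dichotomised items, estimated here by the
standard two-step maximum-likelihood procedure: thresholds are fixed at
the inverse-normal transforms of the marginal proportions and the
multinomial likelihood of the 2x2 table is maximised over rho alone.
Quadrant probabilities are evaluated through Owen's T function, which
makes the likelihood cheap and vectorisable over rho.

Pairs of binary items correlating above 0.80 ("very strong" on Evans'
verbal scale) within a domain are flagged as redundant; a correlation
matrix that is not positive semidefinite indicates linear dependency
among items — both diagnostics that motivated replacing the basic
additive score.
"""

from __future__ import annotations

import math
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, model_validator
from scipy import optimize, special, stats

from .errors import DegenerateTableError

RHO_CLAMP = 0.9999
EVANS_LABELS = (
    (0.00, "very weak"),
    (0.20, "weak"),
    (0.40, "moderate"),
    (0.60, "strong"),
    (0.80, "very strong"),
)


class FourfoldTable(BaseModel):
    """2x2 cross-classification counts; n_xy = #(item1 = x, item2 = y)."""

    model_config = ConfigDict(frozen=True)

    n00: float
    n01: float
    n10: float
    n11: float

    @model_validator(mode="after")
    def _valid(self) -> "FourfoldTable":
        cells = (self.n00, self.n01, self.n10, self.n11)
        if any(c < 0 for c in cells):
            raise ValueError("counts must be non-negative")
        if sum(cells) <= 0:
            raise ValueError("table total must be positive")
        return self

    @classmethod
    def from_columns(cls, x: Sequence[int], y: Sequence[int]) -> "FourfoldTable":
        x, y = np.asarray(x, bool), np.asarray(y, bool)
        return cls(
            n00=int(np.sum(~x & ~y)),
            n01=int(np.sum(~x & y)),
            n10=int(np.sum(x & ~y)),
            n11=int(np.sum(x & y)),
        )

    def corrected(self) -> "FourfoldTable":
        """0.5 continuity correction applied to every cell if any cell is 0."""
        cells = (self.n00, self.n01, self.n10, self.n11)
        if min(cells) > 0:
            return self
        return FourfoldTable(n00=self.n00 + 0.5, n01=self.n01 + 0.5,
                             n10=self.n10 + 0.5, n11=self.n11 + 0.5)


def bvn_cdf(h: float, k: float, rho: np.ndarray | float) -> np.ndarray | float:
    """P(X <= h, Y <= k) for a standard bivariate normal, via Owen's T.

    Owen (1956): Phi2(h,k;rho) = (Phi(h)+Phi(k))/2 - T(h,a_h) - T(k,a_k)
    - delta, with delta = 1/2 iff hk < 0 or (hk = 0 and h+k < 0).
    Vectorised over ``rho`` for fixed thresholds (the shape the
    likelihood needs); |rho| must be < 1.
    """
    rho = np.asarray(rho, dtype=float)
    if h == 0.0 and k == 0.0:
        return 0.25 + np.arcsin(np.clip(rho, -1.0, 1.0)) / (2.0 * math.pi)
    # a +eps nudge of an exactly-zero threshold lands on the correct side
    # of the delta discontinuity and leaves the continuous part unchanged
    # to within floating-point noise
    if h == 0.0:
        h = 1e-14
    if k == 0.0:
        k = 1e-14
    s = np.sqrt(1.0 - rho * rho)
    ah = (k - rho * h) / (h * s)
    ak = (h - rho * k) / (k * s)
    delta = np.where(h * k > 0, 0.0, 0.5)
    return (
        0.5 * (stats.norm.cdf(h) + stats.norm.cdf(k))
        - special.owens_t(h, ah)
        - special.owens_t(k, ak)
        - delta
    )


def table_loglik(table: FourfoldTable, rho: np.ndarray | float) -> np.ndarray | float:
    """Multinomial log-likelihood of the table at rho, thresholds fixed
    at the inverse-normal transforms of the (corrected) margins."""
    t = table.corrected()
    n = t.n00 + t.n01 + t.n10 + t.n11
    # item1 = 1 with prob. p1 corresponds to latent Z1 > h
    p1 = (t.n10 + t.n11) / n
    p2 = (t.n01 + t.n11) / n
    h = stats.norm.ppf(1.0 - p1)
    k = stats.norm.ppf(1.0 - p2)
    p00 = bvn_cdf(h, k, rho)
    p01 = stats.norm.cdf(h) - p00
    p10 = stats.norm.cdf(k) - p00
    p11 = 1.0 - stats.norm.cdf(h) - stats.norm.cdf(k) + p00
    tiny = 1e-300
    return (
        t.n00 * np.log(np.maximum(p00, tiny))
        + t.n01 * np.log(np.maximum(p01, tiny))
        + t.n10 * np.log(np.maximum(p10, tiny))
        + t.n11 * np.log(np.maximum(p11, tiny))
    )


def estimate_tetrachoric(table: FourfoldTable, xatol: float = 1e-6) -> float:
    """Maximum-likelihood tetrachoric correlation of a 2x2 table.

    Raises :class:`DegenerateTableError` when a whole row or column is
    zero before correction (the margin carries no information about rho).
    """
    if (table.n00 + table.n01 == 0 or table.n10 + table.n11 == 0
            or table.n00 + table.n10 == 0 or table.n01 + table.n11 == 0):
        raise DegenerateTableError("a margin of the 2x2 table is empty; rho undefined")
    res = optimize.minimize_scalar(
        lambda r: -table_loglik(table, r),
        bounds=(-RHO_CLAMP, RHO_CLAMP),
        method="bounded",
        options={"xatol": xatol},
    )
    return float(np.clip(res.x, -RHO_CLAMP, RHO_CLAMP))


def tetrachoric_matrix(
    items: pd.DataFrame,
    pairs: Optional[Iterable[tuple[str, str]]] = None,
) -> tuple[pd.DataFrame, dict[tuple[str, str], str]]:
    """Pairwise tetrachoric correlation matrix of binary item columns.

    Returns (matrix with unit diagonal, reasons for undefined pairs).
    ``pairs`` restricts estimation (e.g. to within-domain pairs); other
    entries are left NaN without a reason code.
    """
    if items.shape[1] < 2 or items.shape[0] < 1:
        raise ValueError("need at least 2 items and 1 observation")
    cols = list(items.columns)
    mat = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    wanted = {frozenset(p) for p in pairs} if pairs is not None else None
    reasons: dict[tuple[str, str], str] = {}
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            if wanted is not None and frozenset((a, b)) not in wanted:
                mat.loc[a, b] = mat.loc[b, a] = np.nan
                continue
            table = FourfoldTable.from_columns(items[a], items[b])
            try:
                rho = estimate_tetrachoric(table)
            except DegenerateTableError:
                mat.loc[a, b] = mat.loc[b, a] = np.nan
                reasons[(a, b)] = "degenerate_margin"
                continue
            mat.loc[a, b] = mat.loc[b, a] = rho
    return mat, reasons


def flag_redundant(matrix: pd.DataFrame, threshold: float = 0.80) -> list[tuple[str, str, float]]:
    """Item pairs with |rho| > threshold, sorted descending by |rho|."""
    out = []
    cols = list(matrix.columns)
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            rho = matrix.loc[a, b]
            if pd.notna(rho) and abs(rho) > threshold:
                out.append((a, b, float(rho)))
    return sorted(out, key=lambda t: -abs(t[2]))


def is_positive_semidefinite(matrix: pd.DataFrame | np.ndarray, tol: float = 1e-8) -> tuple[bool, float]:
    """(PSD within tolerance?, minimum eigenvalue) of a symmetric matrix."""
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("matrix must be square")
    if not np.allclose(m, m.T, atol=1e-10):
        raise ValueError("matrix must be symmetric")
    lam_min = float(np.linalg.eigvalsh(m).min())
    return lam_min >= -tol, lam_min


def strength_label(rho: float) -> str:
    """Evans' verbal label for a correlation magnitude."""
    mag = abs(rho)
    label = EVANS_LABELS[0][1]
    for lo, name in EVANS_LABELS:
        if mag >= lo:
            label = name
    return label
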