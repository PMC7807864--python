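"""Restricted (natural) cubic spline basis for the age covariate.

Knots default to Harrell's quantiles of the observed distribution
(for 4 knots: the 0.05, 0.35, 0.65 and 0.95 quantiles).  The basis has
``n_knots - 1`` columns: the identity (linear) term plus ``n_knots - 2``
truncated-cubic terms constructed so the function is linear beyond the
boundary knots and any linear function of age lies in the column span.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Harrell's default knot quantiles by number of knots.
HARRELL_QUANTILES: dict[int, tuple[float, ...]] = {
    3: (0.10, 0.50, 0.90),
    4: (0.05, 0.35, 0.65, 0.95),
    5: (0.05, 0.275, 0.50, 0.725, 0.95),
    6: (0.05, 0.23, 0.41, 0.59, 0.77, 0.95),
    7: (0.025, 0.1833, 0.3417, 0.50, 0.6583, 0.8167, 0.975),
}


def knot_quantiles(n_knots: int) -> np.ndarray:
    if n_knots in HARRELL_QUANTILES:
        return np.asarray(HARRELL_QUANTILES[n_knots])
    return np.linspace(0.05, 0.95, n_knots)


@dataclass
class SplineBasis:
    knots: np.ndarray  # ascending, length k
    matrix: np.ndarray  # n x (k - 1)
    n_knots: int
    n_columns_used: int

    @property
    def columns(self) -> np.ndarray:
        return self.matrix[:, : self.n_columns_used]

    def evaluate(self, x) -> np.ndarray:
        """Evaluate the same basis (same knots) at new points."""
        return _rcs_matrix(np.asarray(x, dtype=float), self.knots)[
            :, : self.n_columns_used
        ]


def _rcs_matrix(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    k = len(knots)
    t = knots
    norm = (t[-1] - t[0]) ** 2  # Harrell's scaling, keeps columns on the x scale
    out = np.empty((len(x), k - 1))
    out[:, 0] = x
    for j in range(k - 2):
        d = (
            np.clip(x - t[j], 0, None) ** 3
            - np.clip(x - t[-2], 0, None) ** 3 * (t[-1] - t[j]) / (t[-1] - t[-2])
            + np.clip(x - t[-1], 0, None) ** 3 * (t[-2] - t[j]) / (t[-1] - t[-2])
        )
        out[:, j + 1] = d / norm
    return out


def build_spline_basis(
    ages, n_knots: int = 4, n_columns_used: int | None = None
) -> SplineBasis:
    """Build a restricted cubic spline basis on the observed age vector.

    ``n_columns_used`` truncates the basis to its first columns (some
    deployments adjust for only the first two); default uses all
    ``n_knots - 1``.
    """
    x = np.asarray(ages, dtype=float)
    if n_knots < 3:
        raise ValueError("n_knots must be >= 3")
    if not np.all(np.isfinite(x)):
        raise ValueError("ages must be finite")
    distinct = np.unique(x)
    if len(distinct) < n_knots:
        raise ValueError(
            f"need at least {n_knots} distinct ages, got {len(distinct)}"
        )
    knots = np.quantile(x, knot_quantiles(n_knots))
    if len(np.unique(knots)) < n_knots:
        raise ValueError("degenerate age distribution: knots are not distinct")
    n_cols = n_knots - 1 if n_columns_used is None else n_columns_used
    if not (1 <= n_cols <= n_knots - 1):
        raise ValueError("n_columns_used must be in [1, n_knots - 1]")
    return SplineBasis(
        knots=knots,
        matrix=_rcs_matrix(x, knots),
        n_knots=n_knots,
        n_columns_used=n_cols,
    )
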