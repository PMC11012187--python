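"""Two-level full factorial designs (2^k + center replicates) for extraction optimization.

The microwave-assisted extraction (MAE) study screens three factors —
solvent-to-solid ratio (mL g⁻¹), extraction time (min) and temperature (°C) —
at two coded levels (−1, +1) plus replicated center points (0).  This module
builds the design matrix, converts between coded and real factor units, and
expands coded settings into the 8-term model basis

    [1, x1, x2, x3, x1x2, x1x3, x2x3, x1x2x3]

used by every downstream fit.  Corner runs are emitted in standard Yates
order with the *first* factor varying fastest; a reorder utility matches an
externally given run order keyed by coded triples.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FactorSpec",
    "DesignTable",
    "MODEL_TERMS",
    "build_full_factorial",
    "coded_to_real",
    "real_to_coded",
    "model_matrix",
    "default_mae_factors",
]

#: fixed term order of the 8-term factorial model basis
MODEL_TERMS = ("b0", "b1", "b2", "b3", "b12", "b13", "b23", "b123")

# index tuples of the interaction columns (0-based factor indices)
_INTERACTIONS = ((0, 1), (0, 2), (1, 2), (0, 1, 2))


@dataclass(frozen=True)
class FactorSpec:
    """One experimental factor with its coded-level anchors.

    ``low`` is the real value at coded −1, ``high`` at +1; the center (coded
    0) is their midpoint.
    """

    name: str
    low: float
    high: float
    units: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite(self.low) or not np.isfinite(self.high):
            raise ValueError(f"factor {self.name!r}: non-finite level")
        if not self.low < self.high:
            raise ValueError(
                f"factor {self.name!r}: low ({self.low}) must be < high ({self.high})"
            )

    @property
    def center(self) -> float:
        return 0.5 * (self.low + self.high)

    @property
    def half_range(self) -> float:
        return 0.5 * (self.high - self.low)


def default_mae_factors() -> tuple[FactorSpec, FactorSpec, FactorSpec]:
    """The three MAE factors at the study's experimental ranges."""
    return (
        FactorSpec("solvent_to_solid", 16.0, 32.0, "mL g^-1"),
        FactorSpec("time_min", 6.0, 30.0, "min"),
        FactorSpec("temperature_C", 50.0, 80.0, "degC"),
    )


def coded_to_real(coded, factor: FactorSpec):
    """Affine map from coded level to real factor units.

    ``real = center + coded * half_range``.  Values outside [−1, 1] are
    extrapolated with a warning.
    """
    arr = np.asarray(coded, dtype=float)
    if np.any(np.abs(arr) > 1 + 1e-12):
        warnings.warn(
            f"coded level outside [-1, 1] for factor {factor.name!r}; extrapolating",
            stacklevel=2,
        )
    out = factor.center + arr * factor.half_range
    return float(out) if np.isscalar(coded) else out


def real_to_coded(real, factor: FactorSpec):
    """Inverse of :func:`coded_to_real`."""
    arr = np.asarray(real, dtype=float)
    out = (arr - factor.center) / factor.half_range
    return float(out) if np.isscalar(real) else out


@dataclass(frozen=True)
class DesignTable:
    """An ordered set of runs with coded settings for each factor."""

    factors: tuple[FactorSpec, ...]
    run_ids: tuple[str, ...]
    coded: np.ndarray  # (n_runs, k), exact −1/0/+1 for corners/centers
    is_center: np.ndarray  # (n_runs,) bool

    def __post_init__(self) -> None:
        coded = np.asarray(self.coded, dtype=float)
        object.__setattr__(self, "coded", coded)
        object.__setattr__(self, "is_center", np.asarray(self.is_center, dtype=bool))
        if coded.shape != (len(self.run_ids), len(self.factors)):
            raise ValueError("coded matrix shape does not match run_ids × factors")

    @property
    def n_runs(self) -> int:
        return len(self.run_ids)

    @property
    def k(self) -> int:
        return len(self.factors)

    @property
    def real(self) -> np.ndarray:
        """Run settings in real factor units, (n_runs, k)."""
        cols = [coded_to_real(self.coded[:, j], f) for j, f in enumerate(self.factors)]
        return np.column_stack(cols)

    def to_frame(self) -> pd.DataFrame:
        data: dict = {"run_id": list(self.run_ids)}
        for j in range(self.k):
            data[f"x{j + 1}_coded"] = self.coded[:, j]
        real = self.real
        for j, f in enumerate(self.factors):
            data[f.name] = real[:, j]
        data["is_center"] = self.is_center
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, factors: tuple[FactorSpec, ...]) -> "DesignTable":
        df = pd.read_csv(path)
        coded = np.column_stack(
            [df[f"x{j + 1}_coded"].to_numpy(float) for j in range(len(factors))]
        )
        return cls(
            factors=tuple(factors),
            run_ids=tuple(str(r) for r in df["run_id"]),
            coded=coded,
            is_center=df["is_center"].to_numpy(bool),
        )

    def reorder_to_match(self, coded_rows) -> "DesignTable":
        """Return a permuted design whose rows follow ``coded_rows``.

        ``coded_rows`` is a sequence of coded tuples that must be a
        permutation of this design's rows (useful to match an externally
        printed experimental matrix whose corner order is not Yates order).
        """
        target = np.asarray(coded_rows, dtype=float)
        if target.shape != self.coded.shape:
            raise ValueError("coded_rows must have the same shape as the design")
        remaining = list(range(self.n_runs))
        order: list[int] = []
        for row in target:
            for pos, idx in enumerate(remaining):
                if np.array_equal(self.coded[idx], row):
                    order.append(remaining.pop(pos))
                    break
            else:
                raise ValueError(f"coded row {row.tolist()} not found in design")
        return DesignTable(
            factors=self.factors,
            run_ids=tuple(self.run_ids[i] for i in order),
            coded=self.coded[order],
            is_center=self.is_center[order],
        )


def build_full_factorial(factors, n_center: int = 0) -> DesignTable:
    """Build a 2^k full factorial design with ``n_center`` center replicates.

    Corner rows enumerate every sign combination exactly once, in standard
    Yates order (first factor alternates fastest); center rows follow with
    coded (0, ..., 0).
    """
    factors = tuple(factors)
    k = len(factors)
    if not 1 <= k <= 6:
        raise ValueError(f"expected 1-6 factors, got {k}")
    if n_center < 0:
        raise ValueError("n_center must be >= 0")
    names = [f.name for f in factors]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate factor names: {names}")

    # product varies the last element fastest; reverse columns so the first
    # factor alternates fastest (Yates standard order)
    corners = np.array(list(itertools.product((-1, 1), repeat=k)), dtype=float)[:, ::-1]
    center = np.zeros((n_center, k))
    coded = np.vstack([corners, center])
    run_ids = tuple(f"R{i + 1}" for i in range(len(corners))) + tuple(
        f"C{i + 1}" for i in range(n_center)
    )
    is_center = np.array([False] * len(corners) + [True] * n_center)
    return DesignTable(factors=factors, run_ids=run_ids, coded=coded, is_center=is_center)


def model_matrix(design) -> np.ndarray:
    """Expand a 3-factor design into the 8-column factorial model basis.

    Columns, in fixed order: 1, x1, x2, x3, x1x2, x1x3, x2x3, x1x2x3.
    Accepts a :class:`DesignTable` or an (n, 3) array of coded levels.
    """
    coded = design.coded if isinstance(design, DesignTable) else np.asarray(design, float)
    if coded.ndim == 1:
        coded = coded[None, :]
    if coded.shape[1] != 3:
        raise ValueError(
            f"the 8-term model basis is specific to 3 factors, got {coded.shape[1]}"
        )
    n = coded.shape[0]
    cols = [np.ones(n), coded[:, 0], coded[:, 1], coded[:, 2]]
    for idx in _INTERACTIONS:
        cols.append(np.prod(coded[:, list(idx)], axis=1))
    return np.column_stack(cols)
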