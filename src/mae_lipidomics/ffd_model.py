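"""Per-subclass response modelling on the 8-term factorial basis.

Each lipid-subclass abundance sum Y (one value per design run) is fitted by
ordinary least squares to

    Y = b0 + b1·x1 + b2·x2 + b3·x3 + b12·x1x2 + b13·x1x3 + b23·x2x3
        + b123·x1x2x3

with the factors in coded units.  With 11 runs (8 corners + 3 centers) the
residual degrees of freedom are 3; coefficient p-values come from two-sided
t tests and the model p-value from the overall F test.  A significance table
collects the retained responses (model p below a threshold) with entries
blanked when a coefficient is not significant, mirroring how such factorial
screens are reported.

Responses are conventionally pretreated by per-column range scaling to
[0, 1] before fitting; :func:`fit_ffd` fits whatever response it is given,
and :func:`range_scale_responses` provides the pretreatment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .design import MODEL_TERMS, DesignTable, model_matrix

__all__ = [
    "CoefficientEstimate",
    "FFDFit",
    "ResponseTable",
    "SignificanceTable",
    "fit_ffd",
    "significance_table",
    "range_scale_responses",
]

# relative r2 slack under which a fit is treated as numerically perfect
_PERFECT_FIT_TOL = 1e-12


def _tier(p_value: float) -> str:
    if not np.isfinite(p_value):
        return "ns"
    if p_value < 0.01:
        return "p01"
    if p_value < 0.05:
        return "p05"
    return "ns"


@dataclass(frozen=True)
class CoefficientEstimate:
    term: str
    value: float
    std_error: float
    t_stat: float
    p_value: float
    tier: str


@dataclass(frozen=True)
class FFDFit:
    """A fitted 8-term factorial model for one response."""

    response_name: str
    coefficients: tuple[CoefficientEstimate, ...]
    r2: float
    r2_adj: float
    f_stat: float
    p_model: float
    df_resid: int
    inference_available: bool = True

    @property
    def coef(self) -> np.ndarray:
        return np.array([c.value for c in self.coefficients])

    def coefficient(self, term: str) -> CoefficientEstimate:
        for c in self.coefficients:
            if c.term == term:
                return c
        raise KeyError(term)

    def predict(self, coded) -> np.ndarray:
        return model_matrix(np.asarray(coded, float)) @ self.coef


@dataclass(frozen=True)
class ResponseTable:
    """Run × subclass abundance matrix aligned to a design.

    ``scaled`` records whether the columns are already on the pretreated
    ([0, 1]-range-scaled) scale, in which case downstream steps must not
    rescale again.
    """

    data: pd.DataFrame  # index: run_id
    scaled: bool = False

    def __post_init__(self) -> None:
        if not np.isfinite(self.data.to_numpy(float)).all():
            raise ValueError("response table contains non-finite values")

    @property
    def run_ids(self) -> tuple[str, ...]:
        return tuple(str(i) for i in self.data.index)

    def check_alignment(self, design: DesignTable) -> None:
        if self.run_ids != design.run_ids:
            raise ValueError(
                "response rows do not align with the design runs: "
                f"{self.run_ids} vs {design.run_ids}"
            )


def range_scale_responses(responses: ResponseTable | pd.DataFrame) -> ResponseTable:
    """Scale every column to the [0, 1] range: x -> (x − min) / (max − min).

    Raises ``ValueError`` naming the column when a column is constant
    (scaling undefined).
    """
    df = responses.data if isinstance(responses, ResponseTable) else responses
    out = {}
    for col in df.columns:
        x = df[col].to_numpy(float)
        lo, hi = x.min(), x.max()
        if hi == lo:
            raise ValueError(f"column {col!r} is constant; [0, 1] scaling undefined")
        out[col] = (x - lo) / (hi - lo)
    return ResponseTable(pd.DataFrame(out, index=df.index), scaled=True)


def fit_ffd(design: DesignTable, response, response_name: str = "response") -> FFDFit:
    """Fit the 8-term factorial model to one response by OLS.

    With n > 8 runs, coefficient inference uses two-sided t tests on the
    residual degrees of freedom (n − 8) and the model-level F test.  With
    exactly 8 runs the system is saturated: coefficients are solved exactly
    but inference is unavailable (``inference_available=False``, NaN
    p-values).  Fewer than 8 runs is an error (rank deficient).
    """
    y = np.asarray(response, dtype=float).ravel()
    design_ok = isinstance(design, DesignTable)
    X = model_matrix(design)
    n = X.shape[0]
    if y.shape[0] != n:
        raise ValueError(f"response length {y.shape[0]} != design runs {n}")
    if not np.isfinite(y).all():
        raise ValueError("response contains non-finite values")
    if n < 8 or np.linalg.matrix_rank(X) < 8:
        raise ValueError("design is rank deficient for the 8-term model (need >= 8 informative runs)")
    if design_ok and n <= 8:
        # saturated fit: exact solve, no residual degrees of freedom
        beta = np.linalg.solve(X, y) if n == 8 else np.linalg.lstsq(X, y, rcond=None)[0]
        coeffs = tuple(
            CoefficientEstimate(t, float(b), math.nan, math.nan, math.nan, "ns")
            for t, b in zip(MODEL_TERMS, beta)
        )
        return FFDFit(response_name, coeffs, 1.0, math.nan, math.nan, math.nan, 0, False)

    res = sm.OLS(y, X).fit()
    beta = res.params
    r2 = float(res.rsquared)
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 8)
    df_resid = n - 8

    if 1.0 - r2 <= _PERFECT_FIT_TOL or res.ssr <= _PERFECT_FIT_TOL * max(res.centered_tss, 1.0):
        # residuals are numerically zero: t statistics are 0/0.  Treat the
        # fit as exact — nonzero coefficients certain, zero ones absent.
        scale = max(np.abs(beta).max(), 1.0)
        coeffs = []
        for t, b in zip(MODEL_TERMS, beta):
            nonzero = abs(b) > 64 * np.finfo(float).eps * scale
            coeffs.append(
                CoefficientEstimate(
                    t, float(b), 0.0, math.inf if nonzero else 0.0,
                    0.0 if nonzero else 1.0, "p01" if nonzero else "ns",
                )
            )
        return FFDFit(response_name, tuple(coeffs), 1.0, 1.0, math.inf, 0.0,
                      df_resid, True)

    coeffs = tuple(
        CoefficientEstimate(
            term=t,
            value=float(b),
            std_error=float(se),
            t_stat=float(tv),
            p_value=float(p),
            tier=_tier(float(p)),
        )
        for t, b, se, tv, p in zip(MODEL_TERMS, beta, res.bse, res.tvalues, res.pvalues)
    )
    return FFDFit(
        response_name=response_name,
        coefficients=coeffs,
        r2=r2,
        r2_adj=float(r2_adj),
        f_stat=float(res.fvalue),
        p_model=float(res.f_pvalue),
        df_resid=df_resid,
    )


@dataclass(frozen=True)
class SignificanceTable:
    """Table-style summary of retained factorial fits.

    ``wide`` holds one column per retained response with rows b0..b123 plus
    r2_adj and p_model; non-significant coefficients are NaN (blank on
    export).  ``long`` is the machine-readable form with every estimate and
    its tier.  ``excluded`` lists responses whose model p exceeded the
    retention threshold ("no significant dependence").
    """

    wide: pd.DataFrame
    long: pd.DataFrame
    retained: tuple[str, ...]
    excluded: tuple[str, ...]
    threshold: float

    def to_csv(self, wide_path, long_path=None) -> None:
        self.wide.to_csv(wide_path)
        if long_path is not None:
            self.long.to_csv(long_path, index=False)


def significance_table(fits, keep_if_model_p: float = 0.05) -> SignificanceTable:
    """Collect fits whose model passes the overall F test at ``keep_if_model_p``."""
    fits = list(fits)
    if not fits:
        raise ValueError("empty fit list")
    retained = [f for f in fits if np.isfinite(f.p_model) and f.p_model <= keep_if_model_p]
    excluded = [f for f in fits if f not in retained]

    wide = pd.DataFrame(index=list(MODEL_TERMS) + ["r2_adj", "p_model"], dtype=float)
    long_rows = []
    for f in retained:
        col = []
        for c in f.coefficients:
            col.append(c.value if c.tier != "ns" else np.nan)
        wide[f.response_name] = col + [f.r2_adj, f.p_model]
    for f in fits:
        for c in f.coefficients:
            long_rows.append(
                {
                    "response": f.response_name,
                    "term": c.term,
                    "value": c.value,
                    "std_error": c.std_error,
                    "p_value": c.p_value,
                    "tier": c.tier,
                    "model_p": f.p_model,
                    "retained": f in retained,
                }
            )
    return SignificanceTable(
        wide=wide,
        long=pd.DataFrame(long_rows),
        retained=tuple(f.response_name for f in retained),
        excluded=tuple(f.response_name for f in excluded),
        threshold=keep_if_model_p,
    )
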