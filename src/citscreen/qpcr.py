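"""Relative quantification of qPCR data.

Two standard routes are implemented:

* the relative standard-curve method — a dilution series of calibrator cDNA
  (default design 20, 4, 0.8, 0.16 ng) defines a regression of Ct on
  log10(input amount); sample Ct values are interpolated back to relative
  input amounts, and target amounts are normalized to the composite
  (geometric-mean) level of two endogenous control genes (Actb, B2m);
* the 2^-ddCt method — fold change relative to a calibrator sample using a
  single endogenous control, appropriate when RNA amounts are too low for a
  full dilution series.

Amplification efficiency derives from the curve slope as
``10**(-1/slope) - 1``; a perfect doubling per cycle gives slope
-1/log10(2) = -3.3219 and efficiency 1.0 (100%). Triplicate Ct values are
combined by arithmetic mean before any transformation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diplotype import DIPLOTYPES

#: Input masses (ng) of the default four-point dilution series.
DEFAULT_DILUTION_SERIES = (20.0, 4.0, 0.8, 0.16)


class QpcrInputError(ValueError):
    """Raised for invalid qPCR inputs (amounts, Ct values, curve shape)."""


class InvalidCurveError(QpcrInputError):
    """Raised when a fitted standard curve has a non-negative slope."""


@dataclass(frozen=True)
class StandardCurve:
    """A fitted relative standard curve (Ct versus log10 input amount)."""

    slope: float  # Ct per log10(amount)
    intercept: float  # Ct at 1 unit input
    r2: float  # coefficient of determination
    gene: str = ""

    @property
    def efficiency(self) -> float:
        """Per-cycle amplification efficiency as a fraction (1.0 = 100%)."""
        return 10.0 ** (-1.0 / self.slope) - 1.0

    @property
    def valid(self) -> bool:
        return self.slope < 0


def fit_standard_curve(amounts, cts, gene: str = "") -> StandardCurve:
    """Least-squares line of mean Ct on log10(input amount).

    Requires at least three distinct positive amounts. A non-negative slope
    (Ct not decreasing with input) yields a curve flagged invalid; callers
    interpolating on it get :class:`InvalidCurveError`.
    """
    amounts = np.asarray(amounts, dtype=float)
    cts = np.asarray(cts, dtype=float)
    if amounts.size != cts.size:
        raise QpcrInputError("amounts and cts must have equal length")
    if np.unique(amounts).size < 3:
        raise QpcrInputError("need >= 3 distinct dilution points")
    if np.any(amounts <= 0):
        raise QpcrInputError("all input amounts must be positive")
    fit = stats.linregress(np.log10(amounts), cts)
    return StandardCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=float(fit.rvalue**2),
        gene=gene,
    )


def interpolate_amount(curve: StandardCurve, ct: float) -> float:
    """Relative input amount for an observed Ct: ``10**((ct - b)/m)``."""
    if not curve.valid:
        raise InvalidCurveError(
            f"standard curve for {curve.gene or 'gene'} has slope {curve.slope} >= 0"
        )
    return 10.0 ** ((ct - curve.intercept) / curve.slope)


def normalize_composite(target_amount: float, control_amounts) -> float:
    """Target amount divided by the geometric mean of the control amounts."""
    controls = np.asarray(control_amounts, dtype=float)
    if target_amount <= 0 or np.any(controls <= 0):
        raise QpcrInputError("amounts must be positive for composite normalization")
    return float(target_amount / stats.gmean(controls))


def delta_delta_ct(
    target_ct_sample: float,
    control_ct_sample: float,
    target_ct_calibrator: float,
    control_ct_calibrator: float,
) -> float:
    """Fold change by 2^-ddCt relative to the calibrator sample."""
    cts = (
        target_ct_sample,
        control_ct_sample,
        target_ct_calibrator,
        control_ct_calibrator,
    )
    if not all(np.isfinite(cts)):
        raise QpcrInputError("all Ct values must be finite")
    ddct = (target_ct_sample - control_ct_sample) - (
        target_ct_calibrator - control_ct_calibrator
    )
    return float(2.0 ** (-ddct))


def aggregate_replicates(measurements: pd.DataFrame) -> pd.DataFrame:
    """Mean Ct per sample x gene from long-format triplicate measurements.

    Expects columns ``sample``, ``gene``, ``ct`` (a ``replicate`` column is
    permitted and ignored). Non-positive Ct values are rejected.
    """
    required = {"sample", "gene", "ct"}
    missing = required - set(measurements.columns)
    if missing:
        raise QpcrInputError(f"measurement table missing columns: {sorted(missing)}")
    if (measurements["ct"] <= 0).any():
        raise QpcrInputError("Ct values must be > 0")
    return (
        measurements.groupby(["sample", "gene"], sort=False)["ct"]
        .mean()
        .reset_index()
    )


def quantify_standard_curve(
    measurements: pd.DataFrame,
    curves: dict[str, StandardCurve],
    target_genes,
    control_genes=("Actb", "B2m"),
) -> pd.DataFrame:
    """Per-sample normalized expression by the relative standard-curve method.

    For each sample, every gene's mean Ct is interpolated on its own curve
    and each target is divided by the geometric mean of the control amounts.
    Returns a wide table: one row per sample, one column per target gene.
    """
    mean_ct = aggregate_replicates(measurements)
    table = mean_ct.pivot(index="sample", columns="gene", values="ct")
    for gene in list(target_genes) + list(control_genes):
        if gene not in table.columns:
            raise QpcrInputError(f"no measurements for gene {gene!r}")
        if gene not in curves:
            raise QpcrInputError(f"no standard curve for gene {gene!r}")
    amounts = {
        gene: table[gene].map(lambda ct: interpolate_amount(curves[gene], ct))
        for gene in list(target_genes) + list(control_genes)
    }
    controls = np.column_stack([amounts[g] for g in control_genes])
    out = {}
    for gene in target_genes:
        out[gene] = [
            normalize_composite(t, c) for t, c in zip(amounts[gene], controls)
        ]
    return pd.DataFrame(out, index=table.index).reset_index()


def rescale_to_reference(levels, diplotypes, reference: str = "B/B") -> np.ndarray:
    """Rescale normalized levels so the reference-diplotype mean equals 1.

    Applied to raw normalized levels for reporting; the causal inference
    battery consumes unscaled levels and residualizes internally. Adjusted
    (litter least-squared) means may legitimately be negative and are never
    clamped.
    """
    levels = np.asarray(levels, dtype=float)
    dips = np.asarray(diplotypes, dtype=object)
    if reference not in DIPLOTYPES:
        raise QpcrInputError(f"unknown reference diplotype {reference!r}")
    mask = dips == reference
    if not mask.any():
        raise QpcrInputError(f"no {reference} individuals to rescale against")
    ref_mean = levels[mask].mean()
    if ref_mean == 0:
        raise QpcrInputError("reference diplotype mean is zero")
    return levels / ref_mean
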