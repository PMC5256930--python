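"""Litter-effect removal and diplotype trait screening.

Litters share maternal environment, so littermates are correlated; following
standard practice for selected-set intercross designs, every variable is
first residualized on the litter factor (ordinary least squares, i.e.
per-litter mean subtraction) and all diplotype comparisons — one-way ANOVA
followed by Tukey's HSD post hoc test — are run on the residuals. The
diplotype ANOVA uses error df = N - 3 (diplotype classes only), matching the
residualize-then-ANOVA workflow rather than a joint two-factor model.

A trait screen renders the results as a report with litter-adjusted
least-squared means, their common standard error, the ANOVA p-value and a
compact ordering string such as ``C/C ≥ B/C > B/B`` in which ``>`` marks
adjacent groups whose Tukey-adjusted p falls below alpha.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .diplotype import DIPLOTYPES, TIE_ORDER, require_all_classes

#: p-values in this half-open band are flagged marginal, not significant.
MARGINAL_BAND: tuple[float, float] = (0.05, 0.06)

GREATER = ">"
GEQ = "≥"  # ≥


class DesignError(ValueError):
    """Raised when the grouping structure cannot support the requested test."""


@dataclass
class ResidualizedVariable:
    """Litter residuals of one measured variable.

    ``values`` are OLS residuals of the one-way litter-factor model in the
    original units; ``litter_model_p`` is the p-value of the litter one-way
    ANOVA on the raw values (NaN when undefined, e.g. a single litter).
    """

    values: np.ndarray
    source: str = ""
    litter_model_p: float = float("nan")
    grand_mean: float = 0.0


def residualize_by_litter(values, litters, source: str = "") -> ResidualizedVariable:
    """OLS residuals of the one-way litter model (per-litter mean subtraction).

    A litter with a single individual gets residual 0; with a single litter
    the residuals are simply ``values - mean``. Idempotent: residualizing the
    residuals returns them unchanged.
    """
    values = np.asarray(values, dtype=float)
    litters = np.asarray(litters, dtype=object)
    if values.size < 2:
        raise DesignError("need at least 2 individuals to residualize")
    if values.shape != litters.shape:
        raise DesignError("values and litters must have equal length")
    if any(l is None or str(l) == "" for l in litters):
        raise DesignError("every litter label must be nonempty")

    resid = values.copy()
    for lab in pd.unique(litters):
        mask = litters == lab
        resid[mask] = values[mask] - values[mask].mean()

    p = _litter_anova_p(values, litters)
    return ResidualizedVariable(
        values=resid, source=source, litter_model_p=p, grand_mean=float(values.mean())
    )


def _litter_anova_p(values: np.ndarray, litters: np.ndarray) -> float:
    groups = [values[litters == lab] for lab in pd.unique(litters)]
    if len(groups) < 2 or sum(len(g) for g in groups) - len(groups) < 1:
        return float("nan")
    if all(np.ptp(g) == 0 for g in groups if len(g) > 1):
        means = [g.mean() for g in groups]
        return 1.0 if np.ptp(means) == 0 else 0.0
    with np.errstate(all="ignore"):
        return float(stats.f_oneway(*groups).pvalue)


def anova_diplotype(residuals, diplotypes) -> tuple[float, float]:
    """One-way ANOVA of a (residualized) variable across the three diplotypes.

    Returns ``(F, p)`` with between df = 2 and error df = N - 3. Degenerate
    inputs are handled explicitly: identical groups give ``(0, 1)``; zero
    within-group variance with unequal means gives ``(inf, 0)``.
    """
    values = _values_of(residuals)
    dips = np.asarray(diplotypes, dtype=object)
    require_all_classes(dips, min_per_class=2)
    groups = [values[dips == d] for d in DIPLOTYPES]

    within_flat = np.concatenate([g - g.mean() for g in groups])
    if np.allclose(within_flat, 0.0):
        means = np.array([g.mean() for g in groups])
        if np.ptp(means) == 0:
            return 0.0, 1.0
        return float("inf"), 0.0
    res = stats.f_oneway(*groups)
    return float(res.statistic), float(res.pvalue)


@dataclass
class TukeySummary:
    """Tukey HSD post hoc summary for the three diplotypes.

    ``order`` lists the diplotypes by descending mean (ties broken by the
    fixed order C/C, B/C, B/B); ``adjacent_significant`` flags, for each of
    the two adjacent pairs, whether the Tukey-adjusted p is below alpha;
    ``grouping`` is the rendered string, e.g. ``"C/C ≥ B/C > B/B"``.
    """

    order: tuple[str, ...]
    adjacent_significant: tuple[bool, ...]
    adjacent_pvalues: tuple[float, ...]
    anova_p: float
    grouping: str
    alpha: float = 0.05
    means: dict = field(default_factory=dict)


def tukey_grouping(residuals, diplotypes, alpha: float = 0.05) -> TukeySummary:
    """Pairwise Tukey HSD with error df = N - 3, rendered as an ordering string."""
    values = _values_of(residuals)
    dips = np.asarray(diplotypes, dtype=object)
    require_all_classes(dips, min_per_class=2)

    means = {d: float(values[dips == d].mean()) for d in DIPLOTYPES}
    order = tuple(
        sorted(DIPLOTYPES, key=lambda d: (-means[d], TIE_ORDER.index(d)))
    )
    pair_p = _tukey_pair_pvalues(values, dips, alpha)
    adj_p = tuple(pair_p[frozenset(pair)] for pair in zip(order, order[1:]))
    adj_sig = tuple(p < alpha for p in adj_p)
    _, anova_p = anova_diplotype(values, dips)
    grouping = _render_grouping(order, adj_sig)
    return TukeySummary(
        order=order,
        adjacent_significant=adj_sig,
        adjacent_pvalues=adj_p,
        anova_p=anova_p,
        grouping=grouping,
        alpha=alpha,
        means=means,
    )


def _tukey_pair_pvalues(values, dips, alpha) -> dict[frozenset, float]:
    within = np.concatenate(
        [values[dips == d] - values[dips == d].mean() for d in DIPLOTYPES]
    )
    if np.allclose(within, 0.0):
        # Zero within-group variance: any mean difference is significant.
        out = {}
        for a, b in itertools.combinations(DIPLOTYPES, 2):
            ma = values[dips == a].mean()
            mb = values[dips == b].mean()
            out[frozenset((a, b))] = 1.0 if np.isclose(ma, mb) else 0.0
        return out
    res = pairwise_tukeyhsd(values, dips, alpha=alpha)
    uniq = list(res.groupsunique)
    pairs = list(itertools.combinations(range(len(uniq)), 2))
    return {
        frozenset((uniq[i], uniq[j])): float(p)
        for (i, j), p in zip(pairs, res.pvalues)
    }


def _render_grouping(order, adjacent_significant) -> str:
    parts = [order[0]]
    for label, sig in zip(order[1:], adjacent_significant):
        parts.append(GREATER if sig else GEQ)
        parts.append(label)
    return " ".join(parts)


def reconstruct_groups(means: dict, se, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Rebuild per-individual groups from summary statistics.

    Given per-diplotype means, a common (or per-diplotype) standard error of
    the mean and the per-group n, constructs groups whose sample means equal
    ``means`` exactly and whose pooled mean square error equals the implied
    ``n * se**2`` (within-group SD ``se * sqrt(n)``), so ANOVA and Tukey HSD
    on the reconstruction reproduce the summary-level statistics.
    """
    if n < 2:
        raise DesignError("need n >= 2 per group to reconstruct")
    base = np.arange(n, dtype=float)
    base -= base.mean()
    base /= base.std(ddof=1)
    values, dips = [], []
    for d in DIPLOTYPES:
        se_d = se[d] if isinstance(se, dict) else se
        values.append(means[d] + se_d * np.sqrt(n) * base)
        dips.extend([d] * n)
    return np.concatenate(values), np.asarray(dips, dtype=object)


def tukey_grouping_from_summary(
    means: dict, se, n: int, alpha: float = 0.05
) -> TukeySummary:
    """Tukey ordering string recomputed from printed means/SE/n."""
    values, dips = reconstruct_groups(means, se, n)
    return tukey_grouping(values, dips, alpha=alpha)


def grouping_rounding_ambiguous(
    means: dict, se: float, n: int, alpha: float = 0.05, mean_ulp: float = 0.01
) -> bool:
    """Whether the ordering string is sensitive to printed-mean rounding.

    Printed means carry half-ulp uncertainty; a pair of adjacent means can
    therefore shift by up to ``mean_ulp`` in difference. The call is flagged
    ambiguous when the studentized range statistic of any adjacent pair
    straddles the critical value within that envelope, i.e. the printed
    precision alone decides between ``>`` and ``≥``.
    """
    order = sorted(DIPLOTYPES, key=lambda d: (-means[d], TIE_ORDER.index(d)))
    df = 3 * (n - 1)
    qcrit = stats.studentized_range.ppf(1 - alpha, 3, df)
    s = se  # SE of a group mean = sqrt(MSE / n)
    for a, b in zip(order, order[1:]):
        diff = abs(means[a] - means[b])
        qlo = max(diff - mean_ulp, 0.0) / s
        qhi = (diff + mean_ulp) / s
        if qlo <= qcrit <= qhi:
            return True
    return False


def two_group_ttest(a, b) -> float:
    """Two-sided pooled-variance (Student) t-test p-value for two groups."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DesignError("each group needs >= 2 values")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        return 1.0 if np.isclose(a.mean(), b.mean()) else 0.0
    return float(stats.ttest_ind(a, b, equal_var=True).pvalue)


def screen_traits(
    frame: pd.DataFrame,
    trait_columns: list[str] | None = None,
    alpha: float = 0.05,
    diplotype_col: str = "diplotype",
    litter_col: str = "litter",
) -> pd.DataFrame:
    """Residualize each trait by litter and screen it for diplotype association.

    Returns one row per trait with litter-adjusted least-squared means and SE
    per diplotype, the litter ANOVA p on the raw values, the diplotype ANOVA
    F and p on the residuals, the Tukey ordering string (``NA`` when the
    ANOVA is not significant at alpha, as in the printed report layout) and a
    ``marginal`` flag for p in the [0.05, 0.06) band.
    """
    reserved = {diplotype_col, litter_col, "individual_id", "set"}
    if trait_columns is None:
        trait_columns = [c for c in frame.columns if c not in reserved]
    rows = []
    for trait in trait_columns:
        sub = frame[[trait, diplotype_col, litter_col]].dropna()
        res = residualize_by_litter(
            sub[trait].to_numpy(float), sub[litter_col].to_numpy(object), source=trait
        )
        dips_t = sub[diplotype_col].to_numpy(object)
        adjusted = res.values + res.grand_mean
        f_stat, p = anova_diplotype(adjusted, dips_t)
        summ = tukey_grouping(adjusted, dips_t, alpha=alpha)
        groups = [adjusted[dips_t == d] for d in DIPLOTYPES]
        mse = np.sum([np.sum((g - g.mean()) ** 2) for g in groups]) / (
            len(adjusted) - 3
        )
        row = {"trait": trait}
        for d, g in zip(DIPLOTYPES, groups):
            row[f"lsmean_{_col(d)}"] = g.mean()
            row[f"se_{_col(d)}"] = np.sqrt(mse / len(g))
        row.update(
            {
                "litter_p": res.litter_model_p,
                "anova_f": f_stat,
                "anova_p": p,
                "differences": summ.grouping if p < alpha else "NA",
                "marginal": MARGINAL_BAND[0] <= p < MARGINAL_BAND[1],
            }
        )
        rows.append(row)
    return pd.DataFrame(rows)


def _col(diplotype: str) -> str:
    return diplotype.replace("/", "").lower()


def _values_of(residuals) -> np.ndarray:
    if isinstance(residuals, ResidualizedVariable):
        return np.asarray(residuals.values, dtype=float)
    return np.asarray(residuals, dtype=float)
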