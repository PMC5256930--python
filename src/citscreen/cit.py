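"""The four-component causal inference test (CIT) on (D, R, T) triplets.

Given diplotype ``D``, a mediator candidate ``R`` (mRNA expression) and a
quantitative trait ``T``, four nested ordinary-least-squares models decide
whether ``R`` mediates the genotype effect on the trait:

====  =======================  =============================================
Test  Model                    Question (tested term, conditioning term)
====  =======================  =============================================
1     T = b0 + b1*D            is D associated with T?
2     R = b0 + b1*D + b2*T     is D associated with R given T?
3     T = b0 + b1*R + b2*D     is R associated with T given D?
4     T = b0 + b1*D + b2*R     is D still associated with T given R?
====  =======================  =============================================

A causal chain D -> R -> T requires Tests 1-3 to reject and Test 4 *not* to
reject (conditioning on the mediator absorbs the genotype effect). Rejecting
all four is ambiguous; a reactive chain D -> T -> R is declared through the
role-swapped battery (R and T exchanged), which for truly reactive data
passes fully while the forward battery stops at Test 2. Diplotype enters
either as a categorical factor (2-df F-test, the default — assumption-free
for a three-class genotype) or as additive C-dosage 0/1/2 (1 df).

The model object residualizes R and T on the litter factor when litter
labels are supplied, mirroring the screening stage; p-values for a tested
term are partial F-tests from full-versus-reduced model fits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .diplotype import dosage, require_all_classes, validate
from .preprocess import MARGINAL_BAND, residualize_by_litter

# Relationship labels.
CAUSAL = "causal"
CAUSAL_MARGINAL = "causal_marginal"
REACTIVE = "reactive"
INDEPENDENT = "independent"
UNDETERMINED = "undetermined"
NOT_ASSESSED = "not_assessed"

LABELS = (CAUSAL, CAUSAL_MARGINAL, REACTIVE, INDEPENDENT, UNDETERMINED, NOT_ASSESSED)

CODINGS = ("categorical", "additive")


class CollinearityError(ValueError):
    """Raised when a model design matrix is rank-deficient."""


@dataclass
class RegressionFit:
    """One fitted CIT regression and the partial test of its leading term."""

    formula_id: int
    params: np.ndarray
    resid_var: float
    p_dependent: float
    f_stat: float
    df_num: int
    df_den: int

    @property
    def beta0(self) -> float:
        return float(self.params[0])


def _dip_columns(dips, coding: str) -> tuple[np.ndarray, str]:
    if coding == "categorical":
        d = validate(dips)
        cols = np.column_stack(
            [(d == "B/C").astype(float), (d == "C/C").astype(float)]
        )
        return cols, "D (categorical)"
    if coding == "additive":
        return dosage(dips).reshape(-1, 1), "D (dosage)"
    raise ValueError(f"unknown coding {coding!r}; expected one of {CODINGS}")


def _check_rank(X: np.ndarray, term: str) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise CollinearityError(f"design matrix is rank-deficient: term {term}")


def _partial_f(y, tested, conditioning, formula_id: int) -> RegressionFit:
    n = y.shape[0]
    ones = np.ones((n, 1))
    X_red = np.hstack([ones] + conditioning)
    X_full = np.hstack([ones, tested] + conditioning)
    for name, block in (("tested", tested), *(("conditioning", c) for c in conditioning)):
        if any(np.array_equal(block[:, j], y) for j in range(block.shape[1])):
            raise CollinearityError(
                f"{name} term is identical to the response (model {formula_id})"
            )
    _check_rank(X_red, "conditioning")
    _check_rank(X_full, "tested + conditioning")

    full = sm.OLS(y, X_full).fit()
    red = sm.OLS(y, X_red).fit()
    q = tested.shape[1]
    df_den = n - X_full.shape[1]
    if df_den <= 0:
        raise CollinearityError("no residual degrees of freedom")
    if full.ssr <= 0:
        f_stat, p = (0.0, 1.0) if red.ssr <= 0 else (math.inf, 0.0)
    else:
        f_stat = ((red.ssr - full.ssr) / q) / (full.ssr / df_den)
        f_stat = max(f_stat, 0.0)
        p = float(stats.f.sf(f_stat, q, df_den))
    return RegressionFit(
        formula_id=formula_id,
        params=np.asarray(full.params),
        resid_var=float(full.ssr / df_den),
        p_dependent=p,
        f_stat=float(f_stat),
        df_num=q,
        df_den=df_den,
    )


def fit_model(formula_id: int, dips, r, t, coding: str = "categorical") -> RegressionFit:
    """Fit one of the four CIT regressions and test its leading term.

    The tested term is D in models 1, 2 and 4 and R in model 3; conditioning
    terms are as tabulated in the module docstring. Rank-deficient designs
    (e.g. R an exact linear function of the D columns) raise
    :class:`CollinearityError`.
    """
    r = np.asarray(r, dtype=float)
    t = np.asarray(t, dtype=float)
    D, _ = _dip_columns(dips, coding)
    if formula_id == 1:
        return _partial_f(t, D, [], 1)
    if formula_id == 2:
        return _partial_f(r, D, [t.reshape(-1, 1)], 2)
    if formula_id == 3:
        return _partial_f(t, r.reshape(-1, 1), [D], 3)
    if formula_id == 4:
        return _partial_f(t, D, [r.reshape(-1, 1)], 4)
    raise ValueError(f"formula_id must be 1..4, got {formula_id}")


def cit_forward(
    dips, r, t, alpha: float = 0.05, coding: str = "categorical", early_stop: bool = True
) -> dict:
    """Run Tests 1-4 on (D, R, T).

    With ``early_stop`` (the default), a failed Test 2 (p2 >= alpha) leaves
    Tests 3 and 4 not assessed (NaN), matching the reporting convention for
    screened-out pairs.
    """
    fits = {1: fit_model(1, dips, r, t, coding), 2: fit_model(2, dips, r, t, coding)}
    p = {"p1": fits[1].p_dependent, "p2": fits[2].p_dependent}
    if early_stop and p["p2"] >= alpha:
        p["p3"] = p["p4"] = float("nan")
    else:
        fits[3] = fit_model(3, dips, r, t, coding)
        fits[4] = fit_model(4, dips, r, t, coding)
        p["p3"] = fits[3].p_dependent
        p["p4"] = fits[4].p_dependent
    p["fits"] = fits
    return p


def cit_reverse(
    dips, r, t, alpha: float = 0.05, coding: str = "categorical", early_stop: bool = True
) -> dict:
    """The battery with R and T exchanged: does T mediate the effect on R?"""
    return cit_forward(dips, t, r, alpha=alpha, coding=coding, early_stop=early_stop)


def _sig(p, alpha) -> bool:
    return p is not None and not math.isnan(p) and p < alpha


def _nonsig(p, alpha) -> bool:
    return p is not None and not math.isnan(p) and p >= alpha


def classify(
    p1,
    p2,
    p3,
    p4,
    p2r=None,
    p3r=None,
    p4r=None,
    alpha: float = 0.05,
    marginal_band: tuple[float, float] = MARGINAL_BAND,
) -> str:
    """Assign a relationship label from the forward (and optional reverse) p-values.

    Rule table (total over every p-value pattern):

    * p1 >= alpha: trait not diplotype-associated — ``not_assessed``.
    * p2 >= alpha: the forward battery stops; if the reverse battery was run
      and fully passes (p2r, p3r < alpha, p4r >= alpha) the triplet is
      ``reactive`` (the trait mediates the effect on expression), otherwise
      ``not_assessed``.
    * p2 < alpha, p3 < alpha, p4 >= alpha: ``causal``.
    * p2 < alpha, p3 in the marginal band, p4 >= alpha: ``causal_marginal``.
    * p2 < alpha, p3 >= alpha, p4 < alpha: ``independent``.
    * p2 < alpha, p3 < alpha, p4 < alpha: ambiguous — ``reactive`` only if a
      supplied reverse battery fully passes, else ``undetermined``.
    * remaining patterns: ``undetermined``.

    ``p1=None`` means Test 1 was pre-screened elsewhere and treated as
    passed. Reverse p-values left as ``None``/NaN count as "not run".
    """
    reverse_passes = _sig(p2r, alpha) and _sig(p3r, alpha) and _nonsig(p4r, alpha)
    if p1 is not None and not _sig(p1, alpha):
        return NOT_ASSESSED
    if not _sig(p2, alpha):
        return REACTIVE if reverse_passes else NOT_ASSESSED
    p3_sig = _sig(p3, alpha)
    p4_sig = _sig(p4, alpha)
    p3_marginal = (
        p3 is not None
        and not math.isnan(p3)
        and marginal_band[0] <= p3 < marginal_band[1]
    )
    if p3_sig and not p4_sig:
        return CAUSAL
    if p3_marginal and not p4_sig:
        return CAUSAL_MARGINAL
    if not p3_sig and p4_sig:
        return INDEPENDENT
    if p3_sig and p4_sig:
        return REACTIVE if reverse_passes else UNDETERMINED
    return UNDETERMINED


@dataclass
class CITResult:
    """Results of one fitted causal inference test."""

    gene: str
    trait: str
    n: int
    coding: str
    alpha: float
    marginal_band: tuple[float, float]
    p1: float
    p2: float
    p3: float
    p4: float
    p2r: float = float("nan")
    p3r: float = float("nan")
    p4r: float = float("nan")
    label: str = UNDETERMINED
    fits: dict = field(default_factory=dict, repr=False)
    reverse_fits: dict = field(default_factory=dict, repr=False)

    @property
    def p3_assessed(self) -> bool:
        return not math.isnan(self.p3)

    @property
    def p4_assessed(self) -> bool:
        return not math.isnan(self.p4)

    def as_row(self) -> dict:
        return {
            "gene": self.gene,
            "trait": self.trait,
            "p1": self.p1,
            "p2": self.p2,
            "p3": self.p3,
            "p4": self.p4,
            "p2r": self.p2r,
            "p3r": self.p3r,
            "p4r": self.p4r,
            "label": self.label,
        }

    def summary(self) -> str:
        def fmt(p):
            return "NA" if p is None or math.isnan(p) else f"{p:.3g}"

        lines = [
            f"Causal inference test: {self.gene} x {self.trait}",
            f"  n = {self.n}, coding = {self.coding}, alpha = {self.alpha:g}",
            f"  Test 1  D -> T          p = {fmt(self.p1)}",
            f"  Test 2  D -> R | T      p = {fmt(self.p2)}",
            f"  Test 3  R -> T | D      p = {fmt(self.p3)}",
            f"  Test 4  D -> T | R      p = {fmt(self.p4)}",
        ]
        if not math.isnan(self.p2r):
            lines.append(
                f"  Reverse battery (R<->T): p2r = {fmt(self.p2r)}, "
                f"p3r = {fmt(self.p3r)}, p4r = {fmt(self.p4r)}"
            )
        lines.append(f"  Relationship: {self.label}")
        return "\n".join(lines)


class CIT:
    """Causal-inference-test model for one (gene, trait) pair.

    Parameters
    ----------
    trait, expression : array-like
        Per-individual trait and expression values, aligned.
    diplotype : array-like of str
        Diplotype labels ("B/B", "B/C", "C/C"); all three classes required.
    litter : array-like of str, optional
        Litter labels. When given, trait and expression are residualized on
        the litter factor before any regression.
    coding : {"categorical", "additive"}
        How diplotype enters the regressions.

    ``fit()`` runs the forward battery, runs the role-swapped reverse battery
    whenever the forward pattern requires it for labelling (a failed Test 2,
    or all conditional tests rejecting), and returns a :class:`CITResult`.
    """

    def __init__(
        self,
        trait,
        expression,
        diplotype,
        litter=None,
        coding: str = "categorical",
        gene_name: str = "expr",
        trait_name: str = "trait",
    ):
        t = np.asarray(trait, dtype=float)
        r = np.asarray(expression, dtype=float)
        dips = validate(diplotype)
        if not (len(t) == len(r) == len(dips)):
            raise ValueError("trait, expression and diplotype must be aligned")
        if len(t) < 6:
            raise ValueError(f"need >= 6 individuals, got {len(t)}")
        require_all_classes(dips)
        if coding not in CODINGS:
            raise ValueError(f"unknown coding {coding!r}")
        if litter is not None:
            t = residualize_by_litter(t, litter, source=trait_name).values
            r = residualize_by_litter(r, litter, source=gene_name).values
        self.trait = t
        self.expression = r
        self.diplotype = dips
        self.coding = coding
        self.gene_name = gene_name
        self.trait_name = trait_name

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        gene: str,
        trait: str,
        diplotype_col: str = "diplotype",
        litter_col: str | None = "litter",
        coding: str = "categorical",
    ) -> "CIT":
        cols = [gene, trait, diplotype_col] + (
            [litter_col] if litter_col and litter_col in data.columns else []
        )
        sub = data[cols].dropna()
        litter = (
            sub[litter_col].to_numpy(object)
            if litter_col and litter_col in sub.columns
            else None
        )
        return cls(
            trait=sub[trait].to_numpy(float),
            expression=sub[gene].to_numpy(float),
            diplotype=sub[diplotype_col].to_numpy(object),
            litter=litter,
            coding=coding,
            gene_name=gene,
            trait_name=trait,
        )

    def fit(
        self,
        alpha: float = 0.05,
        marginal_band: tuple[float, float] = MARGINAL_BAND,
        run_reverse: str = "auto",
    ) -> CITResult:
        """Run the battery and label the triplet.

        ``run_reverse`` is ``"auto"`` (run the reverse battery only when the
        forward pattern needs it), ``"always"`` or ``"never"``.
        """
        fwd = cit_forward(
            self.diplotype, self.expression, self.trait, alpha=alpha, coding=self.coding
        )
        p1, p2, p3, p4 = fwd["p1"], fwd["p2"], fwd["p3"], fwd["p4"]
        needs_reverse = _sig(p1, alpha) and (
            not _sig(p2, alpha) or (_sig(p2, alpha) and _sig(p3, alpha) and _sig(p4, alpha))
        )
        rev: dict = {}
        if run_reverse == "always" or (run_reverse == "auto" and needs_reverse):
            rev = cit_reverse(
                self.diplotype, self.expression, self.trait, alpha=alpha, coding=self.coding
            )
        p2r = rev.get("p2", float("nan"))
        p3r = rev.get("p3", float("nan"))
        p4r = rev.get("p4", float("nan"))
        label = classify(
            p1, p2, p3, p4, p2r, p3r, p4r, alpha=alpha, marginal_band=marginal_band
        )
        return CITResult(
            gene=self.gene_name,
            trait=self.trait_name,
            n=len(self.trait),
            coding=self.coding,
            alpha=alpha,
            marginal_band=marginal_band,
            p1=p1,
            p2=p2,
            p3=p3,
            p4=p4,
            p2r=p2r,
            p3r=p3r,
            p4r=p4r,
            label=label,
            fits=fwd["fits"],
            reverse_fits=rev.get("fits", {}),
        )


def run_battery(
    data: pd.DataFrame,
    genes,
    traits,
    alpha: float = 0.05,
    coding: str = "categorical",
    diplotype_col: str = "diplotype",
    litter_col: str | None = "litter",
    marginal_band: tuple[float, float] = MARGINAL_BAND,
) -> pd.DataFrame:
    """Run the CIT for every gene x trait pair of a merged individual table.

    Returns one row per pair with the forward and (where run) reverse
    p-values and the relationship label. Pairs whose trait fails Test 1 are
    labelled ``not_assessed``.
    """
    rows = []
    for trait in traits:
        for gene in genes:
            model = CIT.from_dataframe(
                data,
                gene=gene,
                trait=trait,
                diplotype_col=diplotype_col,
                litter_col=litter_col,
                coding=coding,
            )
            res = model.fit(alpha=alpha, marginal_band=marginal_band)
            rows.append(res.as_row())
    return pd.DataFrame(
        rows,
        columns=["gene", "trait", "p1", "p2", "p3", "p4", "p2r", "p3r", "p4r", "label"],
    )
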