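"""Synthetic F2-intercross datasets with known mediation structure.

The generator emulates the selected-set design of an F2 intercross between a
subcongenic strain and its background strain: litter-matched sets of three
males, one per diplotype (B/B, B/C, C/C), drawn from a small number of
litters. A shared litter shift is added to both the expression mediator and
the trait, so litter acts as a genuine nuisance factor that downstream
residualization must remove.

Three mediation architectures relate diplotype ``D`` (C-dosage 0/1/2),
expression ``R`` and trait ``T``:

``causal``       D -> R -> T      (R mediates the genotype effect)
``reactive``     D -> T -> R      (expression responds to the trait)
``independent``  D -> R, D -> T   (parallel effects, no mediation)
``null``         no genotype effect on either variable

Structural equations (litter shift ``L ~ N(0, sigma_litter)`` per litter):

causal:       R = a0 + L + a1*D + N(0, sigma_r)
              T = b0 + L + b1*R + N(0, sigma_t)
reactive:     T = b0 + L + b1*D + N(0, sigma_t)
              R = a0 + L + a1*T + N(0, sigma_r)
independent:  R = a0 + L + a1*D + N(0, sigma_r)
              T = b0 + L + b1*D + N(0, sigma_t)
null:         as independent with a1 = b1 = 0
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .diplotype import DIPLOTYPES, dosage

ARCHITECTURES = ("causal", "reactive", "independent", "null")


class SyntheticConfigError(ValueError):
    """Raised for an invalid generator configuration."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Configuration of the synthetic intercross generator.

    Defaults mirror the study design (five diplotype-complete sets of three
    littermate males drawn from four litters) with unit effect sizes and unit
    noise; power simulations scale ``n_sets`` up.

    Parameters
    ----------
    architecture : {"causal", "reactive", "independent", "null"}
        Ground-truth mediation structure.
    n_sets, n_litters : int
        Number of diplotype-complete sets and of litters; sets are assigned
        to litters round-robin.
    a0, a1 : float
        Intercept and per-C-dosage (causal/independent) or per-trait-unit
        (reactive) effect on expression, in expression units.
    b0, b1 : float
        Intercept and per-expression-unit (causal) or per-C-dosage
        (reactive/independent) effect on the trait, in trait units.
    sigma_r, sigma_t, sigma_litter : float
        Residual standard deviations of expression and trait, and the SD of
        the per-litter shift added to both.
    n_extra_genes : int
        Extra non-mediating, diplotype-associated expression columns
        (``indep_1`` ...), generated like the independent architecture's R.
    n_null_genes : int
        Extra expression columns with no genotype effect (``null_1`` ...).
    seed : int
        Seed of the generator's own random stream.
    """

    architecture: str = "causal"
    n_sets: int = 5
    n_litters: int = 4
    a0: float = 1.0
    a1: float = 1.0
    b0: float = 0.0
    b1: float = 1.0
    sigma_r: float = 1.0
    sigma_t: float = 1.0
    sigma_litter: float = 1.0
    n_extra_genes: int = 0
    n_null_genes: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise SyntheticConfigError(
                f"unknown architecture {self.architecture!r}; expected one of {ARCHITECTURES}"
            )
        if self.n_sets < 1 or self.n_litters < 1:
            raise SyntheticConfigError("n_sets and n_litters must be >= 1")
        for name in ("sigma_r", "sigma_t", "sigma_litter"):
            if getattr(self, name) < 0:
                raise SyntheticConfigError(f"{name} must be >= 0")
        if self.n_extra_genes < 0 or self.n_null_genes < 0:
            raise SyntheticConfigError("gene counts must be >= 0")


@dataclass
class SyntheticDataset:
    """A generated dataset: individuals, trait table, expression table, truth."""

    individuals: pd.DataFrame  # individual_id, litter, set, diplotype
    traits: pd.DataFrame  # indexed like individuals; trait columns
    expression: pd.DataFrame  # indexed like individuals; gene columns
    truth: str
    config: SyntheticConfig = field(repr=False, default=None)

    @property
    def frame(self) -> pd.DataFrame:
        """Individuals merged with trait and expression columns (CIT input layout)."""
        return pd.concat([self.individuals, self.expression, self.traits], axis=1)

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write trait and expression tables as TSV; returns the paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, table in (("traits", self.traits), ("expression", self.expression)):
            path = outdir / f"{name}.tsv"
            pd.concat([self.individuals, table], axis=1).to_csv(
                path, sep="\t", index=False
            )
            paths[name] = path
        return paths


def generate(config: SyntheticConfig) -> SyntheticDataset:
    """Generate one synthetic dataset under the configured architecture.

    Deterministic: identical configs (including seed) give identical tables.
    Every set contains exactly one individual of each diplotype, and sets are
    assigned to litters round-robin, so a litter may contribute several sets
    (as in the study, where one litter contributed two).
    """
    rng = np.random.default_rng(config.seed)
    n = 3 * config.n_sets

    sets = np.repeat(np.arange(1, config.n_sets + 1), 3)
    litters = np.array([f"L{(s - 1) % config.n_litters + 1}" for s in sets])
    dips = np.array(list(DIPLOTYPES) * config.n_sets, dtype=object)
    ids = np.array([f"F2-{i + 1:03d}" for i in range(n)])

    shift_by_litter = {
        f"L{j + 1}": rng.normal(0.0, config.sigma_litter)
        for j in range(config.n_litters)
    }
    litter_shift = np.array([shift_by_litter[l] for l in litters])
    d = dosage(dips)

    a1 = 0.0 if config.architecture == "null" else config.a1
    b1 = 0.0 if config.architecture == "null" else config.b1
    eps_r = rng.normal(0.0, config.sigma_r, size=n)
    eps_t = rng.normal(0.0, config.sigma_t, size=n)

    if config.architecture == "causal":
        r = config.a0 + litter_shift + a1 * d + eps_r
        t = config.b0 + litter_shift + b1 * r + eps_t
    elif config.architecture == "reactive":
        t = config.b0 + litter_shift + b1 * d + eps_t
        r = config.a0 + litter_shift + a1 * t + eps_r
    else:  # independent / null
        r = config.a0 + litter_shift + a1 * d + eps_r
        t = config.b0 + litter_shift + b1 * d + eps_t

    expression = {"expr": r}
    for k in range(config.n_extra_genes):
        expression[f"indep_{k + 1}"] = (
            config.a0
            + litter_shift
            + config.a1 * d
            + rng.normal(0.0, config.sigma_r, size=n)
        )
    for k in range(config.n_null_genes):
        expression[f"null_{k + 1}"] = (
            config.a0 + litter_shift + rng.normal(0.0, config.sigma_r, size=n)
        )

    individuals = pd.DataFrame(
        {"individual_id": ids, "litter": litters, "set": sets, "diplotype": dips}
    )
    return SyntheticDataset(
        individuals=individuals,
        traits=pd.DataFrame({"trait": t}),
        expression=pd.DataFrame(expression),
        truth=config.architecture,
        config=config,
    )


def generate_replicates(config: SyntheticConfig, n_replicates: int, seed: int):
    """Yield independent replicate datasets with seeds derived from ``seed``."""
    ss = np.random.SeedSequence(seed)
    for child in ss.spawn(n_replicates):
        child_seed = int(child.generate_state(1)[0] % (2**31))
        yield generate(replace(config, seed=child_seed))
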