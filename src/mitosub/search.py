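"""Exhaustive omit/include/partition model search ranked by aggregated AIC.

Every categorical factor can be omitted, included as an explanatory
variable, or used to partition the data into independently fitted
sub-models; the AIC of a partitioned model is the sum of its sub-models'
AICs (AIC is linear in log-likelihood and parameter count).  Three rules
prune specifications that are contained in another model:

* the codon determines both the amino acid and the nucleotide, so when the
  codon is included or partitioned on, those two factors are omitted
  (11 joint options instead of 27);
* gene and gene-cluster are never both present (5 instead of 9);
* when partitioning by codon position the two neighbor factors are coerced
  to share one inclusion option (21 instead of 27).

For the protein-coding factor set with three response schemes this yields
11 * 5 * 21 * 27 = 31,185 specifications; rRNA and control-region sets
yield 486 each and tRNA (which adds directionality) 1,458.  Specifications
where one factor determines another (gene together with directionality)
are flagged as redundant but kept, so enumeration counts are stable.

Every sub-model is fitted under both Poisson and NB2 families for every
response in the scheme; non-converged and degenerate fits are scored by a
saturated per-state Poisson fallback so the search always completes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exposure import StateExposureTable, response_offsets
from .glm import FitResult, PredictorSpec, fit_families

OMIT, INCLUDE, PARTITION = "omit", "include", "partition"
OPTIONS = (OMIT, INCLUDE, PARTITION)

PROTEIN_FACTORS = (
    "codon",
    "amino_acid",
    "nucleotide",
    "gene",
    "cluster",
    "codon_position",
    "left_neighbor",
    "right_neighbor",
    "directionality",
    "cpg",
)
#: rRNA/control factor set; ``gene`` doubles as the control-region
#: sub-region factor (sub-regions are annotated as the "genes" there)
NONCODING_FACTORS = ("cpg", "left_neighbor", "right_neighbor", "gene", "nucleotide")
TRNA_FACTORS = NONCODING_FACTORS + ("directionality",)

RESPONSE_SCHEMES = {
    "ALL": ("all",),
    "TS_TV": ("ts", "tv"),
    "SYN_NONSYN": ("syn", "nonsyn"),
}

FACTOR_SETS = {
    "protein_coding": PROTEIN_FACTORS,
    "rRNA": NONCODING_FACTORS,
    "control": NONCODING_FACTORS,
    "tRNA": TRNA_FACTORS,
}
SCHEME_SETS = {
    "protein_coding": ("ALL", "TS_TV", "SYN_NONSYN"),
    "rRNA": ("ALL", "TS_TV"),
    "control": ("ALL", "TS_TV"),
    "tRNA": ("ALL", "TS_TV"),
}


@dataclass(frozen=True)
class ModelSpec:
    """One point of the model space: an inclusion option per factor plus a
    response scheme."""

    region_class: str
    inclusions: tuple[tuple[str, str], ...]  # (factor, option), fixed order
    response_scheme: str
    redundancy_flag: bool = False

    @property
    def options(self) -> dict[str, str]:
        return dict(self.inclusions)

    def option(self, factor: str) -> str:
        return self.options.get(factor, OMIT)

    def key(self) -> tuple:
        return (self.response_scheme, self.inclusions)

    def describe(self) -> str:
        parts = [f"{f}={o}" for f, o in self.inclusions if o != OMIT]
        return f"{self.region_class}[{self.response_scheme}] " + ", ".join(parts)


def spec_is_valid(options: Mapping[str, str]) -> bool:
    """Apply the containment-pruning rules to a factor->option assignment."""
    opt = lambda f: options.get(f, OMIT)
    if opt("codon") != OMIT and (
        opt("amino_acid") != OMIT or opt("nucleotide") != OMIT
    ):
        return False
    if opt("gene") != OMIT and opt("cluster") != OMIT:
        return False
    if (
        "left_neighbor" in options
        and "right_neighbor" in options
        and opt("codon_position") == PARTITION
        and opt("left_neighbor") != opt("right_neighbor")
    ):
        return False
    return True


def _is_redundant(options: Mapping[str, str]) -> bool:
    # gene identity determines directionality (only ND6 is light-strand)
    return (
        options.get("gene", OMIT) != OMIT
        and options.get("directionality", OMIT) != OMIT
    )


def enumerate_models(
    region_class: str,
    factors: Sequence[str] | None = None,
    response_schemes: Sequence[str] | None = None,
) -> list[ModelSpec]:
    """Enumerate every valid specification for a region class.

    ``factors``/``response_schemes`` may restrict the space for reduced
    searches; the pruning rules are applied among whichever factors are
    present.
    """
    if region_class not in FACTOR_SETS:
        raise ValueError(f"unknown region class {region_class!r}")
    factors = tuple(factors) if factors is not None else FACTOR_SETS[region_class]
    schemes = (
        tuple(response_schemes)
        if response_schemes is not None
        else SCHEME_SETS[region_class]
    )
    if "SYN_NONSYN" in schemes and region_class != "protein_coding":
        raise ValueError("SYN_NONSYN responses require protein-coding data")
    specs = []
    for assignment in product(OPTIONS, repeat=len(factors)):
        options = dict(zip(factors, assignment))
        if not spec_is_valid(options):
            continue
        for scheme in schemes:
            specs.append(
                ModelSpec(
                    region_class=region_class,
                    inclusions=tuple(zip(factors, assignment)),
                    response_scheme=scheme,
                    redundancy_flag=_is_redundant(options),
                )
            )
    return specs


# ---------------------------------------------------------------------------
# Sub-model expansion


@dataclass
class SubModel:
    data: pd.DataFrame
    predictors: PredictorSpec
    partition_values: tuple[tuple[str, str], ...]


def expand_submodels(
    spec: ModelSpec,
    table: StateExposureTable,
) -> list[SubModel]:
    """Split the table by the spec's partition factors and build predictors.

    Only factor values realized in the data spawn sub-models.  Site
    covariates are always numeric predictors.  When the codon is in the
    model and the data is partitioned by codon position, neighbor
    predictors keep only the out-of-codon side: left neighbor at position
    1, right neighbor at position 3, neither at position 2.
    """
    df = table.data
    options = spec.options
    part_factors = [f for f, o in spec.inclusions if o == PARTITION]
    incl_factors = [f for f, o in spec.inclusions if o == INCLUDE]

    def predictors_for(part_vals: dict[str, str]) -> PredictorSpec:
        cats = list(incl_factors)
        if (
            options.get("codon", OMIT) != OMIT
            and options.get("codon_position") == PARTITION
        ):
            pos = int(part_vals["codon_position"])
            drop = {1: ["right_neighbor"], 2: ["left_neighbor", "right_neighbor"], 3: ["left_neighbor"]}[pos]
            cats = [c for c in cats if c not in drop]
        return PredictorSpec(
            categorical=cats, numeric=list(table.covariate_columns)
        )

    if not part_factors:
        return [SubModel(df, predictors_for({}), ())]
    out = []
    for values, sub in df.groupby(part_factors, sort=True, observed=True):
        if not isinstance(values, tuple):
            values = (values,)
        part_vals = {f: v for f, v in zip(part_factors, values)}
        out.append(
            SubModel(
                sub,
                predictors_for(part_vals),
                tuple((f, str(v)) for f, v in part_vals.items()),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Fallback scoring


def saturated_poisson_loglik(counts: np.ndarray) -> float:
    """Log-likelihood of the saturated per-state Poisson (lambda_i = c_i)."""
    c = np.asarray(counts, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        clogc = np.where(c > 0, c * np.log(np.maximum(c, 1.0)), 0.0)
    return float(np.sum(-c + clogc - [math.lgamma(x + 1) for x in c]))


def fallback_score(counts: Sequence[float]) -> tuple[float, int]:
    """(log-likelihood, degrees of freedom) for degenerate/non-converged sub-models.

    Sub-models with zero substitutions score (0, 1); a single state with at
    least one substitution gets the saturated Poisson likelihood with one
    degree of freedom; otherwise the saturated per-state Poisson is used
    with one degree of freedom per state.
    """
    c = np.asarray(counts, dtype=float)
    n_states = len(c)
    total = c.sum()
    if total == 0:
        return 0.0, 1
    if n_states == 1:
        return saturated_poisson_loglik(c), 1
    return saturated_poisson_loglik(c), n_states


# ---------------------------------------------------------------------------
# Scoring and ranking


@dataclass
class ModelScore:
    spec: ModelSpec
    aic_poisson: float
    aic_negbin: float
    n_submodels: int
    n_params: dict[str, int]
    n_nonconverged: dict[str, int]
    fits: list[FitResult] | None = None

    @property
    def min_aic(self) -> float:
        return min(self.aic_poisson, self.aic_negbin)

    @property
    def best_family(self) -> str:
        return "poisson" if self.aic_poisson <= self.aic_negbin else "negbin"


def score_model(
    spec: ModelSpec,
    table: StateExposureTable,
    r: float = 0.0,
    families: Sequence[str] = ("poisson", "negbin"),
    keep_fits: bool = False,
) -> ModelScore:
    """Fit every sub-model for every response of the scheme and sum AICs.

    Degenerate sub-models (one usable state, or zero substitutions) and
    non-converged fits are scored by :func:`fallback_score`; failures are
    recorded, never raised, so a full search always completes.
    """
    submodels = expand_submodels(spec, table)
    modes = RESPONSE_SCHEMES[spec.response_scheme]
    aic = {fam: 0.0 for fam in families}
    n_params = {fam: 0 for fam in families}
    n_nonconv = {fam: 0 for fam in families}
    kept: list[FitResult] = []
    for sub in submodels:
        for mode in modes:
            col, offset, mask = response_offsets(sub.data, mode, r)
            if mask.all():
                data, off = sub.data, offset
            else:
                data, off = sub.data.loc[mask], offset[mask]
            y = data[col].to_numpy(dtype=float)
            degenerate = len(y) <= 1 or y.sum() == 0
            if degenerate:
                ll, dof = fallback_score(y if len(y) else [0.0])
                for fam in families:
                    aic[fam] += 2 * dof - 2 * ll
                    n_params[fam] += dof
                continue
            fits = fit_families(data, col, sub.predictors, off, families)
            for fam in families:
                fit = fits[fam]
                if fit.converged and np.isfinite(fit.aic):
                    aic[fam] += fit.aic
                    n_params[fam] += fit.n_params
                    if keep_fits:
                        kept.append(fit)
                else:
                    ll, dof = fallback_score(y)
                    aic[fam] += 2 * dof - 2 * ll
                    n_params[fam] += dof
                    n_nonconv[fam] += 1
    return ModelScore(
        spec=spec,
        aic_poisson=aic.get("poisson", np.inf),
        aic_negbin=aic.get("negbin", np.inf),
        n_submodels=len(submodels),
        n_params=n_params,
        n_nonconverged=n_nonconv,
        fits=kept if keep_fits else None,
    )


def search_models(
    table: StateExposureTable,
    region_class: str,
    r: float = 0.0,
    factors: Sequence[str] | None = None,
    response_schemes: Sequence[str] | None = None,
    families: Sequence[str] = ("poisson", "negbin"),
    max_models: int | None = None,
    seed: int | None = None,
) -> list[ModelScore]:
    """Score every enumerated spec (optionally a seeded random sample)."""
    specs = enumerate_models(region_class, factors, response_schemes)
    if max_models is not None and max_models < len(specs):
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(specs), size=max_models, replace=False)
        specs = [specs[i] for i in sorted(idx)]
    return [score_model(spec, table, r=r, families=families) for spec in specs]


def rank_models(scores: Iterable[ModelScore]) -> pd.DataFrame:
    """Ranked report: ascending min AIC, ties by fewer parameters then spec order.

    One column per factor holds ``partition``/``include``/``omit`` marks in
    the style of the published model tables.
    """
    scores = list(scores)
    if not scores:
        raise ValueError("no scores to rank")

    def sort_key(s: ModelScore):
        return (
            s.min_aic,
            s.n_params.get(s.best_family, 0),
            s.spec.key(),
        )

    ranked = sorted(scores, key=sort_key)
    factors = [f for f, _ in ranked[0].spec.inclusions]
    rows = []
    for rank, s in enumerate(ranked, start=1):
        row = {"rank": rank, "response": s.spec.response_scheme}
        row.update({f: s.spec.option(f) for f in factors})
        row.update(
            {
                "aic_poisson": s.aic_poisson,
                "aic_negbin": s.aic_negbin,
                "min_aic": s.min_aic,
                "best_family": s.best_family,
                "n_submodels": s.n_submodels,
                "redundant": s.spec.redundancy_flag,
            }
        )
        rows.append(row)
    return pd.DataFrame(rows)
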