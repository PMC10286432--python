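"""Declarative model variants for disconnected-region spatial smoothing.

The study map splits into disconnected regions (connected components of the
adjacency graph).  The variants differ in how the BYM random effects and the
intercept treat that split:

=======  ==================  ===============  ==============  ==============
variant  intercept           constraint       ICAR scaling    random effects
=======  ==================  ===============  ==============  ==============
I        common              single (joint)   global          shared
II       common              per region       per component   shared
III      per region          per region       per component   shared
IVa      common              per region       per component   split per region
IVb      per region          per region       per component   split per region
V        single-region fit   per region       per component   (one region)
=======  ==================  ===============  ==============  ==============

"Split" means each region gets its own structured (ICAR) and unstructured
(iid) block with its own precision, fitted jointly so a single DIC/WAIC is
obtained.  Priors follow common INLA defaults: effectively flat Gaussian on
intercepts, N(0, precision 0.001) on covariate effects, and Gamma(0.5,
rate 0.005) on every random-effect precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .graph import AdjacencyGraph

__all__ = ["ModelSpec", "Priors", "make_model", "design_matrix", "VARIANTS"]


@dataclass(frozen=True)
class Priors:
    intercept_precision: float = 1e-12  # numerical proxy for a flat prior
    beta_precision: float = 1e-3
    precision_shape: float = 0.5
    precision_rate: float = 0.005


# variant -> (intercept_structure, constraint_mode, scaling_mode, split)
VARIANTS = {
    "I": ("common", "single", "global", False),
    "II": ("common", "per_region", "per_component", False),
    "III": ("per_region", "per_region", "per_component", False),
    "IVa": ("common", "per_region", "per_component", True),
    "IVb": ("per_region", "per_region", "per_component", True),
    "V": ("common", "per_region", "per_component", False),
}


@dataclass(frozen=True)
class ModelSpec:
    """Structural specification of one model variant.

    ``covariates`` is an ordered tuple of terms: a plain column name gives a
    common slope, ``"name:region"`` expands to one slope per region
    (covariate-by-region interaction).  ``region`` selects the component for
    a single-region (variant V) fit.
    """

    variant: str
    intercept_structure: str
    constraint_mode: str
    scaling_mode: str
    split_random_effects: bool
    covariates: tuple = ()
    region: int | None = None
    priors: Priors = field(default_factory=Priors)
    standardize_covariates: bool = True

    def with_covariates(self, covariates) -> "ModelSpec":
        return replace(self, covariates=tuple(covariates))

    def n_hyperparameters(self, graph: AdjacencyGraph) -> int:
        if self.variant == "V":
            return 2
        return 2 * graph.n_components if self.split_random_effects else 2


def make_model(
    variant: str,
    graph: AdjacencyGraph,
    covariates=(),
    region: int | None = None,
    **overrides,
) -> ModelSpec:
    """Build a ModelSpec, validating the variant against the graph."""
    if variant not in VARIANTS:
        raise ValueError(f"unknown model variant {variant!r}; choose from {sorted(VARIANTS)}")
    intercept, constraint, scaling, split = VARIANTS[variant]
    if variant in ("IVa", "IVb") and graph.n_components < 2:
        raise ValueError(
            f"variant {variant} needs a disconnected graph (>=2 components); "
            f"this graph has {graph.n_components}"
        )
    if variant == "V":
        if region is None:
            raise ValueError("variant V needs the region (component index) to fit")
        if not (0 <= region < graph.n_components):
            raise ValueError(
                f"region {region} does not exist; graph has {graph.n_components} component(s)"
            )
    elif region is not None:
        raise ValueError("region is only meaningful for variant V")
    spec = ModelSpec(
        variant=variant,
        intercept_structure=intercept,
        constraint_mode=constraint,
        scaling_mode=scaling,
        split_random_effects=split,
        covariates=tuple(covariates),
        region=region,
    )
    if overrides:
        spec = replace(spec, **overrides)
    return spec


def _standardize(x: np.ndarray, name: str) -> np.ndarray:
    sd = x.std(ddof=0)
    if sd == 0:
        raise ValueError(f"covariate {name!r} is constant")
    return (x - x.mean()) / sd


def design_matrix(
    spec: ModelSpec,
    graph: AdjacencyGraph,
    covariate_table: pd.DataFrame | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Fixed-effect design for the area-level model.

    Columns: intercept block (one column of ones, or one indicator per
    region), then covariate terms.  Covariates are z-scored by default so
    the weakly-informative slope prior is unit-independent.  The matrix must
    have full column rank.
    """
    n = graph.n_areas
    labels = np.asarray(graph.component_labels)
    cols, names = [], []
    if spec.intercept_structure == "common":
        cols.append(np.ones(n))
        names.append("intercept")
    else:
        for c in range(graph.n_components):
            cols.append((labels == c).astype(float))
            names.append(f"intercept:region{c}")

    if spec.covariates:
        if covariate_table is None:
            raise ValueError("model has covariates but no covariate table was given")
        missing_areas = [a for a in graph.area_ids if a not in covariate_table.index]
        if missing_areas:
            raise ValueError(f"covariate table missing areas {missing_areas[:5]!r}")
        tab = covariate_table.loc[list(graph.area_ids)]
        for term in spec.covariates:
            by_region = term.endswith(":region")
            name = term[: -len(":region")] if by_region else term
            if name not in tab.columns:
                raise ValueError(f"unknown covariate {name!r}")
            x = tab[name].to_numpy(dtype=float)
            if np.isnan(x).any():
                bad = [a for a, v in zip(graph.area_ids, x) if np.isnan(v)]
                raise ValueError(f"covariate {name!r} missing for areas {bad[:5]!r}")
            if spec.standardize_covariates:
                x = _standardize(x, name)
            if by_region:
                for c in range(graph.n_components):
                    cols.append(np.where(labels == c, x, 0.0))
                    names.append(f"{name}:region{c}")
            else:
                cols.append(x)
                names.append(name)

    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient (collinear columns)")
    return X, names


def fixed_effect_prior_precisions(spec: ModelSpec, names: list[str]) -> np.ndarray:
    """Prior precision per fixed-effect column (flat intercepts, 0.001 slopes)."""
    return np.array(
        [
            spec.priors.intercept_precision if nm.startswith("intercept") else spec.priors.beta_precision
            for nm in names
        ]
    )
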