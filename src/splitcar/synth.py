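"""Synthetic disconnected-region survey data with known truth.

The generator emulates the study conditions the models are meant for: a map
split into two disconnected rectangular lattices (echoing an 87 + 57 district
split across a sea), area-level prevalence driven by region intercepts plus
structured (ICAR) and unstructured random effects on the logit scale, and a
two-stage stratified cluster survey (strata = region x urban/rural; PSUs
drawn proportional to size with replacement; children sampled within PSUs)
producing unequal sampling weights and a configurable share of areas with no
samples at all.

Default magnitudes: intercepts near logit(0.24) = -1.17, structured marginal
variances 0.05 / 0.20 across the two regions (a clearly present spatial
signal of the scale reported for joint BYM fits of such data, with the
factor-4 regional contrast the split models target), unstructured variance
0.05, ~868 sampled PSUs x 7 children = ~6,000 children over 140 areas, and
12.5% of areas unsampled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit
from shapely.geometry import box, mapping

from .graph import AdjacencyGraph, IcarStructure, scale_icar, write_graph

__all__ = [
    "SyntheticTruth",
    "Bundle",
    "make_lattice_regions",
    "sample_icar_field",
    "simulate_survey",
    "scenario",
    "SCENARIOS",
]


def make_lattice_regions(
    nx1: int = 12, ny1: int = 7, nx2: int = 8, ny2: int = 7, gap: float = 3.0
):
    """Two rook-adjacent rectangular lattices with no cross-region edges.

    Returns ``(graph, geometries)`` where geometries are unit-square shapely
    boxes (the second lattice offset horizontally by ``gap``), labelled
    ``R<region>_<ix>_<iy>``.  Defaults give 84 + 56 areas.
    """
    for d in (nx1, ny1, nx2, ny2):
        if d < 2:
            raise ValueError("lattice dimensions must be >= 2")
    labels, geoms, edges = [], [], []

    def add_lattice(region, nx, ny, x0):
        base = len(labels)
        for ix in range(nx):
            for iy in range(ny):
                labels.append(f"R{region}_{ix}_{iy}")
                geoms.append(box(x0 + ix, iy, x0 + ix + 1, iy + 1))
        for ix in range(nx):
            for iy in range(ny):
                k = base + ix * ny + iy
                if ix + 1 < nx:
                    edges.append((k, k + ny))
                if iy + 1 < ny:
                    edges.append((k, k + 1))

    add_lattice(1, nx1, ny1, 0.0)
    add_lattice(2, nx2, ny2, nx1 + gap)
    graph = AdjacencyGraph.from_edges(labels, edges)
    return graph, list(zip(labels, geoms))


def sample_icar_field(icar: IcarStructure, tau, rng) -> np.ndarray:
    """Draw from the scaled intrinsic field with per-component sum-to-zero.

    Each component block is drawn in its positive eigenspace (null-space
    coordinates set to zero), so every component's effects sum to zero
    exactly and the draw satisfies both the per-region and the joint
    constraint.  ``tau`` may be a scalar or one precision per component.
    """
    rng = np.random.default_rng(rng)
    comps = icar.components()
    taus = np.broadcast_to(np.asarray(tau, dtype=float), (len(comps),))
    u = np.zeros(icar.n_areas)
    for (w, V), idx, tau_c in zip(icar.component_spectra(), comps, taus):
        tol = max(1e-10, 1e-10 * w[-1])
        pos = w > tol
        z = rng.standard_normal(int(pos.sum()))
        u[idx] = V[:, pos] @ (z / np.sqrt(tau_c * w[pos]))
    return u


@dataclass
class SyntheticTruth:
    """Known data-generating state for one synthetic map."""

    graph: AdjacencyGraph
    geometries: list
    alpha: np.ndarray            # per-region intercepts
    beta: dict                   # covariate name -> effect on standardized scale
    covariates: pd.DataFrame | None
    u: np.ndarray
    v: np.ndarray
    struct_var: np.ndarray       # per-region marginal variance of u
    unstruct_var: np.ndarray
    p_true: np.ndarray
    urban_share: np.ndarray
    constraint_mode: str = "per_region"

    @property
    def region_of_area(self) -> np.ndarray:
        return np.asarray(self.graph.component_labels)

    def to_json_dict(self) -> dict:
        return {
            "area_ids": list(self.graph.area_ids),
            "region": self.region_of_area.tolist(),
            "alpha": self.alpha.tolist(),
            "beta": self.beta,
            "struct_var": self.struct_var.tolist(),
            "unstruct_var": self.unstruct_var.tolist(),
            "u": self.u.tolist(),
            "v": self.v.tolist(),
            "p_true": self.p_true.tolist(),
            "urban_share": self.urban_share.tolist(),
            "constraint_mode": self.constraint_mode,
        }


def make_truth(
    graph: AdjacencyGraph,
    geometries,
    alpha,
    struct_var,
    unstruct_var,
    beta: dict | None = None,
    rng=None,
) -> SyntheticTruth:
    """Draw latent effects and true prevalences on a given map."""
    rng = np.random.default_rng(rng)
    n = graph.n_areas
    labels = np.asarray(graph.component_labels)
    k = graph.n_components
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), (k,)).copy()
    struct_var = np.broadcast_to(np.asarray(struct_var, dtype=float), (k,)).copy()
    unstruct_var = np.broadcast_to(np.asarray(unstruct_var, dtype=float), (k,)).copy()

    icar = scale_icar(graph, mode="per_component", constraint_mode="per_region")
    u = sample_icar_field(icar, 1.0 / struct_var, rng)
    v = rng.standard_normal(n) * np.sqrt(unstruct_var[labels])

    beta = dict(beta or {})
    covariates = None
    eta = alpha[labels] + v + u
    if beta:
        cols = {}
        for name in beta:
            x = rng.standard_normal(n)
            x = (x - x.mean()) / x.std(ddof=0)
            cols[name] = x
            eta = eta + beta[name] * x
        covariates = pd.DataFrame(cols, index=list(graph.area_ids))
        covariates.index.name = "area_id"

    urban_share = rng.uniform(0.25, 0.95, size=n)
    return SyntheticTruth(
        graph=graph,
        geometries=geometries,
        alpha=alpha,
        beta=beta,
        covariates=covariates,
        u=u,
        v=v,
        struct_var=struct_var,
        unstruct_var=unstruct_var,
        p_true=expit(eta),
        urban_share=urban_share,
    )


def simulate_survey(
    truth: SyntheticTruth,
    n_psu_per_stratum: int = 217,
    units_per_psu: int = 7,
    psus_per_area: int = 12,
    psu_children_range: tuple = (30, 60),
    unsampled_fraction: float = 0.125,
    seed=None,
) -> pd.DataFrame:
    """Two-stage stratified cluster sample of individual outcomes.

    Strata are region x {urban, rural}; each area's PSUs are urban with the
    area's urban share.  PSUs are drawn with replacement proportional to
    their child count within each stratum (each draw is an independent
    replicate with its own psu label, the with-replacement convention the
    design-variance estimator expects); ``units_per_psu`` children are then
    taken per PSU hit.  Weights are inverse inclusion probabilities, so the
    weighted child total is design-unbiased for the frame total.  A fixed
    fraction of areas is removed from the frame to emulate districts with no
    samples.
    """
    rng = np.random.default_rng(seed)
    graph = truth.graph
    n = graph.n_areas
    labels = truth.region_of_area

    n_excluded = int(round(unsampled_fraction * n))
    excluded = set(rng.choice(n, size=n_excluded, replace=False).tolist()) if n_excluded else set()

    # PSU frame
    areas, urban, size = [], [], []
    lo, hi = psu_children_range
    for j in range(n):
        if j in excluded:
            continue
        areas.extend([j] * psus_per_area)
        urban.extend(rng.random(psus_per_area) < truth.urban_share[j])
        size.extend(rng.integers(lo, hi + 1, size=psus_per_area))
    frame = pd.DataFrame(
        {"area": areas, "urban": urban, "size": size, "region": labels[np.asarray(areas)]}
    )

    area_col, y_col, w_col, psu_col = [], [], [], []
    for (region, is_urban), stratum in frame.groupby(["region", "urban"]):
        sizes = stratum["size"].to_numpy(dtype=float)
        s_areas = stratum["area"].to_numpy()
        total = sizes.sum()
        draws = rng.choice(len(stratum), size=n_psu_per_stratum, p=sizes / total)
        m_d = np.minimum(units_per_psu, sizes[draws]).astype(int)
        # PSU draw weight 1/(n_psu * size/total), spread over its m sampled units
        w_d = total / (n_psu_per_stratum * m_d)
        a_d = s_areas[draws]
        reps = np.repeat(np.arange(n_psu_per_stratum), m_d)
        areas_u = np.repeat(a_d, m_d)
        y_col.append(rng.binomial(1, truth.p_true[areas_u]))
        area_col.append(areas_u)
        w_col.append(np.repeat(w_d, m_d))
        tag = f"psu_r{region}_{'u' if is_urban else 'r'}_"
        psu_col.append(np.char.add(tag, reps.astype(str)))
    area_all = np.concatenate(area_col)
    ids = np.asarray(graph.area_ids, dtype=object)
    out = pd.DataFrame(
        {
            "unit_id": [f"unit{i}" for i in range(area_all.size)],
            "area_id": ids[area_all],
            "outcome": np.concatenate(y_col).astype(int),
            "weight": np.concatenate(w_col),
            "psu_id": np.concatenate(psu_col),
        }
    )
    return out


# ---------------------------------------------------------------------------
# named scenarios
# ---------------------------------------------------------------------------

# name -> (default seed, truth parameters)
SCENARIOS = {
    # same baseline in both regions, same variances: a Model I / II world
    "homogeneous": (20151, dict(alpha=-1.17, struct_var=0.10, unstruct_var=0.06)),
    # equal intercepts but structured variance differing by a factor 4:
    # the split-random-effects (Model IVa) world
    "common_baseline": (20152, dict(alpha=-1.17, struct_var=(0.05, 0.20), unstruct_var=0.05)),
    # regional baselines differ: Model III / IVb world
    "shifted_baseline": (20153, dict(alpha=(-0.9, -1.5), struct_var=(0.05, 0.20), unstruct_var=0.05)),
    # one active standardized covariate on top of the common-baseline world
    "covariate_effect": (
        20154,
        dict(alpha=-1.17, struct_var=(0.05, 0.20), unstruct_var=0.05, beta={"x1": -0.101}),
    ),
}


@dataclass
class Bundle:
    """One generated dataset: map, truth, records, covariates."""

    name: str
    seed: int
    truth: SyntheticTruth
    records: pd.DataFrame

    @property
    def covariates(self) -> pd.DataFrame | None:
        return self.truth.covariates

    def summaries(self, **kwargs) -> pd.DataFrame:
        from .survey import summarize

        return summarize(self.records, area_ids=list(self.truth.graph.area_ids), **kwargs)

    def save(self, directory) -> None:
        """Write graph (plain-text), areas.geojson, records.csv, covariates.csv, truth.json."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        write_graph(self.truth.graph, d / "graph.txt")
        # the plain-text graph dialect is label-free; keep the ordered labels
        (d / "area_ids.txt").write_text(
            "\n".join(str(a) for a in self.truth.graph.area_ids) + "\n"
        )
        feats = [
            {
                "type": "Feature",
                "properties": {"id": lab},
                "geometry": mapping(geom),
            }
            for lab, geom in self.truth.geometries
        ]
        (d / "areas.geojson").write_text(
            json.dumps({"type": "FeatureCollection", "features": feats})
        )
        self.records.to_csv(d / "records.csv", index=False)
        if self.covariates is not None:
            self.covariates.to_csv(d / "covariates.csv")
        meta = {"name": self.name, "seed": self.seed, **self.truth.to_json_dict()}
        (d / "truth.json").write_text(json.dumps(meta))


def scenario(name: str, seed: int | None = None, lattice=(12, 7, 8, 7), **survey_kwargs) -> Bundle:
    """Generate a named scenario bundle with a documented default seed."""
    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; choose from {sorted(SCENARIOS)}")
    default_seed, params = SCENARIOS[name]
    seed = default_seed if seed is None else int(seed)
    rng = np.random.default_rng(seed)
    graph, geoms = make_lattice_regions(*lattice)
    truth = make_truth(graph, geoms, rng=rng, **params)
    records = simulate_survey(truth, seed=rng.integers(2**31 - 1), **survey_kwargs)
    return Bundle(name=name, seed=seed, truth=truth, records=records)
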