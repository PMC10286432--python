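"""File-driven runs from a plain-text ``key: value`` configuration.

Minimal glue for running the pipeline without writing Python: point the
config at a graph (plain-text dialect) or GeoJSON file, a records CSV and
optionally a covariate CSV, name the model variant, and get a fitted
result (optionally exported to CSV).

Recognized keys::

    variant: IVa                  # I | II | III | IVa | IVb | V
    region: 0                     # only for variant V
    graph: path/to/graph.txt      # or geojson: areas.geojson [id_property: id]
    area_labels: area_ids.txt     # optional: one label per graph node, in order
    records: records.csv
    covariates: covariates.csv    # optional
    use_covariates: x1, x2:region # optional terms; default none
    degeneracy_rule: continuity   # or exclude
    contiguity: queen             # or rook (geojson input only)
    grid_step: 0.5                # optional grid resolution override
    seed: 20150101                # seed for fitted-prevalence draws
    output: fitted.csv            # optional export path
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from . import graph as _graph
from .infer import fit_model
from .models import make_model
from .survey import read_records_csv, summarize

__all__ = ["load_config", "run_config"]


def load_config(path) -> dict:
    """Parse ``key: value`` lines; '#' starts a comment, blanks ignored."""
    out = {}
    for ln_no, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if ":" not in line:
            raise ValueError(f"line {ln_no}: expected 'key: value', got {raw!r}")
        key, val = line.split(":", 1)
        out[key.strip()] = val.strip()
    return out


def run_config(path):
    """Execute a configured fit; returns the FitResult."""
    cfg = load_config(path)
    base = Path(path).parent

    def resolve(p):
        p = Path(p)
        return p if p.is_absolute() else base / p

    if "graph" in cfg:
        g = _graph.read_graph(resolve(cfg["graph"]))
        if "area_labels" in cfg:
            labels = resolve(cfg["area_labels"]).read_text().split()
            if len(labels) != g.n_areas:
                raise ValueError(
                    f"{len(labels)} area labels for a {g.n_areas}-area graph"
                )
            g = _graph.AdjacencyGraph(tuple(labels), g.edges, g.component_labels)
    elif "geojson" in cfg:
        items = _graph.read_geojson(resolve(cfg["geojson"]), cfg.get("id_property", "id"))
        g = _graph.build_contiguity_graph(items, rule=cfg.get("contiguity", "queen"))
    else:
        raise ValueError("config needs a 'graph' or 'geojson' entry")

    records = read_records_csv(resolve(cfg["records"]))
    summ = summarize(
        records,
        area_ids=list(g.area_ids),
        degeneracy_rule=cfg.get("degeneracy_rule", "continuity"),
    )

    covariates = None
    if "covariates" in cfg:
        covariates = pd.read_csv(resolve(cfg["covariates"])).set_index("area_id")
    terms = [t.strip() for t in cfg.get("use_covariates", "").split(",") if t.strip()]

    spec = make_model(
        cfg.get("variant", "II"),
        g,
        covariates=terms,
        region=int(cfg["region"]) if "region" in cfg else None,
    )
    kwargs = {}
    if "grid_step" in cfg:
        kwargs["step"] = float(cfg["grid_step"])
    fit = fit_model(spec, g, summ, covariate_table=covariates, **kwargs)
    if "output" in cfg:
        fit.export_csv(resolve(cfg["output"]), seed=int(cfg.get("seed", 20150101)))
    return fit
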