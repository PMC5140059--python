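"""File formats: network specs (YAML), snapshot tables (CSV), result tables."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .network import CandidateLibrary, Reaction, ReactionNetwork, make_species
from .simulate import SnapshotSeries

__all__ = [
    "read_network_spec",
    "write_network_spec",
    "read_snapshots",
    "write_snapshots",
    "write_selection_tables",
    "write_run_metadata",
]


def read_network_spec(path) -> dict:
    """Load a network specification.

    Blocks: ``species`` (list of names), ``reactions`` (list of
    ``{reactants, products, rate}``; rate optional), optional ``modules``
    (name -> species list) and ``cross_module_reactions`` (list of
    ``{reactants, products}``).  Returns a dict with a ``network``
    (:class:`ReactionNetwork`) plus the raw module blocks.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    species = make_species(list(doc["species"]))
    idx = {s.name: s.index for s in species}
    reactions = []
    for i, r in enumerate(doc.get("reactions", [])):
        reactions.append(
            Reaction(
                tuple(idx[n] for n in r.get("reactants", [])),
                tuple(idx[n] for n in r.get("products", [])),
                rate_id=i,
                rate_value=float(r["rate"]) if r.get("rate") is not None else None,
            )
        )
    net = ReactionNetwork(species, reactions)
    constraint = None
    if "modules" in doc:
        constraint = {
            "modules": doc["modules"],
            "cross_module_reactions": [
                (r["reactants"], r["products"])
                for r in doc.get("cross_module_reactions", [])
            ],
        }
    return {"network": net, "module_constraint": constraint}


def write_network_spec(path, network: ReactionNetwork, module_constraint=None):
    names = network.species_names
    doc = {
        "species": names,
        "reactions": [
            {
                "reactants": [names[i] for i in r.reactants],
                "products": [names[i] for i in r.products],
                **({"rate": float(r.rate_value)} if r.rate_value is not None else {}),
            }
            for r in network.reactions
        ],
    }
    if module_constraint:
        doc["modules"] = module_constraint["modules"]
        doc["cross_module_reactions"] = [
            {"reactants": list(a), "products": list(b)}
            for a, b in module_constraint.get("cross_module_reactions", [])
        ]
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def snapshots_to_frame(s: SnapshotSeries) -> pd.DataFrame:
    frames = []
    for t, x in zip(s.time_points, s.counts):
        df = pd.DataFrame(x, columns=s.species_names)
        df.insert(0, "cell", np.arange(x.shape[0]))
        df.insert(0, "time", t)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def write_snapshots(path, s: SnapshotSeries):
    snapshots_to_frame(s).to_csv(path, index=False)


def read_snapshots(path, noise_p=None, replicate_id=0) -> SnapshotSeries:
    df = pd.read_csv(path)
    species = [c for c in df.columns if c not in ("time", "cell")]
    times = np.sort(df["time"].unique())
    counts = [
        df.loc[df["time"] == t, species].to_numpy(dtype=np.int64) for t in times
    ]
    return SnapshotSeries(times, counts, species, noise_p, replicate_id)


def write_selection_tables(outdir, result, library: CandidateLibrary):
    """Write the per-penalty path table and the final-model table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rx = library.network.reactions
    names = library.network.species_names
    path = result.path
    rows = []
    for i, lam in enumerate(path.lambda_grid):
        for j, col in enumerate(path.support):
            rows.append(
                {
                    "lambda": lam,
                    "reaction": rx[col].label(library.network.species),
                    "coefficient": path.coefficients[i, j],
                    "cv_error": path.cv_error[i],
                    "stability_freq": path.stability_freq[i, j],
                    "bic": path.bic[i],
                }
            )
    pd.DataFrame(rows).to_csv(outdir / "path.csv", index=False)

    sel = result.selection
    rows = []
    for idx, k in zip(sel.selected, sel.k_hat):
        r = rx[idx]
        rows.append(
            {
                "reaction": r.label(library.network.species),
                "reactants": "+".join(names[i] for i in r.reactants),
                "products": "+".join(names[i] for i in r.products),
                "k_hat": k,
                "stability_freq": sel.provenance.get(int(idx), np.nan),
            }
        )
    pd.DataFrame(rows).to_csv(outdir / "final_model.csv", index=False)


def write_run_metadata(path, config: dict):
    with open(path, "w") as fh:
        json.dump(config, fh, indent=2, default=str)
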