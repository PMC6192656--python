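"""Model (de)serialization to a structured-text schema.

Schema (YAML or JSON, chosen by file suffix)::

    proteins:
      - {id, f, theta, beta, gcc?, nonmetabolic?, operon?}
    shared:
      - {id, theta, beta, members: [{id, weight}, ...]}
    growth:
      {type: monod, mu_max, phi_half, target: [ids]}   # or
      {type: gcc, mu0}                                  # GCCs live on proteins

Round-trips losslessly for models built by this package.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from .model import (
    CellModel,
    ConfigurationError,
    MonodGrowth,
    OUNoiseSpec,
    ProteinSpec,
    SharedNoiseSpec,
)

__all__ = ["model_to_dict", "model_from_dict", "save_model", "load_model"]


def model_to_dict(model: CellModel) -> dict:
    d: dict = {"proteins": [], "shared": []}
    for p in model.proteins:
        entry: dict = {
            "id": p.id,
            "f": float(p.f),
            "theta": float(p.private_noise.theta),
            "beta": float(p.private_noise.beta),
        }
        if p.gcc is not None:
            entry["gcc"] = float(p.gcc)
        if p.nonmetabolic:
            entry["nonmetabolic"] = True
        if p.operon is not None:
            entry["operon"] = p.operon
        d["proteins"].append(entry)
    for s in model.shared:
        d["shared"].append(
            {
                "id": s.id,
                "theta": float(s.noise.theta),
                "beta": float(s.noise.beta),
                "members": [{"id": pid, "weight": float(w)} for pid, w in s.members],
            }
        )
    if isinstance(model.growth, MonodGrowth):
        d["growth"] = {
            "type": "monod",
            "mu_max": float(model.growth.mu_max),
            "phi_half": float(model.growth.phi_half),
            "target": sorted(model.growth.target),
        }
    elif model.growth is not None:
        raise ConfigurationError(
            f"cannot serialize growth function {type(model.growth).__name__}"
        )
    else:
        d["growth"] = {"type": "gcc", "mu0": float(model.mu0)}
    return d


def model_from_dict(d: dict) -> CellModel:
    try:
        proteins = tuple(
            ProteinSpec(
                id=str(e["id"]),
                f=float(e["f"]),
                private_noise=OUNoiseSpec(f"N_{e['id']}", float(e["theta"]), float(e["beta"])),
                gcc=float(e["gcc"]) if "gcc" in e and e["gcc"] is not None else None,
                nonmetabolic=bool(e.get("nonmetabolic", False)),
                operon=e.get("operon"),
            )
            for e in d["proteins"]
        )
        shared = tuple(
            SharedNoiseSpec(
                id=str(e["id"]),
                noise=OUNoiseSpec(f"N_{e['id']}", float(e["theta"]), float(e["beta"])),
                members=tuple((str(mm["id"]), float(mm["weight"])) for mm in e["members"]),
            )
            for e in d.get("shared", [])
        )
        g = d.get("growth") or {}
        gtype = g.get("type")
        if gtype == "monod":
            growth = MonodGrowth(
                mu_max=float(g["mu_max"]),
                phi_half=float(g["phi_half"]),
                target=frozenset(str(x) for x in g["target"]),
            )
            mu0 = None
        elif gtype == "gcc":
            growth = None
            mu0 = float(g["mu0"])
        else:
            raise ConfigurationError(f"unknown growth type {gtype!r}")
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigurationError(f"malformed model config: {exc}") from exc
    return CellModel(proteins=proteins, shared=shared, growth=growth, mu0=mu0)


def save_model(model: CellModel, path: str | Path) -> None:
    path = Path(path)
    d = model_to_dict(model)
    if path.suffix == ".json":
        path.write_text(json.dumps(d, indent=1, sort_keys=True))
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=True))


def load_model(path: str | Path) -> CellModel:
    path = Path(path)
    text = path.read_text()
    d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return model_from_dict(d)
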