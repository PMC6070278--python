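"""Read/write network specifications as YAML or JSON documents."""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from protoflux.metabolism.network import CatalystSpec, MetaboliteSpec, NetworkSpec

__all__ = ["network_to_dict", "network_from_dict", "read_network", "write_network"]


def network_to_dict(network: NetworkSpec) -> dict:
    return {
        "name": network.name,
        "metabolites": [
            {"id": m.id, "kind": m.kind, "permeability": m.permeability}
            for m in network.metabolites
        ],
        "catalysts": [
            {
                "id": c.id,
                "kcat": c.kcat,
                "substrates": list(c.substrates),
                "products": dict(c.products),
                "Km": c.Km,
                "saturated": c.saturated,
                "a1": c.a1,
                "a2": c.a2,
            }
            for c in network.catalysts
        ],
    }


def network_from_dict(doc: dict) -> NetworkSpec:
    metabolites = [
        MetaboliteSpec(
            id=m["id"], kind=m["kind"], permeability=float(m.get("permeability", 0.0))
        )
        for m in doc["metabolites"]
    ]
    catalysts = [
        CatalystSpec(
            id=c["id"],
            kcat=float(c["kcat"]),
            substrates=tuple(c["substrates"]),
            products={k: float(v) for k, v in c.get("products", {}).items()},
            Km=float(c.get("Km", 1.0)),
            saturated=bool(c.get("saturated", False)),
            a1=float(c.get("a1", 1.0)),
            a2=float(c.get("a2", 1.0)),
        )
        for c in doc["catalysts"]
    ]
    return NetworkSpec(name=doc.get("name", "network"), metabolites=metabolites, catalysts=catalysts)


def read_network(path: str | Path) -> NetworkSpec:
    path = Path(path)
    text = path.read_text()
    doc = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return network_from_dict(doc)


def write_network(network: NetworkSpec, path: str | Path) -> None:
    path = Path(path)
    doc = network_to_dict(network)
    if path.suffix == ".json":
        path.write_text(json.dumps(doc, indent=2))
    else:
        path.write_text(yaml.safe_dump(doc, sort_keys=False))
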