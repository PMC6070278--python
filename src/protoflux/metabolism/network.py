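"""Specification of irreversible catalysed reaction networks.

Networks are feed-forward: catalysts consume either environmental
inputs (plentiful, constant concentration) or intermediates produced by
exactly one upstream catalyst (non-competing wiring), and may produce
the single critical output metabolite whose flux is the protocell
fitness.  Intermediates leak through the membrane at rate ``delta``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

ENVIRONMENTAL_INPUT = "environmental_input"
INTERMEDIATE = "intermediate"
CRITICAL_OUTPUT = "critical_output"

_KINDS = frozenset({ENVIRONMENTAL_INPUT, INTERMEDIATE, CRITICAL_OUTPUT})


class NetworkValidationError(ValueError):
    """A network specification violates a structural invariant."""


@dataclass(frozen=True)
class MetaboliteSpec:
    """A metabolite: environmental input, leaky intermediate, or the
    critical output."""

    id: str
    kind: str
    permeability: float = 0.0  # leak/decay rate of intermediates

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise NetworkValidationError(f"unknown metabolite kind {self.kind!r}")
        if self.permeability < 0:
            raise NetworkValidationError("permeability must be >= 0")


@dataclass(frozen=True)
class CatalystSpec:
    """A catalytic sequence type and its reaction.

    ``products`` maps metabolite id -> stoichiometric coefficient; the
    coefficient on the critical output is the catalyst's metabolite
    benefit (c_M), coefficients on intermediates are waste outputs
    (c_W).  ``Km``, ``a1``, ``a2`` only matter at finite membrane
    permeability; they drop out of the piecewise-linear limit.
    """

    id: str
    kcat: float
    substrates: tuple[str, ...]
    products: dict[str, float] = field(default_factory=dict)
    Km: float = 1.0
    saturated: bool = False
    a1: float = 1.0
    a2: float = 1.0

    def __post_init__(self) -> None:
        if self.kcat <= 0:
            raise NetworkValidationError(f"catalyst {self.id}: kcat must be > 0")
        if self.Km <= 0:
            raise NetworkValidationError(f"catalyst {self.id}: Km must be > 0")
        if len(self.substrates) not in (1, 2):
            raise NetworkValidationError(
                f"catalyst {self.id}: needs 1 or 2 substrates, got {len(self.substrates)}"
            )
        if any(c <= 0 for c in self.products.values()):
            raise NetworkValidationError(
                f"catalyst {self.id}: stoichiometric coefficients must be > 0"
            )
        if self.saturated and len(self.substrates) != 1:
            raise NetworkValidationError(
                f"catalyst {self.id}: saturated catalysts are unimolecular"
            )

    @property
    def bimolecular(self) -> bool:
        return len(self.substrates) == 2


@dataclass
class NetworkSpec:
    """A named catalysed reaction network."""

    name: str
    metabolites: list[MetaboliteSpec]
    catalysts: list[CatalystSpec]

    def __post_init__(self) -> None:
        self.validate()

    # -- lookups ---------------------------------------------------------

    def metabolite(self, mid: str) -> MetaboliteSpec:
        return self._metabolites[mid]

    @property
    def catalyst_ids(self) -> tuple[str, ...]:
        return tuple(c.id for c in self.catalysts)

    @property
    def n_catalysts(self) -> int:
        return len(self.catalysts)

    @property
    def critical_metabolite(self) -> str:
        return self._critical

    def producer_of(self, mid: str) -> CatalystSpec | None:
        """The unique catalyst producing intermediate ``mid`` (or None)."""
        return self._producer.get(mid)

    def topological_order(self) -> list[CatalystSpec]:
        """Catalysts ordered so every producer precedes its consumer."""
        return list(self._topo)

    # -- validation ------------------------------------------------------

    def validate(self) -> None:
        self._metabolites = {m.id: m for m in self.metabolites}
        if len(self._metabolites) != len(self.metabolites):
            raise NetworkValidationError("duplicate metabolite ids")
        cat_ids = [c.id for c in self.catalysts]
        if len(set(cat_ids)) != len(cat_ids):
            raise NetworkValidationError("duplicate catalyst ids")

        outputs = [m.id for m in self.metabolites if m.kind == CRITICAL_OUTPUT]
        if len(outputs) != 1:
            raise NetworkValidationError(
                f"exactly one critical_output required, found {len(outputs)}"
            )
        self._critical = outputs[0]

        producer: dict[str, CatalystSpec] = {}
        for cat in self.catalysts:
            for mid in set(cat.substrates) | set(cat.products):
                if mid not in self._metabolites:
                    raise NetworkValidationError(
                        f"catalyst {cat.id} references unknown metabolite {mid!r}"
                    )
            for mid, _ in cat.products.items():
                kind = self._metabolites[mid].kind
                if kind == ENVIRONMENTAL_INPUT:
                    raise NetworkValidationError(
                        f"environmental input {mid!r} must not be produced internally"
                    )
                if kind == INTERMEDIATE:
                    if mid in producer:
                        raise NetworkValidationError(
                            f"intermediate {mid!r} produced by more than one catalyst"
                        )
                    producer[mid] = cat
            if self._critical in cat.substrates:
                raise NetworkValidationError("the critical output cannot be consumed")
            for mid in cat.substrates:
                kind = self._metabolites[mid].kind
                if cat.saturated and kind != ENVIRONMENTAL_INPUT:
                    raise NetworkValidationError(
                        f"saturated catalyst {cat.id} must consume an environmental input"
                    )
        self._producer = producer

        consumers: dict[str, list[str]] = {}
        for cat in self.catalysts:
            for mid in cat.substrates:
                kind = self._metabolites[mid].kind
                if kind == INTERMEDIATE:
                    consumers.setdefault(mid, []).append(cat.id)
                    if mid not in producer:
                        raise NetworkValidationError(
                            f"intermediate {mid!r} consumed by {cat.id} has no producer"
                        )
        for mid, cons in consumers.items():
            if len(cons) > 1:
                raise NetworkValidationError(
                    f"intermediate {mid!r} consumed by several catalysts "
                    f"({', '.join(cons)}): competing reactions are not modelled"
                )

        if not any(c.saturated for c in self.catalysts):
            raise NetworkValidationError("at least one saturated (keystone) catalyst required")

        # acyclicity of the catalyst dependency digraph (via intermediates)
        graph = nx.DiGraph()
        graph.add_nodes_from(cat.id for cat in self.catalysts)
        by_id = {c.id: c for c in self.catalysts}
        for cat in self.catalysts:
            for mid in cat.substrates:
                up = producer.get(mid)
                if up is not None:
                    graph.add_edge(up.id, cat.id)
        if not nx.is_directed_acyclic_graph(graph):
            raise NetworkValidationError("intermediate wiring must be acyclic")
        self._topo = [by_id[cid] for cid in nx.lexicographical_topological_sort(graph)]

    # -- convenience -----------------------------------------------------

    def cm(self, catalyst_id: str) -> float:
        """Stoichiometric coefficient of the critical output for a catalyst
        (0 if it produces none)."""
        cat = next(c for c in self.catalysts if c.id == catalyst_id)
        return cat.products.get(self._critical, 0.0)

    @property
    def composition_types(self) -> tuple[str, ...]:
        """Type order for compositions over this network: catalysts then omega."""
        return self.catalyst_ids + ("omega",)
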