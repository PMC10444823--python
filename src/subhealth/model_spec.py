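"""Latent-variable model declaration.

A path model is a set of *constructs* (latent variables), each measured by a
block of observed indicators in either reflective (Mode A) or formative
(Mode B) fashion, together with a directed acyclic set of structural paths
between constructs.  The five-construct subhealth physical-examination model
(routine blood test, lipid metabolism, liver function, sublingual-vein
characteristics, obesity) ships as the packaged default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import yaml

__all__ = [
    "Construct",
    "ModelSpec",
    "ModelSpecError",
    "build_model",
    "exogenous_and_endogenous",
    "load_model",
    "subhealth_model",
]

MODES = ("reflective", "formative")


class ModelSpecError(ValueError):
    """Raised for an inconsistent model declaration (cycle, unknown name, ...)."""


@dataclass(frozen=True)
class Construct:
    """A latent variable with its measurement block.

    Parameters
    ----------
    name : str
        Construct identifier, unique within the model.
    mode : {"reflective", "formative"}
        Measurement mode: reflective indicators are manifestations of the
        construct (Mode A), formative indicators jointly compose it (Mode B).
    indicators : tuple of str
        Ordered indicator (column) names; order is preserved in all reports.
    """

    name: str
    mode: str
    indicators: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ModelSpecError(f"unknown measurement mode {self.mode!r}")
        if len(self.indicators) == 0:
            raise ModelSpecError(f"construct {self.name!r} has an empty indicator block")
        object.__setattr__(self, "indicators", tuple(self.indicators))
        if len(set(self.indicators)) != len(self.indicators):
            raise ModelSpecError(f"duplicate indicator within construct {self.name!r}")


@dataclass(frozen=True)
class ModelSpec:
    """Validated constructs + acyclic structural paths."""

    constructs: tuple[Construct, ...]
    paths: tuple[tuple[str, str], ...] = field(default_factory=tuple)

    # -- views -------------------------------------------------------------
    @property
    def construct_names(self) -> list[str]:
        return [c.name for c in self.constructs]

    @property
    def indicator_names(self) -> list[str]:
        return [x for c in self.constructs for x in c.indicators]

    def construct(self, name: str) -> Construct:
        for c in self.constructs:
            if c.name == name:
                return c
        raise KeyError(name)

    def predecessors(self, name: str) -> list[str]:
        return [s for s, t in self.paths if t == name]

    def successors(self, name: str) -> list[str]:
        return [t for s, t in self.paths if s == name]

    def topological_order(self) -> list[str]:
        """Kahn topological sort of construct names; raises on a cycle."""
        names = self.construct_names
        indeg = {n: 0 for n in names}
        for _, t in self.paths:
            indeg[t] += 1
        queue = [n for n in names if indeg[n] == 0]
        order: list[str] = []
        while queue:
            n = queue.pop(0)
            order.append(n)
            for t in self.successors(n):
                indeg[t] -= 1
                if indeg[t] == 0:
                    queue.append(t)
        if len(order) != len(names):
            raise ModelSpecError("structural path graph contains a cycle")
        return order

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "constructs": [
                {"name": c.name, "mode": c.mode, "indicators": list(c.indicators)}
                for c in self.constructs
            ],
            "paths": [[s, t] for s, t in self.paths],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return build_model(
            [(c["name"], c["mode"], c["indicators"]) for c in d["constructs"]],
            [tuple(p) for p in d.get("paths", [])],
        )

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=2)
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict(), sort_keys=False)
        )
        path.write_text(text)


def build_model(
    constructs: Iterable[Construct | tuple[str, str, Sequence[str]]],
    paths: Iterable[tuple[str, str]] = (),
) -> ModelSpec:
    """Validate and assemble a :class:`ModelSpec`.

    ``constructs`` may be :class:`Construct` objects or ``(name, mode,
    indicators)`` tuples.  Validation rejects duplicate construct or
    indicator names, self-paths, duplicate paths, paths naming unknown
    constructs, and any cycle in the path graph.
    """
    cons = tuple(
        c if isinstance(c, Construct) else Construct(c[0], c[1], tuple(c[2]))
        for c in constructs
    )
    names = [c.name for c in cons]
    if len(set(names)) != len(names):
        raise ModelSpecError("duplicate construct name")
    all_inds = [x for c in cons for x in c.indicators]
    if len(set(all_inds)) != len(all_inds):
        raise ModelSpecError("indicator assigned to more than one construct")
    plist: list[tuple[str, str]] = []
    for s, t in paths:
        if s not in names or t not in names:
            raise ModelSpecError(f"path ({s!r}, {t!r}) references an undeclared construct")
        if s == t:
            raise ModelSpecError(f"self-path on construct {s!r}")
        if (s, t) in plist:
            raise ModelSpecError(f"duplicate path ({s!r}, {t!r})")
        plist.append((s, t))
    spec = ModelSpec(cons, tuple(plist))
    spec.topological_order()  # acyclicity check
    return spec


def exogenous_and_endogenous(spec: ModelSpec) -> tuple[list[str], list[str]]:
    """Partition construct names into (exogenous, endogenous).

    A construct is endogenous iff it has at least one incoming path.
    """
    endo = {t for _, t in spec.paths}
    return (
        [n for n in spec.construct_names if n not in endo],
        [n for n in spec.construct_names if n in endo],
    )


def load_model(path: str | Path) -> ModelSpec:
    """Load a model declaration from a YAML or JSON document."""
    text = Path(path).read_text()
    d = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    return ModelSpec.from_dict(d)


def subhealth_model() -> ModelSpec:
    """The packaged default five-construct subhealth model.

    Four reflective blocks (routine blood test, lipid metabolism, liver
    function, SV characteristics), one formative block (obesity), and the
    five hypothesised structural paths, including the blood→SV path that the
    structural analysis does not support.
    """
    with resources.files("subhealth.data").joinpath("subhealth_model.yaml").open() as fh:
        return ModelSpec.from_dict(yaml.safe_load(fh))
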