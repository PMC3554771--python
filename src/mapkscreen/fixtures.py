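"""Frozen parameter sets with known qualitative dynamics.

Each fixture names a cascade variant (topology, concentration vector,
28-rate vector) whose qualitative labels — responsive, ultrasensitive,
bistable, temporal class — were established by running this package's own
dose-response protocol at default and 10x tighter solver tolerances, via
the seeded search in ``scripts/find_fixtures.py``.  The parameter files
under ``data/fixtures/`` are synthetic: they are this package's own
constructions, not parameters from any published system-specific model.

Catalog: quiescent, linear-responder, ultrasensitive, bistable, oscillator,
transient.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

from .network import ConcentrationVector, KineticRates, Topology

__all__ = ["Fixture", "make_fixture", "FIXTURE_NAMES", "UnknownFixtureError"]

FIXTURE_NAMES = ("quiescent", "linear-responder", "ultrasensitive",
                 "bistable", "oscillator", "transient")


class UnknownFixtureError(KeyError):
    """Fixture name not in the documented catalog."""


@dataclass(frozen=True)
class Fixture:
    """A named parameter set with verified qualitative labels."""

    name: str
    topology: Topology
    cv: ConcentrationVector
    rates: KineticRates
    expected: dict
    provenance: str

    @classmethod
    def from_dict(cls, data: dict) -> "Fixture":
        return cls(
            name=data["name"],
            topology=Topology.coerce(data["topology"]),
            cv=ConcentrationVector(**data["cv"]),
            rates=KineticRates(dict(data["rates"])),
            expected=dict(data["expected"]),
            provenance=data.get("provenance", ""),
        )

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "topology": self.topology.value,
            "cv": {"mapkk": self.cv.mapkk, "mapk": self.cv.mapk,
                   "m2kp": self.cv.m2kp, "mkp": self.cv.mkp},
            "rates": dict(self.rates.values),
            "expected": dict(self.expected),
            "provenance": self.provenance,
        }


def _fixture_path(name: str):
    return resources.files("mapkscreen").joinpath(f"data/fixtures/{name}.yaml")


def make_fixture(name: str) -> Fixture:
    """Load a catalog fixture by name."""
    if name not in FIXTURE_NAMES:
        raise UnknownFixtureError(
            f"unknown fixture {name!r}; catalog: {FIXTURE_NAMES}")
    path = _fixture_path(name)
    return Fixture.from_dict(yaml.safe_load(path.read_text()))


def load_fixture_file(path: str | Path) -> Fixture:
    """Load a fixture from an arbitrary parameter file."""
    return Fixture.from_dict(yaml.safe_load(Path(path).read_text()))
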