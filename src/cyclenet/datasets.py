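"""Packaged data and seeded generators for test and example inputs.

The package ships the 14-gene cell cycle interaction table (with its
gene labelling) and a reference parameter set for the five-gene ODE
system.  Seeded generators provide random interaction tables and random
stable parameter sets for property testing.
"""

from __future__ import annotations

import json
from importlib import resources

import numpy as np

from .interactions import Interaction, InteractionTable, parse_interaction_table
from .ode import ODEParameters

__all__ = [
    "KEY_GENES",
    "load_fixture",
    "load_interaction_table",
    "load_reference_params",
    "random_table",
    "random_stable_params",
]

# The five hub regulators, in x1..x5 order.
KEY_GENES: tuple[str, ...] = ("CCNB1", "TP53", "CCND1", "CDKN1B", "CDH1")

_DATA = resources.files(__package__) / "data"


def load_interaction_table() -> InteractionTable:
    """The packaged 14-gene interaction table."""
    return parse_interaction_table((_DATA / "cellcycle_interactions.csv").read_text())


def load_reference_params() -> ODEParameters:
    """The packaged reference coefficients of the five-gene ODE system."""
    return ODEParameters.from_dict(json.loads((_DATA / "cellcycle_params.json").read_text()))


def load_fixture(name: str):
    """Load a packaged object by short name (``table1`` or ``table3``)."""
    if name == "table1":
        return load_interaction_table()
    if name == "table3":
        return load_reference_params()
    raise KeyError(f"unknown fixture {name!r} (expected 'table1' or 'table3')")


def random_table(n_genes: int, edge_density: float = 0.5, seed: int = 0) -> InteractionTable:
    """Seeded random interaction table.

    Each cell is drawn independently: regulation with probability
    ``edge_density/2``, binding with ``edge_density/4``, both with
    ``edge_density/4``, otherwise empty.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if not 0.0 <= edge_density <= 1.0:
        raise ValueError("edge_density must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    choices = np.array(
        [Interaction.REGULATES, Interaction.BINDS, Interaction.BOTH, Interaction.NONE],
        dtype=object,
    )
    probs = [edge_density / 2, edge_density / 4, edge_density / 4, 1.0 - edge_density]
    grid = rng.choice(choices, size=(n_genes, n_genes), p=probs)
    labels = tuple(f"G{i + 1}" for i in range(n_genes))
    return InteractionTable(labels=labels, codes=tuple(tuple(row) for row in grid))


def random_stable_params(seed: int = 0) -> ODEParameters:
    """Seeded random parameter set with a stabilizing linear part.

    The self-interaction coefficients (r11, r22, r32, r43, r54) are
    drawn uniform in [-2, -1] and the cross terms are small and
    nonnegative, giving a diagonally dominant negative linear part so
    the system almost always relaxes to a steady state.
    """
    rng = np.random.default_rng(seed)
    diagonal = {"r11", "r22", "r32", "r43", "r54"}
    values = {}
    for name in ODEParameters.__dataclass_fields__:
        if name in diagonal:
            values[name] = rng.uniform(-2.0, -1.0)
        elif name == "r24":
            values[name] = rng.uniform(0.0, 0.5)
        else:
            values[name] = rng.uniform(0.0, 0.6)
    return ODEParameters.from_dict(values)
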